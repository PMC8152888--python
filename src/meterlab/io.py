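"""File formats: WAV stimuli/tapping, EDF and columnar-text EEG, TSV manifests.

Columnar text is the plain interchange format: first column time (s), one
column per channel, tab-separated with a header row.  EDF reading goes
through :mod:`mne` (imported lazily so the dependency stays optional).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile


@dataclass
class Recording:
    data: np.ndarray  # channels × samples
    rate: float
    ch_names: list[str]


def write_wav(path: str | Path, samples: np.ndarray, rate: float) -> Path:
    path = Path(path)
    wavfile.write(path, int(round(rate)), np.asarray(samples, dtype=np.float32))
    return path


def read_wav(path: str | Path, mono_only: bool = True) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    rate, data = wavfile.read(path)
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    else:
        data = data.T
    if mono_only and data.shape[0] != 1:
        raise ValueError(
            f"{path} has {data.shape[0]} channels; the tapping path expects mono WAV"
        )
    return Recording(data, float(rate), [f"ch{i}" for i in range(data.shape[0])])


def write_columnar(path: str | Path, data: np.ndarray, rate: float,
                   ch_names: list[str] | None = None) -> Path:
    data = np.atleast_2d(np.asarray(data))
    ch_names = ch_names or [f"ch{i}" for i in range(data.shape[0])]
    t = np.arange(data.shape[1]) / rate
    df = pd.DataFrame({"time": t, **{n: data[i] for i, n in enumerate(ch_names)}})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return Path(path)


def read_columnar(path: str | Path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    if "time" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected a 'time' column plus channel columns")
    t = df["time"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: too few samples to infer the sampling rate")
    rate = 1.0 / float(np.median(np.diff(t)))
    chans = [c for c in df.columns if c != "time"]
    return Recording(df[chans].to_numpy().T, rate, chans)


def read_edf(path: str | Path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    import mne  # lazy: optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names))


def read_signals(path: str | Path, format: str | None = None) -> Recording:
    """Dispatch on explicit format or file suffix: edf | columnar | wav."""
    path = Path(path)
    fmt = format or {".edf": "edf", ".wav": "wav"}.get(path.suffix.lower(), "columnar")
    if fmt == "edf":
        return read_edf(path)
    if fmt == "wav":
        return read_wav(path)
    if fmt == "columnar":
        return read_columnar(path)
    raise ValueError(f"unknown format {fmt!r}")


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t")


def write_manifest(path: str | Path, df: pd.DataFrame) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def load_config(path: str | Path) -> dict:
    """YAML or TOML config by suffix."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(path.read_text()) or {}
    if path.suffix == ".toml":
        import tomllib

        return tomllib.loads(path.read_text())
    raise ValueError(f"unsupported config format: {path.suffix}")
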