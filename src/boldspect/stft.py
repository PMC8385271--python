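"""Short-time Fourier transform spectrograms of voxel time series.

Each selected voxel's BOLD series is cut into overlapping windows of
``window_seconds`` (default 10 s = 5 samples at TR 2 s), each window is
tapered, zero-padded to ``fft_length`` (default 60) and Fourier-transformed;
the one-sided magnitudes form a frequency x time image. With the defaults
and a 60-volume run this yields the 31 x 56 spectrogram geometry consumed
by the CNN: (60 - 5)/1 + 1 = 56 frames and 60//2 + 1 = 31 bins.

The DFT convention is unscaled (plain ``sum x_n e^{-2*pi*i*k*n/N}``): for a
boxcar window and two-sided transform each frame satisfies
``sum|X|^2 = fft_length * sum|windowed x|^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import get_window

from .cohort import BoldRun
from .selection import VoxelSelection

__all__ = [
    "StftConfig",
    "Spectrogram",
    "stft",
    "normalize",
    "extract_dataset",
    "stack_dataset",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class StftConfig:
    window_seconds: float = 10.0
    hop_samples: int = 1
    fft_length: int = 60
    window_function: str = "hann"  # or "boxcar"
    one_sided: bool = True
    magnitude: bool = True  # False -> power (|X|^2)

    def window_samples(self, tr_seconds: float) -> int:
        w = int(round(self.window_seconds / tr_seconds))
        if w < 2:
            raise ValueError(
                f"window of {self.window_seconds} s is under 2 samples at TR "
                f"{tr_seconds} s"
            )
        if self.fft_length < w:
            raise ValueError("fft_length must be >= window length in samples")
        if not (1 <= self.hop_samples <= w):
            raise ValueError("hop_samples must lie in [1, window_samples]")
        return w

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "StftConfig":
        return cls(**d)


@dataclass
class Spectrogram:
    """One voxel's time-frequency image with axis metadata."""

    values: np.ndarray  # n_freq x n_frames, >= 0
    freq_axis_hz: np.ndarray
    time_axis_seconds: np.ndarray
    voxel_coordinate: tuple[int, int, int] | None = None
    subject_id: str | None = None
    label: int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def stft(series: np.ndarray, tr_seconds: float, cfg: StftConfig | None = None) -> Spectrogram:
    """Spectrogram of one series; frame m covers samples [m*hop, m*hop + window)."""
    cfg = cfg or StftConfig()
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1D")
    win = cfg.window_samples(tr_seconds)
    n = series.size
    if n < win:
        raise ValueError(f"series of {n} samples is shorter than the {win}-sample window")
    hop = cfg.hop_samples
    frames = np.lib.stride_tricks.sliding_window_view(series, win)[::hop]
    taper = get_window(cfg.window_function, win, fftbins=True)
    windowed = frames * taper
    if cfg.one_sided:
        Z = np.fft.rfft(windowed, n=cfg.fft_length, axis=1)
    else:
        Z = np.fft.fft(windowed, n=cfg.fft_length, axis=1)
    mag = np.abs(Z) if cfg.magnitude else np.abs(Z) ** 2
    n_freq = Z.shape[1]
    freq = np.arange(n_freq) / (cfg.fft_length * tr_seconds)
    n_frames = frames.shape[0]
    times = (np.arange(n_frames) * hop + win / 2.0) * tr_seconds
    return Spectrogram(
        values=mag.T.copy(), freq_axis_hz=freq, time_axis_seconds=times
    )


def normalize(spec: Spectrogram, mode: str = "minmax") -> Spectrogram:
    """Rescale a spectrogram; a constant image maps to all-zeros in any mode."""
    v = spec.values
    if mode == "none":
        out = v.copy()
    elif mode == "minmax":
        lo, hi = v.min(), v.max()
        out = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    elif mode == "zscore":
        sd = v.std()
        out = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(spec, values=out)


def extract_dataset(
    runs: list[BoldRun],
    selection: VoxelSelection,
    cfg: StftConfig | None = None,
    normalize_mode: str | None = None,
) -> list[Spectrogram]:
    """One spectrogram per (subject, selected voxel), subject-major order."""
    if len(selection) == 0:
        raise ValueError("selection is empty")
    cfg = cfg or StftConfig()
    out: list[Spectrogram] = []
    for run in runs:
        grid = run.grid_shape
        for xyz in selection.coordinates:
            x, y, z = (int(c) for c in xyz)
            if not (0 <= x < grid[0] and 0 <= y < grid[1] and 0 <= z < grid[2]):
                raise IndexError(
                    f"selected voxel {(x, y, z)} outside grid {grid} "
                    f"for subject {run.subject_id}"
                )
            spec = stft(run.data[x, y, z], run.paradigm.tr_seconds, cfg)
            if normalize_mode is not None:
                spec = normalize(spec, normalize_mode)
            spec.voxel_coordinate = (x, y, z)
            spec.subject_id = run.subject_id
            spec.label = run.label
            out.append(spec)
    return out


def stack_dataset(
    specs: list[Spectrogram],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack spectrograms into (X, y, subject_ids) arrays for classifiers."""
    X = np.stack([s.values for s in specs])
    y = np.array([s.label for s in specs], dtype=int)
    subjects = [s.subject_id for s in specs]
    return X, y, subjects


def save_dataset(specs: list[Spectrogram], directory: str | Path) -> Path:
    """Persist a spectrogram dataset: one array container + TSV index + YAML."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X, y, subjects = stack_dataset(specs)
    np.savez_compressed(directory / "spectrograms.npz", values=X)
    idx = pd.DataFrame(
        {
            "slot": np.arange(len(specs)),
            "subject_id": subjects,
            "label": y,
            "x": [s.voxel_coordinate[0] for s in specs],
            "y": [s.voxel_coordinate[1] for s in specs],
            "z": [s.voxel_coordinate[2] for s in specs],
        }
    )
    idx.to_csv(directory / "index.tsv", sep="\t", index=False)
    meta = {
        "n_freq": int(X.shape[1]),
        "n_frames": int(X.shape[2]),
        "freq_axis_hz": [float(f) for f in specs[0].freq_axis_hz],
        "time_axis_seconds": [float(t) for t in specs[0].time_axis_seconds],
    }
    with open(directory / "geometry.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    return directory / "index.tsv"


def load_dataset(directory: str | Path) -> list[Spectrogram]:
    directory = Path(directory)
    X = np.load(directory / "spectrograms.npz")["values"]
    idx = pd.read_csv(directory / "index.tsv", sep="\t", dtype={"subject_id": str})
    with open(directory / "geometry.yaml") as fh:
        meta = yaml.safe_load(fh)
    freq = np.array(meta["freq_axis_hz"])
    times = np.array(meta["time_axis_seconds"])
    return [
        Spectrogram(
            values=X[row.slot],
            freq_axis_hz=freq,
            time_axis_seconds=times,
            voxel_coordinate=(int(row.x), int(row.y), int(row.z)),
            subject_id=str(row.subject_id),
            label=int(row.label),
        )
        for row in idx.itertuples(index=False)
    ]
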