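"""Block-design paradigm timing and the canonical haemodynamic response.

A block paradigm alternates fixed-duration task and rest periods; the BOLD
response it evokes is modelled as the task boxcar convolved with a canonical
double-gamma haemodynamic response function (HRF) sampled at the repetition
time (TR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["ParadigmSpec", "make_boxcar", "canonical_hrf"]

TASK = "task"
REST = "rest"


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing of a block-design acquisition.

    Parameters
    ----------
    tr_seconds:
        Repetition time of the acquisition, in seconds.
    n_volumes:
        Number of volumes actually acquired. Authoritative: if the block
        table describes a longer run, the paradigm is truncated to the
        acquired volumes (``truncated`` reports this).
    block_table:
        Ordered ``(condition, duration_seconds)`` pairs, condition one of
        ``"task"`` / ``"rest"``.
    """

    tr_seconds: float = 2.0
    n_volumes: int = 60
    block_table: tuple[tuple[str, float], ...] = field(
        default_factory=lambda: (("task", 20.0), ("rest", 15.0)) * 6
    )

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_volumes <= 0:
            raise ValueError("n_volumes must be positive")
        if len(self.block_table) == 0:
            raise ValueError("block_table must contain at least one block")
        object.__setattr__(self, "block_table", tuple(
            (str(c), float(d)) for c, d in self.block_table
        ))
        for cond, dur in self.block_table:
            if cond not in (TASK, REST):
                raise ValueError(f"unknown block condition {cond!r}")
            if dur <= 0:
                raise ValueError("all block durations must be > 0")
        if self.total_duration_seconds < (self.n_volumes - 1) * self.tr_seconds + 1e-9:
            raise ValueError(
                "block table is shorter than the acquisition: "
                f"{self.total_duration_seconds} s of blocks cannot cover "
                f"{self.n_volumes} volumes at TR {self.tr_seconds} s"
            )

    @property
    def total_duration_seconds(self) -> float:
        return float(sum(d for _, d in self.block_table))

    @property
    def truncated(self) -> bool:
        """True when the block table outlasts the acquired volumes."""
        return self.total_duration_seconds / self.tr_seconds > self.n_volumes

    def to_dict(self) -> dict:
        return {
            "tr_seconds": self.tr_seconds,
            "n_volumes": self.n_volumes,
            "block_table": [[c, d] for c, d in self.block_table],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParadigmSpec":
        return cls(
            tr_seconds=d["tr_seconds"],
            n_volumes=int(d["n_volumes"]),
            block_table=tuple((c, d_) for c, d_ in d["block_table"]),
        )


def make_boxcar(paradigm: ParadigmSpec) -> np.ndarray:
    """Task indicator sampled at the acquisition times.

    Element ``v`` is 1 iff the acquisition time ``v * tr`` of volume ``v``
    falls inside a task block (blocks are half-open ``[start, end)``).
    """
    ends = np.cumsum([d for _, d in paradigm.block_table])
    conds = [c for c, _ in paradigm.block_table]
    t = np.arange(paradigm.n_volumes) * paradigm.tr_seconds
    idx = np.searchsorted(ends, t, side="right")
    idx = np.minimum(idx, len(conds) - 1)
    return np.array([1.0 if conds[i] == TASK else 0.0 for i in idx])


def canonical_hrf(
    tr_seconds: float,
    duration_seconds: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Double-gamma haemodynamic impulse response sampled at TR.

    The response is the difference of two gamma densities — a positive lobe
    peaking ~5 s after the event and a later undershoot scaled down by
    ``ratio`` — rescaled so its maximum is exactly 1.
    """
    if tr_seconds <= 0 or duration_seconds <= 0:
        raise ValueError("tr_seconds and duration_seconds must be positive")
    t = np.arange(0.0, duration_seconds, tr_seconds)
    peak = stats.gamma.pdf(t, peak_delay / dispersion, scale=dispersion)
    undershoot = stats.gamma.pdf(
        t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
    )
    h = peak - undershoot / ratio
    return h / h.max()


def task_regressor(paradigm: ParadigmSpec, **hrf_kwargs) -> np.ndarray:
    """Boxcar convolved with the canonical HRF, truncated to ``n_volumes``."""
    box = make_boxcar(paradigm)
    hrf = canonical_hrf(paradigm.tr_seconds, **hrf_kwargs)
    return np.convolve(box, hrf)[: paradigm.n_volumes]
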