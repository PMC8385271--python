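"""Whole-run configuration: one YAML document drives simulate + run.

A single global seed fans out deterministically to the per-stage seeds
(cohort simulation, fold assignment, CNN init/shuffling, permutations) via
``stage_seed``: stage ``i`` uses ``SeedSequence([global_seed, i])``, so any
stage can be re-run in isolation and the whole run is reproducible from one
integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cnn import CnnSpec, TrainConfig
from .cohort import CohortSpec
from .evaluate import PipelineConfig
from .paradigm import ParadigmSpec
from .stft import StftConfig

__all__ = ["RunConfig", "stage_seed", "STAGES"]

STAGES = {"cohort": 0, "folds": 1, "cnn": 2, "permutation": 3}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(STAGES)}")
    ss = np.random.SeedSequence([int(global_seed), STAGES[stage]])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Resolved configuration for an end-to-end run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    k_folds: int = 10
    n_permutations: int = 200
    seed: int = 0

    def resolve_seeds(self) -> "RunConfig":
        """Fan the global seed out into every stage-level seed field."""
        cohort = CohortSpec.from_dict(
            {**self.cohort.to_dict(), "seed": stage_seed(self.seed, "cohort")}
        )
        train = TrainConfig(
            **{**self.pipeline.train.to_dict(), "seed": stage_seed(self.seed, "cnn")}
        )
        pipeline_d = _pipeline_to_dict(self.pipeline)
        pipeline = _pipeline_from_dict({**pipeline_d, "train": train.to_dict()})
        return RunConfig(
            cohort=cohort,
            paradigm=self.paradigm,
            pipeline=pipeline,
            k_folds=self.k_folds,
            n_permutations=self.n_permutations,
            seed=self.seed,
        )

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "paradigm": self.paradigm.to_dict(),
            "pipeline": _pipeline_to_dict(self.pipeline),
            "k_folds": self.k_folds,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"cohort", "paradigm", "pipeline", "k_folds", "n_permutations", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(
                cohort=CohortSpec.from_dict(d.get("cohort", {})),
                paradigm=ParadigmSpec.from_dict(
                    d.get("paradigm", ParadigmSpec().to_dict())
                ),
                pipeline=_pipeline_from_dict(d.get("pipeline", {})),
                k_folds=int(d.get("k_folds", 10)),
                n_permutations=int(d.get("n_permutations", 200)),
                seed=int(d.get("seed", 0)),
            )
        except TypeError as err:
            raise ValueError(f"invalid config: {err}") from err

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _pipeline_to_dict(p: PipelineConfig) -> dict:
    return {
        "t_threshold": p.t_threshold,
        "cluster_min": p.cluster_min,
        "connectivity": p.connectivity,
        "two_sided": p.two_sided,
        "hp_cutoff_hz": p.hp_cutoff_hz,
        "pooled_ar": p.pooled_ar,
        "stft": p.stft.to_dict(),
        "normalize_mode": p.normalize_mode,
        "classifiers": list(p.classifiers),
        "primary": p.primary,
        "cnn_spec": p.cnn_spec.to_dict(),
        "train": p.train.to_dict(),
    }


def _pipeline_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    kwargs: dict = {}
    if "stft" in d:
        kwargs["stft"] = StftConfig.from_dict(d.pop("stft"))
    if "cnn_spec" in d:
        c = dict(d.pop("cnn_spec"))
        c["input_shape"] = tuple(c.get("input_shape", (31, 56)))
        c["conv_channels"] = tuple(c.get("conv_channels", (16, 32, 64)))
        kwargs["cnn_spec"] = CnnSpec(**c)
    if "train" in d:
        kwargs["train"] = TrainConfig(**d.pop("train"))
    if "classifiers" in d:
        kwargs["classifiers"] = tuple(d.pop("classifiers"))
    known = {
        "t_threshold", "cluster_min", "connectivity", "two_sided",
        "hp_cutoff_hz", "pooled_ar", "normalize_mode", "primary",
    }
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    kwargs.update(d)
    return PipelineConfig(**kwargs)
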