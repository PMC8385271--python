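"""Subject-level cross-validation, vote aggregation and permutation testing.

Subjects (never individual spectrograms) are partitioned into k stratified
folds. Within each fold, voxel selection uses *training subjects only*; all
of that subject's spectrograms at the selected voxels are classified, and
the subject's label is decided by the fraction of its spectrograms voted
into class 1:

    Pre_i = T_i / (T_i + F_i)

with Pre_i < 0.5 -> class 0 (control) and Pre_i >= 0.5 -> class 1 (ties go
to the patient class by the decision rule's "otherwise" clause). Statistical
significance of the cross-validated accuracy is assessed by re-running the
whole cross-validation on label-permuted cohorts and comparing the true
accuracy against the null distribution (add-one permutation p-value).

First-level GLM betas and voxel spectrograms depend only on the data, not
the labels, so they are computed once per cohort (``FeatureCache``) and
shared across folds and permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .baselines import fit_baselines, flatten_spectrograms
from .cnn import CnnSpec, SpectrogramCNN, TrainConfig, train_cnn
from .cohort import BoldRun
from .glm import DEFAULT_HP_CUTOFF_HZ, BetaMap, build_design, fit_glm_ar1
from .selection import (
    EmptySelectionError,
    VoxelSelection,
    select_voxels,
    two_sample_t,
)
from .stft import StftConfig, normalize, stft

__all__ = [
    "FoldPlan",
    "SubjectPrediction",
    "PipelineConfig",
    "FeatureCache",
    "CvReport",
    "PermutationResult",
    "make_folds",
    "aggregate_subject",
    "run_cv",
    "permutation_test",
    "report_discriminative_voxels",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the per-fold pipeline needs, in one place."""

    t_threshold: float = 3.0
    cluster_min: int = 5
    connectivity: int = 26
    two_sided: bool = True
    hp_cutoff_hz: float = DEFAULT_HP_CUTOFF_HZ
    pooled_ar: bool = True
    stft: StftConfig = field(default_factory=StftConfig)
    normalize_mode: str = "minmax"
    classifiers: tuple[str, ...] = ("cnn", "svm", "lr")
    primary: str = "cnn"
    cnn_spec: CnnSpec = field(default_factory=CnnSpec)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        known = {"cnn", "svm", "lr"}
        bad = set(self.classifiers) - known
        if bad:
            raise ValueError(f"unknown classifiers: {sorted(bad)}")
        if self.primary not in self.classifiers:
            raise ValueError("primary classifier must be among classifiers")


@dataclass(frozen=True)
class FoldPlan:
    """Subject -> fold assignment, stratified by group."""

    k: int
    assignments: dict[str, int]
    seed: int

    def test_subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f == fold]


def make_folds(
    subject_ids: list[str], labels: np.ndarray, k: int = 10, seed: int = 0
) -> FoldPlan:
    """Stratified fold assignment: per group, shuffle then deal round-robin,
    so fold sizes within each group differ by at most one."""
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    offset = 0  # stagger groups so total fold sizes also differ by <= 1
    for g in np.unique(labels):
        members = [s for s, l in zip(subject_ids, labels) if l == g]
        order = rng.permutation(len(members))
        for pos, idx in enumerate(order):
            assignments[members[idx]] = (pos + offset) % k
        offset += len(members) % k
    for fold in range(k):
        train_labels = {
            labels[i]
            for i, s in enumerate(subject_ids)
            if assignments[s] != fold
        }
        if len(train_labels) < 2:
            raise ValueError(
                f"fold {fold}: training split would contain a single class"
            )
    return FoldPlan(k=k, assignments=assignments, seed=seed)


@dataclass
class SubjectPrediction:
    """Aggregated decision for one subject in one test fold."""

    subject_id: str
    T: int  # spectrograms voted class 1
    F: int  # spectrograms voted class 0
    pre: float  # T / (T + F)
    predicted_label: int
    true_label: int | None = None


def aggregate_subject(
    votes: list[int] | np.ndarray,
    subject_id: str = "",
    true_label: int | None = None,
) -> SubjectPrediction:
    """Majority-fraction aggregation of per-spectrogram votes (ties -> class 1)."""
    votes = np.asarray(votes, dtype=int)
    if votes.size == 0:
        raise ValueError("empty vote list")
    T = int((votes == 1).sum())
    F = int(votes.size - T)
    pre = T / (T + F)
    predicted = 0 if pre < 0.5 else 1
    return SubjectPrediction(
        subject_id=subject_id,
        T=T,
        F=F,
        pre=pre,
        predicted_label=predicted,
        true_label=true_label,
    )


class FeatureCache:
    """Label-independent per-subject features, shared across folds/permutations.

    Betas are computed eagerly (one GLM per subject); spectrograms lazily,
    keyed by (subject index, voxel coordinate).
    """

    def __init__(self, runs: list[BoldRun], config: PipelineConfig):
        self.runs = runs
        self.config = config
        self.betas: list[BetaMap] = []
        for run in runs:
            design = build_design(run.paradigm, run.motion, config.hp_cutoff_hz)
            self.betas.append(fit_glm_ar1(run, design, pooled_ar=config.pooled_ar))
        self._specs: dict[tuple[int, tuple[int, int, int]], np.ndarray] = {}

    def spectrogram(self, subject_idx: int, xyz: tuple[int, int, int]) -> np.ndarray:
        key = (subject_idx, xyz)
        if key not in self._specs:
            run = self.runs[subject_idx]
            spec = stft(
                run.data[xyz[0], xyz[1], xyz[2]],
                run.paradigm.tr_seconds,
                self.config.stft,
            )
            spec = normalize(spec, self.config.normalize_mode)
            self._specs[key] = spec.values.astype(np.float32)
        return self._specs[key]

    def dataset(
        self, subject_indices: list[int], selection: VoxelSelection
    ) -> tuple[np.ndarray, np.ndarray, list[int]]:
        """(X, y, owner subject index per spectrogram), subject-major order."""
        X, y, owners = [], [], []
        for i in subject_indices:
            for xyz in selection.coordinates:
                X.append(self.spectrogram(i, tuple(int(c) for c in xyz)))
                y.append(self.runs[i].label)
                owners.append(i)
        return np.stack(X), np.array(y, dtype=int), owners


@dataclass
class CvReport:
    k: int
    folds: list[dict]
    mean_spectrogram_acc: dict[str, float]
    mean_subject_acc: dict[str, float]
    n_selected_per_fold: list[int | None]
    voxel_counts: np.ndarray  # 3D selection-frequency map across folds
    consensus_coordinates: np.ndarray  # voxels selected in every successful fold
    subject_predictions: dict[str, list[SubjectPrediction]]
    failed_folds: list[int]

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "k": self.k,
            "folds": [
                {k2: v for k2, v in f.items() if k2 != "selection"}
                for f in self.folds
            ],
            "mean_spectrogram_acc": self.mean_spectrogram_acc,
            "mean_subject_acc": self.mean_subject_acc,
            "n_selected_per_fold": self.n_selected_per_fold,
            "consensus_coordinates": self.consensus_coordinates.tolist(),
            "failed_folds": self.failed_folds,
        }


def _fold_seed(base_seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([base_seed, fold]).generate_state(1)[0] % 2**31)


def run_cv(
    runs: list[BoldRun],
    config: PipelineConfig | None = None,
    k: int = 10,
    seed: int = 0,
    plan: FoldPlan | None = None,
    cache: FeatureCache | None = None,
    labels_override: np.ndarray | None = None,
) -> CvReport:
    """k-fold subject-level cross-validation of the full pipeline.

    Per fold: two-sample t-map and cluster selection from training subjects'
    betas only; spectrogram extraction at the selected voxels; classifier
    training on training spectrograms; spectrogram- and subject-level
    accuracy on the held-out subjects. A fold whose selection is empty is
    marked failed and excluded from the fold means.

    ``labels_override`` substitutes the subject labels everywhere labels are
    used (selection, training, scoring) without touching the data — this is
    the hook the permutation test uses.
    """
    config = config or PipelineConfig()
    cache = cache or FeatureCache(runs, config)
    subject_ids = [r.subject_id for r in runs]
    true_labels = np.array([r.label for r in runs], dtype=int)
    labels = true_labels if labels_override is None else np.asarray(labels_override, dtype=int)
    if plan is None:
        plan = make_folds(subject_ids, labels, k=k, seed=seed)
    grid = runs[0].grid_shape

    folds: list[dict] = []
    failed: list[int] = []
    voxel_counts = np.zeros(grid, dtype=int)
    per_fold_selected: list[set] = []
    subject_preds: dict[str, list[SubjectPrediction]] = {
        c: [] for c in config.classifiers
    }

    for fold in range(plan.k):
        test_idx = [i for i, s in enumerate(subject_ids) if plan.assignments[s] == fold]
        train_idx = [i for i in range(len(runs)) if i not in test_idx]
        if not test_idx:
            continue
        b0 = [cache.betas[i] for i in train_idx if labels[i] == 0]
        b1 = [cache.betas[i] for i in train_idx if labels[i] == 1]
        t_map = two_sample_t(b0, b1)
        try:
            selection = select_voxels(
                t_map,
                t_threshold=config.t_threshold,
                cluster_min=config.cluster_min,
                connectivity=config.connectivity,
                two_sided=config.two_sided,
            )
        except EmptySelectionError:
            log.warning("fold %d: empty voxel selection, fold marked failed", fold)
            failed.append(fold)
            folds.append({"fold": fold, "failed": True})
            continue

        for xyz in selection.coordinates:
            voxel_counts[tuple(xyz)] += 1
        per_fold_selected.append({tuple(int(c) for c in xyz) for xyz in selection.coordinates})

        Xtr, _, _ = cache.dataset(train_idx, selection)
        ytr = np.repeat(labels[train_idx], len(selection))
        Xte, _, owners = cache.dataset(test_idx, selection)
        yte = np.repeat(labels[test_idx], len(selection))

        fold_rec: dict = {
            "fold": fold,
            "failed": False,
            "n_selected": len(selection),
            "selection": selection,
            "spectrogram_acc": {},
            "subject_acc": {},
        }
        for name in config.classifiers:
            if name == "cnn":
                model = SpectrogramCNN(
                    config.cnn_spec, seed=_fold_seed(plan.seed, fold)
                )
                cfg = TrainConfig(**{**config.train.to_dict(), "seed": _fold_seed(plan.seed, fold) + 1})
                train_cnn(model, Xtr, ytr, cfg)
                votes = model.predict(Xte)
            else:
                models = fit_baselines(Xtr, ytr)
                votes = models[name].predict(flatten_spectrograms(Xte))
            fold_rec["spectrogram_acc"][name] = float(np.mean(votes == yte))
            subj_correct = []
            pos = 0
            for i in test_idx:
                n_i = len(selection)
                pred = aggregate_subject(
                    votes[pos : pos + n_i],
                    subject_id=subject_ids[i],
                    true_label=int(labels[i]),
                )
                subject_preds[name].append(pred)
                subj_correct.append(pred.predicted_label == labels[i])
                pos += n_i
            fold_rec["subject_acc"][name] = float(np.mean(subj_correct))
        folds.append(fold_rec)

    ok = [f for f in folds if not f["failed"]]
    mean_spec = {
        c: float(np.mean([f["spectrogram_acc"][c] for f in ok])) if ok else float("nan")
        for c in config.classifiers
    }
    mean_subj = {
        c: float(np.mean([f["subject_acc"][c] for f in ok])) if ok else float("nan")
        for c in config.classifiers
    }
    if per_fold_selected:
        consensus = set.intersection(*per_fold_selected)
        consensus_arr = np.array(sorted(consensus), dtype=int).reshape(-1, 3)
    else:
        consensus_arr = np.empty((0, 3), dtype=int)
    return CvReport(
        k=plan.k,
        folds=folds,
        mean_spectrogram_acc=mean_spec,
        mean_subject_acc=mean_subj,
        n_selected_per_fold=[
            (f["n_selected"] if not f["failed"] else None) for f in folds
        ],
        voxel_counts=voxel_counts,
        consensus_coordinates=consensus_arr,
        subject_predictions=subject_preds,
        failed_folds=failed,
    )


@dataclass
class PermutationResult:
    n_permutations: int
    null_accuracies: np.ndarray
    acc0: float
    p_value: float
    threshold_95: float
    n_failed_permutations: int = 0

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "acc0": self.acc0,
            "p_value": self.p_value,
            "threshold_95": self.threshold_95,
            "n_failed_permutations": self.n_failed_permutations,
            "null_accuracies": [float(a) for a in self.null_accuracies],
        }


def permutation_test(
    runs: list[BoldRun],
    config: PipelineConfig | None = None,
    k: int = 10,
    n_permutations: int = 200,
    seed: int = 0,
    cache: FeatureCache | None = None,
    within_folds: bool = False,
    report0: CvReport | None = None,
) -> PermutationResult:
    """Permutation null for the cross-validated subject-level accuracy.

    Cohort labels are randomly permuted ``n_permutations`` times; the full
    cross-validation (selection included) is re-run on each permuted cohort
    and the mean subject-level accuracy of the primary classifier recorded.
    The add-one estimator ``p = (#{null >= Acc0} + 1) / (n + 1)`` avoids
    p = 0. ``within_folds=True`` instead permutes the training labels inside
    each fold while scoring against the true test labels.

    With the default strict selection thresholds a permuted (null) cohort
    frequently yields no selectable voxels in any fold; a pipeline with no
    features classifies at chance, so such permutations enter the null
    distribution at accuracy 0.5 (their count is reported).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    config = config or PipelineConfig()
    cache = cache or FeatureCache(runs, config)
    if report0 is None:
        report0 = run_cv(runs, config, k=k, seed=seed, cache=cache)
    acc0 = report0.mean_subject_acc[config.primary]
    if np.isnan(acc0):  # no fold selected anything: the pipeline is at chance
        acc0 = 0.5
    labels = np.array([r.label for r in runs], dtype=int)
    rng = np.random.default_rng(seed)
    null = []
    n_failed = 0
    for p_i in range(n_permutations):
        perm_seed = int(rng.integers(2**31))
        perm = labels[np.random.default_rng(perm_seed).permutation(len(labels))]
        if within_folds:
            rep = _run_cv_within_fold_perm(runs, config, k, perm_seed, cache)
        else:
            rep = run_cv(
                runs, config, k=k, seed=perm_seed, cache=cache, labels_override=perm
            )
        acc = rep.mean_subject_acc[config.primary]
        if np.isnan(acc):  # no fold selected any voxel: chance-level pipeline
            n_failed += 1
            acc = 0.5
        null.append(acc)
    null_arr = np.array(null)
    n_eff = len(null_arr)
    p_value = (float((null_arr >= acc0).sum()) + 1.0) / (n_eff + 1.0)
    threshold = float(np.percentile(null_arr, 95)) if n_eff else float("nan")
    return PermutationResult(
        n_permutations=n_permutations,
        null_accuracies=null_arr,
        acc0=float(acc0),
        p_value=float(p_value),
        threshold_95=threshold,
        n_failed_permutations=n_failed,
    )


def _run_cv_within_fold_perm(runs, config, k, seed, cache):
    """CV where each fold's *training* labels are shuffled (test labels true)."""
    labels = np.array([r.label for r in runs], dtype=int)
    subject_ids = [r.subject_id for r in runs]
    plan = make_folds(subject_ids, labels, k=k, seed=seed)
    rng = np.random.default_rng(seed + 1)
    perm = labels.copy()
    for fold in range(plan.k):
        train = [i for i, s in enumerate(subject_ids) if plan.assignments[s] != fold]
        perm[train] = labels[train][rng.permutation(len(train))]
    return run_cv(runs, config, k=k, seed=seed, plan=plan, cache=cache, labels_override=perm)


def report_discriminative_voxels(
    report: CvReport, out_dir: str | Path | None = None
) -> dict:
    """Cross-fold voxel selection frequencies and the all-fold consensus set.

    Returns the count volume, a tidy table, and the consensus coordinates;
    optionally writes them as NIfTI (counts) + TSV (table).
    """
    counts = report.voxel_counts
    xyz = np.argwhere(counts > 0)
    import pandas as pd

    table = pd.DataFrame(
        {
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "n_folds_selected": counts[tuple(xyz.T)],
        }
    ).sort_values(["x", "y", "z"], ignore_index=True)
    out = {
        "counts": counts,
        "table": table,
        "consensus_coordinates": report.consensus_coordinates,
    }
    if out_dir is not None:
        import nibabel as nib

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        nib.Nifti1Image(counts.astype(np.int16), np.diag([3.0, 3.0, 3.0, 1.0])).to_filename(
            out_dir / "voxel_selection_counts.nii.gz"
        )
        with open(out_dir / "voxel_selection_counts.tsv", "w") as fh:
            fh.write("# 0-based voxel indices (x, y, z)\n")
            table.to_csv(fh, sep="\t", index=False)
    return out
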