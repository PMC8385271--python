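"""On-disk cohort layout: NIfTI-1 volumes, TSV motion tables, TSV manifest.

Layout written by :func:`write_cohort` (one directory per cohort)::

    manifest.tsv                subject_id, label, bold, motion (one row each)
    paradigm.yaml               ParadigmSpec echo
    sub-XXX_bold.nii.gz         4D float64 volume, 3 mm isotropic affine
    sub-XXX_motion.tsv          n_volumes rows x 6 columns, no header

The round trip is lossless: volumes are stored as float64 and motion tables
at full decimal precision.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import BoldRun
from .paradigm import ParadigmSpec

__all__ = ["write_cohort", "read_cohort"]

_AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])  # voxels normalised to 3x3x3 mm


def write_cohort(runs: list[BoldRun], directory: str | Path) -> Path:
    """Write a cohort to ``directory``; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    paradigm = runs[0].paradigm
    for run in runs:
        if run.paradigm != paradigm:
            raise ValueError("all runs in a cohort must share one paradigm")
        bold_name = f"{run.subject_id}_bold.nii.gz"
        motion_name = f"{run.subject_id}_motion.tsv"
        img = nib.Nifti1Image(run.data.astype(np.float64), _AFFINE)
        img.header.set_zooms((3.0, 3.0, 3.0, paradigm.tr_seconds))
        img.to_filename(directory / bold_name)
        np.savetxt(directory / motion_name, run.motion, delimiter="\t", fmt="%.17g")
        rows.append(
            {
                "subject_id": run.subject_id,
                "label": int(run.label),
                "bold": bold_name,
                "motion": motion_name,
            }
        )
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    with open(directory / "paradigm.yaml", "w") as fh:
        yaml.safe_dump(paradigm.to_dict(), fh)
    return manifest


def read_cohort(directory: str | Path) -> list[BoldRun]:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = directory / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.tsv in {directory}")
    with open(directory / "paradigm.yaml") as fh:
        paradigm = ParadigmSpec.from_dict(yaml.safe_load(fh))
    table = pd.read_csv(manifest, sep="\t", dtype={"subject_id": str})
    runs = []
    for row in table.itertuples(index=False):
        try:
            label = int(row.label)
        except (TypeError, ValueError):
            raise ValueError(
                f"subject {row.subject_id}: unknown label {row.label!r} "
                "(expected 0 or 1)"
            ) from None
        if label not in (0, 1):
            raise ValueError(
                f"subject {row.subject_id}: unknown label {row.label!r} "
                "(expected 0 or 1)"
            )
        bold_path = directory / row.bold
        motion_path = directory / row.motion
        for p in (bold_path, motion_path):
            if not p.exists():
                raise FileNotFoundError(
                    f"subject {row.subject_id}: missing file {p.name}"
                )
        data = np.asarray(nib.load(bold_path).dataobj, dtype=np.float64)
        motion = np.loadtxt(motion_path, delimiter="\t").reshape(-1, 6)
        runs.append(
            BoldRun(
                data=data,
                paradigm=paradigm,
                motion=motion,
                label=label,
                subject_id=str(row.subject_id),
            )
        )
    return runs
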