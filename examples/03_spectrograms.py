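"""Short-time Fourier spectrograms of voxel time series.

Transforms one discriminative voxel from each group with the pipeline's
STFT (10-s window, hop 1 sample, zero-padded to 60) and compares the power
inside the band where the simulated group difference lives.
"""

import numpy as np

from boldspect import CohortSpec, StftConfig, normalize, simulate_cohort, stft

runs = simulate_cohort(CohortSpec(
    n_group0=1, n_group1=1, grid_shape=(8, 8, 8),
    n_task_voxels=4, n_discriminative_voxels=4, cluster_size=4,
    group_effect=3.0, seed=3,
))
voxel = tuple(runs[0].info["discriminative_voxels"][0])
cfg = StftConfig()  # 10-s window, hop 1, FFT length 60, one-sided magnitude

for run in runs:
    spec = stft(run.data[voxel], run.paradigm.tr_seconds, cfg)
    lo, hi = runs[0].info["spec"].band_hz
    band = (spec.freq_axis_hz >= lo) & (spec.freq_axis_hz <= hi)
    group = "control" if run.label == 0 else "patient"
    print(f"{group}: spectrogram {spec.values.shape[0]} bins x "
          f"{spec.values.shape[1]} frames, "
          f"freq 0-{spec.freq_axis_hz[-1]:.3f} Hz; "
          f"mean magnitude in {lo}-{hi} Hz band: "
          f"{spec.values[band].mean():.2f} "
          f"(elsewhere {spec.values[~band].mean():.2f})")

norm = normalize(spec, "minmax")
print(f"after min-max normalization: values in "
      f"[{norm.values.min():.0f}, {norm.values.max():.0f}]")

# The 31 x 56 geometry is what the CNN consumes. The patient voxel shows
# clearly elevated in-band magnitude — the time-frequency signature the
# classifier exploits and a mean-activation t-test alone would understate.
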