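"""Train the spectrogram CNN and aggregate its votes per subject.

Uses selection ground truth directly (see example 02 for data-driven
selection), splits subjects into train/test, trains the three-block CNN for
a few epochs, and turns per-spectrogram votes into subject decisions via
the vote fraction Pre = T / (T + F).
"""

import numpy as np

from boldspect import (
    CnnSpec, CohortSpec, TrainConfig, VoxelSelection, aggregate_subject,
    build_cnn, extract_dataset, simulate_cohort, stack_dataset, train_cnn,
)

runs = simulate_cohort(CohortSpec(
    n_group0=8, n_group1=8, grid_shape=(8, 8, 8),
    n_task_voxels=6, n_discriminative_voxels=8, cluster_size=8,
    group_effect=3.0, seed=4,
))
coords = runs[0].info["discriminative_voxels"]
selection = VoxelSelection(coordinates=coords,
                           t_values=np.full(len(coords), 5.0),
                           cluster_ids=np.ones(len(coords), dtype=int))

train_runs = runs[:6] + runs[8:14]   # 6 + 6 subjects for training
test_runs = runs[6:8] + runs[14:16]  # 2 + 2 held out

Xtr, ytr, _ = stack_dataset(extract_dataset(train_runs, selection,
                                            normalize_mode="minmax"))
Xte, yte, subj = stack_dataset(extract_dataset(test_runs, selection,
                                               normalize_mode="minmax"))

model = build_cnn(CnnSpec(), seed=0)
history = train_cnn(model, Xtr, ytr, TrainConfig(epochs=3, seed=0))
print(f"loss trace over {len(history['loss_trace'])} epochs: "
      f"{[round(l, 3) for l in history['loss_trace']]}")

votes = model.predict(Xte)
print(f"spectrogram-level test accuracy: {(votes == yte).mean():.2f} "
      f"({len(yte)} spectrograms = 4 subjects x {len(selection)} voxels)")

for sid in dict.fromkeys(subj):  # unique, in order
    mask = np.array(subj) == sid
    pred = aggregate_subject(votes[mask], subject_id=sid,
                             true_label=int(yte[mask][0]))
    print(f"  {sid}: T={pred.T} F={pred.F} Pre={pred.pre:.2f} -> "
          f"predicted {pred.predicted_label} (true {pred.true_label})")

# Pre >= 0.5 labels the subject as the patient class; aggregation makes the
# subject call robust to individual misclassified spectrograms.
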