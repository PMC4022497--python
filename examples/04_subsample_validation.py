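"""Random sub-sampling validation: how much training data is enough?

Retrains the two-round classifier on random fractions of a synthetic
training set (90% down to 20%, in triplicate) and tabulates accuracy/MCC,
probing compositional bias of the training composition.
"""

from ecr import generate_dataset, select_features
from ecr.metrics import subsample_validation

matrix, _ = generate_dataset(100, 60, seed=1)
matrix7 = select_features(matrix)

table = subsample_validation(
    matrix7,
    fractions=[0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2],
    replicates=3,
    seed=1,
    restarts=20,
)
summary = table.groupby("fraction")[["accuracy", "mcc"]].mean()
print(summary.to_string(float_format="%.3f"))

# Mean accuracy stays roughly flat across all fractions here: on this
# synthetic set the clustering structure is recoverable even from ~32
# interfaces, i.e. the classification is not driven by training-set size.
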