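"""Real-chemistry workflow: SMILES in, scaffold-split evaluation out.

Writes a tiny activity table, reads and cleans it (ECFP4 fingerprints,
Tanimoto distances), then performs a Murcko-scaffold holdout split —
train and test share no ring scaffold, mimicking prediction on a novel
chemical series — and scores a plain chemical KNN baseline on it.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

import topreg as tg

rows = [
    ("m01", "c1ccccc1CCO", 7.2), ("m02", "c1ccccc1CCN", 7.0),
    ("m03", "c1ccccc1C(=O)O", 6.8), ("m04", "c1ccccc1CC(=O)N", 6.9),
    ("m05", "c1ccncc1CC", 5.1), ("m06", "c1ccncc1CCO", 5.3),
    ("m07", "c1ccncc1C(=O)O", 5.0), ("m08", "C1CCCCC1O", 8.0),
    ("m09", "C1CCCCC1N", 8.2), ("m10", "C1CCCCC1CC", 7.9),
    ("m11", "CCO", 4.5), ("m12", "CCCCO", 4.7),
]
with tempfile.TemporaryDirectory() as tmp:
    csv = Path(tmp) / "activity.csv"
    pd.DataFrame(rows, columns=["id", "smiles", "activity"]).to_csv(csv, index=False)
    ds = tg.read_activity_table(csv)

print(f"dataset: {len(ds)} molecules, {ds.nbits}-bit ECFP4 fingerprints")
train, test = tg.scaffold_split(ds, test_fraction=0.25, seed=0)
print(f"scaffold split: {len(train)} train / {len(test)} test "
      f"(ids {[ds.ids[i] for i in test]})")

sim = tg.pairwise_similarity_matrix(ds).values
y = ds.activities()
preds = tg.knn_predict(sim[np.ix_(test, train)], y[train], k=3)
for i, p in zip(test, preds):
    print(f"  {ds.ids[i]}: true {y[i]:.1f}, 3-NN prediction {p:.2f}")
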