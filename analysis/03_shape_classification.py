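#!/usr/bin/env python
"""Size-free shape ordination and discriminant attribution of the fossil.

Computes log-shape ratios over the eight fossil-preserved measurements for
the simulated comparative table, runs PCA (fossil projected, not fitted),
fits the four-clade LDA, reports the leave-one-out confusion matrix, and
post-classifies the held-out fossil.  Writes results/confusion.csv and
results/shape_ratios.csv.
"""

from pathlib import Path

import pandas as pd

from paleomorph.classify import classify_holdout, lda_cv_confusion, lda_fit, pca
from paleomorph.logshape import log_shape_ratios, shape_matrix
from paleomorph.morphodata import read_measurements

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    measurements = ROOT / "simulated" / "measurements.csv"
    if not measurements.exists():
        raise SystemExit("run 01_simulate.py first")
    records = read_measurements(measurements)
    matrix = shape_matrix([r for r in records if r.has(
        ("LNW", "UNW", "ANW", "NH", "ATW", "MTW", "ADW", "MDW"))])

    pca_res = pca(matrix)
    print(f"PC1+PC2 share of shape variance: {100 * pca_res.pc_fraction(2):.2f}%")

    lda_res = lda_fit(matrix, priors="equal")
    print(f"LD1 share of discriminating variance: "
          f"{100 * lda_res.axis_variance_fraction[0]:.2f}%")

    confusion = lda_cv_confusion(matrix, priors="equal", cv="loo")
    order = [c.value for c in confusion.clades]
    df = pd.DataFrame(confusion.rounded(), index=order, columns=order)
    print("\nleave-one-out confusion matrix (row %):")
    print(df.to_string())

    fossil = next(r for r in records if r.is_fossil)
    clade, scores = classify_holdout(log_shape_ratios(fossil), lda_res)
    print(f"\nfossil {fossil.specimen_id!r} post-classified as: {clade.value}")
    print(f"  discriminant scores: {[round(float(s), 3) for s in scores]}")

    df.to_csv(ROOT / "confusion.csv", index_label="true_clade")
    shape_df = pd.DataFrame(matrix.values, columns=list(matrix.subset))
    shape_df.insert(0, "specimen_id", matrix.specimen_ids)
    shape_df.insert(1, "clade", [c.value for c in matrix.clades])
    shape_df.to_csv(ROOT / "shape_ratios.csv", index=False)
    print(f"\nwrote {ROOT / 'confusion.csv'} and {ROOT / 'shape_ratios.csv'}")


if __name__ == "__main__":
    main()
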