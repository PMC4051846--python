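#!/usr/bin/env python
"""Shaft-curvature comparison of the fossil against each simulated taxon.

Flattens every 10-landmark 3-D chain to its own plane, registers it to the
(0,0)-(1,0) baseline, and ranks taxa by the mean distance between the
fossil's registered landmarks and each taxon's mean curve (baseline
units).  Writes results/distances.csv and an overlay figure.
"""

from pathlib import Path

import pandas as pd

from paleomorph.curvature import estimate_kappa, mean_curve, rank_taxa, register
from paleomorph.morphodata import Clade, read_landmarks

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    landmarks = ROOT / "simulated" / "landmarks.csv"
    if not landmarks.exists():
        raise SystemExit("run 01_simulate.py first")
    curves = [register(c) for c in read_landmarks(landmarks)]
    fossil = next(c for c in curves if c.clade is Clade.FOSSIL)
    taxa: dict[str, list] = {}
    for c in curves:
        if c.clade is not Clade.FOSSIL:
            taxa.setdefault(c.taxon, []).append(c)

    print(f"fossil mid-shaft bow (baseline units): {estimate_kappa(fossil):.4f}")
    ranking = rank_taxa(fossil, taxa, mode="mean")
    print("\nfossil-to-taxon mean-curve distances (ascending, baseline units):")
    for cd in ranking:
        kappa = estimate_kappa(mean_curve(taxa[cd.taxon]))
        print(f"  {cd.taxon:16s} d = {cd.d:.3f}   (taxon mean bow {kappa:.3f})")

    pd.DataFrame([{"taxon": cd.taxon, "d": cd.d} for cd in ranking]).to_csv(
        ROOT / "distances.csv", index=False)
    from paleomorph.plots import curvature_overlay
    means = {t: mean_curve(shapes) for t, shapes in taxa.items()}
    curvature_overlay(means, fossil, ROOT / "curvature_overlay.png")
    print(f"\nwrote {ROOT / 'distances.csv'} and {ROOT / 'curvature_overlay.png'}")


if __name__ == "__main__":
    main()
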