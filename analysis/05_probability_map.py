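"""Train the classifier on the PC1-PC2 scores and map class probabilities.

The question the map answers: is there a region of the score plane where the
postoperative class dominates, separate from both the healthy and the
preoperative regions?  If yes, the cohort exhibits a distinct "healing
state" rather than a simple return to health.
"""

import argparse
import csv
from pathlib import Path

import numpy as np

from spectroheal.prediction import predict_grid, probability_bands, train_classifier


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--resolution", type=int, default=200)
    args = ap.parse_args()

    scores_csv = args.results / "chemometrics" / "scores.csv"
    with scores_csv.open() as fh:
        rows = list(csv.DictReader(fh))
    X = np.array([[float(r["PC1"]), float(r["PC2"])] for r in rows])
    y = [r["group"] for r in rows]

    clf = train_classifier(X, y)
    print(f"classifier trained on {len(y)} points, "
          f"training accuracy {clf.train_accuracy:.3f}, loss {clf.final_loss:.4f}")
    pmap = predict_grid(clf, resolution=(args.resolution, args.resolution), train_scores=X)

    out = args.results / "prediction"
    out.mkdir(parents=True, exist_ok=True)
    for ci, cname in enumerate(pmap.classes):
        with (out / f"prob_{cname}.csv").open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["pc1\\pc2"] + [f"{v:.8g}" for v in pmap.pc2_axis])
            for i, p1 in enumerate(pmap.pc1_axis):
                w.writerow([f"{p1:.8g}"] + [f"{p:.8g}" for p in pmap.probs[i, :, ci]])

    total = args.resolution**2
    for cname in pmap.classes:
        bands = probability_bands(pmap, cname, (0.30, 0.70))
        frac_high = (bands == 2).sum() / total
        frac_med = (bands == 1).sum() / total
        print(f"  {cname:9s}: high-probability (>=70%) area {frac_high:5.1%}, "
              f"medium (30-70%) {frac_med:5.1%}")
    high = {c: pmap.probs[:, :, i] >= 0.7 for i, c in enumerate(pmap.classes)}
    disjoint = (
        not (high["crc_post"] & high["healthy"]).any()
        and not (high["crc_post"] & high["crc_pre"]).any()
    )
    print(f"postoperative high-probability region non-empty and disjoint from "
          f"the others: {high['crc_post'].any() and disjoint}")
    print(f"probability grids written to {out}")


if __name__ == "__main__":
    main()
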