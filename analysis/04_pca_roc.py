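"""PCA of the cohort spectra, per-patient evolution vectors, and ROC/AUC for
the four group pairings on PC1 and PC2.

The PC1-PC2 plane is where the whole healing question is posed: do the
postoperative points move back toward the healthy cluster, or somewhere new?
"""

import argparse
import csv
import json
from pathlib import Path

import numpy as np

from spectroheal.chemometrics import (
    assemble_matrix,
    evolution_vectors,
    fit_pca,
    four_pairings,
    roc_curve,
)
from spectroheal.cohort import read_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--components", type=int, default=5)
    args = ap.parse_args()

    cohort = read_cohort(args.results / "cohort")
    out = args.results / "chemometrics"
    out.mkdir(parents=True, exist_ok=True)

    matrix = assemble_matrix(list(cohort.spectra.values()), cohort.records)
    pca = fit_pca(matrix, n_components=args.components)
    print("explained variance ratios:",
          [round(float(v), 3) for v in pca.explained_variance_ratio])

    with (out / "scores.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "group"] + [f"PC{k+1}" for k in range(args.components)])
        for i, sid in enumerate(pca.row_ids):
            w.writerow([sid, pca.groups[i]] + [f"{v:.10g}" for v in pca.scores[i]])

    vecs = evolution_vectors(pca, cohort.records)
    (out / "evolution_vectors.json").write_text(json.dumps(
        {v.patient_id: {"pre": v.pre_score, "post": v.post_score,
                        "direction": v.direction, "length": v.length} for v in vecs},
        indent=1) + "\n")
    n_up = sum(v.direction == "pc1_increasing" for v in vecs)
    print(f"evolution arrows: {n_up} toward larger PC1 (black), "
          f"{len(vecs) - n_up} toward smaller PC1 (red)")

    groups = np.array(pca.groups)
    rows = []
    print(f"{'pairing':24s} {'PC':3s} {'AUC':>6s}  cut(sens,spec)  partner+")
    for pairing in four_pairings(cohort.records):
        m = np.isin(groups, list(pairing.positive_labels | pairing.negative_labels))
        y = np.isin(groups[m], list(pairing.positive_labels))
        for k, name in enumerate(["PC1", "PC2"]):
            rc = roc_curve(pca.scores[m, k], y, score_name=name, pairing=pairing.name)
            se, sp, thr = rc.optimal_cutpoint
            rows.append([pairing.name, name, f"{rc.auc:.4f}", f"{se:.2f}", f"{sp:.2f}",
                         f"{thr:.4g}", str(rc.partner_positive)])
            print(f"{pairing.name:24s} {name:3s} {rc.auc:6.3f}  ({se:.2f},{sp:.2f})"
                  f"       {rc.partner_positive}")
    with (out / "auc_table.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pairing", "score", "auc", "cut_sensitivity", "cut_specificity",
                    "cut_threshold", "partner_positive"])
        w.writerows(rows)
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
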