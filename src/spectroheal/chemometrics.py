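"""Chemometrics over the cohort's FT-IR spectra: PCA, per-patient evolution
vectors, and group-contrast ROC statistics.

The spectra (rows) over a common wavenumber axis (columns) are mean-centered
and decomposed by principal component analysis; the PC1-PC2 score plane is the
working coordinate system of the whole downstream analysis.  Each patient's
pre -> post displacement in that plane is an *evolution vector*, colored by
the sign of its PC1 component (the convention used in the source plots: black
for increasing PC1, red for decreasing).  Group separability along a single
PC is quantified by ROC curves for the four standard pairings

    (i)   healthy (positive)  vs  CRC pre + post
    (ii)  healthy (positive)  vs  CRC pre
    (iii) healthy (positive)  vs  CRC post
    (iv)  CRC pre (positive)  vs  CRC post

with the area under the curve and a Youden-J optimal cut-point.  An AUC below
0.5 is reported as-is with a ``partner_positive`` flag (meaning the *other*
group ranks higher on that score), never silently flipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA as _SKPCA
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import SubjectRecord
from .ftir import Spectrum, resample_to_axis

__all__ = [
    "SpectraMatrix",
    "PCAResult",
    "EvolutionVector",
    "GroupPairing",
    "ROCCurve",
    "assemble_matrix",
    "fit_pca",
    "evolution_vectors",
    "roc_curve",
    "four_pairings",
]

_GROUP_ORDER = {"healthy": 0, "crc_pre": 1, "crc_post": 2}


@dataclass
class SpectraMatrix:
    """Rows x wavenumbers absorbance matrix with aligned row metadata."""

    row_ids: list[str]
    groups: list[str]
    axis: np.ndarray
    X: np.ndarray
    plasma_kind: str = "native"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.row_ids), len(self.axis)):
            raise ValueError("X shape does not match row_ids x axis")
        if np.any(~np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")


@dataclass
class PCAResult:
    mean_spectrum: np.ndarray
    loadings: np.ndarray  # components x wavenumbers
    scores: np.ndarray  # rows x components
    explained_variance_ratio: np.ndarray
    row_ids: list[str]
    groups: list[str]

    def score_of(self, row_id: str) -> np.ndarray:
        return self.scores[self.row_ids.index(row_id)]


@dataclass
class EvolutionVector:
    """Pre -> post displacement of one patient in the PC1-PC2 plane."""

    patient_id: str
    pre_score: tuple[float, float]
    post_score: tuple[float, float]
    direction: str  # "pc1_increasing" (black arrow) | "pc1_decreasing" (red)
    length: float


@dataclass(frozen=True)
class GroupPairing:
    name: str
    positive_labels: frozenset[str]
    negative_labels: frozenset[str]

    def __post_init__(self) -> None:
        if self.positive_labels & self.negative_labels:
            raise ValueError("positive and negative label sets must be disjoint")


@dataclass
class ROCCurve:
    score_name: str
    pairing: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutpoint: tuple[float, float, float]  # (sensitivity, specificity, threshold)
    partner_positive: bool


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def assemble_matrix(
    spectra: Sequence[Spectrum],
    records: Sequence[SubjectRecord],
    wn_range: tuple[float, float] | None = None,
) -> SpectraMatrix:
    """Stack spectra into a matrix, rows ordered healthy, crc_pre, crc_post
    (then by id), columns optionally restricted to ``wn_range``."""
    by_id: dict[str, SubjectRecord] = {}
    for r in records:
        if r.subject_id in by_id:
            raise ValueError(f"duplicate subject id {r.subject_id!r}")
        by_id[r.subject_id] = r
    seen: set[str] = set()
    unmatched = []
    for s in spectra:
        if s.subject_id not in by_id:
            unmatched.append(s.subject_id)
        if s.subject_id in seen:
            raise ValueError(f"duplicate spectrum for subject {s.subject_id!r}")
        seen.add(s.subject_id)
    if unmatched:
        raise ValueError(f"spectra without subject records: {sorted(unmatched)}")

    ordered = sorted(
        spectra,
        key=lambda s: (_GROUP_ORDER[by_id[s.subject_id].group], s.subject_id),
    )
    axis = ordered[0].wavenumber
    rows = []
    for s in ordered:
        if len(s) != len(axis) or not np.allclose(s.wavenumber, axis):
            s = resample_to_axis(s, axis)
        rows.append(s.absorbance)
    X = np.vstack(rows)
    if wn_range is not None:
        lo, hi = wn_range
        m = (axis >= lo) & (axis <= hi)
        axis, X = axis[m], X[:, m]
    kinds = {s.plasma_kind for s in ordered}
    return SpectraMatrix(
        row_ids=[s.subject_id for s in ordered],
        groups=[by_id[s.subject_id].group for s in ordered],
        axis=axis.copy(),
        X=X,
        plasma_kind=kinds.pop() if len(kinds) == 1 else "mixed",
    )


def fit_pca(matrix: SpectraMatrix, n_components: int = 5) -> PCAResult:
    """Mean-centered PCA of the spectra matrix.

    No variance scaling is applied (all columns share absorbance units).  The
    sign of each component is fixed so its largest-magnitude loading element
    is positive, making score plots reproducible across library versions.
    """
    n_rows = matrix.X.shape[0]
    if not (1 <= n_components <= n_rows):
        raise ValueError("need 1 <= n_components <= n_rows")
    if np.allclose(matrix.X, matrix.X[0]):
        raise ValueError("matrix has zero variance; PCA is undefined")
    pca = _SKPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.X)
    loadings = pca.components_.copy()
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]
    return PCAResult(
        mean_spectrum=pca.mean_.copy(),
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        row_ids=list(matrix.row_ids),
        groups=list(matrix.groups),
    )


def evolution_vectors(
    pca: PCAResult, records: Sequence[SubjectRecord]
) -> list[EvolutionVector]:
    """One pre -> post arrow per patient in the PC1-PC2 plane.

    Zero PC1 displacement is classified as ``pc1_increasing`` (the documented
    tie-break for a patient whose scores did not move).
    """
    by_id = {r.subject_id: r for r in records}
    posts = [r for r in records if r.group == "crc_post"]
    pres = {r.pair_id: r for r in records if r.group == "crc_pre"}
    out: list[EvolutionVector] = []
    for post in sorted(posts, key=lambda r: r.pair_id):
        pre = pres.get(post.pair_id)
        if pre is None:
            raise ValueError(f"{post.subject_id}: no preoperative partner in records")
        if pre.subject_id not in pca.row_ids or post.subject_id not in pca.row_ids:
            raise ValueError(f"patient {post.pair_id}: scores missing from PCA result")
        s_pre = pca.score_of(pre.subject_id)[:2]
        s_post = pca.score_of(post.subject_id)[:2]
        d = s_post - s_pre
        out.append(
            EvolutionVector(
                patient_id=post.pair_id,
                pre_score=(float(s_pre[0]), float(s_pre[1])),
                post_score=(float(s_post[0]), float(s_post[1])),
                direction="pc1_increasing" if d[0] >= 0 else "pc1_decreasing",
                length=float(np.hypot(*d)),
            )
        )
    return out


def four_pairings(records: Sequence[SubjectRecord]) -> list[GroupPairing]:
    """The four standard group contrasts, positives as conventionally printed."""
    present = {r.group for r in records}
    missing = {"healthy", "crc_pre", "crc_post"} - present
    if missing:
        raise ValueError(f"cohort lacks groups: {sorted(missing)}")
    return [
        GroupPairing("healthy_vs_crc", frozenset({"healthy"}), frozenset({"crc_pre", "crc_post"})),
        GroupPairing("healthy_vs_crc_pre", frozenset({"healthy"}), frozenset({"crc_pre"})),
        GroupPairing("healthy_vs_crc_post", frozenset({"healthy"}), frozenset({"crc_post"})),
        GroupPairing("crc_pre_vs_crc_post", frozenset({"crc_pre"}), frozenset({"crc_post"})),
    ]


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[bool | int],
    score_name: str = "PC1",
    pairing: str = "",
) -> ROCCurve:
    """ROC over a threshold sweep of the raw score (greater score => positive).

    The curve's AUC is the trapezoid area; no orientation flip is applied, so
    an AUC below 0.5 simply means the negative group ranks higher and the
    ``partner_positive`` flag is set.  The optimal cut-point maximizes Youden's
    J = sensitivity + specificity - 1.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("scores and labels differ in length")
    if y.all() or (~y).all():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    sens, spec = tpr, 1.0 - fpr
    j = sens + spec - 1.0
    k = int(np.argmax(j))
    return ROCCurve(
        score_name=score_name,
        pairing=pairing,
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutpoint=(float(sens[k]), float(spec[k]), float(thr[k])),
        partner_positive=bool(auc < 0.5),
    )
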