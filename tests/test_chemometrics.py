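"""PCA, evolution vectors, group pairings and ROC/AUC statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectroheal.chemometrics import (
    SpectraMatrix,
    assemble_matrix,
    evolution_vectors,
    fit_pca,
    four_pairings,
    roc_curve,
)
from spectroheal.cohort import (
    CohortConfig,
    DEFAULT_BANDS,
    SubjectRecord,
    generate_cohort,
    load_table1_fixture,
)
from spectroheal.ftir import Spectrum, default_axis


def mannwhitney_auc(scores, labels):
    """Independent oracle: AUC as the Mann-Whitney pair-counting statistic
    (positive ranked above negative counts 1, ties count 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAssembleMatrix:
    def test_cohort_matrix_shape_and_order(self, small_cohort):
        m = assemble_matrix(list(small_cohort.spectra.values()), small_cohort.records)
        assert m.X.shape == (40, 913)
        assert m.groups[:20] == ["healthy"] * 20
        assert m.groups[20:30] == ["crc_pre"] * 10
        assert m.groups[30:] == ["crc_post"] * 10

    def test_range_restriction_counts_columns(self, small_cohort):
        m = assemble_matrix(
            list(small_cohort.spectra.values()),
            small_cohort.records,
            wn_range=(1500.0, 1800.0),
        )
        axis = default_axis()
        expected = int(np.sum((axis >= 1500) & (axis <= 1800)))  # direct count
        assert m.X.shape[1] == expected

    def test_duplicate_subject_rejected(self):
        axis = default_axis()
        rec = SubjectRecord("V1", "healthy", age=30)
        spec = Spectrum(axis, np.ones(len(axis)), subject_id="V1")
        with pytest.raises(ValueError, match="duplicate"):
            assemble_matrix([spec, spec], [rec, rec])

    def test_unmatched_spectrum_lists_ids(self, small_cohort):
        axis = default_axis()
        stray = Spectrum(axis, np.ones(len(axis)), subject_id="GHOST")
        with pytest.raises(ValueError, match="GHOST"):
            assemble_matrix(
                list(small_cohort.spectra.values()) + [stray], small_cohort.records
            )


class TestFitPCA:
    def _matrix(self, X, groups=None):
        n = X.shape[0]
        groups = groups or ["healthy"] * n
        recs = [f"s{i}" for i in range(n)]
        return SpectraMatrix(recs, groups, np.arange(X.shape[1], dtype=float), X)

    def test_collinear_points_explained_by_pc1(self, rng):
        t = rng.normal(size=12)
        X = np.outer(t, [1.0, 2.0]) + 5.0
        res = fit_pca(self._matrix(X), n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(5):
            X = rng.normal(size=(6, 4))
            res = fit_pca(self._matrix(X), n_components=4)
            # independent oracle: covariance eigendecomposition
            Xc = X - X.mean(axis=0)
            w, V = np.linalg.eigh(Xc.T @ Xc / (len(X) - 1))
            order = np.argsort(w)[::-1]
            V = V[:, order]
            for k in range(4):
                v = V[:, k]
                if v[np.argmax(np.abs(v))] < 0:
                    v = -v
                np.testing.assert_allclose(res.loadings[k], v, atol=1e-8)
                np.testing.assert_allclose(res.scores[:, k], Xc @ v, atol=1e-8)

    def test_mean_spectrum_projects_to_origin(self, rng):
        X = rng.normal(size=(10, 6))
        res = fit_pca(self._matrix(X), n_components=3)
        score = res.loadings @ (X.mean(axis=0) - res.mean_spectrum)
        np.testing.assert_allclose(score, 0, atol=1e-10)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(8, 5))
        res = fit_pca(self._matrix(X), n_components=5)
        recon = res.scores @ res.loadings + res.mean_spectrum
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(15, 9))
        res = fit_pca(self._matrix(X), n_components=4)
        np.testing.assert_allclose(res.loadings @ res.loadings.T, np.eye(4), atol=1e-8)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_pca(self._matrix(np.ones((5, 4))), n_components=2)


class TestEvolutionVectors:
    def _pca_like(self, scores_by_id):
        from spectroheal.chemometrics import PCAResult

        ids = list(scores_by_id)
        scores = np.array([scores_by_id[i] for i in ids], dtype=float)
        return PCAResult(
            mean_spectrum=np.zeros(2),
            loadings=np.eye(2),
            scores=scores,
            explained_variance_ratio=np.array([0.7, 0.3]),
            row_ids=ids,
            groups=["crc_pre" if i.endswith("_pre") else "crc_post" for i in ids],
        )

    def _records(self, pids):
        recs = []
        for pid in pids:
            recs.append(SubjectRecord(f"{pid}_pre", "crc_pre", pair_id=pid, age=60))
            recs.append(SubjectRecord(f"{pid}_post", "crc_post", pair_id=pid, age=60))
        return recs

    def test_zero_displacement_tie_break(self):
        pca = self._pca_like({"P1_pre": (3.0, 4.0), "P1_post": (3.0, 4.0)})
        [v] = evolution_vectors(pca, self._records(["P1"]))
        assert v.length == 0.0
        assert v.direction == "pc1_increasing"

    def test_displacement_arithmetic(self):
        pca = self._pca_like({"P1_pre": (-10.0, 0.0), "P1_post": (20.0, 5.0)})
        [v] = evolution_vectors(pca, self._records(["P1"]))
        assert v.direction == "pc1_increasing"
        assert v.length == pytest.approx(np.hypot(30, 5))

    def test_pc1_decreasing_is_flagged(self):
        pca = self._pca_like({"P1_pre": (5.0, 1.0), "P1_post": (2.0, 1.0)})
        [v] = evolution_vectors(pca, self._records(["P1"]))
        assert v.direction == "pc1_decreasing"

    def test_unpaired_post_rejected(self):
        pca = self._pca_like({"P1_pre": (0, 0), "P1_post": (1, 1)})
        recs = self._records(["P1"])
        recs.append(SubjectRecord("P9_post", "crc_post", pair_id="P9", age=60))
        with pytest.raises(ValueError, match="P9"):
            evolution_vectors(pca, recs)

    def test_planted_recovery_drift_sign(self):
        """Postoperative spectra planted between preoperative and healthy:
        the mean patient displacement along PC1 points from the preoperative
        cluster toward the healthy cluster, whatever PC1's sign convention."""
        for seed in range(10):
            cfg = CohortConfig(n_echoes=2, seed=100 + seed)
            cohort = generate_cohort(cfg)
            matrix = assemble_matrix(list(cohort.spectra.values()), cohort.records)
            pca = fit_pca(matrix, n_components=2)
            g = np.array(pca.groups)
            healthy_pc1 = pca.scores[g == "healthy", 0].mean()
            pre_pc1 = pca.scores[g == "crc_pre", 0].mean()
            vecs = evolution_vectors(pca, cohort.records)
            mean_disp = np.mean([v.post_score[0] - v.pre_score[0] for v in vecs])
            assert np.sign(mean_disp) == np.sign(healthy_pc1 - pre_pc1)


class TestFourPairings:
    def test_presets(self):
        records = load_table1_fixture()
        pairings = four_pairings(records)
        assert [p.name for p in pairings] == [
            "healthy_vs_crc",
            "healthy_vs_crc_pre",
            "healthy_vs_crc_post",
            "crc_pre_vs_crc_post",
        ]
        assert pairings[0].positive_labels == {"healthy"}
        assert pairings[0].negative_labels == {"crc_pre", "crc_post"}
        assert pairings[3].positive_labels == {"crc_pre"}
        assert pairings[3].negative_labels == {"crc_post"}

    def test_missing_group_named_in_error(self):
        records = [r for r in load_table1_fixture() if r.group != "healthy"]
        with pytest.raises(ValueError, match="healthy"):
            four_pairings(records)


class TestROCCurve:
    def test_perfect_separation(self):
        rc = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert rc.auc == pytest.approx(1.0)
        assert rc.optimal_cutpoint[0] == pytest.approx(1.0)
        assert rc.optimal_cutpoint[1] == pytest.approx(1.0)
        assert not rc.partner_positive

    def test_uninformative_scores_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        rc = roc_curve(scores, labels)
        assert rc.auc == pytest.approx(0.5, abs=0.05)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 40))
            scores = rng.integers(0, 6, n).astype(float)  # many ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            rc = roc_curve(scores, labels)
            assert rc.auc == pytest.approx(mannwhitney_auc(scores, labels), abs=1e-12)

    def test_partner_positive_flag(self):
        rc = roc_curve([10, 11, 12, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert rc.auc == pytest.approx(0.0)
        assert rc.partner_positive

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_negation_complements_auc(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 50))
        scores = np.round(r.normal(size=n), 1)
        labels = r.random(n) < 0.5
        if labels.all() or not labels.any():
            return
        a = roc_curve(scores, labels).auc
        b = roc_curve(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_curve([1, 2, 3], [1, 1, 1])
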