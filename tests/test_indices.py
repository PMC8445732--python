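"""Ischemic/leakage indices and the two-threshold discriminant grader."""

import numpy as np
import pytest

from angiograde.frames import Grade, IndexPair, LesionMasks, Provenance, RetinaGeometry
from angiograde.indices import (
    DiscriminantModel,
    compute_indices,
    fit_discriminant,
    index_summary,
    predict_grade_from_indices,
)


def _geom(n=100, d2=None):
    fp = np.ones((n, n), dtype=bool)
    return RetinaGeometry(footprint=fp, disc_xy=(20, 50), macula_xy=(50, 50), d2=d2)


def _masks(np_px=0, lk_px=0, n=100):
    npm = np.zeros((n, n), dtype=bool)
    lkm = np.zeros((n, n), dtype=bool)
    npm.ravel()[:np_px] = True
    lkm.ravel()[n * n - lk_px :] = True
    return LesionMasks(nonperfusion=npm, leakage=lkm, provenance=Provenance.PLANTED)


def _cluster_pairs(rng, centers, n=20, spread=0.005):
    pairs, grades = [], []
    for c, g in zip(centers, (Grade.NORMAL, Grade.NPDR, Grade.PDR)):
        for _ in range(n):
            ii, li = np.clip(rng.normal(c, spread, 2), 0, 1)
            pairs.append(IndexPair(float(ii), float(li)))
            grades.append(g)
    return pairs, grades


class TestComputeIndices:
    def test_leakage_ratio(self):
        geom = _geom(d2=1000)
        pair = compute_indices(_masks(lk_px=50), geom)
        assert pair.leakage_index == pytest.approx(0.05)

    def test_empty_masks_zero(self):
        pair = compute_indices(_masks(), _geom())
        assert (pair.ischemic_index, pair.leakage_index) == (0.0, 0.0)

    def test_invalid_d2(self):
        geom = _geom()
        geom.d2 = 0.0
        with pytest.raises(ValueError):
            compute_indices(_masks(), geom)

    def test_planted_masks_recover_fractions(self, pdr_eye):
        pair = compute_indices(pdr_eye.truth_masks, pdr_eye.geometry)
        assert pair.ischemic_index == pytest.approx(
            pdr_eye.params.np_area_fraction, abs=0.02
        )
        assert pair.leakage_index == pytest.approx(
            pdr_eye.params.lk_area_fraction, abs=0.02
        )


class TestFitDiscriminant:
    def test_separable_1d_clusters_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        pairs, grades = _cluster_pairs(
            rng, [(0.0, 0.1), (0.2, 0.1), (0.4, 0.1)], spread=0.005
        )
        model = fit_discriminant(pairs, grades)
        assert model.training_accuracy == 1.0
        preds = [predict_grade_from_indices(model, p) for p in pairs]
        assert preds == grades

    def test_threshold_recovery_within_half_gap(self):
        """Fitted thresholds land within half the inter-cluster gap of the
        generative boundaries along the known direction."""
        rng = np.random.default_rng(1)
        centers = [(0.02, 0.02), (0.12, 0.10), (0.30, 0.22)]
        pairs, grades = _cluster_pairs(rng, centers, n=30, spread=0.01)
        model = fit_discriminant(pairs, grades)
        scores = {g: [] for g in Grade}
        for p, g in zip(pairs, grades):
            scores[g].append(model.score(p))
        b1_true = (max(scores[Grade.NORMAL]) + min(scores[Grade.NPDR])) / 2
        b2_true = (max(scores[Grade.NPDR]) + min(scores[Grade.PDR])) / 2
        gap1 = min(scores[Grade.NPDR]) - max(scores[Grade.NORMAL])
        gap2 = min(scores[Grade.PDR]) - max(scores[Grade.NPDR])
        half_gap = min(gap1, gap2) / 2
        assert abs(model.thresholds[0] - b1_true) <= half_gap
        assert abs(model.thresholds[1] - b2_true) <= half_gap

    def test_isotropic_scatter_direction_parallel_to_mean_difference(self):
        rng = np.random.default_rng(2)
        # equal isotropic clusters along a known direction
        direction = np.array([3.0, 4.0]) / 5.0
        pairs, grades = [], []
        for k, g in enumerate(Grade):
            mu = 0.1 + 0.1 * k
            for _ in range(200):
                x = mu * direction + rng.normal(0, 0.01, 2)
                pairs.append(IndexPair(*x))
                grades.append(g)
        model = fit_discriminant(pairs, grades)
        w = model.weights / np.linalg.norm(model.weights)
        assert abs(float(w @ direction)) > 0.99

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        pairs, grades = _cluster_pairs(rng, [(0.0, 0.0), (0.1, 0.1), (0.3, 0.3)])
        m1 = fit_discriminant(pairs, grades)
        m2 = fit_discriminant(pairs, grades)
        assert m1.thresholds == m2.thresholds
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_missing_grade_rejected(self):
        pairs = [IndexPair(0, 0), IndexPair(0.1, 0.1)]
        with pytest.raises(ValueError):
            fit_discriminant(pairs, [Grade.NORMAL, Grade.NPDR])

    def test_lstsq_variant_also_separates(self):
        rng = np.random.default_rng(4)
        pairs, grades = _cluster_pairs(rng, [(0.0, 0.0), (0.15, 0.1), (0.35, 0.3)])
        model = fit_discriminant(pairs, grades, method="lstsq")
        assert model.training_accuracy == 1.0

    def test_round_trip_serialization(self):
        rng = np.random.default_rng(5)
        pairs, grades = _cluster_pairs(rng, [(0.0, 0.0), (0.1, 0.1), (0.3, 0.3)])
        model = fit_discriminant(pairs, grades)
        again = DiscriminantModel.from_dict(model.to_dict())
        assert again.thresholds == model.thresholds
        np.testing.assert_array_equal(again.weights, model.weights)

    def test_direction_matches_sklearn_lda(self):
        """Independent cross-check of the canonical axis against sklearn."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(6)
        pairs, grades = _cluster_pairs(
            rng, [(0.03, 0.02), (0.12, 0.08), (0.28, 0.2)], n=40, spread=0.02
        )
        model = fit_discriminant(pairs, grades)
        X = np.array([p.as_array() for p in pairs])
        y = np.array([Grade(g).ordinal for g in grades])
        lda = sklearn.LinearDiscriminantAnalysis(n_components=1).fit(X, y)
        w_ref = lda.scalings_[:, 0]
        w_ref /= np.linalg.norm(w_ref)
        w = model.weights / np.linalg.norm(model.weights)
        assert abs(float(w @ w_ref)) > 0.99


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(7)
    pairs, grades = _cluster_pairs(rng, [(0.01, 0.01), (0.12, 0.1), (0.3, 0.25)])
    return fit_discriminant(pairs, grades)


class TestPredictGrade:

    def test_zero_pair_is_normal(self, model):
        assert predict_grade_from_indices(model, IndexPair(0.0, 0.0)) is Grade.NORMAL

    def test_boundary_belongs_to_lower_class(self, model):
        w, b = model.weights, model.bias
        t1 = model.thresholds[0]
        # construct a pair whose score is exactly t1
        x = (t1 - b) / (w[0] + w[1])
        pair = IndexPair(float(x), float(x))
        assert model.score(pair) == pytest.approx(t1, abs=1e-9)
        assert predict_grade_from_indices(model, pair) is Grade.NORMAL

    def test_monotone_in_leakage(self, model):
        ii = 0.05
        ranks = [
            predict_grade_from_indices(model, IndexPair(ii, li)).ordinal
            for li in np.linspace(0, 0.6, 25)
        ]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))


class TestIndexSummary:
    def test_single_sample_median(self):
        pairs = [IndexPair(0.1, 0.2), IndexPair(0.3, 0.4), IndexPair(0.5, 0.6)]
        grades = [Grade.NORMAL, Grade.NPDR, Grade.PDR]
        s = index_summary(pairs, grades)
        assert s["NPDR"]["ischemic_index"]["median"] == pytest.approx(0.3)

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        pairs, grades = _cluster_pairs(rng, [(0.0, 0.0), (0.1, 0.1), (0.3, 0.3)])
        s1 = index_summary(pairs, grades)
        s2 = index_summary(pairs[::-1], grades[::-1])
        assert s1 == s2

    def test_synthetic_medians_increase_with_grade(self):
        from angiograde.synth import generate_dataset

        eyes = generate_dataset(5, 5, 5, seed=10, image_size=64)
        pairs = [IndexPair(*e.planted_indices) for e in eyes]
        grades = [e.grade for e in eyes]
        s = index_summary(pairs, grades)
        for key in ("ischemic_index", "leakage_index"):
            meds = [s[g.value][key]["median"] for g in Grade]
            assert meds[0] < meds[1] < meds[2]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            index_summary([IndexPair(0, 0)], [Grade.NORMAL])
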