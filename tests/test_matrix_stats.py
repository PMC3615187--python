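"""Mantel, AICc ranking, PCO, and correlation screens against oracles."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

from tetralink.errors import (
    AlignmentError,
    InsufficientDataError,
    ValidationError,
)
from tetralink.lipids import SPECIES_CODES, LipidProfile
from tetralink.matrix_stats import (
    aicc_of_model,
    mantel,
    pco,
    pearson_screen,
    profile_distance,
    rank_models,
)


def _profile(sid, rel, fraction="core"):
    return LipidProfile(
        spring_id=sid, fraction=fraction, rel_abundance=rel, total_igdgt=1.0
    )


def _dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestProfileDistance:
    def test_identical_profiles_are_zero_apart(self):
        a = _profile("A", {"GDGT-0": 50.0, "GDGT-4": 50.0})
        b = _profile("B", {"GDGT-0": 50.0, "GDGT-4": 50.0})
        assert profile_distance([a, b])["A", "B"] == 0.0

    def test_ten_point_shift_compensated_and_not(self):
        base = {"GDGT-0": 50.0, "GDGT-4": 50.0}
        comp = {"GDGT-0": 40.0, "GDGT-4": 60.0}
        uncomp = {"GDGT-0": 40.0, "GDGT-4": 50.0}
        a, b, c = (
            _profile("A", base),
            _profile("B", comp),
            _profile("C", uncomp),
        )
        dm = profile_distance([a, b, c])
        assert dm["A", "B"] == pytest.approx(10.0 * math.sqrt(2.0))
        assert dm["A", "C"] == pytest.approx(10.0)

    def test_fixture_matrix_matches_brute_force(self, core_profiles):
        dm = profile_distance(core_profiles)
        vecs = {p.spring_id: p.abundance_vector() for p in core_profiles}
        for a in ("E1", "E12", "E26"):
            for b in ("E2", "E19", "E36"):
                expected = math.sqrt(
                    sum((x - y) ** 2 for x, y in zip(vecs[a], vecs[b]))
                )
                assert dm[a, b] == pytest.approx(expected)

    def test_duplicate_ids_and_mixed_fractions_rejected(self):
        a = _profile("A", {"GDGT-0": 100.0})
        a2 = _profile("A", {"GDGT-1": 100.0})
        b = _profile("B", {"GDGT-0": 100.0}, fraction="polar")
        with pytest.raises(ValidationError, match="duplicate"):
            profile_distance([a, a2])
        with pytest.raises(ValidationError, match="fraction"):
            profile_distance([a, b])


class TestMantel:
    def test_self_correlation_is_one_with_smallest_attainable_p(self):
        dm = _dm([0.0, 1.0, 3.0, 7.0, 15.0, 31.0, 63.0, 127.0])
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0 / 100.0)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        da = _dm(rng.normal(size=4))
        db = _dm(rng.normal(size=4))
        va = da.condensed_form()
        B = db.data
        r_obs = np.corrcoef(va, db.condensed_form())[0, 1]
        hits = 0
        perms = list(itertools.permutations(range(4)))
        for perm in perms:
            vb = squareform(B[np.ix_(perm, perm)], checks=False)
            if abs(np.corrcoef(va, vb)[0, 1]) >= abs(r_obs) - 1e-12:
                hits += 1
        exact = hits / len(perms)
        res = mantel(da, db, n_perm=999, seed=1)
        mc_sd = math.sqrt(exact * (1 - exact) / 999)
        assert abs(res.p - exact) <= 4 * mc_sd + 2 / 999

    def test_r_invariant_under_positive_affine_transform(self):
        rng = np.random.default_rng(7)
        da = _dm(rng.normal(size=8))
        db = _dm(rng.normal(size=8))
        r0 = mantel(da, db, n_perm=0).r
        scaled = DistanceMatrix(3.5 * db.data, ids=db.ids)
        assert mantel(da, scaled, n_perm=0).r == pytest.approx(r0)
        assert abs(r0) <= 1.0

    def test_r_agrees_with_independent_library_mantel(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(11)
        da = _dm(rng.normal(size=10))
        db = _dm(rng.normal(size=(10, 2)))
        ours = mantel(da, db, n_perm=0).r
        theirs = skbio_mantel(da, db, permutations=0)
        assert ours == pytest.approx(float(theirs[0]), abs=1e-12)

    def test_spearman_form_is_rank_pearson_of_condensed_entries(self):
        rng = np.random.default_rng(13)
        da = _dm(rng.normal(size=9))
        db = _dm(rng.normal(size=9))
        res = mantel(da, db, n_perm=0, method="spearman")
        expected = np.corrcoef(
            rankdata(da.condensed_form()), rankdata(db.condensed_form())
        )[0, 1]
        assert res.r == pytest.approx(expected)

    def test_p_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        da = _dm(rng.normal(size=7))
        db = _dm(rng.normal(size=7))
        p1 = mantel(da, db, n_perm=199, seed=42).p
        p2 = mantel(da, db, n_perm=199, seed=42).p
        assert p1 == p2

    def test_label_mismatch_is_an_alignment_error(self):
        da = _dm([0.0, 1.0, 2.0], ids=["a", "b", "c"])
        db = _dm([0.0, 1.0, 2.0], ids=["a", "b", "d"])
        with pytest.raises(AlignmentError):
            mantel(da, db, n_perm=0)

    def test_same_labels_in_different_order_are_aligned(self):
        pts = {"a": 0.0, "b": 1.0, "c": 3.0, "d": 6.0}
        ids1 = ["a", "b", "c", "d"]
        ids2 = ["d", "b", "a", "c"]
        da = _dm([pts[i] for i in ids1], ids=ids1)
        db = _dm([pts[i] for i in ids2], ids=ids2)
        assert mantel(da, db, n_perm=0).r == pytest.approx(1.0)


class TestAICc:
    def test_five_site_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        resp = _dm(rng.normal(size=5))
        pred = _dm(rng.normal(size=5))
        y, x = resp.condensed_form(), pred.condensed_form()
        m = len(y)  # 10 pairs
        X = np.column_stack([np.ones(m), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        rss = float(((y - X @ beta) ** 2).sum())
        k = 3
        expected = m * math.log(rss / m) + 2 * k + 2 * k * (k + 1) / (m - k - 1)
        assert aicc_of_model(resp, pred) == pytest.approx(expected)

    def test_perfect_fit_reported_as_minus_infinity_with_warning(self):
        dm = _dm([0.0, 1.0, 2.0, 4.0, 8.0])
        with pytest.warns(RuntimeWarning):
            assert aicc_of_model(dm, dm) == -math.inf

    def test_too_few_sites_rejected(self):
        dm = _dm([0.0, 1.0, 2.0])  # m = 3 <= k + 1
        with pytest.raises(InsufficientDataError):
            aicc_of_model(dm, dm)


class TestRankModels:
    @pytest.fixture()
    def matrices(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=12)
        resp = _dm(x + rng.normal(scale=0.3, size=12))
        preds = {
            "signal": _dm(x),
            "noise1": _dm(rng.normal(size=12)),
            "noise2": _dm(rng.normal(size=12)),
        }
        return resp, preds

    def test_true_signal_ranks_first_with_zero_delta(self, matrices):
        resp, preds = matrices
        ranking = rank_models(resp, preds, n_perm=99, seed=0)
        assert ranking.best == "signal"
        assert ranking.table.iloc[0]["delta_aicc"] == 0.0
        assert ranking.table["aicc"].is_monotonic_increasing

    def test_ranking_invariant_to_predictor_order_and_seed(self, matrices):
        resp, preds = matrices
        a = rank_models(resp, preds, n_perm=49, seed=0)
        reordered = dict(reversed(list(preds.items())))
        b = rank_models(resp, reordered, n_perm=49, seed=0)
        c = rank_models(resp, preds, n_perm=49, seed=99)
        assert list(a.table["predictor"]) == list(b.table["predictor"])
        pd.testing.assert_series_equal(a.table["p"], b.table["p"])
        assert list(a.table["predictor"]) == list(c.table["predictor"])
        np.testing.assert_allclose(a.table["aicc"], c.table["aicc"])

    def test_support_categories_follow_delta_and_p(self, matrices):
        resp, preds = matrices
        ranking = rank_models(resp, preds, n_perm=999, seed=0)
        t = ranking.table.set_index("predictor")
        assert t.loc["signal", "support"] == "strong"
        for noise in ("noise1", "noise2"):
            assert t.loc[noise, "support"] == "none"

    def test_zero_permutations_leave_p_unset(self, matrices):
        resp, preds = matrices
        ranking = rank_models(resp, preds, n_perm=0)
        assert ranking.table["p"].isna().all()


class TestPCO:
    def test_planar_points_round_trip_to_procrustes_residual(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(6, 2))
        result = pco(_dm(pts))
        assert (result.eigenvalues > 1e-8).sum() == 2
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, result.coordinates.values[:, :2])
        assert disparity < 1e-8

    def test_equilateral_triangle_splits_variance_evenly(self):
        pts = [(0.0, 0.0), (1.0, 0.0), (0.5, math.sqrt(3) / 2)]
        result = pco(_dm(pts))
        pos = result.eigenvalues[result.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])
        assert result.pct_variance[:2] == pytest.approx([50.0, 50.0])

    def test_embedded_distances_are_preserved(self):
        rng = np.random.default_rng(23)
        pts = rng.normal(size=(7, 3))
        dm = _dm(pts)
        coords = pco(dm).coordinates.values
        np.testing.assert_allclose(
            squareform(pdist(coords)), dm.data, atol=1e-9
        )

    def test_euclidean_matrix_has_no_material_negative_eigenvalues(self):
        rng = np.random.default_rng(29)
        dm = _dm(rng.normal(size=(10, 4)))
        eig = pco(dm).eigenvalues
        assert eig.min() >= -1e-8 * max(1.0, eig.max())

    def test_matches_independent_library_ordination(self):
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(31)
        dm = _dm(rng.normal(size=(8, 3)))
        ours = pco(dm)
        theirs = pcoa(dm, number_of_dimensions=3)
        np.testing.assert_allclose(
            ours.eigenvalues[:3], theirs.eigvals.values[:3], atol=1e-9
        )
        np.testing.assert_allclose(
            np.abs(ours.coordinates.values[:, :3]),
            np.abs(theirs.samples.values[:, :3]),
            atol=1e-8,
        )

    def test_all_zero_distances_degenerate_with_warning(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.warns(RuntimeWarning):
            result = pco(dm)
        assert np.allclose(result.eigenvalues, 0.0)
        assert result.coordinates.shape[1] == 0

    def test_excess_axes_request_truncates_with_warning(self):
        pts = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)]
        with pytest.warns(RuntimeWarning):
            result = pco(_dm(pts), n_axes=5)
        assert result.coordinates.shape[1] == 2


class TestPearsonScreen:
    def test_agrees_with_covariance_formula_oracle(self):
        rng = np.random.default_rng(37)
        x = pd.DataFrame(rng.normal(size=(20, 2)), columns=["u", "v"])
        y = pd.DataFrame(rng.normal(size=(20, 2)), columns=["w", "z"])
        table = pearson_screen(x, y).set_index(["x", "y"])
        for xc in ("u", "v"):
            for yc in ("w", "z"):
                a, b = x[xc].values, y[yc].values
                expected = (
                    ((a - a.mean()) * (b - b.mean())).sum()
                    / math.sqrt(((a - a.mean()) ** 2).sum())
                    / math.sqrt(((b - b.mean()) ** 2).sum())
                )
                assert table.loc[(xc, yc), "r"] == pytest.approx(
                    expected, abs=1e-12
                )

    def test_perfect_and_anti_correlation(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 4.0, 9.0]})
        y = pd.DataFrame({"same": x["a"], "flipped": -x["a"]})
        table = pearson_screen(x, y).set_index("y")
        assert table.loc["same", "r"] == pytest.approx(1.0)
        assert table.loc["flipped", "r"] == pytest.approx(-1.0)

    def test_pairwise_deletion_and_short_pairs_skipped(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, np.nan, np.nan, 2.0]})
        y = pd.DataFrame({"c": [2.0, 4.0, 6.0, np.nan]})
        with pytest.warns(RuntimeWarning, match="skipped"):
            table = pearson_screen(x, y)
        kept = table.set_index(["x", "y"])
        assert kept.loc[("a", "c"), "n"] == 3
        assert ("b", "c") not in kept.index

    def test_benjamini_hochberg_column_is_monotone_in_p(self):
        rng = np.random.default_rng(41)
        x = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        y = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("def"))
        table = pearson_screen(x, y, adjust=True).sort_values("p")
        assert (table["q"] >= table["p"] - 1e-12).all()
        assert table["q"].is_monotonic_increasing
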