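import math

import numpy as np
import pytest

from catnap.core import Bout
from catnap.synchrony import (
    boutwise_correlation,
    connectivity_map,
    edges_to_frame,
    fisher_z,
    fisher_z_inv,
    state_summary,
)
from conftest import make_zmatrix


def qw_bout(n_frames, fpe=40):
    return Bout("QW", 0, n_frames // fpe, 4.0, fpe)


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.6) == pytest.approx(math.log(2.0), rel=1e-12)

    def test_odd_and_increasing(self):
        r = np.linspace(-0.95, 0.95, 21)
        np.testing.assert_allclose(fisher_z(-r), -fisher_z(r), atol=1e-12)
        assert np.all(np.diff(fisher_z(r)) > 0)

    def test_round_trip_and_clipping(self):
        r = np.linspace(-0.999, 0.999, 101)
        np.testing.assert_allclose(fisher_z_inv(fisher_z(r)), r, atol=1e-9)
        assert fisher_z(1.0) == pytest.approx(fisher_z(1 - 1e-6))
        assert np.isfinite(fisher_z(1.0))


class TestBoutwiseCorrelation:
    def test_identical_traces_hit_clip_bound(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(400)
        zm = make_zmatrix(np.vstack([x, x]))
        res = boutwise_correlation(zm, qw_bout(400))
        assert res.Z_R[0, 1] == pytest.approx(fisher_z(1 - 1e-6))

    def test_anticorrelated_pair_has_no_positive_partner(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(400)
        zm = make_zmatrix(np.vstack([x, -x]))
        res = boutwise_correlation(zm, qw_bout(400))
        assert np.isnan(res.per_cell_mean_pos_zr).all()
        assert math.isnan(res.state_mean_zr)

    def test_short_bout_skipped_with_warning(self):
        zm = make_zmatrix(np.random.default_rng(2).standard_normal((3, 80)))
        with pytest.warns(UserWarning, match="skipped"):
            assert boutwise_correlation(zm, qw_bout(80)) is None

    def test_zero_variance_cell_excluded_as_missing(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((3, 400))
        z[2] = 5.0  # flat within the bout
        res = boutwise_correlation(make_zmatrix(z), qw_bout(400))
        assert np.isnan(res.R[2]).all()
        assert not np.isnan(res.R[0, 1])

    def test_white_noise_null_matches_half_normal_oracle(self):
        """Independent cells: mean positive Z_R should match the half-normal
        mean sqrt(2 / (pi (n-3))) of the Fisher-z null within 3 SE."""
        rng = np.random.default_rng(4)
        n = 2000
        vals = []
        for _ in range(30):
            zm = make_zmatrix(rng.standard_normal((30, n)))
            vals.append(boutwise_correlation(zm, qw_bout(n)).state_mean_zr)
        expected = math.sqrt(2.0 / (math.pi * (n - 3)))
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se

    def test_additive_shift_leaves_correlations_unchanged(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((5, 400))
        res1 = boutwise_correlation(make_zmatrix(z), qw_bout(400))
        res2 = boutwise_correlation(make_zmatrix(z + 3.0), qw_bout(400))
        np.testing.assert_allclose(res1.R, res2.R, atol=1e-12, equal_nan=True)
        assert res1.state_mean_zr == pytest.approx(res2.state_mean_zr)


class TestStateSummary:
    def _result(self, zr, state="QW", start=0):
        rng = np.random.default_rng(start)
        z = rng.standard_normal((3, 400))
        res = boutwise_correlation(
            make_zmatrix(z), Bout(state, start, start + 10, 4.0, 40)
        )
        res.state_mean_zr = zr  # summarized value under test
        return res

    def test_identical_bout_values_give_zero_sem(self):
        results = {"g": [self._result(0.2, start=i * 10) for i in range(3)]}
        table, _ = state_summary(results)
        assert table.iloc[0]["mean_zr"] == pytest.approx(0.2)
        assert table.iloc[0]["sem_zr"] == pytest.approx(0.0)

    def test_balanced_design_reports_anova(self):
        results = {
            g: [self._result(v + 0.05 * i, state=s, start=i * 10 + k * 100)
                for (s, v) in (("QW", base), ("NREMS", base + 0.1))
                for i in range(3)]
            for k, (g, base) in enumerate((("ctl", 0.1), ("nar", 0.4)))
        }
        table, anova = state_summary(results)
        assert anova is not None
        assert anova.F_a > 0  # group main effect present

    def test_unbalanced_design_omits_anova(self):
        results = {
            "a": [self._result(0.1, start=0), self._result(0.2, start=10),
                  self._result(0.3, state="NREMS", start=20),
                  self._result(0.4, state="NREMS", start=30)],
            "b": [self._result(0.1, start=40), self._result(0.2, start=50),
                  self._result(0.3, state="NREMS", start=60)],
        }
        with pytest.warns(UserWarning, match="unbalanced"):
            _, anova = state_summary(results)
        assert anova is None


class TestConnectivityMap:
    def test_weak_correlations_give_empty_edges(self):
        rng = np.random.default_rng(6)
        zm = make_zmatrix(rng.standard_normal((10, 2000)))
        res = boutwise_correlation(zm, qw_bout(2000))
        centroids = {c: (0.0, float(i)) for i, c in enumerate(zm.cell_ids)}
        assert connectivity_map(res, centroids) == []

    def test_fully_synchronized_cells_give_all_pairs(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(400)
        zm = make_zmatrix(np.vstack([x] * 6))
        res = boutwise_correlation(zm, qw_bout(400))
        centroids = {c: (float(i), 0.0) for i, c in enumerate(zm.cell_ids)}
        edges = connectivity_map(res, centroids)
        assert len(edges) == 6 * 5 // 2
        df = edges_to_frame(edges)
        assert (df["R"] >= 0.6).all()

    def test_missing_centroid_drops_cell_with_warning(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(400)
        zm = make_zmatrix(np.vstack([x, x, x]))
        res = boutwise_correlation(zm, qw_bout(400))
        centroids = {"c0": (0.0, 0.0), "c1": (1.0, 1.0)}
        with pytest.warns(UserWarning, match="centroids"):
            edges = connectivity_map(res, centroids)
        assert len(edges) == 1


def test_ec_bouts_more_synchronous_than_haw(narco_session, narco_analysis):
    """Shared-drive EC bouts carry higher Z_R and more strong edges than
    same-session HAW bouts (intensity/synchrony dissociation)."""
    results = narco_analysis["synchrony"]
    ec = [r for r in results if r.bout.effective_label == "EC"]
    haw = [r for r in results if r.bout.effective_label == "HAW"]
    assert ec and haw
    assert np.mean([r.state_mean_zr for r in ec]) > np.mean(
        [r.state_mean_zr for r in haw]
    )
    centroids = {t.cell_id: t.centroid_xy for t in narco_session.tunings}
    ec_edges = np.mean([len(connectivity_map(r, centroids)) for r in ec])
    haw_edges = np.mean([len(connectivity_map(r, centroids)) for r in haw])
    assert ec_edges > haw_edges
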