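import numpy as np
import pandas as pd
import pytest

from catnap import synth
from catnap.core import Bout, Hypnogram
from catnap.sleepstate import (
    bout_durations,
    label_cataplexy_type,
    label_haw,
    score_and_segment,
    score_epochs,
    segment_bouts,
)
from conftest import make_zmatrix


def noise_free_features(labels):
    return synth.generate_epoch_features(
        Hypnogram(np.asarray(labels)), seed=0, params=synth.FeatureParams.noise_free()
    )


def epoch_features(delta, theta, emg, moving):
    return pd.DataFrame(
        {"delta_power": delta, "theta_power": theta, "emg_rms": emg,
         "movement_flag": moving}
    )


class TestScoreEpochs:
    def test_single_epoch_rules(self):
        aw = epoch_features([10.0], [2.0], [5.0], [True])
        assert score_epochs(aw).labels[0] == "AW"
        nrem = epoch_features([10.0], [2.0], [0.5], [False])
        assert score_epochs(nrem).labels[0] == "NREMS"
        qw = epoch_features([1.2], [1.0], [1.5], [False])
        assert score_epochs(qw).labels[0] == "QW"

    def test_missing_channel_errors(self):
        with pytest.raises(ValueError, match="emg_rms"):
            score_epochs(pd.DataFrame({"delta_power": [1.0], "theta_power": [1.0],
                                       "movement_flag": [False]}))

    def test_noise_free_round_trip_recovers_generating_hypnogram(self):
        cfg = synth.SessionConfig(
            genotype="narcoleptic", duration_s=7200,
            odor_onset_s=3600, odor_duration_s=3600, seed=13,
        )
        hyp, _ = synth.generate_hypnogram(cfg)
        feats = synth.generate_epoch_features(
            hyp, seed=13, params=synth.FeatureParams.noise_free()
        )
        scored = score_epochs(feats)
        assert (hyp.labels == "CATAPLEXY").any()
        assert (scored.labels == hyp.labels).all()


class TestSegmentBouts:
    def test_basic_runs(self):
        bouts = segment_bouts(Hypnogram(np.array(["AW", "AW", "QW"])))
        assert [(b.state, b.start_epoch, b.end_epoch) for b in bouts] == [
            ("AW", 0, 2), ("QW", 2, 3)
        ]
        assert bouts[0].start_frame == 0 and bouts[0].end_frame == 80

    def test_alternating_labels_give_one_bout_each(self):
        labels = np.array(["AW", "QW"] * 8)
        assert len(segment_bouts(Hypnogram(labels))) == 16

    def test_partition_round_trip(self):
        rng = np.random.default_rng(2)
        labels = rng.choice(["AW", "QW", "NREMS", "REMS"], size=200)
        bouts = segment_bouts(Hypnogram(labels))
        rebuilt = np.concatenate(
            [[b.state] * b.n_epochs for b in bouts]
        )
        np.testing.assert_array_equal(rebuilt, labels)
        assert bouts[0].start_epoch == 0 and bouts[-1].end_epoch == 200


class TestValidateCataplexy:
    def run(self, labels):
        feats = noise_free_features(labels)
        return score_and_segment(feats)

    def test_qualifying_run_kept(self):
        labels = ["AW"] * 10 + ["CATAPLEXY"] * 2 + ["AW"] * 3
        bouts = self.run(labels)
        assert [b.state for b in bouts] == ["AW", "CATAPLEXY", "AW"]

    def test_too_short_run_rejected(self):
        # 4 s atonia does not meet the 8 s minimum; wake context -> QW
        labels = ["AW"] * 10 + ["CATAPLEXY"] + ["AW"] * 3
        bouts = self.run(labels)
        assert "CATAPLEXY" not in {b.state for b in bouts}
        assert bouts[1].state == "QW"

    def test_insufficient_prior_wake_rejected_to_rems_after_nrems(self):
        labels = ["AW"] * 4 + ["NREMS"] * 8 + ["CATAPLEXY"] * 3 + ["AW"] * 2
        bouts = self.run(labels)
        states = [b.state for b in bouts]
        assert "CATAPLEXY" not in states
        assert states == ["AW", "NREMS", "REMS", "AW"]

    def test_sequential_chaining_within_40s(self):
        # second run starts 20 s (5 epochs) after the first qualifying bout
        labels = (["AW"] * 10 + ["CATAPLEXY"] * 3 + ["AW"] * 5
                  + ["CATAPLEXY"] * 2 + ["QW"] * 2)
        bouts = self.run(labels)
        cats = [b for b in bouts if b.state == "CATAPLEXY"]
        assert len(cats) == 2
        assert cats[1].chain_start_epoch == cats[0].start_epoch

    def test_chain_broken_by_sleep_gap(self):
        labels = (["AW"] * 10 + ["CATAPLEXY"] * 2 + ["NREMS"] * 2
                  + ["CATAPLEXY"] * 2 + ["AW"] * 2)
        bouts = self.run(labels)
        cats = [b for b in bouts if b.state == "CATAPLEXY"]
        assert len(cats) == 1  # second run rejected (REMS after NREMS)
        assert [b.state for b in bouts].count("REMS") == 1


def _bout(state, start, end, derived=None, chain=None):
    return Bout(state, start, end, 4.0, 40, derived_label=derived,
                chain_start_epoch=chain)


class TestLabelHaw:
    def make_z(self, post_shift, n_cells=50, seed=0):
        """Pre-odor AW bout [0, 50) epochs, post-odor AW bout [50, 55)."""
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n_cells, 55 * 40))
        z[:, 50 * 40 :] += post_shift
        return make_zmatrix(z)

    def bouts(self):
        return [_bout("AW", 0, 50), _bout("AW", 50, 55)]

    def test_shifted_bout_detected_as_haw(self):
        z = self.make_z(post_shift=1.0)
        out = label_haw(self.bouts(), z, odor_onset_s=200.0)
        assert out[1].derived_label == "HAW"
        assert out[0].derived_label is None  # pre-odor AW untouched

    def test_null_bout_is_awo(self):
        z = self.make_z(post_shift=0.0, seed=1)
        out = label_haw(self.bouts(), z, odor_onset_s=200.0)
        assert out[1].derived_label == "AWO"

    def test_no_pre_odor_baseline_errors(self):
        z = self.make_z(0.0)
        with pytest.raises(ValueError, match="baseline"):
            label_haw([_bout("AW", 50, 55)], z, odor_onset_s=200.0)

    def test_no_post_odor_bouts_is_noop(self):
        z = self.make_z(0.0)
        out = label_haw([_bout("AW", 0, 50)], z, odor_onset_s=300.0)
        assert out[0].derived_label is None


class TestLabelCataplexyType:
    def test_undisturbed_aw_gives_sc(self):
        bouts = [_bout("AW", 0, 10), _bout("CATAPLEXY", 10, 12)]
        out = label_cataplexy_type(bouts)
        assert out[1].derived_label == "SC"

    def test_haw_gives_ec_and_qw_is_skipped(self):
        bouts = [_bout("AW", 0, 10, derived="HAW"), _bout("QW", 10, 12),
                 _bout("AW", 12, 22, derived="HAW"), _bout("CATAPLEXY", 22, 24)]
        out = label_cataplexy_type(bouts)
        assert out[3].derived_label == "EC"

    def test_awo_gives_sc(self):
        bouts = [_bout("AW", 0, 10, derived="AWO"), _bout("CATAPLEXY", 10, 12)]
        assert label_cataplexy_type(bouts)[1].derived_label == "SC"

    def test_chained_bout_inherits_chain_root_type(self):
        bouts = [
            _bout("AW", 0, 10, derived="HAW"),
            _bout("CATAPLEXY", 10, 12, chain=10),
            _bout("AW", 12, 17, derived="AWO"),  # short gap, not hyperactive
            _bout("CATAPLEXY", 17, 19, chain=10),
        ]
        out = label_cataplexy_type(bouts)
        assert out[1].derived_label == "EC"
        assert out[3].derived_label == "EC"  # inherits despite AWO gap

    def test_missing_wake_context_errors(self):
        with pytest.raises(ValueError, match="no preceding wake"):
            label_cataplexy_type([_bout("CATAPLEXY", 0, 2)])


class TestBoutDurations:
    def test_identical_groups_give_zero_f(self):
        bouts = [_bout("CATAPLEXY", i * 4, i * 4 + 2, derived=d)
                 for i, d in enumerate(["SC", "SC", "EC", "EC"])]
        res = bout_durations(bouts)
        assert res.anova.F == 0.0
        assert res.mean_by_label["SC"] == 8.0

    def test_separated_groups_flagged_degenerate(self):
        bouts = (
            [_bout("CATAPLEXY", i * 10, i * 10 + 2, derived="SC") for i in range(3)]
            + [_bout("CATAPLEXY", 100 + i * 10, 100 + i * 10 + 4, derived="EC")
               for i in range(3)]
        )
        res = bout_durations(bouts)
        assert res.anova.degenerate and np.isinf(res.anova.F)

    def test_matches_anova_oracle_on_random_durations(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(8)
        sc = rng.integers(2, 12, size=10)
        ec = rng.integers(2, 12, size=14)
        bouts = []
        t = 0
        for d in sc:
            bouts.append(_bout("CATAPLEXY", t, t + int(d), derived="SC"))
            t += int(d) + 5
        for d in ec:
            bouts.append(_bout("CATAPLEXY", t, t + int(d), derived="EC"))
            t += int(d) + 5
        res = bout_durations(bouts)
        ref = f_oneway(res.durations_by_label["SC"], res.durations_by_label["EC"])
        assert res.anova.F == pytest.approx(ref.statistic, rel=1e-9)

    def test_small_groups_report_durations_only(self):
        bouts = [_bout("CATAPLEXY", 0, 2, derived="SC")]
        res = bout_durations(bouts)
        assert res.anova is None
        assert res.durations_by_label["SC"] == [8.0]
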