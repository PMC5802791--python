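"""Generator contracts: schedule structure, recall model, features, raw signal."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps
from scipy.special import expit, logit
from scipy.stats import ttest_ind

from memloop import synthgen
from memloop.config import StudyConfig, profile_config
from memloop.synthgen import (
    InvalidAssignmentError,
    flanking_indicator,
    make_schedule,
    make_subject,
    simulate_features,
    simulate_raw,
    simulate_recall,
    simulate_trial_table,
)


class TestMakeSchedule:
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_list_counts_exact(self, cfg, seed):
        sched = make_schedule(cfg, seed)
        roles = sched.lists["list_role"].value_counts().to_dict()
        assert roles == {"Stim": 11, "NoStim": 11, "baseline": 3, "practice": 1}
        assert len(sched.lists) == 26
        per_list = sched.words.groupby("list_index").size()
        assert (per_list == 12).all()

    def test_onsets_strictly_increasing(self, cfg):
        sched = make_schedule(cfg, 3)
        assert (np.diff(sched.words["onset_ms"]) > 0).all()

    def test_seed_contract(self, cfg):
        a = make_schedule(cfg, 5)
        b = make_schedule(cfg, 5)
        pd.testing.assert_frame_equal(a.words, b.words)
        # different seeds give a different Stim/NoStim interleave (w.h.p.)
        interleaves = {
            tuple(make_schedule(cfg, s).lists["list_role"].iloc[4:]) for s in range(6)
        }
        assert len(interleaves) > 1

    def test_baseline_lists_are_first_three(self, cfg):
        sched = make_schedule(cfg, 4)
        roles = sched.lists.set_index("list_index")["list_role"]
        assert roles.loc[0] == "practice"
        assert (roles.loc[1:3] == "baseline").all()

    def test_record_only_roles(self, cfg):
        sched = make_schedule(cfg, 4, kind="record_only")
        assert (sched.lists["list_role"].iloc[1:] == "record").all()


class TestSimulateRecall:
    def test_null_stim_effect_balances_rates(self):
        # with a zero stimulation effect, stimulated and unstimulated words
        # on Stim lists recall at the same rate (within Monte-Carlo error)
        cfg = profile_config("lateral_temporal", n_subjects=1, seed=0,
                            stim_log_odds=0.0, flank_log_odds=0.0)
        rates_s, rates_u = [], []
        for s in range(40):
            sched = make_schedule(cfg, s)
            stim = (sched.words["list_role"] == "Stim").to_numpy()
            stim &= np.random.default_rng(s).random(len(stim)) < 0.5
            ev = simulate_recall(sched, cfg, stim_assignment=stim, seed=1000 + s)
            on_stim = ev[ev["list_role"] == "Stim"]
            rates_s.append(on_stim[on_stim["stimulated"]]["recalled"].mean())
            rates_u.append(on_stim[~on_stim["stimulated"]]["recalled"].mean())
        n = 40 * 132 / 2
        se = np.sqrt(2 * 0.26 * 0.74 / n)
        assert abs(np.mean(rates_s) - np.mean(rates_u)) < 2 * se

    def test_grand_mean_matches_baseline_probability(self):
        cfg = profile_config("lateral_temporal", n_subjects=1, seed=0)
        recalls = []
        for s in range(30):
            sched = make_schedule(cfg, s, kind="record_only")
            ev = simulate_recall(sched, cfg, seed=2000 + s)
            recalls.append(ev["recalled"].mean())
        assert np.mean(recalls) == pytest.approx(0.261, abs=0.01)

    def test_generating_odds_ratio_monte_carlo(self):
        # brute-force 2x2 contingency OR over 10^6 trials against the
        # closed-form generating odds ratio of 1.18
        cfg = profile_config("lateral_temporal", n_subjects=1, seed=0,
                            flank_log_odds=0.0)
        rng = np.random.default_rng(123)
        n = 1_000_000
        stim = rng.random(n) < 0.5
        p = expit(logit(cfg.baseline_recall_prob) + cfg.stim_log_odds * stim)
        rec = rng.random(n) < p
        a = np.sum(rec & stim)
        b = np.sum(~rec & stim)
        c = np.sum(rec & ~stim)
        d = np.sum(~rec & ~stim)
        or_hat = (a * d) / (b * c)
        assert 1.16 <= or_hat <= 1.20

    def test_assignment_on_nostim_list_rejected(self, cfg):
        sched = make_schedule(cfg, 6)
        stim = (sched.words["list_role"] == "NoStim").to_numpy()
        with pytest.raises(InvalidAssignmentError):
            simulate_recall(sched, cfg, stim_assignment=stim, seed=0)

    def test_reproducible_under_seed(self, cfg):
        sched = make_schedule(cfg, 7)
        a = simulate_recall(sched, cfg, seed=11)
        b = simulate_recall(sched, cfg, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_flanking_indicator_excludes_stimulated(self, cfg):
        sched = make_schedule(cfg, 8)
        words = sched.words
        stim = np.zeros(len(words), dtype=bool)
        stim_list = words[words["list_role"] == "Stim"]["list_index"].iloc[0]
        rows = words.index[(words["list_index"] == stim_list)
                           & words["serial_pos"].isin([3, 4, 7])]
        stim[rows] = True
        flank = flanking_indicator(words, stim)
        flank_pos = set(words.loc[flank & (words["list_index"] == stim_list).to_numpy(),
                                  "serial_pos"])
        # neighbors of 3, 4, 7 that are not themselves stimulated
        assert flank_pos == {2, 5, 6, 8}
        assert not (flank & stim).any()


class TestSimulateFeatures:
    def test_zero_sme_classifier_at_chance(self, cfg):
        from memloop.decoder import cross_validated_auc
        from memloop.sigproc import normalize_features

        c = cfg.replace(sme_effect=0.0, seed=21)
        prof = make_subject(c, 1)
        ev, feats = synthgen.simulate_record_session(c, prof, 0)
        z = normalize_features(feats, "within_session")
        a = cross_validated_auc(z.values, ev["recalled"], seed=3)
        assert abs(a - 0.5) < 0.11  # ~2.5 SE at ~300 events

    def test_hfa_shift_detectable(self, cfg):
        # recalled events carry more high-frequency power: one-sided t-test
        prof = make_subject(cfg, 0)
        sched = make_schedule(cfg, 30, kind="record_only")
        ev = simulate_recall(sched, cfg, seed=31, profile=prof)
        c = cfg.replace(sme_effect=0.3)
        feats = simulate_features(ev, c, seed=32, profile=prof)
        hfa_cols = feats.columns_for_freqs(feats.freqs >= 100.0)
        hfa = feats.values[:, hfa_cols].mean(axis=1)
        rec = ev["recalled"].to_numpy(dtype=bool)
        res = ttest_ind(hfa[rec], hfa[~rec], alternative="greater")
        assert res.pvalue < 0.01

    def test_zscored_columns_calibrated(self, cfg):
        from memloop.sigproc import normalize_features

        prof = make_subject(cfg, 0)
        sched = make_schedule(cfg, 33, kind="record_only")
        ev = simulate_recall(sched, cfg, seed=34, profile=prof)
        feats = simulate_features(ev, cfg, seed=35, profile=prof)
        z = normalize_features(feats, "within_session")
        assert np.abs(z.values.mean(axis=0)).max() < 0.05
        assert z.values.std(axis=0, ddof=1).min() > 0.9
        assert z.values.std(axis=0, ddof=1).max() < 1.1

    def test_reproducible_and_subject_independent(self, cfg):
        prof0, prof1 = make_subject(cfg, 0), make_subject(cfg, 1)
        sched = make_schedule(cfg, 36, kind="record_only")
        ev = simulate_recall(sched, cfg, seed=37, profile=prof0)
        a = simulate_features(ev, cfg, seed=38, profile=prof0)
        b = simulate_features(ev, cfg, seed=38, profile=prof0)
        other = simulate_features(ev, cfg, seed=38, profile=prof1)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, other.values)


@pytest.fixture(scope="module")
def raw_session():
    cfg = profile_config("lateral_temporal", n_subjects=1, seed=9,
                        electrodes_per_subject=6)
    prof = make_subject(cfg, 0)
    sched = make_schedule(cfg, 40, kind="record_only")
    ev = simulate_recall(sched, cfg, seed=41, profile=prof)
    # a short stretch of events is enough for spectral checks
    ev = ev.iloc[:24].copy()
    raw, layout = simulate_raw(ev, cfg, seed=42, profile=prof)
    return raw, layout, ev


class TestSimulateRaw:
    def test_one_over_f_slope_negative(self, raw_session):
        raw, _, _ = raw_session
        f, pxx = sps.welch(raw.data[0], fs=raw.sfreq, nperseg=4096)
        band = (f >= 3.0) & (f <= 180.0) & (np.abs(f - 60.0) > 5.0)
        slope = np.polyfit(np.log(f[band]), np.log(pxx[band]), 1)[0]
        assert slope < -0.5

    def test_line_noise_peak(self, raw_session):
        raw, _, _ = raw_session
        f, pxx = sps.welch(raw.data[0], fs=raw.sfreq, nperseg=8192)
        i60 = np.argmin(np.abs(f - 60.0))
        neighbors = pxx[[i60 - 4, i60 + 4]]
        assert pxx[i60] >= 10 * neighbors.max()

    def test_word_alignment_and_determinism(self, raw_session):
        raw, layout, ev = raw_session
        cfg = profile_config("lateral_temporal", n_subjects=1, seed=9,
                            electrodes_per_subject=6)
        prof = make_subject(cfg, 0)
        raw2, _ = simulate_raw(ev, cfg, seed=42, profile=prof)
        assert np.array_equal(raw.data, raw2.data)
        assert len(layout) == 5


def test_full_raw_pipeline_recovers_memory_signal():
    """simulate_raw -> notch -> bipolar -> wavelet -> z-score -> classifier
    discriminates later-recalled words well above chance."""
    from memloop import decoder, sigproc

    cfg = profile_config("lateral_temporal", n_subjects=1, seed=5,
                        electrodes_per_subject=6)
    prof = make_subject(cfg, 0)
    X, y = [], []
    for s in range(2):
        base = ("record", prof.site, s)
        sched = make_schedule(cfg, cfg.seed_for(*base, "sched"), kind="record_only")
        ev = simulate_recall(sched, cfg, seed=cfg.seed_for(*base, "recall"),
                             profile=prof, session=s)
        raw, layout = simulate_raw(ev, cfg, seed=cfg.seed_for(*base, "raw"),
                                   profile=prof)
        bip = sigproc.bipolar_rereference(sigproc.notch_filter(raw), layout)
        feats = sigproc.wavelet_power(bip, ev["onset_ms"].to_numpy())
        z = sigproc.normalize_features(feats, "within_session")
        X.append(z.values)
        y.append(ev["recalled"].to_numpy())
    model = decoder.train(X[0], y[0])
    heldout = decoder.auc(decoder.predict(model, X[1]), y[1])
    assert heldout > 0.55


class TestTrialTableGenerators:
    def test_trial_table_shape_and_balance(self):
        tab = simulate_trial_table(29, 130, 0.2, np.log(1.18), seed=0)
        assert len(tab) == 29 * 130
        assert tab["site"].nunique() == 29
        assert tab["subject"].nunique() == 26  # three subjects carry two sites
        per_site = tab.groupby("site")["stim"].sum()
        assert (per_site == 65).all()

    def test_marginal_rates_converge_to_generating_model(self):
        tab = simulate_trial_table(200, 400, 0.25, np.log(1.5),
                                   intercept_sd=0.0, slope_sd=0.0, seed=1)
        p0 = tab[tab["stim"] == 0]["recalled"].mean()
        p1 = tab[tab["stim"] == 1]["recalled"].mean()
        assert p0 == pytest.approx(0.25, abs=0.01)
        assert p1 == pytest.approx(expit(logit(0.25) + np.log(1.5)), abs=0.01)

    def test_delta_table_mean_difference(self):
        tab = synthgen.simulate_delta_table(50, 200, 0.05, seed=2)
        diff = (tab[tab["stim"] == 1]["delta"].mean()
                - tab[tab["stim"] == 0]["delta"].mean())
        assert diff == pytest.approx(0.05, abs=0.01)
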