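"""Effect models: parameter recovery, null calibration, reductions, oracles."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from memloop import stimstats, synthgen
from memloop.glmm import fit_logistic_glmm, intercept_and_slope_blocks
from memloop.stimstats import (
    EmptyAnalysisError,
    balance_checks,
    build_delta_table,
    delta_classifier_analysis,
    fit_flanking_glme,
    fit_log_binomial,
    fit_stim_glme,
    percent_change,
)


class TestStimGlme:
    def test_null_calibration(self):
        """Type-I error at alpha=0.05 stays within its binomial tolerance and
        the mean estimate sits near OR = 1."""
        rejections, ors = 0, []
        n_rep = 40
        for s in range(n_rep):
            tab = synthgen.simulate_trial_table(20, 120, 0.25, 0.0, seed=500 + s)
            est = fit_stim_glme(tab)
            rejections += est.p < 0.05
            ors.append(est.estimate)
        assert rejections / n_rep <= 0.125  # 0.08 + binomial slack at 40 reps
        assert 0.9 <= np.mean(ors) <= 1.1

    def test_recovery_of_generating_odds_ratio(self):
        ors = []
        for s in range(15):
            tab = synthgen.simulate_trial_table(29, 130, 0.20, np.log(1.18),
                                                seed=600 + s)
            ors.append(fit_stim_glme(tab).estimate)
        assert 1.10 <= np.mean(ors) <= 1.26

    def test_collapse_to_glm(self):
        # constraining random-effect variances to (numerically) zero must
        # reproduce the ordinary logistic regression estimate
        tab = synthgen.simulate_trial_table(10, 100, 0.25, 0.3,
                                            intercept_sd=0.0, slope_sd=0.0, seed=3)
        X = np.column_stack([np.ones(len(tab)), tab["stim"].to_numpy(float)])
        collapsed = fit_logistic_glmm(
            tab["recalled"].to_numpy(float), X,
            intercept_and_slope_blocks(tab, "subject", "stim"),
            exog_names=["Intercept", "stim"],
            fixed_log_sd=np.array([-6.0, -6.0]),
        )
        glm = fit_stim_glme(tab, random_effects=False)
        assert collapsed.coef("stim")[0] == pytest.approx(glm.coefficient, abs=1e-3)

    def test_matches_lme4_oracle(self, tmp_path):
        """Independent cross-check: same model fit by lme4::glmer in R."""
        tab = synthgen.simulate_trial_table(29, 130, 0.20, np.log(1.18), seed=0)
        ours = fit_stim_glme(tab)
        csv = tmp_path / "trials.csv"
        tab.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer(recalled ~ stim + (1|subject) + (0+stim|subject)"
            " + (1|site) + (0+stim|site), data=d, family=binomial)\n"
            "cat(fixef(m)['stim'], sqrt(diag(vcov(m)))[2], sep='\\n')\n"
        )
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        beta_r, se_r = (float(x) for x in res.stdout.strip().split("\n")[-2:])
        assert ours.coefficient == pytest.approx(beta_r, abs=0.02)
        assert ours.se == pytest.approx(se_r, rel=0.1)

    def test_row_order_and_label_invariance(self):
        tab = synthgen.simulate_trial_table(8, 80, 0.25, 0.2, seed=4)
        a = fit_stim_glme(tab)
        rng = np.random.default_rng(5)
        shuffled = tab.sample(frac=1.0, random_state=6).reset_index(drop=True)
        relabeled = shuffled.assign(
            subject=shuffled["subject"].map(lambda s: "X" + s[::-1]),
            site=shuffled["site"].map(lambda s: "Y" + s[::-1]),
        )
        b = fit_stim_glme(relabeled)
        assert a.coefficient == pytest.approx(b.coefficient, abs=1e-3)

    def test_single_condition_rejected(self):
        tab = synthgen.simulate_trial_table(4, 40, 0.25, 0.0, seed=7)
        with pytest.raises(EmptyAnalysisError):
            fit_stim_glme(tab[tab["stim"] == 1])


class TestLogBinomial:
    def test_two_by_two_equals_hand_computed_risk_ratio(self):
        # collapsed contingency fixture: RR must equal the ratio of risks
        tab = pd.DataFrame(dict(
            recalled=[1] * 30 + [0] * 70 + [1] * 20 + [0] * 80,
            stim=[1] * 100 + [0] * 100,
            group="lateral_temporal",
            subject="s0", site="t0", serial_pos=1, flank=0,
        ))
        est = fit_log_binomial(tab)
        assert est.estimate == pytest.approx((30 / 100) / (20 / 100), rel=1e-6)

    def test_null_effect_large_n(self):
        tab = synthgen.simulate_trial_table(40, 400, 0.25, 0.0, seed=8,
                                            intercept_sd=0.05, slope_sd=0.0,
                                            link="log")
        est = fit_log_binomial(tab)
        assert 0.95 <= est.estimate <= 1.05

    def test_recovery_of_relative_increase(self):
        pcts = []
        for s in range(20):
            tab = synthgen.simulate_trial_table(
                29, 130, 0.22, np.log(1.15), seed=700 + s,
                intercept_sd=0.15, slope_sd=0.05, link="log",
            )
            pcts.append(percent_change(fit_log_binomial(tab)))
        assert 12.0 <= np.mean(pcts) <= 18.0


class TestFlankingGlme:
    def test_null_calibration(self):
        rejections = 0
        for s in range(30):
            tab = synthgen.simulate_trial_table(15, 60, 0.3, 0.0, seed=900 + s)
            rejections += fit_flanking_glme(tab).p < 0.05
        assert rejections / 30 <= 0.14

    def test_positive_effect_sign_recovery(self):
        correct = 0
        for s in range(25):
            tab = synthgen.simulate_trial_table(20, 80, 0.3, 0.35, seed=950 + s)
            correct += fit_flanking_glme(tab).coefficient > 0
        assert correct >= 23

    def test_flanking_rows_never_stimulated(self, closed_loop_run):
        from memloop.loopsim import build_flanking_table

        _, out = closed_loop_run
        fl = build_flanking_table(out)
        if len(fl):
            assert not fl["stimulated"].any()


class TestDeltaClassifier:
    def test_null_effect_within_two_se(self):
        tab = synthgen.simulate_delta_table(18, 78, 0.0, seed=10)
        est = delta_classifier_analysis(tab)
        assert abs(est.estimate) < 2 * est.se

    def test_recovery_of_generating_shift(self):
        ests = []
        for s in range(20):
            tab = synthgen.simulate_delta_table(18, 78, 0.01, seed=1100 + s)
            ests.append(delta_classifier_analysis(tab).estimate)
        assert 0.005 <= np.mean(ests) <= 0.015

    def test_two_subject_fixture_matches_direct_computation(self):
        # two balanced subjects with equal cell counts and no residual noise:
        # the mixed-model condition effect equals the mean within-subject
        # difference computed directly
        rows = []
        for subj, base, eff in [("a", 0.00, 0.02), ("b", 0.01, 0.04)]:
            for stim in (0, 1):
                for rep in range(30):
                    rows.append(dict(delta=base + eff * stim, stim=stim,
                                     subject=subj, site=subj + "1",
                                     group="lateral_temporal"))
        tab = pd.DataFrame(rows)
        est = delta_classifier_analysis(tab)
        direct = np.mean([0.02, 0.04])
        assert est.estimate == pytest.approx(direct, abs=1e-3)

    def test_empty_analysis_rejected(self):
        tab = synthgen.simulate_delta_table(5, 10, 0.0, seed=11)
        with pytest.raises(EmptyAnalysisError):
            delta_classifier_analysis(tab[tab["stim"] == 1])

    def test_build_delta_table_from_events(self):
        events = pd.DataFrame(dict(
            subject="S", site="Sa", session=0, session_kind="closed_loop",
            list_index=[4] * 4, list_role=["Stim"] * 4,
            serial_pos=[1, 2, 3, 4], word=list("abcd"),
            recalled=[False] * 4,
            stimulated=[True, False, True, False],
            classifier_prob=[0.2, 0.5, 0.3, 0.6],
            matched_control=[False] * 4, group="lateral_temporal",
        ))
        tab = build_delta_table(events)
        assert len(tab) == 2
        assert tab["delta"].tolist() == pytest.approx([0.3, 0.3])
        assert (tab["stim"] == 1).all()


@pytest.fixture(scope="module")
def two_group_events():
    rng = np.random.default_rng(12)
    rows = []
    for group, n_subj in [("lateral_temporal", 8), ("non_lateral", 8)]:
        for i in range(n_subj):
            n = 264
            probs = rng.uniform(0.2, 0.8, size=n)
            rows.append(pd.DataFrame(dict(
                subject=f"{group[:3]}{i}", site=f"{group[:3]}{i}a",
                session=3, session_kind="closed_loop",
                list_index=np.repeat(np.arange(4, 26), 12),
                list_role=np.repeat(["Stim", "NoStim"] * 11, 12),
                serial_pos=np.tile(np.arange(1, 13), 22),
                word="w", recalled=rng.random(n) < 0.27,
                stimulated=False, classifier_prob=probs,
                matched_control=False, group=group,
            )))
    return pd.concat(rows, ignore_index=True)


class TestBalanceChecks:
    def test_identical_generators_balanced(self, two_group_events):
        rng = np.random.default_rng(13)
        rec_rows = []
        for group in ("lateral_temporal", "non_lateral"):
            for i in range(8):
                rec_rows.append(pd.DataFrame(dict(
                    subject=f"{group[:3]}{i}", group=group,
                    recalled=rng.random(300) < 0.27,
                )))
        record = pd.concat(rec_rows, ignore_index=True)
        res = balance_checks(two_group_events, record)
        assert set(res["estimand"]) == {
            "trigger_proportion_group_difference",
            "trigger_position_by_group",
            "record_only_recall_group_difference",
        }
        assert (res["p"] > 0.05).all()

    def test_group_means_near_design_rates(self, two_group_events):
        res = balance_checks(two_group_events)
        row = res[res["estimand"] == "trigger_proportion_group_difference"].iloc[0]
        assert abs(row["estimate"]) < 0.05

    def test_sme_tmap_at_null_electrode(self, cfg):
        """At an electrode with no memory effect, |t| rarely exceeds 2."""
        from memloop.sigproc import normalize_features

        c = cfg.replace(sme_effect=0.0, seed=44)
        exceed, total = 0, 0
        for i in range(6):
            prof = synthgen.make_subject(c, i)
            ev, feats = synthgen.simulate_record_session(c, prof, 0)
            z = normalize_features(feats, "within_session")
            pair0 = z.values[:, z.columns_for_pair(0)]
            t = stimstats.sme_tmap(pair0, ev["recalled"])
            exceed += int((np.abs(t) > 2).sum())
            total += t.size
        assert exceed / total <= 0.10

    def test_sme_map_null_calibration(self):
        rng = np.random.default_rng(14)
        tmaps = pd.DataFrame(dict(
            freq=np.tile(np.geomspace(3, 180, 8), 30),
            group=np.repeat(["lateral_temporal", "non_lateral"], 120),
            t_sme=rng.standard_normal(240),
            site=np.repeat([f"s{i}" for i in range(30)], 8),
        ))
        res = stimstats.sme_map_comparison(tmaps)
        assert len(res) == 8
        assert (np.abs(res["t"]) > 2).mean() <= 0.25
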