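"""Survival machinery: hand-computed oracles and stratification contracts."""

import numpy as np
import pandas as pd
import pytest

from stromasig.scoring import ScoreVector
from stromasig.survival import (
    RelapseLabel,
    StratumLabels,
    cox_fit,
    km_estimate,
    logrank_test,
    median_split,
    optimal_cox_cutoff,
    relapse_labels,
    top_fraction_split,
    youden_cutoff,
)

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


def labels_for(surv, high_ids):
    lab = pd.Series(["High" if i in set(high_ids) else "Low" for i in surv.index], index=surv.index)
    return StratumLabels(labels=lab, cutoff=0.0, method="median")


def km_oracle(times, events):
    """Hand product-limit estimator at each distinct event time."""
    out = []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n_at_risk
        out.append((t, s))
    return out


def logrank_oracle(times, events, in_a):
    """Explicit per-event-time (O-E, V) tabulation for two groups."""
    o_minus_e = 0.0
    v = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & in_a).sum()
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v if v > 0 else 0.0


class TestKaplanMeier:
    def test_no_events_flat_curve(self, toy_surv):
        surv = toy_surv.assign(event=0)
        curves = km_estimate(surv, labels_for(surv, ["P1", "P2", "P3"]))
        for c in curves.values():
            assert np.allclose(c.survival, 1.0)

    def test_hand_product_limit_four_samples(self):
        surv = pd.DataFrame(
            {"rfs_months": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 0, 0]},
            index=list("abcd"),
        )
        curves = km_estimate(surv, labels_for(surv, list("abcd")[:2]) )
        # group must contain all four: use a single-group trick via High=all
        all_lab = labels_for(surv, list("abcd"))
        with pytest.raises(ValueError):
            km_estimate(surv, all_lab)  # Low group empty

    def test_matches_oracle_and_is_monotone_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            surv = pd.DataFrame(
                {
                    "rfs_months": rng.choice([1.0, 2, 3, 5, 8, 13], size=n),
                    "event": rng.integers(0, 2, size=n),
                },
                index=[f"x{i}" for i in range(n)],
            )
            if surv["event"].sum() == 0:
                continue
            high = list(surv.index[: n // 2 + 1])
            low = list(surv.index[n // 2 + 1:])
            if not low:
                continue
            curves = km_estimate(surv, labels_for(surv, high))
            for grp, ids in (("High", high), ("Low", low)):
                sub = surv.loc[ids]
                if sub["event"].sum() == 0:
                    continue
                c = curves[grp]
                assert c.at(0.0) == 1.0
                assert (np.diff(c.survival) <= 1e-12).all()
                assert ((c.survival >= 0) & (c.survival <= 1)).all()
                for t, s in km_oracle(sub["rfs_months"].to_numpy(), sub["event"].to_numpy()):
                    assert c.at(t) == pytest.approx(s, abs=1e-9)

    def test_duplicating_samples_leaves_curve_unchanged(self, toy_surv):
        lab = labels_for(toy_surv, ["P1", "P2", "P3"])
        c1 = km_estimate(toy_surv, lab)["High"]
        doubled = pd.concat([toy_surv, toy_surv.set_index(toy_surv.index + "_b")])
        lab2 = labels_for(doubled, ["P1", "P2", "P3", "P1_b", "P2_b", "P3_b"])
        c2 = km_estimate(doubled, lab2)["High"]
        assert np.allclose(c1.survival, c2.survival)


class TestLogRank:
    def test_identical_groups_statistic_zero(self, toy_surv):
        doubled = pd.concat([toy_surv, toy_surv.set_index(toy_surv.index + "_b")])
        lab = labels_for(doubled, list(toy_surv.index))
        res = logrank_test(doubled, lab)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_per_event_time_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(6, 11))
            surv = pd.DataFrame(
                {
                    "rfs_months": rng.choice([1.0, 2, 3, 5, 8], size=n),
                    "event": rng.integers(0, 2, size=n),
                },
                index=[f"x{i}" for i in range(n)],
            )
            if surv["event"].sum() == 0:
                continue
            high = list(surv.index[: n // 2])
            lab = labels_for(surv, high)
            in_a = surv.index.isin(high)
            want = logrank_oracle(surv["rfs_months"].to_numpy(), surv["event"].to_numpy(), in_a)
            got = logrank_test(surv, lab)
            assert got.statistic == pytest.approx(want, abs=1e-9)

    def test_label_swap_symmetry(self, toy_surv):
        lab = labels_for(toy_surv, ["P1", "P3", "P5"])
        swapped = StratumLabels(
            labels=lab.labels.map({"High": "Low", "Low": "High"}), cutoff=0.0, method="median"
        )
        assert logrank_test(toy_surv, lab).statistic == pytest.approx(
            logrank_test(toy_surv, swapped).statistic, abs=1e-12
        )


def test_logrank_one_event_minimum(toy_surv):
    surv = toy_surv.assign(event=0)
    with pytest.raises(ValueError):
        logrank_test(surv, labels_for(surv, ["P1", "P2"]))


def partial_loglik_oracle(t, e, x, beta):
    """Breslow log partial likelihood, written independently (no ties in data)."""
    ll = 0.0
    for i in range(len(t)):
        if e[i] == 1:
            risk = np.exp(beta * x[t >= t[i]])
            ll += beta * x[i] - np.log(risk.sum())
    return ll


class TestCox:
    def test_fitted_beta_beats_grid(self):
        surv = pd.DataFrame(
            {"rfs_months": [2.0, 4.0, 6.0, 8.0, 10.0], "event": [1, 1, 1, 0, 1]},
            index=list("abcde"),
        )
        x = pd.Series([1.0, 0.0, 1.0, 0.0, 0.0], index=surv.index, name="g")
        for ties in ("efron", "breslow"):  # no ties: both maximise the same likelihood
            fit = cox_fit(surv, x, ties=ties)
            beta_hat = float(fit.summary.loc["g", "coef"])
            t, e, xv = surv["rfs_months"].to_numpy(), surv["event"].to_numpy(), x.to_numpy()
            ll_hat = partial_loglik_oracle(t, e, xv, beta_hat)
            grid = np.linspace(-5, 5, 10001)
            ll_grid = max(partial_loglik_oracle(t, e, xv, b) for b in grid)
            assert ll_hat >= ll_grid - 1e-8

    def test_scaling_a_term_preserves_model_lr_p(self):
        rng = np.random.default_rng(2)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.5 * x))
        surv = pd.DataFrame({"rfs_months": t, "event": 1}, index=[f"s{i}" for i in range(n)])
        t1 = pd.DataFrame({"x": x}, index=surv.index)
        t2 = pd.DataFrame({"x": 2 * x}, index=surv.index)
        f1, f2 = cox_fit(surv, t1), cox_fit(surv, t2)
        assert f1.lr_p == pytest.approx(f2.lr_p, rel=1e-6)
        assert f1.hr("x") == pytest.approx(f2.hr("x") ** 2, rel=1e-4)

    def test_breslow_matches_efron_without_ties(self):
        rng = np.random.default_rng(8)
        n = 40
        x = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.7 * x))
        surv = pd.DataFrame({"rfs_months": t, "event": 1}, index=[f"s{i}" for i in range(n)])
        fe = cox_fit(surv, pd.Series(x, index=surv.index, name="x"), ties="efron")
        fb = cox_fit(surv, pd.Series(x, index=surv.index, name="x"), ties="breslow")
        assert fe.summary.loc["x", "coef"] == pytest.approx(fb.summary.loc["x", "coef"], abs=1e-4)
        assert fe.summary.loc["x", "se"] == pytest.approx(fb.summary.loc["x", "se"], rel=1e-3)

    def test_constant_term_errors(self, toy_surv):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(toy_surv, pd.Series(1.0, index=toy_surv.index, name="c"))

    def test_ci_coverage_of_true_hazard_ratio(self):
        """95% Wald CI covers HR=2 in 93-97 of 100 exponential simulations."""
        true_hr = 2.0
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            grp = np.repeat([0.0, 1.0], 250)
            t = rng.exponential(1.0 / (0.05 * true_hr**grp))
            surv = pd.DataFrame(
                {"rfs_months": t, "event": 1}, index=[f"s{i}" for i in range(500)]
            )
            fit = cox_fit(surv, pd.Series(grp, index=surv.index, name="g"))
            lo, hi = fit.summary.loc["g", ["ci_low", "ci_high"]]
            hits += int(lo <= true_hr <= hi)
        assert 93 <= hits <= 97


class TestOptimalCutoff:
    def test_requires_events(self, toy_surv):
        score = ScoreVector(pd.Series(np.arange(6.0), index=toy_surv.index), method="ssgsea")
        with pytest.raises(ValueError):
            optimal_cox_cutoff(score, toy_surv.assign(event=0))

    def test_constant_scores_error(self, toy_surv):
        score = ScoreVector(pd.Series(1.0, index=toy_surv.index), method="ssgsea")
        with pytest.raises(ValueError, match="admissible"):
            optimal_cox_cutoff(score, toy_surv)

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(4)
        n = 60
        s = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        t = rng.exponential(1 / np.exp(0.8 * (s > 0).astype(float)))
        surv = pd.DataFrame({"rfs_months": t, "event": 1}, index=s.index)
        lab1 = optimal_cox_cutoff(ScoreVector(s, method="x"), surv)
        lab2 = optimal_cox_cutoff(ScoreVector(np.exp(3 * s), method="x"), surv)
        assert (lab1.labels == lab2.labels).all()

    def test_reapplying_cutoff_reproduces_labels(self, default_cohort):
        from stromasig.scoring import fibroblast_geneset, ssgsea_score

        c = default_cohort
        score = ssgsea_score(c.expression, fibroblast_geneset(c.genesets["MCP_FIBROBLAST"]))
        lab = optimal_cox_cutoff(score, c.clinical)
        reapplied = np.where(score.scores >= lab.cutoff, "High", "Low")
        assert (reapplied == lab.labels.to_numpy()).all()


class TestTopFractionSplit:
    def test_validation_cohort_count(self):
        """Top-20% of a 258-sample cohort is exactly 52 samples."""
        rng = np.random.default_rng(0)
        s = pd.Series(rng.normal(size=258), index=[f"s{i:03d}" for i in range(258)])
        lab = top_fraction_split(ScoreVector(s, method="ssgsea"), 0.20)
        assert lab.counts() == {"High": 52, "Low": 206}

    def test_distinct_scores_pick_the_largest(self):
        s = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        lab = top_fraction_split(ScoreVector(s, method="x"), 0.5)
        assert set(lab.high) == {f"s{i}" for i in range(5, 10)}

    def test_all_ties_resolved_by_id_with_warning(self):
        s = pd.Series(1.0, index=[f"s{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="ties"):
            lab = top_fraction_split(ScoreVector(s, method="x"), 0.3)
        assert lab.counts()["High"] == 3
        assert set(lab.high) == {"s0", "s1", "s2"}

    def test_exact_count_property(self):
        rng = np.random.default_rng(1)
        for n in (7, 31, 100, 215):
            for f in (0.1, 0.2, 0.35, 0.5, 0.9):
                s = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
                lab = top_fraction_split(ScoreVector(s, method="x"), f)
                assert lab.counts()["High"] == int(np.ceil(f * n))


class TestMedianSplit:
    @pytest.mark.parametrize("n,want", [(52, 26), (74, 37)])
    def test_even_distinct_scores_split_in_half(self, n, want):
        s = pd.Series(np.arange(float(n)), index=[f"s{i}" for i in range(n)])
        lab = median_split(ScoreVector(s, method="x"))
        assert lab.counts() == {"High": want, "Low": want}

    def test_degenerate_ties_error(self):
        s = pd.Series([1.0, 1.0, 1.0, 2.0], index=list("abcd"))
        # median is 1 -> all four land High under the >= rule
        with pytest.raises(ValueError, match="degenerate|one side"):
            median_split(ScoreVector(s, method="x"))

    def test_zero_variance_errors(self):
        s = pd.Series([2.0] * 6, index=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError):
            median_split(ScoreVector(s, method="x"))


class TestRelapseLabels:
    def test_conventions(self):
        surv = pd.DataFrame(
            {
                "rfs_months": [30.0, 12.0, 70.0, 80.0],
                "event": [1, 0, 1, 0],
            },
            index=["early_event", "short_censor", "late_event", "long_censor"],
        )
        rl = relapse_labels(surv, horizon_months=60)
        assert rl.labels["early_event"] == 1
        assert rl.labels["short_censor"] == 0  # never relapsed, low follow-up
        assert "short_censor" in rl.low_followup
        assert "late_event" in rl.excluded
        assert "late_event" not in rl.labels.index
        assert rl.labels["long_censor"] == 0


class TestYouden:
    def test_perfect_separation(self):
        s = pd.Series([1.0, 2, 3, 10, 11, 12], index=list("abcdef"))
        rl = RelapseLabel(labels=pd.Series([0, 0, 0, 1, 1, 1], index=list("abcdef")), horizon=60)
        cutoff, auroc = youden_cutoff(ScoreVector(s, method="x"), rl)
        assert auroc == pytest.approx(1.0)
        assert 3 < cutoff < 10

    def test_matches_exhaustive_enumeration(self):
        s = pd.Series([0.1, 0.4, 0.35, 0.8, 0.7, 0.2, 0.9, 0.5], index=[f"s{i}" for i in range(8)])
        y = pd.Series([0, 0, 1, 1, 1, 0, 1, 0], index=s.index)
        rl = RelapseLabel(labels=y, horizon=60)
        cutoff, auroc = youden_cutoff(ScoreVector(s, method="x"), rl)
        best_j = -2.0
        for c in np.linspace(0, 1, 2001):
            sens = ((s >= c) & (y == 1)).sum() / (y == 1).sum()
            spec = ((s < c) & (y == 0)).sum() / (y == 0).sum()
            best_j = max(best_j, sens + spec - 1)
        got_sens = ((s >= cutoff) & (y == 1)).sum() / (y == 1).sum()
        got_spec = ((s < cutoff) & (y == 0)).sum() / (y == 0).sum()
        assert got_sens + got_spec - 1 == pytest.approx(best_j, abs=1e-12)
        # rank-statistic AUROC oracle
        pos, neg = s[y == 1].to_numpy(), s[y == 0].to_numpy()
        pairs = [(a > b) + 0.5 * (a == b) for a in pos for b in neg]
        assert auroc == pytest.approx(np.mean(pairs))

    def test_label_independent_scores_auroc_near_half(self):
        rng = np.random.default_rng(9)
        n = 2000
        s = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        y = pd.Series(rng.integers(0, 2, size=n), index=s.index)
        rl = RelapseLabel(labels=y, horizon=60)
        _, auroc = youden_cutoff(ScoreVector(s, method="x"), rl)
        assert abs(auroc - 0.5) <= 0.03

    def test_single_class_errors(self):
        s = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        rl = RelapseLabel(labels=pd.Series([1, 1, 1, 1], index=s.index), horizon=60)
        with pytest.raises(ValueError):
            youden_cutoff(ScoreVector(s, method="x"), rl)
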