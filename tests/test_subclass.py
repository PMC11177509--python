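import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pmnpipe import mcr as mcr_mod
from pmnpipe import scna, subclass
from pmnpipe.exceptions import ValidationError
from pmnpipe.io import ClinicalRecord, ExpressionMatrix
from pmnpipe.mcr import MCRResult
from pmnpipe.scna import GeneCall, PMNHitRecord, PMNHitTable
from pmnpipe.synthetic_data import SimConfig, simulate_cohort

from conftest import seg


def clin(sample, grade=2, pfi=100.0, pfi_event=True):
    return ClinicalRecord(
        sample, grade if grade != 4 else 2, grade == 4, grade, 200.0, False, pfi, pfi_event
    )


@pytest.fixture(scope="module")
def planted_mcr_result(cohort):
    samples = set(cohort.truth[cohort.truth.mcr_loss].sample_id)
    losses = mcr_mod.loss_segments_by_sample(cohort.segments, samples)
    return mcr_mod.find_mcr(losses, samples)


class TestAssignSubclass:
    def test_hit_takes_precedence(self):
        hits = PMNHitTable([PMNHitRecord("S1", True, (("MYC", "GAIN"),))])
        segs = [seg("S1", "chr19", 100, 200, -0.9)]
        m = MCRResult(intervals=[("chr19", 150, 180)], n_samples=1)
        t = subclass.assign_subclass(hits, segs, m)
        assert t.labels["S1"] == "PMN_HIT"

    def test_no_overlap_no_mcr_loss(self):
        hits = PMNHitTable([PMNHitRecord("S1", False, ())])
        segs = [seg("S1", "chr19", 100, 200, -0.9)]
        m = MCRResult(intervals=[("chr19", 500, 600)], n_samples=1)
        assert subclass.assign_subclass(hits, segs, m).labels["S1"] == "WT"

    def test_empty_mcr_rejected(self):
        hits = PMNHitTable([PMNHitRecord("S1", False, ())])
        with pytest.raises(ValidationError):
            subclass.assign_subclass(hits, [], MCRResult(intervals=[], n_samples=0))

    def test_partition_exhaustive_and_matches_truth(self, cohort, cohort_hits, planted_mcr_result):
        t = subclass.assign_subclass(cohort_hits, cohort.segments, planted_mcr_result)
        counts = t.counts()
        assert sum(counts.values()) == len(cohort.truth)
        truth = dict(zip(cohort.truth.sample_id, cohort.truth.subclass))
        assert all(t.labels[s] == truth[s] for s in t.labels)


class TestLinearModel:
    def test_recovers_planted_effect(self):
        inside = 0
        for s in range(25):
            # myc_effect_mcr = 0: MCR-loss samples sit in the non-hit group and
            # would otherwise bias the hit coefficient downward
            cfg = SimConfig(seed=300 + s, myc_effect_pmn=0.8, myc_effect_mcr=0.0, noise_sd=0.5)
            c = simulate_cohort(cfg)
            calls = scna.call_gene_scna(c.segments, c.annotation)
            hits = scna.pmn_hit_status(calls, c.variants)
            lm = subclass.myc_linear_model(c.expression, hits, c.clinical)
            inside += abs(lm.coef_pmn_hit - 0.8) <= 3 * lm.se
        assert inside >= 23  # >= 95%-ish of seeds

    def test_single_grade_reduces_to_t_test(self):
        rng = np.random.default_rng(5)
        samples = [f"S{i}" for i in range(30)]
        hit = np.array([i < 15 for i in range(30)])
        y = rng.normal(0, 1, 30) + 0.5 * hit
        expr = ExpressionMatrix(
            pd.DataFrame(y[None, :], index=pd.Index(["MYC"], name="gene"), columns=samples)
        )
        hits = PMNHitTable(
            [PMNHitRecord(s, bool(h), (("MYC", "GAIN"),) if h else ()) for s, h in zip(samples, hit)]
        )
        clinical = [clin(s, grade=2) for s in samples]
        lm = subclass.myc_linear_model(expr, hits, clinical)
        assert lm.coef_pmn_hit == pytest.approx(y[hit].mean() - y[~hit].mean(), abs=1e-10)
        t, p = stats.ttest_ind(y[hit], y[~hit])
        assert lm.p_value == pytest.approx(p, abs=1e-10)
        assert lm.grade_coefs == {}

    def test_collinear_design_rejected(self):
        # hit indicator identical to grade-3 indicator -> still full rank; force
        # singularity by making all samples hit
        samples = [f"S{i}" for i in range(10)]
        y = np.arange(10.0)
        expr = ExpressionMatrix(
            pd.DataFrame(y[None, :], index=pd.Index(["MYC"], name="gene"), columns=samples)
        )
        hits = PMNHitTable([PMNHitRecord(s, True, (("MYC", "GAIN"),)) for s in samples])
        clinical = [clin(s, grade=2) for s in samples]
        with pytest.raises(ValidationError, match="singular"):
            subclass.myc_linear_model(expr, hits, clinical)


class TestGradeTrend:
    def test_equal_proportions_give_zero(self):
        labels = [True, False] * 30
        grades = [2] * 20 + [3] * 20 + [4] * 20
        z, p = subclass.grade_trend_test(labels, grades)
        assert z == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_increasing_proportions_significant(self):
        rng = np.random.default_rng(0)
        grades = np.array([2] * 100 + [3] * 100 + [4] * 100)
        probs = {2: 0.2, 3: 0.4, 4: 0.6}
        labels = np.array([rng.random() < probs[g] for g in grades])
        z, p = subclass.grade_trend_test(labels, grades)
        assert p < 0.05 and z > 0

    def test_matches_correlation_identity_oracle(self):
        # CA statistic (ungrouped scores) equals sqrt(N) * pearson(label, score)
        rng = np.random.default_rng(1)
        for _ in range(200):
            grades = rng.choice([2, 3, 4], size=40)
            if len(set(grades.tolist())) < 2:
                continue
            labels = rng.random(40) < 0.4
            if labels.all() or not labels.any():
                continue
            z, _ = subclass.grade_trend_test(labels, grades)
            r = np.corrcoef(labels.astype(float), grades.astype(float))[0, 1]
            assert z == pytest.approx(np.sqrt(40) * r, abs=1e-10)

    def test_printed_toy_table(self):
        # grades 2/3/4 with n = (10, 10, 10), hits = (2, 5, 8); hand-computed below
        labels = [True] * 2 + [False] * 8 + [True] * 5 + [False] * 5 + [True] * 8 + [False] * 2
        grades = [2] * 10 + [3] * 10 + [4] * 10
        # pbar = 0.5; num = 2*2+3*5+4*8 - 0.5*(10*2+10*3+10*4) = 51 - 45 = 6
        # var = 0.25 * (10*4+10*9+10*16 - 90^2/30) = 0.25 * 20 = 5
        expected_z = 6 / np.sqrt(5)
        z, p = subclass.grade_trend_test(labels, grades)
        assert z == pytest.approx(expected_z, abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(expected_z), abs=1e-12)

    def test_single_grade_rejected(self):
        with pytest.raises(ValidationError):
            subclass.grade_trend_test([True, False], [2, 2])


def logrank_2group_oracle(times, events, groups):
    """Brute-force observed-minus-expected log-rank for 2 groups."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    gnames = sorted(set(groups.tolist()))
    O_E = 0.0
    V = 0.0
    for t in sorted(set(times[events].tolist())):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == gnames[0])).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (groups == gnames[0])).sum()
        O_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = O_E**2 / V
    return chi2, float(stats.chi2.sf(chi2, df=1))


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        times = [5, 10, 15, 5, 10, 15]
        events = [True, True, False, True, True, False]
        groups = ["A", "A", "A", "B", "B", "B"]
        chi2, p = subclass.logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(6, 14))
            times = rng.exponential(10, n).round(1)
            events = rng.random(n) < 0.8
            groups = rng.choice(["A", "B"], n)
            if not events.any() or len(set(groups.tolist())) < 2:
                continue
            # need at least one event and distinct event times handled by both
            chi2_o, p_o = logrank_2group_oracle(times, events, groups)
            chi2, p = subclass.logrank_test(times, events, groups)
            assert chi2 == pytest.approx(chi2_o, abs=1e-8)
            assert p == pytest.approx(p_o, abs=1e-8)

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            subclass.logrank_test([1, 2], [False, False], ["A", "B"])

    def test_planted_hazard_ratio_power(self):
        detected = 0
        for s in range(10):
            cfg = SimConfig(n_samples=200, seed=400 + s, pfi_hr_pmn=2.0)
            c = simulate_cohort(cfg)
            truth = dict(zip(c.truth.sample_id, c.truth.pmn_hit))
            times = [r.pfi_time for r in c.clinical]
            events = [r.pfi_event for r in c.clinical]
            groups = ["HIT" if truth[r.sample_id] else "REST" for r in c.clinical]
            _, p = subclass.logrank_test(times, events, groups)
            detected += p < 0.05
        assert detected >= 9


class TestFisher:
    def test_2x2_matches_scipy_hypergeometric(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(1, 12, size=(2, 2))
            p, method = subclass.fisher_exact_rxc(t)
            _, p_scipy = stats.fisher_exact(t)
            assert method == "exact"
            assert p == pytest.approx(p_scipy, rel=1e-9)

    def test_dominant_diagonal_small_p(self):
        p, _ = subclass.fisher_exact_rxc([[20, 0, 0], [0, 20, 0], [0, 0, 20]])
        assert p < 1e-6

    def test_empty_margin_rejected(self):
        with pytest.raises(ValidationError):
            subclass.fisher_exact_rxc([[0, 0], [1, 2]])

    def test_monte_carlo_fallback_close_to_exact(self):
        t = np.array([[8, 3, 2], [2, 7, 4], [1, 2, 9]])
        p_exact, m1 = subclass.fisher_exact_rxc(t)
        p_mc, m2 = subclass.fisher_exact_rxc(t, max_tables=10, mc_iterations=40_000, seed=1)
        assert m1 == "exact" and m2 == "monte_carlo"
        se = np.sqrt(p_exact * (1 - p_exact) / 40_000)
        assert abs(p_mc - p_exact) < 4 * se + 1e-4

    def test_independence_calibration(self):
        rng = np.random.default_rng(4)
        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            rows = rng.choice(3, size=60)
            cols = rng.choice(3, size=60)
            t = np.zeros((3, 3), dtype=int)
            np.add.at(t, (rows, cols), 1)
            if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
                continue
            p, _ = subclass.fisher_exact_rxc(t, max_tables=5_000, mc_iterations=2_000)
            rejections += p <= 0.05
        assert rejections / n_rep <= 0.08  # exact test is conservative

    def test_subclass_fisher_runs(self, cohort, cohort_hits, planted_mcr_result):
        t = subclass.assign_subclass(cohort_hits, cohort.segments, planted_mcr_result)
        p, method = subclass.subclass_fisher(t, cohort.clinical)
        assert 0 < p <= 1


def test_subclass_myc_ordering(cohort, cohort_hits, planted_mcr_result):
    t = subclass.assign_subclass(cohort_hits, cohort.segments, planted_mcr_result)
    myc = dict(zip(cohort.expression.samples, cohort.expression.gene_values("MYC")))
    means = {
        cls: np.mean([myc[s] for s in t.samples_in(cls)])
        for cls in ("PMN_HIT", "MCR_LOSS", "WT")
    }
    assert means["PMN_HIT"] > means["MCR_LOSS"] > means["WT"]
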