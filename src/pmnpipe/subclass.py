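"""3-way subclassification and the bulk-level association analyses.

Subclasses: PMN_HIT (any somatic PMN alteration), MCR_LOSS (PMN-WT with a
loss segment overlapping the MCR), WT (neither). Bulk tests: OLS of MYC
expression on hit status adjusting for categorical grade, Cochran-Armitage
trend of a binary label over ordered grades, k-group log-rank, and an
r x c Fisher exact test (full enumeration with Monte-Carlo fallback).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.special import gammaln

from pmnpipe.exceptions import ValidationError
from pmnpipe.intervals import overlap_len
from pmnpipe.io import ClinicalRecord, ExpressionMatrix, SegmentRecord
from pmnpipe.mcr import MCRResult
from pmnpipe.scna import PMNHitTable

__all__ = [
    "SubclassTable",
    "LinearModelResult",
    "assign_subclass",
    "myc_linear_model",
    "grade_trend_test",
    "logrank_test",
    "subclass_fisher",
    "fisher_exact_rxc",
    "write_subclass_table",
]

PMN_HIT = "PMN_HIT"
MCR_LOSS = "MCR_LOSS"
WT = "WT"


@dataclass
class SubclassTable:
    labels: dict[str, str]  # sample_id -> subclass

    def samples_in(self, subclass: str) -> set[str]:
        return {s for s, c in self.labels.items() if c == subclass}

    def counts(self) -> dict[str, int]:
        out = {PMN_HIT: 0, MCR_LOSS: 0, WT: 0}
        for c in self.labels.values():
            out[c] += 1
        return out


@dataclass
class LinearModelResult:
    coef_pmn_hit: float
    se: float
    p_value: float
    grade_coefs: dict[str, float]
    n: int


def assign_subclass(
    hits: PMNHitTable,
    segments: Sequence[SegmentRecord],
    mcr: MCRResult,
    loss_threshold: float = 0.3,
) -> SubclassTable:
    """Partition samples into PMN_HIT / MCR_LOSS / WT (hit takes precedence).

    MCR overlap means >= 1 bp of a loss segment (segment_mean < -threshold)
    intersects any MCR interval.
    """
    if not mcr.intervals:
        raise ValidationError("MCR is empty; cannot assign subclasses")
    loss_by_sample: dict[str, list[tuple[str, int, int]]] = {}
    for s in segments:
        if s.segment_mean < -loss_threshold:
            loss_by_sample.setdefault(s.sample_id, []).append((s.chrom, s.start, s.end))

    labels: dict[str, str] = {}
    for rec in hits.records:
        if rec.pmn_hit:
            labels[rec.sample_id] = PMN_HIT
            continue
        losses = loss_by_sample.get(rec.sample_id, [])
        overlaps = any(
            c == mc and overlap_len(a, b, ms, me) > 0
            for c, a, b in losses
            for mc, ms, me in mcr.intervals
        )
        labels[rec.sample_id] = MCR_LOSS if overlaps else WT
    return SubclassTable(labels)


def myc_linear_model(
    expr: ExpressionMatrix,
    hits: PMNHitTable,
    clinical: Sequence[ClinicalRecord],
    target_gene: str = "MYC",
) -> LinearModelResult:
    """OLS of MYC log-expression on PMN-hit status adjusting for grade.

    Grade enters as a categorical factor (molecular grade 2 = reference);
    grade levels present in fewer than 1 sample are simply absent. Classical
    (non-robust) standard errors; two-sided t-test on the hit coefficient.
    """
    clin = {c.sample_id: c for c in clinical}
    samples = [r.sample_id for r in hits.records if r.sample_id in clin]
    if len(samples) < 3:
        raise ValidationError("need >= 3 samples with clinical data")
    y = expr.gene_values(target_gene, samples)
    hit = np.array([1.0 if hits.is_hit(s) else 0.0 for s in samples])
    grades = np.array([clin[s].molecular_grade for s in samples])

    X = pd.DataFrame({"pmn_hit": hit}, index=samples)
    levels = sorted(set(grades.tolist()))
    for g in levels[1:]:  # lowest grade present is the reference
        X[f"grade_{g}"] = (grades == g).astype(float)
    X = sm.add_constant(X, prepend=True, has_constant="add")

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValidationError(
            f"singular design matrix (rank {rank} < {X.shape[1]}); columns: {list(X.columns)}"
        )
    if len(samples) < X.shape[1] + 1:
        raise ValidationError("fewer samples than parameters + 1")

    fit = sm.OLS(y, X).fit()
    grade_coefs = {c: float(fit.params[c]) for c in X.columns if c.startswith("grade_")}
    return LinearModelResult(
        coef_pmn_hit=float(fit.params["pmn_hit"]),
        se=float(fit.bse["pmn_hit"]),
        p_value=float(fit.pvalues["pmn_hit"]),
        grade_coefs=grade_coefs,
        n=len(samples),
    )


def grade_trend_test(
    labels: Sequence[bool],
    grades: Sequence[int],
    scores: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Cochran-Armitage trend test of a binary label over ordered grades.

    Returns (Z statistic, two-sided normal p). Scores default to the grade
    values themselves.
    """
    labels = np.asarray(labels, dtype=bool)
    grades = np.asarray(grades)
    if labels.shape != grades.shape:
        raise ValidationError("labels and grades must align")
    levels = sorted(set(grades.tolist()))
    if len(levels) < 2:
        raise ValidationError("trend test needs >= 2 grade levels present")
    s = np.asarray(scores if scores is not None else levels, dtype=float)
    if len(s) != len(levels):
        raise ValidationError("scores must match the number of grade levels")

    n_i = np.array([(grades == g).sum() for g in levels], dtype=float)
    x_i = np.array([(labels & (grades == g)).sum() for g in levels], dtype=float)
    N = n_i.sum()
    pbar = x_i.sum() / N
    num = float((s * (x_i - n_i * pbar)).sum())
    var = pbar * (1 - pbar) * float((n_i * s**2).sum() - (n_i * s).sum() ** 2 / N)
    if var <= 0:
        return 0.0, 1.0
    z = num / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def logrank_test(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence[str],
) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square, p) with k-1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if len(set(groups.tolist())) < 2:
        raise ValidationError("log-rank needs >= 2 groups")
    if not events.any():
        raise ValidationError("log-rank needs >= 1 event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# r x c Fisher exact test
# ---------------------------------------------------------------------------


def _log_table_prob(table: np.ndarray, row_sums: np.ndarray, col_sums: np.ndarray, n: int) -> float:
    return float(
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_sums: list[int], col_sums: list[int], max_tables: int):
    """Yield every non-negative integer table with the given margins.

    Cells are filled row-major; the last row and last column are forced by
    the margins. Raises OverflowError after ``max_tables`` tables (the
    caller then falls back to Monte Carlo).
    """
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=int)
    count = 0

    def fill(i: int, j: int, row_left: int, col_left: list[int]):
        nonlocal count
        if i == r - 1:
            # last row is determined by the column margins
            if all(0 <= col_left[k] for k in range(c)):
                table[i, :] = col_left
                count += 1
                if count > max_tables:
                    raise OverflowError
                yield table
            return
        if j == c - 1:
            # last cell of a row is determined by the row margin
            if 0 <= row_left <= col_left[j]:
                table[i, j] = row_left
                col_left[j] -= row_left
                yield from fill(i + 1, 0, row_sums[i + 1], col_left)
                col_left[j] += row_left
            return
        for v in range(min(row_left, col_left[j]) + 1):
            table[i, j] = v
            col_left[j] -= v
            yield from fill(i, j + 1, row_left - v, col_left)
            col_left[j] += v

    yield from fill(0, 0, row_sums[0], list(col_sums))


def fisher_exact_rxc(
    table: np.ndarray | Sequence[Sequence[int]],
    max_tables: int = 2_000_000,
    mc_iterations: int = 100_000,
    seed: int = 0,
) -> tuple[float, str]:
    """Fisher exact test for an r x c contingency table.

    Exact enumeration over all tables with the observed margins when that
    space has at most ``max_tables`` members; otherwise a Monte-Carlo
    estimate from the margin-fixed multivariate hypergeometric null.
    Returns (p, method) with method in {"exact", "monte_carlo"}.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or (t < 0).any():
        raise ValidationError("contingency table must be a non-negative 2-D array")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise ValidationError("contingency table has an empty margin")
    n = int(t.sum())
    logp_obs = _log_table_prob(t, row_sums, col_sums, n)
    eps = 1e-7

    try:
        total = 0.0
        for cand in _enumerate_tables(row_sums.tolist(), col_sums.tolist(), max_tables):
            lp = _log_table_prob(cand, row_sums, col_sums, n)
            if lp <= logp_obs + eps:
                total += np.exp(lp)
        return float(min(total, 1.0)), "exact"
    except OverflowError:
        pass

    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(t.shape[0]), row_sums)
    col_labels = np.repeat(np.arange(t.shape[1]), col_sums)
    hits = 0
    for _ in range(mc_iterations):
        perm = rng.permutation(col_labels)
        sim = np.zeros_like(t)
        np.add.at(sim, (row_labels, perm), 1)
        if _log_table_prob(sim, row_sums, col_sums, n) <= logp_obs + eps:
            hits += 1
    p = (1 + hits) / (mc_iterations + 1)
    return float(p), "monte_carlo"


def subclass_fisher(
    subclasses: SubclassTable,
    clinical: Sequence[ClinicalRecord],
) -> tuple[float, str]:
    """Fisher exact association between subclass and molecular grade."""
    clin = {c.sample_id: c for c in clinical}
    classes = [PMN_HIT, MCR_LOSS, WT]
    grades = sorted({c.molecular_grade for c in clinical})
    table = np.zeros((len(classes), len(grades)), dtype=int)
    for sample, label in subclasses.labels.items():
        if sample not in clin:
            continue
        i = classes.index(label)
        j = grades.index(clin[sample].molecular_grade)
        table[i, j] += 1
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    return fisher_exact_rxc(table)


def write_subclass_table(table: SubclassTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsubclass\n")
        for s, c in table.labels.items():
            fh.write(f"{s}\t{c}\n")
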