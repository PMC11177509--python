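"""Two-filter MYC-regulator screen over PMN-WT samples.

Filter (a): genes whose expression correlates with MYC expression
(|r| > r_min and Pearson p < alpha, two-sided, t-transform with n-2 df).
Filter (b): genes somatically altered in 10-90% of samples whose alteration
is associated with *higher* MYC expression (one-tailed Wilcoxon rank-sum).
Candidates pass both. Commonly mutated astrocytoma genes and the PMN genes
themselves are excluded from both filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from pmnpipe.exceptions import ValidationError
from pmnpipe.io import ExpressionMatrix, VariantRecord
from pmnpipe.scna import NEUTRAL, NON_SILENT_CLASSES, PMN_GENES, GeneCall, PMNHitTable

__all__ = [
    "ScreenResult",
    "DEFAULT_EXCLUDE",
    "select_pmn_wt",
    "correlation_filter",
    "alteration_filter",
    "altered_samples_by_gene",
    "candidate_support_samples",
    "combine_screen",
    "wilcoxon_rank_sum_greater",
    "write_screen_results",
]

logger = logging.getLogger(__name__)

#: Genes excluded from both filters: commonly mutated astrocytoma genes + PMN.
DEFAULT_EXCLUDE = frozenset(
    {"IDH1", "IDH2", "TP53", "ATRX", "CDKN2A", "CDKN2B"} | PMN_GENES.all_genes
)


@dataclass
class CorrelationRecord:
    gene: str
    pearson_r: float
    pearson_p: float
    passes_a: bool


@dataclass
class AlterationRecord:
    gene: str
    wilcoxon_p: float
    n_altered: int
    altered_fraction: float
    passes_b: bool


@dataclass
class ScreenResult:
    gene: str
    pearson_r: float
    pearson_p: float
    wilcoxon_p: float
    n_altered: int
    altered_fraction: float
    passes_a: bool
    passes_b: bool
    candidate: bool


def select_pmn_wt(hits: PMNHitTable) -> set[str]:
    """Samples without any somatic PMN alteration."""
    if not hits.records:
        raise ValidationError("empty PMN hit table")
    return hits.wt_samples()


def correlation_filter(
    expr: ExpressionMatrix,
    samples: set[str],
    target_gene: str = "MYC",
    r_min: float = 0.2,
    alpha: float = 0.05,
    exclude: frozenset[str] | set[str] = DEFAULT_EXCLUDE,
) -> dict[str, CorrelationRecord]:
    """Pearson correlation of each gene's expression with the target gene.

    Vectorized over genes; p-values from the t transform
    ``t = r * sqrt((n-2) / (1-r^2))`` with n-2 degrees of freedom
    (two-sided). Zero-variance genes are flagged and fail filter (a).
    """
    sample_list = sorted(samples)
    if len(sample_list) < 3:
        raise ValidationError(f"need >= 3 samples for correlation, got {len(sample_list)}")
    if target_gene not in expr.genes:
        raise ValidationError(f"target gene {target_gene!r} not in expression matrix")
    sub = expr.subset_samples(sample_list)
    y = sub.gene_values(target_gene)
    n = len(sample_list)
    if np.std(y) == 0:
        raise ValidationError(f"target gene {target_gene!r} has zero variance")

    mat = sub.values  # genes x samples
    genes = sub.genes
    yc = y - y.mean()
    xc = mat - mat.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), np.nan, np.where(np.isinf(t), 0.0, p))

    out: dict[str, CorrelationRecord] = {}
    for i, g in enumerate(genes):
        if g == target_gene or g in exclude:
            continue
        if sx[i] == 0:
            logger.warning("gene %s has zero variance across screened samples; excluded", g)
            out[g] = CorrelationRecord(g, float("nan"), float("nan"), False)
            continue
        ri, pi = float(r[i]), float(p[i])
        out[g] = CorrelationRecord(g, ri, pi, abs(ri) > r_min and pi < alpha)
    return out


def wilcoxon_rank_sum_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-tailed Wilcoxon rank-sum p for H1: x stochastically greater than y.

    Exact enumeration when min group size <= 10 and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue)


def altered_samples_by_gene(
    calls: Sequence[GeneCall],
    variants: Sequence[VariantRecord],
    samples: set[str],
) -> dict[str, set[str]]:
    """Per-gene sets of samples altered by SCNA or non-silent mutation."""
    altered: dict[str, set[str]] = {}
    for c in calls:
        if c.sample_id in samples and c.state != NEUTRAL:
            altered.setdefault(c.gene, set()).add(c.sample_id)
    for v in variants:
        if v.sample_id in samples and v.variant_class in NON_SILENT_CLASSES:
            altered.setdefault(v.gene, set()).add(v.sample_id)
    return altered


def candidate_support_samples(
    altered: dict[str, set[str]],
    candidate_genes: Sequence[str],
    min_fraction: float = 0.5,
) -> set[str]:
    """Samples altered in at least ``min_fraction`` of the candidate genes.

    Used to pick the recurrently co-deleted sample set whose loss segments
    are intersected for the MCR; a stray candidate altered in unrelated
    samples cannot empty the intersection.
    """
    if not candidate_genes:
        raise ValidationError("no candidate genes")
    counts: dict[str, int] = {}
    for g in candidate_genes:
        for s in altered.get(g, set()):
            counts[s] = counts.get(s, 0) + 1
    need = min_fraction * len(candidate_genes)
    return {s for s, k in counts.items() if k >= need}


def alteration_filter(
    calls: Sequence[GeneCall],
    variants: Sequence[VariantRecord],
    expr: ExpressionMatrix,
    samples: set[str],
    freq_range: tuple[float, float] = (0.1, 0.9),
    alpha: float = 0.05,
    exclude: frozenset[str] | set[str] = DEFAULT_EXCLUDE,
    target_gene: str = "MYC",
) -> dict[str, AlterationRecord]:
    """One-tailed Wilcoxon: is a gene's alteration associated with higher MYC?

    A sample is "altered" for gene g iff g has a non-NEUTRAL call or a
    non-silent variant in that sample. Only genes altered in
    ``freq_range[0] <= fraction <= freq_range[1]`` of the screened samples
    are tested; others carry ``wilcoxon_p = nan`` and fail.
    """
    sample_list = sorted(samples)
    if len(sample_list) < 3:
        raise ValidationError(f"need >= 3 samples, got {len(sample_list)}")
    myc = dict(zip(sample_list, expr.gene_values(target_gene, sample_list)))

    altered = altered_samples_by_gene(calls, variants, samples)

    gene_universe = sorted({c.gene for c in calls})
    n = len(sample_list)
    lo, hi = freq_range
    out: dict[str, AlterationRecord] = {}
    for g in gene_universe:
        if g in exclude or g == target_gene:
            continue
        alt = altered.get(g, set())
        frac = len(alt) / n
        if not (lo <= frac <= hi):
            out[g] = AlterationRecord(g, float("nan"), len(alt), frac, False)
            continue
        x = np.array([myc[s] for s in sample_list if s in alt])
        y = np.array([myc[s] for s in sample_list if s not in alt])
        p = wilcoxon_rank_sum_greater(x, y)
        out[g] = AlterationRecord(g, p, len(alt), frac, p < alpha)
    return out


def combine_screen(
    a_results: dict[str, CorrelationRecord],
    b_results: dict[str, AlterationRecord],
) -> list[ScreenResult]:
    """Genes passing both filters, sorted by Wilcoxon p, then |r| desc, then symbol."""
    candidates: list[ScreenResult] = []
    for g, a in a_results.items():
        b = b_results.get(g)
        if b is None or not (a.passes_a and b.passes_b):
            continue
        candidates.append(
            ScreenResult(
                gene=g,
                pearson_r=a.pearson_r,
                pearson_p=a.pearson_p,
                wilcoxon_p=b.wilcoxon_p,
                n_altered=b.n_altered,
                altered_fraction=b.altered_fraction,
                passes_a=True,
                passes_b=True,
                candidate=True,
            )
        )
    candidates.sort(key=lambda s: (s.wilcoxon_p, -abs(s.pearson_r), s.gene))
    return candidates


def write_screen_results(results: Iterable[ScreenResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\tpearson_r\tpearson_p\twilcoxon_p\tn_altered\taltered_fraction\t"
            "passes_a\tpasses_b\tcandidate\n"
        )
        for s in results:
            fh.write(
                f"{s.gene}\t{s.pearson_r:.6g}\t{s.pearson_p:.6g}\t{s.wilcoxon_p:.6g}\t"
                f"{s.n_altered}\t{s.altered_fraction:.6g}\t{s.passes_a}\t{s.passes_b}\t"
                f"{s.candidate}\n"
            )
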