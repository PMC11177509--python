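"""Stratified Monte-Carlo permutation test for SCNA enrichment in a gene set.

Each iteration re-draws (without replacement) a random sample subset of the
same size as the altered group and a random gene set of the same size as the
target set, then counts SCNA events in the induced submatrix. The empirical
p-value uses the add-one estimator ``(1 + #{null >= observed}) / (B + 1)``,
which can never be exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from pmnpipe.exceptions import ValidationError
from pmnpipe.scna import GeneCall, NEUTRAL

__all__ = [
    "PermutationResult",
    "count_scna_events",
    "stratified_permutation_test",
    "alteration_matrix",
]


@dataclass
class PermutationResult:
    observed_count: int
    null_counts: np.ndarray
    b_iterations: int
    p_value: float
    seed: int
    n_altered_samples: int
    n_target_genes: int

    def __post_init__(self) -> None:
        self.null_counts = np.asarray(self.null_counts, dtype=int)
        if len(self.null_counts) != self.b_iterations:
            raise ValidationError("null distribution length != b_iterations")
        if not (0 < self.p_value <= 1):
            raise ValidationError(f"p_value {self.p_value} outside (0, 1]")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "observed_count": int(self.observed_count),
                    "b_iterations": int(self.b_iterations),
                    "p_value": self.p_value,
                    "seed": int(self.seed),
                    "n_altered_samples": int(self.n_altered_samples),
                    "n_target_genes": int(self.n_target_genes),
                    "null_mean": float(self.null_counts.mean()),
                    "null_sd": float(self.null_counts.std(ddof=1)) if self.b_iterations > 1 else 0.0,
                },
                fh,
                indent=2,
            )


def alteration_matrix(calls: Sequence[GeneCall]) -> pd.DataFrame:
    """Samples x genes boolean matrix: True where the call is non-NEUTRAL."""
    samples, genes, altered = [], [], []
    for c in calls:
        samples.append(c.sample_id)
        genes.append(c.gene)
        altered.append(c.state != NEUTRAL)
    df = pd.DataFrame({"sample": samples, "gene": genes, "altered": altered})
    mat = df.pivot_table(index="sample", columns="gene", values="altered", aggfunc="any")
    return mat.fillna(False).astype(bool)


def count_scna_events(
    calls: Sequence[GeneCall], samples: set[str], genes: set[str]
) -> int:
    """Number of (sample, gene) pairs in samples x genes with a non-NEUTRAL call."""
    if not samples or not genes:
        raise ValidationError("samples and genes must be non-empty")
    call_samples = {c.sample_id for c in calls}
    call_genes = {c.gene for c in calls}
    if not samples <= call_samples:
        raise ValidationError(f"samples outside call universe: {sorted(samples - call_samples)}")
    if not genes <= call_genes:
        raise ValidationError(f"genes outside call universe: {sorted(genes - call_genes)}")
    return sum(
        1
        for c in calls
        if c.state != NEUTRAL and c.sample_id in samples and c.gene in genes
    )


def stratified_permutation_test(
    calls: Sequence[GeneCall],
    target_genes: set[str],
    n_altered_samples: int | None = None,
    B: int = 10_000,
    seed: int = 0,
    sample_subset: set[str] | None = None,
) -> PermutationResult:
    """Permutation null for the SCNA count observed in ``target_genes``.

    By default the observed statistic is counted over the samples carrying at
    least one SCNA in a target gene; if ``n_altered_samples`` is given it
    must equal that group's size (a consistency check on the caller's
    bookkeeping). Note this default conditions the observed group on having
    events, which makes the statistic stochastically larger than the null
    draws even for a random target set; pass an externally chosen
    ``sample_subset`` to count the observed statistic over a fixed sample set
    instead (the exchangeable mode used for calibration experiments).

    Raises
    ------
    ValidationError
        If the target set is empty or exceeds the gene universe, B < 1, or
        ``n_altered_samples`` disagrees with the altered-sample count.
    """
    if B < 1:
        raise ValidationError(f"B must be >= 1, got {B}")
    mat = alteration_matrix(calls)
    universe_genes = list(mat.columns)
    universe_samples = list(mat.index)
    if not target_genes:
        raise ValidationError("target gene set is empty")
    missing = sorted(set(target_genes) - set(universe_genes))
    if missing:
        raise ValidationError(f"target genes not in universe: {missing}")
    if len(target_genes) > len(universe_genes):
        raise ValidationError("target gene set larger than gene universe")

    target_idx = [universe_genes.index(g) for g in sorted(target_genes)]
    arr = mat.to_numpy()
    if sample_subset is not None:
        missing_s = sorted(sample_subset - set(universe_samples))
        if missing_s:
            raise ValidationError(f"samples not in universe: {missing_s}")
        subset_mask = np.array([s in sample_subset for s in universe_samples])
        if n_altered_samples is None:
            n_altered_samples = len(sample_subset)
        elif n_altered_samples != len(sample_subset):
            raise ValidationError("n_altered_samples disagrees with sample_subset size")
    else:
        subset_mask = arr[:, target_idx].any(axis=1)
        n_selected = int(subset_mask.sum())
        if n_altered_samples is None:
            n_altered_samples = n_selected
        elif n_altered_samples != n_selected:
            raise ValidationError(
                f"n_altered_samples={n_altered_samples} but {n_selected} samples "
                "carry an SCNA in the target genes"
            )
    if n_altered_samples == 0:
        raise ValidationError("no sample carries an SCNA in the target genes")
    if n_altered_samples > len(universe_samples):
        raise ValidationError("n_altered_samples exceeds sample universe")

    observed = int(arr[np.ix_(subset_mask.nonzero()[0], target_idx)].sum())

    rng = np.random.default_rng(seed)
    n_s, n_g = arr.shape
    k_g = len(target_idx)
    null_counts = np.empty(B, dtype=int)
    for b in range(B):
        si = rng.choice(n_s, size=n_altered_samples, replace=False)
        gi = rng.choice(n_g, size=k_g, replace=False)
        null_counts[b] = arr[np.ix_(si, gi)].sum()

    p = (1 + int((null_counts >= observed).sum())) / (B + 1)
    return PermutationResult(
        observed_count=observed,
        null_counts=null_counts,
        b_iterations=B,
        p_value=p,
        seed=seed,
        n_altered_samples=n_altered_samples,
        n_target_genes=k_g,
    )
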