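"""Per-sample genomic-instability metrics and group comparisons.

Metrics (all thresholds configurable):

- ``snv_burden`` / ``indel_burden`` — variant record counts.
- ``wgii`` — mean over autosomes of the fraction of chromosome length whose
  segments have |segment_mean| above the SCNA threshold.
- ``caer`` — fraction of chromosome arms carrying an arm-level event, i.e.
  at least ``arm_event_fraction`` of the arm altered in a single direction.
- ``cn_amplitude`` — max |segment_mean| over the sample's segments.
- ``chromothripsis`` — any chromosome whose sorted segments change state
  (GAIN/LOSS/NEUTRAL) at least ``oscillation_min`` times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from pmnpipe.exceptions import ValidationError
from pmnpipe.genome import GenomeConfig
from pmnpipe.intervals import merge_intervals, overlap_len
from pmnpipe.io import SegmentRecord, VariantRecord
from pmnpipe.scna import state_from_mean

__all__ = [
    "InstabilityMetrics",
    "compute_metrics",
    "compare_groups",
    "write_metrics",
]

METRIC_NAMES = ("snv_burden", "indel_burden", "wgii", "caer", "cn_amplitude")


@dataclass
class InstabilityMetrics:
    sample_id: str
    snv_burden: int
    indel_burden: int
    wgii: float
    caer: float
    cn_amplitude: float
    chromothripsis: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.wgii <= 1.0):
            raise ValidationError(f"wgii {self.wgii} outside [0,1]")
        if not (0.0 <= self.caer <= 1.0):
            raise ValidationError(f"caer {self.caer} outside [0,1]")
        if self.snv_burden < 0 or self.indel_burden < 0 or self.cn_amplitude < 0:
            raise ValidationError("negative burden or amplitude")


def compute_metrics(
    segments: Sequence[SegmentRecord],
    variants: Sequence[VariantRecord],
    genome: GenomeConfig,
    sample_id: str,
    scna_threshold: float = 0.3,
    arm_event_fraction: float = 0.5,
    oscillation_min: int = 10,
) -> InstabilityMetrics:
    """All instability metrics for one sample.

    Raises
    ------
    ValidationError
        If a segment chromosome is missing from the genome config.
    """
    segs = [s for s in segments if s.sample_id == sample_id]
    vars_ = [v for v in variants if v.sample_id == sample_id]
    for s in segs:
        if s.chrom not in genome.lengths:
            raise ValidationError(f"no length configured for chromosome {s.chrom}")

    snv_burden = sum(1 for v in vars_ if v.variant_type == "SNV")
    indel_burden = sum(1 for v in vars_ if v.variant_type in ("INS", "DEL"))

    # wGII: mean over autosomes of altered-bp fraction
    fractions = []
    for chrom in genome.autosomes:
        length = genome.lengths[chrom]
        altered = merge_intervals(
            [
                (s.start, min(s.end, length))
                for s in segs
                if s.chrom == chrom and abs(s.segment_mean) > scna_threshold
            ]
        )
        fractions.append(sum(e - st + 1 for st, e in altered) / length)
    wgii = float(np.mean(fractions)) if fractions else 0.0

    # CAER: fraction of arms with a single-direction arm-level event
    arms = genome.arms()
    arm_events = 0
    for chrom, arm, a_start, a_end in arms:
        arm_len = a_end - a_start + 1
        for direction in (1, -1):
            ivs = merge_intervals(
                [
                    (max(s.start, a_start), min(s.end, a_end))
                    for s in segs
                    if s.chrom == chrom
                    and direction * s.segment_mean > scna_threshold
                    and overlap_len(s.start, s.end, a_start, a_end) > 0
                ]
            )
            if sum(e - st + 1 for st, e in ivs) >= arm_event_fraction * arm_len:
                arm_events += 1
                break
    caer = arm_events / len(arms) if arms else 0.0

    cn_amplitude = max((abs(s.segment_mean) for s in segs), default=0.0)

    chromothripsis = False
    for chrom in genome.chromosomes:
        chrom_segs = sorted((s for s in segs if s.chrom == chrom), key=lambda s: s.start)
        states = [state_from_mean(s.segment_mean, scna_threshold) for s in chrom_segs]
        changes = sum(1 for a, b in zip(states, states[1:]) if a != b)
        if changes >= oscillation_min:
            chromothripsis = True
            break

    return InstabilityMetrics(
        sample_id=sample_id,
        snv_burden=snv_burden,
        indel_burden=indel_burden,
        wgii=wgii,
        caer=caer,
        cn_amplitude=cn_amplitude,
        chromothripsis=chromothripsis,
    )


@dataclass
class GroupComparison:
    metric: str
    test: str
    statistic: float
    p_value: float
    direction: str  # group with the larger median / higher rate, "" if tied


def compare_groups(
    metrics: Sequence[InstabilityMetrics],
    groups: dict[str, str],
) -> list[GroupComparison]:
    """Rank-based tests of each metric across groups.

    Two groups: two-sided Wilcoxon rank-sum. Three or more: Kruskal-Wallis.
    The chromothripsis flag is compared by Fisher's exact test (2 groups) or
    an r x 2 exact test (more groups).
    """
    by_group: dict[str, list[InstabilityMetrics]] = {}
    for m in metrics:
        if m.sample_id in groups:
            by_group.setdefault(groups[m.sample_id], []).append(m)
    names = sorted(by_group)
    if len(names) < 2 or any(len(by_group[g]) < 2 for g in names):
        raise ValidationError("need >= 2 groups with >= 2 samples each")

    out: list[GroupComparison] = []
    for metric in METRIC_NAMES:
        vecs = [np.array([getattr(m, metric) for m in by_group[g]], dtype=float) for g in names]
        medians = [float(np.median(v)) for v in vecs]
        direction = names[int(np.argmax(medians))] if len(set(medians)) > 1 else ""
        if len(names) == 2:
            res = stats.mannwhitneyu(vecs[0], vecs[1], alternative="two-sided")
            out.append(
                GroupComparison(metric, "wilcoxon_rank_sum", float(res.statistic), float(res.pvalue), direction)
            )
        else:
            res = stats.kruskal(*vecs)
            out.append(
                GroupComparison(metric, "kruskal_wallis", float(res.statistic), float(res.pvalue), direction)
            )

    # chromothripsis: contingency of flag by group
    table = np.array(
        [
            [sum(1 for m in by_group[g] if m.chromothripsis), sum(1 for m in by_group[g] if not m.chromothripsis)]
            for g in names
        ]
    )
    rates = table[:, 0] / table.sum(axis=1)
    direction = names[int(np.argmax(rates))] if len(set(rates.tolist())) > 1 else ""
    if len(names) == 2:
        _, p = stats.fisher_exact(table)
        out.append(GroupComparison("chromothripsis", "fisher_exact", float("nan"), float(p), direction))
    else:
        from pmnpipe.subclass import fisher_exact_rxc

        p, _ = fisher_exact_rxc(table)
        out.append(GroupComparison("chromothripsis", "fisher_exact_rxc", float("nan"), float(p), direction))
    return out


def write_metrics(metrics: Iterable[InstabilityMetrics], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsnv_burden\tindel_burden\twgii\tcaer\tcn_amplitude\tchromothripsis\n")
        for m in metrics:
            fh.write(
                f"{m.sample_id}\t{m.snv_burden}\t{m.indel_burden}\t{m.wgii:.6g}\t"
                f"{m.caer:.6g}\t{m.cn_amplitude:.6g}\t{m.chromothripsis}\n"
            )
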