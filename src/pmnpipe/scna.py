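"""Gene-level SCNA calling from copy-number segments and PMN-hit status.

A gene's copy-number summary is the overlap-length-weighted mean of the
segment means of all segments overlapping its footprint (``weighted_mean``),
or the most extreme overlapping segment mean (``extreme``). States use a
symmetric threshold with strict inequalities: GAIN above ``+threshold``,
LOSS below ``-threshold``, otherwise NEUTRAL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pmnpipe.exceptions import ValidationError
from pmnpipe.intervals import overlap_len
from pmnpipe.io import GeneAnnotation, SegmentRecord, VariantRecord

__all__ = [
    "GeneCall",
    "PMNGeneSet",
    "PMNHitTable",
    "PMN_GENES",
    "NON_SILENT_CLASSES",
    "state_from_mean",
    "call_gene_scna",
    "pmn_hit_status",
    "write_gene_calls",
    "read_gene_calls",
    "write_hit_table",
    "read_hit_table",
]

logger = logging.getLogger(__name__)

GAIN = "GAIN"
LOSS = "LOSS"
NEUTRAL = "NEUTRAL"

#: Variant classifications counted as somatic hits (configurable per call).
NON_SILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


@dataclass(frozen=True)
class PMNGeneSet:
    """The fixed 14-gene proximal MYC network, partitioned by role."""

    activators: frozenset[str] = frozenset({"MYC", "MYCN", "MYCL", "MLXIPL", "MLXIP"})
    inhibitors: frozenset[str] = frozenset(
        {"FBXW7", "MGA", "MNT", "MXD4", "MXD3", "MXI1", "MXD1"}
    )
    dimerizers: frozenset[str] = frozenset({"MAX", "MLX"})

    def __post_init__(self) -> None:
        if (
            self.activators & self.inhibitors
            or self.activators & self.dimerizers
            or self.inhibitors & self.dimerizers
        ):
            raise ValidationError("PMN gene roles must be disjoint")

    @property
    def all_genes(self) -> frozenset[str]:
        return self.activators | self.inhibitors | self.dimerizers


PMN_GENES = PMNGeneSet()


@dataclass(frozen=True)
class GeneCall:
    """Per-sample, per-gene SCNA state with its copy-number summary."""

    sample_id: str
    gene: str
    state: str
    gene_segment_mean: float


@dataclass(frozen=True)
class PMNHitRecord:
    sample_id: str
    pmn_hit: bool
    hit_genes: tuple[tuple[str, str], ...]  # (gene, GAIN/LOSS/MUTATION)


@dataclass
class PMNHitTable:
    records: list[PMNHitRecord] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def hit_samples(self) -> set[str]:
        return {r.sample_id for r in self.records if r.pmn_hit}

    def wt_samples(self) -> set[str]:
        return {r.sample_id for r in self.records if not r.pmn_hit}

    def is_hit(self, sample_id: str) -> bool:
        for r in self.records:
            if r.sample_id == sample_id:
                return r.pmn_hit
        raise ValidationError(f"sample {sample_id!r} not in hit table")


def state_from_mean(mean: float, threshold: float = 0.3) -> str:
    if mean > threshold:
        return GAIN
    if mean < -threshold:
        return LOSS
    return NEUTRAL


def _check_non_overlapping(segments: Sequence[SegmentRecord]) -> None:
    by_key: dict[tuple[str, str], list[SegmentRecord]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping segments for sample {sample} on {chrom}: "
                    f"({a.start},{a.end}) and ({b.start},{b.end})"
                )


def call_gene_scna(
    segments: Sequence[SegmentRecord],
    annotation: Sequence[GeneAnnotation],
    threshold: float = 0.3,
    gene_summary: str = "weighted_mean",
) -> list[GeneCall]:
    """Per-sample, per-gene SCNA calls from segments.

    Every (sample, gene) pair gets a call: genes with at least one
    overlapping segment are summarized per ``gene_summary``; uncovered genes
    are NEUTRAL with summary 0.

    Raises
    ------
    ValidationError
        If segments overlap within one sample/chromosome, or the threshold
        is not positive, or ``gene_summary`` is unknown.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    if gene_summary not in ("weighted_mean", "extreme"):
        raise ValidationError(f"unknown gene_summary {gene_summary!r}")
    _check_non_overlapping(segments)

    segs_by_sample_chrom: dict[tuple[str, str], list[SegmentRecord]] = {}
    samples: list[str] = []
    seen: set[str] = set()
    for seg in segments:
        segs_by_sample_chrom.setdefault((seg.sample_id, seg.chrom), []).append(seg)
        if seg.sample_id not in seen:
            seen.add(seg.sample_id)
            samples.append(seg.sample_id)
    for segs in segs_by_sample_chrom.values():
        segs.sort(key=lambda s: s.start)

    calls: list[GeneCall] = []
    for sample in samples:
        for gene in annotation:
            segs = segs_by_sample_chrom.get((sample, gene.chrom), [])
            weights: list[int] = []
            means: list[float] = []
            for seg in segs:
                if seg.start > gene.end:
                    break
                ov = overlap_len(seg.start, seg.end, gene.start, gene.end)
                if ov > 0:
                    weights.append(ov)
                    means.append(seg.segment_mean)
            if not weights:
                summary = 0.0
                state = NEUTRAL
            else:
                if len(means) == 1:
                    summary = means[0]
                elif gene_summary == "weighted_mean":
                    summary = sum(w * m for w, m in zip(weights, means)) / sum(weights)
                else:
                    summary = max(means, key=abs)
                state = state_from_mean(summary, threshold)
            calls.append(GeneCall(sample, gene.gene, state, summary))
    return calls


def pmn_hit_status(
    calls: Sequence[GeneCall],
    variants: Sequence[VariantRecord],
    pmn: PMNGeneSet = PMN_GENES,
    non_silent_classes: frozenset[str] = NON_SILENT_CLASSES,
) -> PMNHitTable:
    """Per-sample PMN-hit status: any SCNA or non-silent mutation in a PMN gene.

    Variants in genes absent from the call universe are skipped with a
    logged warning. ``hit_genes`` lists every contributing (gene, kind).
    """
    known_genes = {c.gene for c in calls}
    sample_order: list[str] = []
    seen: set[str] = set()
    for c in calls:
        if c.sample_id not in seen:
            seen.add(c.sample_id)
            sample_order.append(c.sample_id)

    hits: dict[str, list[tuple[str, str]]] = {s: [] for s in sample_order}
    for c in calls:
        if c.gene in pmn.all_genes and c.state != NEUTRAL:
            hits[c.sample_id].append((c.gene, c.state))
    for v in variants:
        if v.gene not in known_genes:
            logger.warning("variant in unknown gene %r (sample %s) skipped", v.gene, v.sample_id)
            continue
        if v.gene in pmn.all_genes and v.variant_class in non_silent_classes:
            if v.sample_id not in hits:
                continue  # variant-only sample outside the call universe
            if (v.gene, "MUTATION") not in hits[v.sample_id]:
                hits[v.sample_id].append((v.gene, "MUTATION"))

    records = [
        PMNHitRecord(sample_id=s, pmn_hit=bool(hits[s]), hit_genes=tuple(sorted(hits[s])))
        for s in sample_order
    ]
    return PMNHitTable(records)


# ---------------------------------------------------------------------------
# TSV persistence
# ---------------------------------------------------------------------------


def write_gene_calls(calls: Iterable[GeneCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgene\tstate\tgene_segment_mean\n")
        for c in calls:
            fh.write(f"{c.sample_id}\t{c.gene}\t{c.state}\t{c.gene_segment_mean!r}\n")


def read_gene_calls(path: str) -> list[GeneCall]:
    out: list[GeneCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sample_id", "gene", "state", "gene_segment_mean"]:
            raise ValidationError(f"{path}: bad gene-call header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(GeneCall(f[0], f[1], f[2], float(f[3])))
    return out


def write_hit_table(table: PMNHitTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpmn_hit\thit_genes\n")
        for r in table.records:
            genes = ";".join(f"{g}:{k}" for g, k in r.hit_genes)
            fh.write(f"{r.sample_id}\t{r.pmn_hit}\t{genes}\n")


def read_hit_table(path: str) -> PMNHitTable:
    records: list[PMNHitRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sample_id", "pmn_hit", "hit_genes"]:
            raise ValidationError(f"{path}: bad hit-table header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            genes = (
                tuple(tuple(item.split(":", 1)) for item in f[2].split(";")) if len(f) > 2 and f[2] else ()
            )
            records.append(PMNHitRecord(f[0], f[1] == "True", genes))  # type: ignore[arg-type]
    return PMNHitTable(records)
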