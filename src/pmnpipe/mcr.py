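"""Minimal-common-region (MCR) discovery over copy-number loss segments.

The MCR of a sample set is the maximal interval(s) covered by the merged
loss footprint of *every* sample — the intersection of per-sample merged
loss intervals, computed per chromosome by sweep line. All coordinates are
1-based fully closed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from pmnpipe.exceptions import ValidationError
from pmnpipe.intervals import intersect_many, merge_intervals, overlap_len
from pmnpipe.io import GeneAnnotation, SegmentRecord

__all__ = [
    "MCRResult",
    "loss_segments_by_sample",
    "find_mcr",
    "genes_in_region",
    "chrom_arm_loss_status",
]

Region = tuple[str, int, int]


@dataclass
class MCRResult:
    """Intersected loss interval(s) with supporting samples and contained genes."""

    intervals: list[Region]
    n_samples: int
    genes_contained: list[str] = field(default_factory=list)
    per_sample_support: dict[str, list[Region]] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(e - s + 1 for _, s, e in self.intervals)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intervals": [list(iv) for iv in self.intervals],
                    "n_samples": self.n_samples,
                    "genes_contained": self.genes_contained,
                    "per_sample_support": {
                        s: [list(iv) for iv in ivs] for s, ivs in self.per_sample_support.items()
                    },
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "MCRResult":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            intervals=[(c, int(s), int(e)) for c, s, e in raw["intervals"]],
            n_samples=int(raw["n_samples"]),
            genes_contained=list(raw.get("genes_contained", [])),
            per_sample_support={
                s: [(c, int(a), int(b)) for c, a, b in ivs]
                for s, ivs in raw.get("per_sample_support", {}).items()
            },
        )

    def write_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for i, (chrom, start, end) in enumerate(self.intervals, 1):
                fh.write(f"{chrom}\t{start - 1}\t{end}\tMCR_{i}\n")


def loss_segments_by_sample(
    segments: Sequence[SegmentRecord],
    samples: set[str] | None = None,
    loss_threshold: float = 0.3,
) -> dict[str, list[Region]]:
    """Per-sample loss segments (segment_mean < -loss_threshold), unmerged."""
    out: dict[str, list[Region]] = {}
    for seg in segments:
        if samples is not None and seg.sample_id not in samples:
            continue
        if seg.segment_mean < -loss_threshold:
            out.setdefault(seg.sample_id, []).append((seg.chrom, seg.start, seg.end))
    return out


def find_mcr(
    loss_segments: dict[str, list[Region]],
    samples: set[str],
) -> MCRResult:
    """Intersect the merged loss footprints of all given samples.

    Returns the maximal interval(s) supported by every sample; an empty
    interval list when no base is commonly lost.

    Raises
    ------
    ValidationError
        If a requested sample has no loss segments at all.
    """
    if not samples:
        raise ValidationError("sample set is empty")
    missing = sorted(s for s in samples if not loss_segments.get(s))
    if missing:
        raise ValidationError(f"samples with no loss segments: {missing}")

    sample_list = sorted(samples)
    chroms = sorted({c for s in sample_list for c, _, _ in loss_segments[s]})
    intervals: list[Region] = []
    for chrom in chroms:
        per_sample = []
        for s in sample_list:
            ivs = [(a, b) for c, a, b in loss_segments[s] if c == chrom]
            if not ivs:
                per_sample = []
                break
            per_sample.append(merge_intervals(ivs))
        if per_sample:
            intervals.extend((chrom, a, b) for a, b in intersect_many(per_sample))

    support: dict[str, list[Region]] = {}
    for s in sample_list:
        contributing = [
            (c, a, b)
            for c, a, b in loss_segments[s]
            if any(c == ic and overlap_len(a, b, is_, ie) > 0 for ic, is_, ie in intervals)
        ]
        support[s] = contributing
    return MCRResult(
        intervals=sorted(intervals),
        n_samples=len(sample_list),
        per_sample_support=support,
    )


def genes_in_region(
    intervals: Sequence[Region], annotation: Sequence[GeneAnnotation]
) -> list[str]:
    """Genes overlapping (>= 1 bp, closed-interval) any of the intervals, by coordinate."""
    hits = [
        g
        for g in annotation
        if any(
            g.chrom == c and overlap_len(g.start, g.end, s, e) > 0 for c, s, e in intervals
        )
    ]
    hits.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene))
    return [g.gene for g in hits]


def chrom_arm_loss_status(
    segments: Sequence[SegmentRecord],
    arms: Sequence[tuple[str, str, int, int]],
    sample_id: str,
    loss_threshold: float = 0.3,
    arm_loss_fraction: float = 0.9,
) -> dict[str, bool]:
    """Per-arm total-loss flags for one sample.

    An arm is "lost" iff at least ``arm_loss_fraction`` of its length is
    covered by loss segments (segment_mean < -loss_threshold). Keys are
    ``"chr19q"``-style labels.
    """
    if not arms:
        raise ValidationError("no arms provided")
    sample_losses = [
        (s.chrom, s.start, s.end)
        for s in segments
        if s.sample_id == sample_id and s.segment_mean < -loss_threshold
    ]
    out: dict[str, bool] = {}
    for chrom, arm, a_start, a_end in arms:
        arm_len = a_end - a_start + 1
        merged = merge_intervals(
            [
                (max(s, a_start), min(e, a_end))
                for c, s, e in sample_losses
                if c == chrom and overlap_len(s, e, a_start, a_end) > 0
            ]
        )
        covered = sum(e - s + 1 for s, e in merged)
        out[f"{chrom}{arm}"] = covered >= arm_loss_fraction * arm_len
    return out
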