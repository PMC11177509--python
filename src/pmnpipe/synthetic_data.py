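"""Synthetic bulk-cohort and single-cell generators with planted structure.

The simulator lays genes on a miniature two-chromosome genome (chr8, chr19),
plants PMN gains/losses/mutations at configured rates, plants a focal
19q-like deletion covering ``planted_mcr`` in a configurable fraction of
PMN-WT samples, and ties MYC expression to the planted labels. Truth tables
are emitted alongside the data so every downstream stage can be checked
exactly.

Planted focal losses are strict supersets of ``planted_mcr`` with random
flank extensions, except the first planted sample whose segment equals the
MCR exactly — this anchors the sample-set intersection to the planted
interval for any number of supporting samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from pmnpipe.exceptions import ConfigurationError, ValidationError
from pmnpipe.genome import GenomeConfig, toy_genome
from pmnpipe.io import (
    CellCNMatrix,
    ClinicalRecord,
    ExpressionMatrix,
    GeneAnnotation,
    SegmentRecord,
    VariantRecord,
)
from pmnpipe.scna import PMN_GENES

__all__ = ["SimConfig", "SimulatedCohort", "build_annotation", "simulate_cohort", "simulate_cells"]

_NONCANCER_LABELS = ("Macrophages", "Oligodendrocyte", "Endothelial cell")
_NONCANCER_PROBS = (0.7, 0.2, 0.1)

_GENE_LEN = 4_000
_GENE_SPACING = 8_000
_GENE_OFFSET = 10_001

#: zones where background (non-planted) alterations may land; kept clear of
#: the PMN gene block (chr8 p start) and the planted MCR (chr19 q)
_BACKGROUND_ZONES = {"chr8": (650_001, 1_150_000), "chr19": (50_001, 450_000)}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the cohort and single-cell generators."""

    n_samples: int = 236
    grade_probs: tuple[float, float, float] = (119 / 236, 104 / 236, 13 / 236)
    n_genes: int = 240
    pmn_gain_rate: float = 0.35
    pmn_loss_rate: float = 0.30
    pmn_mutation_rate: float = 0.02
    mcr_loss_rate_in_wt: float = 0.25
    planted_mcr: tuple[str, int, int] = ("chr19", 700_001, 820_000)
    myc_effect_pmn: float = 0.8
    myc_effect_mcr: float = 0.6
    myc_baseline: float = 5.0
    myc_grade_trend: float = 0.3
    mcr_gene_loss_effect: float = 1.2
    noise_sd: float = 0.4
    loss_mean_range: tuple[float, float] = (-1.2, -0.35)
    gain_mean_range: tuple[float, float] = (0.35, 1.2)
    background_segments_per_sample: float = 4.0
    background_pool_size: int = 30
    snv_rate: float = 5.0
    snv_rate_pmn_multiplier: float = 1.0
    indel_rate: float = 1.0
    pfi_base_hazard: float = 1 / 1500
    pfi_hr_pmn: float = 1.0
    pfi_hr_mcr: float = 1.0
    os_base_hazard: float = 1 / 2500
    censor_time: float = 3000.0
    n_cells: int = 2000
    beta0: float = 1.0
    beta1: float = -2.0
    beta2: float = 0.0
    cell_loss_rate: float = 0.5
    cell_cn_shift: float = 0.2
    cell_cn_sd: float = 0.05
    region_jitter_sd: float = 0.0
    noncancer_fraction: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.pmn_gain_rate,
            self.pmn_loss_rate,
            self.pmn_mutation_rate,
            self.mcr_loss_rate_in_wt,
            self.cell_loss_rate,
            self.noncancer_fraction,
        ] + list(self.grade_probs)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all rates must lie in [0, 1]")
        if not math.isclose(sum(self.grade_probs), 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"grade_probs must sum to 1, got {sum(self.grade_probs)}")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        chrom, s, e = self.planted_mcr
        if s < 1 or e < s:
            raise ConfigurationError(f"malformed planted_mcr interval {self.planted_mcr}")
        if self.n_samples < 1 or self.n_genes < 1 or self.n_cells < 1:
            raise ConfigurationError("n_samples, n_genes and n_cells must be >= 1")

        p_hit = 1.0 - (1 - self.pmn_gain_rate) * (1 - self.pmn_loss_rate) * (
            1 - self.pmn_mutation_rate
        )
        if p_hit > 0 and self.n_samples * p_hit < 2:
            raise ConfigurationError("expected PMN-hit group smaller than 2 samples")
        exp_wt = self.n_samples * (1 - p_hit)
        if self.mcr_loss_rate_in_wt > 0 and exp_wt * self.mcr_loss_rate_in_wt < 2:
            raise ConfigurationError("expected MCR-loss group smaller than 2 samples")


@dataclass
class SimulatedCohort:
    segments: list[SegmentRecord]
    variants: list[VariantRecord]
    expression: ExpressionMatrix
    clinical: list[ClinicalRecord]
    annotation: list[GeneAnnotation]
    truth: pd.DataFrame = field(repr=False)  # sample_id, pmn_hit, mcr_loss, subclass
    genome: GenomeConfig = field(default_factory=toy_genome, repr=False)


def build_annotation(config: SimConfig, genome: GenomeConfig | None = None) -> list[GeneAnnotation]:
    """Deterministically tile ``n_genes`` genes over the toy genome.

    The 14 PMN genes occupy the first slots of chr8; all other genes are
    named ``G_0001``-style in coordinate order.
    """
    genome = genome or toy_genome()
    chroms = genome.chromosomes
    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per_chrom[i] += 1
    pmn_names = sorted(PMN_GENES.all_genes)
    annotation: list[GeneAnnotation] = []
    counter = 0
    for chrom, n_here in zip(chroms, per_chrom):
        length = genome.lengths[chrom]
        cen = genome.centromeres.get(chrom, length)
        for k in range(n_here):
            start = _GENE_OFFSET + k * _GENE_SPACING
            end = start + _GENE_LEN - 1
            if end > length:
                raise ConfigurationError(
                    f"{config.n_genes} genes do not fit on the genome (overflow on {chrom})"
                )
            if chrom == "chr8" and k < len(pmn_names):
                name = pmn_names[k]
            else:
                counter += 1
                name = f"G_{counter:04d}"
            annotation.append(
                GeneAnnotation(name, chrom, start, end, "p" if end <= cen else "q")
            )
    return annotation


def _carve(
    segs: list[tuple[int, int, float]], start: int, end: int, mean: float
) -> list[tuple[int, int, float]]:
    """Overwrite [start, end] with a new segment, truncating/splitting others."""
    out: list[tuple[int, int, float]] = []
    for s, e, m in segs:
        if e < start or s > end:
            out.append((s, e, m))
            continue
        if s < start:
            out.append((s, start - 1, m))
        if e > end:
            out.append((end + 1, e, m))
    out.append((start, end, mean))
    out.sort()
    return out


def _num_probes(start: int, end: int) -> int:
    return max(1, (end - start + 1) // 1000)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full bulk cohort with planted structure and truth labels.

    Deterministic given ``config.seed``. Background mutations and background
    SCNAs are confined away from PMN genes and the planted MCR so the planted
    truth tables remain exact.
    """
    rng = np.random.default_rng(config.seed)
    genome = toy_genome()
    annotation = build_annotation(config, genome)
    gene_by_name = {a.gene: a for a in annotation}
    mcr_chrom, mcr_start, mcr_end = config.planted_mcr
    if mcr_chrom not in genome.lengths or mcr_end > genome.lengths[mcr_chrom]:
        raise ConfigurationError(f"planted_mcr {config.planted_mcr} outside the toy genome")

    pmn_present = sorted(PMN_GENES.all_genes & set(gene_by_name))
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    grades = rng.choice([2, 3, 4], size=config.n_samples, p=list(config.grade_probs))

    lo_loss, hi_loss = config.loss_mean_range
    lo_gain, hi_gain = config.gain_mean_range

    segments: list[SegmentRecord] = []
    variants: list[VariantRecord] = []
    pmn_hit = np.zeros(config.n_samples, dtype=bool)
    mcr_loss = np.zeros(config.n_samples, dtype=bool)

    # decide planted events first so MCR planting sees final WT status
    gain_draw = rng.random(config.n_samples) < config.pmn_gain_rate
    loss_draw = rng.random(config.n_samples) < config.pmn_loss_rate
    mut_draw = rng.random(config.n_samples) < config.pmn_mutation_rate
    pmn_hit = gain_draw | loss_draw | mut_draw
    wt_idx = np.where(~pmn_hit)[0]
    mcr_draw = rng.random(len(wt_idx)) < config.mcr_loss_rate_in_wt
    mcr_loss[wt_idx[mcr_draw]] = True
    anchor_planted = False

    bases = np.array(list("ACGT"))
    background_genes = [
        a
        for a in annotation
        if a.chrom in _BACKGROUND_ZONES
        and _BACKGROUND_ZONES[a.chrom][0] <= a.start
        and a.end <= _BACKGROUND_ZONES[a.chrom][1]
    ]
    if not background_genes:
        raise ConfigurationError("no genes fall inside the background zones")
    # SCNA background is concentrated in a small pool so that per-gene
    # alteration frequencies land inside the screen's 10-90% window
    background_pool = background_genes[: max(1, config.background_pool_size)]

    for i, sample in enumerate(samples):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom in genome.chromosomes:
            length = genome.lengths[chrom]
            # neutral base segmentation with sub-threshold means
            n_break = int(rng.integers(1, 4))
            cuts = sorted(rng.integers(2, length, size=n_break).tolist())
            bounds = [1] + cuts + [length + 1]
            segs = [
                (bounds[j], bounds[j + 1] - 1, float(rng.normal(0.0, 0.03)))
                for j in range(len(bounds) - 1)
                if bounds[j + 1] - 1 >= bounds[j]
            ]
            per_chrom[chrom] = segs

        # planted PMN events
        if gain_draw[i]:
            g = gene_by_name[pmn_present[int(rng.integers(len(pmn_present)))]]
            flank = int(rng.integers(0, 2000))
            per_chrom[g.chrom] = _carve(
                per_chrom[g.chrom],
                max(1, g.start - flank),
                min(genome.lengths[g.chrom], g.end + flank),
                float(rng.uniform(lo_gain, hi_gain)),
            )
        if loss_draw[i]:
            g = gene_by_name[pmn_present[int(rng.integers(len(pmn_present)))]]
            flank = int(rng.integers(0, 2000))
            per_chrom[g.chrom] = _carve(
                per_chrom[g.chrom],
                max(1, g.start - flank),
                min(genome.lengths[g.chrom], g.end + flank),
                float(rng.uniform(lo_loss, hi_loss)),
            )
        if mut_draw[i]:
            g = gene_by_name[pmn_present[int(rng.integers(len(pmn_present)))]]
            pos = int(rng.integers(g.start, g.end + 1))
            ref, alt = rng.choice(bases, size=2, replace=False)
            variants.append(
                VariantRecord(sample, g.gene, g.chrom, pos, str(ref), str(alt), "SNV", "Missense_Mutation")
            )

        # planted focal MCR loss in a subset of PMN-WT samples
        if mcr_loss[i]:
            if not anchor_planted:
                left = right = 0
                anchor_planted = True
            else:
                left = int(rng.integers(0, 30_001))
                right = int(rng.integers(0, 30_001))
            per_chrom[mcr_chrom] = _carve(
                per_chrom[mcr_chrom],
                max(1, mcr_start - left),
                min(genome.lengths[mcr_chrom], mcr_end + right),
                float(rng.uniform(lo_loss, hi_loss)),
            )

        # background SCNAs confined to the safe zones
        n_bg = int(rng.poisson(config.background_segments_per_sample))
        for _ in range(n_bg):
            g = background_pool[int(rng.integers(len(background_pool)))]
            flank = int(rng.integers(0, 2000))
            zone = _BACKGROUND_ZONES[g.chrom]
            mean = (
                float(rng.uniform(lo_gain, hi_gain))
                if rng.random() < 0.5
                else float(rng.uniform(lo_loss, hi_loss))
            )
            per_chrom[g.chrom] = _carve(
                per_chrom[g.chrom],
                max(zone[0], g.start - flank),
                min(zone[1], g.end + flank),
                mean,
            )

        for chrom, segs in per_chrom.items():
            for s, e, m in segs:
                segments.append(SegmentRecord(sample, chrom, s, e, _num_probes(s, e), m))

        # background variants (never in PMN genes: keeps truth exact)
        mult = config.snv_rate_pmn_multiplier if pmn_hit[i] else 1.0
        for _ in range(int(rng.poisson(config.snv_rate * mult))):
            g = background_genes[int(rng.integers(len(background_genes)))]
            pos = int(rng.integers(g.start, g.end + 1))
            ref, alt = rng.choice(bases, size=2, replace=False)
            variants.append(
                VariantRecord(sample, g.gene, g.chrom, pos, str(ref), str(alt), "SNV", "Missense_Mutation")
            )
        for _ in range(int(rng.poisson(config.indel_rate))):
            g = background_genes[int(rng.integers(len(background_genes)))]
            pos = int(rng.integers(g.start, g.end + 1))
            if rng.random() < 0.5:
                vt, ref, alt = "INS", "-", "AC"
            else:
                vt, ref, alt = "DEL", "AC", "-"
            variants.append(
                VariantRecord(sample, g.gene, g.chrom, pos, ref, alt, vt, "Frame_Shift_Ins" if vt == "INS" else "Frame_Shift_Del")
            )

    # expression
    mcr_genes = [
        a.gene
        for a in annotation
        if a.chrom == mcr_chrom and not (a.end < mcr_start or a.start > mcr_end)
    ]
    expr_values = np.empty((len(annotation), config.n_samples))
    for gi, a in enumerate(annotation):
        if a.gene == "MYC":
            mu = (
                config.myc_baseline
                + config.myc_grade_trend * (grades - 2)
                + config.myc_effect_pmn * pmn_hit
                + config.myc_effect_mcr * mcr_loss
            )
        elif a.gene in mcr_genes:
            mu = config.myc_baseline - config.mcr_gene_loss_effect * mcr_loss
        else:
            mu = np.full(config.n_samples, config.myc_baseline)
        expr_values[gi] = mu + rng.normal(0.0, config.noise_sd, size=config.n_samples)
    expression = ExpressionMatrix(
        pd.DataFrame(expr_values, index=pd.Index([a.gene for a in annotation], name="gene"), columns=samples)
    )

    # clinical
    clinical: list[ClinicalRecord] = []
    for i, sample in enumerate(samples):
        grade = int(grades[i])
        homdel = grade == 4
        hist = int(rng.choice([2, 3])) if homdel else grade
        pfi_hr = (
            config.pfi_hr_pmn if pmn_hit[i] else (config.pfi_hr_mcr if mcr_loss[i] else 1.0)
        )
        pfi_raw = float(rng.exponential(1.0 / (config.pfi_base_hazard * pfi_hr)))
        os_raw = float(rng.exponential(1.0 / config.os_base_hazard))
        clinical.append(
            ClinicalRecord(
                sample_id=sample,
                histologic_grade=hist,
                cdkn2ab_homdel=homdel,
                molecular_grade=grade,
                os_time=min(os_raw, config.censor_time),
                os_event=os_raw <= config.censor_time,
                pfi_time=min(pfi_raw, config.censor_time),
                pfi_event=pfi_raw <= config.censor_time,
            )
        )

    truth = pd.DataFrame(
        {
            "sample_id": samples,
            "pmn_hit": pmn_hit,
            "mcr_loss": mcr_loss,
            "subclass": np.where(pmn_hit, "PMN_HIT", np.where(mcr_loss, "MCR_LOSS", "WT")),
        }
    )
    return SimulatedCohort(segments, variants, expression, clinical, annotation, truth, genome)


def simulate_cells(
    config: SimConfig, regions: Sequence[tuple[str, int, int]]
) -> tuple[CellCNMatrix, pd.DataFrame]:
    """Generate a per-cell CN matrix with Poisson MYC counts and truth labels.

    Each cancer cell carries a latent CN level (shifted for loss cells); all
    regional estimates equal the latent level plus optional jitter, and MYC
    counts are Poisson with log-mean ``beta0 + beta1*CN*I(loss) +
    beta2*CN*I(no loss)``. Non-cancer cells have neutral CN and
    status-independent counts.
    """
    if not regions:
        raise ValidationError("simulate_cells requires at least one region")
    for c, s, e in regions:
        if e < s or s < 1:
            raise ValidationError(f"malformed region {(c, s, e)}")
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    cells = [f"C{i + 1:05d}" for i in range(n)]
    is_cancer = rng.random(n) >= config.noncancer_fraction
    cell_type = np.where(
        is_cancer,
        "Cancer stem cells",
        rng.choice(_NONCANCER_LABELS, size=n, p=_NONCANCER_PROBS),
    )
    loss = is_cancer & (rng.random(n) < config.cell_loss_rate)

    latent = np.where(loss, -config.cell_cn_shift, 0.0) + rng.normal(
        0.0, config.cell_cn_sd, size=n
    )
    latent = np.where(is_cancer, latent, rng.normal(0.0, config.cell_cn_sd, size=n))
    cn = np.tile(latent, (len(regions), 1))
    if config.region_jitter_sd > 0:
        cn = cn + rng.normal(0.0, config.region_jitter_sd, size=cn.shape)

    log_mu = np.where(
        is_cancer,
        config.beta0
        + config.beta1 * latent * loss
        + config.beta2 * latent * (is_cancer & ~loss),
        config.beta0,
    )
    counts = rng.poisson(np.exp(log_mu))

    mat = CellCNMatrix(
        regions=list(regions),
        cells=cells,
        cn_estimates=cn,
        cell_type=cell_type.tolist(),
        myc_counts=counts,
    )
    truth = pd.DataFrame(
        {"cell_id": cells, "is_cancer": is_cancer, "mcr_loss": loss}
    )
    return mat, truth


def default_cell_regions(
    config: SimConfig, n_regions: int = 9
) -> list[tuple[str, int, int]]:
    """Tile ``n_regions`` contiguous windows over the planted MCR."""
    chrom, start, end = config.planted_mcr
    edges = np.linspace(start, end + 1, n_regions + 1).astype(int)
    return [(chrom, int(edges[k]), int(edges[k + 1] - 1)) for k in range(n_regions)]
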