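"""Typed readers and writers for every on-disk format the pipeline touches.

Formats (all plain-text, tab-delimited):

- SEG: ``Sample  Chromosome  Start  End  Num_Probes  Segment_Mean``
- MAF-lite: ``Sample  Gene  Chromosome  Position  Ref  Alt  Variant_Type
  Variant_Classification``
- expression: genes x samples TSV, first column ``gene``
- gene annotation: ``gene  chrom  start  end  arm`` TSV (+ BED export)
- clinical: one row per sample
- single-cell CN: regions x cells TSV plus a per-cell metadata TSV

Coordinates are 1-based fully-closed throughout; only the BED export converts
to 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pmnpipe.exceptions import ParseError, ValidationError

__all__ = [
    "SegmentRecord",
    "VariantRecord",
    "GeneAnnotation",
    "ExpressionMatrix",
    "ClinicalRecord",
    "CellCNMatrix",
    "normalize_chrom",
    "read_segments",
    "write_segments",
    "read_variants",
    "write_variants",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "write_annotation_bed",
    "read_clinical",
    "write_clinical",
    "read_cell_cn",
    "write_cell_cn",
]

KNOWN_CHROMS = frozenset(
    {f"chr{i}" for i in range(1, 23)} | {"chrX", "chrY", "chrM"}
)

_VARIANT_TYPES = ("SNV", "INS", "DEL")


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label to ``chrN`` form. Idempotent.

    ``"19" -> "chr19"``, ``"chr19" -> "chr19"``, ``"MT"/"M" -> "chrM"``,
    ``"23" -> "chrX"``, ``"24" -> "chrY"``.
    """
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = {"MT": "M", "23": "X", "24": "Y"}.get(c.upper(), c)
    if c.upper() in ("X", "Y", "M"):
        c = c.upper()
    return f"chr{c}"


@dataclass(frozen=True)
class SegmentRecord:
    """One copy-number segment with a log2 copy-ratio segment mean."""

    sample_id: str
    chrom: str
    start: int
    end: int
    num_probes: int
    segment_mean: float

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"segment start {self.start} < 1 ({self.sample_id})")
        if self.end < self.start:
            raise ValidationError(
                f"segment end {self.end} < start {self.start} ({self.sample_id}, {self.chrom})"
            )
        if self.num_probes < 1:
            raise ValidationError(f"num_probes {self.num_probes} < 1 ({self.sample_id})")
        if self.chrom not in KNOWN_CHROMS:
            raise ValidationError(f"unknown chromosome name {self.chrom!r}")
        if not math.isfinite(self.segment_mean):
            raise ValidationError(f"non-finite segment mean ({self.sample_id}, {self.chrom})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class VariantRecord:
    """One somatic simple-nucleotide variant (MAF-lite row)."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str
    variant_class: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position {self.pos} < 1 ({self.sample_id})")
        if self.variant_type not in _VARIANT_TYPES:
            raise ValidationError(f"variant_type {self.variant_type!r} not in {_VARIANT_TYPES}")
        ref, alt = self.ref.replace("-", ""), self.alt.replace("-", "")
        if self.variant_type == "SNV" and len(ref) != len(alt):
            raise ValidationError(f"SNV with ref/alt length mismatch ({self.sample_id}:{self.pos})")
        if self.variant_type == "INS" and len(alt) <= len(ref):
            raise ValidationError(f"INS with alt not longer than ref ({self.sample_id}:{self.pos})")
        if self.variant_type == "DEL" and len(ref) <= len(alt):
            raise ValidationError(f"DEL with ref not longer than alt ({self.sample_id}:{self.pos})")


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic footprint of one gene, 1-based closed, with arm assignment."""

    gene: str
    chrom: str
    start: int
    end: int
    arm: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene}: start {self.start} > end {self.end}")
        if self.arm not in ("p", "q"):
            raise ValidationError(f"gene {self.gene}: arm must be 'p' or 'q', got {self.arm!r}")


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-sample clinical/molecular annotations."""

    sample_id: str
    histologic_grade: int
    cdkn2ab_homdel: bool
    molecular_grade: int
    os_time: float
    os_event: bool
    pfi_time: float
    pfi_event: bool

    def __post_init__(self) -> None:
        if self.histologic_grade not in (2, 3):
            raise ValidationError(f"histologic grade must be 2 or 3, got {self.histologic_grade}")
        expected = 4 if self.cdkn2ab_homdel else self.histologic_grade
        if self.molecular_grade != expected:
            raise ValidationError(
                f"{self.sample_id}: molecular_grade {self.molecular_grade} inconsistent with "
                f"CDKN2A/B status (expected {expected})"
            )
        if self.os_time < 0 or self.pfi_time < 0:
            raise ValidationError(f"{self.sample_id}: negative survival time")


class ExpressionMatrix:
    """Log-scale normalized expression, genes x samples.

    Thin wrapper over a pandas DataFrame enforcing unique gene/sample names
    and the absence of missing values. Values are treated as opaque
    log-scale quantities; no normalization is performed.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dupes}")
        if values.columns.duplicated().any():
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if values.isna().any().any():
            gene = values.index[values.isna().any(axis=1)][0]
            sample = values.columns[values.isna().any(axis=0)][0]
            raise ValidationError(f"missing value at gene {gene!r}, sample {sample!r}")
        self._df = values.astype(float)

    @property
    def genes(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self._df.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def gene_values(self, gene: str, samples: Sequence[str] | None = None) -> np.ndarray:
        """Expression vector of one gene, optionally restricted to samples."""
        if gene not in self._df.index:
            raise ValidationError(f"gene {gene!r} not in expression matrix")
        row = self._df.loc[gene]
        if samples is not None:
            missing = [s for s in samples if s not in self._df.columns]
            if missing:
                raise ValidationError(f"samples not in expression matrix: {missing}")
            row = row.loc[list(samples)]
        return row.to_numpy(dtype=float)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self._df.loc[:, list(samples)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self._df.equals(other._df)


class CellCNMatrix:
    """Per-cell copy-number estimates over genomic windows plus cell metadata.

    ``cn_estimates`` is regions x cells; ``cell_type`` and ``myc_counts``
    are aligned to ``cells``.
    """

    def __init__(
        self,
        regions: Sequence[tuple[str, int, int]],
        cells: Sequence[str],
        cn_estimates: np.ndarray,
        cell_type: Sequence[str],
        myc_counts: Sequence[int],
    ):
        regions = [(str(c), int(s), int(e)) for c, s, e in regions]
        cn = np.asarray(cn_estimates, dtype=float)
        if cn.shape != (len(regions), len(cells)):
            raise ValidationError(
                f"cn matrix shape {cn.shape} != (n_regions={len(regions)}, n_cells={len(cells)})"
            )
        if len(cell_type) != len(cells) or len(myc_counts) != len(cells):
            raise ValidationError("cell metadata length does not match number of cells")
        counts = np.asarray(myc_counts)
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("myc_counts must be integers")
            counts = np.round(counts).astype(int)
        if (counts < 0).any():
            raise ValidationError("myc_counts must be non-negative")
        # regions sorted, non-overlapping within a chromosome
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in regions:
            if e < s:
                raise ValidationError(f"region {c}:{s}-{e} has end < start")
            by_chrom.setdefault(c, []).append((s, e))
        for c, ivs in by_chrom.items():
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValidationError(
                        f"regions on {c} overlap or are unsorted: ({s1},{e1}) then ({s2},{e2})"
                    )
        if len(set(cells)) != len(cells):
            raise ValidationError("duplicate cell ids")
        self.regions = regions
        self.cells = list(cells)
        self.cn_estimates = cn
        self.cell_type = list(cell_type)
        self.myc_counts = counts

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset_cells(self, mask: np.ndarray) -> "CellCNMatrix":
        mask = np.asarray(mask, dtype=bool)
        return CellCNMatrix(
            self.regions,
            [c for c, m in zip(self.cells, mask) if m],
            self.cn_estimates[:, mask],
            [t for t, m in zip(self.cell_type, mask) if m],
            self.myc_counts[mask],
        )


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

_SEG_HEADER = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


def read_segments(path: str) -> list[SegmentRecord]:
    """Read a SEG-dialect file into validated :class:`SegmentRecord` objects."""
    records: list[SegmentRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != _SEG_HEADER:
            raise ParseError(f"{path}: bad SEG header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 fields, got {len(fields)}")
            try:
                rec = SegmentRecord(
                    sample_id=fields[0],
                    chrom=normalize_chrom(fields[1]),
                    start=int(fields[2]),
                    end=int(fields[3]),
                    num_probes=int(fields[4]),
                    segment_mean=float(fields[5]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_segments(records: Iterable[SegmentRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SEG_HEADER) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.num_probes}\t"
                f"{r.segment_mean!r}\n"
            )


# ---------------------------------------------------------------------------
# MAF-lite
# ---------------------------------------------------------------------------

_MAF_HEADER = [
    "Sample",
    "Gene",
    "Chromosome",
    "Position",
    "Ref",
    "Alt",
    "Variant_Type",
    "Variant_Classification",
]


def read_variants(path: str) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != _MAF_HEADER:
            raise ParseError(f"{path}: bad MAF-lite header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ParseError(f"{path}:{lineno}: expected 8 fields, got {len(fields)}")
            try:
                rec = VariantRecord(
                    sample_id=fields[0],
                    gene=fields[1],
                    chrom=normalize_chrom(fields[2]),
                    pos=int(fields[3]),
                    ref=fields[4],
                    alt=fields[5],
                    variant_type=fields[6],
                    variant_class=fields[7],
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_variants(records: Iterable[VariantRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_MAF_HEADER) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.gene}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t"
                f"{r.variant_type}\t{r.variant_class}\n"
            )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def read_expression(path: str) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene symbol)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "gene":
            raise ParseError(f"{path}: expression header must start with 'gene'")
        samples = header[1:]
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {len(header)})"
                )
            genes.append(fields[0])
            row = []
            for sample, cell in zip(samples, fields[1:]):
                try:
                    val = float(cell)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: bad value {cell!r} for gene {fields[0]!r}, "
                        f"sample {sample!r}"
                    ) from exc
                if math.isnan(val):
                    raise ParseError(
                        f"{path}:{lineno}: missing value for gene {fields[0]!r}, sample {sample!r}"
                    )
                row.append(val)
            rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str) -> None:
    expr.df.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

_ANNOT_HEADER = ["gene", "chrom", "start", "end", "arm"]


def read_annotation(path: str) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _ANNOT_HEADER:
        raise ParseError(f"{path}: bad annotation header {list(df.columns)}")
    seen: set[str] = set()
    out: list[GeneAnnotation] = []
    for _, row in df.iterrows():
        if row["gene"] in seen:
            raise ValidationError(f"{path}: duplicate gene symbol {row['gene']!r}")
        seen.add(row["gene"])
        out.append(
            GeneAnnotation(
                gene=row["gene"],
                chrom=normalize_chrom(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                arm=row["arm"],
            )
        )
    return out


def write_annotation(annotation: Iterable[GeneAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_HEADER) + "\n")
        for a in annotation:
            fh.write(f"{a.gene}\t{a.chrom}\t{a.start}\t{a.end}\t{a.arm}\n")


def write_annotation_bed(annotation: Iterable[GeneAnnotation], path: str) -> None:
    """BED export: 0-based half-open (start-1, end)."""
    with open(path, "w") as fh:
        for a in annotation:
            fh.write(f"{a.chrom}\t{a.start - 1}\t{a.end}\t{a.gene}\n")


# ---------------------------------------------------------------------------
# Clinical
# ---------------------------------------------------------------------------

_CLIN_HEADER = [
    "sample_id",
    "histologic_grade",
    "cdkn2ab_homdel",
    "molecular_grade",
    "os_time",
    "os_event",
    "pfi_time",
    "pfi_event",
]


def _parse_bool(s: str, where: str) -> bool:
    if s in ("True", "true", "1"):
        return True
    if s in ("False", "false", "0"):
        return False
    raise ParseError(f"{where}: bad boolean {s!r}")


def read_clinical(path: str) -> list[ClinicalRecord]:
    records: list[ClinicalRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != _CLIN_HEADER:
            raise ParseError(f"{path}: bad clinical header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 8:
                raise ParseError(f"{path}:{lineno}: expected 8 fields, got {len(f)}")
            where = f"{path}:{lineno}"
            records.append(
                ClinicalRecord(
                    sample_id=f[0],
                    histologic_grade=int(f[1]),
                    cdkn2ab_homdel=_parse_bool(f[2], where),
                    molecular_grade=int(f[3]),
                    os_time=float(f[4]),
                    os_event=_parse_bool(f[5], where),
                    pfi_time=float(f[6]),
                    pfi_event=_parse_bool(f[7], where),
                )
            )
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CLIN_HEADER) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.histologic_grade}\t{r.cdkn2ab_homdel}\t"
                f"{r.molecular_grade}\t{r.os_time!r}\t{r.os_event}\t"
                f"{r.pfi_time!r}\t{r.pfi_event}\n"
            )


# ---------------------------------------------------------------------------
# Single-cell CN matrix + metadata
# ---------------------------------------------------------------------------

_META_HEADER = ["cell_id", "cell_type", "myc_count"]


def read_cell_cn(path_cn: str, path_meta: str) -> CellCNMatrix:
    """Read a regions x cells CN TSV plus the aligned per-cell metadata TSV.

    The two files must cover exactly the same cell ids; metadata rows are
    re-ordered to match the CN matrix column order.
    """
    cn_df = pd.read_csv(path_cn, sep="\t", float_precision="round_trip")
    required = ["chrom", "start", "end"]
    if list(cn_df.columns[:3]) != required:
        raise ParseError(f"{path_cn}: first three columns must be {required}")
    cells = [str(c) for c in cn_df.columns[3:]]
    if not cells:
        raise ParseError(f"{path_cn}: no cell columns")
    regions = [
        (normalize_chrom(str(r.chrom)), int(r.start), int(r.end))
        for r in cn_df.itertuples(index=False)
    ]
    meta = pd.read_csv(path_meta, sep="\t", dtype={"cell_id": str})
    if list(meta.columns) != _META_HEADER:
        raise ParseError(f"{path_meta}: bad metadata header {list(meta.columns)}")
    meta = meta.set_index("cell_id")
    missing = sorted(set(cells) - set(meta.index))
    extra = sorted(set(meta.index) - set(cells))
    if missing or extra:
        raise ValidationError(
            f"cell-id mismatch between {path_cn} and {path_meta}: "
            f"missing from metadata {missing}, extra in metadata {extra}"
        )
    meta = meta.loc[cells]
    return CellCNMatrix(
        regions=regions,
        cells=cells,
        cn_estimates=cn_df[cells].to_numpy(dtype=float),
        cell_type=meta["cell_type"].tolist(),
        myc_counts=meta["myc_count"].to_numpy(),
    )


def write_cell_cn(mat: CellCNMatrix, path_cn: str, path_meta: str) -> None:
    cn_df = pd.DataFrame(mat.cn_estimates, columns=mat.cells)
    cn_df.insert(0, "chrom", [r[0] for r in mat.regions])
    cn_df.insert(1, "start", [r[1] for r in mat.regions])
    cn_df.insert(2, "end", [r[2] for r in mat.regions])
    cn_df.to_csv(path_cn, sep="\t", index=False, float_format="%.17g")
    meta = pd.DataFrame(
        {"cell_id": mat.cells, "cell_type": mat.cell_type, "myc_count": mat.myc_counts}
    )
    meta.to_csv(path_meta, sep="\t", index=False)
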