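"""Genome configuration: chromosome lengths and arm boundaries.

All coordinates are 1-based, fully closed intervals. The default is a
miniature two-chromosome genome used by the synthetic-data generator and the
test suite; real chromosome tables can be supplied as YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from pmnpipe.exceptions import ConfigurationError

__all__ = ["GenomeConfig", "toy_genome"]


@dataclass(frozen=True)
class GenomeConfig:
    """Chromosome lengths plus centromere positions defining p/q arms.

    Parameters
    ----------
    lengths
        Map chromosome name -> length in bp.
    centromeres
        Map chromosome name -> last base of the p arm. The q arm spans
        ``centromere + 1 .. length``.
    """

    lengths: dict[str, int]
    centromeres: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length < 1:
                raise ConfigurationError(f"chromosome {chrom} has length {length} < 1")
        for chrom, cen in self.centromeres.items():
            if chrom not in self.lengths:
                raise ConfigurationError(f"centromere given for unknown chromosome {chrom}")
            if not 1 <= cen < self.lengths[chrom]:
                raise ConfigurationError(
                    f"centromere {cen} outside chromosome {chrom} (length {self.lengths[chrom]})"
                )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.lengths if c not in ("chrX", "chrY", "chrM")]

    def arms(self) -> list[tuple[str, str, int, int]]:
        """Return (chrom, arm, start, end) for every defined arm, 1-based closed."""
        out: list[tuple[str, str, int, int]] = []
        for chrom, length in self.lengths.items():
            cen = self.centromeres.get(chrom)
            if cen is None:
                out.append((chrom, "q", 1, length))
            else:
                out.append((chrom, "p", 1, cen))
                out.append((chrom, "q", cen + 1, length))
        return out

    def arm_interval(self, chrom: str, arm: str) -> tuple[int, int]:
        for c, a, s, e in self.arms():
            if c == chrom and a == arm:
                return s, e
        raise ConfigurationError(f"unknown arm {chrom}{arm}")

    @classmethod
    def from_yaml(cls, path: str) -> "GenomeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            lengths={str(k): int(v) for k, v in raw["lengths"].items()},
            centromeres={str(k): int(v) for k, v in raw.get("centromeres", {}).items()},
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"lengths": dict(self.lengths), "centromeres": dict(self.centromeres)}, fh
            )


def toy_genome() -> GenomeConfig:
    """Two-chromosome miniature genome used by the simulator and tests."""
    return GenomeConfig(
        lengths={"chr8": 1_200_000, "chr19": 1_200_000},
        centromeres={"chr8": 600_000, "chr19": 500_000},
    )
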