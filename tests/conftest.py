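import numpy as np
import pytest

from pmnpipe import scna
from pmnpipe.io import GeneAnnotation, SegmentRecord
from pmnpipe.synthetic_data import SimConfig, simulate_cohort


def seg(sample, chrom, start, end, mean, probes=10):
    return SegmentRecord(sample, chrom, start, end, probes, mean)


def gene(name, chrom, start, end, arm="q"):
    return GeneAnnotation(name, chrom, start, end, arm)


@pytest.fixture(scope="session")
def cohort():
    """Default planted cohort (n=236, seed=1) shared across module tests."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_calls(cohort):
    return scna.call_gene_scna(cohort.segments, cohort.annotation)


@pytest.fixture(scope="session")
def cohort_hits(cohort, cohort_calls):
    return scna.pmn_hit_status(cohort_calls, cohort.variants)


def random_segments(rng, sample, chrom, chrom_len, max_segs=6):
    """Non-overlapping random segments covering part of a toy chromosome."""
    n = int(rng.integers(1, max_segs + 1))
    cuts = np.sort(rng.choice(np.arange(2, chrom_len), size=2 * n, replace=False))
    out = []
    for i in range(n):
        s, e = int(cuts[2 * i]), int(cuts[2 * i + 1])
        out.append(seg(sample, chrom, s, e, float(rng.normal(0, 0.6)), probes=1))
    return out
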