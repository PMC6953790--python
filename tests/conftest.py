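from __future__ import annotations

import numpy as np
import pytest

from segstack.genome_model import (
    Cohort,
    GeneRegion,
    GenomeAnnotation,
    GenomeBuild,
    SampleProfile,
    Segment,
)


def make_segment(sample="s1", chrom="1", start=0, end=100, log2=0.0, n_markers=None):
    return Segment(sample, chrom, start, end, log2, n_markers)


def make_profile(sample_id, triples, chrom="1"):
    """Build a profile from (start, end, log2) triples."""
    return SampleProfile(
        sample_id, [Segment(sample_id, chrom, s, e, v) for s, e, v in triples]
    )


@pytest.fixture
def small_build():
    return GenomeBuild("toy", {"1": 10_000_000, "2": 8_000_000, "X": 5_000_000})


@pytest.fixture
def annotation(small_build):
    genes = [
        GeneRegion("GENE1", "1", 100, 500),
        GeneRegion("GENE2", "1", 4_000_000, 4_050_000),
        GeneRegion("GENE3", "2", 1_000_000, 3_000_000),
    ]
    return GenomeAnnotation(
        build=small_build,
        genes=genes,
        centromeres={"1": (5_000_000, 5_200_000), "2": (4_000_000, 4_100_000)},
        fragile_sites=[("1", 3_000_000, 3_200_000)],
        stable_sites=[("2", 6_000_000, 6_500_000)],
        telomere_window_bp=2_000_000,
        expression={"GENE1": 5.0, "GENE3": 1.2},
    )


def random_cohort(rng, n_samples=5, n_chroms=2, chrom_len=1_000_000, max_segs=8):
    """Non-overlapping random cohort for property tests."""
    profiles = []
    for i in range(n_samples):
        sid = f"r{i}"
        segs = []
        for c in range(1, n_chroms + 1):
            n = int(rng.integers(0, max_segs + 1))
            bps = np.sort(rng.choice(chrom_len, size=2 * n, replace=False))
            for j in range(n):
                lo, hi = int(bps[2 * j]), int(bps[2 * j + 1])
                if lo == hi:
                    continue
                segs.append(
                    Segment(sid, str(c), lo, hi, float(rng.normal(0, 0.5)))
                )
        profiles.append(SampleProfile(sid, segs))
    return Cohort(profiles)
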