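import pandas as pd
import pytest

from tetrap import SimConfig, build_genome

SMALL = dict(
    genome_length=400_000,
    n_genes=40,
    n_te_instances=12,
    rnaseq_library_size=20_000,
    smallrna_library_size=40_000,
    n_mirna_loci=20,
    n_rrna_loci=2,
    seed=11,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale configuration for fast unit tests."""
    return SimConfig.from_dict(SMALL)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return build_genome(small_config)


@pytest.fixture()
def toy_reads() -> pd.DataFrame:
    """Hand-written read set exercising strand, MAPQ and multi-overlap."""
    rows = [
        # chrom, start, end, strand, mapq, sample
        ("chr1", 100, 175, "+", 60, "s1"),
        ("chr1", 150, 225, "-", 60, "s1"),
        ("chr1", 190, 265, "+", 19, "s1"),   # below MAPQ cutoff
        ("chr1", 300, 375, "+", 20, "s1"),   # boundary MAPQ retained
        ("chr1", 395, 470, "-", 42, "s1"),
        ("chr1", 400, 475, "+", 60, "s2"),
        ("chr1", 810, 885, "-", 31, "s2"),
        ("chr2", 120, 195, "+", 60, "s2"),
        ("chr2", 150, 225, "+", 60, "s1"),
        ("chr2", 500, 575, "-", 60, "s1"),
        ("chr1", 460, 535, "+", 60, "s1"),   # spans two features
        ("chr1", 0, 75, "-", 60, "s2"),
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "mapq", "sample"])


@pytest.fixture()
def toy_features() -> pd.DataFrame:
    rows = [
        ("chr1", 50, 480, "+", "fA"),
        ("chr1", 450, 900, "-", "fB"),
        ("chr2", 100, 600, "+", "fC"),
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "id"])


def brute_force_counts(reads, features, min_mapq=20):
    """Independent double-loop overlap counter used as an oracle."""
    out = {}
    for f in features.itertuples(index=False):
        for r in reads.itertuples(index=False):
            if r.mapq < min_mapq or r.chrom != f.chrom:
                continue
            if r.start < f.end and f.start < r.end:
                orient = "sense" if r.strand == f.strand else "antisense"
                key = (f.id, r.sample, orient)
                out[key] = out.get(key, 0) + 1
    return out
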