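"""Synthetic data generator for the demethylation time course.

Emulates the statistical structure the downstream analyses assume: a
WT -> conditional-KO demethylation time course (global mean methylation
0.85 -> 0.35 -> 0.20 with an IAP-like class retaining higher levels),
TE-class sense activation coupled to hypomethylation, genic transcription
antisense to embedded TEs, AGO2-IP-like small RNA libraries (~90% miRNA,
22-nt duplex siRNAs with 2-nt 3' overhangs and a 5'-U bias), and per-mark
chromatin enrichment over TE classes.

Every stage draws from a child stream derived deterministically from the
single root seed, so identical (config, seed) yields identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .annotation_io import GenomeAnnotation, tile_genome

TE_CLASSES = ["IAP-like", "MERVL-like", "ETn-like", "L1-like", "MMERVK-like", "SINE-like"]

_DEFAULT_METH_MEANS = {
    "global": {0: 0.85, 3: 0.35, 6: 0.20, 9: 0.20},
    # IAP-like elements retain higher methylation: global + 0.20, capped at 1.
    "IAP-like": {0: 1.0, 3: 0.55, 6: 0.40, 9: 0.40},
}

# Sense activation multipliers per class and day.  ERV/L1 classes activate
# as methylation is lost (some, like IAP-like, partially re-silence by day
# 9); the SINE-like class is transcriptionally neutral.
_DEFAULT_ACTIVATION = {
    "IAP-like": {0: 1.0, 3: 6.0, 6: 10.0, 9: 4.0},
    "MERVL-like": {0: 1.0, 3: 4.0, 6: 3.0, 9: 2.0},
    "ETn-like": {0: 1.0, 3: 4.0, 6: 8.0, 9: 8.0},
    "L1-like": {0: 1.0, 3: 3.0, 6: 5.0, 9: 5.0},
    "MMERVK-like": {0: 1.0, 3: 4.0, 6: 7.0, 9: 6.0},
    "SINE-like": {0: 1.0, 3: 1.0, 6: 1.0, 9: 1.0},
}

# Repressive-mark enrichment multipliers (per mark, class, day): H3K9me3 is
# constitutively high at IAP-like elements, while H3K27me3 and H3K9me2 are
# gained there during demethylation.
_DEFAULT_CHIP_ENRICHMENT = {
    "H3K9me3": {"IAP-like": {0: 4.0, 3: 4.0, 6: 3.5, 9: 3.0}},
    "H3K27me3": {"IAP-like": {0: 1.0, 3: 1.5, 6: 2.5, 9: 3.0}},
    "H3K9me2": {"IAP-like": {0: 1.0, 3: 1.2, 6: 2.0, 9: 2.5}},
}

_DEFAULT_SIRNA_LENGTHS = {20: 0.05, 21: 0.15, 22: 0.55, 23: 0.15, 24: 0.10}

_BASES = np.array(list("ACGT"))


class PlacementError(RuntimeError):
    """Requested features cannot be placed in the configured genome."""


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions being emulated."""

    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    n_genes: int = 200
    n_te_instances: int = 60                # per class
    te_classes: tuple = tuple(TE_CLASSES)
    genic_te_fraction: float = 0.10         # fraction of each class inserted in gene bodies
    antisense_insertion_prob: float = 0.7
    timepoints: tuple = (0, 3, 6, 9)
    meth_means: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_METH_MEANS.items()})
    iap_meth_offset: float = 0.20
    te_activation: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_ACTIVATION.items()})
    meth_coupled: dict = field(default_factory=lambda: {c: c != "SINE-like" for c in TE_CLASSES})
    te_expr_scale: float = 0.1
    gene_expr_sigma: float = 0.5            # lognormal sd of gene expression weights
    cpg_spacing: int = 100                  # one CpG per 100 bp
    meth_coverage_mean: float = 10.0        # Poisson coverage per CpG
    beta_concentration: float = 20.0        # per-site Beta concentration
    rnaseq_library_size: int = 100_000
    rnaseq_replicates: int = 3              # unmoderated per-gene tests need >= 3
    read_length: int = 75
    low_mapq_fraction: float = 0.05
    smallrna_library_size: int = 350_000
    smallrna_replicates: int = 3
    smallrna_mirna_fraction: float = 0.90
    smallrna_rrna_fraction: float = 0.02
    smallrna_te_fraction: float = 0.40      # of the non-miRNA/non-rRNA remainder, at the reference day
    sirna_length_dist: dict = field(default_factory=lambda: dict(_DEFAULT_SIRNA_LENGTHS))
    duplex_overhang: int = 2
    five_prime_u_prob: float = 0.75
    n_mirna_loci: int = 50
    n_rrna_loci: int = 4
    chip_enrichment: dict = field(default_factory=lambda: {m: {c: dict(d) for c, d in v.items()} for m, v in _DEFAULT_CHIP_ENRICHMENT.items()})
    chip_tile_baseline: float = 20.0        # mean reads per 1 kb tile
    chip_tile_width: int = 1000
    consensus_length: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "antisense_insertion_prob": self.antisense_insertion_prob,
            "smallrna_mirna_fraction": self.smallrna_mirna_fraction,
            "smallrna_rrna_fraction": self.smallrna_rrna_fraction,
            "smallrna_te_fraction": self.smallrna_te_fraction,
            "five_prime_u_prob": self.five_prime_u_prob,
            "low_mapq_fraction": self.low_mapq_fraction,
            "genic_te_fraction": self.genic_te_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        mass = sum(self.sirna_length_dist.values())
        if abs(mass - 1.0) > 1e-9:
            raise ConfigError(f"sirna_length_dist masses sum to {mass}, expected 1")
        for cls_or_global, by_day in self.meth_means.items():
            for day, m in by_day.items():
                if not 0.0 <= m <= 1.0:
                    raise ConfigError(
                        f"meth_means[{cls_or_global}][{day}] = {m} outside [0, 1]"
                    )
        if self.smallrna_mirna_fraction + self.smallrna_rrna_fraction > 1.0:
            raise ConfigError("miRNA + rRNA fractions exceed 1")
        if self.duplex_overhang < 0:
            raise ConfigError("duplex_overhang must be >= 0")

    # -- convenience -------------------------------------------------------
    @property
    def chrom_sizes(self) -> dict[str, int]:
        base = self.genome_length // self.n_chromosomes
        sizes = {f"chr{i + 1}": base for i in range(self.n_chromosomes)}
        sizes[f"chr{self.n_chromosomes}"] += self.genome_length - base * self.n_chromosomes
        return sizes

    def meth_mean(self, te_class: str | None, day: int) -> float:
        by_day = self.meth_means.get(te_class, self.meth_means["global"]) if te_class else self.meth_means["global"]
        if day not in by_day:
            raise ConfigError(
                f"day {day} not configured; timepoints are {sorted(self.meth_means['global'])}"
            )
        return by_day[day]

    def expression_coupling(self, te_class: str, day: int) -> float:
        """Linear methylation coupling: rate scales with (1 - methylation mean).

        Classes flagged methylation-uncoupled keep their day-0 coupling so a
        neutral class stays flat through the time course.
        """
        ref_day = day if self.meth_coupled.get(te_class, True) else min(self.timepoints)
        return 1.0 - self.meth_mean(te_class, ref_day)

    def te_rate(self, te_class: str, day: int) -> float:
        act = self.te_activation.get(te_class, {}).get(day, 1.0)
        return self.te_expr_scale * act * self.expression_coupling(te_class, day)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        defaults = cls()
        # nested tables support partial override; flat dicts (distributions,
        # flags) are replaced wholesale
        deep_merge = {"te_activation", "meth_means", "chip_enrichment"}
        kwargs = {}
        for key, value in data.items():
            if not hasattr(defaults, key):
                raise ConfigError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            if key in deep_merge and isinstance(value, dict):
                merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in current.items()}
                for k, v in value.items():
                    if isinstance(v, dict):
                        inner = dict(merged.get(k, {}))
                        inner.update({int(dk) if isinstance(dk, str) and dk.isdigit() else dk: dv
                                      for dk, dv in v.items()})
                        merged[k] = inner
                    else:
                        merged[k] = v
                kwargs[key] = merged
            elif isinstance(current, tuple) and isinstance(value, (list, tuple)):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic child stream for a (stage, sample, ...) key tuple."""
    spawn = tuple(zlib.crc32(str(k).encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=spawn))


def _random_sequences(rng: np.random.Generator, lengths: np.ndarray, u_prob: float | None) -> list[str]:
    """Random base strings; optionally force the 5' base to U(T) with prob u_prob."""
    n = len(lengths)
    if n == 0:
        return []
    maxlen = int(lengths.max())
    mat = _BASES[rng.integers(0, 4, size=(n, maxlen))]
    if u_prob is not None:
        is_u = rng.random(n) < u_prob
        others = np.array(list("ACG"))
        first = np.where(is_u, "T", others[rng.integers(0, 3, size=n)])
        mat[:, 0] = first
    return ["".join(row[:l]) for row, l in zip(mat, lengths)]


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def build_genome(config: SimConfig) -> GenomeAnnotation:
    """Place genes, TE instances and small-RNA loci on the synthetic genome.

    A configurable fraction of each TE class is embedded in gene bodies,
    antisense to the host with probability ``antisense_insertion_prob``;
    the remaining instances are intergenic and kept > 2 kb from any gene so
    they survive the genic-exclusion filter downstream.
    """
    rng = child_rng(config.seed, "genome")
    chrom_sizes = config.chrom_sizes
    chroms = list(chrom_sizes)

    gene_lengths = rng.integers(1500, 2501, size=config.n_genes)
    gene_strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")

    n_genic = int(round(config.n_te_instances * config.genic_te_fraction))
    n_intergenic = config.n_te_instances - n_genic

    # Genic insertions: distinct host genes across all classes.
    total_genic = n_genic * len(config.te_classes)
    if total_genic > config.n_genes:
        raise PlacementError(
            f"{total_genic} genic TE insertions requested but only "
            f"{config.n_genes} genes available"
        )
    host_idx = rng.choice(config.n_genes, size=total_genic, replace=False)

    # Deal each feature kind round-robin across chromosomes (so per-chromosome
    # load is balanced), then interleave the kinds in shuffled order.
    per_chrom: dict[str, list[tuple[str, int]]] = {c: [] for c in chroms}
    def _deal(kind: str, count: int, payload=lambda i: i) -> None:
        for i in range(count):
            per_chrom[chroms[i % len(chroms)]].append((kind, payload(i)))

    _deal("gene", config.n_genes)
    for ci, _cls in enumerate(config.te_classes):
        _deal("te", n_intergenic, payload=lambda i, ci=ci: ci)
    _deal("mirna", config.n_mirna_loci)
    _deal("rrna", config.n_rrna_loci)

    margin = 2000
    gene_rows, te_rows, mirna_rows, rrna_rows = [], [], [], []
    placements: list[tuple[str, str, int]] = []
    for chrom in chroms:
        order = rng.permutation(len(per_chrom[chrom]))
        placements += [(chrom, *per_chrom[chrom][oi]) for oi in order]

    cursors = {c: 0 for c in chroms}
    for chrom, kind, idx in placements:
        gap = int(rng.integers(50, 301))
        cursor = cursors[chrom] + gap
        if kind == "gene":
            start = cursor + margin
            end = start + int(gene_lengths[idx])
            gene_rows.append((chrom, start, end, gene_strands[idx], f"gene{idx:04d}", idx))
            cursor = end + margin
        elif kind == "te":
            length = int(rng.integers(400, 1201))
            cls = config.te_classes[idx]
            te_rows.append((chrom, cursor, cursor + length, rng.choice(["+", "-"]), cls, ""))
            cursor += length
        elif kind == "mirna":
            start = cursor
            mirna_rows.append((chrom, start, start + 80, rng.choice(["+", "-"]), f"mir{idx:03d}"))
            cursor = start + 80
        else:
            length = 1500
            rrna_rows.append((chrom, cursor, cursor + length, rng.choice(["+", "-"]), f"rrna{idx}"))
            cursor += length
        cursors[chrom] = cursor
        if cursor > chrom_sizes[chrom]:
            raise PlacementError(
                f"genome too small: {chrom} needs > {cursor} bp to place "
                f"{config.n_genes} genes (±{margin} bp margins) and "
                f"{config.n_te_instances * len(config.te_classes)} TEs in "
                f"{chrom_sizes[chrom]} bp"
            )

    genes = pd.DataFrame(
        [(c, s, e, st, gid) for c, s, e, st, gid, _ in gene_rows],
        columns=["chrom", "start", "end", "strand", "id"],
    )
    # restore index order gene0000..; placement order was shuffled
    genes = genes.sort_values("id", ignore_index=True)
    genes["expr_weight"] = np.exp(rng.normal(0.0, config.gene_expr_sigma, size=len(genes)))

    # Genic TE insertions inside the selected host genes.
    host_iter = iter(host_idx)
    for cls in config.te_classes:
        for _ in range(n_genic):
            gi = next(host_iter)
            grow = genes.iloc[gi]
            glen = grow.end - grow.start
            tlen = int(rng.integers(400, min(1200, glen - 40) + 1))
            offset = int(rng.integers(20, glen - tlen - 19))
            antis = rng.random() < config.antisense_insertion_prob
            strand = ("-" if grow.strand == "+" else "+") if antis else grow.strand
            te_rows.append((grow.chrom, grow.start + offset, grow.start + offset + tlen,
                            strand, cls, grow.id))

    tes = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "strand", "te_class", "host_gene"])
    tes = tes.sort_values(["te_class", "chrom", "start"], ignore_index=True)
    tes["family"] = tes["te_class"].str.replace("-like", "", regex=False) + "-fam"
    tes["id"] = [f"te{i:05d}" for i in range(len(tes))]

    mirnas = pd.DataFrame(mirna_rows, columns=["chrom", "start", "end", "strand", "id"])
    mirnas["mature_offset"] = rng.integers(10, 49, size=len(mirnas))
    mirnas["mature_length"] = rng.choice([21, 22, 23], size=len(mirnas), p=[0.2, 0.6, 0.2])
    mirnas["weight"] = np.exp(rng.normal(0.0, 1.0, size=len(mirnas)))
    mirnas["mature_sequence"] = _random_sequences(
        rng, mirnas["mature_length"].to_numpy(), u_prob=None
    )
    rrnas = pd.DataFrame(rrna_rows, columns=["chrom", "start", "end", "strand", "id"])

    consensus = {
        cls: "".join(_BASES[rng.integers(0, 4, size=config.consensus_length)])
        for cls in config.te_classes
    }
    # each instance is a window into its class consensus
    tes["consensus_offset"] = rng.integers(0, config.consensus_length - 40, size=len(tes))

    annotation = GenomeAnnotation(
        chrom_sizes=chrom_sizes, genes=genes, tes=tes,
        mirnas=mirnas, rrnas=rrnas, consensus=consensus,
    )
    return annotation


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def simulate_methylome(
    annotation: GenomeAnnotation, config: SimConfig, sample: str, day: int
) -> pd.DataFrame:
    """Per-CpG methylated/unmethylated call counts for one sample/day.

    CpG sites sit on a fixed 1-per-``cpg_spacing`` grid.  Coverage is
    Poisson(``meth_coverage_mean``); methylated calls are Binomial with a
    per-site rate drawn from a Beta centred on the class (or global) mean
    for that day.  Sites with zero coverage are omitted, as in coverage
    files emitted by bisulfite callers.
    """
    if day not in config.timepoints:
        raise ConfigError(f"unknown day {day}; configured timepoints: {list(config.timepoints)}")
    rng = child_rng(config.seed, "methylome", sample, day)

    frames = []
    class_overrides = [c for c in config.meth_means if c != "global"]
    for chrom, size in annotation.chrom_sizes.items():
        pos = np.arange(config.cpg_spacing // 2, size, config.cpg_spacing, dtype=np.int64)
        means = np.full(len(pos), config.meth_mean(None, day))
        for cls in class_overrides:
            sub = annotation.tes[
                (annotation.tes["te_class"] == cls) & (annotation.tes["chrom"] == chrom)
            ].sort_values("start")
            if not len(sub):
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            idx = np.searchsorted(starts, pos, side="right") - 1
            inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
            means[inside] = config.meth_mean(cls, day)

        conc = config.beta_concentration
        rates = means.copy()
        stochastic = (means > 0.0) & (means < 1.0)
        rates[stochastic] = rng.beta(means[stochastic] * conc, (1.0 - means[stochastic]) * conc)
        coverage = rng.poisson(config.meth_coverage_mean, size=len(pos))
        meth = rng.binomial(coverage, rates)
        covered = coverage > 0
        frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": pos[covered],
             "count_meth": meth[covered],
             "count_unmeth": (coverage - meth)[covered]}
        ))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Stranded RNA-seq
# ---------------------------------------------------------------------------

def simulate_rnaseq(
    annotation: GenomeAnnotation, config: SimConfig, sample: str, day: int
) -> pd.DataFrame:
    """Stranded RNA-seq read records for one sample/day.

    Genic reads are emitted on the gene strand at gene-specific rates; TE
    reads on the TE strand at ``te_expr_scale x activation x (1 - methylation
    mean)``.  Read strand equals transcript strand (forward convention).
    """
    if day not in config.timepoints:
        raise ConfigError(f"unknown day {day}; configured timepoints: {list(config.timepoints)}")
    rng = child_rng(config.seed, "rnaseq", sample, day)

    genes, tes = annotation.genes, annotation.tes
    weights = np.concatenate([
        genes["expr_weight"].to_numpy(),
        np.array([config.te_rate(c, day) for c in tes["te_class"]]),
    ])
    chrom = np.concatenate([genes["chrom"], tes["chrom"]])
    fstart = np.concatenate([genes["start"], tes["start"]]).astype(np.int64)
    fend = np.concatenate([genes["end"], tes["end"]]).astype(np.int64)
    strand = np.concatenate([genes["strand"], tes["strand"]])

    total = weights.sum()
    if total <= 0:
        raise ConfigError("all feature expression weights are zero")
    counts = rng.multinomial(config.rnaseq_library_size, weights / total)

    rep = np.repeat(np.arange(len(counts)), counts)
    flen = fend - fstart
    span = np.maximum(flen[rep] - config.read_length, 0)
    offs = (rng.random(len(rep)) * (span + 1)).astype(np.int64)
    starts = fstart[rep] + offs
    ends = np.minimum(starts + config.read_length, fend[rep])

    low = rng.random(len(rep)) < config.low_mapq_fraction
    mapq = np.where(low, rng.integers(0, 20, size=len(rep)), rng.integers(20, 61, size=len(rep)))

    reads = pd.DataFrame(
        {"chrom": chrom[rep], "start": starts, "end": ends,
         "strand": strand[rep], "mapq": mapq, "sample": sample}
    )
    return reads.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Small RNA libraries
# ---------------------------------------------------------------------------

def _sirna_class_weights(annotation: GenomeAnnotation, config: SimConfig, day: int) -> dict[str, float]:
    """siRNA abundance per class scales with sense x antisense transcript product.

    The antisense arm comes from host-gene transcription across antisense
    genic insertions, so it is proportional to the number of such inserts.
    """
    tes = annotation.tes
    genic = tes[tes["host_gene"] != ""]
    host_strand = genic["host_gene"].map(annotation.genes.set_index("id")["strand"])
    antisense = genic[genic["strand"].to_numpy() != host_strand.to_numpy()]
    weights = {}
    for cls in config.te_classes:
        n_anti = int((antisense["te_class"] == cls).sum())
        weights[cls] = config.te_rate(cls, day) * n_anti
    return weights


def simulate_smallrna(
    annotation: GenomeAnnotation, config: SimConfig, sample: str, day: int
) -> pd.DataFrame:
    """AGO2-IP-like small RNA library: miRNAs, an rRNA background, and
    TE-derived duplex siRNAs with configured duplex geometry and 5'-U bias."""
    if day not in config.timepoints:
        raise ConfigError(f"unknown day {day}; configured timepoints: {list(config.timepoints)}")
    rng = child_rng(config.seed, "smallrna", sample, day)

    n = config.smallrna_library_size
    n_mirna, n_rrna, n_rest = rng.multinomial(
        n,
        [config.smallrna_mirna_fraction, config.smallrna_rrna_fraction,
         1.0 - config.smallrna_mirna_fraction - config.smallrna_rrna_fraction],
    )

    cls_w = _sirna_class_weights(annotation, config, day)
    ref_day = max(config.timepoints)
    ref_w = sum(_sirna_class_weights(annotation, config, ref_day).values())
    day_w = sum(cls_w.values())
    scale = (day_w / ref_w) if ref_w > 0 else 0.0
    n_te = min(int(round(n_rest * config.smallrna_te_fraction * scale)), int(n_rest))
    n_duplex = n_te // 2
    n_other = int(n_rest) - 2 * n_duplex

    frames = []

    # -- miRNA reads: fixed mature species per locus --------------------
    if n_mirna and len(annotation.mirnas):
        mir = annotation.mirnas
        p = mir["weight"].to_numpy() / mir["weight"].sum()
        loc = rng.choice(len(mir), size=n_mirna, p=p)
        starts = (mir["start"].to_numpy() + mir["mature_offset"].to_numpy())[loc]
        lengths = mir["mature_length"].to_numpy()[loc]
        frames.append(pd.DataFrame(
            {"chrom": mir["chrom"].to_numpy()[loc], "start": starts,
             "end": starts + lengths, "strand": mir["strand"].to_numpy()[loc],
             "length": lengths,
             "sequence": mir["mature_sequence"].to_numpy()[loc],
             "annotation_class": "miRNA", "cons_id": "", "cons_start": -1}
        ))

    # -- rRNA background -------------------------------------------------
    if n_rrna and len(annotation.rrnas):
        rr = annotation.rrnas
        loc = rng.integers(0, len(rr), size=n_rrna)
        lengths = rng.integers(20, 25, size=n_rrna)
        span = rr["end"].to_numpy()[loc] - rr["start"].to_numpy()[loc] - lengths
        starts = rr["start"].to_numpy()[loc] + (rng.random(n_rrna) * (span + 1)).astype(np.int64)
        frames.append(pd.DataFrame(
            {"chrom": rr["chrom"].to_numpy()[loc], "start": starts,
             "end": starts + lengths,
             "strand": np.where(rng.random(n_rrna) < 0.5, "+", "-"),
             "length": lengths,
             "sequence": _random_sequences(rng, lengths, u_prob=None),
             "annotation_class": "rRNA", "cons_id": "", "cons_start": -1}
        ))

    # -- TE-derived duplex siRNAs ---------------------------------------
    if n_duplex > 0:
        total_w = sum(cls_w.values())
        cls_names = [c for c in config.te_classes if cls_w[c] > 0]
        cls_p = np.array([cls_w[c] / total_w for c in cls_names])
        cls_choice = rng.choice(len(cls_names), size=n_duplex, p=cls_p)
        lens = np.array(sorted(config.sirna_length_dist))
        lprob = np.array([config.sirna_length_dist[l] for l in lens])
        l1 = lens[rng.choice(len(lens), size=n_duplex, p=lprob)]
        l2 = lens[rng.choice(len(lens), size=n_duplex, p=lprob)]
        oh = config.duplex_overhang

        tes = annotation.tes
        for ci, cls in enumerate(cls_names):
            mask = cls_choice == ci
            k = int(mask.sum())
            if k == 0:
                continue
            sub = tes[tes["te_class"] == cls]
            inst = rng.integers(0, len(sub), size=k)
            ts = sub["start"].to_numpy()[inst]
            te_len = (sub["end"].to_numpy() - sub["start"].to_numpy())[inst]
            cl1, cl2 = l1[mask], l2[mask]
            lo = np.maximum(oh, 0)
            hi = te_len - cl1                      # plus-guide start bound (within TE)
            s_off = lo + (rng.random(k) * np.maximum(hi - lo, 1)).astype(np.int64)
            plus_start = ts + s_off
            minus_start = plus_start - oh          # 2-nt 3' overhang on the minus guide
            cons_off = sub["consensus_offset"].to_numpy()[inst]
            cons_pos = (cons_off + s_off) % (config.consensus_length - 40)
            chroms = sub["chrom"].to_numpy()[inst]
            frames.append(pd.DataFrame(
                {"chrom": chroms, "start": plus_start, "end": plus_start + cl1,
                 "strand": "+", "length": cl1,
                 "sequence": _random_sequences(rng, cl1, config.five_prime_u_prob),
                 "annotation_class": f"TE:{cls}", "cons_id": cls, "cons_start": cons_pos}
            ))
            frames.append(pd.DataFrame(
                {"chrom": chroms, "start": minus_start, "end": minus_start + cl2,
                 "strand": "-", "length": cl2,
                 "sequence": _random_sequences(rng, cl2, config.five_prime_u_prob),
                 "annotation_class": f"TE:{cls}", "cons_id": cls,
                 "cons_start": (cons_pos - oh) % (config.consensus_length - 40)}
            ))

    # -- other genome-derived reads (kept clear of annotated repeats) ----
    if n_other > 0:
        blocked = pd.concat([
            annotation.tes[["chrom", "start", "end"]],
            annotation.mirnas[["chrom", "start", "end"]],
            annotation.rrnas[["chrom", "start", "end"]],
        ], ignore_index=True)
        by_chrom = {
            c: (np.sort(sub["start"].to_numpy()), np.sort(sub["end"].to_numpy()))
            for c, sub in blocked.groupby("chrom")
        }
        chroms_arr = np.array(list(annotation.chrom_sizes))
        sizes_arr = np.array([annotation.chrom_sizes[c] for c in chroms_arr])
        picked = {"chrom": [], "start": [], "length": []}
        need = n_other
        while need > 0:
            m = max(2 * need, 64)
            ci = rng.integers(0, len(chroms_arr), size=m)
            lengths = rng.integers(20, 25, size=m)
            starts = (rng.random(m) * (sizes_arr[ci] - lengths)).astype(np.int64)
            ok = np.ones(m, dtype=bool)
            for cname, (bs, be) in by_chrom.items():
                on = chroms_arr[ci] == cname
                n_s = np.searchsorted(bs, starts[on] + lengths[on], side="left")
                n_e = np.searchsorted(be, starts[on], side="right")
                ok[on] &= n_s <= n_e
            take = min(int(ok.sum()), need)
            idx = np.flatnonzero(ok)[:take]
            picked["chrom"].append(chroms_arr[ci[idx]])
            picked["start"].append(starts[idx])
            picked["length"].append(lengths[idx])
            need -= take
        chrom_o = np.concatenate(picked["chrom"])
        start_o = np.concatenate(picked["start"])
        len_o = np.concatenate(picked["length"])
        frames.append(pd.DataFrame(
            {"chrom": chrom_o, "start": start_o, "end": start_o + len_o,
             "strand": np.where(rng.random(n_other) < 0.5, "+", "-"),
             "length": len_o,
             "sequence": _random_sequences(rng, len_o, u_prob=None),
             "annotation_class": "other", "cons_id": "", "cons_start": -1}
        ))

    reads = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "strand", "length", "sequence",
                 "annotation_class", "cons_id", "cons_start"]
    )
    reads["sample"] = sample
    return reads


# ---------------------------------------------------------------------------
# ChIP tile counts
# ---------------------------------------------------------------------------

def simulate_chip(
    annotation: GenomeAnnotation, config: SimConfig, sample: str, mark: str, day: int
) -> pd.DataFrame:
    """Per-1 kb-tile read counts for one mark/sample/day.

    Tiles overlapping a TE class with a configured enrichment multiplier
    draw counts from Poisson(baseline x multiplier); all other tiles use
    the baseline.  Partial terminal tiles are pro-rated by width.
    """
    if mark not in config.chip_enrichment:
        raise ConfigError(
            f"unknown mark {mark!r}; configured marks: {sorted(config.chip_enrichment)}"
        )
    if day not in config.timepoints:
        raise ConfigError(f"unknown day {day}; configured timepoints: {list(config.timepoints)}")
    rng = child_rng(config.seed, "chip", sample, mark, day)

    tiles = tile_genome(annotation.chrom_sizes, config.chip_tile_width)
    mult = np.ones(len(tiles))
    for cls, by_day in config.chip_enrichment[mark].items():
        m = by_day.get(day, 1.0)
        if m == 1.0:
            continue
        sub = annotation.tes[annotation.tes["te_class"] == cls]
        for chrom, csub in sub.groupby("chrom"):
            starts = np.sort(csub["start"].to_numpy())
            ends = np.sort(csub["end"].to_numpy())
            on = (tiles["chrom"] == chrom).to_numpy()
            n = (
                np.searchsorted(starts, tiles.loc[on, "end"].to_numpy(), side="left")
                - np.searchsorted(ends, tiles.loc[on, "start"].to_numpy(), side="right")
            )
            hit = np.flatnonzero(on)[n > 0]
            mult[hit] = np.maximum(mult[hit], m)

    width_frac = (tiles["end"] - tiles["start"]).to_numpy() / config.chip_tile_width
    lam = config.chip_tile_baseline * mult * width_frac
    out = tiles[["chrom", "start", "end", "tile_id"]].copy()
    out["count"] = rng.poisson(lam)
    out["sample"] = sample
    out["mark"] = mark
    return out
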