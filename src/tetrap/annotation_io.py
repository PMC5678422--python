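"""Annotation and read-record I/O, coordinate conventions, and interval filters.

All coordinates are 0-based half-open internally.  BED6 is read/written
natively; GFF3 and Bismark-coverage positions (1-based) are converted on
read and restored on write.  Readers reject malformed records with the
offending line number rather than silently clamping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("tetrap")

STRANDS = {"+", "-"}

GENE_COLUMNS = ["chrom", "start", "end", "strand", "id"]
TE_COLUMNS = ["chrom", "start", "end", "strand", "te_class", "family", "id"]
READ_COLUMNS = ["chrom", "start", "end", "strand", "mapq", "sample"]
METH_COLUMNS = ["chrom", "pos", "count_meth", "count_unmeth"]


class AnnotationError(ValueError):
    """Malformed annotation or read record (carries file/line context)."""


@dataclass
class GenomeAnnotation:
    """Genes, TE instances and small-RNA loci on a common assembly.

    ``genes`` carries one row per gene (chrom, start, end, strand, id, and
    optionally an ``expr_weight`` used by the simulator).  ``tes`` carries
    one row per TE instance with its class/family labels and, for genic
    insertions, the host gene id.  ``mirnas``/``rrnas`` are small-RNA loci
    used by the hierarchical exclusion.  ``consensus`` maps TE class to a
    consensus sequence (plus strand).
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame
    tes: pd.DataFrame
    mirnas: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))
    rrnas: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))
    consensus: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for df, what in ((self.genes, "gene"), (self.tes, "TE")):
            if len(df) == 0:
                continue
            bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
            if len(bad):
                raise AnnotationError(f"{what} records with start >= end or start < 0")
            sizes = df["chrom"].map(self.chrom_sizes)
            if sizes.isna().any():
                raise AnnotationError(f"{what} records on unknown chromosome")
            if (df["end"] > sizes).any():
                raise AnnotationError(f"{what} records extend past chromosome end")
            if not df["strand"].isin(STRANDS).all():
                raise AnnotationError(f"{what} strand must be '+' or '-'")
        if self.genes["id"].duplicated().any() or self.tes["id"].duplicated().any():
            raise AnnotationError("feature ids must be unique")

    @property
    def promoters(self) -> pd.DataFrame:
        """Strand-aware promoters: the 1 kb upstream of each TSS."""
        g = self.genes
        tss = np.where(g["strand"] == "+", g["start"], g["end"])
        start = np.where(g["strand"] == "+", tss - 1000, tss)
        end = np.where(g["strand"] == "+", tss, tss + 1000)
        start = np.maximum(start, 0)
        end = np.minimum(end, g["chrom"].map(self.chrom_sizes).to_numpy())
        return pd.DataFrame(
            {"chrom": g["chrom"], "start": start, "end": end,
             "strand": g["strand"], "id": g["id"] + "_promoter"}
        )


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED6 file into (chrom, start, end, name, score, strand).

    Raises :class:`AnnotationError` with the 1-based line number on any
    malformed or empty-interval record.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise AnnotationError(f"{path}:{lineno}: expected 6 BED fields, got {len(parts)}")
            chrom, start, end, name, score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i < 0 or start_i >= end_i:
                raise AnnotationError(
                    f"{path}:{lineno}: invalid interval [{start_i}, {end_i})"
                )
            if strand not in STRANDS:
                raise AnnotationError(f"{path}:{lineno}: invalid strand {strand!r}")
            rows.append((chrom, start_i, end_i, name, score, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write BED6; accepts any frame with the six BED columns."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    intervals.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def tes_to_bed(tes: pd.DataFrame) -> pd.DataFrame:
    """TE table -> BED6 rows (name = class, score = instance id)."""
    return pd.DataFrame(
        {"chrom": tes["chrom"], "start": tes["start"], "end": tes["end"],
         "name": tes["te_class"], "score": tes["id"], "strand": tes["strand"]}
    )


def bed_to_tes(bed: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": bed["chrom"], "start": bed["start"], "end": bed["end"],
         "strand": bed["strand"], "te_class": bed["name"],
         "family": bed["name"], "id": bed["score"]}
    )


# ---------------------------------------------------------------------------
# GFF3 (genes)
# ---------------------------------------------------------------------------

def write_gff3_genes(genes: pd.DataFrame, path) -> None:
    """Write genes as GFF3 gene features (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\ttetrap\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.id}\n"
            )


def read_gff3_genes(path) -> pd.DataFrame:
    """Read gene features from GFF3, converting to 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GFF3 fields")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i < 1 or end_i < start_i:
                raise AnnotationError(f"{path}:{lineno}: invalid GFF3 span {start_i}-{end_i}")
            if strand not in STRANDS:
                raise AnnotationError(f"{path}:{lineno}: invalid strand {strand!r}")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            rows.append((chrom, start_i - 1, end_i, strand, attr_map.get("ID", f"gene{lineno}")))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


# ---------------------------------------------------------------------------
# Bismark-coverage methylation calls
# ---------------------------------------------------------------------------

def read_bismark_cov(path) -> pd.DataFrame:
    """Read a Bismark-coverage-style file into per-CpG call counts.

    On-disk columns are chrom, start, end (both 1-based, start == end for a
    CpG), percent, count_meth, count_unmeth; positions become 0-based.
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "percent", "count_meth", "count_unmeth"],
        dtype={"chrom": str},
    )
    if len(df) and ((df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any()):
        raise AnnotationError(f"{path}: negative call counts")
    if len(df) and (df["start"] < 1).any():
        raise AnnotationError(f"{path}: positions must be 1-based (>= 1)")
    out = pd.DataFrame(
        {"chrom": df["chrom"], "pos": df["start"] - 1,
         "count_meth": df["count_meth"].astype(np.int64),
         "count_unmeth": df["count_unmeth"].astype(np.int64)}
    )
    return out


def write_bismark_cov(calls: pd.DataFrame, path) -> None:
    cov = calls["count_meth"] + calls["count_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(cov > 0, 100.0 * calls["count_meth"] / cov, 0.0)
    out = pd.DataFrame(
        {"chrom": calls["chrom"], "start": calls["pos"] + 1, "end": calls["pos"] + 1,
         "percent": np.round(percent, 6),
         "count_meth": calls["count_meth"], "count_unmeth": calls["count_unmeth"]}
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Read tables (BED6-like with MAPQ in the score column, sample in name)
# ---------------------------------------------------------------------------

def read_reads_table(path) -> pd.DataFrame:
    bed = read_bed(path)
    try:
        mapq = bed["score"].astype(int)
    except ValueError as exc:
        raise AnnotationError(f"{path}: MAPQ column must be integer") from exc
    if (mapq < 0).any():
        raise AnnotationError(f"{path}: negative MAPQ")
    return pd.DataFrame(
        {"chrom": bed["chrom"], "start": bed["start"], "end": bed["end"],
         "strand": bed["strand"], "mapq": mapq, "sample": bed["name"]}
    )


def write_reads_table(reads: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {"chrom": reads["chrom"], "start": reads["start"], "end": reads["end"],
         "name": reads["sample"], "score": reads["mapq"], "strand": reads["strand"]}
    )
    write_bed(bed, path)


# ---------------------------------------------------------------------------
# FASTA (consensus sequences)
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


# ---------------------------------------------------------------------------
# Annotation-level filters
# ---------------------------------------------------------------------------

def filter_tes_near_genes(
    tes: pd.DataFrame, genes: pd.DataFrame, margin: int = 2000
) -> pd.DataFrame:
    """Drop TE instances intersecting any [gene.start - margin, gene.end + margin).

    The retention boundary is half-open: a TE starting exactly at
    ``gene.end + margin`` is retained.  Input order is preserved.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    if len(tes) == 0:
        return tes.copy()
    keep = np.ones(len(tes), dtype=bool)
    te_chrom = tes["chrom"].to_numpy()
    te_start = tes["start"].to_numpy()
    te_end = tes["end"].to_numpy()
    for chrom, sub in genes.groupby("chrom"):
        zstart = np.sort(np.maximum(sub["start"].to_numpy() - margin, -margin))
        zend_sorted = np.sort(sub["end"].to_numpy() + margin)
        on_chrom = te_chrom == chrom
        # TE intersects some zone iff #(zone starts < te.end) > #(zone ends <= te.start)
        n_start = np.searchsorted(zstart, te_end[on_chrom], side="left")
        n_end = np.searchsorted(zend_sorted, te_start[on_chrom], side="right")
        keep[on_chrom] &= n_start <= n_end
    removed = int((~keep).sum())
    logger.info("filter_tes_near_genes: retained %d, discarded %d (margin %d bp)",
                int(keep.sum()), removed, margin)
    out = tes[keep].copy()
    out.attrs["n_discarded"] = removed
    return out


def tile_genome(chrom_sizes: dict[str, int], width: int = 1000) -> pd.DataFrame:
    """Consecutive non-overlapping tiles per chromosome; terminal partial
    tiles are retained and flagged ``partial``."""
    if width <= 0:
        raise ValueError(f"tile width must be positive, got {width}")
    frames = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, width, dtype=np.int64)
        ends = np.minimum(starts + width, size)
        frames.append(pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends,
             "partial": ends - starts < width}
        ))
    tiles = pd.concat(frames, ignore_index=True)
    tiles["tile_id"] = tiles["chrom"] + ":" + tiles["start"].astype(str)
    return tiles


def count_overlaps(
    reads: pd.DataFrame,
    features: pd.DataFrame,
    min_mapq: int = 20,
    orientation: str = "both",
    id_column: str = "id",
) -> pd.DataFrame:
    """Count reads overlapping each feature, per sample and orientation.

    A read counts toward a feature when their intervals intersect and the
    read MAPQ is >= ``min_mapq``; "sense" means read strand equals feature
    strand.  A read overlapping k features increments all k.  Returns a
    long table (feature, sample, orientation, count) with integer counts;
    for ``orientation='both'`` sense and antisense are summed.
    """
    if orientation not in {"sense", "antisense", "both"}:
        raise ValueError(f"orientation must be sense/antisense/both, got {orientation!r}")
    passing = reads[reads["mapq"] >= min_mapq]
    logger.info("count_overlaps: %d reads retained, %d discarded (MAPQ < %d)",
                len(passing), len(reads) - len(passing), min_mapq)

    samples = sorted(passing["sample"].unique()) if len(passing) else []
    fid = features[id_column].to_numpy()
    n_feat = len(features)
    out_frames = []
    for sample in samples:
        sreads = passing[passing["sample"] == sample]
        sense = np.zeros(n_feat, dtype=np.int64)
        anti = np.zeros(n_feat, dtype=np.int64)
        for (chrom, rstrand), rsub in sreads.groupby(["chrom", "strand"]):
            starts = np.sort(rsub["start"].to_numpy())
            ends = np.sort(rsub["end"].to_numpy())
            on_chrom = (features["chrom"] == chrom).to_numpy()
            if not on_chrom.any():
                continue
            fsub = features[on_chrom]
            n = (
                np.searchsorted(starts, fsub["end"].to_numpy(), side="left")
                - np.searchsorted(ends, fsub["start"].to_numpy(), side="right")
            )
            same = (fsub["strand"] == rstrand).to_numpy()
            idx = np.flatnonzero(on_chrom)
            sense[idx[same]] += n[same]
            anti[idx[~same]] += n[~same]
        if orientation in ("sense", "both"):
            out_frames.append(pd.DataFrame(
                {"feature": fid, "sample": sample, "orientation": "sense", "count": sense}
            ))
        if orientation in ("antisense", "both"):
            out_frames.append(pd.DataFrame(
                {"feature": fid, "sample": sample, "orientation": "antisense", "count": anti}
            ))
    if not out_frames:
        return pd.DataFrame(columns=["feature", "sample", "orientation", "count"])
    out = pd.concat(out_frames, ignore_index=True)
    if orientation == "both":
        out = (
            out.groupby(["feature", "sample"], as_index=False, sort=False)["count"]
            .sum()
            .assign(orientation="both")[["feature", "sample", "orientation", "count"]]
        )
    return out


def pivot_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Long (feature, sample, orientation, count) -> feature x sample matrix."""
    return counts.pivot_table(
        index="feature", columns="sample", values="count", aggfunc="sum", fill_value=0
    )


def write_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False,
                  columns=["feature", "sample", "orientation", "count"])
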