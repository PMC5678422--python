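"""Pipeline orchestration: simulate -> filter -> quantify -> report.

Runs the stages in dependency order against one configuration and seed,
writes interchange files and a machine-readable JSON report (TE-class
Z matrix, pervasive-antisense gene set and proportions, methylation time
course, siRNA signature summary, chromatin flags), and records a run
manifest with the config hash, per-stage outputs and every filter's
discard counts so the filtering cascade is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation_io as aio
from . import antisense as anti
from . import chromatin as chip
from . import methylome as meth
from . import smallrna as sr
from . import te_expression as tex
from .synthetic import (
    SimConfig, build_genome, simulate_chip, simulate_methylome,
    simulate_rnaseq, simulate_smallrna,
)

logger = logging.getLogger("tetrap")

STAGES = ["simulate", "te_expression", "antisense", "methylome", "smallrna", "chip", "report"]


class PipelineError(RuntimeError):
    pass


def _config_hash(config: SimConfig) -> str:
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(
    config: SimConfig,
    outdir: str | Path,
    seed: int | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Execute the requested stages; returns the run manifest.

    Stage order is fixed (simulate first, report last); requesting an
    analysis stage implies the simulation it depends on.  On stage
    failure, partial outputs of that stage are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    if seed is not None:
        config = SimConfig.from_dict({**config.to_dict(), "seed": seed})
    requested = stages or STAGES
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    run = [s for s in STAGES if s in requested or (s == "simulate" and len(requested) > 0)]

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": [],
        "parameters": config.to_dict(),
        "filter_counts": {},
    }
    report: dict = {}

    day0 = min(config.timepoints)
    day_ko = max(config.timepoints)

    state: dict = {}
    for stage in run:
        written: list[Path] = []
        try:
            if stage == "simulate":
                _stage_simulate(config, outdir, state, written)
            elif stage == "te_expression":
                _stage_te_expression(config, outdir, state, report, manifest, written)
            elif stage == "antisense":
                _stage_antisense(config, outdir, state, report, written, day0, day_ko)
            elif stage == "methylome":
                _stage_methylome(config, outdir, state, report, written)
            elif stage == "smallrna":
                _stage_smallrna(config, outdir, state, report, manifest, written, day0, day_ko)
            elif stage == "chip":
                _stage_chip(config, outdir, state, report, written, day0, day_ko)
            elif stage == "report":
                path = outdir / "report.json"
                with open(path, "w") as fh:
                    json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
                written.append(path)
        except PipelineError:
            raise
        except Exception as exc:
            for path in written:
                path.unlink(missing_ok=True)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(
            {"name": stage, "outputs": [str(p.relative_to(outdir)) for p in written]}
        )

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------

def _write(path: Path, writer, written: list[Path]) -> None:
    writer(path)
    written.append(path)


def _stage_simulate(config, outdir, state, written):
    annotation = build_genome(config)
    state["annotation"] = annotation

    _write(outdir / "genes.gff3", lambda p: aio.write_gff3_genes(annotation.genes, p), written)
    _write(outdir / "tes.bed", lambda p: aio.write_bed(aio.tes_to_bed(annotation.tes), p), written)
    _write(outdir / "consensus.fa", lambda p: aio.write_fasta(annotation.consensus, p), written)
    for name, df in (("mirnas", annotation.mirnas), ("rrnas", annotation.rrnas)):
        bed = pd.DataFrame({"chrom": df["chrom"], "start": df["start"], "end": df["end"],
                            "name": df["id"], "score": 0, "strand": df["strand"]})
        _write(outdir / f"{name}.bed", lambda p, b=bed: aio.write_bed(b, p), written)

    day0, day_ko = min(config.timepoints), max(config.timepoints)
    rna = {}
    for day in (day0, day_ko):
        for rep in range(1, config.rnaseq_replicates + 1):
            sample = f"rna_d{day}_r{rep}"
            rna[sample] = simulate_rnaseq(annotation, config, sample, day)
            _write(outdir / f"{sample}.reads.bed",
                   lambda p, r=rna[sample]: aio.write_reads_table(r, p), written)
    state["rna"] = rna
    state["rna_days"] = {s: (day0 if f"_d{day0}_" in s else day_ko) for s in rna}

    meths = {}
    for day in config.timepoints:
        sample = f"meth_d{day}"
        meths[sample] = simulate_methylome(annotation, config, sample, day)
        _write(outdir / f"{sample}.cov", lambda p, c=meths[sample]: aio.write_bismark_cov(c, p), written)
    state["meth"] = meths

    srna = {}
    for day in (day0, day_ko):
        for rep in range(1, config.smallrna_replicates + 1):
            sample = f"sr_d{day}_r{rep}"
            srna[sample] = simulate_smallrna(annotation, config, sample, day)
            _write(outdir / f"{sample}.smallrna.tsv",
                   lambda p, r=srna[sample]: r.to_csv(p, sep="\t", index=False), written)
    state["smallrna"] = srna

    chips = {}
    for mark in config.chip_enrichment:
        for day in (day0, day_ko):
            sample = f"{mark}_d{day}"
            chips[sample] = simulate_chip(annotation, config, sample, mark, day)
            _write(outdir / f"{sample}.tiles.tsv",
                   lambda p, c=chips[sample]: c.to_csv(p, sep="\t", index=False), written)
    state["chip"] = chips


def _require(state, key, stage):
    if key not in state:
        raise PipelineError(f"stage {stage!r} requires the simulate stage first")
    return state[key]


def _filtered_tes(config, state, manifest):
    if "filtered_tes" not in state:
        annotation = state["annotation"]
        filtered = aio.filter_tes_near_genes(annotation.tes, annotation.genes, margin=2000)
        state["filtered_tes"] = filtered
        manifest["filter_counts"]["te_genic_exclusion"] = {
            "input": len(annotation.tes),
            "retained": len(filtered),
            "discarded": filtered.attrs.get("n_discarded", 0),
        }
    return state["filtered_tes"]


def _stage_te_expression(config, outdir, state, report, manifest, written):
    annotation = _require(state, "annotation", "te_expression")
    rna = state["rna"]
    filtered = _filtered_tes(config, state, manifest)
    reads = pd.concat(rna.values(), ignore_index=True)
    n_pass = int((reads["mapq"] >= 20).sum())
    manifest["filter_counts"]["rnaseq_mapq"] = {
        "input": len(reads), "retained": n_pass, "discarded": len(reads) - n_pass,
    }
    counts = aio.count_overlaps(reads, filtered, min_mapq=20, orientation="both")
    counts_so = aio.count_overlaps(reads, filtered, min_mapq=20, orientation="sense")
    counts_as = aio.count_overlaps(reads, filtered, min_mapq=20, orientation="antisense")
    long = pd.concat([counts_so, counts_as], ignore_index=True)
    _write(outdir / "te_counts.tsv", lambda p: aio.write_count_table(long, p), written)

    class_counts, class_lengths, retention = tex.summarize_te_classes(long, filtered)
    library_sizes = {s: int((r["mapq"] >= 20).sum()) for s, r in rna.items()}
    log2rpm = tex.class_log2_rpm_matrix(class_counts, class_lengths, library_sizes,
                                        orientation="sense")
    z, constant = tex.zscore_by_class(log2rpm)
    day0, day_ko = min(config.timepoints), max(config.timepoints)
    groups = {
        "KO": [s for s, d in state["rna_days"].items() if d == day_ko],
        "WT": [s for s, d in state["rna_days"].items() if d == day0],
    }
    diff = tex.differential_te(log2rpm, groups)

    _write(outdir / "te_log2rpm.tsv", lambda p: log2rpm.to_csv(p, sep="\t"), written)
    _write(outdir / "te_zscores.tsv", lambda p: z.to_csv(p, sep="\t"), written)
    _write(outdir / "te_differential.json",
           lambda p: p.write_text(json.dumps(_jsonable(diff.reset_index().to_dict("records")), indent=1)),
           written)
    report["te_expression"] = {
        "zscores": z, "log2_rpm": log2rpm, "constant_classes": constant,
        "differential": diff[["p_value", "q_value", "direction", "significant"]],
        "class_lengths": class_lengths,
    }
    state["te_counts"] = {"both": counts, "sense": counts_so, "antisense": counts_as}


def _stage_antisense(config, outdir, state, report, written, day0, day_ko):
    annotation = _require(state, "annotation", "antisense")
    rna = state["rna"]
    reads = pd.concat(rna.values(), ignore_index=True)
    counts = aio.count_overlaps(reads, annotation.genes, min_mapq=20, orientation="both")
    long = pd.concat([
        aio.count_overlaps(reads, annotation.genes, min_mapq=20, orientation="sense"),
        aio.count_overlaps(reads, annotation.genes, min_mapq=20, orientation="antisense"),
    ], ignore_index=True)

    ko_samples = [s for s, d in state["rna_days"].items() if d == day_ko]
    wt_samples = [s for s, d in state["rna_days"].items() if d == day0]
    ko_counts = anti.gene_orientation_counts(long, ko_samples)
    wt_counts = anti.gene_orientation_counts(long, wt_samples)

    p0 = anti.global_antisense_proportion(ko_counts)
    binom = anti.binomial_antisense_test(ko_counts, p0)
    library_sizes = {s: int((r["mapq"] >= 20).sum()) for s, r in rna.items()}
    rpm = anti.antisense_rpm(long, library_sizes)
    diff = anti.differential_antisense(rpm, wt_samples, ko_samples)
    summary = anti.antisense_gene_set(binom, diff, ko_counts=ko_counts, wt_counts=wt_counts)

    _write(outdir / "antisense_results.tsv", lambda p: binom.to_csv(p, sep="\t", index=False), written)
    _write(outdir / "antisense_summary.json",
           lambda p: p.write_text(json.dumps(_jsonable(summary.to_dict()), indent=1)), written)
    report["antisense"] = summary.to_dict()
    state["gene_counts_long"] = long


def _stage_methylome(config, outdir, state, report, written):
    meths = _require(state, "meth", "methylome")
    annotation = state["annotation"]
    windows = {s: meth.window_methylation(c) for s, c in meths.items()}
    course = {s: float(w["percent_methylation"].mean()) for s, w in windows.items()}
    comparisons = meth.compare_methylomes(
        {s: w["percent_methylation"] for s, w in windows.items()}
    )
    filtered = state.get("filtered_tes", annotation.tes)
    class_meth = meth.te_class_methylation(meths, filtered)

    for s, w in windows.items():
        _write(outdir / f"{s}.windows.tsv", lambda p, ww=w: ww.to_csv(p, sep="\t", index=False), written)
    _write(outdir / "te_class_methylation.tsv", lambda p: class_meth.to_csv(p, sep="\t"), written)
    report["methylome"] = {
        "window_means": course,
        "te_class_percent": class_meth,
        "comparisons": [
            {"pair": list(c.pair), "statistic": c.statistic, "p_value": c.p_value,
             "p_bonferroni": c.p_bonferroni, "significant": c.significant}
            for c in comparisons
        ],
    }


def _stage_smallrna(config, outdir, state, report, manifest, written, day0, day_ko):
    annotation = _require(state, "annotation", "smallrna")
    libs = state["smallrna"]
    ko_samples = [s for s in libs if f"_d{day_ko}_" in s]

    filtered = {}
    for s, reads in libs.items():
        kept = sr.filter_by_length(reads)
        filtered[s] = kept
    manifest["filter_counts"]["smallrna_length"] = {
        "input": sum(len(r) for r in libs.values()),
        "retained": sum(len(r) for r in filtered.values()),
        "discarded": sum(len(libs[s]) - len(filtered[s]) for s in libs),
    }

    # composition + signature on the pooled KO-day library
    pooled = pd.concat([filtered[s] for s in ko_samples], ignore_index=True)
    binned = sr.hierarchical_exclusion(pooled, annotation.rrnas, annotation.mirnas, annotation.tes)
    composition = binned["bin"].value_counts(normalize=True).to_dict()
    non_mirna = binned[~binned["bin"].isin(["miRNA", "rRNA"])]
    te_fraction_of_rest = float((non_mirna["bin"] == "repeat").mean()) if len(non_mirna) else float("nan")

    te_reads = binned[binned["bin"] == "repeat"]
    signature = sr.overlap_signature(te_reads)
    ldist = sr.length_strand_distribution(te_reads)
    comp5 = sr.five_prime_composition(te_reads) if len(te_reads) else {}

    rpm = sr.class_rpm(filtered, annotation.tes)
    wt_group = [s for s in libs if f"_d{day0}_" in s]
    tests = sr.te_class_smallrna(rpm, ko_samples, wt_group) if (
        len(ko_samples) >= 2 and len(wt_group) >= 2
    ) else None

    _write(outdir / "smallrna_signature.json", lambda p: p.write_text(json.dumps(_jsonable({
        "overlap_counts": signature.counts, "overlap_zscores": signature.zscores,
        "overlap_mode": signature.mode, "n_pairs": signature.n_pairs,
        "five_prime_composition": comp5,
        "length_mode": int(ldist.sum(axis=1).idxmax()) if len(ldist) else None,
        "composition": composition, "te_fraction_of_rest": te_fraction_of_rest,
    }), indent=1)), written)
    _write(outdir / "smallrna_class_rpm.tsv", lambda p: rpm.to_csv(p, sep="\t"), written)

    report["smallrna"] = {
        "overlap_mode": signature.mode,
        "overlap_zscore_at_mode": signature.zscores.get(signature.mode) if signature.mode else None,
        "length_mode": int(ldist.sum(axis=1).idxmax()) if len(ldist) else None,
        "five_prime_u_fraction": comp5.get("U"),
        "mirna_fraction": composition.get("miRNA", 0.0),
        "te_fraction_of_rest": te_fraction_of_rest,
        "class_tests": tests[["p_value", "stars", "significant"]] if tests is not None else None,
    }


def _stage_chip(config, outdir, state, report, written, day0, day_ko):
    annotation = _require(state, "annotation", "chip")
    chips = state["chip"]
    filtered = state.get("filtered_tes", annotation.tes)
    genome_length = sum(annotation.chrom_sizes.values())
    flags = {}
    for mark in config.chip_enrichment:
        wt, ko = f"{mark}_d{day0}", f"{mark}_d{day_ko}"
        enr = {
            s: chip.tile_log2_obs_exp(chips[s], genome_length=genome_length)
            for s in (wt, ko)
        }
        table = chip.te_class_chip_enrichment(enr, filtered, wt_sample=wt)
        _write(outdir / f"chip_{mark}.tsv", lambda p, t=table: t.to_csv(p, sep="\t"), written)
        flags[mark] = {
            "flagged": list(table.index[table[f"flag_{ko}_vs_{wt}"]]),
            "fold": table[f"fold_{ko}_vs_{wt}"].to_dict(),
        }
    report["chromatin"] = flags
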