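"""Generator contracts: placement, reproducibility, parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tetrap import (
    ConfigError, PlacementError, SimConfig, build_genome, simulate_chip,
    simulate_methylome, simulate_rnaseq, simulate_smallrna,
)

from conftest import SMALL


def clopper_pearson(k, n, conf=0.99):
    """Exact binomial confidence interval, independent of the generator."""
    alpha = 1 - conf
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return lo, hi


def antisense_genic(annotation):
    genic = annotation.tes[annotation.tes["host_gene"] != ""]
    host = genic["host_gene"].map(annotation.genes.set_index("id")["strand"])
    return genic, genic["strand"].to_numpy() != host.to_numpy()


class TestConfig:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ConfigError, match="five_prime_u_prob"):
            SimConfig(five_prime_u_prob=1.4)

    def test_length_distribution_mass(self):
        with pytest.raises(ConfigError, match="sirna_length_dist"):
            SimConfig(sirna_length_dist={22: 0.5, 21: 0.4})

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({"n_genes": 17, "te_activation": {"IAP-like": {3: 9.0}}}))
        cfg = SimConfig.from_yaml(path)
        assert cfg.n_genes == 17
        assert cfg.te_activation["IAP-like"][3] == 9.0
        assert cfg.te_activation["IAP-like"][6] == 10.0  # other defaults preserved


class TestGenomePlacement:
    def test_genes_disjoint_and_features_in_bounds(self, small_annotation, small_config):
        genes = small_annotation.genes.sort_values(["chrom", "start"])
        for _, sub in genes.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()
        for df in (small_annotation.genes, small_annotation.tes):
            assert (df["start"] >= 0).all()
            sizes = df["chrom"].map(small_annotation.chrom_sizes)
            assert (df["end"] <= sizes).all()

    def test_intergenic_tes_clear_of_genes(self, small_annotation):
        from tetrap import filter_tes_near_genes
        inter = small_annotation.tes[small_annotation.tes["host_gene"] == ""]
        kept = filter_tes_near_genes(inter, small_annotation.genes, margin=2000)
        assert len(kept) == len(inter)

    def test_forced_antisense_orientation(self):
        cfg = SimConfig.from_dict({**SMALL, "antisense_insertion_prob": 1.0})
        ann = build_genome(cfg)
        genic, is_anti = antisense_genic(ann)
        assert len(genic) > 0 and is_anti.all()

    def test_reproducible_and_seed_sensitive(self):
        a = build_genome(SimConfig.from_dict({**SMALL, "seed": 7}))
        b = build_genome(SimConfig.from_dict({**SMALL, "seed": 7}))
        c = build_genome(SimConfig.from_dict({**SMALL, "seed": 8}))
        pd.testing.assert_frame_equal(a.tes, b.tes)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        assert not a.tes["start"].equals(c.tes["start"])

    def test_antisense_fraction_within_exact_binomial_ci(self):
        cfg = SimConfig(seed=1)
        ann = build_genome(cfg)
        genic, is_anti = antisense_genic(ann)
        lo, hi = clopper_pearson(int(is_anti.sum()), len(genic))
        assert lo <= cfg.antisense_insertion_prob <= hi

    def test_placement_failure_names_constraint(self):
        with pytest.raises(PlacementError, match="genome too small"):
            build_genome(SimConfig.from_dict({**SMALL, "genome_length": 50_000}))


class TestMethylome:
    def test_degenerate_all_methylated(self, small_annotation):
        cfg = SimConfig.from_dict({**SMALL, "meth_means": {
            "global": {0: 1.0, 3: 1.0, 6: 1.0, 9: 1.0},
            "IAP-like": {0: 1.0, 3: 1.0, 6: 1.0, 9: 1.0}}})
        calls = simulate_methylome(small_annotation, cfg, "s", 0)
        assert (calls["count_unmeth"] == 0).all()
        assert calls["count_meth"].sum() > 0

    def test_degenerate_all_unmethylated(self, small_annotation):
        cfg = SimConfig.from_dict({**SMALL, "meth_means": {
            "global": {0: 0.0, 3: 0.0, 6: 0.0, 9: 0.0},
            "IAP-like": {0: 0.0, 3: 0.0, 6: 0.0, 9: 0.0}}})
        calls = simulate_methylome(small_annotation, cfg, "s", 0)
        assert (calls["count_meth"] == 0).all()

    def test_unknown_day_lists_timepoints(self, small_annotation, small_config):
        with pytest.raises(ConfigError, match="timepoints"):
            simulate_methylome(small_annotation, small_config, "s", 4)

    def test_day0_site_rate_recovers_configured_mean(self):
        """Monte-Carlo check against the configured day-0 mean (within 1.5 pts)."""
        cfg = SimConfig(seed=5)
        ann = build_genome(cfg)
        calls = simulate_methylome(ann, cfg, "s", 0)
        assert len(calls) >= 15_000
        rate = calls["count_meth"].sum() / (calls["count_meth"] + calls["count_unmeth"]).sum()
        # pooled-call mean sits above 0.85 because IAP-like CpGs are offset
        expected = 0.85
        assert abs(100 * rate - 100 * expected) < 2.5


class TestRnaSeq:
    def test_zero_activation_silences_tes(self, small_annotation):
        acts = {c: {d: 0.0 for d in (0, 3, 6, 9)} for c in SimConfig().te_classes}
        cfg = SimConfig.from_dict({**SMALL, "te_activation": acts})
        reads = simulate_rnaseq(small_annotation, cfg, "s", 9)
        # all reads must start inside a gene and be on the gene strand
        for chrom, sub in reads.groupby("chrom"):
            genes = small_annotation.genes[small_annotation.genes["chrom"] == chrom]
            starts = np.sort(genes["start"].to_numpy())
            order = np.argsort(genes["start"].to_numpy())
            ends = genes["end"].to_numpy()[order]
            strands = genes["strand"].to_numpy()[order]
            idx = np.searchsorted(starts, sub["start"].to_numpy(), side="right") - 1
            assert (idx >= 0).all()
            assert (sub["start"].to_numpy() < ends[idx]).all()
            assert (sub["strand"].to_numpy() == strands[idx]).all()

    def test_antisense_te_gene_gets_both_strands(self):
        cfg = SimConfig.from_dict({**SMALL, "antisense_insertion_prob": 1.0})
        ann = build_genome(cfg)
        genic, is_anti = antisense_genic(ann)
        te = genic[is_anti].iloc[0]
        gene = ann.genes.set_index("id").loc[te["host_gene"]]
        reads = simulate_rnaseq(ann, cfg, "s", 9)
        over = reads[(reads["chrom"] == gene["chrom"])
                     & (reads["start"] < gene["end"]) & (reads["end"] > gene["start"])]
        assert set(over["strand"]) == {"+", "-"}

    def test_library_size_conserved_and_in_bounds(self, small_annotation, small_config):
        reads = simulate_rnaseq(small_annotation, small_config, "s", 3)
        assert len(reads) == small_config.rnaseq_library_size
        sizes = reads["chrom"].map(small_annotation.chrom_sizes)
        assert (reads["start"] >= 0).all() and (reads["end"] <= sizes).all()

    def test_activation_ratio_recovered(self):
        """Day-9 vs day-0 IAP-like read counts match the configured rate ratio."""
        cfg = SimConfig(seed=2)
        ann = build_genome(cfg)
        # intergenic instances only: genic ones also see host-gene reads
        iap = ann.tes[(ann.tes["te_class"] == "IAP-like") & (ann.tes["host_gene"] == "")]

        def iap_reads(day):
            reads = simulate_rnaseq(ann, cfg, f"d{day}", day)
            n = 0
            for te in iap.itertuples(index=False):
                n += int(((reads["chrom"] == te.chrom) & (reads["start"] >= te.start)
                          & (reads["start"] < te.end) & (reads["strand"] == te.strand)).sum())
            return n

        n9 = iap_reads(9)
        # configured expectation: per-read rate ratio scaled by total weight
        w9 = cfg.te_rate("IAP-like", 9)
        assert w9 > 0 and n9 > 200  # activated class is strongly expressed at day 9
        n0 = iap_reads(0)
        assert n0 == 0  # fully methylated at day 0 -> silent under the linear coupling


class TestSmallRna:
    def test_zero_activation_means_no_sirnas(self, small_annotation):
        acts = {c: {d: 0.0 for d in (0, 3, 6, 9)} for c in SimConfig().te_classes}
        cfg = SimConfig.from_dict({**SMALL, "te_activation": acts})
        reads = simulate_smallrna(small_annotation, cfg, "s", 9)
        assert not reads["annotation_class"].str.startswith("TE:").any()

    def test_duplex_geometry_without_overhang(self, small_annotation):
        cfg = SimConfig.from_dict({**SMALL, "duplex_overhang": 0,
                                   "sirna_length_dist": {22: 1.0}})
        reads = simulate_smallrna(small_annotation, cfg, "s", 9)
        te = reads[reads["annotation_class"].str.startswith("TE:")]
        plus = te[te["strand"] == "+"].reset_index()
        minus = te[te["strand"] == "-"].reset_index()
        assert len(plus) == len(minus) > 0
        # with no overhang the guides coincide: 5'-5' overlap = 22 for each pair
        overlap = (minus["end"] - 1) - plus["start"] + 1
        assert (overlap == 22).all()

    def test_five_prime_u_within_exact_binomial_ci(self):
        from conftest import SMALL as S
        cfg = SimConfig.from_dict({**S, "seed": 3})
        ann = build_genome(cfg)
        reads = simulate_smallrna(ann, cfg, "s", 9)
        te = reads[reads["annotation_class"].str.startswith("TE:")]
        k = int((te["sequence"].str[0] == "T").sum())
        lo, hi = clopper_pearson(k, len(te))
        assert lo <= cfg.five_prime_u_prob <= hi

    def test_library_size_conserved(self, small_annotation, small_config):
        reads = simulate_smallrna(small_annotation, small_config, "s", 9)
        assert len(reads) == small_config.smallrna_library_size
        assert (reads["length"] == reads["sequence"].str.len()).all()


class TestChip:
    def test_unknown_mark_rejected(self, small_annotation, small_config):
        with pytest.raises(ConfigError, match="unknown mark"):
            simulate_chip(small_annotation, small_config, "s", "H3K4me3", 0)

    def test_reproducibility(self, small_annotation, small_config):
        a = simulate_chip(small_annotation, small_config, "s", "H3K9me3", 0)
        b = simulate_chip(small_annotation, small_config, "s", "H3K9me3", 0)
        pd.testing.assert_frame_equal(a, b)

    def test_configured_enrichment_ratio_recovered(self):
        cfg = SimConfig.from_dict({**SMALL, "chip_enrichment": {
            "m": {"IAP-like": {0: 1.0, 3: 1.0, 6: 1.0, 9: 2.0}}}})
        ann = build_genome(cfg)
        tiles = simulate_chip(ann, cfg, "s", "m", 9)
        iap = ann.tes[ann.tes["te_class"] == "IAP-like"]
        from tetrap.chromatin import _tiles_overlapping
        hit = _tiles_overlapping(tiles, iap)
        ratio = tiles.loc[hit, "count"].mean() / tiles.loc[~hit, "count"].mean()
        assert ratio == pytest.approx(2.0, rel=0.15)
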