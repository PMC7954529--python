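"""Genic assignment hierarchy, counting, usage fractions, filters."""

import numpy as np
import pandas as pd
import pytest

from apakit.genes import GeneModel
from apakit.quantify import (apply_filters, assign_genic_location,
                             classify_species_specific, count_reads,
                             mean_usage_by_species, usage_fractions)


def cat_row(pas_id, apex, strand="+", contig="c1"):
    return dict(pas_id=pas_id, contig_a=contig, strand_a=strand, apex_a=apex,
                start_a=max(0, apex - 100), end_a=apex + 101,
                contig_b=contig, strand_b=strand, apex_b=apex,
                start_b=max(0, apex - 100), end_b=apex + 101)


@pytest.fixture()
def two_genes():
    # gene A: + strand 1000-5500 with 3' UTR 3700-5500
    ga = GeneModel("gA", "c1", "+", 1000, 5500,
                   exons=[(1000, 1700), (3200, 5500)],
                   cds=[(1300, 1700), (3200, 3700)],
                   utr5=[(1000, 1300)], utr3=[(3700, 5500)])
    # gene B overlaps gene A's UTR with an intron
    gb = GeneModel("gB", "c1", "+", 3000, 9000,
                   exons=[(3000, 3600), (8000, 9000)],
                   cds=[(3300, 3600), (8000, 8300)],
                   utr5=[(3000, 3300)], utr3=[(8300, 9000)])
    return [ga, gb]


class TestHierarchy:
    def test_utr3_beats_intron_of_other_gene(self, two_genes):
        cat = pd.DataFrame([cat_row("p1", 4000)])   # gA utr3, gB intron
        out = assign_genic_location(cat, two_genes)
        assert out.iloc[0][["gene_id", "location"]].tolist() == ["gA", "utr3"]

    def test_downstream_window_is_end(self, two_genes):
        cat = pd.DataFrame([cat_row("p1", 10_500)])  # 1.5 kb past gB end
        out = assign_genic_location(cat, two_genes)
        assert out.iloc[0][["gene_id", "location"]].tolist() == ["gB", "end"]

    def test_intergenic_far_from_genes_unassigned(self, two_genes):
        cat = pd.DataFrame([cat_row("p1", 50_000)])
        out = assign_genic_location(cat, two_genes)
        assert len(out) == 0

    def test_strand_mismatch_not_assigned(self, two_genes):
        cat = pd.DataFrame([cat_row("p1", 4000, strand="-")])
        out = assign_genic_location(cat, two_genes)
        assert len(out) == 0

    def test_utr5_beats_intron_of_other_gene(self, two_genes):
        cat = pd.DataFrame([cat_row("p1", 3100)])   # gB utr5, gA intron
        out = assign_genic_location(cat, two_genes)
        assert out.iloc[0][["gene_id", "location"]].tolist() == ["gB", "utr5"]

    def test_same_priority_overlap_resolves_to_nearer_tx_end(self, two_genes):
        # apex 3400 is CDS in both genes; gA's transcript end is nearer
        cat = pd.DataFrame([cat_row("p1", 3400)])
        out = assign_genic_location(cat, two_genes)
        assert out.iloc[0][["gene_id", "location"]].tolist() == ["gA", "cds"]

    def test_every_assigned_apex_has_exactly_one_row(self, small_result,
                                                     small_dataset):
        ass = small_result.assignments
        assert ass["pas_id"].is_unique
        # recovered locations should mirror the planted mix
        from apakit.pipeline import match_catalog_to_truth
        m = match_catalog_to_truth(small_result.catalog, small_dataset.truth.pas)
        merged = m.dropna(subset=["matched_pas_id"]).merge(
            ass, left_on="matched_pas_id", right_on="pas_id")
        agree = (merged["location_x"] == merged["location_y"]).mean()
        assert agree > 0.9


class TestCounting:
    def test_reads_at_apex_counted(self, two_genes):
        cat = pd.DataFrame([cat_row("p1", 4000)])
        ass = assign_genic_location(cat, two_genes)
        reads = pd.DataFrame({"contig": "c1", "pos": [4000] * 50,
                              "strand": "+", "sample": "a1", "species": "a"})
        counts = count_reads(cat, reads, ass)
        assert counts.loc["p1", "a1"] == 50

    def test_opposite_strand_read_not_counted(self, two_genes):
        cat = pd.DataFrame([cat_row("p1", 4000)])
        ass = assign_genic_location(cat, two_genes)
        reads = pd.DataFrame({"contig": "c1", "pos": [4000, 4001],
                              "strand": ["-", "+"], "sample": "a1",
                              "species": "a"})
        counts = count_reads(cat, reads, ass)
        assert counts.loc["p1", "a1"] == 1

    def test_total_counted_bounded_by_input(self, small_result):
        assert small_result.counts.to_numpy().sum() <= len(small_result.kept_reads)

    def test_overlapping_regions_same_gene_are_trimmed(self, two_genes):
        cat = pd.DataFrame([cat_row("p1", 4000), cat_row("p2", 4120)])
        ass = assign_genic_location(cat, two_genes)   # both gA utr3
        assert set(ass["gene_id"]) == {"gA"}
        reads = pd.DataFrame({"contig": "c1", "pos": [4055, 4070],
                              "strand": "+", "sample": "a1", "species": "a"})
        counts = count_reads(cat, reads, ass)
        # midpoint 4060: one read below, one above — each counted once
        assert counts["a1"].sum() == 2
        assert counts.loc["p1", "a1"] == 1 and counts.loc["p2", "a1"] == 1


class TestUsage:
    def test_fractions(self):
        counts = pd.DataFrame({"s1": [80, 20]}, index=["p1", "p2"])
        g = pd.Series(["g", "g"], index=["p1", "p2"])
        u = usage_fractions(counts, g)
        assert u["s1"].tolist() == [0.8, 0.2]

    def test_single_pas_gene_usage_one(self):
        counts = pd.DataFrame({"s1": [7], "s2": [0]}, index=["p1"])
        g = pd.Series(["g"], index=["p1"])
        u = usage_fractions(counts, g)
        assert u.loc["p1", "s1"] == 1.0
        assert np.isnan(u.loc["p1", "s2"])   # zero total -> missing, not 0

    def test_usage_sums_to_one_per_gene_sample(self, small_result):
        u, g = small_result.quant.usage, small_result.quant.pas2gene
        sums = u.groupby(g).sum(min_count=1)
        valid = sums.stack().dropna()
        assert np.allclose(valid, 1.0, atol=1e-9)


class TestFilters:
    def _world(self):
        # 4 samples (2 per species); gene g1 two PAS, gene g2 one PAS
        counts = pd.DataFrame({
            "a1": [94, 6, 900], "a2": [94, 6, 900],
            "b1": [100, 0, 900], "b2": [100, 0, 900],
        }, index=["p1", "p2", "p3"])
        g = pd.Series(["g1", "g1", "g2"], index=counts.index)
        sp = pd.Series(["a", "a", "b", "b"], index=counts.columns)
        return counts, g, sp

    def test_low_usage_in_one_species_only_is_retained(self):
        counts, g, sp = self._world()
        out = apply_filters(counts, g, sp, cpm_min_samples=4)
        assert "p2" in out.counts.index   # 6% in A, 0% in B -> kept

    def test_low_usage_in_both_species_dropped(self):
        counts, g, sp = self._world()
        counts.loc["p2"] = [3, 3, 3, 3]   # 3% both species
        out = apply_filters(counts, g, sp, cpm_min_samples=4)
        assert "p2" in out.dropped_low_usage
        # usage recomputed over survivors still sums to 1
        sums = out.usage.groupby(out.pas2gene).sum(min_count=1).stack().dropna()
        assert np.allclose(sums, 1.0)

    def test_cpm_filter_drops_lowly_expressed_gene(self):
        # gene with 1 read/sample in a 1M-read library: log2 CPM ~ 0.6 < 2
        counts = pd.DataFrame({
            "a1": [1, 999_999], "b1": [1, 999_999],
        }, index=["p1", "p2"])
        g = pd.Series(["g1", "g2"], index=counts.index)
        sp = pd.Series(["a", "b"], index=counts.columns)
        out = apply_filters(counts, g, sp, cpm_min_samples=1)
        assert "p1" in out.dropped_low_expression
        assert "p2" in out.counts.index

    def test_invalid_min_samples(self):
        counts, g, sp = self._world()
        with pytest.raises(ValueError):
            apply_filters(counts, g, sp, cpm_min_samples=10)


class TestSpeciesSpecific:
    def _usage(self, a, b):
        u = pd.DataFrame({"a1": [a], "a2": [a], "b1": [b], "b2": [b]},
                         index=["p1"])
        sp = pd.Series(["a", "a", "b", "b"], index=u.columns)
        return u, sp

    def test_five_percent_and_zero_is_specific(self):
        u, sp = self._usage(0.10, 0.0)
        assert classify_species_specific(u, sp)["p1"] == "a_specific"

    def test_nonzero_other_species_is_shared(self):
        u, sp = self._usage(0.10, 0.01)
        assert classify_species_specific(u, sp)["p1"] == "shared"

    def test_planted_specific_sites_recovered(self, small_dataset, small_result):
        truth = small_dataset.truth.pas
        planted = truth[truth["species_specific"] != "none"]
        if len(planted) == 0:
            pytest.skip("no species-specific PAS planted at this seed")
        from apakit.pipeline import match_catalog_to_truth
        m = match_catalog_to_truth(small_result.catalog, truth)
        labels = small_result.species_specific
        hits = 0
        for _, r in planted.iterrows():
            pid = r["matched_pas_id"] if "matched_pas_id" in r else None
        m = m.set_index("pas_id")
        for pid, r in m.loc[planted["pas_id"]].iterrows():
            cid = r["matched_pas_id"]
            if cid is not None and cid in labels.index:
                expect = f"{r['species_specific']}_specific"
                hits += labels[cid] == expect
        assert hits >= 0.5 * len(planted)
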