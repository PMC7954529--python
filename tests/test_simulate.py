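"""Synthetic-data generator: determinism, planted structure, disk round trip."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apakit.genes import GeneModel
from apakit.mispriming import is_misprimed, upstream_window
from apakit.simulate import (SimConfig, build_misprime_index,
                             generate_gene_models, generate_genome_pair,
                             plant_apa_truth, read_dataset, simulate_dataset,
                             simulate_reads, write_dataset)


def test_zero_divergence_gives_identical_sequences():
    pair = generate_genome_pair(1, 20_000, divergence_rate=0.0,
                                n_rearranged_blocks=0, seed=1)
    assert pair.sequences_a == pair.sequences_b
    assert len(pair.block_map_ab) == 1
    b = pair.block_map_ab.blocks[0]
    assert (b.start_a, b.end_a) == (b.start_b, b.end_b) == (0, 20_000)


def test_generator_is_deterministic():
    a = generate_genome_pair(2, 15_000, 0.01, 3, seed=42)
    b = generate_genome_pair(2, 15_000, 0.01, 3, seed=42)
    assert a.sequences_a == b.sequences_a
    assert a.sequences_b == b.sequences_b
    assert [vars(x) for x in a.block_map_ab.blocks] == \
        [vars(x) for x in b.block_map_ab.blocks]


def test_divergence_rate_recovered_within_binomial_bound():
    n = 100_000
    pair = generate_genome_pair(1, n, divergence_rate=0.01,
                                n_rearranged_blocks=0, seed=3)
    mism = sum(x != y for x, y in zip(pair.sequences_a["chr1"],
                                      pair.sequences_b["chr1"]))
    se = np.sqrt(0.01 * 0.99 / n)
    assert abs(mism / n - 0.01) < 3 * se


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        generate_genome_pair(0, 20_000)
    with pytest.raises(ValueError):
        generate_genome_pair(1, 5_000)
    with pytest.raises(ValueError):
        generate_genome_pair(1, 20_000, divergence_rate=0.5)


def test_rearranged_blocks_compose_to_identity():
    pair = generate_genome_pair(1, 50_000, 0.0, n_rearranged_blocks=5, seed=9)
    fwd, rev = pair.block_map_ab, pair.block_map_ba
    rng = np.random.default_rng(0)
    for pos in rng.integers(0, 50_000, size=200):
        c, m, _ = fwd.map_position("chr1", int(pos))
        assert rev.map_position(c, m)[:2] == ("chr1", int(pos))
        # sequence content agrees through the map (zero divergence)
        assert pair.sequences_a["chr1"][pos] == pair.sequences_b[c][m]


@pytest.fixture(scope="module")
def planted():
    pair = generate_genome_pair(4, 700_000, 0.01, 4, seed=11)
    genes = generate_gene_models(pair, 250, seed=12)
    truth = plant_apa_truth(genes, pair, seed=13)
    return pair, genes, truth


class TestPlantedTruth:
    def test_usage_vectors_sum_to_one(self, planted):
        _, _, truth = planted
        for col in ("usage_a", "usage_b"):
            sums = truth.pas.groupby("gene_id")[col].sum()
            assert np.allclose(sums, 1.0, atol=1e-9)

    def test_divergent_pas_reach_min_dpau(self, planted):
        _, _, truth = planted
        div = truth.pas[truth.pas["divergent"]]
        assert len(div) > 0
        assert (div["true_dpau"].abs() >= 0.2 - 1e-12).all()
        gaps = (div["usage_a"] - div["usage_b"]).abs()
        assert np.allclose(gaps, div["true_dpau"].abs(), atol=1e-9)

    def test_species_specific_pas_have_zero_usage_elsewhere(self, planted):
        _, _, truth = planted
        ss = truth.pas[truth.pas["species_specific"] != "none"]
        for _, r in ss.iterrows():
            other = "usage_b" if r["species_specific"] == "a" else "usage_a"
            assert r[other] == 0.0

    def test_location_mix_matches_configuration(self, planted):
        _, _, truth = planted
        props = truth.pas["location"].value_counts(normalize=True)
        expected = dict(zip(("utr3", "intron", "cds", "utr5", "end"),
                            (0.40, 0.32, 0.10, 0.05, 0.13)))
        for loc, p in expected.items():
            assert abs(props.get(loc, 0.0) - p) < 0.05

    def test_planted_motifs_present_in_sequence(self, planted):
        pair, _, truth = planted
        sub = truth.pas[truth.pas["motif_a"] != "none"].head(50)
        from apakit.seqfeatures import region_sequence
        for _, r in sub.iterrows():
            apex = int(r["apex_a"])
            seq = region_sequence(pair.sequences_a, r["contig"],
                                  apex - 40, apex + 41, r["strand"])
            # the hexamer sits 10-30 bp upstream of the apex, tx direction
            assert r["motif_a"] in seq[:41]

    def test_zero_divergent_fraction_equalizes_species(self):
        pair = generate_genome_pair(1, 200_000, 0.0, 0, seed=21)
        genes = generate_gene_models(pair, 15, seed=21)
        truth = plant_apa_truth(genes, pair, divergent_fraction=0.0,
                                species_specific_fraction=0.0, seed=22)
        assert np.allclose(truth.pas["usage_a"], truth.pas["usage_b"])


class TestSimulatedReads:
    def test_read_share_follows_usage(self):
        pair = generate_genome_pair(1, 50_000, 0.0, 0, seed=31)
        genes = [GeneModel("g1", "chr1", "+", 1000, 5500,
                           exons=[(1000, 1700), (3200, 5500)],
                           cds=[(1300, 1700), (3200, 3700)],
                           utr5=[(1000, 1300)], utr3=[(3700, 5500)])]
        truth = plant_apa_truth(genes, pair, pas_per_gene_distribution=(0, 1, 0, 0, 0, 0, 0, 0),
                                location_probs=(1, 0, 0, 0, 0),
                                divergent_fraction=0.0, species_specific_fraction=0.0,
                                seed=32)
        truth.pas.loc[truth.pas.index[0], ["usage_a", "usage_b"]] = 0.8
        truth.pas.loc[truth.pas.index[1], ["usage_a", "usage_b"]] = 0.2
        rs = simulate_reads(pair, truth, samples_per_species=(1, 0),
                            reads_per_sample=10_000, mispriming_rate=0.0,
                            jitter_max=0, seed=33)[0]
        share = (rs.reads["provenance"] == truth.pas["pas_id"].iloc[0]).mean()
        assert abs(share - 0.8) <= 3 * np.sqrt(0.8 * 0.2 / 10_000)

    def test_no_mispriming_means_all_reads_true(self, small_dataset):
        pair, truth = small_dataset.pair, small_dataset.truth
        rs = simulate_reads(pair, truth, samples_per_species=(1, 1),
                            reads_per_sample=2000, mispriming_rate=0.0, seed=5)
        for r in rs:
            assert (r.reads["provenance"] != "misprimed").all()

    def test_misprimed_reads_satisfy_filter_rule(self, small_dataset):
        reads = small_dataset.reads_frame()
        mis = reads[reads["provenance"] == "misprimed"]
        assert len(mis) > 0
        for sp in ("a", "b"):
            genome = small_dataset.pair.sequences(sp)
            sub = mis[mis["species"] == sp].head(300)
            for _, r in sub.iterrows():
                call = upstream_window(genome, r["contig"], r["pos"], r["strand"])
                assert call.reason in ("six_consecutive_A", "seven_of_ten_A")

    def test_species_specific_pas_get_no_reads_in_other_species(self, small_dataset):
        truth = small_dataset.truth.pas
        reads = small_dataset.reads_frame()
        for _, r in truth[truth["species_specific"] != "none"].iterrows():
            other = "b" if r["species_specific"] == "a" else "a"
            hits = reads[(reads["species"] == other)
                         & (reads["provenance"] == r["pas_id"])]
            assert len(hits) == 0

    def test_per_gene_counts_are_multinomial_with_truth_usage(self, planted):
        """Chi-square goodness of fit of read counts against planted usage."""
        pair, _, truth = planted
        rs = simulate_reads(pair, truth, samples_per_species=(1, 0),
                            reads_per_sample=2_000_000, mispriming_rate=0.0,
                            seed=34)[0]
        per_pas = rs.reads.groupby("provenance").size()
        bad = total = 0
        for gene, g in truth.pas.groupby("gene_id"):
            use = g[g["usage_a"] > 0]
            obs = per_pas.reindex(use["pas_id"]).fillna(0).to_numpy()
            if obs.sum() < 1000 or len(use) < 2:
                continue
            exp = use["usage_a"].to_numpy() / use["usage_a"].sum() * obs.sum()
            p = stats.chisquare(obs, exp).pvalue
            total += 1
            bad += p < 0.001
        assert total > 100
        assert bad / total <= 0.01 + 2 * np.sqrt(0.01 * 0.99 / total)

    def test_mispriming_requires_a_rich_loci(self):
        pair = generate_genome_pair(1, 20_000, 0.0, 0, seed=41)
        # genome with no A at all cannot host mispriming
        pair.sequences_a = {"chr1": "CG" * 10_000}
        pair.sequences_b = dict(pair.sequences_a)
        genes = [GeneModel("g1", "chr1", "+", 1000, 5500,
                           exons=[(1000, 5500)], cds=[(1300, 3700)],
                           utr5=[(1000, 1300)], utr3=[(3700, 5500)])]
        truth = plant_apa_truth(genes, pair, motif_probs=(0, 0, 1), seed=42)
        with pytest.raises(ValueError, match="A-rich"):
            simulate_reads(pair, truth, (1, 0), 100, mispriming_rate=0.1, seed=43)


def test_misprime_index_matches_rule_everywhere():
    pair = generate_genome_pair(1, 30_000, 0.0, 0, seed=51)
    idx = build_misprime_index(pair.sequences_a)
    assert len(idx) > 0
    for _, r in idx.head(200).iterrows():
        call = upstream_window(pair.sequences_a, r["contig"], r["pos"], r["strand"])
        assert call.reason != "none"


class TestDatasetRoundTrip:
    def test_write_read_round_trip(self, small_dataset, tmp_path):
        d = str(tmp_path / "ds")
        write_dataset(small_dataset, d)
        back = read_dataset(d)
        assert back.pair.sequences_a == small_dataset.pair.sequences_a
        assert back.pair.sequences_b == small_dataset.pair.sequences_b
        assert [vars(b) for b in back.pair.block_map_ab.blocks] == \
            [vars(b) for b in small_dataset.pair.block_map_ab.blocks]
        assert len(back.genes) == len(small_dataset.genes)
        g0, g1 = small_dataset.genes[0], back.genes[0]
        assert (g0.gene_id, g0.strand, g0.exons, g0.cds, g0.utr5, g0.utr3) == \
            (g1.gene_id, g1.strand, g1.exons, g1.cds, g1.utr5, g1.utr3)
        pd.testing.assert_frame_equal(
            back.truth.pas.reset_index(drop=True),
            small_dataset.truth.pas.reset_index(drop=True), check_dtype=False)
        for rs0, rs1 in zip(small_dataset.read_sets, back.read_sets):
            assert rs0.sample_id == rs1.sample_id
            assert (rs0.reads["pos"].to_numpy() == rs1.reads["pos"].to_numpy()).all()

    def test_manifest_hash_tracks_config(self, small_config):
        import dataclasses
        h0 = small_config.config_hash()
        assert SimConfig(**dataclasses.asdict(small_config)).config_hash() == h0
        changed = dataclasses.replace(small_config, mispriming_rate=0.03)
        assert changed.config_hash() != h0

    def test_bed_records_are_zero_based_strand_matched(self, small_dataset, tmp_path):
        d = str(tmp_path / "ds2")
        write_dataset(small_dataset, d)
        rs = small_dataset.read_sets[0]
        bed = pd.read_csv(f"{d}/reads_{rs.sample_id}.bed", sep="\t", header=None)
        assert ((bed[2] - bed[1]) == 1).all()
        strand_by_pas = small_dataset.truth.pas.set_index("pas_id")["strand"]
        true_mask = rs.reads["provenance"] != "misprimed"
        expect = strand_by_pas.reindex(rs.reads.loc[true_mask, "provenance"]).to_numpy()
        assert (bed.loc[true_mask.to_numpy(), 5].to_numpy() == expect).all()
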