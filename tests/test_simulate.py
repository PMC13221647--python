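"""Synthetic-data generators: determinism, degenerate closed forms, recovery."""

import numpy as np
import pandas as pd
import pytest

from mycoreg import io as mio
from mycoreg.clusters import call_clusters
from mycoreg.promoters import extract_promoters, scan_ccaat
from mycoreg.simulate import (
    ComplexTruth,
    GenomeSimParams,
    PlantedCluster,
    TapSimParams,
    generate_genome_with_clusters,
    generate_proteome,
    simulate_tap_runs,
)


class TestProteome:
    def test_degenerate_length_range(self):
        (rec,) = generate_proteome(1, (10, 10), seed=7)
        assert len(rec.sequence) == 10

    def test_byte_identical_fasta_for_same_seed(self, tmp_path):
        paths = []
        for name in ("a.fasta", "b.fasta"):
            recs = generate_proteome(20, (10, 40), seed=7)
            p = tmp_path / name
            mio.write_fasta({r.protein_id: r.sequence for r in recs}, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_lengths_within_bounds_and_alphabet(self):
        recs = generate_proteome(100, (50, 500), seed=1)
        assert len(recs) == 100
        for r in recs:
            assert 50 <= len(r.sequence) <= 500
            assert set(r.sequence) <= set("ACDEFGHIKLMNPQRSTVWY")

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            generate_proteome(0, (10, 20))
        with pytest.raises(ValueError):
            generate_proteome(5, (5, 20))


class TestTapSimulation:
    def test_degenerate_probabilities_exact_membership(self, two_complex_truth):
        params = TapSimParams(1.0, 0.0, 3, background_proteins=("c1", "c2"), seed=0)
        table = simulate_tap_runs(two_complex_truth, params, ["swi1"])
        controls = table[table["is_control"]]
        assert controls.empty
        for _, grp in table.groupby("replicate"):
            assert set(grp["protein"]) == set(
                two_complex_truth.co_complex_members("swi1")
            )

    def test_zero_detection_leaves_bait_and_contaminants(self, two_complex_truth):
        params = TapSimParams(0.0, 1.0, 2, background_proteins=("c1",), seed=0)
        table = simulate_tap_runs(two_complex_truth, params, ["rsc1"],
                                  include_controls=False)
        for _, grp in table.groupby("replicate"):
            assert set(grp["protein"]) == {"rsc1", "c1"}

    def test_controls_never_contain_complex_members(self, two_complex_truth):
        params = TapSimParams(0.5, 0.5, 3,
                              background_proteins=tuple(f"c{i}" for i in range(50)),
                              seed=3)
        table = simulate_tap_runs(two_complex_truth, params, ["swi1", "rsc1"])
        control_proteins = set(table.loc[table["is_control"], "protein"])
        assert not control_proteins & set(two_complex_truth.all_members)

    def test_member_detection_frequency_matches_p(self, two_complex_truth):
        p, reps = 0.9, 3
        params = TapSimParams(p, 0.05, reps,
                              background_proteins=tuple(f"c{i}" for i in range(1000)),
                              seed=10)
        bait = "swi1"
        members = sorted(two_complex_truth.co_complex_members(bait) - {bait})
        table = simulate_tap_runs(two_complex_truth, params, [bait],
                                  include_controls=False)
        n_trials = len(members) * reps
        detected = sum(
            (table["protein"] == m).sum() for m in members
        )
        sd = np.sqrt(n_trials * p * (1 - p))
        assert abs(detected - n_trials * p) <= 3 * sd

    def test_peptide_counts_positive_and_deterministic(self, two_complex_truth):
        params = TapSimParams(0.9, 0.1, 3, background_proteins=("c1", "c2"), seed=21)
        a = simulate_tap_runs(two_complex_truth, params, ["swi1", "rsc1"])
        b = simulate_tap_runs(two_complex_truth, params, ["swi1", "rsc1"])
        assert a.equals(b)
        assert (a["peptides_observed"] >= 1).all()

    def test_unknown_bait_rejected(self, two_complex_truth):
        params = TapSimParams(0.9, 0.0, 1, seed=0)
        with pytest.raises(ValueError):
            simulate_tap_runs(two_complex_truth, params, ["nope"])


class TestComplexTruth:
    def test_shared_is_exactly_multimembership(self, two_complex_truth):
        for protein in two_complex_truth.all_members:
            in_n = sum(protein in m for m in two_complex_truth.complexes.values())
            assert (protein in two_complex_truth.shared) == (in_n >= 2)

    def test_labels(self):
        truth = ComplexTruth({"A": frozenset("xy"), "B": frozenset("yz")})
        assert truth.true_label("y") == "shared"
        assert truth.true_label("x") == "specific:A"
        assert truth.true_label("q") == "unassigned"


class TestGenomeSimulation:
    def test_zero_ccaat_fraction_scans_clean(self):
        params = GenomeSimParams(n_genes=60, n_chromosomes=2, ccaat_fraction=0.0,
                                 seed=4)
        sim = generate_genome_with_clusters(params)
        windows = extract_promoters(sim.genes, sim.genome, params.promoter_len)
        assert not any(scan_ccaat(w).has_motif for w in windows)
        assert sim.truth["ccaat_genes"] == []

    def test_scan_recovers_exactly_the_planted_genes(self):
        params = GenomeSimParams(n_genes=300, n_chromosomes=3, ccaat_fraction=0.4,
                                 seed=11)
        sim = generate_genome_with_clusters(params)
        windows = extract_promoters(sim.genes, sim.genome, params.promoter_len)
        found = {w.gene_id for w in windows if scan_ccaat(w).has_motif}
        assert found == set(sim.truth["ccaat_genes"])

    def test_planted_cluster_recovered_by_caller(self):
        params = GenomeSimParams(
            n_genes=200, n_chromosomes=2, ccaat_fraction=0.2, seed=2,
            planted_clusters=(
                PlantedCluster(0, 30, 6),
                PlantedCluster(1, 10, 9, gap=4, direction="down"),
            ),
        )
        sim = generate_genome_with_clusters(params)
        called = call_clusters(sim.expression)
        got = {(c.chromosome, c.start_ordinal, c.size) for c in called}
        want = {(t["chromosome"], t["start_ordinal"], t["size"])
                for t in sim.truth["clusters"]}
        assert got == want
        gapped = next(c for c in called if c.chromosome == "chr2")
        assert gapped.gap_ordinals == (14,)
        assert gapped.direction == "down"

    def test_noise_never_reaches_threshold(self):
        sim = generate_genome_with_clusters(
            GenomeSimParams(n_genes=500, n_chromosomes=1, ccaat_fraction=0.0, seed=6)
        )
        assert (sim.expression["log2fc"].abs() < 1.0).all()
        assert call_clusters(sim.expression) == []

    def test_gff_fasta_roundtrip_preserves_gene_order(self, tmp_path):
        params = GenomeSimParams(n_genes=40, n_chromosomes=2, seed=9)
        sim = generate_genome_with_clusters(params)
        gff, fasta = tmp_path / "g.gff3", tmp_path / "g.fasta"
        mio.write_gff3(sim.genes, gff)
        mio.write_fasta(sim.genome, fasta)
        genes2 = mio.read_gff_genes(gff)
        pd.testing.assert_frame_equal(
            genes2, sim.genes[genes2.columns], check_dtype=False
        )
        genome2 = mio.read_fasta(fasta)
        assert genome2 == sim.genome

    def test_overlapping_planted_clusters_rejected(self):
        with pytest.raises(ValueError):
            GenomeSimParams(planted_clusters=(
                PlantedCluster(0, 0, 6), PlantedCluster(0, 5, 6),
            ))

    def test_cluster_shape_validation(self):
        with pytest.raises(ValueError):
            PlantedCluster(0, 0, 5)
        with pytest.raises(ValueError):
            PlantedCluster(0, 0, 7, gap=3)
        with pytest.raises(ValueError):
            PlantedCluster(0, 0, 9, gap=0)

    def test_determinism(self):
        params = GenomeSimParams(n_genes=50, seed=13)
        a = generate_genome_with_clusters(params)
        b = generate_genome_with_clusters(params)
        assert a.genome == b.genome
        assert a.expression.equals(b.expression)
        assert a.truth == b.truth
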