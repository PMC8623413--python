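"""Synthetic-data generators: determinism, conservation, and distributional checks."""

import numpy as np
import pytest

from ytraffic import io
from ytraffic.reference import kmer_counts_naive
from ytraffic.simdata import (
    GenomeSpec,
    ReadSimConfig,
    implant_segdup,
    pseudogenize,
    random_cds,
    simulate_event_history,
    simulate_genome,
    simulate_reads,
)
from ytraffic._encode import revcomp_str


class TestSimulateGenome:
    def test_no_repeats_means_no_shared_kmers(self):
        spec = GenomeSpec(2, 2, 8_000, repeat_fraction=0.0, seed=7)
        scaffolds, truth = simulate_genome(spec)
        y_kmers, xa_kmers = set(), set()
        for name, seq in scaffolds.items():
            target = y_kmers if truth.scaffold_class[name] == "Y" else xa_kmers
            target.update(kmer_counts_naive(seq, 15))
        assert not y_kmers & xa_kmers

    def test_same_seed_same_bytes(self, tmp_path):
        spec = GenomeSpec(2, 1, 5_000, repeat_fraction=0.2, seed=3)
        paths = []
        for run in range(2):
            scaffolds, _ = simulate_genome(spec)
            p = tmp_path / f"run{run}.fasta"
            io.write_fasta(scaffolds, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_no_y_scaffolds_means_no_y_truth(self):
        scaffolds, truth = simulate_genome(GenomeSpec(3, 0, 2_000, seed=1))
        assert set(truth.scaffold_class.values()) == {"XA"}
        assert len(scaffolds) == 3

    def test_zero_scaffolds_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(0, 0, 1000)

    def test_every_scaffold_has_one_truth_entry(self):
        scaffolds, truth = simulate_genome(GenomeSpec(4, 3, 2_000, seed=9))
        assert set(scaffolds) == set(truth.scaffold_class)


class TestSimulateReads:
    def test_female_reads_never_come_from_y(self):
        scaffolds, truth = simulate_genome(GenomeSpec(2, 2, 6_000, seed=11))
        _, prov = simulate_reads(
            scaffolds, truth, ReadSimConfig(sex="female", depth=8, seed=12)
        )
        sources = set(prov["scaffold"])
        assert all(truth.scaffold_class[s] == "XA" for s in sources)

    def test_male_y_depth_is_half_autosomal(self):
        # hemizygosity: male depth 20 gives the Y an expected 10x
        scaffolds, truth = simulate_genome(GenomeSpec(1, 1, 120_000, seed=13))
        reads, prov = simulate_reads(
            scaffolds, truth, ReadSimConfig(sex="male", depth=20, seed=14)
        )
        y_name = next(n for n, c in truth.scaffold_class.items() if c == "Y")
        n_y_reads = (prov["scaffold"] == y_name).sum()
        mean_depth = n_y_reads * 100 / 120_000
        assert abs(mean_depth - 10) / 10 < 0.15

    def test_error_free_reads_are_exact_substrings(self):
        scaffolds, truth = simulate_genome(GenomeSpec(1, 1, 3_000, seed=15))
        reads, prov = simulate_reads(
            scaffolds, truth, ReadSimConfig(sex="male", depth=3, seed=16)
        )
        for row in prov.itertuples(index=False):
            seq = reads[row.read_id]
            ref = scaffolds[row.scaffold]
            if row.strand == "-":
                seq = revcomp_str(seq)
            assert ref[row.start : row.start + 100] == seq

    def test_pooled_library_covers_y_at_quarter_depth(self):
        # 50/50 unsexed pool: Y coverage = depth * 0.5 / 2
        scaffolds, truth = simulate_genome(GenomeSpec(1, 1, 120_000, seed=17))
        _, prov = simulate_reads(
            scaffolds,
            truth,
            ReadSimConfig(sex="male", depth=20, seed=18, male_fraction=0.5),
        )
        y_name = next(n for n, c in truth.scaffold_class.items() if c == "Y")
        mean_depth = (prov["scaffold"] == y_name).sum() * 100 / 120_000
        assert abs(mean_depth - 5) / 5 < 0.2

    def test_empty_scaffold_set_rejected(self):
        _, truth = simulate_genome(GenomeSpec(1, 0, 1_000, seed=1))
        with pytest.raises(ValueError):
            simulate_reads({}, truth, ReadSimConfig(sex="male", depth=5))

    def test_error_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            ReadSimConfig(sex="male", depth=5, error_rate=0.2)


class TestImplantSegdup:
    def test_zero_rates_conserve_sequence_exactly(self):
        scaffolds, truth = simulate_genome(GenomeSpec(1, 0, 50_000, seed=19))
        name = next(iter(scaffolds))
        genome, truth = implant_segdup(
            scaffolds, (name, 10_000, 15_000), n_copies=10, seed=20, truth=truth
        )
        copies = truth.segdups[0].copy_scaffolds
        assert len(copies) == 10
        total_extra = sum(len(genome[c]) for c in copies)
        assert total_extra == 10 * 5_000
        assert all(genome[c] == scaffolds[name][10_000:15_000] for c in copies)

    def test_single_undiverged_copy_identical_to_source(self):
        scaffolds, truth = simulate_genome(GenomeSpec(1, 0, 20_000, seed=21))
        name = next(iter(scaffolds))
        genome, truth = implant_segdup(
            scaffolds, (name, 0, 4_000), n_copies=1, seed=22, truth=truth
        )
        copy = truth.segdups[0].copy_scaffolds[0]
        assert genome[copy] == scaffolds[name][0:4_000]
        assert truth.scaffold_class[copy] == "Y"

    def test_divergence_matches_binomial_expectation(self):
        scaffolds, truth = simulate_genome(GenomeSpec(1, 0, 110_000, seed=23))
        name = next(iter(scaffolds))
        genome, truth = implant_segdup(
            scaffolds, (name, 0, 100_000), n_copies=1,
            per_copy_divergence=0.01, seed=24, truth=truth,
        )
        copy = genome[truth.segdups[0].copy_scaffolds[0]]
        src = scaffolds[name][:100_000]
        mismatches = sum(a != b for a, b in zip(copy, src))
        mean, sd = 100_000 * 0.01, (100_000 * 0.01 * 0.99) ** 0.5
        assert abs(mismatches - mean) <= 3 * sd

    def test_interval_outside_scaffold_rejected(self):
        scaffolds, _ = simulate_genome(GenomeSpec(1, 0, 1_000, seed=25))
        name = next(iter(scaffolds))
        with pytest.raises(ValueError):
            implant_segdup(scaffolds, (name, 500, 2_000), n_copies=1)


class TestPseudogenize:
    def test_zero_rates_identity(self):
        cds = random_cds(100, seed=1)
        out, events = pseudogenize(cds, 0.0, 0.0, seed=2)
        assert out == cds and events == []

    def test_short_cds_rejected(self):
        with pytest.raises(ValueError):
            pseudogenize("ATG", 0.1, 0.0)

    def test_premature_stop_fraction_matches_closed_form(self):
        # P(>=1 stop) = 1 - (1 - r)^(internal codons)
        r, n_codons, runs = 0.01, 100, 1000
        cds = random_cds(n_codons, seed=5)
        internal = n_codons - 2
        hits = 0
        for i in range(runs):
            _, events = pseudogenize(cds, stop_rate=r, seed=1000 + i)
            hits += any(e[0] == "premature_stop" for e in events)
        expected = 1 - (1 - r) ** internal
        sd = (expected * (1 - expected) / runs) ** 0.5
        assert abs(hits / runs - expected) <= 3 * sd

    def test_forced_frameshift_detected_downstream(self):
        from ytraffic.genefate import FRAMESHIFT, check_cds_integrity

        cds = random_cds(80, seed=6)
        for i in range(200):
            out, events = pseudogenize(cds, frameshift_rate=0.01, seed=i)
            if len(events) == 1:
                assert check_cds_integrity(out, cds).status == FRAMESHIFT
                break
        else:
            pytest.fail("no single-frameshift draw found")


class TestEventHistory:
    TREE = "((((A:5,B:5):5,C:10):5,D:15):5,E:20);"

    def test_zero_loss_rate_gives_no_losses(self):
        tree = io.tree_from_newick(self.TREE)
        emap, _ = simulate_event_history(tree, gain_rate=0.5, loss_rate=0.0, seed=31)
        _, L, _, _ = emap.totals()
        assert L == 0

    def test_no_gains_no_ancestors_empty_history(self):
        tree = io.tree_from_newick(self.TREE)
        emap, _ = simulate_event_history(tree, gain_rate=0.0, loss_rate=0.5, seed=32)
        G, L, _, _ = emap.totals()
        assert (G, L) == (0, 0)

    def test_mean_gains_match_poisson_expectation(self):
        tree = io.tree_from_newick(self.TREE)
        total_time = sum(e.length or 0 for e in tree.preorder_edge_iter())
        rate = 30.0 / total_time  # gain_rate x total time = 30
        gains = []
        for i in range(500):
            emap, _ = simulate_event_history(tree, rate, 0.0, seed=5000 + i)
            gains.append(emap.totals()[0])
        se = np.sqrt(30.0 / 500)
        assert abs(np.mean(gains) - 30.0) <= 3 * se

    def test_negative_rates_rejected(self):
        tree = io.tree_from_newick(self.TREE)
        with pytest.raises(ValueError):
            simulate_event_history(tree, -0.1, 0.1)

    def test_losses_only_after_gains(self):
        tree = io.tree_from_newick(self.TREE)
        emap, _ = simulate_event_history(tree, 0.5, 0.3, seed=33)
        gained = {g for lst in emap.gains.values() for g in lst}
        lost = [g for lst in emap.losses.values() for g in lst]
        # every lost gene was gained first (losses on sibling lineages may repeat)
        assert set(lost) <= gained
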