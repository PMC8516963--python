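"""Unit and property tests for the synthetic evolution generator."""

import numpy as np
import pytest

import phyloscreen as ps
from phyloscreen.simulate import mutate_sequence
from phyloscreen.translate import six_frame_translate


class TestSimulateTree:
    def test_rejects_fewer_than_two_taxa(self):
        with pytest.raises(ValueError):
            ps.simulate_tree(1, seed=0)

    def test_two_tip_tree_is_unscaled(self):
        t = ps.simulate_tree(2, seed=1, long_clade_fraction=0.0, long_multiplier=1.0)
        assert t.n_tips == 2
        assert t.long_clade_root is None

    def test_seed_determinism(self):
        a = ps.simulate_tree(8, seed=7, long_clade_fraction=0.25, long_multiplier=3.0)
        b = ps.simulate_tree(8, seed=7, long_clade_fraction=0.25, long_multiplier=3.0)
        assert a.to_newick() == b.to_newick()

    def test_long_clade_scaling_is_pure_multiplication(self):
        base = ps.simulate_tree(8, seed=7, long_clade_fraction=0.25, long_multiplier=1.0)
        # flagging happens even at multiplier 1, so the same clade is chosen
        scaled = ps.simulate_tree(8, seed=7, long_clade_fraction=0.25, long_multiplier=3.0)
        assert base.long_clade_root == scaled.long_clade_root
        clade = scaled.long_clade_root
        for nid in scaled.node_ids():
            if nid == scaled.root_id:
                continue
            ratio = scaled.branch_length(nid) / base.branch_length(nid)
            expected = 3.0 if scaled.in_long_clade(nid) else 1.0
            assert ratio == pytest.approx(expected)
        assert clade is not None

    def test_branch_lengths_nonnegative_and_binary(self):
        t = ps.simulate_tree(13, seed=3)
        for nid in t.node_ids():
            assert t.branch_length(nid) >= 0
            kids = t.children(nid)
            assert len(kids) in (0, 2)


class TestEvolveFamily:
    def test_zero_loss_rate_keeps_every_tip(self):
        t = ps.simulate_tree(10, seed=2)
        fam = ps.evolve_family(t, 50, sub_rate=0.5, loss_rate=0.0, seed=5)
        assert set(fam.present_tips) == set(fam.tip_seqs)
        assert not fam.loss_branches

    def test_zero_rates_give_identical_sequences(self):
        t = ps.simulate_tree(6, seed=2)
        fam = ps.evolve_family(t, 40, sub_rate=0.0, loss_rate=0.0, seed=5)
        for seq in fam.tip_seqs.values():
            assert seq == fam.root_seq

    def test_loss_fraction_matches_closed_form(self):
        # two tips on branches of length 1, loss_rate 0.5:
        # P(tip lost) = 1 - exp(-0.5) = 0.3935
        tree = ps.SpeciesTree.from_newick("(A:1.0,B:1.0);")
        n = 10_000
        lost = 0
        for s in range(n):
            fam = ps.evolve_family(tree, 5, 0.0, 0.5, seed=s)
            lost += sum(1 for v in fam.tip_seqs.values() if v is None)
        p = 1 - np.exp(-0.5)
        frac = lost / (2 * n)
        se = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(frac - p) < 3 * se

    def test_substitution_fraction_matches_closed_form(self):
        # P(site differs) = (1 - exp(-rate*t)) * 19/20 under a uniform background
        tree = ps.SpeciesTree.from_newick("(A:1.0,B:1.0);")
        L, reps, rate = 200, 100, 0.4
        diffs = total = 0
        for s in range(reps):
            fam = ps.evolve_family(tree, L, rate, 0.0, seed=s)
            for seq in fam.tip_seqs.values():
                diffs += sum(1 for a, b in zip(seq, fam.root_seq) if a != b)
                total += L
        p = (1 - np.exp(-rate)) * 19 / 20
        se = np.sqrt(p * (1 - p) / total)
        assert abs(diffs / total - p) < 3 * se

    @pytest.mark.parametrize("seed", range(8))
    def test_dollo_consistency(self, seed):
        """No present tip sits below a loss branch; losses form an antichain."""
        t = ps.simulate_tree(12, seed=seed)
        fam = ps.evolve_family(t, 30, 0.3, 0.4, seed=seed + 100)
        for branch in fam.loss_branches:
            for tip in t.tips_below(branch):
                assert fam.tip_seqs[tip] is None
        for a in fam.loss_branches:
            for b in fam.loss_branches:
                if a != b:
                    assert a not in [x for x in _ancestors(t, b)]

    def test_seed_determinism(self):
        t = ps.simulate_tree(6, seed=1)
        a = ps.evolve_family(t, 30, 0.3, 0.2, seed=9)
        b = ps.evolve_family(t, 30, 0.3, 0.2, seed=9)
        assert a.tip_seqs == b.tip_seqs and a.loss_branches == b.loss_branches


def _ancestors(tree, node_id):
    cur = tree.parent(node_id)
    while cur is not None:
        yield cur
        cur = tree.parent(cur)


class TestEmitGenomeAndProteome:
    def _truths(self):
        t = ps.simulate_tree(5, seed=4)
        return [
            ps.evolve_family(t, 60, 0.2, 0.2, seed=k, family_id=f"f{k}") for k in range(4)
        ]

    def test_hide_fraction_zero_keeps_all(self):
        genomes, proteomes, reg = ps.emit_genome_and_proteome(self._truths(), 50, 0.0, seed=1)
        present = reg[reg.state == "present"]
        assert not present.hidden.any()
        n_prot = sum(len(p) for p in proteomes.values())
        assert n_prot == len(present)

    def test_hide_fraction_one_empties_proteome(self):
        genomes, proteomes, reg = ps.emit_genome_and_proteome(self._truths(), 50, 1.0, seed=1)
        assert all(len(p) == 0 for p in proteomes.values())
        present = reg[reg.state == "present"]
        assert present.hidden.all()

    def test_embedded_gene_round_trips_through_translation(self):
        genomes, proteomes, reg = ps.emit_genome_and_proteome(self._truths(), 80, 0.2, seed=3)
        checked = 0
        for row in reg[reg.state == "present"].itertuples():
            contig = genomes[row.taxon][row.contig]
            seqs = {
                s.seq
                for s in six_frame_translate(contig, min_len=10, contig_id=row.contig)
            }
            truth = next(t for t in self._truths() if t.family_id == row.family)
            protein = truth.tip_seqs[row.taxon]
            assert any(protein in s for s in seqs), (row.family, row.taxon)
            checked += 1
        assert checked > 0


class TestSimulatePileup:
    def test_haploid_no_error_is_monoallelic(self):
        df = ps.simulate_pileup(1, 5000, 30, error_rate=0.0, seed=0)
        n_bases = (df[list("ACGT")] > 0).sum(axis=1)
        assert (n_bases <= 1).all()

    def test_diploid_biallelic_fraction(self):
        n = 100_000
        df = ps.simulate_pileup(2, n, 30, error_rate=0.0, het_density=0.01, seed=1)
        biallelic = ((df[list("ACGT")] > 0).sum(axis=1) >= 2).mean()
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(biallelic - 0.01) < 3 * se

    def test_seed_determinism(self):
        a = ps.simulate_pileup(2, 1000, 20, 0.01, 0.02, seed=5)
        b = ps.simulate_pileup(2, 1000, 20, 0.01, 0.02, seed=5)
        assert a.equals(b)

    def test_coverage_conservation(self):
        df = ps.simulate_pileup(2, 2000, 25, 0.02, 0.01, seed=2)
        assert (df[list("ACGT")].sum(axis=1) >= 0).all()


class TestSampleKmerSets:
    def _genome(self, n=2000, seed=2):
        rng = np.random.default_rng(seed)
        return "".join("ACGT"[i] for i in rng.integers(4, size=n))

    def test_no_dropout_reads_subset_of_assembly(self):
        assembly, reads = ps.sample_kmer_sets(self._genome(), 15, 20, 0.0, seed=1)
        assert set(reads) <= assembly

    def test_k_too_long_raises(self):
        with pytest.raises(ValueError):
            ps.sample_kmer_sets("ACGTACGT", 9, 10, 0.0, seed=0)

    def test_different_k_deterministic(self):
        g = self._genome()
        a15, r15 = ps.sample_kmer_sets(g, 15, 20, 0.0, seed=3)
        a15b, r15b = ps.sample_kmer_sets(g, 15, 20, 0.0, seed=3)
        a17, _ = ps.sample_kmer_sets(g, 17, 20, 0.0, seed=3)
        assert a15 == a15b and r15 == r15b
        assert not (a15 & a17)  # different k => disjoint k-mer universes

    def test_canonicalisation(self):
        assembly, _ = ps.sample_kmer_sets("ACGTACGTACGTACG", 11, 10, 0.0, seed=0)
        for kmer in assembly:
            assert kmer <= ps.simulate.revcomp(kmer)
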