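import numpy as np
import pytest

import phyloscreen as ps


@pytest.fixture
def quartet_tree():
    return ps.SpeciesTree.from_newick("((A:0.1,B:0.1)ab:0.1,(C:0.1,D:0.1)cd:0.1)root;")


@pytest.fixture
def small_sim():
    """A small simulated study: tree, family truths, genomes/proteomes with
    30% of embedded genes hidden from the annotation."""
    rng = np.random.default_rng(11)
    tree = ps.simulate_tree(8, 42, 0.25, 2.0)
    truths = [
        ps.evolve_family(
            tree, 120, 0.4, 0.15, seed=int(rng.integers(2**31)), family_id=f"fam{k:03d}"
        )
        for k in range(6)
    ]
    genomes, proteomes, registry = ps.emit_genome_and_proteome(
        truths, intergenic_len=150, hide_fraction=0.3, seed=7
    )
    seed_msas = {
        tr.family_id: [ps.simulate.mutate_sequence(tr.root_seq, 0.95, rng) for _ in range(4)]
        for tr in truths
    }
    return {
        "tree": tree,
        "truths": truths,
        "genomes": genomes,
        "proteomes": proteomes,
        "registry": registry,
        "seed_msas": seed_msas,
    }
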