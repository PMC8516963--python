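"""Tiered absence-verification cascade."""

import numpy as np
import pytest

import phyloscreen as ps
from phyloscreen.pssm import build_profile, calibrate_evalue
from phyloscreen.screen import (
    FamilyModel,
    PresenceCall,
    ScreenConfig,
    screen_all,
    verify_absence,
)
from phyloscreen.simulate import (
    _random_protein,
    mutate_sequence,
    reverse_translate,
    revcomp,
    uniform_background,
)
from phyloscreen.translate import six_frame_translate


@pytest.fixture(scope="module")
def family_model():
    rng = np.random.default_rng(0)
    root = _random_protein(120, rng, uniform_background())
    msa = [mutate_sequence(root, 0.9, rng) for _ in range(5)]
    profile = build_profile(msa, family_id="famX")
    fit = calibrate_evalue(profile, seed=1)
    return FamilyModel("famX", profile, fit), root


def _segments(genome, cfg):
    return six_frame_translate(genome, cfg.min_orf_len, "c1")


class TestVerifyAbsence:
    def test_verbatim_protein_present_via_proteome(self, family_model):
        model, root = family_model
        cfg = ScreenConfig()
        call = verify_absence(model, "tax1", {"p1": root}, [], cfg)
        assert call.state == "present" and call.tier == "proteome"
        assert call.paralogs == 1

    def test_empty_everything_is_absent(self, family_model):
        model, _ = family_model
        call = verify_absence(model, "tax1", {}, [], ScreenConfig())
        assert call.state == "absent" and call.tier == "none"

    def test_hidden_gene_rescued_from_genome(self, family_model):
        model, root = family_model
        cfg = ScreenConfig()
        rng = np.random.default_rng(2)
        cds = reverse_translate(root, rng)
        genome = "CCC" * 40 + cds + "GGG" * 40
        call = verify_absence(model, "tax1", {}, _segments(genome, cfg), cfg)
        assert call.state == "present_genome_only" and call.tier == "six-frame"

    def test_minus_strand_gene_rescued(self, family_model):
        model, root = family_model
        cfg = ScreenConfig()
        rng = np.random.default_rng(3)
        genome = "CCC" * 40 + revcomp(reverse_translate(root, rng)) + "GGG" * 40
        call = verify_absence(model, "tax1", {}, _segments(genome, cfg), cfg)
        assert call.state == "present_genome_only"
        assert call.best.start < call.best.end

    def test_duplicated_gene_counts_two_paralogs(self, family_model):
        model, root = family_model
        cfg = ScreenConfig()
        rng = np.random.default_rng(4)
        cds1, cds2 = reverse_translate(root, rng), reverse_translate(root, rng)
        genome = "CCC" * 40 + cds1 + "AAA" * 50 + cds2 + "GGG" * 40
        call = verify_absence(model, "tax1", {}, _segments(genome, cfg), cfg)
        assert call.state == "present_genome_only"
        assert call.paralogs == 2

    def test_missing_genome_flagged_unchecked(self, family_model):
        model, root = family_model
        call = verify_absence(model, "tax1", {}, None, ScreenConfig())
        assert "genome-unchecked" in call.flags
        assert call.state == "absent"

    def test_domain_tier_rescues_divergent_domain(self):
        """A broad domain sub-profile at the relaxed threshold catches a
        domain variant that the narrow family profile misses: the family
        carries one domain variant, the target an independently diverged
        one (~50% identity to the family's), and only the diverse domain
        alignment covers both."""
        rng = np.random.default_rng(5)
        domain = _random_protein(50, rng, uniform_background())
        fam_variant = mutate_sequence(domain, 0.55, rng)
        root = fam_variant + _random_protein(80, rng, uniform_background())
        msa = [mutate_sequence(root, 0.95, rng) for _ in range(5)]
        profile = build_profile(msa, family_id="famY")
        fit = calibrate_evalue(profile, seed=3)
        dom_msa = [mutate_sequence(domain, 0.75, rng) for _ in range(10)]
        dom_prof = build_profile(dom_msa, family_id="famY/dom1")
        dom_fit = calibrate_evalue(dom_prof, seed=4)
        model = FamilyModel("famY", profile, fit, [(dom_prof, dom_fit)])
        target = mutate_sequence(domain, 0.55, rng) + _random_protein(
            120, rng, uniform_background()
        )
        call = verify_absence(model, "tax1", {"p1": target}, [], ScreenConfig())
        assert call.state == "present" and call.tier == "domain"

    def test_state_tier_consistency_enforced(self):
        with pytest.raises(ValueError):
            PresenceCall("f", "t", "absent", "proteome")


class TestScreenAll:
    def test_no_losses_no_hiding_everything_present(self):
        rng = np.random.default_rng(6)
        tree = ps.simulate_tree(5, 1)
        truths = [
            ps.evolve_family(tree, 100, 0.3, 0.0, seed=k, family_id=f"f{k}")
            for k in range(3)
        ]
        genomes, proteomes, _ = ps.emit_genome_and_proteome(truths, 100, 0.0, seed=2)
        families = {
            t.family_id: {"msa": [mutate_sequence(t.root_seq, 0.95, rng) for _ in range(4)]}
            for t in truths
        }
        taxa = {t: {"proteome": proteomes[t], "genome": genomes[t]} for t in proteomes}
        calls = screen_all(families, taxa, ScreenConfig(seed=3))
        assert all(c.state == "present" for c in calls)

    def test_rescue_beats_proteome_only(self, small_sim):
        """With hidden genes, (present + present_genome_only) recall must
        exceed proteome-only recall, and hidden genes must come back as
        present_genome_only."""
        families = {f: {"msa": m} for f, m in small_sim["seed_msas"].items()}
        taxa = {
            t: {"proteome": small_sim["proteomes"][t], "genome": small_sim["genomes"][t]}
            for t in small_sim["proteomes"]
        }
        calls = screen_all(families, taxa, ScreenConfig(seed=5))
        truth = {
            (tr.family_id, t): (s is not None)
            for tr in small_sim["truths"]
            for t, s in tr.tip_seqs.items()
        }
        hidden = {
            (r.family, r.taxon)
            for r in small_sim["registry"].itertuples()
            if r.hidden
        }
        assert hidden, "fixture should hide some genes"
        n_true = sum(truth.values())
        proteome_recall = (
            sum(1 for c in calls if c.tier == "proteome" and truth[(c.family_id, c.taxon)])
            / n_true
        )
        full_recall = (
            sum(1 for c in calls if c.state != "absent" and truth[(c.family_id, c.taxon)])
            / n_true
        )
        assert full_recall > proteome_recall
        for c in calls:
            if (c.family_id, c.taxon) in hidden and c.state != "absent":
                assert c.state == "present_genome_only"

    def test_known_losses_called_absent(self, small_sim):
        families = {f: {"msa": m} for f, m in small_sim["seed_msas"].items()}
        taxa = {
            t: {"proteome": small_sim["proteomes"][t], "genome": small_sim["genomes"][t]}
            for t in small_sim["proteomes"]
        }
        calls = screen_all(families, taxa, ScreenConfig(seed=5))
        truth = {
            (tr.family_id, t): (s is not None)
            for tr in small_sim["truths"]
            for t, s in tr.tip_seqs.items()
        }
        false_present = [
            c for c in calls if c.state != "absent" and not truth[(c.family_id, c.taxon)]
        ]
        assert not false_present

    def test_deterministic_given_seed(self, small_sim):
        families = {f: {"msa": m} for f, m in small_sim["seed_msas"].items()}
        taxa = {
            t: {"proteome": small_sim["proteomes"][t], "genome": None}
            for t in small_sim["proteomes"]
        }
        a = screen_all(families, taxa, ScreenConfig(seed=9))
        b = screen_all(families, taxa, ScreenConfig(seed=9))
        assert [(c.family_id, c.taxon, c.state, c.tier) for c in a] == [
            (c.family_id, c.taxon, c.state, c.tier) for c in b
        ]
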