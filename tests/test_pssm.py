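"""Profile construction, local alignment (vs brute force), calibration, search."""

import numpy as np
import pytest
from scipy import stats

import phyloscreen as ps
from phyloscreen._dp import sw_score_batch
from phyloscreen._reference import brute_force_local_score
from phyloscreen.pssm import (
    ALPHABET,
    CalibrationError,
    ProfileMatrix,
    build_profile,
    calibrate_evalue,
    evalue,
    iterative_search,
    score_local,
)
from phyloscreen.simulate import _random_protein, mutate_sequence, uniform_background


def random_profile(rng, L):
    scores = rng.normal(0.0, 2.5, size=(L, 20))
    return ProfileMatrix("p", scores, np.ones(L), np.full(20, 0.05), 1.0, np.arange(L))


class TestBuildProfile:
    def test_single_sequence_alpha_zero_is_log_odds_of_certainty(self):
        with pytest.warns(RuntimeWarning):
            p = build_profile(["A"], alpha=0.0)
        assert p.scores[0, 0] == pytest.approx(np.log2(20))
        assert np.isneginf(p.scores[0, 1:]).all()

    def test_huge_alpha_flattens_to_background(self):
        p = build_profile(["ACDE", "ACDF", "GHIK"], alpha=1e6)
        assert np.abs(p.scores).max() < 1e-3

    def test_hand_arithmetic_column(self):
        # counts A:2, C:1, equal weights, alpha=1, uniform background:
        # f'(A) = (2 + 0.05)/4 = 0.5125; s(A) = log2(0.5125/0.05) = 3.358
        p = build_profile(["A", "A", "C"], alpha=1.0, weighting="uniform")
        assert p.scores[0, ALPHABET.index("A")] == pytest.approx(3.3576, abs=1e-3)

    def test_gap_heavy_columns_dropped(self):
        p = build_profile(["A-C", "A-C", "AGC", "A-C"])
        assert list(p.columns) == [0, 2]

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_profile([])

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["AC", "ACD"])


class TestScoreLocal:
    def test_empty_sequence_scores_zero(self):
        p = random_profile(np.random.default_rng(0), 4)
        score, interval, trace = score_local(p, "")
        assert score == 0.0 and interval == (0, 0) and trace == []

    def test_consensus_without_gaps_hits_column_max_sum(self):
        rng = np.random.default_rng(1)
        p = random_profile(rng, 6)
        consensus = p.consensus()
        # gaps disallowed via prohibitive costs -> pure diagonal alignment
        score, _, trace = score_local(p, consensus, gap_open=1e6, gap_extend=1e6)
        assert score == pytest.approx(p.scores.max(axis=1).sum())
        assert [c for _, c in trace] == list(range(6))

    @pytest.mark.parametrize("trial", range(60))
    def test_matches_brute_force_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        L = int(rng.integers(1, 6))
        n = int(rng.integers(0, 7))
        p = random_profile(rng, L)
        seq = "".join(ALPHABET[i] for i in rng.integers(0, 20, size=n))
        go = float(rng.uniform(0.5, 5.0))
        ge = float(rng.uniform(0.1, 2.0))
        dp, _, _ = score_local(p, seq, go, ge)
        ref = brute_force_local_score(p.scores, [ALPHABET.index(c) for c in seq], go, ge)
        assert dp == pytest.approx(ref, abs=1e-9)

    def test_self_score_beats_shuffles(self):
        rng = np.random.default_rng(5)
        seq = _random_protein(80, rng, uniform_background())
        p = build_profile([seq], alpha=0.1)
        self_score, _, _ = score_local(p, seq)
        arr = list(seq)
        for _ in range(100):
            rng.shuffle(arr)
            s, _, _ = score_local(p, "".join(arr))
            assert self_score >= s

    def test_nonpositive_gap_costs_rejected(self):
        p = random_profile(np.random.default_rng(0), 3)
        with pytest.raises(ValueError):
            score_local(p, "ACD", gap_open=0.0)


@pytest.fixture(scope="module")
def profile():
    rng = np.random.default_rng(3)
    root = _random_protein(120, rng, uniform_background())
    return build_profile([mutate_sequence(root, 0.65, rng) for _ in range(10)])


class TestCalibration:
    def test_requires_100_decoys(self, profile):
        with pytest.raises(ValueError):
            calibrate_evalue(profile, n_decoys=50)

    def test_infinite_score_has_zero_evalue(self, profile):
        fit = calibrate_evalue(profile, seed=1)
        assert evalue(fit, np.inf, 10**6) == 0.0

    def test_degenerate_scores_raise(self):
        flat = ProfileMatrix(
            "flat", np.zeros((5, 20)), np.ones(5), np.full(20, 0.05), 1.0, np.arange(5)
        )
        with pytest.raises(CalibrationError):
            calibrate_evalue(flat, seed=0)

    def test_evalue_at_95th_percentile(self, profile):
        # E(score at the empirical 95th percentile) ~ 0.05 * n_decoys when
        # the database equals the decoy set
        n, dlen = 500, 100
        fit = calibrate_evalue(profile, n_decoys=n, decoy_len=dlen, seed=9)
        rng = np.random.default_rng(42)
        dec = rng.choice(20, size=(n, dlen), p=profile.background).astype(np.int64)
        mx = np.sort(sw_score_batch(profile.scores, dec, 4.0, 0.5))
        s95 = mx[int(0.95 * n)]
        E = evalue(fit, float(s95), n * dlen)
        assert 0.5 * 0.05 * n < E < 2.0 * 0.05 * n

    def test_null_pvalues_uniform(self, profile):
        fit = calibrate_evalue(profile, n_decoys=500, decoy_len=100, seed=11)
        rng = np.random.default_rng(12)
        dec = rng.choice(20, size=(200, 100), p=profile.background).astype(np.int64)
        mx = sw_score_batch(profile.scores, dec, 4.0, 0.5)
        pv = stats.gumbel_r.sf(mx, loc=fit.mu, scale=fit.lam)
        assert stats.kstest(pv, "uniform").pvalue > 0.01


class TestIterativeSearch:
    def test_empty_targets(self):
        msa, _ = ps.make_bridge_family(seed=0)
        res = iterative_search(msa, {}, seed=1)
        assert res.hits == [] and len(res.per_iteration_counts) == 1 and res.converged

    def test_max_iter_one_equals_single_pass(self):
        msa, targets = ps.make_bridge_family(seed=5)
        one = iterative_search(msa, targets, max_iter=1, seed=2)
        full = iterative_search(msa, targets, seed=2)
        first_pass = {h.target_id for h in full.hits if h.iteration == 1}
        assert {h.target_id for h in one.hits} == first_pass

    def test_bridge_recovered_only_after_enrichment(self):
        msa, targets = ps.make_bridge_family(seed=5)
        res = iterative_search(msa, targets, seed=2)
        by_id = {h.target_id: h for h in res.hits}
        assert by_id["far"].iteration >= 2
        assert by_id["mid1"].iteration == 1

    def test_hit_counts_monotone(self):
        msa, targets = ps.make_bridge_family(seed=7)
        res = iterative_search(msa, targets, seed=3)
        assert res.per_iteration_counts == sorted(res.per_iteration_counts)

    def test_nested_targets_flattened(self):
        msa, targets = ps.make_bridge_family(seed=4)
        nested = {"taxonA": {"mid1": targets["mid1"]}, "taxonB": {"far": targets["far"]}}
        res = iterative_search(msa, nested, seed=2)
        assert {h.target_id for h in res.hits} <= {"mid1", "far"}

    def test_invalid_arguments(self):
        msa, targets = ps.make_bridge_family(seed=0)
        with pytest.raises(ValueError):
            iterative_search(msa, targets, max_iter=0)
        with pytest.raises(ValueError):
            iterative_search(msa, targets, inclusion_E=0.0)
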