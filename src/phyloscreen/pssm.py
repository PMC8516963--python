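"""Position-specific scoring profiles and the iterative taxa-enrichment search.

The engine of sensitive homology detection: log-odds profiles (bits) built
from seed alignments with Henikoff position-based sequence weighting and
background-proportional pseudocounts, scored against targets by affine-gap
local dynamic programming, with significance from a Gumbel fit to shuffled
decoy maxima.  The search loop folds newly significant hits back into the
alignment and rebuilds the profile until no new target is included — the
mechanism that recovers highly divergent orthologs a single-pass search
misses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from ._dp import sw_fill, sw_score_batch, sw_score_only

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
GAP_CHARS = set("-.")

DEFAULT_GAP_OPEN = 4.0
DEFAULT_GAP_EXTEND = 0.5


class CalibrationError(RuntimeError):
    """Raised when decoy scores are too degenerate to fit a null model."""


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid sequence; unknown residues get the neutral code 20."""
    return np.fromiter((AA_INDEX.get(c, 20) for c in seq.upper()), dtype=np.int64, count=len(seq))


@dataclass
class ProfileMatrix:
    """Log-odds profile of a query family.

    ``scores[i, a]`` is log2(f'(a)/b(a)) in bits for column i; ``columns``
    maps profile columns back to columns of the source alignment (gap-heavy
    columns are dropped).
    """

    family_id: str
    scores: np.ndarray  # (L, 20) float64, bits
    eff_counts: np.ndarray  # (L,) effective (weighted) observation count
    background: np.ndarray  # (20,)
    alpha: float
    columns: np.ndarray  # (L,) indices into the source alignment

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[a] for a in np.argmax(self.scores, axis=1))

    def max_score(self) -> float:
        return float(np.max(self.scores, axis=1).sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=list(ALPHABET))
        df.insert(0, "column", self.columns)
        df["n_eff"] = self.eff_counts
        return df


@dataclass
class CalibrationFit:
    """Gumbel null model for maximal local scores of background decoys."""

    mu: float
    lam: float  # Gumbel scale, > 0
    n_decoys: int
    decoy_len: int

    def pvalue(self, score: float) -> float:
        """P(max decoy score >= score) under the fitted Gumbel."""
        return float(stats.gumbel_r.sf(score, loc=self.mu, scale=self.lam))


@dataclass
class SearchHit:
    family_id: str
    target_id: str
    start: int  # 0-based half-open on the target
    end: int
    bitscore: float
    evalue: float
    iteration: int


@dataclass
class IterativeSearchResult:
    profile: ProfileMatrix
    hits: List[SearchHit]
    per_iteration_counts: List[int]
    converged: bool
    fit: Optional[CalibrationFit] = None
    alignment: List[Tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def _henikoff_weights(rows: List[str], kept: np.ndarray) -> np.ndarray:
    """Henikoff position-based sequence weights over the kept columns,
    normalised to sum to the number of sequences."""
    n = len(rows)
    w = np.zeros(n)
    for col in kept:
        residues: Dict[str, List[int]] = {}
        for i, row in enumerate(rows):
            c = row[col]
            if c in AA_INDEX:
                residues.setdefault(c, []).append(i)
        r = len(residues)
        if r == 0:
            continue
        for members in residues.values():
            share = 1.0 / (r * len(members))
            for i in members:
                w[i] += share
    total = w.sum()
    if total <= 0:
        return np.ones(n)
    return w * n / total


def build_profile(
    msa: Sequence[Union[str, Tuple[str, str]]],
    alpha: float = 1.0,
    background: Optional[np.ndarray] = None,
    family_id: str = "",
    max_gap_frac: float = 0.5,
    weighting: str = "henikoff",
) -> ProfileMatrix:
    """Build a log-odds profile from an aligned family.

    Column frequencies are ``f'(a) = (c(a) + alpha*b(a)) / (n_eff + alpha)``
    with weighted counts ``c`` and per-column effective count ``n_eff``
    (gap rows contribute nothing); scores are ``log2(f'/b)`` bits.
    ``weighting`` is ``"henikoff"`` (position-based, the default — enriched
    alignments are phylogenetically redundant) or ``"uniform"`` (weight 1
    per sequence).  Columns with more than ``max_gap_frac`` gaps are
    dropped.  With ``alpha = 0`` unobserved residues score -inf (allowed,
    with a warning).
    """
    rows = [r[1] if isinstance(r, tuple) else r for r in msa]
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows must have equal length")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)

    rows = [r.upper() for r in rows]
    n = len(rows)
    gap_frac = np.array(
        [sum(1 for r in rows if r[c] not in AA_INDEX) / n for c in range(width)]
    )
    kept = np.nonzero(gap_frac <= max_gap_frac)[0]
    if kept.size == 0:
        raise ValueError("no columns left after gap filtering")

    if weighting == "henikoff":
        weights = _henikoff_weights(rows, kept)
    elif weighting == "uniform":
        weights = np.ones(n)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    L = kept.size
    counts = np.zeros((L, 20))
    n_eff = np.zeros(L)
    for k, col in enumerate(kept):
        for i, row in enumerate(rows):
            a = AA_INDEX.get(row[col])
            if a is not None:
                counts[k, a] += weights[i]
                n_eff[k] += weights[i]
    fprime = (counts + alpha * background) / (n_eff + alpha)[:, None]
    with np.errstate(divide="ignore"):
        scores = np.log2(fprime / background)
    if np.isneginf(scores).any():
        warnings.warn(
            "alpha=0 with unobserved residues: profile contains -inf scores",
            RuntimeWarning,
            stacklevel=2,
        )
    return ProfileMatrix(family_id, scores, n_eff, background, alpha, kept)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_local(
    profile: ProfileMatrix,
    seq: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    traceback: bool = True,
) -> Tuple[float, Tuple[int, int], List[Tuple[int, int]]]:
    """Best affine-gap local alignment of ``seq`` against the profile.

    Returns ``(score, (start, end), trace)`` with a 0-based half-open
    sequence interval and a trace of ``(seq_pos, profile_col)`` match pairs.
    The score is floored at 0; an empty sequence scores 0.
    """
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap costs must be positive")
    if not seq:
        return 0.0, (0, 0), []
    codes = encode(seq)
    scores = np.where(np.isneginf(profile.scores), -1.0e30, profile.scores)
    if not traceback:
        return float(sw_score_only(scores, codes, gap_open, gap_extend)), (0, 0), []
    pM, pX, pY, best, bi, bj = sw_fill(scores, codes, gap_open, gap_extend)
    if best <= 0.0:
        return 0.0, (0, 0), []
    trace: List[Tuple[int, int]] = []
    i, j, state = bi, bj, 0  # 0=M, 1=X, 2=Y
    while i > 0 and j > 0:
        if state == 0:
            trace.append((j - 1, i - 1))
            p = pM[i, j]
            i, j = i - 1, j - 1
            if p == 0:
                break
            state = {1: 0, 2: 1, 3: 2}[int(p)]
        elif state == 1:
            p = pX[i, j]
            i -= 1
            state = 0 if p == 1 else 1
        else:
            p = pY[i, j]
            j -= 1
            state = 0 if p == 1 else 2
    trace.reverse()
    start = trace[0][0]
    end = trace[-1][0] + 1
    return float(best), (start, end), trace


# ---------------------------------------------------------------------------
# E-value calibration
# ---------------------------------------------------------------------------

def calibrate_evalue(
    profile: ProfileMatrix,
    n_decoys: int = 200,
    decoy_len: int = 100,
    seed: int = 0,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> CalibrationFit:
    """Fit a Gumbel to maximal local scores of i.i.d. background decoys."""
    if n_decoys < 100:
        raise ValueError("need at least 100 decoys")
    rng = np.random.default_rng(seed)
    decoys = rng.choice(20, size=(n_decoys, decoy_len), p=profile.background).astype(np.int64)
    scores = np.where(np.isneginf(profile.scores), -1.0e30, profile.scores)
    maxima = sw_score_batch(scores, decoys, gap_open, gap_extend)
    if np.ptp(maxima) <= 1e-12:
        raise CalibrationError("degenerate decoy scores; cannot fit a Gumbel")
    mu, lam = stats.gumbel_r.fit(maxima)
    if lam <= 0:
        raise CalibrationError("non-positive Gumbel scale")
    return CalibrationFit(float(mu), float(lam), n_decoys, decoy_len)


def evalue(fit: CalibrationFit, score: float, db_residues: int) -> float:
    """Expected number of chance hits at ``score`` in a database of
    ``db_residues`` residues: ``db/decoy_len * exp(-(S - mu)/lam)``."""
    e = db_residues / fit.decoy_len * np.exp(-(score - fit.mu) / fit.lam)
    return float(max(e, 0.0))


# ---------------------------------------------------------------------------
# iterative taxa-enrichment search
# ---------------------------------------------------------------------------

def _flatten_targets(
    targets: Mapping[str, Union[str, Mapping[str, str]]]
) -> Dict[str, str]:
    flat: Dict[str, str] = {}
    for key in targets:
        val = targets[key]
        if isinstance(val, str):
            flat[key] = val
        else:
            for sub_id, seq in val.items():
                flat[sub_id] = seq
    return flat


def iterative_search(
    seed_msa: Sequence[Union[str, Tuple[str, str]]],
    targets: Mapping[str, Union[str, Mapping[str, str]]],
    inclusion_E: float = 1e-5,
    max_iter: int = 10,
    alpha: float = 1.0,
    background: Optional[np.ndarray] = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    n_decoys: int = 200,
    decoy_len: int = 100,
    seed: int = 0,
    family_id: str = "",
) -> IterativeSearchResult:
    """Iterate profile build -> score -> include until no new hit.

    Targets may be a flat mapping ``id -> sequence`` or nested ``taxon ->
    {id -> sequence}``.  Hits with E <= ``inclusion_E`` (per the whole target
    database) are realigned to the profile via their trace, stacked onto the
    alignment, and the profile rebuilt; the included set is monotone
    non-decreasing.  Non-convergence at ``max_iter`` is flagged, not an error.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if inclusion_E <= 0:
        raise ValueError("inclusion_E must be positive")
    flat = _flatten_targets(targets)
    db_residues = sum(len(s) for s in flat.values())

    rows: List[Tuple[str, str]] = []
    for k, r in enumerate(seed_msa):
        if isinstance(r, tuple):
            rows.append((r[0], r[1].upper()))
        else:
            rows.append((f"seed{k + 1}", r.upper()))
    width = len(rows[0][1])

    included: set = set()
    hits: List[SearchHit] = []
    counts: List[int] = []
    converged = False
    rng = np.random.default_rng(seed)
    profile = build_profile(
        [r for _, r in rows], alpha=alpha, background=background, family_id=family_id
    )
    fit = calibrate_evalue(
        profile, n_decoys=n_decoys, decoy_len=decoy_len,
        seed=int(rng.integers(2**31)), gap_open=gap_open, gap_extend=gap_extend,
    )
    for it in range(1, max_iter + 1):
        new_rows: List[Tuple[str, str]] = []
        for tid in sorted(flat):
            if tid in included:
                continue
            seq = flat[tid]
            score, (a, b), trace = score_local(profile, seq, gap_open, gap_extend)
            E = evalue(fit, score, db_residues) if db_residues else float("inf")
            if E <= inclusion_E:
                included.add(tid)
                hits.append(SearchHit(family_id, tid, a, b, score, E, it))
                row = ["-"] * width
                for seq_pos, col in trace:
                    row[int(profile.columns[col])] = seq[seq_pos]
                new_rows.append((tid, "".join(row)))
        counts.append(len(included))
        if not new_rows:
            converged = True
            break
        rows.extend(new_rows)
        profile = build_profile(
            [r for _, r in rows], alpha=alpha, background=background, family_id=family_id
        )
        fit = calibrate_evalue(
            profile, n_decoys=n_decoys, decoy_len=decoy_len,
            seed=int(rng.integers(2**31)), gap_open=gap_open, gap_extend=gap_extend,
        )
    return IterativeSearchResult(profile, hits, counts, converged, fit, rows)
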