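"""Tiered absence verification.

A family is only called absent from a taxon after a cascade of searches
fails: (1) the calibrated family profile against the predicted proteome,
(2) the same profile against stop-free six-frame translations of the genome
(rescuing genes the annotation missed), and (3) relaxed domain-level
sub-profiles (E <= 1e-3) against both.  Each call records which tier
produced the evidence, and a paralog count (distinct proteome hits, or
non-overlapping genome intervals).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .pssm import (
    CalibrationFit,
    ProfileMatrix,
    SearchHit,
    build_profile,
    calibrate_evalue,
    evalue,
    iterative_search,
    score_local,
)
from .translate import TranslatedSegment, six_frame_translate

DOMAIN_E_DEFAULT = 1e-3


@dataclass
class ScreenConfig:
    inclusion_E: float = 1e-5
    family_E: Dict[str, float] = field(default_factory=dict)  # per-family overrides
    domain_E: float = DOMAIN_E_DEFAULT
    gap_open: float = 4.0
    gap_extend: float = 0.5
    alpha: float = 1.0
    min_orf_len: int = 25
    n_decoys: int = 200
    decoy_len: int = 100
    max_iter: int = 10
    overlap_merge_frac: float = 0.25
    seed: int = 0

    def threshold_for(self, family_id: str) -> float:
        return self.family_E.get(family_id, self.inclusion_E)


@dataclass
class FamilyModel:
    """A calibrated family profile plus optional domain sub-profiles."""

    family_id: str
    profile: ProfileMatrix
    fit: CalibrationFit
    domains: List[Tuple[ProfileMatrix, CalibrationFit]] = field(default_factory=list)
    enrichment_hits: List[SearchHit] = field(default_factory=list)
    converged: bool = True


@dataclass
class PresenceCall:
    family_id: str
    taxon: str
    state: str  # present | present_genome_only | absent
    tier: str  # proteome | six-frame | domain | none
    best: Optional[SearchHit] = None
    paralogs: int = 0
    flags: List[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.state == "absent") != (self.tier == "none"):
            raise ValueError("state=absent iff tier=none")


# ---------------------------------------------------------------------------
# model building
# ---------------------------------------------------------------------------

def build_family_model(
    family_id: str,
    seed_msa: Sequence,
    proteomes: Mapping[str, Mapping[str, str]],
    config: ScreenConfig,
    domain_msas: Sequence[Sequence] = (),
) -> FamilyModel:
    """Taxa-enrichment search over all proteomes, then final calibration."""
    seed = _derive_seed(config.seed, family_id)
    result = iterative_search(
        seed_msa,
        {tax: dict(prots) for tax, prots in proteomes.items()},
        inclusion_E=config.threshold_for(family_id),
        max_iter=config.max_iter,
        alpha=config.alpha,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
        n_decoys=config.n_decoys,
        decoy_len=config.decoy_len,
        seed=seed,
        family_id=family_id,
    )
    domains = []
    for k, msa in enumerate(domain_msas):
        prof = build_profile(msa, alpha=config.alpha, family_id=f"{family_id}/dom{k + 1}")
        fit = calibrate_evalue(
            prof, n_decoys=config.n_decoys, decoy_len=config.decoy_len,
            seed=_derive_seed(seed, f"dom{k}"), gap_open=config.gap_open,
            gap_extend=config.gap_extend,
        )
        domains.append((prof, fit))
    return FamilyModel(
        family_id, result.profile, result.fit, domains,
        enrichment_hits=result.hits, converged=result.converged,
    )


def _derive_seed(seed: int, token) -> int:
    stable = zlib.crc32(str(token).encode())  # process-independent, unlike hash()
    return int(np.random.default_rng([seed, stable]).integers(2**31))


# ---------------------------------------------------------------------------
# searching one taxon
# ---------------------------------------------------------------------------

def _search_proteome(
    profile: ProfileMatrix,
    fit: CalibrationFit,
    proteome: Mapping[str, str],
    threshold: float,
    config: ScreenConfig,
    family_id: str,
) -> List[SearchHit]:
    db = sum(len(s) for s in proteome.values())
    hits = []
    for pid in sorted(proteome):
        seq = proteome[pid]
        score, (a, b), _ = score_local(profile, seq, config.gap_open, config.gap_extend)
        E = evalue(fit, score, db)
        if E <= threshold:
            hits.append(SearchHit(family_id, pid, a, b, score, E, 0))
    hits.sort(key=lambda h: (-h.bitscore, h.target_id))
    return hits


def _search_segments(
    profile: ProfileMatrix,
    fit: CalibrationFit,
    segments: Sequence[TranslatedSegment],
    threshold: float,
    config: ScreenConfig,
    family_id: str,
) -> List[Tuple[SearchHit, TranslatedSegment, Tuple[int, int]]]:
    """Hits on six-frame segments, with forward-strand nucleotide intervals.

    A long stop-free segment can harbour several gene copies, so after each
    significant alignment the matched stretch is masked (scored neutral) and
    the segment re-scored, up to ``max_hsps`` times.
    """
    db = sum(len(s.seq) for s in segments)
    max_hsps = 8
    out = []
    for seg in segments:
        masked = seg.seq
        for _ in range(max_hsps):
            score, (a, b), _ = score_local(
                profile, masked, config.gap_open, config.gap_extend
            )
            E = evalue(fit, score, db) if db else float("inf")
            if E > threshold or b <= a:
                break
            nt = seg.nt_interval_of(a, b)
            hit = SearchHit(family_id, seg.contig, nt[0], nt[1], score, E, 0)
            out.append((hit, seg, nt))
            masked = masked[:a] + "x" * (b - a) + masked[b:]  # 'x' scores neutral
    out.sort(key=lambda h: (-h[0].bitscore, h[0].target_id, h[2]))
    return out


def _count_nonoverlapping(
    genome_hits: Sequence[Tuple[SearchHit, TranslatedSegment, Tuple[int, int]]],
    merge_frac: float,
) -> int:
    """Greedy by descending bit score; an interval overlapping an accepted one
    by more than ``merge_frac`` of the shorter interval is merged into it."""
    accepted: List[Tuple[str, int, int]] = []
    for hit, seg, (a, b) in genome_hits:
        merged = False
        for contig, xa, xb in accepted:
            if contig != seg.contig:
                continue
            ov = min(b, xb) - max(a, xa)
            shorter = min(b - a, xb - xa)
            if ov > merge_frac * shorter:
                merged = True
                break
        if not merged:
            accepted.append((seg.contig, a, b))
    return len(accepted)


def verify_absence(
    model: FamilyModel,
    taxon: str,
    proteome: Mapping[str, str],
    genome_segments: Optional[Sequence[TranslatedSegment]],
    config: ScreenConfig,
) -> PresenceCall:
    """Run the three-tier cascade for one (family, taxon).

    ``genome_segments`` is the precomputed six-frame translation of the
    taxon's genome, or ``None`` when no genome is available (the call is
    then flagged ``genome-unchecked``).
    """
    threshold = config.threshold_for(model.family_id)
    flags: List[str] = []
    if genome_segments is None:
        flags.append("genome-unchecked")
        genome_segments = []

    prot_hits = _search_proteome(
        model.profile, model.fit, proteome, threshold, config, model.family_id
    )
    if prot_hits:
        return PresenceCall(
            model.family_id, taxon, "present", "proteome",
            best=prot_hits[0], paralogs=len(prot_hits), flags=flags,
        )
    gen_hits = _search_segments(
        model.profile, model.fit, genome_segments, threshold, config, model.family_id
    )
    if gen_hits:
        return PresenceCall(
            model.family_id, taxon, "present_genome_only", "six-frame",
            best=gen_hits[0][0],
            paralogs=_count_nonoverlapping(gen_hits, config.overlap_merge_frac),
            flags=flags,
        )
    for prof, fit in model.domains:
        dom_prot = _search_proteome(
            prof, fit, proteome, config.domain_E, config, model.family_id
        )
        if dom_prot:
            return PresenceCall(
                model.family_id, taxon, "present", "domain",
                best=dom_prot[0], paralogs=len(dom_prot), flags=flags,
            )
        dom_gen = _search_segments(
            prof, fit, genome_segments, config.domain_E, config, model.family_id
        )
        if dom_gen:
            return PresenceCall(
                model.family_id, taxon, "present_genome_only", "domain",
                best=dom_gen[0][0],
                paralogs=_count_nonoverlapping(dom_gen, config.overlap_merge_frac),
                flags=flags,
            )
    return PresenceCall(model.family_id, taxon, "absent", "none", flags=flags)


def screen_all(
    families: Mapping[str, Mapping],
    taxa: Mapping[str, Mapping],
    config: Optional[ScreenConfig] = None,
) -> List[PresenceCall]:
    """One presence call per (family, taxon).

    ``families`` maps family id -> {"msa": seed alignment, "domains":
    optional list of domain sub-alignments}; ``taxa`` maps taxon ->
    {"proteome": {id -> seq}, "genome": {contig -> seq} or None}.
    """
    calls, _models = screen_all_detailed(families, taxa, config)
    return calls


def screen_all_detailed(
    families: Mapping[str, Mapping],
    taxa: Mapping[str, Mapping],
    config: Optional[ScreenConfig] = None,
) -> Tuple[List[PresenceCall], Dict[str, FamilyModel]]:
    """Like :func:`screen_all` but also returns the enriched family models
    (profiles + calibrations) for inspection or serialisation."""
    config = config or ScreenConfig()
    proteomes = {tax: taxa[tax].get("proteome", {}) for tax in taxa}
    segments: Dict[str, Optional[List[TranslatedSegment]]] = {}
    for tax in sorted(taxa):
        genome = taxa[tax].get("genome")
        if genome is None:
            segments[tax] = None
        else:
            segs: List[TranslatedSegment] = []
            for contig in sorted(genome):
                segs.extend(
                    six_frame_translate(genome[contig], config.min_orf_len, contig)
                )
            segments[tax] = segs
    calls: List[PresenceCall] = []
    models: Dict[str, FamilyModel] = {}
    for fam in sorted(families):
        fam_spec = families[fam]
        model = build_family_model(
            fam, fam_spec["msa"], proteomes, config, fam_spec.get("domains", ())
        )
        models[fam] = model
        for tax in sorted(taxa):
            calls.append(
                verify_absence(model, tax, proteomes[tax], segments[tax], config)
            )
    return calls, models
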