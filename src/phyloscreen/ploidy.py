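"""Genome QC: heterozygous-site calling, ploidy inference, k-mer completeness.

The het-site rule is deliberately simple and explicit: a site counts only if
its coverage is at least ``min_cov`` (default 10x), and it is heterozygous
iff at least two distinct bases are each supported by at least
``min_alt_reads`` reads (default 2).

The ploidy verdict separates true allelic signal from sequencing-error
doublets: at 30x coverage and sub-percent error rates, error-driven het
sites cluster at minor-allele fractions near 2/coverage (~0.07), far below
the balanced ~0.5 expected of a diploid, so only het sites with
minor-allele fraction >= ``balance_floor`` (default 0.2) inform the verdict.
A sample is called diploid when the informative het fraction reaches
``het_frac_threshold`` and the minor-allele-fraction mode sits in
``balance_window``; haploid when the informative het fraction is below the
threshold; undetermined otherwise (or when too few sites are considered).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple, Union

import numpy as np
import pandas as pd

BASES = list("ACGT")
N_BALANCE_BINS = 20


class UndefinedCompletenessError(ValueError):
    """No solid read k-mers: completeness is undefined."""


def _as_frame(sites) -> pd.DataFrame:
    if isinstance(sites, pd.DataFrame):
        return sites
    return pd.DataFrame(list(sites), columns=["site"] + BASES)


def call_het_sites(
    sites, min_cov: int = 10, min_alt_reads: int = 2
) -> pd.DataFrame:
    """Apply the het rule to a pileup.

    ``sites`` is a DataFrame with columns ``site, A, C, G, T`` (or an
    iterable of such tuples).  Returns a DataFrame with ``coverage``,
    ``considered``, ``heterozygous`` and ``minor_frac`` (second most frequent
    base count over the top-two total; the two most frequent bases only).
    """
    df = _as_frame(sites).copy()
    counts = df[BASES].to_numpy()
    if (counts < 0).any():
        raise ValueError("base counts must be non-negative")
    cov = counts.sum(axis=1)
    top2 = np.sort(counts, axis=1)[:, -2:]
    second, first = top2[:, 0], top2[:, 1]
    n_supported = (counts >= min_alt_reads).sum(axis=1)
    df["coverage"] = cov
    df["considered"] = cov >= min_cov
    df["heterozygous"] = df["considered"] & (n_supported >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor = np.where(first + second > 0, second / (first + second), 0.0)
    df["minor_frac"] = minor
    return df


@dataclass
class PloidyReport:
    n_considered: int
    n_het: int
    het_fraction: float
    histogram: np.ndarray  # 20 bins on [0, 0.5] over all het sites
    bin_edges: np.ndarray
    n_informative: int
    informative_fraction: float
    mode_balance: Optional[float]  # bin centre of the informative mode
    verdict: str  # haploid | diploid | undetermined
    thresholds: Dict[str, float] = field(default_factory=dict)
    reason: str = ""

    def to_dict(self) -> dict:
        d = {
            "n_considered": self.n_considered,
            "n_het": self.n_het,
            "het_fraction": self.het_fraction,
            "n_informative": self.n_informative,
            "informative_fraction": self.informative_fraction,
            "mode_balance": self.mode_balance,
            "verdict": self.verdict,
            "thresholds": self.thresholds,
            "reason": self.reason,
            "histogram": self.histogram.tolist(),
            "bin_edges": self.bin_edges.tolist(),
        }
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def infer_ploidy(
    calls: pd.DataFrame,
    het_frac_threshold: float = 1e-3,
    balance_window: Tuple[float, float] = (0.4, 0.5),
    min_sites: int = 1000,
    balance_floor: float = 0.2,
) -> PloidyReport:
    """Ploidy verdict from het calls (output of :func:`call_het_sites`)."""
    considered = calls[calls["considered"]]
    het = considered[considered["heterozygous"]]
    n_considered = len(considered)
    n_het = len(het)
    edges = np.linspace(0.0, 0.5, N_BALANCE_BINS + 1)
    balances = np.clip(het["minor_frac"].to_numpy(), 0.0, 0.5)
    hist, _ = np.histogram(balances, bins=edges)
    # np.histogram puts 0.5 in the last bin, so mass always sums to n_het
    thresholds = {
        "het_frac_threshold": het_frac_threshold,
        "balance_window_low": balance_window[0],
        "balance_window_high": balance_window[1],
        "min_sites": min_sites,
        "balance_floor": balance_floor,
    }
    het_fraction = n_het / n_considered if n_considered else 0.0
    if n_considered < min_sites:
        return PloidyReport(
            n_considered, n_het, het_fraction, hist, edges, 0, 0.0, None,
            "undetermined", thresholds,
            reason=f"only {n_considered} considered sites (< {min_sites})",
        )
    informative = balances[balances >= balance_floor]
    n_informative = informative.size
    informative_fraction = n_informative / n_considered
    mode_balance: Optional[float] = None
    if n_informative:
        ihist, _ = np.histogram(informative, bins=edges)
        mode_bin = int(np.argmax(ihist))
        mode_balance = float((edges[mode_bin] + edges[mode_bin + 1]) / 2)
    if (
        informative_fraction >= het_frac_threshold
        and mode_balance is not None
        and balance_window[0] <= mode_balance <= balance_window[1]
    ):
        verdict, reason = "diploid", "balanced het sites at diploid density"
    elif informative_fraction < het_frac_threshold:
        verdict, reason = "haploid", "informative het fraction below threshold"
    else:
        verdict, reason = "undetermined", "het excess without balanced mode"
    return PloidyReport(
        n_considered, n_het, het_fraction, hist, edges,
        int(n_informative), float(informative_fraction), mode_balance,
        verdict, thresholds, reason,
    )


@dataclass
class KmerCompleteness:
    k: int
    solid_min: int
    n_solid: int
    n_found: int

    @property
    def percent(self) -> float:
        return 100.0 * self.n_found / self.n_solid

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "solid_min": self.solid_min,
            "n_solid": self.n_solid,
            "n_found": self.n_found,
            "percent": self.percent,
        }


def kmer_completeness(
    assembly_kmers: Set[str],
    read_kmers: Mapping[str, int],
    solid_min: int = 4,
    k: Optional[int] = None,
) -> KmerCompleteness:
    """Reference-free assembly completeness from k-mer sets.

    Solid read k-mers are those with count >= ``solid_min``; completeness is
    the percentage of them found in the assembly set.
    """
    if k is None:
        k = len(next(iter(assembly_kmers))) if assembly_kmers else 0
    solid = {km for km, c in read_kmers.items() if c >= solid_min}
    if not solid:
        raise UndefinedCompletenessError("no solid read k-mers")
    found = sum(1 for km in solid if km in assembly_kmers)
    return KmerCompleteness(k, solid_min, len(solid), found)
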