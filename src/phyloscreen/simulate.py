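"""Synthetic genome/proteome evolution.

Generates the study conditions the analysis assumes: a rooted species tree
with one long-branch clade (mimicking fast-evolving anaerobic protist
lineages), protein families evolving with irreversible (Dollo) lineage
losses and elevated substitution on long branches, genome/proteome pairs in
which a controlled fraction of genes is deliberately missing from the
annotation, haploid/diploid pileups with sequencing error, and read/assembly
k-mer multisets.

Everything is deterministic given its seed.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .trees import SpeciesTree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_LIST = list(AMINO_ACIDS)
DNA = "ACGT"

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
# amino acid -> sorted list of codons encoding it (standard code, no stops)
CODONS_BY_AA: Dict[str, List[str]] = {}
for codon, aa in sorted(_CODON_TABLE.forward_table.items()):
    CODONS_BY_AA.setdefault(aa, []).append(codon)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


@dataclass
class FamilyTruth:
    """Ground truth for one simulated protein family."""

    family_id: str
    root_seq: str
    tip_seqs: Dict[str, Optional[str]]  # taxon -> sequence, or None if lost
    loss_branches: Set[str]  # child-node ids of branches on which the family was lost
    in_proteome: Dict[str, bool] = field(default_factory=dict)  # present tips only

    @property
    def present_tips(self) -> List[str]:
        return [t for t, s in self.tip_seqs.items() if s is not None]


SiteCounts = collections.namedtuple("SiteCounts", ["site", "A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_tree(
    n_taxa: int,
    seed: int,
    long_clade_fraction: float = 0.0,
    long_multiplier: float = 1.0,
    branch_scale: float = 0.25,
) -> SpeciesTree:
    """Random birth-style rooted binary tree with an optional long-branch clade.

    Branch lengths are i.i.d. exponential with mean ``branch_scale``
    (substitutions/site).  If ``long_clade_fraction > 0``, the internal clade
    whose tip count is closest to ``long_clade_fraction * n_taxa`` is flagged
    and every branch inside it (including its stem) is multiplied by
    ``long_multiplier``.  Clade choice does not depend on the multiplier, so
    runs differing only in ``long_multiplier`` scale exactly the same edges.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if long_multiplier < 1:
        raise ValueError("long_multiplier must be >= 1")
    rng = np.random.default_rng(seed)

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.seed_node.split_order = 0
    leaves = [tree.seed_node]
    # root starts as a single leaf; split random leaves until n_taxa tips
    counter = 0
    while len(leaves) < n_taxa:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        left = node.new_child()
        right = node.new_child()
        counter += 1
        leaves.extend([left, right])
    # deterministic tip labels, left-to-right
    for i, leaf in enumerate(tree.leaf_node_iter()):
        taxon = taxon_namespace.new_taxon(f"t{i + 1}")
        leaf.taxon = taxon
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.exponential(branch_scale))
        else:
            node.edge.length = 0.0

    stree = SpeciesTree(tree)
    if long_clade_fraction > 0 and n_taxa > 2:
        target = max(1.0, long_clade_fraction * n_taxa)
        best_id, best_diff = None, None
        for nid in stree.preorder_ids():
            if nid == stree.root_id:
                continue
            size = len(stree.tips_below(nid))
            if size >= n_taxa:  # never flag the whole tree
                continue
            diff = abs(size - target)
            if best_diff is None or diff < best_diff:
                best_id, best_diff = nid, diff
        if best_id is not None:
            stree.long_clade_root = best_id
            node = stree.node(best_id)
            node.edge.length *= long_multiplier
            for desc in node.preorder_iter():
                if desc is not node:
                    desc.edge.length *= long_multiplier
    return stree


# ---------------------------------------------------------------------------
# family evolution
# ---------------------------------------------------------------------------

def _random_protein(length: int, rng: np.random.Generator, background: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=background)
    return "".join(_AA_LIST[i] for i in idx)


def mutate_sequence(
    seq: str,
    retain_prob: float,
    rng: np.random.Generator,
    background: Optional[np.ndarray] = None,
) -> str:
    """Retain each site with probability ``retain_prob``; otherwise redraw
    the residue from the background distribution (may redraw the same one)."""
    if background is None:
        background = uniform_background()
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) >= retain_prob
    n_hit = int(hit.sum())
    if n_hit:
        repl = rng.choice(20, size=n_hit, p=background)
        arr[hit] = [_AA_LIST[i] for i in repl]
    return "".join(arr)


def evolve_family(
    tree: SpeciesTree,
    root_len: int,
    sub_rate: float,
    loss_rate: float,
    seed: int,
    background: Optional[np.ndarray] = None,
    family_id: str = "fam",
) -> FamilyTruth:
    """Evolve one family down the tree.

    Along a branch of length ``t`` the family is lost with probability
    ``1 - exp(-loss_rate * t)``; loss is irreversible (Dollo), so the walk
    never descends into a lost subtree and recorded loss branches form an
    antichain by construction.  If retained, each site substitutes with
    probability ``1 - exp(-sub_rate * t)``, the replacement drawn from the
    background amino-acid frequencies (so a fraction ``b(a)`` of substitution
    events are silent).
    """
    if root_len <= 0:
        raise ValueError("root_len must be positive")
    if sub_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    if background is None:
        background = uniform_background()
    rng = np.random.default_rng(seed)
    root_seq = _random_protein(root_len, rng, background)

    tip_seqs: Dict[str, Optional[str]] = {}
    losses: Set[str] = set()

    def walk(node_id: str, seq: str) -> None:
        for child in tree.children(node_id):
            t = tree.branch_length(child)
            if rng.random() < 1.0 - np.exp(-loss_rate * t):
                losses.add(child)
                for tip in tree.tips_below(child):
                    tip_seqs[tip] = None
                continue
            child_seq = mutate_sequence(seq, float(np.exp(-sub_rate * t)), rng, background)
            if not tree.children(child):
                tip_seqs[child] = child_seq
            else:
                walk(child, child_seq)

    root = tree.root_id
    if not tree.children(root):  # degenerate single-tip tree
        tip_seqs[root] = root_seq
    else:
        walk(root, root_seq)
    present = {t: True for t, s in tip_seqs.items() if s is not None}
    return FamilyTruth(family_id, root_seq, tip_seqs, losses, present)


def _substitute_exact(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    """Replace the given positions with residues guaranteed to differ."""
    arr = np.array(list(seq))
    for p in positions:
        choices = [a for a in _AA_LIST if a != arr[p]]
        arr[p] = choices[int(rng.integers(19))]
    return "".join(arr)


def make_bridge_family(
    length: int = 150,
    n_seed: int = 4,
    n_mid: int = 3,
    seed_identity: float = 0.95,
    mid_identity: float = 0.55,
    far_root_identity: float = 0.20,
    far_mid_identity: float = 0.55,
    seed: int = 0,
    background: Optional[np.ndarray] = None,
) -> Tuple[List[str], Dict[str, str]]:
    """A family with a divergence bridge for iterative-search experiments.

    Returns ``(seed_msa, targets)``: the seed MSA is a tight cluster around
    an ancestral sequence; the targets hold a small clade of mid-divergent
    homologs at exactly ``mid_identity`` to the ancestor (named ``mid1..``)
    and one far homolog sharing ``far_mid_identity`` with the mids but only
    ``far_root_identity`` with the ancestor.  Substitution counts are exact
    (not binomial), so the far homolog reliably sits beyond single-pass
    reach of the seed profile yet within reach once the mids are folded in.
    """
    if background is None:
        background = uniform_background()
    if not 0 <= far_root_identity <= far_mid_identity <= mid_identity <= 1:
        raise ValueError("identities must satisfy far_root <= far_mid <= mid <= 1")
    rng = np.random.default_rng(seed)
    root = _random_protein(length, rng, background)
    n_seed_sub = int(round((1 - seed_identity) * length))
    seed_msa = [
        _substitute_exact(root, rng.choice(length, n_seed_sub, replace=False), rng)
        for _ in range(n_seed)
    ]
    # mid clade: conserved at exactly mid_identity * length root positions
    n_cons = int(round(mid_identity * length))
    cons_mid = rng.choice(length, n_cons, replace=False)
    var_mid = np.setdiff1d(np.arange(length), cons_mid)
    mid1 = _substitute_exact(root, var_mid, rng)
    targets = {"mid1": mid1}
    for m in range(2, n_mid + 1):
        drift = rng.choice(length, max(1, int(round(0.05 * length))), replace=False)
        targets[f"mid{m}"] = _substitute_exact(mid1, drift, rng)
    # far homolog: keeps k1 of the root-conserved and k2 of the mid-specific
    # positions of mid1, everything else substituted away from mid1
    k1 = int(round(far_root_identity * length))
    k2 = int(round((far_mid_identity - far_root_identity) * length))
    keep = set(rng.choice(cons_mid, k1, replace=False)) | set(
        rng.choice(var_mid, k2, replace=False)
    )
    change = np.array(sorted(set(range(length)) - keep))
    targets["far"] = _substitute_exact(mid1, change, rng)
    return seed_msa, targets


# ---------------------------------------------------------------------------
# genome / proteome emission
# ---------------------------------------------------------------------------

def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate with uniform synonymous codon choice (standard code)."""
    codons = []
    for aa in protein:
        options = CODONS_BY_AA[aa]
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(DNA[i] for i in rng.integers(4, size=length))


def emit_genome_and_proteome(
    truths: Sequence[FamilyTruth],
    intergenic_len: int = 200,
    hide_fraction: float = 0.0,
    seed: int = 0,
) -> Tuple[Dict[str, Dict[str, str]], Dict[str, Dict[str, str]], pd.DataFrame]:
    """Emit per-taxon genomes and proteomes with controlled annotation gaps.

    Every present tip protein is reverse-translated and embedded on a random
    strand in a single contig per taxon, separated by random intergenic
    spacers.  A ``hide_fraction`` Bernoulli subset of embedded genes is
    omitted from the proteome (annotation failure) but kept in the registry.

    Returns ``(genomes, proteomes, registry)`` where genomes/proteomes map
    taxon -> {sequence id -> sequence} and the registry is a DataFrame with
    1-based inclusive coordinates and strand, one row per (family, taxon).
    """
    if not 0 <= hide_fraction <= 1:
        raise ValueError("hide_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    taxa = sorted({t for tr in truths for t in tr.tip_seqs})
    genomes: Dict[str, Dict[str, str]] = {}
    proteomes: Dict[str, Dict[str, str]] = {}
    rows = []
    for taxon in taxa:
        contig_id = f"{taxon}_c1"
        parts = [_random_dna(intergenic_len, rng)]
        pos = intergenic_len
        proteome: Dict[str, str] = {}
        for truth in truths:
            prot = truth.tip_seqs.get(taxon)
            if prot is None:
                rows.append((truth.family_id, taxon, "absent", False, "", 0, 0, ""))
                continue
            cds = reverse_translate(prot, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            embedded = cds if strand == "+" else revcomp(cds)
            start, end = pos, pos + len(embedded)  # 0-based half-open, forward strand
            parts.append(embedded)
            parts.append(_random_dna(intergenic_len, rng))
            pos = end + intergenic_len
            hidden = bool(rng.random() < hide_fraction)
            truth.in_proteome[taxon] = not hidden
            if not hidden:
                proteome[f"{taxon}|{truth.family_id}"] = prot
            rows.append(
                (truth.family_id, taxon, "present", hidden, contig_id, start + 1, end, strand)
            )
        genomes[taxon] = {contig_id: "".join(parts)}
        proteomes[taxon] = proteome
    registry = pd.DataFrame(
        rows,
        columns=["family", "taxon", "state", "hidden", "contig", "start", "end", "strand"],
    )
    return genomes, proteomes, registry


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

def simulate_pileup(
    ploidy: int,
    n_sites: int,
    mean_cov: float,
    error_rate: float = 0.0,
    het_density: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site base counts for a haploid or diploid sample.

    Coverage is Poisson(``mean_cov``).  For a diploid, a ``het_density``
    fraction of sites is truly biallelic with reads drawn 50/50 from the two
    alleles.  Each read is miscalled with probability ``error_rate``, the
    erroneous base uniform over the three alternatives.

    Returns a DataFrame with columns ``site, A, C, G, T``.
    """
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    if mean_cov <= 0:
        raise ValueError("mean_cov must be positive")
    for p, name in ((error_rate, "error_rate"), (het_density, "het_density")):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cov = rng.poisson(mean_cov, n_sites)
    ref = rng.integers(4, size=n_sites)
    counts = np.zeros((n_sites, 4), dtype=np.int64)
    if ploidy == 2 and het_density > 0:
        is_het = rng.random(n_sites) < het_density
    else:
        is_het = np.zeros(n_sites, dtype=bool)
    alt = (ref + rng.integers(1, 4, size=n_sites)) % 4
    alt_reads = np.where(is_het, rng.binomial(cov, 0.5), 0)
    ref_reads = cov - alt_reads
    np.put_along_axis(counts, ref[:, None], ref_reads[:, None], axis=1)
    # accumulate (alt may equal no other column since alt != ref)
    cur = np.take_along_axis(counts, alt[:, None], axis=1)[:, 0]
    np.put_along_axis(counts, alt[:, None], (cur + alt_reads)[:, None], axis=1)
    if error_rate > 0:
        true = counts.copy()
        for b in range(4):
            n_err = rng.binomial(true[:, b], error_rate)
            counts[:, b] -= n_err
            others = [o for o in range(4) if o != b]
            spread = rng.multinomial(n_err, [1.0 / 3] * 3)
            for j, o in enumerate(others):
                counts[:, o] += spread[:, j]
    df = pd.DataFrame(counts, columns=list("ACGT"))
    df.insert(0, "site", np.arange(1, n_sites + 1))
    return df


# ---------------------------------------------------------------------------
# k-mer sets
# ---------------------------------------------------------------------------

def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _contig_kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            yield canonical_kmer(kmer)


def sample_kmer_sets(
    genome: Union[str, Mapping[str, str]],
    k: int,
    read_cov: float = 30.0,
    dropout: float = 0.0,
    seed: int = 0,
) -> Tuple[Set[str], collections.Counter]:
    """Assembly k-mer set and read k-mer counts for a genome.

    Reads sample the full genome: every genome position contributes its
    canonical k-mer Poisson(``read_cov``) times, error-free.  The assembly is
    modelled as an imperfect reconstruction: a contiguous block covering a
    ``dropout`` fraction of each contig's k-mer positions is missing from it,
    so downstream k-mer completeness is ~``100 * (1 - dropout)``.
    """
    if isinstance(genome, str):
        genome = {"contig1": genome}
    if not 0 <= dropout <= 1:
        raise ValueError("dropout must be in [0, 1]")
    if any(len(s) < k for s in genome.values()):
        raise ValueError("k longer than the shortest sequence")
    rng = np.random.default_rng(seed)
    assembly: Set[str] = set()
    read_counts: collections.Counter = collections.Counter()
    for contig_id in sorted(genome):
        seq = genome[contig_id].upper()
        kmers = list(_contig_kmers(seq, k))
        n_copies = rng.poisson(read_cov, len(kmers))
        for kmer, c in zip(kmers, n_copies):
            if c:
                read_counts[kmer] += int(c)
        n_pos = len(seq) - k + 1
        n_drop = int(round(dropout * n_pos))
        if n_drop <= 0:
            assembly.update(kmers)
        else:
            start = int(rng.integers(0, n_pos - n_drop + 1))
            kept = []
            for i in range(n_pos):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                if not (start <= i < start + n_drop):
                    kept.append(canonical_kmer(kmer))
            assembly.update(kept)
    return assembly, read_counts
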