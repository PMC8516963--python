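# Methods

This note records the models, parameter choices, and numerical conventions
behind `phyloscreen`, and what the synthetic validation does and does not
demonstrate about real data.

## Profile model

A family profile is a position-specific log-odds matrix in bits. For
column *i* and residue *a*:

    f'_i(a) = (c_i(a) + α·b(a)) / (n_eff,i + α)
    s_i(a)  = log2(f'_i(a) / b(a))

* `c_i(a)` — weighted residue counts. Sequence weights are Henikoff
  position-based (each column distributes one unit of weight equally over
  its distinct residues, then over the sequences carrying each residue),
  normalised to sum to the number of sequences. Rationale: taxa-enriched
  alignments are phylogenetically redundant, and uniform weights would let
  a clade of near-duplicates dominate. Uniform weighting is available
  (`weighting="uniform"`).
* `b(a)` — background frequencies, uniform 1/20 by default and
  overridable. The simulator draws sequences from the same background, so
  uniform is the matched choice at desk scale.
* `α` — pseudocount weight, default 1.0. Background-proportional
  pseudocounts guarantee finite scores for α > 0; α → ∞ flattens every
  score to 0, α = 0 reproduces raw log-odds (−∞ for unseen residues, with
  a warning).
* Columns with more than 50% gap characters are dropped (majority-rule
  match-column assignment); the profile records the surviving column
  indices so hits can be stacked back onto the master alignment.

## Local alignment

Scoring is affine-gap Smith–Waterman against the profile columns: a gap
run of length *g* costs `gap_open + g·gap_extend` (defaults 4.0 and 0.5
bits), alignments start and end on a match state, adjacent gap runs in
both sequences are disallowed, and the score is floored at 0. Unknown
residues (X etc.) score 0 in every column. Traceback tie-breaks prefer
diagonal over profile-skip over sequence-skip, making results
deterministic. The kernel is numba-compiled; an exhaustive path-enumeration
reference implementation (`phyloscreen._reference`) validates it on all
small instances.

## E-values

Null calibration draws `n_decoys` i.i.d. background sequences of length
`decoy_len` (defaults 200 × 100; at least 100 decoys enforced), takes
their maximal local scores, and fits a Gumbel by maximum likelihood
(scipy). For a database of `N` residues:

    E(S) = (N / decoy_len) · exp(−(S − μ) / λ)

Degenerate decoy score sets (zero range or non-positive fitted scale)
raise a calibration error rather than returning meaningless E-values.

Calibration quality is checked as a distributional property: on fresh
decoys, the implied p-values `1 − exp(−exp(−(S−μ)/λ))` should be uniform.
This holds for profiles built from alignments of mixed divergence (the
shape an enriched alignment actually has, emulated with per-row identities
drawn from U(0.5, 0.8) and 500 calibration decoys in the validation
experiments). It fails for profiles of near-identical sequences, whose
two-valued score lattice is genuinely not Gumbel across the body of the
distribution — only the tail is, which is what the E-values use.

## Iterative taxa enrichment

Each iteration builds the profile from the current master alignment,
recalibrates, scores every not-yet-included target, and includes targets
with E ≤ the family's inclusion threshold (default 10⁻⁵ per database —
strict, to avoid profile drift; per-family overrides honour group-specific
cut-offs). Included hits are realigned to the profile through their
traceback and stacked as new rows; unmatched columns become gaps. The
included set is monotone non-decreasing, convergence is declared when an
iteration adds no new target id (scores may keep drifting), and
`max_iter` (default 10) bounds the loop; hitting it is flagged, not an
error. Alignments grow only by profile-trace stacking — no de novo MSA
construction.

The validation uses bridge families built with exact substitution counts
(ancestor → mid clade at 55% identity → far homolog at 20% identity to the
ancestor but 55% to the mids). Exact counts, rather than per-site
coin-flips, keep the far homolog reliably outside single-pass reach and
inside enriched reach; binomial identity scatter (±4–5 points at length
150) otherwise straddles the inclusion boundary in a fair fraction of
random draws.

## Absence cascade

Tier 1 searches the predicted proteome at the family threshold; tier 2
searches stop-free six-frame translations of the genome at the same
threshold (hits become `present_genome_only`); tier 3 searches both with
domain sub-profiles at the conventional relaxed E ≤ 10⁻³. Tier thresholds
are explicit configuration. A missing genome yields a proteome-only call
flagged `genome-unchecked`. Unassembled-read screening is folded into the
six-frame tier applied to whatever extra nucleotide input is supplied; no
read-level handling exists.

Six-frame segments never read through stop codons; codons containing an
ambiguous base translate to X (neutral in scoring), fully ambiguous codons
break the segment like a stop; segments shorter than `min_orf_len`
(default 25 aa) are discarded. Coordinates are 0-based half-open
internally and 1-based inclusive with an explicit strand column in every
written file.

Paralog counts: distinct qualifying proteome sequences (tier 1), or
non-overlapping genome intervals (tier 2) — greedy by descending bit
score, merging intervals that overlap more than 25% of the shorter one. A
long stop-free frame can contain several gene copies, so each segment is
re-scored after masking the matched stretch (up to 8 alignments per
segment).

## Dollo reconstruction

Under single-origin Dollo parsimony the minimal labeling is closed-form:
origin at the MRCA of the present tips, one loss on the branch to each
maximal subtree below the origin containing no present tip. No gains below
the root of the family are allowed; families suspected of multiple
independent acquisitions should simply be excluded from reconstruction.
`present_genome_only` counts as present — the gene exists; only the
annotation missed it — and stays separately flagged in reports.
Exhaustive enumeration over every labeled rooted binary tree with ≤ 6 tips
and every presence pattern (63,039 cases) confirms minimality.

BUSCO-style percentages round to the nearest integer, half away from zero,
which reproduces every published cell of the 245-protein metamonad
comparison (217 → 89, 207 → 84, ...).

## Ploidy and k-mer QC

Het-site rule, exactly as stated for the analysis it follows: sites with
coverage < 10× are ignored; a considered site is heterozygous iff at least
two distinct bases each have ≥ 2 reads. Minor-allele fraction uses the two
most frequent bases only.

The verdict must separate allelic signal from sequencing error: at 30×
coverage and 0.5% error, error doublets alone make ~0.3–0.4% of haploid
sites "heterozygous" under the two-read rule (≈ C(30,2)·(ε/3)²·3 per
site), which would swamp any het-fraction threshold near 10⁻³. Error
doublets, however, sit at minor-allele fractions near 2/coverage ≈ 0.07,
far from the balanced ≈ 0.5 of true diploid sites, so only *informative*
het sites — minor-allele fraction ≥ `balance_floor` (default 0.2) — enter
the decision: diploid iff the informative het fraction reaches
`het_frac_threshold` (10⁻³) *and* the informative histogram mode falls in
`balance_window` ([0.4, 0.5]); haploid iff the informative fraction is
below threshold; undetermined otherwise, or when fewer than 1,000 sites
are considered. The full 20-bin histogram over all het sites is always
reported, so the error peak remains visible.

K-mer completeness is `100·|solid ∩ assembly|/|solid|` with solid read
k-mers those counted ≥ `solid_min` (default 4 — a fixed integer rather
than histogram-valley detection, adequate at desk scale). The simulator
models an incomplete assembly by removing a contiguous block covering the
dropout fraction of each contig's k-mer positions, while reads sample the
whole genome; dropout 0 therefore gives exactly 100%, and dropout *d*
gives ≈ 100·(1−d). Canonical k-mers are the lexicographic minimum of a
k-mer and its reverse complement.

## Synthetic data: what it does and does not emulate

The simulator provides: a Yule-style rooted binary tree (exponential
branch lengths, mean 0.25 subs/site) with one flagged clade whose branches
are multiplied by a long-branch factor (default 2.0, in the 1.5–3×
range reported for fast-evolving metamonad lineages); Dollo gene loss
(per-branch probability `1 − exp(−loss_rate·t)`, sampled top-down so
losses form an antichain); per-site substitution (`1 − exp(−sub_rate·t)`,
replacement drawn from the background, so a fraction b(a) of events is
silent — the expected observed divergence is `(1 − exp(−rt))·19/20` under
the uniform background); reverse-translated genes (uniform synonymous
codon choice, standard code) embedded on random strands with random
intergenic spacers; a Bernoulli `hide_fraction` of annotation failures;
Poisson-coverage pileups; and k-mer multisets as above.

Not emulated: indels and alignment uncertainty, introns and spliced genes,
codon-usage and composition bias, rate heterogeneity across sites,
exchangeability structure (no substitution matrix — replacements are
background draws), paralogy beyond duplicated embeddings, contamination,
and read-level errors in the k-mer tables. Passing the validation suite
therefore demonstrates the machinery is correct and calibrated under the
generative assumptions, not that real divergent proteomes will be screened
with the same (near-perfect) recall; on real data, recall depends on
alignment quality and on how far true substitution processes depart from
these simplifications.

Default experiment sizes (8–12 taxa, 8–20 families of 120–150 residues,
20 seeds for stochastic recovery rates, 50,000-site pileups, 10-kb genomes
for k-mer checks) were chosen as the smallest scales at which the
recovered rates are stable against their own Monte-Carlo error.

## Determinism and the pipeline

Every stochastic step flows from an explicit integer seed (wall-clock
seeding is refused); per-family and per-iteration seeds are derived with a
CRC-based, process-independent hash. Outputs are written atomically and a
manifest of config/output hashes makes re-runs no-ops when nothing
changed. Validation findings (missing proteomes, unknown complex members,
malformed alignments) are reported as named findings and block execution
before anything is written.
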