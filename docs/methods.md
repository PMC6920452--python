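# Methods

## The randomization test

The core question — are haplotypes distributed independently of sampling
location? — is answered conditionally on both margins of the haplotype ×
location count table.  Conditioning matters: row totals differ because some
haplotypes are globally common and others are singletons, and column totals
differ because sampling effort varies by an order of magnitude between
locations.  An unconditional test would confound both with spatial
structure.  Random tables with the observed margins are sampled from the
multivariate hypergeometric (Fisher-exact) null with Patefield's AS159
algorithm, delegated to `scipy.stats.random_table(..., method="patefield")`.
This is a non-parametric alternative to the chi-squared approximation of
Fisher's exact test, which is unreliable for tables this sparse (most cells
are 0 or 1).

With M random tables (default 10,000), the per-cell null mean Z̄_ran is the
Monte-Carlo average, the whole-table statistic is the chi-squared distance
of a table from that mean, and two-tailed P-values are
2·min(N_≥, N_≤)/M with both tail counts inclusive.  Inclusive ties make raw
P > 1 possible; values are capped at 1.0.  One seeded stream of tables
serves the mean, the per-cell tail counts and the distribution of the
randomized whole-table statistic; the implementation materializes the
stream once (falling back to a literal two-pass regeneration of the same
seeded stream above a memory threshold), which is numerically identical to
two passes at half the sampling cost.

Numerical edge cases:

- All-zero rows/columns make chi-squared undefined; `drop_empty()` removes
  them with a warning before testing.
- In sparse tables a cell with tiny margins can receive no count in any of
  the M random tables, leaving a Monte-Carlo mean of exactly 0.  For those
  cells only, the exact conditional expectation r_i·c_j/N — the quantity the
  Monte-Carlo mean estimates — is substituted, keeping the statistic
  defined without perturbing well-estimated cells.
- An `analytic` ensemble mode fills the mean with r_i·c_j/N for all cells;
  in that mode the whole-table statistic is algebraically the textbook
  Pearson chi-squared, which the tests exploit as an independent oracle.
- Per-cell randomized TS_DIFF compares to the observed TS_DIFF exactly when
  the randomized count compares to the observed count, so cell tail counts
  are accumulated on raw integer counts — no floating-point tie issues.

The per-cell prose convention is that TS_DIFF > 0 marks over-representation
and TS_DIFF < 0 under-representation; direction is sign(TS_DIFF).
Benjamini–Hochberg runs jointly over all R×C cell P-values
(`statsmodels.multipletests`, cross-checked in the tests against a literal
step-up implementation).  The FDR defaults to 0.10 and is configurable.

## Null-model validation

The harness repeatedly (default 10,000×, desk scale 1,000×) generates
pseudo-observed tables under the null and re-runs the whole-table test on
each.  Pseudo-tables allocate the template's N observations independently to
cells with probability proportional to r_i·c_j (the independence null with
expected margins matching the template); a uniform-over-cells option is also
provided.  Realisations with an empty row or column — common when the
template contains singleton haplotypes, since a row with total 1 is empty
with probability ≈ e⁻¹ — are excluded and redrawn so the number of tests
stays fixed, and the exclusion count is reported rather than silently
absorbed.  Calibration is summarised by the rejection rate at α and by a
20-bin chi-squared statistic for rectangularity of the P-value histogram.
P-values at finite M are discrete (multiples of 2/M), so rectangularity
holds only up to that discreteness.

## Haplotype calling and pseudogene QC

Input sequences are same-locus amplicons assumed aligned by position; no
multiple alignment is performed, and unequal lengths are handled by trimming
every sequence to the shortest one's window (the studies being combined
sequence the same 548-bp COI region).  Haplotypes are exact-string
equivalence classes; N is a mismatch, so uncertain sequences never merge.
Labels Hap_01, Hap_02, … follow descending count then first occurrence, and
a user label map can impose an established catalogue.

NUMT/pseudogene screening follows the standard mtDNA battery: (1) premature
stop codons under the invertebrate mitochondrial translation table (TAA/TAG
are stops, TGA is tryptophan), ignoring the trailing partial codon and
allowing a terminator in the final complete codon; (2) amino-acid changes
relative to a reference haplotype classified by a fixed side-chain category
scheme (hydrophobic / small / polar / charged; a change is conservative iff
the residues share a category); (3) whether each distinguishing SNP recurs
in other haplotypes, since recurrent variants are unlikely to be one-off
PCR or NUMT artefacts.  The reading frame defaults to 0 and is
configurable — amplicon primers determine it and it is not knowable from
the sequence alone.

## Diversity estimators

Haplotype diversity uses the unbiased estimator h = n/(n−1)(1 − Σp²) with
Nei's (1987) eq. 8.12 sampling variance.  Nucleotide diversity is the mean
pairwise proportion of differing sites over all C(n,2) pairs, with sites
containing N excluded pairwise, and Nei's eq. 10.7 total variance (sampling
plus stochastic terms) — the convention of the DnaSP lineage of software,
with parity expected to ~2 significant figures, not bitwise.  Computing π
from the haplotype catalogue (count-weighted inter-haplotype distances) is
algebraically identical to the brute-force double loop; the tests assert
equality to 1e-12.  Distances are p-distances: at within-species COI
divergences (≲0.1%) parameter-rich substitution models agree with the
p-distance beyond any reported precision, so no other model is offered.

## Population structure

ΦST and AMOVA follow the standard distance-based framework (the Arlequin
convention): the number of pairwise sequence differences is used directly as
the squared distance in the sums-of-squares decomposition, strata are
individuals within populations within groups, and method-of-moments
variance components give Φ-statistics.  Negative components are reported as
computed and flagged, never truncated, so percentages always sum to exactly
100.  Permutation schemes: individuals across all populations for ΦST,
individuals among populations within groups for ΦSC, whole populations
among groups for ΦCT; P = (1 + #{Φ_perm ≥ Φ_obs})/(1 + n_perm), which keeps
P in (0, 1].  Populations of size 1 are retained with a warning (small
surveys legitimately contain n=2 countries), and singleton groups are
flagged as degenerate.  Exact numeric parity with third-party AMOVA
software is targeted to ~2 decimal places; its internal tie-breaking and
missing-data conventions are not fully published.

## Synthetic data

The generator emulates the features of a continental mtDNA COI survey that
the analysis is sensitive to, at the study's scale by default: 25
haplotypes × 11 locations × 226 individuals; a frequency spectrum with five
dominant haplotypes holding 80% of the mass in geometrically decaying
shares and the remainder spread over a rare tail (matching surveys where
~80% of individuals carry one of the five commonest haplotypes); uniform
sampling effort across locations unless weights are given.  Segregation is
a single parameter: per-location haplotype frequencies are drawn from
Dirichlet(global_spectrum / strength), so strength → 0 recovers the
independence null exactly and large strength gives near-fixed locations.

Sequences are 548-bp amplicons from a random ancestral open reading frame
with haplotype k carrying k−1 transition substitutions at distinct third
codon positions — synonymous by construction under the invertebrate
mitochondrial code, as in real COI surveys where variation is dominated by
silent third-position transitions.  Nested substitution sets guarantee
pairwise-distinct haplotypes; this makes inter-haplotype distances grow
linearly with haplotype index, which inflates synthetic π relative to the
star-like genealogies of real invasion data — synthetic π values are
therefore only compared against internal oracles, never against published
diversity levels.  NUMT-like decoys replace an individual's sequence, at a
configurable rate, with a copy carrying a premature stop at a random
internal codon, and are labelled in the metadata so QC sensitivity is
measurable.  One root seed drives everything; templates for validation runs
are drawn conditionally on every haplotype and location being observed,
because a real survey table has no empty rows by construction.

What passing on synthetic data does not show: robustness to alignment
error, indels, heteroplasmy, sequencing chemistry artefacts, or realistic
coalescent genealogies — none of which the generator models.

## Problem sizes

Defaults follow the published analysis scale (M = 10,000 randomizations,
10,000 permutations, 10,000 validation tests).  The shipped test suite and
the acceptance script run the validation harness at 1,000 tests × 1,000
randomizations and the unit oracles at toy sizes, chosen so the whole suite
completes in a few minutes on a laptop core while binomial error on a
rejection-rate estimate (SE ≈ 0.007 at n=1,000) stays well inside the
3-SE acceptance bands.

## Known limitations

- The study's supplementary inputs (the 25×11 count table, the combined
  314-sequence alignment) are not redistributable here; checks against
  printed values activate only when a user supplies those files under
  `data/`.
- The whole-table P-value is a Monte-Carlo estimate; P = 0.000 means "no
  random realisation as extreme in M draws", i.e. P < 1/M, not literal zero.
- The two-tailed min-tail definition is the only tail rule implemented (no
  mid-P), matching the procedure being reproduced.
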