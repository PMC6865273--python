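# Methods

## The analysis model

The package operationalises one question in four settings: is a feature gene
set F (canonically the minor-intron-containing genes, MIGs) over-represented
in a query gene set Q relative to a background universe U?

Every test reduces to a 2×2 contingency table with margins
N = |U|, K = |F ∩ U|, n = |Q ∩ U|, k = |F ∩ Q ∩ U|. Under the null that Q is
an unstructured draw from U, k is hypergeometric(N, K, n). The two-sided
p-value is Fisher's exact test with the minimum-likelihood rule: the sum of
P(X = x) over every x in the feasible support whose point probability does
not exceed P(X = k). Point probabilities are computed with log-space
factorials (`scipy.special.gammaln`), which keeps N ≈ 20,000 tables accurate
to well over 10 significant digits; a relative tie tolerance of 1e−7 guards
the ≤ comparison against floating-point near-ties. Degenerate margins
(n = 0, K = 0, K = N, n = N) have a single-point null and return p = 1. No
normal approximation is used at any size.

Two background conventions exist in the literature: the query counted as part
of the universe (`universe_includes_query`) or removed from it. The 2×2 cells
are identical either way; only the reported background fraction differs
(K/N vs (K−k)/(N−n)). The package defaults to `universe_includes_query`,
which is the convention that reproduces the published domestication-gene
p-values (0.0535 and 0.0067) from their printed margins — this was verified
numerically, and it also settles that those tests were two-sided (the
one-sided value for the human table is 0.032, which would not have been
reported as non-significant).

Fold enrichment is (k/n)/(K/N) on unrounded fractions; `fold_from_fractions`
additionally re-derives one-decimal fold reports from pre-rounded percentage
pairs, matching how such numbers are quoted. Raw p-values are the default
throughout; Benjamini–Hochberg adjustment across a control battery is
available but off, since the batteries are small and the convention in this
literature is raw p.

## Essentialome construction

Inputs are gene × cell-line matrices, either continuous gene-effect scores
(lower = more essential) or pre-called 0/1 essentiality. Score matrices are
binarized as call = 1 iff score ≤ t with the threshold t mandatory — there is
no defensible universal cutoff, so the package never supplies one silently.
The boundary is inclusive. Missing scores produce missing calls, and a
missing call never counts as essential: zero-filling would fabricate
non-essential (or essential) observations.

Per-line essentialomes are the call = 1 genes of each line. The total
essentialome is their union, the core the intersection, and the majority
essentialome keeps genes essential in at least ⌈f·L⌉ of L lines (ceiling,
because "at least 95% of lines" is a lower bound — for f = 0.95 and L = 341
the integer cutoff is 324). Group essentialomes are unions within groups of
lines sharing a label; union is the natural reading of "combining"
essentialomes of related lines, and per-group majority recomputation can be
obtained by subsetting the matrix if wanted. Nesting core ⊆ majority(f) ⊆
majority(f′) ⊆ total for f′ ≤ f holds by construction and is property-tested
against a brute-force per-gene counting oracle.

## Gene age

Ages come from ortholog-group membership tables (gene → {(group id, clade)}),
resolved against an ordered clade ladder. A gene's age is the *oldest* clade
among its groups. The default ladder is Eukaryota (one rung collapsing LECA
and everything earlier), Opisthokonta, Metazoa, Eumetazoa, Bilateria,
Deuterostomia, Chordata, Euteleostomi, Amniota, species-specific, with the
ancient/younger boundary at Eukaryota. The ladder is configuration, not code:
ortholog databases differ in their level sets across versions, so users can
supply any ordered ladder plus boundary (YAML reader provided).

Genes with no ortholog group at all are placed in the youngest rung and
flagged `unassigned`: absence of detectable orthologs is the standard
phylostratigraphic signal of recency, but because it is also produced by
annotation failure, a `strict` mode excludes such genes from the
ancient/younger partition entirely.

Age-stratified enrichment restricts universe, query and feature to one
stratum before testing. When no gene is unassigned, the ancient and younger
stratified tables sum cell-wise to the unstratified table (tested).

## Cell-cycle expression

Expression tables are gene × (stage, replicate) TPM with the fixed stage
order early G1 → late G1 → S → G2/M. A gene is expressed in a stage when its
replicate-mean TPM ≥ 1 (inclusive); a stricter all-replicates mode exists.
Raising the threshold can only shrink the expressed-in-some and
expressed-in-all sets (tested monotonicity).

Differential expression between successive stages uses Welch's two-sample
t-test on log2(TPM+1) across replicates at α = 0.05, with a gene called DE
if any of the three stage transitions is significant. The published analysis
this mirrors does not name its DE procedure, so Welch-on-log2 is this
package's explicit stand-in: it is the simplest test consistent with
per-transition p-values on replicated TPM, and its operating characteristics
are established here by simulation (calibration near α per transition;
sensitivity ≈ 1 for 4-fold steps at 5% replicate CV and 3 replicates) rather
than by matching any published DE count. Note that testing three transitions
per gene at raw α = 0.05 implies a per-gene false-positive rate near
1 − 0.95³ ≈ 14% under the null — much higher than published stable-expression
counts obtained with stricter methods; users wanting gene-level control
should adjust across transitions. For tables without replicates a
fold-change-only rule (|log2 ratio of stage means| ≥ log2 threshold) is
provided and reports no p-values.

## Domestication overlap and gain events

CDG sharing counts genes present in ≥ k (or exactly k) of the per-species
lists; sharing is monotone in k by construction. MIG enrichment among CDGs is
tested against a *fixed printed background* — 648 MIGs of 20,444
protein-coding genes — supplied as counts rather than as a gene universe,
because the genome-wide gene list is not among the inputs; this background is
deliberately distinct from the CRISPR-screen universe used everywhere else.

Minor-intron gain events: paralogous MIGs that form one minor-intron-rich
family descend from a single ancestral insertion, so each family with at
least one member present collapses to one event and the count is
(genes outside any family) + (families hit). The count never exceeds the gene
count and equals it exactly when no family has two or more present members
(tested). Families must be disjoint; members absent from the input list are
ignored with a warning.

## Synthetic data generator

The generator exists so that every stage has a no-download test bed with
known truth. Defaults describe the emulated study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes | 17,000 | interrogated universe size (screen-library scale) |
| mig_fraction | 0.035 | MIG share of interrogated genes (~595 MIGs) |
| clade_probs | 0.668 ancient | age distribution; remainder over younger rungs |
| mig_family_sizes | (3, 2, 2) | minor-intron-rich families planted among MIGs |
| n_lines | 50 | cell lines screened |
| base_essential_rate | 0.10 | consensus essentiality rate of non-MIG, non-ancient genes |
| planted_odds_ratio | 2.5 | MIG multiplier on consensus essentiality odds |
| ancient_odds_multiplier | 1.5 | ancient genes are more often essential |
| dropout_rate | 0.02 | per-line chance an essential gene is missed |
| spurious_call_rate | 0.0002 | per-line chance a non-essential gene is called |
| n_replicates / replicate_cv | 3 / 0.05 | TPM replicates and noise level |
| tpm_log2_mean / sd | 3 / 2 | log-normal baseline expression |
| de_fraction / de_fold | 0.01 / 4 | planted step DE genes and effect size |
| species / cdg_sizes | 5 / human-heavy | CDG list sizes (union ≈ 1,386) |
| n_shared_two / n_shared_three | 45 / 6 | planted 2-/3-species shared CDGs |
| planted_cdg_mig_odds_ratio | 1.5 | MIG weighting of CDG sampling |

Essentiality is generated as a per-gene latent consensus (odds =
base × ancient multiplier × MIG odds ratio, optionally per age stratum)
corrupted per line. The corruption is deliberately asymmetric: essential
genes drop out of individual lines at 2% while non-essential genes acquire
spurious calls at 0.02%. Dropout is what separates core ⊂ majority ⊂ total;
the spurious rate is kept two orders smaller because the union (total
essentialome) accumulates false positives across all L lines — a symmetric
2% flip would give non-essential genes a 1 − 0.98⁵⁰ ≈ 64% chance of entering
the total essentialome at L = 50, destroying the planted odds ratio. With
the asymmetric defaults the odds ratio estimated from the total essentialome
is mildly attenuated (≈ 2.8 for a planted 3.0 at default scale) but
recoverable within ±25%, which the acceptance suite verifies.

CDG lists are sampled without replacement with MIG-proportional weights; the
planted 2-/3-species shared genes are assigned to random species and all
filler genes are dealt disjointly, so the planted sharing is recovered
exactly rather than approximately. Expression tables share one log-normal
baseline across stages per gene, apply the planted fold as a step at one
random stage boundary, and add multiplicative log-normal replicate noise.

What the generator does *not* emulate: the marginal score distributions of
real screens (there are no continuous scores at all — calls are generated
directly), correlated essentiality between related cell lines, compositional
TPM constraints, dispersion–mean trends in expression noise, or symbol drift
between species gene lists. Tests passing on synthetic data therefore
establish the correctness and calibration of the statistics and set algebra,
not the field validity of any biological conclusion drawn from real data.

All generators are pure functions of (config, seed) built on numpy's PCG64;
the same seed reproduces identical output across platforms.

## Problem sizes and numerical choices

The test suite runs its Monte Carlo suites at these sizes: null calibration
at 2,000 genes × 10 lines × 1,000 replicates; odds-ratio recovery at the full
default 17,000 genes × 50 lines × 200 replicates; stratum specificity at
6,000 genes × 12 lines × 200 replicates; control batteries at the full
default scale × 200 simulations. The exhaustive Fisher validation covers
every 2×2 table with N ≤ 60 (635,375 tables) against an exact
integer-combinatorics enumeration oracle at 1e−12 absolute, with scipy's
`fisher_exact` as a second, independent cross-check on sampled tables.

Ties in the minimum-likelihood rule use a 1e−7 relative tolerance; the
enumeration oracle applies the same rule in exact integer arithmetic.
Identical replicate vectors give a zero-variance Welch test (NaN p), which is
reported as not DE — identical data is no evidence of change. Empty gene
lists are legal everywhere set algebra is concerned (an empty essentialome,
an empty restriction) and are errors only where a statistic would be
undefined (fold with an empty margin, an empty stratum universe).

## Known limitations

- The essentiality call threshold for score matrices is user-supplied by
  design; published headline essentialome sizes cannot be reproduced without
  the original calls and are treated as documented expectations only.
- Gene-age percentages depend on the ortholog database version behind the
  membership tables; the package fixes only the algorithm (oldest clade
  wins), not the annotation source.
- The DE method is a stand-in (see above); real FUCCI RNA-seq analyses with
  other methods will produce different DE counts.
- Cross-species CDG comparison assumes the inputs are already mapped to a
  shared symbol space; only a user-supplied alias map is applied, no ortholog
  resolution.
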