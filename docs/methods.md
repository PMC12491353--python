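# Methods

This note records the statistical models implemented, the defaults and why,
the numerical choices, and what the synthetic-data generator does and does
not emulate.

## Data model

A haplotype table holds one profile per male: a sample id, a population
label, and one allele (decimal repeat count) per panel position.  The
default panel is the 17-position Yfiler set over 16 locus labels; DYS385 is
a constitutively duplicated locus whose two copies cannot be phased by the
assay, so the pair is stored sorted ascending and every per-copy operation
uses that sorted order deterministically.  Missing data has a single
representation: the input sentinel `99` and empty cells both map to a
flagged missing allele.  Legal microvariant fractional parts are .1/.2/.3;
both `.` and `,` decimal separators are accepted and normalised.

DYS389II is stored **raw**.  The familiar display convention reports
DYS389II as the difference raw − DYS389I; that encoding is provided as an
explicit, flag-guarded transform used for allele-frequency reporting, and
is never applied inside distance computations by default.  Because no
convention is universal in published tables, the distance layer exposes
four switch combinations (DYS385 in/out × DYS389II raw/encoded), plus
face-value vs rounded microvariants.

## Forensic parameters

With haplotype counts c₁…c_h over n males and pᵢ = cᵢ/n:

- HD = n(1 − Σpᵢ²)/(n − 1) (Nei); HMP = 1 − HD; MP = Σpᵢ².
- DC = h/n; FUH = 100 × singletons/h.  FUH is defined on distinct
  haplotypes (not on males); the reporting layer also prints the
  alternative ratios singletons/n and h/n so ambiguous published values can
  be compared directly.
- Per-locus gene diversity uses allele frequencies over non-missing calls,
  with DYS385's two copies pooled into one spectrum (haploid n doubles).
  The mean GD over loci defaults to the unbiased n/(n−1) form (the STRAF
  convention); the SD uses the sample (n−1) denominator.
- Haplotype frequencies are printed under both conventions in use in the
  literature — count/n ("counting method") and count/h — labelled
  explicitly.
- Haplogroup composition percentages are **truncated** (floored) to two
  decimals, matching the reporting convention of the forensic haplogroup
  tables this mirrors (76/128 → 59.37%, not 59.38%).
- Profiles with missing alleles stay in the haplotype spectrum (missing is
  distinct from every real allele), keeping DC/HD defined on incomplete
  data; a strict mode drops incomplete profiles instead.

## Distances, pairwise differences, AMOVA R_ST

The microsatellite distance between two haplotypes is Σ (aᵢ − bᵢ)² over
included positions; DYS385 contributes its two sorted positions.  A locus
missing in either profile contributes 0 to that pair (pairwise deletion,
logged); strict mode removes incomplete profiles up front.  Microvariants
enter at face value by default (17.2 vs 17 contributes 0.04), because
rounding discards information; a switch rounds first.

PiX is the mean distance over all n(n−1)/2 within-population pairs; PiXY
the mean over all n_A·n_B cross pairs; corrected = PiXY − (PiX + PiY)/2.
Two-level AMOVA on a pair of populations uses

    SSD_total = (1/N) Σ_{i<j} d_ij,   SSD_within = Σ_p (1/n_p) Σ_{i<j∈p} d_ij,
    MS_among = SSD_among/(P−1),       MS_within = SSD_within/(N−P),
    n_c = (N − Σn_p²/N)/(P−1),
    σ²_w = MS_within,  σ²_a = (MS_among − MS_within)/n_c,
    R_ST = σ²_a/(σ²_a + σ²_w).

R_ST is invariant to adding a constant to a locus and to multiplying repeat
counts by a constant, and may be slightly negative in balanced samples (for
exactly duplicated populations the estimate is −1/(n−1)); negative values
are reported as computed.  Zero total variance is flagged and reported as
R_ST = 0.  AMOVA permutation p-values are out of scope (none are needed by
the downstream analyses).

## Ordination

Classical MDS eigendecomposes −½·J·D²·J and takes the top-k non-negative
eigenvalues; it inverts Euclidean-embeddable matrices to machine precision
and reduces k with a warning otherwise.  Axis signs follow a deterministic
convention (first nonzero coordinate positive); coordinates are centred.

Nonmetric MDS is SMACOF with isotonic disparities: each iteration fits a
monotone regression of configuration distances on dissimilarity ranks,
rescales disparities to Σd̂² = Σd², and applies a Guttman transform.
Stress-1 = sqrt(Σ(d̂ − d)²/Σd²) is reported ×100 (the percent-style
convention).  The default initialisation is the classical solution, making
the solver deterministic; random restarts are available via a seed.
Convergence: stress decrease < 1e−7 or 300 iterations (returned with
`converged=False`).

Hierarchical clustering defaults to average linkage (UPGMA), with
complete/Ward/single available; heights are nondecreasing, the Newick
export uses half merge distances as ultrametric node heights, and `cut(k)`
returns exactly k clusters.  Negative distance entries (possible for R_ST)
are floored at 0 before any ordination, with a log note.

## Median-joining networks

Network input preprocessing follows the conventional Y-STR workflow:
alleles rounded to nearest integer (ties half away from zero — a case that
cannot arise from validated .1/.2/.3 microvariants but is defined for
robustness), DYS385 excluded, missing excluded locus-wise from every
comparison.  Haplotypes at mutual distance 0 after reduction are collapsed
so all edges have positive weight.

The per-locus step distance is |a − b| with uniform weights by default
(locus weights are exposed; no published setting is assumed).  The
ε-relaxed minimum spanning network contains edge (u,v) iff
w(u,v) ≤ bottleneck(u,v) + ε, where the bottleneck is the largest edge on
the MST path — ε = 0 is exactly the union of all MSTs and large ε tends to
the complete graph.  Median vectors come from connected triples, taking the
per-locus statistical median of three integers (the ordered-character
generalisation of the binary majority rule); with one value missing the
present majority is copied, and two unequal present values yield missing.
Medians are added greedily while they strictly reduce the MST cost of the
node set, capped at 12 generations (non-termination guard), then median
nodes whose removal leaves the cost unchanged are pruned to a fixpoint.
All tie-breaks are lexicographic on haplotype vectors, so the construction
is deterministic and seed-free.  The network's `total_length` is the MST
cost over its final node set; it never exceeds the MST over observed
haplotypes alone, and on small fixtures it matches an exhaustive Steiner
search.

## Allelic richness

Distinct-allele rarefaction: α̂_g = Σᵢ [1 − C(N−Nᵢ, g)/C(N, g)] with
C(a,b) = 0 for a < b; private-allele rarefaction multiplies each presence
probability by the absence probabilities in all other populations.
Binomial ratios are computed with log-gamma arithmetic.  The g grid runs
from 2 to the smallest per-(population, locus) sample size; population
grouping (e.g. regions onto countries) is a user-supplied mapping, since no
canonical grouping exists.  Rarefaction variances are omitted by default
(the Monte-Carlo machinery used to validate the formulas lives in the test
suite).

## Ancestry variability (F_ST/F_ST^max)

For a population's Q-matrix block with column means p̄:

    F_ST = (meanᵢ Σ_k q_ik² − Σ_k p̄_k²) / (1 − Σ_k p̄_k²).

F_ST^max is the maximum over all row-stochastic matrices with the same
column means, computed by vertex concentration: ⌊I·p̄_k⌋ rows go wholly to
cluster k; the remaining fractional column masses (each < 1, so at most
K−1 mixed rows) are packed by a sequential fill, taking the best packing
over orderings of the residual columns.  Plain descending-order filling is
not always optimal (e.g. residuals 0.9/0.9/0.2 pack better when the small
column is split), which is why all orderings are tried for K ≤ 7; the
construction is verified against an SLSQP numeric maximiser in the tests.
Degenerate blocks (all mass on one vertex) define F_ST = F_ST^max =
ratio = 0.  The bootstrap resamples rows with replacement within each
population (default B = 100, seed required in the CLI); B = 0 returns the
point estimate only.  Group comparison uses the tie-corrected
Kruskal–Wallis H with df = groups − 1.

## Haplogroup prediction

A naive-Bayes classifier over per-locus allele frequencies:
P(a | hg, locus) = (count + α)/(N + α(V + 1)) with support V = alleles
observed at that locus across the reference plus one unseen bucket, prior
from reference label counts (or uniform), posterior computed in log space,
ties broken alphabetically, missing loci skipped, and a uniform fallback
when no locus is usable.  α defaults to 0.5 (Jeffreys-style) and is echoed
in output metadata.  No claim is made of matching any particular online
predictor's assignments; reference panels are user-supplied (the bundled
defaults are synthetic).

## Synthetic data

The generator is a stepwise mutation model: each individual draws a founder
lineage by proportion, copies its haplotype, and accumulates ±1-step
mutations with probability μ per locus per generation over a genealogical
depth drawn geometric(mean = depth).  Defaults are study-shaped: one
population of 128 males; lineages J1a/E1b1b/Other at 59/21/20%;
μ = 0.002 per locus per generation (the field-standard average Y-STR
rate); mean depth 50 generations, which yields star-like clusters (most
haplotypes 0–2 steps from their founder).  A microvariant rule adds the
".2" offset at DYS458 to every J1a male and 15% of "Other" males, giving
~60% prevalence concentrated in the dominant lineage.  Population
divergence is modelled by drifting each population's founder copies
independently for `divergence_depth` generations.  Q matrices are rows
i.i.d. Dirichlet(α_pop).  Everything is byte-reproducible under a seed.

What the generator does **not** emulate: real per-locus mutation-rate
heterogeneity (all loci share μ), multi-step mutations (off by default),
allele-range constraints, locus dropout patterns, or the correlation
structure of real haplogroups.  Passing tests on simulated tables
demonstrate the estimators' correctness under the stepwise model, not the
biological accuracy of any particular published value.

## Problem sizes used in the packaged checks

The packaged property checks use sizes chosen to make their oracles exact
or statistically decisive: exhaustive Steiner search on ≤5 haplotypes × ≤3
loci; rarefaction enumeration on spectra of ≤9 alleles and Monte-Carlo
validation at 10⁴ subsamples (3 SE); F_ST^max vs SLSQP on I ≤ 6, K ≤ 3;
R_ST divergence ordering on 2 × 50 males at depths 0/20/80 with μ = 0.01
over 10 replicates.  The divergence experiment deliberately uses a higher
μ and fixed shallow depths than the study-shaped defaults so that the
between-population signal is identifiable at these sample sizes.

## Known limitations

- AMOVA is two-level (pairwise populations); no hierarchical
  region/population design and no permutation significance.
- The median-joining implementation targets STR (ordered multistate) data
  only; no maximum-parsimony post-processing or rho dating.
- The supplementary regression values of the reference study require its
  full haplotype table, which is not redistributable here; the test that
  consumes it reports exactly what is missing.
- STRUCTURE inference itself is out of scope: Q matrices are inputs
  (read or simulated), and only their downstream variability statistic is
  computed.
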