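# Methods

This note documents the models implemented in `uniparent`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Data model and coordinates

All analyses operate on aligned haploid sequences with an explicit 1-based
reference coordinate per column. mtDNA coordinates follow the rCRS
(16,569 bp); MSY variant positions use genome (GRCh38) coordinates. Legal
states are `A/C/G/T/N/-`; IUPAC ambiguity codes are rejected at read time
because heterozygous calls violate the haploid contract. `N` and `-` are
ignored pairwise in every distance and diversity computation.

Site handling:

* **Coverage filter.** Sites are retained when their total depth summed
  across individuals lies in the inclusive window `[mean/2, 2·mean]`, the
  mean taken over all sites in the coverage vector. Bounds are compared as
  reals and only rounded for display. The filter is invariant under uniform
  rescaling of depths.
* **Masks.** Single-site hotspot exclusions, inclusive excluded intervals
  (e.g. the 941–942 insertion region) and an inclusive retained region
  (e.g. the mitochondrial coding region 577–16,023) compose by union;
  masking with A then B equals masking with A∪B. The packaged hotspot list
  (`data/mtdna_hotspots.tsv`) covers the classic length-heteroplasmy tracts
  and hypervariable sites and is user-replaceable, since published analyses
  rarely enumerate their exact exclusion lists.

## Haplogroup classification

A haplogroup tree is a rooted hierarchy whose nodes carry *required* derived
variants (position + allele) and optionally *forbidden* variants (for sister
clades defined by the absence of a marker). A child's effective motif is the
union along its root path. Classification is a deterministic deepest-match:
ties at equal depth break by number of matched variants, then lexicographic
name; an unmatched sequence receives the root call with origin
"unassigned". Origin labels (South Asian / European / West Asian /
unassigned) inherit from the nearest labelled ancestor.

The packaged trees seed the named Roma-relevant lineages. Only the
sub-lineage motifs published in the open literature (M5a1b1a = 3954T+9833C,
M5a1b1a1 = +16298C, M5a1b1a2 = +15902C without 16298C,
H107 = 1271G+3621C+16223T, and the Y sub-branch tagged by 26618569C) are
real; backbone nodes carry clearly commented abbreviated tags because their
full SNP sets are not openly enumerated. The classifier itself is
tree-agnostic — swap in a full reference tree for production calls.

**Sub-branch discovery** enumerates, inside each haplogroup, the (position,
allele) pairs whose carrier set (i) has at least `min_carriers` members,
(ii) is confined to that haplogroup, and (iii) is absent from the remainder
of the dataset and an optional reference panel. Variants with identical
carrier sets merge into one candidate branch; nesting between carrier sets
is reported via parent links. This is an exhaustive column scan, feasible
because uniparental alignments are small.

## AMOVA and Φst

Molecular variance is decomposed from squared pairwise differences
(`d² / 2n` sums — the convention of the standard AMOVA software), one-level
(populations) or two-level (groups / populations / samples). Variance
components come from the usual mean-square equations with the sample-size
coefficients n, n′, n″; the Φ statistics are

* Φ_ST = (σ²a + σ²b) / σ²total (one-level: σ²b / σ²total),
* Φ_CT = σ²a / σ²total,
* Φ_SC = σ²b / (σ²b + σ²c).

Negative components are retained in the reported raw components; the
percentage view floors them at zero before normalising to 100% (both views
are emitted because published tables rarely state which convention they
use). Permutation nulls: samples among populations for Φ_ST; whole
populations among groups for Φ_CT; samples among populations within their
group for Φ_SC. p-values use +1 smoothing, `p = (#null ≥ obs + 1)/(B + 1)`,
with B = 10,000 by default (chosen for uniformity with the Mantel default).
An exact mode enumerates all label rearrangements for small n; tests verify
that the Monte-Carlo p converges to the exact one and that the test is
calibrated (5% rejection at α = 0.05) under a simulated null.

Pairwise Φst between populations is the among-population fraction of a
two-population AMOVA on the corresponding sub-matrix, floored at zero so the
matrix remains distance-like; pairs of two singleton populations have no
within-population variance and are reported as missing.

The three grouping scenarios follow the study design: *combined* runs a
one-level AMOVA over country-by-route populations; *country* and *route*
run nested designs with the respective label as the stratum above those
populations. `subsample_balance` draws a seeded uniform subset (the study
uses k = 15 for its largest group) to balance sample sizes.

## MDS, Mantel, contingency tests

Classical MDS double-centers −½·J·D²·J and eigendecomposes; coordinates are
the leading eigenvectors scaled by √λ, exactly centered; negative
eigenvalues are reported but their axes dropped. The Mantel statistic is the
Pearson correlation of upper-triangle entries with a simultaneous
row/column permutation null, **two-sided** (sidedness is rarely stated in
published tables; the signed r is reported, not an R²) and +1-smoothed, with
an exact enumeration mode for small matrices. Both are short numpy
implementations kept in-package for exact seed control; tests cross-check
them against scikit-bio's `pcoa` and `mantel`. χ² independence tests use
`scipy.stats.chi2_contingency` with continuity correction off by default
(matching the common R default for r×c tables); zero-margin rows/columns
are dropped with a record, low expected counts are flagged and a Fisher
exact p is attached for 2×2 tables.

## Median-joining networks

Distinct haplotypes over the variable sites form the initial nodes (sites
containing `N`/`-` are excluded by default, or majority-imputed with
`missing="impute"`). The construction iterates: (1) build the ε-relaxed
minimum spanning network — at every component-merge step admit all links
within ε of the minimal feasible length (ε = 0 by default); (2) for node
triples with at least two linked pairs, propose the per-site
majority-consensus median, resolving three-way ties toward the first node
in deterministic order; accept a median only if it strictly shortens the
minimum spanning length of the node set; (3) prune latent nodes that no
longer shorten it; repeat to fixpoint. The output graph is the ε-relaxed
MSN over the final node set with per-edge mutational lengths and site
changes.

Notes: published "reduced median" and "median-joining" algorithms differ;
this package implements median-joining with a spanning-length (Steiner)
rule for admitting medians, which on the classic three-site, four-haplotype
example infers exactly one median and achieves the exhaustive-search
Steiner minimum (total spanning length 5). With no accepted medians the
output is exactly the minimum spanning network.

## Rho dating

ρ is the carrier-weighted mean shortest-path mutational distance from a
user-designated root (root choice is explicit because rooting comes from
external phylogenetic context, not from the network itself). The error uses
a Saillard-style estimator on a deterministic shortest-path tree
(predecessor ties broken by node-name order): σ² = Σ_links w·(n_link/n)²,
so a star of n singleton tips gives σ = 1/√n. Age = ρ × clock, linear in
the clock constant. Packaged clocks: mtDNA coding region 3,533
years/substitution; MSY 115 years/mutation as printed in the uniparental
literature for a 8.97 Mb callable region at 10⁻⁹ substitutions/site/year —
note the arithmetic 1/(rate × length) gives 111.5, so `msy_clock(strict=True)`
selects the derived value while the printed constant remains the default
for comparability.

## The synthetic-data generator

`synthetic_data.simulate` is a discrete-generation forward Wright–Fisher
simulator of a haploid marker:

* a founding population of `founder_size` lineages drawn round-robin from
  `n_founder_lineages` divergent founder haplotypes (default 4 lineages,
  ~25 private substitutions each — several divergent founder lineages, as a
  serial founder history produces);
* each generation every individual copies a uniform parent from its group,
  is replaced by a fixed external-pool haplotype with probability `m`
  (origin label recorded), then gains Poisson(μL) substitutions at uniform
  sites (finite sites, back-mutation possible — the estimators consume
  finite alignments, so an infinite-alleles shortcut would be unfaithful);
* optional fission into named migrant groups at scheduled generations,
  each group thereafter a constant-size population (no growth model is
  assumed; an exponential `growth_rate` flag exists to produce star-like
  networks);
* `sample_size` draws a uniform subsample of the final generation.

Defaults mirror the study conditions: G = 50 generations, mtDNA length
16,569; MSY scaled to 10⁵ sites standing in for the ~9 Mb callable region.
Per-generation mutation rates derive from the year-based clocks (mtDNA
coding 1.708×10⁻⁸, MSY 10⁻⁹ substitutions/site/year) times a 29-year
generation. Demo and example scripts override length/μ downwards to keep
alignments desk-sized while preserving the demographic structure; the
methods they exercise are scale-free.

What the generator does **not** emulate: donor-pool evolution (external
haplotypes are fixed at start — the simplest model consistent with constant
flow), selection, recombination (both markers are non-recombining),
population growth by default, heteroplasmy/sequencing error, and realistic
site-rate heterogeneity (hotspot masking is therefore exercised with
configured masks, not emergent rate variation). Passing tests show the
estimators recover parameters of this idealized demography; they do not
certify robustness to the additional noise of real sequence data.

A point that matters for interpreting recovery tests: in a finite
Wright–Fisher population the realized founder fraction drifts around
(1−m)^G with variance accumulated as V′ = (1−m)²(V + p(1−p)/N) per
generation — at N = 2,000 and G = 50 the drift s.d. (~0.042) dwarfs the
binomial sampling s.d. of the same number of lineages. Tests that compare
the realized fraction with the closed form therefore use this full
variance, and the gene-flow recovery suite simulates a large background
population (10⁵) sampled at n = 500 so that the sampling noise quantified
by the per-sample bootstrap dominates drift. The recovery suite's problem
sizes (200 replicates, 24-site marker, μ = 10⁻⁶) reflect that only the
origin labels — not the sequences — carry information about m.

## Gene-flow model

`rate_from_fraction` inverts geometric survival, m = 1 − f^(1/G);
`fraction_from_rate` is the forward direction. The additive alternative
m = (1−f)/G is provided but non-default — geometric survival is what
"constant per-generation replacement" means, and it reproduces the standard
worked value (f = 0.25, G = 50 → m = 2.73%) exactly. Note that a paternal
fraction of 0.49 gives 1.42%/generation while 0.50 gives 1.38%; published
summaries that print 1.38% alongside a 49% South Asian MSY proportion have
evidently rounded f to one half — the package always computes from the
supplied f rather than hard-coding either constant. Confidence intervals
are seeded percentile bootstraps over samples (default 1,000 resamples);
an empty founder count in a resample is floored at half a count so the
transformed rate stays finite.

## Determinism and numerics

Every stochastic routine takes an explicit seed (`numpy.random.default_rng`)
and the pipeline derives all stage seeds from one master seed, so manifests
are byte-identical across reruns. Permutation p-values are never zero by
construction (+1 smoothing). AMOVA percentages sum to 100 within 1e-12;
MDS reconstructs Euclidean-realizable matrices within 1e-9. Degenerate
inputs (all-zero coverage, masks removing every site, single populations,
m = 1, k ≥ n in MDS) raise typed errors rather than returning NaNs.

## Known limitations

* The packaged motif trees are deliberately minimal; production haplogroup
  calling should import a full reference tree (the TSV format supports it).
* The median-joining implementation recomputes spanning lengths per
  candidate median (O(n²) each); it is intended for uniparental datasets
  (≲ a few hundred distinct haplotypes), not genome-scale haplotype sets.
* AMOVA uses pairwise-difference distances; alternative distance matrices
  can be supplied but gamma-corrected or model-based distances are not
  computed in-package.
* Rho dating averages equal-cost paths through one deterministic
  shortest-path tree; reticulation-heavy networks can make ρ sensitive to
  the tie-break, which is why the root and the network are both reported.
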