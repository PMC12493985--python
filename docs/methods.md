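# Methods

`eutromics` implements the computational chain linking coastal eutrophication
to benthic microbial community assembly and life-history strategy: trophic
status indices for overlying water and sediments, diversity and niche
metrics, neutral- and null-model assembly inference, and community-averaged
life-history traits from metagenome summaries.  A synthetic-data module
generates inputs with the statistical structure each inference stage assumes,
so the whole chain is testable without sequencing data.

## Trophic status

**TRIX.** For each overlying-water sample,

    TRIX = (log10(Chl-a · aD%O · DIN · P) + x) / m,  x = 1.5, m = 1.2,

with chlorophyll-a in µg/L, aD%O the absolute % deviation of dissolved oxygen
from saturation, DIN = (NH4 + NO2 + NO3) and P = PO4 converted from µmol/L to
µg/L using molar masses 14.007 (N) and 30.974 (P).  Classification:
TRIX ≤ 4 oligotrophic, 4 < TRIX ≤ 5 mesotrophic, TRIX > 5 eutrophic
(boundaries fall to the lower-severity class).  A zero factor makes TRIX
undefined and is reported as such, never as a number; missing chemistry cells
propagate as "not computable" because zero is a valid concentration.

When no measured saturation percentage is supplied, the saturation
concentration comes from the Benson–Krause (1984) temperature–salinity
solubility equation (checked against published table entries: 9.09 mg/L at
20 °C freshwater, 7.40 mg/L at 20 °C, salinity 35).  A directly measured
`do_saturation_pct` always takes precedence, since field studies rarely state
how saturation was obtained.

**Sediments.** Organic nitrogen ON = TN × 95% and organic index OI = TOC × ON
(% dry weight), each classified into four pollution levels with
lower-inclusive boundaries.  OI boundaries are 0.05 / 0.20 / 0.50.  The ON
column of the conventional level table is not printed consistently across
sources; the package fixes the uncontaminated bound at 0.0033 and the heavy
bound at 0.13, sets the intermediate bound to 0.066, and leaves all four
configurable (`SedimentThresholds`).

Reported tables round half-up to 2 decimals; raw values are always retained.

## Diversity, niche breadth, networks

Alpha diversity uses observed richness, bias-corrected Chao1
(S + F1(F1−1)/(2(F2+1)); the classical form is available), Shannon entropy in
nats (values of 6–7.5 at ~10⁴ OTUs are only consistent with natural logs;
base configurable) and Gini–Simpson 1 − Σp².  Levins niche breadth uses
OTU-wise proportions (site share of the OTU's total), giving B_j ∈
[1, n_sites]; Bcom is the unweighted mean over OTUs with positive totals.
Bray–Curtis dissimilarity is computed on relative abundances by default.
Distance decay is an OLS fit of 1 − Bray–Curtis on great-circle (haversine,
R = 6371 km) distance over upper-triangle pairs.  Per-site phylogenetic
distance is mean pairwise patristic distance, either abundance-weighted
(Σᵢ≠ⱼ pᵢpⱼdᵢⱼ) or the plain mean over present-taxon pairs; sites with fewer
than two taxa are reported missing.

Co-occurrence networks keep the top-k (default 1000) OTUs by mean relative
abundance (ties broken lexicographically for determinism), test all retained
pairs with Spearman's ρ, correct across all tested pairs with
Benjamini–Hochberg FDR, and keep edges with ρ > 0.6 and q < 0.001.  The
positive-only rule is the default, matching the stated construction;
`sign_mode="absolute"` gives the common |ρ| alternative.  No rarefaction is
applied by default.

## Neutral community model

The Sloan model predicts a taxon's occurrence frequency from its
metacommunity mean relative abundance p_i:

    Freq_i = 1 − I(1/N | N·m·p_i, N·m·(1−p_i)),

with I the beta CDF.  N is taken as the mean per-site total count and the
detection limit as 1/N (standard fitting practice; surveys rarely state
their choice).  m is fitted by bounded least squares on m ∈ (1e−6, 1] from
multiple bracketing intervals, because the objective can be flat near the
boundaries; a boundary or non-converged solution is flagged in the result,
never silently returned.  R² uses the centered total sum of squares (the
usual reporting convention; a non-centered variant is available).  Wilson
binomial envelopes at n_sites trials around the prediction partition OTUs
into above/within/below.  Exact model-generated frequencies are refit with
|m̂ − m| < 1e−3 and the full simulate-then-fit loop recovers Nm = 10,000
within 15% at 50 sites (test suite).

## Null models: βNTI and RC_Bray

βMNTD between two communities is the abundance-weighted (default; presence
optional) mean of each taxon's patristic distance to its nearest taxon in
the other community, averaged over both directions.  βNTI is the z-score of
the observed βMNTD against `reps` (default 999) randomizations that shuffle
taxon identities across tree tips.  The default shuffle pool is **every tip
of the supplied tree** ("all"), the framework's standard randomization:
homogeneous selection is detectable precisely because filtered communities
occupy a small phylogenetic neighbourhood *relative to the whole taxon
pool*.  A stricter pair-union pool is available (`pool="pair"`), but note it
is degenerate for fully overlapping communities (shared taxa contribute zero
to both observed and null βMNTD), which the code reports as NaN entries.

RC_Bray assembles, per site pair, null communities that preserve each site's
observed richness and total abundance: taxa are drawn without replacement
with probability proportional to metacommunity occurrence frequency, seeded
with one individual each, and the remaining individuals are drawn
multinomially proportional to metacommunity relative abundance.  RC is the
fraction of null Bray–Curtis values below the observed (ties half-weighted),
rescaled to [−1, 1] by 2(RC − 0.5).

Classification per site pair: βNTI > +2 variable selection; βNTI < −2
homogeneous selection; otherwise RC > +0.95 dispersal limitation,
RC < −0.95 homogenizing dispersal, else undominated.  Fractions are taken
over pairs with defined βNTI; excluded pairs are counted in the result.
All null draws use per-pair RNG substreams spawned from one master seed, so
results are independent of pair iteration order and exactly reproducible.

## Synthetic data

All generators are pure functions of (spec, seed).

**Neutral metacommunities** sample the stationary Sloan distribution
directly: local relative abundance ~ Beta(Nm·p_i, Nm·(1−p_i)) per taxon,
then a multinomial draw of N individuals.  This matches the fitted model
exactly and is fast and seed-stable; no forward birth–death simulation is
needed.  The default metacommunity is a ranked log-series.

**Selection metacommunities** place a trait on a unit-depth pure-birth
(Yule) tree and weight each taxon at each site by a Gaussian filter
exp(−(env − trait)²/2w²), with abundances multinomial.  Two design choices
matter and were set by pilot simulation:

* *Trait conservatism.* Plain Brownian motion leaves too much trait
  convergence across clades — taxa passing the same filter are then not
  close relatives, and median βNTI under homogeneous selection stays near
  −0.5 however strong the filter.  The default trait model applies an
  early-burst rate decay (rate × e^(−5t) with t the depth from the root), so
  trait variance concentrates on deep branches and similar traits imply
  close relatedness.  Tip traits are standardized, making `filter_width`
  a trait-sd unit (default 0.1 = strong filter).
* *Drift.* Without site-level noise all same-environment sites contain the
  same taxa; fully overlapping communities give βNTI ≈ 0 regardless of
  selection strength because shared taxa contribute zero turnover.  Each
  site's filter weights are therefore multiplied by lognormal noise
  (sd = 2.0) and local communities are small (100 individuals), producing
  taxon turnover *within* the selected clade.

With the default 256-taxon pool these settings give median βNTI < −2 in
homogeneous mode and strong βNTI > +2 enrichment between environment
clusters in variable mode, across seeds.  Homogeneous mode sets all site
environments to the median trait; variable mode alternates sites between
the 0.2 and 0.8 trait quantiles.

**Genome communities** plant per-taxon genome size, 16S copy number, GC,
transposase count, a ribosomal codon-bias target (ENC′) and relative
abundance.  Each taxon contributes one copy of each of 35 single-copy
markers, its 16S copies, its transposase records, 10 ribosomal-protein and
20 background CDS (300 codons each); per-gene coverage is depth-proportional
with optional gamma multiplicative noise of given CV.  Ribosomal CDS are
produced by a two-regime codon sampler (a preferred codon per amino acid
receives extra probability q, base probabilities follow the taxon's GC);
q is tuned by bisection until a 3000-codon probe realizes the target ENC′
within ±0.5.  Read-pool summaries (total bp, GC) are formed from each
taxon's realized marker depth times its genome size, so the genome-size and
GC estimators see data consistent with the planted community.  The planted
abundance-weighted community averages are returned for closed-loop tests:
exact recovery at zero noise, within 5% at CV = 0.2 with 30 taxa.

**Chemistry** draws each variable uniformly and independently within the
observed per-region ranges for the eutrophic Yangtze River Estuary and the
oligotrophic East China Sea (the ranges are the only constraint the survey
summaries provide; no cross-variable correlation is imposed).  Salinity and
bottom-water temperature ranges (YRE 18–31 / 22–28 °C, ECS 30–34.5 /
18–24 °C) are plausible July values chosen by the package, used only to
compute oxygen saturation.

## Life-history traits

Genome equivalents = aggregate mean coverage of the 35 universal single-copy
markers (plain mean, or a 10%-per-tail trimmed mean against mismapping
outliers).  Average 16S copy number = summed 16S gene coverage / genome
equivalents; average genome size = total bp / genome equivalents (the
`basis` flag records whether total bp is assembled-contig or
coverage-weighted read bp).  GC is counted over unambiguous bases only, with
the ambiguous count reported.

ENC′ is the background-composition-corrected effective number of codons:
per synonymous family, a chi-square deviation of observed codon usage from
the usage expected under the background nucleotide composition corrects the
homozygosity estimate, F′ = (X² + n − k)/(k(n − 1)); family values are
averaged within degeneracy classes and combined as
N₁ + N₂/F̄₂ + N₃/F̄₃ + N₄/F̄₄ + N₆/F̄₆ (bacterial code: 2 + 9/F̄₂ + 1/F̄₃ +
5/F̄₄ + 3/F̄₆), clamped to [20, 61].  The Ile class falls back to the mean of
the 2- and 4-fold classes when unobserved; genes under `min_codons`
(default 100) are excluded and listed.  The default background is the
gene's own composition; uniform or explicit compositions are accepted.
Wright's uncorrected ENC is provided for comparison.  Community codon usage
bias is 1 / (unweighted mean ENC′ over ribosomal-protein genes).

Growth prediction uses a deliberately configurable log-linear calibration,
ln(generation time, h) = a + b·Δ, where Δ = (ENC′_background −
ENC′_ribosomal)/ENC′_background is the ribosomal bias contrast.  The
regression behind published codon-usage growth predictors is not public, so
the shipped default (a = ln 40, b = −12.3: no bias ≈ 40 h generations,
strong bias ≈ 1 h) is only a literature-scale anchor; quantitative use
should fit `fit_growth_calibration` on organisms with known generation
times.  Maximum growth rate is the reciprocal of generation time.

Transposase content is 100 × Σ(coverage × length) over transposase genes
divided by the same sum over the denominator set; the default denominator
excludes rRNA records ("annotated genes", the protein-coding annotation
convention), with an all-records alternative, since the denominator behind
published transposase percentages is rarely stated.

## Problem sizes and numerical choices

Default null-model replicates: 999.  The test suite exercises the βNTI
calibration at 600 independent site pairs (the mean of k standard-normal
values has sd 1/√k, so a ±0.1 check on the mean needs several hundred
pairs), regime recovery at 12 sites × 256 taxa (selection) and 12 × 300
(neutral), and NCM recovery at 50 sites × 500 taxa × 20,000 reads.  Ties in
top-k abundance ranking break lexicographically; pairwise matrices are
symmetric with undefined diagonals; all stochastic outputs carry their seed
in a header comment and the run manifest.

## What the synthetic data do not show

The generators reproduce the structure the estimators assume — beta-
distributed neutral abundances, Gaussian filtering on a conserved trait,
depth-proportional gene coverage, independent uniform chemistry.  Real
sediment data add compositional sequencing noise, correlated environmental
gradients, phylogenetic signal far messier than an early-burst trait, and
chimeric/misannotated genes.  Passing closed-loop tests therefore shows the
estimators are correct for their own model assumptions, not that field
estimates carry the same accuracy.  Field NCM/βNTI results additionally
depend on unstated conventions (detection limit, R² form, shuffle pool,
weighting) that materially change the numbers; every such convention is an
explicit, recorded option here.
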