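# Methods

## Scope and model

`switchnet` implements a network-medicine procedure for locating *switch
genes* in gene co-expression networks: hubs that sit between modules
(high clusterphobic coefficient), are not local hubs (low global
within-module degree) and are anti-correlated with their interaction
partners (negative APCC). The procedure combines three ingredients:

1. a thresholded Pearson correlation network over (differentially
   expressed) genes, with signed correlations kept on the edges;
2. a community partition of the genes under the correlation distance
   d = 1 − r;
3. per-node cartography statistics computed from link counts across the
   partition, plus the expression-based APCC.

The underlying assumptions are those of co-expression analysis in
general: expression profiles are informative about functional coupling,
Pearson correlation is an adequate coupling measure on the normalized
scale supplied, and a single hard threshold yields a network whose
qualitative structure is robust over a range of cutoffs (the
`threshold_scan` table exists to audit exactly this).

## Statistics and conventions

For node *i* with total degree k, internal degree k_in (links into its
own community C_i) and k_s links into community s:

| statistic | definition | notes |
|---|---|---|
| P | 1 − Σ_s (k_s/k)² | ∈ [0, 1 − 1/N]; undefined for k = 0 |
| K_π | 1 − (k_in/k)² | ∈ [0, 1]; topological bound, independent of N |
| z | (k_in − mean k_in(C_i)) / sd k_in(C_i) | internal-degree statistics of the module |
| z_g | (k_in − mean k(C_i)) / sd k(C_i) | **total**-degree statistics of the module |
| APCC | mean signed r over network neighbors | only edges that survived the cutoff count |

Identity P = K_π − Σ_{s≠C_i} (k_s/k)² gives P ≤ K_π everywhere, with both
zero when all links are internal; the enumeration bound sup P = 1 − 1/N
(attained at the uniform allocation) is recomputed by
`scripts/acceptance.py`.

Numerical conventions, chosen once and applied throughout:

- **Degenerate modules.** When a module's degree standard deviation is
  zero, z (or z_g) is set to 0 with a logged warning rather than
  propagating NaN.
- **Standard deviations** in z and z_g are population statistics
  (ddof = 0) of the module's degree distribution.
- **Edge rule** is inclusive: |r| ≥ cutoff.
- **Isolated nodes** stay in the graph flagged `isolated` but are dropped
  from the cartography table (their P, K_π and APCC are undefined).
- **Region boundaries** (configurable `RegionBounds`): below z_g = 2.5
  the K_π cuts are 0.05 / 0.625 / 0.8 (R1–R4); at or above, 0.3 / 0.75
  (R5–R7). The R4 edge at 0.8 is fixed by the role cartography this
  construction extends; the remaining cuts adopt that cartography's
  classic values applied to (K_π, z_g).
- **Hubs** have degree ≥ 5 (`hub_min_degree`); the date/party split is at
  APCC = 0.5 (`party_threshold`) — the literature describes "low" and
  "high" positive APCC modes without printing a universal cutoff, so the
  value is explicit, configurable and recorded in output metadata.
- **Switch call**: region R4 and APCC < 0. A stricter reading — switch
  genes as a subset of fight-club *hubs* — is available via
  `require_hub=True`; on data with clear planted structure the two
  coincide, since R4 membership with negative APCC below 5 neighbors is
  rare.

## Community detection

Clustering operates on expression profiles, not on the thresholded graph:
d = 1 − r keeps anti-correlated genes in different communities, which is
what lets switch genes accumulate *external* links. Because
1 − r(x, y) is proportional to the squared Euclidean distance between
row-standardized profiles, Lloyd iterations with re-standardized mean
centroids locally minimize the total within-cluster correlation distance.
Details:

- assignment ties go to the lowest community index; emptied clusters are
  re-seeded from the worst-fitting point;
- best of `restarts` (default 10) random initializations, all driven by a
  mandatory seed;
- `choose_k` uses an elbow on the **absolute decrease of the per-gene
  mean within-cluster distance** (a bounded [0, 2] scale; tolerance
  0.05). A relative-decrease criterion was rejected because it is
  scale-free: on structureless data every further split of the noise
  ball still yields a large relative gain, so a relative elbow never
  stops at the bottom of the range. On the absolute scale, data with no
  module structure (quality already near zero at k = 2) stops
  immediately, while planted-module data keeps gaining until the true k.

## Robustness

The probe is the average shortest path over **connected pairs**
(disconnected pairs are excluded from the mean; the convention is
configurable to largest-component-only and is recorded in the output
metadata). Removal strategies rank each hub category by descending
degree, ties broken by gene id, and delete the first ⌈f·|category|⌉
members at each fraction f. Because categories differ enormously in
size, every targeted curve carries a *size-matched* random baseline: the
mean and sd of the ASP over `n_random_reps` uniform draws of the same
number of nodes. Comparing a 10-gene switch set against random draws of
10 nodes (rather than 10% of the network) is what the qualitative
targeted-vs-random claim is about. A whole-graph random curve is also
emitted for plotting.

## Survival prioritization

Patients are stratified per gene by tumor expression strictly below the
25th / strictly above the 75th percentile (ties at a quartile fall into
the excluded middle; a gene whose cohorts empty out is skipped with a
warning). Curves are Kaplan–Meier product-limit estimates and cohorts are
compared with the standard unweighted log-rank test (both via lifelines);
genes are ranked by ascending raw p-value. No multiplicity adjustment
enters the ranking; a Benjamini–Hochberg column is reported for
convenience. An optional follow-up horizon (`max_followup_days`)
right-censors longer records.

## Cross-dataset comparison and enrichment

Switch lists (or the unions of switch-gene neighbor sets) are encoded as
binary membership columns over the union of observed genes — not a
genome-wide universe, so normalized Hamming distance (default) is
comparable across panels of different sizes. Datasets are grouped by
average-linkage agglomeration (scipy), with the dendrogram exported as
Newick. Over-representation uses the one-sided Fisher exact test,
computed as the hypergeometric upper tail of the overlap (vectorized),
with BH adjustment at FDR 0.05 by default; the universe defaults to the
tested gene population.

## Synthetic study conditions

`generate_modular_expression` draws one standard-normal latent factor per
module and per sample, and sets

- member gene of module m: x = √c · f_m + σ · ε  (c = `intra_corr`,
  σ = `noise_sd`), so module mates share correlation c/(c + σ²);
- switch gene with target modules T (two by default, all foreign):
  x = −s · mean_{m∈T}(f_m) + σ · ε  (s = `switch_strength`).

At σ = 0 module mates are exactly collinear (sample r = 1), and a switch
gene's population correlation with members of its target modules is
−1/√|T| — both profiles are then noiseless linear images of the factors,
so the value is independent of c and s; at the default |T| = 2 this is
−1/√2 ≈ −0.707. At the default conditions (4 modules × 50 genes, 100
samples, c = 0.8, 10 switches, s = 0.8, σ = 0.3, cutoff 0.6, k = 4) the
switch–member correlation is ≈ −0.59, close enough to the cutoff that
each switch retains dozens of external edges, no internal ones, and a
clearly negative APCC — the regime the detector is designed for. Target
module pairs rotate across switches so that switch–switch correlations
stay mostly below the cutoff.

A positive offset (default 10) shifts all values onto the non-negative
expression scale without affecting any correlation. Paired tumor/normal
matrices scale chosen genes by 2^log2fc in the tumor copies; survival
times are exponential with rate `baseline_rate · exp(beta · z)` for the
standardized driver-gene expression, censored by an independent
exponential clock.

What the generator does **not** emulate: count-type mean–variance
coupling (negative binomial noise), batch effects, correlated censoring,
overlapping module membership, and hub-degree heterogeneity beyond what
thresholding induces. Passing the planted-recovery and removal-ordering
tests therefore shows that the statistics and the calling rule behave as
designed under the model's own assumptions, not that any particular
real dataset will yield a given switch count.

## Problem sizes used in the tests

The default test suite runs entirely on synthetic data: the planted
dataset above (210 genes × 100 samples), 100 random graphs of ≤ 30 nodes
for brute-force oracle equivalence, a 40-patient toy with a
10,000-permutation log-rank oracle, 200 replicates for type-I-error
calibration, exhaustive 2×2 tables with margins ≤ 50 for the
hypergeometric tail check, and 100 random binary matrices for the
Hamming metric axioms. These sizes keep the whole suite under a minute
or two on one CPU while leaving every check statistically meaningful.

## Known limitations

- The DE filter (mean-ratio log2FC with pseudocount 0.05, threshold 1) is
  a deliberate, configurable stand-in for a full count-model test; use an
  external DE tool and pass the filtered matrix when rigor matters.
- The clustering reconstruction (k-means under d = 1 − r) is one
  consistent realization of the stated distance metric; modularity-based
  partitioners are intentionally out of scope.
- APCC trimodality thresholds are fixed cutoffs, not a mixture fit.
- Power-law exponent estimation for the degree distribution is out of
  scope; `degree_summary` only reports the histogram.
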