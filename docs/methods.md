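# Methods

This note documents the statistical procedures implemented in `sumoscape`,
the synthetic data model used to validate them, the numerical conventions,
and the design choices made where more than one reading was defensible.

## Input model and conventions

The package consumes MaxQuant/Perseus-dialect tables. Positions are 1-based
throughout (the convention of the source tables); sequence windows are
odd-length strings centered on the modified lysine and padded with `_`
beyond the protein termini (default half-width 15). Missing intensities are
empty cells (or `NaN`) on disk and `None`/NaN in memory; floats are written
with 12 significant digits so a write–read–write cycle is byte-stable.
Decoy filtering removes rows flagged `Reverse` or `Potential contaminant`
("+" = flagged); the optional localization-probability cutoff is inclusive
(a site at exactly the threshold is kept).

The sample design maps each intensity column to a (timepoint, replicate)
pair; the default layout is the six meiotic stages G0, S, DSB, SI, dHJ, CO
in triplicate.

## Motif classification

Sites are classified from positions −3..+2 around the central K, testing
patterns in strict-to-loose precedence and returning the first match:

1. ΨΨΨ-K-x-E/D (triple-hydrophobic variant)
2. Ψ-K-x-E/D (consensus)
3. E/D-x-K-Ψ (reverse consensus)
4. K-x-E/D (acidic partial consensus)
5. E/D-x-K (reverse acidic)
6. K adjacent on either flank (di-lysine)
7. none

The precedence makes the categories mutually exclusive and exhaustive:
fractions always sum to 1. Ψ defaults to {I, L, V, M, F}, the usual "large
hydrophobic" set of the SUMO-consensus literature; because published
composition percentages depend on this choice it is exposed as a parameter
everywhere. The pad character `_` matches no pattern class, so context
beyond a terminus can never create a motif. Di-lysine checks both flanks
(the minimal symmetric reading). The classifier is verified exactly against
an independent regular-expression implementation on random windows,
including randomly chosen Ψ sets.

## Site topology

Adjacent-site spacings are successive differences of the sorted site
positions of each protein, pooled pair-weighted across proteins (each
spacing counts once); `fraction_below(t)` uses a strict `< t` comparison.
A per-protein-averaged variant is available behind a flag because either
pooling could underlie a published summary fraction.

The distance curves pair every anchor (each SUMO site, or each lysine for
the baseline) with every *other* lysine of the same protein, restricted to
proteins carrying at least one site. Distances are |Δposition| rounded to
the nearest multiple of 10 with half-away-from-zero rounding (1–4 → bin 0,
5–14 → bin 10); half-to-even is available as a knob since "nearest 10"
does not determine the tie rule. Anchors never pair with themselves. The
implementation is vectorized; tests compare it to a pure-Python O(n²)
enumeration.

Two statistical properties of this estimator matter when testing it:

* Pair counting is *ordered*: each site–site pair enters twice (once per
  anchor), so per-bin counts are overdispersed relative to a binomial by
  roughly a factor of two. Calibrated null checks therefore count unordered
  pairs.
* The expected per-bin fraction under no clustering equals the pooled pair
  fraction Σ nₛ(nₛ−1) / Σ nₛ(n_K−1), *not* the per-lysine SUMO rate among
  site-bearing proteins — restricting to proteins with ≥1 site
  zero-truncates the per-protein site count and inflates the per-lysine
  rate. Null tests compare bins to the pooled pair fraction.

## Structural context

Per-residue predictor tracks arrive as a TSV (one row per residue:
globular, long-disorder, short-disorder score, exposed, buried,
coiled-coil, transmembrane). The upstream predictors (IUPred-, ACCpro-,
ncoils-, HMMTOP-style tools) are deliberately not invoked: consuming their
output as data keeps the analysis self-contained and testable, and lets the
generator plant known structure.

Composite classes: SHORT_DISORDER is score ≥ 0.5 (the conventional
disorder decision boundary; configurable); DISORDERED is (long- or
short-disordered) and not globular; DISORDERED_NOT_CC additionally excludes
coiled-coil; DISORDERED_TERMINUS marks residues of disordered regions that
touch a terminus (a flag switches to marking only terminal residues, since
"extends to the terminus" admits both readings);
DISORDER_NEAR_TERMINUS requires DISORDERED_NOT_CC and strict distance
< 100 residues from the nearest terminal residue.

Fold enrichment of class c is

    E(c) = (SUMO-K in c / all SUMO-K) ÷ (K in c / all K),

over proteins with ≥1 site; classes holding no lysines report a missing
value. Note that E(c) is attenuated by class prevalence: if disordered
lysines are modified at r times the rate of ordered ones and a fraction f
of lysines is disordered, E(DISORDERED) = r/(1 + (r−1)f), which is 1.43
for r = 2, f = 0.4. The planted rate multiplier itself is identified by the
rate ratio

    (SUMO-K/K inside c) / (SUMO-K/K outside c),

provided as `rate_ratio`; parameter-recovery tests check that quantity.

## LFQ dynamics

The pipeline enforces the state order RAW → AVERAGED → LOG2 → IMPUTED →
ZSCORED; each operation validates its input state. Replicate averaging
takes the mean of non-missing replicates per timepoint (all-missing stays
missing). Imputation draws each missing cell of column c from
Normal(m_c − 1.8·s_c, (0.3·s_c)²) with m_c, s_c the observed mean and
sample SD of the column — the standard downshifted-normal model for
intensity-dependent missingness; width and downshift are parameters.
Z-scoring uses the sample (n−1) SD; zero-variance rows are flagged and
passed through unscaled rather than silently zeroed. Clustering uses
d(i,j) = 1 − Pearson(row_i, row_j) with average linkage by default (the
distance determines the analysis; the linkage is the common default of the
heatmap tools this emulates, and is configurable). Identification counting
treats a row as identified at a timepoint when ≥1 replicate cell is
non-missing and positive; a strict all-replicates mode exists because the
counting convention is not uniquely determined.

## Synthetic data model

The generator emulates the statistical structure the analyses assume, at
the scale of the study conditions. Defaults: 775 target proteins of
150–1000 residues (uniform; mean ≈ 575 — SUMO targets skew long), lysine
frequency 0.073 (yeast-like), alternating disordered/ordered segments with
geometric lengths of mean 30/45 (≈ 40% disordered), site rate 9.5 per 100
lysines, disordered lysines modified at 2× relative odds, cluster
probability 0.45 with window 5, the motif mix set to the observed
composition proportions, five temporal shapes (rising, falling, U,
peak-mid, flat) of amplitude 2 log2 units on a base intensity
N(25, 2²) with 2% replicate CV, and logistic MNAR missingness with
midpoint 23 and unit steepness. A seeded run yields ≈ 2900 sites in
≈ 640 modified proteins with ≈ 49% of adjacent spacings under 5 residues —
approximating the scale and clustering of a real meiotic SUMO proteome. One
integer seed drives two named generator streams (proteome, intensities);
identical seeds give byte-identical output files.

Placement details that matter for recovery tests:

* Seed sites are Bernoulli-thinned per lysine with probability proportional
  to 1 + (r−1)·disordered(k), normalized by the *global* expected weight.
  (Fixed-count weighted sampling without replacement, and per-protein
  normalization, both attenuate the pooled odds ratio — the former through
  inclusion-probability flattening, the latter through a Jensen effect
  across proteins with different disorder fractions.)
* Cluster sites pick a random existing site and a free offset 1..window,
  converting the residue to lysine when needed — SUMO-site clusters sit in
  K-rich patches, and requiring a pre-existing lysine within ±5 residues
  would make the planted cluster probability unrealizable at 7.3% lysine
  frequency.
* Motif stamping overwrites at most positions −3..+2; collisions between
  nearby stamps resolve later-site-wins, but a stamp never overwrites
  another site's central K. The recorded ground-truth category is the
  classification of the *final* emitted window, so truth always describes
  the data. Consequence: under clustering, adjacent sites force extra
  di-lysine calls and the realized composition shifts away from the
  configured mix (visible in the worked example); composition-recovery
  experiments therefore use sparse, uniformly placed sites
  (cluster_prob 0, disorder_enrichment 1, ~3 sites per 100 lysines) to
  isolate motif realization.
* "None"-category contexts are rejection-sampled from the background
  residue distribution until no pattern matches, with a neutral-residue
  fallback when a protected neighbouring site-K forces a pattern.

What the generator does **not** model: real yeast sequence composition
beyond lysine frequency, peptide digestion and FDR, protein abundance
structure (protein LFQ is the sum of site intensities), correlated
replicate noise, and the study's true missingness mechanism (the logistic
MNAR model is a stand-in; its parameters are plausible, not calibrated).
Passing recovery tests therefore demonstrates correctness of the analysis
code under the stated generative assumptions, not performance on real
spectra.

## Numerical and testing choices

Statistical acceptance checks fix their seeds and problem sizes:
10,000 windows for classifier/oracle agreement; ≥ 5,000 sites for
composition recovery at 99% binomial CIs; ≥ 50,000 lysines for enrichment
recovery within 10%; 10 pooled simulations for distance-curve null
flatness at 3 SE per well-populated bin (unordered pair counts, see
above); 10,000 imputed cells for imputation calibration at 3 SE; and 300
complete averaged profiles for 3-class clustering recovery at adjusted
Rand ≥ 0.95 (profiles with an all-missing timepoint are excluded before
clustering — their imputed values carry no class signal). These sizes keep
the whole suite within a few minutes on one CPU while leaving the checks
well-powered.

Known limitations: the published composition percentages depend on an
unstated Ψ set and window convention, so real-data motif comparisons are
tolerance-based; the distance-curve tie rule and the terminus conventions
are choices exposed as flags; and the per-protein diagrams aim at
correctness of track data, not publication aesthetics.
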