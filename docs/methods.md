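# Methods

`crossfeed-sip` implements a desk-scale version of the analysis used to
infer metabolic cross-feeding in a two-member microbial community
(a yeast-like species A and a lactic-acid-bacterium-like species B)
grown on lactose with either the glucose or the galactose moiety
uniformly ¹³C-labelled. The chain is: species-resolved peptide isotopic
envelopes → per-peptide relative isotope abundance (RIA) → replicate
filtering and median summaries → per-amino-acid contribution regression
and PCA → natural-abundance-corrected metabolite mass-isotopologue
distributions (MIDs). A seeded generator produces synthetic co-culture
data with known ground truth so every stage can be validated by
parameter recovery.

## Isotope model

All envelope arithmetic uses the aggregated (nominal-mass) isotopologue
model: every molecular species with k extra neutrons contributes to a
single intensity at integer offset k. Fine structure, exact masses and
charge states are not modelled; RIA and MID mathematics operate entirely
on nominal offsets.

Natural abundances are fixed IUPAC representative values: ¹³C 0.0107,
²H 0.000115, ¹⁵N 0.00364, ¹⁷O 0.00038, ¹⁸O 0.00205, ³³S 0.0075,
³⁴S 0.0425, ³⁶S 0.0001, and ²⁹Si 0.04685 / ³⁰Si 0.03092 for
derivatized metabolite fragments. An envelope at ¹³C enrichment r is
the convolution of a Binomial(n_C, r) carbon pattern with the
natural-abundance patterns of all other elements, normalized to unit
sum and truncated at a relative intensity of 1e-6 from the tail
(tunable; tests that compare against the exhaustive enumeration oracle
use 1e-9). Residue compositions ship as a plain-text TSV resource; a
peptide is the residue sum plus one water. Ambiguous residues (B/Z/X)
are rejected by composition math and skipped at proteome indexing,
because they have no unique elemental formula.

## Digestion and species assignment

In-silico tryptic digestion cleaves after K or R except before P, with
defaults of at most 2 missed cleavages and a minimum length of 7
residues. (This is the simple MSGF+-style dialect; the ExPASy rule with
WKP/MRP exceptions is deliberately not used.) Species assignment is a
set lookup against digest indices of the two target proteomes and any
decoy proteomes: a peptide unique to one target species carries species
information; a peptide in ≥2 target species is `shared` and excluded
from species-level statistics; any decoy hit dominates and flags a
false-positive candidate. The incorporation false positive rate (iFPR)
is the decoy-flagged fraction of all observed peptides. Proteins are
inferred only when supported by at least two distinct species-unique
peptides.

## RIA estimation and filtering

RIA — the fraction of a peptide's carbons that are ¹³C — is estimated
by fitting the single-enrichment forward model to the normalized
observed envelope with unweighted least squares over r ∈ [0, 1]: a
coarse grid (step 0.01) locates the basin and golden-section search
refines to |Δr| < 1e-4, with ties broken toward the smaller r. The
estimate includes the natural ¹³C baseline, so unlabelled material fits
at ≈ 0.0107; no two-population (old/new protein) decomposition is
attempted. Per peptide × species × condition, replicate RIAs are
summarized by their median; groups seen in a single replicate are
dropped (`removed_support`), and groups seen in exactly 2 of 3
replicates with a coefficient of variation above 40% are dropped
(`removed_cv`). The CV rule is read literally: 3-of-3 groups are kept
regardless of CV. CV uses the sample standard deviation (ddof = 1).

## Amino-acid contribution regression and PCA

For each kept peptide P the predictor for amino acid A is the
standardized value o_AP·c_A/len(P) (occurrences × residue carbons /
peptide length); the response is the median RIA. Ordinary least squares
with an intercept is fitted per species × labelled condition; the
intercept absorbs the natural-abundance floor and medium-derived
labelling. Residues absent from every peptide are flagged and pinned to
coefficient 0 rather than left to the pseudo-inverse. No
non-negativity constraint is imposed. Coefficient vectors use the fixed
residue order ACDEFGHIKLMNPQRSTVWY. PCA over the 20-dimensional
coefficient profiles is column-centered and unscaled (shared units),
computed by SVD with a deterministic sign convention (the
largest-magnitude loading of each component is made positive).
Identical profiles are reported as degenerate rather than decomposed.

Note the regression is deliberately mis-specified in a small way the
data inherit from the formula itself: the response aggregates carbons
with weight 1/Σ o·c while the predictors use 1/len(P). The fitted
coefficients therefore recover the *ranking* of the underlying per-AA
labelling fractions (Spearman ρ ≈ 0.9 at 500 peptides) rather than
their absolute values.

## MID natural-abundance correction

A measured MID of a derivatized fragment is modelled as M_obs = C·x,
where column j of C is the natural envelope of the fragment with j
tracer carbons fixed as ¹³C (a +j shift convolved with the rest of the
fragment at natural abundance). Tracer carbons are a designated count,
not positions. Derivatization atoms (TBDMS carbons, Si) are part of the
fragment formula and always natural. The system is solved by
non-negative least squares and renormalized to unit sum, which keeps
corrected fractions physical on noisy data; unconstrained inversion can
return negative isotopologue fractions. The labelled-fraction summary
reports M1..Mn, total labelled = 1 − M0, and the fully-labelled
fraction Mn.

## Synthetic community generator

The generator emulates the statistical structure of the co-culture
experiments, not their raw signals:

* **Proteomes.** Random proteins (default 25 per species, uniform
  length 200–400) with residues drawn i.i.d. from average-proteome
  frequencies; a decoy proteome is drawn from a disjoint sub-seed.
  Random ≥7-mers essentially never collide, giving the <5%
  inter-species shared-peptide property by construction.
* **Labelling table.** Per species × condition × amino acid ¹³C
  fractions. Medium-supplied amino acids — declared here as
  {F,H,K,M,R,V,W,Y}, standing in for the 8 amino acids of the defined
  co-culture medium — stay at natural abundance in every condition.
  Biosynthesized amino acids ({G,A,E,Q,S,T,D} plus C) are enriched,
  with the glycolysis-proximal trio A/G/C weighted 1.0 under
  galactose-moiety labelling but 0.55 under glucose-moiety labelling
  (other biosynthesized 0.7, remaining 0.25). The shape difference
  matters: it is what makes the four coefficient profiles
  non-collinear, so the galactose-labelled species-A profile separates
  in PCA for structural reasons rather than by noise.
* **Calibration.** A single scale factor per species × condition is
  bisected (fractions capped at 0.95) so that the median true peptide
  RIA over that species' digest peptides hits the scenario targets:
  0.30 / 0.05 for species A and 0.15 / 0.19 for species B under
  gal-/glc-moiety labelling — the labelling degrees the study design
  implies. True peptide RIA is the carbon-weighted mean of residue
  fractions, Σ o·c·f / Σ o·c.
* **Observations.** Each digest peptide, per condition and replicate,
  is detected with probability 0.85 (Bernoulli) and, if detected,
  emitted as its forward-model envelope with multiplicative log-normal
  peak noise (sd 0.05). These defaults produce the 2-of-3-replicate
  cases the filter rule targets. Metabolite MIDs (pyruvate, lactate 3
  tracer carbons; glutamate 5) are the natural-abundance mixing of
  declared true MIDs — ~70%/~40% fully labelled pyruvate/lactate under
  glc/gal labelling; glutamate labelled mostly in 4–5 carbons under gal
  and 1–3 under glc — with 2% multiplicative noise. Fragment formulas
  are synthetic stand-ins for TBDMS-derivatized fragments.
* **Ground truth** (true RIAs, true MIDs) is written to its own JSON
  file and never read by any analysis stage.

What passing recovery tests does **not** show: real data add
chromatographic interference, charge states, co-eluting isobars,
intensity-dependent (not purely multiplicative) noise, peptide
modifications, and search-engine identification errors. The generator
validates the estimators and the pipeline plumbing, not instrument
behaviour.

## Numerical choices and degenerate inputs

* Envelope truncation threshold 1e-6 (bounds length; tests at 1e-9).
* RIA fit: deterministic grid + golden section; ties toward smaller r;
  per-composition grid models are cached (LRU) since each peptide is
  fitted once per condition × replicate.
* OLS via `numpy.linalg.lstsq`; all-zero responses yield exactly zero
  coefficients and intercept.
* PCA degenerate case (no variance): zero scores, explained variance
  reported as undefined.
* NNLS (scipy) for MID correction; an all-zero raw vector or an
  all-zero solution is an error.
* All generator randomness flows from one seed through
  `numpy.random.default_rng` with fixed sub-seed lists, so identical
  seeds give byte-identical tables.

## Problem sizes

Default test and demonstration scale: 6 proteins per species of 150–250
residues (~320 unique tryptic peptides per species), three conditions ×
three replicates, detection 0.85 — about 5,500 envelope fits per run.
Recovery studies use 50 random peptides × 32 enrichments × 20 noise
seeds (RIA) and 500 peptides × 20 seeds (regression). These sizes are
the package's chosen desk-scale defaults; all are parameters.

## Known limitations

* Single-enrichment RIA model: mixtures of old (natural) and new
  (labelled) protein populations bias the fit toward an intermediate
  value rather than resolving two groups.
* Nominal-mass model: no fine structure; very long peptides with many
  S atoms slightly blur the carbon signal.
* The regression recovers rankings, not absolute per-AA fractions
  (see above), and medium amino acids with near-zero predictor variance
  have noisy coefficients.
* Tracer carbons in MIDs are counts, not positions; positional
  isotopomer information is not represented.
* iFPR on synthetic runs is structurally ~0 because observed peptides
  are generated from the target proteomes; the decoy machinery is
  exercised by constructed fixtures instead.
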