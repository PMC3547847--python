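# Methods

## Study design assumed by the scorer

The scoring stage assumes a training set of matched purification pairs:
for each bait, one *control* run with bait expression not induced and one
*induced* run from the same cell background. The default synthetic study
uses 17 such pairs, one bait per pair, the conventional size for this
design. Controls capture the non-specific background — "frequent flyer"
proteins that bind the resin or the tag — so that an induced-run score can
be judged against the same protein's control behaviour rather than against
a global contaminant list.

## The score model

Identification scores (Mascot-like log-odds scores, unit-free, higher =
stronger evidence) are treated as log-normal per protein. On x = log S:

- hyperprior: σ² ~ Inv-Gamma(α₀, β₀), μ | σ² ~ N(m₀, σ²/κ₀) — one shared
  normal–inverse-gamma prior across proteins;
- empirical Bayes: m₀ is the mean of per-protein control means; κ₀ is the
  ratio of the mean within-protein variance to the between-protein
  variance of means (method of moments, after subtracting the sampling
  share of the spread); α₀, β₀ come from the moments of the per-protein
  sample variances (α₀ clamped to [2.1, 50] so the prior always has finite
  variance and never overwhelms 17 observations);
- per protein: the standard conjugate update, giving a Student-t posterior
  predictive t(m_n, β_n(κ_n+1)/(α_n κ_n), 2α_n) on log score;
- a *background model* is the same update applied to all control
  observations pooled, and serves preys never seen in any control run;
- every model records the protein's control `detection_rate`, and models
  with fewer than 2 control observations carry `pooled=True` (their
  posterior is dominated by the hyperprior).

The p-value of an induced observation with score s is the posterior
predictive tail P(S ≥ s | detected). For normal samples this transform is
the classical predictive-t statistic and is exactly uniform under the
null, which is the property the leave-one-out FDR machinery relies on.

**Detection handling.** We deliberately do *not* fold the detection rate
into the p-value multiplicatively (p = P(detected)·P(S ≥ s | detected)):
any such weighting shifts null p-values by roughly (1 − detection rate)
and destroys their uniformity, which would bias the empirical FDR.
Absence from controls influences scoring only through the model fallback
(the background model), and `detection_rate` is reported as a diagnostic.
A `detection_weighting=True` flag implements the multiplicative rule for
exploration; it is off everywhere by default.

## Leave-one-out FDR

Control runs contain only non-specific content by construction, so they
can play the role of a null sample. For each pair i:

1. refit all models (including the empirical-Bayes hyperprior) on the
   other n−1 pairs — the left-out pair contributes nothing to the models
   that score it, which the tests verify by refit equality;
2. score every prey of control run i as if it were an induced observation.

The pooled results are null p-values. For a threshold t,

    FDR(t) = [(#null ≤ t + 1) / n_folds] · n_induced_runs / #observed ≤ t

clipped to [0, 1] and monotonized by a cumulative minimum from large t
downwards (q-value style; ties in p break by higher score, then prey id).
Two numerical choices deserve comment:

- the per-fold null rate is scaled by the number of induced runs scored,
  because each fold's null emulates the contaminant content of *one* run
  while observed discoveries accumulate over all induced runs;
- the +1 pseudo-discovery in the null count is the usual finite-sample
  guard of permutation-style empirical FDR estimates; with only n_folds
  null replicates of each run the raw count at small t is 0 more often
  than its expectation justifies.

Bait self-identification rows are removed before any of this (the bait is
trivially its own top prey). Reporting selects calls with FDR below the
threshold (default 10%) and attaches the expected-contamination bound
⌈n_reported × threshold⌉. Empirically (measured by the acceptance suite,
20 replicate experiments), the realized false-discovery proportion among
reported calls averages just below the nominal 10%; on an unlucky
replicate the estimator may report nothing at all, which is the correct
abstention when no q-value clears the threshold.

## Protein inference filters

Three per-run rules run in a fixed order: (1) if two or more products of
*different* genes were identified from the identical peptide set, all are
removed — the evidence cannot separate them; (2) isoforms of one gene
collapse to the best-coverage one (ties: higher score, then lexicographic
id — the published rule names only coverage, and a deterministic total
order is needed for reproducibility); (3) single-peptide identifications
are discarded. Whether rule (3) runs before or after (1) is not dictated
by anything; the fixed order here is a documented choice, and all three
rules are idempotent projections, so repeated application is harmless.
"Same peptide set" means exact set equality; razor-peptide (subset)
relationships are deliberately out of scope. The peak-list filter keeps
spectra with neutral precursor mass in [600, 6000] Da and at least 10
fragment ions.

## Modification masses and discriminability

All mass shifts derive from elemental composition (monoisotopic element
masses, CODATA/IUPAC): trimethyl = 3×CH₂ = 42.04695 Da, acetyl = C₂H₂O =
42.01057 Da, gap 0.03638 Da. Literature frequently prints these rounded
(42.0468 / 42.0105); the composition values are canonical here since they
are what a search engine itself sums. Two modifications are called
discriminable at precursor mass M and tolerance τ ppm when the gap exceeds
2·τ·10⁻⁶·M — i.e. the two symmetric match windows cannot overlap; a
one-sided single-window convention is available via flag. At 10 ppm the
trimethyl/acetyl verdict flips at ≈1819 Da. Neutral masses throughout;
m/z conversion uses the proton mass 1.007276 Da.

## Site localization and mapping

Localization is by fragment counting, Mascot-style, not a probabilistic
localization score: for each candidate residue (every K for lysine
modifications) the theoretical singly-charged b/y series of the modified
peptide is matched against the observed peaks within the fragment
tolerance (0.6 Da default), and the candidate with the most matches wins.
`delta_score` is the margin over the runner-up; a tie between distinct
candidates is returned as an explicit ambiguous result. The precursor must
match the modified peptide mass within the precursor tolerance (10 ppm
default), which is also what keeps trimethyl from being mistaken for
acetyl below the discriminability boundary. Peptide and protein
coordinates are 1-based, so calls read as "K315". Mapping requires the
peptide to occur exactly once in the protein; multiple occurrences raise
an error listing every candidate coordinate.

## Conservation reports

A methyl-site's 1-based ungapped position in a reference sequence is
mapped to its alignment column by skipping reference gaps; the report
gives the per-sequence residues, the identity fraction over non-gap
entries (invariant ⇔ fraction 1), and a Clustal-style annotation: `*`
single residue, `:` all residues within one strong group, `.` one weak
group, blank otherwise, with the conventional ClustalW groupings
(strong: STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW; weak: CSA,
ATV, SAG, STNK, STPA, SGND, SNDEQK, NDEQHK, NEQHRK, FVLIM, HFY). All-gap
columns are an error; windows overrunning the alignment are truncated
with a warning.

## The synthetic generator

`GeneratorConfig` defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_pairs / n_baits | 17 / 17 | matched pairs; one bait per pair |
| proteome_size | 400 | proteins in the synthetic proteome |
| contaminant_fraction | 0.25 | share of the proteome that is background |
| true_interactors_per_bait | 6 | planted preys per bait |
| score_location / score_scale | 4.0 / 0.5 | log-score hyper-location; within-protein sd |
| between_protein_scale | 1.0 | sd of per-protein locations around the hyper-location |
| enrichment_shift | 3.0 | log-score lift of true interactions |
| detection_prob_control | 0.9 | per-run detection probability of a contaminant |
| singleton_peptide_fraction | 0.05 | contaminant rows downgraded to 1 peptide |
| n_spiked_sites | 5 | planted trimethyl-lysines |

Contaminant log scores are normal with protein-specific locations drawn
from a shared hyperprior — deliberately the same hierarchical structure
the scorer fits, so pooling is testable. A location of 4.0 with unit
between-protein spread puts contaminant scores around e⁴ ≈ 55 with a
plausible range, and shift 3 puts true interactors near e⁷ ≈ 1100 —
strong but not separable by eye, since the background model that scores
them pools between- and within-protein variance. No published score
distributions exist for this design, so these are stated modelling
choices, made once. Missing preys are absent records, never zero scores.
The bait is always the top-scoring prey of its induced run; spiked sites
land on lysines whose covering tryptic peptide (6–25 residues) survives
the peak-list mass window. Trypsin cleaves after K/R not before P, with
up to two missed cleavages, and a methylated lysine is treated as
cleavable (the common search-engine default). A single integer seed
drives one generator instance; identical configs are byte-identical.

What the generator does *not* emulate: chromatography, isotope envelopes,
intensity-based quantification, correlated contaminant abundances across
runs, score/peptide-count coupling beyond a monotone link, or real
protein sequence composition. Passing tests therefore demonstrate the
statistical machinery is correct under its stated assumptions — log-normal
scores, exchangeable runs, matched backgrounds — not that those
assumptions hold for any particular instrument or laboratory.

## Degenerate inputs and edge policies

- Empty control data is a training error for the model proper; the
  pipeline treats a study with *no* contaminant background as the trivial
  case and reports every non-self induced prey (there is nothing to
  decontaminate, and the realized FDP is 0 by construction).
- An all-empty leave-one-out fold is skipped with a logged warning.
- p-values are clamped to (0, 1]; scores ≤ 0 get p = 1.
- `report` accepts threshold 0 (empty report) and rejects thresholds ≥ 1.

## Problem sizes

The default experiment (17 pairs, 400 proteins, ~3,200 observations) fits
and leave-one-out-refits in under half a second; the replicate study used
for the false-discovery measurement runs 20 such experiments, and the
null-uniformity check pools ≥10,000 p-values from a handful of
zero-enrichment experiments. These sizes were chosen as the smallest at
which the Monte-Carlo error of the measured quantities is comfortably
below the margins being tested.

## Known limitations

- The empirical null has only n_pairs folds; at very small thresholds the
  FDR estimate is granular, which the +1 pseudo-count mitigates but does
  not remove.
- The score model is per-protein and ignores covariance between
  contaminants (e.g. whole complexes co-varying across runs).
- Localization assumes the peptide identity is known and the modification
  is supplied; there is no open modification search and no probabilistic
  site-confidence calibration.
- Conservation annotation groups are the conventional Clustal sets, which
  are heuristic; the identity fraction is computed against the reference
  residue, not the column consensus (except in reference-gapped flanking
  columns, where the modal residue is used).
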