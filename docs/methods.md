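# Methods

This note documents the models, parameters, and numerical choices behind
`bridgethemes`, and what the synthetic benchmark does and does not show.

## The detection model

A *bridging theme* is operationalised as: a theme (a short recurring
segment, identified upstream by a profile search) with significant hits on
two domains whose ECOD X-groups differ, where the matching segments align
well while the flanking segments do not. The X-group level is the
conservative choice of "independent lineage": even the loosest level of the
ECOD hierarchy that could indicate common ancestry must differ.

The decision rules, in order:

- **Hit significance**: E ≤ 10⁻³ and coverage ≥ 0.85. These are filter
  thresholds, not calibrated error rates; no multiple-testing correction is
  applied because the values are used only to rank and cut.
- **Theme alignment**: local (Smith–Waterman) with BLOSUM62, affine gaps.
  The local aligner may trim a segment down to a short, highly similar core;
  when the local alignment covers ≤ 20 aligned residues, the global
  (Needleman–Wunsch) alignment of the two segments is used instead. The
  boundary case of exactly 20 takes the global branch.
- **Context rule**: a flank supports independence when its best local
  alignment is shorter than 20 residues *or* below 25% identity. Candidates
  failing the rule on either flank are kept in the output but flagged, so
  downstream consumers can filter without losing provenance.
- **Representative selection**: within a theme × X-group-pair group of
  n₁×n₂ candidates, theme scores and flank scores (arithmetic mean of the
  before- and after-scores, an absent flank contributing 0) are z-normalised
  across the group and the two candidates with maximal
  z_theme − z_flank are returned; a singleton group is returned as is.
  Zero-variance score vectors get z = 0 throughout, and remaining ties break
  by lower hit E-value, then lexicographic domain-id pair.
- **Deduplication**: per unordered domain pair the longest theme alignment
  wins; ties break by higher score, then lexicographically smaller theme id.

Raw alignment scores (not bit scores) enter the normalisation; gap penalties
are open 11 / extend 1, the standard BLOSUM62 pairing, with a gap of length
k costing `open + (k−1)·extend`. End gaps in the global aligner are
penalised by default; both choices are config-exposed because neither is
dictated by the problem. Traceback ties break diagonal > up > left, making
the reported aligned pairs deterministic.

## Alignment significance

The P-value of a theme alignment score S is computed against a
segment-composition-specific null: 1,000 segments of the partner's length
are drawn i.i.d. from the partner segment's residue composition (add-one
pseudocount over the 20 standard residues), aligned to the first segment
with the same aligner and parameters, and a Gumbel (type-I EVD for maxima)
is fitted to the null scores by maximum likelihood
(`scipy.stats.gumbel_r.fit`); then p = 1 − exp(−exp(−(S−μ)/β)). A
degenerate null (zero score variance, possible with pathological scoring
matrices) is flagged and reported as p ∈ {0, 1} by the side of μ the score
falls on. The Gumbel family is an approximation for gapped local alignment
scores and is treated as such: P-values are filters and diagnostics, not
calibrated tail probabilities. Under the null the fitted P-value is close
to uniform; the test suite checks KS < 0.1 over 500 replicates using
100-residue segments, where integer-score discretisation is small relative
to the fitted scale β.

## Structural divergence

All metrics operate on the aligned residue pairs of the chosen theme
alignment, restricted to pairs with coordinates on both sides (`n_used`
records the survivors; fewer than 3 is an error):

- **Cα RMSD** after optimal rigid superposition. Kabsch via SVD of the
  cross-covariance with the determinant sign correction, which excludes
  reflections and is stable for near-degenerate (colinear) point sets.
  This route is rigid-motion invariant to ~1e−13 Å in practice; the test
  suite asserts 1e−8.
- **dRMSD**: RMS difference of all intramolecular pairwise distances,
  superposition-free, hence insensitive to superposition outliers.
- **Contact-map change** at 9 and 11 Å: contacts are Cβ–Cβ distances below
  threshold (Cα for glycine); the statistic is 100 × differing entries / l².
  The diagonal and near-diagonal entries are identical on both sides by
  construction and are deliberately left in the denominator, matching the
  plain `l²` normalisation.
- **Secondary-structure agreement**: 8-state DSSP strings collapsed to 3
  states (H,G,I→H; E,B→E; else C), percent of aligned pairs agreeing.
- **Similarity call**: RMSD < 6 Å (strict; 6.0 itself is "dissimilar";
  threshold config-exposed).

The dataset-level RMSD distribution is summarised by a two-component
univariate Gaussian mixture fitted by EM: initialisation by 1-D 2-means
from 10 seeded random restarts, best final log-likelihood wins; convergence
when the log-likelihood improves by < 1e−8 or after 500 iterations;
variances floored at 1e−6 to prevent component collapse; components
reported in ascending order of mean, so the first weight is the
conformation-preserving fraction. The per-iteration log-likelihood trace is
retained and asserted non-decreasing. The mixture can be fitted on all
pairs or restricted by aligner mode (`mixture_mode`); all pairs is the
default.

## Ligand binding and enrichment

Geometric annotation marks a residue as binding when any of its heavy atoms
lies within 4.5 Å (inclusive) of any atom of a relevant ligand. Relevance
is decided by an exclusion list (waters/unknowns, common modified residues,
common crystallisation additives) because the original curated whitelist of
ligand codes is not recoverable; a user whitelist is accepted as an
alternative. BioLiP-style tables provide the second, curated route.

Enrichment compares two aggregate fractions over the annotated domains:
theme residues / all residues (the random-placement expectation) versus
binding-residues-inside-themes / all binding residues. A residue bound by
several ligands counts once. Under uniform random placement of binding
residues over the pooled residues the two fractions agree in expectation;
the suite verifies this with 1,000 Monte-Carlo resamples.

## The synthetic benchmark

`synthetic.generate_benchmark` emulates the study conditions: themes of
length 49 (the curated set's mean), variations evolved independently from a
common ancestral segment by per-site substitution (a substituted site
always changes, so two variations at rate r share (1−r)² + r²/19 identity
in expectation — rate 0.2 lands at the top of the observed 30–64%
identity/similarity band), flanks drawn independently from the background
(uniform by default, configurable), distinct X-group labels per side, hit
tables with E = 10⁻⁶ / coverage 1.0 for planted occurrences and E = 10⁻²
decoys, toy coordinates (ideal helix: rise 1.5 Å / twist 100°; ideal
strand: rise 3.3 Å alternating offsets; coil: 3.8 Å random walk; Cβ at
1.53 Å), and single-atom (or tetrahedral 4-atom, edge 2.2 Å,
iron-sulfur-like) pseudo-ligands placed 3 Å from a designated mid-theme
residue's Cβ. The default benchmark is 20 X-groups × 5 domains with 10
planted themes.

What passing on this benchmark shows: the decision rules, bookkeeping,
alignment statistics, geometry code and network construction are correct,
and the pipeline recovers planted homology with perfect recall while
rejecting all decoys at the default thresholds. What it does not show:
performance on real profile-search hits (no indels are simulated, hit
envelopes are exact, E-values are assigned rather than computed), realistic
structure (no packing, no physical flank conformations), or the real
dataset's headline numbers, which depend on specific database versions and
cannot be regenerated at desk scale.

## Problem sizes and runtime choices

The test suite uses a 6×2-domain benchmark for detection-level tests and
the 20×5 benchmark for the recovery check; the EVD uniformity check runs
500 replicates of 1,000-sample nulls on 100-residue segments; mixture
recovery uses 5,000 draws. The acceptance script mirrors these sizes with
300 uniformity replicates. These sizes keep a full run to a few minutes on
one CPU while leaving the Monte-Carlo standard errors well below the
asserted tolerances.

## Known limitations

- The aligners are plain affine-gap DP (O(nm)); profile–profile alignment
  and HMM emission scoring are out of scope.
- The Gumbel fit ignores score discreteness; for very short segments
  (≲ 30 residues) the P-value lattice becomes visible.
- Bait-level redundancy among themes is collapsed only via the
  longest-theme-per-domain-pair rule; clustering of similar themes is not
  attempted.
- mmCIF input is not supported; domain extracts must be PDB-format.
- TM-scores are pass-through metadata; no structural alignment is computed.
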