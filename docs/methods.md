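# Methods

## Scoring model

For an ordered pair (Dq, De), De's interaction network is assembled
from five evidence layers: drug–protein associations typed by role
(enzyme, transporter, target), drug–gene pharmacogenetic associations
(gene identifiers share the protein namespace, so an association
grounds on a network protein when the identifiers match), and an
undirected PPI graph. The pharmacodynamic neighbourhood extends
exactly one hop: drugs attached to De's targets *or* to direct PPI
partners of those targets enter the target categories; two-hop
partners never contribute.

Seven scores summarize the pair. `s_d` is the Tanimoto coefficient
|A∧B|/|A∨B| of the two fingerprints. The six network scores are
category maxima of Tanimoto similarity between Dq and the category's
drugs, after removing Dq and De themselves. The maximum (rather than
a mean or sum) encodes the assumption that the single most similar
drug engaging a protein is the one most likely to share its
interaction behaviour. An empty category yields the sentinel −10, a
deliberately out-of-band value that downstream models treat as an
ordinary number: "no evidence in this layer" is itself informative,
and a linear logistic term converts it into a strong prior against
interaction in proportion to the layer's weight.

Pairs where De's network contains no other drug are dropped from
feature tables entirely — with no network there is nothing for six of
the seven scores to measure. Because DDI labels are unordered while
scores are ordered, an orientation policy decides which rows a pair
emits: `both` (default) emits one row per orientation with a
non-empty network; `de_richer` emits a single row with De the drug
whose network holds more drugs (ties to the lexicographically smaller
identifier).

## Logistic score fusion

Models are logistic regressions `P(DDI) = 1/(1+exp(−β₀−Σβᵢsᵢ))` over
a score set's columns, fitted by iteratively reweighted least squares:
zero-initialized, converged when the log-likelihood improves by less
than 1e−8, at most 100 iterations, error on non-convergence. Features
are centred and scaled before fitting; the sample (n−1) standard
deviation is used and recorded in the model file, so stored models
reproduce their training-time standardization bit-for-bit. Perfectly
or quasi-perfectly separated data — routine on tiny fixtures — cap
coefficient magnitudes at 30 with a warning instead of failing; a
capped model still orders its predictions sensibly. Standard errors
come from the inverse Fisher information at the optimum.

The 21 built-in score sets enumerate the meaningful subsets of the
seven scores plus the whole-network maximum, from the full integrated
set (`Set1`) down to single scores (`Set19` = direct similarity only),
so that information-integration questions reduce to comparing rows of
one AUC table. Nested sets are compared by the asymptotic chi-square
test on the deviance difference, with degrees of freedom equal to the
number of extra scores; the comparison table reports raw p-values plus
a Bonferroni column.

## Evaluation protocol

Non-DDI pairs vastly outnumber DDI pairs, so training tables are
balanced 1:1 per query drug: every unordered pair is attributed to the
endpoint with more DDI annotations (ties to the smaller identifier),
and for each query drug as many attributed non-DDI pairs are drawn
without replacement as it has DDI pairs, all of them when fewer exist.
Attribution guarantees each pair is drawn at most once and the global
ratio is 1:1 up to exhaustion. Cross-validation is 4-fold at the row
(pair-orientation) level by default, matching an evaluation that does
not block by drug; `group_by_pair` keeps both orientations of a pair
in one fold for leakage-safe splitting, and label-stratified folds are
available. AUC is the Mann–Whitney rank probability with midrank tie
correction — identical to trapezoidal ROC integration for binary
labels, computed in O(n log n). Sampling stability is measured by
redrawing the balanced negative sample (default ten replicates) and
reporting the standard deviation of the replicate mean AUCs.

All randomness descends from one master seed through a splitmix64
hash of (seed, purpose tags), so every subsample, fold assignment and
replicate is independently replayable and whole CLI pipelines are
byte-reproducible.

## Synthetic universes

The generator emulates the *statistics* the method assumes, not
chemistry. Its moving parts, with defaults and rationale:

- **Scaffolds.** `n_scaffolds=15` prototype bit vectors of width
  `bit_length=881` (matching the common 2D substructure key width) at
  `prototype_density=0.30`; each of `n_drugs=300` drugs is a prototype
  with independent bit flips at `flip_rate=0.08`. This puts
  within-scaffold Tanimoto near 0.74 and between-scaffold Tanimoto
  near 0.17 — structurally coherent families separated by a wide gap,
  the regime in which similarity search is meaningful at all.
- **Protein attachment.** 30 enzymes, 20 transporters, 20 targets and
  20 PPI-neighbour proteins receive home scaffolds round-robin (every
  scaffold is served by every layer) and attach to home-scaffold drugs
  at per-layer densities 0.75/0.70/0.70, and to all other drugs at a
  leak factor of 0.01 — similar drugs hit the same proteins, with a
  little annotation noise.
- **Promiscuity.** Half the proteins additionally serve one random
  second scaffold. These proteins *bridge* structurally unrelated
  families and are the generator's mechanism for network-mediated
  interactions between dissimilar drugs — the phenomenon that makes
  network scores worth computing. Which families are bridged varies
  independently across layers, so no single score type sees every
  mechanism and integrating layers genuinely adds information.
- **PPI and pharmacogenetics.** Neighbour proteins link to targets at
  `ppi_density=0.25`, preferentially within the same scaffold family
  (pathway coherence), grounding the one-hop expansion.
  Pharmacogenetic edges attach at `pg_rate=0.08` with only a weak
  (3×) scaffold preference: pharmacogenetic association is treated as
  structurally diffuse, which keeps the pg scores informative but far
  from duplicating their physical counterparts. (A strong preference
  makes the pg and physical scores nearly collinear, which
  destabilizes fitted coefficients.)
- **Labels.** Every ordered pair is scored with the real engine and
  given probability `F(β₀+Σβs)` with planted coefficients
  (intercept −15.5; s_d 2.0; s_e 8.0; s_eg 1.2; s_tr 6.8; s_trg 1.0;
  s_ta 8.0; s_tag 1.2 — strong PK/PD network effects, a modest direct
  effect, weak pharmacogenetic effects, and a deep intercept so
  unrelated pairs rarely interact and DDI prevalence lands near 0.13).
  The unordered DDI label is Bernoulli in the mean of the two
  orientation probabilities.

### Ordered versus unordered labels

The unordered projection is information-lossy by construction: which
orientation carries the mechanism is discarded, and the two
orientations' linear predictors are nearly uncorrelated (sentinels and
category composition are properties of the De side only). A per-row
maximum-likelihood fit against shared pair labels therefore cannot
recover the planted coefficients — the shared label behaves like
extreme measurement error. The truth table consequently records two
label columns: `label`, the pair-symmetrized draw that populates the
universe's DDI layer and drives every pipeline and ordering check, and
`row_label`, a Bernoulli draw from the ordered probability itself.
Coefficient-recovery checks fit against `row_label`, the estimator's
exact generative frame; everything else uses the unordered labels.

### What passing tests do and do not show

The generator provides ground truth for *internal* validity: that
scoring implements its definitions exactly (verified against
brute-force oracles), that the fitting stack recovers planted
coefficients, and that the evaluation machinery is calibrated (chance
AUC on permuted labels, uniform nested-test p-values under the null).
It does not model real pharmacology: fingerprints are not molecules,
annotation sparsity is not curation bias, and DDI labels in real
databases are neither complete nor generated by any logistic model.
Absolute AUC values on synthetic universes say nothing about
performance on real extracts; the qualitative ordering of score sets
is the transferable claim.

## Numerical choices

- Tanimoto values are exact integer-count ratios (bit counts up to the
  fingerprint width are exact in the float32 matrix product used for
  the all-pairs computation; division happens in float64), so engine
  scores equal brute-force scores bit-for-bit.
- Category maxima use exact floating comparison; no tie-breaking is
  needed for a maximum of reals.
- Zero-variance feature columns are an error at fit time (they carry
  no information and break standardization).
- Degenerate folds (a fold missing one class) are reshuffled with an
  offset sub-seed, logged, at most ten attempts.
- Probabilities are computed through `logaddexp`, so extreme linear
  predictors neither overflow nor lose the likelihood's ordering.
- Candidate rankings break probability ties by ascending drug
  identifier to keep output deterministic.

## Problem sizes

Default analyses use the 300-drug universe (~27k balanced feature
rows); coefficient recovery uses 1000 drugs (~1M ordered rows, the
scale at which asymptotic standard errors are small relative to the
planted effects); null-calibration checks run on 2000-row subsamples
with 1000 replicate refits for the p-value uniformity test. These
sizes keep the full test suite and the acceptance script at a few
minutes on one CPU while leaving every estimate far from its
small-sample regime.

## Known limitations

- Metabolic directionality (inducer/inhibitor/substrate) and edge
  confidences are not modelled; all edges are binary and symmetric in
  consequence.
- PPI expansion is fixed at one hop from targets.
- Absence of a DDI annotation is taken as a negative label; there is
  no "unknown" tier, so real-world incompleteness becomes label noise.
- The leave-one-drug-out ranking scores candidates with the same
  orientation policy as training; case-study probabilities for
  orientation-asymmetric pairs depend on that choice.
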