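# Methods

This note documents the models, conventions and numerical choices behind
`gohidi`, and what the synthetic-data validation does and does not show.

## The indicator framework

The GOH-IDI hierarchy has three levels: 3 first-level indicators (human,
animal, environmental health), 15 second-level indicators, 61 third-level
indicators. Nodes are addressed by dotted codes whose depth equals their
level, so parentage is implicit ("1.2.3" sits under "1.2"). Each node
carries a weight relative to its sibling group; sibling weights sum to 1.

Two fixtures ship with the package. `goh_idi_final.json` is the published
final framework, including the second-level FAHP weights, entropy values,
EWM weights and integrated weights (also mirrored in
`goh_idi_weight_table.csv`). `goh_idi_initial.json` is the pre-revision draft
(3/19/79). The published record lists *which* indicators the expert panel
added, deleted, merged and renamed, but not which sibling group each
deleted third-level indicator belonged to, nor the draft numbering; the
initial fixture reconstructs plausible placements and is labelled a
synthetic reconstruction. `revision_log.json` encodes the documented
revisions; applying it (with code renumbering) to the initial fixture
reproduces the final framework node for node.

Revision conventions the record leaves open, fixed here:

* **merge** — the destination node inherits the union of the sources'
  children (recoded beneath it in source order) and the sum of the
  sources' weights;
* **renormalization** — any sibling group whose membership changed is
  rescaled proportionally to sum to 1;
* **renumbering** — an optional post-pass compacts sibling codes to 1..k
  so revised frameworks use contiguous codes.

Weights are stored in files as two-decimal percentages (the convention of
published framework tables — which in places truncate rather than round,
e.g. 14.28 for 1/7) and handled internally as full-precision fractions.
Validation therefore accepts sibling sums within 0.05 percentage points
of 100; exactly-constructed frameworks pass far tighter. Category tags
(structure/process/outcome) are carried as inert metadata and play no
computational role.

## Subjective weights (FAHP)

One judgment matrix per expert per first-level group, over that group's
second-level indicators. The default scale is the reciprocal Saaty 1–9
scale; a complementary 0.1–0.9 scale is supported and converted to ratio
form via b_ie = r_ie / r_ei before weighting. The published procedure
specifies the judgment matrix and the row-geometric-mean weight equations
but not the questionnaire scale, the fuzzy transformation, or how the 42
questionnaires were pooled — those are conventions of this package, chosen
to match standard group-AHP practice:

* **pooling** — element-wise geometric mean of expert matrices (exactly
  preserves reciprocity; the consensus of consistent matrices sharing a
  priority vector is consistent with that vector). A
  per-expert-weights-then-average mode is available behind a flag for
  sensitivity checks; the two routes coincide on consistent input.
* **weighting** — normalized row geometric means. The published procedure
  applies a second normalization after the first; it is a mathematical
  no-op (the first already normalizes) and is kept for fidelity. The
  weight equation's product index is read as running over the matrix's
  second subscript (a row-wise product), the only reading that yields row
  geometric means.
* **guards** — entries are clipped to [1e-6, 1e6] before the log
  transform, with a warning.

A principal-eigenvalue consistency ratio (CI/RI with the tabulated random
index) is provided as a diagnostic for reciprocal matrices; order ≤ 2 is
always consistent.

## Objective weights (EWM)

Min–max standardization by orientation, column share distributions,
normalized Shannon entropy with the 0·ln 0 := 0 convention (the entropy
limit; an epsilon mode that adds 1e-12 before forming shares is available
for comparison), and weights W_j = (1 − e_j)/Σ(1 − e_k), computed
independently within each first-level sibling group. Degenerate-input
conventions:

* a **constant column** standardizes to 0.5 everywhere — uniform shares,
  entropy 1, weight 0: no variation, no information;
* an **all-zero standardized column** is assigned uniform shares (entropy
  1) with a warning;
* if **every** entropy equals 1 the weight denominator vanishes; uniform
  weights are returned with a warning.

Implemented as written, the normalized entropy is bounded: 0 ≤ e_j ≤ 1.
The published framework table prints per-indicator entropy values between
1.13 and 2.01, which no normalized-entropy computation can produce; the
package does not endorse that scale, but the weight formula is a simple
normalization of (1 − e_j) and remains well defined on it — applied to
the printed entropies it reproduces the printed EWM weights. The
back-check is property-graded: naive re-application to two-decimal-rounded
e reproduces the printed weights to 0.13 pp in the human- and
environmental-health groups but drifts to 0.25 pp in the animal-health
group, where |1 − e| is as small as 0.13 and rounding of e propagates
strongly; a Chebyshev fit shows each group's printed e and W columns are
mutually consistent (e_j = 1 + s·W_j for a single group scale s) within
e's ±0.005 printing precision.

Two structural properties worth stating together: EWM weights are
invariant to positive affine transforms of a raw column (min–max
standardization absorbs them), and consequently *dispersion per se does
not move entropy weights within a location-scale family* — doubling a
normal indicator's σ changes nothing after standardization. Dispersion
matters through distribution shape: a mean-preserving spread of the
standardized values, or a shape parameter such as lognormal σ, lowers
entropy and raises weight. The monotonicity tests exercise exactly those
mechanisms.

The country-level dataset behind the published entropies (countries,
years, source databases) is not published, so the EWM column cannot be
re-derived end to end from raw data; the synthetic generator stands in.

## Integration

W = β·W_subj + (1 − β)·W_obj. The blending coefficient minimizes
Z(β) = Σ[(W − W_subj)² + (W − W_obj)²]; since both deviations are
proportional to (W_subj − W_obj), Z = [(1−β)² + β²]·Σd² and the minimizer
is 0.5 whenever the vectors differ — the published derivation prints the
objective without the squares, but a linear-in-β objective has no interior
minimizer, so the squared form stated in the accompanying text is
implemented. For identical vectors the objective is identically zero and
0.5 is returned with a flat-objective flag. The minimization runs through
bounded scalar optimization; tests verify it against an independent grid
search.

Blending the published FAHP and EWM percentage columns at β = 0.5
reproduces all 15 published integrated weights to two decimals within
±0.01 pp (the table mixes round-half-up and round-half-down on exact .005
cases, e.g. 14.265 → 14.27 but 33.915 → 33.91, hence the ±0.01 rather
than ±0.005).

## Composite scoring

Scores aggregate bottom-up as linear weighted means at each level —
matching the additive semantics of the weight table and keeping anchors
at 0 and 100 — with equal weights at levels 1 and 3 and FAHP-EWM weights
at level 2. Standardization anchors default to the supplied entity pool
(relative scoring: the pool-best profile scores 100); fixed external
min/max anchors can be passed instead. Sibling weights are renormalized by
their group sum during aggregation so the 0.04 pp truncation in
two-decimal fixtures cannot leak into scores. The published study derives
weights but never scores countries; this module is forward-looking
plumbing consistent with the framework.

## Synthetic data and what the tests show

The expert generator mirrors the study geometry: 42 experts, groups of
6/4/5 second-level indicators. Default true priorities are the published
FAHP weights renormalized within each group, so simulations run at the
magnitudes the method actually faced. Judgments follow the standard
multiplicative AHP error model r_ie = (w_i/w_e)·exp(ε),
ε ~ N(0, noise_sd²), mirrored so each matrix is exactly reciprocal;
noise_sd defaults to 0.1 (roughly a one-scale-step wobble on adjacent
judgments). Values are clipped to the 1/9–9 scale bounds (untriggered at
default settings). The data generator draws independent normal or
lognormal columns per indicator with configurable location, dispersion
and orientation, sized at 50–300 entities in the tests — country-panel
scale.

Under these conditions: a noise-free panel recovers the true priorities
to 1e-12; the 42-expert panel at noise 0.1 recovers them with RMSE well
under 0.05; higher lognormal dispersion wins the EWM weight comparison in
20/20 seeds; and the full simulate → FAHP / EWM → β = 0.5 pipeline lands
within RMSE 0.05 of the blend of the two ground truths. What this does
*not* show: robustness to correlated expert opinion (the error model is
independent across experts and pairs), to missing or imputed country
data, to outliers (no winsorization is implemented), or to indicator
collinearity — real SDG/GBD/EPI-style panels have all four. The
generators are a correctness harness, not a realism claim.

## Known limitations

* The published FAHP weights cannot be re-derived from raw data (the 42
  questionnaires are unpublished), nor can the EWM entropies (the country
  dataset is unpublished); both are validated by back-checks on the
  printed table plus parameter-recovery simulation.
* Incomplete judgment matrices are rejected, not completed; triangular
  fuzzy-number extent analysis is out of scope.
* Scoring uses pool-relative anchors by default; cross-pool score
  comparisons require fixed external anchors.
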