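# Methods

## The model

The package quantifies how well a future land-use scenario would serve
the public-good desires a stakeholder has expressed. Both sides are
coded on one ordered catalog of agri-environmental-climate public goods
(AECPGs; the bundled default has nine entries, from biodiversity to
climate regulation).

A stakeholder j is a pair of vectors over the catalog: a desire score
d_ij and a weight w_ij. Organisation visions are scored binarily
(d ∈ {0, 1}); weights encode salience in the vision text — 0 for an
unmentioned good, 1 for a mentioned or implied one, 2 for a central
one. Two structural rules follow from that reading: an unmentioned good
(w = 0) cannot carry desire (d = 0 is forced), and an included vision
must touch at least one good (Σw > 0). Both are hard validation errors,
not warnings, because every downstream quantity divides by Σw.

A scenario is a vector e_i ∈ {0, 0.5, 1}: indifferent, active
conservation of current levels, or demonstrable enhancement.

Agreement between scenario and stakeholder is a weighted, normalised L1
distance mapped to a percentage:

    DEA = Σ_i |e_i − d_ij| · w_ij
    PA  = Σ_i w_ij
    Agreement = 100 · (PA − DEA) / PA .

Because e and d both live in [0, 1], each DEA term is at most w_i, so
0 ≤ DEA ≤ PA and agreement lies in [0, 100]. Agreement is 100 exactly
when the scenario matches the stakeholder on every positively weighted
good; it is invariant under rescaling all of one stakeholder's weights
by a positive constant; and PA = 0 raises an error rather than
returning a silent 0 or 100, since a stakeholder with no weighted goods
has no defined stance.

Group summaries take the arithmetic mean of the member agreements
(rounded half-up to one decimal for reporting; all computation uses
unrounded values). The per-scenario "overall" agreement is reported as
an integer percentage and can aggregate two ways — the mean over all
stakeholders (default, so large groups weigh more) or the mean of the
group means (one vote per group) — because published summary tables of
this kind typically do not say which convention they used. The
reproduction harness (`aecpg_align.reproduction`) therefore tries both,
together with both class-boundary policies, and reports which
combination matches a set of reference values.

Agreement percentages are labelled with five classes whose printed
definitions overlap at 20/40/60/80. The default policy closes the
60–80 band at 80, so "high agreement" means strictly above 80; the
alternative (`high_from_80`) closes every band on the left. The policy
affects labels only, never numbers.

The optimal scenario is the argmax of overall agreement; exact ties
keep the first scenario in input order and emit a warning.

## Citizen scoring

Citizens enter through survey percentage tables (share of respondents
expressing desire per subgroup and good) rather than vision documents,
and use three desire levels: the extra 0.5 separates support for active
conservation from a clearly observable desire for more delivery. The
original mapping from percentages to levels was qualitative; here it is
reified as a two-threshold step function — below t_mid → 0, from t_mid
→ 0.5, from t_high → 1 — because only an explicit rule is reproducible.
The defaults t_mid = 30 and t_high = 60 are plumbing defaults chosen to
bisect the observed percentage range of the bundled survey table; they
are configuration, not estimates of the original judgment, and both are
exposed everywhere citizen scoring is used. Multiple questions per good
are fused by averaging the question-level scores and snapping to the
nearest of {0, 0.5, 1} with ties upward — deterministic and
order-independent. Citizen weights default to uniform 1 (the 0/1/2
weighting has no survey analogue) and are configurable.

## Meta-scenario synthesis

Individual scenario studies sharing a theme are coded on the catalog
with the same 0/0.5/1 alphabet and fused by per-good averaging followed
by snapping to the nearest level. Exact midpoints (0.25, 0.75) snap
upward by default (`tie="down"` is available); the choice is arbitrary
but fixed, and only affects averages landing exactly between levels.
Synthesis is idempotent, permutation-invariant and monotone in every
source value.

## Sensitivity analyses

Two scoring-robustness re-runs accompany every analysis: *simplified
weights* (all weights 2 → 1, removing the central/mentioned
distinction) and *simplified delivery* (all supply 0.5 → 0, counting
active conservation as nothing). Both transforms return new objects,
are idempotent, and are identities on matrices that do not use the
collapsed level.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the underlying vision texts. Per organisation group g and good i:
d = 1 with probability p_gi; a desired good is central (w = 2) with
probability c_gi, else w = 1; an undesired good is still mentioned
(w = 1) with probability m_gi, else w = 0. Draws violating the Σw > 0
inclusion criterion are redrawn. Citizen subgroups are generated by
drawing a survey table around a true percentage profile (Gaussian
noise, clipped to [0, 100]) and pushing it through the threshold
scorer, exactly as real survey tables would be. Supply vectors draw
each level independently from per-scenario level probabilities.

The bundled case-shaped configuration (`dutch_case_config`) mirrors the
Dutch national assessment: ten groups with sizes 6, 5, 6, 18, 7, 13, 3,
3, 9 and 13 (83 stakeholders), organisation desire probabilities equal
to the published per-group mean desire scores, and citizens drawn
around the published 13-subgroup survey percentages with 2 questions
per good and 3 percentage points of noise. The centrality and mention
probabilities are not derivable from published summaries; they default
to c = 0.3 and m = 0.2 — central goods a minority of a vision's
mentions, and occasional mention without desire — and are set once, per
group or per good, in configuration. Randomness uses one seeded
generator per artifact (desire, survey, supply), keyed by the config
seed plus a stable stream tag, so generating one artifact never shifts
another and identical configs are bit-identical.

What passing tests on synthetic data do show: the statistic, its
summaries, the transforms and the pipeline behave correctly on data
with the study's shape and first moments. What they cannot show:
anything about the joint structure of real visions (correlated desires
across goods, group-specific weighting styles), which the generator
draws independently per good.

## Numerical choices

- Scores, weights and supply levels are validated by exact membership
  in their alphabets ({0, 0.5, 1} and {0, 1, 2}); all are exactly
  representable in binary floating point, so no tolerances are needed
  anywhere in the statistic.
- Report rounding is half-up (group means to one decimal, overall
  agreement and summary cells to integers / two decimals); banker's
  rounding would bias printed ties downward half the time.
- Snapping ties (exact 0.25/0.75 averages) go upward by default; the
  comparison uses a 1e-12 slack so binary-exact midpoints are
  recognised.
- Standard errors use the n−1 sample standard deviation over √n
  (verified against the published group summaries, which are only
  reproducible with the n−1 convention); single-member groups report
  SE 0.
- Degenerate inputs: empty matrices, PA = 0 records, mixed-theme
  coding sets, and out-of-range percentages all raise typed errors;
  the pipeline removes partially written report bundles on failure.

## Problem sizes

The default test and acceptance runs use the study-sized problem
(83 stakeholders × 9 goods × 4 scenarios × 3 analysis blocks) plus a
parameter-recovery run at 200 stakeholders per group; both complete in
seconds on one CPU.

## Known limitations

- The original stakeholder-level desire matrix is not redistributable,
  so exact reproduction of the published agreement table is exercised
  against self-consistent synthetic references; the spreadsheet
  ingestion adapter (`read_desire_matrix_xlsx`) is written against
  plausible header layouts and accepts an explicit column map for
  layouts its heuristics miss.
- No uncertainty quantification of agreement values (the statistic is
  a point value; bootstrap over stakeholders would be a natural
  extension).
- Figure rendering is intentionally out of scope; all outputs are CSV.
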