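# Methods

## Model

`carecascade` evaluates a deterministic cohort-expectation model of a care
pathway. A scenario is a starting population N₀ > 0 and an ordered
sequence of filters, each a proportion pᵢ ∈ [0, 1]; the expected count
after filter *i* is Nᵢ = Nᵢ₋₁ · pᵢ, so the final success count is
N₀ · Π pᵢ. Counts are continuous expectations, not integers: this is a
cohort model, not a microsimulation, and Table-style outputs such as
"44,156 remissions" are expectations rounded to whole persons at report
time only. All intermediate arithmetic is carried at full floating-point
precision because the derived outputs (incremental successes, ICERs) are
only reproducible from unrounded intermediates.

Assumptions the model inherits from its structure:

- **Independence of filters.** Changing one filter's proportion never
  alters another's. Real interventions can violate this (training GPs to
  offer treatment may also improve adherence); the model cannot express
  such spillovers.
- **A single implicit time horizon.** No discounting; the outcome filter
  (e.g. remission at six months) simply terminates the cascade.
- **Perfect classification.** Detection-style filters pass a fraction of
  the truly affected; false positives and their downstream costs are not
  modelled.
- **Intervention costs only.** No health-system cost offsets, severity
  stratification, or patient-perspective costing.

## Costs and economics

A filter may carry a unit cost c ≥ 0 applied to one of two bases:

- `post_step` (default): total cost = c · Nᵢ, the persons *passing* the
  step. This is the convention of the bundled worked example (e.g. a $5
  screening cost multiplying the 835,714.9 detected, not the 1,085,344
  screened).
- `pre_step`: total cost = c · Nᵢ₋₁, every entrant. Offered explicitly
  because a screening cost arguably applies to everyone screened; the
  choice is the user's and materially changes totals.

Per-scenario outputs: total cost; cost per participant exposed (total
cost over the cost-basis count of the costed step — with several costed
steps the earliest step's basis count is used, being the widest exposure
since counts only shrink along the cascade); cost per success (total cost
over final successes). Ratios with a zero denominator and nonzero
numerator are *undefined*, represented as `None` and rendered `n/a` —
never a crash, never ±inf.

Scenario-versus-baseline comparison produces incremental cost ΔC,
incremental successes ΔE, and ICER = ΔC/ΔE (undefined when ΔE = 0). The
cost-effectiveness-plane quadrant is a pure sign mapping: (+,+) and
(−,−) are trade-offs, (−,+) is dominant, (+,−) dominated, (0,0)
equivalent. Zero on a single axis is resolved conventionally: a free
improvement (ΔC = 0, ΔE > 0) or a pure saving (ΔC < 0, ΔE = 0) is
dominant; a pure cost or pure loss is dominated. The ICER is computed in
all quadrants where it exists but flagged "meaningful" only in the two
trade-off quadrants — under dominance the sign pattern already decides
and the ratio invites misreading. Zero means exactly zero at full
precision; callers comparing noisy quantities should threshold before
classifying.

Report rounding is half-up (half away from zero), matching how the
bundled example's published figures behave (e.g. 17,203.57 → 17,204); it
is applied once, at render time, so a re-parsed CSV cell equals the
rounded in-memory value exactly.

## Interval bounds (deterministic sensitivity analysis)

Any input parameter — a step's proportion, a unit cost, or the population
— may be given a closed interval; the set of intervals defines a box. An
interval can perturb the intervention scenario, the baseline, or both in
lockstep (the natural choice for shared inputs like population size).

Counts and total cost are multilinear in the parameters and monotone in
each, so their exact extrema lie at box corners; the module enumerates
all 2^k corners (guarded by a configurable limit, default k ≤ 12, beyond
which it refuses and suggests one-way analysis). Ratio outputs (cost per
success, ICER) are ratios of multilinear functions for which corners are
not guaranteed extremal; no closed-form optimiser is attempted. Instead
the box interior is additionally sampled with a seeded Halton sequence
(default 1,000 points) and the envelope widened to cover every sample;
such envelopes are labelled `corner+sampled` and are honest outer
approximations validated by Monte-Carlo containment tests, not certified
bounds. When ΔE can touch or cross zero inside the box the ICER is
unbounded and its envelope is reported undefined with a diagnostic
rather than as a misleading finite pair. Degenerate (zero-width)
intervals collapse exactly to the point evaluation.

## Configuration and reporting

A YAML file (schema_version 1) declares the population, the ordered step
list, and named scenarios as *sparse overrides* of the designated
baseline — writing only what an intervention changes prevents
transcription drift between scenario columns. Validation is strict
(unknown keys rejected, every failure reported with its field path).
Reports render as fixed-width text, CSV (long format, stable column
names), or JSON-lines; undefined values appear as `n/a` (text/CSV) or
`null` (JSON). The CLI (`run`, `bounds`, `example`) is a thin wrapper
over the library; metadata logs to stderr, results to stdout or files.

## Validation oracles

Two independent checks back the deterministic core:

- **Closed form.** Final successes must equal N₀ · Π pᵢ to 1e-9 relative
  on randomly generated scenarios (the generator draws proportions
  uniform on [0, 1], unit costs uniform on a configurable range, and a
  random cost basis per step — deliberately broader than realistic
  pathways to exercise edge cases).
- **Bernoulli microsimulation.** Each of n simulated individuals passes
  filter *i* by an independent Bernoulli(pᵢ) draw; costs accrue per
  costed individual. Empirical success counts must agree with n · Π pᵢ
  within 3σ binomial at n = 200,000, and empirical mean cost per person
  converges to total cost over population. The microsimulation shares the
  independence assumption with the expectation model, so agreement
  validates the arithmetic, not the assumption.

Passing tests therefore show the implementation computes its stated model
correctly; they say nothing about whether a real pathway's filters are
independent or its parameters well-estimated.

## Bundled worked example

The depression-in-primary-care configuration (population 15,055,403;
proportions 0.089, 0.81, 0.47, 0.28, 0.51, 0.37; interventions: detection
0.77 at $5, reach 0.69 at $247, adherence 0.65 at $98; AUD) is shipped as
package data and pinned by regression tests. Recomputing its outcome
block at full precision reproduces every published figure to the printed
integer except one: the training scenario's incremental cost computes to
$86,938,334 against a published $86,938,336, a ±$5-scale rounding
inconsistency in the source spreadsheet. The package reports its own
full-precision value.

## Known limitations

- Ratio envelopes are sampled outer approximations, not certified; a
  pathological box could in principle hide a ratio extremum between
  samples.
- Quadrant classification at exact zero is knife-edge by design; no
  tolerance band is applied.
- No probabilistic sensitivity analysis (distributions, CEACs) — ranges
  only.
- No QALYs, utilities, or willingness-to-pay thresholds: effectiveness is
  a dichotomous success count.
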