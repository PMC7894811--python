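# carecascade

Filter-cascade cost-effectiveness modelling for care pathways.

Many care pathways lose patients at every stage: of everyone with a
condition, only a fraction attend the relevant setting, only a fraction of
attendees are detected, only a fraction of the detected are offered
evidence-based treatment, only a fraction of those adhere, and only a
fraction of adherers achieve a successful outcome. `carecascade` models
such a pathway as a *filter cascade*: a population N₀ flows through an
ordered sequence of proportion filters p₁, …, p_m, so the expected count
after step *i* is

    N_i = N₀ · p₁ · p₂ · ⋯ · p_i

An intervention scenario changes one or more filter proportions and
attaches a per-person unit cost c at the modified step, giving a total
intervention cost c · N_i (the cost applies to the persons passing the
step by default; charging every entrant is available as an explicit
alternative). Scenarios are compared against a designated baseline via

- incremental cost ΔC and incremental successes ΔE,
- the incremental cost-effectiveness ratio ICER = ΔC / ΔE (cost per
  additional success),
- a cost-effectiveness-plane quadrant classification (dominant /
  dominated / trade-off / equivalent) with plain-language policy advice.

Uncertain inputs can be given as intervals instead of point values; the
package propagates the parameter box to lower/upper envelopes on every
output (exact corner enumeration for the multilinear outputs, corner plus
seeded quasi-random interior sampling for the ratio outputs).

The intended users are health-services researchers and policy analysts who
want a transparent, auditable alternative to spreadsheet models for
"where should we intervene in this pathway?" questions. Everything is
driven by a small YAML configuration; no economics software is required.

## Worked example: depression management in general practice

The bundled example models depression care for the 15,055,403 Australian
adults aged 18–75: prevalence 8.9%, GP attendance 81%, detection 47%,
treatment offer (reach) 28%, adherence 51%, remission at six months 37%.
Three intervention scenarios each improve one filter: routine
waiting-room screening (detection 47% → 77%, $5 per detected patient), GP
education and training (reach 28% → 69%, $247), and telephone follow-up
(adherence 51% → 65%, $98). All amounts AUD.

```bash
carecascade example --out depression.yaml
carecascade run depression.yaml
```

prints the per-step expected counts for all four scenarios and then the
outcome block (abridged):

```
scenario                metric     value
 filter1      cost_per_success        95
 filter1      incremental_cost   4178574
 filter1 incremental_successes     17204
 filter1                  icer       243
 filter2      cost_per_success      1309
 filter2      incremental_cost  86938334
 filter2 incremental_successes     39466
 filter2                  icer      2203
 filter3      cost_per_success       265
 filter3      incremental_cost   9098352
 filter3 incremental_successes      7399
 filter3                  icer      1230
```

Reading: screening (filter1) adds 17,204 expected remissions for
$4,178,574, i.e. $243 per additional remission — the cheapest option per
success. GP training (filter2) adds the most remissions (39,466) but at
$2,203 each; telephone adherence support (filter3) adds the fewest
(7,399) at $1,230 each. All three are more effective *and* more expensive
than usual care, so none dominates: the choice is a willingness-to-pay
judgement the ICER informs. Counts are expectations rounded to whole
persons only for display; internally everything is carried at full
floating-point precision (44,156 successes is really 44,155.83…).

`carecascade bounds depression.yaml` runs the interval analyses declared
in the config — the example varies detection over [0.47, 0.77], giving a
successes envelope of [26,952, 44,156].

The same machinery is available as a library:

```python
import carecascade as cc

config = cc.builtin_depression_scenarios()
report = cc.run_model(config)
report.comparisons["filter1"].icer  # 242.88995...
```

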