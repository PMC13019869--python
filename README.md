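# smokefree

Lifetime Markov cohort cost-utility models of smoking and vaping status
for people released from smoke-free prisons, and for their partners and
children.

## The problem

Smoke-free prison policies eliminate tobacco use during custody, but
around 90% of people who smoked before prison relapse to smoking soon
after release. Two policy levers shape what happens next: whether
vaping is permitted inside the smoke-free prison, and whether a
cessation intervention is offered around the time of release. The
knock-on effects reach beyond the released person — partners are exposed
to second-hand smoke (SHS) when the released person smokes, and
children's uptake of smoking and vaping depends on the adult's status.

This package is for health-economics and public-health analysts who
want to run, interrogate or extend that decision model: four released-
person policy scenarios, three household scenarios each for partners
and children, lifetime cost and quality-adjusted-life-year (QALY)
accumulation, pairwise cost-utility comparison, and probabilistic and
deterministic sensitivity analysis.

## The model

Each cohort advances through yearly cycles over the state space
{non-nicotine, smokes, used-to-smoke, vapes, used-to-vape, dead}
(partners gain a distinct SHS-exposed non-nicotine state). Within a
cycle, mortality acts first — the age/sex life-table probability
$q(a, \mathrm{sex})$ scaled by a per-state relative-risk product
(smoking, SHS exposure, post-release excess), capped at 1 — and annual
behavioural transitions redistribute the survivors. Over a trace of
occupancy vectors $\pi_t$, discounted totals are

$$C = \sum_t \frac{\pi_t \cdot c(a_t)}{(1+r_c)^t}, \qquad
Q = \sum_t \frac{\pi_t \cdot u(a_t)}{(1+r_o)^t},$$

with per-state annual costs $c$ (healthcare, personal
smoking/vaping spend, first-year intervention) and utilities $u$
(0 = death, 1 = full health), both age-adjusted, at 3.5%/year
discounting. Scenario pairs are compared by incremental cost
$\Delta C$, incremental QALYs $\Delta Q$, the ICER
$\Delta C/\Delta Q$ (or a dominance label), and incremental net
monetary benefit

$$\mathrm{iNMB} = \lambda \Delta Q - \Delta C, \qquad \lambda = £20000/\mathrm{QALY},$$

where iNMB > 0 indicates cost-effectiveness. Parameter uncertainty is
propagated by probabilistic sensitivity analysis: beta distributions
for probabilities and utilities, gamma for costs, shifted lognormal for
relative risks, with all scenarios evaluated on a common draw and 95%
intervals taken as 2.5/97.5 percentiles.

The four released-person scenarios cross the two policy levers:
1 vaping permitted / no intervention, 2 no vaping / no intervention,
3 vaping permitted / intervention, 4 no vaping / intervention. The
three comparisons are 1 v 2, 1 v 3 and 2 v 4 (first-listed minus
second).

The original analysis's full input table sits in supplementary
material that is not publicly reproduced, so the packaged defaults
anchor every printed value (£112
intervention unit cost, £20,000/QALY threshold, 70%/90% pre-prison
smoking and relapse, 76%/92.1% in-prison vaping and vaper relapse
implied by the printed prevalence rows, partner rates 21%/10%, child
baseline uptake 15.2% with status relative risks from the printed
prevalences) and fill the remainder with documented plausible choices,
each provenance-tagged so a user-supplied parameter file can replace
them wholesale. See `docs/methods.md`.

## Worked example

```python
from smokefree import default_parameters, ReleasedCohortModel

params = default_parameters()
print(ReleasedCohortModel(params, scenario=3).run().summary())
```

```
Scenario 3: vaping permitted, intervention offered
----------------------------------------------------------
Healthcare cost (discounted)   £     6,425
Personal cost (discounted)     £    26,901  (3% vape)
Intervention cost              £        43
Total cost (discounted)        £    33,369
Life-years (discounted)              19.89
QALYs (discounted)                   15.30
Prevalence at release:
  neither                 24.0%
  smoker                  68.2%
  former_smoker            1.8%
  vaper                    5.8%
  former_vaper             0.2%
```

Reading: 68.2% of this cohort smoke at release (76% vaped in prison, of
whom 92.1% relapse to smoking, less the 1.8% whom the intervention
moves to former smoking); the £43 intervention cost per released person
is the £112 unit cost times the offered (76%) and engaging (50.5%)
fractions. Personal spend on smoking and vaping dominates lifetime
costs. Comparing scenarios:

```python
from smokefree import compare_scenarios
s1 = ReleasedCohortModel(params, 1).run().outcome
s2 = ReleasedCohortModel(params, 2).run().outcome
r = compare_scenarios(s1, s2, params.wtp_threshold)
# dC £4,014, dQ -0.278, dominated (more costly and less effective), iNMB £-9,580
```

Permitting vaping is more costly and less effective than not permitting
it (negative iNMB), while offering the intervention dominates not
offering it in both policy settings — matching the published direction
of results. Lowering in-prison vaping prevalence to 60% or vaper
relapse to 50% reverses comparison 1's sign
(`smokefree.one_way_sensitivity`).

A command-line interface mirrors the library:

```bash
smokefree full --out results/ --seed 1 --draws 1000
smokefree released --scenario 2 --out results/s2/
smokefree household --member child --released-status smokes --out results/child/
```

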