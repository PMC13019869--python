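# Methods

## Model structure

Three lifetime Markov cohort models share one engine:

* **Released person** — state space {neither, smoker, former_smoker,
  vaper, former_vaper, dead}, entered at release (default age 35,
  male). The cycle-0 split depends on the prison's vaping policy:
  where vaping is permitted, in-prison vapers (76%) either relapse to
  smoking (92.1%) or continue vaping, and non-vapers leave
  nicotine-free; where vaping is not permitted, pre-prison smokers
  (70%) relapse to smoking (90%) or leave nicotine-free. A cessation
  intervention, in the scenarios that offer one, acts only in the first
  post-release year: the offered group (in-prison vapers or pre-prison
  smokers, by policy) engages at 50.5%, engagers quit with absolute
  probability 5.2% (smokers → former smokers, vapers → former vapers),
  and the per-person cost is unit cost × offered × engagement — hence
  always below the £112 unit cost. No benefit of vaping as a cessation
  aid is modelled; reimprisonment and dual use are out of scope.
* **Partner** — the same state space plus a distinct non-nicotine
  SHS-exposed state, occupied by non-nicotine partners if and only if
  the released person smokes. Partners enter (default age 35, female)
  at their own rates — 21% smoke, 10% vape — independent of the
  released person's status, and never change state in the base case.
* **Child** — the released-person state space, entered at age 15 with
  uptake probabilities equal to a 15.2% baseline ever-uptake rate
  (smoking and vaping each) scaled by parental-status relative risks:
  2.566/1.776 (smoke/vape uptake, parent smokes), 1.974/1.447 (parent
  vapes), 1/1 (neither). These reproduce the published child
  prevalence columns (39/27, 30/22, 15/15 per cent) from one base rate,
  which is also what the published best/worst-case sensitivity (7.6% /
  22.8%) varies.

Within a cycle, mortality acts first: the death probability from state
*s* at age *a* is `q(a, sex) × RR(s)` capped at 1, where the relative
risks multiply — every released-person state carries a post-release
excess (1.5), current smokers a smoking excess (2.0), SHS-exposed
partners an SHS excess (1.05). Survivors then take the annual
behavioural transitions (quit, relapse, switch), all 0 in the base
case: the published prevalence rows keep former-use at 0% through the
no-intervention scenarios, and printed personal costs equal initial
prevalence × annual spend × discounted life-years almost exactly, both
implying no background cessation. The parameters exist (and are
exercised in tests) for sensitivity use. Cycling stops at age 100 or
when living occupancy falls below 1e-9.

## Economics

Costs and utilities are attributed at cycle start with discount factor
`1/(1+r)^t`, `r = 3.5%/yr` for both costs and outcomes (UK appraisal
convention; the source describes discounting without stating a rate).
No half-cycle correction is applied in the base configuration, matching
that choice's silence in the source; `half_cycle=True` switches the
accumulator to trapezoidal averaging so its effect can be inspected
(it changes totals by roughly half of one year's flow).

Healthcare costs are per-state annual amounts at a 45–64 reference
band (non-user £100, smoker £500, former smoker £200, vaper £200 —
reflecting acute-bronchitis-type vaping harms, former vaper £150, SHS
excess £25) times an age multiplier (0.5 below 45, 1.0 at 45–64, 1.8
from 65): smoking-related disease costs concentrate at older ages, and
no age-constant schedule is consistent with the published released /
partner / child healthcare totals simultaneously. Personal spend is
£2,000/yr (smoking) and £600/yr (vaping) at 2022 community prices —
these two, with the printed prevalences, reproduce the published
personal-cost anchors and their smoking/vaping splits closely.
Utilities are 0.88/0.79/0.85/0.84/0.85 (neither/smoker/former
smoker/vaper/former vaper) with a 0.02 SHS decrement, times an
age-band multiplier (1.0/0.915/0.85/0.78 at <45/45/65/75) shaped like
population EQ-5D norms.

Comparisons report ΔC, ΔQ, the ICER (ΔC/ΔQ) or a dominance label
("dominated" = more costly and less effective, attached to the
first-listed scenario; "dominant" = the reverse; ΔQ = 0 with ΔC ≠ 0 is
"cost difference only"), and iNMB = λΔQ − ΔC at λ = £20,000/QALY. The
iNMB identity holds to machine precision on unrounded values.

## Uncertainty

PSA distributions are method-of-moments fits centred on the base case:
beta for probabilities and utilities, gamma for costs, and 1+lognormal
for relative risks (keeping the smoking and SHS risks ≥ 1, as their
invariants require). Parameters are sampled independently — no
correlation structure is specified by the source. Every scenario is
evaluated on the same draw, so per-draw increments and the
cost-effectiveness plane are free of between-arm parameter noise.
Confidence intervals are 2.5/97.5 percentiles of the draws. Structural
policy quantities (prevalences at release, partner rates) are held
fixed; behavioural, cost, utility and risk parameters are sampled.

The deterministic one-way analysis varies, one at a time: in-prison
vaping prevalence (to 60%), vaper relapse (to 50%), vaping harms
(doubled vaper healthcare cost; vaper utility −0.02), intervention
engagement (to 66%), and intervention intensity as paired
(cost, quit-effect) levels — low (£55, 2.6%), medium (£112, 5.2%),
high (£225, 10.4%), a NICE-style three-level structure. The child
analysis re-runs the smoking-parent household at baseline uptake
7.6%/15.2%/22.8%.

## Synthetic defaults and what the tests show

No raw data exist for this model; the packaged defaults emulate the
structure of the original supplementary input table. Printed values
are fixed; values implied by printed tables are derived (the 76%
in-prison vaping / 92.1% vaper relapse pair solves the printed 70%/6%
prevalence row; engagement 50.5% and quit effect 5.2% solve the
printed £43 mean intervention cost and 2% former-smoker prevalence
given the £112 unit cost); the rest are provisional single choices
from plausible ranges, documented in `smokefree.synthetic`, and
`generate_default_parameters(seed)` re-draws them within those ranges
for structural-robustness checks. Mortality is a Gompertz–Makeham fit
shaped like UK national life tables (male q(35) ≈ 0.0015 doubling
every ~7.5 years; female lighter), with ages beyond the table reusing
the last row.

Consequently the passing tests demonstrate the model's *structure* —
conservation, absorbing death, engine/microsimulation agreement,
discounting arithmetic, the iNMB identity, the published orderings,
dominance pattern and sensitivity sign reversals, and that the
base case falls within most of the published uncertainty intervals —
not a value-for-value reproduction of the published tables, which
would require the original input table. Known gaps with the packaged
defaults: discounted life-years run ~2.3 years above the published
released-person values (the provisional mortality inputs are lighter
than the original's), and the single healthcare age profile cannot
match the released, partner and child healthcare totals at once (the
published totals are mutually inconsistent with any age-constant
per-state cost, and our chosen profile splits the difference). A
user-supplied parameter file in the documented format replaces every
default without code change.

One published inconsistency is deliberately preserved rather than
normalised: the partner prevalence column prints 63% non-nicotine +
21% smoke + 10% vape = 94%; the model allocates the true residual
(69%) to the non-nicotine state.

## Numerical choices and problem sizes

Traces use dense numpy arrays; rows of every transition matrix sum to
1 within 1e-12 and occupancies to 1 within 1e-9 (asserted in tests).
Ties and degenerate inputs: zero-variance PSA specs return the mean;
relative-risk products pushing a death probability past 1 are capped
with a logged warning; a cohort is considered extinct below 1e-9
living occupancy. The test suite runs the microsimulation oracle at
n = 40,000–100,000 individuals (4-SE per-cell agreement bound — ~126
cells per instance makes a 3-SE bound trip on sampling noise) and PSA
at up to 1,200 draws; the acceptance script uses 10,000 draws,
matching the published analysis's means-with-CI reporting. Lifetime
horizons are 65 cycles (adults from 35) and 85 cycles (children from
15).

## Limitations

Beyond the source model's own scope limits (no reimprisonment, no dual
use, no vaping-as-cessation-aid benefit, partner status fixed), the
package inherits the evidence gaps the original authors flag: vaping
harms are represented only through healthcare cost and a small utility
gap, long-term vaping risk is unknown, and the post-release relapse
evidence comes from a no-vaping prison system. The synthetic defaults
add one more: absolute cost/QALY levels are only as good as the
provisional inputs, so analyses should prefer within-model contrasts
(increments, orderings, sign reversals) unless the original input
table is supplied.
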