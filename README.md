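# aba-cea

Cost-effectiveness analysis of **early intensive ABA-based interventions**
(EIBI and naturalistic developmental behavioural interventions) versus
**treatment as usual (TAU)** for pre-school autistic children, from UK
payer perspectives.

The package is a tested, configurable re-implementation of a spreadsheet-era
decision model, aimed at health economists and HTA analysts who want to
inspect, perturb and extend the analysis: every input is a named parameter
with a mean, standard error, distribution and range; every result is
reproducible from a config file and a seed.

## The model

A cohort model with monthly cycles tracks mean cognitive ability (IQ) and
adaptive behaviour (Vineland composite, VABS) from age 3 to 18.5 years
(186 cycles). TAU scores drift linearly (−0.28 IQ and −0.45 VABS points per
year); the intervention arm adds a piecewise-linear treatment effect that
reaches Δ_1 = (9.16 IQ, 2.92 VABS) at one year and Δ_2 = (14.13, 7.00) at
two years, then either persists (*optimistic* durability) or decays
linearly to zero at seven model years (*pessimistic*).

Cohort scores drive all outcomes:

- **School placement** — cumulative-logit models give the mix over
  {mainstream, mainstream + support, special education} at primary and
  secondary entry: P(setting ≤ k) = expit(c_k − β_v·VABS − β_q·IQ).
- **Utility** — u = β₀ + β_a·age + β_a²·age² + β_d·ADOS + β_q·ln IQ +
  β_v·VABS, with IQ and ADOS at baseline by default; QALYs accrue per
  cycle, survival-weighted, half-cycle corrected, discounted at 3.5% p.a.
- **Costs** — intervention £36,682.78/yr for 24 months vs nursery-style TAU
  provision £8,634.33/yr; schooling unit costs weighted by the placement
  mix; and an annual social-care/medical cost regression on the scores.
  The NHS & social-services perspective counts intervention and
  social/medical costs; the public-sector perspective adds schooling.
- **ICER** = Δcost / ΔQALY, benchmarked against the NICE £20–30k/QALY range.

Scenario analyses replace the placement regression with observed school
mixes, or extend the horizon to age 80 with five adult independence levels
predicted from VABS at 18.5 by an ordered logit fitted to simulated
individual records. One-way sensitivity analysis produces a tornado
ranking; probabilistic analysis (10,000 Monte Carlo samples) produces
cost-effectiveness acceptability curves via net monetary benefit.

## Worked example

```sh
$ aba-cea basecase --perspective public --durability pessimistic --out reports
ABA £204,783 / 7.52 QALYs; TAU £158,740 / 7.30 QALYs; inc £46,043, 0.222 QALYs; ICER 207,665 (icer)
```

The intervention arm accrues 0.22 extra discounted QALYs but costs £46k
more over childhood (the schooling and care savings only partially offset
the programme cost), i.e. about £208k per QALY — far above the NICE
threshold. Under optimistic durability:

```sh
$ aba-cea basecase --perspective public --durability optimistic --out reports
ABA £193,646 / 8.09 QALYs; TAU £158,740 / 7.30 QALYs; inc £34,906, 0.786 QALYs; ICER 44,411 (icer)
```

Other entry points: `aba-cea scenario --scenario adult|placement`,
`aba-cea dsa`, `aba-cea psa --n-iter 10000 --seed 1`, `aba-cea synth`, and
`aba-cea variants` (the implementation-convention grid, see
`docs/methods.md`). Every command accepts `--config my_params.yaml`; the
full default file, with one block per published input table section, ships
at `src/aba_cea/data/default_config.yaml`.

The same analyses are available as library calls:

```python
from aba_cea import default_parameters, run_basecase
res = run_basecase(default_parameters(), "public_sector", "pessimistic")
print(res.inc_cost, res.inc_qaly, res.icer.value)
```

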