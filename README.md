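# cnsot — CNS oxygen-toxicity risk at rest

Patients in hyperbaric oxygen (HBO) therapy and divers at rest breathe
pure oxygen above atmospheric pressure, with an ever-present risk of
central nervous system oxygen toxicity (CNS-OT): nausea, twitching,
visual and hearing disturbance, convulsions, loss of consciousness.
`cnsot` implements a power-equation risk model for humans **at rest**
(1 MET), separately for thermoneutral immersion and dry chamber
exposures, for the people who plan such exposures: hyperbaric medicine
practitioners designing treatment tables, diving physiologists, and
anyone analysing censored hyperoxic-exposure data.

## The model

A continuous exposure of `t` minutes at oxygen partial pressure
`PO2` (bar) accrues the **CNS-OT index**

    K = t² · PO2^c

and the probability of toxicity is lognormal in K:

    Z = (½·ln K − μ) / σ,        risk = Φ(Z)

with Φ the standard normal CDF. Toxicity reaches 50% at the **critical
index** `Kc = exp(2μ)`. Fitted at-rest parameter sets (shipped in the
registry):

| set             | c     | μ     | σ    | Kc       |
|-----------------|-------|-------|------|----------|
| `immersed_rest` | 10.93 | 8.99  | 0.81 | 6.42×10⁷ |
| `dry_rest`      | 12.99 | 11.34 | 0.65 | 7.10×10⁹ |
| `active_4_4`    | 6.8   | 9.63  | 2.02 | e^18.02  |

Thermoneutral immersion carries a markedly higher risk than dry
exposure at the same dose. During **air breaks** the index decays
exponentially, `K ← K · exp(−0.079 · t_rec)`; when oxygen resumes,
accumulation restarts from the *equivalent time* `√(K / PO2^c)`. The
exponent can be interpolated for intermediate workloads,
`c = 12.14 − 1.21·MET` (dose arithmetic only — σ is unknown between
the fitted endpoints, so interpolated sets refuse risk computation).

The same model is exactly a lognormal accelerated-failure-time (AFT)
survival model — `ln T ~ Normal(μ − (c/2)·ln PO2, σ)` — which is how
the parameters are estimated: right-censored maximum likelihood
(`PowerEquationAFT`, a scikit-learn-style estimator), with Wald and
likelihood-ratio tests for immersed-vs-dry equality.

## Worked example

Risk of a single one-hour dry exposure at 2.5 bar:

```sh
$ cnsot risk 60 2.5 dry_rest
condition: dry_rest (c=12.99, mu=11.34, sigma=0.65)
K:    5.3155e+08 min^2*bar^c
Z:    -1.9913
risk: 0.02322 (2.322%)
```

The index is K = 60²·2.5^12.99 ≈ 5.3×10⁸, about two standard
deviations below the dry critical index, hence a 2.3% toxicity
probability. Splitting the same hour with a 10-minute air break
(bundled profile) cuts the risk in half:

```sh
$ cnsot profile src/cnsot/data/hbot_60min_2p5_break10.yaml
final_K=3.722443e+08 final_risk=0.011746 final_risk_pct=1.175
```

and the first three oxygen periods of US Navy Treatment Table 6
(3 × 20 min at 2.8 bar with 5-min air breaks) give

```sh
$ cnsot profile src/cnsot/data/usn_tt6_first3.yaml
final_K=1.601755e+09 final_risk=0.126562 final_risk_pct=12.66
```

i.e. a predicted 12.7% incidence by the end of the third period.

The same from Python:

```python
from cnsot import ExposureProfile, Segment, accumulate

profile = ExposureProfile(
    [Segment(2.8, 20, "oxygen"), Segment(0.59, 5, "air"),
     Segment(2.8, 20, "oxygen"), Segment(0.59, 5, "air"),
     Segment(2.8, 20, "oxygen")],
    condition="dry_rest",
)
print(accumulate(profile).final_risk)   # 0.1266
```

Fitting simulated censored records and testing condition equality:

```sh
cnsot simulate --params immersed_rest --po2 2.3 --po2 2.9 --po2 3.2 \
      --n 300 --censor 120 --seed 6 --out records.csv
cnsot fit records.csv --condition immersed
cnsot compare records.csv   # needs both immersed and dry rows
```

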