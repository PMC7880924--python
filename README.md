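# stentcea

Cost-effectiveness analysis of diagnostic imaging for stented patients
with suspected obstructive coronary artery disease or in-stent restenosis.
The package compares three strategies — coronary CT angiography (CTA),
stress myocardial CT perfusion (CTP), and both combined — for clinicians
and health-economics researchers who want a transparent, scriptable,
fully tested alternative to point-and-click decision software.

## The model

A decision tree converts prevalence and test accuracy into diagnostic
branches: with pre-test probability *p* and test (Se, Sp),

    TP = p·Se        → timely PTCA
    FN = p·(1−Se)    → delayed PTCA (1.3× cost)
    FP = (1−p)(1−Sp) → unnecessary invasive angiography
    TN = (1−p)·Sp    → no acute cost

The branches seed a three-state annual Markov cohort (alive without
symptomatic stenosis, alive with symptomatic stenosis, dead) that accrues
discounted costs and quality-adjusted life years (QALYs) over a 10-year
horizon at 3%/year. Strategies are compared by net monetary benefit
NMB = WTP·E − C at a willingness to pay of $100,000/QALY, with dominance
and ICERs reported in the standard way. One-way deterministic sensitivity
analysis (tornado), probabilistic sensitivity analysis (Monte Carlo over
beta/gamma input distributions, CEAC), and a patient-level
microsimulation oracle complete the pipeline. Modelling conventions the
problem leaves open (branch-to-state entry, competing-risk rule, reward
accrual, stenosis resolution) are explicit flags — see
[docs/methods.md](docs/methods.md).

## Worked example

All inputs are a JSON file whose keys mirror the `ParameterSet` fields;
an empty object `{}` runs the published base case:

```sh
echo '{}' > config.json
stentcea run --config config.json --out out
```

prints (and writes to `out/base_case.csv`):

```
strategy         cost    qalys           nmb comparator  delta_cost  delta_qalys icer_or_category        inmb
     CTA 49368.866249 5.466659 497297.045212                    NaN          NaN                          NaN
     CTP 48776.677536 5.476144 498837.673933        CTA -592.188713     0.009484         dominant 1540.628721
 CTA_CTP 49769.126369 5.467404 496971.291086        CTA  400.260119     0.000745        537218.69 -325.754126
```

Read: per patient over 10 years, CTP costs $592 less than CTA and yields
0.009 more QALYs — it *dominates* CTA (and the combined strategy, whose
low specificity buys many unnecessary angiographies at an ICER of
$537k/QALY over CTA). At $100,000/QALY the incremental net monetary
benefit of CTP over CTA is $1,541 per patient.

The same library surface is available in Python:

```python
from stentcea import ParameterSet, evaluate_strategies

results = evaluate_strategies(ParameterSet())
print(results["CTP"])  # StrategyResult(name='CTP', cost=48776.67..., qalys=5.4761...)
```

Other commands: `stentcea dsa` (tornado over the published ranges, or
`--ranges` for your own), `stentcea psa --iterations 30000 --seed 1`
(per-iteration samples + CEAC), and `stentcea oracle` (cohort vs
microsimulation equivalence check; nonzero exit beyond 3 SE). Every
command writes fixed-format CSVs (byte-identical across reruns) plus a
JSON manifest recording the configuration digest, seed and convention
flags.

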