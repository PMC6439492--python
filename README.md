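# kelpabc

Coalescent simulation and approximate Bayesian computation (ABC) for a
three-group phylogeographic system typed at microsatellites and one
mitochondrial locus.

## The problem

Two partially isolated lineages of the kelp *Saccharina japonica* — H
(along Japan) and P (west coast of the Japan Sea) — meet in Sakhalin,
where populations (group A) look intermediate. Clustering alone cannot
tell whether that pattern reflects **secondary contact** (admixture of the
two diverged lineages after the Last Glacial Maximum) or **shared
ancestral polymorphism** under a hierarchical split. Distinguishing these
requires fitting explicit demographic models to the genetic data.

`kelpabc` provides the full machinery for that comparison as a reusable
Python library:

* descriptive statistics for microsatellite and sequence data
  (heterozygosities, rarefied allelic richness, PIC, haplotype and
  nucleotide diversity, Weir–Cockerham and haplotype-frequency F_ST,
  (δμ)², assignment log-likelihoods, hierarchical AMOVA);
* seven preset demographic scenarios over demes H/P/A — four hierarchical
  split orders, isolation-with-admixture, and pre-/post-LGM constrained
  variants — with configurable priors;
* a backward-in-time coalescent simulator with generalized stepwise
  microsatellite mutation and K2P sequence mutation;
* rejection + regression ABC: reference tables, multinomial
  logistic-regression model choice with delta-method CIs, local-linear
  parameter estimation with Epanechnikov weights, posterior predictive
  error, and a PCA goodness-of-fit check;
* a synthetic-data module generating study-shaped datasets with known
  ground truth, and GenePop/FASTA/popmap readers and writers for real
  data.

The core model-choice quantity is the posterior probability of scenario
*m* given observed summary statistics **s**: simulations (m, θ, **s**) are
drawn from the prior, the 1% closest to the observed **s** (Euclidean
distance on SD-standardized statistics) are retained, and
P(m | **s**) is estimated both as the retained class proportion and by
multinomial logistic regression evaluated at the observed point.
Parameters are estimated by local-linear regression adjustment
(θ\* = θ − β′(s − s_obs), log/logit scales), summarized by weighted
median and 95% interval.

## Worked example

```python
import numpy as np
import kelpabc as ka
from kelpabc.abc_engine import (build_reference_table, compute_summary_stats,
                                model_choice_logistic, estimate_parameters)
from kelpabc.demography import ParameterDraw

rng = np.random.default_rng(3)
scenarios = [ka.get_scenario(n) for n in ("scenario1", "scenario4", "scenario5")]
cfg = ka.reduced_template().sample_config()
model = ka.MutationModel()

table = build_reference_table(scenarios, 400, cfg, model, rng)

truth = ParameterDraw("scenario5", {"N_H": 63_600, "N_P": 6_910, "N_A": 34_500,
                                    "N_anc": 3_310, "t2": 13_500, "t1": 3_590,
                                    "r": 0.5})
observed = compute_summary_stats(ka.simulate_dataset(scenarios[2], truth, cfg,
                                                     model, rng))
choice = model_choice_logistic(table, observed, tolerance=0.1)
print(choice.probabilities.round(3))
print("selected:", choice.selected)
```

Output from `python examples/03_abc_model_choice.py` (which runs exactly
this):

```
posterior scenario probabilities (direct rejection vs logistic):
           direct  logistic   lo   hi
scenario1  0.3917    0.2225  0.0  1.0
scenario4  0.2583    0.1823  0.0  1.0
scenario5  0.3500    0.5952  0.0  1.0
selected: scenario5   (truth: scenario5)
```

The pseudo-observed dataset was generated under the admixture scenario
with a 50/50 ancestry split; even at this small table size (400
simulations per scenario, so the probabilities are rough and the CIs
degenerate) the admixture scenario is correctly preferred. At the
calibrated scale the package's tests run — 5,000 simulations per
scenario, 1% tolerance — the admixture scenario is selected in 19/20
replicates with a mean posterior probability near 0.9.
`examples/04_parameter_estimation.py` continues with the
regression-adjusted posterior: each generating parameter should fall
inside its 95% interval, and the divergence-time median is also printed
in years BP (2 years/generation).

The other examples cover descriptive statistics on a simulated survey
(`01`), the scenario presets and the simulator's analytic checks (`02`).
A thin CLI (`kelpabc simulate|synth|stats|reftable|modelchoice|estimate|ppe`)
wires the same functions to files; see `kelpabc --help`.

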