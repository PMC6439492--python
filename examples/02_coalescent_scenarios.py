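"""The seven demographic scenarios and the coalescent simulator.

Lists the scenario presets, draws parameters from their priors, and
checks two analytic properties of the simulator: the expected pairwise
coalescence time (2N generations for autosomal copies, 0.5N for
mitochondrial) and the equilibrium gene diversity of the stepwise
mutation model, 1 - 1/sqrt(1 + 8*N*mu).
"""

import numpy as np

import kelpabc as ka
from kelpabc import demography as dm

rng = np.random.default_rng(2)

print("== scenario presets ==")
for s in ka.builtin_scenarios():
    print(f"{s.name}: {s.description}")
print()

s5 = ka.get_scenario("scenario5")
draw = s5.draw(rng)
print("one prior draw for scenario5:")
print({k: round(v, 1) for k, v in draw.values.items()})
print(f"t2 of {draw['t2']:.0f} generations = "
      f"{dm.generations_to_years(draw['t2']):.0f} years BP at 2 yr/generation")
print()

one_pop = dm.DemographicScenario(
    name="onepop", description="single deme", sampled_populations=("H",),
    size_params={"H": "N_H"}, events=(),
    prior=dm.PriorSpec({"N_H": ("uniform", 1.0, 1e9)}),
)
N = 1000.0
cfg = ka.SampleConfig({"H": 1}, 1)
t = [
    ka.simulate_genealogy(
        one_pop, dm.ParameterDraw("onepop", {"N_H": N}), cfg, "autosomal", rng
    ).tmrca
    for _ in range(4000)
]
print(f"mean pairwise TMRCA (autosomal, N={N:.0f}): {np.mean(t):.0f} "
      f"generations (theory: {2 * N:.0f})")

mu = 2.5e-4
model = ka.MutationModel(p_geom=0.0)  # strict stepwise model
cfg10 = ka.SampleConfig({"H": 10}, 1)
he = []
for _ in range(400):
    g = ka.simulate_genealogy(
        one_pop, dm.ParameterDraw("onepop", {"N_H": N}), cfg10, "autosomal", rng
    )
    alleles = ka.mutate_microsat(g, model, mu, rng)
    _, counts = np.unique(alleles, return_counts=True)
    p = counts / counts.sum()
    k = counts.sum()
    he.append(k / (k - 1.0) * (1.0 - p @ p))  # unbiased gene diversity
theory = 1.0 - 1.0 / np.sqrt(1.0 + 8.0 * N * mu)
print(f"mean SMM gene diversity over 400 loci: {np.mean(he):.4f} "
      f"(theory: {theory:.4f})")
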