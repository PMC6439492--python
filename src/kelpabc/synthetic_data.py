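"""Study-shaped synthetic datasets with known ground truth.

The sampled system is three genetic groups of kelp populations: H (8
populations, Japan), P (3 populations, Primorye) and A (5 putatively
admixed populations, Sakhalin) — 16 populations and 352 diploid
individuals in total, genotyped at 24 unlinked microsatellite loci and
sequenced at one non-recombining 1890-bp mitochondrial locus.  The
:func:`study_template` reproduces that design (22 individuals per
population; only the total is published, so near-equal sizes are
assumed); :func:`reduced_template` is a down-scaled configuration used
for calibration experiments where thousands of simulations are needed.

Populations within a group are sampled from the same deme — the
generator does not model within-group structure, genotyping error, null
alleles or missing data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .coalsim import MutationModel, SampleConfig, simulate_dataset
from .datasets import PopulationDataset
from .demography import DemographicScenario, ParameterDraw

__all__ = [
    "StudyTemplate",
    "study_template",
    "reduced_template",
    "generate_pseudo_observed",
    "read_truth",
]


@dataclass(frozen=True)
class StudyTemplate:
    """Sampling design: populations per group, individuals, loci, sites."""

    group_sizes: dict[str, int]  # group -> number of populations
    individuals_per_population: dict[str, int]  # population -> diploids
    n_msat_loci: int
    sequence_length: int

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("each group needs at least one population")
        if any(n < 1 for n in self.individuals_per_population.values()):
            raise ValueError("each population needs at least one individual")

    @property
    def n_populations(self) -> int:
        return len(self.individuals_per_population)

    @property
    def n_individuals(self) -> int:
        return sum(self.individuals_per_population.values())

    def population_group(self) -> dict[str, str]:
        out = {}
        for group, n_pops in self.group_sizes.items():
            for i in range(n_pops):
                out[f"{group}{i + 1:02d}"] = group
        return out

    def sample_config(self) -> SampleConfig:
        mapping = self.population_group()
        return SampleConfig(
            populations={
                pop: self.individuals_per_population[pop] for pop in mapping
            },
            n_msat_loci=self.n_msat_loci,
            sequence_length=self.sequence_length,
            population_deme=mapping,
        )


def _make_template(
    group_sizes: dict[str, int],
    per_population: int,
    n_msat_loci: int,
    sequence_length: int,
) -> StudyTemplate:
    pops = {}
    for group, n_pops in group_sizes.items():
        for i in range(n_pops):
            pops[f"{group}{i + 1:02d}"] = per_population
    return StudyTemplate(
        group_sizes=group_sizes,
        individuals_per_population=pops,
        n_msat_loci=n_msat_loci,
        sequence_length=sequence_length,
    )


def study_template() -> StudyTemplate:
    """The full study design: 16 populations (H:8, P:3, A:5), 352
    individuals (22 per population), 24 loci, 1890-bp sequence."""
    return _make_template(
        {"H": 8, "P": 3, "A": 5}, per_population=22, n_msat_loci=24,
        sequence_length=1890,
    )


def reduced_template(
    per_group: tuple[int, int, int] = (16, 6, 10),
    n_msat_loci: int = 24,
    sequence_length: int = 1890,
) -> StudyTemplate:
    """Down-scaled design for calibration experiments: one population per
    group with H/P/A sample sizes roughly proportional to the study's
    (176/66/110 individuals), keeping the full locus panel and sequence
    length — most of the scenario signal lives in the number of loci, so
    only the individual counts are reduced."""
    n_h, n_p, n_a = per_group
    return StudyTemplate(
        group_sizes={"H": 1, "P": 1, "A": 1},
        individuals_per_population={"H01": n_h, "P01": n_p, "A01": n_a},
        n_msat_loci=n_msat_loci,
        sequence_length=sequence_length,
    )


def generate_pseudo_observed(
    template: StudyTemplate,
    scenario: DemographicScenario,
    params: ParameterDraw,
    model: MutationModel,
    rng: np.random.Generator,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> tuple[PopulationDataset, dict]:
    """Simulate one dataset with known truth; optionally write a bundle.

    Returns the dataset and a truth record (scenario, parameters, seed,
    design).  With ``out_dir`` the dataset is written as GenePop + FASTA
    + popmap + ``truth.json`` under one directory.
    """
    cfg = template.sample_config()
    dataset = simulate_dataset(scenario, params, cfg, model, rng)
    truth = {
        "scenario": scenario.name,
        "parameters": dict(params.values),
        "seed": seed,
        "design": {
            "populations": dict(cfg.populations),
            "groups": template.population_group(),
            "n_msat_loci": template.n_msat_loci,
            "sequence_length": template.sequence_length,
        },
    }
    if out_dir is not None:
        from . import io as kio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kio.write_genepop(dataset.genotypes, dataset.partition, out / "genotypes.gen")
        if dataset.sequences is not None:
            kio.write_fasta(dataset.sequences, out / "sequences.fasta")
        kio.write_popmap(dataset.partition, out / "popmap.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
    return dataset, truth


def read_truth(path: str | Path) -> dict:
    """Load a truth sidecar written by :func:`generate_pseudo_observed`."""
    with open(Path(path)) as fh:
        return json.load(fh)
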