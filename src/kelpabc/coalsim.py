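"""Backward-in-time coalescent simulation with microsatellite and sequence
mutation.

The simulator draws a genealogy for each locus under a
:class:`~kelpabc.demography.DemographicScenario` (continuous-time
coalescent: exponential waiting times, instantaneous deme events), then
superimposes neutral mutations:

* microsatellites mutate under a generalized stepwise model (GSM): the
  per-branch mutation count is Poisson, each mutation steps the repeat
  count by ±s with s geometric on {1, 2, ...} (parameter ``p_geom``;
  ``p_geom = 0`` recovers the strict single-step SMM), and steps that
  would leave the allowed window of ``k_states`` contiguous states are
  redrawn;
* the sequence locus mutates under Kimura's two-parameter model with
  transition:transversion odds ``kappa``:1.

Gene-copy population sizes are ``2N`` for autosomal loci and ``0.5N`` for
the mitochondrial locus (haploid, maternally inherited, even sex ratio;
the coefficient is configurable), with N the diploid effective size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .datasets import MsatGenotypeMatrix, PopulationDataset, PopulationPartition, SequenceAlignment
from .demography import (
    Admixture,
    DemographicScenario,
    Merge,
    ParameterDraw,
    SizeChange,
    validate_scenario,
)

__all__ = [
    "SampleConfig",
    "MutationModel",
    "Genealogy",
    "simulate_genealogy",
    "mutate_microsat",
    "mutate_sequence",
    "simulate_dataset",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleConfig:
    """What is sampled: populations, their demes, loci and the sequence.

    ``populations`` maps population label -> number of diploid
    individuals.  ``population_deme`` maps population label -> scenario
    deme (H/P/A); by default each population label is its own deme.
    ``sequence_length`` 0 disables the mitochondrial locus.
    """

    populations: dict[str, int]
    n_msat_loci: int
    sequence_length: int = 0
    population_deme: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.populations or sum(self.populations.values()) < 1:
            raise ValueError("at least one sampled individual required")
        if any(n < 1 for n in self.populations.values()):
            raise ValueError("population sample sizes must be >= 1")
        if self.n_msat_loci < 0 or self.sequence_length < 0:
            raise ValueError("negative locus counts make no sense")
        if self.n_msat_loci == 0 and self.sequence_length == 0:
            raise ValueError("no loci configured")

    def deme_of(self, population: str) -> str:
        return self.population_deme.get(population, population)

    @property
    def n_individuals(self) -> int:
        return sum(self.populations.values())

    def individual_ids(self) -> list[str]:
        return [
            f"{pop}_{i + 1:03d}"
            for pop, n in self.populations.items()
            for i in range(n)
        ]

    def partition(self) -> PopulationPartition:
        ind_to_pop = {
            f"{pop}_{i + 1:03d}": pop
            for pop, n in self.populations.items()
            for i in range(n)
        }
        pop_to_group = {pop: self.deme_of(pop) for pop in self.populations}
        return PopulationPartition(ind_to_pop, pop_to_group)


@dataclass(frozen=True)
class MutationModel:
    """Mutation-process parameters.

    Microsatellites: per-locus rates are Gamma distributed with shape
    ``msat_rate_shape`` and mean ``msat_mu_mean`` (mutations/locus/
    generation); ``p_geom`` is the geometric step parameter of the GSM and
    ``k_states`` the width of the allowed allele window.  Sequence:
    ``seq_mu`` substitutions/site/generation and K2P ``kappa``.
    ``mito_scale`` converts diploid size to mitochondrial gene-copy size.
    """

    msat_mu_mean: float = 5e-4
    msat_rate_shape: float = 2.0
    p_geom: float = 0.22
    k_states: int = 40
    seq_mu: float = 2e-8
    kappa: float = 2.0
    mito_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.msat_mu_mean <= 0 or self.seq_mu < 0:
            raise ValueError("mutation rates must be positive")
        if not 0.0 <= self.p_geom < 1.0:
            raise ValueError("p_geom must be in [0, 1)")
        if self.k_states < 2:
            raise ValueError("k_states must be >= 2")
        if self.kappa <= 0 or self.mito_scale <= 0 or self.msat_rate_shape <= 0:
            raise ValueError("kappa, mito_scale and rate shape must be positive")

    def draw_locus_rates(self, n_loci: int, rng: np.random.Generator) -> np.ndarray:
        return rng.gamma(
            self.msat_rate_shape,
            self.msat_mu_mean / self.msat_rate_shape,
            size=n_loci,
        )


@dataclass
class Genealogy:
    """Rooted binary tree over sampled gene copies.

    Nodes 0..n_tips-1 are tips; internal nodes are numbered in coalescence
    order, so a parent's index always exceeds its children's.  ``parent``
    is -1 at the root; ``time`` is in generations before sampling;
    ``node_deme`` records the deme of each node (sampling deme for tips,
    deme of coalescence for internal nodes).
    """

    parent: np.ndarray
    time: np.ndarray
    n_tips: int
    node_deme: list[str]

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (root gets 0)."""
        lengths = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        lengths[has_parent] = (
            self.time[self.parent[has_parent]] - self.time[has_parent]
        )
        return lengths

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return kids


# ---------------------------------------------------------------------------
# genealogy simulation
# ---------------------------------------------------------------------------


def _gene_copy_sizes(
    scenario: DemographicScenario, draw: ParameterDraw, scale: float
) -> dict[str, float]:
    return {
        pop: scale * draw[param] for pop, param in scenario.size_params.items()
    }


def simulate_genealogy(
    scenario: DemographicScenario,
    draw: ParameterDraw,
    cfg: SampleConfig,
    locus_kind: str,
    rng: np.random.Generator,
) -> Genealogy:
    """Simulate one genealogy under ``scenario`` with parameters ``draw``.

    ``locus_kind`` is "autosomal" (2 gene copies per diploid, gene-copy
    deme size 2N) or "mito" (1 copy per individual, size ``mito_scale*N``,
    default 0.5N).  Coalescence within a deme of gene-copy size M occurs
    at rate C(k,2)/M per generation.
    """
    violations = validate_scenario(scenario, draw)
    if violations:
        raise ValueError(f"invalid scenario/draw: {violations}")
    if locus_kind == "autosomal":
        copies_per_ind, scale = 2, 2.0
    elif locus_kind == "mito":
        copies_per_ind, scale = 1, 0.5
    else:
        raise ValueError("locus_kind must be 'autosomal' or 'mito'")
    return _simulate_genealogy_scaled(scenario, draw, cfg, copies_per_ind, scale, rng)


def _simulate_genealogy_scaled(
    scenario: DemographicScenario,
    draw: ParameterDraw,
    cfg: SampleConfig,
    copies_per_ind: int,
    scale: float,
    rng: np.random.Generator,
) -> Genealogy:
    sizes = _gene_copy_sizes(scenario, draw, scale)
    n_tips = cfg.n_individuals * copies_per_ind

    parent = np.full(2 * n_tips - 1 if n_tips > 1 else 1, -1, dtype=np.int64)
    time = np.zeros(parent.shape[0])
    node_deme: list[str] = []

    active: dict[str, list[int]] = {}
    tip = 0
    for pop, n in cfg.populations.items():
        deme = cfg.deme_of(pop)
        if deme not in sizes:
            raise ValueError(f"sampled deme {deme!r} has no size parameter")
        ids = list(range(tip, tip + n * copies_per_ind))
        active.setdefault(deme, []).extend(ids)
        node_deme.extend([deme] * len(ids))
        tip += n * copies_per_ind

    # event schedule grouped by time
    schedule: list[tuple[float, list]] = []
    for ev in scenario.events:
        t = draw[ev.time_param]
        if schedule and schedule[-1][0] == t:
            schedule[-1][1].append(ev)
        else:
            schedule.append((t, [ev]))
    schedule.sort(key=lambda pair: pair[0])

    next_node = n_tips
    t_cur = 0.0

    def coalesce_deme(deme: str, t_stop: float) -> None:
        nonlocal next_node
        lineages = active.get(deme)
        if not lineages or len(lineages) < 2:
            return
        M = sizes[deme]
        if M <= 0:
            raise ValueError(f"deme {deme!r} has non-positive size on an active path")
        # Draw the whole ladder of waiting times at once.  By memorylessness,
        # restarting the clock at the epoch start is exact for lineages that
        # did not coalesce earlier.
        k = len(lineages)
        ks = np.arange(k, 1, -1, dtype=float)
        waits = rng.exponential(M / (ks * (ks - 1) / 2.0))
        times = t_cur + np.cumsum(waits)
        n_fit = int(np.searchsorted(times, t_stop))
        for e in range(n_fit):
            kk = len(lineages)
            i = int(rng.integers(kk))
            j = int(rng.integers(kk - 1))
            if j >= i:
                j += 1
            a, b = lineages[i], lineages[j]
            parent[a] = next_node
            parent[b] = next_node
            time[next_node] = times[e]
            node_deme.append(deme)
            # swap-remove both, append the new lineage
            for idx in sorted((i, j), reverse=True):
                lineages[idx] = lineages[-1]
                lineages.pop()
            lineages.append(next_node)
            next_node += 1

    for t_event, events in schedule:
        for deme in list(active):
            coalesce_deme(deme, t_event)
        for ev in events:
            if isinstance(ev, Merge):
                moved = active.pop(ev.source, [])
                active.setdefault(ev.target, []).extend(moved)
            elif isinstance(ev, Admixture):
                moved = active.pop(ev.derived, [])
                r = draw[ev.rate_param]
                to_first = rng.random(len(moved)) < r
                active.setdefault(ev.source1, []).extend(
                    lin for lin, f in zip(moved, to_first) if f
                )
                active.setdefault(ev.source2, []).extend(
                    lin for lin, f in zip(moved, to_first) if not f
                )
            elif isinstance(ev, SizeChange):
                sizes[ev.population] = scale * draw[ev.size_param]
        t_cur = t_event

    live = [d for d, lin in active.items() if lin]
    remaining = sum(len(active[d]) for d in live)
    if remaining > 1 and len(live) > 1:
        raise ValueError(
            f"lineages stranded in {live} with no path to a common ancestor"
        )
    for deme in live:
        coalesce_deme(deme, np.inf)
    return Genealogy(parent=parent, time=time, n_tips=n_tips, node_deme=node_deme)


# ---------------------------------------------------------------------------
# microsatellite mutation
# ---------------------------------------------------------------------------


@njit(cache=True)
def _gsm_walk(parent, counts, root_state, k_states, p_geom, seed):  # pragma: no cover
    np.random.seed(seed)
    n = parent.shape[0]
    allele = np.empty(n, np.int64)
    allele[n - 1] = root_state
    for i in range(n - 2, -1, -1):
        a = allele[parent[i]]
        for _ in range(counts[i]):
            while True:
                if p_geom > 0.0:
                    u = np.random.random()
                    if u <= 0.0:
                        continue
                    s = 1 + int(np.floor(np.log(u) / np.log(p_geom)))
                else:
                    s = 1
                if np.random.random() < 0.5:
                    s = -s
                b = a + s
                if 1 <= b <= k_states:
                    break
            a = b
        allele[i] = a
    return allele


def mutate_microsat(
    genealogy: Genealogy,
    model: MutationModel,
    locus_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Allele size (repeat count) for each sampled copy under the GSM.

    The root allele starts at the middle of the ``k_states`` window;
    per-branch mutation counts are Poisson(rate x branch length); each
    mutation steps ±s with geometric s, and steps leaving the window are
    redrawn.
    """
    if locus_rate < 0:
        raise ValueError("mutation rate must be non-negative")
    counts = rng.poisson(locus_rate * genealogy.branch_lengths()).astype(np.int64)
    root_state = (model.k_states + 1) // 2
    if genealogy.n_nodes == 1:
        return np.array([root_state], dtype=np.int64)
    seed = int(rng.integers(2**31 - 1))
    alleles = _gsm_walk(
        genealogy.parent, counts, root_state, model.k_states, model.p_geom, seed
    )
    return alleles[: genealogy.n_tips]


# ---------------------------------------------------------------------------
# sequence mutation (K2P)
# ---------------------------------------------------------------------------

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype="S1")


def mutate_sequence(
    genealogy: Genealogy,
    model: MutationModel,
    length: int,
    rng: np.random.Generator,
) -> list[str]:
    """K2P-mutated haplotype per sampled copy, as ACGT strings.

    The root sequence is uniform random over ACGT.  Substitution counts
    per branch are Poisson(seq_mu x L x length); the site is uniform; a
    substitution is a transition with odds ``kappa``:1, else one of the
    two transversions equiprobably.  In the base encoding A=0 C=1 G=2 T=3
    the transition partner is ``b ^ 2`` and the transversions ``b ^ 1`` /
    ``b ^ 3``.
    """
    if length < 1:
        raise ValueError("sequence length must be positive")
    root_seq = rng.integers(0, 4, size=length).astype(np.int8)
    counts = rng.poisson(
        model.seq_mu * length * genealogy.branch_lengths()
    ).astype(np.int64)
    total = int(counts.sum())
    sites = rng.integers(0, length, size=total)
    is_transition = rng.random(total) < model.kappa / (model.kappa + 1.0)
    tv_choice = rng.integers(0, 2, size=total)  # 0 -> b^1, 1 -> b^3
    offsets = np.concatenate([[0], np.cumsum(counts)])

    children = genealogy.children()
    seq = root_seq.copy()
    tip_seqs: dict[int, np.ndarray] = {}

    def apply(node: int) -> list[tuple[int, np.int8]]:
        undo = []
        for m in range(offsets[node], offsets[node + 1]):
            site = sites[m]
            old = seq[site]
            if is_transition[m]:
                new = old ^ 2
            else:
                new = old ^ (1 if tv_choice[m] == 0 else 3)
            undo.append((site, old))
            seq[site] = new
        return undo

    # iterative DFS with apply-on-enter / revert-on-exit
    root = genealogy.root
    stack: list[tuple[int, list[tuple[int, np.int8]], int]] = [(root, apply(root), 0)]
    while stack:
        node, undo, child_i = stack[-1]
        kids = children[node]
        if node < genealogy.n_tips:
            tip_seqs[node] = seq.copy()
        if child_i < len(kids):
            stack[-1] = (node, undo, child_i + 1)
            child = kids[child_i]
            stack.append((child, apply(child), 0))
        else:
            for site, old in reversed(undo):
                seq[site] = old
            stack.pop()

    out = []
    for tip in range(genealogy.n_tips):
        out.append(_CODE_TO_BASE[tip_seqs[tip]].tobytes().decode("ascii"))
    return out


# ---------------------------------------------------------------------------
# whole-dataset simulation
# ---------------------------------------------------------------------------


def simulate_dataset(
    scenario: DemographicScenario,
    draw: ParameterDraw,
    cfg: SampleConfig,
    model: MutationModel,
    rng: np.random.Generator,
) -> PopulationDataset:
    """Simulate one study-shaped dataset: unlinked microsatellite loci
    (independent genealogies) plus one non-recombining sequence locus
    shared by a single mitochondrial genealogy."""
    if cfg.n_msat_loci < 1:
        raise ValueError("dataset simulation needs at least one microsatellite locus")
    ids = cfg.individual_ids()
    n_ind = cfg.n_individuals
    locus_rates = model.draw_locus_rates(cfg.n_msat_loci, rng)

    geno = np.empty((n_ind, cfg.n_msat_loci, 2), dtype=np.int64)
    for locus in range(cfg.n_msat_loci):
        g = simulate_genealogy(scenario, draw, cfg, "autosomal", rng)
        alleles = mutate_microsat(g, model, float(locus_rates[locus]), rng)
        geno[:, locus, :] = alleles.reshape(n_ind, 2)
    matrix = MsatGenotypeMatrix(geno, ids)

    sequences = None
    if cfg.sequence_length > 0:
        g = _simulate_genealogy_scaled(
            scenario, draw, cfg, 1, model.mito_scale, rng
        )
        haplotypes = mutate_sequence(g, model, cfg.sequence_length, rng)
        sequences = SequenceAlignment(haplotypes, ids)

    return PopulationDataset(
        genotypes=matrix,
        partition=cfg.partition(),
        sequences=sequences,
        metadata={"scenario": scenario.name, "parameters": dict(draw.values)},
    )
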