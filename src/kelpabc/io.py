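"""File formats: GenePop genotypes, FASTA alignments, popmap TSV, run
configuration.

GenePop dialect: a title line, one locus name per line (or one
comma-separated line), ``Pop`` separators, then per individual
``label ,  aabbcc ...`` with 2- or 3-digit allele codes; ``00``/``000``
(doubled) denotes a missing genotype.  Allele codes are read as repeat
counts directly (a configurable motif length could map fragment lengths
to repeat counts; the default mapping is the identity).

Population labels are taken from an explicit popmap when given,
otherwise from the label of the last individual in each ``Pop`` block
(the GenePop convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datasets import (
    MISSING,
    MsatGenotypeMatrix,
    PopulationPartition,
    SequenceAlignment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GenePopError",
    "read_genepop",
    "write_genepop",
    "read_fasta",
    "write_fasta",
    "read_fasta_with_popmap",
    "read_popmap",
    "write_popmap",
    "RunConfig",
    "load_config",
    "save_config",
]


class GenePopError(ValueError):
    """Malformed GenePop input; the message names the offending line."""


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------


def _parse_genotype(token: str, line_no: int) -> tuple[int, int]:
    if len(token) not in (4, 6) or not token.isdigit():
        raise GenePopError(
            f"line {line_no}: unparseable genotype {token!r} "
            "(need 4 or 6 digits)"
        )
    half = len(token) // 2
    a, b = int(token[:half]), int(token[half:])
    if a == 0 and b == 0:
        return (MISSING, MISSING)
    if a == 0 or b == 0:
        raise GenePopError(
            f"line {line_no}: half-missing genotype {token!r} not supported"
        )
    return (a, b)


def read_genepop(
    path: str | Path,
) -> tuple[MsatGenotypeMatrix, PopulationPartition]:
    """Read a GenePop file; populations from the last label per block."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GenePopError("file too short to be GenePop")
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        locus_ids.extend(chunk)
        i += 1
    if not locus_ids:
        raise GenePopError("no locus names before the first 'Pop'")
    n_loci = len(locus_ids)

    blocks: list[list[tuple[str, list[tuple[int, int]]]]] = []
    current: list[tuple[str, list[tuple[int, int]]]] | None = None
    for line_no in range(i, len(lines)):
        stripped = lines[line_no].strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            current = []
            blocks.append(current)
            continue
        if current is None:
            raise GenePopError(f"line {line_no + 1}: genotype data before 'Pop'")
        if "," not in stripped:
            raise GenePopError(
                f"line {line_no + 1}: expected 'label , genotypes'"
            )
        label, _, rest = stripped.partition(",")
        tokens = rest.split()
        if len(tokens) != n_loci:
            raise GenePopError(
                f"line {line_no + 1}: {len(tokens)} genotypes for "
                f"{n_loci} loci"
            )
        genos = [_parse_genotype(t, line_no + 1) for t in tokens]
        current.append((label.strip(), genos))

    if not blocks or all(not b for b in blocks):
        raise GenePopError("no genotype rows found")

    ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    ind_to_pop: dict[str, str] = {}
    for block in blocks:
        if not block:
            continue
        pop_label = block[-1][0]
        for label, genos in block:
            uid = label
            k = 1
            while uid in ind_to_pop:
                k += 1
                uid = f"{label}.{k}"
            ids.append(uid)
            rows.append(genos)
            ind_to_pop[uid] = pop_label
    alleles = np.array(rows, dtype=np.int64)
    matrix = MsatGenotypeMatrix(alleles, ids, locus_ids)
    return matrix, PopulationPartition(ind_to_pop)


def write_genepop(
    geno: MsatGenotypeMatrix,
    part: PopulationPartition,
    path: str | Path,
    title: str = "kelpabc export",
    digits: int = 3,
) -> None:
    """Write genotypes grouped by population, 3-digit codes by default."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    limit = 10**digits - 1
    valid = geno.alleles[geno.alleles != MISSING]
    if valid.size and valid.max() > limit:
        raise ValueError(f"allele size exceeds {digits}-digit GenePop code")
    out = [title]
    out.extend(geno.locus_ids)
    ind_index = {s: i for i, s in enumerate(geno.individual_ids)}
    for pop in part.populations:
        out.append("Pop")
        for ind in part.members(pop):
            row = geno.alleles[ind_index[ind]]
            tokens = []
            for a, b in row:
                if a == MISSING:
                    tokens.append("0" * (2 * digits))
                else:
                    tokens.append(f"{a:0{digits}d}{b:0{digits}d}")
            out.append(f"{ind} ,  " + " ".join(tokens))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA + popmap
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> SequenceAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return SequenceAlignment([str(r.seq) for r in records], [r.id for r in records])


def write_fasta(aln: SequenceAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(aln.sequence(i)), id=aln.ids[i], description="")
        for i in range(len(aln))
    ]
    SeqIO.write(records, str(path), "fasta")


def read_popmap(path: str | Path) -> PopulationPartition:
    """TSV with columns individual_id, population[, group]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "individual_id" not in cols or "population" not in cols:
        raise ValueError("popmap needs columns: individual_id, population[, group]")
    ind_to_pop = dict(zip(df["individual_id"], df["population"]))
    if len(ind_to_pop) != len(df):
        raise ValueError("duplicate individual ids in popmap")
    pop_to_group = None
    if "group" in cols and df["group"].notna().all():
        pop_to_group = {}
        for pop, grp in zip(df["population"], df["group"]):
            if pop in pop_to_group and pop_to_group[pop] != grp:
                raise ValueError(f"population {pop!r} mapped to multiple groups")
            pop_to_group[pop] = grp
    return PopulationPartition(ind_to_pop, pop_to_group)


def write_popmap(part: PopulationPartition, path: str | Path) -> None:
    rows = []
    for ind, pop in part.individual_to_population.items():
        row = {"individual_id": ind, "population": pop}
        if part.population_to_group is not None:
            row["group"] = part.population_to_group[pop]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta_with_popmap(
    fasta: str | Path, popmap: str | Path
) -> tuple[SequenceAlignment, PopulationPartition]:
    """Load an alignment and its popmap, cross-checking the ids."""
    aln = read_fasta(fasta)
    part = read_popmap(popmap)
    seq_ids = set(aln.ids)
    map_ids = set(part.individual_to_population)
    only_map = sorted(map_ids - seq_ids)
    only_fasta = sorted(seq_ids - map_ids)
    if only_map or only_fasta:
        raise ValueError(
            "id mismatch between FASTA and popmap; "
            f"popmap-only: {only_map[:5]}, fasta-only: {only_fasta[:5]}"
        )
    return aln, part


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline settings (simulation design, ABC knobs, seed)."""

    scenarios: list[str] = dc_field(
        default_factory=lambda: ["scenario1", "scenario2", "scenario3",
                                 "scenario4", "scenario5"]
    )
    n_per_scenario: int = 1000
    tolerance: float = 0.01
    n_pods: int = 100
    seed: int = 1
    genepop: str | None = None
    fasta: str | None = None
    popmap: str | None = None
    out_dir: str = "kelpabc_out"
    # sampling design (used when simulating)
    populations: dict[str, int] = dc_field(
        default_factory=lambda: {"H01": 16, "P01": 6, "A01": 10}
    )
    population_deme: dict[str, str] = dc_field(
        default_factory=lambda: {"H01": "H", "P01": "P", "A01": "A"}
    )
    n_msat_loci: int = 12
    sequence_length: int = 600
    # mutation model
    msat_mu_mean: float = 5e-4
    msat_rate_shape: float = 2.0
    p_geom: float = 0.22
    k_states: int = 40
    seq_mu: float = 2e-8
    kappa: float = 2.0
    mito_scale: float = 0.5
    generation_time_years: float = 2.0


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = {k: getattr(cfg, k) for k in RunConfig.__dataclass_fields__}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
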