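"""Molecular diversity and differentiation statistics.

Sequence side: segregating sites, haplotype counts, haplotype diversity
(Hd), nucleotide diversity (Pi), haplotype-frequency F_ST, AMOVA.
Microsatellite side: allele counts, observed/expected heterozygosity,
rarefied allelic richness, polymorphism information content, allele-size
variance, Weir–Cockerham theta, (delta-mu)^2, individual assignment
log-likelihood ("classification index"), AMOVA.

These functions serve both the observed-data path and the ABC
summary-statistic path, so definitions are deliberately estimator-explicit:

* Hd uses the n/(n-1) small-sample correction.
* H_E defaults to plain 1 - sum(p^2); ``unbiased=True`` applies the
  2n/(2n-1) correction.
* Microsatellite F_ST is Weir & Cockerham's theta with variance components
  summed over alleles and loci before the ratio is formed.
* Sequence F_ST is the haplotype-frequency (distance-free) estimator with
  the Nei & Chesser sample-size correction.
* Missing genotypes are dropped locus-wise/pairwise; nothing is imputed.
* Negative F_ST estimates are reported as computed; pass
  ``clamp_negative=True`` to truncate at zero (used in the ABC path).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datasets import (
    MISSING,
    MsatGenotypeMatrix,
    PopulationPartition,
    SequenceAlignment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SeqDiversitySummary",
    "AmovaResult",
    "seq_diversity",
    "haplotype_counts",
    "top_haplotype_percentage",
    "mean_pairwise_differences",
    "mean_between_differences",
    "msat_diversity",
    "msat_basic_summaries",
    "sequence_group_summaries",
    "pairwise_fst_msat",
    "pairwise_fst_sequences",
    "pairwise_delta_mu_sq",
    "classification_index",
    "amova_sequences",
    "amova_msat",
    "amova_from_squared_distances",
]


# ---------------------------------------------------------------------------
# sequence statistics
# ---------------------------------------------------------------------------

_BASES = (b"A", b"C", b"G", b"T")


@dataclass(frozen=True)
class SeqDiversitySummary:
    """Sequence diversity summary: S, h, Hd, Pi for one sample."""

    n: int
    S: int
    h: int
    Hd: float
    Pi: float


def _base_counts(matrix: np.ndarray) -> np.ndarray:
    """(4, L) counts of A/C/G/T per column; gaps and Ns are not counted."""
    return np.stack([(matrix == b).sum(axis=0) for b in _BASES])


def _row_strings(matrix: np.ndarray) -> np.ndarray:
    """View an (n, L) byte matrix as n fixed-width byte strings."""
    m = np.ascontiguousarray(matrix)
    return m.view(np.dtype((np.bytes_, m.shape[1]))).ravel()


def haplotype_counts(aln: SequenceAlignment) -> np.ndarray:
    """Multiplicity of each distinct haplotype, descending."""
    _, counts = np.unique(_row_strings(aln.matrix), return_counts=True)
    return np.sort(counts)[::-1]


def top_haplotype_percentage(counts) -> float:
    """Share (percent) of the most frequent haplotype in a sample.

    ``counts`` is any sequence of haplotype multiplicities, e.g. the output
    of :func:`haplotype_counts` or a published haplotype frequency table.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0 or (counts < 0).any():
        raise ValueError("counts must be a non-empty vector of multiplicities")
    total = counts.sum()
    if total == 0:
        raise ValueError("empty sample")
    return float(100.0 * counts.max() / total)


def _segregating_sites(matrix: np.ndarray) -> int:
    counts = _base_counts(matrix)
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def _site_pair_mismatch(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site mean mismatch over unordered pairs, with pairwise deletion.

    Returns (mismatch per site, number of valid gene copies per site);
    sites with fewer than 2 valid bases get mismatch 0 and are flagged by
    the returned copy count.
    """
    n_valid = counts.sum(axis=0)
    pairs = n_valid * (n_valid - 1) / 2.0
    same = (counts * (counts - 1) / 2.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mism = np.where(pairs > 0, 1.0 - same / np.where(pairs > 0, pairs, 1.0), 0.0)
    return mism, n_valid


def seq_diversity(aln: SequenceAlignment) -> SeqDiversitySummary:
    """S, h, Hd and Pi for one alignment.

    Hd is the probability that two sequences drawn without replacement are
    different haplotypes, ``n/(n-1) * (1 - sum p_i^2)``.  Pi is the mean
    pairwise mismatch per compared site (sites with a gap/N excluded
    pairwise).  With a single sequence Hd and Pi are undefined (NaN).
    """
    n = len(aln)
    counts = haplotype_counts(aln)
    h = counts.size
    S = _segregating_sites(aln.matrix)
    if n < 2:
        return SeqDiversitySummary(n=n, S=S, h=h, Hd=float("nan"), Pi=float("nan"))
    p = counts / n
    Hd = n / (n - 1.0) * (1.0 - float(p @ p))
    mism, n_valid = _site_pair_mismatch(_base_counts(aln.matrix))
    compared = int((n_valid >= 2).sum())
    Pi = float(mism.sum() / compared) if compared else float("nan")
    return SeqDiversitySummary(n=n, S=S, h=h, Hd=float(Hd), Pi=Pi)


def mean_pairwise_differences(aln: SequenceAlignment) -> float:
    """Mean number of differing sites over unordered sequence pairs."""
    if len(aln) < 2:
        return float("nan")
    mism, _ = _site_pair_mismatch(_base_counts(aln.matrix))
    return float(mism.sum())


def mean_between_differences(
    aln1: SequenceAlignment, aln2: SequenceAlignment
) -> float:
    """Mean number of differing sites over cross pairs of two samples."""
    if aln1.n_sites != aln2.n_sites:
        raise ValueError("alignments have different lengths")
    c1 = _base_counts(aln1.matrix)
    c2 = _base_counts(aln2.matrix)
    n1 = c1.sum(axis=0)
    n2 = c2.sum(axis=0)
    cross = n1 * n2
    same = (c1 * c2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mism = np.where(cross > 0, 1.0 - same / np.where(cross > 0, cross, 1.0), 0.0)
    return float(mism.sum())


# ---------------------------------------------------------------------------
# microsatellite helpers
# ---------------------------------------------------------------------------


def _pop_indices(
    geno: MsatGenotypeMatrix, part: PopulationPartition, level: str = "population"
) -> dict[str, np.ndarray]:
    """Map population (or group) label -> integer row indices into geno."""
    if level == "group":
        part = part.as_group_partition()
    elif level != "population":
        raise ValueError("level must be 'population' or 'group'")
    out: dict[str, np.ndarray] = {}
    for pop in part.populations:
        members = [m for m in part.members(pop) if m in set(geno.individual_ids)]
        if not members:
            raise ValueError(f"population {pop!r} has no genotyped individuals")
        out[pop] = geno.index_of(members)
    return out


def _locus_alleles(geno: MsatGenotypeMatrix, idx: np.ndarray, locus: int) -> np.ndarray:
    """Flat vector of non-missing allele copies for one locus in one sample."""
    a = geno.alleles[idx, locus, :].ravel()
    return a[a != MISSING]


def _locus_genotypes(
    geno: MsatGenotypeMatrix, idx: np.ndarray, locus: int
) -> np.ndarray:
    """(m, 2) non-missing genotypes for one locus in one sample."""
    g = geno.alleles[idx, locus, :]
    return g[g[:, 0] != MISSING]


def _rarefied_richness(allele_counts: np.ndarray, g2: int) -> float:
    """Expected allele count in a subsample of ``g2`` gene copies.

    Hypergeometric rarefaction: sum over alleles of
    ``1 - C(N - N_i, g2) / C(N, g2)`` with N the sampled gene copies.
    """
    N = int(allele_counts.sum())
    if N < g2:
        raise ValueError("rarefaction size exceeds sample")

    def log_comb(n: int, k: int) -> float:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    denom = log_comb(N, g2)
    total = 0.0
    for ni in allele_counts:
        rem = N - int(ni)
        miss = 0.0 if rem < g2 else math.exp(log_comb(rem, g2) - denom)
        total += 1.0 - miss
    return total


# ---------------------------------------------------------------------------
# per-population microsatellite diversity
# ---------------------------------------------------------------------------


def msat_diversity(
    geno: MsatGenotypeMatrix,
    part: PopulationPartition,
    g: int = 6,
    unbiased: bool = False,
    level: str = "population",
) -> pd.DataFrame:
    """Per-population microsatellite diversity table.

    Columns: ``n`` (individuals), ``N_A`` (mean alleles/locus), ``N_P``
    (mean private alleles/locus), ``H_O``, ``H_E``, ``A_R`` (allelic
    richness rarefied to ``g`` diploids, i.e. ``2g`` gene copies), ``PIC``
    and ``V`` (mean allele-size variance).  Loci with fewer than ``2g``
    gene copies in a population are skipped for that population's A_R;
    all-missing loci are excluded from every mean.
    """
    if g < 1:
        raise ValueError("rarefaction size g must be >= 1")
    pops = _pop_indices(geno, part, level)
    # which alleles are private: present in exactly one population
    presence: dict[tuple[int, int], set[str]] = {}
    for pop, idx in pops.items():
        for locus in range(geno.n_loci):
            for allele in np.unique(_locus_alleles(geno, idx, locus)):
                presence.setdefault((locus, int(allele)), set()).add(pop)

    rows = {}
    for pop, idx in pops.items():
        na, npriv, ho, he, pic, var, ar = [], [], [], [], [], [], []
        for locus in range(geno.n_loci):
            copies = _locus_alleles(geno, idx, locus)
            if copies.size == 0:
                logger.debug("population %s: locus %d all missing, excluded", pop, locus)
                continue
            alleles, counts = np.unique(copies, return_counts=True)
            p = counts / counts.sum()
            na.append(alleles.size)
            npriv.append(
                sum(
                    1
                    for a in alleles
                    if presence[(locus, int(a))] == {pop}
                )
            )
            gt = _locus_genotypes(geno, idx, locus)
            if gt.shape[0] > 0:
                ho.append(float((gt[:, 0] != gt[:, 1]).mean()))
            sum_p2 = float(p @ p)
            he_locus = 1.0 - sum_p2
            if unbiased and copies.size > 1:
                he_locus *= copies.size / (copies.size - 1.0)
            he.append(he_locus)
            sum_p4 = float((p**2) @ (p**2))
            pic.append(1.0 - sum_p2 - (sum_p2**2 - sum_p4))
            if copies.size >= 2:
                var.append(float(np.var(copies, ddof=1)))
            if copies.size >= 2 * g:
                ar.append(_rarefied_richness(counts, 2 * g))
            else:
                logger.warning(
                    "population %s locus %s: %d gene copies < 2g=%d, "
                    "skipped for allelic richness",
                    pop,
                    geno.locus_ids[locus],
                    copies.size,
                    2 * g,
                )
        if not na:
            raise ValueError(f"population {pop!r} has no genotyped loci")
        rows[pop] = {
            "n": int(idx.size),
            "N_A": float(np.mean(na)),
            "N_P": float(np.mean(npriv)),
            "H_O": float(np.mean(ho)) if ho else float("nan"),
            "H_E": float(np.mean(he)),
            "A_R": float(np.mean(ar)) if ar else float("nan"),
            "PIC": float(np.mean(pic)),
            "V": float(np.mean(var)) if var else float("nan"),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def msat_basic_summaries(
    geno: MsatGenotypeMatrix,
    part: PopulationPartition,
    level: str = "population",
) -> pd.DataFrame:
    """Lean per-sample microsatellite summaries: N_A, H_E, V.

    The three single-sample statistics of the ABC summary vector (mean
    alleles per locus, mean gene diversity, mean allele-size variance),
    without the rarefaction/private-allele bookkeeping of
    :func:`msat_diversity`.  Loci with no data in a sample are skipped.
    """
    pops = _pop_indices(geno, part, level)
    rows = {}
    for pop, idx in pops.items():
        na, he, var = [], [], []
        for locus in range(geno.n_loci):
            copies = _locus_alleles(geno, idx, locus)
            if copies.size == 0:
                continue
            _, counts = np.unique(copies, return_counts=True)
            p = counts / counts.sum()
            na.append(counts.size)
            he.append(1.0 - float(p @ p))
            var.append(float(np.var(copies, ddof=1)) if copies.size >= 2 else 0.0)
        if not na:
            raise ValueError(f"population {pop!r} has no genotyped loci")
        rows[pop] = {
            "N_A": float(np.mean(na)),
            "H_E": float(np.mean(he)),
            "V": float(np.mean(var)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def sequence_group_summaries(
    aln: SequenceAlignment,
    part: PopulationPartition,
    level: str = "population",
) -> pd.DataFrame:
    """Per-sample sequence summaries for the ABC vector: h, S, MPD.

    ``h`` distinct haplotypes, ``S`` segregating sites and the mean
    pairwise difference count within the sample.
    """
    if level == "group":
        part = part.as_group_partition()
    seq_ids = set(aln.ids)
    rows = {}
    for pop in part.populations:
        members = [m for m in part.members(pop) if m in seq_ids]
        if len(members) < 2:
            raise ValueError(f"population {pop!r} has <2 sequences")
        sub = aln.matrix[aln.index_of(members)]
        counts = np.unique(_row_strings(sub), return_counts=True)[1]
        mism, _ = _site_pair_mismatch(_base_counts(sub))
        rows[pop] = {
            "h": int(counts.size),
            "S": _segregating_sites(sub),
            "MPD": float(mism.sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# single-pass group bundles (fast path for the ABC summary vector)
# ---------------------------------------------------------------------------


def msat_group_bundle(
    geno: MsatGenotypeMatrix,
    part: PopulationPartition,
    level: str = "population",
) -> dict[str, pd.DataFrame]:
    """All group-level microsatellite summaries from one coding pass.

    Returns ``basics`` (N_A, H_E, V per sample), ``fst`` (pairwise
    Weir–Cockerham theta), ``dmu2`` and ``lik`` (classification index
    averaged over both directions).  Numerically identical to the
    dedicated functions (:func:`msat_basic_summaries`,
    :func:`pairwise_fst_msat`, :func:`pairwise_delta_mu_sq`,
    :func:`classification_index`) — asserted by the test suite — but
    shares the per-locus allele coding across statistics, which matters
    when summarizing thousands of simulated datasets.
    """
    pops = _pop_indices(geno, part, level)
    labels = list(pops)
    pairs = list(itertools.combinations(labels, 2))
    K = len(labels)

    na = {g: [] for g in labels}
    he = {g: [] for g in labels}
    vv = {g: [] for g in labels}
    a_tot = {p: 0.0 for p in pairs}
    abc_tot = {p: 0.0 for p in pairs}
    any_locus = {p: False for p in pairs}
    dmu_acc = {p: [] for p in pairs}
    lik_sum = {(g1, g2): 0.0 for g1 in labels for g2 in labels if g1 != g2}

    alleles_all = geno.alleles
    for locus in range(geno.n_loci):
        col = alleles_all[:, locus, :]
        valid_rows = col[:, 0] != MISSING
        observed = col[valid_rows]
        if observed.size == 0:
            continue
        vals = np.unique(observed)
        m = vals.size
        grp: dict[str, dict] = {}
        for g, idx in pops.items():
            rows = idx[valid_rows[idx]]
            if rows.size == 0:
                grp[g] = None
                continue
            codes = np.searchsorted(vals, col[rows])
            counts = np.bincount(codes.ravel(), minlength=m)
            het = codes[:, 0] != codes[:, 1]
            hetc = np.bincount(codes[het].ravel(), minlength=m)
            n_genes = 2 * rows.size
            p = counts / n_genes
            mean_size = float(counts @ vals) / n_genes
            grp[g] = {
                "rows": rows,
                "codes": codes,
                "het": het,
                "counts": counts,
                "hetc": hetc,
                "n": rows.size,
                "p": p,
                "mean": mean_size,
            }
            na[g].append(int((counts > 0).sum()))
            he[g].append(1.0 - float(p @ p))
            if n_genes >= 2:
                vv[g].append(
                    float(counts @ (vals - mean_size) ** 2) / (n_genes - 1)
                )
        # pairwise statistics
        for g1, g2 in pairs:
            d1, d2 = grp[g1], grp[g2]
            if d1 is None or d2 is None:
                continue
            n1, n2 = d1["n"], d2["n"]
            dmu_acc[(g1, g2)].append((d1["mean"] - d2["mean"]) ** 2)
            if n1 + n2 >= 3:
                any_locus[(g1, g2)] = True
                r = 2
                n_bar = (n1 + n2) / r
                n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
                p1, p2 = d1["p"], d2["p"]
                h1 = d1["hetc"] / n1
                h2 = d2["hetc"] / n2
                p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
                s2 = (
                    n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2
                ) / ((r - 1) * n_bar)
                h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
                a = (
                    n_bar
                    / n_c
                    * (
                        s2
                        - 1.0
                        / (n_bar - 1)
                        * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
                    )
                )
                b = (
                    n_bar
                    / (n_bar - 1)
                    * (
                        p_bar * (1 - p_bar)
                        - (r - 1) / r * s2
                        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
                    )
                )
                c = h_bar / 2.0
                a_tot[(g1, g2)] += float(a.sum())
                abc_tot[(g1, g2)] += float((a + b + c).sum())
        # directed assignment log-likelihoods
        for g_from, g_to in itertools.permutations(labels, 2):
            d_from, d_to = grp[g_from], grp[g_to]
            if d_from is None or d_to is None:
                continue
            counts_to = d_to["counts"]
            n_eff = 2 * d_to["n"]
            codes = d_from["codes"]
            ca = counts_to[codes[:, 0]].astype(float)
            cb = counts_to[codes[:, 1]].astype(float)
            pseudo = 1.0 / (n_eff + 1)
            fa = np.where(ca > 0, ca / n_eff, pseudo)
            fb = np.where(cb > 0, cb / n_eff, pseudo)
            het = d_from["het"]
            prob = np.where(het, 2.0 * fa * fb, fa * fa)
            lik_sum[(g_from, g_to)] += float(np.log10(prob).sum())

    basics = pd.DataFrame.from_dict(
        {
            g: {
                "N_A": float(np.mean(na[g])) if na[g] else np.nan,
                "H_E": float(np.mean(he[g])) if he[g] else np.nan,
                "V": float(np.mean(vv[g])) if vv[g] else 0.0,
            }
            for g in labels
        },
        orient="index",
    )
    fst = pd.DataFrame(0.0, index=labels, columns=labels)
    dmu = pd.DataFrame(0.0, index=labels, columns=labels)
    lik = pd.DataFrame(0.0, index=labels, columns=labels)
    n_by_group = {g: pops[g].size for g in labels}
    for g1, g2 in pairs:
        theta = (
            a_tot[(g1, g2)] / abc_tot[(g1, g2)]
            if any_locus[(g1, g2)] and abc_tot[(g1, g2)] != 0.0
            else float("nan")
        )
        fst.loc[g1, g2] = fst.loc[g2, g1] = theta
        dmu_vals = dmu_acc[(g1, g2)]
        dmu.loc[g1, g2] = dmu.loc[g2, g1] = (
            float(np.mean(dmu_vals)) if dmu_vals else float("nan")
        )
        both = 0.5 * (
            lik_sum[(g1, g2)] / n_by_group[g1]
            + lik_sum[(g2, g1)] / n_by_group[g2]
        )
        lik.loc[g1, g2] = lik.loc[g2, g1] = both
    return {"basics": basics, "fst": fst, "dmu2": dmu, "lik": lik}


def sequence_group_bundle(
    aln: SequenceAlignment,
    part: PopulationPartition,
    level: str = "population",
) -> dict[str, pd.DataFrame]:
    """All group-level sequence summaries from one pass.

    Returns ``summaries`` (h, S, MPD per sample), ``fst`` (pairwise
    haplotype-frequency F_ST) and ``mpd_between``.  Numerically identical
    to :func:`sequence_group_summaries`, :func:`pairwise_fst_sequences`
    and :func:`mean_between_differences` (asserted by the test suite).
    """
    if level == "group":
        part = part.as_group_partition()
    seq_ids = set(aln.ids)
    members = {}
    for pop in part.populations:
        mem = [m for m in part.members(pop) if m in seq_ids]
        if len(mem) < 2:
            raise ValueError(f"population {pop!r} has <2 sequences")
        members[pop] = aln.index_of(mem)
    labels = list(members)
    _, inverse = np.unique(_row_strings(aln.matrix), return_inverse=True)
    n_hap = int(inverse.max()) + 1

    base_counts = {g: _base_counts(aln.matrix[idx]) for g, idx in members.items()}
    hap_counts = {
        g: np.bincount(inverse[idx], minlength=n_hap) for g, idx in members.items()
    }
    rows = {}
    for g in labels:
        counts = base_counts[g]
        mism, _ = _site_pair_mismatch(counts)
        rows[g] = {
            "h": int((hap_counts[g] > 0).sum()),
            "S": int(((counts > 0).sum(axis=0) >= 2).sum()),
            "MPD": float(mism.sum()),
        }
    summaries = pd.DataFrame.from_dict(rows, orient="index")

    fst = pd.DataFrame(0.0, index=labels, columns=labels)
    mpd = pd.DataFrame(0.0, index=labels, columns=labels)
    for g1, g2 in itertools.combinations(labels, 2):
        fst.loc[g1, g2] = fst.loc[g2, g1] = _fst_haplotype_pair(
            hap_counts[g1], hap_counts[g2]
        )
        c1, c2 = base_counts[g1], base_counts[g2]
        n1 = c1.sum(axis=0)
        n2 = c2.sum(axis=0)
        cross = n1 * n2
        same = (c1 * c2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            between = np.where(
                cross > 0, 1.0 - same / np.where(cross > 0, cross, 1.0), 0.0
            )
        mpd.loc[g1, g2] = mpd.loc[g2, g1] = float(between.sum())
    return {"summaries": summaries, "fst": fst, "mpd_between": mpd}


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def _wc_components_locus(
    geno: MsatGenotypeMatrix, idx1: np.ndarray, idx2: np.ndarray, locus: int
) -> tuple[float, float] | None:
    """(sum_a a, sum_a a+b+c) over alleles for one locus, two populations.

    Vectorized over alleles; a heterozygous individual contributes once to
    the heterozygote frequency of each of its two alleles.
    """
    g1 = _locus_genotypes(geno, idx1, locus)
    g2 = _locus_genotypes(geno, idx2, locus)
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 1 or n2 < 1 or n1 + n2 < 3:
        return None
    alleles = np.unique(np.concatenate([g1.ravel(), g2.ravel()]))
    m = alleles.size
    code1 = np.searchsorted(alleles, g1)
    code2 = np.searchsorted(alleles, g2)
    c1 = np.bincount(code1.ravel(), minlength=m)
    c2 = np.bincount(code2.ravel(), minlength=m)
    het1 = code1[:, 0] != code1[:, 1]
    het2 = code2[:, 0] != code2[:, 1]
    hc1 = np.bincount(code1[het1].ravel(), minlength=m)
    hc2 = np.bincount(code2[het2].ravel(), minlength=m)
    p1 = c1 / (2.0 * n1)
    p2 = c2 / (2.0 * n2)
    h1 = hc1 / n1
    h2 = hc2 / n2
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (
        n_bar
        / n_c
        * (
            s2
            - 1.0
            / (n_bar - 1)
            * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
        )
    )
    b = (
        n_bar
        / (n_bar - 1)
        * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
    )
    c = h_bar / 2.0
    return float(a.sum()), float((a + b + c).sum())


def _theta_pair(
    geno: MsatGenotypeMatrix, idx1: np.ndarray, idx2: np.ndarray
) -> float:
    a_tot = 0.0
    abc_tot = 0.0
    any_locus = False
    for locus in range(geno.n_loci):
        comp = _wc_components_locus(geno, idx1, idx2, locus)
        if comp is None:
            continue
        any_locus = True
        a_tot += comp[0]
        abc_tot += comp[1]
    if not any_locus:
        raise ValueError("no locus with genotypes in both populations")
    if abc_tot == 0.0:
        return float("nan")  # monomorphic pair: theta undefined
    return a_tot / abc_tot


def pairwise_fst_msat(
    geno: MsatGenotypeMatrix,
    part: PopulationPartition,
    level: str = "population",
    clamp_negative: bool = False,
) -> pd.DataFrame:
    """Pairwise multi-allelic Weir–Cockerham theta matrix.

    Variance components are summed over alleles and loci before the ratio
    is formed.  NaN marks pairs monomorphic at every usable locus.
    """
    pops = _pop_indices(geno, part, level)
    for pop, idx in pops.items():
        if (~geno.missing_mask()[idx]).any(axis=1).sum() < 2:
            raise ValueError(f"population {pop!r} has <2 genotyped individuals")
    labels = list(pops)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for p1, p2 in itertools.combinations(labels, 2):
        theta = _theta_pair(geno, pops[p1], pops[p2])
        if clamp_negative and not math.isnan(theta):
            theta = max(theta, 0.0)
        mat.loc[p1, p2] = mat.loc[p2, p1] = theta
    return mat


# ---------------------------------------------------------------------------
# haplotype-frequency F_ST for sequences
# ---------------------------------------------------------------------------


def _fst_haplotype_pair(counts1: np.ndarray, counts2: np.ndarray) -> float:
    """Nei–Chesser corrected (H_T - H_S)/H_T on haplotype frequencies.

    ``counts1`` and ``counts2`` are aligned haplotype-count vectors.
    Returns 0.0 for a pair with no haplotype variation.
    """
    n1, n2 = counts1.sum(), counts2.sum()
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 sequences per sample")
    p1 = counts1 / n1
    p2 = counts2 / n2
    n_harm = 2.0 / (1.0 / n1 + 1.0 / n2)
    hs_raw = 1.0 - 0.5 * (float(p1 @ p1) + float(p2 @ p2))
    hs = n_harm / (n_harm - 1.0) * hs_raw
    p_bar = 0.5 * (p1 + p2)
    ht = 1.0 - float(p_bar @ p_bar) + hs / (2.0 * n_harm)
    if ht <= 0.0:
        return 0.0
    return (ht - hs) / ht


def pairwise_fst_sequences(
    aln: SequenceAlignment,
    part: PopulationPartition,
    level: str = "population",
    clamp_negative: bool = False,
) -> pd.DataFrame:
    """Pairwise haplotype-frequency F_ST (distance-free) matrix."""
    if level == "group":
        part = part.as_group_partition()
    seq_ids = set(aln.ids)
    pops = {}
    for pop in part.populations:
        members = [m for m in part.members(pop) if m in seq_ids]
        if len(members) < 2:
            raise ValueError(f"population {pop!r} has <2 sequences")
        pops[pop] = aln.index_of(members)
    _, inverse = np.unique(_row_strings(aln.matrix), return_inverse=True)
    n_hap = inverse.max() + 1
    labels = list(pops)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for p1, p2 in itertools.combinations(labels, 2):
        c1 = np.bincount(inverse[pops[p1]], minlength=n_hap)
        c2 = np.bincount(inverse[pops[p2]], minlength=n_hap)
        fst = _fst_haplotype_pair(c1, c2)
        if clamp_negative:
            fst = max(fst, 0.0)
        mat.loc[p1, p2] = mat.loc[p2, p1] = fst
    return mat


# ---------------------------------------------------------------------------
# (delta-mu)^2 and classification index
# ---------------------------------------------------------------------------


def pairwise_delta_mu_sq(
    geno: MsatGenotypeMatrix, part: PopulationPartition, level: str = "population"
) -> pd.DataFrame:
    """Goldstein's (delta-mu)^2: squared difference of mean allele sizes
    per locus, averaged over loci with data in both populations."""
    pops = _pop_indices(geno, part, level)
    labels = list(pops)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for p1, p2 in itertools.combinations(labels, 2):
        vals = []
        for locus in range(geno.n_loci):
            a1 = _locus_alleles(geno, pops[p1], locus)
            a2 = _locus_alleles(geno, pops[p2], locus)
            if a1.size == 0 or a2.size == 0:
                continue
            vals.append((a1.mean() - a2.mean()) ** 2)
        if not vals:
            raise ValueError(f"no shared loci between {p1!r} and {p2!r}")
        mat.loc[p1, p2] = mat.loc[p2, p1] = float(np.mean(vals))
    return mat


def classification_index(
    geno: MsatGenotypeMatrix,
    part: PopulationPartition,
    from_pop: str,
    to_pop: str,
    level: str = "population",
    pseudocount: bool = True,
) -> float:
    """Mean individual assignment log-likelihood (log10 scale).

    For each individual of ``from_pop``, the log10 probability of its
    multilocus genotype under Hardy–Weinberg proportions with ``to_pop``
    allele frequencies, summed over loci and averaged over individuals.
    Self-assignment (``from_pop == to_pop``) removes the focal individual
    from the frequency estimate (leave-one-out).  An allele unseen in
    ``to_pop`` receives frequency ``1/(2N+1)`` (N = gene copies counted)
    when ``pseudocount`` is enabled, otherwise it is an error.
    """
    pops = _pop_indices(geno, part, level)
    if from_pop not in pops or to_pop not in pops:
        raise KeyError("unknown population label")
    idx_from = pops[from_pop]
    idx_to = pops[to_pop]
    self_assign = from_pop == to_pop

    loglik = np.zeros(idx_from.size)
    for locus in range(geno.n_loci):
        copies = _locus_alleles(geno, idx_to, locus)
        if copies.size == 0:
            continue
        alleles, counts = np.unique(copies, return_counts=True)
        g = geno.alleles[idx_from, locus, :]
        valid = g[:, 0] != MISSING
        if not valid.any():
            continue
        a = g[valid, 0]
        b = g[valid, 1]

        def lookup(x: np.ndarray) -> np.ndarray:
            pos = np.searchsorted(alleles, x)
            pos_c = np.minimum(pos, alleles.size - 1)
            seen = (pos < alleles.size) & (alleles[pos_c] == x)
            return np.where(seen, counts[pos_c], 0).astype(float)

        ca = lookup(a)
        cb = lookup(b)
        het = a != b
        n_eff = int(copies.size)
        if self_assign:  # remove the focal individual's two copies
            ca = ca - np.where(het, 1, 2)
            cb = np.where(het, cb - 1, ca)
            n_eff -= 2
        if n_eff <= 0:
            raise ValueError(
                f"population {to_pop!r} too small for leave-one-out at locus "
                f"{geno.locus_ids[locus]}"
            )
        if not pseudocount and (np.any(ca <= 0) or np.any(cb <= 0)):
            raise ValueError(
                f"allele unseen in {to_pop!r} at locus "
                f"{geno.locus_ids[locus]} and pseudocount disabled"
            )
        pseudo = 1.0 / (n_eff + 1)
        fa = np.where(ca > 0, ca / n_eff, pseudo)
        fb = np.where(cb > 0, cb / n_eff, pseudo)
        prob = np.where(het, 2.0 * fa * fb, fa * fa)
        loglik[valid] += np.log10(prob)
    if loglik.size == 0:
        raise ValueError(f"population {from_pop!r} is empty")
    return float(loglik.mean())


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmovaResult:
    """Nested molecular-variance decomposition.

    ``sigma`` holds the variance components (among groups, among
    populations within groups, within populations); for a two-level
    analysis the among-group entries are zero and ``phi_ct``/``phi_sc``
    are NaN.  ``percent`` entries sum to 100.
    """

    df: tuple[int, int, int]
    ss: tuple[float, float, float]
    sigma: tuple[float, float, float]
    percent: tuple[float, float, float]
    phi_st: float
    phi_ct: float
    phi_sc: float


def _ss_within(d2: np.ndarray, members: np.ndarray) -> float:
    sub = d2[np.ix_(members, members)]
    return float(sub.sum() / (2.0 * members.size))


def amova_from_squared_distances(
    d2: np.ndarray, populations: np.ndarray, groups: np.ndarray | None
) -> AmovaResult:
    """AMOVA from a symmetric matrix of squared inter-individual distances.

    Implements the standard sums-of-squares partition with unequal sample
    sizes.  With ``groups`` None (or a single group) the decomposition
    collapses to two levels (among populations / within populations) and a
    warning is logged.
    """
    d2 = np.asarray(d2, dtype=float)
    N = d2.shape[0]
    populations = np.asarray(populations)
    pop_labels, pop_idx = np.unique(populations, return_inverse=True)
    P = pop_labels.size
    if groups is not None:
        groups = np.asarray(groups)
        grp_labels = np.unique(groups)
        if grp_labels.size < 2:
            logger.warning("fewer than 2 groups: two-level AMOVA")
            groups = None
    ss_total = float(d2.sum() / (2.0 * N))
    ss_wp = sum(
        _ss_within(d2, np.flatnonzero(pop_idx == k)) for k in range(P)
    )

    if groups is None:
        df_ap, df_wp = P - 1, N - P
        ss_ap = ss_total - ss_wp
        if df_wp <= 0 or df_ap <= 0:
            raise ValueError("AMOVA needs >=2 populations and residual df")
        ms_ap = ss_ap / df_ap
        ms_wp = ss_wp / df_wp
        sizes = np.bincount(pop_idx)
        n_coef = (N - (sizes**2).sum() / N) / df_ap
        sig_c = ms_wp
        sig_b = (ms_ap - sig_c) / n_coef
        total = sig_b + sig_c
        if total == 0.0:
            percent = (0.0, 0.0, 100.0)
            phi_st = 0.0
        else:
            percent = (0.0, 100.0 * sig_b / total, 100.0 * sig_c / total)
            phi_st = sig_b / total
        return AmovaResult(
            df=(0, df_ap, df_wp),
            ss=(0.0, ss_ap, ss_wp),
            sigma=(0.0, sig_b, sig_c),
            percent=percent,
            phi_st=phi_st,
            phi_ct=float("nan"),
            phi_sc=float("nan"),
        )

    grp_labels, grp_idx = np.unique(groups, return_inverse=True)
    G = grp_labels.size
    ss_groups = sum(
        _ss_within(d2, np.flatnonzero(grp_idx == k)) for k in range(G)
    )
    ss_ag = ss_total - ss_groups
    ss_ap = ss_groups - ss_wp
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    if df_ap <= 0 or df_wp <= 0:
        raise ValueError("AMOVA needs populations nested in groups with residual df")
    ms_ag = ss_ag / df_ag
    ms_ap = ss_ap / df_ap
    ms_wp = ss_wp / df_wp

    # coefficients for unequal sample sizes (three-level nested design)
    pop_sizes = np.bincount(pop_idx).astype(float)
    grp_sizes = np.bincount(grp_idx).astype(float)
    pop_group = np.array(
        [grp_idx[np.flatnonzero(pop_idx == k)[0]] for k in range(P)]
    )
    sum_npg = sum(
        (pop_sizes[pop_group == g] ** 2).sum() / grp_sizes[g] for g in range(G)
    )
    n_coef = (N - sum_npg) / df_ap
    n1_coef = (sum_npg - (pop_sizes**2).sum() / N) / df_ag
    n2_coef = (N - (grp_sizes**2).sum() / N) / df_ag

    sig_c = ms_wp
    sig_b = (ms_ap - sig_c) / n_coef
    sig_a = (ms_ag - sig_c - n1_coef * sig_b) / n2_coef
    total = sig_a + sig_b + sig_c
    if total == 0.0:
        percent = (0.0, 0.0, 100.0)
        phi_st = phi_ct = 0.0
        phi_sc = 0.0
    else:
        percent = (
            100.0 * sig_a / total,
            100.0 * sig_b / total,
            100.0 * sig_c / total,
        )
        phi_st = (sig_a + sig_b) / total
        phi_ct = sig_a / total
        phi_sc = sig_b / (sig_b + sig_c) if (sig_b + sig_c) != 0 else 0.0
    return AmovaResult(
        df=(df_ag, df_ap, df_wp),
        ss=(ss_ag, ss_ap, ss_wp),
        sigma=(sig_a, sig_b, sig_c),
        percent=percent,
        phi_st=phi_st,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
    )


def _sequence_sq_distance_matrix(aln: SequenceAlignment) -> np.ndarray:
    """Pairwise count of differing sites (valid in both sequences)."""
    m = aln.matrix
    valid = aln.valid_mask()
    n = len(aln)
    d2 = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = (m[i] != m[i + 1 :]) & both
        d2[i, i + 1 :] = diff.sum(axis=1)
    return d2 + d2.T


def _msat_sq_distance_matrix(geno: MsatGenotypeMatrix) -> np.ndarray:
    """Pairwise allele-sharing distance summed over loci.

    Per locus, the squared distance between two diploid genotypes is the
    number of allele copies not shared (0, 1 or 2); loci missing in either
    individual are skipped.
    """
    n = geno.n_individuals
    d2 = np.zeros((n, n))
    alleles = geno.alleles
    for i in range(n):
        for j in range(i + 1, n):
            total = 0.0
            for locus in range(geno.n_loci):
                a = alleles[i, locus]
                b = alleles[j, locus]
                if a[0] == MISSING or b[0] == MISSING:
                    continue
                shared = 0
                used = [False, False]
                for x in a:
                    for k, y in enumerate(b):
                        if not used[k] and x == y:
                            used[k] = True
                            shared += 1
                            break
                total += 2 - shared
            d2[i, j] = d2[j, i] = total
    return d2


def _partition_arrays(
    ids: list[str], part: PopulationPartition
) -> tuple[np.ndarray, np.ndarray | None]:
    pops = np.array([part.individual_to_population[i] for i in ids])
    if part.population_to_group is None:
        return pops, None
    groups = np.array(
        [part.population_to_group[p] for p in pops]
    )
    return pops, groups


def amova_sequences(
    aln: SequenceAlignment, part: PopulationPartition
) -> AmovaResult:
    """Hierarchical AMOVA on sequences with pairwise-difference distances."""
    pops, groups = _partition_arrays(aln.ids, part)
    return amova_from_squared_distances(
        _sequence_sq_distance_matrix(aln), pops, groups
    )


def amova_msat(geno: MsatGenotypeMatrix, part: PopulationPartition) -> AmovaResult:
    """Hierarchical AMOVA on microsatellites (allele-sharing distances)."""
    pops, groups = _partition_arrays(geno.individual_ids, part)
    return amova_from_squared_distances(
        _msat_sq_distance_matrix(geno), pops, groups
    )
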