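"""Independent brute-force oracles used by the test suite.

Every function here recomputes a statistic from first principles —
explicit pair enumeration, exact integer combinatorics, Monte-Carlo
subsampling, direct transcription of published variance-component
algebra — deliberately avoiding the vectorized code paths of the
package, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# sequence diversity
# ---------------------------------------------------------------------------


def hd_pair_enumeration(sequences: list[str]) -> float:
    """Haplotype diversity as the fraction of differing unordered pairs."""
    n = len(sequences)
    pairs = different = 0
    for a, b in itertools.combinations(sequences, 2):
        pairs += 1
        different += a != b
    return different / pairs


def pi_pair_enumeration(sequences: list[str]) -> float:
    """Nucleotide diversity: mean per-site mismatch over pairs.

    Complete-data oracle (no gaps/Ns): mean over unordered pairs of
    (hamming distance / length).
    """
    n = len(sequences)
    L = len(sequences[0])
    total = 0.0
    pairs = 0
    for a, b in itertools.combinations(sequences, 2):
        total += sum(x != y for x, y in zip(a, b)) / L
        pairs += 1
    return total / pairs


def mpd_pair_enumeration(sequences: list[str]) -> float:
    """Mean number of differing sites over unordered pairs."""
    total = 0
    pairs = 0
    for a, b in itertools.combinations(sequences, 2):
        total += sum(x != y for x, y in zip(a, b))
        pairs += 1
    return total / pairs


def segregating_sites_direct(sequences: list[str]) -> int:
    S = 0
    for col in zip(*sequences):
        bases = {c for c in col if c in "ACGT"}
        S += len(bases) >= 2
    return S


# ---------------------------------------------------------------------------
# allelic richness
# ---------------------------------------------------------------------------


def richness_exact(allele_counts: list[int], g2: int) -> float:
    """Rarefied allele count by exact integer combinatorics."""
    N = sum(allele_counts)
    denom = math.comb(N, g2)
    total = 0.0
    for ni in allele_counts:
        total += 1.0 - math.comb(N - ni, g2) / denom
    return total


def richness_monte_carlo(
    allele_counts: list[int], g2: int, rng: np.random.Generator, reps: int = 20000
) -> float:
    """Rarefied allele count by subsampling gene copies without replacement."""
    pool = np.repeat(np.arange(len(allele_counts)), allele_counts)
    seen = 0
    for _ in range(reps):
        sub = rng.choice(pool, size=g2, replace=False)
        seen += np.unique(sub).size
    return seen / reps


# ---------------------------------------------------------------------------
# PIC
# ---------------------------------------------------------------------------


def pic_double_loop(freqs: list[float]) -> float:
    """Polymorphism information content with the explicit double sum."""
    s = 1.0 - sum(p * p for p in freqs)
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            s -= 2.0 * freqs[i] ** 2 * freqs[j] ** 2
    return s


# ---------------------------------------------------------------------------
# Weir-Cockerham theta (two populations), direct transcription
# ---------------------------------------------------------------------------


def wc_theta_direct(
    pop1: list[list[tuple[int, int]]], pop2: list[list[tuple[int, int]]]
) -> float:
    """Theta from the published variance-component algebra, loop form.

    ``pop1``/``pop2`` are per-locus lists of (allele, allele) genotype
    tuples (no missing data).  Components a, b, c are accumulated over
    alleles and loci before forming the ratio.
    """
    A = B = C = 0.0
    for g1, g2 in zip(pop1, pop2):
        n1, n2 = len(g1), len(g2)
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
        alleles = sorted({a for g in (g1 + g2) for a in g})
        for al in alleles:
            p1 = sum(int(x == al) + int(y == al) for x, y in g1) / (2 * n1)
            p2 = sum(int(x == al) + int(y == al) for x, y in g2) / (2 * n2)
            h1 = sum(x != y and al in (x, y) for x, y in g1) / n1
            h2 = sum(x != y and al in (x, y) for x, y in g2) / n2
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - ((r - 1) / r) * s2
                - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c = hbar / 2
            A += a
            B += b
            C += c
    return A / (A + B + C)


# ---------------------------------------------------------------------------
# haplotype-frequency F_ST, hand algebra
# ---------------------------------------------------------------------------


def fst_haplotype_hand(counts1: list[int], counts2: list[int]) -> float:
    """Nei-Chesser Gst from the frequency definitions, written out."""
    n1, n2 = sum(counts1), sum(counts2)
    p1 = [c / n1 for c in counts1]
    p2 = [c / n2 for c in counts2]
    ntilde = 2.0 / (1.0 / n1 + 1.0 / n2)
    hs_raw = 1.0 - 0.5 * (sum(p * p for p in p1) + sum(p * p for p in p2))
    hs = ntilde / (ntilde - 1.0) * hs_raw
    pbar = [0.5 * (a + b) for a, b in zip(p1, p2)]
    ht = 1.0 - sum(p * p for p in pbar) + hs / (2.0 * ntilde)
    return (ht - hs) / ht


# ---------------------------------------------------------------------------
# AMOVA, brute-force SS partition
# ---------------------------------------------------------------------------


def amova_direct(
    d2: np.ndarray, pops: list[str], groups: list[str]
) -> tuple[float, float, float]:
    """Variance components (among groups, among pops in groups, within)
    from the brute-force sums-of-squares partition."""
    N = len(pops)

    def ss_of(members: list[int]) -> float:
        tot = 0.0
        for i in members:
            for j in members:
                if i < j:
                    tot += d2[i, j]
        return tot / len(members)

    everyone = list(range(N))
    pop_labels = sorted(set(pops))
    grp_labels = sorted(set(groups))
    pop_members = {p: [i for i in everyone if pops[i] == p] for p in pop_labels}
    grp_members = {g: [i for i in everyone if groups[i] == g] for g in grp_labels}

    ss_total = ss_of(everyone)
    ss_wp = sum(ss_of(m) for m in pop_members.values())
    ss_groups = sum(ss_of(m) for m in grp_members.values())
    ss_ag = ss_total - ss_groups
    ss_ap = ss_groups - ss_wp

    P, G = len(pop_labels), len(grp_labels)
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_ag, ms_ap, ms_wp = ss_ag / df_ag, ss_ap / df_ap, ss_wp / df_wp

    pop_group = {p: groups[pop_members[p][0]] for p in pop_labels}
    sum_npg = 0.0
    for g in grp_labels:
        Ng = len(grp_members[g])
        for p in pop_labels:
            if pop_group[p] == g:
                sum_npg += len(pop_members[p]) ** 2 / Ng
    n_coef = (N - sum_npg) / df_ap
    n1_coef = (sum_npg - sum(len(m) ** 2 for m in pop_members.values()) / N) / df_ag
    n2_coef = (N - sum(len(m) ** 2 for m in grp_members.values()) / N) / df_ag

    sig_c = ms_wp
    sig_b = (ms_ap - sig_c) / n_coef
    sig_a = (ms_ag - sig_c - n1_coef * sig_b) / n2_coef
    return sig_a, sig_b, sig_c


# ---------------------------------------------------------------------------
# coalescent / mutation closed forms
# ---------------------------------------------------------------------------


def smm_equilibrium_he(n_diploid: float, mu: float) -> float:
    """Equilibrium gene diversity under the strict stepwise model."""
    return 1.0 - 1.0 / math.sqrt(1.0 + 8.0 * n_diploid * mu)


def expected_tmrca(n_copies: int, m_size: float) -> float:
    """E[TMRCA] for n gene copies in a population of gene-copy size M."""
    return 2.0 * m_size * (1.0 - 1.0 / n_copies)


def var_tmrca(n_copies: int, m_size: float) -> float:
    """Var[TMRCA]: sum of squared exponential interval means."""
    return sum(
        (m_size / (k * (k - 1) / 2.0)) ** 2 for k in range(2, n_copies + 1)
    )
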