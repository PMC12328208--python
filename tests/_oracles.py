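"""Independent brute-force oracles used by the unit and acceptance tests.

Each function re-derives its statistic from first principles (pair
enumeration, exhaustive combinatorics, direct formula transcription) without
touching the package's implementation paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pairwise_pi(haplotypes: np.ndarray, n_callable: int) -> float:
    """Mean pairwise difference per site by exhaustive pair enumeration."""
    n = haplotypes.shape[0]
    total = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        total += np.sum(haplotypes[i] != haplotypes[j])
        pairs += 1
    return total / pairs / n_callable


def wattersons_theta_direct(S: int, n: int, L: int) -> float:
    a1 = sum(1.0 / i for i in range(1, n))
    return S / (a1 * L)


def tajimas_d_direct(pi_total: float, S: int, n: int) -> float:
    """Straight transcription of the classical constants."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def hudson_fst_direct(p1, p2, n1, n2) -> float:
    """Ratio-of-averages Hudson FST by per-site hand arithmetic."""
    num = den = 0.0
    for a, b, na, nb in zip(p1, p2, n1, n2):
        num += (a - b) ** 2 - a * (1 - a) / (na - 1) - b * (1 - b) / (nb - 1)
        den += a * (1 - b) + b * (1 - a)
    return num / den


def wilcoxon_greater_exact(x: np.ndarray, y: np.ndarray) -> float:
    """P(rank-sum of x >= observed) by exhaustive enumeration of all
    C(nx+ny, nx) rank assignments (distinct values assumed)."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    obs = ranks[: len(x)].sum()
    n = len(pooled)
    count = total = 0
    for combo in itertools.combinations(range(n), len(x)):
        total += 1
        if ranks[list(combo)].sum() >= obs:
            count += 1
    return count / total


def hypergeom_upper_exact(N: int, K: int, n: int, k: int) -> float:
    """Upper tail by enumerating all C(N, n) draws."""
    marked = set(range(K))
    count = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            count += 1
    return count / total


def mantel_exhaustive(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Mantel r and exact permutation p over all n! joint permutations."""
    iu = np.triu_indices_from(a, k=1)
    va = a[iu]
    r_obs = np.corrcoef(va, b[iu])[0, 1]
    count = total = 0
    for perm in itertools.permutations(range(a.shape[0])):
        idx = np.array(perm)
        r = np.corrcoef(va, b[np.ix_(idx, idx)][iu])[0, 1]
        total += 1
        if r >= r_obs - 1e-12:
            count += 1
    return r_obs, count / total


def wza_direct(p: np.ndarray, w: np.ndarray, n_total: int) -> float:
    """Direct weighted-Z formula for a single window."""
    from scipy.stats import norm

    lo = 1.0 / (2 * n_total)
    z = norm.ppf(1 - np.clip(p, lo, 1 - lo))
    return float(np.sum(w * z) / math.sqrt(np.sum(w**2)))


def kendall_tau_pairs(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected tau_b by explicit concordant/discordant pair counting."""
    n = len(x)
    c = d = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        sx = np.sign(x[i] - x[j])
        sy = np.sign(y[i] - y[j])
        if sx == 0 and sy == 0:
            tx += 1
            ty += 1
        elif sx == 0:
            tx += 1
        elif sy == 0:
            ty += 1
        elif sx == sy:
            c += 1
        else:
            d += 1
    n0 = n * (n - 1) // 2
    return (c - d) / math.sqrt((n0 - tx) * (n0 - ty))


def de_null_exhaustive(de: np.ndarray, lfc: np.ndarray, chrom: np.ndarray,
                       target_start: int, g: int) -> tuple[float, float]:
    """Empirical p for the DE count and mean |log2FC| of the target run,
    against every valid contiguous run of g genes within one chromosome."""
    starts = []
    i = 0
    n = len(de)
    order = np.arange(n)
    for c in dict.fromkeys(chrom):
        idx = order[chrom == c]
        if idx.size >= g:
            starts.extend(idx[: idx.size - g + 1])
    obs_de = de[target_start : target_start + g].sum()
    obs_lfc = np.abs(lfc[target_start : target_start + g]).mean()
    null_de = [de[s : s + g].sum() for s in starts]
    null_lfc = [np.abs(lfc[s : s + g]).mean() for s in starts]
    B = len(starts)
    p_de = (1 + sum(v >= obs_de for v in null_de)) / (1 + B)
    p_lfc = (1 + sum(v >= obs_lfc - 1e-12 for v in null_lfc)) / (1 + B)
    return p_de, p_lfc
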