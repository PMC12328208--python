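"""Closed-form population-genetic statistics.

Frequency estimation from genotype likelihoods uses an EM iteration under
Hardy-Weinberg; diversity statistics (theta_pi, theta_w, Tajima's D) follow
the classical frequency-based estimators; differentiation uses Hudson's
FST with the ratio-of-averages weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeLikelihoodMatrix

logger = logging.getLogger(__name__)

_GT_DOSAGE = np.array([0.0, 1.0, 2.0])


@dataclass
class AlleleFrequencyTable:
    """Minor-allele frequency per population x site with haploid sample
    sizes; frequency is NaN wherever no chromosomes were callable."""

    populations: list[str]
    sites: pd.DataFrame
    freq: np.ndarray        # (J, S)
    n_chrom: np.ndarray     # (J, S)
    low_information: np.ndarray | None = None  # (J, S) bool

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            bad = (self.freq < -1e-9) | (self.freq > 1 + 1e-9)
        if np.any(bad & ~np.isnan(self.freq)):
            raise ValueError("frequencies must lie in [0, 1]")


@dataclass
class DiversitySummary:
    pi: float
    theta_w: float
    tajima_d: float
    n_sites: int
    n_segregating: int
    n_chrom: int


def _hwe_prior(p: np.ndarray) -> np.ndarray:
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)


def estimate_allele_frequencies(
    glm: GenotypeLikelihoodMatrix,
    pop_of_sample: np.ndarray,
    populations: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlleleFrequencyTable:
    """Maximum-likelihood allele frequencies per population by EM over
    genotype likelihoods under Hardy-Weinberg.

    Iterates p <- mean posterior dosage / 2 from a naive (uniform-prior)
    start until |dp| < tol or ``max_iter``.  Sites where every GL triple is
    uninformative are flagged ``low_information`` (the EM is stationary at
    its start there).
    """
    pop_of_sample = np.asarray(pop_of_sample)
    J = pop_of_sample.max() + 1 if populations is None else len(populations)
    if populations is None:
        populations = [f"pop{j}" for j in range(J)]
    S = glm.n_sites
    freq = np.full((J, S), np.nan)
    n_chrom = np.zeros((J, S), dtype=int)
    low_info = np.zeros((J, S), dtype=bool)
    for j in range(J):
        members = np.flatnonzero(pop_of_sample == j)
        if members.size == 0:
            raise ValueError(f"population {populations[j]} has zero samples")
        gl = glm.gl[members]                   # (n, S, 3)
        miss = glm.missing[members]
        n_obs = (~miss).sum(axis=0)
        n_chrom[j] = 2 * n_obs
        informative = (
            (gl.max(axis=-1) - gl.min(axis=-1) > 1e-9) & ~miss
        ).any(axis=0)
        low_info[j] = (n_obs > 0) & ~informative

        with np.errstate(invalid="ignore"):
            naive = (gl[..., 1] + 2 * gl[..., 2]) / 2.0
        naive[miss] = np.nan
        p = np.nanmean(np.where(miss, np.nan, naive), axis=0)
        p = np.clip(np.where(n_obs > 0, p, np.nan), 0.0, 1.0)
        active = n_obs > 0
        for _ in range(max_iter):
            prior = _hwe_prior(p[active])      # (s, 3)
            post = gl[:, active, :] * prior[None, :, :]
            tot = post.sum(axis=-1)
            with np.errstate(invalid="ignore", divide="ignore"):
                dos = (post[..., 1] + 2 * post[..., 2]) / tot
            dos[miss[:, active]] = np.nan
            p_new = np.nanmean(dos, axis=0) / 2.0
            delta = np.nanmax(np.abs(p_new - p[active])) if p_new.size else 0.0
            p[active] = p_new
            if delta < tol:
                break
        freq[j] = p
    return AlleleFrequencyTable(populations, glm.sites, freq, n_chrom, low_info)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(freq: np.ndarray, n_chrom: int, n_callable: int) -> float:
    """Per-site nucleotide diversity theta_pi from allele frequencies:
    (1/L) * sum_sites [n/(n-1)] * 2 p (1-p)."""
    if n_chrom < 2:
        raise ValueError("nucleotide diversity needs n >= 2 chromosomes")
    freq = np.asarray(freq, dtype=float)
    het = 2.0 * freq * (1.0 - freq) * n_chrom / (n_chrom - 1)
    return float(np.nansum(het) / n_callable)


def wattersons_theta(n_segregating: int, n_chrom: int, n_callable: int) -> float:
    """Watterson's estimator per site: S / (a1 * L)."""
    if n_chrom < 2:
        raise ValueError("Watterson's theta needs n >= 2 chromosomes")
    a1 = np.sum(1.0 / np.arange(1, n_chrom))
    return float(n_segregating / (a1 * n_callable))


def tajimas_d(pi_total: float, n_segregating: int, n_chrom: int) -> float:
    """Tajima's D from total pairwise diversity (pi summed over sites),
    segregating-site count and haploid sample size; NaN when S = 0."""
    n, S = n_chrom, n_segregating
    if S == 0:
        logger.info("Tajima's D undefined for S = 0")
        return float("nan")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_total - S / a1) / np.sqrt(var))


def diversity_summary(freq: np.ndarray, n_chrom: int, n_callable: int) -> DiversitySummary:
    freq = np.asarray(freq, dtype=float)
    seg = int(np.sum((freq > 0) & (freq < 1)))
    pi = nucleotide_diversity(freq, n_chrom, n_callable)
    tw = wattersons_theta(seg, n_chrom, n_callable)
    d = tajimas_d(pi * n_callable, seg, n_chrom)
    return DiversitySummary(pi, tw, d, n_callable, seg, n_chrom)


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def hudson_fst(
    p1: np.ndarray, p2: np.ndarray, n1: np.ndarray | int, n2: np.ndarray | int
) -> tuple[float, float]:
    """Hudson's FST between two populations over sites.

    Per site N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and
    D = p1(1-p2) + p2(1-p1); returns (weighted, unweighted) where weighted is
    the ratio of averages sum(N)/sum(D) and unweighted is the mean of N/D over
    sites with D > 0.  Negative per-site numerators are retained.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), p1.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), p2.shape)
    ok = ~(np.isnan(p1) | np.isnan(p2)) & (n1 >= 2) & (n2 >= 2)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    N = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    D = p1 * (1 - p2) + p2 * (1 - p1)
    if not np.any(D > 0):
        raise ValueError("Hudson FST undefined: all per-site denominators are zero")
    weighted = float(N.sum() / D.sum())
    m = D > 0
    unweighted = float(np.mean(N[m] / D[m]))
    return weighted, unweighted


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel_test(
    a: np.ndarray, b: np.ndarray, n_perm: int = 999, seed: int = 0,
    method: str = "permutation",
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with a joint
    row/column permutation null; p = (1 + #{r* >= r}) / (1 + n_perm).

    ``method="exhaustive"`` enumerates all n! permutations instead and
    returns the exact p = #{r* >= r} / n! (the identity is counted)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    if a.shape[0] < 3:
        raise ValueError("Mantel test needs >= 3 objects")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    iu = np.triu_indices_from(a, k=1)
    va, vb = a[iu], b[iu]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("Mantel correlation undefined for a constant matrix")
    r = float(np.corrcoef(va, vb)[0, 1])
    n = a.shape[0]
    if method == "exhaustive":
        from itertools import permutations

        count = total = 0
        for perm in permutations(range(n)):
            idx = np.array(perm)
            r_p = np.corrcoef(va, b[np.ix_(idx, idx)][iu])[0, 1]
            total += 1
            if r_p >= r - 1e-12:
                count += 1
        return r, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vb_p = b[np.ix_(perm, perm)][iu]
        r_p = np.corrcoef(va, vb_p)[0, 1]
        if r_p >= r - 1e-12:
            count += 1
    return r, (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# per-sample heterozygosity
# ---------------------------------------------------------------------------

def sample_heterozygosity(
    glm: GenotypeLikelihoodMatrix,
    site_idx: np.ndarray,
    pooled_freq: np.ndarray,
) -> np.ndarray:
    """Per-sample mean posterior heterozygote probability over the region
    sites, under an HWE prior at the population-pooled frequency; NaN for
    samples with no callable region site."""
    site_idx = np.asarray(site_idx)
    if site_idx.size == 0:
        raise ValueError("region contains no sites")
    p = np.clip(np.asarray(pooled_freq, dtype=float), 0.0, 1.0)
    if p.shape != (site_idx.size,):
        raise ValueError("need one pooled frequency per region site")
    gl = glm.gl[:, site_idx, :]
    miss = glm.missing[:, site_idx]
    prior = _hwe_prior(p)[None, :, :]
    post = gl * prior
    tot = post.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = post[..., 1] / tot
    het[miss | (tot <= 0)] = np.nan
    all_missing = np.isnan(het).all(axis=1)
    out = np.full(glm.n_samples, np.nan)
    out[~all_missing] = np.nanmean(het[~all_missing], axis=1)
    return out


def hard_genotype_heterozygosity(genotypes: np.ndarray) -> np.ndarray:
    """Fraction of heterozygous calls per sample (NaN entries ignored)."""
    g = np.asarray(genotypes, dtype=float)
    het = g == 1
    ok = ~np.isnan(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        return het.sum(axis=1) / ok.sum(axis=1)
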