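"""Overlap/enrichment statistics, haploblock clines, relative fitness and the
synteny-preserving differential-expression resampling null."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .io import Region


@dataclass
class OverlapResult:
    """Hypergeometric overlap of two window sets on a common universe."""

    universe: int   # N
    set_k: int      # K
    set_n: int      # n
    overlap: int    # k
    p_upper: float
    fold: float


def hypergeom_overlap(N: int, K: int, n: int, k: int) -> OverlapResult:
    """Upper-tail hypergeometric probability of drawing >= k marked windows
    in n draws from a universe of N containing K marked windows."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    if K == 0 or n == 0:
        raise ValueError("fold enrichment undefined for an empty set")
    fold = (k / n) / (K / N)
    return OverlapResult(N, K, n, k, p, fold)


def haploblock_enrichment(
    outlier_flags: np.ndarray,
    haploblocks: list[Region],
    windows: pd.DataFrame,
) -> OverlapResult:
    """Enrichment of outlier windows inside haploblock regions: windows
    overlapping any haploblock count as haploblock windows."""
    outlier_flags = np.asarray(outlier_flags, dtype=bool)
    in_hb = np.zeros(len(windows), dtype=bool)
    chrom = windows["chrom"].to_numpy()
    start = windows["start"].to_numpy()
    end = windows["end"].to_numpy()
    for hb in haploblocks:
        in_hb |= (chrom == hb.chrom) & (start < hb.end) & (end > hb.start)
    if not in_hb.any():
        raise ValueError("no haploblock windows in the universe")
    k = int((outlier_flags & in_hb).sum())
    return hypergeom_overlap(len(windows), int(in_hb.sum()), int(outlier_flags.sum()), k)


def parallel_overlap(outlier_sets: dict[str, np.ndarray]) -> tuple[pd.DataFrame, dict]:
    """Upset-style intersection counts across ranges plus pairwise
    hypergeometric overlap tests on the shared window universe."""
    names = list(outlier_sets)
    flags = {m: np.asarray(v, dtype=bool) for m, v in outlier_sets.items()}
    sizes = {len(v) for v in flags.values()}
    if len(sizes) != 1:
        raise ValueError("all outlier sets must share one window universe")
    N = sizes.pop()
    stack = np.column_stack([flags[m] for m in names])
    patterns, counts = np.unique(stack, axis=0, return_counts=True)
    rows = [
        {**{names[i]: bool(pat[i]) for i in range(len(names))}, "count": int(c)}
        for pat, c in zip(patterns, counts)
    ]
    upset = pd.DataFrame(rows)
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = flags[names[i]], flags[names[j]]
            pairwise[(names[i], names[j])] = hypergeom_overlap(
                N, int(a.sum()), int(b.sum()), int((a & b).sum())
            )
    return upset, pairwise


def haploblock_cline(
    dosage: np.ndarray,
    latitude: np.ndarray,
    range_label: np.ndarray,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Per-range OLS of individual haploblock allele frequency (aa=0, ab=0.5,
    bb=1) on latitude: slope, standard error, t and two-sided p.

    Ranges with constant dosage report slope 0 and missing p; fits with
    fewer than 3 points (no residual df) report a missing p.
    """
    dosage = np.asarray(dosage, dtype=float)
    latitude = np.asarray(latitude, dtype=float)
    range_label = np.asarray(range_label)
    rows = []
    for rng_name in pd.unique(range_label):
        m = (range_label == rng_name) & ~np.isnan(dosage) & ~np.isnan(latitude)
        n = int(m.sum())
        if n < min_samples:
            raise ValueError(f"range {rng_name!r} has {n} samples; need >= {min_samples}")
        y, x = dosage[m], latitude[m]
        if np.ptp(y) == 0:
            rows.append((rng_name, n, 0.0, np.nan, np.nan, np.nan))
            continue
        res = stats.linregress(x, y)
        p = res.pvalue if n > 2 else np.nan
        t = res.slope / res.stderr if res.stderr > 0 else np.nan
        rows.append((rng_name, n, res.slope, res.stderr, t, p))
    return pd.DataFrame(
        rows, columns=["range", "n", "slope", "stderr", "t", "pvalue"]
    )


def relative_fitness(table: pd.DataFrame, value: str = "seed_mass") -> pd.DataFrame:
    """Relative fitness standardized within gardens: each individual's value
    divided by the mean of the best-performing haploblock genotype in the
    same garden."""
    out = table.copy()
    out["relative_fitness"] = np.nan
    for garden, grp in table.groupby("garden"):
        means = grp.groupby("genotype")[value].mean()
        best = means.max()
        if not best > 0:
            raise ValueError(f"garden {garden!r} has no positive {value}")
        out.loc[grp.index, "relative_fitness"] = grp[value] / best
    return out


def gwas_de_fraction(n_hits: int, n_de: int) -> float:
    """Percentage of GWAS hit genes that were differentially expressed,
    rounded half-up to one decimal."""
    if n_de > n_hits or n_hits <= 0:
        raise ValueError("need 0 <= n_de <= n_hits and n_hits > 0")
    pct = Decimal(100 * n_de) / Decimal(n_hits)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ResamplingNull:
    observed_de: int
    observed_mean_abs_lfc: float
    null_de: np.ndarray
    null_mean_abs_lfc: np.ndarray
    p_de: float
    p_lfc: float
    seed: int | None


def de_resampling_null(
    genes: pd.DataFrame,
    target: np.ndarray,
    comparison: str,
    n_resample: int = 10_000,
    seed: int = 0,
    fdr_threshold: float = 0.1,
    exhaustive: bool = False,
) -> ResamplingNull:
    """Synteny-preserving resampling null for a haploblock's gene set.

    ``target`` indexes a contiguous run of g genes in genome order (rows of
    ``genes`` sorted by chrom, midpoint).  Each resample draws a contiguous
    run of exactly g genes confined to one chromosome, with the start chosen
    uniformly over all valid starts genome-wide; ``exhaustive=True``
    enumerates every valid start instead.  For each draw the number of genes
    with FDR < threshold and the mean |log2FC| are recorded; empirical p is
    (1 + #{null >= observed}) / (1 + B), inclusive.
    """
    genes = genes.sort_values(["chrom", "midpoint"], kind="stable").reset_index(drop=True)
    target = np.asarray(target)
    g = target.size
    if g == 0:
        raise ValueError("empty target gene set")
    if not np.array_equal(np.sort(target), np.arange(target.min(), target.min() + g)):
        raise ValueError("target must be a contiguous run of genes in genome order")
    if genes["chrom"].iloc[target].nunique() != 1:
        raise ValueError("target run must lie on a single chromosome")

    fdr = genes[f"fdr_{comparison}"].to_numpy()
    lfc = np.abs(genes[f"log2FC_{comparison}"].to_numpy())
    de = fdr < fdr_threshold

    starts = []
    for _, grp in genes.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if idx.size >= g:
            starts.extend(idx[: idx.size - g + 1])
    starts = np.asarray(starts)
    if starts.size == 0:
        raise ValueError(f"no chromosome holds a run of {g} genes")

    if exhaustive:
        chosen = starts
    else:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(starts, size=n_resample, replace=True)

    # prefix sums for O(1) run statistics
    cde = np.concatenate([[0], np.cumsum(de)])
    clf = np.concatenate([[0], np.cumsum(lfc)])
    null_de = cde[chosen + g] - cde[chosen]
    null_lfc = (clf[chosen + g] - clf[chosen]) / g

    obs_de = int(de[target].sum())
    obs_lfc = float(lfc[target].mean())
    B = chosen.size
    p_de = (1 + int((null_de >= obs_de).sum())) / (1 + B)
    p_lfc = (1 + int((null_lfc >= obs_lfc - 1e-12).sum())) / (1 + B)
    return ResamplingNull(
        obs_de, obs_lfc, null_de, null_lfc, p_de, p_lfc, None if exhaustive else seed
    )
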