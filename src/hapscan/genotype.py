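"""Genotype candidate haploblock regions and validate them.

A real structural variant produces three sample clusters along one principal
component of the region (two homozygous arrangements and heterozygotes),
elevated heterozygosity in the middle cluster, and region-wide linkage
disequilibrium that collapses within homozygotes.  This module automates the
three checks and combines them into an accept/reject call with reason codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import Region

logger = logging.getLogger(__name__)

GENOTYPE_LABELS = ("aa", "ab", "bb")


@dataclass
class GenotypeAssignment:
    labels: np.ndarray          # per-sample 'aa'/'ab'/'bb'/'missing'
    posterior: np.ndarray       # max assignment posterior per sample
    axis: int                   # PCA axis used (0-based)
    three_clusters: bool        # BIC preferred 3 components
    cluster_sizes: dict
    means: np.ndarray           # component means ordered along the axis


@dataclass
class LDEvidence:
    ld_ratio: float
    region_mean_all: float      # mean r^2, random subset, within-region pairs
    region_mean_hom: float      # mean r^2, major-homozygote subset
    flank_mean: float           # mean r^2, random subset, pairs outside region
    n_region_pairs: int


@dataclass
class HaploblockCall:
    region: Region
    assignment: GenotypeAssignment
    het_p_ab_vs_aa: float
    het_p_ab_vs_bb: float
    ld: LDEvidence | None
    accepted: bool
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# coverage filter
# ---------------------------------------------------------------------------

def filter_by_coverage(
    mean_depth: np.ndarray | None = None,
    min_cov: float = 0.4,
    nonmissing_fraction: np.ndarray | None = None,
    min_fraction: float | None = None,
) -> np.ndarray:
    """Samples retained for genotyping: mean depth >= min_cov (inclusive).

    Without a depth table, a declared proxy (fraction of non-missing sites,
    thresholded at ``min_fraction``) may be used; supplying neither is an
    error.  Returns the boolean keep mask; exclusions are logged.
    """
    if mean_depth is not None:
        keep = np.asarray(mean_depth, dtype=float) >= min_cov
    elif nonmissing_fraction is not None and min_fraction is not None:
        keep = np.asarray(nonmissing_fraction, dtype=float) >= min_fraction
    else:
        raise ValueError(
            "coverage filtering needs a per-sample depth table, or a "
            "non-missing-fraction proxy with an explicit threshold"
        )
    if not keep.any():
        raise ValueError("coverage filter excluded every sample")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("coverage filter excluded %d samples", n_drop)
    return keep


# ---------------------------------------------------------------------------
# region PCA
# ---------------------------------------------------------------------------

def region_pca(
    dosage: np.ndarray,
    site_idx: np.ndarray,
    maf_min: float = 0.05,
    min_sites: int = 20,
    n_axes: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of mean-imputed, centered dosages restricted to region sites
    passing the MAF filter.  Returns (scores (n, n_axes), eigenvalues)."""
    site_idx = np.asarray(site_idx)
    X = dosage[:, site_idx].astype(float)
    mu = np.nanmean(X, axis=0)
    keep = ~np.isnan(mu)
    X, mu = X[:, keep], mu[keep]
    maf = np.minimum(mu / 2.0, 1 - mu / 2.0)
    keep = maf >= maf_min
    X, mu = X[:, keep], mu[keep]
    if X.shape[1] < min_sites:
        raise ValueError(
            f"region has {X.shape[1]} sites passing MAF >= {maf_min}; need {min_sites}"
        )
    inds = np.where(np.isnan(X))
    X[inds] = mu[inds[1]]
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (X.shape[0] - 1)
    return u[:, :n_axes] * s[:n_axes], eigvals[:n_axes]


# ---------------------------------------------------------------------------
# mixture genotyping
# ---------------------------------------------------------------------------

def assign_genotypes(
    scores: np.ndarray,
    posterior_min: float = 0.9,
    seed: int = 0,
) -> GenotypeAssignment:
    """Assign aa/ab/bb from PCA scores with seeded 1-D Gaussian mixtures.

    For each of the first two axes a 3-component shared-variance mixture
    (means initialized at the 10th/50th/90th percentiles) is fit by EM and
    compared against 1- and 2-component fits by BIC; the axis where three
    components win is used.  Components are ordered by mean; the outer two
    are homozygotes and the middle is the heterozygote.  Samples whose max
    posterior falls below ``posterior_min`` are set to missing; 'a' denotes
    the arrangement of the larger homozygote cluster.
    """
    from sklearn.mixture import GaussianMixture

    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1 and scores.shape[1] > 2:
        scores = scores.T
    n_axes = min(2, scores.shape[1])
    best = None
    for axis in range(n_axes):
        x = scores[:, axis : axis + 1]
        fits = {}
        for k in (1, 2, 3):
            qs = np.quantile(x, np.linspace(0.1, 0.9, k))
            gm = GaussianMixture(
                n_components=k,
                covariance_type="tied",
                means_init=qs.reshape(-1, 1),
                max_iter=200,
                tol=1e-8,
                random_state=seed,
                n_init=1,
                reg_covar=1e-10,
            ).fit(x)
            fits[k] = (gm.bic(x), gm)
        margin = min(fits[1][0], fits[2][0]) - fits[3][0]
        if best is None or margin > best[0]:
            best = (margin, axis, fits[3][1], x)
    margin, axis, gm, x = best
    three = margin > 0

    order = np.argsort(gm.means_.ravel())
    post = gm.predict_proba(x)[:, order]
    means = gm.means_.ravel()[order]
    comp = np.argmax(post, axis=1)
    maxpost = post[np.arange(len(x)), comp]

    # polarity: 'a' = arrangement of the larger homozygote cluster
    n_lo = int(np.sum(comp == 0))
    n_hi = int(np.sum(comp == 2))
    if n_hi > n_lo:
        mapping = {0: "bb", 1: "ab", 2: "aa"}
    else:
        mapping = {0: "aa", 1: "ab", 2: "bb"}
    labels = np.array([mapping[c] for c in comp], dtype=object)
    labels[maxpost < posterior_min] = "missing"
    if not three:
        logger.info("no three clusters on either axis (BIC margin %.2f)", margin)
    sizes = {g: int(np.sum(labels == g)) for g in GENOTYPE_LABELS + ("missing",)}
    return GenotypeAssignment(labels, maxpost, axis, bool(three), sizes, means)


# ---------------------------------------------------------------------------
# heterozygosity test
# ---------------------------------------------------------------------------

def heterozygosity_test(
    het: np.ndarray, labels: np.ndarray, min_group: int = 3
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum p-values for ab > aa and ab > bb on
    per-sample region heterozygosity.  Exact when both groups have <= 25
    members and no ties; normal approximation with continuity correction
    otherwise.  A comparison with a too-small cluster returns NaN."""
    het = np.asarray(het, dtype=float)
    labels = np.asarray(labels)
    out = []
    ab = het[(labels == "ab") & ~np.isnan(het)]
    for hom in ("aa", "bb"):
        grp = het[(labels == hom) & ~np.isnan(het)]
        if len(ab) < min_group or len(grp) < min_group:
            logger.info("heterozygosity test skipped for %s: cluster too small", hom)
            out.append(float("nan"))
            continue
        pooled = np.r_[ab, grp]
        if np.ptp(pooled) == 0:
            # fully tied data: mid-rank convention, no evidence either way
            out.append(0.5)
            continue
        exact = len(ab) <= 25 and len(grp) <= 25 and len(np.unique(pooled)) == len(ab) + len(grp)
        res = stats.mannwhitneyu(
            ab, grp, alternative="greater", method="exact" if exact else "asymptotic"
        )
        out.append(float(res.pvalue))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# LD scan and validation
# ---------------------------------------------------------------------------

@dataclass
class LDScan:
    site_idx: np.ndarray     # column indices into the dosage matrix
    positions: np.ndarray    # 1-based positions
    r2: np.ndarray           # (m, m) squared correlations, NaN where undefined


def ld_scan(
    dosage: np.ndarray,
    positions: np.ndarray,
    sample_idx: np.ndarray,
    n_sites: int = 5000,
    maf_min: float = 0.05,
    seed: int = 0,
    candidate_idx: np.ndarray | None = None,
) -> LDScan:
    """Pairwise r^2 on up to ``n_sites`` randomly chosen qualifying sites.

    Sites are MAF-filtered on the full sample set, sampled uniformly without
    replacement, and r^2 is the squared Pearson correlation of mean-imputed
    dosages across ``sample_idx``.  There is no distance cap.  Sites
    monomorphic within the subset yield NaN rows/columns.
    """
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions)
    if candidate_idx is None:
        candidate_idx = np.arange(dosage.shape[1])
    mu = np.nanmean(dosage[:, candidate_idx], axis=0)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(mu / 2.0, 1 - mu / 2.0)
    ok = np.flatnonzero(~np.isnan(maf) & (maf >= maf_min))
    if ok.size < 2:
        raise ValueError("chromosome has fewer than 2 qualifying sites")
    chosen = candidate_idx[np.sort(rng.choice(ok, size=min(n_sites, ok.size), replace=False))]

    X = dosage[np.ix_(sample_idx, chosen)].astype(np.float32)
    col_mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = col_mu[inds[1]]
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    nz = sd > 1e-6
    Xn = np.zeros_like(X)
    Xn[:, nz] = X[:, nz] / sd[nz]
    r = (Xn.T @ Xn) / X.shape[0]
    r2 = np.square(r, dtype=np.float32)
    r2[~nz, :] = np.nan
    r2[:, ~nz] = np.nan
    np.fill_diagonal(r2, np.nan)
    return LDScan(chosen, positions[chosen], r2)


def _mean_r2(scan: LDScan, in_region: np.ndarray, where: str) -> tuple[float, int]:
    if where == "region":
        mask = np.outer(in_region, in_region)
    else:
        mask = np.outer(~in_region, ~in_region)
    iu = np.triu(np.ones_like(mask, dtype=bool), k=1)
    vals = scan.r2[mask & iu]
    vals = vals[~np.isnan(vals)]
    return (float(vals.mean()) if vals.size else float("nan")), int(vals.size)


def ld_validate(
    dosage: np.ndarray,
    positions: np.ndarray,
    region: Region,
    labels: np.ndarray,
    chrom_mask: np.ndarray,
    n_sites: int = 5000,
    maf_min: float = 0.05,
    seed: int = 0,
    min_pairs: int = 10,
    min_homozygotes: int = 5,
) -> LDEvidence | None:
    """LD evidence for a haploblock: within-region mean r^2 for a random
    sample subset vs the major-homozygote subset of equal size, and the
    flank background outside the region.

    ``ld_ratio`` > 1 indicates arrangement-driven LD that collapses within
    homozygotes.  Returns None (logged) when too few homozygotes exist.
    """
    labels = np.asarray(labels)
    counts = {g: int(np.sum(labels == g)) for g in GENOTYPE_LABELS}
    major_hom = "aa" if counts["aa"] >= counts["bb"] else "bb"
    hom_idx = np.flatnonzero(labels == major_hom)
    if hom_idx.size < min_homozygotes:
        logger.info("LD validation skipped: only %d %s homozygotes", hom_idx.size, major_hom)
        return None
    rng = np.random.default_rng(seed)
    rand_idx = rng.choice(dosage.shape[0], size=hom_idx.size, replace=False)

    candidate_idx = np.flatnonzero(chrom_mask)
    scan_rand = ld_scan(dosage, positions, rand_idx, n_sites, maf_min, seed, candidate_idx)
    scan_hom = ld_scan(dosage, positions, hom_idx, n_sites, maf_min, seed, candidate_idx)

    pos0 = scan_rand.positions - 1
    in_region = (pos0 >= region.start) & (pos0 < region.end)
    mean_all, n_pairs = _mean_r2(scan_rand, in_region, "region")
    mean_hom, _ = _mean_r2(scan_hom, in_region, "region")
    flank, _ = _mean_r2(scan_rand, in_region, "flank")
    if n_pairs < min_pairs:
        logger.info("LD validation skipped: %d within-region pairs", n_pairs)
        return None
    ratio = mean_all / mean_hom if mean_hom > 0 else float("inf")
    return LDEvidence(float(ratio), mean_all, mean_hom, flank, n_pairs)


# ---------------------------------------------------------------------------
# final call
# ---------------------------------------------------------------------------

def call_haploblock(
    region: Region,
    assignment: GenotypeAssignment,
    het_p: tuple[float, float],
    ld: LDEvidence | None,
    alpha: float = 0.05,
    ld_ratio_min: float = 2.0,
    min_cluster: int = 3,
) -> HaploblockCall:
    """Accept a candidate region as a haploblock iff three clusters were
    found (each with >= min_cluster samples), both heterozygosity p-values
    are below alpha, and the LD ratio exceeds its threshold.  Every failed
    criterion is recorded as a reason code."""
    reasons = []
    sizes = assignment.cluster_sizes
    if not assignment.three_clusters or any(
        sizes[g] < min_cluster for g in GENOTYPE_LABELS
    ):
        reasons.append("no three clusters")
    p_aa, p_bb = het_p
    if not (p_aa < alpha and p_bb < alpha):
        reasons.append("heterozygosity")
    if ld is None or not np.isfinite(ld.ld_ratio) or ld.ld_ratio <= ld_ratio_min:
        reasons.append("LD")
    return HaploblockCall(
        region, assignment, p_aa, p_bb, ld, accepted=not reasons, reasons=reasons
    )
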