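"""Windowed local population structure: per-window covariance, between-window
distances, classical MDS, corner outliers and candidate-region clustering.

A haploblock (inversion-like structural variant) shows up as a stretch of
windows whose sample covariance is dominated by a three-genotype axis; those
windows sit together at an extreme of the MDS embedding of between-window
distances, and clustering the corner outliers along the chromosome yields
candidate regions for genotyping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io import GenomicWindow, Region

logger = logging.getLogger(__name__)


@dataclass
class WindowCovariance:
    """Trace-normalized sample covariance of a window plus its top
    eigenpairs."""

    window: GenomicWindow
    cov: np.ndarray
    eigenvalues: np.ndarray   # descending, length k
    eigenvectors: np.ndarray  # (n_samples, k)
    n_sites: int


@dataclass
class MDSEmbedding:
    windows: list[GenomicWindow]
    coords: np.ndarray        # (n_windows, n_axes)
    eigenvalues: np.ndarray   # (n_axes,)
    degenerate: np.ndarray    # bool per axis (nonpositive eigenvalue)


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    member_windows: list[int]       # window indices (per-chromosome rank)
    label: tuple                    # (axis, side) or (axis_a, axis_b, corner)
    n_outliers: int
    corner_labels: set = field(default_factory=set)

    @property
    def region(self) -> Region:
        return Region(self.chrom, self.start, self.end, str(self.label))


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------

def window_covariance(
    dosage: np.ndarray,
    window: GenomicWindow,
    site_idx: np.ndarray,
    min_sites: int = 10,
    k: int = 2,
) -> WindowCovariance | None:
    """Sample covariance of mean-imputed, site-centered dosages in a window,
    normalized to unit trace, with the top-k eigenpairs attached.

    Returns None (and logs the reason) when the window has fewer than
    ``min_sites`` polymorphic sites or a degenerate covariance.
    """
    site_idx = np.asarray(site_idx)
    X = dosage[:, site_idx].astype(float)
    mu = np.nanmean(X, axis=0)
    allnan = np.isnan(mu)
    X = X[:, ~allnan]
    mu = mu[~allnan]
    inds = np.where(np.isnan(X))
    X[inds] = mu[inds[1]]
    poly = X.std(axis=0) > 1e-9
    m = int(poly.sum())
    if m < min_sites:
        logger.info("window %s skipped: %d < %d polymorphic sites", window, m, min_sites)
        return None
    Xc = X[:, poly] - X[:, poly].mean(axis=0)
    cov = Xc @ Xc.T / (m - 1)
    tr = np.trace(cov)
    if tr <= 0:
        logger.info("window %s skipped: degenerate covariance", window)
        return None
    cov = cov / tr
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    return WindowCovariance(window, cov, np.maximum(vals[order], 0.0), vecs[:, order], m)


def window_distance(a: WindowCovariance, b: WindowCovariance, k: int = 2) -> float:
    """Frobenius distance between rank-k approximations of two windows'
    trace-normalized covariances."""
    if a.cov.shape != b.cov.shape:
        raise ValueError("windows were computed on different sample sets")
    ca = _rank_k(a, k)
    cb = _rank_k(b, k)
    return float(np.linalg.norm(ca - cb, "fro"))


def _rank_k(wc: WindowCovariance, k: int) -> np.ndarray:
    k = min(k, len(wc.eigenvalues))
    u = wc.eigenvectors[:, :k]
    return (u * wc.eigenvalues[:k]) @ u.T


def distance_matrix(wcs: list[WindowCovariance], k: int = 2) -> np.ndarray:
    """All pairwise rank-k covariance distances (symmetric, zero diagonal)."""
    n = len(wcs)
    # flatten the rank-k reconstructions once; pairwise Frobenius = euclidean
    mats = np.stack([_rank_k(w, k).ravel() for w in wcs])
    sq = np.sum(mats**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * mats @ mats.T, 0.0)
    D = np.sqrt(d2)
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------

def mds_embed(D: np.ndarray, windows: list[GenomicWindow], n_axes: int = 5) -> MDSEmbedding:
    """Classical (Torgerson) metric MDS of a distance matrix.

    B = -1/2 J D^2 J; coordinates are the top eigenvectors scaled by the
    square roots of their positive eigenvalues; axes with nonpositive
    eigenvalues are zero-filled and flagged degenerate.  Each axis's sign is
    fixed so the window with the largest |coordinate| is positive.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if np.max(np.abs(D - D.T)) > 1e-8:
        raise ValueError("distance matrix must be symmetric (tol 1e-8)")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1][:n_axes]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, n_axes))
    degenerate = np.ones(n_axes, dtype=bool)
    got = min(n_axes, len(vals))
    for a in range(got):
        if vals[a] > 1e-12:
            coords[:, a] = vecs[:, a] * np.sqrt(vals[a])
            degenerate[a] = False
    eigvals = np.zeros(n_axes)
    eigvals[:got] = vals[:got]
    # fix axis signs: largest-|coordinate| window positive
    for a in range(n_axes):
        if not degenerate[a]:
            i = np.argmax(np.abs(coords[:, a]))
            if coords[i, a] < 0:
                coords[:, a] *= -1
    return MDSEmbedding(list(windows), coords, eigvals, degenerate)


# ---------------------------------------------------------------------------
# corner outliers
# ---------------------------------------------------------------------------

_CORNERS4 = ((1, 1), (1, -1), (-1, 1), (-1, -1))


def corner_outliers(
    emb: MDSEmbedding, pct: float = 0.05, n_corners: int = 4
) -> dict[tuple, np.ndarray]:
    """Label the ``ceil(pct * n_windows)`` most extreme windows in each
    diagonal corner of every pair of MDS axes.

    Axes are rescaled by their max |coordinate|; a window may carry several
    labels.  Degenerate axis pairs are skipped with a warning.  Returns a
    mapping (axis_a, axis_b, (sign_a, sign_b)) -> window positions.
    """
    n, n_axes = emb.coords.shape
    if n < 20:
        raise ValueError("corner outlier detection needs >= 20 windows")
    m = int(np.ceil(pct * n))
    if n_corners == 4:
        corners = [np.array(c) / np.sqrt(2) for c in _CORNERS4]
    elif n_corners == 3:
        ang = np.array([np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3])
        corners = [np.array([np.cos(t), np.sin(t)]) for t in ang]
    else:
        raise ValueError("n_corners must be 3 or 4")
    labels: dict[tuple, np.ndarray] = {}
    for a, b in combinations(range(n_axes), 2):
        sa = np.max(np.abs(emb.coords[:, a]))
        sb = np.max(np.abs(emb.coords[:, b]))
        if sa <= 0 or sb <= 0 or emb.degenerate[a] or emb.degenerate[b]:
            logger.warning("axis pair (%d, %d) degenerate; skipped", a, b)
            continue
        xy = np.column_stack([emb.coords[:, a] / sa, emb.coords[:, b] / sb])
        for c in corners:
            proj = xy @ c
            top = np.argsort(proj)[::-1][:m]
            key = (a, b, (int(np.sign(c[0])) or 1, int(np.sign(c[1])) or 1)) \
                if n_corners == 4 else (a, b, tuple(np.round(c, 3)))
            labels[key] = np.sort(top)
    return labels


# ---------------------------------------------------------------------------
# clustering outliers into candidate regions
# ---------------------------------------------------------------------------

def _runs(indices: np.ndarray, max_gap: int, min_run: int) -> list[np.ndarray]:
    if indices.size == 0:
        return []
    idx = np.sort(indices)
    breaks = np.flatnonzero(np.diff(idx) > max_gap)
    runs = np.split(idx, breaks + 1)
    return [r for r in runs if r.size >= min_run]


def cluster_outlier_windows(
    labels: dict[tuple, np.ndarray],
    emb: MDSEmbedding,
    min_run: int = 3,
    max_gap: int = 2,
    mode: str = "axis",
    pool_min_frac: float = 0.5,
) -> list[CandidateRegion]:
    """Cluster corner-outlier windows along each chromosome into candidate
    regions.

    mode="axis" (default): corner labels are pooled per (axis, side) —
    windows labeled in any corner involving that axis direction, restricted
    to windows whose coordinate on the axis has that sign and a magnitude of
    at least ``pool_min_frac`` of the axis maximum — because a haploblock
    manifests as a stretch of windows jointly extreme in the SAME direction
    along one axis, while each individual 5% corner holds too few windows to
    span it; the half-max guard keeps continuum noise from unrelated axes
    out of the pool.  mode="corner": strict per-(pair, corner) clustering.
    In both modes overlapping regions from different labels are merged into
    a union region carrying all contributing labels.
    """
    windows = emb.windows
    chrom_of = np.array([w.chrom for w in windows])
    index_of = np.array([w.index for w in windows])

    pooled: dict[tuple, set[int]] = {}
    provenance: dict[tuple, set] = {}
    if mode == "axis":
        for (a, b, corner), members in labels.items():
            for axis, sign in ((a, corner[0]), (b, corner[1])):
                key = (axis, int(np.sign(sign)) or 1)
                amax = np.abs(emb.coords[:, axis]).max()
                keep = [
                    i
                    for i in members
                    if np.sign(emb.coords[i, axis]) == key[1]
                    and np.abs(emb.coords[i, axis]) >= pool_min_frac * amax
                ]
                pooled.setdefault(key, set()).update(keep)
                provenance.setdefault(key, set()).add((a, b, corner))
    elif mode == "corner":
        for key, members in labels.items():
            pooled[key] = set(members)
            provenance[key] = {key}
    else:
        raise ValueError("mode must be 'axis' or 'corner'")

    regions: list[CandidateRegion] = []
    for key, members in pooled.items():
        members = np.array(sorted(members), dtype=int)
        for chrom in np.unique(chrom_of[members]) if members.size else []:
            on_chrom = members[chrom_of[members] == chrom]
            for run in _runs(index_of[on_chrom], max_gap, min_run):
                pos = np.flatnonzero((chrom_of == chrom) & np.isin(index_of, run))
                start = min(windows[i].start for i in pos)
                end = max(windows[i].end for i in pos)
                regions.append(
                    CandidateRegion(
                        chrom, start, end, sorted(run.tolist()), key, len(run),
                        set(provenance[key]),
                    )
                )
    return merge_overlapping_regions(regions)


def merge_overlapping_regions(regions: list[CandidateRegion]) -> list[CandidateRegion]:
    """Union overlapping candidate regions (same chromosome) from different
    labels into one region carrying all contributing labels."""
    merged: list[CandidateRegion] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if merged and merged[-1].chrom == r.chrom and r.start < merged[-1].end:
            last = merged[-1]
            members = sorted(set(last.member_windows) | set(r.member_windows))
            merged[-1] = CandidateRegion(
                last.chrom,
                min(last.start, r.start),
                max(last.end, r.end),
                members,
                last.label,
                len(members),
                last.corner_labels | r.corner_labels | {r.label},
            )
        else:
            merged.append(r)
    return merged
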