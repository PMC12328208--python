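"""End-to-end orchestration: haploblock discovery from genotype likelihoods,
and the windowed selection / environment-association scan."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genotype as gt
from . import popgen, scan, structure
from .io import (
    GenotypeLikelihoodMatrix,
    Region,
    assign_sites_to_windows,
    gl_to_dosage,
    make_windows,
)

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryResult:
    windows: list
    embedding: structure.MDSEmbedding | None
    candidates: list[structure.CandidateRegion]
    calls: list[gt.HaploblockCall]
    genotypes: dict  # region name -> per-sample labels

    @property
    def accepted(self) -> list[gt.HaploblockCall]:
        return [c for c in self.calls if c.accepted]


def discover_haploblocks(
    glm: GenotypeLikelihoodMatrix,
    contig_lengths: dict[str, int],
    window_width: int = 100_000,
    n_axes: int = 5,
    corner_pct: float = 0.05,
    min_run: int = 3,
    max_gap: int = 2,
    min_sites: int = 10,
    rank_k: int = 2,
    mean_depth: np.ndarray | None = None,
    min_cov: float = 0.4,
    alpha: float = 0.05,
    ld_ratio_min: float = 2.0,
    ld_n_sites: int = 5000,
    seed: int = 0,
    cluster_mode: str = "axis",
) -> DiscoveryResult:
    """Full scan -> genotype -> validate pipeline.

    Windowed covariances of GL-derived dosages, rank-k covariance distances,
    classical MDS on ``n_axes`` axes, 5%-corner outliers clustered into
    candidate regions, then per-region PCA genotyping with heterozygosity and
    LD validation gates.
    """
    dos = gl_to_dosage(glm)
    if mean_depth is not None:
        keep = gt.filter_by_coverage(mean_depth, min_cov)
    else:
        keep = np.ones(glm.n_samples, dtype=bool)
    dosage = dos.dosage[keep]

    windows = make_windows(contig_lengths, window_width)
    site_lists = assign_sites_to_windows(windows, glm.sites)
    wcs, kept_windows = [], []
    for w, idx in zip(windows, site_lists):
        wc = structure.window_covariance(dosage, w, idx, min_sites=min_sites, k=rank_k)
        if wc is not None:
            wcs.append(wc)
            kept_windows.append(w)
    if len(wcs) < 20:
        logger.warning("only %d usable windows; no structure scan", len(wcs))
        return DiscoveryResult(windows, None, [], [], {})

    D = structure.distance_matrix(wcs, k=rank_k)
    emb = structure.mds_embed(D, kept_windows, n_axes=n_axes)
    labels = structure.corner_outliers(emb, pct=corner_pct)
    candidates = structure.cluster_outlier_windows(
        labels, emb, min_run=min_run, max_gap=max_gap, mode=cluster_mode
    )

    calls, genos = [], {}
    chrom_arr = glm.sites["chrom"].to_numpy()
    pos_arr = glm.sites["pos"].to_numpy()
    for cand in candidates:
        region = Region(cand.chrom, cand.start, cand.end, str(cand.label))
        call = genotype_and_validate(
            glm, dosage, chrom_arr, pos_arr, region,
            alpha=alpha, ld_ratio_min=ld_ratio_min, ld_n_sites=ld_n_sites, seed=seed,
        )
        if call is not None:
            calls.append(call)
            genos[f"{region.chrom}:{region.start}-{region.end}"] = call.assignment.labels
    return DiscoveryResult(windows, emb, candidates, calls, genos)


def genotype_and_validate(
    glm: GenotypeLikelihoodMatrix,
    dosage: np.ndarray,
    chrom_arr: np.ndarray,
    pos_arr: np.ndarray,
    region: Region,
    alpha: float = 0.05,
    ld_ratio_min: float = 2.0,
    ld_n_sites: int = 5000,
    seed: int = 0,
) -> gt.HaploblockCall | None:
    """Genotype one candidate region and assemble its evidence."""
    in_region = (
        (chrom_arr == region.chrom)
        & (pos_arr - 1 >= region.start)
        & (pos_arr - 1 < region.end)
    )
    site_idx = np.flatnonzero(in_region)
    try:
        scores, _ = gt.region_pca(dosage, site_idx)
    except ValueError as exc:
        logger.info("region %s not genotyped: %s", region, exc)
        return None
    assignment = gt.assign_genotypes(scores, seed=seed)

    pooled = np.nanmean(dosage[:, site_idx], axis=0) / 2.0
    usable = ~np.isnan(pooled)
    het = popgen.sample_heterozygosity(glm, site_idx[usable], pooled[usable])
    het_p = gt.heterozygosity_test(het, assignment.labels)

    chrom_mask = chrom_arr == region.chrom
    ld = gt.ld_validate(
        dosage, pos_arr, region, assignment.labels, chrom_mask,
        n_sites=ld_n_sites, seed=seed,
    )
    return gt.call_haploblock(
        region, assignment, het_p, ld, alpha=alpha, ld_ratio_min=ld_ratio_min
    )


@dataclass
class SelectionScanResult:
    site_stats: pd.DataFrame
    window_table: scan.WindowScoreTable
    omega: scan.OmegaMatrix | np.ndarray


def selection_scan(
    freqs: popgen.AlleleFrequencyTable,
    contig_lengths: dict[str, int],
    env: pd.DataFrame | None = None,
    contrast_groups: tuple | None = None,
    window_width: int = 20_000,
    maf_min: float = 0.05,
    omega: scan.OmegaMatrix | np.ndarray | None = None,
    control_idx: np.ndarray | None = None,
    top: float = 0.01,
    ancestral: np.ndarray | None = None,
) -> SelectionScanResult:
    """Site statistics (XtX, optional contrast, |tau| per environment
    variable) -> empirical p -> WZA window scores -> top-1% outlier flags.

    ``env`` is a populations x variables table; ``contrast_groups`` is a pair
    of population index arrays; ``omega`` defaults to a moment estimate from
    ``control_idx`` (all sites if omitted).
    """
    p = freqs.freq
    w = freqs.n_chrom.astype(float)
    pibar = np.nansum(p * w, axis=0) / np.nansum(w, axis=0)
    maf = np.minimum(pibar, 1 - pibar)
    usable = ~np.isnan(p).any(axis=0) & (maf >= maf_min)
    if omega is None:
        omega = scan.estimate_omega(
            freqs, control_idx if control_idx is not None else np.flatnonzero(usable)
        )

    x = scan.standardize_frequencies(p, w, ancestral=ancestral)
    stats_by_key: dict[str, np.ndarray] = {}
    vals = np.full(p.shape[1], np.nan)
    vals[usable] = scan.xtx(x[:, usable], omega)
    stats_by_key["xtx"] = vals
    if contrast_groups is not None:
        vals = np.full(p.shape[1], np.nan)
        vals[usable] = scan.contrast_stat(
            x[:, usable], omega, contrast_groups[0], contrast_groups[1]
        )
        stats_by_key["contrast"] = vals
    env_keys: list[str] = []
    if env is not None:
        for col in env.columns:
            tau = np.full(p.shape[1], np.nan)
            tau[usable] = scan.env_association(p[:, usable], env[col].to_numpy())
            key = f"tau_{col}"
            stats_by_key[key] = tau
            env_keys.append(key)

    windows = make_windows(contig_lengths, window_width)
    wdf = pd.DataFrame(
        {
            "chrom": [w_.chrom for w_ in windows],
            "start": [w_.start for w_ in windows],
            "end": [w_.end for w_ in windows],
        }
    )
    window_of_site = np.full(p.shape[1], -1)
    for wi, idx in enumerate(assign_sites_to_windows(windows, freqs.sites)):
        window_of_site[idx] = wi
    weights = pibar * (1 - pibar)
    table = scan.score_windows(
        stats_by_key, weights, window_of_site, wdf, top=top, env_keys=tuple(env_keys)
    )
    site_df = pd.DataFrame({"chrom": freqs.sites["chrom"], "pos": freqs.sites["pos"]})
    for k, v in stats_by_key.items():
        site_df[k] = v
    return SelectionScanResult(site_df, table, omega)
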