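"""Readers, writers and the coordinate model shared by every scan.

Internal coordinates are 0-based half-open (BED convention); VCF and BEAGLE
positions are 1-based and converted at the boundary.  Genotype likelihoods are
normalized to probability triples at read time; the expected minor-allele
dosage is the working representation downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


class FormatError(ValueError):
    """A file does not follow its declared format."""


def _site_frame(chrom, pos, ref, alt) -> pd.DataFrame:
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
    df["pos"] = df["pos"].astype(np.int64)
    if (df["pos"] < 1).any():
        raise ValueError("site positions must be >= 1 (1-based)")
    return df


@dataclass
class GenotypeLikelihoodMatrix:
    """Per sample x site likelihoods of the three biallelic genotypes.

    ``gl`` has shape (n_samples, n_sites, 3) ordered (hom-major, het,
    hom-minor); non-missing triples sum to 1.  ``missing`` flags entries with
    no data (all-zero or malformed triples).
    """

    sites: pd.DataFrame
    samples: list[str]
    gl: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        n, s = len(self.samples), len(self.sites)
        if self.gl.shape != (n, s, 3):
            raise ValueError(f"gl shape {self.gl.shape} != ({n}, {s}, 3)")
        if self.missing.shape != (n, s):
            raise ValueError("missing mask shape mismatch")
        ok = ~self.missing
        if ok.any():
            sums = self.gl[ok].sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("non-missing GL triples must sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class DosageMatrix:
    """Expected minor-allele count per sample x site, NaN where missing."""

    sites: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError("dosage shape mismatch")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and (vals.min() < -1e-9 or vals.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.dosage)


@dataclass(frozen=True)
class GenomicWindow:
    """A half-open [start, end) tile of a contig."""

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")


@dataclass(frozen=True)
class Region:
    """A BED-style half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region end {self.end} <= start {self.start}")

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


# ---------------------------------------------------------------------------
# BEAGLE genotype-likelihood text format
# ---------------------------------------------------------------------------

def read_beagle_gl(path) -> GenotypeLikelihoodMatrix:
    """Read a BEAGLE-GL file (header ``marker allele1 allele2`` + 3 columns
    per sample).  Markers are ``chrom_pos``; triples are normalized to sum to
    1; malformed or all-zero triples become missing.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 3 or header[:3] != ["marker", "allele1", "allele2"]:
            raise FormatError(f"{path}: missing BEAGLE header 'marker allele1 allele2'")
        n_cols = len(header)
        if (n_cols - 3) % 3 != 0:
            raise FormatError(f"{path}: header implies a non-integer sample count")
        n_samples = (n_cols - 3) // 3
        samples = _beagle_sample_names(header[3:], n_samples)

        chroms, positions, refs, alts, rows = [], [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_cols} columns, found {len(parts)}"
                )
            marker = parts[0]
            chrom, _, pos = marker.rpartition("_")
            if not chrom:
                raise FormatError(f"{path}:{lineno}: marker {marker!r} is not chrom_pos")
            chroms.append(chrom)
            positions.append(int(pos))
            refs.append(parts[1])
            alts.append(parts[2])
            rows.append(parts[3:])

    raw = np.array(rows, dtype=float) if rows else np.empty((0, 3 * n_samples))
    gl = raw.reshape(len(rows), n_samples, 3).transpose(1, 0, 2).copy()
    bad = ~np.isfinite(gl).all(axis=-1) | (gl < 0).any(axis=-1)
    gl[bad] = 0.0
    sums = gl.sum(axis=-1)
    missing = bad | (sums <= 0)
    gl = np.divide(gl, np.where(sums > 0, sums, 1.0)[..., None])
    gl[missing] = 0.0
    sites = _site_frame(chroms, positions, refs, alts)
    return GenotypeLikelihoodMatrix(sites, samples, gl, missing)


def _beagle_sample_names(cols: list[str], n_samples: int) -> list[str]:
    names = cols[::3]
    if len(set(names)) == n_samples:
        return list(names)
    return [f"sample{i}" for i in range(n_samples)]


def write_beagle_gl(glm: GenotypeLikelihoodMatrix, path) -> None:
    with open(path, "w") as fh:
        cols = ["marker", "allele1", "allele2"]
        for s in glm.samples:
            cols += [s, s, s]
        fh.write("\t".join(cols) + "\n")
        gl = np.where(glm.missing[..., None], 0.0, glm.gl)
        for j, site in enumerate(glm.sites.itertuples(index=False)):
            row = [f"{site.chrom}_{site.pos}", site.ref, site.alt]
            row += [f"{v:.6f}" for v in gl[:, j, :].ravel()]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# VCF (consumption of hard genotypes only)
# ---------------------------------------------------------------------------

def read_vcf_genotypes(path) -> DosageMatrix:
    """Read GT fields of biallelic SNP records into a dosage matrix.

    Multiallelic records are skipped (count logged); ``./.`` becomes NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, positions, refs, alts, rows = [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gts = rec.genotype.array()[:, :2]
        dos = gts.sum(axis=1).astype(float)
        dos[(gts < 0).any(axis=1)] = np.nan
        rows.append(dos)
    if n_skipped:
        logger.info("read_vcf_genotypes: skipped %d non-biallelic records", n_skipped)
    if not rows:
        raise FormatError(f"{path}: no biallelic records")
    dosage = np.array(rows).T
    sites = _site_frame(chroms, positions, refs, alts)
    out = DosageMatrix(sites, samples, dosage)
    out.n_skipped = n_skipped
    return out


# ---------------------------------------------------------------------------
# GL -> dosage
# ---------------------------------------------------------------------------

def gl_to_dosage(glm: GenotypeLikelihoodMatrix, prior: str | np.ndarray = "uniform") -> DosageMatrix:
    """Posterior expected minor-allele dosage under a genotype prior.

    ``prior`` is ``"uniform"`` or a per-site minor-allele frequency vector,
    in which case the Hardy-Weinberg prior ((1-p)^2, 2p(1-p), p^2) is used.
    """
    if (glm.gl < 0).any():
        raise ValueError("negative genotype likelihoods")
    if isinstance(prior, str):
        if prior != "uniform":
            raise ValueError(f"unknown prior {prior!r}")
        w = np.ones((1, glm.n_sites, 3))
    else:
        p = np.asarray(prior, dtype=float)
        if p.shape != (glm.n_sites,):
            raise ValueError("HWE prior needs one frequency per site")
        w = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)[None, :, :]
    post = glm.gl * w
    tot = post.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dosage = (post[..., 1] + 2 * post[..., 2]) / tot
    dosage[glm.missing | (tot <= 0)] = np.nan
    return DosageMatrix(glm.sites, glm.samples, dosage)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def make_windows(contig_lengths: dict[str, int], width: int) -> list[GenomicWindow]:
    """Tile each contig with non-overlapping [k*width, (k+1)*width) windows,
    truncating the last at the contig end.  Indices restart per contig."""
    if width <= 0:
        raise ValueError("window width must be positive")
    windows: list[GenomicWindow] = []
    for chrom, length in contig_lengths.items():
        if length <= 0:
            logger.warning("contig %s has non-positive length; no windows", chrom)
            continue
        for idx, start in enumerate(range(0, length, width)):
            windows.append(GenomicWindow(chrom, start, min(start + width, length), idx))
    return windows


def assign_sites_to_windows(windows: list[GenomicWindow], sites: pd.DataFrame) -> list[np.ndarray]:
    """Column indices of ``sites`` falling in each window (pos-1 in [start, end))."""
    pos0 = sites["pos"].to_numpy() - 1
    chrom = sites["chrom"].to_numpy()
    out = []
    for w in windows:
        mask = (chrom == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
        out.append(np.flatnonzero(mask))
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[Region]:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            regions.append(Region(parts[0], start, end, parts[3] if len(parts) > 3 else ""))
    return regions


def write_bed(regions: list[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            cols = [r.chrom, str(r.start), str(r.end)]
            if r.name:
                cols.append(r.name)
            fh.write("\t".join(cols) + "\n")
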