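"""Synthetic population-genomic datasets with a planted inversion haploblock.

The generator emulates the sampling design of a multi-city, low-coverage
whole-genome study: structured populations under a Balding-Nichols island
model, an inversion-like haploblock whose arrangement frequency follows a
logistic cline along an environmental gradient, Poisson-depth / binomial-error
genotype likelihoods, and per-gene differential-expression result tables.
Every draw is reproducible from a single integer seed, and every dataset
ships with its truth set.

Model choices
-------------
* Population j's allele frequency at a neutral site is Beta-distributed
  around the ancestral frequency ``p`` with drift parameter ``F_j``
  (variance ``F_j p(1-p)``); ``F_j`` are spaced evenly in ``(0, F_max]``.
* The inversion carries two arrangements, A and B.  A fraction ``d`` of
  inversion sites are fixed differences between arrangements (the expected
  per-site arrangement frequency difference is therefore exactly ``d``);
  the remaining sites are shared polymorphism at the background frequency.
  There is no recombination between arrangements: within-arrangement
  haplotype draws are conditionally independent given the arrangement.
* Arrangement B frequency in population j is ``logistic(beta0 + beta1*env_j)``.
* Sequencing: read depth ~ Poisson(c); minor-allele reads ~ Binomial(depth,
  psi) with psi = (g/2)(1-eps) + (1-g/2)eps; genotype likelihoods are the
  binomial likelihoods of the observed read pair; depth 0 is missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeLikelihoodMatrix, Region, _site_frame


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1 - p))


@dataclass(frozen=True)
class InversionSpec:
    """A planted inversion: location, per-site arrangement divergence ``d``
    and the logistic cline of arrangement-B frequency on the environment."""

    chrom: str = "chr1"
    start: int = 2_000_000
    end: int = 3_000_000
    d: float = 0.3
    beta0: float = 0.0
    beta1: float = 1.3862943611198906  # 0.2 -> 0.8 over env in [-1, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("divergence d must lie in [0, 1]")
        if self.end <= self.start:
            raise ValueError("inversion end must exceed start")

    @property
    def region(self) -> Region:
        return Region(self.chrom, self.start, self.end, "inversion")


@dataclass(frozen=True)
class EnvClineSpec:
    """Sites in [start, end) get environment-driven clinal frequencies:
    freq_j = logistic(logit(p_anc) + beta1 * env_j)."""

    chrom: str
    start: int
    end: int
    beta1: float = 2.0


@dataclass
class SimulationConfig:
    """Study-design parameters of the default synthetic scenario:
    8 populations x 25 diploids, one 5-Mb contig of 5,000 sites in fifty
    100-kb windows, an inversion spanning windows 20-29 with d = 0.3 and an
    arrangement-frequency cline 0.2 -> 0.8, 4x mean coverage."""

    n_pops: int = 8
    n_samples_per_pop: int = 25
    contig_lengths: dict = field(default_factory=lambda: {"chr1": 5_000_000})
    n_sites: dict = field(default_factory=lambda: {"chr1": 5_000})
    window_width: int = 100_000
    f_max: float = 0.05
    inversion: InversionSpec | None = field(default_factory=InversionSpec)
    env_clines: tuple = ()
    env: np.ndarray | None = None
    coverage: float = 4.0
    error: float = 0.005
    sample_cov_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.f_max < 1.0:
            raise ValueError("F_max must lie in (0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.error < 0.5:
            raise ValueError("sequencing error must lie in [0, 0.5)")
        if self.env is None:
            self.env = np.linspace(-1.0, 1.0, self.n_pops)
        self.env = np.asarray(self.env, dtype=float)
        if self.env.shape != (self.n_pops,):
            raise ValueError("need one environment value per population")
        if self.inversion is not None:
            if self.inversion.chrom not in self.contig_lengths:
                raise ValueError("inversion contig not in contig_lengths")
            if self.inversion.end > self.contig_lengths[self.inversion.chrom]:
                raise ValueError("inversion interval exceeds its contig")

    @property
    def drift(self) -> np.ndarray:
        """Balding-Nichols F per population, spaced evenly in (0, F_max]."""
        return self.f_max * np.arange(1, self.n_pops + 1) / self.n_pops

    @property
    def populations(self) -> list[str]:
        return [f"pop{j}" for j in range(self.n_pops)]


def true_omega(drift: np.ndarray, n_chrom: int | None = None) -> np.ndarray:
    """Model covariance of standardized frequencies for independent
    Balding-Nichols populations: diag(F/(1-F)), plus 1/n_chrom binomial
    sampling variance when frequencies are estimated from n_chrom haploid
    draws.  The (1-F) factor reflects standardization by the expected
    within-population heterozygosity p(1-p)(1-F)."""
    drift = np.asarray(drift, dtype=float)
    diag = drift / (1.0 - drift)
    if n_chrom is not None:
        diag = diag + 1.0 / n_chrom
    return np.diag(diag)


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTruth:
    sites: pd.DataFrame
    ancestral: np.ndarray          # (S,)
    pop_freq: np.ndarray           # (J, S)
    drift: np.ndarray              # (J,)
    env: np.ndarray                # (J,)
    inversion_sites: np.ndarray    # bool (S,)
    diagnostic_sites: np.ndarray   # bool (S,)
    q_arr_a: np.ndarray            # (S,) arrangement-A allele freq (NaN off-inversion)
    q_arr_b: np.ndarray
    arrangement_freq: np.ndarray   # (J,) arrangement-B frequency per population


def _site_positions(config: SimulationConfig) -> pd.DataFrame:
    chroms, positions = [], []
    for chrom, length in config.contig_lengths.items():
        s = config.n_sites[chrom]
        step = length / s
        pos = np.floor((np.arange(s) + 0.5) * step).astype(np.int64) + 1
        chroms += [chrom] * s
        positions.append(pos)
    return _site_frame(chroms, np.concatenate(positions), "A", "C")


def simulate_frequencies(config: SimulationConfig, seed: int) -> FrequencyTruth:
    """Draw ancestral and per-population allele frequencies.

    Neutral sites: ancestral p ~ U(0.05, 0.95) and Balding-Nichols draws per
    population.  Inversion sites: a Bernoulli(d) subset become fixed
    arrangement differences (q_A, q_B) in {0,1} with random orientation;
    realized population frequency is (1-f_j) q_A + f_j q_B under the
    arrangement cline.  Env-cline sites follow a logistic frequency cline.
    """
    rng = np.random.default_rng(seed)
    sites = _site_positions(config)
    S = len(sites)
    F = config.drift
    anc = rng.uniform(0.05, 0.95, S)
    a = anc[None, :] * (1 - F)[:, None] / F[:, None]
    b = (1 - anc)[None, :] * (1 - F)[:, None] / F[:, None]
    pop_freq = rng.beta(a, b)

    inv_mask = np.zeros(S, dtype=bool)
    diag_mask = np.zeros(S, dtype=bool)
    q_a = np.full(S, np.nan)
    q_b = np.full(S, np.nan)
    f_arr = np.full(config.n_pops, np.nan)
    inv = config.inversion
    if inv is not None:
        pos0 = sites["pos"].to_numpy() - 1
        inv_mask = (
            (sites["chrom"].to_numpy() == inv.chrom)
            & (pos0 >= inv.start)
            & (pos0 < inv.end)
        )
        f_arr = _logistic(inv.beta0 + inv.beta1 * config.env)
        diag_mask = inv_mask & (rng.random(S) < inv.d)
        orient_b = rng.random(S) < 0.5
        q_a[inv_mask] = np.nan  # filled below
        # shared polymorphism: identical arrangement frequencies
        q_a[inv_mask] = anc[inv_mask]
        q_b[inv_mask] = anc[inv_mask]
        q_a[diag_mask] = np.where(orient_b[diag_mask], 0.0, 1.0)
        q_b[diag_mask] = np.where(orient_b[diag_mask], 1.0, 0.0)
        # realized per-population frequency at diagnostic sites
        pop_freq[:, diag_mask] = (
            (1 - f_arr)[:, None] * q_a[None, diag_mask]
            + f_arr[:, None] * q_b[None, diag_mask]
        )

    for cline in config.env_clines:
        pos0 = sites["pos"].to_numpy() - 1
        m = (
            (sites["chrom"].to_numpy() == cline.chrom)
            & (pos0 >= cline.start)
            & (pos0 < cline.end)
        )
        pop_freq[:, m] = _logistic(_logit(anc[m])[None, :] + cline.beta1 * config.env[:, None])

    return FrequencyTruth(
        sites, anc, pop_freq, F, config.env, inv_mask, diag_mask, q_a, q_b, f_arr
    )


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    sites: pd.DataFrame
    samples: list[str]
    populations: list[str]
    pop_of_sample: np.ndarray      # (N,) int
    genotypes: np.ndarray          # (N, S) minor-allele counts 0/1/2
    inversion_genotype: np.ndarray | None  # (N,) copies of arrangement B, or None
    region: Region | None
    env: np.ndarray
    freqs: FrequencyTruth

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_dir(self, path) -> None:
        """Serialize the truth set as plain-text BED/TSV/JSON."""
        import os

        os.makedirs(path, exist_ok=True)
        pops = pd.DataFrame(
            {
                "sample": self.samples,
                "population": [self.populations[j] for j in self.pop_of_sample],
                "env": self.env[self.pop_of_sample],
            }
        )
        if self.inversion_genotype is not None:
            pops["inversion_genotype"] = self.inversion_genotype
        pops.to_csv(os.path.join(path, "samples.tsv"), sep="\t", index=False)
        gt = pd.DataFrame(
            self.genotypes.T,
            columns=self.samples,
        )
        gt.insert(0, "chrom", self.sites["chrom"].to_numpy())
        gt.insert(1, "pos", self.sites["pos"].to_numpy())
        gt.to_csv(os.path.join(path, "genotypes.tsv"), sep="\t", index=False)
        meta = {
            "populations": self.populations,
            "env": list(map(float, self.env)),
        }
        if self.region is not None:
            from .io import write_bed

            write_bed([self.region], os.path.join(path, "truth_region.bed"))
            meta["region"] = [self.region.chrom, self.region.start, self.region.end]
        with open(os.path.join(path, "truth.json"), "w") as fh:
            json.dump(meta, fh, indent=1)


def simulate_samples(config: SimulationConfig, freqs: FrequencyTruth, seed: int) -> TruthSet:
    """Draw individual genotypes from the frequency truth.

    The inversion genotype (copies of arrangement B) is Binomial(2, f_j);
    fixed-difference sites are then determined by the arrangement count, and
    all other sites are Hardy-Weinberg draws at the population frequency.
    """
    rng = np.random.default_rng(seed)
    J, N = config.n_pops, config.n_pops * config.n_samples_per_pop
    pop_of_sample = np.repeat(np.arange(J), config.n_samples_per_pop)
    samples = [
        f"pop{j}_s{i}" for j in range(J) for i in range(config.n_samples_per_pop)
    ]
    G = rng.binomial(2, freqs.pop_freq[pop_of_sample, :])

    inv_gt = None
    region = None
    if config.inversion is not None:
        f = freqs.arrangement_freq[pop_of_sample]
        inv_gt = rng.binomial(2, f)
        diag = freqs.diagnostic_sites
        orient_b = freqs.q_arr_b[diag] == 1.0
        # fixed differences: allele count is the count of the carrying arrangement
        G[:, np.flatnonzero(diag)] = np.where(
            orient_b[None, :], inv_gt[:, None], 2 - inv_gt[:, None]
        )
        region = config.inversion.region

    return TruthSet(
        freqs.sites, samples, config.populations, pop_of_sample, G, inv_gt, region,
        config.env, freqs,
    )


# ---------------------------------------------------------------------------
# genotype likelihoods
# ---------------------------------------------------------------------------

def simulate_gls(
    truth: TruthSet, config: SimulationConfig, seed: int
) -> tuple[GenotypeLikelihoodMatrix, np.ndarray]:
    """Low-coverage sequencing: per sample x site read depths and genotype
    likelihoods.  Returns the GL matrix and the depth matrix."""
    rng = np.random.default_rng(seed)
    N, S = truth.genotypes.shape
    cov = np.full(N, config.coverage)
    if config.sample_cov_sigma > 0:
        sig = config.sample_cov_sigma
        cov = cov * rng.lognormal(-0.5 * sig**2, sig, N)
    depth = rng.poisson(cov[:, None], size=(N, S))
    eps = config.error
    psi_true = truth.genotypes / 2.0 * (1 - eps) + (1 - truth.genotypes / 2.0) * eps
    minor = rng.binomial(depth, psi_true)

    from scipy.special import xlogy

    psi_g = np.array([eps, 0.5, 1 - eps])
    ll = xlogy(minor[..., None], psi_g[None, None, :]) + xlogy(
        (depth - minor)[..., None], 1 - psi_g[None, None, :]
    )
    ll -= ll.max(axis=-1, keepdims=True)
    gl = np.exp(ll)
    gl /= gl.sum(axis=-1, keepdims=True)
    missing = depth == 0
    gl[missing] = 0.0
    glm = GenotypeLikelihoodMatrix(truth.sites, list(truth.samples), gl, missing)
    return glm, depth


def simulate_dataset(config: SimulationConfig, seed: int):
    """Convenience wrapper: frequencies -> samples -> GLs with sub-seeds
    derived from one master seed."""
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    freqs = simulate_frequencies(config, seeds[0])
    truth = simulate_samples(config, freqs, seeds[1])
    glm, depth = simulate_gls(truth, config, seeds[2])
    return truth, glm, depth


def write_dataset(config: SimulationConfig, seed: int, outdir) -> None:
    """Simulate and serialize a full dataset: BEAGLE-GL, depth table and the
    truth set (BED + TSV + JSON)."""
    import os

    from .io import write_beagle_gl

    truth, glm, depth = simulate_dataset(config, seed)
    os.makedirs(outdir, exist_ok=True)
    write_beagle_gl(glm, os.path.join(outdir, "genolike.beagle"))
    pd.DataFrame(
        {"sample": truth.samples, "mean_depth": depth.mean(axis=1)}
    ).to_csv(os.path.join(outdir, "depth.tsv"), sep="\t", index=False)
    truth.to_dir(outdir)


# ---------------------------------------------------------------------------
# gene expression results
# ---------------------------------------------------------------------------

def simulate_gene_table(
    contig_lengths: dict[str, int],
    n_genes: int,
    seed: int,
    de_region: Region | None = None,
    comparisons: tuple[str, ...] = ("treatment", "range", "latitude"),
    sigma0: float = 0.5,
    delta: float = 1.5,
) -> pd.DataFrame:
    """Per-gene differential-expression results table.

    Null genes: raw p ~ U(0,1), log2FC ~ N(0, sigma0).  Genes inside
    ``de_region`` are differentially expressed: raw p ~ Beta(0.1, 1) and
    |log2FC| inflated by ``delta``.  FDR is Benjamini-Hochberg within each
    comparison.  Genes are evenly spaced along each contig in genome order.
    """
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(seed)
    total_len = sum(contig_lengths.values())
    rows = []
    gid = 0
    for chrom, length in contig_lengths.items():
        k = max(1, round(n_genes * length / total_len))
        mids = np.floor((np.arange(k) + 0.5) * length / k).astype(int)
        for m in mids:
            rows.append((f"gene{gid:05d}", chrom, int(m)))
            gid += 1
    df = pd.DataFrame(rows, columns=["gene", "chrom", "midpoint"])
    is_de = np.zeros(len(df), dtype=bool)
    if de_region is not None:
        is_de = (
            (df["chrom"] == de_region.chrom)
            & (df["midpoint"] >= de_region.start)
            & (df["midpoint"] < de_region.end)
        ).to_numpy()
    for comp in comparisons:
        p = rng.uniform(0, 1, len(df))
        p[is_de] = rng.beta(0.1, 1.0, is_de.sum())
        lfc = rng.normal(0, sigma0, len(df))
        lfc[is_de] += np.sign(rng.standard_normal(is_de.sum()) + 1e-12) * delta
        fdr = multipletests(p, method="fdr_bh")[1]
        df[f"log2FC_{comp}"] = lfc
        df[f"pvalue_{comp}"] = p
        df[f"fdr_{comp}"] = fdr
    return df


# ---------------------------------------------------------------------------
# common-garden fitness
# ---------------------------------------------------------------------------

def simulate_fitness(
    genotypes: np.ndarray,
    gardens: list[str],
    seed_mass_mean: dict,
    survival_prob: dict,
    seed: int,
    sigma: float = 0.3,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Common-garden fitness table: survival ~ Bernoulli and seed mass ~
    lognormal around the genotype x garden mean (mean-preserving).

    ``genotypes`` are haploblock genotype labels per sample ('aa'/'ab'/'bb');
    ``seed_mass_mean[(garden, genotype)]`` and ``survival_prob[(garden,
    genotype)]`` supply the effects.
    """
    rng = np.random.default_rng(seed)
    genotypes = np.asarray(genotypes)
    if samples is None:
        samples = [f"s{i}" for i in range(len(genotypes))]
    rows = []
    for garden in gardens:
        for s, g in zip(samples, genotypes):
            mu = seed_mass_mean[(garden, g)]
            p = survival_prob[(garden, g)]
            surv = int(rng.random() < p)
            mass = rng.lognormal(np.log(mu) - 0.5 * sigma**2, sigma) if mu > 0 else 0.0
            rows.append((s, garden, g, surv, mass))
    return pd.DataFrame(
        rows, columns=["sample", "garden", "genotype", "survival", "seed_mass"]
    )
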