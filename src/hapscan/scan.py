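"""Covariance-corrected selection and environment-association scans.

Per-site statistics on standardized population allele frequencies:

* ``XtX = x' Omega^-1 x`` — an FST-like differentiation statistic whitened by
  the population covariance Omega, approximately chi-square with n_pops
  degrees of freedom under neutrality when the true Omega is supplied;
* the contrast statistic ``C2 = (e'x)^2 / (e' Omega e)`` between two
  predefined population groups, approximately chi-square(1);
* ``|Kendall tau_b|`` between population frequencies and each environment
  variable.

Site statistics are converted to upper-tail empirical p-values, aggregated
into window scores with the weighted-Z analysis (WZA, weights q(1-q)), and
thresholded at the top 1% of windows.  These are deterministic moment
analogues of the corresponding Bayesian scan statistics; exact numerical
parity with MCMC implementations is not claimed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import AlleleFrequencyTable

logger = logging.getLogger(__name__)


@dataclass
class OmegaMatrix:
    populations: list[str]
    omega: np.ndarray
    shrinkage: float
    n_control_sites: int

    def __post_init__(self) -> None:
        if not np.allclose(self.omega, self.omega.T):
            raise ValueError("omega must be symmetric")
        eig = np.linalg.eigvalsh(self.omega)
        if eig.min() <= 1e-12 * max(1.0, eig.max()):
            raise ValueError(
                "omega is singular after shrinkage; increase the shrinkage lambda"
            )

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.omega)


def standardize_frequencies(
    freq: np.ndarray, n_chrom: np.ndarray | None = None, ancestral: np.ndarray | None = None
) -> np.ndarray:
    """Standardized frequency vectors x = (p - pi) / sqrt(pi (1 - pi)).

    ``pi`` is the supplied ancestral frequency when available, otherwise the
    sample-size-weighted mean across populations.  Returns (J, S).
    """
    freq = np.asarray(freq, dtype=float)
    if ancestral is not None:
        pi = np.asarray(ancestral, dtype=float)
    elif n_chrom is not None:
        w = np.asarray(n_chrom, dtype=float)
        pi = np.nansum(freq * w, axis=0) / np.nansum(w, axis=0)
    else:
        pi = np.nanmean(freq, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = (freq - pi) / np.sqrt(pi * (1 - pi))
    return x


def estimate_omega(
    freqs: AlleleFrequencyTable,
    control_idx: np.ndarray,
    shrinkage: float = 0.05,
    min_control: int = 100,
) -> OmegaMatrix:
    """Moment estimate of the population covariance of standardized
    frequencies from putatively neutral control sites.

    Control sites must have weighted mean frequency strictly inside
    (0.05, 0.95); Omega-hat = (1/L) sum x x' is shrunk toward its diagonal:
    (1 - lambda) Omega-hat + lambda diag(Omega-hat).
    """
    control_idx = np.asarray(control_idx)
    w = freqs.n_chrom[:, control_idx].astype(float)
    p = freqs.freq[:, control_idx]
    pibar = np.nansum(p * w, axis=0) / np.nansum(w, axis=0)
    ok = (pibar > 0.05) & (pibar < 0.95) & ~np.isnan(p).any(axis=0)
    if ok.sum() < min_control:
        raise ValueError(
            f"only {ok.sum()} usable control sites; need >= {min_control}"
        )
    x = standardize_frequencies(p[:, ok], w[:, ok])
    omega = x @ x.T / ok.sum()
    shrunk = (1 - shrinkage) * omega + shrinkage * np.diag(np.diag(omega))
    return OmegaMatrix(list(freqs.populations), shrunk, shrinkage, int(ok.sum()))


def xtx(x: np.ndarray, omega: OmegaMatrix | np.ndarray) -> np.ndarray:
    """XtX = x' Omega^-1 x per site; x is (J,) or (J, S)."""
    om = omega.omega if isinstance(omega, OmegaMatrix) else np.asarray(omega)
    x = np.asarray(x, dtype=float)
    vec = x.ndim == 1
    x2 = x[:, None] if vec else x
    if x2.shape[0] != om.shape[0]:
        raise ValueError("dimension mismatch between x and omega")
    oi = np.linalg.inv(om)
    out = np.einsum("js,jk,ks->s", x2, oi, x2)
    return float(out[0]) if vec else out


def contrast_stat(
    x: np.ndarray, omega: OmegaMatrix | np.ndarray, group_a: np.ndarray, group_b: np.ndarray
) -> np.ndarray:
    """Contrast statistic C2 between two population groups.

    e has 1/|A| on group A and -1/|B| on group B; C2 = (e'x)^2 / (e'Omega e).
    """
    om = omega.omega if isinstance(omega, OmegaMatrix) else np.asarray(omega)
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("both contrast groups must be non-empty")
    e = np.zeros(om.shape[0])
    e[group_a] = 1.0 / group_a.size
    e[group_b] = -1.0 / group_b.size
    x = np.asarray(x, dtype=float)
    num = (e @ x) ** 2
    den = e @ om @ e
    return num / den


def env_association(freq: np.ndarray, env: np.ndarray) -> np.ndarray:
    """|Kendall tau_b| between population allele frequencies and an
    environment vector, per site; NaN where the frequency is constant.

    Vectorized tie-corrected tau over sites (pairs of populations are
    enumerated once); matches scipy.stats.kendalltau.
    """
    freq = np.asarray(freq, dtype=float)   # (J, S)
    env = np.asarray(env, dtype=float)
    J, S = freq.shape
    if J < 4:
        raise ValueError("environment association needs >= 4 populations")
    ii, jj = np.triu_indices(J, k=1)
    df = freq[ii, :] - freq[jj, :]          # (P, S)
    de = (env[ii] - env[jj])[:, None]       # (P, 1)
    sf = np.sign(df)
    se = np.sign(de)
    concord = (sf * se).sum(axis=0)
    tf = (sf == 0).sum(axis=0)              # ties in frequency, per site
    te = int((se == 0).sum())               # ties in environment
    n_pairs = ii.size
    denom = np.sqrt((n_pairs - tf) * (n_pairs - te))
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = concord / denom
    tau[denom == 0] = np.nan
    return np.abs(tau)


def empirical_pvalues(values: np.ndarray) -> np.ndarray:
    """One-sided upper-tail empirical p: rank-from-top / (n + 1) with
    average ranks for ties; NaN inputs give NaN."""
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        raise ValueError("empirical p-values need >= 2 non-missing values")
    out = np.full(v.shape, np.nan)
    ranks = stats.rankdata(v[ok], method="average")
    n = ok.sum()
    out[ok] = (n + 1 - ranks) / (n + 1)
    return out


def wza(
    pvalues: np.ndarray,
    weights: np.ndarray,
    window_of_site: np.ndarray,
    n_windows: int,
) -> np.ndarray:
    """Weighted-Z window scores: Z_W = sum(w z) / sqrt(sum w^2) with
    z = Phi^-1(1 - p) and p clamped to [1/(2n), 1 - 1/(2n)] over the total
    site count.  Windows without a usable site get NaN."""
    p = np.asarray(pvalues, dtype=float)
    w = np.asarray(weights, dtype=float)
    wos = np.asarray(window_of_site)
    ok = ~np.isnan(p) & ~np.isnan(w) & (wos >= 0)
    n_tot = int(ok.sum())
    if n_tot == 0:
        return np.full(n_windows, np.nan)
    lo = 1.0 / (2 * n_tot)
    z = stats.norm.ppf(1 - np.clip(p[ok], lo, 1 - lo))
    wz = np.bincount(wos[ok], weights=w[ok] * z, minlength=n_windows)
    w2 = np.bincount(wos[ok], weights=w[ok] ** 2, minlength=n_windows)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = wz / np.sqrt(w2)
    out[w2 == 0] = np.nan
    return out


def call_outlier_windows(scores: np.ndarray, top: float = 0.01) -> np.ndarray:
    """Flag the top ``ceil(top * n)`` windows by score; boundary ties are all
    included (inclusive rule).  NaN scores are never flagged."""
    s = np.asarray(scores, dtype=float)
    ok = ~np.isnan(s)
    n = int(ok.sum())
    if n == 0:
        return np.zeros(s.shape, dtype=bool)
    if n < 100:
        logger.warning("only %d scored windows; 1%% tail is a single window", n)
    m = int(np.ceil(top * n))
    thr = np.sort(s[ok])[::-1][m - 1]
    return ok & (s >= thr)


@dataclass
class WindowScoreTable:
    """Per-window WZA scores, empirical p-values and outlier flags for each
    statistic, plus the combined XtX-EAA flag (XtX outlier AND outlier for at
    least one environment variable)."""

    windows: pd.DataFrame
    scores: dict
    empirical_p: dict
    outlier: dict
    xtx_eaa: np.ndarray | None = None


def score_windows(
    site_stats: dict,
    weights: np.ndarray,
    window_of_site: np.ndarray,
    windows: pd.DataFrame,
    top: float = 0.01,
    env_keys: tuple = (),
) -> WindowScoreTable:
    """Empirical p per site -> WZA per window -> top-1% flags, for every
    statistic in ``site_stats``; adds the XtX-EAA flag when 'xtx' and
    environment statistics are present."""
    n_windows = len(windows)
    scores, emp, out = {}, {}, {}
    for key, vals in site_stats.items():
        p_site = empirical_pvalues(vals)
        zw = wza(p_site, weights, window_of_site, n_windows)
        scores[key] = zw
        emp[key] = empirical_pvalues(zw)
        out[key] = call_outlier_windows(zw, top)
    table = WindowScoreTable(windows, scores, emp, out)
    if "xtx" in out and env_keys:
        env_any = np.zeros(n_windows, dtype=bool)
        for k in env_keys:
            env_any |= out[k]
        table.xtx_eaa = out["xtx"] & env_any
    return table
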