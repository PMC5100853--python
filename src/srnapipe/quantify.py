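"""Normalization and differential expression for small-RNA count matrices.

RPM conversion, expression filtering (RPM > 1 in >= 6 of 18 libraries),
trimmed-mean-of-M-values (TMM) normalization, and a negative-binomial
log-linear likelihood-ratio test across a genotype x timepoint design with
Benjamini-Hochberg FDR.

The GLM route fits grouped-means models (one mean per genotype x timepoint
cell, with log library-size offsets), which is the full-rank factorial
parameterization; the reduced model for a contrast merges the two groups
being compared. Dispersions are estimated on a shared grid by adjusted
profile likelihood: a common value across features plus per-feature
empirical-Bayes shrinkage toward it.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

DESIGN_COLUMNS = ("genotype", "timepoint", "replicate")


@dataclass
class CountMatrix:
    """Features x libraries weighted counts with design metadata."""

    counts: pd.DataFrame
    design: pd.DataFrame  # indexed by library id; genotype/timepoint/replicate
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValueError(f"design lacks columns {missing}")
        if list(self.counts.columns) != list(self.design.index):
            self.design = self.design.loc[self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.library_sizes = self.library_sizes.loc[self.counts.columns].astype(float)


def rpm(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Reads per million: count / library_size x 1e6."""
    sizes = library_sizes.loc[counts.columns].astype(float)
    if (sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    return counts / sizes * 1e6


def filter_expressed(
    rpm_matrix: pd.DataFrame, min_rpm: float = 1.0, min_libraries: int = 6
) -> pd.Index:
    """Features with RPM strictly greater than ``min_rpm`` in >= ``min_libraries``."""
    keep = (rpm_matrix > min_rpm).sum(axis=1) >= min_libraries
    return rpm_matrix.index[keep]


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def tmm_factors(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Per-library TMM normalization factors, rescaled to geometric mean 1.

    The reference library is the one whose 75th percentile of scaled counts
    is closest to the mean of those percentiles. For each library, M-values
    (log2 relative abundance ratios vs the reference) are doubly trimmed
    (30% on M, 5% on A) and averaged with inverse asymptotic-variance
    weights; features with a zero in either library of a pair are excluded.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("TMM requires >= 2 libraries")
    lib = (
        library_sizes.loc[counts.columns].to_numpy(dtype=float)
        if library_sizes is not None
        else mat.sum(axis=0)
    )
    if (mat.sum(axis=0) == 0).any():
        raise ValueError("library with all-zero counts")
    q75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [
            _tmm_pair(mat[:, j], mat[:, ref], lib[j], lib[ref], logratio_trim, sum_trim)
            for j in range(mat.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    mask = (obs > 0) & (ref > 0)
    obs, ref = obs[mask], ref[mask]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    keep &= np.isfinite(m) & np.isfinite(a) & (w > 0)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f) or abs(f) < 1e-6:
        f = 0.0
    return float(2.0**f)


# ---------------------------------------------------------------------------
# NB grouped-means GLM
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha) -> np.ndarray:
    """Row-wise NB2 log-likelihood. alpha is scalar or (F, 1)."""
    alpha = np.maximum(alpha, 1e-8)
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-10)
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=1)


def _fit_nb_groups(
    y: np.ndarray,
    offsets: np.ndarray,
    groups: np.ndarray,
    alpha,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> dict:
    """Vectorized Newton fit of per-group NB means with offsets.

    y (F, n); offsets (n,); groups (n,) integer codes 0..G-1; alpha scalar
    or (F, 1). Returns betas (natural log), fitted mu, log-likelihoods,
    Cox-Reid adjustment terms, and a convergence flag per feature.
    """
    y = np.asarray(y, dtype=float)
    n_feat, n_obs = y.shape
    n_groups = int(groups.max()) + 1
    onehot = np.zeros((n_obs, n_groups))
    onehot[np.arange(n_obs), groups] = 1.0
    exp_off = np.exp(offsets)
    denom0 = exp_off @ onehot  # (G,)
    beta = np.log((y @ onehot + 0.125) / denom0)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim == 1:
        alpha = alpha[:, None]
    for _ in range(max_iter):
        mu = np.exp(beta[:, groups] + offsets)
        v = 1.0 + alpha * mu
        score = ((y - mu) / v) @ onehot
        info = (mu / v) @ onehot
        step = score / np.maximum(info, 1e-12)
        np.clip(step, -5.0, 5.0, out=step)
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    mu = np.exp(beta[:, groups] + offsets)
    v = 1.0 + alpha * mu
    score = ((y - mu) / v) @ onehot
    info = (mu / v) @ onehot  # diagonal of X'WX for one-hot designs
    ll = _nb_loglik(y, mu, alpha)
    cr = 0.5 * np.log(np.maximum(info, 1e-12)).sum(axis=1)
    # converged when the score has vanished; a group whose counts are all
    # zero has its MLE at mean -> 0 and a vanishing score, which is fine
    converged = np.abs(score).max(axis=1) < 1e-4 * (1.0 + y.sum(axis=1))
    return {"beta": beta, "mu": mu, "ll": ll, "cr": cr, "converged": converged}


def estimate_dispersions(
    y: np.ndarray,
    offsets: np.ndarray,
    groups: np.ndarray,
    grid: np.ndarray | None = None,
    prior_df: float = 10.0,
) -> tuple[float, np.ndarray]:
    """Common and per-feature shrunk dispersions by adjusted profile likelihood.

    Each grid dispersion is fit to every feature; the common value
    maximizes the summed Cox-Reid adjusted profile likelihood (APL), and
    per-feature values maximize APL_f + prior_weight x mean APL, shrinking
    toward the common value with weight prior_df / residual_df.
    """
    if grid is None:
        grid = np.logspace(-4, 0.7, 25)
    n_feat, n_obs = y.shape
    n_groups = int(groups.max()) + 1
    apl = np.empty((n_feat, grid.size))
    for j, alpha in enumerate(grid):
        fit = _fit_nb_groups(y, offsets, groups, alpha)
        apl[:, j] = fit["ll"] - fit["cr"]
    common_curve = apl.sum(axis=0)
    common = _argmax_interp(grid, common_curve)
    df_resid = max(n_obs - n_groups, 1)
    prior_n = prior_df / df_resid
    scores = apl + prior_n * apl.mean(axis=0)
    per_feature = np.array([_argmax_interp(grid, scores[i]) for i in range(n_feat)])
    return common, per_feature


def _argmax_interp(grid: np.ndarray, curve: np.ndarray) -> float:
    """Grid argmax with parabolic refinement in log-dispersion space."""
    j = int(np.argmax(curve))
    if j == 0 or j == grid.size - 1:
        return float(grid[j])
    x = np.log(grid[j - 1 : j + 2])
    f = curve[j - 1 : j + 2]
    denom = (f[0] - 2 * f[1] + f[2])
    if denom >= 0:
        return float(grid[j])
    shift = 0.5 * (f[0] - f[2]) / denom
    shift = np.clip(shift, -1.0, 1.0)
    return float(np.exp(x[1] + shift * (x[1] - x[0])))


def nb_glm_lrt(
    cm: CountMatrix,
    timepoint: str,
    norm_factors: pd.Series | None = None,
    use_tmm: bool = True,
    dispersion: float | np.ndarray | None = None,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Likelihood-ratio test for genotype effect (mut vs wt) at one timepoint.

    The full model fits one mean per genotype x timepoint group with
    offsets log(library_size x TMM factor); the reduced model merges the
    mutant and wild-type groups at ``timepoint``. LRT statistics are
    referred to chi-squared with 1 df; FDR is Benjamini-Hochberg.
    log2 fold-changes are mutant over wild type.
    """
    counts = cm.counts
    design = cm.design
    if timepoint not in set(design["timepoint"]):
        raise ValueError(f"timepoint {timepoint!r} absent from design")
    if norm_factors is None:
        norm_factors = (
            tmm_factors(counts, cm.library_sizes)
            if use_tmm
            else pd.Series(1.0, index=counts.columns)
        )
    offsets = np.log(cm.library_sizes.to_numpy() * norm_factors.loc[counts.columns].to_numpy())

    cells = design["genotype"].astype(str) + "." + design["timepoint"].astype(str)
    full_levels = sorted(cells.unique())
    if len(full_levels) < 2:
        raise ValueError("design must contain >= 2 genotype x timepoint groups")
    full_codes = np.array([full_levels.index(c) for c in cells])
    merged = cells.replace(
        {f"wt.{timepoint}": f"both.{timepoint}", f"mut.{timepoint}": f"both.{timepoint}"}
    )
    red_levels = sorted(merged.unique())
    if len(red_levels) != len(full_levels) - 1:
        raise ValueError(f"contrast needs both genotypes at {timepoint!r}")
    red_codes = np.array([red_levels.index(c) for c in merged])

    y = counts.to_numpy(dtype=float)
    if dispersion is None:
        _, disp = estimate_dispersions(y, offsets, full_codes, prior_df=prior_df)
    else:
        disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (y.shape[0],)).copy()

    alpha_col = disp[:, None]
    full = _fit_nb_groups(y, offsets, full_codes, alpha_col)
    reduced = _fit_nb_groups(y, offsets, red_codes, alpha_col)

    lrt = np.maximum(2.0 * (full["ll"] - reduced["ll"]), 0.0)
    pvals = chi2.sf(lrt, df=1)
    ok = full["converged"] & reduced["converged"]
    pvals = np.where(ok, pvals, np.nan)

    i_mut = full_levels.index(f"mut.{timepoint}")
    i_wt = full_levels.index(f"wt.{timepoint}")
    logfc = (full["beta"][:, i_mut] - full["beta"][:, i_wt]) / np.log(2.0)

    out = pd.DataFrame(
        {
            "logFC": logfc,
            "LRT": lrt,
            "pvalue": pvals,
            "dispersion": disp,
            "converged": ok,
        },
        index=counts.index,
    )
    out["FDR"] = bh_fdr(out["pvalue"].to_numpy())
    return out


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        if ((p[mask] < 0) | (p[mask] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
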