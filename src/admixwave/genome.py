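"""Genome-wide wavelet variance and correlation decompositions.

Chromosomes are transformed separately and combined by chromosome-length
weighted averaging.  Because chromosomes differ in length, the broadest
scales exist only on the longest chromosomes; raw per-scale magnitudes are
averaged over the chromosomes where a scale exists, while proportions of
total genomic variance assign zero to chromosomes lacking a scale so that
the full decomposition -- wavelet scales, leftover scaling variance, and an
among-chromosome component (the weighted variance of chromosome means,
labelled ``chrom``) -- accounts for all of the genome-wide variance.

The genome-wide correlation between two signals decomposes the same way:
Cor(x, y) = sum_lambda c_lambda * rho_lambda(x, y) + scaling + chrom terms,
where rho_lambda is computed from coefficients pooled across chromosomes
and the weight c_lambda is the geometric mean of the two signals'
proportions of variance at scale lambda.  With biased (all-coefficient)
estimators the reconstruction of the direct Pearson correlation is exact.

Uncertainty is quantified by a weighted delete-one-chromosome jackknife
(Busing et al. 1999), with chromosome length as the block weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .modwt import (
    Estimator,
    modwt_haar,
    scaling_covariance,
    wavelet_covariance,
    wavelet_variance,
)
from .signal_prep import GridSignal

__all__ = [
    "GenomeDecomposition",
    "gnom_var_decomp",
    "gnom_cor_decomp",
    "variance_explained_by_predictor",
    "jackknife_ci",
    "weighted_jackknife",
    "JackknifeCI",
]

MIN_JACKKNIFE_BLOCKS = 3


@dataclass
class GenomeDecomposition:
    """Genome-wide per-scale statistic table.

    ``table`` has one row per wavelet scale plus ``chrom`` (among-chromosome)
    and ``scaling`` rows, with columns: scale, scale_map, level, statistic,
    value, contribution, n_chrom, ci_lo, ci_hi.  ``total`` is the directly
    assembled genome-wide variance (or correlation) that the contributions
    sum to.
    """

    table: pd.DataFrame
    total: float
    statistic: str
    estimator: str
    resolution: float
    weighting: str = "chromosome_length"

    def contributions_sum(self) -> float:
        return float(np.nansum(self.table["contribution"].to_numpy()))


class JackknifeCI(NamedTuple):
    point: float
    se: float
    lo: float
    hi: float


def weighted_jackknife(
    theta_full: float,
    theta_loo: np.ndarray,
    weights: np.ndarray,
    level: float = 0.95,
    use_t: bool = False,
) -> JackknifeCI:
    """Delete-one-block jackknife with unequal block weights.

    ``theta_loo[j]`` is the statistic recomputed with block j removed and
    ``weights[j]`` the block's size (here, chromosome length).  Uses the
    unequal-size pseudovalue formulation, which reduces to the ordinary
    delete-one jackknife for equal weights.  The interval is centred on the
    full-data point estimate.
    """
    theta_loo = np.asarray(theta_loo, dtype=float)
    weights = np.asarray(weights, dtype=float)
    g = len(theta_loo)
    if g < MIN_JACKKNIFE_BLOCKS:
        raise ValueError(f"need >= {MIN_JACKKNIFE_BLOCKS} blocks for a jackknife CI")
    if np.any(weights <= 0):
        raise ValueError("block weights must be positive")
    n = weights.sum()
    h = n / weights
    theta_j = g * theta_full - np.sum((1.0 - weights / n) * theta_loo)
    pseudo = h * theta_full - (h - 1.0) * theta_loo
    var = np.sum((pseudo - theta_j) ** 2 / (h - 1.0)) / g
    se = float(np.sqrt(var))
    if use_t:
        q = stats.t.ppf(0.5 + level / 2.0, df=g - 1)
    else:
        q = stats.norm.ppf(0.5 + level / 2.0)
    return JackknifeCI(float(theta_full), se, float(theta_full - q * se), float(theta_full + q * se))


def jackknife_ci(
    per_chromosome_statistics: Sequence[float],
    weights: Sequence[float],
    level: float = 0.95,
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
    use_t: bool = False,
) -> JackknifeCI:
    """Weighted jackknife CI for a genome-wide statistic over chromosomes.

    By default the genome-wide statistic is the weighted mean of the
    per-chromosome values; pass ``statistic(values, weights)`` to jackknife
    any other combination rule.
    """
    values = np.asarray(per_chromosome_statistics, dtype=float)
    w = np.asarray(weights, dtype=float)
    if statistic is None:
        statistic = lambda v, ww: float(np.average(v, weights=ww))
    full = statistic(values, w)
    keep = np.ones(len(values), dtype=bool)
    loo = np.empty(len(values))
    for i in range(len(values)):
        keep[i] = False
        loo[i] = statistic(values[keep], w[keep])
        keep[i] = True
    return weighted_jackknife(full, loo, w, level=level, use_t=use_t)


# ---------------------------------------------------------------------------
# per-chromosome ingredients


@dataclass
class _ChromStats:
    """Per-chromosome quantities entering the genome-wide assembly."""

    chroms: list[str]
    lengths: np.ndarray  # grid points per chromosome
    n_levels: np.ndarray  # J_c
    var_x: np.ndarray  # (C, Jmax), NaN where absent
    scal_var_x: np.ndarray
    mean_x: np.ndarray
    var_y: np.ndarray | None = None
    cov: np.ndarray | None = None
    scal_var_y: np.ndarray | None = None
    scal_cov: np.ndarray | None = None
    mean_y: np.ndarray | None = None

    @property
    def j_max(self) -> int:
        return self.var_x.shape[1]

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.var_x)


def _check_common_resolution(signals: dict[str, GridSignal]) -> tuple[float, str]:
    resolutions = {s.resolution for s in signals.values()}
    kinds = {s.map_kind for s in signals.values()}
    if len(resolutions) != 1:
        raise ValueError(f"inconsistent grid resolutions: {sorted(resolutions)}")
    if len(kinds) != 1:
        raise ValueError(f"inconsistent map kinds: {sorted(kinds)}")
    return resolutions.pop(), kinds.pop()


def _collect(
    xs: dict[str, GridSignal],
    ys: dict[str, GridSignal] | None,
    estimator: Estimator,
    max_level: int | None,
) -> _ChromStats:
    chroms = list(xs)
    if ys is not None and set(ys) != set(xs):
        raise ValueError("the two signal sets cover different chromosomes")
    per_var_x, per_var_y, per_cov = [], [], []
    scal_x, scal_y, scal_c = [], [], []
    mean_x, mean_y = [], []
    lengths, n_levels = [], []
    for chrom in chroms:
        sx = xs[chrom]
        dx = modwt_haar(sx, max_level=max_level)
        spec_x = wavelet_variance(dx, estimator)
        lengths.append(len(sx))
        n_levels.append(dx.n_levels)
        per_var_x.append(spec_x.variances)
        scal_x.append(spec_x.scaling_variance)
        mean_x.append(np.mean(sx.values))
        if ys is not None:
            sy = ys[chrom]
            if len(sy) != len(sx):
                raise ValueError(f"signal length mismatch on {chrom!r}")
            dy = modwt_haar(sy, max_level=max_level)
            spec_y = wavelet_variance(dy, estimator)
            per_var_y.append(spec_y.variances)
            per_cov.append(wavelet_covariance(dx, dy, estimator))
            scal_y.append(spec_y.scaling_variance)
            scal_c.append(scaling_covariance(dx, dy))
            mean_y.append(np.mean(sy.values))
    j_max = max(n_levels)

    def pad(rows: list[np.ndarray]) -> np.ndarray:
        out = np.full((len(rows), j_max), np.nan)
        for i, r in enumerate(rows):
            out[i, : len(r)] = r
        return out

    return _ChromStats(
        chroms=chroms,
        lengths=np.asarray(lengths, dtype=float),
        n_levels=np.asarray(n_levels),
        var_x=pad(per_var_x),
        scal_var_x=np.asarray(scal_x),
        mean_x=np.asarray(mean_x),
        var_y=pad(per_var_y) if ys is not None else None,
        cov=pad(per_cov) if ys is not None else None,
        scal_var_y=np.asarray(scal_y) if ys is not None else None,
        scal_cov=np.asarray(scal_c) if ys is not None else None,
        mean_y=np.asarray(mean_y) if ys is not None else None,
    )


def _weighted_mean_zero(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Length-weighted mean over chromosomes, absent scales counted as zero."""
    filled = np.nan_to_num(values, nan=0.0)
    return weights @ filled / weights.sum()


def _weighted_var_of_means(means: np.ndarray, weights: np.ndarray) -> float:
    w = weights / weights.sum()
    grand = float(w @ means)
    return float(w @ (means - grand) ** 2)


def _weighted_cov_of_means(mx: np.ndarray, my: np.ndarray, weights: np.ndarray) -> float:
    w = weights / weights.sum()
    return float(w @ ((mx - w @ mx) * (my - w @ my)))


# ---------------------------------------------------------------------------
# variance decomposition


def gnom_var_decomp(
    signals: dict[str, GridSignal],
    estimator: Estimator = "unbiased",
    max_level: int | None = None,
    jackknife_level: float = 0.95,
    jackknife_t: bool = False,
) -> GenomeDecomposition:
    """Genome-wide wavelet variance decomposition of a signal.

    Returns per-scale rows carrying both the raw magnitude (length-weighted
    mean over chromosomes where the scale exists) and the contribution to
    total genomic variance (zero assigned to chromosomes lacking the
    scale), plus ``chrom`` and ``scaling`` component rows.  Contributions
    sum to one exactly.
    """
    if not signals:
        raise ValueError("no chromosomes supplied")
    resolution, map_kind = _check_common_resolution(signals)
    st = _collect(signals, None, estimator, max_level)
    w = st.lengths

    zero_mean = _weighted_mean_zero(st.var_x, w)  # per level
    among = _weighted_var_of_means(st.mean_x, w)
    scal = float(np.average(st.scal_var_x, weights=w))
    total = float(zero_mean.sum() + among + scal)

    rows = []
    for j in range(st.j_max):
        present = st.present[:, j]
        vals = st.var_x[present, j]
        wj = w[present]
        raw = float(np.average(vals, weights=wj))
        ci = (np.nan, np.nan)
        if present.sum() >= MIN_JACKKNIFE_BLOCKS:
            jk = jackknife_ci(vals, wj, level=jackknife_level, use_t=jackknife_t)
            ci = (jk.lo, jk.hi)
        rows.append(
            {
                "scale": 2.0 ** (j + 1),
                "scale_map": 2.0 ** (j + 1) * resolution,
                "level": j + 1,
                "statistic": "variance",
                "value": raw,
                "contribution": zero_mean[j] / total if total > 0 else np.nan,
                "n_chrom": int(present.sum()),
                "ci_lo": ci[0],
                "ci_hi": ci[1],
            }
        )
    n_chrom = len(st.chroms)
    for label, value in (("chrom", among), ("scaling", scal)):
        ci = (np.nan, np.nan)
        if n_chrom >= MIN_JACKKNIFE_BLOCKS:
            if label == "chrom":
                loo_stat = lambda m, ww: _weighted_var_of_means(m, ww)
                jk = jackknife_ci(
                    st.mean_x, w, level=jackknife_level, statistic=loo_stat,
                    use_t=jackknife_t,
                )
            else:
                jk = jackknife_ci(
                    st.scal_var_x, w, level=jackknife_level, use_t=jackknife_t
                )
            ci = (jk.lo, jk.hi)
        rows.append(
            {
                "scale": label,
                "scale_map": np.nan,
                "level": np.nan,
                "statistic": "variance",
                "value": value,
                "contribution": value / total if total > 0 else np.nan,
                "n_chrom": n_chrom,
                "ci_lo": ci[0],
                "ci_hi": ci[1],
            }
        )
    table = pd.DataFrame(rows)
    return GenomeDecomposition(
        table=table,
        total=total,
        statistic="variance",
        estimator=estimator,
        resolution=resolution,
    )


# ---------------------------------------------------------------------------
# correlation decomposition


def _pooled_correlation(st: _ChromStats, j: int, keep: np.ndarray) -> float:
    """Correlation at level j from coefficients pooled over kept chromosomes."""
    present = st.present[:, j] & keep
    if not present.any():
        return np.nan
    w = st.lengths[present]
    cov = np.average(st.cov[present, j], weights=w)
    vx = np.average(st.var_x[present, j], weights=w)
    vy = np.average(st.var_y[present, j], weights=w)
    denom = np.sqrt(vx * vy)
    return float(cov / denom) if denom > 0 else np.nan


def gnom_cor_decomp(
    xs: dict[str, GridSignal],
    ys: dict[str, GridSignal],
    estimator: Estimator = "unbiased",
    max_level: int | None = None,
    jackknife_level: float = 0.95,
    jackknife_t: bool = False,
) -> GenomeDecomposition:
    """Scale decomposition of the genome-wide correlation of two signals.

    Per-scale correlations rho_lambda pool wavelet coefficients across
    chromosomes (length weighting arises naturally); each is weighted by
    c_lambda, the geometric mean of the two signals' proportions of
    variance at that scale, so that the contributions plus the scaling and
    among-chromosome terms reconstruct the genome-wide Pearson correlation
    (exactly so for the biased estimator).
    """
    if not xs:
        raise ValueError("no chromosomes supplied")
    res_x, kind_x = _check_common_resolution(xs)
    res_y, _ = _check_common_resolution(ys)
    if res_x != res_y:
        raise ValueError("x and y signals have different resolutions")
    st = _collect(xs, ys, estimator, max_level)
    w = st.lengths

    var_x = _weighted_mean_zero(st.var_x, w)
    var_y = _weighted_mean_zero(st.var_y, w)
    cov = _weighted_mean_zero(st.cov, w)
    among_vx = _weighted_var_of_means(st.mean_x, w)
    among_vy = _weighted_var_of_means(st.mean_y, w)
    among_cov = _weighted_cov_of_means(st.mean_x, st.mean_y, w)
    scal_vx = float(np.average(st.scal_var_x, weights=w))
    scal_vy = float(np.average(st.scal_var_y, weights=w))
    scal_cov = float(np.average(st.scal_cov, weights=w))

    sigma_x = np.sqrt(var_x.sum() + among_vx + scal_vx)
    sigma_y = np.sqrt(var_y.sum() + among_vy + scal_vy)
    norm = sigma_x * sigma_y

    keep_all = np.ones(len(st.chroms), dtype=bool)
    rows = []
    for j in range(st.j_max):
        present = st.present[:, j]
        rho = _pooled_correlation(st, j, keep_all)
        denom = np.sqrt(var_x[j] * var_y[j])
        c_weight = denom / norm if norm > 0 else np.nan
        contribution = cov[j] / norm if norm > 0 else np.nan
        ci = (np.nan, np.nan)
        if present.sum() >= MIN_JACKKNIFE_BLOCKS and np.isfinite(rho):
            idx = np.flatnonzero(present)
            loo = np.empty(len(idx))
            for k, c in enumerate(idx):
                keep = keep_all.copy()
                keep[c] = False
                loo[k] = _pooled_correlation(st, j, keep)
            if np.all(np.isfinite(loo)):
                jk = weighted_jackknife(
                    rho, loo, st.lengths[idx], level=jackknife_level,
                    use_t=jackknife_t,
                )
                ci = (jk.lo, jk.hi)
        rows.append(
            {
                "scale": 2.0 ** (j + 1),
                "scale_map": 2.0 ** (j + 1) * res_x,
                "level": j + 1,
                "statistic": "correlation",
                "value": rho,
                "c_weight": c_weight,
                "contribution": contribution,
                "n_chrom": int(present.sum()),
                "ci_lo": ci[0],
                "ci_hi": ci[1],
            }
        )

    n_chrom = len(st.chroms)
    among_denom = np.sqrt(among_vx * among_vy)
    scal_denom = np.sqrt(scal_vx * scal_vy)
    for label, cov_term, denom in (
        ("chrom", among_cov, among_denom),
        ("scaling", scal_cov, scal_denom),
    ):
        rows.append(
            {
                "scale": label,
                "scale_map": np.nan,
                "level": np.nan,
                "statistic": "correlation",
                "value": cov_term / denom if denom > 0 else np.nan,
                "c_weight": denom / norm if norm > 0 else np.nan,
                "contribution": cov_term / norm if norm > 0 else np.nan,
                "n_chrom": n_chrom,
                "ci_lo": np.nan,
                "ci_hi": np.nan,
            }
        )
    table = pd.DataFrame(rows)
    total = float(np.nansum(table["contribution"].to_numpy()))
    return GenomeDecomposition(
        table=table,
        total=total,
        statistic="correlation",
        estimator=estimator,
        resolution=res_x,
    )


# ---------------------------------------------------------------------------
# variance explained by predictors


def variance_explained_by_predictor(
    xs: dict[str, GridSignal],
    preds: dict[str, GridSignal] | Sequence[dict[str, GridSignal]],
    max_level: int | None = None,
) -> pd.DataFrame:
    """Per-scale R-squared from regressing wavelet coefficients of ``xs`` on
    those of one or more predictor tracks.

    Non-boundary coefficients are pooled across chromosomes at each scale
    and fitted by ordinary least squares without an intercept (wavelet
    coefficients are zero-mean by construction).  Interpreted causally --
    e.g. ancestry on recombination rate -- the R-squared estimates the
    fraction of ancestry variance at that scale attributable to systematic
    selection.  Scales with fewer than 3 pooled coefficient pairs are
    reported as NaN.
    """
    if isinstance(preds, dict):
        preds = [preds]
    resolution, _ = _check_common_resolution(xs)
    decomp_x = {c: modwt_haar(s, max_level=max_level) for c, s in xs.items()}
    decomp_p = []
    for p, pred in enumerate(preds):
        if set(pred) != set(xs):
            raise ValueError(f"predictor {p} covers different chromosomes")
        decomp_p.append({c: modwt_haar(s, max_level=max_level) for c, s in pred.items()})
    j_max = max(d.n_levels for d in decomp_x.values())
    rows = []
    for j in range(1, j_max + 1):
        resp, design = [], []
        for chrom, dx in decomp_x.items():
            if j > dx.n_levels:
                continue
            resp.append(dx.interior(j))
            design.append(
                np.column_stack([dp[chrom].interior(j) for dp in decomp_p])
            )
        y = np.concatenate(resp)
        X = np.vstack(design)
        n = len(y)
        if n < 3 or n <= X.shape[1]:
            r2 = np.nan
        else:
            r2 = float(sm.OLS(y, X).fit().rsquared)  # uncentered: no intercept
        rows.append(
            {
                "scale": 2.0**j,
                "scale_map": 2.0**j * resolution,
                "level": j,
                "r_squared": r2,
                "n_coefficients": n,
            }
        )
    return pd.DataFrame(rows)
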