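"""Endpoint preprocessing and cue-integration analyses.

Implements the ideal-observer analysis applied to homing endpoints: response
variability as the SD of Euclidean distances to the mean response, optimal
static cue weights from single-cue variabilities and the predicted
combined-cue variance, relative response proximity (the empirical cue weight)
in conflict conditions, the von Mises analogues for heading direction, and
energy-statistics comparisons between 2-D endpoint distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.special import i0, i1

from .env_model import wrap_angle

__all__ = [
    "GaussianCueStats",
    "VonMisesCueStats",
    "ProximityResult",
    "normalize_endpoints",
    "remove_outliers",
    "remove_target_bias",
    "response_variability_euclid",
    "fit_von_mises",
    "optimal_weight_lm",
    "predicted_combined_sd",
    "relative_proximity",
    "vm_combined",
    "circular_sd",
    "energy_distance",
    "homogeneity_test",
    "cue_weight_regression",
    "ablation_report",
    "gaussian_cue_stats",
]

_KAPPA_CAP = 1e8


@dataclass(frozen=True)
class GaussianCueStats:
    """Single-cue response SDs with the optimal-weighting predictions."""

    sigma_sm: float
    sigma_lm: float
    sigma_combined_observed: float
    w_lm: float
    sigma_combined_predicted: float


@dataclass(frozen=True)
class VonMisesCueStats:
    """Per-condition von Mises fits of heading errors."""

    theta: dict
    kappa: dict
    delta: float = 0.0


@dataclass(frozen=True)
class ProximityResult:
    """Distances to the two cue-consistent homes and the relative proximity."""

    d_sm: float
    d_lm: float
    rprox_lm: float


def _points(df_or_arr) -> np.ndarray:
    if isinstance(df_or_arr, pd.DataFrame):
        return df_or_arr[["stop_x", "stop_y"]].to_numpy(float)
    return np.atleast_2d(np.asarray(df_or_arr, float))


def normalize_endpoints(ds: pd.DataFrame, mode: str = "center_on_target") -> pd.DataFrame:
    """Express endpoints in a common per-trial coordinate frame.

    ``center_on_target`` subtracts the true home from each stop location.
    ``rotate_to_heading`` additionally rotates each centered response so that
    the actual homing direction (from the third goal toward the true home)
    points north (+y). Requires columns stop_x/stop_y/home_x/home_y, and, for
    rotation, start3_x/start3_y (the homing start, i.e. the third goal).
    """
    if mode not in ("center_on_target", "rotate_to_heading"):
        raise ValueError("mode must be 'center_on_target' or 'rotate_to_heading'")
    out = ds.copy()
    ex = out["stop_x"] - out["home_x"]
    ey = out["stop_y"] - out["home_y"]
    if mode == "rotate_to_heading":
        hx = out["home_x"] - out["start3_x"]
        hy = out["home_y"] - out["start3_y"]
        # rotate so the homing direction becomes +y
        rot = np.pi / 2 - np.arctan2(hy, hx)
        c, s = np.cos(rot), np.sin(rot)
        ex, ey = c * ex - s * ey, s * ex + c * ey
    out["stop_x"] = out["home_x"] * 0.0 + ex
    out["stop_y"] = out["home_y"] * 0.0 + ey
    out["home_x"] = 0.0
    out["home_y"] = 0.0
    return out


def remove_outliers(points, k: float = 3.0, return_mask: bool = False):
    """Drop points whose distance to the sample mean exceeds Q3 + k * IQR.

    Quartiles use linear interpolation (numpy's default). With fewer than 4
    points the filter passes everything through with a warning. Intended to
    be applied per condition.
    """
    pts = _points(points)
    if len(pts) < 4:
        warnings.warn("fewer than 4 points; outlier filter passes all through")
        mask = np.ones(len(pts), dtype=bool)
    else:
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        q1, q3 = np.percentile(d, [25, 75])
        mask = d <= q3 + k * (q3 - q1)
    if return_mask:
        return mask
    if isinstance(points, pd.DataFrame):
        return points.loc[mask]
    return pts[mask]


def remove_target_bias(ds: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-target, per-condition mean error before pooling.

    Operates on centered errors (stop - home); after the operation every
    (target, condition) cell has zero mean error, so pooling across targets
    does not inflate variability with between-target bias.
    """
    out = ds.copy()
    for col, home in (("stop_x", "home_x"), ("stop_y", "home_y")):
        err = out[col] - out[home]
        centered = err - err.groupby(
            [out["target_id"], out["condition"]]
        ).transform("mean")
        out[col] = out[home] + centered
    return out


def response_variability_euclid(points) -> float:
    """SD of per-point Euclidean distances to the mean response location."""
    pts = _points(points)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    return float(np.std(d, ddof=1))


def fit_von_mises(headings) -> tuple[float, float]:
    """Maximum-likelihood von Mises fit: mean direction and concentration.

    kappa solves I1(k)/I0(k) = Rbar (the mean resultant length), found by
    bracketing; near-uniform samples give kappa ~ 0 with a warning, and
    (near-)degenerate samples are capped at a large concentration.
    """
    h = np.asarray(headings, float)
    if h.size < 3:
        raise ValueError("need at least 3 headings")
    c, s = np.cos(h).mean(), np.sin(h).mean()
    theta = float(np.arctan2(s, c))
    rbar = float(np.hypot(c, s))
    if rbar < 1e-8:
        warnings.warn("resultant length ~ 0; returning kappa = 0")
        return theta, 0.0
    if rbar > 1.0 - 1e-12:
        return theta, _KAPPA_CAP

    def a_ratio(k):
        return i1(k) / i0(k) - rbar

    hi = 1.0
    while a_ratio(hi) < 0 and hi < _KAPPA_CAP:
        hi *= 10.0
    if hi >= _KAPPA_CAP:
        return theta, _KAPPA_CAP
    return theta, float(brentq(a_ratio, 1e-12, hi))


def optimal_weight_lm(sigma_sm: float, sigma_lm: float) -> float:
    """Optimal static landmark weight from single-cue response SDs.

    w_lm = (1/sigma_lm^2) / (1/sigma_sm^2 + 1/sigma_lm^2); a zero SD means
    full reliance on that cue.
    """
    if sigma_sm < 0 or sigma_lm < 0:
        raise ValueError("sigmas must be non-negative")
    if sigma_lm == 0 and sigma_sm == 0:
        raise ValueError("both sigmas are zero; weights undefined")
    if sigma_lm == 0:
        return 1.0
    if sigma_sm == 0:
        return 0.0
    return float(sigma_sm**2 / (sigma_sm**2 + sigma_lm**2))


def predicted_combined_sd(sigma_sm: float, sigma_lm: float) -> float:
    """Predicted combined-cue SD, sigma^2 = w_sm^2 sigma_sm^2 + w_lm^2 sigma_lm^2."""
    w_lm = optimal_weight_lm(sigma_sm, sigma_lm)
    w_sm = 1.0 - w_lm
    return float(np.sqrt(w_sm**2 * sigma_sm**2 + w_lm**2 * sigma_lm**2))


def relative_proximity(
    response, x_sm, x_lm, bias_sm=None, bias_lm=None
) -> ProximityResult:
    """Relative response proximity to the landmark-consistent location.

    rprox = d_sm / (d_sm + d_lm) in [0, 1]: 0 at the self-motion-consistent
    location, 1 at the landmark-consistent one. Optional per-cue mean
    corrections shift the reference locations by a participant's intrinsic
    response bias observed in the corresponding single-cue condition.
    """
    response = np.asarray(response, float)
    x_sm = np.asarray(x_sm, float) + (0 if bias_sm is None else np.asarray(bias_sm, float))
    x_lm = np.asarray(x_lm, float) + (0 if bias_lm is None else np.asarray(bias_lm, float))
    if np.allclose(x_sm, x_lm):
        raise ValueError("cue-consistent locations coincide")
    d_sm = float(np.linalg.norm(response - x_sm))
    d_lm = float(np.linalg.norm(response - x_lm))
    return ProximityResult(d_sm, d_lm, d_sm / (d_sm + d_lm))


def vm_combined(
    theta_lm: float, kappa_lm: float, kappa_sm: float, delta: float
) -> tuple[float, float]:
    """Predicted combined-cue heading distribution under von Mises weighting.

    theta = theta_lm + delta - atan2(sin(delta), kappa_lm/kappa_sm + cos(delta))
    kappa = sqrt(kappa_sm^2 + kappa_lm^2 + 2 kappa_sm kappa_lm cos(delta)).

    delta is the conflict rotation; theta_lm is read relative to the
    self-motion-consistent baseline (the kappa_lm -> 0 limit recovers the
    self-motion heading theta_lm + delta as printed).
    """
    if kappa_lm <= 0 or kappa_sm <= 0:
        raise ValueError("concentrations must be positive")
    theta = theta_lm + delta - np.arctan2(
        np.sin(delta), kappa_lm / kappa_sm + np.cos(delta)
    )
    kappa = np.sqrt(
        kappa_sm**2 + kappa_lm**2 + 2.0 * kappa_sm * kappa_lm * np.cos(delta)
    )
    return float(theta), float(kappa)


def circular_sd(kappa: float) -> float:
    """Circular standard deviation sqrt(2 (1 - I1(k)/I0(k))) of a von Mises."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return float(np.sqrt(2.0))
    if kappa > 1e8:
        return 0.0
    return float(np.sqrt(2.0 * (1.0 - i1(kappa) / i0(kappa))))


def energy_distance(sample_a, sample_b) -> float:
    """Energy distance 2 E||X-Y|| - E||X-X'|| - E||Y-Y'|| (V-statistic).

    Expectations are plain means over all pairs including self-pairs, the
    convention of the V-statistic: identical samples give exactly 0 and two
    point masses at a and b give 2 ||a - b||.
    """
    a = _points(sample_a)
    b = _points(sample_b)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("samples must be non-empty")
    term_ab = cdist(a, b).mean()
    term_aa = squareform(pdist(a)).mean() if len(a) > 1 else 0.0
    term_bb = squareform(pdist(b)).mean() if len(b) > 1 else 0.0
    return float(2.0 * term_ab - term_aa - term_bb)


def homogeneity_test(
    sample_a, sample_b, n_permutations: int = 999, rng=None
) -> tuple[float, float]:
    """Permutation test of distributional equality based on energy distance.

    Pools the samples, permutes the labels, and reports the add-one-corrected
    p-value p = (1 + #{E_perm >= E_obs}) / (n_permutations + 1). Returns
    (statistic, p_value).
    """
    rng = np.random.default_rng(rng)
    a = _points(sample_a)
    b = _points(sample_b)
    na = len(a)
    pool = np.vstack([a, b])
    dmat = squareform(pdist(pool))

    def stat(idx_a):
        mask = np.zeros(len(pool), dtype=bool)
        mask[idx_a] = True
        d_ab = dmat[np.ix_(mask, ~mask)].mean()
        d_aa = dmat[np.ix_(mask, mask)].mean()
        d_bb = dmat[np.ix_(~mask, ~mask)].mean()
        return 2.0 * d_ab - d_aa - d_bb

    observed = stat(np.arange(na))
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(pool))[:na]
        if stat(perm) >= observed:
            count += 1
    return float(observed), float((1 + count) / (n_permutations + 1))


def cue_weight_regression(optimal_weights, empirical_weights):
    """OLS of empirical on optimal cue weights across participants.

    Returns (slope, intercept, r_squared, slope_ci) with a 95% confidence
    interval on the slope.
    """
    import statsmodels.api as sm

    x = np.asarray(optimal_weights, float)
    y = np.asarray(empirical_weights, float)
    if x.size < 3:
        raise ValueError("need at least 3 paired weights")
    if np.var(x) < 1e-15:
        raise ValueError("optimal weights have (near-)zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    ci = model.conf_int(alpha=0.05)[1]
    return float(slope), float(intercept), float(model.rsquared), (float(ci[0]), float(ci[1]))


def gaussian_cue_stats(ds: pd.DataFrame) -> GaussianCueStats:
    """Cue-integration summary from a (single participant's) endpoint table.

    Expects condition labels self_motion / landmark / combined and centered
    or raw coordinates; variability is translation invariant.
    """
    sds = {}
    for cond in ("self_motion", "landmark", "combined"):
        sub = ds[ds["condition"] == cond]
        if len(sub) < 2:
            raise ValueError(f"need >= 2 endpoints in condition {cond!r}")
        sds[cond] = response_variability_euclid(sub)
    return GaussianCueStats(
        sigma_sm=sds["self_motion"],
        sigma_lm=sds["landmark"],
        sigma_combined_observed=sds["combined"],
        w_lm=optimal_weight_lm(sds["self_motion"], sds["landmark"]),
        sigma_combined_predicted=predicted_combined_sd(
            sds["self_motion"], sds["landmark"]
        ),
    )


def ablation_report(reference: pd.DataFrame, model_runs: dict) -> pd.DataFrame:
    """Energy distances of each model variant's endpoints to a reference.

    ``model_runs`` maps model label -> list of endpoint DataFrames (replicate
    runs). Returns a tidy table with one row per (model, condition):
    mean +- SD of the energy distance over replicates; conditions missing
    from a run are reported as NaN.
    """
    conditions = sorted(reference["condition"].unique())
    rows = []
    for label, runs in model_runs.items():
        for cond in conditions:
            ref_pts = reference[reference["condition"] == cond]
            dists = []
            for run in runs:
                sub = run[run["condition"] == cond]
                dists.append(
                    energy_distance(ref_pts, sub) if len(sub) else np.nan
                )
            dists = np.asarray(dists, float)
            rows.append(
                {
                    "model": label,
                    "condition": cond,
                    "energy_distance_mean": float(np.nanmean(dists))
                    if np.any(np.isfinite(dists))
                    else np.nan,
                    "energy_distance_sd": float(np.nanstd(dists, ddof=1))
                    if np.sum(np.isfinite(dists)) > 1
                    else np.nan,
                    "n_replicates": int(np.sum(np.isfinite(dists))),
                }
            )
    return pd.DataFrame(rows)


def heading_errors(ds: pd.DataFrame, origin_cols=("start3_x", "start3_y")) -> np.ndarray:
    """Signed heading errors of endpoints seen from the homing start.

    The error is the angle between the direction to the response and the
    direction to the true home, wrapped to (-pi, pi].
    """
    ox = ds[origin_cols[0]].to_numpy(float)
    oy = ds[origin_cols[1]].to_numpy(float)
    ang_resp = np.arctan2(ds["stop_y"] - oy, ds["stop_x"] - ox)
    ang_home = np.arctan2(ds["home_y"] - oy, ds["home_x"] - ox)
    return wrap_angle(np.asarray(ang_resp - ang_home, float))
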