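"""Power-law exponent estimation, plateau-onset detection, bootstrap CIs.

Conventions: profiles obey ``R²(s) ~ s^{2ν}`` and ``Pc(s) ~ 1/s^α``, so a
log–log least-squares slope maps to ``ν = slope/2`` (``nu_from_R2``) or
``α = −slope`` (``alpha_from_Pc``).  Headline confined-ν fits use the
s ∈ [5, 25] persistence-unit range; confined-α fits use the pre-plateau
range s ∈ [5, 125] (the leveling-off onset of severely confined chains).
Bootstrap resamples whole chains, carrying their importance weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import WeightedEnsemble
from .observables import ContactProfile, DistanceProfile

__all__ = [
    "ScalingFit",
    "fit_power_law",
    "fit_power_law_wls",
    "nu_from_msd",
    "alpha_from_contacts",
    "detect_plateau_onset",
    "bootstrap_ci",
    "bootstrap_nu_from_matrix",
    "pooled_alpha",
    "bootstrap_alpha_from_matrices",
    "exponent_report",
    "NU_FIT_RANGE",
    "ALPHA_FIT_RANGE",
]

#: confined-ν fit range in persistence units
NU_FIT_RANGE = (5.0, 25.0)
#: confined-α fit range (pre-plateau)
ALPHA_FIT_RANGE = (5.0, 125.0)


@dataclass
class ScalingFit:
    """A fitted power law y = amplitude * x^slope with exponent semantics."""

    exponent: float           # reported value (ν, α, ...) per `target`
    amplitude: float
    slope: float              # raw log-log slope
    fit_range: Tuple[float, float]
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_bootstrap: int = 0
    target: str = "slope"     # nu_from_R2 | alpha_from_Pc | nu_free | alpha_free | slope
    n_points: int = 0
    slope_se: float = math.nan  # parametric slope standard error (WLS fits)


def _exponent_from_slope(slope: float, target: str) -> float:
    if target == "nu_from_R2":
        return slope / 2.0
    if target == "alpha_from_Pc":
        return -slope
    return slope


def fit_power_law(xs: Sequence[float], ys: Sequence[float],
                  fit_range: Optional[Tuple[float, float]] = None,
                  target: str = "slope") -> ScalingFit:
    """Least-squares line on (log10 x, log10 y) restricted to ``fit_range``.

    Exact (machine precision) on noiseless power laws.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if fit_range is None:
        fit_range = (float(xs.min()), float(xs.max()))
    lo, hi = fit_range
    sel = (xs >= lo) & (xs <= hi)
    if sel.sum() < 3:
        raise ValueError(f"need >= 3 points inside fit range {fit_range}")
    x, y = xs[sel], ys[sel]
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive values")
    lx, ly = np.log10(x), np.log10(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    return ScalingFit(exponent=_exponent_from_slope(float(slope), target),
                      amplitude=float(10.0 ** intercept),
                      slope=float(slope), fit_range=(lo, hi), target=target,
                      n_points=int(sel.sum()))


def fit_power_law_wls(xs: Sequence[float], ys: Sequence[float],
                      y_errs: Sequence[float],
                      fit_range: Optional[Tuple[float, float]] = None,
                      target: str = "slope") -> ScalingFit:
    """Variance-weighted log–log power-law fit.

    ``y_errs`` are standard errors of ``ys`` on the linear scale; each point
    enters the log-space least squares with weight ``1/sigma_log^2`` where
    ``sigma_log = y_err / (y ln 10)``.  Points with non-positive value or
    non-finite error are dropped.  This is the appropriate estimator when
    the points come from importance-weighted ensembles whose effective
    sample size — and hence precision — varies strongly along the grid.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    es = np.asarray(y_errs, dtype=float)
    if fit_range is None:
        fit_range = (float(xs.min()), float(xs.max()))
    lo, hi = fit_range
    sel = (xs >= lo) & (xs <= hi) & (ys > 0) & np.isfinite(es) & (es > 0)
    if sel.sum() < 3:
        raise ValueError("need >= 3 usable points inside fit range")
    x, y, e = xs[sel], ys[sel], es[sel]
    lx, ly = np.log10(x), np.log10(y)
    sig = e / (y * math.log(10.0))
    wgt = 1.0 / sig ** 2
    W = wgt.sum()
    mx = (wgt * lx).sum() / W
    my = (wgt * ly).sum() / W
    sxx = float((wgt * (lx - mx) ** 2).sum())
    slope = float((wgt * (lx - mx) * (ly - my)).sum() / sxx)
    intercept = my - slope * mx
    return ScalingFit(exponent=_exponent_from_slope(slope, target),
                      amplitude=float(10.0 ** intercept), slope=slope,
                      fit_range=(lo, hi), target=target, n_points=int(sel.sum()),
                      slope_se=math.sqrt(1.0 / sxx))


def nu_from_msd(profile: DistanceProfile,
                fit_range: Tuple[float, float] = NU_FIT_RANGE) -> ScalingFit:
    return fit_power_law(profile.s_values, profile.R2_values, fit_range,
                         target="nu_from_R2")


def alpha_from_contacts(profile: ContactProfile,
                        fit_range: Tuple[float, float] = ALPHA_FIT_RANGE) -> ScalingFit:
    return fit_power_law(profile.s_values, profile.Pc_values, fit_range,
                         target="alpha_from_Pc")


def detect_plateau_onset(profile: DistanceProfile,
                         slope_threshold: float = 0.1,
                         window: int = 5,
                         robust: bool = True) -> Optional[float]:
    """Leveling-off onset: smallest s beyond which the running local
    log–log slope (over ``window`` grid points) stays below the threshold
    for the remainder of the grid.  Returns None when the profile never
    plateaus within the covered range.

    With ``robust=True`` (default) "stays below" is judged by the median of
    the remaining local slopes instead of every single one, so that the
    Monte-Carlo noise of a finite ensemble in the saturated regime — where
    local slopes fluctuate around zero — cannot mask a real plateau.
    """
    s = np.asarray(profile.s_values, dtype=float)
    y = np.asarray(profile.R2_values, dtype=float)
    if len(s) < window + 1:
        raise ValueError("too few points for plateau detection")
    if s.max() / s.min() < 10.0:
        raise ValueError("profile must cover at least a decade of s")
    ls, ly = np.log10(s), np.log10(y)
    n_win = len(s) - window + 1
    slopes = np.empty(n_win)
    for i in range(n_win):
        slopes[i] = np.polyfit(ls[i:i + window], ly[i:i + window], 1)[0]
    below = slopes < slope_threshold
    # first window index from which the remaining local slopes stay below
    idx = None
    for i in range(n_win):
        if below[i] and (np.median(slopes[i:]) < slope_threshold
                         if robust else below[i:].all()):
            idx = i
            break
    if idx is None:
        return None
    return float(s[idx])


def bootstrap_ci(statistic: Callable[[WeightedEnsemble], float],
                 ensemble: WeightedEnsemble,
                 n_boot: int = 1000,
                 seed: int = 0,
                 alpha: float = 0.05) -> Tuple[float, float]:
    """Percentile bootstrap interval of an ensemble-level statistic.

    The resampling unit is the whole chain; each resampled chain carries
    its importance weight.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if len(ensemble) < 2:
        raise ValueError("cannot bootstrap a single-chain ensemble")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        stats[b] = statistic(ensemble.subset(ensemble.bootstrap_indices(rng)))
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _softmax(lw: np.ndarray) -> np.ndarray:
    w = np.exp(lw - lw.max())
    return w / w.sum()


def bootstrap_nu_from_matrix(msd_matrix: np.ndarray,
                             ensemble: WeightedEnsemble,
                             s_values: np.ndarray,
                             fit_range: Tuple[float, float] = NU_FIT_RANGE,
                             n_boot: int = 400,
                             seed: int = 0,
                             alpha: float = 0.05) -> Tuple[float, float]:
    """Percentile bootstrap CI of ν from a cached per-chain R²(s) matrix.

    Rows are chains of ``ensemble``; resampling only permutes rows and
    reweights, so the expensive distance computations are done once.
    Resampling respects genealogy families when present.
    """
    rng = np.random.default_rng(seed)
    log_weights = ensemble.log_weights
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = ensemble.bootstrap_indices(rng)
        w = _softmax(log_weights[idx])
        prof = w @ msd_matrix[idx]
        stats[b] = fit_power_law(s_values, prof, fit_range,
                                 target="nu_from_R2").exponent
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def pooled_alpha(contact_matrices: Sequence[Tuple[np.ndarray, np.ndarray, WeightedEnsemble]],
                 s_values: np.ndarray,
                 fit_range: Tuple[float, float] = ALPHA_FIT_RANGE,
                 weight_sets: Optional[Sequence[np.ndarray]] = None) -> float:
    """α from cached per-ensemble contact matrices.

    ``contact_matrices`` holds ``(s_mask, matrix, ensemble)`` triples, one
    per independent ensemble (the mask marks which s each ensemble can
    reach).  ``weight_sets`` overrides the normalized chain weights, e.g.
    for binder reweighting.
    """
    pc = np.zeros(len(s_values))
    cnt = np.zeros(len(s_values))
    for j, (mask, mat, ens) in enumerate(contact_matrices):
        w = weight_sets[j] if weight_sets is not None \
            else _softmax(ens.log_weights)
        pc[mask] += w @ mat
        cnt[mask] += 1
    pc = pc / np.maximum(cnt, 1)
    ok = pc > 0
    return fit_power_law(s_values[ok], pc[ok], fit_range,
                         target="alpha_from_Pc").exponent


def bootstrap_alpha_from_matrices(
        contact_matrices: Sequence[Tuple[np.ndarray, np.ndarray, WeightedEnsemble]],
        s_values: np.ndarray,
        fit_range: Tuple[float, float] = ALPHA_FIT_RANGE,
        n_boot: int = 400,
        seed: int = 0,
        alpha: float = 0.05) -> Tuple[float, float]:
    """Percentile bootstrap CI of the pooled contact exponent α, resampling
    chains (or genealogy families) independently within every ensemble."""
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        pc = np.zeros(len(s_values))
        cnt = np.zeros(len(s_values))
        for mask, mat, ens in contact_matrices:
            idx = ens.bootstrap_indices(rng)
            w = _softmax(ens.log_weights[idx])
            pc[mask] += w @ mat[idx]
            cnt[mask] += 1
        pc = pc / np.maximum(cnt, 1)
        ok = pc > 0
        stats[b] = fit_power_law(s_values[ok], pc[ok], fit_range,
                                 target="alpha_from_Pc").exponent
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def exponent_report(msd_profiles: Dict[float, DistanceProfile],
                    contact_profiles: Optional[Dict[float, ContactProfile]] = None,
                    nu_range: Tuple[float, float] = NU_FIT_RANGE,
                    alpha_range: Tuple[float, float] = ALPHA_FIT_RANGE,
                    ) -> pd.DataFrame:
    """Per-confinement exponent table over a sweep of sphere diameters D.

    Keys are confinement diameters in µm (``math.inf`` for free space).
    The returned frame carries ``nu_monotone`` / ``alpha_monotone`` flags
    in ``DataFrame.attrs`` stating whether the exponents are non-decreasing
    in D, the signature of confinement release.
    """
    if len(msd_profiles) < 2:
        raise ValueError("need at least two distinct confinement diameters")
    rows = []
    for d in sorted(msd_profiles):
        fit_nu = nu_from_msd(msd_profiles[d], nu_range)
        row = {"D_um": d, "nu": fit_nu.exponent,
               "nu_fit_lo": fit_nu.fit_range[0], "nu_fit_hi": fit_nu.fit_range[1],
               "alpha": math.nan}
        if contact_profiles is not None and d in contact_profiles:
            fit_a = alpha_from_contacts(contact_profiles[d], alpha_range)
            row["alpha"] = fit_a.exponent
            row["alpha_fit_lo"], row["alpha_fit_hi"] = fit_a.fit_range
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["nu_monotone"] = bool(np.all(np.diff(df["nu"].to_numpy()) >= 0))
    a = df["alpha"].dropna().to_numpy()
    df.attrs["alpha_monotone"] = bool(np.all(np.diff(a) >= 0)) if len(a) >= 2 else None
    return df
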