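"""Posterior result surfaces: hourly activity curves, active/inactive hour
classification, sex/season movement-rate tables, and distance-response curves.

All curves are built on the sqrt(km/h) scale draw by draw, back-transformed
by squaring each draw (clipped at zero first), and only then summarized by
the posterior mean and the equal-tailed 2.5-97.5% quantiles.  Squaring a
posterior mean would be biased low and is never done.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import Chain, equal_tailed_interval
from .model import (FIXED_ADDITIVE, FIXED_INTERACTION, FIXED_SEASON, N_HOURS,
                    ModelSpec, SEASON_NAMES)
from .observations import ObservationTable

DEFAULT_PROFILE_KM = 4.0  # anthropogenic terms ~ at their asymptote (phi >= 0.75)


@dataclass
class ActivityCurve:
    """Posterior hourly movement-rate curve (km/h) for one stratum."""

    stratum: object
    hours: np.ndarray
    mean_rate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    draws: np.ndarray = field(repr=False, default=None)  # (n_draws, 24), km/h

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"hour": self.hours, "mean_rate_kmh": self.mean_rate,
                             "ci_low": self.ci_low, "ci_high": self.ci_high})


def _pooled_draws(chains: list[Chain]) -> np.ndarray:
    return np.vstack([c.draws for c in chains])


def _col(chains: list[Chain], name: str) -> int:
    return chains[0].layout.index[name]


def _stratum_label(spec: ModelSpec, season: int, sex: int) -> str:
    labels = spec.stratum_labels()
    if spec.n_strata == 1:
        return labels[0]
    if spec.n_strata == 4:
        return SEASON_NAMES[season]
    return f"{SEASON_NAMES[season]}_{'F' if sex == 1 else 'M'}"


def _sqrt_curve_draws(chains: list[Chain], spec: ModelSpec, season: int, sex: int,
                      covariate_profile=DEFAULT_PROFILE_KM) -> np.ndarray:
    """(n_draws, 24) matrix of lambda* on the sqrt scale for one (season, sex).

    The individual random effect is taken at its population mean alpha (a
    typical bear); distance covariates sit at ``covariate_profile`` km.
    """
    if not (1 <= season <= 4) or sex not in (1, 2):
        raise ValueError(f"stratum (season={season}, sex={sex}) not defined")
    draws = _pooled_draws(chains)
    idx = chains[0].layout.index
    lab = _stratum_label(spec, season, sex)
    lam_cols = [idx[f"lam_{lab}_h{h:02d}"] for h in range(1, N_HOURS + 1)]
    out = draws[:, lam_cols] + draws[:, [idx["alpha"]]]
    if spec.fixed_effects == FIXED_ADDITIVE:
        if sex == 2:
            out += draws[:, [idx["mu_M"]]]
        if season > 1:
            out += draws[:, [idx[f"gamma_{SEASON_NAMES[season]}"]]]
    elif spec.fixed_effects == FIXED_SEASON:
        if season > 1:
            out += draws[:, [idx[f"gamma_{SEASON_NAMES[season]}"]]]
    elif spec.fixed_effects == FIXED_INTERACTION:
        if not (season == 1 and sex == 1):
            out += draws[:, [idx[f"xi_{SEASON_NAMES[season]}_{'F' if sex == 1 else 'M'}"]]]
    profile = covariate_profile if isinstance(covariate_profile, dict) else \
        {j: covariate_profile for j in spec.anthro_features}
    for j in spec.anthro_features:
        suffix = f"_x{j}_{SEASON_NAMES[season]}" if spec.anthro_by_season else f"_x{j}"
        b = draws[:, idx[f"beta{suffix}"]]
        p = draws[:, idx[f"phi{suffix}"]]
        out += (b * np.exp(-p * float(profile[j])))[:, None]
    return out


def _summarize_rate_draws(rate_draws: np.ndarray, stratum) -> ActivityCurve:
    lo, hi = np.quantile(rate_draws, [0.025, 0.975], axis=0)
    return ActivityCurve(stratum=stratum, hours=np.arange(1, N_HOURS + 1),
                         mean_rate=rate_draws.mean(axis=0), ci_low=lo, ci_high=hi,
                         draws=rate_draws)


def hourly_curve(chains: list[Chain], spec: ModelSpec, stratum=None,
                 covariate_profile=DEFAULT_PROFILE_KM, include_noise: bool = False) -> ActivityCurve:
    """Posterior hourly activity curve in km/h.

    ``stratum`` is ``(season, sex)`` with season 1-4 and sex 1 (F) / 2 (M);
    ``sex=None`` averages the sexes 50:50 per draw; ``stratum=None`` averages
    all season x sex combinations per draw (equal weights).  Each draw's
    sqrt-scale curve is clipped at zero and squared; ``include_noise`` adds
    sigma^2 to give the predictive mean of the squared response instead of
    the typical-hour activity index.
    """
    if stratum is None:
        combos = [(r, s) for r in (1, 2, 3, 4) for s in (1, 2)]
    else:
        season, sex = stratum
        combos = [(season, sex)] if sex is not None else [(season, 1), (season, 2)]
    rate = None
    for r, s in combos:
        c = _sqrt_curve_draws(chains, spec, r, s, covariate_profile)
        rc = np.clip(c, 0.0, None) ** 2
        if include_noise:
            rc = rc + _pooled_draws(chains)[:, [_col(chains, "sigma2")]]
        rate = rc if rate is None else rate + rc
    rate /= len(combos)
    return _summarize_rate_draws(rate, stratum if stratum is not None else "pooled")


def population_curve_5050(curve_F: ActivityCurve, curve_M: ActivityCurve) -> ActivityCurve:
    """Even-sex-ratio population curve: per-draw mean of the two sexes' rates."""
    if not np.array_equal(curve_F.hours, curve_M.hours):
        raise ValueError("curves must share the same hour grid")
    if curve_F.draws is None or curve_M.draws is None or \
            curve_F.draws.shape != curve_M.draws.shape:
        raise ValueError("curves must carry matching per-draw rates")
    return _summarize_rate_draws(0.5 * (curve_F.draws + curve_M.draws), "population_5050")


def classify_active_hours(curve: ActivityCurve) -> dict:
    """Partition the 24 hours by the across-hour mean movement rate.

    Hour i is active iff its posterior mean rate strictly exceeds the 24-h
    average of the posterior mean curve; ties count as inactive.
    """
    if not np.isfinite(curve.mean_rate).all():
        raise ValueError("curve has non-finite means")
    threshold = float(curve.mean_rate.mean())
    active = [int(h) for h, m in zip(curve.hours, curve.mean_rate) if m > threshold]
    inactive = [int(h) for h in curve.hours if int(h) not in active]
    return {"active": active, "inactive": inactive, "threshold_kmh": threshold}


def movement_rate_table(chains: list[Chain], spec: ModelSpec, partition: dict,
                        covariate_profile=DEFAULT_PROFILE_KM) -> pd.DataFrame:
    """Mean +/- SD movement rates by sex x season x {24-h, active, inactive}.

    Rates are averaged over the relevant hour set within each posterior draw
    (back-transformed scale); the table reports the posterior mean and SD of
    those per-draw averages.  Sex 'both' is the 50:50 average; season 'all'
    averages the four seasons.
    """
    hour_sets = {"24h": list(range(1, 25)),
                 "active": partition["active"], "inactive": partition["inactive"]}
    sex_groups = {"F": [1], "M": [2], "both": [1, 2]}
    season_groups = {SEASON_NAMES[r]: [r] for r in (1, 2, 3, 4)}
    season_groups["all"] = [1, 2, 3, 4]
    cache = {}
    for r in (1, 2, 3, 4):
        for s in (1, 2):
            cache[(r, s)] = np.clip(
                _sqrt_curve_draws(chains, spec, r, s, covariate_profile), 0.0, None) ** 2
    rows = []
    for sex_name, sexes in sex_groups.items():
        for season_name, seasons in season_groups.items():
            rate = np.mean([cache[(r, s)] for r in seasons for s in sexes], axis=0)
            for period, hours in hour_sets.items():
                if not hours:
                    rows.append({"sex": sex_name, "season": season_name, "period": period,
                                 "mean_kmh": np.nan, "sd_kmh": np.nan})
                    continue
                per_draw = rate[:, np.asarray(hours) - 1].mean(axis=1)
                rows.append({"sex": sex_name, "season": season_name, "period": period,
                             "mean_kmh": float(per_draw.mean()),
                             "sd_kmh": float(per_draw.std(ddof=0))})
    return pd.DataFrame(rows)


@dataclass
class AnthroResponse:
    """Movement rate vs. distance to one anthropogenic feature class."""

    feature: int
    season: int
    distance_km: np.ndarray
    mean_rate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    beta_mean: float
    beta_ci: tuple
    ci_excludes_zero: bool

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_km": self.distance_km, "mean_rate_kmh": self.mean_rate,
                             "ci_low": self.ci_low, "ci_high": self.ci_high})


def anthropogenic_response(chains: list[Chain], spec: ModelSpec, season: int,
                           feature: int, distance_grid_km=None,
                           covariate_profile=DEFAULT_PROFILE_KM) -> AnthroResponse:
    """Back-transformed movement rate along a distance grid to one feature.

    Other terms are held at a typical-hour profile: the random effect at
    alpha, the hour effect at its across-hour mean (sexes averaged), other
    distance covariates at ``covariate_profile`` km.  Also reports whether
    the 95% CI of the amplitude beta excludes zero.
    """
    if feature not in spec.anthro_features:
        raise ValueError(f"feature class x{feature} is not in model {spec.id} "
                         f"(has {spec.anthro_features})")
    if distance_grid_km is None:
        distance_grid_km = np.linspace(0.0, 4.0, 81)
    grid = np.asarray(distance_grid_km, float)
    draws = _pooled_draws(chains)
    idx = chains[0].layout.index
    base = None
    for s in (1, 2):
        profile = covariate_profile if isinstance(covariate_profile, dict) else \
            {j: covariate_profile for j in spec.anthro_features}
        profile = dict(profile)
        profile[feature] = np.inf  # exclude the target feature from the baseline
        c = _sqrt_curve_draws(chains, spec, season, s, profile).mean(axis=1)
        base = c if base is None else base + c
    base *= 0.5
    suffix = f"_x{feature}_{SEASON_NAMES[season]}" if spec.anthro_by_season else f"_x{feature}"
    b = draws[:, idx[f"beta{suffix}"]]
    p = draws[:, idx[f"phi{suffix}"]]
    sqrt_scale = base[:, None] + b[:, None] * np.exp(-p[:, None] * grid[None, :])
    rate = np.clip(sqrt_scale, 0.0, None) ** 2
    lo, hi = np.quantile(rate, [0.025, 0.975], axis=0)
    blo, bhi = equal_tailed_interval(b)
    return AnthroResponse(feature=feature, season=season, distance_km=grid,
                          mean_rate=rate.mean(axis=0), ci_low=lo, ci_high=hi,
                          beta_mean=float(b.mean()), beta_ci=(blo, bhi),
                          ci_excludes_zero=bool(blo > 0 or bhi < 0))
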