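"""Probability model for circadian movement rates.

The response is the square-root of the hourly movement rate (km/h) of a
GPS-collared bear.  Its expectation is a sum of an hour-of-day effect with a
circular-in-time Gaussian covariance, an individual random effect, optional
sex/season fixed effects, and optional exponential distance-decay terms for
roads and settlements.  Thirteen structural variants of the linear predictor
are enumerated in :data:`MODEL_REGISTRY`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
import math

import numpy as np

N_HOURS = 24

SEASON_NAMES = {1: "spring", 2: "early_summer", 3: "late_summer", 4: "fall"}
SEX_NAMES = {1: "F", 2: "M"}


# ---------------------------------------------------------------------------
# circular hour distance and covariance
# ---------------------------------------------------------------------------

def circular_hour_distance(i: int, i2: int) -> int:
    """Circular distance (hours) between two hour indices on the 24-h clock.

    ``min(|i - i2|, 24 - |i - i2|)``; e.g. midnight (24) and 01:00 are one
    hour apart.
    """
    if not (1 <= i <= N_HOURS and 1 <= i2 <= N_HOURS):
        raise ValueError(f"hour indices must lie in 1..{N_HOURS}, got {i}, {i2}")
    d = abs(i - i2)
    return min(d, N_HOURS - d)


def _circular_distances() -> np.ndarray:
    j = np.arange(N_HOURS)
    return np.minimum(j, N_HOURS - j).astype(float)


@dataclass(frozen=True)
class HourCovariance:
    """24x24 circulant covariance of the hour-of-day effect.

    ``Sigma[i, i'] = exp(-nu * d_circ(i, i')) / psi`` with ``nu`` the decay
    per hour and ``psi`` a precision-like scale.  Because the matrix is
    circulant, its eigenvalues are the DFT of the first row, which gives an
    O(n log n) inverse, log-determinant and quadratic form.
    """

    nu: float
    psi: float

    def __post_init__(self):
        if not (self.nu > 0 and self.psi > 0):
            raise ValueError(f"nu and psi must be positive, got nu={self.nu}, psi={self.psi}")

    @property
    def first_row(self) -> np.ndarray:
        return np.exp(-self.nu * _circular_distances()) / self.psi

    @property
    def matrix(self) -> np.ndarray:
        idx = np.abs(np.subtract.outer(np.arange(N_HOURS), np.arange(N_HOURS)))
        idx = np.minimum(idx, N_HOURS - idx)
        return np.exp(-self.nu * idx.astype(float)) / self.psi

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of Sigma (real, positive), via the DFT of the first row."""
        return np.fft.fft(self.first_row).real

    def inverse(self) -> np.ndarray:
        """Spectral (circulant) inverse of Sigma."""
        inv_first_col = np.fft.ifft(1.0 / np.fft.fft(self.first_row)).real
        idx = np.abs(np.subtract.outer(np.arange(N_HOURS), np.arange(N_HOURS)))
        idx = np.minimum(idx, N_HOURS - idx)
        return inv_first_col[idx]

    def logdet(self) -> float:
        return float(np.sum(np.log(self.eigenvalues)))

    def quad_form(self, v: np.ndarray) -> float:
        """v' Sigma^{-1} v via the spectral decomposition."""
        vhat = np.fft.fft(np.asarray(v, float))
        return float(np.sum((vhat * vhat.conj()).real / self.eigenvalues) / N_HOURS)

    def logpdf(self, v: np.ndarray) -> float:
        """Log density of MN(0, Sigma) at v."""
        return -0.5 * (N_HOURS * math.log(2 * math.pi) + self.logdet() + self.quad_form(v))

    def rvs(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        L = np.linalg.cholesky(self.matrix)
        z = rng.standard_normal((size, N_HOURS))
        out = z @ L.T
        return out[0] if size == 1 else out


def build_covariance(nu: float, psi: float) -> HourCovariance:
    """Construct the cyclic hour-of-day covariance ``exp(-nu d_circ)/psi``."""
    return HourCovariance(nu=float(nu), psi=float(psi))


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Priors:
    """Weakly informative priors.

    Normal priors are parameterized by mean and VARIANCE (matching the
    N(expected value, variance) notation used for the observation noise);
    Gamma priors (shape, rate) sit on the precisions 1/rho^2 and 1/sigma^2
    and on the covariance scale psi; nu and each decay phi are uniform, the
    bounds chosen so the practical range 3/nu spans 1-24 h and 3/phi spans
    0.2-4 km.
    """

    alpha_mean: float = 0.0
    alpha_var: float = 1000.0
    rho2_shape: float = 1.0
    rho2_rate: float = 1.0
    psi_shape: float = 1.0
    psi_rate: float = 1.0
    nu_low: float = 3.0 / 24.0
    nu_high: float = 3.0
    fixed_var: float = 1000.0
    beta_var: float = 1000.0
    phi_low: float = 3.0 / 4.0
    phi_high: float = 3.0 / 0.2
    sigma2_shape: float = 1.0
    sigma2_rate: float = 1.0

    def __post_init__(self):
        if self.alpha_var <= 0 or self.fixed_var <= 0 or self.beta_var <= 0:
            raise ValueError("prior variances must be positive")
        for a, b in ((self.rho2_shape, self.rho2_rate), (self.psi_shape, self.psi_rate),
                     (self.sigma2_shape, self.sigma2_rate)):
            if a <= 0 or b <= 0:
                raise ValueError("Gamma shapes/rates must be positive")
        if not (self.nu_low < self.nu_high and self.phi_low < self.phi_high):
            raise ValueError("uniform prior bounds must be ordered")


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

HOUR_ONLY = "hour_only"
HOUR_BY_SEASON = "hour_by_season"
HOUR_BY_SEASON_SEX = "hour_by_season_sex"

FIXED_NONE = "none"
FIXED_ADDITIVE = "additive"          # mu_s + gamma_r
FIXED_INTERACTION = "interaction"    # xi_rs
FIXED_SEASON = "season_only"         # gamma_r

ANTHRO_NONE = "none"
ANTHRO_COMBINED = "combined"  # x1 (all roads) and x4 (settlements)
ANTHRO_SPLIT = "split"        # x2 (primary), x3 (secondary), x4 (settlements)


@dataclass(frozen=True)
class ModelSpec:
    """One structural formulation of the linear predictor lambda*_tk."""

    id: int
    hour_effect: str
    fixed_effects: str
    anthro_block: str
    anthro_by_season: bool

    @property
    def n_strata(self) -> int:
        return {HOUR_ONLY: 1, HOUR_BY_SEASON: 4, HOUR_BY_SEASON_SEX: 8}[self.hour_effect]

    @property
    def anthro_features(self) -> tuple[int, ...]:
        """Distance-covariate indices used by this model (1=all roads,
        2=primary, 3=secondary, 4=settlements)."""
        return {ANTHRO_NONE: (), ANTHRO_COMBINED: (1, 4), ANTHRO_SPLIT: (2, 3, 4)}[self.anthro_block]

    @property
    def k_interaction(self) -> int:
        """Number of parameter blocks in interaction with season and/or sex."""
        k = 0
        if self.hour_effect != HOUR_ONLY:
            k += 1
        if self.fixed_effects == FIXED_INTERACTION:
            k += 1
        if self.anthro_by_season:
            k += len(self.anthro_features)
        return k

    def stratum_index(self, season: np.ndarray, sex: np.ndarray) -> np.ndarray:
        """Map season (1-4) and sex (1-2) codes to the lambda-vector stratum."""
        season = np.asarray(season)
        sex = np.asarray(sex)
        if self.hour_effect == HOUR_ONLY:
            return np.zeros(np.broadcast(season, sex).shape, dtype=int)
        if self.hour_effect == HOUR_BY_SEASON:
            return season - 1
        return (sex - 1) * 4 + (season - 1)

    def stratum_labels(self) -> list[str]:
        if self.hour_effect == HOUR_ONLY:
            return ["all"]
        if self.hour_effect == HOUR_BY_SEASON:
            return [SEASON_NAMES[r] for r in range(1, 5)]
        return [f"{SEASON_NAMES[r]}_{SEX_NAMES[s]}" for s in (1, 2) for r in range(1, 5)]

    def formula(self) -> str:
        """Human-readable rendering of the linear predictor."""
        lam = {HOUR_ONLY: "lambda_i", HOUR_BY_SEASON: "lambda_ir",
               HOUR_BY_SEASON_SEX: "lambda_irs"}[self.hour_effect]
        terms = [lam, "omega_k"]
        if self.fixed_effects == FIXED_ADDITIVE:
            terms += ["mu_s", "gamma_r"]
        elif self.fixed_effects == FIXED_INTERACTION:
            terms += ["xi_rs"]
        elif self.fixed_effects == FIXED_SEASON:
            terms += ["gamma_r"]
        sub = "r" if self.anthro_by_season else ""
        for j in self.anthro_features:
            terms.append(f"beta_{j}{sub}*exp(-phi_{j}{sub}*x_{j}tk)")
        return " + ".join(terms)

    def to_dict(self) -> dict:
        return {"id": self.id, "hour_effect": self.hour_effect,
                "fixed_effects": self.fixed_effects, "anthro_block": self.anthro_block,
                "anthro_by_season": self.anthro_by_season, "K": self.k_interaction,
                "formula": self.formula()}


MODEL_REGISTRY: dict[int, ModelSpec] = {
    1: ModelSpec(1, HOUR_ONLY, FIXED_NONE, ANTHRO_NONE, False),
    2: ModelSpec(2, HOUR_ONLY, FIXED_ADDITIVE, ANTHRO_COMBINED, False),
    3: ModelSpec(3, HOUR_ONLY, FIXED_ADDITIVE, ANTHRO_SPLIT, False),
    4: ModelSpec(4, HOUR_BY_SEASON_SEX, FIXED_ADDITIVE, ANTHRO_COMBINED, True),
    5: ModelSpec(5, HOUR_BY_SEASON_SEX, FIXED_ADDITIVE, ANTHRO_SPLIT, True),
    6: ModelSpec(6, HOUR_BY_SEASON_SEX, FIXED_INTERACTION, ANTHRO_COMBINED, False),
    7: ModelSpec(7, HOUR_BY_SEASON_SEX, FIXED_INTERACTION, ANTHRO_SPLIT, False),
    8: ModelSpec(8, HOUR_BY_SEASON_SEX, FIXED_INTERACTION, ANTHRO_COMBINED, True),
    9: ModelSpec(9, HOUR_BY_SEASON_SEX, FIXED_INTERACTION, ANTHRO_SPLIT, True),
    10: ModelSpec(10, HOUR_BY_SEASON, FIXED_SEASON, ANTHRO_COMBINED, False),
    11: ModelSpec(11, HOUR_BY_SEASON, FIXED_SEASON, ANTHRO_SPLIT, False),
    12: ModelSpec(12, HOUR_BY_SEASON, FIXED_SEASON, ANTHRO_COMBINED, True),
    13: ModelSpec(13, HOUR_BY_SEASON, FIXED_SEASON, ANTHRO_SPLIT, True),
}


def registry_to_json(path=None) -> str:
    """Serialize the model registry as a JSON list (sorted by id)."""
    payload = json.dumps([MODEL_REGISTRY[i].to_dict() for i in sorted(MODEL_REGISTRY)], indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(payload)
    return payload


def registry_from_json(text: str) -> dict[int, ModelSpec]:
    out = {}
    for d in json.loads(text):
        out[int(d["id"])] = ModelSpec(int(d["id"]), d["hour_effect"], d["fixed_effects"],
                                      d["anthro_block"], bool(d["anthro_by_season"]))
    return out


# ---------------------------------------------------------------------------
# parameter state
# ---------------------------------------------------------------------------

@dataclass
class ParameterState:
    """A full set of model parameters for one ModelSpec.

    ``lam`` holds one 24-vector per hour-effect stratum (1, 4 or 8 rows).
    ``mu`` (sex), ``gamma`` (season) and ``xi`` (season x sex) use
    first-level-zero (corner) constraints: the female / spring / female-spring
    entries are pinned at 0.  ``beta``/``phi`` have shape (J,) or (J, 4) when
    the anthropogenic block interacts with season, where J indexes
    ``spec.anthro_features``.
    """

    lam: np.ndarray              # (S, 24)
    omega: np.ndarray            # (K,)
    alpha: float = 0.0
    rho2: float = 1.0
    mu: np.ndarray = field(default_factory=lambda: np.zeros(2))     # index s-1
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(4))  # index r-1
    xi: np.ndarray = field(default_factory=lambda: np.zeros((4, 2)))  # [r-1, s-1]
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    phi: np.ndarray = field(default_factory=lambda: np.zeros(0))
    nu: float = 1.0
    psi: float = 1.0
    sigma2: float = 1.0

    @classmethod
    def initial(cls, spec: ModelSpec, n_animals: int, priors: Priors | None = None) -> "ParameterState":
        """All location parameters 0, precisions 1, nu/phi at prior midpoints."""
        priors = priors or Priors()
        shape = (len(spec.anthro_features), 4) if spec.anthro_by_season else (len(spec.anthro_features),)
        return cls(
            lam=np.zeros((spec.n_strata, N_HOURS)),
            omega=np.zeros(n_animals),
            beta=np.zeros(shape),
            phi=np.full(shape, 0.5 * (priors.phi_low + priors.phi_high)),
            nu=0.5 * (priors.nu_low + priors.nu_high),
        )

    def copy(self) -> "ParameterState":
        return replace(self, lam=self.lam.copy(), omega=self.omega.copy(), mu=self.mu.copy(),
                       gamma=self.gamma.copy(), xi=self.xi.copy(), beta=self.beta.copy(),
                       phi=self.phi.copy())


def anthropogenic_effect(beta, phi, x_km):
    """Distance-decay disturbance term ``beta * exp(-phi * x)``.

    beta is the effect at distance 0 and 3/phi is the practical range (km)
    beyond which the effect is negligible.
    """
    x = np.asarray(x_km, float)
    if np.any(x < 0):
        raise ValueError("distances must be non-negative")
    if np.any(np.asarray(phi, float) <= 0):
        raise ValueError("phi must be positive")
    out = beta * np.exp(-np.asarray(phi, float) * x)
    return float(out) if np.isscalar(x_km) else out


def _check_dims(state: ParameterState, spec: ModelSpec):
    if state.lam.shape != (spec.n_strata, N_HOURS):
        raise ValueError(f"state.lam shape {state.lam.shape} does not match spec {spec.id} "
                         f"({spec.n_strata} strata expected)")
    want = (len(spec.anthro_features), 4) if spec.anthro_by_season else (len(spec.anthro_features),)
    if state.beta.shape != want or state.phi.shape != want:
        raise ValueError(f"beta/phi shape {state.beta.shape} does not match spec {spec.id} (want {want})")


def linear_predictor(state: ParameterState, rec, spec: ModelSpec) -> float:
    """Evaluate lambda*_tk for one movement record.

    ``rec`` needs attributes/keys hour_index, season, sex ('F'/'M' or 1/2),
    animal_index, and x1..x4 (km).
    """
    get = (lambda name: rec[name]) if hasattr(rec, "__getitem__") else (lambda name: getattr(rec, name))
    sex = get("sex")
    sex = {"F": 1, "M": 2}.get(sex, sex)
    rows = linear_predictor_vec(
        state,
        dict(hour=np.array([get("hour_index")]), season=np.array([get("season")]),
             sex=np.array([sex]), animal=np.array([get("animal_index")]),
             x={j: np.array([float(get(f"x{j}"))]) for j in (1, 2, 3, 4)}),
        spec,
    )
    return float(rows[0])


def linear_predictor_vec(state: ParameterState, obs, spec: ModelSpec) -> np.ndarray:
    """Vectorized lambda* over an observation set.

    ``obs`` is a mapping with integer arrays hour (1-24), season (1-4),
    sex (1-2), animal (0-based), and a dict ``x`` of distance arrays in km.
    """
    _check_dims(state, spec)
    hour = np.asarray(obs["hour"]) - 1
    season = np.asarray(obs["season"])
    sex = np.asarray(obs["sex"])
    animal = np.asarray(obs["animal"])
    strat = spec.stratum_index(season, sex)
    lp = state.lam[strat, hour] + state.omega[animal]
    if spec.fixed_effects == FIXED_ADDITIVE:
        lp = lp + state.mu[sex - 1] + state.gamma[season - 1]
    elif spec.fixed_effects == FIXED_INTERACTION:
        lp = lp + state.xi[season - 1, sex - 1]
    elif spec.fixed_effects == FIXED_SEASON:
        lp = lp + state.gamma[season - 1]
    for jpos, j in enumerate(spec.anthro_features):
        x = np.asarray(obs["x"][j], float)
        if spec.anthro_by_season:
            b = state.beta[jpos, season - 1]
            p = state.phi[jpos, season - 1]
        else:
            b = state.beta[jpos]
            p = state.phi[jpos]
        lp = lp + b * np.exp(-p * x)
    return lp


def log_likelihood(state: ParameterState, obs, spec: ModelSpec) -> float:
    """Gaussian log likelihood sum_t log N(y_t | lambda*_t, sigma^2)."""
    if state.sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    y = np.asarray(obs["y"], float)
    if y.size == 0:
        return 0.0
    lp = linear_predictor_vec(state, obs, spec)
    resid = y - lp
    return float(-0.5 * y.size * math.log(2 * math.pi * state.sigma2)
                 - 0.5 * np.sum(resid ** 2) / state.sigma2)


def _norm_logpdf(x, var) -> float:
    x = np.asarray(x, float)
    return float(-0.5 * x.size * math.log(2 * math.pi * var) - 0.5 * np.sum(x ** 2) / var)


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    if x <= 0:
        return -math.inf
    return shape * math.log(rate) - math.lgamma(shape) + (shape - 1) * math.log(x) - rate * x


def log_prior(state: ParameterState, priors: Priors, spec: ModelSpec) -> float:
    """Joint log prior density of a parameter state.

    Densities are evaluated on the stored scale: the Ga(shape, rate) priors on
    the precisions 1/rho^2 and 1/sigma^2 include the change-of-variable
    Jacobian so the value is a proper density over rho2/sigma2 themselves.
    Returns -inf outside the uniform supports of nu and phi.
    """
    _check_dims(state, spec)
    if not (priors.nu_low <= state.nu <= priors.nu_high):
        return -math.inf
    if state.phi.size and not np.all((priors.phi_low <= state.phi) & (state.phi <= priors.phi_high)):
        return -math.inf
    if state.rho2 <= 0 or state.sigma2 <= 0 or state.psi <= 0:
        return -math.inf
    total = 0.0
    cov = build_covariance(state.nu, state.psi)
    for s in range(spec.n_strata):
        total += cov.logpdf(state.lam[s])
    total += _norm_logpdf(state.omega - state.alpha, state.rho2)
    total += _norm_logpdf(state.alpha - priors.alpha_mean, priors.alpha_var)
    # precision ~ Ga(shape, rate); density over the variance includes |d(1/v)/dv| = v^-2
    total += _gamma_logpdf(1.0 / state.rho2, priors.rho2_shape, priors.rho2_rate) - 2 * math.log(state.rho2)
    total += _gamma_logpdf(1.0 / state.sigma2, priors.sigma2_shape, priors.sigma2_rate) - 2 * math.log(state.sigma2)
    total += _gamma_logpdf(state.psi, priors.psi_shape, priors.psi_rate)
    total -= math.log(priors.nu_high - priors.nu_low)
    if spec.fixed_effects == FIXED_ADDITIVE:
        total += _norm_logpdf(state.mu[1:], priors.fixed_var)
        total += _norm_logpdf(state.gamma[1:], priors.fixed_var)
    elif spec.fixed_effects == FIXED_INTERACTION:
        # xi[0, 0] (female in spring) is the pinned reference category
        mask = np.ones_like(state.xi, dtype=bool)
        mask[0, 0] = False
        total += _norm_logpdf(state.xi[mask], priors.fixed_var)
    elif spec.fixed_effects == FIXED_SEASON:
        total += _norm_logpdf(state.gamma[1:], priors.fixed_var)
    if state.beta.size:
        total += _norm_logpdf(state.beta, priors.beta_var)
        total -= state.phi.size * math.log(priors.phi_high - priors.phi_low)
    return total
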