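"""Metropolis-within-Gibbs sampler for the circadian movement-rate model.

All Gaussian location blocks (the 24-vector hour effects jointly per stratum,
the individual random effects, their mean, the sex/season fixed effects and
the distance-decay amplitudes beta given phi) have conjugate normal full
conditionals and are Gibbs-updated in closed form.  The variance-type
parameters 1/sigma^2, 1/rho^2 and the covariance scale psi are conjugate
Gamma.  Only the hour-covariance decay nu and the distance decays phi need
Metropolis steps: adaptive random walks (log-scale for nu) reflected at their
uniform prior bounds, with Robbins-Monro step adaptation frozen after burn-in
so the post-burn-in kernel satisfies detailed balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .model import (
    FIXED_ADDITIVE, FIXED_INTERACTION, FIXED_SEASON, N_HOURS,
    ModelSpec, ParameterState, Priors, SEASON_NAMES, SEX_NAMES, build_covariance,
)
from .observations import ObservationTable

TARGET_ACCEPT = 0.35


@dataclass
class McmcConfig:
    """Chain protocol settings.

    The default profile is the full field-scale protocol: two chains, 50,000
    burn-in iterations, then 20,000 further iterations thinned by 10, giving
    2,000 retained posterior points per chain.  ``desk_scale()`` provides a
    light profile for interactive work and testing.  ``fixed`` pins named
    hyperparameters (``nu``, ``psi``, ``sigma2``, ``rho2``) at given values
    instead of sampling them.
    """

    n_chains: int = 2
    burn_in: int = 50_000
    keep_iters: int = 20_000
    thin: int = 10
    seed: int = 0
    adapt_during_burnin: bool = True
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.keep_iters % self.thin:
            raise ValueError("keep_iters must be divisible by thin")

    @classmethod
    def desk_scale(cls, seed: int = 0, **kw) -> "McmcConfig":
        kw.setdefault("burn_in", 2_000)
        kw.setdefault("keep_iters", 2_000)
        kw.setdefault("thin", 2)
        return cls(seed=seed, **kw)


class ParamLayout:
    """Mapping between a ParameterState and a flat named vector."""

    def __init__(self, spec: ModelSpec, n_animals: int, animal_ids=None):
        self.spec = spec
        self.n_animals = n_animals
        self.animal_ids = list(animal_ids) if animal_ids is not None else list(range(n_animals))
        names: list[str] = []
        for lab in spec.stratum_labels():
            names += [f"lam_{lab}_h{h:02d}" for h in range(1, N_HOURS + 1)]
        names += [f"omega_{a}" for a in self.animal_ids]
        names += ["alpha", "rho2"]
        self._mu_names, self._gamma_names, self._xi_names = [], [], []
        if spec.fixed_effects == FIXED_ADDITIVE:
            self._mu_names = ["mu_M"]
            self._gamma_names = [f"gamma_{SEASON_NAMES[r]}" for r in (2, 3, 4)]
        elif spec.fixed_effects == FIXED_SEASON:
            self._gamma_names = [f"gamma_{SEASON_NAMES[r]}" for r in (2, 3, 4)]
        elif spec.fixed_effects == FIXED_INTERACTION:
            self._xi_names = [f"xi_{SEASON_NAMES[r]}_{SEX_NAMES[s]}"
                              for s in (1, 2) for r in (1, 2, 3, 4) if not (r == 1 and s == 1)]
        names += self._mu_names + self._gamma_names + self._xi_names
        self._beta_names, self._phi_names = [], []
        for j in spec.anthro_features:
            if spec.anthro_by_season:
                self._beta_names += [f"beta_x{j}_{SEASON_NAMES[r]}" for r in (1, 2, 3, 4)]
                self._phi_names += [f"phi_x{j}_{SEASON_NAMES[r]}" for r in (1, 2, 3, 4)]
            else:
                self._beta_names += [f"beta_x{j}"]
                self._phi_names += [f"phi_x{j}"]
        names += self._beta_names + self._phi_names
        names += ["nu", "psi", "sigma2"]
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}

    @property
    def size(self) -> int:
        return len(self.names)

    def vector(self, state: ParameterState) -> np.ndarray:
        spec = self.spec
        parts = [state.lam.ravel(), state.omega, [state.alpha, state.rho2]]
        if spec.fixed_effects == FIXED_ADDITIVE:
            parts += [[state.mu[1]], state.gamma[1:]]
        elif spec.fixed_effects == FIXED_SEASON:
            parts += [state.gamma[1:]]
        elif spec.fixed_effects == FIXED_INTERACTION:
            xi = [state.xi[r - 1, s - 1] for s in (1, 2) for r in (1, 2, 3, 4) if not (r == 1 and s == 1)]
            parts += [xi]
        parts += [state.beta.ravel(), state.phi.ravel(), [state.nu, state.psi, state.sigma2]]
        return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])

    def state(self, vec: np.ndarray) -> ParameterState:
        spec = self.spec
        vec = np.asarray(vec, float)
        st = ParameterState.initial(spec, self.n_animals)
        pos = 0
        n_lam = spec.n_strata * N_HOURS
        st.lam = vec[pos:pos + n_lam].reshape(spec.n_strata, N_HOURS).copy(); pos += n_lam
        st.omega = vec[pos:pos + self.n_animals].copy(); pos += self.n_animals
        st.alpha, st.rho2 = vec[pos], vec[pos + 1]; pos += 2
        if spec.fixed_effects == FIXED_ADDITIVE:
            st.mu[1] = vec[pos]; pos += 1
            st.gamma[1:] = vec[pos:pos + 3]; pos += 3
        elif spec.fixed_effects == FIXED_SEASON:
            st.gamma[1:] = vec[pos:pos + 3]; pos += 3
        elif spec.fixed_effects == FIXED_INTERACTION:
            for s in (1, 2):
                for r in (1, 2, 3, 4):
                    if r == 1 and s == 1:
                        continue
                    st.xi[r - 1, s - 1] = vec[pos]; pos += 1
        nb = st.beta.size
        st.beta = vec[pos:pos + nb].reshape(st.beta.shape).copy(); pos += nb
        st.phi = vec[pos:pos + nb].reshape(st.phi.shape).copy(); pos += nb
        st.nu, st.psi, st.sigma2 = vec[pos], vec[pos + 1], vec[pos + 2]
        return st


@dataclass
class Chain:
    """A thinned sequence of post-burn-in posterior draws from one chain."""

    layout: ParamLayout
    draws: np.ndarray            # (n_draws, n_params)
    acceptance_rates: dict
    seed: int

    def __len__(self) -> int:
        return self.draws.shape[0]

    def get(self, name: str) -> np.ndarray:
        return self.draws[:, self.layout.index[name]]

    def states(self):
        for row in self.draws:
            yield self.layout.state(row)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a real number into [lo, hi] by reflection at the boundaries."""
    if hi <= lo:
        raise ValueError("empty reflection interval")
    period = 2.0 * (hi - lo)
    z = (x - lo) % period
    if z < 0:
        z += period
    return lo + (period - z if z > (hi - lo) else z)


class _GibbsSampler:
    """One-chain sampler state; see the module docstring for the scheme."""

    def __init__(self, obs: ObservationTable, spec: ModelSpec, priors: Priors,
                 config: McmcConfig, rng: np.random.Generator):
        self.obs, self.spec, self.priors, self.cfg, self.rng = obs, spec, priors, config, rng
        self.n = len(obs)
        self.K = obs.n_animals
        self.S = spec.n_strata
        self.y = obs.y
        self.hour0 = obs.hour - 1
        self.season0 = obs.season - 1
        self.sex0 = obs.sex - 1
        self.animal = obs.animal
        self.strat = spec.stratum_index(obs.season, obs.sex)
        self.cell = self.strat * N_HOURS + self.hour0
        self.n_cell = np.bincount(self.cell, minlength=self.S * N_HOURS).reshape(self.S, N_HOURS)
        self.n_k = np.bincount(self.animal, minlength=self.K).astype(float)
        self.state = ParameterState.initial(spec, self.K, priors)
        for name, val in config.fixed.items():
            if name not in ("nu", "psi", "sigma2", "rho2"):
                raise ValueError(f"cannot fix parameter {name!r}")
            setattr(self.state, name, float(val))
        # fixed-effect scalar blocks: (attr, index, record indices)
        self.fixed_blocks = []
        if spec.fixed_effects == FIXED_ADDITIVE:
            self.fixed_blocks.append(("mu", (1,), np.nonzero(self.sex0 == 1)[0]))
            for r in (1, 2, 3):
                self.fixed_blocks.append(("gamma", (r,), np.nonzero(self.season0 == r)[0]))
        elif spec.fixed_effects == FIXED_SEASON:
            for r in (1, 2, 3):
                self.fixed_blocks.append(("gamma", (r,), np.nonzero(self.season0 == r)[0]))
        elif spec.fixed_effects == FIXED_INTERACTION:
            for s in (0, 1):
                for r in (0, 1, 2, 3):
                    if r == 0 and s == 0:
                        continue
                    idx = np.nonzero((self.season0 == r) & (self.sex0 == s))[0]
                    self.fixed_blocks.append(("xi", (r, s), idx))
        # anthropogenic blocks: (jpos, j, season r or None, record indices)
        self.anthro_blocks = []
        for jpos, j in enumerate(spec.anthro_features):
            if spec.anthro_by_season:
                for r in range(4):
                    self.anthro_blocks.append((jpos, j, r, np.nonzero(self.season0 == r)[0]))
            else:
                self.anthro_blocks.append((jpos, j, None, np.arange(self.n)))
        self.xcov = {j: obs.x[j] for j in spec.anthro_features}
        # exp(-phi x) cache, one array per feature
        self.z = {}
        self._refresh_z()
        self._refresh_cov()
        self.lp = self._full_lp()
        # Metropolis bookkeeping: step sizes and acceptance counters
        self.steps = {"nu": 0.3}
        self.acc = {"nu": [0, 0]}
        for _, j, r, _idx in self.anthro_blocks:
            self.steps[self._phi_key(j, r)] = 0.5
            self.acc[self._phi_key(j, r)] = [0, 0]

    @staticmethod
    def _phi_key(j, r):
        return f"phi_x{j}" if r is None else f"phi_x{j}_{SEASON_NAMES[r + 1]}"

    def _refresh_z(self):
        st = self.state
        for jpos, j in enumerate(self.spec.anthro_features):
            p = st.phi[jpos, self.season0] if self.spec.anthro_by_season else st.phi[jpos]
            self.z[jpos] = np.exp(-p * self.xcov[j])

    def _refresh_cov(self):
        """Re-cache the unit-scale circulant C(nu), its inverse and eigenvalues."""
        C = build_covariance(self.state.nu, 1.0)
        self.C_eig = C.eigenvalues
        self.C_inv = C.inverse()

    def _lam_term(self):
        return self.state.lam[self.strat, self.hour0]

    def _fixed_term(self):
        st, spec = self.state, self.spec
        if spec.fixed_effects == FIXED_ADDITIVE:
            return st.mu[self.sex0] + st.gamma[self.season0]
        if spec.fixed_effects == FIXED_SEASON:
            return st.gamma[self.season0]
        if spec.fixed_effects == FIXED_INTERACTION:
            return st.xi[self.season0, self.sex0]
        return np.zeros(self.n)

    def _anthro_term(self):
        st = self.state
        out = np.zeros(self.n)
        for jpos in range(len(self.spec.anthro_features)):
            b = st.beta[jpos, self.season0] if self.spec.anthro_by_season else st.beta[jpos]
            out += b * self.z[jpos]
        return out

    def _full_lp(self):
        return (self._lam_term() + self.state.omega[self.animal]
                + self._fixed_term() + self._anthro_term())

    # ----- Gibbs blocks ---------------------------------------------------

    def update_lam(self):
        st = self.state
        r = self.y - self.lp + self._lam_term()
        sums = np.bincount(self.cell, weights=r, minlength=self.S * N_HOURS).reshape(self.S, N_HOURS) \
            if self.n else np.zeros((self.S, N_HOURS))
        prior_prec = st.psi * self.C_inv
        for s in range(self.S):
            P = prior_prec + np.diag(self.n_cell[s] / st.sigma2)
            c, low = cho_factor(P, lower=True)
            mean = cho_solve((c, low), sums[s] / st.sigma2)
            zdraw = self.rng.standard_normal(N_HOURS)
            st.lam[s] = mean + solve_triangular(c.T, zdraw, lower=False)
        # rebuild lp with the new hour effects
        self.lp = self._full_lp()

    def update_alpha_omega_rho2(self):
        """Joint block: alpha from its conditional with omega marginalized out
        (the per-animal residual means are N(alpha, sigma^2/n_k + rho^2)),
        then omega | alpha, then the conjugate 1/rho^2.  Collapsing omega is
        what lets alpha traverse its diffuse prior instead of random-walking
        against it."""
        st, pri = self.state, self.priors
        old = st.omega[self.animal] if self.n else None
        r = self.y - self.lp + (old if self.n else 0.0)
        sums = np.bincount(self.animal, weights=r, minlength=self.K) if self.n else np.zeros(self.K)
        has = self.n_k > 0
        marg_var = st.sigma2 / np.maximum(self.n_k, 1) + st.rho2
        a_prec = 1.0 / pri.alpha_var + float(np.sum(1.0 / marg_var[has]))
        a_mean = (pri.alpha_mean / pri.alpha_var
                  + float(np.sum((sums[has] / self.n_k[has]) / marg_var[has]))) / a_prec
        st.alpha = a_mean + self.rng.standard_normal() / math.sqrt(a_prec)
        prec = self.n_k / st.sigma2 + 1.0 / st.rho2
        mean = (sums / st.sigma2 + st.alpha / st.rho2) / prec
        st.omega = mean + self.rng.standard_normal(self.K) / np.sqrt(prec)
        if self.n:
            self.lp += st.omega[self.animal] - old
        if "rho2" not in self.cfg.fixed:
            shape = pri.rho2_shape + 0.5 * self.K
            rate = pri.rho2_rate + 0.5 * float(np.sum((st.omega - st.alpha) ** 2))
            st.rho2 = 1.0 / self.rng.gamma(shape, 1.0 / rate)

    def update_fixed(self):
        st, pri = self.state, self.priors
        for attr, idx, rows in self.fixed_blocks:
            arr = getattr(st, attr)
            cur = arr[idx]
            nmask = rows.size
            if nmask:
                r = self.y[rows] - self.lp[rows] + cur
                prec = nmask / st.sigma2 + 1.0 / pri.fixed_var
                mean = (r.sum() / st.sigma2) / prec
            else:
                prec = 1.0 / pri.fixed_var
                mean = 0.0
            new = mean + self.rng.standard_normal() / math.sqrt(prec)
            arr[idx] = new
            if nmask:
                self.lp[rows] += new - cur

    def update_beta(self):
        st, pri = self.state, self.priors
        for jpos, j, r, rows in self.anthro_blocks:
            bidx = (jpos, r) if r is not None else (jpos,)
            cur = st.beta[bidx]
            if rows.size:
                zr = self.z[jpos][rows]
                resid = self.y[rows] - self.lp[rows] + cur * zr
                prec = float(zr @ zr) / st.sigma2 + 1.0 / pri.beta_var
                mean = float(zr @ resid) / st.sigma2 / prec
            else:
                prec, mean = 1.0 / pri.beta_var, 0.0
            new = mean + self.rng.standard_normal() / math.sqrt(prec)
            st.beta[bidx] = new
            if rows.size:
                self.lp[rows] += (new - cur) * zr

    def update_phi(self, adapt: bool, t: int):
        st, pri = self.state, self.priors
        for jpos, j, r, rows in self.anthro_blocks:
            key = self._phi_key(j, r)
            bidx = (jpos, r) if r is not None else (jpos,)
            cur = st.phi[bidx]
            prop = _reflect(cur + self.steps[key] * self.rng.standard_normal(),
                            pri.phi_low, pri.phi_high)
            if rows.size:
                b = st.beta[bidx]
                x = self.xcov[j][rows]
                z0 = self.z[jpos][rows]
                z1 = np.exp(-prop * x)
                resid = self.y[rows] - self.lp[rows] + b * z0
                d0 = resid - b * z0
                d1 = resid - b * z1
                log_acc = -0.5 / st.sigma2 * (float(d1 @ d1) - float(d0 @ d0))
            else:
                log_acc = 0.0
            accept = math.log(self.rng.uniform()) < log_acc
            if accept:
                st.phi[bidx] = prop
                if rows.size:
                    self.z[jpos][rows] = z1
                    self.lp[rows] += b * (z1 - z0)
            self.acc[key][0] += int(accept)
            self.acc[key][1] += 1
            if adapt:
                gain = (t + 10) ** -0.6
                self.steps[key] = float(np.clip(
                    self.steps[key] * math.exp(gain * ((1.0 if accept else 0.0) - TARGET_ACCEPT)),
                    1e-4, pri.phi_high - pri.phi_low))

    def _lam_prior_logpdf(self, eig: np.ndarray) -> float:
        """Sum over strata of log MN(lam_s | 0, C/psi) up to constants."""
        st = self.state
        psi = st.psi
        quad = 0.0
        for s in range(self.S):
            lhat = np.fft.fft(st.lam[s])
            quad += float(np.sum((lhat * lhat.conj()).real / eig) / N_HOURS)
        logdet = self.S * (float(np.sum(np.log(eig))) - N_HOURS * math.log(psi))
        return -0.5 * logdet - 0.5 * psi * quad

    def update_nu(self, adapt: bool, t: int):
        st, pri = self.state, self.priors
        cur = st.nu
        lcur = math.log(cur)
        lprop = _reflect(lcur + self.steps["nu"] * self.rng.standard_normal(),
                         math.log(pri.nu_low), math.log(pri.nu_high))
        prop = math.exp(lprop)
        eig_prop = build_covariance(prop, 1.0).eigenvalues
        # log-scale proposal on a uniform-in-nu prior: Jacobian term log(prop/cur)
        log_acc = (self._lam_prior_logpdf(eig_prop) - self._lam_prior_logpdf(self.C_eig)
                   + (lprop - lcur))
        accept = math.log(self.rng.uniform()) < log_acc
        if accept:
            st.nu = prop
            self._refresh_cov()
        self.acc["nu"][0] += int(accept)
        self.acc["nu"][1] += 1
        if adapt:
            gain = (t + 10) ** -0.6
            self.steps["nu"] = float(np.clip(
                self.steps["nu"] * math.exp(gain * ((1.0 if accept else 0.0) - TARGET_ACCEPT)),
                1e-4, 10.0))

    def update_psi(self):
        st, pri = self.state, self.priors
        quad = 0.0
        for s in range(self.S):
            quad += float(st.lam[s] @ (self.C_inv @ st.lam[s]))
        shape = pri.psi_shape + 0.5 * self.S * N_HOURS
        rate = pri.psi_rate + 0.5 * quad
        st.psi = self.rng.gamma(shape, 1.0 / rate)

    def update_sigma2(self):
        st, pri = self.state, self.priors
        if self.n:
            resid = self.y - self.lp
            ssr = float(resid @ resid)
        else:
            ssr = 0.0
        shape = pri.sigma2_shape + 0.5 * self.n
        rate = pri.sigma2_rate + 0.5 * ssr
        st.sigma2 = 1.0 / self.rng.gamma(shape, 1.0 / rate)

    # ----- sweep ----------------------------------------------------------

    def sweep(self, adapt: bool, t: int):
        self.lp = self._full_lp()
        self.update_lam()
        self.update_alpha_omega_rho2()
        self.update_fixed()
        self.update_beta()
        self.update_phi(adapt, t)
        if "nu" not in self.cfg.fixed:
            self.update_nu(adapt, t)
        if "psi" not in self.cfg.fixed:
            self.update_psi()
        if "sigma2" not in self.cfg.fixed:
            self.update_sigma2()

    def acceptance_rates(self) -> dict:
        return {k: (a / n if n else 0.0) for k, (a, n) in self.acc.items()}

    def reset_acceptance(self):
        for k in self.acc:
            self.acc[k] = [0, 0]


def run_mcmc(records, spec: ModelSpec, priors: Priors | None = None,
             config: McmcConfig | None = None) -> list[Chain]:
    """Fit one model by Metropolis-within-Gibbs; returns one Chain per chain.

    ``records`` is an ObservationTable or an observation DataFrame.  The same
    config and seed give bit-identical chains.
    """
    priors = priors or Priors()
    config = config or McmcConfig()
    if not isinstance(records, ObservationTable):
        records = ObservationTable.from_dataframe(records)
    chains = []
    n_keep = config.keep_iters // config.thin
    for c in range(config.n_chains):
        chain_seed = int(config.seed) + c
        rng = np.random.default_rng(chain_seed)
        sampler = _GibbsSampler(records, spec, priors, config, rng)
        layout = ParamLayout(spec, records.n_animals, records.animal_ids)
        if not np.isfinite(records.y).all():
            raise RuntimeError("non-finite response y in the observation table")
        if not np.isfinite(sampler._full_lp()).all():
            raise RuntimeError("non-finite linear predictor at initialization")
        for t in range(config.burn_in):
            sampler.sweep(adapt=config.adapt_during_burnin, t=t)
        sampler.reset_acceptance()
        draws = np.empty((n_keep, layout.size))
        kept = 0
        for t in range(config.keep_iters):
            sampler.sweep(adapt=False, t=t)
            if (t + 1) % config.thin == 0:
                draws[kept] = layout.vector(sampler.state)
                kept += 1
        chains.append(Chain(layout=layout, draws=draws,
                            acceptance_rates=sampler.acceptance_rates(), seed=chain_seed))
    return chains


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------

def gelman_rubin(chains: list[Chain], parameter: str) -> float:
    """Potential scale reduction factor of one scalar parameter."""
    if len(chains) < 2:
        raise ValueError("gelman_rubin needs at least two chains")
    series = np.array([c.get(parameter) for c in chains])
    m, n = series.shape
    if n < 2:
        raise ValueError("chains too short for PSRF")
    chain_means = series.mean(axis=1)
    W = series.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else math.inf
    var_hat = (n - 1) / n * W + B / n
    return float(math.sqrt(var_hat / W))


def pooled(chains: list[Chain], parameter: str) -> np.ndarray:
    return np.concatenate([c.get(parameter) for c in chains])


def equal_tailed_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credibility interval (2.5% / 97.5% quantiles at 95%)."""
    a = (1.0 - prob) / 2.0
    lo, hi = np.quantile(draws, [a, 1.0 - a])
    return float(lo), float(hi)


def posterior_summary(chains: list[Chain], parameter: str, prob: float = 0.95):
    """Posterior mean and equal-tailed credibility interval, chains pooled."""
    draws = pooled(chains, parameter)
    lo, hi = equal_tailed_interval(draws, prob)
    return float(draws.mean()), lo, hi
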