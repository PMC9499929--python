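"""DIC computation and the 13-model selection table."""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

from .mcmc import Chain
from .model import MODEL_REGISTRY, ModelSpec, log_likelihood
from .observations import ObservationTable


@dataclass(frozen=True)
class DicResult:
    """Deviance Information Criterion for one fitted model.

    ``dbar`` is the posterior mean deviance, ``d_at_mean`` the deviance at
    the (pointwise, sampled-scale) posterior mean of every parameter, and
    ``p_d = dbar - d_at_mean`` the Spiegelhalter effective number of
    parameters, conditional on all sampled quantities including the hour
    effects and individual random effects.
    """

    spec_id: int
    dbar: float
    d_at_mean: float

    @property
    def p_d(self) -> float:
        return self.dbar - self.d_at_mean

    @property
    def dic(self) -> float:
        return self.dbar + self.p_d


def _deviance_draws(chains: list[Chain], obs: ObservationTable, spec: ModelSpec,
                    block: int = 256) -> np.ndarray:
    """D(theta) = -2 log L for every pooled draw, vectorized in blocks."""
    layout = chains[0].layout
    draws = np.vstack([c.draws for c in chains])
    n = len(obs)
    idx = layout.index
    hour0 = obs.hour - 1
    strat = spec.stratum_index(obs.season, obs.sex)
    lam_cols = np.array([idx[f"lam_{lab}_h{h:02d}"] for lab in spec.stratum_labels()
                         for h in range(1, 25)]).reshape(spec.n_strata, 24)
    rec_lam_col = lam_cols[strat, hour0]
    rec_omega_col = np.array([idx[f"omega_{a}"] for a in layout.animal_ids])[obs.animal]
    fixed_cols = []  # (column, record rows)
    for name in layout._mu_names + layout._gamma_names + layout._xi_names:
        if name == "mu_M":
            rows = np.nonzero(obs.sex == 2)[0]
        elif name.startswith("gamma_"):
            season = name[len("gamma_"):]
            rows = np.nonzero(_season_mask(obs, season))[0]
        else:  # xi_<season>_<sex>
            season, sexname = name[len("xi_"):].rsplit("_", 1)
            rows = np.nonzero(_season_mask(obs, season) & (obs.sex == (1 if sexname == "F" else 2)))[0]
        fixed_cols.append((idx[name], rows))
    anthro = []  # (beta col, phi col, rows, x)
    for bname, pname in zip(layout._beta_names, layout._phi_names):
        j = int(bname.split("_x")[1].split("_")[0])
        if spec.anthro_by_season:
            season = bname.split(f"beta_x{j}_")[1]
            rows = np.nonzero(_season_mask(obs, season))[0]
        else:
            rows = np.arange(n)
        anthro.append((idx[bname], idx[pname], rows, obs.x[j][rows]))
    sig_col = idx["sigma2"]
    out = np.empty(draws.shape[0])
    for lo in range(0, draws.shape[0], block):
        chunk = draws[lo:lo + block]
        lp = chunk[:, rec_lam_col] + chunk[:, rec_omega_col]
        for col, rows in fixed_cols:
            lp[:, rows] += chunk[:, col][:, None]
        for bcol, pcol, rows, x in anthro:
            lp[:, rows] += chunk[:, bcol][:, None] * np.exp(-chunk[:, pcol][:, None] * x[None, :])
        resid = obs.y[None, :] - lp
        sigma2 = chunk[:, sig_col]
        out[lo:lo + chunk.shape[0]] = (n * np.log(2 * math.pi * sigma2)
                                       + (resid ** 2).sum(axis=1) / sigma2)
    return out


def _season_mask(obs: ObservationTable, season_name: str) -> np.ndarray:
    from .model import SEASON_NAMES
    r = {v: k for k, v in SEASON_NAMES.items()}[season_name]
    return obs.season == r


def compute_dic(chains: list[Chain], records, spec: ModelSpec) -> DicResult:
    """DIC of a fitted model from its pooled posterior draws.

    The plug-in deviance is evaluated at the pointwise posterior mean of each
    parameter on its sampled scale (e.g. the mean of sigma^2, not of the
    precision).
    """
    if not chains or not len(chains[0]):
        raise ValueError("compute_dic needs non-empty chains")
    if not isinstance(records, ObservationTable):
        records = ObservationTable.from_dataframe(records)
    dev = _deviance_draws(chains, records, spec)
    dbar = float(dev.mean())
    mean_vec = np.vstack([c.draws for c in chains]).mean(axis=0)
    mean_state = chains[0].layout.state(mean_vec)
    d_at_mean = -2.0 * log_likelihood(mean_state, records, spec)
    return DicResult(spec_id=spec.id, dbar=dbar, d_at_mean=d_at_mean)


def selection_table(results: list[DicResult]) -> pd.DataFrame:
    """Model-ranking table: ascending DIC with differences to the best model.

    The K column counts the parameter blocks in interaction with season
    and/or sex, for parity with the published layout.
    """
    if not results:
        raise ValueError("selection_table needs at least one DicResult")
    rows = []
    best = min(r.dic for r in results)
    for r in sorted(results, key=lambda r: r.dic):
        spec = MODEL_REGISTRY.get(r.spec_id)
        rows.append({
            "spec_id": r.spec_id,
            "formula": spec.formula() if spec else "",
            "K": spec.k_interaction if spec else np.nan,
            "dbar": r.dbar,
            "p_d": r.p_d,
            "dic": r.dic,
            "delta_dic": r.dic - best,
        })
    return pd.DataFrame(rows)
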