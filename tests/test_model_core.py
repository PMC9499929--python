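"""Covariance kernel, model registry, linear predictor, likelihood, priors."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bearclock.model import (
    MODEL_REGISTRY, HourCovariance, ParameterState, Priors,
    anthropogenic_effect, build_covariance, circular_hour_distance,
    linear_predictor, linear_predictor_vec, log_likelihood, log_prior,
    registry_from_json, registry_to_json,
)

# ---------------------------------------------------------------------------
# circular hour distance
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("i,i2,expected", [
    (24, 1, 1),    # midnight and 01:00 are one hour apart on the clock circle
    (5, 5, 0),
    (1, 13, 12),
    (2, 23, 3),
])
def test_circular_distance_examples(i, i2, expected):
    assert circular_hour_distance(i, i2) == expected


@given(st.integers(1, 24), st.integers(1, 24))
@settings(derandomize=True)
def test_circular_distance_brute_force(i, i2):
    """Matches the minimum walk length around an explicit 24-cycle."""
    brute = min((i - i2) % 24, (i2 - i) % 24)
    assert circular_hour_distance(i, i2) == brute
    assert circular_hour_distance(i2, i) == circular_hour_distance(i, i2)
    assert circular_hour_distance(i, i2) <= 12


def test_circular_distance_range_check():
    with pytest.raises(ValueError):
        circular_hour_distance(0, 5)
    with pytest.raises(ValueError):
        circular_hour_distance(1, 25)


# ---------------------------------------------------------------------------
# hour covariance
# ---------------------------------------------------------------------------


def test_covariance_diagonal_and_named_entry():
    cov = build_covariance(3.0, 2.0)
    M = cov.matrix
    assert np.allclose(np.diag(M), 1.0 / 2.0)
    # neighbouring hours at nu=3, psi=1: exp(-3)
    assert math.isclose(build_covariance(3.0, 1.0).matrix[0, 1], math.exp(-3.0))


def test_covariance_structure_random(rng):
    for _ in range(20):
        nu = rng.uniform(3 / 24, 3.0)
        psi = rng.uniform(0.2, 50.0)
        cov = build_covariance(nu, psi)
        M = cov.matrix
        assert np.allclose(M, M.T)
        # circulant: every row is a rotation of the first
        for i in range(24):
            assert np.allclose(M[i], np.roll(M[0], i))
        assert np.linalg.eigvalsh(M).min() > 0


def test_covariance_eigenvalues_are_dft_of_first_row():
    cov = build_covariance(0.7, 3.0)
    assert np.allclose(np.sort(cov.eigenvalues),
                       np.sort(np.linalg.eigvalsh(cov.matrix)))


def test_spectral_inverse_and_quadform_match_dense(rng):
    for _ in range(10):
        cov = build_covariance(rng.uniform(0.2, 3.0), rng.uniform(0.5, 20.0))
        dense_inv = np.linalg.inv(cov.matrix)
        assert np.abs(cov.inverse() - dense_inv).max() < 1e-8
        v = rng.normal(size=24)
        assert math.isclose(cov.quad_form(v), v @ dense_inv @ v, rel_tol=1e-9)
        sign, logdet = np.linalg.slogdet(cov.matrix)
        assert sign > 0 and math.isclose(cov.logdet(), logdet, rel_tol=1e-9)


def test_covariance_limits():
    # strong decay -> independent hours; vanishing decay -> rigid (constant) curve
    assert np.allclose(build_covariance(50.0, 4.0).matrix, np.eye(24) / 4.0, atol=1e-12)
    assert np.allclose(build_covariance(1e-9, 4.0).matrix, np.full((24, 24), 0.25), atol=1e-6)


def test_covariance_rejects_bad_parameters():
    for nu, psi in [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)]:
        with pytest.raises(ValueError):
            build_covariance(nu, psi)


def test_covariance_mn_logpdf_matches_scipy(rng):
    cov = build_covariance(0.9, 7.0)
    v = rng.normal(size=24) * 0.3
    expected = stats.multivariate_normal(mean=np.zeros(24), cov=cov.matrix).logpdf(v)
    assert math.isclose(cov.logpdf(v), expected, rel_tol=1e-9)


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

EXPECTED_FORMULAS = {
    1: "lambda_i + omega_k",
    2: "lambda_i + omega_k + mu_s + gamma_r + beta_1*exp(-phi_1*x_1tk) + beta_4*exp(-phi_4*x_4tk)",
    3: "lambda_i + omega_k + mu_s + gamma_r + beta_2*exp(-phi_2*x_2tk) + beta_3*exp(-phi_3*x_3tk) + beta_4*exp(-phi_4*x_4tk)",
    4: "lambda_irs + omega_k + mu_s + gamma_r + beta_1r*exp(-phi_1r*x_1tk) + beta_4r*exp(-phi_4r*x_4tk)",
    5: "lambda_irs + omega_k + mu_s + gamma_r + beta_2r*exp(-phi_2r*x_2tk) + beta_3r*exp(-phi_3r*x_3tk) + beta_4r*exp(-phi_4r*x_4tk)",
    6: "lambda_irs + omega_k + xi_rs + beta_1*exp(-phi_1*x_1tk) + beta_4*exp(-phi_4*x_4tk)",
    7: "lambda_irs + omega_k + xi_rs + beta_2*exp(-phi_2*x_2tk) + beta_3*exp(-phi_3*x_3tk) + beta_4*exp(-phi_4*x_4tk)",
    8: "lambda_irs + omega_k + xi_rs + beta_1r*exp(-phi_1r*x_1tk) + beta_4r*exp(-phi_4r*x_4tk)",
    9: "lambda_irs + omega_k + xi_rs + beta_2r*exp(-phi_2r*x_2tk) + beta_3r*exp(-phi_3r*x_3tk) + beta_4r*exp(-phi_4r*x_4tk)",
    10: "lambda_ir + omega_k + gamma_r + beta_1*exp(-phi_1*x_1tk) + beta_4*exp(-phi_4*x_4tk)",
    11: "lambda_ir + omega_k + gamma_r + beta_2*exp(-phi_2*x_2tk) + beta_3*exp(-phi_3*x_3tk) + beta_4*exp(-phi_4*x_4tk)",
    12: "lambda_ir + omega_k + gamma_r + beta_1r*exp(-phi_1r*x_1tk) + beta_4r*exp(-phi_4r*x_4tk)",
    13: "lambda_ir + omega_k + gamma_r + beta_2r*exp(-phi_2r*x_2tk) + beta_3r*exp(-phi_3r*x_3tk) + beta_4r*exp(-phi_4r*x_4tk)",
}
EXPECTED_K = {1: 0, 2: 0, 3: 0, 4: 3, 5: 4, 6: 2, 7: 2, 8: 4, 9: 5,
              10: 1, 11: 1, 12: 3, 13: 4}


def test_registry_enumerates_all_thirteen_formulas():
    assert sorted(MODEL_REGISTRY) == list(range(1, 14))
    for i, spec in MODEL_REGISTRY.items():
        assert spec.formula() == EXPECTED_FORMULAS[i]
        assert spec.k_interaction == EXPECTED_K[i]


def test_registry_json_round_trip(tmp_path):
    path = tmp_path / "registry.json"
    registry_to_json(path)
    loaded = registry_from_json(path.read_text())
    assert loaded == MODEL_REGISTRY
    assert len(json.loads(path.read_text())) == 13


# ---------------------------------------------------------------------------
# anthropogenic effect
# ---------------------------------------------------------------------------


def test_anthropogenic_effect_shape():
    assert anthropogenic_effect(0.4, 2.0, 0.0) == pytest.approx(0.4)
    assert anthropogenic_effect(0.4, 2.0, 50.0) == pytest.approx(0.0, abs=1e-12)
    # at the practical range x = 3/phi the effect has dropped to e^-3 of beta
    phi = 1.7
    assert anthropogenic_effect(1.0, phi, 3.0 / phi) == pytest.approx(math.exp(-3.0))
    with pytest.raises(ValueError):
        anthropogenic_effect(0.4, 2.0, -0.1)
    with pytest.raises(ValueError):
        anthropogenic_effect(0.4, -2.0, 0.1)


# ---------------------------------------------------------------------------
# linear predictor
# ---------------------------------------------------------------------------


def _record(hour=1, season=1, sex=1, animal=0, x=(1.0, 1.0, 1.0, 1.0)):
    return dict(hour_index=hour, season=season, sex=sex, animal_index=animal,
                x1=x[0], x2=x[1], x3=x[2], x4=x[3])


def test_linear_predictor_base_model_sum():
    spec = MODEL_REGISTRY[1]
    st_ = ParameterState.initial(spec, n_animals=2)
    st_.lam[0, 2] = 0.2
    st_.omega[1] = 0.1
    got = linear_predictor(st_, _record(hour=3, animal=1), spec)
    assert got == pytest.approx(0.3)


def test_full_model_reduces_when_betas_vanish():
    spec = MODEL_REGISTRY[9]
    rng = np.random.default_rng(7)
    st_ = ParameterState.initial(spec, n_animals=3)
    st_.lam = rng.normal(size=st_.lam.shape)
    st_.omega = rng.normal(size=3)
    st_.xi = rng.normal(size=(4, 2))
    st_.beta[:] = 0.0
    rec = _record(hour=11, season=3, sex=2, animal=2)
    strat = spec.stratum_index(np.array([3]), np.array([2]))[0]
    expected = st_.lam[strat, 10] + st_.omega[2] + st_.xi[2, 1]
    assert linear_predictor(st_, rec, spec) == pytest.approx(expected)


def _oracle_lp(state, rec, spec):
    """Independent term-by-term re-evaluation of the published formulas."""
    hour = rec["hour_index"] - 1
    r, s, k = rec["season"], rec["sex"], rec["animal_index"]
    if spec.hour_effect == "hour_only":
        lp = state.lam[0, hour]
    elif spec.hour_effect == "hour_by_season":
        lp = state.lam[r - 1, hour]
    else:
        lp = state.lam[(s - 1) * 4 + (r - 1), hour]
    lp += state.omega[k]
    if spec.fixed_effects == "additive":
        lp += state.mu[s - 1] + state.gamma[r - 1]
    elif spec.fixed_effects == "season_only":
        lp += state.gamma[r - 1]
    elif spec.fixed_effects == "interaction":
        lp += state.xi[r - 1, s - 1]
    for jpos, j in enumerate(spec.anthro_features):
        b = state.beta[jpos, r - 1] if spec.anthro_by_season else state.beta[jpos]
        p = state.phi[jpos, r - 1] if spec.anthro_by_season else state.phi[jpos]
        lp += b * math.exp(-p * rec[f"x{j}"])
    return lp


@pytest.mark.parametrize("spec_id", sorted(MODEL_REGISTRY))
def test_linear_predictor_matches_term_by_term_oracle(spec_id, rng):
    spec = MODEL_REGISTRY[spec_id]
    st_ = ParameterState.initial(spec, n_animals=4)
    st_.lam = rng.normal(size=st_.lam.shape)
    st_.omega = rng.normal(size=4)
    st_.mu = rng.normal(size=2)
    st_.gamma = rng.normal(size=4)
    st_.xi = rng.normal(size=(4, 2))
    if st_.beta.size:
        st_.beta = rng.normal(size=st_.beta.shape)
        st_.phi = rng.uniform(0.75, 15.0, size=st_.phi.shape)
    for _ in range(10):
        rec = _record(hour=int(rng.integers(1, 25)), season=int(rng.integers(1, 5)),
                      sex=int(rng.integers(1, 3)), animal=int(rng.integers(0, 4)),
                      x=tuple(rng.uniform(0, 4, size=4)))
        assert linear_predictor(st_, rec, spec) == pytest.approx(_oracle_lp(st_, rec, spec))


def test_linear_predictor_linear_in_beta_and_lambda(rng):
    spec = MODEL_REGISTRY[9]
    st_ = ParameterState.initial(spec, n_animals=2)
    st_.phi[:] = 2.0
    rec = _record(hour=6, season=2, sex=1, x=(0.5, 0.5, 1.0, 2.0))
    for setter, stepval in [
        (lambda v: st_.beta.__setitem__((0, 1), v), 0.7),
        (lambda v: st_.lam.__setitem__((0 * 4 + 1, 5), v), 0.7),
    ]:
        setter(0.0)
        f0 = linear_predictor(st_, rec, spec)
        setter(1.0)
        f1 = linear_predictor(st_, rec, spec)
        setter(stepval)
        fs = linear_predictor(st_, rec, spec)
        assert fs == pytest.approx(f0 + stepval * (f1 - f0))


def test_linear_predictor_dimension_mismatch():
    spec9 = MODEL_REGISTRY[9]
    st1 = ParameterState.initial(MODEL_REGISTRY[1], n_animals=2)
    with pytest.raises(ValueError):
        linear_predictor(st1, _record(), spec9)


# ---------------------------------------------------------------------------
# likelihood and prior
# ---------------------------------------------------------------------------


def _obs(rng, spec, n=30, n_animals=3):
    return dict(hour=rng.integers(1, 25, n), season=rng.integers(1, 5, n),
                sex=rng.integers(1, 3, n), animal=rng.integers(0, n_animals, n),
                x={j: rng.uniform(0, 4, n) for j in (1, 2, 3, 4)},
                y=rng.normal(0.5, 0.3, n))


def test_log_likelihood_exact_and_additive(rng):
    spec = MODEL_REGISTRY[1]
    st_ = ParameterState.initial(spec, n_animals=1)
    st_.lam[0, 0] = 0.4
    obs = dict(hour=np.array([1]), season=np.array([1]), sex=np.array([1]),
               animal=np.array([0]), x={j: np.zeros(1) for j in (1, 2, 3, 4)},
               y=np.array([0.4]))
    assert log_likelihood(st_, obs, spec) == pytest.approx(-0.5 * math.log(2 * math.pi))
    doubled = {k: (np.tile(v, 2) if not isinstance(v, dict)
                   else {j: np.tile(a, 2) for j, a in v.items()}) for k, v in obs.items()}
    assert log_likelihood(st_, doubled, spec) == pytest.approx(
        2 * log_likelihood(st_, obs, spec))


def test_log_likelihood_matches_scipy_density_sum(rng):
    spec = MODEL_REGISTRY[9]
    st_ = ParameterState.initial(spec, n_animals=3)
    st_.lam = rng.normal(size=st_.lam.shape) * 0.2
    st_.beta = rng.normal(size=st_.beta.shape) * 0.1
    st_.sigma2 = 0.07
    obs = _obs(rng, spec)
    lp = linear_predictor_vec(st_, obs, spec)
    expected = stats.norm(lp, math.sqrt(st_.sigma2)).logpdf(obs["y"]).sum()
    assert log_likelihood(st_, obs, spec) == pytest.approx(expected)


def test_log_prior_uniform_supports():
    spec = MODEL_REGISTRY[9]
    priors = Priors()
    st_ = ParameterState.initial(spec, n_animals=2)
    good = log_prior(st_, priors, spec)
    assert np.isfinite(good)
    st_.phi[0, 0] = 20.0            # outside Unif(3/4, 15)
    assert log_prior(st_, priors, spec) == -math.inf
    st_ = ParameterState.initial(spec, n_animals=2)
    st_.nu = 0.1                     # below 3/24
    assert log_prior(st_, priors, spec) == -math.inf


def test_log_prior_matches_term_by_term_oracle(rng):
    spec = MODEL_REGISTRY[9]
    priors = Priors()
    st_ = ParameterState.initial(spec, n_animals=3)
    st_.lam = rng.normal(size=st_.lam.shape) * 0.2
    st_.omega = rng.normal(0.5, 0.2, size=3)
    st_.alpha, st_.rho2 = 0.5, 0.04
    st_.xi = rng.normal(size=(4, 2)) * 0.1
    st_.xi[0, 0] = 0.0
    st_.beta = rng.normal(size=st_.beta.shape) * 0.2
    st_.phi = rng.uniform(0.75, 15.0, size=st_.phi.shape)
    st_.nu, st_.psi, st_.sigma2 = 0.8, 5.0, 0.09

    cov = build_covariance(st_.nu, st_.psi).matrix
    expected = sum(stats.multivariate_normal(np.zeros(24), cov).logpdf(st_.lam[s])
                   for s in range(8))
    expected += stats.norm(st_.alpha, math.sqrt(st_.rho2)).logpdf(st_.omega).sum()
    expected += stats.norm(0, math.sqrt(priors.alpha_var)).logpdf(st_.alpha)
    # Ga(1,1) on the precisions, written as a density over the variances
    for v in (st_.rho2, st_.sigma2):
        expected += stats.gamma(1, scale=1).logpdf(1 / v) - 2 * math.log(v)
    expected += stats.gamma(1, scale=1).logpdf(st_.psi)
    expected += math.log(1.0 / (priors.nu_high - priors.nu_low))
    mask = np.ones((4, 2), bool)
    mask[0, 0] = False
    expected += stats.norm(0, math.sqrt(priors.fixed_var)).logpdf(st_.xi[mask]).sum()
    expected += stats.norm(0, math.sqrt(priors.beta_var)).logpdf(st_.beta).sum()
    expected += st_.phi.size * math.log(1.0 / (priors.phi_high - priors.phi_low))
    assert log_prior(st_, priors, spec) == pytest.approx(expected)
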