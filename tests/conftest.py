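import numpy as np
import pytest

from viscofit import (
    ContactGeometry,
    GeneralizedKelvinVoigt,
    GeneralizedMaxwell,
    RampProtocol,
    simulate_curve,
)

# bead probe: 25 um diameter polystyrene sphere, incompressible sample
GEOM = ContactGeometry(R=12.5e-6, nu=0.5)


@pytest.fixture(scope="session")
def geom():
    return GEOM


@pytest.fixture(scope="session")
def sls_model():
    """Standard linear solid: Ge=100 Pa, one arm (300 Pa, 1 ms)."""
    return GeneralizedMaxwell(Ge=100.0, arms=((300.0, 1e-3),))


@pytest.fixture(scope="session")
def sls_kv_model():
    """The physically equivalent compliance twin of sls_model."""
    return GeneralizedKelvinVoigt(Jg=2.5e-3, arms=((7.5e-3, 4e-3),))


@pytest.fixture(scope="session")
def elastic_model():
    return GeneralizedMaxwell(Ge=1000.0)


def make_curve(model, duration=0.02, speed=2e-6, sampling_rate=50e3,
               noise_sd=0.0, seed=0, geom=GEOM):
    protocol = RampProtocol(
        speed=speed, sampling_rate=sampling_rate,
        max_force=None, max_indentation=speed * duration,
        noise_sd=noise_sd, seed=seed,
    )
    return simulate_curve(model, protocol, geom)


@pytest.fixture(scope="session")
def sls_curve(sls_model):
    return make_curve(sls_model)


@pytest.fixture(scope="session")
def elastic_curve(elastic_model):
    return make_curve(elastic_model)


def max_param_rel_err(fit_model, true_model) -> float:
    """Largest relative parameter error between two same-shape Maxwell models."""
    a = np.array([fit_model.Ge] + [v for arm in fit_model.arms for v in arm])
    b = np.array([true_model.Ge] + [v for arm in true_model.arms for v in arm])
    assert a.size == b.size, "models have different arm counts"
    return float(np.max(np.abs(a - b) / b))


def oracle_force(model, t, h, geom):
    """O(n^2) trapezoidal double-loop evaluation of the hereditary force.

    Independent of the production recursive-filter path: the integrand
    ``G'(t_i - t_j) * h(t_j)^{3/2}`` is evaluated directly and summed with
    explicit trapezoid weights, row by row.
    """
    from viscofit.hereditary import lr_prefactor

    t = np.asarray(t, float)
    y = np.asarray(h, float) ** 1.5
    dt = t[1] - t[0]
    n = t.size
    out = np.empty(n)
    for i in range(n):
        lags = t[i] - t[: i + 1]
        gp = np.zeros(i + 1)
        for gn, tau in model.arms:
            gp += -(gn / tau) * np.exp(-lags / tau)
        w = np.ones(i + 1)
        w[0] = 0.5
        w[-1] = 0.5
        conv = dt * float(w @ (gp * y[: i + 1])) if i > 0 else 0.0
        out[i] = model.glassy_modulus * y[i] + conv
    return lr_prefactor(geom) * out
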