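import math

import pytest

from stemlineage import (
    evaluate_controls,
    make_model3,
    make_model5,
    solve_mixed,
)

EPS = 0.005

# closed-form mixed equilibria in scaled coordinates
M3_X0 = -math.log(1.0 - math.log(2.0) / 3.0)
M3_Y0 = math.log(2.0) / 3.0
M5_X0 = math.log(1.5) / 2.0
M5_Y0 = (math.log(3.0) - math.log(1.5)) / 0.2


def m3_controls_analytic(x: float, y: float, eps: float):
    """Hand-differentiated controls of the first preset (independent oracle)."""
    u = 1.0 - math.exp(-x)
    q_x = eps * 2.0 * math.exp(-x) * y / (u + y) ** 2
    q_y = eps * 2.0 * (math.exp(-x) - 1.0) / (u + y) ** 2
    p_x = 0.0
    p_y = eps * 3.0 * math.exp(-3.0 * y)
    return q_x, q_y, p_x, p_y


def m5_controls_analytic(x: float, y: float, eps: float):
    sech2 = 1.0 / math.cosh(x + 0.1 * y) ** 2
    q_x = eps * 1.6 / math.cosh(x) ** 2 / (2.0 * math.tanh(x) + 0.4) ** 2
    return q_x, 0.0, eps * sech2, eps * 0.1 * sech2


@pytest.fixture(scope="session")
def model3():
    return make_model3(EPS, 0.5)


@pytest.fixture(scope="session")
def model5():
    return make_model5(EPS, 0.5)


@pytest.fixture(scope="session")
def model3_eq(model3):
    return solve_mixed(model3)


@pytest.fixture(scope="session")
def model5_eq(model5):
    return solve_mixed(model5)


@pytest.fixture(scope="session")
def model3_controls(model3, model3_eq):
    return evaluate_controls(model3, model3.scaled(model3_eq.i0, model3_eq.j0))


@pytest.fixture(scope="session")
def model5_controls(model5, model5_eq):
    return evaluate_controls(model5, model5.scaled(model5_eq.i0, model5_eq.j0))
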