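"""GIN condition: surrogate algebra, empirical test, population oracle, and
the oracle <-> trek-criterion equivalence."""

import itertools

import numpy as np
import pytest

from ivgin.gin import (
    DegenerateCovarianceError,
    gin_test,
    iv_gin_test,
    population_gin_oracle,
    population_iv_gin_oracle,
    solve_omega,
)
from ivgin.graphs import instrument_criteria_holds, ivgin_graphical_criterion, load_fixture
from ivgin.scenarios import fig3_sem, fig8_sem
from ivgin.sem import LinearSEM, NoiseSpec

from conftest import draw_query, random_linear_sem


# ---------------------------------------------------------------------------
# omega
# ---------------------------------------------------------------------------

def test_omega_simple_null_vector():
    np.testing.assert_allclose(
        solve_omega(np.array([[1.0], [0.0]])), [0.0, 1.0], atol=1e-12
    )


def test_omega_for_valid_instrument_population():
    # P = (Y, X), Q = (Z): cross-covariance (2, 2) -> surrogate ~ Y - X
    omega = solve_omega(np.array([[2.0], [2.0]]))
    np.testing.assert_allclose(omega, [1.0, -1.0] / np.sqrt(2.0), atol=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_omega_is_unit_norm_left_null_vector(seed):
    rng = np.random.default_rng(seed)
    q = int(rng.integers(1, 4))
    sigma = rng.normal(size=(q + 1, q))
    omega = solve_omega(sigma)
    np.testing.assert_allclose(omega @ sigma, 0.0, atol=1e-10)
    assert np.linalg.norm(omega) == pytest.approx(1.0)
    first_nonzero = omega[np.abs(omega) > 1e-12][0]
    assert first_nonzero > 0


def test_omega_shape_requirements():
    with pytest.raises(ValueError):
        solve_omega(np.ones((2, 2)))  # |P| = |Q|
    with pytest.raises(ValueError):
        solve_omega(np.ones((4, 2)))  # null space dimension >= 2


def test_omega_degenerate_covariance_warns():
    sigma = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])  # rank 1
    with pytest.warns(UserWarning, match="rank-deficient"):
        _, degenerate = solve_omega(sigma, return_degenerate=True)
    assert degenerate


# ---------------------------------------------------------------------------
# empirical GIN test
# ---------------------------------------------------------------------------

def test_gin_holds_for_valid_instrument_sample():
    data = fig3_sem("a", "uniform").sample(5000, seed=0)
    res = gin_test(data, ["Y", "X"], ["Z"], alpha=0.01, seed=1)
    assert res.holds
    assert np.linalg.norm(res.omega) == pytest.approx(1.0)
    assert len(res.surrogate) == 5000


def test_gin_rejected_for_confounded_instrument_sample():
    data = fig3_sem("b", "uniform").sample(5000, seed=0)
    res = gin_test(data, ["Y", "X"], ["Z"], alpha=0.01, seed=1)
    assert not res.holds


def test_gin_blind_under_gaussian_noise():
    # with Gaussian noise the surrogate is uncorrelated with Q hence
    # independent: the test cannot flag the invalid instrument
    data = fig3_sem("b", "gaussian").sample(5000, seed=0)
    res = gin_test(data, ["Y", "X"], ["Z"], alpha=0.01, seed=1)
    assert res.holds


def test_gaussian_rejection_stays_near_level():
    rejections = 0
    reps = 40
    for r in range(reps):
        data = fig3_sem("b", "gaussian").sample(2000, seed=100 + r)
        res = gin_test(data, ["Y", "X"], ["Z"], alpha=0.01, seed=r)
        rejections += not res.holds
    assert rejections / reps <= 0.1


def test_gin_input_validation():
    data = fig3_sem("a").sample(300, seed=0)
    with pytest.raises(ValueError):
        gin_test(data, [], ["Z"])
    with pytest.raises(ValueError):
        iv_gin_test(data, "Z", {"Z"}, "X", "Y")


# ---------------------------------------------------------------------------
# conditional IV-GIN on worked examples
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "fixture, w, expected",
    [
        ("fig5", ("W1",), True),
        ("fig5", ("W2",), False),  # conditioning on a descendant of Y
        ("fig6", ("W1",), False),  # unblockable nondirected path
    ],
)
def test_conditional_ivgin_on_worked_examples(fixture, w, expected):
    g = load_fixture(fixture)
    rng = np.random.default_rng(5)
    coeffs = {
        e: float(rng.choice([-1, 1]) * rng.uniform(0.5, 2.0)) for e in g.edges
    }
    sem = LinearSEM(g, coeffs, NoiseSpec("squared_exponential"))
    assert population_iv_gin_oracle(sem, "Z", set(w), "X", "Y") is expected
    data = sem.sample(5000, seed=9)
    assert iv_gin_test(data, "Z", set(w), "X", "Y", 0.01, seed=2).holds is expected


# ---------------------------------------------------------------------------
# population oracle
# ---------------------------------------------------------------------------

def test_oracle_on_motivating_mechanisms():
    assert population_gin_oracle(fig3_sem("a"), ["Y", "X"], ["Z"])
    assert not population_gin_oracle(fig3_sem("b"), ["Y", "X"], ["Z"])


@pytest.mark.parametrize("lam", [0.0, 0.5, 1.0, 2.0])
def test_oracle_blind_to_direct_instrument_outcome_effect(lam):
    # the surrogate removes eps_Z exactly, whatever the direct-edge strength
    assert population_gin_oracle(fig8_sem(lam), ["Y", "X"], ["Z"])


@pytest.mark.parametrize("lam", [0.0, 0.5, 1.0, 2.0])
def test_direct_effect_surrogate_has_zero_instrument_noise_loading(lam):
    sem = fig8_sem(lam)
    A = sem.noise_mixing()
    sigma = sem.cross_cov(["Y", "X"], ["Z"])
    omega = solve_omega(sigma)
    beta = omega @ A.loc[["Y", "X"]].to_numpy()
    z_idx = list(sem.node_order).index("Z")
    assert abs(beta[z_idx]) < 1e-12


def test_oracle_respects_gaussian_flags():
    # all-Gaussian noise: shared components never count as detectable
    assert population_gin_oracle(fig3_sem("b", "gaussian"), ["Y", "X"], ["Z"])


def test_oracle_raises_on_degenerate_covariance():
    sem = fig3_sem("a")
    # Q disconnected from P: zero cross-covariance, null space dim >= 2
    g = sem.graph
    from ivgin.graphs import DirectedGraph

    g2 = DirectedGraph(
        [e for e in g.edges if e != ("Z", "X")], latent=g.latent, nodes=g.nodes
    )
    coeffs = {e: sem.coefficients[e] for e in g2.edges}
    sem2 = LinearSEM(g2, coeffs, NoiseSpec("uniform"))
    with pytest.raises(DegenerateCovarianceError):
        population_gin_oracle(sem2, ["Y", "X"], ["Z"])


# ---------------------------------------------------------------------------
# batteries
# ---------------------------------------------------------------------------

def _minimal_oracle(sem, z, w, x, y):
    if not population_iv_gin_oracle(sem, z, w, x, y):
        return False
    for k in range(len(w)):
        for sub in itertools.combinations(sorted(w), k):
            if population_iv_gin_oracle(sem, z, set(sub), x, y):
                return False
    return True


def run_equivalence_battery(seed, n_cases=200):
    """Population GIN oracle (+ minimality) vs the trek criterion on random
    small SEMs; returns (checked, mismatches, oracle_true_count)."""
    rng = np.random.default_rng(seed)
    checked = mismatches = true_count = 0
    while checked < n_cases:
        sem = random_linear_sem(rng)
        query = draw_query(rng, sem)
        if query is None:
            continue
        z, w, x, y = query
        try:
            lhs = _minimal_oracle(sem, z, w, x, y)
        except (DegenerateCovarianceError, ValueError):
            continue
        rhs = ivgin_graphical_criterion(sem.graph, z, w, x, y)
        checked += 1
        true_count += lhs
        mismatches += lhs != rhs
    return checked, mismatches, true_count


def test_oracle_matches_trek_criterion_on_random_sems(battery_rng_seed):
    checked, mismatches, true_count = run_equivalence_battery(battery_rng_seed)
    assert checked >= 200
    assert mismatches == 0
    assert true_count > 10  # the battery exercises both outcomes


def run_necessity_battery(seed, n_sems=150):
    """Unconditional necessity: every graphically valid instrument (empty
    conditioning set) satisfies the population GIN condition."""
    rng = np.random.default_rng(seed)
    valid_cases = violations = 0
    for _ in range(n_sems):
        sem = random_linear_sem(rng)
        g = sem.graph
        for x, y, z in itertools.permutations(g.observed, 3):
            if not instrument_criteria_holds(g, z, set(), x, y):
                continue
            valid_cases += 1
            try:
                ok = population_iv_gin_oracle(sem, z, set(), x, y)
            except (DegenerateCovarianceError, ValueError):
                continue
            violations += not ok
    return valid_cases, violations


FIXTURE_VALID_CASES = [
    ("fig1", "Z", ()),
    ("fig2", "Z", ("W1", "W2")),
    ("fig3a", "Z", ()),
    ("fig5", "Z", ("W1",)),
    ("s1", "Z2", ()),
    ("s1", "Z3", ()),
    ("s2", "Z2", ()),
    ("s2", "Z3", ()),
    ("s3", "Z1", ("Z3",)),
    ("s3", "Z2", ()),
]


def test_valid_instruments_never_fail_the_oracle(battery_rng_seed):
    valid_cases, violations = run_necessity_battery(battery_rng_seed + 2)
    assert valid_cases > 200
    assert violations == 0
    # conditional cases on every shipped fixture with a valid instrument
    rng = np.random.default_rng(battery_rng_seed)
    for name, z, w in FIXTURE_VALID_CASES:
        g = load_fixture(name)
        coeffs = {
            e: float(rng.choice([-1, 1]) * rng.uniform(0.5, 2.0))
            for e in g.edges
        }
        sem = LinearSEM(g, coeffs, NoiseSpec("squared_exponential"))
        assert instrument_criteria_holds(g, z, set(w), "X", "Y"), (name, z)
        assert population_iv_gin_oracle(sem, z, set(w), "X", "Y"), (name, z)


def test_empirical_test_converges_to_oracle(battery_rng_seed):
    """At n = 20000 the finite-sample decision matches the population
    oracle in at least 95% of random fixtures (alpha = 0.01)."""
    rng = np.random.default_rng(battery_rng_seed + 3)
    agree = checked = 0
    while checked < 100:
        sem = random_linear_sem(rng)
        query = draw_query(rng, sem)
        if query is None:
            continue
        z, w, x, y = query
        try:
            truth = population_iv_gin_oracle(sem, z, w, x, y)
        except (DegenerateCovarianceError, ValueError):
            continue
        data = sem.sample(20_000, seed=int(rng.integers(2**31)))
        res = iv_gin_test(
            data, z, w, x, y, alpha=0.01, seed=int(rng.integers(2**31))
        )
        agree += res.holds == truth
        checked += 1
    assert agree / checked >= 0.95
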