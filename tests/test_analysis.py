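"""Growth-rate algebra, cycle tracking, efficiency and regression analytics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from holosim.analysis import (
    AnalysisError,
    asymmetry_point,
    asymmetry_regression,
    cycle_efficiency,
    growth_from_cycle,
    logistic_equilibrium,
    phase_diagram,
    tau_min,
    track_single_cell,
)
from holosim.genome import Bead, BeadKind, Genome


def test_break_even_and_divergent_growth():
    g = growth_from_cycle(tau=5.0, rho=0.5, delta=0.0)
    assert g.R0 == pytest.approx(1.0) and g.r == pytest.approx(0.0)
    g = growth_from_cycle(tau=5.0, rho=1.0, delta=0.0)
    assert g.divergent and g.r == pytest.approx(1 / 5.0) and math.isinf(g.R0)


def test_growth_rate_identities_random_sweep():
    """r = (2 rho - 1 - d tau)/tau and r = (rho/tau)(1 - 1/R0) agree to
    1e-12 over 1000 random parameter triples."""
    rng = np.random.default_rng(7)
    for _ in range(1000):
        rho = rng.uniform(0.01, 0.99)
        tau = rng.uniform(0.5, 50.0)
        delta = rng.uniform(0.0, 0.05)
        g = growth_from_cycle(tau, rho, delta)
        eq4 = (2 * rho - 1 - delta * tau) / tau
        eq5 = (rho / tau) * (1 - 1 / g.R0)
        assert abs(g.r - eq4) < 1e-12
        assert abs(eq5 - eq4) < 1e-12
        assert (g.r > 0) == (g.R0 > 1)


def test_logistic_equilibrium_matches_ode_integration():
    """N* = max(0, r tau / rho) equals the long-time limit of the logistic
    population model integrated numerically from N = 0.01."""
    rng = np.random.default_rng(11)
    for _ in range(25):
        rho = rng.uniform(0.3, 1.0)
        tau = rng.uniform(1.0, 20.0)
        delta = rng.uniform(0.0, 0.02)
        nstar = logistic_equilibrium(rho, tau, delta)

        def f(t, y):
            n = y[0]
            return [(rho / tau) * n * (1 - n) - ((1 - rho) / tau) * n - delta * n]

        sol = solve_ivp(f, (0.0, 5000.0 * tau), [0.01], rtol=1e-10, atol=1e-12)
        assert abs(sol.y[0, -1] - nstar) < 1e-6


def test_equilibrium_zero_when_nonviable():
    assert logistic_equilibrium(1.0, 5.0, 0.0) == pytest.approx(1.0)
    assert logistic_equilibrium(0.4, 10.0, 0.05) == 0.0  # r <= 0 -> extinction


def test_cycle_efficiency_formula_and_bounds():
    from holosim.analysis import CycleStats

    # L = 70, n = 10, tau = 20 -> (3 + 7)/20 = 0.5
    st = CycleStats(n=10.0, duration=100, n_success=5, n_fail=0, tau=20.0, rho=1.0)
    e, excluded = cycle_efficiency(70, {10.0: st}, conditions=(10.0,))
    assert e == pytest.approx(0.5)
    assert excluded == []
    # undefined conditions excluded with a flag
    bad = CycleStats(n=1.0, duration=100, n_success=0, n_fail=9, tau=None, rho=0.0)
    e2, excl = cycle_efficiency(70, {10.0: st, 1.0: bad}, conditions=(10.0, 1.0))
    assert e2 == pytest.approx(0.5) and excl == [1.0]
    with pytest.raises(AnalysisError):
        cycle_efficiency(70, {1.0: bad}, conditions=(1.0,))


def test_clock_tracking_deterministic_limit(clock, stage_table):
    """The period-4 clock at saturating share: rho = 1 and tau equals the
    designed period exactly; per-condition efficiency at n = L is 1."""
    L = clock.genome.size
    rng = np.random.default_rng(0)
    st = track_single_cell(clock.genome, float(L), stage_table, rng,
                           duration=4000, half_saturation=0.0)
    assert st.rho == 1.0
    assert st.tau == float(clock.period)
    e, _ = cycle_efficiency(L, {float(L): st}, conditions=(float(L),))
    assert e == pytest.approx(1.0)
    assert all(d >= tau_min(L, L) for d in st.cycle_durations)


def test_rho_recovery_under_injected_death(clock, stage_table):
    """With a per-step death hazard q, the deterministic clock's expected
    success fraction is (1-q)^period; the tracker must recover it within a
    binomial CI, with tau still exactly the period."""
    q = 0.05
    rng = np.random.default_rng(42)
    st = track_single_cell(clock.genome, float(clock.genome.size), stage_table, rng,
                           duration=12_000, half_saturation=0.0, injected_death_rate=q)
    assert st.tau == float(clock.period)
    expected = (1 - q) ** clock.period
    attempts = st.n_success + st.n_fail
    assert abs(st.rho - expected) < 3 * math.sqrt(expected * (1 - expected) / attempts)


def test_never_dividing_genome_flagged(stage_table, rng):
    g = Genome([Bead(BeadKind.REGULATORY_GENE, type_id=t, threshold=1, activity=1)
                for t in range(5)])
    st = track_single_cell(g, 100.0, stage_table, rng, duration=300, half_saturation=1.0)
    assert st.n_success == 0 and st.rho == 0.0
    assert st.tau is None and not st.tau_defined


def test_tau_lower_bound_holds_stochastically(clock, stage_table):
    """Every completed cycle satisfies tau >= 3 + L/n at any noise level."""
    L = clock.genome.size
    for n in (100.0, 64.0):
        rng = np.random.default_rng(int(n))
        st = track_single_cell(clock.genome, n, stage_table, rng,
                               duration=4000, half_saturation=0.02)
        assert st.n_success > 0
        assert all(d >= tau_min(L, n) for d in st.cycle_durations)


def test_phase_diagram_identical_genomes_is_neutral(clock, stage_table):
    rng = np.random.default_rng(1)
    pdg = phase_diagram(clock.genome, clock.genome.copy(), stage_table, rng,
                        conditions=(64.0, 100.0), duration=1500, half_saturation=0.0)
    assert pdg.regime == "neutral_drift"
    assert pdg.crossings == []


def test_phase_diagram_dominance(clock, slow_clock, stage_table):
    """Fast small-genome cell vs slow larger one, both viable on the grid:
    one-sided growth advantage, no crossing."""
    rng = np.random.default_rng(2)
    # host = period-4 L=64 clock, symbiont = period-5 L=40 clock, grid above both edges
    pdg = phase_diagram(clock.genome, slow_clock.genome, stage_table, rng,
                        conditions=(70.0, 100.0), duration=2500, half_saturation=0.0)
    assert pdg.crossings == []
    assert pdg.regime == "host_dominant"  # the period-4 host grows faster everywhere


def test_phase_diagram_stable_crossing(host_clock, clock, stage_table):
    """Period-10 small host vs period-4 large symbiont: the symbiont is
    favored only above its viability edge -> exactly one stable crossing."""
    rng = np.random.default_rng(3)
    pdg = phase_diagram(host_clock.genome, clock.genome, stage_table, rng,
                        conditions=(20.0, 40.0, 50.0, 64.0, 100.0),
                        duration=4000, half_saturation=0.02)
    assert len(pdg.crossings) == 1
    n_star, stable = pdg.crossings[0]
    assert stable and 40.0 < n_star <= 64.0
    assert pdg.regime == "stable"


def test_pearson_matches_direct_formula():
    xs = np.array([1.0, 2.0, 3.5, 4.0, 5.2, 6.1, 7.0, 8.3, 9.9, 11.0])
    ys = np.array([2.1, 2.0, 3.9, 4.2, 5.0, 7.1, 6.9, 8.0, 9.5, 12.1])
    df = pd.DataFrame({"x": xs, "y": ys})
    res = asymmetry_regression(df, "x", "y")
    # independent textbook computation
    r_direct = (((xs - xs.mean()) * (ys - ys.mean())).sum()
                / math.sqrt(((xs - xs.mean()) ** 2).sum() * ((ys - ys.mean()) ** 2).sum()))
    assert res["r"] == pytest.approx(r_direct, abs=1e-12)
    assert res["R2"] == pytest.approx(r_direct**2, abs=1e-12)
    assert res["N"] == 10


def test_regression_degenerate_inputs():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [5.0, 5.0, 5.0]})
    with pytest.raises(AnalysisError):
        asymmetry_regression(df, "x", "y")
    collinear = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 4.0, 6.0, 8.0]})
    assert asymmetry_regression(collinear, "x", "y")["R2"] == pytest.approx(1.0)


def test_asymmetry_axes():
    x, y = asymmetry_point(128, 64, 0.9, 0.7)
    assert x == pytest.approx(1.0)
    assert y == pytest.approx(0.2)
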