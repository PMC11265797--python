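"""BAR/TI estimators, the Boresch analytic term, ABFE assembly, cycles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from altaccess import units
from altaccess.errors import OverlapError, ValidationError
from altaccess.synth import WorkSamples, make_alchemical_samples
from altaccess.thermo import (AlchemicalLeg, BoreschSpec, FreeEnergyEdge,
                              ThermodynamicCycle, assemble_abfe, bar_estimate,
                              boresch_analytic, cycle_closure,
                              protonation_edge_from_pka, ti_estimate)
from altaccess.titration import PkaEstimate


# --------------------------------------------------------------------- bar

def test_mirrored_distributions_give_zero():
    rng = np.random.default_rng(0)
    w = rng.normal(1.0, 0.5, 5000)
    samples = WorkSamples(w, w)  # reverse mirrors forward -> dG = 0
    dg, sd = bar_estimate(samples)
    assert dg == pytest.approx(0.0, abs=3 * sd)


def test_crooks_gaussian_closed_form():
    """BAR on Gaussian work N(mu, sigma) recovers dG = mu - beta sigma^2/2."""
    samples = make_alchemical_samples(2.0, 1.0, 20_000, seed=7)
    dg, sd = bar_estimate(samples)
    assert dg == pytest.approx(2.0, abs=3 * sd)
    assert sd < 0.02


def test_sigma_zero_gives_exact_mean():
    samples = make_alchemical_samples(3.3, 0.0, 10, seed=0)
    dg, sd = bar_estimate(samples)
    assert dg == pytest.approx(3.3, abs=1e-9)
    assert sd == pytest.approx(0.0, abs=1e-9)


def test_one_sided_falls_back_to_exponential_averaging():
    samples = WorkSamples(np.full(100, 1.5), np.array([]))
    with pytest.warns(UserWarning, match="exponential averaging"):
        dg, _ = bar_estimate(samples)
    assert dg == pytest.approx(1.5, abs=1e-9)


def test_no_overlap_raises():
    samples = WorkSamples(np.full(50, 1e4), np.full(50, 1e4))
    with pytest.raises(OverlapError):
        bar_estimate(samples)


def test_bar_and_ti_agree_on_dense_gaussian_legs():
    """Summed per-interval BAR matches TI over a dense lambda path."""
    lambdas = np.linspace(0.0, 1.0, 11)
    dhdl = 3.0 * lambdas**2 - 1.0  # dG = int = 0
    total, sd_sum = 0.0, 0.0
    for i in range(10):
        dg_interval = float(np.trapezoid(dhdl[i : i + 2], lambdas[i : i + 2]))
        s = make_alchemical_samples(dg_interval, 0.2, 4000, seed=100 + i)
        dg, sd = bar_estimate(s)
        total += dg
        sd_sum += sd**2
    ti_dg, _ = ti_estimate(lambdas, dhdl)
    assert total == pytest.approx(ti_dg, abs=3 * math.sqrt(sd_sum) + 0.02)


# ---------------------------------------------------------------------- ti

def test_ti_constant_and_linear():
    lam = (0.0, 0.5, 1.0)
    assert ti_estimate(lam, (2.5, 2.5, 2.5))[0] == pytest.approx(2.5)
    assert ti_estimate(lam, (0.0, 0.5, 1.0))[0] == pytest.approx(0.5)


def test_ti_cubic_against_dense_quadrature():
    lam = np.linspace(0, 1, 21)
    dg, _ = ti_estimate(lam, 4.0 * lam**3)
    dense = quad(lambda x: 4.0 * x**3, 0, 1)[0]
    assert dg == pytest.approx(dense, abs=0.01)


def test_ti_sem_propagation():
    lam = (0.0, 0.5, 1.0)
    _, sd = ti_estimate(lam, (1.0, 1.0, 1.0), (0.1, 0.2, 0.1))
    weights = np.array([0.25, 0.5, 0.25])
    expected = math.sqrt(((weights * [0.1, 0.2, 0.1]) ** 2).sum())
    assert sd == pytest.approx(expected)


def test_ti_missing_endpoint_rejected():
    with pytest.raises(ValidationError):
        ti_estimate((0.0, 0.5), (1.0, 1.0))


# ------------------------------------------------------------------ boresch

def _spec(**overrides):
    base = dict(r0=0.5, theta_a=1.4, theta_b=1.4, k_r=4184.0, k_theta_a=4184.0,
                k_theta_b=4184.0, k_phi_a=4184.0, k_phi_b=4184.0, k_phi_c=4184.0)
    base.update(overrides)
    return BoreschSpec(**base)


def test_doubling_force_constants_scaling_law():
    base = boresch_analytic(_spec())
    doubled = boresch_analytic(
        _spec(**{k: 2 * 4184.0 for k in ("k_r", "k_theta_a", "k_theta_b",
                                          "k_phi_a", "k_phi_b", "k_phi_c")})
    )
    assert doubled - base == pytest.approx(-3.0 * units.kt() * math.log(2.0), rel=1e-9)


def test_boresch_against_configurational_integral_oracle():
    """Quadrature over the six restrained coordinates (with the r^2 sin
    Jacobian) agrees with the analytic formula within 0.02 kcal/mol."""
    spec = _spec()
    kt = units.kt(spec.temperature)
    b = 1.0 / kt
    k_r, k_ta, k_tb, k_pa, k_pb, k_pc = spec.force_constants_kcal()
    z_r = quad(lambda r: r * r * math.exp(-b * 0.5 * k_r * (r - spec.r0) ** 2),
               0.2, 0.8, limit=200)[0]
    z_ta = quad(lambda t: math.sin(t) * math.exp(-b * 0.5 * k_ta * (t - spec.theta_a) ** 2),
                0.5, 2.3, limit=200)[0]
    z_tb = quad(lambda t: math.sin(t) * math.exp(-b * 0.5 * k_tb * (t - spec.theta_b) ** 2),
                0.5, 2.3, limit=200)[0]
    z_phi = [quad(lambda p: math.exp(-b * 0.5 * k * p**2), -1.0, 1.0, limit=200)[0]
             for k in (k_pa, k_pb, k_pc)]
    z_total = z_r * z_ta * z_tb * z_phi[0] * z_phi[1] * z_phi[2]
    oracle = -kt * math.log(8.0 * math.pi**2 * spec.standard_volume / z_total)
    assert boresch_analytic(spec) == pytest.approx(oracle, abs=0.02)


def test_boresch_regression_pinned():
    # value validated against the quadrature oracle above, then frozen
    assert boresch_analytic(_spec()) == pytest.approx(-14.1408, abs=1e-3)


def test_degenerate_angle_rejected():
    with pytest.raises(ValidationError):
        _spec(theta_a=0.0)
    with pytest.raises(ValidationError):
        _spec(theta_b=math.pi)


# ---------------------------------------------------------------- assembly

def test_all_legs_zero():
    legs_c = [AlchemicalLeg("restraint", 0.0, 0.0), AlchemicalLeg("coulomb", 0.0, 0.0)]
    legs_l = [AlchemicalLeg("coulomb", 0.0, 0.0)]
    affinity, sd = assemble_abfe(legs_c, legs_l, 0.0)
    assert affinity == 0.0
    assert sd == 0.0


def test_rss_of_leg_sds():
    legs_c = [AlchemicalLeg("a", 1.0, 0.2), AlchemicalLeg("b", 1.0, 0.2)]
    legs_l = [AlchemicalLeg("c", 1.0, 0.1)]
    _, sd = assemble_abfe(legs_c, legs_l, 0.0)
    assert sd == pytest.approx(0.3)


def test_missing_leg_reported():
    with pytest.raises(ValidationError, match="ligand"):
        assemble_abfe([AlchemicalLeg("a", 1.0, 0.1)], [], 0.0)


def test_planted_affinity_recovered_from_synthetic_legs():
    """Legs generated to sum to 7.0 kcal/mol assemble back within 3 SD."""
    boresch = boresch_analytic(_spec())
    # choose complex/ligand leg values so the planted affinity is 7.0
    complex_true = {"restraint": 0.8, "coulomb": 42.0, "vdw": 6.5}
    ligand_true = {"coulomb": 39.0, "vdw": 3.3 + boresch - 7.0 + 0.8 + 42.0 + 6.5 - 39.0 - 3.3}
    complex_legs, ligand_legs = [], []
    for i, (label, dg) in enumerate(complex_true.items()):
        est, sd = bar_estimate(make_alchemical_samples(dg, 0.8, 5000, seed=40 + i))
        complex_legs.append(AlchemicalLeg(label, est, sd))
    for i, (label, dg) in enumerate(ligand_true.items()):
        est, sd = bar_estimate(make_alchemical_samples(dg, 0.8, 5000, seed=60 + i))
        ligand_legs.append(AlchemicalLeg(label, est, sd))
    affinity, sd = assemble_abfe(complex_legs, ligand_legs, boresch)
    assert affinity == pytest.approx(7.0, abs=3 * sd)
    assert sd < 0.2


def test_assembly_invariant_to_leg_order():
    legs_c = [AlchemicalLeg("a", 1.0, 0.1), AlchemicalLeg("b", 2.0, 0.2)]
    legs_l = [AlchemicalLeg("c", 0.5, 0.1), AlchemicalLeg("d", 1.5, 0.2)]
    a = assemble_abfe(legs_c, legs_l, -3.0)
    b = assemble_abfe(legs_c[::-1], legs_l[::-1], -3.0)
    assert a[0] == pytest.approx(b[0], rel=1e-12)
    assert a[1] == pytest.approx(b[1], rel=1e-12)


# ------------------------------------------------------------------ cycles

def _square_cycle(dgs, sds):
    states = ["apo_deprot", "apo_prot", "holo_prot", "holo_deprot"]
    edges = []
    for i, (dg, sd) in enumerate(zip(dgs, sds)):
        edges.append(
            FreeEnergyEdge(f"e{i}", dg, sd, states[i], states[(i + 1) % 4])
        )
    return ThermodynamicCycle(tuple(edges))


def test_consistent_cycle_residual_zero():
    cycle = _square_cycle([1.0, 2.0, -1.0, -2.0], [0.1] * 4)
    residual, sd = cycle_closure(cycle)
    assert residual == pytest.approx(0.0, abs=1e-12)
    assert sd == pytest.approx(0.2)


def test_propagated_sd_hand_arithmetic():
    cycle = _square_cycle([0.0] * 4, [0.3, 0.4, 0.2, 0.1])
    _, sd = cycle_closure(cycle)
    assert sd == pytest.approx(math.sqrt(0.30), abs=1e-12)
    assert sd == pytest.approx(0.5477, abs=1e-4)


def test_reversing_cycle_flips_residual_sign():
    cycle = _square_cycle([1.0, 2.0, -0.5, -2.0], [0.1] * 4)
    fwd, sd_f = cycle_closure(cycle)
    rev, sd_r = cycle_closure(cycle.reversed())
    assert rev == pytest.approx(-fwd)
    assert sd_r == pytest.approx(sd_f)


def test_open_loop_names_unmatched_states():
    edges = (
        FreeEnergyEdge("a", 1.0, 0.1, "s1", "s2"),
        FreeEnergyEdge("b", 1.0, 0.1, "s3", "s1"),
    )
    with pytest.raises(ValidationError, match="s2"):
        ThermodynamicCycle(edges)


# -------------------------------------------------------- protonation edge

def test_protonation_edge_values():
    edge = protonation_edge_from_pka(PkaEstimate(7.0, 1.0, 0.0), ph=7.0)
    assert edge.dg == 0.0
    edge = protonation_edge_from_pka(8.0, ph=7.0)
    assert edge.dg == pytest.approx(-1.4186, abs=5e-4)
    edge = protonation_edge_from_pka(8.0, ph=7.0, sd=0.2)
    assert edge.sd == pytest.approx(0.284, abs=5e-4)


def test_end_to_end_cycle_from_titration_and_binding():
    """A protonation/binding square built self-consistently closes within
    twice the propagated SD."""
    from altaccess.synth import make_titration_data
    from altaccess.titration import deprotonated_fractions, fit_titration

    ph = 7.0
    pka_apo, pka_holo = 3.4, 4.0
    factor = units.rt_ln10()
    # affinities chosen consistent with the pKa shift:
    # dG_bind(prot) - dG_bind(deprot) = -RTln10 (pKa_holo - pKa_apo)
    affinity_deprot = 8.0
    affinity_prot = affinity_deprot + factor * (pka_holo - pka_apo)

    def fitted_pka(pka, seed):
        reps = []
        for r in range(3):
            s = make_titration_data(pka, n_frames=40_000, correlation_time=10.0,
                                    seed=seed + r)
            reps.append(fit_titration(deprotonated_fractions(s)).pka)
        return float(np.mean(reps)), float(np.std(reps, ddof=1))

    pka_apo_est, sd_apo = fitted_pka(pka_apo, 100)
    pka_holo_est, sd_holo = fitted_pka(pka_holo, 200)

    def bar_leg(dg, seed):
        est, sd = bar_estimate(make_alchemical_samples(dg, 0.8, 4000, seed=seed))
        return est, sd

    bind_deprot, sd_bd = bar_leg(-affinity_deprot, 300)
    bind_prot, sd_bp = bar_leg(-affinity_prot, 301)

    apo_edge = protonation_edge_from_pka(pka_apo_est, ph=ph, sd=sd_apo,
                                         state_from="apo_deprot", state_to="apo_prot")
    bind_edge_prot = FreeEnergyEdge("bind_prot", bind_prot, sd_bp,
                                    "apo_prot", "holo_prot")
    holo_edge = protonation_edge_from_pka(pka_holo_est, ph=ph, sd=sd_holo,
                                          state_from="holo_deprot", state_to="holo_prot")
    unbind_edge = FreeEnergyEdge("unbind_deprot", -bind_deprot, sd_bd,
                                 "holo_deprot", "apo_deprot")
    cycle = ThermodynamicCycle(
        (apo_edge, bind_edge_prot,
         FreeEnergyEdge(holo_edge.label, holo_edge.dg, holo_edge.sd,
                        holo_edge.state_from, holo_edge.state_to, orientation=-1),
         unbind_edge)
    )
    residual, sd = cycle_closure(cycle)
    assert abs(residual) <= 2.0 * sd
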