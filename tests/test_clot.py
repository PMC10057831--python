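"""Local clot model: permeability, Darcy flow, transport and kinetics oracles."""

import dataclasses

import numpy as np
import pytest

import thrombosim as ts
from thrombosim.clot import (
    BOUND_SPECIES,
    FREE_SPECIES,
    ClotField,
    binding_rates,
    darcy_velocity,
    davis_permeability,
    degrade_sites,
    initial_field,
    simulate_lysis,
    step_reactions,
    step_transport,
    superficial_velocity,
)
from thrombosim.systemic import SystemicTrajectory

N_SPECIES = len(FREE_SPECIES)


# ---------------------------------------------------------------------------
# Permeability and Darcy flow
# ---------------------------------------------------------------------------

def test_davis_permeability_arithmetic_oracle():
    # independent hand evaluation of r^2 / (16 phi^1.5 (1 + 56 phi^3))
    eps, r = 0.75, 1.0e-7
    phi = 0.25
    expected = r * r / (16.0 * phi ** 1.5 * (1.0 + 56.0 * phi ** 3))
    assert davis_permeability(eps, r) == pytest.approx(expected, rel=1e-12)


def test_davis_permeability_monotone_and_scaling():
    assert davis_permeability(0.6, 1e-7) < davis_permeability(0.9, 1e-7)
    assert davis_permeability(0.75, 2e-7) == pytest.approx(
        4.0 * davis_permeability(0.75, 1e-7), rel=1e-12)
    with pytest.raises(ValueError):
        davis_permeability(1.0, 1e-7)
    with pytest.raises(ValueError):
        davis_permeability(0.0, 1e-7)


def test_darcy_velocity_basics():
    assert darcy_velocity(1e-14, 1e-3, 0.0) == 0.0
    u1 = darcy_velocity(1e-14, 1e-3, 1e6)
    assert darcy_velocity(1e-14, 2e-3, 1e6) == pytest.approx(0.5 * u1)


def test_series_resistance_two_zone_oracle():
    """A clot whose halves have different porosity flows like two resistors
    in series: U = dp_total / (mu * (L1/k1 + L2/k2))."""
    cfg = dataclasses.replace(ts.builtin_clot_config(), n_cells=10,
                              pressure_mode="total")
    inlet = np.zeros(N_SPECIES)
    f = initial_field(cfg, inlet)
    f.eps[:5] = 0.8
    f.eps[5:] = 0.7
    k1 = davis_permeability(0.8, cfg.fiber_radius)
    k2 = davis_permeability(0.7, cfg.fiber_radius)
    dp_total = cfg.dp_per_length * cfg.L_clot
    expected = dp_total / (cfg.mu * (0.5 * cfg.L_clot / k1 +
                                     0.5 * cfg.L_clot / k2))
    assert superficial_velocity(f) == pytest.approx(expected, rel=1e-12)


def test_fully_lysed_clot_restores_flow():
    cfg = ts.builtin_clot_config()
    f = initial_field(cfg, np.zeros(N_SPECIES))
    u_intact = superficial_velocity(f)
    f.eps[:] = 1.0
    assert superficial_velocity(f) > 100 * u_intact


# ---------------------------------------------------------------------------
# Transport oracles
# ---------------------------------------------------------------------------

def _free_field(n, dx, eps, U, D):
    """Bare transport field (no binding sites) for scheme verification."""
    cfg = ts.builtin_clot_config()
    f = ClotField(x=(np.arange(n) + 0.5) * dx, dx=dx,
                  C=np.zeros((N_SPECIES, n)), nb=np.zeros((3, n)),
                  ntot=np.zeros(n), eps=np.full(n, eps), U=U,
                  clot_mask=np.zeros(n, bool), ntot_init=np.zeros(n),
                  config=cfg, D=np.full(N_SPECIES, D))
    return f


def test_transport_zero_everywhere_stays_zero():
    f = _free_field(40, 1e-4, 1.0, 1e-5, 1e-10)
    inflow, outflow = step_transport(f, np.zeros(N_SPECIES), 50.0)
    assert np.all(f.C == 0.0)
    assert np.all(inflow == 0.0) and np.all(outflow == 0.0)


def test_pure_advection_step_profile_mass_and_speed():
    """A step profile advects at the superficial velocity with exact mass
    accounting (inflow - outflow = accumulation to 1e-9 relative)."""
    n, dx, U = 200, 1e-4, 1e-5
    f = _free_field(n, dx, 1.0, U, 0.0)
    f.C[0, :40] = 1.0
    mass0 = f.free_mass()[0]
    T = 600.0
    total_in = total_out = 0.0
    for _ in range(60):
        inflow, outflow = step_transport(f, np.zeros(N_SPECIES), T / 60)
        total_in += inflow[0]
        total_out += outflow[0]
    mass1 = f.free_mass()[0]
    assert mass1 - mass0 == pytest.approx(total_in - total_out, rel=1e-9,
                                          abs=1e-15 * mass0)
    # the profile's center of mass advects at exactly U
    com0 = 0.5 * 40 * dx  # initial block over [0, 4 mm]
    com1 = (f.C[0] * f.x).sum() / f.C[0].sum()
    assert com1 - com0 == pytest.approx(U * T, abs=2 * dx)


def test_pure_diffusion_variance_growth():
    """With U = 0 a narrow pulse spreads with variance 2 D t (within 1%)
    and conserves mass."""
    n, dx, D = 300, 1e-5, 1e-10
    f = _free_field(n, dx, 1.0, 0.0, D)
    x0 = f.x[n // 2]
    sigma0 = 8 * dx
    f.C[0] = np.exp(-0.5 * ((f.x - x0) / sigma0) ** 2)
    mass0 = f.free_mass()[0]

    def variance():
        w = f.C[0] / f.C[0].sum()
        mu = (w * f.x).sum()
        return (w * (f.x - mu) ** 2).sum()

    v0 = variance()
    T = 500.0
    net = 0.0
    for _ in range(10):
        inflow, outflow = step_transport(f, np.zeros(N_SPECIES), T / 10)
        net += inflow[0] - outflow[0]
    assert f.free_mass()[0] - mass0 == pytest.approx(net, rel=1e-9,
                                                     abs=1e-12 * mass0)
    assert variance() - v0 == pytest.approx(2 * D * T, rel=1e-2)


def test_transport_balance_every_species_per_step():
    """inflow - outflow - accumulation vanishes (< 1e-8 relative) for every
    species in a porous, reacting-free field with nonuniform state."""
    rng = np.random.default_rng(3)
    n = 60
    f = _free_field(n, 2e-4, 0.8, 8e-6, 5e-11)
    f.C[:] = rng.uniform(0.1, 2.0, size=(N_SPECIES, n))
    inlet = rng.uniform(0.1, 2.0, size=N_SPECIES)
    for _ in range(5):
        m0 = f.free_mass()
        inflow, outflow = step_transport(f, inlet, 10.0)
        m1 = f.free_mass()
        scale = np.maximum(np.abs(inflow) + np.abs(outflow), m0)
        assert np.all(np.abs((m1 - m0) - (inflow - outflow)) / scale < 1e-8)


def test_transport_instability_reported():
    from thrombosim.clot import TransportInstabilityError
    f = _free_field(10, 1e-4, 1.0, 1e-5, 0.0)
    f.C[0, 0] = np.nan
    with pytest.raises(TransportInstabilityError):
        step_transport(f, np.zeros(N_SPECIES), 1.0)


# ---------------------------------------------------------------------------
# Kinetics oracles
# ---------------------------------------------------------------------------

def _quiet_kinetics():
    return ts.PlasmaKinetics(k_pls_ap=0.0, k_pls_mg=0.0, k_pls_fbg=0.0)


def test_langmuir_equilibrium_reproduces_kd(drugs):
    """With catalysis off, the steady bound/free ratio reproduces the
    published dissociation constant within 0.1%."""
    for name in ("alteplase", "tenecteplase", "reteplase"):
        d = dataclasses.replace(drugs[name], kcat_clot=0.0, kcat_plasma=0.0,
                                kPAI=0.0)
        cfg = dataclasses.replace(ts.builtin_clot_config(), n_cells=4,
                                  kdeg=1e-30, ka_plg=0.0, kd_plg=0.0,
                                  ka_pls=0.0, kd_pls=0.0)
        inlet = np.zeros(N_SPECIES)
        f = initial_field(cfg, inlet)
        C_drug = 0.05
        f.C[0, :] = C_drug
        # hold the free concentration fixed while binding equilibrates
        for _ in range(4000):
            step_reactions(f, d, _quiet_kinetics(), 5.0)
            f.C[0, :] = C_drug
        n_free = f.n_free_sites
        ratio = f.nb[0] / (C_drug * n_free)
        assert np.allclose(ratio, d.ka / d.kd_off, rtol=1e-3)


def test_binding_rates_urokinase_has_no_adsorption(drugs, kinetics):
    cfg = ts.builtin_clot_config()
    n = 5
    C = np.ones((N_SPECIES, n))
    nb = np.zeros((3, n))
    ntot = np.full(n, cfg.n_total_init)
    dC, dnb, dntot = binding_rates(C, nb, ntot, drugs["urokinase"], cfg,
                                   kinetics)
    assert np.all(dnb[0] == 0.0)  # no drug adsorption flux
    # plasmin generation still runs off the free concentration
    nb[1, :] = 1.0  # bound plasminogen present
    _, dnb2, _ = binding_rates(C, nb, ntot, drugs["urokinase"], cfg, kinetics)
    assert np.all(dnb2[2] > 0.0)


def test_plasmin_generation_needs_bound_plasminogen(drugs, kinetics):
    cfg = ts.builtin_clot_config()
    n = 3
    C = np.ones((N_SPECIES, n))
    C[2] = 0.0  # no free plasmin to adsorb
    nb = np.zeros((3, n))
    nb[0, :] = 0.5  # bound activator but no bound plasminogen
    ntot = np.full(n, cfg.n_total_init)
    _, dnb, _ = binding_rates(C, nb, ntot, drugs["alteplase"], cfg, kinetics)
    assert np.all(dnb[2] <= 1e-15)


def test_site_degradation_linear_closed_form():
    """Under constant bound plasmin, n_total decays linearly with slope
    -kdeg*gamma*n_PLS (floored at zero)."""
    cfg = dataclasses.replace(ts.builtin_clot_config(), n_cells=5)
    f = initial_field(cfg, np.zeros(N_SPECIES))
    n0 = cfg.n_total_init
    n_pls = 0.05
    rate = np.full(5, -cfg.kdeg * cfg.gamma * n_pls)
    dt = 10.0
    degrade_sites(f, rate, dt)
    assert np.allclose(f.ntot, n0 - cfg.kdeg * cfg.gamma * n_pls * dt,
                       rtol=1e-12)
    # floor at zero after a very long step
    degrade_sites(f, rate, 1e9)
    assert np.all(f.ntot == 0.0)
    assert np.all(f.eps == 1.0)
    assert np.all(f.nb == 0.0)


def test_degradation_releases_bound_mass_conservatively():
    cfg = dataclasses.replace(ts.builtin_clot_config(), n_cells=4)
    f = initial_field(cfg, np.full(N_SPECIES, 1.0))
    f.nb[2, :] = 0.4
    total0 = (f.eps * f.C[2]) + f.nb[2]
    degrade_sites(f, np.full(4, -0.05), 10.0)
    total1 = (f.eps * f.C[2]) + f.nb[2]
    assert np.allclose(total1, total0, rtol=1e-12)
    assert np.all(f.nb.sum(axis=0) <= f.ntot + 1e-12)


def test_zero_plasmin_leaves_sites_unchanged():
    cfg = dataclasses.replace(ts.builtin_clot_config(), n_cells=4)
    f = initial_field(cfg, np.zeros(N_SPECIES))
    n0 = f.ntot.copy()
    degrade_sites(f, np.zeros(4), 100.0)
    assert np.array_equal(f.ntot, n0)


# ---------------------------------------------------------------------------
# Coupled march invariants (fast, small clot)
# ---------------------------------------------------------------------------

def _flat_trajectory(drug_name, c_drug, t_end, proteins):
    """Synthetic systemic trajectory with constant inlet concentrations."""
    times = np.array([0.0, t_end])
    prot = np.tile([p.C_init for p in proteins], (2, 1))
    return SystemicTrajectory(drug=drug_name, times=times,
                              Cc=np.full(2, c_drug), Cp=np.zeros(2),
                              proteins=prot)


def test_drug_free_inlet_leaves_clot_intact(drugs, proteins, kinetics,
                                            small_clot):
    traj = _flat_trajectory("tenecteplase", 0.0, 7200.0, proteins)
    res = simulate_lysis(drugs["tenecteplase"], traj, small_clot, kinetics,
                         7200.0, dt_max=5.0, dt_out=600.0)
    assert not res.dissolved
    assert np.allclose(res.ntot[-1], res.ntot_init, rtol=1e-6)


def test_urokinase_bound_drug_identically_zero(drugs, proteins, kinetics,
                                               small_clot):
    traj = _flat_trajectory("urokinase", 0.02, 3600.0, proteins)
    res = simulate_lysis(drugs["urokinase"], traj, small_clot, kinetics,
                         3600.0, dt_max=5.0, dt_out=300.0)
    assert np.all(res.nb[:, 0, :] == 0.0)


def test_sites_monotone_and_bound_capped(drugs, proteins, kinetics,
                                         small_clot):
    for name in ("alteplase", "urokinase"):
        traj = _flat_trajectory(name, 0.03, 3600.0, proteins)
        res = simulate_lysis(drugs[name], traj, small_clot, kinetics, 3600.0,
                             dt_max=5.0, dt_out=120.0)
        assert np.all(np.diff(res.ntot, axis=0) <= 1e-10)
        assert np.all(res.nb.sum(axis=1) <= res.ntot + 1e-9)
        assert np.all(res.C >= 0.0) and np.all(res.nb >= 0.0)


def test_doubling_inlet_drug_never_slows_lysis(drugs, proteins, kinetics,
                                               small_clot):
    from thrombosim.metrics import lysis_time
    for name in ("alteplase", "urokinase"):
        traj = _flat_trajectory(name, 0.03, 14400.0, proteins)
        t1 = lysis_time(simulate_lysis(drugs[name], traj, small_clot,
                                       kinetics, 14400.0, dt_max=5.0))
        t2 = lysis_time(simulate_lysis(drugs[name], traj, small_clot,
                                       kinetics, 14400.0, dt_max=5.0,
                                       inlet_scale=2.0))
        assert t1 is not None and t2 is not None
        assert t2 <= t1 * 1.001


def test_grid_refinement_converges(drugs, proteins, kinetics):
    """Doubling the cell count moves the lysis time by < 2%."""
    from thrombosim.metrics import lysis_time
    traj = _flat_trajectory("alteplase", 0.03, 14400.0, proteins)
    times = []
    for n_cells in (100, 200):
        cfg = dataclasses.replace(ts.builtin_clot_config(), L_clot=0.004,
                                  n_cells=n_cells, x_monitor=0.002)
        res = simulate_lysis(drugs["alteplase"], traj, cfg, kinetics, 14400.0,
                             dt_max=2.0)
        lt = lysis_time(res)
        assert lt is not None
        times.append(lt)
    assert abs(times[1] - times[0]) / times[0] < 0.02
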