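"""ODE right-hand side, integration, and steady-state solving."""

import numpy as np
import pytest

from thfkin.model import (
    ConstantFlux,
    MassActionIrrev,
    MassActionRev,
    PathwayModel,
    Reaction,
    SaturatingIrrev,
    Species,
)
from thfkin.simulate import (
    SteadyStateError,
    fluxes_at,
    rhs,
    simulate,
    steady_state,
)

from conftest import make_monod_toy

V_NET = 1.66e-7


class TestRhs:
    def test_mass_action_by_hand(self):
        """A -> B with rate k[A]: d[A]/dt = -2k at [A] = 2."""
        m = PathwayModel(
            species=[Species("A", "A", 2.0), Species("B", "B", 0.0)],
            reactions=[Reaction("r", {"A": 1}, {"B": 1}, MassActionIrrev(0.7))],
        )
        dx = rhs(m, [2.0, 0.0])
        assert dx == pytest.approx([-1.4, +1.4])

    def test_negative_concentration_is_domain_error(self, reference_model):
        x = np.full(7, 1e-7)
        x[3] = -1e-9
        with pytest.raises(ValueError, match="negative"):
            rhs(reference_model, x)

    def test_matches_finite_difference_of_simulation(self, reference_model):
        """rhs at t=0 equals the short-time slope of simulate()."""
        x0 = np.array([2e-7, 1.5e-7, 8e-8, 6e-8, 1.5e-5, 8e-6, 9e-7])

        def slope(dt):
            traj = simulate(reference_model, dt, init=x0, n_points=2,
                            rtol=1e-13, atol=1e-18)
            return (traj.conc.iloc[-1].to_numpy() - x0) / dt

        # Richardson extrapolation cancels the O(dt) curvature term
        dt = 1e-5
        extrapolated = 2 * slope(dt / 2) - slope(dt)
        expected = rhs(reference_model, x0)
        scale = np.max(np.abs(expected))
        assert np.allclose(extrapolated, expected, rtol=1e-6, atol=1e-6 * scale)

    def test_fixed_species_not_in_state(self, reference_model):
        assert len(rhs(reference_model, np.full(7, 1e-7))) == 7
        traj = simulate(reference_model, 100.0, n_points=5)
        assert "ATP" not in traj.conc.columns


class TestFluxesAt:
    def test_constant_flux_any_state(self, reference_model):
        for scale in (0.1, 1.0, 17.0):
            f = fluxes_at(reference_model, np.full(7, scale * 1e-7))
            assert f["SRC_HMPt"] == V_NET
            assert f["SRC_pABA"] == V_NET

    def test_glya_zero_net_flux_at_equilibrium(self, reference_model):
        """Detailed balance: [CH2THF][Gly]/([THF][Ser]) = kf/kr gives zero net."""
        m = reference_model
        kf, kr = m.get_param("GlyA", "kf"), m.get_param("GlyA", "kr")
        ser = m.species_by_id("Ser").init_conc
        gly = m.species_by_id("Gly").init_conc
        thf = 1e-5
        ch2 = kf * ser * thf / (kr * gly)
        x = {"H2HMPt": 1e-7, "H2HMPtPP": 1e-7, "H2pteroate": 1e-7, "DHF": 1e-7,
             "THF": thf, "CH2THF": ch2, "pABA": 1e-6}
        f = fluxes_at(m, x)
        assert abs(f["GlyA"]) < 1e-12 * kf * ser * thf

    def test_reversible_flux_can_be_negative(self, reference_model):
        x = {"H2HMPt": 1e-7, "H2HMPtPP": 1e-7, "H2pteroate": 1e-7, "DHF": 1e-7,
             "THF": 1e-9, "CH2THF": 1e-4, "pABA": 1e-6}
        assert fluxes_at(reference_model, x)["GlyA"] < 0


class TestSimulate:
    def test_steady_state_is_fixed_point(self, reference_model, wt_ss):
        traj = simulate(reference_model, 1e4, init=wt_ss.conc_vector(reference_model),
                        n_points=20)
        x0 = traj.conc.iloc[0]
        for sid in traj.conc.columns:
            assert np.allclose(traj.conc[sid], x0[sid], rtol=1e-6)

    def test_monod_toy_approaches_closed_form(self):
        """[X](t) -> km*v0/(vmax - v0) = 1e-6 from below."""
        toy = make_monod_toy(v0=2e-7, vmax=4e-7, km=1e-6, x0=0.0)
        traj = simulate(toy, 200.0, n_points=50)
        x = traj.conc["X"].to_numpy()
        assert np.all(np.diff(x) > -1e-12)  # monotone up to solver noise
        assert x[-1] == pytest.approx(1e-6, rel=1e-4)

    def test_flux_matrix_recomputable(self, reference_model, wt_ss):
        traj = simulate(reference_model, 10.0, init=wt_ss.conc_vector(reference_model),
                        n_points=4)
        row = traj.conc.iloc[-1].to_dict()
        recomputed = fluxes_at(reference_model, row)
        for rid, v in recomputed.items():
            assert traj.flux[rid].iloc[-1] == pytest.approx(v, rel=1e-12)

    def test_rejects_nonpositive_horizon(self, reference_model):
        with pytest.raises(ValueError):
            simulate(reference_model, 0.0)


class TestSteadyState:
    def test_monod_toy_analytic(self, monod_toy):
        ss = steady_state(monod_toy)
        assert ss.conc["X"] == pytest.approx(1e-6, rel=1e-10)
        assert ss.flux["drain"] == pytest.approx(2e-7, rel=1e-10)
        assert ss.stable

    def test_divergence_names_species(self):
        toy = make_monod_toy(v0=5e-7, vmax=4e-7)  # source above drain capacity
        with pytest.raises(SteadyStateError, match="X"):
            steady_state(toy)

    def test_flux_balance(self, reference_model, wt_ss):
        """For every dynamic species, sum(stoich * flux) = 0 to 1e-10 v_net."""
        S = reference_model.stoichiometric_matrix()
        v = np.array([wt_ss.flux[r.id] for r in reference_model.reactions])
        assert np.max(np.abs(S @ v)) < 1e-10 * V_NET

    def test_pterin_throughput(self, wt_ss):
        """Moiety conservation: drains exactly balance the constant source."""
        assert wt_ss.flux["DRAIN_THF"] + wt_ss.flux["DRAIN_CH2THF"] == pytest.approx(
            V_NET, rel=1e-10
        )

    def test_pathway_flux_identity(self, wt_ss):
        """Fol[KPCA] all carry v_net + v_PanB at steady state."""
        expected = V_NET + wt_ss.flux["PanB_side"]
        for rid in ("FolK", "FolP", "FolC", "FolA"):
            assert wt_ss.flux[rid] == pytest.approx(expected, rel=1e-9)
        assert wt_ss.flux["PanB_side"] > 0

    def test_root_and_relaxation_agree(self, reference_model, wt_ss):
        ss_rel = steady_state(reference_model, method="relaxation")
        for sid, c in wt_ss.conc.items():
            assert ss_rel.conc[sid] == pytest.approx(c, rel=1e-6)
        assert wt_ss.method == "root" and ss_rel.method == "relaxation"

    def test_stability_reported(self, wt_ss):
        assert wt_ss.stable
        # the paired sources + moiety recycling leave one conserved
        # direction; its eigenvalue is neutral, all others decay
        assert wt_ss.n_invariants == 1
        assert wt_ss.n_neutral == 1
        real = np.sort(wt_ss.eigenvalues.real)
        assert real[-2] < 0  # all non-neutral modes strictly stable

    def test_conserved_split_follows_guess(self, reference_model):
        """The pABA / H2-HMPt-PP split is set by the guess through the
        conserved combination; other species are unique."""
        g1 = np.array([1e-7, 1e-7, 5e-8, 5e-8, 2e-5, 1e-5, 1e-6])
        g2 = g1.copy()
        g2[-1] = 3e-6  # more pABA in the conserved pool
        ss1 = steady_state(reference_model, guess=g1)
        ss2 = steady_state(reference_model, guess=g2)
        assert ss2.conc["pABA"] > ss1.conc["pABA"] * 1.5
        for sid in ("THF", "CH2THF", "H2HMPt", "DHF", "H2pteroate"):
            assert ss2.conc[sid] == pytest.approx(ss1.conc[sid], rel=1e-6)
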