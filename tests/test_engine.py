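"""Cycle engine: denaturation, annealing kinetics, decay, elongation."""

import math

import numpy as np
import pytest

from taqsim import (
    EnzymeDecayModel,
    InitialConditions,
    PCRSetup,
    ProtocolConfig,
    SpeciesState,
    init_state,
)
from taqsim.engine import (
    SolverOptions,
    annealing,
    annealing_jacobian,
    annealing_rhs,
    denaturation,
    elongation,
    fluorescence_curve,
    run_1_cycle,
    run_PCR,
    taq_efficiency,
)
from taqsim.network import N_SPECIES
from taqsim.thermo import RateConstantSet


def make_rates(**kw):
    base = dict(
        k1_on=0.0, k1_off=0.0, k2_on=0.0, k2_off=0.0, kQ_on=0.0, kQ_off=0.0,
        kr_on=0.0, kr_off=0.0, kPD_on=0.0, kPD_off=0.0,
    )
    base.update(kw)
    return RateConstantSet(**base)


def random_state(rng, scale=1e-7):
    return SpeciesState.from_vector(rng.uniform(0, scale, N_SPECIES))


class TestDenaturation:
    def test_duplex_fully_dissociates(self):
        out = denaturation(SpeciesState(AA=1e-9))
        assert out.AA == 0.0
        assert out.A_for == pytest.approx(1e-9)
        assert out.A_rev == pytest.approx(1e-9)

    def test_ternary_hybrid_releases_three_molecules(self):
        out = denaturation(SpeciesState(H1Q=2e-9))
        assert out.A_for == pytest.approx(2e-9)
        assert out.P_rev == pytest.approx(2e-9)
        assert out.Q == pytest.approx(2e-9)
        assert out.H1Q == 0.0

    def test_family_totals_conserved(self, rng):
        for _ in range(20):
            s = random_state(rng)
            before = s.family_totals()
            after = denaturation(s).family_totals()
            for fam in before:
                assert after[fam] == pytest.approx(before[fam], rel=1e-12)

    def test_cleaved_probe_untouched(self):
        s = SpeciesState(AQ=1e-9, cleavedQ_cum=5e-9)
        assert denaturation(s).cleavedQ_cum == 5e-9


class TestAnnealingRHS:
    def test_frozen_network_has_zero_derivatives(self):
        y = SpeciesState(A_for=1e-9, P_rev=1e-7).to_vector()
        assert np.all(annealing_rhs(y, make_rates()) == 0.0)

    def test_single_binding_channel(self):
        # only A_for + P_rev -> H1 active, irreversible
        k = 1e6
        y = SpeciesState(A_for=2e-9, P_rev=3e-7).to_vector()
        dy = annealing_rhs(y, make_rates(k1_on=k))
        flux = k * 2e-9 * 3e-7
        expected = dict(A_for=-flux, P_rev=-flux, H1=flux)
        s = SpeciesState.from_vector(dy)
        for name in ("AA", "A_rev", "P_for", "Q", "H2", "AQ", "AQP", "H1Q", "PD"):
            assert getattr(s, name) == 0.0
        for name, val in expected.items():
            assert getattr(s, name) == pytest.approx(val, rel=1e-12)

    def test_family_derivative_sums_vanish(self, rng, rates):
        # d(family total)/dt == 0 for all five families at random states
        sums = {
            "A_for": ("A_for", "AA", "H1", "AQ", "AQP", "H1Q"),
            "A_rev": ("A_rev", "AA", "H2"),
            "P_for": ("P_for", "PD", "H2"),
            "P_rev": ("P_rev", "PD", "H1", "AQP", "H1Q"),
            "Q": ("Q", "AQ", "AQP", "H1Q"),
        }
        for _ in range(20):
            y = rng.uniform(0, 1e-7, N_SPECIES)
            dy = SpeciesState.from_vector(annealing_rhs(y, rates))
            scale = float(np.abs(annealing_rhs(y, rates)).max()) or 1.0
            for members in sums.values():
                total = sum(getattr(dy, m) for m in members)
                assert abs(total) <= 1e-12 * scale

    def test_analytic_jacobian_matches_finite_differences(self, rng, rates):
        y = rng.uniform(0, 1e-7, N_SPECIES)
        J = annealing_jacobian(y, rates)
        eps = 1e-13
        for j in range(N_SPECIES):
            yp, ym = y.copy(), y.copy()
            yp[j] += eps
            ym[j] -= eps
            col = (annealing_rhs(yp, rates) - annealing_rhs(ym, rates)) / (2 * eps)
            assert np.allclose(J[:, j], col, rtol=1e-5, atol=1e-2)


class TestAnnealing:
    def test_frozen_dynamics_preserve_state(self):
        s = SpeciesState(A_for=1e-9, P_rev=4.5e-7, Q=1.5e-7)
        final, trace = annealing(s, make_rates(), 30.0)
        assert final == s
        assert trace.y.shape == (N_SPECIES, 100)

    def test_two_species_equilibrium_matches_quadratic_closed_form(self):
        # A + P <-> H with K = k_on/k_off; equilibrium h solves
        # K*(A0-h)*(P0-h) = h
        for K, A0, P0 in [(1e9, 1e-9, 1e-7), (1e7, 5e-8, 5e-8), (1e11, 1e-12, 4.5e-7)]:
            k_on = 1e6
            s = SpeciesState(A_for=A0, P_rev=P0)
            final, _ = annealing(
                s, make_rates(k1_on=k_on, k1_off=k_on / K), 1e5,
                SolverOptions(rtol=1e-10, atol=1e-30),
            )
            b = A0 + P0 + 1.0 / K
            h_eq = (b - math.sqrt(b * b - 4 * A0 * P0)) / 2.0
            assert final.H1 == pytest.approx(h_eq, rel=1e-6)

    def test_conservation_along_trace(self, rates_slow, template_ic):
        state = denaturation(init_state(template_ic))
        _, trace = annealing(state, rates_slow, 30.0)
        for fam, tot in trace.family_totals().items():
            if tot[0] > 0:
                assert np.max(np.abs(tot - tot[0])) / tot[0] < 1e-6, fam

    def test_stiff_methods_agree(self, rates, template_ic):
        state = denaturation(init_state(template_ic))
        a, _ = annealing(state, rates, 30.0, SolverOptions(method="LSODA"))
        b, _ = annealing(state, rates, 30.0, SolverOptions(method="BDF"))
        ya, yb = a.to_vector(), b.to_vector()
        mask = ya > 0
        assert np.max(np.abs(ya - yb)[mask] / ya[mask]) < 1e-4

    def test_invalid_duration(self, rates):
        with pytest.raises(ValueError):
            annealing(SpeciesState(), rates, 0.0)


class TestTaqEfficiency:
    def test_full_activity_at_cycle_zero(self):
        for k_deg, beta in [(1e-4, 1.0), (2e-3, 2.61), (5e-4, 0.5)]:
            assert taq_efficiency(EnzymeDecayModel(k_deg=k_deg, beta=beta), 0, 15.0) == 1.0

    def test_first_order_half_life(self):
        # beta=1 and k_deg*t_den*c = ln 2 halves the activity
        model = EnzymeDecayModel(k_deg=math.log(2) / 15.0, beta=1.0)
        assert taq_efficiency(model, 1, 15.0) == pytest.approx(0.5, rel=1e-12)

    def test_scalar_evaluation(self):
        model = EnzymeDecayModel(k_deg=1e-4, beta=1.0)
        assert taq_efficiency(model, 40, 15.0) == pytest.approx(math.exp(-0.06), rel=1e-12)

    def test_monotone_non_increasing_and_stretched_shape(self):
        model = EnzymeDecayModel(k_deg=5e-4, beta=2.61)
        effs = [taq_efficiency(model, c, 15.0) for c in range(61)]
        assert all(a >= b for a, b in zip(effs, effs[1:]))
        # beta=1 reduces exactly to first-order decay
        m1 = EnzymeDecayModel(k_deg=5e-4, beta=1.0)
        for c in (1, 7, 40):
            assert taq_efficiency(m1, c, 15.0) == pytest.approx(
                math.exp(-5e-4 * 15.0 * c), rel=1e-12
            )

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            taq_efficiency(EnzymeDecayModel(), -1, 15.0)


class TestElongation:
    def test_full_activity_converts_hybrids_without_probe_signal(self):
        out, dF = elongation(SpeciesState(H1=3e-9), 1.0)
        assert out.AA == pytest.approx(3e-9)
        assert out.H1 == 0.0
        assert dF == 0.0

    def test_probe_cleavage_on_ternary_hybrids(self):
        out, dF = elongation(SpeciesState(AQP=2e-9, H1Q=1e-9), 1.0)
        assert out.AA == pytest.approx(3e-9)
        assert dF == pytest.approx(3e-9)
        assert out.cleavedQ_cum == pytest.approx(3e-9)

    def test_zero_activity_is_identity(self, rng):
        s = random_state(rng)
        out, dF = elongation(s, 0.0)
        assert out == s and dF == 0.0

    def test_aq_and_pd_pass_through(self):
        out, _ = elongation(SpeciesState(AQ=1e-9, PD=2e-9), 1.0)
        assert out.AQ == 1e-9 and out.PD == 2e-9

    def test_strand_synthesis_bookkeeping(self, rng):
        # P_rev family drops by Eff*(H1+AQP+H1Q); A_rev family gains the
        # same; Q family drops by exactly dF
        s = random_state(rng)
        eff = 0.37
        before = s.family_totals()
        out, dF = elongation(s, eff)
        after = out.family_totals()
        delta = eff * (s.H1 + s.AQP + s.H1Q)
        assert before["P_rev"] - after["P_rev"] == pytest.approx(delta, rel=1e-12)
        assert after["A_rev"] - before["A_rev"] == pytest.approx(delta, rel=1e-12)
        assert before["Q"] - after["Q"] == pytest.approx(dF, rel=1e-12)
        # the forward family gains the elongated H2 (new A_for strands)
        assert after["A_for"] - before["A_for"] == pytest.approx(eff * s.H2, rel=1e-12)

    def test_activity_bounds_enforced(self):
        with pytest.raises(ValueError):
            elongation(SpeciesState(), 1.5)


class TestCycles:
    def test_ntc_cycle_is_identity_without_primer_dimer(self, rates):
        rc = make_rates(
            k1_on=rates.k1_on, k1_off=rates.k1_off, k2_on=rates.k2_on,
            k2_off=rates.k2_off, kQ_on=rates.kQ_on, kQ_off=rates.kQ_off,
            kr_on=rates.kr_on,
        )  # kPD_on = 0
        s = init_state(InitialConditions(template=0.0))
        rec = run_1_cycle(s, rc, ProtocolConfig(), EnzymeDecayModel(), 1)
        assert rec.dF == 0.0
        assert rec.state.to_vector() == pytest.approx(s.to_vector(), rel=1e-9, abs=1e-20)

    def test_template_doubles_under_saturating_annealing(self, rates):
        a0 = 1.66e-12
        s = SpeciesState(AA=a0, P_for=4.5e-7, P_rev=4.5e-7, Q=1.5e-7)
        prot = ProtocolConfig(time_annealing=300.0)  # long anneal saturates
        rec = run_1_cycle(s, rates, prot, EnzymeDecayModel(), 1)
        assert rec.state.AA == pytest.approx(2 * a0, rel=0.05)

    def test_partial_elongation_leftovers_dissociate_next_cycle(self, rates):
        s = SpeciesState(AA=1e-11, P_for=4.5e-7, P_rev=4.5e-7, Q=1.5e-7)
        enzyme = EnzymeDecayModel(k_deg=2e-3, beta=1.0)
        rec1 = run_1_cycle(s, rates, ProtocolConfig(), enzyme, 10)
        assert rec1.state.H1 > 0  # partial elongation leaves hybrids
        rec2 = run_1_cycle(rec1.state, rates, ProtocolConfig(), enzyme, 11)
        # the leftovers were dissociated and re-annealed, not accumulated
        assert rec2.state.AA > rec1.state.AA

    def test_ntc_run_never_fluoresces(self, rates):
        recs = run_PCR(
            InitialConditions(template=0.0), rates, ProtocolConfig(n_cycles=20)
        )
        assert np.all(fluorescence_curve(recs) == 0.0)

    def test_probe_mass_bounds_fluorescence(self, rng, assay, rates):
        for _ in range(3):
            q0 = float(rng.uniform(5e-8, 3e-7))
            ic = InitialConditions(
                template=float(rng.uniform(1e3, 1e7)),
                p_for=float(rng.uniform(1e-7, 6e-7)),
                p_rev=float(rng.uniform(1e-7, 6e-7)),
                q=q0,
            )
            recs = run_PCR(ic, rates, ProtocolConfig(n_cycles=40))
            F = fluorescence_curve(recs)
            assert np.all(np.diff(F) >= -1e-20)
            assert F[-1] <= q0 * (1 + 1e-9)

    def test_amplification_without_probe_is_silent(self, rates):
        ic = InitialConditions(template=1e6, q=0.0)
        recs = run_PCR(ic, rates, ProtocolConfig(n_cycles=30))
        assert np.all(fluorescence_curve(recs) == 0.0)
        assert recs[-1].state.AA > 100 * recs[0].state.AA

    def test_early_cycle_doubling(self, rates):
        recs = run_PCR(
            InitialConditions(template=1e4), rates, ProtocolConfig(n_cycles=10)
        )
        totals = [
            r.state.AA + r.state.A_for + r.state.H1 + r.state.AQ + r.state.AQP + r.state.H1Q
            for r in recs
        ]
        ratios = [b / a for a, b in zip(totals, totals[1:])]
        assert ratios[-1] == pytest.approx(2.0, abs=0.1)

    def test_sigmoidal_curve_with_plateau_and_depletion(self, setup60):
        recs = setup60.run(1e7)
        F = fluorescence_curve(recs)
        assert np.all(np.diff(F) >= 0)
        # plateau: last cycles nearly flat relative to total signal
        assert (F[-1] - F[-5]) < 0.01 * F[-1]
        # primers and probe monotonically depleted across cycles
        p_rev = np.array([r.state.P_rev for r in recs])
        q = np.array([r.state.Q for r in recs])
        assert np.all(np.diff(p_rev) <= 1e-20)
        assert np.all(np.diff(q) <= 1e-20)

    def test_deterministic(self, rates):
        ic = InitialConditions(template=1e5)
        a = fluorescence_curve(run_PCR(ic, rates, ProtocolConfig(n_cycles=15)))
        b = fluorescence_curve(run_PCR(ic, rates, ProtocolConfig(n_cycles=15)))
        assert np.array_equal(a, b)
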