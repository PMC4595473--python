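"""Equilibrium observables and generator assembly of the twelve-state model."""

import numpy as np
import pytest

from ipr_gating import (
    FluxParams,
    LigandCondition,
    OccupancyParams,
    build_generator,
    mean_times,
    modal_lifetime,
    modal_prevalences,
    open_probability,
    state_occupancies,
    stationary_distribution,
    total_flux,
)
from ipr_gating.model import equilibrium_summary, rsr, transition_rates
from ipr_gating.states import (
    CLOSED_STATES,
    MODE_STATES,
    OPEN_STATES,
    STATE_INDEX,
    STATE_NAMES,
    STATES,
)


class TestStateSpace:
    def test_partition_into_open_and_closed(self):
        assert len(OPEN_STATES) == 3 and len(CLOSED_STATES) == 9
        assert STATE_NAMES[:3] == OPEN_STATES

    def test_mode_membership(self):
        assert set(MODE_STATES["L"]) == {"C00L", "C20L", "C30L", "C32L", "C34L", "C04L"}
        assert set(MODE_STATES["I"]) == {"C04I", "C24I", "O14I", "O24I"}
        assert set(MODE_STATES["H"]) == {"C24H", "O24H"}

    def test_stoichiometry_parsed_from_names(self):
        by_name = {s.name: s for s in STATES}
        assert (by_name["O14I"].ca_bound, by_name["O14I"].ip3_bound) == (1, 4)
        assert by_name["C00L"].conductance == "closed"
        assert by_name["O24H"].mode == "H"

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            LigandCondition(-0.1, 1.0)
        with pytest.raises(ValueError):
            LigandCondition(1.0, -1e-9)


class TestOccupancies:
    def test_unliganded_channel_sits_in_reference_state(self, wt):
        occ, _ = wt
        z, total = state_occupancies(occ, LigandCondition(0.0, 0.0))
        assert total == pytest.approx(1.0)
        assert z[STATE_INDEX["C00L"]] == 1.0
        assert np.count_nonzero(z) == 1
        assert open_probability(occ, LigandCondition(0.0, 0.0)) == 0.0

    def test_occupancy_is_weight_times_ligand_powers(self, wt):
        # O24H at 1 uM Ca2+, 10 uM IP3: K * C^2 * I^4 = 8.702e8 * 1 * 1e4
        occ, _ = wt
        z, _ = state_occupancies(occ, LigandCondition(1.0, 10.0))
        assert z[STATE_INDEX["O24H"]] == pytest.approx(8.702e12, rel=1e-12)

    def test_mutant_occupancy_ratios(self, wt, mutant):
        # the four parameters that change under PS1-M146L, to printed precision
        occ_w, _ = wt
        occ_m, _ = mutant
        ratios = {s: occ_m[s] / occ_w[s] for s in ("O24H", "O24I", "O14I", "C32L")}
        assert ratios["O24H"] == pytest.approx(4.587, abs=5e-4)
        assert ratios["O24I"] == pytest.approx(1.718, abs=5e-4)
        assert ratios["O14I"] == pytest.approx(1.284, abs=5e-4)
        assert ratios["C32L"] == pytest.approx(0.018, abs=5e-4)
        unchanged = set(STATE_NAMES) - set(ratios)
        assert all(occ_m[s] == occ_w[s] for s in unchanged)


class TestOpenProbabilityAndPrevalence:
    def test_no_ip3_means_no_opening(self, wt, mutant):
        for occ, _ in (wt, mutant):
            for ca in (0.0, 0.07, 1.0, 10.0):
                assert open_probability(occ, LigandCondition(ca, 0.0)) == 0.0
                pl, pi, ph = modal_prevalences(occ, LigandCondition(ca, 0.0))
                assert pl == 1.0 and pi == 0.0 and ph == 0.0

    def test_reported_prevalences_at_fitting_condition(self, wt, mutant, optimal_lig):
        (occ_w, _), (occ_m, _) = wt, mutant
        pl_w, pi_w, ph_w = modal_prevalences(occ_w, optimal_lig)
        pl_m, pi_m, ph_m = modal_prevalences(occ_m, optimal_lig)
        assert ph_m == pytest.approx(0.836, abs=0.005)
        assert pl_w == pytest.approx(0.515, abs=0.005)
        assert pl_m == pytest.approx(0.059, abs=0.005)
        assert ph_w == pytest.approx(0.345, abs=0.005)

    def test_mutant_open_probability_at_resting_ip3(self, mutant):
        occ, _ = mutant
        assert open_probability(occ, LigandCondition(1.0, 0.008)) == pytest.approx(
            0.35, abs=0.01
        )

    def test_prevalences_normalized_and_bounded(self, wt, mutant, ligand_grid):
        for occ, _ in (wt, mutant):
            for lig in ligand_grid:
                pl, pi, ph = modal_prevalences(occ, lig)
                assert pl + pi + ph == pytest.approx(1.0, abs=1e-12)
                assert min(pl, pi, ph) >= 0.0
                assert 0.0 <= open_probability(occ, lig) <= 1.0

    def test_po_nondecreasing_in_ip3_at_optimal_ca(self, wt, mutant):
        ip3s = np.geomspace(1e-3, 10.0, 200)
        for occ, _ in (wt, mutant):
            po = [open_probability(occ, LigandCondition(1.0, float(i))) for i in ip3s]
            assert (np.diff(po) >= -1e-12).all()

    def test_mutant_sensitization_in_subsaturating_ip3(self, wt, mutant):
        # the mutant channel is roughly twice as active in subsaturating IP3
        # on the physiological Ca2+ range; the ratio exceeds 2 up to 100 nM
        # IP3 and dips to ~1.89 as IP3 approaches 200 nM
        (occ_w, _), (occ_m, _) = wt, mutant
        for ca in np.geomspace(0.07, 2.0, 8):
            for ip3 in np.geomspace(0.001, 0.2, 8):
                lig = LigandCondition(float(ca), float(ip3))
                ratio = open_probability(occ_m, lig) / open_probability(occ_w, lig)
                assert ratio > 1.85
                if ip3 <= 0.1:
                    assert ratio > 2.0


class TestGenerator:
    def test_rsr_of_equal_rates(self):
        assert rsr(2.0, 2.0) == pytest.approx(1.0)
        assert rsr(3.0, 3.0, 3.0) == pytest.approx(1.0)
        assert rsr(1.0, 0.0) == 0.0  # a blocked step blocks the pathway

    def test_h_mode_opening_rate_from_printed_parameters(self, wt):
        occ, flux = wt
        r = transition_rates(occ, flux, LigandCondition(1.0, 0.1))
        assert r["C24H", "O24H"] == pytest.approx(5.478e7 / 3.082e8, rel=1e-12)

    def test_generator_structure(self, wt, mutant, ligand_grid):
        for occ, flux in (wt, mutant):
            for lig in ligand_grid:
                gen = build_generator(occ, flux, lig)
                off = gen.Q - np.diag(np.diag(gen.Q))
                assert (off >= 0).all()
                assert np.abs(gen.Q.sum(axis=1)).max() < 1e-12 * max(1, np.abs(gen.Q).max())
                # exactly the 15 reversible pairs are populated
                assert np.count_nonzero(off) <= 30

    def test_stationary_distribution_matches_occupancies(self, wt, mutant, ligand_grid):
        # kinetic route (null space of Q^T) vs thermodynamic route (Eq-1
        # weights); agreement is limited by the printed precision of the
        # copied-transition occupancies, see the structural-consistency note
        # in the methods document
        for occ, flux in (wt, mutant):
            for lig in ligand_grid:
                gen = build_generator(occ, flux, lig)
                p = stationary_distribution(gen)
                w = gen.weights / gen.weights.sum()
                assert np.abs(p - w).max() / w.max() < 5e-5

    def test_detailed_balance_to_printed_precision(self, wt, mutant, optimal_lig):
        for occ, flux in (wt, mutant):
            z, _ = state_occupancies(occ, optimal_lig)
            r = transition_rates(occ, flux, optimal_lig)
            for (s, u), v in r.items():
                fwd = z[STATE_INDEX[s]] * v
                bwd = z[STATE_INDEX[u]] * r[u, s]
                assert fwd == pytest.approx(bwd, rel=1e-3)

    def test_zero_ligand_rates_finite(self, wt):
        occ, flux = wt
        for lig in (LigandCondition(0.0, 0.0), LigandCondition(1.0, 0.0),
                    LigandCondition(0.0, 0.1)):
            r = transition_rates(occ, flux, lig)
            assert all(np.isfinite(v) for v in r.values())


class TestFluxAndMeanTimes:
    def test_flux_vanishes_without_ip3(self, wt):
        occ, flux = wt
        assert total_flux(occ, flux, LigandCondition(1.0, 0.0)) == 0.0

    def test_flux_matrix_identity(self, wt, mutant, ligand_grid):
        # per-state sum over closing transitions vs W_O @ Q_OC @ 1
        for occ, flux in (wt, mutant):
            for lig in ligand_grid:
                J = total_flux(occ, flux, lig)
                gen = build_generator(occ, flux, lig)
                assert J == pytest.approx(gen.exit_flux(), rel=1e-10)

    def test_mean_times_reconstruct_open_probability(self, wt, mutant, ligand_grid):
        for occ, flux in (wt, mutant):
            for lig in ligand_grid:
                if lig.ip3 == 0:
                    continue
                tau_o, tau_c = mean_times(occ, flux, lig)
                po = tau_o / (tau_o + tau_c)
                assert po == pytest.approx(open_probability(occ, lig), rel=1e-12)

    def test_mean_times_undefined_without_ip3(self, wt):
        occ, flux = wt
        with pytest.raises(ValueError):
            mean_times(occ, flux, LigandCondition(1.0, 0.0))

    def test_mutant_shortens_closed_time(self, wt, mutant, optimal_lig):
        (occ_w, flux_w), (occ_m, flux_m) = wt, mutant
        _, tc_w = mean_times(occ_w, flux_w, optimal_lig)
        _, tc_m = mean_times(occ_m, flux_m, optimal_lig)
        assert tc_m < tc_w


class TestModalLifetimes:
    def test_full_chain_has_no_exit(self, wt, optimal_lig):
        occ, flux = wt
        with pytest.raises(ValueError):
            modal_lifetime(occ, flux, optimal_lig, list(STATE_NAMES))

    def test_h_mode_exit_flux_matches_printed_expansion(self, wt, mutant, optimal_lig):
        # Z_H / tau_H must equal the explicit sum over the four H-exit channels
        for occ, flux in (wt, mutant):
            z, _ = state_occupancies(occ, optimal_lig)
            r = transition_rates(occ, flux, optimal_lig)
            jh = (
                z[STATE_INDEX["O24H"]] * (r["O24H", "C34L"] + r["O24H", "O24I"])
                + z[STATE_INDEX["C24H"]] * (r["C24H", "C04I"] + r["C24H", "C20L"])
            )
            zh = z[STATE_INDEX["O24H"]] + z[STATE_INDEX["C24H"]]
            tau = modal_lifetime(occ, flux, optimal_lig, "H")
            assert tau == pytest.approx(zh / jh, rel=1e-10)

    def test_mutant_mode_lifetime_shifts(self, wt, mutant, optimal_lig):
        # longer H-mode and shorter L-mode life in the mutant drive its
        # higher open probability
        (occ_w, flux_w), (occ_m, flux_m) = wt, mutant
        assert modal_lifetime(occ_m, flux_m, optimal_lig, "H") > modal_lifetime(
            occ_w, flux_w, optimal_lig, "H"
        )
        assert modal_lifetime(occ_m, flux_m, optimal_lig, "L") < modal_lifetime(
            occ_w, flux_w, optimal_lig, "L"
        )


class TestSummaryAndParams:
    def test_equilibrium_summary_internal_identities(self, wt, optimal_lig):
        occ, flux = wt
        s = equilibrium_summary(occ, flux, optimal_lig)
        assert s.Z == pytest.approx(s.Zo + s.Zc, rel=1e-12)
        assert s.Po == pytest.approx(s.Zo / s.Z, rel=1e-12)
        assert s.pi_L + s.pi_I + s.pi_H == pytest.approx(1.0, abs=1e-12)
        assert s.Po == pytest.approx(s.tau_o_ms / (s.tau_o_ms + s.tau_c_ms), rel=1e-12)

    def test_parameter_validation(self):
        occ = OccupancyParams.wild_type()
        with pytest.raises(ValueError):
            occ.with_values(C00L=2.0)  # reference weight is pinned
        with pytest.raises(ValueError):
            occ.with_values(O24H=-1.0)
        with pytest.raises(ValueError):
            FluxParams.wild_type().with_values(j2424HH=0.0)

    def test_mutant_differs_in_exactly_two_flux_parameters(self):
        jw, jm = FluxParams.wild_type(), FluxParams.m146l()
        diff = {k for k in jw.values if jw[k] != jm[k]}
        assert diff == {"j0414II", "j2424HH"}

    def test_config_roundtrip(self, tmp_path, mutant):
        from ipr_gating import load_params, save_params

        occ, flux = mutant
        path = tmp_path / "m146l.yaml"
        save_params(path, occ, flux)
        occ2, flux2 = load_params(path)
        assert occ2.values == occ.values
        assert flux2.values == flux.values
        assert occ2.variant == "M146L"
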