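"""Nucleotide-cap kinetics: ODE solution vs closed form, pair
combinatorics, PSF convolution and mixed-lattice theory."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebtip import nucsim


def closed_form(params: nucsim.KineticParams, layers: np.ndarray):
    """Independent oracle: analytic solution of the linear cascade
    T' = -k1 T, P' = k1 T - k2 P (k1 != k2)."""
    k1, k2 = params.kappa1, params.kappa2
    T = np.exp(-k1 * layers)
    P = k1 / (k1 - k2) * (np.exp(-k2 * layers) - np.exp(-k1 * layers))
    return T, P, 1.0 - T - P


class TestOdes:
    def test_boundary_condition_at_tip(self):
        prof = nucsim.solve_nucleotide_odes(nucsim.KineticParams(max_layers=10))
        assert (prof.T[0], prof.P[0], prof.D[0]) == (1.0, 0.0, 0.0)

    def test_matches_closed_form_oracle(self):
        params = nucsim.KineticParams(k1_per_s=0.3, k2_per_s=0.15,
                                      growth_speed_nm_s=20.0, max_layers=1000)
        prof = nucsim.solve_nucleotide_odes(params)
        T, P, D = closed_form(params, prof.layers)
        assert np.max(np.abs(prof.T - T) / T) < 1e-6
        mask = P > 0
        assert np.max(np.abs(prof.P - P)[mask] / P[mask]) < 1e-6
        assert np.max(np.abs(prof.D - D)) < 1e-6

    def test_gtp_fraction_at_100nm(self):
        # T(100 nm) = exp(-k1 * 100 / v) = exp(-1.5) = 0.2231
        params = nucsim.KineticParams(0.3, 0.15, 20.0, max_layers=50,
                                      samples_per_layer=8)
        prof = nucsim.solve_nucleotide_odes(params)
        t100 = np.interp(100.0, prof.position_nm, prof.T)
        assert t100 == pytest.approx(np.exp(-1.5), rel=1e-4)

    def test_gdp_pi_peak_position(self):
        # P is maximal at x* = v ln(k1/k2) / (k1 - k2) = 92.4 nm
        params = nucsim.KineticParams(0.3, 0.15, 20.0, max_layers=60,
                                      samples_per_layer=8)
        prof = nucsim.solve_nucleotide_odes(params)
        x_star = 20.0 * np.log(2.0) / 0.15
        assert prof.position_nm[np.argmax(prof.P)] == pytest.approx(x_star, abs=1.5)

    def test_growth_speed_rescales_profiles(self):
        slow = nucsim.solve_nucleotide_odes(
            nucsim.KineticParams(growth_speed_nm_s=20.0, max_layers=200))
        fast = nucsim.solve_nucleotide_odes(
            nucsim.KineticParams(growth_speed_nm_s=40.0, max_layers=400))
        # doubling v stretches every profile by exactly 2x in nm
        t_interp = np.interp(2 * slow.position_nm, fast.position_nm, fast.T)
        assert np.allclose(t_interp, slow.T, rtol=1e-6, atol=1e-9)

    def test_zero_growth_speed_rejected(self):
        with pytest.raises(ValueError, match="growth speed"):
            nucsim.solve_nucleotide_odes(
                nucsim.KineticParams(growth_speed_nm_s=0.0))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(k1=st.floats(0.05, 1.0), k2=st.floats(0.05, 1.0),
           v=st.floats(5.0, 50.0))
    def test_conservation_property(self, k1, k2, v):
        params = nucsim.KineticParams(k1_per_s=k1, k2_per_s=k2,
                                      growth_speed_nm_s=v, max_layers=50)
        prof = nucsim.solve_nucleotide_odes(params)
        assert np.max(np.abs(prof.T + prof.P + prof.D - 1.0)) < 1e-9
        assert np.all(np.diff(prof.T) <= 1e-12)  # T non-increasing


class TestPairDistributions:
    def test_all_gtp_layer(self):
        prof = nucsim.NucleotideProfile(np.array([0.0]), np.array([1.0]),
                                        np.array([0.0]), np.array([0.0]))
        pairs = nucsim.pair_distributions(prof, 13)
        assert pairs.densities["TT"][0] == pytest.approx(13.0)
        for state in ("TP", "PP", "PD", "TD", "DD"):
            assert pairs.densities[state][0] == 0.0

    def test_mixed_layer_combinatorics(self):
        # (T,P,D) = (0.5, 0.3, 0.2): PP = 0.09*13, TP = 0.30*13, DD = 0.04*13
        prof = nucsim.NucleotideProfile(np.array([5.0]), np.array([0.5]),
                                        np.array([0.3]), np.array([0.2]))
        pairs = nucsim.pair_distributions(prof, 13)
        assert pairs.densities["PP"][0] == pytest.approx(1.17)
        assert pairs.densities["TP"][0] == pytest.approx(3.90)
        assert pairs.densities["DD"][0] == pytest.approx(0.52)

    def test_pair_states_sum_to_protofilaments(self):
        params = nucsim.KineticParams(max_layers=300)
        pairs = nucsim.pair_distributions(
            nucsim.solve_nucleotide_odes(params), 13)
        total = sum(pairs.densities.values())
        assert np.max(np.abs(total - 13.0)) < 1e-9

    def test_unnormalised_fractions_rejected(self):
        prof = nucsim.NucleotideProfile(np.array([0.0]), np.array([0.9]),
                                        np.array([0.3]), np.array([0.2]))
        with pytest.raises(ValueError, match="sum to 1"):
            nucsim.pair_distributions(prof)


class TestPsfConvolution:
    def test_dirac_becomes_gaussian(self):
        dens = {s: np.zeros(200) for s in nucsim.PAIR_STATES}
        dens["TT"][50] = 5.0
        pp = nucsim.NucleotidePairProfile(np.arange(200.0), dens, 13)
        out = nucsim.convolve_with_psf(pp, 130.0)
        grid, curve = out["TT"]
        x0 = 50 * 8.0
        assert curve.max() == pytest.approx(1.0)
        assert grid[np.argmax(curve)] == pytest.approx(x0, abs=8.0)
        expected = np.exp(-0.5 * ((grid - x0) / 130.0) ** 2)
        assert np.allclose(curve, expected, atol=1e-6)

    def test_area_preserved_by_unit_kernel(self):
        params = nucsim.KineticParams(max_layers=400)
        pairs = nucsim.pair_distributions(nucsim.solve_nucleotide_odes(params))
        raw = nucsim.convolve_with_psf(pairs, 130.0, normalise=False)
        for state in ("TP", "PP"):
            grid, curve = raw[state]
            area_after = np.trapezoid(curve, grid)
            area_before = np.trapezoid(pairs.densities[state],
                                       pairs.position_nm)
            assert area_after == pytest.approx(area_before, rel=1e-6)

    def test_peak_order_follows_hydrolysis_sequence(self):
        # k1 > k2: peaks appear in lattice order TT < TP < PP < PD
        params = nucsim.KineticParams(k1_per_s=0.3, k2_per_s=0.13,
                                      max_layers=800)
        pairs = nucsim.pair_distributions(nucsim.solve_nucleotide_odes(params))
        conv = nucsim.convolve_with_psf(pairs, 130.0)
        peaks = {s: conv[s][0][np.argmax(conv[s][1])]
                 for s in ("TT", "TP", "PP", "PD")}
        assert peaks["TT"] < peaks["TP"] < peaks["PP"] < peaks["PD"]

    def test_pp_peak_shifts_distally_as_k2_decreases(self):
        def pp_peak(k2):
            params = nucsim.KineticParams(k1_per_s=0.3, k2_per_s=k2,
                                          max_layers=1500)
            pairs = nucsim.pair_distributions(
                nucsim.solve_nucleotide_odes(params))
            grid, curve = nucsim.convolve_with_psf(pairs, 130.0)["PP"]
            return grid[np.argmax(curve)]

        assert pp_peak(0.065) > pp_peak(0.13) > pp_peak(0.26)

    def test_empty_profile_rejected(self):
        pp = nucsim.NucleotidePairProfile(
            np.array([]), {s: np.array([]) for s in nucsim.PAIR_STATES}, 13)
        with pytest.raises(ValueError, match="empty"):
            nucsim.convolve_with_psf(pp)


class TestMixedLattice:
    def test_half_fraction_values(self):
        curve = nucsim.mixed_lattice_theory([0.5])
        assert curve.mixed_pairs[0] == pytest.approx(0.5)
        assert curve.pairs[0] == pytest.approx(0.25)
        assert curve.triplets[0] == pytest.approx(0.125)
        assert curve.quartets[0] == pytest.approx(0.0625)

    def test_pure_lattice(self):
        curve = nucsim.mixed_lattice_theory([1.0])
        for attr in ("singles", "pairs", "triplets", "quartets"):
            assert getattr(curve, attr)[0] == 1.0
        assert curve.mixed_pairs[0] == 0.0

    def test_mixed_pairs_maximal_at_half(self):
        f = np.linspace(0.0, 1.0, 201)
        curve = nucsim.mixed_lattice_theory(f)
        assert f[np.argmax(curve.mixed_pairs)] == pytest.approx(0.5)
        # partition of lateral pairs: f^2 + 2f(1-f) + (1-f)^2 = 1
        assert np.allclose(curve.pairs + curve.mixed_pairs + (1 - f) ** 2, 1.0)

    def test_fraction_domain_enforced(self):
        with pytest.raises(ValueError):
            nucsim.mixed_lattice_theory([1.2])
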