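"""Two-site exchange: Bloch-McConnell CEST, Carver-Richards CPMG, global
fitting and fixed-parameter delta-omega extraction."""

import numpy as np
import pytest

from foldbind.exchange import (CESTProfile, CPMGProfile, TwoSiteExchangeModel,
                               extract_dw, fit_global, rad_per_ppm,
                               simulate_cest, simulate_cest_numeric,
                               simulate_cpmg, simulate_cpmg_numeric)
from foldbind.synthetic import gen_cest_dataset, jnk1_scenario, p38a_scenario

OFFSETS = np.arange(-6.0, 6.01, 0.25)


def model(kEX=100.0, pB=0.087, dA=0.0, dw=3.0, r1=1.5, r2a=5.0, r2b=69.0):
    return TwoSiteExchangeModel(kEX, pB, dA, dA + dw, R1_A=r1,
                                R2_A=r2a, R2_B=r2b)


class TestModelInvariants:
    def test_detailed_balance(self):
        m = model(kEX=137.0, pB=0.0613)
        assert m.k_AB + m.k_BA == pytest.approx(m.kEX, abs=1e-12)
        assert m.k_AB * (1 - m.p_bound) == pytest.approx(
            m.k_BA * m.p_bound, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            TwoSiteExchangeModel(-1.0, 0.1)
        with pytest.raises(ValueError):
            TwoSiteExchangeModel(100.0, 1.2)
        with pytest.raises(ValueError):
            TwoSiteExchangeModel(100.0, 0.1, R2_A=-3.0)

    def test_carrier_frequency_ratio(self):
        prof = CESTProfile(1, 700.0, 21.0, 0.3, OFFSETS)
        assert prof.carrier_MHz == pytest.approx(700.0 * 0.101396, rel=1e-3)


class TestSimulateCest:
    def test_single_dip_at_free_shift_without_exchange(self):
        """p_bound -> 0: one dip at delta_A, deepening with B1 and T_sat."""
        m = model(pB=1e-9, dA=1.5, dw=3.0)
        prof = simulate_cest(m, CESTProfile(1, 700.0, 21.0, 0.3, OFFSETS))
        dip = OFFSETS[np.argmin(prof.intensity_ratio)]
        assert dip == pytest.approx(1.5, abs=0.25)
        # no secondary dip at delta_B
        i_b = np.argmin(np.abs(OFFSETS - 4.5))
        base = np.median(prof.intensity_ratio)
        assert prof.intensity_ratio[i_b] == pytest.approx(base, abs=0.02)
        deeper = simulate_cest(m, CESTProfile(1, 700.0, 35.0, 0.3, OFFSETS))
        longer = simulate_cest(m, CESTProfile(1, 700.0, 21.0, 0.6, OFFSETS))
        assert deeper.intensity_ratio.min() < prof.intensity_ratio.min()
        assert longer.intensity_ratio.min() < prof.intensity_ratio.min()

    def test_far_offset_reduces_to_longitudinal_decay(self):
        m = model(pB=0.01, dA=0.0, dw=1.0, r1=1.5)
        far = np.array([200.0, -200.0])
        prof = simulate_cest(m, CESTProfile(1, 700.0, 21.0, 0.3, far))
        assert prof.intensity_ratio == pytest.approx(
            np.exp(-1.5 * 0.3), abs=1e-3)

    def test_b1_zero_is_pure_longitudinal_relaxation(self):
        """B1 = 0: no offset dependence, I/I0 = exp(-R1 T) exactly for
        tied R1 (longitudinal block decouples from exchange)."""
        m = model(pB=0.087, r1=1.5)
        prof = simulate_cest(m, CESTProfile(1, 700.0, 0.0, 0.3, OFFSETS))
        assert np.ptp(prof.intensity_ratio) < 1e-12
        assert prof.intensity_ratio[0] == pytest.approx(
            np.exp(-1.5 * 0.3), rel=1e-9)

    def test_matches_fine_step_integration(self):
        """Matrix-exponential propagation agrees with RK4 at dt = 10 us to
        |dI/I0| < 1e-6 (3 ppm dw, kEX = 100 s^-1)."""
        m = model(kEX=100.0, pB=0.087, dw=3.0)
        prof_spec = CESTProfile(1, 700.0, 21.0, 0.3, OFFSETS)
        sim = simulate_cest(m, prof_spec).intensity_ratio
        num = simulate_cest_numeric(m, prof_spec, dt=1e-5)
        assert np.max(np.abs(sim - num)) < 1e-6

    def test_dip_positions_slow_vs_fast_exchange(self):
        """Dips sit at delta_A and delta_B for slow exchange and merge
        toward the population average as kEX grows."""
        grid = np.arange(-2.0, 5.01, 0.05)
        slow = simulate_cest(model(kEX=5.0, pB=0.3, dA=0.0, dw=3.0),
                             CESTProfile(1, 700.0, 15.0, 0.5, grid))
        y = slow.intensity_ratio
        i_a = np.argmin(np.abs(grid - 0.0))
        i_b = np.argmin(np.abs(grid - 3.0))
        assert y[i_a] < np.median(y) - 0.2
        assert y[i_b] < np.median(y) - 0.1  # minor dip, shallower
        fast = simulate_cest(model(kEX=50000.0, pB=0.3, dA=0.0, dw=3.0),
                             CESTProfile(1, 700.0, 15.0, 0.5, grid))
        dip_fast = grid[np.argmin(fast.intensity_ratio)]
        assert dip_fast == pytest.approx(0.3 * 3.0, abs=0.15)

    def test_rejects_empty_offsets(self):
        with pytest.raises(ValueError):
            CESTProfile(1, 700.0, 21.0, 0.3, np.array([]))


class TestSimulateCpmg:
    def test_flat_dispersion_without_shift_difference(self):
        m = model(dw=0.0, pB=0.1, r2a=5.0, r2b=69.0)
        prof = simulate_cpmg(m, [50.0, 200.0, 1000.0], 600.0)
        assert prof.r2_eff == pytest.approx(0.9 * 5.0 + 0.1 * 69.0, abs=1e-9)

    def test_fast_exchange_amplitude(self):
        """kEX >> dw: dispersion amplitude -> pA pB dw_rad^2 / kEX."""
        m = model(kEX=20000.0, pB=0.062, dw=0.5, r2a=8.0, r2b=8.0)
        prof = simulate_cpmg(m, [10.0, 50000.0], 600.0)
        dwr = 0.5 * rad_per_ppm(600.0)
        expected = (1 - 0.062) * 0.062 * dwr**2 / 20000.0
        assert prof.r2_eff[0] - prof.r2_eff[1] == pytest.approx(
            expected, rel=0.02)

    def test_matches_numerical_propagation(self):
        """Carver-Richards vs explicit echo-train propagation: < 2% over
        50-1000 Hz at the extended-complex parameters."""
        m = model(kEX=219.0, pB=0.062, dw=3.0, r2a=8.0, r2b=69.0)
        nu = np.linspace(50.0, 1000.0, 25)
        cr = simulate_cpmg(m, nu, 600.0).r2_eff
        num = simulate_cpmg_numeric(m, nu, 600.0)
        assert np.max(np.abs(cr - num) / num) < 0.02

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(ValueError):
            simulate_cpmg(model(), [-50.0], 600.0)

    def test_exchange_broadening_grows_with_pb_dw2(self):
        """Low-nu R2,eff increases monotonically with p_bound * dw^2."""
        lows = []
        for pb, dw in [(0.02, 1.0), (0.05, 2.0), (0.087, 3.0)]:
            m = model(kEX=99.0, pB=pb, dw=dw)
            lows.append(simulate_cpmg(m, [25.0], 600.0).r2_eff[0])
        assert lows[0] < lows[1] < lows[2]


class TestFitGlobal:
    def _dataset(self, seed=11, noise=0.0, subset=(38, 39, 42, 43, 44)):
        sc = jnk1_scenario(seed=seed)
        sc.noise_sd = noise
        sc.cest_fields = (700.0,)
        profiles = gen_cest_dataset(sc, residues=list(subset))
        free = {r: sc.free_shifts_rel()[r] for r in subset}
        return sc, profiles, free

    def test_noiseless_self_consistency(self):
        """Noiseless synthetic data: recovery to optimizer tolerance."""
        sc, profiles, free = self._dataset(noise=0.0)
        res = fit_global(profiles, free_shifts=free)
        assert abs(res.kEX - sc.kEX) / sc.kEX < 1e-4
        assert abs(res.p_bound - sc.pbound) / sc.pbound < 1e-4
        for r, est in res.dw.items():
            assert est.dw == pytest.approx(sc.dw(r), abs=1e-3)

    def test_noisy_recovery_with_errors(self):
        sc, profiles, free = self._dataset(noise=0.01, seed=21)
        res = fit_global(profiles, free_shifts=free)
        assert res.kEX == pytest.approx(sc.kEX, abs=8.0)
        assert res.p_bound == pytest.approx(sc.pbound, abs=0.006)
        assert 0 < res.kEX_error < 10.0
        assert 0 < res.p_bound_error < 0.01

    def test_no_exchange_information_rejected(self):
        """A subset with all dw = 0 is unidentifiable."""
        sc = jnk1_scenario(seed=3)
        sc.cest_fields = (700.0,)
        sc.dw_profile = {}
        profiles = gen_cest_dataset(sc, residues=[60, 61, 62])
        free = {r: sc.free_shifts_rel()[r] for r in (60, 61, 62)}
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_global(profiles, free_shifts=free)

    def test_needs_two_residues(self):
        sc, profiles, free = self._dataset()
        with pytest.raises(ValueError):
            fit_global([profiles[0]], free_shifts=free)


class TestExtractDw:
    def test_recovers_known_dw_at_fixed_truth(self):
        """Fixing (kEX, pB) at truth recovers per-residue dw."""
        sc = jnk1_scenario(seed=31)
        sc.cest_fields = (700.0,)
        subset = [42, 43, 44]
        profiles = gen_cest_dataset(sc, residues=subset)
        free = {r: sc.free_shifts_rel()[r] for r in subset}
        dw = extract_dw(profiles, sc.kEX, sc.pbound, free_shifts=free)
        for r in subset:
            assert dw[r].dw == pytest.approx(sc.dw(r), abs=0.1)
            assert not dw[r].flagged

    def test_zero_dw_residue_flagged_not_error(self):
        sc = jnk1_scenario(seed=31)
        sc.cest_fields = (700.0,)
        profiles = gen_cest_dataset(sc, residues=[60])
        free = {60: sc.free_shifts_rel()[60]}
        dw = extract_dw(profiles, sc.kEX, sc.pbound, free_shifts=free)
        assert dw[60].flagged
        assert abs(dw[60].dw) < 0.5

    def test_paired_scenarios_preserve_dw_ordering(self):
        """The helical complex's larger motif shift differences survive
        extraction: |dw_jnk1| > |dw_p38a| at the core motif residues."""
        shared = [41, 42, 43, 44]
        out = {}
        for make in (jnk1_scenario, p38a_scenario):
            sc = make(seed=17)
            sc.cest_fields = (700.0,)
            profiles = gen_cest_dataset(sc, residues=shared)
            free = {r: sc.free_shifts_rel()[r] for r in shared}
            out[sc.name] = extract_dw(profiles, sc.kEX, sc.pbound,
                                      free_shifts=free)
        for r in shared:
            assert abs(out["jnk1"][r].dw) > abs(out["p38a"][r].dw)

    def test_consistent_with_global_fit_on_subset(self):
        """extract_dw at the globally fitted (kEX, pB) reproduces the
        joint-fit dw within one joint-fit standard error."""
        sc = jnk1_scenario(seed=41)
        sc.noise_sd = 0.005
        sc.cest_fields = (700.0,)
        subset = [42, 43, 44, 45]
        profiles = gen_cest_dataset(sc, residues=subset)
        free = {r: sc.free_shifts_rel()[r] for r in subset}
        res = fit_global(profiles, free_shifts=free)
        dw = extract_dw(profiles, res.kEX, res.p_bound, free_shifts=free)
        for r in subset:
            tol = max(res.dw[r].dw_error, 1e-3)
            assert dw[r].dw == pytest.approx(res.dw[r].dw, abs=tol)
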