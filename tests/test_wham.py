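"""WHAM solver, shift convention, uncertainty and feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gdminsert.model import HairpinSpec
from gdminsert.synthetic import PotentialSpec, make_membrane_frame, sample_umbrella
from gdminsert.wham import (
    KJ_PER_KCAL,
    PMFProfile,
    UmbrellaWindow,
    extract_features,
    pmf_uncertainty,
    shift_pmf,
    thermal_energy_kj,
    wham_solve,
    zeta_series_from_trajectory,
)

from conftest import chain_topology, selections


def reference_wham_maximum_likelihood(windows, bin_width, bin_range,
                                      temperature=310.0):
    """Independent oracle: direct minimization of the binned WHAM likelihood.

    Solves for the window free energies by minimizing
    A(f) = sum_b n_b ln sum_i N_i exp(f_i - W_ib) - sum_i N_i f_i
    with scipy instead of fixed-point iteration, then reconstructs G.
    """
    from scipy.optimize import minimize
    from scipy.special import logsumexp

    kT = thermal_energy_kj(temperature)
    lo, hi = bin_range
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array([np.histogram(w.retained, bins=edges)[0] for w in windows])
    N = counts.sum(axis=1)
    n_b = counts.sum(axis=0)
    W = np.array([w.bias_energy(centers) for w in windows]) / kT
    logN = np.log(N)

    def objective(f):
        log_denom = logsumexp(logN[:, None] + f[:, None] - W, axis=0)
        return float(np.sum(n_b * log_denom) - np.sum(N * f))

    res = minimize(objective, np.zeros(len(windows)), method="L-BFGS-B",
                   options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 10000})
    f = res.x - res.x[0]
    log_denom = logsumexp(logN[:, None] + f[:, None] - W, axis=0)
    G = np.full(centers.size, np.nan)
    occ = n_b > 0
    G[occ] = -kT * (np.log(n_b[occ]) - log_denom[occ]) / KJ_PER_KCAL
    return centers, G


class TestWhamSolve:
    def test_unbiased_window_reduces_to_boltzmann_inversion(self):
        """With no bias, WHAM is the plain histogram free energy."""
        rng = np.random.default_rng(0)
        samples = rng.normal(0.5, 0.4, 5000)
        w = UmbrellaWindow(center=0.0, force_constant=0.0, samples=samples)
        prof = wham_solve([w], bin_width=0.1, bin_range=(-1.5, 2.5))
        kT = prof.kT_kcal
        h, _ = np.histogram(samples, bins=prof.bin_centers.size, range=(-1.5, 2.5))
        direct = np.where(h > 0, -kT * np.log(np.where(h > 0, h, 1)), np.nan)
        diff = prof.free_energy - direct
        diff = diff[np.isfinite(diff)]
        assert np.ptp(diff) < 1e-10  # equal up to one additive constant

    def test_double_well_recovery_within_tolerance(self, double_well,
                                                   small_umbrella_windows):
        prof = shift_pmf(wham_solve(small_umbrella_windows,
                                    bin_range=(-2.5, 3.0)))
        ref = np.asarray(double_well.energy(prof.bin_centers))
        ref -= ref[prof.bin_of(2.5)]
        m = prof.defined & (prof.window_coverage >= 2)
        rms = float(np.sqrt(np.mean((prof.free_energy[m] - ref[m]) ** 2)))
        assert rms <= 0.25  # light sampling; the sharp bound is in acceptance

    def test_agrees_with_independent_likelihood_maximizer(
            self, small_umbrella_windows):
        prof = wham_solve(small_umbrella_windows, bin_range=(-2.5, 3.0))
        centers, G_ref = reference_wham_maximum_likelihood(
            small_umbrella_windows, 0.05, (-2.5, 3.0))
        assert np.allclose(centers, prof.bin_centers)
        m = np.isfinite(G_ref) & prof.defined
        # both profiles are gauge-free up to a constant
        d = prof.free_energy[m] - G_ref[m]
        assert np.ptp(d) < 0.005

    def test_invariant_to_window_order(self, small_umbrella_windows):
        a = wham_solve(small_umbrella_windows, bin_range=(-2.5, 3.0))
        b = wham_solve(small_umbrella_windows[::-1], bin_range=(-2.5, 3.0))
        m = a.defined
        d = a.free_energy[m] - b.free_energy[m]
        assert np.nanmax(np.abs(d - d[0])) < 5e-6

    def test_merging_identical_windows_is_equivalent(self, double_well):
        wins = sample_umbrella(double_well, np.linspace(0.0, 1.0, 11),
                               n_per_window=4000, seed=3)
        half = [
            UmbrellaWindow(w.center, w.force_constant, w.samples[: len(w.samples) // 2])
            for w in wins
        ] + [
            UmbrellaWindow(w.center, w.force_constant, w.samples[len(w.samples) // 2:])
            for w in wins
        ]
        a = wham_solve(wins, bin_range=(-1.0, 2.0))
        b = wham_solve(half, bin_range=(-1.0, 2.0))
        m = a.defined & b.defined
        d = a.free_energy[m] - b.free_energy[m]
        assert np.nanmax(np.abs(d - d[0])) < 5e-6

    def test_widening_bin_range_keeps_defined_bins(self, small_umbrella_windows):
        a = wham_solve(small_umbrella_windows, bin_range=(-2.5, 3.0))
        b = wham_solve(small_umbrella_windows, bin_range=(-4.0, 4.5))
        # match bins by centre and compare the overlap, gauge-aligned
        common = {round(c, 6): g for c, g in zip(b.bin_centers, b.free_energy)}
        pairs = [
            (g, common[round(c, 6)])
            for c, g in zip(a.bin_centers, a.free_energy)
            if np.isfinite(g) and round(c, 6) in common
        ]
        d = np.array([x - y for x, y in pairs])
        assert np.nanmax(np.abs(d - d[0])) < 5e-6

    def test_empty_window_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            wham_solve([])

    def test_nonconvergence_reports_residual(self, small_umbrella_windows):
        with pytest.raises(RuntimeError, match="residual"):
            wham_solve(small_umbrella_windows, max_iter=3, bin_range=(-2.5, 3.0))

    def test_gap_between_windows_warns(self, double_well):
        wins = sample_umbrella(double_well, [-1.5, 2.0], n_per_window=2000, seed=1)
        with pytest.warns(UserWarning, match="share no occupied bin"):
            wham_solve(wins, bin_range=(-2.5, 3.0))


class TestShift:
    def test_zero_at_reference_bin(self, small_umbrella_windows):
        prof = shift_pmf(wham_solve(small_umbrella_windows, bin_range=(-2.5, 3.0)))
        assert prof.free_energy[prof.bin_of(2.5)] == 0.0

    def test_idempotent(self, small_umbrella_windows):
        p1 = shift_pmf(wham_solve(small_umbrella_windows, bin_range=(-2.5, 3.0)))
        p2 = shift_pmf(p1)
        assert np.array_equal(p1.free_energy, p2.free_energy, equal_nan=True)

    def test_undefined_reference_suggests_nearest(self):
        prof = PMFProfile(
            bin_centers=np.array([0.0, 1.0, 2.0, 3.0]),
            free_energy=np.array([1.0, 2.0, np.nan, np.nan]),
        )
        with pytest.raises(ValueError, match="1.000"):
            shift_pmf(prof, zeta_ref=2.5)


class TestUncertainty:
    def test_duplicated_blocks_give_zero_std(self, double_well):
        base = sample_umbrella(double_well, np.linspace(-2.0, 2.6, 24),
                               n_per_window=500, seed=2)
        dup = [UmbrellaWindow(w.center, w.force_constant, np.tile(w.samples, 4))
               for w in base]
        std = pmf_uncertainty(dup, n_parts=4, seed=1, mode="blocks",
                              bin_range=(-2.5, 3.0), tol=1e-8)
        assert np.nanmax(std) == 0.0

    def test_single_part_rejected(self, small_umbrella_windows):
        with pytest.raises(ValueError, match="n_parts"):
            pmf_uncertainty(small_umbrella_windows, n_parts=1, seed=0)

    def test_window_shorter_than_parts_rejected(self):
        w = UmbrellaWindow(center=0.0, force_constant=1000.0,
                           samples=np.array([0.0, 0.1]))
        with pytest.raises(ValueError, match="fewer than n_parts"):
            pmf_uncertainty([w], n_parts=4, seed=0)

    def test_std_shrinks_when_samples_quadruple(self):
        """Monte-Carlo scaling: 4x samples about halves the 4-part std."""
        pot = PotentialSpec("harmonic", {"a": 2.0, "m": 2.0}, domain=(1.0, 3.0))
        centers = np.linspace(1.4, 2.6, 13)
        edges = np.arange(1.0, 3.0001, 0.05)
        mids = 0.5 * (edges[:-1] + edges[1:])
        mask = (mids >= 1.4) & (mids <= 2.6)
        pooled = {}
        for n in (2000, 8000):
            acc = []
            for rep in range(4):
                wins = sample_umbrella(pot, centers, k=500.0, n_per_window=n,
                                       seed=rep)
                std = pmf_uncertainty(wins, n_parts=4, seed=rep + 100,
                                      bin_range=(1.0, 3.0), zeta_ref=2.5)
                acc.append(np.nanmean(std[mask] ** 2))
            pooled[n] = float(np.sqrt(np.mean(acc)))
        ratio = pooled[2000] / pooled[8000]
        assert 1.5 <= ratio <= 3.0


class TestFeatures:
    def _triplet_profile(self):
        z = np.round(np.arange(-2.0, 3.0001, 0.05), 10)
        G = np.zeros_like(z)
        G[np.argmin(np.abs(z - 1.8))] = -1.0
        G[np.argmin(np.abs(z - 0.5))] = 1.0
        G[np.argmin(np.abs(z + 1.5))] = -4.9
        return PMFProfile(bin_centers=z, free_energy=G)

    def test_constructed_triplet(self):
        f = extract_features(self._triplet_profile())
        assert f.barrier_height == pytest.approx(2.0)
        assert f.well_depth == pytest.approx(5.9)
        assert f.insertion_preference == pytest.approx(3.9)
        assert f.zeta_inserted_min == pytest.approx(-1.5)

    def test_symmetric_double_well_has_zero_preference(self):
        z = np.arange(-2.0, 2.0001, 0.05)
        G = ((z - 0.0) ** 2 - 1.44) ** 2  # minima at -1.2 / +1.2, barrier at 0
        f = extract_features(PMFProfile(bin_centers=z, free_energy=G),
                             adsorbed_region=(0.5, 2.0),
                             inserted_region=(-2.0, -0.5))
        assert f.insertion_preference == pytest.approx(0.0, abs=1e-9)

    def test_monotone_profile_flags_no_interior_barrier(self):
        z = np.arange(-2.0, 3.0001, 0.05)
        G = 1.0 * z  # strictly increasing
        f = extract_features(PMFProfile(bin_centers=z, free_energy=G))
        assert not f.interior_barrier

    def test_empty_region_is_error(self):
        z = np.arange(-2.0, 3.0001, 0.05)
        G = np.where(z > 0.5, 0.0, np.nan)
        with pytest.raises(ValueError, match="inserted"):
            extract_features(PMFProfile(bin_centers=z, free_energy=G))

    def test_overlapping_regions_rejected(self):
        prof = self._triplet_profile()
        with pytest.raises(ValueError, match="disjoint"):
            extract_features(prof, adsorbed_region=(0.0, 2.0),
                             inserted_region=(-1.0, 1.0))

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(-8, 8), min_size=40, max_size=40))
    def test_preference_identity_holds_on_any_profile(self, values):
        """insertion_preference == well_depth - barrier_height, always."""
        z = np.linspace(-2.0, 2.9, 40)
        prof = PMFProfile(bin_centers=z, free_energy=np.array(values))
        f = extract_features(prof)
        assert f.insertion_preference == pytest.approx(
            f.well_depth - f.barrier_height, abs=1e-9
        )


class TestZetaSeries:
    def test_prescribed_zetas_recovered(self):
        zetas = (-1.3, 0.0, 2.2)
        frames, top = [], None
        for i, zv in enumerate(zetas):
            top, frame, _ = make_membrane_frame(zeta=zv, seed=200 + i)
            frame.time = float(i)
            frames.append(frame)
        sel = selections(top)
        spec = HairpinSpec("custom", ((1, 5), (7, 11)), 3)
        t, z = zeta_series_from_trajectory(frames, top, spec, sel["lipid"])
        assert np.allclose(z, zetas, atol=1e-9)
        assert np.allclose(t, [0.0, 1.0, 2.0])

    def test_empty_trajectory(self, toy_spec):
        t, z = zeta_series_from_trajectory([], chain_topology(11), toy_spec, {1})
        assert t.size == 0 and z.size == 0

    def test_roundtrip_through_series_writer(self, tmp_path):
        from gdminsert.io import read_xvg_series, write_xvg_series

        t = np.array([0.0, 1.0, 2.0])
        z = np.array([-1.234567, 0.000001, 2.199999])
        path = tmp_path / "zeta.xvg"
        write_xvg_series(path, t, z)
        t2, z2 = read_xvg_series(path)
        assert np.allclose(z2, z, atol=5e-7)
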