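"""dcr unmixing, density rendering, centerline extraction and filament FWHM."""
import math

import numpy as np
import pandas as pd
import pytest

from mtlk.minflux import (
    DensityMap,
    assign_channels,
    extract_centerlines,
    filament_fwhm,
    fit_dcr_mixture,
    localization_precision,
    measure_filaments,
    profile_fwhm,
    render_density,
)
from mtlk.simulate import FilamentSpec, simulate_minflux

GAUSS_FWHM = 2 * math.sqrt(2 * math.log(2))


def _mixture_sample(n=10000, seed=0, mus=(0.30, 0.80), sds=(0.05, 0.05)):
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < 0.5
    return np.where(comp, rng.normal(mus[0], sds[0], n), rng.normal(mus[1], sds[1], n))


class TestDcrMixture:
    def test_recovers_well_separated_means(self):
        fit = fit_dcr_mixture(np.clip(_mixture_sample(), 0, 1))
        assert fit.mu1 == pytest.approx(0.30, abs=0.01)
        assert fit.mu2 == pytest.approx(0.80, abs=0.01)
        assert fit.converged

    def test_components_ordered_by_mean(self):
        rng = np.random.default_rng(5)
        fit = fit_dcr_mixture(rng.uniform(0, 1, 500))
        assert fit.mu1 < fit.mu2
        assert fit.w1 + fit.w2 == pytest.approx(1.0, abs=1e-9)

    def test_loglik_nondecreasing_across_em_iterations(self):
        # run EM at increasing iteration caps: the final log-likelihood of a
        # longer run can never be lower
        x = np.clip(_mixture_sample(2000, seed=1), 0, 1)
        lls = [fit_dcr_mixture(x, max_iter=k, tol=0.0).log_likelihood
               for k in (2, 5, 10, 50)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_matches_sklearn_em_oracle(self):
        from sklearn.mixture import GaussianMixture

        x = np.clip(_mixture_sample(4000, seed=2), 0, 1)
        fit = fit_dcr_mixture(x)
        gm = GaussianMixture(2, covariance_type="full", tol=1e-8,
                             random_state=0, n_init=3).fit(x[:, None])
        mus = np.sort(gm.means_.ravel())
        assert fit.mu1 == pytest.approx(mus[0], abs=0.01)
        assert fit.mu2 == pytest.approx(mus[1], abs=0.01)

    def test_degenerate_and_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_dcr_mixture(np.full(100, 0.5))
        with pytest.raises(ValueError):
            fit_dcr_mixture(np.linspace(0, 1, 10))


class TestChannelAssignment:
    @staticmethod
    def _fit(mu1=0.30, s1=0.05, mu2=0.80, s2=0.05):
        from mtlk.minflux import DcrMixtureFit
        return DcrMixtureFit(mu1, s1, 0.5, mu2, s2, 0.5, 0.0, 1, True)

    def _table(self, dcr):
        return pd.DataFrame({"tid": range(len(dcr)), "t_s": 0.0,
                             "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0, "dcr": dcr})

    def test_worked_examples(self):
        out = assign_channels(self._table([0.20, 0.90, 0.50]), self._fit())
        assert out.channel.tolist() == [1, 2, 0]

    def test_cutoff_boundary_closed_interval(self):
        # µ1 + 0.5σ1 = 0.325 exactly -> channel 1
        out = assign_channels(self._table([0.325]), self._fit())
        assert out.channel.tolist() == [1]

    def test_all_below_first_cutoff_all_channel1(self):
        out = assign_channels(self._table([0.0, 0.1, 0.29]), self._fit())
        assert (out.channel == 1).all()

    def test_partition_is_exclusive_and_exhaustive(self):
        rng = np.random.default_rng(0)
        out = assign_channels(self._table(rng.uniform(0, 1, 500)), self._fit())
        assert out.channel.isin([0, 1, 2]).all()

    def test_overlapping_cutoffs_error(self):
        with pytest.raises(ValueError):
            assign_channels(self._table([0.5]), self._fit(mu1=0.4, s1=0.3,
                                                          mu2=0.5, s2=0.3))


class TestPrecision:
    def test_identical_positions_zero_sd(self):
        df = pd.DataFrame({"tid": [1] * 5, "x_nm": 7.0, "y_nm": 3.0})
        res = localization_precision(df)
        assert res.n_groups == 1
        assert res.sd_x[0] == 0.0 and res.sd_y[0] == 0.0

    def test_groups_of_four_excluded(self):
        df = pd.DataFrame({"tid": [1] * 4 + [2] * 4, "x_nm": 0.0, "y_nm": 0.0})
        res = localization_precision(df)
        assert res.empty

    def test_modal_sd_recovers_simulated_sigma(self):
        spec = FilamentSpec(sigma_xy=3.5, n_localizations=20000,
                            trace_group_size=10.0, rng_seed=8)
        res = localization_precision(simulate_minflux(spec))
        assert res.modal_x == pytest.approx(3.5, abs=0.5)
        assert res.modal_y == pytest.approx(3.5, abs=0.5)


class TestDensityMap:
    def _table(self, coords):
        arr = np.atleast_2d(coords)
        return pd.DataFrame({"tid": range(len(arr)), "t_s": 0.0,
                             "x_nm": arr[:, 0], "y_nm": arr[:, 1],
                             "z_nm": 0.0, "dcr": 0.5})

    def test_floor_indexing_convention(self):
        dmap = render_density(self._table([(10.4, 20.7)]), voxel_size=1.0,
                              origin=(0.0, 0.0), pad=0)
        ix, iy = dmap.index_of(10.4, 20.7)
        assert (ix, iy) == (10, 20)
        assert dmap.counts[20, 10] == 1.0

    def test_total_counts_conserved(self):
        rng = np.random.default_rng(1)
        tab = self._table(rng.uniform(0, 100, size=(357, 2)))
        assert render_density(tab, voxel_size=2.0).total == 357

    def test_two_localizations_one_voxel(self):
        dmap = render_density(self._table([(5.2, 5.3), (5.8, 5.9)]),
                              voxel_size=1.0, origin=(0.0, 0.0), pad=0)
        assert dmap.counts.max() == 2.0

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            render_density(self._table([(0, 0)]).iloc[:0])


class TestFwhm:
    def test_exact_gaussian_profile_closed_form(self):
        x = np.arange(-30.0, 30.5, 1.0)
        y = np.exp(-0.5 * (x / 3.0) ** 2)
        w, peak = profile_fwhm(x, y)
        assert w == pytest.approx(GAUSS_FWHM * 3.0, abs=0.5)
        assert peak == pytest.approx(0.0, abs=0.5)

    def test_no_crossing_flagged_undefined(self):
        x = np.arange(10.0)
        y = np.full(10, 5.0)
        w, _ = profile_fwhm(x, y)
        assert math.isnan(w)

    def test_straight_filament_single_centerline_near_truth(self):
        spec = FilamentSpec(sigma_xy=3.5, n_localizations=3000, rng_seed=9)
        dmap = render_density(simulate_minflux(spec), voxel_size=1.0)
        lines = extract_centerlines(dmap)
        assert len(lines) == 1
        # true axis is y = 0
        assert np.max(np.abs(lines[0][:, 1])) <= 2.0

    def test_two_parallel_filaments_resolved(self):
        a = simulate_minflux(FilamentSpec(
            polyline=np.array([[0.0, 0.0], [1000.0, 0.0]]),
            n_localizations=2500, rng_seed=10))
        b = simulate_minflux(FilamentSpec(
            polyline=np.array([[0.0, 200.0], [1000.0, 200.0]]),
            n_localizations=2500, rng_seed=11))
        b["tid"] += 10000
        dmap = render_density(pd.concat([a, b], ignore_index=True), voxel_size=1.0)
        lines = extract_centerlines(dmap)
        assert len(lines) == 2
        mean_y = sorted(float(np.mean(l[:, 1])) for l in lines)
        assert mean_y[0] == pytest.approx(0.0, abs=3.0)
        assert mean_y[1] == pytest.approx(200.0, abs=3.0)

    def test_empty_map_no_centerlines(self):
        dmap = DensityMap(counts=np.zeros((50, 50), np.float32),
                          origin=np.zeros(2), voxel_size=1.0)
        assert extract_centerlines(dmap) == []

    def test_axial_filament_fwhm_matches_localization_sigma(self):
        fwhms = []
        for seed in range(5):
            spec = FilamentSpec(sigma_xy=3.5, n_localizations=2000, rng_seed=seed)
            fwhms += [p.fwhm for p in measure_filaments(simulate_minflux(spec),
                                                        voxel_size=1.0)]
        assert np.nanmean(fwhms) == pytest.approx(GAUSS_FWHM * 3.5, rel=0.05)

    def test_fwhm_rotation_and_translation_invariant(self):
        spec = FilamentSpec(sigma_xy=3.5, n_localizations=2500, rng_seed=12)
        df = simulate_minflux(spec)
        base = measure_filaments(df, voxel_size=1.0)[0].fwhm
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        xy = df[["x_nm", "y_nm"]].to_numpy() @ rot.T + [250.0, -120.0]
        df2 = df.assign(x_nm=xy[:, 0], y_nm=xy[:, 1])
        rotated = measure_filaments(df2, voxel_size=1.0)[0].fwhm
        assert rotated == pytest.approx(base, abs=1.0)

    def test_fwhm_monotone_in_localization_sigma(self):
        means = []
        for sigma in (2.0, 3.5, 5.0):
            vals = [p.fwhm for seed in range(3) for p in measure_filaments(
                simulate_minflux(FilamentSpec(sigma_xy=sigma,
                                              n_localizations=2000,
                                              rng_seed=100 + seed)),
                voxel_size=1.0)]
            means.append(np.nanmean(vals))
        assert means[0] < means[1] < means[2]
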