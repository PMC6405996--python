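"""Calibration, ratio imaging, edge abundance and sector-profile checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chemoscope as cs
from chemoscope.phratio import CalibrationCurve, CalibrationPoint


def line_points(slope=0.3, intercept=-1.3, phs=(6.0, 7.0, 8.0)):
    return [CalibrationPoint(p, slope * p + intercept) for p in phs]


class TestCalibration:
    def test_exact_line(self):
        curve = cs.fit_calibration(line_points())
        assert curve.slope == pytest.approx(0.3)
        assert curve.intercept == pytest.approx(-1.3)
        assert curve.r_squared == pytest.approx(1.0)

    def test_out_of_range_points_excluded(self):
        """A pH 5 point outside the linear range leaves the fit unchanged."""
        pts = line_points() + [CalibrationPoint(5.0, 99.0)]
        curve = cs.fit_calibration(pts)
        assert curve.slope == pytest.approx(0.3)
        assert curve.intercept == pytest.approx(-1.3)

    def test_noisy_slope_within_sampling_error(self):
        """OLS slope over 100 noisy replicates stays within 3 SEs of truth."""
        rng = np.random.default_rng(0)
        slopes = []
        for _ in range(100):
            pts = [
                CalibrationPoint(p, 0.3 * p - 1.3 + rng.normal(0, 0.01))
                for p in (6.0, 6.5, 7.0, 7.5, 8.0)
            ]
            slopes.append(cs.fit_calibration(pts).slope)
        x = np.array([6.0, 6.5, 7.0, 7.5, 8.0])
        se = 0.01 / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(np.mean(slopes) - 0.3) < 3 * se / np.sqrt(100)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cs.fit_calibration(line_points(phs=(6.0, 7.0)))

    def test_negative_slope_rejected(self):
        pts = [CalibrationPoint(p, -0.3 * p + 3.0) for p in (6.0, 7.0, 8.0)]
        with pytest.raises(ValueError, match="slope"):
            cs.fit_calibration(pts)

    def test_roundtrip_identity(self, calibration_line):
        """pH -> ratio -> pH is the identity to 1e-9 across the valid range."""
        for pH in np.linspace(6.0, 8.0, 41):
            ratio = calibration_line.ratio_at(pH)
            back, flagged = cs.ratio_to_pH(float(ratio), calibration_line)
            assert back == pytest.approx(pH, abs=1e-9)
            assert not flagged

    def test_inversion_examples(self, calibration_line):
        pH, flagged = cs.ratio_to_pH(1.1, calibration_line)
        assert pH == pytest.approx(8.0) and not flagged
        pH, flagged = cs.ratio_to_pH(1.4, calibration_line)
        assert pH == pytest.approx(9.0) and flagged

    def test_nonfinite_ratio_errors(self, calibration_line):
        with pytest.raises(ValueError):
            cs.ratio_to_pH(np.inf, calibration_line)


class TestRatioImage:
    def test_constant_ratio(self):
        img470 = np.full((10, 10), 50.0)
        out = cs.compute_ratio_image(2.0 * img470, img470, min_denominator=5.0)
        assert not out.mask.any()
        assert np.allclose(out.filled(), 2.0)

    def test_low_denominator_masked(self):
        img470 = np.array([[10.0, 0.0]])
        out = cs.compute_ratio_image(np.ones((1, 2)), img470, min_denominator=5.0)
        assert not out.mask[0, 0] and out.mask[0, 1]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cs.compute_ratio_image(np.zeros((2, 2)), np.zeros((3, 3)), 1.0)

    def test_noiseless_scene_per_cell_ratio_exact(self, calibration_line):
        """Planted per-cell ratios are recovered exactly with zero noise."""
        spec = cs.RatioSceneSpec(
            image_shape=(300, 420),
            source_center=(150.0, 80.0),
            source_radius=50.0,
            channel_noise_sd=0.0,
            calibration=calibration_line,
            seed=4,
        )
        scene = cs.gen_ratio_scene(spec)
        ratio = cs.compute_ratio_image(scene.img386, scene.img470, 10.0)
        for row in scene.truth.itertuples():
            sel = scene.labels == row.cell_id
            assert np.allclose(ratio.data[sel], row.true_ratio, atol=1e-9)


class TestEdgeAbundance:
    def test_constant_image_zero(self):
        assert np.all(cs.edge_abundance(np.full((20, 20), 3.0)) == 0)

    def test_step_edge_response(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 10.0
        e = cs.edge_abundance(img)
        assert e[10, 10] > 0 and e[10, 0] == 0 and e[10, 19] == 0
        col_sum = e.sum(axis=0)
        assert col_sum.argmax() in (9, 10)

    def test_signal_scales_with_cell_density(self, calibration_line):
        """Doubling planted density about doubles the summed edge signal.

        Averaged over seeds so Poisson fluctuations in the cell count do not
        dominate; the ratio sits slightly below 2 because overlap rejection
        removes proportionally more cells at the higher density.
        """
        ratios = []
        for seed in range(5):
            sums = []
            for dens in (0.025, 0.05):
                spec = cs.RatioSceneSpec(
                    image_shape=(800, 1200),
                    source_center=(400.0, 150.0),
                    source_radius=70.0,
                    cell_density_profile=cs.uniform_density(dens),
                    channel_noise_sd=0.0,
                    calibration=calibration_line,
                    seed=30 + seed,
                )
                scene = cs.gen_ratio_scene(spec)
                sums.append(cs.edge_abundance(scene.img470).sum())
            ratios.append(sums[1] / sums[0])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.10)


class TestSectorProfile:
    def make_source(self, shape=(200, 300), center=(100, 60), radius=30):
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        return np.hypot(rr - center[0], cc - center[1]) <= radius

    def test_uniform_field_flat_profile(self):
        mask = self.make_source()
        prof = cs.sector_profile(np.full((200, 300), 4.2), mask, 10, 2, 8)
        filled = prof[~prof["empty"]]
        assert np.allclose(filled["mean"], 4.2)

    def test_linear_field_matches_analytic_zone_value(self):
        """Zone means of a linear-in-distance field sit at the zone-mean distance."""
        mask = self.make_source(shape=(400, 400), center=(200, 200), radius=40)
        d = cs.signed_distance_map(mask)
        value = 2.0 + 0.05 * d
        prof = cs.sector_profile(value, mask, 10, 2, 10)
        for row in prof[~prof["empty"]].itertuples():
            sel = (
                (d >= (row.zone - 1) * 10) & (d < row.zone * 10)
                if row.zone > 0
                else (d > row.zone * 10) & (d <= (row.zone + 1) * 10)
            )
            analytic = 2.0 + 0.05 * d[sel].mean()
            assert row.mean == pytest.approx(analytic, abs=0.05 / 2)  # half increment

    def test_zone_partition_complete(self):
        """Every pixel within range belongs to exactly one zone."""
        mask = self.make_source()
        d = cs.signed_distance_map(mask)
        w, n_in, n_out = 10, 2, 8
        counts = np.zeros(d.shape, dtype=int)
        for zone in list(range(-n_in, 0)) + list(range(1, n_out + 1)):
            if zone < 0:
                counts += ((d > zone * w) & (d <= (zone + 1) * w)).astype(int)
            else:
                counts += ((d >= (zone - 1) * w) & (d < zone * w)).astype(int)
        in_range = (d > -n_in * w) & (d < n_out * w) & (d != 0)
        assert np.all(counts[in_range] == 1)
        prof = cs.sector_profile(np.ones(d.shape), mask, w, n_in, n_out)
        assert prof["n_pixels"].sum() == in_range.sum() + (d == 0).sum()

    def test_outermost_zone_center_geometry(self):
        prof_zone = 57
        center = (prof_zone - 0.5) * 25
        assert center == 1412.5

    def test_empty_or_full_mask_errors(self):
        with pytest.raises(ValueError):
            cs.sector_profile(np.ones((10, 10)), np.zeros((10, 10), bool), 5, 1, 2)
        with pytest.raises(ValueError):
            cs.sector_profile(np.ones((10, 10)), np.ones((10, 10), bool), 5, 1, 2)


class TestAggregation:
    def zone_table(self, means):
        return pd.DataFrame(
            {
                "zone": np.arange(1, len(means) + 1),
                "distance_px": (np.arange(1, len(means) + 1) - 0.5) * 25,
                "mean": means,
                "n_pixels": 100,
                "empty": False,
            }
        )

    def test_identical_replicates_zero_ci(self):
        tables = [self.zone_table([1.0, 2.0, 3.0])] * 4
        agg = cs.aggregate_replicates(tables)
        assert np.allclose(agg["ci95"], 0.0)
        assert np.allclose(agg["mean"], [1.0, 2.0, 3.0])

    def test_single_replicate_errors(self):
        with pytest.raises(ValueError):
            cs.aggregate_replicates([self.zone_table([1.0])])

    def test_geometry_mismatch_errors(self):
        a = self.zone_table([1.0, 2.0])
        b = self.zone_table([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            cs.aggregate_replicates([a, b])

    def test_t_interval_coverage(self):
        """95% band covers the true mean for ~95% of simulated zones."""
        rng = np.random.default_rng(77)
        mu, sigma, n_rep, n_zones = 5.0, 1.3, 4, 1000
        covered = 0
        vals = rng.normal(mu, sigma, (n_zones, n_rep))
        tcrit = stats.t.ppf(0.975, n_rep - 1)
        for z in range(n_zones):
            tables = [self.zone_table([vals[z, r]]) for r in range(n_rep)]
            agg = cs.aggregate_replicates(tables)
            m, ci = agg.loc[0, "mean"], agg.loc[0, "ci95"]
            covered += abs(m - mu) <= ci
        assert 0.93 <= covered / n_zones <= 0.97


class TestAccumulation:
    def zone_table(self, means, width_px=25):
        n = len(means)
        return pd.DataFrame(
            {
                "zone": np.arange(1, n + 1),
                "distance_px": (np.arange(1, n + 1) - 0.5) * width_px,
                "mean": means,
            }
        )

    def test_uniform_abundance(self):
        """15 two-micrometre zones cover the 30-um window: total = 15a."""
        table = self.zone_table([3.0] * 20)
        got = cs.accumulation_summary(table, pixel_size_um=0.08, window_um=30.0)
        assert got == pytest.approx(15 * 3.0)

    def test_zero_map(self):
        table = self.zone_table([0.0] * 20)
        assert cs.accumulation_summary(table, 0.08) == 0.0

    def test_insufficient_coverage_errors(self):
        with pytest.raises(ValueError):
            cs.accumulation_summary(self.zone_table([1.0] * 5), 0.08)

    def test_peaked_scene_accumulates_more(self, calibration_line):
        """Source-peaked density yields higher 30-um accumulation than flat."""
        wins = 0
        for seed in range(10):
            accs = []
            for profile in (
                cs.uniform_density(0.008),
                cs.peaked_density(0.008, 0.06, 20.0),
            ):
                spec = cs.RatioSceneSpec(
                    image_shape=(420, 760),
                    source_center=(210.0, 100.0),
                    source_radius=60.0,
                    cell_density_profile=profile,
                    calibration=calibration_line,
                    seed=600 + seed,
                )
                scene = cs.gen_ratio_scene(spec)
                abund = cs.sector_profile(
                    cs.edge_abundance(scene.img470), scene.source_mask, 25, 3, 20
                )
                accs.append(
                    cs.accumulation_summary(
                        abund.rename(columns={}), pixel_size_um=0.08
                    )
                )
            wins += accs[1] > accs[0]
        assert wins == 10


class TestGradientRecovery:
    @pytest.mark.parametrize("direction", ["cyto", "peri"])
    def test_near_source_pH_shift_recovered(self, direction):
        """Planted +-0.3-unit near-source pH shift recovered within 0.05.

        The cytoplasmic-like scene raises pH near the source (7.8 -> 8.1) and
        the periplasmic-like scene lowers it (7.2 -> 6.9); the aggregated
        sector profiles must recover the magnitude and opposite signs.
        """
        cal = CalibrationCurve(0.3, -1.3, valid_range=(6.0, 8.5))
        far, near = (7.8, 8.1) if direction == "cyto" else (7.2, 6.9)
        tables = []
        for rep in range(4):
            spec = cs.RatioSceneSpec(
                image_shape=(620, 1300),
                source_center=(310.0, 140.0),
                source_radius=90.0,
                pH_far=far,
                pH_near=near,
                pH_decay_length_um=20.0,
                calibration=cal,
                channel_noise_sd=2.0,
                cell_density_profile=cs.peaked_density(0.008, 0.06, 20.0),
                seed=300 + rep,
            )
            scene = cs.gen_ratio_scene(spec)
            rmap = cs.compute_ratio_image(scene.img386, scene.img470, 10.0)
            tables.append(cs.sector_profile(rmap, scene.source_mask, 25, 3, 40))
        prof = cs.aggregate_replicates(tables)
        out = prof[prof["zone"] > 0].reset_index(drop=True)
        pH = np.full(len(out), np.nan)
        ok = np.isfinite(out["mean"].values)
        pH[ok], _ = cs.ratio_to_pH(out["mean"].values[ok], cal)
        deviation = pH[0] - np.nanmean(pH[-10:])
        planted = near - far
        assert deviation == pytest.approx(planted, abs=0.05)
        assert np.sign(deviation) == np.sign(planted)
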