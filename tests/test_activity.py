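"""Circular activity densities, overlap, peaks, elevation zones, migration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from camtrap_rem.activity import (
    ActivityDensity,
    classify_zone,
    find_peaks,
    fit_circular_kde,
    hours_to_radians,
    migration_profile,
    overlap_coefficient,
    radians_to_hours,
)

TWO_PI = 2 * np.pi


def bimodal_sample(rng, n, means_h=(8.0, 18.0), kappa=6.0):
    comp = rng.integers(0, 2, size=n)
    mu = hours_to_radians(np.asarray(means_h))[comp]
    return (rng.vonmises(mu - np.pi, kappa) + np.pi) % TWO_PI


class TestCircularKDE:
    def test_single_sample_peaks_at_the_sample(self):
        d = fit_circular_kde([np.pi], bandwidth=50.0)
        assert d.grid[np.argmax(d.density)] == pytest.approx(np.pi, abs=0.01)

    def test_uniform_samples_give_flat_density(self):
        rng = np.random.default_rng(0)
        d = fit_circular_kde(rng.uniform(0, TWO_PI, 10_000))
        assert d.density.max() / d.density.min() == pytest.approx(1.0, abs=0.1)

    def test_matches_direct_kernel_summation(self):
        rng = np.random.default_rng(1)
        x = rng.vonmises(0.5, 2.0, size=40) % TWO_PI
        kappa = 5.0
        d = fit_circular_kde(x, bandwidth=kappa)
        pts = d.grid[:: len(d.grid) // 16][:16]
        direct = np.array(
            [np.mean(stats.vonmises.pdf(p, kappa, loc=x)) for p in pts]
        )
        assert d.at(pts) == pytest.approx(direct, rel=1e-6)

    def test_density_is_normalized_periodic_nonnegative(self):
        d = fit_circular_kde(bimodal_sample(np.random.default_rng(2), 500))
        assert d.integral() == pytest.approx(1.0, abs=1e-6)
        assert d.density[0] == d.density[-1]
        assert (d.density >= 0).all()

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_circular_kde([])
        with pytest.raises(ValueError):
            fit_circular_kde([1.0], bandwidth=-1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(delta=st.floats(0.0, TWO_PI, allow_nan=False))
    def test_rotation_equivariance(self, delta):
        rng = np.random.default_rng(9)
        x = rng.vonmises(1.0, 4.0, size=300) % TWO_PI
        d0 = fit_circular_kde(x, bandwidth=8.0)
        d1 = fit_circular_kde((x + delta) % TWO_PI, bandwidth=8.0)
        m0 = d0.grid[np.argmax(d0.density[:-1])]
        m1 = d1.grid[np.argmax(d1.density[:-1])]
        diff = (m1 - m0 - delta + np.pi) % TWO_PI - np.pi
        assert abs(diff) < 0.05  # one-ish grid cells


class TestOverlap:
    def test_identical_samples_overlap_completely(self):
        x = bimodal_sample(np.random.default_rng(3), 400)
        da, db = fit_circular_kde(x), fit_circular_kde(x)
        assert overlap_coefficient(da, db) >= 0.99

    def test_antipodal_tight_schedules_barely_overlap(self):
        rng = np.random.default_rng(4)
        da = fit_circular_kde(rng.vonmises(0.0, 50.0, 500) % TWO_PI)
        db = fit_circular_kde((rng.vonmises(np.pi, 50.0, 500)) % TWO_PI)
        assert overlap_coefficient(da, db) <= 0.05

    def test_symmetry_and_self_overlap(self):
        rng = np.random.default_rng(5)
        da = fit_circular_kde(rng.vonmises(1.0, 3.0, 300) % TWO_PI)
        db = fit_circular_kde(rng.vonmises(2.5, 5.0, 300) % TWO_PI)
        assert overlap_coefficient(da, db) == pytest.approx(
            overlap_coefficient(db, da)
        )
        assert overlap_coefficient(da, da) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quadrature_truth_for_known_von_mises(self):
        # large samples from two known von Mises laws: the KDE overlap must sit
        # close to the exact integral of min(f, g)
        mu1, k1, mu2, k2 = 0.0, 4.0, 1.2, 3.0
        rng = np.random.default_rng(6)
        da = fit_circular_kde(rng.vonmises(mu1, k1, 8000) % TWO_PI)
        db = fit_circular_kde(rng.vonmises(mu2, k2, 8000) % TWO_PI)
        grid = np.linspace(0, TWO_PI, 20_001)
        truth = np.trapezoid(
            np.minimum(
                stats.vonmises.pdf(grid, k1, loc=mu1),
                stats.vonmises.pdf(grid, k2, loc=mu2),
            ),
            grid,
        )
        assert overlap_coefficient(da, db) == pytest.approx(truth, abs=0.02)

    def test_mismatched_grids_rejected(self):
        da = fit_circular_kde([1.0], bandwidth=2.0, n_grid=512)
        db = fit_circular_kde([1.0], bandwidth=2.0, n_grid=256)
        with pytest.raises(ValueError):
            overlap_coefficient(da, db)


class TestFindPeaks:
    def test_unimodal_density_has_one_peak(self):
        rng = np.random.default_rng(7)
        d = fit_circular_kde(rng.vonmises(2.0, 5.0, 2000) % TWO_PI)
        assert len(find_peaks(d)) == 1

    def test_bimodal_generator_truth_recovered(self):
        rng = np.random.default_rng(8)
        d = fit_circular_kde(bimodal_sample(rng, 2000))
        peaks = find_peaks(d)
        assert len(peaks) == 2
        hours = sorted(p.peak_hour for p in peaks)
        assert hours[0] == pytest.approx(8.0, abs=1.0)
        assert hours[1] == pytest.approx(18.0, abs=1.0)

    def test_flat_density_has_no_peaks(self):
        grid = np.linspace(0, TWO_PI, 513)
        flat = ActivityDensity(grid, np.full(513, 1 / TWO_PI), 1.0, 0)
        assert find_peaks(flat) == []

    def test_midnight_peak_not_split_by_wraparound(self):
        rng = np.random.default_rng(9)
        d = fit_circular_kde(rng.vonmises(0.0, 6.0, 2000) % TWO_PI)
        peaks = find_peaks(d)
        assert len(peaks) == 1
        assert min(peaks[0].peak_hour, 24 - peaks[0].peak_hour) < 1.0


@pytest.mark.parametrize(
    "elev,zone",
    [
        (582, "tropical rainforest"),
        (1100, "subtropical broad-leaved"),
        (2300, "warm-temperate mixed"),
        (3500, "cold-temperate conifer"),
        (4000, "alpine shrub meadow"),
        (4200, "alpine frost"),
        (4800, "ice/snow"),
    ],
)
def test_elevation_zones_half_open(elev, zone):
    assert classify_zone(elev) == zone


def test_hours_radians_round_trip():
    h = np.array([0.0, 6.0, 12.0, 23.99])
    assert radians_to_hours(hours_to_radians(h)) == pytest.approx(h)


class TestMigrationProfile:
    def test_all_high_july_events_give_rainy_fraction_one(self):
        ev = pd.DataFrame({"date": ["2021-07-10"] * 5, "elevation": [4000.0] * 5})
        prof = migration_profile(ev)
        assert prof.rainy_fraction_above == 1.0
        assert np.isnan(prof.dry_fraction_above)
        assert prof.counts.loc[7, "alpine shrub meadow"] == 5

    def test_counts_conserve_events_and_empty_months_are_zero(self):
        rng = np.random.default_rng(10)
        n = 200
        dates = pd.to_datetime("2021-06-01") + pd.to_timedelta(
            rng.integers(0, 60, n), unit="D"
        )
        ev = pd.DataFrame({"date": dates, "elevation": rng.uniform(1000, 4500, n)})
        prof = migration_profile(ev)
        assert prof.counts.to_numpy().sum() == n == prof.n_events
        assert (prof.counts.loc[1] == 0).all()  # no January events

    def test_seasonal_generator_truth_orders_the_fractions(self):
        rng = np.random.default_rng(11)
        n = 500
        rainy = rng.random(n) < 0.5
        dates = np.where(rainy, "2021-07-15", "2021-01-15")
        elev = np.where(
            rainy, rng.normal(4000, 200, n), rng.normal(2000, 300, n)
        ).clip(0)
        prof = migration_profile(pd.DataFrame({"date": dates, "elevation": elev}))
        assert prof.rainy_fraction_above > 0.9
        assert prof.dry_fraction_above < 0.1

    def test_empty_input(self):
        prof = migration_profile(pd.DataFrame({"date": [], "elevation": []}))
        assert prof.n_events == 0 and np.isnan(prof.rainy_fraction_above)
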