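"""Generator properties: determinism, schedules, and known selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soarsel.grids import Raster
from soarsel.synthetic import (
    MetParam,
    SyntheticScenario,
    expected_lnrf_from_landscape,
    generate_landscape,
    generate_met_grid,
    simulate_ar1_panels,
    simulate_tracks,
    _sample_point_process,
)

EXTENT = (0.0, 0.0, 20000.0, 20000.0)


def small_scenario(**kw):
    defaults = dict(
        seed=3, extent=EXTENT, habitat_weights={1: 1.0, 2: 1.0},
        n_birds=2, months=[(2008, 2)], fixes_per_day=4, hr_sigma=2000.0,
    )
    defaults.update(kw)
    return SyntheticScenario(**defaults)


class TestLandscape:
    def test_all_classes_present_and_partitioned(self):
        habitat, ecoregions = generate_landscape(1, EXTENT, n_classes=12,
                                                 patch_scale=1500.0)
        classes, counts = np.unique(habitat.values, return_counts=True)
        assert set(classes) == set(range(1, 13))
        assert counts.sum() == habitat.values.size  # proportions sum to 1
        assert len(ecoregions.geometries) >= 2
        total = sum(g.area for g in ecoregions.geometries.values())
        assert total == pytest.approx(20000.0**2)

    def test_seed_determinism(self):
        a, _ = generate_landscape(7, EXTENT, n_classes=4, patch_scale=2000.0)
        b, _ = generate_landscape(7, EXTENT, n_classes=4, patch_scale=2000.0)
        assert np.array_equal(a.values, b.values)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="extent"):
            generate_landscape(1, (0, 0, 50, 50), n_classes=2, patch_scale=500.0)
        with pytest.raises(ValueError, match="patch_scale"):
            generate_landscape(1, EXTENT, n_classes=2, patch_scale=50.0)
        with pytest.raises(ValueError, match="n_classes"):
            generate_landscape(1, EXTENT, n_classes=1, patch_scale=500.0)


class TestMetGrid:
    def test_degenerate_sinusoid_is_constant(self):
        table, _ = generate_met_grid(
            1, EXTENT, [(2008, m) for m in range(1, 13)],
            {"thermal_height": MetParam(mean=1.0, amplitude=0.0)},
        )
        assert np.allclose(table["value"], 1.0)

    def test_sinusoid_peak_and_range(self):
        table, _ = generate_met_grid(
            1, EXTENT, [(2008, m) for m in range(1, 13)],
            {"thermal_height": MetParam(mean=1.0, amplitude=0.5, phase_month=6)},
        )
        one_cell = table[table["cell_id"] == 1]
        june = one_cell.loc[one_cell["month"] == 6, "value"].iloc[0]
        assert june == pytest.approx(1.5)
        # annual spread reproduces twice the amplitude
        assert one_cell["value"].max() - one_cell["value"].min() == pytest.approx(
            1.0, abs=0.05
        )

    def test_invalid_mean_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            MetParam(mean=0.0)
        with pytest.raises(ValueError, match="non-empty"):
            generate_met_grid(1, EXTENT, [])


class TestTracks:
    def test_timestamps_hourly_within_window(self):
        habitat, _ = generate_landscape(3, EXTENT, n_classes=2, patch_scale=2000.0)
        fixes, _, _ = simulate_tracks(small_scenario(), habitat)
        ts = pd.to_datetime(fixes["timestamp"])
        assert (ts.dt.minute == 0).all() and (ts.dt.second == 0).all()
        assert ts.dt.hour.between(5, 20).all()

    def test_determinism(self):
        habitat, _ = generate_landscape(3, EXTENT, n_classes=2, patch_scale=2000.0)
        a, attrs_a, _ = simulate_tracks(small_scenario(), habitat)
        b, attrs_b, _ = simulate_tracks(small_scenario(), habitat)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(attrs_a, attrs_b)

    def test_uniform_weights_ground_truth_zero(self):
        habitat, _ = generate_landscape(3, EXTENT, n_classes=3, patch_scale=2000.0)
        _, _, truth = simulate_tracks(
            small_scenario(habitat_weights={1: 1.0, 2: 1.0, 3: 1.0}), habitat
        )
        assert all(abs(v) < 1e-12 for v in truth.expected_lnrf.values())

    def test_closed_form_lnrf_for_equal_halves(self):
        values = np.ones((10, 10), dtype=int)
        values[:, 5:] = 2
        habitat = Raster(values, (0, 0), 100.0)
        lnrf, avail = expected_lnrf_from_landscape(habitat, {1: 1.0, 2: 2.0})
        assert avail == {1: 0.5, 2: 0.5}
        assert lnrf[1] == pytest.approx(-np.log(1.5))
        assert lnrf[2] == pytest.approx(np.log(2) - np.log(1.5))

    def test_point_process_matches_multinomial_oracle(self, rng):
        """Class frequencies of 10,000 draws match the kernel-weighted
        multinomial law (chi-square GOF not rejected at alpha=0.01)."""
        habitat, _ = generate_landscape(5, EXTENT, n_classes=3, patch_scale=2500.0)
        weights = {1: 1.0, 2: 2.0, 3: 4.0}
        center, sigma, n = (10000.0, 10000.0), 4000.0, 10000
        pts = _sample_point_process(
            np.random.default_rng(42), center, habitat, weights, sigma, n, EXTENT
        )
        # oracle: expected class mass from direct per-cell kernel summation
        xs, ys = habitat.cell_centers()
        xx, yy = np.meshgrid(xs, ys)
        kern = np.exp(
            -((xx - center[0]) ** 2 + (yy - center[1]) ** 2) / (2 * sigma**2)
        )
        w_grid = np.vectorize(weights.get)(habitat.values)
        probs = np.array(
            [(kern * w_grid * (habitat.values == c)).sum() for c in (1, 2, 3)]
        )
        probs /= probs.sum()
        counts = np.array(
            [(habitat.sample(pts[:, 0], pts[:, 1]) == c).sum() for c in (1, 2, 3)]
        )
        chi2 = ((counts - n * probs) ** 2 / (n * probs)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=2)

    def test_attributes_have_expected_structure(self):
        habitat, _ = generate_landscape(3, EXTENT, n_classes=2, patch_scale=2000.0)
        _, attrs, _ = simulate_tracks(small_scenario(n_birds=50), habitat)
        assert set(attrs["sex"]) <= {"M", "F"}
        immature = attrs[attrs["age_class"] == "immature"]
        assert (immature["breeder"] == "no").all()

    def test_dropout_reduces_fixes(self):
        habitat, _ = generate_landscape(3, EXTENT, n_classes=2, patch_scale=2000.0)
        full, _, _ = simulate_tracks(small_scenario(), habitat)
        dropped, _, _ = simulate_tracks(small_scenario(dropout_rate=0.3), habitat)
        assert len(dropped) < len(full)

    def test_missing_weight_raises(self):
        habitat, _ = generate_landscape(3, EXTENT, n_classes=3, patch_scale=2000.0)
        with pytest.raises(ValueError, match="without weights"):
            simulate_tracks(small_scenario(habitat_weights={1: 1.0, 2: 1.0}), habitat)


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kw, msg",
        [
            (dict(habitat_weights={1: 0.0, 2: 1.0}), "positive"),
            (dict(extent=(0, 0, -10, 10)), "area"),
            (dict(fixes_per_day=17), "fixes_per_day"),
            (dict(months=[]), "months"),
            (dict(movement_mode="teleport"), "movement_mode"),
        ],
    )
    def test_invariants(self, kw, msg):
        with pytest.raises(ValueError, match=msg):
            small_scenario(**kw)


def test_ar1_panel_generator_autocorrelation():
    """Generated residual series reproduce the requested lag-1 correlation."""
    data = simulate_ar1_panels(seed=9, n_birds=200, n_months=24,
                               sigma_u=0.0, sigma_e=1.0, rho=0.55)
    # pooled moment estimate (true mean 0) avoids the short-series bias of
    # per-bird sample autocorrelations
    num = den = 0.0
    for _, grp in data.groupby("bird_id"):
        y = grp.sort_values("month")["ln_rf"].to_numpy()
        num += (y[:-1] * y[1:]).sum()
        den += (y**2).sum()
    assert num / den == pytest.approx(0.55, abs=0.03)


def test_biased_walk_mode_runs_and_prefers_weighted_habitat():
    habitat, _ = generate_landscape(3, EXTENT, n_classes=2, patch_scale=3000.0)
    sc = small_scenario(movement_mode="biased_walk",
                        habitat_weights={1: 1.0, 2: 6.0}, n_birds=1)
    fixes, _, _ = simulate_tracks(sc, habitat)
    classes = habitat.sample(fixes["x_m"].to_numpy(), fixes["y_m"].to_numpy())
    assert (classes == 2).mean() > 0.5
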