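"""Canned validation studies with known ground truth.

Each function generates a synthetic study, runs the relevant pipeline
stages, and returns the measured quantities next to their closed-form
targets.  These are the package's calibration experiments: selection-
ratio recovery under known preference weights, null calibration under
uniform preference, confidence-interval coverage and covariance-structure
selection for the mixed models, and Type I error of the significance
screen.

Study sizes are chosen so each run finishes in tens of seconds on one
core while leaving the Monte Carlo error well inside the documented
tolerances; see the methods note for the sizing rationale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ingest, kernel, models, selection, synthetic

RECOVERY_WEIGHTS = {1: 1.0, 2: 2.0, 3: 4.0}


def _panel_lnrf(panels, habitat, use_estimator="counts", level=0.99, cell=100.0):
    """Per-panel habitat ln(rf) via the full UD / home-range machinery."""
    rows = []
    for p in panels:
        m, ud, hr = kernel.select_adhoc_bandwidth(p.points, level=level, cell=cell)
        recs = selection.habitat_panel(
            ud, hr, habitat, p.bird_id, p.year, p.month,
            points=p.points, use_estimator=use_estimator,
        )
        rows.extend(recs)
    return selection.records_to_frame(rows)


def _tracks_to_panels(scenario, habitat, min_fixes=100):
    fixes, attrs, truth = synthetic.simulate_tracks(scenario, habitat)
    fixes = ingest.window_filter(fixes)
    return ingest.build_panels(fixes, min_fixes=min_fixes), attrs, truth


def lnrf_recovery_study(
    seed: int,
    n_birds: int = 20,
    weights: dict[int, float] | None = None,
    extent_km: float = 60.0,
    patch_scale: float = 1000.0,
    hr_sigma: float = 5000.0,
    use_estimator: str = "counts",
) -> dict:
    """Recover known selection from a point-process scenario.

    Three near-equal-area habitat classes with preference weights
    (1, 2, 4); each bird contributes one month of the full hourly
    schedule (~500 fixes).  Returns per-class mean estimated ln(rf), the
    closed-form expectations, and the pairwise contrasts against ln 2 and
    ln 4 (which are free of the availability normalizer).
    """
    weights = dict(RECOVERY_WEIGHTS) if weights is None else weights
    ext = extent_km * 1000.0
    scenario = synthetic.SyntheticScenario(
        seed=seed, extent=(0.0, 0.0, ext, ext), habitat_weights=weights,
        n_birds=n_birds, months=[(2008, 7)], fixes_per_day=16, hr_sigma=hr_sigma,
    )
    habitat, _ = synthetic.generate_landscape(
        seed, scenario.extent, n_classes=len(weights), patch_scale=patch_scale
    )
    panels, _, truth = _tracks_to_panels(scenario, habitat)
    table = _panel_lnrf(panels, habitat, use_estimator=use_estimator)
    mean_lnrf = table.dropna(subset=["ln_rf"]).groupby("unit")["ln_rf"].mean().to_dict()
    classes = sorted(weights)
    base = classes[0]
    contrasts = {
        (c, base): mean_lnrf[c] - mean_lnrf[base] for c in classes if c != base
    }
    true_contrasts = {
        (c, base): float(np.log(weights[c] / weights[base]))
        for c in classes if c != base
    }
    return {
        "mean_lnrf": mean_lnrf,
        "expected_lnrf": truth.expected_lnrf,
        "contrasts": contrasts,
        "true_contrasts": true_contrasts,
        "n_panels": len(panels),
    }


def null_calibration_study(
    seed: int,
    n_birds: int = 20,
    n_months: int = 2,
    extent_km: float = 60.0,
    patch_scale: float = 1000.0,
) -> dict:
    """Uniform-preference scenario: every class should show no selection."""
    ext = extent_km * 1000.0
    weights = {1: 1.0, 2: 1.0, 3: 1.0}
    scenario = synthetic.SyntheticScenario(
        seed=seed, extent=(0.0, 0.0, ext, ext), habitat_weights=weights,
        n_birds=n_birds, months=[(2008, 6 + m) for m in range(n_months)],
        fixes_per_day=16,
    )
    habitat, _ = synthetic.generate_landscape(
        seed, scenario.extent, n_classes=3, patch_scale=patch_scale
    )
    panels, _, _ = _tracks_to_panels(scenario, habitat)
    table = _panel_lnrf(panels, habitat, use_estimator="counts")
    mean_lnrf = table.dropna(subset=["ln_rf"]).groupby("unit")["ln_rf"].mean().to_dict()
    return {"mean_lnrf": mean_lnrf, "n_panels": len(panels)}


def screen_type1_study(
    seed: int,
    min_tests: int = 1000,
    max_fits: int = 500,
    n_birds: int = 25,
    n_months: int = 8,
    alpha: float = 0.01,
) -> dict:
    """Type I error of the P < alpha screen on null mixed-model panels.

    Each replicate draws ln(rf) panels with *no* attribute effects, fits
    the bird-characteristics mixed model, and screens every per-term Wald
    test (up to 5 attribute terms per fit; aliased terms are dropped), so
    replicates accumulate until at least ``min_tests`` null tests.
    """
    rng = np.random.default_rng(seed)
    marg = synthetic.DEFAULT_ATTRIBUTE_MARGINALS
    n_tests = 0
    n_flagged = 0
    for _ in range(max_fits):
        if n_tests >= min_tests:
            break
        panel = synthetic.simulate_ar1_panels(
            seed=int(rng.integers(2**31)), n_birds=n_birds, n_months=n_months,
            sigma_u=0.4, sigma_e=0.5, rho=0.4,
        )
        attrs = synthetic._draw_attributes(
            rng, sorted(panel["bird_id"].unique()), marg
        )
        data = panel.merge(attrs, on="bird_id")
        terms = models.independent_terms(
            data,
            [t for t in ("sex", "age_class", "breeder", "release_site", "rearing")
             if data[t].nunique() > 1],
        )
        if not terms:
            continue
        fit = models.fit_mixed_ar1(data, models.ModelSpec(terms), method="reml")
        screened = models.screen_effects(fit.wald_tests(), alpha=alpha)
        n_tests += len(screened)
        n_flagged += int(screened["significant"].sum())
    return {"n_tests": n_tests, "n_flagged": n_flagged,
            "flag_rate": n_flagged / n_tests}


def mixed_model_coverage_study(
    seed: int,
    n_replicates: int = 100,
    beta_true: float = 1.0,
    n_birds: int = 40,
    n_months: int = 12,
    rho: float = 0.6,
) -> dict:
    """95% CI coverage of a known slope under the AR(1) model family."""
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_replicates):
        data = synthetic.simulate_ar1_panels(
            seed=int(rng.integers(2**31)), n_birds=n_birds, n_months=n_months,
            beta={"thermal_height": beta_true}, sigma_u=0.5, sigma_e=0.5, rho=rho,
        )
        fit = models.fit_mixed_ar1(data, models.ModelSpec(["thermal_height"]))
        b, se = fit.coefficients["thermal_height"]
        covered += int(b - 1.96 * se <= beta_true <= b + 1.96 * se)
    return {"covered": covered, "n_replicates": n_replicates}


def covariance_selection_study(
    seed: int,
    n_runs: int = 100,
    rho: float = 0.6,
    n_birds: int = 40,
    n_months: int = 12,
) -> dict:
    """How often AICc prefers AR(1) on AR(1)-generated panels."""
    rng = np.random.default_rng(seed)
    picks = 0
    for _ in range(n_runs):
        data = synthetic.simulate_ar1_panels(
            seed=int(rng.integers(2**31)), n_birds=n_birds, n_months=n_months,
            beta={"thermal_height": 0.5}, sigma_u=0.5, sigma_e=0.5, rho=rho,
        )
        result = models.compare_covariance(data, models.ModelSpec(["thermal_height"]))
        picks += int(result["winner"] == "ar1")
    return {"ar1_selected": picks, "n_runs": n_runs}
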