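"""Synthetic bundles, cohorts and activation-linked outcomes."""

import numpy as np
import pandas as pd
import pytest

from vatmap.errors import ParameterError
from vatmap.geometry import resample_polyline
from vatmap.outcome_stats import fit_univariate
from vatmap.spatial_io import DensityVolume, GridSpec
from vatmap.synthetic_data import (
    BundleSpec,
    CohortSpec,
    followup_from_improvement,
    generate_bundle,
    generate_cohort,
    simulate_outcomes,
)

CENTERLINE = tuple((0.0, float(y), 0.0) for y in np.linspace(-30, 30, 7))


def bundle_spec(**kw):
    base = dict(name="b", centerline=CENTERLINE, n_streamlines=10, lateral_sd=2.0,
                step=1.0, seed=42)
    base.update(kw)
    return BundleSpec(**base)


class TestGenerateBundle:
    def test_zero_dispersion_reproduces_centerline(self):
        t = generate_bundle(bundle_spec(n_streamlines=1, lateral_sd=0.0))
        expected = resample_polyline(np.asarray(CENTERLINE), 1.0)
        assert np.allclose(t.streamlines[0], expected)

    def test_deterministic_given_seed(self):
        a = generate_bundle(bundle_spec())
        b = generate_bundle(bundle_spec())
        for sa, sb in zip(a, b):
            assert np.array_equal(sa, sb)

    def test_different_seeds_differ(self):
        a = generate_bundle(bundle_spec(seed=1))
        b = generate_bundle(bundle_spec(seed=2))
        assert not np.allclose(a.streamlines[0], b.streamlines[0])

    def test_lateral_dispersion_matches_spec_within_10pct(self):
        """Monte-Carlo: pooled SD of point offsets from the centerline."""
        t = generate_bundle(bundle_spec(n_streamlines=500, lateral_sd=2.0))
        base = resample_polyline(np.asarray(CENTERLINE), 1.0)
        offsets = np.concatenate([(s - base)[:, [0, 2]].ravel() for s in t])
        assert np.std(offsets) == pytest.approx(2.0, rel=0.10)

    def test_streamlines_are_smooth(self):
        """Perturbation is a smooth field: successive point spacing stays
        close to the nominal step, no jagged independent noise."""
        t = generate_bundle(bundle_spec(n_streamlines=20, lateral_sd=3.0))
        for s in t:
            seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
            assert seg.max() < 3.0  # step 1 mm; iid 3 mm noise would explode this

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            bundle_spec(n_streamlines=0)
        with pytest.raises(ParameterError):
            bundle_spec(lateral_sd=-1.0)
        with pytest.raises(ParameterError):
            bundle_spec(step=0.0)
        with pytest.raises(ParameterError):
            bundle_spec(centerline=((0, 0, 0),))


def cohort_spec(**kw):
    base = dict(name="coh", n_patients=12, target_center_left=(-5.0, 0.0, 0.0),
                target_center_right=(5.0, 0.0, 0.0), placement_sd=1.5, seed=7)
    base.update(kw)
    return CohortSpec(**base)


class TestGenerateCohort:
    def test_cardinality(self):
        contacts, outcomes = generate_cohort(cohort_spec(n_patients=12))
        assert len(outcomes) == 12
        assert len(contacts) == 24
        assert set(contacts["hemisphere"]) == {"L", "R"}

    def test_zero_jitter_places_contacts_on_target(self):
        contacts, _ = generate_cohort(cohort_spec(placement_sd=0.0))
        left = contacts[contacts.hemisphere == "L"]
        assert np.allclose(left[["x_mm", "y_mm", "z_mm"]], (-5.0, 0.0, 0.0))

    def test_deterministic_given_seed(self):
        a = generate_cohort(cohort_spec())
        b = generate_cohort(cohort_spec())
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_clinical_invariants(self):
        _, outcomes = generate_cohort(cohort_spec(n_patients=200, seed=1))
        assert (outcomes["ybocs_baseline"] > 0).all()
        assert outcomes["ybocs_baseline"].between(8, 40).all()
        assert (outcomes["improvement"] <= 1.0).all()
        assert (outcomes["ybocs_followup"] >= 0).all()
        # follow-up is integer-rounded
        assert np.array_equal(outcomes["ybocs_followup"], np.rint(outcomes["ybocs_followup"]))

    def test_currents_positive(self):
        contacts, _ = generate_cohort(cohort_spec(n_patients=100, current_mean=0.5, current_sd=2.0))
        assert (contacts["current_mA"] > 0).all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            cohort_spec(n_patients=1)


class TestFollowupRounding:
    def test_reference_case(self):
        """Baseline 34.3 with improvement 0.44 implies follow-up 19.208,
        rounded to 19 on the clinician scale."""
        followup, improvement = followup_from_improvement(np.array([34.3]), np.array([0.44]))
        assert followup[0] == 19.0
        assert improvement[0] == pytest.approx((34.3 - 19.0) / 34.3)

    def test_unrounded_mode_inverts_exactly(self):
        followup, improvement = followup_from_improvement(
            np.array([34.3]), np.array([0.44]), round_followup=False
        )
        assert followup[0] == pytest.approx(19.208)
        assert improvement[0] == pytest.approx(0.44)


def _uniform_gradient_density():
    """Density increasing linearly along x, so activation tracks x."""
    grid = GridSpec(origin=(-10.0, -10.0, -10.0), voxel_size=1.0, dims=(21, 21, 21))
    vals = np.tile(np.arange(21, dtype=float)[:, None, None], (1, 21, 21))
    return DensityVolume(grid, vals)


def _contacts(positions):
    rows = []
    for i, x in enumerate(positions):
        for hemi, sign in (("L", -1.0), ("R", 1.0)):
            rows.append({"patient_id": f"p{i:02d}", "hemisphere": hemi,
                         "x_mm": x, "y_mm": sign * 2.0, "z_mm": 0.0, "current_mA": 2.0})
    return pd.DataFrame(rows)


class TestSimulateOutcomes:
    def test_noiseless_linear_model_recovered_exactly(self):
        density = _uniform_gradient_density()
        contacts = _contacts(np.linspace(-5, 5, 8))
        out = simulate_outcomes(contacts, density, effect_slope=0.02, noise_sd=0.0, seed=0)
        # regress improvement on the per-patient mean bilateral activation
        from vatmap.overlap_scoring import bundle_activation
        from vatmap.vat_model import build_sites

        acts = {}
        for s in build_sites(contacts):
            acts.setdefault(s.patient_id, []).append(bundle_activation(density, s))
        x = np.array([np.mean(acts[p]) for p in out["patient_id"]])
        fit = fit_univariate((x, out["improvement"].to_numpy()))
        assert fit.slope == pytest.approx(0.02, abs=1e-10)
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-10)

    def test_identical_patients_identical_improvements(self):
        density = _uniform_gradient_density()
        contacts = _contacts([2.0, 2.0])
        out = simulate_outcomes(contacts, density, effect_slope=0.1, noise_sd=0.0, seed=5)
        assert out["improvement"].iloc[0] == out["improvement"].iloc[1]

    def test_deterministic_given_seed(self):
        density = _uniform_gradient_density()
        contacts = _contacts(np.linspace(-4, 4, 6))
        a = simulate_outcomes(contacts, density, effect_slope=0.05, noise_sd=0.1, seed=9)
        b = simulate_outcomes(contacts, density, effect_slope=0.05, noise_sd=0.1, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_null_effect_slope_within_ci(self):
        """Monte-Carlo null calibration: with effect_slope 0 the fitted slope
        is inside its own 95% CI in the clear majority of replicates."""
        density = _uniform_gradient_density()
        from scipy import stats
        from vatmap.overlap_scoring import bundle_activation
        from vatmap.vat_model import build_sites

        covered = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            contacts = _contacts(rng.uniform(-5, 5, 10))
            out = simulate_outcomes(contacts, density, effect_slope=0.0, noise_sd=0.1,
                                    seed=2000 + rep)
            acts = {}
            for s in build_sites(contacts):
                acts.setdefault(s.patient_id, []).append(bundle_activation(density, s))
            x = np.array([np.mean(acts[p]) for p in out["patient_id"]])
            y = out["improvement"].to_numpy()
            fit = fit_univariate((x, y))
            # slope CI from the closed form
            n = len(x)
            resid = y - (fit.intercept + fit.slope * x)
            se = np.sqrt(resid @ resid / (n - 2) / ((x - x.mean()) ** 2).sum())
            half = stats.t.ppf(0.975, n - 2) * se
            covered += abs(fit.slope) <= half
        assert covered >= n_rep - 3

    def test_contact_outside_density_raises(self):
        density = _uniform_gradient_density()
        contacts = _contacts([200.0])
        with pytest.raises(Exception):
            simulate_outcomes(contacts, density, effect_slope=0.1, noise_sd=0.0, seed=0)

    def test_baselines_trigger_rounding(self):
        density = _uniform_gradient_density()
        contacts = _contacts([0.0, 2.0, -2.0])
        baselines = pd.DataFrame({"patient_id": [f"p{i:02d}" for i in range(3)],
                                  "ybocs_baseline": [34.3, 30.0, 28.0]})
        out = simulate_outcomes(contacts, density, effect_slope=0.001, noise_sd=0.0,
                                seed=0, intercept=0.4, baselines=baselines)
        assert np.array_equal(out["ybocs_followup"], np.rint(out["ybocs_followup"]))
        recomputed = (out["ybocs_baseline"] - out["ybocs_followup"]) / out["ybocs_baseline"]
        assert np.allclose(out["improvement"], recomputed)
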