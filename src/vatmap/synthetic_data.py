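"""Synthetic fiber bundles, electrode cohorts and outcomes.

The real inputs to this analysis — normative streamline atlases and two DBS
patient cohorts — are not publicly deposited, so every downstream stage is
exercised on generated stand-ins that reproduce the *statistical* structure
the analysis assumes:

* fiber bundles as smooth polyline families dispersed around a centerline
  (abstract test anatomy; no attempt to mimic real bundle geometry),
* bilateral electrode cohorts with Gaussian placement jitter around a
  per-hemisphere target, truncated-normal currents and baseline scores
  matching the clinical ranges (baseline severity ~34/40 on a 0-40
  clinician scale, ~45% mean improvement at follow-up),
* outcomes whose expectation is linear in the activation score of a chosen
  bundle, with Gaussian noise.

Improvement is the relative reduction (baseline - followup) / baseline, i.e.
follow-up is "compared to the baseline by division"; follow-up scores are
rounded to the nearest integer (a clinician scale) and improvement is then
recomputed from the rounded score.  All generators are deterministic given
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from vatmap.errors import ParameterError
from vatmap.geometry import resample_polyline
from vatmap.overlap_scoring import bundle_activation
from vatmap.spatial_io import DensityVolume, Tractogram
from vatmap.vat_model import VatParams, build_sites

__all__ = [
    "BundleSpec",
    "CohortSpec",
    "generate_bundle",
    "generate_cohort",
    "simulate_outcomes",
    "followup_from_improvement",
]

#: baseline scores are truncated to this clinically plausible range
BASELINE_BOUNDS = (8.0, 40.0)


@dataclass(frozen=True)
class BundleSpec:
    """Parameters of one synthetic fiber bundle.

    ``centerline`` is an ordered ``(k >= 2, 3)`` array of control points in
    world mm; each streamline is a smooth random perturbation of it with
    point offsets of marginal SD ``lateral_sd`` mm, resampled at ``step`` mm.
    """

    name: str
    centerline: tuple
    n_streamlines: int
    lateral_sd: float
    step: float
    seed: int
    correlation_length_knots: float = 2.0  # offset-field smoothness, in units of knot spacing

    def __post_init__(self) -> None:
        cl = np.asarray(self.centerline, dtype=np.float64)
        if cl.ndim != 2 or cl.shape[1] != 3 or cl.shape[0] < 2:
            raise ParameterError(f"centerline must be (k>=2, 3), got shape {cl.shape}")
        if self.n_streamlines < 1:
            raise ParameterError(f"n_streamlines must be >= 1, got {self.n_streamlines}")
        if self.lateral_sd < 0:
            raise ParameterError(f"lateral_sd must be >= 0, got {self.lateral_sd}")
        if self.step <= 0:
            raise ParameterError(f"step must be > 0, got {self.step}")
        object.__setattr__(self, "centerline", tuple(map(tuple, cl)))

    @property
    def centerline_array(self) -> np.ndarray:
        return np.asarray(self.centerline, dtype=np.float64)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic bilateral DBS cohort.

    Defaults follow the clinical ranges of the emulated study populations:
    baseline severity ~34 +/- 4 points, mean improvement fraction ~0.44 +/-
    0.25, currents ~3 +/- 1 mA (stimulation currents are a free choice; no
    published per-patient values exist for the emulated cohorts).
    """

    name: str
    n_patients: int
    target_center_left: tuple[float, float, float]
    target_center_right: tuple[float, float, float]
    placement_sd: float
    seed: int
    current_mean: float = 3.0
    current_sd: float = 1.0
    baseline_mean: float = 34.3
    baseline_sd: float = 4.4
    improvement_mean: float = 0.44
    improvement_sd: float = 0.25
    effect_slope: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ParameterError(f"n_patients must be >= 2, got {self.n_patients}")
        if self.placement_sd < 0:
            raise ParameterError(f"placement_sd must be >= 0, got {self.placement_sd}")
        for nm in ("current_sd", "baseline_sd", "improvement_sd", "noise_sd"):
            if getattr(self, nm) < 0:
                raise ParameterError(f"{nm} must be >= 0")


def generate_bundle(spec: BundleSpec) -> Tractogram:
    """Generate a bundle of smooth streamlines around a centerline.

    The per-streamline offset is a correlated Gaussian field defined at the
    centerline control points (squared-exponential covariance along
    arclength, marginal SD ``lateral_sd``) and interpolated with a cubic
    spline, so streamlines stay smooth while the marginal dispersion of every
    point is ``lateral_sd``.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cl = spec.centerline_array
    base = resample_polyline(cl, spec.step)

    seg = np.linalg.norm(np.diff(cl, axis=0), axis=1)
    knot_s = np.concatenate([[0.0], np.cumsum(seg)])
    total = knot_s[-1]
    if total == 0:
        raise ParameterError("centerline has zero length")
    sample_s = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(base, axis=0), axis=1))]
    )

    k = len(knot_s)
    if spec.lateral_sd > 0 and k >= 2:
        ell = spec.correlation_length_knots * total / (k - 1)
        d = knot_s[:, None] - knot_s[None, :]
        cov = np.exp(-0.5 * (d / ell) ** 2)
        cov[np.diag_indices(k)] += 1e-10
        chol = np.linalg.cholesky(cov)
    else:
        chol = None

    streamlines = []
    for _ in range(spec.n_streamlines):
        if chol is None or spec.lateral_sd == 0:
            # keep the random stream aligned whether or not offsets are used
            rng.standard_normal((k, 3))
            streamlines.append(base.copy())
            continue
        knot_offsets = spec.lateral_sd * (chol @ rng.standard_normal((k, 3)))
        spline = CubicSpline(knot_s, knot_offsets, axis=0)
        streamlines.append(base + spline(np.clip(sample_s, 0.0, total)))
    return Tractogram(streamlines, space_tag="synthetic")


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    """Rejection-sampled truncated normal (exact, adequate for mild truncation)."""
    if sd == 0:
        vals = np.full(size, float(mean))
        if np.any((vals < lo) | (vals > hi)):
            raise ParameterError(f"degenerate draw {mean} outside bounds [{lo}, {hi}]")
        return vals
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, remaining.size)
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def followup_from_improvement(
    baseline: np.ndarray, improvement: np.ndarray, round_followup: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Follow-up score implied by a relative improvement, and the improvement
    recomputed after rounding.

    followup = baseline * (1 - improvement), rounded to the nearest integer
    (clinician scale) and floored at 0 when ``round_followup``; the returned
    improvement is (baseline - followup) / baseline of the (rounded) score.
    """
    baseline = np.asarray(baseline, dtype=np.float64)
    improvement = np.asarray(improvement, dtype=np.float64)
    followup = baseline * (1.0 - improvement)
    followup = np.clip(followup, 0.0, None)
    if round_followup:
        followup = np.rint(followup)
    return followup, (baseline - followup) / baseline


def generate_cohort(
    spec: CohortSpec, round_followup: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one bilateral cohort: a contact table and an outcome table.

    Each patient gets one active contact per hemisphere at the hemisphere's
    target center plus isotropic Gaussian jitter of SD ``placement_sd``, and
    a truncated-normal current.  Baselines are truncated normal in [8, 40];
    improvements are drawn from the cohort's marginal improvement
    distribution (truncated to <= 1), converted to (rounded) follow-up
    scores, and recomputed from them.  Use :func:`simulate_outcomes` to
    replace these marginal improvements with activation-linked ones.

    Returns ``(contacts, outcomes)`` with columns
    ``patient_id, hemisphere, x_mm, y_mm, z_mm, current_mA`` and
    ``patient_id, ybocs_baseline, ybocs_followup, improvement``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    ids = [f"{spec.name}-{i + 1:02d}" for i in range(n)]

    contact_rows = []
    for i, pid in enumerate(ids):
        for hemi, target in (("L", spec.target_center_left), ("R", spec.target_center_right)):
            center = np.asarray(target, dtype=np.float64) + rng.normal(0.0, spec.placement_sd, 3)
            current = _truncated_normal(rng, spec.current_mean, spec.current_sd, 1e-6, np.inf, 1)[0]
            contact_rows.append(
                {
                    "patient_id": pid,
                    "hemisphere": hemi,
                    "x_mm": center[0],
                    "y_mm": center[1],
                    "z_mm": center[2],
                    "current_mA": current,
                }
            )
    contacts = pd.DataFrame(contact_rows)

    baseline = _truncated_normal(rng, spec.baseline_mean, spec.baseline_sd, *BASELINE_BOUNDS, n)
    improvement = _truncated_normal(rng, spec.improvement_mean, spec.improvement_sd, -np.inf, 1.0, n)
    followup, improvement = followup_from_improvement(baseline, improvement, round_followup)
    outcomes = pd.DataFrame(
        {
            "patient_id": ids,
            "ybocs_baseline": baseline,
            "ybocs_followup": followup,
            "improvement": improvement,
        }
    )
    return contacts, outcomes


def simulate_outcomes(
    contacts: pd.DataFrame,
    density: DensityVolume,
    effect_slope: float,
    noise_sd: float,
    seed: int,
    intercept: float = 0.0,
    vat_params: VatParams = VatParams(),
    baselines: pd.DataFrame | None = None,
    round_followup: bool = True,
) -> pd.DataFrame:
    """Outcomes whose expectation is linear in a bundle's activation score.

    Per patient: improvement = intercept + effect_slope * (mean bilateral
    activation) + N(0, noise_sd), truncated to <= 1.  When ``baselines`` (an
    outcome-style table with ``patient_id, ybocs_baseline``) is given, the
    improvement is converted to a follow-up score, rounded, and recomputed;
    otherwise baseline/follow-up columns are NaN.  Deterministic given
    ``seed``; raises if any contact's activation sphere leaves the density
    grid.
    """
    rng = np.random.default_rng(seed)
    sites = build_sites(contacts, vat_params)
    per_patient: dict[str, list[float]] = {}
    for site in sites:
        per_patient.setdefault(site.patient_id, []).append(bundle_activation(density, site))
    ids = sorted(per_patient)
    mean_act = np.array([np.mean(per_patient[pid]) for pid in ids])
    improvement = intercept + effect_slope * mean_act + rng.normal(0.0, noise_sd, len(ids))
    improvement = np.minimum(improvement, 1.0)

    if baselines is not None:
        base = (
            baselines.set_index(baselines["patient_id"].astype(str))["ybocs_baseline"]
            .loc[ids]
            .to_numpy(dtype=np.float64)
        )
        followup, improvement = followup_from_improvement(base, improvement, round_followup)
    else:
        base = np.full(len(ids), np.nan)
        followup = np.full(len(ids), np.nan)
    return pd.DataFrame(
        {
            "patient_id": ids,
            "ybocs_baseline": base,
            "ybocs_followup": followup,
            "improvement": improvement,
        }
    )
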