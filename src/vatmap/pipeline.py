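"""End-to-end orchestration of the overlay and fingerprint analyses.

``run_overlay_analysis`` chains the stages: generate (or load) bundles,
rasterize them to smoothed density images, build stimulation sites from the
contact table, simulate activation-linked outcomes, assemble the pooled
observation table and screen every structure with regression + leave-one-out
validation.  ``run_fingerprint_analysis`` selects streamlines from a
(synthetic) normative connectome around each group's stimulation sites,
renders terminal-density fingerprints and reports peaks and conjugations.

Everything is deterministic given the config seed: one root seed sequence is
forked per stage, and output files carry a provenance record (config hash,
package version, seed) with no timestamps, so a rerun is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vatmap import __version__
from vatmap.connectome_selection import conjugation, group_fingerprint, peaks_to_frame
from vatmap.density_mapping import RasterConfig, rasterize
from vatmap.errors import ValidationError
from vatmap.outcome_stats import structure_screen
from vatmap.overlap_scoring import build_observations
from vatmap.spatial_io import Tractogram, write_volume
from vatmap.synthetic_data import BundleSpec, CohortSpec, generate_bundle, generate_cohort, simulate_outcomes
from vatmap.vat_model import VatParams, build_sites, sites_to_frame

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "demo_config", "run_overlay_analysis", "run_fingerprint_analysis", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full synthetic run.

    The defaults define the package's demo study: a true bundle on the x = 0
    axis flanked by two disjoint decoys 12 mm away, two bilateral cohorts
    (n = 12 and n = 14) whose target clusters sit at different heights along
    the true bundle, improvements linear in true-bundle activation with noise
    calibrated so the true patient-level R² is ~0.5.
    """

    seed: int = 0
    output_dir: str = "results"
    # bundle geometry (abstract test anatomy)
    bundle_half_length_mm: float = 40.0
    bundle_n_streamlines: int = 300
    bundle_lateral_sd_mm: float = 2.0
    bundle_step_mm: float = 1.0
    decoy_offset_mm: float = 12.0
    # density grids
    density_voxel_mm: float = 1.0
    density_sigma_mm: float = 2.0
    terminal_voxel_mm: float = 1.0
    terminal_sigma_mm: float = 3.0
    # VAT model
    sigma_s_per_m: float = 0.1
    e_threshold_v_per_mm: float = 0.2
    # cohorts
    n_patients_a: int = 12
    n_patients_b: int = 14
    placement_sd_mm: float = 1.5
    current_mean_ma: float = 3.0
    current_sd_ma: float = 1.0
    # outcome model
    target_r2: float = 0.5
    improvement_mean: float = 0.45
    improvement_sd: float = 0.25
    # fingerprint analysis
    connectome_n_per_group: int = 120
    roi_diameter_mm: float = 6.0
    threshold_quantile: float = 0.95
    pairing_mm: float = 8.0
    peak_min_separation_mm: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output path is location, not
        analysis, and is excluded so reruns elsewhere compare equal)."""
        fields = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(fields, sort_keys=True).encode()).hexdigest()[:16]

    def vat_params(self) -> VatParams:
        return VatParams(sigma=self.sigma_s_per_m, e_threshold=self.e_threshold_v_per_mm)


def demo_config(seed: int = 0, output_dir: str = "results") -> RunConfig:
    return RunConfig(seed=seed, output_dir=output_dir)


def _seeds(cfg: RunConfig, n: int) -> list[int]:
    """Fork n independent child seeds (< 2**31) from the config seed."""
    ss = np.random.SeedSequence(cfg.seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _line_y(x: float, half: float) -> tuple:
    ys = np.linspace(-half, half, 9)
    return tuple((x, float(y), 0.0) for y in ys)


def _line_x(y: float, half: float) -> tuple:
    xs = np.linspace(-half, half, 9)
    return tuple((float(x), y, 0.0) for x in xs)


def bundle_specs(cfg: RunConfig) -> list[BundleSpec]:
    """The demo anatomy: one true bundle and two disjoint decoys.

    The true bundle runs along y at x = 0; the target clusters sit on it, so
    its activation is driven by each contact's radial (x, z) offset.  The
    decoys run along x, displaced in y beyond the outer target clusters:
    their distance to any contact is set by (y, z), which keeps their
    activation essentially independent of the true bundle's — they are
    genuine null structures, not anti-correlated shadows of the true bundle
    (parallel decoys would be: their tail density falls monotonically with
    the same x-offset that drives true-bundle activation).
    """
    s_bundle, s_da, s_db = _seeds(cfg, 8)[:3]
    half = cfg.bundle_half_length_mm
    common = dict(
        n_streamlines=cfg.bundle_n_streamlines,
        lateral_sd=cfg.bundle_lateral_sd_mm,
        step=cfg.bundle_step_mm,
    )
    y_off = 20.0 + cfg.decoy_offset_mm  # outer target cluster + clearance
    return [
        BundleSpec(name="bundle_S", centerline=_line_y(0.0, half), seed=s_bundle, **common),
        BundleSpec(name="decoy_A", centerline=_line_x(y_off, half), seed=s_da, **common),
        BundleSpec(name="decoy_B", centerline=_line_x(-y_off, half), seed=s_db, **common),
    ]


def cohort_specs(cfg: RunConfig) -> list[CohortSpec]:
    seeds = _seeds(cfg, 8)
    common = dict(
        placement_sd=cfg.placement_sd_mm,
        current_mean=cfg.current_mean_ma,
        current_sd=cfg.current_sd_ma,
        improvement_mean=cfg.improvement_mean,
        improvement_sd=cfg.improvement_sd,
    )
    return [
        CohortSpec(
            name="cohortA",
            n_patients=cfg.n_patients_a,
            target_center_left=(0.0, -10.0, 0.0),
            target_center_right=(0.0, 10.0, 0.0),
            seed=seeds[3],
            baseline_mean=34.3,
            baseline_sd=4.4,
            **common,
        ),
        CohortSpec(
            name="cohortB",
            n_patients=cfg.n_patients_b,
            target_center_left=(0.0, -20.0, 0.0),
            target_center_right=(0.0, 20.0, 0.0),
            seed=seeds[4],
            baseline_mean=33.4,
            baseline_sd=3.7,
            **common,
        ),
    ]


def calibrate_effect(
    activations: np.ndarray, improvement_mean: float, improvement_sd: float, r2: float
) -> tuple[float, float, float]:
    """(intercept, slope, noise_sd) so the patient-level linear model has the
    requested R² and the improvement distribution the requested moments.

    With improvement = a + b x + e: choose b s.t. sd(b x) = improvement_sd *
    sqrt(r2), noise_sd = improvement_sd * sqrt(1 - r2), and a to center the
    mean.
    """
    act_sd = float(np.std(activations))
    if act_sd == 0:
        raise ValidationError("activation scores are constant; cannot calibrate an effect")
    slope = improvement_sd * np.sqrt(r2) / act_sd
    noise_sd = improvement_sd * np.sqrt(1.0 - r2)
    intercept = improvement_mean - slope * float(np.mean(activations))
    return float(intercept), float(slope), float(noise_sd)


def _provenance(cfg: RunConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "package": "vatmap",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
    }


def run_overlay_analysis(cfg: RunConfig, write: bool = True) -> dict:
    """Generate the synthetic study, score activations and screen structures.

    Returns a dict with the contact/outcome/site/observation tables, the
    structure screen, the densities and the calibrated effect; when ``write``
    the tables land under ``cfg.output_dir`` with a provenance record.
    """
    out = Path(cfg.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    logger.info("stage bundles: generating %d bundles", len(bundle_specs(cfg)))
    tractograms = {spec.name: generate_bundle(spec) for spec in bundle_specs(cfg)}

    half = cfg.bundle_half_length_mm
    y_reach = 20.0 + cfg.decoy_offset_mm + 8.0
    bbox = ((-half - 8.0, -max(half + 8.0, y_reach), -8.0), (half + 8.0, max(half + 8.0, y_reach), 8.0))
    raster_cfg = RasterConfig(
        voxel_size=cfg.density_voxel_mm, smoothing_sigma=cfg.density_sigma_mm, bbox=bbox
    )
    densities = {name: rasterize(t, raster_cfg) for name, t in tractograms.items()}
    logger.info("stage densities: rasterized %d bundles on grid %s", len(densities), densities["bundle_S"].grid.dims)

    specs = cohort_specs(cfg)
    seeds = _seeds(cfg, 8)
    contact_parts, baseline_parts, cohort_of = [], [], {}
    for spec in specs:
        contacts, outcomes = generate_cohort(spec)
        contact_parts.append(contacts)
        baseline_parts.append(outcomes)
        cohort_of.update({pid: spec.name for pid in outcomes["patient_id"]})
    contacts = pd.concat(contact_parts, ignore_index=True)
    baselines = pd.concat(baseline_parts, ignore_index=True)

    params = cfg.vat_params()
    sites = build_sites(contacts, params)

    # calibrate the activation -> improvement effect on the true bundle
    from vatmap.overlap_scoring import bundle_activation

    per_patient: dict[str, list[float]] = {}
    for site in sites:
        per_patient.setdefault(site.patient_id, []).append(
            bundle_activation(densities["bundle_S"], site)
        )
    mean_act = np.array([np.mean(v) for v in per_patient.values()])
    intercept, slope, noise_sd = calibrate_effect(
        mean_act, cfg.improvement_mean, cfg.improvement_sd, cfg.target_r2
    )
    outcomes = simulate_outcomes(
        contacts,
        densities["bundle_S"],
        effect_slope=slope,
        noise_sd=noise_sd,
        seed=seeds[5],
        intercept=intercept,
        vat_params=params,
        baselines=baselines,
    )
    logger.info(
        "stage outcomes: slope=%.4g noise_sd=%.4g over %d patients", slope, noise_sd, len(outcomes)
    )

    observations = build_observations(densities, sites, outcomes, cohorts=cohort_of)
    screen = structure_screen(observations)
    logger.info("stage screen: %d structure x partition rows", len(screen))

    result = {
        "tractograms": tractograms,
        "densities": densities,
        "contacts": contacts,
        "outcomes": outcomes,
        "sites": sites,
        "observations": observations,
        "screen": screen,
        "effect": {"intercept": intercept, "slope": slope, "noise_sd": noise_sd},
    }
    if write:
        contacts.to_csv(out / "contacts.csv", index=False)
        outcomes.to_csv(out / "outcomes.csv", index=False)
        sites_to_frame(sites).to_csv(out / "sites.csv", index=False)
        observations.to_csv(out / "observations.csv", index=False)
        screen.to_csv(out / "structure_screen.tsv", sep="\t", index=False)
        (out / "overlay_provenance.json").write_text(
            json.dumps(_provenance(cfg, "overlay"), indent=2) + "\n"
        )
    return result


def synthetic_connectome(cfg: RunConfig) -> tuple[Tractogram, Tractogram, dict]:
    """Two groups' worth of synthetic long-range streamlines.

    Group A streamlines run from its target clusters to a shared "cortical"
    blob and an exclusive one; likewise group B.  Used as the desk-scale
    stand-in for a normative connectome in the fingerprint demo.
    """
    seeds = _seeds(cfg, 8)
    rng = np.random.default_rng(seeds[6])
    blobs = {
        "shared": np.array([0.0, 0.0, 40.0]),
        "only_A": np.array([-25.0, 0.0, 35.0]),
        "only_B": np.array([25.0, 0.0, 35.0]),
    }
    groups = {
        "A": ([(0.0, -10.0, 0.0), (0.0, 10.0, 0.0)], "only_A"),
        "B": ([(0.0, -20.0, 0.0), (0.0, 20.0, 0.0)], "only_B"),
    }
    tracts = {}
    for gname, (targets, exclusive) in groups.items():
        sls = []
        for j in range(cfg.connectome_n_per_group):
            start = np.asarray(targets[j % 2]) + rng.normal(0.0, 2.0, 3)
            end_blob = blobs["shared"] if j % 2 == 0 else blobs[exclusive]
            end = end_blob + rng.normal(0.0, 2.0, 3)
            mid = 0.5 * (start + end) + rng.normal(0.0, 2.0, 3)
            n_pts = 25
            u = np.linspace(0.0, 1.0, n_pts)[:, None]
            # quadratic Bezier through the jittered midpoint
            pts = (1 - u) ** 2 * start + 2 * u * (1 - u) * mid + u**2 * end
            sls.append(pts)
        tracts[gname] = Tractogram(sls, space_tag="synthetic")
    return tracts["A"], tracts["B"], blobs


def run_fingerprint_analysis(cfg: RunConfig, write: bool = True) -> dict:
    """Fingerprints, peaks and conjugations of the two demo groups."""
    out = Path(cfg.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    overlay = run_overlay_analysis(cfg, write=False)
    sites = overlay["sites"]
    cohort_of = {r.patient_id: r.cohort for r in overlay["observations"].itertuples()}
    sites_a = [s for s in sites if cohort_of[s.patient_id] == "cohortA"]
    sites_b = [s for s in sites if cohort_of[s.patient_id] == "cohortB"]

    conn_a, conn_b, blobs = synthetic_connectome(cfg)
    lo = (-45.0, -55.0, -15.0)
    hi = (45.0, 55.0, 55.0)
    term_cfg = RasterConfig(
        voxel_size=cfg.terminal_voxel_mm,
        smoothing_sigma=cfg.terminal_sigma_mm,
        bbox=(lo, hi),
        mode="terminal",
    )
    fp_a = group_fingerprint(conn_a, sites_a, term_cfg, roi_diameter_mm=cfg.roi_diameter_mm)
    fp_b = group_fingerprint(conn_b, sites_b, term_cfg, roi_diameter_mm=cfg.roi_diameter_mm)
    report = conjugation(
        fp_a,
        fp_b,
        threshold_quantile=cfg.threshold_quantile,
        pairing_mm=cfg.pairing_mm,
        min_separation_mm=cfg.peak_min_separation_mm,
    )
    logger.info(
        "stage fingerprint: %d/%d peaks, %d conjugations",
        len(report.peaks_a),
        len(report.peaks_b),
        len(report.conjugations),
    )
    result = {
        "fingerprint_a": fp_a,
        "fingerprint_b": fp_b,
        "report": report,
        "blobs": blobs,
        "peaks": peaks_to_frame(report),
    }
    if write:
        write_volume(fp_a, out / "fingerprint_A.nii")
        write_volume(fp_b, out / "fingerprint_B.nii")
        result["peaks"].to_csv(out / "peaks.tsv", sep="\t", index=False)
        (out / "fingerprint_provenance.json").write_text(
            json.dumps(_provenance(cfg, "fingerprint"), indent=2) + "\n"
        )
    return result


def run_all(cfg: RunConfig) -> dict:
    """Overlay analysis followed by the fingerprint analysis."""
    overlay = run_overlay_analysis(cfg, write=True)
    fingerprint = run_fingerprint_analysis(cfg, write=True)
    return {"overlay": overlay, "fingerprint": fingerprint}
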