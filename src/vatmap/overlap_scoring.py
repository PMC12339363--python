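"""Bundle-activation scoring and per-streamline response correlation.

The activation of a structure at a stimulation site is the mean of its
(smoothed) density image over all voxels whose centers fall inside the VAT
sphere.  Pooling both hemispheres of every patient over all structures gives
the observation table the regression stage consumes.  For visualization, each
streamline of a bundle can be colored by the Pearson correlation between its
VAT overlap and clinical improvement across sites.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from vatmap.errors import (
    InsufficientDataError,
    OutOfBoundsError,
    ResolutionError,
    ValidationError,
)
from vatmap.geometry import resample_polyline
from vatmap.spatial_io import DensityVolume, Tractogram
from vatmap.vat_model import StimulationSite

__all__ = ["bundle_activation", "build_observations", "streamline_response_correlation"]

#: resampling step (mm) for the per-streamline overlap fraction
OVERLAP_RESAMPLE_STEP_MM = 0.5


def _sphere_voxel_values(density: DensityVolume, center: np.ndarray, radius: float) -> np.ndarray:
    """Values at all voxels whose centers lie within ``radius`` of ``center``."""
    grid = density.grid
    center = np.asarray(center, dtype=np.float64)
    lo_w = np.asarray(grid.origin)
    hi_w = grid.voxel_to_world(np.asarray(grid.dims) - 1)
    if np.any(center + radius < lo_w) or np.any(center - radius > hi_w):
        raise OutOfBoundsError(
            f"activation sphere (center {tuple(center)}, r={radius} mm) lies outside the grid"
        )
    # candidate index box, clipped to the grid
    lo = np.maximum(np.ceil((center - radius - lo_w) / grid.voxel_size - 1e-12), 0).astype(int)
    hi = np.minimum(
        np.floor((center + radius - lo_w) / grid.voxel_size + 1e-12), np.asarray(grid.dims) - 1
    ).astype(int)
    if np.any(hi < lo):
        raise ResolutionError(
            "activation sphere contains no voxel centers; use a smaller voxel_size"
        )
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0] + 1),
        np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = grid.voxel_to_world(idx)
    dist = np.linalg.norm(centers - center, axis=1)
    inside = dist <= radius
    if not inside.any():
        raise ResolutionError(
            "activation sphere contains no voxel centers; use a smaller voxel_size"
        )
    sel = idx[inside]
    return density.values[sel[:, 0], sel[:, 1], sel[:, 2]]


def bundle_activation(density: DensityVolume, site: StimulationSite) -> float:
    """Mean density inside the site's activation sphere (voxel-center rule)."""
    vals = _sphere_voxel_values(density, np.asarray(site.center), site.radius)
    return float(vals.mean())


def build_observations(
    densities: Mapping[str, DensityVolume],
    sites: Sequence[StimulationSite],
    outcomes: pd.DataFrame,
    cohorts: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per patient-hemisphere-structure activation scores joined to improvement.

    Left and right hemispheres are pooled as separate observations, each
    carrying its patient's improvement (the known non-independence of the two
    hemispheres of one patient is a property of the design, documented, not
    corrected).  ``cohorts`` optionally maps patient_id to a cohort label,
    carried through for partitioned screening.

    Returns a canonically sorted DataFrame with columns
    ``patient_id, hemisphere, structure, activation, improvement`` (plus
    ``cohort`` when provided): ``len(densities) * len(sites)`` rows.
    """
    if "patient_id" not in outcomes.columns or "improvement" not in outcomes.columns:
        raise ValidationError("outcome table needs columns patient_id, improvement")
    improvement = outcomes.set_index(outcomes["patient_id"].astype(str))["improvement"]
    missing = sorted({s.patient_id for s in sites} - set(improvement.index))
    if missing:
        raise ValidationError(f"sites without an outcome row: {missing}")

    rows = []
    for structure in sorted(densities):
        dens = densities[structure]
        for site in sites:
            rec = {
                "patient_id": site.patient_id,
                "hemisphere": site.hemisphere,
                "structure": structure,
                "activation": bundle_activation(dens, site),
                "improvement": float(improvement.loc[site.patient_id]),
            }
            if cohorts is not None:
                rec["cohort"] = cohorts[site.patient_id]
            rows.append(rec)
    table = pd.DataFrame(rows)
    table = table.sort_values(["structure", "patient_id", "hemisphere"], kind="mergesort")
    return table.reset_index(drop=True)


def streamline_response_correlation(
    t: Tractogram,
    sites: Sequence[StimulationSite],
    outcomes: pd.DataFrame,
    resample_step_mm: float = OVERLAP_RESAMPLE_STEP_MM,
    binary: bool = False,
) -> np.ndarray:
    """Pearson r between per-streamline VAT overlap and improvement.

    For each streamline the overlap with a site is the fraction of its
    resampled points inside the site's sphere (or 1/0 membership when
    ``binary``); r correlates these overlaps with the pooled improvements
    over all sites.  Streamlines whose overlap has zero variance (or when
    the improvements do) get NaN — an explicit undefined marker, never a
    silent 0.

    Returns an array of length ``len(t)``.
    """
    if len(sites) < 3:
        raise InsufficientDataError(f"need >= 3 observations, got {len(sites)}")
    improvement = outcomes.set_index(outcomes["patient_id"].astype(str))["improvement"]
    y = np.array([float(improvement.loc[s.patient_id]) for s in sites])
    centers = np.array([s.center for s in sites])
    radii = np.array([s.radius for s in sites])

    r_values = np.full(len(t), np.nan)
    y_sd = y.std()
    if y_sd == 0:
        return r_values
    yc = y - y.mean()
    for i, sl in enumerate(t):
        pts = resample_polyline(sl, resample_step_mm)
        # fraction of points of streamline i inside each site's sphere
        d2 = ((pts[None, :, :] - centers[:, None, :]) ** 2).sum(axis=2)
        overlap = (d2 <= radii[:, None] ** 2).mean(axis=1)
        if binary:
            overlap = (overlap > 0).astype(float)
        if overlap.std() == 0:
            continue
        oc = overlap - overlap.mean()
        r_values[i] = float((oc * yc).sum() / math.sqrt((oc**2).sum() * (yc**2).sum()))
    return r_values


def correlation_sidecar(r_values: np.ndarray) -> pd.DataFrame:
    """Sidecar table (streamline index, r) for export next to a TRK/TCK."""
    return pd.DataFrame({"streamline": np.arange(len(r_values)), "r": r_values})
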