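"""Normative-connectome streamline selection and cortical fingerprints.

Streamlines are selected from a (normative) tractogram by small spherical
ROIs around stimulation coordinates; each group's union of selections is
rendered as a terminal-density "fingerprint", from which local maxima
(peak cortical penetrations) are extracted and two groups' fingerprints are
compared for conjugation regions — places where both penetrate the same
cortex.  A minimal ASCII mesh reader and trilinear sampler support projecting
fingerprints onto a gray/white transition surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from vatmap.errors import FormatError, GeometryError, ParameterError
from vatmap.density_mapping import RasterConfig, terminal_density
from vatmap.geometry import resample_polyline
from vatmap.spatial_io import DensityVolume, Tractogram
from vatmap.vat_model import StimulationSite

__all__ = [
    "Peak",
    "ConjugationReport",
    "select_by_sphere",
    "group_fingerprint",
    "find_peaks",
    "conjugation",
    "project_to_surface",
    "read_ascii_mesh",
]

logger = logging.getLogger(__name__)

#: default ROI diameter (mm) for streamline selection around a coordinate
DEFAULT_ROI_DIAMETER_MM = 2.0
#: resampling step (mm) applied before the ROI distance test, so selection is
#: robust to sparse polylines
ROI_RESAMPLE_STEP_MM = 0.5


@dataclass(frozen=True)
class Peak:
    """A local maximum of a terminal-density image."""

    coordinate: tuple[float, float, float]
    value: float
    label: str = ""


@dataclass
class ConjugationReport:
    """Peaks of two fingerprints and their conjugations.

    A conjugation pairs one peak from each source lying within the pairing
    distance of each other and touching the supra-threshold overlap mask.
    """

    peaks_a: list[Peak]
    peaks_b: list[Peak]
    conjugations: list[tuple[Peak, Peak]]
    overlap_mask: DensityVolume


def select_by_sphere(
    t: Tractogram,
    center,
    diameter: float = DEFAULT_ROI_DIAMETER_MM,
    resample_step_mm: float = ROI_RESAMPLE_STEP_MM,
) -> Tractogram:
    """Streamlines with at least one resampled point inside a spherical ROI.

    ``diameter`` is the sphere diameter in mm (radius = diameter / 2).
    Selected streamlines keep their original point sequences; an empty
    selection is allowed.
    """
    if diameter <= 0:
        raise ParameterError(f"diameter must be > 0 mm, got {diameter}")
    center = np.asarray(center, dtype=np.float64)
    radius2 = (diameter / 2.0) ** 2
    selected = [
        s
        for s in t
        if (((resample_polyline(s, resample_step_mm) - center) ** 2).sum(axis=1) <= radius2).any()
    ]
    if not selected:
        return Tractogram([], space_tag=t.space_tag)
    return Tractogram([s.copy() for s in selected], space_tag=t.space_tag)


def group_fingerprint(
    t: Tractogram,
    sites: Sequence[StimulationSite],
    cfg: RasterConfig,
    roi_diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
) -> DensityVolume:
    """Terminal-density fingerprint of a group of stimulation sites.

    Takes the union of per-site ROI selections (each streamline counted once
    no matter how many sites select it) and renders its terminal density per
    ``cfg`` (1 mm grid with a 3 mm kernel in the reference analysis).
    """
    if len(sites) == 0:
        raise ParameterError("group_fingerprint needs at least one site")
    selected_ids: set[int] = set()
    for site in sites:
        sel_mask = _roi_membership(t, np.asarray(site.center), roi_diameter_mm)
        selected_ids.update(np.nonzero(sel_mask)[0].tolist())
    union = Tractogram([t.streamlines[i].copy() for i in sorted(selected_ids)], space_tag=t.space_tag)
    if len(union) == 0:
        logger.warning("group_fingerprint: no streamlines selected for any site")
    return terminal_density(union, cfg)


def _roi_membership(t: Tractogram, center: np.ndarray, diameter: float) -> np.ndarray:
    radius2 = (diameter / 2.0) ** 2
    return np.array(
        [
            (((resample_polyline(s, ROI_RESAMPLE_STEP_MM) - center) ** 2).sum(axis=1) <= radius2).any()
            for s in t
        ],
        dtype=bool,
    )


def find_peaks(v: DensityVolume, min_value: float, min_separation_mm: float = 0.0) -> list[Peak]:
    """Local maxima of a density volume, in world coordinates.

    A peak voxel is strictly greater than all of its 26 neighbors (boundary
    voxels compare against their existing neighbors) and has value
    >= ``min_value``.  Peaks closer than ``min_separation_mm`` are suppressed
    greedily keeping the larger (ties broken toward the lexicographically
    smallest index).  Result is sorted by value descending.
    """
    if min_value <= 0:
        raise ParameterError(f"min_value must be > 0, got {min_value}")
    if min_separation_mm < 0:
        raise ParameterError(f"min_separation_mm must be >= 0, got {min_separation_mm}")
    vals = v.values
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neighbor_max = ndimage.maximum_filter(vals, footprint=footprint, mode="constant", cval=-np.inf)
    is_peak = (vals > neighbor_max) & (vals >= min_value)
    idx = np.argwhere(is_peak)
    if idx.size == 0:
        return []
    peak_vals = vals[idx[:, 0], idx[:, 1], idx[:, 2]]
    # sort by value desc, ties by lexicographic index
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -peak_vals))
    idx = idx[order]
    peak_vals = peak_vals[order]
    coords = v.grid.voxel_to_world(idx)

    kept: list[int] = []
    for i in range(len(idx)):
        if all(
            np.linalg.norm(coords[i] - coords[j]) >= min_separation_mm for j in kept
        ):
            kept.append(i)
    return [
        Peak(coordinate=tuple(float(c) for c in coords[i]), value=float(peak_vals[i]))
        for i in kept
    ]


def conjugation(
    va: DensityVolume,
    vb: DensityVolume,
    threshold_quantile: float = 0.95,
    pairing_mm: float = 6.0,
    min_separation_mm: float = 0.0,
) -> ConjugationReport:
    """Overlap mask and paired peaks of two fingerprints on one grid.

    Each volume is thresholded at its own ``threshold_quantile`` (taken over
    its strictly positive voxels; a quantile over all voxels of a sparse
    fingerprint would collapse to zero); the overlap mask marks voxels
    supra-threshold in both.  Conjugations are pairs of peaks, one from each
    source, within ``pairing_mm`` of each other and inside or 26-adjacent to
    the mask.
    """
    if va.grid != vb.grid:
        raise GeometryError(f"fingerprints on different grids: {va.grid} vs {vb.grid}")
    if not (0.0 < threshold_quantile < 1.0):
        raise ParameterError(f"threshold_quantile must be in (0, 1), got {threshold_quantile}")

    thr_a = _positive_quantile(va.values, threshold_quantile)
    thr_b = _positive_quantile(vb.values, threshold_quantile)
    mask = (va.values >= thr_a) & (vb.values >= thr_b) if thr_a > 0 and thr_b > 0 else np.zeros(
        va.values.shape, dtype=bool
    )
    peaks_a = find_peaks(va, thr_a, min_separation_mm) if thr_a > 0 else []
    peaks_b = find_peaks(vb, thr_b, min_separation_mm) if thr_b > 0 else []

    near_mask = ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3), dtype=bool))
    pairs: list[tuple[Peak, Peak]] = []
    for pa in peaks_a:
        ia = va.grid.world_to_voxel(np.asarray(pa.coordinate))
        for pb in peaks_b:
            if np.linalg.norm(np.asarray(pa.coordinate) - np.asarray(pb.coordinate)) > pairing_mm:
                continue
            ib = vb.grid.world_to_voxel(np.asarray(pb.coordinate))
            if near_mask[tuple(ia)] or near_mask[tuple(ib)]:
                pairs.append((pa, pb))
    return ConjugationReport(
        peaks_a=peaks_a,
        peaks_b=peaks_b,
        conjugations=pairs,
        overlap_mask=DensityVolume(va.grid, mask.astype(np.float64)),
    )


def _positive_quantile(values: np.ndarray, q: float) -> float:
    pos = values[values > 0]
    if pos.size == 0:
        return 0.0
    return float(np.quantile(pos, q))


def project_to_surface(v: DensityVolume, vertices: np.ndarray) -> np.ndarray:
    """Trilinear sample of a volume at mesh vertices (world mm).

    Vertices outside the grid bounding box get 0 with a logged warning.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    if vertices.size == 0:
        raise ParameterError("empty mesh: no vertices to project onto")
    if vertices.ndim != 2 or vertices.shape[1] != 3:
        raise ParameterError(f"vertices must be (n, 3) world mm, got shape {vertices.shape}")
    cont = v.grid.world_to_voxel_continuous(vertices)
    dims = np.asarray(v.grid.dims)
    outside = np.any((cont < 0) | (cont > dims - 1), axis=1)
    if outside.any():
        logger.warning("project_to_surface: %d vertices outside the grid get 0", int(outside.sum()))
    sampled = ndimage.map_coordinates(v.values, cont.T, order=1, mode="constant", cval=0.0)
    sampled[outside] = 0.0
    return sampled


def read_ascii_mesh(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read the package's documented ASCII mesh format.

    Line 1: ``n_vertices n_faces``; then ``n_vertices`` lines of ``x y z``
    (world mm) and ``n_faces`` lines of three 0-based vertex indices.
    Returns ``(vertices (n,3) float, faces (m,3) int)``.
    """
    path = Path(path)
    tokens = path.read_text().split()
    if len(tokens) < 2:
        raise FormatError(f"{path}: missing mesh header")
    try:
        nv, nf = int(tokens[0]), int(tokens[1])
        body = np.asarray(tokens[2:], dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed mesh: {exc}") from exc
    if body.size != 3 * nv + 3 * nf:
        raise FormatError(f"{path}: expected {3 * nv + 3 * nf} numbers, found {body.size}")
    vertices = body[: 3 * nv].reshape(nv, 3)
    faces = body[3 * nv :].reshape(nf, 3).astype(int)
    if nf and (faces.min() < 0 or faces.max() >= nv):
        raise FormatError(f"{path}: face indices out of range")
    return vertices, faces


def peaks_to_frame(report: ConjugationReport):
    """Flat TSV-ready table of peaks from both sources with pairing flags."""
    import pandas as pd

    paired_a = {id(pa) for pa, _ in report.conjugations}
    paired_b = {id(pb) for _, pb in report.conjugations}
    rows = []
    for src, peaks, paired in (("A", report.peaks_a, paired_a), ("B", report.peaks_b, paired_b)):
        for p in peaks:
            rows.append(
                {
                    "source": src,
                    "label": p.label,
                    "x_mm": p.coordinate[0],
                    "y_mm": p.coordinate[1],
                    "z_mm": p.coordinate[2],
                    "value": p.value,
                    "conjugated": id(p) in paired,
                }
            )
    return pd.DataFrame(rows)
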