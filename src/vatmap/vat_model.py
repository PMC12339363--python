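"""Analytic volume-of-activated-tissue (VAT) model.

The VAT around an active contact is modelled as a sphere whose radius follows
from Coulomb's law for a point source in a homogeneous medium: the electric
field at distance r from a contact driving current I through tissue of
conductivity sigma is E = I / (4 pi sigma r^2), so the distance at which the
field drops to the axonal activation threshold E_thr is

    r = sqrt( I / (4 pi sigma E_thr) ).

Units are pinned in exactly one place: the public API takes current in mA and
the threshold in V/mm (the conventions of the clinical literature); conversion
to SI happens inside :func:`activation_radius` and nowhere else, and the
result comes back in mm.  Deliberately simple — no tissue anisotropy, no
electrode geometry, no pulse-width dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from vatmap.errors import ParameterError, ValidationError

__all__ = ["VatParams", "StimulationSite", "activation_radius", "effective_center", "build_sites"]


@dataclass(frozen=True)
class VatParams:
    """Tissue and activation constants of the spherical VAT model.

    sigma : tissue conductivity in S/m (default 0.1)
    e_threshold : activation threshold in V/mm (default 0.2)
    """

    sigma: float = 0.1
    e_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ParameterError(f"sigma must be > 0 S/m, got {self.sigma}")
        if self.e_threshold <= 0:
            raise ParameterError(f"e_threshold must be > 0 V/mm, got {self.e_threshold}")


@dataclass(frozen=True)
class StimulationSite:
    """Effective stimulation site of one patient hemisphere.

    ``center`` is the geometric center of the active contacts (world mm);
    ``radius`` is the activation radius in mm implied by ``current`` (mA).
    """

    patient_id: str
    hemisphere: str
    center: tuple[float, float, float]
    current: float
    radius: float


def activation_radius(current_ma: float, params: VatParams = VatParams()) -> float:
    """Activation radius in mm for a contact current in mA.

    Evaluates r = sqrt(I / (4 pi sigma E)) in SI units (I in A, E in V/m) and
    converts back to mm.  Monotone increasing with r(4 I) = 2 r(I); zero
    current gives radius zero.
    """
    if current_ma < 0:
        raise ParameterError(f"current must be >= 0 mA, got {current_ma}")
    current_a = current_ma * 1e-3
    e_vpm = params.e_threshold * 1e3  # V/mm -> V/m
    r_m = math.sqrt(current_a / (4.0 * math.pi * params.sigma * e_vpm))
    return r_m * 1e3


def effective_center(active_contacts: np.ndarray) -> np.ndarray:
    """Geometric center (arithmetic mean) of one or more contact coordinates."""
    pts = np.atleast_2d(np.asarray(active_contacts, dtype=np.float64))
    if pts.size == 0:
        raise ParameterError("effective_center requires at least one contact")
    if pts.shape[1] != 3:
        raise ParameterError(f"contacts must be (n, 3) world-mm points, got shape {pts.shape}")
    return pts.mean(axis=0)


REQUIRED_CONTACT_COLUMNS = ("patient_id", "hemisphere", "x_mm", "y_mm", "z_mm", "current_mA")


def build_sites(contacts: pd.DataFrame, params: VatParams = VatParams()) -> list[StimulationSite]:
    """One :class:`StimulationSite` per patient-hemisphere from a contact table.

    The table has one row per active contact (columns
    ``patient_id, hemisphere, x_mm, y_mm, z_mm, current_mA``); multiple active
    contacts on one lead are averaged to their geometric center.  Every
    patient must appear with both hemispheres.
    """
    missing = [c for c in REQUIRED_CONTACT_COLUMNS if c not in contacts.columns]
    if missing:
        raise ValidationError(f"contact table is missing columns: {missing}")
    bad_hemi = set(contacts["hemisphere"].unique()) - {"L", "R"}
    if bad_hemi:
        raise ValidationError(f"hemisphere values must be 'L' or 'R', found {sorted(bad_hemi)}")

    incomplete = []
    for pid, group in contacts.groupby("patient_id", sort=True):
        if set(group["hemisphere"].unique()) != {"L", "R"}:
            incomplete.append(pid)
    if incomplete:
        raise ValidationError(f"patients missing a hemisphere: {incomplete}")

    sites: list[StimulationSite] = []
    for (pid, hemi), group in contacts.groupby(["patient_id", "hemisphere"], sort=True):
        center = effective_center(group[["x_mm", "y_mm", "z_mm"]].to_numpy())
        currents = group["current_mA"].to_numpy(dtype=np.float64)
        if np.any(currents <= 0):
            raise ValidationError(f"patient {pid} hemisphere {hemi}: current must be > 0 mA")
        current = float(currents.mean())
        sites.append(
            StimulationSite(
                patient_id=str(pid),
                hemisphere=str(hemi),
                center=tuple(center),
                current=current,
                radius=activation_radius(current, params),
            )
        )
    return sites


def sites_to_frame(sites: list[StimulationSite]) -> pd.DataFrame:
    """Export sites as a flat table (CSV-ready)."""
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in sites],
            "hemisphere": [s.hemisphere for s in sites],
            "x_mm": [s.center[0] for s in sites],
            "y_mm": [s.center[1] for s in sites],
            "z_mm": [s.center[2] for s in sites],
            "current_mA": [s.current for s in sites],
            "radius_mm": [s.radius for s in sites],
        }
    )
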