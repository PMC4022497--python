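"""The eight energy-centrality features of a protein-protein interface.

The central quantity is the relationship between each interfacial residue's
alanine-substitution energy (ΔΔG, kcal/mol) and its distance Δr (Å) from
the Center of Interface (CoI), the unweighted mean of the interfacial Cα
positions.  An ordinary least-squares line ΔΔG = slope·Δr + intercept
summarises the radial organisation of the interface: functionally linked
interfaces tend to have a positive intercept and negative slope (hotter
centre), while incidental contacts show little radial correlation.

Features computed per interface:

===========  =================================================================
slope_ddg    slope of the ΔΔG-vs-Δr regression, kcal/mol/Å
intcpt_ddg   its intercept (extrapolated ΔΔG at the CoI), kcal/mol
r2_ddg       coefficient of determination of the fit
sum_ddg      Σ ΔΔG over scanned residues, kcal/mol
avg_ddg      mean ΔΔG over scanned residues, kcal/mol
n_total      total number of interfacial residues (scanned or not)
n_hot        residues with ΔΔG strictly greater than +1 kcal/mol
frac_hot     n_hot / n_total
===========  =================================================================

``n_total`` counts every interface member, including Gly/Pro and residues
the scan did not cover; the energy terms (sum/avg/#hot and the regression)
use only residues with a ΔΔG present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateGeometryError, InsufficientDataError
from .io import Interface

HOT_THRESHOLD = 1.0  # kcal/mol, strict inequality

#: Fixed column order used in every feature table.
FEATURE_NAMES = [
    "slope_ddg",
    "intcpt_ddg",
    "r2_ddg",
    "sum_ddg",
    "avg_ddg",
    "n_total",
    "n_hot",
    "frac_hot",
]


@dataclass
class GeometryResult:
    """Center of Interface and per-residue radial distances (Å)."""

    coi: np.ndarray
    dr_per_residue: np.ndarray


@dataclass
class InterfaceFeatures:
    slope_ddg: float
    intcpt_ddg: float
    r2_ddg: float
    sum_ddg: float
    avg_ddg: float
    n_total: int
    n_hot: int
    frac_hot: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


@dataclass
class ProjectionResult:
    """Interface residues in their own principal plane, for plotting."""

    coords: np.ndarray  # (n, 2) scores on the first two geometric axes
    ddg_normalized: np.ndarray  # ΔΔG / max|ΔΔG|; NaN where ΔΔG missing
    axes: np.ndarray  # (3, 2) eigenvectors of the Cα scatter
    second_axis_defined: bool


def center_of_interface(interface: Interface) -> GeometryResult:
    """CoI (unweighted Cα mean over ALL interfacial residues) and each Δr."""
    if len(interface) == 0:
        raise InsufficientDataError("empty interface has no center")
    ca = np.array([ir.residue.ca_xyz for ir in interface.residues], dtype=float)
    coi = ca.mean(axis=0)
    dr = np.linalg.norm(ca - coi, axis=1)
    for ir, d in zip(interface.residues, dr):
        ir.dr = float(d)
    return GeometryResult(coi=coi, dr_per_residue=dr)


def fit_energy_centrality(
    interface: Interface, geometry: GeometryResult | None = None
) -> tuple[float, float, float]:
    """OLS fit of ΔΔG against Δr; returns (slope, intercept, r²).

    Uses only residues with a ΔΔG present; requires at least three of them.
    A response with zero variance yields slope 0 and r² defined as 0.
    """
    if geometry is None:
        geometry = center_of_interface(interface)
    pairs = [
        (d, ir.ddg)
        for d, ir in zip(geometry.dr_per_residue, interface.residues)
        if ir.ddg is not None
    ]
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"regression needs ≥3 residues with ΔΔG, got {len(pairs)}"
        )
    dr = np.array([p[0] for p in pairs])
    ddg = np.array([p[1] for p in pairs])
    if np.ptp(dr) == 0.0:
        raise DegenerateGeometryError("all residues equidistant from the CoI")

    slope, intercept = np.polyfit(dr, ddg, 1)
    ss_tot = float(np.sum((ddg - ddg.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0, float(ddg.mean()), 0.0
    resid = ddg - (slope * dr + intercept)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    # guard tiny negative round-off on exact fits
    r2 = min(1.0, max(0.0, r2))
    return float(slope), float(intercept), r2


def compute_features(interface: Interface) -> InterfaceFeatures:
    """All eight features for one interface (post exclusion filters)."""
    geometry = center_of_interface(interface)
    slope, intercept, r2 = fit_energy_centrality(interface, geometry)
    ddg = np.array([ir.ddg for ir in interface.residues if ir.ddg is not None])
    n_total = len(interface)
    n_hot = int(np.sum(ddg > HOT_THRESHOLD))
    return InterfaceFeatures(
        slope_ddg=slope,
        intcpt_ddg=intercept,
        r2_ddg=r2,
        sum_ddg=float(ddg.sum()),
        avg_ddg=float(ddg.mean()),
        n_total=n_total,
        n_hot=n_hot,
        frac_hot=n_hot / n_total,
    )


def plot_projection(
    interface: Interface, normalize_distances: bool = False
) -> ProjectionResult:
    """Project interface residues onto the principal plane of their Cα scatter.

    The axes are the leading eigenvectors of the (uncentered-covariance of
    the centered) Cα coordinates, so the interface lies flat in the plot
    plane.  ΔΔG values are scaled by max|ΔΔG| into [-1, 1]; with
    ``normalize_distances`` the in-plane coordinates are scaled by the
    largest Δr as well.
    """
    if len(interface) < 3:
        raise InsufficientDataError("projection needs ≥3 residues")
    ca = np.array([ir.residue.ca_xyz for ir in interface.residues], dtype=float)
    centered = ca - ca.mean(axis=0)
    # SVD of the centered cloud: right singular vectors = covariance eigenvectors
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    axes = vt[:2].T
    coords = centered @ axes
    second_defined = bool(svals[1] > 1e-9 * max(svals[0], 1.0))

    ddg = np.array(
        [np.nan if ir.ddg is None else ir.ddg for ir in interface.residues], dtype=float
    )
    max_abs = np.nanmax(np.abs(ddg)) if np.any(np.isfinite(ddg)) else np.nan
    ddg_norm = ddg / max_abs if max_abs and np.isfinite(max_abs) and max_abs > 0 else ddg

    if normalize_distances:
        dr = np.linalg.norm(centered, axis=1)
        max_dr = dr.max()
        if max_dr > 0:
            coords = coords / max_dr

    return ProjectionResult(
        coords=coords,
        ddg_normalized=ddg_norm,
        axes=axes,
        second_axis_defined=second_defined,
    )
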