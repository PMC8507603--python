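"""Closed-form / quadrature free-energy profiles for the mean-field system.

These serve as independent ground truth for the umbrella/WHAM machinery.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from ..constants import kt
from .bilayer import BilayerModel
from .body import ProteinBody
from .energy import mean_field_bead_energy, _surface_terms
from .params import SimParams


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform directions on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def fixed_orientation_energy(
    body: ProteinBody,
    bilayer: BilayerModel,
    params: SimParams,
    z_grid: np.ndarray,
    orientation: np.ndarray | None = None,
) -> np.ndarray:
    """Mean-field U(z) for a locked orientation (identity by default)."""
    rot = Rotation.identity() if orientation is None else Rotation.from_quat(orientation)
    bead_dz = rot.apply(body.bead_positions)[:, 2]
    dz = np.asarray(z_grid)[:, None] + bead_dz[None, :] - bilayer.plane_z
    sigma = bilayer.surface_charge_density
    u = _surface_terms(dz, params)
    u = u + mean_field_bead_energy(dz, body.bead_charges[None, :], sigma, params)
    return u.sum(axis=1)


def analytic_pmf(
    body: ProteinBody,
    bilayer: BilayerModel,
    params: SimParams,
    z_grid: np.ndarray,
    orientation: np.ndarray | None = None,
    n_orientations: int = 0,
) -> np.ndarray:
    """Exact mean-field free-energy profile G(z), anchored to 0 at max z.

    With ``orientation`` given (or ``n_orientations`` = 0) the profile is
    the fixed-orientation potential.  Otherwise the orientation average

        G(z) = -kT ln < exp(-U(z, omega)/kT) >_omega

    is taken by quadrature over a deterministic sphere lattice of membrane
    normals (the plane energy depends on orientation only through the
    body-frame direction of the lab z-axis).
    """
    z_grid = np.asarray(z_grid, dtype=float)
    if len(z_grid) > 1 and np.any(np.diff(z_grid) <= 0):
        raise ValueError("z_grid must be strictly increasing")
    if bilayer.mode != "mean-field":
        raise ValueError("analytic_pmf requires a mean-field bilayer")
    kbt = kt(params.temperature)
    if orientation is not None or n_orientations == 0:
        g = fixed_orientation_energy(body, bilayer, params, z_grid, orientation)
    else:
        axes = _fibonacci_sphere(n_orientations)  # lab z-axis in body frame
        sigma = bilayer.surface_charge_density
        # bead heights: z + p_i . axis  -> (n_orient, n_z, n_beads)
        proj = body.bead_positions @ axes.T  # (n_beads, n_orient)
        dz = (
            z_grid[None, :, None]
            + proj.T[:, None, :]
            - bilayer.plane_z
        )
        u = _surface_terms(dz, params) + mean_field_bead_energy(
            dz, body.bead_charges[None, None, :], sigma, params
        )
        u_tot = u.sum(axis=2)  # (n_orient, n_z)
        from scipy.special import logsumexp

        g = -kbt * (logsumexp(-u_tot / kbt, axis=0) - np.log(n_orientations))
    return g - g[-1]
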