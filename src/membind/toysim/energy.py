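"""Toy energetics: screened Coulomb bead-lipid interactions, mean-field
charged plane, soft wall, and generic surface adhesion.

The mean-field per-bead attraction is the exact plane integral of the
screened-Coulomb pair energy:

    U_i(z) = 2 pi * sigma_q * q_i * B * lambda_D * exp(-z / lambda_D)

with z the bead height above the plane, sigma_q the upper-leaflet charge
density, and B the Bjerrum-like prefactor of the pair energy
q*Q*B*exp(-r/lambda_D)/r.
"""

from __future__ import annotations

import numpy as np

from .params import SimParams
from .state import SystemState

_TAGGABLE_SPECIES = "PIP2"


def minimum_image(dxy: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Wrap xy displacement(s) to the nearest periodic image."""
    return dxy - box_xy * np.round(dxy / box_xy)


def _check_lambda(lam):
    if lam is not None and not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")


def _effective_lipid_charges(state: SystemState, lam, tagged_lipid) -> np.ndarray:
    from ..errors import InvalidTagError

    charges = state.bilayer.lipid_charges.copy()
    if tagged_lipid is not None:
        if state.bilayer.lipid_species[tagged_lipid] != _TAGGABLE_SPECIES:
            raise InvalidTagError(
                f"tagged lipid {tagged_lipid} is "
                f"{state.bilayer.lipid_species[tagged_lipid]}, expected {_TAGGABLE_SPECIES}"
            )
        if lam is not None:
            charges[tagged_lipid] *= 1.0 - lam
    return charges


def _surface_terms(dz: np.ndarray, params: SimParams) -> np.ndarray:
    """Per-bead wall + adhesion energy as a function of height above the plane."""
    wall = params.wall_stiffness * np.exp(-dz / params.wall_decay)
    adhesion = -params.surface_affinity * np.exp(-dz / params.affinity_decay)
    return wall + adhesion


def mean_field_bead_energy(
    dz: np.ndarray, q: np.ndarray, sigma: float, params: SimParams
) -> np.ndarray:
    """Electrostatic plane energy per bead; dz and q broadcast together.

    This is the exact plane integral of the soft-core pair kernel:
    z is replaced by z_eff = sqrt(z^2 + core_radius^2).
    """
    pref = 2.0 * np.pi * sigma * params.bjerrum_prefactor * params.debye_length
    z_eff = np.sqrt(dz**2 + params.core_radius**2)
    return pref * q * np.exp(-z_eff / params.debye_length)


def _mean_field_sigma(state: SystemState, lam, tagged_lipid) -> float:
    bilayer = state.bilayer
    sigma = bilayer.surface_charge_density
    if lam is not None:
        # discharging one tagged head group in the mean field
        if bilayer.species_counts.get(_TAGGABLE_SPECIES, 0) < 1:
            from ..errors import InvalidTagError

            raise InvalidTagError("no PIP2 present to tag in mean-field mode")
        q_tag = bilayer.species_charges[_TAGGABLE_SPECIES]
        sigma = sigma - lam * q_tag / bilayer.area
    return sigma


def potential_energy(
    state: SystemState,
    params: SimParams,
    lam: float | None = None,
    tagged_lipid: int | None = None,
) -> float:
    """Total potential energy of the configuration, kJ/mol.

    ``lam`` scales the tagged lipid's head charge by (1 - lam)
    (alchemical discharge of one PIP2 head group).
    """
    _check_lambda(lam)
    beads = state.bead_lab_positions()
    dz = beads[:, 2] - state.bilayer.plane_z
    energy = float(_surface_terms(dz, params).sum())
    if state.bilayer.mode == "mean-field":
        sigma = _mean_field_sigma(state, lam, tagged_lipid)
        energy += float(
            mean_field_bead_energy(dz, state.body.bead_charges, sigma, params).sum()
        )
        return energy
    charges = _effective_lipid_charges(state, lam, tagged_lipid)
    energy += _pair_energy_sum(
        beads, state.body.bead_charges, state.bilayer.lipid_xy, charges, state, params
    )
    return energy


def _pair_energy_sum(beads, bead_q, lipid_xy, lipid_q, state, params) -> float:
    active_b = np.nonzero(bead_q)[0]
    active_l = np.nonzero(lipid_q)[0]
    if len(active_b) == 0 or len(active_l) == 0:
        return 0.0
    b = beads[active_b]
    dxy = minimum_image(
        b[:, None, :2] - lipid_xy[active_l][None, :, :], state.bilayer.box_xy
    )
    dz = b[:, 2] - state.bilayer.plane_z
    r = np.sqrt(
        (dxy**2).sum(axis=2) + dz[:, None] ** 2 + params.core_radius**2
    )
    u = (
        params.bjerrum_prefactor
        * bead_q[active_b][:, None]
        * lipid_q[active_l][None, :]
        * np.exp(-r / params.debye_length)
        / r
    )
    return float(u.sum())


def forces_and_torque(
    state: SystemState,
    params: SimParams,
    lam: float | None = None,
    tagged_lipid: int | None = None,
    beads: np.ndarray | None = None,
):
    """(F_com (3,), torque (3,), F_lipid (n,2)) from the toy potential.

    The torque is about the body COM.  Lipid forces are the xy reaction
    forces on explicit upper-leaflet head groups (zeros in mean-field mode).
    ``beads`` may carry precomputed lab-frame bead positions.
    """
    _check_lambda(lam)
    if beads is None:
        beads = state.bead_lab_positions()
    dz = beads[:, 2] - state.bilayer.plane_z
    n = len(beads)
    f_beads = np.zeros((n, 3))
    # wall (repulsive, +z) and adhesion (attractive, -z)
    f_beads[:, 2] += (
        params.wall_stiffness / params.wall_decay * np.exp(-dz / params.wall_decay)
    )
    f_beads[:, 2] -= (
        params.surface_affinity
        / params.affinity_decay
        * np.exp(-dz / params.affinity_decay)
    )
    if state.bilayer.mode == "mean-field":
        sigma = _mean_field_sigma(state, lam, tagged_lipid)
        u = mean_field_bead_energy(dz, state.body.bead_charges, sigma, params)
        z_eff = np.sqrt(dz**2 + params.core_radius**2)
        # -dU/dz for U ~ exp(-z_eff/lD)
        f_beads[:, 2] += u * dz / z_eff / params.debye_length
        f_lipids = np.zeros((0, 2))
    else:
        charges = _effective_lipid_charges(state, lam, tagged_lipid)
        f_lipids = np.zeros((len(charges), 2))
        bead_q = state.body.bead_charges
        active_b = np.nonzero(bead_q)[0]
        active_l = np.nonzero(charges)[0]
        if len(active_b) and len(active_l):
            b = beads[active_b]
            dxy = minimum_image(
                b[:, None, :2] - state.bilayer.lipid_xy[active_l][None, :, :],
                state.bilayer.box_xy,
            )
            dzb = b[:, 2] - state.bilayer.plane_z
            r = np.sqrt(
                (dxy**2).sum(axis=2)
                + dzb[:, None] ** 2
                + params.core_radius**2
            )
            u = (
                params.bjerrum_prefactor
                * bead_q[active_b][:, None]
                * charges[active_l][None, :]
                * np.exp(-r / params.debye_length)
                / r
            )
            # F_bead = U * (1/lambda_D + 1/r_eff) * vec / r_eff
            mag_over_r = u * (1.0 / params.debye_length + 1.0 / r) / r
            fx = mag_over_r * dxy[:, :, 0]
            fy = mag_over_r * dxy[:, :, 1]
            fz = mag_over_r * dzb[:, None]
            f_beads[active_b, 0] += fx.sum(axis=1)
            f_beads[active_b, 1] += fy.sum(axis=1)
            f_beads[active_b, 2] += fz.sum(axis=1)
            np.add.at(f_lipids[:, 0], active_l, -fx.sum(axis=0))
            np.add.at(f_lipids[:, 1], active_l, -fy.sum(axis=0))
    f_com = f_beads.sum(axis=0)
    torque = np.cross(beads - state.body_com, f_beads).sum(axis=0)
    return f_com, torque, f_lipids


def energy_vs_z(
    state: SystemState,
    params: SimParams,
    z_grid: np.ndarray,
    lam: float | None = None,
    tagged_lipid: int | None = None,
) -> np.ndarray:
    """Potential energy as the body COM is translated along z.

    Orientation and explicit lipids are frozen at their current values;
    ``z_grid`` gives COM heights (lab frame).  Vectorized over the grid.
    """
    _check_lambda(lam)
    z_grid = np.asarray(z_grid, dtype=float)
    rot_beads = state.rotation.apply(state.body.bead_positions)
    bead_dz0 = rot_beads[:, 2] - state.bilayer.plane_z  # offset per bead at com z=plane
    dz = z_grid[:, None] + bead_dz0[None, :]  # (g, n) bead heights above plane
    u = _surface_terms(dz, params).sum(axis=1)
    if state.bilayer.mode == "mean-field":
        sigma = _mean_field_sigma(state, lam, tagged_lipid)
        u += mean_field_bead_energy(
            dz, state.body.bead_charges[None, :], sigma, params
        ).sum(axis=1)
        return u
    charges = _effective_lipid_charges(state, lam, tagged_lipid)
    bead_q = state.body.bead_charges
    active_b = np.nonzero(bead_q)[0]
    active_l = np.nonzero(charges)[0]
    if len(active_b) == 0 or len(active_l) == 0:
        return u
    bxy = rot_beads[active_b, :2] + state.body_com[:2]
    dxy = minimum_image(
        bxy[:, None, :] - state.bilayer.lipid_xy[active_l][None, :, :],
        state.bilayer.box_xy,
    )
    d2 = (dxy**2).sum(axis=2)  # (nb, nl)
    qq = params.bjerrum_prefactor * np.outer(bead_q[active_b], charges[active_l])
    # chunk over the grid to bound memory: (chunk, nb, nl)
    out = np.empty(len(z_grid))
    chunk = max(1, int(2e6 / max(1, d2.size)))
    for s in range(0, len(z_grid), chunk):
        dzc = dz[s : s + chunk][:, active_b]
        r = np.sqrt(
            d2[None, :, :] + dzc[:, :, None] ** 2 + params.core_radius**2
        )
        out[s : s + chunk] = (
            qq[None, :, :] * np.exp(-r / params.debye_length) / r
        ).sum(axis=(1, 2))
    return u + out
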