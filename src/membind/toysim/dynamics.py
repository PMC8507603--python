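"""Overdamped Langevin dynamics of the rigid body and explicit lipids.

Diffusion coefficients in :class:`SimParams` are defined at the reference
temperature of 323 K; mobilities are held fixed, so the effective noise
amplitude scales with the simulation temperature (and vanishes at T = 0).
"""

from __future__ import annotations

import numpy as np

from ..constants import KB
from ..errors import IntegrationInstabilityError
from .energy import forces_and_torque
from .params import SimParams
from .state import Frame, SystemState, Trajectory

#: temperature at which SimParams diffusion coefficients are defined
REFERENCE_TEMPERATURE = 323.0


def _quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    """Unit quaternion (x, y, z, w) for a rotation vector."""
    angle = np.sqrt(v @ v)
    if angle < 1e-12:
        return np.array([0.5 * v[0], 0.5 * v[1], 0.5 * v[2], 1.0])
    s = np.sin(0.5 * angle) / angle
    return np.array([v[0] * s, v[1] * s, v[2] * s, np.cos(0.5 * angle)])


def _quat_mult(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b for (x, y, z, w) quaternions."""
    ax, ay, az, aw = a
    bx, by, bz, bw = b
    return np.array(
        [
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
            aw * bw - ax * bx - ay * by - az * bz,
        ]
    )


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    x, y, z, w = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def simulate(
    state: SystemState,
    params: SimParams,
    n_steps: int,
    record_every: int = 10,
    use_upper_wall: bool = False,
    z_restraint: tuple[float, float] | None = None,
    lam: float | None = None,
    tagged_lipid: int | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Propagate the system and return a trajectory (initial frame included).

    ``z_restraint`` is an optional harmonic bias (center_nm, k_kJ/mol/nm^2)
    on the body COM z; ``use_upper_wall`` applies the one-sided harmonic
    wall at ``params.upper_wall_distance`` above the bilayer plane.
    Reproducible from ``params.seed`` (or an explicit ``rng``).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dt = params.timestep
    kt_ref = KB * REFERENCE_TEMPERATURE
    kt_sim = KB * params.temperature
    mu_t = params.diffusion_translation / kt_ref
    mu_r = params.diffusion_rotation / kt_ref
    mu_l = params.diffusion_lipid / kt_ref
    sig_t = np.sqrt(2.0 * mu_t * kt_sim * dt)
    sig_r = np.sqrt(2.0 * mu_r * kt_sim * dt)
    sig_l = np.sqrt(2.0 * mu_l * kt_sim * dt)
    max_step = 0.5 * params.debye_length
    body_pos = state.body.bead_positions
    r_max = float(np.linalg.norm(body_pos, axis=1).max())

    work = state.copy()
    explicit = work.bilayer.mode == "explicit-lipids"
    com = work.body_com.copy()
    quat = work.body_orientation.copy()
    rmat = _quat_to_matrix(quat)
    t = work.time
    plane_z = work.bilayer.plane_z
    frames = [
        Frame(
            time=t,
            body_com=com.copy(),
            body_orientation=quat.copy(),
            lipid_xy=work.bilayer.lipid_xy.copy() if explicit else None,
        )
    ]
    for step in range(n_steps):
        beads = body_pos @ rmat.T + com
        work.body_com = com
        f_com, torque, f_lip = forces_and_torque(
            work, params, lam=lam, tagged_lipid=tagged_lipid, beads=beads
        )
        dz_plane = com[2] - plane_z
        if use_upper_wall and dz_plane > params.upper_wall_distance:
            f_com[2] -= params.upper_wall_stiffness * (
                dz_plane - params.upper_wall_distance
            )
        if z_restraint is not None:
            center, k = z_restraint
            f_com[2] -= k * (com[2] - center)

        drift_t = mu_t * f_com * dt
        drift_r = mu_r * torque * dt
        if np.sqrt(drift_t @ drift_t) + np.sqrt(drift_r @ drift_r) * r_max > max_step:
            raise IntegrationInstabilityError(
                f"step {step}: deterministic displacement exceeds "
                f"0.5*debye_length ({max_step:.3f} nm); reduce timestep"
            )
        com = com + drift_t + sig_t * rng.standard_normal(3)
        rotvec = drift_r + sig_r * rng.standard_normal(3)
        if rotvec.any():
            quat = _quat_mult(_quat_from_rotvec(rotvec), quat)
            quat /= np.sqrt(quat @ quat)
            rmat = _quat_to_matrix(quat)
        if explicit and len(f_lip):
            drift_l = mu_l * f_lip * dt
            if np.abs(drift_l).max(initial=0.0) > max_step:
                raise IntegrationInstabilityError(
                    f"step {step}: lipid drift exceeds 0.5*debye_length"
                )
            xy = (
                work.bilayer.lipid_xy
                + drift_l
                + sig_l * rng.standard_normal(work.bilayer.lipid_xy.shape)
            )
            work.bilayer.lipid_xy = np.mod(xy, work.bilayer.box_xy)
        t += dt
        if (step + 1) % record_every == 0:
            frames.append(
                Frame(
                    time=t,
                    body_com=com.copy(),
                    body_orientation=quat.copy(),
                    lipid_xy=work.bilayer.lipid_xy.copy() if explicit else None,
                )
            )

    work.body_com = com
    work.body_orientation = quat
    work.time = t
    return Trajectory(
        body=state.body,
        bilayer=work.bilayer,
        frames=frames,
        frame_interval=record_every * dt,
        metadata={"seed": params.seed, "n_steps": n_steps},
    )
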