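"""System state, trajectories, and randomized initial placement."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .bilayer import BilayerModel
from .body import ProteinBody


@dataclass
class SystemState:
    """Pose of the rigid body above a bilayer at a point in time.

    ``body_orientation`` is a unit quaternion in scipy's (x, y, z, w)
    convention mapping body-frame to lab-frame coordinates.
    """

    body: ProteinBody
    bilayer: BilayerModel
    body_com: np.ndarray  # (3,) nm
    body_orientation: np.ndarray  # (4,) unit quaternion
    time: float = 0.0  # ps

    def __post_init__(self):
        self.body_com = np.asarray(self.body_com, dtype=float)
        self.body_orientation = np.asarray(self.body_orientation, dtype=float)
        norm = np.linalg.norm(self.body_orientation)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"orientation quaternion norm {norm} != 1")

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.body_orientation)

    def bead_lab_positions(self) -> np.ndarray:
        """(n, 3) bead coordinates in the lab frame."""
        return self.rotation.apply(self.body.bead_positions) + self.body_com

    def copy(self) -> "SystemState":
        import copy as _copy

        return SystemState(
            body=self.body,
            bilayer=_copy.deepcopy(self.bilayer),
            body_com=self.body_com.copy(),
            body_orientation=self.body_orientation.copy(),
            time=self.time,
        )


@dataclass
class Frame:
    """Compact per-frame record of a trajectory."""

    time: float
    body_com: np.ndarray
    body_orientation: np.ndarray
    lipid_xy: np.ndarray | None = None


@dataclass
class Trajectory:
    """Ordered frames sharing one body and one bilayer composition."""

    body: ProteinBody
    bilayer: BilayerModel  # composition/static geometry; per-frame lipid_xy in frames
    frames: list[Frame] = field(default_factory=list)
    frame_interval: float = 0.0  # ps
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        times = self.times
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def coms(self) -> np.ndarray:
        return np.array([f.body_com for f in self.frames])

    @property
    def quaternions(self) -> np.ndarray:
        return np.array([f.body_orientation for f in self.frames])

    def state_at(self, i: int) -> SystemState:
        """Reconstruct a full SystemState for frame ``i``."""
        f = self.frames[i]
        bilayer = self.bilayer
        if f.lipid_xy is not None:
            import copy as _copy

            bilayer = _copy.deepcopy(self.bilayer)
            bilayer.lipid_xy = f.lipid_xy.copy()
        return SystemState(
            body=self.body,
            bilayer=bilayer,
            body_com=f.body_com.copy(),
            body_orientation=f.body_orientation.copy(),
            time=f.time,
        )

    def bead_lab_positions(self, i: int) -> np.ndarray:
        f = self.frames[i]
        return (
            Rotation.from_quat(f.body_orientation).apply(self.body.bead_positions)
            + f.body_com
        )


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """Uniform quaternion on SO(3) (Shoemake subgroup algorithm)."""
    u1, u2, u3 = rng.uniform(size=3)
    q = np.array(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ]
    )
    return q / np.linalg.norm(q)


def init_system(
    body: ProteinBody,
    bilayer: BilayerModel,
    min_separation: float = 4.4,
    seed: int = 0,
) -> SystemState:
    """Place the body with a uniform random orientation above the bilayer.

    The COM height is chosen so that the lowest bead sits exactly
    ``min_separation`` above the bilayer plane; xy is uniform in the box.
    """
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    rng = np.random.default_rng(seed)
    quat = random_orientation(rng)
    rot = Rotation.from_quat(quat)
    bead_z = rot.apply(body.bead_positions)[:, 2]
    com_z = bilayer.plane_z + min_separation - bead_z.min()
    xy = rng.uniform(0.0, 1.0, size=2) * bilayer.box_xy
    return SystemState(
        body=body,
        bilayer=bilayer,
        body_com=np.array([xy[0], xy[1], com_z]),
        body_orientation=quat,
        time=0.0,
    )
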