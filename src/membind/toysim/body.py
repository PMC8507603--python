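"""Rigid multi-bead body representing a peripheral membrane-binding domain."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import DegenerateGeometryError


@dataclass
class ProteinBody:
    """A rigid body of labeled, charged beads in body-frame coordinates.

    The body frame has its center of mass at the origin; the reference
    orientation is the identity rotation.
    """

    bead_positions: np.ndarray  # (n, 3) nm, body frame
    bead_charges: np.ndarray  # (n,) elementary charges
    bead_labels: list[str]  # residue-class tag per bead
    reference_orientation: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )

    def __post_init__(self):
        self.bead_positions = np.asarray(self.bead_positions, dtype=float)
        self.bead_charges = np.asarray(self.bead_charges, dtype=float)
        n = len(self.bead_positions)
        if n < 4:
            raise DegenerateGeometryError(
                f"need >=4 beads for a well-defined orientation, got {n}"
            )
        if self.bead_charges.shape != (n,):
            raise ValueError("bead_charges length must match bead_positions")
        if len(self.bead_labels) != n:
            raise ValueError("bead_labels length must match bead_positions")
        # non-coplanar check: the bead cloud must span 3 dimensions
        centered = self.bead_positions - self.bead_positions.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 3:
            raise DegenerateGeometryError("beads are coplanar or collinear")
        # re-center so the body-frame COM sits exactly at the origin
        self.bead_positions = centered

    @property
    def n_beads(self) -> int:
        return len(self.bead_positions)

    @property
    def total_charge(self) -> float:
        return float(self.bead_charges.sum())

    def beads_with_label(self, label: str) -> np.ndarray:
        """Indices of beads carrying the given label."""
        return np.array(
            [i for i, lab in enumerate(self.bead_labels) if lab == label], dtype=int
        )

    def lab_positions(self, rotation: np.ndarray, com: np.ndarray) -> np.ndarray:
        """Bead coordinates in the lab frame for a given pose."""
        return self.bead_positions @ np.asarray(rotation).T + np.asarray(com)


def make_c2_like_body(
    n_ring: int = 6,
    height: float = 1.6,
    radius: float = 0.9,
    patch_charge: float = 2.0,
    top_charge: float = -1.0,
) -> ProteinBody:
    """Build a compact beta-sandwich-like test body.

    A ring of ``n_ring`` basic beads forms the membrane-binding face
    (label ``basic``), a neutral mid-section (``core``) and an acidic
    apex with terminus beads (``acidic``/``terminus``) sit above it.
    The binding face points along -z in the body frame.
    """
    positions = []
    charges = []
    labels = []
    # basic binding face at the bottom
    for k in range(n_ring):
        ang = 2 * np.pi * k / n_ring
        positions.append([radius * np.cos(ang), radius * np.sin(ang), -height / 2])
        charges.append(patch_charge)
        labels.append("basic")
    # neutral core
    for k in range(n_ring):
        ang = 2 * np.pi * (k + 0.5) / n_ring
        positions.append([0.8 * radius * np.cos(ang), 0.8 * radius * np.sin(ang), 0.0])
        charges.append(0.0)
        labels.append("core")
    # acidic apex + termini
    positions.append([0.0, 0.0, height / 2])
    charges.append(top_charge)
    labels.append("acidic")
    positions.append([0.3 * radius, 0.0, height / 2])
    charges.append(0.0)
    labels.append("terminus")
    positions.append([-0.3 * radius, 0.0, height / 2])
    charges.append(0.0)
    labels.append("terminus")
    return ProteinBody(
        bead_positions=np.array(positions),
        bead_charges=np.array(charges),
        bead_labels=labels,
    )
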