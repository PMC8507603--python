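"""Simulation parameters for the rigid-body Brownian-dynamics model."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass
class SimParams:
    """Overdamped-Langevin parameters; units nm, ps, kJ/mol, K, e.

    ``bjerrum_prefactor`` multiplies q_i*Q_j*exp(-reff/debye_length)/reff in
    the screened-Coulomb pair energy, with reff = sqrt(r^2 + core_radius^2)
    (a soft core keeps contact forces bounded).  ``surface_affinity`` is a generic
    (charge-independent) short-range attraction of every bead to the
    bilayer plane, standing in for non-electrostatic adhesion.
    """

    temperature: float = 323.0
    timestep: float = 5.0  # ps
    diffusion_translation: float = 5e-4  # nm^2/ps
    diffusion_rotation: float = 5e-4  # rad^2/ps
    diffusion_lipid: float = 5e-4  # nm^2/ps
    debye_length: float = 1.1  # nm
    core_radius: float = 0.3  # nm, soft-core softening of the pair kernel
    bjerrum_prefactor: float = 2.0  # kJ/mol nm e^-2
    wall_stiffness: float = 10.0  # kJ/mol, wall prefactor
    wall_decay: float = 0.25  # nm
    surface_affinity: float = 0.0  # kJ/mol per bead at contact
    affinity_decay: float = 1.1  # nm
    upper_wall_distance: float = 7.0  # nm
    upper_wall_stiffness: float = 50.0  # kJ/mol/nm^2
    seed: int = 0

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        positive = (
            "timestep",
            "diffusion_translation",
            "diffusion_rotation",
            "diffusion_lipid",
            "debye_length",
            "wall_stiffness",
            "wall_decay",
            "affinity_decay",
            "upper_wall_distance",
            "upper_wall_stiffness",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.surface_affinity < 0:
            raise ValueError("surface_affinity must be >= 0")
        if self.core_radius < 0:
            raise ValueError("core_radius must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(**d)
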