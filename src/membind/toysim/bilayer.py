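"""Planar bilayer model: explicit diffusing head groups or a mean-field charged plane."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidCompositionError, UnknownSpeciesError

#: default head-group charge per species (elementary charges)
DEFAULT_SPECIES_CHARGES = {"PC": 0.0, "PS": -1.0, "PIP2": -5.0}


@dataclass
class BilayerModel:
    """A flat bilayer at ``plane_z`` with a periodic xy box.

    In ``explicit-lipids`` mode the upper (protein-facing) leaflet carries
    explicit 2D head-group positions; the lower leaflet is implicit
    bookkeeping.  In ``mean-field`` mode only the upper-leaflet surface
    charge density enters the energetics.
    """

    box_xy: np.ndarray  # (2,) nm
    species_counts: dict[str, int]  # per-leaflet counts
    species_charges: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_CHARGES)
    )
    lipid_xy: np.ndarray | None = None  # (n, 2) upper-leaflet positions
    lipid_species: list[str] | None = None  # species per explicit lipid
    plane_z: float = 0.0
    mode: str = "explicit-lipids"

    def __post_init__(self):
        self.box_xy = np.asarray(self.box_xy, dtype=float)
        if self.box_xy.shape != (2,) or np.any(self.box_xy <= 0):
            raise ValueError("box_xy must be two positive lengths")
        for sp, cnt in self.species_counts.items():
            if cnt < 0:
                raise InvalidCompositionError(f"negative count for {sp}")
            if sp not in self.species_charges:
                raise UnknownSpeciesError(f"no charge defined for species {sp}")
        if self.mode not in ("explicit-lipids", "mean-field"):
            raise ValueError(f"unknown bilayer mode {self.mode!r}")
        if self.mode == "explicit-lipids":
            if self.lipid_xy is None or self.lipid_species is None:
                raise ValueError("explicit-lipids mode requires lipid_xy and lipid_species")
            self.lipid_xy = np.asarray(self.lipid_xy, dtype=float)
            if len(self.lipid_xy) != len(self.lipid_species):
                raise ValueError("lipid_xy and lipid_species lengths differ")
            if len(self.lipid_xy) != sum(self.species_counts.values()):
                raise ValueError("explicit lipid count does not match species_counts")
            self.lipid_xy = np.mod(self.lipid_xy, self.box_xy)

    @property
    def n_lipids_per_leaflet(self) -> int:
        return sum(self.species_counts.values())

    @property
    def area(self) -> float:
        """Leaflet area, nm^2."""
        return float(self.box_xy[0] * self.box_xy[1])

    @property
    def lipid_charges(self) -> np.ndarray:
        """Per-explicit-lipid head charges (explicit mode only)."""
        if self.lipid_species is None:
            raise ValueError("no explicit lipids in mean-field mode")
        return np.array([self.species_charges[s] for s in self.lipid_species])

    @property
    def surface_charge_density(self) -> float:
        """Upper-leaflet charge per area, e/nm^2."""
        q = sum(
            cnt * self.species_charges[sp] for sp, cnt in self.species_counts.items()
        )
        return q / self.area

    def total_charge(self, leaflets: int = 2) -> float:
        """Total head-group charge over ``leaflets`` symmetric leaflets."""
        q = sum(
            cnt * self.species_charges[sp] for sp, cnt in self.species_counts.items()
        )
        return leaflets * q

    def species_indices(self, species: str) -> np.ndarray:
        if self.lipid_species is None:
            raise ValueError("no explicit lipids in mean-field mode")
        if species not in self.species_charges:
            raise UnknownSpeciesError(f"unknown species {species}")
        return np.array(
            [i for i, s in enumerate(self.lipid_species) if s == species], dtype=int
        )


def allocate_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Integerize composition fractions by the largest-remainder rule."""
    for sp, f in fractions.items():
        if f < 0:
            raise InvalidCompositionError(f"negative fraction for {sp}: {f}")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise InvalidCompositionError(f"fractions sum to {total}, expected 1")
    species = list(fractions)
    ideal = np.array([fractions[sp] * n for sp in species])
    counts = np.floor(ideal).astype(int)
    remainder = n - counts.sum()
    # hand out leftover seats to the largest fractional remainders;
    # ties broken by listed order (stable argsort)
    order = np.argsort(-(ideal - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return {sp: int(c) for sp, c in zip(species, counts)}


def build_bilayer(
    n_lipids_per_leaflet: int,
    fractions: dict[str, float],
    box_xy=(7.0, 7.0),
    seed: int = 0,
    plane_z: float = 0.0,
    mode: str = "explicit-lipids",
    species_charges: dict[str, float] | None = None,
) -> BilayerModel:
    """Build a bilayer with integer per-leaflet composition.

    Counts come from largest-remainder allocation of ``fractions``;
    explicit upper-leaflet lipids are placed uniformly at random in the
    periodic box, reproducibly from ``seed``.
    """
    if n_lipids_per_leaflet < 1:
        raise InvalidCompositionError("need at least one lipid per leaflet")
    counts = allocate_counts(n_lipids_per_leaflet, fractions)
    charges = dict(DEFAULT_SPECIES_CHARGES)
    if species_charges:
        charges.update(species_charges)
    for sp in counts:
        charges.setdefault(sp, 0.0)
    box_xy = np.asarray(box_xy, dtype=float)
    if mode == "mean-field":
        return BilayerModel(
            box_xy=box_xy,
            species_counts=counts,
            species_charges=charges,
            plane_z=plane_z,
            mode="mean-field",
        )
    rng = np.random.default_rng(seed)
    species_list: list[str] = []
    for sp, cnt in counts.items():
        species_list.extend([sp] * cnt)
    xy = rng.uniform(0.0, 1.0, size=(len(species_list), 2)) * box_xy
    return BilayerModel(
        box_xy=box_xy,
        species_counts=counts,
        species_charges=charges,
        lipid_xy=xy,
        lipid_species=species_list,
        plane_z=plane_z,
        mode="explicit-lipids",
    )
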