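"""Protein-lipid contact and clustering statistics.

Contacts use a single 3D cutoff with the xy minimum-image convention and
lipid head groups at the bilayer plane height.  'Phosphate' in the toy
model means the charged head bead of PS/PIP2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MembindError, UnknownSpeciesError
from .toysim.energy import minimum_image
from .toysim.state import Trajectory


@dataclass
class ContactProfile:
    group_ids: list[str]
    species: list[str]
    frequency: np.ndarray  # (groups, species), fraction of frames in [0, 1]
    cutoff: float
    n_frames_used: int

    def as_dict(self) -> dict:
        return {
            g: {s: float(self.frequency[i, j]) for j, s in enumerate(self.species)}
            for i, g in enumerate(self.group_ids)
        }


@dataclass
class ContactCountSeries:
    times: np.ndarray
    counts: np.ndarray
    mean: float


@dataclass
class EnrichmentProfile:
    radial_bin_edges: np.ndarray  # nm
    enrichment: np.ndarray  # observed / composition-expected surface density
    mean_bound_count: float

    @property
    def annulus_areas(self) -> np.ndarray:
        e = self.radial_bin_edges
        return np.pi * (e[1:] ** 2 - e[:-1] ** 2)


def _frame_lipid_xy(traj: Trajectory, i: int) -> np.ndarray:
    f = traj.frames[i]
    xy = f.lipid_xy if f.lipid_xy is not None else traj.bilayer.lipid_xy
    if xy is None or len(xy) == 0:
        raise MembindError("trajectory has no explicit lipids")
    return xy


def _pair_distances(beads: np.ndarray, lipid_xy: np.ndarray, traj: Trajectory):
    dxy = minimum_image(
        beads[:, None, :2] - lipid_xy[None, :, :], traj.bilayer.box_xy
    )
    dz = beads[:, 2] - traj.bilayer.plane_z
    return np.sqrt((dxy**2).sum(axis=2) + dz[:, None] ** 2)


def contact_frequency(
    traj: Trajectory,
    groups: dict[str, list[int]],
    species: list[str],
    cutoff: float = 0.5,
) -> ContactProfile:
    """Fraction of frames in which any bead of a group is within ``cutoff``
    of any lipid of each species."""
    for sp in species:
        if sp not in traj.bilayer.species_charges:
            raise UnknownSpeciesError(f"unknown species {sp}")
    sp_idx = {sp: traj.bilayer.species_indices(sp) for sp in species}
    group_ids = list(groups)
    hits = np.zeros((len(group_ids), len(species)), dtype=int)
    for i in range(traj.n_frames):
        beads = traj.bead_lab_positions(i)
        r = _pair_distances(beads, _frame_lipid_xy(traj, i), traj)
        within = r <= cutoff
        for gi, g in enumerate(group_ids):
            rows = within[np.asarray(groups[g], dtype=int)]
            for si, sp in enumerate(species):
                idx = sp_idx[sp]
                if len(idx) and rows[:, idx].any():
                    hits[gi, si] += 1
    return ContactProfile(
        group_ids=group_ids,
        species=list(species),
        frequency=hits / traj.n_frames,
        cutoff=cutoff,
        n_frames_used=traj.n_frames,
    )


def basic_phosphate_contacts(
    traj: Trajectory, cutoff: float = 0.5
) -> ContactCountSeries:
    """Per-frame count of (basic bead, PIP2 head) pairs within ``cutoff``."""
    basic = traj.body.beads_with_label("basic")
    if basic.size == 0:
        raise MembindError("body has no beads labeled 'basic'")
    pip2 = traj.bilayer.species_indices("PIP2")
    counts = np.zeros(traj.n_frames, dtype=int)
    for i in range(traj.n_frames):
        beads = traj.bead_lab_positions(i)[basic]
        xy = _frame_lipid_xy(traj, i)
        if len(pip2):
            r = _pair_distances(beads, xy[pip2], traj)
            counts[i] = int((r <= cutoff).sum())
    return ContactCountSeries(
        times=traj.times, counts=counts, mean=float(counts.mean())
    )


def contacts_depth_correlation(mean_counts, well_depths) -> float:
    """Pearson correlation between mean contact counts and PMF well depths
    across systems."""
    return float(np.corrcoef(np.asarray(mean_counts), np.asarray(well_depths))[0, 1])


def _radial_enrichment(
    traj: Trajectory,
    frames: np.ndarray,
    species_idx: np.ndarray,
    r_max: float,
    n_bins: int,
) -> np.ndarray:
    edges = np.linspace(0.0, r_max, n_bins + 1)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    counts = np.zeros(n_bins)
    for i in frames:
        xy = _frame_lipid_xy(traj, i)[species_idx]
        com = traj.frames[i].body_com[:2]
        d = np.linalg.norm(minimum_image(xy - com, traj.bilayer.box_xy), axis=1)
        counts += np.histogram(d, bins=edges)[0]
    obs_density = counts / (len(frames) * areas)
    expected = len(species_idx) / traj.bilayer.area
    return obs_density / expected


def pip2_enrichment(
    traj: Trajectory,
    r_max: float = 2.5,
    n_bins: int = 5,
    bound_mask: np.ndarray | None = None,
    cutoff: float = 0.5,
    species: str = "PIP2",
) -> EnrichmentProfile:
    """Radial enrichment of a lipid species around the bound body footprint.

    Over bound frames, the observed annular surface density of the species
    around the body COM (xy, minimum image) is divided by the density
    expected from leaflet composition.  ``bound_mask`` defaults to all
    frames; supply the kinetics segmentation mask for bound-only statistics.
    """
    if r_max > 0.5 * min(traj.bilayer.box_xy):
        raise ValueError("r_max must not exceed half the box")
    idx = traj.bilayer.species_indices(species)
    if idx.size == 0:
        raise UnknownSpeciesError(f"no {species} lipids present")
    if bound_mask is None:
        frames = np.arange(traj.n_frames)
    else:
        frames = np.flatnonzero(bound_mask)
    if frames.size == 0:
        raise MembindError("no bound frames for enrichment analysis")
    enrich = _radial_enrichment(traj, frames, idx, r_max, n_bins)
    bound_counts = np.empty(len(frames))
    for j, i in enumerate(frames):
        beads = traj.bead_lab_positions(i)
        r = _pair_distances(beads, _frame_lipid_xy(traj, i)[idx], traj)
        bound_counts[j] = (r.min(axis=0) <= cutoff).sum()
    return EnrichmentProfile(
        radial_bin_edges=np.linspace(0.0, r_max, n_bins + 1),
        enrichment=enrich,
        mean_bound_count=float(bound_counts.mean()),
    )


def species_clustering_contrast(
    traj: Trajectory,
    r_max: float = 2.5,
    n_bins: int = 5,
    bound_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """First-annulus enrichment per species (PIP2 vs PS vs PC contrast)."""
    if bound_mask is None:
        frames = np.arange(traj.n_frames)
    else:
        frames = np.flatnonzero(bound_mask)
    if frames.size == 0:
        raise MembindError("no bound frames for enrichment analysis")
    out = {}
    for sp, cnt in traj.bilayer.species_counts.items():
        if cnt == 0:
            continue
        idx = traj.bilayer.species_indices(sp)
        out[sp] = float(
            _radial_enrichment(traj, frames, idx, r_max, n_bins)[0]
        )
    return out
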