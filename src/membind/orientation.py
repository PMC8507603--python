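"""Orientation-density binding-mode analysis.

The orientation of the rigid body relative to a reference structure is
summarized by the zz element of the least-squares (Kabsch) rotation
between the two bead sets.  R_zz = 1 reproduces the reference z
orientation; R_zz = -1 is a 180-degree flip about an in-plane axis.
R_zz is invariant to rotations about z applied on either side, so no
separate in-plane pre-fit is needed for rigid bodies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, MembindError, UnknownLabelError
from .kinetics import DistanceSeries, min_distance_series, segment_events
from .toysim.state import Trajectory


@dataclass
class OrientationSeries:
    times: np.ndarray
    rzz: np.ndarray
    reference_id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rzz = np.asarray(self.rzz, dtype=float)
        if np.any(np.abs(self.rzz) > 1 + 1e-9):
            raise ValueError("R_zz out of [-1, 1]")


@dataclass
class DensityMap:
    distance_edges: np.ndarray
    rzz_edges: np.ndarray
    density: np.ndarray  # probability per unit cell area
    log_floor: float

    @property
    def cell_area(self) -> float:
        return float(
            np.diff(self.distance_edges)[0] * np.diff(self.rzz_edges)[0]
        )

    @property
    def probability(self) -> np.ndarray:
        """Per-cell probability mass (sums to 1)."""
        dd = np.diff(self.distance_edges)[:, None]
        dr = np.diff(self.rzz_edges)[None, :]
        return self.density * dd * dr

    @property
    def distance_centers(self) -> np.ndarray:
        return 0.5 * (self.distance_edges[:-1] + self.distance_edges[1:])

    @property
    def rzz_centers(self) -> np.ndarray:
        return 0.5 * (self.rzz_edges[:-1] + self.rzz_edges[1:])


@dataclass
class BindingMode:
    center: tuple[float, float]  # (distance nm, rzz)
    occupancy: float
    representative_frame: tuple[int, int]  # (trajectory index, frame index)
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in (0, 1]")


@dataclass
class RefinementClassification:
    label: str  # retained | rotated | unbound
    max_delta_distance: float  # nm
    max_delta_angle: float  # degrees


def rotation_matrix(ref_coords: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Proper least-squares rotation R minimizing ||coords - R @ ref||.

    COMs are removed from both bead sets; det(R) = +1 is enforced.
    """
    ref = np.asarray(ref_coords, dtype=float)
    cur = np.asarray(coords, dtype=float)
    if ref.shape != cur.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    if len(ref) < 3:
        raise DegenerateGeometryError("need >= 3 beads for a rotation fit")
    ref = ref - ref.mean(axis=0)
    cur = cur - cur.mean(axis=0)
    h = ref.T @ cur
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise DegenerateGeometryError("beads are collinear; rotation ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r


def rzz_series(traj: Trajectory, reference_coords: np.ndarray,
               reference_id: str = "") -> OrientationSeries:
    """Per-frame R_zz against a fixed reference bead configuration."""
    if len(reference_coords) != traj.body.n_beads:
        raise MembindError("reference bead count differs from trajectory body")
    rzz = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        rzz[i] = rotation_matrix(reference_coords, traj.bead_lab_positions(i))[2, 2]
    return OrientationSeries(times=traj.times, rzz=rzz, reference_id=reference_id)


def com_z_distance_series(traj: Trajectory) -> DistanceSeries:
    """Body COM height above the bilayer plane per frame."""
    if traj.n_frames < 1:
        raise MembindError("trajectory has no frames")
    values = traj.coms[:, 2] - traj.bilayer.plane_z
    return DistanceSeries(times=traj.times, values=values, kind="com-z")


def last_frame_reference(trajs: list[Trajectory]) -> np.ndarray:
    """Initial reference convention: last frame of the first repeat."""
    return trajs[0].bead_lab_positions(trajs[0].n_frames - 1)


def density_map(
    distance_series: list[DistanceSeries],
    orientation_series: list[OrientationSeries],
    distance_bin: float = 0.1,
    rzz_bin: float = 0.05,
    distance_range: tuple[float, float] | None = None,
) -> DensityMap:
    """Pooled, unit-mass 2D histogram over (distance, R_zz) of all frames."""
    if not distance_series or len(distance_series) != len(orientation_series):
        raise MembindError("need matching non-empty series lists")
    d = np.concatenate([s.values for s in distance_series])
    r = np.concatenate([np.clip(s.rzz, -1.0, 1.0) for s in orientation_series])
    if d.size == 0:
        raise MembindError("empty frame pool")
    if distance_range is None:
        lo = np.floor(d.min() / distance_bin) * distance_bin
        hi = np.ceil(d.max() / distance_bin) * distance_bin
        hi = max(hi, lo + distance_bin)
    else:
        lo, hi = distance_range
    d_edges = np.arange(lo, hi + 0.5 * distance_bin, distance_bin)
    r_edges = np.arange(-1.0, 1.0 + 0.5 * rzz_bin, rzz_bin)
    hist, _, _ = np.histogram2d(d, r, bins=(d_edges, r_edges))
    mass = hist.sum()
    density = hist / mass / (distance_bin * rzz_bin)
    return DensityMap(
        distance_edges=d_edges,
        rzz_edges=r_edges,
        density=density,
        log_floor=1.0 / (10.0 * d.size),
    )


def detect_modes(
    dmap: DensityMap,
    distance_series: list[DistanceSeries],
    orientation_series: list[OrientationSeries],
    distance_bound: float = 2.0,
    min_occupancy: float = 0.02,
) -> list[BindingMode]:
    """Grid local maxima (8-neighborhood) of the bound region of the map.

    Bound frames (distance < ``distance_bound``) are assigned to the
    nearest detected center (bin-scaled metric); mode occupancy is the
    assigned fraction of bound frames and the representative frame is the
    bound frame closest to the center.
    """
    prob = dmap.probability
    dc = dmap.distance_centers
    rc = dmap.rzz_centers
    padded = np.full((prob.shape[0] + 2, prob.shape[1] + 2), -np.inf)
    padded[1:-1, 1:-1] = prob
    centers = []
    for i in range(prob.shape[0]):
        if dc[i] >= distance_bound:
            continue
        for j in range(prob.shape[1]):
            p = prob[i, j]
            if p < min_occupancy:
                continue
            neigh = padded[i : i + 3, j : j + 3].copy()
            neigh[1, 1] = -np.inf
            if p > neigh.max():
                centers.append((dc[i], rc[j], p))
    if not centers:
        return []
    d_bin = np.diff(dmap.distance_edges)[0]
    r_bin = np.diff(dmap.rzz_edges)[0]
    cen = np.array([(c[0], c[1]) for c in centers])
    # pooled bound frames with provenance
    pts, who = [], []
    for si, (ds, os_) in enumerate(zip(distance_series, orientation_series)):
        for fi in range(len(ds.values)):
            if ds.values[fi] < distance_bound:
                pts.append((ds.values[fi], os_.rzz[fi]))
                who.append((si, fi))
    pts = np.array(pts)
    if len(pts) == 0:
        return []
    scaled = (pts[:, None, :] - cen[None, :, :]) / np.array([d_bin, r_bin])
    d2 = (scaled**2).sum(axis=2)
    assign = d2.argmin(axis=1)
    modes = []
    for m, (cd, cr, _p) in enumerate(centers):
        mask = assign == m
        if not mask.any():
            continue
        best = np.flatnonzero(mask)[d2[mask, m].argmin()]
        modes.append(
            BindingMode(
                center=(float(cd), float(cr)),
                occupancy=float(mask.sum()) / len(pts),
                representative_frame=who[best],
            )
        )
    modes.sort(key=lambda m: -m.occupancy)
    return modes


def rereference(
    trajs: list[Trajectory], mode: BindingMode
) -> list[OrientationSeries]:
    """Recompute all R_zz series against the mode's representative frame."""
    ti, fi = mode.representative_frame
    ref = trajs[ti].bead_lab_positions(fi)
    ref_id = f"traj{ti}:frame{fi}"
    return [rzz_series(t, ref, reference_id=ref_id) for t in trajs]


def score_modes(
    modes: list[BindingMode],
    trajs: list[Trajectory],
    physical_mask: dict[str, float] | None = None,
    productive_mask: dict[str, float] | None = None,
    occupancy_threshold: float = 0.02,
) -> list[BindingMode]:
    """Attach probable/physical/productive flags to each mode.

    ``physical_mask`` maps bead labels to a minimum height (nm) above the
    plane the labeled beads must keep (e.g. termini must not be buried);
    ``productive_mask`` maps labels to a maximum height (catalytic-face
    beads must reach the surface).  Both are evaluated on the mode's
    representative frame.  Empty masks are vacuously true.
    """
    physical_mask = physical_mask or {}
    productive_mask = productive_mask or {}
    out = []
    for mode in modes:
        ti, fi = mode.representative_frame
        traj = trajs[ti]
        labels = set(traj.body.bead_labels)
        for mask in (physical_mask, productive_mask):
            unknown = set(mask) - labels
            if unknown:
                raise UnknownLabelError(f"unknown bead labels in mask: {sorted(unknown)}")
        beads = traj.bead_lab_positions(fi)
        height = beads[:, 2] - traj.bilayer.plane_z
        physical = all(
            height[traj.body.beads_with_label(lab)].min() >= h_min
            for lab, h_min in physical_mask.items()
        )
        productive = all(
            height[traj.body.beads_with_label(lab)].min() <= h_max
            for lab, h_max in productive_mask.items()
        )
        mode.flags = {
            "probable": mode.occupancy >= occupancy_threshold,
            "physical": bool(physical),
            "productive": bool(productive),
        }
        out.append(mode)
    return out


def classify_refinement(
    traj: Trajectory,
    unbind_cutoff: float = 1.5,
    rotation_threshold_deg: float = 45.0,
    dwell: int = 5,
) -> RefinementClassification:
    """Label a refinement trajectory as retained / rotated / unbound.

    Unbound: the minimum bead-lipid distance exceeds ``unbind_cutoff`` for
    at least ``dwell`` consecutive frames.  Rotated: the geodesic rotation
    angle versus frame 0 exceeds the threshold.  Otherwise retained.
    """
    if traj.n_frames < 2:
        raise MembindError("need >= 2 frames to classify")
    com_z = traj.coms[:, 2]
    max_dd = float(np.abs(com_z - com_z[0]).max())
    q = traj.quaternions
    r0 = Rotation.from_quat(q[0])
    angles = np.degrees(
        (Rotation.from_quat(q) * r0.inv()).magnitude()
    )
    max_angle = float(angles.max())
    dist = min_distance_series(traj).values
    far = dist > unbind_cutoff
    # longest run of consecutive far frames
    run, longest = 0, 0
    for flag in far:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    if longest >= dwell:
        label = "unbound"
    elif max_angle > rotation_threshold_deg:
        label = "rotated"
    else:
        label = "retained"
    return RefinementClassification(
        label=label, max_delta_distance=max_dd, max_delta_angle=max_angle
    )
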