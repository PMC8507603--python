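"""Encounter/binding kinetics: distance traces, event segmentation,
ensemble averaging, and exponential decay fits."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import MembindError
from .toysim.energy import minimum_image
from .toysim.state import Trajectory


@dataclass
class DistanceSeries:
    """A per-frame distance trace; ``kind`` is 'min-bead-pair' or 'com-z'."""

    times: np.ndarray  # ps
    values: np.ndarray  # nm
    kind: str = "min-bead-pair"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.kind == "min-bead-pair" and np.any(self.values < 0):
            raise ValueError("min-bead-pair distances must be non-negative")


@dataclass
class EventSegmentation:
    bound_intervals: list[tuple[float, float]]
    fraction_bound: float
    n_events: int
    first_contact_time: float | None
    bound_mask: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.fraction_bound <= 1.0:
            raise ValueError("fraction_bound must lie in [0, 1]")


@dataclass
class DecayFit:
    d_inf: float
    d0: float
    tau: float  # ps
    rss: float  # nm^2
    converged: bool


def min_distance_series(traj: Trajectory) -> DistanceSeries:
    """Per-frame minimum bead-lipid 3D distance (xy minimum image).

    Explicit lipids sit at the bilayer plane height; in mean-field mode the
    distance is the bead height above the plane (smeared lipids).
    """
    if traj.n_frames < 1:
        raise MembindError("trajectory has no frames")
    bilayer = traj.bilayer
    values = np.empty(traj.n_frames)
    if bilayer.mode == "mean-field":
        for i in range(traj.n_frames):
            dz = traj.bead_lab_positions(i)[:, 2] - bilayer.plane_z
            values[i] = np.abs(dz).min()
        return DistanceSeries(times=traj.times, values=values, kind="min-bead-pair")
    for i, frame in enumerate(traj.frames):
        lipid_xy = frame.lipid_xy if frame.lipid_xy is not None else bilayer.lipid_xy
        if lipid_xy is None or len(lipid_xy) == 0:
            raise MembindError("explicit-lipid trajectory has an empty lipid set")
        beads = traj.bead_lab_positions(i)
        dxy = minimum_image(
            beads[:, None, :2] - lipid_xy[None, :, :], bilayer.box_xy
        )
        dz = beads[:, 2] - bilayer.plane_z
        r2 = (dxy**2).sum(axis=2) + dz[:, None] ** 2
        values[i] = np.sqrt(r2.min())
    return DistanceSeries(times=traj.times, values=values, kind="min-bead-pair")


def segment_events(
    series: DistanceSeries,
    on_cutoff: float = 0.5,
    off_cutoff: float = 1.0,
    min_dwell: int = 5,
) -> EventSegmentation:
    """Hysteresis segmentation of bound/unbound episodes.

    A bound episode starts when the distance drops below ``on_cutoff`` and
    ends only when it stays above ``off_cutoff`` for at least ``min_dwell``
    consecutive frames.  ``fraction_bound`` is frame-count based and hence
    invariant under time-unit rescaling.
    """
    if off_cutoff < on_cutoff:
        raise ValueError("off_cutoff must be >= on_cutoff")
    v = series.values
    t = series.times
    n = len(v)
    bound_mask = np.zeros(n, dtype=bool)
    intervals: list[tuple[float, float]] = []
    first_contact = None
    bound = False
    start_idx = 0
    off_run = 0
    last_in_idx = 0
    for i in range(n):
        if not bound:
            if v[i] < on_cutoff:
                bound = True
                start_idx = i
                last_in_idx = i
                off_run = 0
                if first_contact is None:
                    first_contact = float(t[i])
        else:
            if v[i] > off_cutoff:
                off_run += 1
                if off_run >= min_dwell:
                    intervals.append((float(t[start_idx]), float(t[last_in_idx])))
                    bound_mask[start_idx : last_in_idx + 1] = True
                    bound = False
                    off_run = 0
            else:
                off_run = 0
                last_in_idx = i
    if bound:
        intervals.append((float(t[start_idx]), float(t[last_in_idx])))
        bound_mask[start_idx : last_in_idx + 1] = True
    return EventSegmentation(
        bound_intervals=intervals,
        fraction_bound=float(bound_mask.sum()) / n,
        n_events=len(intervals),
        first_contact_time=first_contact,
        bound_mask=bound_mask,
    )


def ensemble_mean_distance(series_list: list[DistanceSeries]) -> DistanceSeries:
    """Pointwise mean across repeats, resampling to the first series' grid
    (linear interpolation) when grids differ."""
    if not series_list:
        raise MembindError("empty series list")
    ref = series_list[0]
    stacked = np.empty((len(series_list), len(ref.times)))
    for i, s in enumerate(series_list):
        if len(s.times) == len(ref.times) and np.allclose(s.times, ref.times):
            stacked[i] = s.values
        else:
            stacked[i] = np.interp(ref.times, s.times, s.values)
    return DistanceSeries(
        times=ref.times.copy(), values=stacked.mean(axis=0), kind=ref.kind
    )


def fit_exponential_decay(series: DistanceSeries) -> DecayFit:
    """Least-squares fit of d(t) = d_inf + (d0 - d_inf) exp(-t/tau)."""
    t = series.times
    v = series.values
    if len(t) < 4:
        raise MembindError("need at least 4 points for a decay fit")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise MembindError("non-finite values in series")
    if np.ptp(v) == 0.0:
        return DecayFit(
            d_inf=float(v[0]), d0=float(v[0]), tau=float("nan"), rss=0.0,
            converged=False,
        )

    def model(tt, d_inf, d0, tau):
        return d_inf + (d0 - d_inf) * np.exp(-tt / tau)

    span = float(t[-1] - t[0]) or 1.0
    p0 = (float(v[-1]), float(v[0]), span / 3.0)
    try:
        popt, pcov = curve_fit(
            model, t, v, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        converged = bool(np.all(np.isfinite(pcov)))
    except RuntimeError:
        return DecayFit(
            d_inf=p0[0], d0=p0[1], tau=p0[2], rss=float("nan"), converged=False
        )
    resid = v - model(t, *popt)
    return DecayFit(
        d_inf=float(popt[0]),
        d0=float(popt[1]),
        tau=float(popt[2]),
        rss=float((resid**2).sum()),
        converged=converged,
    )
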