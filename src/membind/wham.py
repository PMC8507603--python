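"""Weighted histogram analysis of harmonic umbrella windows.

Self-consistent WHAM iteration over window free-energy shifts f_i (in kT)
and unbiased bin probabilities p_j:

    p_j ~ (sum_i H_ij) / (sum_i N_i exp(f_i - w_ij))
    f_i = -ln sum_j p_j exp(-w_ij)

with w_ij the reduced bias of window i at bin center j.  The profile
G = -kT ln p is anchored to the mean over the outermost plateau of the
occupied range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import kt
from .errors import ConvergenceError, DisconnectedWindowsError, NoWellError
from .toysim.sampling import UmbrellaWindow


@dataclass
class WhamSettings:
    bin_width: float = 0.05  # nm
    tolerance: float = 1e-7  # kT, on max |delta f_i|
    max_iterations: int = 100000
    temperature: float = 323.0
    n_bootstrap: int = 50
    seed: int = 0
    anchor_width: float = 0.5  # nm of outermost occupied range

    def __post_init__(self):
        if self.bin_width <= 0 or self.tolerance <= 0:
            raise ValueError("bin_width and tolerance must be positive")


@dataclass
class PMFProfile:
    bin_centers: np.ndarray  # nm
    g: np.ndarray  # kJ/mol; NaN on unoccupied bins
    g_err: np.ndarray | None  # kJ/mol bootstrap std, aligned with bin_centers
    n_eff: np.ndarray  # samples per bin
    anchor: str = ""
    window_shifts: np.ndarray | None = None  # f_i in kT, diagnostics

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.g)


@dataclass
class WellDepth:
    depth: float  # kJ/mol
    location: float  # nm, argmin of G
    error: float | None = None


@dataclass
class DeltaPMF:
    value: float
    error: float


def _histograms(windows, settings):
    samples = [w.production_samples for w in windows]
    for w, s in zip(windows, samples):
        if s.size == 0:
            raise ValueError(
                f"window at {w.center} has no samples after equilibration skip"
            )
    allx = np.concatenate(samples)
    bw = settings.bin_width
    lo = np.floor(allx.min() / bw) * bw
    hi = np.ceil(allx.max() / bw) * bw
    edges = np.arange(lo, hi + 0.5 * bw, bw)
    if len(edges) < 2:
        edges = np.array([lo, lo + bw])
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.array([np.histogram(s, bins=edges)[0] for s in samples])
    return hist, centers, edges


def _check_chain(windows, hist):
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        occ_a = hist[a] > 0
        occ_b = hist[b] > 0
        if not np.any(occ_a & occ_b):
            raise DisconnectedWindowsError(
                f"no histogram overlap between windows at "
                f"{windows[a].center:.3f} nm and {windows[b].center:.3f} nm"
            )


def _solve(hist, centers, windows, settings):
    kbt = kt(settings.temperature)
    w_ij = np.array(
        [
            0.5 * w.force_constant * (centers - w.center) ** 2 / kbt
            for w in windows
        ]
    )
    log_p, f = solve_wham_bias_matrix(
        hist, w_ij, tolerance=settings.tolerance,
        max_iterations=settings.max_iterations,
    )
    occupied = hist.sum(axis=0) > 0
    g = np.where(occupied, -kbt * log_p, np.nan)
    return g, occupied, f


def solve_wham_bias_matrix(
    hist: np.ndarray,
    w_ij: np.ndarray,
    tolerance: float = 1e-7,
    max_iterations: int = 100000,
):
    """Core WHAM solve for arbitrary reduced bias matrices.

    ``hist[i, j]`` are counts of window i in bin j and ``w_ij`` the bias of
    window i at bin j in kT.  Returns (ln p_j, f_i) with p normalized over
    occupied bins and f_0 = 0.
    """
    n_i = hist.sum(axis=1)
    h_j = hist.sum(axis=0)
    occupied = h_j > 0
    f = np.zeros(len(hist))
    log_n = np.log(n_i)
    log_h = np.where(occupied, np.log(np.maximum(h_j, 1)), -np.inf)

    # warm start: damped Newton on the (convex) WHAM likelihood; the
    # self-consistent sweeps below then certify the fixed point
    n_tot = float(n_i.sum())
    hj_occ = h_j[occupied].astype(float) / n_tot
    n_frac = n_i / n_tot
    w_occ = w_ij[:, occupied]
    for _ in range(200):
        a = log_n[:, None] + f[:, None] - w_occ
        log_denom = logsumexp(a, axis=0)
        wmat = np.exp(a - log_denom[None, :])  # (windows, occ bins)
        grad = wmat @ hj_occ - n_frac
        if np.abs(grad).max() < 1e-14:
            break
        wh = wmat * hj_occ[None, :]
        hess = np.diag(wh.sum(axis=1)) - wh @ wmat.T
        # gauge: fix f[0] = 0
        try:
            step = np.linalg.solve(
                hess[1:, 1:] + 1e-12 * np.eye(len(f) - 1), grad[1:]
            )
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        scale = min(1.0, 2.0 / max(np.abs(step).max(), 1e-30))
        f = f - scale * np.concatenate([[0.0], step])
        f -= f[0]
    for _ in range(max_iterations):
        # ln p_j on occupied bins
        log_denom = logsumexp(log_n[:, None] + f[:, None] - w_ij, axis=0)
        log_p = np.where(occupied, log_h - log_denom, -np.inf)
        log_p -= logsumexp(log_p[occupied])
        f_new = -logsumexp(log_p[None, :] - w_ij, axis=1)
        f_new -= f_new[0]
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tolerance:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iterations} iterations",
            residual=float(delta),
        )
    return log_p, f


def _anchor(g, centers, occupied, settings):
    occ_x = centers[occupied]
    hi = occ_x.max()
    plateau = occupied & (centers >= hi - settings.anchor_width)
    shift = np.nanmean(g[plateau])
    return g - shift, f"zero = mean G over occupied bins in [{hi - settings.anchor_width:.3f}, {hi:.3f}] nm"


def wham(windows: list[UmbrellaWindow], settings: WhamSettings | None = None) -> PMFProfile:
    """Estimate the unbiased free-energy profile from umbrella windows."""
    settings = settings or WhamSettings()
    if len(windows) < 1:
        raise ValueError("need at least one window")
    hist, centers, _ = _histograms(windows, settings)
    if len(windows) >= 2:
        _check_chain(windows, hist)
    g, occupied, f = _solve(hist, centers, windows, settings)
    g, anchor_desc = _anchor(g, centers, occupied, settings)
    return PMFProfile(
        bin_centers=centers,
        g=g,
        g_err=None,
        n_eff=hist.sum(axis=0),
        anchor=anchor_desc,
        window_shifts=f,
    )


def bootstrap_pmf(
    windows: list[UmbrellaWindow], settings: WhamSettings | None = None
) -> np.ndarray:
    """Per-bin std of G over bootstrap replicates.

    Each replicate resamples every window's production samples with
    replacement (window identity and bias are kept fixed), then re-runs
    the full WHAM solve on the original binning.
    """
    settings = settings or WhamSettings()
    if settings.n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    rng = np.random.default_rng(settings.seed)
    base = wham(windows, settings)
    reps = np.full((settings.n_bootstrap, len(base.bin_centers)), np.nan)
    for b in range(settings.n_bootstrap):
        resampled = []
        for w in windows:
            s = w.production_samples
            resampled.append(
                UmbrellaWindow(
                    center=w.center,
                    force_constant=w.force_constant,
                    samples=s[rng.integers(0, len(s), size=len(s))],
                    n_equil_skipped=0,
                )
            )
        prof = wham(resampled, settings)
        # align on bin centers (grids may differ at the edges)
        idx = np.searchsorted(prof.bin_centers, base.bin_centers)
        ok = (idx < len(prof.bin_centers)) & np.isclose(
            prof.bin_centers[np.minimum(idx, len(prof.bin_centers) - 1)],
            base.bin_centers,
        )
        reps[b, ok] = prof.g[idx[ok]]
    return np.nanstd(reps, axis=0, ddof=1)


def well_depth(profile: PMFProfile) -> WellDepth:
    """Depth of the profile's interior minimum below the anchored plateau."""
    g = profile.g
    occ = np.flatnonzero(profile.occupied)
    if occ.size < 3:
        raise NoWellError("too few occupied bins")
    gmin_idx = occ[np.nanargmin(g[occ])]
    if gmin_idx == occ[0] or gmin_idx == occ[-1] or g[gmin_idx] >= -1e-12:
        raise NoWellError("profile has no interior minimum below the plateau")
    err = None
    if profile.g_err is not None and np.isfinite(profile.g_err[gmin_idx]):
        err = float(profile.g_err[gmin_idx])
    return WellDepth(
        depth=float(-g[gmin_idx]),
        location=float(profile.bin_centers[gmin_idx]),
        error=err,
    )


def delta_pmf(
    depth_pip2: float,
    depth_ps: float,
    err_pip2: float = 0.0,
    err_ps: float = 0.0,
) -> DeltaPMF:
    """Well-depth difference between two membrane compositions,
    errors propagated in quadrature."""
    if not (np.isfinite(depth_pip2) and np.isfinite(depth_ps)):
        raise ValueError("depths must be finite")
    return DeltaPMF(
        value=float(depth_pip2 - depth_ps),
        error=float(np.hypot(err_pip2, err_ps)),
    )
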