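"""Biased-sample generators: umbrella windows along COM z and alchemical
lambda windows for head-group discharge.

Umbrella windows draw i.i.d. samples from the exact biased Boltzmann
density of the COM-z coordinate (orientation and explicit lipids frozen),
via inverse-CDF sampling on a fine grid.  This reproduces the statistical
structure WHAM consumes without paying for full dynamics in every window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..constants import kt
from ..errors import InvalidTagError
from .dynamics import simulate
from .energy import energy_vs_z, potential_energy
from .params import SimParams
from .state import SystemState


@dataclass
class UmbrellaWindow:
    """Samples of the reaction coordinate under a harmonic bias."""

    center: float  # nm
    force_constant: float  # kJ/mol/nm^2
    samples: np.ndarray  # nm
    n_equil_skipped: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        # zero is allowed (unbiased window); negative is not
        if self.force_constant < 0:
            raise ValueError("force_constant must be non-negative")
        if self.samples.size < 1:
            raise ValueError("window needs at least one sample")

    @property
    def production_samples(self) -> np.ndarray:
        return self.samples[self.n_equil_skipped :]


@dataclass
class LambdaWindowSet:
    """Reduced-potential matrix across alchemical states.

    ``reduced_potentials[k, l, n]`` is the energy (in kT) of sample ``n``
    drawn at state ``k``, re-evaluated at state ``l``.
    """

    lambdas: np.ndarray  # (K,) monotone in [0, 1]
    reduced_potentials: np.ndarray  # (K, K, N)
    samples_per_state: int
    temperature: float = 323.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.reduced_potentials = np.asarray(self.reduced_potentials, dtype=float)
        k = len(self.lambdas)
        if abs(self.lambdas[0]) > 1e-12 or abs(self.lambdas[-1] - 1.0) > 1e-12:
            raise ValueError("lambda grid must span [0, 1]")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambda grid must be strictly increasing")
        if self.reduced_potentials.shape != (k, k, self.samples_per_state):
            raise ValueError(
                f"reduced_potentials shape {self.reduced_potentials.shape} "
                f"inconsistent with {k} states x {self.samples_per_state} samples"
            )

    @property
    def n_states(self) -> int:
        return len(self.lambdas)


def _inverse_cdf_sample(
    z_grid: np.ndarray, log_density: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw i.i.d. samples from a 1D density tabulated on a fine grid."""
    logp = log_density - log_density.max()
    p = np.exp(logp)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(z_grid))])
    cdf /= cdf[-1]
    # strictly increasing interpolation nodes only
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    return np.interp(rng.uniform(size=n), cdf[keep], z_grid[keep])


def generate_umbrella_windows(
    state: SystemState,
    params: SimParams,
    centers,
    force_constant: float = 2000.0,
    n_samples: int = 5000,
    n_equil: int = 0,
    seed: int = 0,
    grid_step: float = 0.002,
) -> list[UmbrellaWindow]:
    """Sample the COM-z coordinate in harmonic windows over the toy potential.

    The first ``n_equil`` samples of each window are flagged as
    equilibration.  Emits a warning (not an error) if adjacent windows'
    sample histograms share no bins.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise ValueError("centers must be non-empty")
    if force_constant <= 0:
        raise ValueError("force_constant must be positive")
    kbt = kt(params.temperature)
    sig = np.sqrt(kbt / force_constant)
    lo = max(state.bilayer.plane_z + 0.02, centers.min() - 8 * sig - 0.5)
    hi = centers.max() + 8 * sig + 0.5
    z_grid = np.arange(lo, hi, grid_step)
    u = energy_vs_z(state, params, z_grid)
    rng = np.random.default_rng(seed)
    windows = []
    for c in centers:
        bias = 0.5 * force_constant * (z_grid - c) ** 2
        logd = -(u + bias) / kbt
        samples = _inverse_cdf_sample(z_grid, logd, n_samples, rng)
        windows.append(
            UmbrellaWindow(
                center=float(c),
                force_constant=force_constant,
                samples=samples,
                n_equil_skipped=n_equil,
            )
        )
    _warn_on_gaps(windows)
    return windows


def _warn_on_gaps(windows: list[UmbrellaWindow], bin_width: float = 0.05) -> None:
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        sa = windows[a].production_samples
        sb = windows[b].production_samples
        bins_a = set(np.unique(np.floor(sa / bin_width).astype(int)))
        bins_b = set(np.unique(np.floor(sb / bin_width).astype(int)))
        if not bins_a & bins_b:
            warnings.warn(
                f"umbrella windows at {windows[a].center:.3f} and "
                f"{windows[b].center:.3f} nm share no histogram bins",
                stacklevel=2,
            )


def generate_lambda_set(
    state: SystemState,
    params: SimParams,
    n_states: int = 21,
    tagged_lipid: int | None = None,
    n_samples: int = 200,
    seed: int = 0,
    include_protein: bool = True,
    n_equil_steps: int = 200,
    sample_stride: int = 5,
) -> LambdaWindowSet:
    """Sample every lambda state and fill the reduced-potential matrix.

    Explicit-lipid mode runs short Brownian dynamics at each state
    (``tagged_lipid`` must index a PIP2 lipid); mean-field mode draws the
    COM-z coordinate from the exact Boltzmann density under the
    lambda-scaled surface charge.  ``include_protein=False`` produces the
    companion "free" leg: without the body the tagged head group has no
    interaction partner, so all states are degenerate.
    """
    lambdas = np.linspace(0.0, 1.0, n_states)
    kbt = kt(params.temperature)
    rng = np.random.default_rng(seed)
    u_kln = np.zeros((n_states, n_states, n_samples))

    if not include_protein:
        # no body: the tagged lipid interacts with nothing that depends on
        # lambda (lipid-lipid terms are absent in the toy model)
        return LambdaWindowSet(
            lambdas=lambdas,
            reduced_potentials=u_kln,
            samples_per_state=n_samples,
            temperature=params.temperature,
            metadata={"leg": "free", "seed": seed},
        )

    if state.bilayer.mode == "mean-field":
        z_grid = np.arange(
            state.bilayer.plane_z + 0.02, params.upper_wall_distance, 0.002
        )
        u_l = np.array(
            [energy_vs_z(state, params, z_grid, lam=l, tagged_lipid=None) for l in lambdas]
        )  # (K, G)
        z_samples = np.zeros((n_states, n_samples))
        for k in range(n_states):
            z = _inverse_cdf_sample(z_grid, -u_l[k] / kbt, n_samples, rng)
            z_samples[k] = z
            for l in range(n_states):
                u_kln[k, l] = np.interp(z, z_grid, u_l[l]) / kbt
        return LambdaWindowSet(
            lambdas=lambdas,
            reduced_potentials=u_kln,
            samples_per_state=n_samples,
            temperature=params.temperature,
            metadata={
                "leg": "bound",
                "mode": "mean-field",
                "seed": seed,
                "z_samples": z_samples,
            },
        )

    if tagged_lipid is None:
        raise InvalidTagError("explicit-lipid mode requires tagged_lipid")
    if state.bilayer.lipid_species[tagged_lipid] != "PIP2":
        raise InvalidTagError(
            f"tagged lipid {tagged_lipid} is "
            f"{state.bilayer.lipid_species[tagged_lipid]}, expected PIP2"
        )
    n_steps = n_equil_steps + n_samples * sample_stride
    u_off_kn = np.zeros((n_states, n_samples))
    v_tag_kn = np.zeros((n_states, n_samples))
    for k, lam_k in enumerate(lambdas):
        p_k = SimParams(**{**params.to_dict(), "seed": int(rng.integers(2**31))})
        traj = simulate(
            state,
            p_k,
            n_steps=n_steps,
            record_every=sample_stride,
            lam=float(lam_k),
            tagged_lipid=tagged_lipid,
        )
        first = len(traj.frames) - n_samples
        for n in range(n_samples):
            s = traj.state_at(first + n)
            u_off = potential_energy(s, params, lam=1.0, tagged_lipid=tagged_lipid)
            u_on = potential_energy(s, params, lam=0.0, tagged_lipid=tagged_lipid)
            v_tag = u_on - u_off
            u_off_kn[k, n] = u_off
            v_tag_kn[k, n] = v_tag
            u_kln[k, :, n] = (u_off + (1.0 - lambdas) * v_tag) / kbt
    return LambdaWindowSet(
        lambdas=lambdas,
        reduced_potentials=u_kln,
        samples_per_state=n_samples,
        temperature=params.temperature,
        metadata={"leg": "bound", "mode": "explicit-lipids", "seed": seed,
                  "tagged_lipid": int(tagged_lipid), "u_off": u_off_kn,
                  "v_tag": v_tag_kn},
    )
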