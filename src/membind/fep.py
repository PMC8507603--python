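"""Alchemical free-energy estimation: pairwise Bennett acceptance ratio,
self-consistent multistate reweighting, bound-minus-free differencing,
counterion bookkeeping, and the FEP-vs-dPMF internal consistency check."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import kt
from .errors import ConvergenceError, PoorOverlapError, ScheduleMismatchError
from .toysim.sampling import LambdaWindowSet


@dataclass
class BARResult:
    delta_g: float  # kJ/mol
    se: float  # kJ/mol
    overlap: float  # mean Fermi diagnostic in (0, 0.5]


@dataclass
class MultistateResult:
    lambdas: np.ndarray
    f: np.ndarray  # kJ/mol, free energy of each state relative to state 0
    f_err: np.ndarray  # kJ/mol, from chained pairwise BAR variances
    overlap: np.ndarray  # per adjacent pair

    @property
    def delta_g(self) -> float:
        """End-to-end transformation free energy, kJ/mol."""
        return float(self.f[-1])

    @property
    def delta_g_err(self) -> float:
        return float(self.f_err[-1])


@dataclass
class FEPResult:
    """Bound-minus-free transformation free energies, one per tagged lipid."""

    per_lipid_ddg: list[float]  # kJ/mol
    per_lipid_err: list[float]
    total_error: float
    n_repeats: int
    estimator: str = "multistate"
    overlap_diagnostics: list = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(np.sum(self.per_lipid_ddg))


@dataclass
class ConsistencyReport:
    total_fep: float
    delta_pmf: float
    discrepancy: float
    combined_error: float
    consistent: bool


def bar_pair(
    u_forward: np.ndarray, u_reverse: np.ndarray, temperature: float = 323.0
) -> BARResult:
    """Bennett acceptance ratio for one pair of states.

    ``u_forward`` holds U1-U0 (kJ/mol) evaluated on samples from state 0;
    ``u_reverse`` holds U0-U1 on samples from state 1.  Solves the
    self-consistent Bennett equation and reports the standard asymptotic
    error and a Fermi-function overlap diagnostic.
    """
    u_forward = np.asarray(u_forward, dtype=float)
    u_reverse = np.asarray(u_reverse, dtype=float)
    if u_forward.size == 0 or u_reverse.size == 0:
        raise ValueError("both sample sets must be non-empty")
    kbt = kt(temperature)
    wf = u_forward / kbt
    wr = u_reverse / kbt
    n_f, n_r = len(wf), len(wr)

    def fermi(x):
        return 1.0 / (1.0 + np.exp(np.clip(x, -500, 500)))

    def h(c):
        return fermi(wf - c).sum() - fermi(wr + c).sum()

    lo, hi = -10.0, 10.0
    while h(lo) > 0:
        lo *= 2
        if lo < -1e6:
            raise PoorOverlapError("BAR bracket search failed (no overlap)")
    while h(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise PoorOverlapError("BAR bracket search failed (no overlap)")
    c = brentq(h, lo, hi, xtol=1e-12)
    delta_f = c - np.log(n_r / n_f)  # in kT

    f0 = fermi(wf - c)
    f1 = fermi(wr + c)
    overlap = 0.5 * (f0.mean() + f1.mean())
    if overlap < 1e-6:
        raise PoorOverlapError(f"overlap diagnostic {overlap:.2e} < 1e-6")
    var = (np.mean(f0**2) / np.mean(f0) ** 2 - 1.0) / n_f + (
        np.mean(f1**2) / np.mean(f1) ** 2 - 1.0
    ) / n_r
    return BARResult(
        delta_g=float(delta_f * kbt),
        se=float(np.sqrt(max(var, 0.0)) * kbt),
        overlap=float(overlap),
    )


def multistate_free_energy(
    lset: LambdaWindowSet,
    temperature: float | None = None,
    tolerance: float = 1e-10,
    max_iterations: int = 50000,
) -> MultistateResult:
    """Self-consistent multistate reweighting over the full state set.

    Iterates the coupled equations for the reduced free energies f_l until
    the largest shift falls below ``tolerance`` (kT).  Errors are taken
    from the chained adjacent-pair BAR variances (added in quadrature),
    which the multistate estimates must agree with.
    """
    temperature = temperature if temperature is not None else lset.temperature
    kbt = kt(temperature)
    u = lset.reduced_potentials  # (K, K, N), kT units
    k_states, _, n = u.shape
    n_k = np.full(k_states, n, dtype=float)
    # flatten samples: u_ln = u of sample (k, i) at state l
    u_flat = u.transpose(1, 0, 2).reshape(k_states, k_states * n)
    f = np.zeros(k_states)
    log_n = np.log(n_k)
    for _ in range(max_iterations):
        log_w = f[:, None] - u_flat  # (K, M)
        log_denom = logsumexp(log_n[:, None] + log_w, axis=0)  # (M,)
        f_new = -logsumexp(-u_flat - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tolerance:
            break
    else:
        raise ConvergenceError(
            f"multistate iteration did not converge (residual {delta:.2e} kT)",
            residual=float(delta),
        )
    # adjacent-pair BAR errors and overlap diagnostics
    err2 = np.zeros(k_states)
    overlaps = np.zeros(k_states - 1)
    for i in range(k_states - 1):
        fwd = (u[i, i + 1] - u[i, i]) * kbt
        rev = (u[i + 1, i] - u[i + 1, i + 1]) * kbt
        if np.allclose(fwd, 0.0) and np.allclose(rev, 0.0):
            overlaps[i] = 0.5
            err2[i + 1] = err2[i]
            continue
        res = bar_pair(fwd, rev, temperature)
        overlaps[i] = res.overlap
        err2[i + 1] = err2[i] + res.se**2
    return MultistateResult(
        lambdas=lset.lambdas.copy(),
        f=f * kbt,
        f_err=np.sqrt(err2),
        overlap=overlaps,
    )


def bar_chain(lset: LambdaWindowSet, temperature: float | None = None):
    """Chained pairwise BAR along the lambda path; returns (dG, se) kJ/mol."""
    temperature = temperature if temperature is not None else lset.temperature
    kbt = kt(temperature)
    u = lset.reduced_potentials
    total, var = 0.0, 0.0
    for i in range(len(lset.lambdas) - 1):
        fwd = (u[i, i + 1] - u[i, i]) * kbt
        rev = (u[i + 1, i] - u[i + 1, i + 1]) * kbt
        if np.allclose(fwd, 0.0) and np.allclose(rev, 0.0):
            continue
        res = bar_pair(fwd, rev, temperature)
        total += res.delta_g
        var += res.se**2
    return total, float(np.sqrt(var))


@dataclass
class BindingDDG:
    reported: float  # kJ/mol, positive = favorable lipid binding
    raw: float  # kJ/mol, dg_bound - dg_free as computed


def binding_ddg(
    dg_bound: float,
    dg_free: float,
    schedule_bound: np.ndarray | None = None,
    schedule_free: np.ndarray | None = None,
) -> BindingDDG:
    """Bound-minus-free transformation free energy for one tagged lipid.

    Discharging a favorably bound anionic head group costs more in the
    bound leg, so the raw difference is positive for favorable binding;
    the reported value keeps that sign convention (printed tables list
    favorable interactions as positive magnitudes).
    """
    if schedule_bound is not None or schedule_free is not None:
        if schedule_bound is None or schedule_free is None:
            raise ScheduleMismatchError("both schedules must be given to compare")
        a = np.asarray(schedule_bound, float)
        b = np.asarray(schedule_free, float)
        if a.shape != b.shape or not np.allclose(a, b):
            raise ScheduleMismatchError("bound and free lambda schedules differ")
    raw = float(dg_bound - dg_free)
    return BindingDDG(reported=raw, raw=raw)


def total_fep(per_lipid, per_lipid_err=None):
    """Sum of per-lipid free energies; error in quadrature.  Returns
    (total, error)."""
    per_lipid = np.asarray(list(per_lipid), dtype=float)
    total = float(per_lipid.sum()) if per_lipid.size else 0.0
    if per_lipid_err is None:
        return total, 0.0
    err = float(np.sqrt(np.sum(np.asarray(per_lipid_err, float) ** 2)))
    return total, err


def counterion_neutralizer_count(q_initial: float, q_final: float):
    """Monovalent counterions to neutralize a head-group charge change.

    Returns (count, species) with species 'cation' or 'anion'.
    """
    for q in (q_initial, q_final):
        if abs(q - round(q)) > 1e-9:
            raise ValueError(f"charges must be integral, got {q}")
    dq = int(round(q_final)) - int(round(q_initial))
    if dq == 0:
        return 0, "none"
    # system charge rises by dq: neutralize by removing dq cations (dq > 0)
    # or dq anions (dq < 0)
    return abs(dq), "cation" if dq > 0 else "anion"


def aggregate_repeats(
    per_lipid_per_repeat: np.ndarray, estimator: str = "multistate",
    overlap_diagnostics=None,
) -> FEPResult:
    """Build an FEPResult from a (n_repeats, n_lipids) array of bound-minus-
    free values; per-lipid values are means over repeats and the total error
    is the std of per-repeat totals (matching the reporting convention)."""
    arr = np.atleast_2d(np.asarray(per_lipid_per_repeat, dtype=float))
    n_rep = arr.shape[0]
    per_lipid = arr.mean(axis=0)
    per_err = arr.std(axis=0, ddof=1) if n_rep > 1 else np.zeros(arr.shape[1])
    totals = arr.sum(axis=1)
    total_err = float(totals.std(ddof=1)) if n_rep > 1 else 0.0
    return FEPResult(
        per_lipid_ddg=[float(x) for x in per_lipid],
        per_lipid_err=[float(x) for x in per_err],
        total_error=total_err,
        n_repeats=n_rep,
        estimator=estimator,
        overlap_diagnostics=list(overlap_diagnostics or []),
    )


def fep_pmf_consistency(
    fep: FEPResult, delta_pmf_value: float, delta_pmf_err: float
) -> ConsistencyReport:
    """Internal cross-check: total FEP vs the PMF well-depth difference."""
    discrepancy = float(fep.total - delta_pmf_value)
    combined = float(np.hypot(fep.total_error, delta_pmf_err))
    return ConsistencyReport(
        total_fep=float(fep.total),
        delta_pmf=float(delta_pmf_value),
        discrepancy=discrepancy,
        combined_error=combined,
        consistent=bool(abs(discrepancy) <= 2.0 * combined),
    )
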