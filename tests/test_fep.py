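import numpy as np
import pytest

from membind.constants import kt
from membind.errors import PoorOverlapError, ScheduleMismatchError
from membind.fep import (
    FEPResult,
    aggregate_repeats,
    bar_chain,
    bar_pair,
    binding_ddg,
    counterion_neutralizer_count,
    fep_pmf_consistency,
    multistate_free_energy,
    total_fep,
)
from membind.toysim import SimParams, build_bilayer, generate_lambda_set, make_c2_like_body
from membind.toysim.sampling import LambdaWindowSet

from .conftest import make_state

KBT = kt(323.0)


def harmonic_lambda_set(k_start=1000.0, k_end=2000.0, n_states=21, n=2000, seed=5):
    rng = np.random.default_rng(seed)
    ks = np.geomspace(k_start, k_end, n_states)
    u = np.zeros((n_states, n_states, n))
    for a in range(n_states):
        x = rng.normal(0, np.sqrt(KBT / ks[a]), n)
        u[a] = 0.5 * ks[None, :, None] * x[None, None, :] ** 2 / KBT
    return LambdaWindowSet(
        lambdas=np.linspace(0, 1, n_states),
        reduced_potentials=u,
        samples_per_state=n,
    )


class TestBarPair:
    def test_identical_states_zero(self):
        z = np.zeros(500)
        assert bar_pair(z, z, 323.0).delta_g == pytest.approx(0.0, abs=1e-10)

    def test_harmonic_closed_form(self):
        # dG = (1/2) kT ln(k2/k1) = 0.931 kJ/mol at 323 K
        rng = np.random.default_rng(5)
        k1, k2, n = 1000.0, 2000.0, 5000
        x0 = rng.normal(0, np.sqrt(KBT / k1), n)
        x1 = rng.normal(0, np.sqrt(KBT / k2), n)
        res = bar_pair(0.5 * (k2 - k1) * x0**2, 0.5 * (k1 - k2) * x1**2, 323.0)
        exact = 0.5 * KBT * np.log(2.0)
        assert exact == pytest.approx(0.931, abs=5e-4)
        assert abs(res.delta_g - exact) < 3 * res.se

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(1)
        uf = rng.normal(1.0, 0.5, 300)
        ur = rng.normal(-0.5, 0.5, 400)
        a = bar_pair(uf, ur, 323.0)
        b = bar_pair(ur, uf, 323.0)
        assert a.delta_g == pytest.approx(-b.delta_g, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bar_pair(np.array([]), np.zeros(3), 323.0)

    def test_poor_overlap_raises(self):
        uf = np.full(200, 5000.0)
        ur = np.full(200, 5000.0)
        with pytest.raises(PoorOverlapError):
            bar_pair(uf, ur, 323.0)


class TestMultistate:
    def test_two_identical_states(self):
        u = np.zeros((2, 2, 100))
        lset = LambdaWindowSet(np.array([0.0, 1.0]), u, 100)
        res = multistate_free_energy(lset)
        assert res.delta_g == pytest.approx(0.0, abs=1e-10)

    def test_matches_bar_chain_and_closed_form(self):
        lset = harmonic_lambda_set()
        ms = multistate_free_energy(lset)
        chain_dg, chain_se = bar_chain(lset)
        exact = 0.5 * KBT * np.log(2.0)
        assert abs(ms.delta_g - exact) < 3 * ms.delta_g_err
        assert abs(ms.delta_g - chain_dg) < 2 * np.hypot(ms.delta_g_err, chain_se)

    def test_matches_quadrature_on_mean_field_single_bead(self):
        # one charged bead over the mean-field plane: each state's partition
        # function is a 1D integral
        from membind.toysim import ProteinBody
        from membind.toysim.energy import energy_vs_z

        pos = np.array([[0.2, 0, 0], [0, 0.2, 0], [0, 0, 0.2], [-0.2, -0.2, -0.2]])
        body = ProteinBody(pos, np.array([0.0, 0.0, 2.0, 0.0]), ["core"] * 4)
        bl = build_bilayer(80, {"PC": 0.8, "PS": 0.15, "PIP2": 0.05}, seed=1,
                           mode="mean-field")
        st = make_state(body, bl, com=(3.5, 3.5, 2.0))
        p = SimParams(surface_affinity=0.5, bjerrum_prefactor=1.5)
        lset = generate_lambda_set(st, p, n_states=11, n_samples=4000, seed=9)
        res = multistate_free_energy(lset)
        z = np.arange(0.02, p.upper_wall_distance, 0.001)
        g = []
        for lam in (0.0, 1.0):
            u = energy_vs_z(st, p, z, lam=lam)
            g.append(-KBT * np.log(np.trapezoid(np.exp(-u / KBT), z)))
        exact = g[1] - g[0]
        assert res.delta_g == pytest.approx(exact, abs=0.1)

    def test_closed_cycle_sums_to_zero(self):
        # forward path + reversed path = closed cycle
        lset = harmonic_lambda_set(n_states=7, n=1500, seed=3)
        rev = LambdaWindowSet(
            lambdas=lset.lambdas,
            reduced_potentials=lset.reduced_potentials[::-1, ::-1, :],
            samples_per_state=lset.samples_per_state,
        )
        fwd = multistate_free_energy(lset)
        bwd = multistate_free_energy(rev)
        cycle = fwd.delta_g + bwd.delta_g
        err = np.hypot(fwd.delta_g_err, bwd.delta_g_err)
        assert abs(cycle) < 2 * max(err, 1e-6)

    def test_overlap_diagnostics_reported(self):
        lset = harmonic_lambda_set(n_states=5, n=500)
        res = multistate_free_energy(lset)
        assert res.overlap.shape == (4,)
        assert np.all(res.overlap > 0.1)


class TestBindingDdg:
    def test_equal_legs_zero(self):
        assert binding_ddg(5.0, 5.0).reported == 0.0

    def test_schedule_mismatch(self):
        with pytest.raises(ScheduleMismatchError):
            binding_ddg(1.0, 0.0, np.linspace(0, 1, 21), np.linspace(0, 1, 11))

    def test_toy_attraction_on_positive_off_zero(self, body, params):
        bl = build_bilayer(80, {"PC": 0.8, "PS": 0.15, "PIP2": 0.05}, seed=1,
                           mode="mean-field")
        st = make_state(body, bl, com=(3.5, 3.5, 1.0))
        p_on = SimParams(surface_affinity=1.0, bjerrum_prefactor=1.2)
        lset = generate_lambda_set(st, p_on, n_states=11, n_samples=1500, seed=2)
        free = generate_lambda_set(st, p_on, n_states=11, n_samples=1500, seed=3,
                                   include_protein=False)
        dg_bound = multistate_free_energy(lset).delta_g
        dg_free = multistate_free_energy(free).delta_g
        on = binding_ddg(dg_bound, dg_free)
        assert on.reported > 1.0  # favorable PIP2 binding -> positive

        neutral = make_c2_like_body(patch_charge=0.0, top_charge=0.0)
        st0 = make_state(neutral, bl, com=(3.5, 3.5, 1.0))
        lset0 = generate_lambda_set(st0, p_on, n_states=11, n_samples=1500, seed=4)
        off = binding_ddg(multistate_free_energy(lset0).delta_g, dg_free)
        assert abs(off.reported) < 0.2


class TestTotalFep:
    def test_kibra_row(self):
        total, _ = total_fep([6, 7, 7, 6])
        assert total == pytest.approx(26.0)

    def test_empty(self):
        assert total_fep([]) == (0.0, 0.0)

    def test_pten_row_rounded_addends(self):
        # printed addends are rounded; the printed total (32.8) reflects
        # unrounded values, so +-0.5 slack is expected
        total, _ = total_fep([10, 7, 9, 7])
        assert total == pytest.approx(33.0)
        assert abs(total - 32.8) <= 0.5

    def test_error_quadrature(self):
        _, err = total_fep([1.0, 2.0], [3.0, 4.0])
        assert err == pytest.approx(5.0)


class TestCounterions:
    def test_pip2_to_pc_needs_five_cations(self):
        assert counterion_neutralizer_count(-5, 0) == (5, "cation")

    def test_no_change(self):
        assert counterion_neutralizer_count(-1, -1) == (0, "none")

    def test_ps_to_pc(self):
        assert counterion_neutralizer_count(-1, 0) == (1, "cation")

    def test_anion_direction(self):
        assert counterion_neutralizer_count(0, -2) == (2, "anion")

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            counterion_neutralizer_count(-4.5, 0)


class TestAggregateAndConsistency:
    def test_aggregate_repeats_totals(self):
        rng = np.random.default_rng(0)
        arr = rng.normal([6, 7, 7, 6], 0.5, size=(5, 4))
        res = aggregate_repeats(arr)
        assert res.n_repeats == 5
        assert res.total == pytest.approx(arr.sum(axis=1).mean())
        assert res.total_error == pytest.approx(arr.sum(axis=1).std(ddof=1))
        assert res.total == pytest.approx(np.sum(res.per_lipid_ddg), abs=1e-9)

    def test_five_repeat_std_consistency(self):
        # reported std should match the between-repeat spread by construction
        arr = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        res = aggregate_repeats(arr)
        assert res.total_error == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))

    def _fep(self, total_parts, err):
        return FEPResult(
            per_lipid_ddg=list(total_parts),
            per_lipid_err=[0.0] * len(total_parts),
            total_error=err,
            n_repeats=5,
        )

    def test_kibra_consistent(self):
        rep = fep_pmf_consistency(self._fep([6.5, 6.5, 6.5, 6.5], 3.9), 22.0, 2.1)
        assert rep.total_fep == pytest.approx(26.0)
        assert rep.discrepancy == pytest.approx(4.0)
        assert rep.consistent

    def test_pi3k_back_mode_inconsistent(self):
        rep = fep_pmf_consistency(self._fep([10, 7, 4, 9.9], 4.1), 72.4, 2.7)
        assert not rep.consistent

    def test_identical_inputs(self):
        rep = fep_pmf_consistency(self._fep([5.0, 5.0], 1.0), 10.0, 1.0)
        assert rep.discrepancy == 0.0
        assert rep.consistent
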