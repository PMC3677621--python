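"""Equilibrium location, census and local stability classification."""

import numpy as np
import pytest

from seirvax import (
    classify_stability,
    compute_delta,
    disease_free_equilibrium,
    endemic_diagnostics,
    endemic_scalar_residual,
    find_all_equilibria,
    sample_random_params,
    solve_endemic,
)
from seirvax.equilibria import endemic_curves
from seirvax.exceptions import DomainError


def quartic_roots(p):
    """Independent root oracle: real roots of the denominator-cleared quartic.

    f1(i) * (b + eps - alpha i) * (alpha + gamma + b - alpha i) - g(i) as a
    polynomial, solved by companion-matrix eigenvalues.
    """
    (c2, c1, c0), g_slope, g_intercept = endemic_curves(p)
    f1 = np.array([c2, c1, c0])
    l1 = np.array([-p.alpha, p.b + p.epsilon])
    l2 = np.array([-p.alpha, p.alpha + p.gamma + p.b])
    h = np.polymul(np.polymul(f1, l1), l2)
    h[-2:] -= np.array([g_slope, g_intercept])
    r = np.roots(h)
    return sorted(r.real[np.abs(r.imag) < 1e-10])


class TestDiseaseFree:
    def test_benchmark_location(self, ref_params):
        rec = disease_free_equilibrium(ref_params)
        assert round(rec.location.s, 4) == 0.9091
        assert rec.location.e == 0.0 and rec.location.i == 0.0
        assert rec.residual == 0.0

    def test_without_vaccination(self, ref_params):
        rec = disease_free_equilibrium(ref_params.replace(sigma_a=0.0))
        assert rec.location.s == 1.0

    def test_classification_benchmark_unstable(self, ref_params):
        assert disease_free_equilibrium(ref_params).label == "unstable"

    def test_classification_no_transmission_stable(self, ref_params):
        p = ref_params.replace(beta=0.0)
        rec = disease_free_equilibrium(p)
        assert rec.label == "stable"
        got = sorted(v.real for v in rec.eigenvalues)
        expected = sorted([-(p.sigma_a + p.b), -(p.b + p.epsilon), -(p.alpha + p.gamma + p.b)])
        assert got == pytest.approx(expected, rel=1e-12)


class TestScalarResidual:
    def test_zero_at_endemic_root(self, ref_params):
        rec = solve_endemic(ref_params)
        assert abs(endemic_scalar_residual(rec.location.i, ref_params)) < 1e-12

    def test_negative_near_zero_when_R0_exceeds_one(self, ref_params):
        assert endemic_scalar_residual(1e-8, ref_params) < 0

    def test_single_sign_change_on_unit_interval(self, ref_params):
        grid = np.linspace(1e-9, 1 - 1e-9, 100_001)
        vals = np.array([endemic_scalar_residual(i, ref_params) for i in grid[:: 1]])
        sign_changes = int(np.sum(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0))
        assert sign_changes == 1

    def test_domain_restricted_to_open_unit_interval(self, ref_params):
        with pytest.raises(DomainError):
            endemic_scalar_residual(1.5, ref_params)
        with pytest.raises(DomainError):
            endemic_scalar_residual(0.0, ref_params)


class TestSolveEndemic:
    def test_benchmark_matches_reported_point(self, ref_params):
        rec = solve_endemic(ref_params)
        assert rec is not None and rec.kind == "endemic"
        assert rec.location.e == pytest.approx(0.00018673, abs=2e-8)
        assert round(rec.location.i, 4) == 0.0019
        assert rec.location.s == pytest.approx(0.0911, abs=1e-4)
        assert rec.residual < 1e-9
        assert rec.label == "stable"

    def test_agrees_with_polynomial_oracle(self, ref_params):
        rec = solve_endemic(ref_params)
        roots = [r for r in quartic_roots(ref_params) if 0 < r < 1]
        assert len(roots) == 1
        assert rec.location.i == pytest.approx(roots[0], rel=1e-10)

    def test_none_below_threshold(self, ref_params):
        # scaling beta down drives R01 ~ 0.22 < 1: no endemic state
        assert solve_endemic(ref_params.replace(beta=0.001)) is None

    def test_back_substitution_closure(self):
        n = seed = 0
        while n < 30:
            seed += 1
            p = sample_random_params(40_000 + seed, ("b>=alpha",))
            if compute_delta(p).ratio <= 1.0:
                continue
            n += 1
            rec = solve_endemic(p)
            i, e = rec.location.i, rec.location.e
            assert e == pytest.approx(i * (p.alpha + p.gamma + p.b - p.alpha * i) / p.epsilon, rel=1e-12)

    def test_infeasible_branch_roots_filtered_but_censused(self):
        # below-replacement regime (b < alpha): the scalar equation has two
        # roots with i in (0, 1) whose back-substituted states leave T; the
        # endemic solver must ignore them, the census must keep them
        p = sample_random_params(1)
        assert p.b < p.alpha
        assert solve_endemic(p) is None
        recs = find_all_equilibria(p, (0.0, 1.0))
        branch = [r for r in recs if r.kind != "disease-free"]
        assert len(branch) == 2
        assert all(not r.feasible for r in branch)


class TestCensus:
    def test_benchmark_unit_interval(self, ref_params):
        recs = find_all_equilibria(ref_params, (0.0, 1.0))
        assert len(recs) == 2
        assert [r.kind for r in recs] == ["disease-free", "endemic"]
        assert all(r.residual < 1e-9 for r in recs)

    def test_benchmark_wide_interval(self, ref_params):
        recs = find_all_equilibria(ref_params, (0.0, 30.0))
        assert len(recs) == 5
        infeasible = [r for r in recs if not r.feasible]
        assert len(infeasible) == 3
        assert all(r.kind == "other" for r in infeasible)
        assert all(r.residual < 1e-9 for r in recs)
        i_values = [r.location.i for r in recs]
        assert i_values == sorted(i_values)

    def test_wide_census_matches_polynomial_oracle(self, ref_params):
        recs = find_all_equilibria(ref_params, (0.0, 30.0))
        got = [r.location.i for r in recs if r.kind != "disease-free"]
        expected = [r for r in quartic_roots(ref_params) if 0 < r < 30]
        assert got == pytest.approx(expected, rel=1e-8)

    def test_no_transmission_only_disease_free(self, ref_params):
        recs = find_all_equilibria(ref_params.replace(beta=0.0), (0.0, 50.0))
        assert len(recs) == 1 and recs[0].kind == "disease-free"

    def test_uniqueness_in_unit_interval(self):
        n = seed = 0
        while n < 50:
            seed += 1
            p = sample_random_params(50_000 + seed, ("b>=alpha",))
            if compute_delta(p).ratio <= 1.0:
                continue
            n += 1
            rec = solve_endemic(p)  # raises AmbiguousRootsError on multiplicity
            assert rec is not None


class TestDiagnosticsAndClassification:
    def test_diagnostics_report_curves_and_roots(self, ref_params):
        d = endemic_diagnostics(ref_params, (0.0, 1.0))
        assert len(d.i_roots) == 1
        c2, c1, c0 = d.f1_coefficients
        assert c0 == pytest.approx(ref_params.sigma_a + ref_params.b, rel=1e-15)
        assert d.g_slope < 0 < d.g_intercept

    def test_classify_fills_spectrum(self, ref_params):
        rec = solve_endemic(ref_params)
        rec2 = classify_stability(rec, ref_params)
        assert len(rec2.eigenvalues) == 3
        assert rec2.max_real_part == max(v.real for v in rec2.eigenvalues)
        assert rec2.label in {"stable", "unstable", "marginal"}
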