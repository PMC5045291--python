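"""Binding isotherm, fitting, and coupled-equilibrium solver tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from cafarch.binding import (
    BindingFitParams,
    EquilibriumScheme,
    LigandDepletionModel,
    TitrationSeries,
    fit_kd,
    fraction_bound_ligand_depletion,
    signal_from_fraction,
    solve_coupled_equilibrium,
)
from cafarch.simulate import default_titrant_grid, gen_titration


def mass_balance_fraction(kd, a_tot, b_tot):
    """Independent oracle: root-find the free-ligand mass balance.

    A_free solves a_tot = A_free * (1 + B_free/kd) with
    B_free = b_tot - (a_tot - A_free); bound fraction = 1 - A_free/a_tot.
    """
    if b_tot == 0:
        return 0.0

    def eq(a_free):
        ab = a_tot - a_free
        b_free = b_tot - ab
        return a_free * b_free - kd * ab

    lo, hi = 1e-30 * a_tot, a_tot
    return 1.0 - brentq(eq, lo, hi, xtol=1e-30, rtol=1e-15) / a_tot


class TestFractionBound:
    def test_no_titrant_gives_zero(self):
        assert fraction_bound_ligand_depletion(1e-9, 25e-9, 0.0) == 0.0

    def test_stoichiometric_saturation_in_tight_limit(self):
        # kd -> 0 with equimolar titrant: everything pairs up
        assert fraction_bound_ligand_depletion(0.0, 25e-9, 25e-9) == pytest.approx(1.0)

    def test_matches_mass_balance_oracle(self):
        # frozen from the oracle: kd=100 nM, a*=25 nM, b=100 nM -> 0.46887...
        got = fraction_bound_ligand_depletion(100e-9, 25e-9, 100e-9)
        assert got == pytest.approx(0.4688711, abs=1e-6)
        assert got == pytest.approx(mass_balance_fraction(100e-9, 25e-9, 100e-9), rel=1e-9)

    @given(
        kd=st.floats(1e-12, 1e-3),
        a=st.floats(1e-12, 1e-4),
        b=st.floats(0, 1e-3),
    )
    def test_oracle_agreement_and_range(self, kd, a, b):
        frac = fraction_bound_ligand_depletion(kd, a, b)
        assert 0.0 <= frac <= 1.0
        assert frac == pytest.approx(mass_balance_fraction(kd, a, b), rel=1e-9, abs=1e-12)

    @given(
        kd=st.floats(1e-10, 1e-5),
        a=st.floats(1e-10, 1e-6),
        data=st.data(),
    )
    def test_monotone_in_b_and_kd(self, kd, a, data):
        b1 = data.draw(st.floats(0, 1e-4))
        b2 = data.draw(st.floats(0, 1e-4))
        lo, hi = sorted((b1, b2))
        assert (fraction_bound_ligand_depletion(kd, a, hi)
                >= fraction_bound_ligand_depletion(kd, a, lo) - 1e-12)
        # nonincreasing in kd at fixed b
        assert (fraction_bound_ligand_depletion(2 * kd, a, hi)
                <= fraction_bound_ligand_depletion(kd, a, hi) + 1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fraction_bound_ligand_depletion(1e-9, 0.0, 1e-9)
        with pytest.raises(ValueError):
            fraction_bound_ligand_depletion(1e-9, 1e-9, -1e-9)


class TestSignalFromFraction:
    @pytest.mark.parametrize("frac,expected", [(0.0, 1.0), (1.0, 1.5), (0.469, 1.2345)])
    def test_linear_model(self, frac, expected):
        p = BindingFitParams(kd=1e-9, f0=1.0, fmax=0.5)
        assert signal_from_fraction(p, frac) == pytest.approx(expected)

    def test_out_of_range_fraction(self):
        p = BindingFitParams(kd=1e-9, f0=1.0, fmax=0.5)
        with pytest.raises(ValueError):
            signal_from_fraction(p, 1.2)


def profiled_grid_fit(series, kd_grid):
    """Brute-force oracle: dense grid on kd with (f0, fmax) profiled out by
    linear least squares (the model is linear in them at fixed kd)."""
    b, y, a = series.titrant_concs, series.signal, series.labeled_conc
    best = (np.inf, None)
    for kd in kd_grid:
        frac = np.array([fraction_bound_ligand_depletion(kd, a, bi) for bi in b])
        design = np.column_stack([np.ones_like(frac), frac])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ coef) ** 2))
        if rss < best[0]:
            best = (rss, kd)
    return best[1]


class TestFitKd:
    def test_exact_recovery_noiseless(self):
        series = gen_titration(50e-9, 25e-9, noise_sd=0.0, seed=0)
        params = fit_kd(series)
        assert params.status == "ok"
        assert params.kd == pytest.approx(50e-9, rel=1e-6)
        assert params.f0 == pytest.approx(0.05, abs=1e-8)
        assert params.fmax == pytest.approx(0.10, abs=1e-8)

    def test_non_saturating_flagged_not_calculable(self):
        kd = 1e-6
        grid = np.linspace(1e-9, 0.1 * kd, 8)  # max titrant far below kd
        series = gen_titration(kd, 10e-9, b_grid=grid, noise_sd=0.002, seed=3)
        params = fit_kd(series)
        assert params.status == "n.c."
        assert not params.calculable

    def test_matches_grid_search_oracle(self):
        series = gen_titration(80e-9, 25e-9, noise_sd=0.005, seed=7)
        params = fit_kd(series)
        coarse = np.logspace(-9, -5, 200)
        k1 = profiled_grid_fit(series, coarse)
        fine = k1 * np.exp(np.linspace(-0.3, 0.3, 121))  # ~0.5% spacing
        k2 = profiled_grid_fit(series, fine)
        assert params.kd == pytest.approx(k2, rel=0.01)

    def test_median_recovery_under_noise(self):
        kd = 50e-9
        recovered = []
        for seed in range(60):
            series = gen_titration(kd, 25e-9, noise_sd=0.005, seed=seed)
            p = fit_kd(series)
            if p.calculable:
                recovered.append(p.kd)
        assert np.median(recovered) == pytest.approx(kd, rel=0.15)

    def test_too_few_points_rejected(self):
        series = TitrationSeries(25e-9, [1e-9, 2e-9, 4e-9, 8e-9], [0.05, 0.06, 0.07, 0.08])
        with pytest.raises(ValueError):
            LigandDepletionModel(series)

    def test_model_results_surface(self):
        series = gen_titration(50e-9, 25e-9, noise_sd=0.0, seed=0)
        res = LigandDepletionModel(series).fit()
        assert res.kd == res.params.kd
        assert set(res.bse) == {"kd", "f0", "fmax"}
        assert "Kd" in res.summary()
        assert np.allclose(res.resid, 0.0, atol=1e-7)


class TestCoupledEquilibrium:
    def test_no_binding_limit(self):
        sch = EquilibriumScheme(k1=1e6, k2=1e6, ktet=1e6,
                                total_chaperone=1e-6, total_dimer=1e-6)
        out = solve_coupled_equilibrium(sch)
        assert out["C"] == pytest.approx(1e-6, rel=1e-6)
        assert out["D"] == pytest.approx(1e-6, rel=1e-6)
        assert out["CD"] < 1e-15 and out["CD2"] < 1e-20 and out["T"] < 1e-15

    def test_collapses_to_closed_form_quadratic(self):
        # negligible tetramerization and second site: the scheme reduces to
        # one-site binding of D to C, i.e. the ligand-depletion quadratic.
        k1, ct, dt = 5e-8, 2.5e-8, 1e-7
        sch = EquilibriumScheme(k1=k1, k2=1e6, ktet=1e6,
                                total_chaperone=ct, total_dimer=dt)
        out = solve_coupled_equilibrium(sch)
        frac = fraction_bound_ligand_depletion(k1, ct, dt)
        assert out["CD"] == pytest.approx(frac * ct, rel=1e-8)

    @given(
        k1=st.floats(1e-9, 1e-3), k2=st.floats(1e-9, 1e-3),
        ktet=st.floats(1e-9, 1e-3),
        ct=st.floats(1e-9, 1e-4), dt=st.floats(1e-9, 1e-4),
    )
    def test_conservation(self, k1, k2, ktet, ct, dt):
        out = solve_coupled_equilibrium(EquilibriumScheme(k1, k2, ktet, ct, dt))
        c_sum = out["C"] + out["CD"] + out["CD2"]
        d_sum = out["D"] + 2 * out["T"] + out["CD"] + 2 * out["CD2"]
        assert c_sum == pytest.approx(ct, rel=1e-9)
        assert d_sum == pytest.approx(dt, rel=1e-9)
        assert all(v >= 0 for v in out.values())

    def test_zero_totals(self):
        out = solve_coupled_equilibrium(EquilibriumScheme(1e-9, 1e-9, 1e-9, 0.0, 0.0))
        assert all(v == 0.0 for v in out.values())

    def test_mass_action_relations_hold(self):
        sch = EquilibriumScheme(k1=1e-8, k2=5e-8, ktet=1e-5,
                                total_chaperone=1e-6, total_dimer=2e-6)
        out = solve_coupled_equilibrium(sch)
        assert out["CD"] == pytest.approx(out["C"] * out["D"] / sch.k1, rel=1e-9)
        assert out["CD2"] == pytest.approx(out["CD"] * out["D"] / sch.k2, rel=1e-9)
        assert out["T"] == pytest.approx(out["D"] ** 2 / sch.ktet, rel=1e-9)


def test_default_titrant_grid_spans_kd():
    g = default_titrant_grid(50e-9)
    assert g.size == 12
    assert g[0] == pytest.approx(5e-9)
    assert g[-1] == pytest.approx(500e-9)
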