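"""Equilibrium binding models for chaperone–histone titrations.

The central object is the one-site binding isotherm with ligand depletion:
the labeled species A* is held at a fixed concentration comparable to the
dissociation constant, so the free-titrant approximation fails and the
bound fraction is the root of the mass-balance quadratic,

    f_bound = ((Kd + [A*] + [B]) - sqrt((Kd + [A*] + [B])^2 - 4 [A*][B])) / (2 [A*]),

with the observed signal (anisotropy) modelled as ``f0 + fmax * f_bound``.
`LigandDepletionModel` fits (Kd, f0, fmax) to a `TitrationSeries` by
nonlinear least squares; `LigandDepletionResults` carries estimates,
standard errors, and a not-calculable flag for titrations that never reach
saturation.

A coupled three-equilibrium scheme for a chaperone C binding one or two
histone dimers D (C + D <-> CD with K1, CD + D <-> CD2 with K2) competing
with free-histone tetramerization (D + D <-> T with Ktet) is solved
numerically by `solve_coupled_equilibrium`; when tetramerization is
negligible and the second binding site is shut off it collapses to the
closed-form quadratic above.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np
from scipy.optimize import root

__all__ = [
    "TitrationSeries",
    "BindingFitParams",
    "EquilibriumScheme",
    "LigandDepletionModel",
    "LigandDepletionResults",
    "fraction_bound_ligand_depletion",
    "signal_from_fraction",
    "fit_kd",
    "solve_coupled_equilibrium",
]

STATUS_OK = "ok"
STATUS_NOT_CALCULABLE = "n.c."


@dataclass
class TitrationSeries:
    """One binding titration at fixed labeled-species concentration.

    Parameters
    ----------
    labeled_conc : float
        Concentration of the labeled species [A*], molar. Must be > 0.
    titrant_concs : ndarray
        Titrant concentrations [B]_i, molar, nonnegative, strictly increasing.
    signal : ndarray
        Anisotropy (or other saturable signal) at each titrant concentration.
    meta : dict
        Free-form provenance (buffer, temperature, ground truth for synthetic data).
    """

    labeled_conc: float
    titrant_concs: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.titrant_concs = np.asarray(self.titrant_concs, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if not self.labeled_conc > 0:
            raise ValueError("labeled_conc must be positive")
        if self.titrant_concs.ndim != 1:
            raise ValueError("titrant_concs must be 1-D")
        if np.any(self.titrant_concs < 0):
            raise ValueError("titrant concentrations must be nonnegative")
        if np.any(np.diff(self.titrant_concs) <= 0):
            raise ValueError("titrant concentrations must be strictly increasing")
        if self.signal.shape != self.titrant_concs.shape:
            raise ValueError("signal length must equal titrant_concs length")

    def __len__(self) -> int:
        return self.titrant_concs.size


@dataclass
class BindingFitParams:
    """Fitted one-site ligand-depletion parameters.

    kd is the dissociation constant (molar); f0 the baseline signal; fmax the
    amplitude at saturation. ``status`` is "ok" or "n.c." (not calculable,
    for titrations that do not constrain the upper plateau).
    """

    kd: float
    f0: float
    fmax: float
    se_kd: float = float("nan")
    se_f0: float = float("nan")
    se_fmax: float = float("nan")
    status: str = STATUS_OK

    @property
    def calculable(self) -> bool:
        return self.status == STATUS_OK


@dataclass
class EquilibriumScheme:
    """Coupled chaperone/histone-dimer equilibria.

    k1 : Kd for C + D <-> CD (molar)
    k2 : Kd for CD + D <-> CD2 (molar)
    ktet : Kd for D + D <-> T, free-histone tetramerization (molar)
    total_chaperone, total_dimer : conserved totals (molar)
    """

    k1: float
    k2: float
    ktet: float
    total_chaperone: float
    total_dimer: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "ktet"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.total_chaperone < 0 or self.total_dimer < 0:
            raise ValueError("totals must be nonnegative")


def fraction_bound_ligand_depletion(kd: float, a_star: float, b: float) -> float:
    """Bound fraction of the labeled species under ligand depletion.

    Root of the quadratic mass balance for A + B <-> AB with [A]_tot = a_star,
    [B]_tot = b. ``kd = 0`` is accepted as the stoichiometric limit.
    """
    if not a_star > 0:
        raise ValueError("a_star must be positive")
    if b < 0:
        raise ValueError("titrant concentration b must be nonnegative")
    if kd < 0:
        raise ValueError("kd must be nonnegative")
    s = kd + a_star + b
    disc = s * s - 4.0 * a_star * b
    # disc >= (kd + |a_star - b|)^2 >= 0; clip roundoff. The conjugate form
    # 2b / (s + sqrt(disc)) avoids cancellation when 4ab << s^2.
    frac = 2.0 * b / (s + math.sqrt(max(disc, 0.0)))
    return min(max(frac, 0.0), 1.0)


def signal_from_fraction(params: BindingFitParams, fraction: float, *, tol: float = 1e-9) -> float:
    """Linear signal model ``f0 + fmax * fraction``."""
    if fraction < -tol or fraction > 1.0 + tol:
        raise ValueError("fraction must lie in [0, 1]")
    return params.f0 + params.fmax * float(np.clip(fraction, 0.0, 1.0))


def _forward(b: np.ndarray, kd: float, f0: float, fmax: float, a_star: float) -> np.ndarray:
    s = kd + a_star + b
    disc = np.clip(s * s - 4.0 * a_star * b, 0.0, None)
    frac = 2.0 * b / (s + np.sqrt(disc))
    return f0 + fmax * frac


class LigandDepletionModel:
    """One-site ligand-depletion isotherm as a fittable model.

    Parameters
    ----------
    series : TitrationSeries
        The titration data; ``series.labeled_conc`` is held fixed during the fit.
    weights : array-like, optional
        Per-point weights for the least squares (default: unweighted).

    Examples
    --------
    >>> model = LigandDepletionModel(series)
    >>> res = model.fit()
    >>> res.params.kd, res.params.se_kd
    """

    def __init__(self, series: TitrationSeries, weights: Sequence[float] | None = None):
        if len(series) < 5:
            raise ValueError("need at least 5 titration points to fit 3 parameters")
        self.series = series
        self.weights = None if weights is None else np.asarray(weights, dtype=float)

    @classmethod
    def from_dataframe(cls, df, labeled_conc: float, *, titrant_col: str = "titrant_M",
                       signal_col: str = "r", **kwargs) -> "LigandDepletionModel":
        series = TitrationSeries(
            labeled_conc=labeled_conc,
            titrant_concs=df[titrant_col].to_numpy(dtype=float),
            signal=df[signal_col].to_numpy(dtype=float),
        )
        return cls(series, **kwargs)

    # -- initialization -------------------------------------------------
    def _kd_starts(self) -> list[float]:
        b = self.series.titrant_concs
        y = self.series.signal
        span = y[-1] - y[0]
        if span != 0:
            half = y[0] + 0.5 * span
            idx = int(np.argmin(np.abs(y - half)))
            k0 = max(b[idx], b[b > 0].min() if np.any(b > 0) else 1e-9)
        else:
            k0 = float(np.median(b[b > 0])) if np.any(b > 0) else 1e-9
        bmax = float(b.max())
        starts = [k0, 0.1 * k0, 10.0 * k0, bmax, 0.01 * bmax]
        return [max(s, 1e-15) for s in starts]

    def fit(self) -> "LigandDepletionResults":
        """Weighted nonlinear least squares with multi-start initialization."""
        b = self.series.titrant_concs
        y = self.series.signal
        a_star = self.series.labeled_conc
        span = y[-1] - y[0]

        lm_model = lmfit.Model(_forward, independent_vars=["b"])
        best = None
        for kd0 in self._kd_starts():
            pars = lm_model.make_params(
                kd=dict(value=kd0, min=1e-15),
                f0=dict(value=float(y[0])),
                fmax=dict(value=float(span) if span != 0 else float(np.ptp(y)) or 0.1),
            )
            pars["a_star"] = lmfit.Parameter(name="a_star", value=a_star, vary=False)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    out = lm_model.fit(y, pars, b=b, weights=self.weights)
            except Exception:
                continue
            if best is None or out.chisqr < best.chisqr:
                best = out
        if best is None:
            params = BindingFitParams(
                kd=float("nan"), f0=float("nan"), fmax=float("nan"),
                status=STATUS_NOT_CALCULABLE,
            )
            return LigandDepletionResults(self, params, lmfit_result=None)

        kd = float(best.params["kd"].value)
        se_kd = best.params["kd"].stderr
        se_kd = float(se_kd) if se_kd is not None else float("nan")
        params = BindingFitParams(
            kd=kd,
            f0=float(best.params["f0"].value),
            fmax=float(best.params["fmax"].value),
            se_kd=se_kd,
            se_f0=float(best.params["f0"].stderr or "nan"),
            se_fmax=float(best.params["fmax"].stderr or "nan"),
        )
        # Non-saturating data: the plateau is unconstrained when the estimated
        # Kd exceeds the highest titrant concentration, or the Kd standard
        # error exceeds 50% of the estimate (or could not be evaluated).
        bmax = float(b.max())
        if (not best.success) or kd > bmax or not np.isfinite(se_kd) or (kd > 0 and se_kd / kd > 0.5):
            params.status = STATUS_NOT_CALCULABLE
        return LigandDepletionResults(self, params, lmfit_result=best)


class LigandDepletionResults:
    """Fit results: parameter estimates, standard errors, diagnostics."""

    def __init__(self, model: LigandDepletionModel, params: BindingFitParams, lmfit_result=None):
        self.model = model
        self.params = params
        self.lmfit_result = lmfit_result

    @property
    def kd(self) -> float:
        return self.params.kd

    @property
    def bse(self) -> dict:
        return {"kd": self.params.se_kd, "f0": self.params.se_f0, "fmax": self.params.se_fmax}

    def predict(self, b=None) -> np.ndarray:
        b = self.model.series.titrant_concs if b is None else np.asarray(b, dtype=float)
        p = self.params
        return _forward(b, p.kd, p.f0, p.fmax, self.model.series.labeled_conc)

    @property
    def resid(self) -> np.ndarray:
        return self.model.series.signal - self.predict()

    def summary(self) -> str:
        p = self.params
        lines = [
            "One-site ligand-depletion binding fit",
            "=" * 45,
            f"n points           : {len(self.model.series)}",
            f"[A*] (fixed)       : {self.model.series.labeled_conc:.4g} M",
            f"status             : {p.status}",
        ]
        if p.calculable:
            lines += [
                f"Kd                 : {p.kd:.4g} M  (se {p.se_kd:.2g})",
                f"f0                 : {p.f0:.4g}  (se {p.se_f0:.2g})",
                f"fmax               : {p.fmax:.4g}  (se {p.se_fmax:.2g})",
                f"residual ssq       : {float(np.sum(self.resid ** 2)):.3g}",
            ]
        else:
            lines += ["Kd                 : not calculable (titration does not reach saturation)"]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data points and fitted curve on a log-concentration axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        b = self.model.series.titrant_concs
        ax.semilogx(b, self.model.series.signal, "o", label="data")
        if self.params.calculable:
            bb = np.logspace(np.log10(max(b[b > 0].min(), 1e-12)), np.log10(b.max()), 200)
            ax.semilogx(bb, self.predict(bb), "-", label="fit")
        ax.set_xlabel("titrant (M)")
        ax.set_ylabel("signal")
        ax.legend()
        return ax


def fit_kd(series: TitrationSeries, weights: Sequence[float] | None = None) -> BindingFitParams:
    """Fit the one-site ligand-depletion isotherm; see `LigandDepletionModel`."""
    return LigandDepletionModel(series, weights=weights).fit().params


def solve_coupled_equilibrium(scheme: EquilibriumScheme, *, rtol: float = 1e-9) -> Mapping[str, float]:
    """Solve the coupled chaperone/dimer/tetramer equilibria.

    Unknowns are the free concentrations (C, D); complexes follow from
    mass action: CD = C*D/k1, CD2 = CD*D/k2, T = D^2/ktet. Conservation:

        C_tot = C + CD + CD2
        D_tot = D + 2*T + CD + 2*CD2

    Solved in log space to enforce positivity, starting at 10% of totals.
    Returns a dict with keys C, D, T, CD, CD2 (molar). Raises RuntimeError
    (carrying the final residual) on non-convergence.
    """
    ct, dt = scheme.total_chaperone, scheme.total_dimer
    k1, k2, ktet = scheme.k1, scheme.k2, scheme.ktet
    if ct == 0 and dt == 0:
        return {"C": 0.0, "D": 0.0, "T": 0.0, "CD": 0.0, "CD2": 0.0}
    if ct == 0:
        # only dimer/tetramer equilibrium: quadratic in D
        d = (-ktet + math.sqrt(ktet * ktet + 8.0 * ktet * dt)) / 4.0
        return {"C": 0.0, "D": d, "T": d * d / ktet, "CD": 0.0, "CD2": 0.0}
    if dt == 0:
        return {"C": ct, "D": 0.0, "T": 0.0, "CD": 0.0, "CD2": 0.0}

    def species(c: float, d: float):
        cd = c * d / k1
        cd2 = cd * d / k2
        t = d * d / ktet
        return cd, cd2, t

    def residual(logx):
        with np.errstate(over="ignore"):
            c, d = np.exp(np.minimum(logx, 700.0))
            cd, cd2, t = species(c, d)
            return [
                (c + cd + cd2 - ct) / ct,
                (d + 2.0 * t + cd + 2.0 * cd2 - dt) / dt,
            ]

    x0 = np.log([0.1 * ct, 0.1 * dt])
    sol = root(residual, x0, method="hybr", tol=1e-13)
    res = np.max(np.abs(residual(sol.x)))
    if res > rtol:
        # polish from a grid of alternative starts before giving up
        for fc in (0.9, 0.5, 0.01):
            for fd in (0.9, 0.5, 0.01):
                trial = root(residual, np.log([fc * ct, fd * dt]), method="hybr", tol=1e-13)
                r = np.max(np.abs(residual(trial.x)))
                if r < res:
                    sol, res = trial, r
    if res > rtol:
        raise RuntimeError(f"coupled-equilibrium solve did not converge (relative residual {res:.3g})")
    c, d = np.exp(sol.x)
    cd, cd2, t = species(c, d)
    return {"C": float(c), "D": float(d), "T": float(t), "CD": float(cd), "CD2": float(cd2)}
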