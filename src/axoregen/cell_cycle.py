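"""Cumulative-labeling cell-cycle model and weighted least-squares fitting.

Under continuous availability of a thymidine analog (BrdU/EdU) from t = 0,
an asynchronously cycling population with fixed phase lengths accumulates
label as cells transit S-phase.  For a population in which each division
leaves ``r`` daughters proliferating, the labeled fraction among cycling
cells is the piecewise curve ``R'(t)`` implemented by :func:`rprime`;
quiescent cells dilute the signal through the growth fraction ``g(t)``
(:func:`growth_fraction`), giving the observable ``R(t) = g(t) R'(t)``.

``r`` encodes the division mode: ``r = 1`` for asymmetric neurogenic
divisions (one daughter stays a progenitor, the other differentiates and
is excluded from counts), ``r = 2`` for symmetric proliferative divisions.
For ``r = 2`` the cycling pool grows exponentially while the quiescent
pool is constant, so ``g(t)`` rises toward 1; for ``r = 1`` both pools are
constant and ``g(t) = GF``.

Fitting is weighted least squares on per-timepoint means and standard
deviations, with 68% confidence intervals from the parabolic approximation
of the SSE surface (the ΔSSE = 1 contour).  The API follows the
statsmodels Model/Results pattern: build a :class:`CumulativeLabelingModel`
from a :class:`LabelingTimecourse`, call :meth:`~CumulativeLabelingModel.fit`,
inspect the returned :class:`CellCycleResults`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "CellCycleParams",
    "LabelingTimecourse",
    "CellCycleResults",
    "CumulativeLabelingModel",
    "PhaseLengths",
    "MissingSaturationError",
    "rprime",
    "growth_fraction",
    "labeled_fraction",
    "sse",
    "fit_cell_cycle",
    "derive_phase_lengths",
    "estimate_tg2m",
    "extrapolate_full_cycle_differentiation",
]

PARAM_NAMES = ("T_C", "T_S", "T_G2M", "GF")

#: Default coarse grid of starting values for the local minimizer; the
#: piecewise SSE surface has local minima, so the optimum of the grid
#: seeds the polish step.
DEFAULT_GRID = {
    "T_C": tuple(float(x) for x in range(50, 501, 50)),
    "T_S_frac": (0.1, 0.2, 0.3, 0.4, 0.5),  # as a fraction of T_C
    "GF": (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
}


class MissingSaturationError(ValueError):
    """Raised when a labeled-mitoses timecourse never saturates at 1."""


@dataclass(frozen=True)
class CellCycleParams:
    """Cell-cycle parameters of one population.

    Parameters
    ----------
    T_C : float
        Cell cycle length in hours (> 0).
    T_S : float
        S-phase length in hours (> 0).
    T_G2M : float
        Combined G2 + M length in hours (>= 0).
    GF : float
        Growth fraction at labeling onset, in (0, 1].
    r : float
        Average number of daughters per division that remain
        proliferative: 1 (neurogenic) or 2 (proliferative).
    """

    T_C: float
    T_S: float
    T_G2M: float
    GF: float
    r: float

    def __post_init__(self) -> None:
        if not (self.T_C > 0 and self.T_S > 0 and self.T_G2M >= 0):
            raise ValueError("phase lengths must be positive (T_G2M may be 0)")
        if self.T_S + self.T_G2M >= self.T_C:
            raise ValueError("T_S + T_G2M must be smaller than T_C")
        if not (0 < self.GF <= 1):
            raise ValueError("GF must lie in (0, 1]")
        if self.r not in (1, 2):
            raise ValueError("r must be 1 (neurogenic) or 2 (proliferative)")

    @property
    def T_G1(self) -> float:
        return self.T_C - self.T_G2M - self.T_S

    def as_dict(self) -> dict[str, float]:
        return {
            "T_C": self.T_C,
            "T_S": self.T_S,
            "T_G2M": self.T_G2M,
            "GF": self.GF,
            "r": self.r,
        }


@dataclass(frozen=True)
class LabelingTimecourse:
    """Cumulative labeled-fraction measurements for one population."""

    population: str
    time_h: tuple[float, ...]
    fraction: tuple[float, ...]
    sd: tuple[float, ...]
    n_animals: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        f = np.asarray(self.fraction, dtype=float)
        s = np.asarray(self.sd, dtype=float)
        if not (t.size == f.size == s.size) or t.size == 0:
            raise ValueError("time_h, fraction and sd must be equal-length, non-empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_h must be strictly increasing")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")

    def __len__(self) -> int:
        return len(self.time_h)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, population: str | None = None
    ) -> "LabelingTimecourse":
        """Build from a table with columns population, time_h,
        fraction_labeled, sd and optionally n_animals."""
        if population is not None:
            df = df[df["population"] == population]
            if df.empty:
                raise ValueError(f"no rows for population {population!r}")
        else:
            pops = df["population"].unique()
            if len(pops) != 1:
                raise ValueError("multiple populations present; pass population=")
            population = str(pops[0])
        df = df.sort_values("time_h")
        n = (
            tuple(int(x) for x in df["n_animals"])
            if "n_animals" in df.columns
            else ()
        )
        return cls(
            population=str(population),
            time_h=tuple(float(x) for x in df["time_h"]),
            fraction=tuple(float(x) for x in df["fraction_labeled"]),
            sd=tuple(float(x) for x in df["sd"]),
            n_animals=n,
        )


# ---------------------------------------------------------------------------
# model curves
# ---------------------------------------------------------------------------


def _rprime_raw(t: np.ndarray, T_C: float, T_S: float, T_G2M: float, r: float) -> np.ndarray:
    """R'(t) without parameter validation (used by the fitter)."""
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    if r == 1:
        rising = t < T_C - T_S
        out[rising] = (T_S + t[rising]) / T_C
    else:
        denom = r - 1.0
        early = t < T_G2M
        mid = (t >= T_G2M) & (t < T_C - T_S)
        out[early] = (
            r ** ((T_G2M + T_S) / T_C) - r ** ((T_G2M - t[early]) / T_C)
        ) / denom
        out[mid] = 1.0 - (
            r ** ((T_C + T_G2M - t[mid]) / T_C) - r ** ((T_G2M + T_S) / T_C)
        ) / denom
    return np.clip(out, 0.0, 1.0)


def rprime(t: float | Sequence[float], params: CellCycleParams) -> float | np.ndarray:
    """Labeled fraction among proliferating cells at time ``t`` (hours).

    Piecewise in three regimes: before ``T_G2M`` only cells that were in
    S at onset or entered it since are labeled; between ``T_G2M`` and
    ``T_C - T_S`` every mitosis adds labeled daughters; from ``T_C - T_S``
    on, every cycling cell has transited S and R' = 1.
    """
    arr = _rprime_raw(np.atleast_1d(np.asarray(t, dtype=float)), params.T_C, params.T_S, params.T_G2M, params.r)
    if np.any(np.atleast_1d(np.asarray(t, dtype=float)) < 0):
        raise ValueError("t must be >= 0")
    return float(arr[0]) if np.isscalar(t) else arr


def _growth_fraction_raw(t: np.ndarray, GF: float, r: float, T_C: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if r == 1:
        return np.full_like(t, GF)
    grown = GF * r ** (t / T_C)
    return grown / (grown + 1.0 - GF)


def growth_fraction(
    t: float | Sequence[float], GF: float, r: float, T_C: float
) -> float | np.ndarray:
    """Fraction of counted cells that are cycling at time ``t``.

    Constant at GF for neurogenic divisions (r = 1); for proliferative
    divisions (r = 2) the cycling pool doubles every T_C while the
    quiescent pool is constant, so g(t) = GF r^{t/T_C} / (GF r^{t/T_C} + 1 - GF).
    """
    if not (0 < GF <= 1):
        raise ValueError("GF must lie in (0, 1]")
    if T_C <= 0:
        raise ValueError("T_C must be positive")
    if r not in (1, 2):
        raise ValueError("r must be 1 or 2")
    arr = _growth_fraction_raw(np.atleast_1d(np.asarray(t, dtype=float)), GF, r, T_C)
    return float(arr[0]) if np.isscalar(t) else arr


def _labeled_fraction_raw(
    t: np.ndarray, T_C: float, T_S: float, T_G2M: float, GF: float, r: float
) -> np.ndarray:
    return _growth_fraction_raw(t, GF, r, T_C) * _rprime_raw(t, T_C, T_S, T_G2M, r)


def labeled_fraction(
    t: float | Sequence[float], params: CellCycleParams
) -> float | np.ndarray:
    """Observable labeled fraction R(t) = g(t) R'(t)."""
    arr = _labeled_fraction_raw(
        np.atleast_1d(np.asarray(t, dtype=float)),
        params.T_C,
        params.T_S,
        params.T_G2M,
        params.GF,
        params.r,
    )
    return float(arr[0]) if np.isscalar(t) else arr


def sse(timecourse: LabelingTimecourse, params: CellCycleParams) -> float:
    """Weighted sum of squared errors Σ ((Rexp_i − R(t_i)) / σ_i)²."""
    s = np.asarray(timecourse.sd, dtype=float)
    if np.any(s <= 0):
        raise ValueError("all sd values must be > 0 for weighted fitting")
    t = np.asarray(timecourse.time_h, dtype=float)
    f = np.asarray(timecourse.fraction, dtype=float)
    model = _labeled_fraction_raw(
        t, params.T_C, params.T_S, params.T_G2M, params.GF, params.r
    )
    return float(np.sum(((f - model) / s) ** 2))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseLengths:
    """Derived phase lengths with linearly propagated 1σ errors."""

    T_M: float
    dT_M: float
    T_G1: float
    dT_G1: float
    mi: float
    dmi: float


class CellCycleResults:
    """Fit results: estimates, 68% CIs, SSE, convergence and diagnostics.

    Attributes
    ----------
    params : CellCycleParams
        Parameter estimates (fixed parameters at their fixed values).
    ci68 : dict
        Symmetric 68% confidence half-width per free parameter, from the
        parabolic (ΔSSE = 1) approximation.
    sse : float
        Weighted SSE at the optimum.
    converged : bool
        Whether the minimizer reported success.
    fixed : dict
        Names and values of parameters held fixed during the fit.
    """

    def __init__(
        self,
        model: "CumulativeLabelingModel",
        params: CellCycleParams,
        ci68: dict[str, float],
        sse_value: float,
        converged: bool,
        fixed: dict[str, float],
        n_grid_evals: int,
    ) -> None:
        self.model = model
        self.params = params
        self.ci68 = dict(ci68)
        self.sse = float(sse_value)
        self.converged = bool(converged)
        self.fixed = dict(fixed)
        self.n_grid_evals = int(n_grid_evals)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_NAMES if n not in self.fixed)

    def predict(self, t: Sequence[float]) -> np.ndarray:
        """Model curve R(t) on a time grid (hours)."""
        return np.asarray(labeled_fraction(np.asarray(t, dtype=float), self.params))

    def curve_frame(self, t: Sequence[float]) -> pd.DataFrame:
        t = np.asarray(t, dtype=float)
        return pd.DataFrame(
            {
                "time_h": t,
                "fraction_labeled": self.predict(t),
                "rprime": np.asarray(rprime(t, self.params)),
                "growth_fraction": np.asarray(
                    growth_fraction(t, self.params.GF, self.params.r, self.params.T_C)
                ),
            }
        )

    def derive_phase_lengths(self, mi: float, dmi: float = 0.0) -> PhaseLengths:
        """Phase lengths from the fit and a mitotic index; see
        :func:`derive_phase_lengths`."""
        return derive_phase_lengths(self, mi, dmi)

    def to_dict(self) -> dict:
        return {
            "population": self.model.timecourse.population,
            "division_mode": "proliferative" if self.params.r == 2 else "neurogenic",
            "estimates": self.params.as_dict(),
            "ci68": self.ci68,
            "sse": self.sse,
            "converged": self.converged,
            "fixed": self.fixed,
            "n_points": len(self.model.timecourse),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels spirit."""
        lines = [
            "Cumulative-labeling cell-cycle fit",
            "=" * 46,
            f"population:     {self.model.timecourse.population}",
            f"division mode:  r = {self.params.r:g}"
            + (" (proliferative)" if self.params.r == 2 else " (neurogenic)"),
            f"n timepoints:   {len(self.model.timecourse)}",
            f"SSE:            {self.sse:.4g}",
            f"converged:      {self.converged}",
            "-" * 46,
            f"{'param':>8} {'estimate':>12} {'68% CI (±)':>12} {'status':>8}",
        ]
        est = self.params.as_dict()
        for name in PARAM_NAMES:
            if name in self.fixed:
                lines.append(f"{name:>8} {est[name]:>12.4g} {'--':>12} {'fixed':>8}")
            else:
                lines.append(
                    f"{name:>8} {est[name]:>12.4g} {self.ci68[name]:>12.3g} {'free':>8}"
                )
        p = self.params
        lines.append("-" * 46)
        lines.append(f"derived T_G1 = T_C - T_G2M - T_S = {p.T_G1:.4g} h")
        return "\n".join(lines)


class CumulativeLabelingModel:
    """Weighted least-squares model for a cumulative-labeling timecourse.

    Parameters
    ----------
    timecourse : LabelingTimecourse
        Per-timepoint labeled fractions with standard deviations.
    r : float
        Division mode (1 neurogenic, 2 proliferative); never fitted.
    fixed : mapping, optional
        Parameters to hold fixed, e.g. ``{"T_G2M": 9.0}`` (the default:
        G2+M estimated independently from labeled-mitoses saturation).
    unweighted : bool
        If True, ignore the per-point sd and use σ_i = 1 (explicit
        opt-in fallback for tables without usable errors).

    Examples
    --------
    >>> model = CumulativeLabelingModel(tc, r=2)        # doctest: +SKIP
    >>> res = model.fit()                               # doctest: +SKIP
    >>> print(res.summary())                            # doctest: +SKIP
    """

    def __init__(
        self,
        timecourse: LabelingTimecourse,
        r: float,
        fixed: Mapping[str, float] | None = None,
        unweighted: bool = False,
    ) -> None:
        if r not in (1, 2):
            raise ValueError("r must be 1 or 2")
        fixed = dict(fixed) if fixed is not None else {"T_G2M": 9.0}
        unknown = set(fixed) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown fixed parameter(s): {sorted(unknown)}")
        if not unweighted and np.any(np.asarray(timecourse.sd) <= 0):
            raise ValueError(
                "sd values must be > 0 for weighted fitting; "
                "pass unweighted=True to fit with sigma = 1"
            )
        self.timecourse = timecourse
        self.r = float(r)
        self.fixed = fixed
        self.unweighted = bool(unweighted)
        free = [n for n in PARAM_NAMES if n not in fixed]
        if len(timecourse) < len(free):
            raise ValueError(
                f"{len(free)} free parameters but only {len(timecourse)} timepoints"
            )
        self._t = np.asarray(timecourse.time_h, dtype=float)
        self._f = np.asarray(timecourse.fraction, dtype=float)
        self._s = (
            np.ones_like(self._f)
            if unweighted
            else np.asarray(timecourse.sd, dtype=float)
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        population: str | None = None,
        r: float | None = None,
        **kwargs,
    ) -> "CumulativeLabelingModel":
        tc = LabelingTimecourse.from_dataframe(df, population=population)
        if r is None:
            r = 2.0 if tc.population == "regenerating" else 1.0
        return cls(tc, r=r, **kwargs)

    # -- objective ---------------------------------------------------------

    def _full_params(self, theta: np.ndarray, free: Sequence[str]) -> dict[str, float]:
        p = dict(self.fixed)
        p.update(dict(zip(free, theta)))
        return p

    def _objective(self, theta: np.ndarray, free: Sequence[str], penalized: bool = True) -> float:
        p = self._full_params(theta, free)
        T_C, T_S, T_G2M, GF = p["T_C"], p["T_S"], p["T_G2M"], p["GF"]
        feasible = (
            T_C > 0 and T_S > 0 and T_G2M >= 0 and GF > 0 and T_S + T_G2M < T_C
        )
        if penalized and (not feasible or GF > 1):
            # smooth-ish barrier so Nelder-Mead walks back into the box
            return 1e12 * (1.0 + abs(min(T_C - T_S - T_G2M, 0.0)) + abs(min(GF, 0.0)))
        model = _labeled_fraction_raw(self._t, T_C, T_S, T_G2M, min(GF, 1.0) if penalized else GF, self.r)
        return float(np.sum(((self._f - model) / self._s) ** 2))

    def _grid_starts(self, grid: Mapping[str, Sequence[float]]) -> Iterable[dict[str, float]]:
        for T_C in grid["T_C"]:
            for fs in grid["T_S_frac"]:
                for GF in grid["GF"]:
                    yield {"T_C": T_C, "T_S": fs * T_C, "T_G2M": self.fixed.get("T_G2M", 9.0), "GF": GF}

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        start: Mapping[str, float] | None = None,
        grid: Mapping[str, Sequence[float]] | None = None,
        n_starts: int = 8,
    ) -> CellCycleResults:
        """Minimize the weighted SSE and return a results object.

        The SSE surface is piecewise and multimodal, so a coarse grid
        over (T_C, T_S, GF) is scored first and the ``n_starts`` best
        grid points each seed a Nelder-Mead polish (with one restart
        from its own optimum to escape premature simplex collapse); the
        overall best polish wins.  68% CIs come from the ΔSSE = 1
        parabolic approximation via a finite-difference Hessian.
        """
        free = [n for n in PARAM_NAMES if n not in self.fixed]
        grid = dict(DEFAULT_GRID, **(grid or {}))
        n_grid = 0
        if start is not None:
            starts = [np.array([float(start[n]) for n in free])]
        else:
            scored = []
            for cand in self._grid_starts(grid):
                theta = np.array([cand[n] for n in free])
                scored.append((self._objective(theta, free), n_grid, theta))
                n_grid += 1
            scored.sort(key=lambda s: (s[0], s[1]))
            starts = [theta for _, _, theta in scored[: max(n_starts, 1)]]

        opts = {"xatol": 1e-6, "fatol": 1e-10, "maxiter": 5000, "maxfev": 8000}
        res = None
        for x0 in starts:
            cand = minimize(
                self._objective, x0, args=(free,), method="Nelder-Mead", options=opts
            )
            cand = minimize(  # restart at the found optimum
                self._objective, cand.x, args=(free,), method="Nelder-Mead", options=opts
            )
            if res is None or cand.fun < res.fun:
                res = cand
        theta_hat = res.x
        full = self._full_params(theta_hat, free)
        full["GF"] = min(full["GF"], 1.0)
        params = CellCycleParams(r=self.r, **full)
        ci = self._parabolic_ci(theta_hat, free)
        return CellCycleResults(
            model=self,
            params=params,
            ci68=ci,
            sse_value=float(res.fun),
            converged=bool(res.success),
            fixed=self.fixed,
            n_grid_evals=n_grid,
        )

    def _parabolic_ci(self, theta: np.ndarray, free: Sequence[str]) -> dict[str, float]:
        """68% half-widths from ΔSSE = 1: sqrt(2 diag(H⁻¹)) with H the
        finite-difference Hessian of the SSE at the optimum.

        The Hessian is evaluated on the unpenalized smooth extension of
        the objective so boundary optima (e.g. GF = 1) keep a defined
        curvature; if the Hessian is not positive definite the fallback
        is the per-parameter 1D curvature.
        """
        k = len(free)
        h = np.maximum(np.abs(theta) * 1e-3, 1e-5)
        H = np.empty((k, k))
        f0 = self._objective(theta, free, penalized=False)

        def f(x: np.ndarray) -> float:
            return self._objective(x, free, penalized=False)

        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
        ci: dict[str, float] = {}
        try:
            cov = 2.0 * np.linalg.inv(H)
            diag = np.diag(cov)
            if np.any(diag <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
            widths = np.sqrt(diag)
        except np.linalg.LinAlgError:
            widths = np.array(
                [math.sqrt(2.0 / H[i, i]) if H[i, i] > 0 else np.nan for i in range(k)]
            )
        for name, w in zip(free, widths):
            ci[name] = float(w)
        return ci


def fit_cell_cycle(
    timecourse: LabelingTimecourse,
    r: float,
    fixed: Mapping[str, float] | None = None,
    start: Mapping[str, float] | None = None,
    grid: Mapping[str, Sequence[float]] | None = None,
    unweighted: bool = False,
) -> CellCycleResults:
    """Convenience wrapper: build the model and fit in one call."""
    model = CumulativeLabelingModel(timecourse, r=r, fixed=fixed, unweighted=unweighted)
    return model.fit(start=start, grid=grid)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def derive_phase_lengths(
    fit: CellCycleResults, mi: float, dmi: float = 0.0
) -> PhaseLengths:
    """M- and G1-phase lengths from a fit and a mitotic index.

    Cells homogeneously distributed over the cycle imply
    T_M = mi · T_C and T_G1 = T_C − T_G2M − T_S, with 1σ errors by
    linear propagation (fixed parameters contribute zero error):

        ΔT_M  = sqrt((mi ΔT_C)² + (T_C Δmi)²)
        ΔT_G1 = sqrt(ΔT_C² + ΔT_G2M² + ΔT_S²)
    """
    if not (0 <= mi <= 1):
        raise ValueError("mi must lie in [0, 1]")
    if not fit.converged:
        raise ValueError("fit did not converge; phase lengths undefined")
    p = fit.params

    def err(name: str) -> float:
        return fit.ci68.get(name, 0.0)

    T_M = mi * p.T_C
    dT_M = math.sqrt((mi * err("T_C")) ** 2 + (p.T_C * dmi) ** 2)
    T_G1 = p.T_C - p.T_G2M - p.T_S
    dT_G1 = math.sqrt(err("T_C") ** 2 + err("T_G2M") ** 2 + err("T_S") ** 2)
    return PhaseLengths(T_M=T_M, dT_M=dT_M, T_G1=T_G1, dT_G1=dT_G1, mi=mi, dmi=dmi)


def estimate_tg2m(
    mitotic_labeling: Sequence[tuple[float, float]]
) -> float:
    """Combined G2+M length from labeled-mitoses saturation.

    Cells in M at time t since labeling onset were in S a time t ago only
    if t exceeds their G2(+M) transit; once every mitotic figure is
    labeled and stays labeled, the first such time bounds T_G2+M.

    Parameters
    ----------
    mitotic_labeling : sequence of (t_hours, labeled_mitoses_fraction)

    Returns
    -------
    float
        Smallest observed t at which the fraction reaches 1 and remains
        1 for all later observed times.

    Raises
    ------
    MissingSaturationError
        If the fraction never reaches (and keeps) 1.
    """
    pts = sorted(mitotic_labeling)
    times = [t for t, _ in pts]
    fracs = [f for _, f in pts]
    if any(not (0 <= f <= 1) for f in fracs):
        raise ValueError("fractions must lie in [0, 1]")
    if len(set(times)) != len(times):
        raise ValueError("times must be distinct")
    for i, (t, f) in enumerate(pts):
        if f >= 1.0 and all(f2 >= 1.0 for _, f2 in pts[i:]):
            return float(t)
    raise MissingSaturationError(
        "labeled-mitoses fraction never saturates at 1; cannot bound T_G2+M"
    )


@dataclass(frozen=True)
class FullCycleExtrapolation:
    differentiated: float
    stem_retained: float


def extrapolate_full_cycle_differentiation(
    f_diff_observed: float, completed_cycle_fraction: float
) -> FullCycleExtrapolation:
    """Linearly extrapolate an observed differentiated fraction to a full
    cell cycle.

    When only a fraction of the labeled population has completed a cycle
    within the chase, the observed differentiated fraction underestimates
    the per-cycle rate; linear scaling (capped at 1) normalizes for it.
    Returns both the extrapolated differentiated fraction and its
    complement, the fraction retaining the stem marker.
    """
    if not (0 <= f_diff_observed <= 1):
        raise ValueError("f_diff_observed must lie in [0, 1]")
    if not (0 < completed_cycle_fraction <= 1):
        raise ValueError("completed_cycle_fraction must lie in (0, 1]")
    f_full = min(1.0, f_diff_observed / completed_cycle_fraction)
    return FullCycleExtrapolation(differentiated=f_full, stem_retained=1.0 - f_full)
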