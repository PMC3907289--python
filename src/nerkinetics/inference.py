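"""Likelihood-based inference for the NER model.

Bulk time-course observations (means with SDs over replicate cells) are
fitted by weighted least squares, which for independent Gaussian errors is
maximum likelihood; the objective is the weighted half-sum of squares

    nll(p) = 1/2 * sum_j ((y_model_j(p) - y_j) / sd_j)^2 .

Parameter uncertainty is assessed with profile likelihoods: one parameter
is fixed on a grid while all others are re-optimised, and the 95%
confidence region is bounded by 2*(nll - nll_min) <= 3.84 (chi-squared with
one degree of freedom, pointwise).  Prediction uncertainty for a derived
scalar uses the prediction-profile (penalty) variant of the same idea.

Datasets are tidy :class:`pandas.DataFrame` tables with columns
``observable`` (accumulation | edu | incised | flip), ``factor`` (or empty),
``time_min``, ``value``, ``sd``, ``n``.  For FLIP rows ``time_min`` is the
offset from the bleach start, which is carried in a ``flip_start`` column.

The module also provides the stand-alone first-order fit of repair
synthesis, ``EdU(t) = EdU_max (1 - exp(-lambda t))``, used to summarise
measured or simulated EdU accumulation curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import ParameterSet, flip_curve, simulate
from .model import _F, _S

__all__ = [
    "EdUFit",
    "FitResult",
    "ProfileCurve",
    "fit_first_order",
    "model_predictions",
    "negloglik",
    "fit_model",
    "profile_likelihood",
    "prediction_profile",
]

DATASET_COLUMNS = ("observable", "factor", "time_min", "value", "sd", "n")

CHI2_95_DF1 = float(stats.chi2.ppf(0.95, df=1))  # 3.841...


# ---------------------------------------------------------------------------
# first-order EdU fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdUFit:
    """First-order fit of an EdU incorporation curve (time unit: hours)."""

    lam: float
    edu_max: float
    half_time: float
    lam_ci: tuple[float, float]
    edu_max_ci: tuple[float, float]
    linear_slope: float

    @property
    def rate(self) -> float:
        return self.lam


def fit_first_order(
    times: Sequence[float],
    values: Sequence[float],
    sds: Sequence[float] | None = None,
) -> EdUFit:
    """Weighted least-squares fit of ``EdU_max (1 - exp(-lambda t))``.

    ``times`` are in hours.  Reports the rate constant with asymptotic 95%
    confidence intervals, the half-time ``ln 2 / lambda`` and the slope of
    the linearised plot ``ln(1 - EdU/EdU_max)`` versus ``t`` (equal to
    ``-lambda`` for a true exponential).  Raises if the fitted rate is not
    positive.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    sigma = None if sds is None else np.asarray(sds, dtype=float)

    def model(tt, emax, lam):
        return emax * (1.0 - np.exp(-lam * tt))

    a0 = max(y.max(), 1e-12)
    lam0 = 1.0 / max(t[-1] / 3.0, 1e-6)
    popt, pcov = optimize.curve_fit(
        model, t, y, p0=[a0, lam0], sigma=sigma, absolute_sigma=sigma is not None,
        maxfev=20000,
    )
    emax, lam = float(popt[0]), float(popt[1])
    if lam <= 0 or emax <= 0:
        raise RuntimeError(
            f"first-order fit failed: lambda={lam:.4g}, EdU_max={emax:.4g}"
        )
    se = np.sqrt(np.diag(pcov))
    z = stats.norm.ppf(0.975)
    frac = 1.0 - y / emax
    ok = frac > 1e-12
    slope = (
        float(np.polyfit(t[ok], np.log(frac[ok]), 1)[0]) if ok.sum() >= 2 else np.nan
    )
    return EdUFit(
        lam=lam,
        edu_max=emax,
        half_time=float(np.log(2.0) / lam),
        lam_ci=(lam - z * se[1], lam + z * se[1]),
        edu_max_ci=(emax - z * se[0], emax + z * se[0]),
        linear_slope=slope,
    )


# ---------------------------------------------------------------------------
# model-dataset interface
# ---------------------------------------------------------------------------

def _validate_dataset(data: pd.DataFrame) -> None:
    missing = set(("observable", "time_min", "value")) - set(data.columns)
    if missing:
        raise ValueError(f"dataset missing columns {sorted(missing)}")
    if (data["time_min"] < 0).any():
        raise ValueError("negative times in dataset")


def model_predictions(
    params: ParameterSet,
    data: pd.DataFrame,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Model value for every dataset row, in row order.

    All non-FLIP observables are served from a single simulation over the
    union of requested times; each distinct FLIP bleach start costs one
    additional (short) labeled-species simulation.
    """
    _validate_dataset(data)
    pred = np.full(len(data), np.nan)
    is_flip = data["observable"] == "flip"

    bulk = data.loc[~is_flip]
    if len(bulk):
        times = np.unique(np.concatenate([[0.0], bulk["time_min"].to_numpy(float)]))
        traj = simulate(params, times, rtol=rtol, atol=atol)
        index = {tt: i for i, tt in enumerate(times)}
        rows = bulk.index.to_numpy()
        ti = np.array([index[tt] for tt in bulk["time_min"].to_numpy(float)])
        for obs, sub in bulk.groupby("observable"):
            sel = sub.index.to_numpy()
            tsel = ti[np.isin(rows, sel)]
            if obs == "edu":
                pred[data.index.get_indexer(sel)] = traj.edu[tsel]
            elif obs == "incised":
                pred[data.index.get_indexer(sel)] = traj.D[tsel, 2] / max(
                    params.lesions0, 1e-300
                )
            elif obs == "accumulation":
                for f, subf in sub.groupby("factor"):
                    self_sel = subf.index.to_numpy()
                    tse = np.array([index[tt] for tt in subf["time_min"].to_numpy(float)])
                    pred[data.index.get_indexer(self_sel)] = traj.accumulation(f)[tse]
            else:
                raise ValueError(f"unknown observable {obs!r}")

    if is_flip.any():
        flip = data.loc[is_flip]
        if "flip_start" not in flip.columns:
            raise ValueError("flip rows require a flip_start column")
        for (t0, f), sub in flip.groupby(["flip_start", "factor"]):
            offs = sub["time_min"].to_numpy(float)
            vals = flip_curve(params, float(t0), offs, f, rtol=rtol, atol=atol)
            pred[data.index.get_indexer(sub.index.to_numpy())] = vals
    return pred


def negloglik(
    params: ParameterSet,
    data: pd.DataFrame,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Weighted half-sum-of-squares objective.

    Rows with missing or non-positive ``sd`` receive unit weight.
    """
    pred = model_predictions(params, data, rtol=rtol, atol=atol)
    y = data["value"].to_numpy(float)
    sd = data["sd"].to_numpy(float) if "sd" in data.columns else np.ones_like(y)
    sd = np.where(np.isfinite(sd) & (sd > 0), sd, 1.0)
    r = (pred - y) / sd
    return float(0.5 * np.sum(r * r))


# ---------------------------------------------------------------------------
# free-parameter mapping
# ---------------------------------------------------------------------------

def _get_param(params: ParameterSet, name: str) -> float:
    kind, *rest = name.split(":")
    if kind == "kd":
        f, s = rest
        return float(params.koff[_F[f], _S[s]] / params.kon[_F[f], _S[s]])
    if kind == "kon":
        f, s = rest
        return float(params.kon[_F[f], _S[s]])
    if kind == "koff":
        f, s = rest
        return float(params.koff[_F[f], _S[s]])
    if kind == "total":
        return params.total(rest[0])
    if kind in ("alpha", "beta", "gamma", "delta", "epsilon", "lesions0", "phi"):
        return float(getattr(params, kind))
    raise ValueError(f"unknown parameter {name!r}")


def _set_params(params: ParameterSet, names: Sequence[str], values: Sequence[float]) -> ParameterSet:
    kd, kon, koff, totals, scalars = {}, {}, {}, {}, {}
    for name, v in zip(names, values):
        kind, *rest = name.split(":")
        if kind == "kd":
            kd[(rest[0], rest[1])] = v
        elif kind == "kon":
            kon[(rest[0], rest[1])] = v
        elif kind == "koff":
            koff[(rest[0], rest[1])] = v
        elif kind == "total":
            totals[rest[0]] = v
        else:
            scalars[kind] = v
    return params.with_updates(kd=kd or None, kon=kon or None, koff=koff or None,
                               totals=totals or None, **scalars)


@dataclass
class FitResult:
    """Outcome of a multi-start maximum-likelihood fit."""

    params: ParameterSet
    nll: float
    free_names: tuple[str, ...]
    free_values: np.ndarray
    starts: pd.DataFrame
    converged: bool
    residuals: pd.DataFrame

    def value(self, name: str) -> float:
        return _get_param(self.params, name)


def fit_model(
    data: pd.DataFrame,
    base_params: ParameterSet,
    free_names: Sequence[str],
    n_starts: int = 10,
    seed: int = 0,
    spread: float = 3.0,
    bounds_decades: float = 4.0,
    include_center: bool = True,
) -> FitResult:
    """Multi-start weighted least-squares fit in log10 parameter space.

    Starts are latin-hypercube perturbations of the centre (the values in
    ``base_params``) by up to a factor ``spread``; each start is locally
    minimised with L-BFGS-B inside box bounds of ``bounds_decades`` decades
    around the centre.  The best converged start is returned together with a
    log of all starts.  Fully reproducible for a fixed seed.
    """
    names = tuple(free_names)
    if not names:
        raise ValueError("free parameter list is empty")
    center = np.log10([_get_param(base_params, n) for n in names])
    lo = center - bounds_decades
    hi = center + bounds_decades

    def objective(x: np.ndarray) -> float:
        try:
            p = _set_params(base_params, names, 10.0**x)
            # slightly relaxed integrator tolerance: ~2x faster, parameter
            # error well below the optimiser's resolution
            return negloglik(p, data, rtol=1e-7, atol=1e-9)
        except (RuntimeError, FloatingPointError, ValueError):
            return 1e12

    rng = np.random.default_rng(seed)
    sampler = stats.qmc.LatinHypercube(d=len(names), seed=rng)
    n_random = n_starts - int(include_center)
    if n_random > 0:
        unit = sampler.random(n_random)
        starts = center + (2.0 * unit - 1.0) * np.log10(spread)
    else:
        starts = np.empty((0, len(names)))
    if include_center:
        starts = np.vstack([center, starts])

    records = []
    best = None
    for i, x0 in enumerate(starts):
        # derivative-free simplex search: the ODE objective is only
        # piecewise-smooth at finite integrator tolerance, which defeats
        # finite-difference gradients
        res = optimize.minimize(
            objective,
            np.clip(x0, lo, hi),
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options=dict(maxfev=300, xatol=1e-4, fatol=1e-9),
        )
        records.append(
            dict(start=i, nll=float(res.fun), success=bool(res.success),
                 **{n: 10.0**v for n, v in zip(names, res.x)})
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e12:
        raise RuntimeError(
            f"all {len(starts)} starts failed; log: {records}"
        )
    params = _set_params(base_params, names, 10.0**best.x)
    pred = model_predictions(params, data)
    resid = data.copy()
    resid["model"] = pred
    resid["residual"] = pred - data["value"].to_numpy(float)
    return FitResult(
        params=params,
        nll=float(best.fun),
        free_names=names,
        free_values=10.0**best.x,
        starts=pd.DataFrame.from_records(records),
        converged=bool(best.success),
        residuals=resid,
    )


# ---------------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileCurve:
    """Profile likelihood of one parameter.

    ``ci95`` bounds are ``None`` where the 95% threshold is not crossed
    inside the grid; ``verdict`` is one of ``identifiable``,
    ``lower bound only``, ``upper bound only``, ``unidentifiable``.
    """

    name: str
    grid: np.ndarray
    nll: np.ndarray
    nll_min: float
    mle: float
    ci95: tuple[float | None, float | None]
    verdict: str


def _refit_with_fixed(
    data: pd.DataFrame,
    base_params: ParameterSet,
    free_names: Sequence[str],
    x_start: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
) -> tuple[float, np.ndarray]:
    def objective(x):
        try:
            p = _set_params(base_params, free_names, 10.0**x)
            return negloglik(p, data, rtol=1e-7, atol=1e-9)
        except (RuntimeError, FloatingPointError, ValueError):
            return 1e12

    if len(free_names) == 0:
        return objective(np.empty(0)), np.empty(0)
    res = optimize.minimize(
        objective, np.clip(x_start, lo, hi), method="Nelder-Mead",
        bounds=list(zip(lo, hi)),
        options=dict(maxfev=200, xatol=5e-5, fatol=1e-9),
    )
    return float(res.fun), res.x


def profile_likelihood(
    data: pd.DataFrame,
    fit: FitResult,
    name: str,
    grid: Sequence[float],
    base_params: ParameterSet | None = None,
) -> ProfileCurve:
    """Profile the likelihood along one fitted parameter.

    For each grid value the parameter is fixed and all other free
    parameters are re-optimised (warm-started from the neighbouring grid
    point).  The grid must bracket the maximum-likelihood estimate.
    """
    if name not in fit.free_names:
        raise ValueError(f"{name!r} was not a free parameter of the fit")
    grid = np.asarray(grid, dtype=float)
    mle = fit.value(name)
    if not (grid.min() <= mle <= grid.max()):
        raise ValueError(f"grid [{grid.min()}, {grid.max()}] excludes MLE {mle}")
    base = base_params if base_params is not None else fit.params
    others = tuple(n for n in fit.free_names if n != name)
    x_mle = np.log10(
        [fit.free_values[fit.free_names.index(n)] for n in others]
    ) if others else np.empty(0)
    lo, hi = x_mle - 4.0, x_mle + 4.0

    order = np.argsort(grid)
    grid_sorted = grid[order]
    nll = np.empty(grid.size)
    # profile outward from the grid point nearest the MLE, warm-starting
    i_mle = int(np.argmin(np.abs(grid_sorted - mle)))
    for direction in (range(i_mle, grid.size), range(i_mle - 1, -1, -1)):
        x_warm = x_mle.copy()
        for i in direction:
            fixed = _set_params(base, (name,), [grid_sorted[i]])
            nll[i], x_warm = _refit_with_fixed(data, fixed, others, x_warm, lo, hi)
    nll_min = min(fit.nll, float(nll.min()))
    threshold = nll_min + CHI2_95_DF1 / 2.0
    below = nll <= threshold

    def crossing(i0: int, i1: int) -> float:
        # linear interpolation of nll in log-parameter between grid points
        x0, x1 = np.log(grid_sorted[i0]), np.log(grid_sorted[i1])
        f0, f1 = nll[i0], nll[i1]
        w = (threshold - f0) / (f1 - f0)
        return float(np.exp(x0 + w * (x1 - x0)))

    lower = upper = None
    idx = np.nonzero(below)[0]
    if idx.size:
        if idx[0] > 0:
            lower = crossing(idx[0], idx[0] - 1)
        if idx[-1] < grid.size - 1:
            upper = crossing(idx[-1], idx[-1] + 1)
    if lower is not None and upper is not None:
        verdict = "identifiable"
    elif lower is not None:
        verdict = "lower bound only"
    elif upper is not None:
        verdict = "upper bound only"
    else:
        verdict = "unidentifiable"
    return ProfileCurve(
        name=name, grid=grid_sorted, nll=nll,
        nll_min=nll_min, mle=mle, ci95=(lower, upper), verdict=verdict,
    )


def prediction_profile(
    data: pd.DataFrame,
    fit: FitResult,
    predictor: Callable[[ParameterSet], float],
    rel_span: float = 0.5,
    n_grid: int = 11,
    weight: float = 1e4,
) -> tuple[float, tuple[float | None, float | None], pd.DataFrame]:
    """95% confidence interval of a predicted scalar (penalty formulation).

    The prediction profile likelihood at target value ``z`` is
    ``min_p [nll(p) + weight * (predictor(p) - z)^2]``; the CI collects the
    ``z`` range where twice the profile deficit stays below 3.84.  The scan
    covers ``point * (1 ± rel_span)``.  Returns the point prediction, the CI
    and the profile table.
    """
    point = float(predictor(fit.params))
    span = abs(point) * rel_span if point != 0 else rel_span
    zgrid = np.linspace(point - span, point + span, n_grid)
    names = fit.free_names
    x_mle = np.log10(fit.free_values)
    lo, hi = x_mle - 4.0, x_mle + 4.0

    def profiled(z: float, x0: np.ndarray) -> tuple[float, np.ndarray]:
        def objective(x):
            try:
                p = _set_params(fit.params, names, 10.0**x)
                nll = negloglik(p, data, rtol=1e-7, atol=1e-9)
                return nll + weight * (predictor(p) - z) ** 2
            except (RuntimeError, FloatingPointError, ValueError):
                return 1e12
        res = optimize.minimize(
            objective, np.clip(x0, lo, hi), method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options=dict(maxfev=200, xatol=1e-4, fatol=1e-9),
        )
        if res.fun >= 1e12:
            raise RuntimeError(f"prediction-profile solve diverged at z={z}")
        p = _set_params(fit.params, names, 10.0**res.x)
        return float(negloglik(p, data, rtol=1e-7, atol=1e-9)), res.x

    nll = np.empty(zgrid.size)
    i_point = int(np.argmin(np.abs(zgrid - point)))
    for direction in (range(i_point, zgrid.size), range(i_point - 1, -1, -1)):
        x_warm = x_mle.copy()
        for i in direction:
            nll[i], x_warm = profiled(zgrid[i], x_warm)

    nll_min = min(fit.nll, float(nll.min()))
    threshold = nll_min + CHI2_95_DF1 / 2.0
    below = nll <= threshold
    idx = np.nonzero(below)[0]
    lower = upper = None
    if idx.size:
        if idx[0] > 0:
            w = (threshold - nll[idx[0]]) / (nll[idx[0] - 1] - nll[idx[0]])
            lower = float(zgrid[idx[0]] + w * (zgrid[idx[0] - 1] - zgrid[idx[0]]))
        else:
            lower = None
        if idx[-1] < zgrid.size - 1:
            w = (threshold - nll[idx[-1]]) / (nll[idx[-1] + 1] - nll[idx[-1]])
            upper = float(zgrid[idx[-1]] + w * (zgrid[idx[-1] + 1] - zgrid[idx[-1]]))
    table = pd.DataFrame({"prediction": zgrid, "nll": nll})
    return point, (lower, upper), table
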