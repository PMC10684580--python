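"""Least-squares fitting of exchange parameters to titration slices.

Extracting rate constants from exchange-broadened line shapes is done
here with an explicit objective rather than by-eye comparison: simulated
and observed real spectra are max-normalized and compared pointwise
(sum of squared differences over an analysis window), or through peak
features (position and FWHM errors in units of the axis step).  Rate
constants span many decades, so they are fitted internally on a log10
scale and multi-start initial guesses are drawn log-uniformly within
bounds.  A K_d constraint can tie k1_off = K_d * k1_on, reflecting that
the binding constant is usually known independently (stopped-flow, FP)
while the line shape informs the isomerization step.

Line-shape fits of this kind are notoriously under-determined when only
saturated spectra are available (the bound-state shift and the
isomerization rates trade off against each other), so every fit reports
identifiability: near-flat directions of the objective, detected from
the finite-difference curvature at the optimum, are flagged per
parameter instead of being silently resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import lmfit
import numpy as np

from .kinetics import ExchangeScheme, MixComposition
from .lineshape import (
    AcquisitionSettings,
    NoPeakError,
    SpinParameters,
    Spectrum1D,
    measure_peak,
    simulate_slice,
)
from .titration import TitrationSeries

__all__ = ["PARAM_NAMES", "FitConfig", "FitResult", "objective", "fit_series", "model_comparison"]

PARAM_NAMES = ("k1_on", "k1_off", "k2", "k2_prime", "omega_P", "omega_PL", "R2", "scale")
_RATE_PARAMS = ("k1_on", "k1_off", "k2", "k2_prime")

#: eigenvalues of the objective Hessian below this fraction of the largest
#: count as flat directions; parameters loading >40% onto one are flagged
FLAT_EIGENVALUE_RATIO = 1e-6
FLAT_LOADING = 0.4


@dataclass
class FitConfig:
    """Which parameters to fit, their bounds, and optimizer settings.

    Parameters
    ----------
    free : dict
        Map free-parameter name -> (lower, upper) bounds.  Rate
        parameters need strictly positive lower bounds (log-scale fit).
    fixed : dict
        Values for the remaining parameters.  ``scale`` defaults to 1.
    kd_constraint : float, optional
        When set, k1_off is tied to ``kd_constraint * k1_on`` (any
        supplied k1_off entry is ignored).
    n_starts : int
        Multi-start count; starts beyond the first are drawn
        log-uniformly (rates) / uniformly (others) within bounds.
    seed : int
        Seed for the start-point draws; fits are deterministic given it.
    objective_kind : "pointwise" or "feature"
        Pointwise squared differences of normalized spectra, or squared
        peak position/FWHM errors in axis-step units.
    window : (low, high) Hz, optional
        Analysis window; None means the full axis.
    echo_time : float
        Spin-echo duration passed through to the simulator (s).
    """

    free: dict[str, tuple[float, float]]
    fixed: dict[str, float] = field(default_factory=dict)
    kd_constraint: float | None = None
    n_starts: int = 5
    seed: int = 0
    objective_kind: Literal["pointwise", "feature"] = "pointwise"
    normalization: Literal["global", "per-slice"] = "global"
    window: tuple[float, float] | None = None
    echo_time: float = 0.011

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("at least one parameter must be free")
        unknown = set(self.free) | set(self.fixed) - set(PARAM_NAMES)
        unknown -= set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names {sorted(unknown)}")
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        for name, (lo, hi) in self.free.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite and ordered, got ({lo}, {hi})")
            if name in _RATE_PARAMS and lo <= 0:
                raise ValueError(f"rate parameter {name} needs a positive lower bound")
        if self.kd_constraint is not None:
            if self.kd_constraint <= 0:
                raise ValueError("kd_constraint must be > 0")
            if "k1_off" in self.free:
                raise ValueError("k1_off cannot be free when kd_constraint is set")
        covered = set(self.free) | set(self.fixed) | {"scale"}
        if self.kd_constraint is not None:
            covered.add("k1_off")
        missing = set(PARAM_NAMES) - covered
        if missing:
            raise ValueError(f"parameters neither free nor fixed: {sorted(missing)}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitResult:
    """Best multi-start fit: parameters, objective, diagnostics."""

    params: dict[str, float]
    objective: float
    residuals: list[np.ndarray]
    success: bool
    n_starts_converged: int
    identifiability: dict[str, bool]  # True = parameter lies in a flat direction
    flat_modes: list[tuple[float, dict[str, float]]]  # (curvature, loadings)
    bound_hit: dict[str, bool]
    config: FitConfig

    @property
    def flat_parameters(self) -> list[str]:
        return [p for p, flat in self.identifiability.items() if flat]


def _split_params(params: dict[str, float], echo_time: float):
    scheme = ExchangeScheme(
        k1_on=params["k1_on"],
        k1_off=params["k1_off"],
        k2=params["k2"],
        k2_prime=params["k2_prime"],
    )
    spin = SpinParameters(
        omega_P=params["omega_P"],
        omega_PL=params["omega_PL"],
        R2=params["R2"],
        echo_time=echo_time,
    )
    return scheme, spin


def _normalize(y: np.ndarray) -> np.ndarray:
    m = np.max(np.abs(y))
    if m == 0:
        return y
    return y / m


def _feature_residual(
    obs: Spectrum1D, sim: Spectrum1D, window: tuple[float, float]
) -> np.ndarray:
    # peak position and FWHM errors in axis-step units
    step = obs.axis_step
    try:
        po = measure_peak(obs, window)
        ps = measure_peak(sim, window)
    except NoPeakError:
        return np.array([1e3, 1e3])  # penalty: no comparable peak
    return np.array([(ps.position - po.position) / step, (ps.fwhm - po.fwhm) / step])


def _residual_vector(
    observed: TitrationSeries,
    params: dict[str, float],
    acq: AcquisitionSettings,
    kind: str,
    window: tuple[float, float] | None,
    echo_time: float,
    normalization: str = "global",
) -> list[np.ndarray]:
    scheme, spin = _split_params(params, echo_time)
    scale = params.get("scale", 1.0)
    sims, masks, wins = [], [], []
    for eq, obs in observed:
        sim = simulate_slice(scheme, spin, MixComposition(P0=observed.P0, L0=eq * observed.P0), acq)
        if sim.frequency.shape != obs.frequency.shape or not np.allclose(
            sim.frequency, obs.frequency, rtol=0, atol=1e-9
        ):
            raise ValueError("observed slice axis does not match the simulation axis")
        win = window if window is not None else (obs.frequency[0], obs.frequency[-1])
        sims.append(sim)
        wins.append(win)
        masks.append((obs.frequency >= win[0]) & (obs.frequency <= win[1]))
    if kind == "feature":
        return [_feature_residual(obs, sim, win)
                for (_, obs), sim, win in zip(observed, sims, wins)]
    if normalization == "global":
        # one normalization constant per series preserves the relative
        # intensity buildup across titration points and keeps slices whose
        # signal has broadened below the noise from dominating the objective
        obs_max = max(np.max(np.abs(o.intensity)) for _, o in observed) or 1.0
        sim_max = max(np.max(np.abs(s.intensity)) for s in sims) or 1.0
        return [
            scale * sim.intensity[mk] / sim_max - obs.intensity[mk] / obs_max
            for (_, obs), sim, mk in zip(observed, sims, masks)
        ]
    if normalization == "per-slice":
        return [
            scale * _normalize(sim.intensity)[mk] - _normalize(obs.intensity)[mk]
            for (_, obs), sim, mk in zip(observed, sims, masks)
        ]
    raise ValueError(f"unknown normalization {normalization!r}")


def objective(
    observed: TitrationSeries,
    params: dict[str, float],
    acq: AcquisitionSettings,
    kind: str = "pointwise",
    window: tuple[float, float] | None = None,
    echo_time: float = 0.011,
    normalization: str = "global",
) -> float:
    """Total squared mismatch between observed and simulated series.

    Observed and simulated spectra are max-normalized before comparison
    (by default with one constant per series; optionally per slice), so
    the objective is invariant to any common amplitude scale of the
    observed data.
    """
    res = _residual_vector(observed, params, acq, kind, window, echo_time, normalization)
    return float(sum(np.sum(r * r) for r in res))


def _make_lmfit_params(config: FitConfig, start: dict[str, float]) -> lmfit.Parameters:
    """Internal parameterization: log10 for free rates, linear otherwise."""
    p = lmfit.Parameters()
    for name in PARAM_NAMES:
        if name == "k1_off" and config.kd_constraint is not None:
            continue  # added below as a derived quantity
        if name in config.free:
            lo, hi = config.free[name]
            if name in _RATE_PARAMS:
                p.add(f"log10_{name}", value=math.log10(start[name]),
                      min=math.log10(lo), max=math.log10(hi))
            else:
                p.add(name, value=start[name], min=lo, max=hi)
        else:
            value = config.fixed.get(name, 1.0 if name == "scale" else 0.0)
            if name in _RATE_PARAMS and value > 0:
                p.add(f"log10_{name}", value=math.log10(value), vary=False)
            else:
                p.add(name, value=value, vary=False)
    if config.kd_constraint is not None:
        if "log10_k1_on" in p:
            p.add("log10_k1_off", expr=f"log10_k1_on + {math.log10(config.kd_constraint)!r}")
        else:
            k1_on = p["k1_on"].value if "k1_on" in p else 10 ** p["log10_k1_on"].value
            p.add("log10_k1_off", value=math.log10(config.kd_constraint * k1_on), vary=False)
    return p


def _natural(p: lmfit.Parameters) -> dict[str, float]:
    out = {}
    for name in PARAM_NAMES:
        if f"log10_{name}" in p:
            out[name] = 10 ** p[f"log10_{name}"].value
        else:
            out[name] = p[name].value
    return out


def _draw_starts(config: FitConfig, rng: np.random.Generator) -> list[dict[str, float]]:
    starts = []
    for i in range(config.n_starts):
        s = {}
        for name, (lo, hi) in config.free.items():
            if name in _RATE_PARAMS:
                if i == 0:
                    s[name] = math.sqrt(lo * hi)  # geometric midpoint
                else:
                    s[name] = 10 ** rng.uniform(math.log10(lo), math.log10(hi))
            else:
                s[name] = 0.5 * (lo + hi) if i == 0 else rng.uniform(lo, hi)
        starts.append(s)
    return starts


def _flat_directions(
    observed: TitrationSeries,
    best: dict[str, float],
    free_names: list[str],
    acq: AcquisitionSettings,
    config: FitConfig,
) -> dict[str, bool]:
    """Finite-difference curvature scan for near-flat objective directions.

    The Hessian is taken in the internal coordinates (log10 for rates,
    linear otherwise) with relative steps, then eigendecomposed; free
    parameters loading strongly onto eigen-directions whose curvature is
    below FLAT_EIGENVALUE_RATIO of the largest are flagged.
    """

    def coords(params: dict[str, float]) -> np.ndarray:
        return np.array(
            [math.log10(params[n]) if n in _RATE_PARAMS else params[n] for n in free_names]
        )

    def from_coords(x: np.ndarray) -> dict[str, float]:
        params = dict(best)
        for n, v in zip(free_names, x):
            params[n] = 10 ** v if n in _RATE_PARAMS else v
        if config.kd_constraint is not None:
            params["k1_off"] = config.kd_constraint * params["k1_on"]
        return params

    def f(x: np.ndarray) -> float:
        return objective(observed, from_coords(x), acq, config.objective_kind,
                         config.window, config.echo_time, config.normalization)

    x0 = coords(best)
    n = len(x0)
    h = np.where(np.abs(x0) > 1.0, 1e-3 * np.abs(x0), 1e-3)
    H = np.empty((n, n))
    f0 = f(x0)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        fp[i] = f(x0 + e)
        fm[i] = f(x0 - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + f(x0 - ei - ej)
            ) / (2 * h[i] * h[j])
    eigval, eigvec = np.linalg.eigh(H)
    scale = max(np.max(np.abs(eigval)), 1e-300)
    flags = {name: False for name in free_names}
    modes = []
    for k in range(n):
        if eigval[k] < FLAT_EIGENVALUE_RATIO * scale:
            loadings = {name: float(eigvec[i, k]) for i, name in enumerate(free_names)}
            modes.append((float(eigval[k] / scale), loadings))
            for name, load in loadings.items():
                if abs(load) > FLAT_LOADING:
                    flags[name] = True
    return flags, modes


def fit_series(
    observed: TitrationSeries, config: FitConfig, acq: AcquisitionSettings
) -> FitResult:
    """Multi-start bounded least squares over the configured parameters."""
    rng = np.random.default_rng(config.seed)
    free_names = list(config.free)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        params = _natural(p)
        return np.concatenate(
            _residual_vector(observed, params, acq, config.objective_kind,
                             config.window, config.echo_time, config.normalization)
        )

    best = None
    n_converged = 0
    failures = []
    for start in _draw_starts(config, rng):
        try:
            mini = lmfit.Minimizer(residual, _make_lmfit_params(config, start))
            out = mini.minimize(method="least_squares")
        except Exception as exc:  # noqa: BLE001 - collected into diagnostics
            failures.append(f"start {start}: {exc}")
            continue
        n_converged += 1
        ssr = float(np.sum(out.residual**2))
        if best is None or ssr < best[0]:
            best = (ssr, out)
    if best is None:
        raise RuntimeError(
            "no multi-start fit converged; diagnostics:\n" + "\n".join(failures)
        )
    ssr, out = best
    params = _natural(out.params)
    res_vectors = _residual_vector(observed, params, acq, config.objective_kind,
                                   config.window, config.echo_time, config.normalization)
    bound_hit = {}
    for name in free_names:
        lo, hi = config.free[name]
        v = params[name]
        span = math.log10(hi / lo) if name in _RATE_PARAMS else hi - lo
        pos = (math.log10(v / lo) if name in _RATE_PARAMS else v - lo) / span
        bound_hit[name] = pos < 1e-4 or pos > 1 - 1e-4
    ident, modes = _flat_directions(observed, params, free_names, acq, config)
    return FitResult(
        params=params,
        objective=ssr,
        residuals=res_vectors,
        success=True,
        n_starts_converged=n_converged,
        identifiability=ident,
        flat_modes=modes,
        bound_hit=bound_hit,
        config=config,
    )


def model_comparison(
    observed: TitrationSeries, acq: AcquisitionSettings, config: FitConfig
) -> dict:
    """Fit the two-state restriction (k2 = 0) and the full three-state model.

    The two-state fit removes k2/k2_prime from the free set and pins
    them at zero; all other settings are shared.  Since the two-state
    model is nested in the three-state one, objective_ratio =
    obj2 / obj3 >= 1 up to optimizer tolerance, and a ratio well above 1
    is evidence for exchange broadening beyond binding/unbinding.
    """
    free2 = {k: v for k, v in config.free.items() if k not in ("k2", "k2_prime")}
    if not free2:
        raise ValueError("two-state restriction leaves no free parameters")
    fixed2 = dict(config.fixed)
    fixed2.pop("k2", None)
    fixed2.pop("k2_prime", None)
    fixed2["k2"] = 0.0
    fixed2["k2_prime"] = 0.0
    config2 = FitConfig(
        free=free2, fixed=fixed2, kd_constraint=config.kd_constraint,
        n_starts=config.n_starts, seed=config.seed,
        objective_kind=config.objective_kind, normalization=config.normalization,
        window=config.window, echo_time=config.echo_time,
    )
    fit3 = fit_series(observed, config, acq)
    fit2 = fit_series(observed, config2, acq)
    ratio = fit2.objective / fit3.objective if fit3.objective > 0 else math.inf
    return {
        "two_state": fit2,
        "three_state": fit3,
        "objective_two_state": fit2.objective,
        "objective_three_state": fit3.objective,
        "objective_ratio": ratio,
    }
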