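"""Weighted least-squares estimation of model parameters from time courses.

The observables produced by live-cell imaging are mapped onto the model
state as

* ``confluence_pct``        = 100 * n(t)
* ``lipid_ros_ratio``       = ros_baseline + ros_scale * r(t)   (affine map
  of per-cell lipid ROS onto the oxidized/reduced reporter ratio)
* ``dead_per_confluence``   = D(t) / n(t), with the cumulative dead signal
  D(t) = integral of beta * n * sigma(r) — the dead-cell dye marks a cell
  once and the count accrues, so the observable is cumulative.

Fitting minimises the weighted sum of squared residuals over all records
with a bounded trust-region least-squares solver, multistarted from
jittered initial guesses, with rate-like parameters optimised on a log
scale.  Joint fits across conditions share all parameters except an
explicitly declared condition-specific subset (e.g. the death threshold
``r0``, which GPX4 inhibition by RSL3 lowers).

The module surface is a scikit-learn style estimator,
:class:`TimecourseFitter`; the function :func:`fit` is a thin wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .model import IntegrationError, ModelParams, ModelState, _rhs_arrays, death_switch

__all__ = [
    "OBSERVABLES",
    "TimecourseDataset",
    "ObservationModel",
    "FitSpec",
    "FitResult",
    "TimecourseFitter",
    "predict_observables",
    "residuals",
    "fit",
]

OBSERVABLES = ("confluence_pct", "lipid_ros_ratio", "dead_per_confluence")

#: Parameters optimised internally on a log scale (strictly positive rates,
#: yields and thresholds); the rest are fitted on a linear scale.
_LOG_SCALE = frozenset({"alpha", "beta", "a", "b", "c", "r0", "ros_scale"})

_MODEL_FIELDS = tuple(f.name for f in dc_fields(ModelParams))
_OBS_FIELDS = ("ros_scale", "ros_baseline")

_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (1e-3, 1.0),
    "K": (0.05, 2.0),
    "beta": (1e-3, 1.0),
    "a": (0.1, 100.0),
    "b": (1e-3, 1.0),
    "c": (1e-4, 0.5),
    "r0": (0.01, 10.0),
    "h": (1.0, 12.0),
    "ros_scale": (1e-3, 100.0),
    "ros_baseline": (0.0, 10.0),
}


@dataclass(frozen=True)
class ObservationModel:
    """Affine map from model lipid ROS ``r`` to the measured reporter ratio."""

    ros_scale: float = 1.0
    ros_baseline: float = 0.2

    def __post_init__(self) -> None:
        if not self.ros_scale > 0:
            raise ValueError(f"ros_scale must be > 0, got {self.ros_scale!r}")
        if self.ros_baseline < 0:
            raise ValueError(f"ros_baseline must be >= 0, got {self.ros_baseline!r}")

    def ratio_of(self, r):
        return self.ros_baseline + self.ros_scale * np.asarray(r, dtype=float)

    def r_of(self, ratio):
        return np.maximum((np.asarray(ratio, dtype=float) - self.ros_baseline) / self.ros_scale, 0.0)

    def to_dict(self) -> dict[str, float]:
        return {"ros_scale": float(self.ros_scale), "ros_baseline": float(self.ros_baseline)}


class TimecourseDataset:
    """Tidy table of observed time courses, the fitting target.

    Wraps a DataFrame with columns ``condition, replicate, time_h,
    observable, value`` plus optional per-condition metadata (seeding
    label, treatment tags).
    """

    COLUMNS = ("condition", "replicate", "time_h", "observable", "value")

    def __init__(self, records: pd.DataFrame, metadata: dict | None = None):
        df = pd.DataFrame(records).copy()
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        df = df[list(self.COLUMNS)]
        df["time_h"] = df["time_h"].astype(float)
        df["value"] = df["value"].astype(float)
        unknown = set(df["observable"]) - set(OBSERVABLES)
        if unknown:
            raise ValueError(f"unknown observable names: {sorted(unknown)}")
        if (df["time_h"] < 0).any():
            raise ValueError("times must be non-negative")
        conf = df.loc[df["observable"] == "confluence_pct", "value"]
        if ((conf < 0) | (conf > 100)).any():
            raise ValueError("confluence_pct must lie in [0, 100]")
        if (df.loc[df["observable"] == "lipid_ros_ratio", "value"] < 0).any():
            raise ValueError("lipid_ros_ratio must be >= 0")
        n_times = df.groupby(["condition", "replicate", "observable"])["time_h"].nunique()
        if (n_times < 2).any():
            raise ValueError("every fitted series needs >= 2 distinct times")
        self.records = df.reset_index(drop=True)
        self.metadata = dict(metadata or {})

    @property
    def conditions(self) -> list[str]:
        return sorted(self.records["condition"].unique())

    def for_condition(self, condition: str) -> pd.DataFrame:
        return self.records[self.records["condition"] == condition]

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "TimecourseDataset":
        return cls(pd.read_csv(path), metadata=metadata)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False, float_format="%.10g")


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``free`` names the parameters optimised (ModelParams fields plus
    ``ros_scale`` / ``ros_baseline``); ``condition_specific`` is the subset
    that takes an independent value per condition.  Fitting ``a`` and
    ``ros_scale`` simultaneously is refused: under the affine observation
    map only their product is identifiable.
    """

    free: tuple[str, ...] = ("alpha", "K", "beta", "r0")
    condition_specific: tuple[str, ...] = ()
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    weight_scheme: str = "pooled_variance"
    multistart: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        valid = set(_MODEL_FIELDS) | set(_OBS_FIELDS)
        unknown = set(self.free) - valid
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        if not set(self.condition_specific) <= set(self.free):
            raise ValueError("condition_specific must be a subset of free")
        if {"a", "ros_scale"} <= set(self.free):
            raise ValueError(
                "'a' and 'ros_scale' are confounded under the affine observation "
                "map; fix one of them"
            )
        if self.weight_scheme not in ("pooled_variance", "uniform"):
            raise ValueError(f"unknown weight scheme {self.weight_scheme!r}")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if name not in valid:
                raise ValueError(f"bounds given for unknown parameter {name!r}")
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite and ordered")

    def bound_of(self, name: str) -> tuple[float, float]:
        return tuple(self.bounds.get(name, _DEFAULT_BOUNDS[name]))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a (possibly joint multi-condition) weighted LS fit."""

    shared: dict[str, float]
    per_condition: dict[str, dict[str, float]]
    rss: float
    residual_norms: dict[str, float]
    converged: bool
    multistart_rss: tuple[float, ...]
    seed: int

    def params_for(self, condition: str, base: ModelParams) -> ModelParams:
        vals = {k: v for k, v in self.shared.items() if k in _MODEL_FIELDS}
        vals.update(
            {k: v for k, v in self.per_condition.get(condition, {}).items() if k in _MODEL_FIELDS}
        )
        return base.with_(**vals)

    def observation_for(self, condition: str, base: ObservationModel) -> ObservationModel:
        vals = base.to_dict()
        vals.update({k: v for k, v in self.shared.items() if k in _OBS_FIELDS})
        vals.update(
            {k: v for k, v in self.per_condition.get(condition, {}).items() if k in _OBS_FIELDS}
        )
        return ObservationModel(**vals)

    @property
    def multistart_dispersion(self) -> float:
        """Spread (max - min) of converged multistart RSS values."""
        arr = np.asarray(self.multistart_rss, dtype=float)
        arr = arr[np.isfinite(arr)]
        return float(arr.max() - arr.min()) if len(arr) else float("nan")


def predict_observables(
    params: ModelParams,
    obs: ObservationModel,
    init: ModelState,
    times: Sequence[float],
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Forward-model the three imaging observables at the given times.

    The cumulative dead signal D(t) is integrated alongside (n, r) as a
    third state with D(0) = 0.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 1 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be non-negative and strictly increasing")

    def f(t, y):
        n, r = y[0], y[1]
        dn, dr = _rhs_arrays(max(n, 0.0), max(r, 0.0), params)
        dD = params.beta * max(n, 0.0) * death_switch(max(r, 0.0), params)
        return (dn, dr, dD)

    if len(times) == 1 and times[0] == 0.0:
        n, r, D = np.array([init.n]), np.array([init.r]), np.array([0.0])
    else:
        t0 = float(times[0]) if len(times) > 1 else 0.0
        sol = solve_ivp(
            f, (t0, float(times[-1])), [init.n, init.r, 0.0],
            t_eval=times, method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"observable integration failed: {sol.message}")
        n, r, D = np.clip(sol.y, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        dead_per_conf = np.where(n > 0, D / np.maximum(n, 1e-300), 0.0)
    return pd.DataFrame(
        {
            "time_h": times,
            "confluence_pct": 100.0 * n,
            "lipid_ros_ratio": obs.ratio_of(r),
            "dead_per_confluence": dead_per_conf,
        }
    )


def compute_weights(dataset: TimecourseDataset, scheme: str = "pooled_variance") -> pd.Series:
    """Per-record residual weights.

    ``pooled_variance``: for each observable, the replicate variance at
    each (condition, time) is pooled over time and conditions, floored at
    the 10th percentile of all positive per-time variances, and the weight
    is the reciprocal standard deviation.  Observables without replicate
    variance (single replicate, or noiseless data) fall back to a
    1/rms(value) magnitude scale so each observable still contributes on a
    comparable footing.  ``uniform``: all weights 1.
    """
    df = dataset.records
    if scheme == "uniform":
        return pd.Series(1.0, index=df.index)
    per_time_var = df.groupby(["observable", "condition", "time_h"])["value"].var(ddof=1)
    positive = per_time_var[per_time_var > 0]
    floor = float(np.quantile(positive, 0.10)) if len(positive) else 0.0
    weights = {}
    for obs_name, sub in df.groupby("observable"):
        v = per_time_var.loc[obs_name] if obs_name in per_time_var.index.get_level_values(0) else pd.Series(dtype=float)
        v = v.dropna()
        pooled = float(v.mean()) if len(v) else 0.0
        pooled = max(pooled, floor)
        if pooled > 0:
            weights[obs_name] = 1.0 / np.sqrt(pooled)
        else:
            rms = float(np.sqrt(np.mean(np.square(sub["value"]))))
            weights[obs_name] = 1.0 / max(rms, 1e-12)
    return df["observable"].map(weights).astype(float)


def _default_inits(
    dataset: TimecourseDataset, obs_by_cond: Mapping[str, ObservationModel]
) -> dict[str, ModelState]:
    """Initial state per condition from the earliest observed records."""
    out = {}
    for cond in dataset.conditions:
        sub = dataset.for_condition(cond)
        conf = sub[sub["observable"] == "confluence_pct"]
        ratio = sub[sub["observable"] == "lipid_ros_ratio"]
        n0 = float(conf.loc[conf["time_h"] == conf["time_h"].min(), "value"].mean()) / 100.0 if len(conf) else 0.1
        if len(ratio):
            r0 = float(
                obs_by_cond[cond].r_of(
                    ratio.loc[ratio["time_h"] == ratio["time_h"].min(), "value"].mean()
                )
            )
        else:
            r0 = 0.0
        out[cond] = ModelState(n=max(n0, 1e-6), r=max(r0, 0.0))
    return out


def residuals(
    params: ModelParams | Mapping[str, ModelParams],
    obs: ObservationModel | Mapping[str, ObservationModel],
    dataset: TimecourseDataset,
    weights: pd.Series | None = None,
    init_states: Mapping[str, ModelState] | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> np.ndarray:
    """Weighted residual vector (one entry per dataset record).

    ``params`` and ``obs`` may be single objects (applied to every
    condition) or per-condition mappings.
    """
    df = dataset.records
    if weights is None:
        weights = pd.Series(1.0, index=df.index)
    p_of = (lambda c: params[c]) if isinstance(params, Mapping) else (lambda c: params)
    o_of = (lambda c: obs[c]) if isinstance(obs, Mapping) else (lambda c: obs)
    if init_states is None:
        init_states = _default_inits(dataset, {c: o_of(c) for c in dataset.conditions})

    res = np.empty(len(df), dtype=float)
    for cond in dataset.conditions:
        mask = (df["condition"] == cond).to_numpy()
        sub = df[mask]
        times = np.unique(sub["time_h"].to_numpy())
        pred = predict_observables(p_of(cond), o_of(cond), init_states[cond], times, rtol=rtol, atol=atol)
        pred = pred.set_index("time_h")
        predicted = pred.to_numpy()[  # row = time index, col = observable index
            np.searchsorted(times, sub["time_h"].to_numpy()),
            [OBSERVABLES.index(o) for o in sub["observable"]],
        ]
        res[mask] = (sub["value"].to_numpy() - predicted) * weights.to_numpy()[mask]
    return res


class TimecourseFitter(BaseEstimator):
    """Weighted least-squares model fit to live-cell imaging time courses.

    Scikit-learn style estimator: construction stores the fit
    configuration, :meth:`fit` consumes a :class:`TimecourseDataset` (or a
    tidy DataFrame with the same columns) and exposes the estimates as
    fitted attributes.

    Parameters
    ----------
    free : sequence of str
        Parameters to optimise (ModelParams fields, ``ros_scale``,
        ``ros_baseline``).
    condition_specific : sequence of str
        Subset of ``free`` taking an independent value per condition.
    bounds : mapping, optional
        Per-parameter ``(lo, hi)`` overrides of the package defaults.
    weight_scheme : {"pooled_variance", "uniform"}
    multistart : int
        Number of jittered optimisation starts.
    seed : int
        Seed for the start jitter; recorded in the result.
    base_params, base_observation
        Values of the parameters held fixed.

    Attributes
    ----------
    result_ : FitResult
    params_ : dict mapping condition -> fitted ModelParams
    observation_ : dict mapping condition -> fitted ObservationModel
    init_states_ : dict mapping condition -> ModelState used as t=0 state
    rss_ : float
    """

    def __init__(
        self,
        free: Sequence[str] = ("alpha", "K", "beta", "r0"),
        condition_specific: Sequence[str] = (),
        bounds: Mapping[str, tuple[float, float]] | None = None,
        weight_scheme: str = "pooled_variance",
        multistart: int = 16,
        seed: int = 0,
        base_params: ModelParams | None = None,
        base_observation: ObservationModel | None = None,
        rtol: float = 1e-7,
        atol: float = 1e-9,
    ):
        self.free = free
        self.condition_specific = condition_specific
        self.bounds = bounds
        self.weight_scheme = weight_scheme
        self.multistart = multistart
        self.seed = seed
        self.base_params = base_params
        self.base_observation = base_observation
        self.rtol = rtol
        self.atol = atol

    # -- internal/external coordinate transforms ---------------------------
    @staticmethod
    def _to_internal(name: str, x: float) -> float:
        return float(np.log(x)) if name in _LOG_SCALE else float(x)

    @staticmethod
    def _from_internal(name: str, z: float) -> float:
        return float(np.exp(z)) if name in _LOG_SCALE else float(z)

    def _spec(self) -> FitSpec:
        return FitSpec(
            free=tuple(self.free),
            condition_specific=tuple(self.condition_specific),
            bounds=dict(self.bounds or {}),
            weight_scheme=self.weight_scheme,
            multistart=self.multistart,
            seed=self.seed,
        )

    def fit(self, X, y=None, init_states: Mapping[str, ModelState] | None = None):
        """Fit the model to a TimecourseDataset (or tidy DataFrame)."""
        dataset = X if isinstance(X, TimecourseDataset) else TimecourseDataset(X)
        spec = self._spec()
        base_p = self.base_params or ModelParams()
        base_o = self.base_observation or ObservationModel()
        conditions = dataset.conditions

        # one optimisation coordinate per shared free parameter, plus one
        # per (condition-specific parameter, condition) pair
        coords: list[tuple[str, str | None]] = []
        for name in spec.free:
            if name in spec.condition_specific:
                coords.extend((name, cond) for cond in conditions)
            else:
                coords.append((name, None))

        base_vals = {**base_p.to_dict(), **base_o.to_dict()}
        lo = np.array([self._to_internal(n, spec.bound_of(n)[0]) for n, _ in coords])
        hi = np.array([self._to_internal(n, spec.bound_of(n)[1]) for n, _ in coords])
        z0 = np.array(
            [self._to_internal(n, np.clip(base_vals[n], *spec.bound_of(n))) for n, _ in coords]
        )
        z0 = np.clip(z0, lo, hi)

        weights = compute_weights(dataset, spec.weight_scheme)

        def unpack(z: np.ndarray):
            p_by_cond: dict[str, ModelParams] = {}
            o_by_cond: dict[str, ObservationModel] = {}
            for cond in conditions:
                vals = dict(base_vals)
                for (name, c), zi in zip(coords, z):
                    if c is None or c == cond:
                        vals[name] = self._from_internal(name, zi)
                p_by_cond[cond] = ModelParams(**{k: vals[k] for k in _MODEL_FIELDS})
                o_by_cond[cond] = ObservationModel(**{k: vals[k] for k in _OBS_FIELDS})
            return p_by_cond, o_by_cond

        if init_states is None:
            init_states = _default_inits(dataset, {c: base_o for c in conditions})
        init_states = dict(init_states)

        n_records = len(dataset)

        def resid_fn(z):
            try:
                p_by_cond, o_by_cond = unpack(z)
                return residuals(
                    p_by_cond, o_by_cond, dataset, weights, init_states,
                    rtol=self.rtol, atol=self.atol,
                )
            except (ValueError, IntegrationError):
                return np.full(n_records, 1e6)

        rng = np.random.default_rng(spec.seed)
        starts = [z0]
        for _ in range(spec.multistart - 1):
            jitter = rng.uniform(-0.25, 0.25, size=len(z0)) * (hi - lo)
            starts.append(np.clip(z0 + jitter, lo, hi))

        best = None
        start_rss: list[float] = []
        diagnostics: list[str] = []
        for z_start in starts:
            try:
                sol = least_squares(
                    resid_fn, z_start, bounds=(lo, hi), method="trf",
                    xtol=1e-10, ftol=1e-10, gtol=1e-10,
                )
            except Exception as exc:  # pragma: no cover - defensive
                start_rss.append(float("nan"))
                diagnostics.append(str(exc))
                continue
            rss = float(np.sum(sol.fun**2))
            start_rss.append(rss)
            diagnostics.append(sol.message)
            if sol.status > 0 and (best is None or rss < best[1]):
                best = (sol, rss)
        if best is None:
            raise RuntimeError(
                "all optimisation starts failed: " + "; ".join(diagnostics)
            )
        sol, rss = best

        shared: dict[str, float] = {}
        per_condition: dict[str, dict[str, float]] = {c: {} for c in conditions}
        for (name, cond), zi in zip(coords, sol.x):
            v = self._from_internal(name, float(zi))
            if cond is None:
                shared[name] = v
            else:
                per_condition[cond][name] = v
        per_condition = {c: d for c, d in per_condition.items() if d}

        p_by_cond, o_by_cond = unpack(sol.x)
        final_res = residuals(
            p_by_cond, o_by_cond, dataset, weights, init_states,
            rtol=self.rtol, atol=self.atol,
        )
        norms = {
            name: float(np.linalg.norm(final_res[(dataset.records["observable"] == name).to_numpy()]))
            for name in OBSERVABLES
            if (dataset.records["observable"] == name).any()
        }
        self.result_ = FitResult(
            shared=shared,
            per_condition=per_condition,
            rss=float(np.sum(final_res**2)),
            residual_norms=norms,
            converged=bool(sol.status > 0),
            multistart_rss=tuple(start_rss),
            seed=spec.seed,
        )
        self.params_ = p_by_cond
        self.observation_ = o_by_cond
        self.init_states_ = init_states
        self.weights_ = weights
        self.rss_ = self.result_.rss
        return self

    def predict(self, times: Sequence[float], condition: str | None = None) -> pd.DataFrame:
        """Predicted observables at ``times`` for one or all conditions."""
        if not hasattr(self, "result_"):
            raise RuntimeError("fitter is not fitted; call fit() first")
        conds = [condition] if condition is not None else sorted(self.params_)
        out = []
        for cond in conds:
            df = predict_observables(
                self.params_[cond], self.observation_[cond], self.init_states_[cond],
                times, rtol=self.rtol, atol=self.atol,
            )
            df.insert(0, "condition", cond)
            out.append(df)
        return pd.concat(out, ignore_index=True)


def fit(
    dataset: TimecourseDataset,
    spec: FitSpec,
    init_states: Mapping[str, ModelState] | None = None,
    base_params: ModelParams | None = None,
    base_observation: ObservationModel | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> FitResult:
    """Functional wrapper over :class:`TimecourseFitter`."""
    fitter = TimecourseFitter(
        free=spec.free,
        condition_specific=spec.condition_specific,
        bounds=dict(spec.bounds),
        weight_scheme=spec.weight_scheme,
        multistart=spec.multistart,
        seed=spec.seed,
        base_params=base_params,
        base_observation=base_observation,
        rtol=rtol,
        atol=atol,
    )
    fitter.fit(dataset, init_states=init_states)
    return fitter.result_
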