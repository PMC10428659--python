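"""Maximum-entropy presence/background suitability model.

The model is the Gibbs density p(x) = exp(beta . f(x)) / Z over the study
grid, where f are bounded features of the environmental covariates and Z
normalizes over a background sample of cells. Fitting maximizes the
L1-penalized log-likelihood of the presence sample

    (1/m) sum_i beta . f(x_i) - log Z(beta) - sum_j lambda_j |beta_j|

by coordinate-wise proximal Newton updates with backtracking, which makes
the regularized training gain (the improvement over the uniform density)
non-decreasing by construction. Per-feature penalties scale with the
feature's presence-sample spread and shrink with presence count m:
lambda_j = reg_multiplier * base(class_j) * s_j / sqrt(m).

The raw density is mapped to an interpretable 0-1 scale by the
complementary log-log transform 1 - exp(-e^H * raw), with H the entropy of
the fitted distribution over the training background.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tickdist.env_layers import EnvStack, LayerError
from tickdist.suitability import SuitabilityMap


class FitError(ValueError):
    """Fatal problem during model fitting or prediction."""


# class-specific base regularization scales (largest for the very flexible
# hinge class, mirroring standard MaxEnt practice)
REG_BASE = {"linear": 0.05, "quadratic": 0.05, "product": 0.1, "hinge": 0.5}

ALLOWED_CLASSES = ("linear", "quadratic", "product", "hinge")


@dataclass
class Feature:
    """One expanded feature: its class, underlying variable(s), and knot."""

    kind: str
    variables: tuple[str, ...]
    knot: float | None = None  # scaled knot position in (0, 1) for hinges
    direction: str | None = None  # "forward" | "reverse" for hinges

    @property
    def name(self) -> str:
        if self.kind == "hinge":
            return f"hinge_{self.direction}({self.variables[0]}@{self.knot:.3f})"
        if self.kind == "product":
            return f"product({self.variables[0]}*{self.variables[1]})"
        return f"{self.kind}({self.variables[0]})"


@dataclass
class FeatureSet:
    """Feature expansion spec with per-variable scaling learned on training data.

    Every raw covariate x is affinely rescaled to u = (x - min)/(max - min)
    using training bounds, and all derived features lie in [0, 1] on the
    training data. Bounds are stored for projection-time clamping.
    """

    classes: tuple[str, ...] = ("linear", "quadratic", "hinge")
    hinge_knots: int = 10
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    variables: list[str] = field(default_factory=list)
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.classes:
            if c not in ALLOWED_CLASSES:
                raise FitError(f"unknown feature class {c!r}")

    @property
    def fitted(self) -> bool:
        return bool(self.features)

    def fit(self, table: pd.DataFrame, variables: list[str] | None = None) -> "FeatureSet":
        """Record training bounds and lay out the feature list."""
        if variables is None:
            variables = [c for c in table.columns if c not in ("lon", "lat", "species", "source")]
        self.variables = list(variables)
        self.bounds = {}
        self.means = {}
        constant = []
        for v in self.variables:
            x = table[v].to_numpy(dtype=float)
            lo, hi = float(np.min(x)), float(np.max(x))
            self.bounds[v] = (lo, hi)
            self.means[v] = float(np.mean(x))
            if hi == lo:
                constant.append(v)
        if constant:
            warnings.warn(
                f"constant variable(s) {constant}: quadratic/hinge features dropped",
                stacklevel=2,
            )
        feats: list[Feature] = []
        for v in self.variables:
            if "linear" in self.classes:
                feats.append(Feature("linear", (v,)))
            if v in constant:
                continue
            if "quadratic" in self.classes:
                feats.append(Feature("quadratic", (v,)))
            if "hinge" in self.classes:
                for t in range(1, self.hinge_knots + 1):
                    k = t / (self.hinge_knots + 1)
                    feats.append(Feature("hinge", (v,), knot=k, direction="forward"))
                    feats.append(Feature("hinge", (v,), knot=k, direction="reverse"))
        if "product" in self.classes:
            for i, a in enumerate(self.variables):
                if a in constant:
                    continue
                for b in self.variables[i + 1:]:
                    if b in constant:
                        continue
                    feats.append(Feature("product", (a, b)))
        self.features = feats
        return self

    def scale(self, table: pd.DataFrame, clamp: bool = False) -> dict[str, np.ndarray]:
        """Rescale raw covariates to [0,1] training units."""
        out: dict[str, np.ndarray] = {}
        for v in self.variables:
            if v not in table.columns:
                raise FitError(f"input table missing model variable {v!r}")
            lo, hi = self.bounds[v]
            x = table[v].to_numpy(dtype=float)
            if clamp:
                x = np.clip(x, lo, hi)
            if hi == lo:
                out[v] = np.full(x.shape, 0.5)
            else:
                out[v] = (x - lo) / (hi - lo)
        return out

    def transform(self, table: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        """Design matrix (n_points x n_features)."""
        if not self.fitted:
            raise FitError("FeatureSet.fit must be called before transform")
        u = self.scale(table, clamp=clamp)
        cols: list[np.ndarray] = []
        for ft in self.features:
            if ft.kind == "linear":
                cols.append(u[ft.variables[0]])
            elif ft.kind == "quadratic":
                cols.append(u[ft.variables[0]] ** 2)
            elif ft.kind == "product":
                cols.append(u[ft.variables[0]] * u[ft.variables[1]])
            else:  # hinge on scaled units: knots evenly spaced in (0, 1)
                x = u[ft.variables[0]]
                k = ft.knot
                if ft.direction == "forward":
                    cols.append(np.maximum(0.0, (x - k) / (1.0 - k)))
                else:
                    cols.append(np.maximum(0.0, (k - x) / k))
        return np.column_stack(cols)


@dataclass
class FitConfig:
    """Fitting controls.

    convergence_tol and max_iter are the stopping rule (an iteration is one
    full coordinate sweep); n_background caps the background sample;
    reg_multiplier scales every per-feature L1 penalty.
    """

    convergence_tol: float = 1e-5
    max_iter: int = 500
    n_background: int = 10_000
    reg_multiplier: float = 1.0
    output_transform: str = "cloglog"
    seed: int = 0
    feature_classes: tuple[str, ...] = ("linear", "quadratic", "hinge")
    hinge_knots: int = 10

    def __post_init__(self) -> None:
        if self.convergence_tol <= 0 or self.max_iter <= 0 or self.n_background <= 0:
            raise FitError("tolerances and counts must be positive")
        if self.reg_multiplier < 0:
            raise FitError("reg_multiplier must be non-negative")
        if self.output_transform not in ("raw", "cloglog"):
            raise FitError(f"unknown output transform {self.output_transform!r}")


@dataclass
class MaxEntModel:
    """A fitted maximum-entropy model."""

    features: FeatureSet
    beta: np.ndarray
    log_z: float  # log sum of exp(beta.f) over training background
    reg_lambda: np.ndarray
    gain_trace: list[float]
    entropy_H: float
    converged: bool
    termination: str
    n_presence: int
    n_background: int
    contribution_credit: dict[str, float] = field(default_factory=dict)

    @property
    def train_bounds(self) -> dict[str, tuple[float, float]]:
        return self.features.bounds

    @property
    def gain(self) -> float:
        return self.gain_trace[-1]

    def save(self, path: str | Path) -> None:
        doc = {
            "classes": list(self.features.classes),
            "hinge_knots": self.features.hinge_knots,
            "variables": self.features.variables,
            "bounds": {v: list(b) for v, b in self.features.bounds.items()},
            "means": dict(self.features.means),
            "features": [
                {"kind": f.kind, "variables": list(f.variables),
                 "knot": f.knot, "direction": f.direction}
                for f in self.features.features
            ],
            "beta": self.beta.tolist(),
            "log_z": self.log_z,
            "reg_lambda": self.reg_lambda.tolist(),
            "gain_trace": self.gain_trace,
            "entropy_H": self.entropy_H,
            "converged": self.converged,
            "termination": self.termination,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "contribution_credit": self.contribution_credit,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MaxEntModel":
        doc = json.loads(Path(path).read_text())
        fs = FeatureSet(classes=tuple(doc["classes"]), hinge_knots=doc["hinge_knots"])
        fs.variables = list(doc["variables"])
        fs.bounds = {v: tuple(b) for v, b in doc["bounds"].items()}
        fs.means = dict(doc.get("means", {}))
        fs.features = [
            Feature(d["kind"], tuple(d["variables"]), d["knot"], d["direction"])
            for d in doc["features"]
        ]
        return cls(
            features=fs,
            beta=np.asarray(doc["beta"], dtype=float),
            log_z=doc["log_z"],
            reg_lambda=np.asarray(doc["reg_lambda"], dtype=float),
            gain_trace=list(doc["gain_trace"]),
            entropy_H=doc["entropy_H"],
            converged=doc["converged"],
            termination=doc["termination"],
            n_presence=doc["n_presence"],
            n_background=doc["n_background"],
            contribution_credit=dict(doc["contribution_credit"]),
        )


def sample_background(stack: EnvStack, n: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Sample background cells uniformly without replacement.

    Returns a lon/lat + per-layer value table over n valid cells (all valid
    cells if n exceeds their count). Deterministic for a fixed seed.
    """
    if n is None:
        n = 10_000
    g = stack.geometry
    rows, cols = np.nonzero(stack.mask)
    n_valid = rows.size
    if n_valid == 0:
        raise FitError("stack has no valid cells to sample background from")
    rng = np.random.default_rng(seed)
    if n >= n_valid:
        idx = np.arange(n_valid)
    else:
        idx = np.sort(rng.choice(n_valid, size=n, replace=False))
    rr, cc = rows[idx], cols[idx]
    lon = g.x_min + (cc + 0.5) * g.cell_size
    lat = g.y_max - (rr + 0.5) * g.cell_size
    data = {"lon": lon, "lat": lat}
    for lyr in stack.layers:
        data[lyr.name] = lyr.values[rr, cc]
    df = pd.DataFrame(data)
    df.attrs["rows"] = rr
    df.attrs["cols"] = cc
    return df


def build_features(values: pd.DataFrame, spec: FeatureSet, clamp: bool = False) -> np.ndarray:
    """Expand a point-by-variable table into the design matrix."""
    return spec.transform(values, clamp=clamp)


def _soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def fit_maxent(
    presence: np.ndarray,
    background: np.ndarray,
    cfg: FitConfig,
    features: FeatureSet,
) -> MaxEntModel:
    """Fit the penalized Gibbs model from presence/background design rows.

    Coordinate-wise proximal Newton: each sweep visits every feature,
    soft-thresholds its Newton step against the feature's L1 penalty, and
    backtracks until the regularized gain does not decrease. Stops when a
    full sweep improves the gain by less than cfg.convergence_tol or after
    cfg.max_iter sweeps.
    """
    P = np.asarray(presence, dtype=float)
    B = np.asarray(background, dtype=float)
    if P.ndim != 2 or B.ndim != 2 or P.shape[1] != B.shape[1]:
        raise FitError("presence/background design matrices are incompatible")
    m, k = P.shape
    n = B.shape[0]
    if m < 5:
        raise FitError(f"need at least 5 presence rows, got {m}")
    if np.all(np.all(P == P[0], axis=1)):
        raise FitError("degenerate presence sample: all rows identical")

    f_pres = P.mean(axis=0)  # presence feature means (the constraints)
    s_pres = P.std(axis=0)
    lam = np.empty(k)
    for j, ft in enumerate(features.features):
        base = REG_BASE[ft.kind]
        lam[j] = cfg.reg_multiplier * base * max(s_pres[j], 0.05) / np.sqrt(m)

    beta = np.zeros(k)
    eta = np.zeros(n)  # B @ beta, maintained incrementally
    log_z = np.log(n)
    lin_pres = 0.0  # beta . f_pres

    def reg_gain(lin: float, lz: float, b: np.ndarray) -> float:
        # gain over the uniform density, minus the L1 penalty
        return lin - lz + np.log(n) - float(lam @ np.abs(b))

    gain = reg_gain(lin_pres, log_z, beta)  # == 0 at beta = 0
    gain_trace = [gain]
    credit: dict[str, float] = {v: 0.0 for v in features.variables}
    converged = False
    termination = "max_iter"

    from scipy.special import logsumexp

    for sweep in range(cfg.max_iter):
        sweep_start = gain
        for j in range(k):
            fj = B[:, j]
            q = np.exp(eta - log_z)  # current background probabilities
            e_fj = float(q @ fj)
            var_fj = float(q @ (fj * fj)) - e_fj * e_fj
            g = f_pres[j] - e_fj  # gradient of unpenalized gain
            h = max(var_fj, 1e-12)
            bj_new = _soft_threshold(beta[j] + g / h, lam[j] / h)
            delta = bj_new - beta[j]
            if delta == 0.0:
                continue
            # backtracking: accept only non-decreasing regularized gain
            accepted = False
            for _ in range(30):
                b_try = beta[j] + delta
                eta_try = eta + delta * fj
                lz_try = float(logsumexp(eta_try))
                lin_try = lin_pres + delta * f_pres[j]
                pen_delta = lam[j] * (abs(b_try) - abs(beta[j]))
                gain_try = lin_try - lz_try + np.log(n) - float(lam @ np.abs(beta)) - pen_delta
                if gain_try >= gain - 1e-12:
                    beta[j] = b_try
                    eta = eta_try
                    log_z = lz_try
                    lin_pres = lin_try
                    inc = gain_try - gain
                    gain = gain_try
                    accepted = True
                    break
                delta *= 0.5
            if accepted and inc > 0:
                ft = features.features[j]
                share = inc / len(ft.variables)
                for v in ft.variables:
                    credit[v] += share
        gain_trace.append(gain)
        if gain - sweep_start < cfg.convergence_tol:
            converged = True
            termination = f"converged after {sweep + 1} sweeps (gain delta < {cfg.convergence_tol})"
            break
    if not converged:
        warnings.warn(
            f"maxent fit did not converge within {cfg.max_iter} sweeps "
            f"(last sweep gain delta {gain - sweep_start:.3g})",
            stacklevel=2,
        )

    q = np.exp(eta - log_z)
    entropy = float(-np.sum(q * np.log(np.maximum(q, 1e-300))))
    return MaxEntModel(
        features=features,
        beta=beta,
        log_z=log_z,
        reg_lambda=lam,
        gain_trace=gain_trace,
        entropy_H=entropy,
        converged=converged,
        termination=termination,
        n_presence=m,
        n_background=n,
        contribution_credit=credit,
    )


def fit_from_tables(
    presence_table: pd.DataFrame,
    background_table: pd.DataFrame,
    cfg: FitConfig,
    variables: list[str] | None = None,
) -> MaxEntModel:
    """Convenience wrapper: fit scaling on presence+background, expand
    features, and fit the model."""
    if variables is None:
        variables = [
            c for c in background_table.columns
            if c not in ("lon", "lat", "species", "source")
        ]
    train = pd.concat(
        [presence_table[variables], background_table[variables]], ignore_index=True
    )
    fs = FeatureSet(classes=cfg.feature_classes, hinge_knots=cfg.hinge_knots)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fs.fit(train, variables)
    P = fs.transform(presence_table)
    B = fs.transform(background_table)
    return fit_maxent(P, B, cfg, fs)


def score_points(model: MaxEntModel, table: pd.DataFrame, transform: str = "cloglog",
                 clamp: bool = True) -> np.ndarray:
    """Model output at arbitrary points given their covariate values."""
    F = model.features.transform(table, clamp=clamp)
    raw = np.exp(F @ model.beta - model.log_z)
    if transform == "raw":
        return raw
    if transform == "cloglog":
        return 1.0 - np.exp(-np.exp(model.entropy_H) * raw)
    raise FitError(f"unknown output transform {transform!r}")


def predict(
    model: MaxEntModel,
    stack: EnvStack,
    transform: str = "cloglog",
    clamp: bool = True,
) -> SuitabilityMap:
    """Project the fitted model over every valid cell of a stack.

    raw(x) = exp(beta.f(x)) / Z with Z fixed at its training-background
    value, so raw sums to 1 over the training background; cloglog maps raw
    into (0, 1). With clamp on, covariates outside the training bounds are
    truncated to those bounds before feature expansion.
    """
    for v in model.features.variables:
        if v not in stack.names:
            raise LayerError(f"projection stack missing model variable {v!r}")
    g = stack.geometry
    rows, cols = np.nonzero(stack.mask)
    data = {lyr.name: lyr.values[rows, cols] for lyr in stack.layers}
    table = pd.DataFrame(data)
    vals = score_points(model, table, transform=transform, clamp=clamp)
    grid = np.full((g.n_rows, g.n_cols), np.nan)
    grid[rows, cols] = vals
    return SuitabilityMap(continuous=grid, geometry=g, mask=stack.mask.copy(),
                          period=stack.period)
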