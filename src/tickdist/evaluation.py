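"""Replicate evaluation of fitted suitability models.

Covers 75/25 train/test splitting, presence-background ROC/AUC with the
standard verbal rating bands, percent contribution from the optimizer's
path credits, jackknife variable importance on the training gain, and
univariate response curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tickdist.maxent import FitConfig, MaxEntModel, fit_from_tables, score_points
from tickdist.occurrences import OccurrenceSet


class EvalError(ValueError):
    """Fatal problem during evaluation."""


@dataclass
class SplitSpec:
    """Train/test split controls. Reproducible per (seed, replicate_id)."""

    train_fraction: float = 0.75
    seed: int = 0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise EvalError("train_fraction must lie strictly between 0 and 1")


@dataclass
class EvalReport:
    """Per-replicate AUCs plus contribution/jackknife/response summaries."""

    auc_train: list[float] = field(default_factory=list)
    auc_test: list[float] = field(default_factory=list)
    contributions: dict[str, float] = field(default_factory=dict)
    jackknife: dict[str, dict[str, float]] = field(default_factory=dict)
    response_curves: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def mean_auc_train(self) -> float:
        return float(np.mean(self.auc_train))

    @property
    def mean_auc_test(self) -> float:
        return float(np.mean(self.auc_test))

    @property
    def rating(self) -> str:
        return rate_auc(self.mean_auc_test)

    def replicate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": range(len(self.auc_train)),
                "auc_train": self.auc_train,
                "auc_test": self.auc_test,
            }
        )


def split_presences(occ: OccurrenceSet, spec: SplitSpec) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random 75/25 (by default) split of presence records.

    |train| = round(train_fraction * n); remainder is the test set.
    """
    n = len(occ)
    if n < 4:
        raise EvalError(f"need at least 4 records to split, got {n}")
    n_train = int(round(spec.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng([spec.seed, spec.replicate_id])
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    train = OccurrenceSet(species=occ.species, records=[occ.records[i] for i in train_idx])
    test = OccurrenceSet(species=occ.species, records=[occ.records[i] for i in test_idx])
    return train, test


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of (presence, background) pairs where the
    presence scores higher, ties counted one half. Equals the trapezoidal
    area under the empirical presence-background ROC curve."""
    p = np.asarray(presence_scores, dtype=float).ravel()
    b = np.asarray(background_scores, dtype=float).ravel()
    if p.size == 0 or b.size == 0:
        raise EvalError("AUC needs non-empty presence and background scores")
    from scipy.stats import rankdata

    combined = np.concatenate([p, b])
    ranks = rankdata(combined)
    r_p = np.sum(ranks[: p.size])
    u = r_p - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


_BANDS = (
    (0.5, 0.6, "failure"),
    (0.6, 0.7, "poor"),
    (0.7, 0.8, "fair"),
    (0.8, 0.9, "good"),
    (0.9, 1.0, "excellent"),
)


def rate_auc(value: float) -> str:
    """Verbal rating of an AUC value on half-open bands: [0.5,0.6) failure,
    [0.6,0.7) poor, [0.7,0.8) fair, [0.8,0.9) good, [0.9,1.0] excellent;
    below 0.5 is worse than random."""
    if not (0.0 <= value <= 1.0):
        raise EvalError(f"AUC must lie in [0,1], got {value}")
    if value < 0.5:
        return "worse than random"
    if value == 1.0:
        return "excellent"
    for lo, hi, label in _BANDS:
        if lo <= value < hi:
            return label
    raise AssertionError("unreachable")


def percent_contribution(model: MaxEntModel) -> dict[str, float]:
    """Per-variable percent contribution from optimizer path credits.

    Each gain increase during fitting was credited to the variable(s)
    underlying the updated feature; credits are normalized to sum to 100.
    """
    credit = model.contribution_credit
    total = sum(credit.values())
    if total <= 0:
        warnings.warn("zero total gain: contributions set uniform", stacklevel=2)
        k = len(credit)
        return {v: 100.0 / k for v in credit}
    return {v: 100.0 * c / total for v, c in credit.items()}


def permutation_importance(
    model: MaxEntModel,
    presence_table: pd.DataFrame,
    background_table: pd.DataFrame,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance: AUC drop (percent of total drop) when one
    variable's values are shuffled across presence+background points.
    A distinct diagnostic from path-based percent contribution."""
    rng = np.random.default_rng(seed)
    variables = model.features.variables
    p0 = score_points(model, presence_table, transform="raw")
    b0 = score_points(model, background_table, transform="raw")
    base = auc(p0, b0)
    drops: dict[str, float] = {}
    for v in variables:
        pt = presence_table.copy()
        bt = background_table.copy()
        pooled = np.concatenate([pt[v].to_numpy(), bt[v].to_numpy()])
        rng.shuffle(pooled)
        pt[v] = pooled[: len(pt)]
        bt[v] = pooled[len(pt):]
        a = auc(score_points(model, pt, transform="raw"),
                score_points(model, bt, transform="raw"))
        drops[v] = max(base - a, 0.0)
    total = sum(drops.values())
    if total <= 0:
        return {v: 0.0 for v in variables}
    return {v: 100.0 * d / total for v, d in drops.items()}


def jackknife_importance(
    presence_table: pd.DataFrame,
    background_table: pd.DataFrame,
    variables: list[str],
    cfg: FitConfig,
    include_without: bool = True,
) -> dict[str, dict[str, float]]:
    """Jackknife of training gain: for each variable, the gain of a model
    using only that variable and of a model using all others, alongside the
    full-model gain. All fits share one FitConfig. The leave-one-out fits
    dominate the cost; ``include_without=False`` skips them when only the
    single-variable gains are needed."""
    if len(variables) < 1:
        raise EvalError("jackknife needs at least one variable")
    if len(variables) == 1:
        warnings.warn("single variable: gain_without is undefined", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = fit_from_tables(presence_table, background_table, cfg, variables)
        out: dict[str, dict[str, float]] = {}
        for v in variables:
            only = fit_from_tables(presence_table, background_table, cfg, [v])
            rest = [w for w in variables if w != v]
            entry = {"gain_only": only.gain, "gain_full": full.gain}
            if rest and include_without:
                without = fit_from_tables(presence_table, background_table, cfg, rest)
                entry["gain_without"] = without.gain
            out[v] = entry
    return out


def response_curve(
    model: MaxEntModel,
    variable: str,
    n_points: int = 100,
    transform: str = "cloglog",
) -> pd.DataFrame:
    """Univariate response: sweep one variable across its training range
    with every other variable held at its training mean."""
    if variable not in model.features.variables:
        raise EvalError(f"model has no variable {variable!r}")
    lo, hi = model.features.bounds[variable]
    sweep = np.linspace(lo, hi, n_points)
    data = {}
    for v in model.features.variables:
        data[v] = np.full(n_points, model.features.means[v])
    data[variable] = sweep
    table = pd.DataFrame(data)
    y = score_points(model, table, transform=transform)
    return pd.DataFrame({variable: sweep, "suitability": y})
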