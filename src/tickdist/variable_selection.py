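"""Collinearity screening of candidate environmental variables.

Variables with pairwise Pearson |r| above a cut-off (0.9 by default) are
thinned greedily: the member of the worst-offending pair with the lower
model contribution is dropped, until no retained pair exceeds the cut-off.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class SelectionError(ValueError):
    """Fatal problem during variable screening."""


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over named variables.

    Zero-variance variables get NaN correlations against every other
    variable and are listed in ``degenerate``.
    """

    variables: list[str]
    r: np.ndarray
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variables)
        if self.r.shape != (k, k):
            raise SelectionError("correlation matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, equal_nan=True):
            raise SelectionError("correlation matrix is not symmetric")
        finite = np.isfinite(self.r)
        if np.any(np.abs(self.r[finite]) > 1 + 1e-12):
            raise SelectionError("correlation coefficients must lie in [-1, 1]")

    def get(self, a: str, b: str) -> float:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.r[i, j])


@dataclass
class SelectionResult:
    kept: list[str]
    dropped: list[tuple[str, str, float]]  # (dropped, kept partner, r)
    threshold: float

    def to_frame(self, contribution: dict[str, float] | None = None) -> pd.DataFrame:
        rows = []
        partner = {d: (p, r) for d, p, r in self.dropped}
        for v in self.kept + [d for d, _, _ in self.dropped]:
            p, r = partner.get(v, ("", np.nan))
            rows.append(
                {
                    "variable": v,
                    "kept": v in self.kept,
                    "partner": p,
                    "r": r,
                    "contribution": (contribution or {}).get(v, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path, contribution: dict[str, float] | None = None) -> None:
        self.to_frame(contribution).to_csv(path, index=False)


def pearson_matrix(table: pd.DataFrame, variables: list[str] | None = None) -> CorrelationMatrix:
    """Pearson product-moment correlations between variable columns.

    ``table`` is the point-by-layer value table (see extract_at_points);
    non-variable columns lon/lat are ignored unless explicitly listed.
    """
    if variables is None:
        variables = [c for c in table.columns if c not in ("lon", "lat", "species", "source")]
    X = table[variables].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise SelectionError("need at least 3 points for correlation screening")
    if np.isnan(X).any():
        raise SelectionError("value table contains masked/NaN entries")
    sd = X.std(axis=0, ddof=1)
    degenerate = [v for v, s in zip(variables, sd) if s == 0.0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    for v in degenerate:
        i = variables.index(v)
        r[i, :] = np.nan
        r[:, i] = np.nan
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(variables=list(variables), r=r, degenerate=degenerate)


_BIO_RE = re.compile(r"^[Bb]io(\d+)$")


def _canonical_order(name: str) -> tuple[int, int, str]:
    """Sort key: Bio1..Bio19 in numeric order first, then other names."""
    m = _BIO_RE.match(name)
    if m:
        return (0, int(m.group(1)), name)
    return (1, 0, name)


def select_variables(
    corr: CorrelationMatrix,
    contribution: dict[str, float],
    threshold: float = 0.9,
) -> SelectionResult:
    """Greedy screening of highly correlated variable pairs.

    Repeatedly find the retained pair with the largest |r| strictly above
    ``threshold`` and drop its lower-contribution member (ties broken by
    dropping the variable later in canonical Bio-number order), until no
    retained pair exceeds the threshold.
    """
    for v in corr.variables:
        if v not in contribution:
            raise SelectionError(f"no contribution value for variable {v!r}")
    kept = list(corr.variables)
    dropped: list[tuple[str, str, float]] = []
    while True:
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                r = corr.get(a, b)
                if np.isfinite(r) and abs(r) > threshold:
                    if best is None or abs(r) > best[0]:
                        best = (abs(r), a, b)
        if best is None:
            break
        _, a, b = best
        r = corr.get(a, b)
        ca, cb = contribution[a], contribution[b]
        if ca > cb:
            loser, winner = b, a
        elif cb > ca:
            loser, winner = a, b
        else:
            loser, winner = max(a, b, key=_canonical_order), min(a, b, key=_canonical_order)
        kept.remove(loser)
        dropped.append((loser, winner, r))
    # post-condition: no surviving pair above threshold
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            r = corr.get(a, b)
            assert not (np.isfinite(r) and abs(r) > threshold), (a, b, r)
    return SelectionResult(kept=kept, dropped=dropped, threshold=threshold)
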