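"""Suitability classification, binary conversion, areas, and change maps.

Continuous 0-1 suitability surfaces are cut into four levels (unsuitable /
low / medium / high) with Fisher-Jenks natural breaks, binarized at the
lowest break, and differenced between scenarios into gain/loss maps with
geodesic area accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tickdist.env_layers import EnvLayer, GridGeometry, write_layer

KM_PER_DEG = 111.32

CLASS_LABELS = ("unsuitable", "low", "medium", "high")


class ClassifyError(ValueError):
    """Fatal problem during classification or change accounting."""


@dataclass
class SuitabilityMap:
    """Continuous suitability surface plus optional classification.

    ``classes`` holds integer labels 0-3 (unsuitable..high) once computed;
    ``binary`` is 1 where the class is low/medium/high.
    """

    continuous: np.ndarray
    geometry: GridGeometry
    mask: np.ndarray = None
    period: str = "near-current"
    breaks: tuple[float, ...] | None = None
    classes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.continuous = np.asarray(self.continuous, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.continuous)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def binary(self) -> np.ndarray:
        if self.classes is None:
            raise ClassifyError("classify the map before binarizing")
        return binarize(self)

    def apply_breaks(self, breaks: tuple[float, ...]) -> "SuitabilityMap":
        self.breaks = tuple(breaks)
        self.classes = classify(self.continuous, self.breaks, self.mask)
        return self

    def write(self, path: str | Path, what: str = "continuous") -> None:
        g = self.geometry
        if what == "continuous":
            vals = self.continuous
        elif what == "classes":
            vals = np.where(self.mask, self.classes, np.nan).astype(float)
        elif what == "binary":
            vals = np.where(self.mask, self.binary, np.nan).astype(float)
        else:
            raise ClassifyError(f"unknown map kind {what!r}")
        write_layer(EnvLayer(name=what, geometry=g, values=vals, mask=self.mask), path)


@dataclass
class ChangeMap:
    """Per-cell transition between two binary scenarios.

    labels: 0 stable-unsuitable, 1 gain, 2 loss, 3 stable-suitable.
    """

    labels: np.ndarray
    geometry: GridGeometry
    mask: np.ndarray
    gain_km2: float
    loss_km2: float

    LABELS = {0: "stable-unsuitable", 1: "gain", 2: "loss", 3: "stable-suitable"}

    def counts(self) -> dict[str, int]:
        out = {}
        lab = self.labels[self.mask]
        for code, name in self.LABELS.items():
            out[name] = int(np.sum(lab == code))
        return out


def jenks_breaks(values: np.ndarray, k: int = 4, max_sample: int = 50_000,
                 seed: int = 0) -> tuple[float, ...]:
    """Fisher-Jenks natural breaks: k-1 interior break values.

    Dynamic programming over the sorted sample minimizes the total
    within-class sum of squared deviations; breaks are reported as the
    maximum value of each lower class. Samples larger than ``max_sample``
    are subsampled uniformly with a fixed seed.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if k < 1:
        raise ClassifyError("k must be >= 1")
    if np.unique(x).size < k:
        raise ClassifyError(f"need at least {k} distinct values for {k} classes")
    if k == 1:
        return ()
    if x.size > max_sample:
        rng = np.random.default_rng(seed)
        x = x[np.sort(rng.choice(x.size, size=max_sample, replace=False))]
    x = np.sort(x)
    n = x.size

    # prefix sums for O(1) within-class SSD of any contiguous run
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def ssd_vec(j: np.ndarray, i: int) -> np.ndarray:
        # SSD of x[j..i] inclusive, vectorized over j
        cnt = i - j + 1
        s = c1[i + 1] - c1[j]
        s2 = c2[i + 1] - c2[j]
        return s2 - s * s / cnt

    j_all = np.arange(n)
    # dp[i] = optimal SSD of x[0..i] in the current number of classes
    cnt = np.arange(1, n + 1)
    dp = c2[1:] - c1[1:] * c1[1:] / cnt  # single-class SSD of x[0..i]
    split = np.zeros((k, n), dtype=int)
    for cls in range(1, k):
        dp_new = np.full(n, np.inf)
        for i in range(cls, n):
            j = j_all[cls:i + 1]  # first index of the top class
            cand = dp[j - 1] + ssd_vec(j, i)
            best = int(np.argmin(cand))
            dp_new[i] = cand[best]
            split[cls, i] = j[best]
        dp = dp_new
    # recover class boundaries
    breaks = []
    i = n - 1
    for cls in range(k - 1, 0, -1):
        j = split[cls, i]
        breaks.append(x[j - 1])  # max value of the class below
        i = j - 1
    return tuple(sorted(float(b) for b in breaks))


def jenks_breaks_exhaustive(values: np.ndarray, k: int) -> tuple[float, ...]:
    """Brute-force optimal breaks by enumerating all ordered partitions.

    Exponential; for cross-checking the dynamic program on tiny inputs.
    """
    from itertools import combinations

    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    best_ssd = np.inf
    best_cuts: tuple[int, ...] = ()
    for cuts in combinations(range(1, n), k - 1):
        ssd = 0.0
        idx = (0, *cuts, n)
        for a, b in zip(idx[:-1], idx[1:]):
            seg = x[a:b]
            ssd += float(np.sum((seg - seg.mean()) ** 2))
        if ssd < best_ssd - 1e-12:
            best_ssd = ssd
            best_cuts = cuts
    return tuple(float(x[c - 1]) for c in best_cuts)


def classify(continuous: np.ndarray, breaks: tuple[float, ...],
             mask: np.ndarray | None = None) -> np.ndarray:
    """Class grid from interior breaks: value <= b1 -> 0 (unsuitable),
    (b1,b2] -> 1, (b2,b3] -> 2, > b3 -> 3."""
    breaks = tuple(breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ClassifyError(f"breaks must be strictly increasing, got {breaks}")
    x = np.asarray(continuous, dtype=float)
    if mask is None:
        mask = np.isfinite(x)
    cls = np.zeros(x.shape, dtype=int)
    for b in breaks:
        cls += (x > b).astype(int)
    cls[~mask] = -1
    return cls


def binarize(smap: SuitabilityMap) -> np.ndarray:
    """Binary suitable/unsuitable grid: any class above unsuitable counts
    as suitable (threshold = lowest Jenks break)."""
    if smap.classes is None:
        raise ClassifyError("classify the map before binarizing")
    return ((smap.classes > 0) & smap.mask).astype(int)


def cell_areas_km2(geometry: GridGeometry) -> np.ndarray:
    """Per-cell area grid: (111.32 * cellsize)^2 * cos(latitude of centre)."""
    _, lat = geometry.cell_centers()
    side = KM_PER_DEG * geometry.cell_size
    return side * side * np.cos(np.radians(lat))


def area_km2(binary: np.ndarray, geometry: GridGeometry) -> float:
    """Total area of cells flagged 1, in km^2."""
    binary = np.asarray(binary)
    return float(np.sum(cell_areas_km2(geometry) * (binary == 1)))


def change_map(current: SuitabilityMap, future: SuitabilityMap) -> ChangeMap:
    """Difference two binary scenario maps into gain/loss/stable labels."""
    if current.geometry != future.geometry:
        raise ClassifyError("change_map requires identical geometries")
    mask = current.mask & future.mask
    cur = current.binary
    fut = future.binary
    labels = np.zeros(cur.shape, dtype=int)
    labels[(cur == 0) & (fut == 1)] = 1  # gain
    labels[(cur == 1) & (fut == 0)] = 2  # loss
    labels[(cur == 1) & (fut == 1)] = 3  # stable suitable
    labels[~mask] = -1
    areas = cell_areas_km2(current.geometry)
    gain = float(np.sum(areas[mask & (labels == 1)]))
    loss = float(np.sum(areas[mask & (labels == 2)]))
    return ChangeMap(labels=labels, geometry=current.geometry, mask=mask,
                     gain_km2=gain, loss_km2=loss)
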