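"""Seeded synthetic landscapes with known-truth suitability.

Generates the statistical structure the pipeline assumes, without any
download: spatially smooth correlated "climate" rasters (Gaussian random
fields rescaled to plausible bioclimatic ranges), a known Gibbs-density
suitability surface, presence samples drawn from it, manufactured
collinear layer pairs for screening tests, and drifted "future" stacks
that push the favourable climate window in a chosen direction.

The generator emulates the covariance smoothness and masking of real
climate grids, not any real geography.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from tickdist.env_layers import EnvLayer, EnvStack, GridGeometry, PERIOD_LABELS, write_layer
from tickdist.occurrences import OccurrenceRecord, OccurrenceSet


class SyntheticError(ValueError):
    """Invalid synthetic configuration."""


# plausible value ranges per Bio-style layer name (units as in the real
# bioclimatic set: temperatures in deg C, Bio4 as std*100, precipitation mm)
_RANGES = {
    "Bio1": (-4.0, 22.0),
    "Bio3": (18.0, 45.0),
    "Bio4": (600.0, 1500.0),
    "Bio7": (25.0, 50.0),
    "Bio8": (-10.0, 25.0),
    "Bio11": (-20.0, 8.0),
    "Bio12": (50.0, 1100.0),
    "Bio15": (40.0, 160.0),
    "elev": (100.0, 3200.0),
}
_DEFAULT_NAMES = ("Bio1", "Bio4", "Bio7", "Bio12", "Bio15", "Bio3", "Bio8", "elev")


@dataclass
class Drift:
    """Additive per-period change of one variable, in SD units of that
    layer: a uniform offset plus a west-positive longitudinal gradient."""

    offset: float = 0.0
    west_gradient: float = 0.0


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic landscape.

    The grid is a 120 x 160 cell window at 5 arc-minutes (comparable in
    cell count to a provincial-scale study region); eight candidate
    variables with a 6-cell correlation length; the generative truth is a
    Gibbs density dominated by temperature seasonality (Bio4) with a
    secondary precipitation-seasonality effect; 200 presences; one
    manufactured collinear pair (Bio11 ~ Bio1) for screening tests; and a
    progressive warm-west drift over the four future periods.
    """

    n_rows: int = 120
    n_cols: int = 160
    n_layers: int = 8
    smoothness: float = 6.0
    true_beta: dict[str, float] = field(
        default_factory=lambda: {"Bio4": 2.0, "Bio15": -1.0}
    )
    n_presence: int = 200
    collinear_pairs: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("Bio1", "Bio11", 0.05)]
    )
    future_shift: dict[str, dict[str, Drift]] = field(default_factory=dict)
    cell_size: float = 5.0 / 60.0  # 5 arc-minutes
    x_min: float = 97.0
    y_max: float = 53.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 20 or self.n_cols < 20:
            raise SyntheticError("grid must be at least 20 x 20")
        if self.n_presence < 20:
            raise SyntheticError("n_presence must be >= 20")
        names = self.layer_names()
        if len(set(names)) != len(names):
            raise SyntheticError("layer names must be distinct")
        if not self.future_shift:
            self.future_shift = {
                period: {"Bio4": Drift(offset=0.15 * i, west_gradient=0.6 * i)}
                for i, period in enumerate(PERIOD_LABELS[1:], start=1)
            }

    def layer_names(self) -> list[str]:
        base = list(_DEFAULT_NAMES[: self.n_layers])
        if len(base) < self.n_layers:
            base += [f"Bio{i + 20}" for i in range(self.n_layers - len(base))]
        for _, copy, _ in self.collinear_pairs:
            base.append(copy)
        return base


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  smoothness: float) -> np.ndarray:
    z = rng.standard_normal(shape)
    if smoothness > 0:
        z = gaussian_filter(z, sigma=smoothness, mode="reflect")
        z = (z - z.mean()) / z.std()
    return z


def generate_stack(cfg: SyntheticConfig) -> EnvStack:
    """Generate the near-current environment stack.

    Each layer is white noise convolved with a Gaussian kernel of the
    configured correlation length, rescaled to a plausible range for its
    name; collinear pairs add a near-duplicate layer (copy = source plus
    Gaussian noise of noise_sd SDs); a wavy nodata margin is carved along
    the western edge to emulate a coastline/border mask.
    """
    rng = np.random.default_rng(cfg.seed)
    geom = GridGeometry(
        n_rows=cfg.n_rows, n_cols=cfg.n_cols,
        x_min=cfg.x_min, y_max=cfg.y_max, cell_size=cfg.cell_size,
    )
    shape = (cfg.n_rows, cfg.n_cols)

    # coastal-style mask: wavy margin on the west edge
    phase = rng.uniform(0, 2 * np.pi)
    rows = np.arange(cfg.n_rows)
    margin = 2 + 2 * (1 + np.sin(2 * np.pi * rows / cfg.n_rows * 2 + phase))
    mask = np.ones(shape, dtype=bool)
    for r in range(cfg.n_rows):
        mask[r, : int(margin[r])] = False

    base_names = list(_DEFAULT_NAMES[: cfg.n_layers])
    if len(base_names) < cfg.n_layers:
        base_names += [f"Bio{i + 20}" for i in range(cfg.n_layers - len(base_names))]
    fields: dict[str, np.ndarray] = {}
    for name in base_names:
        z = _smooth_field(rng, shape, cfg.smoothness)
        lo, hi = _RANGES.get(name, (0.0, 100.0))
        zmin, zmax = z.min(), z.max()
        fields[name] = lo + (z - zmin) / (zmax - zmin) * (hi - lo)
    for source, copy, noise_sd in cfg.collinear_pairs:
        if source not in fields:
            raise SyntheticError(f"collinear source {source!r} not among layers")
        src = fields[source]
        fields[copy] = src + rng.standard_normal(shape) * noise_sd * src.std()

    layers = [
        EnvLayer(name=n, geometry=geom, values=np.where(mask, v, np.nan), mask=mask)
        for n, v in fields.items()
    ]
    return EnvStack(layers=layers, period="near-current")


def truth_surface(stack: EnvStack, true_beta: dict[str, float],
                  ref_stack: EnvStack | None = None) -> np.ndarray:
    """The generative Gibbs density over valid cells (sums to 1).

    Variables are standardized with the reference stack's statistics (the
    near-current stack by default), so drifted future stacks shift the
    density rather than being re-normalized away.
    """
    ref = ref_stack or stack
    eta = np.zeros(stack.mask.sum())
    for v, b in true_beta.items():
        x = stack.layer(v).values[stack.mask]
        xr = ref.layer(v).values[ref.mask]
        eta = eta + b * (x - xr.mean()) / xr.std()
    eta -= eta.max()
    p = np.exp(eta)
    p /= p.sum()
    grid = np.full(stack.mask.shape, np.nan)
    grid[stack.mask] = p
    return grid


def sample_presences(
    stack: EnvStack,
    true_beta: dict[str, float],
    n: int,
    seed: int = 0,
    species: str = "Dermacentor synthetica",
) -> OccurrenceSet:
    """Draw presence points from the truth density.

    Cells are sampled with probability proportional to exp(beta . z), and
    each point is placed uniformly within its cell.
    """
    rng = np.random.default_rng(seed)
    p_grid = truth_surface(stack, true_beta)
    rows, cols = np.nonzero(stack.mask)
    p = p_grid[rows, cols]
    idx = rng.choice(p.size, size=n, replace=True, p=p)
    g = stack.geometry
    records = []
    for i in idx:
        r, c = rows[i], cols[i]
        lon = g.x_min + (c + rng.uniform()) * g.cell_size
        lat = g.y_max - (r + rng.uniform()) * g.cell_size
        records.append(OccurrenceRecord(species=species, lon=lon, lat=lat,
                                        source="synthetic"))
    return OccurrenceSet(species=species, records=records)


def generate_future_stack(stack: EnvStack, period: str,
                          cfg: SyntheticConfig) -> EnvStack:
    """Apply the configured per-variable drift to produce a future stack.

    Drift is additive in SD units of each layer; the west-positive
    longitudinal gradient raises values toward the western edge, forcing a
    directional shift of the favourable climate window. Geometry and mask
    are unchanged.
    """
    if period not in PERIOD_LABELS[1:]:
        raise SyntheticError(f"unknown future period {period!r}")
    drifts = cfg.future_shift.get(period, {})
    g = stack.geometry
    u_lon = (np.arange(g.n_cols) + 0.5) / g.n_cols  # 0 at west edge
    layers = []
    for lyr in stack.layers:
        vals = lyr.values.copy()
        if lyr.name in drifts:
            d = drifts[lyr.name]
            sd = np.nanstd(vals)
            vals = vals + sd * (d.offset + d.west_gradient * (0.5 - u_lon)[None, :])
        layers.append(EnvLayer(name=lyr.name, geometry=g,
                               values=np.where(stack.mask, vals, np.nan),
                               mask=stack.mask.copy()))
    return EnvStack(layers=layers, period=period, mask=stack.mask.copy())


def write_synthetic_study(cfg: SyntheticConfig, out_dir: str | Path) -> dict:
    """Write a complete synthetic study to disk: occurrence CSV, ASCII-grid
    stacks for all five periods, the truth surface, and a truth manifest.
    Returns the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = generate_stack(cfg)
    occ = sample_presences(stack, cfg.true_beta, cfg.n_presence, seed=cfg.seed + 1)
    occ.to_csv(out / "occurrences.csv")
    stacks = {"near-current": stack}
    for period in PERIOD_LABELS[1:]:
        stacks[period] = generate_future_stack(stack, period, cfg)
    for period, st in stacks.items():
        d = out / f"stack_{period.replace('-', '_')}"
        d.mkdir(exist_ok=True)
        for lyr in st.layers:
            write_layer(lyr, d / f"{lyr.name}.asc")
    truth = truth_surface(stack, cfg.true_beta)
    write_layer(
        EnvLayer(name="truth", geometry=stack.geometry, values=truth,
                 mask=stack.mask), out / "truth_surface.asc",
    )
    manifest = {
        "species": occ.species,
        "n_presence": cfg.n_presence,
        "true_beta": cfg.true_beta,
        "layer_names": stack.names,
        "periods": list(stacks),
        "seed": cfg.seed,
    }
    import json

    (out / "truth_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
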