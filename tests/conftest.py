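"""Shared fixtures: small synthetic landscapes and fitted models.

Everything is generated programmatically with fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tickdist import (
    EnvLayer,
    EnvStack,
    FitConfig,
    GridGeometry,
    SyntheticConfig,
    generate_stack,
    sample_presences,
)
from tickdist.env_layers import extract_at_points
from tickdist.maxent import fit_from_tables, sample_background


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A reduced landscape for fast unit tests (not the study defaults)."""
    return SyntheticConfig(n_rows=40, n_cols=50, n_layers=5, smoothness=3.0,
                           n_presence=120, seed=42)


@pytest.fixture(scope="session")
def small_stack(small_cfg) -> EnvStack:
    return generate_stack(small_cfg)


@pytest.fixture(scope="session")
def small_presences(small_cfg, small_stack):
    return sample_presences(small_stack, small_cfg.true_beta,
                            small_cfg.n_presence, seed=7)


@pytest.fixture(scope="session")
def small_tables(small_stack, small_presences):
    background = sample_background(small_stack, 2000, seed=5)
    presence = extract_at_points(small_stack, small_presences)
    return presence, background


@pytest.fixture(scope="session")
def small_model(small_tables, small_stack):
    presence, background = small_tables
    cfg = FitConfig(seed=1, hinge_knots=5)
    return fit_from_tables(presence, background, cfg, small_stack.names)


@pytest.fixture()
def unit_geometry() -> GridGeometry:
    """3x3 one-degree grid anchored at (0 E, 3 N)."""
    return GridGeometry(n_rows=3, n_cols=3, x_min=0.0, y_max=3.0, cell_size=1.0)


def make_layer(values, name="x", x_min=0.0, y_max=None, cell_size=1.0,
               nodata=-9999.0) -> EnvLayer:
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    if y_max is None:
        y_max = n_rows * cell_size
    geom = GridGeometry(n_rows=n_rows, n_cols=n_cols, x_min=x_min, y_max=y_max,
                        cell_size=cell_size, nodata=nodata)
    return EnvLayer(name=name, geometry=geom, values=values)


@pytest.fixture()
def make_table():
    def _make(**cols) -> pd.DataFrame:
        return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in cols.items()})

    return _make
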