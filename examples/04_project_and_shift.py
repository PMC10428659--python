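"""Project to a future climate and measure the range shift.

Fits a model on the near-current landscape, projects it (with clamping)
onto a drifted 2081-2100 stack, classifies both maps with Jenks natural
breaks fixed on the near-current surface, and reports area change and the
centroid shift in km and compass direction.
"""

import warnings

from tickdist import (
    SyntheticConfig, generate_future_stack, generate_stack, habitat_centroid,
    predict, sample_presences, shift,
)
from tickdist.env_layers import extract_at_points
from tickdist.maxent import FitConfig, fit_from_tables, sample_background
from tickdist.suitability import area_km2, change_map, jenks_breaks

warnings.simplefilter("ignore")

cfg = SyntheticConfig(n_rows=60, n_cols=80, seed=5)
stack = generate_stack(cfg)
occ = sample_presences(stack, cfg.true_beta, n=150, seed=6)
background = sample_background(stack, 5000, seed=7)
presence = extract_at_points(stack, occ)

model = fit_from_tables(presence, background, FitConfig(seed=8), stack.names)

future = generate_future_stack(stack, "2081-2100", cfg)
cur = predict(model, stack, clamp=True)
fut = predict(model, future, clamp=True)

# one set of breaks, fixed on the near-current map, keeps periods comparable
breaks = jenks_breaks(cur.continuous[stack.mask], k=4, seed=0)
cur.apply_breaks(breaks)
fut.apply_breaks(breaks)
print(f"Jenks breaks        : {[round(b, 3) for b in breaks]}")

geom = stack.geometry
a_cur = area_km2(cur.binary, geom)
a_fut = area_km2(fut.binary, geom)
cm = change_map(cur, fut)
print(f"suitable area now   : {a_cur:10.0f} km^2")
print(f"suitable area future: {a_fut:10.0f} km^2")
print(f"gain / loss         : {cm.gain_km2:10.0f} / {cm.loss_km2:.0f} km^2")

rep = shift(habitat_centroid(cur.binary, geom), habitat_centroid(fut.binary, geom))
print(f"centroid shift      : {rep.distance_km:.2f} km toward {rep.cardinal} "
      f"(bearing {rep.bearing_deg:.1f} deg)")
# The default drift raises Bio4 toward the west, so the suitable range
# expands and its centroid moves west of its near-current position.
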