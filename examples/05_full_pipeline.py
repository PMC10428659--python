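"""The complete study in one call.

Writes a reduced synthetic study to a temporary directory, runs the whole
pipeline (thin -> screen -> replicate fits -> evaluate -> classify ->
project -> change maps -> centroid shifts), and prints the manifest
highlights. The same entry point drives real studies from a YAML config
via `tickdist run`.
"""

import tempfile
from pathlib import Path

from tickdist import RunConfig, SyntheticConfig, run_pipeline
from tickdist.maxent import FitConfig
from tickdist.synthetic import write_synthetic_study

PERIODS = ["near-current", "2021-2040", "2041-2060", "2061-2080", "2081-2100"]

with tempfile.TemporaryDirectory() as tmp:
    study = Path(tmp) / "study"
    write_synthetic_study(
        SyntheticConfig(n_rows=50, n_cols=60, n_presence=120, seed=1), study)
    cfg = RunConfig(
        species="Dermacentor synthetica",
        occurrence_csv=str(study / "occurrences.csv"),
        stack_dirs={p: str(study / f"stack_{p.replace('-', '_')}")
                    for p in PERIODS},
        out_dir=str(Path(tmp) / "run"),
        n_replicates=5,
        seed=2,
        fit=FitConfig(hinge_knots=5, n_background=3000),
    )
    man = run_pipeline(cfg)

    sel = man["stages"]["variable_selection"]
    rep = man["stages"]["maxent_replicates"]
    suit = man["stages"]["suitability"]
    print(f"thinned presences : {man['stages']['occurrences']['n_thinned']}")
    dropped = [d for d, _, _ in sel["dropped"]]
    print(f"variables kept    : {len(sel['kept'])} (dropped {dropped})")
    print(f"mean test AUC     : {rep['mean_auc_test']:.3f} ({rep['rating']})")
    print(f"area near-current : {suit['areas_km2']['near-current']:.0f} km^2")
    print(f"area 2081-2100    : {suit['areas_km2']['2081-2100']:.0f} km^2")
    s = suit["centroid_shifts"]["2081-2100"]
    print(f"centroid shift    : {s['distance_km']:.2f} km {s['cardinal']}")
    print(f"outputs written   : {len(man['outputs'])} files + manifest.json")
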