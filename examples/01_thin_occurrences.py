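"""Spatial thinning of occurrence records.

Builds a tiny occurrence CSV with two clusters of tick records, thins it so
at most one record survives per 10 x 10 km grid cell, and prints the
before/after counts. Thinning removes duplicate sampling of the same
locality, which would otherwise bias the presence sample.
"""

import tempfile
from pathlib import Path

from tickdist import read_occurrences, thin_occurrences

rows = [
    # three records within ~3 km of each other near Hohhot
    ("Dermacentor nuttalli", 111.650, 40.820),
    ("Dermacentor nuttalli", 111.660, 40.830),
    ("Dermacentor nuttalli", 111.670, 40.840),
    # two well-separated records
    ("Dermacentor nuttalli", 113.100, 41.500),
    ("Dermacentor nuttalli", 115.900, 43.900),
    # a different species, ignored by the species filter
    ("Ixodes persulcatus", 121.500, 50.400),
    # a malformed coordinate, dropped with a count
    ("Dermacentor nuttalli", 111.700, 95.000),
]

with tempfile.TemporaryDirectory() as tmp:
    csv = Path(tmp) / "occ.csv"
    csv.write_text("species,lon,lat,source\n" + "\n".join(
        f"{s},{lon},{lat},example" for s, lon, lat in rows))
    occ = read_occurrences(csv, "Dermacentor nuttalli")
    thinned = thin_occurrences(occ, cell_km=10.0)

print(f"records read for the species : {len(occ)}")
print(f"malformed coordinates dropped: {occ.n_dropped}")
print(f"records after 10-km thinning : {len(thinned)}")
for r in thinned:
    print(f"  kept ({r.lon:.3f} E, {r.lat:.3f} N)")
# The three clustered records collapse to one: they share a 10-km cell.
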