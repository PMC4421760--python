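"""Link two misaligned monitor networks and aggregate point data to buffers.

Mass monitors (dense) are linked to the closest speciation monitor within
6 miles; community values at ZIP-like centroid points are averaged over the
same 6-mile buffer around each mass monitor.
"""

import numpy as np

import bhpm
from bhpm.geo import MonitorLocation, aggregate_buffer

rng = np.random.default_rng(0)
mass = bhpm.simulate_locations(518, seed=1)
speciation = bhpm.simulate_locations(174, seed=2)

targets = [MonitorLocation(r.location_id, r.lon, r.lat) for r in mass.itertuples()]
sources = [MonitorLocation("s" + r.location_id, r.lon, r.lat) for r in speciation.itertuples()]
links = bhpm.link_nearest_within(targets, sources, radius=6.0)
n_linked = sum(l.source_id is not None for l in links)
d = [l.distance for l in links if l.source_id is not None]
print(f"{n_linked} of {len(targets)} mass monitors have a speciation monitor "
      f"within 6 miles (median link distance {np.median(d):.1f} mi)")

# aggregate simulated centroid values around the first linked monitor
centroids = [
    (MonitorLocation(f"z{i}", t.lon + dx, t.lat + dy), float(rng.normal(40000, 8000)))
    for t in targets[:1]
    for i, (dx, dy) in enumerate(rng.normal(0, 0.04, size=(12, 2)))
]
value, ok = aggregate_buffer(targets[0], centroids, radius=6.0, mode="mean")
print(f"mean community value over the buffer around {targets[0].id}: "
      f"{value:,.0f} (from points within 6 miles; ok={ok})")
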