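"""Inventory summaries: production units, non-producers, DBH filtering.

Builds a tiny in-memory inventory, converts harvester tin-can ("lata")
production estimates to kg, and prints the whole-inventory summary.
"""

import numpy as np
import pandas as pd

from habqual import filter_min_dbh, latas_to_kg, summarize

rng = np.random.default_rng(0)
n = 500
inventory = pd.DataFrame({
    "tree_id": [f"T{i:04d}" for i in range(n)],
    "concession_id": rng.choice(["C001", "C002", "C003"], n),
    "lon": rng.uniform(-69.8, -69.6, n),
    "lat": rng.uniform(-12.8, -12.6, n),
    "dbh": rng.lognormal(4.0, 0.45, n).round(1),
    "height": np.nan,
    "latas": np.where(rng.random(n) < 0.13, 0.0, rng.poisson(3.0, n)),
    "phyto_flags": "",
})
inventory.loc[rng.choice(n, 40, replace=False), "latas"] = np.nan  # not estimated

adults = filter_min_dbh(inventory, 10.0)
s = summarize(adults)
print(s.to_json())
print(f"one lata of fresh in-shell seed = {latas_to_kg(1)} kg")

# n_with_production counts trees whose production was estimated (blank !=
# zero); zero_producer_fraction is the share of those claimed never to
# produce; sp_* statistics are per-tree annual seed production in kg.
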