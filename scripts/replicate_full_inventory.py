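"""Replicate the inventory-level summary statistics on the real
Madre de Dios concession inventory (not shipped with this package).

Supply a local copy of the deposited inventory as a delimited table with
tree id, concession id, coordinates, DBH (cm) and per-tree production in
latas, then run e.g.:

    python scripts/replicate_full_inventory.py inventory.csv \
        --column-map tree_id=ID,concession_id=CONC,lon=X,lat=Y,dbh=DAP,latas=LATAS

Prints the total record count at DBH >= 10 cm, the mean/SD per-tree seed
production in kg, and the non-producer fraction.
"""

import argparse
import json

from habqual.inventory import filter_min_dbh, read_inventory, summarize


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("inventory")
    ap.add_argument("--sep", default=",")
    ap.add_argument("--column-map", default="",
                    help="comma-separated canonical=file column pairs")
    ap.add_argument("--min-dbh", type=float, default=10.0)
    args = ap.parse_args()

    cmap = dict(pair.split("=") for pair in args.column_map.split(",") if pair)
    records = read_inventory(args.inventory, column_map=cmap, sep=args.sep)
    records = filter_min_dbh(records, args.min_dbh)
    s = summarize(records)
    print(json.dumps({
        "n_records_dbh_ge_min": s.n_total,
        "sp_mean_kg": s.sp_mean,
        "sp_sd_kg": s.sp_sd,
        "sp_range_kg": [s.sp_min, s.sp_max],
        "non_producer_fraction": s.zero_producer_fraction,
    }, indent=2))


if __name__ == "__main__":
    main()
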