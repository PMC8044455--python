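"""Fitness-density trade-off classification of environmental responses.

For each environmental variable, three fitted responses are compared: the
tree-centric fitness response (per-tree seed production or biomass), the
density response, and the area-based service response (the per-cell sum).
The classifier labels the fitness/density pair as *congruent* (same
direction), *divergent* (opposite directions), *partial* (only one side
responds) or *null*, and — for divergent/partial cases — records which
component the area-based service follows:

* ``N``: the area response is non-significant (the opposing components
  neutralize each other);
* ``D``: the area response carries the density sign;
* ``F``: the area response carries the fitness sign (or mirrors the flat
  fitness side in a partial case).

Marginal codes (–↑/–↓) count as signal-bearing; arrow strength beyond that
is ignored — only direction matters for the classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .arrows import ArrowCode, parse_arrow

__all__ = [
    "ResponseTriple",
    "TradeoffClass",
    "classify",
    "classify_table",
    "tabulate",
    "load_reference_matrix",
]


@dataclass(frozen=True)
class ResponseTriple:
    """Arrow codes for one environmental variable and one service."""

    variable: str
    service: str  # "seed" or "agb"
    fitness: ArrowCode
    density: ArrowCode
    area: ArrowCode


@dataclass(frozen=True)
class TradeoffClass:
    relation: str  # congruent | divergent | partial | null
    area_label: str  # N | D | F | none
    diagnostic: str = ""


def classify(fitness: ArrowCode, density: ArrowCode, area: ArrowCode) -> TradeoffClass:
    """Classify one (fitness, density, area) arrow triple.

    Pure and total over the 9x9x9 code space.
    """
    f_sb, d_sb = fitness.signal_bearing, density.signal_bearing

    if f_sb and d_sb:
        if fitness.sign == density.sign:
            return TradeoffClass("congruent", "none")
        # opposite directions: who wins the area-based service?
        if not area.signal_bearing:
            return TradeoffClass("divergent", "N")
        if area.sign == density.sign:
            return TradeoffClass("divergent", "D")
        return TradeoffClass("divergent", "F")

    if f_sb or d_sb:
        live_label, flat_label = ("F", "D") if f_sb else ("D", "F")
        live = fitness if f_sb else density
        if area.signal_bearing:
            if area.sign == live.sign:
                return TradeoffClass("partial", live_label)
            # area responds against the only responding component: it matches
            # neither the live side's sign nor the flat side's flatness
            return TradeoffClass(
                "partial", "none", "area opposes the responding component"
            )
        # flat area mirrors the flat component
        return TradeoffClass("partial", flat_label)

    return TradeoffClass("null", "none")


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Classify every row of an arrow table.

    ``table`` needs columns ``variable``, ``service``, ``fitness``,
    ``density``, ``area`` holding arrow strings; returns a copy with
    ``relation`` and ``area_label`` columns appended.
    """
    out = table.copy()
    cls = [
        classify(parse_arrow(r.fitness), parse_arrow(r.density), parse_arrow(r.area))
        for r in table.itertuples()
    ]
    out["relation"] = [c.relation for c in cls]
    out["area_label"] = [c.area_label for c in cls]
    return out


def tabulate(classified: pd.DataFrame) -> dict:
    """Summary counts per (service, relation, area_label).

    Also reports, per service, the number of divergent cases (the
    denominator of the headline neutralization/dominance ratios) and the
    breakdown of their area labels.
    """
    summary: dict = {"n_rows": int(len(classified)), "services": {}}
    for service, grp in classified.groupby("service", sort=True):
        rel_counts = grp["relation"].value_counts().to_dict()
        div = grp[grp["relation"] == "divergent"]
        summary["services"][service] = {
            "relations": {k: int(v) for k, v in sorted(rel_counts.items())},
            "n_divergent": int(len(div)),
            "divergent_labels": {
                k: int(v) for k, v in sorted(div["area_label"].value_counts().items())
            },
        }
    if not summary["services"]:
        summary["services"] = {}
    return summary


def load_reference_matrix() -> pd.DataFrame:
    """Published arrow/letter response matrix for Brazil nut concessions
    in Madre de Dios, Peru (transcribed; 28 environmental variables x
    {seed, agb} services, with the published area-label letters where the
    study printed one)."""
    with resources.files("habqual.data").joinpath("response_matrix.csv").open(
        encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh, dtype=str).fillna("")
    return df
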