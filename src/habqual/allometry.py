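"""Allometric aboveground-biomass (AGB) models for individual trees.

The default model is the pantropical moist-forest DBH-only form

    AGB = rho * exp(-1.499 + 2.148 ln D + 0.207 (ln D)^2 - 0.0281 (ln D)^3)

with AGB in kg, D the diameter at breast height in cm and rho the wood
density in g/cm^3 (0.59 for Brazil nut). A DBH+height variant
AGB = 0.0509 * rho * D^2 * H is registered as ``"dbh_height"`` for
inventories with measured heights. Models are kept in a registry so a
different published equation can be pinned via configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "AllometricModel",
    "get_model",
    "agb_from_dbh",
    "agb_batch",
    "kg_to_t",
    "t_to_kg",
    "DEFAULT_WOOD_DENSITY",
]

#: Brazil nut wood density, g/cm^3
DEFAULT_WOOD_DENSITY = 0.59


@dataclass(frozen=True)
class AllometricModel:
    """Named closed-form AGB model; output scales linearly with wood density."""

    name: str
    wood_density: float = DEFAULT_WOOD_DENSITY
    coefficients: tuple = ()
    needs_height: bool = False

    def __post_init__(self):
        if self.wood_density < 0:
            raise ValueError("wood_density must be non-negative")

    def evaluate(self, dbh, height=None):
        d = np.asarray(dbh, dtype=float)
        if self.name == "moist_dbh":
            a0, a1, a2, a3 = self.coefficients
            ln = np.log(d)
            agb = self.wood_density * np.exp(a0 + a1 * ln + a2 * ln**2 + a3 * ln**3)
        elif self.name == "dbh_height":
            (k,) = self.coefficients
            h = np.asarray(height, dtype=float)
            agb = k * self.wood_density * d**2 * h
        else:  # pragma: no cover - registry guards this
            raise ValueError(f"unknown model {self.name}")
        return agb


_REGISTRY = {
    "moist_dbh": AllometricModel(
        "moist_dbh", coefficients=(-1.499, 2.148, 0.207, -0.0281)
    ),
    "dbh_height": AllometricModel(
        "dbh_height", coefficients=(0.0509,), needs_height=True
    ),
}

DEFAULT_MODEL = "moist_dbh"


def get_model(name: str = DEFAULT_MODEL, wood_density: float = DEFAULT_WOOD_DENSITY) -> AllometricModel:
    """Fetch a registered model, overriding wood density if requested."""
    try:
        model = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"no allometric model named {name!r}; "
                       f"known: {sorted(_REGISTRY)}") from None
    return replace(model, wood_density=wood_density)


def agb_from_dbh(dbh, model: AllometricModel | None = None, height=None):
    """Per-tree AGB in kg from DBH in cm (and height in m for models that
    use it). Raises on non-positive DBH."""
    model = model or get_model()
    arr = np.asarray(dbh, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("dbh must be positive")
    if model.needs_height:
        if height is None:
            raise ValueError(f"model {model.name!r} requires height")
        out = model.evaluate(arr, height)
    else:
        out = model.evaluate(arr)
    return float(out) if arr.ndim == 0 else out


def agb_batch(df: pd.DataFrame, model: AllometricModel | None = None) -> pd.DataFrame:
    """Append an ``agb_kg`` column to an inventory frame.

    Trees without DBH (or without height, under a height-requiring model)
    get an absent (NaN) AGB, never zero.
    """
    model = model or get_model()
    out = df.copy()
    ok = df["dbh"].notna() & (df["dbh"] > 0)
    if model.needs_height:
        ok &= df["height"].notna() & (df["height"] > 0)
    agb = np.full(len(df), np.nan)
    if ok.any():
        agb[ok.to_numpy()] = agb_from_dbh(
            df.loc[ok, "dbh"].to_numpy(),
            model,
            df.loc[ok, "height"].to_numpy() if model.needs_height else None,
        )
    out["agb_kg"] = agb
    return out


def kg_to_t(kg):
    """Kilograms to metric tons."""
    return np.asarray(kg, dtype=float) / 1000.0 if np.ndim(kg) else float(kg) / 1000.0


def t_to_kg(t):
    """Metric tons to kilograms."""
    return np.asarray(t, dtype=float) * 1000.0 if np.ndim(t) else float(t) * 1000.0
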