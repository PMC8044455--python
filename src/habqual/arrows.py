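"""Discretized effect codes ("arrows") for environmental response tables.

A fitted slope is summarised by its direction and a significance band:

====== ======= ========== ==========================
symbol sign    strength   meaning
====== ======= ========== ==========================
↑↑↑    +1      3          p < 0.001, positive
↑↑     +1      2          p < 0.01
↑      +1      1          p < 0.05
–↑     +1      0.5        p < 0.10 (marginal)
–       0      0          not significant
–↓     −1      0.5        p < 0.10 (marginal)
↓      −1      1          p < 0.05
↓↓     −1      2          p < 0.01
↓↓↓    −1      3          p < 0.001, negative
====== ======= ========== ==========================

The marginal band (strength 0.5) is treated as signal-bearing by the
trade-off classifier; strength beyond that only records evidence, the
classification logic uses sign alone.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ArrowCode", "arrow_from_pvalue", "parse_arrow", "ARROW_TABLE"]

#: canonical symbol -> (sign, strength)
ARROW_TABLE: dict[str, tuple[int, float]] = {
    "↑↑↑": (+1, 3),
    "↑↑": (+1, 2),
    "↑": (+1, 1),
    "–↑": (+1, 0.5),
    "–": (0, 0),
    "–↓": (-1, 0.5),
    "↓": (-1, 1),
    "↓↓": (-1, 2),
    "↓↓↓": (-1, 3),
}

_BY_CODE = {v: k for k, v in ARROW_TABLE.items()}


@dataclass(frozen=True)
class ArrowCode:
    """Direction + significance band of one covariate's fitted response."""

    symbol: str
    sign: int
    strength: float

    @property
    def signal_bearing(self) -> bool:
        """True when the code carries any directional signal (incl. marginal)."""
        return self.strength > 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.symbol


def _make(sign: int, strength: float) -> ArrowCode:
    return ArrowCode(_BY_CODE[(sign, strength)], sign, strength)


#: default p-value band edges: (3 arrows, 2 arrows, 1 arrow, marginal)
DEFAULT_THRESHOLDS = (0.001, 0.01, 0.05, 0.10)


def arrow_from_pvalue(
    sign: float,
    p_value: float,
    thresholds: tuple[float, float, float, float] = DEFAULT_THRESHOLDS,
) -> ArrowCode:
    """Discretize a (sign, p-value) pair into an :class:`ArrowCode`.

    ``sign`` is the sign of the fitted coefficient; ``p_value`` its
    two-sided p-value. Bands are half-open: p < t3 -> 3 arrows,
    t3 <= p < t2 -> 2, ..., p >= t_marginal -> flat.
    """
    if not 0 <= p_value <= 1:
        raise ValueError(f"p-value outside [0, 1]: {p_value}")
    t3, t2, t1, tm = thresholds
    if p_value >= tm or sign == 0:
        return _make(0, 0)
    s = 1 if sign > 0 else -1
    if p_value < t3:
        return _make(s, 3)
    if p_value < t2:
        return _make(s, 2)
    if p_value < t1:
        return _make(s, 1)
    return _make(s, 0.5)


def parse_arrow(symbol: str) -> ArrowCode:
    """Parse an arrow string (unicode as printed, hyphen accepted for the dash)."""
    s = symbol.strip().replace("-", "–")
    if s in ARROW_TABLE:
        sign, strength = ARROW_TABLE[s]
        return ArrowCode(s, sign, strength)
    raise ValueError(f"unrecognised arrow code: {symbol!r}")
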