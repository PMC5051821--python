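"""Family species richness from taxonomic evaluation counts.

Checklist projects report, per family, how many proposed species names have
been accepted (S_A), rejected as synonyms (S_R), or not yet evaluated (S_U).
Assuming unevaluated names will be accepted at the same rate as evaluated
ones, richness is estimated by extrapolating the acceptance fraction
S_A/(S_A+S_R) to the unevaluated pool:

    S = S_A + S_A * S_U / (S_A + S_R)

S is kept real-valued; integer rounding happens only where a birth-death
likelihood needs an integer count (see :mod:`cladediv.shifts`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "FamilyCounts",
    "UndefinedAcceptanceRateError",
    "corrected_richness",
    "read_counts_csv",
    "read_richness_csv",
    "richness_series",
    "total_richness",
    "write_richness_csv",
]


class UndefinedAcceptanceRateError(ValueError):
    """No evaluated names, so the acceptance fraction cannot be estimated."""


@dataclass(frozen=True)
class FamilyCounts:
    """Per-family taxonomic evaluation counts (all non-negative integers)."""

    family: str
    S_A: int
    S_R: int
    S_U: int

    def __post_init__(self):
        for name in ("S_A", "S_R", "S_U"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(
                    f"{self.family}: {name} must be a non-negative integer, got {v!r}"
                )


def corrected_richness(counts: FamilyCounts) -> float:
    """Estimated richness S = S_A + S_A·S_U/(S_A+S_R), real-valued.

    Bounds: S_A ≤ S ≤ S_A + S_U.  Raises
    :class:`UndefinedAcceptanceRateError` when there are unevaluated names
    but no evaluated ones (acceptance fraction unestimable).
    """
    a, r, u = counts.S_A, counts.S_R, counts.S_U
    if a + r == 0:
        if u > 0:
            raise UndefinedAcceptanceRateError(
                f"{counts.family}: S_U={u} unevaluated names but no evaluated "
                "names to estimate an acceptance rate from"
            )
        return 0.0
    return a + a * u / (a + r)


def richness_series(
    table: Iterable[FamilyCounts],
    overrides: Optional[Mapping[str, float]] = None,
) -> pd.Series:
    """Per-family richness; direct published estimates override counts."""
    overrides = dict(overrides or {})
    values: dict = {}
    for counts in table:
        if counts.family in values:
            raise ValueError(f"family {counts.family} appears twice in the counts table")
        if counts.family in overrides:
            warnings.warn(
                f"family {counts.family} has both evaluation counts and a direct "
                "richness estimate; using the direct estimate",
                stacklevel=2,
            )
            values[counts.family] = float(overrides.pop(counts.family))
        else:
            s = corrected_richness(counts)
            if s == 0.0:
                warnings.warn(
                    f"family {counts.family} has S_A=0 and S_U=0 (richness 0); "
                    "supply a direct richness override for clade analyses",
                    stacklevel=2,
                )
            values[counts.family] = s
    for fam, s in overrides.items():
        values[fam] = float(s)
    return pd.Series(values, name="richness").sort_index()


def total_richness(
    table: Iterable[FamilyCounts],
    overrides: Optional[Mapping[str, float]] = None,
) -> float:
    """Total richness S_T: sum of per-family (unrounded) estimates."""
    series = richness_series(table, overrides)
    if series.empty:
        warnings.warn("empty richness table; total is 0", stacklevel=2)
        return 0.0
    return float(series.sum())


# -- CSV plumbing -------------------------------------------------------


def read_counts_csv(path) -> list:
    """Read a ``family,S_A,S_R,S_U`` CSV into :class:`FamilyCounts` rows."""
    df = pd.read_csv(path)
    required = {"family", "S_A", "S_R", "S_U"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts CSV needs columns {sorted(required)}, got {list(df.columns)}")
    return [
        FamilyCounts(str(row.family), int(row.S_A), int(row.S_R), int(row.S_U))
        for row in df.itertuples()
    ]


def read_richness_csv(path) -> pd.Series:
    """Read a direct ``family,richness`` (or ``family,S``/``S_direct``) CSV."""
    df = pd.read_csv(path)
    col = next((c for c in ("richness", "S", "S_direct") if c in df.columns), None)
    if col is None or "family" not in df.columns:
        raise ValueError(
            "richness CSV needs a 'family' column and one of 'richness'/'S'/'S_direct'"
        )
    return pd.Series(df[col].astype(float).values, index=df["family"].astype(str), name="richness")


def write_richness_csv(series: pd.Series, path) -> None:
    series.rename_axis("family").to_frame().to_csv(path)
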