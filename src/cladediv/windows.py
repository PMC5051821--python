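"""Age-window regressions of log richness on clade stem age.

The time-for-speciation hypothesis predicts a positive ln(S) ~ age slope
among contemporaneous clades.  Because clades on a tree are nested (and a
nested clade is by definition poorer than the clade containing it), each
10-My stem-age window is first pruned so that no two retained clades share
taxa; the pruning is run twice, once keeping the older member of every
nested pair and once keeping the younger.  Slope p-values from all
window × variant fits are adjusted jointly with the Benjamini-Hochberg
step-up procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .tree_model import CladeRecord

__all__ = [
    "WindowFit",
    "assign_windows",
    "bh_adjust",
    "fit_window",
    "prune_nested",
    "window_analysis",
    "window_table",
]

DEFAULT_WIDTH = 10.0
DEFAULT_MIN_AGE = 20.0
DEFAULT_MAX_AGE = 100.0


@dataclass(frozen=True)
class WindowFit:
    """OLS fit of ln(S) on stem age within one window and pruning variant."""

    window: Tuple[float, float]   # [lo, hi) in My
    variant: str                  # "younger-removed" | "older-removed"
    mean_clade_age: float
    slope: float
    p: float
    r_squared: float
    n: int
    fit_ok: bool
    p_adj: float = float("nan")


def assign_windows(
    clades: Iterable[CladeRecord],
    width: float = DEFAULT_WIDTH,
    min_age: float = DEFAULT_MIN_AGE,
    max_age: float = DEFAULT_MAX_AGE,
) -> Dict[Tuple[float, float], List[CladeRecord]]:
    """Partition clades into adjacent half-open stem-age windows.

    A clade with stem age a falls in [lo, lo+width) with lo = width·⌊a/width⌋;
    ages below ``min_age`` or at/above ``max_age`` are excluded (the deep part
    of a family tree is node-poor and highly nested).  Empty windows are
    present in the result.
    """
    if width <= 0 or min_age >= max_age:
        raise ValueError("need width > 0 and min_age < max_age")
    n_win = int(round((max_age - min_age) / width))
    windows = {
        (min_age + i * width, min_age + (i + 1) * width): [] for i in range(n_win)
    }
    for rec in clades:
        a = rec.stem_age
        if a < min_age or a >= max_age:
            continue
        lo = width * math.floor(a / width)
        windows[(lo, lo + width)].append(rec)
    return windows


def prune_nested(clades: Iterable[CladeRecord], keep: str = "older") -> List[CladeRecord]:
    """Drop members of nested (taxon-overlapping) pairs until none remain.

    On a tree, overlapping taxon sets imply ancestor–descendant containment,
    so the overlap test is set intersection.  Processing is deterministic:
    candidates are visited from the oldest stem age down (``keep="older"``) or
    the youngest up (``keep="younger"``), ties broken by clade_id, and a clade
    is retained iff it shares no taxa with any clade already retained.
    """
    if keep not in ("older", "younger"):
        raise ValueError("keep must be 'older' or 'younger'")
    ordered = sorted(
        clades,
        key=lambda r: (-r.stem_age, r.clade_id) if keep == "older" else (r.stem_age, r.clade_id),
    )
    kept: List[CladeRecord] = []
    taken: set = set()
    for rec in ordered:
        if taken.isdisjoint(rec.tip_families):
            kept.append(rec)
            taken.update(rec.tip_families)
    return kept


def fit_window(clades: Iterable[CladeRecord]) -> WindowFit:
    """OLS of ln(S) on stem age; unfit when n < 3 or ages are constant.

    Returns a :class:`WindowFit` without the (jointly computed) adjusted p.
    """
    recs = list(clades)
    n = len(recs)
    ages = np.array([r.stem_age for r in recs], dtype=float)
    lns = np.array([r.ln_richness for r in recs], dtype=float)
    mean_age = float(ages.mean()) if n else float("nan")
    if n < 3 or np.ptp(ages) == 0:
        return WindowFit((math.nan, math.nan), "", mean_age, math.nan, math.nan,
                         math.nan, n, fit_ok=False)
    if np.ptp(lns) == 0:
        # constant response: slope 0 explains nothing, nothing to test
        return WindowFit((math.nan, math.nan), "", mean_age, 0.0, 1.0, 0.0, n, fit_ok=True)
    model = sm.OLS(lns, sm.add_constant(ages)).fit()
    return WindowFit(
        window=(math.nan, math.nan),
        variant="",
        mean_clade_age=mean_age,
        slope=float(model.params[1]),
        p=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
        n=n,
        fit_ok=True,
    )


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def window_analysis(
    clades: Iterable[CladeRecord],
    width: float = DEFAULT_WIDTH,
    min_age: float = DEFAULT_MIN_AGE,
    max_age: float = DEFAULT_MAX_AGE,
) -> List[WindowFit]:
    """The full windowed analysis: both pruning variants, joint BH family.

    Adjusted p-values recurring across the two variant subtables come from a
    single BH family over all fit-worthy window × variant tests.
    """
    clades = list(clades)
    windows = assign_windows(clades, width, min_age, max_age)
    fits: List[WindowFit] = []
    for variant, keep in (("younger-removed", "older"), ("older-removed", "younger")):
        for win in sorted(windows):
            pruned = prune_nested(windows[win], keep=keep)
            fit = replace(fit_window(pruned), window=win, variant=variant)
            fits.append(fit)
    testable = [i for i, f in enumerate(fits) if f.fit_ok and not math.isnan(f.p)]
    if testable:
        adj = bh_adjust([fits[i].p for i in testable])
        for i, a in zip(testable, adj):
            fits[i] = replace(fits[i], p_adj=float(a))
    return fits


def window_table(fits: Iterable[WindowFit]) -> pd.DataFrame:
    """Tabular (CSV-ready) form of :func:`window_analysis` output."""
    return pd.DataFrame(
        {
            "variant": [f.variant for f in fits],
            "window_lo": [f.window[0] for f in fits],
            "window_hi": [f.window[1] for f in fits],
            "mean_clade_age": [f.mean_clade_age for f in fits],
            "slope": [f.slope for f in fits],
            "p": [f.p for f in fits],
            "p_adj": [f.p_adj for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "n": [f.n for f in fits],
            "fit_ok": [f.fit_ok for f in fits],
        }
    )
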