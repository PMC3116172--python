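"""Results grid assembly, sigma-difference columns and scheme comparison.

A :class:`ResultsGrid` holds one metric value per (model, metric,
cell line, descriptor set) for one division scheme.  The sigma column for
a cell is the drug-like-index value minus the general-descriptor value;
displayed values are rounded to three decimals, internal values keep full
precision.  Two grids (one per division scheme) are compared with a
two-sided paired t-test over all corresponding non-sigma cells.
"""

from __future__ import annotations

import importlib.resources as _resources
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

MODELS = ("PLS", "SVR", "Bayes", "SVM")
REGRESSION_METRICS = ("R2", "Q2", "r2")
CLASSIFICATION_METRICS = ("At", "Av", "Ap")
DESCRIPTOR_SETS = ("general", "drug_like")

_CELLS = ["model", "metric", "cell_line"]


@dataclass
class ResultsGrid:
    """Tidy grid: columns model, metric, cell_line, general, drug_like."""

    table: pd.DataFrame
    division: str = "diverse"

    def __post_init__(self) -> None:
        missing = [c for c in _CELLS if c not in self.table.columns]
        if missing:
            raise ValueError(f"grid missing columns {missing}")
        if self.table.duplicated(_CELLS).any():
            raise ValueError("duplicate grid cells")

    @classmethod
    def from_records(
        cls, records: list[dict], division: str = "diverse"
    ) -> "ResultsGrid":
        """Build from tidy records with a ``descriptor_set`` column."""
        df = pd.DataFrame(records)
        wide = df.pivot_table(
            index=_CELLS, columns="descriptor_set", values="value", aggfunc="first"
        ).reset_index()
        wide.columns.name = None
        return cls(wide, division)

    def values_long(self) -> pd.DataFrame:
        """All non-sigma cells in long form (one row per descriptor set)."""
        cols = [c for c in DESCRIPTOR_SETS if c in self.table.columns]
        long = self.table.melt(
            id_vars=_CELLS, value_vars=cols, var_name="descriptor_set", value_name="value"
        )
        return long.dropna(subset=["value"]).reset_index(drop=True)


@dataclass
class SigmaTable:
    table: pd.DataFrame  # model, metric, cell_line, sigma (NaN = missing)
    division: str


def sigma_columns(grid: ResultsGrid) -> SigmaTable:
    """sigma = drug_like - general for every (model, metric, cell line).

    Cells lacking either descriptor-set entry yield NaN (flagged missing).
    """
    t = grid.table.copy()
    for c in DESCRIPTOR_SETS:
        if c not in t.columns:
            t[c] = np.nan
    t["sigma"] = t["drug_like"] - t["general"]
    return SigmaTable(t[_CELLS + ["sigma"]].copy(), grid.division)


@dataclass
class PairedTTestResult:
    t: Optional[float]
    p: Optional[float]
    n: int
    degenerate: bool = False
    note: str = ""


def paired_ttest(grid_a: ResultsGrid, grid_b: ResultsGrid) -> PairedTTestResult:
    """Two-sided paired t-test over all matching non-sigma cells.

    The pairing universe is every (model, metric, cell line, descriptor
    set) cell present in both grids.  A zero-variance difference vector is
    degenerate: no numeric p is reported.
    """
    keys = _CELLS + ["descriptor_set"]
    a = grid_a.values_long().set_index(keys)["value"]
    b = grid_b.values_long().set_index(keys)["value"]
    common = a.index.intersection(b.index)
    n = len(common)
    if n < 3:
        raise ValueError("need at least 3 paired cells")
    diff = (a.loc[common] - b.loc[common]).to_numpy(float)
    if np.allclose(diff.std(ddof=1), 0.0):
        return PairedTTestResult(None, None, n, degenerate=True,
                                 note="zero variance of paired differences")
    res = stats.ttest_rel(a.loc[common].to_numpy(float), b.loc[common].to_numpy(float))
    return PairedTTestResult(float(res.statistic), float(res.pvalue), n)


def render_grid(grid: ResultsGrid, sigma: Optional[SigmaTable] = None) -> pd.DataFrame:
    """Display table: 3-decimal values, sigma column, and the per-cell-line
    maximum Ap marked with an asterisk (mirroring the published layout)."""
    if sigma is None:
        sigma = sigma_columns(grid)
    t = grid.table.merge(sigma.table, on=_CELLS, how="left")
    out = t.copy()
    for c in list(DESCRIPTOR_SETS) + ["sigma"]:
        if c in out.columns:
            out[c] = out[c].map(lambda v: "NA" if pd.isna(v) else f"{v:.3f}")
    ap = t[t["metric"] == "Ap"]
    marks = set()
    for cl, sub in ap.groupby("cell_line"):
        best = -np.inf
        for _, row in sub.iterrows():
            for ds in DESCRIPTOR_SETS:
                v = row.get(ds)
                if pd.notna(v):
                    best = max(best, v)
        for _, row in sub.iterrows():
            for ds in DESCRIPTOR_SETS:
                v = row.get(ds)
                if pd.notna(v) and v == best:
                    marks.add((row["model"], row["metric"], cl, ds))
    for (model, metric, cl, ds) in marks:
        sel = (
            (out["model"] == model) & (out["metric"] == metric) & (out["cell_line"] == cl)
        )
        out.loc[sel, ds] = out.loc[sel, ds] + "*"
    order = pd.CategoricalDtype(MODELS, ordered=True)
    out["model"] = out["model"].astype(order)
    out = out.sort_values(["model", "metric", "cell_line"]).reset_index(drop=True)
    out["model"] = out["model"].astype(str)
    return out


def parse_rendered(df: pd.DataFrame) -> ResultsGrid:
    """Re-parse a rendered table back to a numeric grid (display precision)."""
    t = df.copy()
    for c in DESCRIPTOR_SETS:
        t[c] = (
            t[c].astype(str).str.rstrip("*").replace("NA", np.nan).astype(float)
        )
    return ResultsGrid(t[_CELLS + list(DESCRIPTOR_SETS)].copy())


def load_reference_grids() -> pd.DataFrame:
    """Published results grid of the original 93-compound cyclopamine
    study: general/drug-like values and printed sigma per division scheme.

    One printed sigma entry (diverse / SVR / R2 / BxPC-3) disagrees in
    sign with the difference of its own operands; the operand values are
    authoritative for recomputation.
    """
    ref = _resources.files("cycloqsar").joinpath("data/reference_grids.csv")
    with _resources.as_file(ref) as path:
        return pd.read_csv(path)


def reference_grid(division: str) -> ResultsGrid:
    df = load_reference_grids()
    sub = df[df["division"] == division]
    if sub.empty:
        raise ValueError(f"unknown division {division!r}")
    return ResultsGrid(
        sub[_CELLS + ["general", "drug_like"]].reset_index(drop=True), division
    )
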