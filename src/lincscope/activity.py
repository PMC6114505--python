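"""Change fractions of transcriptional activity across condition pairs.

For each cell line and a two-level contrast — low vs high dose, or 6 h vs
24 h — the fraction of active profiles (those with at least one DEG) that
reach the ">=50 DEGs" and ">=100 DEGs" categories is computed at both
levels:

    f_A50  = #profiles(>=50 DEGs | A) / #profiles(>=1 DEG | A)
    f_A100 = #profiles(>=100 DEGs | A) / #profiles(>=1 DEG | A)

and likewise f_B50, f_B100 for the second level B.  Two denominator
conventions are supported: under ``"stratum"`` (default) each level is
normalized by its own >=1 count, so all fractions live in [0, 1]; under
``"as_printed"`` the B-level numerators are also divided by the A-level
>=1 count, so f_B can exceed 1.

Plotting (f_A, f_B) against the coded abscissa A=0, B=1 gives one line
segment per category level; the dose-contrast and time-contrast segments
of a cell line are classified as parallel (similar slopes, no crossing),
intersecting (endpoint differences change sign), or neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CONVENTIONS = ("stratum", "as_printed")
DEFAULT_SLOPE_TOL = 0.02

#: Contrast name -> (stratifier level column, (A level, B level)).
CONTRASTS = {
    "dose": ("dose_group", ("low", "high")),
    "time": ("time_h", (6.0, 24.0)),
}

Segment = tuple[float, float]


@dataclass
class FractionSet:
    """The four change fractions for one cell line and one contrast."""

    cell_id: str
    contrast: str  # "dose" (A=low, B=high) or "time" (A=6 h, B=24 h)
    f_a50: float
    f_a100: float
    f_b50: float
    f_b100: float
    convention: str = "stratum"

    @property
    def seg50(self) -> Segment:
        return (self.f_a50, self.f_b50)

    @property
    def seg100(self) -> Segment:
        return (self.f_a100, self.f_b100)


def slope(seg: Segment) -> float:
    """Slope of a segment over the coded abscissa A=0 -> B=1."""
    return seg[1] - seg[0]


def compute_change_fractions(
    stratified: pd.DataFrame,
    cell: str,
    contrast: str,
    convention: str = "stratum",
    levels: tuple | None = None,
) -> FractionSet:
    """Compute the four change fractions for one cell line.

    ``stratified`` is the output of
    :func:`lincscope.deg.stratified_category_counts` with thresholds
    (1, 50, 100), stratified by ``cell_x_dose_group`` for the dose
    contrast or ``cell_x_time`` for the time contrast.  ``levels``
    overrides the default (A, B) pair (low/high, or 6/24 h).
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected {CONVENTIONS}")
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected {tuple(CONTRASTS)}")
    column, default_levels = CONTRASTS[contrast]
    a_level, b_level = levels if levels is not None else default_levels

    rows = stratified.loc[stratified["cell_id"] == cell]
    counts = {}
    for name, level in (("A", a_level), ("B", b_level)):
        row = rows.loc[rows[column] == level]
        if row.empty:
            raise ValueError(
                f"cell {cell!r}: no stratum {column}={level!r} in counts table"
            )
        counts[name] = row.iloc[0]
    denom_a = int(counts["A"]["ge_1"])
    denom_b = int(counts["B"]["ge_1"])
    if denom_a == 0 or (convention == "stratum" and denom_b == 0):
        bad = f"{column}={a_level if denom_a == 0 else b_level}"
        raise ZeroDivisionError(
            f"cell {cell!r}, stratum {bad}: no profiles with >=1 DEG (zero denominator)"
        )
    denom_b_eff = denom_b if convention == "stratum" else denom_a
    return FractionSet(
        cell_id=cell,
        contrast=contrast,
        f_a50=int(counts["A"]["ge_50"]) / denom_a,
        f_a100=int(counts["A"]["ge_100"]) / denom_a,
        f_b50=int(counts["B"]["ge_50"]) / denom_b_eff,
        f_b100=int(counts["B"]["ge_100"]) / denom_b_eff,
        convention=convention,
    )


def classify_segment_pair(
    p: Segment, q: Segment, slope_tol: float = DEFAULT_SLOPE_TOL
) -> str:
    """Classify two A->B segments as parallel, intersecting, or neither.

    Intersecting when the endpoint differences change sign, i.e.
    ``(p_A - q_A) * (p_B - q_B) < 0``; otherwise parallel when the slopes
    agree within ``slope_tol`` (absolute); otherwise neither.  Symmetric
    in its arguments.
    """
    d_a = p[0] - q[0]
    d_b = p[1] - q[1]
    if d_a * d_b < 0:
        return "intersecting"
    if abs(slope(p) - slope(q)) <= slope_tol:
        return "parallel"
    return "neither"


def activity_change_report(
    fraction_sets: list[FractionSet], slope_tol: float = DEFAULT_SLOPE_TOL
) -> pd.DataFrame:
    """Per-cell-line summary of change fractions and segment geometry.

    Expects at most one dose-contrast and one time-contrast FractionSet
    per cell line.  Returns one row per cell with the eight fractions as
    percentages, the four segment slopes, the dose-vs-time classification
    at each category level, and the maximum fraction (the top of the
    y-scale in a four-segment plot).  Cells missing a contrast get
    ``"not_evaluable"`` classifications and NaN for the absent fractions.
    """
    by_cell: dict[str, dict[str, FractionSet]] = {}
    for fs in fraction_sets:
        slot = by_cell.setdefault(fs.cell_id, {})
        if fs.contrast in slot:
            raise ValueError(f"duplicate {fs.contrast!r} contrast for cell {fs.cell_id!r}")
        slot[fs.contrast] = fs

    rows = []
    for cell in sorted(by_cell):
        dose = by_cell[cell].get("dose")
        time = by_cell[cell].get("time")
        row: dict[str, object] = {"cell_id": cell}
        for label, fs in (("dose", dose), ("time", time)):
            a, b = ("low", "high") if label == "dose" else ("6h", "24h")
            row[f"pct_{a}_50"] = 100 * fs.f_a50 if fs else float("nan")
            row[f"pct_{a}_100"] = 100 * fs.f_a100 if fs else float("nan")
            row[f"pct_{b}_50"] = 100 * fs.f_b50 if fs else float("nan")
            row[f"pct_{b}_100"] = 100 * fs.f_b100 if fs else float("nan")
            row[f"slope_{label}_50"] = slope(fs.seg50) if fs else float("nan")
            row[f"slope_{label}_100"] = slope(fs.seg100) if fs else float("nan")
        if dose and time:
            row["class_50"] = classify_segment_pair(dose.seg50, time.seg50, slope_tol)
            row["class_100"] = classify_segment_pair(dose.seg100, time.seg100, slope_tol)
            row["max_pct"] = max(
                v for k, v in row.items() if str(k).startswith("pct_")
            )
        else:
            row["class_50"] = "not_evaluable"
            row["class_100"] = "not_evaluable"
            row["max_pct"] = max(
                (v for k, v in row.items() if str(k).startswith("pct_") and v == v),
                default=float("nan"),
            )
        rows.append(row)
    return pd.DataFrame(rows)
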