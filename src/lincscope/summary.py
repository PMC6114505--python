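"""Compendium-level summaries of signature metadata.

These are the "first layer" descriptive statistics of a perturbational
signature collection: how many signature profiles each cell line carries,
which cell lines are deeply profiled, how the six perturbation categories
are distributed, and how many replicates, distinct doses and distinct
time points back each condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import CATEGORIES

DEFAULT_MIN_PROFILES = 20_000
DEFAULT_CAP = 9


@dataclass
class CappedHistogram:
    """Histogram over positive integers with an overflow bucket.

    Values ``1 .. cap-1`` get their own bins; values ``>= cap`` pool into
    the ``"<cap>+"`` overflow bucket (with the default cap of 9 this is
    the "9 or more" bucket).
    """

    cap: int = DEFAULT_CAP
    bin_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.bin_counts.values())

    @property
    def overflow_label(self) -> str:
        return f"{self.cap}+"

    @classmethod
    def from_values(cls, values, cap: int = DEFAULT_CAP) -> "CappedHistogram":
        if cap < 2:
            raise ValueError("cap must be at least 2")
        counts: dict[str, int] = {}
        overflow = f"{cap}+"
        for v in values:
            v = int(v)
            if v < 1:
                raise ValueError(f"histogram values must be >= 1, got {v}")
            key = overflow if v >= cap else str(v)
            counts[key] = counts.get(key, 0) + 1
        return cls(cap=cap, bin_counts=counts)

    def fraction_below_cap(self) -> float:
        """Fraction of values in the 1..cap-1 range (NaN if empty)."""
        total = self.total
        if total == 0:
            return float("nan")
        return (total - self.bin_counts.get(self.overflow_label, 0)) / total

    def as_series(self) -> pd.Series:
        labels = [str(i) for i in range(1, self.cap)] + [self.overflow_label]
        return pd.Series(
            [self.bin_counts.get(label, 0) for label in labels], index=labels, dtype=int
        )


def profile_counts_by_cell(meta: pd.DataFrame) -> pd.DataFrame:
    """Count signature profiles per cell line.

    Returns a ``(cell_id, count)`` table sorted by descending count, ties
    broken by cell_id, so the result is invariant to input row order.
    """
    counts = (
        meta.groupby("cell_id", sort=False)
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["count", "cell_id"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return counts


def total_profiles(meta: pd.DataFrame, excluded_categories=frozenset()) -> int:
    """Number of signature profiles outside the excluded categories.

    The compendium-wide headline count excludes the genetic perturbations,
    i.e. ``excluded_categories={"shRNA", "overexpression"}``.
    """
    excluded = set(excluded_categories)
    if not excluded:
        return len(meta)
    return int((~meta["pert_category"].isin(excluded)).sum())


def select_highly_profiled(
    counts: pd.DataFrame, min_profiles: int = DEFAULT_MIN_PROFILES
) -> list[str]:
    """Cell lines with strictly more than ``min_profiles`` profiles.

    Takes the output of :func:`profile_counts_by_cell`; returns cell ids
    in descending count order (ties by cell id).  The inequality is
    strict: a cell line with exactly ``min_profiles`` is not selected.
    """
    selected = counts.loc[counts["count"] > min_profiles]
    selected = selected.sort_values(
        ["count", "cell_id"], ascending=[False, True], kind="mergesort"
    )
    return list(selected["cell_id"])


def category_distribution(meta: pd.DataFrame, cells) -> pd.DataFrame:
    """Per-cell-line counts over the six perturbation categories.

    Returns a DataFrame indexed by cell_id (one row per requested cell,
    all-zero for cells absent from the metadata) with one column per
    category; row sums equal the per-cell profile counts.
    """
    cells = list(cells)
    subset = meta.loc[meta["cell_id"].isin(cells)]
    table = (
        subset.groupby(["cell_id", "pert_category"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=cells, columns=list(CATEGORIES), fill_value=0)
        .astype(int)
    )
    table.index.name = "cell_id"
    table.columns.name = None
    return table


def replicate_histogram(
    meta: pd.DataFrame, cells, cap: int = DEFAULT_CAP
) -> tuple[dict[str, CappedHistogram], float]:
    """Replicate-count histograms per cell line, plus a pooled fraction.

    Returns ``(per_cell, pooled_fraction)`` where ``pooled_fraction`` is
    the fraction of all profiles (across the requested cells) whose
    replicate count lies in 1..cap-1 — the complement of the "9 or more"
    bucket under the default cap.
    """
    cells = list(cells)
    subset = meta.loc[meta["cell_id"].isin(cells)]
    per_cell = {
        cell: CappedHistogram.from_values(
            subset.loc[subset["cell_id"] == cell, "n_replicates"], cap=cap
        )
        for cell in cells
    }
    pooled = CappedHistogram.from_values(subset["n_replicates"], cap=cap)
    return per_cell, pooled.fraction_below_cap()


def dose_multiplicity_histogram(
    meta: pd.DataFrame, cells, cap: int = DEFAULT_CAP
) -> dict[str, CappedHistogram]:
    """Histogram of distinct-dose counts per (cell, perturbagen) pair.

    Only compound records with a known dose contribute.  Distinctness is
    on the canonical micromolar value, so 500 nM and 0.5 uM are one dose.
    """
    cells = list(cells)
    subset = meta.loc[
        meta["cell_id"].isin(cells)
        & (meta["pert_category"] == "compound")
        & meta["dose_um"].notna()
    ]
    multiplicity = subset.groupby(["cell_id", "pert_id"])["dose_um"].nunique()
    return {
        cell: CappedHistogram.from_values(
            multiplicity.loc[cell] if cell in multiplicity.index.get_level_values(0) else [],
            cap=cap,
        )
        for cell in cells
    }


def time_multiplicity_histogram(meta: pd.DataFrame, cap: int = DEFAULT_CAP) -> CappedHistogram:
    """Histogram of distinct time-point counts per perturbagen."""
    subset = meta.loc[meta["time_h"].notna()]
    multiplicity = subset.groupby("pert_id")["time_h"].nunique()
    return CappedHistogram.from_values(multiplicity, cap=cap)
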