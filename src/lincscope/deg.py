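"""Differential-expression activity analysis of z-score signatures.

The "second layer" of the compendium characterization: per-signature
counts of differentially expressed genes (DEGs) under a z-score
threshold, cumulative "at least k significant genes" categorization of
profiles and of distinct small molecules, and stratification of those
categories by cell line, dose group (low vs high at a 5 uM cutoff) and
treatment time.

A gene is called differentially expressed in a signature when its z-score
is strictly above ``z_hi`` (up-regulated) or strictly below ``z_lo``
(down-regulated); the conventional thresholds are +2.0 and -2.0, and a
value of exactly +/-2.0 is not significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SignatureMatrix

logger = logging.getLogger(__name__)

Z_HI_DEFAULT = 2.0
Z_LO_DEFAULT = -2.0
DOSE_CUTOFF_UM = 5.0
DEFAULT_THRESHOLDS = (1, 50, 100)
DEFAULT_TIMES_H = frozenset({6.0, 24.0, 48.0})

#: Valid stratifiers for :func:`stratified_category_counts`.
STRATIFIERS = ("cell", "cell_x_dose_group", "cell_x_time")


def count_deg(
    matrix: SignatureMatrix, z_hi: float = Z_HI_DEFAULT, z_lo: float = Z_LO_DEFAULT
) -> pd.DataFrame:
    """Count up-/down-regulated genes per signature.

    Returns a DataFrame with one row per signature column and columns
    ``sig_id, n_up, n_down, n_total``.  Thresholds are strict; NaN
    z-scores are excluded from both counts.
    """
    if not z_lo < z_hi:
        raise ValueError(f"need z_lo < z_hi, got z_lo={z_lo}, z_hi={z_hi}")
    z = matrix.z
    with np.errstate(invalid="ignore"):
        n_up = (z > z_hi).sum(axis=0)
        n_down = (z < z_lo).sum(axis=0)
    return pd.DataFrame(
        {
            "sig_id": matrix.sig_ids,
            "n_up": n_up.astype(int),
            "n_down": n_down.astype(int),
            "n_total": (n_up + n_down).astype(int),
        }
    )


def filter_analysis_set(
    meta: pd.DataFrame,
    cells,
    categories=frozenset({"compound"}),
    times=DEFAULT_TIMES_H,
) -> pd.DataFrame:
    """Restrict metadata to the analysis set.

    Keeps rows whose cell line is in ``cells``, perturbation category in
    ``categories`` and treatment time in ``times`` (hours).  The typical
    analysis set is compound signatures at 6, 24 and 48 h in the highly
    profiled cell lines.
    """
    cells = set(cells)
    categories = set(categories)
    times = {float(t) for t in times}
    keep = (
        meta["cell_id"].isin(cells)
        & meta["pert_category"].isin(categories)
        & meta["time_h"].isin(times)
    )
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_analysis_set: removed %d of %d rows", removed, len(meta))
    subset = meta.loc[keep].reset_index(drop=True)
    if subset.empty:
        logger.warning("filter_analysis_set: empty analysis set")
    return subset


@dataclass
class CategoryCounts:
    """Cumulative "at least k significant genes" tallies.

    ``profiles[k]`` counts signatures with at least ``k`` DEGs (so the
    tallies are nested, not disjoint); ``molecules[k]`` counts distinct
    small molecules with at least one signature reaching ``k`` DEGs.
    ``profiles_none``/``molecules_none`` count the complement of the
    smallest threshold, so ``profiles_none + profiles[thresholds[0]]``
    equals ``total_profiles``.
    """

    thresholds: tuple[int, ...]
    profiles: dict[int, int]
    molecules: dict[int, int]
    profiles_none: int
    molecules_none: int
    total_profiles: int
    total_molecules: int

    def as_frame(self) -> pd.DataFrame:
        rows = [("none", self.profiles_none, self.molecules_none)]
        rows += [
            (f">={k}", self.profiles[k], self.molecules[k]) for k in self.thresholds
        ]
        rows.append(("total", self.total_profiles, self.total_molecules))
        return pd.DataFrame(rows, columns=["category", "profiles", "molecules"])


def _join_deg_meta(deg: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    orphans = set(deg["sig_id"]) - set(meta["sig_id"])
    if orphans:
        shown = ", ".join(sorted(orphans)[:5])
        raise ValueError(
            f"{len(orphans)} DEG record(s) have no metadata row (e.g. {shown})"
        )
    return deg.merge(meta, on="sig_id", how="left", validate="one_to_one")


def categorize_counts(
    deg: pd.DataFrame,
    meta: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    molecule_rule: str = "any",
) -> CategoryCounts:
    """Cumulative categorization of profiles and distinct molecules.

    A profile is in category ``>=k`` when its DEG total reaches ``k``.  A
    distinct molecule (``pert_id``) is in category ``>=k`` when any of
    its signatures reaches ``k`` — equivalently, under
    ``molecule_rule="max"``, when the maximum DEG total over its
    signatures reaches ``k``; the two rules coincide and both are
    accepted.  "none" counts profiles with zero DEGs, and molecules all
    of whose signatures have zero DEGs.
    """
    if molecule_rule not in ("any", "max"):
        raise ValueError(f"unknown molecule_rule {molecule_rule!r}")
    thresholds = tuple(sorted(int(k) for k in thresholds))
    if not thresholds or thresholds[0] < 1:
        raise ValueError("thresholds must be positive integers")
    joined = _join_deg_meta(deg, meta)

    n = joined["n_total"].to_numpy()
    profiles = {k: int((n >= k).sum()) for k in thresholds}
    per_mol_max = joined.groupby("pert_id")["n_total"].max()
    molecules = {k: int((per_mol_max >= k).sum()) for k in thresholds}

    return CategoryCounts(
        thresholds=thresholds,
        profiles=profiles,
        molecules=molecules,
        profiles_none=int((n == 0).sum()),
        molecules_none=int((per_mol_max == 0).sum()),
        total_profiles=len(joined),
        total_molecules=int(joined["pert_id"].nunique()),
    )


def assign_dose_group(dose_um: float, cutoff_um: float = DOSE_CUTOFF_UM) -> str:
    """Two-way dose split: "low" for doses <= cutoff (5 uM), else "high".

    All nanomolar doses land in "low"; the boundary itself is low.
    Raises on missing dose — callers exclude dose-less records first.
    """
    if dose_um is None or np.isnan(dose_um):
        raise ValueError("dose is missing; exclude dose-less records upstream")
    return "low" if dose_um <= cutoff_um else "high"


def stratified_category_counts(
    deg: pd.DataFrame,
    meta: pd.DataFrame,
    by: str = "cell",
    thresholds=DEFAULT_THRESHOLDS,
    dose_cutoff_um: float = DOSE_CUTOFF_UM,
) -> pd.DataFrame:
    """Cumulative profile categories within strata.

    ``by`` is one of ``"cell"``, ``"cell_x_dose_group"`` or
    ``"cell_x_time"``.  Returns one row per non-empty stratum with
    columns ``cell_id`` (plus ``dose_group`` or ``time_h``),
    ``n_profiles``, ``n_none`` and ``ge_<k>`` per threshold.  Dose
    stratification drops records with missing dose and logs the count.
    """
    thresholds = tuple(sorted(int(k) for k in thresholds))
    joined = _join_deg_meta(deg, meta)

    if by == "cell":
        keys = ["cell_id"]
    elif by == "cell_x_dose_group":
        missing = int(joined["dose_um"].isna().sum())
        if missing:
            logger.info(
                "stratified_category_counts: excluding %d dose-less records", missing
            )
        joined = joined.loc[joined["dose_um"].notna()].copy()
        joined["dose_group"] = np.where(
            joined["dose_um"] <= dose_cutoff_um, "low", "high"
        )
        keys = ["cell_id", "dose_group"]
    elif by == "cell_x_time":
        joined = joined.loc[joined["time_h"].notna()]
        keys = ["cell_id", "time_h"]
    else:
        raise ValueError(f"unknown stratifier {by!r}; expected one of {STRATIFIERS}")

    def tally(group: pd.DataFrame) -> pd.Series:
        n = group["n_total"].to_numpy()
        out = {"n_profiles": len(n), "n_none": int((n == 0).sum())}
        for k in thresholds:
            out[f"ge_{k}"] = int((n >= k).sum())
        return pd.Series(out)

    table = (
        joined.groupby(keys, sort=True)
        .apply(tally, include_groups=False)
        .astype(int)
        .reset_index()
    )
    return table


def behavior_direction(
    stratified: pd.DataFrame,
    cell: str,
    levels: tuple,
    level_column: str,
    category: str = "ge_100",
    tol: int = 0,
) -> str:
    """Direction of the DEG-category count across two ordered levels.

    ``levels`` are the (A, B) values of ``level_column`` (e.g. dose
    groups ``("low", "high")`` or times ``(6.0, 24.0)``).  Returns
    "increasing" when count(B) > count(A) + tol, "decreasing" when
    count(B) < count(A) - tol, "unchanged" otherwise, and
    "not_evaluable" when either level is absent for the cell.
    """
    a_level, b_level = levels
    rows = stratified.loc[stratified["cell_id"] == cell]
    a = rows.loc[rows[level_column] == a_level, category]
    b = rows.loc[rows[level_column] == b_level, category]
    if a.empty or b.empty:
        return "not_evaluable"
    a_count, b_count = int(a.iloc[0]), int(b.iloc[0])
    if b_count > a_count + tol:
        return "increasing"
    if b_count < a_count - tol:
        return "decreasing"
    return "unchanged"
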