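"""Simulation experiments validating parameter recovery.

Each experiment plants a known structure with the synthetic generator,
runs the full analysis path (signature simulation -> DEG counting ->
stratified categorization -> direction / geometry calls), and reports how
often the planted truth is recovered over independent replicates.

Two experiments are provided:

* **Direction recovery** — a cell line is simulated with monotone
  increasing or decreasing dose and time responses; the recovered
  quantity is the direction of the ">=100 DEGs" count across dose groups
  and across 6 h vs 24 h.

* **Geometry recovery** — explicit per-condition effect sizes and joint
  condition weights plant either a *parallel* or an *intersecting*
  dose-vs-time segment pair in the change-fraction plane; the recovered
  quantity is the classification of the ">=50" segments.  Effect sizes
  are calibrated with the exact binomial-convolution oracle so the
  population fractions hit pre-chosen values, and the population
  geometry is itself verifiable via
  :func:`lincscope.simulate.expected_category_fractions`.

The geometry classifier's slope tolerance for these experiments
(:data:`GEOMETRY_SLOPE_TOL`) is wider than the reporting default because
a fitted slope from a finite replicate is noisy: with ~4,000 signatures
per replicate the slope difference of two planted-parallel segments has
a standard error near 0.03, so a tolerance of 0.1 (about three standard
errors) separates planted-parallel from planted-intersecting geometry
without misreading sampling noise as divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import activity, deg, simulate

#: Slope tolerance used when classifying geometry in finite-sample experiments.
GEOMETRY_SLOPE_TOL = 0.1

_DOSE_LEVELS = (1.0, 10.0)  # one low (<=5 uM), one high
_TIME_LEVELS = (6.0, 24.0)

# Planted ">=50 given active" population fractions for the parallel
# geometry, on the (dose, time) grid.  The additive offsets (dose +0.30,
# time +0.345) combined with the skewed joint weights below yield two
# same-slope, non-crossing segments separated by ~0.05.
_PARALLEL_TARGETS = {
    (1.0, 6.0): 0.250,
    (1.0, 24.0): 0.595,
    (10.0, 6.0): 0.550,
    (10.0, 24.0): 0.895,
}
_PARALLEL_WEIGHTS = {
    (1.0, 6.0): 0.01,
    (1.0, 24.0): 0.59,
    (10.0, 6.0): 0.20,
    (10.0, 24.0): 0.20,
}

# Intersecting geometry: a pure dose effect with uniform weights makes the
# time segment flat at the grand mean, which the dose segment crosses.
_INTERSECTING_TARGETS = {
    (1.0, 6.0): 0.25,
    (1.0, 24.0): 0.25,
    (10.0, 6.0): 0.75,
    (10.0, 24.0): 0.75,
}

_GEOMETRY_HITS = 150


def make_direction_config(
    seed: int,
    dose_response: str,
    time_response: str,
    n_per_stratum: int = 1000,
    base_effect: float = 3.0,
) -> simulate.SimConfig:
    """One compound-only cell line with monotone dose/time responses.

    ``n_per_stratum`` signatures per dose group (two groups, so twice
    that in total, each also split across the two time points).
    """
    spec = simulate.CellSpec(
        cell_id="SIM",
        n_signatures=2 * n_per_stratum,
        category_mix={"compound": 1.0},
        dose_levels=_DOSE_LEVELS,
        time_levels=_TIME_LEVELS,
        hit_count_distribution={150: 1.0},
        base_effect=base_effect,
        dose_response=dose_response,
        time_response=time_response,
    )
    return simulate.SimConfig(cell_specs=[spec], seed=seed)


def recover_directions(config: simulate.SimConfig) -> tuple[str, str]:
    """Run the analysis path and read off the dose and time directions."""
    meta = simulate.simulate_metadata(config)
    matrix, _ = simulate.simulate_signatures(config, meta)
    counts = deg.count_deg(matrix)
    cell = config.cell_specs[0].cell_id
    by_dose = deg.stratified_category_counts(counts, meta, by="cell_x_dose_group")
    by_time = deg.stratified_category_counts(counts, meta, by="cell_x_time")
    dose_dir = deg.behavior_direction(
        by_dose, cell, ("low", "high"), "dose_group", category="ge_100"
    )
    time_dir = deg.behavior_direction(
        by_time, cell, (6.0, 24.0), "time_h", category="ge_100"
    )
    return dose_dir, time_dir


def direction_recovery_rate(
    n_replicates: int = 100,
    base_seed: int = 0,
    dose_response: str = "increasing",
    time_response: str = "increasing",
    n_per_stratum: int = 1000,
    base_effect: float = 3.0,
) -> float:
    """Fraction of replicates recovering both planted directions."""
    hits = 0
    for r in range(n_replicates):
        config = make_direction_config(
            base_seed * n_replicates + r,
            dose_response,
            time_response,
            n_per_stratum=n_per_stratum,
            base_effect=base_effect,
        )
        if recover_directions(config) == (dose_response, time_response):
            hits += 1
    return hits / n_replicates


_effect_cache: dict[tuple, dict] = {}


def _geometry_config(
    seed: int, targets: dict, weights: dict | None, n_signatures: int
) -> simulate.SimConfig:
    key = tuple(sorted(targets.items()))
    if key not in _effect_cache:
        _effect_cache[key] = {
            pair: simulate.mu_for_tail_probability(
                p, simulate.N_LANDMARK_GENES, _GEOMETRY_HITS, 50
            )
            for pair, p in targets.items()
        }
    effects = dict(_effect_cache[key])
    spec = simulate.CellSpec(
        cell_id="SIM",
        n_signatures=n_signatures,
        category_mix={"compound": 1.0},
        dose_levels=_DOSE_LEVELS,
        time_levels=_TIME_LEVELS,
        hit_count_distribution={_GEOMETRY_HITS: 1.0},
        base_effect=1.0,
        condition_weights=weights,
        condition_effect=effects,
    )
    return simulate.SimConfig(cell_specs=[spec], seed=seed)


def make_parallel_config(seed: int, n_signatures: int = 4000) -> simulate.SimConfig:
    """Plant two same-slope, non-crossing dose/time segments."""
    return _geometry_config(seed, _PARALLEL_TARGETS, _PARALLEL_WEIGHTS, n_signatures)


def make_intersecting_config(seed: int, n_signatures: int = 2000) -> simulate.SimConfig:
    """Plant a dose segment crossing a flat time segment."""
    return _geometry_config(seed, _INTERSECTING_TARGETS, None, n_signatures)


def _classify(fractions_dose, fractions_time, slope_tol: float) -> str:
    return activity.classify_segment_pair(
        fractions_dose.seg50, fractions_time.seg50, slope_tol=slope_tol
    )


def recover_geometry(
    config: simulate.SimConfig, slope_tol: float = GEOMETRY_SLOPE_TOL
) -> str:
    """Classify the planted cell line's >=50 dose-vs-time segment pair."""
    meta = simulate.simulate_metadata(config)
    matrix, _ = simulate.simulate_signatures(config, meta)
    counts = deg.count_deg(matrix)
    cell = config.cell_specs[0].cell_id
    by_dose = deg.stratified_category_counts(counts, meta, by="cell_x_dose_group")
    by_time = deg.stratified_category_counts(counts, meta, by="cell_x_time")
    f_dose = activity.compute_change_fractions(by_dose, cell, "dose")
    f_time = activity.compute_change_fractions(by_time, cell, "time")
    return _classify(f_dose, f_time, slope_tol)


def population_geometry(
    config: simulate.SimConfig, slope_tol: float = GEOMETRY_SLOPE_TOL
) -> str:
    """Classification of the *population* (infinite-sample) segments.

    Uses the exact analytic fractions, so this states what geometry the
    configuration actually plants, independent of any simulation.
    """
    table = simulate.expected_category_fractions(config, thresholds=(1, 50))
    cell = config.cell_specs[0].cell_id
    rows = table.loc[table["cell_id"] == cell].set_index(["stratum_type", "stratum"])

    def frac(stype: str, label: str) -> float:
        row = rows.loc[(stype, label)]
        return float(row["p_ge_50"] / row["p_ge_1"])

    seg_dose = (frac("dose_group", "low"), frac("dose_group", "high"))
    seg_time = (frac("time", "6h"), frac("time", "24h"))
    return activity.classify_segment_pair(seg_dose, seg_time, slope_tol=slope_tol)


@dataclass
class GeometryRecovery:
    planted: str
    population_class: str
    recovery_rate: float


def geometry_recovery_rate(
    planted: str,
    n_replicates: int = 100,
    base_seed: int = 0,
    slope_tol: float = GEOMETRY_SLOPE_TOL,
) -> GeometryRecovery:
    """Recovery rate of a planted parallel or intersecting geometry."""
    if planted == "parallel":
        maker = make_parallel_config
    elif planted == "intersecting":
        maker = make_intersecting_config
    else:
        raise ValueError(f"planted must be 'parallel' or 'intersecting', got {planted!r}")
    population = population_geometry(maker(0), slope_tol=slope_tol)
    hits = 0
    for r in range(n_replicates):
        if recover_geometry(maker(base_seed * n_replicates + r), slope_tol=slope_tol) == planted:
            hits += 1
    return GeometryRecovery(
        planted=planted, population_class=population, recovery_rate=hits / n_replicates
    )
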