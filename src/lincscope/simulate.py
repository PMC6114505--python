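"""Synthetic LINCS-shaped signature data with known ground truth.

The generator emulates the structure of a Level-5 perturbational
signature compendium: a metadata table (cell line, perturbagen,
category, dose, time, replicate count) and a matching 978-landmark-gene
z-score matrix.  Under the null a z-score is N(0, 1); a compound
signature additionally carries a planted set of "hit" genes whose
z-scores are shifted by a signed effect mean mu, with

    mu = base_effect * g(dose) * h(time)

where g and h are monotone multipliers determined by the configured
dose/time response direction (flat, increasing, decreasing).  Hit signs
split 50/50 up/down.  Control, ligand, poscon and genetic signatures are
drawn from the null.

With the conventional |z| > 2 threshold, the expected DEG count of a
signature with m hits at effect mu is

    m * P(|N(mu,1)| > 2) + (978 - m) * 2 * Phi(-2)

(about 44.5 background calls for a pure-null signature), and the exact
distribution of the DEG count is the convolution of two binomials.
:func:`expected_category_fractions` evaluates those tails exactly, which
makes the generator its own analytic oracle for the downstream
"at least k significant genes" analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .deg import DOSE_CUTOFF_UM, Z_HI_DEFAULT, Z_LO_DEFAULT
from .io import METADATA_COLUMNS, SignatureMatrix

N_LANDMARK_GENES = 978

RESPONSES = ("flat", "increasing", "decreasing")

#: Cell lines of a deeply profiled phase-I-style compendium.
DEFAULT_CELL_LINES = (
    "A375",
    "A549",
    "HCC515",
    "HA1E",
    "HEPG2",
    "HT29",
    "MCF7",
    "PC3",
    "VCAP",
)

DEFAULT_CATEGORY_MIX = {
    "control": 0.20,
    "compound": 0.60,
    "ligand": 0.05,
    "poscon": 0.05,
    "overexpression": 0.05,
    "shRNA": 0.05,
}

# Mostly 2-4 replicates, ~1% at 9 or more.
DEFAULT_REPLICATE_DISTRIBUTION = {
    1: 0.05,
    2: 0.20,
    3: 0.40,
    4: 0.20,
    5: 0.05,
    6: 0.04,
    7: 0.03,
    8: 0.02,
    9: 0.005,
    10: 0.005,
}

DEFAULT_HIT_COUNT_DISTRIBUTION = {0: 0.15, 20: 0.25, 50: 0.25, 100: 0.25, 200: 0.10}


@dataclass
class CellSpec:
    """Generator parameters for one cell line.

    ``condition_weights`` optionally gives joint sampling weights over
    (dose_um, time_h) pairs for compound signatures (default: independent
    uniform over the configured levels).  ``condition_effect`` optionally
    maps each (dose_um, time_h) pair to an explicit effect multiplier,
    overriding the separable g(dose)*h(time) form.
    """

    cell_id: str
    n_signatures: int
    category_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    dose_levels: tuple[float, ...] = (0.1, 1.0, 5.0, 10.0)
    time_levels: tuple[float, ...] = (6.0, 24.0, 48.0)
    replicate_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATE_DISTRIBUTION)
    )
    hit_count_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_HIT_COUNT_DISTRIBUTION)
    )
    base_effect: float = 3.0
    dose_response: str = "flat"
    time_response: str = "flat"
    n_compounds: int | None = None
    condition_weights: dict[tuple[float, float], float] | None = None
    condition_effect: dict[tuple[float, float], float] | None = None

    def conditions(self) -> tuple[list[tuple[float, float]], np.ndarray]:
        """(dose, time) pairs and their sampling probabilities."""
        if self.condition_weights is not None:
            pairs = sorted(self.condition_weights)
            probs = np.array([self.condition_weights[p] for p in pairs], dtype=float)
        else:
            pairs = [(d, t) for d in self.dose_levels for t in self.time_levels]
            probs = np.full(len(pairs), 1.0 / len(pairs))
        return pairs, probs

    def effect_multiplier(self, dose_um: float, time_h: float) -> float:
        if self.condition_effect is not None:
            try:
                return self.condition_effect[(dose_um, time_h)]
            except KeyError:
                raise ValueError(
                    f"cell {self.cell_id!r}: no condition_effect entry for "
                    f"({dose_um}, {time_h})"
                ) from None
        return _response_multiplier(
            self.dose_response, dose_um, self.dose_levels
        ) * _response_multiplier(self.time_response, time_h, self.time_levels)


def _response_multiplier(response: str, value: float, levels) -> float:
    # flat = 1; increasing = value / max level; decreasing = min level / value.
    if response == "flat":
        return 1.0
    if response == "increasing":
        return value / max(levels)
    if response == "decreasing":
        return min(levels) / value
    raise ValueError(f"unknown response {response!r}; expected one of {RESPONSES}")


@dataclass
class SimConfig:
    """Full generator configuration.

    Deterministic given ``seed``: metadata and signatures are drawn from
    named RNG streams derived from the seed by fixed offsets.
    """

    cell_specs: list[CellSpec]
    seed: int = 0
    n_genes: int = N_LANDMARK_GENES
    noise_sd: float = 1.0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.cell_specs:
            raise ValueError("at least one cell spec required")
        seen = set()
        for spec in self.cell_specs:
            if spec.cell_id in seen:
                raise ValueError(f"duplicate cell_id {spec.cell_id!r}")
            seen.add(spec.cell_id)
            if spec.n_signatures < 1:
                raise ValueError(f"cell {spec.cell_id!r}: n_signatures must be >= 1")
            for name, dist in (
                ("category_mix", spec.category_mix),
                ("replicate_distribution", spec.replicate_distribution),
                ("hit_count_distribution", spec.hit_count_distribution),
            ):
                probs = np.array(list(dist.values()), dtype=float)
                if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"cell {spec.cell_id!r}: {name} must be a probability "
                        f"distribution (sums to {probs.sum():.6f})"
                    )
            if spec.dose_response not in RESPONSES or spec.time_response not in RESPONSES:
                raise ValueError(f"cell {spec.cell_id!r}: invalid response direction")
            if not np.isfinite(spec.base_effect) or spec.base_effect < 0:
                raise ValueError(f"cell {spec.cell_id!r}: base_effect must be finite >= 0")
            if spec.condition_weights is not None:
                grid = {(d, t) for d in spec.dose_levels for t in spec.time_levels}
                if not set(spec.condition_weights) <= grid:
                    raise ValueError(
                        f"cell {spec.cell_id!r}: condition_weights keys outside the "
                        f"dose x time grid"
                    )
                w = np.array(list(spec.condition_weights.values()), dtype=float)
                if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"cell {spec.cell_id!r}: condition_weights must sum to 1"
                    )
            max_hits = max(spec.hit_count_distribution)
            if max_hits > self.n_genes:
                raise ValueError(
                    f"cell {spec.cell_id!r}: hit count {max_hits} exceeds n_genes"
                )


@dataclass
class PlantedTruth:
    """Per-signature ground truth of the planted effects."""

    table: pd.DataFrame  # sig_id, cell_id, n_hits, mu, expected_deg
    hit_genes: dict[str, np.ndarray]  # sig_id -> gene row indices

    def to_json_dict(self) -> dict:
        return {
            row.sig_id: {
                "n_hits": int(row.n_hits),
                "mu": float(row.mu),
                "expected_deg": float(row.expected_deg),
                "hit_genes": [int(i) for i in self.hit_genes.get(row.sig_id, [])],
            }
            for row in self.table.itertuples()
        }


def default_config(seed: int = 0, signatures_per_cell: int = 222) -> SimConfig:
    """A small, structurally faithful compendium: nine deeply profiled
    cell lines, doses {0.1, 1, 5, 10} uM, times {6, 24, 48} h."""
    specs = [
        CellSpec(cell_id=cell, n_signatures=signatures_per_cell)
        for cell in DEFAULT_CELL_LINES
    ]
    return SimConfig(cell_specs=specs, seed=seed)


_META_STREAM = 1
_SIGNATURE_STREAM = 2


def simulate_metadata(config: SimConfig) -> pd.DataFrame:
    """Draw a metadata table in the canonical schema.

    Compound signatures get a perturbagen from a per-cell compound pool
    and a (dose, time) condition; other categories are dose-less with a
    uniformly drawn time.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _META_STREAM])
    frames = []
    for spec in config.cell_specs:
        n = spec.n_signatures
        cats = list(spec.category_mix)
        cat_probs = np.array([spec.category_mix[c] for c in cats], dtype=float)
        category = rng.choice(cats, size=n, p=cat_probs)

        n_compounds = spec.n_compounds or max(1, n // 10)
        pools = {
            "control": [f"{spec.cell_id}-VEH"],
            "poscon": [f"{spec.cell_id}-POS-{i}" for i in range(2)],
            "ligand": [f"{spec.cell_id}-LIG-{i}" for i in range(5)],
            "overexpression": [f"{spec.cell_id}-OE-{i}" for i in range(20)],
            "shRNA": [f"{spec.cell_id}-SH-{i}" for i in range(20)],
            "compound": [f"{spec.cell_id}-CMP-{i:04d}" for i in range(n_compounds)],
        }
        pert_id = np.array(
            [pools[c][rng.integers(0, len(pools[c]))] for c in category], dtype=object
        )

        pairs, probs = spec.conditions()
        cond_idx = rng.choice(len(pairs), size=n, p=probs)
        dose = np.array([pairs[i][0] for i in cond_idx], dtype=float)
        time = np.array([pairs[i][1] for i in cond_idx], dtype=float)
        is_compound = category == "compound"
        dose[~is_compound] = np.nan
        # non-compound rows: uniform time over the configured levels
        time[~is_compound] = rng.choice(
            np.asarray(spec.time_levels, dtype=float), size=int((~is_compound).sum())
        )

        reps = list(spec.replicate_distribution)
        rep_probs = np.array([spec.replicate_distribution[r] for r in reps], dtype=float)
        n_replicates = rng.choice(np.array(reps, dtype=int), size=n, p=rep_probs)

        frames.append(
            pd.DataFrame(
                {
                    "sig_id": [f"{spec.cell_id}:SIG{i:06d}" for i in range(n)],
                    "cell_id": spec.cell_id,
                    "pert_id": pert_id.astype(str),
                    "pert_iname": pert_id.astype(str),
                    "pert_category": category,
                    "dose_um": dose,
                    "time_h": time,
                    "n_replicates": n_replicates,
                }
            )
        )
    meta = pd.concat(frames, ignore_index=True)
    return meta[list(METADATA_COLUMNS)]


def simulate_signatures(
    config: SimConfig, meta: pd.DataFrame
) -> tuple[SignatureMatrix, PlantedTruth]:
    """Draw the z-score matrix matching a simulated metadata table.

    Non-hit entries are N(0, noise_sd); each compound signature carries a
    drawn number of hit genes whose z-scores are shifted by +/-mu with
    mu = base_effect * g(dose) * h(time).  Deterministic given
    ``config.seed``.
    """
    config.validate()
    specs = {spec.cell_id: spec for spec in config.cell_specs}
    unknown = set(meta["cell_id"]) - set(specs)
    if unknown:
        raise ValueError(f"metadata contains cells absent from config: {sorted(unknown)}")

    rng = np.random.default_rng([config.seed, _SIGNATURE_STREAM])
    n_sigs = len(meta)
    z = rng.standard_normal((config.n_genes, n_sigs)) * config.noise_sd

    p0 = null_deg_probability()
    cats = meta["pert_category"].to_numpy()
    cells = meta["cell_id"].to_numpy()
    doses = meta["dose_um"].to_numpy()
    times = meta["time_h"].to_numpy()
    sig_ids = meta["sig_id"].to_numpy()

    # per-signature planted hit count and effect mean (zero off compounds)
    n_hits = np.zeros(n_sigs, dtype=int)
    mu = np.zeros(n_sigs, dtype=float)
    for spec in config.cell_specs:
        mask = (cells == spec.cell_id) & (cats == "compound")
        m = int(mask.sum())
        if m == 0:
            continue
        hits = np.array(list(spec.hit_count_distribution), dtype=int)
        hit_probs = np.array(
            [spec.hit_count_distribution[int(h)] for h in hits], dtype=float
        )
        n_hits[mask] = rng.choice(hits, size=m, p=hit_probs)
        idx = np.flatnonzero(mask)
        mu[idx] = spec.base_effect * np.array(
            [spec.effect_multiplier(doses[j], times[j]) for j in idx]
        )

    hit_genes: dict[str, np.ndarray] = {}
    for j in np.flatnonzero((n_hits > 0) & (mu > 0)):
        idx = rng.choice(config.n_genes, size=n_hits[j], replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_hits[j])
        z[idx, j] += signs * mu[j]
        hit_genes[sig_ids[j]] = np.sort(idx)

    q_cache = {m: hit_deg_probability(m) for m in np.unique(mu)}
    q = np.array([q_cache[m] for m in mu])
    truth_table = pd.DataFrame(
        {
            "sig_id": sig_ids,
            "cell_id": cells,
            "n_hits": n_hits,
            "mu": mu,
            "expected_deg": n_hits * q + (config.n_genes - n_hits) * p0,
        }
    )

    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    matrix = SignatureMatrix(gene_ids=gene_ids, sig_ids=list(sig_ids), z=z)
    truth = PlantedTruth(table=truth_table, hit_genes=hit_genes)
    return matrix, truth


# ---------------------------------------------------------------------------
# Analytic oracles


def null_deg_probability(z_hi: float = Z_HI_DEFAULT, z_lo: float = Z_LO_DEFAULT) -> float:
    """P(a null N(0,1) z-score is called significant) = 2*Phi(-2) at the
    conventional thresholds (~0.0455)."""
    return float(stats.norm.sf(z_hi) + stats.norm.cdf(z_lo))


def hit_deg_probability(
    mu: float, z_hi: float = Z_HI_DEFAULT, z_lo: float = Z_LO_DEFAULT
) -> float:
    """P(a hit gene with z ~ N(+/-mu, 1) is called significant).

    Symmetric in the sign of the shift, so the 50/50 up/down split does
    not matter.
    """
    return float(stats.norm.sf(z_hi - mu) + stats.norm.cdf(z_lo - mu))


def deg_count_pmf(n_genes: int, n_hits: int, mu: float) -> np.ndarray:
    """Exact pmf of the DEG count: Binom(n_hits, q) + Binom(n_genes - n_hits, p0),
    computed by convolution."""
    p0 = null_deg_probability()
    q = hit_deg_probability(mu)
    background = stats.binom.pmf(np.arange(n_genes - n_hits + 1), n_genes - n_hits, p0)
    if n_hits == 0:
        return background
    hit = stats.binom.pmf(np.arange(n_hits + 1), n_hits, q)
    return np.convolve(background, hit)


def deg_tail_probability(n_genes: int, n_hits: int, mu: float, k: int) -> float:
    """Exact P(DEG count >= k) for a signature with the given planted effect."""
    if k <= 0:
        return 1.0
    pmf = deg_count_pmf(n_genes, n_hits, mu)
    return float(pmf[k:].sum())


def mu_for_tail_probability(
    target: float, n_genes: int, n_hits: int, k: int, mu_max: float = 12.0
) -> float:
    """Effect mean mu such that P(DEG >= k) equals ``target`` (bisection).

    Raises if the target is outside the attainable range at the given hit
    count.
    """
    lo, hi = 0.0, mu_max
    f_lo = deg_tail_probability(n_genes, n_hits, lo, k)
    f_hi = deg_tail_probability(n_genes, n_hits, hi, k)
    if not f_lo <= target <= f_hi:
        raise ValueError(
            f"target {target} outside attainable range [{f_lo:.4g}, {f_hi:.4g}] "
            f"for {n_hits} hits at k={k}"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if deg_tail_probability(n_genes, n_hits, mid, k) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def expected_category_fractions(
    config: SimConfig,
    thresholds=(1, 50, 100),
    dose_cutoff_um: float = DOSE_CUTOFF_UM,
) -> pd.DataFrame:
    """Exact population fractions P(DEG >= k) for compound signatures.

    Returns one row per cell line and stratum — ``overall``, each dose
    group (low/high at the cutoff) and each time level — with a
    ``p_ge_<k>`` column per threshold.  Mixtures are taken over the
    configured condition weights and hit-count distribution; this is the
    analytic counterpart of running the full pipeline on an infinite
    sample.
    """
    config.validate()
    rows = []
    for spec in config.cell_specs:
        pairs, probs = spec.conditions()
        strata: dict[tuple[str, str], list[tuple[tuple[float, float], float]]] = {}
        for pair, w in zip(pairs, probs):
            dose, time = pair
            strata.setdefault(("overall", "all"), []).append((pair, w))
            group = "low" if dose <= dose_cutoff_um else "high"
            strata.setdefault(("dose_group", group), []).append((pair, w))
            strata.setdefault(("time", f"{time:g}h"), []).append((pair, w))
        for (stype, label), members in strata.items():
            total_w = sum(w for _, w in members)
            if total_w == 0:
                continue
            row = {"cell_id": spec.cell_id, "stratum_type": stype, "stratum": label}
            for k in thresholds:
                p = 0.0
                for (dose, time), w in members:
                    mu = spec.base_effect * spec.effect_multiplier(dose, time)
                    for n_hits, ph in spec.hit_count_distribution.items():
                        p += (w / total_w) * ph * deg_tail_probability(
                            config.n_genes, n_hits, mu, k
                        )
                row[f"p_ge_{k}"] = p
            rows.append(row)
    return pd.DataFrame(rows)
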