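"""Synthetic two-matrix metabolomics cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
three age- and sex-matched phenotype groups; log-normal baseline peak
areas; multiplicative per-(metabolite, batch) instrument effects;
left-censoring at the detection limit; per-sample protein concentration
for the cell matrix; a shared metabolite set between cells and spent
media with cross-matrix correlated noise; and a metabotype panel whose
members carry within-pathway-module correlated noise.  Planted single
-metabolite and ratio-level group effects are recorded in a
:class:`~metabophen.containers.SyntheticTruth` for recovery testing.

All randomness flows from one seeded :class:`numpy.random.Generator`
passed explicitly; identical seeds give bit-identical outputs.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    GROUPS,
    PlantedEffect,
    PlantedRatioEffect,
    RawAbundanceTable,
    SampleMetadata,
    SyntheticTruth,
    ValidationError,
)

#: Study-scale defaults: 3 groups x 10 samples (7F/3M), ages 2-59 years,
#: 645 cell / 489 media / 386 shared metabolites, 43-metabolite panel of
#: which 38 are detected in cells and 39 in media.
DEFAULT_N_PER_GROUP = 10
DEFAULT_N_FEMALE_PER_GROUP = 7
DEFAULT_AGE_RANGE = (2.0, 59.0)
DEFAULT_N_BATCHES = 2
DEFAULT_N_CELL_METS = 645
DEFAULT_N_MEDIA_METS = 489
DEFAULT_N_SHARED = 386
DEFAULT_BATCH_SD = 0.3
DEFAULT_NOISE_SD = 0.5
DEFAULT_CENSOR_FRACTION = 0.10

_GROUP_PREFIX = {"ASD_DD": "ASD", "CANCER": "CAN", "CANCER_ASD_DD": "CAS"}

# Within-pathway-module noise correlation for panel metabolites and
# cross-matrix noise correlation for shared metabolites.  Ratios of
# co-regulated metabolites cancel the shared component, which is the
# premise of ratio-based metabotyping.
PANEL_MODULE_RHO = 0.5
CROSS_MATRIX_RHO = 0.5
PANEL_MODULE_SIZE = 5


@dataclass
class EffectPlan:
    """Which group effects to plant when generating tables.

    ``effect`` is the contrast group's mean shift in multiples of the
    generator's noise sd (so ``effect=2`` plants a 2-SD log effect);
    ``ratio_effect`` is likewise in multiples of the nominal log-ratio
    noise sd (sqrt(2) * noise_sd) and splits half-and-half over the pair
    members.  The realized natural-log shifts are recorded in the
    returned ground truth.
    """

    n_affected_cells: int = 0
    n_affected_media: int = 0
    effect: float = 0.0
    contrast_group: str = "CANCER"
    n_ratio_pairs: int = 0
    ratio_effect: float = 0.0
    ratio_matrix: str = "MEDIA"


@dataclass
class SyntheticTables:
    """Bundle returned by :func:`generate_tables`."""

    cells: RawAbundanceTable
    media: RawAbundanceTable
    blank: RawAbundanceTable
    truth: SyntheticTruth
    panel: list[str] = field(default_factory=list)


def generate_cohort(
    n_per_group: int = DEFAULT_N_PER_GROUP,
    n_female_per_group: int = DEFAULT_N_FEMALE_PER_GROUP,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
    n_batches: int = DEFAULT_N_BATCHES,
    seed: int = 0,
) -> SampleMetadata:
    """Three phenotype groups with identical sex composition.

    Ages are drawn uniformly over ``age_range`` with the same law in
    every group, so group age distributions are exchangeable.  Batches
    are assigned round-robin over a group-interleaved sample order so
    batch is never confounded with group.
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    if not 0 <= n_female_per_group <= n_per_group:
        raise ValidationError("n_female_per_group must be in [0, n_per_group]")
    low, high = age_range
    if not low < high:
        raise ValidationError("age_range must satisfy low < high")
    if n_batches < 1:
        raise ValidationError("n_batches must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for group in GROUPS:
        prefix = _GROUP_PREFIX[group]
        ages = rng.uniform(low, high, size=n_per_group)
        for i in range(n_per_group):
            rows.append(
                {
                    "sample_id": f"{prefix}{i + 1:02d}",
                    "group": group,
                    "sex": "F" if i < n_female_per_group else "M",
                    "age_at_consent": float(ages[i]),
                    "batch": 0,
                }
            )
    frame = pd.DataFrame(rows).set_index("sample_id")
    # round-robin batches over group-interleaved order
    interleaved = [
        f"{_GROUP_PREFIX[g]}{i + 1:02d}"
        for i in range(n_per_group)
        for g in GROUPS
    ]
    frame.loc[interleaved, "batch"] = np.arange(len(interleaved)) % n_batches
    return SampleMetadata(frame)


def _met_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


def generate_tables(
    meta: SampleMetadata,
    n_cell_mets: int = DEFAULT_N_CELL_METS,
    n_media_mets: int = DEFAULT_N_MEDIA_METS,
    n_shared: int = DEFAULT_N_SHARED,
    batch_sd: float = DEFAULT_BATCH_SD,
    noise_sd: float = DEFAULT_NOISE_SD,
    censor_fraction: float = DEFAULT_CENSOR_FRACTION,
    plan: EffectPlan | None = None,
    seed: int = 0,
    n_panel: int = 43,
    n_panel_cells_only: int = 4,
    n_panel_media_only: int = 5,
    n_blank_samples: int = 3,
) -> SyntheticTables:
    """Simulate cells / media / blank abundance tables plus ground truth.

    Log-scale model per observation: per-metabolite baseline drawn from
    Normal(10, 2), a per-(metabolite, batch) effect with sd ``batch_sd``,
    the planted group effect, and noise with total sd ``noise_sd``.
    Shared metabolites split their noise into a cross-matrix component
    (correlation :data:`CROSS_MATRIX_RHO` between cells and media) and an
    idiosyncratic remainder; panel metabolites instead share a per-sample
    pathway-module factor (correlation :data:`PANEL_MODULE_RHO` within a
    module).  Values below each metabolite's ``censor_fraction`` quantile
    are censored to missing.
    """
    if plan is None:
        plan = EffectPlan()
    if n_shared > min(n_cell_mets, n_media_mets):
        raise ValidationError("n_shared exceeds a matrix's metabolite count")
    if not 0 <= censor_fraction < 1:
        raise ValidationError("censor_fraction must be in [0, 1)")
    n_panel_shared = n_panel - n_panel_cells_only - n_panel_media_only
    if n_panel_shared < 0:
        raise ValidationError("panel-only counts exceed n_panel")
    if n_panel_shared > n_shared:
        raise ValidationError("panel larger than the shared metabolite set")
    if n_panel_cells_only > n_cell_mets - n_shared:
        raise ValidationError("not enough cell-only metabolites for the panel")
    if n_panel_media_only > n_media_mets - n_shared:
        raise ValidationError("not enough media-only metabolites for the panel")

    rng = np.random.default_rng(seed)
    samples = meta.sample_ids
    n = len(samples)
    batches = meta.frame["batch"].to_numpy()
    n_batches = int(batches.max()) + 1

    shared_ids = _met_ids("SHM", n_shared)
    cell_ids = shared_ids + _met_ids("CEL", n_cell_mets - n_shared)
    media_ids = shared_ids + _met_ids("MED", n_media_mets - n_shared)

    # Panel: mostly shared metabolites, a few detected in one matrix only.
    panel = (
        shared_ids[:n_panel_shared]
        + [m for m in cell_ids if m.startswith("CEL")][:n_panel_cells_only]
        + [m for m in media_ids if m.startswith("MED")][:n_panel_media_only]
    )
    module_of = {
        m: i // PANEL_MODULE_SIZE for i, m in enumerate(panel)
    }
    n_modules = (len(panel) + PANEL_MODULE_SIZE - 1) // PANEL_MODULE_SIZE if panel else 0
    module_factors = rng.standard_normal((n, max(n_modules, 1)))

    mu_cells = rng.normal(10.0, 2.0, size=n_cell_mets)
    # shared metabolites keep one baseline across matrices
    mu_media = rng.normal(10.0, 2.0, size=n_media_mets)
    mu_media[:n_shared] = mu_cells[:n_shared]
    mu_blank = mu_media + rng.normal(0.0, 1.5, size=n_media_mets)

    def _noise(met_ids: list[str], shared_common: np.ndarray | None) -> np.ndarray:
        """Per-observation noise with module / cross-matrix structure."""
        out = np.empty((n, len(met_ids)))
        idio = rng.standard_normal((n, len(met_ids)))
        for j, m in enumerate(met_ids):
            if m in module_of:
                mod = module_factors[:, module_of[m]]
                out[:, j] = (
                    math.sqrt(PANEL_MODULE_RHO) * mod
                    + math.sqrt(1 - PANEL_MODULE_RHO) * idio[:, j]
                )
            elif shared_common is not None and j < n_shared:
                out[:, j] = (
                    math.sqrt(CROSS_MATRIX_RHO) * shared_common[:, j]
                    + math.sqrt(1 - CROSS_MATRIX_RHO) * idio[:, j]
                )
            else:
                out[:, j] = idio[:, j]
        return noise_sd * out

    shared_common = rng.standard_normal((n, n_shared))
    batch_eff_cells = rng.normal(0.0, batch_sd, size=(n_batches, n_cell_mets))
    batch_eff_media = rng.normal(0.0, batch_sd, size=(n_batches, n_media_mets))

    log_cells = mu_cells + batch_eff_cells[batches] + _noise(cell_ids, shared_common)
    log_media = mu_media + batch_eff_media[batches] + _noise(media_ids, shared_common)

    # Planted single-metabolite effects go to matrix-private, non-panel
    # metabolites so each analysis arm's recovery is unambiguous.
    contrast_mask = (meta.groups == plan.contrast_group).to_numpy()
    affected: list[PlantedEffect] = []

    def _plant_singles(log_vals, met_ids, prefix, n_affected, kind):
        pool = [m for m in met_ids if m.startswith(prefix) and m not in module_of]
        if n_affected > len(pool):
            raise ValidationError(f"not enough {kind} metabolites to plant effects")
        chosen = list(rng.choice(pool, size=n_affected, replace=False)) if n_affected else []
        for m in chosen:
            j = met_ids.index(m)
            shift = plan.effect * noise_sd
            log_vals[contrast_mask, j] += shift
            affected.append(PlantedEffect(str(m), kind, plan.contrast_group, shift))

    _plant_singles(log_cells, cell_ids, "CEL", plan.n_affected_cells, "CELLS")
    _plant_singles(log_media, media_ids, "MED", plan.n_affected_media, "MEDIA")

    # Ratio pairs: adjacent panel members within one pathway module, so
    # the pair shares module noise and its ratio is the stable readout.
    ratio_pairs: list[PlantedRatioEffect] = []
    if plan.n_ratio_pairs:
        target_ids = cell_ids if plan.ratio_matrix == "CELLS" else media_ids
        in_matrix = [m for m in panel if m in target_ids]
        candidates = [
            (a, b)
            for a, b in zip(in_matrix, in_matrix[1:])
            if module_of[a] == module_of[b]
        ]
        # disjoint pairs, taken in panel order
        chosen_pairs: list[tuple[str, str]] = []
        used: set[str] = set()
        for a, b in candidates:
            if a in used or b in used:
                continue
            chosen_pairs.append((a, b))
            used.update((a, b))
            if len(chosen_pairs) == plan.n_ratio_pairs:
                break
        if len(chosen_pairs) < plan.n_ratio_pairs:
            raise ValidationError("not enough within-module panel pairs to plant")
        target = log_cells if plan.ratio_matrix == "CELLS" else log_media
        for a, b in chosen_pairs:
            ja, jb = target_ids.index(a), target_ids.index(b)
            # nominal log-ratio sd of two metabolites, sqrt(2) * noise_sd;
            # the shared module factor cancels in the planted pair's own
            # ratio, making it still more detectable - the premise of
            # ratio metabotyping on co-regulated panels
            shift = plan.ratio_effect * math.sqrt(2.0) * noise_sd
            target[contrast_mask, ja] += shift / 2.0
            target[contrast_mask, jb] -= shift / 2.0
            ratio_pairs.append(
                PlantedRatioEffect(
                    a, b, plan.ratio_matrix, plan.contrast_group, shift
                )
            )

    # blank aliquots are technical replicates measured in one batch
    blank_batches = np.zeros(n_blank_samples, dtype=int)
    log_blank = (
        mu_blank
        + batch_eff_media[blank_batches]
        + noise_sd * rng.standard_normal((n_blank_samples, n_media_mets))
    )

    def _censor(log_vals: np.ndarray) -> np.ndarray:
        vals = np.exp(log_vals)
        if censor_fraction > 0:
            thresh = np.quantile(vals, censor_fraction, axis=0)
            vals = np.where(vals < thresh, np.nan, vals)
        return vals

    # Cell-pellet peak areas scale with the amount of cell material, so
    # raw cell values carry each sample's protein factor (log-normal,
    # 20% CV around 2); protein normalization then removes exactly this
    # variation rather than adding unrelated noise.
    protein = pd.Series(
        np.exp(rng.normal(math.log(2.0), math.sqrt(math.log(1 + 0.2**2)), size=n)),
        index=samples,
        name="protein_conc",
    )
    log_cells = log_cells + np.log(protein.to_numpy() / 2.0)[:, None]
    batch_series = pd.Series(batches, index=samples, name="batch")
    blank_ids = [f"BLK{i + 1:02d}" for i in range(n_blank_samples)]

    cells = RawAbundanceTable(
        "CELLS",
        pd.DataFrame(_censor(log_cells), index=samples, columns=cell_ids),
        batch_series,
        protein,
    )
    media = RawAbundanceTable(
        "MEDIA",
        pd.DataFrame(_censor(log_media), index=samples, columns=media_ids),
        batch_series,
    )
    blank = RawAbundanceTable(
        "BLANK",
        pd.DataFrame(_censor(log_blank), index=blank_ids, columns=media_ids),
        pd.Series(blank_batches, index=blank_ids, name="batch"),
    )
    truth = SyntheticTruth(affected, ratio_pairs, seed, censor_fraction)
    return SyntheticTables(cells, media, blank, truth, panel)


def plant_ratio_effects(
    table: RawAbundanceTable,
    meta: SampleMetadata,
    pairs: list[tuple[str, str]],
    effect: float,
    contrast_group: str,
) -> tuple[RawAbundanceTable, list[PlantedRatioEffect]]:
    """Shift each pair (A, B) by +effect/2 / -effect/2 on the log scale.

    Applied multiplicatively to observed raw values of samples in
    ``contrast_group``; the per-sample log-sum of A and B is unchanged.
    """
    if contrast_group not in GROUPS:
        raise ValidationError(f"unknown contrast group {contrast_group!r}")
    values = table.values.copy()
    for a, b in pairs:
        for m in (a, b):
            if m not in values.columns:
                raise KeyError(f"metabolite {m!r} not in {table.matrix_kind} table")
    mask = meta.frame.loc[values.index, "group"] == contrast_group
    up, down = math.exp(effect / 2.0), math.exp(-effect / 2.0)
    planted = []
    for a, b in pairs:
        values.loc[mask, a] *= up
        values.loc[mask, b] *= down
        planted.append(
            PlantedRatioEffect(a, b, table.matrix_kind, contrast_group, effect)
        )
    return (
        RawAbundanceTable(table.matrix_kind, values, table.batch, table.protein_conc),
        planted,
    )


def fisher_exact_gx2(table: np.ndarray) -> float:
    """Exact conditional test for a groups x 2 contingency table.

    Enumerates all tables with the observed margins and sums the
    probabilities of tables no more probable than the observed one
    (within relative tolerance 1e-7), the standard generalization of
    Fisher's exact test to g x 2 tables.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[1] != 2 or (table < 0).any():
        raise ValidationError("expected a nonnegative g x 2 count table")
    row_tot = table.sum(axis=1)
    col1 = int(table[:, 0].sum())
    n_tot = int(table.sum())

    def log_p(counts: tuple[int, ...]) -> float:
        # product of per-row binomials over the column-margin binomial
        lp = -math.lgamma(n_tot + 1) + math.lgamma(col1 + 1) + math.lgamma(n_tot - col1 + 1)
        for r, c in zip(row_tot, counts):
            lp += (
                math.lgamma(r + 1)
                - math.lgamma(c + 1)
                - math.lgamma(r - c + 1)
            )
        return lp

    obs_lp = log_p(tuple(int(c) for c in table[:, 0]))
    total = 0.0
    ranges = [range(0, int(r) + 1) for r in row_tot[:-1]]
    for counts in itertools.product(*ranges):
        last = col1 - sum(counts)
        if not 0 <= last <= row_tot[-1]:
            continue
        lp = log_p(counts + (last,))
        if lp <= obs_lp + 1e-7:
            total += math.exp(lp)
    return min(total, 1.0)


def verify_matching(meta: SampleMetadata) -> tuple[float, float]:
    """Check group matching: Fisher exact on sex, Kruskal-Wallis on age.

    Returns ``(fisher_p, kruskal_p)``.  The Fisher p comes from full
    enumeration over the groups x sex table's fixed margins; the
    Kruskal-Wallis p uses the tie-corrected chi-square reference.
    """
    groups = [g for g in GROUPS if (meta.groups == g).any()]
    if len(groups) < 2:
        raise ValidationError("matching check needs at least two groups")
    counts = []
    ages = []
    for g in groups:
        sub = meta.frame[meta.frame["group"] == g]
        if len(sub) < 2:
            raise ValidationError(f"group {g} has fewer than two samples")
        counts.append([(sub["sex"] == "F").sum(), (sub["sex"] == "M").sum()])
        ages.append(sub["age_at_consent"].to_numpy())
    fisher_p = fisher_exact_gx2(np.array(counts))
    if all(np.array_equal(np.sort(a), np.sort(ages[0])) for a in ages):
        kruskal_p = 1.0  # identical distributions, statistic 0
    else:
        kruskal_p = float(stats.kruskal(*ages).pvalue)
    return float(fisher_p), kruskal_p
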