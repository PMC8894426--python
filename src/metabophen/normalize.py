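"""Normalization chain for raw peak-area tables.

The chain, per matrix:

1. batch median scaling — within each instrument batch, each
   metabolite's observed values are divided by their batch median, so
   every batch (and hence the metabolite) has median 1;
2. protein normalization (cells only) — each sample's values are divided
   by its protein concentration, then each metabolite is re-scaled to
   overall median 1;
3. minimum-value imputation — missing entries receive the metabolite's
   minimum observed scaled value across all batches (below-detection
   missingness);
4. natural-log transform and per-metabolite center-scaling to mean 0 /
   sd 1 (sample sd, n-1 denominator).

Missing values never participate in medians or minima; the imputed mask
marks exactly the originally missing entries.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import NormalizedTable, RawAbundanceTable, ValidationError

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """A table cannot be normalized under the chain's preconditions."""


def batch_median_scale(raw: RawAbundanceTable) -> RawAbundanceTable:
    """Divide each (metabolite, batch) cell group by its observed median."""
    values = raw.values.copy()
    for b, idx in values.groupby(raw.batch).groups.items():
        block = values.loc[idx]
        medians = block.median(axis=0, skipna=True)
        empty = medians.index[medians.isna()]
        if len(empty):
            raise NormalizationError(
                f"metabolite {empty[0]!r} entirely missing in batch {b}"
            )
        values.loc[idx] = block / medians
    return RawAbundanceTable(raw.matrix_kind, values, raw.batch, raw.protein_conc)


def protein_normalize(raw: RawAbundanceTable) -> RawAbundanceTable:
    """Divide each sample by its protein concentration, re-scale to median 1.

    Applies to the CELLS matrix only, after batch scaling and before
    imputation.  The re-scaling median is the overall per-metabolite
    median of observed values.
    """
    if raw.matrix_kind != "CELLS":
        raise ValidationError("protein normalization applies to CELLS only")
    if raw.protein_conc is None:
        raise ValidationError("CELLS table lacks protein concentrations")
    values = raw.values.div(raw.protein_conc, axis=0)
    values = values / values.median(axis=0, skipna=True)
    return RawAbundanceTable(raw.matrix_kind, values, raw.batch, raw.protein_conc)


def impute_min(raw: RawAbundanceTable) -> tuple[RawAbundanceTable, pd.DataFrame]:
    """Replace missing entries by the metabolite's minimum observed value.

    Returns the imputed table and the boolean mask of imputed entries.
    """
    mask = raw.values.isna()
    mins = raw.values.min(axis=0, skipna=True)
    if mins.isna().any():
        bad = mins.index[mins.isna()][0]
        raise NormalizationError(f"metabolite {bad!r} has no observed values")
    values = raw.values.fillna(mins)
    return (
        RawAbundanceTable(raw.matrix_kind, values, raw.batch, raw.protein_conc),
        mask,
    )


def log_center_scale(
    raw: RawAbundanceTable, imputed_mask: pd.DataFrame | None = None
) -> NormalizedTable:
    """Natural-log transform, then center-scale each metabolite to 0 / 1.

    Constant metabolites (sd 0 after imputation) carry no information
    and are dropped with a warning; their ids are listed in ``dropped``.
    """
    vals = raw.values.to_numpy(dtype=float)
    if np.any(vals <= 0) or np.any(np.isnan(vals)):
        raise NormalizationError("log transform requires strictly positive values")
    log_values = np.log(raw.values)
    sd = log_values.std(axis=0, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant):
        logger.warning(
            "dropping %d constant metabolite(s): %s",
            len(constant),
            list(constant[:5]),
        )
    log_values = log_values.drop(columns=constant)
    scaled = (log_values - log_values.mean(axis=0)) / log_values.std(axis=0, ddof=1)
    if imputed_mask is None:
        imputed_mask = pd.DataFrame(
            False, index=log_values.index, columns=log_values.columns
        )
    else:
        imputed_mask = imputed_mask.drop(columns=constant, errors="ignore")
    return NormalizedTable(
        raw.matrix_kind,
        log_values,
        scaled,
        imputed_mask.loc[log_values.index, log_values.columns],
        dropped=list(constant),
    )


def normalize_matrix(raw: RawAbundanceTable) -> NormalizedTable:
    """Run the full chain for one matrix.

    CELLS: batch median scale -> protein normalize -> impute -> log +
    center-scale.  MEDIA / BLANK: the same without the protein step.
    """
    table = batch_median_scale(raw)
    if raw.matrix_kind == "CELLS":
        table = protein_normalize(table)
    table, mask = impute_min(table)
    return log_center_scale(table, mask)
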