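"""Ratio feature construction: cells-over-media and metabotype pairs.

Ratios are formed on the natural-log scale *before* center-scaling
(difference of logs = log of ratio), then the ratio features themselves
are center-scaled for testing and clustering.  Two provenances:

* ``CELL_OVER_MEDIA`` — per shared metabolite, log(cells) - log(media),
  after each matrix's own normalization path;
* ``PANEL_PAIRWISE`` — metabotype features: every unordered pair of
  panel metabolites detected in one matrix, log A - log B with the pair
  stored in lexicographic order (the reversed pair is just the negation
  and would duplicate every test).
"""
from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .containers import NormalizedTable, RatioFeatureTable, ValidationError

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Tables disagree on their sample sets."""


class PanelError(ValueError):
    """The metabotype panel does not overlap the matrix sufficiently."""


def shared_metabolites(cells: NormalizedTable, media: NormalizedTable) -> list[str]:
    """Sorted intersection of the two matrices' metabolite ids."""
    if set(cells.sample_ids) != set(media.sample_ids):
        raise AlignmentError("cells and media tables cover different samples")
    return sorted(set(cells.metabolite_ids) & set(media.metabolite_ids))


def _center_scale(frame: pd.DataFrame) -> pd.DataFrame:
    sd = frame.std(axis=0, ddof=1)
    keep = sd.index[sd > 0]
    if len(keep) < frame.shape[1]:
        logger.warning("dropping %d constant ratio feature(s)", frame.shape[1] - len(keep))
    frame = frame[keep]
    return (frame - frame.mean(axis=0)) / frame.std(axis=0, ddof=1)


def cell_media_ratios(cells: NormalizedTable, media: NormalizedTable) -> RatioFeatureTable:
    """Per-sample log-ratio of each shared metabolite, cells over media."""
    shared = shared_metabolites(cells, media)
    if not shared:
        raise AlignmentError("no shared metabolites between cells and media")
    order = cells.sample_ids
    log_ratio = cells.log_values[shared] - media.log_values.loc[order, shared]
    log_ratio.columns = [f"{m}@cells/{m}@media" for m in shared]
    return RatioFeatureTable("CELL_OVER_MEDIA", log_ratio, _center_scale(log_ratio))


def pairwise_panel_ratios(norm: NormalizedTable, panel: list[str]) -> RatioFeatureTable:
    """All unordered pairs of panel metabolites detected in the matrix."""
    detected = [m for m in panel if m in set(norm.metabolite_ids)]
    missing = [m for m in panel if m not in set(norm.metabolite_ids)]
    if len(detected) < 2:
        raise PanelError(
            f"fewer than 2 panel metabolites detected in {norm.matrix_kind}; "
            f"missing: {missing}"
        )
    if missing:
        logger.info(
            "%d/%d panel metabolites not detected in %s: %s",
            len(missing), len(panel), norm.matrix_kind, missing,
        )
    detected = sorted(detected)
    logger.info(
        "%d detected panel metabolites -> %d ratio tests",
        len(detected), count_ratio_tests(len(detected)),
    )
    cols = {}
    log_vals = norm.log_values
    for a, b in itertools.combinations(detected, 2):
        cols[f"{a}/{b}@{norm.matrix_kind.lower()}"] = log_vals[a] - log_vals[b]
    log_ratio = pd.DataFrame(cols, index=norm.log_values.index)
    return RatioFeatureTable("PANEL_PAIRWISE", log_ratio, _center_scale(log_ratio))


def count_ratio_tests(n_detected: int) -> int:
    """Number of unordered pairs among n detected metabolites: n(n-1)/2."""
    if n_detected < 0:
        raise ValidationError("n_detected must be nonnegative")
    return n_detected * (n_detected - 1) // 2
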