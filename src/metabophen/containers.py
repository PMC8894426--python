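"""Shared data containers for the two-matrix metabolomics pipeline.

All tabular payloads are pandas objects with samples as rows and
metabolites (or ratio features) as columns.  Missing raw abundances are
encoded as NaN; zero is a legal abundance after scaling and never means
missing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("ASD_DD", "CANCER", "CANCER_ASD_DD")
SEXES = ("F", "M")
MATRIX_KINDS = ("CELLS", "MEDIA", "BLANK")


class ValidationError(ValueError):
    """An input object violates its schema or invariants."""


@dataclass
class SampleMetadata:
    """Per-sample phenotype annotations.

    ``frame`` is indexed by sample id with columns ``group`` (one of
    :data:`GROUPS`), ``sex`` (one of :data:`SEXES`), ``age_at_consent``
    (years) and ``batch`` (integer instrument-batch label).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"group", "sex", "age_at_consent", "batch"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        bad_group = set(self.frame["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(
                f"unknown group labels {sorted(bad_group)}; allowed: {list(GROUPS)}"
            )
        bad_sex = set(self.frame["sex"]) - set(SEXES)
        if bad_sex:
            raise ValidationError(
                f"unknown sex codes {sorted(bad_sex)}; allowed: {list(SEXES)}"
            )
        if (self.frame["age_at_consent"] <= 0).any():
            raise ValidationError("age_at_consent must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def groups(self) -> pd.Series:
        return self.frame["group"]

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())


@dataclass
class RawAbundanceTable:
    """Raw peak areas for one matrix (samples x metabolites, NaN = missing).

    ``batch`` is the per-sample instrument batch; ``protein_conc`` is the
    per-sample protein concentration and is present for CELLS only.
    """

    matrix_kind: str
    values: pd.DataFrame
    batch: pd.Series
    protein_conc: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.matrix_kind not in MATRIX_KINDS:
            raise ValidationError(f"matrix_kind must be one of {MATRIX_KINDS}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate metabolite ids: {dupes}")
        if not self.values.index.equals(self.batch.index):
            raise ValidationError("batch index does not match sample ids")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) <= 0:
            raise ValidationError("observed abundances must be strictly positive")
        all_missing = self.values.columns[self.values.isna().all(axis=0)]
        if len(all_missing):
            raise ValidationError(
                f"metabolites entirely missing: {list(all_missing[:5])}"
            )
        if self.protein_conc is not None:
            if self.matrix_kind != "CELLS":
                raise ValidationError("protein_conc only applies to CELLS")
            if not self.values.index.equals(self.protein_conc.index):
                raise ValidationError("protein_conc index does not match sample ids")
            if (self.protein_conc <= 0).any():
                raise ValidationError("protein concentrations must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class NormalizedTable:
    """Fully normalized abundances.

    ``log_values`` are natural-log abundances after batch median scaling,
    (cells only) protein normalization, and minimum-value imputation;
    ``scaled_values`` are the same values center-scaled per metabolite to
    mean 0 / sd 1 (sample sd, n-1); ``imputed_mask`` marks exactly the
    originally missing entries.  Constant metabolites are dropped and
    listed in ``dropped``.
    """

    matrix_kind: str
    log_values: pd.DataFrame
    scaled_values: pd.DataFrame
    imputed_mask: pd.DataFrame
    dropped: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.log_values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.log_values.columns)


@dataclass
class RatioFeatureTable:
    """Log-ratio features, one column per ratio.

    ``provenance`` is ``CELL_OVER_MEDIA`` (per-metabolite cells over spent
    media, feature ids ``met@cells/met@media``) or ``PANEL_PAIRWISE``
    (metabotype pairs ``metA/metB@matrix``, lexicographically ordered).
    ``log_values`` are log-ratio values; ``scaled_values`` center-scale
    each feature for testing and clustering.
    """

    provenance: str
    log_values: pd.DataFrame
    scaled_values: pd.DataFrame

    @property
    def feature_ids(self) -> list[str]:
        return list(self.log_values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.log_values.index)


@dataclass
class PlantedEffect:
    metabolite_id: str
    matrix_kind: str
    contrast_group: str
    effect: float  # log-scale shift of the contrast group's mean


@dataclass
class PlantedRatioEffect:
    metabolite_a: str
    metabolite_b: str
    matrix_kind: str
    contrast_group: str
    effect: float  # log-ratio shift (A up by effect/2, B down by effect/2)


@dataclass
class SyntheticTruth:
    """Ground-truth record of planted effects for recovery testing."""

    affected_metabolites: list[PlantedEffect]
    affected_ratio_pairs: list[PlantedRatioEffect]
    seed: int
    censor_fraction: float

    def __post_init__(self) -> None:
        for e in self.affected_metabolites:
            if not np.isfinite(e.effect):
                raise ValidationError("planted effect sizes must be finite")
        for e in self.affected_ratio_pairs:
            if not np.isfinite(e.effect):
                raise ValidationError("planted ratio effect sizes must be finite")


@dataclass
class ClassificationReport:
    """Confusion-matrix metrics for one LOOCV configuration.

    ``confusion`` has truth on rows and predictions on columns.  For a
    two-group task ``sensitivity``/``specificity`` refer to
    ``positive_class``; for more groups they are one-vs-rest dicts keyed
    by class.
    """

    confusion: pd.DataFrame
    accuracy: float
    ci95: tuple[float, float]
    nir: float
    p_vs_nir: float
    sensitivity: float | dict[str, float]
    specificity: float | dict[str, float]
    positive_class: str
    n: int

    def __post_init__(self) -> None:
        total = self.confusion.to_numpy().sum()
        if total != self.n:
            raise ValidationError("confusion total does not match n")
        if not (self.ci95[0] - 1e-12 <= self.accuracy <= self.ci95[1] + 1e-12):
            raise ValidationError("ci95 must contain the accuracy")
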