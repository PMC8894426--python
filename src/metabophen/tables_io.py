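"""Tabular I/O, configuration, and run manifests.

Abundance tables live on disk as wide delimited text: first column the
sample id, header row the metabolite ids, empty cells or ``NA`` for
missing values (never 0 — zero is a legal abundance after scaling).
The delimiter is sniffed from the extension (.csv -> comma, else tab).
Readers auto-detect the transposed orientation when the first header
token is ``metabolite_id``.  All writers emit a deterministic column
order and fixed decimal formatting so outputs are diffable and
re-writable byte-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import (
    GROUPS,
    ClassificationReport,
    RawAbundanceTable,
    SampleMetadata,
    SEXES,
    SyntheticTruth,
    ValidationError,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """A file violates the expected on-disk schema."""


def _sep(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_abundance_table(
    path,
    matrix_kind: str,
    batch: pd.Series | None = None,
    protein_conc: pd.Series | None = None,
) -> RawAbundanceTable:
    """Read a wide abundance table; missing entries are '' or 'NA'.

    ``batch`` / ``protein_conc`` per-sample annotations usually come
    from the metadata table; absent a batch, all samples are assigned
    batch 0.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep(path))
    tokens = header[1:]
    if len(set(tokens)) < len(tokens):
        dupes = sorted({t for t in tokens if tokens.count(t) > 1})
        raise FormatError(f"{path}: duplicated header column(s) {dupes}")
    frame = pd.read_csv(
        path, sep=_sep(path), index_col=0, na_values=["NA"],
        keep_default_na=False, comment="#",
    )
    if frame.index.name == "metabolite_id":
        frame = frame.T
    frame.index.name = None
    frame.columns.name = None
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicated sample row(s) {dupes}")
    for col in frame.columns:
        converted = pd.to_numeric(frame[col].replace("", np.nan), errors="coerce")
        bad = converted.isna() & frame[col].replace("", np.nan).notna()
        if bad.any():
            raise FormatError(
                f"{path}: non-numeric value {frame.loc[bad.idxmax(), col]!r} "
                f"at row {bad.idxmax()!r}, column {col!r}"
            )
        frame[col] = converted
    if batch is None:
        batch = pd.Series(0, index=frame.index, name="batch")
    return RawAbundanceTable(matrix_kind, frame, batch.loc[frame.index], protein_conc)


def write_abundance_table(path, table: RawAbundanceTable) -> None:
    path = Path(path)
    table.values.to_csv(
        path, sep=_sep(path), float_format=FLOAT_FMT, na_rep="",
        index_label="sample_id",
    )


def write_frame(path, frame: pd.DataFrame, index_label: str = "sample_id") -> None:
    """Deterministically formatted generic frame writer."""
    path = Path(path)
    frame.to_csv(
        path, sep=_sep(path), float_format=FLOAT_FMT, na_rep="NA",
        index_label=index_label,
    )


def read_metadata(path) -> tuple[SampleMetadata, pd.Series | None]:
    """Read the sample metadata table (and protein_conc if present).

    Group and sex codes are case-folded (``cancer`` -> ``CANCER``).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep(path), index_col=0, comment="#")
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = {"group", "sex", "age_at_consent", "batch"}
    if not required <= set(frame.columns):
        raise FormatError(
            f"{path}: metadata needs columns {sorted(required)}"
        )
    frame["group"] = frame["group"].astype(str).str.strip().str.upper()
    frame["sex"] = frame["sex"].astype(str).str.strip().str.upper()
    bad_groups = set(frame["group"]) - set(GROUPS)
    if bad_groups:
        raise ValidationError(
            f"{path}: unknown group label(s) {sorted(bad_groups)}; "
            f"allowed: {list(GROUPS)}"
        )
    bad_sex = set(frame["sex"]) - set(SEXES)
    if bad_sex:
        raise ValidationError(
            f"{path}: unknown sex code(s) {sorted(bad_sex)}; allowed: {list(SEXES)}"
        )
    frame["batch"] = frame["batch"].astype(int)
    protein = None
    if "protein_conc" in frame.columns:
        protein = frame["protein_conc"].astype(float)
    meta = SampleMetadata(frame[["group", "sex", "age_at_consent", "batch"]])
    return meta, protein


def write_metadata(path, meta: SampleMetadata, protein_conc: pd.Series | None = None) -> None:
    frame = meta.frame.copy()
    if protein_conc is not None:
        frame["protein_conc"] = protein_conc
    write_frame(path, frame)


def read_panel(path) -> list[str]:
    """Metabolite panel: one name per line, '#' comments, blanks ignored."""
    names: list[str] = []
    for line in Path(path).read_text().splitlines():
        name = line.split("#", 1)[0].strip()
        if name:
            names.append(name)
    seen = set()
    dupes = [n for n in names if n in seen or seen.add(n)]
    if dupes:
        raise FormatError(f"{path}: duplicated panel name(s) {sorted(set(dupes))}")
    return names


def write_panel(path, names: list[str]) -> None:
    Path(path).write_text("".join(f"{n}\n" for n in names))


def write_diff_results(path, diff: pd.DataFrame) -> None:
    """Differential-abundance results with a fixed diffable column order."""
    cols = [c for c in (
        "coef", "se", "t_ordinary", "t_moderated", "F", "df1",
        "df_residual", "df_total", "p_raw", "p_adj", "significant",
    ) if c in diff.columns]
    out = diff[cols].copy()
    path = Path(path)
    out.to_csv(path, sep=_sep(path), float_format="%.6g", index_label="feature")


def write_report(path, report: ClassificationReport) -> None:
    """Plain-text classification report: metrics then the confusion matrix."""
    lines = [
        f"n\t{report.n}",
        f"accuracy\t{report.accuracy:.6g}",
        f"ci95_low\t{report.ci95[0]:.6g}",
        f"ci95_high\t{report.ci95[1]:.6g}",
        f"nir\t{report.nir:.6g}",
        f"p_vs_nir\t{report.p_vs_nir:.6g}",
        f"positive_class\t{report.positive_class}",
    ]
    if isinstance(report.sensitivity, dict):
        for cls in sorted(report.sensitivity):
            lines.append(f"sensitivity[{cls}]\t{report.sensitivity[cls]:.6g}")
            lines.append(f"specificity[{cls}]\t{report.specificity[cls]:.6g}")
    else:
        lines.append(f"sensitivity\t{report.sensitivity:.6g}")
        lines.append(f"specificity\t{report.specificity:.6g}")
    lines.append("")
    lines.append(report.confusion.to_csv(sep="\t").rstrip("\n"))
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth(path, truth: SyntheticTruth) -> None:
    """Planted-effect ground truth as a diffable TSV."""
    rows = [
        {
            "kind": "single", "metabolite_a": e.metabolite_id, "metabolite_b": "",
            "matrix": e.matrix_kind, "contrast_group": e.contrast_group,
            "effect": e.effect,
        }
        for e in truth.affected_metabolites
    ] + [
        {
            "kind": "ratio", "metabolite_a": e.metabolite_a,
            "metabolite_b": e.metabolite_b, "matrix": e.matrix_kind,
            "contrast_group": e.contrast_group, "effect": e.effect,
        }
        for e in truth.affected_ratio_pairs
    ]
    frame = pd.DataFrame(
        rows,
        columns=["kind", "metabolite_a", "metabolite_b", "matrix",
                 "contrast_group", "effect"],
    )
    path = Path(path)
    frame.to_csv(path, sep=_sep(path), float_format="%.6g", index=False)


@dataclass
class RunConfig:
    """Pipeline configuration; unset paths trigger simulation."""

    cells_path: str | None = None
    media_path: str | None = None
    blank_path: str | None = None
    metadata_path: str | None = None
    panel_path: str | None = None
    alpha_adjusted: float = 0.05
    pca_variance_threshold: float = 0.95
    corr_removal_threshold: float = 0.90
    logitboost_iter_grid: tuple[int, ...] = (11, 21, 31)
    positive_class: str = "CANCER"
    metabotype_matrix: str = "MEDIA"
    seed: int = 0
    # simulation parameters, used when no input paths are given
    simulate: bool = True
    n_per_group: int = 10
    n_female_per_group: int = 7
    n_batches: int = 2
    n_cell_mets: int = 645
    n_media_mets: int = 489
    n_shared: int = 386
    batch_sd: float = 0.3
    noise_sd: float = 0.5
    censor_fraction: float = 0.10
    n_panel: int = 43
    n_panel_cells_only: int = 4
    n_panel_media_only: int = 5
    n_affected_cells: int = 5
    n_affected_media: int = 5
    effect: float = 2.0  # in multiples of noise_sd
    n_ratio_pairs: int = 3
    ratio_effect: float = 2.0  # in multiples of sqrt(2) * noise_sd
    contrast_group: str = "CANCER"

    def __post_init__(self) -> None:
        if not 0 < self.alpha_adjusted < 1:
            raise ValidationError("alpha_adjusted must be in (0, 1)")
        if not 0 < self.pca_variance_threshold <= 1:
            raise ValidationError("pca_variance_threshold must be in (0, 1]")
        if not 0 <= self.corr_removal_threshold <= 1:
            raise ValidationError("corr_removal_threshold must be in [0, 1]")
        if any(i < 1 for i in self.logitboost_iter_grid):
            raise ValidationError("logitboost iterations must be positive")
        for attr in ("cells_path", "media_path", "metadata_path", "panel_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{attr} does not exist: {p}")


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def load_config(path) -> RunConfig:
    """Flat ``key = value`` config; '#' comments; unknown keys warn."""
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in fields:
            warnings.warn(f"{path}:{lineno}: unknown config key {key!r} ignored")
            continue
        ftype = fields[key].type
        if key == "logitboost_iter_grid":
            kwargs[key] = tuple(int(v) for v in value.split(","))
        elif "bool" in str(ftype):
            kwargs[key] = _BOOL[value.lower()]
        elif "int" in str(ftype):
            kwargs[key] = int(value)
        elif "float" in str(ftype):
            kwargs[key] = float(value)
        else:
            kwargs[key] = value or None
    return RunConfig(**kwargs)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, config: RunConfig, files: list[str], extra: dict | None = None) -> Path:
    """Run manifest: config echo, seed, version, per-file content hashes."""
    out_dir = Path(out_dir)
    lines = [f"metabophen_version = {__version__}"]
    for f in dataclasses.fields(RunConfig):
        lines.append(f"config.{f.name} = {getattr(config, f.name)}")
    for key, value in (extra or {}).items():
        lines.append(f"{key} = {value}")
    for name in sorted(files):
        lines.append(f"sha256 {sha256_file(out_dir / name)}  {name}")
    path = out_dir / "manifest.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
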