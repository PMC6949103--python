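"""Shared data model, file I/O, configuration, and multiple-testing utilities.

All omics assays (expression, methylation beta values, RPPA protein
abundance, drug-response AUC, copy-number calls) travel through one
container, :class:`OmicsMatrix`, oriented features x samples.  Files are
plain TSV: feature IDs in the first column, sample IDs in the header row,
``NA``/``NaN``/empty cells for missing values.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("clockscape")

#: The core transcriptional-translational feedback loop components used as
#: the default gene panel.  ARNTL is also known as BMAL1.
CORE_CLOCK_GENES = (
    "CLOCK",
    "ARNTL",
    "CRY1",
    "CRY2",
    "NR1D1",
    "PER1",
    "PER2",
    "PER3",
    "RORA",
)

MATRIX_KINDS = ("expression", "methylation", "rppa", "auc", "cnv")

_CNV_LEVELS = frozenset({-2.0, -1.0, 0.0, 1.0, 2.0})


class MatrixValidationError(ValueError):
    """Raised when an OmicsMatrix violates a kind-specific invariant."""


def _check_unique(ids: Sequence[str], axis: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise MatrixValidationError(f"duplicate {axis} ID: {i!r}")
        seen.add(i)


@dataclass
class OmicsMatrix:
    """A named feature x sample numeric matrix with missing-value support.

    Parameters
    ----------
    values
        DataFrame of floats, index = feature IDs, columns = sample IDs.
        NaN marks missing.
    kind
        One of ``expression``, ``methylation``, ``rppa``, ``auc``, ``cnv``.
        Methylation values must lie in [0, 1]; CNV values must be integer
        codes in {-2, -1, 0, +1, +2} (heterozygous loss/gain = +/-1,
        homozygous = +/-2).
    units
        Free-text unit annotation, e.g. ``"RPKM"`` or ``"beta"``.
    """

    values: pd.DataFrame
    kind: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise MatrixValidationError(
                f"unknown matrix kind {self.kind!r}; expected one of {MATRIX_KINDS}"
            )
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        _check_unique(list(self.values.index), "feature")
        _check_unique(list(self.values.columns), "sample")
        self._validate_ranges()

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, feature: str) -> pd.Series:
        return self.values.loc[feature]

    def subset_samples(self, sample_ids: Iterable[str]) -> "OmicsMatrix":
        keep = [s for s in sample_ids if s in self.values.columns]
        return OmicsMatrix(self.values[keep], kind=self.kind, units=self.units)

    # -- validation ------------------------------------------------------
    def _validate_ranges(self) -> None:
        arr = self.values.to_numpy()
        if self.kind == "methylation":
            bad = np.argwhere(~np.isnan(arr) & ((arr < 0.0) | (arr > 1.0)))
            if bad.size:
                r, c = bad[0]
                raise MatrixValidationError(
                    f"methylation beta out of [0, 1]: value {arr[r, c]!r} at "
                    f"feature {self.values.index[r]!r}, sample {self.values.columns[c]!r}"
                )
        elif self.kind == "cnv":
            flat = arr[~np.isnan(arr)]
            ok = np.isin(flat, list(_CNV_LEVELS))
            if not ok.all():
                bad = np.argwhere(
                    ~np.isnan(arr) & ~np.isin(arr, list(_CNV_LEVELS))
                )
                r, c = bad[0]
                raise MatrixValidationError(
                    f"CNV call not in {{-2,-1,0,1,2}}: value {arr[r, c]!r} at "
                    f"feature {self.values.index[r]!r}, sample {self.values.columns[c]!r}"
                )


@dataclass(frozen=True)
class PathwayDefinition:
    """A signed pathway membership: protein -> +1 (positive regulator) or
    -1 (negative regulator)."""

    pathway_name: str
    members: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_name!r} has no members")
        proteins = [p for p, _ in self.members]
        _check_unique(proteins, f"protein (pathway {self.pathway_name!r})")
        for p, s in self.members:
            if s not in (1, -1):
                raise ValueError(
                    f"pathway {self.pathway_name!r} member {p!r}: sign must be +1 or -1, got {s!r}"
                )

    @property
    def positive(self) -> list[str]:
        return [p for p, s in self.members if s == 1]

    @property
    def negative(self) -> list[str]:
        return [p for p, s in self.members if s == -1]


@dataclass
class SurvivalTable:
    """Per-sample follow-up: time in days, event 1 = death, 0 = censored."""

    data: pd.DataFrame  # columns: sample, time, event[, group]

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"sample", "time", "event"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"survival table missing columns: {sorted(missing)}")
        df["sample"] = df["sample"].astype(str)
        df["time"] = df["time"].astype(float)
        df["event"] = df["event"].astype(int)
        _check_unique(list(df["sample"]), "survival sample")
        if (df["time"] < 0).any():
            bad = df.loc[df["time"] < 0, "sample"].iloc[0]
            raise ValueError(f"negative follow-up time for sample {bad!r}")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (death)")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample"])

    def subset(self, sample_ids: Iterable[str]) -> "SurvivalTable":
        keep = set(sample_ids)
        return SurvivalTable(self.data[self.data["sample"].isin(keep)].reset_index(drop=True))


@dataclass
class AssociationRecord:
    """Generic long-format result row shared by the methylation, drug,
    immune and pathway callers."""

    gene: str
    target: str
    statistic: float
    effect: float
    p_value: float
    fdr: float
    n: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    cols = ["gene", "target", "statistic", "effect", "p_value", "fdr", "n"]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.as_dict() for r in records])[cols]


@dataclass
class AnalysisConfig:
    """Analysis thresholds and the gene panel under study."""

    gene_panel: tuple[str, ...] = CORE_CLOCK_GENES
    fdr_threshold: float = 0.05
    log2fc_threshold: float = 1.0
    cnv_display_fraction: float = 0.05
    rhythm_period_hours: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.gene_panel = tuple(str(g) for g in self.gene_panel)
        if not self.gene_panel:
            raise ValueError("gene panel must be non-empty")
        for name in ("fdr_threshold", "log2fc_threshold", "cnv_display_fraction", "rhythm_period_hours"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {**dataclasses.asdict(self), "gene_panel": list(self.gene_panel)},
                fh,
                sort_keys=False,
            )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_NA_VALUES = ["", "NA", "NaN", "nan"]


def read_matrix(path: str | Path, kind: str) -> OmicsMatrix:
    """Read a features x samples TSV into a validated :class:`OmicsMatrix`.

    The first column holds feature IDs, the header row sample IDs.  Empty
    cells, ``NA`` and ``NaN`` parse as missing.  Duplicate IDs and values
    outside the kind's legal range raise :class:`MatrixValidationError`
    naming the offending coordinate.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=_NA_VALUES,
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise MatrixValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return OmicsMatrix(df, kind=kind)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write an :class:`OmicsMatrix` to TSV; missing cells become ``NA``."""
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="feature")


def read_survival(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    return SurvivalTable(df)


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_pathways(path: str | Path) -> list[PathwayDefinition]:
    """Read a pathway-membership TSV with columns pathway, protein, sign."""
    df = pd.read_csv(path, sep="\t", dtype={"pathway": str, "protein": str})
    required = {"pathway", "protein", "sign"}
    if missing := required - set(df.columns):
        raise ValueError(f"pathway file missing columns: {sorted(missing)}")
    out = []
    for name, grp in df.groupby("pathway", sort=False):
        members = tuple((str(r.protein), int(r.sign)) for r in grp.itertuples())
        out.append(PathwayDefinition(str(name), members))
    return out


def write_records(records: Sequence[AssociationRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing p-values (NaN) are excluded from the adjustment and propagate
    as NaN in the output; order matches the input.  Values outside [0, 1]
    raise ``ValueError``.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        valid = p[mask]
        if (valid < 0).any() or (valid > 1).any():
            bad = valid[(valid < 0) | (valid > 1)][0]
            raise ValueError(f"p-value outside [0, 1]: {bad}")
        out[mask] = multipletests(valid, method="fdr_bh")[1]
    return out


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform z = atanh(r).

    Returns signed infinity for |r| = 1 exactly.
    """
    if abs(r) >= 1.0:
        return math.copysign(math.inf, r)
    return math.atanh(r)
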