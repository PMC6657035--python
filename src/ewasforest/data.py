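"""Typed containers for methylation, phenotype, cell-proportion and expression data.

All matrices are stored as pandas DataFrames with samples as rows and
features (CpG probes, expression probes, cell types) as columns.  The
on-disk interchange format is plain tab-delimited text with a header row of
feature ids, the first column holding sample ids, and ``NA`` marking
missing values (chosen for painless round-tripping through R).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import ClassVar

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Clipping bound for methylation proportions.  beta values are clipped into
#: [EPS, 1-EPS] so that the M-transform log2(beta/(1-beta)) stays finite
#: (|M| <= ~19.93) while preserving the ordering of values.
EPS = 1e-6

#: Token written for missing cells.
MISSING_TOKEN = "NA"

#: Cell types of the two supported reference panels, in canonical order.
PANELS: dict[str, tuple[str, ...]] = {
    "adult7": ("CD8T", "CD4T", "NK", "B", "Mono", "Eos", "Gran"),
    "cord7": ("CD8T", "CD4T", "NK", "B", "Mono", "Gran", "nRBC"),
}

#: The cell type whose mean differs between cases and controls in each panel
#: (eosinophilia in adolescent asthma; nucleated red blood cells in cord blood).
SHIFTED_CELL: dict[str, str] = {"adult7": "Eos", "cord7": "nRBC"}

#: Season-of-birth levels; "winter" is the model reference level.
SEASONS: tuple[str, ...] = ("winter", "spring", "summer", "autumn")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups}")


class FeatureMatrix:
    """Base class for sample x feature matrices backed by a float DataFrame."""

    kind: ClassVar[str] = "generic"

    def __init__(self, frame: pd.DataFrame, *, copy: bool = True):
        frame = frame.copy() if copy else frame
        _check_unique(frame.index, "sample_id")
        _check_unique(frame.columns, f"{self.kind} feature id")
        frame = frame.astype(float)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        frame.index.name = "sample_id"
        self.frame = frame
        self._validate()

    def _validate(self) -> None:  # pragma: no cover - overridden
        pass

    # -- axis accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def feature_ids(self) -> list[str]:
        return self.frame.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    @property
    def n_missing(self) -> int:
        return int(self.frame.isna().to_numpy().sum())

    def subset(self, sample_ids=None, feature_ids=None) -> "FeatureMatrix":
        frame = self.frame
        if sample_ids is not None:
            frame = frame.loc[list(sample_ids)]
        if feature_ids is not None:
            frame = frame[list(feature_ids)]
        return type(self)(frame)

    def __repr__(self) -> str:
        n, p = self.shape
        return f"<{type(self).__name__} {n} samples x {p} features>"


class BetaMatrix(FeatureMatrix):
    """Methylation proportions (beta values), strictly inside (0, 1).

    Values outside ``[EPS, 1-EPS]`` are clipped on construction and the
    number of clipped cells is recorded in :attr:`n_clipped`.
    """

    kind = "beta"

    def _validate(self) -> None:
        vals = self.frame.to_numpy()
        with np.errstate(invalid="ignore"):
            outside = (vals < EPS) | (vals > 1.0 - EPS)
        outside &= ~np.isnan(vals)
        self.n_clipped = int(outside.sum())
        if self.n_clipped:
            logger.info("clipped %d beta values into [%g, %g]", self.n_clipped, EPS, 1 - EPS)
            self.frame.iloc[:, :] = np.clip(vals, EPS, 1.0 - EPS)

    @property
    def cpg_ids(self) -> list[str]:
        return self.feature_ids


class MValueMatrix(FeatureMatrix):
    """M-values, the log2-odds of methylation: M = log2(beta / (1 - beta))."""

    kind = "mvalue"

    def _validate(self) -> None:
        vals = self.frame.to_numpy()
        bad = np.isinf(vals)
        if bad.any():
            raise ValueError(f"{int(bad.sum())} non-finite M-values; clip beta upstream")

    @property
    def cpg_ids(self) -> list[str]:
        return self.feature_ids


class ExpressionMatrix(FeatureMatrix):
    """log2-scale expression values (optionally percentile-shift normalized)."""

    kind = "expression"

    @property
    def probe_ids(self) -> list[str]:
        return self.feature_ids


_MATRIX_KINDS: dict[str, type[FeatureMatrix]] = {
    "beta": BetaMatrix,
    "mvalue": MValueMatrix,
    "expression": ExpressionMatrix,
}


def _check_rectangular(path) -> None:
    """Raise on ragged rows (field count differing from the header's)."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise ValueError(f"{path}: empty file")
        n_fields = header.rstrip("\n").count("\t")
        for lineno, line in enumerate(fh, start=2):
            if line.strip() == "":
                continue
            if line.rstrip("\n").count("\t") != n_fields:
                raise ValueError(f"{path}: ragged row at line {lineno}")


def read_matrix(path, kind: str) -> FeatureMatrix:
    """Read a tab-delimited sample x feature matrix.

    Parameters
    ----------
    path : str or Path
        TSV file; first column sample ids, header row feature ids.
    kind : {"beta", "mvalue", "expression"}
        Selects the container (and its validation) for the values.

    Non-numeric cells become missing; beta values outside (0, 1) are
    clipped with a logged count.  Duplicate ids and ragged rows raise.
    """
    if kind not in _MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    _check_rectangular(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    _check_unique(pd.Index(header), f"{kind} feature id")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    _check_unique(raw.index, "sample_id")
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    numeric = numeric.astype(float) if numeric.size else numeric
    return _MATRIX_KINDS[kind](numeric, copy=False)


def write_matrix(matrix: FeatureMatrix, path) -> None:
    """Write a matrix as TSV; round-trips through :func:`read_matrix` losslessly.

    Floats are written with shortest-round-trip repr, missing cells as "NA".
    """
    matrix.frame.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="sample_id")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

_BINARY_COLS = ("asthma", "sex", "atopy", "wheeze_no_cold", "any_wheeze")
_POSITIVE_COLS = ("feno", "fef2575")


class PhenotypeTable:
    """One row per sample: outcome (asthma / infant wheeze) and covariates.

    Required columns: ``asthma`` (current-asthma indicator) and ``sex``
    (female indicator); optional: ``atopy``, ``feno`` (ppb), ``fev1_fvc``,
    ``fef2575`` (L/s), ``wheeze_no_cold``, ``any_wheeze``,
    ``season_of_birth`` and ``cohort_label``.  Binary fields are coded {0,1}.
    """

    REQUIRED = ("asthma", "sex")

    def __init__(self, frame: pd.DataFrame, *, copy: bool = True):
        frame = frame.copy() if copy else frame
        if frame.index.name != "sample_id" and "sample_id" in frame.columns:
            frame = frame.set_index("sample_id")
        frame.index = frame.index.astype(str)
        frame.index.name = "sample_id"
        _check_unique(frame.index, "sample_id")
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"phenotype table lacks required column {col!r}")
        for col in _BINARY_COLS:
            if col in frame.columns:
                vals = pd.to_numeric(frame[col], errors="coerce")
                ok = vals.dropna().isin([0, 1]).all()
                if not ok:
                    raise ValueError(f"column {col!r} must be coded {{0,1}}")
                frame[col] = vals
        if "season_of_birth" in frame.columns:
            bad = set(frame["season_of_birth"].dropna()) - set(SEASONS)
            if bad:
                raise ValueError(f"unknown season_of_birth levels: {sorted(bad)}")
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.index.tolist()

    def subset(self, sample_ids) -> "PhenotypeTable":
        return PhenotypeTable(self.frame.loc[list(sample_ids)])

    def __repr__(self) -> str:
        return f"<PhenotypeTable {len(self.frame)} samples>"


def read_phenotypes(path) -> PhenotypeTable:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN])
    return PhenotypeTable(frame, copy=False)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.frame.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="sample_id")


def summarize_phenotypes(pheno: PhenotypeTable) -> pd.DataFrame:
    """Cohort characteristics overall and by asthma status.

    Returns a tidy frame with one row per (group, variable): sample counts,
    percent female, and for available continuous covariates the group means.
    Percentages are on the 0-100 scale rounded to one decimal, matching
    conventional cohort-description tables.
    """
    frame = pheno.frame
    groups = {
        "overall": frame,
        "asthmatic": frame[frame["asthma"] == 1],
        "non_asthmatic": frame[frame["asthma"] == 0],
    }
    rows = []
    for name, sub in groups.items():
        rows.append({"group": name, "variable": "n", "value": float(len(sub))})
        if len(sub):
            rows.append(
                {
                    "group": name,
                    "variable": "percent_female",
                    "value": round(100.0 * sub["sex"].mean(), 1),
                }
            )
            if "atopy" in sub.columns and sub["atopy"].notna().any():
                rows.append(
                    {
                        "group": name,
                        "variable": "percent_atopy",
                        "value": round(100.0 * sub["atopy"].mean(), 1),
                    }
                )
            for col in ("fev1_fvc", "fef2575", "feno"):
                if col in sub.columns and sub[col].notna().any():
                    rows.append(
                        {"group": name, "variable": f"mean_{col}", "value": float(sub[col].mean())}
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cell proportions
# ---------------------------------------------------------------------------


@dataclass
class CellProportions:
    """Per-sample cell-type fractions (estimated or simulation truth).

    ``frame`` has samples as rows and the panel's cell types as columns.
    Fractions are non-negative; when produced by the constrained
    deconvolution they sum to one within 1e-6 per sample.
    """

    frame: pd.DataFrame
    panel_name: str = "adult7"
    check_sum: bool = field(default=True)

    def __post_init__(self):
        frame = self.frame.copy()
        frame.index = frame.index.astype(str)
        frame.index.name = "sample_id"
        _check_unique(frame.index, "sample_id")
        vals = frame.to_numpy(dtype=float)
        if (vals < -1e-12).any():
            raise ValueError("cell fractions must be non-negative")
        if self.check_sum and len(frame):
            sums = vals.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-6:
                raise ValueError("cell fractions must sum to 1 within 1e-6 per sample")
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def cell_types(self) -> list[str]:
        return self.frame.columns.tolist()

    def subset(self, sample_ids) -> "CellProportions":
        return CellProportions(
            self.frame.loc[list(sample_ids)], panel_name=self.panel_name, check_sum=self.check_sum
        )


def read_proportions(path, panel_name: str = "adult7", check_sum: bool = True) -> CellProportions:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN])
    return CellProportions(frame, panel_name=panel_name, check_sum=check_sum)


def write_proportions(props: CellProportions, path) -> None:
    props.frame.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="sample_id")
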