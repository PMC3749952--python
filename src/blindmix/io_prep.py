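"""Input/output and normalization of expression matrices and reference panels.

The deconvolution model is linear in expression intensities: a mixed sample
is a non-negative combination of purified cell-type signatures.  Everything
downstream therefore assumes non-negative matrices on a common gene universe
with comparable per-column totals.  This module loads tab-delimited (or CSV)
matrices, aligns gene universes, undoes log transforms, and applies the two
normalizations the algorithm expects: joint quantile normalization across
all columns of all matrices, and rescaling of every column to the mean
column total.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "ReferencePanel",
    "PanelConfig",
    "MatrixFormatError",
    "MatrixValidationError",
    "IncompatibleGenesError",
    "load_matrix",
    "write_matrix",
    "load_panel",
    "write_panel",
    "align_genes",
    "joint_quantile_normalize",
    "normalize_column_sums",
    "unlog",
]


class MatrixFormatError(ValueError):
    """Malformed matrix file (missing header, wrong shape)."""


class MatrixValidationError(ValueError):
    """Matrix content violates the model's contracts (negatives, NaN)."""


class IncompatibleGenesError(ValueError):
    """Gene universes of a mixture and a panel do not overlap."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise MatrixValidationError(f"duplicate {what}: {dupes[:5]}")


def _check_values(values: np.ndarray, what: str) -> None:
    if not np.isfinite(values).all():
        raise MatrixValidationError(f"{what} contains NaN or infinite entries")
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise MatrixValidationError(
            f"{what} contains a negative entry at row {i}, column {j}"
        )


@dataclasses.dataclass
class ExpressionMatrix:
    """Non-negative genes x samples matrix with identifiers.

    ``values`` has shape (m, n) where m = len(gene_ids) >= 2 and
    n = len(sample_ids) >= 1.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise MatrixValidationError("expression values must be 2-D")
        m, n = self.values.shape
        if m != len(self.gene_ids) or n != len(self.sample_ids):
            raise MatrixValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if m < 2:
            raise MatrixValidationError("need at least 2 genes")
        if n < 1:
            raise MatrixValidationError("need at least 1 sample")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        _check_values(self.values, "expression matrix")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def replace_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(values, list(self.gene_ids), list(self.sample_ids))


@dataclasses.dataclass
class ReferencePanel:
    """Candidate purified signatures: genes x k_init matrix with labels.

    ``labels`` names each candidate cell type; ``class_of`` optionally groups
    labels into classes (e.g. two B-cell lines under "B cells").  Labels not
    in the map form singleton classes.
    """

    values: np.ndarray
    gene_ids: list[str]
    labels: list[str]
    class_of: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.labels = [str(t) for t in self.labels]
        if self.values.ndim != 2:
            raise MatrixValidationError("panel values must be 2-D")
        m, k = self.values.shape
        if m != len(self.gene_ids) or k != len(self.labels):
            raise MatrixValidationError(
                f"panel shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.labels)} labels"
            )
        if k < 1:
            raise MatrixValidationError("panel needs at least one reference")
        _check_unique(self.labels, "panel labels")
        _check_values(self.values, "reference panel")
        unknown = set(self.class_of) - set(self.labels)
        if unknown:
            raise MatrixValidationError(
                f"class map refers to labels absent from the panel: {sorted(unknown)}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def k_init(self) -> int:
        return self.values.shape[1]

    def class_for(self, label: str) -> str:
        """Class of a label; labels outside the map are their own class."""
        return self.class_of.get(label, label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.labels)

    def replace_values(self, values: np.ndarray) -> "ReferencePanel":
        return ReferencePanel(
            values, list(self.gene_ids), list(self.labels), dict(self.class_of)
        )


@dataclasses.dataclass
class PanelConfig:
    """Run configuration with the published defaults.

    majority_threshold: fraction of restarts in which a cell type must be
        chosen to survive the vote (default 0.70).
    n_runs: number of random restarts voted over (default 10).
    nmf_max_iter / nmf_tol: iteration cap and relative-objective stopping
        tolerance of the factorization.
    epsilon: probability floor applied inside the SKLD so zero expression
        cannot produce infinite divergences.
    unlog_base: if set, inputs are exponentiated (base**x) before analysis,
        undoing a log transform such as RMA's log2.
    quantile_normalize: jointly quantile-normalize mixture and panel before
        deconvolution (default on — required when they come from different
        studies; note it flattens genuine compositional differences between
        samples, so it may be disabled for data already on a common scale).
    """

    majority_threshold: float = 0.70
    n_runs: int = 10
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    epsilon: float = 1e-12
    seed: int = 0
    unlog_base: float | None = None
    quantile_normalize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.majority_threshold <= 1.0:
            raise ValueError("majority_threshold must be in (0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be a positive integer")
        if self.nmf_max_iter < 1:
            raise ValueError("nmf_max_iter must be a positive integer")
        if self.nmf_tol <= 0:
            raise ValueError("nmf_tol must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.unlog_base is not None and self.unlog_base <= 1:
            raise ValueError("unlog_base must be > 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_matrix(path: str | Path, genes_in_rows: bool = True) -> ExpressionMatrix:
    """Load a delimited matrix with gene-id index and sample-id header.

    Duplicated gene rows are collapsed by their arithmetic mean.  Negative
    or non-numeric cells are rejected with the offending position named.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0, header=0)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0 or df.index.isna().any():
        raise MatrixFormatError(f"{path} lacks a valid header/identifier column")
    if not genes_in_rows:
        df = df.T
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise MatrixValidationError(
                f"non-numeric value in column {col!r}, row {df.index[bad][0]!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise MatrixValidationError(f"missing value in column {col!r}, row {row!r}")
    neg = df.lt(0)
    if neg.any().any():
        col = df.columns[neg.any()][0]
        row = df.index[neg[col]][0]
        raise MatrixValidationError(
            f"negative value in column {col!r}, row {row!r}"
        )
    if df.index.duplicated().any():
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(df.to_numpy(float), list(df.index), list(df.columns))


def write_matrix(matrix: ExpressionMatrix | ReferencePanel, path: str | Path) -> None:
    """Write a matrix as delimited text (separator chosen by extension)."""
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep_for(path), float_format="%.10g")


def load_panel(
    path: str | Path, meta_path: str | Path | None = None
) -> ReferencePanel:
    """Load a reference panel matrix plus an optional YAML/JSON sidecar.

    The sidecar may carry ``labels`` (list or column->label map) and
    ``classes`` (label -> class name).  Without a sidecar, column headers
    are the labels and every label is its own class.
    """
    em = load_matrix(path)
    labels = list(em.sample_ids)
    class_of: dict[str, str] = {}
    if meta_path is not None:
        meta_path = Path(meta_path)
        text = meta_path.read_text()
        meta = (
            json.loads(text)
            if meta_path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        ) or {}
        raw_labels = meta.get("labels")
        if isinstance(raw_labels, Mapping):
            labels = [str(raw_labels.get(c, c)) for c in em.sample_ids]
        elif isinstance(raw_labels, Sequence) and not isinstance(raw_labels, str):
            if len(raw_labels) != len(labels):
                raise MatrixFormatError(
                    f"{meta_path}: {len(raw_labels)} labels for {len(labels)} columns"
                )
            labels = [str(x) for x in raw_labels]
        class_of = {str(k): str(v) for k, v in (meta.get("classes") or {}).items()}
    return ReferencePanel(em.values, em.gene_ids, labels, class_of)


def write_panel(panel: ReferencePanel, path: str | Path, meta_path: str | Path) -> None:
    write_matrix(panel, path)
    meta = {"labels": list(panel.labels), "classes": dict(panel.class_of)}
    Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=True))


# ---------------------------------------------------------------------------
# Normalizations
# ---------------------------------------------------------------------------

def align_genes(
    M: ExpressionMatrix, L: ReferencePanel
) -> tuple[ExpressionMatrix, ReferencePanel]:
    """Restrict both matrices to their shared genes, in M's gene order."""
    panel_pos = {g: i for i, g in enumerate(L.gene_ids)}
    shared = [g for g in M.gene_ids if g in panel_pos]
    if not shared:
        raise IncompatibleGenesError(
            "mixture and panel share no gene identifiers"
        )
    m_pos = {g: i for i, g in enumerate(M.gene_ids)}
    m_idx = [m_pos[g] for g in shared]
    l_idx = [panel_pos[g] for g in shared]
    M_out = ExpressionMatrix(M.values[m_idx], shared, list(M.sample_ids))
    L_out = ReferencePanel(
        L.values[l_idx], shared, list(L.labels), dict(L.class_of)
    )
    return M_out, L_out


def _quantile_normalize_columns(X: np.ndarray) -> np.ndarray:
    """Map every column onto the mean sorted profile; ties get the mean of
    the reference values at the tied positions."""
    m, _ = X.shape
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        target = mean_sorted.copy()
        # average the reference profile over runs of tied input values
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [m]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                target[s:e] = target[s:e].mean()
        out[order, j] = target
    return out


def joint_quantile_normalize(
    matrices: Sequence[ExpressionMatrix],
) -> list[ExpressionMatrix]:
    """Quantile-normalize the pooled columns of several matrices jointly.

    All matrices must share an identical gene order; the pooled columns are
    mapped to a common distribution so mixtures and references become
    directly comparable.
    """
    if not matrices:
        raise ValueError("no matrices given")
    ref_genes = matrices[0].gene_ids
    for mat in matrices[1:]:
        if mat.gene_ids != ref_genes:
            raise MatrixValidationError(
                "matrices must share an identical gene order; align first"
            )
    pooled = np.concatenate([mat.values for mat in matrices], axis=1)
    normalized = _quantile_normalize_columns(pooled)
    out: list[ExpressionMatrix] = []
    start = 0
    for mat in matrices:
        stop = start + mat.values.shape[1]
        out.append(mat.replace_values(normalized[:, start:stop]))
        start = stop
    return out


def normalize_column_sums(X: np.ndarray) -> np.ndarray:
    """Rescale every column so its sum equals the mean of all column sums.

    Equalizes per-column totals while preserving each column's shape and
    the total matrix sum.
    """
    X = np.asarray(X, dtype=float)
    sums = X.sum(axis=0)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        raise MatrixValidationError(
            f"column {bad[0]} has non-positive sum; cannot normalize"
        )
    return X * (sums.mean() / sums)


def unlog(M: ExpressionMatrix, base: float) -> ExpressionMatrix:
    """Exponentiate every entry (base**x), undoing a log transform."""
    if base <= 1:
        raise ValueError("unlog base must be > 1")
    return M.replace_values(np.power(float(base), M.values))
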