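"""Per-sample cell-type proportion estimation.

Given the identified signature matrix G_hat, each sample's expression
column is regressed onto the signatures under a non-negativity constraint
(Lawson-Hanson NNLS); the resulting weights are normalized to sum to one so
they read as cell-type fractions.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_prep import ExpressionMatrix

__all__ = ["ProportionEstimate", "nnls_fit", "normalize_proportions"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ProportionEstimate:
    """Cell types x samples fractions; every sample column sums to one."""

    C_hat: np.ndarray
    labels: list[str]
    sample_ids: list[str]
    residual_norm: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Samples in rows, one column per cell type."""
        return pd.DataFrame(
            self.C_hat.T, index=self.sample_ids, columns=self.labels
        )


def nnls_fit(
    G_hat: np.ndarray, M: ExpressionMatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve min_{c>=0} ||m_j - G_hat c||_2 for every sample column m_j.

    Returns the raw weight matrix (k x n) and per-sample residual norms.
    A rank-deficient G_hat is warned about but still solved.
    """
    G_hat = np.asarray(G_hat, float)
    Mv = M.values if isinstance(M, ExpressionMatrix) else np.asarray(M, float)
    if G_hat.ndim != 2 or Mv.ndim != 2 or G_hat.shape[0] != Mv.shape[0]:
        raise ValueError(
            f"signature matrix {G_hat.shape} and mixture {Mv.shape} disagree"
        )
    k = G_hat.shape[1]
    if np.linalg.matrix_rank(G_hat) < k:
        logger.warning(
            "signature matrix is rank-deficient (rank < %d); "
            "proportions may not be unique", k,
        )
    n = Mv.shape[1]
    raw = np.empty((k, n))
    residuals = np.empty(n)
    for j in range(n):
        raw[:, j], residuals[j] = nnls(G_hat, Mv[:, j])
    return raw, residuals


def normalize_proportions(
    raw: np.ndarray,
    labels: list[str],
    sample_ids: list[str],
    residual_norm: np.ndarray | None = None,
) -> ProportionEstimate:
    """Divide every sample's weight vector by its sum."""
    raw = np.asarray(raw, float)
    sums = raw.sum(axis=0)
    bad = np.flatnonzero(~(sums > 0))
    if bad.size:
        raise ValueError(
            f"sample {sample_ids[bad[0]]!r} received zero total weight; "
            f"cannot form proportions"
        )
    if residual_norm is None:
        residual_norm = np.full(raw.shape[1], np.nan)
    return ProportionEstimate(
        C_hat=raw / sums,
        labels=list(labels),
        sample_ids=list(sample_ids),
        residual_norm=np.asarray(residual_norm, float),
    )
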