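"""Comparison baselines and evaluation metrics.

Two deliberately weaker variants isolate the value of the cell-type
determination step:

* ``baseline_nmf_no_determination`` — factorization exactly as the main
  pipeline, but the NNLS fit uses ALL k_init factor columns: no SKLD
  selection, no majority voting.  Factor identities are assigned post hoc
  by best Pearson correlation to the panel columns.  With an over-complete
  panel this over-fits: decoy factors soak up real proportion mass.
* ``baseline_nnls_only`` — no factorization at all; the (normalized)
  reference panel itself is taken as the signature matrix and proportions
  come straight from NNLS.

``evaluate`` scores any estimate against a synthetic ground truth using the
benchmark's headline metric — the average absolute proportion error in
percentage points — plus per-cell-type correlations, a pairwise SKLD table
between estimated and true signatures, and label accuracy (true types
identified, decoys rejected).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .factorization import init_factors, nmf_factorize
from .identification import skld_matrix
from .io_prep import (
    ExpressionMatrix,
    PanelConfig,
    ReferencePanel,
    align_genes,
    joint_quantile_normalize,
    normalize_column_sums,
    unlog,
)
from .pipeline import DeconvolutionResult
from .proportions import ProportionEstimate, nnls_fit, normalize_proportions
from .synthetic import SyntheticScenario

__all__ = [
    "EvaluationReport",
    "baseline_nmf_no_determination",
    "baseline_nnls_only",
    "evaluate",
]


def _preprocess(
    M: ExpressionMatrix,
    panel: ReferencePanel,
    unlog_base: float | None = None,
    quantile_normalize: bool = True,
) -> tuple[ExpressionMatrix, ReferencePanel]:
    """The pipeline's normalization chain, shared so comparisons are fair."""
    M_aligned, panel_aligned = align_genes(M, panel)
    if unlog_base is not None:
        M_aligned = unlog(M_aligned, unlog_base)
        panel_aligned = panel_aligned.replace_values(
            np.power(float(unlog_base), panel_aligned.values)
        )
    if quantile_normalize:
        M_aligned, panel_aligned = joint_quantile_normalize(
            [M_aligned, panel_aligned]
        )
    return (
        M_aligned.replace_values(normalize_column_sums(M_aligned.values)),
        panel_aligned.replace_values(
            normalize_column_sums(panel_aligned.values)
        ),
    )


def baseline_nmf_no_determination(
    M: ExpressionMatrix,
    panel: ReferencePanel,
    config: PanelConfig | None = None,
) -> tuple[np.ndarray, list[str], ProportionEstimate]:
    """NMF as in the main pipeline but skipping the determination step.

    Returns the full k_init-column signature matrix, its post-hoc labels
    (best panel correlation per factor), and per-sample proportions over
    all k_init candidates.
    """
    config = config or PanelConfig()
    M_norm, panel_norm = _preprocess(
        M, panel, config.unlog_base, config.quantile_normalize
    )
    state = init_factors(M_norm, panel_norm, rng_seed=config.seed + 1)
    state = nmf_factorize(
        state, M_norm, max_iter=config.nmf_max_iter, tol=config.nmf_tol
    )
    corr = np.corrcoef(state.W.T, panel_norm.values.T)[
        : panel_norm.k_init, panel_norm.k_init:
    ]
    labels = [panel_norm.labels[int(np.argmax(corr[j]))] for j in range(corr.shape[0])]
    raw, residuals = nnls_fit(state.W, M_norm)
    proportions = normalize_proportions(raw, labels, M_norm.sample_ids, residuals)
    return state.W, labels, proportions


def baseline_nnls_only(
    M: ExpressionMatrix,
    panel: ReferencePanel,
    unlog_base: float | None = None,
    quantile_normalize: bool = True,
) -> ProportionEstimate:
    """NNLS of the mixture directly against the reference panel.

    No factorization: the panel columns themselves, after the shared
    normalization chain and rescaled to sum to one, serve as the signature
    matrix.  With off-study references and decoys this over-fits — the
    references are never advanced toward the data.
    """
    M_norm, panel_norm = _preprocess(M, panel, unlog_base, quantile_normalize)
    signatures = panel_norm.values / panel_norm.values.sum(axis=0)
    raw, residuals = nnls_fit(signatures, M_norm)
    return normalize_proportions(
        raw, panel_norm.labels, M_norm.sample_ids, residuals
    )


@dataclasses.dataclass
class EvaluationReport:
    """Benchmark scores of an estimate against synthetic ground truth."""

    mean_abs_error_pct: float
    sd_abs_error_pct: float
    per_celltype_correlation: dict[str, float]
    signature_correlation: dict[str, float]
    skld_table: np.ndarray | None
    label_accuracy: float
    matched_labels: list[str]


def _aggregate_truth(
    scenario: SyntheticScenario,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Collapse true proportions/signatures to class-level entities.

    When the scenario's panel groups true labels into classes, the truth a
    class-level estimate should match is the SUM of member proportions and
    the mean of member signatures.
    """
    class_of = scenario.panel.class_of
    entities: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, label in enumerate(scenario.true_labels):
        ent = class_of.get(label, label)
        if ent not in groups:
            groups[ent] = []
            entities.append(ent)
        groups[ent].append(i)
    C = np.vstack([scenario.C_true[groups[e]].sum(axis=0) for e in entities])
    G = np.column_stack(
        [scenario.G_true[:, groups[e]].mean(axis=1) for e in entities]
    )
    return entities, C, G


def evaluate(
    estimate: DeconvolutionResult | ProportionEstimate,
    truth: SyntheticScenario,
) -> EvaluationReport:
    """Score estimated proportions (and signatures, if present) vs truth.

    Labels are matched by exact name (class names count as names).  A true
    cell type with no matching estimated label contributes its full
    proportion as error; estimated labels that match nothing true are
    decoys kept, penalized through ``label_accuracy``.
    """
    if isinstance(estimate, DeconvolutionResult):
        prop = estimate.proportions
        G_est = estimate.identification.G_hat
    else:
        prop = estimate
        G_est = None
    entities, C_truth, G_truth = _aggregate_truth(truth)
    est_index = {label: i for i, label in enumerate(prop.labels)}
    matched = [e for e in entities if e in est_index]
    if not matched:
        raise ValueError(
            f"no overlap between estimated labels {prop.labels} and "
            f"true entities {entities}"
        )
    n = C_truth.shape[1]
    if prop.C_hat.shape[1] != n:
        raise ValueError("estimate and truth have different sample counts")

    # estimated proportion for each true entity (0 when absent)
    C_est = np.zeros_like(C_truth)
    for i, ent in enumerate(entities):
        if ent in est_index:
            C_est[i] = prop.C_hat[est_index[ent]]
    abs_err = np.abs(C_est - C_truth) * 100.0
    mean_err = float(abs_err.mean())
    sd_err = float(abs_err.std())

    per_ct_corr: dict[str, float] = {}
    for i, ent in enumerate(entities):
        if n >= 2 and np.std(C_truth[i]) > 0 and np.std(C_est[i]) > 0:
            per_ct_corr[ent] = float(np.corrcoef(C_est[i], C_truth[i])[0, 1])
        else:
            per_ct_corr[ent] = float("nan")

    sig_corr: dict[str, float] = {}
    skld_table = None
    if G_est is not None:
        for i, ent in enumerate(entities):
            if ent in est_index and est_index[ent] < G_est.shape[1]:
                g = G_est[:, est_index[ent]]
                sig_corr[ent] = float(np.corrcoef(g, G_truth[:, i])[0, 1])
        skld_table = skld_matrix(G_est, G_truth)

    decoys = set(truth.decoy_labels)
    decoy_classes = {truth.panel.class_of.get(d, d) for d in decoys}
    true_found = sum(1 for e in entities if e in est_index)
    decoys_rejected = sum(1 for d in decoy_classes if d not in prop.labels)
    denom = len(entities) + len(decoy_classes)
    label_accuracy = (true_found + decoys_rejected) / denom if denom else 1.0

    return EvaluationReport(
        mean_abs_error_pct=mean_err,
        sd_abs_error_pct=sd_err,
        per_celltype_correlation=per_ct_corr,
        signature_correlation=sig_corr,
        skld_table=skld_table,
        label_accuracy=label_accuracy,
        matched_labels=matched,
    )
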