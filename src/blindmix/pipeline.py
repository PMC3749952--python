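"""End-to-end blind deconvolution orchestration.

Runs the full method in order: gene alignment, optional un-logging, joint
quantile normalization of mixture and panel, column-sum normalization,
``n_runs`` random-restart factorizations each followed by SKLD reference
matching and class collapsing, a majority vote over the restarts, and a
final NNLS proportion fit against the consensus signatures.  The NNLS is
run on the same normalized mixture the signatures were learned from, so
residuals are meaningful.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .factorization import init_factors, nmf_factorize
from .identification import (
    IdentificationResult,
    assign_references,
    collapse_classes,
    majority_vote,
)
from .io_prep import (
    ExpressionMatrix,
    PanelConfig,
    ReferencePanel,
    align_genes,
    joint_quantile_normalize,
    normalize_column_sums,
    unlog,
)
from .proportions import ProportionEstimate, nnls_fit, normalize_proportions

__all__ = ["DeconvolutionResult", "run_deconvolution", "save_result"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class DeconvolutionResult:
    """Composite output: identities, signatures, proportions, provenance."""

    identification: IdentificationResult
    proportions: ProportionEstimate
    config_used: PanelConfig
    provenance: dict


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def run_deconvolution(
    M: ExpressionMatrix,
    panel: ReferencePanel,
    config: PanelConfig | None = None,
) -> DeconvolutionResult:
    """Blind deconvolution of a mixed expression matrix.

    Determines which of the panel's candidate cell types are present, their
    consensus signatures, and their per-sample proportions.
    """
    config = config or PanelConfig()
    t0 = time.perf_counter()
    M_aligned, panel_aligned = align_genes(M, panel)
    logger.info(
        "aligned gene universe: %d shared genes, %d samples, %d candidates",
        M_aligned.n_genes, M_aligned.n_samples, panel_aligned.k_init,
    )
    if config.unlog_base is not None:
        M_aligned = unlog(M_aligned, config.unlog_base)
        panel_aligned = panel_aligned.replace_values(
            np.power(float(config.unlog_base), panel_aligned.values)
        )
    if config.quantile_normalize:
        M_aligned, panel_aligned = joint_quantile_normalize(
            [M_aligned, panel_aligned]
        )
    M_norm = M_aligned.replace_values(normalize_column_sums(M_aligned.values))
    panel_norm = panel_aligned.replace_values(
        normalize_column_sums(panel_aligned.values)
    )

    per_run: list[tuple[np.ndarray, list[str]]] = []
    assignments = []
    objective_minima = []
    for r in range(1, config.n_runs + 1):
        state = init_factors(M_norm, panel_norm, rng_seed=config.seed + r)
        state = nmf_factorize(
            state, M_norm, max_iter=config.nmf_max_iter, tol=config.nmf_tol
        )
        assignment = assign_references(state.W, panel_norm, config.epsilon)
        G_run, labels_run = collapse_classes(
            assignment, state.W, panel_norm.class_of
        )
        per_run.append((G_run, labels_run))
        assignments.append(assignment)
        objective_minima.append(state.objective_trace[-1])
        logger.info(
            "run %d/%d: %d iterations, objective %.6g, chose %s",
            r, config.n_runs, state.iterations_run,
            state.objective_trace[-1], labels_run,
        )

    identification = majority_vote(per_run, config.majority_threshold)
    identification.per_run_assignments = assignments
    logger.info(
        "majority vote retained %d cell type(s): %s (frequencies %s)",
        identification.k_t_hat, identification.labels,
        {k: round(v, 3) for k, v in identification.selection_frequency.items()},
    )
    if identification.k_t_hat == panel_norm.k_init:
        logger.warning(
            "every candidate in the panel was retained (k_hat = k_init = %d); "
            "a cell type present in the mixture but missing from the panel "
            "would not be detected", panel_norm.k_init,
        )

    raw, residuals = nnls_fit(identification.G_hat, M_norm)
    proportions = normalize_proportions(
        raw, identification.labels, M_norm.sample_ids, residuals
    )
    logger.debug("deconvolution finished in %.2f s", time.perf_counter() - t0)

    provenance = {
        "mixture_sha256": _sha256(M.values),
        "panel_sha256": _sha256(panel.values),
        "seed": config.seed,
        "n_shared_genes": M_aligned.n_genes,
        "gene_ids": list(M_aligned.gene_ids),
        "class_of": dict(panel_norm.class_of),
        "per_run_objective_minimum": [float(x) for x in objective_minima],
    }
    return DeconvolutionResult(
        identification=identification,
        proportions=proportions,
        config_used=config,
        provenance=provenance,
    )


def save_result(
    result: DeconvolutionResult,
    outdir: str | Path,
    gene_ids: list[str] | None = None,
) -> None:
    """Write proportions.tsv, signatures.tsv, identification_report.tsv
    and config.yaml into ``outdir``.  All output is deterministic."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.proportions.to_frame().to_csv(
        outdir / "proportions.tsv", sep="\t", float_format="%.6f"
    )
    ident = result.identification
    if gene_ids is None:
        gene_ids = result.provenance.get("gene_ids")
    index = gene_ids if gene_ids is not None else [
        f"g{i + 1}" for i in range(ident.G_hat.shape[0])
    ]
    pd.DataFrame(ident.G_hat, index=index, columns=ident.labels).to_csv(
        outdir / "signatures.tsv", sep="\t", float_format="%.10g"
    )
    rows = []
    class_of = result.provenance.get("class_of", {})
    mean_d: dict[str, list[float]] = {}
    for a in ident.per_run_assignments:
        for ref_label, d in a.distance.items():
            # voting happens on class labels; pool members' distances
            mean_d.setdefault(class_of.get(ref_label, ref_label), []).append(d)
    for label, freq in ident.selection_frequency.items():
        rows.append(
            {
                "label": label,
                "retained": label in ident.labels,
                "selection_frequency": round(freq, 6),
                "mean_skld_to_nearest_factor": (
                    round(float(np.mean(mean_d[label])), 10)
                    if label in mean_d else float("nan")
                ),
            }
        )
    pd.DataFrame(rows).to_csv(
        outdir / "identification_report.tsv", sep="\t", index=False
    )
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(result.config_used.to_dict(), sort_keys=True)
    )
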