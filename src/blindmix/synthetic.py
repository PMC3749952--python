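"""Synthetic mixture scenarios with known ground truth.

Emulates the controlled-mixture benchmark design: a small set of true
cell-type signatures is mixed in known per-sample proportions, measured
with multiplicative log-normal noise, and offered to the algorithm through
an over-complete reference panel containing perturbed copies of the truths
("off-study" references) plus decoy cell types that are not in the mixture
at all.  Decoys come from the same generative family as the truths, so
rejecting them is a real test of the identification step.

Default parameters define the standard noisy benchmark regime used across
the test-suite and the acceptance script: 500 genes, 3 true cell types,
3 decoys, 30 samples, reference noise sd 0.1 and measurement noise sd 0.05
on the natural-log scale.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .io_prep import (
    ExpressionMatrix,
    ReferencePanel,
    normalize_column_sums,
    write_matrix,
    write_panel,
)

__all__ = [
    "SyntheticScenario",
    "make_signatures",
    "make_proportions",
    "mix_and_perturb",
    "make_scenario",
    "save_scenario",
]

# log-scale geometry of the signature generator
BASELINE_LOG_MEAN = 6.0    # overall abundance level of a gene
BASELINE_LOG_SD = 1.0      # spread of abundance across genes
TYPE_LOG_SD = 0.3          # non-marker cell-type-specific wiggle
MARKER_BOOST = 1.5         # log-fold elevation of a marker in its own type
MARKER_SUPPRESS = 0.5      # log-fold suppression of a marker elsewhere
DECOY_RHO = 0.7            # correlation of a decoy's profile with its sibling type
MARKER_SHARE = 0.7         # fraction of the marker contrast a decoy shares


@dataclasses.dataclass
class SyntheticScenario:
    """Ground truth plus the observable inputs derived from it."""

    G_true: np.ndarray
    C_true: np.ndarray
    M: ExpressionMatrix
    panel: ReferencePanel
    true_labels: list[str]
    decoy_labels: list[str]
    ref_noise_sd: float
    meas_noise_sd: float
    seed: int


def make_signatures(
    m: int,
    k_true: int,
    k_decoy: int,
    seed: int,
    marker_fraction: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw true and decoy signatures as exponentiated Gaussian profiles.

    Each gene has a shared baseline log-expression plus a per-type
    deviation.  A ``marker_fraction`` of genes are designated
    cell-type-specific markers, elevated in their own type and suppressed
    elsewhere — the dial that controls how separable (in SKLD) the
    signatures are.  Decoys come from the same family but, as with real
    tissue panels, are not independent of the mixture's cell types: each
    decoy's deviation profile is correlated (``DECOY_RHO``) with a
    "sibling" true type and it expresses the sibling's markers at an
    intermediate level (``MARKER_SHARE`` of the full contrast), the way
    related tissues share transcriptional programs.
    """
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    if not 0.0 <= marker_fraction <= 1.0:
        raise ValueError("marker_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k_all = k_true + k_decoy
    baseline = rng.normal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, size=m)
    dev = rng.normal(0.0, TYPE_LOG_SD, size=(m, k_all))
    sibling = [t % k_true for t in range(k_decoy)]
    for t in range(k_decoy):
        dev[:, k_true + t] = (
            DECOY_RHO * dev[:, sibling[t]]
            + np.sqrt(1.0 - DECOY_RHO ** 2) * dev[:, k_true + t]
        )
    log_expr = baseline[:, None] + dev
    n_markers = int(round(marker_fraction * m))
    marker_genes = rng.choice(m, size=n_markers, replace=False)
    owners = rng.integers(0, k_all, size=n_markers)
    contrast = MARKER_SUPPRESS + MARKER_BOOST
    for g, t in zip(marker_genes, owners):
        log_expr[g, :] -= MARKER_SUPPRESS
        log_expr[g, t] += contrast
        if t < k_true:
            for d in range(k_decoy):
                if sibling[d] == t:
                    log_expr[g, k_true + d] += MARKER_SHARE * contrast
    # equal column totals: mixtures are made by combining equal amounts of
    # RNA, so per-unit signatures carry the same total intensity — this is
    # also what makes the proportion matrix well-defined
    G_all = normalize_column_sums(np.exp(log_expr))
    return G_all[:, :k_true], G_all[:, k_true:]


def make_proportions(
    k_true: int, n: int, concentration: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Sample column-stochastic proportions from a symmetric Dirichlet."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(k_true, concentration), size=n).T


def mix_and_perturb(
    G_true: np.ndarray,
    C_true: np.ndarray,
    decoys: np.ndarray,
    ref_noise_sd: float,
    meas_noise_sd: float,
    seed: int,
) -> SyntheticScenario:
    """Form the observed mixture and the noisy over-complete panel.

    M = (G_true C_true) * exp(N(0, meas_noise_sd^2)) elementwise; the panel
    holds each true signature perturbed by exp(N(0, ref_noise_sd^2)) — an
    "off-study" reference — plus the decoys.
    """
    if ref_noise_sd < 0 or meas_noise_sd < 0:
        raise ValueError("noise standard deviations must be >= 0")
    G_true = np.asarray(G_true, float)
    C_true = np.asarray(C_true, float)
    decoys = np.asarray(decoys, float)
    m, k_true = G_true.shape
    n = C_true.shape[1]
    rng = np.random.default_rng(seed)
    clean = G_true @ C_true
    M_vals = clean * np.exp(rng.normal(0.0, meas_noise_sd, size=clean.shape)) \
        if meas_noise_sd > 0 else clean
    refs = G_true * np.exp(rng.normal(0.0, ref_noise_sd, size=G_true.shape)) \
        if ref_noise_sd > 0 else G_true.copy()
    panel_vals = np.concatenate([refs, decoys], axis=1) if decoys.size else refs
    gene_ids = [f"g{i + 1:05d}" for i in range(m)]
    sample_ids = [f"s{j + 1:03d}" for j in range(n)]
    true_labels = [f"celltype_{t + 1}" for t in range(k_true)]
    decoy_labels = [f"decoy_{t + 1}" for t in range(decoys.shape[1] if decoys.size else 0)]
    return SyntheticScenario(
        G_true=G_true,
        C_true=C_true,
        M=ExpressionMatrix(M_vals, gene_ids, sample_ids),
        panel=ReferencePanel(panel_vals, gene_ids, true_labels + decoy_labels),
        true_labels=true_labels,
        decoy_labels=decoy_labels,
        ref_noise_sd=ref_noise_sd,
        meas_noise_sd=meas_noise_sd,
        seed=seed,
    )


def make_scenario(
    m: int = 500,
    k_true: int = 3,
    k_decoy: int = 3,
    n: int = 30,
    ref_noise_sd: float = 0.1,
    meas_noise_sd: float = 0.05,
    concentration: float = 1.0,
    marker_fraction: float = 0.2,
    seed: int = 0,
) -> SyntheticScenario:
    """One-call scenario builder; defaults are the standard benchmark regime."""
    G_true, decoys = make_signatures(
        m, k_true, k_decoy, seed=seed, marker_fraction=marker_fraction
    )
    C_true = make_proportions(k_true, n, concentration=concentration, seed=seed + 1)
    return mix_and_perturb(
        G_true, C_true, decoys, ref_noise_sd, meas_noise_sd, seed=seed + 2
    )


def save_scenario(scenario: SyntheticScenario, outdir: str | Path) -> None:
    """Write mixture.tsv, panel.tsv, panel.yaml, truth_G.tsv, truth_C.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(scenario.M, outdir / "mixture.tsv")
    write_panel(scenario.panel, outdir / "panel.tsv", outdir / "panel.yaml")
    gene_ids = scenario.M.gene_ids
    write_matrix(
        ExpressionMatrix(scenario.G_true, gene_ids, scenario.true_labels),
        outdir / "truth_G.tsv",
    )
    pd.DataFrame(
        scenario.C_true, index=scenario.true_labels, columns=scenario.M.sample_ids
    ).to_csv(outdir / "truth_C.tsv", sep="\t", float_format="%.10g")
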