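"""Cell-type number/identity determination and majority voting.

After factorization, each reference signature is matched to its nearest
learned factor under the symmetric Kullback-Leibler divergence (SKLD).
The distinct set of winning factors determines how many cell types are
actually present (k_hat <= k_init); factors no reference points to are
dropped, which is how decoy references get rejected.  Classes collapse
near-equivalent references (e.g. two B-cell lines) into one labeled
signature, and majority voting over random restarts keeps only cell types
selected in at least a threshold fraction of runs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_prep import ReferencePanel

__all__ = [
    "ReferenceAssignment",
    "IdentificationResult",
    "NoCellTypesError",
    "skld",
    "skld_matrix",
    "assign_references",
    "collapse_classes",
    "majority_vote",
]

DEFAULT_EPSILON = 1e-12


class NoCellTypesError(ValueError):
    """No cell type reached the majority-voting threshold."""


def _to_probability(v: np.ndarray, epsilon: float, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if (v < 0).any():
        raise ValueError(f"{name} has negative entries")
    total = v.sum()
    if not total > 0:
        raise ValueError(f"{name} has zero sum; cannot normalize to a distribution")
    p = np.maximum(v / total, epsilon)
    return p / p.sum()


def skld(w: np.ndarray, d: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> float:
    """Symmetric Kullback-Leibler divergence between two signatures.

    Both vectors are normalized to probability distributions, floored at
    ``epsilon`` and renormalized, then scored as

        sum_i (p_i - q_i) (ln p_i - ln q_i)  =  KL(p||q) + KL(q||p).

    Symmetric, non-negative, and zero exactly when the normalized vectors
    coincide.
    """
    w = np.asarray(w, float).ravel()
    d = np.asarray(d, float).ravel()
    if w.shape != d.shape:
        raise ValueError(f"length mismatch: {w.size} vs {d.size}")
    p = _to_probability(w, epsilon, "first signature")
    q = _to_probability(d, epsilon, "second signature")
    return float(np.sum((p - q) * (np.log(p) - np.log(q))))


def skld_matrix(
    A: np.ndarray, B: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Pairwise SKLD between the columns of A and the columns of B."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    out = np.empty((A.shape[1], B.shape[1]))
    for i in range(A.shape[1]):
        for j in range(B.shape[1]):
            out[i, j] = skld(A[:, i], B[:, j], epsilon)
    return out


@dataclasses.dataclass
class ReferenceAssignment:
    """Mapping of every reference label to its nearest factor column.

    ``nearest_column[label]`` is the winning W column index,
    ``distance[label]`` its SKLD.  ``chosen_columns`` lists the distinct
    winners in ascending index order and ``column_labels`` the reference
    label that names each chosen column (the one at minimal SKLD when
    several references share a winner).
    """

    nearest_column: dict[str, int]
    distance: dict[str, float]
    chosen_columns: list[int]
    column_labels: list[str]

    @property
    def k_hat(self) -> int:
        return len(self.chosen_columns)


def assign_references(
    W: np.ndarray, L: ReferencePanel, epsilon: float = DEFAULT_EPSILON
) -> ReferenceAssignment:
    """Match every reference to its nearest factor; drop unchosen factors.

    Ties (exactly equal SKLD) break to the lower column index for winners
    and to the lower panel index for labels, so the result is deterministic.
    """
    W = np.asarray(W, float)
    if W.shape[0] != L.n_genes:
        raise ValueError("W and panel are not gene-aligned")
    D = skld_matrix(L.values, W, epsilon)  # refs x factors
    winners = D.argmin(axis=1)
    nearest = {lab: int(winners[i]) for i, lab in enumerate(L.labels)}
    dist = {lab: float(D[i, winners[i]]) for i, lab in enumerate(L.labels)}
    chosen = sorted(set(int(j) for j in winners))
    labels: list[str] = []
    for j in chosen:
        claimants = [i for i in range(L.k_init) if winners[i] == j]
        best = min(claimants, key=lambda i: (D[i, j], i))
        labels.append(L.labels[best])
    return ReferenceAssignment(
        nearest_column=nearest,
        distance=dist,
        chosen_columns=chosen,
        column_labels=labels,
    )


def collapse_classes(
    assignment: ReferenceAssignment,
    W: np.ndarray,
    class_of: dict[str, str],
) -> tuple[np.ndarray, list[str]]:
    """Average chosen columns whose winning labels share a class.

    Assignment is computed label-wise first; collapsing happens afterwards.
    Singleton classes pass through.  Output columns are renormalized to sum
    to one and carry the class name (or the label itself for singletons).
    """
    W = np.asarray(W, float)
    groups: dict[str, list[int]] = {}
    order: list[str] = []
    for col, label in zip(assignment.chosen_columns, assignment.column_labels):
        cls = class_of.get(label, label)
        if cls not in groups:
            groups[cls] = []
            order.append(cls)
        groups[cls].append(col)
    columns = []
    for cls in order:
        avg = W[:, groups[cls]].mean(axis=1)
        total = avg.sum()
        if not total > 0:
            raise ValueError(f"class {cls!r} collapsed to an all-zero signature")
        columns.append(avg / total)
    return np.column_stack(columns), order


@dataclasses.dataclass
class IdentificationResult:
    """Consensus of the per-restart identifications.

    ``G_hat`` holds one signature column per retained label (columns sum to
    one); ``selection_frequency`` records, for every label ever chosen, the
    fraction of restarts in which it was chosen.
    """

    G_hat: np.ndarray
    labels: list[str]
    k_t_hat: int
    selection_frequency: dict[str, float]
    per_run_assignments: list[ReferenceAssignment] = dataclasses.field(
        default_factory=list
    )


def majority_vote(
    per_run: list[tuple[np.ndarray, list[str]]],
    threshold: float,
) -> IdentificationResult:
    """Retain labels chosen in at least ``threshold`` fraction of runs.

    The final signature of a retained label is the entry-wise mean of its
    per-run signatures over the runs in which it was chosen, renormalized
    to sum to one.  Raises :class:`NoCellTypesError` when nothing survives.
    """
    if not per_run:
        raise ValueError("majority_vote requires at least one run")
    n_runs = len(per_run)
    n_genes = np.asarray(per_run[0][0]).shape[0]
    counts: dict[str, int] = {}
    sums: dict[str, np.ndarray] = {}
    order: list[str] = []
    for G, labels in per_run:
        G = np.asarray(G, float)
        if G.shape[0] != n_genes:
            raise ValueError("runs are not gene-aligned")
        for j, label in enumerate(labels):
            if label not in counts:
                counts[label] = 0
                sums[label] = np.zeros(n_genes)
                order.append(label)
            counts[label] += 1
            sums[label] += G[:, j]
    frequency = {label: counts[label] / n_runs for label in order}
    retained = [label for label in order if frequency[label] >= threshold]
    if not retained:
        best = max(frequency.values())
        raise NoCellTypesError(
            f"no cell type reached the majority-voting threshold "
            f"{threshold:.2f} (best frequency {best:.2f}); lower the "
            f"threshold, add runs, or revise the reference panel"
        )
    columns = []
    for label in retained:
        mean_sig = sums[label] / counts[label]
        columns.append(mean_sig / mean_sig.sum())
    return IdentificationResult(
        G_hat=np.column_stack(columns),
        labels=retained,
        k_t_hat=len(retained),
        selection_frequency=frequency,
    )
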