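"""Semi-supervised non-negative matrix factorization.

The mixture matrix M (genes x samples) is factored as M ~ W H, where the
columns of W are candidate cell-type signatures and H holds per-sample
mixing weights.  W is initialized from the reference panel — this is what
makes the factorization "semi-supervised" and lets the later matching step
name the factors — while H starts from seeded uniform noise.  The Frobenius
reconstruction error is minimized by multiplicative updates

    H <- H * (W'M) / (W'WH + delta)
    W <- W * (MH') / (WHH' + delta)

followed, each iteration, by rescaling the columns of W to sum to one with
the compensating inverse rescale of the rows of H, so the product WH (and
hence the objective) is unchanged by the rescale.  Multiplicative updates
never leave the non-negative orthant and are monotone in the objective.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_prep import ExpressionMatrix, ReferencePanel

__all__ = [
    "FactorizationState",
    "IdentifiabilityError",
    "NumericalError",
    "init_factors",
    "nmf_factorize",
    "frobenius_objective",
]

#: division guard; also the floor applied to exact zeros of the initial W,
#: which multiplicative updates could otherwise never revise.
DELTA = 1e-12


class IdentifiabilityError(ValueError):
    """Raised when k_init >= n, where the factorization has no unique solution."""


class NumericalError(ArithmeticError):
    """NaN or infinity appeared during the multiplicative updates."""


@dataclasses.dataclass
class FactorizationState:
    """Factors and objective history of one (partial) NMF run."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: list[float]
    iterations_run: int = 0
    converged: bool = False


def frobenius_objective(M: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    return float(np.linalg.norm(M - W @ H, "fro"))


def _as_values(M: ExpressionMatrix | np.ndarray) -> np.ndarray:
    return M.values if isinstance(M, ExpressionMatrix) else np.asarray(M, float)


def init_factors(
    M: ExpressionMatrix | np.ndarray,
    L: ReferencePanel,
    rng_seed: int,
) -> FactorizationState:
    """Build the starting point: W from the panel, H from seeded uniforms.

    Requires k_init < n: with as many candidate signatures as samples the
    mixing weights are not uniquely determined.
    """
    Mv = _as_values(M)
    if isinstance(M, ExpressionMatrix) and M.gene_ids != L.gene_ids:
        raise ValueError("mixture and panel are not gene-aligned")
    m, n = Mv.shape
    if L.n_genes != m:
        raise ValueError(f"panel has {L.n_genes} genes, mixture has {m}")
    k_init = L.k_init
    if k_init >= n:
        raise IdentifiabilityError(
            f"k_init={k_init} must be smaller than the number of samples "
            f"n={n} for the factorization to have a unique solution"
        )
    W = np.maximum(L.values, DELTA)
    W = W / W.sum(axis=0)
    rng = np.random.default_rng(rng_seed)
    H = rng.uniform(0.0, 1.0, size=(k_init, n))
    return FactorizationState(
        W=W, H=H, objective_trace=[frobenius_objective(Mv, W, H)]
    )


def nmf_factorize(
    state: FactorizationState,
    M: ExpressionMatrix | np.ndarray,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> FactorizationState:
    """Run multiplicative updates until convergence or the iteration cap.

    Stops when the relative change of the Frobenius objective falls below
    ``tol``.  Returns a new state; the input state is not modified.
    """
    Mv = _as_values(M)
    W = state.W.copy()
    H = state.H.copy()
    if W.shape[0] != Mv.shape[0] or H.shape[1] != Mv.shape[1]:
        raise ValueError(
            f"factor shapes {W.shape}x{H.shape} inconsistent with M {Mv.shape}"
        )
    trace = list(state.objective_trace)
    prev = trace[-1] if trace else frobenius_objective(Mv, W, H)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ Mv) / (W.T @ W @ H + DELTA)
        W *= (Mv @ H.T) / (W @ (H @ H.T) + DELTA)
        scale = W.sum(axis=0)
        W /= scale
        H *= scale[:, None]
        if not (np.isfinite(W).all() and np.isfinite(H).all()):
            raise NumericalError(f"non-finite factor entries at iteration {it}")
        obj = frobenius_objective(Mv, W, H)
        trace.append(obj)
        if prev > 0 and abs(prev - obj) / prev < tol:
            converged = True
            break
        if prev == 0.0 and obj == 0.0:
            converged = True
            break
        prev = obj
    return FactorizationState(
        W=W,
        H=H,
        objective_trace=trace,
        iterations_run=state.iterations_run + it,
        converged=converged,
    )
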