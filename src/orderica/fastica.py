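"""One restart of the kurtosis fixed-point iteration under deflation.

Each restart runs the cubic (kurtosis-based) FastICA update

    w  <-  X (y o y o y)^T / M  -  3 w,      y = w^T X,

followed by projection off the span of previously accepted rows
(Gram-Schmidt deflation) and renormalization. A restart converges when the
direction is fixed up to sign: min(||w - w_prev||, ||w + w_prev||) <= eps.
Sign flips are inherent to the cubic update, so the raw norm test is applied
to both signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import as_array

__all__ = [
    "CandidateResult",
    "DeflationProjector",
    "DegenerateDirectionError",
    "estimate_kurtosis",
    "fastica_candidate",
]

#: Post-deflation norm below which an initial direction is considered to lie
#: inside the deflation subspace and must be resampled by the caller.
DEGENERATE_TOLERANCE = 1e-12


class DegenerateDirectionError(ValueError):
    """The direction collapsed into the deflation subspace.

    Distinct from non-convergence: the caller should resample the initial
    direction rather than treat the restart as a failed fixed-point search.
    """


@dataclass(frozen=True)
class CandidateResult:
    """Outcome of a single FastICA restart.

    Attributes
    ----------
    w : unit direction in the whitened space (length N)
    y : recovered row, ``w @ X_white`` (length M)
    alpha : estimated excess kurtosis of ``y``
    converged : whether the sign-invariant stopping rule fired within k_max
    iterations : number of full update cycles performed
    """

    w: np.ndarray
    y: np.ndarray
    alpha: float
    converged: bool
    iterations: int


@dataclass(frozen=True)
class DeflationProjector:
    """Symmetric idempotent projector onto the span of accepted rows."""

    matrix: np.ndarray

    @classmethod
    def empty(cls, n: int) -> "DeflationProjector":
        return cls(np.zeros((n, n)))

    @classmethod
    def from_rows(cls, w_rows: np.ndarray) -> "DeflationProjector":
        w = np.atleast_2d(np.asarray(w_rows, dtype=float))
        if w.shape[0] == 0:
            return cls.empty(w.shape[1])
        return cls(w.T @ w)  # rows orthonormal -> W^T W is the projector


def estimate_kurtosis(y) -> float:
    """Excess kurtosis estimator ``sum(y^4)/M - 3``.

    The caller guarantees unit variance (directions are unit vectors in the
    whitened space), so no studentization is applied.
    """
    arr = np.asarray(y, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot estimate kurtosis of an empty vector")
    return float(np.mean(arr**4) - 3.0)


def fastica_candidate(
    w0,
    x_white,
    e: DeflationProjector | None = None,
    k_max: int = 30,
    eps: float = 1e-6,
    degenerate_tolerance: float = DEGENERATE_TOLERANCE,
) -> CandidateResult:
    """Run one deflated fixed-point restart from the initial direction ``w0``.

    Parameters
    ----------
    w0
        Initial direction, length N; need not be normalized.
    x_white
        Whitened signals, shape ``(N, M)``.
    e
        Deflation projector onto previously accepted rows (None for the
        first component).
    k_max
        Maximum number of update cycles (non-convergence is reported, not
        raised).
    eps
        Convergence threshold on min(||w - w_prev||, ||w + w_prev||).

    Raises
    ------
    DegenerateDirectionError
        If ``w0`` (or an iterate) has norm below ``degenerate_tolerance``
        after deflation; the caller should resample.
    """
    x = as_array(x_white)
    n, m = x.shape
    proj = e.matrix if e is not None else None

    w = np.asarray(w0, dtype=float).copy()
    if proj is not None:
        w = w - proj @ w
    norm = np.linalg.norm(w)
    if norm <= degenerate_tolerance:
        raise DegenerateDirectionError(
            "initial direction lies inside the deflation subspace"
        )
    w /= norm

    converged = False
    t = 0
    for t in range(1, k_max + 1):
        w_prev = w
        y = w @ x
        w = x @ (y * y * y) / m - 3.0 * w
        if proj is not None:
            w = w - proj @ w
        norm = np.linalg.norm(w)
        if norm <= degenerate_tolerance:
            raise DegenerateDirectionError(
                "update collapsed into the deflation subspace"
            )
        w = w / norm
        if min(np.linalg.norm(w - w_prev), np.linalg.norm(w + w_prev)) <= eps:
            converged = True
            break

    y = w @ x
    return CandidateResult(
        w=w, y=y, alpha=estimate_kurtosis(y), converged=converged, iterations=t
    )
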