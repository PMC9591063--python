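"""The ordering ICA: globally ordered deflation via parallel random restarts.

Plain deflation FastICA converges to whichever local extremum of the
kurtosis its initialization happens to fall into, so its solution (and the
order of its rows) differs from run to run. The ordering ICA removes this
ambiguity: at each deflation step it launches ``L`` independent restarts,
scores every converged candidate by the convex non-Gaussianity transform

    Upsilon(alpha) = alpha - 2 log(alpha / 2 + 1),

and keeps the candidate with the largest Upsilon. Because Upsilon is convex
with its minimum 0 at alpha = 0, its global maximum over the constraint set
is attained at one of the local extrema of the kurtosis — exactly the fixed
points the restarts find. With enough restarts the components are therefore
extracted in descending order of Upsilon(kappa) of the true sources and the
separating matrix is unique (up to sign), provided no source is a symmetric
Bernoulli variable (excess kurtosis -2, where Upsilon is undefined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fastica import (
    CandidateResult,
    DeflationProjector,
    DegenerateDirectionError,
    fastica_candidate,
)
from .preprocessing import SignalMatrix, WhiteningModel, as_array, whiten

__all__ = [
    "SeparationResult",
    "ConvergenceFailureError",
    "upsilon",
    "run_ordering_ica",
    "default_candidate_count",
]

logger = logging.getLogger(__name__)

#: Default maximum number of fixed-point cycles per restart. Kept small:
#: individual restart failures are harmless because each deflation step only
#: needs one restart to reach the global extremum.
DEFAULT_K_MAX = 30

#: Default convergence threshold for the fixed-point iteration.
DEFAULT_EPS = 1e-6

#: Bound on redraws of a single initial direction that lands (numerically)
#: inside the deflation subspace — an event of probability zero for
#: Gaussian initialization.
_MAX_RESAMPLE = 100


class ConvergenceFailureError(RuntimeError):
    """Every restart of a deflation step failed to converge, twice."""

    def __init__(self, component: int):
        self.component = component
        super().__init__(
            f"all restarts failed to converge for component {component} "
            "(after one full batch re-draw)"
        )


def upsilon(alpha):
    """Non-Gaussianity score ``Upsilon(alpha) = alpha - 2 log(alpha/2 + 1)``.

    Non-negative, zero only at alpha = 0 (Gaussian), and defined for
    alpha > -2; the boundary alpha = -2 is the symmetric Bernoulli variable
    excluded by the uniqueness theorem.
    """
    a = np.asarray(alpha, dtype=float)
    if np.any(a <= -2.0):
        raise ValueError(
            "upsilon is undefined for excess kurtosis <= -2 "
            "(the symmetric Bernoulli boundary)"
        )
    out = a - 2.0 * np.log1p(a / 2.0)
    return float(out) if np.isscalar(alpha) or out.ndim == 0 else out


def default_candidate_count(n_cores: int, overhead_rate: float = 1.0) -> int:
    """Number of restarts ``L = round(n_cores * overhead_rate)``, at least 1.

    The restart count is tied to the core count because restarts are
    embarrassingly parallel; the overhead rate R (default 1) trades extra
    robustness for proportional extra work.
    """
    if n_cores < 1:
        raise ValueError(f"n_cores must be >= 1, got {n_cores}")
    if overhead_rate <= 0:
        raise ValueError(f"overhead_rate must be positive, got {overhead_rate}")
    return max(1, round(n_cores * overhead_rate))


@dataclass(frozen=True)
class SeparationResult:
    """Ordered separating matrix with per-component scores and provenance.

    ``w_matrix`` rows live in the whitened space and are orthonormal there;
    row order is extraction order (descending Upsilon). ``mixing_estimate``
    maps the unmixing back through the whitening model to an estimate of the
    original mixing matrix A.
    """

    w_matrix: np.ndarray
    alphas: np.ndarray
    upsilons: np.ndarray
    mixing_estimate: np.ndarray
    run_meta: dict
    whitening: WhiteningModel | None = None
    candidates: list | None = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return self.w_matrix.shape[0]


def _candidate_rng(seed: int, component: int, index: int, attempt: int):
    """Independent generator for one (component, restart) pair.

    Seeding by spawn key rather than by worker makes the result identical
    whether restarts run serially or in parallel, and for any worker count.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(component, index, attempt))
    )


def _run_one_candidate(seed, component, index, attempt, x, e, k_max, eps):
    rng = _candidate_rng(seed, component, index, attempt)
    n = x.shape[0]
    for _ in range(_MAX_RESAMPLE):
        w0 = rng.standard_normal(n)
        try:
            return fastica_candidate(w0, x, e, k_max=k_max, eps=eps)
        except DegenerateDirectionError:
            continue
    raise DegenerateDirectionError(
        f"could not draw a non-degenerate start for component {component}"
    )


def _select_best(cands: list[CandidateResult]) -> int | None:
    """Index of the converged candidate with the highest Upsilon.

    Non-converged candidates are excluded (their alpha may be meaningless),
    as are candidates at or below the Upsilon domain boundary. Ties break by
    lowest restart index, keeping the reduction deterministic.
    """
    best, best_ups = None, -np.inf
    for idx, c in enumerate(cands):
        if not c.converged or not np.isfinite(c.alpha) or c.alpha <= -2.0:
            continue
        ups = upsilon(c.alpha)
        if ups > best_ups:
            best, best_ups = idx, ups
    return best


def run_ordering_ica(
    x,
    l_candidates: int = 64,
    k_max: int = DEFAULT_K_MAX,
    eps: float = DEFAULT_EPS,
    seed: int = 0,
    *,
    whiten_input: bool = False,
    workers: int = 1,
    keep_candidates: bool = False,
) -> SeparationResult:
    """Estimate the ordered separating matrix of ``x``.

    Parameters
    ----------
    x
        Signals, shape ``(N, M)``. Must already be whitened unless
        ``whiten_input=True``.
    l_candidates
        Number of independent restarts L per deflation step.
    k_max, eps
        Fixed-point iteration budget and convergence threshold.
    seed
        Master seed. Each (component, restart) pair draws its
        initialization from an independent sub-stream, so equal
        ``(seed, l_candidates)`` gives bit-identical results regardless of
        ``workers``.
    whiten_input
        Center and whiten ``x`` first, and carry the model into the result.
    workers
        Restarts per deflation step are independent tasks; with
        ``workers != 1`` they are dispatched through joblib.
    keep_candidates
        Retain every restart's :class:`CandidateResult` per component
        (needed by the success-rate statistics).

    Raises
    ------
    ConvergenceFailureError
        If every restart of some step fails to converge and a full batch
        re-draw with fresh sub-streams fails as well.
    """
    if l_candidates < 1:
        raise ValueError(f"l_candidates must be >= 1, got {l_candidates}")

    model = None
    if whiten_input:
        xw, model = whiten(x)
        data = xw.data
    else:
        data = as_array(x)
        if not isinstance(x, SignalMatrix):
            data = SignalMatrix(data).data

    n = data.shape[0]
    rows: list[np.ndarray] = []
    alphas: list[float] = []
    conv_counts: list[int] = []
    all_candidates: list[list[CandidateResult]] = []

    if workers != 1:
        from joblib import Parallel, delayed

        pool = Parallel(n_jobs=workers)
    else:
        pool = None

    for i in range(n):
        e = (
            DeflationProjector.from_rows(np.array(rows))
            if rows
            else DeflationProjector.empty(n)
        )
        best = None
        for attempt in range(2):
            args = [
                (seed, i, l, attempt, data, e, k_max, eps)
                for l in range(l_candidates)
            ]
            if pool is not None:
                cands = pool(delayed(_run_one_candidate)(*a) for a in args)
            else:
                cands = [_run_one_candidate(*a) for a in args]
            best = _select_best(cands)
            if best is not None:
                break
            logger.warning(
                "component %d: all %d restarts failed to converge; re-drawing",
                i,
                l_candidates,
            )
        if best is None:
            raise ConvergenceFailureError(i)

        chosen = cands[best]
        n_conv = sum(c.converged for c in cands)
        conv_counts.append(n_conv)
        logger.info(
            "component %d: %d/%d restarts converged, selected restart %d "
            "with alpha=%.6g Upsilon=%.6g",
            i,
            n_conv,
            l_candidates,
            best,
            chosen.alpha,
            upsilon(chosen.alpha),
        )
        rows.append(chosen.w)
        alphas.append(chosen.alpha)
        if keep_candidates:
            all_candidates.append(list(cands))

    w_matrix = np.array(rows)
    alphas_arr = np.array(alphas)
    # rows are orthonormal in the whitened space, so W^{-1} = W^T there
    if model is not None:
        mixing_estimate = model.inverse_transform @ w_matrix.T
    else:
        mixing_estimate = w_matrix.T
    return SeparationResult(
        w_matrix=w_matrix,
        alphas=alphas_arr,
        upsilons=upsilon(alphas_arr),
        mixing_estimate=mixing_estimate,
        run_meta={
            "seed": seed,
            "L": l_candidates,
            "K": k_max,
            "eps": eps,
            "n_channels": n,
            "n_samples": data.shape[1],
            "convergence_counts": conv_counts,
            "whitened_internally": whiten_input,
        },
        whitening=model,
        candidates=all_candidates if keep_candidates else None,
    )
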