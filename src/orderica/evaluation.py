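"""Stability and success-rate statistics for run-to-run evaluation.

Two empirical questions are answered here. First, how stable is the
solution across repeated runs: the divergence ``delta = 1 - |cos|`` between
matched components of different runs, averaged over run pairs, measures the
fluctuation of each component (0 means a unique, reproducible solution).
Components are matched across runs by their Upsilon rank, which removes the
permutation ambiguity without any assignment search. Second, how likely is
a single restart to find the global optimum: the success rate ``mu_i`` is
the fraction of restarts landing within a divergence threshold of the best
candidate, from which per-component and cumulative failure rates of the
whole L-restart scheme follow as ``(1 - mu_i)^L`` and a product recurrence.
The empirical power law ``log10 mu = b1 + b2 log10 Upsilon`` links the
success rate to the component's non-Gaussianity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fastica import CandidateResult
from .ordering import SeparationResult, upsilon

__all__ = [
    "StabilityReport",
    "divergence",
    "align_runs",
    "mean_fluctuation",
    "fluctuation_curve",
    "success_rate",
    "failure_rates",
    "fit_success_model",
    "analytic_failure_bound",
]

#: Divergence threshold defining "same solution" for the success rate.
DEFAULT_SUCCESS_EPS = 0.001

#: Default number of restarts retained for success-rate estimation.
DEFAULT_L_MAX = 1000


def divergence(w_a, w_b) -> float:
    """Sign-invariant divergence ``1 - |cos(w_a, w_b)|`` in [0, 1].

    Zero iff the directions are equal or opposite; one if orthogonal. A
    missing operand (None) scores the maximum 1, so runs that failed to
    produce a component are penalized maximally.
    """
    if w_a is None or w_b is None:
        return 1.0
    a = np.asarray(w_a, dtype=float)
    b = np.asarray(w_b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("divergence is undefined for a zero vector")
    return float(1.0 - abs(a @ b) / (na * nb))


def align_runs(runs) -> list[list]:
    """Sort each run's components by descending Upsilon and pad to equal length.

    Accepts :class:`SeparationResult` objects or ``(w_matrix, upsilons)``
    pairs. Runs with fewer components than the longest run are padded with
    ``None`` markers; any comparison against a marker scores divergence 1.
    """
    aligned = []
    for run in runs:
        if isinstance(run, SeparationResult):
            w, ups = run.w_matrix, run.upsilons
        else:
            w, ups = run
            w = np.atleast_2d(np.asarray(w, dtype=float))
            ups = np.asarray(ups, dtype=float)
        order = np.argsort(-ups, kind="stable")
        aligned.append([w[j] for j in order])
    n_max = max(len(rows) for rows in aligned)
    for rows in aligned:
        rows.extend([None] * (n_max - len(rows)))
    return aligned


def mean_fluctuation(aligned_runs: list[list], component: int) -> float:
    """Average divergence of one component over all unordered run pairs."""
    t = len(aligned_runs)
    if t < 2:
        raise ValueError(f"need at least 2 runs, got {t}")
    total = 0.0
    for p in range(t):
        for q in range(p + 1, t):
            total += divergence(aligned_runs[p][component], aligned_runs[q][component])
    return total / (t * (t - 1) / 2)


def fluctuation_curve(runs) -> np.ndarray:
    """Per-component mean fluctuation ``delta_bar(i)`` across aligned runs."""
    aligned = align_runs(runs)
    n = len(aligned[0])
    return np.array([mean_fluctuation(aligned, i) for i in range(n)])


def success_rate(
    candidates: list[CandidateResult],
    best_index: int,
    eps: float = DEFAULT_SUCCESS_EPS,
) -> float:
    """Fraction of restarts within divergence ``eps`` of the best candidate.

    The best candidate (highest Upsilon) is taken as the unique global
    solution; diverged restarts (non-convergence or non-finite kurtosis)
    cannot witness it and never enter the near set. The minimum is
    ``1 / len(candidates)`` since the best candidate matches itself.
    """
    if len(candidates) == 0:
        raise ValueError("success rate requires at least one candidate")
    w_best = candidates[best_index].w
    near = 0
    for c in candidates:
        if not c.converged or not np.isfinite(c.alpha):
            continue
        if divergence(c.w, w_best) < eps:
            near += 1
    return near / len(candidates)


def component_success_rates(
    per_component_candidates: list[list[CandidateResult]],
    eps: float = DEFAULT_SUCCESS_EPS,
) -> np.ndarray:
    """Success rate of every component from a run retaining its restarts.

    A component whose restarts all diverged is reported as NaN (neglected
    in downstream analysis).
    """
    mus = []
    for cands in per_component_candidates:
        valid = [
            (k, c)
            for k, c in enumerate(cands)
            if c.converged and np.isfinite(c.alpha) and c.alpha > -2.0
        ]
        if not valid:
            mus.append(np.nan)
            continue
        best_k = max(valid, key=lambda kc: (upsilon(kc[1].alpha), -kc[0]))[0]
        mus.append(success_rate(cands, best_k, eps=eps))
    return np.array(mus)


def failure_rates(mu, l_candidates: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-component and cumulative failure rates of the L-restart scheme.

    ``nu_each[i] = (1 - mu[i])^L`` is the probability that none of L
    independent restarts finds the unique solution of component i (given
    the preceding components were estimated correctly), and the cumulative
    rate follows ``nu_total[i] = nu_total[i-1] + (1 - nu_total[i-1]) *
    nu_each[i]`` with ``nu_total[-1] = 0`` — equivalently
    ``1 - prod(1 - nu_each)``.
    """
    m = np.asarray(mu, dtype=float)
    if np.any(m <= 0.0):
        raise ValueError("success rates must be positive")
    if l_candidates < 1:
        raise ValueError(f"l_candidates must be >= 1, got {l_candidates}")
    nu_each = (1.0 - m) ** l_candidates
    nu_total = np.empty_like(nu_each)
    prev = 0.0
    for i, ne in enumerate(nu_each):
        prev = prev + (1.0 - prev) * ne
        nu_total[i] = prev
    return nu_each, nu_total


def fit_success_model(upsilons, mus) -> tuple[float, float]:
    """OLS fit of ``log10 mu = b1 + b2 * log10 Upsilon``.

    Components whose restarts all diverged must be excluded beforehand; all
    remaining Upsilon and mu values must be positive.
    """
    u = np.asarray(upsilons, dtype=float)
    m = np.asarray(mus, dtype=float)
    if u.shape != m.shape:
        raise ValueError("upsilons and mus must have equal length")
    if u.size < 2:
        raise ValueError("need at least 2 points to fit the power law")
    if np.any(u <= 0) or np.any(m <= 0):
        raise ValueError("power-law fit requires positive Upsilon and mu")
    b2, b1 = np.polyfit(np.log10(u), np.log10(m), 1)
    return float(b1), float(b2)


def analytic_failure_bound(l_candidates: int) -> float:
    """Upper bound ``(1 - 10^-1.5)^L`` on the per-component failure rate.

    Applies to strongly non-Gaussian components (Upsilon > 10), whose
    empirical single-restart success rate exceeds 10^-1.5; the bound decays
    as roughly ``10^(-0.0139 L)``.
    """
    if l_candidates < 0:
        raise ValueError("l_candidates must be non-negative")
    return float((1.0 - 10.0**-1.5) ** l_candidates)


@dataclass
class StabilityReport:
    """Bundle of the stability and success-rate statistics of a study.

    Fields not computed for a given analysis are left None.
    """

    per_component_fluctuation: np.ndarray | None = None
    n_runs: int | None = None
    success_rates: np.ndarray | None = None
    regression: tuple[float, float] | None = None
    failure_each: np.ndarray | None = None
    failure_total: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_runs(cls, runs) -> "StabilityReport":
        """Fluctuation analysis of repeated runs on the same data."""
        return cls(
            per_component_fluctuation=fluctuation_curve(runs),
            n_runs=len(runs),
        )

    @classmethod
    def from_candidates(
        cls,
        result: SeparationResult,
        l_candidates: int,
        eps: float = DEFAULT_SUCCESS_EPS,
    ) -> "StabilityReport":
        """Success-rate analysis of one run that retained its restarts.

        ``l_candidates`` is the restart count L whose failure rates are to
        be predicted from the measured success rates (it need not equal the
        L_max used to measure them).
        """
        if result.candidates is None:
            raise ValueError("run must be executed with keep_candidates=True")
        mus = component_success_rates(result.candidates, eps=eps)
        ok = np.isfinite(mus)
        nu_each, nu_total = failure_rates(mus[ok], l_candidates)
        ups = result.upsilons[ok]
        pos = (ups > 0) & (mus[ok] > 0)
        regression = (
            fit_success_model(ups[pos], mus[ok][pos]) if pos.sum() >= 2 else None
        )
        return cls(
            success_rates=mus,
            regression=regression,
            failure_each=nu_each,
            failure_total=nu_total,
            meta={"L": l_candidates, "eps": eps, "L_max": len(result.candidates[0])},
        )
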