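"""Centering and whitening of multichannel signals.

The separation algorithm operates on whitened data: zero-mean signals whose
sample covariance (normalized by the sample size ``M``) is the identity.
This module provides the :class:`SignalMatrix` container (channels in rows),
the :class:`WhiteningModel` affine transform, and :func:`whiten`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignalMatrix",
    "WhiteningModel",
    "RankDeficiencyError",
    "whiten",
]


class RankDeficiencyError(ValueError):
    """Sample covariance is numerically rank deficient.

    The number of extracted components is fixed at the channel count ``N``,
    so a degenerate covariance cannot be silently reduced away.
    """

    def __init__(self, n_deficient: int, n_channels: int):
        self.n_deficient = n_deficient
        self.n_channels = n_channels
        super().__init__(
            f"sample covariance is rank deficient: {n_deficient} of "
            f"{n_channels} dimensions fall below the rank tolerance"
        )


@dataclass(frozen=True)
class SignalMatrix:
    """An ``N x M`` real matrix of ``N`` channels by ``M`` samples.

    Holds observed signals ``X``, sources ``S``, or recovered sources ``Y``
    of the linear mixing model ``X = A S``. Channels are rows throughout.
    """

    data: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"signal matrix must be 2-D, got shape {arr.shape}")
        n, m = arr.shape
        if n < 2:
            raise ValueError(f"need at least 2 channels, got {n}")
        if m <= n:
            raise ValueError(
                f"sample size M={m} must exceed the channel count N={n}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("signal matrix contains non-finite entries")
        object.__setattr__(self, "data", arr)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def as_array(x) -> np.ndarray:
    """Return the underlying ``N x M`` array of a SignalMatrix or ndarray."""
    if isinstance(x, SignalMatrix):
        return x.data
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class WhiteningModel:
    """Affine map taking raw signals to zero mean and identity covariance.

    ``whitened = transform @ (x - mean[:, None])`` and
    ``x = inverse_transform @ whitened + mean[:, None]``.
    """

    mean: np.ndarray
    transform: np.ndarray
    inverse_transform: np.ndarray
    eigenvalues: np.ndarray = field(default=None, repr=False)

    def apply(self, x) -> np.ndarray:
        arr = as_array(x)
        return self.transform @ (arr - self.mean[:, None])

    def invert(self, x_white) -> np.ndarray:
        arr = as_array(x_white)
        return self.inverse_transform @ arr + self.mean[:, None]

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "transform": self.transform.tolist(),
            "inverse_transform": self.inverse_transform.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WhiteningModel":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            transform=np.asarray(d["transform"], dtype=float),
            inverse_transform=np.asarray(d["inverse_transform"], dtype=float),
        )


def whiten(x, rank_tolerance: float = 1e-10) -> tuple[SignalMatrix, WhiteningModel]:
    """Center and whiten signals so their covariance ``X X^T / M`` is identity.

    Whitening is computed from the singular value decomposition of the
    centered data (better conditioned than forming the covariance matrix
    explicitly). The covariance convention divides by ``M``, matching the
    moment estimators used by the separation objective.

    Parameters
    ----------
    x
        SignalMatrix or array of shape ``(N, M)``.
    rank_tolerance
        Relative eigenvalue threshold below which the covariance is declared
        rank deficient.

    Returns
    -------
    (SignalMatrix, WhiteningModel)
        The whitened signals and the invertible transform that produced them.

    Raises
    ------
    RankDeficiencyError
        If any covariance eigenvalue is below ``rank_tolerance`` times the
        largest (for example when a channel is duplicated).
    """
    sm = x if isinstance(x, SignalMatrix) else SignalMatrix(np.asarray(x, float))
    arr = sm.data
    n, m = arr.shape
    mean = arr.mean(axis=1)
    centered = arr - mean[:, None]

    u, sing, _ = np.linalg.svd(centered, full_matrices=False)
    # covariance eigenvalues under the divide-by-M convention
    eigvals = sing**2 / m
    n_deficient = int(np.sum(eigvals <= rank_tolerance * eigvals.max()))
    if n_deficient > 0:
        raise RankDeficiencyError(n_deficient, n)

    scale = np.sqrt(eigvals)
    transform = (u / scale).T  # rows: u_k^T / sqrt(lambda_k)
    inverse_transform = u * scale
    model = WhiteningModel(
        mean=mean,
        transform=transform,
        inverse_transform=inverse_transform,
        eigenvalues=eigvals,
    )
    return SignalMatrix(transform @ centered), model
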