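"""Proper orthogonal decomposition of vocal-fold kinematics.

The snapshot matrix (rows = time snapshots, columns = displacement degrees
of freedom) is mean-removed and factorized by a singular value
decomposition; the right singular vectors are the spatial modes, the
energy fraction of mode ``k`` is ``sigma_k² / sum(sigma²)``, and the modal
coefficient of mode ``k`` is the projection of each snapshot onto it.

Mode sign is arbitrary, so the modal-similarity measure used to compare
runs is the absolute cosine between shape vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PODModes", "pod_decompose", "modal_similarity", "coefficient_lag"]


@dataclass
class PODModes:
    """Result of a POD: orthonormal spatial modes sorted by energy.

    Attributes
    ----------
    modes : (k, n_dof) array, orthonormal rows
    energy_fractions : (k,) array, non-increasing, summing to <= 1
    coefficients : (n_t, k) array, snapshot projections onto each mode
    mean : (n_dof,) array, mean field removed before decomposition
    singular_values : (k,) array
    """

    modes: np.ndarray
    energy_fractions: np.ndarray
    coefficients: np.ndarray
    mean: np.ndarray
    singular_values: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Snapshots rebuilt from the retained modes (plus the mean)."""
        return self.mean + self.coefficients @ self.modes


def pod_decompose(snapshots: np.ndarray, n_modes: int | None = None) -> PODModes:
    """POD of a snapshot matrix via mean-removed SVD.

    Parameters
    ----------
    snapshots : (n_t, n_dof) array
        Time snapshots of displacement degrees of freedom (steady cycles).
    n_modes : int, optional
        Number of modes to retain; defaults to the full rank.  Requests
        beyond the rank are truncated with a warning.
    """
    x = np.asarray(snapshots, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("snapshots must be a (n_t >= 2, n_dof) matrix")
    mean = x.mean(axis=0)
    fluct = x - mean
    u, s, vt = np.linalg.svd(fluct, full_matrices=False)
    total = float((s**2).sum())
    if total == 0.0:
        rank = 0
    else:
        rank = int((s > s[0] * 1e-12).sum())
    if n_modes is None:
        n_modes = rank
    elif n_modes > rank:
        warnings.warn(
            f"requested {n_modes} modes but fluctuation rank is {rank}; truncating",
            RuntimeWarning, stacklevel=2)
        n_modes = rank
    k = n_modes
    energy = (s[:k] ** 2 / total) if total > 0 else np.zeros(0)
    return PODModes(
        modes=vt[:k],
        energy_fractions=energy,
        coefficients=u[:, :k] * s[:k],
        mean=mean,
        singular_values=s[:k],
    )


def modal_similarity(mode_a: np.ndarray, mode_b: np.ndarray) -> float:
    """Absolute cosine between two shape vectors, in [0, 1].

    1 means identical mode shapes (up to sign and scale), 0 means
    orthogonal shapes.
    """
    a = np.asarray(mode_a, dtype=float).ravel()
    b = np.asarray(mode_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("mode vectors must have the same dimension")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero mode vector")
    return float(min(abs(a @ b) / (na * nb), 1.0))


def coefficient_lag(
    coeff_a: np.ndarray,
    coeff_b: np.ndarray,
    dt: float,
    period: float | None = None,
) -> float:
    """Lag (seconds) at the circular cross-correlation peak of two modal
    coefficient series: the shift of ``coeff_b`` that best aligns it with
    ``coeff_a``.

    With ``period`` given, the lag is reported modulo one period in
    ``[0, period)``; records should span an integer number of cycles for
    the circular correlation to be meaningful.
    """
    a = np.asarray(coeff_a, dtype=float)
    b = np.asarray(coeff_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("coefficient series must be 1-D and equally long")
    a = a - a.mean()
    b = b - b.mean()
    corr = np.fft.irfft(np.fft.rfft(a) * np.conj(np.fft.rfft(b)), n=len(a))
    lag = float(np.argmax(corr)) * dt
    if period is not None:
        lag %= period
    return lag
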