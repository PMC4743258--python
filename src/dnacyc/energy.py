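"""Harmonic step energies and the principal-axis decomposition.

The elastic energy of one step is the quadratic form
``G = 1/2 * dTheta^T (beta F) dTheta`` in the deviation of the six
helicoidal coordinates from their equilibrium values (angles in radians,
displacements in Å); the force matrix is stored pre-divided by kT, so all
energies are in units of kT and temperature never appears explicitly.
Chain energies are sums of independent step energies, and configuration
probabilities are Boltzmann factors ``exp(-G)``.

Diagonalizing beta*F yields independent normal coordinates along the
principal axes of deformation; the Monte Carlo sampler draws each with
standard deviation ``1/sqrt(D_ii)``.  Zero eigenvalues mark frozen
directions (sampled deviation identically zero), matching the sigma = 0
shorthand of :class:`~dnacyc.params.FluctuationModel`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import FluctuationModel

__all__ = [
    "PrincipalAxes",
    "step_energy",
    "total_energy",
    "boltzmann_weight",
    "principal_axes",
]

_EIG_TOL = 1e-10


@dataclass(frozen=True, eq=False)
class PrincipalAxes:
    """Eigendecomposition of a stiffness matrix: beta_f = axes @ diag(D) @ axes.T."""

    D: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float).reshape(6)
        axes = np.asarray(self.axes, dtype=float).reshape(6, 6)
        if D.min() < -_EIG_TOL:
            raise ValueError(f"negative stiffness eigenvalue {D.min():g}")
        if not np.allclose(axes.T @ axes, np.eye(6), atol=1e-10):
            raise ValueError("axes must be orthonormal")
        object.__setattr__(self, "D", np.maximum(D, 0.0))
        object.__setattr__(self, "axes", axes)

    def sampling_sigmas(self, tol: float = _EIG_TOL) -> np.ndarray:
        """Thermal standard deviation along each axis: 1/sqrt(D_ii), 0 if frozen."""
        return np.where(self.D > tol, 1.0 / np.sqrt(np.where(self.D > tol, self.D, 1.0)), 0.0)

    def normal_coordinates(self, deviation: np.ndarray) -> np.ndarray:
        """Project a 6-vector of coordinate deviations onto the principal axes."""
        return self.axes.T @ np.asarray(deviation, dtype=float).reshape(6)

    def reconstruct(self) -> np.ndarray:
        return self.axes @ np.diag(self.D) @ self.axes.T


def step_energy(deviation: np.ndarray, fluct: FluctuationModel) -> float:
    """Harmonic energy (kT) of one step's deviation from equilibrium.

    ``deviation`` is the 6-vector dTheta (radians / Å).  Non-negative for any
    positive-semidefinite model and exactly zero at equilibrium.
    """
    d = np.asarray(deviation, dtype=float).reshape(6)
    if not np.all(np.isfinite(d)):
        raise ValueError("deviation contains non-finite entries")
    return 0.5 * float(d @ fluct.beta_f @ d)


def total_energy(
    deviations: np.ndarray,
    flucts: FluctuationModel | list[FluctuationModel],
) -> float:
    """Total chain energy (kT): sum of per-step harmonic energies.

    ``flucts`` may be one model applied uniformly (the headline case) or one
    model per step.
    """
    devs = np.asarray(deviations, dtype=float)
    if devs.ndim == 1:
        devs = devs.reshape(1, 6)
    if isinstance(flucts, FluctuationModel):
        flucts = [flucts] * devs.shape[0]
    if len(flucts) != devs.shape[0]:
        raise ValueError(
            f"{devs.shape[0]} deviation vectors but {len(flucts)} fluctuation models"
        )
    return float(sum(step_energy(d, f) for d, f in zip(devs, flucts)))


def boltzmann_weight(energy_kt: float) -> float:
    """Relative configuration probability exp(-G/kT)."""
    if not np.isfinite(energy_kt):
        raise ValueError("energy must be finite")
    return float(np.exp(-energy_kt))


def principal_axes(fluct: FluctuationModel) -> PrincipalAxes:
    """Diagonalize the (kT-normalized) stiffness matrix.

    For an already-diagonal matrix the axes are returned as the identity
    (coordinates are their own principal axes), keeping frozen coordinates
    in place; otherwise ``numpy.linalg.eigh`` supplies the decomposition.
    """
    m = fluct.beta_f
    if np.allclose(m, np.diag(np.diag(m)), atol=1e-15):
        return PrincipalAxes(np.diag(m).copy(), np.eye(6))
    w, v = np.linalg.eigh(m)
    if w.min() < -_EIG_TOL:
        raise ValueError(f"non-physical stiffness: eigenvalue {w.min():g}")
    return PrincipalAxes(w, v)
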