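"""Rigid-body frame algebra for base-pair chains.

Each base pair carries an orthonormal right-handed frame (columns: short
axis, long axis, normal).  A step's six helicoidal coordinates define the
rigid transform carrying frame k onto frame k+1 via the mid-step triad
construction (the standard rebuild algebra for these coordinates):

* the bend of magnitude Gamma = sqrt(tilt^2 + roll^2) is applied about an
  axis in the base-pair plane at phase angle phi = atan2(tilt, roll) from
  the roll (long) axis,
* the twist is split symmetrically, half before and half after the bend:
  ``R = Rz(twist/2 - phi) @ Ry(Gamma) @ Rz(twist/2 + phi)``,
* displacements (shift, slide, rise) are expressed in the mid-step triad
  ``Rm = Rz(twist/2 - phi) @ Ry(Gamma/2) @ Rz(phi)``.

Pure twist therefore rotates about the normal and translates by (0, 0,
rise); a single nonzero bend angle produces a rotation by exactly that
angle.  This module is plain numpy and deliberately independent of the
vectorized Monte Carlo kernels, which are cross-checked against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .params import StepParameters, profile_radians

__all__ = [
    "Frame",
    "canonical_frame",
    "ChainConfiguration",
    "ClosureGeometry",
    "step_transform",
    "build_chain",
    "closure_geometry",
    "residual_twist",
    "chain_to_dataframe",
    "write_chain_tsv",
    "write_pdb_trace",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class Frame:
    """Base-pair frame: origin (Å) and orthonormal triad with det +1."""

    origin: np.ndarray
    triad: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        t = np.asarray(self.triad, dtype=float).reshape(3, 3)
        if not np.all(np.isfinite(o)) or not np.all(np.isfinite(t)):
            raise ValueError("frame contains non-finite entries")
        if not np.allclose(t.T @ t, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("triad is not orthonormal")
        if np.linalg.det(t) < 0:
            raise ValueError("triad must be right-handed (det +1)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "triad", t)

    @property
    def normal(self) -> np.ndarray:
        return self.triad[:, 2]

    @property
    def short_axis(self) -> np.ndarray:
        return self.triad[:, 0]


def canonical_frame() -> Frame:
    return Frame(np.zeros(3), np.eye(3))


class ChainConfiguration:
    """Ordered base-pair frames of one chain (N frames for N-1 steps)."""

    def __init__(self, origins: np.ndarray, triads: np.ndarray):
        origins = np.asarray(origins, dtype=float)
        triads = np.asarray(triads, dtype=float)
        if origins.ndim != 2 or origins.shape[1] != 3:
            raise ValueError("origins must be (N, 3)")
        if triads.shape != (origins.shape[0], 3, 3):
            raise ValueError("triads must be (N, 3, 3)")
        if origins.shape[0] < 2:
            raise ValueError("a chain needs at least 2 base pairs")
        self.origins = origins
        self.triads = triads

    @classmethod
    def from_frames(cls, frames: Sequence[Frame]) -> "ChainConfiguration":
        return cls(
            np.stack([f.origin for f in frames]),
            np.stack([f.triad for f in frames]),
        )

    def __len__(self) -> int:
        return self.origins.shape[0]

    @property
    def n_bp(self) -> int:
        return len(self)

    def frame(self, k: int) -> Frame:
        return Frame(self.origins[k], self.triads[k])

    @property
    def frames(self) -> list[Frame]:
        return [self.frame(k) for k in range(len(self))]

    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.origins[-1] - self.origins[0]))

    def contour_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.origins, axis=0), axis=1).sum())


@dataclass(frozen=True)
class ClosureGeometry:
    """End-to-end closure coordinates of a chain.

    ``r``: distance between terminal base-pair origins (Å).
    ``cos_gamma``: cosine of the net bending angle between terminal normals.
    ``phi``: residual twist (radians, in (-pi, pi]) — the rotation about the
    average terminal normal carrying the first short axis onto the last.
    """

    r: float
    cos_gamma: float
    phi: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be non-negative")
        if not -1.0 - 1e-12 <= self.cos_gamma <= 1.0 + 1e-12:
            raise ValueError("cos_gamma outside [-1, 1]")


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def step_transform(step: StepParameters) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (rotation, translation) of one base-pair step.

    The rotation carries frame k's axes onto frame k+1's
    (``triad_{k+1} = triad_k @ R``); the translation is expressed in frame
    k's coordinates (``origin_{k+1} = origin_k + triad_k @ t``).
    """
    tilt, roll, twist = (math.radians(getattr(step, n)) for n in ("tilt", "roll", "twist"))
    disp = np.array([step.shift, step.slide, step.rise], dtype=float)
    gamma = math.hypot(tilt, roll)
    phi = math.atan2(tilt, roll) if gamma > 0.0 else 0.0
    rot = _rot_z(0.5 * twist - phi) @ _rot_y(gamma) @ _rot_z(0.5 * twist + phi)
    mid = _rot_z(0.5 * twist - phi) @ _rot_y(0.5 * gamma) @ _rot_z(phi)
    return rot, mid @ disp


def build_chain(
    profile: Sequence[StepParameters],
    start: Frame | None = None,
) -> ChainConfiguration:
    """Compose a chain of frames from an equilibrium (or sampled) profile.

    Frame 1 is the canonical frame at the origin unless ``start`` is given;
    frame k+1 = frame k composed with ``step_transform(profile[k])``.
    """
    if len(profile) < 1:
        raise ValueError("profile must contain at least one step")
    if start is None:
        start = canonical_frame()
    n = len(profile) + 1
    origins = np.empty((n, 3))
    triads = np.empty((n, 3, 3))
    origins[0] = start.origin
    triads[0] = start.triad
    for k, step in enumerate(profile):
        rot, trans = step_transform(step)
        origins[k + 1] = origins[k] + triads[k] @ trans
        triads[k + 1] = triads[k] @ rot
    return ChainConfiguration(origins, triads)


def residual_twist(
    n1: np.ndarray, x1: np.ndarray, n2: np.ndarray, x2: np.ndarray
) -> float:
    """Signed residual twist between two frames' short axes.

    Rotation angle about the *average* normal carrying ``x1`` onto ``x2``
    after projecting both onto the plane perpendicular to that average.
    Well defined whenever the normals are not anti-parallel, which is the
    only regime where the closure test evaluates it.
    """
    nbar = n1 + n2
    norm = np.linalg.norm(nbar)
    if norm < 1e-12:  # anti-parallel normals: fall back to the first normal
        nbar = np.asarray(n1, dtype=float)
    else:
        nbar = nbar / norm
    p1 = x1 - np.dot(x1, nbar) * nbar
    p2 = x2 - np.dot(x2, nbar) * nbar
    n1_, n2_ = np.linalg.norm(p1), np.linalg.norm(p2)
    if n1_ < 1e-12 or n2_ < 1e-12:
        return 0.0
    cosp = float(np.dot(p1, p2) / (n1_ * n2_))
    sinp = float(np.dot(nbar, np.cross(p1, p2)) / (n1_ * n2_))
    return math.atan2(sinp, cosp)


def closure_geometry(chain: ChainConfiguration) -> ClosureGeometry:
    """End-to-end distance, net-bend cosine and residual twist of a chain."""
    r = chain.end_to_end()
    n1 = chain.triads[0][:, 2]
    nN = chain.triads[-1][:, 2]
    cos_gamma = float(np.clip(np.dot(n1, nN), -1.0, 1.0))
    phi = residual_twist(n1, chain.triads[0][:, 0], nN, chain.triads[-1][:, 0])
    return ClosureGeometry(r=r, cos_gamma=cos_gamma, phi=phi)


def chain_to_dataframe(chain: ChainConfiguration):
    """Per-frame origins and triads as a tidy table (one row per base pair)."""
    import pandas as pd

    cols = {"bp": np.arange(1, len(chain) + 1)}
    for i, ax in enumerate("xyz"):
        cols[f"origin_{ax}"] = chain.origins[:, i]
    for j, name in enumerate(("short", "long", "normal")):
        for i, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = chain.triads[:, i, j]
    return pd.DataFrame(cols)


def write_chain_tsv(chain: ChainConfiguration, path) -> None:
    chain_to_dataframe(chain).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_pdb_trace(chain: ChainConfiguration, path) -> None:
    """Coarse PDB-like trace: one pseudo-atom per base-pair origin."""
    with open(path, "w") as fh:
        for k, o in enumerate(chain.origins, start=1):
            fh.write(
                f"ATOM  {k % 100000:5d}  P   DNA A{k % 10000:4d}    "
                f"{o[0]:8.3f}{o[1]:8.3f}{o[2]:8.3f}  1.00  0.00           P\n"
            )
        fh.write("END\n")
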