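"""Sequence-dependent equilibrium base-pair-step parameters.

The rigid base-pair-step description of double-stranded DNA assigns six
helicoidal coordinates to every pair of consecutive base pairs: three angles
(tilt, roll, helix twist, in degrees) and three displacements (shift, slide,
rise, in Å).  A *parameter set* maps a local sequence context (di-, tri- or
pentanucleotide) to equilibrium values of these coordinates; contexts or
coordinates a set does not cover fall back to canonical B-DNA defaults
(straight, 34.30° twist, 3.40 Å rise).  Thermal fluctuations around the
equilibrium values are described separately by a :class:`FluctuationModel`
(a 6x6 elastic-modulus matrix normalized to kT, or the diagonal RMS
shorthand used throughout the headline analyses).

Angles are degrees and displacements Å at every public interface; conversion
to radians happens exactly once, in :func:`profile_radians`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FIELD_NAMES",
    "ANGLE_FIELDS",
    "DNA_ALPHABET",
    "StepParameters",
    "TABLE_DEFAULTS",
    "FluctuationModel",
    "default_fluctuations",
    "ParameterSet",
    "load_parameter_set",
    "write_parameter_set",
    "builtin_straight",
    "builtin_curved",
    "curved_sequence",
    "equilibrium_profile",
    "profile_radians",
    "reverse_complement",
]

#: Canonical coordinate order used for every 6-vector / 6x6 matrix in the package.
FIELD_NAMES = ("tilt", "roll", "twist", "shift", "slide", "rise")
ANGLE_FIELDS = ("tilt", "roll", "twist")
DNA_ALPHABET = "ACGT"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: Coordinates whose sign flips when a step is read on the complementary strand.
_ANTISYMMETRIC = ("tilt", "shift")


def reverse_complement(kmer: str) -> str:
    """Reverse complement of an A/C/G/T k-mer."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(kmer))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"cannot complement non-ACGT k-mer {kmer!r}") from exc


@dataclass(frozen=True)
class StepParameters:
    """Equilibrium helicoidal coordinates of one base-pair step.

    Angles in degrees, displacements in Å.  Defaults are the canonical
    straight B-DNA values used to fill coordinates a parameter set omits.
    """

    tilt: float = 0.0
    roll: float = 0.0
    twist: float = 34.30
    shift: float = 0.0
    slide: float = 0.0
    rise: float = 3.40

    def __post_init__(self) -> None:
        for name in FIELD_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"step parameter {name} is not finite: {v!r}")
        if self.rise <= 0:
            raise ValueError(f"rise must be positive, got {self.rise}")

    def as_array(self) -> np.ndarray:
        """The six coordinates in canonical order (degrees / Å)."""
        return np.array([getattr(self, n) for n in FIELD_NAMES], dtype=float)

    def replace(self, **kwargs: float) -> "StepParameters":
        d = {n: getattr(self, n) for n in FIELD_NAMES}
        d.update(kwargs)
        return StepParameters(**d)


#: Default values applied wherever a parameter set provides no information.
TABLE_DEFAULTS = StepParameters(tilt=0.0, roll=0.0, twist=34.30, shift=0.0, slide=0.0, rise=3.40)


@dataclass(frozen=True, eq=False)
class FluctuationModel:
    """Harmonic elastic model for thermal fluctuations of one step.

    ``beta_f`` is the symmetric positive-semidefinite 6x6 matrix of elastic
    moduli already divided by the thermal energy kT, expressed against
    deviations in radians (angles) and Å (displacements).  A zero diagonal
    entry (more generally a zero stiffness eigenvalue) marks a coordinate
    that is frozen at its equilibrium value, matching the sigma = 0
    convention of the diagonal shorthand.
    """

    beta_f: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.beta_f, dtype=float)
        if m.shape != (6, 6):
            raise ValueError(f"beta_f must be 6x6, got shape {m.shape}")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("beta_f must be symmetric")
        w = np.linalg.eigvalsh(m)
        if w.min() < -1e-10:
            raise ValueError(f"beta_f must be positive semidefinite (min eigenvalue {w.min():g})")
        m = m.copy()
        m.flags.writeable = False
        object.__setattr__(self, "beta_f", m)

    @classmethod
    def from_sigmas(
        cls,
        sigma_tilt: float = 4.84,
        sigma_roll: float = 4.84,
        sigma_twist: float = 4.09,
        sigma_shift: float = 0.0,
        sigma_slide: float = 0.0,
        sigma_rise: float = 0.0,
    ) -> "FluctuationModel":
        """Diagonal shorthand: angle RMS values in degrees, displacements in Å.

        ``f_ii = 1 / sigma_i**2`` (after converting angles to radians);
        ``sigma_i = 0`` freezes the coordinate.
        """
        sig = [sigma_tilt, sigma_roll, sigma_twist, sigma_shift, sigma_slide, sigma_rise]
        if any(s < 0 for s in sig):
            raise ValueError("sigma values must be non-negative")
        sig = [math.radians(s) for s in sig[:3]] + list(sig[3:])
        diag = [0.0 if s == 0.0 else 1.0 / (s * s) for s in sig]
        return cls(np.diag(diag))

    @classmethod
    def from_matrix(cls, beta_f: np.ndarray) -> "FluctuationModel":
        return cls(np.asarray(beta_f, dtype=float))

    def sigmas(self) -> np.ndarray:
        """RMS fluctuation per coordinate for a diagonal model (degrees / Å).

        Raises for models with off-diagonal couplings, where per-coordinate
        RMS values are not the natural description.
        """
        m = self.beta_f
        if not np.allclose(m, np.diag(np.diag(m)), atol=1e-15):
            raise ValueError("sigmas() is only defined for diagonal models")
        d = np.diag(m)
        sig = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
        out = sig.copy()
        out[:3] = np.degrees(out[:3])
        return out


def default_fluctuations() -> FluctuationModel:
    """Isotropic-bending model used by the headline analyses.

    RMS tilt = RMS roll = 4.84° (persistence length ~147 bp), RMS twist =
    4.09° (compatible with measured topoisomer distributions); displacements
    frozen.
    """
    return FluctuationModel.from_sigmas()


@dataclass
class ParameterSet:
    """Context-keyed table of equilibrium step parameters with defaults.

    ``table`` maps k-mers (length ``context_width``, over ``alphabet``) to a
    partial mapping of the six coordinates; the *effective* parameters of a
    context take table values where present and ``defaults`` elsewhere.
    """

    name: str
    context_width: int
    table: dict[str, dict[str, float]] = field(default_factory=dict)
    defaults: StepParameters = TABLE_DEFAULTS
    alphabet: str = DNA_ALPHABET
    #: apply reverse-complement symmetry when a context is absent (ACGT only)
    use_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if self.context_width not in (2, 3, 5):
            raise ValueError(f"context_width must be 2, 3 or 5, got {self.context_width}")
        for kmer, fields_ in self.table.items():
            self._validate_context(kmer)
            unknown = set(fields_) - set(FIELD_NAMES)
            if unknown:
                raise ValueError(f"unknown parameter fields for context {kmer!r}: {sorted(unknown)}")

    def _validate_context(self, kmer: str) -> None:
        if len(kmer) != self.context_width:
            raise ValueError(
                f"context {kmer!r} has width {len(kmer)}, expected {self.context_width}"
            )
        bad = set(kmer) - set(self.alphabet)
        if bad:
            raise ValueError(f"context {kmer!r} contains characters outside alphabet {self.alphabet!r}")

    def effective(self, context: str) -> StepParameters:
        """Effective parameters for a context: table values over defaults.

        Falls back to the reverse complement (tilt and shift negated) when
        the context itself is absent, then to the defaults.
        """
        context = context.upper()
        self._validate_context(context)
        fields_ = self.table.get(context)
        if fields_ is None and self.use_reverse_complement and self.alphabet == DNA_ALPHABET:
            rc = reverse_complement(context)
            rc_fields = self.table.get(rc)
            if rc_fields is not None:
                fields_ = {
                    k: (-v if k in _ANTISYMMETRIC else v) for k, v in rc_fields.items()
                }
        if fields_ is None:
            return self.defaults
        return self.defaults.replace(**fields_)

    def contexts(self) -> list[str]:
        return sorted(self.table)


def builtin_straight() -> ParameterSet:
    """Sequence-independent straight-DNA validation model.

    Equilibrium twist 34.28°, rise 3.40 Å, all other coordinates zero, for
    every dinucleotide.
    """
    return ParameterSet(
        name="straight",
        context_width=2,
        table={},
        defaults=StepParameters(tilt=0.0, roll=0.0, twist=34.28, shift=0.0, slide=0.0, rise=3.40),
    )


def builtin_curved() -> ParameterSet:
    """Intrinsically curved validation model over the artificial {X, Z} alphabet.

    XX/XZ steps: twist 36.00° (one helical turn per 10 steps), no bend.
    ZZ/ZX steps: twist 35.57°, roll 7.41°.  Displacements as in the straight
    model.  A 5X/5Z repeat bends a 150 bp fragment into a near-circle.
    """
    disp = dict(shift=0.0, slide=0.0, rise=3.40)
    table = {
        "XX": dict(tilt=0.0, roll=0.0, twist=36.00, **disp),
        "XZ": dict(tilt=0.0, roll=0.0, twist=36.00, **disp),
        "ZZ": dict(tilt=0.0, roll=7.41, twist=35.57, **disp),
        "ZX": dict(tilt=0.0, roll=7.41, twist=35.57, **disp),
    }
    return ParameterSet(
        name="curved",
        context_width=2,
        table=table,
        defaults=StepParameters(tilt=0.0, roll=0.0, twist=36.00, shift=0.0, slide=0.0, rise=3.40),
        alphabet="XZ",
        use_reverse_complement=False,
    )


def curved_sequence(n_bp: int, block: int = 5) -> str:
    """Periodic X/Z sequence for the curved model (default 5X/5Z repeat)."""
    if n_bp < 2:
        raise ValueError("need at least 2 bp")
    if block < 1:
        raise ValueError("block must be >= 1")
    unit = "X" * block + "Z" * block
    reps = -(-n_bp // len(unit))
    return (unit * reps)[:n_bp]


def load_parameter_set(
    path,
    name: str | None = None,
    context_width: int | None = None,
    defaults: StepParameters = TABLE_DEFAULTS,
    alphabet: str = DNA_ALPHABET,
) -> ParameterSet:
    """Load a parameter set from a delimited text table.

    The file must have a header row with a ``context`` column plus any subset
    of ``tilt, roll, twist, shift, slide, rise`` (degrees / Å; comma- or
    tab-delimited).  Absent columns and empty cells fall back to ``defaults``.
    Malformed contexts, duplicate contexts and non-numeric cells raise a
    ``ValueError`` naming the offending row.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#", skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "context" not in df.columns:
        raise ValueError(f"{path}: missing required 'context' column (found {list(df.columns)})")
    unknown = set(df.columns) - {"context", *FIELD_NAMES}
    if unknown:
        raise ValueError(f"{path}: unknown columns {sorted(unknown)}")

    contexts = df["context"].astype(str).str.strip().str.upper()
    if context_width is None:
        context_width = len(contexts.iloc[0]) if len(contexts) else 2

    table: dict[str, dict[str, float]] = {}
    for row_no, (kmer, row) in enumerate(zip(contexts, df.itertuples(index=False)), start=2):
        if len(kmer) != context_width:
            raise ValueError(
                f"{path} row {row_no}: context {kmer!r} has width {len(kmer)}, expected {context_width}"
            )
        if set(kmer) - set(alphabet):
            raise ValueError(f"{path} row {row_no}: context {kmer!r} outside alphabet {alphabet!r}")
        if kmer in table:
            raise ValueError(f"{path} row {row_no}: duplicate context {kmer!r}")
        fields_: dict[str, float] = {}
        for col in FIELD_NAMES:
            if col not in df.columns:
                continue
            raw = getattr(row, col)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
                continue  # empty cell: fall back to defaults for this field
            try:
                fields_[col] = float(raw)
            except ValueError:
                raise ValueError(
                    f"{path} row {row_no}: non-numeric value {raw!r} in column {col!r}"
                ) from None
        table[kmer] = fields_

    return ParameterSet(
        name=name or str(path),
        context_width=context_width,
        table=table,
        defaults=defaults,
        alphabet=alphabet,
    )


def write_parameter_set(pset: ParameterSet, path) -> None:
    """Write the effective table (all six columns, defaults filled in) as TSV.

    ``load_parameter_set(write_parameter_set(p))`` reproduces the effective
    parameters of every listed context exactly.
    """
    rows = []
    for kmer in sorted(pset.table):
        eff = pset.effective(kmer)
        rows.append({"context": kmer, **{n: getattr(eff, n) for n in FIELD_NAMES}})
    pd.DataFrame(rows, columns=["context", *FIELD_NAMES]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def _validate_sequence(sequence: str, alphabet: str) -> str:
    seq = sequence.upper()
    allowed = set(alphabet)
    for pos, c in enumerate(seq):
        if c not in allowed:
            raise ValueError(
                f"invalid character {c!r} at position {pos + 1} (alphabet {alphabet!r})"
            )
    return seq


def equilibrium_profile(
    sequence: str,
    params: ParameterSet,
    circular: bool = False,
) -> list[StepParameters]:
    """Per-step equilibrium parameters of a sequence (length N-1 for N bases).

    Step ``k`` (1-based, between bases ``k`` and ``k+1``) is assigned the
    parameters of the context window anchored on its 5' base: bases
    ``k..k+1`` for width 2, ``k-1..k+1`` for width 3, ``k-2..k+2`` for
    width 5.  In linear mode (default) a window that overruns either
    sequence end yields the set's defaults; in circular mode the window
    wraps around.
    """
    seq = _validate_sequence(sequence, params.alphabet)
    n = len(seq)
    w = params.context_width
    if n < w:
        raise ValueError(f"sequence length {n} shorter than context width {w}")
    up = (w - 1) // 2  # bases upstream of the step's 5' base in the window
    profile: list[StepParameters] = []
    for i in range(n - 1):  # step i is between bases i and i+1 (0-based)
        start = i - up
        if circular:
            kmer = "".join(seq[(start + t) % n] for t in range(w))
            profile.append(params.effective(kmer))
        elif start < 0 or start + w > n:
            profile.append(params.defaults)
        else:
            profile.append(params.effective(seq[start : start + w]))
    return profile


def profile_radians(profile: Sequence[StepParameters]) -> np.ndarray:
    """Stack a profile into an (n_steps, 6) array with angles in radians.

    This is the single point where interface degrees become internal radians.
    """
    arr = np.array([p.as_array() for p in profile], dtype=float)
    if arr.ndim != 2:
        arr = arr.reshape(0, 6)
    arr[:, :3] = np.radians(arr[:, :3])
    return arr
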