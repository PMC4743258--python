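"""Batch analyses: benchmark evaluation, concordance curves, random surveys.

The workflows here mirror how sequence-dependent parameter sets are judged:
estimate J for every (sequence, parameter set) pair of a curated benchmark,
summarize agreement with experimental J factors as *order-of-magnitude
concordance* (the percentage of sequences whose simulated J lies within a
threshold number of decades of the measured one), survey random sequences,
and compare sequence-dependent J factors against the straight-DNA baseline
at the same length.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, MutableMapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .montecarlo import (
    JEstimate,
    SamplerConfig,
    estimate_j_halfchain,
    estimate_j_naive,
)
from .params import (
    DNA_ALPHABET,
    FluctuationModel,
    ParameterSet,
    builtin_straight,
    default_fluctuations,
    equilibrium_profile,
)

__all__ = [
    "BenchmarkRecord",
    "ConcordanceCurve",
    "load_benchmark",
    "write_benchmark",
    "read_fasta",
    "write_fasta",
    "evaluate_benchmark",
    "concordance_curve",
    "generate_random_sequences",
    "straight_j_curve",
    "straight_baseline_deviation",
    "length_stratified_summary",
    "local_peak_positions",
]

#: Default threshold grid for concordance curves (orders of magnitude).
DEFAULT_THRESHOLDS = np.round(np.arange(0.0, 8.0 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class BenchmarkRecord:
    """One benchmark sequence with an experimentally measured J factor."""

    sequence_id: str
    sequence: str
    j_experimental: float
    #: noiseless generating value carried by synthetic benchmarks (optional)
    j_baseline: float | None = None

    def __post_init__(self) -> None:
        if self.j_experimental <= 0:
            raise ValueError(f"{self.sequence_id}: j_experimental must be positive")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ConcordanceCurve:
    """Percentage of sequences within each order-of-magnitude threshold."""

    thresholds: np.ndarray
    percent_within: np.ndarray
    n: int

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        p = np.asarray(self.percent_within, dtype=float)
        if t.shape != p.shape:
            raise ValueError("thresholds and percent_within must align")
        if np.any(np.diff(p) < -1e-9):
            raise ValueError("concordance curve must be non-decreasing")
        if p.size and (p.min() < -1e-9 or p.max() > 100 + 1e-9):
            raise ValueError("percentages must lie in [0, 100]")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "percent_within", p)

    def percent_at(self, threshold: float) -> float:
        """Percentage at the grid point closest to ``threshold``."""
        i = int(np.argmin(np.abs(self.thresholds - threshold)))
        return float(self.percent_within[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "percent_within": self.percent_within}
        )


def load_benchmark(path) -> list[BenchmarkRecord]:
    """Read a benchmark TSV: columns sequence_id, sequence, j_experimental_M."""
    df = pd.read_csv(path, sep="\t")
    required = {"sequence_id", "sequence", "j_experimental_M"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing benchmark columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            BenchmarkRecord(
                sequence_id=str(row.sequence_id),
                sequence=str(row.sequence),
                j_experimental=float(row.j_experimental_M),
                j_baseline=float(row.j_baseline_M)
                if "j_baseline_M" in df.columns and not pd.isna(row.j_baseline_M)
                else None,
            )
        )
    return records


def write_benchmark(records: Sequence[BenchmarkRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "sequence_id": r.sequence_id,
            "sequence": r.sequence,
            "j_experimental_M": r.j_experimental,
        }
        if r.j_baseline is not None:
            row["j_baseline_M"] = r.j_baseline
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, uppercase sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def _cell_seed(base: int | None, sequence_id: str, set_name: str) -> int | None:
    """Deterministic, order-independent per-cell seed below 2**31."""
    if base is None:
        return None
    h = zlib.crc32(f"{sequence_id}\t{set_name}".encode())
    return (int(base) + h) % (2**31)


_ESTIMATORS: dict[str, Callable] = {
    "halfchain": estimate_j_halfchain,
    "naive": estimate_j_naive,
}


def _estimate_row(est: JEstimate, length: int, status: str = "ok") -> dict:
    return {
        "sequence_id": est.sequence_id,
        "parameter_set": est.parameter_set,
        "length_bp": length,
        "j_M": est.j,
        "rel_error": est.rel_error,
        "n_total": est.counts.n_total,
        "n_r": est.counts.n_r,
        "n_gamma": est.counts.n_gamma,
        "n_phi": est.counts.n_phi,
        "floored": est.floored,
        "seed": est.seed,
        "status": status,
    }


def evaluate_benchmark(
    records: Sequence[BenchmarkRecord],
    sets: Sequence[ParameterSet],
    cfg: SamplerConfig,
    fluct: FluctuationModel | None = None,
    method: str = "halfchain",
    cache: MutableMapping | None = None,
) -> pd.DataFrame:
    """One J estimate per (benchmark record, parameter set) pair.

    A sequence whose alphabet is incompatible with a set is recorded as a
    failed cell and the run continues.  ``cache`` (any mutable mapping) is
    keyed by sequence, set name, sampler configuration and method, making
    reruns resumable and idempotent.
    """
    if not records or not sets:
        raise ValueError("records and sets must be nonempty")
    if method not in _ESTIMATORS:
        raise ValueError(f"unknown method {method!r} (use 'halfchain' or 'naive')")
    estimator = _ESTIMATORS[method]
    fluct = fluct or default_fluctuations()
    rows = []
    for rec in records:
        for pset in sets:
            key = (rec.sequence, pset.name, cfg.cache_key(), method)
            if cache is not None and key in cache:
                est = cache[key]
            else:
                try:
                    profile = equilibrium_profile(rec.sequence, pset)
                except ValueError as exc:
                    rows.append(
                        {
                            "sequence_id": rec.sequence_id,
                            "parameter_set": pset.name,
                            "length_bp": rec.length,
                            "j_M": math.nan,
                            "rel_error": math.nan,
                            "n_total": 0,
                            "n_r": 0,
                            "n_gamma": 0,
                            "n_phi": 0,
                            "floored": False,
                            "seed": cfg.seed,
                            "status": f"failed: {exc}",
                        }
                    )
                    continue
                cell_cfg = replace(cfg, seed=_cell_seed(cfg.seed, rec.sequence_id, pset.name))
                est = estimator(
                    profile,
                    fluct,
                    cell_cfg,
                    parameter_set=pset.name,
                    sequence_id=rec.sequence_id,
                )
                if cache is not None:
                    cache[key] = est
            rows.append(_estimate_row(est, rec.length))
    return pd.DataFrame(rows)


def concordance_curve(
    j_sim: Sequence[float],
    j_exp: Sequence[float],
    thresholds: np.ndarray | None = None,
) -> ConcordanceCurve:
    """Percent of sequences with |log10 J_sim - log10 J_exp| <= t, per t.

    Both arrays must be paired and strictly positive (floored estimates are
    included as-is, at the floor value).
    """
    js = np.asarray(j_sim, dtype=float)
    je = np.asarray(j_exp, dtype=float)
    if js.shape != je.shape or js.ndim != 1 or js.size == 0:
        raise ValueError("j_sim and j_exp must be equal-length nonempty 1D arrays")
    if np.any(js <= 0) or np.any(je <= 0):
        raise ValueError("J factors must be positive")
    t = DEFAULT_THRESHOLDS if thresholds is None else np.asarray(thresholds, dtype=float)
    diff = np.abs(np.log10(js) - np.log10(je))
    percent = 100.0 * (diff[np.newaxis, :] <= t[:, np.newaxis]).mean(axis=1)
    return ConcordanceCurve(thresholds=t, percent_within=percent, n=js.size)


def generate_random_sequences(
    n_per_length: int,
    lengths: Sequence[int],
    seed: int | None = None,
) -> list[tuple[str, str]]:
    """Random sequences with equal probability for each nucleotide.

    Returns ``n_per_length`` (id, sequence) pairs for every requested length,
    deterministic under the seed.
    """
    if n_per_length < 1:
        raise ValueError("n_per_length must be >= 1")
    if any(l < 1 for l in lengths):
        raise ValueError("lengths must be positive")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(DNA_ALPHABET.encode(), dtype="S1")
    out = []
    for length in lengths:
        draws = rng.integers(0, 4, size=(n_per_length, int(length)))
        for i in range(n_per_length):
            seq = alphabet[draws[i]].tobytes().decode()
            out.append((f"L{int(length)}_{i + 1:04d}", seq))
    return out


def straight_j_curve(
    lengths: Sequence[int],
    cfg: SamplerConfig,
    fluct: FluctuationModel | None = None,
    method: str = "halfchain",
) -> dict[int, JEstimate]:
    """Straight-model J factor per fragment length (computed once per length)."""
    fluct = fluct or default_fluctuations()
    straight = builtin_straight()
    estimator = _ESTIMATORS[method]
    out: dict[int, JEstimate] = {}
    for length in lengths:
        profile = equilibrium_profile("A" * int(length), straight)
        cell_cfg = replace(cfg, seed=_cell_seed(cfg.seed, f"L{length}", straight.name))
        out[int(length)] = estimator(
            profile, fluct, cell_cfg, parameter_set="straight", sequence_id=f"L{length}"
        )
    return out


def straight_baseline_deviation(
    j_values: Sequence[float],
    lengths: Sequence[int],
    baseline: Mapping[int, float],
    thresholds: np.ndarray | None = None,
) -> ConcordanceCurve:
    """Concordance of per-sequence J factors against the straight-DNA baseline.

    ``baseline`` maps fragment length to the straight-model J at that length;
    a missing length is an error.
    """
    js = np.asarray(j_values, dtype=float)
    lens = [int(l) for l in lengths]
    if js.size != len(lens):
        raise ValueError("j_values and lengths must align")
    missing = sorted({l for l in lens if l not in baseline})
    if missing:
        raise ValueError(f"missing straight-model baseline for lengths {missing}")
    ref = np.array([baseline[l] for l in lens], dtype=float)
    return concordance_curve(js, ref, thresholds)


def length_stratified_summary(
    j_values: Sequence[float], lengths: Sequence[int]
) -> pd.DataFrame:
    """Median and 25/75 % quantiles of J per fragment length (exact order statistics)."""
    js = np.asarray(j_values, dtype=float)
    lens = np.asarray(lengths, dtype=int)
    if js.size != lens.size or js.size == 0:
        raise ValueError("j_values and lengths must be nonempty and aligned")
    df = pd.DataFrame({"length_bp": lens, "j_M": js})
    out = (
        df.groupby("length_bp")["j_M"]
        .agg(
            n="size",
            q25=lambda s: s.quantile(0.25),
            median="median",
            q75=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    return out


def local_peak_positions(
    x: Sequence[float],
    y: Sequence[float],
    smooth_window: int = 3,
    min_separation: float = 5.0,
) -> np.ndarray:
    """Positions of local maxima of y(x), with parabolic refinement.

    A light moving-average smooth suppresses sampling noise before peak
    picking; peaks closer than ``min_separation`` keep only the higher one.
    Used to measure the torsional oscillation period of J(L).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 aligned points")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        ypad = np.pad(y, pad, mode="edge")
        y = np.convolve(ypad, kernel, mode="valid")[: x.size]
    peaks = []
    for i in range(1, x.size - 1):
        if y[i] > y[i - 1] and y[i] >= y[i + 1]:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            offset = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
            offset = float(np.clip(offset, -0.5, 0.5))
            dx = x[i + 1] - x[i] if offset >= 0 else x[i] - x[i - 1]
            peaks.append((x[i] + offset * dx, y[i]))
    kept: list[tuple[float, float]] = []
    for pos, height in peaks:
        if kept and pos - kept[-1][0] < min_separation:
            if height > kept[-1][1]:
                kept[-1] = (pos, height)
        else:
            kept.append((pos, height))
    return np.array([p for p, _ in kept])
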