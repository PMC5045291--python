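"""Differential hydrogen/deuterium exchange (HX-MS) between two states.

Per-peptide deuteron uptake tables from a bound and a free sample are
matched on (protein, start, end, sequence) and differenced
(delta = bound - free) at a chosen exposure time. No back-exchange
correction is applied: only relative changes are interpreted, for which raw
and corrected deuteration levels are equivalent. Negative delta means less
uptake in the bound state, i.e. apparent protection.

Deltas are binned into symmetric ordinal classes (protection / no change /
deprotection) and painted onto residues for structure mapping, with the
largest-|delta| covering peptide winning on overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PeptideUptakeRecord",
    "UptakeDifference",
    "DEFAULT_BIN_THRESHOLDS",
    "match_and_difference",
    "classify_bins",
    "residue_paint",
    "coverage_fraction",
    "NO_COVERAGE",
]

#: Deuteron cutoffs for the 7-bin classification (3 protection + neutral +
#: 3 deprotection). Configurable; chosen to mirror a 3-cool/3-warm legend.
DEFAULT_BIN_THRESHOLDS = (0.3, 0.6, 1.0)

#: Sentinel class label for residues covered by no peptide.
NO_COVERAGE = None


@dataclass(frozen=True)
class PeptideUptakeRecord:
    """One peptide's deuteron uptake per exposure time in one sample.

    start/end are 1-based inclusive residue numbers in the full-length
    protein. ``uptake`` maps exposure time (minutes) to weighted-average
    deuterons incorporated.
    """

    protein: str
    start: int
    end: int
    sequence: str
    uptake: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid residue range {self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match range "
                f"{self.start}-{self.end} for {self.protein}")
        max_amides = self.max_exchangeable
        for t, u in self.uptake.items():
            if u < 0:
                raise ValueError(f"negative uptake at {t} min")
            if u > max_amides + 1e-9:
                raise ValueError(
                    f"uptake {u} exceeds exchangeable amides ({max_amides}) "
                    f"for {self.protein} {self.start}-{self.end}")

    @property
    def key(self) -> tuple:
        return (self.protein, self.start, self.end, self.sequence)

    @property
    def max_exchangeable(self) -> int:
        """Exchangeable backbone amides: residues minus prolines minus the N-terminus."""
        return max(len(self.sequence) - self.sequence.count("P") - 1, 0)


@dataclass
class UptakeDifference:
    """Bound-minus-free uptake difference for one matched peptide."""

    protein: str
    start: int
    end: int
    sequence: str
    delta: float
    bin: int | None = None  # signed ordinal class; negative = protection

    @property
    def key(self) -> tuple:
        return (self.protein, self.start, self.end, self.sequence)


def _index(records: Iterable[PeptideUptakeRecord], label: str) -> dict:
    out: dict = {}
    for rec in records:
        if rec.key in out:
            raise ValueError(f"duplicate peptide key {rec.key} in {label} sample")
        out[rec.key] = rec
    return out


def match_and_difference(
    bound: Sequence[PeptideUptakeRecord],
    free: Sequence[PeptideUptakeRecord],
    time: float,
) -> tuple[list[UptakeDifference], dict]:
    """Difference uptake (bound - free) for peptides present in both samples.

    Returns (differences, report); the report counts matched peptides and
    the unmatched peptides excluded from each side.
    """
    bound_idx = _index(bound, "bound")
    free_idx = _index(free, "free")
    common = [k for k in bound_idx if k in free_idx]
    diffs = []
    for k in common:
        ub, uf = bound_idx[k].uptake, free_idx[k].uptake
        if time not in ub or time not in uf:
            raise ValueError(f"exposure time {time} min missing for peptide {k}")
        diffs.append(UptakeDifference(*k, delta=ub[time] - uf[time]))
    report = {
        "matched": len(common),
        "excluded_bound_only": len(bound_idx) - len(common),
        "excluded_free_only": len(free_idx) - len(common),
    }
    return diffs, report


def classify_bins(
    diffs: Sequence[UptakeDifference],
    thresholds: Sequence[float] = DEFAULT_BIN_THRESHOLDS,
) -> list[UptakeDifference]:
    """Assign each delta a signed ordinal bin.

    ``thresholds`` are positive, strictly increasing deuteron cutoffs
    (t1 < t2 < ... < tk), applied symmetrically about zero: |delta| <= t1 is
    the neutral bin 0; t1 < |delta| <= t2 is bin ±1 (sign of delta), etc.;
    |delta| > tk is bin ±k. Negative bins are protection.
    """
    th = np.asarray(thresholds, dtype=float)
    if th.ndim != 1 or th.size == 0 or np.any(th <= 0) or np.any(np.diff(th) <= 0):
        raise ValueError("thresholds must be positive and strictly increasing")
    for d in diffs:
        mag = int(np.searchsorted(th, abs(d.delta), side="left"))
        d.bin = int(np.sign(d.delta)) * mag if mag else 0
    return list(diffs)


def residue_paint(
    diffs: Sequence[UptakeDifference],
    protein_length: int,
    thresholds: Sequence[float] = DEFAULT_BIN_THRESHOLDS,
) -> list:
    """Per-residue class map (length ``protein_length``, 1-based residues at
    index residue-1).

    Each covered residue takes the bin of the largest-|delta| covering
    peptide (ties broken toward the earlier-starting peptide); uncovered
    residues get `NO_COVERAGE`.
    """
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    for d in diffs:
        if d.end > protein_length:
            raise ValueError(
                f"peptide {d.start}-{d.end} exceeds protein length {protein_length}")
    if any(d.bin is None for d in diffs):
        diffs = classify_bins(list(diffs), thresholds)
    paint: list = [NO_COVERAGE] * protein_length
    best_mag = np.full(protein_length, -np.inf)
    for d in sorted(diffs, key=lambda d: (-abs(d.delta), d.start)):
        for i in range(d.start - 1, d.end):
            if abs(d.delta) > best_mag[i]:
                best_mag[i] = abs(d.delta)
                paint[i] = d.bin
    return paint


def coverage_fraction(records: Sequence[PeptideUptakeRecord], protein_length: int) -> float:
    """Fraction of residues covered by at least one peptide (interval union)."""
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    covered = np.zeros(protein_length, dtype=bool)
    for rec in records:
        if rec.end > protein_length:
            raise ValueError(
                f"peptide {rec.start}-{rec.end} exceeds protein length {protein_length}")
        covered[rec.start - 1:rec.end] = True
    return float(covered.sum()) / protein_length
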