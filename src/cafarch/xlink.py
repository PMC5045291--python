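"""Chemical cross-link (XL-MS) filtering, linkage-map construction, and
distance validation against structures.

Cross-link tables are consumed from search-engine exports (one residue pair
per row with a score and an expectation value); the search itself is out of
scope. Confident links are those with score > 20 and expect < 1e-5.
Distance semantics per chemistry: DSS bridges two primary amines through an
11.4 Å spacer arm, giving a Cα–Cα satisfaction threshold of 24 Å once
lysine side chains are accounted for; EDC is zero-length (amine–carboxyl),
threshold 16 Å. Both thresholds are configurable and recorded in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio.SeqUtils import molecular_weight

__all__ = [
    "CrossLinkRecord",
    "LinkageMap",
    "ResidueMap",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_MIN_SCORE",
    "DEFAULT_MAX_EXPECT",
    "filter_crosslinks",
    "build_linkage_map",
    "validate_against_structure",
    "sequence_mass",
]

CHEMISTRIES = ("DSS", "EDC")
DEFAULT_MIN_SCORE = 20.0
DEFAULT_MAX_EXPECT = 1e-5
#: Cα–Cα satisfaction thresholds (Å) per chemistry.
DEFAULT_THRESHOLDS = {"DSS": 24.0, "EDC": 16.0}


@dataclass(frozen=True)
class CrossLinkRecord:
    """One residue-pair linkage with its search statistics."""

    protein_a: str
    res_a: int
    protein_b: str
    res_b: int
    chemistry: str
    score: float
    expect: float
    peptide_a: str = ""
    peptide_b: str = ""

    def __post_init__(self) -> None:
        if self.res_a < 1 or self.res_b < 1:
            raise ValueError("residue numbers are 1-based and must be >= 1")
        if self.chemistry not in CHEMISTRIES:
            raise ValueError(f"chemistry must be one of {CHEMISTRIES}")
        if self.expect < 0:
            raise ValueError("expect value must be nonnegative")

    @property
    def is_intra(self) -> bool:
        return self.protein_a == self.protein_b

    @property
    def pair_key(self) -> tuple:
        """Unordered (protein, residue) endpoint pair plus chemistry."""
        ends = sorted([(self.protein_a, self.res_a), (self.protein_b, self.res_b)])
        return (*ends[0], *ends[1], self.chemistry)


def filter_crosslinks(
    records: Sequence[CrossLinkRecord],
    min_score: float = DEFAULT_MIN_SCORE,
    max_expect: float = DEFAULT_MAX_EXPECT,
) -> tuple[list[CrossLinkRecord], dict]:
    """Keep records with score > min_score AND expect < max_expect
    (strict inequalities). Order is preserved; the report carries counts."""
    kept = [r for r in records if r.score > min_score and r.expect < max_expect]
    report = {
        "input": len(records),
        "kept": len(kept),
        "removed": len(records) - len(kept),
        "min_score": min_score,
        "max_expect": max_expect,
    }
    return kept, report


@dataclass
class LinkageMap:
    """Deduplicated intra/inter linkage map over proteins of known length."""

    lengths: Mapping[str, int]
    links: list = field(default_factory=list)  # dicts with endpoints, chemistry, kind, multiplicity
    tick: int = 50

    @property
    def n_intra(self) -> int:
        return sum(1 for l in self.links if l["kind"] == "intra")

    @property
    def n_inter(self) -> int:
        return sum(1 for l in self.links if l["kind"] == "inter")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.links)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def plot_description(self) -> dict:
        """Plotting-ready description: per-protein bars with tick marks every
        ``tick`` residues and the deduplicated link list."""
        return {
            "proteins": [
                {"name": p, "length": n,
                 "ticks": list(range(self.tick, n + 1, self.tick))}
                for p, n in self.lengths.items()
            ],
            "links": list(self.links),
        }


def build_linkage_map(
    records: Sequence[CrossLinkRecord],
    lengths: Mapping[str, int],
    tick: int = 50,
) -> LinkageMap:
    """Classify links intra/inter and deduplicate identical residue pairs
    (same chemistry) with a multiplicity count."""
    if tick <= 0:
        raise ValueError("tick interval must be positive")
    for r in records:
        for prot, res in ((r.protein_a, r.res_a), (r.protein_b, r.res_b)):
            if prot not in lengths:
                raise ValueError(f"no length provided for protein {prot!r}")
            if res > lengths[prot]:
                raise ValueError(
                    f"residue {prot} {res} beyond protein length {lengths[prot]} "
                    f"in link {r}")
    dedup: dict[tuple, dict] = {}
    for r in records:
        k = r.pair_key
        if k in dedup:
            dedup[k]["multiplicity"] += 1
        else:
            (pa, ra, pb, rb, chem) = k
            dedup[k] = {
                "protein_a": pa, "res_a": ra, "protein_b": pb, "res_b": rb,
                "chemistry": chem,
                "kind": "intra" if pa == pb else "inter",
                "multiplicity": 1,
            }
    return LinkageMap(lengths=dict(lengths), links=list(dedup.values()), tick=tick)


@dataclass(frozen=True)
class ResidueMap:
    """Sequence-to-structure numbering for one protein: the residue numbered
    i in the full-length sequence is chain ``chain``, residue ``i + offset``
    in the structure."""

    chain: str
    offset: int = 0


def validate_against_structure(
    records: Sequence[CrossLinkRecord],
    structure,
    residue_mapping: Mapping[str, ResidueMap],
    thresholds: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cα–Cα distance check of each link against a structure.

    ``residue_mapping`` gives per-protein chain and numbering offset; links
    whose residues are absent from the structure (unmodelled regions or
    unmapped proteins) are flagged ``mapped=False`` and excluded from the
    satisfaction rate. Returns (per-link table, summary).
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    for chem, thr in thresholds.items():
        if thr <= 0:
            raise ValueError(f"threshold for {chem} must be positive")

    ca_by_chain: dict[str, dict] = {}
    rows = []
    for r in records:
        coords = []
        for prot, res in ((r.protein_a, r.res_a), (r.protein_b, r.res_b)):
            rmap = residue_mapping.get(prot)
            if rmap is None:
                coords.append(None)
                continue
            if rmap.chain not in ca_by_chain:
                ca_by_chain[rmap.chain] = structure.ca_coords(chain=rmap.chain)
            coords.append(ca_by_chain[rmap.chain].get(res + rmap.offset))
        mapped = all(c is not None for c in coords)
        dist = float(((coords[0] - coords[1]) ** 2).sum() ** 0.5) if mapped else float("nan")
        thr = thresholds.get(r.chemistry)
        rows.append({
            "protein_a": r.protein_a, "res_a": r.res_a,
            "protein_b": r.protein_b, "res_b": r.res_b,
            "chemistry": r.chemistry, "distance": dist,
            "mapped": mapped,
            "satisfied": bool(mapped and thr is not None and dist <= thr),
        })
    table = pd.DataFrame(rows)
    summary: dict = {"thresholds": thresholds}
    for chem in sorted({r.chemistry for r in records}):
        sub = table[(table.chemistry == chem) & table.mapped]
        summary[chem] = {
            "n_mapped": int(len(sub)),
            "n_satisfied": int(sub.satisfied.sum()),
            "satisfaction_rate": float(sub.satisfied.mean()) if len(sub) else float("nan"),
        }
    return table, summary


def sequence_mass(sequence: str, mode: str = "average") -> float:
    """Mass (Da) of an unmodified peptide/protein: residue masses plus one
    water. ``mode`` is "average" (IUPAC average atomic masses) or
    "monoisotopic"."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    allowed = set("ACDEFGHIKLMNPQRSTVWY")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"unknown amino-acid letter(s): {sorted(bad)}")
    if mode not in ("average", "monoisotopic"):
        raise ValueError("mode must be 'average' or 'monoisotopic'")
    return float(molecular_weight(seq, seq_type="protein",
                                  monoisotopic=(mode == "monoisotopic")))
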