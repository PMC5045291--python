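"""Table and structure readers/writers.

All concentrations are carried in molar units internally; titration tables
may declare nM/µM through their column names. Residue coordinates are
1-based inclusive everywhere. Structures (PDB or mmCIF) are read through
gemmi with author numbering; altlocs are resolved to the highest-occupancy
conformer and waters are excluded by default.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binding import TitrationSeries
from .fluorescence import PolarizedIntensities, Spectrum, anisotropy
from .hxdiff import PeptideUptakeRecord
from .structure import StructureModel, vdw_radius
from .xlink import CrossLinkRecord

__all__ = [
    "read_table",
    "read_titration_csv",
    "read_spectrum_csv",
    "read_lanes_csv",
    "read_uptake_csv",
    "read_xlinks_csv",
    "read_structure",
    "write_json",
]

_UNIT_FACTORS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "nm": 1e-9, "pm": 1e-12}


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


def read_table(path, required: list[str], *, optional_groups: list[list[str]] | None = None,
               sep=None) -> pd.DataFrame:
    """Read a CSV/TSV with case-insensitive header validation.

    ``required`` columns must all be present; each group in
    ``optional_groups`` must be satisfied by at least one of its members.
    Column names are normalised to lower case. Raises `SchemaError` naming
    the missing column, and a row-numbered error for unparseable cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in required:
        if col.lower() not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    for group in optional_groups or []:
        if not any(c.lower() in df.columns for c in group):
            raise SchemaError(f"{path.name}: need one of columns {group}")
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0]) + 2  # header + 1-based
        raise SchemaError(f"{Path(path).name}: unparseable value in column {col!r}, line {row}")
    return vals.to_numpy(dtype=float)


def _titrant_column(df: pd.DataFrame) -> tuple[str, float]:
    for col in df.columns:
        if col.startswith("titrant_"):
            unit = col.split("_", 1)[1]
            if unit in _UNIT_FACTORS:
                return col, _UNIT_FACTORS[unit]
    raise SchemaError("no titrant column with a recognised unit suffix "
                      "(titrant_M, titrant_nM, titrant_uM, ...)")


def read_titration_csv(path, labeled_conc: float) -> TitrationSeries:
    """Titration table: `titrant_M` (or `_nM`/`_uM`) plus either `r` or the
    four polarized-intensity columns i_vv, i_vh, i_hv, i_hh."""
    df = read_table(path, required=[], optional_groups=[["r", "i_vv"]])
    col, factor = _titrant_column(df)
    b = _numeric(df, col, path) * factor
    if "r" in df.columns:
        signal = _numeric(df, "r", path)
    else:
        for c in ("i_vv", "i_vh", "i_hv", "i_hh"):
            if c not in df.columns:
                raise SchemaError(f"{Path(path).name}: missing intensity column {c!r}")
        cols = {c: _numeric(df, c, path) for c in ("i_vv", "i_vh", "i_hv", "i_hh")}
        signal = np.array([
            anisotropy(PolarizedIntensities(vv, vh, hv, hh))
            for vv, vh, hv, hh in zip(cols["i_vv"], cols["i_vh"], cols["i_hv"], cols["i_hh"])
        ])
    order = np.argsort(b)
    return TitrationSeries(labeled_conc=labeled_conc, titrant_concs=b[order],
                           signal=signal[order], meta={"source": str(path)})


def read_spectrum_csv(path, series: str | None = None) -> Spectrum:
    """Spectrum table: columns `wavelength_nm`, `intensity`; long format with
    a `series` column is selected by the ``series`` argument."""
    df = read_table(path, required=["wavelength_nm", "intensity"])
    if series is not None:
        if "series" not in df.columns:
            raise SchemaError(f"{Path(path).name}: no 'series' column for selection")
        df = df[df["series"] == series]
        if df.empty:
            raise SchemaError(f"{Path(path).name}: series {series!r} not found")
    wl = _numeric(df, "wavelength_nm", path)
    inten = _numeric(df, "intensity", path)
    order = np.argsort(wl)
    return Spectrum(wl[order], inten[order])


def read_lanes_csv(path) -> pd.DataFrame:
    """EMSA lane table: lane, idv_tetrasome, idv_tetrasome_bg, idv_disome, idv_disome_bg."""
    cols = ["lane", "idv_tetrasome", "idv_tetrasome_bg", "idv_disome", "idv_disome_bg"]
    df = read_table(path, required=cols)
    for c in cols[1:]:
        df[c] = _numeric(df, c, path)
    return df


def read_uptake_csv(path) -> list[PeptideUptakeRecord]:
    """Uptake table (DynamX-export-like): protein, start, end, sequence,
    exposure_min, uptake_da; one row per (peptide, exposure)."""
    df = read_table(path, required=["protein", "start", "end", "sequence",
                                    "exposure_min", "uptake_da"])
    df["start"] = _numeric(df, "start", path).astype(int)
    df["end"] = _numeric(df, "end", path).astype(int)
    df["exposure_min"] = _numeric(df, "exposure_min", path)
    df["uptake_da"] = _numeric(df, "uptake_da", path)
    records = []
    for key, sub in df.groupby(["protein", "start", "end", "sequence"], sort=False):
        uptake = dict(zip(sub["exposure_min"], sub["uptake_da"]))
        records.append(PeptideUptakeRecord(str(key[0]), int(key[1]), int(key[2]),
                                           str(key[3]), uptake))
    return records


def read_xlinks_csv(path) -> list[CrossLinkRecord]:
    """Cross-link table: protein_a, res_a, protein_b, res_b, chemistry, score, expect."""
    df = read_table(path, required=["protein_a", "res_a", "protein_b", "res_b",
                                    "chemistry", "score", "expect"])
    df["res_a"] = _numeric(df, "res_a", path).astype(int)
    df["res_b"] = _numeric(df, "res_b", path).astype(int)
    df["score"] = _numeric(df, "score", path)
    df["expect"] = _numeric(df, "expect", path)
    return [
        CrossLinkRecord(str(r.protein_a), int(r.res_a), str(r.protein_b), int(r.res_b),
                        str(r.chemistry).upper(), float(r.score), float(r.expect))
        for r in df.itertuples()
    ]


def read_structure(path, *, include_waters: bool = False) -> StructureModel:
    """Read a PDB or mmCIF file into a `StructureModel`.

    Author chain IDs and residue numbers are kept; hydrogens are dropped;
    altlocs resolve to the highest-occupancy conformer; waters excluded
    unless requested.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if not include_waters:
        st.remove_waters()
    best: dict[tuple, tuple[float, tuple]] = {}
    order: list[tuple] = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.element.name == "H":
                        continue
                    key = (chain.name, res.seqid.num, atom.name)
                    occ = float(atom.occ)
                    row = (chain.name, res.seqid.num, res.name, atom.name,
                           atom.element.name.upper(),
                           atom.pos.x, atom.pos.y, atom.pos.z)
                    if key not in best:
                        order.append(key)
                        best[key] = (occ, row)
                    elif occ > best[key][0]:
                        best[key] = (occ, row)
        break  # first model only
    final = [best[k][1] for k in order]
    if not final:
        raise ValueError(f"{path}: no atoms read")
    return StructureModel.from_atoms(final, title=st.name or str(path))


def provenance(config: dict) -> dict:
    import hashlib

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {"package": "cafarch", "version": __version__,
            "config_sha1": hashlib.sha1(blob).hexdigest(), "config": config}


def write_json(path, payload: dict, *, config: dict | None = None) -> None:
    """Write a JSON result with a provenance block (package version, config hash)."""
    out = dict(payload)
    out["provenance"] = provenance(config or {})
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True, default=float) + "\n")
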