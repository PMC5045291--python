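"""Tetrasome-fraction quantification from EMSA band densitometry.

A tetrasome ((H3/H4)2 tetramer on DNA) carries two labeled H3/H4 dimers, so
its fluorescence is twice that of a disome per particle. The molar fraction
of tetrasomes from background-subtracted integrated density values is

    T' = (IDV_tet - IDV_tet_bg) / 2        # fluorescence -> particle units
    D' = IDV_di - IDV_di_bg
    fraction = T' / (T' + D')

The halving is applied to the whole background-subtracted tetrasome signal;
``literal_background_half=True`` reproduces the alternative reading in which
only the background term is halved, for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BandQuant", "fraction_tetrasome", "summarize_lanes"]


@dataclass
class BandQuant:
    """Integrated density values for the two bands and their local backgrounds."""

    idv_tetrasome: float
    idv_tetrasome_bg: float
    idv_disome: float
    idv_disome_bg: float

    def __post_init__(self) -> None:
        if min(self.idv_tetrasome, self.idv_tetrasome_bg,
               self.idv_disome, self.idv_disome_bg) < 0:
            raise ValueError("integrated density values must be nonnegative")


def fraction_tetrasome(b: BandQuant, *, literal_background_half: bool = False) -> float:
    """Molar fraction of tetrasomes in a lane; see module docstring.

    Negative background-subtracted signals are clamped to zero with a warning
    (small bands can undershoot local background).
    """
    if literal_background_half:
        t = b.idv_tetrasome - b.idv_tetrasome_bg / 2.0
    else:
        t = (b.idv_tetrasome - b.idv_tetrasome_bg) / 2.0
    d = b.idv_disome - b.idv_disome_bg
    if t < 0:
        warnings.warn("tetrasome band below local background; clamped to 0", stacklevel=2)
        t = 0.0
    if d < 0:
        warnings.warn("disome band below local background; clamped to 0", stacklevel=2)
        d = 0.0
    total = t + d
    if total == 0:
        raise ValueError("no signal above background in either band")
    return t / total


def summarize_lanes(lanes: pd.DataFrame, *, literal_background_half: bool = False) -> pd.DataFrame:
    """Per-lane tetrasome fractions plus a mean ± sd summary row.

    ``lanes`` columns: lane, idv_tetrasome, idv_tetrasome_bg, idv_disome,
    idv_disome_bg (one row per replicate lane).
    """
    fracs = []
    for _, row in lanes.iterrows():
        bq = BandQuant(row["idv_tetrasome"], row["idv_tetrasome_bg"],
                       row["idv_disome"], row["idv_disome_bg"])
        fracs.append(fraction_tetrasome(bq, literal_background_half=literal_background_half))
    out = lanes[["lane"]].copy()
    out["fraction_tetrasome"] = fracs
    out.attrs["mean"] = float(np.mean(fracs))
    out.attrs["sd"] = float(np.std(fracs, ddof=1)) if len(fracs) > 1 else float("nan")
    return out
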