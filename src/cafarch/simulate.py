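"""Seed-controlled synthetic-data generators.

Each generator produces inputs with the statistical structure its analysis
stage assumes — saturable anisotropy titrations with fluorophore quenching,
donor/acceptor emission spectra with controllable FRET mixing, two-band gel
lanes, peptide-uptake tables with regional protection, and cross-link lists
mixing true contacts with decoys — so the whole pipeline is exercisable
without instrument data. Every generator is a deterministic function of its
parameters and seed, and embeds its ground truth in a metadata side-channel
(never in the analysed columns).
"""

from __future__ import annotations

import math
from typing import Callable, Mapping, Sequence

import numpy as np

from .binding import TitrationSeries, fraction_bound_ligand_depletion
from .fluorescence import SpectraSet, Spectrum
from .emsa import BandQuant
from .hxdiff import PeptideUptakeRecord
from .structure import StructureModel
from .xlink import CrossLinkRecord

__all__ = [
    "default_titrant_grid",
    "gen_titration",
    "gen_spectra",
    "gen_gel",
    "gen_hx_tables",
    "gen_xlinks",
    "gen_ca_structure",
    "fret_efficiency_from_distance",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def default_titrant_grid(kd: float, n: int = 12, span: tuple[float, float] = (0.1, 10.0)) -> np.ndarray:
    """Log-spaced titrant grid spanning ``span`` multiples of kd (default
    0.1–10x, 12 points) — the standard design for a saturable titration."""
    return np.logspace(math.log10(span[0] * kd), math.log10(span[1] * kd), n)


def gen_titration(
    kd: float,
    a_star: float,
    b_grid: Sequence[float] | None = None,
    *,
    f0: float = 0.05,
    fmax: float = 0.10,
    quench_ratio: float = 1.0,
    noise_sd: float = 0.0,
    seed=0,
) -> TitrationSeries:
    """Forward-simulate an anisotropy titration under ligand depletion.

    The observed anisotropy at each point is the intensity-weighted mixture
    of the free (anisotropy f0, intensity 1) and bound (anisotropy f0+fmax,
    intensity ``quench_ratio``) species; quench_ratio < 1 models fluorophore
    quenching on binding. Gaussian noise of sd ``noise_sd`` is added.
    Ground truth is stored in ``series.meta``.
    """
    if quench_ratio <= 0:
        raise ValueError("quench_ratio must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if b_grid is None:
        b_grid = default_titrant_grid(kd)
    b = np.asarray(b_grid, dtype=float)
    if b.ndim != 1 or b.size < 2 or np.any(np.diff(b) <= 0) or np.any(b < 0):
        raise ValueError("b_grid must be a 1-D strictly increasing nonnegative grid")
    rng = _rng(seed)
    frac = np.array([fraction_bound_ligand_depletion(kd, a_star, bi) for bi in b])
    r_free, r_bound = f0, f0 + fmax
    w_bound = frac * quench_ratio
    w_free = 1.0 - frac
    r_obs = (w_free * r_free + w_bound * r_bound) / (w_free + w_bound)
    r_obs = r_obs + rng.normal(0.0, noise_sd, size=b.size)
    return TitrationSeries(
        labeled_conc=a_star, titrant_concs=b, signal=r_obs,
        meta={"truth": {"kd": kd, "f0": f0, "fmax": fmax,
                        "quench_ratio": quench_ratio, "noise_sd": noise_sd}},
    )


def fret_efficiency_from_distance(distance: float, r0: float = 52.0) -> float:
    """Förster efficiency E = 1 / (1 + (d/R0)^6); R0 defaults to 52 Å
    (the CPM–FM donor–acceptor pair)."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    return 1.0 / (1.0 + (distance / r0) ** 6)


def gen_spectra(
    efficiency: float | None = None,
    *,
    distance: float | None = None,
    r0: float = 52.0,
    grid: Sequence[float] | None = None,
    donor_center: float = 470.0,
    donor_width: float = 25.0,
    donor_amp: float = 1.0,
    acceptor_center: float = 520.0,
    acceptor_width: float = 18.0,
    acceptor_amp: float = 1.0,
    donor_scale_in_dual: float = 0.8,
    noise_sd: float = 0.0,
    seed=0,
) -> SpectraSet:
    """Gaussian-band emission spectra with controllable FRET mixing.

    The dual-labeled donor-excited spectrum contains the donor band (scaled
    by ``donor_scale_in_dual``) plus the acceptor band at ``efficiency``
    times its direct-excitation amplitude, so the acceptor-enhancement
    extraction should recover ``efficiency`` exactly in the noiseless case.
    Give either ``efficiency`` in [0, 1] or a donor–acceptor ``distance``.
    """
    if (efficiency is None) == (distance is None):
        raise ValueError("give exactly one of efficiency or distance")
    if distance is not None:
        efficiency = fret_efficiency_from_distance(distance, r0)
    if not (0.0 <= efficiency <= 1.0):
        raise ValueError("efficiency must lie in [0, 1]")
    wl = np.arange(400.0, 600.0 + 0.5, 1.0) if grid is None else np.asarray(grid, dtype=float)
    rng = _rng(seed)

    def gauss(center, width, amp):
        return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)

    donor_band = gauss(donor_center, donor_width, donor_amp)
    acceptor_band = gauss(acceptor_center, acceptor_width, acceptor_amp)

    def noisy(y):
        return y + rng.normal(0.0, noise_sd, size=wl.size) if noise_sd > 0 else y

    return SpectraSet(
        donor_only_ex_d=Spectrum(wl, noisy(donor_band)),
        dual_ex_d=Spectrum(wl, noisy(donor_scale_in_dual * donor_band
                                     + efficiency * acceptor_band)),
        dual_ex_a=Spectrum(wl, noisy(acceptor_band)),
        meta={"truth": {"efficiency": efficiency, "r0": r0,
                        "donor_scale_in_dual": donor_scale_in_dual}},
    )


def gen_gel(
    molar_tetrasome_fraction: float,
    *,
    total_particles: float = 1000.0,
    per_dimer_intensity: float = 10.0,
    backgrounds: tuple[float, float] = (500.0, 500.0),
    noise_frac: float = 0.0,
    seed=0,
) -> BandQuant:
    """Two-band gel densitometry from a known molar tetrasome fraction.

    Tetrasomes carry two labeled dimers, so the tetrasome band fluorescence
    is 2 x (molar tetrasome amount) x (per-dimer intensity); the disome band
    is 1x. Local backgrounds are added to each band; multiplicative Gaussian
    noise of fractional sd ``noise_frac`` perturbs the band signals.
    """
    f = molar_tetrasome_fraction
    if not (0.0 <= f <= 1.0):
        raise ValueError("molar_tetrasome_fraction must lie in [0, 1]")
    if total_particles < 0 or per_dimer_intensity < 0:
        raise ValueError("totals must be nonnegative")
    rng = _rng(seed)
    tet_signal = 2.0 * f * total_particles * per_dimer_intensity
    di_signal = (1.0 - f) * total_particles * per_dimer_intensity
    if noise_frac > 0:
        tet_signal *= 1.0 + rng.normal(0.0, noise_frac)
        di_signal *= 1.0 + rng.normal(0.0, noise_frac)
    bg_t, bg_d = backgrounds
    return BandQuant(
        idv_tetrasome=max(tet_signal, 0.0) + bg_t,
        idv_tetrasome_bg=bg_t,
        idv_disome=max(di_signal, 0.0) + bg_d,
        idv_disome_bg=bg_d,
    )


def _tile_peptides(protein_length: int, peptide_length: int, step: int):
    starts = list(range(1, max(protein_length - peptide_length + 2, 2), step))
    out = []
    for s in starts:
        e = min(s + peptide_length - 1, protein_length)
        if e - s + 1 >= 3:
            out.append((s, e))
    return out


def gen_hx_tables(
    protein_length: int,
    *,
    protein: str = "Cac1",
    protection_profile: Callable[[int], float] | Mapping[int, float] | None = None,
    peptide_length: int = 15,
    step: int = 10,
    times: Sequence[float] = (30.0, 60.0),
    noise_sd: float = 0.0,
    seed=0,
) -> tuple[list[PeptideUptakeRecord], list[PeptideUptakeRecord]]:
    """Bound/free peptide-uptake tables with a known protection footprint.

    Peptides tile the protein (length ``peptide_length``, step ``step``);
    free-state uptake per peptide is drawn uniformly between 30% and 70% of
    its exchangeable amides; bound-state uptake adds the mean of
    ``protection_profile`` (deuterons, negative = protection) over the
    peptide's residues. Identical peptide keys appear in both tables.
    """
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    rng = _rng(seed)
    if protection_profile is None:
        profile = lambda r: 0.0  # noqa: E731
    elif callable(protection_profile):
        profile = protection_profile
    else:
        mapping = dict(protection_profile)
        profile = lambda r: mapping.get(r, 0.0)  # noqa: E731
    aas = "ADEFGHIKLMNQRSTVWY"  # proline-free so every residue can exchange
    seq_full = "".join(rng.choice(list(aas), size=protein_length))
    bound, free = [], []
    for s, e in _tile_peptides(protein_length, peptide_length, step):
        seq = seq_full[s - 1:e]
        n_amides = len(seq) - 1
        base = rng.uniform(0.3, 0.7) * n_amides
        delta = float(np.mean([profile(r) for r in range(s, e + 1)]))
        f_uptake, b_uptake = {}, {}
        for t in times:
            # slower times see a modest uptake increase toward the plateau
            tf = 1.0 - 0.5 * math.exp(-t / 30.0)
            uf = base * tf + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            ub = uf + delta + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            f_uptake[t] = float(np.clip(uf, 0.0, n_amides))
            b_uptake[t] = float(np.clip(ub, 0.0, n_amides))
        free.append(PeptideUptakeRecord(protein, s, e, seq, f_uptake))
        bound.append(PeptideUptakeRecord(protein, s, e, seq, b_uptake))
    return bound, free


def gen_ca_structure(n_res: int, *, chain: str = "A", seed=0,
                     step: float = 3.8, compactness: float = 0.1) -> StructureModel:
    """Synthetic Cα-only chain: a self-avoiding-ish random walk with ~3.8 Å
    steps, biased back toward the centroid so the fold is compact. Useful as
    a stand-in structure for cross-link distance tests."""
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    rng = _rng(seed)
    coords = [np.zeros(3)]
    for _ in range(n_res - 1):
        d = rng.normal(size=3)
        centroid = np.mean(coords, axis=0)
        d = d / np.linalg.norm(d) - compactness * (coords[-1] - centroid) / max(
            np.linalg.norm(coords[-1] - centroid), 1.0)
        d = d / np.linalg.norm(d)
        coords.append(coords[-1] + step * d)
    atoms = [(chain, i + 1, "ALA", "CA", "C", *coords[i]) for i in range(n_res)]
    return StructureModel.from_atoms(atoms, title=f"synthetic {n_res}-residue CA chain")


def gen_xlinks(
    structure: StructureModel,
    protein: str,
    n_true: int,
    n_decoy: int,
    *,
    chemistry: str = "DSS",
    threshold: float = 24.0,
    decoy_margin: float = 6.0,
    min_seq_sep: int = 5,
    seed=0,
) -> tuple[list[CrossLinkRecord], dict]:
    """Cross-link list mixing true contacts with decoys.

    True links are residue pairs whose Cα–Cα distance is within
    ``threshold`` (and pass score/expect filtering); decoys are pairs beyond
    ``threshold + decoy_margin`` and are additionally given failing search
    statistics. Ground-truth labels are returned separately.
    """
    if n_true < 0 or n_decoy < 0:
        raise ValueError("n_true and n_decoy must be nonnegative")
    rng = _rng(seed)
    ca = structure.ca_coords()
    resnums = sorted(ca)
    close, far = [], []
    for i, ri in enumerate(resnums):
        for rj in resnums[i + 1:]:
            if rj - ri < min_seq_sep:
                continue
            d = float(np.linalg.norm(ca[ri] - ca[rj]))
            if d <= threshold:
                close.append((ri, rj))
            elif d > threshold + decoy_margin:
                far.append((ri, rj))
    if len(close) < n_true or len(far) < n_decoy:
        raise ValueError(
            f"insufficient eligible pairs (close {len(close)}, far {len(far)})")
    true_pairs = [close[i] for i in rng.choice(len(close), size=n_true, replace=False)]
    decoy_pairs = [far[i] for i in rng.choice(len(far), size=n_decoy, replace=False)]
    records, labels = [], []
    for ra, rb in true_pairs:
        records.append(CrossLinkRecord(
            protein, ra, protein, rb, chemistry,
            score=float(rng.uniform(25.0, 45.0)),
            expect=float(10.0 ** rng.uniform(-9.0, -6.0))))
        labels.append(True)
    for ra, rb in decoy_pairs:
        records.append(CrossLinkRecord(
            protein, ra, protein, rb, chemistry,
            score=float(rng.uniform(5.0, 15.0)),
            expect=float(10.0 ** rng.uniform(-4.0, -1.0))))
        labels.append(False)
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    labels = [labels[i] for i in order]
    return records, {"is_true": labels, "threshold": threshold, "chemistry": chemistry}
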