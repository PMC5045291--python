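# cafarch

Quantitative analysis of histone-chaperone/histone architecture, built
around the biophysics of the yeast CAF-1 complex and its H3/H4 cargo:
equilibrium binding titrations read out by fluorescence anisotropy, FRET
and pyrene-excimer spectroscopy of histone tetramerization, EMSA
densitometry of tetrasome deposition, differential hydrogen/deuterium
exchange (HX-MS), chemical cross-link (XL-MS) maps with structural distance
validation, and the structural metrics (SASA, buried interface area,
superposition RMSD) used to characterize the Cac1 winged-helix homodimer.

It is aimed at structural biochemists who have instrument-level tables
(titration CSVs, emission spectra, gel densitometry, peptide-uptake
exports, cross-link search results, PDB/mmCIF coordinates) and want the
downstream numbers — dissociation constants, FRET Effects, tetrasome
fractions, protection maps, link-satisfaction rates — with the numerical
conventions made explicit and testable. A seed-controlled synthetic-data
module generates statistically faithful inputs for every stage, so the
whole pipeline is exercised end to end without any instrument data.

## The core model

Binding titrations are fitted with the one-site isotherm with **ligand
depletion**: the labeled tracer A\* is held at a concentration comparable
to K_D, so the bound fraction at total titrant concentration [B] is the
root of the mass-balance quadratic

```
f_bound = ((K_D + [A*] + [B]) − sqrt((K_D + [A*] + [B])² − 4·[A*]·[B])) / (2·[A*])
```

and the observed anisotropy is `F = F0 + Fmax · f_bound`. The fit is a
weighted nonlinear least squares over (K_D, F0, Fmax) with multi-start
initialization; titrations that never constrain the upper plateau are
reported as **not calculable** ("n.c.") rather than as a number. When
binding quenches the fluorophore by more than 10%, observed anisotropies
are first corrected for the intensity weighting using the free/saturated
endpoint anisotropies and intensities. A coupled-equilibrium solver for
chaperone + 1–2 histone dimers competing with free-histone tetramerization
(`solve_coupled_equilibrium`) verifies when the one-site reduction is
valid.

## Worked example

Fit a synthetic homo-dimerization titration (10 nM labeled tracer,
ground-truth K_D = 26 nM, anisotropy noise sd 0.005):

```python
from cafarch.simulate import gen_titration
from cafarch.binding import LigandDepletionModel

series = gen_titration(2.6e-8, 10e-9, noise_sd=0.005, seed=7)
res = LigandDepletionModel(series).fit()
print(res.summary())
```

```
One-site ligand-depletion binding fit
=============================================
n points           : 12
[A*] (fixed)       : 1e-08 M
status             : ok
Kd                 : 2.849e-08 M  (se 4.9e-09)
f0                 : 0.04925  (se 0.0027)
fmax               : 0.1035  (se 0.0037)
residual ssq       : 0.000109
```

The fitted K_D (28.5 nM) recovers the generating 26 nM within its standard
error; F0 and Fmax recover the free-tracer anisotropy (0.05) and the
binding-induced amplitude (0.10). A single noisy titration scatters around
the truth — the acceptance analysis below uses the median over 100 seeds.

The same objects work from files: `cafarch fit-kd --input titration.csv
--labeled-conc 1e-8 --out fit.json`, with analogous subcommands for the
other stages (`fret`, `emsa`, `hx-diff`, `xlink-filter`, `xlink-map`,
`xlink-validate`, `sasa`, `interface`, `superpose`, `mass`, `simulate`).

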