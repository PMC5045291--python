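# Methods

This note documents the models, numerical conventions, and design choices
behind each analysis stage, and what the synthetic-data generators do and
do not emulate.

## Binding isotherms with ligand depletion

Anisotropy titrations of a labeled tracer A\* (held at 5–25 nM, comparable
to the dissociation constants being measured) cannot use the hyperbolic
free-ligand approximation. The bound fraction is the physical root of the
quadratic mass balance for A + B ⇌ AB, evaluated in the conjugate form
`2[B]/(s + sqrt(s² − 4[A*][B]))` with `s = K_D + [A*] + [B]` to avoid
catastrophic cancellation when `[A*] ≪ K_D + [B]`. The signal model is
`F = F0 + Fmax·f_bound`. K_D = 0 is accepted as the stoichiometric limit.

Fitting (`LigandDepletionModel.fit`) is nonlinear least squares (lmfit,
Levenberg–Marquardt) over (K_D, F0, Fmax) with [A\*] fixed. F0 is fitted,
not pinned to a constant, so both raw and normalized anisotropy inputs
work. Initialization is multi-start: K_D starts at the titrant
concentration of half-maximal signal and at ±1 decade around it plus the
grid extremes; the best-χ² solution wins. Bounds enforce K_D > 0.

**Not-calculable criterion.** A titration that never reaches saturation
does not constrain Fmax, and K_D trades off freely against it. A fit is
reported "n.c." when the estimated K_D exceeds the highest titrant
concentration, or the relative standard error of K_D exceeds 50%, or the
optimizer fails. This mirrors how weak-affinity titrations are reported in
practice: a status, not a number.

**Quench correction.** Binding that changes the fluorophore intensity
biases the observed anisotropy toward the brighter species. When the
endpoint intensities differ by more than 10% (`quench_flag`), the
correction inverts the intensity weighting given the free/saturated
anisotropies (A_f, A_b) and intensities (Q_f, Q_b); it is an algebraic
identity at Q_f = Q_b and is exact for a two-state mixture (property-tested
by generating mixtures and inverting). The observed-equals-saturated input
is singular and rejected with a message naming the endpoint.

**Coupled equilibria.** The scheme C + D ⇌ CD (K1), CD + D ⇌ CD2 (K2),
D + D ⇌ T (Ktet) is solved by root-finding on the two free concentrations
in log space (positivity by construction), starting at 10% of the totals,
with a small deterministic grid of fallback starts; convergence requires
relative conservation residuals < 1e-9. When tetramerization is negligible
and the second site is shut off, the solution collapses to the closed-form
quadratic — this is the regime that justifies the one-site apparent-K_D
fits, since K1 and K2 are not separately identifiable from a single
titration.

Concentrations are molar everywhere internally; readers accept nM/µM
through column-name suffixes (`titrant_nM` etc.).

## FRET Effect (acceptor enhancement)

The FRET Effect is F_385/F_491: acceptor emission extracted from the
dual-labeled spectrum under donor-band excitation, normalized by acceptor
emission under direct excitation (robust to acceptor quenching by binding
partners). The donor-only spectrum is fitted to the dual-labeled spectrum
by a single least-squares scale over a **donor-fit window** (default
400–480 nm, where acceptor emission is negligible for the CPM/FM-like band
layout), subtracted, and the residual integrated (trapezoid) over the
**acceptor window** (default 500–560 nm). Windows are configurable because
instrument band positions vary; integrated areas are used instead of
single-wavelength peaks for noise robustness. Spectra on different grids
are linearly interpolated to the dual-labeled grid. F_491 ≤ 0 is an error;
a negative extracted integral beyond tolerance is reported with a warning,
not silently clipped.

The extraction is exact (to machine precision) when the acceptor band does
not leak into the donor-fit window; with realistically overlapping
CPM/FM-like default bands the recovery error of the mixing coefficient is
a few tenths of a percent.

The pyrene excimer readout is the mean intensity in a ±5 nm window around
465 nm over the same-width window around the 375 nm monomer band; two pyrenes within
~10 Å produce the excimer band, so the ratio reports local conformation.

## EMSA tetrasome quantification

A tetrasome carries two labeled H3/H4 dimers, a disome one; fluorescence
is therefore converted to molar particle units by halving the
background-subtracted tetrasome signal before forming
`T′/(T′ + D′)`. The halving applies to the whole background-subtracted
term; the alternative literal reading (halving only the background) is
available as `literal_background_half=True` for comparison. Negative
background-subtracted bands are clamped to zero with a warning. Replicate
lanes are summarized as mean ± sd.

## Differential HX-MS

Per-peptide deuteron uptake tables for two states are matched on the full
key (protein, start, end, sequence) — the sequence string guards against
coordinate collisions between different digests — and differenced
(bound − free) at one exposure time; unmatched peptides are excluded and
counted. No back-exchange correction is applied: only relative changes are
interpreted, for which raw and corrected levels are equivalent. Duplicate
keys within a sample are an input error.

Deltas are classed into 2k+1 ordinal bins by symmetric thresholds
(default ±0.3, ±0.6, ±1.0 deuterons, giving 7 bins; configurable since
legend cutoffs are conventions, not physics). Negative delta = protection.
Residue painting assigns each covered residue the bin of the
largest-|delta| covering peptide (conservative highlighting of the
strongest signal; ties break toward the earlier-starting peptide);
uncovered residues carry a distinct no-coverage label. Coverage is the
interval-union fraction.

## Cross-links

Search-engine exports are filtered at score > 20 AND expect < 1e-5 (strict
inequalities, record-level values). Maps deduplicate identical unordered
residue pairs per chemistry with a multiplicity count and tag links
intra/inter; tick marks every 50 residues support the standard linkage
figure. Distance validation uses Cα–Cα distances with per-chemistry
thresholds, default DSS ≤ 24 Å (11.4 Å spacer plus two lysine side chains)
and EDC ≤ 16 Å (zero-length chemistry) — standard XL-MS practice values,
recorded in output metadata and fully configurable. Sequence-to-structure
numbering is an explicit per-protein (chain, offset) map; links touching
unmodelled residues are flagged unmapped and excluded from satisfaction
rates rather than counted as violations. Peptide/protein masses sum IUPAC
average (or monoisotopic) residue masses plus one water, via Biopython.

## Structural metrics

SASA is Shrake–Rupley on a **deterministic Fibonacci sphere lattice**
(default 960 points, probe 1.4 Å): no RNG, exactly reproducible, and
refinable by raising the point count (coarse-vs-dense agreement is within
1%). Radii are the Bondi van der Waals set (C 1.70, N 1.55, O 1.52,
S 1.80 Å; fallback 1.70 Å); hydrogens are dropped on reading. Exactly
coincident equal spheres are counted once (the later duplicate is buried),
which makes the degenerate superposed-copies case well defined. Because
the lattice is fixed in space, SASA under rigid motion agrees only to
sampling tolerance (≲1% at 960 points).

Buried interface area reports both conventions — ΔSASA_total =
SASA(A) + SASA(B) − SASA(AB) and its per-interface half — since published
interface numbers use either. Symmetry mates are supplied as explicit
rigid transforms (`RigidTransform`, validated orthonormal with det +1) or
pre-expanded coordinates; space-group expansion is out of scope.

Superposition is the Kabsch SVD solution with reflections excluded, over
atoms matched by (residue number, atom name) after an optional numbering
offset, optionally restricted to an atom-name selection. Fewer than 3
matches or a collinear set is an error. RMSD is cross-checked in tests
against SciPy's `Rotation.align_vectors`.

## Synthetic data: what it does and does not emulate

Generators are deterministic functions of (parameters, seed) with ground
truth embedded only in metadata. Defaults reflect the study conditions the
analyses assume: titrations use 12 log-spaced points spanning 0.1–10× K_D
with tracer anisotropy baseline 0.05, amplitude 0.10, and Gaussian noise
sd 0.005 (typical pyrene anisotropy scales and instrument noise); spectra
use Gaussian CPM/FM-like bands (donor 470/25 nm, acceptor 520/18 nm) with
the acceptor amplitude in the donor-excited dual spectrum equal to the
FRET efficiency times its direct-excitation amplitude (E = 1/(1+(d/R0)⁶),
R0 = 52 Å); gels implement the 2× tetrasome stoichiometry; HX tables tile
proline-free random sequences with 15-residue peptides at 10-residue
steps; cross-link lists draw true contacts within the chemistry threshold
with passing statistics and decoys beyond it with failing statistics, on a
compact synthetic Cα chain.

Not emulated: heteroscedastic or correlated instrument noise, inner-filter
and photobleaching effects, spectral baseline drift, gel smearing and band
detection (densitometry values are inputs), isotope-envelope processing
and back-exchange in HX, and the MS2 search itself. Passing tests
therefore demonstrate correctness of the analysis algebra and estimators
under the stated noise model, not robustness to every instrument artifact.

## Problem sizes

The acceptance analysis uses 100 seeded titrations per affinity value (12
points each), chosen to make the median estimator stable to a few percent;
SASA oracles use 10⁴-point dense lattices on 1–2-atom systems and 960
points on synthetic chains of tens of residues. The public crystallographic
accessions (5JBM and its molecular-replacement search model, and the
full-length Cac1 database sequence) are not redistributed here; the buried
interface area, superposition RMSD, and fragment-mass operations accept
any PDB/mmCIF and FASTA-derived sequence, so those published numbers can
be recomputed directly once the accessions are downloaded.

## Known limitations

- Single-curve fits only: no global multi-construct fitting, no kinetics.
- K1 and K2 of the coupled scheme are not separately identifiable from a
  one-dimensional titration; only the apparent K_D is reported.
- The fitted-K_D estimator shows a small (~3–5%) downward median bias at
  noise sd 0.005 under ligand depletion; it is well within the accepted
  recovery tolerance and shrinks with noise.
- HX deltas carry no significance testing; bins are descriptive.
- Cross-link satisfaction is a geometric check on a static model; it does
  not account for conformational ensembles.
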