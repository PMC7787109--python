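# Methods

This note documents the models, conventions and numerical choices behind
`em-table1`, what the synthetic generator does and does not emulate, and the
known limitations of each metric.

## Admission filters

An entry (model + map + optional half-maps + resolution metadata) is
screened by eight independent filters; all are evaluated and every violation
is reported:

| Code | Condition |
|---|---|
| `NO_MODEL` | the bundle has no atomic model |
| `RESOLUTION_MISMATCH` | no unique resolution value common to model and map metadata (agreement tolerance 0.01 Å, since reported values carry 0.1–0.01 Å precision) |
| `HALFMAP_GRID_MISMATCH` | half-map grid sampling or cell differs from the full map |
| `BOX_MISMATCH` | model cell absent, degenerate (any edge ≤ 2 Å), or differing from the map cell by > 0.5 Å on any edge |
| `PROCESS_FAILURE` | a reader failed; the failure is carried into the verdict rather than raised |
| `ENSEMBLE_MODEL` | more than one coordinate set in the model file |
| `SINGLE_ATOM_FRACTION` | more than 25% of residues consist of a single atom (Cα- or P-trace models) |
| `RESOLUTION_TOO_LOW` | consensus resolution worse than 5 Å |

The "nonsensical dimensions" arm of the box filter is not quantified
anywhere authoritative; the ≤ 2 Å degeneracy rule is this package's
operational stand-in (a 1 Å cell is the canonical real-world example of the
pathology). MRC headers carry no resolution, so the map-side value comes
from a JSON sidecar (`{"reported_resolutions": [...]}`) standing in for
repository-level metadata; the model side is read from mmCIF
reconstruction/refinement items or PDB REMARK 2/3 records, keeping every
distinct value found.

## Map handling

Maps are read through gemmi and canonicalized so the in-memory grid is
always indexed along the cell X/Y/Z axes regardless of the file's
MAPC/MAPR/MAPS permutation. The origin is taken from the ORIGIN header
record, falling back to start-index × voxel size when ORIGIN is all zero.
Only orthogonal cells are supported by the Fourier metrics and density
synthesis (cryo-EM boxes are orthogonal in practice); non-90° angles are
accepted at read time but rejected by the synthesis step.

## Density synthesis

A model map is the sum over atoms of occupancy-weighted isotropic Gaussians.
Element shapes use the Peng five-Gaussian electron form factors
(f(s) = Σ aᵢ exp(−bᵢ s²/4), gemmi's bundled table); in real space each term
is a normalized Gaussian of width bᵢ + B, so the atomic B factor enters as
exact Gaussian blurring and the box integral of an atom equals f(0) = Σ aᵢ
independent of B. Atom footprints are truncated where the Gaussian exponent
exceeds 30 (relative error < 10⁻¹³ of the peak) and wrap periodically, the
natural convention on an FFT grid. Band-limiting is a sharp Fourier cutoff
at s = 1/d. Elements missing from the form-factor table raise an error; an
explicit flag substitutes carbon instead.

## Resolution estimates

**FSC / d_FSC.** Shells are of equal frequency width from 0 to the smallest
per-axis Nyquist, N/2 shells for the largest grid dimension N by default;
the DC term is excluded. The crossing frequency at a threshold (0.143 for
half-maps; 0.5 also reported) is linearly interpolated between shell
centers. A curve that never crosses reports the Nyquist resolution (twice
the voxel size) — the sampling, not the data, is then the limit.

**d_99.** Candidate cutoffs are scanned from Nyquist toward coarse in steps
of 0.05 in 1/d; the result is the coarsest d at which the low-passed map
still correlates at ≥ 0.99 with the original. Because the low-passed map
shares its retained coefficients with the original, that correlation equals
√(P_in/P_total) by Parseval's theorem (DC excluded), which is how it is
evaluated; a test confirms the identity against the literal real-space
computation. Fourier coefficients beyond the per-axis Nyquist sphere (the
"corners") count toward P_total: a map whose corners carry real power (e.g.
unfiltered noise) can therefore never score better than Nyquist, which is
the honest answer.

**d_model.** A model map is synthesized once from the deposited B factors,
then a grid search over cutoffs d ∈ [max(1.0, 2·voxel), 10.0] Å in 0.1 Å
steps low-passes it and scores CC_mask against the experimental map; the
argmax is d_model, ties breaking toward finer d. No overall-B re-sharpening
search is performed alongside the cutoff search; this is a deliberate
simplification and is echoed into report provenance. When the optimum
CC_mask is below 0.2 the estimate is flagged unreliable — a model that does
not sit in its density cannot date-stamp the map's resolution.

## Map–model correlation

CC_box is the Pearson correlation over every voxel. CC_mask restricts it to
a hard union of spheres of radius 2.5 Å around non-hydrogen atoms, evaluated
at grid nodes. The fixed radius is deterministic and configurable
(`--mask-radius`); resolution-dependent radii used elsewhere are not
replicated. Per-residue CC uses each residue's own sphere union; per-chain
CC is computed over the union of its residues' masks — not the mean of
per-residue values — separately for protein and ligand/water residues. A
residue whose mask is empty reports an absent value, never zero. The model
map used for CC is truncated at the consensus resolution.

## Geometry indicators

**Connectivity** comes from per-residue heavy-atom templates, with peptide
bonds added where C(i)–N(i+1) < 1.8 Å, disulfides where SG–SG < 2.5 Å, and
hydrogens (when present) attached to the nearest heavy atom within 1.3 Å.
Unknown residues keep their atoms with no template bonds and are counted as
unmatched in the RMS statistics.

**Restraint dictionary.** Backbone and Cβ ideals are fixed Engh–Huber-style
constants (N–CA 1.458, CA–C 1.525, C–O 1.231, CA–CB 1.536 Å; N–CA–C 111.0°,
CA–C–O 120.8°, N–CA–CB 110.5°, C–CA–CB 110.1°; peptide C–N 1.329 Å,
CA–C–N 116.2°, C–N–CA 121.7°, O–C–N 123.0°). Side-chain bond and angle
ideals for the 20 amino acids are measured once from the idealized residue
coordinates of the Chemical Component Dictionary bundled with biotite.
Sigmas are class-based: 0.02 Å / 2.0° for side-chain items, tighter
published values for the backbone. RMSZ is √mean((obs−ideal)/σ)². Nucleic
acids and ligands are skipped and reported in the unmatched counts.

**Cβ deviations.** The ideal Cβ is reconstructed from N, CA, C by
intersecting the two cones that make the ideal N–CA–CB and C–CA–CB angles
(the same constants as the dictionary, so the two subsystems agree exactly)
and taking the L-configuration branch; a residue counts when the observed
Cβ is more than 0.25 Å away.

**Clashscore** counts pairs of van der Waals spheres overlapping by more
than 0.4 Å, per 1000 atoms, excluding pairs fewer than four bonds apart in
the connectivity graph. Atoms are scored *as given*: no hydrogens are added
(the canonical MolProbity clashscore adds them with Reduce first), so
absolute values are not bit-compatible with MolProbity on H-free models;
reports carry an `h_present` flag to make the regime explicit. Radii:
C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å (configurable table).

**Minimum non-bonded distance** excludes 1-2 and 1-3 pairs only. Both
pairwise scans use a k-d tree whose results are verified against O(n²)
brute-force oracles in the test suite.

## Ramachandran statistics and Rama-Z

The reference is a probability table on the (φ, ψ) torus at 2° × 2°
resolution for three residue classes (general, glycine, proline),
materialized from a fixed analytic mixture of wrapped Gaussians centered on
the classical basins (α, β/extended, polyproline-II, left-handed α, plus
diffuse shoulders). Favored and allowed contour levels enclose 0.98 and
0.9995 of the probability mass respectively; residues are scored by
bilinear interpolation on the torus and classified against those levels.
Chain termini and residues not peptide-bonded to both neighbors have no
φ or ψ and are excluded from the denominator.

This reference is deliberately coarser than the Top8000-derived MolProbity
tables — three classes instead of six, smooth analytic basins instead of
empirical densities — so favored/allowed percentages are comparable in
spirit but not digit-for-digit with MolProbity output.
`RamaReference.from_tables` accepts drop-in replacement tables of the same
shape for users who need higher fidelity.

Rama-Z compares the observed mean per-residue log-probability with its
Monte Carlo null: B = 500 pseudo-models of the same size and class
composition are drawn from the reference itself and the Z-score is
(m_obs − μ_null)/σ_null. The calibration is cached per composition, so
repeated scoring is cheap; models with fewer than 10 scorable residues
return an absent value. Bands: |Z| < 2 good, 2–3 suspicious, > 3 poor. Note
that the score is two-sided by construction: a model whose dihedrals all sit
on a single point — however favored that point — scores a large *positive*
Z, because a one-point distribution is itself improbable. The ideal helix
fixture exhibits exactly this.

## Synthetic generator

`build_polyala` constructs a poly-alanine chain by internal-coordinate
chaining from the dictionary's own ideals (helix default φ = −57°,
ψ = −47°, ω = 180°; B = 30 Å², unit occupancy), so deviation metrics are
zero by construction. `synthesize_entry` centers the model in a cubic box,
computes the Gaussian-atom density, and adds two independent noise draws
whose per-shell power follows the signal-to-noise model FSC = λ/(λ+1): λ(s)
crosses 0.143/(1−0.143) at the planned resolution with an exponential
fall-off (slope 8 per fractional frequency, steep enough that the crossing
interpolates within one shell). The deposited full map is the half-map
average low-passed at the nominal resolution, as reconstruction packages
do before deposition. Everything is deterministic given the seed.

The fixtures emulate metric-relevant structure only: there is no CTF,
detector or solvent physics, no masking artifacts, no anisotropy and no
non-uniform local resolution. Passing tests therefore demonstrate that the
estimators recover planted ground truth under ideal assumptions — not that
they are robust to every pathology of experimental reconstructions.

Default problem sizes: 40 Å boxes at 1 Å voxels (40³ grids) and 20-residue
helices, which make the full acceptance computation run in seconds while
keeping ≥ 8 Fourier shells below the planned crossing.

## Other conventions and degenerate inputs

- Alternate locations: the first-listed conformer per atom name is used for
  every metric; others are ignored.
- Assembly expansion appends `_<operator index>` to chain ids; a single
  identity operator returns the model unchanged; singular operator matrices
  raise.
- Constant (zero-variance) maps make every correlation undefined and raise,
  as do empty atom masks and models with no matchable restraints.
- Curation never raises on content problems — all failure modes are verdict
  codes; only unreadable files raise, and the CLI converts those into
  `PROCESS_FAILURE` verdicts.

## Limitations

Rotamer outliers, CaBLAM and EMRinger are not computed (each needs a large
external reference library); the report marks them explicitly, including
EMRinger's better-than-4 Å applicability rule. Clashscore differs from
MolProbity on hydrogen-free models as described above. The Ramachandran
reference is a coarse analytic stand-in. d_model omits the B-sharpening
search. Metrics are computed on periodic grids; models must lie inside
their box for masks to be meaningful.
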