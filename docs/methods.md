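# Methods

## Scope and model

`amide2d` computes amide-I vibrational spectra of short single-chain
peptides from backbone coordinates alone.  The chain of N residues carries
N−1 amide-I oscillators (one per peptide bond); the unit between residues
i and i+1 is labelled by residue i+1 throughout, so a 20-mer produces
tables running Trp2…Thr20.  The model has three layers: a one-exciton
Hamiltonian, its two-exciton extension, and third-order response theory
for the rephasing photon echo.

### One-exciton Hamiltonian

* **Site energies.** ε_m = ε₀ + isotope shift + disorder.  ε₀ = 1660 cm⁻¹
  places the computed bands in the experimentally familiar 1600–1700 cm⁻¹
  window; it is a convention, not a fitted value.  Isotope labelling
  (¹³C/¹⁸O) shifts a labelled unit by −65 cm⁻¹.  Solvent and conformational
  microheterogeneity enter as i.i.d. Gaussian diagonal disorder of standard
  deviation σ_ε (cm⁻¹), drawn freshly per ensemble member from a seeded
  generator.
* **Nearest-neighbour coupling.** Units sharing a residue are coupled by a
  tabulated surface J(φ, ψ) evaluated at the shared residue's dihedrals,
  interpolated bilinearly and periodically from a packaged 30° grid.  The
  packaged table is a smooth synthetic surface,
  J = 2.7 + 10.2·cos(φ+ψ−76°) cm⁻¹, calibrated so the α-helical basin gives
  ≈ −7.5 cm⁻¹ and the extended/β basin ≈ +4.5 cm⁻¹ — the sign structure
  that reproduces the known amide-I phenomenology (strong red-shifted ν⊥
  band in antiparallel sheets, red-shifted helix band).  Any TSV with
  columns phi/psi/J can replace it.
* **Long-range coupling.** All non-adjacent pairs couple through
  point-dipole TDC, J = 5034·κ·|μ|²/r³ cm⁻¹ (μ in D, r in Å), with the
  transition dipole of magnitude 0.37 D placed 0.868 Å from the carbonyl C
  along C=O and tilted 20° toward the amide N in the O=C–N plane.  Nearest
  neighbours do **not** additionally receive TDC (no double counting).
  Point-dipole TDC is known to be unreliable below ~4 Å; compact coil
  geometries can therefore produce occasional outlier couplings of tens of
  cm⁻¹, which appear as weak outlying bands.

### Two-exciton block and anharmonicity

Pair states |m≤n⟩ (dimension N(N+1)/2) carry energies ε_m+ε_n, with the
doubly excited |mm⟩ lowered by the anharmonicity Δ (default 16 cm⁻¹, the
standard amide-I value).  Couplings follow the harmonic single-quantum-move
convention: ⟨mm|H|mn⟩ = √2·J_mn, ⟨mn|H|mk⟩ = J_nk, disjoint pairs
uncoupled.  With Δ = 0 the two-exciton eigenvalues are exactly all pairwise
sums of one-exciton eigenvalues (verified numerically in the tests), and
the photon-echo signal cancels identically — the observable 2D signal is
purely an anharmonicity effect.

### Response functions

The kI = −k₁+k₂+k₃ signal at t₂ = 0 is a sum over Liouville pathways:
GSB and SE over one-exciton pairs (e, e′) (positive), ESA over (e, e′, f)
(negative), each a product of a complex Lorentzian in ω₁ at the bra
coherence E_e and one in ω₃ at E_e′ (GSB/SE) or E_f − E_e (ESA), with
half-width γ = Γ/2 (Γ is the Lorentzian FWHM).  Orientational averaging
uses the isotropic all-parallel fourth-rank formula
(1/15)[(a·b)(c·d)+(a·c)(b·d)+(a·d)(b·c)] over the four pathway dipoles;
one→two-exciton dipoles carry harmonic √2 factors consistent with the
two-exciton block.  Axes are displayed on positive grids in the
(ω₁, −ω₃) table convention; the default grid is 1580–1720 cm⁻¹.

**Displayed component.** Pure rephasing spectra are phase twisted; their
raw real/imaginary parts carry dispersive sidelobes reaching ~12% of the
peak, which defeats fractional-threshold peak picking.  The default
display is therefore the signed magnitude sign(Re C)·|C| (bleach positive,
ESA negative, smooth |C| surface for peak detection); `real`, `imag` and
`abs` are available via `ResponseSettings.component`.  Note that a
coupled-dimer cross peak is intrinsically a GSB/ESA doublet split by the
exciton-induced combination-band shift; when that shift is comparable to
Γ the two lobes resolve as separate extrema — peak counts are therefore a
function of (Δ, J, Γ), not artifacts.

**Oracle.** `brute_force_response` recomputes the same signal for ≤4 sites
by numerical time propagation: per-step matrix exponentials of the shifted
(rotating-frame) one- and two-exciton Hamiltonians, damping e^{−γt} per
coherence interval, Simpson quadrature against e^{∓iωt} (default
dt = 2.5·10⁻⁴ (cm⁻¹)⁻¹ radians, propagated until the coherence envelope
decays to 10⁻⁹).  It shares no code path with the closed-form Lorentzian
sum and agrees with it to better than 10⁻⁶ relative.

## Synthetic ensembles

The generator replaces undeposited MD trajectories.  Backbones are built
by sequential internal-coordinate placement (N–CA 1.458, CA–C 1.525,
C–N 1.329, C=O 1.231 Å; ω = 180°), with the amide H reconstructed on the
external bisector at N–H = 1.02 Å.  The five Beta3s conformers use
canonical templates — strand (−139, 135), helix (−57, −47), 3₁₀ (−49, −26),
type-I/I′ two-residue turns — with strand pairing chosen per conformer:
native ladders (5,8), (3,10), 12→1, (13,16), (11,18), (9,20); Ns-or and
Cs-or shift the N-/C-terminal strand pairing by two residues; Ch-curl
keeps only the C-terminal hairpin plus a 3₁₀ N-terminal curl; the 6-12
helix is helical at residues 6–12 exactly and coil elsewhere.  Because
ideal dihedral templates alone do not close hydrogen bonds, a
deterministic L-BFGS refinement minimizes deviations of designated N···O
(2.9 Å) and reconstructed-H···O (1.9 Å) distances with a soft CA–CA clash
guard and a weak pull toward the template dihedrals.  Residue 1 donates no
H-bond (it has no amide hydrogen), so its pairing enters as the single
directed bond 12→1.

Ensembles are n seeded Gaussian-jittered copies (default σ_coord = 0.05 Å
per coordinate, n = 500 as the study condition; the bundled pipeline
default uses n = 50 to keep a full run in minutes).  Members whose jitter
pushes a peptide-bond length outside the amide-unit validity window
(≈3σ events) are redrawn from the same stream, preserving reproducibility.
What the generator does **not** emulate: solvent structure and
electrostatic site-shift maps, side chains, force-field relaxation, or
correlated backbone motions — so passing tests demonstrate the spectral
machinery and its structure sensitivity, not force-field realism.

## Conformational fingerprints

Hydrogen bonds use the Kabsch–Sander electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with the
−0.5 kcal/mol threshold (pairs closer than 0.5 Å are treated as clashes,
not bonds).  The reduced secondary-structure assignment covers residues
2…N−1 (termini have undefined φ/ψ), alphabet {H, G, E, T, S, ~}, priority
H > G > E > T > S: H and G from ≥2 consecutive 4-/3-turns, E from
parallel/antiparallel bridge ladders with isolated bridges folded into E,
T from *isolated* turns, S from CA-pentad bends (>70°).  A turn whose
H-bond is simultaneously a bond of an accepted bridge ladder (the 4→1 bond
of a tight hairpin turn) is not isolated and yields no T — this reading is
what lets a hydrogen-bonded hairpin show the published `…SS…` turn pattern
rather than `…TT…`.  π-helices are not assigned.

Q is the fraction of reference CA–CA contacts (6.7 Å cutoff, |i−j| ≥ 3)
present in the query; the contact definition stands in for the original
NOE-based criterion, whose constraint list is not public.  Rg is the
unweighted RMS backbone-atom distance from the centroid; SASA is
Shrake–Rupley with 960 deterministic golden-spiral points, probe 1.4 Å and
vdW radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / H 1.20 Å (rotating a
structure re-samples the spheres, so SASA is rigid-motion invariant only
to the ~1% sampling error).  RMSD superposes N/CA/C/O atoms by Kabsch;
quintile representatives sort members by RMSD to the centroid member
(ties by index), split into five contiguous blocks differing by ≤1 in
size (larger blocks first), and return each block's floor-median member.

Conformation matching is Hamming distance between secondary-structure
strings with a default tolerance of 3 mismatches (~80% identity); an
ambiguous tie raises rather than guessing.  The synthetic conformers
reproduce the published strings at 18/18 (native), 15/18 (Ns-or, Cs-or,
Ch-curl) and 13/18 (6-12 helix, whose construction follows the
residues-6–12 definition rather than the longer published helix) —
intermediate conformers are genuinely intermediate, and their best match
can fall on a neighbouring reference string.

## NMD and peaks

C_mn = Σ_k v_k(m)² v_k(n)² is symmetric with unit row sums (a direct
consequence of eigenvector orthonormality) and tends to the identity as
couplings vanish.  The alternative reading (Σ_k v_k(m)v_k(n))² collapses
to the identity by orthogonality and was rejected.  Residue↔mode
frequencies use maximum-weight bipartite matching on v_k(m)² rather than
per-residue argmax, guaranteeing a bijection (one frequency per residue).
Peaks are strict 8-neighbourhood maxima of |amplitude| above 5% of the
global maximum; diagonal means |ω₁−ω₃| ≤ 2 cm⁻¹; assignment accepts a
residue pair only when both NMD frequencies lie within 3 cm⁻¹ of the peak
coordinates.  Peak-list comparison is greedy nearest matching within
tolerance (ascending distance, ties by lower ω₁), each peak matched once.

## Pipeline, determinism, problem sizes

The master seed fans out to per-stage seeds through one seeded generator
(recorded in the run log), so stages are independently reproducible and
re-runs are bit-identical.  Default problem sizes — 5 conformers × 50
members, Γ ∈ {1, 5, 10} cm⁻¹, 1D step 0.5 cm⁻¹, 2D step 1.0 cm⁻¹ — were
chosen so a complete run takes a few minutes on one core; the ensemble
size of 500 used for the study conditions is available by configuration.
Oracle cross-validation is restricted to ≤4 sites where the time-domain
propagation is exact and cheap.

## Known limitations

* Hamiltonian defaults are community conventions; absolute peak positions
  of published tables derived from unpublished parameter sets are not
  reproducible and are not targeted.
* Point-dipole TDC misbehaves at short range (see above).
* Only the rephasing (kI) signal at t₂ = 0 is implemented; no
  non-rephasing or absorptive combinations, no waiting-time dynamics.
* The DSSP reduction omits π-helices and chirality/extended DSSP features;
  it is not a drop-in replacement for the reference implementation.
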