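# amide2d

Amide-I exciton Hamiltonians, simulated one- and two-dimensional infrared
photon-echo spectra, normal-mode-decomposition (NMD) peak assignment, and
conformational fingerprinting for short peptide ensembles — built around the
folding intermediates of the 20-residue three-stranded β-sheet mini-protein
**Beta3s** (Thr1-Trp2-Ile3-…-Thr20).

The package is for computational spectroscopists and structural
bioinformaticians who want to relate peptide backbone conformation to
amide-I band structure: which conformations a 2D IR experiment could
distinguish, and which residue pairs produce which cross peaks.

## The model

Each of the 19 peptide bonds contributes one local amide-I oscillator.  The
one-exciton (Local Amide) Hamiltonian is

```
H_mn = ε_m δ_mn + J_mn (1 − δ_mn)
```

with site energies ε_m = ε₀ + isotope shifts + Gaussian solvent disorder
(ε₀ = 1660 cm⁻¹ by default), nearest-neighbour couplings taken from a
packaged (φ, ψ) map evaluated at the shared residue's backbone dihedrals,
and all longer-range couplings from transition-dipole coupling
J = κ μ²/r³.  Doubly excited states live in the pair basis |m≤n⟩ with a
diagonal anharmonic shift Δ on |mm⟩ (16 cm⁻¹ by default); with Δ = 0 the
two-exciton spectrum is exactly all pairwise sums of one-exciton energies
and the photon-echo signal cancels identically.

Linear absorption is a sum of Lorentzians of FWHM Γ over the one-exciton
states.  The rephasing photon-echo signal kI = −k₁+k₂+k₃ at waiting time
t₂ = 0 is computed by sum over states: ground-state bleach and stimulated
emission over state pairs (e, e′), excited-state absorption over
(e, e′, f) with opposite sign, each weighted by the isotropic all-parallel
orientational average and displayed on the (ω₁, −ω₃) plane.  A brute-force
time-domain propagation oracle validates the SOS engine to 1e-6 on small
systems.

NMD diagonalizes H, assigns one frequency per residue (maximum-weight
bipartite matching on squared eigenvector weights) and forms the 19×19
coupling-contribution map C_mn = Σ_k v_k(m)² v_k(n)², whose rows sum to 1.

Conformations are fingerprinted with a reduced Kabsch–Sander secondary
structure string (alphabet H, G, E, T, S, ~; 18 characters for the
20-mer), the fraction-of-native-contacts Q (CA–CA contacts at 6.7 Å),
radius of gyration, and Shrake–Rupley SASA.  A synthetic-structure
generator builds the five Beta3s conformers (native sheet, Ns-or, Cs-or,
Ch-curl, 6-12 helix) from dihedral templates refined so the designed
backbone hydrogen bonds actually form, and emulates MD/solvent
heterogeneity with seeded Gaussian coordinate jitter plus site-energy
disorder.

## Worked example

```python
from amide2d.synthetic import (make_beta3s_conformers, perturb_ensemble,
                               EnsembleNoiseModel)
from amide2d.metrics import dssp_string, contact_map, q_score
from amide2d.hamiltonian import HamiltonianParams, build_hamiltonian
from amide2d.spectra import (SpectralGrid, ResponseSettings,
                             ensemble_spectrum)

native = make_beta3s_conformers(0)["Native"]
print(dssp_string(native))          # EEEESSEEEEEESSEEEE
print(q_score(native, contact_map(native)))   # 1.0

h = build_hamiltonian(native, HamiltonianParams())
print(h.matrix.shape)               # (19, 19)

ens = perturb_ensemble(native, EnsembleNoiseModel(sigma_coord=0.05,
                                                  n=100, seed=10))
spec = ensemble_spectrum(ens, HamiltonianParams(),
                         SpectralGrid(1580, 1720, 0.5),
                         ResponseSettings(gamma_fwhm=10.0), kind="1d")
```

The native conformer's secondary-structure string is the full
three-stranded antiparallel pattern `EEEESSEEEEEESSEEEE`; its Q against its
own 28-contact map is 1.0.  The ensemble 1D spectrum at Γ = 10 cm⁻¹ shows
the classic antiparallel β-sheet band pair — a dominant ν⊥ band at
1631 cm⁻¹ and a weaker ν∥ band at 1675.5 cm⁻¹ (68% relative height) —
whereas the 6-12 helix ensemble's two strongest bands lie only
6.5 cm⁻¹ apart (1637 and 1643.5 cm⁻¹).  Picking peaks from the native 2D kI spectrum at
Γ = 5 cm⁻¹ yields 2 diagonal and 9 cross features, which
`amide2d.nmd.assign_peaks` maps to residue pairs via the NMD frequency
table (Trp2 … Thr20).

The whole analysis — five conformers → ensembles → fingerprints → 1D/2D
spectra at Γ ∈ {1, 5, 10} cm⁻¹ → NMD tables → peak assignment → native
vs intermediate peak comparison — runs from one command:

```
amide2d pipeline --seed 0 --out results_dir
```

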