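"""Normal-mode decomposition (NMD), 2D peak picking and peak assignment.

NMD diagonalizes the one-exciton Hamiltonian and reads the result two ways:

* per-residue frequencies — each amide site is matched bijectively to one
  eigenmode by maximum-weight bipartite matching on the squared eigenvector
  weights v_k(m)², giving the one-frequency-per-residue table used to
  assign peaks to residues;
* a residue–residue coupling-contribution matrix
  C_mn = Σ_k v_k(m)² v_k(n)², symmetric, entries in [0, 1], rows summing to
  one — the map of which residue pairs share delocalized modes.

Peaks are local maxima of |amplitude| in the 2D spectrum above a fractional
threshold, classified diagonal/cross by |ω1 − ω3|; cross peaks are assigned
to the residue pair whose NMD frequencies are nearest (ω1, ω3) within a
tolerance.  Peak lists from two conformations are compared by greedy
nearest matching to give shared / reference-only / other-only partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .hamiltonian import ExcitonHamiltonian
from .spectra import Spectrum2D

__all__ = [
    "NMDResult",
    "Peak",
    "PeakList",
    "PeakAssignment",
    "nmd_decompose",
    "residue_frequency_table",
    "pick_peaks_2d",
    "assign_peaks",
    "compare_peak_lists",
]


@dataclass
class NMDResult:
    eigenvalues: np.ndarray         # ascending, cm⁻¹
    eigenvectors: np.ndarray        # columns = modes
    coupling: np.ndarray            # C_mn, (N, N)
    site_frequencies: np.ndarray    # per-site assigned frequency, cm⁻¹


@dataclass
class Peak:
    omega1: float
    omega3: float
    amplitude: float
    kind: str                       # "diagonal" | "cross"


@dataclass
class PeakList:
    peaks: list[Peak]
    threshold_frac: float
    diag_tol: float

    @property
    def cross(self) -> list[Peak]:
        return [p for p in self.peaks if p.kind == "cross"]

    @property
    def diagonal(self) -> list[Peak]:
        return [p for p in self.peaks if p.kind == "diagonal"]


@dataclass
class PeakAssignment:
    rows: list[tuple[float, float, str, str]]   # (ω1, ω3, residue A, residue B)


def nmd_decompose(h1: ExcitonHamiltonian | np.ndarray) -> NMDResult:
    """Eigen-decomposition with coupling contributions and site frequencies."""
    matrix = h1.matrix if isinstance(h1, ExcitonHamiltonian) else np.asarray(h1, dtype=float)
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("Hamiltonian must be symmetric")
    evals, evecs = np.linalg.eigh(matrix)
    w = evecs ** 2                          # w[m, k] = v_k(m)²
    coupling = w @ w.T
    # bijective residue↔mode assignment maximizing total squared weight
    rows, cols = linear_sum_assignment(-w)
    site_freq = np.empty(matrix.shape[0])
    site_freq[rows] = evals[cols]
    return NMDResult(eigenvalues=evals, eigenvectors=evecs,
                     coupling=coupling, site_frequencies=site_freq)


def residue_frequency_table(nmd: NMDResult, labels: list[str],
                            ndigits: int = 0) -> list[tuple[str, float]]:
    """Rows (residue label, frequency) — one per amide unit, N-side labels."""
    if len(labels) != len(nmd.site_frequencies):
        raise ValueError("label count must equal Hamiltonian dimension")
    return [(lab, round(float(f), ndigits))
            for lab, f in zip(labels, nmd.site_frequencies)]


def pick_peaks_2d(spectrum: Spectrum2D, threshold_frac: float = 0.05,
                  diag_tol: float = 2.0) -> PeakList:
    """Local maxima of |amplitude| over 8-neighbourhoods above threshold."""
    if not (0.0 < threshold_frac < 1.0):
        raise ValueError("threshold_frac must lie in (0, 1)")
    if diag_tol <= 0:
        raise ValueError("diag_tol must be positive")
    a = np.abs(spectrum.amplitude)
    peaks: list[Peak] = []
    vmax = a.max()
    if vmax == 0.0:
        return PeakList(peaks=[], threshold_frac=threshold_frac, diag_tol=diag_tol)
    omega = spectrum.grid.omega
    n1, n3 = a.shape
    for i in range(1, n1 - 1):
        for j in range(1, n3 - 1):
            v = a[i, j]
            if v < threshold_frac * vmax:
                continue
            patch = a[i - 1:i + 2, j - 1:j + 2].copy()
            patch[1, 1] = -np.inf
            if v > patch.max():
                kind = "diagonal" if abs(omega[i] - omega[j]) <= diag_tol else "cross"
                peaks.append(Peak(float(omega[i]), float(omega[j]),
                                  float(spectrum.amplitude[i, j]), kind))
    return PeakList(peaks=peaks, threshold_frac=threshold_frac, diag_tol=diag_tol)


def assign_peaks(peaks: PeakList, table: list[tuple[str, float]],
                 tol: float = 3.0) -> PeakAssignment:
    """Nearest-frequency residue assignment of each peak within tolerance."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    labels = [lab for lab, _ in table]
    freqs = np.array([f for _, f in table])
    rows = []
    for p in peaks.peaks:
        i = int(np.argmin(np.abs(freqs - p.omega1)))
        j = int(np.argmin(np.abs(freqs - p.omega3)))
        ok1 = abs(freqs[i] - p.omega1) <= tol
        ok3 = abs(freqs[j] - p.omega3) <= tol
        if ok1 and ok3:
            rows.append((p.omega1, p.omega3, labels[i], labels[j]))
        else:
            rows.append((p.omega1, p.omega3, "", ""))
    return PeakAssignment(rows=rows)


def compare_peak_lists(reference: PeakList, other: PeakList, tol: float = 3.0
                       ) -> tuple[list[tuple[Peak, Peak]], list[Peak], list[Peak]]:
    """Greedy nearest matching within tol in both coordinates.

    Returns (shared pairs, reference-only, other-only); each peak is matched
    at most once; candidate matches are taken in ascending distance order,
    ties broken by lower ω1.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    candidates = []
    for i, p in enumerate(reference.peaks):
        for j, q in enumerate(other.peaks):
            if abs(p.omega1 - q.omega1) <= tol and abs(p.omega3 - q.omega3) <= tol:
                dist = np.hypot(p.omega1 - q.omega1, p.omega3 - q.omega3)
                candidates.append((dist, p.omega1, i, j))
    candidates.sort()
    used_ref: set[int] = set()
    used_other: set[int] = set()
    shared = []
    for _, _, i, j in candidates:
        if i in used_ref or j in used_other:
            continue
        used_ref.add(i)
        used_other.add(j)
        shared.append((reference.peaks[i], other.peaks[j]))
    ref_only = [p for i, p in enumerate(reference.peaks) if i not in used_ref]
    other_only = [q for j, q in enumerate(other.peaks) if j not in used_other]
    return shared, ref_only, other_only
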