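"""Linear absorption and kI photon-echo (rephasing) 2D spectra.

The third-order signal emitted along kI = −k1 + k2 + k3 is computed by sum
over states (SOS) at waiting time t2 = 0 with Lorentzian lineshapes of FWHM
Γ (internal half width γ = Γ/2).  Three Liouville pathway families
contribute: ground-state bleach (GSB) and stimulated emission (SE) over
one-exciton pairs (e, e′), both positive, and excited-state absorption
(ESA) over (e, e′, f) with opposite sign, where f runs over the two-exciton
manifold.  Each pathway contributes a product of a complex Lorentzian in
ω1 (at the t1 bra coherence frequency E_e) and in ω3 (at E_e′ for GSB/SE,
E_f − E_e for ESA), weighted by the isotropic all-parallel fourth-rank
orientational average (1/15)[(a·b)(c·d) + (a·c)(b·d) + (a·d)(b·c)] of the
four pathway transition dipoles.

Axes are displayed on positive frequency grids, the ω1 axis relabelled from
its physically negative rephasing coherence (the usual (ω1, −ω3) table
convention); the displayed component defaults to ``signed_abs``
(sign(Re C)·|C|), which keeps 0→1 features positive, 1→2 features negative
and avoids the dispersive sidelobes of the raw phase-twisted components.

``brute_force_response`` provides an independent small-system oracle: it
propagates the same three-pulse response numerically in the time domain
(matrix exponentials per time step over the 0/1/2-exciton manifolds,
exponential damping γ per coherence interval) and Fourier-transforms
t1 → ω1, t3 → ω3 by Simpson quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .hamiltonian import (
    ExcitonHamiltonian,
    HamiltonianParams,
    NNCouplingMap,
    TwoExcitonHamiltonian,
    build_hamiltonian,
    two_exciton_block,
)
from .structures import StructureEnsemble

__all__ = [
    "SpectralGrid",
    "ResponseSettings",
    "Spectrum1D",
    "Spectrum2D",
    "one_exciton_states",
    "two_exciton_dipoles",
    "linear_absorption",
    "kI_2d_spectrum",
    "brute_force_response",
    "ensemble_spectrum",
]


@dataclass
class SpectralGrid:
    """Frequency axis (cm⁻¹); for 2D spectra the (ω1, ω3) product grid."""

    start: float = 1580.0
    stop: float = 1720.0
    step: float = 0.5

    def __post_init__(self) -> None:
        if not (self.start < self.stop and self.step > 0):
            raise ValueError("require start < stop and step > 0")

    @property
    def omega(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 0.5 * self.step, self.step)

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.stop)


_COMPONENTS = ("signed_abs", "real", "imag", "abs")


@dataclass
class ResponseSettings:
    """Lineshape and display settings for the photon-echo calculation."""

    gamma_fwhm: float = 5.0
    t2: float = 0.0
    component: str = "signed_abs"

    def __post_init__(self) -> None:
        if self.gamma_fwhm <= 0:
            raise ValueError("Γ (FWHM) must be positive")
        if self.t2 != 0.0:
            raise ValueError("only t2 = 0 is supported")
        if self.component not in _COMPONENTS:
            raise ValueError(f"component must be one of {_COMPONENTS}")

    @property
    def gamma(self) -> float:
        """Lorentzian half width at half maximum."""
        return 0.5 * self.gamma_fwhm


@dataclass
class Spectrum1D:
    grid: SpectralGrid
    intensity: np.ndarray
    gamma_fwhm: float
    n_members: int = 1

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < -1e-12):
            raise ValueError("1D intensity must be finite and non-negative")


@dataclass
class Spectrum2D:
    grid: SpectralGrid
    amplitude: np.ndarray       # (n_ω1, n_ω3), signed real
    gamma_fwhm: float
    component: str = "signed_abs"
    n_members: int = 1

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("2D amplitude must be finite")


@dataclass
class ExcitonStates:
    """Eigen-decomposition of the one-exciton Hamiltonian with state dipoles."""

    energies: np.ndarray        # ascending, cm⁻¹
    vectors: np.ndarray         # columns = eigenvectors
    dipoles: np.ndarray         # (N, 3) state transition dipoles, D


def one_exciton_states(h1: ExcitonHamiltonian | np.ndarray,
                       dipoles: np.ndarray | None = None) -> ExcitonStates:
    """Diagonalize H1; state dipoles are M_k = Σ_m v_k(m) μ_m."""
    if isinstance(h1, ExcitonHamiltonian):
        matrix = h1.matrix
        dipoles = h1.dipoles if dipoles is None else dipoles
    else:
        matrix = np.asarray(h1, dtype=float)
        if dipoles is None:
            raise ValueError("site dipoles required for a bare matrix")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("Hamiltonian must be symmetric")
    energies, vectors = np.linalg.eigh(matrix)
    state_dip = vectors.T @ np.asarray(dipoles, dtype=float)
    return ExcitonStates(energies=energies, vectors=vectors, dipoles=state_dip)


def two_exciton_dipoles(states: ExcitonStates, h2: TwoExcitonHamiltonian,
                        site_dipoles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One→two exciton transition dipoles μ_{e→f}.

    Harmonic √2 scaling on doubly excited sites, consistent with the
    two-exciton block convention.  Returns (f energies, array (Nf, Ne, 3)).
    """
    e2, v2 = np.linalg.eigh(h2.matrix)
    n = states.vectors.shape[0]
    mu = np.asarray(site_dipoles, dtype=float)
    # site-basis creation amplitudes: <pair (m,n)| B†_m |site k>
    dim2 = len(h2.pairs)
    up = np.zeros((dim2, n, 3))     # pair p, one-exciton site k -> dipole vec
    for p, (m, k) in enumerate(h2.pairs):
        if m == k:
            up[p, m] += np.sqrt(2.0) * mu[m]
        else:
            up[p, m] += mu[k]
            up[p, k] += mu[m]
    # rotate into both eigenbases
    mu_ef = np.einsum("pf,pkx,ke->fex", v2, up, states.vectors)
    return e2, mu_ef


def linear_absorption(states: ExcitonStates, grid: SpectralGrid,
                      gamma_fwhm: float) -> Spectrum1D:
    """A(ω) = Σ_k |M_k|² (Γ/2) / [(ω − E_k)² + (Γ/2)²]."""
    if gamma_fwhm <= 0:
        raise ValueError("Γ must be positive")
    if len(states.energies) == 0:
        raise ValueError("no states")
    gamma = 0.5 * gamma_fwhm
    omega = grid.omega
    strengths = np.sum(states.dipoles ** 2, axis=1)
    a = np.zeros_like(omega)
    for ek, sk in zip(states.energies, strengths):
        a += sk * gamma / ((omega - ek) ** 2 + gamma ** 2)
    return Spectrum1D(grid=grid, intensity=a, gamma_fwhm=gamma_fwhm)


def _iso4(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float | np.ndarray:
    """Isotropic all-parallel orientational average of four dipole vectors."""
    return (np.dot(a, b) * np.dot(c, d)
            + np.dot(a, c) * np.dot(b, d)
            + np.dot(a, d) * np.dot(b, c)) / 15.0


def _display(c: np.ndarray, component: str) -> np.ndarray:
    if component == "real":
        return c.real
    if component == "imag":
        return c.imag
    if component == "abs":
        return np.abs(c)
    # signed magnitude; the sign is ±1 everywhere (Re = 0 counts as +) so
    # |amplitude| remains the smooth magnitude surface
    return np.where(c.real >= 0.0, 1.0, -1.0) * np.abs(c)


def kI_2d_spectrum(h1: ExcitonHamiltonian, h2: TwoExcitonHamiltonian | None = None,
                   grid: SpectralGrid | None = None,
                   settings: ResponseSettings | None = None,
                   anharmonicity: float | None = None) -> Spectrum2D:
    """Sum-over-states kI (rephasing) 2D spectrum at t2 = 0."""
    grid = grid or SpectralGrid()
    settings = settings or ResponseSettings()
    if h2 is None:
        if anharmonicity is None:
            raise ValueError("provide h2 or anharmonicity")
        h2 = two_exciton_block(h1, anharmonicity)
    states = one_exciton_states(h1)
    if h2.matrix.shape[0] != states.energies.size * (states.energies.size + 1) // 2:
        raise ValueError("two-exciton block inconsistent with H1 dimension")
    e2, mu_ef = two_exciton_dipoles(states, h2, h1.dipoles)
    e1 = states.energies
    m1 = states.dipoles
    gamma = settings.gamma
    omega = grid.omega
    ne = len(e1)

    # complex Lorentzians; ω1 axis displayed positive (relabelled rephasing axis)
    l1 = 1.0 / (gamma + 1j * (omega[:, None] - e1[None, :]))          # (nw, ne)
    l3_one = 1.0 / (gamma - 1j * (omega[:, None] - e1[None, :]))      # (nw, ne)

    # GSB + SE amplitude over (e, e'): A[e, e']
    dots = m1 @ m1.T
    amp_gs = (dots.diagonal()[:, None] * dots.diagonal()[None, :]
              + 2.0 * dots ** 2) * (2.0 / 15.0)
    c = l1 @ amp_gs @ l3_one.T

    # ESA: -Σ_{e,e',f} F(e,e',f) L1_e L3_{f-e}; pathway dipole order is
    # (M_e, M_e', μ_{e'→f}, μ_{e→f})
    for e in range(ne):
        a = m1[e]                 # (3,)
        b = m1                    # (ne', 3)
        cvec = mu_ef              # (nf, ne', 3) = μ_{e'→f}
        d = mu_ef[:, e, :]        # (nf, 3) = μ_{e→f}
        term_ab_cd = (b @ a)[None, :] * np.einsum("fx,fex->fe", d, cvec)
        term_ac_bd = np.einsum("fex,x->fe", cvec, a) * (d @ b.T)
        term_ad_bc = (d @ a)[:, None] * np.einsum("ex,fex->fe", b, cvec)
        f_esa = (term_ab_cd + term_ac_bd + term_ad_bc) / 15.0    # (nf, ne')
        l3_esa = 1.0 / (gamma - 1j * (omega[:, None] - (e2[None, :] - e1[e])))
        c -= np.outer(l1[:, e], l3_esa @ f_esa.sum(axis=1))
    amp = _display(c, settings.component)
    return Spectrum2D(grid=grid, amplitude=amp, gamma_fwhm=settings.gamma_fwhm,
                      component=settings.component)


# ---------------------------------------------------------------------------
# brute-force time-domain oracle

def brute_force_response(h1: ExcitonHamiltonian, h2: TwoExcitonHamiltonian | None = None,
                         grid: SpectralGrid | None = None,
                         settings: ResponseSettings | None = None,
                         anharmonicity: float | None = None,
                         dt: float = 2.5e-4, decay_to: float = 1e-9) -> Spectrum2D:
    """Numerical time-domain propagation of the kI response (≤ 4 sites).

    Independent of the SOS path: the three pathway families are evolved with
    per-step matrix exponentials of the one- and two-exciton Hamiltonians in
    the site basis, damped by e^{−γt} per coherence interval, and transformed
    with Simpson quadrature against e^{∓iωt}.
    """
    grid = grid or SpectralGrid()
    settings = settings or ResponseSettings()
    if h1.n_sites > 4:
        raise ValueError("oracle limited to 4 sites")
    if h2 is None:
        if anharmonicity is None:
            raise ValueError("provide h2 or anharmonicity")
        h2 = two_exciton_block(h1, anharmonicity)
    gamma = settings.gamma
    w0 = grid.center
    n1 = h1.n_sites
    m1 = h1.matrix - w0 * np.eye(n1)
    m2 = h2.matrix - 2.0 * w0 * np.eye(h2.matrix.shape[0])
    mu = h1.dipoles                      # (n1, 3): 0→1 dipole block columns
    # 1→2 block in the site basis with harmonic factors: D2[p, k, x]
    d2 = np.zeros((len(h2.pairs), n1, 3))
    for p, (m, k) in enumerate(h2.pairs):
        if m == k:
            d2[p, m] += np.sqrt(2.0) * mu[m]
        else:
            d2[p, m] += mu[k]
            d2[p, k] += mu[m]

    tmax = -np.log(decay_to) / gamma
    nt = int(np.ceil(tmax / dt))
    if nt % 2 == 1:
        nt += 1                          # Simpson needs an even interval count
    t = np.arange(nt + 1) * dt
    g1 = expm(-1j * m1 * dt)
    g2 = expm(-1j * m2 * dt)
    u1 = np.empty((nt + 1, n1, n1), dtype=complex)
    u2 = np.empty((nt + 1, len(h2.pairs), len(h2.pairs)), dtype=complex)
    u1[0] = np.eye(n1)
    u2[0] = np.eye(len(h2.pairs))
    for k in range(nt):
        u1[k + 1] = g1 @ u1[k]
        u2[k + 1] = g2 @ u2[k]

    weights = np.ones(nt + 1)
    weights[1:-1:2] = 4.0
    weights[2:-1:2] = 2.0
    weights *= dt / 3.0
    damp = np.exp(-gamma * t) * weights

    omega = grid.omega - w0
    # transform kernels: bra (t1) side pairs e^{-iωt} with the conjugated
    # coherence, ket (t3) side uses e^{+iωt}
    ker1 = damp[None, :] * np.exp(-1j * np.outer(omega, t))     # (nw, nt+1)
    ker3 = damp[None, :] * np.exp(+1j * np.outer(omega, t))

    # bra history: A[t, x, :] = U1(t) mu_x; P = ∫ A* e^{-iωt} e^{-γt} dt
    a_t = np.einsum("tij,jx->txi", u1, mu)
    p1 = np.einsum("wt,txi->wxi", ker1, a_t.conj())

    # ket t3 row vectors mu_x† U1(t3), transformed
    v_t = np.einsum("ix,tij->txj", mu, u1)
    v3 = np.einsum("wt,txj->wxj", ker3, v_t)

    # ESA t3 kernel U1†(t3) D2_x† U2(t3), transformed: (nw, x, i, q)
    k_t = np.einsum("tji,pjx,tpq->txiq", u1.conj(), d2, u2)
    k3 = np.einsum("wt,txiq->wxiq", ker3, k_t)

    nw = len(omega)
    c = np.zeros((nw, nw), dtype=complex)
    # isotropic all-parallel average: pathway components (a,b,c,d) summed
    # over the pairings (pp,qq), (pq,pq), (pq,qp)
    for p in range(3):
        for q in range(3):
            for a, b, cc, d in ((p, p, q, q), (p, q, p, q), (p, q, q, p)):
                s1_gsb = p1[:, a, :] @ mu[:, b]
                s3_gsb = v3[:, d, :] @ mu[:, cc]
                c += np.outer(s1_gsb, s3_gsb)
                s1_se = p1[:, a, :] @ mu[:, cc]
                s3_se = v3[:, d, :] @ mu[:, b]
                c += np.outer(s1_se, s3_se)
                vq = d2[:, :, cc] @ mu[:, b]                    # (npairs,)
                s3_esa = k3[:, d, :, :] @ vq                    # (nw, i)
                c -= np.einsum("wi,vi->wv", p1[:, a, :], s3_esa)
    c /= 15.0
    amp = _display(c, settings.component)
    return Spectrum2D(grid=grid, amplitude=amp, gamma_fwhm=settings.gamma_fwhm,
                      component=settings.component)


def ensemble_spectrum(ensemble: StructureEnsemble, params: HamiltonianParams,
                      grid: SpectralGrid, settings: ResponseSettings,
                      kind: str = "1d", map_table: NNCouplingMap | None = None,
                      seed: int | None = None):
    """Unweighted ensemble mean of per-member spectra.

    Each member's Hamiltonian is built independently with fresh (seeded)
    site-energy disorder draws.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    total = None
    for member in ensemble:
        h1 = build_hamiltonian(member, params, map_table=map_table, rng=rng)
        if kind == "1d":
            spec = linear_absorption(one_exciton_states(h1), grid, settings.gamma_fwhm)
            arr = spec.intensity
        elif kind == "2d":
            spec = kI_2d_spectrum(h1, anharmonicity=params.anharmonicity,
                                  grid=grid, settings=settings)
            arr = spec.amplitude
        else:
            raise ValueError("kind must be '1d' or '2d'")
        total = arr if total is None else total + arr
    mean = total / len(ensemble)
    if kind == "1d":
        return Spectrum1D(grid=grid, intensity=mean, gamma_fwhm=settings.gamma_fwhm,
                          n_members=len(ensemble))
    return Spectrum2D(grid=grid, amplitude=mean, gamma_fwhm=settings.gamma_fwhm,
                      component=settings.component, n_members=len(ensemble))
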