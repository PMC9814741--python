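"""SOAP descriptors for monomer-center environments.

The neighbour density around a center is a sum of Gaussians of width ``sigma``
placed on every neighbour within ``rcut`` (each weighted by a smooth cutoff
function of its distance), expanded in orthonormal radial functions R_n(r) and
spherical harmonics Y_lm.  The rotationally invariant power spectrum

    gamma_{n n' l} = 1/sqrt(2l+1) * sum_m  conj(c_nlm) c_n'lm ,   n' >= n

collects the quadratic contractions over m into a D-dimensional real vector,
D = nmax(nmax+1)/2 * (lmax+1)  (324 for nmax = lmax = 8).

The expansion coefficient of a single Gaussian separates into an angular factor
Y*_lm(rhat_j) and a 1-D radial integral against the scaled modified spherical
Bessel function e^{-z} i_l(z); the radial integral is evaluated with
Gauss-Legendre quadrature on [0, rcut].  This keeps per-frame cost linear in
the number of neighbour pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y

from .trajectory import Frame, minimum_image

__all__ = [
    "SoapParams",
    "CoefficientSet",
    "SoapSpectrum",
    "smooth_cutoff",
    "expansion_coefficients",
    "power_spectrum",
    "soap_frame",
    "soap_trajectory",
]


@dataclass(frozen=True)
class SoapParams:
    """SOAP hyperparameters.

    Attributes
    ----------
    nmax, lmax : int
        Radial basis size and maximum angular momentum (l runs 0..lmax).
    rcut : float
        Environment cutoff radius in nm.
    sigma : float
        Gaussian smearing width in nm (default 0.1).
    w_switch : float
        Width of the cosine switching region of the cutoff function in nm.
    include_self : bool
        Whether a center's own Gaussian contributes to its density.
    radial_basis : {"poly", "gaussian"}
        Orthonormal radial family; "poly" is the self-contained default.
    n_radial_quad : int or None
        Gauss-Legendre node count for radial integrals; None picks
        ``max(64, 8 * rcut / sigma)`` rounded up to an even number.
    """

    nmax: int = 8
    lmax: int = 8
    rcut: float = 0.8
    sigma: float = 0.1
    w_switch: float = 0.05
    include_self: bool = True
    radial_basis: str = "poly"
    n_radial_quad: int | None = None

    def __post_init__(self):
        if self.nmax < 1 or self.lmax < 0:
            raise ValueError("nmax >= 1 and lmax >= 0 required")
        if not (0 < self.w_switch < self.rcut):
            raise ValueError("need 0 < w_switch < rcut")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.radial_basis not in ("poly", "gaussian"):
            raise ValueError(f"unknown radial basis {self.radial_basis!r}")

    @property
    def n_features(self) -> int:
        """Dimension D of the power-spectrum vector."""
        return self.nmax * (self.nmax + 1) // 2 * (self.lmax + 1)

    @property
    def _n_quad(self) -> int:
        if self.n_radial_quad is not None:
            return self.n_radial_quad
        k = max(64, int(np.ceil(8.0 * self.rcut / self.sigma)))
        return k + (k % 2)


@dataclass
class CoefficientSet:
    """Complex expansion coefficients c_nlm of one center's neighbour density.

    ``c`` has shape (nmax, lmax+1, 2*lmax+1); the m axis is offset so that
    ``c[n-1, l, lmax+m]`` holds c_nlm.  A real density satisfies
    c_{n,l,-m} = (-1)^m conj(c_{n,l,m}).
    """

    c: np.ndarray
    params: SoapParams
    center_index: int = 0


@dataclass
class SoapSpectrum:
    """Real power-spectrum vector in canonical order (l outer, then n'>=n)."""

    p: np.ndarray
    params: SoapParams
    center_index: int = 0


def smooth_cutoff(r, rcut: float, w_switch: float):
    """Cosine half-switch: 1 below ``rcut - w_switch``, 0 at ``rcut``."""
    r = np.asarray(r, dtype=float)
    t = (r - (rcut - w_switch)) / w_switch
    w = np.where(t <= 0, 1.0, np.where(t >= 1, 0.0, 0.5 * (1.0 + np.cos(np.pi * np.clip(t, 0, 1)))))
    return w if w.ndim else float(w)


# --------------------------------------------------------------------------
# scaled modified spherical Bessel function  e^{-z} i_l(z)

def _scaled_sph_in(lmax: int, z: np.ndarray) -> np.ndarray:
    """e^{-z} i_l(z) for l = 0..lmax, elementwise on ``z >= 0``.

    Three branches: a short power series for z <= 0.7, Miller downward
    recurrence for moderate z, and the (there stable) upward recurrence for
    z >= 25.  Relative accuracy ~1e-9 over the whole range.
    """
    z = np.asarray(z, dtype=float)
    flat = z.ravel()
    out = np.empty((lmax + 1, flat.size))

    ser = flat <= 0.7
    mid = (flat > 0.7) & (flat < 25.0)
    big = flat >= 25.0

    if np.any(ser):
        zs = flat[ser]
        u = 0.5 * zs * zs
        emz = np.exp(-zs)
        df = 1.0
        for l in range(lmax + 1):
            if l > 0:
                df *= 2 * l + 1
            a, b, cc, d = 2 * l + 3, 2 * l + 5, 2 * l + 7, 2 * l + 9
            s = 1.0 + u / a * (1.0 + u / (2 * b) * (1.0 + u / (3 * cc) * (1.0 + u / (4 * d))))
            out[l, ser] = emz * zs ** l / df * s

    if np.any(mid):
        zm = flat[mid]
        ltop = lmax + 16
        pup = np.zeros_like(zm)
        p = np.full_like(zm, 1e-280)
        store = [None] * (lmax + 1)
        for l in range(ltop, 0, -1):
            pm = pup + (2 * l + 1) / zm * p
            if l - 1 <= lmax:
                store[l - 1] = pm
            if l <= lmax and store[l] is None:
                store[l] = p
            pup, p = p, pm
        scale = (-np.expm1(-2 * zm) / (2 * zm)) / store[0]
        for l in range(lmax + 1):
            out[l, mid] = store[l] * scale

    if np.any(big):
        zb = flat[big]
        i0 = -np.expm1(-2 * zb) / (2 * zb)
        out[0, big] = i0
        if lmax >= 1:
            i1 = ((zb - 1.0) + (zb + 1.0) * np.exp(-2 * zb)) / (2 * zb * zb)
            out[1, big] = i1
            prev, cur = i0, i1
            for l in range(1, lmax):
                prev, cur = cur, prev - (2 * l + 1) / zb * cur
                out[l + 1, big] = cur

    return out.reshape((lmax + 1,) + z.shape)


# --------------------------------------------------------------------------
# orthonormal radial bases on [0, rcut] with weight r^2

@lru_cache(maxsize=8)
def _poly_basis_coeffs(nmax: int) -> np.ndarray:
    """Monomial coefficients of Q_n(x), orthonormal on [0,1] with weight x^2.

    Raw family x^{i-1} (1-x)^2, i = 1..nmax; Gram matrix entries are exact
    rationals (Beta integrals), orthonormalised by exact-fraction Cholesky.
    Returns an (nmax, nmax+2) array: Q_n(x) = sum_k coeff[n, k] x^k.
    """
    G = [[Fraction(24 * _fact(i + j)) / _fact(i + j + 5) for j in range(1, nmax + 1)]
         for i in range(1, nmax + 1)]
    # rational LDL^T (square roots deferred to the final float conversion)
    L = [[Fraction(1) if i == j else Fraction(0) for j in range(nmax)] for i in range(nmax)]
    D = [Fraction(0)] * nmax
    for i in range(nmax):
        D[i] = G[i][i] - sum(L[i][k] * L[i][k] * D[k] for k in range(i))
        for j in range(i + 1, nmax):
            L[j][i] = (G[j][i] - sum(L[j][k] * L[i][k] * D[k] for k in range(i))) / D[i]
    # A = D^{-1/2} L^{-1}: rows are the orthonormal combinations of raw funcs
    Ainv = [[Fraction(0)] * nmax for _ in range(nmax)]
    for i in range(nmax):
        Ainv[i][i] = Fraction(1)
        for j in range(i - 1, -1, -1):
            Ainv[i][j] = -sum(L[i][k] * Ainv[k][j] for k in range(j, i))
    coeffs = np.zeros((nmax, nmax + 2))
    for n in range(nmax):
        scale = 1.0 / np.sqrt(float(D[n]))
        for i in range(n + 1):          # raw function x^i (1-x)^2
            a = float(Ainv[n][i]) * scale
            coeffs[n, i] += a
            coeffs[n, i + 1] += -2.0 * a
            coeffs[n, i + 2] += a
    return coeffs


def _fact(n: int) -> int:
    out = 1
    for k in range(2, n + 1):
        out *= k
    return out


@lru_cache(maxsize=16)
def _gaussian_basis(nmax: int, rcut: float):
    """Numerically orthonormalised Gaussian radial family on [0, rcut]."""
    widths = rcut * (np.arange(1, nmax + 1)) / (nmax + 1.0)
    x, w = np.polynomial.legendre.leggauss(400)
    r = 0.5 * rcut * (x + 1.0)
    wq = 0.5 * rcut * w * r * r
    raw = np.exp(-r[None, :] ** 2 / (2.0 * widths[:, None] ** 2))
    G = raw @ (wq[:, None] * raw.T)
    Lc = np.linalg.cholesky(G)
    A = np.linalg.inv(Lc)
    return widths, A


def radial_basis_values(params: SoapParams, r: np.ndarray) -> np.ndarray:
    """Evaluate R_n(r), n = 1..nmax, zero outside [0, rcut].

    The family is orthonormal: integral of R_n R_m r^2 dr over [0, rcut]
    equals delta_nm.
    """
    r = np.asarray(r, dtype=float)
    x = r / params.rcut
    inside = (x >= 0) & (x <= 1)
    if params.radial_basis == "poly":
        coeffs = _poly_basis_coeffs(params.nmax)
        vals = np.zeros((params.nmax,) + r.shape)
        xs = np.where(inside, x, 0.0)
        for n in range(params.nmax):
            acc = np.zeros_like(xs)
            for ck in coeffs[n][::-1]:
                acc = acc * xs + ck
            vals[n] = acc
        vals *= inside
        return vals * params.rcut ** -1.5
    widths, A = _gaussian_basis(params.nmax, params.rcut)
    raw = np.exp(-np.where(inside, r, 0.0)[None] ** 2 / (2.0 * widths.reshape(
        (params.nmax,) + (1,) * r.ndim) ** 2))
    return (np.tensordot(A, raw, axes=(1, 0))) * inside


@lru_cache(maxsize=16)
def _radial_quadrature(params: SoapParams):
    """GL nodes/weights on [0, rcut] and R_n values there (cached per params)."""
    K = params._n_quad
    x, w = np.polynomial.legendre.leggauss(K)
    r = 0.5 * params.rcut * (x + 1.0)
    wq = 0.5 * params.rcut * w
    Rn = radial_basis_values(params, r)
    return r, wq * r * r, Rn


# --------------------------------------------------------------------------
# coefficients and spectra

def _pair_coefficient_table(r: np.ndarray, unit: np.ndarray, w: np.ndarray,
                            params: SoapParams) -> np.ndarray:
    """Coefficient contributions of neighbour Gaussians.

    Parameters: neighbour distances ``r`` (P,), unit direction vectors
    ``unit`` (P, 3) (any value for r = 0), cutoff weights ``w`` (P,).
    Returns complex array (P, nmax, lmax+1, 2*lmax+1).
    """
    nmax, lmax, sigma = params.nmax, params.lmax, params.sigma
    rk, wk, Rn = _radial_quadrature(params)
    P = r.shape[0]
    out = np.zeros((P, nmax, lmax + 1, 2 * lmax + 1), dtype=complex)
    theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))
    phi = np.arctan2(unit[:, 1], unit[:, 0])
    # chunk pairs to bound the (lmax+1, P, K) intermediate
    chunk = max(1, int(4e6 / ((lmax + 1) * rk.size)))
    for s in range(0, P, chunk):
        sl = slice(s, min(s + chunk, P))
        rj = r[sl]
        z = rj[:, None] * rk[None, :] / sigma ** 2
        ihat = _scaled_sph_in(lmax, z)                       # (L+1, p, K)
        gauss = np.exp(-0.5 * ((rk[None, :] - rj[:, None]) / sigma) ** 2)
        # radial integrals I[p, n, l]
        I = np.einsum("k,nk,pk,lpk->pnl", wk, Rn, gauss, ihat, optimize=True)
        for l in range(lmax + 1):
            for m in range(0, l + 1):
                Y = sph_harm_y(l, m, theta[sl], phi[sl])
                contrib = (4.0 * np.pi) * w[sl] * np.conj(Y)
                out[sl, :, l, lmax + m] = contrib[:, None] * I[:, :, l]
                if m > 0:  # real density: c_{n,l,-m} = (-1)^m conj(c_{n,l,m})
                    out[sl, :, l, lmax - m] = ((-1) ** m) * np.conj(out[sl, :, l, lmax + m])
    return out


def _neighbour_pairs(frame: Frame, params: SoapParams):
    """Minimum-image neighbour list (i, r_ij, unit_ij, weight) within rcut."""
    box = frame.box
    Lper = box.lengths[box.periodic]
    if Lper.size and params.rcut > 0.5 * float(Lper.min()):
        raise ValueError(
            f"rcut={params.rcut} exceeds half the smallest periodic box length "
            f"({0.5 * float(Lper.min()):.3f} nm); periodic images would be missed"
        )
    X = frame.coords
    M = X.shape[0]
    from scipy.spatial import cKDTree
    if np.all(box.periodic):
        Xw = np.mod(X, box.lengths[None, :])
        Xw = np.where(Xw >= box.lengths[None, :], 0.0, Xw)  # guard fp edge
        tree = cKDTree(Xw, boxsize=box.lengths)
    else:
        tree = cKDTree(X)
    pairs = tree.query_pairs(params.rcut, output_type="ndarray")
    i_idx = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j_idx = np.concatenate([pairs[:, 1], pairs[:, 0]])
    disp = minimum_image(X[j_idx] - X[i_idx], box)
    r = np.linalg.norm(disp, axis=1)
    keep = r <= params.rcut
    i_idx, disp, r = i_idx[keep], disp[keep], r[keep]
    if params.include_self:
        i_idx = np.concatenate([i_idx, np.arange(M)])
        disp = np.concatenate([disp, np.zeros((M, 3))])
        r = np.concatenate([r, np.zeros(M)])
    unit = np.where(r[:, None] > 0, disp / np.where(r[:, None] > 0, r[:, None], 1.0),
                    np.array([0.0, 0.0, 1.0]))
    w = smooth_cutoff(r, params.rcut, params.w_switch)
    return i_idx, r, unit, np.asarray(w)


def frame_coefficients(frame: Frame, params: SoapParams) -> np.ndarray:
    """c_nlm for every center of a frame; shape (M, nmax, lmax+1, 2lmax+1)."""
    M = frame.n_centers
    i_idx, r, unit, w = _neighbour_pairs(frame, params)
    C = np.zeros((M, params.nmax, params.lmax + 1, 2 * params.lmax + 1), dtype=complex)
    if r.size:
        table = _pair_coefficient_table(r, unit, w, params)
        np.add.at(C, i_idx, table)
    return C


def expansion_coefficients(frame: Frame, i: int, params: SoapParams) -> CoefficientSet:
    """Expansion coefficients of the density around center ``i``."""
    if not (0 <= i < frame.n_centers):
        raise IndexError(f"center index {i} out of range for M={frame.n_centers}")
    i_idx, r, unit, w = _neighbour_pairs(frame, params)
    sel = i_idx == i
    c = np.zeros((params.nmax, params.lmax + 1, 2 * params.lmax + 1), dtype=complex)
    if np.any(sel):
        c = _pair_coefficient_table(r[sel], unit[sel], w[sel], params).sum(axis=0)
    return CoefficientSet(c=c, params=params, center_index=i)


def power_spectrum_from_c(c: np.ndarray, params: SoapParams) -> np.ndarray:
    """Canonically ordered gamma vector(s) from coefficient array(s).

    ``c`` may be (nmax, lmax+1, 2lmax+1) or batched (..., nmax, lmax+1, 2lmax+1).
    """
    nmax, lmax = params.nmax, params.lmax
    G = np.einsum("...nlm,...klm->...nkl", np.conj(c), c)
    resid = np.abs(G.imag).max() if G.size else 0.0
    scale = max(1.0, np.abs(G.real).max()) if G.size else 1.0
    if resid > 1e-10 * scale:
        raise ArithmeticError(
            f"power spectrum imaginary residue {resid:.3e} exceeds tolerance"
        )
    G = G.real / np.sqrt(2.0 * np.arange(lmax + 1) + 1.0)
    iu, ju = np.triu_indices(nmax)
    # canonical order: l outer, then (n, n'>=n) lexicographic
    vec = np.moveaxis(G, -1, -3)[..., :, iu, ju]
    return vec.reshape(G.shape[:-3] + (params.n_features,))


def power_spectrum(coeffs: CoefficientSet, params: SoapParams | None = None) -> SoapSpectrum:
    params = params or coeffs.params
    return SoapSpectrum(p=power_spectrum_from_c(coeffs.c, params), params=params,
                        center_index=coeffs.center_index)


def soap_frame(frame: Frame, params: SoapParams):
    """Per-center spectra and coefficient sets for one frame.

    Returns (spectra, coefficient_sets), both ordered as the frame's centers.
    The coefficient sets are retained because the frame-average fingerprint is
    the spectrum of the *averaged coefficients*, not the average spectrum.
    """
    C = frame_coefficients(frame, params)
    P = power_spectrum_from_c(C, params)
    spectra = [SoapSpectrum(p=P[i], params=params, center_index=i)
               for i in range(frame.n_centers)]
    csets = [CoefficientSet(c=C[i], params=params, center_index=i)
             for i in range(frame.n_centers)]
    return spectra, csets


def soap_trajectory(traj, params: SoapParams):
    """Per-frame coefficient arrays and spectra for a whole trajectory.

    Returns (spectra, coeffs): arrays of shape (T, M, D) and
    (T, M, nmax, lmax+1, 2lmax+1).
    """
    T, M = traj.n_frames, traj.n_centers
    spectra = np.empty((T, M, params.n_features))
    coeffs = np.empty((T, M, params.nmax, params.lmax + 1, 2 * params.lmax + 1),
                      dtype=complex)
    for t, fr in enumerate(traj.frames):
        C = frame_coefficients(fr, params)
        coeffs[t] = C
        spectra[t] = power_spectrum_from_c(C, params)
    return spectra, coeffs
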