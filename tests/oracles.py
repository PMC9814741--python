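"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's fast evaluation paths: the SOAP
coefficient oracle integrates the neighbour density on a dense 3-D product
quadrature (Gauss-Legendre radial x Gauss-Legendre cos(theta) x uniform phi)
against the radial basis and spherical harmonics directly.
"""

import numpy as np
from scipy.special import sph_harm_y

from defectometer.trajectory import minimum_image
from defectometer.soap import radial_basis_values, smooth_cutoff


def quadrature_coefficients(frame, i, params, n_rad=600, n_theta=40, n_phi=81):
    """c_nlm of center ``i`` by dense numerical quadrature of the density."""
    X = frame.coords
    disp = minimum_image(X - X[i], frame.box)
    rj = np.linalg.norm(disp, axis=1)
    neigh = [(disp[j], rj[j]) for j in range(len(X))
             if rj[j] <= params.rcut and (j != i or params.include_self)]

    xq, wq = np.polynomial.legendre.leggauss(n_rad)
    rr = 0.5 * params.rcut * (xq + 1.0)
    wr = 0.5 * params.rcut * wq
    ct, wt = np.polynomial.legendre.leggauss(n_theta)
    th = np.arccos(ct)
    ph = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    wp = 2.0 * np.pi / n_phi

    st = np.sin(th)
    px = rr[:, None, None] * (st[:, None] * np.cos(ph)[None, :])[None]
    py = rr[:, None, None] * (st[:, None] * np.sin(ph)[None, :])[None]
    pz = rr[:, None, None] * (ct[:, None] * np.ones(n_phi)[None, :])[None]

    dens = np.zeros((n_rad, n_theta, n_phi))
    for d, rdist in neigh:
        w_cut = smooth_cutoff(rdist, params.rcut, params.w_switch)
        dens += w_cut * np.exp(
            -((px - d[0]) ** 2 + (py - d[1]) ** 2 + (pz - d[2]) ** 2)
            / (2.0 * params.sigma ** 2)
        )

    Rn = radial_basis_values(params, rr)
    lmax = params.lmax
    Th = th[:, None] * np.ones(n_phi)[None, :]
    Ph = np.ones(n_theta)[:, None] * ph[None, :]
    c = np.zeros((params.nmax, lmax + 1, 2 * lmax + 1), dtype=complex)
    for l in range(lmax + 1):
        for m in range(-l, l + 1):
            Y = sph_harm_y(l, abs(m), Th, Ph)
            if m < 0:
                Y = (-1) ** abs(m) * np.conj(Y)
            ang = np.einsum("rtp,tp,t->r", dens, np.conj(Y), wt) * wp
            c[:, l, lmax + m] = Rn @ (wr * rr * rr * ang)
    return c


def mean_of_spectra(coeff_sets, params):
    """The *wrong* outer average (mean of per-center spectra), as a contrast."""
    from defectometer.soap import power_spectrum_from_c

    return np.mean([power_spectrum_from_c(cs.c, params) for cs in coeff_sets], axis=0)
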