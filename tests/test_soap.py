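import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from defectometer import Box, Frame, SoapParams, smooth_cutoff, soap_frame
from defectometer.soap import (expansion_coefficients, frame_coefficients,
                               power_spectrum, power_spectrum_from_c,
                               radial_basis_values, _scaled_sph_in)

from conftest import stack_frame
from oracles import quadrature_coefficients


class TestSmoothCutoff:
    def test_plateau_midpoint_and_zero(self):
        assert smooth_cutoff(0.0, 0.8, 0.2) == 1.0
        assert smooth_cutoff(0.8, 0.8, 0.2) == 0.0
        assert smooth_cutoff(0.7, 0.8, 0.2) == pytest.approx(0.5)
        assert smooth_cutoff(1.5, 0.8, 0.2) == 0.0

    def test_monotone_and_bounded(self):
        r = np.linspace(0, 1.0, 400)
        w = smooth_cutoff(r, 0.8, 0.2)
        assert np.all(np.diff(w) <= 1e-12)
        assert np.all((w >= 0) & (w <= 1))


@pytest.mark.parametrize("nmax,lmax", [(8, 8), (4, 4), (3, 0), (1, 5)])
def test_feature_dimension(nmax, lmax):
    p = SoapParams(nmax=nmax, lmax=lmax, rcut=0.8)
    assert p.n_features == nmax * (nmax + 1) // 2 * (lmax + 1)
    fr = Frame(coords=np.array([[3.0, 3, 3], [3, 3, 3.4]]),
               box=Box(lengths=[6, 6, 6]))
    spectra, _ = soap_frame(fr, p)
    assert spectra[0].p.shape == (p.n_features,)


def test_scaled_spherical_bessel_against_scipy():
    from scipy.special import ive

    z = np.concatenate([[0.0], np.logspace(-8, 3.2, 500)])
    mine = _scaled_sph_in(8, z)
    for l in range(9):
        zs = np.where(z < 1e-12, 1.0, z)
        ref = np.sqrt(np.pi / (2 * zs)) * ive(l + 0.5, zs)
        ref = np.where(z < 1e-12, 1.0 if l == 0 else 0.0, ref)
        np.testing.assert_allclose(mine[l], ref, rtol=5e-9, atol=1e-300)


@pytest.mark.parametrize("basis", ["poly", "gaussian"])
def test_radial_basis_orthonormal(basis):
    p = SoapParams(nmax=6, lmax=2, rcut=1.3, radial_basis=basis)
    x, w = np.polynomial.legendre.leggauss(500)
    r = 0.5 * p.rcut * (x + 1.0)
    wq = 0.5 * p.rcut * w * r * r
    R = radial_basis_values(p, r)
    G = R @ (wq[:, None] * R.T)
    np.testing.assert_allclose(G, np.eye(6), atol=1e-7)
    # compact support
    assert np.all(radial_basis_values(p, np.array([1.31, 5.0])) == 0.0)


def test_isolated_center_without_self_term_is_zero(cube10):
    fr = Frame(coords=np.array([[5.0, 5, 5], [5, 5, 8.0]]), box=cube10)
    p = SoapParams(nmax=3, lmax=3, rcut=0.8, include_self=False)
    cs = expansion_coefficients(fr, 0, p)
    assert np.all(cs.c == 0)
    assert np.all(power_spectrum(cs).p == 0)


def test_axial_configuration_has_only_m0_coefficients(cube10):
    fr = Frame(coords=np.array([[5.0, 5, 5], [5, 5, 5.4]]), box=cube10)
    p = SoapParams(nmax=3, lmax=3, rcut=0.8, include_self=False)
    c = expansion_coefficients(fr, 0, p).c
    m0 = p.lmax
    mask = np.ones(2 * p.lmax + 1, bool)
    mask[m0] = False
    assert np.abs(c[:, :, mask]).max() == 0.0
    assert np.abs(c[:, :, m0]).max() > 1e-4


def test_conjugation_symmetry(random_cluster_frame, small_params):
    c = expansion_coefficients(random_cluster_frame, 0, small_params).c
    lmax = small_params.lmax
    for l in range(lmax + 1):
        for m in range(1, l + 1):
            np.testing.assert_allclose(
                c[:, l, lmax - m], (-1) ** m * np.conj(c[:, l, lmax + m]),
                rtol=1e-12, atol=1e-15)


@pytest.mark.parametrize("include_self", [True, False])
def test_coefficients_match_quadrature_oracle(random_cluster_frame, include_self):
    """Fast Bessel-expansion path against dense 3-D quadrature of the density."""
    p = SoapParams(nmax=4, lmax=4, rcut=0.8, include_self=include_self)
    mine = expansion_coefficients(random_cluster_frame, 0, p).c
    orc = quadrature_coefficients(random_cluster_frame, 0, p)
    assert np.abs(mine - orc).max() / np.abs(orc).max() < 1e-6


def test_coefficients_match_oracle_across_periodic_boundary():
    box = Box(lengths=[3.0, 3.0, 3.0])
    coords = np.array([[0.1, 0.1, 0.1], [2.9, 2.9, 2.9], [0.1, 0.1, 2.8]])
    fr = Frame(coords=coords, box=box)
    p = SoapParams(nmax=3, lmax=3, rcut=0.8)
    mine = expansion_coefficients(fr, 0, p).c
    orc = quadrature_coefficients(fr, 0, p)
    assert np.abs(mine - orc).max() / np.abs(orc).max() < 1e-6


def test_full_params_match_oracle(random_cluster_frame, full_params):
    mine = expansion_coefficients(random_cluster_frame, 0, full_params).c
    orc = quadrature_coefficients(random_cluster_frame, 0, full_params)
    assert np.abs(mine - orc).max() / np.abs(orc).max() < 1e-6


class TestInvariances:
    def rotated(self, frame, seed):
        Rm = Rotation.random(random_state=seed).as_matrix()
        ctr = np.array([5.0, 5.0, 5.0])
        return Frame(coords=(frame.coords - ctr) @ Rm.T + ctr, box=frame.box)

    def test_rotation_invariance(self, random_cluster_frame, full_params):
        p0 = power_spectrum_from_c(
            frame_coefficients(random_cluster_frame, full_params)[0], full_params)
        for seed in range(3):
            fr = self.rotated(random_cluster_frame, seed)
            p1 = power_spectrum_from_c(frame_coefficients(fr, full_params)[0], full_params)
            assert np.abs(p1 - p0).max() / np.abs(p0).max() < 1e-8

    def test_translation_invariance(self, random_cluster_frame, full_params):
        p0 = power_spectrum_from_c(
            frame_coefficients(random_cluster_frame, full_params)[0], full_params)
        fr = Frame(coords=random_cluster_frame.coords + [1.3, -2.1, 0.7],
                   box=random_cluster_frame.box)
        p1 = power_spectrum_from_c(frame_coefficients(fr, full_params)[0], full_params)
        assert np.abs(p1 - p0).max() / np.abs(p0).max() < 1e-8

    def test_neighbour_permutation_invariance(self, random_cluster_frame, full_params):
        coords = random_cluster_frame.coords.copy()
        coords[1:] = coords[1:][::-1]
        fr = Frame(coords=coords, box=random_cluster_frame.box)
        p0 = power_spectrum_from_c(
            frame_coefficients(random_cluster_frame, full_params)[0], full_params)
        p1 = power_spectrum_from_c(frame_coefficients(fr, full_params)[0], full_params)
        assert np.abs(p1 - p0).max() / np.abs(p0).max() < 1e-8


def test_periodic_stack_sites_equivalent(full_params):
    fr = stack_frame(n=8)
    spectra, _ = soap_frame(fr, full_params)
    P = np.stack([s.p for s in spectra])
    ref = P[0]
    assert np.abs(P - ref).max() / np.abs(ref).max() < 1e-8


def test_imaginary_residue_detection(small_params):
    c = np.zeros((4, 5, 9), dtype=complex)
    # a density with these coefficients is not real: the m-contraction of
    # channel (n=1, n'=2, l=1) acquires an imaginary part
    c[0, 1, small_params.lmax + 1] = 1.0j
    c[1, 1, small_params.lmax + 1] = 1.0
    with pytest.raises(ArithmeticError, match="residue"):
        power_spectrum_from_c(c, small_params)


def test_rcut_beyond_half_box_rejected():
    fr = Frame(coords=np.array([[0.5, 0.5, 0.5]]), box=Box(lengths=[1.0, 1.0, 1.0]))
    with pytest.raises(ValueError, match="half"):
        soap_frame(fr, SoapParams(nmax=2, lmax=2, rcut=0.8))
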