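"""Global SOAP fingerprints and the kernel-induced distance d_SOAP.

The frame-average fingerprint is the power spectrum of the *coefficient*
average over the M centers (inner average), not the mean of per-center
spectra.  Simulation averages are plain means of frame fingerprints and are
stored unnormalized; unit normalization happens only inside the kernel.
The induced metric d = sqrt(2 - 2K) is Euclidean on the unit sphere, so it is
bounded by sqrt(2) and satisfies the triangle inequality exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .soap import CoefficientSet, SoapParams, SoapSpectrum, power_spectrum_from_c

__all__ = [
    "AveragedSpectrum",
    "DistanceMatrix",
    "frame_average",
    "simulation_average",
    "soap_kernel",
    "soap_distance",
    "distance_matrix",
    "trajectory_average",
]


@dataclass
class AveragedSpectrum:
    """A frame-average or simulation-average SOAP fingerprint."""

    p: np.ndarray
    level: str  # "frame" | "simulation"
    system_id: str
    params: SoapParams


@dataclass
class DistanceMatrix:
    """Symmetric pairwise d_SOAP between systems; entries in [0, sqrt(2)]."""

    d: np.ndarray
    labels: list
    params: SoapParams

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(path)


def frame_average(coeff_sets, params: SoapParams | None = None,
                  system_id: str = "system") -> AveragedSpectrum:
    """Fingerprint of one frame: spectrum of the averaged coefficients."""
    if len(coeff_sets) == 0:
        raise ValueError("frame_average needs at least one coefficient set")
    if isinstance(coeff_sets, np.ndarray):
        carr = coeff_sets
        if params is None:
            raise ValueError("params required when passing a raw coefficient array")
    else:
        p0 = coeff_sets[0].params
        for cs in coeff_sets:
            if (cs.params.nmax, cs.params.lmax) != (p0.nmax, p0.lmax):
                raise ValueError("coefficient sets disagree on (nmax, lmax)")
        params = params or p0
        carr = np.stack([cs.c for cs in coeff_sets])
    cbar = carr.mean(axis=0)
    return AveragedSpectrum(p=power_spectrum_from_c(cbar, params), level="frame",
                            system_id=system_id, params=params)


def simulation_average(frame_avgs) -> AveragedSpectrum:
    """Componentwise mean of frame-average fingerprints over T frames."""
    if len(frame_avgs) == 0:
        raise ValueError("simulation_average needs at least one frame average")
    params = frame_avgs[0].params
    sysid = frame_avgs[0].system_id
    P = np.stack([fa.p for fa in frame_avgs])
    return AveragedSpectrum(p=P.mean(axis=0), level="simulation",
                            system_id=sysid, params=params)


def trajectory_average(traj, params: SoapParams) -> AveragedSpectrum:
    """Simulation-average fingerprint of a trajectory (runs SOAP per frame)."""
    from .soap import frame_coefficients

    favgs = []
    for fr in traj.frames:
        C = frame_coefficients(fr, params)
        favgs.append(frame_average(C, params, system_id=traj.system_id))
    return simulation_average(favgs)


def _vec(a) -> np.ndarray:
    return a.p if isinstance(a, (AveragedSpectrum, SoapSpectrum)) else np.asarray(a, float)


def soap_kernel(a, b) -> float:
    """Normalized linear kernel K = (p_a / |p_a|) . (p_b / |p_b|)."""
    va, vb = _vec(a), _vec(b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ZeroDivisionError("cannot normalize a zero SOAP vector")
    return float(va @ vb / (na * nb))


def soap_distance(a, b) -> float:
    """Kernel-induced metric d = sqrt(2 - 2 K(a, b)).

    Evaluated as the Euclidean distance between the unit-normalized vectors,
    which is algebraically identical and exactly zero for identical inputs.
    """
    va, vb = _vec(a), _vec(b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ZeroDivisionError("cannot normalize a zero SOAP vector")
    return float(np.linalg.norm(va / na - vb / nb))


def distance_matrix(avgs) -> DistanceMatrix:
    """Pairwise d_SOAP between simulation-average fingerprints."""
    if len(avgs) < 2:
        raise ValueError("need at least two systems for a distance matrix")
    S = len(avgs)
    d = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            d[i, j] = d[j, i] = soap_distance(avgs[i], avgs[j])
    labels = [a.system_id if isinstance(a, AveragedSpectrum) else str(i)
              for i, a in enumerate(avgs)]
    return DistanceMatrix(d=d, labels=labels, params=avgs[0].params)
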