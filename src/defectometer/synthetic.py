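"""Synthetic monomer-center assemblies with planted ground truth.

Desk-scale stand-ins for the assembly classes the method targets: 1-D stacks
(fibers) with planted stacking defects and adsorbed monomers, 2-D triangular
lattices in gel- or liquid-like regimes, spherical shells (micelle-like) and
filled balls (droplet-like, surface/bulk monomers).  Geometry is loosely
Martini-scale: stacking distance 0.5 nm, thermal jitter a few hundredths of a
nm.  Every generator is deterministic under its seed and returns both the
coordinate trajectory and the per-(monomer, frame) state labels, so the whole
downstream pipeline can be tested without any reference data.

These are geometric emulations, not dynamics: no forces are integrated, and
state changes (when a planted transition matrix is supplied) are Markov jumps,
not barrier crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import Box, Frame, Trajectory

__all__ = ["SyntheticSpec", "SyntheticAssembly", "generate",
           "gen_fiber", "gen_planar", "gen_shell", "gen_ball",
           "largest_remainder"]

_STATE_NAMES = {
    "fiber": ["ordered", "defect", "adsorbed"],
    "planar": ["gel", "liquid"],
    "shell": ["surface"],
    "ball": ["bulk", "surface"],
}


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic assembly trajectory.

    ``geometry`` accepts kind-specific keys (all lengths in nm):

    fiber   spacing (0.5), stack_radius (0.6), adsorbed_radius (1.4),
            box_xy (6.4)
    planar  lattice_constant (0.5), box_z (10.0), regime ("gel"|"liquid"|
            "mixed"), liquid_noise (0.08), diffusion_step (0.05)
    shell   radius (None -> from surface_density 4.0 nm^-2), box (auto),
            diffusion_step (0.05)
    ball    radius (None -> from density 6.0 nm^-3), thickness (0.4),
            box (auto)
    """

    kind: str
    n_monomers: int = 200
    n_frames: int = 50
    geometry: dict = field(default_factory=dict)
    state_fractions: tuple | None = None
    planted_P: np.ndarray | None = None
    thermal_noise: float = 0.03
    diffusion: float = 0.0
    seed: int = 0
    system_id: str | None = None

    def __post_init__(self):
        if self.kind not in _STATE_NAMES:
            raise ValueError(f"unknown assembly kind {self.kind!r}")
        if self.n_monomers < 1 or self.n_frames < 1:
            raise ValueError("n_monomers and n_frames must be positive")
        if self.state_fractions is not None:
            fr = np.asarray(self.state_fractions, float)
            if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
                raise ValueError("state fractions must be non-negative and sum to 1")
        if self.planted_P is not None:
            P = np.asarray(self.planted_P, float)
            if P.ndim != 2 or P.shape[0] != P.shape[1] or \
                    not np.allclose(P.sum(axis=1), 1.0, atol=1e-9) or np.any(P < 0):
                raise ValueError("planted_P must be row-stochastic")
        if any(v < 0 for k, v in self.geometry.items()
               if k not in ("regime",) and v is not None):
            raise ValueError("geometry lengths must be non-negative")

    @property
    def label(self) -> str:
        return self.system_id or f"{self.kind}-seed{self.seed}"


@dataclass
class SyntheticAssembly:
    """Generated trajectory plus planted per-(monomer, frame) state labels."""

    trajectory: Trajectory
    labels: np.ndarray          # (M, T) ints
    state_names: list
    spec: SyntheticSpec

    def labels_to_csv(self, path) -> None:
        import pandas as pd

        M, T = self.labels.shape
        pd.DataFrame({
            "frame": np.repeat(np.arange(T), M),
            "monomer": np.tile(np.arange(M), T),
            "state": self.labels.T.ravel(),
        }).to_csv(path, index=False)


def largest_remainder(fractions, n: int) -> np.ndarray:
    """Integer counts per class summing to n, by largest-remainder rounding."""
    fr = np.asarray(fractions, dtype=float)
    raw = fr * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def _evolve_states(init: np.ndarray, P, T: int, rng) -> np.ndarray:
    """(M, T) labels: static columns if P is None, else Markov jumps."""
    M = init.size
    lab = np.empty((M, T), dtype=int)
    lab[:, 0] = init
    if P is None:
        lab[:] = init[:, None]
        return lab
    P = np.asarray(P, float)
    cdf = np.cumsum(P, axis=1)
    for t in range(1, T):
        u = rng.random(M)
        lab[:, t] = (u[:, None] > cdf[lab[:, t - 1]]).sum(axis=1)
    return lab


def generate(spec: SyntheticSpec) -> SyntheticAssembly:
    """Dispatch to the generator for ``spec.kind``."""
    return {"fiber": gen_fiber, "planar": gen_planar,
            "shell": gen_shell, "ball": gen_ball}[spec.kind](spec)


# --------------------------------------------------------------------------

def gen_fiber(spec: SyntheticSpec) -> SyntheticAssembly:
    """1-D stack along z crossing the periodic boundary, with planted
    defect and adsorbed monomers.

    Ordered monomers occupy consecutive stack sites (the box height is
    exactly n_sites * spacing, so the backbone is continuous across the
    boundary).  A defect hangs off the side of the backbone: it sits at one
    stack radius laterally from a host backbone monomer at the host's
    height, so it is bound to the stack through a single first-shell
    contact.  Adsorbed monomers sit on a cylindrical surface around the
    stack, outside the first coordination shell, and random-walk along it.
    With a planted transition matrix every monomer keeps a permanent stack
    site and its state (hence its position rule) jumps per frame, so the
    backbone then transiently shows vacancies where monomers have detached.
    """
    g = spec.geometry
    a = g.get("spacing", 0.5)
    r_stack = g.get("stack_radius", 0.6)
    r_ads = g.get("adsorbed_radius", 1.4)
    box_xy = g.get("box_xy", 6.4)
    fr = spec.state_fractions if spec.state_fractions is not None else (0.85, 0.10, 0.05)
    if len(fr) != 3:
        raise ValueError("fiber needs (ordered, defect, adsorbed) fractions")
    rng = np.random.default_rng(spec.seed)
    M, T = spec.n_monomers, spec.n_frames
    counts = largest_remainder(fr, M)
    init = np.repeat(np.arange(3), counts)
    rng.shuffle(init)
    labels = _evolve_states(init, spec.planted_P, T, rng)

    static = spec.planted_P is None
    if static:
        # only ordered monomers own a site: the backbone has no holes
        site = np.full(M, -1)
        ordered = init == 0
        site[ordered] = np.arange(int(ordered.sum()))
        n_sites = int(ordered.sum())
        # each defect branches off its own host site; hosts are kept at
        # least two sites apart so defects never enter each other's shell
        host_site = np.full(M, -1)
        n_def = int((init == 1).sum())
        if n_def > max(n_sites // 2, 0):
            raise ValueError("too many defects for the backbone length")
        if n_def:
            host_site[init == 1] = 2 * rng.choice(n_sites // 2, size=n_def,
                                                  replace=False)
    else:
        site = np.arange(M)
        host_site = site.copy()
        n_sites = M
    n_sites = max(n_sites, 1)
    Lz = n_sites * a
    box = Box(lengths=[box_xy, box_xy, Lz])
    cx = cy = box_xy / 2.0

    phi_m = rng.uniform(0.0, 2.0 * np.pi, M)       # per-monomer branch direction
    theta_ads = rng.uniform(0.0, 2.0 * np.pi, M)
    # stratified z slots keep adsorbed walkers out of each other's shell
    # (excluded volume on the cylinder surface, without integrating forces)
    if static:
        ads_idx = np.where(init == 2)[0]
        n_ads = max(len(ads_idx), 1)
        z_ads = np.zeros(M)
        z_ads[ads_idx] = ((np.arange(len(ads_idx)) + rng.uniform(0.2, 0.8, len(ads_idx)))
                          * Lz / n_ads)
    else:
        z_ads = (np.arange(M) + rng.uniform(0.2, 0.8, M)) * Lz / M
    step = spec.diffusion if spec.diffusion > 0 else 0.1

    frames = []
    for t in range(T):
        theta_ads = theta_ads + rng.normal(0.0, step / r_ads, M)
        z_ads = z_ads + rng.normal(0.0, step, M)
        X = np.empty((M, 3))
        st = labels[:, t]
        zsite = np.where(site >= 0, site, 0) * a
        X[:, 0] = cx
        X[:, 1] = cy
        X[:, 2] = zsite
        # defect: one stack radius off its host, at the host's height
        d = st == 1
        X[d, 0] = cx + r_stack * np.cos(phi_m[d])
        X[d, 1] = cy + r_stack * np.sin(phi_m[d])
        X[d, 2] = np.where(host_site[d] >= 0, host_site[d], 0) * a
        # adsorbed: cylinder surface random walk
        adl = st == 2
        X[adl, 0] = cx + r_ads * np.cos(theta_ads[adl])
        X[adl, 1] = cy + r_ads * np.sin(theta_ads[adl])
        X[adl, 2] = z_ads[adl] % Lz
        X += rng.normal(0.0, spec.thermal_noise, (M, 3)) if spec.thermal_noise > 0 else 0.0
        frames.append(Frame(coords=X, box=box, time=float(t)))
    traj = Trajectory(frames=frames, system_id=spec.label)
    return SyntheticAssembly(traj, labels, _STATE_NAMES["fiber"], spec)


def gen_planar(spec: SyntheticSpec) -> SyntheticAssembly:
    """Periodic triangular lattice in the x-y plane (bilayer head-group proxy).

    gel: small jitter, no diffusion.  liquid: larger jitter plus a cumulative
    2-D random walk.  mixed: contiguous column blocks of gel and liquid
    monomers according to the planted fractions.
    """
    g = spec.geometry
    a = g.get("lattice_constant", 0.5)
    box_z = g.get("box_z", 10.0)
    regime = g.get("regime", "gel")
    liquid_noise = g.get("liquid_noise", 0.08)
    diff_step = g.get("diffusion_step", 0.05)
    if regime not in ("gel", "liquid", "mixed"):
        raise ValueError(f"unknown planar regime {regime!r}")
    M, T = spec.n_monomers, spec.n_frames
    nx = int(round(np.sqrt(M)))
    while M % nx:
        nx -= 1
    ny = M // nx
    if ny % 2 and (M // (nx - 1)) % 2 == 0 and nx > 1 and M % (nx - 1) == 0:
        nx -= 1
        ny = M // nx
    rng = np.random.default_rng(spec.seed)

    ix = np.tile(np.arange(nx), ny)
    iy = np.repeat(np.arange(ny), nx)
    x0 = (ix + 0.5 * (iy % 2)) * a
    y0 = iy * a * np.sqrt(3.0) / 2.0
    box = Box(lengths=[nx * a, ny * a * np.sqrt(3.0) / 2.0, box_z])

    if regime == "mixed":
        frl = spec.state_fractions if spec.state_fractions is not None else (0.5, 0.5)
        n_gel = largest_remainder(frl, M)[0]
        order = np.argsort(x0 + 1e-9 * y0, kind="stable")
        init = np.ones(M, dtype=int)
        init[order[:n_gel]] = 0          # contiguous low-x block is gel
    else:
        init = np.zeros(M, dtype=int) if regime == "gel" else np.ones(M, dtype=int)
    labels = _evolve_states(init, spec.planted_P, T, rng)

    sigma_gel = spec.thermal_noise
    walk = np.zeros((M, 2))
    frames = []
    for t in range(T):
        st = labels[:, t]
        liq = st == 1
        walk[liq] += rng.normal(0.0, diff_step, (int(liq.sum()), 2))
        X = np.empty((M, 3))
        X[:, 0] = x0 + walk[:, 0]
        X[:, 1] = y0 + walk[:, 1]
        X[:, 2] = box_z / 2.0
        sig = np.where(liq, liquid_noise, sigma_gel)
        if np.any(sig > 0):
            X += rng.normal(0.0, 1.0, (M, 3)) * sig[:, None]
        frames.append(Frame(coords=X, box=box, time=float(t)))
    traj = Trajectory(frames=frames, system_id=spec.label)
    return SyntheticAssembly(traj, labels, _STATE_NAMES["planar"], spec)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def gen_shell(spec: SyntheticSpec) -> SyntheticAssembly:
    """Quasi-uniform spherical shell (micelle-like), single surface state.

    The radius defaults to sqrt(n / (4 pi * surface_density)) with a surface
    density of 4 monomers/nm^2, so larger shells stay at constant packing.
    """
    g = spec.geometry
    R = g.get("radius") or float(np.sqrt(spec.n_monomers /
                                         (4.0 * np.pi * g.get("surface_density", 4.0))))
    box_len = g.get("box") or max(2.5 * R + 1.0, 6.4)
    diff_step = g.get("diffusion_step", 0.05)
    M, T = spec.n_monomers, spec.n_frames
    rng = np.random.default_rng(spec.seed)
    box = Box(lengths=[box_len] * 3)
    c = box_len / 2.0
    u = _fibonacci_sphere(M)
    frames = []
    for t in range(T):
        if t and (spec.diffusion > 0 or diff_step > 0):
            step = spec.diffusion if spec.diffusion > 0 else diff_step
            u = u + rng.normal(0.0, step / R, (M, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
        X = c + R * u
        if spec.thermal_noise > 0:
            X = X + rng.normal(0.0, spec.thermal_noise, (M, 3))
        frames.append(Frame(coords=X, box=box, time=float(t)))
    traj = Trajectory(frames=frames, system_id=spec.label)
    labels = np.zeros((M, T), dtype=int)
    return SyntheticAssembly(traj, labels, _STATE_NAMES["shell"], spec)


def gen_ball(spec: SyntheticSpec) -> SyntheticAssembly:
    """Uniformly filled sphere (droplet-like) with surface/bulk ground truth.

    The radius defaults to (3 n / (4 pi * density))^(1/3) at 6 monomers/nm^3,
    so bigger droplets have a smaller surface fraction at fixed shell
    thickness.  Monomers within ``thickness`` of the radius are labelled
    surface (1), the rest bulk (0).  A planted transition matrix drives
    surface/bulk exchange by resampling a monomer's radius inside its new
    region whenever its state jumps.
    """
    g = spec.geometry
    density = g.get("density", 6.0)
    R = g.get("radius") or float((3.0 * spec.n_monomers / (4.0 * np.pi * density)) ** (1.0 / 3.0))
    t_shell = g.get("thickness", 0.4)
    if t_shell >= R:
        raise ValueError("shell thickness must be smaller than the radius")
    box_len = g.get("box") or max(2.5 * R + 1.0, 6.4)
    M, T = spec.n_monomers, spec.n_frames
    rng = np.random.default_rng(spec.seed)
    box = Box(lengths=[box_len] * 3)
    c = box_len / 2.0

    u = rng.normal(size=(M, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radii = R * rng.random(M) ** (1.0 / 3.0)
    init = (radii > R - t_shell).astype(int)
    labels = _evolve_states(init, spec.planted_P, T, rng)

    rin3 = (R - t_shell) ** 3
    frames = []
    for t in range(T):
        if spec.planted_P is not None and t > 0:
            jumped = labels[:, t] != labels[:, t - 1]
            if np.any(jumped):
                nj = int(jumped.sum())
                v = rng.random(nj)
                to_surface = labels[jumped, t] == 1
                new_r = np.where(
                    to_surface,
                    (rin3 + v * (R ** 3 - rin3)) ** (1.0 / 3.0),
                    (v * rin3) ** (1.0 / 3.0),
                )
                radii = radii.copy()
                radii[jumped] = new_r
        X = c + radii[:, None] * u
        if spec.thermal_noise > 0:
            X = X + rng.normal(0.0, spec.thermal_noise, (M, 3))
        frames.append(Frame(coords=X, box=box, time=float(t)))
    traj = Trajectory(frames=frames, system_id=spec.label)
    return SyntheticAssembly(traj, labels, _STATE_NAMES["ball"], spec)
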