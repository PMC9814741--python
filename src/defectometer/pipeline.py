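"""End-to-end orchestration: trajectories -> SOAP -> PCA -> motifs -> reports.

A :class:`PipelineConfig` (usually loaded from TOML) names the systems to
analyse — on-disk trajectories or synthetic recipes — and the stage
parameters.  :func:`run_pipeline` executes every stage with explicit seeds and
writes plain-text artifacts (CSV / JSON / Newick / DOT) plus a manifest that
records every parameter, so a run can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import LinkageTree, dendrogram_order, rank_by_distance, reorder_matrix, single_linkage, to_newick
from .dynamics import interconversion_matrix, state_populations, state_trajectories, transition_matrix
from .metric import distance_matrix, frame_average, simulation_average
from .pamm import assign_microstates, cut_macroclusters, fit_microclusters
from .reduction import SpectraDataset, fit_projection, pool_balanced, project
from .soap import SoapParams, soap_trajectory
from .synthetic import SyntheticSpec, generate
from .trajectory import CenterSelection, Trajectory, compute_centers, read_trajectory

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SystemConfig", "run_pipeline", "load_config"]


@dataclass
class SystemConfig:
    """One analysed system: a trajectory file or a synthetic recipe."""

    id: str
    trajectory: str | None = None
    format: str = "extended-xyz"
    unit: str | None = None
    synthetic: dict | None = None
    selection: list | None = None  # bead-index groups; None = one bead per monomer

    def load(self) -> Trajectory:
        if (self.trajectory is None) == (self.synthetic is None):
            raise ValueError(f"system {self.id}: give exactly one of trajectory/synthetic")
        if self.synthetic is not None:
            spec = SyntheticSpec(system_id=self.id, **self.synthetic)
            return generate(spec).trajectory
        traj = read_trajectory(self.trajectory, format=self.format,
                               system_id=self.id, unit=self.unit)
        if self.selection:
            sel = CenterSelection(groups=tuple(tuple(g) for g in self.selection))
            frames = [compute_centers(fr.coords, fr.box, sel, time=fr.time)
                      for fr in traj.frames]
            traj = Trajectory(frames=frames, system_id=self.id,
                              sampling_interval=traj.sampling_interval)
        return traj


@dataclass
class PipelineConfig:
    systems: list
    soap: SoapParams = field(default_factory=SoapParams)
    n_per_system: int = 2000
    pool_seed: int = 0
    n_components: int = 3
    K: int = 3
    n_grid: int | None = None
    n_boot: int = 73
    lambda_qs: float = 3.0
    cluster_seed: int = 0
    lag: int = 1
    output_dir: str = "defectometer_out"

    def __post_init__(self):
        if not self.systems:
            raise ValueError("at least one system is required")
        self.systems = [s if isinstance(s, SystemConfig) else SystemConfig(**s)
                        for s in self.systems]


def load_config(path) -> PipelineConfig:
    """Read a pipeline configuration from a TOML file."""
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    soap = SoapParams(**doc.get("soap", {}))
    pool = doc.get("pooling", {})
    clus = doc.get("clustering", {})
    return PipelineConfig(
        systems=doc.get("systems", []),
        soap=soap,
        n_per_system=pool.get("n_per_system", 2000),
        pool_seed=pool.get("seed", 0),
        n_components=doc.get("reduction", {}).get("n_components", 3),
        K=clus.get("K", 3),
        n_grid=clus.get("n_grid"),
        n_boot=clus.get("n_boot", 73),
        lambda_qs=clus.get("lambda_qs", 3.0),
        cluster_seed=clus.get("seed", 0),
        lag=doc.get("dynamics", {}).get("lag", 1),
        output_dir=doc.get("output_dir", "defectometer_out"),
    )


def _write_vector_csv(path, vectors, params, labels=None):
    iu_cols = []
    for l in range(params.lmax + 1):
        for n in range(1, params.nmax + 1):
            for n2 in range(n, params.nmax + 1):
                iu_cols.append(f"g_{n}_{n2}_{l}")
    df = pd.DataFrame(np.atleast_2d(vectors), columns=iu_cols)
    if labels is not None:
        df.insert(0, "system", labels)
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the artifact directory; returns its path."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"soap": asdict(config.soap),
                "n_per_system": config.n_per_system, "pool_seed": config.pool_seed,
                "n_components": config.n_components, "K": config.K,
                "n_boot": config.n_boot, "lambda_qs": config.lambda_qs,
                "cluster_seed": config.cluster_seed, "lag": config.lag,
                "systems": [], "stages": {}}
    params = config.soap
    try:
        # --- per-system SOAP ---
        per_system = {}
        for syscfg in config.systems:
            logger.info("SOAP for system %s", syscfg.id)
            traj = syscfg.load()
            spectra, coeffs = soap_trajectory(traj, params)
            favgs = [frame_average(coeffs[t], params, system_id=syscfg.id)
                     for t in range(traj.n_frames)]
            sim_avg = simulation_average(favgs)
            per_system[syscfg.id] = dict(traj=traj, spectra=spectra, sim_avg=sim_avg)
            sysdir = out / syscfg.id
            sysdir.mkdir(exist_ok=True)
            T, M, D = spectra.shape
            _write_vector_csv(sysdir / "spectra.csv", spectra.reshape(T * M, D), params)
            manifest["systems"].append({"id": syscfg.id, "T": T, "M": M, "D": D})
        manifest["stages"]["soap"] = "ok"

        # --- shared dataset, PCA ---
        datasets = [SpectraDataset.from_trajectory_spectra(d["spectra"], sid)
                    for sid, d in per_system.items()]
        pooled = pool_balanced(datasets, config.n_per_system, config.pool_seed)
        model = fit_projection(pooled, config.n_components)
        np.savetxt(out / "projection_mean.csv", model.mean[None], delimiter=",")
        np.savetxt(out / "projection_components.csv", model.components, delimiter=",")
        np.savetxt(out / "projection_explained_ratio.csv", model.explained_ratio[None],
                   delimiter=",")
        manifest["stages"]["reduction"] = {
            "explained_ratio": model.explained_ratio.tolist()}

        # --- clustering on the pooled projections ---
        Ypool = project(model, pooled.vectors)
        mc = fit_microclusters(Ypool, n_grid=config.n_grid, seed=config.cluster_seed,
                               lambda_qs=config.lambda_qs, n_boot=config.n_boot)
        mm = cut_macroclusters(mc.merge_tree, min(config.K, mc.n_micro))
        np.savetxt(out / "stability.csv", mc.stability, delimiter=",")
        micro_tree = LinkageTree(merges=mc.merge_tree,
                                 leaf_labels=[f"micro{i}" for i in range(mc.n_micro)])
        (out / "microclusters.nwk").write_text(to_newick(micro_tree) + "\n")
        manifest["stages"]["clustering"] = {"n_micro": int(mc.n_micro), "K": int(mm.K)}

        # --- per-system states, populations, transitions ---
        for sid, d in per_system.items():
            T, M, _ = d["spectra"].shape
            Y = project(model, d["spectra"].reshape(T * M, -1))
            micro = assign_microstates(Y, mc.grid, mc.grid_labels)
            macro = mm.apply(micro)
            sysdir = out / sid
            pd.DataFrame({
                "frame": np.repeat(np.arange(T), M),
                "center": np.tile(np.arange(M), T),
                "pc": list(np.round(Y[:, 0], 10)),
                "micro": micro, "macro": macro,
            }).to_csv(sysdir / "labels.csv", index=False)
            np.savetxt(sysdir / "scores.csv", Y, delimiter=",")
            st = state_trajectories(macro, M=M, T=T)
            tm = transition_matrix(st, lag=config.lag, n_states=mm.K)
            doc = tm.to_json(lag_ns=config.lag * d["traj"].sampling_interval)
            doc["interconversion"] = [[None if not np.isfinite(x) else x for x in row]
                                      for row in interconversion_matrix(tm)]
            with open(sysdir / "states.json", "w") as fh:
                json.dump(doc, fh, indent=1)
            _write_dot(sysdir / "interconversion.dot", tm, sid)
        manifest["stages"]["dynamics"] = "ok"

        # --- system comparison ---
        if len(per_system) >= 2:
            dm = distance_matrix([d["sim_avg"] for d in per_system.values()])
            dm.to_csv(out / "dsoap.csv")
            tree = single_linkage(dm)
            (out / "systems.nwk").write_text(to_newick(tree) + "\n")
            reorder_matrix(dm, tree).to_csv(out / "dsoap_reordered.csv")
            for sid in per_system:
                rk = rank_by_distance(dm, sid)
                pd.DataFrame(rk, columns=["system", "d_soap"]).to_csv(
                    out / f"ranking_{sid}.csv", index=False)
            manifest["stages"]["compare"] = {"order": dendrogram_order(tree)}
    except Exception as exc:
        manifest["stages"]["failed"] = repr(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def _write_dot(path, tm, system_id):
    K = tm.P.shape[0]
    inter = interconversion_matrix(tm)
    lines = [f'digraph "{system_id}" {{']
    for a in range(K):
        lines.append(f'  s{a} [label="state {a}\\npop {tm.populations[a]:.3f}"];')
    for a in range(K):
        for b in range(K):
            if a != b and np.isfinite(inter[a, b]) and inter[a, b] > 0:
                lines.append(f'  s{a} -> s{b} [label="{inter[a, b]:.3f}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
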