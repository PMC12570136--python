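"""Configuration-driven orchestration of the analysis stages.

A YAML configuration names the input topology/trajectory, named atom
selections, the discard window (frames dropped from the start of each
trajectory before any statistic is computed), all geometric/statistical
thresholds, and the stages to run.  Every per-frame statistic uses the
post-discard window uniformly, occupancy denominators included.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble import (
    dccm,
    gromos_cluster,
    hexbin_density,
    pairwise_rmsd_matrix,
    pca_fit,
    pca_project,
)
from .geometry import (
    com_angle_series,
    com_distance_series,
    count_clashes,
    min_distance_series,
    radius_of_gyration_series,
    rmsd_series,
    rmsf_profile,
)
from .interactions import (
    StackingCriteria,
    assign_donors_acceptors,
    contact_frequency,
    hbond_occupancy,
    stacking_occupancy,
)
from .selection import select
from .topology import read_pdb_topology
from .trajectory import read_frames

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "ConfigError",
    "load_config",
    "dump_config",
    "run_pipeline",
    "compare_ensembles",
    "ALL_STAGES",
]

ALL_STAGES = (
    "rmsd",
    "rmsf",
    "rg",
    "domains",
    "cluster",
    "pca",
    "dccm",
    "hbonds",
    "contacts",
    "stacking",
    "mindist",
    "clashes",
)

_THRESHOLD_RANGES = {
    "hbond_distance_nm": (0.0, 1.0),
    "hbond_angle_deg": (0.0, 90.0),
    "hbond_occupancy": (0.0, 1.0),
    "contact_distance_nm": (0.0, 2.0),
    "contact_persistence": (0.0, 1.0),
    "stacking_distance_nm": (0.0, 2.0),
    "stacking_angle_deg": (0.0, 90.0),
    "stacking_occupancy": (0.0, 1.0),
    "cluster_cutoff_nm": (0.0, 10.0),
    "clash_distance_nm": (0.0, 1.0),
}

_DEFAULT_THRESHOLDS = {
    "hbond_distance_nm": 0.30,
    "hbond_angle_deg": 30.0,
    "hbond_occupancy": 0.20,
    "contact_distance_nm": 0.45,
    "contact_persistence": 0.50,
    "stacking_distance_nm": 0.55,
    "stacking_angle_deg": 40.0,
    "stacking_occupancy": 0.40,
    "cluster_cutoff_nm": 0.60,
    "clash_distance_nm": 0.22,
}

_DEFAULT_SELECTIONS = {
    "calpha": "name CA",
    "backbone": "( name N or name CA or name C or name O ) and heavy",
    "rrm1": "resid 20-98",
    "rrm2": "resid 106-186",
    "rrm3": "resid 244-322",
    "protein": "protein",
    "nucleic": "nucleic",
}

_KNOWN_KEYS = {
    "topology",
    "trajectory",
    "selections",
    "discard_frames",
    "thresholds",
    "stages",
    "output_dir",
    "seed",
    "contact_groups",
    "stacking_rings",
}


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    topology: str
    trajectory: str
    output_dir: str = "rnpdyn_out"
    discard_frames: int = 0
    seed: int = 0
    selections: dict = field(default_factory=lambda: dict(_DEFAULT_SELECTIONS))
    thresholds: dict = field(default_factory=lambda: dict(_DEFAULT_THRESHOLDS))
    stages: tuple = ALL_STAGES
    contact_groups: tuple = ("protein", "nucleic")
    stacking_rings: dict | None = None  # {"protein": [[chain, resid], ...], ...}

    def __post_init__(self) -> None:
        self.selections = {**_DEFAULT_SELECTIONS, **self.selections}
        self.thresholds = {**_DEFAULT_THRESHOLDS, **self.thresholds}
        for key, value in self.thresholds.items():
            if key not in _THRESHOLD_RANGES:
                raise ConfigError(f"unknown threshold {key!r}")
            lo, hi = _THRESHOLD_RANGES[key]
            if not lo < value <= hi:
                raise ConfigError(
                    f"threshold {key}={value} outside documented range ({lo}, {hi}]"
                )
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ConfigError(f"unknown stage {stage!r}")
        if self.discard_frames < 0:
            raise ConfigError("discard_frames must be >= 0")


@dataclass
class ReportBundle:
    manifest: dict          # artifact name -> file path
    provenance: dict        # config echo, version, seed
    results: dict           # in-memory results per stage


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a YAML analysis configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for req in ("topology", "trajectory"):
        if req not in raw:
            raise ConfigError(f"missing required key {req!r}")
    selections = dict(_DEFAULT_SELECTIONS)
    selections.update(raw.get("selections", {}))
    thresholds = dict(_DEFAULT_THRESHOLDS)
    thresholds.update(raw.get("thresholds", {}))
    return AnalysisConfig(
        topology=raw["topology"],
        trajectory=raw["trajectory"],
        output_dir=raw.get("output_dir", "rnpdyn_out"),
        discard_frames=int(raw.get("discard_frames", 0)),
        seed=int(raw.get("seed", 0)),
        selections=selections,
        thresholds=thresholds,
        stages=tuple(raw.get("stages", ALL_STAGES)),
        contact_groups=tuple(raw.get("contact_groups", ("protein", "nucleic"))),
        stacking_rings=raw.get("stacking_rings"),
    )


def dump_config(config: AnalysisConfig) -> str:
    data = asdict(config)
    data["stages"] = list(config.stages)
    data["contact_groups"] = list(config.contact_groups)
    return yaml.safe_dump(data, sort_keys=True)


def _write_series(path: Path, series, name: str, expression: str) -> None:
    df = pd.DataFrame({"frame": series.frame_indices, name: series.values})
    with open(path, "w") as fh:
        fh.write(f"# unit: {series.unit}; selection: {expression}\n")
        df.to_csv(fh, sep="\t", index=False)


def _log(message: str) -> None:
    print(f"[rnpdyn] {message}", file=sys.stderr)


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Run the requested stages in dependency order and write all tables."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _log(f"effective config:\n{dump_config(config)}")

    topology = read_pdb_topology(Path(config.topology).read_text())
    full = read_frames(Path(config.trajectory).read_text(), topology)
    traj = full.sliced(config.discard_frames)
    _log(
        f"{full.n_frames} frames read, {traj.n_frames} analyzed "
        f"(first {config.discard_frames} discarded)"
    )

    sels = {
        name: select(topology, expr) for name, expr in config.selections.items()
    }
    thr = config.thresholds
    manifest: dict[str, str] = {}
    results: dict = {}

    def emit(name: str, path: Path) -> None:
        manifest[name] = str(path)

    for stage in config.stages:
        try:
            if stage == "rmsd":
                res = rmsd_series(traj, sels["backbone"], 0, fit=True)
                results["rmsd"] = res
                p = outdir / "rmsd.tsv"
                _write_series(p, res, "rmsd", config.selections["backbone"])
                emit("rmsd", p)
            elif stage == "rmsf":
                res = rmsf_profile(traj, sels["calpha"], fit=True)
                results["rmsf"] = res
                p = outdir / "rmsf.tsv"
                pd.DataFrame({"residue": res.labels, "rmsf_nm": res.values}).to_csv(
                    p, sep="\t", index=False
                )
                emit("rmsf", p)
            elif stage == "rg":
                heavy = select(topology, "protein and heavy")
                res = radius_of_gyration_series(traj, heavy)
                results["rg"] = res
                p = outdir / "rg.tsv"
                _write_series(p, res, "rg", "protein and heavy")
                emit("rg", p)
            elif stage == "domains":
                for pair in (("rrm1", "rrm2"), ("rrm2", "rrm3"), ("rrm1", "rrm3")):
                    a, b = pair
                    if len(sels[a]) == 0 or len(sels[b]) == 0:
                        continue
                    res = com_distance_series(traj, sels[a], sels[b])
                    results[f"dist_{a}_{b}"] = res
                    p = outdir / f"dist_{a}_{b}.tsv"
                    _write_series(p, res, f"d_{a}_{b}", f"{a}|{b}")
                    emit(f"dist_{a}_{b}", p)
                if all(len(sels[k]) > 0 for k in ("rrm1", "rrm2", "rrm3")):
                    res = com_angle_series(
                        traj, sels["rrm1"], sels["rrm2"], sels["rrm3"]
                    )
                    results["angle_rrm1_rrm2_rrm3"] = res
                    p = outdir / "angle_rrm1_rrm2_rrm3.tsv"
                    _write_series(p, res, "angle", "rrm1|rrm2|rrm3")
                    emit("angle_rrm1_rrm2_rrm3", p)
            elif stage == "cluster":
                confs = [fr.coordinates for fr in traj.frames]
                mat = pairwise_rmsd_matrix(confs, sels["calpha"], fit=True)
                assignment = gromos_cluster(mat, thr["cluster_cutoff_nm"])
                results["cluster"] = assignment
                p = outdir / "clusters.tsv"
                pd.DataFrame(
                    {
                        "conformation_id": np.arange(len(assignment.labels)),
                        "cluster_id": assignment.labels,
                        "is_centroid": np.isin(
                            np.arange(len(assignment.labels)),
                            assignment.centroid_ids,
                        ),
                    }
                ).to_csv(p, sep="\t", index=False)
                emit("cluster", p)
            elif stage == "pca":
                model = pca_fit(traj, sels["calpha"])
                proj = pca_project(model, traj, sels["calpha"], components=2)
                grid = hexbin_density(proj)
                results["pca"] = model
                results["pca_projections"] = proj
                results["pca_density"] = grid
                p = outdir / "pca_projections.tsv"
                pd.DataFrame(proj, columns=["pc1", "pc2"]).to_csv(
                    p, sep="\t", index=False
                )
                emit("pca", p)
            elif stage == "dccm":
                res = dccm(traj, sels["calpha"])
                results["dccm"] = res
                p = outdir / "dccm.dat"
                header = " ".join(str(l) for l in res.labels)
                np.savetxt(p, res.matrix, header=header)
                emit("dccm", p)
            elif stage == "hbonds":
                donors, acceptors = assign_donors_acceptors(
                    topology, traj.frames[0]
                )
                table, kept = hbond_occupancy(
                    traj,
                    donors,
                    acceptors,
                    dist_cut=thr["hbond_distance_nm"],
                    angle_cut=thr["hbond_angle_deg"],
                    occupancy_cut=thr["hbond_occupancy"],
                )
                results["hbonds"] = table
                results["hbonds_filtered"] = kept
                p = outdir / "hbonds.tsv"
                _write_hbond_table(p, kept, topology, thr)
                emit("hbonds", p)
            elif stage == "contacts":
                ga, gb = config.contact_groups
                freqs, persistent = contact_frequency(
                    traj,
                    sels[ga],
                    sels[gb],
                    contact_dist=thr["contact_distance_nm"],
                    persistence_cut=thr["contact_persistence"],
                )
                results["contacts"] = freqs
                results["contacts_persistent"] = persistent
                p = outdir / "contacts.tsv"
                rows = [
                    {
                        "residueA": f"{ka[0]}:{ka[1]}",
                        "residueB": f"{kb[0]}:{kb[1]}",
                        "frequency": v,
                    }
                    for (ka, kb), v in sorted(persistent.items(), key=lambda x: -x[1])
                ]
                pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
                emit("contacts", p)
            elif stage == "stacking":
                rings = config.stacking_rings or _autodetect_rings(topology)
                criteria = StackingCriteria(
                    d_cut=thr["stacking_distance_nm"],
                    alpha_cut=thr["stacking_angle_deg"],
                    occupancy_cut=thr["stacking_occupancy"],
                )
                all_pairs, kept = stacking_occupancy(
                    traj,
                    [tuple(k) for k in rings["protein"]],
                    [tuple(k) for k in rings["nucleic"]],
                    criteria,
                )
                results["stacking"] = all_pairs
                results["stacking_filtered"] = kept
                p = outdir / "stacking.tsv"
                rows = [
                    {
                        "protein_residue": f"{sp.protein_residue[0]}:{sp.protein_residue[1]}",
                        "nucleic_residue": f"{sp.nucleic_residue[0]}:{sp.nucleic_residue[1]}",
                        "occupancy": sp.occupancy,
                    }
                    for sp in kept
                ]
                with open(p, "w") as fh:
                    fh.write(
                        f"# d_cut={criteria.d_cut} nm, alpha_cut={criteria.alpha_cut} deg, "
                        f"occupancy_cut={criteria.occupancy_cut}\n"
                    )
                    pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
                emit("stacking", p)
            elif stage == "mindist":
                if len(sels["protein"]) and len(sels["nucleic"]):
                    res = min_distance_series(traj, sels["protein"], sels["nucleic"])
                    results["mindist"] = res
                    p = outdir / "mindist.tsv"
                    _write_series(p, res, "mindist", "protein|nucleic")
                    emit("mindist", p)
            elif stage == "clashes":
                counts = np.array(
                    [
                        count_clashes(fr, topology, thr["clash_distance_nm"])
                        for fr in traj.frames
                    ]
                )
                results["clashes"] = counts
                p = outdir / "clashes.tsv"
                pd.DataFrame(
                    {"frame": np.arange(len(counts)), "clashes": counts}
                ).to_csv(p, sep="\t", index=False)
                emit("clashes", p)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "discard_frames": config.discard_frames,
        "n_frames_total": full.n_frames,
        "n_frames_analyzed": traj.n_frames,
        "thresholds": dict(thr),
        "selections": dict(config.selections),
        "stages": list(config.stages),
        "notes": [
            "stacking distance cutoff interpreted as 0.55 nm ring-centroid distance",
        ],
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2))
    manifest["provenance"] = str(prov_path)
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2))
    return ReportBundle(manifest=manifest, provenance=provenance, results=results)


def _write_hbond_table(path: Path, table, topology, thr) -> None:
    atoms = topology.atoms
    rows = []
    for (d, h, a), occ in sorted(table.occupancies.items(), key=lambda x: -x[1]):
        rows.append(
            {
                "donor_residue": f"{atoms[d].residue_name}{atoms[d].residue_index}",
                "donor_atom": atoms[d].name,
                "acceptor_residue": f"{atoms[a].residue_name}{atoms[a].residue_index}",
                "acceptor_atom": atoms[a].name,
                "occupancy": occ,
            }
        )
    with open(path, "w") as fh:
        fh.write(
            f"# dist_cut={thr['hbond_distance_nm']} nm, angle_cut={thr['hbond_angle_deg']} deg, "
            f"occupancy_cut={thr['hbond_occupancy']}\n"
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, mode="a")


def _autodetect_rings(topology) -> dict:
    from .interactions import DEFAULT_RING_SPEC

    rings = {"protein": [], "nucleic": []}
    for res in topology.residues:
        if res.residue_name not in DEFAULT_RING_SPEC.rings:
            continue
        names = {topology.atoms[i].name for i in res.atom_indices}
        if len(names & set(DEFAULT_RING_SPEC.rings[res.residue_name])) >= 3:
            cls = topology.atoms[res.first_atom].polymer_class
            if cls in rings:
                rings[cls].append((res.chain_id, res.residue_index))
    return rings


def compare_ensembles(
    bundle_a: ReportBundle,
    bundle_b: ReportBundle,
    density_threshold: float = 0.05,
    bins: int = 40,
) -> dict:
    """Compare two analyzed ensembles (e.g. unbound vs bound).

    Returns per-residue RMSF differences (A - B), radius-of-gyration
    summaries (mean +/- sd), the PC1/PC2 occupied-area ratio at a density
    threshold on a shared grid, and the DCCM difference matrix, for every
    statistic present in both bundles.
    """
    out: dict = {}
    ra, rb = bundle_a.results, bundle_b.results
    if "rmsf" in ra and "rmsf" in rb:
        pa, pb = ra["rmsf"], rb["rmsf"]
        if not np.array_equal(pa.labels, pb.labels):
            raise ValueError(
                "incompatible RMSF selections: residue labels differ "
                f"({len(pa.labels)} vs {len(pb.labels)} atoms)"
            )
        out["rmsf_difference"] = pa.values - pb.values
        out["rmsf_labels"] = pa.labels
    if "rg" in ra and "rg" in rb:
        out["rg_summary"] = {
            "A": (float(np.mean(ra["rg"].values)), float(np.std(ra["rg"].values))),
            "B": (float(np.mean(rb["rg"].values)), float(np.std(rb["rg"].values))),
        }
    if "pca_projections" in ra and "pca_projections" in rb:
        proj_a, proj_b = ra["pca_projections"], rb["pca_projections"]
        allpts = np.vstack([proj_a[:, :2], proj_b[:, :2]])
        xe = np.linspace(allpts[:, 0].min(), allpts[:, 0].max(), bins + 1)
        ye = np.linspace(allpts[:, 1].min(), allpts[:, 1].max(), bins + 1)

        def occupied(proj: np.ndarray) -> int:
            counts, _, _ = np.histogram2d(proj[:, 0], proj[:, 1], bins=(xe, ye))
            peak = counts.max()
            if peak == 0:
                return 0
            return int(np.sum(counts / peak >= density_threshold))

        occ_a, occ_b = occupied(proj_a), occupied(proj_b)
        out["pc_area_bins"] = {"A": occ_a, "B": occ_b}
        out["pc_area_ratio"] = occ_a / occ_b if occ_b else np.inf
    if "dccm" in ra and "dccm" in rb:
        ma, mb = ra["dccm"], rb["dccm"]
        if not np.array_equal(ma.labels, mb.labels):
            raise ValueError("incompatible DCCM selections: labels differ")
        out["dccm_difference"] = ma.matrix - mb.matrix
    return out
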