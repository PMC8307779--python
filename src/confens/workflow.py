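"""End-to-end analysis pipeline with a machine-readable manifest.

Stages mirror the standard ensemble-analysis sequence: superposition →
equilibration removal → descriptors → secondary structure →
interactions → ensemble clustering → free-energy landscapes over
(RMSD, Rg), (Hfp, Rg) and (SASA, Rg) → per-residue Markov models →
replica Fisher–Rao distance matrix → MDS embedding.  Every numeric
output is a TSV; the manifest records parameters, seeds and frame
counts so a rerun with the same seeds is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensembles import (ConformationEnsemble, EnsembleError, concatenate,
                        drop_equilibration, read_ensemble, superpose,
                        write_ensemble, write_table)
from .descriptors import (probability_distribution, radius_of_gyration,
                          rmsd_series, rmsf_per_residue, sasa)
from .secondary_structure import assign_dssp, helical_fraction, helix_segments
from .interactions import (contact_map, hydrogen_bonds, hydrophobic_contacts,
                           records_table, segment_contacts)
from .clustering import cluster_ensemble
from .landscape import FreeEnergyLandscape, ReactionCoordinatePair
from .dynamics import (ClassicalMDS, replica_distance_matrix,
                       transition_matrices)
from .synthetic import kid_like_replicas

log = logging.getLogger("confens.workflow")


@dataclass
class PipelineConfig:
    """All pipeline knobs in one place (YAML-loadable flat mapping)."""

    input_paths: list[str] = field(default_factory=list)
    input_groups: list[str] = field(default_factory=list)
    synthetic: bool = True
    synthetic_frames: int = 1500
    synthetic_coordinate_frames: int = 120
    seed: int = 0
    equilibration_frames: int = 0
    shared_reference: bool = True
    cluster_r: float = 4.0
    cluster_stride: int = 1
    temperature_K: float = 310.0
    knn_k: int | None = None
    grid_nx: int = 100
    grid_ny: int = 100
    min_well_depth: float = 0.5
    contact_cutoff: float = 10.0
    hbond_dist_cutoff: float = 3.6
    hbond_angle_cutoff: float = 120.0
    hydrophobic_cutoff: float = 4.0
    segment_min_occurrence: float = 0.80
    segments: list[tuple[int, int]] = field(
        default_factory=lambda: [(699, 709), (754, 764), (731, 733)])
    sasa_stride: int = 5
    markov_alpha: float = 0.5
    markov_lag: int = 1
    output_dir: str = "confens_out"

    def __post_init__(self):
        for name in ("cluster_r", "contact_cutoff", "hbond_dist_cutoff",
                     "hydrophobic_cutoff", "temperature_K"):
            if getattr(self, name) <= 0:
                raise EnsembleError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise EnsembleError(f"unknown config keys: {sorted(unknown)}")
        if "segments" in data:
            data["segments"] = [tuple(s) for s in data["segments"]]
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are kept."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_replicas(config: PipelineConfig) -> list[dict]:
    if config.synthetic:
        reps = kid_like_replicas(
            n_frames=config.synthetic_frames, seed=config.seed,
            build_coordinates=True,
            coordinate_frames=config.synthetic_coordinate_frames)
        return reps
    if not config.input_paths:
        raise EnsembleError("no input replicas configured")
    groups = config.input_groups or [""] * len(config.input_paths)
    reps = []
    for path, group in zip(config.input_paths, groups):
        ens = read_ensemble(path)
        reps.append({"label": ens.label, "group": group, "ensemble": ens,
                     "track": None})
    return reps


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": [],
        "outputs": [],
    }

    def stage(name):
        log.info("stage %s: start", name)
        manifest["stages"].append(name)
        return time.time()

    def emit(path):
        manifest["outputs"].append(str(path))

    try:
        t0 = stage("input")
        replicas = _load_replicas(config)
        log.info("loaded %d replicas", len(replicas))
    except Exception as exc:
        raise StageError("input", exc) from exc

    try:
        stage("superpose")
        ref_ens = replicas[0]["ensemble"]
        for rec in replicas:
            ens = rec["ensemble"]
            if config.equilibration_frames:
                ens = drop_equilibration(ens, config.equilibration_frames)
            if config.shared_reference and rec is not replicas[0]:
                merged = concatenate([ref_ens, ens], label=ens.label)
                merged = superpose(merged, reference_frame=0)
                coords = merged.coordinates[ref_ens.n_frames:]
                ens = ConformationEnsemble(ens.topology, coords, ens.frame_times,
                                           ens.label)
            else:
                ens = superpose(ens, reference_frame=0)
            rec["ensemble"] = ens
    except Exception as exc:
        raise StageError("superpose", exc) from exc

    try:
        stage("descriptors")
        for rec in replicas:
            ens = rec["ensemble"]
            rec["rmsd"] = rmsd_series(ens)
            rec["rg"] = radius_of_gyration(ens)
            rec["rmsf"] = rmsf_per_residue(ens)
            rec["rmsd"].write(out / f"{rec['label']}_rmsd.tsv")
            rec["rg"].write(out / f"{rec['label']}_rg.tsv")
            rec["rmsf"].write(out / f"{rec['label']}_rmsf.tsv")
            emit(out / f"{rec['label']}_rmsd.tsv")
            hist = probability_distribution(rec["rmsd"], bin_width=0.25)
            hist.write(out / f"{rec['label']}_rmsd_hist.tsv")
    except Exception as exc:
        raise StageError("descriptors", exc) from exc

    try:
        stage("secondary_structure")
        for rec in replicas:
            if rec.get("track") is None:
                rec["track"] = assign_dssp(rec["ensemble"])
            rec["coord_track"] = assign_dssp(rec["ensemble"])
            rec["hfp"] = helical_fraction(rec["coord_track"])
            rec["coord_track"].write(out / f"{rec['label']}_ss.tsv")
            rec["hfp"].write(out / f"{rec['label']}_hfp.tsv")
            segs = helix_segments(rec["coord_track"], min_lifetime=0.1)
            write_table(pd.DataFrame(
                [(s.label, s.start_residue, s.end_residue, s.lifetime,
                  s.alpha_fraction, s.three10_fraction) for s in segs],
                columns=["helix", "start", "end", "lifetime", "alpha_frac",
                         "g_frac"]), out / f"{rec['label']}_helices.tsv")
    except Exception as exc:
        raise StageError("secondary_structure", exc) from exc

    try:
        stage("interactions")
        for rec in replicas:
            ens = rec["ensemble"]
            cm = contact_map(ens, cutoff=config.contact_cutoff)
            cm.write(out / f"{rec['label']}_contacts.tsv")
            hb = hydrogen_bonds(ens, dist_cutoff=config.hbond_dist_cutoff,
                                angle_cutoff=config.hbond_angle_cutoff)
            hp = hydrophobic_contacts(ens, cutoff=config.hydrophobic_cutoff)
            records_table(hb + hp).to_csv(
                out / f"{rec['label']}_interactions.tsv", sep="\t", index=False)
            seg = segment_contacts(cm, config.segments,
                                   min_occurrence=config.segment_min_occurrence)
            records_table(seg).to_csv(
                out / f"{rec['label']}_segment_contacts.tsv", sep="\t",
                index=False)
    except Exception as exc:
        raise StageError("interactions", exc) from exc

    try:
        stage("clustering")
        for i, rec in enumerate(replicas):
            assignment = cluster_ensemble(rec["ensemble"], r=config.cluster_r,
                                          seed=config.seed + i,
                                          stride=config.cluster_stride)
            rec["clusters"] = assignment
            assignment.write(out / f"{rec['label']}_clusters.tsv")
    except Exception as exc:
        raise StageError("clustering", exc) from exc

    try:
        stage("free_energy_landscapes")
        groups = sorted({rec["group"] for rec in replicas})
        fel_summary = []
        for group in groups:
            members = [r for r in replicas if r["group"] == group]
            ens = concatenate([r["ensemble"] for r in members],
                              label=f"group_{group}")
            ens = superpose(ens, reference_frame=0)
            rmsd = rmsd_series(ens)
            rg = radius_of_gyration(ens)
            track = assign_dssp(ens)
            hfp = helical_fraction(track)
            sasa_ens = ens.strided(config.sasa_stride)
            sasa_series = sasa(sasa_ens)
            pairs = {
                "rmsd_rg": (rmsd.values, rg.values),
                "hfp_rg": (hfp.values, rg.values),
                "sasa_rg": (sasa_series.values,
                            rg.values[::config.sasa_stride]),
            }
            for name, (a, b) in pairs.items():
                rc = ReactionCoordinatePair(tuple(name.split("_")),
                                            np.column_stack([a, b]))
                fel = FreeEnergyLandscape(
                    temperature=config.temperature_K, k=config.knn_k,
                    grid_size=(config.grid_nx, config.grid_ny),
                    min_well_depth=config.min_well_depth).fit(rc)
                fel.write(out / f"group_{group}_fel_{name}.tsv")
                fel.write_wells(out / f"group_{group}_wells_{name}.tsv")
                fel_summary.append((group, name, len(fel.wells_)))
        manifest["fel_wells"] = [
            {"group": g, "coordinates": n, "n_wells": w}
            for g, n, w in fel_summary]
    except Exception as exc:
        raise StageError("free_energy_landscapes", exc) from exc

    try:
        stage("folding_dynamics")
        sets = [transition_matrices(rec["track"], alpha=config.markov_alpha,
                                    lag=config.markov_lag)
                for rec in replicas]
        dm = replica_distance_matrix(sets, groups=[r["group"] for r in replicas])
        dm.write(out / "replica_fisher_rao.tsv")
        mds = ClassicalMDS(n_components=2).fit(dm)
        emb = pd.DataFrame({
            "replica": dm.labels,
            "group": [r["group"] for r in replicas],
            "x": mds.embedding_[:, 0], "y": mds.embedding_[:, 1]})
        write_table(emb, out / "replica_mds.tsv")
        manifest["mds_stress"] = mds.stress_
        manifest["n_replicas"] = len(replicas)
    except Exception as exc:
        raise StageError("folding_dynamics", exc) from exc

    manifest["frame_counts"] = {r["label"]: r["ensemble"].n_frames
                                for r in replicas}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    log.info("pipeline complete: %s", out / "manifest.json")
    return manifest
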