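"""End-to-end pipeline: trajectories + cohort table → knob levels → boundary.

Runs the full analysis from files: read each mutant's multi-model PDB
trajectory, score the (shared) binding site's solid-angle curvature per
frame, reduce to knob levels with both methods at every configured
threshold, fit the Response/No-response boundary, and write everything as
CSV/JSON.  Outputs are deterministic for identical inputs and configuration
(fixed float formatting, no timestamps), and every bundle embeds the exact
configuration used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .classify import ClassifierResult, fit_threshold_classifier
from .curvature import CurvatureProfile, trajectory_curvature
from .knob import (CohortRecord, DEFAULT_THRESHOLD, DEFAULT_THRESHOLDS,
                   cohort_to_dataframe, knob_level, read_cohort_csv)
from .structure import BindingSite, read_trajectory, select_binding_site

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6f"


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end run (defaults are the package conventions)."""

    probe_radius: float = 1.4          # Å, solvent probe in the atom weights
    alpha: float = 0.0                 # Å², alpha-shape filtration value
    sa_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    threshold: float = DEFAULT_THRESHOLD   # threshold used for the classifier
    site_mode: Literal["residue-list", "ligand-cutoff"] = "residue-list"
    site_residues: Sequence[tuple[str, int]] | None = None
    site_cutoff: float = 5.0           # Å, ligand-cutoff mode
    ligand_resname: str | None = None
    frame_spacing: float = 10.0        # ps
    method: Literal["A", "B", "both"] = "both"
    jitter_seed: int = 0               # degeneracy-resolution seed
    output_dir: str | Path = "alphapocket_out"

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.sa_thresholds) or self.threshold < 0:
            raise ValueError("solid-angle thresholds must be ≥ 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(d["output_dir"])
        d["sa_thresholds"] = list(d["sa_thresholds"])
        if d["site_residues"] is not None:
            d["site_residues"] = [[c, int(r)] for c, r in d["site_residues"]]
        return d


@dataclass
class PipelineResult:
    records: list[CohortRecord]
    classifiers: dict[str, ClassifierResult]
    profiles: dict[str, CurvatureProfile]
    knob_table: pd.DataFrame
    output_dir: Path


def read_site_residues_csv(path: str | Path) -> list[tuple[str, int]]:
    df = pd.read_csv(path)
    return [(str(c), int(r)) for c, r in zip(df["chain"], df["residue_id"])]


def _methods(config: PipelineConfig) -> list[str]:
    return ["A", "B"] if config.method == "both" else [config.method]


def run_pipeline(config: PipelineConfig, trajectories: Sequence[str | Path],
                 cohort: str | Path) -> PipelineResult:
    """Run the full analysis and write the output bundle.

    ``trajectories`` are multi-model PDB paths whose stems are the mutant
    ids; ``cohort`` is the CSV of clinical response levels.  Every cohort id
    must have a trajectory and vice versa.
    """
    records = read_cohort_csv(cohort)
    paths = {Path(p).stem: Path(p) for p in trajectories}
    cohort_ids = [r.mutant_id for r in records]
    missing = sorted(set(cohort_ids) - set(paths))
    extra = sorted(set(paths) - set(cohort_ids))
    if missing or extra:
        raise ValueError(
            f"cohort/trajectory id mismatch: missing trajectories {missing}, "
            f"unmatched trajectories {extra}")

    outdir = Path(config.output_dir)
    (outdir / "curvature").mkdir(parents=True, exist_ok=True)

    site: BindingSite | None = None
    profiles: dict[str, CurvatureProfile] = {}
    knob_rows = []
    for rec in records:
        traj = read_trajectory(paths[rec.mutant_id], config.frame_spacing,
                               probe_radius=config.probe_radius,
                               ligand_resname=config.ligand_resname)
        if site is None:
            if config.site_mode == "residue-list":
                if not config.site_residues:
                    raise ValueError("residue-list site mode needs site_residues")
                site = select_binding_site(traj.topology, "residue-list",
                                           residues=config.site_residues)
            else:
                site = select_binding_site(traj.topology, "ligand-cutoff",
                                           cutoff=config.site_cutoff)
        member_site = site.resolve(traj.topology)
        logger.info("%s: %d frames, site of %d atoms", rec.mutant_id,
                    traj.n_frames, member_site.n_atoms)
        profile = trajectory_curvature(traj, member_site, config.alpha,
                                       jitter_seed=config.jitter_seed)
        profiles[rec.mutant_id] = profile
        profile.to_dataframe(traj.topology).to_csv(
            outdir / "curvature" / f"{rec.mutant_id}.csv", index=False,
            float_format=FLOAT_FMT)
        for method in _methods(config):
            for t in config.sa_thresholds:
                kr = knob_level(profile, t, method, rec.mutant_id)
                knob_rows.append({"mutant_id": rec.mutant_id, "method": method,
                                  "threshold": t, "knob_level": kr.knob_level,
                                  "n_convex_used": kr.n_convex_used,
                                  "n_empty_frames": kr.n_empty_frames})
                if t == config.threshold:
                    if method == "A":
                        rec.knob_a = kr.knob_level
                    else:
                        rec.knob_b = kr.knob_level

    knob_table = pd.DataFrame(knob_rows)
    knob_table.to_csv(outdir / "knob_levels.csv", index=False,
                      float_format=FLOAT_FMT)

    classifiers: dict[str, ClassifierResult] = {}
    cohort_df = cohort_to_dataframe(records)
    for method in _methods(config):
        clf = fit_threshold_classifier(records, method)
        classifiers[method] = clf
        cohort_df[f"predicted_{method}"] = [
            clf.predict(r.knob(method)) for r in records]
        with open(outdir / f"classifier_{method}.json", "w") as fh:
            json.dump({"method": method, "threshold": config.threshold,
                       "boundary": clf.boundary, "orientation": clf.orientation,
                       "accuracy": clf.accuracy, "errors": clf.errors},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")
    cohort_df.to_csv(outdir / "cohort_results.csv", index=False,
                     float_format=FLOAT_FMT)
    with open(outdir / "run_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(records=records, classifiers=classifiers,
                          profiles=profiles, knob_table=knob_table,
                          output_dir=outdir)
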