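"""Scoring pipeline output against synthetic-scene ground truth.

Matches each ground-truth outgrowth to the detected outgrowth that claimed
its nuclei (nearest-nucleus majority vote) and computes recovery metrics:
phenotype accuracy, migratory-cell count error, total migration distance
error and maximum invasion depth error. Used by the test suite and the
acceptance script; not part of the analysis of real images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .spheroid import SpheroidResult
from .synthetic import SceneGroundTruth

_CLS_TO_PHENOTYPE = {
    "contiguous_strand": "strand",
    "disconnected_cluster": "cluster",
    "disconnected_single": "single",
}


@dataclass
class SceneScore:
    n_truth_outgrowths: int
    n_phenotype_correct: int
    truth_migratory: int
    detected_migratory: int
    truth_distance_um: float
    detected_distance_um: float
    truth_max_depth_um: float
    detected_max_depth_um: float
    nuclei_conserved: bool


def score_scene(truth: SceneGroundTruth, result: SpheroidResult,
                match_radius_px: float = 8.0) -> SceneScore:
    """Score one analyzed scene against its ground truth."""
    det_nuclei = []
    det_owner = []
    for o in result.outgrowths:
        for p in o.nuclei_xy:
            det_nuclei.append(p)
            det_owner.append(o.index)
    det_nuclei = np.array(det_nuclei).reshape(-1, 2)
    by_index = {o.index: o for o in result.outgrowths}

    n_correct = 0
    tdf = truth.outgrowths
    mig = truth.nuclei[truth.nuclei["outgrowth"] >= 0]
    tree = cKDTree(det_nuclei) if det_nuclei.size else None
    for row in tdf.itertuples():
        expected = _CLS_TO_PHENOTYPE[row.cls]
        nuc = mig[mig["outgrowth"] == row.outgrowth]
        votes = []
        if tree is not None and len(nuc):
            d, idx = tree.query(nuc[["x_px", "y_px"]].to_numpy())
            votes = [det_owner[i] for di, i in zip(d, idx)
                     if di <= match_radius_px]
        if not votes:
            continue
        owner = max(set(votes), key=votes.count)
        if by_index[owner].phenotype == expected:
            n_correct += 1

    mt = result.totals()
    conserved = result.n_detected_nuclei == (
        result.n_body_nuclei + sum(o.n_nuclei for o in result.outgrowths))
    return SceneScore(
        n_truth_outgrowths=len(tdf),
        n_phenotype_correct=n_correct,
        truth_migratory=int(truth.totals["n_migratory_cells"]),
        detected_migratory=int(mt["n_migratory_cells"]),
        truth_distance_um=float(truth.totals["total_migration_distance_um"]),
        detected_distance_um=float(mt["total_migration_distance_um"]),
        truth_max_depth_um=float(truth.totals["max_invasion_depth_um"]),
        detected_max_depth_um=float(mt["max_invasion_depth_um"]),
        nuclei_conserved=conserved,
    )


@dataclass
class PopulationScore:
    """Aggregated recovery metrics over a population of scenes."""
    phenotype_accuracy: float
    count_rel_error: float
    distance_rel_error: float
    depth_rel_error: float
    all_conserved: bool
    n_scenes: int

    @classmethod
    def from_scores(cls, scores) -> "PopulationScore":
        n_out = sum(s.n_truth_outgrowths for s in scores)
        tm = sum(s.truth_migratory for s in scores)
        dm = sum(s.detected_migratory for s in scores)
        td = sum(s.truth_distance_um for s in scores)
        dd = sum(s.detected_distance_um for s in scores)
        # max depth compared per scene (the paper reports it per spheroid)
        depth_errs = [abs(s.detected_max_depth_um / s.truth_max_depth_um - 1)
                      for s in scores if s.truth_max_depth_um > 0]
        return cls(
            phenotype_accuracy=sum(s.n_phenotype_correct
                                   for s in scores) / n_out,
            count_rel_error=abs(dm / tm - 1.0),
            distance_rel_error=abs(dd / td - 1.0),
            depth_rel_error=max(depth_errs) if depth_errs else 0.0,
            all_conserved=all(s.nuclei_conserved for s in scores),
            n_scenes=len(scores),
        )
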