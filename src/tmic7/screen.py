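"""Candidate-discovery orchestration: forward screen, reverse validation,
topology and fold checks, control bands, and per-candidate reports.

The procedure mirrors the structural screening workflow: align every
library structure to the query, rank by Z-score, keep hits above the
threshold (default Z > 10), then for each hit (a) verify by a reverse
search of a reference structural proteome that the query's family is the
top hit, (b) check the three topology criteria, (c) detect the fold
features, and (d) compare scores to positive/negative control bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .distscore import (ZCalibration, distance_matrix, elastic_score,
                        optimize_path_subset, z_score)
from .structure_io import ChainStructure
from .superpose import tm_align
from .topology import (FoldFeatures, TopologyModel, TopologyVerdict,
                       detect_fold_features, evaluate_criteria)

__all__ = [
    "ScreenConfig",
    "ScreenHit",
    "ControlBands",
    "CandidateReport",
    "compare_to_query",
    "forward_screen",
    "reverse_validate",
    "control_bands",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    z_threshold: float = 10.0
    reverse_top_k: int = 10
    target_family_ids: frozenset[str] = frozenset()
    positive_controls: frozenset[str] = frozenset()
    negative_controls: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        self.target_family_ids = frozenset(self.target_family_ids)
        self.positive_controls = frozenset(self.positive_controls)
        self.negative_controls = frozenset(self.negative_controls)
        if self.positive_controls & self.negative_controls:
            raise ValueError("control sets must be disjoint")


@dataclass(frozen=True)
class ScreenHit:
    protein_id: str
    z: float
    rank: int


@dataclass
class ControlBands:
    """Score ranges of positive controls and maxima of negative controls,
    for both the Z and TM-score channels."""

    positive_range: dict[str, tuple[float, float]]
    negative_max: dict[str, float]


@dataclass
class CandidateReport:
    protein_id: str
    z: float
    passed_threshold: bool
    reverse_validated: bool
    reverse_top_k_fraction: float
    topology: TopologyVerdict | None
    fold: FoldFeatures | None
    tm_score_vs_query: float
    within_positive_band: bool
    above_negative_band: bool
    final_call: str  # {"candidate", "rejected", "ambiguous"}

    def __post_init__(self):
        if self.final_call == "candidate":
            ok = (self.passed_threshold and self.reverse_validated and
                  self.topology is not None and self.topology.passes and
                  self.above_negative_band)
            if not ok:
                raise ValueError("candidate call violates gate invariant")


def compare_to_query(query: ChainStructure, target: ChainStructure,
                     cal: ZCalibration):
    """Align target to query; return (StructAlignResult, elastic raw, z)."""
    res = tm_align(query, target)
    DA, DB = distance_matrix(query), distance_matrix(target)
    path = optimize_path_subset(res.path, DA, DB)
    raw = elastic_score(path, DA, DB)
    z = z_score(raw, len(query), len(target), cal)
    return res, raw, z


def forward_screen(query: ChainStructure, library: list[ChainStructure],
                   cfg: ScreenConfig, cal: ZCalibration) -> list[ScreenHit]:
    """Score every library member against the query; keep z > threshold.

    Ranks are 1..n by descending z, ties broken by id, so the result is
    invariant under permutation of the library.
    """
    if not library:
        raise ValueError("empty library")
    scored = []
    for member in library:
        _, _, z = compare_to_query(query, member, cal)
        log.info("forward screen: %s z=%.2f", member.identifier, z)
        scored.append((member.identifier, z))
    hits = [(pid, z) for pid, z in scored if z > cfg.z_threshold]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return [ScreenHit(pid, z, rank) for rank, (pid, z) in enumerate(hits, start=1)]


def reverse_validate(candidate: ChainStructure,
                     reference_proteome: list[ChainStructure],
                     cfg: ScreenConfig, cal: ZCalibration
                     ) -> tuple[bool, float]:
    """Reverse-search the reference proteome with the candidate as query.

    Validation passes iff the top-1 reverse hit belongs to the target
    family; the fraction of the top-k hits in the family is also returned
    for transparency.
    """
    if not reference_proteome:
        raise ValueError("empty reference proteome")
    ids = {c.identifier for c in reference_proteome}
    if not cfg.target_family_ids or not cfg.target_family_ids <= ids:
        raise ValueError("target_family_ids must be a subset of the "
                         "reference proteome")
    scored = []
    for member in reference_proteome:
        _, _, z = compare_to_query(candidate, member, cal)
        scored.append((member.identifier, z))
    scored.sort(key=lambda t: (-t[1], t[0]))
    top1 = scored[0][0] in cfg.target_family_ids
    k = min(cfg.reverse_top_k, len(scored))
    frac = sum(1 for pid, _ in scored[:k] if pid in cfg.target_family_ids) / k
    return top1, frac


def control_bands(query: ChainStructure, controls: list[ChainStructure],
                  cfg: ScreenConfig, cal: ZCalibration) -> ControlBands:
    """Positive-range and negative-max bands for the z and TM channels."""
    pos = {c.identifier: c for c in controls if c.identifier in cfg.positive_controls}
    neg = {c.identifier: c for c in controls if c.identifier in cfg.negative_controls}
    if not pos or not neg:
        raise ValueError("both control sets must be non-empty")
    chans: dict[str, dict[str, float]] = {"z": {}, "tm": {}}
    for cid, chain in {**pos, **neg}.items():
        res, _, z = compare_to_query(query, chain, cal)
        chans["z"][cid] = z
        chans["tm"][cid] = res.tm_score_by_A
    positive_range = {ch: (min(chans[ch][i] for i in pos),
                           max(chans[ch][i] for i in pos)) for ch in chans}
    negative_max = {ch: max(chans[ch][i] for i in neg) for ch in chans}
    return ControlBands(positive_range=positive_range, negative_max=negative_max)


def run_pipeline(query: ChainStructure, library: list[ChainStructure],
                 reference_proteome: list[ChainStructure],
                 topologies: dict[str, TopologyModel],
                 cfg: ScreenConfig, cal: ZCalibration,
                 controls: list[ChainStructure] | None = None,
                 bands: ControlBands | None = None) -> list[CandidateReport]:
    """Full screening pipeline; returns one report per above-threshold hit.

    A hit becomes a ``candidate`` only if it passes the Z threshold, is
    reverse-validated, satisfies all three topology criteria, and scores
    clearly above the negative controls (both channels).  Hits whose
    topology is unavailable are ``ambiguous``; every other failure is
    ``rejected``.  Fold features are reported, not gated.
    """
    if bands is None and controls:
        bands = control_bands(query, controls, cfg, cal)
    by_id = {c.identifier: c for c in library}
    comparisons = {c.identifier: compare_to_query(query, c, cal) for c in library}
    scored = sorted(((pid, z) for pid, (_, _, z) in comparisons.items()
                     if z > cfg.z_threshold), key=lambda t: (-t[1], t[0]))
    hits = [ScreenHit(pid, z, rank) for rank, (pid, z) in enumerate(scored, start=1)]
    reports: list[CandidateReport] = []
    for hit in hits:
        chain = by_id[hit.protein_id]
        res, _, z = comparisons[hit.protein_id]
        rev, frac = reverse_validate(chain, reference_proteome, cfg, cal)
        topo = topologies.get(hit.protein_id)
        verdict = evaluate_criteria(topo) if topo is not None else None
        fold = None
        if topo is not None and topo.length == len(chain) and topo.membrane_segments:
            fold = detect_fold_features(chain, topo)
        tm = res.tm_score_by_A
        if bands is not None:
            above_neg = (z > bands.negative_max["z"] and
                         tm > bands.negative_max["tm"])
            lo, hi = bands.positive_range["tm"]
            within_pos = lo <= tm <= hi
        else:
            above_neg, within_pos = True, False
        passed = z > cfg.z_threshold
        if topo is None:
            call = "ambiguous"
        elif passed and rev and verdict.passes and above_neg:
            call = "candidate"
        else:
            call = "rejected"
        reports.append(CandidateReport(
            protein_id=hit.protein_id, z=z, passed_threshold=passed,
            reverse_validated=rev, reverse_top_k_fraction=frac,
            topology=verdict, fold=fold, tm_score_vs_query=tm,
            within_positive_band=within_pos, above_negative_band=above_neg,
            final_call=call))
    reports.sort(key=lambda r: (-r.z, r.protein_id))
    return reports
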