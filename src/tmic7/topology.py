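"""Membrane topology models and the 7TMIC candidate criteria.

Topology can come from an external predictor table (DeepTMHMM/Phobius-style
output, ingested as plain text) or from a built-in Kyte-Doolittle hydropathy
stand-in so the pipeline runs without any external predictor.  On top of a
topology model the module evaluates the three candidate criteria used in
the screen: seven TM segments, intracellular N-terminus, and longer
intracellular than extracellular loops; and, given a structure, the two
fold features characteristic of the Or/Gr fold: the TM7a/TM7b split and the
cytoplasmic anchor projection of TM4-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import ChainStructure

__all__ = [
    "TMSegment",
    "TopologyModel",
    "TopologyVerdict",
    "FoldFeatures",
    "read_topology_table",
    "predict_topology_hydropathy",
    "evaluate_criteria",
    "detect_fold_features",
    "KYTE_DOOLITTLE",
]

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

SLAB_THICKNESS = 30.0    # Angstrom; hydrophobic bilayer thickness
KINK_ANGLE_DEG = 20.0    # helix-break threshold within TM7
ANCHOR_MIN_EXTENSION = 10.0  # Angstrom beyond the cytosolic slab face


@dataclass(frozen=True)
class TMSegment:
    start: int   # 0-based, half-open over the sequence
    end: int
    kind: str    # {"membrane", "inside", "outside"}

    def __post_init__(self):
        if self.kind not in {"membrane", "inside", "outside"}:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.start >= self.end:
            raise ValueError("segment start must precede end")

    def __len__(self):
        return self.end - self.start


@dataclass
class TopologyModel:
    """Ordered segments tiling one sequence, with sidedness."""

    segments: list[TMSegment]

    def __post_init__(self):
        segs = self.segments
        if not segs:
            raise ValueError("empty topology")
        for a, b in zip(segs, segs[1:]):
            if b.start != a.end:
                raise ValueError(f"segments do not tile: [{a.start},{a.end}) then "
                                 f"[{b.start},{b.end})")
        # membrane segments must alternate sides: the non-membrane kinds
        # before and after each membrane segment must differ
        sides = [s.kind for s in segs if s.kind != "membrane"]
        for x, y in zip(sides, sides[1:]):
            if x == y:
                raise ValueError("membrane segments do not alternate sides "
                                 f"({x!r} followed by {y!r})")

    @property
    def length(self) -> int:
        return self.segments[-1].end

    @property
    def membrane_segments(self) -> list[TMSegment]:
        return [s for s in self.segments if s.kind == "membrane"]

    @property
    def n_terminus_side(self) -> str:
        for s in self.segments:
            if s.kind != "membrane":
                return s.kind
        return "inside"

    def loop_lengths(self, side: str) -> int:
        """Summed length of internal loops on one side (terminal tails excluded)."""
        segs = self.segments
        total = 0
        for i, s in enumerate(segs):
            if s.kind == side and 0 < i < len(segs) - 1:
                total += len(s)
        return total


@dataclass(frozen=True)
class TopologyVerdict:
    seven_tm: bool
    n_term_intracellular: bool
    loops_longer_inside: bool

    @property
    def passes(self) -> bool:
        return self.seven_tm and self.n_term_intracellular and self.loops_longer_inside


@dataclass(frozen=True)
class FoldFeatures:
    tm7_split: bool
    anchor_projection: bool
    helix_count_in_slab: int


_KIND_ALIASES = {
    "membrane": "membrane", "tmhelix": "membrane", "tm": "membrane", "m": "membrane",
    "inside": "inside", "in": "inside", "cytoplasmic": "inside", "i": "inside",
    "outside": "outside", "out": "outside", "extracellular": "outside", "o": "outside",
    "periplasmic": "outside", "signal": "outside",
}


def read_topology_table(path) -> dict[str, TopologyModel]:
    """Parse a 3-column predictor table: id, segment label, start-end.

    Coordinates in the file are 1-based inclusive (predictor convention);
    they are converted to 0-based half-open.  Lines starting with '#' and
    blank lines are ignored.  Violated tiling/alternation raises with the
    offending sequence id.
    """
    raw: dict[str, list[TMSegment]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 3 and "-" in parts[2]:
                sid, label, span = parts
                a, b = span.split("-")
            elif len(parts) >= 4:
                sid, label, a, b = parts[:4]
            else:
                raise ValueError(f"{path}:{ln}: unparseable line {line!r}")
            kind = _KIND_ALIASES.get(label.lower())
            if kind is None:
                raise ValueError(f"{path}:{ln}: unknown segment label {label!r} "
                                 f"for {sid}")
            raw.setdefault(sid, []).append(TMSegment(int(a) - 1, int(b), kind))
    out = {}
    for sid, segs in raw.items():
        segs.sort(key=lambda s: s.start)
        try:
            out[sid] = TopologyModel(segs)
        except ValueError as exc:
            raise ValueError(f"{sid}: {exc}") from exc
    return out


def predict_topology_hydropathy(seq: str, window: int = 19,
                                cutoff: float = 1.6) -> TopologyModel:
    """Kyte-Doolittle sliding-window stand-in for a TM topology predictor.

    Maximal runs of window-means above ``cutoff`` of length >= 15 become
    membrane segments; orientation follows the positive-inside rule (the
    loop side with more K+R in 15-residue membrane flanks is 'inside').
    """
    n = len(seq)
    if n <= window:
        raise ValueError(f"sequence length {n} not greater than window {window}")
    vals = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in seq])
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    half = window // 2
    above = means > cutoff  # index i covers window centered at i + half
    runs = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            if j - i >= 15:
                runs.append((i + half, j + half))  # centers of qualifying windows
            i = j
        else:
            i += 1
    if not runs:
        return TopologyModel([TMSegment(0, n, "inside")])
    # positive-inside: count K/R in 15-residue flanks, grouped by loop parity
    kr = np.array([1 if c in "KR" else 0 for c in seq])
    side_count = [0, 0]  # parity of the flank region (0 = N-terminal side of TM1)
    for k, (a, b) in enumerate(runs):
        side_count[k % 2] += int(kr[max(0, a - 15):a].sum())
        side_count[(k + 1) % 2] += int(kr[b:b + 15].sum())
    inside_parity = 0 if side_count[0] >= side_count[1] else 1
    segments = []
    prev = 0
    for k, (a, b) in enumerate(runs):
        side = "inside" if k % 2 == inside_parity else "outside"
        if a > prev:
            segments.append(TMSegment(prev, a, side))
        segments.append(TMSegment(a, b, "membrane"))
        prev = b
    final_side = "inside" if len(runs) % 2 == inside_parity else "outside"
    if prev < n:
        segments.append(TMSegment(prev, n, final_side))
    return TopologyModel(segments)


def evaluate_criteria(t: TopologyModel) -> TopologyVerdict:
    """The three screen criteria for a candidate 7TMIC topology."""
    return TopologyVerdict(
        seven_tm=len(t.membrane_segments) == 7,
        n_term_intracellular=t.n_terminus_side == "inside",
        loops_longer_inside=t.loop_lengths("inside") > t.loop_lengths("outside"),
    )


def _membrane_normal(X: np.ndarray, t: TopologyModel) -> np.ndarray:
    axes = []
    for seg in t.membrane_segments:
        v = X[seg.end - 1] - X[seg.start]
        nv = np.linalg.norm(v)
        if nv > 1e-9:
            axes.append(v / nv)
    if not axes:
        raise ValueError("no membrane segments to estimate a normal from")
    ref = axes[0]
    aligned = [a if a @ ref >= 0 else -a for a in axes]
    m = np.mean(aligned, axis=0)
    return m / np.linalg.norm(m)


def _best_slab(proj_mem: np.ndarray, thickness: float) -> tuple[float, float]:
    """30 A window along the normal maximizing membrane-residue occupancy.

    Ties (plateaus are common for idealized bundles) resolve toward the
    window centered nearest the median membrane projection.
    """
    s = np.sort(proj_mem)
    med = np.median(s)
    best = None
    for lo in s:
        hi = lo + thickness
        count = int(np.searchsorted(s, hi, side="right") - np.searchsorted(s, lo))
        center_off = abs(lo + thickness / 2 - med)
        key = (-count, center_off)
        if best is None or key < best[0]:
            best = (key, lo)
    # also try windows ending at each residue
    for hi in s:
        lo = hi - thickness
        count = int(np.searchsorted(s, hi, side="right") - np.searchsorted(s, lo))
        center_off = abs(lo + thickness / 2 - med)
        key = (-count, center_off)
        if key < best[0]:
            best = (key, lo)
    lo = best[1]
    return float(lo), float(lo + thickness)


def _segment_breakpoint(Xseg: np.ndarray, ss_seg: str) -> tuple[int | None, float]:
    """Find a helix break: a >=2-residue non-helical gap, else the max kink."""
    n = len(Xseg)
    interior = ss_seg[2:-2]
    # non-helical gap of >= 2 in the segment interior
    run, run_start = 0, None
    for i, c in enumerate(interior):
        if c != "H":
            if run == 0:
                run_start = i
            run += 1
            if run >= 2:
                return run_start + 2 + 1, 180.0  # break after gap start
        else:
            run = 0
    best_k, best_angle = None, 0.0
    for k in range(4, n - 3):
        v1 = Xseg[k - 1] - Xseg[0]
        v2 = Xseg[-1] - Xseg[k]
        c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
        ang = float(np.degrees(np.arccos(np.clip(c, -1, 1))))
        if ang > best_angle:
            best_angle, best_k = ang, k
    if best_angle >= KINK_ANGLE_DEG:
        return best_k, best_angle
    return None, best_angle


def detect_fold_features(s: ChainStructure, t: TopologyModel) -> FoldFeatures:
    """Detect the TM7a/7b split and the anchor-domain projection of TM4-6.

    The membrane slab is the 30 A layer (along the mean TM-helix axis)
    maximizing membrane-segment C-alpha occupancy; all geometry is computed
    in projections onto that axis, so the result is invariant under rigid
    transforms of the structure.
    """
    if t.length != len(s):
        raise ValueError(f"topology length {t.length} != structure length {len(s)}")
    from .superpose import secondary_structure

    X = s.coords
    normal = _membrane_normal(X, t)
    proj = X @ normal
    mem_idx = np.concatenate([np.arange(seg.start, seg.end)
                              for seg in t.membrane_segments])
    lo, hi = _best_slab(proj[mem_idx], SLAB_THICKNESS)
    # which slab face is cytosolic: side of the 'inside' residues
    inside_idx = [i for seg in t.segments if seg.kind == "inside"
                  for i in range(seg.start, seg.end)]
    if inside_idx:
        inside_mean = float(proj[inside_idx].mean())
    else:
        inside_mean = lo - 1.0
    cyto_low = inside_mean < (lo + hi) / 2

    mem_segs = t.membrane_segments
    helix_in_slab = 0
    for seg in mem_segs:
        c = float(proj[seg.start:seg.end].mean())
        if lo <= c <= hi:
            helix_in_slab += 1

    def beyond_cyto(p: np.ndarray) -> np.ndarray:
        return (lo - p) if cyto_low else (p - hi)

    tm7_split = False
    if len(mem_segs) >= 7:
        seg = mem_segs[6]
        Xseg = X[seg.start:seg.end]
        ss = secondary_structure(s)[seg.start:seg.end]
        k, _ = _segment_breakpoint(Xseg, ss)
        if k is not None and 2 <= k <= len(Xseg) - 3:
            p1 = float(proj[seg.start:seg.start + k].mean())
            p2 = float(proj[seg.start + k:seg.end].mean())
            out1 = beyond_cyto(np.array([p1]))[0] > 0
            out2 = beyond_cyto(np.array([p2]))[0] > 0
            in1 = lo <= p1 <= hi
            in2 = lo <= p2 <= hi
            tm7_split = bool((out1 and in2) or (out2 and in1))

    anchor = False
    if len(mem_segs) >= 6:
        ext = []
        for seg in mem_segs[3:6]:
            ext.append(float(beyond_cyto(proj[seg.start:seg.end]).max()))
        anchor = min(ext) >= ANCHOR_MIN_EXTENSION

    return FoldFeatures(tm7_split=tm7_split, anchor_projection=anchor,
                        helix_count_in_slab=helix_in_slab)
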