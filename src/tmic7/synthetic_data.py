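"""Synthetic inputs with planted ground truth for every pipeline stage.

Structures are idealized C-alpha alpha-helices (1.5 A rise, 100 deg/residue)
packed on a circle and joined by loops; this is deliberately not biophysical
realism — it exists so that score monotonicity, topology criteria, fold
features, calibration, and the end-to-end screen can be exercised with
known answers and no downloads.  Sequence families are generated by point
substitution from family ancestors at controlled identity levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import ChainStructure, ResidueRecord
from .topology import TMSegment, TopologyModel

__all__ = [
    "BundleSpec",
    "FamilySpec",
    "make_bundle",
    "perturb",
    "make_decoys",
    "make_family_sequences",
    "make_gene_model",
]

RISE = 1.5            # A per residue along an ideal helix axis
TURN = 100.0          # degrees per residue
HELIX_RADIUS = 2.3    # A, C-alpha radius about the helix axis
CA_STEP = 3.8         # A, consecutive C-alpha spacing used for loops/tails

MEMBRANE_AA = "LIVFALIVM"          # hydrophobic TM stretch
INSIDE_AA = "KRKRSGKT"             # positive-inside loops
OUTSIDE_AA = "EDSTNQGE"            # extracellular loops
AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class BundleSpec:
    n_helices: int = 7
    helix_length: int = 25
    split_seventh: bool = False
    anchor_extension: float = 0.0   # A below the slab for helices 4-6
    seed: int = 0

    def __post_init__(self):
        if self.n_helices < 1:
            raise ValueError("n_helices must be >= 1")
        if self.helix_length < 10:
            raise ValueError("helix_length must be >= 10")


@dataclass
class FamilySpec:
    n_families: int = 3
    members_per_family: int = 5
    within_identity: float = 0.92
    between_identity: float = 0.40
    length: int = 300
    seed: int = 0

    def __post_init__(self):
        if not self.within_identity > self.between_identity:
            raise ValueError("within_identity must exceed between_identity")


def _ideal_helix(n_res: int, phase_deg: float = 0.0) -> np.ndarray:
    """Ideal alpha-helix along +z, first residue at z=0."""
    k = np.arange(n_res)
    ang = np.radians(phase_deg + TURN * k)
    return np.stack([HELIX_RADIUS * np.cos(ang),
                     HELIX_RADIUS * np.sin(ang),
                     RISE * k], axis=1)


def _place_helix(n_res: int, center_xy: np.ndarray, z_start: float, up: bool,
                 phase: float = 0.0, axis: np.ndarray | None = None) -> np.ndarray:
    """Helix of n_res residues; N-terminal residue at z_start, running up or down."""
    local = _ideal_helix(n_res, phase)
    if axis is not None:
        axis = axis / np.linalg.norm(axis)
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, axis)
        s, c = np.linalg.norm(v), float(z @ axis)
        if s < 1e-12:
            R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            R = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
        local = local @ R.T
    elif not up:
        # rotate 180 deg about x: keeps handedness, axis now -z
        local = local * np.array([1.0, -1.0, -1.0])
    local[:, 0] += center_xy[0]
    local[:, 1] += center_xy[1]
    local[:, 2] += z_start
    return local


def _loop(P: np.ndarray, Q: np.ndarray, n_res: int, bulge_dir: np.ndarray) -> np.ndarray:
    t = (np.arange(n_res) + 1.0) / (n_res + 1.0)
    base = P[None, :] + t[:, None] * (Q - P)[None, :]
    h = 1.5 + 0.55 * n_res
    return base + np.sin(np.pi * t)[:, None] * h * bulge_dir[None, :]


def _seq(rng: np.random.Generator, pool: str, n: int) -> list[str]:
    return [pool[i] for i in rng.integers(0, len(pool), n)]


def make_bundle(spec: BundleSpec) -> tuple[ChainStructure, TopologyModel]:
    """Idealized TM-helix bundle plus its ground-truth topology.

    N-terminus is intracellular (below the membrane), helices alternate
    direction, intracellular loops are longer than extracellular ones, so a
    7-helix bundle passes all three candidate criteria by construction.
    The optional seventh-helix split plants a TM7a sub-helix below the slab
    joined by a short non-helical connector to a membrane-spanning TM7b;
    the optional anchor extension prolongs helices 4-6 below the slab.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_helices
    H = spec.helix_length * RISE
    z_lo, z_hi = -H / 2.0, H / 2.0
    radius = 0.0 if n == 1 else max(6.0, 9.4 / (2.0 * math.sin(math.pi / n)))
    centers = [np.array([radius * math.cos(2 * math.pi * i / n),
                         radius * math.sin(2 * math.pi * i / n)]) for i in range(n)]
    loop_in, loop_out = 14, 8
    tail_n, tail_c = 10, 4

    coords: list[np.ndarray] = []
    seq: list[str] = []
    segments: list[TMSegment] = []
    pos = 0

    def add(block: np.ndarray, letters: list[str], kind: str):
        nonlocal pos
        coords.append(block)
        seq.extend(letters)
        k = len(letters)
        if segments and segments[-1].kind == kind and kind != "membrane":
            last = segments.pop()
            segments.append(TMSegment(last.start, pos + k, kind))
        else:
            segments.append(TMSegment(pos, pos + k, kind))
        pos += k

    # intracellular N-tail descending below helix 1
    start1 = np.array([centers[0][0], centers[0][1], z_lo])
    tail = np.stack([start1 + np.array([0.5 * (i + 1), 0.2 * (i + 1),
                                        -CA_STEP * (tail_n - i)])
                     for i in range(tail_n)])
    add(tail, ["M"] + _seq(rng, INSIDE_AA, tail_n - 1), "inside")

    prev_end = None
    for i in range(n):
        up = (i % 2 == 0)
        extended = (spec.anchor_extension > 0 and n >= 6 and i in (3, 4, 5))
        lo_i = z_lo - (spec.anchor_extension if extended else 0.0)
        n_res = int(round((z_hi - lo_i) / RISE))
        split_here = spec.split_seventh and n >= 7 and i == 6
        if split_here:
            # TM7a: tilted sub-helix below the slab, short non-helical
            # connector, then TM7b spanning the membrane
            phi = 2 * math.pi * i / n
            tilt = np.array([math.sin(math.radians(50)) * math.cos(phi),
                             math.sin(math.radians(50)) * math.sin(phi),
                             math.cos(math.radians(50))])
            n_7a, n_conn = 10, 2
            b_start = np.array([centers[i][0], centers[i][1], -12.0])
            a_end = b_start + np.array([-2.0, 0.0, -5.0])
            a_start = a_end - tilt * RISE * (n_7a - 1)
            tm7a = _place_helix(n_7a, np.zeros(2), 0.0, True, axis=tilt)
            tm7a = tm7a - tm7a[0] + a_start
            t = (np.arange(n_conn) + 1.0) / (n_conn + 1.0)
            conn = tm7a[-1][None, :] + t[:, None] * (b_start - tm7a[-1])[None, :]
            n_7b = int(round((z_hi - (-12.0)) / RISE))
            tm7b = _place_helix(n_7b, centers[i], -12.0, True,
                                phase=rng.uniform(0, 360))
            block = np.concatenate([tm7a, conn, tm7b])
        else:
            block = _place_helix(n_res, centers[i], lo_i if up else z_hi, up,
                                 phase=rng.uniform(0, 360))
        if prev_end is not None:
            # loop joining previous helix C-end to this helix N-end
            side_out = (i % 2 == 1)   # after an up-helix the loop is at the top
            n_loop = loop_out if side_out else loop_in
            bulge = np.array([0.0, 0.0, 1.0 if side_out else -1.0])
            lp = _loop(prev_end, block[0], n_loop, bulge)
            add(lp, _seq(rng, OUTSIDE_AA if side_out else INSIDE_AA, n_loop),
                "outside" if side_out else "inside")
        add(block, _seq(rng, MEMBRANE_AA, len(block)), "membrane")
        prev_end = block[-1]
    # C-tail: on the side where the last helix ends
    last_up = ((n - 1) % 2 == 0)
    side = "outside" if last_up else "inside"
    dz = CA_STEP if last_up else -CA_STEP
    ctail = np.stack([prev_end + np.array([0.4 * (i + 1), -0.3 * (i + 1),
                                           dz * (i + 1)]) for i in range(tail_c)])
    add(ctail, _seq(rng, OUTSIDE_AA if side == "outside" else INSIDE_AA, tail_c), side)

    xyz = np.concatenate(coords)
    residues = [ResidueRecord("A", i + 1, aa, tuple(p))
                for i, (aa, p) in enumerate(zip(seq, xyz))]
    chain = ChainStructure(f"bundle-n{n}-s{spec.seed}", residues, source="predicted")
    topo = TopologyModel(segments)
    assert topo.length == len(chain)
    return chain, topo


def perturb(s: ChainStructure, sigma: float, seed: int = 0) -> ChainStructure:
    """Add zero-mean Gaussian displacement (sigma per axis) to every C-alpha."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    xyz = s.coords + rng.normal(0.0, sigma, size=(len(s), 3))
    return s.with_coords(xyz, identifier=f"{s.identifier}-p{sigma}s{seed}")


def _random_rigid(rng: np.random.Generator, X: np.ndarray) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return X @ R.T + rng.normal(0, 5, 3)


def _extended_chain(rng: np.random.Generator, n: int) -> np.ndarray:
    """Beta/extended-like zigzag with occasional random turns."""
    pts = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    perp = np.array([0.0, 1.0, 0.0])
    for i in range(1, n):
        if i % int(rng.integers(10, 25)) == 0:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            perp = np.cross(direction, rng.normal(size=3))
            perp /= np.linalg.norm(perp)
        zig = perp * (1.0 if i % 2 else -1.0)
        step = direction * 3.3 + zig * 1.9
        step = step / np.linalg.norm(step) * CA_STEP
        pts.append(pts[-1] + step)
    return np.stack(pts)


def make_decoys(n: int, length_range: tuple[int, int] = (100, 600),
                seed: int = 0) -> list[ChainStructure]:
    """Non-7TMIC negative controls: varied helical bundles and extended chains.

    Bundle decoys use 3-12 helices (never 7), randomized packing radius,
    helix tilt/length, and loop lengths, plus coordinate jitter, so that
    none shares the query template's geometry.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    rng = np.random.default_rng(seed)
    out: list[ChainStructure] = []
    for d in range(n):
        target = int(rng.integers(lo, hi + 1))
        if rng.random() < 0.30:
            xyz = _extended_chain(rng, target)
        else:
            nh = int(rng.choice([3, 4, 5, 6, 8, 9, 10, 12]))
            hl = int(rng.integers(14, 31))
            loop = int(rng.integers(4, 12))
            radius = max(5.0, (9.4 + rng.uniform(-1.5, 4.0)) /
                         (2.0 * math.sin(math.pi / max(nh, 2))))
            blocks = []
            prev = None
            for i in range(nh):
                ang = 2 * math.pi * i / nh
                c = np.array([radius * math.cos(ang), radius * math.sin(ang)])
                up = i % 2 == 0
                tilt_deg = rng.uniform(0, 25)
                tphi = rng.uniform(0, 2 * math.pi)
                ax = np.array([math.sin(math.radians(tilt_deg)) * math.cos(tphi),
                               math.sin(math.radians(tilt_deg)) * math.sin(tphi),
                               math.cos(math.radians(tilt_deg))])
                if not up:
                    ax = -ax
                nres = hl + int(rng.integers(-3, 4))
                z0 = -hl * RISE / 2 if up else hl * RISE / 2
                hx = _place_helix(nres, np.zeros(2), 0.0, True, axis=ax,
                                  phase=rng.uniform(0, 360))
                hx = hx - hx[0] + np.array([c[0], c[1], z0])
                if prev is not None:
                    nl = loop + int(rng.integers(-2, 3))
                    blocks.append(_loop(prev, hx[0], max(2, nl),
                                        np.array([0, 0, 1.0 if not up else -1.0])))
                blocks.append(hx)
                prev = hx[-1]
            xyz = np.concatenate(blocks)
            # pad or trim to the target length
            while xyz.shape[0] < target:
                step = rng.normal(size=3)
                step = step / np.linalg.norm(step) * CA_STEP
                xyz = np.concatenate([xyz, (xyz[-1] + step)[None, :]])
            xyz = xyz[:target]
        xyz = xyz + rng.normal(0, 0.8, xyz.shape)
        xyz = _random_rigid(rng, xyz)
        letters = _seq(rng, AA20, xyz.shape[0])
        residues = [ResidueRecord("A", i + 1, aa, tuple(p))
                    for i, (aa, p) in enumerate(zip(letters, xyz))]
        out.append(ChainStructure(f"decoy{d:03d}-s{seed}", residues))
    return out


def _identity_after_mutation(m: float) -> float:
    # expected pairwise identity of two copies independently mutated at
    # per-site rate m, mutations drawn uniformly from the 19 alternatives
    return (1 - m) ** 2 + (m ** 2) / 19.0


def _rate_for_identity(target: float) -> float:
    from scipy.optimize import brentq

    return float(brentq(lambda m: _identity_after_mutation(m) - target, 0.0, 0.95))


def _mutate(rng: np.random.Generator, seq: str, m: float) -> str:
    n = len(seq)
    k = int(round(m * n))
    sites = rng.choice(n, size=k, replace=False)
    out = list(seq)
    for i in sites:
        alts = AA20.replace(out[i], "")
        out[i] = alts[rng.integers(0, len(alts))]
    return "".join(out)


def make_family_sequences(spec: FamilySpec, n_partial: int = 0,
                          n_ambiguous: int = 0, n_low_quality: int = 0,
                          n_duplicates: int = 0):
    """Sequence families with planted cluster structure.

    Family ancestors diverge from a common root to the between-family
    identity target; members diverge from their ancestor so that pairwise
    within-family identity matches the within target.  Mutation counts are
    exact (not binomial), keeping realized identities tight around the
    targets.  Optionally appends flagged partial / ambiguous / low-quality
    records and exact duplicates for curation tests.

    Returns ``(records, labels)`` where labels maps record id -> family
    index (-1 for injected junk records).
    """
    from .seqkit import SeqRecord

    rng = np.random.default_rng(spec.seed)
    root = "".join(_seq(rng, AA20, spec.length))
    p = _rate_for_identity(spec.between_identity)
    m = _rate_for_identity(spec.within_identity)
    records: list[SeqRecord] = []
    labels: dict[str, int] = {}
    for f in range(spec.n_families):
        anc = _mutate(rng, root, p)
        for j in range(spec.members_per_family):
            s = _mutate(rng, anc, m)
            # longest-representative selection needs distinct lengths: the
            # first member of each family carries a short C-terminal add-on
            if j == 0:
                s = s + "".join(_seq(rng, AA20, 5))
            rid = f"fam{f}_m{j}"
            records.append(SeqRecord(id=rid, description=f"family {f}", sequence=s))
            labels[rid] = f
    base = [r for r in records]
    for i in range(n_partial):
        src = base[int(rng.integers(0, len(base)))]
        half = src.sequence[: len(src.sequence) // 2]
        rid = f"junk_partial{i}"
        records.append(SeqRecord(id=rid, description="partial", sequence=half))
        labels[rid] = -1
    for i in range(n_low_quality):
        src = base[int(rng.integers(0, len(base)))]
        rid = f"junk_lowq{i}"
        records.append(SeqRecord(id=rid, description="LOW QUALITY PROTEIN",
                                 sequence=src.sequence))
        labels[rid] = -1
    for i in range(n_ambiguous):
        src = base[int(rng.integers(0, len(base)))]
        s = list(src.sequence)
        for pos in rng.choice(len(s), size=3, replace=False):
            s[pos] = "X"
        rid = f"junk_ambig{i}"
        records.append(SeqRecord(id=rid, description="ambiguous", sequence="".join(s)))
        labels[rid] = -1
    for i in range(n_duplicates):
        src = base[int(rng.integers(0, len(base)))]
        rid = f"dup{i}_{src.id}"
        records.append(SeqRecord(id=rid, description="duplicate", sequence=src.sequence))
        labels[rid] = labels[src.id]
    return records, labels


def make_gene_model(protein, intron_residue: int, phase: int) -> list[tuple[int, int]]:
    """Two-exon CDS coordinates planting one intron at a residue and phase.

    The CDS is the back-translated protein (3 nt per residue, codons
    arbitrary); the intron junction falls after ``3*intron_residue + phase``
    coding nucleotides, i.e., a phase-0 intron sits exactly between codons.
    """
    seq = protein.sequence if hasattr(protein, "sequence") else str(protein)
    L = len(seq)
    if phase not in (0, 1, 2):
        raise ValueError("phase must be 0, 1 or 2")
    if not 0 <= intron_residue < L:
        raise ValueError("intron_residue out of range")
    cut = 3 * intron_residue + phase
    if cut <= 0 or cut >= 3 * L:
        raise ValueError("impossible intron position/phase combination")
    return [(0, cut), (cut, 3 * L)]
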