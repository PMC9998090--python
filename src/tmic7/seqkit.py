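"""Sequence-side pipeline: curation, identity clustering, all-vs-all
similarity networks, graph-splitting trees with edge-perturbation supports,
TM7 motif matching, and intron-phase mapping onto alignments.

This side of the pipeline handles families too divergent for confident
multiple alignment: relationships are inferred from an all-to-all local
alignment E-value network and a tree built by recursive spectral
bipartition of that network (graph splitting), with branch supports from
edge perturbation summarized as transfer bootstrap expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .topology import TopologyModel

__all__ = [
    "SeqRecord",
    "SimilarityNetwork",
    "GSNode",
    "MotifPattern",
    "IntronMark",
    "read_fasta",
    "write_fasta",
    "curate",
    "cluster_representatives",
    "global_identity",
    "all_vs_all",
    "graph_split",
    "edge_perturbation_support",
    "match_motif",
    "map_intron_to_alignment",
]

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
HYDROPHOBIC = set("AVLIMFWYC")   # the 'h' class of the TM7 motif

# ungapped Karlin-Altschul parameters for BLOSUM62; applied to gapped
# Smith-Waterman scores as a documented approximation
KA_LAMBDA = 0.3176
KA_K = 0.134
KA_H = 0.4012
E_CAP = 10.0


@dataclass
class SeqRecord:
    id: str
    description: str
    sequence: str
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        desc = self.description.lower()
        if "partial" in desc:
            self.flags.add("partial")
        if "low quality" in desc or "low_quality" in desc:
            self.flags.add("low_quality")
        if any(c not in AA20 for c in self.sequence):
            self.flags.add("ambiguous")
        else:
            self.flags.discard("ambiguous")


def read_fasta(path) -> list[SeqRecord]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(SeqRecord(id=rec.id, description=rec.description,
                             sequence=str(rec.seq)))
    return out


def write_fasta(records: list[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id} {r.description}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i:i + 60] + "\n")


def curate(records: list[SeqRecord],
           topologies: dict[str, TopologyModel] | None = None,
           min_tm: int = 4) -> tuple[list[SeqRecord], dict[str, int]]:
    """Database curation: drop flagged, redundant and low-TM records.

    Removes records flagged partial/low-quality/ambiguous, collapses exact
    duplicates (100% identity; first-seen id kept), and removes records
    with fewer than ``min_tm`` membrane segments.  Records without a
    topology are kept and counted as unassessed.  Idempotent.
    """
    topologies = topologies or {}
    report = {"partial": 0, "low_quality": 0, "ambiguous": 0,
              "redundant": 0, "low_tm": 0, "unassessed": 0}
    kept: list[SeqRecord] = []
    seen_seqs: set[str] = set()
    for r in records:
        bad = r.flags & {"partial", "low_quality", "ambiguous"}
        if bad:
            # a record may carry several flags; count it once, by priority
            for f in ("partial", "low_quality", "ambiguous"):
                if f in bad:
                    report[f] += 1
                    break
            continue
        if r.sequence in seen_seqs:
            report["redundant"] += 1
            continue
        topo = topologies.get(r.id)
        if topo is None:
            report["unassessed"] += 1
        elif len(topo.membrane_segments) < min_tm:
            report["low_tm"] += 1
            continue
        seen_seqs.add(r.sequence)
        kept.append(r)
    return kept, report


def global_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length (incl. gaps)."""
    import edlib

    res = edlib.align(a, b, task="path", mode="NW")
    nice = edlib.getNiceAlignment(res, a, b)
    matched = nice["matched_aligned"]
    return matched.count("|") / len(matched)


def cluster_representatives(records: list[SeqRecord],
                            identity_threshold: float = 0.9
                            ) -> list[SeqRecord]:
    """Greedy longest-first identity clustering; returns representatives.

    Sequences are sorted by length (descending, ties by id); each joins the
    first existing representative with global identity >= threshold, else
    founds its own cluster.  The longest member of each cluster is thus its
    representative.  Thresholds outside the conventional 0.7-0.9 range run
    with a warning.
    """
    if not records:
        raise ValueError("no sequences to cluster")
    if not 0.7 <= identity_threshold <= 0.9:
        import warnings

        warnings.warn(f"identity threshold {identity_threshold} outside the "
                      "conventional 0.7-0.9 range", stacklevel=2)
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[SeqRecord] = []
    for r in ordered:
        for rep in reps:
            if global_identity(r.sequence, rep.sequence) >= identity_threshold:
                break
        else:
            reps.append(r)
    return reps


@dataclass
class SimilarityNetwork:
    """Undirected E-value-weighted graph over sequence ids (no self-edges).

    ``weights`` normally derive from the E-values as ``-log10(E)`` floored
    at 0, but can be overridden (used by the edge-perturbation replicates,
    where round-tripping perturbed weights through E-values would
    underflow for near-identical sequences).
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    weights: list[float] | None = None

    def __post_init__(self):
        for a, b, e in self.edges:
            if a == b:
                raise ValueError("self-edges are not allowed")
            if not e > 0:
                raise ValueError("stored E-values must be > 0")
        if self.weights is not None and len(self.weights) != len(self.edges):
            raise ValueError("weights length mismatch")

    def edge_weights(self) -> np.ndarray:
        if self.weights is not None:
            return np.asarray(self.weights, dtype=float)
        return np.array([self.weight(e) for _, _, e in self.edges])

    def to_tsv(self, path) -> None:
        """3-column export (source, target, E-value); weak edges (E > 1) tagged."""
        with open(path, "w") as fh:
            for a, b, e in self.edges:
                tag = "\tweak" if e > 1.0 else ""
                fh.write(f"{a}\t{b}\t{e:.3g}{tag}\n")

    def weight(self, e_value: float) -> float:
        return max(0.0, -math.log10(e_value))


def _sw_score(a: str, b: str) -> float:
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return float(aligner.score(a.replace("X", "A"), b.replace("X", "A")))


def _e_value(score: float, m: int, n: int) -> float:
    """Karlin-Altschul E-value with effective search-space correction."""
    ell = math.log(KA_K * m * n) / KA_H
    m_eff = max(m - ell, 1.0)
    n_eff = max(n - ell, 1.0)
    return KA_K * m_eff * n_eff * math.exp(-KA_LAMBDA * score)


def all_vs_all(records: list[SeqRecord]) -> SimilarityNetwork:
    """All-to-all Smith-Waterman (BLOSUM62, gap 11/1) similarity network.

    Each unordered pair is aligned once; finite E-values <= 10 become
    edges.  Same-to-same comparisons are never stored.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    edges = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            s = _sw_score(a.sequence, b.sequence)
            e = _e_value(s, len(a.sequence), len(b.sequence))
            if np.isfinite(e) and e <= E_CAP:
                edges.append((a.id, b.id, max(e, 1e-300)))
    return SimilarityNetwork([r.id for r in records], edges)


@dataclass
class GSNode:
    """Node of a graph-splitting tree (binary; supports on internal nodes)."""

    children: list["GSNode"] = field(default_factory=list)
    leaf: str | None = None
    support: float | None = None   # percent, internal nodes only

    @property
    def leaves(self) -> frozenset[str]:
        if self.leaf is not None:
            return frozenset([self.leaf])
        return frozenset().union(*(c.leaves for c in self.children))

    def internal_nodes(self):
        if self.leaf is None:
            yield self
            for c in self.children:
                yield from c.internal_nodes()

    def newick(self) -> str:
        def fmt(node):
            if node.leaf is not None:
                return node.leaf
            inner = ",".join(fmt(c) for c in node.children)
            sup = "" if node.support is None else f"{node.support:.0f}"
            return f"({inner}){sup}"
        return fmt(self) + ";"


def _weight_matrix(net: SimilarityNetwork, nodes: list[str]) -> np.ndarray:
    idx = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for (a, b, _), w in zip(net.edges, net.edge_weights()):
        if a in idx and b in idx:
            W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
    return W


def _fiedler_split(W: np.ndarray) -> np.ndarray:
    """Boolean side assignment from the normalized-Laplacian Fiedler vector."""
    n = W.shape[0]
    deg = W.sum(axis=1)
    # zero-degree nodes: separate them first
    if (deg <= 0).any():
        return deg <= 0
    dinv = 1.0 / np.sqrt(deg)
    L = np.eye(n) - dinv[:, None] * W * dinv[None, :]
    vals, vecs = np.linalg.eigh(L)
    f = vecs[:, 1]
    side = f > 0
    if side[0]:
        side = ~side  # deterministic sign convention: first node on False side
    if side.sum() in (0, n):
        # numerically flat vector: split by median rank
        order = np.argsort(f, kind="stable")
        side = np.zeros(n, dtype=bool)
        side[order[n // 2:]] = True
    return side


def _split_recursive(net: SimilarityNetwork, nodes: list[str]) -> GSNode:
    if len(nodes) == 1:
        return GSNode(leaf=nodes[0])
    W = _weight_matrix(net, nodes)
    # disconnected subnetworks split by component membership
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(range(len(nodes)))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if W[i, j] > 0:
                G.add_edge(i, j)
    comps = sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c)))
    if len(comps) > 1:
        side = np.zeros(len(nodes), dtype=bool)
        side[list(comps[0])] = True
    else:
        side = _fiedler_split(W)
        if side.sum() in (0, len(nodes)):
            side = np.zeros(len(nodes), dtype=bool)
            side[0] = True
    left = [n for n, s in zip(nodes, side) if s]
    right = [n for n, s in zip(nodes, side) if not s]
    return GSNode(children=[_split_recursive(net, left),
                            _split_recursive(net, right)])


def graph_split(net: SimilarityNetwork) -> GSNode:
    """Graph-splitting tree: recursive spectral bipartition of the network.

    Edge weights are ``-log10(E)`` floored at 0; each split takes the sign
    pattern of the normalized-Laplacian Fiedler vector; disconnected parts
    split by component.  Branch lengths are not estimated (topology only).
    """
    if not net.nodes:
        raise ValueError("empty network")
    return _split_recursive(net, list(net.nodes))


def _bipartitions(root: GSNode, all_leaves: frozenset[str]):
    """Non-trivial bipartitions (as the smaller-side leafset) per internal node."""
    out = []
    for node in root.internal_nodes():
        lv = node.leaves
        if 1 < len(lv) < len(all_leaves):
            out.append((node, lv))
    return out


def _transfer_index(bip: frozenset[str], other_bips: list[frozenset[str]],
                    all_leaves: frozenset[str]) -> int:
    """Minimum transfer distance from bip to any branch of the other tree."""
    best = min(len(bip), len(all_leaves - bip))  # distance to trivial branches
    for ob in other_bips:
        d1 = len(bip ^ ob)
        d2 = len(bip ^ (all_leaves - ob))
        best = min(best, d1, d2)
        if best == 0:
            return 0
    return best


def edge_perturbation_support(net: SimilarityNetwork, replicates: int = 1000,
                              seed: int = 0, sigma: float = 0.5) -> GSNode:
    """Graph-splitting tree with edge-perturbation branch supports.

    Each replicate multiplies every edge weight by an independent
    log-normal factor (scale ``sigma``; sigma=0 reproduces the input) and
    rebuilds the tree; supports are transfer bootstrap expectations (TBE):
    ``100 * (1 - mean(transfer distance) / (p - 1))`` with p the smaller
    bipartition side.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    ref = graph_split(net)
    all_leaves = ref.leaves
    ref_bips = _bipartitions(ref, all_leaves)
    sums = np.zeros(len(ref_bips))
    base_w = net.edge_weights()
    for _ in range(replicates):
        factors = np.exp(rng.normal(0.0, sigma, size=len(net.edges))) \
            if sigma > 0 else np.ones(len(net.edges))
        pnet = SimilarityNetwork(list(net.nodes), list(net.edges),
                                 weights=list(base_w * factors))
        ptree = graph_split(pnet)
        pbips = [lv for _, lv in _bipartitions(ptree, all_leaves)]
        for k, (_, bip) in enumerate(ref_bips):
            sums[k] += _transfer_index(bip, pbips, all_leaves)
    for k, (node, bip) in enumerate(ref_bips):
        p = min(len(bip), len(all_leaves - bip))
        avg = sums[k] / replicates
        node.support = float(np.clip(100.0 * (1.0 - avg / max(p - 1, 1)), 0.0, 100.0))
    # trivial internal nodes (both children leaves of a 2-leaf tree etc.)
    for node in ref.internal_nodes():
        if node.support is None and node is not ref:
            node.support = 100.0
    return ref


@dataclass
class MotifPattern:
    """Position classes: a literal residue set per position, or hydrophobic.

    Patterns are written like ``TYhhhhhQF`` or ``T(H/N)(S/A)hhhhQ(Y/F/W)``:
    an uppercase letter is itself, ``h`` is the hydrophobic class, and
    ``(A/B/C)`` is an explicit alternative set.
    """

    positions: list[frozenset[str]]

    @classmethod
    def parse(cls, text: str) -> "MotifPattern":
        out: list[frozenset[str]] = []
        i = 0
        while i < len(text):
            c = text[i]
            if c == "(":
                j = text.index(")", i)
                out.append(frozenset(text[i + 1:j].replace("/", "")))
                i = j + 1
            elif c == "h":
                out.append(frozenset(HYDROPHOBIC))
                i += 1
            else:
                out.append(frozenset(c.upper()))
                i += 1
        if not out or any(not p for p in out):
            raise ValueError("empty motif pattern or class")
        return cls(out)

    def __len__(self):
        return len(self.positions)

    def conformity(self, window: str) -> float:
        """Fraction of positions whose residue is in the position class."""
        assert len(window) == len(self)
        return sum(1 for c, cl in zip(window, self.positions) if c in cl) / len(self)


@dataclass
class MotifMatch:
    seq_id: str
    position: int | None       # degapped offset of the best window
    conformity: float          # best fraction of conforming positions
    full_match: bool
    per_position: list[bool]


def match_motif(alignment: dict[str, str], region: tuple[int, int],
                pattern: MotifPattern) -> list[MotifMatch]:
    """Best motif match per sequence within an alignment column interval.

    ``alignment`` maps sequence id to its gapped row; the region is a
    half-open column interval.  Each row is degapped within the region and
    the pattern slid over it; the best-conformity window is reported.
    """
    if not alignment:
        raise ValueError("empty alignment")
    out = []
    a, b = region
    for sid, row in alignment.items():
        sub = row[a:b].replace("-", "").upper()
        if len(sub) < len(pattern):
            out.append(MotifMatch(sid, None, 0.0, False, [False] * len(pattern)))
            continue
        best_pos, best_conf = 0, -1.0
        for i in range(len(sub) - len(pattern) + 1):
            conf = pattern.conformity(sub[i:i + len(pattern)])
            if conf > best_conf:
                best_pos, best_conf = i, conf
        window = sub[best_pos:best_pos + len(pattern)]
        per = [c in cl for c, cl in zip(window, pattern.positions)]
        out.append(MotifMatch(sid, best_pos, best_conf, all(per), per))
    return out


@dataclass(frozen=True)
class IntronMark:
    gene_id: str
    cds_position: int     # nucleotide offset of the junction in the CDS
    phase: int            # cds_position mod 3
    residue_index: int    # 0-based protein residue containing/following it
    alignment_column: int


def map_intron_to_alignment(gene_model: list[tuple[int, int]],
                            protein_aln: dict[str, str], seq_id: str,
                            intron_after_exon: int = 0) -> IntronMark:
    """Map an intron junction to a protein alignment column.

    ``gene_model`` is a list of CDS exon (start, end) coordinate pairs in
    coding order.  The intron phase is the cumulative CDS length at the
    junction mod 3 (phase 0 = between codons); the affected residue is
    ``floor(cumulative/3)`` and is mapped through the gapped row of
    ``seq_id`` to an alignment column.
    """
    if seq_id not in protein_aln:
        raise ValueError(f"{seq_id} not in alignment")
    row = protein_aln[seq_id]
    protein_len = len(row.replace("-", ""))
    cds_len = sum(e - s for s, e in gene_model)
    if cds_len % 3 != 0 or cds_len // 3 != protein_len:
        raise ValueError("CDS length does not match protein length")
    if not 0 <= intron_after_exon < len(gene_model) - 1:
        raise ValueError("no intron after the last exon")
    cum = sum(e - s for s, e in gene_model[:intron_after_exon + 1])
    phase = cum % 3
    residue = cum // 3
    # walk the gapped row to the column of that residue
    count = -1
    col = None
    for c, ch in enumerate(row):
        if ch != "-":
            count += 1
            if count == residue:
                col = c
                break
    if col is None:
        raise ValueError("residue index beyond aligned sequence")
    return IntronMark(gene_id=seq_id, cds_position=cum, phase=phase,
                      residue_index=residue, alignment_column=col)
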