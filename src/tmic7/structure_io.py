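"""Read, write, select, and mask protein structures at C-alpha resolution.

All structural comparison in this package (TM-score alignment, elastic
distance-matrix scoring) operates on C-alpha traces only, so a chain is
represented as an ordered list of C-alpha records.  Residues are addressed
by 0-based ordinal over the *resolved* residues; author numbering from the
source file is kept as metadata only, because insertion codes and numbering
gaps make it unsafe for alignment arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "ResidueRecord",
    "ChainStructure",
    "RegionMask",
    "read_structure",
    "apply_mask",
    "write_pdb",
]

#: 3-letter -> 1-letter codes for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
AA_ALPHABET = set(THREE_TO_ONE.values())


@dataclass(frozen=True)
class ResidueRecord:
    """One resolved residue: identity plus its C-alpha position (Angstrom)."""

    chain_id: str
    residue_index: int          # author numbering as in the source file
    amino_acid: str             # 1-letter code, "X" for nonstandard
    ca_position: tuple[float, float, float]
    insertion: str = ""

    def __post_init__(self):
        if self.amino_acid not in AA_ALPHABET and self.amino_acid != "X":
            raise ValueError(f"invalid amino acid code {self.amino_acid!r}")
        if not all(np.isfinite(self.ca_position)):
            raise ValueError("non-finite C-alpha coordinate")


@dataclass
class ChainStructure:
    """Ordered C-alpha trace of one polypeptide chain."""

    identifier: str             # e.g. "6C70-A"
    residues: list[ResidueRecord]
    source: str = "experimental"        # {"experimental", "predicted"}
    skipped_residues: int = 0   # residues in the source lacking a C-alpha

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("empty ChainStructure")
        seen = set()
        for r in self.residues:
            key = (r.chain_id, r.residue_index, r.insertion)
            if key in seen:
                raise ValueError(f"duplicate residue {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(L, 3) float array of C-alpha positions."""
        return np.array([r.ca_position for r in self.residues], dtype=float)

    def with_coords(self, xyz: np.ndarray, identifier: str | None = None) -> "ChainStructure":
        """Copy of this chain with replaced coordinates (same residues)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self), 3):
            raise ValueError("coordinate array shape mismatch")
        new = [replace(r, ca_position=tuple(p)) for r, p in zip(self.residues, xyz)]
        return ChainStructure(identifier or self.identifier, new, self.source)


@dataclass
class RegionMask:
    """Half-open, 0-based ordinal intervals to remove from a chain.

    Used e.g. to drop a long unstructured N-terminal region or first
    intracellular loop before visual/quantitative comparison.
    """

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        iv = sorted((int(a), int(b)) for a, b in self.intervals)
        for a, b in iv:
            if a >= b or a < 0:
                raise ValueError(f"invalid interval [{a}, {b})")
        for (a1, b1), (a2, b2) in zip(iv, iv[1:]):
            if a2 < b1:
                raise ValueError("overlapping mask intervals")
        self.intervals = iv

    def covered(self, length: int) -> np.ndarray:
        """Boolean array of masked ordinals; errors if out of bounds."""
        out = np.zeros(length, dtype=bool)
        for a, b in self.intervals:
            if b > length:
                raise ValueError(f"mask interval [{a}, {b}) exceeds length {length}")
            out[a:b] = True
        return out


def _structure_from_file(path: str) -> gemmi.Structure:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def read_structure(path, chain: str | None = None, model_number: int | None = None,
                   source: str | None = None) -> ChainStructure:
    """Read one chain's C-alpha trace from a PDB or mmCIF file.

    Residues lacking a C-alpha atom are skipped (counted in
    ``skipped_residues`` and reported as a warning).  AltLoc conformers
    resolve to the highest occupancy, ties to the first encountered.
    """
    st = _structure_from_file(path)
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    if model_number is None:
        model = st[0]
    else:
        model = None
        for m in st:
            if m.num == model_number:
                model = m
                break
        if model is None:
            raise ValueError(f"{path}: no model number {model_number}")
    if chain is None:
        if len(model) != 1:
            raise ValueError(f"{path}: multiple chains, pass chain=")
        gchain = model[0]
    else:
        gchain = model.find_chain(chain)
        if gchain is None:
            raise ValueError(f"{path}: no chain {chain!r}")
    records: list[ResidueRecord] = []
    skipped = 0
    for res in gchain:
        if not gemmi.find_tabulated_residue(res.name) or \
                not gemmi.find_tabulated_residue(res.name).is_amino_acid():
            continue
        best = None
        for atom in res:
            if atom.name == "CA" and atom.element.name == "C":
                if best is None or atom.occ > best.occ:
                    best = atom
        if best is None:
            skipped += 1
            continue
        aa = THREE_TO_ONE.get(res.name, "X")
        records.append(ResidueRecord(
            chain_id=gchain.name,
            residue_index=res.seqid.num,
            amino_acid=aa,
            ca_position=(best.pos.x, best.pos.y, best.pos.z),
            insertion=(res.seqid.icode or "").strip(),
        ))
    if not records:
        raise ValueError(f"{path} chain {gchain.name}: zero C-alpha atoms")
    if skipped:
        warnings.warn(f"{path} chain {gchain.name}: skipped {skipped} residues "
                      "lacking a C-alpha atom", stacklevel=2)
    ident = f"{st.name or 'struct'}-{gchain.name}" if chain is not None else (st.name or "struct")
    if source is None:
        source = "predicted" if "AF-" in str(path).upper() else "experimental"
    return ChainStructure(ident, records, source=source, skipped_residues=skipped)


def apply_mask(s: ChainStructure, m: RegionMask) -> ChainStructure:
    """Return a copy of ``s`` with masked ordinals removed (original untouched)."""
    drop = m.covered(len(s))
    kept = [r for r, d in zip(s.residues, drop) if not d]
    if not kept:
        raise ValueError("mask removes every residue")
    return ChainStructure(s.identifier, kept, s.source)


def write_pdb(s: ChainStructure, path) -> None:
    """Write a C-alpha-only PDB file; coordinates keep 3 decimals."""
    if not str(path):
        raise ValueError("empty path")
    lines = []
    for i, r in enumerate(s.residues, start=1):
        x, y, z = r.ca_position
        res3 = ONE_TO_THREE.get(r.amino_acid, "UNK")
        lines.append(
            f"ATOM  {i:5d}  CA  {res3:<3s} {r.chain_id[:1] or 'A'}"
            f"{r.residue_index:4d}{(r.insertion or ' ')[:1]}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}           C  "
        )
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
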