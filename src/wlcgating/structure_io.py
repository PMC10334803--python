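"""Read and write tetrameric channel structures (PDB / mmCIF).

Extracts per-chain Cα coordinates keyed by author residue numbers — the
numbering the analysis is defined in (pore anchor Ile99, ring anchor
Ser115, alignment selection 20–83).  Only model 1 is read; altlocs are
resolved to the highest-occupancy conformer; waters and heteroatoms are
ignored.  A fixture writer emits minimal Cα-only PDB/mmCIF files for the
synthetic structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AnchorError",
    "ChainRecord",
    "FormatError",
    "StructureModel",
    "detect_resolved_linker",
    "extract_anchors",
    "read_structure",
    "write_fixture_cif",
    "write_fixture_pdb",
]

DEFAULT_PORE_ANCHOR = 99
DEFAULT_RING_ANCHOR = 115
DEFAULT_LINKER_RANGE = (100, 114)


class FormatError(ValueError):
    """Input file could not be parsed, or contains no usable protein chain."""


class AnchorError(ValueError):
    """A required anchor Cα is missing from a chain."""


@dataclass
class ChainRecord:
    """Cα trace of one chain: residue number → 3-vector in Å."""

    chain_id: str
    ca_coords: dict[int, np.ndarray]

    @property
    def resolved_range(self) -> set[int]:
        return set(self.ca_coords)

    def __len__(self) -> int:
        return len(self.ca_coords)


@dataclass
class StructureModel:
    """One structure: ordered chains of Cα coordinates plus metadata."""

    id: str
    chains: list[ChainRecord]
    state_label: str = "open"  # closed | open | chimera | synthetic
    provenance: str = ""
    aligned: bool = False  # pore fourfold axis coincides with z
    analysis_chain_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.chains:
            raise FormatError(f"structure {self.id!r} has no chains")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate chain identifiers in {self.id!r}")

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def analysis_chains(self) -> list[ChainRecord]:
        """Chains entering the tetramer analysis.

        An explicit ``analysis_chain_ids`` list wins; otherwise the four
        longest protein chains (all chains if fewer than four).
        """
        if self.analysis_chain_ids is not None:
            return [self.chain(cid) for cid in self.analysis_chain_ids]
        if len(self.chains) <= 4:
            return list(self.chains)
        ranked = sorted(self.chains, key=lambda c: (-len(c), c.chain_id))[:4]
        order = {c.chain_id for c in ranked}
        return [c for c in self.chains if c.chain_id in order]


def _resolve_altlocs(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy Cα, ties broken by lexicographic altloc id."""
    candidates = [a for a in residue if a.name == "CA" and a.element.name != "Ca"]
    if not candidates:
        return None
    return min(candidates, key=lambda a: (-a.occ, a.altloc))


def read_structure(path: str | Path, format: str = "auto",
                   state_label: str = "open",
                   analysis_chain_ids: list[str] | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel` (model 1 only)."""
    path = Path(path)
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}.get(format)
    if fmt is None:
        raise FormatError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path} contains no models")
    st.setup_entities()
    model = st[0]
    chains: list[ChainRecord] = []
    for chain in model:
        coords: dict[int, np.ndarray] = {}
        for residue in chain:
            if residue.is_water() or residue.het_flag == "H":
                continue
            if residue.seqid.icode not in (" ", "", "\x00"):
                raise FormatError(
                    f"{path}: insertion code {residue.seqid.icode!r} at "
                    f"{chain.name}/{residue.seqid.num} is not supported")
            atom = _resolve_altlocs(residue)
            if atom is None:
                continue
            coords[residue.seqid.num] = np.array(
                [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
        if coords:
            chains.append(ChainRecord(chain.name, coords))
    if not chains:
        raise FormatError(f"{path} contains no protein chains with Cα atoms")
    return StructureModel(id=st.name or path.stem, chains=chains,
                          state_label=state_label, provenance=str(path),
                          analysis_chain_ids=analysis_chain_ids)


def extract_anchors(structure: StructureModel,
                    pore_anchor: int = DEFAULT_PORE_ANCHOR,
                    ring_anchor: int = DEFAULT_RING_ANCHOR):
    """Per-chain (pore, ring) anchor Cα pairs, chain order preserved.

    Returns a :class:`wlcgating.geometry.AnchorSet`.  Raises
    :class:`AnchorError` naming the first chain missing either anchor.
    """
    from .geometry import AnchorSet  # late import: geometry is independent

    chains = structure.analysis_chains()
    pore, ring, ids = [], [], []
    for c in chains:
        for res in (pore_anchor, ring_anchor):
            if res not in c.ca_coords:
                raise AnchorError(
                    f"structure {structure.id!r}: chain {c.chain_id!r} has no "
                    f"Cα for anchor residue {res}")
        pore.append(c.ca_coords[pore_anchor].copy())
        ring.append(c.ca_coords[ring_anchor].copy())
        ids.append(c.chain_id)
    return AnchorSet(structure_id=structure.id, chain_ids=ids,
                     pore=np.array(pore), ring=np.array(ring),
                     aligned=structure.aligned)


def detect_resolved_linker(structure: StructureModel,
                           linker_range: tuple[int, int] = DEFAULT_LINKER_RANGE,
                           min_fraction: float = 0.8) -> dict[str, bool]:
    """Per analysis chain: is the linker segment ordered (resolved)?

    True iff at least ``min_fraction`` of the residues in ``linker_range``
    have Cα coordinates.  Folded/ordered linkers are excluded from the
    entropic-spring analysis.
    """
    lo, hi = linker_range
    n_range = hi - lo + 1
    out = {}
    for c in structure.analysis_chains():
        n_present = sum(1 for r in range(lo, hi + 1) if r in c.ca_coords)
        out[c.chain_id] = n_present >= min_fraction * n_range
    return out


def _to_gemmi(structure: StructureModel) -> gemmi.Structure:
    resnames = {DEFAULT_PORE_ANCHOR: "ILE", DEFAULT_RING_ANCHOR: "SER"}
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain_rec in structure.chains:
        chain = gemmi.Chain(chain_rec.chain_id)
        for resnum in sorted(chain_rec.ca_coords):
            xyz = chain_rec.ca_coords[resnum]
            res = gemmi.Residue()
            res.name = resnames.get(resnum, "ALA")
            res.seqid = gemmi.SeqId(resnum, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.b_iso = 0.0
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_fixture_pdb(structure: StructureModel, path: str | Path) -> Path:
    """Write a minimal legal Cα-only PDB file (coordinates to 0.001 Å)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _to_gemmi(structure).write_pdb(str(path))
    return path


def write_fixture_cif(structure: StructureModel, path: str | Path) -> Path:
    """Write the same fixture as mmCIF (for format round-trip checks)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    st = _to_gemmi(structure)
    st.assign_label_seq_id()
    st.make_mmcif_document().write_file(str(path))
    return path
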