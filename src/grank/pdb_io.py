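"""Reading and writing two-chain protein complexes in PDB format.

Docking decoys are plain single-model PDB files with two protein chains
(receptor and ligand). Parsing is delegated to gemmi; on top of it this
module enforces the conventions the rest of the pipeline relies on:

* only the first MODEL of a multi-model file is used (with a warning);
* HETATM records (waters, ions, ligand chemistry) are dropped;
* of several alternate locations of an atom, the first-listed one is kept;
* the element symbol comes from PDB columns 77-78 when present, otherwise it
  is inferred from the atom name (first alphabetic character, so "HG1" on a
  protein residue is hydrogen);
* residue identity is the triple (chain id, residue number, insertion code).

Graph featurization further restricts atoms to the five modeled elements
C, N, O, S, H via :func:`filter_elements`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: elements the scoring network models, in canonical one-hot order
ALLOWED_ELEMENTS = ("C", "N", "O", "S", "H")

#: residue identity: (chain_id, residue_seq, insertion_code)
ResidueId = tuple[str, int, str]


class PDBParseError(ValueError):
    """A PDB file could not be parsed into a valid two-chain complex."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a complex, with coordinates in Angstrom."""

    element: str
    atom_name: str
    chain_id: str
    residue_seq: int
    icode: str
    residue_name: str
    coords: np.ndarray

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain_id, self.residue_seq, self.icode)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class ChainComplex:
    """A validated two-chain complex: every atom belongs to one of two chains."""

    complex_id: str
    model_id: str
    receptor_chain: str
    ligand_chain: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.receptor_chain == self.ligand_chain:
            raise ValueError("receptor and ligand chain ids must differ")
        chains = {a.chain_id for a in self.atoms}
        extra = chains - {self.receptor_chain, self.ligand_chain}
        if extra:
            raise ValueError(f"atoms on unexpected chains: {sorted(extra)}")
        for cid in (self.receptor_chain, self.ligand_chain):
            if not any(a.chain_id == cid for a in self.atoms):
                raise ValueError(f"chain {cid!r} has no atoms")
        coords = self.coords
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.coords for a in self.atoms])

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def is_receptor(self) -> np.ndarray:
        """Boolean mask over atoms: True for receptor-chain atoms."""
        return np.array([a.chain_id == self.receptor_chain for a in self.atoms])

    def subset(self, indices) -> "ChainComplex":
        """New complex keeping the atoms at ``indices`` (order preserved)."""
        keep = [self.atoms[i] for i in sorted(set(int(i) for i in indices))]
        return ChainComplex(self.complex_id, self.model_id,
                            self.receptor_chain, self.ligand_chain, keep)


def _infer_element(atom_name: str) -> str:
    for ch in atom_name.strip():
        if ch.isalpha():
            return ch.upper()
    raise PDBParseError(f"cannot infer element from atom name {atom_name!r}")


def _validate_atom_lines(pdb_text: str) -> None:
    """Raise with a line number if an ATOM record has malformed coordinates."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated ATOM record")
        try:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                float(line[lo:hi])
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: unparseable coordinates in ATOM record"
            ) from None


def parse_complex(pdb_text: str, receptor_chain: str, ligand_chain: str,
                  complex_id: str = "", model_id: str = "") -> ChainComplex:
    """Parse PDB text into a :class:`ChainComplex` of the two named chains.

    HETATM records are ignored, only the first MODEL is read, and the
    first-listed altloc of each atom is kept. Element filtering is *not*
    applied here; see :func:`filter_elements`.

    Raises
    ------
    PDBParseError
        If an ATOM record is malformed (reported with its line number) or a
        requested chain has no atoms.
    """
    _validate_atom_lines(pdb_text)
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise PDBParseError("no coordinate models in PDB input")
    if len(structure) > 1:
        logger.warning("multi-MODEL PDB input: using the first MODEL only "
                       "(%d present)", len(structure))
    model = structure[0]

    wanted = {receptor_chain, ligand_chain}
    atoms: list[AtomRecord] = []
    seen: set[tuple[ResidueId, str]] = set()
    for chain in model:
        if chain.name not in wanted:
            continue
        for residue in chain:
            if residue.het_flag != "A":  # HETATM (waters, ions, ...)
                continue
            seq = residue.seqid.num
            icode = residue.seqid.icode.strip()
            for atom in residue:
                key = ((chain.name, seq, icode), atom.name)
                if key in seen:  # later altloc of an atom already kept
                    continue
                seen.add(key)
                if atom.element and atom.element.name != "X":
                    element = atom.element.name.upper()
                else:
                    element = _infer_element(atom.name)
                atoms.append(AtomRecord(
                    element=element,
                    atom_name=atom.name,
                    chain_id=chain.name,
                    residue_seq=seq,
                    icode=icode,
                    residue_name=residue.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                ))

    present = {a.chain_id for a in atoms}
    for cid in (receptor_chain, ligand_chain):
        if cid not in present:
            raise PDBParseError(f"chain {cid!r} not found in PDB input")
    return ChainComplex(complex_id, model_id, receptor_chain, ligand_chain,
                        atoms)


def filter_elements(complex_: ChainComplex) -> ChainComplex:
    """Keep only atoms of the five modeled elements C, N, O, S, H.

    Idempotent; atom order is preserved. Raises ``ValueError`` if a chain is
    left without atoms (e.g. a ligand "chain" that was a single metal ion).
    """
    kept = [a for a in complex_.atoms if a.element in ALLOWED_ELEMENTS]
    for cid in (complex_.receptor_chain, complex_.ligand_chain):
        if not any(a.chain_id == cid for a in kept):
            raise ValueError(
                f"chain {cid!r} has no C/N/O/S/H atoms after element filtering")
    return replace(complex_, atoms=kept)


def write_pdb(complex_: ChainComplex) -> str:
    """Serialize a complex back to PDB text (ATOM/TER/END records)."""
    lines: list[str] = []
    serial = 0
    for cid in (complex_.receptor_chain, complex_.ligand_chain):
        last = None
        for a in complex_.atoms:
            if a.chain_id != cid:
                continue
            serial += 1
            name = a.atom_name
            # standard PDB alignment: 1-3 letter names start in column 14
            padded = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = a.coords
            lines.append(
                f"ATOM  {serial:5d} {padded:<4s} {a.residue_name:<3s} "
                f"{a.chain_id}{a.residue_seq:4d}{a.icode or ' '}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
            last = a
        if last is not None:
            serial += 1
            lines.append(
                f"TER   {serial:5d}      {last.residue_name:<3s} "
                f"{last.chain_id}{last.residue_seq:4d}{last.icode or ' '}")
    lines.append("END")
    return "\n".join(lines) + "\n"


MANIFEST_COLUMNS = ["complex_id", "model_id", "path",
                    "receptor_chain", "ligand_chain"]


def read_manifest(path) -> pd.DataFrame:
    """Read a batch manifest (TSV: complex_id, model_id, path, chains)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=MANIFEST_COLUMNS)
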