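"""Miniature two-chain complexes and rigid-body decoys for end-to-end runs.

Real docking benchmarks are hundreds of thousands of PDB files; this module
emulates their *shape* at desk scale. A native is two short coarse peptide
chains laid out so that their side-chain pseudo-atoms meet in a contact
interface (>=1 cross-chain heavy-atom pair within 5 A). Decoys are produced
by rigid-body perturbation of the ligand chain — a random rotation about its
centroid followed by a random-direction translation of controlled
magnitude — so decoy quality degrades smoothly from f-nat 1 at zero
perturbation to 0 (and eventually to no interface at all, which the dataset
assembly records as an exclusion, as happens with real far-off decoys).

Labels are always *measured* with :mod:`grank.quality_labels`, never assumed
from the construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .interface_graph import (DEFAULT_EDGE_CUTOFF, DEFAULT_INTERFACE_CUTOFF,
                              DEFAULT_N_RBF, InterfaceGraph, NoContactError,
                              build_graph, extract_interface)
from .pdb_io import AtomRecord, ChainComplex, filter_elements
from .quality_labels import QualityLabel, label_model, native_contacts

logger = logging.getLogger(__name__)

#: default perturbation magnitudes: translations (A) x rotations (degrees)
DEFAULT_TRANSLATIONS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
DEFAULT_ROTATIONS = (0.0, 5.0, 15.0, 45.0)

#: side-chain pseudo-atom element frequencies (exercises all one-hot slots)
_SIDE_ELEMENTS = ("C", "N", "O", "S")
_SIDE_PROBS = (0.6, 0.15, 0.2, 0.05)

_RES_SPACING = 3.5   # A between consecutive residue origins
_CHAIN_GAP = 6.8     # A between the two backbone axes


@dataclass(frozen=True)
class DecoyRecipe:
    """Geometry of one synthetic native and the default decoy perturbation."""

    n_res_per_chain: int = 6
    atoms_per_res: int = 5          # heavy atoms: N, CA, C, O + pseudo side
    add_hydrogens: bool = True      # one amide H per residue
    perturbation: tuple[float, float] = (1.0, 5.0)  # (A, degrees)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_res_per_chain < 3:
            raise ValueError("need at least 3 residues per chain")
        if self.atoms_per_res < 4:
            raise ValueError("atoms_per_res must cover the N/CA/C/O backbone")


def _chain_atoms(chain_id: str, n_res: int, n_side: int, add_h: bool,
                 toward: float, y0: float, rng: np.random.Generator,
                 ) -> list[AtomRecord]:
    """One coarse chain along x at height ``y0``; side chains point
    ``toward`` (+1 or -1) along y. Small seeded jitter keeps complexes
    distinct; the sinusoidal z-wiggle makes them non-planar."""
    backbone = {"N": (-1.2, 0.2, 0.0), "CA": (0.0, 0.0, 0.0),
                "C": (1.25, 0.2, 0.0), "O": (1.5, 1.4 * toward, 0.0)}
    atoms: list[AtomRecord] = []
    for i in range(n_res):
        origin = np.array([_RES_SPACING * i, y0, 0.8 * np.sin(1.7 * i)])
        jitter = rng.normal(0.0, 0.15, size=(len(backbone) + n_side
                                             + int(add_h), 3))
        j = 0
        for name, off in backbone.items():
            atoms.append(AtomRecord("C" if name in ("CA", "C") else name[0],
                                    name, chain_id, i + 1, "", "GLY",
                                    origin + np.asarray(off) + jitter[j]))
            j += 1
        for k in range(n_side):
            element = rng.choice(_SIDE_ELEMENTS, p=_SIDE_PROBS)
            off = np.array([0.3 * k, toward * (1.6 + 1.1 * k), 0.4])
            atoms.append(AtomRecord(str(element), f"S{k + 1}", chain_id,
                                    i + 1, "", "GLY", origin + off + jitter[j]))
            j += 1
        if add_h:
            off = np.array([-1.4, -0.8 * toward, 0.0])
            atoms.append(AtomRecord("H", "H", chain_id, i + 1, "", "GLY",
                                    origin + off + jitter[j]))
    return atoms


def make_native(recipe: DecoyRecipe) -> ChainComplex:
    """Deterministic native complex with a guaranteed contact interface.

    Receptor chain A sits at y=0 with side chains pointing up; ligand chain
    B sits one chain gap above, staggered by half a residue, side chains
    pointing down, so the pseudo side chains interdigitate at ~3.5-4 A.
    """
    rng = np.random.default_rng(recipe.seed)
    n_side = recipe.atoms_per_res - 4
    atoms = _chain_atoms("A", recipe.n_res_per_chain, n_side,
                         recipe.add_hydrogens, toward=+1.0, y0=0.0, rng=rng)
    lig = _chain_atoms("B", recipe.n_res_per_chain, n_side,
                       recipe.add_hydrogens, toward=-1.0, y0=_CHAIN_GAP,
                       rng=rng)
    shift = np.array([_RES_SPACING / 2.0, 0.0, 0.0])
    lig = [AtomRecord(a.element, a.atom_name, a.chain_id, a.residue_seq,
                      a.icode, a.residue_name, a.coords + shift) for a in lig]
    return ChainComplex(f"syn{recipe.seed}", "native", "A", "B", atoms + lig)


def make_decoy(native: ChainComplex, translation: float, rotation: float,
               seed: int, model_id: str = "decoy") -> ChainComplex:
    """Rigid-body decoy: rotate the ligand chain about its centroid by
    ``rotation`` degrees around a random axis, then translate it by
    ``translation`` A in a random direction. The receptor is untouched."""
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.deg2rad(rotation) * axis).as_matrix()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = translation * direction

    lig_coords = np.stack([a.coords for a in native.atoms
                           if a.chain_id == native.ligand_chain])
    centroid = lig_coords.mean(axis=0)

    atoms = []
    for a in native.atoms:
        if a.chain_id == native.ligand_chain:
            moved = (a.coords - centroid) @ R.T + centroid + t
            atoms.append(AtomRecord(a.element, a.atom_name, a.chain_id,
                                    a.residue_seq, a.icode, a.residue_name,
                                    moved))
        else:
            atoms.append(a)
    return ChainComplex(native.complex_id, model_id, native.receptor_chain,
                        native.ligand_chain, atoms)


@dataclass
class DatasetEntry:
    complex_id: str
    model_id: str
    graph: InterfaceGraph | None  # None when the decoy had no interface
    label: QualityLabel
    translation: float
    rotation: float
    decoy: ChainComplex | None = None


@dataclass
class SyntheticDataset:
    entries: list[DatasetEntry]
    natives: dict[str, ChainComplex]
    n_excluded: int

    @property
    def usable(self) -> list[DatasetEntry]:
        """Entries that survived interface extraction (graph present)."""
        return [e for e in self.entries if e.graph is not None]

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"complex_id": e.complex_id, "model_id": e.model_id,
             "fnat": e.label.fnat, "lrmsd": e.label.lrmsd,
             "irmsd": e.label.irmsd, "capri_class": e.label.capri_class,
             "is_positive": e.label.is_positive}
            for e in self.entries])


def default_magnitude_grid() -> list[tuple[float, float]]:
    """(translation, rotation) combinations, mildest first."""
    return sorted(
        ((t, r) for t in DEFAULT_TRANSLATIONS for r in DEFAULT_ROTATIONS),
        key=lambda tr: (tr[0], tr[1]))


def make_dataset(n_complexes: int = 40, n_decoys_per_complex: int = 20,
                 magnitude_grid: list[tuple[float, float]] | None = None,
                 seed: int = 0,
                 recipe_kwargs: dict | None = None,
                 interface_cutoff: float = DEFAULT_INTERFACE_CUTOFF,
                 edge_cutoff: float = DEFAULT_EDGE_CUTOFF,
                 n_rbf: int = DEFAULT_N_RBF) -> SyntheticDataset:
    """Generate natives, decoys, measured labels and interface graphs.

    Every complex's decoys stride across the magnitude grid from mildest to
    harshest, so each complex spans the full quality range, including the
    exact native (f-nat 1) and far-off decoys (f-nat 0). Decoys whose chains no
    longer share an 8.5 A interface are kept in the label table but carry no
    graph; their count is logged, mirroring the exclusion of contact-free
    models from real datasets.
    """
    grid = magnitude_grid if magnitude_grid is not None \
        else default_magnitude_grid()
    entries: list[DatasetEntry] = []
    natives: dict[str, ChainComplex] = {}
    n_excluded = 0
    for ci in range(n_complexes):
        recipe = DecoyRecipe(seed=(seed * 10_007 + ci) % (2**31),
                             **(recipe_kwargs or {}))
        native = make_native(recipe)
        cid = f"cpx{ci:03d}"
        native = ChainComplex(cid, "native", native.receptor_chain,
                              native.ligand_chain, native.atoms)
        natives[cid] = native
        native_set = native_contacts(native)
        for j in range(n_decoys_per_complex):
            # stride across the whole grid so every complex spans the full
            # quality range whatever n_decoys_per_complex is
            trans, rot = grid[(j * len(grid)) // n_decoys_per_complex
                              % len(grid)]
            decoy = make_decoy(native, trans, rot,
                               seed=(seed * 65_537 + ci * 1_021 + j) % (2**31),
                               model_id=f"decoy{j:03d}")
            label = label_model(decoy, native, native_set)
            try:
                interface = extract_interface(filter_elements(decoy),
                                              cutoff=interface_cutoff)
                graph = build_graph(interface, edge_cutoff=edge_cutoff,
                                    n_rbf=n_rbf)
            except NoContactError:
                graph = None
                n_excluded += 1
            entries.append(DatasetEntry(cid, decoy.model_id, graph, label,
                                        trans, rot, decoy=decoy))
    if n_excluded:
        logger.info("excluded %d decoys with no contact atoms within %.1f A",
                    n_excluded, interface_cutoff)
    return SyntheticDataset(entries=entries, natives=natives,
                            n_excluded=n_excluded)
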