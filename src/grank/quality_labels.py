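"""Ground-truth quality of docking models measured against the native complex.

The primary training target is f-nat, the fraction of native inter-chain
residue contacts reproduced by the model: a contact is any cross-chain
residue pair with at least one heavy-atom pair within 5 A (hydrogens are
graph nodes but never count toward contacts). A model with f-nat >= 0.3 is
labeled near-native. For the CAPRI-style assessment two RMSD measures are
added, both via least-squares (Kabsch) superposition on backbone atoms
(N, CA, C, O):

* lRMSD — superpose on the receptor backbone, measure the ligand backbone;
* iRMSD — superpose and measure on the backbone of native interface
  residues (any residue with a heavy atom within 10 A of the other chain).

The CAPRI class combines the three measures into high / medium / acceptable
/ incorrect; the threshold table follows the CAPRI assessment standard and
can be overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .pdb_io import ChainComplex, ResidueId

FNAT_CONTACT_CUTOFF = 5.0      # A, heavy-atom cross-chain contact
NEAR_NATIVE_FNAT = 0.3         # f-nat >= 0.3 -> positive
IRMSD_INTERFACE_CUTOFF = 10.0  # A, interface residues for iRMSD
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: (class, fnat_min, lrmsd_max, irmsd_max) rows, best class first; a class
#: applies when fnat >= fnat_min and (lrmsd <= lrmsd_max or irmsd <= irmsd_max)
DEFAULT_CAPRI_TABLE = (
    ("high", 0.5, 1.0, 1.0),
    ("medium", 0.3, 5.0, 2.0),
    ("acceptable", 0.1, 10.0, 4.0),
)

ContactSet = frozenset  # of (receptor ResidueId, ligand ResidueId) pairs


@dataclass(frozen=True)
class QualityLabel:
    fnat: float
    lrmsd: float
    irmsd: float
    capri_class: str
    is_positive: bool


def _cross_chain_residue_pairs(complex_: ChainComplex, cutoff: float,
                               ) -> set[tuple[ResidueId, ResidueId]]:
    heavy = [a for a in complex_.atoms if a.is_heavy]
    rec = [a for a in heavy if a.chain_id == complex_.receptor_chain]
    lig = [a for a in heavy if a.chain_id == complex_.ligand_chain]
    if not rec or not lig:
        return set()
    pairs = cKDTree(np.stack([a.coords for a in rec])).query_ball_tree(
        cKDTree(np.stack([a.coords for a in lig])), r=cutoff)
    out: set[tuple[ResidueId, ResidueId]] = set()
    for i, neighbors in enumerate(pairs):
        for j in neighbors:
            out.add((rec[i].residue_id, lig[j].residue_id))
    return out


def native_contacts(native: ChainComplex,
                    contact_cutoff: float = FNAT_CONTACT_CUTOFF) -> ContactSet:
    """Cross-chain residue pairs of the native with heavy atoms within cutoff."""
    pairs = _cross_chain_residue_pairs(native, contact_cutoff)
    if not pairs:
        raise ValueError(
            f"native complex {native.complex_id!r} has no inter-chain "
            f"contacts within {contact_cutoff} A: invalid reference")
    return frozenset(pairs)


def compute_fnat(model: ChainComplex, native_set: ContactSet,
                 contact_cutoff: float = FNAT_CONTACT_CUTOFF) -> float:
    """Fraction of native contacts present in the model, in [0, 1]."""
    model_residues = {a.residue_id for a in model.atoms}
    for pair in native_set:
        for rid in pair:
            if rid not in model_residues:
                raise ValueError(
                    f"residue {rid} from the native contact set is absent "
                    "from the model (inconsistent numbering?)")
    model_pairs = _cross_chain_residue_pairs(model, contact_cutoff)
    return len(model_pairs & native_set) / len(native_set)


def kabsch_superpose(P: np.ndarray, Q: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition of Q onto P.

    Returns (R, t, rmsd) with R a 3x3 proper rotation (det +1) and t a
    translation such that ``Q @ R.T + t`` best fits P in the least-squares
    sense; rmsd is the minimum RMSD. Degenerate (collinear/coplanar) point
    sets are handled by the SVD determinant correction inside scipy's
    ``Rotation.align_vectors``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    with warnings.catch_warnings():
        # collinear/coplanar sets make the optimum non-unique; the SVD
        # determinant correction still returns a deterministic proper rotation
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(P - cp, Q - cq)
    R = rot.as_matrix()
    t = cp - cq @ R.T
    # recompute the RMSD from the residuals: scipy's rssd loses precision
    # to cancellation for near-perfect fits
    rmsd = float(np.sqrt(((Q @ R.T + t - P) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def _backbone_map(complex_: ChainComplex, chain_id: str | None = None,
                  residues: set[ResidueId] | None = None,
                  ) -> dict[tuple[ResidueId, str], np.ndarray]:
    out = {}
    for a in complex_.atoms:
        if a.atom_name not in BACKBONE_ATOMS:
            continue
        if chain_id is not None and a.chain_id != chain_id:
            continue
        if residues is not None and a.residue_id not in residues:
            continue
        out[(a.residue_id, a.atom_name)] = a.coords
    return out


def _matched_coords(model: ChainComplex, native: ChainComplex,
                    chain_id: str | None = None,
                    residues: set[ResidueId] | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Backbone coordinates shared by model and native, in native key order.

    Missing atoms (e.g. a residue without O) are tolerated: only keys present
    in both structures are used.
    """
    m = _backbone_map(model, chain_id, residues)
    n = _backbone_map(native, chain_id, residues)
    keys = [k for k in sorted(n) if k in m]
    if not keys:
        return np.zeros((0, 3)), np.zeros((0, 3))
    return (np.stack([m[k] for k in keys]), np.stack([n[k] for k in keys]))


def compute_lrmsd(model: ChainComplex, native: ChainComplex) -> float:
    """Ligand RMSD: superpose on the receptor backbone, measure the ligand."""
    rec_m, rec_n = _matched_coords(model, native, native.receptor_chain)
    if len(rec_m) < 3:
        raise ValueError("fewer than 3 shared receptor backbone atoms")
    R, t, _ = kabsch_superpose(rec_n, rec_m)
    lig_m, lig_n = _matched_coords(model, native, native.ligand_chain)
    if len(lig_m) == 0:
        raise ValueError("no shared ligand backbone atoms")
    moved = lig_m @ R.T + t
    return float(np.sqrt(((moved - lig_n) ** 2).sum(axis=1).mean()))


def interface_residues(native: ChainComplex,
                       cutoff: float = IRMSD_INTERFACE_CUTOFF,
                       ) -> set[ResidueId]:
    """Native residues with any heavy atom within ``cutoff`` of the partner."""
    pairs = _cross_chain_residue_pairs(native, cutoff)
    out: set[ResidueId] = set()
    for rec_id, lig_id in pairs:
        out.add(rec_id)
        out.add(lig_id)
    return out


def compute_irmsd(model: ChainComplex, native: ChainComplex,
                  interface_cutoff: float = IRMSD_INTERFACE_CUTOFF) -> float:
    """Interface RMSD on the backbone of native interface residues."""
    residues = interface_residues(native, interface_cutoff)
    sel_m, sel_n = _matched_coords(model, native, residues=residues)
    if len(sel_m) < 3:
        raise ValueError("fewer than 3 shared interface backbone atoms")
    _, _, rmsd = kabsch_superpose(sel_n, sel_m)
    return rmsd


def capri_class(fnat: float, irmsd: float, lrmsd: float,
                table=DEFAULT_CAPRI_TABLE) -> str:
    """Best CAPRI quality class whose criteria the model satisfies."""
    for name, fnat_min, lrmsd_max, irmsd_max in table:
        if fnat >= fnat_min and (lrmsd <= lrmsd_max or irmsd <= irmsd_max):
            return name
    return "incorrect"


def binary_label(fnat: float, cutoff: float = NEAR_NATIVE_FNAT) -> bool:
    """Near-native flag: f-nat >= cutoff (boundary counts as positive)."""
    if not 0.0 <= fnat <= 1.0:
        raise ValueError(f"fnat must be in [0, 1], got {fnat}")
    return fnat >= cutoff


def label_model(model: ChainComplex, native: ChainComplex,
                native_set: ContactSet | None = None,
                contact_cutoff: float = FNAT_CONTACT_CUTOFF,
                interface_cutoff: float = IRMSD_INTERFACE_CUTOFF,
                fnat_cutoff: float = NEAR_NATIVE_FNAT) -> QualityLabel:
    """All quality measures of one docking model against the native."""
    if native_set is None:
        native_set = native_contacts(native, contact_cutoff)
    fnat = compute_fnat(model, native_set, contact_cutoff)
    lrmsd = compute_lrmsd(model, native)
    irmsd = compute_irmsd(model, native, interface_cutoff)
    return QualityLabel(
        fnat=fnat,
        lrmsd=lrmsd,
        irmsd=irmsd,
        capri_class=capri_class(fnat, irmsd, lrmsd),
        is_positive=binary_label(fnat, fnat_cutoff),
    )
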