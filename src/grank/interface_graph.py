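"""Interface extraction and atom-level graph featurization.

The scoring network never sees the whole complex: following the interface
restriction used throughout docking-model quality assessment, only atoms
within 8.5 A of the partner chain are kept. On those atoms an atom-level
graph is built in which every atom is a node and every (ordered) pair of
atoms within 4.5 A is a directed edge. Node scalars are the one-hot atom
type over (C, N, O, S, H); edge features are a Gaussian radial-basis
expansion of the edge length plus the unit vector along the edge. The unit
vector of edge j->i points from the source j to the target i, i.e. along the
message direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pdb_io import ALLOWED_ELEMENTS, ChainComplex

DEFAULT_INTERFACE_CUTOFF = 8.5  # A, cross-chain contact for interface atoms
DEFAULT_EDGE_CUTOFF = 4.5       # A, graph edges
DEFAULT_N_RBF = 16

_ELEMENT_INDEX = {e: i for i, e in enumerate(ALLOWED_ELEMENTS)}


class NoContactError(ValueError):
    """The two chains share no atoms within the interface cutoff."""


@dataclass
class InterfaceGraph:
    """Atom graph of one docking model's interface.

    Attributes
    ----------
    node_coords : (n, 3) float array, A
    node_scalar : (n, 5) one-hot atom types
    node_vector : (n, 0, 3) empty vector channel (populated by the network)
    edges : (e, 2) int array of (source j, target i) pairs, both directions
    edge_scalar : (e, n_rbf) RBF-encoded edge lengths
    edge_vector : (e, 1, 3) unit vectors from source to target
    """

    node_coords: np.ndarray
    node_scalar: np.ndarray
    node_vector: np.ndarray
    edges: np.ndarray
    edge_scalar: np.ndarray
    edge_vector: np.ndarray
    complex_id: str = ""
    model_id: str = ""

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


def find_contact_atoms(complex_: ChainComplex,
                       cutoff: float = DEFAULT_INTERFACE_CUTOFF) -> set[int]:
    """Indices of atoms with >=1 cross-chain partner within ``cutoff`` A."""
    mask = complex_.is_receptor
    coords = complex_.coords
    rec_idx = np.flatnonzero(mask)
    lig_idx = np.flatnonzero(~mask)
    if rec_idx.size == 0 or lig_idx.size == 0:
        return set()
    pairs = cKDTree(coords[rec_idx]).query_ball_tree(
        cKDTree(coords[lig_idx]), r=cutoff)
    contacts: set[int] = set()
    for i, neighbors in enumerate(pairs):
        if neighbors:
            contacts.add(int(rec_idx[i]))
            contacts.update(int(lig_idx[j]) for j in neighbors)
    return contacts


def extract_interface(complex_: ChainComplex,
                      cutoff: float = DEFAULT_INTERFACE_CUTOFF,
                      mode: str = "atoms") -> ChainComplex:
    """Subset a complex to its inter-chain interface.

    ``mode="atoms"`` keeps exactly the contact atoms; ``mode="residues"``
    keeps all atoms of any residue that has a contact atom. Atom order is
    preserved. Raises :class:`NoContactError` when the chains do not touch,
    in which case the model must be excluded from the dataset.
    """
    contacts = find_contact_atoms(complex_, cutoff)
    if not contacts:
        raise NoContactError(
            f"no contact atoms within {cutoff} A for "
            f"{complex_.complex_id}/{complex_.model_id}")
    if mode == "residues":
        residues = {complex_.atoms[i].residue_id for i in contacts}
        keep = [i for i, a in enumerate(complex_.atoms)
                if a.residue_id in residues]
    elif mode == "atoms":
        keep = sorted(contacts)
    else:
        raise ValueError(f"unknown interface mode {mode!r}")
    return complex_.subset(keep)


def one_hot_atom(element: str) -> np.ndarray:
    """One-hot encode an element over the canonical order (C, N, O, S, H)."""
    try:
        idx = _ELEMENT_INDEX[element]
    except KeyError:
        raise ValueError(
            f"element {element!r} is not one of {ALLOWED_ELEMENTS}; "
            "run filter_elements first") from None
    vec = np.zeros(len(ALLOWED_ELEMENTS))
    vec[idx] = 1.0
    return vec


def rbf_centers(n_rbf: int, d_max: float) -> tuple[np.ndarray, float]:
    """Evenly spaced Gaussian centers on [0, d_max] with sigma = spacing."""
    centers = np.linspace(0.0, d_max, n_rbf)
    sigma = centers[1] - centers[0] if n_rbf > 1 else d_max
    return centers, sigma


def encode_edge(coord_i: np.ndarray, coord_j: np.ndarray,
                n_rbf: int = DEFAULT_N_RBF,
                d_max: float = DEFAULT_EDGE_CUTOFF,
                ) -> tuple[np.ndarray, np.ndarray]:
    """RBF length encoding and unit vector for the directed edge j -> i."""
    diff = np.asarray(coord_i, float) - np.asarray(coord_j, float)
    d = float(np.linalg.norm(diff))
    if d == 0.0:
        raise ValueError("zero-length edge: duplicate atom coordinates")
    centers, sigma = rbf_centers(n_rbf, d_max)
    rbf = np.exp(-((d - centers) ** 2) / (2.0 * sigma ** 2))
    return rbf, diff / d


def build_graph(complex_: ChainComplex,
                edge_cutoff: float = DEFAULT_EDGE_CUTOFF,
                n_rbf: int = DEFAULT_N_RBF) -> InterfaceGraph:
    """Build the atom graph of an interface-extracted, element-filtered complex.

    All atom pairs (intra- and inter-chain) within ``edge_cutoff`` become
    edges, both directions, no self-loops. Nodes keep the input atom order.
    """
    n = len(complex_.atoms)
    if n == 0:
        raise ValueError("cannot build a graph with zero atoms")
    coords = complex_.coords
    node_scalar = np.stack([one_hot_atom(a.element) for a in complex_.atoms])

    tree = cKDTree(coords)
    undirected = tree.query_pairs(r=edge_cutoff, output_type="ndarray")
    if undirected.size:
        src = np.concatenate([undirected[:, 0], undirected[:, 1]])
        dst = np.concatenate([undirected[:, 1], undirected[:, 0]])
        order = np.lexsort((src, dst))
        edges = np.stack([src[order], dst[order]], axis=1)
    else:
        edges = np.zeros((0, 2), dtype=np.intp)

    diff = coords[edges[:, 1]] - coords[edges[:, 0]]  # target minus source
    dist = np.linalg.norm(diff, axis=1)
    if np.any(dist == 0.0):
        raise ValueError("zero-length edge: duplicate atom coordinates")
    centers, sigma = rbf_centers(n_rbf, edge_cutoff)
    edge_scalar = np.exp(-((dist[:, None] - centers[None, :]) ** 2)
                         / (2.0 * sigma ** 2))
    edge_vector = (diff / dist[:, None])[:, None, :] if len(edges) else \
        np.zeros((0, 1, 3))

    return InterfaceGraph(
        node_coords=coords,
        node_scalar=node_scalar,
        node_vector=np.zeros((n, 0, 3)),
        edges=edges,
        edge_scalar=edge_scalar,
        edge_vector=edge_vector,
        complex_id=complex_.complex_id,
        model_id=complex_.model_id,
    )


def save_graph(graph: InterfaceGraph, path) -> None:
    """Write one graph to an .npz container (used by the featurize stage)."""
    np.savez(path,
             node_coords=graph.node_coords,
             node_scalar=graph.node_scalar,
             node_vector=graph.node_vector,
             edges=graph.edges,
             edge_scalar=graph.edge_scalar,
             edge_vector=graph.edge_vector,
             complex_id=np.array(graph.complex_id),
             model_id=np.array(graph.model_id))


def load_graph(path) -> InterfaceGraph:
    with np.load(path, allow_pickle=False) as data:
        return InterfaceGraph(
            node_coords=data["node_coords"],
            node_scalar=data["node_scalar"],
            node_vector=data["node_vector"],
            edges=data["edges"],
            edge_scalar=data["edge_scalar"],
            edge_vector=data["edge_vector"],
            complex_id=str(data["complex_id"]),
            model_id=str(data["model_id"]),
        )
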