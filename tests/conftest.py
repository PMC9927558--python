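"""Shared fixtures: toy complexes, random point clouds, small models."""

from __future__ import annotations

import numpy as np
import pytest

from grank.gvp_model import GVPModel, ModelConfig
from grank.interface_graph import InterfaceGraph, build_graph, extract_interface
from grank.pdb_io import AtomRecord, ChainComplex, filter_elements
from grank.synthetic_decoys import DecoyRecipe, make_dataset, make_native


def cloud_complex(coords_a: np.ndarray, coords_b: np.ndarray,
                  element: str = "C") -> ChainComplex:
    """Two chains of single-atom carbon 'residues' at the given coordinates."""
    atoms = []
    for cid, coords in (("A", np.atleast_2d(coords_a)),
                        ("B", np.atleast_2d(coords_b))):
        for i, xyz in enumerate(coords):
            atoms.append(AtomRecord(element, "CA", cid, i + 1, "", "GLY",
                                    np.asarray(xyz, dtype=float)))
    return ChainComplex("toy", "m0", "A", "B", atoms)


def random_cloud_complex(rng: np.random.Generator, n_a: int = 40,
                         n_b: int = 40, box: float = 18.0) -> ChainComplex:
    """Random point-cloud complex whose chains overlap enough to touch."""
    a = rng.uniform(0, box, size=(n_a, 3))
    b = rng.uniform(0, box, size=(n_b, 3)) + np.array([box * 0.4, 0, 0])
    return cloud_complex(a, b)


def rebuild_transformed(graph_source: ChainComplex, R: np.ndarray,
                        t: np.ndarray, **kwargs) -> InterfaceGraph:
    """Featurize a rigidly transformed copy of an interface complex."""
    moved = ChainComplex(
        graph_source.complex_id, graph_source.model_id,
        graph_source.receptor_chain, graph_source.ligand_chain,
        [AtomRecord(a.element, a.atom_name, a.chain_id, a.residue_seq,
                    a.icode, a.residue_name, a.coords @ R.T + t)
         for a in graph_source.atoms])
    return build_graph(moved, **kwargs)


def permute_graph(graph: InterfaceGraph, perm: np.ndarray) -> InterfaceGraph:
    """Reorder nodes by ``perm`` (new index i holds old node perm[i])."""
    inverse = np.empty_like(perm)
    inverse[perm] = np.arange(len(perm))
    return InterfaceGraph(
        node_coords=graph.node_coords[perm],
        node_scalar=graph.node_scalar[perm],
        node_vector=graph.node_vector[perm],
        edges=inverse[graph.edges],
        edge_scalar=graph.edge_scalar,
        edge_vector=graph.edge_vector,
        complex_id=graph.complex_id,
        model_id=graph.model_id,
    )


@pytest.fixture(scope="session")
def small_native() -> ChainComplex:
    return make_native(DecoyRecipe(seed=11))


@pytest.fixture(scope="session")
def small_interface(small_native):
    return extract_interface(filter_elements(small_native))


@pytest.fixture(scope="session")
def small_graph(small_interface):
    return build_graph(small_interface)


@pytest.fixture(scope="session")
def small_model_config() -> ModelConfig:
    return ModelConfig(node_dims=(16, 3), edge_dims=(8, 1), n_blocks=2,
                       n_rbf=16, dense_hidden=32, seed=5)


@pytest.fixture(scope="session")
def small_model(small_model_config) -> GVPModel:
    return GVPModel(small_model_config)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Six complexes x eight decoys, shared across training/eval tests."""
    return make_dataset(n_complexes=6, n_decoys_per_complex=8, seed=3)
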