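"""Shared fixtures: synthetic datasets and hand-built structure files."""

from __future__ import annotations

import numpy as np
import pytest

from solpot.config import RunConfig
from solpot.counting import BinningScheme, stack_counts
from solpot.synthetic import (
    GeneratorParams,
    RECOVERY_BIASES,
    format_atom_line,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig(seed=7)


@pytest.fixture(scope="session")
def scheme(default_config) -> BinningScheme:
    return BinningScheme.from_config(default_config)


@pytest.fixture(scope="session")
def null_dataset():
    """Exchangeable classes: no planted contacts."""
    dataset, proteins, manifest = generate_dataset(
        GeneratorParams(n_per_class=(15, 15), seed=11, planted_biases=())
    )
    return dataset, proteins, manifest


@pytest.fixture(scope="session")
def planted_dataset():
    """Study conditions: Lys-Glu at 4 Å in soluble, Trp-Trp at 6.3 Å in insoluble."""
    dataset, proteins, manifest = generate_dataset(
        GeneratorParams(seed=5, planted_biases=RECOVERY_BIASES)
    )
    return dataset, proteins, manifest


@pytest.fixture(scope="session")
def planted_stack(planted_dataset, scheme):
    dataset, _, _ = planted_dataset
    return stack_counts(dataset.records, scheme)


# ---------------------------------------------------------------------------
# a hand-built PDB with known geometry

TOY_SER_SIDECHAIN = np.array([[1.0, 0.0, 0.0], [3.0, 2.0, 0.0], [2.0, 1.0, 3.0]])
TOY_GLY_CA = np.array([10.0, 10.0, 10.0])
TOY_ALA_CB_A = np.array([20.0, 0.0, 0.0])  # altloc A, occupancy 0.7
TOY_ALA_CB_B = np.array([30.0, 0.0, 0.0])  # altloc B, occupancy 0.3
TOY_MSE_SIDECHAIN = np.array([[5.0, 5.0, 5.0], [7.0, 5.0, 5.0]])
TOY_CHAIN_B_CA = np.array([50.0, 50.0, 50.0])


@pytest.fixture(scope="session")
def toy_pdb(tmp_path_factory):
    """Chain A: SER (3 side-chain atoms), GLY (backbone only), ALA with two
    CB altlocs, MSE (maps to MET), SEP (non-standard, dropped), HOH
    (ignored); chain B: one ALA."""
    lines = []
    serial = 1

    def atom(name, res3, chain, resseq, xyz, occ=1.0, elem="C", altloc=" "):
        nonlocal serial
        lines.append(
            format_atom_line(serial, name, res3, chain, resseq, xyz,
                             occ=occ, element=elem, altloc=altloc)
        )
        serial += 1

    # SER 1: backbone + side chain OG/CB/CB2-like trio with known centroid
    atom("N", "SER", "A", 1, (0.0, 0.0, -2.0), elem="N")
    atom("CA", "SER", "A", 1, (0.0, 0.0, 0.0))
    atom("C", "SER", "A", 1, (0.0, 0.0, 2.0))
    atom("O", "SER", "A", 1, (0.0, 1.0, 2.0), elem="O")
    atom("CB", "SER", "A", 1, TOY_SER_SIDECHAIN[0])
    atom("OG", "SER", "A", 1, TOY_SER_SIDECHAIN[1], elem="O")
    atom("OXT", "SER", "A", 1, (9.0, 9.0, 9.0), elem="O")  # backbone, excluded
    atom("CG", "SER", "A", 1, TOY_SER_SIDECHAIN[2])
    # GLY 2: backbone only -> centroid falls back to CA
    atom("N", "GLY", "A", 2, (10.0, 10.0, 8.0), elem="N")
    atom("CA", "GLY", "A", 2, TOY_GLY_CA)
    atom("C", "GLY", "A", 2, (10.0, 10.0, 12.0))
    # ALA 3: CB in two conformations, A has higher occupancy
    atom("CA", "ALA", "A", 3, (20.0, 0.0, -2.0))
    atom("CB", "ALA", "A", 3, TOY_ALA_CB_A, occ=0.7, altloc="A")
    atom("CB", "ALA", "A", 3, TOY_ALA_CB_B, occ=0.3, altloc="B")
    # MSE 4 (selenomethionine -> MET)
    atom("CA", "MSE", "A", 4, (5.0, 5.0, 3.0))
    atom("CB", "MSE", "A", 4, TOY_MSE_SIDECHAIN[0])
    atom("SE", "MSE", "A", 4, TOY_MSE_SIDECHAIN[1], elem="SE")
    # SEP 5 (phosphoserine): non-standard amino acid, dropped with warning
    atom("CA", "SEP", "A", 5, (6.0, 6.0, 6.0))
    atom("CB", "SEP", "A", 5, (6.0, 6.0, 7.0))
    # water: ignored silently
    lines.append(
        "HETATM" + format_atom_line(serial, "O", "HOH", "A", 6,
                                    (1.0, 1.0, 1.0), element="O")[6:]
    )
    serial += 1
    # chain B
    atom("CA", "ALA", "B", 1, TOY_CHAIN_B_CA)
    atom("CB", "ALA", "B", 1, (51.0, 50.0, 50.0))
    lines.append("END\n")

    path = tmp_path_factory.mktemp("structures") / "toy.pdb"
    path.write_text("".join(lines))
    return path
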