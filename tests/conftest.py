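"""Shared fixtures: tiny hand-built PDB texts and in-memory interfaces."""

from __future__ import annotations

import numpy as np
import pytest

from ecr.io import Interface, InterfaceResidue, Residue


def format_atom(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz,
    altloc: str = " ",
    icode: str = " ",
    occ: float = 1.0,
    record: str = "ATOM",
) -> str:
    x, y, z = xyz
    return (
        f"{record:<6}{serial:>5} {name:^4}{altloc}{resname:>3} {chain}{resseq:>4}"
        f"{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{20.0:6.2f}"
        f"          {name.strip()[0]:>2}"
    )


def residue_lines(
    serial_start: int,
    resname: str,
    chain: str,
    resseq: int,
    ca_xyz,
    icode: str = " ",
    with_backbone: bool = True,
    record: str = "ATOM",
) -> list[str]:
    """ATOM records for one residue: full backbone around the given Cα."""
    ca = np.asarray(ca_xyz, dtype=float)
    atoms = [("CA", ca)]
    if with_backbone:
        atoms = [
            ("N", ca + [-1.46, 0.0, 0.0]),
            ("CA", ca),
            ("C", ca + [1.52, 0.0, 0.0]),
            ("O", ca + [1.52, 1.23, 0.0]),
        ]
    return [
        format_atom(serial_start + i, n, resname, chain, resseq, xyz, icode=icode,
                    record=record)
        for i, (n, xyz) in enumerate(atoms)
    ]


def write_pdb_text(path, lines: list[str]) -> str:
    text = "\n".join(lines + ["END"]) + "\n"
    path.write_text(text)
    return str(path)


def make_interface(
    ca_coords,
    ddgs,
    res_names=None,
    chain_split: int | None = None,
    iface_id: str = "test_AB",
) -> Interface:
    """In-memory interface from Cα coordinates and ΔΔG values.

    ``ddgs[i]`` may be None for a missing value.  Residues up to
    ``chain_split`` (default: half) go to chain A, the rest to chain B.
    """
    ca_coords = np.asarray(ca_coords, dtype=float)
    n = len(ca_coords)
    if chain_split is None:
        chain_split = n // 2
    if res_names is None:
        res_names = ["LEU"] * n
    members = []
    for i in range(n):
        chain = "A" if i < chain_split else "B"
        res = Residue(
            chain_id=chain,
            res_seq=i + 1,
            icode="",
            res_name=res_names[i],
            ca_xyz=ca_coords[i],
            heavy_atoms=ca_coords[i][None, :].copy(),
            atom_names=["CA"],
        )
        members.append(InterfaceResidue(residue=res, ddg=ddgs[i]))
    return Interface(id=iface_id, chain_a="A", chain_b="B", residues=members)


@pytest.fixture
def two_chain_pdb(tmp_path):
    """Two chains of 3 residues each, closest heavy-atom pair at 3.5 Å."""
    lines = []
    serial = 1
    for i, x in enumerate((0.0, 4.0, 8.0)):
        lines += residue_lines(serial, "LEU", "A", i + 1, (x, 0.0, 0.0))
        serial += 4
    for i, x in enumerate((0.0, 4.0, 8.0)):
        lines += residue_lines(serial, "VAL", "B", i + 1, (x, 0.0, 3.5))
        serial += 4
    return write_pdb_text(tmp_path / "two_chain.pdb", lines)


@pytest.fixture(scope="session")
def trained_synthetic():
    """One seeded 100+60 synthetic dataset with its trained model (shared)."""
    from ecr import generate_dataset, select_features, train_two_round

    matrix, synths = generate_dataset(100, 60, seed=1)
    matrix7 = select_features(matrix)
    model = train_two_round(matrix7, seed=1)
    return matrix7, model, synths
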