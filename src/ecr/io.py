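"""Structure and ΔΔG input: PDB reading, interface detection, exclusion filters.

An *interface* here is the pairwise chain-chain contact unit: a residue of
chain A belongs to the A:B interface iff any of its heavy (non-hydrogen)
atoms lies within ``cutoff`` Å of any heavy atom of chain B, and vice versa.
The default cutoff is 4.0 Å, a standard heavy-atom contact criterion.

ΔΔG values (kcal/mol, one per scanned residue) come from an external
computational alanine scan and are joined onto interface residues by
(chain, residue number, insertion code). Native glycine and proline are
never alanine-scanned, so their ΔΔG is always treated as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import EmptyStructureError, InputError

logger = logging.getLogger(__name__)

#: 20 standard three-letter amino-acid codes.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Monoatomic "simple ions" tolerated in an interface, plus water.
SIMPLE_IONS = frozenset({"NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE"})
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

DEFAULT_CUTOFF = 4.0  # Å, heavy-atom contact distance


@dataclass
class Residue:
    """One protein residue with its heavy-atom coordinates (Å)."""

    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    ca_xyz: np.ndarray
    heavy_atoms: np.ndarray  # (n, 3) array, includes Cα
    atom_names: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AA

    @property
    def has_full_backbone(self) -> bool:
        return BACKBONE_ATOMS.issubset(self.atom_names)


@dataclass
class HetRecord:
    """A heteroatom (non-protein, non-water, non-simple-ion) with coordinates."""

    res_name: str
    xyz: np.ndarray  # (n, 3) heavy atoms of the het group


@dataclass
class InterfaceResidue:
    """An interfacial residue: geometry plus (optionally) its alanine-scan ΔΔG."""

    residue: Residue
    ddg: float | None = None  # kcal/mol; None when unscanned or native Gly/Pro
    dr: float | None = None  # Å from the Center of Interface; filled by features


@dataclass
class Interface:
    """A pairwise chain-chain interface with its member residues and label."""

    id: str
    chain_a: str
    chain_b: str
    residues: list[InterfaceResidue]
    category: str = "unknown"  # FLIP | FunC | unknown
    subcategory: str = "unknown"

    def __len__(self) -> int:
        return len(self.residues)

    def residue_keys(self) -> set[tuple[str, int, str]]:
        return {ir.residue.key for ir in self.residues}


class DdgTable:
    """ΔΔG rows keyed by (chain, residue number, insertion code)."""

    def __init__(self, rows: dict[tuple[str, int, str], float]):
        for key, value in rows.items():
            if not np.isfinite(value):
                raise InputError(f"non-finite ΔΔG for residue {key}")
        self.rows = dict(rows)

    def __len__(self) -> int:
        return len(self.rows)

    def get(self, key: tuple[str, int, str]) -> float | None:
        return self.rows.get(key)


@dataclass
class FilterDecision:
    keep: bool
    reason: str


# ---------------------------------------------------------------------------
# PDB reading


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties go to the lexically first altloc id."""
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "~"))


def read_structure(
    path: str, model_index: int = 0
) -> tuple[list[Residue], list[HetRecord]]:
    """Read protein residues (and het groups) from a PDB file.

    Returns one :class:`Residue` per (chain, res_seq, icode) that has a Cα;
    residues lacking a Cα are dropped with a warning.  Waters and simple
    ions are ignored entirely; other het groups are returned separately so
    the heteroatom exclusion filter can test their proximity to interfaces.
    Only the model selected by ``model_index`` (default: first) is read.
    """
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise InputError(f"cannot read structure {path!r}: {exc}") from exc
    if len(structure) == 0:
        raise EmptyStructureError(f"{path!r} contains no models")
    try:
        model = structure[model_index]
    except IndexError:
        raise InputError(
            f"model index {model_index} out of range ({len(structure)} models)"
        ) from None

    residues: list[Residue] = []
    het_records: list[HetRecord] = []
    for chain in model:
        for res in chain:
            name = res.name.strip().upper()
            if name in WATER_NAMES or name in SIMPLE_IONS:
                continue
            # Collapse altlocs: group heavy atoms by atom name.
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            if not by_name:
                continue
            chosen = {n: _pick_altloc(atoms) for n, atoms in by_name.items()}
            coords = np.array(
                [[a.pos.x, a.pos.y, a.pos.z] for a in chosen.values()], dtype=float
            )
            is_protein = name in STANDARD_AA or res.het_flag == "A"
            if not is_protein:
                het_records.append(HetRecord(res_name=name, xyz=coords))
                continue
            if "CA" not in chosen:
                logger.warning(
                    "residue %s %s%d%s has no Cα; dropped",
                    name,
                    chain.name,
                    res.seqid.num,
                    res.seqid.icode.strip(),
                )
                continue
            if name not in STANDARD_AA:
                logger.warning(
                    "nonstandard residue %s at %s%d kept", name, chain.name, res.seqid.num
                )
            ca = chosen["CA"]
            residues.append(
                Residue(
                    chain_id=chain.name,
                    res_seq=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    res_name=name,
                    ca_xyz=np.array([ca.pos.x, ca.pos.y, ca.pos.z], dtype=float),
                    heavy_atoms=coords,
                    atom_names=list(chosen.keys()),
                )
            )
    if not residues:
        raise EmptyStructureError(f"{path!r} contains no protein residues")
    return residues, het_records


# ---------------------------------------------------------------------------
# Interface detection


def find_interface(
    residues: list[Residue],
    chain_a: str,
    chain_b: str,
    cutoff: float = DEFAULT_CUTOFF,
    pdb_id: str = "",
) -> Interface:
    """Identify the chain_a:chain_b interface by heavy-atom proximity.

    A residue is interfacial iff any of its heavy atoms lies within
    ``cutoff`` Å of any heavy atom of the partner chain.  The result is the
    union of interfacial residues from both chains and is symmetric in
    (chain_a, chain_b) up to the order residues are listed.
    """
    if cutoff <= 0:
        raise InputError(f"cutoff must be positive, got {cutoff}")
    res_a = [r for r in residues if r.chain_id == chain_a]
    res_b = [r for r in residues if r.chain_id == chain_b]
    if not res_a:
        raise InputError(f"chain {chain_a!r} absent from structure")
    if not res_b:
        raise InputError(f"chain {chain_b!r} absent from structure")

    members: list[InterfaceResidue] = []
    for side, other in ((res_a, res_b), (res_b, res_a)):
        other_atoms = np.vstack([r.heavy_atoms for r in other])
        tree = cKDTree(other_atoms)
        for res in side:
            dmin, _ = tree.query(res.heavy_atoms, k=1)
            if np.min(dmin) <= cutoff:
                members.append(InterfaceResidue(residue=res))

    iid = f"{pdb_id}_{chain_a}{chain_b}" if pdb_id else f"{chain_a}{chain_b}"
    return Interface(id=iid, chain_a=chain_a, chain_b=chain_b, residues=members)


def heteroatoms_near_interface(
    interface: Interface, het_records: list[HetRecord], cutoff: float = DEFAULT_CUTOFF
) -> bool:
    """True if any non-water, non-simple-ion het group contacts the interface."""
    if not interface.residues or not het_records:
        return False
    iface_atoms = np.vstack([ir.residue.heavy_atoms for ir in interface.residues])
    tree = cKDTree(iface_atoms)
    for het in het_records:
        dmin, _ = tree.query(het.xyz, k=1)
        if np.min(dmin) <= cutoff:
            return True
    return False


def apply_exclusion_filters(
    interface: Interface, heteroatoms_near: bool = False
) -> FilterDecision:
    """Apply the structural exclusion rules to a built interface.

    Rejects interfaces with 2 or fewer residues (a linear fit of energy to
    distance needs at least 3 points), interfaces contacted by heteroatoms
    other than water or simple monoatomic ions, and interfaces containing
    disordered residues (incomplete backbone).
    """
    if len(interface) <= 2:
        return FilterDecision(False, "≤2 residues in interface")
    if heteroatoms_near:
        return FilterDecision(False, "non-water/non-ion heteroatoms in interface")
    disordered = [
        ir.residue.key for ir in interface.residues if not ir.residue.has_full_backbone
    ]
    if disordered:
        return FilterDecision(
            False, f"disordered residues (incomplete backbone): {disordered[:5]}"
        )
    return FilterDecision(True, "")


# ---------------------------------------------------------------------------
# ΔΔG tables

_DEFAULT_COLUMNS = {
    "chain": "chain",
    "res": "res",
    "icode": "icode",
    "resname": "resname",
    "ddg": "ddg",
}


def read_ddg_table(path: str, column_map: dict[str, str] | None = None) -> DdgTable:
    """Read a whitespace/tab-separated ΔΔG table.

    The default dialect has a header line ``chain res icode resname ddg``.
    ``column_map`` maps the canonical names ({'chain','res','icode','ddg'})
    onto the file's own column names for other dialects (e.g. Robetta-style
    listings).  ``icode`` is optional; missing or '-' means blank.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#")
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read ΔΔG table {path!r}: {exc}") from exc

    for canonical in ("chain", "res", "ddg"):
        if colmap[canonical] not in df.columns:
            raise InputError(
                f"ΔΔG table {path!r} lacks required column {colmap[canonical]!r}"
            )

    rows: dict[tuple[str, int, str], float] = {}
    icode_col = colmap["icode"] if colmap["icode"] in df.columns else None
    for _, row in df.iterrows():
        icode = ""
        if icode_col is not None:
            raw = str(row[icode_col]).strip()
            if raw not in ("", "-", "nan", "NaN", "."):
                icode = raw
        try:
            res_seq = int(row[colmap["res"]])
            ddg = float(row[colmap["ddg"]])
        except (TypeError, ValueError) as exc:
            raise InputError(f"non-numeric entry in ΔΔG table {path!r}: {exc}") from exc
        key = (str(row[colmap["chain"]]).strip(), res_seq, icode)
        if key in rows:
            raise InputError(f"duplicate ΔΔG row for residue {key} in {path!r}")
        rows[key] = ddg
    return DdgTable(rows)


def attach_ddg(interface: Interface, table: DdgTable) -> Interface:
    """Join ΔΔG values onto interface residues by (chain, res_seq, icode).

    Native Gly/Pro always keep a missing ΔΔG (they are not alanine-scanned),
    even if the table carries a row for them.  Unmatched residues are
    permitted and logged; geometry is never altered, so the join is
    idempotent.
    """
    matched = unmatched = 0
    new_residues = []
    for ir in interface.residues:
        if ir.residue.res_name in ("GLY", "PRO"):
            new_residues.append(replace(ir, ddg=None))
            continue
        value = table.get(ir.residue.key)
        if value is None:
            unmatched += 1
        else:
            matched += 1
        new_residues.append(replace(ir, ddg=value))
    logger.info(
        "interface %s: %d ΔΔG values matched, %d interfacial residues unmatched",
        interface.id,
        matched,
        unmatched,
    )
    return replace(interface, residues=new_residues)
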