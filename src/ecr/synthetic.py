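"""Synthetic interfaces with controlled energy-centrality structure.

The generator emulates the two interface populations the classifier is
meant to separate:

* **FLIP-like** interfaces place residues roughly uniformly over a disc
  (radius ``radius_scale`` Å, small out-of-plane jitter) and assign
  ΔΔG_i = intercept + slope·Δr_i + N(0, noise_sd) — a hot centre whose
  energetic importance decays with distance from the interface centre.
* **FunC-like** interfaces use the same spatial process but draw
  ΔΔG_i ~ N(func_mean_ddg, noise_sd) independent of position: lower
  overall substitution sensitivity and no radial organisation.

Residues alternate between two chains (A/B) and every residue carries a
contact pseudo-atom steered toward its nearest partner-chain residue, so
written coordinate files round-trip through heavy-atom interface detection
at the default 4 Å cutoff with exactly the generated membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

from .exceptions import InputError
from .io import Interface, InterfaceResidue, Residue

#: Standard residues excluding Gly/Pro (which are never alanine-scanned).
SCANNABLE_AA = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "SER", "THR", "TRP", "TYR", "VAL",
]

_BACKBONE_OFFSETS = {
    "N": np.array([-1.46, 0.0, 0.0]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([1.52, 1.23, 0.0]),
}


@dataclass
class GeneratorParams:
    """Knobs of the synthetic-interface model (Å and kcal/mol)."""

    n_residues: int = 30
    radius_scale: float = 10.0
    flip_intercept: float = 2.0
    flip_slope: float = -0.15
    func_mean_ddg: float = 0.3
    noise_sd: float = 0.5
    hot_threshold: float = 1.0
    out_of_plane_sd: float = 1.0
    simulate_glypro: bool = False
    glypro_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_residues < 3:
            raise InputError("n_residues must be ≥ 3")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be ≥ 0")
        if self.radius_scale <= 0:
            raise InputError("radius_scale must be > 0")


@dataclass
class SyntheticInterface:
    interface: Interface
    true_category: str  # FLIP | FunC
    true_params: dict = field(default_factory=dict)


def _disc_positions(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    n = params.n_residues
    r = params.radius_scale * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    z = rng.normal(0.0, params.out_of_plane_sd, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _build_residues(
    positions: np.ndarray, params: GeneratorParams, rng: np.random.Generator
) -> list[Residue]:
    n = len(positions)
    chains = ["A" if i % 2 == 0 else "B" for i in range(n)]
    if params.simulate_glypro:
        names = [
            rng.choice(["GLY", "PRO"]) if rng.random() < params.glypro_fraction
            else rng.choice(SCANNABLE_AA)
            for _ in range(n)
        ]
    else:
        names = [rng.choice(SCANNABLE_AA) for _ in range(n)]

    residues: list[Residue] = []
    seq = {"A": 0, "B": 0}
    for i in range(n):
        ca = positions[i]
        # nearest partner-chain Cα decides where the contact atom points
        other = [j for j in range(n) if chains[j] != chains[i]]
        dists = np.linalg.norm(positions[other] - ca, axis=1)
        j = other[int(np.argmin(dists))]
        d = float(dists.min())
        u = (positions[j] - ca) / d if d > 0 else np.array([1.0, 0.0, 0.0])
        # place CB so it sits within 3.5 Å of the partner residue's Cα
        t = max(0.8, d - 3.5)
        cb = ca + t * u
        atoms = {"CA": ca, "CB": cb}
        for name, off in _BACKBONE_OFFSETS.items():
            atoms[name] = ca + off
        seq[chains[i]] += 1
        residues.append(
            Residue(
                chain_id=chains[i],
                res_seq=seq[chains[i]],
                icode="",
                res_name=str(names[i]),
                ca_xyz=ca.copy(),
                heavy_atoms=np.array(list(atoms.values())),
                atom_names=list(atoms.keys()),
            )
        )
    return residues


def _assemble(
    residues: list[Residue],
    ddg: np.ndarray,
    category: str,
    true_params: dict,
    iface_id: str,
) -> SyntheticInterface:
    members = []
    for res, value in zip(residues, ddg):
        missing = res.res_name in ("GLY", "PRO")
        members.append(InterfaceResidue(residue=res, ddg=None if missing else float(value)))
    interface = Interface(
        id=iface_id,
        chain_a="A",
        chain_b="B",
        residues=members,
        category=category,
        subcategory=category,
    )
    return SyntheticInterface(
        interface=interface, true_category=category, true_params=true_params
    )


def generate_flip(params: GeneratorParams, iface_id: str = "synthFLIP_AB") -> SyntheticInterface:
    """One FLIP-like interface: ΔΔG decays linearly with distance from centre."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    positions = _disc_positions(params, rng)
    residues = _build_residues(positions, params, rng)
    ca = np.array([r.ca_xyz for r in residues])
    dr = np.linalg.norm(ca - ca.mean(axis=0), axis=1)
    ddg = (
        params.flip_intercept
        + params.flip_slope * dr
        + rng.normal(0.0, params.noise_sd, size=len(dr))
    )
    return _assemble(
        residues,
        ddg,
        "FLIP",
        {"intercept": params.flip_intercept, "slope": params.flip_slope,
         "noise_sd": params.noise_sd},
        iface_id,
    )


def generate_func(params: GeneratorParams, iface_id: str = "synthFunC_AB") -> SyntheticInterface:
    """One FunC-like interface: ΔΔG independent of position, lower overall."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    positions = _disc_positions(params, rng)
    residues = _build_residues(positions, params, rng)
    ddg = rng.normal(params.func_mean_ddg, params.noise_sd, size=len(positions))
    return _assemble(
        residues,
        ddg,
        "FunC",
        {"mean_ddg": params.func_mean_ddg, "noise_sd": params.noise_sd},
        iface_id,
    )


#: Dataset-level jitter of per-interface generating parameters.
INTERCEPT_JITTER_SD = 0.45  # kcal/mol
SLOPE_JITTER_SD = 0.03  # kcal/mol/Å
FUNC_MEAN_JITTER_SD = 0.1  # kcal/mol
#: Half the FLIPs form a strongly organised sub-population (enzyme/AbHL-like)
#: whose central sensitivity exceeds the default by this much; the rest stay
#: at the default (AbAg/inhibitor-like) and are only separable in round 2.
STRONG_FLIP_BOOST = 1.5  # kcal/mol
STRONG_FLIP_FRACTION = 0.5
N_RESIDUE_RANGE = (10, 40)


def generate_dataset(
    n_flip: int,
    n_func: int,
    params: GeneratorParams | None = None,
    seed: int = 1,
):
    """A labelled synthetic dataset with per-interface parameter jitter.

    Interface sizes are drawn uniformly in 10–40 residues; FLIP intercepts
    and slopes (and FunC mean ΔΔG) are jittered around the defaults.  FLIPs
    are a mixture of a strongly organised sub-population (annotated
    ``Enzyme``) and a moderately organised one (annotated ``AbAg``), so the
    first clustering round separates only part of the FLIPs and the second
    round does real work — mirroring the sub-category structure of curated
    interface sets.  Fully deterministic per seed.  Returns
    ``(FeatureMatrix, list[SyntheticInterface])``.
    """
    from . import features as feat
    from .classify import FeatureMatrix

    if n_flip + n_func < 6:
        raise InputError("dataset needs at least 6 interfaces")
    base = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    lo, hi = N_RESIDUE_RANGE

    synths: list[SyntheticInterface] = []
    for i in range(n_flip + n_func):
        child_seed = int(rng.integers(0, 2**31 - 1))
        n_res = int(rng.integers(lo, hi + 1))
        if i < n_flip:
            strong = rng.random() < STRONG_FLIP_FRACTION
            center = base.flip_intercept + (STRONG_FLIP_BOOST if strong else 0.0)
            p = replace(
                base,
                n_residues=n_res,
                flip_intercept=float(rng.normal(center, INTERCEPT_JITTER_SD)),
                flip_slope=float(rng.normal(base.flip_slope, SLOPE_JITTER_SD)),
                seed=child_seed,
            )
            s = generate_flip(p, iface_id=f"synthFLIP{i:03d}_AB")
            s.interface.subcategory = "Enzyme" if strong else "AbAg"
            synths.append(s)
        else:
            p = replace(
                base,
                n_residues=n_res,
                func_mean_ddg=float(rng.normal(base.func_mean_ddg, FUNC_MEAN_JITTER_SD)),
                seed=child_seed,
            )
            synths.append(generate_func(p, iface_id=f"synthFunC{i:03d}_AB"))

    rows = [feat.compute_features(s.interface).as_array() for s in synths]
    matrix = FeatureMatrix(
        interface_ids=[s.interface.id for s in synths],
        values=np.array(rows),
        feature_names=list(feat.FEATURE_NAMES),
        labels=[s.true_category for s in synths],
        subcategories=[s.interface.subcategory for s in synths],
    )
    return matrix, synths


def generate_null_dataset(
    n_pos: int,
    n_neg: int,
    params: GeneratorParams | None = None,
    seed: int = 1,
):
    """A calibration dataset where the FLIP/FunC labels carry no signal.

    Every interface is drawn from the FunC process; the first ``n_pos``
    rows are nevertheless labelled FLIP.  Any classifier trained on such
    data should score an MCC near zero.  Returns the same pair as
    :func:`generate_dataset`.
    """
    from . import features as feat
    from .classify import FeatureMatrix

    if n_pos + n_neg < 6:
        raise InputError("dataset needs at least 6 interfaces")
    base = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    lo, hi = N_RESIDUE_RANGE

    synths: list[SyntheticInterface] = []
    for i in range(n_pos + n_neg):
        p = replace(
            base,
            n_residues=int(rng.integers(lo, hi + 1)),
            func_mean_ddg=float(rng.normal(base.func_mean_ddg, FUNC_MEAN_JITTER_SD)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        synths.append(generate_func(p, iface_id=f"synthNull{i:03d}_AB"))

    rows = [feat.compute_features(s.interface).as_array() for s in synths]
    matrix = FeatureMatrix(
        interface_ids=[s.interface.id for s in synths],
        values=np.array(rows),
        feature_names=list(feat.FEATURE_NAMES),
        labels=["FLIP"] * n_pos + ["FunC"] * n_neg,
        subcategories=["FunC"] * (n_pos + n_neg),
    )
    return matrix, synths


# ---------------------------------------------------------------------------
# Emitters matching what the io layer consumes


def write_pdb(synth: SyntheticInterface, path: str) -> None:
    """Write the synthetic interface as a two-chain PDB file."""
    st = gemmi.Structure()
    st.name = synth.interface.id
    model = gemmi.Model(1)
    chains = {"A": gemmi.Chain("A"), "B": gemmi.Chain("B")}
    for ir in synth.interface.residues:
        res = ir.residue
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.res_seq, " ")
        gres.het_flag = "A"
        for name, xyz in zip(res.atom_names, res.heavy_atoms):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            gres.add_atom(atom)
        chains[res.chain_id].add_residue(gres)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_ddg_tsv(synth: SyntheticInterface, path: str) -> None:
    """Write the ΔΔG table in the default dialect (Gly/Pro rows omitted)."""
    records = [
        {
            "chain": ir.residue.chain_id,
            "res": ir.residue.res_seq,
            "icode": ir.residue.icode or "-",
            "resname": ir.residue.res_name,
            "ddg": ir.ddg,
        }
        for ir in synth.interface.residues
        if ir.ddg is not None
    ]
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)
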