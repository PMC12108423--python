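"""Seeded synthetic screening inputs: decoy libraries with planted analogs.

Screening pipelines are benchmarked on libraries where ground truth is
known by construction: ``n_decoys`` drug-like molecules sampled from a
curated in-package fixture, plus ``n_analogs`` close structural variants of
the query ("planted analogs") produced by a small number of valence-safe
edits.  A good similarity ranking should place the planted analogs at the
top; :func:`enrichment` measures the fraction recovered in the top *k*.

All randomness flows through one :class:`numpy.random.Generator` (PCG64)
seeded from the spec, so identical specs produce byte-identical libraries
on any platform.

Analog edits are drawn from a fixed whitelist of transformations that can
never break valence — O-methylation of a hydroxyl, halogen swap, terminal
methyl chain extension, aromatic C-H methylation — so generated structures
always sanitize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem_io import MoleculeRecord, standardize, standardize_smiles
from .consensus import ScreenRow

logger = logging.getLogger("fpscreen.synth")

__all__ = [
    "SyntheticLibrarySpec",
    "DEFAULT_QUERY_SMILES",
    "decoy_source_smiles",
    "generate_library",
    "enrichment",
]

# Curcumin: a drug-like natural product with phenol, aromatic, methoxy and
# halogen-free sites, so every whitelisted analog edit is applicable.
DEFAULT_QUERY_SMILES = "COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)ccc1O"

_DECOY_SOURCES = {"drugs": "decoys.smi"}

_HALOGENS = (9, 17, 35)  # F, Cl, Br


def decoy_source_smiles(name: str = "drugs") -> list[tuple[str, str]]:
    """Return the ``(smiles, id)`` entries of a registered decoy source."""
    if name not in _DECOY_SOURCES:
        raise ValueError(
            f"unknown decoy source {name!r}; registered: {sorted(_DECOY_SOURCES)}"
        )
    text = (
        resources.files("fpscreen").joinpath("data", _DECOY_SOURCES[name]).read_text()
    )
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smi, name_ = line.split(None, 1)
        entries.append((smi, name_.strip()))
    return entries


@dataclass(frozen=True)
class SyntheticLibrarySpec:
    """Recipe for one synthetic screening library.

    Attributes
    ----------
    seed : int
        Seeds every random choice; identical specs give identical output.
    n_decoys : int
        Decoys sampled without replacement from *decoy_source*.
    n_analogs : int
        Close variants of the query planted into the library.
    query_smiles : str
        The screening query the analogs are derived from.
    analog_edit_depth : int
        Number of successive whitelisted structural edits per analog; depth
        1 variants retain most of the query's atom environments.
    decoy_source : str
        Name of a registered decoy scaffold set.
    """

    seed: int
    n_decoys: int
    n_analogs: int = 0
    query_smiles: str = DEFAULT_QUERY_SMILES
    analog_edit_depth: int = 1
    decoy_source: str = "drugs"

    def __post_init__(self) -> None:
        if self.n_decoys <= 0:
            raise ValueError("n_decoys must be positive")
        if self.n_analogs < 0:
            raise ValueError("n_analogs must be non-negative")
        if self.analog_edit_depth <= 0:
            raise ValueError("analog_edit_depth must be positive")


def _edit_sites(mol: Chem.Mol) -> list[tuple[str, int]]:
    """Enumerate (edit kind, atom index) pairs applicable to *mol*."""
    sites: list[tuple[str, int]] = []
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z == 8 and atom.GetTotalNumHs() >= 1 and atom.GetDegree() == 1:
            sites.append(("o_methylation", atom.GetIdx()))
        elif z in _HALOGENS:
            sites.append(("halogen_swap", atom.GetIdx()))
        elif z == 6 and not atom.GetIsAromatic() and atom.GetTotalNumHs() == 3:
            sites.append(("chain_extension", atom.GetIdx()))
        elif z == 6 and atom.GetIsAromatic() and atom.GetTotalNumHs() >= 1:
            sites.append(("aromatic_methylation", atom.GetIdx()))
    return sites


def _apply_edit(mol: Chem.Mol, edit: str, atom_idx: int, rng: np.random.Generator) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    if edit == "halogen_swap":
        current = rw.GetAtomWithIdx(atom_idx).GetAtomicNum()
        choices = [z for z in _HALOGENS if z != current]
        rw.GetAtomWithIdx(atom_idx).SetAtomicNum(int(rng.choice(choices)))
    else:
        # o_methylation / chain_extension / aromatic_methylation all append
        # one sp3 carbon to the chosen atom.
        new_idx = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(atom_idx, new_idx, Chem.BondType.SINGLE)
        rw.GetAtomWithIdx(atom_idx).SetNoImplicit(False)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def _make_analog(query: Chem.Mol, depth: int, rng: np.random.Generator) -> str:
    mol = Chem.Mol(query)
    for _ in range(depth):
        sites = _edit_sites(mol)
        if not sites:  # whitelist guarantees sites for any organic query
            break
        edit, idx = sites[int(rng.integers(len(sites)))]
        mol = _apply_edit(mol, edit, idx, rng)
    return Chem.MolToSmiles(mol)


def generate_library(spec: SyntheticLibrarySpec) -> list[MoleculeRecord]:
    """Build the library a spec describes: decoys first, then analogs.

    All records are standardized and valid; analog ids carry the
    ``analog_`` prefix, decoys keep their fixture names.
    """
    query_canonical = standardize_smiles(spec.query_smiles)  # raises if unparseable
    source = decoy_source_smiles(spec.decoy_source)
    if spec.n_decoys > len(source):
        raise ValueError(
            f"n_decoys={spec.n_decoys} exceeds decoy source size {len(source)}"
        )
    rng = np.random.default_rng(spec.seed)
    picks = rng.choice(len(source), size=spec.n_decoys, replace=False)
    records: list[MoleculeRecord] = []
    for i in picks:
        smi, name = source[int(i)]
        rec = standardize(
            MoleculeRecord(id=name, smiles_input=smi, source=f"decoy_source:{i}")
        )
        if not rec.valid:  # fixture is pre-validated; guard anyway
            raise RuntimeError(f"decoy fixture entry {name} failed standardization")
        records.append(rec)

    query_mol = Chem.MolFromSmiles(query_canonical)
    for j in range(spec.n_analogs):
        smi = _make_analog(query_mol, spec.analog_edit_depth, rng)
        rec = standardize(
            MoleculeRecord(
                id=f"analog_{j + 1}", smiles_input=smi, source=f"synthetic:{j}"
            )
        )
        if not rec.valid:
            raise RuntimeError(f"generated analog {j} failed standardization: {smi}")
        records.append(rec)
    logger.info(
        "generated library: %d decoys + %d analogs (seed %d)",
        spec.n_decoys, spec.n_analogs, spec.seed,
    )
    return records


def enrichment(
    ranking: Sequence[ScreenRow], planted_ids: set[str], k: int
) -> float:
    """Fraction of planted ids recovered in the top *k* ranked rows."""
    if not ranking:
        raise ValueError("empty ranking")
    if not planted_ids:
        raise ValueError("planted_ids must be non-empty")
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds ranking length {len(ranking)}")
    top = {row.compound_id for row in ranking[:k]}
    return len(top & set(planted_ids)) / len(planted_ids)
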