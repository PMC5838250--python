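"""Approximate computation of the five pKa-QSAR molecular descriptors.

The QSAR model uses five descriptors: the relative number of N atoms
(constitutional), the order-3 Randic connectivity index (topological), RNCG
and RNCS from the charged-partial-surface-area family (electrostatic), and
the maximum net atomic charge.  The original descriptor values came from a
closed commercial pipeline with quantum-chemical charges; this module is an
*open approximation* of the same quantities:

* partial charges are empirical Gasteiger charges (deterministic,
  desk-scale) rather than quantum-chemical or Zefirov charges;
* the solvent-accessible surface area entering RNCS is computed numerically
  by fixed-point-set sphere sampling (probe 1.4 Å) on a seeded 3-D
  embedding with force-field cleanup.

Downstream numeric values therefore differ from any commercially derived
table; the descriptors remain well-defined, deterministic functions of the
input structure.  Structures are used as drawn — no pKa-dependent
protonation enumeration.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = [
    "DescriptorError",
    "DescriptorUndefinedError",
    "MissingCoordinatesError",
    "mol_from_smiles",
    "gasteiger_charges",
    "relative_n_atoms",
    "randic3_from_graph",
    "randic_index_order3",
    "rncg",
    "rncs",
    "atomic_sasa",
    "max_net_atomic_charge",
    "descriptor_table",
    "DESCRIPTOR_COLUMNS",
]

DESCRIPTOR_COLUMNS = ["rel_n_atoms", "randic3", "rncg", "rncs", "max_net_charge"]

PROBE_RADIUS = 1.4  # water probe, Angstrom


class DescriptorError(ValueError):
    """Base class for descriptor computation failures."""


class DescriptorUndefinedError(DescriptorError):
    """The descriptor is mathematically undefined for this molecule."""


class MissingCoordinatesError(DescriptorError):
    """A 3-D conformer is required but absent; embed the molecule first."""


def mol_from_smiles(smiles: str, embed: bool = False, seed: int = 7) -> Chem.Mol:
    """Parse SMILES into an explicit-hydrogen molecule with Gasteiger charges.

    With ``embed=True`` a 3-D conformer is generated (seeded distance
    geometry) and relaxed with MMFF94, falling back to UFF where MMFF
    parameters are missing.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DescriptorError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    AllChem.ComputeGasteigerCharges(mol)
    if embed:
        params = AllChem.ETKDGv3()
        params.randomSeed = seed
        if AllChem.EmbedMolecule(mol, params) != 0:
            params.useRandomCoords = True
            if AllChem.EmbedMolecule(mol, params) != 0:
                raise MissingCoordinatesError(
                    f"3-D embedding failed for {smiles!r}"
                )
        try:
            if AllChem.MMFFOptimizeMolecule(mol) != 0:
                AllChem.UFFOptimizeMolecule(mol)
        except Exception:
            AllChem.UFFOptimizeMolecule(mol)
    return mol


def gasteiger_charges(mol: Chem.Mol) -> np.ndarray:
    """Per-atom Gasteiger partial charges (elementary-charge units)."""
    if not mol.GetNumAtoms():
        raise DescriptorError("empty molecule")
    if not mol.GetAtomWithIdx(0).HasProp("_GasteigerCharge"):
        AllChem.ComputeGasteigerCharges(mol)
    charges = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()]
    )
    if not np.all(np.isfinite(charges)):
        raise DescriptorError("Gasteiger charges are non-finite for this molecule")
    return charges


def relative_n_atoms(mol: Chem.Mol, include_h: bool = True) -> float:
    """Fraction of atoms that are nitrogen.

    The denominator counts hydrogens by default (the constitutional
    descriptor convention); set ``include_h=False`` to count heavy atoms
    only.
    """
    if mol.GetNumAtoms() == 0:
        raise DescriptorError("empty molecule")
    atoms = list(mol.GetAtoms())
    if include_h:
        total = len(atoms) + sum(a.GetNumImplicitHs() + a.GetNumExplicitHs()
                                 for a in atoms if a.GetAtomicNum() != 1)
        # explicit-H molecules contribute zero in the sum above
    else:
        atoms_heavy = [a for a in atoms if a.GetAtomicNum() != 1]
        total = len(atoms_heavy)
    if total == 0:
        raise DescriptorError("no atoms to count")
    n_nitrogen = sum(1 for a in atoms if a.GetAtomicNum() == 7)
    return n_nitrogen / total


def randic3_from_graph(neighbors: Sequence[Iterable[int]]) -> float:
    """Order-3 Randic connectivity index of an abstract simple graph.

    ``neighbors[i]`` lists the vertices adjacent to vertex ``i``.  The index
    sums ``1/sqrt(d_a d_b d_c d_d)`` over all simple 3-edge paths
    ``a-b-c-d`` (4 distinct vertices), each undirected path counted once.
    """
    nbrs = [set(n) for n in neighbors]
    deg = [len(n) for n in nbrs]
    total = 0.0
    for b in range(len(nbrs)):
        for c in nbrs[b]:
            for a in nbrs[b]:
                if a == c:
                    continue
                for d in nbrs[c]:
                    if d == b or d == a:
                        continue
                    total += 1.0 / math.sqrt(deg[a] * deg[b] * deg[c] * deg[d])
    return total / 2.0  # each undirected path visited in both orientations


def randic_index_order3(mol: Chem.Mol) -> float:
    """Order-3 Randic index of the hydrogen-suppressed molecular graph.

    A branching/shape descriptor; zero for molecules with fewer than four
    heavy atoms (no 3-edge path exists).
    """
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    if len(heavy) < 4:
        return 0.0
    index_of = {idx: i for i, idx in enumerate(heavy)}
    nbrs: list[set[int]] = [set() for _ in heavy]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in index_of and j in index_of:
            nbrs[index_of[i]].add(index_of[j])
            nbrs[index_of[j]].add(index_of[i])
    return randic3_from_graph(nbrs)


def rncg(charges) -> float:
    """Relative negative charge: |most negative charge| / |total negative charge|.

    Lies in (0, 1]; undefined (raises) when no atom carries a negative
    partial charge.
    """
    q = np.asarray(charges, dtype=float).ravel()
    neg = q[q < 0]
    if neg.size == 0:
        raise DescriptorUndefinedError(
            "rncg undefined: molecule has no negatively charged atom"
        )
    return float(np.abs(neg).max() / np.abs(neg).sum())


def max_net_atomic_charge(charges) -> float:
    """Most positive atomic partial charge (polarization descriptor)."""
    q = np.asarray(charges, dtype=float).ravel()
    if q.size == 0:
        raise DescriptorError("empty charge vector")
    return float(q.max())


def _fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (n_points, 3)."""
    k = np.arange(n_points) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n_points)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _vdw_radii(mol: Chem.Mol) -> np.ndarray:
    table = Chem.GetPeriodicTable()
    return np.array([table.GetRvdw(a.GetAtomicNum()) for a in mol.GetAtoms()])


def atomic_sasa(
    mol: Chem.Mol,
    atom_idx: int,
    probe: float = PROBE_RADIUS,
    n_points: int = 960,
) -> float:
    """Solvent-accessible surface area (Å²) of one atom by sphere sampling.

    Points on the probe-inflated van der Waals sphere of the atom count as
    accessible when outside every other atom's inflated sphere; the SASA is
    the accessible fraction of ``4 pi (r + probe)^2``.  The point set is
    fixed, so the value is deterministic.
    """
    if mol.GetNumConformers() == 0:
        raise MissingCoordinatesError(
            "molecule has no 3-D conformer; embed it first (mol_from_smiles(..., embed=True))"
        )
    conf = mol.GetConformer()
    coords = np.array([[*conf.GetAtomPosition(i)] for i in range(mol.GetNumAtoms())])
    radii = _vdw_radii(mol) + probe
    center = coords[atom_idx]
    r = radii[atom_idx]
    pts = center + r * _fibonacci_sphere(n_points)
    accessible = np.ones(n_points, dtype=bool)
    for j in range(mol.GetNumAtoms()):
        if j == atom_idx:
            continue
        d2 = np.sum((pts - coords[j]) ** 2, axis=1)
        accessible &= d2 > radii[j] ** 2
    frac = accessible.mean()
    return float(4.0 * math.pi * r**2 * frac)


def rncs(mol: Chem.Mol, probe: float = PROBE_RADIUS, n_points: int = 960) -> float:
    """Relative negative charged surface area: SASA(most negative atom) * RNCG.

    Requires Gasteiger charges and a 3-D conformer.  Units Å².
    """
    charges = gasteiger_charges(mol)
    value_rncg = rncg(charges)  # raises if no negative charge
    most_negative = int(np.argmin(charges))
    sa = atomic_sasa(mol, most_negative, probe=probe, n_points=n_points)
    return sa * value_rncg


def descriptor_table(
    smiles_list: Sequence[str],
    names: Optional[Sequence[str]] = None,
    seed: int = 7,
) -> tuple[pd.DataFrame, list[dict]]:
    """Compute the five descriptors for a list of structures.

    Returns a ``(table, errors)`` pair: the table has one row per
    successfully processed compound (columns ``DESCRIPTOR_COLUMNS``, index =
    compound name), and ``errors`` records each failure with the offending
    string instead of silently dropping it.  Deterministic given ``seed``.
    """
    if names is None:
        names = list(smiles_list)
    if len(names) != len(smiles_list):
        raise ValueError("names must match smiles_list in length")
    rows = []
    index = []
    errors: list[dict] = []
    for name, smi in zip(names, smiles_list):
        try:
            mol = mol_from_smiles(smi, embed=True, seed=seed)
            charges = gasteiger_charges(mol)
            rows.append(
                {
                    "rel_n_atoms": relative_n_atoms(mol),
                    "randic3": randic_index_order3(mol),
                    "rncg": rncg(charges),
                    "rncs": rncs(mol),
                    "max_net_charge": max_net_atomic_charge(charges),
                }
            )
            index.append(name)
        except Exception as exc:  # per-row error record
            errors.append({"name": name, "smiles": smi, "error": str(exc)})
    table = pd.DataFrame(rows, index=pd.Index(index, name="name"),
                         columns=DESCRIPTOR_COLUMNS)
    return table, errors
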