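"""The two descriptor sets compared throughout the pipeline.

``general`` descriptors are additive physicochemical properties computed
from the connection table: Wildman-Crippen atomic-contribution logP and
molar refractivity, Labute approximate van der Waals surface area together
with its partitions into logP / MR / partial-charge property bins
(SlogP_VSA, SMR_VSA, PEOE_VSA), and summary statistics of Gasteiger
partial charges.

``drug_like_index`` descriptors are topological counts describing the
hierarchy of a drug structure — rings, ring systems, linkers, molecular
framework and side chains — plus a scalar index combining them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors, rdPartialCharges
from rdkit.Chem.Scaffolds import MurckoScaffold

from cycloqsar.chem_io import CompoundLibrary, Molecule

#: Number of Gasteiger charge-equilibration sweeps; fixed for determinism.
GASTEIGER_ITERATIONS = 12

SET_TAGS = ("general", "drug_like_index")


@dataclass
class DescriptorMatrix:
    compound_ids: list[str]
    names: list[str]
    values: np.ndarray  # compounds x descriptors, float64, no NaN
    set_tag: str
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate descriptor names")
        if self.values.shape != (len(self.compound_ids), len(self.names)):
            raise ValueError("descriptor matrix shape mismatch")
        if np.isnan(self.values).any():
            raise ValueError("NaN in descriptor matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.names)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, set_tag: str) -> "DescriptorMatrix":
        df = pd.read_csv(path, index_col="id")
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy(float), set_tag)


@dataclass
class Normalization:
    """Per-column centering/scaling learned on a library; zero-variance
    columns are recorded and dropped from distance computations."""

    names: list[str]
    center: np.ndarray
    scale: np.ndarray
    dropped: list[str]
    method: str = "zscore"

    def apply(self, matrix: DescriptorMatrix) -> DescriptorMatrix:
        df = matrix.to_frame()[self.names]
        vals = (df.to_numpy(float) - self.center) / self.scale
        return DescriptorMatrix(matrix.compound_ids, list(self.names), vals, matrix.set_tag)


def _gasteiger_stats(mol: Chem.Mol) -> dict[str, float]:
    m = Chem.AddHs(mol)
    rdPartialCharges.ComputeGasteigerCharges(m, nIter=GASTEIGER_ITERATIONS)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in m.GetAtoms()])
    if not np.all(np.isfinite(q)):
        raise ValueError("Gasteiger charges did not converge")
    return {
        "PEOE_PC_plus": float(q[q > 0].sum()) if (q > 0).any() else 0.0,
        "PEOE_PC_minus": float(q[q < 0].sum()) if (q < 0).any() else 0.0,
        "PEOE_QMAX": float(q.max()),
        "PEOE_QMIN": float(q.min()),
    }


def compute_general_descriptors(mol: Molecule | Chem.Mol) -> dict[str, float]:
    """Physicochemical descriptor vector for one molecule.

    Raises ``ValueError`` for molecules whose valences cannot be resolved;
    callers collect such failures per compound.
    """
    m = mol.mol if isinstance(mol, Molecule) else mol
    if m is None:
        raise ValueError("molecule is None")
    out: dict[str, float] = {}
    out["SlogP"] = float(Crippen.MolLogP(m))
    out["SMR"] = float(Crippen.MolMR(m))
    out["LabuteASA"] = float(rdMolDescriptors.CalcLabuteASA(m))
    for i, v in enumerate(rdMolDescriptors.SlogP_VSA_(m), start=1):
        out[f"SlogP_VSA{i}"] = float(v)
    for i, v in enumerate(rdMolDescriptors.SMR_VSA_(m), start=1):
        out[f"SMR_VSA{i}"] = float(v)
    for i, v in enumerate(rdMolDescriptors.PEOE_VSA_(m), start=1):
        out[f"PEOE_VSA{i}"] = float(v)
    out.update(_gasteiger_stats(m))
    return out


def _ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Fused-ring components: SSSR rings merged when they share an atom."""
    ri = mol.GetRingInfo()
    systems: list[set[int]] = []
    for ring in ri.AtomRings():
        ring = set(ring)
        merged = [s for s in systems if s & ring]
        for s in merged:
            ring |= s
            systems.remove(s)
        systems.append(ring)
    return systems


def compute_drug_like_index(mol: Molecule | Chem.Mol) -> dict[str, float]:
    """Topological drug-like index descriptor vector.

    Counts rings (SSSR), ring systems (fused components), linker atoms
    (acyclic framework atoms between ring systems), framework atoms
    (Murcko scaffold), and side-chain atoms; the scalar ``DLI`` combines
    the counts as a sum of log2(1 + count) terms so that each structural
    level contributes on a comparable diminishing scale.
    """
    m = mol.mol if isinstance(mol, Molecule) else mol
    if m is None:
        raise ValueError("molecule is None")
    n_rings = rdMolDescriptors.CalcNumRings(m)
    systems = _ring_systems(m)
    n_systems = len(systems)
    if n_rings > 0:
        framework = MurckoScaffold.GetScaffoldForMol(m)
        n_framework = framework.GetNumAtoms()
        ring_atoms_in_framework = sum(
            1 for a in framework.GetAtoms() if a.IsInRing()
        )
        n_linker = n_framework - ring_atoms_in_framework
    else:
        n_framework = 0
        n_linker = 0
    n_side = m.GetNumAtoms() - n_framework
    counts = {
        "DLI_rings": float(n_rings),
        "DLI_ring_systems": float(n_systems),
        "DLI_linker_atoms": float(n_linker),
        "DLI_framework_atoms": float(n_framework),
        "DLI_side_chain_atoms": float(n_side),
    }
    counts["DLI"] = float(sum(np.log2(1.0 + v) for v in counts.values()))
    return counts


_COMPUTE = {
    "general": compute_general_descriptors,
    "drug_like_index": compute_drug_like_index,
}


def compute_descriptors(mol: Molecule | Chem.Mol, set_tag: str) -> dict[str, float]:
    if set_tag not in _COMPUTE:
        raise ValueError(f"unknown descriptor set {set_tag!r}; choose from {SET_TAGS}")
    return _COMPUTE[set_tag](mol)


def build_matrix(library: CompoundLibrary, set_tag: str) -> DescriptorMatrix:
    """Descriptor matrix for a library, rows in library order.

    Compounds whose descriptor computation fails are excluded with a
    warning; an error is raised only if every compound fails.
    """
    if set_tag not in _COMPUTE:
        raise ValueError(f"unknown descriptor set {set_tag!r}; choose from {SET_TAGS}")
    if len(library) == 0:
        raise ValueError("empty library")
    rows: list[list[float]] = []
    ids: list[str] = []
    names: list[str] | None = None
    warnings: list[str] = []
    for rec in library:
        try:
            vec = compute_descriptors(rec.molecule, set_tag)
        except Exception as exc:  # per-compound failure record
            warnings.append(f"descriptor failure for {rec.molecule.id!r}: {exc}")
            continue
        if names is None:
            names = list(vec)
        rows.append([vec[n] for n in names])
        ids.append(rec.molecule.id)
    if names is None:
        raise ValueError("descriptor computation failed for every compound")
    return DescriptorMatrix(ids, names, np.array(rows, dtype=float), set_tag, warnings)


def normalize(matrix: DescriptorMatrix) -> tuple[DescriptorMatrix, Normalization]:
    """Z-score each column on the full library; drop zero-variance columns.

    Standardization is computed before dataset division because the
    max-min diversity ranking must see all compounds in a common metric.
    """
    if len(matrix.compound_ids) < 2:
        raise ValueError("need at least 2 rows to normalize")
    vals = matrix.values
    center = vals.mean(axis=0)
    scale = vals.std(axis=0, ddof=1)
    keep = scale > 0
    if not keep.any():
        raise ValueError("all descriptor columns have zero variance")
    dropped = [n for n, k in zip(matrix.names, keep) if not k]
    names = [n for n, k in zip(matrix.names, keep) if k]
    norm = Normalization(names, center[keep], scale[keep], dropped)
    out = DescriptorMatrix(
        matrix.compound_ids,
        names,
        (vals[:, keep] - center[keep]) / scale[keep],
        matrix.set_tag,
        warnings=[f"dropped zero-variance column {n!r}" for n in dropped],
    )
    return out, norm
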