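"""Synthetic compound-library generator.

Emulates the statistical structure of the 93-compound cyclopamine
derivative dataset: four scaffolds carrying R-groups at numbered
positions, a handful of off-scaffold molecules, and IC50 measurements
against four cell lines where exactly one cell line (the Hedgehog-specific
assay, NCI-H446 analogue) is descriptor-driven and the others are
dominated by non-specific cytotoxicity noise.

The activity model is additive on log10 IC50:

    log10 IC50 = baseline(cell line) + sum_p coeff(cell line, p, R_p) + noise

By default the beneficial modifications on the signal cell line are
demethylation at position 8 (largest effect), methylation at position 7
and hydroxylation at position 11, so the downstream suggestion engine has
a recoverable ground truth; the other three cell lines carry no
descriptor signal.  Cut-offs default to the positive control's IC50 per
cell line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from rdkit import Chem

from cycloqsar.chem_io import (
    CELL_LINES,
    CYCLOPAMINE_IC50,
    CompoundLibrary,
    CompoundRecord,
    Molecule,
    join_library,
    read_activity_table,
    read_structures,
)
from cycloqsar.sar import Scaffold, assemble, normalize_rgroup

#: Four synthetic scaffolds sharing an aryl-tetrahydrofuranyl template and
#: differing only in the aromatic heteroatom pattern, mimicking a close
#: analogue series.  Position 7 sits on the aromatic ring, position 8 on an
#: aliphatic tetrahydrofuran carbon and position 11 on the ether-adjacent
#: carbon, so each position has a distinct chemical environment and no core
#: automorphism can exchange positions during decomposition.
DEFAULT_SCAFFOLDS: tuple[Scaffold, ...] = (
    Scaffold("S1", "c1ccc([*:7])cc1C2OC([*:11])C([*:8])C2"),
    Scaffold("S2", "c1ncc([*:7])cc1C2OC([*:11])C([*:8])C2"),
    Scaffold("S3", "c1cnc([*:7])cc1C2OC([*:11])C([*:8])C2"),
    Scaffold("S4", "c1sc([*:7])cc1C2OC([*:11])C([*:8])C2"),
)

#: Six structurally distinct off-scaffold molecules (activity = noise only).
OFF_SCAFFOLD_SMILES: tuple[str, ...] = (
    "c1ccc2ccccc2c1CCN",
    "c1ccc(cc1)S(=O)(=O)NC2CC2",
    "O=C(O)c1ccco1",
    "C1CCN(CC1)C(=O)c1ccncc1",
    "Clc1ccc(cc1)C(=O)NCCO",
    "c1cc2[nH]ccc2cc1CC(=O)N",
)

_H = "[H][*:1]"
_ME = "C[*:1]"
_ET = "CC[*:1]"
_OH = "O[*:1]"
_OME = "CO[*:1]"


def _canon(d: Mapping[str, float]) -> dict[str, float]:
    return {normalize_rgroup(k): v for k, v in d.items()}


@dataclass
class GeneratorConfig:
    n_compounds: int = 93
    n_off_scaffold: int = 6
    cell_lines: tuple[str, ...] = CELL_LINES
    signal_cell_line: str = "NCI-H446"
    #: per-position R-group sampling probabilities (shared by all scaffolds)
    rgroup_probs: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            7: {_H: 0.65, _ME: 0.15, _ET: 0.20},
            8: {_ME: 0.70, _H: 0.30},
            11: {_H: 0.65, _OH: 0.15, _OME: 0.20},
        }
    )
    #: additive effects on log10 IC50 of the signal cell line, relative to
    #: the reference substitution pattern (H at 7, methyl at 8, H at 11);
    #: demethylation at 8 is the largest potency gain.
    signal_coefficients: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            7: {_ME: -0.50, _ET: +0.10},
            8: {_H: -0.90},
            11: {_OH: -0.30, _OME: +0.10},
        }
    )
    #: baseline log10 IC50 (µg/mL); noise cell lines sit at their cut-off
    #: so their active/inactive balance is near 50/50.
    baseline_log_ic50: dict[str, float] = field(
        default_factory=lambda: {
            "NCI-H446": 1.25,
            "BxPC-3": float(np.log10(CYCLOPAMINE_IC50["BxPC-3"])),
            "SW1990": float(np.log10(CYCLOPAMINE_IC50["SW1990"])),
            "NCI-H157": float(np.log10(CYCLOPAMINE_IC50["NCI-H157"])),
        }
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "NCI-H446": 0.15,
            "BxPC-3": 0.35,
            "SW1990": 0.35,
            "NCI-H157": 0.35,
        }
    )
    cutoffs: dict[str, float] = field(default_factory=lambda: dict(CYCLOPAMINE_IC50))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_off_scaffold >= self.n_compounds:
            raise ValueError("n_off_scaffold must be smaller than n_compounds")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SD must be non-negative")
        self.rgroup_probs = {
            int(p): _canon(d) for p, d in self.rgroup_probs.items()
        }
        self.signal_coefficients = {
            int(p): _canon(d) for p, d in self.signal_coefficients.items()
        }
        for sc in DEFAULT_SCAFFOLDS:
            for p in sc.positions:
                if p not in self.rgroup_probs:
                    raise ValueError(f"no R-group vocabulary for position {p}")


@dataclass
class GroundTruth:
    """Generating parameters and noiseless activity surface."""

    #: per-compound true mean log10 IC50 per cell line
    mean_log_ic50: pd.DataFrame
    #: per-compound true labels at the configured cut-offs (noiseless)
    labels: pd.DataFrame
    #: the generating coefficients on the signal cell line
    coefficients: dict[int, dict[str, float]]
    #: compound id -> (scaffold id or "", position -> R-group)
    assignments: dict[str, tuple[str, dict[int, str]]]


def generate_library(
    config: GeneratorConfig | None = None, seed: Optional[int] = None
) -> tuple[CompoundLibrary, GroundTruth]:
    """Draw a synthetic library; deterministic given the seed."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_scaffolded = config.n_compounds - config.n_off_scaffold
    records: list[CompoundRecord] = []
    means: dict[str, dict[str, float]] = {}
    assignments: dict[str, tuple[str, dict[int, str]]] = {}

    for i in range(n_scaffolded):
        cid = f"CPD-{i + 1:03d}"
        sc = DEFAULT_SCAFFOLDS[int(rng.integers(len(DEFAULT_SCAFFOLDS)))]
        rgroups: dict[int, str] = {}
        for p in sc.positions:
            probs = config.rgroup_probs[p]
            names = sorted(probs)
            weights = np.array([probs[n] for n in names])
            rgroups[p] = names[int(rng.choice(len(names), p=weights / weights.sum()))]
        mol = assemble(sc, rgroups)
        effect = sum(
            config.signal_coefficients.get(p, {}).get(rg, 0.0)
            for p, rg in rgroups.items()
        )
        mean_row = {}
        for cl in config.cell_lines:
            mean_row[cl] = config.baseline_log_ic50[cl] + (
                effect if cl == config.signal_cell_line else 0.0
            )
        means[cid] = mean_row
        assignments[cid] = (sc.id, rgroups)
        acts = {
            cl: float(10.0 ** (mean_row[cl] + rng.normal(0.0, config.noise_sd[cl])))
            for cl in config.cell_lines
        }
        records.append(CompoundRecord(Molecule(cid, mol), acts))

    for j in range(config.n_off_scaffold):
        cid = f"OFF-{j + 1:03d}"
        mol = Chem.MolFromSmiles(OFF_SCAFFOLD_SMILES[j % len(OFF_SCAFFOLD_SMILES)])
        # off-scaffold decoys: noise-only activity around the cut-off on
        # every cell line, including the signal one
        mean_row = {
            cl: float(np.log10(config.cutoffs[cl])) for cl in config.cell_lines
        }
        means[cid] = mean_row
        assignments[cid] = ("", {})
        acts = {
            cl: float(10.0 ** (mean_row[cl] + rng.normal(0.0, config.noise_sd[cl])))
            for cl in config.cell_lines
        }
        records.append(CompoundRecord(Molecule(cid, mol), acts))

    library = CompoundLibrary(records, config.cell_lines)
    mean_df = pd.DataFrame(means).T.loc[library.ids, list(config.cell_lines)]
    label_df = pd.DataFrame(
        {
            cl: mean_df[cl] <= np.log10(config.cutoffs[cl])
            for cl in config.cell_lines
        }
    )
    truth = GroundTruth(mean_df, label_df, config.signal_coefficients, assignments)
    return library, truth


def export_fixture(
    library: CompoundLibrary,
    truth: GroundTruth,
    directory: str | Path,
    config: GeneratorConfig | None = None,
) -> dict[str, Path]:
    """Write structures, activities, ground truth and a config echo."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "structures": directory / "structures.smi",
        "activities": directory / "activities.csv",
        "truth": directory / "truth.csv",
        "config": directory / "config.json",
    }
    library.write_smiles(paths["structures"])
    library.write_activities(paths["activities"])
    tdf = truth.mean_log_ic50.copy()
    tdf.columns = [f"mean_log10_ic50_{c}" for c in tdf.columns]
    for c in truth.labels.columns:
        tdf[f"active_{c}"] = truth.labels[c].astype(int)
    tdf.index.name = "id"
    tdf.to_csv(paths["truth"])
    cfg = asdict(config) if config is not None else asdict(GeneratorConfig())
    cfg["coefficients"] = {
        str(p): d for p, d in truth.coefficients.items()
    }
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
    return paths


def load_fixture(directory: str | Path) -> CompoundLibrary:
    """Re-read an exported fixture as a library."""
    directory = Path(directory)
    mols, _ = read_structures(directory / "structures.smi", "smiles")
    acts = read_activity_table(directory / "activities.csv")
    return join_library(mols, acts)
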