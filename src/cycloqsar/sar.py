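"""Structure-activity suggestion engine.

Given a library matched against a set of scaffolds with numbered R-group
positions, the engine enumerates hypothetical *chimeric* molecules by
single-point mutation — replacing the R-group at one position of one
input molecule with an R-group observed at the same position in another
molecule of the same scaffold — scores each chimera by the gain in
predicted probability of activity over the average input molecule, weights
it by cumulative structural similarity to the same-scaffold inputs (the
statistical base supporting the prediction), and reports the ranked table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdRGroupDecomposition as _RGD

from cycloqsar.chem_io import CompoundLibrary, Molecule
from cycloqsar.descriptors import compute_descriptors
from cycloqsar.models import BayesModel


@dataclass(frozen=True)
class Scaffold:
    """A core structure with numbered attachment positions.

    ``smiles`` contains one labeled dummy atom ``[*:n]`` per position.
    Cores must have no graph automorphism so position assignment during
    decomposition is unambiguous.
    """

    id: str
    smiles: str

    @property
    def core(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise ValueError(f"invalid scaffold SMILES {self.smiles!r}")
        return m

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(
            sorted(
                a.GetAtomMapNum()
                for a in self.core.GetAtoms()
                if a.GetAtomicNum() == 0 and a.GetAtomMapNum() > 0
            )
        )


def normalize_rgroup(smiles: str) -> str:
    """Canonical position-agnostic form of an R-group fragment.

    R-groups observed at different positions compare equal when their
    fragments are identical up to the attachment label.
    """
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ValueError(f"invalid R-group SMILES {smiles!r}")
    for a in m.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetAtomMapNum(1)
    return Chem.MolToSmiles(m)


def _with_position(rgroup_canonical: str, position: int) -> str:
    return rgroup_canonical.replace("[*:1]", f"[*:{position}]")


#: human-readable names for the common fragments
RGROUP_NAMES = {
    "[H][*:1]": "H",
    "C[*:1]": "methyl",
    "CC[*:1]": "ethyl",
    "O[*:1]": "hydroxyl",
    "CO[*:1]": "methoxy",
}


def rgroup_name(canonical: str) -> str:
    return RGROUP_NAMES.get(canonical, canonical)


def mutation_class(old: str, new: str) -> str:
    """Chemical name of a single-point mutation (canonical R-group forms)."""
    o, n = rgroup_name(old), rgroup_name(new)
    if o == "methyl" and n == "H":
        return "demethylation"
    if o == "H" and n == "methyl":
        return "methylation"
    if o == "H" and n == "hydroxyl":
        return "hydroxylation"
    return f"{o}->{n} substitution"


@dataclass
class ScaffoldMatch:
    compound_id: str
    scaffold_id: str
    #: position -> canonical position-agnostic R-group SMILES
    rgroups: dict[int, str]


def assemble(scaffold: Scaffold, rgroups: Mapping[int, str]) -> Chem.Mol:
    """Reassemble core + R-groups into a sanitized molecule."""
    mol = scaffold.core
    for pos in scaffold.positions:
        frag_smi = _with_position(rgroups[pos], pos)
        frag = Chem.MolFromSmiles(frag_smi)
        if frag is None:
            raise ValueError(f"invalid R-group {frag_smi!r}")
        mol = Chem.CombineMols(mol, frag)
    out = Chem.RemoveHs(Chem.molzip(mol))
    Chem.SanitizeMol(out)
    return out


def match_scaffolds(
    library: CompoundLibrary | Sequence[Molecule],
    scaffolds: Sequence[Scaffold],
) -> tuple[list[ScaffoldMatch], list[str]]:
    """Assign each compound to the first scaffold whose core matches it.

    Matching requires every non-core atom to belong to a fragment attached
    at a numbered position (substituents are only allowed at R-group
    positions).  Compounds matching no scaffold are returned as unmatched;
    this is a normal outcome, not an error.
    """
    if not scaffolds:
        raise ValueError("empty scaffold set")
    molecules = library.molecules if isinstance(library, CompoundLibrary) else list(library)
    params = _RGD.RGroupDecompositionParameters()
    params.onlyMatchAtRGroups = True
    matches: dict[str, ScaffoldMatch] = {}
    remaining = list(molecules)
    for sc in scaffolds:
        if not remaining:
            break
        res, unmatched_idx = _RGD.RGroupDecompose(
            [sc.core], [m.mol for m in remaining], asSmiles=True, options=params
        )
        unmatched_set = set(unmatched_idx)
        next_remaining = []
        ri = 0
        for i, m in enumerate(remaining):
            if i in unmatched_set:
                next_remaining.append(m)
                continue
            row = res[ri]
            ri += 1
            rg = {p: normalize_rgroup("[H][*:1]") for p in sc.positions}
            for key, frag in row.items():
                if key.startswith("R"):
                    rg[int(key[1:])] = normalize_rgroup(frag)
            matches[m.id] = ScaffoldMatch(m.id, sc.id, rg)
        remaining = next_remaining
    ordered = [matches[m.id] for m in molecules if m.id in matches]
    unmatched = [m.id for m in remaining]
    return ordered, unmatched


@dataclass
class Provenance:
    """One way of reaching a chimera: parent molecule and the mutation."""

    parent_id: str
    position: int
    old_rgroup: str
    new_rgroup: str


@dataclass
class Chimera:
    parent_id: str
    scaffold_id: str
    position: int
    old_rgroup: str
    new_rgroup: str
    rgroups: dict[int, str]
    mol: Chem.Mol
    #: every (parent, mutation) pair producing this molecule; the primary
    #: fields above mirror provenances[0]
    provenances: list[Provenance] = field(default_factory=list)

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    def attribute(self, provenance: Provenance) -> None:
        """Relabel the primary parent/mutation to the given provenance."""
        self.parent_id = provenance.parent_id
        self.position = provenance.position
        self.old_rgroup = provenance.old_rgroup
        self.new_rgroup = provenance.new_rgroup


def observed_rgroups(
    matches: Sequence[ScaffoldMatch],
) -> dict[tuple[str, int], set[str]]:
    """R-group vocabulary observed at each (scaffold, position)."""
    vocab: dict[tuple[str, int], set[str]] = {}
    for m in matches:
        for pos, rg in m.rgroups.items():
            vocab.setdefault((m.scaffold_id, pos), set()).add(rg)
    return vocab


def enumerate_chimeras(
    matches: Sequence[ScaffoldMatch],
    scaffolds: Sequence[Scaffold],
) -> list[Chimera]:
    """All unique single-point mutants of the matched molecules.

    For every molecule, position, and R-group observed at that position in
    another same-scaffold molecule (and differing from the parent's), one
    chimera is formed.  The list is deduplicated by the full
    (scaffold, position -> R-group) map, and chimeras identical to an
    existing input molecule are removed.
    """
    if not matches:
        raise ValueError("no scaffold matches to enumerate from")
    by_id = {s.id: s for s in scaffolds}
    vocab = observed_rgroups(matches)
    existing = {
        (m.scaffold_id, tuple(sorted(m.rgroups.items()))) for m in matches
    }
    seen: dict[tuple[str, tuple], Chimera] = {}
    out: list[Chimera] = []
    for m in matches:
        sc = by_id[m.scaffold_id]
        for pos in sc.positions:
            old = m.rgroups[pos]
            for new in sorted(vocab[(m.scaffold_id, pos)]):
                if new == old:
                    continue
                rg = dict(m.rgroups)
                rg[pos] = new
                key = (m.scaffold_id, tuple(sorted(rg.items())))
                if key in existing:
                    continue
                prov = Provenance(m.compound_id, pos, old, new)
                if key in seen:
                    seen[key].provenances.append(prov)
                    continue
                ch = Chimera(m.compound_id, m.scaffold_id, pos, old, new, rg,
                             assemble(sc, rg), [prov])
                seen[key] = ch
                out.append(ch)
    return out


def position_similarity(a: Mapping[int, str], b: Mapping[int, str]) -> float:
    """Fraction of shared scaffold positions bearing an identical R-group."""
    positions = sorted(set(a) | set(b))
    if not positions:
        return 0.0
    same = sum(1 for p in positions if a.get(p) == b.get(p))
    return same / len(positions)


def weight_chimera(
    chimera_rgroups: Mapping[int, str],
    scaffold_id: str,
    matches: Sequence[ScaffoldMatch],
) -> float:
    """Cumulative-similarity weight: mean positionwise similarity of the
    chimera to all same-scaffold input molecules, in [0, 1]."""
    peers = [m for m in matches if m.scaffold_id == scaffold_id]
    if not peers:
        return 0.0
    return float(
        np.mean([position_similarity(chimera_rgroups, m.rgroups) for m in peers])
    )


@dataclass
class SuggestionTable:
    table: pd.DataFrame
    mean_input_probability: float
    notice: str = ""

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_sar_report(
    model: BayesModel,
    library: CompoundLibrary,
    scaffolds: Sequence[Scaffold],
    descriptor_set: str = "general",
    top_n: int = 10,
    matches: Optional[Sequence[ScaffoldMatch]] = None,
    descriptor_names: Optional[Sequence[str]] = None,
) -> SuggestionTable:
    """Ranked table of single-point mutation suggestions.

    The score of a chimera is its predicted probability of activity minus
    the mean predicted probability over the input molecules, so 0 means
    "as likely active as an average input molecule" and positive means
    better; the printed percentage gain is 100x the score.  Suggestions
    are ranked by score x weight (descending), ties by weight then parent
    id.
    """
    if matches is None:
        matches, _ = match_scaffolds(library, scaffolds)
    if not matches:
        return SuggestionTable(pd.DataFrame(), 0.0, "no scaffold matches")
    chimeras = enumerate_chimeras(matches, scaffolds)

    def descr(mol: Chem.Mol) -> np.ndarray:
        vec = compute_descriptors(mol, descriptor_set)
        names = descriptor_names if descriptor_names is not None else list(vec)
        return np.array([vec[n] for n in names], dtype=float)

    input_X = np.array([descr(rec.molecule.mol) for rec in library])
    input_p = model.predict_proba(input_X)
    mean_p = float(np.mean(input_p))
    p_of = dict(zip(library.ids, input_p))

    rows = []
    for ch in chimeras:
        # attribute each unique chimera to the parent with the lowest
        # predicted activity: the mutation credited with the largest gain
        best = min(ch.provenances, key=lambda pr: (p_of.get(pr.parent_id, 1.0), pr.parent_id))
        ch.attribute(best)
        try:
            x = descr(ch.mol)
        except Exception:
            continue  # dropped with a warning row below
        p = float(model.predict_proba(x[None, :])[0])
        score = p - mean_p
        weight = weight_chimera(ch.rgroups, ch.scaffold_id, matches)
        rows.append(
            {
                "parent": ch.parent_id,
                "scaffold": ch.scaffold_id,
                "position": ch.position,
                "old_rgroup": rgroup_name(ch.old_rgroup),
                "new_rgroup": rgroup_name(ch.new_rgroup),
                "mutation": f"{mutation_class(ch.old_rgroup, ch.new_rgroup)} at position {ch.position}",
                "smiles": ch.smiles,
                "p_active": p,
                "score": score,
                "percent_gain": 100.0 * score,
                "weight": weight,
                "rank_key": score * weight,
            }
        )
    if not rows:
        return SuggestionTable(pd.DataFrame(), mean_p, "zero chimeras")
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["rank_key", "weight", "parent"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df = df.head(top_n) if top_n >= 0 else df
    return SuggestionTable(df.reset_index(drop=True), mean_p)
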