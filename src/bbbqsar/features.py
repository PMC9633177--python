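"""Structural feature mining: fragments, scaffolds and enrichment statistics.

Features come in three kinds:

``linear_path``
    Simple (non-self-intersecting) heavy-atom paths of 2..N atoms.  Atom
    labels distinguish aromatic atoms (lowercase, as in SMILES), aliphatic
    ring atoms (``CR``) and acyclic atoms (``C``), so a chain amine, a cyclic
    amine and an aromatic nitrogen are three different features.  A path and
    its reverse are one feature.

``ring_system``
    Maximal fused ring systems, identified by their canonical SMILES.

``scaffold``
    Murcko frameworks (ring systems plus linkers), canonical SMILES.

Per-feature enrichment is summarised by a Z-score.  The raw form ``z_raw`` is
the difference between the mean activity of the compounds carrying the
feature and the mean activity of the full set; the standardised form
``z_std`` divides that difference by the binomial standard error
sqrt(p(1-p)/frequency) at the full-set positive rate p, so that thresholds
like |Z| >= 1 are meaningful across frequencies.  Selection thresholds are
applied to ``z_std``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


@dataclass(frozen=True)
class Fragment:
    """A canonical structural feature."""

    fragment_id: str
    kind: str  # linear_path | ring_system | scaffold
    n_atoms: int


@dataclass(frozen=True)
class FeatureStats:
    fragment_id: str
    frequency: int
    n_positive: int
    mean_activity: float
    z_raw: float
    z_std: float

    @property
    def precision(self) -> float:
        """Fraction of feature-bearing training compounds that are positive."""
        return self.mean_activity


@dataclass
class FeatureMatrix:
    """Binary occurrence matrix: compounds (rows) x fragments (columns)."""

    compound_ids: list[str]
    fragments: list[Fragment]
    values: np.ndarray  # bool, shape (n_compounds, n_fragments)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.compound_ids), len(self.fragments)):
            raise ValueError("matrix shape does not match ids/fragments")

    def column(self, fragment_id: str) -> np.ndarray:
        idx = [f.fragment_id for f in self.fragments].index(fragment_id)
        return self.values[:, idx]

    def subset(self, fragment_ids: Sequence[str]) -> "FeatureMatrix":
        wanted = set(fragment_ids)
        cols = [j for j, f in enumerate(self.fragments) if f.fragment_id in wanted]
        return FeatureMatrix(
            compound_ids=list(self.compound_ids),
            fragments=[self.fragments[j] for j in cols],
            values=self.values[:, cols],
        )


# ---------------------------------------------------------------------------
# linear path enumeration


def atom_label(atom: Chem.Atom) -> str:
    """Feature-alphabet label of one atom.

    Aromatic atoms are lowercase; aliphatic ring atoms get an ``R`` suffix so
    the cyclic/acyclic chemical environment is part of the feature identity.
    """
    sym = atom.GetSymbol()
    if atom.GetIsAromatic():
        return sym.lower()
    if atom.IsInRing():
        return sym + "R"
    return sym


def path_label(mol: Chem.Mol, path: Sequence[int]) -> str:
    """Canonical label of an atom-index path: min of the two read directions."""
    atoms = [atom_label(mol.GetAtomWithIdx(i)) for i in path]
    bonds = []
    for a, b in zip(path, path[1:]):
        bond = mol.GetBondBetweenAtoms(a, b)
        bonds.append(BOND_SYMBOL.get(bond.GetBondType(), "-"))
    forward = atoms[0] + "".join(b + a for b, a in zip(bonds, atoms[1:]))
    backward = atoms[-1] + "".join(b + a for b, a in zip(reversed(bonds), reversed(atoms[:-1])))
    return min(forward, backward)


def _simple_paths(mol: Chem.Mol, max_atoms: int) -> Iterable[list[int]]:
    """All simple paths of 2..max_atoms atoms, each undirected path once."""
    adjacency = [[n.GetIdx() for n in a.GetNeighbors()] for a in mol.GetAtoms()]

    def extend(path: list[int], visited: set[int]):
        if len(path) >= 2 and path[0] < path[-1]:
            # each undirected path emitted once: from its smaller endpoint
            yield list(path)
        if len(path) == max_atoms:
            return
        for nxt in adjacency[path[-1]]:
            if nxt not in visited:
                path.append(nxt)
                visited.add(nxt)
                yield from extend(path, visited)
                visited.remove(nxt)
                path.pop()

    for start in range(mol.GetNumAtoms()):
        yield from extend([start], {start})


def enumerate_linear_fragments(
    mol: Chem.Mol, min_atoms: int = 2, max_atoms: int = 7
) -> set[Fragment]:
    """All canonical linear-path fragments of ``mol`` with min..max atoms."""
    if not (2 <= min_atoms <= max_atoms <= 8):
        raise ValueError("path length bounds must satisfy 2 <= min <= max <= 8")
    out: dict[str, Fragment] = {}
    for path in _simple_paths(mol, max_atoms):
        if len(path) < min_atoms:
            continue
        label = path_label(mol, path)
        if label not in out:
            out[label] = Fragment(fragment_id=label, kind="linear_path", n_atoms=len(path))
    return set(out.values())


def molecule_path_labels(mol: Chem.Mol, min_atoms: int = 2, max_atoms: int = 7) -> set[str]:
    return {f.fragment_id for f in enumerate_linear_fragments(mol, min_atoms, max_atoms)}


# ---------------------------------------------------------------------------
# ring systems and scaffolds


def ring_systems(mol: Chem.Mol) -> list[Fragment]:
    """Maximal fused ring systems (rings sharing an atom are merged)."""
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    systems: list[set[int]] = []
    for ring in rings:
        merged = ring
        rest = []
        for s in systems:
            if s & merged:
                merged = merged | s
            else:
                rest.append(s)
        systems = rest + [merged]
    out = []
    for atoms in systems:
        smiles = Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms), canonical=True)
        canonical = Chem.MolFromSmiles(smiles)
        if canonical is None:  # fragment SMILES not independently valid; skip
            continue
        out.append(
            Fragment(
                fragment_id=Chem.MolToSmiles(canonical),
                kind="ring_system",
                n_atoms=canonical.GetNumHeavyAtoms(),
            )
        )
    return out


def murcko_scaffold(mol: Chem.Mol) -> Fragment | None:
    core = MurckoScaffold.GetScaffoldForMol(mol)
    if core is None or core.GetNumHeavyAtoms() == 0:
        return None
    return Fragment(
        fragment_id=Chem.MolToSmiles(core), kind="scaffold", n_atoms=core.GetNumHeavyAtoms()
    )


@dataclass(frozen=True)
class ScaffoldConfig:
    min_compounds: int = 3
    min_atoms: int = 6
    min_abs_z: float = 1.0
    # rotatable bonds in the scaffold are deliberately unrestricted


def enumerate_scaffolds(
    molecules: Sequence[Chem.Mol],
    labels: Sequence[int],
    constraints: ScaffoldConfig | None = None,
) -> set[Fragment]:
    """Ring-system/framework features passing the frequency, size and Z cuts.

    Candidates are every fused ring system and Murcko framework occurring in
    the training molecules; a candidate is emitted iff it occurs in at least
    ``min_compounds`` molecules, has at least ``min_atoms`` heavy atoms, and
    its standardised Z-score magnitude reaches ``min_abs_z``.
    """
    constraints = constraints or ScaffoldConfig()
    if len(molecules) == 0:
        raise ValueError("empty training set")
    if len(molecules) != len(labels):
        raise ValueError("labels must align with molecules")
    candidates: dict[str, Fragment] = {}
    for mol in molecules:
        for frag in ring_systems(mol):
            candidates.setdefault(frag.fragment_id, frag)
        sc = murcko_scaffold(mol)
        if sc is not None:
            candidates.setdefault(sc.fragment_id, sc)
    sized = [f for f in candidates.values() if f.n_atoms >= constraints.min_atoms]
    if not sized:
        return set()
    matrix = build_feature_matrix(molecules, sized)
    stats = {s.fragment_id: s for s in feature_statistics(matrix, labels)}
    return {
        f
        for f in sized
        if stats[f.fragment_id].frequency >= constraints.min_compounds
        and abs(stats[f.fragment_id].z_std) >= constraints.min_abs_z
    }


# ---------------------------------------------------------------------------
# occurrence matrix


def _query_mol(fragment: Fragment) -> Chem.Mol:
    q = Chem.MolFromSmiles(fragment.fragment_id)
    if q is None:
        raise ValueError(f"fragment {fragment.fragment_id!r} is not a valid SMILES query")
    return q


def molecule_feature_bits(
    mol: Chem.Mol,
    fragments: Sequence[Fragment],
    path_labels: set[str] | None = None,
) -> np.ndarray:
    """Binary occurrence vector of ``fragments`` in one molecule."""
    path_kinds = [f for f in fragments if f.kind == "linear_path"]
    if path_labels is None and path_kinds:
        max_len = max(f.n_atoms for f in path_kinds)
        path_labels = molecule_path_labels(mol, 2, max_len)
    bits = np.zeros(len(fragments), dtype=bool)
    for j, f in enumerate(fragments):
        if f.kind == "linear_path":
            bits[j] = f.fragment_id in (path_labels or set())
        else:
            bits[j] = mol.HasSubstructMatch(_query_mol(f))
    return bits


def build_feature_matrix(
    molecules: Sequence[Chem.Mol],
    features: Iterable[Fragment],
    compound_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Binary molecules x fragments occurrence matrix (deterministic order)."""
    fragments = sorted(set(features), key=lambda f: (f.kind, f.fragment_id))
    if not fragments:
        raise ValueError("feature set must be non-empty")
    ids = list(compound_ids) if compound_ids is not None else [f"mol_{i}" for i in range(len(molecules))]
    path_max = max((f.n_atoms for f in fragments if f.kind == "linear_path"), default=0)
    rows = []
    for mol in molecules:
        labels = molecule_path_labels(mol, 2, path_max) if path_max else set()
        rows.append(molecule_feature_bits(mol, fragments, path_labels=labels))
    return FeatureMatrix(compound_ids=ids, fragments=fragments, values=np.array(rows, dtype=bool))


# ---------------------------------------------------------------------------
# statistics and pruning


def feature_statistics(matrix: FeatureMatrix, labels: Sequence[int]) -> list[FeatureStats]:
    """Per-feature activity enrichment relative to the full-set positive rate."""
    y = np.asarray(labels, dtype=float)
    if y.shape[0] != matrix.values.shape[0]:
        raise ValueError("labels must align with matrix rows")
    base_rate = float(y.mean())
    out = []
    for j, frag in enumerate(matrix.fragments):
        col = matrix.values[:, j]
        freq = int(col.sum())
        if freq == 0:
            raise ValueError(f"feature {frag.fragment_id!r} has zero frequency; drop it upstream")
        n_pos = int(y[col].sum())
        mean_act = n_pos / freq
        z_raw = mean_act - base_rate
        se = np.sqrt(base_rate * (1.0 - base_rate) / freq)
        z_std = z_raw / se if se > 0 else 0.0
        out.append(
            FeatureStats(
                fragment_id=frag.fragment_id,
                frequency=freq,
                n_positive=n_pos,
                mean_activity=mean_act,
                z_raw=z_raw,
                z_std=float(z_std),
            )
        )
    return out


@dataclass(frozen=True)
class PruneConfig:
    min_count: int = 4
    min_abs_z: float = 1.0
    corr_cutoff: float = 0.95  # phi coefficient between binary columns


def prune_features(
    stats: Sequence[FeatureStats],
    matrix: FeatureMatrix,
    params: PruneConfig | None = None,
) -> list[str]:
    """Reduce to a non-redundant predictive feature set.

    Features below the frequency or |z_std| cut are dropped; among pairs of
    surviving columns with phi correlation >= ``corr_cutoff`` the higher
    |z_std| one is kept (ties: fewer atoms, then lexicographic id).  Result
    order is deterministic (by descending |z_std|).
    """
    params = params or PruneConfig()
    if not stats:
        raise ValueError("no feature statistics supplied")
    by_id = {f.fragment_id: f for f in matrix.fragments}
    survivors = [
        s for s in stats
        if s.frequency >= params.min_count and abs(s.z_std) >= params.min_abs_z
    ]
    if not survivors:
        raise ValueError(
            "all features pruned; relax min_count/min_abs_z or enlarge the training set"
        )
    order = sorted(
        survivors,
        key=lambda s: (-abs(s.z_std), by_id[s.fragment_id].n_atoms, s.fragment_id),
    )
    col_index = {f.fragment_id: j for j, f in enumerate(matrix.fragments)}
    X = matrix.values[:, [col_index[s.fragment_id] for s in order]].astype(float)
    corr = _phi_matrix(X)
    kept_pos: list[int] = []
    for j in range(len(order)):
        if all(corr[j, k] < params.corr_cutoff for k in kept_pos):
            kept_pos.append(j)
    return [order[j].fragment_id for j in kept_pos]


def _phi_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise phi coefficients between binary columns; constant columns get
    correlation 1 with identical columns and 0 otherwise."""
    n, k = X.shape
    std = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False) if k > 1 else np.ones((1, 1))
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
    constant = std == 0
    if constant.any():
        for j in np.flatnonzero(constant):
            same = np.all(X == X[:, [j]], axis=0)
            corr[j, :] = np.where(same, 1.0, 0.0)
            corr[:, j] = corr[j, :]
    return corr


# ---------------------------------------------------------------------------
# functional group profiling

DEFAULT_FUNCTIONAL_GROUPS: dict[str, str] = {
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "carboxylate": "[CX3](=O)[O-]",
    "sulfonamide": "[SX4](=O)(=O)[NX3]",
    "sulfone": "[SX4](=O)(=O)([#6])[#6]",
    "sulfonyl": "[SX4](=O)(=O)",
    "primary_amine": "[NX3;H2;!$(NC=O);!$(N=*)]",
    "secondary_amine": "[NX3;H1;!$(NC=O);!$(N=*)]([#6])[#6]",
    "tertiary_amine": "[NX3;H0;!$(NC=O);!$(N=*);!$(N#*)]([#6])([#6])[#6]",
    "ether": "[OD2]([#6])[#6]",
    "alcohol": "[OX2H][CX4]",
    "phenol": "[OX2H][c]",
    "carbonyl": "[CX3]=[OX1]",
    "amide": "[NX3][CX3](=[OX1])",
    "halogen": "[F,Cl,Br,I]",
    "nitrile": "[NX1]#[CX2]",
    "aromatic_ring": "a1aaaaa1",
}


def functional_group_profile(
    molecules: Sequence[Chem.Mol],
    group_library: Mapping[str, str] | None = None,
    labels: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Count molecules (and the positive subset) matching each named group."""
    library = dict(group_library) if group_library is not None else DEFAULT_FUNCTIONAL_GROUPS
    if not library:
        raise ValueError("functional group library is empty")
    queries = {}
    for name, smarts in library.items():
        q = Chem.MolFromSmarts(smarts)
        if q is None:
            raise ValueError(f"invalid SMARTS for group {name!r}: {smarts!r}")
        queries[name] = q
    y = np.asarray(labels, dtype=int) if labels is not None else None
    rows = []
    for name, q in queries.items():
        hits = np.array([m.HasSubstructMatch(q) for m in molecules], dtype=bool)
        rows.append(
            {
                "group": name,
                "n_total": int(hits.sum()),
                "n_positive": int(y[hits].sum()) if y is not None else -1,
            }
        )
    return pd.DataFrame(rows)


def stats_to_csv(stats: Sequence[FeatureStats], fragments: Sequence[Fragment], path) -> None:
    by_id = {f.fragment_id: f for f in fragments}
    pd.DataFrame(
        {
            "fragment_id": [s.fragment_id for s in stats],
            "kind": [by_id[s.fragment_id].kind for s in stats],
            "n_atoms": [by_id[s.fragment_id].n_atoms for s in stats],
            "frequency": [s.frequency for s in stats],
            "n_positive": [s.n_positive for s in stats],
            "mean_activity": [s.mean_activity for s in stats],
            "z_raw": [s.z_raw for s in stats],
            "z_std": [s.z_std for s in stats],
        }
    ).to_csv(path, index=False)
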