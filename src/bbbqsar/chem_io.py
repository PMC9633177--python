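"""Structure file I/O and training-set curation.

Structures enter as SDF V2000 or SMILES+CSV.  Curation mirrors the usual
QSAR-modelling hygiene for organic small molecules: simple salts are reduced
to the neutralised free form of the parent, while inorganics, noble gases,
mixtures, single atoms, metal-containing compounds and very large molecules
(MW >= 1800: polysaccharides, proteins, polymers) are excluded.

Exclusion reasons are deterministic because the rules are applied in a fixed
order: parse_error > mixture > metal/inorganic > noble_gas > single_atom >
high_mw.  The inorganic-element rule deliberately does not fire on noble
gases so that a bare noble-gas atom reports the more specific reason.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: element alphabet assumed by organic fragment descriptors
ORGANIC_ELEMENTS = frozenset({"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"})
NOBLE_GASES = frozenset({"He", "Ne", "Ar", "Kr", "Xe", "Rn"})

#: counter-ions recognised when reducing a salt to its parent (canonical SMILES)
DEFAULT_COUNTER_IONS = (
    "[Na+]", "[K+]", "[Li+]", "[Ca+2]", "[Mg+2]", "[NH4+]",
    "[Cl-]", "[Br-]", "[I-]", "[F-]", "[OH-]", "O",
    "[O-]S([O-])(=O)=O", "OS([O-])(=O)=O", "CS([O-])(=O)=O",
    "Cc1ccc(S([O-])(=O)=O)cc1", "[O-][N+]([O-])=O", "[O-]P([O-])([O-])=O",
    "CC(=O)[O-]", "CC(=O)O", "Cl", "Br", "O=S(O)O",
)


class Status(str, enum.Enum):
    KEPT = "kept"
    EXCLUDED = "excluded"
    ERROR = "error"


class Reason(str, enum.Enum):
    INORGANIC = "inorganic"
    NOBLE_GAS = "noble_gas"
    MIXTURE = "mixture"
    SINGLE_ATOM = "single_atom"
    METAL = "metal"
    HIGH_MW = "high_mw"
    PARSE_ERROR = "parse_error"
    NONE = "none"


class Transform(str, enum.Enum):
    NONE = "none"
    SALT_NEUTRALIZED = "salt_neutralized"


@dataclass(frozen=True)
class MoleculeRecord:
    """One curated chemical structure with provenance."""

    compound_id: str
    name: str = ""
    structure: str = ""  # canonical SMILES
    heavy_atom_count: int = 0
    mw: float = 0.0
    role: str = "unknown"
    species: str = "unknown"
    source_refs: tuple[str, ...] = ()
    properties: dict = field(default_factory=dict, compare=False)

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.structure)
        if mol is None:
            raise ValueError(f"structure of {self.compound_id!r} failed to parse")
        return mol


@dataclass(frozen=True)
class CurationResult:
    record: MoleculeRecord
    status: Status
    reason: Reason = Reason.NONE
    transform_applied: Transform = Transform.NONE

    def __post_init__(self) -> None:
        if self.status is Status.KEPT and self.reason is not Reason.NONE:
            raise ValueError("kept records must carry reason none")
        if self.status is Status.EXCLUDED and self.reason is Reason.NONE:
            raise ValueError("excluded records must carry a reason")


@dataclass(frozen=True)
class CurationRules:
    mw_cutoff: float = 1800.0  # strict >= excludes
    counter_ions: tuple[str, ...] = DEFAULT_COUNTER_IONS
    allowed_elements: frozenset[str] = ORGANIC_ELEMENTS

    def counter_ion_set(self) -> frozenset[str]:
        out = set()
        for smi in self.counter_ions:
            mol = Chem.MolFromSmiles(smi)
            if mol is not None:
                out.add(Chem.MolToSmiles(mol))
        return frozenset(out)


# ---------------------------------------------------------------------------
# reading


def read_structures(path, format: str) -> tuple[list[MoleculeRecord], list[CurationResult]]:
    """Read structures from ``path`` (``sdf`` or ``smiles_csv``).

    Returns (records, errors): every entry of the file appears in exactly one
    of the two lists; unparseable entries become error-status curation results
    rather than being silently dropped.  SDF data fields LOGBB, SPECIES and
    ROLE (and CSV columns logbb, species) are captured into
    ``MoleculeRecord.properties``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "sdf":
        return _read_sdf(path)
    if format == "smiles_csv":
        return _read_smiles_csv(path)
    raise ValueError(f"unknown structure format {format!r}")


def _error_result(compound_id: str, name: str = "") -> CurationResult:
    return CurationResult(
        record=MoleculeRecord(compound_id=compound_id, name=name),
        status=Status.ERROR,
        reason=Reason.PARSE_ERROR,
    )


def _read_sdf(path: Path) -> tuple[list[MoleculeRecord], list[CurationResult]]:
    records: list[MoleculeRecord] = []
    errors: list[CurationResult] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    if len(supplier) == 0:
        raise ValueError(f"{path} contains no SDF records")
    for i, mol in enumerate(supplier):
        if mol is None:
            errors.append(_error_result(f"entry_{i}"))
            continue
        props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        compound_id = props.get("COMPOUND_ID", name or f"entry_{i}")
        extracted = {}
        if "LOGBB" in props:
            extracted["logbb"] = float(props["LOGBB"])
        if "LABEL" in props:
            extracted["label"] = int(props["LABEL"])
        records.append(
            MoleculeRecord(
                compound_id=str(compound_id),
                name=name,
                structure=Chem.MolToSmiles(mol),
                heavy_atom_count=mol.GetNumHeavyAtoms(),
                mw=Descriptors.MolWt(mol),
                role=props.get("ROLE", "unknown"),
                species=props.get("SPECIES", "unknown"),
                source_refs=tuple(filter(None, [props.get("REF", "")])),
                properties=extracted,
            )
        )
    return records, errors


def _read_smiles_csv(path: Path) -> tuple[list[MoleculeRecord], list[CurationResult]]:
    df = pd.read_csv(path, dtype={"compound_id": str})
    if df.empty:
        raise ValueError(f"{path} contains no rows")
    records: list[MoleculeRecord] = []
    errors: list[CurationResult] = []
    for i, row in df.iterrows():
        compound_id = str(row.get("compound_id", f"entry_{i}"))
        mol = Chem.MolFromSmiles(str(row["smiles"]))
        if mol is None:
            errors.append(_error_result(compound_id))
            continue
        extracted = {}
        if "logbb" in df.columns and pd.notna(row["logbb"]):
            extracted["logbb"] = float(row["logbb"])
        records.append(
            MoleculeRecord(
                compound_id=compound_id,
                structure=Chem.MolToSmiles(mol),
                heavy_atom_count=mol.GetNumHeavyAtoms(),
                mw=Descriptors.MolWt(mol),
                species=str(row["species"]) if "species" in df.columns and pd.notna(row.get("species")) else "unknown",
                properties=extracted,
            )
        )
    return records, errors


# ---------------------------------------------------------------------------
# curation


_UNCHARGER = rdMolStandardize.Uncharger()


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    return _UNCHARGER.uncharge(mol)


def curate(record: MoleculeRecord, rules: CurationRules | None = None) -> CurationResult:
    """Apply the exclusion/neutralisation rules to one parsed record.

    Order: parse -> salt/mixture resolution -> element check -> size checks.
    All outcomes are CurationResults; nothing raises on chemistry grounds.
    """
    rules = rules or CurationRules()
    mol = Chem.MolFromSmiles(record.structure)
    if mol is None:
        return CurationResult(record=record, status=Status.ERROR, reason=Reason.PARSE_ERROR)

    transform = Transform.NONE
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        parent = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), m.GetNumAtoms()))
        counter_set = rules.counter_ion_set()
        others = [f for f in frags if f is not parent]
        best = max(f.GetNumHeavyAtoms() for f in frags)
        n_best = sum(1 for f in frags if f.GetNumHeavyAtoms() == best)
        if n_best > 1 or any(Chem.MolToSmiles(f) not in counter_set for f in others):
            return CurationResult(record=record, status=Status.EXCLUDED, reason=Reason.MIXTURE)
        mol = parent
        transform = Transform.SALT_NEUTRALIZED

    # a bare single atom (no hydrogens) carries no modellable structure;
    # decided before neutralization, which may add hydrogens to bare ions
    bare_single_atom = mol.GetNumHeavyAtoms() == 1 and Chem.AddHs(mol).GetNumAtoms() == 1

    before = Chem.MolToSmiles(mol)
    mol = _neutralize(mol)
    after = Chem.MolToSmiles(mol)
    if after != before:
        transform = Transform.SALT_NEUTRALIZED

    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    if symbols - rules.allowed_elements - NOBLE_GASES:
        return CurationResult(
            record=record, status=Status.EXCLUDED, reason=Reason.METAL,
            transform_applied=transform,
        )
    if symbols & NOBLE_GASES:
        return CurationResult(
            record=record, status=Status.EXCLUDED, reason=Reason.NOBLE_GAS,
            transform_applied=transform,
        )
    if bare_single_atom:
        return CurationResult(
            record=record, status=Status.EXCLUDED, reason=Reason.SINGLE_ATOM,
            transform_applied=transform,
        )
    mw = Descriptors.MolWt(mol)
    if mw >= rules.mw_cutoff:
        return CurationResult(
            record=record, status=Status.EXCLUDED, reason=Reason.HIGH_MW,
            transform_applied=transform,
        )

    curated = replace(
        record,
        structure=after,
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        mw=mw,
    )
    return CurationResult(record=curated, status=Status.KEPT, transform_applied=transform)


def curate_all(
    records: Sequence[MoleculeRecord],
    rules: CurationRules | None = None,
    errors: Sequence[CurationResult] = (),
) -> list[CurationResult]:
    """Curate every record; read errors are passed through so the output
    partitions the input (kept + excluded + error counts sum to input count)."""
    return list(errors) + [curate(r, rules) for r in records]


def merge_duplicates(
    records: Sequence[MoleculeRecord],
) -> tuple[list[MoleculeRecord], list[tuple[str, str]]]:
    """Merge records sharing a canonical structure; returns (unique, collisions).

    The first record for each structure is kept; each later duplicate is
    reported as (kept_id, duplicate_id) so conflicting annotations can be
    reviewed instead of silently overwritten.
    """
    seen: dict[str, MoleculeRecord] = {}
    collisions: list[tuple[str, str]] = []
    for r in records:
        if r.structure in seen:
            collisions.append((seen[r.structure].compound_id, r.compound_id))
        else:
            seen[r.structure] = r
    return list(seen.values()), collisions


# ---------------------------------------------------------------------------
# writing


def write_sdf(records: Iterable[MoleculeRecord], path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for r in records:
            mol = r.to_mol()
            mol.SetProp("_Name", r.name or r.compound_id)
            mol.SetProp("COMPOUND_ID", r.compound_id)
            if "logbb" in r.properties:
                mol.SetProp("LOGBB", repr(float(r.properties["logbb"])))
            if "label" in r.properties:
                mol.SetProp("LABEL", str(int(r.properties["label"])))
            if r.species != "unknown":
                mol.SetProp("SPECIES", r.species)
            if r.role != "unknown":
                mol.SetProp("ROLE", r.role)
            writer.write(mol)
    finally:
        writer.close()


def write_curation_report(results: Sequence[CurationResult], path) -> None:
    pd.DataFrame(
        {
            "compound_id": [r.record.compound_id for r in results],
            "status": [r.status.value for r in results],
            "reason": [r.reason.value for r in results],
            "transform": [r.transform_applied.value for r in results],
        }
    ).to_csv(path, index=False)
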