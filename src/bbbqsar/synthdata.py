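"""Synthetic structure-activity data with planted ground truth.

Molecules are assembled from a small grammar (~15 ring cores, ~19
substituents) by seeded draws, then scored through a latent logit:

    latent = base_rate_logit + sum(planted fragment effects)
             + lipophilicity_coeff * z(AlogP) + Normal(0, noise_sd)

    log BB = -1 + 0.5 * latent        label = 1  iff  log BB >= -1

so the emitted log BB values are consistent with the activity-scoring rule by
construction and the Gaussian term provides label noise near the boundary.
The planted effects emulate the enrichment patterns seen in rodent log BB
data: fused bicyclic aromatics and cyclic amines push compounds across the
barrier, carboxylic acids and sulfonamides keep them out, and a
lipophilicity covariate (the computed AlogP of the assembled structure)
carries the remaining graded signal.

Each planted effect is *defined* by the presence of a canonical fragment
label from the features module, so recovery tests can close the loop: the
generator's truth labels are exactly what fragment enumeration finds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .chem_io import MoleculeRecord
from .features import molecule_path_labels

# Grammar: ring cores and substituents (attachment atom first in each SMILES)
CORE_SMILES = (
    "c1ccccc1",            # benzene
    "c1ccc2ccccc2c1",      # naphthalene (fused bicyclic aromatic)
    "c1ccc2[nH]ccc2c1",    # indole
    "c1ccc2ncccc2c1",      # quinoline
    "c1ccncc1",            # pyridine
    "c1ccsc1",             # thiophene
    "c1ccoc1",             # furan
    "c1ccc2occc2c1",       # benzofuran
    "C1CCCCC1",            # cyclohexane
    "C1CCCC1",             # cyclopentane
    "C1CCOC1",             # tetrahydrofuran
    "C1CCc2ccccc2C1",      # tetralin
    "C1CCNCC1",            # piperidine (cyclic amine)
    "CN1CCCCC1",           # 1-methylpiperidine (cyclic amine)
    "C1COCCN1",            # morpholine (cyclic amine)
)

SUBSTITUENT_SMILES = (
    "C",            # methyl
    "CC",           # ethyl
    "C(C)C",        # isopropyl
    "O",            # hydroxyl
    "OC",           # methoxy
    "CO",           # hydroxymethyl
    "F",
    "Cl",
    "Br",
    "C(F)(F)F",     # trifluoromethyl
    "N",            # primary amine
    "N(C)C",        # dimethylamino
    "C#N",          # nitrile
    "C(C)=O",       # acetyl
    "C(N)=O",       # carboxamide
    "NC(C)=O",      # acetamido
    "C(=O)O",       # carboxylic acid
    "S(N)(=O)=O",   # sulfonamide
    "S(C)(=O)=O",   # methylsulfonyl
    "c1ccccc1",     # phenyl
)

# z-scaling constants for the AlogP covariate, fixed for this grammar
LIPO_CENTER = 2.0
LIPO_SCALE = 1.5
LOGBB_SCALE = 0.5


@dataclass(frozen=True)
class PlantedFragment:
    name: str
    effect: float
    canonical_label: str
    kind: str  # linear_path | ring_system


def _naphthalene_label() -> str:
    return Chem.MolToSmiles(Chem.MolFromSmiles("c1ccc2ccccc2c1"))


def _known_detectors() -> dict[str, tuple[str, str]]:
    """name -> (canonical fragment label, kind) for plantable effects."""
    return {
        "fused_bicyclic_aromatic": (_naphthalene_label(), "ring_system"),
        "cyclic_amine": ("CR-NR", "linear_path"),
        "carboxylic_acid": ("O-C=O", "linear_path"),
        "sulfonamide": ("N-S", "linear_path"),
    }


DEFAULT_FRAGMENT_EFFECTS = {
    "fused_bicyclic_aromatic": 2.0,
    "cyclic_amine": 1.5,
    "carboxylic_acid": -2.5,
    "sulfonamide": -1.5,
}


@dataclass(frozen=True)
class SynthConfig:
    n_compounds: int = 800
    base_rate_logit: float = 0.0
    fragment_effects: dict = field(default_factory=lambda: dict(DEFAULT_FRAGMENT_EFFECTS))
    lipophilicity_coeff: float = 0.5
    noise_sd: float = 0.5
    max_substituents: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.fragment_effects) - set(_known_detectors())
        if unknown:
            raise ValueError(f"no grammar detector for planted fragment(s) {sorted(unknown)}")


@dataclass(frozen=True)
class SynthRecord:
    compound_id: str
    structure: str
    latent_score: float
    logbb: float
    label: int
    planted_fragments: tuple[str, ...]


def planted_truth(config: SynthConfig) -> dict[str, PlantedFragment]:
    """Machine-readable ground truth of the planted structure-activity map."""
    detectors = _known_detectors()
    return {
        name: PlantedFragment(
            name=name, effect=eff, canonical_label=detectors[name][0], kind=detectors[name][1]
        )
        for name, eff in config.fragment_effects.items()
    }


def _attach(core: Chem.Mol, n_core_atoms: int, sub_smiles: str, rng: np.random.Generator) -> Chem.Mol | None:
    """Attach a substituent to a random core carbon bearing a hydrogen."""
    candidates = [
        a.GetIdx()
        for a in core.GetAtoms()
        if a.GetIdx() < n_core_atoms and a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]
    if not candidates:
        return None
    site = int(rng.choice(candidates))
    sub = Chem.MolFromSmiles(sub_smiles)
    combined = Chem.RWMol(Chem.CombineMols(core, sub))
    combined.AddBond(site, core.GetNumAtoms(), Chem.BondType.SINGLE)
    mol = combined.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _assemble(rng: np.random.Generator, max_substituents: int) -> Chem.Mol:
    core = Chem.MolFromSmiles(str(rng.choice(CORE_SMILES)))
    n_core = core.GetNumAtoms()
    mol = core
    for _ in range(int(rng.integers(0, max_substituents + 1))):
        attached = _attach(mol, n_core, str(rng.choice(SUBSTITUENT_SMILES)), rng)
        if attached is not None:
            mol = attached
    return mol


_NAPHTHALENE_QUERY = None


def _planted_in(mol: Chem.Mol, truth: dict[str, PlantedFragment]) -> tuple[str, ...]:
    global _NAPHTHALENE_QUERY
    labels = molecule_path_labels(mol, 2, 3)
    present = []
    for name, frag in truth.items():
        if frag.kind == "linear_path":
            hit = frag.canonical_label in labels
        else:
            if _NAPHTHALENE_QUERY is None:
                _NAPHTHALENE_QUERY = Chem.MolFromSmiles(frag.canonical_label)
            hit = mol.HasSubstructMatch(_NAPHTHALENE_QUERY)
        if hit:
            present.append(name)
    return tuple(sorted(present))


def generate_dataset(config: SynthConfig | None = None) -> list[SynthRecord]:
    """Generate a seeded synthetic log BB dataset with known fragment truth."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    truth = planted_truth(config)
    records = []
    for i in range(config.n_compounds):
        mol = _assemble(rng, config.max_substituents)
        present = _planted_in(mol, truth)
        lipo_z = (Crippen.MolLogP(mol) - LIPO_CENTER) / LIPO_SCALE
        latent = (
            config.base_rate_logit
            + sum(truth[name].effect for name in present)
            + config.lipophilicity_coeff * lipo_z
            + rng.normal(0.0, config.noise_sd)
        )
        logbb = -1.0 + LOGBB_SCALE * latent
        records.append(
            SynthRecord(
                compound_id=f"synth_{i:05d}",
                structure=Chem.MolToSmiles(mol),
                latent_score=float(latent),
                logbb=float(logbb),
                label=int(logbb >= -1.0),
                planted_fragments=present,
            )
        )
    return records


def to_molecule_records(records: Sequence[SynthRecord]) -> list[MoleculeRecord]:
    out = []
    for r in records:
        mol = Chem.MolFromSmiles(r.structure)
        out.append(
            MoleculeRecord(
                compound_id=r.compound_id,
                structure=r.structure,
                heavy_atom_count=mol.GetNumHeavyAtoms(),
                mw=Descriptors.MolWt(mol),
                properties={"logbb": r.logbb, "label": r.label},
            )
        )
    return out


def truth_to_json(config: SynthConfig, path) -> None:
    truth = planted_truth(config)
    with open(path, "w") as fh:
        json.dump(
            {
                name: {"effect": f.effect, "canonical_label": f.canonical_label, "kind": f.kind}
                for name, f in truth.items()
            },
            fh,
            indent=2,
        )
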