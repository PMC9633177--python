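"""Physicochemical descriptors and their correlation with log BB.

Eight whole-molecule properties: molecular weight, rotatable bond count,
hydrogen-bond donor and acceptor counts, Lipinski rule-of-five violation
count, AlogP (Crippen atomic-contribution octanol/water partition
coefficient), topological polar surface area (Ertl fragment contributions)
and heavy atom count.  Donors are counted as O-H/N-H hydrogens and acceptors
as N/O atoms, the conventions the rule of five was stated in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

DESCRIPTOR_NAMES = (
    "mw",
    "n_rotatable_bonds",
    "n_hbd",
    "n_hba",
    "lipinski_violations",
    "alogp",
    "psa",
    "heavy_atom_count",
)


@dataclass(frozen=True)
class DescriptorVector:
    mw: float
    n_rotatable_bonds: int
    n_hbd: int
    n_hba: int
    lipinski_violations: int
    alogp: float
    psa: float
    heavy_atom_count: int

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in DESCRIPTOR_NAMES], dtype=float)


def compute_descriptors(mol: Chem.Mol) -> DescriptorVector:
    """Descriptor vector of one curated, single-fragment molecule."""
    if mol is None:
        raise ValueError("molecule failed to parse")
    mw = Descriptors.MolWt(mol)
    hbd = Lipinski.NHOHCount(mol)
    hba = Lipinski.NOCount(mol)
    alogp = Crippen.MolLogP(mol)
    violations = sum([mw > 500.0, alogp > 5.0, hbd > 5, hba > 10])
    return DescriptorVector(
        mw=mw,
        n_rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        n_hbd=hbd,
        n_hba=hba,
        lipinski_violations=violations,
        alogp=alogp,
        psa=rdMolDescriptors.CalcTPSA(mol),
        heavy_atom_count=mol.GetNumHeavyAtoms(),
    )


def descriptor_table(molecules: Sequence[Chem.Mol], compound_ids: Sequence[str] | None = None) -> pd.DataFrame:
    rows = [compute_descriptors(m).to_array() for m in molecules]
    df = pd.DataFrame(rows, columns=list(DESCRIPTOR_NAMES))
    df.insert(0, "compound_id", list(compound_ids) if compound_ids is not None else range(len(molecules)))
    return df


def descriptor_matrix(molecules: Sequence[Chem.Mol]) -> np.ndarray:
    return np.array([compute_descriptors(m).to_array() for m in molecules], dtype=float)


@dataclass(frozen=True)
class DescriptorScaler:
    """Training-set z-scaling, stored with any model that consumes descriptors."""

    mean: tuple[float, ...]
    sd: tuple[float, ...]

    @classmethod
    def fit(cls, X: np.ndarray) -> "DescriptorScaler":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)  # constant columns pass through centred
        return cls(mean=tuple(map(float, mean)), sd=tuple(map(float, sd)))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - np.array(self.mean)) / np.array(self.sd)


def descriptor_activity_r2(
    descriptor_values: Sequence[float], logbb_values: Sequence[float]
) -> tuple[float, bool]:
    """Squared Pearson correlation between one descriptor and log BB.

    Returns (r_squared, degenerate).  A zero-variance input yields
    (0.0, True) rather than an undefined correlation.
    """
    x = np.asarray(descriptor_values, dtype=float)
    y = np.asarray(logbb_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("descriptor and log BB lists must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if x.std() == 0 or y.std() == 0:
        return 0.0, True
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r), False


def r2_report(
    molecules: Sequence[Chem.Mol], logbb_values: Sequence[float]
) -> pd.DataFrame:
    """Per-descriptor R^2 against log BB (degenerate descriptors flagged)."""
    X = descriptor_matrix(molecules)
    rows = []
    for j, name in enumerate(DESCRIPTOR_NAMES):
        r2, flag = descriptor_activity_r2(X[:, j], logbb_values)
        rows.append({"descriptor": name, "r_squared": r2, "degenerate": flag})
    return pd.DataFrame(rows)
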