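"""Two binary QSAR classifier styles for log BB permeability.

LS-style
    Retained structural features plus eight z-scaled physicochemical
    descriptors enter a partial-least-squares regression against the binary
    activity; the PLS score is mapped to a probability by a one-dimensional
    logistic calibration (plain penalized logistic regression is available as
    a config alternative).  Probabilities in (0.4, 0.6) are equivocal.  A test
    compound is out of domain when it matches no model feature or when its
    maximum Tanimoto similarity to any training compound, computed on the
    model's own feature fingerprints, is below 0.30.

CU-style
    Structural alerts (fragments enriched in permeable compounds) and
    deactivating features (fragments that lower the positive rate among
    alert-carrying compounds) enter one global logistic regression with
    signed weights; no hyper-parameter optimization is performed.  The
    classification threshold is chosen on the ROC curve to balance
    sensitivity and specificity (0.55 on the original data); scores within
    +/-0.1 of the threshold are equivocal.  A test compound is out of domain
    when it contains a three-atom linear fragment never seen in training and
    its score is not strong enough for a positive call.
"""

from __future__ import annotations

import base64
import enum
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LogisticRegression

from .descriptors import DescriptorScaler, compute_descriptors
from .features import (
    FeatureMatrix,
    Fragment,
    ScaffoldConfig,
    build_feature_matrix,
    enumerate_linear_fragments,
    enumerate_scaffolds,
    feature_statistics,
    molecule_feature_bits,
    molecule_path_labels,
    prune_features,
    ring_systems,
    PruneConfig,
)

MODEL_SCHEMA_VERSION = 1


class CallValue(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    EQUIVOCAL = "equivocal"
    OUT_OF_DOMAIN = "out_of_domain"


@dataclass(frozen=True)
class Call:
    value: CallValue
    probability: float | None
    reason: str = ""

    def __post_init__(self) -> None:
        if (self.value is CallValue.OUT_OF_DOMAIN) != (self.probability is None):
            raise ValueError("probability must be absent exactly when out of domain")


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def classify(probability: float, pos_cutoff: float, neg_cutoff: float) -> CallValue:
    """Three-way call from a probability; cutoff boundaries are equivocal."""
    if not (0.0 <= probability <= 1.0):
        raise ValueError(f"probability must be in [0,1], got {probability!r}")
    if not (0.0 <= neg_cutoff < pos_cutoff <= 1.0):
        raise ValueError("cutoffs must satisfy 0 <= neg < pos <= 1")
    if probability > pos_cutoff:
        return CallValue.POSITIVE
    if probability < neg_cutoff:
        return CallValue.NEGATIVE
    return CallValue.EQUIVOCAL


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |A & B| / |A | B| between binary fingerprints."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def select_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC-balanced classification threshold.

    Candidates are midpoints between adjacent sorted unique scores; the one
    minimizing |sensitivity - specificity| wins (ties: higher Youden J, then
    closer to 0.5).  Calls at a candidate t are positive iff score > t.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes required to place a threshold")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("all scores identical; no threshold separates anything")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for t in candidates:
        pred = s > t
        sens = float(pred[y == 1].mean())
        spec = float((~pred[y == 0]).mean())
        key = (abs(sens - spec), -(sens + spec - 1.0), abs(t - 0.5))
        if best is None or key < best[0]:
            best = (key, float(t))
    assert best is not None
    return best[1]


# ---------------------------------------------------------------------------
# LS-style model


@dataclass(frozen=True)
class LSConfig:
    n_components: int = 5
    method: str = "pls"  # pls | logistic
    pos_cutoff: float = 0.6
    neg_cutoff: float = 0.4
    similarity_threshold: float = 0.30
    seed: int = 0


@dataclass
class LSModel:
    fragments: list[Fragment]
    feature_weights: np.ndarray
    descriptor_weights: np.ndarray
    intercept: float
    descriptor_scaler: DescriptorScaler
    training_fingerprints: np.ndarray  # bool, n_train x n_features
    pos_cutoff: float = 0.6
    neg_cutoff: float = 0.4
    similarity_threshold: float = 0.30
    config: LSConfig = field(default_factory=LSConfig)

    @property
    def feature_ids(self) -> list[str]:
        return [f.fragment_id for f in self.fragments]

    def probability(self, feature_bits: np.ndarray, descriptors: np.ndarray) -> float:
        d = self.descriptor_scaler.transform(np.atleast_2d(descriptors))[0]
        z = float(
            feature_bits.astype(float) @ self.feature_weights
            + d @ self.descriptor_weights
            + self.intercept
        )
        return float(_sigmoid(z))


def _check_fit_inputs(n: int, labels: np.ndarray) -> None:
    if n < 20:
        raise ValueError(f"need at least 20 training compounds, got {n}")
    if len(set(labels.tolist())) < 2:
        raise ValueError("training labels contain a single class")


def _fit_linear_probability(
    X: np.ndarray, y: np.ndarray, config: LSConfig
) -> tuple[np.ndarray, float]:
    """Linear weights + intercept such that sigmoid(X@w + c) estimates P(pos)."""
    if config.method == "logistic":
        lr = LogisticRegression(C=1.0, max_iter=5000, random_state=config.seed)
        lr.fit(X, y)
        return lr.coef_[0].copy(), float(lr.intercept_[0])
    if config.method != "pls":
        raise ValueError(f"unknown LS fitting method {config.method!r}")
    n_comp = max(1, min(config.n_components, X.shape[1], X.shape[0] - 1))
    pls = PLSRegression(n_components=n_comp, scale=True)
    pls.fit(X, y.astype(float))
    raw = pls.predict(X).ravel()
    calib = LogisticRegression(C=10.0, max_iter=5000, random_state=config.seed)
    calib.fit(raw.reshape(-1, 1), y)
    a = float(calib.coef_[0, 0])
    b = float(calib.intercept_[0])
    # the PLS prediction is linear in X with slope coef_; recover its constant
    # term from the fitted values rather than trusting centering conventions
    slope = pls.coef_[0]
    const = float(np.mean(raw - X @ slope))
    w = a * slope
    c = a * const + b
    return w, c


def fit_ls_style(
    matrix: FeatureMatrix,
    descriptors: np.ndarray,
    labels: Sequence[int],
    config: LSConfig | None = None,
) -> LSModel:
    """Fit the LS-style classifier on a pruned feature matrix + descriptors."""
    config = config or LSConfig()
    y = np.asarray(labels, dtype=int)
    _check_fit_inputs(matrix.values.shape[0], y)
    if matrix.values.shape[1] == 0:
        raise ValueError("empty feature set")
    scaler = DescriptorScaler.fit(np.asarray(descriptors, dtype=float))
    D = scaler.transform(descriptors)
    X = np.hstack([matrix.values.astype(float), D])
    w, c = _fit_linear_probability(X, y, config)
    m = matrix.values.shape[1]
    return LSModel(
        fragments=list(matrix.fragments),
        feature_weights=w[:m],
        descriptor_weights=w[m:],
        intercept=c,
        descriptor_scaler=scaler,
        training_fingerprints=matrix.values.copy(),
        pos_cutoff=config.pos_cutoff,
        neg_cutoff=config.neg_cutoff,
        similarity_threshold=config.similarity_threshold,
        config=config,
    )


def prepare_ls_features(
    molecules: Sequence[Chem.Mol],
    labels: Sequence[int],
    path_min: int = 2,
    path_max: int = 7,
    scaffold_config: ScaffoldConfig | None = None,
    prune_config: PruneConfig | None = None,
    compound_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Mine and prune the LS feature vocabulary from training molecules.

    Candidates are all linear-path fragments plus the scaffolds passing the
    frequency/size/Z constraints; the pruned occurrence matrix is what
    ``fit_ls_style`` consumes.
    """
    y = np.asarray(labels, dtype=int)
    candidates: dict[str, Fragment] = {}
    for mol in molecules:
        for frag in enumerate_linear_fragments(mol, path_min, path_max):
            candidates.setdefault(frag.fragment_id, frag)
    for frag in enumerate_scaffolds(molecules, y, scaffold_config):
        candidates.setdefault(frag.fragment_id, frag)
    matrix = build_feature_matrix(molecules, candidates.values(), compound_ids=compound_ids)
    stats = feature_statistics(matrix, y)
    retained = prune_features(stats, matrix, prune_config)
    return matrix.subset(retained)


def applicability_domain_ls(model: LSModel, mol: Chem.Mol) -> tuple[bool, str]:
    """(in_domain, reason) for the LS feature/similarity domain rule."""
    bits = molecule_feature_bits(mol, model.fragments)
    if bits.sum() == 0:
        return False, "no model features matched"
    sims = [tanimoto(bits, fp) for fp in model.training_fingerprints]
    best = max(sims) if sims else 0.0
    if best < model.similarity_threshold:
        return False, f"max training-set Tanimoto {best:.3f} < {model.similarity_threshold:.2f}"
    return True, f"max training-set Tanimoto {best:.3f}"


# ---------------------------------------------------------------------------
# CU-style model


@dataclass(frozen=True)
class CUConfig:
    min_atoms: int = 2
    max_atoms: int = 7
    min_count: int = 4
    alert_z: float = 2.0
    deactivation_drop: float = 0.2
    corr_cutoff: float = 0.95
    equivocal_halfwidth: float = 0.1
    threshold: float | None = None  # None: choose on the training ROC curve
    seed: int = 0


@dataclass
class CUModel:
    fragments: list[Fragment]  # alerts then deactivators
    weights: np.ndarray
    intercept: float
    alert_ids: list[str]
    deactivator_ids: list[str]
    threshold: float
    equivocal_halfwidth: float
    known_triplets: frozenset[str]
    config: CUConfig = field(default_factory=CUConfig)

    @property
    def pos_cutoff(self) -> float:
        return self.threshold + self.equivocal_halfwidth

    @property
    def neg_cutoff(self) -> float:
        return self.threshold - self.equivocal_halfwidth

    def probability(self, feature_bits: np.ndarray) -> float:
        return float(_sigmoid(float(feature_bits.astype(float) @ self.weights + self.intercept)))


def cu_fragment_set(mol: Chem.Mol, config: CUConfig | None = None) -> set[Fragment]:
    """Fragments the CU style mines from one molecule: linear paths + rings."""
    config = config or CUConfig()
    frags = set(enumerate_linear_fragments(mol, config.min_atoms, config.max_atoms))
    frags.update(ring_systems(mol))
    return frags


def fit_cu_style(
    molecules: Sequence[Chem.Mol],
    labels: Sequence[int],
    config: CUConfig | None = None,
) -> CUModel:
    """Mine alerts/deactivators and fit the global logistic model."""
    config = config or CUConfig()
    y = np.asarray(labels, dtype=int)
    _check_fit_inputs(len(molecules), y)

    candidates: dict[str, Fragment] = {}
    for mol in molecules:
        for frag in cu_fragment_set(mol, config):
            candidates.setdefault(frag.fragment_id, frag)
    matrix = build_feature_matrix(molecules, candidates.values())
    freq = matrix.values.sum(axis=0)
    common = [f.fragment_id for f, n in zip(matrix.fragments, freq) if n >= config.min_count]
    if not common:
        raise ValueError("no fragment reaches min_count; lower it or add data")
    matrix = matrix.subset(common)
    stats = feature_statistics(matrix, y)
    retained = prune_features(
        stats,
        matrix,
        PruneConfig(min_count=config.min_count, min_abs_z=0.0, corr_cutoff=config.corr_cutoff),
    )
    stats_by_id = {s.fragment_id: s for s in stats}
    alert_ids = sorted(
        (fid for fid in retained if stats_by_id[fid].z_std >= config.alert_z),
        key=lambda fid: (-stats_by_id[fid].z_std, fid),
    )
    if not alert_ids:
        raise ValueError("no structural alerts found; lower alert_z or min_count")

    cols = {f.fragment_id: matrix.values[:, j] for j, f in enumerate(matrix.fragments)}
    alert_mask = np.any(np.column_stack([cols[a] for a in alert_ids]), axis=1)
    deactivator_ids = []
    for fid in retained:
        if fid in alert_ids:
            continue
        d = cols[fid]
        with_d = alert_mask & d
        without_d = alert_mask & ~d
        if with_d.sum() < config.min_count or without_d.sum() == 0:
            continue
        drop = y[without_d].mean() - y[with_d].mean()
        if drop >= config.deactivation_drop:
            deactivator_ids.append(fid)
    deactivator_ids.sort()

    frag_by_id = {f.fragment_id: f for f in matrix.fragments}
    model_fragments = [frag_by_id[fid] for fid in alert_ids + deactivator_ids]
    X = matrix.subset([f.fragment_id for f in model_fragments])
    # keep column order aligned with model_fragments (subset sorts internally)
    order = {f.fragment_id: j for j, f in enumerate(X.fragments)}
    Xv = X.values[:, [order[f.fragment_id] for f in model_fragments]].astype(float)
    lr = LogisticRegression(C=1.0, max_iter=5000, random_state=config.seed)
    lr.fit(Xv, y)
    weights = lr.coef_[0].copy()
    intercept = float(lr.intercept_[0])

    scores = _sigmoid(Xv @ weights + intercept)
    threshold = (
        config.threshold if config.threshold is not None else select_threshold(scores, y)
    )

    known: set[str] = set()
    for mol in molecules:
        known.update(molecule_path_labels(mol, 3, 3))

    return CUModel(
        fragments=model_fragments,
        weights=weights,
        intercept=intercept,
        alert_ids=list(alert_ids),
        deactivator_ids=list(deactivator_ids),
        threshold=float(threshold),
        equivocal_halfwidth=config.equivocal_halfwidth,
        known_triplets=frozenset(known),
        config=config,
    )


def applicability_domain_cu(model: CUModel, mol: Chem.Mol) -> tuple[bool, str]:
    """(in_domain, reason) for the CU unknown-triplet domain rule.

    A compound carrying unknown three-atom fragments stays in domain only if
    its score is strong enough for a positive call on its own.
    """
    triplets = molecule_path_labels(mol, 3, 3)
    unknown = triplets - model.known_triplets
    if not unknown:
        return True, "all three-atom fragments known"
    bits = molecule_feature_bits(mol, model.fragments)
    p = model.probability(bits)
    if p > model.pos_cutoff:
        return True, f"{len(unknown)} unknown fragments but score {p:.3f} forces a positive call"
    return False, f"{len(unknown)} three-atom fragments not seen in training"


# ---------------------------------------------------------------------------
# prediction


def predict(model: LSModel | CUModel, mol: Chem.Mol, descriptors: np.ndarray | None = None) -> Call:
    """Domain-checked prediction for one molecule under either model style."""
    if mol is None:
        raise ValueError("molecule failed to parse")
    if isinstance(model, LSModel):
        ok, reason = applicability_domain_ls(model, mol)
        if not ok:
            return Call(value=CallValue.OUT_OF_DOMAIN, probability=None, reason=reason)
        if descriptors is None:
            descriptors = compute_descriptors(mol).to_array()
        bits = molecule_feature_bits(mol, model.fragments)
        p = model.probability(bits, descriptors)
        return Call(value=classify(p, model.pos_cutoff, model.neg_cutoff), probability=p, reason=reason)
    if isinstance(model, CUModel):
        ok, reason = applicability_domain_cu(model, mol)
        if not ok:
            return Call(value=CallValue.OUT_OF_DOMAIN, probability=None, reason=reason)
        bits = molecule_feature_bits(mol, model.fragments)
        p = model.probability(bits)
        return Call(value=classify(p, model.pos_cutoff, model.neg_cutoff), probability=p, reason=reason)
    raise TypeError(f"unknown model type {type(model).__name__}")


# ---------------------------------------------------------------------------
# serialization (single versioned JSON document per model)


def _fragments_to_json(fragments: Sequence[Fragment]) -> list[list]:
    return [[f.fragment_id, f.kind, f.n_atoms] for f in fragments]


def _fragments_from_json(data) -> list[Fragment]:
    return [Fragment(fragment_id=i, kind=k, n_atoms=n) for i, k, n in data]


def _bits_to_b64(bits: np.ndarray) -> dict:
    packed = np.packbits(bits.astype(np.uint8), axis=None)
    return {"shape": list(bits.shape), "data": base64.b64encode(packed.tobytes()).decode()}


def _bits_from_b64(obj) -> np.ndarray:
    shape = tuple(obj["shape"])
    packed = np.frombuffer(base64.b64decode(obj["data"]), dtype=np.uint8)
    flat = np.unpackbits(packed)[: int(np.prod(shape))]
    return flat.reshape(shape).astype(bool)


def model_to_json(model: LSModel | CUModel) -> str:
    if isinstance(model, LSModel):
        doc = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "style": "ls",
            "fragments": _fragments_to_json(model.fragments),
            "feature_weights": model.feature_weights.tolist(),
            "descriptor_weights": model.descriptor_weights.tolist(),
            "intercept": model.intercept,
            "scaler": {"mean": list(model.descriptor_scaler.mean), "sd": list(model.descriptor_scaler.sd)},
            "pos_cutoff": model.pos_cutoff,
            "neg_cutoff": model.neg_cutoff,
            "similarity_threshold": model.similarity_threshold,
            "training_fingerprints": _bits_to_b64(model.training_fingerprints),
        }
    elif isinstance(model, CUModel):
        doc = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "style": "cu",
            "fragments": _fragments_to_json(model.fragments),
            "weights": model.weights.tolist(),
            "intercept": model.intercept,
            "alert_ids": model.alert_ids,
            "deactivator_ids": model.deactivator_ids,
            "threshold": model.threshold,
            "equivocal_halfwidth": model.equivocal_halfwidth,
            "known_triplets": sorted(model.known_triplets),
        }
    else:
        raise TypeError(f"unknown model type {type(model).__name__}")
    return json.dumps(doc)


def model_from_json(text: str) -> LSModel | CUModel:
    doc = json.loads(text)
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {doc.get('schema_version')!r}")
    if doc["style"] == "ls":
        return LSModel(
            fragments=_fragments_from_json(doc["fragments"]),
            feature_weights=np.array(doc["feature_weights"], dtype=float),
            descriptor_weights=np.array(doc["descriptor_weights"], dtype=float),
            intercept=float(doc["intercept"]),
            descriptor_scaler=DescriptorScaler(
                mean=tuple(doc["scaler"]["mean"]), sd=tuple(doc["scaler"]["sd"])
            ),
            training_fingerprints=_bits_from_b64(doc["training_fingerprints"]),
            pos_cutoff=float(doc["pos_cutoff"]),
            neg_cutoff=float(doc["neg_cutoff"]),
            similarity_threshold=float(doc["similarity_threshold"]),
        )
    if doc["style"] == "cu":
        return CUModel(
            fragments=_fragments_from_json(doc["fragments"]),
            weights=np.array(doc["weights"], dtype=float),
            intercept=float(doc["intercept"]),
            alert_ids=list(doc["alert_ids"]),
            deactivator_ids=list(doc["deactivator_ids"]),
            threshold=float(doc["threshold"]),
            equivocal_halfwidth=float(doc["equivocal_halfwidth"]),
            known_triplets=frozenset(doc["known_triplets"]),
        )
    raise ValueError(f"unknown model style {doc['style']!r}")
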