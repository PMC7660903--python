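"""The 10-member cross-validation ensemble.

Ten networks are trained over sets 1D-10D, each fold using one set for
validation and the other nine for training; the TEST set never touches
training or standardization. The trained members double as the scoring
ensemble: at prediction time every member emits a softmax vector and
the per-class scores are summed downstream.

Each fold fits its own per-feature z-score standardizer on that fold's
training data — k-mer frequencies and the physicochemical extras live
on very different scales and the networks train poorly on raw values.
Class weights inversely proportional to class size compensate for the
heavy class imbalance typical of these corpora.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from phagenn.features import FeatureSchema, SideChainAlphabet, extract_matrix, get_schema
from phagenn.homology_split import SplitAssignment
from phagenn.network import MLPClassifier, NetworkConfig, Standardizer, TrainingLog
from phagenn.seqio import ClassList, ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "FoldModel",
    "EnsembleModel",
    "class_weights",
    "train_fold",
    "cross_validate",
    "predict_members",
    "save_bundle",
    "load_bundle",
]


def class_weights(counts: Sequence[int] | np.ndarray) -> np.ndarray:
    """Per-class weights inversely proportional to class size,
    normalized so equal-sized classes all get weight 1:

        w_c = N_total / (K * n_c)
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 1).any():
        raise ValueError("every class must have at least one training example")
    return counts.sum() / (len(counts) * counts)


@dataclass
class FoldModel:
    network: MLPClassifier
    standardizer: Standardizer
    fold_index: int
    training_log: TrainingLog
    validation_metrics: dict[str, float] = field(default_factory=dict)

    def predict_proba(self, X_raw: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(self.standardizer.transform(X_raw))


@dataclass
class EnsembleModel:
    members: list[FoldModel]
    schema: FeatureSchema
    classes: ClassList
    confidence: "object | None" = None  # ConfidenceTable, attached after calibration

    def __post_init__(self) -> None:
        widths = {m.network.config.n_features for m in self.members}
        if widths and widths != {self.schema.total_dim}:
            raise ValueError("member input width does not match schema")


def train_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: NetworkConfig,
    fold_index: int = 0,
) -> FoldModel:
    """Train one fold: fit the standardizer on the training matrix only,
    train with class-weighted cross-entropy, early-stop on training
    loss, and keep the epoch with minimum validation loss."""
    if X_train.shape[1] != config.n_features:
        raise ValueError(
            f"feature width {X_train.shape[1]} != config.n_features {config.n_features}"
        )
    std = Standardizer.fit(X_train)
    Xt = std.transform(X_train)
    Xv = std.transform(X_val)
    counts = np.bincount(y_train, minlength=config.n_classes)
    present = counts > 0
    weights = np.ones(config.n_classes)
    weights[present] = class_weights(counts[present])
    net = MLPClassifier(config)
    net.fit(Xt, y_train, Xv, y_val, class_weight=weights)
    fold = FoldModel(network=net, standardizer=std, fold_index=fold_index,
                     training_log=net.log)
    preds = net.predict_proba(Xv).argmax(axis=1)
    fold.validation_metrics = _basic_metrics(y_val, preds, config.n_classes)
    return fold


def _basic_metrics(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> dict[str, float]:
    from sklearn.metrics import precision_recall_fscore_support

    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=range(n_classes), average="weighted", zero_division=0
    )
    return {
        "accuracy": float((y_true == y_pred).mean()),
        "weighted_precision": float(prec),
        "weighted_recall": float(rec),
        "weighted_f1": float(f1),
    }


def cross_validate(
    split: SplitAssignment,
    records: Mapping[str, ProteinRecord],
    schema: FeatureSchema,
    classes: ClassList,
    config: NetworkConfig,
    features: Mapping[str, np.ndarray] | None = None,
) -> EnsembleModel:
    """Train the 10 members, fold i validating on set iD.

    ``features`` may carry pre-extracted vectors keyed by id (to avoid
    re-extracting across model types); otherwise vectors are extracted
    here. The TEST set is never touched.
    """
    fold_sets = split.config.set_names[:-1]
    missing = [s for s in fold_sets if not split.ids_in(s)]
    if missing:
        raise ValueError(f"split is missing / has empty sets: {missing}")

    ids_by_set = {s: sorted(split.ids_in(s)) for s in fold_sets}
    all_ids = [i for s in fold_sets for i in ids_by_set[s]]
    unlabeled = [i for i in all_ids if records[i].label is None]
    if unlabeled:
        raise ValueError(f"{len(unlabeled)} training records lack labels")

    if features is None:
        X_all = extract_matrix([records[i] for i in all_ids], schema)
        features = {i: X_all[j] for j, i in enumerate(all_ids)}
    y_of = {i: classes.index(records[i].label) for i in all_ids}

    master = np.random.default_rng(config.rng_seed)
    fold_seeds = master.integers(0, 2**31 - 1, size=len(fold_sets))

    members: list[FoldModel] = []
    for fi, val_set in enumerate(fold_sets, start=1):
        train_ids = [i for s in fold_sets if s != val_set for i in ids_by_set[s]]
        val_ids = ids_by_set[val_set]
        X_train = np.vstack([features[i] for i in train_ids])
        y_train = np.array([y_of[i] for i in train_ids])
        X_val = np.vstack([features[i] for i in val_ids])
        y_val = np.array([y_of[i] for i in val_ids])
        fold_cfg = NetworkConfig(
            n_features=schema.total_dim,
            n_classes=len(classes),
            hidden_width=config.hidden_width,
            n_hidden=config.n_hidden,
            dropout_p=config.dropout_p,
            learning_rate=config.learning_rate,
            patience_epochs=config.patience_epochs,
            max_epochs=config.max_epochs,
            batch_size=config.batch_size,
            rng_seed=int(fold_seeds[fi - 1]),
        )
        fold = train_fold(X_train, y_train, X_val, y_val, fold_cfg, fold_index=fi)
        logger.info("fold %d (%s): %s", fi, val_set, fold.validation_metrics)
        members.append(fold)

    return EnsembleModel(members=members, schema=schema, classes=classes)


def predict_members(ensemble: EnsembleModel, X_raw: np.ndarray) -> np.ndarray:
    """Per-member softmax outputs: array (n_members, n_sequences, n_classes)."""
    X_raw = np.atleast_2d(X_raw)
    if X_raw.shape[1] != ensemble.schema.total_dim:
        raise ValueError(
            f"feature width {X_raw.shape[1]} != schema dim {ensemble.schema.total_dim}"
        )
    return np.stack([m.predict_proba(X_raw) for m in ensemble.members])


# ----- persistence --------------------------------------------------------

def save_bundle(ensemble: EnsembleModel, directory: str | Path) -> None:
    """Persist a model bundle: manifest JSON, one .npz per member
    (weights + standardizer), training-log CSV, and the confidence
    table CSV when calibrated."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cfg0 = ensemble.members[0].network.config
    manifest = {
        "model_name": ensemble.schema.model_name,
        "side_chain_groups": dict(ensemble.schema.side_chain.groups),
        "side_chain_name": ensemble.schema.side_chain.name,
        "classes": list(ensemble.classes.names),
        "n_members": len(ensemble.members),
        "network": {
            "hidden_width": cfg0.hidden_width,
            "n_hidden": cfg0.n_hidden,
            "dropout_p": cfg0.dropout_p,
            "learning_rate": cfg0.learning_rate,
            "patience_epochs": cfg0.patience_epochs,
            "max_epochs": cfg0.max_epochs,
            "batch_size": cfg0.batch_size,
        },
        "member_seeds": [m.network.config.rng_seed for m in ensemble.members],
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for m in ensemble.members:
        arrays = dict(m.network.get_params())
        arrays["std_mean"] = m.standardizer.mean
        arrays["std_scale"] = m.standardizer.scale
        np.savez(d / f"member_{m.fold_index:02d}.npz", **arrays)
    with open(d / "training_logs.csv", "w") as fh:
        fh.write("fold,epoch,train_loss,val_loss\n")
        for m in ensemble.members:
            for e, (tl, vl) in enumerate(zip(m.training_log.train_loss, m.training_log.val_loss)):
                fh.write(f"{m.fold_index},{e},{tl:.6f},{vl:.6f}\n")
    if ensemble.confidence is not None:
        ensemble.confidence.to_csv(d / "confidence_table.csv")


def load_bundle(directory: str | Path) -> EnsembleModel:
    from phagenn.scoring import ConfidenceTable

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    side_chain = SideChainAlphabet(
        groups=manifest["side_chain_groups"], name=manifest["side_chain_name"]
    )
    schema = get_schema(manifest["model_name"], side_chain)
    classes = ClassList(tuple(manifest["classes"]))
    net_cfg = manifest["network"]
    members = []
    for fi in range(1, manifest["n_members"] + 1):
        data = np.load(d / f"member_{fi:02d}.npz")
        cfg = NetworkConfig(
            n_features=schema.total_dim,
            n_classes=len(classes),
            rng_seed=int(manifest["member_seeds"][fi - 1]),
            **net_cfg,
        )
        net = MLPClassifier(cfg)
        net.set_params({k: data[k] for k in data.files if k.startswith(("W", "b"))})
        std = Standardizer(data["std_mean"], data["std_scale"])
        members.append(FoldModel(network=net, standardizer=std, fold_index=fi,
                                 training_log=TrainingLog()))
    ensemble = EnsembleModel(members=members, schema=schema, classes=classes)
    conf_path = d / "confidence_table.csv"
    if conf_path.exists():
        ensemble.confidence = ConfidenceTable.from_csv(conf_path, classes)
    return ensemble
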