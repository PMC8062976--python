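"""End-to-end predictor: oral genus table in, stool family composition out.

``GutFromOralPredictor`` chains the whole training protocol — genus
filtering, standardization, target construction, k-fold epoch selection,
refit, and training-set bias-correction estimation — and at predict time
applies standardization (zero-imputing genera the input lacks), the network
forward pass, the bias correction and the composition closure. Fitted
predictors round-trip through a plain-text bundle directory (JSON manifest +
JSON weights + TSV cross-validation curve).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import __version__
from .io_tables import FamilyTable, GenusTable
from .network import (
    CVCurve,
    NetworkConfig,
    TrainedNetwork,
    fit_final,
    predict_raw,
    train_cv,
)
from .postprocess import (
    BiasCorrection,
    apply_bias_correction,
    clip_and_rescale,
    estimate_bias_correction,
)
from .preprocess import (
    FeatureScaler,
    FeatureSet,
    OralFeatureTransformer,
    TargetSchema,
    build_targets,
    select_target_families,
    transform,
)

MANIFEST_NAME = "manifest.json"
WEIGHTS_NAME = "weights.json"
CV_CURVE_NAME = "cv_curve.tsv"


def train_test_split_ids(
    sample_ids: list[str], train_frac: float, seed: int
) -> tuple[list[str], list[str]]:
    """Disjoint subject-level split; sizes round to the training fraction."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sample_ids))
    n_train = int(round(train_frac * len(sample_ids)))
    n_train = min(max(n_train, 1), len(sample_ids) - 1)
    train_idx = np.sort(order[:n_train])
    test_idx = np.sort(order[n_train:])
    return (
        [sample_ids[i] for i in train_idx],
        [sample_ids[i] for i in test_idx],
    )


class GutFromOralPredictor(BaseEstimator):
    """Predict family-level stool composition from a genus-level oral table.

    Parameters mirror the training protocol: the genus prevalence filter,
    the network architecture and optimization settings, the k-fold epoch
    selection, and the bias-correction flag threshold. ``schema_families``
    fixes the predicted families (default: the built-in 12-family schema);
    ``select_k`` instead re-derives the schema from the training stool table
    by median abundance.
    """

    def __init__(
        self,
        min_samples: int = 4,
        min_abundance: float = 0.001,
        schema_families: list[str] | None = None,
        select_k: int | None = None,
        hidden_sizes: tuple[int, ...] = (50, 50),
        l2_coeff: float = 0.001,
        dropout_rate: float = 0.5,
        epochs: int = 500,
        k_folds: int = 4,
        learning_rate: float = 0.001,
        batch_size: int = 16,
        flag_threshold: float = 0.25,
        seed: int = 0,
    ):
        self.min_samples = min_samples
        self.min_abundance = min_abundance
        self.schema_families = schema_families
        self.select_k = select_k
        self.hidden_sizes = hidden_sizes
        self.l2_coeff = l2_coeff
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.k_folds = k_folds
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.flag_threshold = flag_threshold
        self.seed = seed

    # ------------------------------------------------------------------ fit
    def fit(
        self, oral: GenusTable, stool: FamilyTable
    ) -> "GutFromOralPredictor":
        oral_set = set(oral.sample_ids)
        stool_set = set(stool.sample_ids)
        if oral_set != stool_set:
            unpaired = sorted(oral_set ^ stool_set)
            raise ValueError(f"unpaired samples between tables: {unpaired}")
        stool = stool.subset_samples(oral.sample_ids)

        self.transformer_ = OralFeatureTransformer(
            min_samples=self.min_samples, min_abundance=self.min_abundance
        ).fit(oral)
        X = self.transformer_.transform(oral)

        if self.select_k is not None:
            self.schema_ = select_target_families(stool, self.select_k)
        elif self.schema_families is not None:
            self.schema_ = TargetSchema(list(self.schema_families))
        else:
            self.schema_ = TargetSchema()
        targets = build_targets(stool, self.schema_)
        Y = targets.values

        config = NetworkConfig(
            n_inputs=X.shape[1],
            hidden_sizes=tuple(self.hidden_sizes),
            n_outputs=self.schema_.n_outputs,
            l2_coeff=self.l2_coeff,
            dropout_rate=self.dropout_rate,
            epochs=self.epochs,
            k_folds=self.k_folds,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            seed=self.seed,
        )
        self.cv_curve_ = train_cv(X, Y, config)
        self.best_epoch_ = self.cv_curve_.best_epoch
        self.network_ = fit_final(X, Y, config, self.best_epoch_)
        self.network_.feature_set = self.transformer_.feature_set_
        self.network_.scaler = self.transformer_.scaler_
        self.network_.schema = self.schema_

        train_pred = clip_and_rescale(
            predict_raw(self.network_, X),
            self.schema_.output_names,
            oral.sample_ids,
        )
        self.bias_correction_ = estimate_bias_correction(
            train_pred, targets, flag_threshold=self.flag_threshold
        )
        return self

    # -------------------------------------------------------------- predict
    def predict(self, oral: GenusTable) -> FamilyTable:
        """Standardize, forward pass, bias-correct and close to 100%."""
        feature_labels = set(self.transformer_.feature_set_.retained_genera)
        if not feature_labels & set(oral.genus_labels):
            raise ValueError(
                "input table shares no genus with the model's feature set"
            )
        X = self.transformer_.transform(oral)
        raw = predict_raw(self.network_, X)
        pred = clip_and_rescale(
            raw, self.schema_.output_names, oral.sample_ids
        )
        return apply_bias_correction(pred, self.bias_correction_)

    # ---------------------------------------------------------- persistence
    def save(self, bundle_dir: str | Path) -> Path:
        """Write the fitted model as a plain-text bundle directory."""
        bundle_dir = Path(bundle_dir)
        bundle_dir.mkdir(parents=True, exist_ok=True)
        cfg = self.network_.config
        manifest = {
            "tool_version": __version__,
            "config": {
                "min_samples": self.min_samples,
                "min_abundance": self.min_abundance,
                "hidden_sizes": list(cfg.hidden_sizes),
                "n_inputs": cfg.n_inputs,
                "n_outputs": cfg.n_outputs,
                "l2_coeff": cfg.l2_coeff,
                "dropout_rate": cfg.dropout_rate,
                "epochs": cfg.epochs,
                "k_folds": cfg.k_folds,
                "learning_rate": cfg.learning_rate,
                "batch_size": cfg.batch_size,
                "seed": cfg.seed,
                "flag_threshold": self.flag_threshold,
            },
            "retained_genera": self.transformer_.feature_set_.retained_genera,
            "scaler": {
                "means": self.transformer_.scaler_.genus_means.tolist(),
                "sds": self.transformer_.scaler_.genus_sds.tolist(),
            },
            "schema_families": self.schema_.family_names,
            "best_epoch": self.best_epoch_,
            "bias_correction": {
                "families": self.bias_correction_.families,
                "factors": self.bias_correction_.factors.tolist(),
                "flagged": self.bias_correction_.flagged,
                "flag_threshold": self.bias_correction_.flag_threshold,
            },
        }
        (bundle_dir / MANIFEST_NAME).write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        weights = {
            "weights": [w.tolist() for w in self.network_.weights],
            "biases": [b.tolist() for b in self.network_.biases],
        }
        (bundle_dir / WEIGHTS_NAME).write_text(
            json.dumps(weights, sort_keys=True)
        )
        with (bundle_dir / CV_CURVE_NAME).open("w") as fh:
            fh.write("epoch\tmean_val_mae\n")
            for i, mae in enumerate(self.cv_curve_.per_epoch_mae, start=1):
                fh.write(f"{i}\t{mae:.6f}\n")
        return bundle_dir

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "GutFromOralPredictor":
        bundle_dir = Path(bundle_dir)
        manifest = json.loads((bundle_dir / MANIFEST_NAME).read_text())
        weights = json.loads((bundle_dir / WEIGHTS_NAME).read_text())
        cfg = manifest["config"]
        self = cls(
            min_samples=cfg["min_samples"],
            min_abundance=cfg["min_abundance"],
            schema_families=manifest["schema_families"],
            hidden_sizes=tuple(cfg["hidden_sizes"]),
            l2_coeff=cfg["l2_coeff"],
            dropout_rate=cfg["dropout_rate"],
            epochs=cfg["epochs"],
            k_folds=cfg["k_folds"],
            learning_rate=cfg["learning_rate"],
            batch_size=cfg["batch_size"],
            flag_threshold=cfg["flag_threshold"],
            seed=cfg["seed"],
        )
        feature_set = FeatureSet(
            manifest["retained_genera"],
            min_samples=cfg["min_samples"],
            min_abundance=cfg["min_abundance"],
        )
        scaler = FeatureScaler(
            np.asarray(manifest["scaler"]["means"]),
            np.asarray(manifest["scaler"]["sds"]),
        )
        transformer = OralFeatureTransformer(
            min_samples=cfg["min_samples"], min_abundance=cfg["min_abundance"]
        )
        transformer.feature_set_ = feature_set
        transformer.scaler_ = scaler
        transformer.n_features_out_ = len(feature_set)
        self.transformer_ = transformer
        self.schema_ = TargetSchema(list(manifest["schema_families"]))
        net_config = NetworkConfig(
            n_inputs=cfg["n_inputs"],
            hidden_sizes=tuple(cfg["hidden_sizes"]),
            n_outputs=cfg["n_outputs"],
            l2_coeff=cfg["l2_coeff"],
            dropout_rate=cfg["dropout_rate"],
            epochs=cfg["epochs"],
            k_folds=cfg["k_folds"],
            learning_rate=cfg["learning_rate"],
            batch_size=cfg["batch_size"],
            seed=cfg["seed"],
        )
        self.network_ = TrainedNetwork(
            config=net_config,
            weights=[np.asarray(w) for w in weights["weights"]],
            biases=[np.asarray(b) for b in weights["biases"]],
            best_epoch=manifest["best_epoch"],
            feature_set=feature_set,
            scaler=scaler,
            schema=self.schema_,
        )
        self.best_epoch_ = manifest["best_epoch"]
        bc = manifest["bias_correction"]
        self.bias_correction_ = BiasCorrection(
            bc["families"],
            np.asarray(bc["factors"]),
            bc["flagged"],
            bc["flag_threshold"],
        )
        curve_path = bundle_dir / CV_CURVE_NAME
        if curve_path.exists():
            maes = [
                float(line.split("\t")[1])
                for line in curve_path.read_text().splitlines()[1:]
            ]
            self.cv_curve_ = CVCurve(np.asarray(maes), manifest["best_epoch"])
        return self
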