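"""Metrics and fat-compartment benchmark models.

The benchmark models mirror conventional practice: total, visceral and
upper-extremity adipose tissue volumes (from the phantom ground-truth
masks) feed linear, k-nearest-neighbor, random-forest and support-vector
models, and their AUROC / normalized MAE are compared head-by-head with
the network.  For the scarce-positive diabetes and prediabetes labels the
validation and test folds are pooled by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import mean_absolute_error, roc_auc_score
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .nn.densenet import CLASSIFICATION_HEADS, REGRESSION_HEADS
from .synthgen import BodyVolume

FAT_THRESHOLD = 0.6  # midway between lean (~0.3) and fat (~1.0) phantom intensity


@dataclass
class CompartmentFeatures:
    """Adipose tissue volumes in liters."""

    total_adipose_volume: float
    visceral_adipose_volume: float
    upper_extremity_adipose_volume: float

    def validate(self) -> None:
        for v in (self.total_adipose_volume, self.visceral_adipose_volume, self.upper_extremity_adipose_volume):
            if v < 0:
                raise ValueError("compartment volumes must be nonnegative")
        if self.visceral_adipose_volume + self.upper_extremity_adipose_volume > self.total_adipose_volume + 1e-9:
            raise ValueError("sub-compartments exceed the total volume")


def compartment_volumes(volume: BodyVolume, fat_threshold: float = FAT_THRESHOLD) -> CompartmentFeatures:
    """Fat-voxel counts within the compartment masks, scaled to liters.

    Visceral = upper + lower visceral masks; upper extremity = arm mask.
    Requires ground-truth region masks (phantoms always carry them).
    """
    if not volume.region_masks:
        raise ValueError("region masks are required for compartment volumes")
    fat = volume.voxels >= fat_threshold
    ml = volume.voxel_volume_ml
    visc = volume.region_masks["visceral_upper"] | volume.region_masks["visceral_lower"]
    total = float(np.count_nonzero(fat & volume.body_mask) * ml / 1000.0)
    visceral = float(np.count_nonzero(fat & visc) * ml / 1000.0)
    arms = float(np.count_nonzero(fat & volume.region_masks["arm"]) * ml / 1000.0)
    feats = CompartmentFeatures(total, visceral, arms)
    feats.validate()
    return feats


def compartment_table(volumes: list[BodyVolume]) -> pd.DataFrame:
    rows = [compartment_volumes(v) for v in volumes]
    return pd.DataFrame(
        {
            "total_adipose_volume": [r.total_adipose_volume for r in rows],
            "visceral_adipose_volume": [r.visceral_adipose_volume for r in rows],
            "upper_extremity_adipose_volume": [r.upper_extremity_adipose_volume for r in rows],
        }
    )


def auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal AUROC over all thresholds; undefined for one-class truth."""
    y = np.asarray(y_true).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined: truth contains a single class")
    return float(roc_auc_score(y, scores))


def score_metrics(
    predictions: dict[str, np.ndarray],
    truth: dict[str, np.ndarray],
    transforms: dict[str, tuple[float, float]] | None = None,
    masks: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """AUROC per binary label, normalized + absolute MAE per regression label."""
    rows = []
    masks = masks or {}
    for head in CLASSIFICATION_HEADS:
        if head not in truth:
            continue
        m = masks.get(head, np.ones(len(truth[head]), dtype=bool))
        scores = predictions[head]
        scores = scores[:, 1] if scores.ndim == 2 else scores
        try:
            value = auroc(truth[head][m], scores[m])
        except ValueError:
            value = np.nan
        rows.append({"label": head, "metric": "auroc", "value": value})
    for head in REGRESSION_HEADS:
        if head not in truth:
            continue
        m = masks.get(head, np.ones(len(truth[head]), dtype=bool))
        nmae = float(mean_absolute_error(truth[head][m], predictions[head][m]))
        row = {"label": head, "metric": "nmae", "value": nmae}
        if transforms and head in transforms:
            lo, hi = transforms[head]
            row["absolute_mae"] = nmae * (hi - lo)
        rows.append(row)
    return pd.DataFrame(rows)


BENCHMARK_FAMILIES = ("linear", "knn", "random_forest", "svm")


def _make_model(family: str, task: str, seed: int):
    scaler = StandardScaler()
    if task == "classification":
        models = {
            "linear": LogisticRegression(max_iter=2000),
            "knn": KNeighborsClassifier(n_neighbors=5),
            "random_forest": RandomForestClassifier(n_estimators=200, random_state=seed),
            "svm": SVC(kernel="rbf", probability=False, random_state=seed),
        }
    else:
        models = {
            "linear": LinearRegression(),
            "knn": KNeighborsRegressor(n_neighbors=5),
            "random_forest": RandomForestRegressor(n_estimators=200, random_state=seed),
            "svm": SVR(kernel="rbf"),
        }
    return make_pipeline(scaler, models[family])


def _scores(model, X: np.ndarray) -> np.ndarray:
    last = model[-1]
    if hasattr(last, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(last, "decision_function"):
        return model.decision_function(X)
    return model.predict(X)


def fit_benchmarks(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    folds: pd.Series,
    seed: int = 0,
    heads: tuple[str, ...] = CLASSIFICATION_HEADS + REGRESSION_HEADS,
    pool_val_test: tuple[str, ...] = ("diabetes", "prediabetes"),
) -> pd.DataFrame:
    """Fit the four benchmark families on the three compartment volumes.

    Classification heads are scored by AUROC on the test fold (validation
    and test pooled for the scarce-positive labels); regression heads by
    MAE on the test fold.  Zero-variance features are rejected.
    """
    X = features.to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("degenerate (zero-variance) compartment features")
    folds = np.asarray(folds)
    tr = folds == "train"
    rows = []
    for head in heads:
        if head not in labels.columns:
            continue
        y = labels[head].to_numpy(dtype=float)
        obs = np.isfinite(y)
        task = "classification" if head in CLASSIFICATION_HEADS else "regression"
        ev = (folds != "train") if (head in pool_val_test) else (folds == "test")
        for family in BENCHMARK_FAMILIES:
            model = _make_model(family, task, seed)
            model.fit(X[tr & obs], y[tr & obs])
            if task == "classification":
                try:
                    value = auroc(y[ev & obs], _scores(model, X[ev & obs]))
                except ValueError:
                    value = np.nan
                metric = "auroc"
            else:
                value = float(mean_absolute_error(y[ev & obs], model.predict(X[ev & obs])))
                metric = "nmae"
            rows.append({"label": head, "model": family, "metric": metric, "value": value})
    return pd.DataFrame(rows)


def comparison_table(network_metrics: pd.DataFrame, benchmark_metrics: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side network vs best-benchmark table (one row per label)."""
    rows = []
    for _, row in network_metrics.iterrows():
        bench = benchmark_metrics[benchmark_metrics.label == row.label].dropna(subset=["value"])
        if bench.empty:
            continue
        if row.metric == "auroc":
            best = bench.loc[bench.value.idxmax()]
        else:
            best = bench.loc[bench.value.idxmin()]
        rows.append(
            {
                "label": row.label,
                "metric": row.metric,
                "network": row.value,
                "best_benchmark": best.value,
                "best_benchmark_model": best.model,
            }
        )
    return pd.DataFrame(rows)
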