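"""End-to-end orchestration: simulate -> preprocess -> split -> train ->
select -> infer -> saliency -> cluster -> evaluate.

Every stage writes its artifacts into the run directory together with a
manifest (config hash, seeds, package version); a completed stage leaves a
marker file so interrupted runs can resume.  The in-memory entry points
(:func:`prepare_cohort`, :func:`train_signal_model`) are what the tests and
the acceptance analyses drive; :func:`run_pipeline` is the file-writing
wrapper behind the command line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .augment import center_volume, make_augment_fn
from .cluster import bootstrap_stability, gower_matrix, outcome_analysis, pam_silhouette
from .config import AugmentConfig, Profile, RunConfig, save_config
from .evaluate import compartment_table, comparison_table, fit_benchmarks, score_metrics
from .io import save_volume
from .nn import DenseNet3D, ModelConfig, infer, select_checkpoint, train_model
from .nn.densenet import ALL_HEADS, CLASSIFICATION_HEADS
from .nn.training import evaluate_heads
from .preprocess import (
    body_voxel_stats,
    normalize_labels,
    normalize_shape,
    normalize_voxels,
    remove_outliers,
    stratified_split,
)
from .saliency import gradient_x_input, postprocess_heatmap, region_fractions, region_mean_attribution
from .synthgen import generate_cohort

HEAD_COLUMNS = {
    "sex": "sex",
    "diabetes": "diabetes",
    "prediabetes": "prediabetes",
    "diabetes_ext": "diabetes_ext",
    "age": "age",
    "bmi": "bmi",
    "insulin_sensitivity": "insulin_sensitivity",
    "hba1c": "hba1c_pct",
}


def profile_augment(profile: Profile, base: AugmentConfig | None = None) -> AugmentConfig:
    """Scale augmentation ranges to the profile's grid.

    The full-scale ranges (pad 2, rotations 10/5 degrees) are larger than
    the planted anatomical structures at 1/6 linear scale, so the tiny
    profile pads by at most 1 voxel and rotates by 5/2 degrees.
    """
    base = base or AugmentConfig()
    if profile.name != "tiny":
        return base
    return dataclasses.replace(base, max_pad=min(base.max_pad, 1),
                               rot_vertical_deg=min(base.rot_vertical_deg, 5.0),
                               rot_other_deg=min(base.rot_other_deg, 2.0))


@dataclass
class CohortData:
    """Everything the modeling stages consume, in memory."""

    raw_volumes: list
    normalized: list
    labels: pd.DataFrame
    followup: pd.DataFrame
    split: pd.DataFrame
    X: np.ndarray
    Y: dict[str, np.ndarray]
    M: dict[str, np.ndarray]
    transforms: dict
    voxel_stats: tuple[float, float]
    keep_mask: np.ndarray


def prepare_cohort(cfg: RunConfig, profile: Profile | None = None) -> CohortData:
    """Simulate, preprocess, outlier-filter and split one cohort."""
    profile = profile or cfg.get_profile()
    raw, labels, followup = generate_cohort(cfg.n_subjects, cfg.label_model, seed=cfg.seed, profile=profile)

    feats = compartment_table(raw)
    outl = labels[["insulin_sensitivity", "bmi"]].copy()
    outl["hba1c"] = labels["hba1c_pct"]
    outl["total_adipose_volume"] = feats["total_adipose_volume"].to_numpy()
    keep = remove_outliers(outl.fillna(outl.median()), contamination=cfg.contamination, seed=cfg.seed + 1)

    raw = [v for v, k in zip(raw, keep) if k]
    labels = labels.loc[keep].reset_index(drop=True)
    followup = followup.loc[keep].reset_index(drop=True)

    normed = [center_volume(normalize_shape(v, profile.target_dims, profile.final_dims)) for v in raw]
    split = stratified_split(labels, fractions=cfg.fractions, seed=cfg.seed + 2)
    tr = (split["fold"] == "train").to_numpy()
    stats = body_voxel_stats([v for v, m in zip(normed, tr) if m])
    normed = [normalize_voxels(v, stats_source=stats) for v in normed]

    lab_norm, transforms, observed = normalize_labels(labels, train_mask=tr)
    X = np.stack([v.voxels for v in normed])
    Y, M = {}, {}
    for head, col in HEAD_COLUMNS.items():
        y = lab_norm[col].to_numpy(dtype=float)
        M[head] = np.isfinite(y)
        Y[head] = np.nan_to_num(y)
    return CohortData(raw, normed, labels, followup, split, X, Y, M, transforms, stats, keep)


def train_signal_model(
    data: CohortData,
    cfg: RunConfig,
    profile: Profile | None = None,
    augment: bool = True,
    model_config: ModelConfig | None = None,
):
    """Train on the training fold, select by validation diabetes AUROC.

    Returns ``(net, history, selected_epoch, held_out_metrics)`` where the
    held-out metrics pool validation and test (the scarce-positive labels
    need the pooled folds for stable AUROC estimates).
    """
    profile = profile or cfg.get_profile()
    mcfg = model_config or ModelConfig(layers_per_block=profile.layers_per_block, init_lr=profile.init_lr)
    net = DenseNet3D(mcfg, profile.final_dims, seed=cfg.seed + 3)
    fold = data.split["fold"].to_numpy()
    tr, va = fold == "train", fold == "validation"
    aug_fn = make_augment_fn(None, profile_augment(profile, cfg.augment)) if augment else None
    hist = train_model(
        net,
        (data.X[tr], {h: data.Y[h][tr] for h in ALL_HEADS}, {h: data.M[h][tr] for h in ALL_HEADS}),
        (data.X[va], {h: data.Y[h][va] for h in ALL_HEADS}, {h: data.M[h][va] for h in ALL_HEADS}),
        cfg=mcfg,
        epochs=cfg.epochs,
        seed=cfg.seed + 4,
        augment_fn=aug_fn,
    )
    try:
        epoch, state = select_checkpoint(hist)
    except ValueError:
        # degenerate validation fold (single-class diabetes): keep the last epoch
        epoch, state = hist.epochs[-1], hist.checkpoints[-1]
    net.load_state_dict(state)
    ho = fold != "train"
    metrics = evaluate_heads(net, data.X[ho], {h: data.Y[h][ho] for h in ALL_HEADS}, {h: data.M[h][ho] for h in ALL_HEADS})
    return net, hist, epoch, metrics


def _stage(run_dir: Path, name: str):
    marker = run_dir / f".done_{name}"

    class _Ctx:
        def __enter__(self):
            return marker

        def __exit__(self, exc_type, exc, tb):
            if exc_type is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            marker.write_text("ok")

    return _Ctx()


def run_pipeline(cfg: RunConfig, resume: bool = True, write_volumes: bool = False) -> Path:
    """Execute every stage, writing artifacts and a manifest to ``cfg.out_dir``."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    profile = cfg.get_profile()

    save_config(cfg, run_dir / "config.yaml")
    # hash the scientific configuration only (output location excluded)
    hashed = dataclasses.replace(cfg, out_dir="")
    cfg_hash = hashlib.sha256(yaml.safe_dump(dataclasses.asdict(hashed), sort_keys=True).encode()).hexdigest()
    manifest = {
        "package_version": __version__,
        "config_sha256": cfg_hash,
        "profile": profile.name,
        "seed": cfg.seed,
        "stage_seeds": {
            "simulate": cfg.seed,
            "outliers": cfg.seed + 1,
            "split": cfg.seed + 2,
            "model_init": cfg.seed + 3,
            "train": cfg.seed + 4,
            "cluster": cfg.seed + 5,
            "bootstrap": cfg.seed + 6,
        },
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    with _stage(run_dir, "prepare"):
        data = prepare_cohort(cfg, profile)
        data.labels.to_csv(run_dir / "labels.csv", index=False)
        data.followup.to_csv(run_dir / "followup.csv", index=False)
        data.split.to_csv(run_dir / "split.csv", index=False)
        (run_dir / "normalization.json").write_text(
            json.dumps({"voxel_mean": data.voxel_stats[0], "voxel_sd": data.voxel_stats[1],
                        "label_transforms": {k: list(v) for k, v in data.transforms.items()}}, indent=1)
        )
        if write_volumes:
            vol_dir = run_dir / "volumes"
            for vol in data.raw_volumes:
                save_volume(vol, vol_dir / f"{vol.subject_id}.nii.gz")
            manifest_rows = [{"subject_id": v.subject_id, "path": f"volumes/{v.subject_id}.nii.gz"}
                             for v in data.raw_volumes]
            pd.DataFrame(manifest_rows).merge(data.labels, on="subject_id").to_csv(
                run_dir / "cohort_manifest.csv", index=False)

    with _stage(run_dir, "train"):
        net, hist, epoch, held_out = train_signal_model(data, cfg, profile)
        hist.to_frame().to_csv(run_dir / "history.csv", index=False)
        (run_dir / "selected_checkpoint.json").write_text(json.dumps({"epoch": epoch, **held_out}, indent=1))
        np.savez_compressed(run_dir / "checkpoint.npz", **net.state_dict())

    with _stage(run_dir, "infer"):
        preds = infer(net, data.X)
        emb = preds["embedding"]
        np.savetxt(run_dir / "embeddings.csv", emb, delimiter=",")
        pred_df = pd.DataFrame({"subject_id": data.labels["subject_id"]})
        for head in CLASSIFICATION_HEADS:
            pred_df[f"p_{head}"] = preds[head][:, 1]
        for head in ("age", "bmi", "insulin_sensitivity", "hba1c"):
            pred_df[head] = preds[head]
        pred_df.to_csv(run_dir / "predictions.csv", index=False)

    with _stage(run_dir, "saliency"):
        fold = data.split["fold"].to_numpy()
        ho = fold != "train"
        pos = np.flatnonzero(ho & (data.Y["diabetes"] > 0.5))[:25]
        maps = [gradient_x_input(net, data.X[i], "diabetes", true_label=1) for i in pos]
        masks = [data.normalized[i].region_masks for i in pos]
        if maps:
            report = region_fractions(maps, masks)
            ranks = region_mean_attribution(maps, masks)
            pd.DataFrame({"region": list(report), "highlight_fraction": list(report.values()),
                          "mean_attribution": [ranks[r] for r in report]}).to_csv(
                run_dir / "region_report.csv", index=False)
            proj, _ = postprocess_heatmap(maps[0])
            try:
                import matplotlib

                matplotlib.use("Agg")
                import matplotlib.pyplot as plt

                fig, ax = plt.subplots(figsize=(4, 4))
                ax.imshow(proj, cmap="inferno")
                ax.set_title("diabetes attribution (coronal mean)")
                ax.axis("off")
                fig.savefig(run_dir / "heatmap_diabetes.png", dpi=120)
                plt.close(fig)
            except Exception:
                pass

    with _stage(run_dir, "cluster"):
        sexes = data.labels["sex"].to_numpy()
        assignments = np.full(len(sexes), -1)
        sil_rows, jac_rows = [], []
        offset = 0
        k_lo, k_hi = cfg.k_range
        for s in np.unique(sexes):
            idx = np.flatnonzero(sexes == s)
            if idx.size < 6:
                assignments[idx] = offset
                offset += 1
                continue
            D = gower_matrix(emb[idx])
            res = pam_silhouette(D, range(k_lo, min(k_hi, idx.size - 1) + 1), seed=cfg.seed + 5)
            jac = bootstrap_stability(D, res, B=cfg.bootstrap_B, seed=cfg.seed + 6)
            assignments[idx] = res.assignments + offset
            for k, w in res.silhouette.items():
                sil_rows.append({"sex": s, "k": k, "avg_silhouette": w, "selected": k == res.k})
            for c, j in enumerate(jac):
                jac_rows.append({"sex": s, "cluster": c + offset, "jaccard": j})
            offset += res.k
        pd.DataFrame({"subject_id": data.labels["subject_id"], "cluster": assignments}).to_csv(
            run_dir / "assignments.csv", index=False)
        pd.DataFrame(sil_rows).to_csv(run_dir / "silhouette.csv", index=False)
        pd.DataFrame(jac_rows).to_csv(run_dir / "jaccard.csv", index=False)
        covs = data.labels[["sex", "age", "bmi"]].fillna(data.labels[["sex", "age", "bmi"]].median())
        outcome = outcome_analysis(assignments, data.followup, covariates=covs)
        summary = {}
        for endpoint, entry in outcome.items():
            if "logrank_p" in entry:
                summary[endpoint] = {"logrank_stat": entry["logrank_stat"], "logrank_p": entry["logrank_p"]}
                for c, km in entry["km"].items():
                    km.to_csv(run_dir / f"km_{endpoint}_cluster{c}.csv")
            else:
                summary[endpoint] = entry
        (run_dir / "outcomes.json").write_text(json.dumps(summary, indent=1))

    with _stage(run_dir, "evaluate"):
        fold = data.split["fold"].to_numpy()
        pooled = fold != "train"
        truth = {h: data.Y[h] for h in ALL_HEADS}
        net_metrics = score_metrics(
            {h: preds[h][pooled] if preds[h].ndim == 1 else preds[h][pooled] for h in ALL_HEADS},
            {h: truth[h][pooled] for h in ALL_HEADS},
            transforms={"age": data.transforms.get("age"), "bmi": data.transforms.get("bmi"),
                        "insulin_sensitivity": data.transforms.get("insulin_sensitivity"),
                        "hba1c": data.transforms.get("hba1c_pct")},
            masks={h: data.M[h][pooled] for h in ALL_HEADS},
        )
        feats = compartment_table(data.raw_volumes)
        bench_labels = data.labels.rename(columns={"hba1c_pct": "hba1c"}).copy()
        lab_norm, _, _ = normalize_labels(data.labels, train_mask=fold == "train")
        for h in ("age", "bmi", "insulin_sensitivity"):
            bench_labels[h] = lab_norm[h]
        bench_labels["hba1c"] = lab_norm["hba1c_pct"]
        bench = fit_benchmarks(feats, bench_labels, data.split["fold"], seed=cfg.seed + 7)
        comp = comparison_table(net_metrics, bench)
        net_metrics.to_csv(run_dir / "network_metrics.csv", index=False)
        bench.to_csv(run_dir / "benchmark_metrics.csv", index=False)
        comp.to_csv(run_dir / "comparison.csv", index=False)
        with open(run_dir / "comparison.md", "w") as fh:
            fh.write(comp.to_markdown(index=False))

    return run_dir
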