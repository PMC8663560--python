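"""Run configuration: profiles, label-model parameters, YAML round-trip.

Two resolution profiles are provided.  ``paper`` reproduces the printed
preprocessing grids of the full-scale analysis: raw scans of 90-120
transverse slices at 150x250 in-plane are interpolated to 95x150x250 and
downsampled to 85x110x135.  ``tiny`` keeps similar per-axis downsampling
ratios at roughly one sixth of the linear scale with a vertically finer
grid (raw in-plane 22x37 -> 24x22x37 -> 20x16x20), since the planted
anatomical contrasts vary along the body axis, and trains on a single CPU
in minutes with shallower dense blocks (2 layers instead of 4) and a
faster optimizer rate suited to runs of 10-20 epochs instead of 250.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

# HbA1c unit conversion (IFCC <-> NGSP/DCCT): mmol/mol = (% - 2.15) * 10.929
HBA1C_SLOPE = 10.929
HBA1C_OFFSET = 2.15


def hba1c_pct_to_mmolmol(pct):
    return (pct - HBA1C_OFFSET) * HBA1C_SLOPE


def hba1c_mmolmol_to_pct(mmolmol):
    return mmolmol / HBA1C_SLOPE + HBA1C_OFFSET


@dataclass
class Profile:
    """Grid geometry and network depth for one resolution tier."""

    name: str = "tiny"
    raw_inplane: tuple[int, int] = (22, 37)
    target_dims: tuple[int, int, int] = (24, 22, 37)
    final_dims: tuple[int, int, int] = (20, 16, 20)
    layers_per_block: int = 2
    init_lr: float = 1e-3  # scaled-run optimizer rate; the full-scale profile uses 1e-4
    voxel_volume_ml: float = 80.0  # physical volume represented by one raw voxel

    def __post_init__(self) -> None:
        self.raw_inplane = tuple(self.raw_inplane)
        self.target_dims = tuple(self.target_dims)
        self.final_dims = tuple(self.final_dims)


PROFILES: dict[str, Profile] = {
    "tiny": Profile(),
    "paper": Profile(
        name="paper",
        raw_inplane=(150, 250),
        target_dims=(95, 150, 250),
        final_dims=(85, 110, 135),
        layers_per_block=4,
        init_lr=1e-4,
        voxel_volume_ml=2.0,
    ),
}


@dataclass
class DiagnosisThresholds:
    """Glycemic diagnosis cut-offs.

    Diabetes: fasting glucose > 7.0 mmol/l (strict), 2h post-challenge
    glucose >= 11.1 mmol/l, or HbA1c >= 48 mmol/mol.  Prediabetes bands use
    the ADA research definitions: IFG 5.6-6.9 mmol/l fasting, IGT 7.8-11.0
    mmol/l at 2h.
    """

    fasting_diabetes: float = 7.0  # strict >
    g2h_diabetes: float = 11.1  # inclusive >=
    hba1c_diabetes_mmolmol: float = 48.0  # inclusive >=
    ifg_low: float = 5.6
    ifg_high: float = 6.9
    igt_low: float = 7.8
    igt_high: float = 11.0
    uacr_microalbuminuria: float = 30.0  # mg/g creatinine, inclusive >=


@dataclass
class LabelModelConfig:
    """Generative model for cohort labels and their anatomical coupling.

    The planted diabetes signal: positives receive an elevated lower
    visceral depot fraction (``signal='volume'``) or a lower-for-upper
    visceral swap at matched total visceral load (``signal='pattern'``).
    Insulin sensitivity (Matsuda-like, AU) falls with lower-visceral and
    thigh depot load; glycemia rises as insulin sensitivity falls.
    """

    signal: str = "volume"  # 'volume' | 'pattern'
    prevalence_diabetes: float = 0.30
    sex_female_prob: float = 0.5
    age_mean: float = 48.0
    age_sd: float = 12.0
    bmi_mean: float = 28.0
    bmi_sd: float = 4.5
    # depot fraction model
    visc_lower_base: float = 0.30
    visc_lower_sd: float = 0.08
    visc_lower_delta: float = 0.40  # added for diabetes positives (volume signal)
    visc_upper_base: float = 0.30
    visc_upper_sd: float = 0.08
    pattern_high: float = 0.55  # pattern signal: (lower, upper) = (high, low) vs (low, high)
    pattern_low: float = 0.15
    subcut_base: float = 0.25
    subcut_bmi_slope: float = 0.012  # per kg/m2 above 25
    subcut_sd: float = 0.05
    thigh_mean: float = 0.35
    thigh_sd: float = 0.10
    arm_mean: float = 0.30
    arm_sd: float = 0.08
    neck_mean: float = 0.25
    neck_sd: float = 0.08
    breast_female: float = 0.55
    breast_male: float = 0.15
    breast_sd: float = 0.08
    # insulin sensitivity (AU, Matsuda-like scale)
    is_base: float = 18.0
    is_visc_slope: float = 16.0
    is_thigh_slope: float = 4.0
    is_noise_sd: float = 1.5
    is_floor: float = 0.5
    # glycemia (mmol/l, %); non-diabetic component stays below all thresholds
    fasting_base: float = 4.9
    fasting_is_slope: float = 0.08
    fasting_noise_sd: float = 0.30
    g2h_base: float = 5.8
    g2h_is_slope: float = 0.25
    g2h_noise_sd: float = 0.80
    hba1c_base_pct: float = 5.2
    hba1c_is_slope: float = 0.05
    hba1c_noise_sd: float = 0.20
    # diabetic glycemia component (crosses every threshold by construction)
    fasting_dm_offset: float = 0.3
    fasting_dm_spread: float = 1.2
    g2h_dm_offset: float = 0.4
    g2h_dm_spread: float = 2.5
    hba1c_dm_offset_pct: float = 0.2
    hba1c_dm_spread_pct: float = 0.6
    # follow-up survival
    dm_base_hazard: float = 0.020  # events / person-year at reference glycemia
    dm_hba1c_loghr: float = 0.9  # per % HbA1c above base
    ma_base_hazard: float = 0.030
    ma_hba1c_loghr: float = 0.5
    uacr_log_mean: float = 2.1  # log mg/g
    uacr_log_sd: float = 0.7
    uacr_hba1c_slope: float = 0.25
    censor_min: float = 0.25
    censor_max: float = 9.75
    admin_censor: float = 10.0
    missing_rate: float = 0.0
    thresholds: DiagnosisThresholds = field(default_factory=DiagnosisThresholds)


@dataclass
class EmbeddingMixtureConfig:
    """Default subtype mixture for stand-alone embedding draws.

    Four well-separated Gaussian components in 128 dimensions; component
    means are drawn with a standard deviation of ``separation`` times the
    within-component standard deviation, which at 128 dimensions puts the
    between-mean distances at several multiples of the within-cluster
    spread.
    """

    n_components: int = 4
    dim: int = 128
    separation: float = 3.0
    within_sd: float = 1.0
    weights: tuple | None = None  # None -> equal


@dataclass
class AugmentConfig:
    """Training-time augmentation ranges (all disabled-able)."""

    max_pad: int = 2  # voxels per side
    rot_vertical_deg: float = 10.0
    rot_other_deg: float = 5.0
    noise_sd: float = 0.05  # as a fraction of body-voxel SD
    zoom_range: float = 0.0  # +- fraction; 0 disables (sensitivity analyses use 0.1)
    pad_enabled: bool = True
    rotation_enabled: bool = True
    noise_enabled: bool = True
    zoom_enabled: bool = False
    crop_torso: tuple[float, float] = (0.25, 0.75)
    crop_abdomen: tuple[float, float] = (0.40, 0.65)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    profile: str = "tiny"
    seed: int = 0
    n_subjects: int = 300
    epochs: int = 12
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    contamination: float = 0.02
    k_range: tuple[int, int] = (2, 8)
    bootstrap_B: int = 50
    label_model: LabelModelConfig = field(default_factory=LabelModelConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    mixture: EmbeddingMixtureConfig = field(default_factory=EmbeddingMixtureConfig)
    out_dir: str = "runs/latest"

    def get_profile(self) -> Profile:
        return PROFILES[self.profile]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _from_plain(f.type, v)
        elif f.name == "label_model":
            v = _from_plain(LabelModelConfig, v)
        elif f.name == "augment":
            v = _from_plain(AugmentConfig, v)
        elif f.name == "mixture":
            v = _from_plain(EmbeddingMixtureConfig, v)
        elif f.name == "thresholds":
            v = _from_plain(DiagnosisThresholds, v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return _from_plain(RunConfig, data)
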