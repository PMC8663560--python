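"""Label-conditioned synthetic whole-body phantoms and cohort simulation.

Real whole-body T1-weighted scans contrast bright adipose against dim lean
tissue.  The phantoms emulate that statistical structure without any MR
physics: a body is stacked elliptical cross-sections (head, neck, torso
with extended-arm cylinders, abdomen, pelvis, legs), each anatomical fat
depot is a voxel region in which a ``depot_fraction`` share of voxels is
set to fat intensity, and Gaussian texture noise is added inside the body.
BMI scales overall girth; sex toggles the shoulder/hip ratio and the
anterior breast bulge.

The cohort generator couples depot fractions to metabolic labels: lower
visceral and thigh fat load depress insulin sensitivity, glycemia rises as
insulin sensitivity falls, and diabetes-positive subjects receive elevated
lower-visceral fractions so the planted signal is anatomically localized
(or, in ``pattern`` mode, a lower-for-upper visceral swap at matched
compartment volumes).  Follow-up events are drawn from exponential hazards
that increase with baseline glycemia, with administrative censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import (
    DiagnosisThresholds,
    EmbeddingMixtureConfig,
    LabelModelConfig,
    Profile,
    hba1c_pct_to_mmolmol,
)

REGIONS = ("subcutaneous", "visceral_upper", "visceral_lower", "thigh", "arm", "neck", "breast")

LEAN_INTENSITY = 0.30
FAT_INTENSITY = 1.00
TEXTURE_SD = 0.03
BODY_FLOOR = 0.05
BACKGROUND_FAT_FRACTION = 0.08

SLICE_RANGE = (90, 120)


@dataclass
class PhantomSpec:
    """One subject's anatomy and metabolic labels."""

    sex: int  # 0 = male, 1 = female
    age: float
    bmi: float
    insulin_sensitivity: float
    hba1c_pct: float
    fasting_glucose: float
    glucose_2h: float
    depot_fractions: dict[str, float]
    slice_count: int
    seed: int

    def validate(self) -> None:
        if not (SLICE_RANGE[0] <= self.slice_count <= SLICE_RANGE[1]):
            raise ValueError(f"slice_count {self.slice_count} outside {SLICE_RANGE}")
        for region, frac in self.depot_fractions.items():
            if region not in REGIONS:
                raise ValueError(f"unknown depot region {region!r}")
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"depot fraction {region}={frac} outside [0, 1]")
        for name in ("age", "bmi", "insulin_sensitivity", "hba1c_pct", "fasting_glucose", "glucose_2h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BodyVolume:
    """A voxel grid with axis order (vertical, sagittal, coronal).

    ``region_masks`` are disjoint subsets of ``body_mask`` and serve as the
    ground truth for saliency region scoring and compartment volumes.
    ``fat_counts`` records the planted number of fat voxels per region.
    """

    voxels: np.ndarray
    body_mask: np.ndarray
    region_masks: dict[str, np.ndarray]
    axis_order: tuple[str, str, str] = ("vertical", "sagittal", "coronal")
    voxel_volume_ml: float = 80.0
    fat_counts: dict[str, int] = field(default_factory=dict)
    subject_id: str | None = None

    def check_invariants(self) -> None:
        assert np.all(self.voxels[~self.body_mask] == 0)
        union = np.zeros_like(self.body_mask)
        for m in self.region_masks.values():
            assert not np.any(union & m), "region masks overlap"
            assert np.all(self.body_mask[m]), "region mask outside body"
            union |= m


@dataclass
class FollowUpRecord:
    time_to_diabetes: float
    diabetes_event: int
    time_to_microalbuminuria: float
    microalbuminuria_event: int
    baseline_uacr: float


def _ellipse(xg: np.ndarray, yg: np.ndarray, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    return ((xg - cx) / max(rx, 1e-6)) ** 2 + ((yg - cy) / max(ry, 1e-6)) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec, profile: Profile | None = None) -> BodyVolume:
    """Render one phantom. Deterministic given ``spec.seed``."""
    spec.validate()
    profile = profile or Profile()
    nz = spec.slice_count
    ny, nx = profile.raw_inplane
    rng = np.random.default_rng(spec.seed)

    # normalized in-plane coordinates: x = left-right (coronal), y = anterior-posterior
    x = np.linspace(-1, 1, nx)
    y = np.linspace(-1, 1, ny)
    yg, xg = np.meshgrid(y, x, indexing="ij")
    f = (np.arange(nz) + 0.5) / nz  # vertical fraction, 0 = head end

    g = float(np.sqrt(spec.bmi / 25.0))  # girth scale
    female = spec.sex == 1
    shoulder = 1.0 if female else 1.15
    hip = 1.12 if female else 1.0

    body = np.zeros((nz, ny, nx), dtype=bool)
    regions = {r: np.zeros((nz, ny, nx), dtype=bool) for r in REGIONS}

    torso_band = (0.15, 0.42)
    abdomen_band = (0.42, 0.66)
    breast_band = (0.17, 0.27)
    visc_split = 0.54
    pelvis_band = (0.66, 0.74)
    thigh_top, thigh_bottom = 0.74, 0.88

    for iz, fz in enumerate(f):
        if fz < 0.10:  # head
            body[iz] = _ellipse(xg, yg, 0, 0, 0.18, 0.28)
        elif fz < 0.15:  # neck
            sl = _ellipse(xg, yg, 0, 0, 0.10, 0.16)
            body[iz] = sl
            regions["neck"][iz] = sl
        elif fz < torso_band[1]:  # torso + arms
            rx = 0.42 * g * (shoulder if fz < 0.30 else 1.0)
            ry = 0.30 * g
            in_breast_band = breast_band[0] <= fz < breast_band[1]
            ry_eff = ry * (1.25 if (female and in_breast_band) else 1.0)
            torso = _ellipse(xg, yg, 0, 0, rx, ry_eff)
            body[iz] |= torso
            if in_breast_band:
                regions["breast"][iz] = torso & (yg > 0.45 * ry)
            sub = torso & ~_ellipse(xg, yg, 0, 0, 0.78 * rx, 0.78 * ry_eff)
            regions["subcutaneous"][iz] = sub & ~regions["breast"][iz]
            if fz < 0.60:  # arms flanking the torso
                ax = min(rx + 0.18, 0.90)
                arm_r = 0.08 * np.sqrt(g)
                arms = _ellipse(xg, yg, ax, 0, arm_r, arm_r) | _ellipse(xg, yg, -ax, 0, arm_r, arm_r)
                body[iz] |= arms
                regions["arm"][iz] = arms
        elif fz < abdomen_band[1]:  # abdomen
            rx = 0.40 * g
            ry = 0.32 * g
            abd = _ellipse(xg, yg, 0, 0, rx, ry)
            body[iz] |= abd
            core = _ellipse(xg, yg, 0, 0, 0.55 * rx, 0.55 * ry)
            key = "visceral_upper" if fz < visc_split else "visceral_lower"
            regions[key][iz] = core
            regions["subcutaneous"][iz] = abd & ~_ellipse(xg, yg, 0, 0, 0.78 * rx, 0.78 * ry)
        elif fz < pelvis_band[1]:  # pelvis
            body[iz] = _ellipse(xg, yg, 0, 0, 0.40 * g * hip, 0.30 * g)
        else:  # legs
            leg_r = 0.15 * g
            cx = 0.18 * g + leg_r
            legs = _ellipse(xg, yg, cx, 0, leg_r, leg_r) | _ellipse(xg, yg, -cx, 0, leg_r, leg_r)
            body[iz] = legs
            if fz < thigh_bottom:
                regions["thigh"][iz] = legs

    # clip regions to body and enforce disjointness (construction order = priority)
    taken = np.zeros_like(body)
    for r in REGIONS:
        regions[r] &= body & ~taken
        taken |= regions[r]

    # fat placement: per-region top-priority voxels under a smooth random field
    priority = gaussian_filter(rng.normal(size=body.shape), sigma=1.5)
    vox = np.full(body.shape, LEAN_INTENSITY, dtype=np.float32)
    fat_counts: dict[str, int] = {}
    for r in REGIONS:
        idx = np.flatnonzero(regions[r])
        frac = spec.depot_fractions.get(r, 0.0)
        n_fat = int(round(frac * idx.size))
        fat_counts[r] = n_fat
        if n_fat > 0:
            order = np.argsort(priority.ravel()[idx])[::-1]
            vox.ravel()[idx[order[:n_fat]]] = FAT_INTENSITY
    rest = np.flatnonzero(body & ~taken)
    n_bg = int(round(BACKGROUND_FAT_FRACTION * rest.size))
    if n_bg > 0:
        order = np.argsort(priority.ravel()[rest])[::-1]
        vox.ravel()[rest[order[:n_bg]]] = FAT_INTENSITY
    fat_counts["other"] = n_bg

    vox += rng.normal(0.0, TEXTURE_SD, size=vox.shape).astype(np.float32)
    vox = np.clip(vox, BODY_FLOOR, None)
    vox[~body] = 0.0

    return BodyVolume(
        voxels=vox,
        body_mask=body,
        region_masks=regions,
        voxel_volume_ml=profile.voxel_volume_ml,
        fat_counts=fat_counts,
    )


def assign_diagnosis(fasting, g2h, hba1c_mmolmol, thresholds: DiagnosisThresholds | None = None):
    """Glycemic diagnosis labels from thresholds.

    Returns ``(d_alpha, d_beta, d_gamma)``: diabetes (fasting > 7.0 mmol/l,
    2h glucose >= 11.1 mmol/l or HbA1c >= 48 mmol/mol), prediabetes (IFG or
    IGT, without diabetes), and diabetes extended with concomitant IFG+IGT.
    Accepts scalars or arrays.
    """
    t = thresholds or DiagnosisThresholds()
    fasting = np.asarray(fasting, dtype=float)
    g2h = np.asarray(g2h, dtype=float)
    hba1c = np.asarray(hba1c_mmolmol, dtype=float)
    if np.any(fasting < 0) or np.any(g2h < 0) or np.any(hba1c < 0):
        raise ValueError("glycemic inputs must be nonnegative")
    d_alpha = (fasting > t.fasting_diabetes) | (g2h >= t.g2h_diabetes) | (hba1c >= t.hba1c_diabetes_mmolmol)
    ifg = (fasting >= t.ifg_low) & (fasting <= t.ifg_high)
    igt = (g2h >= t.igt_low) & (g2h <= t.igt_high)
    d_beta = ~d_alpha & (ifg | igt)
    d_gamma = d_alpha | (ifg & igt)
    return (d_alpha.astype(int), d_beta.astype(int), d_gamma.astype(int))


def assign_microalbuminuria(uacr, thresholds: DiagnosisThresholds | None = None):
    """1 iff urinary albumin-to-creatinine ratio >= 30 mg/g creatinine."""
    t = thresholds or DiagnosisThresholds()
    uacr = np.asarray(uacr, dtype=float)
    if np.any(uacr < 0):
        raise ValueError("uACR must be nonnegative")
    return (uacr >= t.uacr_microalbuminuria).astype(int)


def _truncnorm_pos(rng, mean, sd, size):
    return mean + np.abs(rng.normal(0.0, 1.0, size)) * sd


def generate_labels(n: int, cfg: LabelModelConfig, seed: int) -> pd.DataFrame:
    """Draw the label table alone (no volumes). Deterministic given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    t = cfg.thresholds

    sex = (rng.random(n) < cfg.sex_female_prob).astype(int)
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 20, 75)
    bmi = np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd, n), 18, 45)
    diabetes = (rng.random(n) < cfg.prevalence_diabetes).astype(int)

    if cfg.signal == "volume":
        visc_lower = rng.normal(cfg.visc_lower_base, cfg.visc_lower_sd, n)
        visc_lower = visc_lower + cfg.visc_lower_delta * diabetes
        visc_upper = rng.normal(cfg.visc_upper_base, cfg.visc_upper_sd, n)
    elif cfg.signal == "pattern":
        lo = rng.normal(cfg.pattern_low, cfg.visc_lower_sd, n)
        hi = rng.normal(cfg.pattern_high, cfg.visc_lower_sd, n)
        visc_lower = np.where(diabetes == 1, hi, lo)
        visc_upper = np.where(diabetes == 1, lo, hi)
    else:
        raise ValueError(f"unknown signal mode {cfg.signal!r}")
    visc_lower = np.clip(visc_lower, 0.02, 0.95)
    visc_upper = np.clip(visc_upper, 0.02, 0.95)

    subcut = np.clip(
        cfg.subcut_base + cfg.subcut_bmi_slope * (bmi - 25.0) + rng.normal(0, cfg.subcut_sd, n), 0.02, 0.95
    )
    thigh = np.clip(rng.normal(cfg.thigh_mean, cfg.thigh_sd, n), 0.02, 0.95)
    arm = np.clip(rng.normal(cfg.arm_mean, cfg.arm_sd, n), 0.02, 0.95)
    neck = np.clip(rng.normal(cfg.neck_mean, cfg.neck_sd, n), 0.02, 0.95)
    breast = np.clip(
        np.where(sex == 1, cfg.breast_female, cfg.breast_male) + rng.normal(0, cfg.breast_sd, n), 0.02, 0.95
    )

    ins = cfg.is_base - cfg.is_visc_slope * visc_lower - cfg.is_thigh_slope * thigh
    ins = np.clip(ins + rng.normal(0, cfg.is_noise_sd, n), cfg.is_floor, None)
    deficit = np.clip(cfg.is_base - ins, 0, None)

    # non-diabetic glycemia stays strictly inside the sub-threshold bands
    fasting = cfg.fasting_base + cfg.fasting_is_slope * deficit + rng.normal(0, cfg.fasting_noise_sd, n)
    fasting = np.clip(fasting, 3.8, t.ifg_high)
    g2h = cfg.g2h_base + cfg.g2h_is_slope * deficit + rng.normal(0, cfg.g2h_noise_sd, n)
    g2h = np.clip(g2h, 3.5, t.igt_high)
    hba1c_pct = cfg.hba1c_base_pct + cfg.hba1c_is_slope * deficit + rng.normal(0, cfg.hba1c_noise_sd, n)
    hba1c_pct = np.clip(hba1c_pct, 4.2, 6.3)

    # diabetic component crosses all three thresholds
    dm = diabetes == 1
    n_dm = int(dm.sum())
    if n_dm:
        fasting[dm] = t.fasting_diabetes + cfg.fasting_dm_offset + np.abs(rng.normal(0, 1, n_dm)) * cfg.fasting_dm_spread
        g2h[dm] = t.g2h_diabetes + cfg.g2h_dm_offset + np.abs(rng.normal(0, 1, n_dm)) * cfg.g2h_dm_spread
        hba1c_dm = 6.5 + cfg.hba1c_dm_offset_pct + np.abs(rng.normal(0, 1, n_dm)) * cfg.hba1c_dm_spread_pct
        hba1c_pct[dm] = hba1c_dm

    hba1c_mmolmol = hba1c_pct_to_mmolmol(hba1c_pct)
    d_alpha, d_beta, d_gamma = assign_diagnosis(fasting, g2h, hba1c_mmolmol, t)

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "insulin_sensitivity": ins,
            "hba1c_pct": hba1c_pct,
            "hba1c_mmolmol": hba1c_mmolmol,
            "fasting_glucose": fasting,
            "glucose_2h": g2h,
            "diabetes": d_alpha,
            "prediabetes": d_beta,
            "diabetes_ext": d_gamma,
            "frac_subcutaneous": subcut,
            "frac_visceral_upper": visc_upper,
            "frac_visceral_lower": visc_lower,
            "frac_thigh": thigh,
            "frac_arm": arm,
            "frac_neck": neck,
            "frac_breast": breast,
            "slice_count": rng.integers(SLICE_RANGE[0], SLICE_RANGE[1] + 1, n),
            "phantom_seed": rng.integers(0, 2**31, n),
        }
    )
    if cfg.missing_rate > 0:
        for col in ("age", "bmi", "insulin_sensitivity", "hba1c_pct"):
            miss = rng.random(n) < cfg.missing_rate
            table.loc[miss, col] = np.nan
    return table


def generate_followup(labels: pd.DataFrame, cfg: LabelModelConfig, seed: int) -> pd.DataFrame:
    """Exponential event hazards increasing with baseline glycemia."""
    rng = np.random.default_rng(seed)
    n = len(labels)
    hba1c = labels["hba1c_pct"].to_numpy()
    hba1c = np.where(np.isnan(hba1c), cfg.hba1c_base_pct, hba1c)
    excess = np.clip(hba1c - cfg.hba1c_base_pct, 0, None)

    censor = np.minimum(rng.uniform(cfg.censor_min, cfg.censor_max, n), cfg.admin_censor)

    lam_dm = cfg.dm_base_hazard * np.exp(cfg.dm_hba1c_loghr * excess)
    t_dm = rng.exponential(1.0 / lam_dm)
    dm_event = (t_dm <= censor).astype(int)
    time_dm = np.minimum(t_dm, censor)

    uacr = np.exp(rng.normal(cfg.uacr_log_mean + cfg.uacr_hba1c_slope * excess, cfg.uacr_log_sd))
    lam_ma = cfg.ma_base_hazard * np.exp(cfg.ma_hba1c_loghr * excess)
    t_ma = rng.exponential(1.0 / lam_ma)
    ma_event = (t_ma <= censor).astype(int)
    time_ma = np.minimum(t_ma, censor)

    return pd.DataFrame(
        {
            "subject_id": labels["subject_id"].to_numpy(),
            "time_to_diabetes": time_dm,
            "diabetes_event": dm_event,
            "time_to_microalbuminuria": time_ma,
            "microalbuminuria_event": ma_event,
            "baseline_uacr": uacr,
        }
    )


def spec_from_row(row: pd.Series) -> PhantomSpec:
    fracs = {r: float(row[f"frac_{r}"]) for r in REGIONS}

    def _pos(v, default):
        return float(v) if np.isfinite(v) and v > 0 else default

    return PhantomSpec(
        sex=int(row["sex"]),
        age=_pos(row["age"], 48.0),
        bmi=_pos(row["bmi"], 28.0),
        insulin_sensitivity=_pos(row["insulin_sensitivity"], 10.0),
        hba1c_pct=_pos(row["hba1c_pct"], 5.4),
        fasting_glucose=float(row["fasting_glucose"]),
        glucose_2h=float(row["glucose_2h"]),
        depot_fractions=fracs,
        slice_count=int(row["slice_count"]),
        seed=int(row["phantom_seed"]),
    )


def generate_cohort(
    n: int,
    cfg: LabelModelConfig | None = None,
    seed: int = 0,
    profile: Profile | None = None,
) -> tuple[list[BodyVolume], pd.DataFrame, pd.DataFrame]:
    """Full cohort: phantom volumes, label table, follow-up table."""
    cfg = cfg or LabelModelConfig()
    profile = profile or Profile()
    labels = generate_labels(n, cfg, seed)
    followup = generate_followup(labels, cfg, seed + 1)
    volumes = []
    for _, row in labels.iterrows():
        vol = generate_phantom(spec_from_row(row), profile)
        vol.subject_id = row["subject_id"]
        volumes.append(vol)
    return volumes, labels, followup


def generate_embedding_mixture(
    n: int, cfg: EmbeddingMixtureConfig | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw embedding-like vectors from the default well-separated subtype mixture.

    Returns ``(X, z)`` with ``X`` of shape (n, dim) and ``z`` the true
    component of each draw.
    """
    cfg = cfg or EmbeddingMixtureConfig()
    if n < cfg.n_components:
        raise ValueError("n must be at least the number of components")
    rng = np.random.default_rng(seed)
    means = rng.normal(0.0, cfg.separation * cfg.within_sd, size=(cfg.n_components, cfg.dim))
    w = np.asarray(cfg.weights, dtype=float) if cfg.weights else np.full(cfg.n_components, 1.0 / cfg.n_components)
    w = w / w.sum()
    z = rng.choice(cfg.n_components, size=n, p=w)
    X = means[z] + rng.normal(0.0, cfg.within_sd, size=(n, cfg.dim))
    return X.astype(np.float32), z
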