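"""Synthetic longitudinal image cohort with a known continuous latent severity.

Real severity-graded cohorts (retinal photographs graded normal/pre-plus/plus,
knee radiographs graded KL 0-4) are restricted-access.  This module generates
a stand-in cohort whose images are a deterministic function of a latent
severity s in [0, 1], so that every downstream stage — metric learning,
anchor-pool scoring, change detection, occlusion mapping — can be validated
against ground truth.

Appearance model (all seeded, bit-identical under regeneration):

* a curvilinear bright "vessel" confined to an upper band, whose sinusoidal
  tortuosity amplitude grows linearly with s;
* up to four bright "lesion" blobs in a lower band (spatially disjoint from
  the vessel), whose count, radius and contrast grow monotonically with s;
  blob positions are fixed per imaging unit so longitudinal change is driven
  by severity alone;
* nuisance variation independent of s: a per-unit smooth background texture
  and global brightness offset (scaled by ``nuisance_level``), plus small
  per-visit white noise.

Ordinal grades are obtained by binning s at fixed thresholds; the marginal
grade distribution is controlled by ``grade_weights`` (the retina-mode
default reproduces the heavy normal-class imbalance of a real screening
cohort, 84/13/3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "CohortConfig",
    "rop_config",
    "knee_config",
    "latent_to_grade",
    "simulate_trajectory",
    "unit_appearance_params",
    "render_image",
    "generate_cohort",
    "split_by_patient",
    "load_manifest",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["patient_id", "unit_id", "timepoint", "latent_severity",
                    "grade", "image_path", "split"]

MAX_LESIONS = 4
# activation thresholds: lesion i fades in once s passes _LESION_ONSET[i]
_LESION_ONSET = (0.0, 0.3, 0.55, 0.8)
_LESION_RAMP = 0.25


@dataclass
class CohortConfig:
    """Generator configuration.

    ``timepoints_per_unit`` maps visit count -> probability.  ``mode`` is
    "rop" (severity may regress between visits) or "knee" (monotone
    non-decreasing severity, as radiographic osteoarthritis does not heal).
    """

    n_patients: int = 200
    units_per_patient: int = 2
    timepoints_per_unit: dict[int, float] = field(default_factory=lambda: {2: 0.25, 3: 0.5, 4: 0.25})
    n_grades: int = 3
    grade_thresholds: tuple[float, ...] = (0.5, 0.8)
    grade_weights: tuple[float, ...] = (0.84, 0.13, 0.03)
    image_size: tuple[int, int] = (64, 64)
    nuisance_level: float = 0.3
    progression_prob: float = 0.4
    increment_mean: float = 0.2
    regression_prob: float = 0.05
    decrement_mean: float = 0.1
    mode: str = "rop"
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if not 2 <= self.n_grades <= 10:
            raise ValueError("n_grades must be in 2..10")
        th = tuple(self.grade_thresholds)
        if len(th) != self.n_grades - 1:
            raise ValueError("need n_grades - 1 thresholds")
        if any(not 0 < t < 1 for t in th) or any(a >= b for a, b in zip(th, th[1:])):
            raise ValueError("grade_thresholds must be strictly increasing, all in (0,1)")
        w = np.asarray(self.grade_weights, dtype=float)
        if len(w) != self.n_grades or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("grade_weights must be a probability vector over grades")
        if self.mode not in ("rop", "knee"):
            raise ValueError("mode must be 'rop' or 'knee'")
        tp = self.timepoints_per_unit
        if abs(sum(tp.values()) - 1.0) > 1e-9 or any(t < 1 for t in tp):
            raise ValueError("timepoints_per_unit must be a distribution over counts >= 1")
        if not 0 <= self.nuisance_level <= 1:
            raise ValueError("nuisance_level must be in [0,1]")

    @property
    def effective_regression_prob(self) -> float:
        # knee-mode severity never decreases
        return 0.0 if self.mode == "knee" else self.regression_prob

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["timepoints_per_unit"] = {int(k): float(v) for k, v in d["timepoints_per_unit"].items()}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("grade_thresholds", "grade_weights", "image_size", "split_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        d["timepoints_per_unit"] = {int(k): float(v) for k, v in d["timepoints_per_unit"].items()}
        return cls(**d)


def rop_config(**overrides) -> CohortConfig:
    """Retina-mode defaults: 3 grades, 84/13/3 imbalance, regression allowed."""
    return CohortConfig(**overrides)


def knee_config(**overrides) -> CohortConfig:
    """Knee-mode defaults: 5 KL-like grades, monotone progression, 5 visits."""
    defaults = dict(
        n_grades=5,
        grade_thresholds=(0.25, 0.45, 0.65, 0.85),
        grade_weights=(0.35, 0.25, 0.2, 0.13, 0.07),
        timepoints_per_unit={5: 1.0},
        mode="knee",
        progression_prob=0.15,
        increment_mean=0.1,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def latent_to_grade(s: float, thresholds) -> int:
    """Grade = number of thresholds strictly below s (boundaries -> lower bin)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"latent severity {s} outside [0,1]")
    return int(sum(t < s for t in thresholds))


def simulate_trajectory(s0: float, n_timepoints: int, config: CohortConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Latent severity over visits: exponential jumps up (and, in retina
    mode, occasionally down), clipped to [0,1]."""
    if n_timepoints < 1:
        raise ValueError("need at least one timepoint")
    s = float(s0)
    out = [s]
    for _ in range(n_timepoints - 1):
        u_prog = rng.random()
        u_reg = rng.random()
        if u_prog < config.progression_prob:
            s += rng.exponential(config.increment_mean)
        elif u_reg < config.effective_regression_prob:
            s -= rng.exponential(config.decrement_mean)
        s = float(np.clip(s, 0.0, 1.0))
        out.append(s)
    return np.array(out)


def unit_appearance_params(rng: np.random.Generator, config: CohortConfig) -> dict:
    """Per-unit appearance parameters, fixed across that unit's visits."""
    h, w = config.image_size
    centers = np.column_stack([
        rng.uniform(0.52 * h, 0.85 * h, size=MAX_LESIONS),   # rows (lesion band)
        rng.uniform(0.12 * w, 0.88 * w, size=MAX_LESIONS),   # cols
    ])
    return {
        "lesion_centers": centers,
        "lesion_radius_jitter": rng.uniform(0.8, 1.2, size=MAX_LESIONS),
        "vessel_y0": (0.22 + rng.uniform(-0.03, 0.03)) * h,
        "vessel_freq": rng.uniform(1.2, 2.2),
        "vessel_phase": rng.uniform(0, 2 * np.pi),
        "texture_seed": int(rng.integers(0, 2**31 - 1)),
        "brightness_offset": rng.uniform(-0.1, 0.1),
    }


def lesion_amplitude(s: float, i: int) -> float:
    """Contrast of lesion i at severity s; monotone non-decreasing in s."""
    ramp = np.clip((s - _LESION_ONSET[i]) / _LESION_RAMP, 0.0, 1.0)
    return float((0.12 + 0.6 * s) * ramp)


def lesion_radius(s: float, i: int, unit: dict, image_size) -> float:
    h = image_size[0]
    return float((0.05 + 0.04 * s) * h * unit["lesion_radius_jitter"][i])


def render_image(s: float, unit: dict, config: CohortConfig,
                 visit_rng: np.random.Generator | None = None) -> tuple[np.ndarray, dict]:
    """Render one grayscale image for severity ``s``.

    Returns (image in [0,1], info) where ``info`` lists each lesion's
    center/radius/amplitude (used for localization checks).
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("latent severity outside [0,1]")
    h, w = config.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    img = np.full((h, w), 0.12)

    # nuisance: unit texture + brightness offset, independent of s
    if config.nuisance_level > 0:
        tex_rng = np.random.default_rng(unit["texture_seed"])
        texture = gaussian_filter(tex_rng.standard_normal((h, w)), sigma=3.0)
        texture /= max(texture.std(), 1e-12)
        img += config.nuisance_level * (0.08 * texture + unit["brightness_offset"])

    # vessel: sinusoid whose amplitude (tortuosity) grows with s
    amp = (0.02 + 0.10 * s) * h
    yc = unit["vessel_y0"] + amp * np.sin(
        2 * np.pi * unit["vessel_freq"] * np.arange(w) / w + unit["vessel_phase"])
    img += 0.35 * np.exp(-((yy - yc[None, :]) ** 2) / (2 * 1.2**2))

    lesions = []
    for i in range(MAX_LESIONS):
        a = lesion_amplitude(s, i)
        r = lesion_radius(s, i, unit, config.image_size)
        cy, cx = unit["lesion_centers"][i]
        if a > 0:
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            img += a * np.exp(-(d2 / r**2) ** 2)
        lesions.append({"cy": float(cy), "cx": float(cx), "radius": r, "amplitude": a})

    if visit_rng is not None:
        img += 0.015 * visit_rng.standard_normal((h, w))

    return np.clip(img, 0.0, 1.0), {"lesions": lesions, "severity": float(s)}


def _draw_initial_severity(rng: np.random.Generator, config: CohortConfig) -> float:
    """Initial severity: grade ~ grade_weights, then uniform within the bin."""
    g = int(rng.choice(config.n_grades, p=np.asarray(config.grade_weights, dtype=float)))
    edges = (0.0,) + tuple(config.grade_thresholds) + (1.0,)
    return float(rng.uniform(edges[g], edges[g + 1]))


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> pd.DataFrame:
    """Generate images + manifest; returns the manifest DataFrame.

    Writes 8-bit grayscale PNGs under ``out_dir/images`` and the manifest as
    ``out_dir/manifest.csv`` (columns patient_id, unit_id, timepoint,
    latent_severity, grade, image_path, split; image paths relative to
    ``out_dir``).  Regeneration with the same config is bit-identical.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    if not img_dir.is_dir():
        raise OSError(f"cannot create image directory {img_dir}")

    tp_counts = sorted(config.timepoints_per_unit)
    tp_probs = np.array([config.timepoints_per_unit[t] for t in tp_counts], dtype=float)

    root_ss = np.random.SeedSequence(config.seed)
    patient_ss = root_ss.spawn(config.n_patients)

    rows = []
    for p_idx in range(config.n_patients):
        pid = f"P{p_idx:04d}"
        unit_children = patient_ss[p_idx].spawn(config.units_per_patient)
        for u_idx in range(config.units_per_patient):
            unit_id = f"{pid}_U{u_idx}"
            unit_ss, traj_ss, visit_root = unit_children[u_idx].spawn(3)
            unit_rng = np.random.default_rng(unit_ss)
            traj_rng = np.random.default_rng(traj_ss)

            unit = unit_appearance_params(unit_rng, config)
            n_tp = int(unit_rng.choice(tp_counts, p=tp_probs))
            s0 = _draw_initial_severity(unit_rng, config)
            traj = simulate_trajectory(s0, n_tp, config, traj_rng)

            for t, s in enumerate(traj):
                visit_rng = np.random.default_rng(visit_root.spawn(n_tp)[t])
                img, _ = render_image(float(s), unit, config, visit_rng)
                rel = f"images/{unit_id}_T{t}.png"
                Image.fromarray(np.round(img * 255).astype(np.uint8), mode="L").save(out_dir / rel)
                rows.append({
                    "patient_id": pid,
                    "unit_id": unit_id,
                    "timepoint": t,
                    "latent_severity": float(s),
                    "grade": latent_to_grade(float(s), config.grade_thresholds),
                    "image_path": rel,
                    "split": "",
                })

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest = split_by_patient(manifest, config.split_fractions,
                                seed=int(root_ss.generate_state(1)[0] % (2**31)))
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _largest_remainder_counts(n: int, fractions) -> list[int]:
    exact = np.asarray(fractions, dtype=float) * n
    counts = np.floor(exact).astype(int)
    remainders = exact - counts
    # ties broken toward the earlier split, deterministically
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def split_by_patient(manifest: pd.DataFrame, fractions=(0.8, 0.1, 0.1),
                     seed: int = 0) -> pd.DataFrame:
    """Patient-level train/val/test assignment with largest-remainder rounding.

    Every image of a patient shares that patient's split, so no patient leaks
    across splits.
    """
    fractions = tuple(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    names = ["train", "val", "test"][: len(fractions)]
    if len(fractions) != 3:
        raise ValueError("expected three fractions (train, val, test)")
    patients = sorted(manifest["patient_id"].unique())
    if len(patients) < len(fractions):
        raise ValueError(f"need at least {len(fractions)} patients, got {len(patients)}")
    counts = _largest_remainder_counts(len(patients), fractions)
    perm = np.random.default_rng(seed).permutation(len(patients))
    assignment = {}
    start = 0
    for name, cnt in zip(names, counts):
        for idx in perm[start : start + cnt]:
            assignment[patients[idx]] = name
        start += cnt
    out = manifest.copy()
    out["split"] = out["patient_id"].map(assignment)
    return out


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV; image_path is resolved relative to its folder."""
    path = Path(path)
    manifest = pd.read_csv(path, dtype={"patient_id": str, "unit_id": str})
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    manifest["image_path"] = [str(path.parent / p) for p in manifest["image_path"]]
    dup = manifest.duplicated(subset=["unit_id", "timepoint"])
    if dup.any():
        raise ValueError("duplicate (unit_id, timepoint) rows in manifest")
    return manifest
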