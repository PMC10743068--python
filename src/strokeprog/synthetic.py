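"""Synthetic phantoms and cohorts with the statistical structure the models
assume.

The NCCT phantoms are ellipsoidal brain-like volumes, mirror-symmetric
about the midsagittal plane up to noise, in which a unilateral hypodense
spherical lesion is planted with a configurable probability; the planted
lesion drives the poor-outcome label.  The CTA phantoms add bright
branching vessel structures, symmetric across the MSP within the axial MIP
window, with one hemisphere's branch attenuated in occlusion-positive
subjects.  The cohort generator draws the eight predictor variables with
marginals anchored to the study population (age median 71, NIHSS median
7.5, glucose median 120, ASPECTS median 10, occlusion prevalence 50%) and
an outcome from a logistic model with known coefficients, calibrated by
default to 34% poor-outcome prevalence.

These are geometric primitives, not anatomy: they exercise exactly the
invariants (symmetry, planted asymmetry, logistic structure) that the
architectures and the fusion models exploit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import TEMPLATE_SHAPES, Volume3D, save_volume

# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    grid: str = "mni-2mm"
    shape: tuple[int, int, int] | None = None  # downscaled override
    n_subjects: int = 100
    lesion_prob: float = 0.5
    lesion_intensity_delta: float = -12.0      # HU-like hypodensity
    lesion_radius_range: tuple[int, int] | None = None
    vessel_tree: bool = False
    vessel_intensity: float = 180.0
    occlusion_attenuation: float = 0.25
    base_noise_std: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.shape is None:
            self.shape = TEMPLATE_SHAPES[self.grid]
        if self.lesion_radius_range is None:
            # ~11-20% of the LR extent, the scale of a sizeable MCA infarct
            lo = max(2, round(0.11 * self.shape[0]))
            hi = max(lo + 1, round(0.20 * self.shape[0]))
            self.lesion_radius_range = (lo, hi)


@dataclass
class PhantomSubject:
    volume: Volume3D
    label: int                      # 1 = poor outcome / occlusion present
    lesion_mask: np.ndarray | None  # boolean, ground truth
    side: str | None                # 'left' | 'right' | None


def _ellipsoid_mask(shape) -> np.ndarray:
    nx, ny, nz = shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    r = (((x - cx) / (0.45 * nx)) ** 2 + ((y - cy) / (0.45 * ny)) ** 2
         + ((z - cz) / (0.45 * nz)) ** 2)
    return r <= 1.0


def _symmetrize(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + a[::-1])


def _noise(rng, shape, std) -> np.ndarray:
    """Mostly MSP-symmetric noise: a symmetric field of scale `std` plus an
    asymmetric residual at std/2, so mirror-subtraction residuals stay well
    below the planted-lesion contrast."""
    sym = _symmetrize(rng.normal(0.0, std * np.sqrt(2.0), shape))
    asym = rng.normal(0.0, std / 2.0, shape)
    return (sym + asym).astype(np.float32)


def _sphere(shape, center, radius) -> np.ndarray:
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return ((x - center[0]) ** 2 + (y - center[1]) ** 2
            + (z - center[2]) ** 2) <= radius ** 2


def _sample_lesion(rng, shape, brain, radius_range):
    """A unilateral sphere fully inside one hemisphere of the brain mask."""
    nx = shape[0]
    for _ in range(200):
        radius = int(rng.integers(radius_range[0], radius_range[1] + 1))
        side = "left" if rng.random() < 0.5 else "right"
        if side == "left":
            lo, hi = radius, nx // 2 - radius - 1
        else:
            lo, hi = nx // 2 + radius + 1, nx - radius
        if hi <= lo:
            continue
        cx = int(rng.integers(lo, hi))
        cy = int(rng.integers(radius, shape[1] - radius))
        cz = int(rng.integers(radius, shape[2] - radius))
        mask = _sphere(shape, (cx, cy, cz), radius)
        if brain[mask].mean() > 0.95:  # fully inside brain tissue
            return mask, side
    raise ValueError("lesion radius range incompatible with the hemisphere size")


def gen_ncct_phantoms(spec: PhantomSpec) -> list[PhantomSubject]:
    """Brain-like NCCT phantoms with planted unilateral hypodense lesions."""
    if max(spec.lesion_radius_range) * 2 + 2 >= spec.shape[0]:
        raise ValueError("lesion radius exceeds the hemisphere extent")
    rng = np.random.default_rng(spec.seed)
    brain = _ellipsoid_mask(spec.shape)
    nx, ny, nz = spec.shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    r2 = (((x - (nx - 1) / 2) / (0.45 * nx)) ** 2
          + ((y - (ny - 1) / 2) / (0.45 * ny)) ** 2
          + ((z - (nz - 1) / 2) / (0.45 * nz)) ** 2)
    base = (32.0 - 6.0 * r2).astype(np.float32)  # 26-32 HU-like interior
    subjects = []
    for _ in range(spec.n_subjects):
        vox = np.zeros(spec.shape, dtype=np.float32)
        interior = base + _noise(rng, spec.shape, spec.base_noise_std)
        positive = rng.random() < spec.lesion_prob
        mask, side = (None, None)
        if positive:
            mask, side = _sample_lesion(rng, spec.shape, brain,
                                        spec.lesion_radius_range)
            interior = interior + spec.lesion_intensity_delta * mask
        vox[brain] = interior[brain]
        subjects.append(PhantomSubject(
            volume=Volume3D(vox, template="free",
                            spacing=(2.0, 2.0, 2.0) if spec.grid == "mni-2mm" else (1.0,) * 3),
            label=int(positive),
            lesion_mask=(mask & brain) if mask is not None else None,
            side=side))
    return subjects


def _half_vessel_tree(rng, shape, z_lo, z_hi):
    """Random branching polylines confined to the left hemisphere, running
    within the axial MIP window.  Returns a list of branches (arrays of
    voxel coordinates), proximal to distal."""
    nx, ny, nz = shape
    n_steps = max(8, nx // 3)
    branches = []
    # main stem: starts near the midline, runs laterally and superiorly
    start = np.array([nx // 2 - 2, ny * 0.5, (z_lo + z_hi) / 2], dtype=float)
    for b in range(3):
        pos = start.copy()
        direction = np.array([-1.0, rng.uniform(-0.6, 0.6), rng.uniform(-0.3, 0.3)])
        direction /= np.linalg.norm(direction)
        pts = []
        for _ in range(n_steps):
            pos = pos + direction * 1.5
            direction = direction + rng.normal(0, 0.25, 3)
            direction[0] = min(direction[0], -0.2)  # keep moving laterally
            direction /= np.linalg.norm(direction)
            p = np.round(pos).astype(int)
            if not (1 <= p[0] < nx // 2 - 1 and 1 <= p[1] < ny - 1):
                break
            p[2] = np.clip(p[2], z_lo, z_hi)
            pts.append(p.copy())
        if pts:
            branches.append(np.array(pts))
    return branches


def _paint(vox, points, value, radius=1):
    for p in points:
        sl = tuple(slice(max(0, c - radius), c + radius + 1) for c in p)
        vox[sl] = np.maximum(vox[sl], value)


def gen_cta_phantoms(spec: PhantomSpec):
    """CTA phantoms: symmetric bright vessel trees inside the MIP window;
    occlusion-positive subjects have one hemisphere's distal branch
    attenuated.  Yields PhantomSubject lazily (full-resolution volumes are
    large)."""
    if not spec.vessel_tree:
        raise ValueError("gen_cta_phantoms requires vessel_tree=True")
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    nz = shape[2]
    z_lo, z_hi = round(45 / 182 * nz), min(nz - 1, round(100 / 182 * nz))
    brain = _ellipsoid_mask(shape)
    spacing = (1.0, 1.0, 1.0) if spec.grid == "mni-1mm" else (2.0, 2.0, 2.0)
    for _ in range(spec.n_subjects):
        vox = np.zeros(shape, dtype=np.float32)
        interior = 35.0 + _noise(rng, shape, spec.base_noise_std)
        vox[brain] = interior[brain]
        branches = _half_vessel_tree(rng, shape, z_lo, z_hi)
        positive = rng.random() < spec.lesion_prob
        occluded_side = ("left" if rng.random() < 0.5 else "right") if positive else None
        # distal half of one branch is attenuated on the occluded side
        occluded_branch = int(rng.integers(len(branches))) if positive else -1
        half_trees = {"left": vox, "right": np.zeros_like(vox)}
        vessel_mask = np.zeros(shape, dtype=bool)
        for b, pts in enumerate(branches):
            left_val = spec.vessel_intensity
            right_val = spec.vessel_intensity
            split = len(pts) // 2
            prox, dist = pts[:split], pts[split:]
            for seg_pts, seg_scale in ((prox, 1.0), (dist, spec.occlusion_attenuation)):
                lv = left_val * (seg_scale if (b == occluded_branch and
                                               occluded_side == "left") else 1.0)
                rv = right_val * (seg_scale if (b == occluded_branch and
                                                occluded_side == "right") else 1.0)
                _paint(vox, seg_pts, lv)
                mirrored = seg_pts.copy()
                mirrored[:, 0] = shape[0] - 1 - mirrored[:, 0]
                _paint(vox, mirrored, rv)
                for p in np.concatenate([seg_pts, mirrored]):
                    vessel_mask[tuple(p)] = True
        yield PhantomSubject(
            volume=Volume3D(vox, template="free", spacing=spacing),
            label=int(positive), lesion_mask=vessel_mask,
            side=occluded_side)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

#: per-standard-deviation log-odds of poor 90-day outcome
DEFAULT_COEFFICIENTS = {
    "age": 0.9, "nihss": 1.2, "delay": 0.1, "visual_defect": 0.15,
    "loc": 0.25, "glucose": 0.25, "aspects": -0.35, "occlusion": 0.4,
}

PREDICTORS = tuple(DEFAULT_COEFFICIENTS)

_ASPECTS_P = np.array([0.005, 0.005, 0.01, 0.02, 0.03, 0.04, 0.05,
                       0.07, 0.10, 0.12, 0.55])


@dataclass
class CohortSpec:
    n: int = 1000
    outcome_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    intercept: float | None = None       # calibrated to target_prevalence if None
    target_prevalence: float = 0.34      # poor outcome (mRS > 2)
    missing_rate: float = 0.0
    seed: int = 0


def _lognormal(rng, median, q1, q3, size):
    mu = np.log(median)
    sigma = np.log(q3 / q1) / (2 * 0.6744897501960817)
    return rng.lognormal(mu, sigma, size)


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a patient table with study-like marginals and a logistic
    outcome; returns (table, truth) where truth holds the generating
    coefficients (per-SD log-odds) and intercept for recovery tests."""
    if not all(np.isfinite(list(spec.outcome_coefficients.values()))):
        raise ValueError("outcome coefficients must be finite")
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    df = pd.DataFrame({
        "age": np.clip(rng.normal(71, 17, n), 18, 100).round(0),
        "nihss": np.clip(_lognormal(rng, 7.5, 3, 14, n), 0, 42).round(0),
        "delay": np.clip(_lognormal(rng, 2, 1, 5, n), 0.1, 72).round(2),
        "visual_defect": (rng.random(n) < 0.38).astype(int),
        "loc": (rng.random(n) < 0.08).astype(int),
        "glucose": np.clip(_lognormal(rng, 120, 101, 154, n), 40, 500).round(0),
        "aspects": rng.choice(11, size=n, p=_ASPECTS_P),
        "occlusion": (rng.random(n) < 0.50).astype(int),
    })
    z = (df[list(spec.outcome_coefficients)]
         - df[list(spec.outcome_coefficients)].mean()) / df[
             list(spec.outcome_coefficients)].std(ddof=0).replace(0.0, 1.0)
    linear = z.to_numpy() @ np.array(list(spec.outcome_coefficients.values()))
    if spec.intercept is None:
        lo, hi = -20.0, 20.0
        for _ in range(80):  # calibrate the expected prevalence by bisection
            mid = (lo + hi) / 2
            if np.mean(1 / (1 + np.exp(-(linear + mid)))) < spec.target_prevalence:
                lo = mid
            else:
                hi = mid
        intercept = (lo + hi) / 2
    else:
        intercept = spec.intercept
    p_poor = 1 / (1 + np.exp(-(linear + intercept)))
    poor = rng.random(n) < p_poor
    mrs = np.where(poor, rng.integers(3, 7, n), rng.integers(0, 3, n))
    df["mrs90"] = mrs
    if spec.missing_rate > 0:
        for col in PREDICTORS:
            mask = rng.random(n) < spec.missing_rate
            df.loc[mask, col] = np.nan
    truth = {"coefficients": dict(spec.outcome_coefficients),
             "intercept": float(intercept),
             "target_prevalence": spec.target_prevalence}
    return df, truth


# ---------------------------------------------------------------------------
# on-disk fixtures
# ---------------------------------------------------------------------------

def write_demo_dataset(out_dir, n_ncct=200, n_cta=150, n_cohort=1000, seed=0,
                       ncct_shape=(46, 55, 46), cta_shape=(46, 56, 46)):
    """Materialize a full demo dataset: NCCT/CTA phantom NIfTIs with
    ground-truth masks, plus a cohort table with a truth sidecar."""
    from pathlib import Path

    out = Path(out_dir)
    (out / "ncct").mkdir(parents=True, exist_ok=True)
    (out / "cta").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(gen_ncct_phantoms(PhantomSpec(
            n_subjects=n_ncct, shape=ncct_shape, seed=seed))):
        save_volume(s.volume, out / "ncct" / f"sub-{i:04d}.nii.gz")
        if s.lesion_mask is not None:
            save_volume(Volume3D(s.lesion_mask.astype(np.float32),
                                 spacing=s.volume.spacing),
                        out / "ncct" / f"sub-{i:04d}_mask.nii.gz")
        rows.append(("ncct", i, s.label, s.side or ""))
    for i, s in enumerate(gen_cta_phantoms(PhantomSpec(
            n_subjects=n_cta, shape=cta_shape, vessel_tree=True, seed=seed + 1))):
        save_volume(s.volume, out / "cta" / f"sub-{i:04d}.nii.gz")
        rows.append(("cta", i, s.label, s.side or ""))
    with open(out / "labels.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["modality", "subject", "label", "side"])
        w.writerows(rows)
    cohort, truth = gen_cohort(CohortSpec(n=n_cohort, seed=seed + 2))
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    with open(out / "cohort_truth.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["variable", "per_sd_log_odds"])
        for k, v in truth["coefficients"].items():
            w.writerow([k, v])
        w.writerow(["intercept", truth["intercept"]])
    return out
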