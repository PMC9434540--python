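"""Synthetic chest-phantom cohort generator.

Produces identity-structured 8-bit grayscale "radiographs" plus metadata in
the ChestX-ray14 CSV dialect, so the whole verification/retrieval pipeline
is exercisable without any external download. Each patient is a geometric
latent (lung ellipses, rib arcs, heart ellipse, clavicles, diaphragm, body
width); each image of that patient re-renders the latent under acquisition
nuisance (windowing, rotation, scaling, translation, additive noise, view
flip, aging drift across follow-up years) and optional disease marks that
alter pixels and finding labels jointly.

The phantom is deliberately schematic: it emulates the identity-vs-nuisance
structure of a longitudinal chest X-ray archive, not radiographic physics.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .cohort import Cohort, ImageRecord, NO_FINDING, write_metadata

PATHOLOGIES = ("Cardiomegaly", "Effusion", "Infiltration",
               "Mass", "Nodule", "Pneumothorax")


@dataclasses.dataclass
class IdentityLatent:
    """Patient-level geometry, in canvas fractions / degrees."""

    body_width: float               # silhouette width fraction of canvas
    lung_ax: float                  # lung semi-axis, x
    lung_ay: float                  # lung semi-axis, y
    lung_cy: float                  # lung center height
    lung_gap: float                 # lung center offset from midline
    rib_count: int
    rib_curvature: float
    heart_ax: float
    heart_ay: float
    heart_dx: float                 # leftward heart offset
    heart_cy: float
    clavicle_angle: float           # degrees from horizontal
    diaphragm_amp: float


@dataclasses.dataclass
class DiseaseMark:
    label: str
    cx: float                       # blob center (canvas fraction)
    cy: float
    radius: float
    amplitude: float


@dataclasses.dataclass
class AcquisitionNuisance:
    """Concrete per-image acquisition parameters; defaults are 'none'."""

    window_center: float = 0.5
    window_width: float = 1.0
    rotation_deg: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)   # (dy, dx) canvas fractions
    noise_sd: float = 0.0
    noise_seed: int = 0
    view: str = "PA"
    age_gap_years: int = 0
    aging_scale_per_year: float = 0.006
    aging_diaphragm_per_year: float = 0.004
    disease_marks: tuple[DiseaseMark, ...] = ()

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.view not in ("PA", "AP"):
            raise ValueError("view must be 'PA' or 'AP'")


@dataclasses.dataclass
class NuisanceRanges:
    """Sampling ranges for acquisition nuisance; ``scaled`` rescales them."""

    rotation_deg: float = 4.0
    scale_jitter: float = 0.05
    translation_frac: float = 0.03
    window_center_sd: float = 0.04
    window_width_jitter: float = 0.15
    noise_sd: float = 0.02
    view_flip_prob: float = 0.1
    aging_scale_per_year: float = 0.006
    aging_diaphragm_per_year: float = 0.004

    def scaled(self, level: float) -> "NuisanceRanges":
        return NuisanceRanges(
            rotation_deg=self.rotation_deg * level,
            scale_jitter=self.scale_jitter * level,
            translation_frac=self.translation_frac * level,
            window_center_sd=self.window_center_sd * level,
            window_width_jitter=self.window_width_jitter * level,
            noise_sd=self.noise_sd * level,
            view_flip_prob=self.view_flip_prob,
            aging_scale_per_year=self.aging_scale_per_year,
            aging_diaphragm_per_year=self.aging_diaphragm_per_year)


@dataclasses.dataclass
class PhantomConfig:
    n_patients: int = 200
    canvas_side: int = 64
    images_per_patient_poisson: float = 2.5      # count = 1 + Poisson(rate)
    nuisance: NuisanceRanges = dataclasses.field(default_factory=NuisanceRanges)
    disease_base_prob: float = 0.3               # persistent baseline finding
    disease_new_prob: float = 0.15               # new finding per follow-up
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.canvas_side < 32:
            raise ValueError("canvas side must be >= 32")


def sample_identity(rng: np.random.Generator) -> IdentityLatent:
    """Draw patient geometry from documented uniform ranges."""
    return IdentityLatent(
        body_width=rng.uniform(0.58, 0.82),
        lung_ax=rng.uniform(0.11, 0.18),
        lung_ay=rng.uniform(0.2, 0.3),
        lung_cy=rng.uniform(0.4, 0.48),
        lung_gap=rng.uniform(0.14, 0.2),
        rib_count=int(rng.integers(4, 8)),
        rib_curvature=rng.uniform(0.08, 0.3),
        heart_ax=rng.uniform(0.1, 0.17),
        heart_ay=rng.uniform(0.09, 0.15),
        heart_dx=rng.uniform(0.02, 0.09),
        heart_cy=rng.uniform(0.55, 0.64),
        clavicle_angle=rng.uniform(4.0, 22.0),
        diaphragm_amp=rng.uniform(0.02, 0.09))


def _ellipse_mask(yy, xx, cy, cx, ay, ax):
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def render_image(latent: IdentityLatent, nuisance: AcquisitionNuisance,
                 side: int) -> np.ndarray:
    """Deterministic rendering: geometry, then windowing, then noise."""
    # aging drift: a slow global rescale plus a rising diaphragm dome
    gap = nuisance.age_gap_years
    aging_scale = 1.0 + gap * nuisance.aging_scale_per_year
    lat = dataclasses.replace(latent, diaphragm_amp=latent.diaphragm_amp
                              + gap * nuisance.aging_diaphragm_per_year)

    yy, xx = np.meshgrid(np.linspace(0, 1, side), np.linspace(0, 1, side),
                         indexing="ij")
    img = np.full((side, side), 0.08)
    # body silhouette
    img[_ellipse_mask(yy, xx, 0.55, 0.5, 0.46, lat.body_width / 2)] = 0.55
    # lungs (air: dark)
    heart_ax, heart_dx = lat.heart_ax, lat.heart_dx
    if nuisance.view == "AP":
        heart_ax *= 1.12            # AP projection magnifies the heart shadow
    lungs = np.zeros_like(img, dtype=bool)
    for sign in (-1, 1):
        cx = 0.5 + sign * lat.lung_gap
        m = _ellipse_mask(yy, xx, lat.lung_cy, cx, lat.lung_ay, lat.lung_ax)
        lungs |= m
    img[lungs] = 0.22
    # ribs: bright parabolic bands across each lung
    for sign in (-1, 1):
        cx = 0.5 + sign * lat.lung_gap
        in_lung = _ellipse_mask(yy, xx, lat.lung_cy, cx, lat.lung_ay, lat.lung_ax)
        for k in range(lat.rib_count):
            frac = (k + 0.5) / lat.rib_count
            y0 = lat.lung_cy - lat.lung_ay + 2 * lat.lung_ay * frac
            curve = y0 + lat.rib_curvature * ((xx - cx) / max(lat.lung_ax, 1e-6)) ** 2 * 0.1
            band = np.abs(yy - curve) < (0.75 / side)
            img[band & in_lung] = 0.5
    # heart shadow (patient left = image right in PA)
    img[_ellipse_mask(yy, xx, lat.heart_cy, 0.5 + heart_dx, lat.heart_ay,
                      heart_ax)] = 0.68
    # clavicles: slanted bright lines near the apex
    slope = np.tan(np.deg2rad(lat.clavicle_angle))
    for sign in (-1, 1):
        line = 0.24 + slope * sign * (xx - 0.5)
        band = (np.abs(yy - line) < (0.9 / side)) & (np.abs(xx - 0.5) < lat.body_width / 2.2) \
            & (np.abs(xx - 0.5) > 0.04)
        img[band] = 0.62
    # diaphragm: bright dome under the lungs
    dome = lat.lung_cy + lat.lung_ay + lat.diaphragm_amp * np.sin(
        np.pi * np.clip((xx - (0.5 - lat.body_width / 2)) / lat.body_width, 0, 1))
    below = (yy > dome) & (yy < dome + 0.12) & (np.abs(xx - 0.5) < lat.body_width / 2)
    img[below] = 0.6
    # disease marks: soft bright blobs, joint with labels
    for mark in nuisance.disease_marks:
        d2 = (yy - mark.cy) ** 2 + (xx - mark.cx) ** 2
        img += mark.amplitude * np.exp(-d2 / (2 * mark.radius ** 2))
    if nuisance.view == "AP":
        img = img[:, ::-1]
    # geometric nuisance: rotation + scale (incl. aging) + translation
    total_scale = nuisance.scale * aging_scale
    if nuisance.rotation_deg or total_scale != 1.0 or any(nuisance.translation):
        theta = np.deg2rad(nuisance.rotation_deg)
        c, s = np.cos(theta), np.sin(theta)
        mat = np.array([[c, -s], [s, c]]) / total_scale
        center = np.array([(side - 1) / 2, (side - 1) / 2])
        shift = np.array(nuisance.translation) * side
        offset = center - mat @ (center + shift)
        img = ndimage.affine_transform(img, mat, offset=offset, order=1,
                                       mode="constant", cval=0.08)
    # windowing (contrast/brightness), then additive noise
    lo = nuisance.window_center - nuisance.window_width / 2
    img = np.clip((img - lo) / nuisance.window_width, 0.0, 1.0)
    if nuisance.noise_sd > 0:
        noise_rng = np.random.default_rng(nuisance.noise_seed)
        img = img + noise_rng.normal(0.0, nuisance.noise_sd, size=img.shape)
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


def sample_nuisance(rng: np.random.Generator, ranges: NuisanceRanges,
                    age_gap_years: int = 0,
                    disease_marks: Sequence[DiseaseMark] = ()) -> AcquisitionNuisance:
    return AcquisitionNuisance(
        window_center=0.5 + rng.normal(0.0, ranges.window_center_sd),
        window_width=1.0 + rng.uniform(-ranges.window_width_jitter,
                                       ranges.window_width_jitter),
        rotation_deg=rng.uniform(-ranges.rotation_deg, ranges.rotation_deg),
        scale=1.0 + rng.uniform(-ranges.scale_jitter, ranges.scale_jitter),
        translation=(rng.uniform(-ranges.translation_frac, ranges.translation_frac),
                     rng.uniform(-ranges.translation_frac, ranges.translation_frac)),
        noise_sd=ranges.noise_sd,
        noise_seed=int(rng.integers(2 ** 31)),
        view="AP" if rng.random() < ranges.view_flip_prob else "PA",
        age_gap_years=age_gap_years,
        aging_scale_per_year=ranges.aging_scale_per_year,
        aging_diaphragm_per_year=ranges.aging_diaphragm_per_year,
        disease_marks=tuple(disease_marks))


def _mark_for(label: str, rng: np.random.Generator) -> DiseaseMark:
    side_sign = -1 if rng.random() < 0.5 else 1
    return DiseaseMark(label=label,
                       cx=0.5 + side_sign * rng.uniform(0.08, 0.2),
                       cy=rng.uniform(0.3, 0.6),
                       radius=rng.uniform(0.02, 0.05),
                       amplitude=rng.uniform(0.15, 0.3))


def generate_cohort(config: PhantomConfig, out_dir: str | pathlib.Path
                    ) -> Cohort:
    """Render a phantom cohort to ``out_dir`` (PNGs + metadata.csv + manifest).

    All randomness flows from ``config.seed`` through three named substreams
    (identity, nuisance, labels); a fixed config reproduces the cohort
    byte-for-byte.
    """
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    id_rng, nui_rng, lab_rng = (np.random.default_rng(c) for c in ss.spawn(3))

    records = []
    for p in range(config.n_patients):
        latent = sample_identity(id_rng)
        n_images = 1 + int(id_rng.poisson(config.images_per_patient_poisson))
        base_age = int(id_rng.integers(20, 81))
        sex = "M" if id_rng.random() < 0.5 else "F"
        patient_id = str(p + 1)

        baseline: list[DiseaseMark] = []
        if lab_rng.random() < config.disease_base_prob:
            baseline.append(_mark_for(
                PATHOLOGIES[int(lab_rng.integers(len(PATHOLOGIES)))], lab_rng))
        marks = list(baseline)
        age_gap = 0
        for k in range(n_images):
            if k > 0:
                age_gap += int(nui_rng.poisson(1.2))
                if lab_rng.random() < config.disease_new_prob:
                    existing = {m.label for m in marks}
                    candidates = [x for x in PATHOLOGIES if x not in existing]
                    if candidates:
                        marks = marks + [_mark_for(
                            candidates[int(lab_rng.integers(len(candidates)))], lab_rng)]
            nuisance = sample_nuisance(nui_rng, config.nuisance,
                                       age_gap_years=age_gap,
                                       disease_marks=marks)
            pixels = render_image(latent, nuisance, config.canvas_side)
            fname = f"{p + 1:08d}_{k:03d}.png"
            Image.fromarray(pixels).save(out_dir / fname)
            findings = frozenset(m.label for m in marks) or frozenset({NO_FINDING})
            records.append(ImageRecord(
                image_id=pathlib.Path(fname).stem,
                patient_id=patient_id,
                follow_up_index=k,
                age_years=base_age + age_gap,
                sex=sex,
                view=nuisance.view,
                findings=findings,
                image_path=out_dir / fname))
    cohort = Cohort(records)
    write_metadata(cohort, out_dir / "metadata.csv")
    manifest = {"seed": config.seed, "n_patients": config.n_patients,
                "canvas_side": config.canvas_side,
                "n_images": len(records),
                "nuisance": dataclasses.asdict(config.nuisance)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cohort
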