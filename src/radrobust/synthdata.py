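"""Synthetic lesion phantoms and feature-level simulations.

Phantoms are minimal structures that exercise every downstream stage —
masses are smooth blobs with irregular (low-frequency radially
perturbed) boundaries on a textured background, calcifications are
clusters of bright specks inside an enclosing region — with ground-truth
masks that keep enough border margin for morphological dilation never to
clip.  Malignant pathology raises core intensity and within-mask
heterogeneity by documented, configurable effect sizes.

Everything is deterministic given the seed.  No realism is attempted
(no projection physics, no BI-RADS modelling).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import (
    ABNORMALITIES,
    PATHOLOGIES,
    VIEWS,
    GreyImage,
    LesionRecord,
    PhantomCase,
)


@dataclass(frozen=True)
class PhantomConfig:
    """Generator parameters, all expressed as fractions of the dynamic range.

    ``malignant_intensity_gain`` (+15% core intensity) and
    ``malignant_variance_gain`` (+30% within-mask variance) encode the
    benign→malignant effect; both are applied multiplicatively after all
    random draws so the same seed yields the same lesion geometry for
    either pathology.
    """

    bitdepth: int = 16
    background_level: float = 0.25
    background_texture_sd: float = 0.02
    noise_sd: float = 0.005
    mass_core: float = 0.45
    calc_region_elevation: float = 0.08
    calc_speck_intensity: float = 0.50
    boundary_irregularity: float = 0.12
    malignant_intensity_gain: float = 1.15
    malignant_variance_gain: float = 1.30


def _smooth_noise(shape: tuple[int, int], rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Unit-variance low-frequency noise field."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return field / field.std()


def _radial_boundary(
    radius: float, irregularity: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fourier coefficients (amplitudes, phases) of the boundary perturbation."""
    harmonics = np.arange(2, 6)
    amps = rng.uniform(-irregularity / 2, irregularity / 2, size=harmonics.size)
    phases = rng.uniform(0, 2 * np.pi, size=harmonics.size)
    return amps, phases


def _boundary_radius(theta: np.ndarray, radius: float, amps: np.ndarray, phases: np.ndarray) -> np.ndarray:
    k = np.arange(2, 2 + amps.size)
    pert = np.sum(amps[:, None] * np.cos(k[:, None] * theta.ravel()[None, :] + phases[:, None]), axis=0)
    return radius * (1.0 + pert.reshape(theta.shape))


def make_lesion_phantom(
    abnormality: str,
    pathology: str,
    view: str,
    image_size: tuple[int, int] = (128, 128),
    seed: int = 0,
    cfg: PhantomConfig = PhantomConfig(),
    case_id: str | None = None,
) -> PhantomCase:
    """Generate one lesion phantom with its ground-truth mask."""
    if abnormality not in ABNORMALITIES:
        raise ValueError(f"unknown abnormality {abnormality!r}")
    if pathology not in PATHOLOGIES:
        raise ValueError(f"unknown pathology {pathology!r}")
    if view not in VIEWS:
        raise ValueError(f"unknown view {view!r}")
    h, w = image_size
    if h < 64 or w < 64:
        raise ValueError("image_size must be at least 64×64")

    rng = np.random.default_rng(seed)
    maxval = (1 << cfg.bitdepth) - 1

    radius = float(rng.uniform(0.09, 0.14) * min(h, w))
    margin = math.ceil(0.1 * radius) + 3
    extent = math.ceil(radius * (1.0 + cfg.boundary_irregularity)) + 1
    lo_r, hi_r = extent + margin, h - 1 - extent - margin
    lo_c, hi_c = extent + margin, w - 1 - extent - margin
    if lo_r >= hi_r or lo_c >= hi_c:
        raise ValueError("lesion cannot fit inside the image with the required margin")
    cy = float(rng.uniform(lo_r, hi_r))
    cx = float(rng.uniform(lo_c, hi_c))

    rows = np.arange(h)[:, None] - cy
    cols = np.arange(w)[None, :] - cx
    rho = np.hypot(rows, cols)
    theta = np.arctan2(rows, cols)

    # intensity gains applied after all draws → geometry shared across pathologies
    igain = cfg.malignant_intensity_gain if pathology == "malignant" else 1.0
    vgain = math.sqrt(cfg.malignant_variance_gain) if pathology == "malignant" else 1.0

    background = (
        cfg.background_level * maxval
        + cfg.background_texture_sd * maxval * _smooth_noise((h, w), rng, sigma=4.0)
    )
    canvas = background

    amps, phases = _radial_boundary(radius, cfg.boundary_irregularity, rng)
    r_theta = _boundary_radius(theta, radius, amps, phases)
    region = rho <= r_theta

    heterogeneity = _smooth_noise((h, w), rng, sigma=2.0)

    if abnormality == "mass":
        mask = region
        profile = np.clip(1.0 - 0.45 * (rho / np.maximum(r_theta, 1e-9)) ** 2, 0.0, None)
        lesion = igain * cfg.mass_core * maxval * profile
        lesion += vgain * 0.02 * maxval * heterogeneity
        canvas = canvas + np.where(region, lesion, 0.0)
        n_specks = 0
    else:  # calcification: bright specks inside the enclosing cluster region
        mask = region
        n_specks = int(rng.integers(5, 21))
        speck_canvas = np.zeros((h, w))
        for _ in range(n_specks):
            srho = rng.uniform(0.0, 0.7 * radius)
            sth = rng.uniform(0.0, 2 * np.pi)
            sy, sx = cy + srho * np.sin(sth), cx + srho * np.cos(sth)
            srad = rng.uniform(0.6, 2.0)  # specks of 1–4 px across
            speck = np.clip(1.0 - np.hypot(rows - (sy - cy), cols - (sx - cx)) / (srad + 0.5), 0.0, 1.0)
            speck_canvas = np.maximum(speck_canvas, speck)
        lesion = igain * (
            cfg.calc_region_elevation * maxval
            + cfg.calc_speck_intensity * maxval * speck_canvas
        )
        lesion += vgain * 0.015 * maxval * heterogeneity
        canvas = canvas + np.where(region, lesion, 0.0)

    canvas += cfg.noise_sd * maxval * rng.standard_normal((h, w))
    pixels = np.clip(np.rint(canvas), 0, maxval).astype(
        np.uint16 if cfg.bitdepth == 16 else np.uint8
    )
    record = LesionRecord(
        case_id=case_id or f"phantom_{abnormality}_{pathology}_{view}_{seed}",
        abnormality=abnormality,
        pathology=pathology,
        view=view,
    )
    params = {
        "center": (cy, cx),
        "radius": radius,
        "margin": margin,
        "core_intensity": igain * (cfg.mass_core if abnormality == "mass" else cfg.calc_speck_intensity) * maxval,
        "rim_intensity": float(background.mean()),
        "noise_sd": cfg.noise_sd * maxval,
        "n_specks": n_specks,
        "seed": seed,
        "bitdepth": cfg.bitdepth,
        "malignant_intensity_gain": cfg.malignant_intensity_gain,
        "malignant_variance_gain": cfg.malignant_variance_gain,
    }
    return PhantomCase(
        image=GreyImage(pixels=pixels, bitdepth=cfg.bitdepth),
        mask=mask,
        record=record,
        params=params,
    )


def make_cohort(
    n_per_stratum: int,
    image_size: tuple[int, int] = (128, 128),
    seed: int = 0,
    cfg: PhantomConfig = PhantomConfig(),
) -> list[PhantomCase]:
    """A balanced cohort: n_per_stratum cases per (abnormality, pathology, view)."""
    if n_per_stratum < 1:
        raise ValueError("n_per_stratum must be ≥ 1")
    strata = [(a, p, v) for a in ABNORMALITIES for p in PATHOLOGIES for v in VIEWS]
    case_seeds = np.random.default_rng(seed).integers(0, 2**63, size=len(strata) * n_per_stratum)
    cases = []
    i = 0
    for a, p, v in strata:
        for _ in range(n_per_stratum):
            cases.append(
                make_lesion_phantom(
                    a, p, v, image_size, int(case_seeds[i]), cfg,
                    case_id=f"case{i:04d}_{a[:4]}_{p[:3]}_{v}",
                )
            )
            i += 1
    return cases


def make_sensitivity_pair(
    seed: int = 0, cfg: PhantomConfig = PhantomConfig()
) -> tuple[PhantomCase, PhantomCase]:
    """Fixture pair probing robustness-score semantics.

    Case A ("insensitive"): the lesion sits on a constant intensity
    plateau extending well beyond the maximum dilation, so masked
    statistics barely change across the triplet.  Case B ("sensitive"):
    a dark annulus just inside the mask boundary (stripped by erosion)
    and a bright annulus just outside it (captured by dilation) force
    large feature shifts.
    """
    h = w = 128
    r = 20.0
    maxval = (1 << cfg.bitdepth) - 1
    rng = np.random.default_rng(seed)
    cy = float(rng.uniform(56, 72))
    cx = float(rng.uniform(56, 72))
    level = maxval * rng.uniform(0.38, 0.44)

    rows = np.arange(h)[:, None] - cy
    cols = np.arange(w)[None, :] - cx
    rho = np.hypot(rows, cols)
    mask = rho <= r
    tiny_noise = 0.002 * level * rng.standard_normal((h, w))
    background = cfg.background_level * maxval + cfg.background_texture_sd * maxval * _smooth_noise(
        (h, w), rng, sigma=4.0
    )

    # case A: constant band out to r + 12 px ≫ the d=3 dilation
    img_a = np.where(rho <= r + 12.0, level, background) + tiny_noise
    px_a = np.clip(np.rint(img_a), 0, maxval).astype(np.uint16 if cfg.bitdepth == 16 else np.uint8)
    case_a = PhantomCase(
        image=GreyImage(px_a, cfg.bitdepth),
        mask=mask,
        record=LesionRecord(f"sensA_{seed}", "mass", "benign", "CC"),
        params={"kind": "insensitive", "radius": r, "level": level, "seed": seed},
    )

    # case B: dark inner annulus [r−4, r], bright outer annulus (r, r+4]
    img_b = np.where(rho <= r - 4.0, level, background)
    img_b = np.where((rho > r - 4.0) & (rho <= r), 0.4 * level, img_b)
    img_b = np.where((rho > r) & (rho <= r + 4.0), 2.0 * level, img_b)
    img_b = img_b + tiny_noise
    px_b = np.clip(np.rint(img_b), 0, maxval).astype(np.uint16 if cfg.bitdepth == 16 else np.uint8)
    case_b = PhantomCase(
        image=GreyImage(px_b, cfg.bitdepth),
        mask=mask,
        record=LesionRecord(f"sensB_{seed}", "mass", "benign", "CC"),
        params={"kind": "sensitive", "radius": r, "level": level, "seed": seed},
    )
    return case_a, case_b


def simulate_feature_values(
    n_lesions: int,
    shift_over: float,
    shift_under: float,
    noise_sd: float,
    distribution: str = "normal",
    seed: int = 0,
    base: float = 10.0,
) -> pd.DataFrame:
    """Long-format table with one synthetic feature column ``SIM.value``.

    Per lesion, the value for segmentation class c is drawn as
    ``base + shift_c + ε`` with ε ~ N(0, noise_sd²) i.i.d. across rows
    (``lognormal``: exp of the same latent, i.e. shifts act on the log
    scale).  With zero shifts all three class samples are i.i.d. from a
    single distribution — an exchangeable null.
    """
    if n_lesions < 3:
        raise ValueError("n_lesions must be ≥ 3")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if distribution not in ("normal", "lognormal"):
        raise ValueError(f"unknown distribution {distribution!r}")
    rng = np.random.default_rng(seed)
    shifts = {"original": 0.0, "over": shift_over, "under": shift_under}
    noise = rng.normal(0.0, noise_sd, size=(3, n_lesions))
    rows = []
    for ci, (cls, shift) in enumerate(shifts.items()):
        latent = base + shift + noise[ci]
        values = np.exp(latent - base) * base if distribution == "lognormal" else latent
        for i in range(n_lesions):
            rows.append(
                {
                    "case_id": f"sim{i:04d}",
                    "abnormality": "mass",
                    "pathology": "benign",
                    "view": "CC",
                    "segmentation_class": cls,
                    "SIM.value": values[i],
                }
            )
    return pd.DataFrame(rows)


def with_bitdepth(cfg: PhantomConfig, bitdepth: int) -> PhantomConfig:
    return replace(cfg, bitdepth=bitdepth)
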