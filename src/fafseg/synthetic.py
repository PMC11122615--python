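"""Synthetic fundus-autofluorescence scenes with simulated multi-rater annotations.

Real FAF images of lesioned retinas show bright hyperfluorescent (HF)
blobs and dark reduced-autofluorescence (RA) patches on a textured
background, with the optic disc as a naturally dark circle.  Clinical
data with multi-expert annotations is not publicly available, so this
module generates scenes with the two disagreement mechanisms that matter
for evaluating ambiguity-aware segmentation:

* **edge jitter** — every rater sees the same lesion but outlines its
  unsharp border slightly differently (implemented as a per-rater,
  per-component signed morphological offset plus sparse boundary noise,
  keeping the disagreement spatially coherent like human raters rather
  than pixel-i.i.d.);
* **area disagreement** — a rater may miss or reject a lesion outright
  (implemented as dropping non-anchor components independently per rater).

Anchor components are visible to every rater, guaranteeing a non-empty
all-raters-agree region for the confident ternary class.  Lesion shapes
are ellipses with a smooth radial wobble, giving curved borders without
sharp corners.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.morphology import disk


@dataclasses.dataclass
class Component:
    """One lesion: its crisp pixel mask plus generation parameters."""

    kind: Literal["hf", "ra"]
    mask: np.ndarray
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float
    brightness_offset: float
    anchor: bool = False
    # filled by simulate_expert_annotations: visibility[e] is True when
    # rater e includes this component
    visibility: list[bool] | None = None

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass
class SyntheticScene:
    """A generated image, its ground-truth masks and the component registry."""

    image: np.ndarray
    true_hf: np.ndarray
    true_ra: np.ndarray
    components: list[Component]
    params: dict
    expert_stack: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    def components_of(self, kind: str) -> list[Component]:
        return [c for c in self.components if c.kind == kind]


def _wobbled_ellipse(shape, center, semi_axes, angle, wobble, rng) -> np.ndarray:
    """Boolean mask of an ellipse whose radius is modulated by a smooth
    low-order harmonic perturbation of relative amplitude <= ``wobble``."""
    h, w = shape
    cy, cx = center
    a, b = semi_axes
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / a
    v = (-sa * dx + ca * dy) / b
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    bound = 1.0
    for k in (2, 3):
        amp = rng.uniform(-wobble / 2, wobble / 2)
        phase = rng.uniform(0, 2 * np.pi)
        bound = bound + amp * np.cos(k * theta + phase)
    return rho <= bound


def _place_components(rng, shape, n, kind, size_range, offset_range, occupied,
                      max_tries=200) -> list[Component]:
    h, w = shape
    comps: list[Component] = []
    for _ in range(n):
        placed = False
        for _ in range(max_tries):
            a = rng.uniform(*size_range)
            b = rng.uniform(size_range[0], a)
            margin = max(a, b) * 1.2 + 2
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            angle = rng.uniform(0, np.pi)
            mask = _wobbled_ellipse(shape, (cy, cx), (a, b), angle, wobble=0.25, rng=rng)
            if not mask.any() or (mask & occupied).any():
                continue
            offset = rng.uniform(*offset_range)
            comps.append(Component(kind=kind, mask=mask, center=(cy, cx),
                                   semi_axes=(a, b), angle=angle,
                                   brightness_offset=offset))
            occupied |= ndimage.binary_dilation(mask, structure=disk(3))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place {kind} component within the overlap budget; "
                "reduce component count or size")
    return comps


def generate_scene(width: int = 768, height: int = 768, n_hf_components: int = 4,
                   n_ra_components: int = 2, background_level: float | None = None,
                   texture_sd: float = 8.0, texture_scale: float = 12.0,
                   edge_feather_px: float | None = None,
                   seed: int | None = None) -> SyntheticScene:
    """Generate one FAF-like scene without rater annotations.

    The background is a smooth Gaussian random field around
    ``background_level`` (drawn per scene from 75–110 when not given —
    FAF exposure varies between acquisitions); HF components add a bright
    offset, RA components a dark one, both feathered at the border so
    lesion edges are unsharp like in real FAF; a dark optic-disc circle
    is placed near the image side.  Brightness offsets are assigned by
    component size — larger lesions are the conspicuous, bright ones,
    small faint lesions the ones raters tend to disagree about.  The
    true masks cover the crisp (pre-feathering) component pixels exactly.

    Component semi-axes span roughly 4–10 % of the smaller image side, so
    at the native 768 px they are in the tens-of-pixels range typical of
    macular lesions; wobble keeps borders curved without creating
    structures thinner than the default edge-jitter magnitudes.
    """
    if width < 64 or height < 64:
        raise ValueError("scene must be at least 64x64")
    if n_hf_components < 0 or n_ra_components < 0:
        raise ValueError("component counts must be non-negative")
    rng = np.random.default_rng(seed)
    shape = (height, width)
    smin = min(width, height)
    if background_level is None:
        background_level = float(rng.uniform(75.0, 110.0))
    if edge_feather_px is None:
        # unsharp lesion borders, proportional to the lesion scale
        edge_feather_px = max(0.5, 2.0 * smin / 768.0)

    field = rng.normal(0.0, 1.0, shape)
    field = ndimage.gaussian_filter(field, sigma=texture_scale)
    if field.std() > 0:
        field *= texture_sd / field.std()
    image = background_level + field

    # optic disc: dark circle near a horizontal border, a confounder for RA
    disc_r = smin * 0.07
    disc_cy = rng.uniform(0.35, 0.65) * height
    disc_cx = (disc_r * 1.8) if rng.random() < 0.5 else (width - disc_r * 1.8)
    yy, xx = np.mgrid[0:height, 0:width]
    disc = (yy - disc_cy) ** 2 + (xx - disc_cx) ** 2 <= disc_r ** 2
    image -= ndimage.gaussian_filter(disc.astype(float), sigma=2.0) * 55.0

    occupied = ndimage.binary_dilation(disc, structure=disk(5))
    size_range = (0.04 * smin, 0.10 * smin)
    hf = _place_components(rng, shape, n_hf_components, "hf", size_range,
                           offset_range=(45.0, 95.0), occupied=occupied)
    ra = _place_components(rng, shape, n_ra_components, "ra", size_range,
                           offset_range=(-80.0, -45.0), occupied=occupied)

    # conspicuity tracks size: reassign the drawn offsets so the largest
    # component of each kind is also the brightest (darkest for RA)
    for group, reverse in ((hf, False), (ra, True)):
        offsets = sorted((c.brightness_offset for c in group), reverse=reverse)
        for off, comp in zip(offsets, sorted(group, key=lambda c: c.area)):
            comp.brightness_offset = off

    if hf:
        max(hf, key=lambda c: c.area).anchor = True

    for comp in hf + ra:
        feathered = ndimage.gaussian_filter(comp.mask.astype(float), sigma=edge_feather_px)
        image += feathered * comp.brightness_offset

    true_hf = np.zeros(shape, dtype=bool)
    for comp in hf:
        true_hf |= comp.mask
    true_ra = np.zeros(shape, dtype=bool)
    for comp in ra:
        true_ra |= comp.mask

    params = dict(width=width, height=height, n_hf_components=n_hf_components,
                  n_ra_components=n_ra_components, background_level=background_level,
                  texture_sd=texture_sd, texture_scale=texture_scale,
                  edge_feather_px=edge_feather_px, seed=seed)
    return SyntheticScene(image=np.clip(image, 0, 255).astype(np.uint8),
                          true_hf=true_hf, true_ra=true_ra,
                          components=hf + ra, params=params)


def _morphological_offset(mask: np.ndarray, offset_px: int) -> np.ndarray:
    """Dilate (positive) or erode (negative) by a disk; an erosion that
    would empty the mask is backed off until the mask survives."""
    if offset_px == 0:
        return mask
    if offset_px > 0:
        return ndimage.binary_dilation(mask, structure=disk(offset_px))
    r = -offset_px
    while r > 0:
        eroded = ndimage.binary_erosion(mask, structure=disk(r))
        if eroded.any():
            return eroded
        r -= 1
    return mask


def _boundary_noise(mask: np.ndarray, prob: float, rng) -> np.ndarray:
    """Randomly add/remove pixels on the 1-px boundary ring of the mask."""
    if prob <= 0:
        return mask
    outer = ndimage.binary_dilation(mask) & ~mask
    inner = mask & ~ndimage.binary_erosion(mask)
    out = mask.copy()
    out[outer & (rng.random(mask.shape) < prob)] = True
    out[inner & (rng.random(mask.shape) < prob)] = False
    return out


def max_pairwise_displacement(edge_jitter_px: int, boundary_noise_prob: float = 0.2) -> int:
    """Upper bound (px) on the distance of any jitter-induced disagreement
    pixel from the mutual-overlap region of two raters: two opposing
    morphological offsets plus one pixel each of boundary noise.  Zero
    jitter disables boundary noise as well, so the bound is 0."""
    if edge_jitter_px == 0:
        return 0
    return 2 * (int(edge_jitter_px) + (1 if boundary_noise_prob > 0 else 0))


def simulate_expert_annotations(scene: SyntheticScene, n_experts: int = 5,
                                edge_jitter_px: int = 3,
                                area_disagreement_prob: float = 0.3,
                                boundary_noise_prob: float = 0.2,
                                label: str = "hf",
                                seed: int | None = None) -> np.ndarray:
    """Simulate ``n_experts`` binary annotations of the scene's lesions.

    Each rater's mask is the union, over the components they consider
    present, of the crisp component mask offset by a random signed
    morphological radius of at most ``edge_jitter_px`` with sparse
    boundary noise on top.  Non-anchor components are dropped
    independently per rater with probability ``area_disagreement_prob``;
    anchors are always included.  Visibility flags are recorded on the
    component registry and the stack is attached to the scene.

    With zero jitter, zero noise and zero drop probability all raters
    reproduce the true mask exactly.
    """
    if n_experts < 1:
        raise ValueError("need at least one rater")
    if not 0.0 <= area_disagreement_prob <= 1.0:
        raise ValueError("area_disagreement_prob must be in [0, 1]")
    if edge_jitter_px < 0:
        raise ValueError("edge_jitter_px must be non-negative")
    rng = np.random.default_rng(seed)
    comps = scene.components_of(label)
    stack = np.zeros((n_experts, *scene.shape), dtype=bool)
    for comp in comps:
        comp.visibility = []
    for e in range(n_experts):
        for comp in comps:
            visible = comp.anchor or (rng.random() >= area_disagreement_prob)
            comp.visibility.append(bool(visible))
            if not visible:
                continue
            m = comp.mask
            if edge_jitter_px > 0:
                offset = int(rng.integers(-edge_jitter_px, edge_jitter_px + 1))
                m = _morphological_offset(m, offset)
                m = _boundary_noise(m, boundary_noise_prob, rng)
            stack[e] |= m
    if label == "hf":
        scene.expert_stack = stack
    return stack


def expert_count_map(stack: np.ndarray) -> np.ndarray:
    """Per-pixel number of raters that marked the pixel, in {0..k}."""
    stack = np.asarray(stack).astype(bool)
    if stack.ndim != 3:
        raise ValueError("annotation stack must be (k, H, W)")
    return stack.sum(axis=0)
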