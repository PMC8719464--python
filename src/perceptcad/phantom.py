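"""Synthetic mammogram-like lesion phantom.

Generates two-view lesion cases — a grayscale patch plus a binary ROI mask
per view — whose geometry is driven by the five quantified BI-RADS
descriptor codes, and whose benign/malignant label is a stochastic logistic
function of those codes.  This emulates a curated FFDM mass dataset
(radiologist-drawn ROIs, per-case pathology) so the full pipeline is
exercisable without patient data.

Descriptor semantics map onto controllable image physics:

* shape code        — 0: ellipse; 1: irregular boundary (random low-order
                      radial harmonics); intermediate codes interpolate.
* margin code       — edge blur sigma applied to the lesion support
                      (circumscribed sharpest, indistinct most blurred).
* microlobulated    — small sinusoidal boundary undulations.
* spiculated        — narrow radial spikes extending beyond the core
                      boundary.
* density code      — lesion-to-background contrast.

The lesion boundary is a star-shaped polar radius function around the patch
centre, so the mask is always a single connected component.  The mask is
the *pre-blur* support: margin blur degrades the image edge, not the ROI,
mirroring radiologist outlines that track the lesion regardless of edge
conspicuity.  The two views are independent re-renders of the same
descriptor vector (only descriptor sharing across views matters
downstream).  Per-case RNG streams are derived by hashing (seed, case
index) so generation is reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .birads import DESCRIPTOR_FIELDS, DescriptorVector

__all__ = [
    "VIEWS",
    "LesionPatch",
    "Case",
    "PhantomConfig",
    "GeometryError",
    "case_rng",
    "sample_descriptors",
    "render_case",
    "assign_label",
    "generate_dataset",
]

VIEWS = ("CC", "MLO")

#: Categorical marginals for each descriptor code, chosen symmetric about
#: their midpoints so the malignancy marginal under the default logit
#: weights is 1/2 (emulating a roughly balanced benign:malignant case mix).
DEFAULT_MARGINALS: dict[str, dict[float, float]] = {
    "shape": {0.0: 0.5, 1.0: 0.5},
    "margin_sharpness": {0.0: 1 / 3, 0.5: 1 / 3, 1.0: 1 / 3},
    "microlobulated": {0.0: 0.5, 1.0: 0.5},
    "spiculated": {0.0: 0.5, 1.0: 0.5},
    "density": {0.0: 1 / 3, 0.5: 1 / 3, 1.0: 1 / 3},
}


class GeometryError(ValueError):
    """Lesion geometry does not fit inside the patch."""


@dataclass
class LesionPatch:
    """One view of a lesion: grayscale image in [0,1] plus binary ROI mask."""

    image: np.ndarray
    mask: np.ndarray
    view: str

    def validate(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.image.shape != self.mask.shape or self.image.ndim != 2:
            raise ValueError("image and mask must be identical 2-D shapes")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        n_fg = int(self.mask.sum())
        if n_fg < 1:
            raise ValueError("mask has no foreground pixel")
        _, n_components = ndimage.label(self.mask, structure=np.ones((3, 3)))
        if n_components != 1:
            raise ValueError(f"mask must be a single connected component, got {n_components}")


@dataclass
class Case:
    """A two-view lesion case sharing one descriptor vector and one label."""

    case_id: str
    patches: dict[str, LesionPatch]
    descriptors: DescriptorVector
    label: str  # "benign" | "malignant"

    def validate(self) -> None:
        if set(self.patches) != set(VIEWS):
            raise ValueError(f"case {self.case_id} must have views {VIEWS}")
        if self.label not in ("benign", "malignant"):
            raise ValueError(f"bad label {self.label!r}")
        for patch in self.patches.values():
            patch.validate()


@dataclass
class PhantomConfig:
    """Knobs of the synthetic-lesion generator.

    ``malignancy_logit_weights`` is (intercept, then one weight per
    descriptor in the canonical order).  The default weights are ordered by
    clinical salience (spiculation strongest, density weakest) and scaled so
    the label noise leaves a best-possible case-level AUC near 0.95; the
    intercept is minus half the weight sum, which makes the malignancy
    marginal exactly 1/2 under the symmetric descriptor marginals.

    ``blur_sigmas`` / ``contrast_levels`` are indexed by margin / density
    code (0, 0.5, 1) and must be strictly increasing.  All geometry is
    expressed relative to ``patch_side`` (default 64 px for desk-scale work;
    set 288 px for full-resolution patches) so lesions scale with the patch.
    """

    n_cases: int = 416
    patch_side: int = 64
    malignancy_logit_weights: tuple[float, ...] = (-9.5, 4.5, 4.5, 3.0, 5.0, 2.0)
    descriptor_marginals: dict[str, dict[float, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    blur_sigmas: tuple[float, float, float] = (0.5, 1.6, 3.2)  # px at side 64
    n_lobes_range: tuple[int, int] = (5, 9)
    n_spicules_range: tuple[int, int] = (8, 15)
    contrast_levels: tuple[float, float, float] = (0.14, 0.28, 0.46)
    lesion_radius_frac: tuple[float, float] = (0.16, 0.22)  # of patch side
    background_level: float = 0.35
    background_noise_scale: float = 0.05
    train_size: int | float | None = None
    stratify_split: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.malignancy_logit_weights) != 6:
            raise ValueError("malignancy_logit_weights needs intercept + 5 weights")
        if not all(np.isfinite(self.malignancy_logit_weights)):
            raise ValueError("malignancy_logit_weights must be finite")
        for name, rng_ in (("n_lobes_range", self.n_lobes_range),
                           ("n_spicules_range", self.n_spicules_range)):
            if len(rng_) != 2 or rng_[1] < rng_[0]:
                raise ValueError(f"{name} must be a nonempty (lo, hi) range")
        if not (self.blur_sigmas[0] < self.blur_sigmas[1] < self.blur_sigmas[2]):
            raise ValueError("blur_sigmas must be strictly increasing in margin code")
        if not (self.contrast_levels[0] < self.contrast_levels[1] < self.contrast_levels[2]):
            raise ValueError("contrast_levels must be strictly increasing in density code")
        for fname, marg in self.descriptor_marginals.items():
            if fname not in DESCRIPTOR_FIELDS:
                raise ValueError(f"unknown descriptor field {fname!r}")
            total = sum(marg.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"marginal for {fname} sums to {total}, not 1")

    @property
    def scale(self) -> float:
        """Geometry scale factor relative to the 64-px reference side."""
        return self.patch_side / 64.0


def case_rng(seed: int, case_index: int) -> np.random.Generator:
    """Deterministic per-case RNG stream derived by hashing (seed, index)."""
    return np.random.default_rng(np.random.SeedSequence((seed, case_index)))


def sample_descriptors(
    rng: np.random.Generator,
    marginals: dict[str, dict[float, float]] | None = None,
) -> DescriptorVector:
    """Draw each descriptor code independently from its categorical marginal."""
    marginals = marginals or DEFAULT_MARGINALS
    codes = []
    for fname in DESCRIPTOR_FIELDS:
        marg = marginals[fname]
        levels = np.array(sorted(marg))
        probs = np.array([marg[v] for v in levels])
        codes.append(float(rng.choice(levels, p=probs)))
    return DescriptorVector(*codes)


def _code_level(code: float) -> int:
    """Index of a {0, 0.5, 1} code into a 3-entry lookup table."""
    return int(round(code * 2))


def _radius_profile(
    theta: np.ndarray,
    descriptors: DescriptorVector,
    config: PhantomConfig,
    rng: np.random.Generator,
    r0: float,
) -> np.ndarray:
    """Star-shaped lesion boundary radius as a function of angle."""
    # base ellipse, random orientation and mild eccentricity
    q = rng.uniform(0.70, 0.95)
    phi0 = rng.uniform(0, 2 * np.pi)
    a, b = r0, r0 * q
    t = theta - phi0
    r = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)

    # irregular shape: random low-order radial harmonics.  Amplitudes are
    # sized so the signature spans several pixels at the 64-px test scale.
    s = descriptors.shape_code
    if s > 0:
        for order in range(2, 7):
            amp = s * r0 * 0.14 * rng.uniform(0.5, 1.0)
            r += amp * np.cos(order * theta + rng.uniform(0, 2 * np.pi))

    # microlobulation: small sinusoidal undulations
    m = descriptors.microlobulated_code
    if m > 0:
        n_lobes = int(rng.integers(config.n_lobes_range[0], config.n_lobes_range[1] + 1))
        r += m * r0 * 0.14 * np.sin(n_lobes * theta + rng.uniform(0, 2 * np.pi))

    # spiculation: narrow radial spikes beyond the core boundary; overlapping
    # spikes merge (max) rather than stack, so the profile stays bounded
    p = descriptors.spiculated_code
    if p > 0:
        n_spic = int(rng.integers(config.n_spicules_range[0], config.n_spicules_range[1] + 1))
        centers = rng.uniform(0, 2 * np.pi, n_spic)
        amps = rng.uniform(0.45, 0.85, n_spic) * r0 * p
        width = 0.045  # radians
        spikes = np.zeros_like(r)
        for c, amp in zip(centers, amps):
            d = np.angle(np.exp(1j * (theta - c)))  # wrapped angular distance
            np.maximum(spikes, amp * np.exp(-0.5 * (d / width) ** 2), out=spikes)
        r += spikes

    return np.maximum(r, 0.30 * r0)


def _render_patch(
    descriptors: DescriptorVector,
    config: PhantomConfig,
    rng: np.random.Generator,
    view: str,
) -> LesionPatch:
    side = config.patch_side
    r0 = rng.uniform(*config.lesion_radius_frac) * side
    limit = side / 2.0 - 2.0
    if r0 >= limit:
        raise GeometryError(f"base lesion radius {r0:.1f} px exceeds patch half-side {side / 2}")

    yy, xx = np.mgrid[0:side, 0:side]
    cy = cx = (side - 1) / 2.0
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    r_bound = _radius_profile(theta.ravel(), descriptors, config, rng, r0)
    r_bound = r_bound.reshape(theta.shape)
    if r_bound.max() > limit:
        # boundary perturbations overflowed the patch: shrink uniformly,
        # which preserves every scale-invariant shape characteristic
        r_bound *= limit / r_bound.max()
    mask = (rho <= r_bound).astype(np.uint8)
    # rasterization can shear sub-pixel spike tips off the body: keep the
    # main 8-connected component and fill any pinhole
    labeled, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n_comp + 1))
        mask = (labeled == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    mask = ndimage.binary_fill_holes(mask).astype(np.uint8)

    sigma = config.blur_sigmas[_code_level(descriptors.margin_sharpness_code)] * config.scale
    support = mask.astype(np.float64)
    if sigma > 0:
        support = ndimage.gaussian_filter(support, sigma)

    contrast = config.contrast_levels[_code_level(descriptors.density_code)]
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (side, side)), 3.0 * config.scale)
    texture *= config.background_noise_scale / max(texture.std(), 1e-12)
    background = config.background_level + texture
    image = background + contrast * support
    image += rng.normal(0.0, 0.01, (side, side))
    image = np.clip(image, 0.0, 1.0)

    return LesionPatch(image=image, mask=mask, view=view)


def render_case(
    descriptors: DescriptorVector,
    config: PhantomConfig,
    rng: np.random.Generator,
    case_id: str = "case",
    label: str | None = None,
) -> Case:
    """Render both views of a case from one descriptor vector.

    The label is drawn via :func:`assign_label` unless supplied.
    """
    if label is None:
        label = assign_label(descriptors, config, rng)
    patches = {view: _render_patch(descriptors, config, rng, view) for view in VIEWS}
    case = Case(case_id=case_id, patches=patches, descriptors=descriptors, label=label)
    case.validate()
    return case


def assign_label(
    descriptors: DescriptorVector,
    config: PhantomConfig,
    rng: np.random.Generator,
) -> str:
    """Draw the pathology label ~ Bernoulli(sigmoid(w0 + w . codes))."""
    w = np.asarray(config.malignancy_logit_weights, dtype=np.float64)
    logit = w[0] + w[1:] @ descriptors.as_array()
    p_malignant = 1.0 / (1.0 + np.exp(-logit))
    return "malignant" if rng.random() < p_malignant else "benign"


def _resolve_train_size(train_size: int | float, n: int) -> int:
    if isinstance(train_size, float):
        if not 0 < train_size < 1:
            raise ValueError(f"train fraction {train_size} must lie in (0, 1)")
        return int(round(train_size * n))
    if not 0 < train_size < n:
        raise ValueError(f"train_size {train_size} incompatible with {n} cases")
    return int(train_size)


def generate_dataset(
    config: PhantomConfig,
) -> tuple[list[Case], pd.DataFrame]:
    """Generate ``config.n_cases`` cases plus a manifest table.

    The manifest has one row per view with the descriptor codes, label and
    (when ``train_size`` is set) a stratified train/test split.  Image/mask
    path columns are left empty until the patches are written to disk (see
    :func:`perceptcad.io.write_dataset`).
    """
    if config.n_cases < 2:
        raise ValueError("need at least 2 cases")
    cases: list[Case] = []
    for i in range(config.n_cases):
        rng = case_rng(config.seed, i)
        desc = sample_descriptors(rng, config.descriptor_marginals)
        case = render_case(desc, config, rng, case_id=f"case{i:04d}")
        cases.append(case)

    split = _assign_split(cases, config)
    rows = []
    for case in cases:
        for view in VIEWS:
            row = {
                "case_id": case.case_id,
                "view": view,
                "image_path": "",
                "mask_path": "",
            }
            codes = case.descriptors.as_array()
            for fname, code in zip(DESCRIPTOR_FIELDS, codes):
                row[f"{fname}_code"] = code
            row["label"] = case.label
            row["split"] = split[case.case_id]
            rows.append(row)
    manifest = pd.DataFrame(rows)
    return cases, manifest


def _assign_split(cases: Sequence[Case], config: PhantomConfig) -> dict[str, str]:
    if config.train_size is None:
        return {c.case_id: "" for c in cases}
    n = len(cases)
    n_train = _resolve_train_size(config.train_size, n)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x5B711)))
    ids = np.array([c.case_id for c in cases])
    if config.stratify_split:
        labels = np.array([c.label for c in cases])
        train_ids: list[str] = []
        # proportional allocation per label, remainder to the larger class
        for lab in ("malignant", "benign"):
            members = ids[labels == lab]
            k = int(round(n_train * len(members) / n))
            train_ids.extend(rng.permutation(members)[:k].tolist())
        # fix rounding drift
        short = n_train - len(train_ids)
        if short != 0:
            pool = [i for i in ids if (i in train_ids) == (short < 0)]
            pool = [i for i in rng.permutation(pool)]
            if short > 0:
                train_ids.extend(pool[:short])
            else:
                for drop in pool[: -short]:
                    train_ids.remove(drop)
    else:
        train_ids = rng.permutation(ids)[:n_train].tolist()
    train_set = set(train_ids)
    return {c.case_id: ("train" if c.case_id in train_set else "test") for c in cases}
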