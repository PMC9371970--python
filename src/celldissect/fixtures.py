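"""Synthetic fixtures: microscopy images with ground truth, and proteome matrices.

Every downstream stage of the pipeline — segmentation evaluation, phenotype
discovery, cut planning, proteomics statistics, spatial re-integration — is
exercised on data from this module, so its generators are first-class,
tested code with fully specified randomness.

Image fixtures place non-overlapping rotated ellipses of several morphology
classes (distinct area, eccentricity and staining intensity, at stated
frequencies) on a noisy background: enough structure for area / perimeter /
solidity / form-factor / total-intensity phenotyping to discriminate
classes, without pretending to be photorealistic tissue.

Proteome fixtures draw log2 intensities Gaussian within group, plant a
log2 fold change between groups 1 and 2 in a known subset of proteins, and
censor values missing-not-at-random through a logistic function of the true
intensity — the mechanism under which downshifted-normal imputation is the
appropriate fill-in.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .segmentation import LabelMask

__all__ = [
    "ClassSpec",
    "ImageFixtureSpec",
    "ProteomeFixtureSpec",
    "default_nuclei_classes",
    "make_image_fixture",
    "make_proteome_fixture",
    "make_gaussian_classes",
]


@dataclass(frozen=True)
class ClassSpec:
    """Morphology class of synthetic nuclei.

    ``frequency`` is the multinomial probability of the class;
    ``mean_area_um2`` the mean nuclear area; ``eccentricity_range`` the
    uniform sampling range of ellipse eccentricity; ``intensity_mean`` /
    ``intensity_cv`` parametrize the per-object mean staining intensity.
    """

    class_id: int
    frequency: float
    mean_area_um2: float
    eccentricity_range: tuple[float, float]
    intensity_mean: float
    intensity_cv: float


def default_nuclei_classes() -> list[ClassSpec]:
    """Six nuclei morphology classes: three primary (~28-33%) and three rare (3%).

    The per-class morphology values are free parameters of the generator,
    chosen so that classes separate on the standard feature set (area,
    perimeter, solidity, form factor, total DNA-stain intensity).
    """
    return [
        ClassSpec(1, 0.33, 120.0, (0.20, 0.60), 1200.0, 0.15),
        ClassSpec(2, 0.30, 160.0, (0.30, 0.70), 1500.0, 0.15),
        ClassSpec(3, 0.28, 200.0, (0.40, 0.80), 1800.0, 0.15),
        ClassSpec(4, 0.03, 60.0, (0.10, 0.40), 3000.0, 0.10),
        ClassSpec(5, 0.03, 260.0, (0.60, 0.90), 1000.0, 0.15),
        ClassSpec(6, 0.03, 90.0, (0.50, 0.85), 2200.0, 0.15),
    ]


@dataclass(frozen=True)
class ImageFixtureSpec:
    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 0.5
    n_objects: int = 100
    class_specs: list[ClassSpec] = field(default_factory=default_nuclei_classes)
    background_level: float = 100.0
    noise_sd: float = 20.0
    seed: int = 0
    # minimum empty-pixel gap enforced between placed objects
    min_gap_px: int = 4

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_objects < 0:
            raise ValueError("n_objects must be non-negative")
        if not self.class_specs:
            raise ValueError("at least one class spec required")
        freqs = np.array([c.frequency for c in self.class_specs])
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("class frequencies must sum to 1")
        if any(c.mean_area_um2 <= 0 for c in self.class_specs):
            raise ValueError("mean areas must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ImageFixtureSpec":
        with open(path) as fh:
            d = json.load(fh)
        d["class_specs"] = [
            ClassSpec(**{**c, "eccentricity_range": tuple(c["eccentricity_range"])})
            for c in d["class_specs"]
        ]
        return cls(**d)


_MAX_PLACEMENT_ATTEMPTS = 100


def make_image_fixture(
    spec: ImageFixtureSpec,
) -> tuple[np.ndarray, LabelMask, pd.DataFrame]:
    """Render a synthetic stained-nuclei image with ground truth.

    Returns ``(image, mask, truth)`` where ``image`` is a uint16 intensity
    image, ``mask`` the ground-truth instance labels (1..n in placement
    order) and ``truth`` a per-object table with the planted class, area,
    centroid and intensity.

    Objects are placed by rejection sampling with at most 100 attempts
    each; objects never overlap and keep a ``min_gap_px`` clearance.  If
    the field is too dense some objects are silently not placed — the
    truth table reports what was placed.  Fixed seed gives byte-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height_px, spec.width_px
    px = spec.pixel_size_um
    labels = np.zeros((H, W), dtype=np.int32)
    occupied = np.zeros((H, W), dtype=bool)  # objects + clearance margin
    img = np.full((H, W), float(spec.background_level))

    freqs = np.array([c.frequency for c in spec.class_specs])
    class_draws = rng.choice(len(spec.class_specs), size=spec.n_objects, p=freqs)

    records = []
    next_label = 1
    for cls_idx in class_draws:
        cs = spec.class_specs[cls_idx]
        placed = False
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            area_um2 = max(cs.mean_area_um2 * 0.2, rng.normal(cs.mean_area_um2, 0.10 * cs.mean_area_um2))
            ecc = rng.uniform(*cs.eccentricity_range)
            theta = rng.uniform(0, np.pi)
            # ellipse semi-axes (px) from area and eccentricity: b = a*sqrt(1-e^2)
            axis_ratio = np.sqrt(1.0 - ecc**2)
            a_px = np.sqrt(area_um2 / (np.pi * axis_ratio)) / px
            b_px = a_px * axis_ratio
            margin = int(np.ceil(a_px)) + spec.min_gap_px
            if 2 * margin >= min(H, W):
                continue
            r0 = rng.uniform(margin, H - margin)
            c0 = rng.uniform(margin, W - margin)
            rr, cc = draw_ellipse(r0, c0, a_px, b_px, shape=(H, W), rotation=theta)
            if rr.size < 4:
                continue
            # clearance check: candidate plus gap must be free
            rmin, rmax = rr.min(), rr.max()
            cmin, cmax = cc.min(), cc.max()
            g = spec.min_gap_px
            if occupied[
                max(0, rmin - g) : rmax + g + 1, max(0, cmin - g) : cmax + g + 1
            ].any():
                continue
            labels[rr, cc] = next_label
            occupied[max(0, rmin - g) : rmax + g + 1, max(0, cmin - g) : cmax + g + 1] = True
            base = rng.normal(cs.intensity_mean, cs.intensity_cv * cs.intensity_mean)
            base = max(base, 0.05 * cs.intensity_mean)
            texture = rng.lognormal(mean=0.0, sigma=0.1, size=rr.size)
            img[rr, cc] = spec.background_level + base * texture
            records.append(
                {
                    "object_id": next_label,
                    "class_label": cs.class_id,
                    "area_um2": rr.size * px**2,
                    "centroid_x_um": float((cc + 0.5).mean() * px),
                    "centroid_y_um": float((rr + 0.5).mean() * px),
                    "mean_intensity": base,
                }
            )
            next_label += 1
            placed = True
            break
        if not placed:
            continue

    img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    truth = pd.DataFrame(
        records,
        columns=[
            "object_id",
            "class_label",
            "area_um2",
            "centroid_x_um",
            "centroid_y_um",
            "mean_intensity",
        ],
    )
    return img, LabelMask(labels, px), truth


@dataclass(frozen=True)
class ProteomeFixtureSpec:
    """Parameters of a synthetic protein-by-sample log2 intensity matrix.

    Baseline protein abundances are N(``base_mean``, ``base_sd``) on the
    log2 scale; the first ``n_true_effects`` proteins carry
    ``effect_log2fc`` added in group 2.  Missingness is left-censoring: a
    cell with true intensity x drops out with probability
    sigmoid(slope * (midpoint - x)).
    """

    n_proteins: int = 1000
    n_groups: int = 2
    reps_per_group: int = 4
    n_true_effects: int = 100
    effect_log2fc: float = 2.0
    within_group_sd: float = 0.3
    dropout_logistic_midpoint: float = 21.0
    dropout_logistic_slope: float = 1.0
    base_mean: float = 25.0
    base_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.n_groups <= 0:
            raise ValueError("n_proteins and n_groups must be positive")
        if self.reps_per_group < 2:
            raise ValueError("reps_per_group must be at least 2")
        if not (0 <= self.n_true_effects <= self.n_proteins):
            raise ValueError("n_true_effects must be within [0, n_proteins]")


def make_proteome_fixture(
    spec: ProteomeFixtureSpec,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate a log2 intensity matrix with planted effects and MNAR dropout.

    Returns ``(matrix, groups, truth)``: ``matrix`` is proteins × samples
    with NaN for censored cells, ``groups`` maps sample id → group label
    ("G1".."Gk"), and ``truth`` lists the affected proteins with their
    planted log2 fold change (group 2 minus group 1).
    """
    rng = np.random.default_rng(spec.seed)
    n, g, r = spec.n_proteins, spec.n_groups, spec.reps_per_group
    proteins = [f"P{i:05d}" for i in range(1, n + 1)]
    samples = [f"G{j + 1}_R{i + 1}" for j in range(g) for i in range(r)]
    group_labels = pd.Series(
        [f"G{j + 1}" for j in range(g) for _ in range(r)], index=samples, name="group"
    )

    base = rng.normal(spec.base_mean, spec.base_sd, size=n)
    means = np.tile(base[:, None], (1, g * r))
    if spec.n_true_effects and g >= 2:
        g2_cols = slice(r, 2 * r)
        means[: spec.n_true_effects, g2_cols] += spec.effect_log2fc
    values = rng.normal(means, spec.within_group_sd)

    p_drop = 1.0 / (
        1.0 + np.exp(-spec.dropout_logistic_slope * (spec.dropout_logistic_midpoint - values))
    )
    dropped = rng.random(values.shape) < p_drop
    values = np.where(dropped, np.nan, values)

    matrix = pd.DataFrame(values, index=proteins, columns=samples)
    truth = pd.DataFrame(
        {
            "protein": proteins[: spec.n_true_effects],
            "log2fc": [spec.effect_log2fc] * spec.n_true_effects,
        }
    )
    return matrix, group_labels, truth


def make_gaussian_classes(
    n: int,
    frequencies: list[float] | np.ndarray,
    n_features: int,
    separation_sd: float = 6.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted-cluster feature cloud for phenotype-finder benchmarks.

    ``k`` class centers are placed pairwise ``separation_sd`` apart (scaled
    simplex) in ``n_features`` dimensions (requires n_features >= k - 1);
    points get unit within-class sd.  Returns ``(X, labels)`` with labels
    1..k drawn multinomially at the stated frequencies.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    k = freqs.size
    if n_features < k - 1:
        raise ValueError("need n_features >= k - 1 to separate k classes")
    rng = np.random.default_rng(seed)
    # regular simplex: rows of c*I are pairwise c*sqrt(2) apart; center and
    # embed the rank-(k-1) configuration into the first k-1 feature dims
    E = np.eye(k) * (separation_sd / np.sqrt(2.0))
    E -= E.mean(axis=0)
    U, s, _ = np.linalg.svd(E, full_matrices=False)
    centers = np.zeros((k, n_features))
    centers[:, : k - 1] = U[:, : k - 1] * s[: k - 1]
    labels = rng.choice(k, size=n, p=freqs) + 1
    X = centers[labels - 1] + rng.normal(0.0, 1.0, size=(n, n_features))
    return X, labels
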