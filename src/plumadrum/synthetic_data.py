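"""Synthetic inputs with known ground truth.

Two generators: plumage-like images (a few discrete colour patches inside
a head-outline mask, with optional per-pixel Gaussian sRGB noise) whose
colour statistics are known analytically from the noiseless layout, and
species trait tables evolved on simulated pure-birth trees under λ-scaled
Brownian covariance with known regression coefficients and a thresholded
Brownian-liability habitat covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from plumadrum.colorspace import lab_array_to_rgb, rgb_array_to_lab
from plumadrum.pattern_metrics import (
    PatternMetrics,
    RED_THRESHOLDS,
    boundary_strength,
    red_mask_lab,
    simpson_scaled,
)
from plumadrum.phylo_gls import lambda_transform, phylo_covariance
from plumadrum.segmentation import ColorMap, MaskedImage

# Lab colours that land in distinct sRGB histogram bins and sit far apart
# in Lab space; used for randomly generated cohorts.
_PALETTE_LAB = {
    "black": (12.0, 0.0, 0.0),
    "white": (96.0, 0.0, 0.0),
    "red": (62.0, 60.0, 55.0),
    "yellow": (85.0, 5.0, 80.0),
    "green": (46.0, -50.0, 50.0),
    "blue": (32.0, 20.0, -60.0),
}


@dataclass
class Patch:
    """One colour patch: a band, rectangle or ellipse in fractional units.

    geometry:
      - band:    (row_start, row_end) fractions of the height
      - rect:    (x0, y0, x1, y1) fractions
      - ellipse: (cx, cy, rx, ry) fractions
    """

    shape: str
    color_lab: tuple[float, float, float]
    geometry: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.shape not in ("band", "rect", "ellipse"):
            raise ValueError(f"unknown patch shape {self.shape!r}")


@dataclass
class PlumageSpec:
    """Recipe for a synthetic plumage image."""

    width: int = 120
    height: int = 120
    base_color_lab: tuple[float, float, float] = (12.0, 0.0, 0.0)
    patches: list[Patch] = field(default_factory=list)
    noise_sd: float = 0.0
    mask_shape: str = "full"  # "full" or "ellipse" head outline
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.mask_shape not in ("full", "ellipse"):
            raise ValueError(f"unknown mask shape {self.mask_shape!r}")


@dataclass
class PlumageImage:
    """Rendered image plus analytic ground truth from the noiseless layout."""

    image: MaskedImage
    truth_map: ColorMap
    truth_metrics: PatternMetrics


def _patch_mask(patch: Patch, h: int, w: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    if patch.shape == "band":
        r0, r1 = patch.geometry
        return (yy >= round(r0 * h)) & (yy < round(r1 * h))
    if patch.shape == "rect":
        x0, y0, x1, y1 = patch.geometry
        return (
            (xx >= round(x0 * w))
            & (xx < round(x1 * w))
            & (yy >= round(y0 * h))
            & (yy < round(y1 * h))
        )
    cx, cy, rx, ry = patch.geometry
    return ((xx - cx * w) / (rx * w)) ** 2 + ((yy - cy * h) / (ry * h)) ** 2 <= 1.0


def make_plumage_image(
    spec: PlumageSpec, red_thresholds=RED_THRESHOLDS
) -> PlumageImage:
    """Render a spec and return the image with its analytic ground truth.

    Patches are drawn in order (later wins) on top of the base colour;
    noise is clipped Gaussian in sRGB.  Ground-truth metrics are computed
    from the noiseless label grid and the realised 8-bit patch colours, so
    a zero-noise image measured through the segmentation pipeline should
    reproduce them exactly.
    """
    h, w = spec.height, spec.width
    if spec.mask_shape == "ellipse":
        yy, xx = np.mgrid[0:h, 0:w]
        mask = ((xx - w / 2) / (w / 2 - 0.5)) ** 2 + (
            (yy - h / 2) / (h / 2 - 0.5)
        ) ** 2 <= 1.0
    else:
        mask = np.ones((h, w), dtype=bool)

    colors_lab = [spec.base_color_lab] + [p.color_lab for p in spec.patches]
    colors_rgb = lab_array_to_rgb(np.asarray(colors_lab, dtype=float))
    labels = np.zeros((h, w), dtype=int)
    for k, patch in enumerate(spec.patches, start=1):
        labels[_patch_mask(patch, h, w)] = k
    # merge classes that realise to the same 8-bit sRGB triple
    _, uniq_idx, inverse = np.unique(
        colors_rgb, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(uniq_idx)  # keep first-drawn order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    labels = rank[inverse][labels]
    colors_rgb = colors_rgb[np.sort(uniq_idx)]

    pixels = colors_rgb[labels]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = pixels.astype(float) + rng.normal(0.0, spec.noise_sd, pixels.shape)
        pixels = np.clip(np.round(noisy), 0, 255).astype(np.uint8)
    image = MaskedImage(pixels=pixels, mask=mask)

    counts = np.bincount(labels[mask], minlength=len(colors_rgb))
    keep = np.flatnonzero(counts)
    remap = -np.ones(len(colors_rgb), dtype=int)
    remap[keep] = np.arange(len(keep))
    truth_labels = np.where(mask, remap[labels], -1)
    palette_lab = rgb_array_to_lab(colors_rgb[keep].astype(float))
    proportions = counts[keep] / counts.sum()
    truth_map = ColorMap(
        labels=truth_labels, palette=palette_lab, proportions=proportions
    )
    chrom, achrom = boundary_strength(truth_map)
    red_truth = float(
        proportions[red_mask_lab(palette_lab, red_thresholds)].sum()
    )
    truth_metrics = PatternMetrics(
        chromatic_contrast=chrom,
        achromatic_contrast=achrom,
        simpson_scaled=simpson_scaled(proportions),
        red_proportion=red_truth,
    )
    return PlumageImage(image=image, truth_map=truth_map, truth_metrics=truth_metrics)


def random_plumage_spec(
    rng: np.random.Generator,
    width: int = 120,
    height: int = 120,
    noise_sd: float = 4.0,
    mask_shape: str = "ellipse",
    min_class_fraction: float = 0.04,
    max_tries: int = 50,
) -> PlumageSpec:
    """A varied multi-patch spec for cohort-level tests.

    Base colour plus two or three patches drawn from a fixed well-separated
    Lab palette, with randomised geometry; most specs include a red patch
    of variable size.  Specs whose draw order (almost) occludes a patch are
    rejected and redrawn so every colour class keeps at least
    ``min_class_fraction`` of the mask — sliver classes are not stable
    under resampling and do not resemble real plumage patches.
    """
    # imported here to avoid a module-level cycle
    from plumadrum.pattern_metrics import compute_pattern_metrics
    from plumadrum.segmentation import make_color_map, resample_to_common_width

    for _ in range(max_tries):
        spec = _draw_plumage_spec(rng, width, height, noise_sd, mask_shape)
        quiet = PlumageSpec(
            width=width,
            height=height,
            base_color_lab=spec.base_color_lab,
            patches=spec.patches,
            noise_sd=0.0,
            mask_shape=spec.mask_shape,
        )
        full = make_plumage_image(quiet)
        props = full.truth_map.proportions
        if len(props) != len(spec.patches) + 1 or props.min() < min_class_fraction:
            continue
        # the layout must be resolvable at coarser sampling frequencies:
        # near-coincident patch edges can leave sub-pixel slivers whose
        # adjacency structure flips between sampling schemes
        ok = True
        ref = full.truth_metrics
        for w in (3 * width // 4, width // 2):
            ds = resample_to_common_width(full.image, w)
            m = compute_pattern_metrics(ds, make_color_map(ds))
            if not (
                abs(m.chromatic_contrast - ref.chromatic_contrast) <= 1.5
                and abs(m.achromatic_contrast - ref.achromatic_contrast) <= 1.5
                and abs(m.simpson_scaled - ref.simpson_scaled) <= 0.02
                and abs(m.red_proportion - ref.red_proportion) <= 0.01
            ):
                ok = False
                break
        if ok:
            return spec
    raise RuntimeError("could not draw a non-degenerate plumage spec")


def _draw_plumage_spec(rng, width, height, noise_sd, mask_shape) -> PlumageSpec:
    names = list(_PALETTE_LAB)
    base = names[rng.integers(0, 2)]  # black or white base
    others = [n for n in names if n != base]
    n_patches = int(rng.integers(1, 4))
    chosen = list(rng.choice(others, size=n_patches, replace=False))
    if "red" not in chosen and rng.random() < 0.7:
        chosen[0] = "red"
    patches = []
    for name in chosen:
        if rng.random() < 0.5:
            cx, cy = rng.uniform(0.25, 0.75, 2)
            rx, ry = rng.uniform(0.12, 0.42, 2)
            geom = (cx, cy, rx, ry)
            shape = "ellipse"
        else:
            r0 = rng.uniform(0.02, 0.6)
            r1 = r0 + rng.uniform(0.1, 0.5)
            geom = (r0, min(r1, 0.98))
            shape = "band"
        patches.append(Patch(shape=shape, color_lab=_PALETTE_LAB[name], geometry=geom))
    return PlumageSpec(
        width=width,
        height=height,
        base_color_lab=_PALETTE_LAB[base],
        patches=patches,
        noise_sd=noise_sd,
        mask_shape=mask_shape,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def simulate_tree(n: int, rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth tree with ``n`` tips, rescaled to unit root-to-tip depth.

    A Yule process: starting from two lineages at the root, each lineage
    splits at rate ``rate``; the simulation stops after reaching n tips
    plus one final exponential waiting time.  The result is ultrametric
    with all tips at depth 1 and labels T1..Tn.
    """
    if n < 3:
        raise ValueError("need at least 3 tips")
    if rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = root.new_child()
        active.append((child, 0.0))
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (rate * k))
        idx = int(rng.integers(0, k))
        node, birth = active.pop(idx)
        node.edge.length = t - birth
        for _ in range(2):
            active.append((node.new_child(), t))
    t += rng.exponential(1.0 / (rate * n))
    for node, birth in active:
        node.edge.length = t - birth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tns.new_taxon(label=f"T{i}")
    return tree


#: Design-matrix term order used throughout the package.
TRAIT_TERMS = (
    "intercept",
    "color_diversity",
    "chromatic_contrast",
    "achromatic_contrast",
    "red_patch_size",
    "habitat",
)

_METRIC_LOG_MEANS = {
    "color_diversity": -0.4,
    "chromatic_contrast": 1.2,
    "achromatic_contrast": 1.3,
    "red_patch_size": -0.8,
}


@dataclass
class SimulationSpec:
    """Parameters of the trait-evolution simulation.

    ``beta`` orders as (intercept, colour diversity, chromatic contrast,
    achromatic contrast, red patch size, habitat) and acts on the log10
    scale; the emitted trait table is on the raw scale (10^x), with
    habitat as a closed/open string.
    """

    n_species: int = 132
    birth_rate: float = 1.0
    beta: tuple[float, ...] = (0.0, 0.0, 0.15, 0.0, 0.0, 0.0)
    beta_length: tuple[float, ...] = (1.2, 0.0, 0.0, 0.0, 0.0, 0.0)
    lam: float = 0.9
    resid_sigma2: float = 0.04
    bm_sigma2: float = 0.09
    habitat_threshold: float = 0.0
    mass_slope: float = -0.3
    mass_intercept: float = 1.0
    mass_log_mean: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        if self.resid_sigma2 <= 0 or self.bm_sigma2 <= 0:
            raise ValueError("variances must be positive")
        if self.n_species < 4:
            raise ValueError("need at least 4 species")
        if len(self.beta) != 6 or len(self.beta_length) != 6:
            raise ValueError("beta vectors must have 6 entries")


def simulate_traits(tree: dendropy.Tree, spec: SimulationSpec) -> pd.DataFrame:
    """Evolve a trait table on ``tree`` under the spec's model.

    Colour predictors and the log body mass follow Brownian motion on the
    tree; habitat is the indicator of a Brownian liability exceeding its
    threshold; the responses are linear in the design matrix with
    multivariate-normal residuals of covariance σ²·C(λ).  Deterministic
    for a fixed seed.
    """
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    n = len(species)
    if spec.n_species != n:
        raise ValueError(f"tree has {n} tips but spec.n_species={spec.n_species}")
    c = phylo_covariance(tree, species)
    chol_c = np.linalg.cholesky(c)
    chol_cl = np.linalg.cholesky(
        lambda_transform(c, spec.lam) + 1e-12 * np.eye(n)
    )
    streams = np.random.default_rng(spec.seed).spawn(9)

    log_metrics = {}
    for name, sub in zip(_METRIC_LOG_MEANS, streams[:4]):
        z = sub.standard_normal(n)
        log_metrics[name] = _METRIC_LOG_MEANS[name] + np.sqrt(
            spec.bm_sigma2
        ) * (chol_c @ z)
    liability = chol_c @ streams[4].standard_normal(n)
    habitat01 = (liability > spec.habitat_threshold).astype(int)
    log_mass = spec.mass_log_mean + np.sqrt(spec.bm_sigma2) * (
        chol_c @ streams[5].standard_normal(n)
    )

    x = np.column_stack(
        [np.ones(n)]
        + [log_metrics[m] for m in _METRIC_LOG_MEANS]
        + [habitat01]
    )
    eps_speed = np.sqrt(spec.resid_sigma2) * (
        chol_cl @ streams[6].standard_normal(n)
    )
    eps_length = np.sqrt(spec.resid_sigma2) * (
        chol_cl @ streams[7].standard_normal(n)
    )
    y_speed = x @ np.asarray(spec.beta) + eps_speed
    log_speed = spec.mass_intercept + spec.mass_slope * log_mass + y_speed
    log_length = x @ np.asarray(spec.beta_length) + eps_length

    return pd.DataFrame(
        {
            "species": species,
            "drum_speed": 10.0**log_speed,
            "drum_length": 10.0**log_length,
            "body_mass": 10.0**log_mass,
            "habitat": np.where(habitat01 == 1, "open", "closed"),
            "color_diversity": 10.0 ** log_metrics["color_diversity"],
            "chromatic_contrast": 10.0 ** log_metrics["chromatic_contrast"],
            "achromatic_contrast": 10.0 ** log_metrics["achromatic_contrast"],
            "red_patch_size": 10.0 ** log_metrics["red_patch_size"],
        }
    )
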