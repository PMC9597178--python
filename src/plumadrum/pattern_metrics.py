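"""Colour-pattern geometry statistics and inter-image colour distances.

Four per-image statistics are computed from a colour map: chromatic and
achromatic boundary strength (transition-frequency-weighted mean colour
distance between adjacent colour classes), a scaled Simpson diversity of
the class proportions, and the fraction of plumage pixels falling in the
red region of Lab space.  Pairwise image colour distances (an
earth-mover's transport distance over palette/proportion signatures) feed
a neighbour-joining tree of colour similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from plumadrum.colorspace import rgb_array_to_lab
from plumadrum.segmentation import ColorMap, MaskedImage

#: Lab thresholds delimiting the "red" region: L > 55, a > 30, b > 5
#: (all strict inequalities).
RED_THRESHOLDS = (55.0, 30.0, 5.0)


@dataclass
class TransitionMatrix:
    """Counts of adjacent valid-pixel class pairs (4-neighbourhood).

    ``counts[i, j]`` with i ≤ j is the number of unordered horizontal or
    vertical neighbour pairs with classes (i, j); the lower triangle is
    zero by construction.
    """

    counts: np.ndarray  # (k, k) upper-triangular int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def off_diagonal_total(self) -> int:
        return self.total - int(np.trace(self.counts))

    def get(self, i: int, j: int) -> int:
        lo, hi = min(i, j), max(i, j)
        return int(self.counts[lo, hi])


@dataclass
class PatternMetrics:
    """The four per-species colour statistics."""

    chromatic_contrast: float
    achromatic_contrast: float
    simpson_scaled: float
    red_proportion: float

    def __post_init__(self) -> None:
        for name in ("chromatic_contrast", "achromatic_contrast"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("simpson_scaled", "red_proportion"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "chromatic_contrast": self.chromatic_contrast,
            "achromatic_contrast": self.achromatic_contrast,
            "simpson_scaled": self.simpson_scaled,
            "red_proportion": self.red_proportion,
        }


def transition_counts(cm: ColorMap) -> TransitionMatrix:
    """Count unordered class pairs over horizontal + vertical neighbours.

    Pairs touching background (label −1) are excluded.
    """
    k = cm.n_classes
    counts = np.zeros((k, k), dtype=np.int64)
    labels = cm.labels
    for a, b in (
        (labels[:, :-1], labels[:, 1:]),  # horizontal pairs
        (labels[:-1, :], labels[1:, :]),  # vertical pairs
    ):
        valid = (a >= 0) & (b >= 0)
        lo = np.minimum(a[valid], b[valid])
        hi = np.maximum(a[valid], b[valid])
        np.add.at(counts, (lo, hi), 1)
    return TransitionMatrix(counts=counts)


def boundary_strength(
    cm: ColorMap, tm: TransitionMatrix | None = None
) -> tuple[float, float]:
    """Mean chromatic and achromatic contrast across class boundaries.

    Each off-diagonal class pair (i < j) contributes its colour distance
    weighted by its share of the off-diagonal transition counts.  A map
    with a single class (or no off-diagonal transitions) scores (0, 0).
    """
    if tm is None:
        tm = transition_counts(cm)
    k = cm.n_classes
    if k < 2:
        return 0.0, 0.0
    iu = np.triu_indices(k, k=1)
    t = tm.counts[iu].astype(float)
    t_sum = t.sum()
    if t_sum == 0:
        return 0.0, 0.0
    w = t / t_sum
    pal = cm.palette
    diff = pal[iu[0]] - pal[iu[1]]
    chrom = np.sqrt((diff[:, 1:] ** 2).sum(axis=1))
    achrom = np.abs(diff[:, 0])
    return float(w @ chrom), float(w @ achrom)


def simpson_scaled(proportions, method: str = "excess") -> float:
    """Scaled Simpson diversity of class proportions, in [0, 1].

    With inverse Simpson D = 1/Σp², the default ``excess`` scaling returns
    (D − 1)/(k − 1): 1 when all k classes are equal in size, → 0 when one
    class dominates, and exactly 0 for the degenerate single-class map.
    ``method="ratio"`` returns the alternative D/k scaling.
    """
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or len(p) < 1:
        raise ValueError("proportions must be a non-empty 1-D array")
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    k = len(p)
    d = 1.0 / float((p**2).sum())
    if method == "excess":
        return 0.0 if k == 1 else float((d - 1.0) / (k - 1.0))
    if method == "ratio":
        return float(d / k)
    raise ValueError(f"unknown scaling method {method!r}")


def red_mask_lab(lab: np.ndarray, thresholds=RED_THRESHOLDS) -> np.ndarray:
    """Boolean mask of Lab triples in the red region (strict inequalities)."""
    lab = np.asarray(lab, dtype=float)
    l_t, a_t, b_t = thresholds
    return (lab[..., 0] > l_t) & (lab[..., 1] > a_t) & (lab[..., 2] > b_t)


def red_proportion(img: MaskedImage, thresholds=RED_THRESHOLDS) -> float:
    """Fraction of valid pixels whose Lab colour lies in the red region.

    Computed on raw pixels, before segmentation.
    """
    lab = rgb_array_to_lab(img.pixels[img.mask].astype(float))
    return float(red_mask_lab(lab, thresholds).mean())


def compute_pattern_metrics(
    img: MaskedImage,
    cm: ColorMap,
    simpson_method: str = "excess",
    red_thresholds=RED_THRESHOLDS,
) -> PatternMetrics:
    """All four statistics for one image/colour-map pair."""
    chrom, achrom = boundary_strength(cm)
    return PatternMetrics(
        chromatic_contrast=chrom,
        achromatic_contrast=achrom,
        simpson_scaled=simpson_scaled(cm.proportions, method=simpson_method),
        red_proportion=red_proportion(img, thresholds=red_thresholds),
    )


def image_color_distance(a: ColorMap, b: ColorMap) -> float:
    """Earth-mover distance between two (palette, proportions) signatures.

    Minimum-cost transport of proportion mass with CIE76 ΔE as ground
    cost, solved exactly as a small linear program (palettes have at most
    27 entries).
    """
    pa, wa = a.palette, a.proportions
    pb, wb = b.palette, b.proportions
    ka, kb = len(wa), len(wb)
    cost = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=-1))
    # supply rows + demand columns; the final demand row is redundant
    n_var = ka * kb
    a_eq = np.zeros((ka + kb - 1, n_var))
    b_eq = np.zeros(ka + kb - 1)
    for i in range(ka):
        a_eq[i, i * kb : (i + 1) * kb] = 1.0
        b_eq[i] = wa[i]
    for j in range(kb - 1):
        a_eq[ka + j, j::kb] = 1.0
        b_eq[ka + j] = wb[j]
    res = linprog(cost.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - tiny LPs are always feasible
        raise RuntimeError(f"transport LP failed: {res.message}")
    return max(0.0, float(res.fun))


def _validate_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    return d


def neighbour_joining(d, names) -> str:
    """Saitou–Nei neighbour joining; returns an unrooted Newick string.

    Negative branch lengths are clamped to zero with a warning.  Ties in
    the Q criterion break on the lowest pair of indices.
    """
    d = _validate_distance_matrix(d)
    names = list(names)
    n = len(names)
    if len(d) != n:
        raise ValueError("names length must match matrix size")
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")

    def _blen(x: float) -> float:
        if x < -1e-12:
            warnings.warn(
                f"negative branch length {x:.6g} clamped to 0", stacklevel=3
            )
        return max(0.0, x)

    nodes = list(names)  # newick fragments
    dist = d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = dist.sum(axis=1)
        q = (m - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        iu = np.triu_indices(m, k=1)
        best = np.argmin(q[iu])
        i, j = int(iu[0][best]), int(iu[1][best])
        li = 0.5 * dist[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dist[i, j] - li
        li, lj = _blen(li), _blen(lj)
        merged = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        d_new = 0.5 * (dist[i, :] + dist[j, :] - dist[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_dist = np.zeros((m - 1, m - 1))
        new_dist[:-1, :-1] = dist[np.ix_(keep, keep)]
        new_dist[-1, :-1] = new_dist[:-1, -1] = d_new[keep]
        dist = new_dist
        nodes = [nodes[k] for k in keep] + [merged]
    # resolve the final three nodes exactly
    la = _blen(0.5 * (dist[0, 1] + dist[0, 2] - dist[1, 2]))
    lb = _blen(0.5 * (dist[0, 1] + dist[1, 2] - dist[0, 2]))
    lc = _blen(0.5 * (dist[0, 2] + dist[1, 2] - dist[0, 1]))
    return (
        f"({nodes[0]}:{la:.10g},{nodes[1]}:{lb:.10g},{nodes[2]}:{lc:.10g});"
    )
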