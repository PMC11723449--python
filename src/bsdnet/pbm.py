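"""Prediction balance module (PBM).

Long-tailed detection sets are dominated by a few head categories; the PBM
counteracts this at train time only, by adding zero-mean Gaussian noise to
the per-category classification logits, scaled per category by normalised
inverse pixel frequency:

    p_k        = sum of annotated box areas (pixels^2) of category k
    Pix_k      = log( sum_i p_i / p_k )                 (class frequency vector)
    Var_k      = Pix_k / max_i Pix_i * delta,  delta ~ Normal(0, sigma^2)
    score_k   += Var_k                                   (training only)

The head category (largest p_k) gets the smallest perturbation, the tail
the largest.  sigma defaults to 4, the value found best in ablation.  The
module is weightless and is a strict no-op at inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_SIGMA = 4.0


@dataclass(frozen=True)
class ClassPixelStats:
    """Per-category accumulated pixel areas and derived frequency vector."""
    pixel_sum: np.ndarray  # p_k, clamped to >= 1
    frequency: np.ndarray  # Pix_k = log(sum_i p_i / p_k)

    @property
    def n_categories(self) -> int:
        return len(self.pixel_sum)


@dataclass(frozen=True)
class VariationVector:
    variation: np.ndarray  # Variation_k, one entry per category
    sigma: float


def compute_class_pixel_stats(annotations, n_categories: int) -> ClassPixelStats:
    """Accumulate per-category box areas and derive the frequency vector.

    `annotations` is an iterable of (category_id, box_width_px, box_height_px).
    Categories absent from the annotations are clamped to 1 pixel (with a
    warning) so the logarithm stays defined.
    """
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    p = np.zeros(n_categories, dtype=np.float64)
    for cat, w, h in annotations:
        if not 0 <= cat < n_categories:
            raise ValueError(f"category id {cat} outside [0, {n_categories})")
        if w <= 0 or h <= 0:
            raise ValueError(f"non-positive box dims ({w}, {h})")
        p[cat] += float(w) * float(h)
    empty = p < 1.0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} categories have no annotated pixels; "
            "clamping their pixel sum to 1", stacklevel=2)
        p[empty] = 1.0
    freq = np.log(p.sum() / p)
    return ClassPixelStats(pixel_sum=p, frequency=freq)


def sample_variation(stats: ClassPixelStats, sigma: float = DEFAULT_SIGMA,
                     rng_seed: int | np.random.Generator = 0) -> VariationVector:
    """Draw one perturbation vector: Var_k = Pix_k / max_i Pix_i * delta_k,
    delta_k ~ Normal(0, sigma^2), drawn independently per category."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    top = stats.frequency.max()
    if top <= 0.0 or sigma == 0.0:
        # uniform class distribution (or single category, or sigma 0):
        # no perturbation by convention
        var = np.zeros(stats.n_categories, dtype=np.float64)
    else:
        delta = rng.normal(0.0, sigma, size=stats.n_categories)
        var = stats.frequency / top * delta
    return VariationVector(variation=var, sigma=float(sigma))


def apply_variation(scores: np.ndarray, variation: VariationVector,
                    training: bool) -> np.ndarray:
    """Add the perturbation to per-category prediction scores while training;
    return scores unchanged (the very same array) at inference."""
    if not training:
        return scores
    scores = np.asarray(scores)
    if scores.shape[-1] != len(variation.variation):
        raise ValueError(
            f"scores have {scores.shape[-1]} categories, "
            f"variation has {len(variation.variation)}")
    return scores + variation.variation.astype(scores.dtype)
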