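"""Colorimetric in situ signal quantification.

The hybridization signal of a stained rhopalium micrograph is the fraction of
rhopalium pixels whose color falls in a purple hue band (NBT/BCIP reaction
product), after gray-world white balancing and with an explicit exclusion of
the brown hue band occupied by melanin pigment. Stain intensity is
deliberately not interpreted — only the stained area fraction.

Colors are handled in HSV. The purple band defaults to 260-320 degrees and
the brown exclusion to 20-50 degrees; the thresholds are configurable because
no canonical values exist for this stain/camera combination.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv

from .containers import StainQuant
from .errors import InsufficientDataError, RejectedInputError
from .stats import GroupComparison, anova_tukey, ks_two_sample

DEFAULT_PURPLE_BAND = (260.0, 320.0)
DEFAULT_BROWN_BAND = (20.0, 50.0)
DEFAULT_MIN_SATURATION = 0.15


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise RejectedInputError("expected an (h, w, 3) RGB image")
    if img.dtype == np.uint8:
        img = img / 255.0
    return np.asarray(img, dtype=float)


def white_balance(image) -> np.ndarray:
    """Gray-world white balance: scale channels so their means equalize.

    Idempotent within tolerance (a second pass changes nothing beyond clipping
    effects). Rejects an all-black image, whose channel means are zero.
    """
    img = _as_float_rgb(image)
    means = img.reshape(-1, 3).mean(axis=0)
    if np.any(means == 0.0):
        raise RejectedInputError("cannot white balance: a channel mean is zero")
    gray = means.mean()
    return np.clip(img * (gray / means)[None, None, :], 0.0, 1.0)


def purple_mask(
    image,
    hue_band: tuple = DEFAULT_PURPLE_BAND,
    min_saturation: float = DEFAULT_MIN_SATURATION,
    exclude_brown_band: tuple = DEFAULT_BROWN_BAND,
) -> np.ndarray:
    """Boolean mask of stained (purple) pixels.

    A pixel is in the mask iff its hue lies inside ``hue_band`` (degrees),
    its saturation is at least ``min_saturation``, and its hue lies outside
    ``exclude_brown_band`` (melanin).
    """
    lo, hi = hue_band
    blo, bhi = exclude_brown_band
    if not (0 <= lo < hi <= 360 and 0 <= blo < bhi <= 360 and 0 <= min_saturation <= 1):
        raise RejectedInputError("thresholds outside valid ranges")
    hsv = rgb2hsv(_as_float_rgb(image))
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    return (hue >= lo) & (hue <= hi) & (sat >= min_saturation) & ~((hue >= blo) & (hue <= bhi))


def signal_ratio(
    purple: np.ndarray,
    rhopalium_mask: np.ndarray,
    image_id: str = "",
    condition: str = "control",
) -> StainQuant:
    """Signal = |purple AND rhopalium| / |rhopalium| as a :class:`StainQuant`."""
    purple = np.asarray(purple, dtype=bool)
    rhop = np.asarray(rhopalium_mask, dtype=bool)
    if purple.shape != rhop.shape:
        raise RejectedInputError("purple mask and rhopalium mask shapes differ")
    total = int(rhop.sum())
    if total == 0:
        raise RejectedInputError("empty rhopalium mask")
    return StainQuant(
        image_id=image_id,
        condition=condition,
        rhopalium_px=total,
        purple_px=int((purple & rhop).sum()),
    )


def quantify_image(
    image,
    rhopalium_mask: np.ndarray,
    image_id: str = "",
    condition: str = "control",
    balance: bool = True,
    **mask_kwargs,
) -> StainQuant:
    """White balance (optional), mask purple pixels, and compute the ratio."""
    img = white_balance(image) if balance else _as_float_rgb(image)
    return signal_ratio(purple_mask(img, **mask_kwargs), rhopalium_mask,
                        image_id=image_id, condition=condition)


def compare_signal_distributions(a, b, method: str = "ks", labels=("a", "b")) -> GroupComparison:
    """Compare two groups of stain quantifications.

    ``method='ks'`` (default) runs the two-sample Kolmogorov-Smirnov test on
    the signal ratios; ``method='anova'`` runs one-way ANOVA + Tukey (used for
    the RNAi comparison). Each group needs at least 5 quantifications.
    """
    sig_a = np.array([q.signal if isinstance(q, StainQuant) else float(q) for q in a])
    sig_b = np.array([q.signal if isinstance(q, StainQuant) else float(q) for q in b])
    if sig_a.size < 5 or sig_b.size < 5:
        raise InsufficientDataError("each group needs >= 5 quantifications")
    if method == "ks":
        return ks_two_sample(sig_a, sig_b, labels=labels)
    if method == "anova":
        return anova_tukey({labels[0]: sig_a, labels[1]: sig_b})
    raise RejectedInputError(f"unknown method {method!r}")
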