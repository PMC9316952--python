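"""Otsu-based discriminability filtering of detected cells.

Each detected-cell crop is converted to a single-channel stain signal
(by default the DAB optical-density channel of Ruifrok-Johnston colour
deconvolution, so stained pixels score high and the counterstain stays
dark-free), denoised with a Gaussian kernel and optionally
contrast-enhanced with a local range filter. Otsu's method then yields a per-patch statistic sigma —
the histogram split maximizing between-class variance — which acts as a
stain-strength summary: clearly stained ("discriminable") cells produce
a high sigma, weak ones a low sigma.

Per whole-slide image (the antibody labelling intensity varies from
slide to slide) an acceptance threshold is computed from all detections:

    T = (sum of sigma values) / N  -  min(sigma)

i.e. the mean Otsu statistic minus the lowest one. A detection is kept
("discriminable") when its sigma strictly surpasses T.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter, minimum_filter
from skimage import exposure
from skimage.color import rgb2hed

from .heatmap import DetectionRecord

_LUMA = np.array([0.2126, 0.7152, 0.0722])

# DAB optical density that maps to full signal; ~0.2 is a saturated
# strong ring after Ruifrok-Johnston colour deconvolution
DAB_SCALE = 0.2


class ConstantImageError(ValueError):
    """Otsu statistic undefined: the signal has no bimodal split."""


@dataclass(frozen=True)
class SignalPatch:
    """Single-channel stain-signal image in [0, 1] (stain = high)."""

    values: np.ndarray
    source: DetectionRecord | None = None


@dataclass(frozen=True)
class ThresholdSummary:
    """Per-case Otsu statistics and the acceptance threshold T."""

    sigmas: tuple[float, ...]
    n: int
    sigma_sum: float
    t_min: float
    T: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "n": self.n, "sigma_sum": self.sigma_sum,
            "t_min": self.t_min, "T": self.T}, indent=2))


def preprocess(crop: np.ndarray, gaussian_sigma: float = 1.0,
               enhance: bool = True, enhance_method: str = "range",
               enhance_size: int = 5, signal_channel: str = "stain",
               source: DetectionRecord | None = None) -> SignalPatch:
    """RGB crop -> denoised, optionally contrast-enhanced stain signal.

    The single-channel conversion puts stained pixels at the highest
    values. ``signal_channel="stain"`` (default) takes the DAB optical
    density from Ruifrok-Johnston colour deconvolution, which isolates
    the brown chromogen from the counterstain — with a hemalum
    counterstain present, a plain grayscale makes nuclei as dark as a
    weakly stained ring and the Otsu statistic stops tracking stain
    strength. ``signal_channel="luminance"`` is the generic inverted
    grayscale for stains without a deconvolution basis.

    Then: Gaussian denoising (``gaussian_sigma = 0`` is the identity)
    and optional local-contrast enhancement where each output pixel
    reflects the intensity variation in its neighbourhood — ``"range"``
    uses a max-min range filter, ``"clahe"`` adaptive histogram
    equalisation. Output is clipped to [0, 1].
    """
    if crop.size == 0:
        raise ValueError("empty crop")
    crop = np.asarray(crop, dtype=np.float64)
    if signal_channel == "stain":
        signal = rgb2hed(crop)[..., 2] / DAB_SCALE
    elif signal_channel == "luminance":
        signal = 1.0 - crop @ _LUMA
    else:
        raise ValueError(f"unknown signal_channel {signal_channel!r}")
    if gaussian_sigma > 0:
        signal = gaussian_filter(signal, sigma=gaussian_sigma)
    if enhance:
        if enhance_method == "range":
            signal = (maximum_filter(signal, size=enhance_size)
                      - minimum_filter(signal, size=enhance_size))
        elif enhance_method == "clahe":
            signal = exposure.equalize_adapthist(
                np.clip(signal, 0.0, 1.0))
        else:
            raise ValueError(f"unknown enhance_method {enhance_method!r}")
    return SignalPatch(values=np.clip(signal, 0.0, 1.0), source=source)


def otsu_statistic(signal: SignalPatch | np.ndarray, bins: int = 256) -> float:
    """Otsu threshold of the signal histogram, as a bin-centre value.

    Maximizes between-class variance over `bins` equal bins on [0, 1].
    When the variance curve has a flat maximal plateau (two modes with
    empty bins between them), the plateau's midpoint is returned, so a
    symmetric bimodal signal splits halfway between its modes. Raises
    :class:`ConstantImageError` for an (effectively) constant image,
    which callers treat as less-discriminable.
    """
    values = signal.values if isinstance(signal, SignalPatch) else signal
    x = np.asarray(values, dtype=np.float64).ravel()
    hist, edges = np.histogram(x, bins=bins, range=(0.0, 1.0))
    if np.count_nonzero(hist) < 2:
        raise ConstantImageError("constant signal: no bimodal split exists")
    centres = (edges[:-1] + edges[1:]) / 2.0
    p = hist / hist.sum()
    w0 = np.cumsum(p)                       # weight of class <= bin k
    mu = np.cumsum(p * centres)
    mu_total = mu[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    between = np.zeros(bins)
    between[valid] = (mu_total * w0[valid] - mu[valid]) ** 2 \
        / (w0[valid] * w1[valid])
    first = int(np.argmax(between))
    # midpoint of the contiguous maximal plateau containing the argmax
    tol = max(1e-15, abs(between[first]) * 1e-12)
    last = first
    while last + 1 < bins and abs(between[last + 1] - between[first]) <= tol:
        last += 1
    return float((centres[first] + centres[last]) / 2.0)


def acceptance_threshold(sigmas: Sequence[float]) -> ThresholdSummary:
    """Per-case acceptance threshold: mean sigma minus minimum sigma."""
    sig = tuple(float(s) for s in sigmas)
    if not sig:
        raise ValueError("need at least one Otsu statistic")
    n = len(sig)
    total = float(np.sum(sig))
    t_min = float(np.min(sig))
    return ThresholdSummary(sigmas=sig, n=n, sigma_sum=total, t_min=t_min,
                            T=total / n - t_min)


def partition(records: Iterable[DetectionRecord], summary: ThresholdSummary,
              strict: bool = True):
    """Split detections into (discriminable, less_discriminable) by T.

    A record is discriminable when its sigma surpasses T — strictly by
    default (``sigma > T``); set ``strict=False`` for ``>=``. Flags and
    T are written back onto the records.
    """
    keep: list[DetectionRecord] = []
    drop: list[DetectionRecord] = []
    for rec in records:
        if rec.sigma is None:
            raise ValueError("record has no Otsu statistic; run preprocess/otsu first")
        ok = rec.sigma > summary.T if strict else rec.sigma >= summary.T
        rec.discriminable = bool(ok)
        rec.threshold_T = summary.T
        (keep if ok else drop).append(rec)
    return keep, drop


def score_detections(records: Sequence[DetectionRecord],
                     gaussian_sigma: float = 1.0, enhance: bool = False,
                     enhance_method: str = "range",
                     signal_channel: str = "stain",
                     central_radius: float | None = 24.0) -> None:
    """Fill each record's sigma from its crop (constant crops get 0.0).

    By default sigma is computed on the denoised stain signal without
    local-contrast enhancement: a contrast image no longer carries
    absolute stain intensity, and the statistic is meant to read the
    minimum intensity of the cell's own pixels. ``central_radius``
    restricts the histogram to a disc around the detection centre so a
    neighbouring cell intruding into the crop's corner cannot skew the
    statistic; ``None`` uses the whole crop.
    """
    mask = None
    for rec in records:
        if rec.crop is None:
            raise ValueError("detection has no crop attached")
        patch = preprocess(rec.crop, gaussian_sigma=gaussian_sigma,
                           enhance=enhance, enhance_method=enhance_method,
                           signal_channel=signal_channel, source=rec)
        values = patch.values
        if central_radius is not None:
            if mask is None or mask.shape != values.shape:
                h, w = values.shape
                yy, xx = np.ogrid[:h, :w]
                mask = np.hypot(xx - w // 2, yy - h // 2) <= central_radius
            values = values[mask]
        try:
            rec.sigma = otsu_statistic(values)
        except ConstantImageError:
            rec.sigma = 0.0     # flat patch: trivially less-discriminable


def filter_case(records: Sequence[DetectionRecord], strict: bool = True):
    """Compute the per-case T from these records' sigmas and partition."""
    summary = acceptance_threshold([r.sigma for r in records])
    keep, drop = partition(records, summary, strict=strict)
    return keep, drop, summary
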