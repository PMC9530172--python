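"""Threshold-gated starch quantification on paired TPF/SHG photon-count images.

The statistic implemented here is the ratio of summed second-harmonic (SHG)
intensity to the number of two-photon-fluorescence (TPF) pixels above
threshold.  SHG arises only from semicrystalline starch granules, while the
chlorophyll TPF marks chloroplast thylakoids, so the ratio is a relative
measure of starch content per unit chloroplast area in an imaged field:

    ratio = I_SHG / Cnt_TPF

with I_SHG the sum of raw SHG counts over pixels whose count exceeds a small
background level (default 2 counts at 0.128 ms dwell) and Cnt_TPF the number
of TPF pixels whose count exceeds a morphology-delineating threshold (default
50 counts at 0.016 ms dwell).  "Above" means strictly greater than; the
convention is isolated in :func:`above` so it can be flipped in one place.

Thresholds are defined at the reference dwell times.  When an image carries a
different dwell, the threshold is rescaled linearly with dwell (photon counts
are proportional to integration time) and the rescaling is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import closing as _closing
from skimage.morphology import disk

logger = logging.getLogger(__name__)

CHANNEL_TPF = "TPF"
CHANNEL_SHG = "SHG"

#: Dwell times (ms) at which the default thresholds are defined.
REF_TPF_DWELL_MS = 0.016
REF_SHG_DWELL_MS = 0.128

DEFAULT_TPF_THRESHOLD = 50.0
DEFAULT_SHG_BACKGROUND = 2.0
DEFAULT_CLOSING_RADIUS_PX = 2

FLAG_NO_TPF_PIXELS = "no_tpf_pixels"
FLAG_NO_SHG_PIXELS = "no_shg_positive_pixels"


class ChannelMismatchError(ValueError):
    """An operation received an image tagged with the wrong channel."""


@dataclass(frozen=True)
class ChannelImage:
    """A single-channel photon-count raster.

    pixels are nonnegative integers (detected photon counts during the pixel
    dwell interval); ``channel`` is ``"TPF"`` or ``"SHG"``; ``dwell_ms`` is the
    per-pixel integration time.
    """

    pixels: np.ndarray
    channel: str
    dwell_ms: float
    provenance: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(
                "photon-count contract: pixels must be an integer array, "
                f"got dtype {px.dtype}"
            )
        if px.size and px.min() < 0:
            raise ValueError("photon counts must be nonnegative")
        if self.channel not in (CHANNEL_TPF, CHANNEL_SHG):
            raise ValueError(f"channel must be TPF or SHG, got {self.channel!r}")
        if not self.dwell_ms > 0:
            raise ValueError("dwell_ms must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class StarchQuant:
    """Per-image record of the starch ratio statistic and its operands."""

    i_shg: int
    cnt_tpf: int
    ratio: float  # NaN when cnt_tpf == 0
    shg_threshold: float
    tpf_threshold: float
    flags: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return FLAG_NO_TPF_PIXELS not in self.flags


@dataclass(frozen=True)
class ColocReport:
    """SHG-inside-chloroplast colocalization summary.

    ``inside_fraction`` = |SHG-positive ∩ chloroplast| / |SHG-positive|,
    NaN (flagged) when there are no SHG-positive pixels.
    """

    chloroplast_mask: np.ndarray
    shg_positive_mask: np.ndarray
    inside_fraction: float
    closing_radius_px: int
    flags: tuple[str, ...] = ()


def above(values: np.ndarray, threshold: float, strict: bool = True) -> np.ndarray:
    """Boolean mask of values above threshold.

    The single place where the "above" convention lives: strict (>) by
    default, ``strict=False`` for >=.
    """
    values = np.asarray(values)
    return values > threshold if strict else values >= threshold


def effective_threshold(
    threshold: float, dwell_ms: float, ref_dwell_ms: float
) -> float:
    """Rescale a count threshold defined at ``ref_dwell_ms`` to ``dwell_ms``."""
    if math.isclose(dwell_ms, ref_dwell_ms, rel_tol=1e-9):
        return float(threshold)
    eff = threshold * dwell_ms / ref_dwell_ms
    logger.info(
        "threshold %g (defined at %g ms dwell) rescaled to %g for %g ms dwell",
        threshold, ref_dwell_ms, eff, dwell_ms,
    )
    return eff


def _require_channel(img: ChannelImage, channel: str) -> None:
    if img.channel != channel:
        raise ChannelMismatchError(
            f"expected a {channel} image, got channel {img.channel!r}"
        )


def tpf_pixel_count(
    img: ChannelImage,
    threshold: float = DEFAULT_TPF_THRESHOLD,
    *,
    strict: bool = True,
    closing_radius_px: int = 0,
    rescale_with_dwell: bool = True,
) -> int:
    """Number of TPF pixels above threshold (Cnt_TPF).

    ``closing_radius_px > 0`` counts pixels of the morphologically closed mask
    instead of the raw thresholded mask (the cleaned variant; default raw).
    """
    _require_channel(img, CHANNEL_TPF)
    thr = (
        effective_threshold(threshold, img.dwell_ms, REF_TPF_DWELL_MS)
        if rescale_with_dwell
        else float(threshold)
    )
    mask = above(img.pixels, thr, strict)
    if closing_radius_px > 0:
        mask = _padded_closing(mask, closing_radius_px)
    return int(mask.sum())


def shg_intensity(
    img: ChannelImage,
    background: float = DEFAULT_SHG_BACKGROUND,
    *,
    strict: bool = True,
    rescale_with_dwell: bool = True,
) -> int:
    """Summed raw SHG counts over pixels above the background level (I_SHG).

    Retained pixels contribute their full count; the background level gates
    pixel membership but is not subtracted.
    """
    _require_channel(img, CHANNEL_SHG)
    bg = (
        effective_threshold(background, img.dwell_ms, REF_SHG_DWELL_MS)
        if rescale_with_dwell
        else float(background)
    )
    keep = above(img.pixels, bg, strict)
    return int(img.pixels[keep].sum())


def starch_ratio(
    tpf: ChannelImage,
    shg: ChannelImage,
    *,
    tpf_threshold: float = DEFAULT_TPF_THRESHOLD,
    shg_background: float = DEFAULT_SHG_BACKGROUND,
    strict: bool = True,
    tpf_closing_radius_px: int = 0,
    rescale_with_dwell: bool = True,
) -> StarchQuant:
    """Compute I_SHG / Cnt_TPF for a paired TPF/SHG acquisition.

    A field with no TPF pixels above threshold yields a flagged record with
    NaN ratio — never a silent zero — so downstream aggregation can exclude it
    explicitly.
    """
    _require_channel(tpf, CHANNEL_TPF)
    _require_channel(shg, CHANNEL_SHG)
    if tpf.shape != shg.shape:
        raise ValueError(f"shape mismatch: TPF {tpf.shape} vs SHG {shg.shape}")
    cnt = tpf_pixel_count(
        tpf, tpf_threshold, strict=strict,
        closing_radius_px=tpf_closing_radius_px,
        rescale_with_dwell=rescale_with_dwell,
    )
    i_shg = shg_intensity(
        shg, shg_background, strict=strict, rescale_with_dwell=rescale_with_dwell
    )
    if cnt > 0:
        ratio = i_shg / cnt
        flags: tuple[str, ...] = ()
    else:
        ratio = float("nan")
        flags = (FLAG_NO_TPF_PIXELS,)
    return StarchQuant(
        i_shg=i_shg, cnt_tpf=cnt, ratio=ratio,
        shg_threshold=shg_background, tpf_threshold=tpf_threshold, flags=flags,
    )


def _padded_closing(mask: np.ndarray, radius_px: int) -> np.ndarray:
    # Pad before closing so border objects are treated the same as interior
    # ones; closing is extensive, so the cropped result still contains `mask`.
    r = int(radius_px)
    padded = np.pad(mask, r + 1, mode="constant", constant_values=False)
    closed = _closing(padded, disk(r))
    return closed[r + 1 : -(r + 1), r + 1 : -(r + 1)]


def chloroplast_mask(
    img: ChannelImage,
    threshold: float = DEFAULT_TPF_THRESHOLD,
    closing_radius_px: int = DEFAULT_CLOSING_RADIUS_PX,
    *,
    strict: bool = True,
    rescale_with_dwell: bool = True,
) -> np.ndarray:
    """Chloroplast region estimated from the TPF channel.

    Thresholds the autofluorescence and applies a morphological closing with a
    disk of the given radius.  The closing fills the TPF-dark stroma pockets
    inside chloroplasts (where the starch granules sit) so that "inside the
    chloroplast" includes them; it never removes above-threshold pixels.
    """
    _require_channel(img, CHANNEL_TPF)
    thr = (
        effective_threshold(threshold, img.dwell_ms, REF_TPF_DWELL_MS)
        if rescale_with_dwell
        else float(threshold)
    )
    raw = above(img.pixels, thr, strict)
    if closing_radius_px <= 0:
        return raw
    return _padded_closing(raw, closing_radius_px)


def colocalization(
    tpf: ChannelImage,
    shg: ChannelImage,
    *,
    tpf_threshold: float = DEFAULT_TPF_THRESHOLD,
    shg_background: float = DEFAULT_SHG_BACKGROUND,
    closing_radius_px: int = DEFAULT_CLOSING_RADIUS_PX,
    strict: bool = True,
    rescale_with_dwell: bool = True,
) -> ColocReport:
    """Fraction of SHG-positive pixels that fall inside the chloroplast mask."""
    _require_channel(tpf, CHANNEL_TPF)
    _require_channel(shg, CHANNEL_SHG)
    if tpf.shape != shg.shape:
        raise ValueError(f"shape mismatch: TPF {tpf.shape} vs SHG {shg.shape}")
    mask = chloroplast_mask(
        tpf, tpf_threshold, closing_radius_px,
        strict=strict, rescale_with_dwell=rescale_with_dwell,
    )
    bg = (
        effective_threshold(shg_background, shg.dwell_ms, REF_SHG_DWELL_MS)
        if rescale_with_dwell
        else float(shg_background)
    )
    shg_pos = above(shg.pixels, bg, strict)
    n_pos = int(shg_pos.sum())
    if n_pos == 0:
        return ColocReport(
            chloroplast_mask=mask, shg_positive_mask=shg_pos,
            inside_fraction=float("nan"),
            closing_radius_px=closing_radius_px, flags=(FLAG_NO_SHG_PIXELS,),
        )
    inside = int((shg_pos & mask).sum())
    return ColocReport(
        chloroplast_mask=mask, shg_positive_mask=shg_pos,
        inside_fraction=inside / n_pos, closing_radius_px=closing_radius_px,
    )
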