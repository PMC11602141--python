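"""Image conditioning and kymograph extraction.

The raw assay data are two-channel time-lapse stacks of a surface-tethered,
doubly-anchored DNA imaged with an intercalator stain (DNA channel) and
labeled ParB (protein channel). Conditioning follows the standard recipe
for this assay: a per-frame 2-D median filter (window 10 px), white
top-hat background subtraction, then a kymograph built by summing 11
pixels across the DNA axis at every axial position and stacking frames.
The two channels are excited alternately, so the protein channel is
aligned by a single-frame shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Kymograph",
    "median_smooth_image",
    "tophat_subtract",
    "extract_kymograph",
    "align_second_channel",
    "smooth_series",
    "estimate_background",
    "find_tether_ends",
]


@dataclass
class Kymograph:
    """Space-time intensity matrix for one channel.

    ``intensity`` is ``(n_frames, n_positions)``; position runs along the
    DNA axis. ``end_pixels`` marks the tether anchors (left < right) and
    ``kb_per_pixel`` converts axial pixels to genomic kilobases.
    """

    intensity: np.ndarray
    frame_interval_s: float
    kb_per_pixel: float
    end_pixels: tuple[int, int]
    channel: str = "dna"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("kymograph intensity must be 2-D (frames x positions)")
        n_frames, n_pos = self.intensity.shape
        if n_frames < 1 or n_pos < 4:
            raise ValueError("kymograph needs >= 1 frame and >= 4 positions")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("kymograph intensities must be finite")
        if self.kb_per_pixel <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration values must be positive")
        left, right = self.end_pixels
        if not (0 <= left < right < n_pos):
            raise ValueError("end_pixels must satisfy 0 <= left < right < n_positions")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_positions(self) -> int:
        return self.intensity.shape[1]

    @property
    def span(self) -> slice:
        """Pixel slice between (and including) the tether ends."""
        return slice(self.end_pixels[0], self.end_pixels[1] + 1)

    def position_kb(self, position_px) -> np.ndarray:
        """Genomic position (kb from the left tether) of axial pixel(s)."""
        return (np.asarray(position_px, dtype=float) - self.end_pixels[0]) * self.kb_per_pixel


def _as_stack(image: np.ndarray) -> tuple[np.ndarray, bool]:
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image[None], True
    if image.ndim != 3:
        raise ValueError("expected a 2-D frame or a 3-D stack")
    return image, False


def median_smooth_image(stack: np.ndarray, window_px: int = 10) -> np.ndarray:
    """Per-frame 2-D median filter (square window, reflected edges)."""
    if window_px < 1:
        raise ValueError("window_px must be >= 1")
    arr, single = _as_stack(stack)
    out = ndimage.median_filter(arr, size=(1, window_px, window_px), mode="reflect")
    return out[0] if single else out


def tophat_subtract(stack: np.ndarray, struct_px: int = 15) -> np.ndarray:
    """Per-frame morphological white top-hat with a flat square element.

    Removes any structure broader than ``struct_px`` (smooth background,
    uneven illumination) while preserving narrow bright features; the
    result is nonnegative for flat structuring elements.
    """
    if struct_px < 1:
        raise ValueError("struct_px must be >= 1")
    arr, single = _as_stack(stack)
    out = ndimage.white_tophat(arr, size=(1, struct_px, struct_px), mode="reflect")
    out = np.maximum(out, 0.0)
    return out[0] if single else out


def extract_kymograph(
    stack: np.ndarray,
    axis_row: int,
    frame_interval_s: float,
    end_pixels: tuple[int, int],
    dna_length_kb: float,
    half_width_px: int = 5,
    channel: str = "dna",
) -> Kymograph:
    """Build a kymograph by summing ``2*half_width+1`` rows across the DNA axis.

    The DNA is assumed horizontal in the frame at row ``axis_row``; per
    frame the intensities of rows ``axis_row +/- half_width_px`` (11 px by
    default) are summed at every axial position, then frames are stacked.
    The same axis must be reused for the second channel.
    """
    arr, single = _as_stack(stack)
    n_frames, height, width = arr.shape
    lo = axis_row - half_width_px
    hi = axis_row + half_width_px + 1
    if lo < 0 or hi > height:
        raise ValueError("axis band extends outside the image")
    kymo = arr[:, lo:hi, :].sum(axis=1)
    left, right = end_pixels
    kb_per_pixel = dna_length_kb / (right - left)
    return Kymograph(intensity=kymo, frame_interval_s=frame_interval_s,
                     kb_per_pixel=kb_per_pixel, end_pixels=(left, right),
                     channel=channel)


def align_second_channel(first: Kymograph, second: Kymograph,
                         shift_frames: int = 1) -> tuple[Kymograph, Kymograph]:
    """Align alternately-excited channels by shifting the second channel.

    Frame ``t`` of the returned second channel was acquired one exposure
    after frame ``t`` of the first; both are truncated to the common range.
    """
    if shift_frames < 0:
        raise ValueError("shift_frames must be >= 0")
    n = min(first.n_frames, second.n_frames - shift_frames)
    if n < 1:
        raise ValueError("channels do not overlap after the shift")
    a = Kymograph(first.intensity[:n], first.frame_interval_s, first.kb_per_pixel,
                  first.end_pixels, first.channel)
    b = Kymograph(second.intensity[shift_frames:shift_frames + n],
                  second.frame_interval_s, second.kb_per_pixel,
                  second.end_pixels, second.channel)
    return a, b


def smooth_series(series, window_frames: int = 9) -> np.ndarray:
    """Running median of a 1-D signal; the window shrinks at the ends.

    NaNs are ignored inside each window (a window of all-NaN yields NaN).
    """
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError("window_frames must be odd and >= 1")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    half = window_frames // 2
    out = np.empty_like(x)
    n = x.size
    for i in range(n):
        w = x[max(0, i - half):min(n, i + half + 1)]
        valid = w[~np.isnan(w)]
        out[i] = np.median(valid) if valid.size else np.nan
    return out


def estimate_background(kymo: Kymograph) -> float:
    """Robust per-pixel background level of a kymograph.

    Uses the median of pixels outside the tether span when at least 20 such
    pixels exist, otherwise the 5th percentile of all intensities.
    """
    left, right = kymo.end_pixels
    outside = np.concatenate([kymo.intensity[:, :left].ravel(),
                              kymo.intensity[:, right + 1:].ravel()])
    if outside.size >= 20:
        return float(np.median(outside))
    return float(np.percentile(kymo.intensity, 5))


def find_tether_ends(kymo_intensity: np.ndarray, min_step_frac: float = 0.2) -> tuple[int, int]:
    """Automatic tether-end finder (convenience; ends are normally given).

    Locates the largest rising and falling steps of the time-averaged
    axial profile. ``min_step_frac`` rejects profiles whose step is less
    than this fraction of the dynamic range.
    """
    profile = np.asarray(kymo_intensity, dtype=float).mean(axis=0)
    grad = np.diff(profile)
    left = int(np.argmax(grad)) + 1   # first bright pixel
    right = int(np.argmin(grad))      # last bright pixel
    rng = profile.max() - profile.min()
    if right <= left or rng <= 0 or (np.max(grad) < min_step_frac * rng):
        raise ValueError("could not locate tether ends from the intensity profile")
    return left, right
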