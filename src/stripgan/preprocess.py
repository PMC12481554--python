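"""Image standardization chain and rotation augmentation.

The chain mirrors the raw-strip pipeline: tight edge crop to 3×660×50,
symmetric zero padding to 3×660×660, then a crop around the control and
test line rows resized to 3×128×128.  Geometric augmentation rotates each
final image in 3.6° steps over a full revolution (100 images per input).

All images are channel-first float arrays in [0, 1]; coordinates are
row-major with the origin at the top-left.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from skimage.transform import resize

RAW_SHAPE = (3, 660, 50)
SQUARE_SHAPE = (3, 660, 660)
FINAL_SIZE = 128


class PreprocessError(ValueError):
    pass


class SegmentationError(PreprocessError):
    """No foreground strip region found."""


class LineDetectionError(PreprocessError):
    """Fewer than two line minima found; carries the intensity profile."""

    def __init__(self, message: str, profile: np.ndarray):
        super().__init__(message)
        self.profile = profile


def _resize_chw(img: np.ndarray, height: int, width: int) -> np.ndarray:
    out = resize(np.moveaxis(img, 0, 2), (height, width), order=1,
                 mode="constant", cval=0.0, anti_aliasing=False,
                 preserve_range=True)
    return np.moveaxis(out, 2, 0)


def crop_to_edges(img: np.ndarray, out_height: int = 660, out_width: int = 50,
                  fg_threshold: float = 0.05) -> np.ndarray:
    """Tight bounding-box crop of the strip, resized to ``out_height×out_width``.

    Foreground is any pixel whose channel-mean exceeds ``fg_threshold``;
    strips are bright against a dark background.
    """
    if img.ndim != 3 or img.shape[0] != 3:
        raise PreprocessError(f"expected 3×H×W image, got {img.shape}")
    gray = img.mean(axis=0)
    mask = gray > fg_threshold
    if not mask.any():
        raise SegmentationError("no foreground region above threshold")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    crop = img[:, rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    if crop.shape == (3, out_height, out_width):
        return crop.copy()
    return _resize_chw(crop, out_height, out_width)


def pad_to_square(img: np.ndarray) -> np.ndarray:
    """Zero-pad columns symmetrically so width equals height.

    For the standard 3×660×50 input the padding splits 305/305 and the
    content occupies columns 305..354.
    """
    if img.ndim != 3 or img.shape[0] != 3:
        raise PreprocessError(f"expected 3×H×W image, got {img.shape}")
    _, h, w = img.shape
    if w > h:
        raise PreprocessError(f"width {w} exceeds height {h}")
    left = (h - w) // 2
    right = h - w - left
    return np.pad(img, ((0, 0), (0, 0), (left, right)))


def detect_line_rows(img: np.ndarray, smooth_sigma: float | None = None,
                     prominence: float = 0.05) -> tuple[int, int]:
    """Locate the control and test line rows on the row-mean intensity profile.

    Only columns carrying strip content (nonzero after padding) enter the
    profile.  The two most prominent minima of the smoothed profile are
    returned in increasing row order; fewer than two raises
    :class:`LineDetectionError` with the profile attached.
    """
    col_mass = img.mean(axis=(0, 1))
    cols = col_mass > 1e-9
    if not cols.any():
        cols = np.ones_like(cols, dtype=bool)
    profile = img[:, :, cols].mean(axis=(0, 2))
    sigma = smooth_sigma if smooth_sigma is not None else max(1.0,
                                                              len(profile) / 200)
    smoothed = gaussian_filter1d(profile, sigma)
    peaks, props = find_peaks(-smoothed, prominence=prominence)
    if len(peaks) < 2:
        raise LineDetectionError(
            f"found {len(peaks)} line minima, need 2", profile=smoothed)
    order = np.argsort(props["prominences"])[::-1][:2]
    r1, r2 = sorted(int(peaks[i]) for i in order)
    return r1, r2


def crop_lines(img: np.ndarray, line_rows: tuple[int, int] | None = None,
               margin_frac: float = 0.2,
               out_size: int = FINAL_SIZE) -> np.ndarray:
    """Crop a window spanning both line rows and resize to ``out_size`` square.

    ``line_rows`` gives (control_row, test_row) explicitly; if omitted they
    are auto-detected from the intensity profile.  The window extends past
    each line by ``margin_frac`` of the inter-line distance.
    """
    if img.ndim != 3 or img.shape[0] != 3:
        raise PreprocessError(f"expected 3×H×W image, got {img.shape}")
    _, h, _ = img.shape
    if line_rows is None:
        r1, r2 = detect_line_rows(img)
    else:
        r1, r2 = sorted(int(r) for r in line_rows)
        if not (0 <= r1 < h and 0 <= r2 < h):
            raise PreprocessError("line rows outside image bounds")
    d = max(1, r2 - r1)
    m = margin_frac * d
    top = max(0, int(round(r1 - m)))
    bottom = min(h, int(round(r2 + m)) + 1)
    return _resize_chw(img[:, top:bottom, :], out_size, out_size)


# -- rotation ------------------------------------------------------------------

def rotate_batch(stack: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a (N, C, H, W) stack counter-clockwise about the image center.

    Bilinear interpolation, zero fill outside the frame; one vectorized
    gather for the whole stack, which keeps full-revolution schedules over
    thousands of images fast.  Matches ``skimage.transform.rotate`` with
    ``order=1, mode='constant'``.
    """
    n, c, h, w = stack.shape
    a = np.deg2rad(angle_deg)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yo, xo = np.meshgrid(np.arange(h) - cy, np.arange(w) - cx, indexing="ij")
    # inverse map of a CCW rotation in (x right, y down) image coordinates
    xs = np.cos(a) * xo - np.sin(a) * yo + cx
    ys = np.sin(a) * xo + np.cos(a) * yo + cy
    x0 = np.floor(xs).astype(np.int64)
    y0 = np.floor(ys).astype(np.int64)
    fx = xs - x0
    fy = ys - y0
    out = np.zeros_like(stack)
    for dy in (0, 1):
        for dx in (0, 1):
            yy = y0 + dy
            xx = x0 + dx
            wgt = ((fy if dy else 1 - fy) * (fx if dx else 1 - fx))
            valid = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
            yc = np.clip(yy, 0, h - 1)
            xc = np.clip(xx, 0, w - 1)
            out += stack[:, :, yc, xc] * (wgt * valid)[None, None, :, :]
    return out


def rotation_angles(step_deg: float = 3.6) -> np.ndarray:
    """The angle schedule k·step for k = 0..N−1, one full revolution."""
    if not 0.0 < step_deg <= 360.0:
        raise PreprocessError("step_deg must be in (0, 360]")
    ratio = 360.0 / step_deg
    if abs(ratio - round(ratio)) > 1e-9:
        raise PreprocessError(
            f"step {step_deg}° does not divide 360° (no partial revolutions)")
    n = int(round(ratio))
    return np.arange(n) * step_deg


def augment_rotations(img: np.ndarray, step_deg: float = 3.6) -> list[np.ndarray]:
    """All rotations of one image over a full revolution.

    Returns exactly ``round(360/step_deg)`` images; the k=0 entry is a
    bit-identical copy of the input.
    """
    angles = rotation_angles(step_deg)
    out = [img.copy()]
    for angle in angles[1:]:
        out.append(rotate_batch(img[None], float(angle))[0])
    return out


def iter_rotation_batches(stack: np.ndarray, step_deg: float = 3.6):
    """Yield ``(angle, rotated stack)`` over the full-revolution schedule.

    Streams one angle at a time so a 100-fold augmentation of thousands of
    images never materializes in memory at once.
    """
    for angle in rotation_angles(step_deg):
        if angle == 0.0:
            yield 0.0, stack.copy()
        else:
            yield float(angle), rotate_batch(stack, float(angle))


def flip(img: np.ndarray, axis: str = "horizontal") -> np.ndarray:
    """Mirror an image; flipping twice restores the original bit-exactly."""
    if axis == "horizontal":
        return img[:, :, ::-1].copy()
    if axis == "vertical":
        return img[:, ::-1, :].copy()
    raise PreprocessError(f"unknown flip axis {axis!r}")
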