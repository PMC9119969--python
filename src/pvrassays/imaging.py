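"""Segmentation primitives shared by the proliferation and wound assays.

The pipeline mirrors classical texture-based segmentation of phase-contrast
and widefield fluorescence microscopy: Gaussian denoising, a pixel-wise
local-entropy map (Shannon entropy of the intensity histogram in a square
neighbourhood), thresholding of the entropy map, morphological cleanup and
connected-component labelling.  Cellular regions carry fine intensity
texture and therefore high local entropy; smooth background does not.

Conventions (fixed for determinism, configurable where noted):

* intensities are quantised to 256 integer bins (0-255) before
  histogramming; entropy is reported in bits (log2);
* both the Gaussian filter and the entropy window use reflective
  (symmetric) border padding;
* connected components are 8-connected.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.filters.rank import entropy as _rank_entropy
from skimage.measure import label as _cc_label
from skimage.measure import regionprops
from skimage.morphology import disk
from sklearn.base import BaseEstimator, TransformerMixin

from .frames import FilterConfig, ImageFrame, InputError, SegmentationMask

__all__ = [
    "gaussian_denoise",
    "local_entropy",
    "threshold_entropy",
    "morphological_cleanup",
    "label_regions",
    "EntropySegmenter",
]


def _as_pixels(frame: ImageFrame | np.ndarray) -> np.ndarray:
    if isinstance(frame, ImageFrame):
        return frame.pixels
    return np.asarray(frame, dtype=float)


def gaussian_denoise(frame: ImageFrame, sigma: float) -> ImageFrame:
    """Gaussian smoothing with reflective border handling and unit DC gain.

    Parameters
    ----------
    frame : ImageFrame
        Input frame; pixel values must be finite.
    sigma : float
        Standard deviation of the Gaussian kernel, in pixels.
    """
    if sigma <= 0:
        raise InputError("sigma must be > 0")
    pixels = _as_pixels(frame)
    if not np.all(np.isfinite(pixels)):
        raise InputError("frame contains non-finite pixel values")
    smoothed = ndi.gaussian_filter(pixels, sigma=sigma, mode="reflect")
    return ImageFrame(
        pixels=smoothed,
        channel=frame.channel,
        timepoint=frame.timepoint,
        field_id=frame.field_id,
    )


def local_entropy(frame: ImageFrame | np.ndarray, window: int = 9) -> np.ndarray:
    """Pixel-wise Shannon entropy (bits) of the local intensity histogram.

    Each output pixel is the base-2 entropy of the 256-bin histogram of the
    quantised intensities in its ``window x window`` neighbourhood, with
    symmetric padding at the borders.  Values lie in ``[0, log2(256)]`` and,
    for a window of 81 pixels, are additionally bounded by ``log2(81)``.
    """
    if window % 2 == 0:
        raise InputError("entropy window must be odd")
    if window < 3:
        raise InputError("entropy window must be >= 3")
    pixels = _as_pixels(frame)
    if window > min(pixels.shape):
        raise InputError(
            f"window {window} does not fit in frame of shape {pixels.shape}"
        )
    quantised = np.clip(np.round(pixels), 0, 255).astype(np.uint8)
    pad = window // 2
    padded = np.pad(quantised, pad, mode="symmetric")
    footprint = np.ones((window, window), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank filters warn about bit depth
        ent = _rank_entropy(padded, footprint)
    return np.asarray(ent[pad:-pad, pad:-pad], dtype=float)


#: absolute local-entropy level (bits) separating texture from smooth background;
#: a window of cell-scale speckle carries well over 2 bits, denoised background well under
TEXTURED_BITS = 2.0


def threshold_entropy(
    entropy_map: np.ndarray, config: FilterConfig | None = None
) -> SegmentationMask:
    """Binarise an entropy map into textured (cellular) vs smooth pixels.

    Three threshold modes via ``config.entropy_threshold``:

    * ``"robust"`` (default): midpoint of the 0.5th and 99.5th entropy
      percentiles, i.e. halfway between the background and texture
      plateaus.  Unlike Otsu (or midpoints of interior percentiles), this
      stays on the slope between the plateaus even when one class covers
      almost the whole frame (near-blank or near-confluent fields).
    * ``"otsu"``: Otsu's threshold on the entropy map.
    * a float: fixed threshold in bits.

    A single-class map yields an all-true or all-false mask with a warning
    rather than failing, judged on the absolute entropy scale: when even
    the low extreme of the map is textured (> 2 bits) the frame is fully
    confluent; when even the high extreme is smooth (< 2 bits) it is
    blank.  This lets empty and fully-confluent fields flow through the
    pipeline.
    """
    config = config or FilterConfig()
    entropy_map = np.asarray(entropy_map, dtype=float)
    if not np.all(np.isfinite(entropy_map)):
        raise InputError("entropy map contains non-finite values")
    mode = config.entropy_threshold
    if isinstance(mode, str):
        p_lo, p_hi = np.percentile(entropy_map, [0.5, 99.5])
        if p_lo > TEXTURED_BITS or p_hi < TEXTURED_BITS:
            textured = p_lo > TEXTURED_BITS
            warnings.warn(
                "single-class entropy map; returning "
                + ("full" if textured else "empty")
                + " mask",
                stacklevel=2,
            )
            return SegmentationMask(
                np.full(entropy_map.shape, textured, dtype=bool),
                provenance={"threshold": None, "method": f"{mode}-single-class"},
            )
        if mode == "otsu":
            thr = float(threshold_otsu(entropy_map))
        else:  # robust extreme-percentile midpoint
            thr = float(0.5 * (p_lo + p_hi))
        method = mode
    else:
        thr = float(mode)
        method = "fixed"
    return SegmentationMask(
        entropy_map > thr, provenance={"threshold": thr, "method": method}
    )


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_area`` pixels."""
    labels = _cc_label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[labels]


def _padded_morph(mask: np.ndarray, radius: int, op) -> np.ndarray:
    """Apply a binary morphology op with edge-replicated padding (no border bias)."""
    fp = disk(radius)
    padded = np.pad(mask, radius, mode="edge")
    return op(padded, structure=fp)[radius:-radius, radius:-radius]


def edge_compensate(mask: SegmentationMask, radius: int) -> SegmentationMask:
    """Erode a raw entropy mask to undo the dilation of the entropy window.

    The local-entropy window (and the texture diffusion of the preceding
    Gaussian) raises entropy up to about half a window width beyond a
    textured region's true boundary, so the thresholded mask is dilated by
    roughly ``window // 2`` pixels.  A matching erosion restores the
    boundary and re-opens narrow background gaps falsely bridged by the
    window.
    """
    if radius <= 0:
        return mask
    m = ndi.binary_erosion(mask.mask, structure=disk(radius), border_value=1)
    prov = dict(mask.provenance, edge_compensation_radius=radius)
    return SegmentationMask(m, provenance=prov)


def morphological_cleanup(
    mask: SegmentationMask, config: FilterConfig | None = None
) -> SegmentationMask:
    """Opening, closing, optional hole filling and small-object removal."""
    config = config or FilterConfig()
    m = mask.mask
    if config.opening_radius > 0:
        m = _padded_morph(m, config.opening_radius, ndi.binary_opening)
    if config.closing_radius > 0:
        m = _padded_morph(m, config.closing_radius, ndi.binary_closing)
    if config.fill_holes:
        m = ndi.binary_fill_holes(m)
    if config.min_object_area > 0:
        m = _remove_small(m, config.min_object_area)
    prov = dict(mask.provenance)
    prov.update(
        opening_radius=config.opening_radius,
        closing_radius=config.closing_radius,
        fill_holes=config.fill_holes,
        min_object_area=config.min_object_area,
    )
    return SegmentationMask(m, provenance=prov)


def label_regions(
    mask: SegmentationMask, intensity_frames: list[ImageFrame] | None = None
) -> pd.DataFrame:
    """Label 8-connected components and tabulate per-region measurements.

    Returns a RegionTable: a DataFrame with one row per region, columns
    ``label``, ``area`` (pixels), ``centroid_row``, ``centroid_col`` and one
    ``mean_<channel>`` column per supplied intensity frame.
    """
    intensity_frames = intensity_frames or []
    for fr in intensity_frames:
        if fr.shape != mask.shape:
            raise InputError(
                f"intensity frame shape {fr.shape} does not match mask {mask.shape}"
            )
    labelled = _cc_label(mask.mask, connectivity=2)
    props = regionprops(labelled)
    rows = []
    for p in props:
        row = {
            "label": int(p.label),
            "area": int(p.area),
            "centroid_row": float(p.centroid[0]),
            "centroid_col": float(p.centroid[1]),
        }
        coords = tuple(p.coords.T)
        for fr in intensity_frames:
            row[f"mean_{fr.channel}"] = float(fr.pixels[coords].mean())
        rows.append(row)
    columns = ["label", "area", "centroid_row", "centroid_col"] + [
        f"mean_{fr.channel}" for fr in intensity_frames
    ]
    return pd.DataFrame(rows, columns=columns)


class EntropySegmenter(BaseEstimator, TransformerMixin):
    """Texture segmentation of a frame: denoise, local entropy, threshold, cleanup.

    A stateless scikit-learn transformer over 2-D frames.  ``transform``
    maps an :class:`ImageFrame` (or bare array) to a
    :class:`SegmentationMask`; ``fit`` is a no-op kept for pipeline
    compatibility.

    Parameters
    ----------
    sigma : float
        Gaussian denoising width in pixels (2 for phase contrast, 1 for
        fluorescence by convention).
    window : int
        Side of the square entropy neighbourhood (odd; default 9).
    threshold : "otsu" or float
        Entropy threshold in bits, or Otsu's method on the entropy map.
    opening_radius, closing_radius, min_object_area, fill_holes
        Morphological cleanup parameters.
    """

    def __init__(
        self,
        sigma: float = 2.0,
        window: int = 9,
        threshold: str | float = "robust",
        edge_compensation: int | None = None,
        opening_radius: int = 1,
        closing_radius: int = 3,
        min_object_area: int = 25,
        fill_holes: bool = False,
    ):
        self.sigma = sigma
        self.window = window
        self.threshold = threshold
        self.edge_compensation = edge_compensation
        self.opening_radius = opening_radius
        self.closing_radius = closing_radius
        self.min_object_area = min_object_area
        self.fill_holes = fill_holes

    def _config(self) -> FilterConfig:
        return FilterConfig(
            sigma_phase=self.sigma,
            sigma_fluor=self.sigma,
            entropy_window=self.window,
            entropy_threshold=self.threshold,
            edge_compensation_radius=self.edge_compensation,
            opening_radius=self.opening_radius,
            closing_radius=self.closing_radius,
            min_object_area=self.min_object_area,
            fill_holes=self.fill_holes,
        )

    def fit(self, X=None, y=None) -> "EntropySegmenter":
        self.n_features_in_ = 0  # stateless; attribute marks the estimator as fitted
        return self

    def transform(self, X: ImageFrame | np.ndarray) -> SegmentationMask:
        frame = X if isinstance(X, ImageFrame) else ImageFrame(pixels=X)
        cfg = self._config()
        denoised = gaussian_denoise(frame, self.sigma)
        ent = local_entropy(denoised, self.window)
        mask = threshold_entropy(ent, cfg)
        mask = edge_compensate(mask, cfg.resolved_edge_compensation(self.sigma))
        mask = morphological_cleanup(mask, cfg)
        mask.provenance.update(sigma=self.sigma, window=self.window)
        return mask

    def fit_transform(self, X, y=None, **kwargs) -> SegmentationMask:
        return self.fit(X, y).transform(X)
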