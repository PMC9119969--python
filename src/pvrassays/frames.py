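"""Core containers for image data and segmentation parameters.

All images are single-channel 2-D grids of nonnegative intensities on a
0-255 scale, stored as floats.  Channels follow the acquisition naming of
the assays: ``phase`` (phase contrast), ``405`` (nuclear stain) and ``488``
(marker: Ki67 or NRF2).  Pixel indexing is row-major, origin top-left,
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

VALID_CHANNELS = ("phase", "405", "488")

#: minimum frame side length: the 9x9 entropy window must fit
MIN_SIDE = 9


class InputError(ValueError):
    """Raised when an input frame, table or manifest is invalid."""


@dataclass
class ImageFrame:
    """One channel of one imaged field at one timepoint."""

    pixels: np.ndarray
    channel: str = "phase"
    timepoint: float = 0.0
    field_id: str = "field0"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InputError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < MIN_SIDE or self.pixels.shape[1] < MIN_SIDE:
            raise InputError(
                f"frame must be at least {MIN_SIDE}x{MIN_SIDE}, got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("frame contains non-finite pixel values")
        if self.channel not in VALID_CHANNELS:
            raise InputError(f"channel must be one of {VALID_CHANNELS}, got {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_tiff(self, path: str | Path) -> None:
        """Write the frame as a single-channel float32 TIFF."""
        tifffile.imwrite(str(path), self.pixels.astype(np.float32))

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        channel: str = "phase",
        timepoint: float = 0.0,
        field_id: Optional[str] = None,
    ) -> "ImageFrame":
        """Read a single-channel TIFF/PNG image file."""
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            pixels = tifffile.imread(str(path))
        else:
            import imageio.v3 as iio

            pixels = iio.imread(str(path))
        pixels = np.asarray(pixels, dtype=float)
        if pixels.ndim == 3 and pixels.shape[2] in (3, 4):
            # accept greyscale saved as RGB(A)
            pixels = pixels[..., 0]
        return cls(
            pixels=pixels,
            channel=channel,
            timepoint=timepoint,
            field_id=field_id if field_id is not None else path.stem,
        )


@dataclass
class SegmentationMask:
    """Binary mask congruent with its source frame, with provenance."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise InputError(f"mask must be 2-D, got shape {self.mask.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area(self) -> int:
        """Number of foreground pixels."""
        return int(self.mask.sum())

    @property
    def area_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class FilterConfig:
    """Parameters of the entropy-filter segmentation pipelines.

    ``sigma_phase`` / ``sigma_fluor`` are the Gaussian denoising widths for
    the phase-contrast and fluorescence pipelines.  ``entropy_window`` is the
    side of the square neighbourhood over which pixel-wise Shannon entropy
    is computed.  ``entropy_threshold`` is either ``"otsu"`` (threshold
    chosen by Otsu's method on the entropy map) or a fixed value in bits.
    """

    sigma_phase: float = 2.0
    sigma_fluor: float = 1.0
    entropy_window: int = 9
    entropy_threshold: str | float = "robust"
    edge_compensation_radius: int | None = None  # None -> entropy_window // 2
    opening_radius: int = 1
    closing_radius: int = 3
    min_object_area: int = 25
    fill_holes: bool = False
    # wound-specific parameters
    bandpass_sigma_low: float = 2.0
    bandpass_sigma_high: float = 16.0
    wound_closing_radius: int = 8
    wound_largest_component_only: bool = True
    # optional watershed split of touching nuclei (off by default)
    watershed_split: bool = False

    def __post_init__(self) -> None:
        if self.entropy_window < 3 or self.entropy_window % 2 == 0:
            raise InputError("entropy_window must be odd and >= 3")
        if self.sigma_phase <= 0 or self.sigma_fluor <= 0:
            raise InputError("Gaussian sigmas must be > 0")
        if isinstance(self.entropy_threshold, str) and self.entropy_threshold not in (
            "robust",
            "otsu",
        ):
            raise InputError(
                "entropy_threshold must be 'robust', 'otsu' or a fixed value in bits"
            )

    def resolved_edge_compensation(self, sigma: float) -> int:
        """Edge-compensation erosion radius for a pipeline denoised at ``sigma``.

        Defaults to ``entropy_window // 2 - round(sigma / 2)``: thresholding
        the entropy ramp at the plateau midpoint places the detected edge
        about half a window beyond the true texture boundary, pulled back
        in proportion to how far the Gaussian denoise spreads the ramp.
        """
        if self.edge_compensation_radius is None:
            return max(0, self.entropy_window // 2 - round(sigma / 2))
        return self.edge_compensation_radius

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        return cls(**d)
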