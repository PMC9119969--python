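"""Confluence growth curves and Ki67 / NRF2 fluorescence quantification.

Two pipelines: (1) phase-contrast frames are texture-segmented to give the
percent of the field occupied by cells (confluence), summarised over time
as a growth curve; (2) nuclei are segmented from the nuclear-stain (405)
channel, and each nucleus is called proliferation-positive when its mean
marker (488) intensity exceeds 10 on the 0-255 scale — a strict inequality
applied to the raw, unsmoothed 488 frame.  NRF2 nuclear localisation is
the area-weighted mean 488 intensity over all nuclear pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import FilterConfig, ImageFrame, InputError, SegmentationMask
from .imaging import EntropySegmenter, label_regions

__all__ = [
    "KI67_THRESHOLD",
    "ConfluenceRecord",
    "NucleiQuantification",
    "confluence_from_phase",
    "growth_curve",
    "segment_nuclei",
    "classify_ki67",
    "nuclear_mfi",
]

#: marker-positivity cutoff: mean 488 intensity strictly above this value
KI67_THRESHOLD = 10.0


@dataclass
class ConfluenceRecord:
    field_id: str
    timepoint: float
    confluence: float  # percent of frame area

    def __post_init__(self) -> None:
        if not 0 <= self.confluence <= 100:
            raise InputError(f"confluence must be in [0, 100], got {self.confluence}")


@dataclass
class NucleiQuantification:
    field_id: str
    nuclei_count: int
    ki67_positive_count: int
    ki67_positive_pct: float  # NaN when nuclei_count == 0
    nuclear_mfi_488: float  # NaN when nuclei_count == 0


def _segmenter(config: FilterConfig, sigma: float) -> EntropySegmenter:
    return EntropySegmenter(
        sigma=sigma,
        window=config.entropy_window,
        threshold=config.entropy_threshold,
        edge_compensation=config.edge_compensation_radius,
        opening_radius=config.opening_radius,
        closing_radius=config.closing_radius,
        min_object_area=config.min_object_area,
        fill_holes=config.fill_holes,
    )


def confluence_from_phase(
    frame: ImageFrame, config: FilterConfig | None = None
) -> ConfluenceRecord:
    """Percent of a phase-contrast frame covered by textured (cellular) area."""
    config = config or FilterConfig()
    mask = _segmenter(config, config.sigma_phase).fit_transform(frame)
    return ConfluenceRecord(
        field_id=frame.field_id,
        timepoint=frame.timepoint,
        confluence=100.0 * mask.area_fraction,
    )


def growth_curve(records: dict[str, list[ConfluenceRecord]]) -> pd.DataFrame:
    """Per-timepoint mean and sample s.d. of confluence across replicates.

    ``records`` maps replicate id to that replicate's confluence records;
    all replicates must cover the same timepoints.  With a single replicate
    the s.d. is reported as 0 with ``sd_defined = False``.
    """
    if not records:
        raise InputError("no replicates supplied")
    timesets = {
        rep: tuple(sorted(r.timepoint for r in recs)) for rep, recs in records.items()
    }
    reference = next(iter(timesets.values()))
    offenders = [rep for rep, ts in timesets.items() if ts != reference]
    if offenders:
        raise InputError(
            f"replicates {offenders} do not cover the same timepoints as the others"
        )
    n = len(records)
    rows = []
    for t in reference:
        values = [
            next(r.confluence for r in recs if r.timepoint == t)
            for recs in records.values()
        ]
        rows.append(
            {
                "timepoint": t,
                "mean_confluence": float(np.mean(values)),
                "sd": float(np.std(values, ddof=1)) if n > 1 else 0.0,
                "n": n,
                "sd_defined": n > 1,
            }
        )
    return pd.DataFrame(rows)


def segment_nuclei(
    frame405: ImageFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, SegmentationMask]:
    """Segment nuclei from the 405 channel; returns (RegionTable, mask).

    The region table carries per-nucleus area, centroid and mean 405
    intensity; attach 488 means via :func:`quantify_field` or
    :func:`classify_ki67` downstream.
    """
    config = config or FilterConfig()
    mask = _segmenter(config, config.sigma_fluor).fit_transform(frame405)
    if config.watershed_split:
        mask = _watershed_split(mask)
    table = label_regions(mask, [frame405])
    return table, mask


def _watershed_split(mask: SegmentationMask) -> SegmentationMask:
    """Optional distance-transform watershed to split touching nuclei."""
    import scipy.ndimage as ndi
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    dist = ndi.distance_transform_edt(mask.mask)
    peaks = peak_local_max(dist, min_distance=3, labels=mask.mask)
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=mask.mask, watershed_line=True)
    prov = dict(mask.provenance, watershed_split=True)
    return SegmentationMask(labels > 0, provenance=prov)


def classify_ki67(
    regions: pd.DataFrame, field_id: str = "", threshold: float = KI67_THRESHOLD
) -> NucleiQuantification:
    """Call each nucleus positive iff its mean 488 intensity strictly exceeds 10.

    With zero nuclei the percentage is reported as NaN (missing), never 0,
    so empty fields do not bias condition-level averages.
    """
    if "mean_488" not in regions.columns and len(regions):
        raise InputError("region table lacks a mean_488 column")
    n = len(regions)
    if n == 0:
        return NucleiQuantification(field_id, 0, 0, math.nan, math.nan)
    positive = int((regions["mean_488"] > threshold).sum())
    return NucleiQuantification(
        field_id=field_id,
        nuclei_count=n,
        ki67_positive_count=positive,
        ki67_positive_pct=100.0 * positive / n,
        nuclear_mfi_488=math.nan,
    )


def nuclear_mfi(mask: SegmentationMask, frame488: ImageFrame) -> float:
    """Area-weighted mean 488 intensity over the union of nuclear pixels.

    Returns NaN (missing) when no nuclear pixels are present.
    """
    if mask.shape != frame488.shape:
        raise InputError("mask and 488 frame shapes differ")
    if mask.area == 0:
        return math.nan
    return float(frame488.pixels[mask.mask].mean())


def quantify_field(
    frame405: ImageFrame,
    frame488: ImageFrame,
    config: FilterConfig | None = None,
) -> NucleiQuantification:
    """Full fluorescence pipeline for one field: segment, classify, MFI."""
    if frame405.shape != frame488.shape:
        raise InputError("405 and 488 frames must be congruent")
    table, mask = segment_nuclei(frame405, config)
    table = label_regions(mask, [frame405, frame488]) if len(table) else table
    quant = classify_ki67(table, field_id=frame405.field_id)
    quant.nuclear_mfi_488 = nuclear_mfi(mask, frame488)
    return quant
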