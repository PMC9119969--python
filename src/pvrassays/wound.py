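"""Scratch-wound quantification: wound masking and the recovery formula.

The cell-free scratch is found by texture analysis of phase-contrast
frames: a Gaussian band-pass (difference of Gaussians) isolates cell-scale
texture while suppressing slow illumination gradients, local entropy and
thresholding give the cellular region, a large-radius closing bridges
intracellular gaps, and the wound is the largest connected cell-free
component of the complement.  Recovery at time t is

    recovery_t = 100 * (A_0 - A_t) / A_0

where A_0 is the wound area immediately after scratching and A_t the wound
area t hours later.  Negative values (a growing wound) are reported and
flagged, never clipped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.measure import label as _cc_label

from .frames import FilterConfig, ImageFrame, InputError, SegmentationMask
from .imaging import (
    _padded_morph,
    edge_compensate,
    local_entropy,
    morphological_cleanup,
    threshold_entropy,
)

__all__ = ["wound_mask", "wound_recovery", "recovery_summary"]


class UndefinedBaselineError(ValueError):
    """Baseline wound area A_0 is zero; recovery is undefined."""


def wound_mask(frame: ImageFrame, config: FilterConfig | None = None) -> SegmentationMask:
    """Cell-free wound mask of a phase-contrast frame.

    A fully confluent frame yields an empty mask (wound area 0), not an
    error.
    """
    config = config or FilterConfig()
    px = frame.pixels
    low = ndi.gaussian_filter(px, config.bandpass_sigma_low, mode="reflect")
    high = ndi.gaussian_filter(px, config.bandpass_sigma_high, mode="reflect")
    bandpassed = np.clip(low - high + 128.0, 0.0, 255.0)
    ent = local_entropy(bandpassed, config.entropy_window)
    cellular = threshold_entropy(ent, config)
    cellular = edge_compensate(
        cellular, config.resolved_edge_compensation(config.bandpass_sigma_low)
    )
    cellular = morphological_cleanup(cellular, config)
    closed = _padded_morph(cellular.mask, config.wound_closing_radius, ndi.binary_closing)
    wound = ~closed
    if config.wound_largest_component_only and wound.any():
        labels = _cc_label(wound, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0  # background
        wound = labels == int(np.argmax(counts))
    prov = dict(cellular.provenance)
    prov.update(
        bandpass=(config.bandpass_sigma_low, config.bandpass_sigma_high),
        wound_closing_radius=config.wound_closing_radius,
        largest_component_only=config.wound_largest_component_only,
    )
    return SegmentationMask(wound, provenance=prov)


def wound_recovery(
    areas: dict[float, float] | pd.Series, well_id: str = ""
) -> pd.DataFrame:
    """Wound-recovery trajectory from per-timepoint wound areas.

    ``areas`` maps timepoint (hours) to wound area (pixels); it must contain
    timepoint 0, which defines the baseline A_0 for that well.  Returns a
    WoundTrajectory table with columns well_id, timepoint, wound_area,
    baseline_area, recovery (percent) and wound_grew (flag for negative
    recovery).
    """
    if isinstance(areas, pd.Series):
        areas = dict(areas)
    if 0 not in areas and 0.0 not in areas:
        raise InputError("areas must include the time-zero baseline")
    a0 = float(areas.get(0, areas.get(0.0)))
    if a0 <= 0:
        raise UndefinedBaselineError("baseline wound area A_0 must be > 0")
    rows = []
    for t in sorted(areas):
        at = float(areas[t])
        rec = 100.0 * (a0 - at) / a0
        rows.append(
            {
                "well_id": well_id,
                "timepoint": float(t),
                "wound_area": at,
                "baseline_area": a0,
                "recovery": rec,
                "wound_grew": rec < 0,
            }
        )
    return pd.DataFrame(rows)


def wound_trajectory_from_frames(
    frames: list[ImageFrame],
    config: FilterConfig | None = None,
    well_id: str = "",
) -> pd.DataFrame:
    """Mask every frame of a well's time series and compute its recovery."""
    areas = {fr.timepoint: float(wound_mask(fr, config).area) for fr in frames}
    return wound_recovery(areas, well_id=well_id)


def recovery_summary(
    trajectories: dict[str, list[pd.DataFrame]],
    timepoints: tuple[float, ...] = (12.0, 24.0, 36.0),
) -> pd.DataFrame:
    """Per-condition mean +- sample s.d. of recovery at fixed timepoints.

    ``trajectories`` maps condition to the wound trajectories of its
    replicate wells.  A replicate lacking a requested timepoint is excluded
    from that timepoint's mean and counted in ``n_missing``.
    """
    if not trajectories:
        raise InputError("no conditions supplied")
    rows = []
    for condition, wells in trajectories.items():
        if not wells:
            raise InputError(f"condition {condition!r} has no replicate wells")
        for t in timepoints:
            values = []
            missing = 0
            for traj in wells:
                hit = traj[traj["timepoint"] == t]
                if hit.empty:
                    missing += 1
                else:
                    values.append(float(hit["recovery"].iloc[0]))
            rows.append(
                {
                    "condition": condition,
                    "timepoint": t,
                    "mean_recovery": float(np.mean(values)) if values else np.nan,
                    "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
                    "n": len(values),
                    "n_missing": missing,
                }
            )
    return pd.DataFrame(rows)
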