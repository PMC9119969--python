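"""Seeded generators for every assay input, with ground-truth sidecars.

Each generator emulates the *property the downstream pipeline exploits*
rather than the optics of the instrument: phase-contrast and nuclear-stain
images are built from uniform intensity speckle inside cell regions (high
local entropy) on a near-constant background (low local entropy);
scratch-wound series carry a cell-free stripe whose area follows a
prescribed recovery trajectory; dye-solubilisation curves are two-segment
piecewise-linear with a known breakpoint; Ct tables invert exactly to known
fold changes in the absence of noise.

All randomness in one call flows from a single `numpy` Generator seeded
from the spec, so identical (spec, seed) pairs reproduce outputs
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .frames import ImageFrame
from .physchem import SolubilisationCurve

__all__ = [
    "PackingError",
    "SpecError",
    "PhaseFieldSpec",
    "FluorFieldSpec",
    "WoundSeriesSpec",
    "SolubilisationSpec",
    "CtTableSpec",
    "GroundTruth",
    "generate_phase_field",
    "generate_fluor_field",
    "generate_wound_series",
    "generate_solubilisation",
    "generate_ct_table",
]


class SpecError(ValueError):
    """A generator spec violates its invariants."""


class PackingError(RuntimeError):
    """Requested objects cannot be packed into the frame."""


def _round_half_away(x: float) -> int:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass
class GroundTruth:
    """Machine-readable ground truth accompanying a generated dataset.

    ``data`` holds scalar/array truth values keyed by name; arrays (masks)
    stay in memory, while :meth:`summary` returns a JSON-serialisable dict
    of the scalar quantities for sidecar files.
    """

    assay: str
    data: dict
    seed: int

    def summary(self) -> dict:
        out = {"assay": self.assay, "seed": self.seed}
        for k, v in self.data.items():
            if isinstance(v, np.ndarray):
                if v.size <= 4096:
                    out[k] = v.tolist()
                continue  # large arrays (masks) are written separately
            if isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            elif isinstance(v, list):
                v = [float(x) if isinstance(x, (np.floating, float)) else x for x in v]
            out[k] = v
        return out


# ---------------------------------------------------------------------------
# phase-contrast confluence fields
# ---------------------------------------------------------------------------


@dataclass
class PhaseFieldSpec:
    """Synthetic phase-contrast field at a prescribed confluence."""

    height: int = 256
    width: int = 256
    confluence_target: float = 50.0
    cell_radius_range: tuple[int, int] = (6, 12)
    texture_contrast: float = 80.0
    background_level: float = 100.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise SpecError("height and width must be >= 64")
        if not 0 <= self.confluence_target <= 100:
            raise SpecError("confluence_target must be in [0, 100]")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        rmin, rmax = self.cell_radius_range
        if rmin < 1 or rmax < rmin:
            raise SpecError("cell_radius_range must satisfy 1 <= min <= max")


def _disc_coords(h: int, w: int, cy: int, cx: int, r: int):
    y0, y1 = max(0, cy - r), min(h, cy + r + 1)
    x0, x1 = max(0, cx - r), min(w, cx + r + 1)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return (slice(y0, y1), slice(x0, x1)), inside


def _texture_field(
    mask: np.ndarray, background: float, contrast: float, noise_sd: float, rng
) -> np.ndarray:
    """Uniform speckle inside ``mask``, constant background outside, shared noise."""
    h, w = mask.shape
    img = np.full((h, w), background, dtype=float)
    n_in = int(mask.sum())
    if n_in:
        img[mask] = background + contrast * rng.uniform(-1.0, 1.0, size=n_in)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=(h, w))
    return np.clip(img, 0.0, 255.0)


def _cell_region_mask(
    h: int,
    w: int,
    target_fraction: float,
    radius_range: tuple[int, int],
    rng,
) -> np.ndarray:
    """Cell-region mask covering ``target_fraction`` of an ``h x w`` frame.

    The mask is a sub-level set of a correlated Gaussian random field whose
    correlation length is the mean cell radius, thresholded at the exact
    area quantile.  This emulates colony-like growth: cellular area and the
    remaining open background both form connected patches at the cell
    scale, so the mask area matches the target to well within one
    percentage point at any coverage.
    """
    from scipy.ndimage import gaussian_filter

    rmin, rmax = radius_range
    if target_fraction <= 0:
        return np.zeros((h, w), dtype=bool)
    if target_fraction >= 1:
        return np.ones((h, w), dtype=bool)
    if 4 * rmax > min(h, w):
        raise PackingError(
            f"cell radius {rmax} is too large for a {h}x{w} frame; "
            f"confluence_target {100 * target_fraction:.1f}% cannot be laid out"
        )
    corr = 0.5 * (rmin + rmax)
    field = gaussian_filter(rng.standard_normal((h, w)), sigma=corr, mode="reflect")
    return field < np.quantile(field, target_fraction)


def generate_phase_field(spec: PhaseFieldSpec) -> tuple[ImageFrame, GroundTruth]:
    """Textured phase-contrast field covering ``confluence_target`` +-1 point."""
    rng = np.random.default_rng(spec.seed)
    mask = _cell_region_mask(
        spec.height, spec.width, spec.confluence_target / 100.0,
        spec.cell_radius_range, rng,
    )
    img = _texture_field(
        mask, spec.background_level, spec.texture_contrast, spec.noise_sd, rng
    )
    frame = ImageFrame(pixels=img, channel="phase", timepoint=0.0, field_id=f"phase_s{spec.seed}")
    truth = GroundTruth(
        assay="confluence",
        data={
            "mask": mask,
            "area_fraction_pct": 100.0 * float(mask.mean()),
        },
        seed=spec.seed,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# two-channel fluorescence fields (nuclei + marker)
# ---------------------------------------------------------------------------


@dataclass
class FluorFieldSpec:
    """Synthetic two-channel field: nuclear stain (405) and marker (488).

    A fraction of nuclei carries a supra-threshold marker mean (the
    proliferation-positive population); the rest sit below the cutoff.
    """

    height: int = 640
    width: int = 640
    n_nuclei: int = 200
    nucleus_radius_range: tuple[int, int] = (5, 7)
    positive_fraction: float = 0.5
    positive_488_mean: float = 25.0
    negative_488_mean: float = 3.0
    nucleus_405_mean: float = 120.0
    noise_sd: float = 1.0
    min_separation: float = 28.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.positive_fraction <= 1:
            raise SpecError("positive_fraction must be in [0, 1]")
        if not (self.positive_488_mean > 10 >= self.negative_488_mean):
            raise SpecError(
                "positive_488_mean must exceed the cutoff 10 and "
                "negative_488_mean must not"
            )
        if self.n_nuclei < 0:
            raise SpecError("n_nuclei must be >= 0")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")


def _place_centres(
    h: int, w: int, n: int, margin: float, min_sep: float, rng, max_attempts: int
) -> np.ndarray:
    centres: list[tuple[float, float]] = []
    arr = np.empty((0, 2))
    lo_y, hi_y = margin, h - margin
    lo_x, hi_x = margin, w - margin
    if hi_y <= lo_y or hi_x <= lo_x:
        raise PackingError("frame too small for the requested nucleus margin")
    attempts = 0
    while len(centres) < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed only {len(centres)}/{n} nuclei at min_separation={min_sep}"
            )
        attempts += 1
        cand = np.array([rng.uniform(lo_y, hi_y), rng.uniform(lo_x, hi_x)])
        if min_sep > 0 and arr.size:
            d2 = ((arr - cand) ** 2).sum(axis=1)
            if d2.min() < min_sep * min_sep:
                continue
        centres.append((cand[0], cand[1]))
        arr = np.vstack([arr, cand])
    return arr


def generate_fluor_field(
    spec: FluorFieldSpec,
) -> tuple[ImageFrame, ImageFrame, GroundTruth]:
    """Nuclei discs in the 405 channel; marker intensities in the 488 channel.

    Exactly ``round(positive_fraction * n_nuclei)`` nuclei (half away from
    zero) receive 488 pixel means at ``positive_488_mean``; the rest at
    ``negative_488_mean``.  Ground truth lists per-nucleus centre, radius,
    positivity label and assigned 488 mean.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    rmin, rmax = spec.nucleus_radius_range
    margin = rmax + 2
    centres = _place_centres(
        h, w, spec.n_nuclei, margin, spec.min_separation, rng,
        max_attempts=max(10_000, 2_000 * max(spec.n_nuclei, 1)),
    )
    radii = rng.integers(rmin, rmax + 1, size=spec.n_nuclei)
    n_pos = _round_half_away(spec.positive_fraction * spec.n_nuclei)
    labels = np.zeros(spec.n_nuclei, dtype=bool)
    labels[rng.permutation(spec.n_nuclei)[:n_pos]] = True

    img405 = np.zeros((h, w), dtype=float)
    img488 = np.zeros((h, w), dtype=float)
    mask = np.zeros((h, w), dtype=bool)
    for (cy, cx), r, pos in zip(centres, radii, labels):
        sl, inside = _disc_coords(h, w, int(round(cy)), int(round(cx)), int(r))
        mask[sl] |= inside
        n_px = int(inside.sum())
        # nuclear stain: wide uniform speckle -> high local entropy
        tex = spec.nucleus_405_mean * rng.uniform(0.4, 1.6, size=n_px)
        img405[sl][inside] = tex
        mean488 = spec.positive_488_mean if pos else spec.negative_488_mean
        img488[sl][inside] = mean488
    if spec.noise_sd > 0:
        img405 += rng.normal(0.0, spec.noise_sd, size=(h, w))
        img488 += rng.normal(0.0, min(spec.noise_sd, 1.0), size=(h, w))
    img405 = np.clip(img405, 0.0, 255.0)
    img488 = np.clip(img488, 0.0, 255.0)

    frame405 = ImageFrame(img405, channel="405", field_id=f"fluor_s{spec.seed}")
    frame488 = ImageFrame(img488, channel="488", field_id=f"fluor_s{spec.seed}")
    truth = GroundTruth(
        assay="ki67",
        data={
            "nuclei_mask": mask,
            "centres": centres,
            "radii": np.asarray(radii),
            "positive": labels,
            "n_nuclei": spec.n_nuclei,
            "n_positive": int(n_pos),
            "positive_pct": (100.0 * n_pos / spec.n_nuclei) if spec.n_nuclei else float("nan"),
            "mean_488_assigned": np.where(
                labels, spec.positive_488_mean, spec.negative_488_mean
            ),
        },
        seed=spec.seed,
    )
    return frame405, frame488, truth


# ---------------------------------------------------------------------------
# scratch-wound series
# ---------------------------------------------------------------------------


@dataclass
class WoundSeriesSpec:
    """Time series of phase frames with a shrinking cell-free stripe."""

    height: int = 384
    width: int = 384
    timepoints: Sequence[float] = (0.0, 12.0, 24.0, 36.0)
    recovery_targets: Sequence[float] = (0.0, 25.0, 50.0, 75.0)
    wound_orientation: str = "vertical"
    initial_wound_fraction: float = 0.3
    texture_contrast: float = 80.0
    background_level: float = 100.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = list(self.timepoints)
        r = list(self.recovery_targets)
        if len(t) != len(r):
            raise SpecError("timepoints and recovery_targets must align")
        if len(t) < 1 or t[0] != 0:
            raise SpecError("timepoints must start at 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise SpecError("timepoints must be strictly increasing")
        if r[0] != 0:
            raise SpecError("recovery at time zero must be 0")
        if any(not 0 <= x <= 100 for x in r):
            raise SpecError("recovery targets must lie in [0, 100]")
        if any(b < a for a, b in zip(r, r[1:])):
            raise SpecError("recovery targets must be nondecreasing")
        if self.wound_orientation not in ("vertical", "horizontal"):
            raise SpecError("wound_orientation must be 'vertical' or 'horizontal'")
        if not 0 < self.initial_wound_fraction < 1:
            raise SpecError("initial_wound_fraction must be in (0, 1)")


def generate_wound_series(
    spec: WoundSeriesSpec,
) -> tuple[list[ImageFrame], GroundTruth]:
    """Frames whose wound stripe shrinks along the recovery trajectory.

    Frame ``t`` has wound area ``A_t = A_0 * (1 - recovery_targets[t]/100)``
    up to integer rounding of the stripe width; ground truth stores every
    ``A_t`` in pixels.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    vertical = spec.wound_orientation == "vertical"
    span = w if vertical else h
    w0 = int(round(spec.initial_wound_fraction * span))
    frames: list[ImageFrame] = []
    areas: list[int] = []
    for t, rec in zip(spec.timepoints, spec.recovery_targets):
        wt = int(round(w0 * (1.0 - rec / 100.0)))
        lo = (span - wt) // 2
        hi = lo + wt
        cells = np.ones((h, w), dtype=bool)
        if wt > 0:
            if vertical:
                cells[:, lo:hi] = False
            else:
                cells[lo:hi, :] = False
        img = _texture_field(
            cells, spec.background_level, spec.texture_contrast, spec.noise_sd, rng
        )
        frames.append(
            ImageFrame(img, channel="phase", timepoint=float(t), field_id=f"wound_s{spec.seed}")
        )
        areas.append(int((~cells).sum()))
    a0 = areas[0]
    truth = GroundTruth(
        assay="wound",
        data={
            "timepoints": list(map(float, spec.timepoints)),
            "wound_areas_px": areas,
            "baseline_area_px": a0,
            "recovery_pct": [
                100.0 * (a0 - a) / a0 if a0 > 0 else float("nan") for a in areas
            ],
        },
        seed=spec.seed,
    )
    return frames, truth


# ---------------------------------------------------------------------------
# dye-solubilisation curves
# ---------------------------------------------------------------------------


@dataclass
class SolubilisationSpec:
    """Two-segment piecewise-linear absorbance-difference curve.

    Below the breakpoint (the true CMC) the dye signal grows with the
    unimeric slope; above it, micelles solubilise the dye and the slope
    steepens.  The curve is continuous at the breakpoint.
    """

    concentrations: Sequence[float] = tuple(np.geomspace(0.001, 1.0, 10))
    breakpoint: float = 0.03
    unimeric_slope: float = 1.0
    micellar_slope: float = 20.0
    intercept: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.ndim != 1 or len(c) < 2:
            raise SpecError("need at least 2 concentrations")
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise SpecError("concentrations must be positive and strictly increasing")
        if not (self.micellar_slope > self.unimeric_slope >= 0):
            raise SpecError("micellar_slope must exceed unimeric_slope >= 0")
        if not (c[0] <= self.breakpoint <= c[-1]):
            raise SpecError("breakpoint must lie within the concentration range")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")


def generate_solubilisation(spec: SolubilisationSpec) -> SolubilisationCurve:
    """Noisy two-segment curve; noiseless points are exactly collinear per segment."""
    rng = np.random.default_rng(spec.seed)
    c = np.asarray(spec.concentrations, dtype=float)
    bp, s1, s2 = spec.breakpoint, spec.unimeric_slope, spec.micellar_slope
    da = np.where(
        c <= bp,
        spec.intercept + s1 * c,
        spec.intercept + s1 * bp + s2 * (c - bp),
    )
    if spec.noise_sd > 0:
        da = da + rng.normal(0.0, spec.noise_sd, size=c.shape)
    return SolubilisationCurve(concentration=c, delta_absorbance=da)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


@dataclass
class CtTableSpec:
    """Ct table whose noiseless comparative-CT analysis recovers known fold changes."""

    genes: Sequence[str] = ("Snai1", "Snai2", "Col1a1")
    conditions: Sequence[str] = ("control", "treated")
    control_condition: str = "control"
    true_log2_fold_changes: dict | None = None  # {(gene, condition): log2 FC}
    reference_gene: str = "Gapdh"
    base_ct: float = 18.0
    replicates: int = 3
    ct_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise SpecError("replicates must be >= 1")
        if self.control_condition not in self.conditions:
            raise SpecError("control_condition must be one of conditions")
        if self.ct_noise_sd < 0:
            raise SpecError("ct_noise_sd must be >= 0")
        if self.reference_gene in self.genes:
            raise SpecError("reference_gene must not also be a target gene")
        if self.true_log2_fold_changes is None:
            self.true_log2_fold_changes = {
                (g, cond): 0.0 for g in self.genes for cond in self.conditions
            }
        for g in self.genes:
            lfc = self.true_log2_fold_changes.get((g, self.control_condition), 0.0)
            if lfc != 0.0:
                raise SpecError("control condition must have log2 fold change 0")


def generate_ct_table(spec: CtTableSpec) -> pd.DataFrame:
    """Long-form Ct table (gene, condition, replicate, ct).

    The reference gene sits at ``base_ct`` everywhere; each target gene's
    control ΔCt is drawn once per gene, and a condition's Ct is lowered by
    its true log2 fold change (one cycle per doubling), so the noiseless
    ΔΔCt computation returns the specified fold changes exactly.
    """
    rng = np.random.default_rng(spec.seed)
    delta_ct_control = {g: rng.uniform(1.0, 8.0) for g in spec.genes}
    rows = []
    for cond in spec.conditions:
        for rep in range(1, spec.replicates + 1):
            for g in (spec.reference_gene, *spec.genes):
                if g == spec.reference_gene:
                    ct = spec.base_ct
                else:
                    lfc = spec.true_log2_fold_changes.get((g, cond), 0.0)
                    ct = spec.base_ct + delta_ct_control[g] - lfc
                if spec.ct_noise_sd > 0:
                    ct += rng.normal(0.0, spec.ct_noise_sd)
                rows.append(
                    {"gene": g, "condition": cond, "replicate": rep, "ct": float(ct)}
                )
    table = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
    table.attrs["reference_gene"] = spec.reference_gene
    table.attrs["control_condition"] = spec.control_condition
    return table
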