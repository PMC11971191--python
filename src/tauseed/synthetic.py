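"""Synthetic data with known ground truth for the tau seeding pipeline.

Everything the pipeline consumes can be generated here: 96-well plate-reader
ThT curves, single-channel histology fields with diffuse dots and perikaryal
blobs, two-channel biosensor cell fields, and cohort sample sheets.  Each
generator is driven by one explicit integer seed and records the ground
truth (analytic lag times, true object areas and classes, true inclusion
fractions, true group labels) alongside the data, so recovery by the
analysis modules can be tested exactly.

The kinetic model is a four-parameter logistic with additive Gaussian read
noise,

    F(t) = f0 + amplitude / (1 + exp(-rate_k * (t - t_half))) + eps,

the simplest shape with distinct lag, growth and plateau phases whose
threshold-crossing time has a closed form (the analytic lag oracle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .kinetics import ThTCurve

__all__ = [
    "GroupName",
    "AggregationKineticsParams",
    "TruncNormal",
    "GroupPreset",
    "SyntheticImageSpec",
    "logistic_fluorescence",
    "logistic_crossing_time",
    "simulate_tht_curve",
    "simulate_plate",
    "simulate_histology_image",
    "simulate_fret_field",
    "simulate_cohort_measurements",
    "default_presets",
    "cohort_presets",
]


class GroupName(str, Enum):
    """Pathology strata and assay controls."""

    DOUBLE_NEGATIVE = "DOUBLE_NEGATIVE"
    INTERMEDIATE = "INTERMEDIATE"
    DOUBLE_POSITIVE = "DOUBLE_POSITIVE"
    NEG_CONTROL = "NEG_CONTROL"
    POS_CONTROL = "POS_CONTROL"


# ---------------------------------------------------------------------------
# kinetic curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AggregationKineticsParams:
    """Parameters of one simulated seeded-aggregation curve.

    ``f0`` is the baseline fluorescence, ``amplitude`` the plateau rise above
    it, ``rate_k`` the logistic growth rate (1/h), ``t_half`` the time of
    half-maximal rise (h), ``noise_sd`` the additive Gaussian read noise SD.
    Reads are taken every ``read_interval_h`` from 0 to ``duration_h``.
    """

    f0: float
    amplitude: float
    rate_k: float
    t_half: float
    noise_sd: float = 0.0
    read_interval_h: float = 0.25
    duration_h: float = 60.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.rate_k <= 0:
            raise ValueError("rate_k must be positive")
        if self.read_interval_h <= 0:
            raise ValueError("read_interval_h must be positive")
        if self.duration_h < self.read_interval_h:
            raise ValueError("duration_h must cover at least one read interval")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def times_h(self) -> np.ndarray:
        n = int(math.floor(self.duration_h / self.read_interval_h + 1e-9)) + 1
        return np.arange(n) * self.read_interval_h


def logistic_fluorescence(
    t: np.ndarray | float, f0: float, amplitude: float, rate_k: float, t_half: float
) -> np.ndarray | float:
    """Noise-free logistic fluorescence at time(s) ``t``."""
    return f0 + amplitude / (1.0 + np.exp(-rate_k * (np.asarray(t, float) - t_half)))


def logistic_crossing_time(
    f0: float, amplitude: float, rate_k: float, t_half: float, threshold: float
) -> float:
    """Analytic time at which the noise-free curve crosses ``threshold``.

    Defined for thresholds strictly inside ``(f0, f0 + amplitude)``; outside
    that range the curve never crosses and ``inf`` is returned.
    """
    if not (f0 < threshold < f0 + amplitude):
        return math.inf
    return t_half - math.log(amplitude / (threshold - f0) - 1.0) / rate_k


@dataclass
class SimulatedCurve:
    """A generated well together with its ground truth."""

    curve: ThTCurve
    params: AggregationKineticsParams

    def analytic_lag(self, threshold: float) -> float:
        """Closed-form threshold-crossing time; ``inf`` if never crossed."""
        p = self.params
        return logistic_crossing_time(p.f0, p.amplitude, p.rate_k, p.t_half, threshold)


def simulate_tht_curve(
    params: AggregationKineticsParams,
    well_id: str = "A1",
    sample_id: str = "sim",
    dilution: float = 0.1,
    is_control: bool = False,
) -> SimulatedCurve:
    """Simulate one well's ThT time series."""
    rng = np.random.default_rng(params.rng_seed)
    t = params.times_h
    f = logistic_fluorescence(t, params.f0, params.amplitude, params.rate_k, params.t_half)
    if params.noise_sd > 0:
        f = f + rng.normal(0.0, params.noise_sd, size=t.size)
    curve = ThTCurve(
        well_id=well_id,
        sample_id=sample_id,
        dilution=dilution,
        times_h=t,
        fluorescence_au=np.asarray(f, float),
        is_control=is_control,
    )
    return SimulatedCurve(curve=curve, params=params)


# ---------------------------------------------------------------------------
# group presets and plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruncNormal:
    """Normal distribution truncated to ``[lower, upper]`` (via resampling)."""

    mean: float
    sd: float
    lower: float = 0.0
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return float(min(max(self.mean, self.lower), self.upper))
        for _ in range(10_000):
            x = rng.normal(self.mean, self.sd)
            if self.lower <= x <= self.upper:
                return float(x)
        raise RuntimeError("truncated-normal resampling failed; bounds too tight")


@dataclass(frozen=True)
class GroupPreset:
    """Study conditions for one cohort group or control.

    Samples draw their kinetic parameters (``t_half``, ``rate_k``,
    ``amplitude``) once from the between-sample distributions; replicate
    wells of a sample share that draw and differ only in read noise, which
    mimics per-case triplicates.  ``pla_count`` and ``at8_count`` are the
    distributions of per-sample mean diffuse tau-PLA and perikaryal AT8
    particle counts; ``inclusion_fraction`` is the biosensor inclusion
    fraction distribution.
    """

    group: GroupName
    n_samples: int
    t_half: TruncNormal
    rate_k: TruncNormal
    amplitude: TruncNormal
    pla_count: TruncNormal
    at8_count: TruncNormal
    inclusion_fraction: TruncNormal
    n_replicates: int = 3
    f0: float = 100.0
    noise_sd: float = 40.0
    braak_stage: str = "0"

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_replicates < 1:
            raise ValueError("n_samples and n_replicates must be at least 1")
        for d in (self.pla_count, self.at8_count):
            if d.lower < 0:
                raise ValueError("count distributions must be non-negative")


def default_presets() -> tuple[GroupPreset, ...]:
    """The default study conditions: 6/5/5 cohort plus the two controls.

    Double-Negative tissue seeds slowly (most wells censor at the 52-h
    cut-off), Intermediate and Double-Positive tissue seeds within hours.
    The negative control (tau-knock-out brain homogenate) aggregates only
    spontaneously, with half-rise placed after the recording ends or at
    least late enough that no threshold crossing occurs before 52 h; the
    positive control (pre-aggregated substrate) seeds almost immediately.
    """
    return (
        GroupPreset(
            group=GroupName.DOUBLE_NEGATIVE,
            n_samples=6,
            t_half=TruncNormal(60.0, 6.0, lower=50.0),
            rate_k=TruncNormal(0.6, 0.08, lower=0.2),
            amplitude=TruncNormal(2500.0, 400.0, lower=500.0),
            pla_count=TruncNormal(12.0, 5.0),
            at8_count=TruncNormal(0.2, 0.2),
            inclusion_fraction=TruncNormal(0.02, 0.02, lower=0.0, upper=1.0),
            braak_stage="0",
        ),
        GroupPreset(
            group=GroupName.INTERMEDIATE,
            n_samples=5,
            t_half=TruncNormal(14.0, 2.0, lower=9.0),
            rate_k=TruncNormal(0.6, 0.08, lower=0.2),
            amplitude=TruncNormal(2600.0, 400.0, lower=500.0),
            pla_count=TruncNormal(90.0, 15.0),
            at8_count=TruncNormal(0.2, 0.2),
            inclusion_fraction=TruncNormal(0.25, 0.05, lower=0.0, upper=1.0),
            braak_stage="II",
        ),
        GroupPreset(
            group=GroupName.DOUBLE_POSITIVE,
            n_samples=5,
            t_half=TruncNormal(17.0, 2.5, lower=8.0),
            rate_k=TruncNormal(0.6, 0.08, lower=0.2),
            amplitude=TruncNormal(2400.0, 400.0, lower=500.0),
            pla_count=TruncNormal(130.0, 25.0),
            at8_count=TruncNormal(9.0, 2.0),
            inclusion_fraction=TruncNormal(0.30, 0.05, lower=0.0, upper=1.0),
            braak_stage="IV",
        ),
        GroupPreset(
            group=GroupName.NEG_CONTROL,
            n_samples=1,
            t_half=TruncNormal(63.0, 3.0, lower=58.0, upper=70.0),
            rate_k=TruncNormal(1.0, 0.05, lower=0.5),
            amplitude=TruncNormal(2000.0, 200.0, lower=500.0),
            pla_count=TruncNormal(0.0, 0.0),
            at8_count=TruncNormal(0.0, 0.0),
            inclusion_fraction=TruncNormal(0.0, 0.0, upper=1.0),
            braak_stage="-",
        ),
        GroupPreset(
            group=GroupName.POS_CONTROL,
            n_samples=1,
            t_half=TruncNormal(8.0, 0.8, lower=6.0),
            rate_k=TruncNormal(1.0, 0.1, lower=0.5),
            amplitude=TruncNormal(3000.0, 300.0, lower=500.0),
            pla_count=TruncNormal(0.0, 0.0),
            at8_count=TruncNormal(0.0, 0.0),
            inclusion_fraction=TruncNormal(0.9, 0.02, lower=0.0, upper=1.0),
            braak_stage="-",
        ),
    )


def cohort_presets() -> tuple[GroupPreset, ...]:
    """The three tissue groups only (no assay controls)."""
    return tuple(
        p
        for p in default_presets()
        if p.group
        in (GroupName.DOUBLE_NEGATIVE, GroupName.INTERMEDIATE, GroupName.DOUBLE_POSITIVE)
    )


_WELL_NAMES = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]


def simulate_plate(
    presets: list[GroupPreset] | tuple[GroupPreset, ...],
    rng_seed: int,
    dilution: float = 0.1,
    read_interval_h: float = 0.25,
    duration_h: float = 60.0,
    lag_threshold_n_sd: float = 5.0,
    cutoff_h: float = 52.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a 96-well plate for the given group presets.

    Returns ``(plate, truth)``.  ``plate`` is long format with columns
    ``well, sample_id, group, dilution, time_h, fluorescence_au``; ``truth``
    has one row per well with the generating parameters and the analytic
    lag ``true_lag_h`` at the design threshold ``f0 + lag_threshold_n_sd *
    noise_sd``.  Wells whose analytic crossing falls after ``cutoff_h``
    (negative controls, which only aggregate spontaneously after the
    cut-off) carry ``true_lag_h = NaN`` and ``true_lag_never = True``; the
    raw crossing time, wherever it falls, is kept in
    ``analytic_crossing_h`` (``NaN`` if the curve never crosses at all).
    """
    n_wells = sum(p.n_samples * p.n_replicates for p in presets)
    if n_wells > 96:
        raise ValueError(f"{n_wells} wells requested; a plate has 96")
    rng = np.random.default_rng(rng_seed)

    plate_rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    well_iter = iter(_WELL_NAMES)
    for preset in presets:
        short = "".join(w[0] for w in preset.group.value.split("_"))
        for i in range(preset.n_samples):
            sample_id = f"{short}_{i + 1}"
            t_half = preset.t_half.draw(rng)
            rate_k = preset.rate_k.draw(rng)
            amplitude = preset.amplitude.draw(rng)
            theta = preset.f0 + lag_threshold_n_sd * preset.noise_sd
            crossing = logistic_crossing_time(
                preset.f0, amplitude, rate_k, t_half, theta
            )
            never = not (crossing <= cutoff_h)
            for _ in range(preset.n_replicates):
                well = next(well_iter)
                params = AggregationKineticsParams(
                    f0=preset.f0,
                    amplitude=amplitude,
                    rate_k=rate_k,
                    t_half=t_half,
                    noise_sd=preset.noise_sd,
                    read_interval_h=read_interval_h,
                    duration_h=duration_h,
                    rng_seed=int(rng.integers(0, 2**31 - 1)),
                )
                sim = simulate_tht_curve(
                    params,
                    well_id=well,
                    sample_id=sample_id,
                    dilution=dilution,
                    is_control=preset.group
                    in (GroupName.NEG_CONTROL, GroupName.POS_CONTROL),
                )
                plate_rows.append(
                    pd.DataFrame(
                        {
                            "well": well,
                            "sample_id": sample_id,
                            "group": preset.group.value,
                            "dilution": dilution,
                            "time_h": sim.curve.times_h,
                            "fluorescence_au": np.round(sim.curve.fluorescence_au, 2),
                        }
                    )
                )
                truth_rows.append(
                    {
                        "well": well,
                        "sample_id": sample_id,
                        "group": preset.group.value,
                        "f0": preset.f0,
                        "amplitude": amplitude,
                        "rate_k": rate_k,
                        "t_half": t_half,
                        "noise_sd": preset.noise_sd,
                        "true_lag_h": (np.nan if never else crossing),
                        "true_lag_never": never,
                        "analytic_crossing_h": (
                            np.nan if math.isinf(crossing) else crossing
                        ),
                    }
                )
    plate = pd.concat(plate_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return plate, truth


# ---------------------------------------------------------------------------
# histology images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Specification of one synthetic histology field.

    Diffuse objects are rasterised as digital disks with areas drawn
    uniformly from ``diffuse_um2``; perikaryal objects as digital ellipses
    (axis ratio uniform in [1, 2]) with areas from ``perikaryal_um2``.
    Objects are placed by rejection sampling so that no two foreground
    components touch (centre distance at least the sum of the effective
    radii plus ``min_separation_px``).
    """

    n_diffuse: int
    n_perikaryal: int
    width_px: int = 384
    height_px: int = 384
    pixel_size_um: float = 0.25
    foreground_intensity: int = 3000
    background_mean: float = 500.0
    background_sd: float = 60.0
    min_separation_px: int = 2
    rng_seed: int = 0
    diffuse_um2: tuple[float, float] = (1.5, 3.5)
    perikaryal_um2: tuple[float, float] = (12.5, 100.0)
    max_attempts: int = 500

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_diffuse < 0 or self.n_perikaryal < 0:
            raise ValueError("object counts must be non-negative")
        if self.foreground_intensity <= self.background_mean + 3 * self.background_sd:
            raise ValueError(
                "foreground_intensity must exceed background_mean + 3*background_sd"
            )


def _digital_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    n_pixels: int,
    axis_ratio: float,
    angle: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rows/cols of the ``n_pixels`` grid points nearest ``center`` in the
    (possibly anisotropic) elliptical metric.  Ties break deterministically
    by (row, col), so the realised pixel area is exactly ``n_pixels``."""
    cy, cx = center
    # half-extent generous enough to contain the blob for ratios up to 2
    half = int(math.ceil(math.sqrt(n_pixels * axis_ratio / math.pi))) + 2
    r0, r1 = max(0, int(cy) - half), min(shape[0], int(cy) + half + 1)
    c0, c1 = max(0, int(cx) - half), min(shape[1], int(cx) + half + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - cy
    dx = cc - cx
    u = dx * math.cos(angle) + dy * math.sin(angle)
    v = -dx * math.sin(angle) + dy * math.cos(angle)
    metric = u * u + (v * axis_ratio) ** 2
    flat = np.argsort(metric, axis=None, kind="stable")[:n_pixels]
    return rr.ravel()[flat], cc.ravel()[flat]


def simulate_histology_image(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, list[dict]]:
    """Render one 16-bit field; returns ``(image, objects)``.

    Each ground-truth object record carries ``class`` (``diffuse`` or
    ``perikaryal``), the requested and realised areas in square microns,
    the realised ``pixel_count`` and the placement ``centroid_px``.  The
    realised pixel area always lies inside the requested class window and
    within one pixel-area of the requested area.
    """
    rng = np.random.default_rng(spec.rng_seed)
    pa = spec.pixel_size_um**2
    h, w = spec.height_px, spec.width_px

    jobs: list[tuple[str, tuple[float, float], float]] = []
    # place large perikaryal blobs first: they are the hardest to fit
    jobs += [("perikaryal", spec.perikaryal_um2, 1.0)] * spec.n_perikaryal
    jobs += [("diffuse", spec.diffuse_um2, 0.0)] * spec.n_diffuse

    placed: list[tuple[float, float, float]] = []  # (cy, cx, effective radius)
    image = np.clip(
        np.round(rng.normal(spec.background_mean, spec.background_sd, size=(h, w))),
        0,
        65535,
    ).astype(np.uint16)
    objects: list[dict] = []

    for cls, (lo, hi), is_peri in jobs:
        requested = rng.uniform(lo, hi)
        lo_px = int(math.ceil(lo / pa - 1e-9))
        hi_px = int(math.floor(hi / pa + 1e-9))
        n_px = int(np.clip(round(requested / pa), lo_px, hi_px))
        ratio = rng.uniform(1.0, 2.0) if is_peri else 1.0
        angle = rng.uniform(0.0, math.pi) if is_peri else 0.0
        radius = math.sqrt(n_px * ratio / math.pi) + 1.5
        margin = radius + 1.0
        for attempt in range(spec.max_attempts):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all(
                math.hypot(cy - py, cx - px) >= radius + pr + spec.min_separation_px
                for py, px, pr in placed
            ):
                break
        else:
            raise RuntimeError(
                f"could not place a {cls} object after {spec.max_attempts} "
                f"attempts; requested object density is too high for a "
                f"{w}x{h} px field"
            )
        rows, cols = _digital_blob((h, w), (cy, cx), n_px, ratio, angle)
        image[rows, cols] = spec.foreground_intensity
        placed.append((cy, cx, radius))
        objects.append(
            {
                "class": cls,
                "requested_area_um2": float(requested),
                "area_um2": float(n_px * pa),
                "pixel_count": int(n_px),
                "centroid_px": (float(cy), float(cx)),
            }
        )
    return image, objects


# ---------------------------------------------------------------------------
# biosensor cell fields
# ---------------------------------------------------------------------------


def simulate_fret_field(
    n_cells: int,
    inclusion_fraction: float,
    rng_seed: int,
    width_px: int = 768,
    height_px: int = 768,
    cell_radius_px: tuple[float, float] = (6.0, 9.0),
    cell_intensity: int = 3000,
    punctum_intensity: int = 12000,
    punctum_half_px: int = 1,
    background_mean: float = 300.0,
    background_sd: float = 40.0,
    max_attempts: int = 2000,
) -> tuple[np.ndarray, dict]:
    """Two-channel biosensor field: cells in channel 0, puncta in channel 1.

    Exactly ``round(n_cells * inclusion_fraction)`` cells carry one bright
    inclusion punctum (a ``(2*punctum_half_px)``-pixel square placed inside
    the cell body).  Returns the ``(2, H, W)`` uint16 stack and a ground
    truth dict listing every cell with its flag.
    """
    if not 0.0 <= inclusion_fraction <= 1.0:
        raise ValueError("inclusion_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    h, w = height_px, width_px
    cells = np.clip(
        np.round(rng.normal(background_mean, background_sd, size=(h, w))), 0, 65535
    ).astype(np.uint16)
    puncta = np.clip(
        np.round(rng.normal(background_mean / 2, background_sd / 2, size=(h, w))),
        0,
        65535,
    ).astype(np.uint16)

    placed: list[tuple[float, float, float]] = []
    for _ in range(n_cells):
        r = rng.uniform(*cell_radius_px)
        for attempt in range(max_attempts):
            cy = rng.uniform(r + 2, h - r - 2)
            cx = rng.uniform(r + 2, w - r - 2)
            if all(
                math.hypot(cy - py, cx - px) >= r + pr + 3 for py, px, pr in placed
            ):
                break
        else:
            raise RuntimeError(
                f"could not place {n_cells} cells in a {w}x{h} px field"
            )
        placed.append((cy, cx, r))

    n_flagged = int(round(n_cells * inclusion_fraction))
    flagged = set(rng.permutation(n_cells)[:n_flagged].tolist())
    truth_cells = []
    for i, (cy, cx, r) in enumerate(placed):
        r0, r1 = int(cy - r) - 1, int(cy + r) + 2
        c0, c1 = int(cx - r) - 1, int(cx + r) + 2
        yy, xx = np.mgrid[r0:r1, c0:c1]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        cells[r0:r1, c0:c1][mask] = cell_intensity
        has_inclusion = i in flagged
        if has_inclusion:
            # drop the punctum near the cell centre, fully inside the body
            off = r - punctum_half_px - 2.0
            py = int(round(cy + rng.uniform(-off, off) * 0.5))
            px = int(round(cx + rng.uniform(-off, off) * 0.5))
            hp = punctum_half_px
            puncta[py - hp : py + hp + 1, px - hp : px + hp + 1] = punctum_intensity
        truth_cells.append(
            {
                "centroid_px": (float(cy), float(cx)),
                "radius_px": float(r),
                "has_inclusion": bool(has_inclusion),
            }
        )
    truth = {
        "n_cells": n_cells,
        "n_with_inclusions": n_flagged,
        "inclusion_fraction": inclusion_fraction,
        "cells": truth_cells,
    }
    return np.stack([cells, puncta]), truth


# ---------------------------------------------------------------------------
# cohort sample sheets
# ---------------------------------------------------------------------------


def simulate_cohort_measurements(
    presets: list[GroupPreset] | tuple[GroupPreset, ...],
    rng_seed: int,
    n_images: int = 3,
) -> pd.DataFrame:
    """Per-sample mean particle counts for a cohort, without rasterising.

    Each sample draws its true mean diffuse tau-PLA and perikaryal AT8
    counts from the group preset; per-image counts are Poisson around those
    means and the reported measurement is the mean over ``n_images`` fields,
    mirroring the three representative images scored per sample.  Returns a
    sample sheet with the generating group label as ground truth.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for preset in presets:
        short = "".join(w[0] for w in preset.group.value.split("_"))
        for i in range(preset.n_samples):
            pla_true = preset.pla_count.draw(rng)
            at8_true = preset.at8_count.draw(rng)
            pla_imgs = rng.poisson(pla_true, size=n_images)
            at8_imgs = rng.poisson(at8_true, size=n_images)
            rows.append(
                {
                    "sample_id": f"{short}_{i + 1}",
                    "braak_stage": preset.braak_stage,
                    "pla_diffuse_mean": float(pla_imgs.mean()),
                    "at8_perikaryal_mean": float(at8_imgs.mean()),
                    "true_group": preset.group.value,
                    "true_pla_mean": pla_true,
                    "true_at8_mean": at8_true,
                }
            )
    return pd.DataFrame(rows)
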