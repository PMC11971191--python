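"""End-to-end cohort run: simulate -> quantify -> classify -> kinetics -> stats.

One seeded, fully deterministic pass over a synthetic cohort that mirrors
the study design: a 96-well seeded-aggregation plate (triplicate wells per
case plus controls), three histology fields per sample and stain, CI-based
stratification into Double-Negative / Intermediate / Double-Positive,
kinetic parameter extraction with 52-h censoring, biosensor inclusion
scoring, and the group-comparison statistics.  Every output file carries
the configuration hash; re-running with the same configuration and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import GroupThresholds, classify_cohort
from .fret import quantify_field
from .group_stats import anova_oneway_bonferroni, anova_oneway_dunnett
from .io import save_image, write_json, write_plate_csv, write_table
from .kinetics import KINETIC_PARAMS, AssayConfig, summarize_plate
from .particles import ImageGrid, SizeWindows, quantify_image
from .synthetic import (
    GroupName,
    GroupPreset,
    SyntheticImageSpec,
    default_presets,
    simulate_fret_field,
    simulate_histology_image,
    simulate_plate,
)

__all__ = ["PipelineConfig", "run_cohort"]

logger = logging.getLogger("tauseed")

_COHORT_GROUPS = (
    GroupName.DOUBLE_NEGATIVE,
    GroupName.INTERMEDIATE,
    GroupName.DOUBLE_POSITIVE,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full cohort run.

    ``thresholds`` is either the string ``"derive"`` (cut-offs from the
    Braak-0 reference samples) or an explicit ``(pla_cutoff, at8_cutoff)``
    pair.  All defaults equal the study constants: 52-h cut-off, 5-SD lag
    threshold, 1.5-3.5 and 12.5-100 um^2 size windows, 99% confidence
    cut-offs, alpha = 0.05.
    """

    seed: int = 0
    presets: tuple[GroupPreset, ...] = field(default_factory=default_presets)
    assay: AssayConfig = field(default_factory=AssayConfig)
    windows: SizeWindows = field(default_factory=SizeWindows)
    thresholds: str | tuple[float, float] = "derive"
    n_images: int = 3
    image_size_px: int = 384
    pixel_size_um: float = 0.25
    fret_n_cells: int = 120
    dilution: float = 0.1
    save_images: bool = False

    def to_dict(self) -> dict:
        def default(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return str(obj)

        raw = dataclasses.asdict(self)
        return json.loads(json.dumps(raw, default=default, sort_keys=True))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(
                    f"cohort pipeline failed at stage '{name}': {exc}"
                ) from exc
            logger.info("stage %s: done", name)
            return out

        return inner

    return wrap


@_stage("simulate-plate")
def _run_plate(config: PipelineConfig, seed: int, out: Path, tag: str):
    plate, truth = simulate_plate(
        config.presets,
        rng_seed=seed,
        dilution=config.dilution,
        lag_threshold_n_sd=config.assay.n_sd,
        cutoff_h=config.assay.cutoff_h,
    )
    with open(out / "plate.csv", "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {tag}\n")
        write_plate_csv(plate, fh)
    write_table(truth, out / "plate_truth.tsv", header_comment=tag)
    return plate


@_stage("simulate-and-quantify-images")
def _run_histology(config: PipelineConfig, seed: int, out: Path) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    img_dir = out / "images"
    if config.save_images:
        img_dir.mkdir(exist_ok=True)
    rows = []
    for preset in config.presets:
        if preset.group not in _COHORT_GROUPS:
            continue
        short = "".join(w[0] for w in preset.group.value.split("_"))
        for i in range(preset.n_samples):
            sample_id = f"{short}_{i + 1}"
            pla_true = preset.pla_count.draw(rng)
            at8_true = preset.at8_count.draw(rng)
            pla_counts, at8_counts = [], []
            for j in range(config.n_images):
                # tau-PLA labels both diffuse dots and perikaryal lesions;
                # AT8 fields carry the perikaryal lesions only
                specs = {
                    "pla": SyntheticImageSpec(
                        n_diffuse=int(rng.poisson(pla_true)),
                        n_perikaryal=int(rng.poisson(at8_true)),
                        width_px=config.image_size_px,
                        height_px=config.image_size_px,
                        pixel_size_um=config.pixel_size_um,
                        rng_seed=int(rng.integers(0, 2**31 - 1)),
                    ),
                    "at8": SyntheticImageSpec(
                        n_diffuse=0,
                        n_perikaryal=int(rng.poisson(at8_true)),
                        width_px=config.image_size_px,
                        height_px=config.image_size_px,
                        pixel_size_um=config.pixel_size_um,
                        rng_seed=int(rng.integers(0, 2**31 - 1)),
                    ),
                }
                for stain, spec in specs.items():
                    image, objects = simulate_histology_image(spec)
                    thr = (spec.background_mean + spec.foreground_intensity) / 2
                    counts = quantify_image(
                        ImageGrid(image, spec.pixel_size_um),
                        threshold=thr,
                        windows=config.windows,
                    )
                    if stain == "pla":
                        pla_counts.append(counts.diffuse_count)
                    else:
                        at8_counts.append(counts.perikaryal_count)
                    if config.save_images:
                        save_image(
                            img_dir / f"{sample_id}_{stain}_{j + 1}.tiff",
                            image,
                            sidecar={
                                "pixel_size_um": spec.pixel_size_um,
                                "objects": objects,
                            },
                        )
            rows.append(
                {
                    "sample_id": sample_id,
                    "braak_stage": preset.braak_stage,
                    "pla_diffuse_mean": float(np.mean(pla_counts)),
                    "at8_perikaryal_mean": float(np.mean(at8_counts)),
                    "true_group": preset.group.value,
                }
            )
    return pd.DataFrame(rows)


@_stage("classify")
def _run_classification(config: PipelineConfig, samples: pd.DataFrame, out: Path):
    explicit = None
    if config.thresholds != "derive":
        pla, at8 = config.thresholds
        explicit = GroupThresholds(pla_cutoff=float(pla), at8_cutoff=float(at8))
    groups, thresholds = classify_cohort(samples, thresholds=explicit)
    groups = groups.merge(samples[["sample_id", "true_group"]], on="sample_id")
    return groups, thresholds


@_stage("kinetics")
def _run_kinetics(config: PipelineConfig, plate: pd.DataFrame, out: Path):
    return summarize_plate(plate, config.assay)


@_stage("fret")
def _run_fret(config: PipelineConfig, seed: int, out: Path) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for preset in config.presets:
        if preset.group not in _COHORT_GROUPS:
            continue
        short = "".join(w[0] for w in preset.group.value.split("_"))
        for i in range(preset.n_samples):
            fraction = preset.inclusion_fraction.draw(rng)
            field_img, _truth = simulate_fret_field(
                n_cells=config.fret_n_cells,
                inclusion_fraction=fraction,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
            result = quantify_field(
                field_img, cell_threshold=1500, punctum_threshold=6000
            )
            rows.append(
                {
                    "sample_id": f"{short}_{i + 1}",
                    "n_cells": result.n_cells,
                    "n_with_inclusions": result.n_with_inclusions,
                    "percent_inclusions": result.percent,
                    "true_fraction": fraction,
                }
            )
    return pd.DataFrame(rows)


def _stats_rows(readout: str, design: str, result) -> list[dict]:
    rows = []
    for r in result.posthoc.itertuples():
        rows.append(
            {
                "readout": readout,
                "design": design,
                "omnibus_F": result.omnibus_F,
                "omnibus_p": result.omnibus_p,
                "comparison": r.comparison,
                "estimate": r.estimate,
                "adjusted_p": r.adjusted_p,
                "significant": r.significant,
            }
        )
    return rows


@_stage("stats")
def _run_stats(
    config: PipelineConfig,
    groups: pd.DataFrame,
    per_sample_kinetics: pd.DataFrame,
    fret: pd.DataFrame,
    out: Path,
) -> pd.DataFrame:
    labelled = groups[["sample_id", "group"]]
    kin = per_sample_kinetics.drop(columns=["group"], errors="ignore").merge(
        labelled, on="sample_id"
    )
    fret_tab = fret.merge(labelled, on="sample_id")

    def by_group(tab: pd.DataFrame, column: str) -> dict[str, np.ndarray]:
        sizes = tab.groupby("group")[column].size()
        keep = sizes[sizes >= 2].index
        return {
            g: tab.loc[tab["group"] == g, column].to_numpy() for g in keep
        }

    rows: list[dict] = []
    for param in KINETIC_PARAMS:
        data = by_group(kin, param)
        if len(data) < 2:
            logger.warning("skipping %s: fewer than two groups of size >= 2", param)
            continue
        rows += _stats_rows(param, "oneway-bonferroni", anova_oneway_bonferroni(data))
    fret_data = by_group(fret_tab, "percent_inclusions")
    if len(fret_data) >= 2:
        rows += _stats_rows(
            "percent_inclusions",
            "oneway-bonferroni",
            anova_oneway_bonferroni(fret_data),
        )
    counts = by_group(groups, "pla_diffuse_mean")
    if len(counts) >= 2 and "DOUBLE_NEGATIVE" in counts:
        rows += _stats_rows(
            "pla_diffuse_mean",
            "oneway-dunnett",
            anova_oneway_dunnett(counts, control_group="DOUBLE_NEGATIVE"),
        )
    return pd.DataFrame(rows)


def run_cohort(config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Execute the full cohort pipeline; returns the paths written.

    Deterministic given ``config`` (including its seed): repeated runs
    write byte-identical files.  A failure in any stage aborts the run
    with the stage named.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"seed={config.seed} config_hash={config.config_hash()}"
    s_plate, s_img, s_fret = _subseeds(config.seed, 3)

    plate = _run_plate(config, s_plate, out, tag)
    samples = _run_histology(config, s_img, out)
    write_table(samples, out / "samples.tsv", header_comment=tag)
    groups, thresholds = _run_classification(config, samples, out)
    write_table(groups, out / "groups.tsv", header_comment=tag)
    write_json(
        out / "thresholds.json",
        {
            "config_hash": config.config_hash(),
            "pla_cutoff": thresholds.pla_cutoff,
            "at8_cutoff": thresholds.at8_cutoff,
            "confidence": thresholds.confidence,
            "reference_n": thresholds.reference_n,
        },
    )
    per_well, per_sample = _run_kinetics(config, plate, out)
    write_table(per_well, out / "kinetics_wells.tsv", header_comment=tag)
    write_table(per_sample, out / "kinetics.tsv", header_comment=tag)
    fret = _run_fret(config, s_fret, out)
    write_table(fret, out / "fret.tsv", header_comment=tag)
    stats_tab = _run_stats(config, groups, per_sample, fret, out)
    write_table(stats_tab, out / "stats.tsv", header_comment=tag)

    lines = [f"tauseed cohort report ({tag})", ""]
    lines.append(
        "group sizes: "
        + ", ".join(
            f"{g}={n}" for g, n in groups["group"].value_counts().sort_index().items()
        )
    )
    n_cens = int(per_well["lag_censored"].sum())
    lines.append(
        f"censored wells: {n_cens}/{len(per_well)} at {config.assay.cutoff_h} h"
    )
    lines.append("")
    for r in stats_tab.itertuples():
        star = " *" if r.significant else ""
        lines.append(
            f"{r.readout:20s} {r.comparison:45s} "
            f"diff={r.estimate:+.4g} p_adj={r.adjusted_p:.4g}{star}"
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")

    write_json(
        out / "provenance.json",
        {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "versions": {
                "tauseed": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        },
    )
    names = [
        "plate.csv",
        "plate_truth.tsv",
        "samples.tsv",
        "groups.tsv",
        "thresholds.json",
        "kinetics_wells.tsv",
        "kinetics.tsv",
        "fret.tsv",
        "stats.tsv",
        "report.txt",
        "provenance.json",
    ]
    return {name: out / name for name in names}
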