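"""End-to-end orchestration: simulate/load → preprocess → classify → detect → stats.

The processing order follows the acquisition workflow: drift registration,
timepoint selection, inversion, median filtering (2 px), CLAHE, non-myelin
probability mapping by a sparsely-trained pixel classifier, hysteresis
thresholding (core 0.85, final 0.5), size filtering and roundness
classification, ending in swelling densities per mm³ and group statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import (
    DEFAULT_SCALES_PX,
    PixelModel,
    compute_features,
    predict_probability,
    sample_sparse_labels,
    train_pixel_classifier,
)
from .detect import (
    DEFAULT_CORE,
    DEFAULT_FINAL,
    DEFAULT_MAX_DIAMETER_UM,
    DEFAULT_MIN_DIAMETER_UM,
    DEFAULT_SPHERICITY,
    SwellingSet,
    detect_swellings,
)
from .io import AcquisitionGeometry, VolumeStack
from .preprocess import (
    DEFAULT_TIMEPOINT_TARGETS_MIN,
    clahe,
    invert,
    median_filter_2px,
    register_timelapse,
    select_timepoints,
)
from .stats import two_sample_t
from .synthetic import (
    MS_PRESET,
    NONMS_PRESET,
    sample_donor_densities,
    simulate_timelapse,
)

__all__ = [
    "PipelineConfig",
    "preprocess_volume",
    "train_classifier_on_truth",
    "quantify_stack",
    "run_pipeline",
    "density_recovery_experiment",
    "baseline_power",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated parameters of a full pipeline run."""

    seed: int
    output_dir: str = "thgswell_out"
    # input: either a simulation preset name or TIFF paths
    preset: str | None = "MS"
    n_donors: int = 1
    input_tiffs: list = field(default_factory=list)
    fov_um: float = 100.0
    grid_px: int = 250
    z_step_um: float = 0.4
    n_z: int = 50
    timestamps_min: list = field(default_factory=lambda: [0.0])
    register: bool = True
    timepoint_targets_min: list = field(
        default_factory=lambda: list(DEFAULT_TIMEPOINT_TARGETS_MIN)
    )
    clahe_tile_px: int = 64
    clahe_clip: float = 0.01
    scales_px: tuple = DEFAULT_SCALES_PX
    n_labels_per_class: int = 400
    n_trees: int = 100
    core: float = DEFAULT_CORE
    final: float = DEFAULT_FINAL
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM
    max_diameter_um: float = DEFAULT_MAX_DIAMETER_UM
    sphericity_threshold: float = DEFAULT_SPHERICITY

    def __post_init__(self):
        if not 0 < self.final <= self.core <= 1:
            raise ValueError("detection thresholds require 0 < final <= core <= 1")
        if not 0 < self.sphericity_threshold <= 1:
            raise ValueError("sphericity_threshold must lie in (0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic stages")

    @property
    def geometry(self) -> AcquisitionGeometry:
        return AcquisitionGeometry(
            fov_um=self.fov_um, grid_px=self.grid_px, z_step_um=self.z_step_um
        )


def preprocess_volume(volume: np.ndarray, tile_px: int = 64,
                      clip_limit: float = 0.01) -> np.ndarray:
    """Inversion → 2 px median → CLAHE on one (z, y, x) volume; float output."""
    work = invert(volume)
    work = median_filter_2px(work)
    work = clahe(work, tile_px=tile_px, clip_limit=clip_limit)
    if work.dtype == np.uint8:
        work = work.astype(np.float32) / 255.0
    return work


def train_classifier_on_truth(
    stack: VolumeStack,
    truth,
    seed: int,
    t_index: int = 0,
    n_per_class: int = 400,
    scales_px=DEFAULT_SCALES_PX,
    n_trees: int = 100,
    tile_px: int = 64,
    clip_limit: float = 0.01,
) -> PixelModel:
    """Train the pixel classifier from generator truth (synthetic scribbles)."""
    processed = preprocess_volume(stack.voxels[t_index], tile_px, clip_limit)
    features = compute_features(processed, scales_px)
    labels = sample_sparse_labels(truth.labels[t_index], n_per_class, seed)
    return train_pixel_classifier(features, labels, seed, scales_px, n_trees)


def quantify_stack(
    stack: VolumeStack,
    model: PixelModel,
    config: PipelineConfig,
    timepoints: list[int] | None = None,
) -> dict[int, SwellingSet]:
    """Run preprocessing, probability mapping and detection per timepoint."""
    if config.register and stack.n_t > 1:
        stack = register_timelapse(stack).registered
    if timepoints is None:
        if stack.n_t > 1:
            timepoints = sorted(set(select_timepoints(
                stack.timestamps_min, config.timepoint_targets_min)))
        else:
            timepoints = [0]
    results = {}
    for t in timepoints:
        processed = preprocess_volume(
            stack.voxels[t], config.clahe_tile_px, config.clahe_clip
        )
        features = compute_features(processed, config.scales_px)
        prob = predict_probability(model, features)
        results[t] = detect_swellings(
            prob, stack.geometry, timepoint=t,
            core=config.core, final=config.final,
            sphericity_threshold=config.sphericity_threshold,
            min_diameter_um=config.min_diameter_um,
            max_diameter_um=config.max_diameter_um,
        )
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured run and write all artifacts plus a manifest.

    Returns the manifest (paths of outputs, parameter echo, version, seeds).
    Rerunning with an identical config reproduces the outputs.
    """
    from .io import read_tiff_stack, write_tiff_stack

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    geometry = config.geometry
    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "outputs": [],
    }

    stacks, truths = [], []
    if config.input_tiffs:
        for p in config.input_tiffs:
            stacks.append(read_tiff_stack(p))
            truths.append(None)
    else:
        preset = {"MS": MS_PRESET, "non-MS": NONMS_PRESET}.get(
            config.preset, MS_PRESET
        )
        for d in range(config.n_donors):
            stack, truth = simulate_timelapse(
                preset, geometry, config.n_z, config.timestamps_min,
                seed=int(rng.integers(2 ** 31)),
            )
            stacks.append(stack)
            truths.append(truth)
            path = out / f"donor{d:02d}.tiff"
            write_tiff_stack(stack, path)
            manifest["outputs"].append(str(path))

    if truths[0] is None:
        raise ValueError(
            "file input requires a trained model; use the library API to "
            "supply annotations for real acquisitions"
        )
    model = train_classifier_on_truth(
        stacks[0], truths[0], seed=int(rng.integers(2 ** 31)),
        n_per_class=config.n_labels_per_class,
        scales_px=config.scales_px, n_trees=config.n_trees,
        tile_px=config.clahe_tile_px, clip_limit=config.clahe_clip,
    )

    density_rows = []
    object_rows = []
    for d, stack in enumerate(stacks):
        sets = quantify_stack(stack, model, config)
        for t, sset in sets.items():
            density_rows.append(
                {"donor": d, "timepoint": t,
                 "time_min": stack.timestamps_min[t],
                 "density_per_mm3": sset.density_per_mm3,
                 "n_accepted": len(sset.accepted),
                 "n_objects": len(sset.objects)}
            )
            for o in sset.objects:
                object_rows.append(
                    {"donor": d, "timepoint": t, "id": o.id,
                     "z_um": o.centroid_um[0], "y_um": o.centroid_um[1],
                     "x_um": o.centroid_um[2], "volume_um3": o.volume_um3,
                     "sphericity": o.sphericity, "accepted": o.accepted}
                )
    import pandas as pd

    densities = pd.DataFrame(density_rows)
    objects = pd.DataFrame(object_rows)
    dpath = out / "densities.csv"
    opath = out / "objects.csv"
    densities.to_csv(dpath, index=False)
    objects.to_csv(opath, index=False)
    manifest["outputs"] += [str(dpath), str(opath)]
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# ---------------------------------------------------------------------------
# Parameter-recovery experiments (the package's replacement for the
# undeposited tissue acquisitions)


def density_recovery_experiment(
    seed: int,
    n_ms: int = 5,
    n_nonms: int = 6,
    fov_um: float = 100.0,
    grid_px: int = 250,
    z_step_um: float = 0.4,
    n_z: int = 50,
    n_labels_per_class: int = 400,
    progress: bool = False,
) -> dict:
    """Simulate MS and non-MS donor volumes and recover group mean densities.

    One 100×100×20 µm white-matter volume per donor at 0.4 µm voxels, default
    noise.  A single classifier is trained on one MS-preset training scene
    (synthetic sparse annotations) and applied to every donor, mirroring the
    train-once / apply-everywhere workflow of interactive tools.  Detection
    uses the published thresholds (core 0.85, final 0.5).

    Returns per-donor detected and planted densities plus group means.
    """
    geometry = AcquisitionGeometry(fov_um=fov_um, grid_px=grid_px,
                                   z_step_um=z_step_um)
    config = PipelineConfig(seed=seed, fov_um=fov_um, grid_px=grid_px,
                            z_step_um=z_step_um, n_z=n_z)
    rng = np.random.default_rng(seed)

    train_stack, train_truth = simulate_timelapse(
        MS_PRESET, geometry, n_z, [0.0], seed=int(rng.integers(2 ** 31))
    )
    model = train_classifier_on_truth(
        train_stack, train_truth, seed=int(rng.integers(2 ** 31)),
        n_per_class=n_labels_per_class,
    )

    out = {"MS": {"detected": [], "planted": []},
           "non-MS": {"detected": [], "planted": []}}
    jobs = [("MS", MS_PRESET)] * n_ms + [("non-MS", NONMS_PRESET)] * n_nonms
    for i, (group, preset) in enumerate(jobs):
        stack, truth = simulate_timelapse(
            preset, geometry, n_z, [0.0], seed=int(rng.integers(2 ** 31))
        )
        sets = quantify_stack(stack, model, config, timepoints=[0])
        detected = sets[0].density_per_mm3
        out[group]["detected"].append(detected)
        out[group]["planted"].append(float(truth.true_density_per_mm3[0]))
        if progress:
            logger.info("donor %d/%d (%s): detected %.3g, planted %.3g per mm3",
                        i + 1, len(jobs), group, detected,
                        truth.true_density_per_mm3[0])
    for group in out:
        out[group]["mean_detected"] = float(np.mean(out[group]["detected"]))
        out[group]["mean_planted"] = float(np.mean(out[group]["planted"]))
    out["preset_density"] = {
        "MS": MS_PRESET.swelling_density_per_mm3,
        "non-MS": NONMS_PRESET.swelling_density_per_mm3,
    }
    return out


def baseline_power(
    n_reps: int = 200,
    seed: int = 0,
    n_ms: int = 5,
    n_nonms: int = 6,
    alpha: float = 0.05,
    variant: str = "pooled",
) -> float:
    """Fraction of replicates where the MS vs non-MS baseline test rejects.

    Donor densities are drawn from the preset lognormals (group mean and SD
    from the published baseline densities); each replicate applies the
    two-sample t-test at level ``alpha``.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        ms = sample_donor_densities(
            MS_PRESET.swelling_density_per_mm3, MS_PRESET.swelling_density_spread,
            n_ms, seed=int(rng.integers(2 ** 31)))
        nonms = sample_donor_densities(
            NONMS_PRESET.swelling_density_per_mm3,
            NONMS_PRESET.swelling_density_spread,
            n_nonms, seed=int(rng.integers(2 ** 31)))
        if two_sample_t(ms, nonms, variant=variant).p < alpha:
            hits += 1
    return hits / n_reps
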