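"""End-to-end pipeline: scene -> waveform -> events -> features -> sort.

Also ships the demo mixture configurations that mirror the instrument's
three sorting experiments at desk scale:

* ``bead_mixture_config`` -- 1:1 mixtures of polystyrene beads (7 vs 10 um
  and 7 vs 15 um), gated on the size product (T1*v)*(T2*v_scan) at the
  histogram valley.
* ``leukemia_config`` -- a 1:50 spike of large granular cells (leukemia
  analog, 13 um, 10 granules) into smaller smooth cells (white-blood-cell
  analog, 9 um, sub-resolution granular contrast), gated jointly on
  T1*v and N*v.
* ``algae_config`` -- elongated algal colonies spiked 1:5 into small mixed
  micro-organisms, gated on T1*v.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .beam import comb_weights
from .config import GatingConfig, RunConfig, SceneConfig, _build_beam
from .forward import AcquisitionParams
from .features import (
    GateSpec,
    SortReport,
    apply_gate_and_score,
    estimate_noise_sigma,
    extract_features,
    valley_threshold,
)
from .forward import WaveformRecord, synthesize_waveform
from .phantom import MixtureClass, make_scene
from .reconstruct import detect_events, subtract_background

__all__ = [
    "PipelineResult",
    "simulate",
    "analyze",
    "run_pipeline",
    "bead_mixture_config",
    "leukemia_config",
    "algae_config",
]


@dataclass
class PipelineResult:
    record: WaveformRecord
    features: pd.DataFrame
    gate: GateSpec | None
    report: SortReport | None


def simulate(config: RunConfig, seed: int | None = None) -> WaveformRecord:
    """Draw the scene and synthesize the two-channel waveform."""
    seed = config.seed if seed is None else seed
    scene = make_scene(
        config.scene.classes,
        seed=seed,
        spacing_us=config.scene.spacing_us,
        start_us=config.scene.start_us,
        lateral_sigma_um=config.scene.lateral_sigma_um,
    )
    comb = comb_weights(config.beam)
    return synthesize_waveform(scene, comb, config.acquisition, seed=seed + 1)


def resolve_gate(config: RunConfig, features: pd.DataFrame) -> GateSpec:
    """Materialize the gate: fixed bounds from config, or a 1D valley gate
    placed at the KDE density minimum of the configured axis (the gate then
    selects everything above the valley, the larger-object mode)."""
    g = config.gating
    if g is None:
        raise ValueError("config has no gating section")
    if g.mode == "bounds":
        return GateSpec(bounds=dict(g.bounds))
    thr = valley_threshold(features[g.valley_axis].to_numpy())
    return GateSpec(bounds={g.valley_axis: (thr, float("inf"))})


def analyze(record: WaveformRecord, config: RunConfig) -> PipelineResult:
    """Background-subtract, detect events, extract features, gate, score."""
    clean = subtract_background(record)
    events = detect_events(clean, threshold=config.detection_threshold)
    sigma = estimate_noise_sigma(clean)
    features = extract_features(clean, events, sigma=sigma, peak_k=config.peak_k)
    gate = report = None
    if config.gating is not None and len(features):
        gate = resolve_gate(config, features)
        report = apply_gate_and_score(features, gate, config.gating.target_label)
    return PipelineResult(record=clean, features=features, gate=gate, report=report)


def run_pipeline(config: RunConfig, seed: int | None = None) -> PipelineResult:
    return analyze(simulate(config, seed=seed), config)


def _bead_class(label: str, diameter: float, count: int) -> MixtureClass:
    return MixtureClass(
        label=label,
        count=count,
        kind="bead",
        diameter_mean=diameter,
        diameter_cv=0.03,
        bright_spot=True,
        rim_transmission=0.5,
        body_transmission=0.75,
        center_transmission=1.15,
    )


def bead_mixture_config(
    d_small: float = 7.0, d_large: float = 10.0, n_each: int = 200, seed: int = 0
) -> RunConfig:
    """1:1 two-size polystyrene bead mixture, valley-gated on the size
    product to select the larger beads."""
    return RunConfig(
        beam=_build_beam({}),
        acquisition=AcquisitionParams(),
        scene=SceneConfig(
            classes=[
                _bead_class(f"bead_{d_small:g}um", d_small, n_each),
                _bead_class(f"bead_{d_large:g}um", d_large, n_each),
            ]
        ),
        gating=GatingConfig(
            target_label=f"bead_{d_large:g}um",
            mode="valley",
            valley_axis="size_product_um2",
        ),
        seed=seed,
    )


def leukemia_config(n_target: int = 20, ratio: int = 50, seed: int = 0) -> RunConfig:
    """Granular 13 um target cells spiked 1:ratio into smooth 9 um
    background cells; fixed 2D gate on (L_um, Nv) chosen from the designed
    class statistics (targets: L near 14.5 um, >= 6 bright granules;
    background: L near 10.5 um, no countable positive peaks)."""
    return RunConfig(
        beam=_build_beam({}),
        acquisition=AcquisitionParams(),
        scene=SceneConfig(
            classes=[
                MixtureClass(
                    label="target_cell",
                    count=n_target,
                    kind="cell",
                    diameter_mean=13.0,
                    diameter_cv=0.10,
                    n_granules=10,
                    granule_contrast=0.40,
                    granule_diameter=2.0,
                    body_transmission=0.85,
                ),
                MixtureClass(
                    label="background_cell",
                    count=n_target * ratio,
                    kind="cell",
                    diameter_mean=9.0,
                    diameter_cv=0.10,
                    n_granules=3,
                    granule_contrast=0.10,
                    granule_diameter=1.5,
                    body_transmission=0.85,
                ),
            ]
        ),
        gating=GatingConfig(
            target_label="target_cell",
            mode="bounds",
            bounds={"L_um": (12.0, 25.0), "Nv": (40.0, 1e9)},
        ),
        seed=seed,
    )


def algae_config(n_target: int = 30, ratio: int = 5, seed: int = 0) -> RunConfig:
    """Elongated 4-cell algal colonies spiked 1:ratio into small mixed
    micro-organisms; 1D gate on object length L_um."""
    return RunConfig(
        beam=_build_beam({}),
        acquisition=AcquisitionParams(),
        scene=SceneConfig(
            classes=[
                MixtureClass(
                    label="alga_colony",
                    count=n_target,
                    kind="alga_colony",
                    diameter_mean=10.0,
                    diameter_cv=0.08,
                    n_cells=4,
                    width=4.0,
                    body_transmission=0.8,
                ),
                MixtureClass(
                    label="micro_organism",
                    count=n_target * ratio,
                    kind="cell",
                    diameter_mean=5.0,
                    diameter_cv=0.20,
                    n_granules=1,
                    granule_contrast=0.15,
                    body_transmission=0.85,
                ),
            ]
        ),
        gating=GatingConfig(
            target_label="alga_colony",
            mode="bounds",
            bounds={"L_um": (8.5, 30.0)},
        ),
        seed=seed,
    )
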