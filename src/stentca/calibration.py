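"""Anchor-based calibration of the free reaction probabilities.

The CA's probabilities are free parameters; the packaged defaults were fixed
once by matching four milestone statistics of the simulated study conditions:

  hs_initial_rate      MgF2 initial degradation rate in the high-strain mask,
                       PDLLA-deformed            → 0.025 (fraction / 100 steps)
  overall_initial_rate same, whole lattice       → 0.004
  pbat_onset           PBAT coating onset step (F ≥ 0.01), PBAT-deformed
                                                 → 1200 steps
  crack_half_step      first step with crack-site MgF2 degraded fraction
                       ≥ 0.5, PDLLA-deformed     → 700 steps

All four are "∼" milestones, so the calibration tolerance is ±30 % and
statistics are medians over a seed bank.  Re-running this search is slow
(full simulations per candidate); its frozen output is the default material
table in :mod:`stentca.materials`.
"""

from __future__ import annotations

import numpy as np

from . import engine, metrics
from .geometry import COMPONENTS
from .metrics import Anchor, CalibrationResult, calibrate_defaults
from .scenarios import make_scenario

__all__ = ["ANCHORS", "simulate_stats", "run_calibration"]

ANCHORS = [
    Anchor("hs_initial_rate", 0.025),
    Anchor("overall_initial_rate", 0.004),
    Anchor("pbat_onset", 1200.0),
    Anchor("crack_half_step", 700.0),
]

CRACK_HALF_FRACTION = 0.5
ONSET_THRESHOLD = 0.01


def _run_until(cfg, max_steps, done):
    """Iterate the engine, stopping early once ``done(trace_so_far)`` is true.

    ``done`` sees a DegradationTrace snapshot every rate_window steps.
    """
    lat, env, dm, materials, rng = engine.build_initial(cfg)
    regions = metrics.standard_regions(lat, env, dm)
    rec = metrics.TraceRecorder(lat, regions)
    for t in range(1, max_steps + 1):
        engine.step(lat, materials, cfg, rng)
        rec.record(lat)
        if t % cfg.rate_window == 0 and t >= 3 * cfg.rate_window:
            if done(rec.finalize(cfg.rate_window)):
                break
    return rec.finalize(cfg.rate_window)


def simulate_stats(overrides: dict, seed: int, steps: int = 2000) -> dict:
    """The four anchor statistics for one seed under material overrides."""
    stats: dict[str, float | None] = {}

    cfg = make_scenario("PDLLA-deformed", steps=steps, seed=seed)
    cfg.material_overrides = overrides

    def pdlla_done(trace):
        f = trace.fraction("MGF2", metrics.CRACK_SITE)
        return metrics.detect_onset(f, CRACK_HALF_FRACTION) is not None

    trace = _run_until(cfg, steps, pdlla_done)
    stats["hs_initial_rate"] = metrics.initial_rate(trace, "MGF2", metrics.HIGH_STRAIN)
    stats["overall_initial_rate"] = metrics.initial_rate(trace, "MGF2", metrics.OVERALL)
    half = metrics.detect_onset(trace.fraction("MGF2", metrics.CRACK_SITE),
                                CRACK_HALF_FRACTION)
    stats["crack_half_step"] = None if half is None else float(half)

    cfg = make_scenario("PBAT-deformed", steps=steps, seed=seed)
    cfg.material_overrides = overrides

    def pbat_done(trace):
        return metrics.detect_onset(trace.fraction("POLY"), ONSET_THRESHOLD) is not None

    trace = _run_until(cfg, steps, pbat_done)
    onset = metrics.detect_onset(trace.fraction("POLY"), ONSET_THRESHOLD)
    stats["pbat_onset"] = None if onset is None else float(onset)
    return stats


def _to_overrides(params: dict) -> dict:
    """Flat search parameters → material_overrides blocks.

    The PBAT hydrolysis probability is tied to half the PDLLA one (the
    observed coating-degradation-rate ratio), so only PDLLA's is searched.
    """
    return {
        "MGF2": {"dissolution_prob": params["mgf2_dissolution"],
                 "acid_boost": params["mgf2_acid_boost"]},
        "PDLLA": {"hydrolysis_prob": params["pdlla_hydrolysis"]},
        "PBAT": {"hydrolysis_prob": params["pdlla_hydrolysis"] / 2.0},
    }


def run_calibration(seed_bank=(0, 1, 2), steps: int = 2000,
                    param_space: dict | None = None) -> CalibrationResult:
    """Coordinate search over the free probabilities against ANCHORS."""
    if param_space is None:
        param_space = {
            "mgf2_dissolution": [5e-4, 1e-3, 2e-3, 4e-3],
            "mgf2_acid_boost": [1.0, 2.0, 4.0, 8.0],
            "pdlla_hydrolysis": [5e-5, 1e-4, 2e-4, 4e-4],
        }

    def evaluate(params, seed):
        return simulate_stats(_to_overrides(params), seed, steps=steps)

    return calibrate_defaults(ANCHORS, param_space, evaluate, seeds=seed_bank)
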