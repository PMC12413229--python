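"""Degradation traces, rates, region masks, milestones, and calibration.

The simulator's primary quantitative output is the degraded fraction

    F_c(t) = 1 − N_c(t) / N_c(0)

per component c, over the whole lattice and over named region masks (the
high-strain zone around the arc apex, the crack-site columns).  Rates are
finite differences of F over a fixed window (default 100 steps); the
"initial rate" of a component is the mean rate over the first three windows.
Milestones: onset = first step with F ≥ 0.01; crack-site half-degradation =
first step with F ≥ 0.5 at the crack columns.

``calibrate_defaults`` is the coordinate-descent search that once fixed the
packaged reaction probabilities against the printed milestones; it stays
available for re-calibration but its frozen output lives in
:mod:`stentca.materials`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Lattice, COMPONENTS, COMPONENT_IDS, ELEC, POLY, MG, INNER, OUTER
from .mechanics import StrainField

__all__ = [
    "DegradationTrace", "TraceRecorder", "RegionMask", "standard_regions",
    "degradation_rate", "initial_rate", "high_strain_mask",
    "detect_onset", "detect_stabilization",
    "Anchor", "CalibrationResult", "calibrate_defaults",
]

OVERALL = "overall"
HIGH_STRAIN = "high_strain"
CRACK_SITE = "crack_site"

N_INITIAL_WINDOWS = 3  # "initial rate" = mean over the first this-many windows


@dataclass
class RegionMask:
    name: str
    mask: np.ndarray  # boolean, lattice-shaped

    @property
    def size(self) -> int:
        return int(self.mask.sum())


def high_strain_mask(field: StrainField, lattice: Lattice,
                     threshold_mode: str = "half-peak",
                     elongation_at_break: float | None = None) -> RegionMask:
    """Cells where the deformation concentrates.

    "half-peak" (default): ε_eff ≥ 0.5 × max ε_eff — undefined (empty, with a
    warning-free empty mask) on a zero field.  "above-eb": ε_eff strictly
    above the coating's elongation at break, i.e. the crack-prone zone.
    """
    mag = field.magnitude
    if threshold_mode == "half-peak":
        peak = mag.max()
        if peak <= 0:
            return RegionMask(HIGH_STRAIN, np.zeros_like(mag, dtype=bool))
        mask = mag >= 0.5 * peak
    elif threshold_mode == "above-eb":
        if elongation_at_break is None:
            raise ValueError("above-eb mode needs elongation_at_break")
        mask = mag > elongation_at_break
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    return RegionMask(HIGH_STRAIN, mask)


def crack_site_mask(lattice: Lattice, damage_map) -> RegionMask:
    """All cells of a face whose column cracked on that face."""
    mask = np.zeros(lattice.comp.shape, dtype=bool)
    if damage_map is not None:
        for fi, side in enumerate((OUTER, INNER)):
            cols = damage_map.cracked[fi]
            if lattice.comp.ndim == 2:
                mask |= (lattice.side == side) & cols[None, :]
            else:
                mask |= (lattice.side == side) & cols[None, :, None]
    return RegionMask(CRACK_SITE, mask)


def standard_regions(lattice: Lattice, field: StrainField, damage_map) -> list[RegionMask]:
    regions = [RegionMask(OVERALL, np.ones(lattice.comp.shape, dtype=bool))]
    hs = high_strain_mask(field, lattice)
    if hs.size:
        regions.append(hs)
    cs = crack_site_mask(lattice, damage_map)
    if cs.size:
        regions.append(cs)
    return regions


@dataclass
class DegradationTrace:
    """Component counts and degraded fractions per region over time.

    ``counts[region]`` has shape (steps+1, n_components); step 0 is the
    damaged initial state, so F_c(0) = 0 by construction.  For Mg, "degraded"
    includes conversion to product and subsequent dissolution alike, since
    both remove cells from the MG count.
    """

    counts: dict[str, np.ndarray]
    rate_window: int = 100

    @property
    def n_steps(self) -> int:
        return next(iter(self.counts.values())).shape[0] - 1

    @property
    def regions(self) -> list[str]:
        return list(self.counts)

    def initial_count(self, component: str, region: str = OVERALL) -> int:
        return int(self.counts[region][0, COMPONENT_IDS[component]])

    def fraction(self, component: str, region: str = OVERALL) -> np.ndarray:
        """F_c(t) series, length steps+1; zeros if the component is absent."""
        c = self.counts[region][:, COMPONENT_IDS[component]].astype(float)
        n0 = c[0]
        if n0 == 0:
            return np.zeros_like(c)
        return 1.0 - c / n0


class TraceRecorder:
    """Accumulates per-step component counts for a set of regions."""

    def __init__(self, lattice: Lattice, regions: list[RegionMask]):
        self._masks = {r.name: r.mask for r in regions}
        self._rows = {name: [self._count(lattice, m)] for name, m in self._masks.items()}

    @staticmethod
    def _count(lattice: Lattice, mask: np.ndarray) -> np.ndarray:
        return np.bincount(lattice.comp[mask].ravel(), minlength=len(COMPONENTS))

    def record(self, lattice: Lattice) -> None:
        for name, m in self._masks.items():
            self._rows[name].append(self._count(lattice, m))

    def finalize(self, rate_window: int = 100) -> DegradationTrace:
        return DegradationTrace(
            {name: np.asarray(rows) for name, rows in self._rows.items()},
            rate_window=rate_window,
        )


def degradation_rate(trace: DegradationTrace, component: str,
                     region: str = OVERALL, window: int | None = None) -> np.ndarray:
    """Per-window rate series r(t) = F(t) − F(t − window), at t = window, 2·window, …

    Units: degraded fraction per window (default window 100 steps).
    """
    w = trace.rate_window if window is None else window
    if w < 1:
        raise ValueError("window must be >= 1")
    if region not in trace.counts:
        raise KeyError(f"unknown region {region!r}; have {trace.regions}")
    if component not in COMPONENT_IDS:
        raise KeyError(f"unknown component {component!r}")
    f = trace.fraction(component, region)
    if len(f) <= w:
        raise ValueError(f"trace length {len(f)-1} not longer than window {w}")
    pts = f[w::w]
    prev = f[0:-w:w][: len(pts)]
    return pts - prev


def initial_rate(trace: DegradationTrace, component: str, region: str = OVERALL,
                 window: int | None = None, n_windows: int = N_INITIAL_WINDOWS) -> float:
    """Mean rate over the first ``n_windows`` windows (the "initial rate")."""
    r = degradation_rate(trace, component, region, window)
    return float(r[:n_windows].mean())


def detect_onset(series: np.ndarray, threshold: float = 0.01) -> int | None:
    """Smallest t with F(t) ≥ threshold, or None if never reached."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    idx = np.nonzero(np.asarray(series) >= threshold)[0]
    return int(idx[0]) if idx.size else None


def detect_stabilization(rates: np.ndarray, tol: float,
                         consecutive: int = 3) -> int | None:
    """First window index after which |Δrate| stays below tol for ≥ 3 windows.

    Returns the index into ``rates`` where the plateau begins, or None.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    rates = np.asarray(rates, dtype=float)
    if len(rates) < consecutive + 1:
        return None
    delta = np.abs(np.diff(rates))
    ok = delta < tol
    run = 0
    for i, flag in enumerate(ok):
        run = run + 1 if flag else 0
        if run >= consecutive:
            return i - consecutive + 1
    return None


# ---------------------------------------------------------------------------
# calibration

@dataclass
class Anchor:
    """One target statistic with tolerance.

    ``stat`` names a key of the dict returned by the evaluation callable;
    ``target`` the desired value; ``rel_tol`` the accepted relative error
    (default ±30 % — the printed milestones are all "∼" values).
    Alternatively ``lo``/``hi`` give an explicit acceptance interval.
    """

    stat: str
    target: float | None = None
    rel_tol: float = 0.30
    lo: float | None = None
    hi: float | None = None

    def interval(self) -> tuple[float, float]:
        if self.lo is not None and self.hi is not None:
            return self.lo, self.hi
        t = self.target
        return t - abs(t) * self.rel_tol, t + abs(t) * self.rel_tol

    def error(self, value: float) -> float:
        if value is None or not np.isfinite(value):
            return np.inf
        if self.target is not None:
            return abs(value - self.target) / max(abs(self.target), 1e-12)
        lo, hi = self.interval()
        mid, half = (lo + hi) / 2, (hi - lo) / 2
        return max(0.0, abs(value - mid) - half) / max(half, 1e-12)

    def satisfied(self, value: float) -> bool:
        if value is None or not np.isfinite(value):
            return False
        lo, hi = self.interval()
        return lo <= value <= hi


@dataclass
class CalibrationResult:
    params: dict
    achieved: dict
    satisfied: bool
    flag: str  # "ok" | "unconstrained" | "failed"
    history: list = field(default_factory=list)


def calibrate_defaults(anchors: list[Anchor], param_space: dict,
                       evaluate, seeds=(0,), max_rounds: int = 3,
                       refine: int = 2) -> CalibrationResult:
    """Coordinate grid search minimizing mean relative anchor error.

    ``param_space`` maps parameter name → list of candidate values (the grid).
    ``evaluate(params: dict, seed) -> dict`` runs the model and returns the
    statistics the anchors reference (averaged here over ``seeds``).  Search
    sweeps one parameter at a time, keeping the best value, for up to
    ``max_rounds`` rounds (with ``refine`` geometric refinements of the grid
    around the incumbent), and never silently accepts a miss: the result
    carries a "failed" flag when some anchor is unsatisfied.
    """
    if not param_space:
        raise ValueError("param_space must not be empty")
    params = {k: v[len(v) // 2] for k, v in param_space.items()}
    if not anchors:
        return CalibrationResult(params, {}, True, "unconstrained")

    def score(p):
        stats_list = [evaluate(p, s) for s in seeds]
        stats = {k: float(np.nanmedian([d[k] if d[k] is not None else np.nan
                                        for d in stats_list]))
                 for k in stats_list[0]}
        err = float(np.mean([a.error(stats.get(a.stat, np.nan)) for a in anchors]))
        return err, stats

    history = []
    best_err, best_stats = score(params)
    history.append((dict(params), best_err))
    space = {k: list(v) for k, v in param_space.items()}
    for refinement in range(refine + 1):
        for _ in range(max_rounds):
            improved = False
            for name, grid in space.items():
                for cand in grid:
                    if cand == params[name]:
                        continue
                    trial = dict(params, **{name: cand})
                    err, stats = score(trial)
                    history.append((dict(trial), err))
                    if err < best_err - 1e-12:
                        params, best_err, best_stats = trial, err, stats
                        improved = True
            if not improved:
                break
        if refinement < refine:
            # geometric refinement around the incumbent
            new_space = {}
            for name, grid in space.items():
                lo, hi = min(grid), max(grid)
                c = params[name]
                span = (hi - lo) / 4 if hi > lo else abs(c) * 0.25
                if span <= 0:
                    new_space[name] = [c]
                    continue
                cand = sorted({max(lo, c - span), c, min(hi, c + span)})
                new_space[name] = cand
            space = new_space

    ok = all(a.satisfied(best_stats.get(a.stat)) for a in anchors)
    return CalibrationResult(params, best_stats, ok, "ok" if ok else "failed", history)
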