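"""The cellular-automaton corrosion engine.

Each step is a synchronous two-phase update of the lattice:

Phase 1 — transport.  Mobile species (H2O, Cl-, H+) are discrete walkers,
several per cell.  Every walker picks a uniformly random neighbor and moves if
the destination is electrolyte (always), polymer (with that polymer's
permeation probability — the barrier property), and never into MgF2/MgO/Mg or
corrosion product.  The bulk-electrolyte reservoir rows are reset to their
nominal concentrations at the end of the phase, modeling an effectively
infinite, refreshed PBS bath.

Phase 2 — reactions, evaluated on a frozen copy of the post-transport state:

  (i)   POLY with water in its neighborhood (or resident) → ELEC
        (ester hydrolysis) with the polymer's hydrolysis probability;
  (ii)  MgF2 with a water-bearing electrolyte neighbor → ELEC with its
        dissolution probability, multiplied by ``acid_boost`` when an H+
        walker is adjacent;
  (iii) MgO likewise with its own constants;
  (iv)  Mg with a water-bearing electrolyte neighbor → PRODUCT (Mg(OH)2);
        Mg reachable only through a wetted product shell reacts at
        ``dissolution_prob × shielding_factor`` — the passivating effect of
        the hydroxide layer;
  (v)   PRODUCT with an adjacent Cl- walker → ELEC (chloride breakdown of
        the passive film).

Each cell class has exactly one candidate transition, so the nominal priority
ordering (i) < … < (v) never has to break a tie; at most one transition per
cell per step holds by construction.  Allowed transitions are only
POLY→ELEC, MGF2→ELEC, MGO→ELEC, MG→PRODUCT, PRODUCT→ELEC: cells relabel in
place, so the total cell count is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from . import geometry, mechanics, damage as damage_mod
from .geometry import (
    Lattice, ELEC, POLY, MGF2, MGO, MG, PRODUCT, COMPONENTS, SPECIES,
)
from .materials import MaterialProps, default_materials

__all__ = [
    "SimConfig", "LatticeConfig", "StrainConfig", "StepReport",
    "step", "run", "RunResult", "validate_config",
]

DEFAULT_RESERVOIR_CONC = {"H2O": 2.0, "CL": 1.0, "H": 0.2}


@dataclass
class LatticeConfig:
    cell_size_um: float = geometry.DEFAULT_CELL_UM
    arc_length_cells: int = geometry.DEFAULT_ARC_CELLS
    strut_thickness_um: float = geometry.DEFAULT_STRUT_UM
    reservoir_rows: int = geometry.DEFAULT_RESERVOIR_ROWS
    # (material, thickness_um) outermost first; empty entries allowed for bare scenarios
    layers: list = field(default_factory=lambda: [
        ["POLY", 4.0], ["MGF2", 1.0], ["MGO", 0.5],
    ])
    depth: int = 0  # 0 = 2D; >0 extrudes for 3D cloud runs


@dataclass
class StrainConfig:
    deformed: bool = True
    peak_inner_compression: float = 0.30
    peak_outer_compression: float = 0.25
    peak_inner_tension: float = 0.20
    peak_outer_tension: float = 0.15
    width: float = mechanics.DEFAULT_WIDTH


@dataclass
class SimConfig:
    """Complete, reproducible description of one simulation run."""

    scenario: str = "custom"
    steps: int = 4000
    seed: int = 0
    polymer: str | None = "PDLLA"
    reservoir_conc: dict = field(default_factory=lambda: dict(DEFAULT_RESERVOIR_CONC))
    neighborhood: str = "vonNeumann"
    rate_window: int = 100
    snapshot_every: int = 0
    shielding_factor: float = 0.2
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    strain: StrainConfig = field(default_factory=StrainConfig)
    material_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if isinstance(d.get("lattice"), dict):
            d["lattice"] = LatticeConfig(**d["lattice"])
        if isinstance(d.get("strain"), dict):
            d["strain"] = StrainConfig(**d["strain"])
        return cls(**d)


def validate_config(cfg: SimConfig) -> list[str]:
    """List of violations of the config invariants (empty when valid)."""
    v = []
    if cfg.steps < 0:
        v.append(f"steps must be >= 0, got {cfg.steps}")
    if cfg.rate_window < 1:
        v.append(f"rate_window must be >= 1, got {cfg.rate_window}")
    if any(c < 0 for c in cfg.reservoir_conc.values()):
        v.append("reservoir_conc values must be >= 0")
    if cfg.neighborhood not in ("vonNeumann", "Moore"):
        v.append(f"unknown neighborhood {cfg.neighborhood!r}")
    if not (0.0 <= cfg.shielding_factor <= 1.0):
        v.append(f"shielding_factor must be in [0, 1], got {cfg.shielding_factor}")
    return v


@dataclass
class StepReport:
    """Per-step event bookkeeping."""

    step: int
    events: dict
    walkers: dict


# ---------------------------------------------------------------------------
# neighborhood machinery

def _offsets(ndim: int, neighborhood: str):
    if neighborhood == "vonNeumann":
        offs = []
        for ax in range(ndim):
            for d in (-1, 1):
                o = [0] * ndim
                o[ax] = d
                offs.append(tuple(o))
        return offs
    if neighborhood == "Moore":
        from itertools import product
        return [o for o in product((-1, 0, 1), repeat=ndim) if any(o)]
    raise ValueError(f"unknown neighborhood {neighborhood!r}")


def _shift(a: np.ndarray, off, fill=0) -> np.ndarray:
    """out[x] = a[x + off], with ``fill`` outside the grid."""
    out = np.full_like(a, fill)
    src, dst = [], []
    for n, o in zip(a.shape, off):
        if o > 0:
            src.append(slice(o, n)); dst.append(slice(0, n - o))
        elif o < 0:
            src.append(slice(0, n + o)); dst.append(slice(-o, n))
        else:
            src.append(slice(None)); dst.append(slice(None))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _any_neighbor(mask: np.ndarray, offs) -> np.ndarray:
    out = np.zeros_like(mask)
    for o in offs:
        out |= _shift(mask, o, fill=False)
    return out


# ---------------------------------------------------------------------------
# material parameter grids

class _Params:
    """Per-component parameter lookup tables resolved once per run."""

    def __init__(self, materials: dict[str, MaterialProps], polymer: str | None,
                 shielding_factor: float):
        nc = len(COMPONENTS)
        self.dissolution = np.zeros(nc)
        self.acid_boost = np.ones(nc)
        self.hydrolysis = 0.0
        self.permeation = 0.0
        self.shielding = shielding_factor
        if polymer is not None:
            pm = materials[polymer]
            self.hydrolysis = pm.hydrolysis_prob
            self.permeation = pm.permeation_prob
        for comp_id, name in ((MGF2, "MGF2"), (MGO, "MGO"), (MG, "MG"), (PRODUCT, "PRODUCT")):
            m = materials.get(name)
            if m is not None:
                self.dissolution[comp_id] = m.dissolution_prob
                self.acid_boost[comp_id] = m.acid_boost


def resolve_materials(cfg: SimConfig) -> dict[str, MaterialProps]:
    """Default table with the config's per-field overrides applied."""
    table = default_materials()
    for name, fields in cfg.material_overrides.items():
        table[name] = table[name].replace(**fields)
    return table


# ---------------------------------------------------------------------------
# one CA step

def _move_block(counts, accept, offs, rng):
    """One transport hop on a (sub-)grid; walkers bounce off accept-0 cells."""
    k = len(offs)
    remaining = counts.astype(np.int64)
    new = np.zeros_like(remaining)
    for i, off in enumerate(offs):
        if i < k - 1:
            movers = np.zeros_like(remaining)
            m = remaining > 0
            if m.any():
                movers[m] = rng.binomial(remaining[m], 1.0 / (k - i))
            remaining = remaining - movers
        else:
            movers = remaining
        # acceptance prob of each mover's destination, 0 outside the grid
        p_dst = _shift(accept, off, fill=0.0)
        accepted = np.zeros_like(movers)
        has = movers > 0
        full = has & (p_dst >= 1.0)
        part = has & (p_dst > 0.0) & ~full
        accepted[full] = movers[full]
        if part.any():
            accepted[part] = rng.binomial(movers[part], p_dst[part])
        new += movers - accepted              # bounced walkers stay
        new += _shift(accepted, tuple(-o for o in off))  # arrivals
    return new


def _transport_species(comp, counts, offs, perm: float, rng):
    """Move every walker one attempted hop; return the new count grid.

    Only contiguous bands of rows that hold walkers or can accept them are
    processed: the intact metal core is opaque to walkers, so the two coating
    faces evolve as independent bands until the strut is breached.
    """
    if not counts.any():
        return counts
    accept = np.zeros(comp.shape, dtype=np.float64)
    accept[comp == ELEC] = 1.0
    if perm > 0:
        accept[comp == POLY] = perm
    other_axes = tuple(range(1, comp.ndim))
    active = (accept > 0).any(axis=other_axes) | (counts > 0).any(axis=other_axes)
    new = counts.astype(np.int64)
    r = 0
    nrows = comp.shape[0]
    while r < nrows:
        if not active[r]:
            r += 1
            continue
        r1 = r
        while r1 < nrows and active[r1]:
            r1 += 1
        if counts[r:r1].any():
            new[r:r1] = _move_block(counts[r:r1], accept[r:r1], offs, rng)
        r = r1
    return new.astype(counts.dtype)


def _replenish(lat: Lattice, conc: dict, rng):
    res = lat.reservoir
    for sp in SPECIES:
        c = float(conc.get(sp, 0.0))
        base = int(np.floor(c))
        arr = lat.species[sp]
        arr[res] = base
        frac = c - base
        if frac > 0:
            arr[res] += (rng.random(res.sum()) < frac).astype(arr.dtype)


_SOLID = (MGF2, MGO, MG, PRODUCT)


def step(lat: Lattice, materials: dict[str, MaterialProps], cfg: SimConfig,
         rng: np.random.Generator, polymer: str | None = None) -> tuple[Lattice, StepReport]:
    """Advance the lattice one step in place; returns (lattice, StepReport)."""
    poly_name = polymer if polymer is not None else cfg.polymer
    par = _Params(materials, poly_name if (lat.comp == POLY).any() else None,
                  cfg.shielding_factor)
    offs = _offsets(lat.comp.ndim, cfg.neighborhood)
    comp = lat.comp

    # --- phase 1: transport -------------------------------------------------
    for sp in SPECIES:
        lat.species[sp] = _transport_species(comp, lat.species[sp], offs,
                                             par.permeation, rng)
    _replenish(lat, cfg.reservoir_conc, rng)

    h2o, cl, hplus = (lat.species[s] for s in SPECIES)
    solid = (comp == MGF2) | (comp == MGO) | (comp == MG) | (comp == PRODUCT)
    if ((h2o > 0) | (cl > 0) | (hplus > 0))[solid].any():
        raise RuntimeError("internal corruption: walker found inside a solid cell")

    # --- phase 2: reactions on the frozen post-transport state --------------
    wet_elec = (comp == ELEC) & (h2o > 0)
    wet_adj = _any_neighbor(wet_elec, offs)
    water_nbhd = (h2o > 0) | _any_neighbor(h2o > 0, offs)
    h_adj = _any_neighbor(hplus > 0, offs)
    cl_adj = _any_neighbor(cl > 0, offs)

    p = np.zeros(comp.shape)
    target = np.full(comp.shape, 255, dtype=np.uint8)

    is_poly = comp == POLY
    m = is_poly & water_nbhd
    p[m] = par.hydrolysis
    target[m] = ELEC

    for cid in (MGF2, MGO):
        m = (comp == cid) & wet_adj
        boost = np.where(h_adj[m], par.acid_boost[cid], 1.0)
        p[m] = np.minimum(par.dissolution[cid] * boost, 1.0)
        target[m] = ELEC

    # Mg: direct wet exposure, or shielded attack through a wetted product blob
    mg_direct = (comp == MG) & wet_adj
    boost = np.where(h_adj[mg_direct], par.acid_boost[MG], 1.0)
    p[mg_direct] = np.minimum(par.dissolution[MG] * boost, 1.0)
    target[mg_direct] = PRODUCT

    product = comp == PRODUCT
    if product.any():
        labels, n = ndimage.label(product, structure=ndimage.generate_binary_structure(comp.ndim, 1))
        touched = np.zeros(n + 1, dtype=bool)
        touched[np.unique(labels[product & wet_adj])] = True
        touched[0] = False
        wet_product = touched[labels]
        mg_shield = (comp == MG) & ~wet_adj & _any_neighbor(wet_product, offs)
        p[mg_shield] = par.dissolution[MG] * par.shielding
        target[mg_shield] = PRODUCT

        m = product & cl_adj
        p[m] = par.dissolution[PRODUCT]
        target[m] = ELEC
    else:
        mg_shield = np.zeros_like(mg_direct)

    fire = (p > 0) & (rng.random(comp.shape) < p)
    events = {
        "hydrolysis": int((fire & is_poly).sum()),
        "mgf2_dissolution": int((fire & (comp == MGF2)).sum()),
        "mgo_dissolution": int((fire & (comp == MGO)).sum()),
        "mg_product": int((fire & (comp == MG)).sum()),
        "product_dissolution": int((fire & product).sum()) if product.any() else 0,
    }
    comp[fire] = target[fire]

    report = StepReport(
        step=-1,
        events=events,
        walkers={sp: int(lat.species[sp].sum()) for sp in SPECIES},
    )
    return lat, report


# ---------------------------------------------------------------------------
# full run

@dataclass
class RunResult:
    trace: "object"             # metrics.DegradationTrace
    snapshots: list             # [(step, comp grid copy), ...]
    reports: list               # [StepReport, ...]
    lattice: Lattice            # final state
    damage_map: "object | None"
    config: SimConfig


def build_initial(cfg: SimConfig, seed_seq: np.random.SeedSequence | None = None):
    """Lattice + envelope strain field + realized damage for a config."""
    from .mechanics import strain_surrogate, strain_envelope, zero_field

    if seed_seq is None:
        seed_seq = np.random.SeedSequence(cfg.seed)
    damage_seed, engine_seed = seed_seq.spawn(2)

    lc = cfg.lattice
    layers = [geometry.LayerSpec(m, t) for m, t in lc.layers]
    lat = geometry.build_lattice(
        layers=layers,
        strut_thickness_um=lc.strut_thickness_um,
        arc_length_cells=lc.arc_length_cells,
        cell_size_um=lc.cell_size_um,
        reservoir_rows=lc.reservoir_rows,
    )
    if lc.depth:
        lat = geometry.extrude(lat, lc.depth)

    sc = cfg.strain
    if sc.deformed:
        comp_f = strain_surrogate("compression", lat, sc.peak_inner_compression,
                                  sc.peak_outer_compression, sc.width)
        tens_f = strain_surrogate("tension", lat, sc.peak_inner_tension,
                                  sc.peak_outer_tension, sc.width)
        env = strain_envelope(comp_f, tens_f)
    else:
        env = zero_field(lat)

    materials = resolve_materials(cfg)
    dm = None
    if cfg.polymer is not None and (lat.comp == POLY).any():
        lat, dm = damage_mod.apply_damage(
            lat, env, materials[cfg.polymer],
            np.random.default_rng(damage_seed))
    engine_rng = np.random.default_rng(engine_seed)
    return lat, env, dm, materials, engine_rng


def run(cfg: SimConfig, progress: bool = False) -> RunResult:
    """Execute a configured run: build, damage, iterate, trace.

    Fully reproducible from (cfg, cfg.seed): one master seed spawns separate
    streams for the damage realization and the CA evolution.
    """
    from . import metrics

    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))

    lat, env, dm, materials, rng = build_initial(cfg)
    regions = metrics.standard_regions(lat, env, dm)
    trace = metrics.TraceRecorder(lat, regions)

    snapshots = [(0, lat.comp.copy())]
    reports = []
    iterator = range(1, cfg.steps + 1)
    if progress:
        from tqdm import tqdm  # optional nicety; not a declared dependency
        iterator = tqdm(iterator)
    for t in iterator:
        lat, rep = step(lat, materials, cfg, rng)
        rep.step = t
        reports.append(rep)
        trace.record(lat)
        if cfg.snapshot_every and t % cfg.snapshot_every == 0:
            snapshots.append((t, lat.comp.copy()))
    if not cfg.snapshot_every or cfg.steps % max(cfg.snapshot_every, 1) != 0:
        snapshots.append((cfg.steps, lat.comp.copy()))

    return RunResult(trace.finalize(cfg.rate_window), snapshots, reports, lat, dm, cfg)
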