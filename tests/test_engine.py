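import itertools

import numpy as np
import pytest

from stentca import engine, scenarios
from stentca.engine import SimConfig, step, run, resolve_materials
from stentca.geometry import (
    Lattice, build_lattice, component_counts,
    ELEC, POLY, MGF2, MGO, MG, PRODUCT, SPECIES, COMPONENTS,
)
from stentca.materials import default_materials

ALLOWED = {(POLY, ELEC), (MGF2, ELEC), (MGO, ELEC), (MG, PRODUCT), (PRODUCT, ELEC)}


def tiny_lattice(comp_grid, walkers=(), reservoir_rows=0):
    comp = np.array(comp_grid, dtype=np.uint8)
    species = {s: np.zeros_like(comp, dtype=np.int32) for s in SPECIES}
    for sp, (r, c) in walkers:
        species[sp][r, c] += 1
    res = np.zeros_like(comp, dtype=bool)
    if reservoir_rows:
        res[:reservoir_rows] = True
    side = np.where(np.arange(comp.shape[0])[:, None] < comp.shape[0] / 2, 1, -1)
    return Lattice(comp, species, 0.5,
                   (np.arange(comp.shape[1]) + 0.5) / comp.shape[1],
                   np.broadcast_to(side, comp.shape).astype(np.int8).copy(), res)


def toy_cfg(**kw):
    kw.setdefault("polymer", None)
    kw.setdefault("reservoir_conc", {"H2O": 0, "CL": 0, "H": 0})
    return SimConfig(**kw)


def test_perfect_barrier_preserves_inorganic_layers():
    """Intact zero-porosity coating with zero permeation: no inorganic attack."""
    lat = build_lattice(arc_length_cells=40)
    cfg = SimConfig(polymer="PDLLA",
                    material_overrides={"PDLLA": {"permeation_prob": 0.0}})
    mats = resolve_materials(cfg)
    rng = np.random.default_rng(0)
    before = component_counts(lat)
    for _ in range(300):
        step(lat, mats, cfg, rng)
    after = component_counts(lat)
    for comp in ("MG", "MGO", "MGF2"):
        assert after[comp] == before[comp]


def test_forced_transition_probability_one():
    lat = tiny_lattice([[ELEC, ELEC], [MG, MG]], reservoir_rows=1)
    cfg = toy_cfg(reservoir_conc={"H2O": 1, "CL": 0, "H": 0},
                  material_overrides={"MG": {"dissolution_prob": 1.0, "acid_boost": 1.0}})
    step(lat, resolve_materials(cfg), cfg, np.random.default_rng(0))
    assert (lat.comp[1] == PRODUCT).all()


@pytest.mark.parametrize(
    "solid,prob,overrides",
    [
        (MGF2, 0.2, {"MGF2": {"dissolution_prob": 0.2, "acid_boost": 1.0}}),
        (MGO, 0.35, {"MGO": {"dissolution_prob": 0.35, "acid_boost": 1.0}}),
    ],
)
def test_one_step_dissolution_frequency_matches_binomial(solid, prob, overrides):
    """Empirical transition frequency over 1000 trials within 3 binomial SEs."""
    base = tiny_lattice([[ELEC, ELEC], [solid, solid]], reservoir_rows=1)
    cfg = toy_cfg(reservoir_conc={"H2O": 1, "CL": 0, "H": 0},
                  material_overrides=overrides)
    mats = resolve_materials(cfg)
    rng = np.random.default_rng(42)
    n, hits = 1000, 0
    for _ in range(n):
        lat = base.copy()
        step(lat, mats, cfg, rng)
        hits += int(lat.comp[1, 0] != solid)
    se = np.sqrt(prob * (1 - prob) / n)
    assert abs(hits / n - prob) <= 3 * se


def test_hydrolysis_frequency_matches_binomial():
    base = tiny_lattice([[ELEC, ELEC], [POLY, POLY]], reservoir_rows=1)
    cfg = toy_cfg(polymer="PDLLA",
                  reservoir_conc={"H2O": 1, "CL": 0, "H": 0},
                  material_overrides={"PDLLA": {"hydrolysis_prob": 0.3,
                                                "permeation_prob": 0.0}})
    mats = resolve_materials(cfg)
    rng = np.random.default_rng(7)
    n, hits = 1000, 0
    for _ in range(n):
        lat = base.copy()
        step(lat, mats, cfg, rng)
        hits += int(lat.comp[1, 1] == ELEC)
    se = np.sqrt(0.3 * 0.7 / n)
    assert abs(hits / n - 0.3) <= 3 * se


def test_conservation_and_allowed_transitions(small_run):
    """Cell count conserved each step; components only relabel along allowed edges."""
    size = small_run.snapshots[0][1].size
    for region, counts in small_run.trace.counts.items():
        if region == "overall":
            assert (counts.sum(axis=1) == size).all()
    for (_, a), (_, b) in zip(small_run.snapshots, small_run.snapshots[1:]):
        changed = a != b
        pairs = set(zip(a[changed].ravel().tolist(), b[changed].ravel().tolist()))
        assert pairs <= ALLOWED


def test_mg_needs_electrolyte_exposure(small_run):
    """Mg converts only next to electrolyte or product, never while fully buried."""
    for (_, a), (_, b) in zip(small_run.snapshots, small_run.snapshots[1:]):
        converted = (a == MG) & (b == PRODUCT)
        if not converted.any():
            continue
        reachable = (a == ELEC) | (a == PRODUCT)
        adj = np.zeros_like(reachable)
        adj[1:, :] |= reachable[:-1, :]
        adj[:-1, :] |= reachable[1:, :]
        adj[:, 1:] |= reachable[:, :-1]
        adj[:, :-1] |= reachable[:, 1:]
        assert (adj[converted]).all()


def test_walker_inside_solid_aborts():
    lat = tiny_lattice([[ELEC, ELEC], [MG, MG]])
    lat.species["H2O"][1, 0] = 1  # corrupt: walker in metal
    cfg = toy_cfg()
    with pytest.raises(RuntimeError, match="corruption"):
        step(lat, resolve_materials(cfg), cfg, np.random.default_rng(0))


def test_zero_steps_gives_initial_trace_only():
    cfg = scenarios.make_scenario("PDLLA-deformed", steps=0, seed=3)
    res = run(cfg)
    assert res.trace.n_steps == 0
    assert res.trace.fraction("MG")[0] == 0.0


def test_same_seed_runs_are_bit_identical():
    cfg1 = scenarios.make_scenario("PDLLA-deformed", steps=120, seed=11)
    cfg2 = scenarios.make_scenario("PDLLA-deformed", steps=120, seed=11)
    r1, r2 = run(cfg1), run(cfg2)
    for region in r1.trace.counts:
        assert np.array_equal(r1.trace.counts[region], r2.trace.counts[region])
    assert np.array_equal(r1.lattice.comp, r2.lattice.comp)
    for sp in SPECIES:
        assert np.array_equal(r1.lattice.species[sp], r2.lattice.species[sp])


def test_reservoir_replenished_to_nominal_concentration():
    cfg = scenarios.make_scenario("bare", steps=1, seed=0)
    res = run(cfg)
    lat = res.lattice
    assert (lat.species["H2O"][lat.reservoir] == 2).all()
    assert (lat.species["CL"][lat.reservoir] == 1).all()
    frac = lat.species["H"][lat.reservoir].mean()
    assert 0.1 < frac < 0.3  # Bernoulli(0.2) replenishment
    assert set(np.unique(lat.species["H"][lat.reservoir])) <= {0, 1}


def test_moore_neighborhood_runs_and_conserves():
    cfg = scenarios.make_scenario("F-only", steps=30, seed=2)
    cfg.neighborhood = "Moore"
    res = run(cfg)
    counts = res.trace.counts["overall"]
    assert (counts.sum(axis=1) == counts[0].sum()).all()


def test_invalid_config_rejected():
    cfg = scenarios.make_scenario("bare")
    cfg.neighborhood = "hex"
    with pytest.raises(ValueError, match="neighborhood"):
        run(cfg)


# ---------------------------------------------------------------------------
# exhaustive one-step enumeration oracle on a 3x3 lattice with two walkers

ORACLE_GRID = [
    [MGF2, ELEC, PRODUCT],
    [ELEC, ELEC, MG],
    [MG,   MG,   MGO],
]
ORACLE_WALKERS = [("H2O", (0, 1)), ("CL", (1, 1))]
ORACLE_PROBS = {"MGF2": 0.3, "MGO": 0.2, "MG": 0.25, "PRODUCT": 0.4}
ORACLE_SHIELD = 0.5
NBRS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _enumerate_outcomes():
    """Exact one-step distribution over component grids, derived independently.

    Walkers pick one of four directions uniformly; moves succeed only into
    electrolyte.  Reactions fire independently per cell on the post-move
    state, following the documented rules (including shielded Mg attack
    through a water-touched product blob).
    """
    comp = np.array(ORACLE_GRID, dtype=np.uint8)
    shape = comp.shape

    def in_grid(r, c):
        return 0 <= r < shape[0] and 0 <= c < shape[1]

    def neighbors(r, c):
        return [(r + dr, c + dc) for dr, dc in NBRS if in_grid(r + dr, c + dc)]

    dist: dict[bytes, float] = {}
    walker_moves = []
    for _, (r, c) in ORACLE_WALKERS:
        dests = []
        for dr, dc in NBRS:
            rr, cc = r + dr, c + dc
            dest = (rr, cc) if in_grid(rr, cc) and comp[rr, cc] == ELEC else (r, c)
            dests.append(dest)
        walker_moves.append(dests)

    for choice in itertools.product(range(4), repeat=len(ORACLE_WALKERS)):
        branch_p = 0.25 ** len(ORACLE_WALKERS)
        pos = {sp: [] for sp in ("H2O", "CL", "H")}
        for (sp, _), dests, k in zip(ORACLE_WALKERS, walker_moves, choice):
            pos[sp].append(dests[k])

        wet = set(pos["H2O"])  # water-bearing electrolyte cells
        cl_cells = set(pos["CL"])

        # product blobs touched by wet electrolyte
        prod_cells = [(r, c) for r in range(shape[0]) for c in range(shape[1])
                      if comp[r, c] == PRODUCT]
        wet_products = set()
        frontier = [p for p in prod_cells if any(n in wet for n in neighbors(*p))]
        while frontier:
            p = frontier.pop()
            if p in wet_products:
                continue
            wet_products.add(p)
            frontier += [n for n in neighbors(*p)
                         if comp[n] == PRODUCT and n not in wet_products]

        events = []  # (cell, prob, new_state)
        for r in range(shape[0]):
            for c in range(shape[1]):
                cell, nbrs = comp[r, c], neighbors(r, c)
                wet_adj = any(n in wet for n in nbrs)
                if cell in (MGF2, MGO) and wet_adj:
                    name = "MGF2" if cell == MGF2 else "MGO"
                    events.append(((r, c), ORACLE_PROBS[name], ELEC))
                elif cell == MG:
                    if wet_adj:
                        events.append(((r, c), ORACLE_PROBS["MG"], PRODUCT))
                    elif any(n in wet_products for n in nbrs):
                        events.append(((r, c), ORACLE_PROBS["MG"] * ORACLE_SHIELD, PRODUCT))
                elif cell == PRODUCT and any(n in cl_cells for n in nbrs):
                    events.append(((r, c), ORACLE_PROBS["PRODUCT"], ELEC))

        for fire in itertools.product((False, True), repeat=len(events)):
            p = branch_p
            out = comp.copy()
            for (cell, q, new), f in zip(events, fire):
                p *= q if f else (1 - q)
                if f:
                    out[cell] = new
            if p > 0:
                dist[out.tobytes()] = dist.get(out.tobytes(), 0.0) + p
    return dist


def test_one_step_distribution_matches_enumeration_oracle():
    """10^4 simulated steps agree with exhaustive enumeration within 3 SE."""
    exact = _enumerate_outcomes()
    assert abs(sum(exact.values()) - 1.0) < 1e-12

    cfg = toy_cfg(
        shielding_factor=ORACLE_SHIELD,
        material_overrides={
            name: {"dissolution_prob": p, "acid_boost": 1.0}
            for name, p in ORACLE_PROBS.items()
        },
    )
    mats = resolve_materials(cfg)
    base = tiny_lattice(ORACLE_GRID, walkers=ORACLE_WALKERS)
    rng = np.random.default_rng(2024)
    n = 10_000
    freq: dict[bytes, int] = {}
    for _ in range(n):
        lat = base.copy()
        step(lat, mats, cfg, rng)
        key = lat.comp.tobytes()
        freq[key] = freq.get(key, 0) + 1

    assert set(freq) <= set(exact)  # no outcome outside the exact support
    for key, p in exact.items():
        if p < 0.002:
            continue
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq.get(key, 0) / n - p) <= 3 * se + 1e-9, (
            f"outcome p={p:.4f} freq={freq.get(key, 0) / n:.4f}")
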