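"""Discrete layered strut lattice.

The strut is one sine-wave arc of the stent, unrolled into a rectangular strip:
columns run along the arclength (apex at s = 0.5), rows through the thickness.
Both faces carry the same conversion-film/coating stack by default
(ELEC reservoir | POLY | MgF2 | MgO | Mg core | MgO | MgF2 | POLY | reservoir),
matching an HF-treated, dip-coated strut immersed in electrolyte on both sides.

The primary lattice is 2D; :func:`extrude` produces a thin 3D version (same
rules, 6-neighbor) used for voxel cloud renders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ELEC", "POLY", "MGF2", "MGO", "MG", "PRODUCT",
    "COMPONENTS", "COMPONENT_IDS", "SPECIES",
    "LayerSpec", "Lattice", "build_lattice", "component_counts", "extrude",
]

# component codes (uint8 grid values)
ELEC, POLY, MGF2, MGO, MG, PRODUCT = 0, 1, 2, 3, 4, 5
COMPONENTS = ("ELEC", "POLY", "MGF2", "MGO", "MG", "PRODUCT")
COMPONENT_IDS = {n: i for i, n in enumerate(COMPONENTS)}
SPECIES = ("H2O", "CL", "H")

OUTER, INNER = 1, -1  # side tags: rows nearer the row-0 reservoir are "outer"


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the face stack, outermost first.

    ``material`` is a component label ("POLY", "MGF2", "MGO"); ``thickness_um``
    must survive discretization as at least one cell.
    """

    material: str
    thickness_um: float

    def __post_init__(self):
        if self.thickness_um <= 0:
            raise ValueError(f"layer {self.material}: thickness must be > 0 um")
        if self.material not in COMPONENT_IDS:
            raise ValueError(f"unknown layer material {self.material!r}")


@dataclass
class Lattice:
    """Component grid plus mobile-species occupancy.

    ``comp`` is uint8 (rows x cols [x depth]); ``species`` maps each walker
    species to a same-shaped non-negative int array.  ``arc_coord`` gives each
    column its normalized arclength s in [0, 1]; ``side`` tags every cell
    outer (+1) or inner (-1) relative to the strut mid-plane; ``reservoir`` is
    the boolean mask of bulk-electrolyte cells replenished every step.
    """

    comp: np.ndarray
    species: dict[str, np.ndarray]
    cell_size_um: float
    arc_coord: np.ndarray
    side: np.ndarray
    reservoir: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.comp.shape

    @property
    def ncols(self) -> int:
        return self.comp.shape[1]

    def copy(self) -> "Lattice":
        return Lattice(
            comp=self.comp.copy(),
            species={k: v.copy() for k, v in self.species.items()},
            cell_size_um=self.cell_size_um,
            arc_coord=self.arc_coord.copy(),
            side=self.side.copy(),
            reservoir=self.reservoir.copy(),
        )


DEFAULT_LAYERS = (
    LayerSpec("POLY", 4.0),   # ~4 um dip coating
    LayerSpec("MGF2", 1.0),   # HF conversion film
    LayerSpec("MGO", 0.5),    # native oxide
)
DEFAULT_STRUT_UM = 30.0
DEFAULT_CELL_UM = 0.5
DEFAULT_ARC_CELLS = 600
DEFAULT_RESERVOIR_ROWS = 6


def _layer_cells(layers, cell_size_um):
    counts = []
    for sp in layers:
        n = int(round(sp.thickness_um / cell_size_um))
        if n < 1:
            raise ValueError(
                f"layer {sp.material} ({sp.thickness_um} um) thinner than one "
                f"cell at cell_size {cell_size_um} um; use a finer grid"
            )
        counts.append(n)
    return counts


def build_lattice(
    layers=DEFAULT_LAYERS,
    strut_thickness_um: float = DEFAULT_STRUT_UM,
    arc_length_cells: int = DEFAULT_ARC_CELLS,
    cell_size_um: float = DEFAULT_CELL_UM,
    reservoir_rows: int = DEFAULT_RESERVOIR_ROWS,
    inner_layers=None,
) -> Lattice:
    """Build the fresh (undamaged, walker-free except reservoir) 2D lattice.

    ``layers`` is the outer-face stack, outermost first; the inner face uses
    the same stack unless ``inner_layers`` is given.  Species counts start at
    zero everywhere; the engine fills the reservoir on its first step.
    """
    if arc_length_cells < 10:
        raise ValueError("arc_length_cells must be >= 10")
    layers = tuple(layers)
    inner = tuple(inner_layers) if inner_layers is not None else layers
    core = int(round(strut_thickness_um / cell_size_um))
    if core < 1:
        raise ValueError("strut thinner than one cell")

    out_counts = _layer_cells(layers, cell_size_um)
    in_counts = _layer_cells(inner, cell_size_um)

    rows: list[tuple[int, int]] = [(ELEC, reservoir_rows)]
    rows += [(COMPONENT_IDS[sp.material], n) for sp, n in zip(layers, out_counts)]
    rows.append((MG, core))
    rows += [(COMPONENT_IDS[sp.material], n) for sp, n in zip(reversed(inner), reversed(in_counts))]
    rows.append((ELEC, reservoir_rows))

    nrows = sum(n for _, n in rows)
    comp = np.empty((nrows, arc_length_cells), dtype=np.uint8)
    reservoir = np.zeros((nrows, arc_length_cells), dtype=bool)
    r = 0
    for code, n in rows:
        comp[r:r + n] = code
        r += n
    if reservoir_rows:
        reservoir[:reservoir_rows] = True
        reservoir[-reservoir_rows:] = True

    # mid-plane of the Mg core separates outer from inner
    core_start = reservoir_rows + sum(out_counts)
    mid = core_start + core / 2.0
    side = np.where(np.arange(nrows)[:, None] < mid, OUTER, INNER).astype(np.int8)
    side = np.broadcast_to(side, comp.shape).copy()

    arc_coord = (np.arange(arc_length_cells) + 0.5) / arc_length_cells
    species = {s: np.zeros_like(comp, dtype=np.int32) for s in SPECIES}
    return Lattice(comp, species, cell_size_um, arc_coord, side, reservoir)


def component_counts(lat: Lattice) -> dict[str, int]:
    """Cell count per component label; values sum to the total cell count."""
    counts = np.bincount(lat.comp.ravel(), minlength=len(COMPONENTS))
    return {name: int(counts[i]) for i, name in enumerate(COMPONENTS)}


def extrude(lat: Lattice, depth: int = 20) -> Lattice:
    """Thin 3D extrusion of a 2D lattice (for voxel cloud renders).

    The CA rules apply unchanged with a 6-cell von Neumann neighborhood.
    """
    if lat.comp.ndim != 2:
        raise ValueError("extrude expects a 2D lattice")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rep = lambda a: np.repeat(a[:, :, None], depth, axis=2)
    return Lattice(
        comp=rep(lat.comp).copy(),
        species={k: rep(v).copy() for k, v in lat.species.items()},
        cell_size_um=lat.cell_size_um,
        arc_coord=lat.arc_coord.copy(),
        side=rep(lat.side).copy(),
        reservoir=rep(lat.reservoir).copy(),
    )
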