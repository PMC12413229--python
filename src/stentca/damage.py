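"""Strain-driven coating damage: porosity and through-cracks.

Deformation damages the polymer coating two ways.  Below the film's elongation
at break, stretching opens sub-resolution pores; the pore fraction follows

    P(ε) = (1 − K^(ε+1)) × 100 %

with K ∈ (0, 1] a material constant (K → 1: damage-immune; smaller K: porous
already at rest and increasingly so with strain — the dependence on ε is
exponential).  Where the local strain exceeds the elongation at break the film
fractures outright; cracks are modeled as through-thickness channels spanning
the whole polymer band of the affected columns, giving the electrolyte direct
access from step 0.  Porosity is realized stochastically per cell; the crack
set is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Lattice, POLY, ELEC, INNER, OUTER
from .materials import MaterialProps
from .mechanics import StrainField

__all__ = ["DamageMap", "porosity", "apply_damage", "porosity_profile"]


def porosity(eps, K: float):
    """Pore percentage P(ε, K) = (1 − K^(ε+1)) × 100, clipped to [0, 100).

    ``eps`` is |strain| (fraction, ≥ 0; scalar or array); K ∈ (0, 1].
    Monotone non-decreasing in ε; identically 0 at K = 1.
    """
    if not (0.0 < K <= 1.0):
        raise ValueError(f"K must be in (0, 1], got {K}")
    eps_arr = np.asarray(eps, dtype=float)
    if np.any(eps_arr < 0):
        raise ValueError("strain must be non-negative (pass |eps|)")
    p = (1.0 - K ** (eps_arr + 1.0)) * 100.0
    p = np.clip(p, 0.0, np.nextafter(100.0, 0.0))
    return float(p) if np.isscalar(eps) or eps_arr.ndim == 0 else p


@dataclass
class DamageMap:
    """Per-column damage realized on the polymer band of each face.

    Arrays are shaped (2, ncols) with row 0 the outer face and row 1 the
    inner face; ``porosity`` in percent, ``cracked`` boolean.
    """

    porosity: np.ndarray
    cracked: np.ndarray
    K_used: float
    eb_used: float
    arc_coord: np.ndarray

    FACES = ("outer", "inner")

    def face_index(self, side: str) -> int:
        return self.FACES.index(side)


def apply_damage(
    lattice: Lattice,
    field: StrainField,
    material: MaterialProps,
    rng_seed,
) -> tuple[Lattice, DamageMap]:
    """Realize deformation damage on a fresh lattice.

    Columns whose effective strain exceeds the coating's elongation at break
    become through-cracks (full polymer band → ELEC); every other polymer cell
    independently becomes a pore with probability P(ε)/100.  Inorganic layers
    are untouched.  Returns a new lattice and the DamageMap record.
    """
    if field.epsilon.shape != lattice.comp.shape:
        raise ValueError("strain field does not match lattice")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    K = material.porosity_K
    eb = material.elongation_at_break
    if eb is None:
        raise ValueError(f"material {material.name} has no elongation_at_break")

    out = lattice.copy()
    ncols = lattice.ncols
    por = np.zeros((2, ncols))
    cracked = np.zeros((2, ncols), dtype=bool)

    for fi, side in enumerate((OUTER, INNER)):
        prof = field.column_profile(lattice, side)          # |eps| per column
        por[fi] = porosity(prof, K)
        cracked[fi] = prof > eb
        band = (lattice.comp == POLY) & (lattice.side == side)
        if lattice.comp.ndim == 2:
            crack_cells = band & cracked[fi][None, :]
            pore_p = (por[fi] / 100.0)[None, :]
        else:
            crack_cells = band & cracked[fi][None, :, None]
            pore_p = (por[fi] / 100.0)[None, :, None]
        pores = band & ~crack_cells & (rng.random(lattice.comp.shape) < pore_p)
        out.comp[crack_cells | pores] = ELEC

    dm = DamageMap(por, cracked, K_used=K, eb_used=eb, arc_coord=lattice.arc_coord.copy())
    return out, dm


def porosity_profile(dm: DamageMap, side: str = "inner") -> np.ndarray:
    """Porosity percent along the arc for one face (inner = arc interior)."""
    return dm.porosity[dm.face_index(side)].copy()


def damage_table(dm: DamageMap, side: str = "inner") -> pd.DataFrame:
    """Tabular export (arc position, porosity %, cracked flag) for one face."""
    fi = dm.face_index(side)
    return pd.DataFrame({
        "arc_coord": dm.arc_coord,
        "porosity_pct": dm.porosity[fi],
        "cracked": dm.cracked[fi].astype(int),
    })
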