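"""Packaged scenario presets and deterministic toy lattices for testing.

The four principal presets mirror the simulated study conditions: PDLLA- and
PBAT-coated strut models after crimp-expansion deformation, plus undeformed
variants of each (extensions supporting the qualitative claim that deformation
degrades coating protection; the deformed pair is the quantitative surface).
"bare" and "F-only" reproduce the uncoated substrate and the HF-converted
substrate without polymer.
"""

from __future__ import annotations

import numpy as np

from .engine import SimConfig, LatticeConfig, StrainConfig
from .geometry import (
    Lattice, build_lattice, LayerSpec, ELEC, POLY, MGF2, MGO, MG, SPECIES,
)

__all__ = ["SCENARIOS", "make_scenario", "make_toy_lattice"]

_COATED_LAYERS = [["POLY", 4.0], ["MGF2", 1.0], ["MGO", 0.5]]
_F_ONLY_LAYERS = [["MGF2", 1.0], ["MGO", 0.5]]
_BARE_LAYERS: list = []

SCENARIOS = (
    "PDLLA-deformed", "PBAT-deformed",
    "PDLLA-undeformed", "PBAT-undeformed",
    "bare", "F-only",
)


def make_scenario(name: str, steps: int = 4000, seed: int = 0) -> SimConfig:
    """Complete validated SimConfig for a named preset."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; available: {', '.join(SCENARIOS)}")
    polymer = name.split("-")[0] if name.startswith(("PDLLA", "PBAT")) else None
    deformed = name.endswith("-deformed")
    if polymer is not None:
        layers = _COATED_LAYERS
    elif name == "F-only":
        layers = _F_ONLY_LAYERS
    else:
        layers = _BARE_LAYERS
    return SimConfig(
        scenario=name,
        steps=steps,
        seed=seed,
        polymer=polymer,
        lattice=LatticeConfig(layers=[list(l) for l in layers]),
        strain=StrainConfig(deformed=deformed),
    )


_TOY_PATTERNS = ("single-interface", "checkerboard", "crack-channel")


def make_toy_lattice(rows: int, cols: int, pattern: str = "single-interface") -> Lattice:
    """Small deterministic lattices for unit and oracle tests.

    "single-interface": one reservoir row on top, Mg below.
    "checkerboard": alternating ELEC / MG (no reservoir).
    "crack-channel": reservoir | polymer band with one ELEC column | MgF2 | Mg.
    """
    if rows < 2 or cols < 2:
        raise ValueError("toy lattices need rows, cols >= 2")
    comp = np.full((rows, cols), MG, dtype=np.uint8)
    reservoir = np.zeros((rows, cols), dtype=bool)
    if pattern == "single-interface":
        comp[0] = ELEC
        reservoir[0] = True
    elif pattern == "checkerboard":
        idx = np.add.outer(np.arange(rows), np.arange(cols)) % 2
        comp[idx == 0] = ELEC
    elif pattern == "crack-channel":
        comp[0] = ELEC
        reservoir[0] = True
        poly_rows = slice(1, max(2, rows // 2))
        comp[poly_rows] = POLY
        comp[poly_rows, cols // 2] = ELEC  # the crack
        if rows >= 4:
            comp[max(2, rows // 2)] = MGF2
    else:
        raise ValueError(f"unknown pattern {pattern!r}; have {_TOY_PATTERNS}")
    side = np.where(np.arange(rows)[:, None] < rows / 2, 1, -1).astype(np.int8)
    side = np.broadcast_to(side, comp.shape).copy()
    return Lattice(
        comp=comp,
        species={s: np.zeros_like(comp, dtype=np.int32) for s in SPECIES},
        cell_size_um=0.5,
        arc_coord=(np.arange(cols) + 0.5) / cols,
        side=side,
        reservoir=reservoir,
    )
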