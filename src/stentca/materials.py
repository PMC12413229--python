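"""Material constants for the coated-strut corrosion model.

Two biodegradable polyester coatings are compared throughout: PDLLA, a stiff
low-elongation polymer that cracks under stent crimp-expansion, and PBAT, a
flexible copolyester whose elongation at break (~533 %) far exceeds any strain
the strut sees.  Beneath the polymer sit an HF-conversion MgF2 film, the native
MgO film, and the AZ31B magnesium substrate; corrosion of Mg deposits a
partially passivating Mg(OH)2 product that chloride slowly dissolves.

Mechanical constants (tensile strength, elongation at break) are measured film
properties.  The per-step reaction and permeation probabilities and the
porosity constants K are free parameters of the cellular automaton; the values
packaged here were fixed once by the calibration procedure in
:mod:`stentca.metrics` against the printed degradation milestones and are not
to be edited casually — every quantitative claim of the model is made against
this frozen table.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field, replace

__all__ = [
    "MaterialProps",
    "default_materials",
    "validate_material",
    "materials_to_dict",
    "materials_from_dict",
]


@dataclass(frozen=True)
class MaterialProps:
    """Constants for one lattice component.

    Strains are dimensionless fractions (0.03 = 3 %).  All ``*_prob`` fields
    are per-step probabilities of the cellular automaton.  ``porosity_K`` is
    the proportionality constant K of the strain→porosity law
    P = (1 − K^(ε+1)) × 100 %; smaller K means a more damage-prone coating.
    ``acid_boost`` multiplies the dissolution probability when an H+ walker is
    adjacent; ``tensile_strength`` (MPa) is informational for polymers.
    """

    name: str
    tensile_strength: float | None = None
    elongation_at_break: float | None = None
    porosity_K: float = 1.0
    hydrolysis_prob: float = 0.0
    permeation_prob: float = 0.0
    dissolution_prob: float = 0.0
    acid_boost: float = 1.0

    def replace(self, **kw) -> "MaterialProps":
        return replace(self, **kw)


_NAMES = ("PDLLA", "PBAT", "MGF2", "MGO", "MG", "PRODUCT")


def default_materials() -> dict[str, MaterialProps]:
    """Packaged default material table.

    Mechanical constants are the measured film means (PDLLA 12.33 MPa / 3 %
    elongation; PBAT 14.49 MPa / 533 %).  Probabilities and K values are the
    frozen calibration output; see docs/methods.md for the anchors they were
    fitted to.  Mg(OH)2 PRODUCT dissolves only under chloride attack, so its
    plain-water ``dissolution_prob`` is the chloride-attack probability used by
    the engine's product rule.
    """
    return {
        "PDLLA": MaterialProps(
            name="PDLLA",
            tensile_strength=12.33,
            elongation_at_break=0.03,
            porosity_K=0.85,
            hydrolysis_prob=1.2e-4,
            permeation_prob=0.02,
        ),
        "PBAT": MaterialProps(
            name="PBAT",
            tensile_strength=14.49,
            elongation_at_break=5.33,
            porosity_K=0.99,
            hydrolysis_prob=6.0e-5,
            permeation_prob=0.005,
        ),
        "MGF2": MaterialProps(name="MGF2", dissolution_prob=1.5e-4, acid_boost=24.0),
        "MGO": MaterialProps(name="MGO", dissolution_prob=3.0e-3, acid_boost=4.0),
        "MG": MaterialProps(name="MG", dissolution_prob=8.0e-3, acid_boost=2.0),
        "PRODUCT": MaterialProps(name="PRODUCT", dissolution_prob=2.0e-2),
    }


def validate_material(m: MaterialProps) -> list[str]:
    """Return one human-readable violation per broken invariant (never raises)."""
    v: list[str] = []
    for f in ("hydrolysis_prob", "permeation_prob", "dissolution_prob"):
        p = getattr(m, f)
        if not (0.0 <= p <= 1.0):
            v.append(f"{m.name}.{f} must be in [0, 1], got {p}")
    if not (0.0 < m.porosity_K <= 1.0):
        v.append(f"{m.name}.porosity_K must be in (0, 1], got {m.porosity_K}")
    if m.acid_boost < 1.0:
        v.append(f"{m.name}.acid_boost must be >= 1, got {m.acid_boost}")
    if m.elongation_at_break is not None and m.elongation_at_break <= 0:
        v.append(f"{m.name}.elongation_at_break must be > 0, got {m.elongation_at_break}")
    return v


def materials_to_dict(table: dict[str, MaterialProps]) -> dict:
    """Serializable form of a material table (plain nested dicts)."""
    return {k: asdict(m) for k, m in table.items()}


def materials_from_dict(d: dict) -> dict[str, MaterialProps]:
    """Inverse of :func:`materials_to_dict`; field-for-field round trip."""
    return {k: MaterialProps(**v) for k, v in d.items()}
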