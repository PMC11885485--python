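"""Optical constants for phantom materials.

The complex X-ray refractive index is written n = 1 - delta + i*beta; for
soft tissue at hard X-ray energies the phase decrement delta exceeds the
absorption index beta by one to three orders of magnitude, which is the
whole point of phase-contrast imaging.  Away from absorption edges delta
scales as 1/E^2; each material here stores delta at a reference energy and
a fixed delta/beta ratio, so the ratio of every voxel of a given material
is exact by construction.

Named ratio presets (27, 15, 45) mirror the homogeneous-object beta/delta
values commonly used in single-material CTF retrieval of unstained,
methanol-embedded and cleared tissue, respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

_REF_ENERGY_KEV = 10.0


@dataclass(frozen=True)
class OpticalConstants:
    material_name: str
    delta: float
    beta: float
    energy_keV: float

    def __post_init__(self):
        if self.delta < 0 or self.beta < 0:
            raise ValueError("delta and beta must be non-negative")

    @property
    def delta_over_beta(self) -> float:
        return self.delta / self.beta if self.beta > 0 else float("inf")


# (delta at 10 keV, delta/beta ratio); delta ~ 1e-6 is the soft-tissue scale.
_MATERIAL_DB: dict[str, dict[str, tuple[float, float]]] = {
    # One shared delta/beta ratio per preparation: the single-material
    # (homogeneous-object) assumption of the retrieval filters then holds
    # exactly for the contrast against the embedding medium, with the ratio
    # matching the CTF beta/delta preset used for that preparation.
    "unstained-in-methanol": {
        "background": (8.0e-7, 15.0),    # methanol embedding
        "tissue": (1.0e-6, 15.0),
        "membrane": (1.15e-6, 15.0),
        "bone": (1.25e-6, 15.0),         # decalcified: collagen matrix only
        "blob": (1.35e-6, 15.0),         # SGN soma, dense nucleus
    },
    "osmium-in-resin": {
        "background": (1.2e-6, 27.0),    # epoxy resin
        "tissue": (1.5e-6, 27.0),
        "membrane": (1.7e-6, 27.0),
        "bone": (2.0e-6, 27.0),
        "blob": (2.4e-6, 27.0),          # heavy-metal stained nervous tissue
    },
    "cleared-in-DBE": {
        "background": (1.0e-6, 45.0),    # dibenzyl ether, index-matched
        "tissue": (1.1e-6, 45.0),
        "membrane": (1.2e-6, 45.0),
        "bone": (1.3e-6, 45.0),          # decalcified and cleared
        "blob": (1.4e-6, 45.0),
    },
    # homogeneous-object ratio presets: a single tissue material embedded in
    # vacuum, with the given delta/beta ratio.
    "ctf_1_27": {"tissue": (1.0e-6, 27.0)},
    "ctf_1_15": {"tissue": (1.0e-6, 15.0)},
    "ctf_1_45": {"tissue": (1.0e-6, 45.0)},
}


def material_table(preset_name: str, energy_keV: float = _REF_ENERGY_KEV) -> list[OpticalConstants]:
    """Optical constants of all materials of a named preset at one energy.

    delta is rescaled from the 10 keV tabulation by (10/E)^2; beta follows
    from the material's fixed delta/beta ratio.  The "vacuum" preset returns
    a single all-zero entry.
    """
    if energy_keV <= 0:
        raise ValueError("energy must be positive")
    if preset_name == "vacuum":
        return [OpticalConstants("vacuum", 0.0, 0.0, energy_keV)]
    try:
        entries = _MATERIAL_DB[preset_name]
    except KeyError:
        raise KeyError(
            f"unknown material preset {preset_name!r}; "
            f"available: {sorted(_MATERIAL_DB) + ['vacuum']}"
        ) from None
    scale = (_REF_ENERGY_KEV / energy_keV) ** 2
    out = []
    for name, (delta_ref, ratio) in entries.items():
        delta = delta_ref * scale
        out.append(OpticalConstants(name, delta, delta / ratio, energy_keV))
    return out


def material_dict(preset_name: str, energy_keV: float = _REF_ENERGY_KEV) -> dict[str, OpticalConstants]:
    return {m.material_name: m for m in material_table(preset_name, energy_keV)}
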