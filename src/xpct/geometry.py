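"""Acquisition geometry for propagation-based phase-contrast imaging.

All quantities derive from five independent inputs: photon energy, physical
detector pixel pitch, binning, source-to-sample distance ``z01`` and
source-to-detector distance ``z02``.  For a divergent (cone) beam the
geometric magnification is ``M = z02/z01``; the detector pixel then samples
the object at an effective pitch ``dx_eff = dx·binning/M`` and free-space
propagation acts over the effective distance ``z_eff = z12/M`` (Fresnel
scaling theorem).  The dimensionless Fresnel number

    F = dx_eff**2 / (z_eff * wavelength)

classifies the imaging regime: F << 1 holographic, F ~ 1 direct contrast
(edge enhancement), F >> 1 plain absorption.

Distances are stored in metres internally; the preset table accepts
millimetres, matching how instrument geometries are usually reported.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from enum import Enum

import yaml

#: hc in keV·Å; fixed so that E[keV]·λ[Å] = 12.3984.
HC_KEV_ANGSTROM = 12.3984

_REL_TOL = 1e-12


class BeamType(str, Enum):
    parallel = "parallel"
    cone = "cone"


class ImagingRegime(str, Enum):
    holographic = "holographic"
    direct_contrast = "direct_contrast"
    absorption = "absorption"


class GeometryError(ValueError):
    """Inconsistent or unphysical acquisition geometry."""


def wavelength_from_energy(energy_keV: float) -> float:
    """Photon wavelength in metres for an energy in keV."""
    if not energy_keV > 0:
        raise ValueError(f"energy must be positive, got {energy_keV}")
    return HC_KEV_ANGSTROM / energy_keV * 1e-10


def energy_from_wavelength(wavelength_m: float) -> float:
    """Inverse of :func:`wavelength_from_energy`."""
    if not wavelength_m > 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_m}")
    return HC_KEV_ANGSTROM / (wavelength_m * 1e10)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """One scan configuration with all derived optical quantities.

    Use :func:`build_geometry` to construct instances; the constructor does
    not re-derive fields.
    """

    energy_keV: float
    wavelength_m: float
    dx_m: float
    binning: int
    z01_m: float
    z12_m: float
    z02_m: float
    magnification: float
    dx_eff_m: float
    z_eff_m: float
    fresnel_number: float
    beam_type: BeamType

    def validate(self) -> "AcquisitionGeometry":
        """Check the type invariants; return self for chaining."""
        def _close(a, b):
            return abs(a - b) <= _REL_TOL * max(abs(a), abs(b))

        if not _close(self.z02_m, self.z01_m + self.z12_m):
            raise GeometryError("z02 != z01 + z12")
        if self.beam_type is BeamType.cone:
            if not _close(self.magnification, self.z02_m / self.z01_m):
                raise GeometryError("cone magnification != z02/z01")
        elif self.magnification != 1.0:
            raise GeometryError("parallel beam requires M = 1")
        if not _close(self.dx_eff_m, self.dx_m * self.binning / self.magnification):
            raise GeometryError("dx_eff != dx*binning/M")
        if not _close(self.z_eff_m, self.z12_m / self.magnification):
            raise GeometryError("z_eff != z12/M")
        expect_f = self.dx_eff_m**2 / (self.z_eff_m * self.wavelength_m)
        if not (self.fresnel_number > 0 and _close(self.fresnel_number, expect_f)):
            raise GeometryError("Fresnel number inconsistent with geometry")
        return self

    def with_distance(self, z12_m: float) -> "AcquisitionGeometry":
        """Same optics at a different propagation distance (defocus series)."""
        return build_geometry(
            self.energy_keV, self.dx_m, self.binning,
            self.z01_m, self.z01_m + z12_m, self.beam_type,
        )


def build_geometry(
    energy_keV: float,
    dx_m: float,
    binning: int,
    z01_m: float,
    z02_m: float,
    beam_type: BeamType | str = BeamType.cone,
) -> AcquisitionGeometry:
    """Derive a full :class:`AcquisitionGeometry` from the independent inputs.

    For a parallel beam ``z01`` enters only through ``z12 = z02 - z01``; the
    magnification is identically 1.
    """
    beam_type = BeamType(beam_type)
    if binning < 1 or int(binning) != binning:
        raise ValueError(f"binning must be a positive integer, got {binning}")
    if not (dx_m > 0 and z01_m > 0 and z02_m > 0):
        raise ValueError("pixel size and distances must be positive")
    if z02_m <= z01_m:
        raise GeometryError(f"z02 ({z02_m}) must exceed z01 ({z01_m})")
    wavelength_m = wavelength_from_energy(energy_keV)
    z12_m = z02_m - z01_m
    if beam_type is BeamType.cone:
        magnification = z02_m / z01_m
    else:
        magnification = 1.0
    dx_eff_m = dx_m * binning / magnification
    z_eff_m = z12_m / magnification
    geom = AcquisitionGeometry(
        energy_keV=energy_keV,
        wavelength_m=wavelength_m,
        dx_m=dx_m,
        binning=int(binning),
        z01_m=z01_m,
        z12_m=z12_m,
        z02_m=z02_m,
        magnification=magnification,
        dx_eff_m=dx_eff_m,
        z_eff_m=z_eff_m,
        fresnel_number=dx_eff_m**2 / (z_eff_m * wavelength_m),
        beam_type=beam_type,
    )
    return geom.validate()


def fresnel_number(geometry: AcquisitionGeometry) -> float:
    """F = dx_eff² / (z_eff λ) of a validated geometry."""
    geometry.validate()
    return geometry.fresnel_number


def fresnel_number_from(dx_eff_m: float, z_eff_m: float, wavelength_m: float) -> float:
    """F from effective pixel, effective distance and wavelength directly."""
    if not (dx_eff_m > 0 and z_eff_m > 0 and wavelength_m > 0):
        raise ValueError("all arguments must be positive")
    return dx_eff_m**2 / (z_eff_m * wavelength_m)


# Regime thresholds: the field only pins down "F << 1" (holographic) and
# "F ~ 1" (direct contrast); the cut points below are a package convention.
HOLOGRAPHIC_MAX_F = 0.1
DIRECT_CONTRAST_MAX_F = 10.0


def classify_regime(F: float) -> ImagingRegime:
    """Map a Fresnel number onto the qualitative imaging regime."""
    if not F > 0:
        raise ValueError(f"Fresnel number must be positive, got {F}")
    if F < HOLOGRAPHIC_MAX_F:
        return ImagingRegime.holographic
    if F < DIRECT_CONTRAST_MAX_F:
        return ImagingRegime.direct_contrast
    return ImagingRegime.absorption


# ---------------------------------------------------------------------------
# Instrument presets


@dataclass(frozen=True)
class InstrumentPreset:
    """One instrument/scan column of the preset table.

    ``verified`` is False for synchrotron entries whose source distances are
    reported in ambiguous units upstream; for those, ``dx_eff_um``/``fresnel``
    carry the published values directly instead of being derivable from
    z01/z02.
    """

    name: str
    energy_keV: float
    dx_um: float
    binning: int
    beam_type: BeamType
    z01_mm: float | None = None
    z02_mm: float | None = None
    n_distances: int = 1
    phase_method: str | None = None
    beta_over_delta: float | None = None
    dx_eff_um: float | None = None
    fresnel: float | None = None
    verified: bool = True

    def geometry(self) -> AcquisitionGeometry:
        if self.z01_mm is None or self.z02_mm is None:
            raise GeometryError(
                f"preset {self.name!r} has no unambiguous z01/z02; "
                "it stores published dx_eff/F only"
            )
        return build_geometry(
            self.energy_keV, self.dx_um * 1e-6, self.binning,
            self.z01_mm * 1e-3, self.z02_mm * 1e-3, self.beam_type,
        )


def _load_preset_file() -> dict:
    text = (importlib.resources.files("xpct") / "data" / "presets.yaml").read_text()
    return yaml.safe_load(text)


_PRESETS: dict[str, InstrumentPreset] | None = None


def load_presets() -> dict[str, InstrumentPreset]:
    global _PRESETS
    if _PRESETS is None:
        raw = _load_preset_file()
        out = {}
        for name, entry in raw["instruments"].items():
            out[name] = InstrumentPreset(
                name=name,
                energy_keV=entry["energy_keV"],
                dx_um=entry["dx_um"],
                binning=entry.get("binning", 1),
                beam_type=BeamType(entry["beam_type"]),
                z01_mm=entry.get("z01_mm"),
                z02_mm=entry.get("z02_mm"),
                n_distances=entry.get("n_distances", 1),
                phase_method=entry.get("phase_method"),
                beta_over_delta=entry.get("beta_over_delta"),
                dx_eff_um=entry.get("dx_eff_um"),
                fresnel=entry.get("fresnel"),
                verified=entry.get("verified", True),
            )
        _PRESETS = out
    return _PRESETS


def get_preset(name: str) -> InstrumentPreset:
    presets = load_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None


def describe_geometry(preset_or_geom) -> dict:
    """Flat dict of derived quantities (for the CLI ``geometry`` table)."""
    if isinstance(preset_or_geom, str):
        preset_or_geom = get_preset(preset_or_geom)
    if isinstance(preset_or_geom, InstrumentPreset):
        p = preset_or_geom
        if p.z01_mm is None:
            F = p.fresnel
            return {
                "instrument": p.name, "energy_keV": p.energy_keV,
                "magnification": None,
                "dx_eff_um": p.dx_eff_um, "z_eff_mm": None,
                "fresnel_number": F,
                "regime": classify_regime(F).value if F else None,
                "verified": p.verified,
            }
        g = p.geometry()
        name = p.name
        verified = p.verified
    else:
        g = preset_or_geom
        name = "(explicit)"
        verified = True
    return {
        "instrument": name,
        "energy_keV": g.energy_keV,
        "magnification": g.magnification,
        "dx_eff_um": g.dx_eff_m * 1e6,
        "z_eff_mm": g.z_eff_m * 1e3,
        "fresnel_number": g.fresnel_number,
        "regime": classify_regime(g.fresnel_number).value,
        "verified": verified,
    }
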