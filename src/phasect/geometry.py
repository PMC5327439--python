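"""Acquisition geometry for point-source phase-contrast CT.

A point (microfocus) source at distance ``z1`` from the sample and a detector
at distance ``z2`` behind it produce a magnified image with geometrical
magnification ``M = (z1+z2)/z1``.  The standard Fresnel-scaling equivalence
maps this cone-beam configuration onto a parallel-beam one sampled at the
*effective pixel* ``detector_pixel/M`` and propagated over the *effective
distance* ``z_eff = z1*z2/(z1+z2)``.  Two practical operating points exist:

* ``cone``    — z1 small, z2 large: high magnification, large field of view
  trade-off, strong penumbra blur from the finite source spot.
* ``inverse`` — z1 >> z2: magnification near 1, penumbra blur
  ``source_fwhm * z2/z1`` shrinks with z2, resolution limited by the
  detector.  This is the high-resolution mode for region-of-interest scans.

All distances are kept in consistent micrometre units internally; ``z1``/``z2``
are given in millimetres as is customary on an optical bench.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: hc in keV * nm; lambda[nm] = HC_KEV_NM / E[keV]
HC_KEV_NM = 1.23984193

MODES = ("parallel", "cone", "inverse")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Source/sample/detector layout of a tomographic scan.

    Parameters
    ----------
    mode:
        ``"parallel"``, ``"cone"`` or ``"inverse"``.  ``parallel`` forces
        M = 1 and uses ``z2`` as the propagation distance; ``inverse``
        additionally requires ``z1 > z2``.
    z1, z2:
        Source-to-sample and sample-to-detector distance in mm.
    energy:
        Effective photon energy in keV (default 9.25, the Ga-Kalpha line of a
        liquid-metal jet anode).
    detector_pixel:
        Detector pixel pitch in um.
    source_fwhm:
        Source spot FWHM in um (drives penumbra blur).
    """

    mode: str = "inverse"
    z1: float = 1000.0
    z2: float = 100.0
    energy: float = 9.25
    detector_pixel: float = 0.65
    source_fwhm: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown geometry mode {self.mode!r}; choose from {MODES}")
        for name in ("z1", "z2", "energy", "detector_pixel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.source_fwhm < 0:
            raise ValueError("source_fwhm must be >= 0")
        if self.mode == "inverse" and not self.z1 > self.z2:
            raise ValueError("inverse geometry requires z1 > z2")

    # ---- derived quantities -------------------------------------------------

    @property
    def wavelength(self) -> float:
        """Wavelength in um."""
        return HC_KEV_NM / self.energy * 1e-3

    @property
    def wavenumber(self) -> float:
        """k = 2*pi/lambda in 1/um."""
        return 2.0 * math.pi / self.wavelength

    @property
    def magnification(self) -> float:
        if self.mode == "parallel":
            return 1.0
        return (self.z1 + self.z2) / self.z1

    @property
    def z_eff(self) -> float:
        """Effective parallel-beam propagation distance in um."""
        if self.mode == "parallel":
            return self.z2 * 1e3
        return self.z1 * self.z2 / (self.z1 + self.z2) * 1e3

    @property
    def effective_pixel(self) -> float:
        """Detector pixel demagnified to the sample plane, in um."""
        return self.detector_pixel / self.magnification

    @property
    def penumbra_fwhm(self) -> float:
        """Geometric source blur FWHM at the detector, in um."""
        if self.mode == "parallel":
            return 0.0
        return self.source_fwhm * self.z2 / self.z1

    @property
    def penumbra_fwhm_pixels(self) -> float:
        """Penumbra FWHM in detector pixels."""
        return self.penumbra_fwhm / self.detector_pixel

    def fresnel_zone_width(self) -> float:
        """First Fresnel-zone width sqrt(lambda*z_eff) in um.

        The near-field (edge-enhancement / TIE) regime requires this to stay
        comparable to the effective pixel; once it spans many pixels the
        single-distance retrieval model erodes.
        """
        return math.sqrt(self.wavelength * self.z_eff)

    def half_cone_angle(self, n_pixels: int) -> float:
        """Half opening angle (degrees) for a detector of ``n_pixels`` columns."""
        half_width = 0.5 * n_pixels * self.effective_pixel
        return math.degrees(math.atan2(half_width, self.z1 * 1e3))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "z1": self.z1,
            "z2": self.z2,
            "energy": self.energy,
            "detector_pixel": self.detector_pixel,
            "source_fwhm": self.source_fwhm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(**{k: d[k] for k in ("mode", "z1", "z2", "energy", "detector_pixel", "source_fwhm")})
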