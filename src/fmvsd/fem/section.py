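"""Beam cross-section and material properties.

Units are mm / N / MPa throughout the package: moduli in MPa (N/mm^2),
areas in mm^2, second moments in mm^4, forces in N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class MaterialSection:
    """Material + cross-section bundle for a Timoshenko/Euler-Bernoulli beam.

    Parameters
    ----------
    E : float
        Young's modulus (MPa).
    nu : float
        Poisson ratio.
    A : float
        Cross-section area (mm^2).
    Iy, Iz : float
        Second moments of area about the local y and z axes (mm^4).
    J : float
        Torsion constant (mm^4).
    Asy, Asz : float or None
        Shear areas (mm^2). ``None`` (or ``inf``) disables shear
        deformation, i.e. the Euler-Bernoulli limit (phi = 0).
    """

    E: float
    nu: float
    A: float
    Iy: float
    Iz: float
    J: float
    Asy: float | None = None
    Asz: float | None = None

    def __post_init__(self) -> None:
        for name in ("E", "A", "Iy", "Iz", "J"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"section parameter {name} must be > 0")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (-1, 0.5)")
        for name in ("Asy", "Asz"):
            v = getattr(self, name)
            if v is not None and not v > 0.0:
                raise ValueError(f"shear area {name} must be > 0 or None")

    @property
    def G(self) -> float:
        """Shear modulus G = E / (2 (1 + nu)) (MPa)."""
        return self.E / (2.0 * (1.0 + self.nu))

    def phi(self, l: float) -> tuple[float, float]:
        """Shear deformation parameters (phi_y, phi_z) for element length l.

        phi_y = 12 E Iz / (G Asy l^2), phi_z = 12 E Iy / (G Asz l^2);
        both are 0 when the shear areas are unset (Euler-Bernoulli).
        """
        if l <= 0.0:
            raise ValueError("element length must be > 0")
        phi_y = 0.0
        phi_z = 0.0
        if self.Asy is not None and math.isfinite(self.Asy):
            phi_y = 12.0 * self.E * self.Iz / (self.G * self.Asy * l * l)
        if self.Asz is not None and math.isfinite(self.Asz):
            phi_z = 12.0 * self.E * self.Iy / (self.G * self.Asz * l * l)
        return phi_y, phi_z

    @classmethod
    def circular(
        cls,
        E: float,
        nu: float,
        diameter: float,
        shear_factor: float | None = 0.9,
    ) -> "MaterialSection":
        """Solid circular section of the given diameter (mm).

        ``shear_factor`` sets As = shear_factor * A; pass ``None`` for the
        Euler-Bernoulli limit.
        """
        if diameter <= 0.0:
            raise ValueError("diameter must be > 0")
        r = 0.5 * diameter
        A = math.pi * r * r
        I = math.pi * r**4 / 4.0
        As = shear_factor * A if shear_factor is not None else None
        return cls(E=E, nu=nu, A=A, Iy=I, Iz=I, J=2.0 * I, Asy=As, Asz=As)


#: 316L stainless steel defaults used for stent struts.
STEEL_316L = dict(E=193000.0, nu=0.30)
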