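"""Physical constants and experimental conditions.

Temperatures default to 295 K, the midpoint of the 21-24 degC range at which
patch-clamp recordings of Kir2.1 are typically made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.constants import R as _R, physical_constants as _pc

FARADAY: float = _pc["Faraday constant"][0]  # C/mol
GAS_CONSTANT: float = _R  # J/(mol K)
ELEMENTARY_CHARGE: float = _pc["elementary charge"][0]  # C


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants used throughout the permeation model.

    Attributes
    ----------
    F : Faraday constant (C/mol).
    R : gas constant (J/(mol K)).
    T : absolute temperature (K); default 295 K (21-24 degC recordings).
    v_w : molar volume of water (m^3/mol).
    z_ion : valence of the permeant ion (+1 for K+).
    rho_w : water density (kg/L) used to convert osmolality (Osm/kg) into
        an osmolar concentration; approximately 1 kg/L at room temperature.
    """

    F: float = FARADAY
    R: float = GAS_CONSTANT
    T: float = 295.0
    v_w: float = 1.807e-5
    z_ion: int = 1
    rho_w: float = 1.0

    @property
    def kT_over_e(self) -> float:
        """Thermal voltage RT/F in volts."""
        return self.R * self.T / self.F


@dataclass(frozen=True)
class Condition:
    """A single electro-chemical condition of the membrane.

    Attributes
    ----------
    V_m : membrane potential in volts, intracellular minus extracellular.
    K_in, K_out : intracellular / extracellular K+ concentration (molar).
    delta_osm : osmolality difference Osm_out - Osm_in (Osm/kg); only the
        streaming-potential observables depend on it, the rate constants
        do not.
    """

    V_m: float
    K_in: float
    K_out: float
    delta_osm: float = 0.0

    def __post_init__(self) -> None:
        if self.K_in <= 0 or self.K_out <= 0:
            raise ValueError("K+ concentrations must be positive")

    @classmethod
    def symmetric(cls, V_mV: float, K_mM: float, delta_osm: float = 0.0) -> "Condition":
        """Symmetric-[K+] condition from mV / mM values."""
        return cls(V_m=V_mV * 1e-3, K_in=K_mM * 1e-3, K_out=K_mM * 1e-3,
                   delta_osm=delta_osm)
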