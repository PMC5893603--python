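"""Unit conventions and conversion constants.

Internal convention throughout the package:

* length    — ångström (Å)
* time      — nanosecond (ns)
* velocity  — metre per second (m/s)
* vorticity — reciprocal nanosecond (1/ns)

Velocities are kept in m/s because that is the scale on which bulk drift
(cm/s–m/s) and thermal noise (hundreds of m/s) are naturally quoted, while
positions stay in Å, the natural length of an atomistic trajectory.  The
constants below are the only place the two unit systems meet.
"""

#: 1 m/s expressed in Å/ns  (1 m/s = 1e10 Å / 1e9 ns).
M_PER_S_TO_ANG_PER_NS: float = 10.0

#: 1 Å/ns expressed in m/s.
ANG_PER_NS_TO_M_PER_S: float = 0.1

#: Velocity gradient (m/s per Å) expressed in 1/ns.
GRAD_M_PER_S_PER_ANG_TO_PER_NS: float = 10.0

#: 1/ns expressed in 1/s.
PER_NS_TO_PER_S: float = 1.0e9

#: Boltzmann constant, J/K.
K_BOLTZMANN: float = 1.380649e-23

#: Atomic mass unit, kg.
ATOMIC_MASS_KG: float = 1.66053906892e-27


def thermal_sigma(temperature_k: float, mass_amu: float) -> float:
    """Per-component Maxwell–Boltzmann velocity standard deviation, m/s.

    sigma = sqrt(kB * T / m): each Cartesian velocity component of a particle
    of mass ``mass_amu`` in equilibrium at ``temperature_k`` is Gaussian with
    this standard deviation.
    """
    if temperature_k < 0:
        raise ValueError("temperature must be non-negative")
    if mass_amu <= 0:
        raise ValueError("mass must be positive")
    return (K_BOLTZMANN * temperature_k / (mass_amu * ATOMIC_MASS_KG)) ** 0.5


#: Default thermal noise scale: water (18 amu) at 310 K, ≈ 378 m/s per component.
WATER_SIGMA_310K: float = thermal_sigma(310.0, 18.015)
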