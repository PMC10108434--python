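"""Physical constants shared across the package.

Energies are kilojoules per mole throughout; temperatures are kelvin;
correlation times are seconds.  NMR constants follow the usual
heteronuclear-relaxation conventions for a backbone amide N-H spin pair.
"""

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Gas constant, kJ mol^-1 K^-1 (energies in this package are kJ/mol).
R_KJ = R_GAS / 1000.0

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 2.675e8

#: Nitrogen-15 gyromagnetic ratio, rad s^-1 T^-1 (negative).
GAMMA_N = -2.713e7

#: Vacuum permeability over 4*pi, T^2 J^-1 m^3.
MU0_OVER_4PI = 1e-7

#: Reduced Planck constant, J s.
HBAR = 1.054571817e-34

#: Default amide N-H bond length, m.
R_NH = 1.02e-10

#: Default 15N chemical shift anisotropy (unitless; -160 ppm).
CSA_N = -160e-6


def rt_kj(temperature: float) -> float:
    """R*T in kJ/mol at ``temperature`` kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ * temperature
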