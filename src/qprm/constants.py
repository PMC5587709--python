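"""Physical constants used across the package.

Values are fixed CODATA-derived numbers; override only through the
explicit ``PhysConstants`` object (e.g. from a YAML ``physics:`` section),
never by editing module state.
"""

from dataclasses import dataclass

#: Bohr magneton over Planck constant, MHz per gauss.
MU_B_OVER_H_MHZ_PER_G = 1.399624604

#: Same, in Hz per gauss (the unit used internally for frequencies).
MU_B_OVER_H_HZ_PER_G = MU_B_OVER_H_MHZ_PER_G * 1e6

#: Avogadro constant, mol^-1.
N_AVOGADRO = 6.02214076e23

#: Free-electron g-factor (to the precision relevant here).
G_FREE_ELECTRON = 2.0023


@dataclass(frozen=True)
class PhysConstants:
    """Immutable bundle of the constants a calculation may override."""

    mu_B_over_h: float = MU_B_OVER_H_HZ_PER_G  # Hz / G
    N_A: float = N_AVOGADRO  # mol^-1

    def __post_init__(self):
        if self.mu_B_over_h <= 0 or self.N_A <= 0:
            raise ValueError("physical constants must be positive")


DEFAULT_CONSTANTS = PhysConstants()
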