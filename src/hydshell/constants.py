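"""Physical constants and unit conventions.

All quantities in the package use a single unit system: energies in μeV,
times in ps, momentum transfer q in Å⁻¹, lengths in Å, temperatures in K.
Every conversion between the energy and time domains, or between thermal
energies and temperatures, routes through :class:`Constants` so that the
ħ- and kB-dependent factors appear in exactly one place.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class Constants:
    """Immutable physical constants in the package's unit system.

    Attributes
    ----------
    hbar : float
        Reduced Planck constant, μeV·ps.
    kB : float
        Boltzmann constant, meV/K.
    """

    hbar: float = 658.2119569
    kB: float = 0.08617333


#: Shared instance; modules import this rather than re-instantiating.
CONSTANTS = Constants()

HBAR_UEV_PS = CONSTANTS.hbar
KB_MEV_PER_K = CONSTANTS.kB
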