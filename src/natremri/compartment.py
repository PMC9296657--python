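"""Two-compartment tissue sodium model.

Total tissue sodium is the volume-weighted mixture of the intracellular and
extracellular compartments:

    total = (1 - EVF) * [Na+]i + EVF * [Na+]e,      IVF = 1 - EVF

where EVF/IVF are the extracellular/intracellular volume fractions. Given
any three of (total, [Na+]i, [Na+]e, EVF) the fourth follows algebraically;
this module provides the forward evaluation and both inversions. The model
ignores blood and ductal compartments, so non-physiological solutions
(EVF outside [0, 1], negative concentrations) are diagnostic — they are
returned with explicit flags, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

_TOL = 1e-9


@dataclass
class CompartmentState:
    """A complete (total, [Na+]i, [Na+]e, EVF, IVF) tuple.

    ``physiological`` is False when the state lies outside the model's
    physical domain (EVF not in [0, 1] or a negative concentration).
    """

    total_na: float  # mM
    nai: float  # mM
    nae: float  # mM
    evf: float
    ivf: float
    physiological: bool = True

    def __post_init__(self) -> None:
        if abs(self.ivf - (1.0 - self.evf)) > _TOL:
            raise ValueError("IVF must equal 1 - EVF")
        mixture = (1.0 - self.evf) * self.nai + self.evf * self.nae
        if abs(mixture - self.total_na) > _TOL * max(1.0, abs(self.total_na)):
            raise ValueError("state violates the mixture identity")


def _is_physiological(total: float, nai: float, nae: float, evf: float) -> bool:
    return 0.0 <= evf <= 1.0 and min(total, nai, nae) >= 0.0


def forward_total(nai: float, nae: float, evf: float) -> float:
    """Total tissue [Na+] from compartment concentrations and the EVF."""
    if not 0.0 <= evf <= 1.0:
        raise ValueError(f"EVF must lie in [0, 1], got {evf}")
    if nai < 0 or nae < 0:
        raise ValueError("concentrations must be non-negative")
    return (1.0 - evf) * nai + evf * nae


def solve_evf(total: float, nai: float, nae: float) -> CompartmentState:
    """Resolve the volume fractions from total, intracellular and
    extracellular sodium: EVF = (total - [Na+]i) / ([Na+]e - [Na+]i)."""
    if nae == nai:
        raise ZeroDivisionError(
            "degenerate model: [Na+]e equals [Na+]i, EVF is unidentifiable"
        )
    evf = (total - nai) / (nae - nai)
    return CompartmentState(
        total_na=total, nai=nai, nae=nae, evf=evf, ivf=1.0 - evf,
        physiological=_is_physiological(total, nai, nae, evf),
    )


def solve_nai(total: float, evf: float, nae: float) -> CompartmentState:
    """Resolve intracellular sodium from total, EVF and extracellular
    sodium: [Na+]i = (total - EVF * [Na+]e) / (1 - EVF)."""
    if evf == 1.0:
        raise ZeroDivisionError(
            "degenerate model: EVF = 1 leaves no intracellular compartment"
        )
    nai = (total - evf * nae) / (1.0 - evf)
    return CompartmentState(
        total_na=total, nai=nai, nae=nae, evf=evf, ivf=1.0 - evf,
        physiological=_is_physiological(total, nai, nae, evf),
    )
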