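"""Mutant-anchored conformer population analysis.

A wild-type resonance in fast exchange between two conformations ("in" and
"out") sits at the population-weighted average of the two anchor shifts,
here provided by mutants locked into either conformation.  The per-nucleus
population is the linear interpolation

    p_in = (delta_wt - delta_out) / (delta_in - delta_out),

combined across nuclei by inverse-variance weighting.  The shift-position
error of a weak peak is half its linewidth divided by the signal-to-noise
ratio; binding-induced population shifts follow from the ratio of the
conformer-specific dissociation constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "NucleusShifts",
    "ConformerShiftData",
    "ConformerKd",
    "populations_from_shifts",
    "shift_error",
    "population_shift_from_kd",
]


@dataclass(frozen=True)
class NucleusShifts:
    """Anchor and wild-type chemical shifts (ppm) of one nucleus, with the
    linewidth (Hz), signal-to-noise ratio and resonance frequency (MHz)
    used for the position error of the wild-type peak."""

    delta_wt: float
    delta_in: float
    delta_out: float
    linewidth_hz: float
    snr: float
    spectrometer_MHz: float

    def __post_init__(self) -> None:
        if self.delta_in == self.delta_out:
            raise ValueError("anchor shifts must differ")
        if self.snr <= 0 or self.linewidth_hz <= 0 or self.spectrometer_MHz <= 0:
            raise ValueError("linewidth, snr and spectrometer_MHz must be positive")


@dataclass(frozen=True)
class ConformerShiftData:
    """Shift data per observed nucleus (e.g. {"1H": ..., "15N": ...})."""

    nuclei: dict[str, NucleusShifts]

    def __post_init__(self) -> None:
        if not self.nuclei:
            raise ValueError("at least one nucleus required")


@dataclass(frozen=True)
class ConformerKd:
    """Dissociation constants (M) of the partner for the "in"- and
    "out"-locked conformations, with standard errors."""

    kd_in: float
    kd_out: float
    kd_in_sigma: float = 0.0
    kd_out_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kd_in <= 0 or self.kd_out <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.kd_in_sigma < 0 or self.kd_out_sigma < 0:
            raise ValueError("errors must be non-negative")


def shift_error(linewidth_hz: float, snr: float, spectrometer_MHz: float) -> float:
    """Peak-position uncertainty in ppm: (linewidth / 2 / snr) converted from
    Hz via the spectrometer frequency."""
    if linewidth_hz <= 0 or snr <= 0 or spectrometer_MHz <= 0:
        raise ValueError("all inputs must be positive")
    return linewidth_hz / 2.0 / snr / spectrometer_MHz


_REL_TOL = 0.05  # pad the anchor interval by 5% of its width


def populations_from_shifts(data: ConformerShiftData) -> tuple[float, float, float]:
    """Wild-type "in"/"out" populations from anchor interpolation.

    Per nucleus, p_in = (delta_wt - delta_out)/(delta_in - delta_out) with
    sigma_p = sigma_shift / |delta_in - delta_out| by first-order
    propagation of the wild-type position error; nuclei are combined by
    inverse-variance weighting.  Returns (p_in, p_out, sigma).
    """
    estimates = []
    for name, nuc in data.nuclei.items():
        span = nuc.delta_in - nuc.delta_out
        p = (nuc.delta_wt - nuc.delta_out) / span
        pad = _REL_TOL
        if not -pad <= p <= 1.0 + pad:
            raise ValueError(
                f"{name}: wild-type shift {nuc.delta_wt} lies outside the anchor "
                f"interval [{min(nuc.delta_in, nuc.delta_out)}, "
                f"{max(nuc.delta_in, nuc.delta_out)}] beyond tolerance"
            )
        p = min(max(p, 0.0), 1.0)
        sig_ppm = shift_error(nuc.linewidth_hz, nuc.snr, nuc.spectrometer_MHz)
        estimates.append((p, sig_ppm / abs(span)))
    w = [1.0 / s**2 for _, s in estimates]
    p_in = sum(wi * pi for wi, (pi, _) in zip(w, estimates)) / sum(w)
    sigma = 1.0 / math.sqrt(sum(w))
    return p_in, 1.0 - p_in, sigma


def population_shift_from_kd(
    p_free_in: float, kd: ConformerKd
) -> tuple[float, float, float]:
    """Binding-induced population shift of the "in" conformation.

    Bound-state populations are proportional to the free population divided
    by the conformer's dissociation constant (competitive binding of two
    interconverting conformers):

        p_bound_in = (p_in/Kd_in) / (p_in/Kd_in + p_out/Kd_out).

    Returns (p_bound_in, shift, sigma_shift) with shift = p_bound_in -
    p_free_in and the error propagated to first order from the K_d errors.
    """
    if not 0.0 <= p_free_in <= 1.0:
        raise ValueError("p_free_in must lie in [0, 1]")
    p_out = 1.0 - p_free_in
    a = p_free_in / kd.kd_in
    b = p_out / kd.kd_out
    if a + b == 0.0:
        raise ValueError("degenerate populations")
    p_bound = a / (a + b)
    # d p_bound / d Kd_in = -a*b/((a+b)^2 Kd_in); symmetric for Kd_out
    common = a * b / (a + b) ** 2
    var = (common / kd.kd_in * kd.kd_in_sigma) ** 2 + (
        common / kd.kd_out * kd.kd_out_sigma
    ) ** 2
    return p_bound, p_bound - p_free_in, math.sqrt(var)
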