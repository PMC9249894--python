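"""CPMG relaxation-dispersion data handling and fast-exchange fitting.

Effective transverse relaxation rates are obtained from constant-time CPMG
peak intensities as

    R2_eff(nu) = -(1/T) ln(I(nu)/I0),

and dispersion profiles R2_eff(nu) are fitted with the Luz-Meiboom
fast-exchange model

    R2_eff = R2_0(B0) + (psi_ex b0^2 / k_ex) (1 - (4 nu / k_ex) tanh(k_ex / 4 nu)),

where nu is the CPMG frequency (Hz), k_ex the exchange rate (s^-1) and
psi_ex the exchange amplitude.  The static-field factor is realized as
b0 = 2*pi*field_MHz (rad s^-1 per ppm), which makes psi_ex carry units of
ppm^2 and equal p_A p_B delta^2 in the fast-exchange limit of two-site
exchange with populations p_A, p_B and chemical-shift difference delta
(ppm).  Only the ratio of the two fields enters k_ex, so the convention
affects the scale of psi_ex but nothing else.

Profiles measured at several static fields for the same residue and sample
condition are fitted jointly: one baseline R2_0 per field, with psi_ex and
k_ex shared.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._lsq import fit_multistart

__all__ = [
    "DispersionCurve",
    "IntensityRecord",
    "DispersionFitResult",
    "b0_scale",
    "r2eff_from_intensities",
    "luz_meiboom_r2eff",
    "curves_from_frame",
    "fit_dispersion_joint",
    "estimate_uncertainties",
    "UncertaintyModel",
]


def b0_scale(field_MHz: float) -> float:
    """Static-field factor b0 = 2*pi*field_MHz, in rad s^-1 per ppm."""
    return 2.0 * math.pi * field_MHz


@dataclass(frozen=True)
class DispersionCurve:
    """One residue's R2_eff(nu) profile at one static field and one total
    ligand concentration, with per-point uncertainties."""

    residue_id: str
    field_MHz: float
    L0: float
    nu_cpmg: tuple[float, ...]
    R2eff: tuple[float, ...]
    sigma: tuple[float, ...]

    def __post_init__(self) -> None:
        nu = tuple(float(v) for v in self.nu_cpmg)
        r2 = tuple(float(v) for v in self.R2eff)
        sg = tuple(float(v) for v in self.sigma)
        if not (len(nu) == len(r2) == len(sg)):
            raise ValueError("nu_cpmg, R2eff and sigma must have equal length")
        if len(nu) < 4:
            raise ValueError("a dispersion curve needs at least 4 points")
        if any(v <= 0 for v in nu) or any(b <= a for a, b in zip(nu, nu[1:])):
            raise ValueError("nu_cpmg must be positive and strictly increasing")
        if any(s <= 0 for s in sg):
            raise ValueError("sigma must be positive")
        if self.field_MHz <= 0:
            raise ValueError("field_MHz must be positive")
        object.__setattr__(self, "nu_cpmg", nu)
        object.__setattr__(self, "R2eff", r2)
        object.__setattr__(self, "sigma", sg)


@dataclass(frozen=True)
class IntensityRecord:
    """A single constant-time CPMG peak intensity.

    ``nu_cpmg`` is None for the reference experiment recorded without the
    CPMG relaxation period.
    """

    residue_id: str
    nu_cpmg: float | None
    intensity: float
    T_relax: float

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        if self.T_relax <= 0:
            raise ValueError("T_relax must be positive")
        if self.nu_cpmg is not None and self.nu_cpmg <= 0:
            raise ValueError("nu_cpmg must be positive (or None for the reference)")


@dataclass
class DispersionFitResult:
    """Joint fast-exchange fit result for one residue/condition."""

    kex: float
    kex_sigma: float
    psi_ex: float
    psi_ex_sigma: float
    R20_per_field: dict[float, float]
    R20_sigma_per_field: dict[float, float]
    chi2_red: float
    n_points: int
    converged: bool = True
    no_dispersion: bool = False
    message: str = ""


def r2eff_from_intensities(rec: IntensityRecord, ref: IntensityRecord) -> float:
    """R2_eff(nu) = -(1/T) ln(I(nu)/I0) from a CPMG record and its reference."""
    if ref.nu_cpmg is not None:
        raise ValueError("reference record must have nu_cpmg = None")
    if rec.nu_cpmg is None:
        raise ValueError("record must carry a CPMG frequency")
    if rec.residue_id != ref.residue_id:
        raise ValueError(f"residue mismatch: {rec.residue_id!r} vs {ref.residue_id!r}")
    if rec.T_relax != ref.T_relax:
        raise ValueError("records must share the constant-time delay")
    return -math.log(rec.intensity / ref.intensity) / rec.T_relax


def luz_meiboom_r2eff(R20, psi_ex, field_MHz, kex, nu):
    """Luz-Meiboom fast-exchange dispersion model (vectorized over nu).

    Non-increasing in nu; bounded between R20 (nu -> inf) and
    R20 + psi_ex*b0^2/kex (nu -> 0).
    """
    nu = np.asarray(nu, dtype=float)
    if kex <= 0:
        raise ValueError("kex must be positive")
    if psi_ex < 0:
        raise ValueError("psi_ex must be non-negative")
    b0sq = b0_scale(field_MHz) ** 2
    x = kex / (4.0 * nu)
    out = R20 + (psi_ex * b0sq / kex) * (1.0 - np.tanh(x) / x)
    return out if out.ndim else float(out)


_KEX_STARTS = (1e3, 1e4, 3e4)


def fit_dispersion_joint(curves: list[DispersionCurve]) -> DispersionFitResult:
    """Weighted joint fit of the Luz-Meiboom model across static fields.

    One R2_0 per field; psi_ex and k_ex shared.  Points are weighted by
    1/sigma^2; parameter uncertainties come from the residual-scaled
    covariance evaluated in linear parameter space.  k_ex and psi_ex are
    optimized on a log scale to enforce positivity, with multiple k_ex
    starting values to escape the shallow local minima typical of
    fast-exchange dispersion fits.
    """
    if not curves:
        raise ValueError("need at least one dispersion curve")
    rid, L0 = curves[0].residue_id, curves[0].L0
    if any(c.residue_id != rid or c.L0 != L0 for c in curves[1:]):
        raise ValueError("joint fit requires curves sharing residue and L0")
    fields = [c.field_MHz for c in curves]
    if len(set(fields)) != len(fields):
        raise ValueError("one curve per field expected")
    n_points = sum(len(c.nu_cpmg) for c in curves)
    n_par = len(curves) + 2
    if n_points < n_par:
        raise ValueError(f"{n_points} points cannot constrain {n_par} parameters")

    nus = [np.array(c.nu_cpmg) for c in curves]
    r2s = [np.array(c.R2eff) for c in curves]
    sgs = [np.array(c.sigma) for c in curves]

    def residuals(x: np.ndarray) -> np.ndarray:
        kex, psi = x[0], x[1]
        return np.concatenate([
            (r2s[i] - luz_meiboom_r2eff(x[2 + i], psi, c.field_MHz, kex, nus[i])) / sgs[i]
            for i, c in enumerate(curves)
        ])

    # data-driven psi start: low-nu/high-nu contrast at the first field
    c0 = curves[0]
    amp0 = max(c0.R2eff[0] - c0.R2eff[-1], 0.1)
    r20_starts = [max(c.R2eff[-1], 1e-2) for c in curves]
    starts = [
        np.array([kex0, max(amp0 * kex0 / b0_scale(c0.field_MHz) ** 2, 1e-8), *r20_starts])
        for kex0 in _KEX_STARTS
    ]
    lower = np.array([1.0, 1e-12] + [1e-3] * len(curves))
    upper = np.array([1e7, 1e4] + [1e4] * len(curves))
    best = fit_multistart(residuals, starts, lower, upper)

    if not best.success:
        return DispersionFitResult(
            kex=float("nan"), kex_sigma=float("nan"), psi_ex=float("nan"),
            psi_ex_sigma=float("nan"), R20_per_field={}, R20_sigma_per_field={},
            chi2_red=float("nan"), n_points=n_points, converged=False,
            message=best.message,
        )

    kex, psi = best.x[0], best.x[1]
    kex_sig, psi_sig = best.sigma[0], best.sigma[1]
    chi2_red = best.wsse / max(n_points - n_par, 1)
    r20 = {c.field_MHz: best.x[2 + i] for i, c in enumerate(curves)}
    r20_sig = {c.field_MHz: best.sigma[2 + i] for i, c in enumerate(curves)}
    no_disp = (not math.isfinite(psi_sig)) or psi < 2.0 * psi_sig
    return DispersionFitResult(
        kex=kex, kex_sigma=kex_sig, psi_ex=psi, psi_ex_sigma=psi_sig,
        R20_per_field=r20, R20_sigma_per_field=r20_sig,
        chi2_red=chi2_red, n_points=n_points, converged=True,
        no_dispersion=no_disp,
        message="amplitude below 2x its error: kex unidentifiable" if no_disp else "",
    )


def curves_from_frame(frame) -> list[DispersionCurve]:
    """Group a long-format rate-schema table (columns residue, field_MHz,
    L0_M, nu_hz, r2eff, sigma) into validated dispersion curves."""
    curves = []
    for (rid, f_MHz, L0), grp in frame.groupby(["residue", "field_MHz", "L0_M"]):
        grp = grp.sort_values("nu_hz")
        curves.append(
            DispersionCurve(
                residue_id=str(rid), field_MHz=float(f_MHz), L0=float(L0),
                nu_cpmg=tuple(grp["nu_hz"]), R2eff=tuple(grp["r2eff"]),
                sigma=tuple(grp["sigma"]),
            )
        )
    return curves


@dataclass
class UncertaintyModel:
    """Assigned per-residue R2_eff uncertainties: the larger of a global
    estimate (reference non-exchanging residues) and a residue-specific
    estimate (repeat measurements)."""

    sigma_global: float
    sigma_residue: dict[str, float]
    reference_residues: tuple[str, ...]

    def sigma_for(self, residue_id: str) -> float:
        return max(self.sigma_global, self.sigma_residue.get(residue_id, 0.0))


def estimate_uncertainties(
    r2eff_by_residue: dict[str, np.ndarray],
    reference_residues: list[str] | None = None,
    repeats: dict[str, np.ndarray] | None = None,
    n_reference: int = 5,
) -> UncertaintyModel:
    """Measurement-uncertainty protocol for R2_eff data.

    Parameters
    ----------
    r2eff_by_residue
        R2_eff values over the CPMG frequency grid, per residue.
    reference_residues
        Explicit non-exchanging reference set.  When None, the
        ``n_reference`` residues with the lowest standard deviation of
        R2_eff over the grid are selected automatically.
    repeats
        Repeat R2_eff measurements at one suitable CPMG frequency, per
        residue; the residue-specific sigma is the standard deviation of the
        repeats.  Residues without repeats fall back to the global sigma.

    The global sigma is the mean of the reference residues' standard
    deviations; the assigned sigma per residue is the larger of the global
    and residue-specific estimates.
    """
    if not r2eff_by_residue:
        raise ValueError("no R2_eff data")
    sds = {rid: float(np.std(np.asarray(v), ddof=1)) for rid, v in r2eff_by_residue.items()}
    if reference_residues is None:
        reference_residues = sorted(sds, key=sds.get)[:n_reference]
    else:
        missing = [r for r in reference_residues if r not in sds]
        if missing:
            raise ValueError(f"reference residues not in data: {missing}")
    if len(reference_residues) < 2:
        raise ValueError("need at least 2 reference residues")
    sigma_global = float(np.mean([sds[r] for r in reference_residues]))
    sigma_residue: dict[str, float] = {}
    if repeats:
        for rid, vals in repeats.items():
            vals = np.asarray(vals, dtype=float)
            if vals.size >= 2:
                sigma_residue[rid] = float(np.std(vals, ddof=1))
    else:
        warnings.warn("no repeat measurements: residue-specific uncertainties "
                      "fall back to the global estimate", stacklevel=2)
    return UncertaintyModel(
        sigma_global=sigma_global,
        sigma_residue=sigma_residue,
        reference_residues=tuple(reference_residues),
    )
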