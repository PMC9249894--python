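"""Closed-form kinetics of two-state and three-state binding mechanisms.

A protein P binds a partner (ligand) L either directly,

    TS:   P + L  <=>  PL                     (k_on, k_off)

or through a conformational step that precedes binding (conformational
selection) or follows it (induced fit),

    CS:   P1  <=>  P2;   P2 + L  <=>  P2L    (k12, k21; k_plus, k_minus)
    IF:   P1 + L <=> P1L;  P1L <=> P2L       (k_plus, k_minus; k12, k21)

The NMR-visible exchange rate ``k_ex`` of an observed protein residue is the
slowest nonzero relaxation rate of the corresponding single-molecule jump
process at equilibrium ligand concentration [L]_eq.  For both three-state
mechanisms it is the smaller root of ``lambda^2 - S*lambda + Q = 0`` with
``S = k12 + k21 + k_plus*[L]_eq + k_minus`` and a mechanism-specific ``Q``;
for two-state binding it is ``k_on*[L]_eq + k_off``.

Because k_ex(TS) and k_ex(IF) increase with total ligand concentration
whereas k_ex(CS) decreases whenever the conformational excitation rate k12
is smaller than the unbinding rate k_minus, the sign of the concentration
dependence is a litmus test for the recognition mechanism.

All concentrations are in molar (M) and all rates in s^-1 (bimolecular
rates in M^-1 s^-1).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Mechanism",
    "MechanismParams",
    "TitrationDesign",
    "ligand_eq",
    "kex_two_state",
    "kex_conf_selection",
    "kex_induced_fit",
    "kd_for_mechanism",
    "kex_curve",
    "relaxation_oracle",
    "bound_fraction",
]


class Mechanism(str, enum.Enum):
    """Binding mechanism tag: two-state (TS), conformational selection (CS),
    induced fit (IF)."""

    TS = "TS"
    CS = "CS"
    IF = "IF"


@dataclass(frozen=True)
class MechanismParams:
    """Rate constants of one binding mechanism.

    TS uses ``k_on`` (M^-1 s^-1) and ``k_off`` (s^-1).  CS and IF use the
    conformational rates ``k12`` (excitation) and ``k21`` (relaxation, both
    s^-1) plus the bimolecular on-rate ``k_plus`` (M^-1 s^-1) and unbinding
    rate ``k_minus`` (s^-1).  Fields not belonging to the tagged mechanism
    stay ``None``.
    """

    mechanism: Mechanism
    k_on: float | None = None
    k_off: float | None = None
    k12: float | None = None
    k21: float | None = None
    k_plus: float | None = None
    k_minus: float | None = None

    def __post_init__(self) -> None:
        mech = Mechanism(self.mechanism)
        object.__setattr__(self, "mechanism", mech)
        if mech is Mechanism.TS:
            required, forbidden = ("k_on", "k_off"), ("k12", "k21", "k_plus", "k_minus")
        else:
            required, forbidden = ("k12", "k21", "k_plus", "k_minus"), ("k_on", "k_off")
        for name in required:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"{mech.value} mechanism requires {name}")
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be a finite non-negative rate, got {value!r}")
        for name in forbidden:
            if getattr(self, name) is not None:
                raise ValueError(f"{name} does not belong to the {mech.value} mechanism")
        if mech is Mechanism.CS and self.k21 == 0 and self.k12 == 0:
            raise ValueError("CS requires k12 + k21 > 0")

    @classmethod
    def two_state(cls, k_on: float, k_off: float) -> "MechanismParams":
        return cls(Mechanism.TS, k_on=k_on, k_off=k_off)

    @classmethod
    def conf_selection(cls, k12: float, k21: float, k_plus: float, k_minus: float) -> "MechanismParams":
        return cls(Mechanism.CS, k12=k12, k21=k21, k_plus=k_plus, k_minus=k_minus)

    @classmethod
    def induced_fit(cls, k12: float, k21: float, k_plus: float, k_minus: float) -> "MechanismParams":
        return cls(Mechanism.IF, k12=k12, k21=k21, k_plus=k_plus, k_minus=k_minus)


@dataclass(frozen=True)
class TitrationDesign:
    """Total observed-protein concentration P0 (M) and a strictly increasing
    series of total partner concentrations L0 (M)."""

    P0: float
    L0_series: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.P0 <= 0:
            raise ValueError("P0 must be positive")
        series = tuple(float(v) for v in self.L0_series)
        if any(v < 0 for v in series):
            raise ValueError("L0 values must be non-negative")
        if any(b <= a for a, b in zip(series, series[1:])):
            raise ValueError("L0_series must be strictly increasing")
        object.__setattr__(self, "L0_series", series)


def _mass_balance(L: float, L0: float, P0: float, Kd: float) -> float:
    # f(L) = L + [PL] - L0 with [PL] = P0*L/(Kd+L)
    return L + P0 * L / (Kd + L) - L0


def ligand_eq(L0: float, P0: float, Kd: float) -> float:
    """Equilibrium concentration of unbound ligand from the quadratic mass
    balance,

        [L]_eq = 1/2 (L0 - P0 - Kd + sqrt((L0 - P0 + Kd)^2 + 4 P0 Kd)).

    The closed form is followed by one Newton step on the mass-balance
    residual to suppress cancellation when L0 ~ P0 and Kd << P0.  For the
    stoichiometric limit Kd = 0 the continuous extension max(L0 - P0, 0) is
    returned.
    """
    if L0 < 0 or P0 < 0 or Kd < 0:
        raise ValueError("L0, P0 and Kd must be non-negative")
    if L0 == 0:
        return 0.0
    if Kd == 0:
        return max(L0 - P0, 0.0)
    if P0 == 0:
        return float(L0)
    b = L0 - P0 - Kd
    L = 0.5 * (b + math.sqrt((L0 - P0 + Kd) ** 2 + 4.0 * P0 * Kd))
    L = min(max(L, 0.0), L0)
    # Newton polish on f(L) = L + P0 L/(Kd+L) - L0
    f = _mass_balance(L, L0, P0, Kd)
    fprime = 1.0 + P0 * Kd / (Kd + L) ** 2
    L = min(max(L - f / fprime, 0.0), L0)
    return L


def _smaller_root(S: float, Q: float) -> float:
    """Smaller root of lambda^2 - S lambda + Q = 0, evaluated without
    catastrophic cancellation as 2Q / (S + sqrt(S^2 - 4Q))."""
    disc = S * S - 4.0 * Q
    if disc < 0:
        if disc < -1e-9 * S * S:
            raise ArithmeticError(f"negative discriminant {disc} for S={S}, Q={Q}")
        disc = 0.0
    denom = S + math.sqrt(disc)
    if denom == 0.0:
        return 0.0
    return 2.0 * Q / denom


def kex_two_state(p: MechanismParams, L_eq: float) -> float:
    """k_ex for two-state binding: k_on*[L]_eq + k_off."""
    _require(p, Mechanism.TS)
    if L_eq < 0:
        raise ValueError("L_eq must be non-negative")
    return p.k_on * L_eq + p.k_off


def kex_conf_selection(p: MechanismParams, L_eq: float) -> float:
    """Dominant (slowest nonzero) relaxation rate of the CS jump process:
    smaller root of lambda^2 - S lambda + Q with
    Q = k12 (k_plus [L]_eq + k_minus) + k_minus k21."""
    _require(p, Mechanism.CS)
    if L_eq < 0:
        raise ValueError("L_eq must be non-negative")
    kpL = p.k_plus * L_eq
    S = p.k12 + p.k21 + kpL + p.k_minus
    Q = p.k12 * (kpL + p.k_minus) + p.k_minus * p.k21
    return _smaller_root(S, Q)


def kex_induced_fit(p: MechanismParams, L_eq: float) -> float:
    """Dominant relaxation rate of the IF jump process: smaller root of
    lambda^2 - S lambda + Q with Q = k_plus [L]_eq (k12 + k21) + k21 k_minus."""
    _require(p, Mechanism.IF)
    if L_eq < 0:
        raise ValueError("L_eq must be non-negative")
    kpL = p.k_plus * L_eq
    S = p.k12 + p.k21 + kpL + p.k_minus
    Q = kpL * (p.k12 + p.k21) + p.k21 * p.k_minus
    return _smaller_root(S, Q)


def kd_for_mechanism(p: MechanismParams) -> float:
    """Dissociation constant of the tagged mechanism:

    K_d(TS) = k_off/k_on;
    K_d(CS) = k_minus (k12 + k21) / (k_plus k12)  (>= k_minus/k_plus);
    K_d(IF) = k_minus k21 / (k_plus (k21 + k12))  (<= k_minus/k_plus).
    """
    if p.mechanism is Mechanism.TS:
        if p.k_on == 0:
            raise ZeroDivisionError("TS with k_on = 0 has no finite K_d")
        return p.k_off / p.k_on
    if p.k_plus == 0:
        raise ZeroDivisionError("k_plus = 0: system cannot bind")
    if p.mechanism is Mechanism.CS:
        if p.k12 == 0:
            raise ZeroDivisionError("CS with k12 = 0: binding-competent state unreachable")
        return p.k_minus * (p.k12 + p.k21) / (p.k_plus * p.k12)
    return p.k_minus * p.k21 / (p.k_plus * (p.k21 + p.k12))


_KEX_DISPATCH = {
    Mechanism.TS: kex_two_state,
    Mechanism.CS: kex_conf_selection,
    Mechanism.IF: kex_induced_fit,
}


def kex_curve(p: MechanismParams, design: TitrationDesign) -> list[tuple[float, float]]:
    """k_ex along a titration: for each total ligand concentration L0,
    [L]_eq from the mechanism's K_d, then the mechanism's k_ex law.

    Returns a list of (L0, k_ex) pairs aligned with ``design.L0_series``.
    """
    Kd = kd_for_mechanism(p)
    fn = _KEX_DISPATCH[p.mechanism]
    out = []
    for L0 in design.L0_series:
        L_eq = ligand_eq(L0, design.P0, Kd)
        out.append((L0, fn(p, L_eq)))
    return out


def _generator(p: MechanismParams, L_eq: float) -> np.ndarray:
    """Column-stochastic generator (columns sum to zero) of the tagged-molecule
    jump process at fixed equilibrium free-ligand concentration."""
    if p.mechanism is Mechanism.TS:
        a, b = p.k_on * L_eq, p.k_off
        return np.array([[-a, b], [a, -b]], dtype=float)
    if p.mechanism is Mechanism.CS:
        # states: P1, P2, P2L
        rates = [(0, 1, p.k12), (1, 0, p.k21), (1, 2, p.k_plus * L_eq), (2, 1, p.k_minus)]
    else:
        # states: P1, P1L, P2L
        rates = [(0, 1, p.k_plus * L_eq), (1, 0, p.k_minus), (1, 2, p.k12), (2, 1, p.k21)]
    G = np.zeros((3, 3))
    for i, j, k in rates:
        G[j, i] += k
        G[i, i] -= k
    return G


def relaxation_oracle(p: MechanismParams, L_eq: float) -> list[float]:
    """Nonzero relaxation rates of the jump process, sorted ascending.

    Brute-force cross-check for the closed-form k_ex laws: eigenvalues of the
    generator are computed numerically and polished with two Newton steps on
    the characteristic polynomial assembled from matrix invariants (trace,
    second invariant, determinant), so the oracle never touches the S, Q
    algebra of the analytic formulas.
    """
    G = _generator(p, L_eq)
    lams = np.linalg.eigvals(-G).real.astype(np.longdouble)
    n = G.shape[0]
    # char-poly coefficients from matrix invariants in extended precision:
    # the second invariant suffers heavy cancellation at extreme rate ratios
    Gl = G.astype(np.longdouble)
    if n == 2:
        coeffs = np.array([1.0, np.trace(Gl), 0.0], dtype=np.longdouble)
    else:
        trG = np.trace(Gl)
        tr2 = np.trace(Gl @ Gl)
        c1 = 0.5 * (trG * trG - tr2)
        coeffs = np.array([1.0, trG, c1, 0.0], dtype=np.longdouble)  # det(G) = 0
    deriv = np.polyder(coeffs)
    for _ in range(2):
        fval = np.polyval(coeffs, lams)
        fder = np.polyval(deriv, lams)
        step = np.where(fder != 0, fval / fder, 0.0)
        lams = lams - step
    scale = max(abs(G).max(), 1.0)
    nonzero = sorted(float(l) for l in lams if l > 1e-10 * scale)
    return nonzero


def bound_fraction(p: MechanismParams, L_eq: float) -> float:
    """Equilibrium fraction of the observed protein in the ligand-bound
    state(s), from the stationary distribution of the jump process."""
    if p.mechanism is Mechanism.TS:
        a, b = p.k_on * L_eq, p.k_off
        return a / (a + b) if (a + b) > 0 else 0.0
    kpL = p.k_plus * L_eq
    if p.mechanism is Mechanism.CS:
        # pi ~ (k21 k_minus, k12 k_minus, k12 kpL)
        w = (p.k21 * p.k_minus, p.k12 * p.k_minus, p.k12 * kpL)
        bound = w[2]
    else:
        # pi ~ (k_minus k21, kpL k21, kpL k12)
        w = (p.k_minus * p.k21, kpL * p.k21, kpL * p.k12)
        bound = w[1] + w[2]
    total = sum(w)
    return bound / total if total > 0 else 0.0


def _require(p: MechanismParams, mech: Mechanism) -> None:
    if p.mechanism is not mech:
        raise ValueError(f"expected {mech.value} parameters, got {p.mechanism.value}")
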