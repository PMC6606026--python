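"""Equilibrium model of cohesin-chromatin binding.

Nuclear cohesin C_T partitions into unbound (U), dynamically chromatin-bound
(D) and stably chromatin-bound (S) pools, C_T = U + D + S, with first-order
exchange between U and D balanced at steady state (k_on * U = k_off * D).
Eliminating U and D gives the chromatin-bound fraction b_T = (D + S)/C_T as
an affine function of the stable fraction s = S/C_T:

    b_T = k_on/(k_on + k_off) + k_off/(k_on + k_off) * s,

so intercept + slope = 1.  G1 cells have no stable pool (s = 0), so the G1
bound fraction calibrates the intercept; the model then predicts the G2
bound fraction from the measured G2 stable fraction alone, under the
assumption that k_on and k_off themselves do not change between G1 and G2.
Fractions only identify the ratio k_on/k_off; supplying an absolute k_off
(1/residence time from FRAP) anchors both rates.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EquilibriumParams",
    "EquilibriumState",
    "Discrepancy",
    "bound_fraction",
    "calibrate_from_g1",
    "partition",
    "compare_prediction",
]


@dataclass(frozen=True)
class EquilibriumParams:
    """On/off rate constants (time^-1); only their ratio matters for b_T."""

    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rate constants must be positive")

    @property
    def intercept(self) -> float:
        """b_T at s = 0: k_on / (k_on + k_off)."""
        return self.k_on / (self.k_on + self.k_off)

    @property
    def slope(self) -> float:
        """db_T/ds: k_off / (k_on + k_off); intercept + slope == 1."""
        return self.k_off / (self.k_on + self.k_off)


@dataclass(frozen=True)
class EquilibriumState:
    """Copy-number partition of nuclear cohesin at equilibrium."""

    c_total: float
    unbound: float
    dynamic: float
    stable: float

    @property
    def bound(self) -> float:
        return self.dynamic + self.stable

    @property
    def fractions(self) -> dict[str, float]:
        if self.c_total == 0:
            return {"u": 0.0, "d": 0.0, "s": 0.0, "b_T": 0.0}
        return {
            "u": self.unbound / self.c_total,
            "d": self.dynamic / self.c_total,
            "s": self.stable / self.c_total,
            "b_T": self.bound / self.c_total,
        }


@dataclass(frozen=True)
class Discrepancy:
    predicted: float
    observed: float

    @property
    def absolute(self) -> float:
        return abs(self.predicted - self.observed)

    @property
    def relative(self) -> float:
        return self.absolute / self.observed if self.observed else float("inf")


def bound_fraction(s: float, params: EquilibriumParams) -> float:
    """Chromatin-bound fraction b_T = intercept + slope * s (affine in s)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("stable fraction must lie in [0, 1]")
    return params.intercept + params.slope * s


def calibrate_from_g1(
    b_t_g1: float, k_off: float | None = None
) -> EquilibriumParams:
    """Calibrate the model from the G1 bound fraction (where s = 0).

    The G1 bound fraction is the intercept, 1 - b_T(G1) the slope, and
    k_on/k_off = b_T/(1 - b_T).  Without an absolute ``k_off`` the rates are
    stored on an arbitrary unit scale (k_off = 1); supplying k_off (e.g. the
    inverse dynamic residence time) anchors both.
    """
    if not 0.0 < b_t_g1 < 1.0:
        raise ValueError("G1 bound fraction must lie strictly in (0, 1): "
                         "boundary values give degenerate kinetics")
    k_off_val = 1.0 if k_off is None else float(k_off)
    if k_off_val <= 0:
        raise ValueError("k_off must be positive")
    k_on = k_off_val * b_t_g1 / (1.0 - b_t_g1)
    return EquilibriumParams(k_on=k_on, k_off=k_off_val)


def partition(c_total: float, s: float, params: EquilibriumParams) -> EquilibriumState:
    """Partition ``c_total`` nuclear copies at stable fraction ``s``.

    S = s*C_T, D = (b_T - s)*C_T and U takes the remainder so that
    U + D + S == C_T up to one rounding ulp.  The steady-state balance
    k_on*U = k_off*D holds by construction.
    """
    if c_total < 0:
        raise ValueError("copy number must be non-negative")
    b_t = bound_fraction(s, params)
    if s > b_t:
        raise ValueError(
            f"stable fraction {s} exceeds the bound fraction {b_t}: "
            "impossible under the model (the stable pool is part of the bound pool)"
        )
    stable = s * c_total
    dynamic = (b_t - s) * c_total
    unbound = c_total - (stable + dynamic)
    return EquilibriumState(
        c_total=c_total, unbound=unbound, dynamic=dynamic, stable=stable
    )


def compare_prediction(observed_b_t: float, predicted_b_t: float) -> Discrepancy:
    """Absolute and relative difference between observed and predicted b_T."""
    for name, value in (("observed", observed_b_t), ("predicted", predicted_b_t)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} bound fraction must lie in [0, 1]")
    return Discrepancy(predicted=predicted_b_t, observed=observed_b_t)
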