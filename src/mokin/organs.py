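"""Organ compartment topologies and closed-form tissue solutions.

Five organs are modeled.  Heart, lungs and liver use a single reversible
tissue compartment whose efflux rate is tied to the uptake rate through a
fixed volume of distribution (``k2 = K1 / Vd``, Vd set to the tissue water
fraction).  The femur adds an irreversible trapping compartment (k3, bone
hydroxyapatite incorporation); the kidneys additionally clear the trapped
compartment to the bladder (k4).

With an exponential-sum arterial input ``Ca`` the compartment ODEs

    dC1/dt = K1*Ca - (k2 + k3)*C1
    dC2/dt = k3*C1 - k4*C2

have exact solutions inside the same exponential-sum algebra:
``C1 = K1 * (Ca (x) e^{-(k2+k3)t})`` and ``C2 = k3 * (C1 (x) e^{-k4 t})``,
where ``(x)`` is causal convolution.  The measured VOI signal is
``CT = (1 - vb) * (C1 + C2) + vb * Ca_org``, with ``Ca_org`` the organ's own
corrected input standing in for the vascular fraction vb of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expsum import ExpSum, concat

__all__ = [
    "OrganModel",
    "KineticParams",
    "ORGANS",
    "ORGAN_IDS",
    "solve_tissue",
    "tissue_curve",
    "influx_rate",
    "frame_average",
]


@dataclass(frozen=True)
class OrganModel:
    """Compartment topology of one organ."""

    organ_id: str
    n_tissue_compartments: int
    has_trapping: bool
    has_clearance: bool
    vd_constraint: float | None  # mL/cm^3; ties k2 = K1/Vd when set

    def __post_init__(self) -> None:
        if self.n_tissue_compartments not in (1, 2):
            raise ValueError("only 1 or 2 tissue compartments supported")
        if self.has_clearance and not self.has_trapping:
            raise ValueError("clearance (k4) requires a trapping compartment")
        if self.vd_constraint is not None and self.n_tissue_compartments != 1:
            raise ValueError("Vd constraint applies to 1-compartment organs only")


#: The study's five organs. Vd values are tissue water fractions (mL/cm^3).
ORGANS: dict[str, OrganModel] = {
    "heart": OrganModel("heart", 1, False, False, 0.665),
    "lungs": OrganModel("lungs", 1, False, False, 0.763),
    "liver": OrganModel("liver", 1, False, False, 0.751),
    "kidneys": OrganModel("kidneys", 2, True, True, None),
    "femur": OrganModel("femur", 2, True, False, None),
}

ORGAN_IDS: tuple[str, ...] = tuple(ORGANS)


@dataclass
class KineticParams:
    """Rate constants, blood fraction and bolus-arrival delay for one organ.

    Units: K1 in mL/mL/min, k2/k3/k4 in 1/min, vb dimensionless in [0, 1],
    delay in minutes (may be negative).
    """

    K1: float
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    vb: float = 0.0
    delay: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0.0 <= self.vb <= 1.0:
            raise ValueError("vb must lie in [0, 1]")

    @classmethod
    def for_organ(cls, model: OrganModel, **kwargs: float) -> "KineticParams":
        """Build params honoring the organ's Vd tie (k2 derived, not free)."""
        if model.vd_constraint is not None:
            if "k2" in kwargs:
                raise ValueError(
                    f"{model.organ_id}: k2 is determined by K1/Vd, not free"
                )
            kwargs["k2"] = kwargs.get("K1", 0.0) / model.vd_constraint
        return cls(**kwargs)


def solve_tissue(
    model: OrganModel, params: KineticParams, ca: ExpSum
) -> tuple[ExpSum, ExpSum | None]:
    """Exact tissue compartment concentrations driven by input ``ca``.

    Returns ``(C1, C2)``; ``C2`` is None for 1-compartment organs.
    """
    k3 = params.k3 if model.has_trapping else 0.0
    k4 = params.k4 if model.has_clearance else 0.0
    c1 = ca.convolve_exp(params.k2 + k3).scale(params.K1)
    if model.n_tissue_compartments == 1:
        return c1, None
    c2 = c1.convolve_exp(k4).scale(k3)
    return c1, c2


def tissue_curve(model: OrganModel, params: KineticParams, ca: ExpSum) -> ExpSum:
    """Total modeled VOI signal ``(1-vb)(C1+C2) + vb*Ca``."""
    c1, c2 = solve_tissue(model, params, ca)
    w = 1.0 - params.vb
    pieces = [c1.scale(w), ca.scale(params.vb)]
    if c2 is not None:
        pieces.append(c2.scale(w))
    return concat(pieces)


def influx_rate(params: KineticParams) -> float:
    """Net influx rate Ki = K1*k3/(k2+k3) (mL/mL/min) for trapping organs.

    Ki is the macro-parameter that stays estimable even when K1 and k2
    individually ride an exchange degeneracy.
    """
    denom = params.k2 + params.k3
    if denom <= 0:
        raise ValueError("Ki undefined: k2 + k3 must be positive")
    return params.K1 * params.k3 / denom


def frame_average(curve: ExpSum, frame: tuple[float, float]) -> float:
    """Mean of ``curve`` over one PET frame ``(start, duration)`` in minutes."""
    start, duration = frame
    if duration <= 0:
        raise ValueError("frame duration must be positive")
    return float(
        curve.frame_averages(np.array([start]), np.array([duration]))[0]
    )
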