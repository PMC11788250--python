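"""Synthetic multi-organ Na[18F]F datasets with known ground truth.

Generates framed, noisy time-activity curves for the five modeled organs
plus a vena-cava IDIF under the study's acquisition conditions: the
33-frame hour-long schedule, a bolus-shaped input function scaled to a
~12 MBq-class injection, per-subject kinetic parameters drawn around the
long-scale population means, and a counting-statistics noise model

    sigma(t) = Sc * exp(lambda * t) * sqrt(CT(t) / dt_frame)

with lambda the 18F decay constant (the exp factor undoes the variance
benefit lost to decay correction), CT the noiseless frame activity and
dt_frame the frame length.  Noise is Gaussian and independent across
frames and organs; negative simulated activities are kept, as in real
decay-corrected PET data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expsum import ExpSum
from .fitting import (
    DEFAULT_NOISE_SC as _DEFAULT_NOISE_SC,
    JointParams,
    ParamSpec,
    build_param_spec,
    model_frame_averages,
)
from .input_function import F18_LAMBDA_PER_MIN, bolus_curve
from .organs import ORGAN_IDS
from .schedule import FrameSchedule

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "KINETIC_PRIORS",
    "DEFAULT_NOISE_SC",
    "default_ground_truth",
    "default_idif_curve",
    "simulate_dataset",
    "noise_sigma",
]

#: Per-organ noise scaling factors Sc, chosen qualitatively so that organ
#: TACs show ~5% relative noise in the early 10 s frames and 1-2% in the
#: late 5 min frames (typical of small-animal data at a ~12 MBq dose);
#: the image-derived IDIF is distinctly noisier.  Re-exported from
#: :mod:`mokin.fitting`, which uses the same factors as residual weights.
DEFAULT_NOISE_SC = _DEFAULT_NOISE_SC

#: Population (mean, SD) for each free parameter, centered on the long-scale
#: study means; parameters without a published long-scale value use
#: physiologically plausible defaults (documented in docs/methods.md).
KINETIC_PRIORS: dict[str, tuple[float, float]] = {
    "gamma": (0.80, 0.20),
    "tau": (0.20, 0.10),
    "delay_heart": (0.25, 0.10),
    "delay_lungs": (0.25, 0.10),
    "delay_liver": (0.30, 0.10),
    "delay_kidneys": (0.30, 0.10),
    "delay_femur": (0.20, 0.15),
    "vb_heart": (0.60, 0.15),
    "vb_lungs": (0.30, 0.10),
    "vb_liver": (0.25, 0.08),
    "vb_kidneys": (0.20, 0.07),
    "vb_femur": (0.05, 0.03),
    "K1_heart": (0.30, 0.15),
    "K1_lungs": (0.06, 0.08),
    "K1_liver": (0.49, 0.43),
    "K1_kidneys": (2.21, 0.45),
    "k2_kidneys": (2.40, 1.00),
    "k3_kidneys": (2.40, 0.90),
    "k4_kidneys": (1.40, 0.56),
    "K1_femur": (0.26, 0.08),
    "k2_femur": (0.20, 0.24),
    "k3_femur": (0.14, 0.15),
}

#: Rates are floored slightly above zero when truncating the draws, so every
#: synthetic subject has nonzero perfusion and a defined influx rate.
RATE_FLOOR = 0.01


@dataclass
class NoiseSpec:
    """Counting-statistics noise configuration."""

    sc: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SC))
    lambda_decay: float = F18_LAMBDA_PER_MIN
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.sc.values()):
            raise ValueError("Sc factors must be non-negative")


@dataclass
class GroundTruth:
    """Everything needed to simulate (and later grade) one subject."""

    joint_params: JointParams
    idif_true: ExpSum
    schedule: FrameSchedule
    noise: NoiseSpec
    gamma_mode: str = "divide"


def default_idif_curve(dose_scale: float = 1.0) -> ExpSum:
    """Bolus-shaped vena-cava input for a ~12 MBq-class injection.

    Rise over ~15 s to a peak near 3000 kBq/mL, then tri-exponential decay
    (fast vascular mixing, renal extraction, slow bone-pool tail).
    """
    amps = dose_scale * np.array([2100.0, 600.0, 300.0])
    rates = np.array([4.0, 0.5, 0.008])
    return bolus_curve(t0=0.15, rise=0.25, amps=amps, rates=rates)


def default_ground_truth(
    subject_seed: int = 0,
    schedule: FrameSchedule | None = None,
    noise: NoiseSpec | None = None,
    spec: ParamSpec | None = None,
) -> GroundTruth:
    """Draw one subject's ground truth from the population priors.

    Draws are truncated to the fitting bounds (rates additionally floored at
    :data:`RATE_FLOOR`); the IDIF amplitude is scaled by a per-subject
    injected-dose factor. A fixed ``subject_seed`` reproduces the subject.
    """
    rng = np.random.default_rng(subject_seed)
    schedule = schedule or FrameSchedule.default()
    noise = noise or NoiseSpec(seed=subject_seed)
    spec = spec or build_param_spec()
    values: dict[str, float] = {}
    for i, name in enumerate(spec.names):
        mean, sd = KINETIC_PRIORS[name]
        lo, hi = spec.lower[i], spec.upper[i]
        if name.split("_")[0] in ("K1", "k2", "k3", "k4"):
            lo = max(lo, RATE_FLOOR)
        for _ in range(1000):
            draw = rng.normal(mean, sd)
            if lo <= draw <= hi:
                break
        else:  # pragma: no cover - priors sit well inside the bounds
            draw = float(np.clip(mean, lo, hi))
        values[name] = float(draw)
    # injected dose 12 +/- 8 MBq, floored at a usable activity
    dose_scale = max(rng.normal(12.0, 8.0), 3.0) / 12.0
    return GroundTruth(
        joint_params=JointParams(spec, values),
        idif_true=default_idif_curve(dose_scale),
        schedule=schedule,
        noise=noise,
    )


def noise_sigma(
    ct: np.ndarray,
    schedule: FrameSchedule,
    sc: float,
    lambda_decay: float = F18_LAMBDA_PER_MIN,
) -> np.ndarray:
    """Counting-statistics noise SD per frame for noiseless activities ``ct``."""
    ct = np.clip(np.asarray(ct, dtype=float), 0.0, None)
    return (
        sc
        * np.exp(lambda_decay * schedule.mid_min)
        * np.sqrt(ct / schedule.durations_min)
    )


def noiseless_frames(gt: GroundTruth) -> pd.DataFrame:
    """Frame-averaged noiseless model output for every organ plus the IDIF."""
    model = model_frame_averages(
        gt.joint_params, gt.idif_true, gt.schedule, gt.gamma_mode
    )
    out = pd.DataFrame(
        {
            "frame_start_s": gt.schedule.starts_s,
            "frame_duration_s": gt.schedule.durations_s,
        }
    )
    for organ in ORGAN_IDS:
        out[organ] = model[organ]
    out["idif"] = gt.idif_true.frame_averages(
        gt.schedule.starts_min, gt.schedule.durations_min
    )
    return out


def simulate_dataset(
    gt: GroundTruth,
    rng: np.random.Generator | int | None = None,
    return_sigma: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Noisy framed dataset for one subject.

    Gaussian noise with the counting-statistics SD is added independently to
    every organ frame and to the IDIF (its own Sc).  Values may go slightly
    negative, as decay-corrected PET data can.  With ``return_sigma`` the
    exact noise SDs used are returned alongside.
    """
    if rng is None:
        rng = np.random.default_rng(gt.noise.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    clean = noiseless_frames(gt)
    noisy = clean.copy()
    sigmas = clean.copy()
    for col in (*ORGAN_IDS, "idif"):
        sigma = noise_sigma(
            clean[col].to_numpy(), gt.schedule, gt.noise.sc[col],
            gt.noise.lambda_decay,
        )
        sigmas[col] = sigma
        noisy[col] = clean[col].to_numpy() + rng.standard_normal(sigma.size) * sigma
    if return_sigma:
        return noisy, sigmas
    return noisy
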