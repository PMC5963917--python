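"""Closed-form assay computations: ddCT relative expression, percent intron
retained, and log-linear half-life fitting."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def ddct_relative(
    ct_target_cond: float,
    ct_ref_cond: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative level 2^(-ddCT) with amplification efficiency fixed at 2.

    dCT = ct_target - ct_ref per condition; ddCT = dCT_cond - dCT_ctrl.
    """
    for ct in (ct_target_cond, ct_ref_cond, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(ct):
            raise ValueError("CT values must be finite")
    ddct = (ct_target_cond - ct_ref_cond) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def percent_retained(retained_level: float, total_level: float) -> float:
    """100 * retained / total."""
    if total_level <= 0:
        raise ValueError("undefined: total level must be positive")
    if retained_level < 0:
        raise ValueError("retained level must be non-negative")
    return 100.0 * retained_level / total_level


@dataclass
class HalfLifeFit:
    t_half: float | None  # hours; None when no decay
    slope: float
    intercept: float
    r_squared: float
    no_decay: bool


def half_life_fit(times, levels) -> HalfLifeFit:
    """Least-squares fit of ln(level) vs time; t_half = ln2 / |slope|.

    A non-negative slope is flagged ``no_decay`` with undefined t_half.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(levels, dtype=float)
    if len(t) < 3:
        raise ValueError("need >= 3 timepoints")
    if np.any(y <= 0):
        raise ValueError("levels must be positive")
    ln_y = np.log(y)
    slope, intercept = np.polyfit(t, ln_y, 1)
    fitted = slope * t + intercept
    ss_res = float(((ln_y - fitted) ** 2).sum())
    ss_tot = float(((ln_y - ln_y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if slope >= 0:
        return HalfLifeFit(None, float(slope), float(intercept), r2, True)
    return HalfLifeFit(math.log(2) / abs(slope), float(slope), float(intercept), r2, False)
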