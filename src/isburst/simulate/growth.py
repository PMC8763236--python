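"""Two-phase batch growth curves: exponential growth to a breakpoint, then a
continuous linear extension (the phase structure typical of dense
cyanobacterial batch cultures under light/carbon limitation)."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def simulate_growth_curve(
    a: float = 0.001,
    r: float = 0.0163,
    m: float = 0.00135,
    t_break: float = 400.0,
    b: float | None = None,
    noise_sd: float = 0.0,
    timepoints: np.ndarray | list[float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """OD(t) = a e^{rt} for t <= t_break, b + m t after (b chosen for
    continuity unless given). Default rates are an exponential OD increase of
    e^{0.0163 t} and a linear increase of 0.00135 OD/h, measured every 48 h.
    Gaussian noise of SD ``noise_sd`` is added; negative values clip to 0
    with a warning. Returns columns (time_h, od).
    """
    if timepoints is None:
        timepoints = np.arange(0.0, 800.0 + 1, 48.0)
    t = np.asarray(timepoints, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (t.min() <= t_break <= t.max()):
        raise ValueError("t_break must lie within the timepoint range")
    if b is None:
        b = a * np.exp(r * t_break) - m * t_break
    od = np.where(t <= t_break, a * np.exp(r * t), b + m * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, size=len(t))
    if (od < 0).any():
        warnings.warn("negative OD after noise; clipping to 0", stacklevel=2)
        od = np.clip(od, 0.0, None)
    return pd.DataFrame({"time_h": t, "od": od})
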