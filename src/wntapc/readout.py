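"""Power-law mapping from total beta-catenin to TCF reporter activity.

Relative TCF activity is modelled as a power of the relative detectable
beta-catenin level, ``T_rel = (B_detect,mut / B_detect,WT) ** a``, with the
wild-type untreated cell as the unit point.  The exponent ``a`` defaults to
1.51, the value obtained by fitting paired (beta-catenin ratio, TCF ratio)
measurements across expression mutants; :func:`fit_power_exponent`
reproduces that fit on any such panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["DEFAULT_EXPONENT", "DEFAULT_LAMBDA", "TcfParams", "tcf_relative", "fit_power_exponent"]

DEFAULT_EXPONENT = 1.51
#: scale translating molar beta-catenin into the calibration assay's
#: measurement units; used only when emulating that assay.
DEFAULT_LAMBDA = 2.2e4


@dataclass(frozen=True)
class TcfParams:
    a: float = DEFAULT_EXPONENT
    lam: float = DEFAULT_LAMBDA

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError(f"power-law exponent must be positive, got {self.a}")


def tcf_relative(b_detect_mut: float, b_detect_wt: float, a: float = DEFAULT_EXPONENT) -> float:
    """TCF activity of a cell relative to untreated wild type.

    Both arguments are detectable beta-catenin concentrations (free plus
    complex-bound, molar) and must be positive.
    """
    if not (b_detect_mut > 0 and b_detect_wt > 0):
        raise ValueError(
            f"beta-catenin levels must be positive, got {b_detect_mut!r}, {b_detect_wt!r}"
        )
    return math.exp(a * math.log(b_detect_mut / b_detect_wt))


def fit_power_exponent(pairs: Iterable[Sequence[float]]) -> float:
    """Fit the exponent of ``tcf_ratio = beta_ratio ** a`` from paired ratios.

    Least squares in log-log space through the origin: the wild type sits at
    (1, 1) exactly, so the model has no intercept.  Requires at least one
    pair with ``beta_ratio != 1``; degenerate input (all ratios 1) leaves the
    exponent unidentified and raises.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("pairs must be a nonempty sequence of (beta_ratio, tcf_ratio)")
    if np.any(arr <= 0):
        raise ValueError("all ratios must be positive")
    x = np.log(arr[:, 0])
    y = np.log(arr[:, 1])
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("degenerate input: every beta_ratio equals 1, exponent unidentified")
    return float(x @ y / sxx)
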