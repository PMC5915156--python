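"""Bead standard curve: mapping forward scatter to physical size (um).

Calibration beads of known diameter (1-15 um) are run on the cytometer; the
standard curve is an ordinary least-squares line in log(FSC)-log(size)
space, the usual choice for bead scatter calibration where FSC grows as an
approximate power law of particle size. A linear-in-FSC mode is available
behind a flag for instruments already linearized upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, InputError

__all__ = ["CalibrationCurve", "fit_bead_curve", "fsc_to_size"]


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares standard curve with its fit diagnostics.

    For the default log-log form, ``size = exp(intercept + slope*log(fsc))``;
    for the linear form, ``size = intercept + slope*fsc``.
    """

    slope: float
    intercept: float
    r_squared: float
    size_range_um: Tuple[float, float]
    log_log: bool = True

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "size_range_um": list(self.size_range_um),
            "form": "log-log" if self.log_log else "linear",
        }


def fit_bead_curve(beads: pd.DataFrame, log_log: bool = True) -> CalibrationCurve:
    """Fit the standard curve to a bead table with columns (size_um, fsc).

    Requires >= 3 beads with strictly increasing sizes and positive FSC, and
    FSC monotone increasing with size (otherwise the inverse mapping would
    be ambiguous).
    """
    if not {"size_um", "fsc"}.issubset(beads.columns):
        raise InputError("bead table needs columns 'size_um' and 'fsc'")
    sizes = np.asarray(beads["size_um"], dtype=float)
    fsc = np.asarray(beads["fsc"], dtype=float)
    if sizes.size < 3:
        raise InputError(f"need at least 3 beads, got {sizes.size}")
    if np.any(np.diff(sizes) <= 0):
        raise InputError("bead sizes must be strictly increasing")
    if np.any(fsc <= 0):
        raise InputError("bead FSC values must be positive")
    if np.any(np.diff(fsc) <= 0):
        raise CalibrationError(
            "bead FSC is not monotone increasing with size; curve would be ambiguous"
        )
    if log_log:
        res = stats.linregress(np.log(fsc), np.log(sizes))
    else:
        res = stats.linregress(fsc, sizes)
    if res.slope <= 0:
        raise CalibrationError("fitted slope is non-positive; calibration rejected")
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        size_range_um=(float(sizes.min()), float(sizes.max())),
        log_log=log_log,
    )


def fsc_to_size(
    fsc: Union[float, np.ndarray], curve: CalibrationCurve
) -> Tuple[Union[float, np.ndarray], Union[bool, np.ndarray]]:
    """Convert FSC to size in um; returns (size, extrapolated flag).

    Sizes outside the bead range are still returned but flagged as
    extrapolated — never silently.
    """
    x = np.asarray(fsc, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise InputError("fsc values must be finite and > 0")
    if curve.log_log:
        size = np.exp(curve.intercept + curve.slope * np.log(x))
    else:
        size = curve.intercept + curve.slope * x
    lo, hi = curve.size_range_um
    # Relative tolerance absorbs exp/log round-trip noise at the range edges.
    extrapolated = (size < lo * (1 - 1e-9)) | (size > hi * (1 + 1e-9))
    if scalar:
        return float(size[0]), bool(extrapolated[0])
    return size, extrapolated
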