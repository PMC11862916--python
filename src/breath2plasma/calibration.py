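"""Signal-intensity to gas-concentration calibration.

The instrument response is an upward-opening quadratic in concentration
(adsorption saturates at low concentration), so the map is
``signal = c0 + c1*x + c2*x^2`` with x in ppbv.  Inversion takes the positive
root.  LOD/LOQ are bookkept on the curve; sub-LOD inversions are flagged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .errors import CalibrationError, OutOfRangeError
from .units import convert_units  # noqa: F401  (re-exported: unit handling lives with calibration)

DEFAULT_LOD_PPBV = 0.04
DEFAULT_LOQ_PPBV = 0.12
DEFAULT_ANALYTE_MZ = 177.6

#: tolerated extrapolation beyond the standards' range, as a fraction of span
EXTRAPOLATION_FRACTION = 0.10


@dataclass(frozen=True)
class CalibrationCurve:
    """Quadratic signal(concentration) map with LOD/LOQ metadata."""

    c0: float
    c1: float
    c2: float
    valid_range: Tuple[float, float]
    lod: float = DEFAULT_LOD_PPBV
    loq: float = DEFAULT_LOQ_PPBV
    r_squared: float = float("nan")
    analyte_mz: float = DEFAULT_ANALYTE_MZ

    def __post_init__(self):
        lo, hi = self.valid_range
        if not lo < hi:
            raise CalibrationError("valid_range must be (low, high) with low < high")
        if not self.c1 > 0:
            raise CalibrationError("linear coefficient c1 must be positive")
        # quadratic derivative is linear: endpoint checks suffice for monotonicity
        if self.c1 + 2 * self.c2 * lo <= 0 or self.c1 + 2 * self.c2 * hi <= 0:
            raise CalibrationError("curve is not strictly increasing on valid_range")
        if not self.lod < self.loq:
            raise CalibrationError("LOD must be below LOQ")

    def signal(self, concentration_ppbv):
        x = np.asarray(concentration_ppbv, dtype=float)
        out = self.c0 + self.c1 * x + self.c2 * x * x
        return float(out) if out.ndim == 0 else out

    def to_json(self) -> str:
        d = asdict(self)
        d["lod_ppbv"] = d.pop("lod")
        d["loq_ppbv"] = d.pop("loq")
        d["range"] = list(d.pop("valid_range"))
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationCurve":
        d = json.loads(text)
        return cls(
            c0=d["c0"],
            c1=d["c1"],
            c2=d["c2"],
            valid_range=tuple(d["range"]),
            lod=d["lod_ppbv"],
            loq=d["loq_ppbv"],
            r_squared=d.get("r_squared", float("nan")),
            analyte_mz=d.get("analyte_mz", DEFAULT_ANALYTE_MZ),
        )


def fit_calibration(
    standards: Iterable[Tuple[float, float]],
    lod: float = DEFAULT_LOD_PPBV,
    loq: float = DEFAULT_LOQ_PPBV,
) -> CalibrationCurve:
    """Least-squares quadratic through (concentration ppbv, signal) standards."""
    pts = [(float(x), float(y)) for x, y in standards]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.unique(xs).size < 4:
        raise CalibrationError("need at least 4 distinct standard concentrations")
    c0, c1, c2 = np.polynomial.polynomial.polyfit(xs, ys, 2)
    fitted = c0 + c1 * xs + c2 * xs * xs
    sst = float(np.sum((ys - ys.mean()) ** 2))
    ssr = float(np.sum((ys - fitted) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - ssr / sst
    return CalibrationCurve(
        c0=float(c0),
        c1=float(c1),
        c2=float(c2),
        valid_range=(float(xs.min()), float(xs.max())),
        lod=lod,
        loq=loq,
        r_squared=r2,
    )


def signal_to_concentration(
    curve: CalibrationCurve, signal: float
) -> Tuple[float, bool]:
    """Invert the calibration curve; returns (concentration ppbv, below_lod).

    Signals below the zero-concentration response clamp to 0 ppbv (flagged
    below-LOD).  Inversions up to 10% of the span beyond the standards' range
    warn; farther out they raise OutOfRangeError.
    """
    if abs(curve.c2) < 1e-300:
        x = (signal - curve.c0) / curve.c1
    else:
        disc = curve.c1 ** 2 - 4.0 * curve.c2 * (curve.c0 - signal)
        if disc < 0:
            raise OutOfRangeError(f"signal {signal} has no real inverse on this curve")
        x = (-curve.c1 + np.sqrt(disc)) / (2.0 * curve.c2)
    if x < 0:
        return 0.0, True  # below zero-concentration response: physically zero
    lo, hi = curve.valid_range
    margin = EXTRAPOLATION_FRACTION * (hi - lo)
    if x > hi + margin or x < lo - margin:
        raise OutOfRangeError(
            f"inverted concentration {x:.4g} ppbv is outside the trusted range "
            f"[{max(lo - margin, 0):.4g}, {hi + margin:.4g}]"
        )
    eps = 1e-9 * (hi - lo)  # roundoff guard at the range boundaries
    # the sub-LOD regime below the lowest standard is flagged, not warned about
    if x > hi + eps:
        warnings.warn(
            f"concentration {x:.4g} ppbv extrapolates beyond calibration range ({lo}, {hi})",
            stacklevel=2,
        )
    return float(x), bool(x < curve.lod)


def estimate_lod_loq(
    blank_signals: Sequence[float], curve: CalibrationCurve
) -> Tuple[float, float]:
    """Blank-based LOD/LOQ: (mean + 3 sd)/slope-at-origin, 10 sd for LOQ."""
    blanks = np.asarray(blank_signals, dtype=float)
    if blanks.size < 2:
        raise CalibrationError("need at least 2 blank measurements")
    mean, sd = float(blanks.mean()), float(blanks.std(ddof=1))
    lod = (mean + 3.0 * sd) / curve.c1
    loq = (mean + 10.0 * sd) / curve.c1
    return lod, loq
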