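"""Series container, LOD censoring and breath/plasma pairing.

The censoring rule: values below the detection limit are zeroed (and kept)
before the observed peak, and excluded from all downstream computation at or
after the peak.  Pairing anchors on the sparse plasma schedule and picks the
nearest breath sample within a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence

import numpy as np

from .errors import DataError, PairingError
from .units import convert_units

# censor flag vocabulary
OBSERVED = "observed"
BELOW_LOD_ZEROED = "below_lod_zeroed"
EXCLUDED = "excluded"

FLAGS = (OBSERVED, BELOW_LOD_ZEROED, EXCLUDED)

#: default pairing tolerance: half the 20-s breath sampling interval, minutes
DEFAULT_PAIR_TOLERANCE = 1.0 / 6.0


@dataclass
class ConcentrationSeries:
    """One matrix's time course for one subject.

    Times are minutes, strictly increasing.  ``flags`` records the censoring
    state per point so that censoring is an audit trail, not a deletion.
    """

    subject_id: str
    matrix: str  # "breath" | "plasma"
    times: np.ndarray
    values: np.ndarray
    unit: str
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.flags is None:
            self.flags = np.full(self.times.shape, OBSERVED, dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise DataError("times and values must be 1-D arrays of equal length")
        if self.flags.shape != self.times.shape:
            raise DataError("flags must match times in length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise DataError(f"times not strictly increasing for {self.subject_id}/{self.matrix}")
        if self.matrix not in ("breath", "plasma"):
            raise DataError(f"unknown matrix {self.matrix!r}")
        bad = set(self.flags) - set(FLAGS)
        if bad:
            raise DataError(f"unknown censor flags {sorted(bad)}")
        observed = self.flags == OBSERVED
        if np.any(self.values[observed] < 0):
            raise DataError(f"negative observed concentration in {self.subject_id}/{self.matrix}")

    def __len__(self) -> int:
        return self.times.size

    def usable_mask(self) -> np.ndarray:
        """Points that enter fitting: observed or zeroed, strictly post-dose."""
        retained = self.flags != EXCLUDED
        return retained & (self.times > 0)

    def fit_points(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.usable_mask()
        return self.times[m], self.values[m]

    def observed_mask(self) -> np.ndarray:
        return (self.flags == OBSERVED) & (self.times > 0)


def censor_series(series: ConcentrationSeries, lod: float) -> ConcentrationSeries:
    """Apply the LOD rule and return a new series with updated flags.

    Sub-LOD points strictly before the raw-value argmax are zeroed and kept;
    sub-LOD points at or after the argmax are excluded.  Points already
    excluded stay excluded.
    """
    if len(series) == 0:
        raise DataError("cannot censor an empty series")
    values = series.values.copy()
    flags = series.flags.copy()
    peak_idx = int(np.argmax(series.values))  # earliest maximum of the raw trace
    below = series.values < lod
    for i in np.flatnonzero(below):
        if flags[i] == EXCLUDED:
            continue
        if i < peak_idx:
            values[i] = 0.0
            flags[i] = BELOW_LOD_ZEROED
        else:
            flags[i] = EXCLUDED
    return replace(series, values=values, flags=flags)


@dataclass(frozen=True)
class MatchedPair:
    """A time-matched (breath, plasma) observation in pptv / ng/mL."""

    time: float
    ce: float  # breath concentration, pptv
    cp: float  # plasma concentration, ng/mL

    def __post_init__(self):
        if not (self.ce > 0 and self.cp > 0):
            raise DataError("matched pairs require positive concentrations")


def pair_matrices(
    breath: ConcentrationSeries,
    plasma: ConcentrationSeries,
    tolerance: float = DEFAULT_PAIR_TOLERANCE,
) -> List[MatchedPair]:
    """Pair each plasma draw with the nearest breath sample within tolerance.

    Plasma is the anchor; censored or non-positive points on either side never
    produce a pair.  Ties in distance resolve to the earlier breath time.
    Output units are normalized to pptv (breath) and ng/mL (plasma).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    bm = breath.observed_mask() & (breath.values > 0)
    bt, bv = breath.times[bm], breath.values[bm]
    pm = plasma.observed_mask() & (plasma.values > 0)
    pairs: List[MatchedPair] = []
    for t, cp in zip(plasma.times[pm], plasma.values[pm]):
        if bt.size == 0:
            break
        dist = np.abs(bt - t)
        j = int(np.argmin(dist))  # argmin returns the first (earlier) minimum
        if dist[j] > tolerance + 1e-12:
            continue
        pairs.append(
            MatchedPair(
                time=float(t),
                ce=convert_units(float(bv[j]), breath.unit, "pptv"),
                cp=convert_units(float(cp), plasma.unit, "ng/mL"),
            )
        )
    if not pairs:
        raise PairingError(
            f"no breath/plasma pairs within {tolerance} min for {plasma.subject_id}"
        )
    return pairs


def pairs_from_records(records: Sequence, tolerance: float = DEFAULT_PAIR_TOLERANCE):
    """Pool pairs across subject records (objects with .breath/.plasma)."""
    pooled: List[MatchedPair] = []
    for rec in records:
        try:
            pooled.extend(pair_matrices(rec.breath, rec.plasma, tolerance))
        except PairingError:
            continue
    return pooled
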