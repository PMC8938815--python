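"""Quantitative-ultrasound spectral response values.

The spectra produced by the frequency sweep are reduced to scalar response
values used to differentiate duct pathologies:

* **peak density** — the total count of interior peaks and valleys in the
  magnitude-vs-frequency spectrum;
* **MPVD** (mean peak-to-valley distance) — the average absolute magnitude
  difference between adjacent peak/valley pairs;
* spectral features — peak pressure magnitude and its frequency, overall
  (mean) magnitude, and a jaggedness measure (mean absolute successive
  difference).

Extremum detection uses strict inequalities against both neighbours; a plateau
(run of equal values) collapses to a single extremum at the run's midpoint when
both run neighbours lie below (peak) or above (valley) it.  The first and last
grid points are never extrema.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExtremaList",
    "MetricsResult",
    "GroupSummary",
    "find_extrema",
    "peak_density",
    "mpvd",
    "spectral_features",
    "summarize",
    "summaries_to_frame",
]

_MODE_CHANNEL = {"pulse_echo": "front_abs", "pitch_catch": "back_abs"}


@dataclass(frozen=True)
class ExtremaList:
    """Interior extrema of a sampled spectrum, alternating peak/valley."""

    indices: tuple[int, ...]
    kinds: tuple[str, ...]  # "peak" | "valley"

    def __post_init__(self):
        if len(self.indices) != len(self.kinds):
            raise ValueError("indices and kinds must have equal length")
        if any(b <= a for a, b in zip(self.indices, self.indices[1:])):
            raise ValueError("extrema indices must be strictly increasing")
        if any(a == b for a, b in zip(self.kinds, self.kinds[1:])):
            raise ValueError("peaks and valleys must alternate")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class MetricsResult:
    """Scalar response values of one spectrum channel."""

    peak_density: int
    mpvd: float | None
    peak_frequency: float
    peak_magnitude: float
    overall_magnitude: float
    jaggedness: float


@dataclass(frozen=True)
class GroupSummary:
    """Mean/SD of each response value over duct positions for one pathology+mode."""

    pathology: str
    mode: str
    mean: dict[str, float]
    sd: dict[str, float]
    n: int


def _channel(spectrum, mode: str) -> np.ndarray:
    try:
        attr = _MODE_CHANNEL[mode]
    except KeyError:
        raise ValueError(
            f"mode must be one of {sorted(_MODE_CHANNEL)}, got {mode!r}"
        ) from None
    return np.asarray(getattr(spectrum, attr), dtype=float)


def find_extrema(values: Sequence[float]) -> ExtremaList:
    """Locate interior peaks and valleys of a sampled curve.

    A point is a peak (valley) if it is strictly greater (less) than both
    neighbours.  Runs of equal values count as one extremum at the run midpoint
    if both run neighbours lie on the same side.  Endpoints are excluded.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise ValueError("need a 1D sequence of length >= 3")

    idx: list[int] = []
    kinds: list[str] = []
    n = len(v)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        # run v[i..j]; interior only
        if i > 0 and j < n - 1:
            left, right = v[i - 1], v[j + 1]
            if left < v[i] and right < v[i]:
                idx.append((i + j) // 2)
                kinds.append("peak")
            elif left > v[i] and right > v[i]:
                idx.append((i + j) // 2)
                kinds.append("valley")
        i = j + 1
    return ExtremaList(tuple(idx), tuple(kinds))


def peak_density(spectrum, mode: str) -> int:
    """Total count of peaks and valleys in the selected spectrum channel."""
    return len(find_extrema(_channel(spectrum, mode)))


def mpvd(spectrum, mode: str) -> float:
    """Mean absolute magnitude difference between adjacent peak/valley pairs.

    Raises ``ValueError`` when the channel has fewer than two extrema (the
    quantity is undefined there; it is never silently reported as zero).
    """
    v = _channel(spectrum, mode)
    ex = find_extrema(v)
    if len(ex) < 2:
        raise ValueError(
            f"MPVD undefined: spectrum has {len(ex)} extrema (need at least 2)"
        )
    mags = v[list(ex.indices)]
    return float(np.mean(np.abs(np.diff(mags))))


def spectral_features(spectrum, mode: str) -> MetricsResult:
    """Bundle all response values for one spectrum channel."""
    v = _channel(spectrum, mode)
    f = np.asarray(spectrum.frequencies, dtype=float)
    if len(f) != len(v):
        raise ValueError("frequency grid and channel lengths differ")
    ex = find_extrema(v)
    imax = int(np.argmax(v))  # argmax takes the lowest index on ties
    return MetricsResult(
        peak_density=len(ex),
        mpvd=(
            float(np.mean(np.abs(np.diff(v[list(ex.indices)]))))
            if len(ex) >= 2
            else None
        ),
        peak_frequency=float(f[imax]),
        peak_magnitude=float(v[imax]),
        overall_magnitude=float(np.mean(v)),
        jaggedness=float(np.mean(np.abs(np.diff(v)))),
    )


def summarize(
    results: Sequence[MetricsResult], pathology: str, mode: str
) -> GroupSummary:
    """Per-metric mean and sample SD (n-1) over duct positions."""
    if len(results) == 0:
        raise ValueError("cannot summarize an empty result list")
    if len(results) == 1:
        warnings.warn("single-position summary: SD reported as 0", stacklevel=2)

    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for fld in fields(MetricsResult):
        vals = [getattr(r, fld.name) for r in results]
        if any(v is None for v in vals):
            mean[fld.name] = math.nan
            sd[fld.name] = math.nan
            continue
        arr = np.asarray(vals, dtype=float)
        mean[fld.name] = float(arr.mean())
        sd[fld.name] = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return GroupSummary(pathology=pathology, mode=mode, mean=mean, sd=sd, n=len(results))


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Tidy table: one row per pathology x mode, mean/sd columns per metric."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"pathology": s.pathology, "mode": s.mode, "n": s.n}
        for k, v in s.mean.items():
            row[f"{k}_mean"] = v
        for k, v in s.sd.items():
            row[f"{k}_sd"] = v
        rows.append(row)
    return pd.DataFrame(rows)
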