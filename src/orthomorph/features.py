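"""The three postural SBP features: early phase, stabilization point, late phase.

Each feature is the SBP shift from the supine baseline, expressed both as a
percentage of baseline (the clustering space) and in mmHg:

* early phase  — nadir of trailing 2-s means within the first 15 s of standing
  (the initial-orthostatic-hypotension window);
* stabilization point — 5-s mean centred on 40 s (impaired early stabilization);
* late phase   — minimum 10-s rolling mean over 60-120 s (sustained deficit,
  the classic-orthostatic-hypotension window).

Drops are negative, rises positive. Ties in either nadir search resolve to the
earliest occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_prep import (
    BASELINE_WINDOW,
    CoverageError,
    Recording,
    UniformSeries,
    compute_baseline,
    interpolate_uniform,
)

__all__ = [
    "FeatureVector",
    "windowed_mean",
    "early_phase_delta",
    "stabilization_delta",
    "late_phase_delta",
    "extract_features",
    "features_to_frame",
    "frame_to_matrix",
    "FEATURE_PCT_COLUMNS",
]

#: full analysis window each recording must cover
ANALYSIS_WINDOW = (BASELINE_WINDOW[0], 120.0)

FEATURE_PCT_COLUMNS = ["early_pct", "stab_pct", "late_pct"]
FEATURE_MMHG_COLUMNS = ["early_mmhg", "stab_mmhg", "late_mmhg"]


@dataclass
class FeatureVector:
    """Per-participant clustering features (Δ% and ΔmmHg twins plus baseline)."""

    participant_id: str
    baseline: float
    early_pct: float
    stab_pct: float
    late_pct: float
    early_mmhg: float
    stab_mmhg: float
    late_mmhg: float

    def as_array(self) -> np.ndarray:
        """The three Δ% coordinates used for clustering."""
        return np.array([self.early_pct, self.stab_pct, self.late_pct])


def windowed_mean(series: UniformSeries, span: tuple[float, float]) -> float:
    """Mean of grid values in the half-open span [a, b)."""
    return float(np.mean(series.window(*span)))


def _delta(value: float, baseline: float) -> tuple[float, float]:
    mmhg = value - baseline
    return 100.0 * mmhg / baseline, mmhg


def early_phase_delta(series: UniformSeries, baseline: float,
                      width: float = 2.0, t_max: float = 15.0) -> tuple[float, float]:
    """Nadir of trailing ``width``-s means ending at each grid point in (0, t_max].

    Returns (Δ%, ΔmmHg) of the nadir relative to baseline.
    """
    ends = np.arange(1.0, t_max + 0.5)
    means = [windowed_mean(series, (end - width + 1.0, end + 1.0)) for end in ends]
    nadir = min(means)  # earliest wins ties: min() keeps first minimum
    return _delta(nadir, baseline)


def stabilization_delta(series: UniformSeries, baseline: float,
                        center: float = 40.0, width: float = 5.0) -> tuple[float, float]:
    """Δ of the ``width``-s mean centred on ``center`` (grid points 38..42 by default)."""
    half = (width - 1.0) / 2.0
    value = windowed_mean(series, (center - half, center + half + 1.0))
    return _delta(value, baseline)


def late_phase_delta(series: UniformSeries, baseline: float,
                     window: tuple[float, float] = (60.0, 120.0),
                     width: float = 10.0) -> tuple[float, float]:
    """Minimum 10-s rolling mean over windows [s, s+10) fully inside 60-120 s."""
    a, b = window
    starts = np.arange(a, b - width + 0.5)
    means = [windowed_mean(series, (s, s + width)) for s in starts]
    nadir = min(means)
    return _delta(nadir, baseline)


def extract_features(rec: Recording) -> FeatureVector:
    """Compose baseline and the three feature deltas for one recording.

    Deterministic: the same recording always yields a bit-identical vector.
    Coverage errors from any window propagate unchanged.
    """
    series = interpolate_uniform(rec, ANALYSIS_WINDOW)
    baseline = compute_baseline(series)
    e_pct, e_mmhg = early_phase_delta(series, baseline)
    s_pct, s_mmhg = stabilization_delta(series, baseline)
    l_pct, l_mmhg = late_phase_delta(series, baseline)
    return FeatureVector(
        participant_id=rec.participant_id,
        baseline=baseline,
        early_pct=e_pct,
        stab_pct=s_pct,
        late_pct=l_pct,
        early_mmhg=e_mmhg,
        stab_mmhg=s_mmhg,
        late_mmhg=l_mmhg,
    )


def features_to_frame(fvs: list[FeatureVector]) -> pd.DataFrame:
    """Feature table (round-trip stable through CSV) indexed by participant."""
    df = pd.DataFrame([vars(fv) for fv in fvs])
    return df.set_index("participant_id")


def frame_to_matrix(df: pd.DataFrame) -> np.ndarray:
    """The n x 3 Δ% clustering matrix from a feature table."""
    return df[FEATURE_PCT_COLUMNS].to_numpy(dtype=float)
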