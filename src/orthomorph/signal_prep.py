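"""Reading, quality screening and regularization of beat-to-beat recordings.

A recording is one participant's active stand test: per-heartbeat systolic and
diastolic pressures with inter-beat (RR) intervals, time-stamped in seconds
relative to the moment of standing up (t = 0; negative times are supine).
Supine baseline pressure is defined as the mean over the window 60-30 s before
stand onset, chosen to avoid both motion noise and anticipatory pressure rises.

All windows are half-open ``[a, b)`` and the uniform grid sits on integer
seconds, so window membership is never ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "UniformSeries",
    "QualityConfig",
    "QualityFlag",
    "QualityReport",
    "RestingIndices",
    "read_recording",
    "write_recording",
    "screen_quality",
    "interpolate_uniform",
    "compute_baseline",
    "resting_indices",
    "CoverageError",
]

#: baseline window (seconds relative to stand onset), half-open
BASELINE_WINDOW = (-60.0, -30.0)


class CoverageError(ValueError):
    """Raised when beats do not cover a requested analysis window."""


@dataclass
class Recording:
    """One participant's beat-indexed recording with stand onset at t = 0.

    Parameters
    ----------
    participant_id:
        Identifier used throughout the pipeline.
    t:
        Beat times in seconds relative to stand onset, strictly increasing.
    sbp, dbp:
        Systolic / diastolic pressure (mmHg) for the beat ending at ``t``.
    rr:
        Inter-beat interval (s) ending at ``t``.
    """

    participant_id: str
    t: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        n = self.t.size
        if n == 0:
            raise ValueError("recording has no beats")
        if not (self.sbp.size == self.dbp.size == self.rr.size == n):
            raise ValueError("beat arrays must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.dbp <= 0) or np.any(self.sbp <= self.dbp):
            raise ValueError("require sbp > dbp > 0 for every beat")
        if np.any(self.rr <= 0):
            raise ValueError("require rr > 0 for every beat")

    @property
    def supine_span(self) -> float:
        """Seconds of recording available before stand onset."""
        return max(0.0, -float(self.t[0]))

    @property
    def stand_span(self) -> float:
        """Seconds of recording available after stand onset."""
        return max(0.0, float(self.t[-1]))

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass
class UniformSeries:
    """SBP resampled onto a uniform 1-s grid starting at integer second ``t0``."""

    t0: float
    values: np.ndarray
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-d array")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("uniform series may not contain missing values")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.grid_step * np.arange(self.values.size)

    def window(self, a: float, b: float) -> np.ndarray:
        """Grid values with t in the half-open window [a, b)."""
        t = self.times
        mask = (t >= a) & (t < b)
        expected = int(round((b - a) / self.grid_step))
        if mask.sum() != expected:
            raise CoverageError(f"series does not cover window [{a}, {b})")
        return self.values[mask]


@dataclass
class QualityConfig:
    """Thresholds for the quality screen (stand-in rules; see docs/methods.md)."""

    flatline_sd: float = 0.1     # mmHg; SD below this over flatline_span is a flatline
    flatline_span: float = 10.0  # s
    spike_delta: float = 40.0    # mmHg jump vs both neighbours, with reversion
    gap_max: float = 3.0         # s without a beat
    min_supine: float = 60.0     # s
    min_stand: float = 120.0     # s


@dataclass
class QualityFlag:
    kind: str                    # flatline | spike | gap | calibration_step | short_phase
    span: tuple[float, float]


@dataclass
class QualityReport:
    passed: bool
    flags: list[QualityFlag] = field(default_factory=list)


@dataclass
class RestingIndices:
    """Supine resting cardiovascular indices (baseline window 60-30 s pre-stand)."""

    sbp: float
    dbp: float
    pp: float
    map: float
    hr: float
    rr_30_15: float


# ---------------------------------------------------------------------------
# I/O: one delimited text file per participant, columns
# t_sec,sbp_mmhg,dbp_mmhg,rr_sec with a "# stand_onset=0" header line.

_COLUMNS = ["t_sec", "sbp_mmhg", "dbp_mmhg", "rr_sec"]


def read_recording(path, participant_id: str | None = None, sep: str = ",") -> Recording:
    """Parse one beat-to-beat recording file.

    Malformed rows raise a parse error naming the line; non-monotone beat
    times raise a validation error from :class:`Recording`.
    """
    path = str(path)
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(sep)]
            if header is None:
                if parts != _COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {','.join(_COLUMNS)}"
                    )
                header = parts
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
    if header is None or not rows:
        raise ValueError(f"{path}: no beat rows found")
    arr = np.asarray(rows, dtype=float)
    if participant_id is None:
        import os

        participant_id = os.path.splitext(os.path.basename(path))[0]
    return Recording(participant_id, arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


def write_recording(rec: Recording, path, sep: str = ",") -> None:
    """Write a recording in the dialect read by :func:`read_recording`."""
    df = pd.DataFrame(
        {"t_sec": rec.t, "sbp_mmhg": rec.sbp, "dbp_mmhg": rec.dbp, "rr_sec": rec.rr}
    )
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("# stand_onset=0\n")
        df.to_csv(fh, sep=sep, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Quality screening


def screen_quality(rec: Recording, cfg: QualityConfig | None = None) -> QualityReport:
    """Deterministic rule-based quality screen.

    Three signal rules (flatline, spike, calibration step), a beat-gap rule
    and a phase-coverage rule. A recording passes iff no rule fires.
    """
    cfg = cfg or QualityConfig()
    flags: list[QualityFlag] = []

    if rec.supine_span < cfg.min_supine or rec.stand_span < cfg.min_stand:
        flags.append(QualityFlag("short_phase", (float(rec.t[0]), float(rec.t[-1]))))

    # gaps between consecutive beats
    dt = np.diff(rec.t)
    for i in np.nonzero(dt > cfg.gap_max)[0]:
        flags.append(QualityFlag("gap", (float(rec.t[i]), float(rec.t[i + 1]))))

    # flatline: SBP SD below tolerance over any span of >= flatline_span seconds
    t, sbp = rec.t, rec.sbp
    j = 0
    reported_until = -np.inf
    for i in range(len(rec)):
        while j < len(rec) and t[j] < t[i] + cfg.flatline_span:
            j += 1
        # need the window to actually span flatline_span seconds of signal
        if j < len(rec) and j - i >= 3:
            if np.std(sbp[i:j + 1]) < cfg.flatline_sd and t[i] >= reported_until:
                flags.append(QualityFlag("flatline", (float(t[i]), float(t[j]))))
                reported_until = t[j]

    # spikes (single-beat excursion, reverting) and calibration steps (sustained)
    for i in range(1, len(rec) - 1):
        d_prev = sbp[i] - sbp[i - 1]
        d_next = sbp[i] - sbp[i + 1]
        if abs(d_prev) > cfg.spike_delta:
            if abs(d_next) > cfg.spike_delta and np.sign(d_prev) == np.sign(d_next):
                flags.append(QualityFlag("spike", (float(t[i - 1]), float(t[i + 1]))))
            elif abs(sbp[i + 1] - sbp[i]) < cfg.spike_delta / 4:
                flags.append(
                    QualityFlag("calibration_step", (float(t[i - 1]), float(t[i])))
                )

    return QualityReport(passed=not flags, flags=flags)


# ---------------------------------------------------------------------------
# Resampling and baseline


def interpolate_uniform(rec: Recording, window: tuple[float, float],
                        signal: str = "sbp") -> UniformSeries:
    """Linearly interpolate beat values onto the integer-second grid in [a, b).

    No extrapolation: every grid point must lie between the first and last
    beat, otherwise a :class:`CoverageError` is raised.
    """
    a, b = window
    if b <= a:
        raise ValueError("window must satisfy a < b")
    grid = np.arange(np.ceil(a), b)  # integer grid points in [a, b)
    values = getattr(rec, signal)
    if grid[0] < rec.t[0] or grid[-1] > rec.t[-1]:
        raise CoverageError(
            f"beats cover [{rec.t[0]:.2f}, {rec.t[-1]:.2f}] but window "
            f"[{a}, {b}) was requested"
        )
    interp = np.interp(grid, rec.t, values)
    return UniformSeries(t0=float(grid[0]), values=interp)


def compute_baseline(series: UniformSeries) -> float:
    """Supine baseline SBP: mean of grid values with t in [-60, -30)."""
    return float(np.mean(series.window(*BASELINE_WINDOW)))


def resting_indices(rec: Recording) -> RestingIndices:
    """Resting indices from the supine baseline window plus the RR 30:15 ratio.

    MAP uses the standard one-third pulse-pressure estimate
    ``(SBP + 2 DBP) / 3``; HR is 60 over the mean RR interval in the window;
    the 30:15 ratio divides the RR interval of the beat nearest 30 s after
    standing by that of the beat nearest 15 s (heart-rate recovery marker).
    """
    sbp = compute_baseline(interpolate_uniform(rec, BASELINE_WINDOW))
    dbp = float(np.mean(
        interpolate_uniform(rec, BASELINE_WINDOW, signal="dbp").window(*BASELINE_WINDOW)
    ))
    a, b = BASELINE_WINDOW
    in_win = (rec.t >= a) & (rec.t < b)
    if not np.any(in_win):
        raise CoverageError("no beats inside the baseline window")
    hr = 60.0 / float(np.mean(rec.rr[in_win]))
    if rec.t[-1] < 30.0:
        raise CoverageError("no beats near t = 30 s for the RR 30:15 ratio")
    rr30 = float(rec.rr[np.argmin(np.abs(rec.t - 30.0))])
    rr15 = float(rec.rr[np.argmin(np.abs(rec.t - 15.0))])
    return RestingIndices(
        sbp=sbp,
        dbp=dbp,
        pp=sbp - dbp,
        map=(sbp + 2.0 * dbp) / 3.0,
        hr=hr,
        rr_30_15=rr30 / rr15,
    )
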