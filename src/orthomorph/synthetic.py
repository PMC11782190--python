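"""Synthetic active-stand cohorts with the statistical structure the analysis assumes.

The generator emulates four archetypal orthostatic SBP morphologies — initial
deficit (iOHYPO), sustained deficit (OHYPO), persistent rise (OHYPER) and the
normal orthostatic response (NOR) — each parameterized by the mean and SD of
the three Δ% features, a supine baseline distribution, heart rate and a
beat-level AR(1) noise model. Per-participant feature targets are drawn from
the archetype's Gaussian, a smooth standing curve is threaded through them,
and beats are laid down at stochastic RR intervals. Frailty indicators are
drawn per group from configurable prevalences.

The default archetype parameters and indicator prevalences equal the values a
clustered community cohort of older adults exhibits (supine ~116/70 mmHg,
HR ~70 bpm, the four morphologies' feature means/SDs, and per-group indicator
rates); see docs/methods.md for the full table and what the generator does
*not* emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .signal_prep import Recording

__all__ = [
    "ArchetypeParams",
    "SimConfig",
    "ARCHETYPES",
    "GROUP_PREVALENCES",
    "simulate_recording",
    "simulate_cohort",
    "draw_feature_matrix",
    "standing_curve",
]


@dataclass
class ArchetypeParams:
    name: str
    feature_means: tuple[float, float, float]   # early, stab, late Δ%
    feature_sds: tuple[float, float, float]
    baseline_mean: float                        # supine SBP mmHg
    baseline_sd: float
    pp_mean: float                              # SBP − DBP offset, mmHg
    hr_mean: float                              # beats/min
    nadir_time: float = 10.0                    # s, early-phase nadir
    beat_noise_sd: float = 2.0                  # mmHg, AR(1) innovation scale
    ar1: float = 0.8
    rr_sd: float = 0.05                         # s, beat-interval jitter

    def __post_init__(self) -> None:
        if any(sd <= 0 for sd in self.feature_sds) or self.baseline_sd < 0:
            raise ValueError("SDs must be positive")
        if not (2.0 < self.nadir_time < 14.0):
            raise ValueError("nadir time must lie inside the early window")


#: Defaults reproduce the per-group feature means/SDs, supine baselines,
#: pulse pressures and heart rates of the four morphologies.
ARCHETYPES: dict[str, ArchetypeParams] = {
    "iOHYPO": ArchetypeParams("iOHYPO", (-15.2, 0.7, 0.3), (9.3, 6.6, 7.3),
                              119.1, 18.7, 46.5, 70.3),
    "OHYPO": ArchetypeParams("OHYPO", (-35.6, -15.5, -13.4), (12.2, 9.5, 10.8),
                             115.6, 18.9, 46.8, 69.2),
    "OHYPER": ArchetypeParams("OHYPER", (2.2, 17.3, 15.6), (11.3, 9.6, 10.4),
                              111.2, 20.1, 43.6, 70.6),
    "NOR": ArchetypeParams("NOR", (-8.2, 1.6, 1.3), (7.4, 5.1, 5.3),
                           121.4, 19.6, 47.2, 70.7),
}

#: Per-group frailty indicator prevalences (fractions).
GROUP_PREVALENCES: dict[str, dict[str, float]] = {
    "adl_compromised":    {"iOHYPO": 0.201, "OHYPO": 0.192, "OHYPER": 0.315, "NOR": 0.276},
    "cognition_impaired": {"iOHYPO": 0.656, "OHYPO": 0.735, "OHYPER": 0.761, "NOR": 0.791},
    "fried_positive":     {"iOHYPO": 0.244, "OHYPO": 0.198, "OHYPER": 0.324, "NOR": 0.276},
    "slow_gait":          {"iOHYPO": 0.120, "OHYPO": 0.119, "OHYPER": 0.230, "NOR": 0.130},
    "balance_impaired":   {"iOHYPO": 0.057, "OHYPO": 0.057, "OHYPER": 0.113, "NOR": 0.055},
    "recent_fall":        {"iOHYPO": 0.177, "OHYPO": 0.181, "OHYPER": 0.225, "NOR": 0.252},
}

#: Per-group mixture proportions (final group sizes of the reference cohort).
DEFAULT_PROPORTIONS = {"iOHYPO": 0.245, "OHYPO": 0.208, "OHYPER": 0.250, "NOR": 0.297}

#: Per-group female proportion; cohort mean age 68.1 ± 7.2 years.
FEMALE_PROPORTION = {"iOHYPO": 0.506, "OHYPO": 0.446, "OHYPER": 0.657, "NOR": 0.537}


@dataclass
class SimConfig:
    n: int = 400
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    prevalences: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in GROUP_PREVALENCES.items()})
    seed: int = 0
    age_mean: float = 68.1
    age_sd: float = 7.2

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"mixture proportions must sum to 1, got {total}")
        for ind, per_group in self.prevalences.items():
            for g, p in per_group.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"prevalence out of range for {ind}/{g}")


def standing_curve(early: float, stab: float, late: float,
                   nadir_time: float = 10.0) -> PchipInterpolator:
    """Monotone-cubic Δ% curve through the feature control points.

    Flat plateaus are placed over each feature's read-out window — the
    early-phase nadir (nadir_time−1 to 15 s), the stabilization window
    (37-43 s) and the late phase (60-120 s) — so that the trailing-mean
    minimum, the centred 5-s mean and the minimum 10-s rolling mean each
    recover their target exactly on the 1-s grid. The curve starts at 0 at
    stand onset for deficit profiles and at the early target for profiles
    whose SBP never dips below baseline (a minimum-based feature cannot
    otherwise be above the onset value).
    """
    onset = max(0.0, early)
    t = [0.0, nadir_time - 1.0, 15.0, 37.0, 43.0, 60.0, 120.0, 150.0]
    v = [onset, early, early, stab, stab, late, late, late]
    return PchipInterpolator(t, v, extrapolate=True)


def simulate_recording(arch: ArchetypeParams, rng: np.random.Generator | int | None,
                       targets: tuple[float, float, float] | None = None,
                       baseline: float | None = None,
                       supine_span: float = 70.0,
                       stand_span: float = 125.0) -> Recording:
    """One synthetic beat-to-beat recording.

    Per-participant Δ% targets and the supine baseline are drawn from the
    archetype's Gaussians unless given explicitly. Supine SBP is baseline plus
    AR(1) beat noise; standing SBP follows the Δ% curve times baseline, plus
    the same noise process. DBP is SBP minus the archetype's pulse pressure
    (no independent DBP morphology). Deterministic for a fixed rng state.
    """
    rng = np.random.default_rng(rng)
    if targets is None:
        targets = tuple(rng.normal(arch.feature_means, arch.feature_sds))
    if baseline is None:
        baseline = float(rng.normal(arch.baseline_mean, arch.baseline_sd))
    baseline = max(baseline, 70.0)
    curve = standing_curve(*targets, nadir_time=arch.nadir_time)

    mean_rr = 60.0 / arch.hr_mean
    n_max = int(np.ceil((supine_span + stand_span) / 0.3)) + 2
    rr = np.clip(rng.normal(mean_rr, arch.rr_sd, size=n_max), 0.3, None)
    t = -supine_span + np.cumsum(rr)
    keep = t <= stand_span
    t, rr = t[keep], rr[keep]

    noise = np.zeros(len(t))
    if arch.beat_noise_sd > 0:
        eps = rng.normal(0.0, arch.beat_noise_sd, size=len(t))
        for i in range(1, len(t)):
            noise[i] = arch.ar1 * noise[i - 1] + eps[i]
        noise[0] = eps[0]

    # the onset step (non-zero only for rise profiles) is placed just before
    # t = 0 so the integer-grid point at 0 already sits on the standing curve
    onset = max(0.0, targets[0])
    delta_pct = np.where(
        t < -1.0, 0.0,
        np.where(t < 0.0, onset, curve(np.clip(t, 0.0, None))),
    )
    sbp = baseline * (1.0 + delta_pct / 100.0) + noise
    sbp = np.clip(sbp, 40.0, None)
    dbp = np.clip(sbp - arch.pp_mean, 20.0, sbp - 5.0)
    return Recording("sim", t, sbp, dbp, rr)


def draw_feature_matrix(names: list[str], counts: list[int],
                        rng: np.random.Generator | int | None,
                        archetypes: dict[str, ArchetypeParams] | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Direct Gaussian draws of Δ% feature vectors per archetype.

    Returns the stacked n x 3 matrix and integer generating labels; the fast
    path for clustering recovery experiments that do not need full recordings.
    """
    archetypes = archetypes or ARCHETYPES
    rng = np.random.default_rng(rng)
    blocks, labels = [], []
    for i, (name, n) in enumerate(zip(names, counts)):
        a = archetypes[name]
        blocks.append(rng.normal(a.feature_means, a.feature_sds, size=(n, 3)))
        labels.append(np.full(n, i))
    return np.vstack(blocks), np.concatenate(labels)


def simulate_cohort(cfg: SimConfig,
                    archetypes: dict[str, ArchetypeParams] | None = None,
                    with_recordings: bool = True,
                    ) -> tuple[dict[str, Recording], pd.DataFrame]:
    """A full synthetic cohort: recordings plus covariates and indicators.

    Group membership is multinomial over the configured proportions; frailty
    indicators are independent Bernoulli draws at the group's prevalence; age
    and sex are drawn from the cohort's marginal distributions. Returns a
    mapping participant id → Recording (empty when ``with_recordings`` is
    False) and the participant table with true group labels.
    """
    archetypes = archetypes or ARCHETYPES
    rng = np.random.default_rng(cfg.seed)
    names = sorted(cfg.proportions)
    probs = np.array([cfg.proportions[g] for g in names])
    assignment = rng.choice(len(names), size=cfg.n, p=probs)

    rows = []
    recordings: dict[str, Recording] = {}
    for i in range(cfg.n):
        group = names[assignment[i]]
        pid = f"P{i:05d}"
        arch = archetypes[group]
        row = {
            "participant_id": pid,
            "true_group": group,
            "age": float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 55.0, 105.0)),
            "female": bool(rng.random() < FEMALE_PROPORTION.get(group, 0.537)),
        }
        for ind, per_group in cfg.prevalences.items():
            row[ind] = bool(rng.random() < per_group[group])
        if with_recordings:
            rec = simulate_recording(arch, rng)
            rec.participant_id = pid
            recordings[pid] = rec
        rows.append(row)
    participants = pd.DataFrame(rows).set_index("participant_id")
    return recordings, participants
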