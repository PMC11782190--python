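"""Normal-orthostatic-response (NOR) reference group and cluster reassignment.

A participant shows a normal orthostatic response when the SBP shift from
baseline stays within 20% in the early phase and within 10% at both the
stabilization point and the late phase (inclusive bounds; the wider early
margin accommodates the higher pressure variability of the first 15 s of
standing). Participants meeting the rule at all three feature points are moved
out of their morphology cluster into the NOR reference group used for the
frailty comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_PCT_COLUMNS, FeatureVector

__all__ = [
    "NOR_THRESHOLDS",
    "classify_nor",
    "reassign",
    "reduction_percent",
    "GroupAssignment",
    "ReassignmentSummary",
]

NOR_THRESHOLDS = (20.0, 10.0, 10.0)


@dataclass
class GroupAssignment:
    participant_id: str
    original_cluster: str
    final_group: str  # original cluster name, or "NOR"


@dataclass
class ReassignmentSummary:
    original_size: dict[str, int]
    final_size: dict[str, int]
    reduction_pct: dict[str, float]  # rounded to 1 dp
    nor_size: int


def classify_nor(fv, thresholds: tuple[float, float, float] = NOR_THRESHOLDS) -> bool:
    """True iff |early| <= 20, |stab| <= 10 and |late| <= 10 (Δ% units).

    Geometrically: the point lies in the axis-aligned box
    [-20, 20] x [-10, 10] x [-10, 10] of the Δ% feature space.
    """
    if isinstance(fv, FeatureVector):
        coords = fv.as_array()
    else:
        coords = np.asarray(fv, dtype=float)
    if coords.shape != (3,) or not np.all(np.isfinite(coords)):
        raise ValueError("expected three finite Δ% coordinates")
    return bool(np.all(np.abs(coords) <= np.asarray(thresholds)))


def reduction_percent(original: int, final: int) -> float:
    """Cluster size reduction 100·(orig − final)/orig, rounded to 1 dp."""
    if original <= 0:
        raise ValueError("original cluster size must be positive")
    return round(100.0 * (original - final) / original, 1)


def reassign(clusters: pd.Series, features: pd.DataFrame,
             thresholds: tuple[float, float, float] = NOR_THRESHOLDS,
             ) -> tuple[pd.DataFrame, ReassignmentSummary]:
    """Apply the NOR rule to every participant of every cluster.

    Parameters
    ----------
    clusters:
        Morphology label per participant, indexed by participant id.
    features:
        Feature table indexed by participant id with the Δ% columns.

    Returns the assignment table (original_cluster, final_group) and a summary
    with per-cluster reductions. Idempotent: re-applying to the final groups
    never moves anyone again.
    """
    if not clusters.index.equals(features.index):
        if set(clusters.index) != set(features.index):
            raise ValueError("cluster labels and features index different participants")
        features = features.loc[clusters.index]
    coords = features[FEATURE_PCT_COLUMNS].to_numpy(dtype=float)
    is_nor = np.all(np.abs(coords) <= np.asarray(thresholds), axis=1)
    out = pd.DataFrame(
        {
            "original_cluster": clusters.to_numpy(),
            "final_group": np.where(is_nor, "NOR", clusters.to_numpy()),
        },
        index=clusters.index,
    )
    orig = out["original_cluster"].value_counts().to_dict()
    final = {c: int((out["final_group"] == c).sum()) for c in orig}
    summary = ReassignmentSummary(
        original_size={c: int(n) for c, n in orig.items()},
        final_size=final,
        reduction_pct={c: reduction_percent(orig[c], final[c]) for c in orig},
        nor_size=int(is_nor.sum()),
    )
    return out, summary
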