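"""Growth/no-growth classification from microplate OD595 assays.

A knockout strain is scored per condition: significant growth means that a
strict majority of its biological replicate wells exceed a threshold set at
five standard deviations above the mean OD595 of sterile control wells
("mean standard deviation" read as the mean of per-control-set sample SDs).
A strain that grows under at least one tested condition and fails under at
least one other is *conditionally essential*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: strain_id marking sterile (uninoculated) wells in assay tables
STERILE_ID = "STERILE"

GROWS_EVERYWHERE = "grows_everywhere"
CONDITIONALLY_ESSENTIAL = "conditionally_essential"
NO_GROWTH_ALL = "no_growth_all"


@dataclass(frozen=True)
class GrowthCall:
    strain_id: str
    condition_id: str
    grows: bool
    n_above: int
    n_total: int
    threshold: float


def growth_threshold(
    sterile_sets: Mapping | Sequence[Sequence[float]],
    n_sd: float = 5.0,
) -> float:
    """Significant-growth OD595 threshold from sterile control wells.

    threshold = grand mean of all sterile ODs
                + n_sd x mean of per-set sample SDs

    *sterile_sets* groups wells into control sets (e.g. one per plate or
    condition); pass a single set for a pooled SD.
    """
    if isinstance(sterile_sets, Mapping):
        sets = list(sterile_sets.values())
    else:
        sets = list(sterile_sets)
    if not sets:
        raise ValueError("no sterile control wells provided")
    arrays = [np.asarray(s, dtype=np.float64) for s in sets]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each sterile control set needs at least 2 wells")
    grand_mean = float(np.mean(np.concatenate(arrays)))
    mean_sd = float(np.mean([np.std(a, ddof=1) for a in arrays]))
    return grand_mean + n_sd * mean_sd


def classify_growth(
    replicate_ods: Sequence[float],
    threshold: float,
    strain_id: str = "",
    condition_id: str = "",
) -> GrowthCall:
    """Strict-majority growth call: grows iff (#wells with OD > threshold)
    exceeds half the wells.  Both comparisons are strict."""
    ods = np.asarray(replicate_ods, dtype=np.float64)
    if ods.size == 0:
        raise ValueError("need at least one replicate OD")
    n_above = int(np.count_nonzero(ods > threshold))
    return GrowthCall(
        strain_id=strain_id,
        condition_id=condition_id,
        grows=n_above > ods.size / 2,
        n_above=n_above,
        n_total=int(ods.size),
        threshold=float(threshold),
    )


def conditional_essentiality(calls: Iterable[GrowthCall]) -> str:
    """Label a strain from its growth calls across conditions.

    ``conditionally_essential`` — grows somewhere and fails somewhere;
    ``grows_everywhere`` — grows under every tested condition;
    ``no_growth_all`` — fails everywhere (flagged for manual review rather
    than folded into conditional essentiality).
    """
    calls = list(calls)
    if len(calls) < 2:
        raise ValueError("need growth calls for at least 2 conditions")
    grows = [c.grows for c in calls]
    if all(grows):
        return GROWS_EVERYWHERE
    if any(grows):
        return CONDITIONALLY_ESSENTIAL
    return NO_GROWTH_ALL


def classify_assay(
    assay: pd.DataFrame,
    n_sd: float = 5.0,
    sterile_group: str = "condition_id",
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Classify a full assay table.

    *assay* has columns ``strain_id, condition_id, replicate_id, od595``;
    sterile wells carry ``strain_id == "STERILE"`` and are grouped by
    *sterile_group* into control sets for the threshold.

    Returns (growth_calls, labels, threshold) where growth_calls has one row
    per strain x condition and labels one row per strain.
    """
    sterile = assay[assay["strain_id"] == STERILE_ID]
    if sterile.empty:
        raise ValueError("assay table contains no sterile control wells")
    sets = {
        key: grp["od595"].to_numpy()
        for key, grp in sterile.groupby(sterile_group, observed=True)
    }
    threshold = growth_threshold(sets, n_sd=n_sd)

    tested = assay[assay["strain_id"] != STERILE_ID]
    calls = [
        classify_growth(
            grp["od595"].to_numpy(), threshold, strain_id=s, condition_id=c
        )
        for (s, c), grp in tested.groupby(
            ["strain_id", "condition_id"], observed=True, sort=True
        )
    ]
    calls_df = pd.DataFrame([c.__dict__ for c in calls])
    by_strain: dict[str, list[GrowthCall]] = {}
    for c in calls:
        by_strain.setdefault(c.strain_id, []).append(c)
    labels = pd.DataFrame({"strain_id": sorted(by_strain)})
    labels["label"] = [
        conditional_essentiality(by_strain[s]) for s in labels["strain_id"]
    ]
    labels["review_flag"] = labels["label"] == NO_GROWTH_ALL
    return calls_df, labels, threshold
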