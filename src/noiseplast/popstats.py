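"""Population expression statistics, replicate averaging, and plasticity.

For each gated, background-corrected clonal population the mean (E_pop) and
sample standard deviation (V_pop) of log10 fluorescence summarise the
population mean expression level and the cell-to-cell heterogeneity (noise).
E_pop and V_pop are averaged over biological replicates (conditions lacking
duplicates are omitted), and a gene's *plasticity* is the standard deviation
of its replicate-averaged E_pop across nutrient conditions.

Sample (n-1) standard deviations are used throughout; at the >= 4,000 events
per population enforced upstream the choice of denominator is negligible for
V_pop, and for plasticity it is the unbiased convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gating import GatedPopulation


def sample_sd(x: np.ndarray) -> float:
    """Sample (n-1) SD; exactly 0.0 for a constant sample.

    Guarding the constant case avoids the ~1e-16 residue that floating-point
    summation would otherwise leave, keeping the noise-free limit exact.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2 or np.ptp(x) == 0:
        return 0.0
    return float(np.std(x, ddof=1))


@dataclass(frozen=True)
class PopulationStats:
    """E_pop / V_pop of one replicate population."""

    strain_id: str
    condition_id: str
    replicate_id: str
    e_pop: float
    v_pop: float
    n_events: int


@dataclass(frozen=True)
class GeneConditionStats:
    """Replicate-averaged statistics for one gene under one condition."""

    gene_id: str
    condition_id: str
    e_pop_mean: float
    v_pop_mean: float
    n_replicates: int


def population_stats(pop: GatedPopulation) -> PopulationStats:
    """Mean (E_pop) and sample SD (V_pop) of log10 corrected fluorescence."""
    if pop.n_events == 0:
        raise ValueError("cannot compute statistics of an empty population")
    log_yfp = np.asarray(pop.log_yfp, dtype=np.float64)
    e_pop = float(np.mean(log_yfp))
    v_pop = sample_sd(log_yfp)
    return PopulationStats(
        strain_id=pop.strain_id,
        condition_id=pop.condition_id,
        replicate_id=pop.replicate_id,
        e_pop=e_pop,
        v_pop=v_pop,
        n_events=pop.n_events,
    )


def average_replicates(
    stats: Sequence[PopulationStats],
    min_replicates: int = 2,
) -> GeneConditionStats | None:
    """Unweighted mean of E_pop and V_pop across biological replicates.

    Returns None when fewer than *min_replicates* populations survive QC:
    conditions lacking biological duplicates are omitted from downstream
    analyses.
    """
    if not stats:
        return None
    genes = {s.strain_id for s in stats}
    conds = {s.condition_id for s in stats}
    if len(genes) != 1 or len(conds) != 1:
        raise ValueError(
            "replicates to average must share one gene and one condition; "
            f"got genes {sorted(genes)} conditions {sorted(conds)}"
        )
    if len(stats) < min_replicates:
        return None
    return GeneConditionStats(
        gene_id=stats[0].strain_id,
        condition_id=stats[0].condition_id,
        e_pop_mean=float(np.mean([s.e_pop for s in stats])),
        v_pop_mean=float(np.mean([s.v_pop for s in stats])),
        n_replicates=len(stats),
    )


def compute_plasticity(
    e_pop_means: Iterable[float],
    min_conditions: int = 5,
) -> float:
    """Sample SD of a gene's replicate-averaged E_pop across conditions."""
    e = np.asarray(list(e_pop_means), dtype=np.float64)
    if e.size < min_conditions:
        raise ValueError(
            f"plasticity requires at least {min_conditions} conditions; "
            f"got {e.size}"
        )
    return float(np.std(e, ddof=1))


# ---------------------------------------------------------------------------
# Vectorised table-level equivalents used by the pipeline.
# ---------------------------------------------------------------------------


def population_stats_frame(pops: Iterable[GatedPopulation]) -> pd.DataFrame:
    """Table of E_pop/V_pop rows for an iterable of gated populations."""
    rows = [population_stats(p).__dict__ for p in pops]
    return pd.DataFrame(
        rows,
        columns=[
            "strain_id",
            "condition_id",
            "replicate_id",
            "e_pop",
            "v_pop",
            "n_events",
        ],
    )


def average_replicates_frame(
    stats: pd.DataFrame, min_replicates: int = 2
) -> pd.DataFrame:
    """Replicate-average a population-stats table.

    Groups by (strain_id, condition_id); groups with fewer than
    *min_replicates* rows are dropped.  Returns columns
    ``gene_id, condition_id, e_pop_mean, v_pop_mean, n_replicates``.
    """
    g = stats.groupby(["strain_id", "condition_id"], observed=True, sort=True)
    out = g.agg(
        e_pop_mean=("e_pop", "mean"),
        v_pop_mean=("v_pop", "mean"),
        n_replicates=("e_pop", "size"),
    ).reset_index()
    out = out[out["n_replicates"] >= min_replicates].reset_index(drop=True)
    return out.rename(columns={"strain_id": "gene_id"})


def plasticity_frame(
    gene_condition: pd.DataFrame, min_conditions: int = 5
) -> pd.DataFrame:
    """Per-gene plasticity table from replicate-averaged statistics.

    Genes observed in fewer than *min_conditions* conditions are dropped.
    Returns ``gene_id, plasticity, mean_e_pop, n_conditions``.
    """
    g = gene_condition.groupby("gene_id", observed=True, sort=True)
    out = g.agg(
        plasticity=("e_pop_mean", lambda x: np.std(x, ddof=1)),
        mean_e_pop=("e_pop_mean", "mean"),
        n_conditions=("e_pop_mean", "size"),
    ).reset_index()
    return out[out["n_conditions"] >= min_conditions].reset_index(drop=True)
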