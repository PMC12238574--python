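"""End-to-end analysis pipeline.

Stage order mirrors the measurement workflow: per (condition, batch) the
pooled cumulative population defines a narrow FSC gate; gated events are
background-corrected against the reporter-free control strain measured
through the same gate; populations keeping fewer than the minimum event
count are dropped; E_pop/V_pop are computed per replicate population and
averaged over biological replicates (conditions lacking duplicates drop
out); plasticity is the SD of E_pop across conditions per gene; the
noise-vs-mean trend is fitted on the pooled replicate-averaged points and
mean DM_V per gene is the gene's mean residual; association analyses run on
the resulting per-gene summary.

Every population entering the pipeline leaves a row in the QC log with its
filtering counts and a status code, so endpoint gene counts are auditable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from .dmnoise import NoiseTrendModel, NoiseTrendResult
from .gating import (
    build_fsc_gate,
    estimate_autofluorescence,
    estimate_fsc_mode,
    gate_mask,
)
from .popstats import average_replicates_frame, plasticity_frame, sample_sd


@dataclass(frozen=True)
class PipelineParams:
    control_strain: str = "BW25113"
    gate_halfwidth: float = 0.1
    min_events: int = 4000
    min_control_events: int = 100
    autofluorescence_stat: str = "mean"
    min_replicates: int = 2
    min_conditions: int = 5
    window: int | str = "auto"
    smoothing: float | str = "auto"
    per_replicate_dm: bool = False
    pca_max_missing: int = 4


@dataclass
class PipelineResult:
    population_stats: pd.DataFrame
    gene_condition: pd.DataFrame
    gene_plasticity: pd.DataFrame
    trend: NoiseTrendResult | None
    gene_noise: pd.DataFrame
    gene_summary: pd.DataFrame
    gates: pd.DataFrame
    qc_log: pd.DataFrame
    associations: dict = field(default_factory=dict)

    def summary(self) -> str:
        qc = self.qc_log
        lines = [
            "Noise/plasticity pipeline result",
            "=" * 40,
            f"populations processed   {len(qc)}",
            f"populations passing QC  {int((qc['status'] == 'ok').sum())}",
            f"(gene, condition) pairs {len(self.gene_condition)}",
            f"genes with plasticity   {len(self.gene_plasticity)}",
            f"genes with mean DM_V    {len(self.gene_noise)}",
        ]
        for name, res in self.associations.items():
            if isinstance(res, assoc_mod.CorrelationResult):
                lines.append(
                    f"{name:<28} R = {res.r:+.3f}  p = {res.p:.3g}  n = {res.n}"
                )
            elif isinstance(res, float):
                lines.append(f"{name:<28} p = {res:.3g}")
        return "\n".join(lines)


def _iter_batches(events: pd.DataFrame) -> Iterable[pd.DataFrame]:
    for _, chunk in events.groupby(
        ["condition_id", "batch_id"], observed=True, sort=True
    ):
        yield chunk


def process_batch(
    chunk: pd.DataFrame, params: PipelineParams
) -> tuple[pd.DataFrame, dict]:
    """Gate, background-correct and summarise one (condition, batch) chunk.

    Returns (population rows, gate record).  The chunk must contain all
    strains measured under one condition in one batch, including the
    control strain.
    """
    cond = str(chunk["condition_id"].iloc[0])
    batch = str(chunk["batch_id"].iloc[0])
    fsc = chunk["fsc"].to_numpy(dtype=np.float64)
    mode = estimate_fsc_mode(fsc)
    gate = build_fsc_gate(
        mode, params.gate_halfwidth, condition_id=cond, batch_id=batch
    )
    in_gate = gate_mask(fsc, gate)

    strain = chunk["strain_id"].astype(str).to_numpy()
    is_control = strain == params.control_strain
    if not is_control.any():
        raise ValueError(
            f"no control strain {params.control_strain!r} in "
            f"(condition={cond}, batch={batch})"
        )
    yfp = chunk["yfp_raw"].to_numpy(dtype=np.float64)
    af = estimate_autofluorescence(
        yfp[in_gate & is_control],
        stat=params.autofluorescence_stat,
        min_events=params.min_control_events,
    )

    rep = chunk["replicate_id"].astype(str).to_numpy()
    sample = ~is_control
    corrected_ok = yfp > af
    log_corr = np.full(len(chunk), np.nan)
    sel = sample & in_gate & corrected_ok
    log_corr[sel] = np.log10(yfp[sel] - af)

    df = pd.DataFrame(
        {
            "strain_id": strain[sample],
            "replicate_id": rep[sample],
            "in_gate": in_gate[sample],
            "kept": sel[sample],
            "log_yfp": log_corr[sample],
        }
    )
    g = df.groupby(["strain_id", "replicate_id"], sort=True)
    kept = df[df["kept"]]
    gk = kept.groupby(["strain_id", "replicate_id"], sort=True)
    out = g.agg(
        n_total=("in_gate", "size"), n_gated=("in_gate", "sum")
    ).join(
        gk.agg(
            n_events=("log_yfp", "size"),
            e_pop=("log_yfp", "mean"),
            v_pop=("log_yfp", sample_sd),
        )
    )
    out = out.reset_index()
    out["n_events"] = out["n_events"].fillna(0).astype(int)
    out["n_rejected_gate"] = out["n_total"] - out["n_gated"]
    out["n_rejected_background"] = out["n_gated"] - out["n_events"]
    out["condition_id"] = cond
    out["batch_id"] = batch
    out["autofluorescence"] = af
    out["qc_pass"] = out["n_events"] >= params.min_events
    gate_record = {
        "condition_id": cond,
        "batch_id": batch,
        "mode_log10": gate.mode_log10,
        "low": gate.low,
        "high": gate.high,
        "autofluorescence": af,
    }
    return out, gate_record


def run_pipeline(
    events: pd.DataFrame | Iterable[pd.DataFrame],
    gene_meta: pd.DataFrame | None = None,
    condition_meta: pd.DataFrame | None = None,
    params: PipelineParams = PipelineParams(),
    out_dir: str | Path | None = None,
    compute_assoc: bool = True,
) -> PipelineResult:
    """Run the full analysis.

    Parameters
    ----------
    events
        Canonical event table, or an iterable of per-(condition, batch)
        chunks (each including the control strain) for bounded memory.
    gene_meta
        Optional table ``gene_id, essential, msr_count, tr_count`` merged
        into the gene summary and required for the association analyses.
    condition_meta
        Optional table with ``condition_id`` and ``supplement_richness``
        used by the PCA score test.
    """
    if isinstance(events, pd.DataFrame):
        batches = _iter_batches(events)
    else:
        batches = events

    pop_frames, gate_records = [], []
    for chunk in batches:
        pops, gate = process_batch(chunk, params)
        pop_frames.append(pops)
        gate_records.append(gate)
    pop = pd.concat(pop_frames, ignore_index=True)
    gates = pd.DataFrame(gate_records)

    qc_log = pop[
        [
            "strain_id",
            "condition_id",
            "replicate_id",
            "batch_id",
            "n_total",
            "n_rejected_gate",
            "n_rejected_background",
            "n_events",
            "qc_pass",
        ]
    ].copy()
    qc_log["status"] = np.where(qc_log["qc_pass"], "ok", "dropped_low_events")

    stats_cols = [
        "strain_id",
        "condition_id",
        "replicate_id",
        "e_pop",
        "v_pop",
        "n_events",
    ]
    pop_ok = pop[pop["qc_pass"]][stats_cols].reset_index(drop=True)

    gene_condition = average_replicates_frame(
        pop_ok, min_replicates=params.min_replicates
    )
    gene_plasticity = plasticity_frame(
        gene_condition, min_conditions=params.min_conditions
    )

    if params.per_replicate_dm:
        dm_points = pop_ok.rename(columns={"strain_id": "gene_id"})
        e_col, v_col = "e_pop", "v_pop"
    else:
        dm_points = gene_condition
        e_col, v_col = "e_pop_mean", "v_pop_mean"
    if len(dm_points) >= 6:
        model = NoiseTrendModel.from_dataframe(
            dm_points,
            e_col=e_col,
            v_col=v_col,
            window=params.window,
            smoothing=params.smoothing,
        )
        trend = model.fit()
        gene_noise = trend.mean_dm_per_gene()
    else:
        # degenerate input (e.g. every population failed QC): report the QC
        # log rather than crash
        trend = None
        gene_noise = pd.DataFrame(
            {"gene_id": pd.Series(dtype=str), "mean_dmv": [], "n_conditions": []}
        )

    gene_summary = gene_plasticity.merge(gene_noise, on="gene_id", how="outer")
    if gene_meta is not None:
        gene_summary = gene_summary.merge(gene_meta, on="gene_id", how="left")

    result = PipelineResult(
        population_stats=pop_ok,
        gene_condition=gene_condition,
        gene_plasticity=gene_plasticity,
        trend=trend,
        gene_noise=gene_noise,
        gene_summary=gene_summary,
        gates=gates,
        qc_log=qc_log,
    )
    if compute_assoc and gene_meta is not None:
        result.associations = compute_associations(
            result, condition_meta=condition_meta, params=params
        )
    if out_dir is not None:
        write_result(result, out_dir, params)
    return result


def compute_associations(
    result: PipelineResult,
    condition_meta: pd.DataFrame | None = None,
    params: PipelineParams = PipelineParams(),
) -> dict:
    """Headline association analyses on the per-gene summary.

    Returns a dict with Spearman correlations between noise (mean DM_V) and
    plasticity per essentiality class, Wilcoxon class comparisons of
    plasticity and noise, cumulative rank-scan curves for nonessential
    genes, a variance comparison of regulator counts, and (when condition
    metadata is available) PCA of the expression matrix with a
    Kruskal-Wallis test of PC1 scores by supplement richness.
    """
    gs = result.gene_summary.dropna(subset=["plasticity", "mean_dmv"])
    out: dict = {}
    if "essential" not in gs.columns or gs.empty:
        return out
    ess = gs[gs["essential"].astype(bool)]
    non = gs[~gs["essential"].astype(bool)]

    if len(non) >= 4:
        out["noise_plasticity_nonessential"] = assoc_mod.spearman(
            non["mean_dmv"], non["plasticity"]
        )
    if len(ess) >= 4:
        out["noise_plasticity_essential"] = assoc_mod.spearman(
            ess["mean_dmv"], ess["plasticity"]
        )
    if len(gs) >= 4:
        out["noise_plasticity_pooled"] = assoc_mod.spearman(
            gs["mean_dmv"], gs["plasticity"]
        )
    if len(ess) >= 3 and len(non) >= 3:
        out["plasticity_wilcoxon_p"] = assoc_mod.ranksum_test(
            ess["plasticity"], non["plasticity"]
        )
        out["mean_dmv_wilcoxon_p"] = assoc_mod.ranksum_test(
            ess["mean_dmv"], non["mean_dmv"]
        )
        if "tr_count" in gs.columns:
            out["tr_count_levene_p"] = assoc_mod.levene_test(
                ess["tr_count"], non["tr_count"]
            )
    if "msr_count" in non.columns and len(non) >= 6:
        out["msr_curve_nonessential"] = assoc_mod.cumulative_curve(
            non["mean_dmv"].to_numpy(), non["msr_count"].to_numpy(dtype=float)
        )
        out["plasticity_curve_nonessential"] = (
            assoc_mod.cumulative_plasticity_curve(
                non["mean_dmv"].to_numpy(), non["plasticity"].to_numpy()
            )
        )
        out["msr_plasticity_nonessential"] = assoc_mod.spearman(
            non["msr_count"], non["plasticity"]
        )

    # PCA of the mean-expression matrix (genes x conditions, NaN = dropped)
    e_matrix = result.gene_condition.pivot(
        index="gene_id", columns="condition_id", values="e_pop_mean"
    )
    try:
        pca = assoc_mod.pca_expression(
            e_matrix, max_missing_genes_per_condition=params.pca_max_missing
        )
        out["pca"] = pca
        if condition_meta is not None and "supplement_richness" in condition_meta:
            rich = condition_meta.set_index("condition_id")[
                "supplement_richness"
            ]
            groups = rich.reindex(pca.kept_conditions).to_numpy()
            pc1 = pca.scores[:, 0]
            ok = ~pd.isna(groups)
            counts = pd.Series(groups[ok]).value_counts()
            if (counts >= 2).sum() >= 2:
                usable = np.isin(groups, counts[counts >= 2].index) & ok
                out["pc1_kruskal_p"] = assoc_mod.kruskal_wallis(
                    pc1[usable], groups[usable]
                )
    except ValueError:
        pass
    return out


def write_result(
    result: PipelineResult,
    out_dir: str | Path,
    params: PipelineParams = PipelineParams(),
) -> Path:
    """Write all result tables, the QC log and a manifest to *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.population_stats.to_csv(out / "population_stats.csv", index=False)
    result.gene_condition.to_csv(out / "gene_condition_stats.csv", index=False)
    if result.trend is not None:
        result.trend.frame().to_csv(out / "dmv_points.csv", index=False)
    result.gene_noise.to_csv(out / "gene_noise.csv", index=False)
    result.gene_summary.to_csv(out / "gene_summary.csv", index=False)
    result.gates.to_csv(out / "gates.csv", index=False)
    result.qc_log.to_csv(out / "qc_log.csv", index=False)
    curves = []
    for name in ("msr_curve_nonessential", "plasticity_curve_nonessential"):
        if name in result.associations:
            c = result.associations[name].frame()
            c["covariate"] = name
            curves.append(c)
    if curves:
        pd.concat(curves).to_csv(out / "curves.csv", index=False)
    if "pca" in result.associations:
        result.associations["pca"].scores_frame().to_csv(
            out / "pca_scores.csv"
        )
    manifest = {
        "parameters": asdict(params),
        "tables": sorted(p.name for p in out.glob("*.csv")),
        "n_populations": int(len(result.qc_log)),
        "n_populations_ok": int((result.qc_log["status"] == "ok").sum()),
    }
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    return out
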