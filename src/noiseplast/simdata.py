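"""Synthetic flow-cytometry and growth-assay data with planted ground truth.

The generator emulates the statistical structure of a YFP-fusion
flow-cytometry screen across nutrient conditions, so that every pipeline
stage — gating, background correction, population statistics, the
noise-vs-mean trend, plasticity, and the association analyses — can be
verified against planted parameters without any external data.

Generative model, per gene g, condition c, cell i:

1.  Baseline log10 expression ``beta_g ~ Normal(base_mean_log10)``;
    regulator count ``msr_g ~ Poisson(class rate)`` with
    ``tr_g = msr_g + Poisson(tr_extra_rate)``.
2.  Plasticity scale ``P_g = softplus(a_g)`` with latent
    ``a_g = intercept_class + msr_slope * msr_g + Normal(0, gene_scatter)``;
    condition effect ``delta_{g,c} = P_g * z_{g,c}``, ``z ~ Normal(0,1)``;
    true population log10 mean ``L_{g,c} = beta_g + delta_{g,c}``.
3.  Gene extrinsic-noise SD ``eta_g = softplus(loc_class + scale * u_g)``
    where ``u_g`` is coupled to the plasticity latent through a Gaussian
    copula with class-specific target *rank* correlation ``rho_plant``
    (latent Pearson ``r = 2 sin(pi rho / 6)`` on empirical normal scores,
    so the planted Spearman correlation is exact up to gene sampling error).
4.  Per cell: extrinsic deviation ``e_i ~ Normal(0, eta_g)``; expected
    abundance ``mu_i = 10**(L + e_i)``; intrinsic draw
    ``A_i ~ Gamma(mu_i / b, b)`` with burst size b, giving the low-mean
    ``CV^2 = b / mu`` intrinsic regime and a mean-independent extrinsic
    floor at high expression (``b = 0`` means a deterministic ``A_i = mu_i``).
5.  Cell size ``s_i = 10**Normal(phi_c, sigma_s)`` (condition-dependent
    location); ``fsc = s_i * 10**Normal(0, sigma_fsc)``;
    ``yfp_raw = A_i * (s_i / 10**phi_c) * 10**Normal(0, sigma_inst) + AF_i``
    with log-normal autofluorescence ``AF_i``.  The reporter-free control
    strain emits autofluorescence only.

One global seed determines everything; per-population substreams are derived
from (seed, gene index, condition index, replicate index) so that, for a
fixed set of planted truth parameters, adding replicates never perturbs
previously generated populations.
Each biological replicate is measured on its own day, so ``batch_id``
follows ``replicate_id``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .cytio import EVENT_COLUMNS, KEY_COLUMNS
from .essentiality import STERILE_ID


def softplus(x):
    """Numerically stable log(1 + exp(x))."""
    x = np.asarray(x, dtype=np.float64)
    return np.logaddexp(0.0, x)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic screen (defaults mirror the study scale:
    89 genes = 67 nonessential + 22 essential, ~20 nutrient conditions, two
    biological replicates, 10,000 events per population)."""

    n_nonessential: int = 67
    n_essential: int = 22
    n_conditions: int = 20
    n_replicates: int = 2
    events_per_population: int = 10_000
    seed: int = 0
    control_strain: str = "BW25113"

    # gene baseline expression, log10 a.u.
    base_mean_log10: tuple[float, float] = (2.8, 0.35)

    # regulator counts
    msr_rate_nonessential: float = 2.0
    msr_rate_essential: float = 0.8
    tr_extra_rate: float = 1.5

    # plasticity latent (softplus scale, log10 units)
    plasticity_intercept_nonessential: float = -1.5
    plasticity_intercept_essential: float = -2.2
    plasticity_msr_slope: float = 0.15
    plasticity_gene_scatter: float = 0.6

    # extrinsic noise (softplus scale, log10 units)
    extrinsic_loc_nonessential: float = -2.0
    extrinsic_loc_essential: float = -2.5
    extrinsic_scale: float = 0.5

    # planted rank correlation between eta_g and P_g, per class
    coupling_nonessential: float = 0.6
    coupling_essential: float = 0.0

    # intrinsic noise: burst size, linear a.u. (0 = deterministic abundance)
    burst_size: float = 10.0

    # cell size / scatter model (log10 scale)
    cellsize_loc: float = 2.5
    cellsize_spread: float = 0.15  # SD of phi_c across conditions
    cellsize_sigma: float = 0.04  # per-cell SD of log10 size
    fsc_instrument_sigma: float = 0.02
    ssc_instrument_sigma: float = 0.05
    instrument_sigma: float = 0.02  # multiplicative YFP measurement noise

    # autofluorescence, natural-log parameters of a log-normal (a.u.)
    autofluorescence_log_mean: float = float(np.log(20.0))
    autofluorescence_log_sd: float = 0.3

    def validate(self) -> "SimulationConfig":
        bad = []
        for name in (
            "n_nonessential",
            "n_essential",
            "n_conditions",
            "n_replicates",
            "events_per_population",
        ):
            if getattr(self, name) < 1:
                bad.append(name)
        for name in (
            "plasticity_gene_scatter",
            "extrinsic_scale",
            "burst_size",
            "cellsize_sigma",
            "fsc_instrument_sigma",
            "ssc_instrument_sigma",
            "instrument_sigma",
            "autofluorescence_log_sd",
            "cellsize_spread",
        ):
            if getattr(self, name) < 0:
                bad.append(name)
        for name in ("coupling_nonessential", "coupling_essential"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                bad.append(name)
        if bad:
            raise ValueError(f"invalid simulation parameters: {bad}")
        return self

    def noise_free(self) -> "SimulationConfig":
        """Copy with every stochastic term at a cell level switched off:
        zero extrinsic noise, deterministic abundance, constant cell size
        and autofluorescence.  Downstream V_pop is exactly zero."""
        return replace(
            self,
            extrinsic_loc_nonessential=-np.inf,
            extrinsic_loc_essential=-np.inf,
            extrinsic_scale=0.0,
            burst_size=0.0,
            cellsize_sigma=0.0,
            fsc_instrument_sigma=0.0,
            ssc_instrument_sigma=0.0,
            instrument_sigma=0.0,
            autofluorescence_log_sd=0.0,
        )


@dataclass
class SimTruth:
    """Planted per-gene and per-condition parameters."""

    genes: pd.DataFrame  # gene_id, essential, msr_count, tr_count, beta,
    #                      plasticity (P_g), extrinsic_sd (eta_g), latents
    conditions: pd.DataFrame  # condition_id, carbon_source, environment_id,
    #                           supplement_richness, phi_c
    means: pd.DataFrame  # genes x conditions true log10 means L_{g,c}


@dataclass
class SimulatedDataset:
    events: pd.DataFrame
    truth: SimTruth
    gene_meta: pd.DataFrame
    condition_meta: pd.DataFrame


_CARBONS = ["glucose", "glycerol", "mannose"]


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Empirical normal scores (rank-based inverse normal transform)."""
    ranks = pd.Series(x).rank(method="average").to_numpy()
    return ndtri((ranks - 0.5) / len(x))


def simulate_truth(config: SimulationConfig) -> SimTruth:
    """Draw all gene- and condition-level planted parameters."""
    config.validate()
    rng_g = np.random.default_rng([config.seed, 11])
    rng_c = np.random.default_rng([config.seed, 13])

    n_total = config.n_nonessential + config.n_essential
    gene_ids = [f"g{i + 1:03d}" for i in range(n_total)]
    essential = np.array(
        [False] * config.n_nonessential + [True] * config.n_essential
    )

    beta = rng_g.normal(*config.base_mean_log10, size=n_total)
    msr = np.where(
        essential,
        rng_g.poisson(config.msr_rate_essential, size=n_total),
        rng_g.poisson(config.msr_rate_nonessential, size=n_total),
    )
    tr = msr + rng_g.poisson(config.tr_extra_rate, size=n_total)

    intercept = np.where(
        essential,
        config.plasticity_intercept_essential,
        config.plasticity_intercept_nonessential,
    )
    a_lat = (
        intercept
        + config.plasticity_msr_slope * msr
        + rng_g.normal(0.0, config.plasticity_gene_scatter, size=n_total)
    )
    plasticity = softplus(a_lat)

    # Gaussian copula within each essentiality class: eta's latent u is
    # correlated with the plasticity latent's normal scores at the Pearson
    # value giving the target Spearman correlation.
    eps = rng_g.normal(size=n_total)
    u = np.empty(n_total)
    for is_ess, rho in (
        (False, config.coupling_nonessential),
        (True, config.coupling_essential),
    ):
        mask = essential == is_ess
        if not mask.any():
            continue
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        z_p = _normal_scores(a_lat[mask])
        u[mask] = r * z_p + np.sqrt(max(0.0, 1.0 - r * r)) * eps[mask]
    eta_loc = np.where(
        essential,
        config.extrinsic_loc_essential,
        config.extrinsic_loc_nonessential,
    )
    eta = softplus(eta_loc + config.extrinsic_scale * u)

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "essential": essential,
            "msr_count": msr.astype(int),
            "tr_count": tr.astype(int),
            "beta": beta,
            "plasticity_latent": a_lat,
            "plasticity": plasticity,
            "extrinsic_latent": u,
            "extrinsic_sd": eta,
        }
    )

    cond_ids = [f"c{j + 1:02d}" for j in range(config.n_conditions)]
    phi = rng_c.normal(
        config.cellsize_loc, config.cellsize_spread, size=config.n_conditions
    )
    conditions = pd.DataFrame(
        {
            "condition_id": cond_ids,
            "carbon_source": [
                _CARBONS[j % len(_CARBONS)] for j in range(config.n_conditions)
            ],
            "environment_id": [
                f"E{j + 1:02d}" for j in range(config.n_conditions)
            ],
            "supplement_richness": [
                (j % 8) + 1 for j in range(config.n_conditions)
            ],
            "phi_c": phi,
        }
    )

    z_gc = rng_c.normal(size=(n_total, config.n_conditions))
    L = beta[:, None] + plasticity[:, None] * z_gc
    means = pd.DataFrame(L, index=gene_ids, columns=cond_ids)
    return SimTruth(genes=genes, conditions=conditions, means=means)


def _population_rng(
    config: SimulationConfig, gene_idx: int, cond_idx: int, rep_idx: int
) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, 101, gene_idx, cond_idx, rep_idx]
    )


def _sample_cells(
    rng: np.random.Generator,
    config: SimulationConfig,
    n: int,
    phi_c: float,
    L: float | None,
    eta: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (fsc, ssc, yfp_raw) for n cells; L=None means the reporter-free
    control strain (autofluorescence only)."""
    log_s = phi_c + rng.normal(0.0, config.cellsize_sigma, size=n)
    fsc = 10.0 ** (log_s + rng.normal(0.0, config.fsc_instrument_sigma, n))
    ssc = fsc * 10.0 ** rng.normal(0.0, config.ssc_instrument_sigma, n)
    af = np.exp(
        config.autofluorescence_log_mean
        + config.autofluorescence_log_sd * rng.standard_normal(n)
    )
    if L is None:
        yfp = af
    else:
        e_cell = eta * rng.standard_normal(n) if eta > 0 else 0.0
        mu = 10.0 ** (L + e_cell)
        if config.burst_size > 0:
            a = rng.gamma(mu / config.burst_size, config.burst_size)
        else:
            a = mu
        size_factor = 10.0 ** (log_s - phi_c)
        inst = 10.0 ** rng.normal(0.0, config.instrument_sigma, n)
        yfp = a * size_factor * inst + af
    return fsc, ssc, yfp


def iter_condition_batches(
    config: SimulationConfig, truth: SimTruth | None = None
) -> Iterator[pd.DataFrame]:
    """Yield one event table per (condition, batch): all strains plus the
    reporter-free control measured under that condition on that day.

    This is the natural unit for gate construction (the pooled "cumulative
    population") and keeps memory bounded for large screens.
    """
    config.validate()
    if truth is None:
        truth = simulate_truth(config)
    n = config.events_per_population
    gene_ids = truth.genes["gene_id"].to_list()
    eta = truth.genes["extrinsic_sd"].to_numpy()
    for ci, cond in truth.conditions.iterrows():
        phi_c = float(cond["phi_c"])
        for ri in range(config.n_replicates):
            rep_id = f"r{ri + 1}"
            batch_id = f"d{ri + 1}"
            frames = []
            for gi, gene_id in enumerate(gene_ids):
                rng = _population_rng(config, gi, ci, ri)
                L = float(truth.means.iat[gi, ci])
                fsc, ssc, yfp = _sample_cells(
                    rng, config, n, phi_c, L, float(eta[gi])
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "strain_id": gene_id,
                            "condition_id": cond["condition_id"],
                            "replicate_id": rep_id,
                            "batch_id": batch_id,
                            "fsc": fsc,
                            "ssc": ssc,
                            "yfp_raw": yfp,
                        }
                    )
                )
            rng = _population_rng(config, len(gene_ids), ci, ri)
            fsc, ssc, yfp = _sample_cells(rng, config, n, phi_c, None, 0.0)
            frames.append(
                pd.DataFrame(
                    {
                        "strain_id": config.control_strain,
                        "condition_id": cond["condition_id"],
                        "replicate_id": rep_id,
                        "batch_id": batch_id,
                        "fsc": fsc,
                        "ssc": ssc,
                        "yfp_raw": yfp,
                    }
                )
            )
            yield pd.concat(frames, ignore_index=True)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full event table plus metadata and planted truth.

    Key columns are categorical to keep large tables compact.  For screens
    too large to hold in memory, iterate :func:`iter_condition_batches`
    instead and feed the chunks to the pipeline directly.
    """
    truth = simulate_truth(config)
    chunks = list(iter_condition_batches(config, truth))
    events = pd.concat(chunks, ignore_index=True)
    for col in KEY_COLUMNS:
        events[col] = events[col].astype("category")
    events = events[EVENT_COLUMNS]
    gene_meta = truth.genes[
        ["gene_id", "essential", "msr_count", "tr_count"]
    ].copy()
    condition_meta = truth.conditions[
        ["condition_id", "carbon_source", "environment_id", "supplement_richness"]
    ].copy()
    return SimulatedDataset(
        events=events,
        truth=truth,
        gene_meta=gene_meta,
        condition_meta=condition_meta,
    )


def simulate_growth_assay(
    n_strains: int = 100,
    n_conditions: int = 6,
    n_replicates: int = 4,
    n_conditional: int = 5,
    n_no_growth: int = 0,
    grow_mean: float = 0.5,
    grow_sd: float = 0.05,
    sterile_mean: float = 0.05,
    sterile_sd: float = 0.005,
    n_sterile_sets: int = 3,
    wells_per_set: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic microplate OD595 growth assay with planted labels.

    The first *n_conditional* strains fail to grow in a random non-empty,
    proper subset of conditions; the next *n_no_growth* strains grow
    nowhere; all others grow everywhere.  Growing wells draw OD595 from
    ``Normal(grow_mean, grow_sd)`` and non-growing / sterile wells from
    ``Normal(sterile_mean, sterile_sd)``, both truncated at zero.

    Returns ``(assay, truth_labels)`` where *assay* has columns
    ``strain_id, condition_id, replicate_id, od595`` (sterile wells carry
    ``strain_id == "STERILE"``).
    """
    if n_conditional + n_no_growth > n_strains:
        raise ValueError("more planted special strains than strains")
    rng = np.random.default_rng([seed, 23])
    implied_threshold = sterile_mean + 5.0 * sterile_sd
    if grow_mean <= implied_threshold:
        warnings.warn(
            "grow_mean does not exceed the implied sterile threshold; "
            "planted labels may be unrecoverable by design",
            stacklevel=2,
        )

    strain_ids = [f"ko{i + 1:03d}" for i in range(n_strains)]
    cond_ids = [f"gc{j + 1:02d}" for j in range(n_conditions)]
    grows = np.ones((n_strains, n_conditions), dtype=bool)
    for i in range(n_conditional):
        k = int(rng.integers(1, n_conditions))  # fail in 1..n-1 conditions
        fail = rng.choice(n_conditions, size=k, replace=False)
        grows[i, fail] = False
    for i in range(n_conditional, n_conditional + n_no_growth):
        grows[i, :] = False

    records = []
    for i, s in enumerate(strain_ids):
        for j, c in enumerate(cond_ids):
            loc, sd = (
                (grow_mean, grow_sd) if grows[i, j] else (sterile_mean, sterile_sd)
            )
            ods = np.clip(rng.normal(loc, sd, size=n_replicates), 0.0, None)
            for k, od in enumerate(ods):
                records.append((s, c, f"w{k + 1}", float(od)))
    for m in range(n_sterile_sets):
        ods = np.clip(
            rng.normal(sterile_mean, sterile_sd, size=wells_per_set), 0.0, None
        )
        for k, od in enumerate(ods):
            records.append((STERILE_ID, f"set{m + 1}", f"w{k + 1}", float(od)))
    assay = pd.DataFrame(
        records, columns=["strain_id", "condition_id", "replicate_id", "od595"]
    )

    labels = []
    for i, s in enumerate(strain_ids):
        if grows[i].all():
            labels.append("grows_everywhere")
        elif grows[i].any():
            labels.append("conditionally_essential")
        else:
            labels.append("no_growth_all")
    truth = pd.DataFrame({"strain_id": strain_ids, "label": labels})
    return assay, truth
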