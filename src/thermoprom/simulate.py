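"""Ground-truth simulator for the full expression + ChIP-occupancy pipeline.

Emulates the study's measurement process on a ligation-built synthetic
promoter library: promoters are random site strings (site count following
a truncated geometric, matching the length decay of ligation products;
tokens drawn from a site-frequency vector), expression readouts are the
thermodynamic model's polymerase occupancy with multiplicative lognormal
noise and high-end censoring (values beyond the flow cytometer's dynamic
range become missing, never clipped), and ChIP sequencing is multinomial
read sampling over Dirichlet-distributed library abundances, with IP
capture linear in the promoter's true bound-site count on top of uniform
non-specific background.

Every simulated expectation is recomputable exactly from the emitted
:class:`TruthRecord`; all randomness flows from a single seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_CONDITIONS,
    DEFAULT_FACTORS,
    EnergyParameters,
    ModelSpec,
    Promoter,
    predict_bound_count,
    predict_expression,
)
from .occupancy import CountTable, combine_replicates, relative_occupancy
from .inference import ObservationSet

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "study_spec",
    "study_truth_params",
    "generate_library",
    "simulate_expression",
    "simulate_occupancy_scores",
    "simulate_chip_counts",
    "end_to_end_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulated study; defaults mirror the study conditions.

    ``site_count_decay`` is the per-site continuation weight of the
    truncated geometric site-count distribution (P(L) ∝ decay**L on
    [site_count_min, site_count_max]).  ``censor_threshold`` is in
    normalized expression units (no-insert control ≈ 1).  Read totals are
    per replicate; ``capture_kappa`` (per factor) is the specific-capture
    slope of the IP step, defaulting to the truth model's occ_scale so the
    scoring module's large-count limit is the model's occupancy surface.
    """

    n_promoters: int = 300
    factors: tuple = DEFAULT_FACTORS
    conditions: tuple = DEFAULT_CONDITIONS
    site_frequencies: tuple = (0.25, 0.25, 0.25, 0.25)
    site_count_min: int = 1
    site_count_max: int = 8
    site_count_decay: float = 0.65
    expression_noise_sd: float = 0.05
    occupancy_noise_sd: float = 0.05
    censor_threshold: float = 4.5
    total_input_reads: int = 2_000_000
    total_ip_reads: int = 2_000_000
    n_replicates: int = 3
    dirichlet_concentration: float = 5.0
    chip_factors: tuple = ("Cbf1", "Gcn4")
    capture_kappa: tuple = ()  # ((factor, kappa), ...); empty -> truth occ_scale
    library_tag: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if len(self.site_frequencies) != len(self.factors):
            raise ValueError("site_frequencies must match the factor alphabet")
        if abs(sum(self.site_frequencies) - 1.0) > 1e-9:
            raise ValueError("site_frequencies must sum to 1")
        if self.total_input_reads <= 0 or self.total_ip_reads <= 0:
            raise ValueError("read totals must be positive")
        if not (0 <= self.site_count_min <= self.site_count_max):
            raise ValueError("invalid site-count range")

    def kappa(self, factor: str, params: EnergyParameters) -> float:
        for f, k in self.capture_kappa:
            if f == factor:
                return float(k)
        return params.occ_scale.get(factor, 0.0)


@dataclass
class TruthRecord:
    """Generating parameters plus every noiseless quantity of the simulation."""

    params: EnergyParameters
    spec: ModelSpec
    config: SimulationConfig
    promoters: dict
    expression: pd.DataFrame
    bound_counts: pd.DataFrame
    relative_occupancy: pd.DataFrame
    seed: int


def study_spec(
    competitive: bool = False,
    switching: bool = False,
    free_interactions: Sequence = (),
    pol_overrides: Sequence = (),
    shared_pol: bool = False,
    shared_basal: bool = False,
) -> ModelSpec:
    """Model structures used throughout the study configuration.

    ``switching`` frees the Gcn4–polymerase energy per condition (the
    activator-to-repressor switching mechanism); ``competitive`` instead
    adds a condition-shared competitor at Gcn4 sites with a
    condition-constant Gcn4–polymerase energy.  ``shared_pol`` ties every
    TF–polymerase energy across conditions (the 10-ΔG recovery design).
    """
    if competitive and switching:
        raise ValueError("competitive and switching variants are alternatives")
    pol_cs = frozenset() if (competitive or shared_pol or not switching) else frozenset({"Gcn4"})
    return ModelSpec(
        competitive=competitive,
        dna_condition_specific=frozenset({"Gcn4"}),
        pol_condition_specific=pol_cs,
        free_interactions=frozenset(tuple(sorted(p)) for p in free_interactions),
        pol_overrides=tuple(pol_overrides),
        basal_condition_specific=not shared_basal,
    )


def study_truth_params(spec: ModelSpec | None = None, competitive: bool = False) -> EnergyParameters:
    """Ground-truth energies (kT) used as the simulator's study conditions.

    Gcn4 binds much more favorably under amino-acid starvation (apparent
    ΔΔG ≈ -2.5 kT, concentration-driven) and always activates; under the
    competitive truth a repressive competitor (unfavorable polymerase
    contact) occupies Gcn4 sites with condition-constant affinity, which
    is what makes Gcn4 sites net-repressive in glucose.  Nrg1 represses;
    Cbf1 and Met31 are mild activators.  expr_scale maps polymerase
    occupancy onto no-insert-normalized expression units; occ_scale maps
    bound-site counts onto the background-relative ChIP scale.
    """
    if spec is None:
        spec = study_spec(competitive=competitive)
    params = EnergyParameters(
        dG_dna={
            ("Cbf1", "glucose"): -2.0, ("Cbf1", "AAS"): -2.0,
            ("Gcn4", "glucose"): 0.8, ("Gcn4", "AAS"): -1.7,
            ("Met31", "glucose"): -1.5, ("Met31", "AAS"): -1.5,
            ("Nrg1", "glucose"): -1.5, ("Nrg1", "AAS"): -1.5,
        },
        dG_pol={
            ("Cbf1", "glucose"): -1.0, ("Cbf1", "AAS"): -1.0,
            ("Gcn4", "glucose"): -1.5, ("Gcn4", "AAS"): -1.5,
            ("Met31", "glucose"): -0.5, ("Met31", "AAS"): -0.5,
            ("Nrg1", "glucose"): 1.5, ("Nrg1", "AAS"): 1.5,
        },
        dG_pol_basal={"glucose": 1.5, "AAS": 1.5},
        dG_comp_dna=-1.5 if spec.competitive else 0.0,
        dG_comp_pol=0.7 if spec.competitive else 0.0,
        expr_scale=5.0,
        occ_scale={f: 2.5 for f in DEFAULT_FACTORS},
    )
    params.dG_pol_override = {k: -1.8 for k in spec.pol_overrides}
    return params


# ---------------------------------------------------------------------------
# library and measurements
# ---------------------------------------------------------------------------

def generate_library(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[Promoter]:
    """Draw a promoter library: geometric site counts, i.i.d. site tokens.

    Duplicate compositions are expected, as in real ligation libraries
    (distinct colonies carrying the same promoter).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lengths = np.arange(config.site_count_min, config.site_count_max + 1)
    if len(lengths) == 1:
        length_p = np.ones(1)
    else:
        length_p = config.site_count_decay ** lengths.astype(float)
        length_p = length_p / length_p.sum()
    promoters = []
    freqs = np.asarray(config.site_frequencies, dtype=float)
    for i in range(config.n_promoters):
        n = int(rng.choice(lengths, p=length_p))
        sites = tuple(rng.choice(config.factors, size=n, p=freqs)) if n else ()
        promoters.append(Promoter(
            id=f"P{i:05d}", sites=sites, library_tag=config.library_tag,
        ))
    return promoters


def _truth_tables(promoters, params, spec, config):
    expr_rows, count_rows, occ_rows = [], [], []
    for p in promoters:
        for c in config.conditions:
            expr_rows.append({
                "promoter_id": p.id, "condition": c,
                "value": predict_expression(p, params, c, spec),
            })
            for f in config.chip_factors:
                b = predict_bound_count(p, f, params, c, spec)
                count_rows.append({
                    "promoter_id": p.id, "factor": f, "condition": c, "count": b,
                })
                occ_rows.append({
                    "promoter_id": p.id, "factor": f, "condition": c,
                    "score": 1.0 + config.kappa(f, params) * b,
                })
    return (pd.DataFrame(expr_rows), pd.DataFrame(count_rows), pd.DataFrame(occ_rows))


def simulate_expression(
    promoters: Sequence[Promoter],
    truth: TruthRecord,
    conditions: Sequence[str] | None = None,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Noisy, censored expression records (NaN value = beyond dynamic range)."""
    config = truth.config if config is None else config
    conditions = config.conditions if conditions is None else conditions
    rng = np.random.default_rng(config.seed) if rng is None else rng
    true_expr = truth.expression.set_index(["promoter_id", "condition"])["value"]
    rows = []
    for p in promoters:
        for c in conditions:
            v = float(true_expr.loc[(p.id, c)])
            v *= float(np.exp(rng.normal(0.0, config.expression_noise_sd)))
            rows.append({
                "promoter_id": p.id, "condition": c,
                "value": np.nan if v > config.censor_threshold else v,
            })
    return pd.DataFrame(rows)


def simulate_occupancy_scores(
    promoters: Sequence[Promoter],
    truth: TruthRecord,
    factor: str,
    condition: str,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Noisy relative-occupancy records drawn directly from the truth surface.

    Bypasses read-level sampling (use :func:`simulate_chip_counts` plus the
    scoring module for that); handy for inference studies where the
    occupancy noise level should be controlled directly.
    """
    config = truth.config if config is None else config
    rng = np.random.default_rng(config.seed) if rng is None else rng
    true_occ = truth.relative_occupancy.set_index(["promoter_id", "factor", "condition"])["score"]
    rows = []
    for p in promoters:
        s = float(true_occ.loc[(p.id, factor, condition)])
        s *= float(np.exp(rng.normal(0.0, config.occupancy_noise_sd)))
        rows.append({"promoter_id": p.id, "factor": factor, "condition": condition, "score": s})
    return pd.DataFrame(rows)


def simulate_chip_counts(
    promoters: Sequence[Promoter],
    truth: TruthRecord,
    factor: str,
    condition: str,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CountTable:
    """Multinomial IP/input read counts for one ChIPed factor x condition.

    Library abundances are drawn once from a symmetric Dirichlet (uneven
    pooled cultures); each replicate's input is multinomial over the
    abundances and its IP is multinomial over abundances reweighted by
    ``1 + kappa * true bound count``.  Column sums equal the configured
    per-replicate totals exactly.
    """
    config = truth.config if config is None else config
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = len(promoters)
    abundances = rng.dirichlet(np.full(n, config.dirichlet_concentration))
    true_b = truth.bound_counts.set_index(["promoter_id", "factor", "condition"])["count"]
    kappa = config.kappa(factor, truth.params)
    bound = np.array([float(true_b.loc[(p.id, factor, condition)]) for p in promoters])
    ip_p = abundances * (1.0 + kappa * bound)
    ip_p = ip_p / ip_p.sum()
    data = {}
    for r in range(1, config.n_replicates + 1):
        data[("input", str(r))] = rng.multinomial(config.total_input_reads, abundances)
        data[("IP", str(r))] = rng.multinomial(config.total_ip_reads, ip_p)
    counts = pd.DataFrame(data, index=[p.id for p in promoters])
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["sample_type", "replicate"])
    counts.index.name = "promoter_id"
    return CountTable(factor=factor, condition=condition, counts=counts)


def end_to_end_dataset(
    config: SimulationConfig,
    spec: ModelSpec | None = None,
    params: EnergyParameters | None = None,
    occupancy_mode: str = "scored",
    min_input: int = 50,
) -> dict:
    """One call producing a full two-condition multi-factor dataset + truth.

    Returns ``{"observations": ObservationSet, "count_tables": {...},
    "occupancy_tables": {...}, "truth": TruthRecord}``.  With
    ``occupancy_mode="scored"`` (default) occupancy records come from
    simulating ChIP read counts and scoring them exactly as real data
    (replicates summed, <``min_input``-input-read filter); ``"direct"``
    draws lognormal-noised scores straight from the truth surface
    (controlled noise level, no read sampling); ``"none"`` yields an
    expression-only dataset.  Identical seeds give identical output.
    """
    if occupancy_mode not in ("scored", "direct", "none"):
        raise ValueError(f"unknown occupancy_mode {occupancy_mode!r}")
    spec = study_spec() if spec is None else spec
    params = study_truth_params(spec) if params is None else params
    rng = np.random.default_rng(config.seed)
    promoters = generate_library(config, rng)
    prom_map = {p.id: p for p in promoters}
    expr_t, counts_t, occ_t = _truth_tables(promoters, params, spec, config)
    truth = TruthRecord(
        params=params, spec=spec, config=config, promoters=prom_map,
        expression=expr_t, bound_counts=counts_t, relative_occupancy=occ_t,
        seed=config.seed,
    )
    expression = simulate_expression(promoters, truth, rng=rng)
    count_tables = {}
    occupancy_tables = {}
    occ_frames = []
    for f in config.chip_factors:
        for c in config.conditions:
            if occupancy_mode == "scored":
                ct = simulate_chip_counts(promoters, truth, f, c, rng=rng)
                count_tables[(f, c)] = ct
                combined = combine_replicates([ct], mode="sum")
                ot = relative_occupancy(combined, prom_map, f, min_input=min_input)
                occupancy_tables[(f, c)] = ot
                occ = ot.scores.rename_axis("promoter_id").reset_index()
                occ["factor"] = f
                occ["condition"] = c
                occ_frames.append(occ[["promoter_id", "factor", "condition", "score"]])
            elif occupancy_mode == "direct":
                occ_frames.append(simulate_occupancy_scores(promoters, truth, f, c, rng=rng))
    occupancy = (pd.concat(occ_frames, ignore_index=True)
                 if occ_frames else pd.DataFrame(columns=["promoter_id", "factor", "condition", "score"]))
    observations = ObservationSet(
        promoters=prom_map, expression=expression, occupancy=occupancy,
    )
    return {
        "observations": observations,
        "count_tables": count_tables,
        "occupancy_tables": occupancy_tables,
        "truth": truth,
    }
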