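"""Shared fixtures and the independent brute-force oracle.

The oracle enumerates every microstate with ``itertools.product`` and sums
energies by direct bookkeeping, sharing no code with the package's
evaluation paths.
"""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

import thermoprom as tp


@pytest.fixture
def spec():
    return tp.study_spec()


@pytest.fixture
def comp_spec():
    return tp.study_spec(competitive=True)


@pytest.fixture
def params(spec):
    return tp.study_truth_params(spec)


@pytest.fixture
def comp_params(comp_spec):
    return tp.study_truth_params(comp_spec)


def random_params(rng, spec, with_tftf=True, scale=2.0):
    """Random finite energies over the spec's alphabet."""
    p = tp.study_truth_params(spec)
    for k in list(p.dG_dna):
        p.dG_dna[k] = rng.normal(0, scale)
    for k in list(p.dG_pol):
        p.dG_pol[k] = rng.normal(0, scale)
    for c in spec.conditions:
        p.dG_pol_basal[c] = rng.normal(0, scale)
    if with_tftf:
        for i, f in enumerate(spec.factors):
            for g in spec.factors[i:]:
                p.dG_tftf[(f, g)] = rng.normal(0, scale / 2)
    if spec.competitive:
        p.dG_comp_dna = rng.normal(0, scale)
        p.dG_comp_pol = rng.normal(0, scale)
    return p


def oracle_marginals(promoter, prms, condition, spec):
    """(P(pol bound), bound count per factor) by direct full enumeration.

    Independent of the package's evaluation code: states are generated
    with itertools, each state's energy is summed term by term, and
    weights are plain exp(-E) (fine for moderate energies).
    """
    options = []
    for site in promoter.sites:
        opts = ["empty", site]
        if spec.competitive and site == spec.competitor_site:
            opts.append("competitor")
        options.append(opts)
    Z = 0.0
    pol_w = 0.0
    counts = {f: 0.0 for f in spec.factors}
    for combo in itertools.product(*options):
        for pol in (0, 1):
            e = 0.0
            bound = []
            for site, occ in zip(promoter.sites, combo):
                if occ == "empty":
                    continue
                if occ == "competitor":
                    e += prms.dG_comp_dna + pol * prms.dG_comp_pol
                else:
                    e += prms.dG_dna[(occ, condition)]
                    if pol:
                        key = (occ, promoter.library_tag)
                        e += prms.dG_pol_override.get(key, prms.dG_pol.get((occ, condition)))
                    bound.append(occ)
            if pol:
                e += prms.dG_pol_basal[condition]
            for i in range(len(bound)):
                for j in range(i + 1, len(bound)):
                    a, b = sorted((bound[i], bound[j]))
                    e += prms.dG_tftf.get((a, b), 0.0)
            w = math.exp(-e)
            Z += w
            if pol:
                pol_w += w
            for f in bound:
                counts[f] += w
    return pol_w / Z, {f: counts[f] / Z for f in spec.factors}


def make_observations(seed, n_promoters=250, planted=None, chip_factors=("Cbf1", "Gcn4"),
                      censor=4.5, spec=None, expr_noise=0.05, occ_noise=0.05):
    """Simulated study dataset with direct (controlled-noise) occupancy scores."""
    spec = tp.study_spec() if spec is None else spec
    truth_params = tp.study_truth_params(spec)
    if planted:
        for pair, v in planted.items():
            truth_params.dG_tftf[tp.pair_key(*pair)] = v
    cfg = tp.SimulationConfig(
        n_promoters=n_promoters, seed=seed, censor_threshold=censor,
        chip_factors=tuple(chip_factors),
        expression_noise_sd=expr_noise, occupancy_noise_sd=occ_noise,
    )
    data = tp.end_to_end_dataset(cfg, spec=spec, params=truth_params, occupancy_mode="direct")
    return data["observations"], data["truth"]
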