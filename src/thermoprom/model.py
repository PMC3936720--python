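"""Statistical-thermodynamic model of transcription and TF occupancy.

A synthetic promoter is an ordered list of transcription-factor binding
sites drawn from a small alphabet (Cbf1, Gcn4, Met31, Nrg1 in the study
configuration).  The promoter exists as an ensemble of states: every site
is either empty or bound by its cognate TF (or, in the competitive model
variant, a Gcn4 site may instead be bound by an unidentified competitor),
and an implicit polymerase site is bound or unbound.  Unbound DNA is the
reference state with statistical weight 1; the energy of any other state
is the sum of the ΔG terms (in kT, negative = favorable) of the
protein–DNA and protein–protein contacts present in that state, and its
weight is ``exp(-energy)``.

Expression is modeled as the probability that polymerase is bound, times
a constant scale; TF occupancy as the expected number of sites bound by
the factor, mapped onto the background-relative ChIP scale as
``1 + occ_scale * bound_count``.

Two evaluation paths are provided: explicit state enumeration
(:func:`enumerate_states` / :func:`partition`), which is the transparent
reference path, and a compressed path that sums over occupancy-count
classes with multinomial multiplicities.  The two are algebraically
identical for the all-pairs interaction convention and are cross-checked
in the test suite.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "DEFAULT_FACTORS",
    "DEFAULT_CONDITIONS",
    "COMPETITOR",
    "EMPTY",
    "ConfigurationError",
    "EnumerationLimitError",
    "Promoter",
    "ModelSpec",
    "EnergyParameters",
    "PromoterState",
    "PartitionResult",
    "pair_key",
    "slot_list",
    "enumerate_states",
    "state_energy",
    "partition",
    "predict_expression",
    "predict_bound_count",
    "predict_relative_occupancy",
    "switching_equivalent",
    "competitive_equivalent",
]

DEFAULT_FACTORS: tuple[str, ...] = ("Cbf1", "Gcn4", "Met31", "Nrg1")
DEFAULT_CONDITIONS: tuple[str, ...] = ("glucose", "AAS")

#: site-state labels used in explicit enumeration
EMPTY = "empty"
COMPETITOR = "competitor"

DEFAULT_ENUMERATION_CAP = 20


class ConfigurationError(Exception):
    """An unknown factor, condition or parameter key was referenced."""


class EnumerationLimitError(Exception):
    """Explicit state enumeration would exceed the configured site cap."""


def pair_key(f: str, g: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered TF pair; (f, f) is a self pair."""
    return (f, g) if f <= g else (g, f)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Promoter:
    """One synthetic promoter: an ordered composition of binding-site tokens.

    ``library_tag`` identifies the tagged-TF strain library the promoter was
    built in (relevant only through library-specific polymerase overrides,
    e.g. the tagged-Cbf1 correction).
    """

    id: str
    sites: tuple[str, ...] = ()
    library_tag: str = ""

    @classmethod
    def from_composition(cls, id: str, composition: str, library_tag: str = "") -> "Promoter":
        """Build from a semicolon-joined token string, e.g. ``"Gcn4;Cbf1"``."""
        sites = tuple(t for t in composition.split(";") if t)
        return cls(id=id, sites=sites, library_tag=library_tag)

    @property
    def composition(self) -> str:
        return ";".join(self.sites)

    def site_count(self, factor: str | None = None) -> int:
        if factor is None:
            return len(self.sites)
        return sum(1 for s in self.sites if s == factor)

    def validate(self, alphabet: Sequence[str], cap: int = DEFAULT_ENUMERATION_CAP) -> None:
        unknown = [s for s in self.sites if s not in alphabet]
        if unknown:
            raise ConfigurationError(
                f"promoter {self.id!r}: unknown site token(s) {unknown}; alphabet is {list(alphabet)}"
            )
        if len(self.sites) > cap:
            raise EnumerationLimitError(
                f"promoter {self.id!r} has {len(self.sites)} sites, above the enumeration cap {cap}"
            )


@dataclass(frozen=True)
class ModelSpec:
    """Structure of a fittable model: which energies exist and which are free.

    The free-parameter vector is defined by the tying structure:

    * TF–DNA energies are per (factor, condition) for factors in
      ``dna_condition_specific`` and shared across conditions otherwise.
    * TF–polymerase energies are per condition for factors in
      ``pol_condition_specific`` and shared otherwise.
    * TF–TF interaction energies are free only for pairs listed in
      ``free_interactions`` (sorted 2-tuples; self pairs allowed); all other
      pairs are constrained to 0.
    * ``pol_overrides`` lists (factor, library_tag) pairs with a free
      library-specific TF–polymerase energy replacing the factor's shared
      one (the tagged-Cbf1 correction); TF–DNA energies are always shared
      between tagged and untagged versions.
    * ``competitive`` adds two shared free energies for the unidentified
      competitor at Gcn4 sites (DNA and polymerase contacts, identical in
      both conditions).
    """

    factors: tuple[str, ...] = DEFAULT_FACTORS
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    competitive: bool = False
    competitor_site: str = "Gcn4"
    dna_condition_specific: frozenset = frozenset({"Gcn4"})
    pol_condition_specific: frozenset = frozenset()
    free_interactions: frozenset = frozenset()
    pol_overrides: tuple = ()
    fit_dna: bool = True
    fit_pol: bool = True
    fit_basal: bool = True
    basal_condition_specific: bool = True
    fit_expr_scale: bool = False
    fit_occ_scale: frozenset = frozenset()
    pair_mode: str = "all_pairs"
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP

    def __post_init__(self):
        if self.pair_mode not in ("all_pairs", "adjacent"):
            raise ConfigurationError(f"unknown pair_mode {self.pair_mode!r}")
        if self.competitor_site not in self.factors:
            raise ConfigurationError(
                f"competitor_site {self.competitor_site!r} not in factor alphabet {self.factors}"
            )
        for f in itertools.chain(self.dna_condition_specific, self.pol_condition_specific):
            if f not in self.factors:
                raise ConfigurationError(f"unknown factor {f!r} in condition-specific set")
        for p in self.free_interactions:
            t = tuple(p)
            if len(t) != 2 or t != pair_key(*t) or any(f not in self.factors for f in t):
                raise ConfigurationError(f"free interaction {p!r} must be a sorted in-alphabet pair")

    @property
    def n_free_energies(self) -> int:
        """Number of free ΔG parameters implied by the tying structure."""
        return len(free_parameter_names(self))

    def site_options(self, factor: str) -> tuple[str, ...]:
        """Possible occupants of one site of the given factor."""
        if self.competitive and factor == self.competitor_site:
            return (EMPTY, factor, COMPETITOR)
        return (EMPTY, factor)


@dataclass
class EnergyParameters:
    """All ΔG terms (kT) and scaling constants of one parameterized model.

    ``dG_dna`` and ``dG_pol`` are keyed by (factor, condition); apparent
    binding energies absorb the TF's concentration/chemical potential, which
    is why they may differ between growth conditions.  ``dG_tftf`` is keyed
    by sorted pair and applies once per unordered co-bound TF pair; missing
    pairs mean 0 (independent binding).  ``dG_pol_override`` is keyed by
    (factor, library_tag) and replaces ``dG_pol`` for promoters of that
    library.  Competitor energies are scalars, shared across conditions.
    """

    dG_dna: dict = field(default_factory=dict)
    dG_pol: dict = field(default_factory=dict)
    dG_pol_basal: dict = field(default_factory=dict)
    dG_tftf: dict = field(default_factory=dict)
    dG_pol_override: dict = field(default_factory=dict)
    dG_comp_dna: float = 0.0
    dG_comp_pol: float = 0.0
    expr_scale: float = 1.0
    occ_scale: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dG_tftf = {pair_key(*k): v for k, v in self.dG_tftf.items()}

    # -- accessors -----------------------------------------------------
    def dna(self, factor: str, condition: str) -> float:
        try:
            return self.dG_dna[(factor, condition)]
        except KeyError:
            raise ConfigurationError(f"no dG_dna for factor {factor!r}, condition {condition!r}") from None

    def pol(self, factor: str, condition: str, library_tag: str = "") -> float:
        """TF–polymerase energy, honoring library-specific overrides."""
        if (factor, library_tag) in self.dG_pol_override:
            return self.dG_pol_override[(factor, library_tag)]
        try:
            return self.dG_pol[(factor, condition)]
        except KeyError:
            raise ConfigurationError(f"no dG_pol for factor {factor!r}, condition {condition!r}") from None

    def basal(self, condition: str) -> float:
        try:
            return self.dG_pol_basal[condition]
        except KeyError:
            raise ConfigurationError(f"no dG_pol_basal for condition {condition!r}") from None

    def tftf(self, f: str, g: str) -> float:
        return self.dG_tftf.get(pair_key(f, g), 0.0)

    def validate(self) -> None:
        vals = list(self.dG_dna.values()) + list(self.dG_pol.values()) + \
            list(self.dG_pol_basal.values()) + list(self.dG_tftf.values()) + \
            list(self.dG_pol_override.values()) + [self.dG_comp_dna, self.dG_comp_pol]
        if not all(math.isfinite(v) for v in vals):
            raise ConfigurationError("all ΔG values must be finite")
        if not self.expr_scale > 0:
            raise ConfigurationError("expr_scale must be > 0")
        if any(v < 0 for v in self.occ_scale.values()):
            raise ConfigurationError("occ_scale values must be >= 0")

    def copy(self) -> "EnergyParameters":
        return EnergyParameters(
            dG_dna=dict(self.dG_dna), dG_pol=dict(self.dG_pol),
            dG_pol_basal=dict(self.dG_pol_basal), dG_tftf=dict(self.dG_tftf),
            dG_pol_override=dict(self.dG_pol_override),
            dG_comp_dna=self.dG_comp_dna, dG_comp_pol=self.dG_comp_pol,
            expr_scale=self.expr_scale, occ_scale=dict(self.occ_scale),
        )

    # -- slot vector interface (used by the fitting machinery) ---------
    def get_slot(self, slot: tuple) -> float:
        kind = slot[0]
        if kind == "dna":
            return self.dG_dna.get((slot[1], slot[2]), 0.0)
        if kind == "pol":
            return self.dG_pol.get((slot[1], slot[2]), 0.0)
        if kind == "basal":
            return self.dG_pol_basal.get(slot[1], 0.0)
        if kind == "tftf":
            return self.dG_tftf.get((slot[1], slot[2]), 0.0)
        if kind == "pol_override":
            return self.dG_pol_override.get((slot[1], slot[2]), 0.0)
        if kind == "comp_dna":
            return self.dG_comp_dna
        if kind == "comp_pol":
            return self.dG_comp_pol
        raise ConfigurationError(f"unknown slot {slot!r}")

    def set_slot(self, slot: tuple, value: float) -> None:
        kind = slot[0]
        if kind == "dna":
            self.dG_dna[(slot[1], slot[2])] = value
        elif kind == "pol":
            self.dG_pol[(slot[1], slot[2])] = value
        elif kind == "basal":
            self.dG_pol_basal[slot[1]] = value
        elif kind == "tftf":
            self.dG_tftf[(slot[1], slot[2])] = value
        elif kind == "pol_override":
            self.dG_pol_override[(slot[1], slot[2])] = value
        elif kind == "comp_dna":
            self.dG_comp_dna = value
        elif kind == "comp_pol":
            self.dG_comp_pol = value
        else:
            raise ConfigurationError(f"unknown slot {slot!r}")

    def to_slot_vector(self, slots: Sequence[tuple]) -> np.ndarray:
        return np.array([self.get_slot(s) for s in slots], dtype=float)

    def with_slot_vector(self, slots: Sequence[tuple], values: np.ndarray) -> "EnergyParameters":
        out = self.copy()
        for s, v in zip(slots, values):
            out.set_slot(s, float(v))
        return out


def slot_list(spec: ModelSpec) -> tuple:
    """Canonical ordered list of every energy slot the spec's model uses.

    A state's energy is linear in this slot vector; the fitting machinery
    exploits that by precomputing per-state coefficient matrices.
    """
    slots = []
    for f in spec.factors:
        for c in spec.conditions:
            slots.append(("dna", f, c))
    for f in spec.factors:
        for c in spec.conditions:
            slots.append(("pol", f, c))
    for c in spec.conditions:
        slots.append(("basal", c))
    for i, f in enumerate(spec.factors):
        for g in spec.factors[i:]:
            slots.append(("tftf",) + pair_key(f, g))
    if spec.competitive:
        slots.append(("comp_dna",))
        slots.append(("comp_pol",))
    for f, tag in spec.pol_overrides:
        slots.append(("pol_override", f, tag))
    return tuple(slots)


def free_parameter_names(spec: ModelSpec) -> tuple:
    """Names of the free ΔG parameters implied by the spec's tying structure.

    Each name maps to one or more slots; see :func:`free_parameter_map`.
    """
    names = []
    if spec.fit_dna:
        for f in spec.factors:
            if f in spec.dna_condition_specific:
                names += [("dna", f, c) for c in spec.conditions]
            else:
                names.append(("dna", f))
    if spec.fit_pol:
        for f in spec.factors:
            if f in spec.pol_condition_specific:
                names += [("pol", f, c) for c in spec.conditions]
            else:
                names.append(("pol", f))
        for f, tag in spec.pol_overrides:
            names.append(("pol_override", f, tag))
    if spec.fit_basal:
        if spec.basal_condition_specific:
            names += [("basal", c) for c in spec.conditions]
        else:
            names.append(("basal",))
    for p in sorted(tuple(p) for p in spec.free_interactions):
        names.append(("tftf",) + p)
    if spec.competitive:
        names += [("comp_dna",), ("comp_pol",)]
    return tuple(names)


def free_parameter_map(spec: ModelSpec) -> tuple:
    """(names, T, free_mask): slot_vector = T @ theta + base_slots * (~free_mask).

    ``T`` is the 0/1 tying matrix (n_slots x n_free); ``free_mask`` marks
    slots governed by the free vector (their base values are ignored).
    """
    slots = slot_list(spec)
    names = free_parameter_names(spec)
    slot_pos = {s: i for i, s in enumerate(slots)}
    T = np.zeros((len(slots), len(names)))
    free_mask = np.zeros(len(slots), dtype=bool)
    for j, name in enumerate(names):
        kind = name[0]
        if kind in ("dna", "pol") and len(name) == 2:
            covered = [(kind, name[1], c) for c in spec.conditions]
        elif kind == "basal" and len(name) == 1:
            covered = [("basal", c) for c in spec.conditions]
        else:
            covered = [name]
        for s in covered:
            i = slot_pos[s]
            T[i, j] = 1.0
            free_mask[i] = True
    return names, T, free_mask


# ---------------------------------------------------------------------------
# explicit state enumeration (reference path)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterState:
    """One microstate: the occupant of every site plus the polymerase state."""

    site_states: tuple[str, ...]
    pol: bool


def enumerate_states(promoter: Promoter, spec: ModelSpec) -> list[PromoterState]:
    """All microstates of a promoter: 2 x prod(2 or 3 per site).

    Gcn4 sites have three possible occupants (empty / Gcn4 / competitor)
    under the competitive model and two otherwise.
    """
    promoter.validate(spec.factors, spec.enumeration_cap)
    options = [spec.site_options(f) for f in promoter.sites]
    return [
        PromoterState(site_states=combo, pol=pol)
        for combo in itertools.product(*options)
        for pol in (False, True)
    ]


def state_energy(
    state: PromoterState,
    promoter: Promoter,
    params: EnergyParameters,
    condition: str,
    spec: ModelSpec | None = None,
) -> float:
    """Energy (kT) of one microstate: the sum of the ΔGs of its contacts.

    Contacts are: each bound TF with its site, each bound competitor with
    its site, polymerase with the promoter (basal) plus each bound protein
    (when polymerase is bound), and every unordered pair of co-bound TFs
    (the competitor has no modeled TF contacts).  Under
    ``spec.pair_mode == "adjacent"`` only co-bound TFs on neighboring sites
    (no bound TF between them) interact.
    """
    pair_mode = spec.pair_mode if spec is not None else "all_pairs"
    e = 0.0
    bound: list[str] = []  # factors of TF-bound sites, in site order
    for site, occ in zip(promoter.sites, state.site_states):
        if occ == EMPTY:
            continue
        if occ == COMPETITOR:
            e += params.dG_comp_dna
            if state.pol:
                e += params.dG_comp_pol
        else:
            if occ != site:
                raise ConfigurationError(
                    f"promoter {promoter.id!r}: site {site!r} cannot be bound by {occ!r}"
                )
            e += params.dna(occ, condition)
            if state.pol:
                e += params.pol(occ, condition, promoter.library_tag)
            bound.append(occ)
    if state.pol:
        e += params.basal(condition)
    if pair_mode == "all_pairs":
        for i in range(len(bound)):
            for j in range(i + 1, len(bound)):
                e += params.tftf(bound[i], bound[j])
    else:
        for i in range(len(bound) - 1):
            e += params.tftf(bound[i], bound[i + 1])
    return e


@dataclass
class PartitionResult:
    """States, their Boltzmann statistics and the partition function."""

    states: list
    log_weights: np.ndarray
    log_Z: float

    @property
    def Z(self) -> float:
        return float(np.exp(self.log_Z))

    @property
    def probabilities(self) -> np.ndarray:
        return np.exp(self.log_weights - self.log_Z)


def partition(
    promoter: Promoter,
    params: EnergyParameters,
    condition: str,
    spec: ModelSpec,
) -> PartitionResult:
    """Full-enumeration partition function and state probabilities.

    The all-empty, polymerase-unbound state has energy 0 and weight 1
    (unbound DNA is the reference state).  Weights are handled in log
    space so extreme energies cannot overflow.
    """
    states = enumerate_states(promoter, spec)
    logw = np.array(
        [-state_energy(s, promoter, params, condition, spec) for s in states]
    )
    return PartitionResult(states=states, log_weights=logw, log_Z=float(logsumexp(logw)))


# ---------------------------------------------------------------------------
# compressed path: sum over occupancy-count classes
# ---------------------------------------------------------------------------

@lru_cache(maxsize=65536)
def _count_classes(
    n_by_factor: tuple, competitive_factor_idx: int
) -> tuple:
    """Occupancy-count classes of a promoter, with multinomial multiplicities.

    ``n_by_factor`` gives the number of sites per factor (fixed order).  A
    class is (k_0, ..., k_F-1, m): k_f sites bound by factor f and, if
    ``competitive_factor_idx >= 0``, m of that factor's sites bound by the
    competitor.  Returns (K, m, log_mult) as numpy arrays.

    Valid only for the all-pairs interaction convention, where state energy
    depends on the counts alone.
    """
    per_factor_choices = []
    for idx, n in enumerate(n_by_factor):
        choices = []
        if idx == competitive_factor_idx:
            for k in range(n + 1):
                for m in range(n - k + 1):
                    lm = (math.lgamma(n + 1) - math.lgamma(k + 1)
                          - math.lgamma(m + 1) - math.lgamma(n - k - m + 1))
                    choices.append((k, m, lm))
        else:
            for k in range(n + 1):
                lm = math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
                choices.append((k, 0, lm))
        per_factor_choices.append(choices)

    K_rows, m_rows, lm_rows = [], [], []
    for combo in itertools.product(*per_factor_choices):
        K_rows.append([c[0] for c in combo])
        m_rows.append(sum(c[1] for c in combo))
        lm_rows.append(sum(c[2] for c in combo))
    K = np.array(K_rows, dtype=float)
    m = np.array(m_rows, dtype=float)
    lm = np.array(lm_rows, dtype=float)
    K.setflags(write=False); m.setflags(write=False); lm.setflags(write=False)
    return K, m, lm


def _marginals_compressed(
    promoter: Promoter,
    params: EnergyParameters,
    condition: str,
    spec: ModelSpec,
) -> tuple[float, dict]:
    """(P(polymerase bound), expected bound count per factor) via count classes."""
    promoter.validate(spec.factors, spec.enumeration_cap)
    factors = spec.factors
    n_by_factor = tuple(promoter.site_count(f) for f in factors)
    comp_idx = factors.index(spec.competitor_site) if spec.competitive else -1
    K, m, lm = _count_classes(n_by_factor, comp_idx)

    dna_vec = np.array([params.dna(f, condition) for f in factors])
    pol_vec = np.array([params.pol(f, condition, promoter.library_tag) for f in factors])
    Tm = np.array([[params.tftf(f, g) for g in factors] for f in factors])

    # all-pairs interaction energy: sum over unordered co-bound TF pairs
    pair_e = 0.5 * np.einsum("rf,fg,rg->r", K, Tm, K) - 0.5 * K @ np.diag(Tm)
    e_nopol = K @ dna_vec + m * params.dG_comp_dna + pair_e
    e_pol = e_nopol + params.basal(condition) + K @ pol_vec + m * params.dG_comp_pol

    logw = np.concatenate([lm - e_nopol, lm - e_pol])
    log_Z = logsumexp(logw)
    p = np.exp(logw - log_Z)
    n_cls = len(lm)
    p_pol = float(p[n_cls:].sum())
    p_cls = p[:n_cls] + p[n_cls:]
    counts = {f: float(p_cls @ K[:, i]) for i, f in enumerate(factors)}
    return p_pol, counts


def _marginals_enumerated(
    promoter: Promoter,
    params: EnergyParameters,
    condition: str,
    spec: ModelSpec,
) -> tuple[float, dict]:
    """(P(pol bound), expected bound counts) via explicit enumeration."""
    part = partition(promoter, params, condition, spec)
    p = part.probabilities
    p_pol = float(sum(pi for pi, s in zip(p, part.states) if s.pol))
    counts = {f: 0.0 for f in spec.factors}
    for pi, s in zip(p, part.states):
        for site, occ in zip(promoter.sites, s.site_states):
            if occ not in (EMPTY, COMPETITOR):
                counts[occ] += float(pi)
    return p_pol, counts


def _marginals(promoter, params, condition, spec):
    if spec.pair_mode == "all_pairs":
        return _marginals_compressed(promoter, params, condition, spec)
    return _marginals_enumerated(promoter, params, condition, spec)


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def predict_expression(
    promoter: Promoter,
    params: EnergyParameters,
    condition: str,
    spec: ModelSpec,
) -> float:
    """Normalized expression: expr_scale times P(polymerase bound)."""
    p_pol, _ = _marginals(promoter, params, condition, spec)
    return params.expr_scale * p_pol


def predict_bound_count(
    promoter: Promoter,
    factor: str,
    params: EnergyParameters,
    condition: str,
    spec: ModelSpec,
) -> float:
    """Expected number of sites bound by ``factor`` (in [0, n_sites(factor)])."""
    if factor not in spec.factors:
        raise ConfigurationError(f"factor {factor!r} not in alphabet {spec.factors}")
    _, counts = _marginals(promoter, params, condition, spec)
    return counts[factor]


def predict_relative_occupancy(
    promoter: Promoter,
    factor: str,
    params: EnergyParameters,
    condition: str,
    spec: ModelSpec,
) -> float:
    """Background-relative ChIP occupancy score: 1 + occ_scale * bound count.

    A promoter with no sites for the factor scores exactly 1, matching the
    background-median normalization of the measured scores.
    """
    return 1.0 + params.occ_scale.get(factor, 0.0) * predict_bound_count(
        promoter, factor, params, condition, spec
    )


# ---------------------------------------------------------------------------
# competitive <-> switching degeneracy (expression-only indistinguishability)
# ---------------------------------------------------------------------------

def switching_equivalent(
    params: EnergyParameters, spec: ModelSpec
) -> EnergyParameters:
    """Map competitive-model parameters to switching-model parameters with
    identical expression predictions.

    With no TF–TF interactions involving the competed factor, each 3-state
    site (empty / Gcn4 / competitor) collapses exactly to an effective
    2-state site with association weight ``q' = q + r`` and polymerase
    weight ``w' = (q*wg + r*wr) / (q + r)`` per condition.  This is the
    algebraic content of the claim that expression data alone cannot
    distinguish a competitor from a condition-switching Gcn4.
    """
    if not spec.competitive:
        raise ConfigurationError("switching_equivalent requires a competitive spec")
    g = spec.competitor_site
    if any(params.tftf(g, f) != 0.0 for f in spec.factors):
        raise ConfigurationError(
            "collapse is exact only when the competed factor has no TF-TF interactions"
        )
    out = params.copy()
    out.dG_comp_dna = 0.0
    out.dG_comp_pol = 0.0
    r = math.exp(-params.dG_comp_dna)
    wr = math.exp(-params.dG_comp_pol)
    for c in spec.conditions:
        q = math.exp(-params.dna(g, c))
        wg = math.exp(-params.dG_pol[(g, c)])
        q_eff = q + r
        w_eff = (q * wg + r * wr) / q_eff
        out.dG_dna[(g, c)] = -math.log(q_eff)
        out.dG_pol[(g, c)] = -math.log(w_eff)
    return out


def competitive_equivalent(
    params: EnergyParameters,
    spec: ModelSpec,
    r_fraction: float = 0.5,
) -> EnergyParameters | None:
    """Inverse of :func:`switching_equivalent` when it exists.

    Given switching-model parameters (condition-specific Gcn4 DNA and
    polymerase energies), solve for competitive-model parameters (shared
    competitor energies, condition-constant Gcn4–polymerase energy) that
    reproduce the same effective per-site weights in both conditions.  The
    system is underdetermined by one dof; the competitor's DNA weight is
    placed at ``r_fraction`` of its feasible interval (where all weights
    stay positive).  Returns None when that interval is empty, i.e. no
    competitive model reproduces the switching behavior exactly.
    """
    g = spec.competitor_site
    if any(params.tftf(g, f) != 0.0 for f in spec.factors):
        return None
    c1, c2 = spec.conditions[0], spec.conditions[1]
    q1 = math.exp(-params.dna(g, c1))
    q2 = math.exp(-params.dna(g, c2))
    w1 = math.exp(-params.dG_pol[(g, c1)])
    w2 = math.exp(-params.dG_pol[(g, c2)])
    if abs(q1 - q2) < 1e-12:
        return None
    wg = (q1 * w1 - q2 * w2) / (q1 - q2)
    if wg <= 0:
        return None
    # feasible competitor weight: 0 < r < min(q'); wr > 0 additionally
    # requires r > q1*(wg - w1)/wg when the competitor represses (w1 < wg)
    r_hi = min(q1, q2)
    r_lo = max(0.0, q1 * (wg - w1) / wg)
    if r_lo >= r_hi:
        return None
    r = r_lo + r_fraction * (r_hi - r_lo)
    wr = wg + q1 * (w1 - wg) / r
    if wr <= 0:
        return None
    out = params.copy()
    out.dG_comp_dna = -math.log(r)
    out.dG_comp_pol = -math.log(wr)
    for c, q in ((c1, q1), (c2, q2)):
        out.dG_dna[(g, c)] = -math.log(q - r)
        out.dG_pol[(g, c)] = -math.log(wg)
    return out
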