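"""Fitting thermodynamic models to expression and occupancy observations.

Free energies are estimated by nonlinear least squares on the combined
(optionally weighted) expression and occupancy residuals, with multiple
random starts inside box bounds.  Nested models are compared with F-tests;
TF–TF interactions are added by Bonferroni-corrected forward selection;
models are validated by k-fold cross-validation; and multistart/Jacobian
diagnostics expose non-identifiability (the signature that discriminated
the competitive from the switching mechanism for Gcn4).

Implementation note: a promoter state's energy is *linear* in the vector
of all ΔG slots, so each observation record reduces to a fixed coefficient
matrix over its occupancy-count classes.  Residuals and an analytic
Jacobian are then dense linear algebra over all records at once, which is
what makes multistart fitting and simulation studies affordable.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import logsumexp
from scipy.stats import f as f_dist

from .model import (
    COMPETITOR,
    EMPTY,
    ConfigurationError,
    EnergyParameters,
    ModelSpec,
    Promoter,
    enumerate_states,
    free_parameter_map,
    free_parameter_names,
    pair_key,
    slot_list,
    _count_classes,
)

__all__ = [
    "ObservationSet",
    "FitResult",
    "ComparisonResult",
    "CVResult",
    "SelectionResult",
    "Objective",
    "objective",
    "fit_model",
    "r_squared",
    "nested_f_test",
    "forward_select_interactions",
    "cross_validate",
    "multistart_diagnostics",
]

DEFAULT_BOUNDS = (-10.0, 10.0)
SINGULAR_CONDITION_THRESHOLD = 1e8


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

@dataclass
class ObservationSet:
    """Expression and occupancy measurements keyed by promoter x condition.

    ``expression`` columns: promoter_id, condition, value (NaN marks a
    censored/missing measurement, e.g. expression beyond the flow
    cytometer's dynamic range — such records are excluded from fitting,
    never imputed).  ``occupancy`` columns: promoter_id, factor, condition,
    score (background-relative).  Promoter compositions and library tags
    live in ``promoters``.
    """

    promoters: dict
    expression: pd.DataFrame
    occupancy: pd.DataFrame

    def __post_init__(self):
        if self.expression is None or len(self.expression) == 0:
            self.expression = pd.DataFrame(columns=["promoter_id", "condition", "value"])
        if self.occupancy is None or len(self.occupancy) == 0:
            self.occupancy = pd.DataFrame(columns=["promoter_id", "factor", "condition", "score"])
        self.expression = self.expression.reset_index(drop=True)
        self.occupancy = self.occupancy.reset_index(drop=True)
        for df, cols in ((self.expression, ("promoter_id", "condition", "value")),
                         (self.occupancy, ("promoter_id", "factor", "condition", "score"))):
            missing = set(cols) - set(df.columns)
            if missing:
                raise ValueError(f"observation table lacks columns {sorted(missing)}")
        known = set(self.promoters)
        for df in (self.expression, self.occupancy):
            bad = set(df["promoter_id"]) - known
            if bad:
                raise ValueError(f"observations reference unknown promoters: {sorted(bad)[:5]}")

    @property
    def observed_expression(self) -> pd.DataFrame:
        return self.expression[self.expression["value"].notna()]

    @property
    def n_records(self) -> int:
        return len(self.observed_expression) + len(self.occupancy)

    def subset(self, expr_index: Sequence[int], occ_index: Sequence[int]) -> "ObservationSet":
        return ObservationSet(
            promoters=self.promoters,
            expression=self.expression.loc[list(expr_index)],
            occupancy=self.occupancy.loc[list(occ_index)],
        )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: EnergyParameters
    spec: ModelSpec
    theta: np.ndarray
    parameter_names: tuple
    objective_value: float
    rss: dict
    r2: dict
    n_obs: int
    n_free: int
    converged: bool
    n_starts: int
    seed: object
    jacobian_condition: float
    start_objectives: np.ndarray

    @property
    def singular(self) -> bool:
        c = self.jacobian_condition
        return (not math.isfinite(c)) or c > SINGULAR_CONDITION_THRESHOLD


@dataclass
class ComparisonResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    alpha_threshold: float = float("nan")
    significant: bool = False


@dataclass
class CVResult:
    folds: list
    assignments: pd.DataFrame
    k: int
    seed: object

    @property
    def mean_test_r2(self) -> float:
        vals = [f["test_r2"] for f in self.folds if not f.get("flagged")]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_train_r2(self) -> float:
        vals = [f["train_r2"] for f in self.folds if not f.get("flagged")]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass
class SelectionResult:
    spec: ModelSpec
    fit: FitResult
    trail: pd.DataFrame
    retained: tuple


# ---------------------------------------------------------------------------
# objective: stacked linear-coefficient design over all records
# ---------------------------------------------------------------------------

class Objective:
    """Sum-of-squares objective with analytic Jacobian for one observation set.

    The free-parameter vector ``theta`` consists of the spec's free ΔGs
    (see :func:`thermoprom.model.free_parameter_names`) optionally followed
    by ``expr_scale`` and ``occ_scale`` entries when the spec frees them.
    """

    def __init__(
        self,
        spec: ModelSpec,
        observations: ObservationSet,
        base_params: EnergyParameters,
        weights: Mapping[str, float] | None = None,
        residual_scale: str = "absolute",
    ):
        if observations.n_records == 0:
            raise ValueError("empty observation set")
        weights = dict(weights or {})
        self.w_expr = float(weights.get("expression", 1.0))
        self.w_occ = float(weights.get("occupancy", 1.0))
        if self.w_expr < 0 or self.w_occ < 0:
            raise ValueError("data-type weights must be >= 0")
        if residual_scale not in ("absolute", "relative", "log"):
            raise ValueError(f"unknown residual_scale {residual_scale!r}")
        self.residual_scale = residual_scale
        self.spec = spec
        self.base_params = base_params.copy()
        self.slots = slot_list(spec)
        self.names, self.T, self.free_mask = free_parameter_map(spec)
        base_slot_vec = base_params.to_slot_vector(self.slots)
        self.v_fixed = np.where(self.free_mask, 0.0, base_slot_vec)

        extra = set(base_params.dG_pol_override) - set(spec.pol_overrides)
        if extra:
            raise ConfigurationError(
                f"base parameters carry pol overrides {sorted(extra)} not declared in the spec"
            )
        self._override_keys = set(spec.pol_overrides)

        self.scale_names = []
        if spec.fit_expr_scale:
            self.scale_names.append(("expr_scale",))
        for fct in sorted(spec.fit_occ_scale):
            self.scale_names.append(("occ_scale", fct))
        self.n_free = len(self.names) + len(self.scale_names)

        self._build_design(observations)

    # -- design construction ------------------------------------------
    def _record_block(self, promoter: Promoter, condition: str, y_factor: str | None):
        """Coefficient rows for one record.

        Returns (A, logmult, y): per-state-class slot coefficients, log
        multiplicities, and the response coefficient (polymerase indicator
        when ``y_factor`` is None, else that factor's bound-site count).
        """
        spec = self.spec
        key = (
            tuple(promoter.site_count(f) for f in spec.factors)
            if spec.pair_mode == "all_pairs" else tuple(promoter.sites),
            promoter.library_tag, condition, y_factor,
        )
        cached = self._block_cache.get(key)
        if cached is not None:
            return cached
        slot_pos = self._slot_pos
        S = len(self.slots)
        factors = spec.factors

        def pol_col(f):
            if (f, promoter.library_tag) in self._override_keys:
                return slot_pos[("pol_override", f, promoter.library_tag)]
            return slot_pos[("pol", f, condition)]

        if spec.pair_mode == "all_pairs":
            K, m, lm = _count_classes(
                tuple(promoter.site_count(f) for f in factors),
                factors.index(spec.competitor_site) if spec.competitive else -1,
            )
            n_cls = len(lm)
            A0 = np.zeros((n_cls, S))
            for i, f in enumerate(factors):
                A0[:, slot_pos[("dna", f, condition)]] += K[:, i]
            if spec.competitive:
                A0[:, slot_pos[("comp_dna",)]] += m
            for i, f in enumerate(factors):
                A0[:, slot_pos[("tftf", *pair_key(f, f))]] += K[:, i] * (K[:, i] - 1) / 2
                for j in range(i + 1, len(factors)):
                    g = factors[j]
                    A0[:, slot_pos[("tftf", *pair_key(f, g))]] += K[:, i] * K[:, j]
            A1 = A0.copy()
            A1[:, slot_pos[("basal", condition)]] += 1.0
            for i, f in enumerate(factors):
                A1[:, pol_col(f)] += K[:, i]
            if spec.competitive:
                A1[:, slot_pos[("comp_pol",)]] += m
            A = np.vstack([A0, A1])
            logmult = np.concatenate([lm, lm])
            if y_factor is None:
                y = np.concatenate([np.zeros(n_cls), np.ones(n_cls)])
            else:
                kf = K[:, factors.index(y_factor)]
                y = np.concatenate([kf, kf])
        else:
            # adjacent-pair convention: energies depend on site order, so
            # coefficients are built from explicit states
            states = enumerate_states(promoter, spec)
            A = np.zeros((len(states), S))
            y = np.zeros(len(states))
            for r, st in enumerate(states):
                bound = []
                for site, occ in zip(promoter.sites, st.site_states):
                    if occ == EMPTY:
                        continue
                    if occ == COMPETITOR:
                        A[r, slot_pos[("comp_dna",)]] += 1.0
                        if st.pol:
                            A[r, slot_pos[("comp_pol",)]] += 1.0
                    else:
                        A[r, slot_pos[("dna", occ, condition)]] += 1.0
                        if st.pol:
                            A[r, pol_col(occ)] += 1.0
                        bound.append(occ)
                if st.pol:
                    A[r, slot_pos[("basal", condition)]] += 1.0
                for a, b in zip(bound, bound[1:]):
                    A[r, slot_pos[("tftf", *pair_key(a, b))]] += 1.0
                if y_factor is None:
                    y[r] = 1.0 if st.pol else 0.0
                else:
                    y[r] = sum(1 for s_, o_ in zip(promoter.sites, st.site_states)
                               if o_ == y_factor)
            logmult = np.zeros(len(states))
        out = (A, logmult, y)
        self._block_cache[key] = out
        return out

    def _build_design(self, observations: ObservationSet):
        self._block_cache: dict = {}
        self._slot_pos = {s: i for i, s in enumerate(self.slots)}
        A_blocks, lm_blocks, y_blocks = [], [], []
        kinds, obs_vals, occ_factors, rec_ids = [], [], [], []
        row_counts = []
        for _, row in observations.observed_expression.iterrows():
            p = observations.promoters[row["promoter_id"]]
            A, lm, y = self._record_block(p, row["condition"], None)
            A_blocks.append(A); lm_blocks.append(lm); y_blocks.append(y)
            kinds.append(0); obs_vals.append(float(row["value"]))
            occ_factors.append(""); rec_ids.append((0, row["promoter_id"], row["condition"]))
            row_counts.append(len(lm))
        for _, row in observations.occupancy.iterrows():
            fct = row["factor"]
            if fct not in self.spec.factors:
                raise ConfigurationError(f"occupancy record for unknown factor {fct!r}")
            p = observations.promoters[row["promoter_id"]]
            A, lm, y = self._record_block(p, row["condition"], fct)
            A_blocks.append(A); lm_blocks.append(lm); y_blocks.append(y)
            kinds.append(1); obs_vals.append(float(row["score"]))
            occ_factors.append(fct); rec_ids.append((1, row["promoter_id"], row["condition"]))
            row_counts.append(len(lm))

        self.A = np.vstack(A_blocks)
        self.logmult = np.concatenate(lm_blocks)
        self.y = np.concatenate(y_blocks)
        self.kind = np.array(kinds)
        self.obs = np.array(obs_vals)
        self.occ_factor = np.array(occ_factors, dtype=object)
        self.record_ids = rec_ids
        self.row_counts = np.array(row_counts)
        self.starts = np.concatenate([[0], np.cumsum(self.row_counts)])[:-1]
        self.n_groups = len(self.kind)
        w = np.where(self.kind == 0, self.w_expr, self.w_occ)
        if self.residual_scale == "relative":
            # residuals divided by the observed value
            if (self.obs <= 0).any():
                raise ValueError("relative residual scale requires positive observations")
            w = w / self.obs**2
        elif self.residual_scale == "log":
            # log(pred) - log(obs): iid Gaussian under multiplicative
            # lognormal noise, which keeps the nested F-tests calibrated
            if (self.obs <= 0).any():
                raise ValueError("log residual scale requires positive observations")
            self._log_obs = np.log(self.obs)
        self.sqrt_w = np.sqrt(w)
        # per-group base scale (occ_scale of the scored factor / expr_scale)
        self._base_scale = np.array([
            self.base_params.expr_scale if k == 0
            else self.base_params.occ_scale.get(f, 0.0)
            for k, f in zip(self.kind, self.occ_factor)
        ])
        self._offset = np.where(self.kind == 0, 0.0, 1.0)

    # -- theta handling ------------------------------------------------
    def _split(self, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        n_e = len(self.names)
        v_full = self.T @ theta[:n_e] + self.v_fixed
        scale = self._base_scale.copy()
        scale_grads = []
        for j, sname in enumerate(self.scale_names):
            val = theta[n_e + j]
            if sname[0] == "expr_scale":
                sel = self.kind == 0
            else:
                sel = (self.kind == 1) & (self.occ_factor == sname[1])
            scale[sel] = val
            scale_grads.append(sel)
        return v_full, scale, scale_grads

    def _group_stats(self, v_full: np.ndarray):
        logw = self.logmult - self.A @ v_full
        gmax = np.maximum.reduceat(logw, self.starts)
        w = np.exp(logw - np.repeat(gmax, self.row_counts))
        S0 = np.add.reduceat(w, self.starts)
        S1 = np.add.reduceat(w * self.y, self.starts)
        return w, S0, S1

    def predictions(self, theta: np.ndarray) -> np.ndarray:
        v_full, scale, _ = self._split(theta)
        _, S0, S1 = self._group_stats(v_full)
        return scale * (S1 / S0) + self._offset

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        pred = self.predictions(theta)
        if self.residual_scale == "log":
            return self.sqrt_w * (np.log(np.maximum(pred, 1e-300)) - self._log_obs)
        return self.sqrt_w * (pred - self.obs)

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        v_full, scale, scale_grads = self._split(theta)
        w, S0, S1 = self._group_stats(v_full)
        frac = S1 / S0
        M0 = np.add.reduceat(w[:, None] * self.A, self.starts, axis=0)
        M1 = np.add.reduceat((w * self.y)[:, None] * self.A, self.starts, axis=0)
        dfrac_dv = -(M1 - frac[:, None] * M0) / S0[:, None]
        front = scale * self.sqrt_w
        if self.residual_scale == "log":
            pred = scale * frac + self._offset
            front = front / np.maximum(pred, 1e-12)
            scale_front = self.sqrt_w * frac / np.maximum(pred, 1e-12)
        else:
            scale_front = self.sqrt_w * frac
        J_energy = front[:, None] * (dfrac_dv @ self.T)
        cols = [J_energy]
        for sel in scale_grads:
            cols.append((scale_front * sel)[:, None])
        return np.hstack(cols)

    def value(self, theta: np.ndarray) -> float:
        r = self.residuals(theta)
        return float(r @ r)

    def rss_by_kind(self, theta: np.ndarray) -> dict:
        r_raw = self.predictions(theta) - self.obs
        return {
            "expression": float(np.sum(r_raw[self.kind == 0] ** 2)),
            "occupancy": float(np.sum(r_raw[self.kind == 1] ** 2)),
        }

    def params_from_theta(self, theta: np.ndarray) -> EnergyParameters:
        theta = np.asarray(theta, dtype=float)
        n_e = len(self.names)
        v_full = self.T @ theta[:n_e] + self.v_fixed
        out = self.base_params.with_slot_vector(self.slots, v_full)
        for j, sname in enumerate(self.scale_names):
            if sname[0] == "expr_scale":
                out.expr_scale = float(theta[n_e + j])
            else:
                out.occ_scale[sname[1]] = float(theta[n_e + j])
        return out

    def theta_from_params(self, params: EnergyParameters) -> np.ndarray:
        theta = []
        for name in self.names:
            kind = name[0]
            if kind in ("dna", "pol") and len(name) == 2:
                slot = (kind, name[1], self.spec.conditions[0])
            elif kind == "basal" and len(name) == 1:
                slot = ("basal", self.spec.conditions[0])
            else:
                slot = name
            theta.append(params.get_slot(slot))
        for sname in self.scale_names:
            if sname[0] == "expr_scale":
                theta.append(params.expr_scale)
            else:
                theta.append(params.occ_scale.get(sname[1], 1.0))
        return np.array(theta, dtype=float)

    def with_spec(self, spec: ModelSpec) -> "Objective":
        """Same design (observations, coefficient matrices), new tying structure.

        Valid for specs that share the slot layout — e.g. the nested
        alternatives of forward selection, which differ only in which
        TF-TF energies are free.
        """
        import copy

        if slot_list(spec) != self.slots or spec.pair_mode != self.spec.pair_mode:
            raise ConfigurationError("spec is not design-compatible with this objective")
        new = copy.copy(self)
        new.spec = spec
        new.names, new.T, new.free_mask = free_parameter_map(spec)
        base_slot_vec = new.base_params.to_slot_vector(new.slots)
        new.v_fixed = np.where(new.free_mask, 0.0, base_slot_vec)
        new.scale_names = []
        if spec.fit_expr_scale:
            new.scale_names.append(("expr_scale",))
        for fct in sorted(spec.fit_occ_scale):
            new.scale_names.append(("occ_scale", fct))
        new.n_free = len(new.names) + len(new.scale_names)
        return new

    def bounds_arrays(self, bounds=DEFAULT_BOUNDS, scale_bounds=(1e-6, 1e3)):
        lo = np.full(self.n_free, bounds[0])
        hi = np.full(self.n_free, bounds[1])
        n_e = len(self.names)
        lo[n_e:], hi[n_e:] = scale_bounds
        return lo, hi


def objective(
    theta: np.ndarray,
    spec: ModelSpec,
    observations: ObservationSet,
    weights: Mapping[str, float] | None = None,
    base_params: EnergyParameters | None = None,
) -> float:
    """Weighted sum of squared residuals at the given free-parameter vector.

    Convenience wrapper around :class:`Objective`; missing expression
    values contribute nothing.
    """
    if base_params is None:
        base_params = default_base_params(spec)
    return Objective(spec, observations, base_params, weights).value(theta)


def default_base_params(spec: ModelSpec) -> EnergyParameters:
    """Neutral parameters (all ΔG = 0) covering every slot of the spec."""
    p = EnergyParameters(
        dG_dna={(f, c): 0.0 for f in spec.factors for c in spec.conditions},
        dG_pol={(f, c): 0.0 for f in spec.factors for c in spec.conditions},
        dG_pol_basal={c: 0.0 for c in spec.conditions},
        dG_pol_override={k: 0.0 for k in spec.pol_overrides},
        expr_scale=1.0,
        occ_scale={f: 1.0 for f in spec.factors},
    )
    return p


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_model(
    spec: ModelSpec,
    observations: ObservationSet,
    base_params: EnergyParameters,
    n_starts: int = 10,
    seed: object = 0,
    bounds: tuple = DEFAULT_BOUNDS,
    tol: float = 1e-12,
    weights: Mapping[str, float] | None = None,
    extra_starts: Sequence[np.ndarray] = (),
    residual_scale: str = "log",
    objective: Objective | None = None,
    max_nfev: int | None = None,
) -> FitResult:
    """Best-of-``n_starts`` bounded nonlinear least squares fit.

    Starts are drawn uniformly inside ``bounds`` from a generator seeded by
    ``seed`` (results are reproducible bit-for-bit); ``extra_starts`` are
    tried first and are how nested alternatives are warm-started from a
    null fit.  The returned result carries per-data-type RSS and R², the
    best objective across starts, and the Jacobian condition number at the
    optimum (singularities flag non-identifiable parameterizations).

    Residuals default to the relative scale (divided by the observed
    value), matching the multiplicative noise of flow-cytometry and
    sequencing readouts and keeping the nested-model F-tests calibrated;
    pass ``residual_scale="absolute"`` for plain squared differences.  A
    prebuilt ``objective`` (e.g. shared across nested specs) bypasses the
    design construction.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    obj = objective if objective is not None else Objective(
        spec, observations, base_params, weights, residual_scale)
    if obj.spec != spec:
        raise ValueError("prebuilt objective was constructed for a different spec")
    if obj.n_free >= obj.n_groups:
        raise ValueError(
            f"{obj.n_free} free parameters for only {obj.n_groups} observations")
    if obj.n_free == 0:
        # fully constrained model: the objective at the base parameters is the fit
        theta = np.zeros(0)
        return FitResult(
            params=obj.params_from_theta(theta), spec=spec, theta=theta,
            parameter_names=(), objective_value=obj.value(theta),
            rss=obj.rss_by_kind(theta),
            r2=_r2_by_kind(obj, theta), n_obs=obj.n_groups, n_free=0,
            converged=True, n_starts=0, seed=seed,
            jacobian_condition=1.0, start_objectives=np.array([]),
        )
    rng = np.random.default_rng(seed)
    lo, hi = obj.bounds_arrays(bounds)
    starts = [np.clip(np.asarray(s, dtype=float), lo, hi) for s in extra_starts]
    n_random = max(n_starts - len(starts), 0)
    n_e = len(obj.names)
    for _ in range(n_random):
        x0 = rng.uniform(bounds[0], bounds[1], size=obj.n_free)
        # scale entries start at their base values, not random energies
        x0[n_e:] = obj.theta_from_params(base_params)[n_e:]
        starts.append(np.clip(x0, lo, hi))

    best = None
    objectives = []
    any_converged = False
    for x0 in starts:
        try:
            res = least_squares(
                obj.residuals, x0, jac=obj.jacobian, bounds=(lo, hi),
                method="trf", xtol=tol, ftol=tol, gtol=tol, max_nfev=max_nfev,
            )
        except Exception:
            objectives.append(np.inf)
            continue
        cost = 2.0 * res.cost
        objectives.append(cost)
        if res.status > 0:
            any_converged = True
        if best is None or cost < best[0]:
            best = (cost, res)
    if best is None:
        raise RuntimeError("all optimization starts raised")
    cost, res = best
    theta = res.x
    params = obj.params_from_theta(theta)

    J = obj.jacobian(theta)
    sv = np.linalg.svd(J, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")

    rss = obj.rss_by_kind(theta)
    r2 = _r2_by_kind(obj, theta)
    return FitResult(
        params=params, spec=spec, theta=theta, parameter_names=obj.names + tuple(obj.scale_names),
        objective_value=cost, rss=rss, r2=r2, n_obs=obj.n_groups, n_free=obj.n_free,
        converged=any_converged, n_starts=len(starts), seed=seed,
        jacobian_condition=cond, start_objectives=np.array(objectives),
    )


def _r2_by_kind(obj: Objective, theta: np.ndarray) -> dict:
    pred = obj.predictions(theta)
    r2 = {}
    for label, mask in (("expression", obj.kind == 0), ("occupancy", obj.kind == 1),
                        ("combined", np.ones_like(obj.kind, dtype=bool))):
        o = obj.obs[mask]
        if len(o) >= 2 and np.var(o) > 0:
            r2[label] = r_squared(o, pred[mask])
        else:
            r2[label] = float("nan")
    return r2


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SSE/SST (SST about the observed mean)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    ok = np.isfinite(o) & np.isfinite(p)
    o, p = o[ok], p[ok]
    if len(o) < 2:
        raise ValueError("r_squared needs at least 2 non-missing pairs")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values have zero variance")
    sse = float(np.sum((o - p) ** 2))
    return 1.0 - sse / sst


def nested_f_test(null_fit: FitResult, alt_fit: FitResult) -> ComparisonResult:
    """F-test for a nested pair of fits on the same observations.

    F = ((RSS0 - RSS1)/Δp) / (RSS1/(n - p1)); the alternative must have
    strictly more free parameters and an objective no worse than the null
    (guaranteed when it was warm-started from the null optimum).
    """
    if null_fit.n_obs != alt_fit.n_obs:
        raise ValueError("fits compare different observation sets")
    if alt_fit.n_free <= null_fit.n_free:
        raise ValueError("alternative model must have strictly more free parameters")
    rss0, rss1 = null_fit.objective_value, alt_fit.objective_value
    if rss1 > rss0 * (1 + 1e-9) + 1e-12:
        raise ValueError(
            "alternative fit worse than null (RSS1 > RSS0): models not nested "
            "or alternative not warm-started"
        )
    rss1 = min(rss1, rss0)
    n = null_fit.n_obs
    dp = alt_fit.n_free - null_fit.n_free
    dfd = n - alt_fit.n_free
    if dfd <= 0:
        raise ValueError("no residual degrees of freedom")
    if rss1 == 0:
        f_stat = 0.0 if rss0 == rss1 else float("inf")
    else:
        f_stat = ((rss0 - rss1) / dp) / (rss1 / dfd)
    p = float(f_dist.sf(f_stat, dp, dfd))
    return ComparisonResult(f_statistic=float(f_stat), df_num=dp, df_den=dfd, p_value=p)


def forward_select_interactions(
    base_spec: ModelSpec,
    candidates: Iterable,
    observations: ObservationSet,
    base_params: EnergyParameters,
    alpha: float = 0.05,
    n_starts: int = 4,
    refit_starts: int = 1,
    seed: object = 0,
    weights: Mapping[str, float] | None = None,
    bonferroni_family: str = "round",
    bounds: tuple = DEFAULT_BOUNDS,
    tol: float = 1e-8,
    null_tol: float = 1e-11,
    max_nfev: int | None = 200,
    residual_scale: str = "log",
) -> SelectionResult:
    """Bonferroni-corrected forward selection of TF–TF interaction energies.

    Starting from ``base_spec`` (whose ``free_interactions`` stay fixed),
    each round fits every remaining candidate pair as a one-parameter
    extension of the current model (warm-started from the current optimum),
    compares it with an F-test, and retains the most significant candidate
    whose p-value clears ``alpha / m`` — where ``m`` is the number of
    candidates tested this round ("round" family) or the initial candidate
    count ("all").  Selection stops when no candidate passes.  The trail
    records every test performed.

    The current (null) model is always polished to ``null_tol`` before a
    round: the F-test is only valid when RSS0 is at the null optimum, so
    any descent still available in the shared parameters must not be
    credited to a candidate.  Candidate refits may stop earlier (``tol``,
    ``max_nfev``), which can only understate their improvement.
    """
    candidates = sorted({pair_key(*tuple(c)) for c in candidates})
    overlap = set(candidates) & {tuple(sorted(tuple(p))) for p in base_spec.free_interactions}
    if overlap:
        raise ValueError(f"candidates already free in the base spec: {sorted(overlap)}")
    if bonferroni_family not in ("round", "all"):
        raise ValueError(f"unknown bonferroni_family {bonferroni_family!r}")

    current_spec = base_spec
    base_obj = Objective(base_spec, observations, base_params, weights, residual_scale)
    current_obj = base_obj
    current_fit = fit_model(
        current_spec, observations, base_params, n_starts=n_starts,
        seed=np.random.default_rng((_seed_entropy(seed), 0)).integers(2**31),
        weights=weights, bounds=bounds, tol=tol, objective=base_obj, max_nfev=max_nfev,
    )
    current_fit = fit_model(
        current_spec, observations, base_params, n_starts=1, seed=0,
        weights=weights, bounds=bounds, tol=null_tol, objective=current_obj,
        extra_starts=[current_fit.theta],
    )
    remaining = list(candidates)
    trail_rows = []
    n_family_all = max(len(candidates), 1)
    round_no = 0
    while remaining:
        round_no += 1
        m = len(remaining) if bonferroni_family == "round" else n_family_all
        threshold = alpha / m
        round_results = []
        for idx, cand in enumerate(remaining):
            alt_spec = replace(
                current_spec,
                free_interactions=frozenset(set(current_spec.free_interactions) | {cand}),
            )
            alt_obj_seed = np.random.default_rng(
                (_seed_entropy(seed), round_no, idx + 1)
            ).integers(2**31)
            alt_obj = base_obj.with_spec(alt_spec)
            warm = alt_obj.theta_from_params(current_fit.params)
            alt_fit = fit_model(
                alt_spec, observations, base_params, n_starts=refit_starts,
                seed=alt_obj_seed, weights=weights, bounds=bounds, tol=tol,
                extra_starts=[warm], objective=alt_obj, max_nfev=max_nfev,
            )
            comp = nested_f_test(current_fit, alt_fit)
            comp.alpha_threshold = threshold
            comp.significant = comp.p_value < threshold
            round_results.append((cand, alt_spec, alt_fit, comp))
            trail_rows.append({
                "round": round_no, "pair": f"{cand[0]}:{cand[1]}",
                "rss_null": current_fit.objective_value,
                "rss_alt": alt_fit.objective_value,
                "f_statistic": comp.f_statistic, "p_value": comp.p_value,
                "threshold": threshold, "significant": comp.significant,
            })
        passers = [r for r in round_results if r[3].significant]
        if not passers:
            break
        cand, alt_spec, alt_fit, _ = min(passers, key=lambda r: r[3].p_value)
        current_spec = alt_spec
        current_obj = base_obj.with_spec(alt_spec)
        # polish the newly accepted model: it is the next round's null
        current_fit = fit_model(
            alt_spec, observations, base_params, n_starts=1, seed=0,
            weights=weights, bounds=bounds, tol=null_tol, objective=current_obj,
            extra_starts=[alt_fit.theta],
        )
        remaining.remove(cand)
    trail = pd.DataFrame(
        trail_rows,
        columns=["round", "pair", "rss_null", "rss_alt", "f_statistic",
                 "p_value", "threshold", "significant"],
    )
    retained = tuple(sorted(
        set(tuple(sorted(tuple(p))) for p in current_spec.free_interactions)
        - set(tuple(sorted(tuple(p))) for p in base_spec.free_interactions)
    ))
    return SelectionResult(spec=current_spec, fit=current_fit, trail=trail, retained=retained)


def _seed_entropy(seed: object) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return int(np.random.SeedSequence(seed).entropy) % (2**31)


def cross_validate(
    spec: ModelSpec,
    observations: ObservationSet,
    base_params: EnergyParameters,
    k: int = 5,
    seed: object = 0,
    n_starts: int = 4,
    weights: Mapping[str, float] | None = None,
    bounds: tuple = DEFAULT_BOUNDS,
    tol: float = 1e-12,
    residual_scale: str = "log",
) -> CVResult:
    """k-fold cross-validation with a random equal partition of the records.

    Every observation (non-missing expression record or occupancy record)
    lands in exactly one validation fold; folds differ in size by at most
    one.  Each fold's model is fit on the other k-1 folds and scored by R²
    on the held-out records; folds whose held-out values have no variance
    are flagged and excluded from the summary.
    """
    expr_idx = list(observations.observed_expression.index)
    occ_idx = list(observations.occupancy.index)
    records = [("expr", i) for i in expr_idx] + [("occ", i) for i in occ_idx]
    if len(records) < k:
        raise ValueError(f"need at least k={k} observations, have {len(records)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    fold_of = np.empty(len(records), dtype=int)
    for fold, chunk in enumerate(np.array_split(order, k)):
        fold_of[chunk] = fold

    assignments = pd.DataFrame({
        "record_kind": [r[0] for r in records],
        "record_index": [r[1] for r in records],
        "fold": fold_of,
    })
    folds = []
    for fold in range(k):
        test_mask = fold_of == fold
        tr_expr = [records[i][1] for i in np.flatnonzero(~test_mask) if records[i][0] == "expr"]
        tr_occ = [records[i][1] for i in np.flatnonzero(~test_mask) if records[i][0] == "occ"]
        te_expr = [records[i][1] for i in np.flatnonzero(test_mask) if records[i][0] == "expr"]
        te_occ = [records[i][1] for i in np.flatnonzero(test_mask) if records[i][0] == "occ"]
        train = observations.subset(tr_expr, tr_occ)
        test = observations.subset(te_expr, te_occ)
        fit = fit_model(
            spec, train, base_params, n_starts=n_starts,
            seed=np.random.default_rng((_seed_entropy(seed), fold)).integers(2**31),
            weights=weights, bounds=bounds, tol=tol, residual_scale=residual_scale,
        )
        test_obj = Objective(spec, test, base_params, weights, residual_scale)
        pred = test_obj.predictions(test_obj.theta_from_params(fit.params))
        entry = {"fold": fold, "train_r2": fit.r2["combined"], "n_test": test_obj.n_groups}
        if len(test_obj.obs) >= 2 and np.var(test_obj.obs) > 0:
            entry["test_r2"] = r_squared(test_obj.obs, pred)
            entry["flagged"] = False
        else:
            entry["test_r2"] = float("nan")
            entry["flagged"] = True
        folds.append(entry)
    return CVResult(folds=folds, assignments=assignments, k=k, seed=seed)


def multistart_diagnostics(
    spec: ModelSpec,
    observations: ObservationSet,
    base_params: EnergyParameters,
    n_starts: int = 20,
    seed: object = 0,
    cluster_tol: float = 1e-4,
    singular_threshold: float = SINGULAR_CONDITION_THRESHOLD,
    bounds: tuple = DEFAULT_BOUNDS,
    weights: Mapping[str, float] | None = None,
    tol: float = 1e-12,
    residual_scale: str = "log",
) -> dict:
    """Convergence-basin and identifiability diagnostics over random starts.

    Runs ``n_starts`` independent single-start fits, clusters the final
    objective values within ``cluster_tol`` relative tolerance, and reports
    the fraction landing in the modal (best-populated) cluster plus the
    fraction whose Jacobian condition number at the optimum exceeds the
    singularity threshold.  A well-identified mechanism shows a large modal
    fraction and non-singular Jacobians; this is the diagnostic that favored
    the competitive over the switching model of Gcn4.
    """
    if n_starts < 10:
        raise ValueError("n_starts must be >= 10 for meaningful fractions")
    obj = Objective(spec, observations, base_params, weights, residual_scale)
    rng = np.random.default_rng(seed)
    lo, hi = obj.bounds_arrays(bounds)
    n_e = len(obj.names)
    finals, conds = [], []
    for _ in range(n_starts):
        x0 = rng.uniform(bounds[0], bounds[1], size=obj.n_free)
        x0[n_e:] = obj.theta_from_params(base_params)[n_e:]
        res = least_squares(
            obj.residuals, np.clip(x0, lo, hi), jac=obj.jacobian,
            bounds=(lo, hi), method="trf", xtol=tol, ftol=tol, gtol=tol,
        )
        finals.append(2.0 * res.cost)
        J = obj.jacobian(res.x)
        sv = np.linalg.svd(J, compute_uv=False)
        conds.append(float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf"))
    finals = np.array(finals)
    order = np.argsort(finals)
    clusters: list[list[int]] = []
    for i in order:
        placed = False
        for cl in clusters:
            ref = finals[cl[0]]
            denom = max(abs(ref), 1e-12)
            if abs(finals[i] - ref) / denom <= cluster_tol:
                cl.append(i)
                placed = True
                break
        if not placed:
            clusters.append([i])
    modal = max(len(c) for c in clusters) / n_starts
    singular = float(np.mean([
        (not math.isfinite(c)) or c > singular_threshold for c in conds
    ]))
    return {
        "modal_fraction": float(modal),
        "singular_fraction": singular,
        "n_clusters": len(clusters),
        "best_objective": float(finals.min()),
        "objectives": finals,
        "condition_numbers": np.array(conds),
    }
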