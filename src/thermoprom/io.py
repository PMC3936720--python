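"""Readers/writers for promoter, expression, count and occupancy tables.

One canonical dialect everywhere: UTF-8 TSV with a header row, "NA" for
missing expression values, semicolon-joined site tokens for promoter
compositions, JSON (or YAML) for parameters, model structures and
structured results.  Synthetic and real files are interchangeable at
every stage.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    ConfigurationError,
    EnergyParameters,
    ModelSpec,
    Promoter,
    pair_key,
)
from .occupancy import CountTable, OccupancyTable
from .inference import FitResult, ObservationSet

__all__ = [
    "read_promoters", "write_promoters",
    "read_expression", "write_expression",
    "read_counts", "write_counts",
    "read_occupancy", "write_occupancy",
    "read_site_catalog",
    "params_to_dict", "params_from_dict",
    "spec_to_dict", "spec_from_dict",
    "save_json", "load_config",
    "read_tables",
    "fit_result_to_dict",
]

NA = "NA"


class TableFormatError(ValueError):
    """A malformed row in an input table; the message names the line."""


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(required) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_promoters(path, alphabet: Sequence[str] | None = None) -> dict:
    """Load promoters from TSV (promoter_id, library_tag, composition).

    Duplicate ids with conflicting compositions and out-of-alphabet tokens
    are hard errors naming the offending line (line 1 = header).
    """
    df = _read_tsv(path, ["promoter_id", "composition"])
    promoters: dict[str, Promoter] = {}
    for i, row in df.iterrows():
        line = i + 2
        p = Promoter.from_composition(
            row["promoter_id"], row["composition"], row.get("library_tag", ""),
        )
        if alphabet is not None:
            try:
                p.validate(alphabet)
            except Exception as e:
                raise TableFormatError(f"{path} line {line}: {e}") from None
        prev = promoters.get(p.id)
        if prev is not None and prev.sites != p.sites:
            raise TableFormatError(
                f"{path} line {line}: duplicate promoter id {p.id!r} with conflicting composition"
            )
        promoters[p.id] = p
    return promoters


def write_promoters(promoters: Mapping[str, Promoter], path) -> None:
    rows = [{"promoter_id": p.id, "library_tag": p.library_tag, "composition": p.composition}
            for p in promoters.values()]
    pd.DataFrame(rows, columns=["promoter_id", "library_tag", "composition"]).to_csv(
        path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Expression TSV (promoter_id, condition, value); "NA" marks missing."""
    df = _read_tsv(path, ["promoter_id", "condition", "value"])
    out = df.copy()
    vals = []
    for i, v in enumerate(df["value"]):
        if v == NA or v == "":
            vals.append(np.nan)
        else:
            try:
                vals.append(float(v))
            except ValueError:
                raise TableFormatError(
                    f"{path} line {i + 2}: bad expression value {v!r}") from None
    out["value"] = vals
    return out


def write_expression(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["value"] = [NA if pd.isna(v) else repr(float(v)) for v in out["value"]]
    out.to_csv(path, sep="\t", index=False)


def read_counts(path) -> dict:
    """Long-form counts TSV -> {(factor, condition): CountTable}.

    Columns: promoter_id, sample_type (IP/input), replicate, count, factor,
    condition.  Negative or non-integer counts are errors naming the line.
    """
    df = _read_tsv(path, ["promoter_id", "sample_type", "replicate", "count",
                          "factor", "condition"])
    counts = []
    for i, v in enumerate(df["count"]):
        try:
            c = int(v)
        except ValueError:
            raise TableFormatError(f"{path} line {i + 2}: bad count {v!r}") from None
        if c < 0:
            raise TableFormatError(f"{path} line {i + 2}: negative count {c}")
        counts.append(c)
    df = df.assign(count=counts)
    bad = set(df["sample_type"]) - {"IP", "input"}
    if bad:
        raise TableFormatError(f"{path}: unknown sample_type values {sorted(bad)}")
    tables = {}
    for (factor, condition), grp in df.groupby(["factor", "condition"]):
        tables[(factor, condition)] = CountTable.from_long(grp, factor, condition)
    return tables


def write_counts(tables: Mapping, path) -> None:
    rows = []
    for (factor, condition), t in tables.items():
        long = t.counts.stack(["sample_type", "replicate"], future_stack=True).rename("count").reset_index()
        long.columns = ["promoter_id", "sample_type", "replicate", "count"]
        long["factor"] = factor
        long["condition"] = condition
        rows.append(long)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_occupancy(path) -> pd.DataFrame:
    df = _read_tsv(path, ["promoter_id", "factor", "condition", "score"])
    out = df.copy()
    out["score"] = pd.to_numeric(df["score"], errors="raise")
    if "n_input_reads" in df.columns:
        out["n_input_reads"] = pd.to_numeric(df["n_input_reads"], errors="raise")
    return out


def write_occupancy(tables, path) -> None:
    """Write OccupancyTable(s) (or a prepared long frame) to TSV."""
    if isinstance(tables, pd.DataFrame):
        tables.to_csv(path, sep="\t", index=False)
        return
    if isinstance(tables, OccupancyTable):
        tables = [tables]
    frames = []
    for t in tables:
        df = t.scores.rename_axis("promoter_id").reset_index()
        df.insert(1, "factor", t.factor)
        df.insert(2, "condition", t.condition)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_site_catalog(path) -> dict:
    """Optional FASTA catalog mapping site token -> binding-site sequence.

    Tokens (FASTA headers) are authoritative; sequences are carried as
    annotation only.
    """
    catalog = {}
    token = None
    seq: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if token is not None:
                    catalog[token] = "".join(seq)
                token = line[1:].split()[0]
                seq = []
            elif token is None:
                raise TableFormatError(f"{path}: sequence before first FASTA header")
            else:
                seq.append(line)
    if token is not None:
        catalog[token] = "".join(seq)
    return catalog


# ---------------------------------------------------------------------------
# parameters / spec / results
# ---------------------------------------------------------------------------

def params_to_dict(params: EnergyParameters) -> dict:
    return {
        "dG_dna": [{"factor": f, "condition": c, "value": v}
                   for (f, c), v in sorted(params.dG_dna.items())],
        "dG_pol": [{"factor": f, "condition": c, "value": v}
                   for (f, c), v in sorted(params.dG_pol.items())],
        "dG_pol_basal": [{"condition": c, "value": v}
                         for c, v in sorted(params.dG_pol_basal.items())],
        "dG_tftf": [{"pair": list(k), "value": v}
                    for k, v in sorted(params.dG_tftf.items())],
        "dG_pol_override": [{"factor": f, "library_tag": t, "value": v}
                            for (f, t), v in sorted(params.dG_pol_override.items())],
        "dG_comp_dna": params.dG_comp_dna,
        "dG_comp_pol": params.dG_comp_pol,
        "expr_scale": params.expr_scale,
        "occ_scale": [{"factor": f, "value": v} for f, v in sorted(params.occ_scale.items())],
    }


def params_from_dict(d: Mapping) -> EnergyParameters:
    return EnergyParameters(
        dG_dna={(e["factor"], e["condition"]): float(e["value"]) for e in d.get("dG_dna", [])},
        dG_pol={(e["factor"], e["condition"]): float(e["value"]) for e in d.get("dG_pol", [])},
        dG_pol_basal={e["condition"]: float(e["value"]) for e in d.get("dG_pol_basal", [])},
        dG_tftf={pair_key(*e["pair"]): float(e["value"]) for e in d.get("dG_tftf", [])},
        dG_pol_override={(e["factor"], e["library_tag"]): float(e["value"])
                         for e in d.get("dG_pol_override", [])},
        dG_comp_dna=float(d.get("dG_comp_dna", 0.0)),
        dG_comp_pol=float(d.get("dG_comp_pol", 0.0)),
        expr_scale=float(d.get("expr_scale", 1.0)),
        occ_scale={e["factor"]: float(e["value"]) for e in d.get("occ_scale", [])},
    )


def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "factors": list(spec.factors),
        "conditions": list(spec.conditions),
        "competitive": spec.competitive,
        "competitor_site": spec.competitor_site,
        "dna_condition_specific": sorted(spec.dna_condition_specific),
        "pol_condition_specific": sorted(spec.pol_condition_specific),
        "free_interactions": sorted(list(p) for p in spec.free_interactions),
        "pol_overrides": [list(p) for p in spec.pol_overrides],
        "fit_dna": spec.fit_dna,
        "fit_pol": spec.fit_pol,
        "fit_basal": spec.fit_basal,
        "fit_expr_scale": spec.fit_expr_scale,
        "fit_occ_scale": sorted(spec.fit_occ_scale),
        "pair_mode": spec.pair_mode,
        "enumeration_cap": spec.enumeration_cap,
    }


def spec_from_dict(d: Mapping) -> ModelSpec:
    kwargs = dict(d)
    for key in ("factors", "conditions"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    for key in ("dna_condition_specific", "pol_condition_specific", "fit_occ_scale"):
        if key in kwargs:
            kwargs[key] = frozenset(kwargs[key])
    if "free_interactions" in kwargs:
        kwargs["free_interactions"] = frozenset(tuple(p) for p in kwargs["free_interactions"])
    if "pol_overrides" in kwargs:
        kwargs["pol_overrides"] = tuple(tuple(p) for p in kwargs["pol_overrides"])
    return ModelSpec(**kwargs)


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "objective_value": fit.objective_value,
        "rss": fit.rss,
        "r2": fit.r2,
        "n_obs": fit.n_obs,
        "n_free": fit.n_free,
        "converged": bool(fit.converged),
        "n_starts": int(fit.n_starts),
        "seed": fit.seed if isinstance(fit.seed, (int, str)) else str(fit.seed),
        "jacobian_condition": fit.jacobian_condition,
        "singular": bool(fit.singular),
        "parameter_names": ["/".join(str(x) for x in n) for n in fit.parameter_names],
        "theta": [float(x) for x in fit.theta],
        "params": params_to_dict(fit.params),
        "spec": spec_to_dict(fit.spec),
    }


class _JsonEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def save_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_JsonEncoder)
        fh.write("\n")


def load_config(path) -> dict:
    """Load a JSON or YAML configuration file into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def read_tables(paths: Mapping) -> dict:
    """Read the tables named in ``paths`` into validated in-memory objects.

    Recognized keys: promoters (required for any other table), expression,
    occupancy, counts, params, spec.  Returns a dict with promoters, an
    :class:`ObservationSet` (when expression and/or occupancy present),
    count_tables, params and spec entries as available.
    """
    out: dict = {}
    alphabet = None
    spec = None
    if "spec" in paths:
        spec = spec_from_dict(load_config(paths["spec"]))
        alphabet = spec.factors
        out["spec"] = spec
    if "params" in paths:
        out["params"] = params_from_dict(load_config(paths["params"]))
    if "promoters" in paths:
        out["promoters"] = read_promoters(paths["promoters"], alphabet=alphabet)
    expression = read_expression(paths["expression"]) if "expression" in paths else None
    occupancy = read_occupancy(paths["occupancy"]) if "occupancy" in paths else None
    if expression is not None or occupancy is not None:
        if "promoters" not in out:
            raise ValueError("observation tables require a promoters table")
        out["observations"] = ObservationSet(
            promoters=out["promoters"],
            expression=expression,
            occupancy=occupancy if occupancy is None else
            occupancy[["promoter_id", "factor", "condition", "score"]],
        )
    if "counts" in paths:
        out["count_tables"] = read_counts(paths["counts"])
    return out
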