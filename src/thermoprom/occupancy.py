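"""ChIP IP/input occupancy scoring on designed promoter libraries.

Each promoter's occupancy by a tagged TF is summarized as a background-
relative score: the promoter's normalized-IP over normalized-input ratio
divided by the median of that ratio over all promoters lacking a binding
site for the ChIPed factor.  The background median anchors the score at 1
for non-specific binding, putting all factors and conditions on the same
relative scale.  Promoters with fewer than ``min_input`` input reads are
dropped before any computation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Promoter

__all__ = [
    "UNASSIGNED",
    "CountTable",
    "OccupancyTable",
    "parse_read",
    "combine_replicates",
    "relative_occupancy",
    "occupancy_qc",
]

logger = logging.getLogger(__name__)

#: marker for reads whose site tokens cannot be mapped to a promoter
UNASSIGNED = "__unassigned__"

DEFAULT_MIN_INPUT = 50


@dataclass
class CountTable:
    """IP and input read counts per promoter for one factor x condition.

    ``counts`` is a wide frame indexed by promoter id with a
    (sample_type, replicate) column MultiIndex; sample_type is "input" or
    "IP".  Counts are non-negative integers.
    """

    factor: str
    condition: str
    counts: pd.DataFrame

    def __post_init__(self):
        if not isinstance(self.counts.columns, pd.MultiIndex):
            raise ValueError("counts must have a (sample_type, replicate) column MultiIndex")
        bad = set(self.counts.columns.get_level_values(0)) - {"input", "IP"}
        if bad:
            raise ValueError(f"unknown sample types {bad}; expected 'input'/'IP'")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        for st in ("input", "IP"):
            if st not in self.counts.columns.get_level_values(0):
                raise ValueError(f"count table has no {st} columns")

    @property
    def replicates(self) -> tuple:
        return tuple(sorted(set(self.counts.columns.get_level_values(1))))

    @classmethod
    def from_long(cls, df: pd.DataFrame, factor: str, condition: str) -> "CountTable":
        """Build from long-form rows (promoter_id, sample_type, replicate, count)."""
        wide = df.pivot_table(
            index="promoter_id", columns=["sample_type", "replicate"],
            values="count", aggfunc="sum", fill_value=0,
        )
        return cls(factor=factor, condition=condition, counts=wide)


@dataclass
class OccupancyTable:
    """Background-relative occupancy scores for one factor x condition.

    ``scores`` has columns score and n_input_reads, indexed by promoter id;
    promoters that failed the input-read filter are absent, not zero.
    """

    factor: str
    condition: str
    scores: pd.DataFrame
    replicates: tuple = ()
    min_input: int = DEFAULT_MIN_INPUT
    n_background: int = 0


def parse_read(read_tokens: Sequence[str], catalog: Iterable[str]) -> str:
    """Map a read's site-token sequence to its promoter composition key.

    Returns the semicolon-joined composition for fully recognized token
    sequences and :data:`UNASSIGNED` for empty reads or reads containing a
    token outside the site catalog.
    """
    catalog = set(catalog)
    tokens = list(read_tokens)
    if not tokens or any(t not in catalog for t in tokens):
        return UNASSIGNED
    return ";".join(tokens)


def tally_reads(
    reads: Iterable[Sequence[str]], catalog: Iterable[str]
) -> tuple[dict, int]:
    """Count reads per composition key; unassigned reads go to a discard tally."""
    catalog = set(catalog)
    counts: dict[str, int] = {}
    discarded = 0
    for read in reads:
        key = parse_read(read, catalog)
        if key == UNASSIGNED:
            discarded += 1
        else:
            counts[key] = counts.get(key, 0) + 1
    if discarded:
        logger.info("discarded %d unassigned reads", discarded)
    return counts, discarded


def combine_replicates(tables: Sequence[CountTable], mode: str = "sum") -> CountTable:
    """Combine replicate count tables by summing, or select a single replicate.

    ``mode`` is "sum" (element-wise sum of all replicates across all tables,
    the default used for modeling) or "single:<r>" (use replicate ``r``
    only, as done for Gcn4 in amino-acid starvation where two input
    replicates were depleted).
    """
    if not tables:
        raise ValueError("no count tables given")
    meta = {(t.factor, t.condition) for t in tables}
    if len(meta) != 1:
        raise ValueError(f"count tables mix factors/conditions: {sorted(meta)}")
    factor, condition = next(iter(meta))
    stacked = pd.concat([t.counts for t in tables], axis=1).fillna(0)
    if mode == "sum":
        combined = stacked.T.groupby(level=0).sum().T
        combined.columns = pd.MultiIndex.from_product(
            [combined.columns, ["combined"]], names=["sample_type", "replicate"]
        )
    elif mode.startswith("single:"):
        rep = mode.split(":", 1)[1]
        reps = {str(r) for r in stacked.columns.get_level_values(1)}
        if rep not in reps:
            raise ValueError(f"replicate {rep!r} not present; have {sorted(reps)}")
        mask = [str(r) == rep for r in stacked.columns.get_level_values(1)]
        combined = stacked.loc[:, mask]
    else:
        raise ValueError(f"unknown combine mode {mode!r}")
    return CountTable(factor=factor, condition=condition, counts=combined)


def relative_occupancy(
    counts: CountTable,
    promoters: Mapping[str, Promoter],
    factor: str | None = None,
    min_input: int = DEFAULT_MIN_INPUT,
    filter_scope: str = "combined",
) -> OccupancyTable:
    """Background-scaled relative occupancy from IP/input counts.

    For each promoter, score = (IP_i / IP_total) / (input_i / input_total),
    divided by the median of that ratio over *background* promoters (those
    with no binding site for the ChIPed factor).  Promoters with fewer than
    ``min_input`` input reads (summed across replicates when
    ``filter_scope == "combined"``, required of every replicate when
    ``"per_replicate"``) are excluded before any normalization.
    """
    factor = counts.factor if factor is None else factor
    df = counts.counts
    input_per_rep = df["input"]
    ip_total_counts = df["IP"].sum(axis=1)
    input_total_counts = input_per_rep.sum(axis=1)

    if filter_scope == "combined":
        keep = input_total_counts >= min_input
    elif filter_scope == "per_replicate":
        keep = (input_per_rep >= min_input).all(axis=1)
    else:
        raise ValueError(f"unknown filter_scope {filter_scope!r}")
    ip = ip_total_counts[keep]
    inp = input_total_counts[keep]
    unknown = [pid for pid in ip.index if pid not in promoters]
    if unknown:
        raise ValueError(f"count table has promoters without compositions: {unknown[:5]}")

    ip_frac = ip / ip.sum()
    inp_frac = inp / inp.sum()
    ratio = ip_frac / inp_frac

    background = [pid for pid in ratio.index if promoters[pid].site_count(factor) == 0]
    if not background:
        raise ValueError(
            f"no background promoters (lacking a {factor} site) pass the "
            f"min_input={min_input} filter; background scaling impossible"
        )
    bg_median = float(ratio.loc[background].median())
    scores = pd.DataFrame(
        {"score": ratio / bg_median, "n_input_reads": inp.astype(int)}
    )
    return OccupancyTable(
        factor=factor,
        condition=counts.condition,
        scores=scores,
        replicates=counts.replicates,
        min_input=min_input,
        n_background=len(background),
    )


def occupancy_qc(
    table: OccupancyTable,
    promoters: Mapping[str, Promoter],
    other: OccupancyTable | None = None,
) -> dict:
    """Diagnostics: median score by planted site count, and replicate concordance.

    With a second table, reports the Pearson correlation of scores over the
    promoters present in both (replicate reproducibility).
    """
    by_count: dict[int, list] = {}
    for pid, row in table.scores.iterrows():
        by_count.setdefault(promoters[pid].site_count(table.factor), []).append(row["score"])
    summary = {
        "factor": table.factor,
        "condition": table.condition,
        "n_promoters": int(len(table.scores)),
        "median_by_site_count": {
            k: float(np.median(v)) for k, v in sorted(by_count.items())
        },
        "iqr_by_site_count": {
            k: float(np.subtract(*np.percentile(v, [75, 25]))) for k, v in sorted(by_count.items())
        },
    }
    if other is not None:
        shared = table.scores.index.intersection(other.scores.index)
        if len(shared) >= 2:
            a = table.scores.loc[shared, "score"].to_numpy()
            b = other.scores.loc[shared, "score"].to_numpy()
            if np.std(a) > 0 and np.std(b) > 0:
                summary["replicate_correlation"] = float(np.corrcoef(a, b)[0, 1])
            else:
                summary["replicate_correlation"] = float("nan")
            summary["n_shared"] = int(len(shared))
    return summary
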