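"""Per-EST differential calls and EC-number isoform aggregation.

Multi-copy enzymes (isoforms/paralogs sharing one EC number) are summed
replicate-wise before the direction of metabolic flux is called, while the
per-copy calls are kept alongside — a summed-level call of "unchanged" can
hide isoforms moving in opposite directions (the diacylglycerol
acyltransferase situation).

Significance uses a two-sided Welch t-test on log2(TPM + 1); fold changes
use a shared pseudo-count so zero denominators stay finite.  Both fold
thresholds are strict (> t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PSEUDO_COUNT, ec_groups, level_columns, safe_ratio

__all__ = [
    "DifferentialCall",
    "ECAggregate",
    "differential_call",
    "differential_table",
    "aggregate_ec",
    "aggregate_all_ecs",
    "pathway_flux_table",
    "copies_per_ec_summary",
    "fraction_differential",
    "welch_log_p",
]


@dataclass(frozen=True)
class DifferentialCall:
    est_id: str
    mean_nd: float
    mean_nr: float
    ratio: float  # mean_nd / mean_nr, pseudo-count patching zero means
    fold: float  # max(ratio, 1/ratio), >= 1
    direction: str  # up | down | unchanged
    p: float
    q: float  # NaN unless FDR adjustment was applied table-wide
    significant: bool


@dataclass(frozen=True)
class ECAggregate:
    ec: str
    member_est_ids: tuple[str, ...]
    summed_nd: tuple[float, ...]  # per-replicate sums under ND
    summed_nr: tuple[float, ...]
    call: DifferentialCall  # on the summed replicate vectors
    n_copies: int
    n_up: int  # members individually up at (1.5, 0.05)
    n_dn: int

    @property
    def direction(self) -> str:
        return self.call.direction


def welch_log_p(levels_a: np.ndarray, levels_b: np.ndarray) -> float:
    """Two-sided Welch t p-value on log2(level + 1).

    Degenerate all-constant input in both groups yields p = 1 when the means
    agree and p = 0 otherwise.
    """
    a = np.log2(np.asarray(levels_a, dtype=float) + 1.0)
    b = np.log2(np.asarray(levels_b, dtype=float) + 1.0)
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(p) if np.isfinite(p) else 1.0


def differential_call(
    levels_nd: Sequence[float],
    levels_nr: Sequence[float],
    fold_threshold: float = 4.0,
    alpha: float = 0.05,
    adjust: str = "none",
    *,
    est_id: str = "",
    q: float = float("nan"),
    pseudo_count: float = PSEUDO_COUNT,
) -> DifferentialCall:
    """Differential call for one EST from its ND/NR replicate vectors.

    ``adjust="fdr"`` means the significance gate uses a table-wide
    Benjamini-Hochberg q-value, which must be supplied via ``q`` (use
    :func:`differential_table` for whole tables); ``adjust="none"`` gates on
    the raw p-value.
    """
    nd = np.asarray(levels_nd, dtype=float)
    nr = np.asarray(levels_nr, dtype=float)
    if nd.size < 2 or nr.size < 2:
        raise ValueError("need >= 2 replicates per condition")
    if adjust not in ("none", "fdr"):
        raise ValueError(f"adjust must be 'none' or 'fdr', got {adjust!r}")
    mean_nd, mean_nr = float(nd.mean()), float(nr.mean())
    ratio = safe_ratio(mean_nd, mean_nr, pseudo_count)
    fold = max(ratio, 1.0 / ratio)
    p = welch_log_p(nd, nr)
    gate = q if adjust == "fdr" else p
    significant = fold > fold_threshold and gate < alpha
    if significant:
        direction = "up" if ratio > 1 else "down"
    else:
        direction = "unchanged"
    return DifferentialCall(
        est_id=est_id, mean_nd=mean_nd, mean_nr=mean_nr, ratio=ratio,
        fold=fold, direction=direction, p=p, q=q, significant=significant,
    )


def differential_table(
    table: pd.DataFrame,
    fold_threshold: float = 4.0,
    alpha: float = 0.05,
    adjust: str = "none",
    *,
    id_col: str = "est_id",
    pseudo_count: float = PSEUDO_COUNT,
) -> pd.DataFrame:
    """Differential calls for every row, with table-wide BH-FDR when asked.

    Returns one row per input row: est_id, mean_nd, mean_nr, ratio, fold,
    p, q, direction, significant.  q is NaN under ``adjust="none"``.
    """
    nd = table[level_columns(table, "ND")].to_numpy(dtype=float)
    nr = table[level_columns(table, "NR")].to_numpy(dtype=float)
    mean_nd, mean_nr = nd.mean(axis=1), nr.mean(axis=1)
    ratio = safe_ratio(mean_nd, mean_nr, pseudo_count)
    fold = np.maximum(ratio, 1.0 / ratio)
    p = np.array([welch_log_p(nd[i], nr[i]) for i in range(len(table))])
    if adjust == "fdr" and len(p):
        q = multipletests(p, method="fdr_bh")[1]
        gate = q
    elif adjust == "none":
        q = np.full_like(p, np.nan)
        gate = p
    else:
        raise ValueError(f"adjust must be 'none' or 'fdr', got {adjust!r}")
    significant = (fold > fold_threshold) & (gate < alpha)
    direction = np.where(significant, np.where(ratio > 1, "up", "down"), "unchanged")
    return pd.DataFrame(
        {
            "est_id": table[id_col].to_numpy(),
            "mean_nd": mean_nd,
            "mean_nr": mean_nr,
            "ratio": ratio,
            "fold": fold,
            "p": p,
            "q": q,
            "direction": direction,
            "significant": significant,
        }
    )


def aggregate_ec(
    table: pd.DataFrame,
    ec: str,
    fold_threshold: float = 1.5,
    alpha: float = 0.05,
    *,
    member_fold_threshold: float = 1.5,
    member_alpha: float = 0.05,
) -> ECAggregate:
    """Sum all isoforms of one EC replicate-wise and call the flux direction.

    The aggregate call is made on the summed replicate vectors at
    (fold_threshold, alpha); n_up/n_dn count members that are individually
    significant at (member_fold_threshold, member_alpha) on raw p-values.
    """
    members = table[table["ec"].fillna("").astype(str).str.strip() == ec]
    if members.empty:
        raise ValueError(f"EC {ec!r} has no members in the table")
    nd_cols, nr_cols = level_columns(table, "ND"), level_columns(table, "NR")
    summed_nd = members[nd_cols].sum(axis=0).to_numpy(dtype=float)
    summed_nr = members[nr_cols].sum(axis=0).to_numpy(dtype=float)
    call = differential_call(summed_nd, summed_nr, fold_threshold, alpha, est_id=ec)
    n_up = n_dn = 0
    for _, row in members.iterrows():
        member = differential_call(
            row[nd_cols].to_numpy(dtype=float),
            row[nr_cols].to_numpy(dtype=float),
            member_fold_threshold,
            member_alpha,
            est_id=row["est_id"],
        )
        n_up += member.direction == "up"
        n_dn += member.direction == "down"
    return ECAggregate(
        ec=ec,
        member_est_ids=tuple(members["est_id"]),
        summed_nd=tuple(summed_nd),
        summed_nr=tuple(summed_nr),
        call=call,
        n_copies=len(members),
        n_up=n_up,
        n_dn=n_dn,
    )


def aggregate_all_ecs(
    table: pd.DataFrame, fold_threshold: float = 1.5, alpha: float = 0.05
) -> dict[str, ECAggregate]:
    """ECAggregate for every EC annotated in the table, in sorted EC order."""
    return {
        ec: aggregate_ec(table, ec, fold_threshold, alpha)
        for ec in sorted(ec_groups(table))
    }


def pathway_flux_table(
    aggregates: Mapping[str, ECAggregate],
    pathway_definition: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Direction label for every EC of every defined pathway.

    ECs absent from the expression analysis are labeled ``not found`` (drawn
    without a box on pathway schematics); the rest carry their aggregate
    direction and copy counts.
    """
    if not pathway_definition:
        raise ValueError("pathway_definition is empty")
    rows = []
    for pathway in sorted(pathway_definition):
        for ec in pathway_definition[pathway]:
            agg = aggregates.get(ec)
            rows.append(
                {
                    "pathway": pathway,
                    "ec": ec,
                    "direction": agg.direction if agg else "not found",
                    "n_copies": agg.n_copies if agg else 0,
                    "n_up": agg.n_up if agg else 0,
                    "n_dn": agg.n_dn if agg else 0,
                }
            )
    return pd.DataFrame(rows, columns=["pathway", "ec", "direction", "n_copies", "n_up", "n_dn"])


def copies_per_ec_summary(table: pd.DataFrame) -> tuple[int, float]:
    """(number of distinct ECs, mean gene copies per EC)."""
    groups = ec_groups(table)
    if not groups:
        raise ValueError("table has no EC annotations")
    n_annotated = sum(len(m) for m in groups.values())
    return len(groups), n_annotated / len(groups)


def fraction_differential(
    table: pd.DataFrame,
    fold_threshold: float = 4.0,
    alpha: float = 0.05,
    adjust: str = "none",
) -> float:
    """Fraction of ESTs called differential at the given screen settings."""
    if table.empty:
        raise ValueError("expression table is empty")
    calls = differential_table(table, fold_threshold, alpha, adjust)
    return float(calls["significant"].mean())
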