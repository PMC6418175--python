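"""Top-set and sliding-window pathway enrichment over ranked expression tables.

ESTs are sorted by mean expression under one condition (or by the ND/NR ratio
of means), a window covering a fixed fraction of the ranked list slides from
the most to the least abundant end, and the occurrence of each pathway's
members inside the window is compared with its background frequency.  The
enrichment statistic is the upper binomial tail at the background rate, with
a family-wise Bonferroni correction over every (window, pathway) test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import PSEUDO_COUNT, condition_means, pathway_sets, safe_ratio

log = logging.getLogger(__name__)

__all__ = [
    "Window",
    "rank_ests",
    "make_windows",
    "enrichment_stat",
    "bonferroni_adjust",
    "sliding_window_enrichment",
    "top_set_enrichment",
]


@dataclass(frozen=True)
class Window:
    """Half-open 0-based rank interval [start, end) at position ``index``."""

    index: int
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start


def rank_ests(
    table: pd.DataFrame,
    key: str = "NR",
    *,
    pseudo_count: float = PSEUDO_COUNT,
) -> pd.DataFrame:
    """Sort ESTs by descending key value.

    ``key`` is a condition name (mean TPM over its replicates) or ``"ratio"``
    for mean_ND / mean_NR with a pseudo-count standing in for zero means.  Ties break by ascending est_id so
    the ranking is deterministic.  Returns a DataFrame with columns
    ``est_id`` and ``key_value``; the row position is the 0-based rank.
    """
    if table.empty:
        raise ValueError("expression table is empty")
    if key == "ratio":
        values = pd.Series(
            safe_ratio(
                condition_means(table, "ND").to_numpy(),
                condition_means(table, "NR").to_numpy(),
                pseudo_count,
            )
        )
    else:
        values = condition_means(table, key)
    ranked = pd.DataFrame({"est_id": table["est_id"].to_numpy(), "key_value": values.to_numpy()})
    ranked = ranked.sort_values(
        ["key_value", "est_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return ranked


def make_windows(
    n: int, window_frac: float = 0.10, step_frac: float = 0.05, *, extend_last: bool = False
) -> list[Window]:
    """Floor-based sliding windows over ``n`` ranks.

    Window width W = floor(window_frac*n) and step S = floor(step_frac*n);
    starts run 0, S, 2S, ... while start + W <= n.  For n = 12,609 with the
    default 10%/5% fractions this yields W = 1,260, S = 630 and 19 windows.
    Ranks past the last window end are dropped unless ``extend_last`` widens
    the final window to cover them.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 < step_frac <= window_frac < 1:
        raise ValueError(
            f"need 0 < step_frac <= window_frac < 1, got step_frac={step_frac}, "
            f"window_frac={window_frac}"
        )
    width = int(np.floor(window_frac * n))
    step = int(np.floor(step_frac * n))
    if width == 0 or step == 0:
        raise ValueError(f"window width floor({window_frac}*{n}) is zero")
    windows = []
    start = 0
    while start + width <= n:
        windows.append(Window(index=len(windows), start=start, end=start + width))
        start += step
    if extend_last and windows and windows[-1].end < n:
        last = windows[-1]
        windows[-1] = Window(index=last.index, start=last.start, end=n)
    return windows


def enrichment_stat(
    k: int, w: int, K: int, N: int, *, model: str = "binomial"
) -> tuple[float, float]:
    """Fold enrichment and upper-tail probability of k pathway members in a
    set of w ESTs against a background of K members among N.

    fold = (k/w) / (K/N).  The tail is P(X >= k) for X ~ Binomial(w, K/N)
    (sampling with replacement at the background rate); ``model="hypergeometric"``
    uses the without-replacement tail instead.
    """
    if not 0 <= k <= w <= N:
        raise ValueError(f"need 0 <= k <= w <= N, got k={k}, w={w}, N={N}")
    if not 0 <= K <= N:
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if K == 0:
        if k > 0:
            raise ValueError("observed pathway member with empty background (K=0, k>0)")
        return 0.0, 1.0
    p0 = K / N
    fold = (k / w) / p0
    if model == "binomial":
        p = float(stats.binom.sf(k - 1, w, p0))
    elif model == "hypergeometric":
        p = float(stats.hypergeom.sf(k - 1, N, K, w))
    else:
        raise ValueError(f"unknown tail model {model!r}")
    return fold, min(p, 1.0)


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni family-wise adjustment min(1, p*m)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return min(1.0, p * m)


def sliding_window_enrichment(
    table: pd.DataFrame,
    pathway_map: Mapping[str, set] | None = None,
    key: str = "NR",
    min_pathway_size: int = 60,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    *,
    window_frac: float = 0.10,
    step_frac: float = 0.05,
    model: str = "binomial",
    extend_last: bool = False,
    pseudo_count: float = PSEUDO_COUNT,
) -> pd.DataFrame:
    """Pathway enrichment in every sliding window of the ranked EST list.

    Pathways with fewer than ``min_pathway_size`` members in the table are
    excluded before testing.  The Bonferroni universe is the full test family
    m = retained pathways x windows.  A (window, pathway) cell is flagged
    enriched when fold > fold_threshold and the adjusted tail probability is
    below alpha.

    Returns a long-format DataFrame with one row per retained
    (window, pathway): window_index, start, end, pathway, k, w, K, N, fold,
    p, p_adj, enriched.  Attrs record the Bonferroni universe and tail model.
    """
    if min_pathway_size < 1:
        raise ValueError("min_pathway_size must be >= 1")
    if pathway_map is None:
        pathway_map = pathway_sets(table)
    n_total = len(table)
    ranked = rank_ests(table, key, pseudo_count=pseudo_count)
    windows = make_windows(n_total, window_frac, step_frac, extend_last=extend_last)

    retained = {
        pw: frozenset(members)
        for pw, members in sorted(pathway_map.items())
        if len(members) >= min_pathway_size
    }
    if not retained:
        warnings.warn("no pathway passes min_pathway_size; empty enrichment result")
        log.warning("no pathway passes min_pathway_size=%d", min_pathway_size)
    m = max(1, len(retained) * len(windows))

    ids = ranked["est_id"].to_numpy()
    rows = []
    for win in windows:
        in_window = ids[win.start : win.end]
        window_set = set(in_window)
        for pw, members in retained.items():
            k = len(window_set & members)
            fold, p = enrichment_stat(k, win.width, len(members), n_total, model=model)
            p_adj = bonferroni_adjust(p, m)
            rows.append(
                {
                    "window_index": win.index,
                    "start": win.start,
                    "end": win.end,
                    "pathway": pw,
                    "k": k,
                    "w": win.width,
                    "K": len(members),
                    "N": n_total,
                    "fold": fold,
                    "p": p,
                    "p_adj": p_adj,
                    "enriched": fold > fold_threshold and p_adj < alpha,
                }
            )
    result = pd.DataFrame(
        rows,
        columns=[
            "window_index", "start", "end", "pathway", "k", "w", "K", "N",
            "fold", "p", "p_adj", "enriched",
        ],
    )
    result.attrs["bonferroni_m"] = m
    result.attrs["bonferroni_universe"] = "retained pathways x windows"
    result.attrs["tail_model"] = model
    result.attrs["rank_key"] = key
    return result


def top_set_enrichment(
    table: pd.DataFrame,
    condition: str,
    n_top: int,
    category_map: Mapping[str, set],
) -> pd.DataFrame:
    """Enrichment of functional categories among the ``n_top`` most abundant
    ESTs under one condition.

    Tail probabilities are reported raw (no multiplicity adjustment), matching
    how top-set hits such as light-harvesting genes among the top 10 are
    usually quoted.
    """
    n_total = len(table)
    if n_top > n_total:
        raise ValueError(f"n_top={n_top} exceeds table size {n_total}")
    top = set(rank_ests(table, condition)["est_id"].iloc[:n_top])
    rows = []
    for category, members in sorted(category_map.items()):
        members = set(members)
        k = len(top & members)
        fold, p = enrichment_stat(k, n_top, len(members), n_total)
        rows.append(
            {
                "category": category,
                "k": k,
                "w": n_top,
                "K": len(members),
                "N": n_total,
                "fold": fold,
                "p": p,
            }
        )
    return pd.DataFrame(rows, columns=["category", "k", "w", "K", "N", "fold", "p"])
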