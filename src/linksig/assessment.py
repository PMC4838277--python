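"""Global and local link assessment: rankings, PPV_k and AUC.

The global task (GLAP) ranks all candidate pairs at once; the local task
(LLAP) ranks each node's candidate partners separately. Both are scored
against a ground truth with

* **PPV_k** — the fraction of ground-truth pairs among the k top-ranked
  pairs, with k defaulting to the ground-truth size t globally and to
  t(v) per node locally. With k = t, PPV_k equals the recall TP/t.
* **AUC** — the probability that a uniformly random ground-truth pair
  outscores a uniformly random non-ground-truth pair, ties counted 1/2.

Each measure has a fixed direction of strength: larger is stronger for
all measures except the two p-values (``hypergeom``, ``p_emp``), where
smaller is stronger, and ``z_star``, which is the composite order
p ascending / z descending. Undefined scores (NaN) rank below every
defined score. All residual ties break by canonical pair order, so every
ranking is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .graph import GroundTruth
from .table import ScoreTable

logger = logging.getLogger("linksig")

#: Measures for which a smaller value is stronger evidence.
ASCENDING_MEASURES = frozenset({"hypergeom", "p_emp"})

__all__ = [
    "ASCENDING_MEASURES",
    "Ranking",
    "strengths",
    "rank_global",
    "ppv_at_k",
    "auc",
    "rank_local",
    "evaluate_llap",
    "evaluate_all",
]


def strengths(table: ScoreTable, measure: str) -> np.ndarray:
    """Per-row strength: larger is always stronger; NaN maps to −inf.

    ``z_star`` is handled as a composite: the (negated) z* rank, which
    encodes p-ascending / z-descending / canonical-order ordering.
    """
    if measure == "z_star":
        if "z_star_rank" not in table.df.columns:
            raise KeyError("table has no z_star_rank column; run the FDSM first")
        return -table.values("z_star_rank").astype(float)
    vals = table.values(measure).astype(float)
    if measure in ASCENDING_MEASURES:
        vals = -vals
    return np.where(np.isnan(vals), -np.inf, vals)


@dataclass
class Ranking:
    """An ordered list of candidate pairs for one measure."""

    measure: str
    pairs: list[tuple[str, str]]
    scores: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def top(self, k: int) -> list[tuple[str, str]]:
        return self.pairs[:k]


def rank_global(table: ScoreTable, measure: str) -> Ranking:
    """Rank all candidate pairs by one measure (GLAP ordering)."""
    s = strengths(table, measure)
    pairs = table.pairs
    order = sorted(range(len(pairs)), key=lambda i: (-s[i], pairs[i]))
    raw = (
        table.values("z_star_rank").astype(float)
        if measure == "z_star"
        else table.values(measure).astype(float)
    )
    return Ranking(
        measure=measure,
        pairs=[pairs[i] for i in order],
        scores=[float(raw[i]) for i in order],
    )


def ppv_at_k(r: Ranking, gt: GroundTruth, k: int | None = None) -> float:
    """Positive predictive value among the k top-ranked pairs (k = t default).

    Ground-truth pairs that are not candidate pairs can never appear in
    the top k; with k = t they count against the measure, which makes
    PPV_t identical to the recall TP/t.
    """
    if k is None:
        k = gt.t
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(r):
        raise ValueError(f"k={k} exceeds the number of ranked pairs ({len(r)})")
    hits = sum(1 for pair in r.top(k) if pair in gt)
    return hits / k


def auc(table: ScoreTable, measure: str, gt: GroundTruth) -> float:
    """Mann–Whitney probability that a ground-truth pair outscores a
    non-ground-truth pair; ties count 1/2.

    Ground-truth pairs without a score (not candidate pairs) are ignored
    with a logged count; either class being empty is an error.
    """
    s = strengths(table, measure)
    is_gt = np.array([pair in gt for pair in table.pairs], dtype=bool)
    n_pos = int(is_gt.sum())
    n_neg = len(s) - n_pos
    uncovered = gt.t - n_pos
    if uncovered:
        logger.info(
            "AUC(%s): %d ground-truth pair(s) are not candidate pairs and are "
            "excluded",
            measure,
            uncovered,
        )
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"AUC needs both classes among candidate pairs "
            f"(ground-truth: {n_pos}, other: {n_neg})"
        )
    ranks = _sps.rankdata(s)  # average ranks implement the tie-1/2 convention
    u = ranks[is_gt].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def rank_local(
    table: ScoreTable, v: str, measure: str, m: int | None = None
) -> list[str]:
    """Top-m candidate partners of node v (LLAP ordering; m=1 gives the
    most-similar-partner map).

    Returns all partners when m exceeds their number; an empty list with
    a warning when v has no candidate pair.
    """
    if m is not None and m < 1:
        raise ValueError("m must be positive")
    s = strengths(table, measure)
    incident = table.pairs_of(v)
    if not incident:
        logger.warning("node %r has no candidate pair", v)
        return []
    incident.sort(key=lambda rp: (-s[rp[0]], rp[1]))
    partners = [p for _, p in incident]
    return partners if m is None else partners[:m]


def evaluate_llap(
    table: ScoreTable, measure: str, gt: GroundTruth, average: str = "micro"
) -> float:
    """PPV of the per-node top-t(v) selections (local link assessment).

    For every node v with t(v) ≥ 1, its t(v) locally highest-ranked
    partners are selected (fewer if v has fewer candidate pairs).

    ``average="micro"`` (default) pools all selections: total selected
    ground-truth links / total selected links, each selection counted
    from its anchor node. ``average="macro"`` averages the per-node
    fraction hits/t(v) over anchor nodes instead.
    """
    if average not in ("micro", "macro"):
        raise ValueError("average must be 'micro' or 'macro'")
    if gt.t == 0:
        raise ValueError("ground truth is empty")
    total_sel = 0
    total_hit = 0
    per_node: list[float] = []
    for v in table.nodes():
        tv = gt.t_of(v)
        if tv < 1:
            continue
        partners = rank_local(table, v, measure, m=tv)
        hits = sum(1 for w in partners if (v, w) in gt)
        total_sel += len(partners)
        total_hit += hits
        per_node.append(hits / tv)
    if average == "macro":
        return float(np.mean(per_node)) if per_node else 0.0
    if total_sel == 0:
        return 0.0
    return total_hit / total_sel


def evaluate_all(
    table: ScoreTable,
    gt: GroundTruth,
    measures: list[str] | None = None,
    k: int | None = None,
) -> pd.DataFrame:
    """GLAP and LLAP report for every measure of the table.

    Columns: measure, task, k, ppv, auc (GLAP only), n_candidates, n_gt,
    n_gt_uncovered.
    """
    if measures is None:
        measures = [
            m
            for m in table.measures
            if m not in ("fdsm_mean", "fdsm_sd", "z_star_rank")
        ]
        if "z_star_rank" in table.df.columns:
            measures.append("z_star")
    n_cand = len(table)
    covered = sum(1 for pair in table.pairs if pair in gt)
    uncovered = gt.t - covered
    rows = []
    for m in measures:
        r = rank_global(table, m)
        kk = k if k is not None else gt.t
        rows.append(
            {
                "measure": m,
                "task": "GLAP",
                "k": kk,
                "ppv": ppv_at_k(r, gt, kk),
                "auc": auc(table, m, gt),
                "n_candidates": n_cand,
                "n_gt": gt.t,
                "n_gt_uncovered": uncovered,
            }
        )
        rows.append(
            {
                "measure": m,
                "task": "LLAP",
                "k": None,
                "ppv": evaluate_llap(table, m, gt),
                "auc": None,
                "n_candidates": n_cand,
                "n_gt": gt.t,
                "n_gt_uncovered": uncovered,
            }
        )
    return pd.DataFrame(rows)
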