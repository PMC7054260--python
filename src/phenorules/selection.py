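"""Significant-rule selection: filtering, per-phenotype optimal thresholds,
accumulation, deduplication, and direction resolution.

Rules are first filtered per sweep step by three criteria — at least two
abnormal co-expressions, lift strictly above 2, and FDR q below 0.1.
Each phenotype's optimal |ES| call threshold is the grid value maximizing
the number of filtered rules incident to it (ties toward the larger, more
stringent threshold).  Rules incident to each phenotype at its optimum are
accumulated, duplicates collapsed (keeping the occurrence with larger
lift, then larger n11), and each surviving bidirectional rule is stored in
the direction of the larger confidence, which orients rules from the
phenotype with fewer abnormal cases toward the one with more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .calls import CallMatrix
from .mining import PairwiseCounts, mine_all, pvalue_family_calibrated, rule_polarity

MIN_CO_DEFAULT = 2
MIN_LIFT_DEFAULT = 2.0
MAX_Q_DEFAULT = 0.1


@dataclass
class SignificantRuleSet:
    """The directed, deduplicated rule atlas plus selection provenance."""

    rules: pd.DataFrame  # directed rules, one row per unordered pair
    optimal_thresholds: dict[str, float] = field(default_factory=dict)
    min_co: int = MIN_CO_DEFAULT
    min_lift: float = MIN_LIFT_DEFAULT
    max_q: float = MAX_Q_DEFAULT
    excluded_thresholds: list[float] = field(default_factory=list)

    @property
    def phenotypes(self) -> list[str]:
        return sorted(set(self.rules["lhs"]) | set(self.rules["rhs"]))

    @property
    def n_rules(self) -> int:
        return len(self.rules)


def filter_rules(
    measures: pd.DataFrame,
    min_co: int = MIN_CO_DEFAULT,
    min_lift: float = MIN_LIFT_DEFAULT,
    max_q: float = MAX_Q_DEFAULT,
) -> pd.DataFrame:
    """Keep records with n11 >= min_co, lift > min_lift (strict), q < max_q."""
    keep = (
        (measures["n11"] >= min_co)
        & (measures["lift"] > min_lift)
        & (measures["q"] < max_q)
    )
    return measures[keep.fillna(False)].copy()


def optimal_threshold_per_phenotype(
    sweep: Mapping[float, pd.DataFrame],
) -> dict[str, float]:
    """argmax over the grid of each phenotype's incident filtered-rule count.

    ``sweep`` maps each global |ES| threshold to its filtered rule table.
    Ties break toward the larger threshold; phenotypes with zero rules at
    every threshold are absent from the map.
    """
    best: dict[str, tuple[int, float]] = {}
    for t in sorted(sweep):
        table = sweep[t]
        counts = (
            pd.concat([table["lhs"], table["rhs"]]).value_counts()
            if len(table)
            else pd.Series(dtype=int)
        )
        for ph, cnt in counts.items():
            cur = best.get(ph)
            if cur is None or cnt >= cur[0]:  # >= implements the larger-threshold tie-break
                best[ph] = (int(cnt), float(t))
    return {ph: t for ph, (_, t) in best.items()}


def accumulate_and_dedupe(
    sweep: Mapping[float, pd.DataFrame],
    optimal: Mapping[str, float],
) -> pd.DataFrame:
    """Union over phenotypes of rules incident to them at their optimum.

    Duplicate unordered pairs collapse to the occurrence with larger lift,
    then larger n11.  The surviving row keeps the threshold it was
    selected at in ``threshold``.
    """
    pieces = []
    for ph, t in optimal.items():
        table = sweep[t]
        inc = table[(table["lhs"] == ph) | (table["rhs"] == ph)].copy()
        inc["threshold"] = t
        pieces.append(inc)
    if not pieces:
        cols = ["lhs", "rhs", "n11", "n10", "n01", "n00", "N", "support",
                "confidence_fwd", "confidence_rev", "lift", "polarity",
                "significance_p", "q", "threshold"]
        return pd.DataFrame(columns=cols)
    acc = pd.concat(pieces, ignore_index=True)
    key = acc.apply(lambda r: tuple(sorted((r["lhs"], r["rhs"]))), axis=1)
    acc["_key"] = key
    acc = acc.sort_values(["lift", "n11"], ascending=False, kind="mergesort")
    acc = acc.drop_duplicates("_key", keep="first").drop(columns="_key")
    return acc.reset_index(drop=True)


def resolve_direction(record: pd.Series) -> pd.Series:
    """Store the direction with the larger confidence.

    The premise of the stored rule has no more abnormal complete cases
    than the conclusion.  Exact confidence ties break lexicographically
    (smaller phenotype id as premise) and set ``tie_flag``.
    """
    rec = record.copy()
    cf, cr = rec["confidence_fwd"], rec["confidence_rev"]
    tie = False
    swap = False
    if cf == cr:
        tie = True
        swap = rec["lhs"] > rec["rhs"]
    elif cr > cf:
        swap = True
    if swap:
        rec["lhs"], rec["rhs"] = record["rhs"], record["lhs"]
        rec["n10"], rec["n01"] = record["n01"], record["n10"]
        rec["confidence_fwd"], rec["confidence_rev"] = cr, cf
    rec["tie_flag"] = tie
    return rec


def select_significant_rules(
    sweep_matrices: Mapping[float, CallMatrix],
    min_co: int = MIN_CO_DEFAULT,
    min_lift: float = MIN_LIFT_DEFAULT,
    max_q: float = MAX_Q_DEFAULT,
    pi0: float | None = None,
) -> SignificantRuleSet:
    """End-to-end: mine each sweep step, filter, optimize, accumulate,
    dedupe, and resolve directions into the final atlas.

    q-values are computed within each sweep step, each being a separate
    mining pass.  Sweep steps whose evaluated p-value family is too
    discrete to calibrate (no p-values anywhere near 1, so the q < max_q
    criterion cannot fail and would admit the entire evaluated family) are
    excluded from the optimal-threshold scan and reported in
    ``excluded_thresholds``.  Polarity is recomputed for the retained
    rules only.
    """
    filtered: dict[float, pd.DataFrame] = {}
    excluded: list[float] = []
    for t, cm in sweep_matrices.items():
        measures = mine_all(cm, compute_polarity=False, pi0=pi0)
        evaluated = measures["significance_p"].dropna()
        if len(evaluated) and not pvalue_family_calibrated(evaluated):
            excluded.append(float(t))
            continue
        filtered[float(t)] = filter_rules(measures, min_co=min_co, min_lift=min_lift, max_q=max_q)
    optimal = optimal_threshold_per_phenotype(filtered)
    acc = accumulate_and_dedupe(filtered, optimal)
    if len(acc):
        acc["polarity"] = [
            rule_polarity(PairwiseCounts(r.n11, r.n10, r.n01, r.n00))
            for r in acc.itertuples()
        ]
        acc = pd.DataFrame([resolve_direction(r) for _, r in acc.iterrows()])
        acc = acc.reset_index(drop=True)
    return SignificantRuleSet(
        rules=acc,
        optimal_thresholds=optimal,
        min_co=min_co,
        min_lift=min_lift,
        max_q=max_q,
        excluded_thresholds=sorted(excluded),
    )
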