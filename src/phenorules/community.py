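"""Similarity clustering of PPAPs and the Fisher-exact enrichment suites.

PPAPs are compared by the Simpson (overlap) distance between their
phenotype sets, 1 - |A n B| / min(|A|, |B|), and agglomerated with Ward
linkage; cutting the tree yields community labels (default k = 7 at
phenotype level, k = 4 at biological-system level).  Enrichment of rule
categories uses exact hypergeometric tests: one-tailed when only positive
enrichment is of interest (evaluated only at fold >= 1), two-tailed when
both directions matter, with Bonferroni/Holm or FDR corrections as
appropriate.  A bootstrap test compares the observed number of realized
between-system rule categories with its null expectation under uniform
sampling of phenotype pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .calls import CallMatrix, NOT_TESTED
from .mining import compute_qvalues, fisher_two_tailed_p
from .ppap import PPAP
from .selection import SignificantRuleSet

MEMBER = "member"
NON_MEMBER = "non_member"
NEVER_CO_TESTED = "never_co_tested"

SELECTION_MEASURES = ("support", "confidence", "polarity", "significance")


@dataclass
class ClusterResult:
    labels: dict[str, int]  # item -> cluster label in 1..k
    linkage: np.ndarray
    k: int
    items: list[str] = field(default_factory=list)


@dataclass
class EnrichmentRecord:
    category: str
    observed: int
    expected: float
    fold: float
    p: float
    corrected: float = float("nan")
    direction: str = "positive"
    degenerate: bool = False


def linkage_to_newick(result: ClusterResult) -> str:
    """Serialize the Ward tree as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(result.linkage)

    def render(node) -> str:
        if node.is_leaf():
            return result.items[node.id]
        left, right = node.left, node.right
        parts = []
        for child in (left, right):
            length = node.dist - (0.0 if child.is_leaf() else child.dist)
            parts.append(f"{render(child)}:{length:.6g}")
        return "(" + ",".join(parts) + ")"

    return render(tree) + ";"


def simpson_distance(set_a: set, set_b: set) -> float:
    """1 - |A n B| / min(|A|, |B|); 0 when one set contains the other."""
    if not set_a or not set_b:
        return float("nan")
    return 1.0 - len(set_a & set_b) / min(len(set_a), len(set_b))


def _ward_cut(items: list[str], sets: list[set], k: int) -> ClusterResult:
    n = len(items)
    if k > n:
        raise ValueError(f"k={k} exceeds item count {n}")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = simpson_distance(sets[i], sets[j])
    Z = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(labels=dict(zip(items, map(int, labels))), linkage=Z, k=k, items=items)


def cluster_ppaps(ppaps: Mapping[str, PPAP] | Sequence[PPAP], k: int = 7) -> ClusterResult:
    """Ward clustering of PPAP phenotype sets under Simpson distance.

    Input order does not affect the partition: PPAPs are sorted by query
    id before distances are computed.
    """
    if isinstance(ppaps, Mapping):
        ppaps = list(ppaps.values())
    ppaps = sorted(ppaps, key=lambda p: p.query)
    return _ward_cut([p.query for p in ppaps], [p.nodes for p in ppaps], k)


def cluster_systems(
    ppaps: Mapping[str, PPAP] | Sequence[PPAP],
    systems_of: Mapping[str, tuple[str, ...]],
    k: int = 4,
) -> ClusterResult:
    """Ward clustering of biological systems by the PPAPs they appear in."""
    if isinstance(ppaps, Mapping):
        ppaps = list(ppaps.values())
    profiles: dict[str, set] = {}
    for p in ppaps:
        for ph in p.nodes:
            for s in systems_of.get(ph, ()):
                profiles.setdefault(s, set()).add(p.query)
    items = sorted(profiles)
    return _ward_cut(items, [profiles[s] for s in items], k)


def build_membership_matrix(
    ppaps: Mapping[str, PPAP], calls: CallMatrix
) -> pd.DataFrame:
    """PPAP x phenotype membership with never-co-tested cells flagged.

    Rows and columns are the query phenotypes; cell (i, j) is ``member``
    when phenotype j belongs to PPAP(i), ``never_co_tested`` when the
    (i, j) phenotype pair shares zero complete cases in the call matrix,
    and ``non_member`` otherwise.
    """
    queries = sorted(ppaps)
    tested = (calls.df.loc[queries] != NOT_TESTED).to_numpy()
    co_tested = (tested.astype(np.int64) @ tested.T.astype(np.int64)) > 0
    out = np.full((len(queries), len(queries)), NON_MEMBER, dtype=object)
    for i, qi in enumerate(queries):
        nodes = ppaps[qi].nodes
        for j, qj in enumerate(queries):
            if qj in nodes:
                out[i, j] = MEMBER
            elif not co_tested[i, j]:
                out[i, j] = NEVER_CO_TESTED
    return pd.DataFrame(out, index=queries, columns=queries)


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(table: Sequence[Sequence[int]], tail: str = "two", category: str = "") -> EnrichmentRecord:
    """Exact hypergeometric enrichment of cell (0, 0) of a 2x2 table.

    Fold = observed / expected-under-margins.  One-tailed p is evaluated
    only when fold >= 1 (positive-enrichment screens); two-tailed p uses
    the minimum-likelihood convention.  Degenerate margins give p = 1,
    flagged.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    N = a + b + c + d
    r1, c1 = a + b, a + c
    degenerate = N == 0 or r1 == 0 or c1 == 0 or r1 == N or c1 == N
    expected = r1 * c1 / N if N > 0 else float("nan")
    fold = a / expected if expected and expected > 0 else float("nan")
    direction = "positive" if not (fold < 1.0) else "negative"
    if degenerate:
        p = 1.0
    elif tail == "two":
        p = fisher_two_tailed_p(a, b, c, d)
    elif tail == "one":
        p = float(stats.hypergeom.sf(a - 1, N, r1, c1)) if fold >= 1.0 else float("nan")
    else:
        raise ValueError("tail must be 'one' or 'two'")
    return EnrichmentRecord(
        category=category,
        observed=a,
        expected=float(expected) if N > 0 else float("nan"),
        fold=float(fold),
        p=p,
        direction=direction,
        degenerate=degenerate,
    )


def _phenotype_category_counts(values: Mapping[str, str]) -> pd.Series:
    return pd.Series(list(values.values())).value_counts()


def stage_type_rule_enrichment(
    atlas: SignificantRuleSet, stage_type_of: Mapping[str, str]
) -> pd.DataFrame:
    """Per ordered stage/type category pair: observed atlas rules vs the
    category composition of all possible ordered phenotype pairs.

    Two-tailed Fisher per pair, Holm-corrected across the 16 tests.
    """
    missing = [p for p in atlas.phenotypes if p not in stage_type_of]
    if missing:
        raise KeyError(f"phenotypes without stage/type annotation: {missing[:5]}")
    cat_counts = _phenotype_category_counts(stage_type_of)
    cats = sorted(cat_counts.index)
    n_total = int(cat_counts.sum())
    possible_total = n_total * (n_total - 1)

    rules = atlas.rules
    obs = pd.Series(
        [
            (stage_type_of[r.lhs], stage_type_of[r.rhs])
            for r in rules.itertuples()
        ]
    ).value_counts()
    n_rules = len(rules)

    records = []
    for ca in cats:
        for cb in cats:
            na, nb = int(cat_counts[ca]), int(cat_counts[cb])
            possible = na * nb - (na if ca == cb else 0)
            o = int(obs.get((ca, cb), 0))
            rec = fisher_enrichment(
                [[o, n_rules - o], [possible - o, possible_total - possible - (n_rules - o)]],
                tail="two",
                category=f"{ca}=>{cb}",
            )
            records.append(rec)
    out = pd.DataFrame([vars(r) for r in records])
    out["corrected"] = multipletests(out["p"], method="holm")[1]
    return out


def system_pair_enrichment(
    atlas: SignificantRuleSet,
    primary_system_of: Mapping[str, str],
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Enrichment of between-system rule categories at FDR < ``fdr``.

    Each phenotype carries one (primary) biological system; a rule whose
    endpoints differ in system realizes the unordered system pair.  For
    each realized pair: 2x2 of (atlas rules in pair vs not) x (possible
    unordered phenotype pairs in pair vs not), two-tailed Fisher,
    q-values, and a positive/negative direction.
    """
    sys_counts = _phenotype_category_counts(primary_system_of)
    n_total = int(sys_counts.sum())
    possible_total = n_total * (n_total - 1) // 2

    rules = atlas.rules
    pair_of = []
    for r in rules.itertuples():
        sa, sb = primary_system_of[r.lhs], primary_system_of[r.rhs]
        pair_of.append(tuple(sorted((sa, sb))) if sa != sb else None)
    obs = pd.Series([p for p in pair_of if p is not None]).value_counts()
    n_rules = len(rules)

    records = []
    for (sa, sb), o in obs.items():
        na, nb = int(sys_counts[sa]), int(sys_counts[sb])
        possible = na * nb
        rec = fisher_enrichment(
            [[int(o), n_rules - int(o)], [possible - int(o), possible_total - possible - (n_rules - int(o))]],
            tail="two",
            category=f"{sa}--{sb}",
        )
        records.append(rec)
    out = pd.DataFrame([vars(r) for r in records])
    if len(out):
        out["q"] = compute_qvalues(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr
    return out


def bootstrap_expected_system_pairs(
    pair_categories: Sequence[int],
    n_rules: int,
    B: int = 10_000,
    seed: int = 0,
    observed: int | None = None,
) -> tuple[float, float]:
    """Null expectation (and lower-tail p) of realized between-system
    rule categories under uniform pair sampling.

    ``pair_categories``: one integer code per possible phenotype pair;
    codes < 0 mark within-system pairs.  Each replicate draws ``n_rules``
    pairs without replacement and counts the distinct non-negative codes
    realized.  Returns (mean count over B replicates, fraction of
    replicates with count <= observed); the p-value is NaN when
    ``observed`` is not given.
    """
    codes = np.asarray(pair_categories, dtype=np.int64)
    if n_rules > len(codes):
        raise ValueError("n_rules exceeds the number of possible pairs")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty(B, dtype=np.int64)
    for b in range(B):
        drawn = codes[rng.choice(len(codes), size=n_rules, replace=False)]
        counts[b] = len(np.unique(drawn[drawn >= 0]))
    expected = float(counts.mean())
    p = float(np.mean(counts <= observed)) if observed is not None else float("nan")
    return expected, p


def measure_extreme_enrichment(
    atlas: SignificantRuleSet,
    measure: str,
    category_of: Mapping[str, str],
    quantile: float = 0.25,
) -> pd.DataFrame:
    """Category over-representation in the upper/lower tails of a measure.

    Rules are split at the lower/upper ``quantile`` of the chosen measure
    (support, confidence, polarity, or significance as -log10 p); per
    category and extreme, a one-tailed Fisher test screens for
    over-representation, Bonferroni-corrected over all tests run.
    """
    if measure not in SELECTION_MEASURES:
        raise ValueError(f"measure must be one of {SELECTION_MEASURES}")
    rules = atlas.rules
    if measure == "support":
        vals = rules["support"].to_numpy(float)
    elif measure == "confidence":
        vals = rules["confidence_fwd"].to_numpy(float)
    elif measure == "polarity":
        vals = rules["polarity"].to_numpy(float)
    else:
        vals = -np.log10(rules["significance_p"].to_numpy(float))
    if len(rules) == 0 or len(np.unique(vals[~np.isnan(vals)])) <= 1:
        return pd.DataFrame()
    lo, hi = np.nanquantile(vals, [quantile, 1.0 - quantile])
    cats = np.array(
        [category_of.get((r.lhs, r.rhs), category_of.get(r.lhs, "")) for r in rules.itertuples()]
    )
    records = []
    for extreme, mask in (("lower", vals <= lo), ("upper", vals >= hi)):
        for cat in sorted(set(cats)):
            in_cat = cats == cat
            a = int(np.sum(mask & in_cat))
            b = int(np.sum(~mask & in_cat))
            c = int(np.sum(mask & ~in_cat))
            d = int(np.sum(~mask & ~in_cat))
            rec = fisher_enrichment([[a, c], [b, d]], tail="one", category=f"{cat}:{extreme}")
            records.append(rec)
    out = pd.DataFrame([vars(r) for r in records])
    n_tests = int(out["p"].notna().sum())
    out["corrected"] = np.minimum(out["p"] * max(n_tests, 1), 1.0)
    return out


def measure_correlations(atlas: SignificantRuleSet) -> pd.DataFrame:
    """Spearman rho and p for all 6 pairs of the four selection measures."""
    rules = atlas.rules
    if len(rules) < 3:
        raise ValueError("need at least 3 rules for correlations")
    cols = {
        "support": rules["support"].to_numpy(float),
        "confidence": rules["confidence_fwd"].to_numpy(float),
        "polarity": rules["polarity"].to_numpy(float),
        "significance": -np.log10(rules["significance_p"].to_numpy(float)),
    }
    names = list(cols)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rho, p = stats.spearmanr(cols[names[i]], cols[names[j]], nan_policy="omit")
            rows.append({"measure_a": names[i], "measure_b": names[j], "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows)
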