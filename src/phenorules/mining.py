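"""Pairwise association-rule measures over a three-valued call matrix.

For every ordered phenotype pair (X, Y), the complete cases — strains
tested in both phenotypes — form a 2x2 cross table (n11, n10, n01, n00).
Six measures describe the rule "X abnormal => Y abnormal":

* num. of abnormal co-expressions: n11
* support: n11 / N
* confidence: n11 / (n11 + n10) forward, n11 / (n11 + n01) reverse
* lift: n11 * N / ((n11 + n10) * (n11 + n01)); 1 = independence,
  symmetric under direction swap
* rule polarity: -log10 of the two-tailed Fisher p comparing the two
  directional confidences (table [[n11, n10], [n11, n01]]); large values
  mean the premise has far fewer abnormal cases than the conclusion
* rule significance: two-tailed Fisher p of the cross table itself,
  evaluated only when n11 >= 2; q-values (FDR with a sliding-linear-model
  pi0 estimate) are computed over the evaluated p-values
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calls import ABNORMAL, NOT_TESTED, CallMatrix

#: relative slack when summing hypergeometric outcomes no more probable
#: than the observed table (guards against float noise in exact ties)
_FISHER_EPS = 1e-7


@dataclass(frozen=True)
class PairwiseCounts:
    """Complete-case 2x2 cross table for one phenotype pair."""

    n11: int  # both abnormal
    n10: int  # X abnormal, Y normal
    n01: int  # X normal, Y abnormal
    n00: int  # both normal

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def N(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def enumerate_pairs(n_phenotypes: int) -> list[tuple[int, int, bool]]:
    """All ordered (X, Y) combinations including X = Y; count = n^2.

    Each entry is (i, j, is_self) so downstream stages can exclude
    self-pairs from rules.
    """
    if n_phenotypes < 1:
        raise ValueError("need at least one phenotype")
    return [(i, j, i == j) for i in range(n_phenotypes) for j in range(n_phenotypes)]


def pairwise_counts(calls: CallMatrix, x: str, y: str) -> PairwiseCounts:
    """Cross table for phenotypes X, Y over strains tested in both."""
    if x == y:
        raise ValueError("self-pairs carry no rule")
    for ph in (x, y):
        if ph not in calls.df.index:
            raise KeyError(f"unknown phenotype: {ph}")
    rx = calls.df.loc[x].to_numpy()
    ry = calls.df.loc[y].to_numpy()
    keep = (rx != NOT_TESTED) & (ry != NOT_TESTED)
    ax = rx[keep] == ABNORMAL
    ay = ry[keep] == ABNORMAL
    return PairwiseCounts(
        n11=int(np.sum(ax & ay)),
        n10=int(np.sum(ax & ~ay)),
        n01=int(np.sum(~ax & ay)),
        n00=int(np.sum(~ax & ~ay)),
    )


def support(c: PairwiseCounts) -> float:
    """Co-abnormality frequency n11 / N; NaN when no complete cases."""
    return c.n11 / c.N if c.N > 0 else float("nan")


def confidence(c: PairwiseCounts, direction: str = "fwd") -> float:
    """Conditional abnormal probability; NaN on an empty premise margin."""
    if direction == "fwd":
        denom = c.n11 + c.n10
    elif direction == "rev":
        denom = c.n11 + c.n01
    else:
        raise ValueError("direction must be 'fwd' or 'rev'")
    return c.n11 / denom if denom > 0 else float("nan")


def lift(c: PairwiseCounts) -> float:
    """n11 * N / ((n11+n10) * (n11+n01)); symmetric, 1 = independence."""
    mx = c.n11 + c.n10
    my = c.n11 + c.n01
    if mx == 0 or my == 0:
        return float("nan")
    return c.n11 * c.N / (mx * my)


def fisher_two_tailed_p(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-tailed Fisher exact p: sum of hypergeometric outcomes whose
    probability does not exceed that of the observed table."""
    r1 = n11 + n10
    c1 = n11 + n01
    N = n11 + n10 + n01 + n00
    if N == 0 or r1 == 0 or r1 == N or c1 == 0 or c1 == N:
        return 1.0
    kmin = max(0, c1 - (N - r1))
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(ks, N, r1, c1)
    p_obs = pmf[n11 - kmin]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + _FISHER_EPS)].sum()))


def rule_polarity(c: PairwiseCounts) -> float:
    """-log10 p of the exact test comparing the two directional confidences.

    The 2x2 compares forward successes/failures against reverse
    successes/failures: [[n11, n10], [n11, n01]].  NaN when either
    confidence is undefined.
    """
    if c.n11 + c.n10 == 0 or c.n11 + c.n01 == 0:
        return float("nan")
    p = fisher_two_tailed_p(c.n11, c.n10, c.n11, c.n01)
    return -np.log10(p)


def rule_significance(c: PairwiseCounts) -> float:
    """Two-tailed Fisher p of the cross table (significance of lift).

    Evaluated only for n11 >= 2; NaN marks not-evaluated pairs, which are
    excluded from the q-value vector.
    """
    if c.n11 < 2:
        return float("nan")
    return fisher_two_tailed_p(c.n11, c.n10, c.n01, c.n00)


# ---------------------------------------------------------------------------
# q-values: BH step-up scaled by a sliding-linear-model pi0 estimate
# ---------------------------------------------------------------------------

def pvalue_family_calibrated(p_values, lambda_top: float = 0.95) -> bool:
    """Whether a p-value family can support q-value calibration.

    The q-value machinery (pi0 estimation and BH) presumes null p-values
    spread over [0, 1].  Heavily discrete exact tests on sparse tables,
    gated on n11 >= 2, can have a maximum achievable p far below 1 — the
    evaluated family is then conditioned toward small p and FDR control is
    meaningless for it.  The family is considered calibrated when its
    largest p-value reaches the top of the pi0 lambda grid.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    return len(p) > 0 and float(p.max()) >= lambda_top


def estimate_pi0_slim(
    p_values: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    window: int = 5,
) -> float:
    """Estimate the true-null proportion pi0 by a sliding linear model.

    The survival function S(lam) = P(p > lam) of a null/alternative
    mixture behaves as pi0 * (1 - lam) once lam clears the bulk of the
    alternative p-values.  Straight lines are fitted to S over sliding
    windows of the lambda grid; the slope with respect to (1 - lam),
    averaged over the upper-lambda windows where the alternative
    contribution has flattened out, estimates pi0.  Degenerate estimates
    (<= 0, > 1, or too few p-values) fall back to pi0 = 1, i.e. plain
    Benjamini-Hochberg.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) < 20:
        return 1.0
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    # Identifiability guard: the slope of S(lam) estimates pi0 only if null
    # p-values actually reach the upper end of [0, 1] (see
    # pvalue_family_calibrated); otherwise the high-lambda slope is 0
    # regardless of the true pi0, so fall back to plain BH.
    if not pvalue_family_calibrated(p, lambda_grid[-1]):
        return 1.0
    surv = np.array([(p > lam).mean() for lam in lambda_grid])
    x = 1.0 - lambda_grid
    slopes = []
    for i in range(len(lambda_grid) - window + 1):
        xi, yi = x[i : i + window], surv[i : i + window]
        slopes.append(np.polyfit(xi, yi, 1)[0])
    upper = slopes[len(slopes) // 2 :]  # windows at high lambda (null-dominated)
    pi0 = float(np.mean(upper))
    # Conservative floor: Storey's survival-ratio estimator S(lam)/(1-lam).
    # Discrete super-uniform p-value families make the survival curve
    # convex, which biases the local slope downward; an underestimated pi0
    # deflates every q-value uniformly, so take the larger (more
    # conservative) of the two classical estimates.
    storey = max(float((p > lam).mean() / (1.0 - lam)) for lam in (0.5, 0.8))
    pi0 = max(pi0, storey)
    # degenerate: non-finite, out of (0, 1], or indistinguishable from a
    # flat survival curve (slope at float-noise level)
    if not np.isfinite(pi0) or pi0 <= 1e-8 or pi0 > 1.0:
        return 1.0
    return min(pi0, 1.0)


def compute_qvalues(p_values, pi0: float | None = None, m_family: int | None = None) -> np.ndarray:
    """q_i = pi0 * (BH-adjusted p_i), clipped to [0, 1].

    NaN entries (not-evaluated tests) stay NaN and get no q-value.
    ``pi0=None`` estimates pi0 with the sliding linear model; ``pi0=1``
    reproduces plain Benjamini-Hochberg on the supplied vector.

    ``m_family`` sets the size of the hypothesis family the step-up
    denominator uses.  When the supplied vector is a gated subset of a
    larger screen (pairs with >= 2 co-abnormal strains out of all
    phenotype pairs), the unevaluated members carry no evidence and enter
    as p = 1; correcting only over the gated subset would ignore that the
    gate itself preselects extreme tables.  In dense screens nearly every
    pair is evaluated and the two choices coincide.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if not mask.any():
        return q
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    evaluated = p[mask]
    n_pad = 0 if m_family is None else max(0, int(m_family) - len(evaluated))
    if pi0 is None:
        # pi0 of the whole family: unevaluated members are nulls by
        # construction (no evidence), so they enter the mixture at pi0 = 1
        pi0_ev = estimate_pi0_slim(evaluated)
        pi0 = (n_pad + pi0_ev * len(evaluated)) / (n_pad + len(evaluated))
    padded = np.concatenate([evaluated, np.ones(n_pad)])
    bh = multipletests(padded, method="fdr_bh")[1][: len(evaluated)]
    q[mask] = np.minimum(pi0 * bh, 1.0)
    return q


# ---------------------------------------------------------------------------
# Full mining pass
# ---------------------------------------------------------------------------

def _count_matrices(calls: CallMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs complete-case count matrices via boolean matrix products."""
    arr = calls.df.to_numpy()
    A = ((arr == ABNORMAL)).astype(np.float64)
    T = ((arr != NOT_TESTED)).astype(np.float64)
    Nrm = T - A  # tested and normal
    n11 = A @ A.T
    n10 = A @ Nrm.T
    n01 = Nrm @ A.T
    n00 = Nrm @ Nrm.T
    return (
        np.rint(n11).astype(np.int64),
        np.rint(n10).astype(np.int64),
        np.rint(n01).astype(np.int64),
        np.rint(n00).astype(np.int64),
    )


def mine_all(
    calls: CallMatrix,
    compute_polarity: bool = True,
    pi0: float | None = None,
) -> pd.DataFrame:
    """One record per unordered phenotype pair with all six measures.

    ``lhs``/``rhs`` follow the matrix row order; both directional
    confidences are carried so direction can be resolved later.  q-values
    are computed over the evaluated (n11 >= 2) significance p-values.
    """
    phenos = calls.phenotypes
    n11m, n10m, n01m, n00m = _count_matrices(calls)
    iu, ju = np.triu_indices(len(phenos), k=1)
    n11 = n11m[iu, ju]
    n10 = n10m[iu, ju]
    n01 = n01m[iu, ju]
    n00 = n00m[iu, ju]
    N = n11 + n10 + n01 + n00
    mx = n11 + n10
    my = n11 + n01
    with np.errstate(divide="ignore", invalid="ignore"):
        sup = np.where(N > 0, n11 / np.maximum(N, 1), np.nan)
        conf_f = np.where(mx > 0, n11 / np.maximum(mx, 1), np.nan)
        conf_r = np.where(my > 0, n11 / np.maximum(my, 1), np.nan)
        lft = np.where((mx > 0) & (my > 0), n11 * N / np.maximum(mx * my, 1), np.nan)

    polarity = np.full(len(n11), np.nan)
    sig = np.full(len(n11), np.nan)
    for k in range(len(n11)):
        if compute_polarity and mx[k] > 0 and my[k] > 0:
            if n11[k] == 0:
                polarity[k] = 0.0  # both confidences are 0 -> identical rows, p = 1
            else:
                polarity[k] = -np.log10(
                    fisher_two_tailed_p(n11[k], n10[k], n11[k], n01[k])
                )
        if n11[k] >= 2:
            sig[k] = fisher_two_tailed_p(n11[k], n10[k], n01[k], n00[k])

    out = pd.DataFrame(
        {
            "lhs": [phenos[i] for i in iu],
            "rhs": [phenos[j] for j in ju],
            "n11": n11,
            "n10": n10,
            "n01": n01,
            "n00": n00,
            "N": N,
            "support": sup,
            "confidence_fwd": conf_f,
            "confidence_rev": conf_r,
            "lift": lft,
            "polarity": polarity,
            "significance_p": sig,
        }
    )
    out["q"] = compute_qvalues(out["significance_p"].to_numpy(), pi0=pi0, m_family=len(out))
    return out
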