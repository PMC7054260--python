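"""Three-valued phenotypic calls from quantitative measurements.

A (phenotype, strain) cell is called ``abnormal`` when the standardized
mutant-vs-control difference (unbiased Hedges' g) clears a magnitude
threshold and two significance prerequisites: the normal-approximation
p-value for g and the exact p-value of a two-group significance test must
both fall below 0.05.  Cells whose effect size cannot be computed (fewer
than two observations in a group, or zero pooled variance) are ``not
tested``.  Sweeping the |ES| threshold over a grid yields one call matrix
per threshold; the abnormal set shrinks monotonically as the threshold
grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ABNORMAL = "A"
NORMAL = "N"
NOT_TESTED = "NT"
CALL_SYMBOLS = (ABNORMAL, NORMAL, NOT_TESTED)

#: p-value ceiling for both call prerequisites
ALPHA_CALL = 0.05


class EffectSizeError(ValueError):
    """Effect size not computable for this cell (too few values or zero variance)."""


class AnnotationError(ValueError):
    """Parameters present in the data but missing from the annotation map."""

    def __init__(self, offenders: Sequence[str]):
        self.offenders = list(offenders)
        super().__init__(
            "parameters without phenotype annotation: " + ", ".join(self.offenders)
        )


@dataclass(frozen=True)
class EffectSizeResult:
    """Unbiased standardized mean difference for one (parameter, strain) cell."""

    g: float
    se_g: float
    ci95: tuple[float, float]
    p_g: float
    p_exact: float
    n_mutant: int
    n_control: int


@dataclass
class CallMatrix:
    """Phenotype x strain grid of calls in {A, N, NT}.

    ``df`` holds string symbols; index = phenotype ids, columns = strain ids.
    ``threshold_used`` records the |ES| threshold the matrix was called at
    (``None`` for matrices supplied directly, e.g. synthetic shortcuts).
    """

    df: pd.DataFrame
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        bad = set(np.unique(self.df.to_numpy())) - set(CALL_SYMBOLS)
        if bad:
            raise ValueError(f"unknown call symbols: {sorted(bad)}")

    @property
    def phenotypes(self) -> list[str]:
        return list(self.df.index)

    @property
    def strains(self) -> list[str]:
        return list(self.df.columns)

    def abnormal_mask(self) -> pd.DataFrame:
        return self.df == ABNORMAL

    def tested_mask(self) -> pd.DataFrame:
        return self.df != NOT_TESTED

    def n_abnormal(self) -> int:
        return int(self.abnormal_mask().to_numpy().sum())


def make_grid(start: float = 0.8, stop: float = 3.0, step: float = 0.1) -> np.ndarray:
    """Ordered |ES| threshold grid; default 0.8..3.0 in bins of 0.1 (23 values)."""
    grid = np.round(np.arange(start, stop + step / 2, step), 10)
    if len(grid) == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing and positive")
    return grid


# ---------------------------------------------------------------------------
# Effect size
# ---------------------------------------------------------------------------

def hedges_g(
    mutant_values: Sequence[float],
    control_values: Sequence[float],
    exact_test: str = "welch",
) -> EffectSizeResult:
    """Unbiased Hedges' g for mutant vs control values.

    g = J * (mean_m - mean_c) / s_pooled with the small-sample correction
    J = 1 - 3/(4*df - 1), df = n_m + n_c - 2.  The standard error uses the
    large-sample Hedges-Olkin approximation
    se(g)^2 = (n_m + n_c)/(n_m * n_c) + g^2 / (2*(n_m + n_c)),
    from which the 95% CI and the normal-approximation p-value for g != 0
    follow.  ``p_exact`` is the accompanying two-sided significance test:
    Welch's t by default, or an exact-style Wilcoxon rank-sum
    (``exact_test="wilcoxon"``).
    """
    m = np.asarray(mutant_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    n1, n2 = len(m), len(c)
    if n1 < 2 or n2 < 2:
        raise EffectSizeError("each group needs at least two values")
    v1, v2 = m.var(ddof=1), c.var(ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if sp2 <= 0 or not np.isfinite(sp2):
        raise EffectSizeError("zero or non-finite pooled variance")
    d = (m.mean() - c.mean()) / np.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = J * d
    se = np.sqrt((n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2)))
    z = stats.norm.ppf(0.975)
    p_g = 2.0 * stats.norm.sf(abs(g) / se)
    if exact_test == "welch":
        p_exact = float(stats.ttest_ind(m, c, equal_var=False).pvalue)
    elif exact_test == "wilcoxon":
        p_exact = float(stats.mannwhitneyu(m, c, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown exact_test: {exact_test!r}")
    return EffectSizeResult(
        g=float(g),
        se_g=float(se),
        ci95=(float(g - z * se), float(g + z * se)),
        p_g=float(p_g),
        p_exact=p_exact,
        n_mutant=n1,
        n_control=n2,
    )


def make_call(es: EffectSizeResult | None, threshold: float) -> str:
    """Abnormal iff |g| >= threshold and both prerequisite p-values < 0.05."""
    if es is None:
        return NOT_TESTED
    if abs(es.g) >= threshold and es.p_g < ALPHA_CALL and es.p_exact < ALPHA_CALL:
        return ABNORMAL
    return NORMAL


# ---------------------------------------------------------------------------
# Vectorized effect-size table over a long measurement table
# ---------------------------------------------------------------------------

def effect_size_table(measurements: pd.DataFrame, exact_test: str = "welch") -> pd.DataFrame:
    """Per-(parameter, strain) effect sizes from a long measurement table.

    ``measurements`` columns: parameter_id, strain_id, cohort, value.
    Control values are pooled per parameter and shared across strains of
    that parameter (screening-style shared control group).  Returns one row
    per (parameter_id, strain_id) mutant group with columns g, se_g, ci_low,
    ci_high, p_g, p_exact, n_mutant, n_control and a ``computable`` flag.
    """
    mut = measurements[measurements["cohort"] == "mutant"]
    ctl = measurements[measurements["cohort"] == "control"]

    gm = mut.groupby(["parameter_id", "strain_id"], observed=True)["value"].agg(
        n1="count", m1="mean", v1="var"
    )
    gc = ctl.groupby("parameter_id", observed=True)["value"].agg(
        n2="count", m2="mean", v2="var"
    )
    tab = gm.reset_index().merge(gc.reset_index(), on="parameter_id", how="left")

    n1 = tab["n1"].to_numpy(float)
    n2 = tab["n2"].fillna(0).to_numpy(float)
    m1 = tab["m1"].to_numpy(float)
    m2 = tab["m2"].to_numpy(float)
    v1 = tab["v1"].to_numpy(float)
    v2 = tab["v2"].to_numpy(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        computable = (n1 >= 2) & (n2 >= 2) & np.isfinite(sp2) & (sp2 > 0)
        d = (m1 - m2) / np.sqrt(sp2)
        J = 1.0 - 3.0 / (4.0 * df - 1.0)
        g = J * d
        se = np.sqrt((n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2)))
        p_g = 2.0 * stats.norm.sf(np.abs(g) / se)

        if exact_test == "welch":
            se1, se2 = v1 / n1, v2 / n2
            t = (m1 - m2) / np.sqrt(se1 + se2)
            df_w = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
            p_exact = 2.0 * stats.t.sf(np.abs(t), df_w)
        elif exact_test == "wilcoxon":
            p_exact = _wilcoxon_by_group(mut, ctl, tab)
        else:
            raise ValueError(f"unknown exact_test: {exact_test!r}")

    z = stats.norm.ppf(0.975)
    out = tab[["parameter_id", "strain_id"]].copy()
    out["g"] = np.where(computable, g, np.nan)
    out["se_g"] = np.where(computable, se, np.nan)
    out["ci_low"] = out["g"] - z * out["se_g"]
    out["ci_high"] = out["g"] + z * out["se_g"]
    out["p_g"] = np.where(computable, p_g, np.nan)
    out["p_exact"] = np.where(computable, p_exact, np.nan)
    out["n_mutant"] = n1.astype(int)
    out["n_control"] = n2.astype(int)
    out["computable"] = computable
    return out


def _wilcoxon_by_group(mut: pd.DataFrame, ctl: pd.DataFrame, tab: pd.DataFrame) -> np.ndarray:
    ctl_by_par = {k: v["value"].to_numpy() for k, v in ctl.groupby("parameter_id", observed=True)}
    mut_groups = {
        k: v["value"].to_numpy()
        for k, v in mut.groupby(["parameter_id", "strain_id"], observed=True)
    }
    out = np.full(len(tab), np.nan)
    for i, (par, strain) in enumerate(zip(tab["parameter_id"], tab["strain_id"])):
        mv = mut_groups.get((par, strain))
        cv = ctl_by_par.get(par)
        if mv is None or cv is None or len(mv) < 2 or len(cv) < 2:
            continue
        out[i] = stats.mannwhitneyu(mv, cv, alternative="two-sided").pvalue
    return out


# ---------------------------------------------------------------------------
# Parameter -> phenotype collapse and threshold sweep
# ---------------------------------------------------------------------------

def collapse_parameters(
    parameter_calls: pd.DataFrame,
    parameter_to_phenotype: Mapping[str, str],
    threshold: float | None = None,
) -> CallMatrix:
    """Collapse per-parameter calls to phenotype level.

    A phenotype is abnormal if any constituent parameter is abnormal,
    normal if none is abnormal and at least one was tested, and not tested
    otherwise.  ``parameter_calls``: parameters x strains DataFrame of call
    symbols.
    """
    missing = [p for p in parameter_calls.index if p not in parameter_to_phenotype]
    if missing:
        raise AnnotationError(missing)
    phen = pd.Index([parameter_to_phenotype[p] for p in parameter_calls.index])
    arr = parameter_calls.to_numpy()
    ab = pd.DataFrame(arr == ABNORMAL, index=phen, columns=parameter_calls.columns)
    tested = pd.DataFrame(arr != NOT_TESTED, index=phen, columns=parameter_calls.columns)
    any_ab = ab.groupby(level=0).any()
    any_tested = tested.groupby(level=0).any()
    vals = np.where(any_ab.to_numpy(), ABNORMAL, np.where(any_tested.to_numpy(), NORMAL, NOT_TESTED))
    return CallMatrix(
        pd.DataFrame(vals, index=any_ab.index, columns=any_ab.columns),
        threshold_used=threshold,
    )


def calls_from_effect_sizes(
    es_table: pd.DataFrame,
    parameter_to_phenotype: Mapping[str, str],
    threshold: float,
    strains: Sequence[str] | None = None,
) -> CallMatrix:
    """Apply one |ES| threshold to a precomputed effect-size table."""
    t = es_table
    status = np.where(
        ~t["computable"].to_numpy(),
        NOT_TESTED,
        np.where(
            (np.abs(t["g"].to_numpy()) >= threshold)
            & (t["p_g"].to_numpy() < ALPHA_CALL)
            & (t["p_exact"].to_numpy() < ALPHA_CALL),
            ABNORMAL,
            NORMAL,
        ),
    )
    wide = (
        pd.DataFrame(
            {"parameter_id": t["parameter_id"], "strain_id": t["strain_id"], "call": status}
        )
        .pivot(index="parameter_id", columns="strain_id", values="call")
        .fillna(NOT_TESTED)
    )
    if strains is not None:
        wide = wide.reindex(columns=list(strains), fill_value=NOT_TESTED)
    return collapse_parameters(wide, parameter_to_phenotype, threshold=threshold)


def sweep_call_matrices(
    measurements: pd.DataFrame,
    parameter_to_phenotype: Mapping[str, str],
    grid: Iterable[float] | None = None,
    exact_test: str = "welch",
) -> dict[float, CallMatrix]:
    """One call matrix per |ES| threshold; effect sizes computed once."""
    grid = make_grid() if grid is None else np.asarray(list(grid), float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing and positive")
    es = effect_size_table(measurements, exact_test=exact_test)
    strains = sorted(measurements.loc[measurements["cohort"] == "mutant", "strain_id"].unique())
    return {
        float(t): calls_from_effect_sizes(es, parameter_to_phenotype, float(t), strains=strains)
        for t in grid
    }
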