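"""Association tests between imprinting status and clinical groups.

Pearson chi-squared (no continuity correction) links region status to
categorical clinical factors; altered-DMR burdens are compared between
groups with a two-sided Wilcoxon rank-sum test (configurable to Welch's t).
P-values are Benjamini-Hochberg adjusted within one analysis family.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AssociationResult",
    "BurdenComparison",
    "crosstab_test",
    "bh_adjust",
    "compare_burden",
    "associate_factors",
]


@dataclass
class AssociationResult:
    dmr_name: str
    factor: str
    contingency: pd.DataFrame
    chi2: float
    df: int
    p: float
    p_bh: float | None = None


@dataclass
class BurdenComparison:
    group_a: str
    group_b: str
    statistic: float
    p: float
    p_bh: float | None = None


def crosstab_test(
    region_status: pd.Series, factor: pd.Series, dmr_name: str = "", factor_name: str = ""
) -> AssociationResult | None:
    """Pearson chi-squared test of status x factor on the shared samples.

    Samples missing either label are dropped.  Degenerate tables (a single
    observed status or factor level) yield ``None`` with a warning, and a
    warning is emitted when any expected cell count falls below 5.
    """
    joined = pd.concat(
        {"status": region_status, "factor": factor}, axis=1, join="inner"
    ).dropna()
    table = pd.crosstab(joined["status"], joined["factor"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        warnings.warn(
            f"{dmr_name}/{factor_name}: degenerate table {table.shape}, test skipped",
            stacklevel=2,
        )
        return None
    chi2, p, df, expected = sps.chi2_contingency(table.to_numpy(), correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"{dmr_name}/{factor_name}: expected cell count < 5", stacklevel=2
        )
    return AssociationResult(
        dmr_name=dmr_name,
        factor=factor_name,
        contingency=table,
        chi2=float(chi2),
        df=int(df),
        p=float(p),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def compare_burden(
    burdens: pd.Series, groups: pd.Series, method: str = "wilcoxon"
) -> list[BurdenComparison]:
    """All pairwise group comparisons of per-sample altered-DMR counts.

    Uses the two-sided Wilcoxon rank-sum test by default (``method='ttest'``
    switches to Welch's t).  Adjusted p-values are BH over the pairs of this
    call.  Pairs with an empty group are skipped with a warning.
    """
    joined = pd.concat({"burden": burdens, "group": groups}, axis=1, join="inner").dropna()
    levels = sorted(joined["group"].unique())
    if len(levels) < 2:
        raise ValueError(f"need >= 2 groups, got {levels}")
    results: list[BurdenComparison] = []
    for a, b in itertools.combinations(levels, 2):
        xa = joined.loc[joined["group"] == a, "burden"].to_numpy(dtype=float)
        xb = joined.loc[joined["group"] == b, "burden"].to_numpy(dtype=float)
        if xa.size == 0 or xb.size == 0:
            warnings.warn(f"empty group in pair ({a}, {b}); skipped", stacklevel=2)
            continue
        if method == "wilcoxon":
            stat, p = sps.ranksums(xa, xb)
        elif method == "ttest":
            stat, p = sps.ttest_ind(xa, xb, equal_var=False)
        else:
            raise ValueError(f"unknown method {method!r}")
        results.append(BurdenComparison(str(a), str(b), float(stat), float(p)))
    if results:
        adj = bh_adjust([r.p for r in results])
        for r, q in zip(results, adj):
            r.p_bh = float(q)
    return results


def associate_factors(
    region_calls: pd.DataFrame,
    clinical: pd.DataFrame,
    factors: list[str],
    dmr_names: list[str] | None = None,
) -> pd.DataFrame:
    """Chi-squared association of region status with each clinical factor.

    One BH family per factor, across the tested DMRs (by default the DMRs
    present in ``region_calls``; pass the most-altered set to mirror the
    primary analysis).  ``clinical`` must be indexed by sample_id.

    Returns a tidy DataFrame (dmr_name, factor, chi2, df, p, p_bh).
    """
    if dmr_names is None:
        dmr_names = sorted(region_calls["dmr_name"].unique())
    status_by_dmr = {
        name: grp.set_index("sample_id")["call"]
        for name, grp in region_calls.groupby("dmr_name")
        if name in set(dmr_names)
    }
    rows = []
    for factor in factors:
        if factor not in clinical.columns:
            raise KeyError(f"clinical table lacks factor {factor!r}")
        family = []
        for name in dmr_names:
            status = status_by_dmr.get(name)
            if status is None:
                continue
            res = crosstab_test(status, clinical[factor], dmr_name=name, factor_name=factor)
            if res is not None:
                family.append(res)
        if family:
            adj = bh_adjust([r.p for r in family])
            for r, q in zip(family, adj):
                r.p_bh = float(q)
                rows.append((r.dmr_name, r.factor, r.chi2, r.df, r.p, r.p_bh))
    return pd.DataFrame(rows, columns=["dmr_name", "factor", "chi2", "df", "p", "p_bh"])
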