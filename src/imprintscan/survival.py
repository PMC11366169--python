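"""Survival stratification by imprinting status.

Kaplan-Meier curves with multi-group log-rank tests, Cox
proportional-hazards contrasts (focal status category vs "No change",
optionally adjusted for the binary clinical risk markers) and an exhaustive
expression-cutoff scan whose best log-rank p is Bonferroni-corrected by the
number of cutoffs actually tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test

from .classify import NO_CHANGE

__all__ = [
    "LogRankResult",
    "CoxResult",
    "KaplanScanResult",
    "km_logrank",
    "cox_fit",
    "cox_status_contrast",
    "kaplan_scan",
    "stratified_km_low_risk",
]


@dataclass
class LogRankResult:
    dmr_name: str
    group_sizes: dict[str, int]
    chi2: float
    df: int
    p: float


@dataclass
class CoxResult:
    term: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass
class KaplanScanResult:
    gene: str
    cutoff: float
    n_cutoffs_tested: int
    p_raw: float
    p_bonferroni: float
    n_low: int
    n_high: int


def _align(status: pd.Series, surv: pd.DataFrame) -> pd.DataFrame:
    df = pd.concat({"group": status}, axis=1).join(surv[["time", "event"]], how="inner")
    return df.dropna()


def km_logrank(
    status: pd.Series, surv: pd.DataFrame, dmr_name: str = ""
) -> tuple[LogRankResult, dict[str, pd.DataFrame]] | None:
    """Multi-group log-rank test plus per-group Kaplan-Meier curve tables.

    ``status`` holds group labels indexed by sample_id; ``surv`` must carry
    ``time`` and ``event`` columns on the same index.  Samples missing either
    are dropped.  With fewer than two nonempty groups the result is absent.

    Curve tables have columns time, at_risk, survival.
    """
    df = _align(status, surv)
    sizes = df["group"].value_counts().to_dict()
    if len(sizes) < 2:
        warnings.warn(f"{dmr_name}: <2 nonempty groups, log-rank skipped", stacklevel=2)
        return None
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    curves: dict[str, pd.DataFrame] = {}
    for name, grp in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"])
        tbl = kmf.event_table.join(kmf.survival_function_)
        curves[str(name)] = pd.DataFrame(
            {
                "time": tbl.index.to_numpy(dtype=float),
                "at_risk": tbl["at_risk"].to_numpy(dtype=int),
                "survival": tbl["KM_estimate"].to_numpy(dtype=float),
            }
        )
    result = LogRankResult(
        dmr_name=dmr_name,
        group_sizes={str(k): int(v) for k, v in sizes.items()},
        chi2=float(res.test_statistic),
        df=len(sizes) - 1,
        p=float(res.p_value),
    )
    return result, curves


def cox_fit(
    surv: pd.DataFrame, focal: pd.Series, adjusters: pd.DataFrame | None = None
) -> list[CoxResult] | None:
    """Cox proportional-hazards fit of a binary focal indicator (+ adjusters).

    ``surv`` needs ``time`` and ``event`` columns; ``focal`` is a 0/1 series
    on the same index (samples with NA are excluded).  Adjusters are
    binary-coded columns; constant adjusters are dropped with a warning, a
    constant focal indicator is an error.  Ties are handled with the Efron
    approximation.  Returns one :class:`CoxResult` per retained term, or
    ``None`` when the fit does not converge.
    """
    focal_name = str(focal.name) if focal.name is not None else "focal"
    df = pd.concat({focal_name: focal}, axis=1).join(surv[["time", "event"]], how="inner")
    if adjusters is not None:
        df = df.join(adjusters, how="inner")
    df = df.dropna()
    if df[focal_name].nunique() < 2:
        raise ValueError("focal indicator is constant over the analysed samples")
    for col in list(df.columns):
        if col in ("time", "event", focal_name):
            continue
        if df[col].nunique() < 2:
            warnings.warn(f"constant covariate {col!r} dropped", stacklevel=2)
            df = df.drop(columns=col)
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="time", event_col="event",
                   fit_options={"precision": 1e-09})
    except (ConvergenceError, Exception) as exc:  # separation raises generic errors too
        warnings.warn(f"Cox fit failed: {exc}", stacklevel=2)
        return None
    summary = fitter.summary
    results = []
    for term, row in summary.iterrows():
        results.append(
            CoxResult(
                term=str(term),
                hr=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p=float(row["p"]),
                n=int(len(df)),
            )
        )
    return results


def cox_status_contrast(
    status: pd.Series,
    surv: pd.DataFrame,
    focal_category: str,
    adjusters: pd.DataFrame | None = None,
    contrast: str = "restrict",
) -> list[CoxResult] | None:
    """Hazard of one status category against "No change".

    ``contrast='restrict'`` (default) keeps only samples in the focal
    category or NO_CHANGE and fits a single indicator;
    ``contrast='dummy'`` keeps all samples and dummy-codes every
    non-reference category against NO_CHANGE.
    """
    status = status.dropna()
    if contrast == "restrict":
        keep = status.isin([focal_category, NO_CHANGE])
        focal = (status[keep] == focal_category).astype(int).rename(f"{focal_category}")
        return cox_fit(surv, focal, adjusters=adjusters)
    if contrast == "dummy":
        dummies = pd.get_dummies(status).drop(columns=NO_CHANGE, errors="ignore").astype(int)
        if focal_category not in dummies.columns:
            raise ValueError(f"status never takes category {focal_category!r}")
        focal = dummies[focal_category]
        others = dummies.drop(columns=focal_category)
        adj = others if adjusters is None else others.join(adjusters, how="inner")
        return cox_fit(surv, focal, adjusters=adj)
    raise ValueError(f"unknown contrast {contrast!r}")


def kaplan_scan(
    expression: pd.Series, surv: pd.DataFrame, min_group: int = 8, gene: str = ""
) -> KaplanScanResult | None:
    """Exhaustive expression-cutoff scan minimising the two-group log-rank p.

    Every distinct expression value is tried as the lower bound of the
    "high" group; cutoffs leaving fewer than ``min_group`` samples on either
    side are not tested.  The best cutoff is returned with its raw p and the
    Bonferroni-corrected p (raw p times the number of cutoffs actually
    tested, capped at 1).  Absent when no cutoff is admissible.
    """
    df = pd.concat({"expr": expression}, axis=1).join(surv[["time", "event"]], how="inner")
    df = df.dropna()
    values = np.sort(df["expr"].unique())
    best: tuple[float, float] | None = None  # (p, cutoff)
    n_tested = 0
    for cutoff in values[1:]:  # the smallest value leaves an empty low group
        low = df["expr"] < cutoff
        n_low, n_high = int(low.sum()), int((~low).sum())
        if n_low < min_group or n_high < min_group:
            continue
        res = logrank_test(
            df.loc[low, "time"], df.loc[~low, "time"],
            df.loc[low, "event"], df.loc[~low, "event"],
        )
        n_tested += 1
        p = float(res.p_value)
        if best is None or p < best[0]:
            best = (p, float(cutoff))
    if best is None:
        warnings.warn(f"{gene}: no cutoff satisfies min_group={min_group}", stacklevel=2)
        return None
    p_raw, cutoff = best
    low = df["expr"] < cutoff
    return KaplanScanResult(
        gene=gene,
        cutoff=cutoff,
        n_cutoffs_tested=n_tested,
        p_raw=p_raw,
        p_bonferroni=min(1.0, p_raw * n_tested),
        n_low=int(low.sum()),
        n_high=int((~low).sum()),
    )


def stratified_km_low_risk(
    status: pd.Series,
    surv: pd.DataFrame,
    clinical: pd.DataFrame,
    dmr_name: str = "",
    mycn_negative: str = "not amplified",
    strata: tuple[str, ...] = ("11q normal", "11q deleted"),
) -> dict[str, LogRankResult]:
    """Status-group log-rank tests within the MYCN-non-amplified stratum.

    Restricts to samples whose ``mycn`` label equals ``mycn_negative`` and
    runs a per-stratum log-rank across status groups for each requested
    ``chr11`` stratum.  Empty or degenerate strata are skipped with a
    warning.
    """
    for col in ("mycn", "chr11"):
        if col not in clinical.columns:
            raise KeyError(f"clinical table lacks column {col!r}")
    low_risk = clinical.index[clinical["mycn"] == mycn_negative]
    results: dict[str, LogRankResult] = {}
    for stratum in strata:
        ids = clinical.index[
            (clinical["mycn"] == mycn_negative) & (clinical["chr11"] == stratum)
        ]
        ids = ids.intersection(status.dropna().index)
        if len(ids) == 0:
            warnings.warn(f"{dmr_name}: empty stratum {stratum!r}, skipped", stacklevel=2)
            continue
        res = km_logrank(status.loc[ids], surv, dmr_name=f"{dmr_name}|{stratum}")
        if res is not None:
            results[stratum] = res[0]
    return results
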