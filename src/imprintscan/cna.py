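"""Allele-specific copy-number ingestion and CNA-predicted methylation.

Allele-specific segment profiles (``nMajor``/``nMinor`` per genomic
interval, as produced by allele-specific CNA callers) are resolved to one
copy state per (sample, DMR).  From the copy state a methylation value is
predicted under the assumption that, absent epimutation, the beta-value is
the fraction of allele copies carrying the methylated parental haplotype:

* minor methylation value = nMinor / (nMajor + nMinor)
* if the majority of the region's observed probe betas are <= 0.5, the
  minor allele is taken as the methylated one and the prediction equals the
  minor methylation value; otherwise the major allele is methylated and the
  prediction is 1 - minor methylation value.

Per region, observed methylation is regressed on the prediction by OLS; a
high adjusted R^2 means the observed alterations are explained by copy
number, a near-zero (often negative) one marks a true epimutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .registry import ImprintedDMR

__all__ = [
    "AllelicSegment",
    "DMRCopyState",
    "PredictedMethylation",
    "RegressionResult",
    "SegmentError",
    "load_segments",
    "resolve_copy_state",
    "resolve_copy_states",
    "predict_methylation",
    "predict_cohort",
    "regress_observed_on_predicted",
    "regression_table",
]

SEGMENT_COLUMNS = ("sample", "chrom", "startpos", "endpos", "nMajor", "nMinor")


class SegmentError(ValueError):
    """Raised when a segment profile violates the allele-count convention."""


@dataclass(frozen=True)
class AllelicSegment:
    sample_id: str
    chrom: str
    start: int
    end: int
    n_major: int
    n_minor: int

    def __post_init__(self) -> None:
        if self.n_minor < 0 or self.n_major < 0:
            raise SegmentError(f"{self.sample_id}: negative allele count")
        if self.n_minor > self.n_major:
            raise SegmentError(
                f"{self.sample_id}: nMinor {self.n_minor} > nMajor {self.n_major}"
            )
        if self.start > self.end:
            raise SegmentError(f"{self.sample_id}: segment start > end")

    @property
    def total(self) -> int:
        return self.n_major + self.n_minor


@dataclass(frozen=True)
class DMRCopyState:
    sample_id: str
    dmr_name: str
    n_major: int
    n_minor: int
    coverage: float  # fraction of the DMR covered by the chosen segment

    @property
    def total(self) -> int:
        return self.n_major + self.n_minor


@dataclass(frozen=True)
class PredictedMethylation:
    sample_id: str
    dmr_name: str
    minor_meth_value: float
    observed_beta: float
    methylated_allele_side: str  # "minor" or "major"
    predicted: float


@dataclass(frozen=True)
class RegressionResult:
    dmr_name: str
    n: int
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p_value: float


def load_segments(path: str | Path) -> pd.DataFrame:
    """Load and validate an allele-specific segment TSV.

    Expects columns sample, chrom, startpos, endpos, nMajor, nMinor.  Rows
    violating nMajor >= nMinor >= 0 are rejected.  Segments are returned
    sorted by (sample, chrom, startpos).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    if df.empty and df.columns.size <= 1:
        warnings.warn(f"empty segment file: {path}", stacklevel=2)
        return pd.DataFrame(columns=list(SEGMENT_COLUMNS))
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SegmentError(f"segment file {path} is missing columns: {missing}")
    df = df[list(SEGMENT_COLUMNS)].copy()
    if df.empty:
        warnings.warn(f"empty segment file: {path}", stacklevel=2)
        return df
    for col in ("startpos", "endpos", "nMajor", "nMinor"):
        df[col] = df[col].astype(int)
    if (df["nMajor"] < 0).any() or (df["nMinor"] < 0).any():
        raise SegmentError("negative allele counts in segment file")
    bad = df["nMinor"] > df["nMajor"]
    if bad.any():
        rows = df.index[bad].tolist()
        raise SegmentError(f"nMinor > nMajor at rows {rows[:5]} (0-based, data order)")
    if (df["startpos"] > df["endpos"]).any():
        raise SegmentError("segment with startpos > endpos")
    return df.sort_values(["sample", "chrom", "startpos"]).reset_index(drop=True)


def resolve_copy_state(
    sample_segments: pd.DataFrame, dmr: ImprintedDMR
) -> DMRCopyState | None:
    """Copy state of one sample at one DMR, or ``None`` with no overlap.

    Among segments overlapping the DMR interval the one covering the
    largest fraction of the DMR wins; allele counts are not averaged.
    """
    if sample_segments.empty:
        return None
    seg = sample_segments[sample_segments["chrom"] == dmr.chrom]
    if seg.empty:
        return None
    ov_start = np.maximum(seg["startpos"].to_numpy(), dmr.start)
    ov_end = np.minimum(seg["endpos"].to_numpy(), dmr.end)
    ov_len = ov_end - ov_start + 1
    if (ov_len <= 0).all():
        return None
    cov = ov_len / dmr.length
    best = int(np.argmax(cov))
    row = seg.iloc[best]
    return DMRCopyState(
        sample_id=str(row["sample"]),
        dmr_name=dmr.name,
        n_major=int(row["nMajor"]),
        n_minor=int(row["nMinor"]),
        coverage=float(min(cov[best], 1.0)),
    )


def resolve_copy_states(
    segments: pd.DataFrame, catalog: Sequence[ImprintedDMR]
) -> pd.DataFrame:
    """Copy states for all (sample, DMR) pairs with an overlapping segment."""
    records = []
    for sample_id, seg in segments.groupby("sample"):
        for dmr in catalog:
            state = resolve_copy_state(seg, dmr)
            if state is not None:
                records.append(
                    (state.sample_id, state.dmr_name, state.n_major, state.n_minor, state.coverage)
                )
    return pd.DataFrame(
        records, columns=["sample_id", "dmr_name", "nMajor", "nMinor", "coverage"]
    )


def predict_methylation(
    state: DMRCopyState, observed_betas: Sequence[float], summary: str = "median"
) -> PredictedMethylation | None:
    """CNA-predicted methylation for one (sample, DMR).

    The minor allele is assigned as the methylated allele when the fraction
    of observed probe betas <= 0.5 is at least one half; the prediction is
    then the minor methylation value nMinor/(nMajor+nMinor), else its
    complement.  ``observed_beta`` records the per-region summary (median by
    default, configurable to mean) used downstream as the regression outcome.
    Homozygous deletions (total copy number 0) yield no prediction.
    """
    betas = np.asarray([b for b in observed_betas if not np.isnan(b)], dtype=float)
    if betas.size == 0:
        raise ValueError(f"{state.sample_id}/{state.dmr_name}: no observed betas")
    if state.total == 0:
        warnings.warn(
            f"{state.sample_id}/{state.dmr_name}: homozygous deletion, no prediction",
            stacklevel=2,
        )
        return None
    minor_meth = state.n_minor / state.total
    side = "minor" if np.mean(betas <= 0.5) >= 0.5 else "major"
    predicted = minor_meth if side == "minor" else 1.0 - minor_meth
    observed = float(np.median(betas)) if summary == "median" else float(np.mean(betas))
    return PredictedMethylation(
        sample_id=state.sample_id,
        dmr_name=state.dmr_name,
        minor_meth_value=minor_meth,
        observed_beta=observed,
        methylated_allele_side=side,
        predicted=predicted,
    )


def predict_cohort(
    copy_states: pd.DataFrame,
    betas: pd.DataFrame,
    probe_map: pd.DataFrame,
    summary: str = "median",
) -> pd.DataFrame:
    """Predictions for every (sample, DMR) pair with a copy state and betas.

    Returns a long DataFrame (sample_id, dmr_name, minor_meth_value,
    observed_beta, methylated_allele_side, predicted).
    """
    probes_by_dmr = (
        probe_map.dropna(subset=["dmr_name"]).groupby("dmr_name")["probe_id"].agg(list)
    )
    rows = []
    for rec in copy_states.itertuples(index=False):
        if rec.dmr_name not in probes_by_dmr.index:
            continue
        probes = [p for p in probes_by_dmr[rec.dmr_name] if p in betas.index]
        if not probes or rec.sample_id not in betas.columns:
            continue
        obs = betas.loc[probes, rec.sample_id].dropna()
        if obs.empty:
            continue
        state = DMRCopyState(
            rec.sample_id, rec.dmr_name, int(rec.nMajor), int(rec.nMinor), float(rec.coverage)
        )
        pred = predict_methylation(state, obs.to_numpy(), summary=summary)
        if pred is not None:
            rows.append(
                (
                    pred.sample_id,
                    pred.dmr_name,
                    pred.minor_meth_value,
                    pred.observed_beta,
                    pred.methylated_allele_side,
                    pred.predicted,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "dmr_name",
            "minor_meth_value",
            "observed_beta",
            "methylated_allele_side",
            "predicted",
        ],
    )


def regress_observed_on_predicted(
    pairs: pd.DataFrame, dmr_name: str = ""
) -> RegressionResult | None:
    """OLS of observed region beta on CNA-predicted methylation for one DMR.

    ``pairs`` needs columns observed_beta and predicted.  Requires n >= 3 and
    a non-constant predictor; otherwise returns ``None`` with a warning.
    The adjusted R^2 uses the single-predictor formula
    ``1 - (1 - r2) * (n - 1) / (n - 2)`` and may be negative.
    """
    obs = pairs["observed_beta"].to_numpy(dtype=float)
    pred = pairs["predicted"].to_numpy(dtype=float)
    n = len(obs)
    if n < 3:
        warnings.warn(f"{dmr_name}: n={n} < 3, regression skipped", stacklevel=2)
        return None
    if np.allclose(pred, pred[0]):
        warnings.warn(f"{dmr_name}: constant predictor, regression skipped", stacklevel=2)
        return None
    fit = sps.linregress(pred, obs)
    r2 = float(fit.rvalue**2)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        dmr_name=dmr_name,
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        adj_r2=float(adj_r2),
        p_value=float(fit.pvalue),
    )


def regression_table(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-DMR regression summary sorted by adjusted R^2, descending.

    Returns a DataFrame (dmr_name, n, adj_r2, r2, slope, intercept, p_value)
    with one row per DMR that admitted a regression.
    """
    rows = []
    for dmr_name, grp in predictions.groupby("dmr_name"):
        res = regress_observed_on_predicted(grp, dmr_name=str(dmr_name))
        if res is not None:
            rows.append(
                (res.dmr_name, res.n, res.adj_r2, res.r2, res.slope, res.intercept, res.p_value)
            )
    out = pd.DataFrame(
        rows, columns=["dmr_name", "n", "adj_r2", "r2", "slope", "intercept", "p_value"]
    )
    return out.sort_values("adj_r2", ascending=False).reset_index(drop=True)
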