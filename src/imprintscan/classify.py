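"""Probe- and region-level imprinting-status calling and cohort summaries.

An imprinted DMR in a biparental sample is methylated on exactly one allele,
so its array beta-value sits near 0.5.  Each (sample, probe) beta is assigned
one of five states:

* ``GOM``  — beta strictly above the gain threshold (default 0.8)
* ``LOM``  — beta strictly below the loss threshold (default 0.2)
* ``INT_LOM`` / ``INT_GOM`` — beta outside the control mean +/- k*SD band
  (default k = 2) but not past the strong thresholds
* ``NO_CHANGE`` — everything else

Strong calls take precedence over intermediate calls, and all comparisons
are strict.  Region calls take the state backed by strictly more than a
majority fraction (default 60%) of the region's usable probes; otherwise the
region is ``NO_CHANGE`` with ``ambiguous=True``.  A cohort-level "most
altered" region is one whose strong GOM or strong LOM proportion strictly
exceeds the altered fraction (default 30%) — in every cohort supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GOM",
    "LOM",
    "INT_GOM",
    "INT_LOM",
    "NO_CHANGE",
    "LABELS",
    "REPORT_LABELS",
    "ControlReference",
    "build_control_reference",
    "classify_probe",
    "classify_probes",
    "aggregate_region",
    "aggregate_regions",
    "summarize_cohort",
    "altered_dmr_burden",
]

GOM = "GOM"
LOM = "LOM"
INT_GOM = "INT_GOM"
INT_LOM = "INT_LOM"
NO_CHANGE = "NO_CHANGE"
LABELS = (GOM, LOM, INT_GOM, INT_LOM, NO_CHANGE)

#: Spelling used in written reports.
REPORT_LABELS = {
    GOM: "GOM",
    LOM: "LOM",
    INT_GOM: "Intermediate GOM",
    INT_LOM: "Intermediate LOM",
    NO_CHANGE: "No change",
}

STRONG = (GOM, LOM)


@dataclass(frozen=True)
class ControlReference:
    """Per-probe control-group summary used for the intermediate bands."""

    probe_id: str
    mean: float
    sd: float
    n_controls: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError(f"{self.probe_id}: control mean {self.mean} outside [0, 1]")
        if self.sd < 0:
            raise ValueError(f"{self.probe_id}: negative control sd")
        if self.n_controls < 2:
            raise ValueError(f"{self.probe_id}: need >= 2 controls, got {self.n_controls}")


def build_control_reference(betas: pd.DataFrame, control_ids: Sequence[str]) -> pd.DataFrame:
    """Per-probe mean/SD over the control columns of a beta matrix.

    Returns a DataFrame indexed by probe_id with columns mean, sd, n_controls.
    SD uses ddof=1; at least two control samples are required.
    """
    missing = [s for s in control_ids if s not in betas.columns]
    if missing:
        raise KeyError(f"control samples absent from beta matrix: {missing}")
    if len(control_ids) < 2:
        raise ValueError(f"need >= 2 control samples, got {len(control_ids)}")
    ctrl = betas[list(control_ids)]
    out = pd.DataFrame(
        {
            "mean": ctrl.mean(axis=1),
            "sd": ctrl.std(axis=1, ddof=1),
            "n_controls": ctrl.notna().sum(axis=1),
        }
    )
    out.index.name = "probe_id"
    return out


def classify_probe(
    beta: float,
    ctrl: ControlReference,
    gom_threshold: float = 0.8,
    lom_threshold: float = 0.2,
    k_sd: float = 2.0,
) -> str | None:
    """Five-state call for a single beta; ``None`` when the beta is missing.

    Evaluation order: GOM, LOM, then the intermediate bands, then NO_CHANGE.
    All comparisons are strict, so beta == 0.8 is not GOM.
    """
    if beta is None or (isinstance(beta, float) and np.isnan(beta)):
        return None
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta {beta} outside [0, 1]")
    if beta > gom_threshold:
        return GOM
    if beta < lom_threshold:
        return LOM
    if beta < ctrl.mean - k_sd * ctrl.sd:
        return INT_LOM
    if beta > ctrl.mean + k_sd * ctrl.sd:
        return INT_GOM
    return NO_CHANGE


def classify_probes(
    betas: pd.DataFrame,
    probe_map: pd.DataFrame,
    controls: pd.DataFrame,
    gom_threshold: float = 0.8,
    lom_threshold: float = 0.2,
    k_sd: float = 2.0,
) -> pd.DataFrame:
    """Vectorised probe calls for every (sample, DMR-mapped probe) with data.

    Parameters
    ----------
    betas
        Beta matrix, probes x samples (tumour columns only).
    probe_map
        Output of :func:`imprintscan.registry.map_probes_to_dmrs` — must carry
        ``probe_id`` and ``dmr_name``.
    controls
        Per-probe reference (index probe_id; columns mean, sd, n_controls),
        e.g. from :func:`build_control_reference`.

    Returns a long DataFrame (sample_id, probe_id, dmr_name, beta, call).
    """
    bad = betas.stack()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("beta matrix contains values outside [0, 1]")
    if (controls["n_controls"] < 2).any():
        bad_probes = controls.index[controls["n_controls"] < 2].tolist()
        raise ValueError(f"fewer than 2 controls for probes: {bad_probes[:5]}")

    mapped = probe_map.dropna(subset=["dmr_name"])
    probe_ids = [p for p in mapped["probe_id"] if p in betas.index]
    long = (
        betas.loc[probe_ids]
        .rename_axis("probe_id")
        .reset_index()
        .melt(id_vars="probe_id", var_name="sample_id", value_name="beta")
        .dropna(subset=["beta"])
    )
    long = long.merge(mapped[["probe_id", "dmr_name"]], on="probe_id", how="left")

    no_ref = set(long["probe_id"]) - set(controls.index)
    if no_ref:
        raise KeyError(f"no control reference for probes: {sorted(no_ref)[:5]}")
    long = long.merge(
        controls[["mean", "sd"]], left_on="probe_id", right_index=True, how="left"
    )

    beta = long["beta"].to_numpy()
    mean = long["mean"].to_numpy()
    sd = long["sd"].to_numpy()
    long["call"] = np.select(
        [
            beta > gom_threshold,
            beta < lom_threshold,
            beta < mean - k_sd * sd,
            beta > mean + k_sd * sd,
        ],
        [GOM, LOM, INT_LOM, INT_GOM],
        default=NO_CHANGE,
    )
    return long[["sample_id", "probe_id", "dmr_name", "beta", "call"]]


def aggregate_region(
    calls: Iterable[str], majority: float = 0.60
) -> tuple[str, float, int, bool]:
    """Region call from one sample's probe calls at one DMR.

    Returns ``(call, support, n_probes_used, ambiguous)``.  The winning
    category must be backed by strictly more than ``majority`` of the usable
    probes; otherwise the call is ``NO_CHANGE`` with ``ambiguous=True`` and
    ``support`` set to the modal fraction.
    """
    calls = [c for c in calls if c is not None]
    n = len(calls)
    if n == 0:
        raise ValueError("no usable probe calls for region aggregation")
    counts = pd.Series(calls).value_counts()
    top_frac = counts.iloc[0] / n
    if top_frac > majority:
        return str(counts.index[0]), float(top_frac), n, False
    return NO_CHANGE, float(top_frac), n, True


def aggregate_regions(probe_calls: pd.DataFrame, majority: float = 0.60) -> pd.DataFrame:
    """Region calls for every (sample, DMR) with at least one usable probe.

    Returns a DataFrame (sample_id, dmr_name, call, support, n_probes_used,
    ambiguous).
    """
    counts = (
        probe_calls.groupby(["sample_id", "dmr_name", "call"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    n = counts.sum(axis=1)
    fracs = counts.div(n, axis=0)
    top_frac = fracs.max(axis=1)
    top_call = fracs.idxmax(axis=1)
    wins = top_frac > majority
    out = pd.DataFrame(
        {
            "call": np.where(wins, top_call, NO_CHANGE),
            "support": top_frac,
            "n_probes_used": n.astype(int),
            "ambiguous": ~wins,
        }
    ).reset_index()
    return out[["sample_id", "dmr_name", "call", "support", "n_probes_used", "ambiguous"]]


def summarize_cohort(
    region_calls: pd.DataFrame,
    altered_fraction: float = 0.30,
    validation_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-DMR category proportions and the "most altered" flag.

    Proportions are over samples with a region call at that DMR.  A region is
    most-altered when its strong GOM proportion or strong LOM proportion
    strictly exceeds ``altered_fraction``; intermediates do not count.  When
    ``validation_calls`` is given, the criterion (for the same event) must
    hold in both cohorts.
    """
    summary = _per_dmr_proportions(region_calls)
    gom_hit = summary[GOM] > altered_fraction
    lom_hit = summary[LOM] > altered_fraction
    if validation_calls is not None:
        val = _per_dmr_proportions(validation_calls).reindex(summary.index).fillna(0.0)
        gom_hit &= val[GOM] > altered_fraction
        lom_hit &= val[LOM] > altered_fraction
    summary["most_altered"] = gom_hit | lom_hit
    dominant = np.where(
        summary["most_altered"],
        np.where(summary[GOM] >= summary[LOM], GOM, LOM),
        "none",
    )
    # when only one event passes the threshold, report that event
    dominant = np.where(summary["most_altered"] & gom_hit & ~lom_hit, GOM, dominant)
    dominant = np.where(summary["most_altered"] & lom_hit & ~gom_hit, LOM, dominant)
    summary["dominant_event"] = dominant
    return summary.reset_index()


def _per_dmr_proportions(region_calls: pd.DataFrame) -> pd.DataFrame:
    counts = (
        region_calls.groupby(["dmr_name", "call"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(LABELS), fill_value=0)
    )
    n = counts.sum(axis=1)
    props = counts.div(n, axis=0)
    props["n_called"] = n.astype(int)
    return props


def altered_dmr_burden(region_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample counts of DMRs with strong GOM and strong LOM region calls.

    Intermediate and NO_CHANGE calls do not contribute.  Returns a DataFrame
    indexed by sample_id with columns n_gom, n_lom.
    """
    if region_calls.empty:
        raise ValueError("no region calls supplied")
    grouped = region_calls.groupby("sample_id")["call"]
    out = pd.DataFrame(
        {
            "n_gom": grouped.apply(lambda s: int((s == GOM).sum())),
            "n_lom": grouped.apply(lambda s: int((s == LOM).sum())),
        }
    )
    return out


def to_report_labels(df: pd.DataFrame, column: str = "call") -> pd.DataFrame:
    """Copy of *df* with internal labels replaced by report spellings."""
    out = df.copy()
    out[column] = out[column].map(REPORT_LABELS).fillna(out[column])
    return out
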