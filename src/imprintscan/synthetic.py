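"""Synthetic methylation cohorts with recorded ground truth.

Generates everything the pipeline consumes — a beta matrix (tumours plus
biparental controls), a probe manifest, whole-chromosome allele-specific
segments, a clinical table with survival outcomes, and UPD-like reference
samples — from a single seeded configuration, alongside truth tables that
record each sample's simulated status, allele counts and hazard.

Betas are drawn from a Beta(mean * s, (1 - mean) * s) distribution; the
precision ``s`` defaults to a value giving a control SD of about 0.03 at a
mean of 0.5.  Status-driven means sit at 0.5 (no change), 0.9 / 0.1 (strong
gain / loss) and three control SDs either side of 0.5 (intermediates).  For
CNA-driven regions the mean is instead the fraction of allele copies
carrying the methylated parental haplotype, so the betas track the sample's
copy state.  Survival times are exponential with hazard
``baseline * exp(linear predictor)`` and administrative censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify
from .registry import ImprintedDMR, load_dmr_catalog

__all__ = [
    "DMRSimSpec",
    "Enrichment",
    "CNAModel",
    "ClinicalModel",
    "SurvivalModel",
    "SimulationConfig",
    "CohortBundle",
    "generate_cohort",
    "generate_upd_references",
    "write_bundle",
    "demo_config",
]

EVENT_STATES = (classify.GOM, classify.LOM, classify.INT_GOM, classify.INT_LOM)


@dataclass(frozen=True)
class DMRSimSpec:
    """Per-DMR event prevalences and the beta-generation mode.

    ``prevalences`` maps status labels (GOM, LOM, INT_GOM, INT_LOM) to
    probabilities; the remainder is "No change".  When ``cna_driven`` is
    true the betas ignore the epigenetic status and follow the sample's
    allele counts instead.
    """

    prevalences: Mapping[str, float] = field(default_factory=dict)
    cna_driven: bool = False

    def __post_init__(self) -> None:
        bad = set(self.prevalences) - set(EVENT_STATES)
        if bad:
            raise ValueError(f"unknown status in prevalences: {sorted(bad)}")
        total = sum(self.prevalences.values())
        if any(v < 0 for v in self.prevalences.values()) or total > 1 + 1e-9:
            raise ValueError(f"prevalences must be nonnegative and sum to <= 1 (got {total})")


@dataclass(frozen=True)
class Enrichment:
    """Log-odds shift of a binary clinical factor given a status at a DMR."""

    dmr_name: str
    status: str
    factor: str  # "mycn", "age_group" or "chr11"
    log_odds: float


@dataclass(frozen=True)
class CNAModel:
    """Distribution of whole-chromosome allele-count states.

    ``state_probs`` maps a chromosome label (or ``"*"`` for the default) to
    a sequence of ((nMajor, nMinor), probability) pairs.
    """

    state_probs: Mapping[str, Sequence[tuple[tuple[int, int], float]]] = field(
        default_factory=lambda: {"*": (((1, 1), 1.0),)}
    )

    def states_for(self, chrom: str) -> Sequence[tuple[tuple[int, int], float]]:
        states = self.state_probs.get(chrom, self.state_probs.get("*"))
        if states is None:
            return (((1, 1), 1.0),)
        probs = [p for _, p in states]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"CNA state probabilities for {chrom} must sum to 1")
        for (n_major, n_minor), _ in states:
            if n_minor > n_major or n_minor < 0:
                raise ValueError("CNA states must satisfy nMajor >= nMinor >= 0")
        return states


@dataclass(frozen=True)
class ClinicalModel:
    p_mycn: float = 0.25
    p_11q_del: float = 0.30
    p_age_ge_15: float = 0.60
    stage_probs: Mapping[str, float] = field(
        default_factory=lambda: {"1": 0.08, "2": 0.05, "3": 0.08, "4": 0.66, "4s": 0.13}
    )
    enrichment: Sequence[Enrichment] = ()


@dataclass(frozen=True)
class SurvivalModel:
    baseline_hazard: float = 0.05
    censor_time: float = 10.0
    #: dmr name -> status -> log hazard ratio
    status_log_hr: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    mycn_log_hr: float = 0.0
    age_log_hr: float = 0.0
    chr11_log_hr: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_tumours: int = 300
    n_controls: int = 11
    catalog: tuple[ImprintedDMR, ...] | None = None  # None -> packaged catalog
    probes_per_dmr: int = 5
    dmr_specs: Mapping[str, DMRSimSpec] = field(default_factory=dict)
    beta_precision: float = 277.0
    cna: CNAModel = field(default_factory=CNAModel)
    clinical: ClinicalModel = field(default_factory=ClinicalModel)
    survival: SurvivalModel = field(default_factory=SurvivalModel)

    @property
    def control_sd(self) -> float:
        """Approximate control-group beta SD implied by the precision."""
        return math.sqrt(0.25 / (1.0 + self.beta_precision))

    def status_centre(self, status: str) -> float:
        offsets = {
            classify.NO_CHANGE: 0.5,
            classify.GOM: 0.9,
            classify.LOM: 0.1,
            classify.INT_GOM: 0.5 + 3.0 * self.control_sd,
            classify.INT_LOM: 0.5 - 3.0 * self.control_sd,
        }
        return offsets[status]


@dataclass
class CohortBundle:
    """In-memory simulated cohort plus its ground truth."""

    config: SimulationConfig
    betas: pd.DataFrame  # probes x (tumours + controls)
    manifest: pd.DataFrame  # probe_id, chrom, pos
    segments: pd.DataFrame  # sample, chrom, startpos, endpos, nMajor, nMinor
    clinical: pd.DataFrame  # indexed by sample_id
    truth_region: pd.DataFrame  # sample_id, dmr_name, status, nMajor, nMinor, n_meth
    truth_sample: pd.DataFrame  # sample_id, linear_predictor
    control_ids: list[str]
    tumour_ids: list[str]


def _resolve_catalog(config: SimulationConfig) -> list[ImprintedDMR]:
    if config.catalog is not None:
        return list(config.catalog)
    return load_dmr_catalog()


def _make_manifest(catalog: Sequence[ImprintedDMR], probes_per_dmr: int) -> pd.DataFrame:
    rows = []
    idx = 0
    for dmr in catalog:
        n = min(probes_per_dmr, dmr.length)
        positions = np.linspace(dmr.start, dmr.end, num=n).round().astype(int)
        positions = np.unique(positions)
        for pos in positions:
            rows.append((f"cg{idx:08d}", dmr.chrom, int(pos), dmr.name))
            idx += 1
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "dmr_name"])


def _draw_betas(rng: np.random.Generator, centres: np.ndarray, precision: float, n_probes: int) -> np.ndarray:
    """(n_probes, n_samples) beta draws around per-sample centres, clipped to [0,1]."""
    c = np.clip(centres, 0.01, 0.99)
    a = c * precision
    b = (1.0 - c) * precision
    draws = rng.beta(a[None, :], b[None, :], size=(n_probes, c.size))
    return np.clip(draws, 0.0, 1.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a full cohort bundle; one seed yields one bundle, always.

    The generation order is fixed (manifest, statuses, copy states, betas,
    clinical, survival), so the same configuration reproduces byte-identical
    files via :func:`write_bundle`.
    """
    catalog = _resolve_catalog(config)
    for name in config.dmr_specs:
        if name not in {d.name for d in catalog}:
            raise ValueError(f"dmr_specs references unknown DMR {name!r}")
    rng = np.random.default_rng(config.seed)
    manifest = _make_manifest(catalog, config.probes_per_dmr)

    tumour_ids = [f"T{i:04d}" for i in range(1, config.n_tumours + 1)]
    control_ids = [f"C{i:03d}" for i in range(1, config.n_controls + 1)]
    n = config.n_tumours

    # --- epigenetic truth -------------------------------------------------
    status: dict[str, np.ndarray] = {}
    for dmr in catalog:
        spec = config.dmr_specs.get(dmr.name, DMRSimSpec())
        states = list(spec.prevalences.keys())
        probs = [spec.prevalences[s] for s in states]
        states.append(classify.NO_CHANGE)
        probs.append(max(0.0, 1.0 - sum(probs)))
        status[dmr.name] = rng.choice(states, size=n, p=np.asarray(probs) / sum(probs))

    # --- allele-specific copy states (one segment per chromosome) ---------
    chroms = sorted({d.chrom for d in catalog}, key=lambda c: (len(c), c))
    chrom_end = {c: max(d.end for d in catalog if d.chrom == c) + 1_000_000 for c in chroms}
    seg_rows = []
    chrom_state: dict[str, np.ndarray] = {}
    meth_is_major: dict[str, np.ndarray] = {}
    for chrom in chroms:
        states = config.cna.states_for(chrom)
        idx = rng.choice(len(states), size=n, p=[p for _, p in states])
        chrom_state[chrom] = idx
        # parental origin of the methylated haplotype is random per sample
        meth_is_major[chrom] = rng.random(n) < 0.5
        for i, sample in enumerate(tumour_ids):
            (n_major, n_minor), _ = states[idx[i]]
            seg_rows.append((sample, chrom, 1, chrom_end[chrom], n_major, n_minor))
    segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "startpos", "endpos", "nMajor", "nMinor"]
    ).sort_values(["sample", "chrom", "startpos"]).reset_index(drop=True)

    # --- betas ------------------------------------------------------------
    beta_blocks = []
    probe_index = []
    truth_rows = []
    for dmr in catalog:
        spec = config.dmr_specs.get(dmr.name, DMRSimSpec())
        states = config.cna.states_for(dmr.chrom)
        counts = np.array([states[i][0] for i in chrom_state[dmr.chrom]])  # (n, 2)
        n_major, n_minor = counts[:, 0], counts[:, 1]
        total = n_major + n_minor
        n_meth = np.where(meth_is_major[dmr.chrom], n_major, n_minor)
        if spec.cna_driven:
            with np.errstate(invalid="ignore", divide="ignore"):
                centres = np.where(total > 0, n_meth / np.maximum(total, 1), 0.5)
        else:
            centres = np.array([config.status_centre(s) for s in status[dmr.name]])
        probes = manifest[manifest["dmr_name"] == dmr.name]
        tumour_block = _draw_betas(rng, centres, config.beta_precision, len(probes))
        ctrl_block = _draw_betas(
            rng, np.full(config.n_controls, 0.5), config.beta_precision, len(probes)
        )
        beta_blocks.append(np.hstack([tumour_block, ctrl_block]))
        probe_index.extend(probes["probe_id"].tolist())
        for i, sample in enumerate(tumour_ids):
            truth_rows.append(
                (sample, dmr.name, status[dmr.name][i], int(n_major[i]), int(n_minor[i]), int(n_meth[i]))
            )
    betas = pd.DataFrame(
        np.vstack(beta_blocks), index=probe_index, columns=tumour_ids + control_ids
    )
    betas.index.name = "probe_id"
    truth_region = pd.DataFrame(
        truth_rows, columns=["sample_id", "dmr_name", "status", "nMajor", "nMinor", "n_meth"]
    )

    # --- clinical covariates ---------------------------------------------
    cm = config.clinical
    status_df = truth_region.pivot(index="sample_id", columns="dmr_name", values="status")
    status_df = status_df.loc[tumour_ids]

    def factor_probs(base_p: float, factor: str) -> np.ndarray:
        logit = math.log(base_p / (1.0 - base_p))
        shift = np.zeros(n)
        for enr in cm.enrichment:
            if enr.factor != factor:
                continue
            hit = (status_df[enr.dmr_name] == enr.status).to_numpy()
            shift += enr.log_odds * hit
        return _sigmoid(logit + shift)

    mycn = rng.random(n) < factor_probs(cm.p_mycn, "mycn")
    chr11_del = rng.random(n) < factor_probs(cm.p_11q_del, "chr11")
    age_ge = rng.random(n) < factor_probs(cm.p_age_ge_15, "age_group")
    stages = list(cm.stage_probs)
    stage = rng.choice(stages, size=n, p=[cm.stage_probs[s] for s in stages])

    clinical = pd.DataFrame(
        {
            "age_group": np.where(age_ge, ">=1.5", "<1.5"),
            "stage": stage,
            "mycn": np.where(mycn, "amplified", "not amplified"),
            "chr11": np.where(chr11_del, "11q deleted", "11q normal"),
        },
        index=pd.Index(tumour_ids, name="sample_id"),
    )

    # --- survival ---------------------------------------------------------
    sm = config.survival
    lp = np.zeros(n)
    for dmr_name, effects in sm.status_log_hr.items():
        col = status_df[dmr_name].to_numpy()
        for st, log_hr in effects.items():
            lp += log_hr * (col == st)
    lp += sm.mycn_log_hr * mycn + sm.age_log_hr * age_ge + sm.chr11_log_hr * chr11_del
    rate = sm.baseline_hazard * np.exp(lp)
    raw_t = rng.exponential(1.0 / rate)
    event = raw_t <= sm.censor_time
    clinical["os_time_years"] = np.minimum(raw_t, sm.censor_time)
    clinical["os_event"] = event.astype(int)
    truth_sample = pd.DataFrame(
        {"sample_id": tumour_ids, "linear_predictor": lp}
    ).set_index("sample_id")

    return CohortBundle(
        config=config,
        betas=betas,
        manifest=manifest[["probe_id", "chrom", "pos"]].copy(),
        segments=segments,
        clinical=clinical,
        truth_region=truth_region,
        truth_sample=truth_sample,
        control_ids=control_ids,
        tumour_ids=tumour_ids,
    )


def generate_upd_references(
    config: SimulationConfig, n_mupd: int = 1, n_pupd: int = 2
) -> pd.DataFrame:
    """Beta matrix for uniparental-diploidy-like reference samples.

    A maternal-UPD sample carries two maternal haplotypes, so DMRs
    methylated on the maternal allele sit near beta 0.97 and paternally
    methylated DMRs near 0.03; paternal UPD is the mirror image.
    """
    catalog = _resolve_catalog(config)
    rng = np.random.default_rng(config.seed + 1)
    manifest = _make_manifest(catalog, config.probes_per_dmr)
    samples = [f"mUPD{i}" for i in range(1, n_mupd + 1)] + [
        f"pUPD{i}" for i in range(1, n_pupd + 1)
    ]
    is_maternal = [True] * n_mupd + [False] * n_pupd
    blocks, probe_index = [], []
    for dmr in catalog:
        centres = np.array(
            [
                0.97 if (m == (dmr.methylated_allele == "M")) else 0.03
                for m in is_maternal
            ]
        )
        probes = manifest[manifest["dmr_name"] == dmr.name]
        blocks.append(_draw_betas(rng, centres, config.beta_precision, len(probes)))
        probe_index.extend(probes["probe_id"].tolist())
    out = pd.DataFrame(np.vstack(blocks), index=probe_index, columns=samples)
    out.index.name = "probe_id"
    return out


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> dict[str, Path]:
    """Serialise a bundle to TSV files; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "betas": outdir / "betas.tsv",
        "manifest": outdir / "manifest.tsv",
        "segments": outdir / "segments.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth_region": outdir / "truth_region.tsv",
        "truth_sample": outdir / "truth_sample.tsv",
        "controls": outdir / "controls.txt",
    }
    bundle.betas.to_csv(paths["betas"], sep="\t", float_format="%.6f")
    bundle.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    bundle.segments.to_csv(paths["segments"], sep="\t", index=False)
    bundle.clinical.to_csv(paths["clinical"], sep="\t", float_format="%.6f")
    bundle.truth_region.to_csv(paths["truth_region"], sep="\t", index=False)
    bundle.truth_sample.to_csv(paths["truth_sample"], sep="\t", float_format="%.6f")
    paths["controls"].write_text("\n".join(bundle.control_ids) + "\n")
    return paths


def demo_config(seed: int = 0, n_tumours: int = 300) -> SimulationConfig:
    """A 300-tumour preset with a handful of strongly altered regions.

    Prevalences loosely follow commonly reported alteration rates at a few
    well-known regions, a survival effect is attached to the two most
    prognostic ones, and MYCN amplification is enriched among samples with
    gains at the NNAT region.
    """
    specs = {
        "NDN:TSS-DMR": DMRSimSpec({classify.LOM: 0.50, classify.INT_LOM: 0.26}),
        "SNRPN:Int1-DMR2": DMRSimSpec({classify.LOM: 0.50}),
        "MAGEL2:TSS-DMR": DMRSimSpec({classify.LOM: 0.37, classify.INT_LOM: 0.28}),
        "HTR5A:TSS-DMR": DMRSimSpec({classify.LOM: 0.34, classify.INT_LOM: 0.21}),
        "IGF2:Ex9-DMR": DMRSimSpec({classify.LOM: 0.41}),
        "NNAT:TSS-DMR": DMRSimSpec({classify.GOM: 0.75}),
        "RB1:Int2-DMR": DMRSimSpec({classify.GOM: 0.46}),
        "GPR1-AS:TSS-DMR": DMRSimSpec({classify.GOM: 0.33}),
        # a CNA-driven counterpoint with strong copy-state variation
        "KCNQ1OT1:TSS-DMR": DMRSimSpec(cna_driven=True),
    }
    cna = CNAModel(
        state_probs={
            "*": (((1, 1), 0.70), ((2, 1), 0.20), ((2, 0), 0.05), ((2, 2), 0.05)),
            "chr11": (((1, 1), 0.40), ((2, 1), 0.25), ((2, 0), 0.15), ((3, 1), 0.20)),
        }
    )
    clinical = ClinicalModel(
        enrichment=(
            Enrichment("NNAT:TSS-DMR", classify.GOM, "mycn", 2.0),
            Enrichment("MAGEL2:TSS-DMR", classify.LOM, "age_group", 1.5),
        )
    )
    surv = SurvivalModel(
        status_log_hr={
            "NNAT:TSS-DMR": {classify.GOM: math.log(3.0)},
            "MAGEL2:TSS-DMR": {classify.LOM: math.log(2.6)},
        },
        mycn_log_hr=math.log(2.0),
        age_log_hr=math.log(1.5),
    )
    return SimulationConfig(
        seed=seed,
        n_tumours=n_tumours,
        dmr_specs=specs,
        cna=cna,
        clinical=clinical,
        survival=surv,
    )
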