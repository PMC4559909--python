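"""Synthetic prostate-cancer expression cohorts with planted structure.

Real cohorts of this kind mix normal prostate tissue, primary tumours and
metastases, sometimes with several metastases per patient and with
biochemical-recurrence (BCR) follow-up.  The generator plants the group-level
log2 fold-change structure the downstream analyses look for:

* tissue-contrast mean shifts per gene (an :class:`EffectTable`),
* per-patient random effects shared by all metastases from one patient,
* i.i.d. Gaussian log2 noise (microarray-like), and
* BCR outcomes whose hazard is log-linear in a lymphangiogenic risk score.

Every draw comes from a single ``numpy.random.Generator`` so a fixed seed
reproduces the cohort bit for bit.  Effect magnitudes are free parameters
(the real datasets report directions and q-values, not effect sizes); the
defaults are chosen once so planted effects are detectable at the group
sizes used here, and are documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import (
    ExpressionMatrix, GenePanel, TISSUE_METASTATIC, TISSUE_NORMAL,
    TISSUE_PRIMARY, default_vegf_sema_panel,
)

CONTRASTS = ("primary_vs_normal", "metastatic_vs_normal")

#: default signature whose high expression drives biochemical recurrence
DEFAULT_BCR_SIGNATURE = {"FIGF": 1.5, "NRP2": 1.5, "VEGFC": 1.5, "KDR": 1.5}


@dataclass
class EffectTable:
    """Planted per-gene mean shifts (log2) and noise scales.

    ``shifts`` is genes x contrasts; ``noise_sd`` is the within-group s.d.
    and ``patient_sd`` the s.d. of the per-patient random effect shared by
    metastases from one patient (both log2 units).
    """

    shifts: pd.DataFrame
    noise_sd: float = 0.5
    patient_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.patient_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not np.isfinite(self.shifts.to_numpy()).all():
            raise ValueError("shifts must be finite")
        missing = [c for c in CONTRASTS if c not in self.shifts.columns]
        if missing:
            raise ValueError(f"missing contrasts: {missing}")

    def shift(self, gene: str, contrast: str) -> float:
        return float(self.shifts.at[gene, contrast])

    def tissue_shift(self, gene: str, tissue: str) -> float:
        if tissue == TISSUE_NORMAL:
            return 0.0
        contrast = ("primary_vs_normal" if tissue == TISSUE_PRIMARY
                    else "metastatic_vs_normal")
        return self.shift(gene, contrast)


def default_effect_table(panel: GenePanel | None = None,
                         noise_sd: float = 0.5,
                         patient_sd: float = 0.8) -> EffectTable:
    """Planted effects mirroring the recurrent alterations in prostate cohorts.

    Primary vs normal: three of five VEGF ligands (VEGFA, VEGFB, VEGFC) and
    five of seven class-3 semaphorins (SEMA3A-E) down.  Metastatic vs normal:
    VEGFA up; SEMA3A-E down with SEMA3C repressed furthest; NRP1, PLXNA1 and
    PLXNA3 up; KDR and NRP2 down.  All other panel genes are null.
    """
    panel = panel or default_vegf_sema_panel()
    shifts = pd.DataFrame(0.0, index=list(panel.genes), columns=list(CONTRASTS))
    down_primary = ["VEGFA", "VEGFB", "VEGFC",
                    "SEMA3A", "SEMA3B", "SEMA3C", "SEMA3D", "SEMA3E"]
    shifts.loc[down_primary, "primary_vs_normal"] = -1.0
    shifts.at["VEGFA", "metastatic_vs_normal"] = 1.0
    for g in ("SEMA3A", "SEMA3B", "SEMA3D", "SEMA3E"):
        shifts.at[g, "metastatic_vs_normal"] = -1.25
    shifts.at["SEMA3C", "metastatic_vs_normal"] = -1.75
    for g in ("NRP1", "PLXNA1", "PLXNA3"):
        shifts.at[g, "metastatic_vs_normal"] = 1.0
    for g in ("KDR", "NRP2"):
        shifts.at[g, "metastatic_vs_normal"] = -1.0
    return EffectTable(shifts=shifts, noise_sd=noise_sd, patient_sd=patient_sd)


@dataclass
class BCRConfig:
    """Outcome-generation settings: exponential event times, uniform censoring."""

    signature: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BCR_SIGNATURE))
    baseline_hazard: float = 0.03      # events per year at score 0
    censoring_horizon_years: float = 10.0


@dataclass
class CohortConfig:
    """Sizes and structure of one synthetic cohort."""

    n_normals: int = 12
    n_primary: int = 49
    n_metastatic: int | None = None    # derived from patients when None
    n_patients: int = 5
    #: per-patient metastasis counts; a 2-tuple means "draw uniformly in range",
    #: a longer sequence fixes the counts exactly (one entry per patient)
    mets_per_patient: Sequence[int] = (4, 4, 4, 3, 3)
    baseline_log2: float = 8.0
    dataset_id: str = "synthetic"
    bcr: BCRConfig = field(default_factory=BCRConfig)

    def __post_init__(self) -> None:
        if min(self.n_normals, self.n_primary) < 0:
            raise ValueError("counts must be >= 0")

    def metastasis_counts(self, rng: np.random.Generator) -> list[int]:
        mp = list(self.mets_per_patient)
        if len(mp) == 2 and self.n_patients != 2:
            lo, hi = mp
            counts = [int(rng.integers(lo, hi + 1)) for _ in range(self.n_patients)]
        else:
            if len(mp) != self.n_patients:
                raise ValueError("mets_per_patient must match n_patients")
            counts = [int(c) for c in mp]
        if self.n_metastatic is not None and sum(counts) != self.n_metastatic:
            raise ValueError("n_metastatic inconsistent with per-patient counts")
        return counts

    @classmethod
    def gse35988_like(cls) -> "CohortConfig":
        """Benign/localized/metastatic sizes 12/49/27 as in the simulation cohort."""
        return cls(n_normals=12, n_primary=49, n_patients=9,
                   mets_per_patient=(3, 3, 3, 3, 3, 3, 3, 3, 3),
                   dataset_id="synthetic_gse35988_like")

    @classmethod
    def bcr_cohort(cls) -> "CohortConfig":
        """RNA-Seq-scale primary-tumour cohort for outcome modelling.

        Recurrence signatures need event counts in the dozens; this mirrors
        the larger primary cohorts with BCR follow-up rather than the small
        simulation cohort.
        """
        return cls(n_normals=50, n_primary=250, n_patients=0,
                   mets_per_patient=(), dataset_id="synthetic_bcr")

    @classmethod
    def multi_metastasis(cls) -> "CohortConfig":
        """21 normals and 18 metastases as 3-4 per patient from 5 patients."""
        return cls(n_normals=21, n_primary=0, n_patients=5,
                   mets_per_patient=(4, 4, 4, 3, 3),
                   dataset_id="synthetic_multimet")


@dataclass
class TruthRecord:
    """Planted signals, sufficient to score recovery of each of them."""

    shifts: pd.DataFrame                 # genes x contrasts
    patient_effects: pd.DataFrame        # patients x genes
    risk_scores: pd.Series               # per primary sample (empty until BCR attached)
    seed: int | None = None

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "shifts": {c: self.shifts[c].to_dict() for c in self.shifts.columns},
            "patient_effects": {p: self.patient_effects.loc[p].to_dict()
                                for p in self.patient_effects.index},
            "risk_scores": self.risk_scores.to_dict(),
        }


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_cohort(
    cfg: CohortConfig,
    eff: EffectTable | None = None,
    seed: int | np.random.Generator | None = 0,
) -> tuple[ExpressionMatrix, TruthRecord]:
    """Draw one cohort: x = baseline + tissue shift + patient effect + noise."""
    eff = eff or default_effect_table()
    rng = _as_rng(seed)
    genes = list(eff.shifts.index)
    met_counts = cfg.metastasis_counts(rng) if cfg.n_patients > 0 else []
    n_met = sum(met_counts)
    if cfg.n_normals + cfg.n_primary + n_met == 0:
        raise ValueError("cohort has zero samples")

    rows, meta_rows = [], []
    patients = [f"patient{i + 1}" for i in range(len(met_counts))]
    patient_effects = pd.DataFrame(
        rng.normal(0.0, eff.patient_sd, size=(len(patients), len(genes))),
        index=patients, columns=genes,
    )
    shift_by_tissue = {
        t: np.array([eff.tissue_shift(g, t) for g in genes])
        for t in (TISSUE_NORMAL, TISSUE_PRIMARY, TISSUE_METASTATIC)
    }

    def add_sample(sid: str, tissue: str, patient: str | None) -> None:
        x = cfg.baseline_log2 + shift_by_tissue[tissue].copy()
        if patient is not None:
            x = x + patient_effects.loc[patient].to_numpy()
        x = x + rng.normal(0.0, eff.noise_sd, size=len(genes))
        rows.append(x)
        meta_rows.append({"sample_id": sid, "dataset_id": cfg.dataset_id,
                          "tissue_type": tissue, "patient_id": patient,
                          "bcr_event": None, "bcr_time_years": None,
                          "gleason": None})

    for i in range(cfg.n_normals):
        add_sample(f"{cfg.dataset_id}_N{i + 1:03d}", TISSUE_NORMAL, None)
    for i in range(cfg.n_primary):
        add_sample(f"{cfg.dataset_id}_P{i + 1:03d}", TISSUE_PRIMARY, None)
    k = 0
    for patient, count in zip(patients, met_counts):
        for _ in range(count):
            k += 1
            add_sample(f"{cfg.dataset_id}_M{k:03d}", TISSUE_METASTATIC, patient)

    values = pd.DataFrame(rows, columns=genes,
                          index=[r["sample_id"] for r in meta_rows])
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    m = ExpressionMatrix(values=values, metadata=metadata)
    truth = TruthRecord(shifts=eff.shifts.copy(), patient_effects=patient_effects,
                        risk_scores=pd.Series(dtype=float))
    return m, truth


def attach_bcr_outcomes(
    m: ExpressionMatrix,
    cfg: CohortConfig,
    seed: int | np.random.Generator | None = 0,
    truth: TruthRecord | None = None,
) -> ExpressionMatrix:
    """Attach BCR event indicators and follow-up times to primary samples.

    A linear risk score over the configured signature genes (centered on the
    primary-group mean) sets an exponential event hazard
    ``h = h0 * exp(score)``; censoring times are uniform on the follow-up
    horizon, and the recorded time is the earlier of event and censoring.
    """
    rng = _as_rng(seed)
    bcr = cfg.bcr
    mask = m.tissue_mask(TISSUE_PRIMARY)
    if not mask.any():
        raise ValueError("no primary-tumor samples to attach outcomes to")
    missing = [g for g in bcr.signature if g not in m.values.columns]
    if missing:
        raise ValueError(f"signature genes absent: {missing}")

    prim = m.values.loc[mask]
    weights = pd.Series(bcr.signature, dtype=float)
    centered = prim[weights.index] - prim[weights.index].mean(axis=0)
    score = centered.mul(weights, axis=1).sum(axis=1)

    hazard = bcr.baseline_hazard * np.exp(score.to_numpy())
    horizon = bcr.censoring_horizon_years
    censor = rng.uniform(0.0, horizon, size=len(score)) if horizon > 0 else np.zeros(len(score))
    with np.errstate(divide="ignore"):
        event_time = np.where(hazard > 0, rng.exponential(1.0, len(score)) / np.maximum(hazard, 1e-300), np.inf)
    event = event_time <= censor
    time = np.minimum(event_time, censor)

    metadata = m.metadata.copy()
    metadata["bcr_event"] = pd.array([None] * len(metadata), dtype=object)
    metadata["bcr_time_years"] = np.nan
    metadata.loc[prim.index, "bcr_event"] = event
    metadata.loc[prim.index, "bcr_time_years"] = time
    if truth is not None:
        truth.risk_scores = score
    return ExpressionMatrix(values=m.values.copy(), metadata=metadata)


def simulate_multidataset(
    cfg: CohortConfig,
    eff: EffectTable | None = None,
    n_datasets: int = 4,
    seed: int | np.random.Generator | None = 0,
    baseline_spread_sd: float = 0.5,
) -> list[ExpressionMatrix]:
    """Independent cohorts sharing one effect table, dataset-specific baselines.

    Emulates the cross-dataset recurrence analysis: each dataset gets its own
    per-gene baseline offset (platform effect) but the same planted shifts.
    """
    if n_datasets < 2:
        raise ValueError("n_datasets must be >= 2")
    eff = eff or default_effect_table()
    rng = _as_rng(seed)
    out = []
    for d in range(n_datasets):
        offsets = rng.normal(0.0, baseline_spread_sd, size=len(eff.shifts.index))
        shifted = EffectTable(shifts=eff.shifts.copy(), noise_sd=eff.noise_sd,
                              patient_sd=eff.patient_sd)
        dcfg = CohortConfig(**{**asdict(cfg),
                               "bcr": cfg.bcr,
                               "dataset_id": f"{cfg.dataset_id}_ds{d + 1}"})
        m, _ = simulate_cohort(dcfg, shifted, rng)
        m.values.iloc[:] = m.values.to_numpy() + offsets[None, :]
        out.append(m)
    return out
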