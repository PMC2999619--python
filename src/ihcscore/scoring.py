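"""Composite scores: nuclear/cytoplasmic autoscores, their ratio (CNR),
duplicate-core aggregation, evaluability and dichotomisation.

An *autoscore* is ``100 x positive_fraction x mean_intensity`` with both
factors on [0, 1], so the score lives on [0, 100].  The cytoplasmic-to-nuclear
ratio (CNR) is the ratio of the two autoscores and is undefined when the
nuclear autoscore is zero; such records are treated as non-evaluable rather
than assigned an infinite ratio.

Duplicate cores from the same tumour are aggregated by taking the maximum of
each measure across evaluable replicates; the patient-level CNR is recomputed
from the aggregated autoscores (ratio of maxima, not maximum of ratios).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats as sps

#: Concordance measures reported per replicate pair.
CONCORDANCE_MEASURES = ("nuclear_pct", "nuclear_intensity", "cyt_pct", "cyt_intensity")


@dataclass(frozen=True)
class ThresholdConfig:
    """Dichotomisation cut points for the composite scores."""

    snas_threshold: float = 4.26
    cnr_threshold: float = 5.0
    prior_snas_threshold: float = 8.0

    def __post_init__(self) -> None:
        if min(self.snas_threshold, self.cnr_threshold, self.prior_snas_threshold) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class AutoscoreRecord:
    """Scores for one core (replicate) or one aggregated patient."""

    patient_id: str
    replicate: int  # 1 or 2; 0 after aggregation
    nuclear_autoscore: float
    cytoplasmic_autoscore: float
    evaluable: bool = True

    def __post_init__(self) -> None:
        if self.nuclear_autoscore < 0 or self.cytoplasmic_autoscore < 0:
            raise ValueError("autoscores must be >= 0")

    @property
    def cnr(self) -> float | None:
        return compute_cnr(self.cytoplasmic_autoscore, self.nuclear_autoscore)


def compute_autoscore(positive_fraction: float, mean_intensity: float) -> float:
    """Score on [0, 100]: 100 x positive fraction x normalised mean intensity."""
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValueError(f"positive_fraction out of [0, 1]: {positive_fraction}")
    if not (0.0 <= mean_intensity <= 1.0):
        raise ValueError(f"mean_intensity out of [0, 1]: {mean_intensity}")
    return 100.0 * positive_fraction * mean_intensity


def compute_cnr(cytoplasmic_autoscore: float, nuclear_autoscore: float) -> float | None:
    """Cytoplasmic / nuclear autoscore ratio; ``None`` when nuclear is zero."""
    if cytoplasmic_autoscore < 0 or nuclear_autoscore < 0:
        raise ValueError("autoscores must be >= 0")
    if nuclear_autoscore == 0:
        return None
    return cytoplasmic_autoscore / nuclear_autoscore


def aggregate_duplicates(records: Sequence[AutoscoreRecord]) -> AutoscoreRecord:
    """Patient-level record: per-measure maximum over evaluable replicates.

    A patient with no evaluable replicate is returned flagged non-evaluable
    (marker status unknown).
    """
    if not records:
        raise ValueError("no records supplied")
    pids = {r.patient_id for r in records}
    if len(pids) != 1:
        raise ValueError(f"records belong to multiple patients: {sorted(pids)}")
    usable = [r for r in records if r.evaluable]
    if not usable:
        return AutoscoreRecord(
            patient_id=records[0].patient_id,
            replicate=0,
            nuclear_autoscore=0.0,
            cytoplasmic_autoscore=0.0,
            evaluable=False,
        )
    return AutoscoreRecord(
        patient_id=usable[0].patient_id,
        replicate=0,
        nuclear_autoscore=max(r.nuclear_autoscore for r in usable),
        cytoplasmic_autoscore=max(r.cytoplasmic_autoscore for r in usable),
        evaluable=True,
    )


def aggregate_cohort(cores: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-core table (one row per replicate) to one row per patient.

    Expects columns ``patient_id``, ``replicate``, ``nuclear_autoscore``,
    ``cyt_autoscore`` and ``evaluable``.  Returns one row per patient with
    ``snas`` (the patient-level nuclear autoscore), ``cytoplasmic_autoscore``,
    ``cnr`` (NaN when undefined) and ``evaluable``.
    """
    rows = []
    for pid, grp in cores.groupby("patient_id", sort=False):
        recs = [
            AutoscoreRecord(
                patient_id=str(pid),
                replicate=int(r.replicate),
                nuclear_autoscore=float(r.nuclear_autoscore),
                cytoplasmic_autoscore=float(r.cyt_autoscore),
                evaluable=bool(r.evaluable),
            )
            for r in grp.itertuples()
        ]
        agg = aggregate_duplicates(recs)
        cnr = agg.cnr
        rows.append(
            {
                "patient_id": agg.patient_id,
                "snas": agg.nuclear_autoscore,
                "cytoplasmic_autoscore": agg.cytoplasmic_autoscore,
                "cnr": math.nan if cnr is None else cnr,
                "evaluable": agg.evaluable and cnr is not None,
            }
        )
    return pd.DataFrame(rows)


def duplicate_concordance(cores: pd.DataFrame, min_pairs: int = 10) -> pd.DataFrame:
    """Spearman's rho between replicate 1 and replicate 2, per raw measure.

    ``cores`` must contain ``patient_id``, ``replicate`` and the four measure
    columns in :data:`CONCORDANCE_MEASURES`.  Only patients with both
    replicates contribute; fewer than ``min_pairs`` such patients is an error.
    """
    wide = cores.pivot(index="patient_id", columns="replicate", values=list(CONCORDANCE_MEASURES))
    out = []
    for measure in CONCORDANCE_MEASURES:
        pair = wide[measure].dropna()
        if len(pair) < min_pairs:
            raise ValueError(
                f"only {len(pair)} complete replicate pairs for {measure}; need >= {min_pairs}"
            )
        rho, p = sps.spearmanr(pair[1], pair[2])
        out.append({"measure": measure, "rho": float(rho), "p": float(p), "n_pairs": len(pair)})
    return pd.DataFrame(out)


def dichotomize(score: float, threshold: float) -> str | None:
    """'high' iff score > threshold, 'low' iff score <= threshold.

    Undefined scores (None/NaN) yield ``None``: the record is excluded, not
    grouped.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return None
    return "high" if score > threshold else "low"


def assess_evaluability(quant, min_tumour_px: int = 2000) -> bool:
    """A core is evaluable when it holds enough tumour tissue and a nuclear
    compartment on which the nuclear autoscore can be computed."""
    return bool(
        quant.tumour_px >= min_tumour_px
        and quant.nuclear.total_px > 0
    )


def quant_to_record(patient_id: str, replicate: int, quant) -> dict:
    """Flatten a CompartmentQuant into one per-core CSV row (public contract)."""
    nuclear_pct = quant.nuclear.positive_fraction
    cyt_pct = quant.cytoplasmic.positive_fraction
    nuclear_intensity = quant.nuclear.intensity
    cyt_intensity = quant.cytoplasmic.intensity
    nuc_auto = compute_autoscore(nuclear_pct, nuclear_intensity)
    cyt_auto = compute_autoscore(cyt_pct, cyt_intensity)
    cnr = compute_cnr(cyt_auto, nuc_auto)
    return {
        "patient_id": patient_id,
        "replicate": replicate,
        "nuclear_pct": nuclear_pct,
        "nuclear_intensity": nuclear_intensity,
        "cyt_pct": cyt_pct,
        "cyt_intensity": cyt_intensity,
        "nuclear_autoscore": nuc_auto,
        "cyt_autoscore": cyt_auto,
        "cnr": math.nan if cnr is None else cnr,
        "evaluable": bool(quant.evaluable and cnr is not None),
        "tumour_px": quant.tumour_px,
    }
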