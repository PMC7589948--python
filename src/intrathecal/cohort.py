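"""Cohort data model, diagnosis grouping, CSV I/O and the study pipeline.

A cohort is a list of :class:`PatientRecord`: one patient's paired
serum/CSF laboratory values, IEF pattern and final diagnosis.  Eleven
diagnosis categories are recognised; the first five (MS, CIS, other
demyelinating, autoimmune/paraneoplastic, infectious) form the CNS
infectious/inflammatory disorder (CNSID) group, the rest the
non-inflammatory disease (NID) group.

:func:`run_study` is the end-to-end analysis: descriptive summaries,
kappa-index/OCB concordance with a per-diagnosis discordance breakdown,
diagnostic-accuracy tables for the MS and CNSID outcomes (fixed and
Youden-optimal cut-offs), and the single-CSF-IgG-band subcohort
reclassification analysis.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .diagnostics import (
    ConcordanceResult,
    ConfusionMetrics,
    ConfusionTable,
    CutoffResult,
    binary_marker,
    concordance,
    confusion_metrics,
    youden_optimal_cutoff,
)
from .ief import IEFPattern, ocb_or_single_band_positive, ocb_positive
from .quotients import (
    DEFAULT_DETECTION_LIMIT,
    HyperbolicCurveParams,
    KFLC_CURVES,
    PairedSpecimen,
    QuotientProfile,
    derive_profile,
    impute_censored_kflc,
)

__all__ = [
    "DiagnosisGroup",
    "PatientRecord",
    "StudyConfig",
    "StudyReport",
    "CohortLoadError",
    "is_cnsid",
    "load_cohort",
    "cohort_to_frame",
    "write_cohort",
    "derive_all",
    "marker_values",
    "run_study",
    "single_band_reclassification",
    "accuracy_table_from_counts",
]


class DiagnosisGroup(str, Enum):
    """Final-diagnosis categories; the first five constitute CNSID."""

    MS = "MS"
    CIS = "CIS"
    OTHER_DEMYELINATING = "other_demyelinating"
    AUTOIMMUNE_PARANEOPLASTIC = "autoimmune_paraneoplastic"
    INFECTIOUS = "infectious"
    EPILEPSY = "epilepsy"
    PNS = "PNS"
    NEOPLASM = "neoplasm"
    VASCULAR = "vascular"
    DEGENERATIVE = "degenerative"
    MISCELLANEOUS = "miscellaneous"

    @classmethod
    def parse(cls, token: str, *, strict: bool = True) -> "DiagnosisGroup":
        candidate = token if strict else token.strip()
        try:
            return cls(candidate)
        except ValueError:
            if not strict:
                lowered = {g.value.lower(): g for g in cls}
                if candidate.lower() in lowered:
                    return lowered[candidate.lower()]
            valid = ", ".join(g.value for g in cls)
            raise ValueError(
                f"unknown diagnosis token {token!r}; expected one of: {valid}"
            ) from None


_CNSID = frozenset(
    {
        DiagnosisGroup.MS,
        DiagnosisGroup.CIS,
        DiagnosisGroup.OTHER_DEMYELINATING,
        DiagnosisGroup.AUTOIMMUNE_PARANEOPLASTIC,
        DiagnosisGroup.INFECTIOUS,
    }
)


def is_cnsid(d: "DiagnosisGroup | str") -> bool:
    """True iff the diagnosis belongs to the CNS infectious/inflammatory group."""
    if not isinstance(d, DiagnosisGroup):
        d = DiagnosisGroup.parse(d)
    return d in _CNSID


@dataclass
class PatientRecord:
    """One patient: identifier, raw labs, IEF pattern, diagnosis, derived panel."""

    id: str
    specimen: PairedSpecimen
    pattern: IEFPattern
    diagnosis: DiagnosisGroup
    derived: Optional[QuotientProfile] = None


class CohortLoadError(ValueError):
    """Raised when a cohort CSV fails validation; carries row-level messages."""

    def __init__(self, problems: List[str]):
        self.problems = problems
        preview = "\n".join(problems[:20])
        more = f"\n... and {len(problems) - 20} more" if len(problems) > 20 else ""
        super().__init__(f"{len(problems)} invalid row(s):\n{preview}{more}")


#: CSV columns, in canonical order.
CSV_COLUMNS = [
    "patient_id",
    "serum_albumin",
    "csf_albumin",
    "serum_igg",
    "csf_igg",
    "serum_kflc",
    "csf_kflc",
    "ief_pattern",
    "diagnosis_group",
]

#: Default units per concentration column; "g_per_L" columns are scaled
#: x1000 to mg/L at ingestion.
DEFAULT_UNITS = {
    "serum_albumin": "mg_per_L",
    "csf_albumin": "mg_per_L",
    "serum_igg": "mg_per_L",
    "csf_igg": "mg_per_L",
    "serum_kflc": "mg_per_L",
    "csf_kflc": "mg_per_L",
}

_UNIT_FACTORS = {"mg_per_L": 1.0, "g_per_L": 1000.0}


def load_cohort(
    path: "str | Path",
    units: Optional[Dict[str, str]] = None,
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
    *,
    strict: bool = True,
) -> List[PatientRecord]:
    """Load a cohort CSV, converting units and imputing censored CSF KFLC.

    An empty ``csf_kflc`` cell means "unmeasurable" and is imputed at half
    the detection limit with the censoring flag set; measurable values
    below the limit are treated the same way.  Malformed rows (unknown
    category tokens, non-positive or non-numeric concentrations, duplicate
    ids) are collected and reported together as :class:`CohortLoadError`.
    """
    unit_map = dict(DEFAULT_UNITS)
    if units:
        for col, unit in units.items():
            if col not in DEFAULT_UNITS:
                raise ValueError(f"unknown concentration column {col!r}")
            if unit not in _UNIT_FACTORS:
                raise ValueError(f"unknown unit {unit!r}; expected mg_per_L or g_per_L")
            unit_map[col] = unit

    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortLoadError([f"missing column(s): {', '.join(missing)}"])

    records: List[PatientRecord] = []
    problems: List[str] = []
    seen_ids: set = set()
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            records.append(
                _parse_row(row, unit_map, detection_limit, strict, seen_ids)
            )
        except ValueError as exc:
            problems.append(f"row {row_number}: {exc}")
    if problems:
        raise CohortLoadError(problems)
    return records


def _parse_row(row, unit_map, detection_limit, strict, seen_ids) -> PatientRecord:
    pid = row.patient_id
    if pid is None or (isinstance(pid, float) and math.isnan(pid)) or str(pid) == "":
        raise ValueError("missing patient_id")
    pid = str(pid) if strict else str(pid).strip()
    if pid in seen_ids:
        raise ValueError(f"duplicate patient_id {pid!r}")
    seen_ids.add(pid)

    values: Dict[str, float] = {}
    for col in DEFAULT_UNITS:
        raw = getattr(row, col)
        if col == "csf_kflc" and (raw is None or (isinstance(raw, float) and math.isnan(raw))):
            values[col] = math.nan
            continue
        try:
            value = float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric {col}: {raw!r}") from None
        if math.isnan(value):
            raise ValueError(f"missing {col}")
        values[col] = value * _UNIT_FACTORS[unit_map[col]]

    csf_kflc, censored = impute_censored_kflc(
        None if math.isnan(values["csf_kflc"]) else values["csf_kflc"],
        detection_limit,
    )
    pattern = IEFPattern.parse(str(row.ief_pattern), strict=strict)
    diagnosis = DiagnosisGroup.parse(str(row.diagnosis_group), strict=strict)
    specimen = PairedSpecimen(
        serum_albumin=values["serum_albumin"],
        csf_albumin=values["csf_albumin"],
        serum_igg=values["serum_igg"],
        csf_igg=values["csf_igg"],
        serum_kflc=values["serum_kflc"],
        csf_kflc=csf_kflc,
        csf_kflc_censored=censored,
    )
    return PatientRecord(id=pid, specimen=specimen, pattern=pattern, diagnosis=diagnosis)


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Serialise records to the canonical CSV frame (censored KFLC -> empty)."""
    rows = []
    for r in records:
        s = r.specimen
        rows.append(
            {
                "patient_id": r.id,
                "serum_albumin": s.serum_albumin,
                "csf_albumin": s.csf_albumin,
                "serum_igg": s.serum_igg,
                "csf_igg": s.csf_igg,
                "serum_kflc": s.serum_kflc,
                "csf_kflc": math.nan if s.csf_kflc_censored else s.csf_kflc,
                "ief_pattern": r.pattern.value,
                "diagnosis_group": r.diagnosis.value,
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cohort(records: Sequence[PatientRecord], path: "str | Path") -> None:
    """Write records as a cohort CSV (all concentrations mg/L)."""
    cohort_to_frame(records).to_csv(path, index=False)


def derive_all(
    records: Sequence[PatientRecord],
    kflc_lim_params: HyperbolicCurveParams = KFLC_CURVES["lim"],
    *,
    clamp_negative_if: bool = False,
) -> None:
    """Populate the derived quotient panel of every record, in place."""
    for r in records:
        r.derived = derive_profile(
            r.specimen, kflc_lim_params, clamp_negative_if=clamp_negative_if
        )


def marker_values(records: Sequence[PatientRecord], name: str) -> np.ndarray:
    """Extract a derived continuous marker ('kappa_index', 'kflc_if', ...)."""
    valid = {"q_alb", "q_igg", "q_kappa", "kappa_index", "igg_index",
             "reiber_igg_loc", "kflc_if"}
    if name not in valid:
        raise ValueError(f"unknown marker {name!r}; expected one of {sorted(valid)}")
    out = []
    for r in records:
        if r.derived is None:
            raise ValueError(f"record {r.id}: derived panel not populated")
        out.append(getattr(r.derived, name))
    return np.asarray(out, dtype=float)


# --------------------------------------------------------------------------
# study pipeline

@dataclass(frozen=True)
class StudyConfig:
    """Run parameters for :func:`run_study`."""

    kappa_cutoff: float = 5.8
    kappa_op: str = "ge"
    kflc_if_cutoff: float = 0.0
    kflc_if_op: str = "gt"
    ci_level: float = 0.95
    kflc_lim_params: HyperbolicCurveParams = KFLC_CURVES["lim"]
    clamp_negative_if: bool = False
    include_youden: bool = True


@dataclass
class StudyReport:
    """All pipeline outputs; see :meth:`to_dir` for on-disk layout."""

    descriptive: pd.DataFrame
    concordance: ConcordanceResult
    discordant_breakdown: pd.DataFrame
    accuracy_ms: Optional[pd.DataFrame]
    accuracy_cnsid: Optional[pd.DataFrame]
    single_band: Optional[Tuple[int, int, int]]
    youden_cutoffs: Dict[str, CutoffResult]
    config: StudyConfig
    n_total: int
    warnings: List[str] = field(default_factory=list)

    def to_dir(self, out_dir: "str | Path") -> None:
        """Write tables as CSV plus a JSON twin and a run log."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.descriptive.to_csv(out / "descriptive.csv", index=False)
        self.discordant_breakdown.to_csv(out / "discordant_breakdown.csv", index=False)
        if self.accuracy_ms is not None:
            self.accuracy_ms.to_csv(out / "accuracy_ms.csv", index=False)
        if self.accuracy_cnsid is not None:
            self.accuracy_cnsid.to_csv(out / "accuracy_cnsid.csv", index=False)
        summary = {
            "n_total": self.n_total,
            "warnings": self.warnings,
            "concordance": dataclasses.asdict(self.concordance),
            "single_band": (
                None
                if self.single_band is None
                else dict(
                    zip(("correct_by_kappa", "correct_by_band", "total"), self.single_band)
                )
            ),
            "youden_cutoffs": {
                k: dataclasses.asdict(v) for k, v in self.youden_cutoffs.items()
            },
            "accuracy_ms": (
                None if self.accuracy_ms is None
                else self.accuracy_ms.to_dict(orient="records")
            ),
            "accuracy_cnsid": (
                None if self.accuracy_cnsid is None
                else self.accuracy_cnsid.to_dict(orient="records")
            ),
            "config": {
                "kappa_cutoff": self.config.kappa_cutoff,
                "kappa_op": self.config.kappa_op,
                "kflc_if_cutoff": self.config.kflc_if_cutoff,
                "kflc_if_op": self.config.kflc_if_op,
                "ci_level": self.config.ci_level,
                "clamp_negative_if": self.config.clamp_negative_if,
                "kflc_lim_params": dataclasses.asdict(self.config.kflc_lim_params),
            },
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2))


def _summary_stats(x: np.ndarray) -> Tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else math.nan


def _descriptive_table(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """MS versus non-MS means/SDs and IEF pattern counts."""
    groups = {
        "MS": [r for r in records if r.diagnosis is DiagnosisGroup.MS],
        "non_MS": [r for r in records if r.diagnosis is not DiagnosisGroup.MS],
    }
    quantities = [
        ("serum_kflc_mg_L", lambda r: r.specimen.serum_kflc),
        ("csf_kflc_mg_L", lambda r: r.specimen.csf_kflc),
        ("kappa_index", lambda r: r.derived.kappa_index),
        ("kflc_if_pct", lambda r: r.derived.kflc_if),
        ("igg_index", lambda r: r.derived.igg_index),
        ("reiber_igg_loc_mg_L", lambda r: r.derived.reiber_igg_loc),
        ("q_alb", lambda r: r.derived.q_alb),
    ]
    rows = []
    for label, recs in groups.items():
        if not recs:
            continue
        row: Dict[str, object] = {"group": label, "n": len(recs)}
        for name, getter in quantities:
            x = np.asarray([getter(r) for r in recs], dtype=float)
            mean, sd = _summary_stats(x)
            row[f"{name}_mean"] = mean
            row[f"{name}_sd"] = sd
        row["kflc_if_positive_n"] = int(sum(r.derived.kflc_if > 0 for r in recs))
        for pattern in IEFPattern:
            row[f"ief_{pattern.value}_n"] = sum(r.pattern is pattern for r in recs)
        rows.append(row)
    return pd.DataFrame(rows)


def _metrics_row(
    marker: str,
    cutoff_desc: str,
    table: ConfusionTable,
    metrics: ConfusionMetrics,
) -> Dict[str, object]:
    row: Dict[str, object] = {
        "marker": marker,
        "cutoff": cutoff_desc,
        "tp": table.tp,
        "fp": table.fp,
        "fn": table.fn,
        "tn": table.tn,
    }
    for name in ("sensitivity", "specificity", "ppv", "npv", "auc_binary"):
        m = getattr(metrics, name)
        pct, lo, hi = m.as_percent() if m.defined else (math.nan,) * 3
        short = "auc" if name == "auc_binary" else name
        row[f"{short}"] = m.estimate
        row[f"{short}_pct"] = pct
        row[f"{short}_ci_low_pct"] = lo
        row[f"{short}_ci_high_pct"] = hi
    return row


def _accuracy_table(
    records: Sequence[PatientRecord],
    outcome: np.ndarray,
    outcome_name: str,
    config: StudyConfig,
    youden_cutoffs: Dict[str, CutoffResult],
) -> pd.DataFrame:
    kappa = marker_values(records, "kappa_index")
    flc_if = marker_values(records, "kflc_if")
    ocb = np.array([ocb_positive(r.pattern) for r in records])
    ocb_band = np.array([ocb_or_single_band_positive(r.pattern) for r in records])

    rows = []

    def add(marker: str, desc: str, predictions: np.ndarray) -> None:
        t = ConfusionTable.from_predictions(outcome, predictions)
        rows.append(_metrics_row(marker, desc, t, confusion_metrics(t, config.ci_level)))

    add("ocb", "pattern", ocb)
    add("ocb_or_single_band", "pattern", ocb_band)
    op_sym = {"ge": ">=", "gt": ">"}
    add(
        "kappa_index",
        f"{op_sym[config.kappa_op]}{config.kappa_cutoff}",
        binary_marker(kappa, config.kappa_cutoff, config.kappa_op),
    )
    add(
        "kflc_if",
        f"{op_sym[config.kflc_if_op]}{config.kflc_if_cutoff}",
        binary_marker(flc_if, config.kflc_if_cutoff, config.kflc_if_op),
    )
    if config.include_youden:
        for marker, values, op, display_decimals in (
            ("kappa_index", kappa, config.kappa_op, 1),
            ("kflc_if", flc_if, config.kflc_if_op, 0),
        ):
            best = youden_optimal_cutoff(values, outcome, op=op)
            shown = round(best.cutoff, display_decimals)
            youden_cutoffs[f"{marker}_{outcome_name}"] = best
            add(
                f"{marker}_youden",
                f"{op_sym[op]}{shown}",
                binary_marker(values, best.cutoff, op),
            )
    return pd.DataFrame(rows)


def single_band_reclassification(
    records: Sequence[PatientRecord],
    kappa_cutoff: float = 5.8,
    kappa_op: str = "ge",
) -> Tuple[int, int, int]:
    """Among single-CSF-IgG-band patients, who does each rule classify right?

    The single band itself predicts CNSID for everyone, so it is correct
    for exactly the CNSID members; the kappa index is correct for
    kappa-positive CNSID plus kappa-negative non-CNSID patients.

    Returns ``(correct_by_kappa, correct_by_band, total)``.
    """
    sub = [
        r
        for r in records
        if r.pattern in (IEFPattern.SINGLE_CSF_BAND, IEFPattern.MIRROR_PLUS_SINGLE_BAND)
    ]
    if not sub:
        raise ValueError("no single-CSF-IgG-band patients in the cohort")
    kappa = marker_values(sub, "kappa_index")
    positive = binary_marker(kappa, kappa_cutoff, kappa_op)
    cnsid = np.array([is_cnsid(r.diagnosis) for r in sub])
    correct_by_kappa = int(np.sum(positive & cnsid) + np.sum(~positive & ~cnsid))
    return correct_by_kappa, int(cnsid.sum()), len(sub)


def run_study(
    records: Sequence[PatientRecord], config: StudyConfig = StudyConfig()
) -> StudyReport:
    """Run the full analysis pipeline on a cohort.

    Derives the quotient panel if not yet populated, then produces the
    descriptive summaries, the kappa/OCB concordance with per-diagnosis
    discordance breakdown, the MS and CNSID diagnostic-accuracy tables,
    and the single-band reclassification analysis.  Deterministic: same
    records and config give bit-identical output.
    """
    if len(records) < 4:
        raise ValueError("need at least a handful of records to run the study")
    if any(r.derived is None for r in records):
        derive_all(
            records, config.kflc_lim_params, clamp_negative_if=config.clamp_negative_if
        )

    kappa = marker_values(records, "kappa_index")
    kappa_pos = binary_marker(kappa, config.kappa_cutoff, config.kappa_op)
    ocb = np.array([ocb_positive(r.pattern) for r in records])
    conc = concordance(kappa_pos, ocb)

    breakdown_rows = []
    for g in DiagnosisGroup:
        in_group = np.array([r.diagnosis is g for r in records])
        breakdown_rows.append(
            {
                "diagnosis": g.value,
                "kappa_pos_ocb_neg": int(np.sum(in_group & kappa_pos & ~ocb)),
                "ocb_pos_kappa_neg": int(np.sum(in_group & ocb & ~kappa_pos)),
            }
        )

    ms = np.array([r.diagnosis is DiagnosisGroup.MS for r in records])
    cnsid = np.array([is_cnsid(r.diagnosis) for r in records])
    youden: Dict[str, CutoffResult] = {}
    warnings: List[str] = []

    def outcome_table(mask: np.ndarray, name: str) -> Optional[pd.DataFrame]:
        if mask.sum() < 2 or (~mask).sum() < 2:
            warnings.append(
                f"outcome {name!r} skipped: needs >=2 records in each class "
                f"(got {int(mask.sum())} positive / {int((~mask).sum())} negative)"
            )
            return None
        return _accuracy_table(records, mask, name, config, youden)

    accuracy_ms = outcome_table(ms, "MS")
    accuracy_cnsid = outcome_table(cnsid, "CNSID")
    if accuracy_ms is None and accuracy_cnsid is None:
        raise ValueError(
            "neither outcome has both classes represented; " + "; ".join(warnings)
        )

    try:
        single_band = single_band_reclassification(
            records, config.kappa_cutoff, config.kappa_op
        )
    except ValueError as exc:
        warnings.append(f"single-band analysis skipped: {exc}")
        single_band = None

    return StudyReport(
        descriptive=_descriptive_table(records),
        concordance=conc,
        discordant_breakdown=pd.DataFrame(breakdown_rows),
        accuracy_ms=accuracy_ms,
        accuracy_cnsid=accuracy_cnsid,
        single_band=single_band,
        youden_cutoffs=youden,
        config=config,
        n_total=len(records),
        warnings=warnings,
    )


def accuracy_table_from_counts(
    counts: Dict[str, Tuple[int, int, int, int]], ci_level: float = 0.95
) -> pd.DataFrame:
    """Accuracy table from pre-aggregated (tp, fp, fn, tn) counts per marker.

    The count-level entry path: published 2x2 counts reproduce every table
    cell without patient-level data.
    """
    rows = []
    for marker, (tp, fp, fn, tn) in counts.items():
        t = ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
        rows.append(_metrics_row(marker, "from_counts", t, confusion_metrics(t, ci_level)))
    return pd.DataFrame(rows)
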