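"""ARDS day-1 labeling from diagnosis codes and oxygenation time series.

The endpoint for the cross-site use case is the presence of ARDS on the
first ICU day. Only the oxygenation component of the Berlin definition
is implemented: onset is the first time the Horowitz index (PaO2/FiO2)
drops below 300 mmHg and stays below for at least 24 h under
last-observation-carried-forward semantics. A patient is a case iff
they carry a qualifying diagnosis code (ICD-10 J80, or the ICD-9
pulmonary-insufficiency/respiratory-failure list where ICD-10 is not
available) AND onset falls within the first day; coded patients with a
later onset join the controls, which is audited separately in the label
counts.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .cohorts import CohortTable

__all__ = [
    "ICD10_ARDS_CODES",
    "ICD9_ARDS_CODES",
    "OnsetResult",
    "horowitz_index",
    "detect_onset",
    "build_horowitz_series",
    "assign_ards_labels",
]

ICD10_ARDS_CODES = frozenset({"J80"})
# ICD-9 has no specific ARDS code; pulmonary insufficiency / respiratory
# failure codes are the accepted surrogate set.
ICD9_ARDS_CODES = frozenset({"5185", "51851", "51852", "51853", "51882"})

CODE_SYSTEMS = {"icd10": ICD10_ARDS_CODES, "icd9": ICD9_ARDS_CODES}

REQUIRED_PARAMETERS = ("PaO2", "FiO2", "PEEP")


@dataclasses.dataclass(frozen=True)
class OnsetResult:
    """Sustained-hypoxemia onset for one patient."""

    patient_id: str | None
    onset_time_h: float | None
    is_day1: bool

    def __post_init__(self) -> None:
        if self.is_day1 and (self.onset_time_h is None or self.onset_time_h >= 24):
            raise ValueError("is_day1 requires an onset before 24 h")


def _normalize_code(code: str) -> str:
    return str(code).replace(".", "").replace(",", "").replace(" ", "").upper()


def horowitz_index(pao2, fio2):
    """P/F ratio: arterial oxygen partial pressure over inspired O2 fraction.

    ``fio2`` values above 1 are interpreted as percentages and divided by
    100 (both conventions occur in ICU charting); valid fractions lie in
    (0, 1]. Accepts scalars or arrays.
    """
    pao2 = np.asarray(pao2, dtype=float)
    fio2 = np.asarray(fio2, dtype=float)
    if np.any(fio2 <= 0):
        raise ValueError("FiO2 must be positive")
    if np.any(fio2 > 100):
        raise ValueError("FiO2 above 100% is not a valid inspired-oxygen fraction")
    if np.any(pao2 <= 0):
        raise ValueError("PaO2 must be positive")
    frac = np.where(fio2 > 1, fio2 / 100.0, fio2)
    out = pao2 / frac
    return float(out) if out.ndim == 0 else out


def detect_onset(
    times,
    values,
    threshold: float = 300.0,
    sustain_h: float = 24.0,
    patient_id: str | None = None,
) -> OnsetResult:
    """First sustained drop of an index below a threshold.

    Between measurements the state is carried forward (LOCF): a
    below-threshold run starts at a measurement < ``threshold`` and is
    broken by the first subsequent measurement >= ``threshold``. The run
    qualifies as onset when its span — until the breaking measurement,
    or until the last measurement if the record ends while still below —
    is at least ``sustain_h`` hours. Onset is the earliest qualifying
    run start; ``is_day1`` flags onset before 24 h.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        raise ValueError("cannot detect onset on an empty series")
    if t.shape != v.shape:
        raise ValueError("times and values must have identical shapes")
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    below = v < threshold
    n = len(t)
    i = 0
    while i < n:
        if below[i] and (i == 0 or not below[i - 1]):
            j = i + 1
            while j < n and below[j]:
                j += 1
            end = t[j] if j < n else t[-1]
            if end - t[i] >= sustain_h:
                onset = float(t[i])
                return OnsetResult(patient_id, onset, onset < 24.0)
            i = j
        else:
            i += 1
    return OnsetResult(patient_id, None, False)


def build_horowitz_series(
    series: pd.DataFrame,
    pao2_name: str = "PaO2",
    fio2_name: str = "FiO2",
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-patient Horowitz-index series from long-format measurements.

    At each PaO2 time the most recent FiO2 (LOCF, ties allowed at the
    same time) is used; PaO2 values before the first FiO2 record are
    dropped, since no inspired-oxygen fraction is known for them.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pid, grp in series.groupby("patient_id", sort=False):
        pao2 = grp[grp["parameter"] == pao2_name].sort_values("time_h")
        fio2 = grp[grp["parameter"] == fio2_name].sort_values("time_h")
        if pao2.empty or fio2.empty:
            continue
        tp = pao2["time_h"].to_numpy(float)
        tf = fio2["time_h"].to_numpy(float)
        idx = np.searchsorted(tf, tp, side="right") - 1
        valid = idx >= 0
        if not valid.any():
            continue
        pf = horowitz_index(
            pao2["value"].to_numpy(float)[valid],
            fio2["value"].to_numpy(float)[idx[valid]],
        )
        out[str(pid)] = (tp[valid], np.asarray(pf, dtype=float))
    return out


def assign_ards_labels(
    cohort: CohortTable,
    series: pd.DataFrame,
    code_systems: Mapping[str, Mapping] | None = None,
    window_h: float = 24.0,
    threshold: float = 300.0,
    sustain_h: float = 24.0,
) -> tuple[CohortTable, pd.DataFrame]:
    """Label a cohort's day-1 ARDS endpoint and report label composition.

    ``code_systems`` maps site id to ``{"system": "icd10"|"icd9"}`` or
    ``{"codes": [...]}`` (explicit qualifying set). Patients must carry
    PaO2, FiO2 and PEEP measurements within the first ``window_h`` hours
    to be included; the rest are dropped and counted. Cases are coded
    patients with day-1 onset; coded patients with later (or no) onset
    and uncoded patients are controls, counted separately so either
    control reading can be audited.
    """
    if cohort.codes is None:
        raise ValueError(f"site {cohort.site_id!r} carries no diagnosis codes")
    code_systems = code_systems or {}
    if cohort.site_id not in code_systems:
        raise ValueError(
            f"no code-system entry for site {cohort.site_id!r}; "
            f"known sites: {sorted(code_systems)}"
        )
    entry = code_systems[cohort.site_id]
    if "codes" in entry:
        qualifying = frozenset(_normalize_code(c) for c in entry["codes"])
    else:
        system = str(entry.get("system", "")).lower()
        if system not in CODE_SYSTEMS:
            raise ValueError(
                f"unknown coding system {system!r}; valid: {sorted(CODE_SYSTEMS)}"
            )
        qualifying = CODE_SYSTEMS[system]

    series = series[series["patient_id"].isin([str(p) for p in cohort.patient_ids])]
    first_day = series[series["time_h"] < window_h]
    has_param = first_day.groupby("patient_id")["parameter"].agg(set)
    included = [
        pid
        for pid in cohort.patient_ids
        if set(REQUIRED_PARAMETERS) <= has_param.get(str(pid), set())
    ]
    excluded = cohort.n_patients - len(included)

    pf_series = build_horowitz_series(series)
    labels = {}
    n_cases = n_ctrl_uncoded = n_ctrl_coded_late = 0
    for pid in included:
        codes = {_normalize_code(c) for c in cohort.codes.get(pid, frozenset())}
        coded = bool(codes & qualifying)
        if coded:
            tp, pf = pf_series.get(str(pid), (np.array([]), np.array([])))
            onset = (
                detect_onset(tp, pf, threshold=threshold, sustain_h=sustain_h, patient_id=pid)
                if tp.size
                else OnsetResult(pid, None, False)
            )
            if onset.is_day1:
                labels[pid] = 1
                n_cases += 1
            else:
                labels[pid] = 0
                n_ctrl_coded_late += 1
        else:
            labels[pid] = 0
            n_ctrl_uncoded += 1

    data = cohort.data.loc[included]
    endpoint = pd.Series([labels[p] for p in included], index=data.index)
    labeled = CohortTable(
        cohort.site_id,
        data,
        endpoint=endpoint,
        codes={p: cohort.codes.get(p, frozenset()) for p in included},
    )
    counts = pd.DataFrame(
        [
            {
                "site_id": cohort.site_id,
                "n_total": cohort.n_patients,
                "cases_day1": n_cases,
                "controls_uncoded": n_ctrl_uncoded,
                "controls_coded_late_or_no_onset": n_ctrl_coded_late,
                "excluded": excluded,
            }
        ]
    )
    return labeled, counts
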