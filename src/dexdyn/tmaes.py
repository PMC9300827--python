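"""Per-patient dynamics of epitope-specific T-cell populations.

Comparing a patient's baseline (BL) and on-therapy follow-up (FU)
response sets classifies each population as appearing (FU only),
disappearing (BL only) or stable (both).  Score A is the triple of those
counts; score B = appearing − disappearing condenses the dynamics into
one signed integer, and the cohort is dichotomized at score B > 0
("increased") versus ≤ 0 ("decreased/balanced", which includes patients
with no detected populations at either timepoint).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .synthlib import (
    BL,
    FU,
    GROUP_DECREASED_BALANCED,
    GROUP_INCREASED,
    LibraryDef,
    SampleSheet,
)


@dataclass
class DynamicsRecord:
    patient_id: str
    appearing: frozenset[str]
    disappearing: frozenset[str]
    stable: frozenset[str]

    @property
    def score_a(self) -> tuple[int, int, int]:
        return (len(self.appearing), len(self.disappearing), len(self.stable))

    @property
    def score_b(self) -> int:
        return len(self.appearing) - len(self.disappearing)

    @property
    def group(self) -> str:
        return dichotomize(self.score_b)


def classify_dynamics(
    bl_responses: Iterable[str], fu_responses: Iterable[str], patient_id: str
) -> DynamicsRecord:
    """Split populations into appearing / disappearing / stable sets."""
    bl = frozenset(bl_responses)
    fu = frozenset(fu_responses)
    return DynamicsRecord(
        patient_id=patient_id,
        appearing=fu - bl,
        disappearing=bl - fu,
        stable=bl & fu,
    )


def dichotomize(score_b: int) -> str:
    """score B > 0 → 'increased'; ≤ 0 → 'decreased_balanced'."""
    return GROUP_INCREASED if score_b > 0 else GROUP_DECREASED_BALANCED


def responses_by_patient(
    responses: set[tuple[str, str]], sheet: SampleSheet
) -> dict[str, dict[str, set[str]]]:
    """Group (sample_id, pmhc_id) response calls into per-patient BL/FU sets.

    Raises ConsistencyError if a patient has more than one BL or FU
    sample (merging would be ambiguous).
    """
    out: dict[str, dict[str, set[str]]] = {}
    for pid in sheet.patient_ids:
        out[pid] = {}
        for tp in (BL, FU):
            sid = sheet.sample_of(pid, tp)  # raises on duplicates
            out[pid][tp] = {pm for s, pm in responses if s == sid}
    return out


def cohort_dynamics(
    responses: set[tuple[str, str]], sheet: SampleSheet
) -> list[DynamicsRecord]:
    """classify_dynamics for every patient in the sheet."""
    per_patient = responses_by_patient(responses, sheet)
    return [
        classify_dynamics(sets[BL], sets[FU], pid)
        for pid, sets in per_patient.items()
    ]


def cohort_abundance(
    response_sets: Mapping[str, Mapping[str, set[str]]],
    n_patients: int,
    pmhc_ids: Iterable[str],
) -> pd.DataFrame:
    """Cohort-level abundance per population and timepoint.

    ``normalized_count`` is the number of patients with a response for
    that population divided by the cohort size; ``prevalence_pct`` is the
    same as a percentage rounded to one decimal.
    """
    if n_patients < 1:
        raise ConsistencyError("n_patients must be >= 1")
    rows = []
    for pm in pmhc_ids:
        for tp in (BL, FU):
            n = sum(1 for sets in response_sets.values() if pm in sets[tp])
            rows.append(
                {
                    "pmhc_id": pm,
                    "timepoint": tp,
                    "n_patients_responding": n,
                    "normalized_count": n / n_patients,
                    "prevalence_pct": round(100.0 * n / n_patients, 1),
                }
            )
    return pd.DataFrame(rows)


def delta_matrix(
    dynamics: Iterable[DynamicsRecord], library: LibraryDef | Iterable[str]
) -> pd.DataFrame:
    """Patients × populations matrix of {−1, 0, +1} presence changes.

    +1 for appearing, −1 for disappearing, 0 for stable or absent at both
    timepoints; each row sums to the patient's score B.
    """
    if isinstance(library, LibraryDef):
        pmhc_ids = library.pmhc_ids
    else:
        pmhc_ids = list(library)
    records = list(dynamics)
    pids = [r.patient_id for r in records]
    if len(set(pids)) != len(pids):
        raise ConsistencyError("expected exactly one DynamicsRecord per patient")
    idx = {pm: j for j, pm in enumerate(pmhc_ids)}
    mat = np.zeros((len(records), len(pmhc_ids)), dtype=np.int8)
    for i, rec in enumerate(records):
        for pm in rec.appearing:
            mat[i, idx[pm]] = 1
        for pm in rec.disappearing:
            mat[i, idx[pm]] = -1
    return pd.DataFrame(mat, index=pids, columns=pmhc_ids)


def dynamics_frame(dynamics: Iterable[DynamicsRecord]) -> pd.DataFrame:
    """Tabular summary: one row per patient with scores and group."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "n_appearing": len(r.appearing),
                "n_disappearing": len(r.disappearing),
                "n_stable": len(r.stable),
                "score_b": r.score_b,
                "group": r.group,
            }
            for r in dynamics
        ]
    )
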