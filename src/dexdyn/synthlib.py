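"""Synthetic dextramer libraries, patient cohorts, count matrices and reads.

The generator emulates the structure of a DNA-barcoded pMHC-dextramer
screen of a melanoma ICB cohort: a library of HLA-A*02:01-restricted
epitopes each tagged with two unique 25-mer DNA barcodes, paired
baseline (BL) and follow-up (FU) blood samples per patient, an input
triplicate of the unsorted library, and clinical follow-up whose hazard
is linked to the planted T-cell dynamics group.  Every stage is a pure
function of its parameters and the seed, and the planted ground truth
(`CohortTruth`) is returned so downstream recovery can be scored.

Count model
-----------
Each barcode carries a gamma-distributed library-composition weight
(mean 1, variance ``background_dispersion``) shared by every sample and
the input triplicate, and per-sample counts are Poisson around the
sample's depth times its (enrichment-scaled) composition.  Marginally
across barcodes the counts are therefore negative binomial with
dispersion ``background_dispersion``, while the sample-vs-input contrast
stays free of the shared skew.  PCR duplication is modelled by adding a
Poisson number of duplicate reads on top of each clonal (distinct-UMI)
count, so the clonal layer is always <= the total layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .barcode_io import CountMatrix
from .errors import ConsistencyError, InvalidParameterError, SchemaError

BL = "BL"
FU = "FU"
INPUT = "INPUT"

GROUP_INCREASED = "increased"
GROUP_DECREASED_BALANCED = "decreased_balanced"

_BASES = np.array(list("ACGT"))
_AA = list("ACDEFGHIKLMNPQRSTVWY")

# melanoma-associated antigen names used to label synthetic library entries
_ANTIGEN_POOL = [
    "MAGE-A1", "MAGE-A2", "MAGE-A3", "MAGE-A10", "MAGE-C2", "NY-ESO-1",
    "Melan-A", "TRP-2", "Tyrosinase", "gp100", "TAG-1", "TRAG-3", "STEAP1",
    "Telomerase", "p53", "Survivin", "CDKN1A", "P-cadherin", "PRAME",
    "SSX-2",
]


def epitope_label(antigen_name: str, peptide: str) -> str:
    """Population label: antigen name + first 3 letters of the peptide."""
    return f"{antigen_name} {peptide[:3]}"


@dataclass(frozen=True)
class LibraryEntry:
    pmhc_id: str
    antigen_name: str
    peptide: str
    epitope_label: str
    barcode_a: str
    barcode_b: str
    hla: str = "HLA-A*02:01"


@dataclass
class LibraryDef:
    """The dextramer library: one entry per pMHC, two unique 25-mer barcodes."""

    entries: list[LibraryEntry]

    def __post_init__(self) -> None:
        ids = [e.pmhc_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise SchemaError("pmhc_id values must be unique")
        pairs = [(e.barcode_a, e.barcode_b) for e in self.entries]
        if len(set(pairs)) != len(pairs):
            raise SchemaError("(barcode_a, barcode_b) pairs must be unique")
        for e in self.entries:
            for bc in (e.barcode_a, e.barcode_b):
                if len(bc) != 25 or set(bc) - set("ACGT"):
                    raise SchemaError(
                        f"{e.pmhc_id}: barcodes must be 25-mers over ACGT"
                    )
            if e.epitope_label != epitope_label(e.antigen_name, e.peptide):
                raise SchemaError(
                    f"{e.pmhc_id}: epitope_label inconsistent with antigen/peptide"
                )

    @property
    def pmhc_ids(self) -> list[str]:
        return [e.pmhc_id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.entries])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LibraryDef":
        df = pd.read_csv(path, sep="\t")
        return cls([LibraryEntry(**row) for row in df.to_dict("records")])


@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    patient_id: str  # "input" for library-input rows
    timepoint: str  # BL / FU / INPUT
    dna_key: str
    multimer_pos_pct: float | None = None  # absent for INPUT


@dataclass
class SampleSheet:
    """Sample metadata: patient, timepoint, DNA key and FACS multimer gate."""

    rows: list[SampleRow]

    def __post_init__(self) -> None:
        keys = [r.dna_key for r in self.rows]
        if len(set(keys)) != len(keys):
            raise SchemaError("dna_key must be unique per sample")
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise SchemaError("sample_id must be unique")
        for r in self.rows:
            if r.timepoint not in (BL, FU, INPUT):
                raise SchemaError(f"unknown timepoint {r.timepoint!r}")
        by_patient: dict[str, set[str]] = {}
        for r in self.rows:
            if r.timepoint != INPUT:
                by_patient.setdefault(r.patient_id, set()).add(r.timepoint)
        for pid, tps in by_patient.items():
            if tps != {BL, FU}:
                raise SchemaError(f"patient {pid!r} lacks a BL or FU sample")

    @property
    def input_rows(self) -> list[SampleRow]:
        return [r for r in self.rows if r.timepoint == INPUT]

    @property
    def patient_rows(self) -> list[SampleRow]:
        return [r for r in self.rows if r.timepoint != INPUT]

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.patient_rows:
            seen.setdefault(r.patient_id)
        return list(seen)

    def row_for(self, sample_id: str) -> SampleRow:
        for r in self.rows:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def sample_of(self, patient_id: str, timepoint: str) -> str:
        hits = [
            r.sample_id
            for r in self.rows
            if r.patient_id == patient_id and r.timepoint == timepoint
        ]
        if len(hits) != 1:
            raise ConsistencyError(
                f"expected exactly one {timepoint} sample for {patient_id!r}, "
                f"found {len(hits)}"
            )
        return hits[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path)
        rows = []
        for rec in df.to_dict("records"):
            pct = rec.get("multimer_pos_pct")
            if pct is not None and isinstance(pct, float) and math.isnan(pct):
                rec["multimer_pos_pct"] = None
            rows.append(SampleRow(**rec))
        return cls(rows)


@dataclass
class SimParams:
    """Knobs of the synthetic screen; defaults mirror the emulated study.

    ``n_patients=36`` and ``library_size=167`` follow the cohort and panel
    size of the emulated study; ``planted_hr=0.24`` is the reported OS
    hazard ratio of the dominantly-increased dynamics group.  ``depth`` is
    mean clonal reads per sample (free parameter; no depths are reported).
    """

    n_patients: int = 36
    library_size: int = 167
    depth: float = 5e5
    depth_cv: float = 0.3  # lognormal sd of per-sample depth (log scale)
    background_dispersion: float = 0.3  # NB dispersion of marginal counts
    duplication_rate: float = 0.5  # mean PCR duplicates per clonal read
    enrichment_factor: float = 8.0  # fold-change of planted responses
    planted_hr: float = 0.24  # hazard ratio, increased vs decreased/balanced
    censor_rate: float = 0.2
    umi_length: int = 10
    key_length: int = 8
    read_error_rate: float = 0.0
    # dynamics of planted response sets
    mean_bl_populations: float = 5.0
    persist_prob: float = 0.7
    mean_appearing: float = 3.0
    # survival model
    baseline_hazard: float = 0.04  # per month, decreased/balanced group
    survival_model: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.5
    pfs_hazard_multiplier: float = 1.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise InvalidParameterError("n_patients must be >= 2")
        if self.library_size < 1:
            raise InvalidParameterError("library_size must be >= 1")
        if self.depth <= 0:
            raise InvalidParameterError("depth must be > 0")
        if self.enrichment_factor < 1:
            raise InvalidParameterError("enrichment_factor must be >= 1")
        for name in ("censor_rate", "read_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidParameterError(f"{name} must be in [0, 1]")
        if not 0 < self.persist_prob <= 1:
            raise InvalidParameterError("persist_prob must be in (0, 1]")
        if self.background_dispersion < 0:
            raise InvalidParameterError("background_dispersion must be >= 0")
        if self.planted_hr <= 0:
            raise InvalidParameterError("planted_hr must be > 0")
        if self.survival_model not in ("exponential", "weibull"):
            raise InvalidParameterError("survival_model must be exponential|weibull")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible stream per pipeline stage."""
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class PatientTruth:
    patient_id: str
    present_bl: set[str]
    present_fu: set[str]
    true_score_b: int
    group: str
    os_time: float
    os_event: int
    pfs_time: float
    pfs_event: int
    covariates: dict

    def __post_init__(self) -> None:
        expect = len(self.present_fu - self.present_bl) - len(
            self.present_bl - self.present_fu
        )
        if self.true_score_b != expect:
            raise SchemaError(
                f"{self.patient_id}: true_score_b {self.true_score_b} != {expect}"
            )
        if self.os_time <= 0 or self.pfs_time <= 0:
            raise SchemaError(f"{self.patient_id}: survival times must be > 0")
        if self.os_event not in (0, 1) or self.pfs_event not in (0, 1):
            raise SchemaError(f"{self.patient_id}: events must be 0/1")


@dataclass
class CohortTruth:
    """Planted ground truth for a synthetic cohort."""

    patients: list[PatientTruth]
    pmhc_ids: list[str]
    params: SimParams

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def clinical_frame(self) -> pd.DataFrame:
        recs = []
        for p in self.patients:
            rec = {
                "patient_id": p.patient_id,
                "os_time": p.os_time,
                "os_event": p.os_event,
                "pfs_time": p.pfs_time,
                "pfs_event": p.pfs_event,
                "group": p.group,
            }
            rec.update(p.covariates)
            recs.append(rec)
        return pd.DataFrame(recs)

    def response_sets(self) -> dict[str, dict[str, set[str]]]:
        """patient_id -> {'BL': set, 'FU': set} of planted responses."""
        return {
            p.patient_id: {BL: set(p.present_bl), FU: set(p.present_fu)}
            for p in self.patients
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pmhc_ids": self.pmhc_ids,
            "params": asdict(self.params),
            "patients": [
                {
                    **asdict(p),
                    "present_bl": sorted(p.present_bl),
                    "present_fu": sorted(p.present_fu),
                }
                for p in self.patients
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        payload = json.loads(Path(path).read_text())
        params = SimParams(**payload["params"])
        patients = [
            PatientTruth(
                **{
                    **rec,
                    "present_bl": set(rec["present_bl"]),
                    "present_fu": set(rec["present_fu"]),
                }
            )
            for rec in payload["patients"]
        ]
        return cls(patients, payload["pmhc_ids"], params)


# ---------------------------------------------------------------------------
# generators


def _random_kmers(rng: np.random.Generator, n: int, k: int, min_dist: int = 3) -> list[str]:
    """Distinct random DNA k-mers with pairwise Hamming distance >= min_dist."""
    out: list[str] = []
    while len(out) < n:
        cand = "".join(rng.choice(_BASES, size=k))
        if all(sum(a != b for a, b in zip(cand, prev)) >= min_dist for prev in out):
            out.append(cand)
    return out


def make_library(params: SimParams) -> LibraryDef:
    """Generate a synthetic dextramer library with unique barcode pairs."""
    params.validate()
    rng = params.rng(1)
    n = params.library_size
    barcodes = _random_kmers(rng, 2 * n, 25, min_dist=5)
    entries = []
    peptides_seen: set[str] = set()
    for i in range(n):
        antigen = _ANTIGEN_POOL[i % len(_ANTIGEN_POOL)]
        while True:
            peptide = "".join(rng.choice(_AA, size=9))
            if peptide not in peptides_seen:
                peptides_seen.add(peptide)
                break
        entries.append(
            LibraryEntry(
                pmhc_id=f"pMHC{i + 1:03d}",
                antigen_name=antigen,
                peptide=peptide,
                epitope_label=epitope_label(antigen, peptide),
                barcode_a=barcodes[2 * i],
                barcode_b=barcodes[2 * i + 1],
            )
        )
    return LibraryDef(entries)


def simulate_cohort(params: SimParams) -> CohortTruth:
    """Plant per-patient BL/FU response sets and linked survival outcomes.

    Dynamics: each patient starts with a Poisson number of baseline
    populations, each persisting to FU independently; a Poisson number of
    new populations appears at FU.  The hazard of the exponential (or
    Weibull) survival model is multiplied by ``planted_hr`` for patients
    whose planted score (appearing − disappearing) is > 0; censoring is
    drawn independently of group.
    """
    params.validate()
    rng = params.rng(2)
    pmhc_ids = [f"pMHC{i + 1:03d}" for i in range(params.library_size)]
    patients: list[PatientTruth] = []
    for i in range(params.n_patients):
        pid = f"P{i + 1:02d}"
        n_bl = min(rng.poisson(params.mean_bl_populations), params.library_size)
        bl = set(rng.choice(pmhc_ids, size=n_bl, replace=False))
        stable = {b for b in bl if rng.random() < params.persist_prob}
        pool = [b for b in pmhc_ids if b not in bl]
        n_app = min(rng.poisson(params.mean_appearing), len(pool))
        appearing = set(rng.choice(pool, size=n_app, replace=False)) if n_app else set()
        fu = stable | appearing
        score_b = len(fu - bl) - len(bl - fu)
        group = GROUP_INCREASED if score_b > 0 else GROUP_DECREASED_BALANCED

        hr = params.planted_hr if group == GROUP_INCREASED else 1.0
        os_time, os_event = _draw_survival(rng, params, params.baseline_hazard * hr)
        pfs_hazard = params.baseline_hazard * params.pfs_hazard_multiplier * hr
        pfs_time, pfs_event = _draw_survival(rng, params, pfs_hazard)

        covariates = {
            "age": int(np.clip(rng.normal(66, 12), 28, 88)),
            "sex": "male" if rng.random() < 2 / 3 else "female",
            "therapy": "mono" if rng.random() < 17 / 36 else "combo",
            "ldh_elevated": int(rng.random() < 11 / 36),
        }
        patients.append(
            PatientTruth(
                patient_id=pid,
                present_bl=bl,
                present_fu=fu,
                true_score_b=score_b,
                group=group,
                os_time=os_time,
                os_event=os_event,
                pfs_time=pfs_time,
                pfs_event=pfs_event,
                covariates=covariates,
            )
        )
    return CohortTruth(patients, pmhc_ids, params)


def _draw_survival(
    rng: np.random.Generator, params: SimParams, hazard: float
) -> tuple[float, int]:
    """Event time under the configured model, censored independently."""
    if params.survival_model == "weibull":
        # proportional-hazards Weibull: S(t) = exp(-hazard * t^shape)
        u = rng.random()
        t_event = (-np.log(u) / hazard) ** (1.0 / params.weibull_shape)
    else:
        t_event = rng.exponential(1.0 / hazard)
    if params.censor_rate > 0:
        cens_hazard = params.baseline_hazard * params.censor_rate / (1 - params.censor_rate)
        t_cens = rng.exponential(1.0 / cens_hazard)
    else:
        t_cens = np.inf
    t = min(t_event, t_cens)
    return max(float(t), 1e-3), int(t_event <= t_cens)


def simulate_counts(
    truth: CohortTruth, library: LibraryDef, params: SimParams
) -> tuple[CountMatrix, SampleSheet]:
    """Draw barcode counts for every patient sample and the input triplicate.

    Input replicates see the bare library composition; patient samples see
    the composition with planted-present barcodes multiplied by
    ``enrichment_factor`` and renormalized.  The clonal layer is Poisson
    around depth × proportion; PCR duplicates are added on top for the
    total layer.
    """
    params.validate()
    if not library.entries:
        raise InvalidParameterError("library must be nonempty")
    if library.pmhc_ids != truth.pmhc_ids:
        raise ConsistencyError("library and cohort truth disagree on pmhc_ids")
    rng = params.rng(3)
    n_bar = len(library.entries)

    # library composition skew, shared by all samples (drawn from its own
    # stream so counts are comparable across cohorts with the same seed)
    wrng = params.rng(4)
    if params.background_dispersion > 0:
        shape = 1.0 / params.background_dispersion
        weights = wrng.gamma(shape, scale=1.0 / shape, size=n_bar)
        weights = np.maximum(weights, 1e-9)
    else:
        weights = np.ones(n_bar)

    idx = {p: i for i, p in enumerate(truth.pmhc_ids)}
    sample_ids: list[str] = []
    tp_of: dict[str, str] = {}
    present_of: dict[str, set[str]] = {}
    for p in truth.patients:
        for tp, present in ((BL, p.present_bl), (FU, p.present_fu)):
            sid = f"{p.patient_id}_{tp}"
            sample_ids.append(sid)
            tp_of[sid] = tp
            present_of[sid] = present
    for k in range(3):
        sid = f"input_{k + 1}"
        sample_ids.append(sid)
        tp_of[sid] = INPUT
        present_of[sid] = set()

    clonal = np.zeros((n_bar, len(sample_ids)), dtype=np.int64)
    total = np.zeros_like(clonal)
    for j, sid in enumerate(sample_ids):
        boost = np.ones(n_bar)
        for pm in present_of[sid]:
            boost[idx[pm]] = params.enrichment_factor
        props = weights * boost
        props = props / props.sum()
        depth_j = params.depth * rng.lognormal(0.0, params.depth_cv)
        clo = rng.poisson(depth_j * props)
        dup = rng.poisson(params.duplication_rate * clo)
        clonal[:, j] = clo
        total[:, j] = clo + dup

    keys = _random_kmers(rng, len(sample_ids), params.key_length, min_dist=3)
    rows = []
    for j, sid in enumerate(sample_ids):
        if tp_of[sid] == INPUT:
            rows.append(SampleRow(sid, "input", INPUT, keys[j], None))
        else:
            pct = float(
                np.round(0.05 + 0.08 * len(present_of[sid]) * rng.lognormal(0.0, 0.4), 4)
            )
            rows.append(SampleRow(sid, sid.rsplit("_", 1)[0], tp_of[sid], keys[j], pct))
    matrix = CountMatrix(list(truth.pmhc_ids), sample_ids, total, clonal)
    return matrix, SampleSheet(rows)


def emit_fastq(
    counts: CountMatrix,
    library: LibraryDef,
    sheet: SampleSheet,
    params: SimParams,
    path: str | Path,
) -> Path:
    """Write synthetic reads (key + barcode_a + UMI + barcode_b) as FASTQ.

    Per (sample, barcode) cell, ``clonal`` distinct UMIs are generated and
    the ``total`` reads are distributed over them (each UMI at least
    once), so an error-free round trip through demux_and_count restores
    both layers exactly.  A ``.gz`` suffix selects gzip output.
    """
    import gzip as _gzip

    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    params.validate()
    sheet_ids = {r.sample_id for r in sheet.rows}
    missing = [s for s in counts.sample_ids if s not in sheet_ids]
    if missing:
        raise ConsistencyError(f"samples in counts missing from sheet: {missing}")
    lib_by_id = {e.pmhc_id: e for e in library.entries}
    rng = params.rng(5)
    path = Path(path)

    def records() -> Iterable[SeqRecord]:
        n_read = 0
        for j, sid in enumerate(counts.sample_ids):
            key = sheet.row_for(sid).dna_key
            for i, pm in enumerate(counts.pmhc_ids):
                t = int(counts.total[i, j])
                c = int(counts.clonal[i, j])
                if t == 0:
                    continue
                if c == 0:
                    raise SchemaError(
                        f"cell ({pm}, {sid}) has total reads but zero clonal reads"
                    )
                entry = lib_by_id[pm]
                umis: set[str] = set()
                while len(umis) < c:
                    umis.add("".join(rng.choice(_BASES, size=params.umi_length)))
                umi_list = list(umis)
                assignments = umi_list + [
                    umi_list[k] for k in rng.integers(0, c, size=t - c)
                ]
                for umi in assignments:
                    seq = key + entry.barcode_a + umi + entry.barcode_b
                    if params.read_error_rate > 0:
                        seq = _mutate(rng, seq, params.read_error_rate)
                    n_read += 1
                    rec = SeqRecord(Seq(seq), id=f"read{n_read}", description="")
                    rec.letter_annotations["phred_quality"] = [30] * len(seq)
                    yield rec

    if path.suffix == ".gz":
        with _gzip.open(path, "wt") as handle:
            seqio_write(records(), handle, "fastq")
    else:
        with open(path, "w") as handle:
            seqio_write(records(), handle, "fastq")
    return path


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# direct delta-matrix cohorts for regression-selection experiments


@dataclass
class InformativeCohort:
    """A cohort whose hazard depends on a few planted dynamic populations."""

    delta: pd.DataFrame  # patients × populations, entries in {-1, 0, +1}
    clinical: pd.DataFrame  # patient_id, os_time, os_event, ...
    informative_ids: list[str]


def simulate_informative_cohort(
    params: SimParams,
    n_informative: int = 3,
    hr_per_unit: float = 0.15,
    informative_rate: float = 0.3,
    noise_rate: float = 0.05,
) -> InformativeCohort:
    """Plant hazard signal in ``n_informative`` population-dynamics columns.

    Informative columns take ±1 with probability ``informative_rate`` each;
    the log-hazard is ``log(hr_per_unit)`` per unit of their sum (protective
    appearance, deleterious disappearance, matching the emulated biology).
    Noise columns take ±1 with probability ``noise_rate`` each and carry no
    signal.  With ``n_informative=0`` the cohort is a pure null.
    """
    params.validate()
    if not 0 <= n_informative <= params.library_size:
        raise InvalidParameterError("n_informative out of range")
    rng = params.rng(6)
    n, m = params.n_patients, params.library_size
    pmhc_ids = [f"pMHC{i + 1:03d}" for i in range(m)]
    info_ids = list(rng.choice(pmhc_ids, size=n_informative, replace=False))
    delta = np.zeros((n, m), dtype=np.int8)
    for j, pm in enumerate(pmhc_ids):
        rate = informative_rate if pm in info_ids else noise_rate
        u = rng.random(n)
        delta[:, j] = np.where(u < rate, 1, np.where(u < 2 * rate, -1, 0))
    info_cols = [pmhc_ids.index(pm) for pm in info_ids]
    signal = delta[:, info_cols].sum(axis=1) if info_cols else np.zeros(n)
    beta = math.log(hr_per_unit)
    recs = []
    for i in range(n):
        hazard = params.baseline_hazard * math.exp(beta * float(signal[i]))
        t, e = _draw_survival(rng, params, hazard)
        recs.append(
            {"patient_id": f"P{i + 1:02d}", "os_time": t, "os_event": e}
        )
    clinical = pd.DataFrame(recs)
    frame = pd.DataFrame(delta, index=clinical["patient_id"], columns=pmhc_ids)
    return InformativeCohort(frame, clinical, sorted(info_ids))
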