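"""Read parsing, demultiplexing, UMI collapse and count-matrix I/O.

A screen read has the layout ``dna_key + barcode_a + UMI + barcode_b``
(documented in docs/formats.md).  Reads are assigned to a sample by exact
(or near-exact) match of the DNA key and to a pMHC dextramer by matching
*both* 25-mer barcodes; the clonal layer counts distinct
(sample, pMHC, UMI) triples, removing PCR duplicates.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError, SchemaError

if TYPE_CHECKING:  # pragma: no cover
    from .synthlib import LibraryDef, SampleSheet


@dataclass
class CountMatrix:
    """Barcodes × samples counts with a total-reads and a UMI-collapsed layer.

    Parameters
    ----------
    pmhc_ids :
        Row labels, one per dextramer in the library.
    sample_ids :
        Column labels, one per sequenced sample (patients and inputs).
    total :
        Total read counts, shape ``(len(pmhc_ids), len(sample_ids))``.
    clonal :
        Clonally reduced (distinct-UMI) counts, same shape; elementwise
        ``clonal <= total``.
    """

    pmhc_ids: list[str]
    sample_ids: list[str]
    total: np.ndarray
    clonal: np.ndarray

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total)
        self.clonal = np.asarray(self.clonal)
        shape = (len(self.pmhc_ids), len(self.sample_ids))
        if self.total.shape != shape or self.clonal.shape != shape:
            raise SchemaError(
                f"count layers must have shape {shape}, got "
                f"{self.total.shape} and {self.clonal.shape}"
            )
        for name, layer in (("total", self.total), ("clonal", self.clonal)):
            if not np.issubdtype(layer.dtype, np.integer):
                if not np.all(np.equal(np.mod(layer, 1), 0)):
                    raise SchemaError(f"{name} layer has non-integer entries")
                layer = layer.astype(np.int64)
            if (layer < 0).any():
                raise SchemaError(f"{name} layer has negative entries")
        self.total = self.total.astype(np.int64)
        self.clonal = self.clonal.astype(np.int64)
        if (self.clonal > self.total).any():
            raise SchemaError("clonal counts exceed total counts")
        if len(set(self.pmhc_ids)) != len(self.pmhc_ids):
            raise SchemaError("duplicate pmhc_id in count matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SchemaError("duplicate sample_id in count matrix")

    # -- convenience accessors -------------------------------------------
    def column(self, sample_id: str, layer: str = "clonal") -> np.ndarray:
        j = self.sample_ids.index(sample_id)
        return getattr(self, layer)[:, j]

    def to_frame(self) -> pd.DataFrame:
        """Wide TSV schema: pmhc_id, then <sample>_total, <sample>_clonal pairs."""
        data: dict[str, object] = {"pmhc_id": self.pmhc_ids}
        for j, sid in enumerate(self.sample_ids):
            data[f"{sid}_total"] = self.total[:, j]
            data[f"{sid}_clonal"] = self.clonal[:, j]
        return pd.DataFrame(data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.pmhc_ids == other.pmhc_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.total, other.total)
            and np.array_equal(self.clonal, other.clonal)
        )


@dataclass
class DemuxReport:
    """Bookkeeping of a demultiplexing run; assigned + discards = scanned."""

    reads_scanned: int = 0
    reads_assigned: int = 0
    discards: dict[str, int] = field(default_factory=dict)

    def discard(self, reason: str) -> None:
        self.discards[reason] = self.discards.get(reason, 0) + 1

    @property
    def reads_discarded(self) -> int:
        return sum(self.discards.values())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "reads_scanned": self.reads_scanned,
                    "reads_assigned": self.reads_assigned,
                    "reads_discarded": self.reads_discarded,
                    "discards": self.discards,
                },
                indent=2,
            )
        )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class _Matcher:
    """Exact-first sequence matcher with a Hamming-distance fallback.

    Ambiguity at the chosen radius (two references within ``max_mismatch``
    of a query) yields no match rather than an arbitrary assignment.
    """

    def __init__(self, refs: dict[str, str], max_mismatch: int, what: str):
        # refs: sequence -> label
        self.refs = refs
        self.max_mismatch = max_mismatch
        self.length = len(next(iter(refs)))
        if any(len(s) != self.length for s in refs):
            raise ConfigurationError(f"{what} sequences have unequal lengths")
        # keys/barcodes must stay unambiguous at the chosen radius
        seqs = list(refs)
        for i, a in enumerate(seqs):
            for b in seqs[i + 1 :]:
                if _hamming(a, b) <= 2 * max_mismatch:
                    raise ConfigurationError(
                        f"{what} {refs[a]!r} and {refs[b]!r} collide at "
                        f"mismatch radius {max_mismatch}"
                    )
        self._cache: dict[str, str | None] = {}

    def match(self, query: str) -> str | None:
        hit = self.refs.get(query)
        if hit is not None:
            return hit
        if self.max_mismatch == 0:
            return None
        cached = self._cache.get(query)
        if cached is not None or query in self._cache:
            return cached
        best: str | None = None
        for seq, label in self.refs.items():
            if _hamming(seq, query) <= self.max_mismatch:
                if best is not None:  # unreachable given collision check, kept as guard
                    best = None
                    break
                best = label
        self._cache[query] = best
        return best


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq_seqs(path: str | Path) -> Iterable[str]:
    from Bio import SeqIO

    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fastq"):
            yield str(record.seq)


def demux_and_count(
    fastq_paths: Sequence[str | Path] | str | Path,
    library: "LibraryDef",
    sheet: "SampleSheet",
    max_mismatch: int = 1,
    key_mismatch: int = 0,
    umi_length: int = 10,
) -> tuple[CountMatrix, DemuxReport]:
    """Assign reads to (sample, pMHC) cells and collapse UMIs.

    Both 25-mer barcodes must match (within ``max_mismatch`` substitutions
    each) for a read to be assigned; the DNA key is matched within
    ``key_mismatch`` (default exact).  Returns the count matrix plus a
    report whose discard tally satisfies assigned + discarded = scanned.
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    if max_mismatch < 0 or key_mismatch < 0:
        raise ConfigurationError("mismatch tolerances must be >= 0")

    key_matcher = _Matcher(
        {row.dna_key: row.sample_id for row in sheet.rows}, key_mismatch, "DNA key"
    )
    a_matcher = _Matcher(
        {e.barcode_a: e.pmhc_id for e in library.entries}, max_mismatch, "barcode_a"
    )
    b_matcher = _Matcher(
        {e.barcode_b: e.pmhc_id for e in library.entries}, max_mismatch, "barcode_b"
    )
    klen = key_matcher.length
    alen = a_matcher.length
    blen = b_matcher.length
    read_len = klen + alen + umi_length + blen

    sample_ids = [row.sample_id for row in sheet.rows]
    pmhc_ids = [e.pmhc_id for e in library.entries]
    sidx = {s: j for j, s in enumerate(sample_ids)}
    pidx = {p: i for i, p in enumerate(pmhc_ids)}
    total = np.zeros((len(pmhc_ids), len(sample_ids)), dtype=np.int64)
    clonal = np.zeros_like(total)
    seen_umis: set[tuple[int, int, str]] = set()
    report = DemuxReport()

    for path in fastq_paths:
        for seq in _iter_fastq_seqs(path):
            report.reads_scanned += 1
            if len(seq) < read_len:
                report.discard("too_short")
                continue
            sample = key_matcher.match(seq[:klen])
            if sample is None:
                report.discard("no_key_match")
                continue
            pm_a = a_matcher.match(seq[klen : klen + alen])
            if pm_a is None:
                report.discard("no_barcode_a_match")
                continue
            umi = seq[klen + alen : klen + alen + umi_length]
            pm_b = b_matcher.match(seq[klen + alen + umi_length : read_len])
            if pm_b is None:
                report.discard("no_barcode_b_match")
                continue
            if pm_a != pm_b:
                report.discard("barcode_pair_mismatch")
                continue
            i, j = pidx[pm_a], sidx[sample]
            total[i, j] += 1
            key = (i, j, umi)
            if key not in seen_umis:
                seen_umis.add(key)
                clonal[i, j] += 1
            report.reads_assigned += 1

    return CountMatrix(pmhc_ids, sample_ids, total, clonal), report


# ---------------------------------------------------------------------------
# TSV round trip


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write the wide count-matrix TSV (see docs/formats.md)."""
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, library: "LibraryDef | None" = None) -> CountMatrix:
    """Read a count-matrix TSV; optionally validate row ids against a library.

    Raises
    ------
    SchemaError
        On negative/non-integer entries, clonal > total, or malformed columns.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "pmhc_id":
        raise SchemaError("first column must be 'pmhc_id'")
    value_cols = list(df.columns[1:])
    samples: list[str] = []
    for col in value_cols:
        if col.endswith("_total"):
            sid = col[: -len("_total")]
            if f"{sid}_clonal" not in df.columns:
                raise SchemaError(f"missing clonal column for sample {sid!r}")
            samples.append(sid)
        elif not col.endswith("_clonal"):
            raise SchemaError(f"unrecognized column {col!r}")
    for col in value_cols:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number) or (np.mod(vals, 1) != 0).any():
            raise SchemaError(f"non-integer entries in column {col!r}")
        if (vals < 0).any():
            raise SchemaError(f"negative entries in column {col!r}")
    pmhc_ids = df["pmhc_id"].astype(str).tolist()
    total = df[[f"{s}_total" for s in samples]].to_numpy(dtype=np.int64)
    clonal = df[[f"{s}_clonal" for s in samples]].to_numpy(dtype=np.int64)
    if (clonal > total).any():
        raise SchemaError("clonal counts exceed total counts")
    matrix = CountMatrix(pmhc_ids, samples, total, clonal)
    if library is not None:
        known = {e.pmhc_id for e in library.entries}
        unknown = sorted(set(pmhc_ids) - known)
        if unknown:
            import warnings

            from .errors import DexdynWarning

            warnings.warn(
                f"count matrix contains pmhc_ids not in library: {unknown}",
                DexdynWarning,
                stacklevel=2,
            )
    return matrix


def require_samples(matrix: CountMatrix, sheet: "SampleSheet") -> None:
    """Raise ConsistencyError if counts and sheet disagree on sample ids."""
    sheet_ids = {row.sample_id for row in sheet.rows}
    missing = [s for s in matrix.sample_ids if s not in sheet_ids]
    if missing:
        raise ConsistencyError(f"samples in counts missing from sheet: {missing}")
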