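"""Read filtering: minimum length, low-complexity removal, deduplication.

The chain is fixed (length → complexity → dedupe) and its per-sample
counts satisfy the conservation identity
``input == removed_short + removed_low_complexity + removed_duplicate + retained``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_MIN_LEN = 25          # fragments shorter than this are discarded
DEFAULT_COMPLEXITY = 0.55     # minimum distinct-k-mer fraction
DEFAULT_COMPLEXITY_K = 4


@dataclass(frozen=True)
class Read:
    """A sequenced fragment with sample provenance."""

    read_id: str
    sample_id: str
    sequence: str
    quality: tuple[int, ...] | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QCReport:
    """Per-sample filtering counts; validates the conservation identity."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def add(self, sample_id: str, **kwargs: int) -> None:
        row = self.counts.setdefault(
            sample_id,
            {
                "input": 0,
                "removed_short": 0,
                "removed_low_complexity": 0,
                "removed_duplicate": 0,
                "retained": 0,
            },
        )
        for key, value in kwargs.items():
            row[key] += value

    def validate(self) -> None:
        for sample_id, row in self.counts.items():
            lost = (
                row["removed_short"]
                + row["removed_low_complexity"]
                + row["removed_duplicate"]
            )
            if row["input"] != lost + row["retained"]:
                raise AssertionError(f"QC count identity violated for {sample_id}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.counts, orient="index")
        df.index.name = "sample_id"
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def filter_length(
    reads: Sequence[Read], min_len: int = DEFAULT_MIN_LEN
) -> tuple[list[Read], int]:
    """Drop reads shorter than ``min_len`` (strictly), preserving order."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    retained = [r for r in reads if len(r) >= min_len]
    return retained, len(reads) - len(retained)


def complexity_score(sequence: str, k: int = DEFAULT_COMPLEXITY_K) -> float:
    """Distinct k-mer fraction: unique k-mers over k-mer windows.

    Windows containing N are excluded from both numerator and denominator.
    A sequence too short to hold a single window (or with every window
    masked by Ns) cannot be assessed and scores 1.0 with a warning, so it
    is never discarded on complexity grounds.
    """
    n_windows = len(sequence) - k + 1
    if n_windows < 1:
        warnings.warn(f"sequence of length {len(sequence)} too short to assess (k={k})")
        return 1.0
    kmers = set()
    valid = 0
    for i in range(n_windows):
        window = sequence[i : i + k]
        if "N" in window:
            continue
        valid += 1
        kmers.add(window)
    if valid == 0:
        warnings.warn("all k-mer windows contain N; complexity not assessable")
        return 1.0
    return len(kmers) / valid


def filter_complexity(
    reads: Sequence[Read],
    threshold: float = DEFAULT_COMPLEXITY,
    k: int = DEFAULT_COMPLEXITY_K,
) -> tuple[list[Read], int]:
    """Retain reads whose complexity score is >= threshold (boundary kept)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    retained = [r for r in reads if complexity_score(r.sequence, k=k) >= threshold]
    return retained, len(reads) - len(retained)


def deduplicate(reads: Sequence[Read]) -> tuple[list[Read], int]:
    """Collapse exact sequence duplicates within each sample to the first copy.

    Duplicates across samples are retained: each library is deduplicated
    independently of the pooled run.
    """
    seen: set[tuple[str, str]] = set()
    retained = []
    for read in reads:
        key = (read.sample_id, read.sequence)
        if key in seen:
            continue
        seen.add(key)
        retained.append(read)
    return retained, len(reads) - len(retained)


def run_qc(
    reads: Sequence[Read],
    min_len: int = DEFAULT_MIN_LEN,
    threshold: float = DEFAULT_COMPLEXITY,
    k: int = DEFAULT_COMPLEXITY_K,
) -> tuple[list[Read], QCReport]:
    """Apply the fixed filter chain (length → complexity → dedupe)."""
    report = QCReport()
    by_sample: dict[str, int] = {}
    for r in reads:
        by_sample[r.sample_id] = by_sample.get(r.sample_id, 0) + 1
    for sample_id, n in by_sample.items():
        report.add(sample_id, input=n)

    def _count(before: Sequence[Read], after: Sequence[Read], key: str) -> None:
        removed: dict[str, int] = {}
        kept = {id(r) for r in after}
        for r in before:
            if id(r) not in kept:
                removed[r.sample_id] = removed.get(r.sample_id, 0) + 1
        for sample_id, n in removed.items():
            report.add(sample_id, **{key: n})

    step1, _ = filter_length(reads, min_len=min_len)
    _count(reads, step1, "removed_short")
    step2, _ = filter_complexity(step1, threshold=threshold, k=k)
    _count(step1, step2, "removed_low_complexity")
    step3, _ = deduplicate(step2)
    _count(step2, step3, "removed_duplicate")

    for read in step3:
        report.add(read.sample_id, retained=1)
    report.validate()
    return step3, report


# ---------------------------------------------------------------------------
# FASTQ / FASTA I/O
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path, sample_id: str) -> list[Read]:
    reads = []
    for record in SeqIO.parse(str(path), "fastq"):
        quality = tuple(record.letter_annotations["phred_quality"])
        reads.append(Read(record.id, sample_id, str(record.seq).upper(), quality))
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path, default_quality: int = 37) -> None:
    records = []
    for read in reads:
        record = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        quality = read.quality or tuple([default_quality] * len(read.sequence))
        record.letter_annotations["phred_quality"] = list(quality)
        records.append(record)
    SeqIO.write(records, str(path), "fastq")
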