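"""Read-level quality control for merged/single-end amplicon FASTQ.

A read is excluded when it is shorter than ``min_length`` or when its
expected error — the sum over bases of the Phred-implied error probability
10^(-Q/10) — exceeds ``max_expected_error``; survivors are truncated to a
constant ``trunc_length``. Defaults (EE > 1.0 excluded, 245 nt) follow the
standard expected-error filtering convention for 16S V4 libraries. By default
the expected error is computed on the truncated prefix so the EE contract
refers to the bases that actually enter downstream analysis; computing it on
the full read is available behind ``ee_on_full_read``.

Quality encoding is fixed to Phred+33 (Sanger/Illumina 1.8+); other
encodings are rejected loudly at parse time.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .model import ConfigurationError, FormatError

__all__ = ["QualRead", "QcParams", "QcReport", "expected_error", "qc_filter",
           "read_fastq", "write_fastq"]

REASON_LENGTH = "length"
REASON_EE = "expected_error"


@dataclass(frozen=True)
class QualRead:
    """One sequencing read with per-base Phred quality scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise FormatError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if any(q < 0 for q in self.quals):
            raise FormatError(f"read {self.read_id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class QcParams:
    max_expected_error: float = 1.0
    min_length: int = 245
    trunc_length: int = 245
    ee_on_full_read: bool = False

    def __post_init__(self):
        if self.max_expected_error <= 0 or self.min_length <= 0 or self.trunc_length <= 0:
            raise ConfigurationError("QC parameters must be strictly positive")
        if self.trunc_length > self.min_length:
            raise ConfigurationError(
                "trunc_length may not exceed min_length: retained reads could "
                "not be truncated to the requested constant length"
            )


@dataclass
class QcReport:
    """Partition of the input reads by outcome; conserves the input count."""

    retained: int = 0
    by_reason: dict = field(default_factory=lambda: {REASON_LENGTH: 0, REASON_EE: 0})

    @property
    def total(self) -> int:
        return self.retained + sum(self.by_reason.values())

    def to_rows(self) -> list[tuple[str, int]]:
        return [("retained", self.retained)] + sorted(self.by_reason.items())


def expected_error(read: QualRead | Sequence[int]) -> float:
    """Expected number of erroneous bases: sum_i 10^(-Q_i / 10)."""
    quals = read.quals if isinstance(read, QualRead) else tuple(read)
    if not quals:
        return 0.0
    q = np.asarray(quals, dtype=float)
    return float(np.power(10.0, -q / 10.0).sum())


def qc_filter(reads: Iterable[QualRead], params: QcParams | None = None,
              ) -> tuple[list[QualRead], QcReport]:
    """Filter and truncate reads.

    A read is excluded iff its length is below ``min_length``, or the
    expected error over its first ``trunc_length`` bases (the whole read when
    ``ee_on_full_read``) exceeds ``max_expected_error`` — the threshold is
    strict, EE exactly at the limit is retained. Retained reads are truncated
    to exactly ``trunc_length`` bases.
    """
    params = params or QcParams()
    kept: list[QualRead] = []
    report = QcReport()
    for read in reads:
        if len(read) < params.min_length:
            report.by_reason[REASON_LENGTH] += 1
            continue
        window = read.quals if params.ee_on_full_read \
            else read.quals[: params.trunc_length]
        if expected_error(window) > params.max_expected_error:
            report.by_reason[REASON_EE] += 1
            continue
        kept.append(QualRead(read.read_id,
                             read.bases[: params.trunc_length],
                             read.quals[: params.trunc_length]))
        report.retained += 1
    return kept, report


def _open_maybe_gzip(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path) -> Iterator[QualRead]:
    """Stream Phred+33 FASTQ records (plain or .gz)."""
    with _open_maybe_gzip(path, "r") as handle:
        records = SeqIO.parse(handle, "fastq")
        index = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise FormatError(
                    f"malformed FASTQ in {path} at record {index}: {exc}"
                ) from exc
            yield QualRead(rec.id, str(rec.seq),
                           tuple(rec.letter_annotations["phred_quality"]))
            index += 1


def write_fastq(reads: Iterable[QualRead], path) -> int:
    """Write Phred+33 FASTQ; returns the number of records written."""
    n = 0
    with _open_maybe_gzip(path, "w") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            handle.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    return n
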