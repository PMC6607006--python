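"""Read cleanup for small-RNA libraries.

Three ordered stages: 3'-adapter trimming (TruSeq small-RNA adapter,
minimum 5 nt overlap, reads < 6 nt after trimming discarded), removal of
reads matching rRNA within 2 mismatches, and selection of the 18-35 nt
length window that brackets both miRNA-sized and tRNA-half-sized species.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

from . import align as _align

__all__ = [
    "SmallRNARead",
    "TRUSEQ_ADAPTER",
    "trim_adapter",
    "filter_rrna",
    "select_length",
    "preprocess_reads",
    "PreprocessReport",
    "read_fastq",
    "write_fastq",
]

#: TruSeq small-RNA 3' adapter
TRUSEQ_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class SmallRNARead:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"{self.read_id}: sequence/quality length mismatch"
            )


def read_fastq(path) -> List[SmallRNARead]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            reads.append(SmallRNARead(header.rstrip("\n")[1:].split()[0], seq, qual))
    return reads


def write_fastq(reads: Iterable[SmallRNARead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def trim_adapter(
    read: SmallRNARead,
    adapter: str = TRUSEQ_ADAPTER,
    min_overlap: int = 5,
    min_len: int = 6,
) -> Optional[SmallRNARead]:
    """Trim the 3' adapter; return the trimmed read or None if discarded.

    The leftmost exact occurrence of the full adapter is removed together
    with everything 3' of it.  Failing that, the longest adapter *prefix*
    of at least ``min_overlap`` nt that is a suffix of the read is removed
    (a partially sequenced adapter at the read end).  A read that becomes
    shorter than ``min_len`` is discarded (None); a read with no adapter
    match passes through unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence
    cut = None
    idx = seq.find(adapter)
    if idx != -1:
        cut = idx
    else:
        max_k = min(len(adapter) - 1, len(seq))
        for k in range(max_k, min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                cut = len(seq) - k
                break
    if cut is None:
        return read
    if cut < min_len:
        return None
    return replace(read, sequence=seq[:cut], quality=read.quality[:cut])


def filter_rrna(
    reads: Sequence[SmallRNARead],
    rrna_reference: Sequence[Tuple[str, str]],
    max_mismatches: int = 2,
) -> List[SmallRNARead]:
    """Drop reads that align to rRNA (Hamming, either strand, <= 2 mm)."""
    if not rrna_reference:
        warnings.warn("empty rRNA reference: no reads filtered")
        return list(reads)
    targets = [
        _align.Target(target_id=tid, sequence=seq, both_strands=True)
        for tid, seq in rrna_reference
    ]
    hits = _align.reads_with_hit(reads, targets, max_mismatches)
    return [r for r in reads if r.read_id not in hits]


def select_length(
    reads: Sequence[SmallRNARead], lo: int = 18, hi: int = 35
) -> List[SmallRNARead]:
    if lo > hi:
        raise ValueError("lo must be <= hi")
    return [r for r in reads if lo <= len(r.sequence) <= hi]


@dataclass
class PreprocessReport:
    n_input: int
    n_trimmed: int
    n_discarded_short: int
    n_rrna_dropped: int
    n_length_filtered: int
    n_kept: int

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["stage", "count"])
            w.writerow(["input_reads", self.n_input])
            w.writerow(["adapter_trimmed", self.n_trimmed])
            w.writerow(["discarded_short", self.n_discarded_short])
            w.writerow(["rrna_dropped", self.n_rrna_dropped])
            w.writerow(["length_filtered_out", self.n_length_filtered])
            w.writerow(["kept", self.n_kept])


def preprocess_reads(
    reads: Sequence[SmallRNARead],
    rrna_reference: Sequence[Tuple[str, str]],
    adapter: str = TRUSEQ_ADAPTER,
    min_overlap: int = 5,
    min_len: int = 6,
    length_lo: int = 18,
    length_hi: int = 35,
    max_mismatches: int = 2,
) -> Tuple[List[SmallRNARead], PreprocessReport]:
    """Run trim -> rRNA filter -> length selection and tally a report."""
    trimmed: List[SmallRNARead] = []
    n_trim = n_short = 0
    for r in reads:
        t = trim_adapter(r, adapter, min_overlap, min_len)
        if t is None:
            n_short += 1
            continue
        if t.sequence != r.sequence:
            n_trim += 1
        trimmed.append(t)
    kept_rrna = filter_rrna(trimmed, rrna_reference, max_mismatches)
    n_rrna = len(trimmed) - len(kept_rrna)
    final = select_length(kept_rrna, length_lo, length_hi)
    report = PreprocessReport(
        n_input=len(reads),
        n_trimmed=n_trim,
        n_discarded_short=n_short,
        n_rrna_dropped=n_rrna,
        n_length_filtered=len(kept_rrna) - len(final),
        n_kept=len(final),
    )
    return final, report
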