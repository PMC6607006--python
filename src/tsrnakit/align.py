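"""Mismatch-bounded Hamming alignment of short reads to small references.

All alignments in this pipeline are ungapped with at most a fixed number
of mismatches (default 2), matching bowtie's ``-v`` mode: no indels, no
quality weighting.  For one read, every placement achieving the minimal
mismatch count (the best stratum) is reported, and placements share the
read's unit weight equally, so totals are conserved under residual
multi-mapping.

tRNA cluster targets are searched on the forward strand only (reads are
sequenced from the mature tRNA strand); genomic decoy contigs are searched
on both strands.

The scan is exact: reads are one-hot encoded and match counts for every
window offset are obtained with a matrix product, grouped by read length.
This is O(total reads x target length) but vectorized, which is ample for
references up to a few hundred kilobases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

__all__ = ["Target", "ReadAlignment", "align_reads", "reads_with_hit",
           "revcomp", "write_sam"]

_COMP = str.maketrans("ACGTN", "TGCAN")

_BASE_INDEX = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class Target:
    target_id: str
    sequence: str
    both_strands: bool = False


@dataclass
class ReadAlignment:
    """One placement of a read; ``start``/``end`` are 0-based half-open."""

    read_id: str
    target_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    weight: float = 1.0


def _onehot_windows(t_idx: np.ndarray, length: int) -> np.ndarray:
    """All windows of ``length`` in a target as one-hot rows (w, 4*length)."""
    onehot = (t_idx[:, None] == np.arange(4)).astype(np.float32)
    win = np.lib.stride_tricks.sliding_window_view(onehot, length, axis=0)
    # win: (w, 4, length) -> (w, length, 4) -> (w, 4*length)
    return np.ascontiguousarray(win.transpose(0, 2, 1)).reshape(
        win.shape[0], 4 * length
    )


def _scan_group(
    read_idx: np.ndarray, t_idx: np.ndarray, max_mm: int
) -> List[List[Tuple[int, int]]]:
    """Scan equal-length reads against one target.

    Returns, per read, the list of (offset, mismatches) with mm <= max_mm.
    """
    n, length = read_idx.shape
    if len(t_idx) < length:
        return [[] for _ in range(n)]
    windows = _onehot_windows(t_idx, length)
    r_onehot = (read_idx[:, :, None] == np.arange(4)).astype(np.float32)
    r_flat = r_onehot.reshape(n, 4 * length)
    out: List[List[Tuple[int, int]]] = [[] for _ in range(n)]
    chunk = max(1, int(16e6 // max(1, windows.shape[0])))
    for c0 in range(0, n, chunk):
        matches = r_flat[c0 : c0 + chunk] @ windows.T
        mm = length - np.rint(matches).astype(np.int64)
        rows, cols = np.nonzero(mm <= max_mm)
        for r, c in zip(rows, cols):
            out[c0 + r].append((int(c), int(mm[r, c])))
    return out


def align_reads(
    reads: Sequence,
    targets: Sequence[Target],
    max_mismatches: int = 2,
) -> List[ReadAlignment]:
    """Best-stratum Hamming alignment of reads to targets.

    ``reads`` are objects with ``read_id`` and ``sequence`` attributes.
    All placements at the minimal mismatch count for a read (over every
    target, strand and offset) are reported with weight ``1/n_placements``.
    A read longer than every target simply yields no alignment.
    """
    by_len: Dict[int, List[int]] = {}
    for i, r in enumerate(reads):
        by_len.setdefault(len(r.sequence), []).append(i)

    encoded_targets = [(t, _encode(t.sequence)) for t in targets]
    raw_hits: Dict[int, List[Tuple[str, int, str, int]]] = {}

    for length, idxs in by_len.items():
        if length == 0:
            continue
        fwd = np.stack([_encode(reads[i].sequence) for i in idxs])
        rev = None
        for t, t_idx in encoded_targets:
            strands = [("+", fwd)]
            if t.both_strands:
                if rev is None:
                    rev = np.stack(
                        [_encode(revcomp(reads[i].sequence)) for i in idxs]
                    )
                strands.append(("-", rev))
            for strand, mat in strands:
                for row, hits in enumerate(
                    _scan_group(mat, t_idx, max_mismatches)
                ):
                    if hits:
                        raw_hits.setdefault(idxs[row], []).extend(
                            (t.target_id, off, strand, mm) for off, mm in hits
                        )

    alignments: List[ReadAlignment] = []
    for i in sorted(raw_hits):
        read = reads[i]
        length = len(read.sequence)
        hits = raw_hits[i]
        best = min(mm for _, _, _, mm in hits)
        kept = [h for h in hits if h[3] == best]
        w = 1.0 / len(kept)
        for tid, off, strand, mm in kept:
            alignments.append(
                ReadAlignment(
                    read_id=read.read_id,
                    target_id=tid,
                    start=off,
                    end=off + length,
                    strand=strand,
                    mismatches=mm,
                    weight=w,
                )
            )
    return alignments


def reads_with_hit(
    reads: Sequence, targets: Sequence[Target], max_mismatches: int = 2
) -> Set[str]:
    """Ids of reads with at least one placement within the mismatch bound."""
    return {a.read_id for a in align_reads(reads, targets, max_mismatches)}


def write_sam(
    alignments: Sequence[ReadAlignment],
    targets: Sequence[Target],
    reads: Sequence,
    path,
) -> None:
    """Export alignments as SAM with @SQ lines and NM tags."""
    seqs = {r.read_id: r.sequence for r in reads}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for t in targets:
            fh.write(f"@SQ\tSN:{t.target_id}\tLN:{len(t.sequence)}\n")
        for a in alignments:
            seq = seqs.get(a.read_id, "*")
            flag = 0
            if a.strand == "-" and seq != "*":
                seq = revcomp(seq)
                flag = 16
            cigar = f"{a.end - a.start}M" if seq != "*" else "*"
            qual = "I" * len(seq) if seq != "*" else "*"
            fh.write(
                f"{a.read_id}\t{flag}\t{a.target_id}\t{a.start + 1}\t255\t"
                f"{cigar}\t*\t0\t0\t{seq}\t{qual}\tNM:i:{a.mismatches}\n"
            )
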