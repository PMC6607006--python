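"""tsRNA calling, per-base coverage and composition statistics.

A read counts as a tsRNA when it is 30-35 nt long and has an alignment to
the clustered tRNA reference.  Fragments are labelled by which tRNA end
they derive from: 5' fragments start within the first 4 nucleotides of the
mature tRNA, 3' fragments end within the last 4, everything else is
internal.  Shorter tRNA-mapping reads (18-24 nt, the miRNA-sized window)
are deliberately not called tsRNAs.

Coverage follows the shared-denominator convention: the per-base value of
a cluster is the weighted number of reads spanning that base divided by
the total weighted number of tRNA-mapped reads in the whole sample, so
profiles are comparable across clusters within a sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence
import warnings

import numpy as np
import pandas as pd

from .align import ReadAlignment
from .reference import TRNACluster

__all__ = [
    "TsRNACall",
    "CoverageProfile",
    "call_tsrnas",
    "per_base_coverage",
    "trna_fraction_by_length",
    "count_tsrnas",
    "calls_to_tsv",
    "coverage_matrix",
]

TSRNA_MIN_LEN = 30
TSRNA_MAX_LEN = 35
FIVE_PRIME_MAX_START = 4


@dataclass
class TsRNACall:
    read_id: str
    cluster_id: str
    start_1based: int
    end_1based: int
    length: int
    species: str  # 5prime | 3prime | internal
    is_tsrna: bool
    weight: float


@dataclass
class CoverageProfile:
    cluster_id: str
    coverage: np.ndarray


def call_tsrnas(
    alignments: Sequence[ReadAlignment], clusters: Sequence[TRNACluster]
) -> List[TsRNACall]:
    """Classify tRNA-cluster alignments as tsRNA calls.

    Coordinates are reported 1-based inclusive.  The 3' boundary uses the
    cluster representative's length (representatives are the longest
    member, so 3' labels are with respect to that sequence).
    """
    rep_len = {c.cluster_id: len(c.representative_sequence) for c in clusters}
    calls = []
    for a in alignments:
        if a.target_id not in rep_len:
            raise ValueError(f"alignment to unknown cluster {a.target_id!r}")
        start1 = a.start + 1
        end1 = a.end
        length = a.end - a.start
        if start1 <= FIVE_PRIME_MAX_START:
            species = "5prime"
        elif end1 >= rep_len[a.target_id] - 3:
            species = "3prime"
        else:
            species = "internal"
        calls.append(
            TsRNACall(
                read_id=a.read_id,
                cluster_id=a.target_id,
                start_1based=start1,
                end_1based=end1,
                length=length,
                species=species,
                is_tsrna=TSRNA_MIN_LEN <= length <= TSRNA_MAX_LEN,
                weight=a.weight,
            )
        )
    return calls


def per_base_coverage(
    calls: Sequence[TsRNACall], clusters: Sequence[TRNACluster]
) -> List[CoverageProfile]:
    """Per-base coverage fraction of each cluster.

    coverage[b] = (weighted reads spanning base b) / (total weighted
    tRNA-mapped reads in the sample); the denominator is shared by all
    clusters of the sample.
    """
    total = sum(c.weight for c in calls)
    profiles = []
    by_cluster: Dict[str, List[TsRNACall]] = {}
    for c in calls:
        by_cluster.setdefault(c.cluster_id, []).append(c)
    if total == 0:
        warnings.warn("no tRNA-mapped reads: coverage profiles are all zero")
    for cl in clusters:
        n = len(cl.representative_sequence)
        cov = np.zeros(n)
        for call in by_cluster.get(cl.cluster_id, ()):
            cov[call.start_1based - 1 : call.end_1based] += call.weight
        if total > 0:
            cov /= total
        profiles.append(CoverageProfile(cluster_id=cl.cluster_id, coverage=cov))
    return profiles


def trna_fraction_by_length(
    genome_alignments: Sequence[ReadAlignment],
    trna_alignments: Sequence[ReadAlignment],
    lo: int = 18,
    hi: int = 35,
) -> pd.DataFrame:
    """Fraction of genome-mapped reads of each length that map to tRNA.

    The genome alignment set is expected to include the tRNA placements
    (tRNA loci are part of the genome); the tRNA set restricts to the
    clustered tRNA reference.  Lengths with no genome-mapped reads get NA.
    """
    genome_ids: Dict[int, set] = {}
    for a in genome_alignments:
        genome_ids.setdefault(a.end - a.start, set()).add(a.read_id)
    trna_ids: Dict[int, set] = {}
    for a in trna_alignments:
        trna_ids.setdefault(a.end - a.start, set()).add(a.read_id)
    rows = []
    for s in range(lo, hi + 1):
        denom = len(genome_ids.get(s, ()))
        num = len(trna_ids.get(s, ()))
        rows.append(
            {
                "length": s,
                "n_genome": denom,
                "n_trna": num,
                "fraction": (num / denom) if denom else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("length")


def count_tsrnas(
    calls: Sequence[TsRNACall],
    group_by: str = "cluster",
    species_filter: Optional[str] = "5prime",
    anticodon_map: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Weighted tsRNA counts per cluster (or anticodon).

    Returns a frame with the unrounded weighted sum and the half-up
    rounded integer count used by downstream count models.
    """
    if group_by not in ("cluster", "anticodon"):
        raise ValueError(f"unknown group key {group_by!r}")
    if group_by == "anticodon" and anticodon_map is None:
        raise ValueError("anticodon grouping requires anticodon_map")
    acc: Dict[str, float] = {}
    for c in calls:
        if not c.is_tsrna:
            continue
        if species_filter is not None and c.species != species_filter:
            continue
        if group_by == "cluster":
            key = c.cluster_id
        else:
            try:
                key = anticodon_map[c.cluster_id]
            except KeyError:
                raise ValueError(f"unknown group key for {c.cluster_id!r}")
        acc[key] = acc.get(key, 0.0) + c.weight
    df = pd.DataFrame(
        {
            "weighted": pd.Series(acc, dtype=float).sort_index(),
        }
    )
    df["count"] = np.floor(df["weighted"] + 0.5).astype(int)
    df.index.name = group_by
    return df


def calls_to_tsv(calls: Sequence[TsRNACall], path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "cluster_id": c.cluster_id,
                "start": c.start_1based,
                "end": c.end_1based,
                "length": c.length,
                "species": c.species,
                "is_tsrna": int(c.is_tsrna),
                "weight": round(c.weight, 6),
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def coverage_matrix(profiles: Sequence[CoverageProfile]) -> pd.DataFrame:
    """Clusters x positions coverage table (ragged ends padded with NA)."""
    n = max((len(p.coverage) for p in profiles), default=0)
    mat = np.full((len(profiles), n), np.nan)
    for i, p in enumerate(profiles):
        mat[i, : len(p.coverage)] = p.coverage
    return pd.DataFrame(
        mat,
        index=[p.cluster_id for p in profiles],
        columns=[f"pos{j + 1}" for j in range(n)],
    )
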