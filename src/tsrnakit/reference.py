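"""tRNA reference handling.

Mature tRNA sequences (GtRNAdb-style) are loaded together with a small
annotation table (isotype, anticodon, anticodon position).  Because many
genomic loci encode identical or near-identical tRNAs, reads from the 5'
half of a tRNA cannot be assigned to a single locus.  The remedy used here
is to collapse loci that share their first 50 nucleotides into clusters and
to treat the cluster as the unit of alignment and quantification.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import SeqIO

__all__ = [
    "TRNAGene",
    "TRNACluster",
    "load_trna_fasta",
    "locate_anticodon",
    "cluster_by_prefix",
    "write_clusters_tsv",
    "read_clusters_tsv",
]

_VALID = set("ACGT")

# canonical anticodon position: the anticodon triplet of a standard tRNA
# starts around residue 34; the search window below brackets that.
ANTICODON_WINDOW = (30, 40)


@dataclass
class TRNAGene:
    """One mature tRNA sequence with its anticodon annotation.

    ``anticodon_start`` is the 1-based position of the first anticodon base
    within ``sequence``.
    """

    gene_id: str
    amino_acid: str
    anticodon: str
    sequence: str
    anticodon_start: int
    genome_locus: Optional[tuple] = None

    def validate(self) -> None:
        if not 60 <= len(self.sequence) <= 120:
            raise ValueError(
                f"{self.gene_id}: mature tRNA length {len(self.sequence)} "
                "outside [60, 120]"
            )
        if self.anticodon_start < 25:
            raise ValueError(
                f"{self.gene_id}: anticodon_start {self.anticodon_start} < 25"
            )
        i = self.anticodon_start - 1
        if self.sequence[i : i + 3] != self.anticodon:
            raise ValueError(
                f"{self.gene_id}: sequence[{self.anticodon_start}..] = "
                f"{self.sequence[i:i + 3]!r} does not match anticodon "
                f"{self.anticodon!r}"
            )


@dataclass
class TRNACluster:
    """A set of tRNA genes identical over their first 50 nt."""

    cluster_id: str
    prefix_key: str
    members: list = field(default_factory=list)
    representative_sequence: str = ""
    anticodon_start: int = 0


def _normalize(seq: str, record_id: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(
            f"record {record_id!r}: non-ACGTU character(s) {sorted(bad)}"
        )
    return s


def locate_anticodon(sequence: str, anticodon: str) -> int:
    """Find the 1-based start of the anticodon triplet.

    The triplet is first searched with its start inside the canonical
    window [30, 40]; if absent there, the first occurrence anywhere in the
    sequence is used.  Raises ``ValueError`` if the triplet never occurs.
    """
    lo, hi = ANTICODON_WINDOW
    idx = sequence.find(anticodon, lo - 1, hi - 1 + 3)
    if idx != -1 and lo <= idx + 1 <= hi:
        return idx + 1
    idx = sequence.find(anticodon)
    if idx == -1:
        raise ValueError(f"anticodon {anticodon!r} absent from sequence")
    return idx + 1


def load_trna_fasta(fasta_path, annotation_path) -> list:
    """Load a tRNA FASTA plus its annotation TSV into ``TRNAGene`` records.

    The annotation TSV has columns gene_id, amino_acid, anticodon,
    anticodon_start; anticodon_start may be "NA", in which case the
    position is located from the sequence.
    """
    ann = {}
    with open(annotation_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "amino_acid", "anticodon"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"annotation {annotation_path}: expected columns "
                "gene_id, amino_acid, anticodon[, anticodon_start]"
            )
        for row in reader:
            gid = row["gene_id"]
            if gid in ann:
                raise ValueError(f"duplicate gene_id in annotation: {gid!r}")
            ann[gid] = row

    genes = []
    seen = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gid = rec.id
        if gid in seen:
            raise ValueError(f"duplicate gene_id in FASTA: {gid!r}")
        seen.add(gid)
        if gid not in ann:
            raise ValueError(f"gene {gid!r} present in FASTA but not annotation")
        row = ann[gid]
        seq = _normalize(str(rec.seq), gid)
        anticodon = _normalize(row["anticodon"], gid)
        raw_start = (row.get("anticodon_start") or "NA").strip()
        if raw_start.upper() in ("", "NA", "NAN"):
            start = locate_anticodon(seq, anticodon)
        else:
            start = int(raw_start)
        gene = TRNAGene(
            gene_id=gid,
            amino_acid=row["amino_acid"],
            anticodon=anticodon,
            sequence=seq,
            anticodon_start=start,
        )
        gene.validate()
        genes.append(gene)

    missing = set(ann) - seen
    if missing:
        raise ValueError(
            f"annotation gene_id(s) absent from FASTA: {sorted(missing)[:5]}"
        )
    return genes


def cluster_by_prefix(genes: Sequence[TRNAGene], prefix_len: int = 50) -> list:
    """Group tRNA genes by exact identity of their first ``prefix_len`` nt.

    Genes shorter than ``prefix_len`` use their full sequence as the key.
    Cluster ids are assigned in order of the smallest member gene_id, so
    output is independent of input record order.  The representative is the
    longest member sequence (ties broken by smallest gene_id).
    """
    if prefix_len < 1:
        raise ValueError(f"prefix_len must be >= 1, got {prefix_len}")
    if not genes:
        raise ValueError("no genes to cluster")
    groups: dict = {}
    for g in genes:
        key = g.sequence[: min(prefix_len, len(g.sequence))]
        groups.setdefault(key, []).append(g)

    ordered = sorted(groups.items(), key=lambda kv: min(g.gene_id for g in kv[1]))
    clusters = []
    for i, (key, members) in enumerate(ordered):
        members = sorted(members, key=lambda g: g.gene_id)
        rep = min(members, key=lambda g: (-len(g.sequence), g.gene_id))
        clusters.append(
            TRNACluster(
                cluster_id=f"cluster-{i + 1:04d}",
                prefix_key=key,
                members=[g.gene_id for g in members],
                representative_sequence=rep.sequence,
                anticodon_start=rep.anticodon_start,
            )
        )
    return clusters


def write_clusters_tsv(clusters: Sequence[TRNACluster], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["cluster_id", "prefix_key", "n_members", "member_ids",
                    "anticodon_start"])
        for c in clusters:
            w.writerow([c.cluster_id, c.prefix_key, len(c.members),
                        ",".join(c.members), c.anticodon_start])


def read_clusters_tsv(path) -> list:
    clusters = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            clusters.append(
                TRNACluster(
                    cluster_id=row["cluster_id"],
                    prefix_key=row["prefix_key"],
                    members=row["member_ids"].split(","),
                    representative_sequence="",
                    anticodon_start=int(row["anticodon_start"]),
                )
            )
    return clusters
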