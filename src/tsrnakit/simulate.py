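"""Synthetic data generation with ground-truth manifests.

Every input the pipeline consumes can be generated here: a tRNA reference
with planted anticodons and shared 50-nt prefixes (so clustering has work
to do), small-RNA libraries dominated by 30-35 nt 5'-tRNA fragments mixed
with miRNA-sized reads, rRNA contamination and genomic background,
negative-binomial pulldown count matrices with planted enriched
transcripts, emPAI tables with non-detects, and saturation binding series.

Each generator takes an integer seed and is byte-deterministic given it.
Manifests record the true origin of every emitted record so downstream
stages can be scored exactly.

The 5'-tsRNA read model mirrors the fragment geometry seen in
differentiating mESC libraries: fragments start within the first 1-4
nucleotides of the mature tRNA and end just before the anticodon loop
(1-3 nt upstream of the anticodon), with final lengths clipped to
30-35 nt.  Inserts receive the TruSeq 3' adapter and are truncated to the
machine read length, then per-base substitution errors are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .align import revcomp
from .preprocess import SmallRNARead, TRUSEQ_ADAPTER
from .containers import CountMatrix
from .reference import TRNAGene

__all__ = [
    "LibraryConfig",
    "simulate_trna_reference",
    "random_contigs",
    "simulate_small_rna_library",
    "simulate_count_matrix",
    "simulate_pulldown_counts",
    "simulate_empai_table",
    "simulate_binding_series",
    "write_reference",
    "write_library",
]

_BASES = np.array(list("ACGT"))
_AA_CODES = [
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]

PULLDOWN_SAMPLES = ("LIF_scr", "LIF_ts", "RA_scr", "RA_ts")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


# ---------------------------------------------------------------------------
# tRNA reference


def simulate_trna_reference(
    n_genes: int, n_anticodons: int, seed: int
) -> Tuple[List[TRNAGene], pd.DataFrame]:
    """Simulate a mature-tRNA reference with known cluster structure.

    Genes are 72-90 nt with the anticodon triplet planted at position
    34-36.  Genes of the same anticodon are organized in groups sharing an
    identical first-50-nt prefix (differing only 3' of it), so the planted
    number of prefix clusters is known.  Returns the genes and a manifest
    (gene_id, anticodon, planted_cluster, anticodon_start).
    """
    if not n_genes >= n_anticodons >= 1:
        raise ValueError("need n_genes >= n_anticodons >= 1")
    rng = np.random.default_rng(seed)

    anticodons: List[str] = []
    while len(anticodons) < n_anticodons:
        ac = _random_seq(rng, 3)
        if ac not in anticodons:
            anticodons.append(ac)

    # round-robin gene allocation over anticodons
    counts = [0] * n_anticodons
    for i in range(n_genes):
        counts[i % n_anticodons] += 1

    genes: List[TRNAGene] = []
    manifest_rows = []
    used_prefixes: set = set()
    gi = 0
    cluster_idx = 0
    for ai, (ac, k) in enumerate(zip(anticodons, counts)):
        aa = _AA_CODES[ai % len(_AA_CODES)]
        n_groups = max(1, (k + 1) // 2)
        sizes = [0] * n_groups
        for j in range(k):
            sizes[j % n_groups] += 1
        for g, size in enumerate(sizes):
            prefix, ac_start = _make_prefix(rng, ac, used_prefixes)
            cluster_idx += 1
            for m in range(size):
                gi += 1
                total_len = int(rng.integers(72, 91))
                seq = prefix + _random_seq(rng, total_len - 50)
                gene_id = f"tRNA-{aa}-{ac}-{g + 1}-{m + 1}"
                genes.append(
                    TRNAGene(
                        gene_id=gene_id,
                        amino_acid=aa,
                        anticodon=ac,
                        sequence=seq,
                        anticodon_start=ac_start,
                    )
                )
                manifest_rows.append(
                    {
                        "gene_id": gene_id,
                        "anticodon": ac,
                        "planted_cluster": cluster_idx,
                        "anticodon_start": ac_start,
                    }
                )
    manifest = pd.DataFrame(manifest_rows)
    return genes, manifest


def _make_prefix(rng, anticodon: str, used: set, max_tries: int = 1000) -> Tuple[str, int]:
    """A 50-nt prefix with the anticodon planted at 34-36 and no other
    occurrence of the triplet inside the canonical search window."""
    for _ in range(max_tries):
        pos = int(rng.integers(34, 37))  # 1-based start
        prefix = _random_seq(rng, 50)
        prefix = prefix[: pos - 1] + anticodon + prefix[pos + 2 :]
        window = prefix[29:42]  # triplet starts 30..40 (1-based)
        if window.find(anticodon) != pos - 30:
            continue
        if window.find(anticodon, pos - 30 + 1) != -1:
            continue
        if prefix in used:
            continue
        used.add(prefix)
        return prefix, pos
    raise RuntimeError("could not place anticodon in prefix")


def write_reference(genes: Sequence[TRNAGene], fasta_path, annotation_path) -> None:
    with open(fasta_path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n{g.sequence}\n")
    with open(annotation_path, "w") as fh:
        fh.write("gene_id\tamino_acid\tanticodon\tanticodon_start\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.amino_acid}\t{g.anticodon}\t{g.anticodon_start}\n"
            )


def random_contigs(
    n: int, length: int, seed: int, prefix: str = "contig"
) -> List[Tuple[str, str]]:
    """Random uniform-composition contigs (genome decoys, rRNA stand-ins)."""
    rng = np.random.default_rng(seed)
    return [(f"{prefix}-{i + 1}", _random_seq(rng, length)) for i in range(n)]


# ---------------------------------------------------------------------------
# small-RNA library


@dataclass
class LibraryConfig:
    """Composition and noise model of one simulated small-RNA library.

    Fractions are of all reads; the remainder after tsRNA, miRNA-like and
    rRNA classes is random genomic (decoy) background with insert lengths
    uniform on [18, 35].  With the defaults the expected tRNA share among
    30-35 nt inserts is 0.4 / (0.4 + 0.3 * 6/18) = 0.8.
    """

    n_reads: int = 20000
    tsrna_fraction: float = 0.4
    mirna_fraction: float = 0.2
    rrna_fraction: float = 0.1
    producing_cluster_weights: Optional[Dict[str, float]] = None
    adapter: str = TRUSEQ_ADAPTER
    error_rate: float = 0.001
    read_len: int = 50
    seed: int = 0

    def __post_init__(self):
        total = self.tsrna_fraction + self.mirna_fraction + self.rrna_fraction
        if not 0 <= total <= 1 + 1e-12:
            raise ValueError("class fractions must sum to <= 1")
        if self.producing_cluster_weights is not None:
            w = sum(self.producing_cluster_weights.values())
            if abs(w - 1.0) > 1e-9:
                raise ValueError("producing cluster weights must sum to 1")


def _draw_tsrna_interval(rng, anticodon_start: int) -> Tuple[int, int]:
    """1-based (start, end) of a 5'-tsRNA fragment; raises if geometry
    cannot produce a 30-35 nt fragment ending before the anticodon."""
    for _ in range(100):
        start = int(rng.integers(1, 5))
        end = int(rng.integers(anticodon_start - 3, anticodon_start))
        length = end - start + 1
        if length > 35:
            end = start + 34
            length = 35
        if length < 30:
            end = start + 29
            length = 30
        if end <= anticodon_start - 1:
            return start, end
    raise ValueError(
        f"cannot draw a 30-35 nt 5' fragment before anticodon at "
        f"{anticodon_start}"
    )


def _apply_errors(rng, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < error_rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def simulate_small_rna_library(
    config: LibraryConfig,
    clusters: Sequence,
    decoys: Sequence[Tuple[str, str]],
    rrna: Sequence[Tuple[str, str]],
) -> Tuple[List[SmallRNARead], pd.DataFrame]:
    """Simulate one adapter-ligated small-RNA library.

    ``clusters`` are TRNACluster objects (fragments are drawn from cluster
    representatives).  Returns reads and a manifest with one row per read:
    read_id, cls in {tsrna, mirna, rrna, decoy}, source id, 1-based
    start/end on the source, and insert length.
    """
    rng = np.random.default_rng(config.seed)
    rest = 1.0 - (
        config.tsrna_fraction + config.mirna_fraction + config.rrna_fraction
    )
    probs = [config.tsrna_fraction, config.mirna_fraction,
             config.rrna_fraction, max(rest, 0.0)]
    probs = np.array(probs) / np.sum(probs)

    if config.producing_cluster_weights is None:
        chosen = sorted(c.cluster_id for c in clusters)[: min(5, len(clusters))]
        weights = {cid: 1.0 / len(chosen) for cid in chosen}
    else:
        weights = config.producing_cluster_weights
    by_id = {c.cluster_id: c for c in clusters}
    unknown = set(weights) - set(by_id)
    if unknown:
        raise ValueError(f"unknown producing clusters: {sorted(unknown)}")
    w_ids = sorted(weights)
    w_p = np.array([weights[c] for c in w_ids])

    if config.n_reads and not decoys and (probs[1] > 0 or probs[3] > 0):
        raise ValueError("decoy contigs required for miRNA/background reads")
    if config.n_reads and not rrna and probs[2] > 0:
        raise ValueError("rRNA reference required for rRNA reads")

    reads: List[SmallRNARead] = []
    rows = []
    classes = ("tsrna", "mirna", "rrna", "decoy")
    for i in range(config.n_reads):
        cls = classes[int(rng.choice(4, p=probs))]
        if cls == "tsrna":
            cid = w_ids[int(rng.choice(len(w_ids), p=w_p))]
            cl = by_id[cid]
            start, end = _draw_tsrna_interval(rng, cl.anticodon_start)
            insert = cl.representative_sequence[start - 1 : end]
            source = cid
        elif cls == "mirna":
            sid, seq = decoys[int(rng.integers(0, len(decoys)))]
            length = int(rng.integers(21, 24))
            start = int(rng.integers(1, len(seq) - length + 2))
            end = start + length - 1
            insert = seq[start - 1 : end]
            if rng.random() < 0.5:
                insert = revcomp(insert)
            source = sid
        elif cls == "rrna":
            sid, seq = rrna[int(rng.integers(0, len(rrna)))]
            length = int(rng.integers(28, 36))
            start = int(rng.integers(1, len(seq) - length + 2))
            end = start + length - 1
            insert = seq[start - 1 : end]
            source = sid
        else:
            sid, seq = decoys[int(rng.integers(0, len(decoys)))]
            length = int(rng.integers(18, 36))
            start = int(rng.integers(1, len(seq) - length + 2))
            end = start + length - 1
            insert = seq[start - 1 : end]
            if rng.random() < 0.5:
                insert = revcomp(insert)
            source = sid

        raw = (insert + config.adapter)[: config.read_len]
        raw = _apply_errors(rng, raw, config.error_rate)
        rid = f"read-{i + 1:06d}"
        reads.append(SmallRNARead(rid, raw, "I" * len(raw)))
        rows.append(
            {
                "read_id": rid,
                "cls": cls,
                "source": source,
                "start": start,
                "end": end,
                "insert_len": len(insert),
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["read_id", "cls", "source", "start", "end", "insert_len"]
    )
    return reads, manifest


def write_library(
    reads: Sequence[SmallRNARead],
    manifest: pd.DataFrame,
    fastq_path,
    manifest_path,
    config: Optional[LibraryConfig] = None,
    config_path=None,
) -> None:
    from .preprocess import write_fastq

    write_fastq(reads, fastq_path)
    manifest.to_csv(manifest_path, sep="\t", index=False)
    if config is not None and config_path is not None:
        with open(config_path, "w") as fh:
            yaml.safe_dump(asdict(config), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# count matrices


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance = mean + dispersion * mean^2 (Poisson at 0)."""
    mean = np.asarray(mean, float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_count_matrix(
    n_features: int,
    sample_depths: Mapping[str, float],
    baseline_mean: float = 200.0,
    dispersion: float = 0.1,
    seed: int = 0,
    planted_fc: Optional[Mapping[str, Mapping[str, float]]] = None,
    mean_log_sd: float = 0.5,
) -> Tuple[CountMatrix, pd.DataFrame]:
    """Generic NB count matrix with optional per-feature planted effects.

    Per-feature baseline means are lognormal around ``baseline_mean``
    (sd ``mean_log_sd`` on the log scale, mean-corrected).  ``planted_fc``
    maps feature id -> {sample id: fold change}.  Returns the raw matrix
    and a manifest of true baselines and planted effects.
    """
    rng = np.random.default_rng(seed)
    samples = list(sample_depths)
    features = [f"f{i + 1:05d}" for i in range(n_features)]
    base = baseline_mean * rng.lognormal(
        -0.5 * mean_log_sd**2, mean_log_sd, n_features
    )
    planted_fc = planted_fc or {}
    mat = np.zeros((n_features, len(samples)), dtype=np.int64)
    fidx = {f: i for i, f in enumerate(features)}
    fc = np.ones((n_features, len(samples)))
    for f, per_sample in planted_fc.items():
        for s, v in per_sample.items():
            fc[fidx[f], samples.index(s)] = v
    for j, s in enumerate(samples):
        mean = base * sample_depths[s] * fc[:, j]
        mat[:, j] = _nb_draw(rng, mean, dispersion)
    cm = CountMatrix(
        data=pd.DataFrame(mat, index=features, columns=samples), normalized=False
    )
    manifest = pd.DataFrame({"feature": features, "true_base_mean": base}).set_index(
        "feature"
    )
    return cm, manifest


def simulate_pulldown_counts(
    n_transcripts: int,
    n_enriched: int,
    true_fc: float = 4.0,
    baseline_mean: float = 200.0,
    dispersion: float = 0.01,
    depth_factors: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    mean_log_sd: float = 0.5,
) -> Tuple[CountMatrix, pd.DataFrame]:
    """Pulldown count matrix for {LIF_scr, LIF_ts, RA_scr, RA_ts}.

    Planted transcripts are enriched ``true_fc``-fold in the bait (ts)
    sample of their condition; the planted set is split near-evenly into
    RA-only, LIF-only and both-condition (ubiquitous) transcripts.  The
    default dispersion is small because bait-vs-control pulldowns have no
    biological replicates: count noise is technical.
    """
    if true_fc <= 1:
        raise ValueError("true_fc must be > 1")
    if n_enriched > n_transcripts:
        raise ValueError("n_enriched exceeds n_transcripts")
    rng = np.random.default_rng(seed)
    depth_factors = dict(depth_factors or {s: 1.0 for s in PULLDOWN_SAMPLES})

    features = [f"t{i + 1:05d}" for i in range(n_transcripts)]
    planted = list(rng.choice(n_transcripts, size=n_enriched, replace=False))
    third = n_enriched // 3
    states = {}
    for k, i in enumerate(planted):
        if k < third:
            states[features[i]] = "RA_enriched"
        elif k < 2 * third:
            states[features[i]] = "LIF_enriched"
        else:
            states[features[i]] = "ubiquitous"

    planted_fc: Dict[str, Dict[str, float]] = {}
    for f, st in states.items():
        if st in ("RA_enriched", "ubiquitous"):
            planted_fc.setdefault(f, {})["RA_ts"] = true_fc
        if st in ("LIF_enriched", "ubiquitous"):
            planted_fc.setdefault(f, {})["LIF_ts"] = true_fc

    base = baseline_mean * rng.lognormal(
        -0.5 * mean_log_sd**2, mean_log_sd, n_transcripts
    )
    mat = np.zeros((n_transcripts, 4), dtype=np.int64)
    for j, s in enumerate(PULLDOWN_SAMPLES):
        fc = np.ones(n_transcripts)
        for f, per in planted_fc.items():
            if s in per:
                fc[features.index(f)] = per[s]
        mat[:, j] = _nb_draw(rng, base * depth_factors[s] * fc, dispersion)

    cm = CountMatrix(
        data=pd.DataFrame(mat, index=features, columns=list(PULLDOWN_SAMPLES)),
        normalized=False,
    )
    manifest = pd.DataFrame(
        {
            "transcript_id": features,
            "state": [states.get(f, "none") for f in features],
            "true_base_mean": base,
        }
    ).set_index("transcript_id")
    return cm, manifest


# ---------------------------------------------------------------------------
# emPAI


def simulate_empai_table(
    n_proteins: int,
    n_enriched: int,
    seed: int = 0,
    fold: float = 4.0,
    cv: float = 0.0,
    nondetect_fraction: float = 0.1,
    bead_dominant_fraction: float = 0.05,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """emPAI table (protein_id, beads, LIF, RA) with -1 non-detects.

    Planted proteins carry an exactly ``fold``-times bead-subtracted
    change between states (half RA-enriched, half LIF-enriched);
    background proteins have equal bead-subtracted values in both states.
    ``cv`` applies multiplicative lognormal noise to detected values.
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched exceeds n_proteins")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    ids = [f"P{i + 1:04d}" for i in range(n_proteins)]
    order = rng.permutation(n_proteins)
    n_ra = n_enriched // 2
    classes = {}
    for k, i in enumerate(order):
        if k < n_ra:
            classes[ids[i]] = "enriched_RA"
        elif k < n_enriched:
            classes[ids[i]] = "enriched_LIF"
        else:
            classes[ids[i]] = "background"
    # tail of the background becomes non-detects / bead-dominant records
    bg = [p for p in ids if classes[p] == "background"]
    n_nd = int(nondetect_fraction * n_proteins)
    n_bd = int(bead_dominant_fraction * n_proteins)
    for p in bg[:n_nd]:
        classes[p] = "nondetect"
    for p in bg[n_nd : n_nd + n_bd]:
        classes[p] = "bead_dominant"

    rows = []
    for p in ids:
        cls = classes[p]
        beads = round(float(rng.uniform(0.01, 0.05)), 4)
        v = round(float(rng.uniform(0.05, 2.0)), 4)
        if cls == "enriched_RA":
            lif, ra = beads + v, beads + fold * v
        elif cls == "enriched_LIF":
            lif, ra = beads + fold * v, beads + v
        elif cls == "background":
            lif, ra = beads + v, beads + v
        elif cls == "nondetect":
            lif, ra = NONDETECT_SENTINEL, NONDETECT_SENTINEL
        else:  # bead_dominant
            beads = round(v + 0.5, 4)
            lif, ra = v, v
        if cv > 0:
            noise = np.exp(rng.normal(0.0, sigma, 3))
            beads = beads * noise[0]
            if lif != NONDETECT_SENTINEL:
                lif = lif * noise[1]
            if ra != NONDETECT_SENTINEL:
                ra = ra * noise[2]
        rows.append({"protein_id": p, "beads": beads, "LIF": lif, "RA": ra})
    table = pd.DataFrame(rows)
    manifest = pd.DataFrame(
        {"protein_id": ids, "cls": [classes[p] for p in ids]}
    ).set_index("protein_id")
    return table, manifest


NONDETECT_SENTINEL = -1.0


# ---------------------------------------------------------------------------
# binding series


def simulate_binding_series(
    kd_nM: float,
    bmax: float = 1.0,
    concentrations_nM: Sequence[float] = (20, 40, 80, 200, 400),
    cv: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> List:
    """Saturation binding series with multiplicative lognormal noise.

    signal = bmax * C / (kd + C) * lognormal(median 1, cv); downstream
    fitting normalizes to the highest-concentration point.
    """
    from .interactome import BindingSeries

    if kd_nM <= 0:
        raise ValueError("kd must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations_nM, float)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    out = []
    for _ in range(n_replicates):
        signal = bmax * conc / (kd_nM + conc)
        if cv > 0:
            signal = signal * np.exp(rng.normal(0.0, sigma, conc.size))
        out.append(BindingSeries(concentrations_nM=conc, signal=signal))
    return out
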