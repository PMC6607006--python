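"""tsRNA interactome analysis: emPAI protein enrichment, gene-set tests,
and one-site equilibrium binding fits.

emPAI (exponentially modified protein abundance index) values from bait
and bead-control pulldowns in two cell states are cleaned (non-detect
sentinel -1 replaced by the minimum detected value, bead background
subtracted, bead-dominant records discarded) and proteins with a >2-fold
bead-subtracted change between states are flagged enriched.  Enriched
sets are tested against gene-set collections (GMT) with the Fisher exact
test and BH-FDR.  Binding affinity is estimated from saturation series by
least-squares fitting of the one-site isotherm y = Bmax*C/(Kd+C) on
signal normalized to the highest-concentration point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .differential import bh_adjust
from .pulldown import fisher_two_sided

__all__ = [
    "EmpaiRecord",
    "BindingSeries",
    "KdFit",
    "clean_empai",
    "empai_enriched",
    "geneset_enrichment",
    "read_gmt",
    "fit_kd",
]

NONDETECT = -1.0
ADJ_FLOOR = 0.01  # floor on bead-subtracted values entering ratios


@dataclass
class EmpaiRecord:
    protein_id: str
    empai_beads: float
    empai_LIF: float
    empai_RA: float
    adj_LIF: float = np.nan
    adj_RA: float = np.nan
    log2_ratio: float = np.nan
    discarded_bead_dominant: bool = False
    enriched_RA: bool = False
    enriched_LIF: bool = False


@dataclass
class BindingSeries:
    """Saturation binding observations at increasing ligand concentration."""

    concentrations_nM: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        self.concentrations_nM = np.asarray(self.concentrations_nM, float)
        self.signal = np.asarray(self.signal, float)
        if self.concentrations_nM.shape != self.signal.shape:
            raise ValueError("concentration and signal lengths differ")
        if (np.diff(self.concentrations_nM) <= 0).any():
            raise ValueError("concentrations must be strictly increasing")
        if (self.signal < 0).any():
            raise ValueError("signal must be nonnegative")

    @property
    def normalized(self) -> np.ndarray:
        """Signal relative to the highest-concentration point."""
        top = self.signal[-1]
        if top == 0:
            raise ValueError("signal at maximal concentration is zero")
        return self.signal / top


@dataclass
class KdFit:
    kd_nM: float
    bmax: float
    residual_sum_squares: float
    converged: bool


def clean_empai(table: pd.DataFrame) -> List[EmpaiRecord]:
    """Clean a raw emPAI table (columns protein_id/beads/LIF/RA).

    -1 marks a non-detect and is replaced by the minimum detected value of
    the whole table; bead values are subtracted from each condition; a
    record whose bead value exceeds the condition value in all conditions
    is flagged bead-dominant and excluded from enrichment calls.
    """
    cols = ["beads", "LIF", "RA"]
    vals = table[cols].values.astype(float)
    bad = (vals < 0) & (vals != NONDETECT)
    if bad.any():
        raise ValueError("negative non-sentinel emPAI values present")
    detected = vals[vals != NONDETECT]
    if detected.size == 0:
        raise ValueError("no detected emPAI values in table")
    floor = float(detected.min())
    vals = np.where(vals == NONDETECT, floor, vals)

    records = []
    for (pid, row) in zip(table["protein_id"], vals):
        beads, lif, ra = row
        adj_l = lif - beads
        adj_r = ra - beads
        dominated = (beads > lif) and (beads > ra)
        ratio = max(adj_r, ADJ_FLOOR) / max(adj_l, ADJ_FLOOR)
        records.append(
            EmpaiRecord(
                protein_id=pid,
                empai_beads=beads,
                empai_LIF=lif,
                empai_RA=ra,
                adj_LIF=adj_l,
                adj_RA=adj_r,
                log2_ratio=float(np.log2(ratio)),
                discarded_bead_dominant=dominated,
            )
        )
    return records


def empai_enriched(
    records: Sequence[EmpaiRecord], fold: float = 2.0
) -> List[EmpaiRecord]:
    """Flag records with a > ``fold`` change between states.

    Bead-subtracted values are floored at 0.01 before forming the ratio.
    Bead-dominant records never carry enrichment flags.
    """
    for r in records:
        if r.discarded_bead_dominant:
            r.enriched_RA = r.enriched_LIF = False
            continue
        num = max(r.adj_RA, ADJ_FLOOR)
        den = max(r.adj_LIF, ADJ_FLOOR)
        r.enriched_RA = num / den > fold
        r.enriched_LIF = den / num > fold
    return list(records)


def read_gmt(path) -> Dict[str, set]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: Dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def geneset_enrichment(
    hit_proteins: Sequence[str],
    background: Sequence[str],
    gene_sets: Mapping[str, set],
) -> pd.DataFrame:
    """Fisher exact over-representation of hits in each gene set.

    Background is the full detected-protein universe; sets with no overlap
    with the background are skipped with a warning.  Returns per-set
    counts, two-sided p and BH-FDR q.
    """
    hits = set(hit_proteins)
    bg = set(background)
    if not hits <= bg:
        raise ValueError("hit proteins must be a subset of the background")
    rows = []
    for name, members in gene_sets.items():
        in_bg = members & bg
        if not in_bg:
            warnings.warn(f"gene set {name!r} has no background overlap; skipped")
            continue
        a = len(hits & in_bg)
        b = len(hits - in_bg)
        c = len(in_bg - hits)
        d = len(bg - in_bg - hits)
        p = fisher_two_sided(a, b, c, d)
        rows.append(
            {"gene_set": name, "hits_in_set": a, "hits_out": b,
             "bg_in_set": c, "bg_out": d, "pval": p}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["qval"] = bh_adjust(df["pval"].values)
        df = df.sort_values("pval", kind="mergesort").set_index("gene_set")
    return df


def fit_kd(series: BindingSeries) -> KdFit:
    """Fit the one-site isotherm y = Bmax*C/(Kd+C) to normalized signal.

    Multi-start nonlinear least squares (Kd started at the min, median and
    max concentration); Bmax is free because normalization to the top
    concentration does not imply saturation there.  A fit driven to the
    Kd ~ 0 boundary (signal flat in concentration) is reported with
    converged=False.
    """
    conc = series.concentrations_nM
    if len(np.unique(conc)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.all(series.signal == 0):
        raise ValueError("all-zero binding signal")
    y = series.normalized

    def resid(theta):
        kd, bmax = theta
        return bmax * conc / (kd + conc) - y

    best = None
    for kd0 in (conc.min(), float(np.median(conc)), conc.max()):
        sol = least_squares(
            resid,
            x0=[kd0, max(y.max(), 1e-6)],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol)
    rss, sol = best
    kd, bmax = map(float, sol.x)
    identifiable = kd > 1e-6 * conc.min()
    return KdFit(
        kd_nM=kd,
        bmax=bmax,
        residual_sum_squares=rss,
        converged=bool(sol.success) and identifiable,
    )
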