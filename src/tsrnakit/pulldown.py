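"""tsRNA-mRNA pulldown enrichment analysis.

A biotinylated tsRNA bait and a scrambled control (Scr1) are each pulled
down in two cell states (LIF-maintained pluripotency, RA-induced
differentiation), giving four mRNA libraries: LIF_scr, LIF_ts, RA_scr,
RA_ts.  Transcripts associated with the bait are found by (1) an
expression floor on median-of-ratios normalized counts, (2) a >2-fold
bait/control ratio, and (3) a two-sided Fisher exact test of the
transcript's counts against the rest of the library, bait vs control,
Bonferroni-corrected across tested transcripts.  Significant transcripts
are then allocated to a cell state by their bait-count ratio between RA
and LIF, and annotated against a reference RA-response fold-change table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import CountMatrix
from .differential import normalize_counts, size_factors

__all__ = [
    "SAMPLES",
    "EnrichmentRecord",
    "filter_expressed",
    "fisher_two_sided",
    "fisher_association",
    "call_enriched",
    "allocate_state",
    "classify_targets",
    "analyze_pulldown",
]

SAMPLES = ("LIF_scr", "LIF_ts", "RA_scr", "RA_ts")
CONDITIONS = ("LIF", "RA")
PSEUDO = 0.5  # pseudo-count for zero denominators in fold changes


@dataclass
class EnrichmentRecord:
    transcript_id: str
    counts: dict = field(default_factory=dict)  # normalized, per sample
    fc_LIF: float = np.nan
    fc_RA: float = np.nan
    fisher_p: dict = field(default_factory=dict)  # per condition
    bonf_p: dict = field(default_factory=dict)
    significant: bool = False
    state: str = "none"
    target_class: str = "unknown"


def filter_expressed(norm: CountMatrix, min_value: float = 200.0) -> list:
    """Features with normalized count strictly above the floor in >=1 sample."""
    if not norm.normalized:
        raise ValueError("expression filter requires a normalized matrix")
    keep = (norm.data > min_value).any(axis=1)
    return list(norm.data.index[keep])


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    The p-value sums the hypergeometric point probabilities of all tables
    with the same margins whose probability does not exceed the observed
    one (with a 1e-7 relative tolerance on ties, the R convention).
    Log-space hypergeometric pmf, so large margins are fine.
    """
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative cell in Fisher table: {[a, b, c, d]}")
    n1, n2, k = a + b, c + d, a + c
    lo, hi = max(0, k - n2), min(n1, k)
    if lo == hi:
        return 1.0
    support = np.arange(lo, hi + 1)
    logp = (
        _log_binom(n1, support)
        + _log_binom(n2, k - support)
        - _log_binom(n1 + n2, k)
    )
    cutoff = logp[a - lo] + np.log1p(1e-7)
    return float(min(1.0, np.exp(logp[logp <= cutoff]).sum()))


def fisher_association(
    transcript_counts: Mapping[str, float],
    library_totals: Mapping[str, float],
    condition: str,
) -> float:
    """Two-sided Fisher exact p for bait-vs-control association.

    2x2 table: transcript count vs rest-of-library count, in the bait (ts)
    and scramble (scr) pulldowns of one condition.  Counts are rounded
    half-up to integers.
    """
    ts_key, scr_key = f"{condition}_ts", f"{condition}_scr"
    a = int(np.floor(transcript_counts[ts_key] + 0.5))
    c = int(np.floor(transcript_counts[scr_key] + 0.5))
    b = int(np.floor(library_totals[ts_key] + 0.5)) - a
    d = int(np.floor(library_totals[scr_key] + 0.5)) - c
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative cell in Fisher table: {[a, b, c, d]}")
    return fisher_two_sided(a, b, c, d)


def _fold_change(num: float, den: float) -> float:
    return (num if num > 0 else PSEUDO) / (den if den > 0 else PSEUDO)


def call_enriched(
    records: Sequence[EnrichmentRecord],
    alpha: float = 0.05,
    fc_cutoff: float = 2.0,
) -> None:
    """Flag significant records: fc > cutoff and Bonferroni p < alpha in
    at least one condition (m = number of tested transcripts)."""
    m = len(records)
    for cond in CONDITIONS:
        p = np.array([r.fisher_p[cond] for r in records])
        bonf = np.minimum(1.0, p * m)
        for r, b in zip(records, bonf):
            r.bonf_p[cond] = float(b)
    for r in records:
        r.significant = any(
            (getattr(r, f"fc_{c}") > fc_cutoff) and (r.bonf_p[c] < alpha)
            for c in CONDITIONS
        )


def allocate_state(
    records: Sequence[EnrichmentRecord], cutoff: float = 2.0
) -> None:
    """Assign significant records to RA_enriched / LIF_enriched / ubiquitous.

    The allocation ratio is the bait's normalized count in RA over LIF
    (0.5 pseudo-count on zeros).  Records enriched over control in both
    conditions with a ratio inside [1/cutoff, cutoff] are ubiquitous.
    """
    for r in records:
        if not r.significant:
            r.state = "none"
            continue
        ratio = _fold_change(r.counts["RA_ts"], r.counts["LIF_ts"])
        if ratio > cutoff:
            r.state = "RA_enriched"
        elif ratio < 1.0 / cutoff:
            r.state = "LIF_enriched"
        elif r.fc_LIF > cutoff and r.fc_RA > cutoff:
            r.state = "ubiquitous"
        else:
            r.state = "none"


def classify_targets(
    records: Sequence[EnrichmentRecord],
    reference_fc: Mapping[str, float],
    up_cutoff: float = 2.0,
    down_cutoff: float = 0.5,
) -> None:
    """Annotate records against a reference RA-vs-stem fold-change table.

    Transcripts >2-fold up after RA are differentiation-responsive,
    >2-fold down are pluripotency-associated.
    """
    for r in records:
        fc = reference_fc.get(r.transcript_id)
        if fc is None:
            r.target_class = "unknown"
        elif not np.isfinite(fc) or fc < 0:
            raise ValueError(
                f"malformed reference fold change for {r.transcript_id!r}: {fc}"
            )
        elif fc > up_cutoff:
            r.target_class = "differentiation_responsive"
        elif fc < down_cutoff:
            r.target_class = "pluripotency_associated"
        else:
            r.target_class = "other"


def analyze_pulldown(
    raw: CountMatrix,
    min_value: float = 200.0,
    fc_cutoff: float = 2.0,
    alpha: float = 0.05,
    reference_fc: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Full pulldown analysis on a raw 4-sample count matrix.

    Returns one row per transcript surviving the expression filter, with
    fold changes, Fisher/Bonferroni p-values, significance, state and
    target class.
    """
    missing = set(SAMPLES) - set(raw.data.columns)
    if missing:
        raise ValueError(f"pulldown matrix missing samples: {sorted(missing)}")
    norm = normalize_counts(raw, size_factors(raw))
    expressed = filter_expressed(norm, min_value)
    sub = norm.data.loc[expressed]
    totals = {s: float(norm.data[s].sum()) for s in SAMPLES}

    records = []
    for tid, row in sub.iterrows():
        rec = EnrichmentRecord(
            transcript_id=tid, counts={s: float(row[s]) for s in SAMPLES}
        )
        rec.fc_LIF = _fold_change(rec.counts["LIF_ts"], rec.counts["LIF_scr"])
        rec.fc_RA = _fold_change(rec.counts["RA_ts"], rec.counts["RA_scr"])
        for cond in CONDITIONS:
            rec.fisher_p[cond] = fisher_association(rec.counts, totals, cond)
        records.append(rec)

    call_enriched(records, alpha=alpha, fc_cutoff=fc_cutoff)
    allocate_state(records, cutoff=fc_cutoff)
    if reference_fc is not None:
        classify_targets(records, reference_fc)

    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                **{s: r.counts[s] for s in SAMPLES},
                "fc_LIF": r.fc_LIF,
                "fc_RA": r.fc_RA,
                "fisher_p_LIF": r.fisher_p["LIF"],
                "fisher_p_RA": r.fisher_p["RA"],
                "bonf_p_LIF": r.bonf_p["LIF"],
                "bonf_p_RA": r.bonf_p["RA"],
                "significant": r.significant,
                "state": r.state,
                "target_class": r.target_class,
            }
            for r in records
        ]
    ).set_index("transcript_id")


def summarize_states(result: pd.DataFrame) -> pd.Series:
    """Set sizes of the associated/RA/LIF/ubiquitous partition."""
    sig = result[result["significant"]]
    return pd.Series(
        {
            "associated": len(sig),
            "RA_enriched": int((sig["state"] == "RA_enriched").sum()),
            "LIF_enriched": int((sig["state"] == "LIF_enriched").sum()),
            "ubiquitous": int((sig["state"] == "ubiquitous").sum()),
        }
    )
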