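from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from tsrnakit.containers import CountMatrix
from tsrnakit.differential import normalize_counts
from tsrnakit.pulldown import (
    EnrichmentRecord,
    allocate_state,
    analyze_pulldown,
    call_enriched,
    classify_targets,
    filter_expressed,
    fisher_two_sided,
    summarize_states,
)
from tsrnakit.simulate import simulate_pulldown_counts

SAMPLES = ["LIF_scr", "LIF_ts", "RA_scr", "RA_ts"]


def exact_fisher_enumeration(a, b, c, d):
    """Integer-arithmetic two-sided Fisher oracle (no floats in the pmf)."""
    n1, n2, k = a + b, c + d, a + c
    lo, hi = max(0, k - n2), min(n1, k)
    num = {x: comb(n1, x) * comb(n2, k - x) for x in range(lo, hi + 1)}
    obs = num[a]
    total = sum(num.values())
    # 1e-7 relative slack on ties, applied in exact rational arithmetic
    keep = [v for v in num.values() if Fraction(v, obs) <= 1 + Fraction(1, 10**7)]
    return float(Fraction(sum(keep), total))


class TestFisher:
    def test_identical_margins_p1(self):
        assert fisher_two_sided(10, 990, 10, 990) == 1.0

    def test_diagonal_table(self):
        assert fisher_two_sided(5, 0, 0, 5) == pytest.approx(1 / 126, rel=1e-12)

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            assert fisher_two_sided(a, b, c, d) == pytest.approx(
                exact_fisher_enumeration(a, b, c, d), abs=1e-10
            )

    def test_row_and_column_swap_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            p = fisher_two_sided(a, b, c, d)
            assert fisher_two_sided(c, d, a, b) == pytest.approx(p, rel=1e-9)
            assert fisher_two_sided(b, a, d, c) == pytest.approx(p, rel=1e-9)

    def test_negative_raises(self):
        with pytest.raises(ValueError, match="negative"):
            fisher_two_sided(-1, 2, 3, 4)


class TestFilterExpressed:
    def _norm(self, rows):
        df = pd.DataFrame(rows, columns=SAMPLES,
                          index=[f"t{i}" for i in range(len(rows))])
        return CountMatrix(data=df, normalized=True)

    def test_strict_boundary(self):
        norm = self._norm([[200.0, 200.0, 200.0, 200.0],
                           [201.0, 0.0, 0.0, 0.0]])
        assert filter_expressed(norm) == ["t1"]

    def test_raw_matrix_rejected(self):
        raw = CountMatrix(
            data=pd.DataFrame([[1, 2, 3, 4]], columns=SAMPLES, index=["t0"])
        )
        with pytest.raises(ValueError, match="normalized"):
            filter_expressed(raw)

    def test_monotone_in_floor(self):
        rng = np.random.default_rng(2)
        norm = self._norm(rng.uniform(0, 500, size=(200, 4)))
        prev = set(filter_expressed(norm, 100))
        for floor in (200, 300, 400):
            cur = set(filter_expressed(norm, floor))
            assert cur <= prev
            prev = cur


def _record(tid="t1", lif_scr=100, lif_ts=100, ra_scr=100, ra_ts=100,
            p_lif=1.0, p_ra=1.0):
    r = EnrichmentRecord(
        transcript_id=tid,
        counts={"LIF_scr": lif_scr, "LIF_ts": lif_ts,
                "RA_scr": ra_scr, "RA_ts": ra_ts},
    )
    r.fc_LIF = (lif_ts or 0.5) / (lif_scr or 0.5)
    r.fc_RA = (ra_ts or 0.5) / (ra_scr or 0.5)
    r.fisher_p = {"LIF": p_lif, "RA": p_ra}
    return r


class TestCallAndAllocate:
    def test_significant_needs_both_gates(self):
        strong = _record("t1", ra_scr=100, ra_ts=300, p_ra=1e-6)
        weak_fc = _record("t2", ra_scr=100, ra_ts=150, p_ra=1e-6)
        weak_p = _record("t3", ra_scr=100, ra_ts=300, p_ra=0.01)
        recs = [strong, weak_fc, weak_p] + [_record(f"x{i}") for i in range(997)]
        call_enriched(recs)
        assert strong.significant
        assert not weak_fc.significant  # fold-change gate
        assert not weak_p.significant  # Bonferroni with m=1000
        assert strong.bonf_p["RA"] == pytest.approx(1e-3)

    def test_allocation_rules(self):
        ra = _record("t1", ra_ts=400, lif_ts=50, ra_scr=50, p_ra=1e-9)
        lif = _record("t2", ra_ts=50, lif_ts=400, lif_scr=50, p_lif=1e-9)
        ubi = _record("t3", ra_ts=300, lif_ts=300, ra_scr=50, lif_scr=50,
                      p_ra=1e-9, p_lif=1e-9)
        recs = [ra, lif, ubi]
        call_enriched(recs)
        allocate_state(recs)
        assert ra.state == "RA_enriched"
        assert lif.state == "LIF_enriched"
        assert ubi.state == "ubiquitous"

    def test_insignificant_gets_none(self):
        r = _record("t1")
        call_enriched([r])
        allocate_state([r])
        assert r.state == "none"


class TestClassifyTargets:
    def test_classes(self):
        recs = [_record(t) for t in ("up", "down", "mid", "missing")]
        classify_targets(recs, {"up": 4.0, "down": 0.25, "mid": 1.2})
        assert [r.target_class for r in recs] == [
            "differentiation_responsive", "pluripotency_associated",
            "other", "unknown",
        ]

    def test_malformed_table(self):
        r = _record("t1")
        with pytest.raises(ValueError, match="malformed"):
            classify_targets([r], {"t1": float("nan")})


class TestPlantedRecovery:
    def test_full_analysis_recovers_planted_sets(self):
        cm, manifest = simulate_pulldown_counts(2000, 60, seed=21)
        res = analyze_pulldown(cm)
        planted = set(manifest.index[manifest.state != "none"])
        called = set(res.index[res.significant])
        recall = len(called & planted) / len(planted)
        assert recall >= 0.9
        assert len(called - planted) <= 2
        for st in ("RA_enriched", "LIF_enriched", "ubiquitous"):
            idx = manifest.index[manifest.state == st]
            hit = (res.loc[res.index.intersection(idx), "state"] == st).sum()
            assert hit / len(idx) >= 0.9

    def test_label_swap_maps_fc_and_keeps_p(self):
        cm, _ = simulate_pulldown_counts(300, 10, seed=22)
        res = analyze_pulldown(cm)
        swapped = cm.data.rename(
            columns={"LIF_scr": "LIF_ts", "LIF_ts": "LIF_scr",
                     "RA_scr": "RA_ts", "RA_ts": "RA_scr"}
        )[list(cm.data.columns)]
        res2 = analyze_pulldown(CountMatrix(data=swapped))
        common = res.index.intersection(res2.index)
        assert np.allclose(
            res.loc[common, "fc_LIF"], 1.0 / res2.loc[common, "fc_LIF"],
            rtol=1e-9,
        )
        assert np.allclose(
            res.loc[common, "fisher_p_LIF"], res2.loc[common, "fisher_p_LIF"],
            rtol=1e-7,
        )

    def test_summary_partition(self):
        cm, _ = simulate_pulldown_counts(1000, 30, seed=23)
        res = analyze_pulldown(cm)
        summary = summarize_states(res)
        assert summary["associated"] >= (
            summary["RA_enriched"] + summary["LIF_enriched"]
            + summary["ubiquitous"]
        )
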