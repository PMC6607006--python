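import numpy as np
import pytest

from tsrnakit.align import Target, align_reads, revcomp, write_sam
from tsrnakit.calling import (
    call_tsrnas,
    count_tsrnas,
    per_base_coverage,
    trna_fraction_by_length,
)
from tsrnakit.preprocess import SmallRNARead, preprocess_reads


def _read(seq, rid="r1"):
    return SmallRNARead(rid, seq, "I" * len(seq))


def brute_force_scan(reads, targets, max_mm):
    """Independent exhaustive Hamming scan (sliding-window comparison)."""
    out = {}
    for r in reads:
        arr = np.frombuffer(r.sequence.encode(), dtype=np.uint8)
        hits = []
        for t in targets:
            strands = [("+", r.sequence)]
            if t.both_strands:
                strands.append(("-", revcomp(r.sequence)))
            tarr = np.frombuffer(t.sequence.encode(), dtype=np.uint8)
            if len(tarr) < len(arr):
                continue
            win = np.lib.stride_tricks.sliding_window_view(tarr, len(arr))
            for strand, q in strands:
                qarr = np.frombuffer(q.encode(), dtype=np.uint8)
                mm = (win != qarr).sum(axis=1)
                for off in np.nonzero(mm <= max_mm)[0]:
                    hits.append((t.target_id, int(off), strand, int(mm[off])))
        if hits:
            best = min(h[3] for h in hits)
            out[r.read_id] = sorted(h for h in hits if h[3] == best)
    return out


class TestAligner:
    def test_exact_prefix_single_hit(self, clusters):
        cl = clusters[0]
        read = _read(cl.representative_sequence[:33])
        targets = [Target(c.cluster_id, c.representative_sequence) for c in clusters]
        aln = align_reads([read], targets)
        ours = [a for a in aln if a.target_id == cl.cluster_id and a.start == 0]
        assert len(ours) == 1
        a = ours[0]
        assert (a.mismatches, a.end) == (0, 33)
        # weight shared over all equally-good placements sums to 1
        assert sum(x.weight for x in aln) == pytest.approx(1.0)

    def test_multi_cluster_weight_split(self):
        t1 = Target("c1", "A" * 20 + "C" * 40)
        t2 = Target("c2", "A" * 20 + "G" * 40)
        aln = align_reads([_read("A" * 20)], [t1, t2])
        # exact hit at the start of both targets
        starts0 = [a for a in aln if a.start == 0]
        assert {a.target_id for a in starts0} == {"c1", "c2"}
        assert all(a.weight == pytest.approx(1.0 / len(aln)) for a in aln)
        assert sum(a.weight for a in aln) == pytest.approx(1.0)

    def test_best_stratum_only(self):
        t = Target("c1", "ACGTACGTACGTACGTACGT" + "T" * 30)
        # exact at 0; the same read with 1 mismatch elsewhere is suppressed
        aln = align_reads([_read("ACGTACGTACGT")], [t])
        assert all(a.mismatches == 0 for a in aln)

    def test_reverse_strand_decoy(self, decoys):
        tid, seq = decoys[0]
        frag = revcomp(seq[500:530])
        targets = [Target(tid, seq, both_strands=True)]
        aln = align_reads([_read(frag)], targets)
        assert any(a.strand == "-" and a.start == 500 for a in aln)

    def test_read_longer_than_target(self):
        aln = align_reads([_read("A" * 50)], [Target("t", "A" * 20)])
        assert aln == []

    def test_matches_brute_force(self, clean_library, clusters, decoys, rrna):
        cfg, reads, _ = clean_library
        cleaned, _ = preprocess_reads(reads, rrna, adapter=cfg.adapter)
        sub = cleaned[:500]
        targets = [
            Target(c.cluster_id, c.representative_sequence) for c in clusters
        ] + [Target(t, s, both_strands=True) for t, s in decoys]
        aln = align_reads(sub, targets, 2)
        got = {}
        for a in aln:
            got.setdefault(a.read_id, []).append(
                (a.target_id, a.start, a.strand, a.mismatches)
            )
        expected = brute_force_scan(sub, targets, 2)
        assert {k: sorted(v) for k, v in got.items()} == expected

    def test_mismatch_monotonicity(self, clean_library, clusters, rrna):
        cfg, reads, _ = clean_library
        cleaned, _ = preprocess_reads(reads, rrna, adapter=cfg.adapter)
        targets = [
            Target(c.cluster_id, c.representative_sequence) for c in clusters
        ]
        prev: set = set()
        for mm in (0, 1, 2):
            ids = {a.read_id for a in align_reads(cleaned[:300], targets, mm)}
            assert prev <= ids
            prev = ids

    def test_sam_export_parses(self, tmp_path, clusters):
        cl = clusters[0]
        read = _read(cl.representative_sequence[:33])
        targets = [Target(c.cluster_id, c.representative_sequence) for c in clusters]
        aln = align_reads([read], targets)
        path = tmp_path / "out.sam"
        write_sam(aln, targets, [read], path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("@HD")
        body = [l for l in lines if not l.startswith("@")]
        assert body and body[0].split("\t")[2] == aln[0].target_id
        assert body[0].endswith("NM:i:0")


class TestCalling:
    def _aln(self, cid, start0, length, w=1.0, rid="r1"):
        from tsrnakit.align import ReadAlignment

        return ReadAlignment(rid, cid, start0, start0 + length, "+", 0, w)

    def test_five_prime_call(self, clusters):
        cid = clusters[0].cluster_id
        (call,) = call_tsrnas([self._aln(cid, 0, 33)], clusters)
        assert call.is_tsrna and call.species == "5prime"
        assert (call.start_1based, call.end_1based) == (1, 33)

    def test_short_read_not_tsrna(self, clusters):
        cid = clusters[0].cluster_id
        (call,) = call_tsrnas([self._aln(cid, 0, 22)], clusters)
        assert call.species == "5prime" and not call.is_tsrna

    def test_three_prime_and_internal(self, clusters):
        cl = clusters[0]
        L = len(cl.representative_sequence)
        (c3,) = call_tsrnas([self._aln(cl.cluster_id, L - 31, 31)], clusters)
        assert c3.species == "3prime"
        (ci,) = call_tsrnas([self._aln(cl.cluster_id, 10, 30)], clusters)
        assert ci.species == "internal"

    def test_unknown_cluster_errors(self, clusters):
        with pytest.raises(ValueError, match="unknown cluster"):
            call_tsrnas([self._aln("nope", 0, 33)], clusters)

    def test_manifest_oracle_5prime_set(self, clean_library, clusters, rrna):
        cfg, reads, manifest = clean_library
        cleaned, _ = preprocess_reads(reads, rrna, adapter=cfg.adapter)
        targets = [
            Target(c.cluster_id, c.representative_sequence) for c in clusters
        ]
        calls = call_tsrnas(align_reads(cleaned, targets), clusters)
        called = {c.read_id for c in calls if c.is_tsrna and c.species == "5prime"}
        assert called == set(manifest.read_id[manifest.cls == "tsrna"])


class TestCoverage:
    def _aln(self, cid, start0, length, rid, w=1.0):
        from tsrnakit.align import ReadAlignment

        return ReadAlignment(rid, cid, start0, start0 + length, "+", 0, w)

    def test_single_read_profile(self, clusters):
        cl = clusters[0]
        calls = call_tsrnas([self._aln(cl.cluster_id, 0, 33, "r1")], clusters)
        profiles = per_base_coverage(calls, clusters)
        prof = {p.cluster_id: p.coverage for p in profiles}[cl.cluster_id]
        assert np.allclose(prof[:33], 1.0)
        assert np.allclose(prof[33:], 0.0)

    def test_shared_denominator(self, clusters):
        c1, c2 = clusters[0], clusters[1]
        calls = call_tsrnas(
            [self._aln(c1.cluster_id, 0, 33, "r1"),
             self._aln(c2.cluster_id, 0, 30, "r2")],
            clusters,
        )
        profiles = {p.cluster_id: p.coverage for p in per_base_coverage(calls, clusters)}
        assert profiles[c1.cluster_id][0] == pytest.approx(0.5)
        assert profiles[c2.cluster_id][0] == pytest.approx(0.5)

    def test_conservation_of_read_bases(self, clean_library, clusters, rrna):
        cfg, reads, _ = clean_library
        cleaned, _ = preprocess_reads(reads, rrna, adapter=cfg.adapter)
        targets = [
            Target(c.cluster_id, c.representative_sequence) for c in clusters
        ]
        calls = call_tsrnas(align_reads(cleaned, targets), clusters)
        total = sum(c.weight for c in calls)
        profiles = per_base_coverage(calls, clusters)
        covered = sum(p.coverage.sum() for p in profiles) * total
        expected = sum(c.weight * c.length for c in calls)
        assert covered == pytest.approx(expected, rel=1e-9)

    def test_zero_reads_warns(self, clusters):
        with pytest.warns(UserWarning, match="no tRNA-mapped"):
            profiles = per_base_coverage([], clusters)
        assert all((p.coverage == 0).all() for p in profiles)


class TestComposition:
    def test_all_31mers_trna(self, clusters):
        from tsrnakit.align import ReadAlignment

        trna = [ReadAlignment(f"r{i}", clusters[0].cluster_id, 0, 31, "+", 0, 1.0)
                for i in range(5)]
        table = trna_fraction_by_length(trna, trna)
        assert table.loc[31, "fraction"] == 1.0
        assert np.isnan(table.loc[20, "fraction"])

    def test_pooled_fraction_matches_truth(self, clean_library, clusters,
                                           decoys, rrna):
        cfg, reads, manifest = clean_library
        cleaned, _ = preprocess_reads(reads, rrna, adapter=cfg.adapter)
        trna_targets = [
            Target(c.cluster_id, c.representative_sequence) for c in clusters
        ]
        decoy_targets = [Target(t, s, both_strands=True) for t, s in decoys]
        trna_aln = align_reads(cleaned, trna_targets)
        genome_aln = trna_aln + align_reads(cleaned, decoy_targets)
        table = trna_fraction_by_length(genome_aln, trna_aln)
        pooled = table.loc[30:35]
        frac = pooled.n_trna.sum() / pooled.n_genome.sum()
        sub = manifest[(manifest.insert_len >= 30) & (manifest.insert_len <= 35)
                       & (manifest.cls != "rrna")]
        truth = (sub.cls == "tsrna").mean()
        assert frac == pytest.approx(truth, abs=1e-9)


class TestCounting:
    def _call(self, cid, w, rid):
        from tsrnakit.calling import TsRNACall

        return TsRNACall(rid, cid, 1, 33, 33, "5prime", True, w)

    def test_unit_weights(self):
        calls = [self._call("c1", 1.0, f"r{i}") for i in range(10)]
        df = count_tsrnas(calls)
        assert df.loc["c1", "count"] == 10

    def test_fractional_rounding_half_up(self):
        calls = [self._call("c1", 0.5, "r1"), self._call("c1", 0.5, "r2")]
        assert count_tsrnas(calls).loc["c1", "count"] == 1
        calls3 = calls + [self._call("c1", 0.5, "r3")]
        assert count_tsrnas(calls3).loc["c1", "count"] == 2  # 1.5 rounds up

    def test_species_filter(self):
        from tsrnakit.calling import TsRNACall

        calls = [
            TsRNACall("r1", "c1", 1, 33, 33, "5prime", True, 1.0),
            TsRNACall("r2", "c1", 10, 40, 31, "internal", True, 1.0),
            TsRNACall("r3", "c1", 1, 22, 22, "5prime", False, 1.0),
        ]
        assert count_tsrnas(calls).loc["c1", "count"] == 1

    def test_manifest_tallies(self, clean_library, clusters, rrna):
        cfg, reads, manifest = clean_library
        cleaned, _ = preprocess_reads(reads, rrna, adapter=cfg.adapter)
        targets = [
            Target(c.cluster_id, c.representative_sequence) for c in clusters
        ]
        calls = call_tsrnas(align_reads(cleaned, targets), clusters)
        counts = count_tsrnas(calls)
        truth = manifest[manifest.cls == "tsrna"].groupby("source").size()
        assert counts["weighted"].sum() == pytest.approx(truth.sum())
        # per-cluster weighted totals match the manifest tallies
        for cid, n in truth.items():
            assert counts.loc[cid, "weighted"] == pytest.approx(n, abs=1e-9)
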