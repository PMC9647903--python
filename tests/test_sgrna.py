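"""sgRNA candidate enumeration, ranking, cut-site prediction, specificity."""

import numpy as np
import pytest

from krabzfp.annotation import ZnFArrayAnnotation, LinkerUnit, annotate_table, find_pam_offsets
from krabzfp.clusters import Cluster, call_clusters
from krabzfp.io import GeneRecord, GeneTable
from krabzfp.sgrna import (
    DesignLog,
    SgRNACandidate,
    enumerate_candidates,
    predict_cut_sites,
    revcomp,
    select_top,
    specificity_report,
)


def linker_only_gene(gene_id, cds, linker_nt_ranges):
    """A gene whose annotation carries linkers at the given CDS nt ranges
    (each range must be codon-aligned)."""
    rec = GeneRecord(gene_id, "m", "chr1", 1, len(cds), "+",
                     protein_seq="X" * (len(cds) // 3), cds_seq=cds)
    linkers = []
    for i, (lo, hi) in enumerate(linker_nt_ranges, start=1):
        nt = cds[lo:hi]
        linkers.append(
            LinkerUnit(gene_id, i, (lo // 3 + 1, hi // 3), "X" * ((hi - lo) // 3),
                       nt, find_pam_offsets(nt))
        )
    ann = ZnFArrayAnnotation(gene_id=gene_id, znfs=[], linkers=linkers)
    return rec, ann


def naive_candidates(cds, linker_nt_ranges):
    """Oracle: scan the CDS directly for NGG starting inside a linker range."""
    out = {}
    for p in range(len(cds) - 2):
        if cds[p + 1 : p + 3] != "GG":
            continue
        if not any(lo <= p <= hi - 3 for lo, hi in linker_nt_ranges):
            continue
        if p < 20:
            continue
        out[cds[p - 20 : p]] = out.get(cds[p - 20 : p], 0) + 1
    return out


def naive_cut_sites(candidate, cds, max_mismatches):
    """Oracle: sliding-window Hamming comparison on both strands."""
    hits = []
    for strand, seq in (("+", cds), ("-", revcomp(cds))):
        for p in range(len(seq) - 22):
            if seq[p + 21 : p + 23] != "GG":
                continue
            mm = sum(a != b for a, b in zip(seq[p : p + 20], candidate))
            if mm <= max_mismatches:
                hits.append((strand, p, mm))
    return sorted(hits)


class TestEnumerate:
    def test_window_rule(self):
        # PAM at CDS offset 23: protospacer = the 20 nt immediately 5' of N
        cds = "TTT" + "ACGTACGTACGTACGTACGT" + "AGG" + "TTT"
        rec, ann = linker_only_gene("g1", cds, [(0, 27)])
        table = GeneTable([rec])
        cands = enumerate_candidates({"g1": ann}, table, ["g1"])
        assert len(cands) == 1
        assert cands[0].protospacer == "ACGTACGTACGTACGTACGT"
        assert cands[0].pam == "AGG"
        assert cands[0].design_frequency == 1

    def test_short_upstream_window_skipped_and_logged(self):
        cds = "ACGTACGTAC" + "AGG" + "ACGTACGTACGTACGTA"  # PAM at offset 10
        rec, ann = linker_only_gene("g1", cds, [(0, len(cds) // 3 * 3)])
        log = DesignLog()
        cands = enumerate_candidates({"g1": ann}, GeneTable([rec]), ["g1"], log=log)
        assert cands == []
        assert log.n_skipped_short == 1

    def test_window_may_cross_into_preceding_znf(self):
        # linker starts at nt 15; PAM at nt 24 -> window reaches back to nt 4
        cds = "AAAACCCCTTTTACACACACACAC" + "TGG" + "ATATAT"
        rec, ann = linker_only_gene("g1", cds, [(15, 30)])
        cands = enumerate_candidates({"g1": ann}, GeneTable([rec]), ["g1"])
        assert [c.protospacer for c in cands] == [cds[4:24]]

    def test_matches_naive_scan_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            n_codons = int(rng.integers(100, 700))
            cds = "".join(rng.choice(list("ACGT"), size=3 * n_codons))
            ranges = []
            pos = 0
            while pos + 45 < len(cds):
                lo = pos + int(rng.integers(0, 10)) * 3
                hi = lo + int(rng.integers(10, 16)) * 3
                if hi > len(cds):
                    break
                ranges.append((lo, hi))
                pos = hi + 30
            rec, ann = linker_only_gene("g1", cds, ranges)
            cands = enumerate_candidates({"g1": ann}, GeneTable([rec]), ["g1"])
            got = {c.protospacer: c.design_frequency for c in cands}
            assert got == naive_candidates(cds, ranges)

    def test_planted_guides_top_ranked(self, zero_noise_bundle,
                                       zero_noise_annotations):
        table = zero_noise_bundle.table
        for tc in zero_noise_bundle.truth.clusters:
            cands = enumerate_candidates(
                zero_noise_annotations, table, list(tc.gene_ids), (tc.cluster_id,)
            )
            assert {c.protospacer for c in cands} == {p for p, _ in tc.protospacers}
            for c in cands:
                assert c.design_frequency == tc.n_linkers
                assert c.pam == dict(tc.protospacers)[c.protospacer]


class TestSelectTop:
    def _cand(self, proto, freq):
        return SgRNACandidate(proto, "AGG", (), freq)

    def test_tie_broken_lexicographically(self):
        a = self._cand("T" * 20, 5)
        b = self._cand("A" * 20, 5)
        c = self._cand("G" * 20, 9)
        top = select_top([a, b, c], k=2)
        assert [x.protospacer for x in top] == ["G" * 20, "A" * 20]

    def test_k_exceeding_count_returns_all(self):
        cands = [self._cand("A" * 20, 1)]
        assert len(select_top(cands, k=11)) == 1


class TestPredictCutSites:
    def test_strand_symmetry(self):
        proto = "ACGTACGTACCGTACGTACG"
        hit = proto + "TGG"
        cds = "TTT" + hit + "AAA" + revcomp(hit) + "TTT"
        rec = GeneRecord("g1", "m", "chr1", 1, len(cds), "+",
                         protein_seq="X", cds_seq=cds)
        cand = SgRNACandidate(proto, "TGG", (), 1)
        sites = predict_cut_sites(cand, GeneTable([rec]))
        assert sorted(s.strand for s in sites) == ["+", "-"]

    def test_no_ngg_no_sites(self):
        cds = "ACATACATACATACATACATACATACAT"
        rec = GeneRecord("g1", "m", "chr1", 1, len(cds), "+",
                         protein_seq="X", cds_seq=cds)
        cand = SgRNACandidate("ACATACATACATACATACAT", "AGG", (), 1)
        assert predict_cut_sites(cand, GeneTable([rec])) == []

    def test_pam_must_be_exact_even_with_mismatches(self):
        proto = "A" * 20
        cds = proto + "TAG" + "CCC"  # PAM is not NGG
        rec = GeneRecord("g1", "m", "chr1", 1, len(cds), "+",
                         protein_seq="XX", cds_seq=cds)
        cand = SgRNACandidate(proto, "TGG", (), 1)
        assert predict_cut_sites(cand, GeneTable([rec]), max_mismatches=2) == []

    @pytest.mark.parametrize("max_mm", [0, 1])
    def test_matches_hamming_oracle_with_planted_hits(self, max_mm):
        rng = np.random.default_rng(31)
        proto = "".join(rng.choice(list("ACGT"), size=20))
        cand = SgRNACandidate(proto, "AGG", (), 1)
        for _ in range(40):
            cds = list(rng.choice(list("ACGT"), size=int(rng.integers(300, 2000))))
            # plant an exact hit and a 1-mismatch hit at known offsets
            for off, n_mut in ((17, 0), (len(cds) - 60, 1)):
                site = list(proto + "CGG")
                for j in rng.choice(20, size=n_mut, replace=False):
                    site[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[site[j]]
                cds[off : off + 23] = site
            cds = "".join(cds)
            rec = GeneRecord("g1", "m", "chr1", 1, len(cds), "+",
                             protein_seq="X", cds_seq=cds)
            got = sorted(
                (s.strand, s.position, s.mismatches)
                for s in predict_cut_sites(cand, GeneTable([rec]), max_mm)
            )
            assert got == naive_cut_sites(proto, cds, max_mm)
            if max_mm == 0:
                assert ("+", 17, 0) in got
            else:
                assert ("+", len(cds) - 60, 1) in got


class TestSpecificity:
    def test_fraction_is_on_target_over_total(self):
        proto = "ACGTACGTACCGTACGTACG"
        on = proto + "TGG"
        cds_a = "TTT" + on + "AAA" + on + "TTT"
        cds_b = "CCC" + on + "CCC"
        recs = [
            GeneRecord("gA", "m", "chr1", 1, 100, "+", protein_seq="X", cds_seq=cds_a),
            GeneRecord("gB", "m", "chr2", 1, 100, "+", protein_seq="X", cds_seq=cds_b),
        ]
        clusters = [Cluster(1, "chr1", ("gA",), 1, 100)]
        cand = SgRNACandidate(proto, "TGG", (1,), 2)
        rep = specificity_report([cand], GeneTable(recs), clusters)
        assert rep.total_sites[proto] == 3
        assert rep.matrix.loc[proto, "1"] == 2
        assert rep.matrix.loc[proto, "unclustered"] == 1
        assert rep.on_target_fraction[proto] == pytest.approx(2 / 3)

    def test_zero_sites_reported_as_nan_not_zero(self):
        rec = GeneRecord("gA", "m", "chr1", 1, 100, "+", protein_seq="X",
                         cds_seq="ACATACATACATACATACATACATACAT")
        cand = SgRNACandidate("G" * 20, "TGG", (1,), 1)
        rep = specificity_report([cand], GeneTable([rec]),
                                 [Cluster(1, "chr1", ("gA",), 1, 100)])
        assert rep.total_sites["G" * 20] == 0
        assert np.isnan(rep.on_target_fraction["G" * 20])

    def test_cluster_private_linkers_fully_on_target(self, zero_noise_bundle,
                                                     zero_noise_annotations):
        table = zero_noise_bundle.table
        clusters = call_clusters(table)
        for tc in zero_noise_bundle.truth.clusters:
            cands = enumerate_candidates(
                zero_noise_annotations, table, list(tc.gene_ids), (tc.cluster_id,)
            )
            rep = specificity_report(cands, table, clusters)
            assert (rep.on_target_fraction == 1.0).all()
            assert (rep.total_sites >= tc.n_linkers).all()

    def test_design_windows_are_genuine_sites(self, default_bundle,
                                              default_annotations):
        # every designed candidate must rediscover at least its own windows
        table = default_bundle.table
        clusters = call_clusters(table)
        tc = default_bundle.truth.clusters[0]
        cands = enumerate_candidates(
            default_annotations, table, list(tc.gene_ids), (tc.cluster_id,)
        )
        rep = specificity_report(cands, table, clusters)
        for c in cands:
            assert rep.total_sites[c.protospacer] >= c.design_frequency

    def test_row_sums_conserve_totals(self, zero_noise_bundle,
                                      zero_noise_annotations):
        table = zero_noise_bundle.table
        clusters = call_clusters(table)
        tc = zero_noise_bundle.truth.clusters[1]
        cands = enumerate_candidates(
            zero_noise_annotations, table, list(tc.gene_ids), (tc.cluster_id,)
        )
        rep = specificity_report(cands, table, clusters)
        assert (rep.matrix.sum(axis=1) == rep.total_sites).all()
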