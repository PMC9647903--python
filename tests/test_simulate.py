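"""Synthetic family generator: determinism, planted-truth consistency,
noise behaviour, and the truth_check audit."""

import dataclasses
import filecmp

import numpy as np
import pytest
from Bio.Seq import Seq

from krabzfp.annotation import annotate_table
from krabzfp.clusters import call_clusters
from krabzfp.conservation import profile_levels
from krabzfp.simulate import (
    ClusterSpec,
    ExpressionSpec,
    FamilyConfig,
    generate_family,
    truth_check,
    write_family,
)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = FamilyConfig(seed=42)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_family(generate_family(cfg), d1)
        write_family(generate_family(cfg), d2)
        for name in ("genes.tsv", "protein.fa", "cds.fa", "tpm.tsv", "truth.json"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_different_seeds_differ(self):
        a = generate_family(FamilyConfig(seed=1))
        b = generate_family(FamilyConfig(seed=2))
        assert a.proteins != b.proteins


class TestPlantedStructure:
    def test_cluster_recovery(self, zero_noise_bundle):
        clusters = call_clusters(zero_noise_bundle.table)
        truth = zero_noise_bundle.truth.clusters
        assert len(clusters) == len(truth) == 3
        for got, want in zip(clusters, truth):
            assert got.cluster_id == want.cluster_id
            assert got.chromosome == want.chromosome
            assert got.members == want.gene_ids
        assert [len(c.members) for c in clusters] == [5, 4, 3]

    def test_isolated_genes_stay_unclustered(self, zero_noise_bundle):
        clusters = call_clusters(zero_noise_bundle.table)
        clustered = {g for c in clusters for g in c.members}
        for gid in zero_noise_bundle.truth.isolated_genes:
            assert gid not in clustered

    def test_cds_translates_to_protein(self, default_bundle):
        for rec in default_bundle.table:
            assert str(Seq(rec.cds_seq).translate()) == rec.protein_seq

    def test_linker_consensus_carries_exactly_two_ngg(self, default_bundle):
        for tc in default_bundle.truth.clusters:
            nt = tc.linker_consensus_nt
            offsets = [o for o in range(len(nt) - 2) if nt[o + 1 : o + 3] == "GG"]
            assert offsets == list(tc.pam_offsets)
            assert len(offsets) == 2
            assert len(tc.protospacers) == 2  # both windows fit in the linker

    def test_zero_mutation_linkers_identical_and_max_ic(self, zero_noise_bundle,
                                                        zero_noise_annotations):
        clusters = call_clusters(zero_noise_bundle.table)
        for tc in zero_noise_bundle.truth.clusters:
            nts = {
                l.nt_seq
                for g in tc.gene_ids
                for l in zero_noise_annotations[g].linkers
            }
            assert nts == {tc.linker_consensus_nt}
            prof = profile_levels(
                zero_noise_annotations, clusters,
                f"cluster:{tc.cluster_id}", "linker", "nt",
            )
            assert np.allclose(prof.ic, 2.0)

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            FamilyConfig(clusters=(ClusterSpec(1),))
        with pytest.raises(ValueError):
            FamilyConfig(linker_mutation_rate=1.5)
        with pytest.raises(ValueError):
            FamilyConfig(pool_weights=(0.5, 0.5))


class TestNoiseBehaviour:
    RATES = (0.0, 0.01, 0.05, 0.1)

    def _mean_linker_ic(self, rate, seed):
        cfg = FamilyConfig(seed=seed, linker_mutation_rate=rate,
                           synonymous_wobble_rate=0.0)
        bundle = generate_family(cfg)
        ann = annotate_table(bundle.table)
        clusters = call_clusters(bundle.table)
        return np.mean([
            profile_levels(ann, clusters, f"cluster:{c.cluster_id}",
                           "linker", "nt").mean_ic()
            for c in clusters
        ])

    @pytest.mark.parametrize("seed", [42, 7])
    def test_mean_linker_ic_non_increasing_in_mutation_rate(self, seed):
        ics = [self._mean_linker_ic(r, seed) for r in self.RATES]
        assert all(a >= b - 1e-12 for a, b in zip(ics, ics[1:]))

    @pytest.mark.parametrize("seed", [42, 7])
    def test_planted_guide_frequency_non_increasing(self, seed):
        freqs = []
        for rate in self.RATES:
            cfg = FamilyConfig(seed=seed, linker_mutation_rate=rate,
                               synonymous_wobble_rate=0.0)
            bundle = generate_family(cfg)
            tc = bundle.truth.clusters[0]
            freqs.append(sum(tc.protospacer_counts.values()))
        assert all(a >= b for a, b in zip(freqs, freqs[1:]))
        assert freqs[0] == 2 * bundle.truth.clusters[0].n_linkers

    def test_wobble_preserves_protein_and_linker_nt(self):
        quiet = generate_family(FamilyConfig(seed=5, synonymous_wobble_rate=0.0,
                                             linker_mutation_rate=0.0))
        noisy = generate_family(FamilyConfig(seed=5, synonymous_wobble_rate=0.3,
                                             linker_mutation_rate=0.0))
        assert quiet.proteins == noisy.proteins  # wobble is synonymous
        ann_q = annotate_table(quiet.table)
        ann_n = annotate_table(noisy.table)
        for gid in ann_q:
            assert [l.nt_seq for l in ann_q[gid].linkers] == [
                l.nt_seq for l in ann_n[gid].linkers
            ]


class TestTruthCheck:
    def test_valid_bundle_passes(self, default_bundle):
        report = truth_check(default_bundle)
        assert report.ok, report.failures

    def test_corrupted_cds_isolated_to_one_gene(self, zero_noise_config):
        bundle = generate_family(zero_noise_config)
        victim = bundle.table.records[3]
        cds = victim.cds_seq
        # flip one codon to a non-synonymous one
        from krabzfp._codons import CODON_TO_AA

        bad = "GAT" if CODON_TO_AA[cds[:3]] != "D" else "AAA"
        victim.cds_seq = bad + cds[3:]
        bundle.cds[victim.gene_id] = victim.cds_seq
        report = truth_check(bundle)
        assert not report.ok
        offenders = {f.split(":")[0] for f in report.failures if "translate" in f}
        assert offenders == {victim.gene_id}

    def test_random_config_sweep(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            sizes = [int(rng.integers(2, 6)) for _ in range(int(rng.integers(1, 4)))]
            cfg = FamilyConfig(
                seed=int(rng.integers(0, 2**31 - 1)),
                n_chromosomes=int(rng.integers(1, 5)),
                clusters=tuple(ClusterSpec(s) for s in sizes),
                isolated_genes=int(rng.integers(0, 3)),
                znf_per_gene=(3, 6),
                linker_mutation_rate=float(rng.uniform(0, 0.1)),
                synonymous_wobble_rate=float(rng.uniform(0, 0.3)),
            )
            report = truth_check(generate_family(cfg))
            assert report.ok, report.failures

    def test_expression_specs_follow_config(self):
        cfg = FamilyConfig(
            clusters=(ClusterSpec(4), ClusterSpec(3)),
            expression=(
                ExpressionSpec("mESC", 60.0, 1.0),
                ExpressionSpec("gut", 40.0, 1.0),
            ),
        )
        bundle = generate_family(cfg)
        truth = bundle.truth
        assert set(truth.high_expression["mESC"]) == set(truth.clusters[0].gene_ids)
        assert set(truth.high_expression["gut"]) == set(truth.clusters[1].gene_ids)
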