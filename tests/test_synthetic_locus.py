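"""Simulator correctness: zero-rate limits, determinism, Jukes-Cantor
consistency, gene-conversion semantics and locus assembly ground truth."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import binomtest

from pcdhkit._codons import STOP_CODONS, translate_cds
from pcdhkit.motifs import MotifModel
from pcdhkit.synthetic_locus import (
    ClusterInput,
    DomainPartition,
    apply_gene_conversion,
    assemble_locus,
    make_ancestral_cluster,
    make_constant_exon_seq,
    make_partition,
    simulate_cluster,
    simulate_reads,
)

ANCESTOR, PARTITION, _TEMPLATES = make_ancestral_cluster(seed=3)


def _pair_identity(a: str, b: str, lo: int = 0, hi: int | None = None) -> float:
    hi = len(a) if hi is None else hi
    return sum(x == y for x, y in zip(a[lo:hi], b[lo:hi])) / (hi - lo)


class TestSimulateCluster:
    def test_zero_rate_is_identity(self):
        _, cds = simulate_cluster(4, ANCESTOR, branch_scale=0.0, seed=1)
        assert all(s == ANCESTOR for s in cds.values())

    def test_deterministic_given_seed(self):
        t1, c1 = simulate_cluster(5, ANCESTOR, 0.1, seed=42)
        t2, c2 = simulate_cluster(5, ANCESTOR, 0.1, seed=42)
        assert c1 == c2
        assert str(t1) == str(t2)
        _, c3 = simulate_cluster(5, ANCESTOR, 0.1, seed=43)
        assert c1 != c3

    def test_no_stop_codons_and_start_preserved(self):
        _, cds = simulate_cluster(6, ANCESTOR, 0.3, partition=PARTITION, seed=5)
        for s in cds.values():
            assert s.startswith("ATG")
            assert all(s[i : i + 3] not in STOP_CODONS for i in range(0, len(s), 3))

    def test_invalid_ancestor_rejected(self):
        with pytest.raises(ValueError, match="stop codon"):
            simulate_cluster(3, "ATGTAAAAA", 0.1, seed=0)
        with pytest.raises(ValueError, match="divisible by 3"):
            simulate_cluster(3, "ATGC", 0.1, seed=0)

    def test_pairwise_p_distance_matches_jukes_cantor(self):
        """Mean observed nucleotide p-distance across replicates agrees with
        the JC expectation p = 3/4(1 - exp(-4d/3)) at the realized path
        length d, within three standard errors."""
        rng = np.random.default_rng(0)
        protein = "M" + "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(20, size=499))
        from pcdhkit.synthetic_locus import _reverse_translate

        anc = "ATG" + _reverse_translate(protein, rng)[3:]
        L = len(anc)
        obs, exp = [], []
        for rep in range(50):
            tree, cds = simulate_cluster(
                4, anc, branch_scale=0.05, default_omega=1.0, seed=1000 + rep,
                protect_start=False,
            )
            tips = list(tree.tips())
            for i in range(len(tips)):
                for j in range(i + 1, len(tips)):
                    a, b = tips[i], tips[j]
                    lca = tree.lowest_common_ancestor([a, b])
                    d_subs = 0
                    for tip in (a, b):
                        node = tip
                        while node is not lca:
                            d_subs += node.n_subs
                            node = node.parent
                    d = d_subs / L
                    exp.append(0.75 * (1 - math.exp(-4 * d / 3)))
                    sa, sb = cds[a.name], cds[b.name]
                    obs.append(sum(x != y for x, y in zip(sa, sb)) / L)
        obs, exp = np.array(obs), np.array(exp)
        se = obs.std(ddof=1) / math.sqrt(len(obs))
        assert abs(obs.mean() - exp.mean()) < 3 * se


class TestGeneConversion:
    def test_zero_rate_null_process(self):
        tree, cds = simulate_cluster(4, ANCESTOR, 0.1, seed=2)
        out, events = apply_gene_conversion(cds, tree, rate=0.0, seed=2)
        assert out == cds
        assert events == []

    def test_empty_domains_with_positive_rate_errors(self):
        tree, cds = simulate_cluster(4, ANCESTOR, 0.1, seed=2)
        with pytest.raises(ValueError, match="allowed_domains"):
            apply_gene_conversion(cds, tree, rate=1.0, partition=PARTITION, seed=0)

    def test_event_copy_semantics_and_identity_increase(self):
        """The last logged event leaves the acceptor identical to the donor
        over its tract, and every event can only increase tract identity."""
        tree, cds = simulate_cluster(6, ANCESTOR, 0.2, seed=9)
        out, events = apply_gene_conversion(
            cds, tree, rate=2.0,
            allowed_domains={"EC4", "EC5", "EC6"}, partition=PARTITION, seed=9,
        )
        assert events, "expected at least one event at this rate"
        last = events[-1]
        s, e = 3 * last.tract_start_codon, 3 * last.tract_end_codon
        assert out[last.acceptor_id][s:e] == out[last.donor_id][s:e]
        # replay: identity over the tract never decreases at the event
        state = dict(cds)
        for ev in events:
            s, e = 3 * ev.tract_start_codon, 3 * ev.tract_end_codon
            before = _pair_identity(state[ev.donor_id], state[ev.acceptor_id], s, e)
            state[ev.acceptor_id] = (
                state[ev.acceptor_id][:s] + state[ev.donor_id][s:e] + state[ev.acceptor_id][e:]
            )
            after = _pair_identity(state[ev.donor_id], state[ev.acceptor_id], s, e)
            assert after == 1.0 >= before
        assert state == out

    def test_events_restricted_to_allowed_domains(self):
        tree, cds = simulate_cluster(6, ANCESTOR, 0.2, seed=4)
        _, events = apply_gene_conversion(
            cds, tree, rate=3.0, allowed_domains={"EC5"}, partition=PARTITION, seed=4
        )
        s5, e5 = PARTITION.range_of("EC5")
        for ev in events:
            assert s5 <= ev.tract_start_codon < ev.tract_end_codon <= e5

    def test_restricted_conversion_raises_identity_in_target_domains(self):
        """With conversion confined to EC4-EC6, nucleotide identity there
        exceeds EC2-EC3 identity (paired one-sided sign test, 20 loci)."""
        wins = 0
        n = 20
        s23 = PARTITION.range_of("EC2")[0] * 3, PARTITION.range_of("EC3")[1] * 3
        s46 = PARTITION.range_of("EC4")[0] * 3, PARTITION.range_of("EC6")[1] * 3
        for rep in range(n):
            tree, cds = simulate_cluster(6, ANCESTOR, 0.15, seed=500 + rep)
            out, _ = apply_gene_conversion(
                cds, tree, rate=10.0,
                allowed_domains={"EC4", "EC5", "EC6"}, partition=PARTITION,
                seed=500 + rep,
            )
            ids = sorted(out)
            i23, i46 = [], []
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    a, b = out[ids[i]], out[ids[j]]
                    i23.append(_pair_identity(a, b, *s23))
                    i46.append(_pair_identity(a, b, *s46))
            if np.mean(i46) > np.mean(i23):
                wins += 1
        assert binomtest(wins, n, alternative="greater").pvalue < 0.01


def _small_locus(seed=0, n_decoys=2, pwm=None):
    _, cds = simulate_cluster(3, ANCESTOR, 0.1, seed=seed)
    ce = make_constant_exon_seq(60, seed=seed)
    cluster = ClusterInput("c1", cds, ce, PARTITION)
    return assemble_locus(
        [cluster], intergenic_len=600, promoter_pwm=pwm, motif_offset=-200,
        n_decoys=n_decoys, decoy_len_aa=100, seed=seed,
    )


class TestAssembleLocus:
    def test_gene_coordinates_resolve_to_cds(self):
        locus = _small_locus(seed=1)
        for gm in locus.gene_models:
            s, e = gm.variable_exon
            ve = locus.genome_sequence[s:e]
            assert ve.startswith("ATG")
            assert locus.genome_sequence[e : e + 3] in STOP_CODONS
            assert locus.genome_sequence[s - 3 : s] == "TAA"
            spliced = ve + "".join(
                locus.genome_sequence[cs:ce] for cs, ce in gm.constant_exons
            )
            assert spliced == gm.cds_sequence
            assert translate_cds(spliced) == gm.protein_sequence

    def test_decoys_are_orfs_of_requested_length(self):
        locus = _small_locus(seed=2, n_decoys=3)
        assert len(locus.decoys) == 3
        for s, e in locus.decoys:
            orf = locus.genome_sequence[s:e]
            assert orf.startswith("ATG")
            assert len(translate_cds(orf)) == 100

    def test_planted_motif_truth_offsets(self):
        pwm = MotifModel.from_consensus("GTCGCTAATGGCA")
        locus = _small_locus(seed=3, pwm=pwm)
        assert len(locus.motif_truth) == 3
        assert all(off == -200 for _, off in locus.motif_truth)
        # the planted instance really sits 200 bp upstream of each ATG
        for gm in locus.gene_models:
            atg = gm.variable_exon[0]
            planted = locus.genome_sequence[atg - 200 : atg - 200 + pwm.width]
            matches = sum(a == b for a, b in zip(planted, pwm.consensus))
            assert matches >= pwm.width - 4

    def test_genome_length_conservation(self):
        locus = _small_locus(seed=4, n_decoys=2)
        ce_len = sum(e - s for s, e in locus.gene_models[0].constant_exons)
        ve_lens = sum(e - s for s, e in (g.variable_exon for g in locus.gene_models))
        expected = (
            3 * 600 + ve_lens + 3 * 3          # per-gene spacer + VE + stop
            + 600 + ce_len + 2 * 200 + 3       # CE block with introns + stop
            + 2 * (600 + 100 * 3 + 3)          # decoys (incl. their stops)
            + 600                              # trailing spacer
        )
        assert len(locus.genome_sequence) == expected

    def test_deterministic(self):
        assert (
            _small_locus(seed=5).genome_sequence == _small_locus(seed=5).genome_sequence
        )

    def test_negative_intergenic_rejected(self):
        _, cds = simulate_cluster(3, ANCESTOR, 0.1, seed=0)
        ce = make_constant_exon_seq(60, seed=0)
        with pytest.raises(ValueError):
            assemble_locus(
                [ClusterInput("c1", cds, ce, PARTITION)], intergenic_len=-1, seed=0
            )


class TestSimulateReads:
    def test_zero_expression_cluster_gets_no_fragments(self, demo_sim):
        placements = simulate_reads(
            demo_sim.locus, {"alpha": 100.0, "gamma1": 0.0}, 2000, seed=1
        )
        assert placements
        assert all(p.cluster_id == "alpha" for p in placements)

    def test_fragment_ratio_within_binomial_ci(self, demo_sim):
        n = 100_000
        placements = simulate_reads(
            demo_sim.locus, {"alpha": 300.0, "gamma1": 100.0}, n, seed=2
        )
        n_alpha = sum(p.cluster_id == "alpha" for p in placements)
        # both clusters share identical transcript geometry, so the design
        # probability of an alpha fragment is 300/(300+100) = 0.75
        ci = binomtest(n_alpha, n, p=0.75).proportion_ci(confidence_level=0.99)
        assert ci.low <= 0.75 <= ci.high

    def test_determinism_and_block_validity(self, demo_sim):
        a = simulate_reads(demo_sim.locus, {"alpha": 1.0, "gamma1": 2.0}, 500, seed=3)
        b = simulate_reads(demo_sim.locus, {"alpha": 1.0, "gamma1": 2.0}, 500, seed=3)
        assert a == b
        glen = len(demo_sim.locus.genome_sequence)
        for p in a:
            total = sum(e - s for s, e in p.blocks)
            assert total == 300
            assert all(0 <= s < e <= glen for s, e in p.blocks)

    def test_zero_abundance_error(self, demo_sim):
        with pytest.raises(ValueError, match="zero total abundance"):
            simulate_reads(demo_sim.locus, {"alpha": 0.0, "gamma1": 0.0}, 10, seed=0)


class TestDomainPartition:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            DomainPartition((("EC1", 0, 10), ("EC2", 5, 20)))

    def test_six_ec_required_for_cpcdh(self):
        part = make_partition(10, 5, 5)
        part.validate_cpcdh(70)
        bad = DomainPartition((("EC1", 0, 10), ("TM", 10, 15)))
        with pytest.raises(ValueError, match="EC1..EC6"):
            bad.validate_cpcdh(15)

    def test_region_range_requires_contiguity(self):
        part = make_partition(10, 5, 5)
        assert part.region_range(("EC2", "EC3")) == (10, 30)
        with pytest.raises(ValueError, match="not contiguous"):
            part.region_range(("EC2", "EC4"))
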