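"""NG86 dS/dN estimation, codon-alignment back-translation, per-domain
group averaging and the conversion-ratio statistic."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import wilcoxon

from pcdhkit._codons import SENSE_CODONS
from pcdhkit.ds_geneconv import (
    CodonAlignment,
    backtranslate_alignment,
    conversion_ratio,
    group_domain_ds,
    ng86_pairwise,
)
from pcdhkit.synthetic_locus import (
    apply_gene_conversion,
    make_ancestral_cluster,
    simulate_cluster,
)

ANCESTOR, PARTITION, _ = make_ancestral_cluster(seed=3)

codon = st.sampled_from(SENSE_CODONS)
codon_row = st.lists(codon, min_size=1, max_size=30).map("".join)


class TestBacktranslate:
    def test_ungapped_msa_concatenates_codons(self):
        aln = backtranslate_alignment({"x": "MK"}, {"x": "ATGAAA"})
        assert aln.rows["x"] == "ATGAAA"

    def test_gap_propagation(self):
        aln = backtranslate_alignment({"x": "M-K"}, {"x": "ATGAAA"})
        assert aln.rows["x"] == "ATG---AAA"

    @settings(max_examples=30, deadline=None)
    @given(codon_row, st.randoms(use_true_random=False))
    def test_round_trip_recovers_cds(self, cds, rnd):
        from pcdhkit._codons import translate_cds

        protein = translate_cds(cds)
        # sprinkle random gaps into the protein row
        chars = list(protein)
        for _ in range(rnd.randint(0, 5)):
            chars.insert(rnd.randint(0, len(chars)), "-")
        row = "".join(chars)
        aln = backtranslate_alignment({"x": row}, {"x": cds})
        assert aln.ungapped("x") == cds

    def test_mismatch_errors_name_the_isoform(self):
        with pytest.raises(ValueError, match="bad"):
            backtranslate_alignment({"bad": "MK"}, {"bad": "ATGAAAGGG"})
        with pytest.raises(ValueError, match="bad"):
            backtranslate_alignment({"bad": "MM"}, {"bad": "ATGAAA"})

    def test_partial_gap_codon_rejected(self):
        with pytest.raises(ValueError, match="partial gap"):
            CodonAlignment(["x"], {"x": "AT-GAA"})


class TestNg86:
    def test_identical_rows(self):
        p = ng86_pairwise("ATGAAA", "ATGAAA")
        assert (p.Sd, p.Nd, p.dS, p.dN) == (0.0, 0.0, 0.0, 0.0)

    def test_single_nonsynonymous_difference(self):
        """TTT vs TTA: S=0.5, N=2.5, one nonsynonymous difference,
        dN = -(3/4)ln(1 - (4/3)(1/2.5))."""
        p = ng86_pairwise("TTT", "TTA")
        assert p.S == pytest.approx(0.5)
        assert p.N == pytest.approx(2.5)
        assert (p.Sd, p.Nd) == (0.0, 1.0)
        assert p.dS == 0.0
        assert p.dN == pytest.approx(0.5716, abs=1e-4)

    def test_single_synonymous_difference_with_jc(self):
        """Five codons, one third-position synonymous change: S=5/3,
        ps=0.6, dS = -(3/4)ln(0.2)."""
        p = ng86_pairwise("AAAAAAAAAAAAGAT", "AAAAAAAAAAAAGAC")
        assert p.S == pytest.approx(5 / 3)
        assert (p.Sd, p.Nd) == (1.0, 0.0)
        assert p.ps == pytest.approx(0.6)
        assert p.dS == pytest.approx(-0.75 * math.log(0.2), abs=1e-9)
        assert p.dN == 0.0

    def test_saturation_flagged(self):
        """CGA/CGG pairs have S=4/3 per codon and one synonymous difference,
        so ps = 0.75 exactly: saturated, dS undefined."""
        p = ng86_pairwise("CGA" * 10, "CGG" * 10)
        assert p.ps == pytest.approx(0.75)
        assert p.saturated
        assert math.isnan(p.dS)

    def test_gapped_codons_excluded_pairwise(self):
        p = ng86_pairwise("ATG---AAA", "ATGCCCAAA")
        q = ng86_pairwise("ATGAAA", "ATGAAA")
        assert (p.S, p.Sd, p.Nd) == (q.S, q.Sd, q.Nd)

    def test_zero_comparable_codons_errors(self):
        with pytest.raises(ValueError, match="zero comparable"):
            ng86_pairwise("---", "AAA")

    @settings(max_examples=40, deadline=None)
    @given(codon_row, codon_row)
    def test_symmetry_and_site_conservation(self, a, b):
        n = min(len(a), len(b)) // 3 * 3
        a, b = a[:n], b[:n]
        if n == 0:
            return
        p = ng86_pairwise(a, b)
        q = ng86_pairwise(b, a)
        assert p.S == pytest.approx(q.S)
        assert p.Sd == pytest.approx(q.Sd)
        assert p.Nd == pytest.approx(q.Nd)
        assert p.S + p.N == pytest.approx(3 * (n // 3))
        if p.Sd == 0:
            assert p.dS == 0.0


class TestConversionRatio:
    @pytest.mark.parametrize(
        "means,expected",
        [
            # published per-domain mean dS rows whose printed ratio is
            # reproducible from the printed values
            ((1.15, 2.84, 2.11, 1.84, 1.27, 1.35), 2.47),  # frog alpha 1-14
            ((1.24, 2.55, 2.62, 1.44, 1.13, 1.72), 2.32),  # frog gamma2 1-13
            ((1.08, 1.66, 1.43, 1.60, 0.79, 1.36), 2.10),  # mouse beta 1-22
            ((2.16, 2.29, 2.45, 2.61, 2.34, 1.88), 1.39),  # mouse gammaA 1-12
        ],
    )
    def test_published_worked_examples(self, means, expected):
        assert round(conversion_ratio(means), 2) == expected

    def test_equal_values_give_one(self):
        assert conversion_ratio([1.5] * 6) == 1.0

    def test_undefined_inputs_rejected_with_reason(self):
        with pytest.raises(ValueError, match="non-positive"):
            conversion_ratio([1, 2, 3, 4, 5, 0])
        with pytest.raises(ValueError, match="undefined"):
            conversion_ratio([1, 2, 3, 4, 5, math.nan])
        with pytest.raises(ValueError, match="six"):
            conversion_ratio([1, 2, 3])


def _cluster_alignment(rate: float, seed: int, n_iso: int = 6):
    tree, cds = simulate_cluster(n_iso, ANCESTOR, 0.15, partition=PARTITION, seed=seed)
    if rate > 0:
        cds, _ = apply_gene_conversion(
            cds, tree, rate=rate, allowed_domains={"EC4", "EC5", "EC6"},
            partition=PARTITION, seed=seed,
        )
    from pcdhkit._codons import translate_cds

    return CodonAlignment(sorted(cds), dict(cds))


class TestGroupDomainDs:
    def test_identical_group_all_zero_ratio_undefined(self):
        aln = CodonAlignment(["a", "b"], {"a": ANCESTOR, "b": ANCESTOR})
        (s,) = group_domain_ds(aln, PARTITION, {"g": ["a", "b"]})
        assert all(v == 0.0 for v in s.mean_ds.values())
        assert s.ratio is None
        assert "non-positive" in s.ratio_reason

    def test_matches_brute_force_pairwise_means(self):
        aln = _cluster_alignment(0.0, seed=17)
        (s,) = group_domain_ds(aln, PARTITION, {"g": aln.isoform_ids})
        for dom in ("EC2", "EC6"):
            lo, hi = PARTITION.range_of(dom)
            vals = [
                ng86_pairwise(
                    aln.codon_slice(a, lo, hi), aln.codon_slice(b, lo, hi)
                ).dS
                for a, b in itertools.combinations(aln.isoform_ids, 2)
            ]
            assert s.mean_ds[dom] == pytest.approx(np.mean(vals))

    def test_undersized_group_rejected(self):
        aln = _cluster_alignment(0.0, seed=17)
        with pytest.raises(ValueError, match="fewer than 2"):
            group_domain_ds(aln, PARTITION, {"g": aln.isoform_ids[:1]})

    def test_converted_domains_have_lower_ds(self):
        """With conversion restricted to EC4-EC6, their mean dS falls below
        the EC2-EC3 mean (one-sided paired test across 20 seeds)."""
        diffs = []
        for seed in range(20):
            aln = _cluster_alignment(10.0, seed=4000 + seed)
            (s,) = group_domain_ds(aln, PARTITION, {"g": aln.isoform_ids})
            m23 = np.mean([s.mean_ds["EC2"], s.mean_ds["EC3"]])
            m46 = np.mean([s.mean_ds["EC4"], s.mean_ds["EC5"], s.mean_ds["EC6"]])
            diffs.append(m23 - m46)
        assert wilcoxon(diffs, alternative="greater").pvalue < 0.01

    def test_saturated_pairs_counted_out_of_domain_means(self):
        rows = {
            "a": "CGA" * 10 + "ATG" * 10,
            "b": "CGG" * 10 + "ATG" * 10,
            "c": "CGA" * 10 + "ATG" * 10,
        }
        from pcdhkit.synthetic_locus import DomainPartition

        part = DomainPartition((("EC1", 0, 10), ("EC2", 10, 20)))
        (s,) = group_domain_ds(
            CodonAlignment(sorted(rows), rows), part, {"g": sorted(rows)},
            domains=("EC1", "EC2"),
        )
        # a-b and b-c are saturated in EC1 (ps = 0.75); only a-c remains
        assert s.n_pairs_used["EC1"] == 1
        assert s.mean_ds["EC1"] == 0.0
        assert s.n_pairs_used["EC2"] == 3
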