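"""Shared fixtures and replicate helpers reused across test modules."""

from __future__ import annotations

import pytest

from pcdhkit.ds_geneconv import CodonAlignment, group_domain_ds
from pcdhkit.pipeline import default_config, simulate_locus
from pcdhkit.synthetic_locus import (
    apply_gene_conversion,
    make_ancestral_cluster,
    simulate_cluster,
)


def conversion_ratio_replicate(rate: float, seed: int, n_iso: int = 6) -> float:
    """One replicate cluster's max/min per-domain dS ratio, with conversion
    (if any) restricted to EC4-EC6 at the given events/pair rate."""
    ancestor, partition, _ = make_ancestral_cluster(seed=3)
    tree, cds = simulate_cluster(n_iso, ancestor, 0.15, partition=partition, seed=seed)
    if rate > 0:
        cds, _ = apply_gene_conversion(
            cds, tree, rate=rate, allowed_domains={"EC4", "EC5", "EC6"},
            partition=partition, seed=seed,
        )
    aln = CodonAlignment(sorted(cds), dict(cds))
    (summary,) = group_domain_ds(aln, partition, {"g": aln.isoform_ids})
    return summary.ratio


@pytest.fixture(scope="session")
def demo_sim():
    """The demo locus: two clusters of eight isoforms, one conversion-free
    (alpha) and one under moderate EC4-EC6 conversion (gamma1), plus decoys."""
    return simulate_locus(default_config()["locus"], seed=11)


@pytest.fixture(scope="session")
def alpha14_sim():
    """A single 14-isoform conversion-free cluster with five short decoys,
    mirroring an alpha-cluster-sized array (the default truth-bearing locus)."""
    cfg = {
        "clusters": [{"name": "alpha", "n_isoforms": 14, "conversion_rate": 0.0}],
        "decoys": {"n": 5, "len_aa": 350},
    }
    return simulate_locus(cfg, seed=7)
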