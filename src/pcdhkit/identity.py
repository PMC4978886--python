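"""Domain-wise pairwise percent-identity analysis.

Percent identity between isoform pairs is computed from a Needleman–Wunsch
global alignment (BLOSUM62, affine gaps by default) with the denominator
fixed as the number of alignment columns, so terminal gaps count against
identity. Within-group per-domain averages mirror the structure of the
field's standard domain-conservation tables (EC1..EC6 plus the constant
domain), and the "highly similar isoform" screen reports all pairs above a
threshold over a chosen region (default EC2–EC3, the homophilic-specificity
interface).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .synthetic_locus import GeneModel

_VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

TABLE_DOMAINS = ("EC1", "EC2", "EC3", "EC4", "EC5", "EC6", "CD")


def make_aligner(
    matrix: str = "BLOSUM62",
    open_gap: float = -10.0,
    extend_gap: float = -0.5,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def pairwise_identity(
    seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Percent identity over a global alignment; gap columns count in the
    denominator (gap–gap columns cannot occur in a pairwise alignment)."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    for name, s in (("A", seq_a), ("B", seq_b)):
        bad = set(s.upper()) - _VALID_AA
        if bad:
            raise ValueError(f"non-amino-acid characters in sequence {name}: {sorted(bad)}")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    columns = aln.shape[1]
    return 100.0 * counts.identities / columns


@dataclass
class SimilarPairReport:
    threshold_pct: float
    region: tuple[str, ...]
    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    max_identity: dict[str, float] = field(default_factory=dict)


def _domain_seq(gm: GeneModel, label: str) -> str:
    return gm.domain_protein(label)


def _region_seq(gm: GeneModel, region: tuple[str, ...]) -> str:
    s, e = gm.partition.region_range(region)
    return gm.protein_sequence[s:e]


def domain_identity_table(
    isoforms: list[GeneModel],
    groups: dict[str, list[str]],
    domains: tuple[str, ...] = TABLE_DOMAINS,
    aligner: Align.PairwiseAligner | None = None,
) -> pd.DataFrame:
    """Per-group per-domain mean pairwise identity (rows: domains, cols: groups).

    Each cell is the mean of `pairwise_identity` over all unordered
    within-group pairs restricted to that domain; the constant domain (CD)
    is compared like any other region, which within one simulated cluster is
    identical across isoforms by construction. Groups of size < 2 are
    reported as NaN (undefined), not an error.
    """
    if aligner is None:
        aligner = make_aligner()
    by_id = {gm.id: gm for gm in isoforms}
    table = pd.DataFrame(index=list(domains), columns=list(groups), dtype=float)
    for gname, ids in groups.items():
        members = [by_id[i] for i in ids]
        for dom in domains:
            if len(members) < 2:
                table.loc[dom, gname] = math.nan
                continue
            vals = [
                pairwise_identity(_domain_seq(a, dom), _domain_seq(b, dom), aligner)
                for a, b in itertools.combinations(members, 2)
            ]
            table.loc[dom, gname] = float(np.mean(vals))
    return table


def high_similarity_pairs(
    isoforms: list[GeneModel],
    region: tuple[str, ...] = ("EC2", "EC3"),
    threshold_pct: float = 90.0,
    aligner: Align.PairwiseAligner | None = None,
) -> SimilarPairReport:
    """All unordered pairs whose identity over `region` meets the threshold,
    plus each isoform's maximum identity to any other isoform."""
    if aligner is None:
        aligner = make_aligner()
    report = SimilarPairReport(threshold_pct=threshold_pct, region=region)
    seqs = {gm.id: _region_seq(gm, region) for gm in isoforms}
    ids = sorted(seqs)
    best = {i: 0.0 for i in ids}
    for a, b in itertools.combinations(ids, 2):
        pid = pairwise_identity(seqs[a], seqs[b], aligner)
        best[a] = max(best[a], pid)
        best[b] = max(best[b], pid)
        if pid >= threshold_pct:
            report.pairs.append((a, b, pid))
    report.max_identity = best
    return report
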