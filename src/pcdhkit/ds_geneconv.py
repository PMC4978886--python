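"""Nei–Gojobori (1986) dS/dN estimation and the gene-conversion ratio statistic.

Gene conversion between tandem paralogs homogenizes the affected tract; it
depresses the synonymous substitution rate dS there because synonymous sites
are otherwise free of protein-level constraint. Averaging pairwise dS per
extracellular domain within a paralog group and taking the ratio of the
highest to the lowest per-domain mean therefore summarizes how unevenly
conversion has acted across the ectodomains: a ratio near 1 indicates no
domain-restricted conversion, a large ratio indicates strong homogenization
of the low-dS domains.

dS and dN here follow the NG86 pathway-counting estimator with the
Jukes–Cantor multiple-hit correction d = -(3/4)·ln(1 - (4/3)p); pairs with
p >= 3/4 are saturated (undefined) and excluded from group means.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codons import (
    CODON_TABLE,
    pathway_differences,
    syn_site_fraction,
    translate_cds,
)
from .synthetic_locus import DomainPartition, EC_LABELS

GAP_CODON = "---"


@dataclass
class CodonAlignment:
    """Aligned codon rows; gaps occur only in whole-codon units."""

    isoform_ids: list[str]
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("all rows must have equal length")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        for rid, row in self.rows.items():
            for i in range(0, length, 3):
                codon = row[i : i + 3]
                if "-" in codon and codon != GAP_CODON:
                    raise ValueError(f"{rid}: partial gap codon {codon!r} at {i}")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.rows.values()))) // 3

    def ungapped(self, rid: str) -> str:
        return self.rows[rid].replace("-", "")

    def codon_slice(self, rid: str, start: int, end: int) -> str:
        return self.rows[rid][3 * start : 3 * end]


def backtranslate_alignment(
    protein_msa: dict[str, str], cds_map: dict[str, str]
) -> CodonAlignment:
    """Thread each CDS through its aligned protein row (RevTrans-style)."""
    rows = {}
    for rid, prot_row in protein_msa.items():
        if rid not in cds_map:
            raise ValueError(f"no CDS provided for isoform {rid!r}")
        cds = cds_map[rid]
        ungapped = prot_row.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"{rid}: CDS length {len(cds)} != 3 x ungapped protein length {len(ungapped)}"
            )
        if translate_cds(cds) != ungapped:
            raise ValueError(f"{rid}: CDS does not translate to the aligned protein")
        out = []
        k = 0
        for aa in prot_row:
            if aa == "-":
                out.append(GAP_CODON)
            else:
                out.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows[rid] = "".join(out)
    return CodonAlignment(isoform_ids=sorted(rows), rows=rows)


@dataclass
class DsPair:
    idA: str
    idB: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    dS: float  # nan when saturated
    dN: float
    saturated: bool


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86_pairwise(codon_row_a: str, codon_row_b: str, idA: str = "A", idB: str = "B") -> DsPair:
    """NG86 site/difference counting over two equal-length codon rows.

    Codons containing a gap or any non-ACGT character in either row are
    excluded pairwise. Synonymous site fractions are averaged over the two
    sequences; multi-hit codons average over all minimal mutational pathways
    (stop-crossing pathways excluded and re-weighted).
    """
    if len(codon_row_a) != len(codon_row_b):
        raise ValueError("codon rows must have equal length")
    if len(codon_row_a) % 3 != 0:
        raise ValueError("row length not divisible by 3")
    S = N = Sd = Nd = 0.0
    n_comp = 0
    for i in range(0, len(codon_row_a), 3):
        ca = codon_row_a[i : i + 3].upper()
        cb = codon_row_b[i : i + 3].upper()
        if ca not in CODON_TABLE or cb not in CODON_TABLE:
            continue  # gap, ambiguity or stop codon: pairwise-complete deletion
        n_comp += 1
        S += 0.5 * (syn_site_fraction(ca) + syn_site_fraction(cb))
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    if n_comp == 0:
        raise ValueError("zero comparable codons")
    N = 3.0 * n_comp - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    saturated = ps >= 0.75
    return DsPair(
        idA=idA, idB=idB, S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn,
        dS=_jc_correct(ps), dN=_jc_correct(pn), saturated=saturated,
    )


def conversion_ratio(per_domain_means: list[float] | tuple[float, ...]) -> float:
    """max/min of the per-domain mean dS values (the Table-2-style statistic)."""
    vals = list(per_domain_means)
    if len(vals) != 6:
        raise ValueError("expected six per-domain mean dS values")
    for v in vals:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError("ratio undefined: a per-domain mean is undefined")
        if v <= 0:
            raise ValueError("ratio undefined: non-positive per-domain mean")
    return max(vals) / min(vals)


@dataclass
class DomainDsSummary:
    group_label: str
    mean_ds: dict[str, float]  # EC label -> mean dS (nan if undefined)
    n_pairs_used: dict[str, int]
    ratio: float | None = None
    ratio_reason: str | None = None
    per_pair: dict[str, list[DsPair]] = field(default_factory=dict)

    def as_row(self) -> dict:
        row: dict = {"group": self.group_label}
        for label in EC_LABELS:
            row[f"dS_{label}"] = self.mean_ds.get(label, math.nan)
        row["dS_highest/dS_lowest"] = self.ratio if self.ratio is not None else math.nan
        return row


def group_domain_ds(
    alignment: CodonAlignment,
    partition: DomainPartition,
    groups: dict[str, list[str]],
    domains: tuple[str, ...] = EC_LABELS,
) -> list[DomainDsSummary]:
    """Mean pairwise dS per domain per group, plus the max/min ratio.

    The partition is interpreted in alignment codon-column coordinates.
    Pairs saturated within a domain are excluded from that domain's mean and
    not counted in n_pairs_used; a domain with zero usable pairs is flagged
    undefined (NaN).
    """
    n = alignment.n_codons
    summaries = []
    for gname, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"group {gname!r} has fewer than 2 members")
        mean_ds: dict[str, float] = {}
        n_used: dict[str, int] = {}
        per_pair: dict[str, list[DsPair]] = {}
        for dom in domains:
            s, e = partition.range_of(dom)
            if e > n:
                raise ValueError(f"domain {dom} extends beyond the alignment")
            values = []
            pairs = []
            for a, b in itertools.combinations(sorted(ids), 2):
                pair = ng86_pairwise(
                    alignment.codon_slice(a, s, e),
                    alignment.codon_slice(b, s, e),
                    idA=a, idB=b,
                )
                pairs.append(pair)
                if not pair.saturated:
                    values.append(pair.dS)
            per_pair[dom] = pairs
            n_used[dom] = len(values)
            mean_ds[dom] = float(np.mean(values)) if values else math.nan
        summary = DomainDsSummary(
            group_label=gname, mean_ds=mean_ds, n_pairs_used=n_used, per_pair=per_pair
        )
        try:
            summary.ratio = conversion_ratio([mean_ds[d] for d in domains])
        except ValueError as exc:
            summary.ratio = None
            summary.ratio_reason = str(exc)
        summaries.append(summary)
    return summaries


def summaries_to_frame(summaries: list[DomainDsSummary]) -> pd.DataFrame:
    """Table-2-style frame: one row per group, per-domain mean dS columns and
    the highest/lowest ratio, rounded to 2 decimals for reporting."""
    df = pd.DataFrame([s.as_row() for s in summaries]).set_index("group")
    return df.round(2)
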