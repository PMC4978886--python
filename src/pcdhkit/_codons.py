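"""Shared codon-level utilities: genetic code lookups and CDS validation."""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TABLE))
NUCLEOTIDES = "ACGT"

# purine<->purine / pyrimidine<->pyrimidine
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (no terminal stop expected) to protein."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return str(Seq(cds).translate())


def validate_cds(cds: str, *, require_start: bool = False) -> None:
    """Reject CDS strings with bad length, invalid codons or internal stops."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon not in CODON_TABLE:
            if codon in STOP_CODONS:
                raise ValueError(f"internal stop codon {codon} at codon {i // 3}")
            raise ValueError(f"invalid codon {codon!r} at codon {i // 3}")
    if require_start and not cds.startswith("ATG"):
        raise ValueError("CDS does not start with ATG")


def codons_of(cds: str) -> list[str]:
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> float:
    """Synonymous site count of a sense codon (Nei–Gojobori convention).

    Each position contributes (number of synonymous single-base changes)/3;
    changes that create a stop codon count as nonsynonymous, so the
    synonymous + nonsynonymous site counts always total 3 per codon.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between two codons.

    Codons differing at k positions are connected by k! single-step mutational
    pathways; pathways passing through a stop codon are excluded and the
    remainder re-weighted equally. If every pathway crosses a stop (possible
    only for a handful of codon pairs) all pathways are used, with the
    stop-crossing steps counted as nonsynonymous.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = codon_a
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            aa_cur = CODON_TABLE.get(cur, "*")
            aa_nxt = CODON_TABLE.get(nxt, "*")
            if aa_cur == aa_nxt and aa_nxt != "*":
                sd += 1.0
            else:
                nd += 1.0  # stop-crossing steps count as nonsynonymous
            cur = nxt
        return sd, nd

    paths = [p for order in permutations(diff) if (p := walk(order, False)) is not None]
    if not paths:
        paths = [walk(order, True) for order in permutations(diff)]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd
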