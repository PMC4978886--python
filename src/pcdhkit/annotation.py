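"""Gene-model construction: six-frame ORF scanning and the cadherin-repeat filter.

Candidate gene models are maximal ATG→stop open reading frames on both
strands with a protein-length cutoff (default 700 aa, counting the
initiator Met and excluding the stop), then filtered to those whose protein
carries six detected extracellular cadherin repeats. Repeat detection uses
a sliding amino-acid log-odds profile; for simulated loci the profile is
derived from the simulator's EC templates, for real data a user-supplied
profile plays the same role.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from ._codons import IUPAC_NT, translate_cds
from .motifs import reverse_complement
from .synthetic_locus import LocusModel

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA_ORDER)}
_STOP_RE = re.compile(r"(?=(TAA|TAG|TGA))")
_ATG_RE = re.compile(r"(?=(ATG))")


@dataclass(frozen=True)
class OrfCandidate:
    """A maximal ATG→stop ORF; [start,end) excludes the stop codon."""

    contig_id: str
    strand: str
    frame: int
    start: int
    end: int
    protein_sequence: str

    @property
    def id(self) -> str:
        return f"orf:{self.strand}:{self.start}-{self.end}"


@dataclass
class RepeatCall:
    candidate_id: str
    n_repeats: int
    repeat_intervals: list[tuple[int, int]] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)


@dataclass
class AnnotationEvaluation:
    n_truth: int
    n_predicted: int
    n_true_positive: int

    @property
    def precision(self) -> float:
        return self.n_true_positive / self.n_predicted if self.n_predicted else float("nan")

    @property
    def recall(self) -> float:
        return self.n_true_positive / self.n_truth if self.n_truth else float("nan")


def _validate_genome(genome: str) -> str:
    genome = genome.upper()
    bad = [i for i, ch in enumerate(genome) if ch not in IUPAC_NT]
    if bad:
        shown = ", ".join(map(str, bad[:10]))
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise ValueError(f"non-IUPAC characters at positions {shown}{more}")
    return genome


def _scan_strand(seq: str, min_aa: int) -> list[tuple[int, int, int, str]]:
    """(frame, start, end, protein) for maximal ORFs on one strand of `seq`."""
    stops = [m.start() for m in _STOP_RE.finditer(seq)]
    atgs = [m.start() for m in _ATG_RE.finditer(seq)]
    out = []
    for frame in range(3):
        fstops = [p for p in stops if p % 3 == frame]
        fatgs = [p for p in atgs if p % 3 == frame]
        prev = frame - 3  # sentinel: segment open from the contig start
        for stop in fstops:
            # first ATG strictly after the previous stop codon
            k = bisect_left(fatgs, prev + 3)
            if k < len(fatgs) and fatgs[k] < stop:
                start = fatgs[k]
                n_aa = (stop - start) // 3
                if n_aa >= min_aa:
                    protein = translate_cds(seq[start:stop])
                    out.append((frame, start, stop, protein))
            prev = stop
    return out


def find_orfs(genome: str, min_aa: int = 700, contig_id: str = "locus") -> list[OrfCandidate]:
    """All maximal ATG→stop ORFs, both strands, three frames, >= min_aa.

    Protein length counts the initiator Met and excludes the stop codon.
    ORFs must terminate at a stop codon; open-ended runs at contig edges are
    not reported. Identical intervals arising in different scans are
    deduplicated.
    """
    if not genome:
        return []
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    genome = _validate_genome(genome)
    n = len(genome)
    found: dict[tuple[str, int, int], OrfCandidate] = {}
    for frame, start, stop, protein in _scan_strand(genome, min_aa):
        found[("+", start, stop)] = OrfCandidate(contig_id, "+", frame, start, stop, protein)
    rc = reverse_complement(genome)
    for frame, start, stop, protein in _scan_strand(rc, min_aa):
        # mirror coordinates back to the forward strand
        gstart, gend = n - stop, n - start
        found[("-", gstart, gend)] = OrfCandidate(contig_id, "-", frame, gstart, gend, protein)
    return sorted(found.values(), key=lambda o: (o.start, o.end, o.strand))


class RepeatProfile:
    """Amino-acid log-odds profile of one cadherin (EC) repeat unit."""

    def __init__(self, log_odds: np.ndarray):
        self.log_odds = np.asarray(log_odds, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[0] != 20:
            raise ValueError("log_odds must be 20 x W (rows in ACDEFGHIKLMNPQRSTVWY order)")

    @property
    def width(self) -> int:
        return self.log_odds.shape[1]

    @classmethod
    def from_templates(
        cls,
        templates: list[str],
        pseudocount: float = 1.0,
        background: np.ndarray | None = None,
    ) -> "RepeatProfile":
        widths = {len(t) for t in templates}
        if len(widths) != 1:
            raise ValueError("repeat templates must share one length")
        (w,) = widths
        counts = np.full((20, w), pseudocount)
        for t in templates:
            for j, aa in enumerate(t.upper()):
                if aa in _AA_INDEX:
                    counts[_AA_INDEX[aa], j] += 1.0
        probs = counts / counts.sum(axis=0)
        bg = np.full(20, 1 / 20) if background is None else np.asarray(background, float)
        return cls(np.log2(probs / bg[:, None]))

    def to_tsv(self) -> str:
        header = "\t".join(_AA_ORDER)
        rows = ["\t".join(f"{v:.6f}" for v in col) for col in self.log_odds.T]
        return header + "\n" + "\n".join(rows) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "RepeatProfile":
        lines = [l for l in text.strip().splitlines() if l]
        cols = [[float(x) for x in line.split("\t")] for line in lines[1:]]
        return cls(np.array(cols).T)


def detect_cadherin_repeats(
    protein: str, repeat_profile: RepeatProfile, min_score: float = 0.0
) -> RepeatCall:
    """Greedy left-to-right non-overlapping profile matches above min_score."""
    if not protein:
        raise ValueError("empty protein")
    w = repeat_profile.width
    if w > len(protein):
        raise ValueError("profile wider than protein")
    enc = np.array([_AA_INDEX.get(a, -1) for a in protein.upper()], dtype=int)
    lo = np.vstack([repeat_profile.log_odds, np.zeros((1, w))])  # unknown aa -> 0
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    scores = lo[windows, np.arange(w)].sum(axis=1)
    call = RepeatCall(candidate_id="", n_repeats=0)
    i = 0
    while i < len(scores):
        if scores[i] >= min_score:
            call.repeat_intervals.append((i, i + w))
            call.scores.append(float(scores[i]))
            call.n_repeats += 1
            i += w
        else:
            i += 1
    return call


def annotate_locus(
    genome: str,
    min_aa: int = 700,
    repeat_profile: RepeatProfile | None = None,
    min_score: float = 0.0,
    min_repeats: int = 6,
    truth: LocusModel | None = None,
) -> tuple[list[OrfCandidate], AnnotationEvaluation | None]:
    """ORF scan, then keep candidates whose protein shows >= 6 repeats.

    When simulator truth is supplied, a predicted model is a true positive
    iff its [start,end) interval matches a truth variable exon exactly.
    """
    candidates = find_orfs(genome, min_aa=min_aa)
    if repeat_profile is not None:
        kept = []
        for cand in candidates:
            call = detect_cadherin_repeats(cand.protein_sequence, repeat_profile, min_score)
            if call.n_repeats >= min_repeats:
                kept.append(cand)
        candidates = kept
    evaluation = None
    if truth is not None:
        truth_ves = {
            (gm.variable_exon[0], gm.variable_exon[1], gm.strand)
            for gm in truth.gene_models
        }
        tp = sum(1 for c in candidates if (c.start, c.end, c.strand) in truth_ves)
        evaluation = AnnotationEvaluation(
            n_truth=len(truth_ves), n_predicted=len(candidates), n_true_positive=tp
        )
    return candidates, evaluation
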