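"""Promoter extraction, EM motif discovery and PWM scanning.

Clustered-protocadherin promoters carry a conserved sequence element (CSE)
roughly 200 bp upstream of the translational start codon; within the 2 kb
upstream windows this module discovers over-represented motifs with a
ZOOPS-style (zero-or-one occurrence per sequence) EM algorithm and reports
scored occurrences with offsets relative to the ATG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; any other (ambiguity) character to 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(b)] = i
    return out


@dataclass
class MotifModel:
    """Position probability matrix over {A,C,G,T} with derived statistics."""

    ppm: np.ndarray  # shape (4, W), columns sum to 1
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.ppm.ndim != 2 or self.ppm.shape[0] != 4:
            raise ValueError("ppm must be a 4 x W matrix (rows A,C,G,T)")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        colsums = self.ppm.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("every PPM column must sum to 1")

    @property
    def width(self) -> int:
        return self.ppm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.ppm.argmax(axis=0))

    @property
    def information_content(self) -> float:
        """Total information content in bits, 2 + sum_b p log2 p per column."""
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(self.ppm > 0, self.ppm * np.log2(self.ppm), 0.0)
        return float(np.sum(2.0 + h.sum(axis=0)))

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        p = (self.ppm + 1e-9) / (1.0 + 4e-9)
        return np.log2(p / bg[:, None])

    def max_score(self, background: np.ndarray | None = None) -> float:
        return float(self.log_odds(background).max(axis=0).sum())

    def sample(
        self,
        rng: np.random.Generator,
        min_score_frac: float | None = None,
        max_tries: int = 100,
    ) -> str:
        """Draw one motif instance column-by-column.

        With `min_score_frac`, rejection-sample until the instance scores at
        least that fraction of the maximum log-odds — i.e. condition on the
        instance remaining functional, the way conserved promoter elements
        are under selection to keep binding.
        """
        lo = self.log_odds()
        threshold = None if min_score_frac is None else min_score_frac * self.max_score()
        for _ in range(max_tries):
            cols = [rng.choice(4, p=self.ppm[:, j]) for j in range(self.width)]
            if threshold is None or lo[cols, np.arange(self.width)].sum() >= threshold:
                return "".join(BASES[i] for i in cols)
        return self.consensus

    @classmethod
    def from_sequences(cls, seqs: list[str], pseudocount: float = 0.5) -> "MotifModel":
        widths = {len(s) for s in seqs}
        if len(widths) != 1:
            raise ValueError("all motif instances must have equal length")
        (w,) = widths
        counts = np.full((4, w), pseudocount, dtype=float)
        for s in seqs:
            for j, ch in enumerate(s.upper()):
                if ch in _BASE_INDEX:
                    counts[_BASE_INDEX[ch], j] += 1.0
        return cls(counts / counts.sum(axis=0), pseudocount=pseudocount)

    @classmethod
    def from_consensus(cls, consensus: str, match_prob: float = 0.85) -> "MotifModel":
        """Sharp PWM putting `match_prob` on the consensus base per column."""
        w = len(consensus)
        ppm = np.full((4, w), (1.0 - match_prob) / 3.0)
        for j, ch in enumerate(consensus.upper()):
            ppm[_BASE_INDEX[ch], j] = match_prob
        return cls(ppm)

    def to_meme(self, name: str = "MOTIF1", background: np.ndarray | None = None) -> str:
        """Serialize in MEME minimal motif format."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            "Background letter frequencies",
            " ".join(f"{b} {f:.4f}" for b, f in zip(BASES, bg)),
            "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width}",
        ]
        for j in range(self.width):
            lines.append(" ".join(f"{self.ppm[i, j]:.6f}" for i in range(4)))
        return "\n".join(lines) + "\n"


@dataclass
class PromoterHit:
    """A PWM occurrence; offset is motif start relative to the A of ATG (<0)."""

    gene_id: str
    offset: int
    strand: str
    score: float


@dataclass
class ScanSummary:
    n_promoters: int
    n_with_hit: int
    mean_best_offset: float
    sd_best_offset: float
    best_hits: dict[str, PromoterHit] = field(default_factory=dict)

    @property
    def fraction_with_hit(self) -> float:
        return self.n_with_hit / self.n_promoters if self.n_promoters else 0.0


def extract_promoters(
    genome: str, gene_models, upstream_bp: int = 2000
) -> dict[str, str]:
    """Upstream_bp bases 5' of each gene's ATG, on the coding strand.

    Promoters truncated at contig edges keep their (shorter) actual length;
    a gene flush against the contig edge yields an empty string.
    """
    promoters: dict[str, str] = {}
    for gm in gene_models:
        if gm.strand == "+":
            atg = gm.variable_exon[0]
            start = max(0, atg - upstream_bp)
            promoters[gm.id] = genome[start:atg]
        else:
            atg = gm.variable_exon[1]
            end = min(len(genome), atg + upstream_bp)
            promoters[gm.id] = reverse_complement(genome[atg:end])
    return promoters


def _window_log_probs(enc: np.ndarray, log_mat: np.ndarray, width: int) -> np.ndarray:
    """Sum of per-position log scores over all windows of `enc`."""
    if len(enc) < width:
        return np.empty(0)
    padded = np.vstack([log_mat, np.zeros((1, width))])  # row 4: ambiguity -> 0
    windows = np.lib.stride_tricks.sliding_window_view(enc, width)
    return padded[windows, np.arange(width)].sum(axis=1)


def _background_freqs(encoded: list[np.ndarray]) -> np.ndarray:
    counts = np.ones(4)
    for enc in encoded:
        valid = enc[enc < 4]
        counts += np.bincount(valid, minlength=4)
    return counts / counts.sum()


def discover_motif_em(
    promoters: list[str],
    width: int,
    mode: str = "zoops",
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
    pseudocount: float = 0.5,
) -> tuple[MotifModel, list[np.ndarray]]:
    """EM motif discovery over latent start positions (MEME-style).

    mode "zoops": each sequence carries zero or one occurrence with a learned
    prior; mode "oops": exactly one occurrence per sequence. The 0th-order
    background is estimated from the input. Returns the best-likelihood model
    over `n_restarts` seeded restarts plus per-sequence posterior start
    distributions (last entry of each posterior vector is the absence
    probability in zoops mode).
    """
    if mode not in ("zoops", "oops"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 6 <= width <= 30:
        raise ValueError("width must be in [6, 30]")
    seqs = [s.upper() for s in promoters]
    if any(len(s) < width for s in seqs):
        raise ValueError("motif width exceeds the shortest sequence")

    encoded = [_encode(s) for s in seqs]
    bg = _background_freqs(encoded)
    log_bg = np.log(bg)
    # per-sequence background log-likelihood of the full sequence
    bg_ll = []
    for enc in encoded:
        valid = enc[enc < 4]
        bg_ll.append(float(np.bincount(valid, minlength=4) @ log_bg))

    # per-sequence invariants reused across restarts and iterations
    windows_list = [
        np.lib.stride_tricks.sliding_window_view(enc, width) for enc in encoded
    ]
    win_bg_list = [
        _window_log_probs(enc, np.tile(log_bg[:, None], width), width)
        for enc in encoded
    ]
    onehot_list = [
        np.stack([(w == b) for b in range(4)]).astype(float) for w in windows_list
    ]  # each: (4, m, width)

    rng = np.random.default_rng(seed)
    best: tuple[float, MotifModel, list[np.ndarray]] | None = None

    # MEME-style seeding: screen random candidate subsequences by how well
    # the data matches a sharp PWM built from each, keep the best as starts.
    total_windows = sum(len(e) - width + 1 for e in encoded)
    n_candidates = int(min(1000, max(20 * n_restarts, 150, total_windows // 30)))
    scored = []
    for _ in range(n_candidates):
        si = rng.integers(len(seqs))
        sj = rng.integers(len(seqs[si]) - width + 1)
        cand = MotifModel.from_consensus(seqs[si][sj : sj + width], 0.7)
        log_m = np.log(cand.ppm)
        score = sum(
            float(np.max(_window_log_probs(enc, log_m, width) - wbg))
            for enc, wbg in zip(encoded, win_bg_list)
        )
        scored.append((score, si, sj))
    scored.sort(reverse=True)
    starts = []
    seen = set()
    for score, si, sj in scored:
        window = seqs[si][sj : sj + width]
        if window not in seen:
            seen.add(window)
            starts.append(window)
        if len(starts) >= max(1, n_restarts):
            break

    def run_em(ppm: np.ndarray) -> tuple[float, np.ndarray, list[np.ndarray]]:
        gamma = 0.5 if mode == "zoops" else 1.0
        prev_ll = -math.inf
        posteriors: list[np.ndarray] = []

        for _it in range(max_iter):
            log_motif = np.log(np.maximum(ppm, 1e-12))
            # MAP-EM objective: data log-likelihood plus the Dirichlet
            # log-prior implied by the pseudocounts (monotone under EM;
            # the raw likelihood alone is not, once pseudocounts regularize
            # the M-step).
            total_ll = pseudocount * float(log_motif.sum())
            posteriors = []
            counts = np.full((4, width), pseudocount)
            gamma_num = 0.0
            for enc, base_ll, windows, win_bg, onehot in zip(
                encoded, bg_ll, windows_list, win_bg_list, onehot_list
            ):
                m = len(enc) - width + 1
                # log-lik of sequence with motif at each start (bg elsewhere)
                win_motif = _window_log_probs(enc, log_motif, width)
                with_motif = base_ll - win_bg + win_motif + math.log(gamma / m)
                if mode == "zoops":
                    parts = np.append(with_motif, base_ll + math.log(max(1 - gamma, 1e-12)))
                else:
                    parts = with_motif
                seq_ll = float(np.logaddexp.reduce(parts))
                total_ll += seq_ll
                post = np.exp(parts - seq_ll)
                posteriors.append(post)
                w_start = post[:m]
                gamma_num += w_start.sum()
                counts += np.einsum("bmw,m->bw", onehot, w_start)
            if total_ll < prev_ll - 1e-6:
                raise AssertionError(
                    f"EM objective decreased: {prev_ll} -> {total_ll}"
                )
            ppm = counts / counts.sum(axis=0)
            if mode == "zoops":
                gamma = min(max(gamma_num / len(seqs), 1e-6), 1 - 1e-6)
            if total_ll - prev_ll < tol:
                prev_ll = total_ll
                break
            prev_ll = total_ll
        return prev_ll, ppm, posteriors

    for start_window in starts:
        result = run_em(MotifModel.from_consensus(start_window, 0.7).ppm)
        if best is None or result[0] > best[0]:
            best = result

    # phase refinement: EM can lock onto a shifted copy of the optimum, so
    # hill-climb over column-shifted restarts of the best model until no
    # shift improves the objective (background fills vacated columns).
    assert best is not None
    for _pass in range(width):
        improved = False
        for shift in (-2, -1, 1, 2):
            base = best[1]
            shifted = np.tile(bg[:, None], width).astype(float)
            if shift > 0:
                shifted[:, shift:] = base[:, : width - shift]
            else:
                shifted[:, :shift] = base[:, -shift:]
            result = run_em(shifted)
            if result[0] > best[0] + 1e-9:
                best = result
                improved = True
        if not improved:
            break

    return MotifModel(best[1], pseudocount=pseudocount), best[2]


def scan_pwm(
    promoters: dict[str, str],
    motif: MotifModel,
    min_logodds: float | None = None,
    background: np.ndarray | None = None,
    scan_reverse: bool = False,
) -> tuple[list[PromoterHit], ScanSummary]:
    """All windows scoring >= threshold; offsets are relative to the ATG.

    The promoter is assumed to end immediately 5' of the translational start,
    so a window starting at position i of a length-P promoter has offset
    i - P (always negative). Default threshold is 60% of the maximum
    achievable log-odds score. Only the coding strand is scanned unless
    `scan_reverse` is set.
    """
    lo = motif.log_odds(background)
    if min_logodds is None:
        min_logodds = 0.6 * motif.max_score(background)
    hits: list[PromoterHit] = []
    best: dict[str, PromoterHit] = {}
    for gene_id in sorted(promoters):
        seq = promoters[gene_id].upper()
        plen = len(seq)
        strands = [("+", seq)] + ([("-", reverse_complement(seq))] if scan_reverse else [])
        for strand, s in strands:
            scores = _window_log_probs(_encode(s), lo, motif.width)
            for i in np.nonzero(scores >= min_logodds)[0]:
                start = int(i) if strand == "+" else plen - motif.width - int(i)
                hit = PromoterHit(gene_id, start - plen, strand, float(scores[i]))
                hits.append(hit)
                if gene_id not in best or hit.score > best[gene_id].score:
                    best[gene_id] = hit
    offsets = np.array([h.offset for h in best.values()], dtype=float)
    summary = ScanSummary(
        n_promoters=len(promoters),
        n_with_hit=len(best),
        mean_best_offset=float(offsets.mean()) if len(offsets) else math.nan,
        sd_best_offset=float(offsets.std(ddof=0)) if len(offsets) else math.nan,
        best_hits=best,
    )
    return hits, summary


def has_cgct_box(motif: MotifModel) -> bool:
    """Exact substring check for the CGCT tetranucleotide in the consensus."""
    return "CGCT" in motif.consensus
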