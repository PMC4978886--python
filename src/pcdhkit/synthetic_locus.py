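"""Ground-truthed synthetic clustered-protocadherin-like loci.

Clustered protocadherins are encoded as tandem arrays of large "variable"
exons — each coding for six extracellular cadherin repeats (EC1–EC6), a
transmembrane segment and a short tail — spliced to a set of "constant"
exons shared by every isoform of a cluster. This module emulates such a
locus end to end: an ancestral variable-exon CDS is evolved along a random
duplication tree under a codon model with per-domain selective constraint,
optional inter-paralog gene-conversion tracts homogenize chosen domains,
and the evolved paralogs are laid out on a synthetic contig together with
planted promoter motifs, decoy ORFs and per-cluster constant exons.
Sequencing fragments can then be drawn from the spliced transcripts.

All coordinates are 0-based half-open internally; GFF3 output follows the
1-based inclusive convention of the format. Every operation is
deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skbio import TreeNode

from ._codons import (
    CODON_TABLE,
    SENSE_CODONS,
    STOP_CODONS,
    TRANSITION,
    TRANSVERSIONS,
    codons_of,
    translate_cds,
    validate_cds,
)
from .motifs import MotifModel

DOMAIN_LABELS = ("EC1", "EC2", "EC3", "EC4", "EC5", "EC6", "TM", "TAIL")
EC_LABELS = DOMAIN_LABELS[:6]

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DomainPartition:
    """Ordered protein-coordinate segments labelling EC1–EC6, TM and TAIL.

    Coordinates are 0-based half-open over the variable-exon protein; the
    constant domain of the spliced transcript is referred to by `cd_label`.
    """

    segments: tuple[tuple[str, int, int], ...]
    cd_label: str = "CD"

    def __post_init__(self) -> None:
        prev_end = None
        for label, start, end in self.segments:
            if start >= end or start < 0:
                raise ValueError(f"bad segment {label}: [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"segment {label} overlaps/unordered at {start}")
            prev_end = end

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.segments)

    def validate_cpcdh(self, protein_len: int) -> None:
        """A valid cPcdh-like isoform carries exactly six EC segments."""
        ec = [l for l in self.labels if l.startswith("EC")]
        if sorted(ec) != list(EC_LABELS):
            raise ValueError(f"expected exactly EC1..EC6, got {ec}")
        if self.segments[-1][2] > protein_len:
            raise ValueError("partition extends beyond protein length")

    def range_of(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.segments:
            if lab == label:
                return start, end
        raise KeyError(label)

    def label_at(self, aa_pos: int) -> str | None:
        for lab, start, end in self.segments:
            if start <= aa_pos < end:
                return lab
        return None

    def region_range(self, labels: tuple[str, ...]) -> tuple[int, int]:
        """Span covering a run of contiguous labels (e.g. EC2–EC3)."""
        spans = [self.range_of(l) for l in labels]
        starts, ends = zip(*spans)
        lo, hi = min(starts), max(ends)
        covered = sum(e - s for s, e in spans)
        if covered != hi - lo:
            raise ValueError(f"labels {labels} are not contiguous")
        return lo, hi


@dataclass(frozen=True)
class GeneModel:
    """One isoform: a variable exon spliced to its cluster's constant exons."""

    id: str
    cluster_id: str
    strand: str
    variable_exon: tuple[int, int]
    constant_exons: tuple[tuple[int, int], ...]
    cds_sequence: str
    protein_sequence: str
    partition: DomainPartition

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        if translate_cds(self.cds_sequence) != self.protein_sequence:
            raise ValueError(f"{self.id}: CDS does not translate to protein")
        ivals = sorted((self.variable_exon, *self.constant_exons))
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(f"{self.id}: overlapping exons")

    @property
    def variable_protein(self) -> str:
        n_aa = (self.variable_exon[1] - self.variable_exon[0]) // 3
        return self.protein_sequence[:n_aa]

    @property
    def constant_protein(self) -> str:
        n_aa = (self.variable_exon[1] - self.variable_exon[0]) // 3
        return self.protein_sequence[n_aa:]

    def domain_protein(self, label: str) -> str:
        if label == self.partition.cd_label:
            return self.constant_protein
        s, e = self.partition.range_of(label)
        return self.protein_sequence[s:e]


@dataclass(frozen=True)
class ConversionEvent:
    """One non-reciprocal tract copy between paralogs (codon coordinates)."""

    donor_id: str
    acceptor_id: str
    tract_start_codon: int
    tract_end_codon: int
    time_of_event: int

    def __post_init__(self) -> None:
        if self.donor_id == self.acceptor_id:
            raise ValueError("donor and acceptor must differ")
        if not 0 <= self.tract_start_codon < self.tract_end_codon:
            raise ValueError("bad tract bounds")


@dataclass
class LocusModel:
    """A simulated contig plus all ground truth the analyses may be scored on."""

    genome_sequence: str
    gene_models: list[GeneModel]
    events: list[ConversionEvent]
    motif_truth: list[tuple[str, int]]
    decoys: list[tuple[int, int]]
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.genome_sequence)
        for gm in self.gene_models:
            for s, e in (gm.variable_exon, *gm.constant_exons):
                if not 0 <= s < e <= n:
                    raise ValueError(f"{gm.id}: exon [{s},{e}) outside genome")
        for _, off in self.motif_truth:
            if off >= 0:
                raise ValueError("motif offsets must be negative (upstream)")

    def cluster_ids(self) -> list[str]:
        seen: list[str] = []
        for gm in self.gene_models:
            if gm.cluster_id not in seen:
                seen.append(gm.cluster_id)
        return seen

    def genes_of(self, cluster_id: str) -> list[GeneModel]:
        return [g for g in self.gene_models if g.cluster_id == cluster_id]


@dataclass
class ClusterInput:
    """Everything assemble_locus needs for one cluster."""

    name: str
    cds_by_id: dict[str, str]
    constant_exon_seq: str
    partition: DomainPartition
    events: tuple[ConversionEvent, ...] = ()


# ---------------------------------------------------------------------------
# ancestral sequence construction


def make_partition(
    ec_len_aa: int = 110, tm_len_aa: int = 25, tail_len_aa: int = 45
) -> DomainPartition:
    segs = []
    pos = 0
    for label in EC_LABELS:
        segs.append((label, pos, pos + ec_len_aa))
        pos += ec_len_aa
    segs.append(("TM", pos, pos + tm_len_aa))
    pos += tm_len_aa
    segs.append(("TAIL", pos, pos + tail_len_aa))
    return DomainPartition(tuple(segs))


_HYDROPHOBIC = "AILMFVWG"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    by_aa: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        by_aa.setdefault(CODON_TABLE[codon], []).append(codon)
    return "".join(
        by_aa[aa][rng.integers(len(by_aa[aa]))] for aa in protein
    )


def make_ancestral_cluster(
    ec_len_aa: int = 110,
    tm_len_aa: int = 25,
    tail_len_aa: int = 45,
    ec_divergence: float = 0.25,
    seed: int = 0,
) -> tuple[str, DomainPartition, list[str]]:
    """Build an ancestral variable-exon CDS from a shared EC repeat template.

    The six EC domains are independent corruptions (at `ec_divergence` amino
    acid replacement rate) of one master repeat consensus, so a log-odds
    profile derived from them detects all six repeats in descendants. Returns
    (ancestral CDS starting with ATG, partition, the six EC amino-acid
    template sequences).
    """
    rng = np.random.default_rng(seed)
    consensus = "".join(_AA20[i] for i in rng.integers(20, size=ec_len_aa))
    ec_seqs = []
    for _ in range(6):
        aa = list(consensus)
        n_mut = rng.binomial(ec_len_aa, ec_divergence)
        for pos in rng.choice(ec_len_aa, size=n_mut, replace=False):
            aa[pos] = _AA20[rng.integers(20)]
        ec_seqs.append("".join(aa))
    ec_seqs[0] = "M" + ec_seqs[0][1:]  # initiator Met opens EC1
    tm = "".join(_HYDROPHOBIC[i] for i in rng.integers(len(_HYDROPHOBIC), size=tm_len_aa))
    tail = "".join(_AA20[i] for i in rng.integers(20, size=tail_len_aa))
    protein = "".join(ec_seqs) + tm + tail
    cds = _reverse_translate(protein, rng)
    cds = "ATG" + cds[3:]
    partition = make_partition(ec_len_aa, tm_len_aa, tail_len_aa)
    return cds, partition, ec_seqs


def make_constant_exon_seq(cd_len_aa: int = 125, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    protein = "".join(_AA20[i] for i in rng.integers(20, size=cd_len_aa))
    return _reverse_translate(protein, rng)


# ---------------------------------------------------------------------------
# codon evolution along a duplication tree


def _random_coalescent_tree(n: int, branch_scale: float, rng: np.random.Generator) -> TreeNode:
    """Random bifurcating topology with coalescent waiting times, rescaled so
    the root-to-tip path length equals `branch_scale` substitutions/site."""
    lineages = [TreeNode(name=f"iso{i + 1}") for i in range(n)]
    heights = {id(node): 0.0 for node in lineages}
    h = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        h += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        parent = TreeNode(children=[a, b])
        a.length = h - heights[id(a)]
        b.length = h - heights[id(b)]
        heights[id(parent)] = h
        lineages.append(parent)
    root = lineages[0]
    root.length = None
    if h > 0:
        scale = branch_scale / h
        for node in root.traverse(include_self=False):
            node.length *= scale
    return root


def _evolve_branch(
    seq: np.ndarray,
    t: float,
    kappa: float,
    omega_codon: np.ndarray,
    rng: np.random.Generator,
    protect_start: bool,
) -> int:
    """Mutate `seq` (int-coded nt array) in place along a branch of length t
    substitutions/site; returns the number of accepted substitutions."""
    L = len(seq)
    n_attempts = rng.poisson(t * L)
    accepted = 0
    bases = "ACGT"
    for _ in range(n_attempts):
        site = int(rng.integers(L)) if L else 0
        codon_idx = site // 3
        if protect_start and codon_idx == 0:
            continue
        old_base = bases[seq[site]]
        if rng.random() < kappa / (kappa + 2.0):
            new_base = TRANSITION[old_base]
        else:
            new_base = TRANSVERSIONS[old_base][rng.integers(2)]
        cstart = codon_idx * 3
        codon = [bases[b] for b in seq[cstart : cstart + 3]]
        old_codon = "".join(codon)
        codon[site - cstart] = new_base
        new_codon = "".join(codon)
        if new_codon in STOP_CODONS:
            continue
        if CODON_TABLE[new_codon] != CODON_TABLE[old_codon]:
            if rng.random() >= omega_codon[codon_idx]:
                continue
        seq[site] = bases.index(new_base)
        accepted += 1
    return accepted


def evolve_cds(
    cds: str,
    t: float,
    kappa: float = 2.0,
    omega_per_domain: dict[str, float] | None = None,
    partition: DomainPartition | None = None,
    default_omega: float = 0.2,
    seed: int = 0,
    protect_start: bool = True,
) -> str:
    """Evolve one CDS along a single branch of length t substitutions/site."""
    validate_cds(cds)
    n_codons = len(cds) // 3
    omega_codon = np.full(n_codons, default_omega)
    if omega_per_domain:
        if partition is None:
            raise ValueError("omega_per_domain requires a partition")
        for label, om in omega_per_domain.items():
            s, e = partition.range_of(label)
            omega_codon[s:e] = om
    rng = np.random.default_rng(seed)
    base_index = {b: i for i, b in enumerate("ACGT")}
    seq = np.array([base_index[b] for b in cds], dtype=np.int8)
    _evolve_branch(seq, t, kappa, omega_codon, rng, protect_start)
    return "".join("ACGT"[b] for b in seq)


def simulate_cluster(
    n_isoforms: int,
    ancestral_cds: str,
    branch_scale: float,
    kappa: float = 2.0,
    omega_per_domain: dict[str, float] | None = None,
    partition: DomainPartition | None = None,
    default_omega: float = 0.2,
    seed: int = 0,
    protect_start: bool = True,
) -> tuple[TreeNode, dict[str, str]]:
    """Evolve an ancestral CDS codon-by-codon along a random duplication tree.

    Mutations are proposed per nucleotide with a transition/transversion bias
    `kappa`; proposals creating stop codons are rejected, and nonsynonymous
    proposals are accepted with the probability `omega` of the protein domain
    they fall in (synonymous proposals always accepted). Each tree node
    carries `n_subs`, the realized number of accepted substitutions on its
    parent branch. Deterministic given `seed`.
    """
    if n_isoforms < 2:
        raise ValueError("n_isoforms must be >= 2")
    validate_cds(ancestral_cds)
    if omega_per_domain and partition is None:
        raise ValueError("omega_per_domain requires a partition")
    n_codons = len(ancestral_cds) // 3
    omega_codon = np.full(n_codons, default_omega)
    if omega_per_domain:
        for label, om in omega_per_domain.items():
            s, e = partition.range_of(label)
            omega_codon[s:e] = om

    rng = np.random.default_rng(seed)
    tree = _random_coalescent_tree(n_isoforms, branch_scale, rng)
    base_index = {b: i for i, b in enumerate("ACGT")}
    root_seq = np.array([base_index[b] for b in ancestral_cds], dtype=np.int8)

    cds_by_leaf: dict[str, str] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = seq.copy()
            child.n_subs = _evolve_branch(
                child_seq, child.length, kappa, omega_codon, rng, protect_start
            )
            if child.is_tip():
                cds_by_leaf[child.name] = "".join("ACGT"[b] for b in child_seq)
            else:
                descend(child, child_seq)

    tree.n_subs = 0
    descend(tree, root_seq)
    return tree, {name: cds_by_leaf[name] for name in sorted(cds_by_leaf)}


# ---------------------------------------------------------------------------
# gene conversion


def _truncated_geometric(
    mean: float, lo: int, hi: int, rng: np.random.Generator
) -> int:
    draw = int(rng.geometric(min(1.0, 1.0 / max(mean, 1.0))))
    return int(min(max(draw, lo), hi))


def apply_gene_conversion(
    cds_set: dict[str, str],
    tree: TreeNode,
    rate: float,
    tract_len_dist: tuple[float, int, int] = (30.0, 10, 80),
    allowed_domains: set[str] | frozenset[str] = frozenset(),
    partition: DomainPartition | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], list[ConversionEvent]]:
    """Apply inter-paralog gene-conversion tracts restricted to chosen domains.

    The post-duplication epoch is treated as one unit of time, so the number
    of events is Poisson(rate × n_pairs). Each event copies a donor tract
    (truncated-geometric codon length) verbatim into the acceptor; events are
    applied sequentially to the tip sequences and logged.
    """
    ids = sorted(cds_set)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate > 0 and not allowed_domains:
        raise ValueError("allowed_domains must be non-empty when rate > 0")
    rng = np.random.default_rng(seed)
    out = dict(cds_set)
    events: list[ConversionEvent] = []
    if rate == 0:
        return out, events
    if partition is None:
        raise ValueError("partition required when rate > 0")
    segments = [
        (label, s, e)
        for label, s, e in partition.segments
        if label in allowed_domains
    ]
    if not segments:
        raise ValueError("allowed_domains do not match any partition segment")
    seg_weights = np.array([e - s for _, s, e in segments], dtype=float)
    seg_weights /= seg_weights.sum()
    mean_len, lo, hi = tract_len_dist

    n_pairs = len(ids) * (len(ids) - 1) // 2
    n_events = rng.poisson(rate * n_pairs)
    for t in range(n_events):
        di, ai = rng.choice(len(ids), size=2, replace=False)
        donor, acceptor = ids[di], ids[ai]
        _, seg_s, seg_e = segments[rng.choice(len(segments), p=seg_weights)]
        tract = _truncated_geometric(mean_len, int(lo), int(hi), rng)
        tract = min(tract, seg_e - seg_s)
        start = seg_s + int(rng.integers(seg_e - seg_s - tract + 1))
        end = start + tract
        n_codons = len(out[acceptor]) // 3
        if end > n_codons:
            raise ValueError("tract extends beyond CDS")
        acc = out[acceptor]
        out[acceptor] = acc[: 3 * start] + out[donor][3 * start : 3 * end] + acc[3 * end :]
        events.append(ConversionEvent(donor, acceptor, start, end, t))
    return out, events


# ---------------------------------------------------------------------------
# locus assembly


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _random_orf(n_aa: int, rng: np.random.Generator) -> str:
    """ATG + random sense codons + TAA; ORF protein length is n_aa."""
    body = "".join(
        SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_aa - 1)
    )
    return "ATG" + body + "TAA"


def assemble_locus(
    clusters: list[ClusterInput],
    intergenic_len: int = 2500,
    promoter_pwm: MotifModel | None = None,
    motif_offset: int = -200,
    n_decoys: int = 5,
    decoy_len_aa: int = 350,
    ce_intron_len: int = 200,
    motif_min_score_frac: float | None = 0.6,
    seed: int = 0,
) -> LocusModel:
    """Lay the evolved clusters out on a synthetic contig.

    Per cluster: [spacer+promoter, variable exon, stop] per isoform, then the
    shared constant exons (split in three, separated by fixed-length neutral
    introns). Decoy ORFs follow the last cluster. A sample from
    `promoter_pwm` is planted at `motif_offset` upstream of every gene's ATG,
    and an in-frame TAA immediately 5' of each ATG pins the ORF start.
    """
    if intergenic_len < 0:
        raise ValueError("intergenic_len must be >= 0")
    if motif_offset >= 0:
        raise ValueError("motif_offset must be negative (upstream)")
    if promoter_pwm is not None and intergenic_len < -motif_offset + promoter_pwm.width:
        raise ValueError("intergenic_len too short to hold the promoter motif")
    if promoter_pwm is not None and -motif_offset < promoter_pwm.width + 3:
        raise ValueError("motif placement overlaps the pre-ATG stop codon")

    rng = np.random.default_rng(seed)
    parts: list[str] = []
    cursor = 0
    gene_rows: list[dict] = []
    motif_truth: list[tuple[str, int]] = []
    decoys: list[tuple[int, int]] = []

    def emit(seq: str) -> int:
        nonlocal cursor
        parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    for cluster in clusters:
        validate_cds(cluster.constant_exon_seq)
        for iso in sorted(cluster.cds_by_id):
            cds = cluster.cds_by_id[iso]
            validate_cds(cds, require_start=True)
            spacer = list(_random_dna(intergenic_len, rng))
            spacer[intergenic_len - 3 :] = "TAA"  # in-frame stop pins the ORF start
            if promoter_pwm is not None:
                sample = promoter_pwm.sample(rng, min_score_frac=motif_min_score_frac)
                pos = intergenic_len + motif_offset
                spacer[pos : pos + promoter_pwm.width] = sample
            emit("".join(spacer))
            gene_id = f"{cluster.name}.{iso}"
            ve_start = emit(cds)
            emit("TAA")
            gene_rows.append(
                dict(
                    id=gene_id,
                    cluster=cluster.name,
                    ve=(ve_start, ve_start + len(cds)),
                    cds=cds,
                    partition=cluster.partition,
                )
            )
            if promoter_pwm is not None:
                motif_truth.append((gene_id, motif_offset))
        # shared constant exons, split in three with fixed-length introns
        emit(_random_dna(intergenic_len, rng))
        ce = cluster.constant_exon_seq
        third = len(ce) // 3
        pieces = [ce[:third], ce[third : 2 * third], ce[2 * third :]]
        ce_intervals: list[tuple[int, int]] = []
        for k, piece in enumerate(pieces):
            if k:
                emit(_random_dna(ce_intron_len, rng))
            s = emit(piece)
            ce_intervals.append((s, s + len(piece)))
        emit("TAA")
        for row in gene_rows:
            if row["cluster"] == cluster.name:
                row["ce"] = tuple(ce_intervals)

    for _ in range(n_decoys):
        spacer = list(_random_dna(intergenic_len, rng))
        spacer[intergenic_len - 3 :] = "TAA"
        emit("".join(spacer))
        orf = _random_orf(decoy_len_aa, rng)
        s = emit(orf)
        decoys.append((s, s + len(orf) - 3))  # stop codon excluded
    emit(_random_dna(intergenic_len, rng))

    genome = "".join(parts)
    gene_models = []
    events: list[ConversionEvent] = []
    for cluster in clusters:
        events.extend(cluster.events)
    for row in gene_rows:
        full_cds = row["cds"] + next(
            c.constant_exon_seq for c in clusters if c.name == row["cluster"]
        )
        gene_models.append(
            GeneModel(
                id=row["id"],
                cluster_id=row["cluster"],
                strand="+",
                variable_exon=row["ve"],
                constant_exons=row["ce"],
                cds_sequence=full_cds,
                protein_sequence=translate_cds(full_cds),
                partition=row["partition"],
            )
        )
    return LocusModel(
        genome_sequence=genome,
        gene_models=gene_models,
        events=events,
        motif_truth=motif_truth,
        decoys=decoys,
        seed=seed,
        params=dict(
            intergenic_len=intergenic_len,
            motif_offset=motif_offset,
            n_decoys=n_decoys,
            decoy_len_aa=decoy_len_aa,
            ce_intron_len=ce_intron_len,
        ),
    )


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class FragmentPlacement:
    """One sequenced fragment; `blocks` are genomic intervals (spliced)."""

    name: str
    cluster_id: str
    gene_id: str
    blocks: tuple[tuple[int, int], ...]
    unique: bool


def _transcript_blocks(gm: GeneModel) -> list[tuple[int, int]]:
    return [gm.variable_exon, *gm.constant_exons]


def _map_to_genome(
    blocks: list[tuple[int, int]], start: int, end: int
) -> tuple[tuple[int, int], ...]:
    """Map a transcript-coordinate interval onto genomic exon blocks."""
    out = []
    offset = 0
    for bs, be in blocks:
        blen = be - bs
        lo = max(start, offset)
        hi = min(end, offset + blen)
        if lo < hi:
            out.append((bs + lo - offset, bs + hi - offset))
        offset += blen
    return tuple(out)


def simulate_reads(
    locus: LocusModel,
    cluster_expression: dict[str, float],
    n_fragments: int,
    frag_len: int = 300,
    read_len: int = 100,
    seed: int = 0,
    frac_multi: float = 0.0,
) -> list[FragmentPlacement]:
    """Draw sequencing fragments from spliced transcripts.

    Cluster sampling weights are chosen so that the *expected* number of
    fragments overlapping a cluster's constant exons is proportional to
    target_FPKM × constant-exon kilobases, i.e. constant-exon counting
    downstream recovers the target abundances up to one common scale factor.
    """
    if frag_len < read_len:
        raise ValueError("frag_len must be >= read_len")
    if any(v < 0 for v in cluster_expression.values()):
        raise ValueError("expression values must be >= 0")
    total = sum(cluster_expression.values())
    if total <= 0:
        if n_fragments > 0:
            raise ValueError("zero total abundance with n_fragments > 0")
        return []

    rng = np.random.default_rng(seed)
    cids = sorted(cluster_expression)
    weights = []
    cluster_iso: dict[str, list[GeneModel]] = {}
    for cid in cids:
        genes = locus.genes_of(cid)
        if not genes and cluster_expression[cid] > 0:
            raise ValueError(f"no gene models for cluster {cid!r}")
        cluster_iso[cid] = genes
        fpkm = cluster_expression[cid]
        if fpkm == 0 or not genes:
            weights.append(0.0)
            continue
        ce_len = sum(e - s for s, e in genes[0].constant_exons)
        p_overlap = 0.0
        for gm in genes:
            T = sum(e - s for s, e in _transcript_blocks(gm))
            if T < frag_len:
                raise ValueError(f"fragment length {frag_len} exceeds transcript {gm.id}")
            nstarts = T - frag_len + 1
            p_overlap += min(nstarts, ce_len + frag_len - 1) / nstarts
        p_overlap /= len(genes)
        weights.append(fpkm * (ce_len / 1000.0) / p_overlap)
    weights = np.asarray(weights)
    probs = weights / weights.sum()
    counts = rng.multinomial(n_fragments, probs)

    placements: list[FragmentPlacement] = []
    idx = 0
    for cid, n_c in zip(cids, counts):
        genes = cluster_iso[cid]
        for _ in range(int(n_c)):
            gm = genes[int(rng.integers(len(genes)))]
            blocks = _transcript_blocks(gm)
            T = sum(e - s for s, e in blocks)
            start = int(rng.integers(T - frag_len + 1))
            gblocks = _map_to_genome(blocks, start, start + frag_len)
            unique = bool(rng.random() >= frac_multi)
            placements.append(
                FragmentPlacement(f"frag{idx:07d}", cid, gm.id, gblocks, unique)
            )
            idx += 1
    return placements
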