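"""End-to-end orchestration: simulate -> annotate -> identity -> dsconv ->
tree -> motifs -> express, from one config, with a reproducibility manifest.

The config is a plain nested dict (YAML on disk). All randomness flows from
one seed; per-stage seeds are derived deterministically from it, so
re-running with the same config and seed reproduces identical output
checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotation, ds_geneconv, expression, identity, io, motifs, phylogeny
from .synthetic_locus import (
    ClusterInput,
    LocusModel,
    apply_gene_conversion,
    assemble_locus,
    evolve_cds,
    make_ancestral_cluster,
    make_constant_exon_seq,
    simulate_cluster,
    simulate_reads,
)

STAGES = ("simulate", "annotate", "identity", "dsconv", "tree", "motifs", "express")

DEFAULT_MOTIF_CONSENSUS = "GTCGCTAATGGCA"  # 13 bp, carries a CGCT box


def default_config() -> dict:
    """The demo configuration: two clusters of eight isoforms plus decoys."""
    return {
        "locus": {
            "clusters": [
                {"name": "alpha", "n_isoforms": 8, "conversion_rate": 0.0},
                {"name": "gamma1", "n_isoforms": 8, "conversion_rate": 10.0},
            ],
            "ec_len_aa": 110,
            "tm_len_aa": 25,
            "tail_len_aa": 45,
            "cd_len_aa": 125,
            "ec_divergence": 0.25,
            "branch_scale": 0.15,
            "cluster_divergence": 0.10,
            "kappa": 2.0,
            "default_omega": 0.2,
            "conversion": {
                "tract_mean": 30,
                "tract_min": 10,
                "tract_max": 80,
                "domains": ["EC4", "EC5", "EC6"],
            },
            "motif_consensus": DEFAULT_MOTIF_CONSENSUS,
            "motif_offset": -200,
            "intergenic_len": 2500,
            "ce_intron_len": 200,
            "decoys": {"n": 5, "len_aa": 350},
        },
        "reads": {
            "n_fragments": 100000,
            "frag_len": 300,
            "read_len": 100,
            "expression": {"alpha": 300.0, "gamma1": 100.0},
        },
        "analysis": {
            "min_aa": 700,
            "min_repeat_score": 0.0,
            "identity_threshold": 90.0,
            "identity_region": ["EC2", "EC3"],
            "bootstrap_reps": 100,
            "motif_width": 13,
            "motif_restarts": 10,
            "promoter_bp": 2000,
        },
    }


def validate_config(config: dict) -> None:
    """Minimal schema validation, performed before any compute."""
    for section in ("locus", "reads", "analysis"):
        if section not in config or not isinstance(config[section], dict):
            raise ValueError(f"config missing section {section!r}")
    clusters = config["locus"].get("clusters")
    if not isinstance(clusters, list) or not clusters:
        raise ValueError("config locus.clusters must be a non-empty list")
    names = set()
    for c in clusters:
        if "name" not in c or "n_isoforms" not in c:
            raise ValueError("each cluster needs 'name' and 'n_isoforms'")
        if int(c["n_isoforms"]) < 2:
            raise ValueError("each cluster needs n_isoforms >= 2")
        if c["name"] in names:
            raise ValueError(f"duplicate cluster name {c['name']!r}")
        names.add(c["name"])


@dataclass
class SimulatedLocus:
    """A locus plus the simulator internals the analyses may be scored on."""

    locus: LocusModel
    trees: dict[str, object]
    repeat_templates: list[str]
    planted_pwm: motifs.MotifModel
    partition: object
    ancestral_cds: str
    cds_pre_conversion: dict[str, dict[str, str]] = field(default_factory=dict)


def _derive_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def simulate_locus(locus_cfg: dict, seed: int) -> SimulatedLocus:
    """Build a full locus per the config; all clusters share one ancestral
    variable-exon gene, as tandem clusters are themselves paralogous."""
    ancestral_cds, partition, ec_templates = make_ancestral_cluster(
        ec_len_aa=locus_cfg.get("ec_len_aa", 110),
        tm_len_aa=locus_cfg.get("tm_len_aa", 25),
        tail_len_aa=locus_cfg.get("tail_len_aa", 45),
        ec_divergence=locus_cfg.get("ec_divergence", 0.25),
        seed=_derive_seed(seed, 0),
    )
    pwm = motifs.MotifModel.from_consensus(
        locus_cfg.get("motif_consensus", DEFAULT_MOTIF_CONSENSUS)
    )
    conv = locus_cfg.get("conversion", {})
    clusters: list[ClusterInput] = []
    trees: dict[str, object] = {}
    pre: dict[str, dict[str, str]] = {}
    cluster_divergence = float(locus_cfg.get("cluster_divergence", 0.10))
    for k, ccfg in enumerate(locus_cfg["clusters"], start=1):
        # each cluster radiates from its own anciently-diverged copy of the
        # ancestral gene, giving the inter-cluster split a real branch
        cluster_ancestor = evolve_cds(
            ancestral_cds,
            cluster_divergence,
            kappa=float(locus_cfg.get("kappa", 2.0)),
            partition=partition,
            default_omega=float(locus_cfg.get("default_omega", 0.2)),
            seed=_derive_seed(seed, 1000 + k),
        )
        tree, cds_by_id = simulate_cluster(
            n_isoforms=int(ccfg["n_isoforms"]),
            ancestral_cds=cluster_ancestor,
            branch_scale=float(ccfg.get("branch_scale", locus_cfg.get("branch_scale", 0.15))),
            kappa=float(locus_cfg.get("kappa", 2.0)),
            default_omega=float(locus_cfg.get("default_omega", 0.2)),
            partition=partition,
            seed=_derive_seed(seed, 10 + k),
        )
        pre[ccfg["name"]] = dict(cds_by_id)
        rate = float(ccfg.get("conversion_rate", 0.0))
        events = ()
        if rate > 0:
            cds_by_id, ev = apply_gene_conversion(
                cds_by_id,
                tree,
                rate=rate,
                tract_len_dist=(
                    float(conv.get("tract_mean", 30)),
                    int(conv.get("tract_min", 10)),
                    int(conv.get("tract_max", 80)),
                ),
                allowed_domains=frozenset(conv.get("domains", ["EC4", "EC5", "EC6"])),
                partition=partition,
                seed=_derive_seed(seed, 100 + k),
            )
            events = tuple(ev)
        ce_seq = make_constant_exon_seq(
            cd_len_aa=locus_cfg.get("cd_len_aa", 125), seed=_derive_seed(seed, 200 + k)
        )
        clusters.append(
            ClusterInput(
                name=ccfg["name"],
                cds_by_id=cds_by_id,
                constant_exon_seq=ce_seq,
                partition=partition,
                events=events,
            )
        )
        trees[ccfg["name"]] = tree
    locus = assemble_locus(
        clusters,
        intergenic_len=int(locus_cfg.get("intergenic_len", 2500)),
        promoter_pwm=pwm,
        motif_offset=int(locus_cfg.get("motif_offset", -200)),
        n_decoys=int(locus_cfg.get("decoys", {}).get("n", 5)),
        decoy_len_aa=int(locus_cfg.get("decoys", {}).get("len_aa", 350)),
        ce_intron_len=int(locus_cfg.get("ce_intron_len", 200)),
        seed=_derive_seed(seed, 300),
    )
    return SimulatedLocus(
        locus=locus,
        trees=trees,
        repeat_templates=ec_templates,
        planted_pwm=pwm,
        partition=partition,
        ancestral_cds=ancestral_cds,
        cds_pre_conversion=pre,
    )


def variable_protein_msa(locus: LocusModel, cluster_id: str | None = None) -> dict[str, str]:
    """Variable-exon protein 'alignment' (substitution-only evolution keeps
    paralogs colinear, so the identity map is the alignment)."""
    genes = locus.gene_models if cluster_id is None else locus.genes_of(cluster_id)
    return {gm.id: gm.variable_protein for gm in genes}


def cluster_codon_alignment(locus: LocusModel, cluster_id: str) -> ds_geneconv.CodonAlignment:
    msa = variable_protein_msa(locus, cluster_id)
    cds = {
        gm.id: gm.cds_sequence[: gm.variable_exon[1] - gm.variable_exon[0]]
        for gm in locus.genes_of(cluster_id)
    }
    return ds_geneconv.backtranslate_alignment(msa, cds)


def region_protein_msa(
    locus: LocusModel, labels: tuple[str, ...] = ("EC2", "EC3")
) -> dict[str, str]:
    out = {}
    for gm in locus.gene_models:
        s, e = gm.partition.region_range(labels)
        out[gm.id] = gm.protein_sequence[s:e]
    return out


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: dict, outdir: str | Path, seed: int, stages: tuple[str, ...] = STAGES
) -> dict:
    """Run the stages in dependency order; returns the manifest dict.

    Any stage after `simulate` may be skipped. Failures halt the run with
    the failing stage named.
    """
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config, sort_keys=True)
    manifest: dict = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "pcdhkit_version": __version__,
        "method_notes": {
            "phylogeny": "neighbor joining on Poisson-corrected distances (no ML)",
            "ds": "NG86 pathway counting with Jukes-Cantor correction",
        },
        "stages": {},
        "warnings": [],
    }

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in sorted(files)}
        }

    sim: SimulatedLocus | None = None
    current = "simulate"
    try:
        sim = simulate_locus(config["locus"], seed)
        locus = sim.locus
        files = []
        p = outdir / "genome.fa"
        io.write_fasta(p, {"locus": locus.genome_sequence})
        files.append(p)
        p = outdir / "models.gff3"
        io.write_gff3(p, locus)
        files.append(p)
        p = outdir / "cds.fa"
        io.write_fasta(p, {gm.id: gm.cds_sequence for gm in locus.gene_models})
        files.append(p)
        p = outdir / "proteins.fa"
        io.write_fasta(p, {gm.id: gm.protein_sequence for gm in locus.gene_models})
        files.append(p)
        p = outdir / "events.tsv"
        io.write_events(p, locus.events)
        files.append(p)
        p = outdir / "motif_truth.tsv"
        io.write_motif_truth(p, locus.motif_truth)
        files.append(p)
        profile = annotation.RepeatProfile.from_templates(sim.repeat_templates)
        p = outdir / "repeat_profile.tsv"
        p.write_text(profile.to_tsv())
        files.append(p)
        reads_cfg = config["reads"]
        placements = simulate_reads(
            locus,
            {str(k): float(v) for k, v in reads_cfg["expression"].items()},
            n_fragments=int(reads_cfg.get("n_fragments", 100000)),
            frag_len=int(reads_cfg.get("frag_len", 300)),
            read_len=int(reads_cfg.get("read_len", 100)),
            seed=_derive_seed(seed, 400),
        )
        p = outdir / "placements.bed"
        io.write_placements(p, placements)
        files.append(p)
        record("simulate", files)

        ana = config["analysis"]
        if "annotate" in stages:
            current = "annotate"
            models, ev = annotation.annotate_locus(
                locus.genome_sequence,
                min_aa=int(ana.get("min_aa", 700)),
                repeat_profile=profile,
                min_score=float(ana.get("min_repeat_score", 0.0)),
                truth=locus,
            )
            df = pd.DataFrame(
                [
                    dict(id=m.id, strand=m.strand, start=m.start, end=m.end,
                         protein_len=len(m.protein_sequence))
                    for m in models
                ]
            )
            p1 = outdir / "annotation.tsv"
            df.to_csv(p1, sep="\t", index=False)
            p2 = outdir / "annotation_eval.tsv"
            pd.DataFrame(
                [dict(n_truth=ev.n_truth, n_predicted=ev.n_predicted,
                      n_true_positive=ev.n_true_positive,
                      precision=ev.precision, recall=ev.recall)]
            ).to_csv(p2, sep="\t", index=False)
            record("annotate", [p1, p2])

        groups = {
            cid: [g.id for g in locus.genes_of(cid)] for cid in locus.cluster_ids()
        }
        if "identity" in stages:
            current = "identity"
            table = identity.domain_identity_table(locus.gene_models, groups)
            p1 = outdir / "identity_table.tsv"
            table.round(2).to_csv(p1, sep="\t")
            report = identity.high_similarity_pairs(
                locus.gene_models,
                region=tuple(ana.get("identity_region", ["EC2", "EC3"])),
                threshold_pct=float(ana.get("identity_threshold", 90.0)),
            )
            p2 = outdir / "similar_pairs.tsv"
            pd.DataFrame(report.pairs, columns=["idA", "idB", "identity"]).to_csv(
                p2, sep="\t", index=False
            )
            record("identity", [p1, p2])

        if "dsconv" in stages:
            current = "dsconv"
            summaries = []
            for cid in locus.cluster_ids():
                aln = cluster_codon_alignment(locus, cid)
                summaries.extend(
                    ds_geneconv.group_domain_ds(
                        aln, sim.partition, {cid: aln.isoform_ids}
                    )
                )
            p1 = outdir / "ds_summary.tsv"
            ds_geneconv.summaries_to_frame(summaries).to_csv(p1, sep="\t")
            record("dsconv", [p1])

        if "tree" in stages:
            current = "tree"
            msa = region_protein_msa(locus, ("EC2", "EC3"))
            tree, support = phylogeny.bootstrap_support(
                msa, n_reps=int(ana.get("bootstrap_reps", 100)),
                seed=_derive_seed(seed, 500),
            )
            phylogeny.annotate_supports(tree, support)
            p1 = outdir / "tree.nwk"
            p1.write_text(str(tree))
            p2 = outdir / "splits.tsv"
            pd.DataFrame(
                sorted(
                    (";".join(sorted(s)), pct) for s, pct in support.items()
                ),
                columns=["split", "support_pct"],
            ).to_csv(p2, sep="\t", index=False)
            record("tree", [p1, p2])

        if "motifs" in stages:
            current = "motifs"
            promoters = motifs.extract_promoters(
                locus.genome_sequence, locus.gene_models,
                upstream_bp=int(ana.get("promoter_bp", 2000)),
            )
            model, _ = motifs.discover_motif_em(
                [promoters[g] for g in sorted(promoters)],
                width=int(ana.get("motif_width", 13)),
                n_restarts=int(ana.get("motif_restarts", 10)),
                seed=_derive_seed(seed, 600),
            )
            p1 = outdir / "motif.meme"
            p1.write_text(model.to_meme("discovered"))
            hits, summary = motifs.scan_pwm(promoters, model)
            p2 = outdir / "motif_hits.tsv"
            pd.DataFrame(
                [dict(gene_id=h.gene_id, offset=h.offset, strand=h.strand,
                      score=round(h.score, 4)) for h in hits]
            ).to_csv(p2, sep="\t", index=False)
            p3 = outdir / "motif_summary.tsv"
            pd.DataFrame(
                [dict(n_promoters=summary.n_promoters, n_with_hit=summary.n_with_hit,
                      fraction_with_hit=summary.fraction_with_hit,
                      mean_best_offset=summary.mean_best_offset,
                      sd_best_offset=summary.sd_best_offset,
                      cgct_in_consensus=motifs.has_cgct_box(model))]
            ).to_csv(p3, sep="\t", index=False)
            record("motifs", [p1, p2, p3])

        if "express" in stages:
            current = "express"
            placed = io.read_placements(outdir / "placements.bed")
            table = expression.quantify_clusters(placed, locus.gene_models)
            p1 = outdir / "expression.tsv"
            table.to_csv(p1, sep="\t", index=False)
            record("express", [p1])
    except Exception as exc:  # noqa: BLE001 - reported with the failing stage
        raise PipelineError(current, exc) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
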