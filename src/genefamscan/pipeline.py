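"""End-to-end orchestration: simulate -> identify -> props -> cis ->
structure -> tree -> classify -> dnds -> expr.

Each stage consumes the declared outputs of earlier stages, logs record
counts, and appends to a run manifest that suffices to re-run the
pipeline identically.  One global seed is fanned out as per-stage
derived seeds (seed + stage index) so stages are independently
reproducible.  All thresholds live in the PipelineConfig.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from genefamscan import __version__
from genefamscan.align_phylo import bootstrap_support, center_star_msa
from genefamscan.classify_groups import assign_groups_tree, cterm_typing, reconcile
from genefamscan.dup_dnds import (
    DuplicationCriteria,
    find_duplicate_pairs,
    pair_dnds,
    selection_summary,
)
from genefamscan.expression import delta_delta_ct, scale_matrix
from genefamscan.family_id import assign_names, filter_candidates
from genefamscan.gene_structure import architecture
from genefamscan.io_formats import (
    PipelineConfig,
    get_logger,
    read_fasta,
    read_gff3,
    write_newick,
)
from genefamscan.promoter_cis import element_matrix, extract_promoter
from genefamscan.protein_props import protein_properties
from genefamscan.synthetic_data import (
    GeneratorProfile,
    SequenceRecord,
    generate_expression_profiles,
    generate_family_genome,
)

logger = get_logger(__name__)

STAGES = [
    "simulate", "identify", "props", "cis", "structure",
    "tree", "classify", "dnds", "expr",
]


@dataclass
class RunManifest:
    seed: int
    config: dict
    tool_version: str = __version__
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, str], counts: dict[str, int]) -> None:
        self.stages[stage] = {"outputs": outputs, "counts": counts}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "tool_version": self.tool_version,
                    "config": self.config,
                    "stages": self.stages,
                },
                fh, indent=1, sort_keys=True,
            )


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    profile: GeneratorProfile | None = None,
    stages: list[str] | None = None,
) -> RunManifest:
    """Run the requested stages (default: all) into ``out_dir``."""
    config.validate()
    stages = STAGES if stages is None else stages
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed
    manifest = RunManifest(seed=seed, config=asdict(config) if hasattr(config, "__dataclass_fields__") else dict(config.__dict__))

    sim_dir = out / "simulated"

    if "simulate" in stages:
        prof = profile or GeneratorProfile(rng_seed=seed)
        prof.rng_seed = seed
        generated = generate_family_genome(prof)
        paths = generated.write(sim_dir)
        fpkm, ct, _folds = generate_expression_profiles(
            generated.truth, seed=seed + 1
        )
        fpkm_path = sim_dir / "fpkm.tsv"
        ct_path = sim_dir / "ct.tsv"
        fpkm.to_csv(fpkm_path, sep="\t")
        ct.to_csv(ct_path, sep="\t", index=False)
        paths["fpkm"] = str(fpkm_path)
        paths["ct"] = str(ct_path)
        manifest.record(
            "simulate", paths,
            {
                "members": len(generated.truth.members),
                "decoys": len(generated.truth.kinase_decoys)
                + len(generated.truth.nonkinase_decoys),
                "chromosomes": len(generated.genome),
            },
        )

    def require(path: Path, stage: str) -> Path:
        if not path.exists():
            raise StageError(stage, f"missing input {path}")
        return path

    members_tsv = out / "members.tsv"

    if "identify" in stages:
        proteins = read_fasta(require(sim_dir / "proteins.faa", "identify"))
        models = {
            m.gene_id: m
            for m in read_gff3(require(sim_dir / "genes.gff3", "identify"))
        }
        accepted, rejections = filter_candidates(
            proteins, config.signatures, config.signature_max_mismatch
        )
        named = assign_names(accepted, models, config.name_prefix)
        rows = [
            {
                "gene_id": m.gene_id,
                "name": m.assigned_name,
                "chromosome": m.chromosome,
                "start": m.start,
                "n_hits": len(m.hits),
                "protein_length": m.protein_length,
            }
            for m in named
        ]
        pd.DataFrame(rows).to_csv(members_tsv, sep="\t", index=False)
        with open(out / "rejections.tsv", "w") as fh:
            fh.write("gene_id\treason\n")
            for gid, reason in rejections:
                fh.write(f"{gid}\t{reason}\n")
        manifest.record(
            "identify",
            {"members": str(members_tsv), "rejections": str(out / "rejections.tsv")},
            {"accepted": len(named), "rejected": len(rejections)},
        )

    def member_frame(stage: str) -> pd.DataFrame:
        return pd.read_csv(require(members_tsv, stage), sep="\t")

    if "props" in stages:
        members = member_frame("props")
        cds = {r.id: r.residues for r in read_fasta(require(sim_dir / "cds.fna", "props"))}
        models = {m.gene_id: m for m in read_gff3(sim_dir / "genes.gff3")}
        rows = []
        for _, m in members.iterrows():
            p = protein_properties(m.gene_id, cds[m.gene_id], config.pka_set)
            model = models[m.gene_id]
            rows.append(
                {
                    "name": m["name"],
                    "chromosome": model.chromosome,
                    "start": model.start,
                    "end": model.end,
                    "gene_length": model.paper_gene_length,
                    "gene_id": p.gene_id,
                    "n_residues": p.n_residues,
                    "mol_mass": round(p.mol_mass, 1),
                    "pI": round(p.pI, 2),
                    "cds_length": p.cds_length,
                    "gravy": round(p.gravy, 3),
                    "hydropathy_class": p.hydropathy_class,
                }
            )
        pd.DataFrame(rows).to_csv(out / "props.tsv", sep="\t", index=False)
        manifest.record("props", {"props": str(out / "props.tsv")}, {"proteins": len(rows)})

    if "cis" in stages:
        members = member_frame("cis")
        genome = {
            r.id: r.residues for r in read_fasta(require(sim_dir / "genome.fna", "cis"))
        }
        models = {m.gene_id: m for m in read_gff3(sim_dir / "genes.gff3")}
        promoters = [
            SequenceRecord(
                gid,
                extract_promoter(models[gid], genome, config.promoter_length),
            )
            for gid in members.gene_id
        ]
        matrix = element_matrix(promoters, config.cis_elements, config.scan_both_strands)
        matrix.counts.to_csv(out / "cis.tsv", sep="\t")
        matrix.presence.to_frame("n_genes_with_element").to_csv(
            out / "cis_presence.tsv", sep="\t"
        )
        manifest.record(
            "cis",
            {"cis": str(out / "cis.tsv"), "presence": str(out / "cis_presence.tsv")},
            {"promoters": len(promoters)},
        )

    if "structure" in stages:
        members = member_frame("structure")
        models = {m.gene_id: m for m in read_gff3(require(sim_dir / "genes.gff3", "structure"))}
        rows = []
        for gid in members.gene_id:
            a = architecture(models[gid])
            rows.append(
                {
                    "gene_id": gid,
                    "n_exons": a.n_exons,
                    "n_introns": a.n_introns,
                    "exon_lengths": ",".join(map(str, a.exon_lengths)),
                    "intron_lengths": ",".join(map(str, a.intron_lengths)),
                    "intron_phases": ",".join(map(str, a.intron_phases)),
                    "gene_length": a.paper_gene_length,
                }
            )
        pd.DataFrame(rows).to_csv(out / "structure.tsv", sep="\t", index=False)
        manifest.record(
            "structure", {"structure": str(out / "structure.tsv")}, {"genes": len(rows)}
        )

    tree_path = out / "tree.nwk"
    msa_cache: dict[str, list] = {}

    def build_tree(stage: str):
        members = member_frame(stage)
        proteins = {r.id: r for r in read_fasta(require(sim_dir / "proteins.faa", stage))}
        refs = read_fasta(require(sim_dir / "references.faa", stage))
        seqs = [proteins[g] for g in members.gene_id] + refs
        msa = center_star_msa(seqs, gap_open=config.gap_open, gap_extend=config.gap_extend)
        msa_cache["msa"] = msa
        return bootstrap_support(
            msa,
            replicates=max(config.bootstrap_replicates, 1),
            seed=seed + STAGES.index("tree"),
            model=config.distance_model,
        )

    tree_obj = None
    if "tree" in stages:
        tree_obj = build_tree("tree")
        write_newick(tree_obj, tree_path)
        manifest.record(
            "tree", {"tree": str(tree_path)},
            {"leaves": len(tree_obj.leaf_names()),
             "bootstrap_replicates": config.bootstrap_replicates},
        )

    if "classify" in stages:
        if tree_obj is None:
            tree_obj = build_tree("classify")
        members = member_frame("classify")
        proteins = {r.id: r for r in read_fasta(sim_dir / "proteins.faa")}
        ref_labels = {}
        for r in read_fasta(require(sim_dir / "references.faa", "classify")):
            # reference ids carry their group: REF_<group>_<n>
            ref_labels[r.id] = r.id.split("_")[1]
        tree_groups = assign_groups_tree(tree_obj, ref_labels)
        typings = {
            gid: cterm_typing(gid, proteins[gid].residues)
            for gid in members.gene_id
        }
        final, conflicts, matrix = reconcile(
            {g: a for g, a in tree_groups.items() if g in typings}, typings
        )
        rows = [
            {
                "gene_id": gid,
                "group": a.group,
                "method": a.method,
                "patch_type": typings[gid].patch_type,
                "aba_box": typings[gid].aba_box_present,
                "snrk2_box": typings[gid].snrk2_box_present,
            }
            for gid, a in sorted(final.items())
        ]
        pd.DataFrame(rows).to_csv(out / "groups.tsv", sep="\t", index=False)
        with open(out / "classify_conflicts.txt", "w") as fh:
            fh.write("\n".join(conflicts) + ("\n" if conflicts else ""))
        manifest.record(
            "classify",
            {"groups": str(out / "groups.tsv")},
            {"assigned": len(rows), "conflicts": len(conflicts)},
        )

    if "dnds" in stages:
        members = member_frame("dnds")
        proteins = {r.id: r for r in read_fasta(require(sim_dir / "proteins.faa", "dnds"))}
        cds = {r.id: r.residues for r in read_fasta(require(sim_dir / "cds.fna", "dnds"))}
        models = {m.gene_id: m for m in read_gff3(sim_dir / "genes.gff3")}
        criteria = DuplicationCriteria(config.coverage_min, config.identity_min)
        pairs = find_duplicate_pairs(
            list(members.gene_id), proteins, models, criteria,
            config.gap_open, config.gap_extend,
        )
        rows = []
        for p in pairs:
            try:
                pair_dnds(p, proteins, cds, config.gap_open, config.gap_extend)
            except ValueError as exc:
                # synonymous sites saturated (p >= 3/4): distances undefined
                logger.warning(
                    "dnds: %s/%s skipped: %s", p.gene_id_a, p.gene_id_b, exc
                )
            row = {
                "gene_a": p.gene_id_a,
                "gene_b": p.gene_id_b,
                "identity_pct": round(100 * p.identity, 2),
                "coverage": round(p.coverage, 4),
                "dS": "NA", "dN": "NA", "dN_dS": "NA",
                "duplicate": p.duplication_class,
                "purifying": "NA",
            }
            if p.ng is not None:
                row.update(
                    dS=round(p.ng.dS, 4),
                    dN=round(p.ng.dN, 4),
                    dN_dS=round(p.ng.omega, 4) if p.ng.omega is not None else "NA",
                    purifying=(
                        "Yes" if p.ng.purifying else "No"
                    ) if p.ng.purifying is not None else "NA",
                )
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "pairs.tsv", sep="\t", index=False)
        summary = selection_summary(pairs)
        with open(out / "selection_summary.json", "w") as fh:
            json.dump(
                {k: v for k, v in summary.items() if k != "pairs"}, fh, indent=1
            )
        manifest.record(
            "dnds",
            {"pairs": str(out / "pairs.tsv"),
             "summary": str(out / "selection_summary.json")},
            {"pairs": len(pairs), "purifying": summary["n_purifying"]},
        )

    if "expr" in stages:
        fpkm = pd.read_csv(require(sim_dir / "fpkm.tsv", "expr"), sep="\t", index_col=0)
        scaled, responsive = scale_matrix(fpkm, mode="zscore")
        scaled.round(4).to_csv(out / "expr_scaled.tsv", sep="\t")
        responsive.to_frame("responsive").to_csv(out / "expr_calls.tsv", sep="\t")
        ct = pd.read_csv(require(sim_dir / "ct.tsv", "expr"), sep="\t")
        rel = delta_delta_ct(ct, reference_gene="histone3")
        rel.folds.round(4).to_csv(out / "folds.tsv", sep="\t", index=False)
        manifest.record(
            "expr",
            {"scaled": str(out / "expr_scaled.tsv"),
             "calls": str(out / "expr_calls.tsv"),
             "folds": str(out / "folds.tsv")},
            {"genes": fpkm.shape[0], "responsive": int(responsive.sum())},
        )

    manifest.write(out / "manifest.json")
    logger.info("pipeline complete: %d stages", len(manifest.stages))
    return manifest
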