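"""Orchestrate the full family study as one reproducible run.

Stages run in dependency order (identify -> classify -> align/tree ->
duplications/KaKs/windows -> promoters -> expression) and emit nine TSV/
Newick outputs plus a manifest recording the config hash, seed, library
versions and per-stage row counts. Reruns with an identical config are
byte-identical apart from the manifest timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import famscan
from famscan import expression as fexpr
from famscan import identify as fid
from famscan import phylo as fphylo
from famscan import promoter as fprom
from famscan import selection as fsel
from famscan.io import (
    parse_fasta,
    parse_gff3,
    read_tsv,
    serialize_newick,
    write_tsv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "simulate_study"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class RunConfig:
    genome: str
    gff: str
    proteins: str
    cds: str
    outdir: str
    ct_table: str | None = None
    motifs: str | None = None
    domain: str | None = None
    reference_gene: str | None = None
    calibrator_sample: str | None = None
    e_threshold: float = 0.001
    promoter_length: int = 1500
    window_nt: int = 150
    step_nt: int = 9
    identity_threshold_pct: float = 80.0
    tandem_max_separation_bp: int = 200_000
    distance_model: str = "p_distance"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        for name in ("genome", "gff", "proteins", "cds", "ct_table",
                     "motifs", "domain"):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                raise PipelineError(f"config: {name} file {val!r} does not exist")
        if self.ct_table is not None and (
                self.reference_gene is None or self.calibrator_sample is None):
            raise PipelineError(
                "config: ct_table requires reference_gene and calibrator_sample"
            )
        if not 1500 <= self.promoter_length <= 2000:
            raise PipelineError("config: promoter_length outside [1500, 2000]")

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (the output
        location is excluded: reruns into a different directory are the
        same analysis)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:          # noqa: BLE001 - re-raised with stage
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrap

    # ---------------- load -------------------------------------------
    def _load():
        genome = {r.id: r for r in parse_fasta(cfg.genome, "dna")}
        genes = parse_gff3(cfg.gff)
        proteins = parse_fasta(cfg.proteins, "protein")
        cds = {r.id: r for r in parse_fasta(cfg.cds, "dna")}
        motifs = (fprom.load_motif_table(cfg.motifs) if cfg.motifs
                  else fprom.default_motif_table())
        domain = (parse_fasta(cfg.domain, "protein")[0] if cfg.domain
                  else fid.default_domain_reference())
        return genome, genes, proteins, cds, motifs, domain

    genome, genes, proteins, cds, motifs, domain = stage("load")(_load)
    models = {g.gene_id: g for g in genes}

    # ---------------- identify ---------------------------------------
    def _identify():
        scan_cfg = fid.ScanConfig(
            domain_reference=domain, e_threshold=cfg.e_threshold
        )
        hits = fid.scan_for_domain(proteins, scan_cfg)
        class1, class2 = fid.default_class_references()
        prot_by_id = {p.id: p for p in proteins}
        rows = []
        calls = []
        for h in hits:
            prot = prot_by_id[h.protein_id]
            call = fid.classify_subfamily(h, prot, class1, class2)
            prof = fid.physicochemical_profile(prot)
            calls.append(call)
            rows.append({
                "protein_id": h.protein_id, "score": h.raw_score,
                "e_value": h.e_value, "hit_start": h.hit_start,
                "hit_end": h.hit_end, "class": call.class_label,
                "MW_kDa": round(prof.molecular_weight_kda, 3),
                "pI": round(prof.isoelectric_point, 2),
                "GRAVY": round(prof.gravy, 3),
            })
        write_tsv(pd.DataFrame(rows), outdir / "members.tsv")
        write_tsv(pd.DataFrame([{
            "protein_id": c.protein_id, "class": c.class_label,
            "basic_region_gap": c.basic_region_gap,
            "r_domain_found": c.r_domain_found,
            "r_start": c.r_domain_interval[0] if c.r_domain_interval else "NA",
            "r_end": c.r_domain_interval[1] if c.r_domain_interval else "NA",
        } for c in calls]), outdir / "classes.tsv")
        return hits

    hits = stage("identify")(_identify)
    counts["members"] = len(hits)
    member_ids = [h.protein_id for h in hits]
    prot_by_id = {p.id: p for p in proteins}

    # ---------------- phylogeny --------------------------------------
    def _phylo():
        if len(member_ids) < 2:
            raise ValueError("fewer than 2 family members; no tree")
        member_prots = [prot_by_id[m] for m in sorted(member_ids)]
        aln = fphylo.progressive_msa(member_prots)
        dm = fphylo.protein_distance_matrix(aln, cfg.distance_model)
        tree = fphylo.build_nj_tree(dm)
        (outdir / "tree.nwk").write_text(serialize_newick(tree) + "\n")
        return tree

    tree = stage("phylogeny")(_phylo)
    counts["tree_leaves"] = len(tree.leaf_names())

    # ---------------- duplications / KaKs ----------------------------
    def _selection():
        events = fsel.classify_duplications(
            models, prot_by_id, cds, tree,
            identity_threshold_pct=cfg.identity_threshold_pct,
            tandem_max_separation_bp=cfg.tandem_max_separation_bp,
        )
        ev_rows, kaks_rows, win_rows = [], [], []
        wcfg = fsel.WindowConfig(cfg.window_nt, cfg.step_nt)
        for ev in events:
            ev_rows.append({
                "gene_a": ev.gene_a, "gene_b": ev.gene_b,
                "identity_pct": round(ev.identity_pct, 2),
                "relation": ev.chromosomal_relation,
                "separation_bp": _fmt(ev.separation_bp),
                "dup_type": ev.dup_type,
            })
            k = ev.kaks
            kaks_rows.append({
                "gene_a": ev.gene_a, "gene_b": ev.gene_b,
                "S": round(k.s_sites, 4), "N": round(k.n_sites, 4),
                "Sd": round(k.sd, 4), "Nd": round(k.nd, 4),
                "Ka": _fmt(k.ka), "Ks": _fmt(k.ks),
                "ratio": _fmt(k.ratio), "call": k.selection_call,
                "dup_type": ev.dup_type,
            })
            _, row_a, row_b = fsel.align_global(
                prot_by_id[ev.gene_a].residues, prot_by_id[ev.gene_b].residues
            )
            caln = fsel.map_protein_alignment_to_codons(
                row_a, row_b, cds[ev.gene_a], cds[ev.gene_b]
            )
            if caln.n_columns >= cfg.window_nt:
                for start, end, res in fsel.sliding_window_kaks(caln, wcfg):
                    win_rows.append({
                        "gene_a": ev.gene_a, "gene_b": ev.gene_b,
                        "start_nt": start, "end_nt": end,
                        "Ka": _fmt(res.ka), "Ks": _fmt(res.ks),
                        "ratio": _fmt(res.ratio),
                    })
        write_tsv(pd.DataFrame(ev_rows), outdir / "events.tsv")
        write_tsv(pd.DataFrame(kaks_rows), outdir / "kaks.tsv")
        write_tsv(pd.DataFrame(win_rows), outdir / "windows.tsv")
        return events, win_rows

    events, win_rows = stage("selection")(_selection)
    counts["duplication_events"] = len(events)
    counts["kaks_windows"] = len(win_rows)

    # ---------------- promoters --------------------------------------
    def _promoter():
        member_models = [models[m] for m in sorted(member_ids) if m in models]
        proms = fprom.extract_promoters(genome, member_models,
                                        cfg.promoter_length)
        cis_hits = fprom.scan_cis_elements(proms, motifs, "given_only")
        per_gene, per_cat = fprom.census_by_category(cis_hits, motifs)
        write_tsv(pd.DataFrame([{
            "gene_id": h.gene_id, "element": h.element_name,
            "offset": h.offset, "strand": h.strand_of_match,
        } for h in cis_hits]), outdir / "hits.tsv")
        element_rows = [{
            "element": m.element_name, "category": m.category,
            "total": int(per_gene[m.element_name].sum()) if len(per_gene) else 0,
        } for m in motifs]
        census = pd.DataFrame(element_rows)
        write_tsv(census, outdir / "census.tsv")
        write_tsv(per_cat, outdir / "census_categories.tsv")
        per_gene.reset_index().to_csv(
            outdir / "census_by_gene.tsv", sep="\t", index=False
        )
        return cis_hits

    cis_hits = stage("promoter")(_promoter)
    counts["cis_element_hits"] = len(cis_hits)

    # ---------------- expression -------------------------------------
    def _expression():
        if cfg.ct_table is None:
            write_tsv(pd.DataFrame(
                columns=["sample", "gene", "fold", "delta_ct_mean",
                         "delta_ct_sd", "fold_low", "fold_high"]
            ), outdir / "folds.tsv")
            return []
        df = read_tsv(cfg.ct_table)
        tbl = fexpr.CtTable(df, cfg.reference_gene, cfg.calibrator_sample)
        rel = fexpr.relative_expression_ddct(tbl)
        write_tsv(pd.DataFrame([{
            "sample": r.sample_id, "gene": r.gene_id,
            "fold": round(r.fold, 6),
            "delta_ct_mean": round(r.delta_ct_mean, 4),
            "delta_ct_sd": round(r.delta_ct_sd, 4),
            "fold_low": round(r.fold_range[0], 6),
            "fold_high": round(r.fold_range[1], 6),
        } for r in rel]), outdir / "folds.tsv")
        return rel

    rel = stage("expression")(_expression)
    counts["expression_records"] = len(rel)

    manifest = {
        "config_sha256": cfg.digest(),
        "seed": cfg.seed,
        "versions": {
            "famscan": famscan.__version__,
            "numpy": __import__("numpy").__version__,
            "biopython": __import__("Bio").__version__,
        },
        "counts": counts,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    for name, n in counts.items():
        logger.info("pipeline: %s = %d", name, n)
    return manifest


# ---------------------------------------------------------------------------
# one-stop synthetic study
# ---------------------------------------------------------------------------

def simulate_study(outdir: str | Path, seed: int,
                   spec=None, n_chromosomes: int = 5) -> dict[str, Path]:
    """Generate a complete synthetic study fixture plus a ready run.yaml.

    Plants a hormone-element census shaped like a mid-size family study
    (75 ABRE occurrences across the member promoters, plus light-response
    and GA elements) and a 4-tissue Ct table with known fold changes.
    """
    from famscan import synthgen

    rng_master = int(seed) % (2 ** 31)
    spec = spec or synthgen.FamilySpec(
        n_pcf=5, n_cin=4, n_cyc=3, n_background=10,
        tandem_separations_bp=(50_000,), n_segmental_pairs=1,
        low_identity_fractions=(0.70,),
    )
    fam = synthgen.generate_family_genome(n_chromosomes, spec, rng_master)
    import numpy as np
    rng = np.random.default_rng(rng_master + 1)
    motifs = fprom.default_motif_table()
    member_ids = sorted(fam.truth.members)
    plan = synthgen.random_promoter_plan(
        member_ids, {"ABRE": 75, "G-box": 20, "GARE-motif": 10},
        motifs, rng,
    )
    genome, planted = synthgen.plant_promoter_elements(
        fam.genome, fam.genes, motifs, plan, rng_master + 2
    )
    fam.genome = genome
    fam.truth.promoter_plants = planted

    outdir = Path(outdir)
    paths = fam.write(outdir)
    design = {
        "fruit": {member_ids[0]: 1.0, member_ids[1]: 1.0},
        "flower": {member_ids[0]: 4.0, member_ids[1]: 1.0},
        "leaf": {member_ids[0]: 0.5, member_ids[1]: 1.0},
        "stem": {member_ids[0]: 1.0, member_ids[1]: 2.0},
    }
    tbl, fold_truth = synthgen.generate_ct_table(
        design, "TUBULIN", "fruit", noise_sd=0.15, replicates=3,
        seed=rng_master + 3,
    )
    fam.truth.fold_changes = fold_truth
    ct_path = outdir / "ct.tsv"
    write_tsv(tbl.data, ct_path)
    paths["ct"] = ct_path

    cfg = RunConfig(
        genome=str(paths["genome"]), gff=str(paths["gff"]),
        proteins=str(paths["proteins"]), cds=str(paths["cds"]),
        ct_table=str(ct_path), reference_gene="TUBULIN",
        calibrator_sample="fruit", outdir=str(outdir / "results"),
        seed=rng_master,
    )
    run_yaml = outdir / "run.yaml"
    run_yaml.write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
    paths["run_yaml"] = run_yaml
    return paths
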