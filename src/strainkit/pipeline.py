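"""End-to-end orchestration: one config in, the study's result tables out.

``run`` executes the stages sequentially over a strain set (synthetic or
loaded from files) and writes TSV/Newick outputs: a per-strain summary
(size, gene count, G+C, CRISPR count, specific genes), the CRISPR detail
table, composition matrices with CV vector and dendrogram merge tables,
the pairwise ANI matrix with the per-category long table and region
labels, the 16S identity/distance matrices with an NJ tree, and the HGT
summaries.  A manifest records every effective parameter, so a rerun with
the same config and seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ani import (AniParams, classify_category_regions, compute_ani, compute_category_ani,
                  distance_matrix_from_identity, identity_16s, nj_tree)
from .composition import (amino_acid_composition, cluster_strains, codon_usage, gc_content,
                          variable_coefficient)
from .crispr import CrisprParams, detect_crispr_arrays, write_crispr_table
from .homology import SearchParams, call_orthologs, classify_hgt, search, summarize_hgt
from .io_formats import (GeneRecord, GenomeRecord, StrainkitError, load_genome,
                         read_category_map, read_fasta, read_gene_table, read_taxonomy,
                         write_matrix)
from .synthetic import HitDatabase, SimulationConfig, simulate, write_simulation

__all__ = ["PipelineConfig", "run"]

logger = logging.getLogger("strainkit")

ALL_STAGES = ("composition", "ani", "trees", "homology", "hgt", "crispr")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    In ``synthetic`` mode the strain set is generated from ``sim`` (whose
    seed is taken from ``seed``); in ``real`` mode assemblies, the gene
    table and the optional hit database are loaded from the given paths.
    """

    mode: str = "synthetic"                      # "synthetic" | "real"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    genome_paths: list[str] = field(default_factory=list)
    gene_table: str | None = None
    category_map: str | None = None
    hit_db_fasta: str | None = None
    hit_db_taxonomy: str | None = None
    focal_order: str = "Sphingobacteriales"
    outdir: str = "strainkit_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    ani_params: AniParams = field(default_factory=AniParams)
    protein_search: SearchParams = field(default_factory=lambda: SearchParams(alphabet="aa"))
    crispr_params: CrisprParams = field(default_factory=CrisprParams)
    e_cutoff: float = 1e-5
    theta_up: float = 0.9
    threshold_16s: float = 94.5
    write_simulation_inputs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise StrainkitError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                setattr(cfg, key, dataclasses.replace(current, **value))
            else:
                setattr(cfg, key, value)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    def validate(self) -> None:
        if self.mode not in {"synthetic", "real"}:
            raise StrainkitError(f"mode must be 'synthetic' or 'real', got {self.mode!r}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise StrainkitError(f"unknown stages {sorted(unknown)}")
        if self.mode == "real":
            needed = [*self.genome_paths, self.gene_table]
            if self.gene_table is None or not self.genome_paths:
                raise StrainkitError("real mode requires genome_paths and gene_table")
            for p in needed:
                if p and not Path(p).exists():
                    raise StrainkitError(f"input path {p!r} does not exist")

    def manifest(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["stages"] = list(self.stages)
        doc["package_version"] = __version__
        return doc


def _stage(config: PipelineConfig, name: str) -> bool:
    return name in config.stages


def run(config: PipelineConfig) -> dict[str, Path]:
    """Run the configured stages; returns a name -> path map of outputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    counts: dict[str, int] = {}

    # ------------------------------------------------------------------ inputs
    truth = None
    hit_db: HitDatabase | None = None
    if config.mode == "synthetic":
        sim = dataclasses.replace(config.sim, seed=config.seed)
        result = simulate(sim)
        genomes, genes = result.genomes, result.genes
        category_map, hit_db, truth = result.category_map, result.hit_db, result.truth
        if config.write_simulation_inputs:
            paths.update(write_simulation(result, outdir / "inputs"))
    else:
        genomes = [load_genome(p) for p in config.genome_paths]
        genes = read_gene_table(config.gene_table, genomes)
        category_map = (read_category_map(config.category_map)
                        if config.category_map else
                        {g.gene_id: g.category for g in genes if g.feature_type == "cds"})
        if config.hit_db_fasta and config.hit_db_taxonomy:
            hit_db = HitDatabase(entries=read_fasta(config.hit_db_fasta, alphabet="aa"),
                                 taxonomy=read_taxonomy(config.hit_db_taxonomy))
    logger.info("loaded %d genomes, %d genes", len(genomes), len(genes))
    genome_ids = [g.genome_id for g in genomes]
    cds_genes = [g for g in genes if g.feature_type == "cds"]
    by_genome: dict[str, list[GeneRecord]] = {gid: [] for gid in genome_ids}
    for g in cds_genes:
        by_genome[g.genome_id].append(g)

    # -------------------------------------------------------------- composition
    if _stage(config, "composition"):
        proteomes = {gid: [g.protein for g in gs if g.protein]
                     for gid, gs in by_genome.items()}
        cds_sets = {gid: [g.cds for g in gs] for gid, gs in by_genome.items()}
        aa = amino_acid_composition(proteomes)
        cu = codon_usage(cds_sets)
        for name, df in [("aa_composition", aa), ("codon_usage", cu)]:
            paths[name] = outdir / f"{name}.tsv"
            write_matrix(paths[name], list(df.index), list(df.columns), df.to_numpy())
        for name, df in [("aa", aa), ("codon", cu)]:
            cv = variable_coefficient(df)
            paths[f"cv_{name}"] = outdir / f"cv_{name}.tsv"
            cv.to_frame().to_csv(paths[f"cv_{name}"], sep="\t", float_format="%.4f")
            merge = cluster_strains(df)
            paths[f"dendrogram_{name}"] = outdir / f"dendrogram_{name}.tsv"
            merge.to_csv(paths[f"dendrogram_{name}"], sep="\t", index=False,
                         float_format="%.6f")
        counts["composition_strains"] = len(aa)
        logger.info("composition: %d strains", len(aa))

    # ----------------------------------------------------------- 16S identities
    seqs_16s = {g.genome_id: g.cds for g in genes if g.feature_type == "rRNA_16S"}
    id16s: dict[tuple[str, str], float] = {}
    if len(seqs_16s) == len(genomes) and len(genomes) >= 2:
        for a, b in itertools.combinations(genome_ids, 2):
            id16s[(a, b)] = identity_16s(seqs_16s[a], seqs_16s[b])

    # ------------------------------------------------------------------- ANI
    if _stage(config, "ani"):
        ani_values: dict[tuple[str, str], float] = {}
        long_rows = []
        profiles = []
        for a, b in itertools.combinations(range(len(genomes)), 2):
            ga, gb = genomes[a], genomes[b]
            res = compute_ani(ga, gb, config.ani_params)
            ani_values[(ga.genome_id, gb.genome_id)] = res.ani
            profile = compute_category_ani(by_genome[ga.genome_id], by_genome[gb.genome_id],
                                           category_map, config.ani_params,
                                           genome_ani=res.ani)
            profiles.append(profile)
            pair16 = id16s.get((ga.genome_id, gb.genome_id))
            for cat, (cat_ani, n_hits) in sorted(profile.categories.items()):
                long_rows.append((ga.genome_id, gb.genome_id, cat, cat_ani, n_hits,
                                  res.ani, res.one_way[0].ani, res.one_way[1].ani,
                                  pair16 if pair16 is not None else float("nan")))
        n = len(genome_ids)
        matrix = [[100.0 if i == j else
                   ani_values.get((genome_ids[i], genome_ids[j]),
                                  ani_values.get((genome_ids[j], genome_ids[i])))
                   for j in range(n)] for i in range(n)]
        paths["ani_matrix"] = outdir / "ani_matrix.tsv"
        write_matrix(paths["ani_matrix"], genome_ids, genome_ids, matrix)
        long_df = pd.DataFrame(long_rows, columns=[
            "genome_a", "genome_b", "category", "category_ani", "n_gene_hits",
            "genome_ani", "ani_a_to_b", "ani_b_to_a", "identity_16s"])
        paths["category_ani"] = outdir / "category_ani.tsv"
        long_df.to_csv(paths["category_ani"], sep="\t", index=False, float_format="%.4f")
        if len(profiles) >= 3 and id16s:
            regions = classify_category_regions(profiles, id16s, config.theta_up,
                                                config.threshold_16s)
            paths["category_regions"] = outdir / "category_regions.tsv"
            regions.to_csv(paths["category_regions"], sep="\t", float_format="%.4f")
        counts["ani_pairs"] = len(ani_values)
        logger.info("ani: %d pairs", len(ani_values))

    # ------------------------------------------------------------------ trees
    if _stage(config, "trees") and id16s:
        paths["identity_16s"] = outdir / "identity_16s.tsv"
        n = len(genome_ids)
        mat = [[100.0 if i == j else
                id16s.get((genome_ids[i], genome_ids[j]),
                          id16s.get((genome_ids[j], genome_ids[i])))
                for j in range(n)] for i in range(n)]
        write_matrix(paths["identity_16s"], genome_ids, genome_ids, mat)
        dist = distance_matrix_from_identity(genome_ids, id16s)
        paths["distance_16s"] = outdir / "distance_16s.tsv"
        write_matrix(paths["distance_16s"], genome_ids, genome_ids, dist.values)
        if len(genome_ids) >= 3:
            tree = nj_tree(dist)
            paths["tree_16s"] = outdir / "tree_16s.nwk"
            paths["tree_16s"].write_text(tree.to_newick() + "\n")
        counts["tree_taxa"] = len(genome_ids)

    # --------------------------------------------------------------- homology
    specific_counts: dict[str, int] = {}
    if _stage(config, "homology") and len(genomes) >= 2:
        specific_sets: dict[str, list[set[str]]] = {gid: [] for gid in genome_ids}
        ortho_rows = []
        min_len = config.protein_search.word_size
        for a, b in itertools.combinations(genome_ids, 2):
            # proteins shorter than one seed word cannot be searched; they
            # keep their place in the universe and come out as specific
            prot_a = [(g.gene_id, g.protein) for g in by_genome[a]
                      if len(g.protein) >= min_len]
            prot_b = [(g.gene_id, g.protein) for g in by_genome[b]
                      if len(g.protein) >= min_len]
            if not prot_a or not prot_b:
                continue
            hits_ab = search(prot_a, prot_b, config.protein_search)
            hits_ba = search(prot_b, prot_a, config.protein_search)
            pairs, spec_a, spec_b = call_orthologs(
                hits_ab, hits_ba, e_cutoff=config.e_cutoff,
                genes_a=[g.gene_id for g in by_genome[a] if g.protein],
                genes_b=[g.gene_id for g in by_genome[b] if g.protein])
            specific_sets[a].append(set(spec_a))
            specific_sets[b].append(set(spec_b))
            ortho_rows.append((a, b, len(pairs), len(spec_a), len(spec_b)))
        ortho_df = pd.DataFrame(ortho_rows, columns=[
            "genome_a", "genome_b", "n_orthologs", "n_specific_a_vs_b",
            "n_specific_b_vs_a"])
        paths["ortholog_counts"] = outdir / "ortholog_counts.tsv"
        ortho_df.to_csv(paths["ortholog_counts"], sep="\t", index=False)
        # a gene is specific overall when it has no ortholog in ANY other genome
        for gid in genome_ids:
            sets = specific_sets[gid]
            specific_counts[gid] = len(set.intersection(*sets)) if sets else 0
        counts["ortholog_pairs_total"] = int(ortho_df["n_orthologs"].sum()) if len(ortho_df) else 0
        logger.info("homology: %d genome pairs", len(ortho_rows))

    # -------------------------------------------------------------------- HGT
    if _stage(config, "hgt") and hit_db is not None:
        focal = genomes[0]
        min_len = config.protein_search.word_size
        queries = [(g.gene_id, g.protein) for g in by_genome[focal.genome_id]
                   if len(g.protein) >= min_len]
        db_entries = [(e, s) for e, s in hit_db.entries if len(s) >= min_len]
        hits = search(queries, db_entries, config.protein_search)
        sig = [h for h in hits if h.e_value <= config.e_cutoff]
        by_query: dict[str, list] = {}
        for h in sig:
            by_query.setdefault(h.query_id, []).append(h)
        calls = [classify_hgt(gid, by_query.get(gid, []), hit_db.taxonomy,
                              config.focal_order) for gid, _ in queries]
        orders, cats = summarize_hgt(calls, category_map)
        paths["hgt_orders"] = outdir / "hgt_orders.tsv"
        orders.to_csv(paths["hgt_orders"], sep="\t", index=False)
        paths["hgt_categories"] = outdir / "hgt_categories.tsv"
        cats.to_csv(paths["hgt_categories"], sep="\t", index=False, float_format="%.2f")
        calls_df = pd.DataFrame(
            [(c.gene_id, c.is_hgt, c.donor_order or "", c.n_hits) for c in calls],
            columns=["gene_id", "is_hgt", "donor_order", "n_hits"])
        paths["hgt_calls"] = outdir / "hgt_calls.tsv"
        calls_df.to_csv(paths["hgt_calls"], sep="\t", index=False)
        counts["hgt_genes"] = int(sum(c.is_hgt for c in calls))
        logger.info("hgt: %d of %d genes called", counts["hgt_genes"], len(calls))

    # ------------------------------------------------------------------ CRISPR
    crispr_counts: dict[str, int] = {}
    if _stage(config, "crispr"):
        arrays_by_genome = {}
        for g in genomes:
            arrays = detect_crispr_arrays(g, config.crispr_params)
            arrays_by_genome[g.genome_id] = arrays
            crispr_counts[g.genome_id] = sum(1 for a in arrays
                                             if a.confidence == "confirmed")
        paths["crispr_table"] = outdir / "crispr.tsv"
        write_crispr_table(paths["crispr_table"], arrays_by_genome)
        counts["crispr_arrays"] = sum(len(v) for v in arrays_by_genome.values())
        logger.info("crispr: %d arrays", counts["crispr_arrays"])

    # ----------------------------------------------------------------- summary
    summary_rows = []
    for g in genomes:
        summary_rows.append((
            g.genome_id, g.length, len(by_genome[g.genome_id]),
            round(gc_content(g), 2),
            crispr_counts.get(g.genome_id, 0) if _stage(config, "crispr") else "",
            specific_counts.get(g.genome_id, 0) if _stage(config, "homology") else "",
        ))
    summary = pd.DataFrame(summary_rows, columns=[
        "genome_id", "size_bp", "n_genes", "gc_percent", "confirmed_crisprs",
        "specific_genes"])
    paths["strain_summary"] = outdir / "strain_summary.tsv"
    summary.to_csv(paths["strain_summary"], sep="\t", index=False)

    manifest = config.manifest()
    manifest["record_counts"] = counts
    manifest["outputs"] = {k: str(v) for k, v in sorted(paths.items())}
    paths["manifest"] = outdir / "manifest.yaml"
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths
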