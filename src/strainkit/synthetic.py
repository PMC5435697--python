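"""Synthetic strain-set generator with known, recoverable structure.

A strain set is built from one random ancestor genome: strain 1 *is* the
ancestor, and each further strain is an independent site-wise mutated copy
(substitutions only, no indels, so gene coordinates are identical across
strains).  Sites inside genes of functional category ``c`` flip with the
configured per-category probability to a uniformly chosen different base;
intergenic and uncategorized sites use the backbone rate; annotated 16S
genes use their own rate.  Because divergence is applied independently per
strain, the expected per-site identity between two derived strains at rate
``p`` is ``(1-p)^2 + p^2/3``, while ancestor-vs-derived is ``1-p``; the
truth object stores these pairwise expectations.

Foreign (HGT) genes and CRISPR arrays are planted by overwriting
intergenic sequence, preserving genome length and every coordinate
guarantee.  Everything planted is recorded in a :class:`SyntheticTruth`
against which downstream recovery is scored.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_formats import (
    GeneRecord,
    GenomeRecord,
    StrainkitError,
    TaxonomyLabel,
    reverse_complement,
    translate_cds,
    write_fasta,
    write_gene_table,
)

__all__ = [
    "CrisprSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "CrisprTruth",
    "HitDatabase",
    "SimulationResult",
    "generate_strain_set",
    "plant_hgt_genes",
    "plant_crispr_array",
    "simulate",
    "write_simulation",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

# default donor order -> phylum used for planted foreign genes
_DONOR_PHYLA = {
    "Flavobacteriales": "Bacteroidetes",
    "Cytophagales": "Bacteroidetes",
    "Burkholderiales": "Proteobacteria",
}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(StrainkitError):
    """A simulation configuration violates its invariants."""


class InsufficientSpaceError(StrainkitError):
    """Not enough intergenic room to plant the requested elements."""


@dataclass(frozen=True)
class CrisprSpec:
    """One array to plant: exact DR copies separated by distinct spacers."""

    dr_length: int = 30
    n_spacers: int = 3
    spacer_min: int = 33
    spacer_max: int = 44

    def validate(self) -> None:
        if not (23 <= self.dr_length <= 55):
            raise ConfigError(f"DR length {self.dr_length} outside [23, 55]")
        if self.n_spacers < 1:
            raise ConfigError("n_spacers must be >= 1")
        lo, hi = 0.6 * self.dr_length, 2.5 * self.dr_length
        if not (lo <= self.spacer_min <= self.spacer_max <= hi):
            raise ConfigError(
                f"spacer lengths [{self.spacer_min}, {self.spacer_max}] outside "
                f"[{lo:.0f}, {hi:.0f}] for DR length {self.dr_length}"
            )

    def max_block_length(self) -> int:
        return (self.n_spacers + 1) * self.dr_length + self.n_spacers * self.spacer_max


@dataclass
class SimulationConfig:
    """Parameters of a synthetic strain set.

    Defaults describe the standard desk-scale scenario: four strains of
    120 kb at the focal strain's G+C of 0.385, four gene categories with
    divergence rates spanning the conserved-to-divergent range observed
    between real strains (0.02 ... 0.25 substitutions per site), ten
    planted foreign genes, and two CRISPR arrays whose DR length and
    spacer counts mirror the focal strain's confirmed arrays (DR 30 bp
    with 17 and with 3 spacers).
    """

    n_strains: int = 4
    genome_length: int = 120_000
    gc_target: float = 0.385
    genes_per_category: dict[str, int] = field(
        default_factory=lambda: {"Y": 12, "M": 12, "Q": 12, "D": 12})
    per_category_divergence: dict[str, float] = field(
        default_factory=lambda: {"Y": 0.02, "M": 0.05, "Q": 0.10, "D": 0.25})
    backbone_divergence: float = 0.10
    gene_length: int = 900
    n_hgt_genes: int = 10
    hgt_gene_length: int = 900
    hgt_donor_orders: list[str] = field(default_factory=lambda: list(_DONOR_PHYLA))
    focal_order: str = "Sphingobacteriales"
    focal_phylum: str = "Bacteroidetes"
    crispr_specs: list[CrisprSpec] = field(
        default_factory=lambda: [CrisprSpec(30, 17, 33, 44), CrisprSpec(30, 3, 36, 37)])
    include_16s: bool = True
    length_16s: int = 1500
    divergence_16s: float = 0.02
    strand_alternation: bool = True
    strain_prefix: str = "S"
    seed: int = 0

    def validate(self) -> None:
        if self.n_strains < 2:
            raise ConfigError("n_strains must be >= 2")
        if not (0.0 < self.gc_target < 1.0):
            raise ConfigError("gc_target must be in (0, 1)")
        if self.gene_length % 3 or self.gene_length < 9:
            raise ConfigError("gene_length must be a multiple of 3 and >= 9")
        if self.hgt_gene_length % 3 or self.hgt_gene_length < 9:
            raise ConfigError("hgt_gene_length must be a multiple of 3 and >= 9")
        for cat, rate in self.per_category_divergence.items():
            if not (0.0 <= rate <= 0.4):
                raise ConfigError(f"divergence for category {cat!r} outside [0, 0.4]")
        if not (0.0 <= self.backbone_divergence <= 0.4):
            raise ConfigError("backbone_divergence outside [0, 0.4]")
        missing = set(self.genes_per_category) - set(self.per_category_divergence)
        if missing:
            raise ConfigError(f"no divergence rate for categories {sorted(missing)}")
        if self.n_hgt_genes < 0:
            raise ConfigError("n_hgt_genes must be >= 0")
        for spec in self.crispr_specs:
            spec.validate()
        total = sum(self.genes_per_category.values()) * self.gene_length
        if self.include_16s:
            total += self.length_16s
        if total >= self.genome_length:
            raise ConfigError(
                f"gene content ({total} bp) must be smaller than genome_length "
                f"({self.genome_length} bp)"
            )


@dataclass
class CrisprTruth:
    genome_id: str
    contig_id: str
    start: int
    end: int
    dr_consensus: str
    dr_length: int
    n_spacers: int
    spacer_lengths: list[int]


@dataclass
class SyntheticTruth:
    """Planted parameters against which recovery is scored."""

    per_category_divergence: dict[str, float]
    backbone_divergence: float
    divergence_16s: float
    # (genome_a, genome_b) -> {category letter | "BACKBONE" | "16S"} -> expected % identity
    expected_identity: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    hgt_genes: dict[str, str] = field(default_factory=dict)   # gene_id -> donor order
    crisprs: list[CrisprTruth] = field(default_factory=list)

    def expected_identity_16s(self, genome_a: str, genome_b: str) -> float:
        key = (genome_a, genome_b) if (genome_a, genome_b) in self.expected_identity \
            else (genome_b, genome_a)
        return self.expected_identity[key]["16S"]


@dataclass
class HitDatabase:
    """Protein hit database with taxonomy, the synthetic stand-in for NR."""

    entries: list[tuple[str, str]]                 # (entry_id, protein sequence)
    taxonomy: dict[str, TaxonomyLabel]


@dataclass
class SimulationResult:
    config: SimulationConfig
    genomes: list[GenomeRecord]
    genes: list[GeneRecord]
    category_map: dict[str, str]
    hit_db: HitDatabase
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# sequence helpers


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_seq_array(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    return rng.choice(4, size=length, p=_base_probs(gc)).astype(np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise StrainkitError("cannot encode sequence with non-ACGT characters")
    return arr


# Composition-preserving replacements for stop codons drawn inside a CDS:
# each substitute is a base permutation of the stop, so the expected G+C
# of gene regions stays at the configured target.
_STOP_SUBSTITUTE = {"TAA": "ATA", "TAG": "GTA", "TGA": "GTA"}


def _random_cds(rng: np.random.Generator, length: int, gc: float) -> str:
    """ATG start, stop-free internal codons from the base distribution, TAA end."""
    n_internal = length // 3 - 2
    probs = _base_probs(gc)
    draw = rng.choice(4, size=(n_internal, 3), p=probs)
    codons = []
    for row in draw:
        codon = _decode(row.astype(np.uint8))
        codons.append(_STOP_SUBSTITUTE.get(codon, codon))
    return "ATG" + "".join(codons) + "TAA"


def _mutate_array(rng: np.random.Generator, arr: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Flip each site with its own probability to a uniformly chosen other base."""
    hit = rng.random(arr.shape[0]) < rates
    shift = rng.integers(1, 4, size=arr.shape[0], dtype=np.uint8)
    out = arr.copy()
    out[hit] = (out[hit] + shift[hit]) % 4
    return out


def _pairwise_expected_identity(p: float, q: float) -> float:
    """Expected % identity between two lineages mutated at rates p and q.

    Under "flip to a uniformly chosen different base", two sites derived
    from the same ancestor site agree when neither flipped, or both
    flipped to the same base (probability p*q/3).
    """
    match = (1 - p) * (1 - q) + p * q / 3
    return 100.0 * match


# ---------------------------------------------------------------------------
# core generator


def generate_strain_set(config: SimulationConfig
                        ) -> tuple[list[GenomeRecord], list[GeneRecord], dict[str, str],
                                   SyntheticTruth]:
    """Generate the strain set: ancestor plus mutated copies.

    Returns ``(genomes, genes, category_map, truth)``.  Strain 1 is the
    ancestor; genes keep identical coordinates in every strain.  The same
    seed yields byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.genome_length

    # gene layout on the single contig, evenly spaced
    slots: list[tuple[str, int, int, str]] = []   # (category or "16S", start, end, strand)
    n_genes = sum(config.genes_per_category.values()) + (1 if config.include_16s else 0)
    total_gene_bp = sum(config.genes_per_category.values()) * config.gene_length
    if config.include_16s:
        total_gene_bp += config.length_16s
    gap = (L - total_gene_bp) // (n_genes + 1)
    pos = gap
    idx = 0
    for cat in sorted(config.genes_per_category):
        for _ in range(config.genes_per_category[cat]):
            strand = "-" if (config.strand_alternation and idx % 2) else "+"
            slots.append((cat, pos, pos + config.gene_length, strand))
            pos += config.gene_length + gap
            idx += 1
    if config.include_16s:
        slots.append(("16S", pos, pos + config.length_16s, "+"))
        pos += config.length_16s + gap

    ancestor = _random_seq_array(rng, L, config.gc_target)
    rates = np.full(L, config.backbone_divergence)
    for cat, start, end, strand in slots:
        cds = (_random_seq_array(rng, config.length_16s, config.gc_target)
               if cat == "16S" else _encode(_random_cds(rng, config.gene_length,
                                                        config.gc_target)))
        if strand == "-":
            placed = _encode(reverse_complement(_decode(cds)))
        else:
            placed = cds
        ancestor[start:end] = placed
        rates[start:end] = (config.divergence_16s if cat == "16S"
                            else config.per_category_divergence[cat])

    strain_ids = [f"{config.strain_prefix}{i + 1:02d}" for i in range(config.n_strains)]
    arrays = [ancestor]
    for _ in range(config.n_strains - 1):
        arrays.append(_mutate_array(rng, ancestor, rates))

    genomes: list[GenomeRecord] = []
    genes: list[GeneRecord] = []
    category_map: dict[str, str] = {}
    for sid, arr in zip(strain_ids, arrays):
        contig_id = f"{sid}_c1"
        seq = _decode(arr)
        genomes.append(GenomeRecord(genome_id=sid, contigs=[(contig_id, seq)],
                                    source="synthetic"))
        for j, (cat, start, end, strand) in enumerate(slots):
            if cat == "16S":
                gid = f"{sid}_16S"
                genes.append(GeneRecord(
                    gene_id=gid, genome_id=sid, contig_id=contig_id, start=start, end=end,
                    strand=strand, cds=seq[start:end], protein="", category="UNASSIGNED",
                    feature_type="rRNA_16S"))
                continue
            gid = f"{sid}_g{j:04d}"
            sub = seq[start:end]
            cds = reverse_complement(sub) if strand == "-" else sub
            genes.append(GeneRecord(
                gene_id=gid, genome_id=sid, contig_id=contig_id, start=start, end=end,
                strand=strand, cds=cds, protein=translate_cds(cds, warn=False),
                category=cat, feature_type="cds"))
            category_map[gid] = cat

    # pairwise expectations: rate 0 for the ancestor, the configured rate otherwise
    truth = SyntheticTruth(
        per_category_divergence=dict(config.per_category_divergence),
        backbone_divergence=config.backbone_divergence,
        divergence_16s=config.divergence_16s,
    )
    for a, b in itertools.combinations(range(config.n_strains), 2):
        pa = 0.0 if a == 0 else 1.0
        pb = 0.0 if b == 0 else 1.0
        expect: dict[str, float] = {}
        for cat, rate in config.per_category_divergence.items():
            expect[cat] = _pairwise_expected_identity(pa * rate, pb * rate)
        expect["BACKBONE"] = _pairwise_expected_identity(
            pa * config.backbone_divergence, pb * config.backbone_divergence)
        expect["16S"] = _pairwise_expected_identity(
            pa * config.divergence_16s, pb * config.divergence_16s)
        truth.expected_identity[(strain_ids[a], strain_ids[b])] = expect

    return genomes, genes, category_map, truth


# ---------------------------------------------------------------------------
# planting


def _intergenic_gaps(genome: GenomeRecord, genes: list[GeneRecord], margin: int = 50
                     ) -> list[tuple[str, int, int]]:
    """Free (contig_id, start, end) intervals of the genome, margin-trimmed."""
    occupied: dict[str, list[tuple[int, int]]] = {cid: [] for cid, _ in genome.contigs}
    for g in genes:
        if g.genome_id == genome.genome_id:
            occupied[g.contig_id].append((g.start, g.end))
    gaps: list[tuple[str, int, int]] = []
    for cid, seq in genome.contigs:
        spans = sorted(occupied[cid])
        prev = 0
        for start, end in spans + [(len(seq), len(seq))]:
            lo, hi = prev + margin, start - margin
            if hi - lo > 0:
                gaps.append((cid, lo, hi))
            prev = max(prev, end)
    return gaps


def _overwrite(genomes: list[GenomeRecord], genome_id: str, contig_id: str, start: int,
               block: str) -> None:
    for i, g in enumerate(genomes):
        if g.genome_id != genome_id:
            continue
        contigs = []
        for cid, seq in g.contigs:
            if cid == contig_id:
                if start + len(block) > len(seq):
                    raise InsufficientSpaceError(
                        f"block of {len(block)} bp does not fit at {contig_id}:{start}")
                seq = seq[:start] + block + seq[start + len(block):]
            contigs.append((cid, seq))
        genomes[i] = replace(g, contigs=contigs)
        return
    raise StrainkitError(f"genome {genome_id!r} not found")


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    out = []
    for aa in protein:
        if rng.random() < rate:
            choices = _AA20.replace(aa, "") if aa in _AA20 else _AA20
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def plant_hgt_genes(genomes: list[GenomeRecord], genes: list[GeneRecord],
                    config: SimulationConfig, truth: SyntheticTruth | None = None,
                    rng: np.random.Generator | None = None
                    ) -> tuple[list[GeneRecord], HitDatabase]:
    """Plant composition-shifted foreign genes into the first strain.

    Each planted gene overwrites intergenic sequence of the focal (first)
    genome with a CDS whose G+C is offset by at least 0.12 from the host
    target, and is registered in the emitted hit database as a
    near-identical homolog carrying a donor order — and no homolog from
    the focal order.  Every native protein-coding gene of the focal
    genome gets a focal-order homolog (plus, for every fifth gene, an
    extra non-focal homolog) so that false-positive calls are
    measurable.  Updates ``genomes`` in place; returns the updated gene
    list and the database.  Truth, when given, records the planted ids.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    focal = genomes[0]
    donor_gc = config.gc_target + (0.15 if config.gc_target <= 0.5 else -0.15)

    genes = list(genes)
    planted: list[GeneRecord] = []
    if config.n_hgt_genes > 0:
        gaps = [g for g in _intergenic_gaps(focal, genes)
                if g[2] - g[1] >= config.hgt_gene_length]
        if len(gaps) < config.n_hgt_genes:
            raise InsufficientSpaceError(
                f"need {config.n_hgt_genes} intergenic slots of {config.hgt_gene_length} bp, "
                f"found {len(gaps)}")
        pick = rng.choice(len(gaps), size=config.n_hgt_genes, replace=False)
        categories = sorted(config.genes_per_category) or ["UNASSIGNED"]
        for i, gi in enumerate(sorted(pick)):
            cid, lo, hi = gaps[gi]
            start = lo
            cds = _random_cds(rng, config.hgt_gene_length, donor_gc)
            _overwrite(genomes, focal.genome_id, cid, start, cds)
            gid = f"{focal.genome_id}_hgt{i:02d}"
            planted.append(GeneRecord(
                gene_id=gid, genome_id=focal.genome_id, contig_id=cid, start=start,
                end=start + len(cds), strand="+", cds=cds,
                protein=translate_cds(cds, warn=False),
                category=categories[i % len(categories)], feature_type="cds"))
    genes.extend(planted)

    entries: list[tuple[str, str]] = []
    taxonomy: dict[str, TaxonomyLabel] = {}
    native = [g for g in genes if g.genome_id == focal.genome_id
              and g.feature_type == "cds" and g not in planted]
    alt_orders = config.hgt_donor_orders or ["Flavobacteriales"]
    for i, g in enumerate(native):
        eid = f"db_{g.gene_id}_focal"
        entries.append((eid, _mutate_protein(rng, g.protein, 0.02)))
        taxonomy[eid] = TaxonomyLabel(eid, config.focal_order, config.focal_phylum)
        if i % 5 == 0:
            order = alt_orders[i % len(alt_orders)]
            eid2 = f"db_{g.gene_id}_out"
            entries.append((eid2, _mutate_protein(rng, g.protein, 0.05)))
            taxonomy[eid2] = TaxonomyLabel(eid2, order, _DONOR_PHYLA.get(order, "Unknown"))

    donors = config.hgt_donor_orders or ["Flavobacteriales"]
    truth_map: dict[str, str] = {}
    for i, g in enumerate(planted):
        order = donors[i % len(donors)]
        eid = f"db_{g.gene_id}_donor"
        entries.append((eid, _mutate_protein(rng, g.protein, 0.03)))
        taxonomy[eid] = TaxonomyLabel(eid, order, _DONOR_PHYLA.get(order, "Unknown"))
        truth_map[g.gene_id] = order
    if truth is not None:
        truth.hgt_genes.update(truth_map)

    return genes, HitDatabase(entries=entries, taxonomy=taxonomy)


def plant_crispr_array(genomes: list[GenomeRecord], genome_id: str, spec: CrisprSpec,
                       rng: np.random.Generator,
                       avoid: list[GeneRecord] | None = None,
                       truth: SyntheticTruth | None = None) -> CrisprTruth:
    """Plant one CRISPR array (exact DR copies, distinct random spacers).

    The array ``DR s1 DR s2 ... DR`` overwrites intergenic sequence of
    the chosen genome; its coordinates, DR consensus and spacer lengths
    are returned (and appended to ``truth`` when given).
    """
    spec.validate()
    genome = next(g for g in genomes if g.genome_id == genome_id)
    gaps = [g for g in _intergenic_gaps(genome, avoid or [])
            if g[2] - g[1] >= spec.max_block_length()]
    if not gaps:
        raise InsufficientSpaceError(
            f"no intergenic slot of {spec.max_block_length()} bp in genome {genome_id!r}")
    cid, lo, hi = gaps[int(rng.integers(len(gaps)))]
    start = lo

    dr = _decode(_random_seq_array(rng, spec.dr_length, 0.5))
    spacers: list[str] = []
    seen = set()
    while len(spacers) < spec.n_spacers:
        length = int(rng.integers(spec.spacer_min, spec.spacer_max + 1))
        s = _decode(_random_seq_array(rng, length, 0.5))
        if s not in seen and dr not in s:
            seen.add(s)
            spacers.append(s)
    block = dr + "".join(s + dr for s in spacers)

    _overwrite(genomes, genome_id, cid, start, block)
    entry = CrisprTruth(
        genome_id=genome_id, contig_id=cid, start=start, end=start + len(block),
        dr_consensus=dr, dr_length=spec.dr_length, n_spacers=spec.n_spacers,
        spacer_lengths=[len(s) for s in spacers])
    if truth is not None:
        truth.crisprs.append(entry)
    return entry


# ---------------------------------------------------------------------------
# one-call scenario builder


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate a complete scenario: strains, planted HGT genes, CRISPR arrays."""
    genomes, genes, category_map, truth = generate_strain_set(config)
    rng = np.random.default_rng(config.seed + 1)
    genes, hit_db = plant_hgt_genes(genomes, genes, config, truth=truth, rng=rng)
    for g in genes:
        if g.gene_id not in category_map and g.feature_type == "cds":
            category_map[g.gene_id] = g.category
    placed: list[GeneRecord] = []
    for i, spec in enumerate(config.crispr_specs):
        entry = plant_crispr_array(genomes, genomes[0].genome_id, spec, rng,
                                   avoid=genes + placed, truth=truth)
        placed.append(GeneRecord(
            gene_id=f"_crispr_slot_{i}", genome_id=entry.genome_id,
            contig_id=entry.contig_id, start=entry.start, end=entry.end, strand="+",
            feature_type="crispr_slot"))
    # re-extract CDS for focal-strain genes: planting rebuilt the genome string
    focal = genomes[0]
    contig = dict(focal.contigs)
    for i, g in enumerate(genes):
        if g.genome_id == focal.genome_id and g.feature_type == "cds":
            sub = contig[g.contig_id][g.start:g.end]
            cds = reverse_complement(sub) if g.strand == "-" else sub
            if cds != g.cds:
                genes[i] = replace(g, cds=cds, protein=translate_cds(cds, warn=False))
    return SimulationResult(config=config, genomes=genomes, genes=genes,
                            category_map=category_map, hit_db=hit_db, truth=truth)


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write genomes, gene table, category map, hit database and truth as text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for g in result.genomes:
        p = outdir / f"{g.genome_id}.fasta"
        write_fasta(p, g.contigs)
        paths[f"genome_{g.genome_id}"] = p
    paths["gene_table"] = outdir / "genes.tsv"
    write_gene_table(paths["gene_table"], result.genes)
    paths["category_map"] = outdir / "categories.tsv"
    with open(paths["category_map"], "w") as fh:
        fh.write("gene_id\tcategory\n")
        for gid, cat in sorted(result.category_map.items()):
            fh.write(f"{gid}\t{cat}\n")
    paths["hit_db_fasta"] = outdir / "hit_db.faa"
    write_fasta(paths["hit_db_fasta"], result.hit_db.entries)
    paths["hit_db_taxonomy"] = outdir / "hit_db_taxonomy.tsv"
    with open(paths["hit_db_taxonomy"], "w") as fh:
        fh.write("entry_id\torder\tphylum\n")
        for eid, lab in sorted(result.hit_db.taxonomy.items()):
            fh.write(f"{eid}\t{lab.order}\t{lab.phylum}\n")
    truth = result.truth
    paths["truth_identity"] = outdir / "truth_identity.tsv"
    with open(paths["truth_identity"], "w") as fh:
        fh.write("genome_a\tgenome_b\tfeature\texpected_identity\n")
        for (a, b), expect in truth.expected_identity.items():
            for feat, val in sorted(expect.items()):
                fh.write(f"{a}\t{b}\t{feat}\t{val:.4f}\n")
    paths["truth_hgt"] = outdir / "truth_hgt.tsv"
    with open(paths["truth_hgt"], "w") as fh:
        fh.write("gene_id\tdonor_order\n")
        for gid, order in sorted(truth.hgt_genes.items()):
            fh.write(f"{gid}\t{order}\n")
    paths["truth_crispr"] = outdir / "truth_crispr.tsv"
    with open(paths["truth_crispr"], "w") as fh:
        fh.write("genome_id\tcontig_id\tstart\tend\tdr_consensus\tdr_length\tn_spacers"
                 "\tspacer_lengths\n")
        for c in truth.crisprs:
            fh.write(f"{c.genome_id}\t{c.contig_id}\t{c.start}\t{c.end}\t{c.dr_consensus}"
                     f"\t{c.dr_length}\t{c.n_spacers}\t"
                     + ",".join(map(str, c.spacer_lengths)) + "\n")
    return paths
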