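"""Toy-scale synthetic inputs with planted, recoverable structure.

The generator emits every input the screen consumes — reference FASTA,
multi-species alignment (MAF), phylogeny (newick), motif library, gene
models, ontology, an individual's variants (VCF) and an outgroup track —
with motif consensus instances planted in the basal regulatory domains of
genes annotated to a chosen target term.  Planted sites are copied
unchanged to every species (perfect conservation), so the conservation
filters recover them deterministically; a configurable fraction receives a
maximally eroding derived variant.  Decoy conserved sites far from the
target genes populate matched-control pools.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .cobel_caller import OutgroupTrack, Variant
from .conservation_scan import (
    AlignmentBlock,
    GenomeAlignment,
    PhyloTree,
    write_maf,
)
from .great_enrichment import GeneModel, Ontology, write_genes_tsv
from .motif_model import BASES, Pwm, information_vector, write_meme, write_pwm_tsv

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

REF_SPECIES = "ref"

# fixed offsets from the master seed, one per stochastic component
_SEED_TREE = 1
_SEED_MOTIFS = 2
_SEED_GENES = 3
_SEED_GENOME = 4
_SEED_ALIGNMENT = 5
_SEED_INDIVIDUAL = 6


@dataclasses.dataclass
class FixtureConfig:
    """Study conditions of the synthetic screen.

    The defaults describe a signal fixture: 8 target genes each carrying 5
    perfectly conserved planted sites, 80% of which are eroded by the
    simulated individual, over a 600 kb single-chromosome genome aligned
    across 8 species.
    """

    n_species: int = 8
    genome_length: int = 600_000
    n_genes: int = 60
    n_terms: int = 12
    target_term: str = "T_TARGET"
    n_target_genes: int = 8
    n_planted_sites_per_target_gene: int = 5
    n_decoy_sites: int = 150
    erosion_fraction: float = 0.8
    background_snv_rate: float = 1e-4
    substitution_rate_scale: float = 1.0
    seed: int = 0
    chrom: str = "chr1"
    block_size: int = 2000
    n_motifs: int = 6
    motif_length: int = 8
    consensus_freq: float = 0.88

    def __post_init__(self) -> None:
        if not (0 <= self.erosion_fraction <= 1):
            raise ValueError("erosion_fraction must lie in [0, 1]")
        if self.genome_length < 10 * self.n_genes * 1000:
            raise ValueError("genome_length must be >= 10 * n_genes * 1000")
        if self.n_terms < 3:
            raise ValueError("need at least root, parent and target terms")
        if self.n_target_genes > self.n_genes:
            raise ValueError("n_target_genes cannot exceed n_genes")
        if self.n_species < 2:
            raise ValueError("need at least two aligned species")


@dataclasses.dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted conserved site."""

    chrom: str
    start: int
    end: int
    strand: str
    motif_id: str
    kind: str  # target | decoy
    gene: str | None = None
    eroded: bool = False
    variant_pos: int | None = None


@dataclasses.dataclass
class FixtureManifest:
    """In-memory fixture objects plus (optionally) the files they were
    written to."""

    config: FixtureConfig
    genome: dict[str, str]
    alignment: GenomeAlignment
    tree: PhyloTree
    pwms: list[Pwm]
    genes: list[GeneModel]
    chrom_lengths: dict[str, int]
    ontology: Ontology
    variants: list[Variant]
    outgroup: OutgroupTrack
    truth: list[PlantedSite]
    paths: dict[str, str] = dataclasses.field(default_factory=dict)


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


def simulate_tree(n_species: int, seed: int) -> PhyloTree:
    """A random bifurcating phylogeny of ``n_species`` plus the reference.

    Branch lengths are uniform on [0.05, 0.5] substitutions/site; the
    reference leaf joins at the root with a zero-length terminal branch.
    Branch lengths are scaled up if needed so the total branch length
    spanned by the full species set is at least 2.0.
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)

    def bl() -> float:
        return float(rng.uniform(0.05, 0.5))

    nodes = [f"sp{i + 1:02d}" for i in range(n_species)]
    lengths = {name: bl() for name in nodes}
    subtrees = {name: name for name in nodes}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop larger index first
        nodes.pop(j)
        nodes.pop(i)
        merged = f"({subtrees[a]}:{lengths[a]:.6f},{subtrees[b]}:{lengths[b]:.6f})"
        name = f"n{len(subtrees)}"
        subtrees[name] = merged
        lengths[name] = bl()
        nodes.append(name)
    root = nodes[0]
    newick = f"({subtrees[root]}:{lengths[root]:.6f},{REF_SPECIES}:0.0);"
    tree = PhyloTree.from_newick(newick, REF_SPECIES)
    total = tree.induced_branch_length(tree.species)
    if total < 2.0:
        scale = 2.1 / total
        for clade in tree._tree.find_clades():
            if clade.branch_length:
                clade.branch_length *= scale
        tree = PhyloTree.from_newick(tree.to_newick(), REF_SPECIES)
    return tree


# ---------------------------------------------------------------------------
# Motifs, genes and ontology
# ---------------------------------------------------------------------------


def make_motif_library(config: FixtureConfig, seed: int) -> list[Pwm]:
    """Sharp random motifs (one consensus base at ``consensus_freq``); the
    first motif carries a consensus CpG for shuffle exercises."""
    rng = np.random.default_rng(seed)
    off = (1.0 - config.consensus_freq) / 3.0
    pwms: list[Pwm] = []
    seen: set[str] = set()
    while len(pwms) < config.n_motifs:
        cons = "".join(rng.choice(list(BASES), size=config.motif_length))
        if len(pwms) == 0 and "CG" not in cons:
            mid = config.motif_length // 2
            cons = cons[: mid - 1] + "CG" + cons[mid + 1 :]
        if cons in seen:
            continue
        seen.add(cons)
        freqs = np.full((config.motif_length, 4), off)
        for i, base in enumerate(cons):
            freqs[i, BASES.index(base)] = config.consensus_freq
        idx = len(pwms) + 1
        pwms.append(Pwm(id=f"M{idx:02d}", tf_name=f"TF{idx:02d}", freqs=freqs))
    return pwms


def make_toy_ontology(
    config: FixtureConfig, genes: Sequence[GeneModel], target_genes: Sequence[str], seed: int
) -> Ontology:
    """A rooted DAG: root -> parent -> target term, plus decoy terms under
    the root.  Target genes annotate the target term; every remaining gene
    annotates one decoy term, and two genes annotate the parent directly
    (so the related-term group is a strict superset)."""
    rng = np.random.default_rng(seed)
    decoys = [f"T_DEC{i + 1:02d}" for i in range(config.n_terms - 3)]
    edges = [("T_PARENT", "T_ROOT"), (config.target_term, "T_PARENT")]
    edges += [(d, "T_ROOT") for d in decoys]
    annotations: dict[str, set[str]] = {config.target_term: set(target_genes)}
    others = [g.symbol for g in genes if g.symbol not in set(target_genes)]
    for i, symbol in enumerate(others[:2]):
        annotations.setdefault("T_PARENT", set()).add(symbol)
    for symbol in others[2:]:
        annotations.setdefault(str(rng.choice(decoys)), set()).add(symbol)
    return Ontology(edges=edges, annotations=annotations)


def _make_genes(config: FixtureConfig, seed: int) -> tuple[list[GeneModel], list[str]]:
    rng = np.random.default_rng(seed)
    spacing = config.genome_length // (config.n_genes + 1)
    genes = []
    for i in range(config.n_genes):
        jitter = int(rng.integers(-spacing // 8, spacing // 8 + 1))
        tss = (i + 1) * spacing + jitter
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"G{i + 1:03d}", config.chrom, tss, strand))
    target_idx = rng.choice(config.n_genes, size=config.n_target_genes, replace=False)
    target_genes = sorted(genes[i].symbol for i in target_idx)
    return genes, target_genes


# ---------------------------------------------------------------------------
# Genome, planted sites and alignment
# ---------------------------------------------------------------------------


def _basal_interval(gene: GeneModel, config: FixtureConfig) -> tuple[int, int]:
    if gene.strand == "-":
        lo, hi = gene.tss - 1000, gene.tss + 5000
    else:
        lo, hi = gene.tss - 5000, gene.tss + 1000
    return max(10, lo), min(config.genome_length - 10, hi)


def _fits(start: int, end: int, occupied: list[tuple[int, int]], block_size: int) -> bool:
    if start // block_size != (end - 1) // block_size:
        return False  # must not straddle an alignment block boundary
    return all(end + 2 <= s or e + 2 <= start for s, e in occupied)


def simulate_genome_and_alignment(
    config: FixtureConfig,
    genes: Sequence[GeneModel],
    target_genes: Sequence[str],
    pwms: Sequence[Pwm],
    tree: PhyloTree,
) -> tuple[dict[str, str], GenomeAlignment, list[PlantedSite]]:
    """Reference genome with planted consensus sites and the per-species
    alignment.

    The reference is i.i.d. uniform DNA.  Each target gene receives
    ``n_planted_sites_per_target_gene`` consensus instances inside its
    basal domain; ``n_decoy_sites`` more are planted well away from target
    genes.  Planted columns are copied unchanged to every species; all
    other columns mutate independently per species at a Jukes–Cantor
    probability set by the species' distance from the reference.
    """
    rng = np.random.default_rng(config.seed + _SEED_GENOME)
    L = config.motif_length
    ref = rng.integers(0, 4, size=config.genome_length, dtype=np.int8)

    occupied: list[tuple[int, int]] = []
    planted: list[PlantedSite] = []
    gene_by_symbol = {g.symbol: g for g in genes}

    def plant(start: int, motif: Pwm, strand: str, kind: str, gene: str | None) -> None:
        cons = motif.consensus
        if strand == "-":
            cons = "".join(_COMPLEMENT[b] for b in reversed(cons))
        ref[start : start + L] = [BASES.index(b) for b in cons]
        occupied.append((start, start + L))
        planted.append(
            PlantedSite(config.chrom, start, start + L, strand, motif.id, kind, gene)
        )

    for symbol in target_genes:
        lo, hi = _basal_interval(gene_by_symbol[symbol], config)
        for j in range(config.n_planted_sites_per_target_gene):
            motif = pwms[(len(planted) + j) % len(pwms)]
            for _ in range(1000):
                start = int(rng.integers(lo, hi - L))
                if _fits(start, start + L, occupied, config.block_size):
                    break
            else:
                raise RuntimeError("could not place a planted site without collision")
            strand = "+" if rng.random() < 0.5 else "-"
            plant(start, motif, strand, "target", symbol)

    target_tss = [gene_by_symbol[s].tss for s in target_genes]
    exclusion = 15_000
    n_decoys = 0
    attempts = 0
    max_attempts = 200 * config.n_decoy_sites
    while n_decoys < config.n_decoy_sites:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place decoy sites away from target genes; "
                "the genome is too small for the requested layout"
            )
        start = int(rng.integers(10, config.genome_length - L - 10))
        if any(abs(start - t) < exclusion for t in target_tss):
            continue
        if not _fits(start, start + L, occupied, config.block_size):
            continue
        motif = pwms[n_decoys % len(pwms)]
        strand = "+" if rng.random() < 0.5 else "-"
        plant(start, motif, strand, "decoy", None)
        n_decoys += 1

    planted_mask = np.zeros(config.genome_length, dtype=bool)
    for s, e in occupied:
        planted_mask[s:e] = True

    # evolve species rows: independent Jukes-Cantor flips per branch distance
    align_rng = np.random.default_rng(config.seed + _SEED_ALIGNMENT)
    rows: dict[str, np.ndarray] = {REF_SPECIES: ref}
    for species in tree.species:
        d = tree.distance(REF_SPECIES, species) * config.substitution_rate_scale
        p_diff = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        mutate = (align_rng.random(config.genome_length) < p_diff) & ~planted_mask
        row = ref.copy()
        shifts = align_rng.integers(1, 4, size=int(mutate.sum()), dtype=np.int8)
        row[mutate] = (row[mutate] + shifts) % 4
        rows[species] = row

    base_array = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    seqs = {
        sp: base_array[row].tobytes().decode("ascii") for sp, row in rows.items()
    }
    genome = {config.chrom: seqs[REF_SPECIES]}

    blocks = []
    for start in range(0, config.genome_length, config.block_size):
        end = min(start + config.block_size, config.genome_length)
        blocks.append(
            AlignmentBlock(
                chrom=config.chrom,
                start=start,
                end=end,
                ref_species=REF_SPECIES,
                rows={sp: seq[start:end] for sp, seq in seqs.items()},
            )
        )
    alignment = GenomeAlignment(blocks, REF_SPECIES)
    planted.sort(key=lambda s: s.start)
    return genome, alignment, planted


# ---------------------------------------------------------------------------
# The individual
# ---------------------------------------------------------------------------


def simulate_individual(
    config: FixtureConfig,
    genome: dict[str, str],
    truth: Sequence[PlantedSite],
    pwms: Sequence[Pwm],
) -> tuple[list[Variant], OutgroupTrack, list[PlantedSite]]:
    """An individual's derived SNVs plus the matching outgroup track.

    For ``erosion_fraction`` of the planted target sites, one SNV at the
    site's maximum-information position replaces the consensus base with
    the motif's least frequent base — a guaranteed erosion well beyond the
    5% threshold.  Background SNVs are sprinkled outside all planted
    sites.  The outgroup base equals the reference base at every variant
    position, so every variant passes the ancestral filter.
    """
    rng = np.random.default_rng(config.seed + _SEED_INDIVIDUAL)
    seq = genome[config.chrom]
    pwm_by_id = {p.id: p for p in pwms}

    target_sites = [s for s in truth if s.kind == "target"]
    n_eroded = int(round(config.erosion_fraction * len(target_sites)))
    eroded_idx = set(
        rng.choice(len(target_sites), size=n_eroded, replace=False).tolist()
    )

    variants: list[Variant] = []
    outgroup_map: dict[tuple[str, int], str] = {}
    updated: list[PlantedSite] = [s for s in truth if s.kind != "target"]
    for i, site in enumerate(target_sites):
        if i not in eroded_idx:
            updated.append(site)
            continue
        pwm = pwm_by_id[site.motif_id]
        info = information_vector(pwm)
        j = int(info.argmax())
        worst = pwm.min_frequency_base(j)
        if site.strand == "+":
            pos = site.start + j
            alt = worst
        else:
            pos = site.start + (len(pwm) - 1 - j)
            alt = _COMPLEMENT[worst]
        ref_base = seq[pos]
        if alt == ref_base:  # tie-broken column; pick any other base
            alt = next(b for b in BASES if b != ref_base)
        zygosity = "het" if rng.random() < 0.5 else "hom"
        variants.append(
            Variant(chrom=site.chrom, pos=pos, ref_allele=ref_base, alt_allele=alt, zygosity=zygosity)
        )
        outgroup_map[(site.chrom, pos)] = ref_base
        updated.append(dataclasses.replace(site, eroded=True, variant_pos=pos))

    planted_mask = np.zeros(config.genome_length, dtype=bool)
    for s in truth:
        planted_mask[s.start : s.end] = True
    taken = {v.pos for v in variants}
    n_background = int(rng.binomial(config.genome_length, config.background_snv_rate))
    candidates = rng.permutation(config.genome_length)
    placed = 0
    for pos in candidates:
        if placed >= n_background:
            break
        pos = int(pos)
        if planted_mask[pos] or pos in taken:
            continue
        ref_base = seq[pos]
        alt = BASES[(BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
        zygosity = "het" if rng.random() < 0.5 else "hom"
        variants.append(
            Variant(chrom=config.chrom, pos=pos, ref_allele=ref_base, alt_allele=alt, zygosity=zygosity)
        )
        outgroup_map[(config.chrom, pos)] = ref_base
        taken.add(pos)
        placed += 1

    variants.sort(key=lambda v: (v.chrom, v.pos))
    updated.sort(key=lambda s: s.start)
    return variants, OutgroupTrack.from_mapping(outgroup_map), updated


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def _write_fasta(genome: dict[str, str], path: Path) -> None:
    with open(path, "w") as out:
        for chrom, seq in genome.items():
            out.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                out.write(seq[i : i + 60] + "\n")


def _write_vcf(variants: Sequence[Variant], chrom_lengths: dict[str, int], path: Path) -> None:
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            out.write(f"##contig=<ID={chrom},length={length}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tindividual\n")
        for v in variants:
            gt = "1/1" if v.zygosity == "hom" else "0/1"
            out.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def _write_outgroup_tsv(variants: Sequence[Variant], path: Path) -> None:
    with open(path, "w") as out:
        for v in variants:
            out.write(f"{v.chrom}\t{v.pos}\t{v.ref_allele}\n")


def _write_truth_bed(truth: Sequence[PlantedSite], path: Path) -> None:
    with open(path, "w") as out:
        for s in truth:
            out.write(
                "\t".join(
                    [
                        s.chrom,
                        str(s.start),
                        str(s.end),
                        s.motif_id,
                        "0",
                        s.strand,
                        s.kind,
                        s.gene or ".",
                        "1" if s.eroded else "0",
                        str(s.variant_pos if s.variant_pos is not None else -1),
                    ]
                )
                + "\n"
            )


def _write_ontology_tsvs(ontology: Ontology, edges_path: Path, ann_path: Path) -> None:
    with open(edges_path, "w") as out:
        for parent, child in sorted(ontology.graph.edges):
            out.write(f"{child}\t{parent}\n")
    with open(ann_path, "w") as out:
        for term in sorted(ontology.direct):
            for gene in sorted(ontology.direct[term]):
                out.write(f"{gene}\t{term}\n")


def generate_fixture(config: FixtureConfig, outdir: str | Path | None = None) -> FixtureManifest:
    """Generate a complete fixture; write files when ``outdir`` is given.

    All randomness flows from ``config.seed``; each component derives its
    own generator from the master seed plus a fixed offset.
    """
    tree = simulate_tree(config.n_species, config.seed + _SEED_TREE)
    pwms = make_motif_library(config, config.seed + _SEED_MOTIFS)
    genes, target_genes = _make_genes(config, config.seed + _SEED_GENES)
    ontology = make_toy_ontology(config, genes, target_genes, config.seed + _SEED_GENES)
    genome, alignment, planted = simulate_genome_and_alignment(
        config, genes, target_genes, pwms, tree
    )
    variants, outgroup, truth = simulate_individual(config, genome, planted, pwms)
    chrom_lengths = {config.chrom: config.genome_length}

    manifest = FixtureManifest(
        config=config,
        genome=genome,
        alignment=alignment,
        tree=tree,
        pwms=pwms,
        genes=genes,
        chrom_lengths=chrom_lengths,
        ontology=ontology,
        variants=variants,
        outgroup=outgroup,
        truth=truth,
    )
    if outdir is None:
        return manifest

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "alignment": outdir / "alignment.maf",
        "tree": outdir / "tree.nwk",
        "motifs_tsv": outdir / "motifs.tsv",
        "motifs_meme": outdir / "motifs.meme",
        "genes": outdir / "genes.tsv",
        "chrom_sizes": outdir / "chrom.sizes",
        "ontology_edges": outdir / "ontology_edges.tsv",
        "ontology_annotations": outdir / "ontology_annotations.tsv",
        "variants": outdir / "variants.vcf",
        "outgroup": outdir / "outgroup.tsv",
        "truth": outdir / "truth.bed",
        "manifest": outdir / "manifest.json",
    }
    _write_fasta(genome, paths["genome"])
    write_maf(alignment, paths["alignment"])
    paths["tree"].write_text(tree.to_newick() + "\n")
    write_pwm_tsv(pwms, paths["motifs_tsv"])
    write_meme(pwms, paths["motifs_meme"])
    write_genes_tsv(genes, paths["genes"])
    paths["chrom_sizes"].write_text(
        "".join(f"{c}\t{l}\n" for c, l in chrom_lengths.items())
    )
    _write_ontology_tsvs(
        ontology, paths["ontology_edges"], paths["ontology_annotations"]
    )
    _write_vcf(variants, chrom_lengths, paths["variants"])
    _write_outgroup_tsv(variants, paths["outgroup"])
    _write_truth_bed(truth, paths["truth"])
    manifest.paths = {k: str(p) for k, p in paths.items()}
    summary = {
        "seed": config.seed,
        "seed_offsets": {
            "tree": _SEED_TREE,
            "motifs": _SEED_MOTIFS,
            "genes_ontology": _SEED_GENES,
            "genome": _SEED_GENOME,
            "alignment": _SEED_ALIGNMENT,
            "individual": _SEED_INDIVIDUAL,
        },
        "config": dataclasses.asdict(config),
        "target_genes": target_genes,
        "n_planted_target_sites": sum(1 for s in truth if s.kind == "target"),
        "n_eroded_sites": sum(1 for s in truth if s.eroded),
        "n_variants": len(variants),
        "files": manifest.paths,
    }
    paths["manifest"].write_text(json.dumps(summary, indent=2) + "\n")
    return manifest
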