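"""End-to-end orchestration of the erosion screen.

Stage order: scan & conserve -> ancestral polarization -> erosion calling
-> enrichment -> optional permutation nulls.  All randomness derives from
one master seed; reruns with an identical configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

from . import __version__
from .cobel_caller import (
    CallConfig,
    Cobel,
    OutgroupTrack,
    Variant,
    ancestral_filter,
    call_cobels,
    load_variants,
    summarize_cobels,
    write_cobel_bed,
)
from .conservation_scan import (
    ConservedSite,
    GenomeAlignment,
    PhyloTree,
    ScanConfig,
    find_conserved_sites,
    read_maf,
    write_conserved_bed,
)
from .great_enrichment import (
    GeneModel,
    GreatConfig,
    Ontology,
    enrich,
    rank_and_select_top,
    read_chrom_sizes,
    read_genes_tsv,
)
from .motif_model import Pwm, read_meme, read_pwm_tsv
from .null_models import (
    build_control_pool,
    empirical_top_term_p,
    top_terms_for_controls,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Paths and parameters of one screen run."""

    genome: str
    alignment: str
    tree: str
    motifs: str
    genes: str
    chrom_sizes: str
    ontology_edges: str
    ontology_annotations: str
    variants: str
    outgroup: str
    out_dir: str
    seed: int = 0
    reference_species: str = "ref"
    variant_format: str = "vcf"
    n_control_shuffles: int = 10_000
    n_history_shuffles: int = 1_000
    scan: ScanConfig = dataclasses.field(default_factory=ScanConfig)
    call: CallConfig = dataclasses.field(default_factory=CallConfig)
    great: GreatConfig = dataclasses.field(default_factory=GreatConfig)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        for key, klass in (("scan", ScanConfig), ("call", CallConfig), ("great", GreatConfig)):
            if key in data and isinstance(data[key], dict):
                data[key] = klass(**data[key])
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output location is
        excluded so relocated reruns hash identically)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclasses.dataclass
class ScreenResult:
    """Outputs of one screen run."""

    conserved_sites: list[ConservedSite]
    cobels: list[Cobel]
    enrichment: pd.DataFrame
    top: pd.Series | None
    summary: dict

    @property
    def top_term(self) -> str | None:
        return None if self.top is None else str(self.top["term"])


def screen(
    pwms: Sequence[Pwm],
    genome: Mapping[str, str],
    alignment: GenomeAlignment,
    tree: PhyloTree,
    variants: Sequence[Variant],
    outgroup: OutgroupTrack,
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    ontology: Ontology,
    scan_config: ScanConfig | None = None,
    call_config: CallConfig | None = None,
    great_config: GreatConfig | None = None,
    seed: int = 0,
) -> ScreenResult:
    """Run the screen on in-memory inputs (the library-level entry point)."""
    scan_config = scan_config or ScanConfig()
    call_config = call_config or CallConfig()
    great_config = great_config or GreatConfig()

    sites = find_conserved_sites(pwms, genome, alignment, tree, scan_config, seed)
    logger.info("conserved sites: %d", len(sites))
    polarized = ancestral_filter(variants, outgroup)
    logger.info("variants: %d loaded, %d ancestral-polarized", len(variants), len(polarized))
    cobels = call_cobels(
        sites, polarized, {p.id: p for p in pwms}, genome, call_config
    )
    logger.info("eroded loci: %d", len(cobels))
    regions = [(c.chrom, c.start, c.end) for c in cobels]
    enrichment = enrich(regions, genes, chrom_lengths, ontology, great_config)
    top = rank_and_select_top(enrichment, great_config)
    summary = {
        "n_conserved_sites": len(sites),
        "n_variants": len(variants),
        "n_variants_ancestral": len(polarized),
        "cobels": summarize_cobels(cobels),
        "top_term": None if top is None else str(top["term"]),
    }
    return ScreenResult(sites, cobels, enrichment, top, summary)


def control_empirical_p(
    result: ScreenResult,
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    ontology: Ontology,
    great_config: GreatConfig,
    target_set: set[str],
    n_shuffles: int,
    seed: int,
):
    """Matched-control empirical p-value for the observed top term."""
    if result.top_term is None:
        raise ValueError("no observed top term to test")
    pool = build_control_pool(result.conserved_sites)

    def top_fn(regions):
        df = enrich(regions, genes, chrom_lengths, ontology, great_config)
        top = rank_and_select_top(df, great_config)
        return None if top is None else str(top["term"])

    tops = top_terms_for_controls(result.cobels, pool, top_fn, n_shuffles, seed)
    return empirical_top_term_p(result.top_term, tops, target_set), tops


def load_inputs(config: RunConfig) -> dict:
    """Load every input referenced by a run configuration."""
    genome_fa = Fasta(config.genome, sequence_always_upper=True)
    genome = {name: str(genome_fa[name][:]) for name in genome_fa.keys()}
    motifs_path = Path(config.motifs)
    if motifs_path.suffix in (".meme", ".txt"):
        pwms = read_meme(motifs_path)
    else:
        pwms = read_pwm_tsv(motifs_path)
    outgroup_path = Path(config.outgroup)
    if outgroup_path.suffix in (".fa", ".fasta"):
        outgroup = OutgroupTrack.from_fasta(outgroup_path)
    else:
        outgroup = OutgroupTrack.from_tsv(outgroup_path)
    return {
        "pwms": pwms,
        "genome": genome,
        "alignment": read_maf(config.alignment, config.reference_species),
        "tree": PhyloTree.from_newick(Path(config.tree), config.reference_species),
        "variants": load_variants(config.variants, config.variant_format, genome),
        "outgroup": outgroup,
        "genes": read_genes_tsv(config.genes),
        "chrom_lengths": read_chrom_sizes(config.chrom_sizes),
        "ontology": Ontology.from_tsv(config.ontology_edges, config.ontology_annotations),
    }


def _output_header(config: RunConfig) -> str:
    return (
        f" cobel {__version__}\n"
        f" config_hash={config.config_hash()}\n"
        f" seed={config.seed}"
    )


def run_screen(config: RunConfig) -> ScreenResult:
    """File-level screen run: load inputs, run, write outputs.

    Outputs (in ``out_dir``): conserved_sites.bed, cobels.bed,
    enrichment.tsv, top_term.json and run.log, each headed by tool
    version, configuration hash and seed.  Reruns with an identical
    configuration are byte-identical (log lines carry no timestamps).
    """
    inputs = load_inputs(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_lines: list[str] = [f"cobel {__version__} seed={config.seed} config_hash={config.config_hash()}"]
    for name, value in (
        ("scan", config.scan),
        ("call", config.call),
        ("great", config.great),
    ):
        log_lines.append(f"config.{name}: {dataclasses.asdict(value)}")

    result = screen(
        pwms=inputs["pwms"],
        genome=inputs["genome"],
        alignment=inputs["alignment"],
        tree=inputs["tree"],
        variants=inputs["variants"],
        outgroup=inputs["outgroup"],
        genes=inputs["genes"],
        chrom_lengths=inputs["chrom_lengths"],
        ontology=inputs["ontology"],
        scan_config=config.scan,
        call_config=config.call,
        great_config=config.great,
        seed=config.seed,
    )

    header = _output_header(config)
    write_conserved_bed(result.conserved_sites, out_dir / "conserved_sites.bed", header)
    write_cobel_bed(result.cobels, out_dir / "cobels.bed", header)
    with open(out_dir / "enrichment.tsv", "w") as out:
        for line in header.splitlines():
            out.write(f"#{line}\n")
        result.enrichment.to_csv(out, sep="\t", index=False, float_format="%.6g")
    top_payload = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "top_term": result.top_term,
        "summary": result.summary,
    }
    if result.top is not None:
        top_payload["top"] = {
            k: (v if isinstance(v, (str, int)) else float(v))
            for k, v in result.top.items()
        }
    (out_dir / "top_term.json").write_text(json.dumps(top_payload, indent=2, sort_keys=True) + "\n")
    for key, value in result.summary.items():
        log_lines.append(f"summary.{key}: {value}")
    (out_dir / "run.log").write_text("".join(l + "\n" for l in log_lines))
    return result


def run_cohort(
    cohort_tops: Mapping[str, str | None],
    target_sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Tabulate per-genome top terms and occurrence rates of query groups.

    ``cohort_tops`` maps genome id to its top term (or None);
    ``target_sets`` maps a query label to its term set.
    """
    from .null_models import occurrence_rate

    tops = list(cohort_tops.values())
    rows = [
        {
            "query": label,
            "n_genomes": len(tops),
            "occurrence_rate": occurrence_rate(terms, tops),
        }
        for label, terms in target_sets.items()
    ]
    return pd.DataFrame(rows)
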