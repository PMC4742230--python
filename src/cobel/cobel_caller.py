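"""Call conserved binding site eroding loci (CoBELs).

A CoBEL is a conserved binding site in which an individual's derived
variant alleles, substituted into the reference window, lower the MATCH
score by at least the erosion threshold (default 5%, relative).  Variants
are first polarized against an outgroup so that the reference base is the
likely ancestral state; overlapping eroded sites are merged into loci.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pysam
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .conservation_scan import ConservedSite
from .motif_model import (
    BASES,
    Pwm,
    AmbiguousBaseError,
    UnscoreableSiteError,
    match_score,
    reverse_complement,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclasses.dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant in 0-based reference coordinates."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    zygosity: str  # het | hom
    id: str | None = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("only single-nucleotide variants are supported")
        if self.zygosity not in ("het", "hom"):
            raise ValueError("zygosity must be het or hom")


@dataclasses.dataclass
class CallConfig:
    """Erosion-calling thresholds."""

    min_drop: float = 0.05
    drop_mode: str = "relative"  # relative | absolute
    outgroup_label: str = "outgroup"

    def __post_init__(self) -> None:
        if self.min_drop < 0:
            raise ValueError("min_drop must be >= 0")


@dataclasses.dataclass
class Cobel:
    """A merged locus of conserved binding sites eroded by an individual."""

    chrom: str
    start: int
    end: int
    site: ConservedSite  # representative: greatest affinity drop
    tf_name: str
    ancestral_score: float
    derived_score: float
    drop: float
    variants: tuple[Variant, ...]
    zygosity: str  # worst-case of contributing variants (hom > het)


# ---------------------------------------------------------------------------
# Variant loading
# ---------------------------------------------------------------------------


def load_variants(
    path: str | Path,
    format: str = "vcf",
    genome: Mapping[str, str] | None = None,
) -> list[Variant]:
    """Load SNVs from a VCF (v4.x) or UCSC pgSnp file.

    Multi-allelic records are split into one variant per alt allele; indels
    and records with ambiguous alleles are skipped (counts logged).  VCF
    positions are converted from 1-based to 0-based.  For multi-sample
    VCFs only the first sample's genotype is read; records without
    genotypes are treated as heterozygous.  pgSnp lacks a reference allele
    column, so ``genome`` is required to polarize observed alleles.
    """
    if format == "vcf":
        return _load_vcf(path)
    if format == "pgSnp":
        if genome is None:
            raise ValueError("pgSnp input requires a reference genome")
        return _load_pgsnp(path, genome)
    raise ValueError(f"unknown variant format {format!r}")


def _load_vcf(path: str | Path) -> list[Variant]:
    variants: list[Variant] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        sample = next(iter(vcf.header.samples), None)
        for rec in vcf:
            ref = (rec.ref or "").upper()
            if len(ref) != 1 or ref not in BASES:
                skipped += 1
                continue
            zygosity = "het"
            if sample is not None:
                gt = rec.samples[sample].get("GT")
                alleles = [a for a in (gt or ()) if a is not None]
                if alleles and len(set(alleles)) == 1 and alleles[0] != 0:
                    zygosity = "hom"
            any_kept = False
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(alt) != 1 or alt not in BASES or alt == ref:
                    continue
                variants.append(
                    Variant(
                        chrom=rec.chrom,
                        pos=rec.pos - 1,
                        ref_allele=ref,
                        alt_allele=alt,
                        zygosity=zygosity,
                        id=rec.id,
                    )
                )
                any_kept = True
            if not any_kept:
                skipped += 1
    if skipped:
        logger.info("load_variants: skipped %d non-SNV/malformed records", skipped)
    return variants


def _load_pgsnp(path: str | Path, genome: Mapping[str, str]) -> list[Variant]:
    variants: list[Variant] = []
    skipped = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        try:
            chrom, start, end, observed = fields[0], int(fields[1]), int(fields[2]), fields[3]
        except (IndexError, ValueError):
            skipped += 1
            continue
        if end - start != 1:
            skipped += 1
            continue
        alleles = [a.upper() for a in observed.split("/")]
        if any(len(a) != 1 or a not in BASES for a in alleles):
            skipped += 1
            continue
        ref = str(genome[chrom])[start].upper()
        alts = [a for a in alleles if a != ref]
        if not alts:
            skipped += 1
            continue
        zygosity = "het" if len(set(alleles)) > 1 else "hom"
        for alt in alts:
            variants.append(
                Variant(chrom=chrom, pos=start, ref_allele=ref, alt_allele=alt, zygosity=zygosity)
            )
    if skipped:
        logger.info("load_variants: skipped %d non-SNV/malformed pgSnp records", skipped)
    return variants


# ---------------------------------------------------------------------------
# Outgroup (ancestral proxy) track
# ---------------------------------------------------------------------------


class OutgroupTrack:
    """Per-position outgroup bases used to polarize ancestral vs derived.

    Backed either by a sparse (chrom, pos) -> base mapping (TSV) or by a
    FASTA aligned to reference coordinates.  Positions the outgroup does
    not cover return None.
    """

    def __init__(self, lookup: Callable[[str, int], str | None]):
        self._lookup = lookup

    def base_at(self, chrom: str, pos: int) -> str | None:
        return self._lookup(chrom, pos)

    @classmethod
    def from_mapping(cls, mapping: Mapping[tuple[str, int], str]) -> "OutgroupTrack":
        return cls(lambda chrom, pos: mapping.get((chrom, pos)))

    @classmethod
    def from_tsv(cls, path: str | Path, chrom: str | None = None) -> "OutgroupTrack":
        """Read a 3-column (chrom, pos, base) or, with ``chrom`` given, a
        2-column (pos, base) TSV; positions 0-based."""
        mapping: dict[tuple[str, int], str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 3:
                mapping[(fields[0], int(fields[1]))] = fields[2].upper()
            elif len(fields) == 2 and chrom is not None:
                mapping[(chrom, int(fields[0]))] = fields[1].upper()
            else:
                raise ValueError(f"cannot parse outgroup line {line!r}")
        return cls.from_mapping(mapping)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "OutgroupTrack":
        fasta = Fasta(str(path))

        def lookup(chrom: str, pos: int) -> str | None:
            if chrom not in fasta or pos >= len(fasta[chrom]):
                return None
            base = str(fasta[chrom][pos]).upper()
            return base if base in BASES else None

        return cls(lookup)


def ancestral_filter(
    variants: Iterable[Variant], outgroup: OutgroupTrack
) -> list[Variant]:
    """Keep variants whose reference allele is likely ancestral.

    A variant survives iff the outgroup has an orthologous base at its
    position, that base equals the reference allele, and the derived
    (alt) allele differs from it.  Unpolarizable variants are dropped.
    """
    kept = []
    for v in variants:
        base = outgroup.base_at(v.chrom, v.pos)
        if base is not None and base == v.ref_allele and v.alt_allele != base:
            kept.append(v)
    return kept


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------


def call_cobels(
    sites: Sequence[ConservedSite],
    variants: Sequence[Variant],
    pwms: Mapping[str, Pwm],
    genome: Mapping[str, str],
    config: CallConfig | None = None,
) -> list[Cobel]:
    """Intersect conserved sites with variants and call eroded loci.

    All of the individual's alt alleles inside a site's window are
    substituted jointly (one derived haplotype) before rescoring.  Sites
    whose affinity drop reaches ``min_drop`` become candidates; candidates
    overlapping in genomic coordinates (either strand) are merged into one
    locus represented by the site with the greatest drop (ties: higher
    ancestral score, then leftmost).
    """
    config = config or CallConfig()
    trees: dict[str, IntervalTree] = {}
    for v in variants:
        trees.setdefault(v.chrom, IntervalTree()).addi(v.pos, v.pos + 1, v)

    candidates: list[Cobel] = []
    for site in sites:
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        overlapping = sorted(
            (iv.data for iv in tree.overlap(site.start, site.end)),
            key=lambda v: v.pos,
        )
        if not overlapping:
            continue
        pwm = pwms[site.motif_id]
        ref_window = str(genome[site.chrom])[site.start : site.end].upper()
        window = list(ref_window)
        consistent = True
        for v in overlapping:
            if ref_window[v.pos - site.start] != v.ref_allele:
                logger.warning(
                    "variant %s:%d allele %s inconsistent with reference window; site %s skipped",
                    v.chrom,
                    v.pos,
                    v.ref_allele,
                    site.key,
                )
                consistent = False
                break
            window[v.pos - site.start] = v.alt_allele
        if not consistent:
            continue
        alt_window = "".join(window)
        oriented = pwm if site.strand == "+" else reverse_complement(pwm)
        try:
            s_ref = match_score(oriented, ref_window)
            s_alt = match_score(oriented, alt_window)
        except AmbiguousBaseError:
            continue
        if config.drop_mode == "absolute":
            drop = s_ref - s_alt
        else:
            if s_ref == 0.0:
                logger.warning("site %s unscoreable (reference score 0); skipped", site.key)
                continue
            drop = (s_ref - s_alt) / s_ref
        if drop < config.min_drop or s_alt >= s_ref:
            continue
        zygosity = "hom" if any(v.zygosity == "hom" for v in overlapping) else "het"
        candidates.append(
            Cobel(
                chrom=site.chrom,
                start=site.start,
                end=site.end,
                site=site,
                tf_name=pwm.tf_name,
                ancestral_score=s_ref,
                derived_score=s_alt,
                drop=drop,
                variants=tuple(overlapping),
                zygosity=zygosity,
            )
        )

    return _merge_overlapping(candidates)


def _merge_overlapping(candidates: list[Cobel]) -> list[Cobel]:
    candidates.sort(key=lambda c: (c.chrom, c.start, c.end))
    merged: list[list[Cobel]] = []
    for c in candidates:
        if merged and merged[-1][0].chrom == c.chrom and c.start < max(m.end for m in merged[-1]):
            merged[-1].append(c)
        else:
            merged.append([c])
    loci = []
    for group in merged:
        rep = min(group, key=lambda c: (-c.drop, -c.ancestral_score, c.start))
        variants = sorted(
            {v for c in group for v in c.variants}, key=lambda v: (v.chrom, v.pos, v.alt_allele)
        )
        loci.append(
            Cobel(
                chrom=group[0].chrom,
                start=min(c.start for c in group),
                end=max(c.end for c in group),
                site=rep.site,
                tf_name=rep.tf_name,
                ancestral_score=rep.ancestral_score,
                derived_score=rep.derived_score,
                drop=rep.drop,
                variants=tuple(variants),
                zygosity="hom" if any(c.zygosity == "hom" for c in group) else "het",
            )
        )
    loci.sort(key=lambda c: (c.chrom, c.start, c.end))
    return loci


def summarize_cobels(cobels: Sequence[Cobel]) -> dict:
    """Totals and a per-TF breakdown of a CoBEL call set."""
    per_tf: dict[str, int] = {}
    for c in cobels:
        per_tf[c.tf_name] = per_tf.get(c.tf_name, 0) + 1
    return {
        "total": len(cobels),
        "het": sum(1 for c in cobels if c.zygosity == "het"),
        "hom": sum(1 for c in cobels if c.zygosity == "hom"),
        "per_tf": dict(sorted(per_tf.items())),
    }


def write_cobel_bed(
    cobels: Iterable[Cobel], path: str | Path, header: str | None = None
) -> None:
    """BED6+ output: name=motif id, score=1000*drop (capped), strand, then
    tf, ancestral_score, derived_score, drop, variant ids."""
    with open(path, "w") as out:
        if header:
            for line in header.rstrip().splitlines():
                out.write(f"#{line}\n")
        for c in cobels:
            variant_ids = ",".join(
                v.id if v.id else f"{v.chrom}:{v.pos}{v.ref_allele}>{v.alt_allele}"
                for v in c.variants
            )
            out.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.start),
                        str(c.end),
                        c.site.motif_id,
                        str(min(1000, int(round(1000 * c.drop)))),
                        c.site.strand,
                        c.tf_name,
                        f"{c.ancestral_score:.6f}",
                        f"{c.derived_score:.6f}",
                        f"{c.drop:.6f}",
                        variant_ids,
                    ]
                )
                + "\n"
            )
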