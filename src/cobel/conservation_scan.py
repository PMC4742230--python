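"""Cross-species conserved binding site prediction.

Reference-genome motif hits are retained as *conserved sites* when enough
aligned species preserve the site (score above the scan cutoff in their
gap-free orthologous window), the preserving species span sufficient
neutral phylogenetic branch length, and the observed conservation beats a
motif-shuffle null within the same alignment block.
"""

from __future__ import annotations

import bisect
import dataclasses
import io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO, Phylo

from .motif_model import (
    Pwm,
    encode_sequence,
    reverse_complement,
    score_codes,
    shuffle_pwm_preserve_cpg,
)


@dataclasses.dataclass
class ScanConfig:
    """Thresholds of the conservation screen.

    min_species
        Minimum number of non-reference species preserving a site.
    min_branch_length
        Minimum total neutral branch length (substitutions/site) spanned by
        the preserving species together with the reference.
    max_sites_per_motif
        Cap on retained predictions per motif, best-ranked first.
    max_conservation_p
        Empirical conservation p-value cutoff.
    score_cutoff
        MATCH score a window must reach to count as a hit, for the
        reference scan and for species preservation alike.
    n_shuffles_for_p
        Motif shuffles per site for the conservation p-value.
    """

    min_species: int = 5
    min_branch_length: float = 2.0
    max_sites_per_motif: int = 5000
    max_conservation_p: float = 0.05
    score_cutoff: float = 0.9
    n_shuffles_for_p: int = 49

    def __post_init__(self) -> None:
        for name in (
            "min_species",
            "min_branch_length",
            "max_sites_per_motif",
            "max_conservation_p",
            "score_cutoff",
            "n_shuffles_for_p",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class PhyloTree:
    """A rooted phylogeny with branch lengths in substitutions per site.

    The reference species must appear exactly once as a leaf; its terminal
    branch joins the tree where orthology is anchored.
    """

    def __init__(self, tree, reference: str):
        self._tree = tree
        self.reference = reference
        leaves = [t.name for t in tree.get_terminals()]
        if leaves.count(reference) != 1:
            raise ValueError(f"reference {reference!r} must appear exactly once")
        for clade in tree.find_clades():
            if clade.branch_length is not None and clade.branch_length < 0:
                raise ValueError("negative branch length")
        self.species = sorted(l for l in leaves if l != reference)
        self._leaf_set = set(leaves)

    @classmethod
    def from_newick(cls, source: str | Path, reference: str) -> "PhyloTree":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        tree = Phylo.read(io.StringIO(text), "newick")
        return cls(tree, reference)

    def to_newick(self) -> str:
        buf = io.StringIO()
        Phylo.write(self._tree, buf, "newick")
        return buf.getvalue().strip()

    def distance(self, a: str, b: str) -> float:
        return float(self._tree.distance(a, b))

    def induced_branch_length(self, species: Iterable[str]) -> float:
        """Total branch length of the subtree spanning ``species`` + reference.

        An edge contributes iff selected leaves lie both below and outside
        it.  Empty species set yields 0 (only the reference is selected).
        Monotone non-decreasing as species are added.
        """
        selected = set(species)
        unknown = selected - self._leaf_set
        if unknown:
            raise KeyError(f"species not in tree: {sorted(unknown)}")
        selected.add(self.reference)
        total_sel = len(selected)
        length = 0.0
        for clade in self._tree.find_clades():
            if clade is self._tree.root:
                continue
            below = sum(1 for t in clade.get_terminals() if t.name in selected)
            if 0 < below < total_sel:
                length += clade.branch_length or 0.0
        return length


def preserved_branch_length(species: Iterable[str], tree: PhyloTree) -> float:
    """Branch length (subs/site) of the subtree induced by the preserving
    species plus the reference."""
    return tree.induced_branch_length(species)


@dataclasses.dataclass
class AlignmentBlock:
    """One reference-anchored alignment block.

    Rows are aligned strings of equal length; the reference row carries the
    block's coordinates (0-based half-open on the reference chromosome).
    """

    chrom: str
    start: int
    end: int
    ref_species: str
    rows: Mapping[str, str]  # species -> aligned sequence (incl. reference)

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows.values()}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in length")
        ref_row = self.rows[self.ref_species]
        ref_cols = np.frombuffer(ref_row.encode("ascii"), dtype=np.uint8) != ord("-")
        if int(ref_cols.sum()) != self.end - self.start:
            raise ValueError("reference row ungapped length != end - start")
        self._ref_cols = np.flatnonzero(ref_cols)
        self._codes_by_species: dict[str, np.ndarray] = {}

    def species_codes(self, species: str) -> np.ndarray:
        """Per-reference-position base codes for one species' row.

        Gaps and ambiguity codes both map to -1 (the species cannot be
        scored at such positions).
        """
        cached = self._codes_by_species.get(species)
        if cached is None:
            cached = encode_sequence(self.rows[species])[self._ref_cols]
            self._codes_by_species[species] = cached
        return cached

    @property
    def ref_seq(self) -> str:
        return self.rows[self.ref_species].replace("-", "")


class GenomeAlignment:
    """Per-chromosome collection of non-overlapping alignment blocks."""

    def __init__(self, blocks: Sequence[AlignmentBlock], ref_species: str):
        self.ref_species = ref_species
        self._by_chrom: dict[str, list[AlignmentBlock]] = {}
        for b in blocks:
            self._by_chrom.setdefault(b.chrom, []).append(b)
        for chrom_blocks in self._by_chrom.values():
            chrom_blocks.sort(key=lambda b: b.start)
        self._starts = {
            chrom: [b.start for b in bl] for chrom, bl in self._by_chrom.items()
        }

    @property
    def blocks(self) -> list[AlignmentBlock]:
        return [b for bl in self._by_chrom.values() for b in bl]

    def block_containing(self, chrom: str, start: int, end: int) -> AlignmentBlock | None:
        """The block fully containing [start, end), or None (sites spanning
        block boundaries are dropped)."""
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect.bisect_right(starts, start) - 1
        if i < 0:
            return None
        block = self._by_chrom[chrom][i]
        if block.start <= start and end <= block.end:
            return block
        return None


def read_maf(path: str | Path, ref_species: str) -> GenomeAlignment:
    """Read a reference-anchored MAF file.

    Row sources are ``species.chrom``; the reference species row anchors
    each block's coordinates.
    """
    blocks = []
    with open(path) as handle:
        for msa in AlignIO.parse(handle, "maf"):
            rows: dict[str, str] = {}
            chrom = start = end = None
            for rec in msa:
                species, _, src_chrom = rec.id.partition(".")
                rows[species] = str(rec.seq).upper()
                if species == ref_species:
                    chrom = src_chrom
                    start = int(rec.annotations["start"])
                    end = start + int(rec.annotations["size"])
            if chrom is None:
                raise ValueError(f"MAF block without reference row ({ref_species})")
            blocks.append(
                AlignmentBlock(
                    chrom=chrom, start=start, end=end, ref_species=ref_species, rows=rows
                )
            )
    return GenomeAlignment(blocks, ref_species)


def write_maf(alignment: GenomeAlignment, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("##maf version=1\n")
        for block in alignment.blocks:
            out.write("a\n")
            width = len(block.rows[block.ref_species])
            ordered = [block.ref_species] + sorted(
                s for s in block.rows if s != block.ref_species
            )
            for species in ordered:
                row = block.rows[species]
                size = len(row) - row.count("-")
                start = block.start if species == block.ref_species else 0
                out.write(
                    f"s {species}.{block.chrom} {start} {size} + {block.end} {row}\n"
                )
            out.write("\n")


@dataclasses.dataclass(frozen=True)
class ConservedSite:
    """A reference-genome motif hit preserved across species."""

    chrom: str
    start: int
    end: int
    strand: str
    motif_id: str
    score: float
    preserving_species: frozenset[str]
    branch_length: float
    conservation_p: float

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand, self.motif_id)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def _window_scores(pwm: Pwm, codes: np.ndarray) -> np.ndarray:
    """MATCH score of every length-L window of ``codes``; NaN where the
    window contains an invalid base."""
    L = len(pwm)
    if len(codes) < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    raw = np.zeros(len(windows))
    for i in range(L):
        raw += pwm._weights[i, windows[:, i]]
    span = pwm._max_raw - pwm._min_raw
    if span <= 0.0:
        scores = np.ones(len(windows))
    else:
        scores = (raw - pwm._min_raw) / span
    scores[~valid] = np.nan
    return scores


def scan_reference(
    pwm: Pwm, genome: Mapping[str, str], score_cutoff: float
) -> list[tuple[str, int, int, str, float]]:
    """Scan both strands of every chromosome for windows scoring at or
    above ``score_cutoff``.

    Returns (chrom, start, end, strand, score) tuples with 0-based
    half-open reference coordinates; minus-strand hits are reported at the
    coordinates of the forward-strand window they occupy.  Windows with
    ambiguity codes are skipped.
    """
    hits = []
    rc = reverse_complement(pwm)
    L = len(pwm)
    for chrom in sorted(genome):
        codes = encode_sequence(str(genome[chrom]).upper())
        for strand, oriented in (("+", pwm), ("-", rc)):
            scores = _window_scores(oriented, codes)
            for pos in np.flatnonzero(scores >= score_cutoff):
                hits.append((chrom, int(pos), int(pos) + L, strand, float(scores[pos])))
    hits.sort(key=lambda h: (h[0], h[1], h[3]))
    return hits


def species_preserving_site(
    site,
    block: AlignmentBlock,
    pwm: Pwm,
    score_cutoff: float,
) -> set[str]:
    """Non-reference species whose gap-free orthologous window preserves the
    site (MATCH score >= cutoff on the site's strand).

    ``site`` needs ``chrom``, ``start``, ``end`` and ``strand`` attributes.
    Species with a gap or ambiguity code inside the window are excluded.
    """
    if not (block.start <= site.start and site.end <= block.end):
        raise ValueError("site lies outside the alignment block")
    oriented = pwm if site.strand == "+" else reverse_complement(pwm)
    lo = site.start - block.start
    hi = site.end - block.start
    preserving = set()
    for species in block.rows:
        if species == block.ref_species:
            continue
        codes = block.species_codes(species)[lo:hi]
        if (codes < 0).any():
            continue
        if score_codes(oriented, codes) >= score_cutoff:
            preserving.add(species)
    return preserving


@dataclasses.dataclass(frozen=True)
class _SiteView:
    chrom: str
    start: int
    end: int
    strand: str


def conservation_pvalue(
    site,
    pwm: Pwm,
    alignment: GenomeAlignment | AlignmentBlock,
    tree: PhyloTree,
    config: ScanConfig,
    seed: int,
) -> float:
    """Empirical conservation p-value against CpG-preserving motif shuffles.

    Each shuffled motif is scanned within the site's own alignment block
    (controlling for regional conservation); a shuffle counts when its best
    hit attains a preserving branch length at least the real site's.
    p = (1 + count) / (1 + n_shuffles), in (0, 1].
    """
    if config.n_shuffles_for_p < 1:
        raise ValueError("n_shuffles_for_p must be >= 1")
    if isinstance(alignment, AlignmentBlock):
        block = alignment
    else:
        block = alignment.block_containing(site.chrom, site.start, site.end)
        if block is None:
            raise ValueError("site spans alignment block boundaries")
    real_species = species_preserving_site(site, block, pwm, config.score_cutoff)
    real_bl = preserved_branch_length(real_species, tree)
    codes = encode_sequence(block.ref_seq)
    count = 0
    for i in range(config.n_shuffles_for_p):
        shuffled = shuffle_pwm_preserve_cpg(pwm, seed + i)
        if _shuffle_beats(shuffled, block, codes, tree, config, real_bl):
            count += 1
    return (1 + count) / (1 + config.n_shuffles_for_p)


def _shuffle_beats(
    shuffled: Pwm,
    block: AlignmentBlock,
    ref_codes: np.ndarray,
    tree: PhyloTree,
    config: ScanConfig,
    real_bl: float,
) -> bool:
    if real_bl <= 0.0:
        return True  # a shuffle with no hit still ties a zero branch length
    L = len(shuffled)
    for oriented, strand in ((shuffled, "+"), (reverse_complement(shuffled), "-")):
        scores = _window_scores(oriented, ref_codes)
        positions = np.flatnonzero(scores >= config.score_cutoff)
        # best-scoring hits first: branch length tends to track score
        for pos in positions[np.argsort(-scores[positions], kind="stable")]:
            view = _SiteView(
                block.chrom, block.start + int(pos), block.start + int(pos) + L, strand
            )
            species = species_preserving_site(view, block, shuffled, config.score_cutoff)
            if preserved_branch_length(species, tree) >= real_bl:
                return True
    return False


def filter_conserved(
    hits: Iterable[ConservedSite], config: ScanConfig
) -> list[ConservedSite]:
    """Apply the three conservation filters and the per-motif cap.

    Survivors have >= min_species preserving species, branch length
    >= min_branch_length and conservation p <= max_conservation_p; within a
    motif at most ``max_sites_per_motif`` survive, ranked by conservation p
    ascending, score descending, coordinate ascending.  Idempotent.
    """
    by_motif: dict[str, list[ConservedSite]] = {}
    for h in hits:
        if (
            len(h.preserving_species) >= config.min_species
            and h.branch_length >= config.min_branch_length
            and h.conservation_p <= config.max_conservation_p
        ):
            by_motif.setdefault(h.motif_id, []).append(h)
    kept: list[ConservedSite] = []
    for motif_id in sorted(by_motif):
        ranked = sorted(
            by_motif[motif_id],
            key=lambda s: (s.conservation_p, -s.score, s.chrom, s.start, s.strand),
        )
        kept.extend(ranked[: config.max_sites_per_motif])
    kept.sort(key=lambda s: (s.chrom, s.start, s.end, s.strand, s.motif_id))
    return kept


def find_conserved_sites(
    pwms: Sequence[Pwm],
    genome: Mapping[str, str],
    alignment: GenomeAlignment,
    tree: PhyloTree,
    config: ScanConfig,
    seed: int,
) -> list[ConservedSite]:
    """Full conservation screen: scan, preservation, branch length,
    shuffle p-value, filters.

    Species-count and branch-length thresholds are applied before the
    (costly) shuffle p-value; sites failing them can never survive
    :func:`filter_conserved`, so the result is unchanged.
    """
    sites: list[ConservedSite] = []
    site_index = 0
    for pwm in sorted(pwms, key=lambda p: p.id):
        for chrom, start, end, strand, score in scan_reference(
            pwm, genome, config.score_cutoff
        ):
            block = alignment.block_containing(chrom, start, end)
            if block is None:
                continue
            view = _SiteView(chrom, start, end, strand)
            species = species_preserving_site(view, block, pwm, config.score_cutoff)
            if len(species) < config.min_species:
                continue
            bl = preserved_branch_length(species, tree)
            if bl < config.min_branch_length:
                continue
            p = conservation_pvalue(view, pwm, block, tree, config, seed + site_index)
            site_index += 1
            sites.append(
                ConservedSite(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    motif_id=pwm.id,
                    score=score,
                    preserving_species=frozenset(species),
                    branch_length=bl,
                    conservation_p=p,
                )
            )
    return filter_conserved(sites, config)


# ---------------------------------------------------------------------------
# BED6+3 output (name=motif id, score=1000*match, extras: n_species,
# branch_length, conservation_p)
# ---------------------------------------------------------------------------


def read_conserved_bed(path: str | Path) -> list[ConservedSite]:
    """Read sites written by :func:`write_conserved_bed`.

    The BED stores only the preserving-species *count*; placeholder species
    labels are synthesized to carry it (identities are not needed once the
    conservation filters have run).
    """
    sites = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        n_species = int(f[6])
        sites.append(
            ConservedSite(
                chrom=f[0],
                start=int(f[1]),
                end=int(f[2]),
                strand=f[5],
                motif_id=f[3],
                score=int(f[4]) / 1000.0,
                preserving_species=frozenset(f"s{i + 1}" for i in range(n_species)),
                branch_length=float(f[7]),
                conservation_p=float(f[8]),
            )
        )
    return sites


def write_conserved_bed(
    sites: Iterable[ConservedSite], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as out:
        if header:
            for line in header.rstrip().splitlines():
                out.write(f"#{line}\n")
        for s in sites:
            out.write(
                "\t".join(
                    [
                        s.chrom,
                        str(s.start),
                        str(s.end),
                        s.motif_id,
                        str(int(round(1000 * s.score))),
                        s.strand,
                        str(len(s.preserving_species)),
                        f"{s.branch_length:.4f}",
                        f"{s.conservation_p:.6g}",
                    ]
                )
                + "\n"
            )
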