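"""Region-based functional enrichment over gene regulatory domains.

Genes receive basal-plus-extension regulatory domains (5 kb upstream /
1 kb downstream of the TSS, extended to the nearest flanking basal domain
or at most 1 Mb).  A region set is tested per ontology term with a
binomial test over the genome fraction covered by the term's domain union
and a hypergeometric test over gene counts; both are FDR-corrected and a
top term must pass q <= 0.05 on both tests with binomial fold >= 2.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclasses.dataclass(frozen=True)
class GeneModel:
    symbol: str
    chrom: str
    tss: int  # 0-based
    strand: str


@dataclasses.dataclass(frozen=True)
class RegulatoryDomain:
    gene: str
    chrom: str
    basal_start: int
    basal_end: int
    start: int  # extended
    end: int


@dataclasses.dataclass
class GreatConfig:
    basal_up: int = 5000
    basal_down: int = 1000
    max_extension: int = 1_000_000
    max_q: float = 0.05
    min_fold: float = 2.0
    attribution: str = "midpoint"  # midpoint | overlap

    def __post_init__(self) -> None:
        if min(self.basal_up, self.basal_down, self.max_extension) <= 0:
            raise ValueError("domain sizes must be positive")


class Ontology:
    """Terms related by is_a edges (a DAG) with gene annotations.

    Annotations propagate upward: a gene annotated to a term is annotated
    to all its ancestors, so an ancestor's propagated gene set is a
    superset of each descendant's.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],  # (child, parent)
        annotations: Mapping[str, Iterable[str]],  # term -> genes (direct)
        names: Mapping[str, str] | None = None,
        namespaces: Mapping[str, str] | None = None,
    ):
        # stored parent -> child so descendants() walks downward
        graph = nx.DiGraph()
        for child, parent in edges:
            graph.add_edge(parent, child)
        for term in annotations:
            graph.add_node(term)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology is_a edges contain a cycle")
        self.graph = graph
        self.direct: dict[str, frozenset[str]] = {
            t: frozenset(genes) for t, genes in annotations.items()
        }
        self.names = dict(names or {})
        self.namespaces = dict(namespaces or {})
        self._propagated: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def namespace(self, term: str) -> str:
        return self.namespaces.get(term, "default")

    def descendants(self, term: str) -> set[str]:
        if term not in self.graph:
            raise KeyError(f"unknown term {term!r}")
        return set(nx.descendants(self.graph, term))

    def related_term_group(self, ancestor: str) -> set[str]:
        """The ancestor plus all of its descendant terms."""
        return {ancestor} | self.descendants(ancestor)

    def genes(self, term: str) -> frozenset[str]:
        """Propagated annotation: direct genes of the term and of every
        descendant."""
        cached = self._propagated.get(term)
        if cached is None:
            group = self.related_term_group(term)
            cached = frozenset(
                g for t in group for g in self.direct.get(t, ())
            )
            self._propagated[term] = cached
        return cached

    @property
    def annotated_genes(self) -> frozenset[str]:
        return frozenset(g for genes in self.direct.values() for g in genes)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(
        cls, edges_path: str | Path, annotations_path: str | Path
    ) -> "Ontology":
        """Read 2-column TSVs: edges (child, parent) and gene annotations
        (gene, term)."""
        edges_df = pd.read_csv(
            edges_path, sep="\t", header=None, names=["child", "parent"], comment="#"
        )
        ann_df = pd.read_csv(
            annotations_path, sep="\t", header=None, names=["gene", "term"], comment="#"
        )
        annotations: dict[str, set[str]] = {}
        for gene, term in ann_df.itertuples(index=False):
            annotations.setdefault(str(term), set()).add(str(gene))
        return cls(
            edges=[(str(c), str(p)) for c, p in edges_df.itertuples(index=False)],
            annotations=annotations,
        )

    @classmethod
    def from_obo(
        cls, obo_path: str | Path, annotations_path: str | Path
    ) -> "Ontology":
        """Read an OBO file (is_a edges only) plus a (gene, term) TSV."""
        import obonet

        graph = obonet.read_obo(str(obo_path))
        edges = [
            (child, parent)
            for child, parent, key in graph.edges(keys=True)
            if key == "is_a"
        ]
        names = {n: d.get("name", n) for n, d in graph.nodes(data=True)}
        namespaces = {
            n: d.get("namespace", "default") for n, d in graph.nodes(data=True)
        }
        ann_df = pd.read_csv(
            annotations_path, sep="\t", header=None, names=["gene", "term"], comment="#"
        )
        annotations: dict[str, set[str]] = {}
        for gene, term in ann_df.itertuples(index=False):
            annotations.setdefault(str(term), set()).add(str(gene))
        return cls(edges, annotations, names=names, namespaces=namespaces)


# ---------------------------------------------------------------------------
# Regulatory domains
# ---------------------------------------------------------------------------


def basal_plus_extension_domains(
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    config: GreatConfig | None = None,
) -> list[RegulatoryDomain]:
    """Assign each gene a basal-plus-extension regulatory domain.

    The basal domain is strand-aware: [tss - basal_up, tss + basal_down)
    on plus-strand genes, mirrored on minus-strand genes.  Each side then
    extends to the nearest flanking basal-domain boundary of another gene,
    or by at most ``max_extension``, whichever is closer; a neighbor's
    basal domain overlapping the gene's own prevents extension on that
    side.  Domains are clipped at chromosome ends.
    """
    config = config or GreatConfig()
    domains: list[RegulatoryDomain] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise ValueError(f"gene {g.symbol}: unknown chromosome {g.chrom}")
        if not (0 <= g.tss < chrom_lengths[g.chrom]):
            raise ValueError(f"gene {g.symbol}: TSS beyond chromosome end")
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom, chrom_genes in by_chrom.items():
        clen = chrom_lengths[chrom]
        basal = {}
        for g in chrom_genes:
            if g.strand == "-":
                b = (g.tss - config.basal_down + 1, g.tss + config.basal_up + 1)
            else:
                b = (g.tss - config.basal_up, g.tss + config.basal_down)
            basal[g.symbol] = (max(0, b[0]), min(clen, b[1]))
        for g in sorted(chrom_genes, key=lambda g: g.tss):
            b_start, b_end = basal[g.symbol]
            left = max(0, b_start - config.max_extension)
            right = min(clen, b_end + config.max_extension)
            for other in chrom_genes:
                if other.symbol == g.symbol:
                    continue
                o_start, o_end = basal[other.symbol]
                if o_end <= b_start:
                    left = max(left, o_end)
                elif o_start >= b_end:
                    right = min(right, o_start)
                else:  # neighbor basal overlaps ours: no extension that side
                    if o_start < b_start:
                        left = b_start
                    if o_end > b_end:
                        right = b_end
            domains.append(
                RegulatoryDomain(
                    gene=g.symbol,
                    chrom=chrom,
                    basal_start=b_start,
                    basal_end=b_end,
                    start=min(left, b_start),
                    end=max(right, b_end),
                )
            )
    domains.sort(key=lambda d: (d.chrom, d.start, d.gene))
    return domains


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for start, end in sorted(intervals):
        if last_end is None or start > last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


def term_genome_fraction(
    term: str,
    ontology: Ontology,
    domains: Sequence[RegulatoryDomain],
    genome_size: int,
) -> float:
    """Fraction of the genome covered by the union of extended domains of
    genes annotated (after propagation) to ``term``."""
    genes = ontology.genes(term)
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for d in domains:
        if d.gene in genes:
            per_chrom.setdefault(d.chrom, []).append((d.start, d.end))
    covered = sum(_union_length(ivs) for ivs in per_chrom.values())
    return covered / genome_size


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def binomial_region_test(n: int, k: int, p: float) -> tuple[float, float, float]:
    """Upper-tail binomial test of k of n regions in a domain set covering
    genome fraction p.

    Returns (p_value, fold, expected) with expected = n*p and
    fold = k / expected.  p == 0 with k > 0 yields p_value 0 and infinite
    fold.
    """
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    if k > n:
        raise ValueError("k cannot exceed n")
    expected = n * p
    if expected == 0:
        # p == 0 (empty domain union) or n == 0 (empty region set)
        return (1.0, 0.0, 0.0) if k == 0 else (0.0, math.inf, 0.0)
    p_value = float(stats.binom.sf(k - 1, n, p))
    fold = k / expected
    return p_value, fold, expected


def hypergeometric_gene_test(N: int, K: int, n_hit: int, k_hit: int) -> float:
    """Upper-tail hypergeometric probability of >= k_hit annotated genes
    among n_hit genes with regions, from N genes of which K are annotated."""
    if not (0 <= K <= N and 0 <= n_hit <= N and 0 <= k_hit <= min(K, n_hit)):
        raise ValueError("inconsistent hypergeometric counts")
    return float(stats.hypergeom.sf(k_hit - 1, N, K, n_hit))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (order-preserving with p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# The enrichment screen
# ---------------------------------------------------------------------------


def enrich(
    regions: Sequence[tuple[str, int, int]],
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    ontology: Ontology,
    config: GreatConfig | None = None,
) -> pd.DataFrame:
    """Per-term enrichment of a region set over regulatory domains.

    A region is attributed to every gene whose extended domain contains
    its midpoint (``attribution="overlap"`` uses any overlap instead).
    Terms with zero annotated genes are skipped; q-values are computed
    separately within each ontology namespace.
    """
    config = config or GreatConfig()
    domains = basal_plus_extension_domains(genes, chrom_lengths, config)
    genome_size = int(sum(chrom_lengths.values()))
    gene_symbols = sorted({g.symbol for g in genes})
    N = len(gene_symbols)

    trees: dict[str, IntervalTree] = {}
    for d in domains:
        trees.setdefault(d.chrom, IntervalTree()).addi(d.start, d.end, d.gene)

    n = len(regions)
    region_genes: list[frozenset[str]] = []
    for chrom, start, end in regions:
        tree = trees.get(chrom)
        if tree is None:
            region_genes.append(frozenset())
            continue
        if config.attribution == "overlap":
            hits = tree.overlap(start, end)
        else:
            mid = (start + end) // 2
            hits = tree.overlap(mid, mid + 1)
        region_genes.append(frozenset(iv.data for iv in hits))
    genes_with_region = frozenset(g for rg in region_genes for g in rg)

    rows = []
    for term in ontology.terms:
        annotated = ontology.genes(term) & set(gene_symbols)
        if not annotated:
            continue
        p = term_genome_fraction(term, ontology, domains, genome_size)
        k = sum(1 for rg in region_genes if rg & annotated)
        binom_p, fold, expected = binomial_region_test(n, k, p)
        K = len(annotated)
        n_hit = len(genes_with_region)
        k_hit = len(genes_with_region & annotated)
        hyper_p = hypergeometric_gene_test(N, K, n_hit, k_hit)
        rows.append(
            {
                "term": term,
                "name": ontology.names.get(term, term),
                "namespace": ontology.namespace(term),
                "n": n,
                "k": k,
                "p": p,
                "expected": expected,
                "fold": fold,
                "binom_p": binom_p,
                "N_genes": N,
                "K_annotated": K,
                "n_hit_genes": n_hit,
                "k_hit_annotated": k_hit,
                "hyper_p": hyper_p,
                "genes_hit": ",".join(sorted(genes_with_region & annotated)),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["binom_q"] = df["hyper_q"] = pd.Series(dtype=float)
        return df
    df["binom_q"] = np.nan
    df["hyper_q"] = np.nan
    for _, idx in df.groupby("namespace").groups.items():
        df.loc[idx, "binom_q"] = bh_fdr(df.loc[idx, "binom_p"].to_numpy())
        df.loc[idx, "hyper_q"] = bh_fdr(df.loc[idx, "hyper_p"].to_numpy())
    return df.sort_values(["binom_p", "term"], kind="stable").reset_index(drop=True)


def rank_and_select_top(
    results: pd.DataFrame, config: GreatConfig | None = None
) -> pd.Series | None:
    """The top term passing the default filters, or None.

    Candidates need binom_q <= max_q, hyper_q <= max_q and fold >= min_fold;
    the winner has the smallest binomial p (ties: larger fold, then
    lexicographic term id).
    """
    config = config or GreatConfig()
    if results.empty:
        return None
    passing = results[
        (results["binom_q"] <= config.max_q)
        & (results["hyper_q"] <= config.max_q)
        & (results["fold"] >= config.min_fold)
    ]
    if passing.empty:
        return None
    ranked = passing.sort_values(
        ["binom_p", "fold", "term"], ascending=[True, False, True], kind="stable"
    )
    return ranked.iloc[0]


def related_term_group(ancestor: str, ontology: Ontology) -> set[str]:
    """The ancestor term and all of its descendants (set semantics)."""
    return ontology.related_term_group(ancestor)


# ---------------------------------------------------------------------------
# Gene model I/O
# ---------------------------------------------------------------------------


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    """Read genes from a TSV with columns symbol, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        GeneModel(str(r.symbol), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples(index=False)
    ]


def write_genes_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.symbol, g.chrom, g.tss, g.strand) for g in genes],
        columns=["symbol", "chrom", "tss", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes
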