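"""Permutation null models for the erosion screen.

Matched control sets replace every eroded locus with a random conserved
site of the same motif, identical binding affinity (score rounded to two
decimals) and a conservation p-value in the same order of magnitude; the
empirical p-value of a top enrichment is the fraction of control sets
recovering it.  Cohort utilities compute occurrence rates of a term across
many genomes and allele frequencies of eroding variants.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .cobel_caller import Cobel
from .conservation_scan import ConservedSite

logger = logging.getLogger(__name__)

PoolKey = tuple[str, float, int]


@dataclasses.dataclass
class EmpiricalResult:
    """An empirical permutation p-value: p = n_hits / n_shuffles."""

    n_shuffles: int
    n_hits: int

    @property
    def p(self) -> float:
        return self.n_hits / self.n_shuffles


def site_pool_key(site: ConservedSite) -> PoolKey:
    """Matching key: (motif id, score to 2 decimals, conservation-p decade)."""
    return (site.motif_id, round(site.score, 2), math.floor(math.log10(site.conservation_p)))


def build_control_pool(
    sites: Iterable[ConservedSite],
) -> dict[PoolKey, list[ConservedSite]]:
    """Index the conserved-site universe by matching key.

    Every site lands in exactly one bucket (the buckets partition the
    input), so any site is retrievable under its own key.
    """
    pool: dict[PoolKey, list[ConservedSite]] = {}
    for site in sites:
        pool.setdefault(site_pool_key(site), []).append(site)
    return pool


def sample_matched_control_set(
    cobels: Sequence[Cobel],
    pool: Mapping[PoolKey, Sequence[ConservedSite]],
    seed: int,
) -> list[ConservedSite]:
    """One size-matched control set: per locus a random conserved site
    with the same motif, affinity bucket and conservation-p decade.

    The locus's own site is excluded whenever alternatives exist.  An
    empty or singleton bucket falls back to the same-motif site of nearest
    score (logged).
    """
    rng = np.random.default_rng(seed)
    controls: list[ConservedSite] = []
    for cobel in cobels:
        site = cobel.site
        bucket = pool.get(site_pool_key(site), ())
        candidates = [s for s in bucket if s.key != site.key]
        if candidates:
            controls.append(candidates[rng.integers(len(candidates))])
            continue
        if bucket:
            logger.info(
                "control pool: bucket for %s holds only the locus itself", site.key
            )
            controls.append(site)
            continue
        same_motif = [
            s
            for sites in pool.values()
            for s in sites
            if s.motif_id == site.motif_id and s.key != site.key
        ]
        if not same_motif:
            logger.info("control pool: no alternative site for motif %s", site.motif_id)
            controls.append(site)
            continue
        logger.info(
            "control pool: empty bucket for %s, falling back to nearest score", site.key
        )
        best = min(abs(s.score - site.score) for s in same_motif)
        nearest = [s for s in same_motif if abs(s.score - site.score) == best]
        controls.append(nearest[rng.integers(len(nearest))])
    return controls


def top_terms_for_controls(
    cobels: Sequence[Cobel],
    pool: Mapping[PoolKey, Sequence[ConservedSite]],
    top_fn: Callable[[Sequence[tuple[str, int, int]]], str | None],
    n_shuffles: int,
    seed: int,
) -> list[str | None]:
    """Top enrichment of each of ``n_shuffles`` matched control sets.

    ``top_fn`` maps a region list to the top passing term (or None).
    Shuffle i uses seed ``seed + i``.
    """
    tops: list[str | None] = []
    for i in range(n_shuffles):
        controls = sample_matched_control_set(cobels, pool, seed + i)
        regions = [(s.chrom, s.start, s.end) for s in controls]
        tops.append(top_fn(regions))
    return tops


def empirical_top_term_p(
    observed_top: str,
    shuffle_tops: Sequence[str | None],
    target_set: set[str],
) -> EmpiricalResult:
    """Fraction of shuffles whose top term falls in ``target_set``.

    A shuffle with no passing term (None) is never a hit but stays in the
    denominator.
    """
    if observed_top not in target_set:
        raise ValueError("observed top term must belong to the target set")
    n_hits = sum(1 for t in shuffle_tops if t is not None and t in target_set)
    return EmpiricalResult(n_shuffles=len(shuffle_tops), n_hits=n_hits)


def combine_pvalues_product(ps: Sequence[float]) -> float:
    """Combine independent empirical p-values by multiplication."""
    if len(ps) == 0:
        raise ValueError("cannot combine an empty list of p-values")
    if any(not (0 < p <= 1) for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    return float(math.prod(ps))


def occurrence_rate(
    target_set: set[str], cohort_tops: Sequence[str | None]
) -> float:
    """Fraction of cohort genomes whose top term lies in ``target_set``."""
    if len(cohort_tops) == 0:
        raise ValueError("cohort is empty")
    return sum(1 for t in cohort_tops if t is not None and t in target_set) / len(
        cohort_tops
    )


def cohort_allele_frequency(
    cobel: Cobel,
    cohort_variant_sets: Sequence[set[tuple[str, int, str]]],
) -> float:
    """Fraction of cohort genomes carrying any of the locus's derived
    alleles, each keyed as (chrom, pos, alt allele)."""
    if len(cohort_variant_sets) == 0:
        raise ValueError("cohort is empty")
    alleles = {(v.chrom, v.pos, v.alt_allele) for v in cobel.variants}
    carriers = sum(1 for genome in cohort_variant_sets if alleles & genome)
    return carriers / len(cohort_variant_sets)


def filter_by_frequency(
    cobels: Sequence[Cobel],
    frequencies: Sequence[float],
    max_freq: float,
) -> list[Cobel]:
    """Keep loci whose cohort allele frequency is at most ``max_freq``."""
    if len(cobels) != len(frequencies):
        raise ValueError("one frequency per locus required")
    return [c for c, f in zip(cobels, frequencies) if f <= max_freq]
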