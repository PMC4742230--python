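import numpy as np
import pytest

from cobel.conservation_scan import (
    AlignmentBlock,
    ConservedSite,
    GenomeAlignment,
    PhyloTree,
    ScanConfig,
    conservation_pvalue,
    filter_conserved,
    preserved_branch_length,
    read_conserved_bed,
    read_maf,
    scan_reference,
    species_preserving_site,
    write_conserved_bed,
    write_maf,
)
from cobel.motif_model import Pwm, match_score
from conftest import random_pwm

NEWICK = "((A:0.5,B:0.5):0.5,C:1.0,R:0.0);"


def sharp_pwm(consensus, freq=0.88, motif_id="m"):
    off = (1 - freq) / 3
    rows = []
    for b in consensus:
        row = [off] * 4
        row["ACGT".index(b)] = freq
        rows.append(row)
    return Pwm(id=motif_id, tf_name=motif_id, freqs=np.array(rows), pseudocount=0.0)


class TestBranchLength:
    def test_hand_computed_subtrees(self):
        tree = PhyloTree.from_newick(NEWICK, "R")
        assert preserved_branch_length(set(), tree) == pytest.approx(0.0)
        assert preserved_branch_length({"A", "B"}, tree) == pytest.approx(1.5)
        assert preserved_branch_length({"A", "B", "C"}, tree) == pytest.approx(2.5)
        assert preserved_branch_length({"C"}, tree) == pytest.approx(1.0)

    def test_unknown_species_raises(self):
        tree = PhyloTree.from_newick(NEWICK, "R")
        with pytest.raises(KeyError):
            preserved_branch_length({"Z"}, tree)

    def test_monotone_in_species(self, rng):
        tree = PhyloTree.from_newick(
            "(((A:0.2,B:0.4):0.1,(C:0.3,D:0.1):0.5):0.2,E:0.7,R:0.0);", "R"
        )
        species = list("ABCDE")
        for _ in range(30):
            subset = {s for s in species if rng.random() < 0.5}
            extra = str(rng.choice(species))
            small = preserved_branch_length(subset, tree)
            big = preserved_branch_length(subset | {extra}, tree)
            assert big >= small - 1e-12

    def test_reference_must_be_unique(self):
        with pytest.raises(ValueError):
            PhyloTree.from_newick("((A:1,R:1):1,R:0.0);", "R")


def make_block(ref_seq, species_rows, start=0, chrom="chr1"):
    rows = {"R": ref_seq}
    rows.update(species_rows)
    end = start + len(ref_seq) - ref_seq.count("-")
    return AlignmentBlock(chrom=chrom, start=start, end=end, ref_species="R", rows=rows)


class TestScanReference:
    def test_planted_consensus_found_once(self, rng):
        pwm = sharp_pwm("ACGTACTG")
        background = "".join(rng.choice(list("ACGT"), size=300))
        seq = background[:100] + "ACGTACTG" + background[100:]
        hits = [
            h for h in scan_reference(pwm, {"chr1": seq}, 0.95) if h[3] == "+"
        ]
        assert len(hits) == 1
        assert hits[0][:4] == ("chr1", 100, 108, "+")
        assert hits[0][4] == pytest.approx(1.0)

    def test_cutoff_zero_counts_all_windows(self):
        pwm = sharp_pwm("ACG")
        seq = "ACGTACGTAC"  # M=10, L=3 -> 8 windows per strand
        hits = scan_reference(pwm, {"chr1": seq}, 0.0)
        assert len(hits) == 2 * (len(seq) - 3 + 1)

    def test_matches_brute_force_oracle(self, rng):
        from cobel.motif_model import reverse_complement

        pwm = random_pwm(rng, 6)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        cutoff = 0.9
        hits = set(scan_reference(pwm, {"chr1": seq}, cutoff))
        expected = set()
        rc = reverse_complement(pwm)
        for i in range(len(seq) - 5):
            window = seq[i : i + 6]
            for strand, oriented in (("+", pwm), ("-", rc)):
                s = match_score(oriented, window)
                if s >= cutoff:
                    expected.add(("chr1", i, i + 6, strand, s))
        assert {h[:4] for h in hits} == {h[:4] for h in expected}

    def test_empty_genome(self):
        assert scan_reference(sharp_pwm("ACGT"), {}, 0.5) == []

    def test_ambiguous_windows_skipped(self):
        pwm = sharp_pwm("AAAA")
        hits = scan_reference(pwm, {"chr1": "AANAAAA"}, 0.99)
        assert all(start >= 3 for _, start, _, _, _ in hits)


class TestSpeciesPreservation:
    def test_identical_rows_all_preserve(self):
        pwm = sharp_pwm("ACGTAC")
        block = make_block("ACGTAC", {f"s{i}": "ACGTAC" for i in range(5)})
        site = ConservedSite("chr1", 0, 6, "+", "m", 1.0, frozenset(), 0, 1)
        assert species_preserving_site(site, block, pwm, 0.9) == {
            f"s{i}" for i in range(5)
        }

    def test_gap_excludes_species(self):
        pwm = sharp_pwm("ACG")
        block = make_block("AC-GT", {"s1": "ACAGT", "s2": "AC--T"})
        # reference columns 0,1,3,4 -> ref positions 0..3 spell ACGT
        site = ConservedSite("chr1", 0, 3, "+", "m", 1.0, frozenset(), 0, 1)
        preserving = species_preserving_site(site, block, pwm, 0.9)
        assert "s2" not in preserving

    def test_substitutions_destroy_score(self):
        pwm = sharp_pwm("ACGTACGT")
        good = "ACGTACGT"
        bad = "ACGTATTT"  # 3 mismatches
        block = make_block(
            good,
            {"s1": good, "s2": good, "s3": good, "s4": good, "s5": bad, "s6": bad},
        )
        site = ConservedSite("chr1", 0, 8, "+", "m", 1.0, frozenset(), 0, 1)
        assert species_preserving_site(site, block, pwm, 0.9) == {"s1", "s2", "s3", "s4"}

    def test_site_outside_block_raises(self):
        pwm = sharp_pwm("ACG")
        block = make_block("ACGTT", {"s1": "ACGTT"})
        site = ConservedSite("chr1", 4, 7, "+", "m", 1.0, frozenset(), 0, 1)
        with pytest.raises(ValueError):
            species_preserving_site(site, block, pwm, 0.9)


class TestConservationPvalue:
    def _tree(self, n):
        leaves = ",".join(f"s{i}:0.4" for i in range(n))
        return PhyloTree.from_newick(f"({leaves},R:0.0);", "R")

    def test_unpreserved_site_p_one(self, rng):
        pwm = sharp_pwm("ACGTACGT")
        ref = "ACGTACGT" + "".join(rng.choice(list("ACGT"), size=92))
        rows = {
            f"s{i}": "".join(rng.choice(list("ACGT"), size=100)) for i in range(4)
        }
        block = make_block(ref, rows)
        site = ConservedSite("chr1", 0, 8, "+", "m", 1.0, frozenset(), 0, 1)
        config = ScanConfig(n_shuffles_for_p=19)
        p = conservation_pvalue(site, pwm, block, self._tree(4), config, seed=0)
        assert p == pytest.approx(1.0)

    def test_single_column_motif_p_one(self):
        pwm = sharp_pwm("A")
        block = make_block("AAAA", {"s0": "AAAA", "s1": "AAAA"})
        site = ConservedSite("chr1", 0, 1, "+", "m", 1.0, frozenset(), 0, 1)
        config = ScanConfig(n_shuffles_for_p=9, min_species=1)
        p = conservation_pvalue(site, pwm, block, self._tree(2), config, seed=0)
        assert p == pytest.approx(1.0)

    def test_planted_deep_conservation_is_significant(self):
        """A perfectly conserved planted 8-mer in an otherwise random
        alignment earns p <= 0.05 for nearly all seeds."""
        tree = self._tree(6)
        config = ScanConfig(n_shuffles_for_p=49)
        n_sig = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            pwm = sharp_pwm("".join(rng.choice(list("ACGT"), size=8)))
            ref = "".join(rng.choice(list("ACGT"), size=400))
            start = 200
            ref = ref[:start] + pwm.consensus + ref[start + 8 :]
            rows = {}
            for i in range(6):
                mutate = rng.random(400) < 0.3
                row = np.array(list(ref))
                idx = np.flatnonzero(mutate)
                row[idx] = rng.choice(list("ACGT"), size=len(idx))
                row[start : start + 8] = list(pwm.consensus)
                rows[f"s{i}"] = "".join(row)
            block = make_block(ref, rows)
            site = ConservedSite("chr1", start, start + 8, "+", "m", 1.0, frozenset(), 0, 1)
            p = conservation_pvalue(site, pwm, block, tree, config, seed=seed)
            n_sig += p <= 0.05
        assert n_sig >= int(0.9 * n_seeds)

    def test_deterministic_given_seed(self, rng):
        pwm = sharp_pwm("ACGTTGCA")
        ref = "".join(rng.choice(list("ACGT"), size=200))
        ref = ref[:50] + pwm.consensus + ref[58:]
        rows = {f"s{i}": ref for i in range(4)}
        block = make_block(ref, rows)
        site = ConservedSite("chr1", 50, 58, "+", "m", 1.0, frozenset(), 0, 1)
        config = ScanConfig(n_shuffles_for_p=19)
        tree = self._tree(4)
        assert conservation_pvalue(
            site, pwm, block, tree, config, 5
        ) == conservation_pvalue(site, pwm, block, tree, config, 5)


def make_site(motif="m", n_species=6, bl=3.0, p=0.01, start=0, score=1.0):
    return ConservedSite(
        chrom="chr1",
        start=start,
        end=start + 8,
        strand="+",
        motif_id=motif,
        score=score,
        preserving_species=frozenset(f"s{i}" for i in range(n_species)),
        branch_length=bl,
        conservation_p=p,
    )


class TestFilterConserved:
    def test_species_threshold(self):
        config = ScanConfig()
        assert filter_conserved([make_site(n_species=4)], config) == []
        assert len(filter_conserved([make_site(n_species=5)], config)) == 1

    def test_cap_keeps_best_ranked(self):
        config = ScanConfig(max_sites_per_motif=3)
        sites = [make_site(start=i * 10, p=0.01 * (i + 1)) for i in range(5)]
        kept = filter_conserved(sites, config)
        assert {s.start for s in kept} == {0, 10, 20}  # smallest conservation p

    def test_matches_brute_force_on_mixed_set(self):
        config = ScanConfig(max_sites_per_motif=5000)
        sites = [
            make_site(n_species=4, bl=3.0, p=0.01, start=0),
            make_site(n_species=6, bl=1.0, p=0.01, start=10),
            make_site(n_species=6, bl=3.0, p=0.2, start=20),
            make_site(n_species=6, bl=3.0, p=0.01, start=30),
            make_site(n_species=5, bl=2.0, p=0.05, start=40),
            make_site(n_species=9, bl=9.0, p=0.001, start=50),
            make_site(n_species=5, bl=1.99, p=0.001, start=60),
            make_site(n_species=7, bl=2.5, p=0.049, start=70),
            make_site(n_species=4, bl=9.0, p=0.001, start=80),
            make_site(n_species=8, bl=4.0, p=0.06, start=90),
        ]
        expected = {
            s.start
            for s in sites
            if len(s.preserving_species) >= 5
            and s.branch_length >= 2.0
            and s.conservation_p <= 0.05
        }
        kept = filter_conserved(sites, config)
        assert {s.start for s in kept} == expected

    def test_idempotent(self):
        config = ScanConfig(max_sites_per_motif=3)
        sites = [make_site(start=i * 10, p=0.01 * (i + 1)) for i in range(5)]
        once = filter_conserved(sites, config)
        assert filter_conserved(once, config) == once


class TestAlignmentIO:
    def test_maf_round_trip(self, tmp_path, signal_manifest):
        path = tmp_path / "slice.maf"
        blocks = signal_manifest.alignment.blocks[:3]
        write_maf(GenomeAlignment(blocks, "ref"), path)
        back = read_maf(path, "ref")
        assert len(back.blocks) == 3
        for a, b in zip(blocks, back.blocks):
            assert (a.chrom, a.start, a.end) == (b.chrom, b.start, b.end)
            assert a.rows == b.rows

    def test_block_containing(self, signal_manifest):
        aln = signal_manifest.alignment
        block = aln.blocks[1]
        assert aln.block_containing(block.chrom, block.start + 5, block.start + 13) is block
        # spanning a boundary -> dropped
        assert aln.block_containing(block.chrom, block.start - 2, block.start + 6) is None

    def test_conserved_bed_round_trip(self, tmp_path):
        sites = [make_site(start=i * 20, p=0.01) for i in range(3)]
        path = tmp_path / "sites.bed"
        write_conserved_bed(sites, path, header="test")
        back = read_conserved_bed(path)
        assert [(s.chrom, s.start, s.end, s.strand, s.motif_id) for s in back] == [
            (s.chrom, s.start, s.end, s.strand, s.motif_id) for s in sites
        ]
        assert all(len(b.preserving_species) == 6 for b in back)


class TestRescoreInvariant:
    def test_conserved_sites_rescore_to_stored_score(self, signal_manifest, signal_result):
        from cobel.motif_model import reverse_complement

        pwms = {p.id: p for p in signal_manifest.pwms}
        genome = signal_manifest.genome
        for site in signal_result.conserved_sites[:50]:
            pwm = pwms[site.motif_id]
            oriented = pwm if site.strand == "+" else reverse_complement(pwm)
            window = genome[site.chrom][site.start : site.end]
            assert match_score(oriented, window) == pytest.approx(site.score)
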