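"""Primer enumeration, Tm model and assay design."""

import dataclasses

import numpy as np
import pytest

from methassay.primer_design import (
    DesignConstraints,
    NoIslandError,
    design_assay,
    enumerate_candidates,
    melting_temperature,
)
from methassay.seqcore import GenomicLocus, bisulfite_convert, find_cpg_islands
from methassay.synthfix import LocusSpec, make_locus

from .conftest import random_dna
from .oracles import brute_force_candidates, hand_summed_tm

from . import pairing_oracle


class TestMeltingTemperature:
    def test_matches_hand_summed_nn_table(self):
        for seq in ("ACGTACGTACGTACGT", "GATTACAGATTACA", "CCGGTTAACCGGTTAA"):
            assert melting_temperature(seq) == pytest.approx(hand_summed_tm(seq), abs=1e-6)

    def test_gc_raises_stability(self):
        assert melting_temperature("A" * 18) < melting_temperature("GC" * 9)

    def test_too_short_or_ambiguous(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTAC")
        with pytest.raises(ValueError):
            melting_temperature("ACGTNACGTNACGT")


class TestEnumerateCandidates:
    def test_all_t_template_yields_nothing(self):
        template = bisulfite_convert("T" * 300)
        assert enumerate_candidates(template, "+") == []

    def test_invalid_length_bounds(self):
        with pytest.raises(ValueError):
            DesignConstraints(primer_len_min=25, primer_len_max=20)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_exhaustive_oracle(self, strand):
        rng = np.random.default_rng(5)
        region = random_dna(rng, 220, gc=0.55)
        template = bisulfite_convert(region)
        constraints = DesignConstraints()
        got = [
            (p.start, p.end, p.strand, p.sequence)
            for p in enumerate_candidates(template, strand, constraints)
        ]
        expected = brute_force_candidates(
            template.converted, template.cpg_positions, strand, constraints
        )
        assert sorted(got) == expected

    def test_zero_internal_cpg_cap_is_honored(self):
        rng = np.random.default_rng(3)
        region = random_dna(rng, 400, gc=0.6)
        template = bisulfite_convert(region)
        constraints = DesignConstraints(max_internal_cpg=0)
        cpgs = template.cpg_positions
        for p in enumerate_candidates(template, "+", constraints):
            assert not any(p.start <= c < p.end for c in cpgs)


class TestDesignAssay:
    def test_published_bounds_hold_on_synthetic_locus(self, locus42, islands42, designs42):
        """Every emitted design keeps the product in 120-350 bp with primer
        Tm in 53-62 degC (the published assay guidelines)."""
        assert len(designs42) > 0
        for d in designs42:
            assert 120 <= d.amplicon_length <= 350
            for p in (*d.inner_pair, *d.outer_pair):
                assert 53.0 <= p.tm <= 62.0

    def test_no_island_is_an_error(self):
        rng = np.random.default_rng(9)
        seq = random_dna(rng, 1000, gc=0.40)
        # deplete CpGs so no island can be detected
        seq = seq.replace("CG", "CA")
        locus = GenomicLocus(name="flat", sequence=seq, tss=500)
        assert find_cpg_islands(seq) == []
        with pytest.raises(NoIslandError, match="no CGI"):
            design_assay(locus, [])

    def test_top_design_matches_exhaustive_pairing_oracle(self, small_locus):
        constraints = DesignConstraints()
        islands = find_cpg_islands(small_locus.sequence)
        result = design_assay(small_locus, islands, constraints)
        assert result.designs, "fixture must admit at least one design"
        best = pairing_oracle.exhaustive_best_design(small_locus, islands[0], constraints)
        top = result.designs[0]
        assert best is not None
        assert (top.amplicon_start, top.amplicon_end) == best[:2]
        assert top.score == pytest.approx(best[2])

    def test_nesting_structure(self, locus42, islands42):
        semi = design_assay(locus42, islands42, DesignConstraints(nesting="semi_nested"))
        nested = design_assay(locus42, islands42, DesignConstraints(nesting="nested"))
        for d in semi.designs[:25]:
            inner = {(p.start, p.end, p.strand) for p in d.inner_pair}
            outer = {(p.start, p.end, p.strand) for p in d.outer_pair}
            assert len(inner & outer) == 1
            assert d.outer_start <= d.amplicon_start and d.amplicon_end <= d.outer_end
        for d in nested.designs[:25]:
            inner = {(p.start, p.end, p.strand) for p in d.inner_pair}
            outer = {(p.start, p.end, p.strand) for p in d.outer_pair}
            assert not (inner & outer)
            assert d.outer_start < d.amplicon_start and d.amplicon_end < d.outer_end
            assert d.outer_end - d.outer_start <= 600

    def test_deterministic(self, locus42, islands42, designs42):
        again = design_assay(locus42, islands42, DesignConstraints())
        key = lambda d: (d.amplicon_start, d.amplicon_end, d.score)
        assert [key(d) for d in designs42.designs] == [key(d) for d in again.designs]

    def test_tightening_constraints_never_adds_designs(self, locus42, islands42, designs42):
        baseline = {
            (d.amplicon_start, d.amplicon_end) for d in designs42.designs
        }
        tighter = design_assay(
            locus42,
            islands42,
            DesignConstraints(tm_min=54.0, tm_max=61.0, product_len_min=150, product_len_max=300),
        )
        assert {
            (d.amplicon_start, d.amplicon_end) for d in tighter.designs
        } <= baseline

    def test_hard_constraints_recheck_on_seeded_loci(self):
        """Independent re-check of every hard constraint on the designs of
        many seeded loci."""
        from methassay.cobra import DEFAULT_ENZYMES, find_informative_sites

        constraints = DesignConstraints()
        n_checked = 0
        for seed in range(12):
            locus = make_locus(LocusSpec(seed=seed, total_length=1500, island_length=400))
            islands = find_cpg_islands(locus.sequence)
            result = design_assay(locus, islands, constraints)
            island = result.island
            for d in result.designs[:20]:
                n_checked += 1
                product = d.amplicon_end - d.amplicon_start
                assert constraints.product_len_min <= product <= constraints.product_len_max
                f, r = d.inner_pair
                assert abs(f.tm - r.tm) <= constraints.tm_pair_max_diff
                for p in (*d.inner_pair, *d.outer_pair):
                    assert constraints.tm_min <= p.tm <= constraints.tm_max
                    assert p.n_internal_cpg <= constraints.max_internal_cpg
                assert d.amplicon_start >= locus.tss - constraints.tss_window
                assert d.amplicon_end <= locus.tss + constraints.tss_window
                overlap = min(d.amplicon_end, island.end) - max(d.amplicon_start, island.start)
                assert overlap >= constraints.min_island_overlap * product
                amp = locus.sequence[d.amplicon_start : d.amplicon_end]
                n_sites = sum(
                    len(find_informative_sites(amp, e)) for e in DEFAULT_ENZYMES
                )
                assert n_sites >= constraints.min_informative_sites
        assert n_checked > 100
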