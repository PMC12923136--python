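"""oPool design: segmentation, codebook, pairing, oligo assembly."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodedms.design import (
    BSAI_MODULE,
    PBS_I7,
    SPACER_OFFSETS,
    BarcodePair,
    CodebookWarning,
    CodingSequence,
    assemble_barcode_template,
    build_full_design,
    build_opool,
    count_bsai_sites,
    enumerate_nnk,
    fragment_residue_range,
    generate_codebook,
    pair_barcodes,
    segment_cds,
    translate_codon,
    validate_design,
)
from barcodedms.simulate import random_cds


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class TestSegmentation:
    def test_full_gene_tiling(self, cds_full, contexts):
        up, down = contexts
        frags = segment_cds(cds_full, 25, upstream_context=up, downstream_context=down)
        assert len(frags) == 43
        assert all(f.nt_length == 75 for f in frags[:-1])
        assert frags[-1].nt_length == 54
        # tiling conservation: disjoint, exhaustive, ordered
        assert sum(f.nt_length for f in frags) == len(cds_full.seq)
        covered = list(
            itertools.chain.from_iterable(f.positions for f in frags)
        )
        assert covered == list(range(1, cds_full.codon_count + 1))
        assert "".join(f.fragment_seq for f in frags) == cds_full.seq

    def test_single_tile_cds(self, contexts):
        up, down = contexts
        cds = random_cds(25, np.random.default_rng(0))
        frags = segment_cds(cds, 25, upstream_context=up, downstream_context=down)
        assert len(frags) == 1
        assert (frags[0].codon_start, frags[0].codon_end) == (1, 25)

    def test_80_codon_binning_matches_enumeration(self, contexts):
        up, down = contexts
        cds = random_cds(80, np.random.default_rng(1))
        frags = segment_cds(cds, 25, upstream_context=up, downstream_context=down)
        # brute force: accumulate codons into bins of 25
        bins = [list(range(1, 81))[i : i + 25] for i in range(0, 80, 25)]
        assert [f.n_codons for f in frags] == [len(b) for b in bins] == [25, 25, 25, 5]
        for f, b in zip(frags, bins):
            assert list(f.positions) == b

    def test_homology_and_anchor_come_from_parent_construct(self, contexts):
        up, down = contexts
        cds = random_cds(50, np.random.default_rng(2))
        frags = segment_cds(cds, 25, upstream_context=up, downstream_context=down)
        assert frags[0].upstream_homology == up[-40:]
        assert frags[1].upstream_homology == cds.seq[75 - 40 : 75]
        assert frags[0].downstream_anchor == cds.seq[75:79]
        assert frags[-1].downstream_anchor == down[:4]

    @pytest.mark.parametrize(
        "index,expected",
        # the last fragment spans 18 codons (1051-1068 = 54 nt): 42 full
        # 25-codon tiles end at codon 1050, so 1051 is the first codon left
        [(1, (1, 25)), (13, (301, 325)), (43, (1051, 1068))],
    )
    def test_residue_ranges(self, index, expected):
        assert fragment_residue_range(index, 25, 1068) == expected

    def test_residue_range_out_of_bounds(self):
        with pytest.raises(IndexError):
            fragment_residue_range(44, 25, 1068)

    def test_invalid_cds_rejected(self):
        with pytest.raises(ValueError):
            CodingSequence("bad", "ATGA")  # not a multiple of 3
        with pytest.raises(ValueError):
            CodingSequence("bad", "ATGNNNGGG")  # ambiguity codes
        with pytest.raises(ValueError):
            CodingSequence("bad", "ATGTAAGGG")  # internal stop
        CodingSequence("ok", "ATGTAAGGG", allow_internal_stops=True)

    @given(n_codons=st.integers(1, 200), tile=st.integers(1, 40))
    @settings(max_examples=50, deadline=None)
    def test_tiling_is_exhaustive_for_any_size(self, n_codons, tile):
        count = -(-n_codons // tile)
        covered = []
        for i in range(1, count + 1):
            s, e = fragment_residue_range(i, tile, n_codons)
            covered.extend(range(s, e + 1))
        assert covered == list(range(1, n_codons + 1))


class TestGeneticCode:
    def test_nnk_enumerates_32_codons(self):
        nnk = enumerate_nnk()
        assert len(nnk) == 32
        assert all(c[2] in "GT" for c in nnk)

    def test_tag_is_the_only_nnk_stop(self):
        # brute force over all 64 codons
        all_codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
        stops = {c for c in all_codons if translate_codon(c) == "*"}
        assert stops == {"TAA", "TAG", "TGA"}
        assert set(enumerate_nnk()) & stops == {"TAG"}

    def test_nnk_spans_all_amino_acids(self):
        states = {translate_codon(c) for c in enumerate_nnk()}
        assert len(states) == 21  # 20 amino acids + stop

    def test_invalid_codon(self):
        with pytest.raises(ValueError):
            translate_codon("AXG")


class TestCodebook:
    def test_small_codebook_satisfies_all_constraints(self, codebook_small):
        members = codebook_small.members
        assert len(members) == 2500
        assert len(set(members)) == 2500
        for bc in members:
            gc = sum(1 for b in bc if b in "GC")
            assert 5 <= gc <= 7  # integer solutions of 0.40 <= GC <= 0.60
            assert bc[0] != bc[1] and bc[-1] != bc[-2]
            assert "GGTCTC" not in bc and "GAGACC" not in bc

    def test_pairwise_hamming_by_exhaustive_oracle(self, codebook_small):
        # full O(m^2) audit on a 500-member random subsample
        rng = np.random.default_rng(0)
        idx = rng.choice(len(codebook_small.members), size=500, replace=False)
        sub = [codebook_small.members[i] for i in idx]
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                assert hamming(sub[i], sub[j]) >= 3

    def test_seed_determinism(self):
        a = generate_codebook(k=12, target_size=200, seed=21)
        b = generate_codebook(k=12, target_size=200, seed=21)
        assert a.members == b.members
        c = generate_codebook(k=12, target_size=200, seed=22)
        assert a.members != c.members

    def test_singleton_codebook(self):
        cb = generate_codebook(k=12, target_size=1, seed=0)
        assert len(cb) == 1

    def test_k4_exhaustion_brute_force(self):
        # k=4 with relaxed GC: exhaustible; every returned pair checked by
        # the O(m^2) oracle, and a warning is emitted for the big target
        with pytest.warns(CodebookWarning):
            cb = generate_codebook(
                k=4, target_size=10_000, min_hamming=3,
                gc_min=0.25, gc_max=0.75, seed=2,
            )
        assert 0 < len(cb) < 10_000
        for a, b in itertools.combinations(cb.members, 2):
            assert hamming(a, b) >= 3

    def test_index_free_path_agrees_with_constraints(self):
        # min_hamming != 3 exercises the unindexed greedy
        cb = generate_codebook(k=6, target_size=50, min_hamming=2, seed=3)
        for a, b in itertools.combinations(cb.members, 2):
            assert hamming(a, b) >= 2


class TestPairing:
    def _pair(self, b1, b2):
        return BarcodePair(codon_position=1, barcode1=b1, barcode2=b2)

    def test_combined_gc_window(self, codebook_small):
        pairs = pair_barcodes(codebook_small, 100, seed=1)
        assert len(pairs) == 100
        used = [p.barcode1 for p in pairs] + [p.barcode2 for p in pairs]
        assert len(set(used)) == 200  # each member used at most once
        for p in pairs:
            assert 11 <= p.combined_gc_count <= 13

    def test_combined_gc_arithmetic(self):
        # 6+6 and 5+7 accepted at tolerance 1; 5+5 = 10/24 would be rejected
        assert self._pair("ACGTACGTACGT", "ACGTACGTACGT").combined_gc_count == 12
        assert self._pair("ACGTACGTACAT", "ACGTACGTACGC").combined_gc_count == 12
        assert self._pair("ACGTACGTACAT", "ACGTACGTACAT").combined_gc_count == 10

    def test_pairing_deterministic(self, codebook_small):
        a = pair_barcodes(codebook_small, 50, seed=9)
        b = pair_barcodes(codebook_small, 50, seed=9)
        assert a == b

    def test_exhaustion_raises(self):
        cb = generate_codebook(k=12, target_size=10, seed=4)
        with pytest.raises(ValueError, match="exhausted"):
            pair_barcodes(cb, 10)


class TestTemplateAndOligo:
    def test_template_structure(self, codebook_small):
        pair = pair_barcodes(codebook_small, 1, seed=0)[0]
        tpl = assemble_barcode_template(pair)
        assert len(tpl.template) == 30
        assert tpl.template.count("N") == 6
        assert [i for i, c in enumerate(tpl.template) if c == "N"] == list(SPACER_OFFSETS)
        assert tpl.barcode1 == pair.barcode1 and tpl.barcode2 == pair.barcode2

    def test_all_4096_spacer_instantiations_keep_fixed_12mers(self, codebook_small):
        pair = pair_barcodes(codebook_small, 1, seed=0)[0]
        tpl = assemble_barcode_template(pair).template
        for fill in itertools.product("ACGT", repeat=6):
            chars = list(tpl)
            for off, base in zip(SPACER_OFFSETS, fill):
                chars[off] = base
            realized = "".join(chars)
            assert realized[2:14] == pair.barcode1
            assert realized[16:28] == pair.barcode2

    def test_oligo_lengths(self, full_design):
        lengths = [len(o.sequence) for pool in full_design for o in pool.oligos]
        assert max(lengths) == 207  # 40 + 75 + 4 + 24 + 30 + 34
        assert min(lengths) == 186  # 40 + 54 + 4 + 24 + 30 + 34
        assert all(o.degenerate_count == 9 for p in full_design for o in p.oligos)

    def test_oligo_concatenation_order_and_wt_instantiation(self, toy_design, toy_cds):
        pool = toy_design[0]
        frag = pool.fragment
        for oligo in pool.oligos:
            seq = oligo.sequence
            assert seq.startswith(frag.upstream_homology)
            assert seq.endswith(PBS_I7)
            body = seq[40 : 40 + frag.nt_length]
            off = (oligo.codon_position - frag.codon_start) * 3
            assert body[off : off + 3] == "NNK"
            # the WT instantiation of NNK reproduces the WT fragment exactly
            restored = body[:off] + oligo.wt_codon + body[off + 3 :]
            assert restored == frag.fragment_seq
            assert seq[40 + frag.nt_length : 44 + frag.nt_length] == frag.downstream_anchor
            assert BSAI_MODULE in seq

    def test_codon_outside_fragment_rejected(self, toy_design, codebook_small):
        frag = toy_design[0].fragment
        tpl = assemble_barcode_template(pair_barcodes(codebook_small, 1, seed=0)[0])
        with pytest.raises(ValueError, match="outside fragment"):
            build_opool(frag, 26, tpl)


class TestFullDesign:
    def test_count_identities(self, full_design, cds_full):
        assert len(full_design) == 43  # ceil(1068 / 25)
        n_oligos = sum(len(p.oligos) for p in full_design)
        assert n_oligos == cds_full.codon_count == 1068
        assert all(len(p.oligos) == 25 for p in full_design[:-1])
        assert len(full_design[-1].oligos) == 18  # 54 nt / 3

    def test_barcode_pairs_unique_genome_wide(self, full_design):
        pairs = {
            (o.barcode_template.barcode1, o.barcode_template.barcode2)
            for p in full_design
            for o in p.oligos
        }
        assert len(pairs) == 1068

    def test_design_determinism(self, toy_cds, contexts):
        up, down = contexts
        cb = generate_codebook(k=12, target_size=80, seed=13)
        a = build_full_design(toy_cds, cb, upstream_context=up,
                              downstream_context=down, seed=13)
        b = build_full_design(toy_cds, cb, upstream_context=up,
                              downstream_context=down, seed=13)
        assert [o.sequence for p in a for o in p.oligos] == [
            o.sequence for p in b for o in p.oligos
        ]


class TestValidation:
    def test_bsai_module_has_exactly_two_sites(self):
        assert count_bsai_sites(BSAI_MODULE) == 2
        assert BSAI_MODULE.index("GGTCTC") == 13
        assert BSAI_MODULE.index("GAGACC") == 1

    def test_full_design_validates_clean(self, full_design):
        # the synthetic CDS and contexts are domesticated against BsaI, so
        # the only sites anywhere are the two inside each oligo's module
        report = validate_design(full_design)
        assert report.ok

    def test_clean_design_has_no_flags(self, toy_design):
        report = validate_design(toy_design)
        assert report.ok
        assert all(c.bsai_site_count == 2 for c in report.checks)
        assert all(c.degenerate_count == 9 for c in report.checks)

    def test_injected_bsai_site_in_barcode_is_flagged(self, toy_design):
        import dataclasses

        pool = toy_design[0]
        bad_template = dataclasses.replace(
            pool.oligos[0].barcode_template,
            template="NN" + "GGTCTCAAATGC" + "NN" + pool.oligos[0].barcode_template.barcode2 + "NN",
        )
        bad_oligo = dataclasses.replace(
            pool.oligos[0],
            sequence=pool.oligos[0].sequence.replace(
                pool.oligos[0].barcode_template.template, bad_template.template
            ),
            barcode_template=bad_template,
        )
        bad_pool = dataclasses.replace(pool, oligos=(bad_oligo,) + pool.oligos[1:])
        report = validate_design([bad_pool])
        assert not report.ok
        assert any("bsai" in f for c in report.flagged for f in c.flags)
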