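"""Assay-design operations: HDR templates, control alleles, NMD geometry, filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from polyase.design import (
    STOP_CODONS,
    TranscriptModel,
    build_hdr_template,
    filter_eqtl_candidates,
    filter_non_eqtl_controls,
    filter_stop_gained_candidates,
    nmd_distance,
    pick_synthetic_control_allele,
    predict_nmd,
    reverse_complement,
    tile_stop_codons,
)
from polyase.exceptions import (
    CoordinateError,
    DesignInfeasibleError,
    FlankBoundsError,
    NoJunctionError,
    ReferenceMismatchError,
    SchemaError,
)


class TestHdrTemplate:
    def test_snv_template_is_101bp_with_alt_centred(self):
        ctx = "A" * 50 + "G" + "C" * 50
        t = build_hdr_template(ctx, 50, "G", "T")
        assert t.sequence == "A" * 50 + "T" + "C" * 50
        assert len(t.sequence) == 101
        assert t.variant_offset == 50

    def test_ref_mismatch_raises(self):
        ctx = "A" * 50 + "G" + "C" * 50
        with pytest.raises(ReferenceMismatchError):
            build_hdr_template(ctx, 50, "C", "T")

    def test_insufficient_flank_raises(self):
        with pytest.raises(FlankBoundsError):
            build_hdr_template("ACGT" * 20, 20, "A", "T", flank=50)

    def test_alt_at_offset_and_context_preserved_elsewhere(self, rng):
        for _ in range(20):
            n = int(rng.integers(110, 200))
            ctx = "".join(rng.choice(list("ACGT"), n))
            i = int(rng.integers(50, n - 50))
            ref = ctx[i]
            alt = "ACGT"[("ACGT".index(ref) + 2) % 4]
            t = build_hdr_template(ctx, i, ref, alt)
            assert t.sequence[t.variant_offset] == alt
            expect = ctx[i - 50 : i] + alt + ctx[i + 1 : i + 51]
            assert t.sequence == expect


class TestSyntheticControlAllele:
    @pytest.mark.parametrize(
        "codon,off,ref,stop_alt,expected",
        [
            ("TGC", 2, "C", "A", "G"),  # TGG = Trp, not stop
            ("AAA", 0, "A", "T", "C"),  # CAA = Gln
            ("TAC", 2, "C", "A", "T"),  # TAG is stop, TAT = Tyr
        ],
    )
    def test_known_cases(self, codon, off, ref, stop_alt, expected):
        assert pick_synthetic_control_allele(codon, off, ref, stop_alt) == expected

    def test_matches_brute_force_over_all_codons(self):
        """Exhaustive oracle: first base (A<C<G<T) that is neither allele nor stop-making."""
        bases = "ACGT"
        for codon in map("".join, itertools.product(bases, repeat=3)):
            for off in range(3):
                ref = codon[off]
                for stop_alt in bases:
                    if stop_alt == ref:
                        continue
                    expected = None
                    for b in bases:
                        if b in (ref, stop_alt):
                            continue
                        if codon[:off] + b + codon[off + 1 :] not in STOP_CODONS:
                            expected = b
                            break
                    if expected is None:
                        with pytest.raises(DesignInfeasibleError):
                            pick_synthetic_control_allele(codon, off, ref, stop_alt)
                    else:
                        got = pick_synthetic_control_allele(codon, off, ref, stop_alt)
                        assert got == expected

    def test_ref_mismatch_raises(self):
        with pytest.raises(ReferenceMismatchError):
            pick_synthetic_control_allele("TGC", 0, "C", "A")


class TestNmdDistance:
    def test_plus_strand_upstream_of_junction(self, two_exon_plus):
        assert nmd_distance(two_exon_plus, 41) == 60

    def test_plus_strand_last_exon_is_negative(self, two_exon_plus):
        assert nmd_distance(two_exon_plus, 250) == -49

    def test_minus_strand(self):
        tx = TranscriptModel("txm", "-", ((201, 300), (1, 100)), cds_start=300, cds_end=1)
        assert nmd_distance(tx, 260) == 60

    def test_non_exonic_position_raises(self, two_exon_plus):
        with pytest.raises(CoordinateError):
            nmd_distance(two_exon_plus, 150)

    def test_single_exon_raises(self):
        tx = TranscriptModel("tx1", "+", ((1, 300),))
        with pytest.raises(NoJunctionError):
            nmd_distance(tx, 50)

    def test_strand_equivalence_via_spliced_string_oracle(self, rng):
        """d computed from the spliced transcript string equals nmd_distance,
        and a minus-strand transcript built on the reverse-complemented genome
        gives the same d for the mirrored position."""
        for _ in range(15):
            n_ex = int(rng.integers(2, 5))
            bounds = np.sort(rng.choice(np.arange(1, 500), size=2 * n_ex, replace=False))
            exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_ex)]
            genome_len = 520
            genome = "".join(rng.choice(list("ACGT"), genome_len))
            tx = TranscriptModel("t", "+", tuple(exons), cds_start=exons[0][0],
                                 cds_end=exons[-1][1])
            # pick an exonic stop position
            ex_i = int(rng.integers(0, n_ex))
            pos = int(rng.integers(exons[ex_i][0], exons[ex_i][1] + 1))

            # oracle: index within the spliced string
            spliced = tx.spliced_sequence(genome)
            tpos = sum(b - a + 1 for a, b in exons[:ex_i]) + (pos - exons[ex_i][0])
            junction = sum(b - a + 1 for a, b in exons[:-1])
            d_oracle = junction - (tpos + 1) + 1
            assert nmd_distance(tx, pos) == d_oracle
            assert len(spliced) == tx.length

            # mirrored minus-strand construction on the flipped genome
            mexons = tuple(
                (genome_len - b + 1, genome_len - a + 1) for a, b in exons
            )
            txm = TranscriptModel("tm", "-", mexons, cds_start=mexons[0][1],
                                  cds_end=mexons[-1][0])
            assert txm.spliced_sequence(reverse_complement(genome)) == spliced
            assert nmd_distance(txm, genome_len - pos + 1) == d_oracle


class TestPredictNmd:
    @pytest.mark.parametrize("d,expect", [(60, "trigger"), (55, "trigger"),
                                          (54, "escape"), (-49, "escape")])
    def test_boundary(self, d, expect):
        assert predict_nmd(d) == expect

    def test_monotone(self):
        labels = [predict_nmd(d) for d in range(-60, 120)]
        # once trigger, always trigger as d increases
        first_trigger = labels.index("trigger")
        assert all(l == "trigger" for l in labels[first_trigger:])
        assert all(l == "escape" for l in labels[:first_trigger])


def _tiling_transcript(rng, exon1_len=399, exon2_len=120):
    """Two-exon fully-coding transcript whose CDS repeats TGG (Trp), so every
    codon can become a stop (TAG or TGA) by a single substitution."""
    total = exon1_len + exon2_len
    assert total % 3 == 0
    cds = "TGG" * (total // 3)
    tx = TranscriptModel(
        "dg", "+", ((1, exon1_len), (exon1_len + 101, exon1_len + 100 + exon2_len)),
        cds_start=1, cds_end=exon1_len + 100 + exon2_len,
    )
    return tx, cds


class TestTileStopCodons:
    def test_ten_variants_spaced_20bp_across_boundary(self, rng):
        tx, cds = _tiling_transcript(rng)
        res = tile_stop_codons(tx, cds, n_each_side=5)
        assert len(res.variants) == 10
        assert not res.unfillable
        ds = sorted(res.distances.values())
        # one slot within codon granularity of each 20-bp-spaced target d,
        # five tiling each direction from the 55-bp cutoff
        targets = sorted([55 + 20 * k for k in range(5)] + [55 - 20 * (k + 1) for k in range(5)])
        for t, d in zip(targets, ds):
            assert abs(d - t) <= 2
        gaps = np.diff(ds)
        assert all(abs(g - 20) <= 4 for g in gaps)

    def test_each_variant_creates_a_stop_codon(self, rng):
        tx, cds = _tiling_transcript(rng)
        res = tile_stop_codons(tx, cds, n_each_side=5)
        cds_tstart = tx.genomic_to_transcript(tx.cds_start)
        for v in res.variants:
            tpos = tx.genomic_to_transcript(v.pos)
            ci = (tpos - cds_tstart) // 3
            j = (tpos - cds_tstart) % 3
            codon = cds[3 * ci : 3 * ci + 3]
            mutated = codon[:j] + v.alt_allele + codon[j + 1 :]
            assert mutated in STOP_CODONS
            assert codon not in STOP_CODONS

    def test_zero_slots_gives_empty(self, rng):
        tx, cds = _tiling_transcript(rng)
        assert tile_stop_codons(tx, cds, n_each_side=0).variants == []

    def test_unfillable_slot_reported_not_fatal(self):
        # CCC codons can never become stops by one substitution except none
        exon1, exon2 = 120, 60  # cds 60+60+60 = 180
        cds = "TGG" * 20 + "CCC" * 20 + "TGG" * 20
        tx = TranscriptModel("u", "+", ((1, exon1), (201, 200 + exon2)),
                             cds_start=1, cds_end=200 + exon2)
        res = tile_stop_codons(tx, cds, n_each_side=3)
        assert res.unfillable  # at least one slot falls in the CCC desert
        assert res.variants  # others are still designed

    def test_minus_strand_alleles_are_genomic(self):
        # same CDS placed on a minus-strand transcript; alleles must complement
        cds = "TGG" * 180
        txp = TranscriptModel("p", "+", ((1, 400), (501, 640)), cds_start=1, cds_end=640)
        txm = TranscriptModel("m", "-", ((241, 640), (1, 140)), cds_start=640, cds_end=1)
        vp = tile_stop_codons(txp, cds, n_each_side=2).variants
        vm = tile_stop_codons(txm, cds, n_each_side=2).variants
        assert sorted(v.alt_allele for v in vm) == sorted(
            reverse_complement(v.alt_allele) for v in vp
        )


class TestFilters:
    def test_stop_gained_boundary_row_kept(self):
        row = pd.DataFrame([{"coverage": 20, "ref_ratio": 0.71, "rpkm": 0.6,
                             "n_tissues_with_ase": 5, "ase_q1": 0.71,
                             "dist_to_exon_end": 31}])
        assert len(filter_stop_gained_candidates(row)) == 1

    def test_stop_gained_each_predicate_can_fail_alone(self):
        passing = {"coverage": 30, "ref_ratio": 0.9, "rpkm": 2.0,
                   "n_tissues_with_ase": 8, "ase_q1": 0.9, "dist_to_exon_end": 100}
        fails = [
            {"coverage": 19}, {"ref_ratio": 0.7}, {"rpkm": 0.5},
            {"n_tissues_with_ase": 4}, {"ase_q1": 0.7}, {"dist_to_exon_end": 30},
        ]
        rows = [dict(passing, **f) for f in fails] + [dict(passing)]
        out = filter_stop_gained_candidates(pd.DataFrame(rows))
        assert list(out.index) == [6]

    def test_eqtl_boundaries(self):
        rows = pd.DataFrame(
            [
                {"in_protein_coding_transcript": True, "caviar_pp": 0.81,
                 "egene_rpkm": 1.1, "abs_afc": 0.31},
                {"in_protein_coding_transcript": True, "caviar_pp": 0.8,
                 "egene_rpkm": 2, "abs_afc": 1.0},
                {"in_protein_coding_transcript": False, "caviar_pp": 0.95,
                 "egene_rpkm": 2, "abs_afc": 1.0},
                {"in_protein_coding_transcript": True, "caviar_pp": 0.95,
                 "egene_rpkm": 1.0, "abs_afc": 1.0},
                {"in_protein_coding_transcript": True, "caviar_pp": 0.95,
                 "egene_rpkm": 2, "abs_afc": 0.30},
            ]
        )
        assert list(filter_eqtl_candidates(rows).index) == [0]

    def test_non_eqtl_controls(self):
        rows = pd.DataFrame(
            [
                {"is_synonymous": True, "is_common": True, "eqtl_p": 0.5},
                {"is_synonymous": True, "is_common": True, "eqtl_p": 0.1},
                {"is_synonymous": False, "is_common": True, "eqtl_p": 0.9},
            ]
        )
        assert list(filter_non_eqtl_controls(rows).index) == [0]

    @pytest.mark.parametrize(
        "fn,cols",
        [
            (filter_stop_gained_candidates,
             ["coverage", "ref_ratio", "rpkm", "n_tissues_with_ase", "ase_q1",
              "dist_to_exon_end"]),
            (filter_eqtl_candidates,
             ["in_protein_coding_transcript", "caviar_pp", "egene_rpkm", "abs_afc"]),
            (filter_non_eqtl_controls, ["is_synonymous", "is_common", "eqtl_p"]),
        ],
    )
    def test_missing_column_raises_and_filters_idempotent(self, fn, cols, rng):
        with pytest.raises(SchemaError):
            fn(pd.DataFrame({c: [1] for c in cols[:-1]}))
        # random numeric tables: subset + idempotence
        df = pd.DataFrame(rng.uniform(0, 2, size=(50, len(cols))), columns=cols)
        once = fn(df)
        assert set(once.index) <= set(df.index)
        pd.testing.assert_frame_equal(fn(once), once)
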