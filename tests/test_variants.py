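"""Variant extraction, application, annotation and partitioning."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoscreen.reference import GeneFeature, MtReference, ValidationError
from mitoscreen.variants import (
    AmbiguousRegionError,
    Variant,
    annotate_variant,
    apply_variants,
    extract_variants,
    parse_replacement,
    partition_variants,
    read_variant_table,
    write_vcf,
)


class TestVariantType:
    @pytest.mark.parametrize(
        "ref,alt,kind",
        [("T", "C", "substitution"), ("C", "CC", "insertion"), ("CA", "C", "deletion")],
    )
    def test_kind_classification(self, ref, alt, kind):
        assert Variant(position=10, ref=ref, alt=alt).kind == kind

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValidationError):
            Variant(position=1, ref="A", alt="A")

    @pytest.mark.parametrize(
        "cell,expected",
        [
            ("T-C", ("T", "C", None)),
            ("C-CC", ("C", "CC", None)),
            ("A-G( Thr112Ala)", ("A", "G", "Thr112Ala")),
        ],
    )
    def test_parse_replacement(self, cell, expected):
        assert parse_replacement(cell) == expected

    def test_parse_replacement_rejects_garbage(self):
        with pytest.raises(ValidationError):
            parse_replacement("T/C")


class TestApply:
    def test_empty_list_is_identity(self, reference):
        assert apply_variants(reference, []) == reference.sequence

    def test_single_base_insertion_extends_by_one(self, reference):
        sample = apply_variants(reference, [Variant(310, "C", "CC")])
        assert len(sample) == reference.length + 1

    def test_ref_mismatch_signals_dialect_error(self, reference):
        base = reference.base_at(1000)
        wrong = "A" if base != "A" else "G"
        with pytest.raises(ValidationError, match="mismatch"):
            apply_variants(reference, [Variant(1000, wrong, "T")])

    def test_overlapping_variants_rejected(self, reference):
        v1 = Variant(1000, reference.base_at(1000) + reference.base_at(1001),
                     reference.base_at(1000))
        v2 = Variant(1001, reference.base_at(1001),
                     "A" if reference.base_at(1001) != "A" else "C")
        with pytest.raises(ValidationError, match="overlap"):
            apply_variants(reference, [v1, v2])


def _random_genome(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestExtract:
    def test_identical_genomes_give_empty_list(self, reference):
        assert extract_variants(reference.sequence, reference) == []

    def test_spaced_substitutions_match_positional_diff_oracle(self):
        rng = random.Random(7)
        ref = _random_genome(rng, 16569)
        positions = [500, 3000, 8000, 12000, 16000]
        variants = []
        for p in positions:
            old = ref[p - 1]
            new = rng.choice([b for b in "ACGT" if b != old])
            variants.append(Variant(p, old, new))
        sample = apply_variants(ref, variants)
        # oracle: direct position-wise character diff of the two strings
        oracle = [
            (i + 1, r, s) for i, (r, s) in enumerate(zip(ref, sample)) if r != s
        ]
        got = [(v.position, v.ref, v.alt) for v in extract_variants(sample, ref)]
        assert got == oracle
        assert len(got) == 5

    def test_adjacent_substitutions_stay_separate(self):
        ref = "A" * 30 + "TCA" + "G" * 30
        sample = ref[:30] + "CTA" + ref[33:]
        got = extract_variants(sample, ref)
        assert [(v.position, v.ref, v.alt) for v in got] == [
            (31, "T", "C"), (32, "C", "T")
        ]

    def test_homopolymer_insertion_reported_in_table_dialect(self):
        ref = "ATGATTGACA" + "TC" + "GATTCAGGAA"
        sample = ref[:11] + "C" + ref[11:]  # duplicate the C run base
        got = extract_variants(sample, ref)
        assert [(v.position, v.ref, v.alt) for v in got] == [(12, "C", "CC")]

    def test_indel_crowded_by_substitution_is_ambiguous(self):
        rng = random.Random(11)
        ref = _random_genome(rng, 200)
        sample = apply_variants(ref, [Variant(100, ref[99], ref[99] + "T")])
        # substitution 4 bases downstream of the insertion
        pos = 104
        old = sample[pos - 1]
        new = "A" if old != "A" else "C"
        sample = sample[: pos - 1] + new + sample[pos:]
        with pytest.raises(AmbiguousRegionError):
            extract_variants(sample, ref)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=40)
    def test_apply_extract_round_trip(self, seed):
        rng = random.Random(seed)
        ref = _random_genome(rng, 400)
        variants = []
        for p in range(20, 400, 40):
            old = ref[p - 1]
            kind = rng.choice(["sub", "sub", "ins", "del"])
            if kind == "sub":
                variants.append(
                    Variant(p, old, rng.choice([b for b in "ACGT" if b != old]))
                )
            elif kind == "ins":
                ins = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 3)))
                variants.append(Variant(p, old, old + ins))
            else:
                k = rng.randint(1, 3)
                variants.append(Variant(p, ref[p - 1 : p + k], old))
        sample = apply_variants(ref, variants)
        recovered = extract_variants(sample, ref)
        assert apply_variants(ref, recovered) == sample


class TestAnnotation:
    @pytest.mark.parametrize(
        "position,ref,alt,gene,fclass,notation",
        [
            (5802, "T", "C", "MT-TC", "tRNA", "m.5802A>G"),
            (73, "A", "G", "D-loop", "control_region", "m.73A>G"),
            (14668, "C", "T", "MT-ND6", "protein_coding", "m.14668G>A"),
        ],
    )
    def test_gene_and_strand_notation(self, reference, position, ref, alt,
                                      gene, fclass, notation):
        av = annotate_variant(Variant(position, ref, alt), reference)
        assert (av.gene, av.feature_class, av.gene_strand_notation) == (
            gene, fclass, notation
        )

    @pytest.mark.parametrize(
        "position,ref,alt,effect,aa",
        [
            (8860, "A", "G", "missense", "Thr112Ala"),
            (10398, "A", "G", "missense", "Thr114Ala"),
            (8701, "A", "G", "missense", "Thr59Ala"),
            (4769, "A", "G", "silent", None),
            (14668, "C", "T", "silent", None),  # L-strand gene
            (73, "A", "G", "non_coding", None),
        ],
    )
    def test_coding_effects(self, reference, position, ref, alt, effect, aa):
        av = annotate_variant(Variant(position, ref, alt), reference)
        assert (av.coding_effect, av.aa_change) == (effect, aa)

    def test_coding_indel_classified_other(self, reference):
        base = reference.base_at(4800)  # inside MT-ND2
        av = annotate_variant(Variant(4800, base, base + "A"), reference)
        assert av.coding_effect == "other"

    def test_l_strand_notation_complements_alleles(self, reference):
        rng = random.Random(3)
        for _ in range(50):
            pos = rng.randint(1, reference.length)
            feature = reference.feature_at(pos)
            old = reference.base_at(pos)
            new = rng.choice([b for b in "ACGT" if b != old])
            av = annotate_variant(Variant(pos, old, new), reference)
            body = av.gene_strand_notation.removeprefix(f"m.{pos}")
            if feature.strand == "L":
                assert body == f"{_comp(old)}>{_comp(new)}"
            else:
                assert body == f"{old}>{new}"


def _comp(b):
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[b]


class TestPartition:
    def test_empty_input_gives_zero_counts(self):
        counts = partition_variants([])
        assert sum(counts.values()) == 0

    def test_counts_sum_to_total(self, reference, variant_records):
        annotated = [annotate_variant(r.variant, reference) for r in variant_records]
        counts = partition_variants(annotated)
        assert sum(counts.values()) == len(variant_records)

    def test_injected_categories_recovered(self, reference):
        # oracle: category labels recorded at injection time
        injected = [
            (Variant(100, reference.base_at(100), _comp(reference.base_at(100))), "D-loop"),
            (Variant(800, reference.base_at(800), _comp(reference.base_at(800))), "MT-RNR1"),
            (Variant(2000, reference.base_at(2000), _comp(reference.base_at(2000))), "MT-RNR2"),
            (Variant(5802, "T", "C"), "tRNA"),
        ]
        annotated = [annotate_variant(v, reference) for v, _ in injected]
        counts = partition_variants(annotated)
        for _, label in injected:
            assert counts[label] >= 1
        assert sum(counts.values()) == len(injected)


class TestTableIO:
    def test_bundled_table_parses_with_gene_fill_down(self, variant_records):
        assert len(variant_records) == 47
        by_pos = {r.variant.position: r for r in variant_records}
        assert by_pos[194].gene == "D-loop"  # blank cell filled from row above
        assert by_pos[310].variant.kind == "insertion"
        assert by_pos[8860].aa_annotation == "Thr112Ala"
        assert not by_pos[5802].previously_reported
        assert sum(not r.previously_reported for r in variant_records) == 1

    def test_vcf_writer_emits_sorted_minimal_records(self, reference, tmp_path,
                                                     variant_records):
        annotated = [annotate_variant(r.variant, reference) for r in variant_records]
        out = tmp_path / "out.vcf"
        write_vcf(annotated, reference, out)
        lines = out.read_text().splitlines()
        body = [ln for ln in lines if not ln.startswith("#")]
        assert len(body) == 47
        positions = [int(ln.split("\t")[1]) for ln in body]
        assert positions == sorted(positions)
        assert body[0].startswith("chrM\t73\t.\tA\tG")
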