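"""Cloverleaf domains, stem pairing, and the conservation index."""

import io
import random

import pytest

from mitoscreen.reference import ValidationError
from mitoscreen.trna import (
    TrnaAlignment,
    canonical_cloverleaf,
    conservation_index,
    conservation_profile,
    genome_to_trna_position,
    parse_domain_alignment,
)

STRUCTURE = canonical_cloverleaf()


class TestStructure:
    @pytest.mark.parametrize(
        "position,domain",
        [
            (30, "anticodon_stem_5p"),
            (35, "anticodon_loop"),
            (73, "discriminator"),
            (1, "acceptor_stem_5p"),
            (45, "variable_region"),
            (55, "t_loop"),
        ],
    )
    def test_domain_mapping(self, position, domain):
        assert STRUCTURE.domain_of(position).name == domain

    def test_position_outside_cloverleaf_rejected(self):
        with pytest.raises(ValidationError):
            STRUCTURE.domain_of(74)

    @pytest.mark.parametrize(
        "position,partner", [(30, 40), (1, 72), (27, 43), (49, 65), (35, None), (45, None)]
    )
    def test_pair_partner(self, position, partner):
        assert STRUCTURE.pair_partner(position) == partner

    def test_pairing_is_a_fixed_involution(self):
        for i, j in STRUCTURE.pairs.items():
            assert STRUCTURE.pairs[j] == i
        # anticodon stem closes 27-43 .. 31-39
        assert {(i, STRUCTURE.pairs[i]) for i in range(27, 32)} == {
            (27, 43), (28, 42), (29, 41), (30, 40), (31, 39)
        }


class TestParsing:
    def test_bundled_alignment_has_17_species(self, alignment):
        assert alignment.n_species == 17
        assert alignment.species[alignment.human_row] == "Homo sapiens"

    def test_human_gene_length_and_sequence(self, alignment):
        seq = alignment.human_sequence()
        assert len(seq) == 66
        assert seq.startswith("AGCTCCG")
        assert seq.endswith("CGGGGCTT")

    def test_missing_stem_block_rejected(self, alignment):
        path = __import__("mitoscreen.data", fromlist=["data_path"]).data_path(
            "trna_cys_alignment_17species.tsv"
        )
        text = open(path).read().replace("TTGAA\tTTGCAAA\tTTCGA\tAGAA", "TTGA\tTTGCAAA\tTTCGA\tAGAA")
        with pytest.raises(ValidationError):
            parse_domain_alignment(io.StringIO(text))

    def test_single_species_alignment_is_valid_and_trivially_conserved(self, alignment):
        blocks = {
            name: [cells[alignment.human_row]] for name, cells in alignment.blocks.items()
        }
        solo = TrnaAlignment(species=["Homo sapiens"], blocks=blocks)
        profile = conservation_profile(solo)
        assert profile.positions  # defined wherever the human row has a base
        assert all(v == 100.0 for v in profile.ci.values())


class TestConservationIndex:
    def test_fully_conserved_column(self, alignment):
        # position 73 (discriminator) is T in all 17 rows
        assert conservation_index(alignment, 73) == 100.0

    def test_counting_oracle_on_constructed_column(self):
        # 17 species, 12 of 16 non-human rows match the human base at stem col 1
        base_blocks = {d.name: "A" * (d.width or 3) for d in STRUCTURE.domains}
        rows = {name: [cell] for name, cell in base_blocks.items()}
        for i in range(16):
            for name, cell in base_blocks.items():
                if name == "acceptor_stem_5p" and i >= 12:
                    cell = "C" + cell[1:]
                rows[name].append(cell)
        aln = TrnaAlignment(
            species=["Homo sapiens"] + [f"sp{i}" for i in range(16)], blocks=rows
        )
        assert conservation_index(aln, 1) == 75.0  # 12/16 by direct count

    def test_anticodon_position_30_from_fixture(self, alignment):
        ci = conservation_index(alignment, 30)
        assert ci == pytest.approx(100.0 * 15 / 16)  # one non-matching species
        assert ci > 75.0

    def test_human_gap_reported_absent_not_zero(self, alignment):
        # canonical 17-21 have no human bases (short mitochondrial D loop)
        assert conservation_index(alignment, 20) is None

    def test_row_permutation_invariance(self, alignment):
        rng = random.Random(5)
        order = list(range(alignment.n_species))
        rng.shuffle(order)
        shuffled = TrnaAlignment(
            species=[alignment.species[i] for i in order],
            blocks={
                name: [cells[i] for i in order]
                for name, cells in alignment.blocks.items()
            },
        )
        for pos in (1, 5, 30, 40, 73):
            assert conservation_index(shuffled, pos) == conservation_index(alignment, pos)

    def test_duplicating_rows_preserves_profile(self, alignment):
        doubled = TrnaAlignment(
            species=alignment.species
            + [s + " (dup)" for s in alignment.species if s != "Homo sapiens"],
            blocks={
                name: cells
                + [c for s, c in zip(alignment.species, cells) if s != "Homo sapiens"]
                for name, cells in alignment.blocks.items()
            },
        )
        p1 = conservation_profile(alignment)
        p2 = conservation_profile(doubled)
        assert p1.positions == p2.positions
        assert all(p1.ci[p] == pytest.approx(p2.ci[p]) for p in p1.positions)

    def test_adding_matching_species_never_decreases_ci(self, alignment):
        human = {name: cells[alignment.human_row] for name, cells in alignment.blocks.items()}
        bigger = TrnaAlignment(
            species=alignment.species + ["perfect match"],
            blocks={name: cells + [human[name]] for name, cells in alignment.blocks.items()},
        )
        for pos in conservation_profile(alignment).positions:
            assert conservation_index(bigger, pos) >= conservation_index(alignment, pos)

    def test_profile_bounds_and_stem_coverage(self, alignment):
        profile = conservation_profile(alignment)
        assert all(0.0 <= v <= 100.0 for v in profile.ci.values())
        for d in STRUCTURE.domains:
            if d.kind == "stem":
                for pos in range(d.anchor, d.anchor + d.width):
                    assert pos in profile.ci


class TestGenomeMapping:
    def test_m5802_maps_to_canonical_30(self, reference, alignment):
        mt_tc = reference.feature_by_name("MT-TC")
        assert genome_to_trna_position(reference, mt_tc, 5802, alignment) == 30

    def test_gene_ends_map_to_1_and_73(self, reference, alignment):
        mt_tc = reference.feature_by_name("MT-TC")
        assert genome_to_trna_position(reference, mt_tc, 5826, alignment) == 1
        # 66-base gene: last base is the discriminator
        assert genome_to_trna_position(reference, mt_tc, 5761, alignment) == 73

    def test_non_trna_feature_rejected(self, reference, alignment):
        nd2 = reference.feature_by_name("MT-ND2")
        with pytest.raises(ValidationError):
            genome_to_trna_position(reference, nd2, 4769, alignment)
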