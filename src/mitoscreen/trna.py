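"""tRNA cloverleaf model and multi-species domain alignments.

The cloverleaf is described in canonical tRNA numbering: acceptor stem
1-7/66-72, D arm 10-13/22-25, anticodon stem 27-31/39-43 with loop 32-38
(anticodon 34-36), variable region 44-48, T arm 49-53/61-65 with loop 54-60,
discriminator 73. Mitochondrial tRNAs are shorter than the canonical 76-mer,
so a gene's sequential positions map onto canonical numbers with gaps; the
mapping is derived from the block layout of the species alignment (each block
is anchored at the canonical number of its first column, loop blocks are
left-aligned).

The conservation index (CI) at a position is the percentage of non-human
species carrying the human wild-type base in that alignment column; a gap or
missing base counts as a mismatch, and a column where the human row itself
has no base has no defined CI.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .reference import GeneFeature, MtReference, ValidationError, gene_offset

__all__ = [
    "TrnaStructure",
    "TrnaAlignment",
    "ConservationProfile",
    "canonical_cloverleaf",
    "parse_domain_alignment",
    "conservation_index",
    "conservation_profile",
    "genome_to_trna_position",
]


@dataclass(frozen=True)
class TrnaDomain:
    name: str
    anchor: int           # canonical position of the block's first column
    width: Optional[int]  # None for variable-width (loop) blocks
    kind: str             # "stem" | "loop" | "single"


#: canonical block layout shared by the alignment dialect
_DOMAINS = (
    TrnaDomain("acceptor_stem_5p", 1, 7, "stem"),
    TrnaDomain("link_8_9", 8, 2, "single"),
    TrnaDomain("d_stem_5p", 10, 4, "stem"),
    TrnaDomain("d_loop", 14, None, "loop"),
    TrnaDomain("d_stem_3p", 22, 4, "stem"),
    TrnaDomain("pos_26", 26, 1, "single"),
    TrnaDomain("anticodon_stem_5p", 27, 5, "stem"),
    TrnaDomain("anticodon_loop", 32, 7, "loop"),
    TrnaDomain("anticodon_stem_3p", 39, 5, "stem"),
    TrnaDomain("variable_region", 44, None, "loop"),
    TrnaDomain("t_stem_5p", 49, 5, "stem"),
    TrnaDomain("t_loop", 54, None, "loop"),
    TrnaDomain("t_stem_3p", 61, 5, "stem"),
    TrnaDomain("acceptor_stem_3p", 66, 7, "stem"),
    TrnaDomain("discriminator", 73, 1, "single"),
)

#: canonical range covered by each block (upper bound for variable blocks is
#: the next anchor - 1)
_NEXT_ANCHOR = {d.name: n.anchor for d, n in zip(_DOMAINS, _DOMAINS[1:])}
_NEXT_ANCHOR[_DOMAINS[-1].name] = _DOMAINS[-1].anchor + 1


def _stem_pairs() -> dict[int, int]:
    pairs = {}
    for five, three in (
        (range(1, 8), range(72, 65, -1)),     # acceptor stem
        (range(10, 14), range(25, 21, -1)),   # D stem
        (range(27, 32), range(43, 38, -1)),   # anticodon stem
        (range(49, 54), range(65, 60, -1)),   # T stem
    ):
        for i, j in zip(five, three):
            pairs[i] = j
            pairs[j] = i
    return pairs


@dataclass(frozen=True)
class TrnaStructure:
    """Cloverleaf segmentation plus the stem base-pair table."""

    domains: tuple[TrnaDomain, ...] = _DOMAINS
    pairs: dict[int, int] = field(default_factory=_stem_pairs)

    def domain_of(self, position: int) -> TrnaDomain:
        """The unique domain covering a canonical position."""
        for d in self.domains:
            hi = d.anchor + d.width - 1 if d.width else _NEXT_ANCHOR[d.name] - 1
            if d.anchor <= position <= hi:
                return d
        raise ValidationError(f"canonical position {position} outside the cloverleaf")

    def pair_partner(self, position: int) -> Optional[int]:
        """Stem pairing partner, or None for unpaired positions."""
        self.domain_of(position)  # range check
        return self.pairs.get(position)

    def is_paired(self, position: int) -> bool:
        return position in self.pairs


def canonical_cloverleaf() -> TrnaStructure:
    """The canonical cloverleaf used for mitochondrial tRNA screening."""
    return TrnaStructure()


@dataclass
class TrnaAlignment:
    """Block-structured multi-species tRNA alignment.

    ``blocks[name][i]`` is species ``i``'s subsequence for that domain block.
    Stem blocks must have identical width across species; loop blocks are
    left-aligned and may be ragged.
    """

    species: list[str]
    blocks: dict[str, list[str]]
    structure: TrnaStructure = field(default_factory=canonical_cloverleaf)
    human_name: str = "Homo sapiens"

    def __post_init__(self) -> None:
        names = {d.name for d in self.structure.domains}
        missing = names - set(self.blocks)
        if missing:
            raise ValidationError(f"alignment missing blocks: {sorted(missing)}")
        n = len(self.species)
        for d in self.structure.domains:
            col = self.blocks[d.name]
            if len(col) != n:
                raise ValidationError(
                    f"block {d.name}: {len(col)} rows for {n} species"
                )
            if any(not cell for cell in col):
                raise ValidationError(f"block {d.name}: a species row is empty")
            if d.width is not None:
                widths = {len(cell) for cell in col}
                if widths != {d.width}:
                    raise ValidationError(
                        f"fixed-width block {d.name}: widths {sorted(widths)} != {d.width}"
                    )
        if self.human_name not in self.species:
            raise ValidationError(f"no row named {self.human_name!r}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def human_row(self) -> int:
        return self.species.index(self.human_name)

    def base(self, species_idx: int, domain: str, col: int) -> Optional[str]:
        """Base of one species at a block column; None for gap/absent."""
        cell = self.blocks[domain][species_idx]
        if col >= len(cell) or cell[col] == "-":
            return None
        return cell[col]

    def column_of(self, position: int) -> tuple[TrnaDomain, int]:
        d = self.structure.domain_of(position)
        return d, position - d.anchor

    def human_base(self, position: int) -> Optional[str]:
        d, col = self.column_of(position)
        return self.base(self.human_row, d.name, col)

    def human_sequence(self) -> str:
        """The human gene sequence, concatenated 5'->3' (no gaps)."""
        row = self.human_row
        return "".join(
            self.blocks[d.name][row].replace("-", "") for d in self.structure.domains
        )

    def sequential_to_canonical(self, offset: int) -> int:
        """Canonical number of the human gene's ``offset``-th base (1-based)."""
        row = self.human_row
        consumed = 0
        for d in self.structure.domains:
            cell = self.blocks[d.name][row].replace("-", "")
            if consumed + len(cell) >= offset:
                return d.anchor + (offset - consumed - 1)
            consumed += len(cell)
        raise ValidationError(
            f"offset {offset} beyond the human gene length {consumed}"
        )


def parse_domain_alignment(source) -> TrnaAlignment:
    """Parse the block-structured alignment TSV dialect.

    Expects a header row of block names, an ``#anchor`` row giving each
    block's canonical start position, and one row per species.
    """
    close = False
    if not isinstance(source, io.TextIOBase):
        source = open(source, "rt")
        close = True
    try:
        lines = [ln.rstrip("\n") for ln in source if ln.strip()]
    finally:
        if close:
            source.close()
    lines = [ln for ln in lines if not ln.startswith("#") or ln.startswith("#anchor")]
    if len(lines) < 3:
        raise ValidationError("alignment table too short")
    header = lines[0].split("\t")
    if header[0] != "species":
        raise ValidationError("first header column must be 'species'")
    block_names = header[1:]
    anchor_row = lines[1].split("\t")
    if anchor_row[0] != "#anchor":
        raise ValidationError("second row must be the #anchor row")
    anchors = [int(a) for a in anchor_row[1:]]
    expected = {d.name: d.anchor for d in _DOMAINS}
    for name, anchor in zip(block_names, anchors):
        if expected.get(name) != anchor:
            raise ValidationError(
                f"block {name!r} anchored at {anchor}, expected {expected.get(name)}"
            )

    species: list[str] = []
    blocks: dict[str, list[str]] = {name: [] for name in block_names}
    for ln in lines[2:]:
        cells = ln.split("\t")
        if len(cells) != len(block_names) + 1:
            raise ValidationError(
                f"species row {cells[0]!r} has {len(cells) - 1} blocks, "
                f"expected {len(block_names)}"
            )
        species.append(cells[0])
        for name, cell in zip(block_names, cells[1:]):
            blocks[name].append(cell.strip().upper())
    return TrnaAlignment(species=species, blocks=blocks)


def conservation_index(
    alignment: TrnaAlignment, position: int, include_human: bool = False
) -> Optional[float]:
    """CI at a canonical position: % of species carrying the human base.

    Returns None when the human row has no base in the column (no defined
    wild-type). Non-human gaps and absent bases count as mismatches; the
    denominator is all compared species (non-human rows by default). With no
    species to compare against, a defined position is trivially 100%
    conserved.
    """
    d, col = alignment.column_of(position)
    human = alignment.human_base(position)
    if human is None:
        return None
    matches = 0
    total = 0
    for i in range(alignment.n_species):
        if i == alignment.human_row and not include_human:
            continue
        total += 1
        if alignment.base(i, d.name, col) == human:
            matches += 1
    if total == 0:
        return 100.0
    return 100.0 * matches / total


@dataclass
class ConservationProfile:
    """Per-position CI over the canonical numbering, with context columns."""

    positions: list[int]
    human_bases: dict[int, str]
    ci: dict[int, float]
    domains: dict[int, str]
    partners: dict[int, Optional[int]]
    n_species_compared: int

    def write_tsv(self, out) -> None:
        close = False
        if isinstance(out, (str, bytes)) or hasattr(out, "__fspath__"):
            out = open(out, "wt")
            close = True
        try:
            w = csv.writer(out, delimiter="\t", lineterminator="\n")
            w.writerow(["trna_position", "human_base", "ci", "domain", "pair_partner"])
            for p in self.positions:
                w.writerow(
                    [p, self.human_bases[p], f"{self.ci[p]:.2f}",
                     self.domains[p], self.partners[p] if self.partners[p] else ""]
                )
        finally:
            if close:
                out.close()


def conservation_profile(
    alignment: TrnaAlignment, include_human: bool = False
) -> ConservationProfile:
    """CI at every canonical position where the human row has a base."""
    s = alignment.structure
    positions, bases, ci, domains, partners = [], {}, {}, {}, {}
    for d in s.domains:
        hi = d.anchor + d.width - 1 if d.width else _NEXT_ANCHOR[d.name] - 1
        for p in range(d.anchor, hi + 1):
            value = conservation_index(alignment, p, include_human=include_human)
            if value is None:
                continue
            positions.append(p)
            bases[p] = alignment.human_base(p)
            ci[p] = value
            domains[p] = d.name
            partners[p] = s.pair_partner(p)
    n = alignment.n_species if include_human else alignment.n_species - 1
    return ConservationProfile(
        positions=positions, human_bases=bases, ci=ci,
        domains=domains, partners=partners, n_species_compared=n,
    )


def genome_to_trna_position(
    reference: MtReference,
    feature: GeneFeature,
    genome_position: int,
    alignment: TrnaAlignment,
) -> int:
    """Canonical tRNA number of a genome position inside a tRNA gene.

    Converts through the gene's 5' offset on its coding strand, then through
    the canonical-number gaps implied by the human row of the alignment.
    """
    if feature.feature_class != "tRNA":
        raise ValidationError(f"{feature.gene} is not a tRNA gene")
    offset = gene_offset(feature, genome_position, reference.length)
    return alignment.sequential_to_canonical(offset)
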