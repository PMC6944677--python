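"""Circular mitochondrial reference genome and its gene annotation.

All coordinate and strand conventions of the package live here: positions are
1-based and inclusive on the heavy (H) strand, matching ``m.<pos>`` notation;
position arithmetic wraps modulo the genome length, so a feature whose end
coordinate is smaller than its start (the control region, 16024..576) spans
the origin. Genes encoded on the light (L) strand are read off the
complementary strand; :func:`gene_offset` converts a genome position into a
1-based offset from the gene's 5' end on its coding strand.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

__all__ = [
    "MtReference",
    "GeneFeature",
    "ValidationError",
    "load_reference",
    "read_gene_map",
    "complement",
    "reverse_complement",
    "gene_offset",
]

DNA_BASES = frozenset("ACGT")
_COMP = str.maketrans("ACGTN", "TGCAN")

FEATURE_CLASSES = ("control_region", "rRNA", "tRNA", "protein_coding", "intergenic")

#: feature_at precedence when features overlap: most specific class wins.
CLASS_PRIORITY = {
    "tRNA": 0,
    "rRNA": 1,
    "protein_coding": 2,
    "control_region": 3,
    "intergenic": 4,
}


class ValidationError(ValueError):
    """An input file or value violated a documented contract."""


def complement(base: str) -> str:
    """Complement of a single DNA base (N maps to N)."""
    if len(base) != 1 or base.upper() not in DNA_BASES | {"N"}:
        raise ValidationError(f"not a DNA base: {base!r}")
    return base.upper().translate(_COMP)


def reverse_complement(seq: str) -> str:
    """Reverse complement; an involution that preserves length."""
    up = seq.upper()
    bad = set(up) - DNA_BASES - {"N"}
    if bad:
        raise ValidationError(f"non-DNA characters in sequence: {sorted(bad)}")
    return up.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature of the mitochondrial genome.

    ``end < start`` indicates the feature wraps through the origin.
    ``strand`` is ``"H"`` or ``"L"``.
    """

    gene: str
    start: int
    end: int
    strand: str
    feature_class: str

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValidationError(f"{self.gene}: strand must be H or L, got {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(
                f"{self.gene}: unknown feature_class {self.feature_class!r}"
            )
        if self.start < 1 or self.end < 1:
            raise ValidationError(f"{self.gene}: coordinates must be >= 1")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    def positions(self, genome_length: int) -> Iterable[int]:
        """Genome positions covered, 5'->3' on the H strand."""
        if self.wraps:
            yield from range(self.start, genome_length + 1)
            yield from range(1, self.end + 1)
        else:
            yield from range(self.start, self.end + 1)


def gene_offset(feature: GeneFeature, position: int, genome_length: int) -> int:
    """1-based offset of ``position`` from the feature's 5' end on its coding strand.

    For an H-strand gene the 5' end is ``start``; for an L-strand gene it is
    ``end`` (the gene reads rightward on the complementary strand, i.e.
    leftward in H-strand coordinates).
    """
    if not feature.contains(position):
        raise ValidationError(
            f"position {position} not inside feature {feature.gene}"
        )
    if feature.wraps:
        upstream = (
            position - feature.start
            if position >= feature.start
            else genome_length - feature.start + position
        )
    else:
        upstream = position - feature.start
    if feature.strand == "H":
        return upstream + 1
    return feature.length(genome_length) - upstream


@dataclass
class MtReference:
    """A circular mitochondrial reference sequence plus its gene features."""

    name: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - DNA_BASES
        if bad:
            raise ValidationError(
                f"reference {self.name}: disallowed characters {sorted(bad)} "
                "(N is not permitted in a reference)"
            )
        seen: set[str] = set()
        for f in self.features:
            if f.gene in seen:
                raise ValidationError(f"duplicate gene name {f.gene!r} in annotation")
            seen.add(f.gene)
            if f.start > self.length or f.end > self.length:
                raise ValidationError(
                    f"feature {f.gene} ({f.start}..{f.end}) outside [1, {self.length}]"
                )
        # stable lookup order: class priority, then start, then name
        self._ordered = sorted(
            self.features,
            key=lambda f: (CLASS_PRIORITY[f.feature_class], f.start, f.gene),
        )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        """Base at a 1-based position; wraps modulo length."""
        return self.sequence[(position - 1) % self.length]

    def feature_by_name(self, gene: str) -> GeneFeature:
        for f in self.features:
            if f.gene == gene:
                return f
        raise KeyError(gene)

    def feature_at(self, position: int) -> GeneFeature:
        """The single feature owning a position.

        Deterministic under the overlap-resolution order
        tRNA > rRNA > protein_coding > control_region, first-by-start;
        unannotated positions fall back to a synthesized intergenic feature.
        """
        if not 1 <= position <= self.length:
            raise ValidationError(
                f"position {position} outside [1, {self.length}]"
            )
        for f in self._ordered:
            if f.contains(position):
                return f
        return GeneFeature(
            gene="intergenic", start=position, end=position,
            strand="H", feature_class="intergenic",
        )


Source = Union[str, Path, io.TextIOBase]


def _open_text(source: Source):
    if isinstance(source, io.TextIOBase):
        return source, False
    return open(source, "rt"), True


def read_gene_map(source: Source) -> list[GeneFeature]:
    """Read a gene annotation TSV (gene, start, end, strand, feature_class).

    Lines starting with ``#`` are comments; ``end < start`` marks a feature
    wrapping the origin.
    """
    fh, close = _open_text(source)
    try:
        rows = [
            r for r in csv.DictReader(
                (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
            )
        ]
    finally:
        if close:
            fh.close()
    if not rows:
        raise ValidationError("empty gene map")
    feats = []
    for r in rows:
        try:
            feats.append(
                GeneFeature(
                    gene=r["gene"].strip(),
                    start=int(r["start"]),
                    end=int(r["end"]),
                    strand=r["strand"].strip(),
                    feature_class=r["feature_class"].strip(),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValidationError(f"bad gene map row {r!r}: {exc}") from exc
    return feats


def read_single_fasta(source: Source) -> tuple[str, str]:
    """Read exactly one record from a FASTA file; returns (name, sequence)."""
    fh, close = _open_text(source)
    try:
        records = list(SeqIO.parse(fh, "fasta"))
    finally:
        if close:
            fh.close()
    if len(records) != 1:
        raise ValidationError(
            f"expected exactly one FASTA record, found {len(records)}"
        )
    return records[0].id, str(records[0].seq).upper()


def load_reference(fasta_source: Source, annotation_source: Source) -> MtReference:
    """Load and validate a reference genome with its gene annotation."""
    name, seq = read_single_fasta(fasta_source)
    features = read_gene_map(annotation_source)
    return MtReference(name=name, sequence=seq, features=features)
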