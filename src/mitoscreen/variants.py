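"""Point-variant extraction, application, and annotation against the mtDNA reference.

Variants are stated on the H strand in reference orientation (``m.<pos>``
numbering). The table dialect used throughout writes a replacement as
``ref-alt`` (``T-C``), an insertion as an extended alt (``310 C-CC``), and an
optional amino-acid change in parentheses (``A-G(Thr112Ala)``).

Extraction uses a deterministic anchored scan suited to this variant model
(isolated substitutions plus short, well-separated indels): mismatches are
reported per position, and an indel is accepted only where the sequences
re-synchronize over a clean matching flank, then left-normalized VCF-style.
The result is verified by round-trip (re-applying it must reproduce the
sample); inputs that violate the model raise instead of guessing. Because
both genomes are linearized at the same origin, circularity needs no special
handling here.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

from .reference import (
    DNA_BASES,
    GeneFeature,
    MtReference,
    ValidationError,
    complement,
    gene_offset,
)

__all__ = [
    "Variant",
    "AnnotatedVariant",
    "AmbiguousRegionError",
    "extract_variants",
    "apply_variants",
    "annotate_variant",
    "classify_coding_effect",
    "partition_variants",
    "read_variant_table",
    "write_variant_table",
    "write_vcf",
    "parse_replacement",
]

#: NCBI translation table 2 (vertebrate mitochondrial).
MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

#: minimum matching flank around an indel for unambiguous placement
INDEL_FLANK = 10

#: longest indel the extraction scan will call
MAX_INDEL = 5


class AmbiguousRegionError(ValidationError):
    """Variants too densely clustered around an indel to place unambiguously."""


@dataclass(frozen=True)
class Variant:
    """A single mtDNA change in reference (H-strand) notation."""

    position: int
    ref: str
    alt: str
    homoplasmic: bool = True

    def __post_init__(self) -> None:
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or set(allele) - DNA_BASES - {"N"}:
                raise ValidationError(f"invalid {label} allele {allele!r}")
        if self.ref == self.alt:
            raise ValidationError("ref and alt alleles are identical")
        if len(self.ref) > 1 and len(self.alt) > 1:
            raise ValidationError(
                "complex substitutions are not supported; "
                f"got {self.ref}>{self.alt}"
            )

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "substitution"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def replacement(self) -> str:
        """Table-dialect spelling, e.g. ``T-C`` or ``C-CC``."""
        return f"{self.ref}-{self.alt}"

    def hgvs(self) -> str:
        if self.kind == "substitution":
            return f"m.{self.position}{self.ref}>{self.alt}"
        if self.kind == "insertion":
            return f"m.{self.position}{self.ref}>{self.alt}"
        return f"m.{self.position}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant plus its gene context and coding consequence."""

    variant: Variant
    gene: str
    feature_class: str
    gene_strand: str
    gene_strand_notation: str
    coding_effect: str  # non_coding | silent | missense | other
    aa_change: Optional[str] = None

    @property
    def position(self) -> int:
        return self.variant.position


# ---------------------------------------------------------------------------
# apply / extract


def apply_variants(reference: MtReference | str, variants: Sequence[Variant]) -> str:
    """Apply non-overlapping variants to the reference, returning the sample sequence.

    Ref alleles are checked against the reference; a mismatch signals a
    coordinate or dialect error and raises :class:`ValidationError`.
    """
    seq = reference.sequence if isinstance(reference, MtReference) else str(reference).upper()
    ordered = sorted(variants, key=lambda v: v.position)
    prev_end = 0
    for v in ordered:
        if v.position <= prev_end:
            raise ValidationError(f"overlapping variants at position {v.position}")
        prev_end = v.position + len(v.ref) - 1
        if v.position + len(v.ref) - 1 > len(seq):
            raise ValidationError(f"variant at {v.position} runs off the sequence")
        found = seq[v.position - 1 : v.position - 1 + len(v.ref)]
        if found != v.ref:
            raise ValidationError(
                f"ref allele mismatch at {v.position}: expected {v.ref}, "
                f"reference has {found}"
            )
    out = []
    cursor = 0
    for v in ordered:
        out.append(seq[cursor : v.position - 1])
        out.append(v.alt)
        cursor = v.position - 1 + len(v.ref)
    out.append(seq[cursor:])
    return "".join(out)


def _left_normalize(seq: str, pos: int, unit: str) -> tuple[int, str]:
    """Shift an inserted/deleted string leftward through repeats (VCF style).

    ``pos`` is the 1-based reference position *after which* the event occurs
    (for insertions) or the first event base (internally adjusted by caller).
    """
    while pos >= 1 and seq[pos - 1] == unit[-1]:
        unit = seq[pos - 1] + unit[:-1]
        pos -= 1
    return pos, unit


def extract_variants(sample_seq: str, reference: MtReference | str) -> list[Variant]:
    """Diff a complete sample genome against the reference.

    Returns variants sorted by position; applying them to the reference
    reproduces the sample exactly (verified before returning). Substitutions
    are reported per position (adjacent mismatches stay separate variants);
    an indel of up to ``MAX_INDEL`` bases is called only where the two
    sequences re-synchronize over ``INDEL_FLANK`` matching bases, is anchored
    on the reference base preceding the event and left-normalized, and must
    sit at least ``INDEL_FLANK`` bases from any other variant. Inputs
    violating this model raise :class:`AmbiguousRegionError`.
    """
    ref = reference.sequence if isinstance(reference, MtReference) else str(reference).upper()
    sample = sample_seq.upper()
    if set(sample) - DNA_BASES - {"N"}:
        raise ValidationError("sample contains non-DNA characters")

    if sample == ref:
        return []

    variants: list[Variant] = []
    i = 0  # 0-based cursor into reference
    j = 0  # 0-based cursor into sample
    while i < len(ref) and j < len(sample):
        if ref[i] == sample[j]:
            i += 1
            j += 1
            continue
        # mismatch: accept an indel only on a clean re-synchronization, else
        # treat it as a substitution (adjacent substitutions never resync an
        # indel interpretation over a full flank)
        called_indel = False
        for k in range(1, MAX_INDEL + 1):
            if sample[j + k : j + k + INDEL_FLANK] == ref[i : i + INDEL_FLANK]:
                inserted = sample[j : j + k]
                anchor, inserted = _left_normalize(ref, i, inserted)
                if anchor < 1:
                    raise AmbiguousRegionError(
                        "insertion normalizes past the origin; cannot anchor"
                    )
                if anchor < len(ref) and set(inserted) == {ref[anchor]}:
                    # duplication of the following base run: anchor on the
                    # run's first base, the table dialect's 310 C-CC form
                    variants.append(
                        Variant(
                            position=anchor + 1,
                            ref=ref[anchor],
                            alt=ref[anchor] + inserted,
                        )
                    )
                else:
                    variants.append(
                        Variant(
                            position=anchor,
                            ref=ref[anchor - 1],
                            alt=ref[anchor - 1] + inserted,
                        )
                    )
                j += k
                called_indel = True
                break
            if sample[j : j + INDEL_FLANK] == ref[i + k : i + k + INDEL_FLANK]:
                deleted = ref[i : i + k]
                anchor, deleted = _left_normalize(ref, i, deleted)
                if anchor < 1:
                    raise AmbiguousRegionError(
                        "deletion normalizes past the origin; cannot anchor"
                    )
                variants.append(
                    Variant(
                        position=anchor,
                        ref=ref[anchor - 1] + deleted,
                        alt=ref[anchor - 1],
                    )
                )
                i += k
                called_indel = True
                break
        if not called_indel:
            variants.append(Variant(position=i + 1, ref=ref[i], alt=sample[j]))
            i += 1
            j += 1
    if i < len(ref):  # trailing deletion
        if i == 0:
            raise AmbiguousRegionError("sample shorter than reference at the origin")
        variants.append(Variant(position=i, ref=ref[i - 1 :], alt=ref[i - 1]))
    elif j < len(sample):  # trailing insertion
        if i == 0:
            raise AmbiguousRegionError("sample longer than reference at the origin")
        variants.append(
            Variant(position=i, ref=ref[i - 1], alt=ref[i - 1] + sample[j:])
        )

    variants.sort(key=lambda v: v.position)
    _check_indel_separation(variants)
    if apply_variants(ref, variants) != sample:
        raise AmbiguousRegionError(
            "extraction does not round-trip; input violates the isolated-variant model"
        )
    return variants


def _check_indel_separation(variants: Sequence[Variant]) -> None:
    for i, v in enumerate(variants):
        if v.kind == "substitution":
            continue
        a1, a2 = v.position, v.position + len(v.ref) - 1
        for other in variants:
            if other is v:
                continue
            b1, b2 = other.position, other.position + len(other.ref) - 1
            if b1 > a2:
                gap = b1 - a2 - 1
            elif a1 > b2:
                gap = a1 - b2 - 1
            else:
                gap = 0
            if gap < INDEL_FLANK:
                raise AmbiguousRegionError(
                    f"indel at {v.position} within {INDEL_FLANK} bases of variant "
                    f"at {other.position}; region is ambiguous"
                )


# ---------------------------------------------------------------------------
# annotation


def classify_coding_effect(
    variant: Variant, feature: GeneFeature, reference: MtReference
) -> tuple[str, Optional[str]]:
    """Coding consequence of a substitution inside a protein-coding gene.

    Translation uses the vertebrate mitochondrial code. Returns
    ``(effect, aa_change)`` where effect is ``silent``, ``missense`` or
    ``other`` (indels, partial terminal codons, stop gain/loss). The
    amino-acid change uses three-letter codes with the 1-based codon index,
    e.g. ``Thr112Ala``.
    """
    if feature.feature_class != "protein_coding":
        raise ValidationError(f"{feature.gene} is not protein coding")
    if variant.kind != "substitution":
        return "other", None

    L = reference.length
    g0 = gene_offset(feature, variant.position, L)
    codon_idx = (g0 - 1) // 3  # 0-based
    off = (g0 - 1) % 3
    if 3 * (codon_idx + 1) > feature.length(L):
        return "other", None  # incomplete terminal codon

    positions = list(feature.positions(L))
    if feature.strand == "L":
        positions = positions[::-1]  # gene order runs rightward on the L strand

    codon_genome_pos = positions[3 * codon_idx : 3 * codon_idx + 3]
    fetch = (
        (lambda p: complement(reference.base_at(p)))
        if feature.strand == "L"
        else reference.base_at
    )
    ref_codon = "".join(fetch(p) for p in codon_genome_pos)

    gene_ref = variant.ref if feature.strand == "H" else complement(variant.ref)
    gene_alt = variant.alt if feature.strand == "H" else complement(variant.alt)
    if ref_codon[off] != gene_ref:
        raise ValidationError(
            f"ref allele mismatch in {feature.gene} codon {codon_idx + 1}: "
            f"codon {ref_codon} vs allele {gene_ref}"
        )
    alt_codon = ref_codon[:off] + gene_alt + ref_codon[off + 1 :]

    def translate(codon: str) -> str:
        if codon in MITO_TABLE.stop_codons:
            return "*"
        return MITO_TABLE.forward_table[codon]

    aa_ref, aa_alt = translate(ref_codon), translate(alt_codon)
    if aa_ref == aa_alt:
        return "silent", None
    if "*" in (aa_ref, aa_alt):
        return "other", None
    return "missense", f"{seq3(aa_ref)}{codon_idx + 1}{seq3(aa_alt)}"


def annotate_variant(variant: Variant, reference: MtReference) -> AnnotatedVariant:
    """Attach gene, feature class, gene-strand notation, and coding effect."""
    feature = reference.feature_at(variant.position)
    if feature.strand == "L" and variant.kind == "substitution":
        notation = f"m.{variant.position}{complement(variant.ref)}>{complement(variant.alt)}"
    else:
        notation = variant.hgvs()

    effect: str = "non_coding"
    aa_change: Optional[str] = None
    if feature.feature_class == "protein_coding":
        effect, aa_change = classify_coding_effect(variant, feature, reference)

    return AnnotatedVariant(
        variant=variant,
        gene=feature.gene,
        feature_class=feature.feature_class,
        gene_strand=feature.strand,
        gene_strand_notation=notation,
        coding_effect=effect,
        aa_change=aa_change,
    )


PARTITION_KEYS = ("D-loop", "MT-RNR1", "MT-RNR2", "tRNA", "silent", "missense", "other")


def partition_variants(annotated: Iterable[AnnotatedVariant]) -> dict[str, int]:
    """Partition annotated variants into the standard reporting categories.

    Categories are disjoint and exhaustive: control-region, the two rRNA
    genes, tRNA genes, then coding variants by effect (silent / missense /
    other, the last also collecting intergenic oddities). Counts sum to the
    input length.
    """
    counts = dict.fromkeys(PARTITION_KEYS, 0)
    for av in annotated:
        if av.feature_class == "control_region":
            counts["D-loop"] += 1
        elif av.feature_class == "rRNA":
            counts[av.gene] = counts.get(av.gene, 0) + 1
        elif av.feature_class == "tRNA":
            counts["tRNA"] += 1
        elif av.feature_class == "protein_coding":
            key = av.coding_effect if av.coding_effect in ("silent", "missense") else "other"
            counts[key] += 1
        else:
            counts["other"] += 1
    return counts


# ---------------------------------------------------------------------------
# table / VCF I/O

_REPL_RE = re.compile(
    r"^([ACGTN]+)-([ACGTN]+)(?:\(\s*([A-Za-z]{3}\d+[A-Za-z]{3})\s*\))?$"
)


def parse_replacement(text: str) -> tuple[str, str, Optional[str]]:
    """Parse a replacement cell like ``T-C``, ``C-CC`` or ``A-G(Thr112Ala)``."""
    m = _REPL_RE.match(text.replace(" ", ""))
    if not m:
        raise ValidationError(f"unparseable replacement {text!r}")
    return m.group(1), m.group(2), m.group(3)


@dataclass(frozen=True)
class VariantRecord:
    """One row of the variant table dialect."""

    gene: str
    variant: Variant
    previously_reported: bool
    aa_annotation: Optional[str] = None


def read_variant_table(source) -> list[VariantRecord]:
    """Read a variant table TSV (gene, position, replacement, ..., previously_reported).

    Blank gene cells continue the gene of the row above, mirroring the printed
    table layout.
    """
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        source = open(source, "rt")
        close = True
    try:
        reader = csv.DictReader(
            (ln for ln in source if not ln.startswith("#")), delimiter="\t"
        )
        records: list[VariantRecord] = []
        gene = ""
        for row in reader:
            gene = row["gene"].strip() or gene
            if not gene:
                raise ValidationError("first table row has an empty gene cell")
            ref, alt, aa = parse_replacement(row["replacement"])
            records.append(
                VariantRecord(
                    gene=gene,
                    variant=Variant(position=int(row["position"]), ref=ref, alt=alt),
                    previously_reported=row.get("previously_reported", "").strip().lower()
                    in ("yes", "y", "1", "true"),
                    aa_annotation=aa,
                )
            )
    finally:
        if close:
            source.close()
    if not records:
        raise ValidationError("empty variant table")
    return records


def write_variant_table(annotated: Sequence[AnnotatedVariant], out) -> None:
    """Write annotated variants as a TSV in the table dialect plus effect columns."""
    close = False
    if isinstance(out, (str, bytes)) or hasattr(out, "__fspath__"):
        out = open(out, "wt")
        close = True
    try:
        w = csv.writer(out, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["gene", "position", "replacement", "feature_class",
             "gene_strand_notation", "coding_effect", "aa_change"]
        )
        for av in annotated:
            w.writerow(
                [av.gene, av.position, av.variant.replacement, av.feature_class,
                 av.gene_strand_notation, av.coding_effect, av.aa_change or ""]
            )
    finally:
        if close:
            out.close()


def write_vcf(annotated: Sequence[AnnotatedVariant], reference: MtReference, out) -> None:
    """Write a minimal VCF v4.2 (CHROM=chrM, 1-based POS, gene/effect in INFO)."""
    close = False
    if isinstance(out, (str, bytes)) or hasattr(out, "__fspath__"):
        out = open(out, "wt")
        close = True
    try:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##contig=<ID=chrM,length={reference.length}>\n")
        out.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        out.write('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for av in sorted(annotated, key=lambda a: a.position):
            info = f"GENE={av.gene};EFFECT={av.coding_effect}"
            if av.aa_change:
                info += f";AA={av.aa_change}"
            out.write(
                f"chrM\t{av.position}\t.\t{av.variant.ref}\t{av.variant.alt}"
                f"\t.\tPASS\t{info}\n"
            )
    finally:
        if close:
            out.close()
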