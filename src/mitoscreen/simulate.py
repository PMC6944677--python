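"""Synthetic-data generators for every input the screening pipeline consumes.

The generators emulate the study's data regime with no downloads: a circular
~16.6 kb surrogate reference carrying the real gene coordinate map, sample
genomes built from a haplogroup backbone plus injected candidate variants
under strict maternal transmission, a control cohort with a configurable
candidate carrier frequency (106 subjects, frequency 0 by default), and
multi-species tRNA alignments with a set per-column conservation probability.

The surrogate reference is random DNA, *not* the true GenBank rCRS record.
It is made consistent with a supplied variant table: ref alleles are planted
at every variant position, the human tRNA-Cys gene sequence is embedded at
the MT-TC locus (reverse-complemented, as the gene is L-strand encoded), and
codon contexts at coding variant sites are solved from the table's silent /
missense annotations under the vertebrate mitochondrial code — so coding
effects classified from the surrogate's sequence reproduce the annotated
ones. Every generator is a pure function of (config, seed): one independent
seed stream per sub-generator, so adding a generator never perturbs another's
output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from Bio.SeqUtils import seq3

from .clinical import Pedigree
from .reference import (
    GeneFeature,
    MtReference,
    ValidationError,
    complement,
    reverse_complement,
)
from .trna import TrnaAlignment, TrnaStructure, canonical_cloverleaf
from .variants import MITO_TABLE, Variant, VariantRecord

__all__ = [
    "SimulationConfig",
    "generate_reference",
    "generate_pedigree_genomes",
    "generate_controls",
    "generate_alignment",
]

_BASES = np.array(list("ACGT"))

# fixed stream ids so each sub-generator has its own reproducible stream
_STREAM_REFERENCE = 1
_STREAM_CONTROLS = 2
_STREAM_ALIGNMENT = 3
_STREAM_PEDIGREE = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults: 16,569 b genome, 106 controls, candidate
    absent from controls, 17 alignment species."""

    seed: int = 0
    genome_length: int = 16569
    n_controls: int = 106
    control_carrier_freq: float = 0.0
    backbone_carrier_freq: float = 1.0
    alignment_species: int = 17
    per_column_match_prob: Union[float, Mapping[str, float]] = 0.75

    def __post_init__(self) -> None:
        for p in (self.control_carrier_freq, self.backbone_carrier_freq):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.genome_length < 1 or self.n_controls < 0:
            raise ValidationError("sizes must be positive")

    def match_prob(self, domain: str) -> float:
        if isinstance(self.per_column_match_prob, Mapping):
            return float(self.per_column_match_prob.get(domain, 0.75))
        return float(self.per_column_match_prob)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# surrogate reference


def _feature_for(features: Sequence[GeneFeature], gene: str) -> GeneFeature:
    for f in features:
        if f.gene == gene:
            return f
    raise ValidationError(f"gene {gene!r} not in the gene map")


def _gene_position_to_genome(f: GeneFeature, offset0: int, length: int) -> int:
    """Genome position of the 0-based ``offset0``-th base of a (non-wrapping)
    coding gene, on its coding strand."""
    if f.strand == "H":
        return f.start + offset0
    return f.end - offset0


def _parse_aa(annotation: str) -> tuple[str, int, str]:
    i = 3
    j = len(annotation) - 3
    return annotation[:3], int(annotation[3:j]), annotation[j:]


def _translate(codon: str) -> Optional[str]:
    if codon in MITO_TABLE.stop_codons:
        return None
    return MITO_TABLE.forward_table[codon]


def _solve_codon(constraints) -> str:
    """First codon (lexicographic) satisfying all (off, ref, alt, expect)
    constraints; expect is 'silent' or an (aa_ref, aa_alt) three-letter pair."""
    for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
        aa = _translate(codon)
        if aa is None:
            continue
        ok = True
        for off, g_ref, g_alt, expect in constraints:
            if codon[off] != g_ref:
                ok = False
                break
            mutated = codon[:off] + g_alt + codon[off + 1 :]
            aa_mut = _translate(mutated)
            if aa_mut is None:
                ok = False
                break
            if expect == "silent":
                if aa_mut != aa:
                    ok = False
                    break
            else:
                if (seq3(aa), seq3(aa_mut)) != expect:
                    ok = False
                    break
        if ok:
            return codon
    raise ValidationError(f"no codon satisfies constraints {constraints}")


def surrogate_reference(
    config: SimulationConfig,
    records: Sequence[VariantRecord],
    features: Sequence[GeneFeature],
    trna_genes: Optional[Mapping[str, str]] = None,
    name: str = "synthetic_mtdna_surrogate",
) -> MtReference:
    """Seed-deterministic synthetic reference consistent with a variant table.

    The background is random DNA; positions touched by the table (ref
    alleles, codon contexts for coding substitutions, tRNA gene embeddings,
    indel flanks) are pinned so that applying the table's variants and
    re-analyzing the result reproduces the table's annotations exactly.
    This is a synthetic stand-in, not the GenBank reference record.
    """
    L = config.genome_length
    rng = _rng(config, _STREAM_REFERENCE)
    seq = rng.choice(_BASES, size=L)

    pinned: dict[int, str] = {}  # 1-based position -> base

    def pin(pos: int, base: str, why: str) -> None:
        pos = (pos - 1) % L + 1
        prev = pinned.get(pos)
        if prev is not None and prev != base:
            raise ValidationError(
                f"conflicting constraints at {pos}: {prev} vs {base} ({why})"
            )
        pinned[pos] = base

    # embed tRNA genes (reverse-complemented for L-strand genes)
    for gene, gene_seq in (trna_genes or {}).items():
        f = _feature_for(features, gene)
        h_segment = reverse_complement(gene_seq) if f.strand == "L" else gene_seq
        if len(h_segment) != f.length(L):
            raise ValidationError(
                f"{gene}: sequence length {len(h_segment)} != feature span {f.length(L)}"
            )
        for pos, base in zip(f.positions(L), h_segment):
            pin(pos, base, gene)

    # classify each record as coding / plain by the gene map
    codon_constraints: dict[tuple[str, int], list] = {}
    for rec in records:
        v = rec.variant
        f = next((x for x in features if x.gene == rec.gene), None)
        if f is None:
            raise ValidationError(f"record gene {rec.gene!r} not in gene map")
        if f.feature_class == "protein_coding" and v.kind == "substitution":
            if f.strand == "H":
                g0 = v.position - f.start  # 0-based gene offset (non-wrapping CDS)
                g_ref, g_alt = v.ref, v.alt
            else:
                g0 = f.end - v.position
                g_ref, g_alt = complement(v.ref), complement(v.alt)
            codon_idx, off = divmod(g0, 3)
            if rec.aa_annotation:
                aa_ref, aa_pos, aa_alt = _parse_aa(rec.aa_annotation)
                if aa_pos != codon_idx + 1:
                    raise ValidationError(
                        f"{rec.gene} {v.position}: annotation codon {aa_pos} "
                        f"!= map-derived codon {codon_idx + 1}"
                    )
                expect = (aa_ref, aa_alt)
            else:
                expect = "silent"
            codon_constraints.setdefault((rec.gene, codon_idx), []).append(
                (off, g_ref, g_alt, expect)
            )
        else:
            pin(v.position, v.ref[0], f"ref allele of {v.position}")
            if v.kind == "insertion":
                # keep indel placement unambiguous: the base left of the anchor
                # must differ from the inserted run
                inserted_last = v.alt[len(v.ref) :][-1]
                left = (v.position - 2) % L + 1  # base immediately left of the anchor
                choices = [b for b in "ACGT" if b != inserted_last]
                if left not in pinned:
                    pin(left, choices[int(rng.integers(len(choices)))], "indel flank")
                elif pinned[left] == inserted_last:
                    raise ValidationError(f"cannot disambiguate indel at {v.position}")

    for (gene, codon_idx), constraints in sorted(codon_constraints.items()):
        f = _feature_for(features, gene)
        codon = _solve_codon(constraints)
        for k, base in enumerate(codon):
            pos = _gene_position_to_genome(f, 3 * codon_idx + k, L)
            pin(pos, base if f.strand == "H" else complement(base), f"{gene} codon")

    for pos, base in pinned.items():
        seq[pos - 1] = base

    return MtReference(name=name, sequence="".join(seq), features=list(features))


def generate_reference(
    config: SimulationConfig,
    records: Optional[Sequence[VariantRecord]] = None,
    features: Optional[Sequence[GeneFeature]] = None,
) -> MtReference:
    """Generate the surrogate reference under study conditions.

    With no arguments beyond the config, uses the bundled gene map, variant
    table, and human tRNA-Cys gene, which together define the study's data
    regime; pass explicit records/features for custom scenarios.
    """
    from . import data as _data  # local import to keep module load light

    if features is None:
        features = _data.gene_map()
    if records is None:
        records = _data.variant_table()
    return surrogate_reference(
        config, records, features, trna_genes={"MT-TC": _data.human_trna_cys_gene()}
    )


# ---------------------------------------------------------------------------
# cohorts and pedigrees


def generate_controls(
    config: SimulationConfig,
    reference: MtReference,
    backbone: Sequence[Variant],
    candidate: Sequence[Variant],
) -> tuple[list[str], list[bool]]:
    """Control-cohort genomes; returns (genomes, candidate-carrier flags).

    Each subject carries the haplogroup backbone with probability
    ``backbone_carrier_freq`` (default 1: a regionally matched cohort) and the
    candidate variants with probability ``control_carrier_freq`` (default 0,
    the study condition). Carrier counts are Binomial(n, freq).
    """
    from .variants import apply_variants

    rng = _rng(config, _STREAM_CONTROLS)
    genomes: list[str] = []
    flags: list[bool] = []
    for _ in range(config.n_controls):
        has_backbone = rng.random() < config.backbone_carrier_freq
        has_candidate = rng.random() < config.control_carrier_freq
        variants = (list(backbone) if has_backbone else []) + (
            list(candidate) if has_candidate else []
        )
        genomes.append(apply_variants(reference, variants))
        flags.append(has_candidate)
    return genomes, flags


def generate_pedigree_genomes(
    config: SimulationConfig,
    pedigree: Pedigree,
    reference: MtReference,
    backbone: Sequence[Variant],
    candidate: Sequence[Variant],
) -> tuple[dict[str, str], dict[str, set]]:
    """Genomes for every pedigree member under strict maternal transmission.

    Members flagged as carriers in the pedigree (matrilineal descendants of a
    carrier founder) receive backbone + candidate variants; everyone else
    receives the backbone only (one shared regional haplogroup). Homoplasmy
    makes transmission deterministic, so two children of one mother have
    identical mtDNA. Returns (genomes, injected-variant bookkeeping).
    """
    from .variants import apply_variants

    genomes: dict[str, str] = {}
    truth: dict[str, set] = {}
    backbone_seq = apply_variants(reference, list(backbone))
    carrier_seq = apply_variants(reference, list(backbone) + list(candidate))
    backbone_keys = {(v.position, v.ref, v.alt) for v in backbone}
    carrier_keys = backbone_keys | {(v.position, v.ref, v.alt) for v in candidate}
    for member in pedigree.members:
        if member in pedigree.carriers:
            genomes[member] = carrier_seq
            truth[member] = set(carrier_keys)
        else:
            genomes[member] = backbone_seq
            truth[member] = set(backbone_keys)
    return genomes, truth


# ---------------------------------------------------------------------------
# alignments


def generate_alignment(
    config: SimulationConfig,
    structure: Optional[TrnaStructure] = None,
    human_blocks: Optional[Mapping[str, str]] = None,
) -> TrnaAlignment:
    """Multi-species tRNA alignment with controlled per-column conservation.

    The human row is the bundled tRNA-Cys block layout unless supplied; each
    of the other ``alignment_species - 1`` rows matches the human base at
    every column independently with the domain's match probability, otherwise
    carrying a uniformly random different base. Block widths equal the
    human row's, so stem blocks stay fixed-width by construction.
    """
    structure = structure or canonical_cloverleaf()
    if human_blocks is None:
        from . import data as _data

        bundled = _data.trna_cys_alignment()
        human_blocks = {
            d.name: bundled.blocks[d.name][bundled.human_row]
            for d in structure.domains
        }
    rng = _rng(config, _STREAM_ALIGNMENT)
    n_other = config.alignment_species - 1
    species = ["Homo sapiens"] + [f"Species {i + 1:02d}" for i in range(n_other)]
    blocks: dict[str, list[str]] = {}
    for d in structure.domains:
        human_cell = human_blocks[d.name]
        p = config.match_prob(d.name)
        rows = [human_cell]
        for _ in range(n_other):
            out = []
            for base in human_cell:
                if rng.random() < p:
                    out.append(base)
                else:
                    others = [b for b in "ACGT" if b != base]
                    out.append(others[int(rng.integers(3))])
            rows.append("".join(out))
        blocks[d.name] = rows
    return TrnaAlignment(species=species, blocks=blocks, structure=structure)
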