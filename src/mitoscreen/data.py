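"""Accessors for the data files bundled with the package.

These are small plain-text fixtures: the standard human mtDNA gene coordinate
map, the proband variant table, the 17-species tRNA-Cys domain alignment, and
demo-only marker/cutoff/pedigree tables (demo files are labeled as such in
their headers and are illustrative, not curated references).
"""

from __future__ import annotations

from importlib.resources import files

from .clinical import BmiCutoffs, Pedigree, SubjectRecord, load_bmi_cutoffs, read_pedigree, read_subject_table
from .haplogroup import MarkerDB, load_marker_db
from .reference import GeneFeature, read_gene_map
from .trna import TrnaAlignment, parse_domain_alignment
from .variants import VariantRecord, read_variant_table

_DATA = files("mitoscreen") / "data"


def data_path(name: str) -> str:
    return str(_DATA / name)


def gene_map() -> list[GeneFeature]:
    """The standard human mtDNA gene coordinate map (rCRS numbering)."""
    return read_gene_map(data_path("human_mtdna_gene_map.tsv"))


def variant_table() -> list[VariantRecord]:
    """The proband's 47-variant table in the replacement dialect."""
    return read_variant_table(data_path("hzf001_mtdna_variants.tsv"))


def trna_cys_alignment() -> TrnaAlignment:
    """The 17-species tRNA-Cys block alignment."""
    return parse_domain_alignment(data_path("trna_cys_alignment_17species.tsv"))


def human_trna_cys_gene() -> str:
    """Human mitochondrial tRNA-Cys gene sequence (5'->3', gene orientation)."""
    return trna_cys_alignment().human_sequence()


def demo_marker_db() -> MarkerDB:
    return load_marker_db(data_path("demo_haplogroup_markers.json"))


def demo_bmi_cutoffs() -> BmiCutoffs:
    return load_bmi_cutoffs(data_path("demo_bmi_cutoffs.tsv"))


def family_subjects() -> list[SubjectRecord]:
    return read_subject_table(data_path("family_subjects.tsv"))


def demo_pedigree() -> Pedigree:
    return read_pedigree(data_path("demo_pedigree.tsv"))
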