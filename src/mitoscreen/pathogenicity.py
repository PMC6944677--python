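"""Three-criterion candidate-mutation filter and control-cohort statistics.

A variant is a *candidate* pathogenic mutation when it simultaneously
(1) occurs in fewer than 1% of control subjects, (2) shows evolutionary
conservation above 75% at its position, and (3) can plausibly alter the tRNA
secondary structure (it sits in a paired stem or in the anticodon loop).
Thresholds are strict inequalities and configurable. A variant for which a
criterion's input is unavailable (e.g. conservation outside the aligned tRNA)
is *indeterminate* unless another criterion already fails.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .reference import MtReference, ValidationError
from .trna import TrnaAlignment, TrnaStructure, conservation_index, genome_to_trna_position
from .variants import AnnotatedVariant, Variant

__all__ = [
    "PathogenicityReport",
    "ScreenThresholds",
    "control_frequency",
    "fisher_exact",
    "structural_flag",
    "classify_pathogenicity",
    "screen_variants",
    "write_screen_report",
]


@dataclass(frozen=True)
class ScreenThresholds:
    control_freq_pct: float = 1.0   # criterion 1: control frequency < this
    ci_pct: float = 75.0            # criterion 2: conservation index > this

    def __post_init__(self) -> None:
        if self.control_freq_pct <= 0 or self.ci_pct <= 0:
            raise ValidationError("thresholds must be positive")


def control_frequency(carriers: int, n_controls: int) -> float:
    """Carrier frequency in the control cohort, as a percentage."""
    if n_controls <= 0:
        raise ValidationError("n_controls must be positive")
    if not 0 <= carriers <= n_controls:
        raise ValidationError("carriers must lie in [0, n_controls]")
    return 100.0 * carriers / n_controls


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test for the 2x2 table [[a, b], [c, d]].

    The p-value is the sum of hypergeometric probabilities of all tables with
    the same margins whose probability does not exceed the observed table's
    (the usual ≤-probable-tables convention).
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValidationError("all-zero table")
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, row1, col1)
    cutoff = pmf[a - lo] * (1 + 1e-7)  # relative slack for float ties
    p = float(pmf[pmf <= cutoff].sum())
    return min(p, 1.0)


def structural_flag(trna_position: int, structure: TrnaStructure) -> bool:
    """True when the position sits in a paired stem or the anticodon loop."""
    if structure.is_paired(trna_position):
        return True
    return structure.domain_of(trna_position).name == "anticodon_loop"


@dataclass(frozen=True)
class PathogenicityReport:
    variant: AnnotatedVariant
    control_carriers: int
    control_n: int
    control_freq: float
    freq_criterion: bool
    ci_value: Optional[float]
    conservation_criterion: Optional[bool]
    trna_position: Optional[int]
    structural_criterion: Optional[bool]
    verdict: str  # candidate | not_candidate | indeterminate
    fisher_p: Optional[float] = None


def classify_pathogenicity(
    variant: AnnotatedVariant,
    control_carriers: int,
    control_n: int,
    ci_value: Optional[float] = None,
    trna_position: Optional[int] = None,
    structural: Optional[bool] = None,
    thresholds: ScreenThresholds = ScreenThresholds(),
    fisher_p: Optional[float] = None,
) -> PathogenicityReport:
    """Combine the three criteria into a verdict.

    Any criterion that is False forces ``not_candidate``; otherwise a missing
    criterion input yields ``indeterminate``; all three True yields
    ``candidate``.
    """
    freq = control_frequency(control_carriers, control_n)
    crit1 = freq < thresholds.control_freq_pct
    crit2 = None if ci_value is None else ci_value > thresholds.ci_pct
    crit3 = structural

    if crit1 is False or crit2 is False or crit3 is False:
        verdict = "not_candidate"
    elif crit2 is None or crit3 is None:
        verdict = "indeterminate"
    else:
        verdict = "candidate"

    return PathogenicityReport(
        variant=variant,
        control_carriers=control_carriers,
        control_n=control_n,
        control_freq=freq,
        freq_criterion=crit1,
        ci_value=ci_value,
        conservation_criterion=crit2,
        trna_position=trna_position,
        structural_criterion=crit3,
        verdict=verdict,
        fisher_p=fisher_p,
    )


def screen_variants(
    annotated: Sequence[AnnotatedVariant],
    control_variant_sets: Sequence[set[tuple[int, str, str]]],
    reference: MtReference,
    alignment: Optional[TrnaAlignment] = None,
    thresholds: ScreenThresholds = ScreenThresholds(),
    with_fisher: bool = False,
) -> list[PathogenicityReport]:
    """Run the full three-criterion screen over annotated variants.

    ``control_variant_sets`` holds one ``{(pos, ref, alt), ...}`` set per
    control subject; carrier counts and the frequency criterion come from
    them. Conservation and structure are evaluated only for variants inside
    a tRNA gene covered by ``alignment``.
    """
    n = len(control_variant_sets)
    if n == 0:
        raise ValidationError("empty control cohort")
    reports = []
    structure = alignment.structure if alignment is not None else None
    for av in annotated:
        key = (av.position, av.variant.ref, av.variant.alt)
        carriers = sum(key in s for s in control_variant_sets)
        ci_value = None
        trna_pos = None
        structural = None
        if av.feature_class == "tRNA" and alignment is not None:
            feature = reference.feature_by_name(av.gene)
            trna_pos = genome_to_trna_position(reference, feature, av.position, alignment)
            ci_value = conservation_index(alignment, trna_pos)
            structural = structural_flag(trna_pos, structure)
        fp = None
        if with_fisher:
            # carrier vs non-carrier counts, proband (1 subject) vs controls
            fp = fisher_exact(1, 0, carriers, n - carriers)
        reports.append(
            classify_pathogenicity(
                av, carriers, n,
                ci_value=ci_value, trna_position=trna_pos,
                structural=structural, thresholds=thresholds, fisher_p=fp,
            )
        )
    return reports


def write_screen_report(reports: Iterable[PathogenicityReport], out) -> None:
    """One TSV row per variant with all criterion fields, then a summary block."""
    close = False
    if isinstance(out, (str, bytes)) or hasattr(out, "__fspath__"):
        out = open(out, "wt")
        close = True
    try:
        w = csv.writer(out, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["gene", "position", "replacement", "notation", "control_carriers",
             "control_n", "control_freq_pct", "freq_criterion", "trna_position",
             "ci_pct", "conservation_criterion", "structural_criterion",
             "fisher_p", "verdict"]
        )
        candidates = []
        for r in reports:
            av = r.variant
            if r.verdict == "candidate":
                candidates.append(av.gene_strand_notation)
            fmt = lambda x: "" if x is None else x
            w.writerow(
                [av.gene, av.position, av.variant.replacement,
                 av.gene_strand_notation, r.control_carriers, r.control_n,
                 f"{r.control_freq:.2f}", r.freq_criterion, fmt(r.trna_position),
                 "" if r.ci_value is None else f"{r.ci_value:.2f}",
                 fmt(r.conservation_criterion), fmt(r.structural_criterion),
                 "" if r.fisher_p is None else f"{r.fisher_p:.4g}", r.verdict]
            )
        w.writerow([])
        w.writerow(["# candidates", ";".join(candidates) or "none"])
    finally:
        if close:
            out.close()
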