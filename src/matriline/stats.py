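"""Maternal-line statistics: reference population, haplotype imputation and
per-founder-dam distributions.

Imputation propagates each line's (unique) observed haplotype to every member
of the line; it refuses to run while haplotype conflicts exist, because a
conflicted line has no well-defined haplotype.  Lines with no sequenced member
stay unassigned — the effective-size module later gives them unique
pseudo-haplotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import ConflictError
from .forest import UniparentalForest, build_forest
from .pedigree_io import Gender, Pedigree, ReferenceWindow
from .verify import has_conflicts


def reference_population(p: Pedigree, w: ReferenceWindow) -> set[str]:
    """Ids of individuals born inside the (inclusive) window.  Individuals
    without a recorded birth year are never in the reference population."""
    refpop = {r.id for r in p if r.yob in w}
    if not refpop:
        warnings.warn(
            f"reference population is empty for window "
            f"{w.first_year}-{w.last_year}; effective sizes are undefined",
            stacklevel=2,
        )
    return refpop


def impute_haplotypes(
    f: UniparentalForest, p: Pedigree, *, check_conflicts: bool = True
) -> dict[str, str | None]:
    """Map every individual to its maternal line's haplotype (``None`` for
    lines with no sequenced member).

    Raises :class:`ConflictError` when any line carries two distinct
    haplotypes; run the verification step and fix the pedigree first.
    """
    if check_conflicts and has_conflicts(f, p):
        raise ConflictError(
            "haplotype conflicts present in maternal lines; "
            "run the verif step and resolve them before imputation"
        )
    line_hap: dict[str, str] = {}
    for r in p:
        if r.haplotype is not None:
            line_hap.setdefault(f.line_of[r.id], r.haplotype)
    return {ind: line_hap.get(root) for ind, root in f.line_of.items()}


@dataclass
class LineStats:
    total: int = 0
    females_in_ref: int = 0
    all_in_ref: int = 0
    haplotype: str | None = None  # imputed line haplotype, None = unassigned


@dataclass
class LineDistribution:
    """Per-founder-dam membership counts plus the split of reference-
    represented lines into those with females in the reference population and
    those represented only by males (the latter drop out of the maternal-line
    effective size but still count for haplotype lines)."""

    per_line: dict[str, LineStats]
    lines_with_females_in_ref: list[str] = field(default_factory=list)
    lines_with_only_males_in_ref: list[str] = field(default_factory=list)
    ref_size: int = 0
    ref_females: int = 0


def line_distributions(
    f: UniparentalForest,
    p: Pedigree,
    refpop: set[str],
    imputed: dict[str, str | None] | None = None,
) -> LineDistribution:
    """Count, per founder dam: total descendants, descendants in the reference
    population, and female descendants in the reference population."""
    if imputed is None:
        imputed = impute_haplotypes(f, p)
    per_line: dict[str, LineStats] = {root: LineStats() for root in f.roots}
    ref_females = 0
    for r in p:
        st = per_line[f.line_of[r.id]]
        st.total += 1
        if r.id in refpop:
            st.all_in_ref += 1
            if r.gender is Gender.FEMALE:
                st.females_in_ref += 1
                ref_females += 1
    for root, st in per_line.items():
        st.haplotype = imputed.get(root)
    with_females = sorted(
        root for root, st in per_line.items() if st.females_in_ref > 0
    )
    only_males = sorted(
        root
        for root, st in per_line.items()
        if st.all_in_ref > 0 and st.females_in_ref == 0
    )
    return LineDistribution(
        per_line=per_line,
        lines_with_females_in_ref=with_females,
        lines_with_only_males_in_ref=only_males,
        ref_size=len(refpop),
        ref_females=ref_females,
    )


def run_stat(
    p: Pedigree, window: ReferenceWindow
) -> tuple[UniparentalForest, set[str], dict[str, str | None], LineDistribution]:
    """Convenience pipeline: forest → refpop → imputation → distributions."""
    f = build_forest(p)
    refpop = reference_population(p, window)
    imputed = impute_haplotypes(f, p)
    dist = line_distributions(f, p, refpop, imputed)
    return f, refpop, imputed, dist
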