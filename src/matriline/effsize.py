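"""Effective population sizes of uniparental lines via probability of identity.

For a system of uniparental lines (maternal, mtDNA-haplotype or paternal) the
probability of identity is PI = Σ q² over line (or haplotype) frequencies q.
In the founder population the k founder lines are equifrequent, q = 1/k.  In
the reference population the maternal frequencies are female descendant counts
per founder dam over all reference females; haplotype frequencies count all
reference individuals (both sexes) per imputed haplotype.  The increase in
identity

    ΔPI = (PI_r − PI_f) / (1 − PI_f)

measures drift from founders to the reference population, and the effective
size is Ne = 1/ΔPI (infinite when ΔPI = 0, i.e. no drift).

Founder lines with no sequenced member get deterministic unique
pseudo-haplotypes ``PSEUDO_<rootID>`` so that unknown lines never spuriously
merge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .errors import UndefinedResultError
from .forest import UniparentalForest, build_forest
from .pedigree_io import Gender, Pedigree
from .stats import impute_haplotypes

INFINITE = math.inf


@dataclass
class EffectiveSizeResult:
    mode: str  # "maternal" | "haplotype" | "paternal"
    frequencies_founder: dict[str, float]
    frequencies_reference: dict[str, float]
    pi_founder: float
    pi_reference: float
    delta_pi: float | None
    ne: float | None  # math.inf when delta_pi == 0; None when undefined
    undefined_reason: str | None = None


def pi(frequencies: Mapping[str, float]) -> float:
    """Probability of identity: the sum of squared frequencies.  Equals 1/k
    for k uniform labels."""
    if not frequencies:
        raise UndefinedResultError("probability of identity of an empty frequency map")
    total = sum(frequencies.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {total!r}")
    return sum(q * q for q in frequencies.values())


def delta_pi(pi_f: float, pi_r: float) -> float:
    """Relative increase in identity from founder to reference population."""
    if pi_f >= 1.0:
        raise UndefinedResultError(
            "founder probability of identity is 1 (single founder line); "
            "identity increase is undefined"
        )
    return (pi_r - pi_f) / (1.0 - pi_f)


def effective_size(delta: float) -> float:
    """Ne = 1/ΔPI; infinite when there is no identity increase."""
    if delta < 0:
        raise ValueError(
            f"negative identity increase ({delta!r}): reference and founder "
            "populations are inconsistent"
        )
    if delta == 0:
        return INFINITE
    return 1.0 / delta


def _sex_frequencies(
    f: UniparentalForest, p: Pedigree, refpop: set[str], sex: Gender
) -> tuple[dict[str, float], dict[str, float]]:
    founder = {root: 1.0 / len(f.roots) for root in f.roots}
    counts: dict[str, int] = {}
    total = 0
    for ind in refpop:
        r = p.record(ind)
        if r.gender is sex:
            root = f.line_of[ind]
            counts[root] = counts.get(root, 0) + 1
            total += 1
    if total == 0:
        label = "females" if sex is Gender.FEMALE else "males"
        raise UndefinedResultError(
            f"no {label} in the reference population; line effective size undefined"
        )
    reference = {root: c / total for root, c in counts.items()}
    return founder, reference


def maternal_frequencies(
    f: UniparentalForest, p: Pedigree, refpop: set[str]
) -> tuple[dict[str, float], dict[str, float]]:
    """Founder map: uniform over the k founder dams.  Reference map: female
    descendant counts per founder dam over all reference females."""
    return _sex_frequencies(f, p, refpop, Gender.FEMALE)


def pseudo_haplotype(root: str) -> str:
    return f"PSEUDO_{root}"


def haplotype_frequencies(
    f: UniparentalForest,
    p: Pedigree,
    refpop: set[str],
    imputed: dict[str, str | None],
) -> tuple[dict[str, float], dict[str, float]]:
    """Founder map: haplotype frequencies among founder lines, unknown lines
    carrying unique pseudo-haplotypes.  Reference map: imputed-haplotype
    frequencies over all reference individuals, both sexes."""
    if not refpop:
        raise UndefinedResultError("empty reference population")

    def label(root: str) -> str:
        h = imputed.get(root)
        return h if h is not None else pseudo_haplotype(root)

    founder_counts: dict[str, int] = {}
    for root in f.roots:
        h = label(root)
        founder_counts[h] = founder_counts.get(h, 0) + 1
    k = len(f.roots)
    founder = {h: c / k for h, c in founder_counts.items()}

    ref_counts: dict[str, int] = {}
    for ind in refpop:
        h = label(f.line_of[ind])
        ref_counts[h] = ref_counts.get(h, 0) + 1
    reference = {h: c / len(refpop) for h, c in ref_counts.items()}
    return founder, reference


def _assemble(
    mode: str, founder: dict[str, float], reference: dict[str, float]
) -> EffectiveSizeResult:
    pi_f = pi(founder)
    pi_r = pi(reference)
    try:
        d = delta_pi(pi_f, pi_r)
        ne = effective_size(d)
        reason = None
    except UndefinedResultError as exc:
        d, ne, reason = None, None, str(exc)
    return EffectiveSizeResult(
        mode=mode,
        frequencies_founder=founder,
        frequencies_reference=reference,
        pi_founder=pi_f,
        pi_reference=pi_r,
        delta_pi=d,
        ne=ne,
        undefined_reason=reason,
    )


def maternal_effective_size(
    p: Pedigree, refpop: set[str], f: UniparentalForest | None = None
) -> EffectiveSizeResult:
    if f is None:
        f = build_forest(p)
    founder, reference = maternal_frequencies(f, p, refpop)
    return _assemble("maternal", founder, reference)


def haplotype_effective_size(
    p: Pedigree,
    refpop: set[str],
    f: UniparentalForest | None = None,
    imputed: dict[str, str | None] | None = None,
) -> EffectiveSizeResult:
    if f is None:
        f = build_forest(p)
    if imputed is None:
        imputed = impute_haplotypes(f, p)  # raises ConflictError on conflicts
    founder, reference = haplotype_frequencies(f, p, refpop, imputed)
    return _assemble("haplotype", founder, reference)


def paternal_effective_size(
    p: Pedigree, refpop: set[str], f: UniparentalForest | None = None
) -> EffectiveSizeResult:
    """Symmetric calculation on father links: founder sires, reference males."""
    if f is None or f.parent_link != "sire":
        f = build_forest(p, parent_link="sire")
    founder, reference = _sex_frequencies(f, p, refpop, Gender.MALE)
    return _assemble("paternal", founder, reference)
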