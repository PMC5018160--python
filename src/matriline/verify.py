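"""Haplotype-concordance verification of maternal lines.

All members of a maternal line inherit the same mtDNA haplotype, so two
sequenced same-line individuals with different haplotypes (a *conflicting
pair*) expose a pedigree recording error.  This module finds conflicting
pairs, attributes conflicts to individuals, locates *misplaced* branches
(whole subtrees recorded under the wrong line) and summarizes pedigree
reliability with three indices:

HC        percentage of conflicting individuals among all haplotyped ones,
IC        percentage of conflicting individuals among *informative* ones
          (individuals lying on a tree path between two haplotyped ones),
MISPLACED percentage of misplaced individuals among conflicting ones.

The *pruned* conflict count reduces each misplaced branch to a single error.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .forest import UniparentalForest, build_forest, nearest_haplotyped_ancestor
from .pedigree_io import Pedigree

Pair = tuple[str, str]


@dataclass
class ConflictReport:
    conflicting_pairs: set[Pair]
    conflict_count: dict[str, int]
    conflicting_individuals: set[str]
    informative_individuals: set[str]
    misplaced_individuals: set[str]
    misplaced_branches: list[tuple[str, int]]  # (branch root, conflicts inside)
    n_haplotyped: int
    hc_index: float | None
    ic_index: float | None
    misplaced_index: float | None
    pruned_conflicts: int
    undefined: dict[str, str] = field(default_factory=dict)

    @property
    def has_conflicts(self) -> bool:
        return bool(self.conflicting_individuals) or bool(self.conflicting_pairs)


def _haplotyped_by_line(f: UniparentalForest, p: Pedigree) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for r in p:
        if r.haplotype is not None:
            out.setdefault(f.line_of[r.id], []).append(r.id)
    return out


def find_conflicting_pairs(f: UniparentalForest, p: Pedigree) -> set[Pair]:
    """All unordered pairs of same-line haplotyped individuals whose haplotypes
    differ.  Pairs are stored with lexicographically sorted members."""
    pairs: set[Pair] = set()
    for members in _haplotyped_by_line(f, p).values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                if p.record(i).haplotype != p.record(j).haplotype:
                    pairs.add((i, j) if i < j else (j, i))
    return pairs


def conflict_counts(f: UniparentalForest, p: Pedigree) -> dict[str, int]:
    """Pairwise-conflict count per haplotyped individual, computed from
    per-line haplotype tallies (no pair enumeration)."""
    counts: dict[str, int] = {}
    for members in _haplotyped_by_line(f, p).values():
        tally = Counter(p.record(i).haplotype for i in members)
        total = len(members)
        for i in members:
            c = total - tally[p.record(i).haplotype]
            if c:
                counts[i] = c
    return counts


def flag_conflicting_individuals(
    pairs: set[Pair], conflict_count: dict[str, int], tie_rule: str = "both"
) -> set[str]:
    """Attribute conflicts to individuals.

    Under ``strict`` an individual is flagged only when its pairwise-conflict
    count exceeds that of every individual it conflicts with; under ``both``
    (the default) ties flag both members, so 1-vs-1 conflicts are surfaced
    rather than silently unattributed.
    """
    if tie_rule not in ("strict", "both"):
        raise ValueError(f"tie_rule must be 'strict' or 'both', got {tie_rule!r}")
    adversaries: dict[str, list[str]] = {}
    for i, j in pairs:
        adversaries.setdefault(i, []).append(j)
        adversaries.setdefault(j, []).append(i)
    flagged: set[str] = set()
    for i, opp in adversaries.items():
        ci = conflict_count[i]
        if tie_rule == "strict":
            ok = all(ci > conflict_count[j] for j in opp)
        else:
            ok = all(ci >= conflict_count[j] for j in opp)
        if ok:
            flagged.add(i)
    return flagged


def find_informative_individuals(f: UniparentalForest, p: Pedigree) -> set[str]:
    """Union, over all same-line haplotyped pairs, of the node sets of the tree
    paths between them (endpoints included) — i.e. the minimal subtree spanning
    each line's haplotyped members.

    Computed per line in linear time from subtree counts of haplotyped
    members rather than by pair enumeration.
    """
    informative: set[str] = set()
    hap_by_line = _haplotyped_by_line(f, p)
    members_by_line: dict[str, list[str]] = {}
    for ind, root in f.line_of.items():
        members_by_line.setdefault(root, []).append(ind)
    for root, hap in hap_by_line.items():
        total = len(hap)
        if total < 2:
            continue
        hap_set = set(hap)
        members = sorted(members_by_line[root], key=lambda v: f.depth[v], reverse=True)
        below: dict[str, int] = {}
        hap_children: dict[str, int] = {}
        for v in members:  # children processed before parents
            b = (1 if v in hap_set else 0) + sum(
                below.get(c, 0) for c in f.children_of.get(v, ())
            )
            below[v] = b
            hap_children[v] = sum(
                1 for c in f.children_of.get(v, ()) if below.get(c, 0) > 0
            )
        for v in members:
            b = below[v]
            if b == 0:
                continue
            if total - b >= 1 or v in hap_set or hap_children[v] >= 2:
                informative.add(v)
    return informative


def find_misplaced(
    f: UniparentalForest, p: Pedigree, conflicting: set[str]
) -> tuple[set[str], list[tuple[str, int]]]:
    """Misplaced individuals and the branches they root.

    An individual is misplaced when it is conflicting yet carries the same
    haplotype as its nearest haplotyped maternal ancestor — the signature of a
    subtree recorded under the wrong line.  Branches are the maximal maternal
    subtrees rooted at misplaced individuals with no misplaced strict
    ancestor; each branch is reported with the number of conflicting
    individuals it contains.
    """
    misplaced: set[str] = set()
    for i in sorted(conflicting):
        anc = nearest_haplotyped_ancestor(f, p, i)
        if anc is not None and p.record(anc).haplotype == p.record(i).haplotype:
            misplaced.add(i)
    roots: list[str] = []
    for i in sorted(misplaced):
        v = f.parent_of[i]
        outermost = True
        while v is not None:
            if v in misplaced:
                outermost = False
                break
            v = f.parent_of[v]
        if outermost:
            roots.append(i)
    branches: list[tuple[str, int]] = []
    for r in roots:
        inside = sum(1 for v in f.subtree(r) if v in conflicting)
        branches.append((r, inside))
    return misplaced, branches


def compute_indices(
    *,
    conflicting: set[str],
    informative: set[str],
    misplaced: set[str],
    branches: list[tuple[str, int]],
    n_haplotyped: int,
) -> tuple[float | None, float | None, float | None, int, dict[str, str]]:
    """HC / IC / MISPLACED percentages and the pruned conflict count.

    A zero denominator yields ``None`` with a reason rather than a silent 0.
    """
    undefined: dict[str, str] = {}
    if n_haplotyped:
        hc: float | None = 100.0 * len(conflicting) / n_haplotyped
    else:
        hc = None
        undefined["hc"] = "no haplotyped individuals"
    if informative:
        ic: float | None = 100.0 * len(conflicting & informative) / len(informative)
    else:
        ic = None
        undefined["ic"] = "no informative individuals"
    if conflicting:
        mis: float | None = 100.0 * len(misplaced) / len(conflicting)
    else:
        mis = None
        undefined["misplaced"] = "no conflicting individuals"
    pruned = len(conflicting) - sum(cnt - 1 for _, cnt in branches)
    return hc, ic, mis, pruned, undefined


def verify_pedigree(
    p: Pedigree,
    f: UniparentalForest | None = None,
    tie_rule: str = "both",
) -> ConflictReport:
    """Run the full concordance verification and return the report."""
    if f is None:
        f = build_forest(p)
    n_haplotyped = sum(1 for r in p if r.haplotype is not None)
    pairs = find_conflicting_pairs(f, p)
    counts = conflict_counts(f, p)
    conflicting = flag_conflicting_individuals(pairs, counts, tie_rule=tie_rule)
    informative = find_informative_individuals(f, p)
    misplaced, branches = find_misplaced(f, p, conflicting)
    hc, ic, mis, pruned, undefined = compute_indices(
        conflicting=conflicting,
        informative=informative,
        misplaced=misplaced,
        branches=branches,
        n_haplotyped=n_haplotyped,
    )
    return ConflictReport(
        conflicting_pairs=pairs,
        conflict_count=counts,
        conflicting_individuals=conflicting,
        informative_individuals=informative,
        misplaced_individuals=misplaced,
        misplaced_branches=branches,
        n_haplotyped=n_haplotyped,
        hc_index=hc,
        ic_index=ic,
        misplaced_index=mis,
        pruned_conflicts=pruned,
        undefined=undefined,
    )


def has_conflicts(f: UniparentalForest, p: Pedigree) -> bool:
    """Cheap check: does any maternal line carry two distinct haplotypes?"""
    seen: dict[str, str] = {}
    for r in p:
        if r.haplotype is None:
            continue
        root = f.line_of[r.id]
        prev = seen.setdefault(root, r.haplotype)
        if prev != r.haplotype:
            return True
    return False
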