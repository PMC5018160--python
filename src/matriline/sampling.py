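"""Optimized molecular-sampling plans over maternal lines.

Stage 1 (allocation) splits a sequencing budget N across the L maternal lines
present in the reference population:

* no prior sequencings — every line gets one base slot, the remaining N − L
  slots go proportionally to (R_l − 1) (largest-remainder division); when
  L > N the N largest lines by R_l get one slot each;
* with priors — every line with P_l = 0 keeps a base slot (k such lines); the
  pool N − k + ΣP_l is divided proportionally to R_l into per-line targets
  T_l (floored at 1 for P_l = 0 lines), and the new samplings per line are
  max(T_l − P_l, 0).

Targets are capped at R_l; surplus is reported, never redistributed.

Stage 2 (selection) picks, within each line, the group with the largest sum
of pairwise tree distances that contains a central individual: the first pick
minimizes the sum of distances to the rest of the pool (SD_l,i), each further
pick greedily maximizes the sum of distances to the already-selected set.
Previously sequenced individuals seed the selected set and are never
re-picked.  All ties break lexicographically on individual id so plans are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ConfigError
from .forest import UniparentalForest, pairwise_distances
from .pedigree_io import Pedigree


@dataclass
class LineAllocation:
    line: str
    r: int  # R_l: line members in the reference population
    p: int  # P_l: previously sequenced line members
    target: int  # N_l (total haplotyped target, priors included)
    new: int  # new samplings planned for the line
    surplus: int = 0  # slots lost to the R_l cap


@dataclass
class LinePlan:
    allocation: LineAllocation
    selected: list[str] = field(default_factory=list)
    pool_size: int = 0  # selectable (available, unsequenced) candidates
    shortfall: int = 0  # planned new picks that found no candidate


@dataclass
class SamplingPlan:
    n_planned: int
    lines: dict[str, LinePlan]
    availability_used: bool = False

    @property
    def selected(self) -> list[str]:
        out: list[str] = []
        for root in sorted(self.lines):
            out.extend(self.lines[root].selected)
        return out

    @property
    def total_new(self) -> int:
        return sum(len(lp.selected) for lp in self.lines.values())

    @property
    def total_shortfall(self) -> int:
        return sum(lp.shortfall for lp in self.lines.values())


def _largest_remainder(
    total: int, weights: Sequence[float], sizes: Sequence[int], keys: Sequence[str]
) -> list[int]:
    """Hamilton apportionment of ``total`` integer slots proportional to
    ``weights``.  Remainder ties break by larger line size, then id."""
    if total <= 0:
        return [0] * len(weights)
    wsum = float(sum(weights))
    if wsum <= 0:
        return [0] * len(weights)
    quotas = [total * w / wsum for w in weights]
    floors = [int(q) for q in quotas]
    leftover = total - sum(floors)
    order = sorted(
        range(len(weights)),
        key=lambda i: (-(quotas[i] - floors[i]), -sizes[i], keys[i]),
    )
    for i in order[:leftover]:
        floors[i] += 1
    return floors


def allocate_slots(
    n: int, lines: Sequence[tuple[str, int, int]]
) -> list[LineAllocation]:
    """Split budget ``n`` over ``lines`` given as (line id, R_l, P_l).

    Returns one :class:`LineAllocation` per input line, same order.
    """
    if n < 0:
        raise ConfigError(f"sampling budget must be >= 0, got {n}")
    for line, r, prior in lines:
        if r < 0 or prior < 0:
            raise ConfigError(f"line {line}: R_l and P_l must be >= 0")
    ids = [t[0] for t in lines]
    rs = [t[1] for t in lines]
    ps = [t[2] for t in lines]
    L = len(lines)
    out = [LineAllocation(line=ids[i], r=rs[i], p=ps[i], target=0, new=0) for i in range(L)]
    if n == 0 or L == 0:
        return out

    if sum(ps) == 0:
        if n >= L:
            weights: list[float] = [float(r - 1) for r in rs]
            if sum(weights) == 0:
                # all singleton lines: divide evenly so the R_l cap can
                # account for every undistributable slot
                weights = [1.0] * L
            extra = _largest_remainder(n - L, weights, rs, ids)
            for i in range(L):
                raw = 1 + extra[i]
                out[i].target = min(raw, rs[i])
                out[i].surplus = raw - out[i].target
                out[i].new = out[i].target
        else:
            order = sorted(range(L), key=lambda i: (-rs[i], ids[i]))
            for i in order[:n]:
                out[i].target = min(1, rs[i])
                out[i].new = out[i].target
        return out

    # prior-aware branch
    zero_prior = [i for i in range(L) if ps[i] == 0]
    k = len(zero_prior)
    if n < k:
        # budget smaller than the number of unsequenced lines: single slots to
        # the n largest unsequenced lines (mirrors the L > N rule)
        order = sorted(zero_prior, key=lambda i: (-rs[i], ids[i]))
        for i in range(L):
            out[i].target = ps[i]
        for i in order[:n]:
            out[i].target = min(ps[i] + 1, max(rs[i], ps[i]))
            out[i].new = out[i].target - ps[i]
        return out
    # Divide the pool N - k + ΣP_l proportionally to R_l.  Lines already
    # sequenced beyond their proportional share are frozen at P_l (no new
    # samplings) and removed from the division, so the budget is conserved
    # instead of their excess priors inflating other lines' targets.
    active = list(range(L))
    targets = [0] * L
    while True:
        pool = n - k + sum(ps[i] for i in active)
        shares = _largest_remainder(
            pool, [float(rs[i]) for i in active], [rs[i] for i in active], [ids[i] for i in active]
        )
        for i, t in zip(active, shares):
            targets[i] = t
        saturated = [i for i in active if targets[i] < ps[i]]
        if not saturated:
            break
        for i in saturated:
            targets[i] = ps[i]
        active = [i for i in active if i not in saturated]
        if not active:
            break
    for i in range(L):
        t = targets[i]
        if ps[i] == 0 and t < 1:
            t = 1  # guaranteed base slot for unsequenced lines
        raw = t
        capped = min(raw, max(rs[i], ps[i]))
        out[i].target = capped
        out[i].surplus = raw - capped
        out[i].new = max(capped - ps[i], 0)
    return out


def central_individual(f: UniparentalForest, pool: Iterable[str]) -> str:
    """The pool member minimizing SD_l,i, the sum of tree distances to all
    other pool members; ties break lexicographically."""
    members = sorted(pool)
    if not members:
        raise ConfigError("central individual of an empty pool")
    if len(members) == 1:
        return members[0]
    dist = pairwise_distances(f, members)
    best = None
    best_sd = None
    for i in members:
        sd = sum(dist[(i, j)] for j in members if j != i)
        if best_sd is None or sd < best_sd:
            best, best_sd = i, sd
    return best  # type: ignore[return-value]


def greedy_select(
    f: UniparentalForest,
    pool: Iterable[str],
    n_new: int,
    seeds: Iterable[str] = (),
) -> list[str]:
    """Pick up to ``n_new`` individuals from ``pool`` maximizing the sum of
    pairwise tree distances of the selected group.

    Without seeds the first pick is the central individual of the pool; with
    seeds every pick is a greedy addition against the seed group and prior
    picks.  When the pool runs out the whole remainder is returned (the caller
    reports the shortfall).
    """
    seeds = set(seeds)
    candidates = sorted(set(pool) - seeds)
    if n_new <= 0 or not candidates:
        return []
    all_nodes = sorted(set(candidates) | seeds)
    dist = pairwise_distances(f, all_nodes)

    picked: list[str] = []
    sum_to_selected = {c: 0 for c in candidates}
    for s in seeds:
        for c in candidates:
            sum_to_selected[c] += dist[(c, s)]

    remaining = list(candidates)
    if not seeds:
        first = central_individual(f, candidates)
        picked.append(first)
        remaining.remove(first)
        for c in remaining:
            sum_to_selected[c] += dist[(c, first)]
    while len(picked) < n_new and remaining:
        best = None
        best_sd = None
        for c in remaining:  # lexicographic order; strict > keeps first on ties
            sd = sum_to_selected[c]
            if best_sd is None or sd > best_sd:
                best, best_sd = c, sd
        picked.append(best)  # type: ignore[arg-type]
        remaining.remove(best)  # type: ignore[arg-type]
        for c in remaining:
            sum_to_selected[c] += dist[(c, best)]  # type: ignore[index]
    return picked


def group_score(f: UniparentalForest, group: Iterable[str]) -> int:
    """Sum of pairwise tree distances within a same-line group."""
    members = sorted(group)
    dist = pairwise_distances(f, members)
    return sum(
        dist[(members[a], members[b])]
        for a in range(len(members))
        for b in range(a + 1, len(members))
    )


def build_plan(
    p: Pedigree,
    f: UniparentalForest,
    refpop: set[str],
    n: int,
    use_availability: bool | None = None,
) -> SamplingPlan:
    """Allocate the budget over the lines present in the reference population
    and select maximally dispersed individuals within each line.

    ``use_availability``: ``None`` means "use the available column if the
    pedigree has one"; when active, selection pools are restricted to
    available individuals (allocation is unchanged) and per-line shortfalls
    are reported, never redistributed.  Previously sequenced (haplotyped)
    line members count as P_l and seed the dispersion but are never
    re-selected.
    """
    if not refpop:
        raise ConfigError("reference population is empty; nothing to sample")
    if use_availability is None:
        use_availability = p.has_available
    if use_availability and not p.has_available:
        raise ConfigError("availability requested but the pedigree has no available column")

    ref_by_line: dict[str, list[str]] = {}
    for ind in sorted(refpop):
        ref_by_line.setdefault(f.line_of[ind], []).append(ind)
    seeds_by_line: dict[str, list[str]] = {}
    for r in p:
        if r.haplotype is not None:
            root = f.line_of[r.id]
            if root in ref_by_line:
                seeds_by_line.setdefault(root, []).append(r.id)

    roots = sorted(ref_by_line)
    alloc = allocate_slots(
        n,
        [(root, len(ref_by_line[root]), len(seeds_by_line.get(root, []))) for root in roots],
    )
    lines: dict[str, LinePlan] = {}
    for a in alloc:
        seeds = set(seeds_by_line.get(a.line, []))
        pool = [ind for ind in ref_by_line[a.line] if ind not in seeds]
        if use_availability:
            pool = [ind for ind in pool if p.record(ind).available]
        selected = greedy_select(f, pool, a.new, seeds=seeds)
        lines[a.line] = LinePlan(
            allocation=a,
            selected=selected,
            pool_size=len(pool),
            shortfall=max(a.new - len(pool), 0),
        )
    return SamplingPlan(n_planned=n, lines=lines, availability_used=use_availability)
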