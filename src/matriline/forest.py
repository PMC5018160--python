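"""Uniparental forests: matrilineal (dam-link) trees rooted at founder dams.

Every individual — male or female — belongs to exactly one maternal line, the
one of the founder dam reached by following mother links until an unknown
mother.  An individual whose mother is unknown roots its own line (males with
unknown mothers form singleton lines).  The same builder run on father links
yields the paternal forest used for the symmetric paternal-line calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .errors import FatalPedigreeError, MatrilineError
from .pedigree_io import FatalError, Pedigree


@dataclass
class UniparentalForest:
    """Partition of a pedigree into single-parent-link trees.

    ``line_of`` maps every individual to its line root; roots map to
    themselves and have ``depth`` 0.
    """

    parent_link: str  # "dam" or "sire"
    line_of: dict[str, str]
    parent_of: dict[str, str | None]
    children_of: dict[str, list[str]]
    depth: dict[str, int]
    roots: list[str] = field(default_factory=list)
    _lines: dict[str, list[str]] | None = field(default=None, repr=False)

    @property
    def founder_dams(self) -> list[str]:
        return self.roots

    @property
    def n_lines(self) -> int:
        return len(self.roots)

    def lines(self) -> dict[str, list[str]]:
        """Map line root → sorted member ids (cached)."""
        if self._lines is None:
            out: dict[str, list[str]] = {r: [] for r in self.roots}
            for ind, root in self.line_of.items():
                out[root].append(ind)
            for members in out.values():
                members.sort()
            self._lines = out
        return self._lines

    def members(self, root: str) -> list[str]:
        return self.lines()[root]

    def subtree(self, individual: str) -> list[str]:
        """All ids in the subtree rooted at ``individual`` (itself included)."""
        out = [individual]
        stack = [individual]
        while stack:
            v = stack.pop()
            for c in self.children_of.get(v, ()):
                out.append(c)
                stack.append(c)
        return out


MaternalForest = UniparentalForest  # the default, dam-link instantiation


def build_forest(p: Pedigree, parent_link: str = "dam") -> UniparentalForest:
    """Assign every individual to the founder reached through ``parent_link``
    references, recording depth below the root.

    A parent reference without a record is treated as unknown (auto-correction
    removes or materializes such references beforehand).  A cycle raises
    :class:`FatalPedigreeError` — it should have been caught upstream.
    """
    if parent_link not in ("dam", "sire"):
        raise ValueError(f"parent_link must be 'dam' or 'sire', got {parent_link!r}")
    parent_of: dict[str, str | None] = {}
    for r in p:
        q = r.dam if parent_link == "dam" else r.sire
        parent_of[r.id] = q if (q is not None and q in p.by_id) else None

    line_of: dict[str, str] = {}
    depth: dict[str, int] = {}
    roots: list[str] = []
    for ind in parent_of:
        if ind in line_of:
            continue
        chain = []
        v: str | None = ind
        seen = set()
        while v is not None and v not in line_of:
            if v in seen:
                raise FatalPedigreeError(
                    [FatalError("cycle", (v,), f"{parent_link}-link cycle at {v}")]
                )
            seen.add(v)
            chain.append(v)
            v = parent_of[v]
        if v is None:
            root = chain[-1]
            base_depth = -1  # so the root itself lands at depth 0
        else:
            root = line_of[v]
            base_depth = depth[v]
        for i, node in enumerate(reversed(chain)):
            line_of[node] = root
            depth[node] = base_depth + 1 + i
        if v is None:
            roots.append(root)

    children_of: dict[str, list[str]] = {ind: [] for ind in parent_of}
    for ind, q in parent_of.items():
        if q is not None:
            children_of[q].append(ind)
    for kids in children_of.values():
        kids.sort()
    roots.sort()
    return UniparentalForest(
        parent_link=parent_link,
        line_of=line_of,
        parent_of=parent_of,
        children_of=children_of,
        depth=depth,
        roots=roots,
    )


def mrca(f: UniparentalForest, i: str, j: str) -> str:
    """Most recent common ancestor of two same-line individuals in the
    single-parent-link tree."""
    if f.line_of[i] != f.line_of[j]:
        raise MatrilineError(f"{i} and {j} are in different lines")
    di, dj = f.depth[i], f.depth[j]
    while di > dj:
        i = f.parent_of[i]  # type: ignore[assignment]
        di -= 1
    while dj > di:
        j = f.parent_of[j]  # type: ignore[assignment]
        dj -= 1
    while i != j:
        i = f.parent_of[i]  # type: ignore[assignment]
        j = f.parent_of[j]  # type: ignore[assignment]
    return i


def tree_distance(f: UniparentalForest, i: str, j: str) -> int:
    """Number of parent-link edges on the unique tree path between two
    same-line individuals: ``depth(i) + depth(j) - 2 depth(mrca)``."""
    if i == j:
        if i not in f.line_of:
            raise MatrilineError(f"unknown individual {i!r}")
        return 0
    a = mrca(f, i, j)
    return f.depth[i] + f.depth[j] - 2 * f.depth[a]


def nearest_haplotyped_ancestor(
    f: UniparentalForest, p: Pedigree, individual: str
) -> str | None:
    """Closest strict maternal (parent-link) ancestor carrying a haplotype, or
    ``None`` when no ancestor is haplotyped."""
    v = f.parent_of[individual]
    while v is not None:
        if p.record(v).haplotype is not None:
            return v
        v = f.parent_of[v]
    return None


def pairwise_distances(
    f: UniparentalForest, individuals: Iterable[str]
) -> dict[tuple[str, str], int]:
    """Distance map over all unordered pairs of a same-line pool (both key
    orders present, diagonal omitted)."""
    pool = list(individuals)
    out: dict[tuple[str, str], int] = {}
    for a in range(len(pool)):
        for b in range(a + 1, len(pool)):
            i, j = pool[a], pool[b]
            d = tree_distance(f, i, j)
            out[(i, j)] = d
            out[(j, i)] = d
    return out
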