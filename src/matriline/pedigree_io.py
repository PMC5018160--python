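"""Pedigree CSV dialect: parsing, validation, auto-correction, serialization.

The input is a comma-separated file whose first line is a header carrying five
mandatory keywords (``ID``, ``father``, ``mother``, ``YOB``, ``gender``) and two
optional ones (``haplotype``, ``available``).  Column order is free; the header
keyword positions bind the columns.  Extra columns are ignored.  Keyword match
is case-insensitive and whitespace-tolerant.

Two optional side files accompany a pedigree:

* ``reference_years.txt`` — two integer lines, the first and last birth year of
  the reference population.  When absent the window defaults to the full YOB
  span of the pedigree.
* ``planned_number_of_sequencings.txt`` — a single integer, the sampling budget
  (read by the CLI, see :mod:`matriline.cli`).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import FatalPedigreeError, PedigreeFormatError

MANDATORY_KEYWORDS = ("ID", "father", "mother", "YOB", "gender")
OPTIONAL_KEYWORDS = ("haplotype", "available")

DEFAULT_UNKNOWN_TOKENS = frozenset({"", "0"})
DEFAULT_MALE_TOKENS = frozenset({"M", "m", "1"})
DEFAULT_FEMALE_TOKENS = frozenset({"F", "f", "2"})

DEFAULT_INPUT_NAME = "pdg_in.csv"
REFERENCE_YEARS_NAME = "reference_years.txt"
PLANNED_SEQUENCINGS_NAME = "planned_number_of_sequencings.txt"


class Gender(enum.Enum):
    MALE = "M"
    FEMALE = "F"
    UNKNOWN = "U"


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual.  ``sire``/``dam`` are ``None`` when unknown; ``yob`` and
    ``haplotype`` are ``None`` when missing."""

    id: str
    sire: str | None = None
    dam: str | None = None
    yob: int | None = None
    gender: Gender = Gender.UNKNOWN
    haplotype: str | None = None
    available: bool = False


@dataclass
class Pedigree:
    """An ordered collection of records with unique ids.

    ``has_haplotype`` / ``has_available`` record whether the optional columns
    were present in the source file; features tied to an absent column are
    disabled downstream.
    """

    records: list[PedigreeRecord]
    has_haplotype: bool = True
    has_available: bool = False
    by_id: dict[str, PedigreeRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.by_id = {}
        for r in self.records:
            if r.id in self.by_id:
                raise PedigreeFormatError(f"duplicate individual id {r.id!r}")
            self.by_id[r.id] = r

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PedigreeRecord]:
        return iter(self.records)

    def __contains__(self, individual: str) -> bool:
        return individual in self.by_id

    def get(self, individual: str) -> PedigreeRecord | None:
        return self.by_id.get(individual)

    def record(self, individual: str) -> PedigreeRecord:
        return self.by_id[individual]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass(frozen=True)
class ReferenceWindow:
    """Inclusive birth-year window delimiting the reference population."""

    first_year: int
    last_year: int

    def __post_init__(self) -> None:
        if self.first_year > self.last_year:
            raise PedigreeFormatError(
                f"reference window first year {self.first_year} is after last year {self.last_year}"
            )

    def __contains__(self, yob: int | None) -> bool:
        return yob is not None and self.first_year <= yob <= self.last_year


@dataclass
class AutocorrectLog:
    """What auto-correction did: parent references removed (child, parent) and
    parent records created from repeated references."""

    deleted_parent_refs: list[tuple[str, str]] = field(default_factory=list)
    created_records: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.deleted_parent_refs and not self.created_records


@dataclass(frozen=True)
class FatalError:
    kind: str  # "cycle" | "gender_inconsistency"
    ids: tuple[str, ...]
    message: str


def _resolve_header(header: Sequence[str]) -> dict[str, int]:
    cleaned = [h.strip().lower() for h in header]
    colmap: dict[str, int] = {}
    for kw in MANDATORY_KEYWORDS + OPTIONAL_KEYWORDS:
        try:
            colmap[kw] = cleaned.index(kw.lower())
        except ValueError:
            pass
    missing = [kw for kw in MANDATORY_KEYWORDS if kw not in colmap]
    if missing:
        raise PedigreeFormatError(
            "header is missing mandatory keyword(s): " + ", ".join(missing)
        )
    return colmap


def read_pedigree(
    path: str | Path,
    *,
    unknown_tokens: Iterable[str] = DEFAULT_UNKNOWN_TOKENS,
    male_tokens: Iterable[str] = DEFAULT_MALE_TOKENS,
    female_tokens: Iterable[str] = DEFAULT_FEMALE_TOKENS,
) -> Pedigree:
    """Parse a pedigree CSV.

    Raises :class:`PedigreeFormatError` on a missing mandatory keyword, a row
    shorter than a bound column, a non-integer birth year, or a duplicate id.
    """
    unknown = frozenset(t.strip() for t in unknown_tokens)
    males = frozenset(male_tokens)
    females = frozenset(female_tokens)
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PedigreeFormatError(f"{path}: empty file") from None
        colmap = _resolve_header(header)
        max_col = max(colmap.values())
        records: list[PedigreeRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue  # blank line
            if len(row) <= max_col:
                raise PedigreeFormatError(
                    f"{path}:{lineno}: row has {len(row)} fields, "
                    f"but the header binds column {max_col + 1}"
                )
            get = lambda kw: row[colmap[kw]].strip()  # noqa: E731

            ind = get("ID")
            if ind in unknown:
                raise PedigreeFormatError(f"{path}:{lineno}: empty/unknown individual id")

            def parent(kw: str) -> str | None:
                tok = get(kw)
                return None if tok in unknown else tok

            yob_tok = get("YOB")
            if yob_tok in unknown:
                yob: int | None = None
            else:
                try:
                    yob = int(yob_tok)
                except ValueError:
                    raise PedigreeFormatError(
                        f"{path}:{lineno}: YOB {yob_tok!r} is not an integer"
                    ) from None

            gtok = get("gender")
            if gtok in males:
                gender = Gender.MALE
            elif gtok in females:
                gender = Gender.FEMALE
            else:
                gender = Gender.UNKNOWN

            hap: str | None = None
            if "haplotype" in colmap:
                htok = get("haplotype")
                hap = None if htok in unknown else htok

            avail = False
            if "available" in colmap:
                avail = get("available") == "1"  # anything else negates availability

            records.append(
                PedigreeRecord(
                    id=ind,
                    sire=parent("father"),
                    dam=parent("mother"),
                    yob=yob,
                    gender=gender,
                    haplotype=hap,
                    available=avail,
                )
            )
    return Pedigree(
        records,
        has_haplotype="haplotype" in colmap,
        has_available="available" in colmap,
    )


def write_pedigree(p: Pedigree, path: str | Path) -> Path:
    """Serialize a pedigree back to the CSV dialect (optional columns only when
    active).  ``read_pedigree(write_pedigree(p)) == p`` field-for-field."""
    path = Path(path)
    header = list(MANDATORY_KEYWORDS)
    if p.has_haplotype:
        header.append("haplotype")
    if p.has_available:
        header.append("available")
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in p:
            row = [
                r.id,
                r.sire or "",
                r.dam or "",
                "" if r.yob is None else str(r.yob),
                {Gender.MALE: "M", Gender.FEMALE: "F", Gender.UNKNOWN: ""}[r.gender],
            ]
            if p.has_haplotype:
                row.append(r.haplotype or "")
            if p.has_available:
                row.append("1" if r.available else "")
            writer.writerow(row)
    return path


# ---------------------------------------------------------------------------
# fatal-error checks


def _cycle_members(p: Pedigree) -> list[list[str]]:
    """Strongly connected components of size > 1 (and self-loops) in the
    child→parent graph: every member is its own ancestor."""
    index: dict[str, int] = {}
    lowlink: dict[str, int] = {}
    on_stack: set[str] = set()
    stack: list[str] = []
    counter = 0
    sccs: list[list[str]] = []

    def parents(v: str) -> list[str]:
        r = p.by_id[v]
        out = []
        for q in (r.sire, r.dam):
            if q is not None and q in p.by_id:
                out.append(q)
        return out

    for root in p.by_id:
        if root in index:
            continue
        work: list[tuple[str, int]] = [(root, 0)]
        while work:
            v, pi = work[-1]
            if pi == 0:
                index[v] = lowlink[v] = counter
                counter += 1
                stack.append(v)
                on_stack.add(v)
            advanced = False
            ps = parents(v)
            while pi < len(ps):
                w = ps[pi]
                pi += 1
                if w not in index:
                    work[-1] = (v, pi)
                    work.append((w, 0))
                    advanced = True
                    break
                if w in on_stack:
                    lowlink[v] = min(lowlink[v], index[w])
            if advanced:
                continue
            work.pop()
            if lowlink[v] == index[v]:
                comp = []
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp.append(w)
                    if w == v:
                        break
                r = p.by_id[v]
                if len(comp) > 1 or r.sire == v or r.dam == v:
                    sccs.append(sorted(comp))
            if work:
                u, _ = work[-1]
                lowlink[u] = min(lowlink[u], lowlink[v])
    return sccs


def check_fatal_errors(p: Pedigree) -> list[FatalError]:
    """Return every fatal error: ancestry cycles (an individual its own
    ancestor through any parent chain) and parental-role gender
    inconsistencies.  An empty list means the pedigree is structurally sound.
    """
    errors: list[FatalError] = []
    for comp in _cycle_members(p):
        errors.append(
            FatalError(
                kind="cycle",
                ids=tuple(comp),
                message="ancestry cycle involving: " + ", ".join(comp),
            )
        )
    father_ids = {r.sire for r in p if r.sire is not None}
    mother_ids = {r.dam for r in p if r.dam is not None}
    for ind in sorted(father_ids & mother_ids):
        errors.append(
            FatalError(
                kind="gender_inconsistency",
                ids=(ind,),
                message=f"{ind} appears in both the father and the mother column",
            )
        )
    for ind in sorted(father_ids):
        r = p.get(ind)
        if r is not None and r.gender is Gender.FEMALE:
            errors.append(
                FatalError(
                    kind="gender_inconsistency",
                    ids=(ind,),
                    message=f"{ind} is recorded female but appears in the father column",
                )
            )
    for ind in sorted(mother_ids):
        r = p.get(ind)
        if r is not None and r.gender is Gender.MALE:
            errors.append(
                FatalError(
                    kind="gender_inconsistency",
                    ids=(ind,),
                    message=f"{ind} is recorded male but appears in the mother column",
                )
            )
    return errors


def raise_on_fatal(p: Pedigree) -> None:
    errors = check_fatal_errors(p)
    if errors:
        raise FatalPedigreeError(errors)


# ---------------------------------------------------------------------------
# auto-correction


def autocorrect_missing_parents(p: Pedigree) -> tuple[Pedigree, AutocorrectLog]:
    """Repair parent references that have no record of their own.

    A parent id referenced exactly once carries no relational information and
    the reference is replaced by unknown; one referenced twice or more gets a
    new record (gender inferred from the parental column).  Idempotent: a
    second run logs nothing.
    """
    refs: dict[str, int] = {}
    role: dict[str, str] = {}
    for r in p:
        for q, which in ((r.sire, "sire"), (r.dam, "dam")):
            if q is not None and q not in p.by_id:
                refs[q] = refs.get(q, 0) + 1
                prev = role.setdefault(q, which)
                if prev != which:
                    raise FatalPedigreeError(
                        [
                            FatalError(
                                kind="gender_inconsistency",
                                ids=(q,),
                                message=f"{q} referenced in both parental roles",
                            )
                        ]
                    )
    log = AutocorrectLog()
    singles = {q for q, n in refs.items() if n == 1}
    to_create = sorted(q for q, n in refs.items() if n >= 2)

    new_records: list[PedigreeRecord] = []
    for r in p:
        sire, dam = r.sire, r.dam
        if sire in singles:
            log.deleted_parent_refs.append((r.id, sire))
            sire = None
        if dam in singles:
            log.deleted_parent_refs.append((r.id, dam))
            dam = None
        if sire is not r.sire or dam is not r.dam:
            r = replace(r, sire=sire, dam=dam)
        new_records.append(r)
    for q in to_create:
        gender = Gender.MALE if role[q] == "sire" else Gender.FEMALE
        new_records.append(PedigreeRecord(id=q, gender=gender))
        log.created_records.append(q)
    corrected = Pedigree(
        new_records, has_haplotype=p.has_haplotype, has_available=p.has_available
    )
    return corrected, log


# ---------------------------------------------------------------------------
# side files


def read_reference_window(
    path: str | Path | None, p: Pedigree
) -> ReferenceWindow:
    """Read the two-line reference-years file; fall back to the full YOB span
    of the pedigree when the file is absent (or ``path`` is ``None``)."""
    if path is not None:
        path = Path(path)
    if path is None or not path.exists():
        yobs = [r.yob for r in p if r.yob is not None]
        if not yobs:
            raise PedigreeFormatError(
                "cannot derive a default reference window: no individual has a birth year"
            )
        return ReferenceWindow(min(yobs), max(yobs))
    lines = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if len(lines) < 2:
        raise PedigreeFormatError(f"{path}: expected two integer lines (first and last year)")
    try:
        first, last = int(lines[0]), int(lines[1])
    except ValueError:
        raise PedigreeFormatError(f"{path}: years must be integers") from None
    return ReferenceWindow(first, last)


def read_planned_sequencings(path: str | Path) -> int:
    """Parse the one-line planned-sequencings file into a budget."""
    path = Path(path)
    text = path.read_text(encoding="utf-8").strip().split()
    if not text:
        raise PedigreeFormatError(f"{path}: empty planned-sequencings file")
    try:
        n = int(text[0])
    except ValueError:
        raise PedigreeFormatError(f"{path}: planned number of sequencings must be an integer") from None
    if n < 0:
        raise PedigreeFormatError(f"{path}: planned number of sequencings must be >= 0")
    return n
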