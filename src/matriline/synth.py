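"""Synthetic-pedigree generator with ground truth.

A forward-time breeding scheme: founder dams and sires with unknown parents,
then a fixed number of discrete generations in which every female of the
previous generation produces Poisson-distributed numbers of daughters and
sons sired by males drawn from the previous generation (founder sires for the
first one).  Each founder line carries one true mtDNA haplotype; a Bernoulli
sequencing mask decides whose haplotype appears in the pedigree file.

Error injection reproduces the two classes of recording errors the
verification stage must recover: a single individual carrying a foreign
haplotype, and a *misplaced branch* — a subtree whose sequenced members all
carry a foreign haplotype, as if the branch had been recorded under the wrong
line.  The injector builds the canonical single-branch pattern (the
relocation node ``u`` is sequenced, exactly one child subtree below it holds
the remaining foreign-haplotype members, everything else under ``u`` is
unsequenced) so recovery tests have unambiguous ground truth.

Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .forest import UniparentalForest, build_forest
from .pedigree_io import Gender, Pedigree, PedigreeRecord


@dataclass(frozen=True)
class SynthConfig:
    n_founder_dams: int = 10
    n_founder_sires: int = 5
    generations: int = 5
    mean_daughters: float = 1.5
    mean_sons: float = 1.5
    year_span: tuple[int, int] = (1980, 2010)
    n_haplotypes: int = 6
    sequencing_fraction: float = 0.3
    n_conflicts_injected: int = 0
    n_misplaced_branches: int = 0
    availability_fraction: float | None = None  # None = no available column
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founder_dams < 1:
            raise ConfigError("need at least one founder dam")
        if self.n_founder_sires < 0 or self.generations < 0:
            raise ConfigError("counts must be >= 0")
        if self.mean_daughters < 0 or self.mean_sons < 0:
            raise ConfigError("offspring means must be >= 0")
        if not 0.0 <= self.sequencing_fraction <= 1.0:
            raise ConfigError("sequencing_fraction must lie in [0, 1]")
        if self.availability_fraction is not None and not (
            0.0 <= self.availability_fraction <= 1.0
        ):
            raise ConfigError("availability_fraction must lie in [0, 1]")
        if self.n_haplotypes < 1:
            raise ConfigError("need at least one haplotype label")
        if self.year_span[0] > self.year_span[1]:
            raise ConfigError("year_span must be (first, last) with first <= last")


@dataclass(frozen=True)
class InjectedConflict:
    individual: str
    original_haplotype: str
    foreign_haplotype: str


@dataclass(frozen=True)
class InjectedBranch:
    relocation_node: str  # u: sequenced top of the foreign-haplotype block
    branch_root: str  # c: the (single) misplaced-branch root the verifier should find
    branch_members: tuple[str, ...]  # sequenced members of subtree(c)
    foreign_haplotype: str
    host_line: str


@dataclass
class GroundTruth:
    line_of: dict[str, str]
    true_line_haplotype: dict[str, str]  # line root -> haplotype label
    sequenced: set[str]
    singleton_lines: set[str]  # founder-sire (and childless) one-member lines
    injected_conflicts: list[InjectedConflict] = field(default_factory=list)
    injected_branches: list[InjectedBranch] = field(default_factory=list)

    @property
    def n_lines(self) -> int:
        return len(self.true_line_haplotype)


def _haplotype_labels(cfg: SynthConfig, n_lines: int, rng: np.random.Generator) -> list[str]:
    labels = [f"HT{i + 1}" for i in range(cfg.n_haplotypes)]
    if cfg.n_haplotypes >= n_lines:
        # enough labels for distinct lines: sample without replacement
        idx = rng.permutation(cfg.n_haplotypes)[:n_lines]
    else:
        # shared haplotypes across lines (haplotype Ne != maternal Ne)
        idx = rng.integers(0, cfg.n_haplotypes, size=n_lines)
    return [labels[i] for i in idx]


def generate(cfg: SynthConfig) -> tuple[Pedigree, GroundTruth]:
    """Generate a pedigree and its ground truth; deterministic in the seed."""
    rng = np.random.default_rng(cfg.seed)
    first, last = cfg.year_span
    step = max((last - first) // (cfg.generations + 1), 1) if cfg.generations else 1

    records: list[PedigreeRecord] = []
    counter = 0

    dams = [f"D{i + 1:04d}" for i in range(cfg.n_founder_dams)]
    sires = [f"S{i + 1:04d}" for i in range(cfg.n_founder_sires)]
    for d in dams:
        records.append(PedigreeRecord(id=d, yob=first, gender=Gender.FEMALE))
    for s in sires:
        records.append(PedigreeRecord(id=s, yob=first, gender=Gender.MALE))

    prev_females = list(dams)
    prev_males = list(sires)
    for g in range(1, cfg.generations + 1):
        yob = min(first + g * step, last)
        females: list[str] = []
        males: list[str] = []
        sire_pool = prev_males if prev_males else sires
        for dam in prev_females:
            nd = int(rng.poisson(cfg.mean_daughters))
            ns = int(rng.poisson(cfg.mean_sons))
            for child_idx in range(nd + ns):
                counter += 1
                ind = f"I{counter:06d}"
                sire = sire_pool[int(rng.integers(0, len(sire_pool)))] if sire_pool else None
                gender = Gender.FEMALE if child_idx < nd else Gender.MALE
                records.append(
                    PedigreeRecord(
                        id=ind,
                        sire=sire,
                        dam=dam,
                        yob=int(yob + rng.integers(-1, 2)) if step > 1 else yob,
                        gender=gender,
                    )
                )
                (females if gender is Gender.FEMALE else males).append(ind)
        prev_females, prev_males = females, males

    # clamp years into the span
    records = [
        r if r.yob is None else replace(r, yob=min(max(r.yob, first), last))
        for r in records
    ]

    line_roots = dams + sires  # every founder roots its own maternal line
    labels = _haplotype_labels(cfg, len(line_roots), rng)
    true_hap = dict(zip(line_roots, labels))

    ped = Pedigree(records, has_haplotype=True, has_available=cfg.availability_fraction is not None)
    f = build_forest(ped)
    sequenced: set[str] = set()
    final: list[PedigreeRecord] = []
    for r in ped:
        hap = None
        if rng.random() < cfg.sequencing_fraction:
            hap = true_hap[f.line_of[r.id]]
            sequenced.add(r.id)
        avail = False
        if cfg.availability_fraction is not None:
            avail = bool(rng.random() < cfg.availability_fraction)
        final.append(replace(r, haplotype=hap, available=avail))
    ped = Pedigree(
        final,
        has_haplotype=True,
        has_available=cfg.availability_fraction is not None,
    )
    truth = GroundTruth(
        line_of=dict(f.line_of),
        true_line_haplotype=true_hap,
        sequenced=sequenced,
        singleton_lines={root for root, mem in f.lines().items() if len(mem) == 1},
    )
    for _ in range(cfg.n_conflicts_injected):
        ped, truth = inject_conflict(ped, truth, mode="single_individual", rng=rng)
    for _ in range(cfg.n_misplaced_branches):
        ped, truth = inject_conflict(ped, truth, mode="misplaced_branch", rng=rng)
    return ped, truth


def _foreign_label(truth: GroundTruth, own: str) -> str:
    for lab in sorted(set(truth.true_line_haplotype.values())):
        if lab != own:
            return lab
    return "HT_FOREIGN"


def _set_haplotype(p: Pedigree, individual: str, hap: str | None) -> Pedigree:
    recs = [
        replace(r, haplotype=hap) if r.id == individual else r for r in p.records
    ]
    return Pedigree(recs, has_haplotype=True, has_available=p.has_available)


def inject_conflict(
    p: Pedigree,
    truth: GroundTruth,
    mode: str,
    rng: np.random.Generator | None = None,
) -> tuple[Pedigree, GroundTruth]:
    """Mutate a clean pedigree to carry one verifiable recording error."""
    if rng is None:
        rng = np.random.default_rng(0)
    f = build_forest(p)
    if mode == "single_individual":
        return _inject_single(p, truth, f, rng)
    if mode == "misplaced_branch":
        return _inject_branch(p, truth, f, rng)
    raise ConfigError(f"unknown injection mode {mode!r}")


def _inject_single(
    p: Pedigree, truth: GroundTruth, f: UniparentalForest, rng: np.random.Generator
) -> tuple[Pedigree, GroundTruth]:
    touched = {c.individual for c in truth.injected_conflicts} | {
        m for b in truth.injected_branches for m in (b.relocation_node, *b.branch_members)
    }
    touched_lines = {f.line_of[i] for i in touched}
    candidates = []
    for root, members in sorted(f.lines().items()):
        if root in touched_lines:
            continue
        seq = [m for m in members if p.record(m).haplotype is not None]
        if len(seq) >= 3:
            candidates.append((root, seq))
    if not candidates:
        raise ConfigError("no line with >= 3 sequenced members to inject a conflict into")
    root, seq = candidates[int(rng.integers(0, len(candidates)))]
    victim = seq[int(rng.integers(0, len(seq)))]
    own = truth.true_line_haplotype[root]
    foreign = _foreign_label(truth, own)
    mutated = _set_haplotype(p, victim, foreign)
    new_truth = GroundTruth(
        line_of=truth.line_of,
        true_line_haplotype=truth.true_line_haplotype,
        sequenced=truth.sequenced,
        singleton_lines=truth.singleton_lines,
        injected_conflicts=truth.injected_conflicts
        + [InjectedConflict(victim, own, foreign)],
        injected_branches=list(truth.injected_branches),
    )
    return mutated, new_truth


def _inject_branch(
    p: Pedigree, truth: GroundTruth, f: UniparentalForest, rng: np.random.Generator
) -> tuple[Pedigree, GroundTruth]:
    """Plant a misplaced branch inside a host line.

    Picks a node ``u`` with a child ``c`` whose subtree holds >= 2 sequenced
    members, then rewrites haplotypes so that {u, c, sequenced(subtree(c))}
    all carry a foreign haplotype while the rest of subtree(u) is
    unsequenced.  Requires the host line to keep strictly more sequenced
    native members than the foreign block so the verifier flags the block.
    """
    touched = {c.individual for c in truth.injected_conflicts} | {
        m for b in truth.injected_branches for m in (b.relocation_node, *b.branch_members)
    }
    touched_lines = {f.line_of[i] for i in touched}
    candidates: list[tuple[str, str, str]] = []  # (root, u, c)
    for root, members in sorted(f.lines().items()):
        if root in touched_lines:
            continue
        seq_line = {m for m in members if p.record(m).haplotype is not None}
        for u in members:
            if u == root:
                continue  # relocating the whole line leaves no host conflict
            sub_u = set(f.subtree(u))
            for c in f.children_of.get(u, ()):
                sub_c = set(f.subtree(c))
                seq_c = (seq_line & sub_c) | {c}
                block = len(seq_c) + 1  # plus u
                native = len(seq_line - sub_u - {u})
                if len(seq_c) >= 2 and native > block:
                    candidates.append((root, u, c))
    if not candidates:
        raise ConfigError("no subtree suitable for a misplaced-branch injection")
    root, u, c = candidates[int(rng.integers(0, len(candidates)))]
    own = truth.true_line_haplotype[root]
    foreign = _foreign_label(truth, own)

    sub_u = set(f.subtree(u))
    sub_c = set(f.subtree(c))
    block = {u, c} | {
        m for m in sub_c if p.record(m).haplotype is not None
    }
    recs = []
    for r in p.records:
        if r.id in block:
            recs.append(replace(r, haplotype=foreign))
        elif r.id in sub_u:
            recs.append(replace(r, haplotype=None))
        else:
            recs.append(r)
    mutated = Pedigree(recs, has_haplotype=True, has_available=p.has_available)
    members = tuple(sorted(block - {u}))
    new_truth = GroundTruth(
        line_of=truth.line_of,
        true_line_haplotype=truth.true_line_haplotype,
        sequenced=truth.sequenced,
        singleton_lines=truth.singleton_lines,
        injected_conflicts=list(truth.injected_conflicts),
        injected_branches=truth.injected_branches
        + [InjectedBranch(u, c, members, foreign, root)],
    )
    return mutated, new_truth
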