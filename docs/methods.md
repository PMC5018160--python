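# Methods

This note documents the models and algorithms implemented in `matriline`,
the numerical and design choices made where the problem left room, what the
synthetic-pedigree generator does and does not emulate, and the package's
known limitations.

## The matrilineal forest

Following mother links upward from any individual ends at an individual with
an unknown (or unrecorded) mother; that terminal individual roots a
*maternal line*. Lines partition the pedigree: males belong to their
mother's line (as leaves — a male cannot appear in the mother column once
gender checks pass), and an individual with an unknown mother roots its own
line, so founder sires and immigrants form singleton lines. Singleton lines
count in the number of lines L and among the k founder lines; nothing in the
data distinguishes "a male founder" from "a one-member maternal line whose
future is unrecorded", and excluding them would silently bias the founder
identity downward. The same builder run on father links yields the paternal
forest for the symmetric paternal-line calculation.

Distances are tree distances in a line's mother-link tree:
`d(i,j) = depth(i) + depth(j) − 2·depth(mrca(i,j))`. They are exact path
lengths, verified in the tests against a general shortest-path oracle
(networkx) on the mother-link graph.

Fatal errors are detected before anything else: ancestry cycles (an
individual its own ancestor through any parent chain — detected as strongly
connected components of the child→parent graph, which covers the
self-parent case) and parental-role gender inconsistencies (a recorded
female in the father column, a recorded male in the mother column, or one
id in both parent columns). All errors are collected and reported in a
single run; collecting more than the first changes no accept/reject
decision but saves round trips. Parent ids without records are
auto-corrected: referenced once, the reference is dropped (it carries no
relational information); referenced twice or more, a record is created with
the gender implied by the parental column. The operation is idempotent and
logged.

## Verification indices

A *conflicting pair* is two sequenced same-line individuals with different
haplotypes. Pairwise conflict counts are computed from per-line haplotype
tallies (`count(i) = haplotyped in line − carriers of i's haplotype`) in
linear time; the test suite checks this against brute-force pair
enumeration. An individual is *conflicting* when its count exceeds that of
every individual it conflicts with; for 1-vs-1 ties the strict rule flags
neither, which leaves real errors invisible, so the default tie rule flags
both members and surfaces the pair for curation (`strict` remains available
as a switch — `--strict-ties`).

*Informative* individuals — those on a tree path between two sequenced
same-line individuals — are computed per line as the minimal subtree
spanning the sequenced members, in linear time from subtree counts: a node
v is informative iff its subtree contains at least one sequenced member and
either (a) another sequenced member lies outside the subtree, (b) v is
itself sequenced, or (c) sequenced members occur in two different child
subtrees of v. The tests verify equivalence with the union-of-paths
definition by pair enumeration.

A conflicting individual whose nearest sequenced maternal ancestor shares
its haplotype is *misplaced*: the error is above it, and a whole branch is
sitting in the wrong line. A reported branch is the maximal maternal
subtree rooted at a misplaced individual with no misplaced ancestor; nested
misplaced roots merge into the outermost. Note an asymmetry inherent in the
definition: the topmost sequenced member of a relocated branch is itself
conflicting but never misplaced (its own nearest sequenced ancestor lies in
the host line), so the detected branch root sits one sequenced level below
the relocation point, and the relocation node is reported as an ordinary
conflicting individual. The pruned conflict count reduces each branch to a
single error: `pruned = conflicting − Σ_branches (branch conflicts − 1)`.

Indices: `HC = 100·conflicting/haplotyped`,
`IC = 100·(conflicting ∩ informative)/informative`,
`MISPLACED = 100·misplaced/conflicting`. A zero denominator yields
*undefined* with a reason, never a silent zero.

## Imputation and reference population

The reference population is every individual with a recorded birth year
inside the inclusive window; individuals without a birth year are counted
in line totals but never in the reference population. When the
`reference_years.txt` file is absent the window defaults to the pedigree's
full YOB span — a data-driven default in place of a hard-coded constant.

Imputation assigns each line's unique observed haplotype to all of its
members, inside and outside the reference window (line membership, not
cohort, determines mtDNA). It refuses to run while any line carries two
distinct haplotypes, because a conflicted line has no well-defined
haplotype; the CLI surfaces this as "run verif first" and exits non-zero.

## Probability of identity and effective size

For line frequencies q the probability of identity is PI = Σ q². Among k
founder lines q = 1/k, so PI_f = 1/k. In the reference population:

- *maternal* mode: q per founder dam = her female descendants in the
  reference population / all reference females (males carry their mother's
  mtDNA but do not transmit it);
- *haplotype* mode: q per haplotype = reference individuals (both sexes)
  with that imputed haplotype / reference size. Founder lines with no
  sequenced member receive deterministic unique pseudo-haplotypes
  `PSEUDO_<rootID>`, so unknown lines never merge and runs are
  reproducible;
- *paternal* mode: the mirror of maternal on father links and reference
  males.

ΔPI = (PI_r − PI_f)/(1 − PI_f) and N_e = 1/ΔPI, reported as INFINITE when
ΔPI = 0 (uniform line survival) and undefined with a reason when PI_f = 1
(a single founder line). A negative ΔPI cannot arise from a founder-uniform
frequency map against nested reference lines; it is treated as a hard error
(inconsistent inputs), never clamped. Closed-form limits used as tests: for
reference female counts {3,1} over two founder lines PI_r = 0.625,
ΔPI = 0.25, N_e = 4; collapsing all reference females into one of k lines
gives ΔPI = 1, N_e = 1.

All founder lines — including male singletons — count in k in every mode,
matching the line count L used by the sampler; lines represented in the
reference population only by males drop out of the maternal reference map
but stay in the haplotype map, and the stat reports list them separately.

## Sampling plans

**Allocation.** With no prior sequencings and budget N ≥ L, each line gets
one base slot and the remaining N − L slots are divided proportionally to
(R_l − 1); with L > N the N largest lines by R_l get one slot each. With
priors, the k unsequenced lines keep base slots and the pool
N − k + ΣP_l is divided proportionally to R_l into total targets T_l
(floored at 1 for unsequenced lines); new samplings are max(T_l − P_l, 0).
Proportional divisions use the largest-remainder (Hamilton) method, with
remainder ties broken by larger R_l then lexicographic line id. Two
refinements keep the budget conserved in degenerate cases:

- lines already sequenced beyond their proportional share are frozen at
  P_l and removed from the division (otherwise their excess priors would
  inflate other lines' targets past the budget);
- when every (R_l − 1) weight is zero (all singleton lines) the remaining
  slots are divided evenly so the R_l cap can record every
  undistributable slot as surplus.

Targets are capped at R_l; surplus and availability shortfalls are
reported, never redistributed — the user adjusts the budget or selects
manually. Consequences verified in tests: Σ new ≤ N always, with equality
in the no-priors branch when no caps bind; every unsequenced line gets a
slot whenever N ≥ L.

**Selection.** Within a line the goal is the group with the largest sum of
pairwise tree distances *that contains a central individual*: the first
pick minimizes SD_l,i, the sum of distances to all other pool members, and
each subsequent pick greedily maximizes the sum of distances to the
already-selected set. Previously sequenced members seed the selected set
(they shape dispersion, also when outside the reference window) and are
never re-picked. The central-containment constraint is part of the method's
contract, not an approximation artifact: the unconstrained optimum can
exclude the center (on a star it always does), but a central representative
is wanted when per-line slots are few. Against exhaustive enumeration over
groups containing the forced first pick, the greedy score is exact on all
chains and stars up to 12 members for every group size, and within 10% (in
practice exact) on random line trees up to 12 members. All ties break
lexicographically on individual id, so plans are reproducible.

The implementation maintains incremental distance sums (the contract is
the selected set, not any particular loop structure).

## Synthetic pedigrees

The generator emulates a closed breeding population: founder dams and
sires with unknown parents, then discrete generations in which each female
of the previous generation bears Poisson-distributed numbers of daughters
and sons (defaults: mean 1.5 each) sired by males of the previous
generation. Defaults — 10 founder dams, 5 founder sires, 5 generations,
birth years spread over 1980–2010, 6 haplotype labels, 30% of individuals
sequenced — give ≈500-individual pedigrees with unequal line sizes
(non-degenerate allocation and PI) and shared haplotypes across lines
(maternal N_e ≠ haplotype N_e). With at least as many labels as founder
lines, haplotypes are assigned distinct. Everything is reproducible from
the seed.

Error injection produces the two recovery targets: a *single conflict*
(one sequenced member of a line with ≥3 sequenced members gets another
line's haplotype) and a *misplaced branch* (a relocation node u and a
single child subtree are rewritten to a foreign haplotype, the rest of u's
subtree unsequenced, with the host line left strictly larger than the
foreign block). The branch pattern is constructed so exactly one branch
root is detectable — see the asymmetry noted above — which makes the
ground truth unambiguous.

What the generator does **not** model: mutation on haplotypes (any
difference is a conflict by design), overlapping generations, selection,
inbreeding avoidance, missing birth years, genotyping error. Passing
recovery tests therefore demonstrate correctness of the detection logic
under clean segregation, not robustness to mutation or genotyping noise in
real data.

## Numerical and degenerate-input choices

- Frequency maps are validated to sum to 1 within 1e−9 before squaring;
  PI of an empty map, an empty reference population, zero reference
  females (maternal) or males (paternal) raise undefined-result errors.
- Indices with zero denominators are reported as undefined with a reason.
- Unknown-parent tokens default to `""` and `"0"`; gender tokens
  `M/m/1` and `F/f/2`; all configurable. Anything else is unknown gender,
  non-fatal until it creates a parental-role inconsistency.
- `available` is true only for the literal token `1`.
- Auto-created parents referenced in both parental roles are impossible:
  that configuration is a fatal gender inconsistency caught beforehand.
- The scale test uses a ≈100k-record generated pedigree (3500 founder
  dams, 6 generations) for the linear-time verif/stat/calc path; the
  sampler's per-line selection is quadratic in line size and is exercised
  at planning scales (hundreds per line).

## Limitations

- Y-chromosome haplotype effective size is not implemented (the paternal
  analogue of haplotype mode would require male-line haplotype data).
- No mutation-rate modelling: a single real mutation inside a line is
  indistinguishable from a recording error and will be flagged.
- The tie rules (flag-both, lexicographic) and the branch-extent rule
  (maximal subtree under the outermost misplaced root) are this package's
  documented choices among defensible alternatives; other tools may
  attribute ties or delimit branches differently.
- Sampling optimizes tree-distance dispersion only; no per-farm costs or
  multi-objective diversity criteria.
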