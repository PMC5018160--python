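"""Named text report files.

File names follow the ``Output<Module>_<Content>.txt`` convention
(``OutputVerif_Summary.txt``, ``OutputStat_DamLineMembership_1.txt``,
``OutputCalc_InputAndResults.txt``, ``OutputSampl_IndividualsForSampling.txt``,
``ERROR_ALERT.TXT``, ``autocorrection_log.txt``).  Layouts are plain,
line-oriented text documented here; the stat membership files additionally get
machine-readable TSV twins.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

from .effsize import EffectiveSizeResult
from .forest import UniparentalForest
from .pedigree_io import AutocorrectLog, FatalError, Pedigree
from .sampling import SamplingPlan
from .stats import LineDistribution
from .verify import ConflictReport


def _write(path: Path, lines: Iterable[str]) -> Path:
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _fmt_index(value: float | None, reason: str | None) -> str:
    if value is None:
        return f"undefined ({reason})"
    return f"{value:.2f} %"


def write_error_alert(errors: list[FatalError], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    lines = ["FATAL PEDIGREE ERRORS", ""]
    for e in errors:
        lines.append(f"[{e.kind}] {e.message}")
    return _write(out / "ERROR_ALERT.TXT", lines)


def write_autocorrection_log(log: AutocorrectLog, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    lines = ["Auto-correction of parent references without own records", ""]
    lines.append(f"deleted parent references (set to unknown): {len(log.deleted_parent_refs)}")
    for child, parent in log.deleted_parent_refs:
        lines.append(f"  {parent} (referenced once, by {child})")
    lines.append(f"created parent records: {len(log.created_records)}")
    for ind in log.created_records:
        lines.append(f"  {ind}")
    return _write(out / "autocorrection_log.txt", lines)


def write_verif_reports(
    report: ConflictReport,
    p: Pedigree,
    out_dir: str | Path,
    include_pairs: bool = False,
) -> list[Path]:
    out = Path(out_dir)
    paths = []
    summary = [
        "Maternal-line haplotype concordance: summary",
        "",
        f"individuals in pedigree:     {len(p)}",
        f"haplotyped individuals:      {report.n_haplotyped}",
        f"informative individuals:     {len(report.informative_individuals)}",
        f"conflicting pairs:           {len(report.conflicting_pairs)}",
        f"conflicting individuals:     {len(report.conflicting_individuals)}",
        f"misplaced individuals:       {len(report.misplaced_individuals)}",
        f"misplaced branches:          {len(report.misplaced_branches)}",
        f"pruned conflict count:       {report.pruned_conflicts}",
        "",
        f"HC index:        {_fmt_index(report.hc_index, report.undefined.get('hc'))}",
        f"IC index:        {_fmt_index(report.ic_index, report.undefined.get('ic'))}",
        f"MISPLACED index: {_fmt_index(report.misplaced_index, report.undefined.get('misplaced'))}",
    ]
    paths.append(_write(out / "OutputVerif_Summary.txt", summary))

    units = ["conflicting individual\tpairwise conflicts"]
    for ind in sorted(report.conflicting_individuals):
        units.append(f"{ind}\t{report.conflict_count.get(ind, 0)}")
    paths.append(_write(out / "OutputVerif_ConflictingUnits.txt", units))

    branches = ["branch root\tconflicts in branch"]
    for root, cnt in report.misplaced_branches:
        branches.append(f"{root}\t{cnt}")
    paths.append(_write(out / "OutputVerif_MisplacedBranches.txt", branches))

    if include_pairs:
        pairs = ["individual 1\tindividual 2"]
        for i, j in sorted(report.conflicting_pairs):
            pairs.append(f"{i}\t{j}")
        paths.append(_write(out / "OutputVerif_ConflictingPairs.txt", pairs))
    return paths


def write_stat_reports(
    dist: LineDistribution,
    f: UniparentalForest,
    p: Pedigree,
    refpop: set[str],
    imputed: dict[str, str | None],
    out_dir: str | Path,
) -> list[Path]:
    out = Path(out_dir)
    paths = []

    lines1 = ["Maternal-line membership by founder dam", ""]
    for root in f.roots:
        st = dist.per_line[root]
        hap = st.haplotype if st.haplotype is not None else "UNASSIGNED"
        lines1.append(
            f"founder dam {root}: descendants={st.total} "
            f"in_ref={st.all_in_ref} females_in_ref={st.females_in_ref} haplotype={hap}"
        )
        for member in f.members(root):
            lines1.append(f"  {member}")
        lines1.append("")
    paths.append(_write(out / "OutputStat_DamLineMembership_1.txt", lines1))

    lines2 = ["individual\tfounder dam\timputed haplotype"]
    for r in p:
        hap = imputed.get(r.id)
        lines2.append(f"{r.id}\t{f.line_of[r.id]}\t{hap if hap is not None else 'UNASSIGNED'}")
    paths.append(_write(out / "OutputStat_DamLineMembership_2.txt", lines2))

    all_ref = ["individual\tfounder dam"]
    fem_ref = ["individual\tfounder dam"]
    from .pedigree_io import Gender

    for ind in sorted(refpop):
        row = f"{ind}\t{f.line_of[ind]}"
        all_ref.append(row)
        if p.record(ind).gender is Gender.FEMALE:
            fem_ref.append(row)
    paths.append(_write(out / "OutputStat_DamLineMembershipAllInRefPop.txt", all_ref))
    paths.append(_write(out / "OutputStat_DamLineMembershipFemaleOnlyInRefPop.txt", fem_ref))

    withf = ["founder dam\tfemales in ref\tall in ref\ttotal descendants"]
    for root in dist.lines_with_females_in_ref:
        st = dist.per_line[root]
        withf.append(f"{root}\t{st.females_in_ref}\t{st.all_in_ref}\t{st.total}")
    paths.append(_write(out / "OutputStat_DamLinesWithFemalesInRefPop.txt", withf))

    onlym = ["founder dam\tall in ref\ttotal descendants"]
    for root in dist.lines_with_only_males_in_ref:
        st = dist.per_line[root]
        onlym.append(f"{root}\t{st.all_in_ref}\t{st.total}")
    paths.append(_write(out / "OutputStat_DamLinesWithOnlyMalesInRefPop.txt", onlym))

    # machine-readable twin of the per-line distribution
    tsv = ["founder_dam\ttotal\tall_in_ref\tfemales_in_ref\thaplotype"]
    for root in f.roots:
        st = dist.per_line[root]
        tsv.append(
            f"{root}\t{st.total}\t{st.all_in_ref}\t{st.females_in_ref}\t"
            f"{st.haplotype if st.haplotype is not None else 'UNASSIGNED'}"
        )
    paths.append(_write(out / "OutputStat_DamLineDistribution.tsv", tsv))
    return paths


def _fmt_ne(res: EffectiveSizeResult) -> list[str]:
    lines = [f"[{res.mode} lines]"]
    lines.append(f"  founder lines/haplotypes: {len(res.frequencies_founder)}")
    lines.append(f"  PI founder:   {res.pi_founder:.6f}")
    lines.append(f"  PI reference: {res.pi_reference:.6f}")
    if res.delta_pi is None:
        lines.append(f"  delta PI:     undefined ({res.undefined_reason})")
        lines.append("  Ne:           undefined")
    else:
        lines.append(f"  delta PI:     {res.delta_pi:.6f}")
        lines.append(
            "  Ne:           INFINITE" if math.isinf(res.ne or 0) else f"  Ne:           {res.ne:.4f}"
        )
    lines.append("  reference frequencies:")
    for label in sorted(res.frequencies_reference):
        lines.append(f"    {label}\t{res.frequencies_reference[label]:.6f}")
    return lines


def write_calc_report(
    results: dict[str, EffectiveSizeResult | None],
    p: Pedigree,
    refpop: set[str],
    out_dir: str | Path,
    notes: dict[str, str] | None = None,
) -> Path:
    out = Path(out_dir)
    lines = [
        "Uniparental effective population sizes (probability of identity)",
        "",
        f"individuals in pedigree:        {len(p)}",
        f"reference population size:      {len(refpop)}",
        "",
    ]
    for mode in ("maternal", "haplotype", "paternal"):
        res = results.get(mode)
        if res is None:
            reason = (notes or {}).get(mode, "not computed")
            lines.append(f"[{mode} lines]")
            lines.append(f"  undefined ({reason})")
        else:
            lines.extend(_fmt_ne(res))
        lines.append("")
    return _write(out / "OutputCalc_InputAndResults.txt", lines)


def write_sampl_reports(plan: SamplingPlan, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    paths = []

    chosen = ["individual\tmaternal line"]
    for root in sorted(plan.lines):
        for ind in plan.lines[root].selected:
            chosen.append(f"{ind}\t{root}")
    paths.append(_write(out / "OutputSampl_IndividualsForSampling.txt", chosen))

    detail = [
        f"planned number of sequencings: {plan.n_planned}",
        f"maternal lines in reference population: {len(plan.lines)}",
        f"new samplings selected: {plan.total_new}",
        "",
        "line\tR_l\tP_l\ttarget N_l\tnew\tselected\tshortfall\tsurplus",
    ]
    for root in sorted(plan.lines):
        lp = plan.lines[root]
        a = lp.allocation
        detail.append(
            f"{root}\t{a.r}\t{a.p}\t{a.target}\t{a.new}\t"
            f"{len(lp.selected)}\t{lp.shortfall}\t{a.surplus}"
        )
    paths.append(_write(out / "OutputSampl_DetailedInfo.txt", detail))

    if plan.availability_used:
        restr = [
            "Availability restrictions on the sampling plan",
            "",
            "line\tplanned new\tavailable candidates\tshortfall",
        ]
        for root in sorted(plan.lines):
            lp = plan.lines[root]
            restr.append(
                f"{root}\t{lp.allocation.new}\t{lp.pool_size}\t{lp.shortfall}"
            )
        paths.append(_write(out / "OutputSampl_AvailabilityRestrictions.txt", restr))
    return paths
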