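"""Shared fixtures: hand-built pedigrees and synthetic generation helpers."""

from __future__ import annotations

import pytest

from matriline.pedigree_io import Gender, Pedigree, PedigreeRecord


def rec(ind, sire=None, dam=None, yob=None, gender=Gender.FEMALE, hap=None, avail=False):
    return PedigreeRecord(
        id=ind, sire=sire, dam=dam, yob=yob, gender=gender, haplotype=hap, available=avail
    )


def chain_pedigree(n: int, prefix: str = "a") -> Pedigree:
    """Mother-link chain a00 <- a01 <- ... (all female)."""
    recs = [rec(f"{prefix}00")]
    for i in range(1, n):
        recs.append(rec(f"{prefix}{i:02d}", dam=f"{prefix}{i - 1:02d}"))
    return Pedigree(recs)


def star_pedigree(n_daughters: int, prefix: str = "s") -> Pedigree:
    """Founder dam with n direct daughters."""
    recs = [rec(f"{prefix}F")]
    recs += [rec(f"{prefix}{i:02d}", dam=f"{prefix}F") for i in range(n_daughters)]
    return Pedigree(recs)


@pytest.fixture
def conflict_line() -> Pedigree:
    """One line {x: A, y: A, z: B} hanging off founder F, plus a second
    concordant line to keep indices non-degenerate."""
    return Pedigree(
        [
            rec("F"),
            rec("x", dam="F", hap="A"),
            rec("y", dam="F", hap="A"),
            rec("z", dam="F", hap="B"),
            rec("G"),
            rec("g1", dam="G", hap="C"),
        ]
    )


@pytest.fixture
def csv_writer(tmp_path):
    def write(text: str, name: str = "ped.csv"):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path

    return write
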