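"""Reference cohort: published aneuploid egg/polar-body karyotypes.

A published Nocodazole dose-response IVM experiment screened matched
mouse egg / first-polar-body pairs by shallow sequencing (control n=11,
25 nM n=13, 50 nM n=23 analyzable pairs) and printed the karyotype
strings of the 20 aneuploid pairs.  Those strings are bundled here as a
validation input: re-parsing and re-classifying them must reproduce the
published aneuploidy-type and severity tallies, which exercises the
karyotype grammar and the reciprocal classification end to end on real
calls rather than simulated ones.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reciprocal import (
    ReciprocalCallSet,
    SampleKaryotype,
    classify_sample,
    designate_pair,
    parse_karyotype,
)

__all__ = [
    "CohortPair",
    "REFERENCE_PAIRS",
    "GROUP_SIZES",
    "reference_callsets",
    "reference_karyotypes",
]


@dataclass(frozen=True)
class CohortPair:
    sample_id: str
    treatment: str
    egg_karyotype: str
    pb_karyotype: str
    published_type: str


#: analyzable pairs per treatment group (after QC and exclusions)
GROUP_SIZES: dict[str, int] = {"control": 11, "25 nM": 13, "50 nM": 23}

#: the 20 aneuploid pairs; all other pairs in the cohort were euploid
REFERENCE_PAIRS: tuple[CohortPair, ...] = (
    CohortPair("Sample 1", "25 nM", "sseq cht(1)x4", "sseq cht(1)x0", "NDJ"),
    CohortPair("Sample 2", "50 nM", "sseq cht(4)x4", "sseq cht(4)x0", "NDJ"),
    CohortPair("Sample 3", "50 nM", "sseq cht(4)x4", "sseq cht(4)x0", "NDJ"),
    CohortPair("Sample 4", "50 nM", "sseq cht(7)x0", "sseq cht(7)x4", "NDJ"),
    CohortPair("Sample 5", "50 nM", "sseq cht(1)x1", "sseq cht(1)x3", "PSSC"),
    CohortPair("Sample 6", "50 nM", "sseq cht(8,11)x0", "sseq cht(8,11)x4", "NDJ"),
    CohortPair(
        "Sample 7", "50 nM", "sseq cht(2,16,18)x4", "sseq cht(2,16,18)x0", "NDJ"
    ),
    CohortPair(
        "Sample 8",
        "50 nM",
        "sseq cht(14)x4, cht(18)x0",
        "sseq cht(14)x0, cht(18)x4",
        "NDJ",
    ),
    CohortPair(
        "Sample 9",
        "50 nM",
        "sseq cht(9)x0, cht(12,14)x4",
        "sseq cht(9)x4, cht(12,14)x0",
        "NDJ",
    ),
    CohortPair(
        "Sample 10", "50 nM", "sseq cht(4,9,16,19)x0", "sseq cht(4,9,16,19)x4", "NDJ"
    ),
    CohortPair(
        "Sample 11",
        "50 nM",
        "sseq cht(1,8)x0, cht(4,18)x4",
        "sseq cht(1,8)x4, cht(4,18)x0",
        "NDJ",
    ),
    CohortPair(
        "Sample 12",
        "50 nM",
        "sseq cht(5)x4, cht(6,12,14)x0",
        "sseq cht(5)x0, cht(6,12,14)x4",
        "NDJ",
    ),
    CohortPair(
        "Sample 13",
        "50 nM",
        "sseq cht(1,10,17)x0, cht(2)x3",
        "sseq cht(1,10,17)x4, cht(2)x1",
        "NDJ+PSSC",
    ),
    CohortPair(
        "Sample 14",
        "50 nM",
        "sseq cht(X, 1-6,8-19)x0, cht(7)x4",
        "sseq cht(X , 1-6,8-19)x4, cht(7)x0",
        "NDJ",
    ),
    CohortPair(
        "Sample 15",
        "50 nM",
        "sseq cht(X, 1-6,8-19)x0, cht(7)x4",
        "sseq cht(X , 1-6,8-19)x4, cht(7)x0",
        "NDJ",
    ),
    CohortPair(
        "Sample 16",
        "50 nM",
        "sseq cht(X, 1-10,12,13,15-19)x0, cht(11,14)x3",
        "sseq cht(X , 1-10,12,13,15-19)x4, cht(11,14)x1",
        "NDJ+PSSC",
    ),
    CohortPair(
        "Sample 17",
        "50 nM",
        "sseq cht(X, 1-4, 6-17,19)x0, cht(5,18)x3",
        "sseq cht(X , 1-4, 6-17,19)x4, cht(5,18)x1",
        "NDJ+PSSC",
    ),
    CohortPair(
        "Sample 18",
        "50 nM",
        "sseq cht(1,3-8,10-13,15-19)x0, cht(X, 2,9,14)x3",
        "sseq cht(1,3-8,10-13,15-19)x4, cht(X , 2,9,14)x1",
        "NDJ+PSSC",
    ),
    CohortPair(
        "Sample 19",
        "50 nM",
        "sseq cht(X, 1,3-9,12,13)x3, cht(2,10,11,14,16-19)x0, cht(15)x1",
        "sseq cht(X , 1,3-9, 12,13)x1, cht(2,10,11,14,16-19)x4, cht(15)x3",
        "NDJ+PSSC",
    ),
    CohortPair(
        "Sample 20",
        "50 nM",
        "sseq cht(X, 1-4,6-8,11-17,19)x0, cht(5)x4, cht(9,10,18)x3",
        "sseq cht(X , 1-4,6-8,11-17,19)x4, cht(5)x0, cht(9,10,18)x1",
        "NDJ+PSSC",
    ),
)


def reference_callsets() -> list[ReciprocalCallSet]:
    """Parse the bundled karyotype strings into designated call sets."""
    out = []
    for pair in REFERENCE_PAIRS:
        egg = {c: float(v) for c, v in parse_karyotype(pair.egg_karyotype).items()}
        pb = {c: float(v) for c, v in parse_karyotype(pair.pb_karyotype).items()}
        out.append(designate_pair(egg, pb, pair_id=pair.sample_id))
    return out


def reference_karyotypes() -> list[SampleKaryotype]:
    """Classify every bundled pair (type, severity, error count)."""
    return [classify_sample(cs) for cs in reference_callsets()]
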