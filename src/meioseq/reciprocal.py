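"""Reciprocal egg/polar-body aneuploidy designation and classification.

At meiosis I each bivalent's four chromatids are partitioned between the
egg and the first polar body, so for every chromosome the designated
integer chromatid counts must satisfy ``egg + pb = 4``.  The reciprocal
pattern identifies the error mechanism:

* ``(2, 2)`` — normal segregation (euploid for that chromosome);
* ``(3, 1)`` or ``(1, 3)`` — premature separation of sister chromatids
  (PSSC): one chromatid crossed over to the wrong cell;
* ``(4, 0)`` or ``(0, 4)`` — non-disjunction (NDJ): the whole bivalent
  segregated to one cell.

This module designates integer copies from fractional observed copy
numbers under that conservation constraint, classifies chromosomes and
whole samples, and reads/writes the shallow-sequencing karyotype string
nomenclature (``sseq cht(...)xN`` clauses).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import AUTOSOME_NAMES

__all__ = [
    "EUPLOID_TOKEN",
    "ChromosomeCall",
    "ReciprocalCallSet",
    "SampleKaryotype",
    "KaryotypeParseError",
    "classify_chromosome",
    "designate_pair",
    "fit_pair_scales",
    "classify_sample",
    "write_karyotype",
    "parse_karyotype",
    "sex_concordance_blastomeres",
    "sex_concordance_egg_pb",
]

TOTAL_CHROMATIDS = 4  # per bivalent, split between egg and PB1

#: rendering of a karyotype with no abnormal chromosomes
EUPLOID_TOKEN = "sseq euploid"

#: chromosomes carried by oocyte-derived samples, X first in karyotype order
_KARYOTYPE_ORDER: tuple[str, ...] = ("X",) + AUTOSOME_NAMES


@dataclass(frozen=True)
class ChromosomeCall:
    """Designated (egg, pb) chromatid counts and error class for one chromosome."""

    chrom: str
    egg: int | None
    pb: int | None
    label: str  # euploid | PSSC | NDJ | discordant
    residual: float

    @property
    def is_error(self) -> bool:
        return self.label in ("PSSC", "NDJ")


@dataclass(frozen=True)
class ReciprocalCallSet:
    """Per-chromosome designated copies for one matched egg/PB pair."""

    pair_id: str
    calls: tuple[ChromosomeCall, ...]

    def by_chrom(self) -> dict[str, ChromosomeCall]:
        return {c.chrom: c for c in self.calls}

    @property
    def concordant(self) -> bool:
        return all(c.label != "discordant" for c in self.calls)

    def egg_copies(self) -> dict[str, int]:
        return {c.chrom: c.egg for c in self.calls if c.egg is not None}

    def pb_copies(self) -> dict[str, int]:
        return {c.chrom: c.pb for c in self.calls if c.pb is not None}


@dataclass(frozen=True)
class SampleKaryotype:
    """Pair-level summary: karyotype strings, error type, and severity."""

    pair_id: str
    egg_karyotype: str
    pb_karyotype: str
    aneuploidy_type: str  # euploid | NDJ | PSSC | NDJ+PSSC
    severity: str  # euploid | 1-3 | >=4
    n_errors: int
    n_discordant: int = 0


def classify_chromosome(egg: int, pb: int) -> str:
    """Map a designated (egg, pb) chromatid pair to its error class.

    Requires ``egg + pb == 4``; callers holding a pair that cannot be
    reconciled with conservation must route it to discordant handling
    instead.
    """
    if egg + pb != TOTAL_CHROMATIDS:
        raise ValueError(
            f"(egg={egg}, pb={pb}) violates chromatid conservation (sum must be 4)"
        )
    if (egg, pb) == (2, 2):
        return "euploid"
    if (egg, pb) in ((3, 1), (1, 3)):
        return "PSSC"
    return "NDJ"  # (4,0) or (0,4)


def fit_pair_scales(
    egg_cn: Mapping[str, float],
    pb_cn: Mapping[str, float],
    ridge: float = 0.05,
) -> tuple[float, float]:
    """Joint rescaling of a pair's observed copy numbers under conservation.

    Within-sample normalization fixes each sample's autosomal total, so a
    sample whose true complement deviates grossly from euploid (e.g. a
    near-whole-complement segregation error) has all its observed copy
    numbers multiplied by an unknown common factor.  The chromatid
    conservation constraint ``egg + pb = 4`` identifies those factors:
    we fit scales ``(a, b)`` minimizing

        sum_c (a*egg_c + b*pb_c - 4)^2  +  ridge * n * ((a-1)^2 + (b-1)^2)

    The small ridge term anchors the fit at (1, 1) when the data leave a
    direction unconstrained (e.g. a fully euploid pair, where only the
    sum a+b is identified).
    """
    chroms = [c for c in egg_cn if c in pb_cn]
    if not chroms:
        raise ValueError("no shared chromosomes between egg and PB profiles")
    x = np.array([egg_cn[c] for c in chroms], dtype=float)
    y = np.array([pb_cn[c] for c in chroms], dtype=float)
    n = len(chroms)
    lam = ridge * n
    # normal equations of the penalized least squares
    ata = np.array(
        [[np.dot(x, x) + lam, np.dot(x, y)], [np.dot(x, y), np.dot(y, y) + lam]]
    )
    atb = np.array(
        [TOTAL_CHROMATIDS * x.sum() + lam, TOTAL_CHROMATIDS * y.sum() + lam]
    )
    a, b = np.linalg.solve(ata, atb)
    return float(a), float(b)


def _designate_one(obs_egg: float, obs_pb: float, tol: float) -> ChromosomeCall | None:
    """Choose integers (e, p), e+p=4, nearest to the observed pair.

    Brute force over the five admissible pairs; ties broken toward the
    euploid (2, 2) configuration.  Returns None fields (discordant) when
    the best residual exceeds ``tol``.
    """
    best: tuple[float, int, int, int] | None = None
    for e in range(TOTAL_CHROMATIDS + 1):
        p = TOTAL_CHROMATIDS - e
        resid = math.sqrt((e - obs_egg) ** 2 + (p - obs_pb) ** 2)
        key = (round(resid, 12), abs(e - 2))
        if best is None or key < (best[0], best[3]):
            best = (key[0], e, p, key[1])
    assert best is not None
    resid, e, p, _ = best
    if resid > tol:
        return None
    return ChromosomeCall("", e, p, classify_chromosome(e, p), resid)


def designate_pair(
    egg_cn: Mapping[str, float],
    pb_cn: Mapping[str, float],
    pair_id: str = "",
    *,
    tol: float = 0.5,
    rescale: bool = False,
) -> ReciprocalCallSet:
    """Designate integer chromatid counts for a matched egg/PB pair.

    Both profiles must cover the same chromosomes (X included, Y
    excluded).  For each chromosome the integer pair ``(e, p)`` with
    ``e + p = 4`` nearest in Euclidean distance to the observed pair is
    chosen; a chromosome whose best residual exceeds ``tol`` (default
    0.5, the half-copy rounding radius) is marked discordant rather than
    forced.  With ``rescale=True`` the conservation-constrained scale fit
    (:func:`fit_pair_scales`) is applied first, which is required for
    pairs with near-whole-complement errors.
    """
    missing = set(egg_cn) ^ set(pb_cn)
    if missing:
        raise ValueError(
            f"pair {pair_id!r}: chromosomes not shared by both profiles: "
            f"{sorted(missing)}"
        )
    egg = dict(egg_cn)
    pb = dict(pb_cn)
    if rescale:
        a, b = fit_pair_scales(egg, pb)
        egg = {c: a * v for c, v in egg.items()}
        pb = {c: b * v for c, v in pb.items()}

    order = [c for c in _KARYOTYPE_ORDER if c in egg]
    order += [c for c in egg if c not in order]
    calls: list[ChromosomeCall] = []
    for chrom in order:
        call = _designate_one(egg[chrom], pb[chrom], tol)
        if call is None:
            resid = min(
                math.sqrt((e - egg[chrom]) ** 2 + (4 - e - pb[chrom]) ** 2)
                for e in range(5)
            )
            calls.append(ChromosomeCall(chrom, None, None, "discordant", resid))
        else:
            calls.append(
                ChromosomeCall(chrom, call.egg, call.pb, call.label, call.residual)
            )
    return ReciprocalCallSet(pair_id=pair_id, calls=tuple(calls))


def classify_sample(callset: ReciprocalCallSet) -> SampleKaryotype:
    """Summarize a pair: error count, severity bucket, and error type.

    Severity buckets: 0 errors -> ``euploid``; 1..3 -> ``1-3``;
    >=4 -> ``>=4``.  Discordant chromosomes are tallied separately and
    never counted as segregation errors.
    """
    labels = [c.label for c in callset.calls if c.is_error]
    n_errors = len(labels)
    n_disc = sum(1 for c in callset.calls if c.label == "discordant")
    has_ndj = "NDJ" in labels
    has_pssc = "PSSC" in labels
    if n_errors == 0:
        atype = "euploid"
    elif has_ndj and has_pssc:
        atype = "NDJ+PSSC"
    elif has_ndj:
        atype = "NDJ"
    else:
        atype = "PSSC"
    if n_errors == 0:
        severity = "euploid"
    elif n_errors <= 3:
        severity = "1-3"
    else:
        severity = ">=4"
    egg_copies = {c.chrom: c.egg for c in callset.calls if c.egg is not None}
    pb_copies = {c.chrom: c.pb for c in callset.calls if c.pb is not None}
    return SampleKaryotype(
        pair_id=callset.pair_id,
        egg_karyotype=write_karyotype(egg_copies),
        pb_karyotype=write_karyotype(pb_copies),
        aneuploidy_type=atype,
        severity=severity,
        n_errors=n_errors,
        n_discordant=n_disc,
    )


def _collapse_runs(autosomes: list[int]) -> str:
    """Render sorted autosome numbers with maximal runs as 'a-b'."""
    out: list[str] = []
    i = 0
    while i < len(autosomes):
        j = i
        while j + 1 < len(autosomes) and autosomes[j + 1] == autosomes[j] + 1:
            j += 1
        if j > i + 1:
            out.append(f"{autosomes[i]}-{autosomes[j]}")
            i = j + 1
        elif j == i + 1:
            out.append(str(autosomes[i]))
            out.append(str(autosomes[i + 1]))
            i = j + 1
        else:
            out.append(str(autosomes[i]))
            i += 1
    return ",".join(out)


def write_karyotype(copies: Mapping[str, int]) -> str:
    """Render designated copies as a shallow-sequencing karyotype string.

    One ``cht(<chroms>)x<n>`` clause per abnormal copy value; within a
    clause X leads, then autosomes ascending with maximal consecutive
    runs collapsed to ``a-b``; clauses are ordered by their lowest
    chromosome, X sorting lowest.  A sample with no abnormal chromosome
    renders as the fixed euploid token.
    """
    for chrom, n in copies.items():
        if not (0 <= n <= TOTAL_CHROMATIDS):
            raise ValueError(f"chromosome {chrom}: copies {n} outside 0..4")
    by_copies: dict[int, list[str]] = {}
    for chrom, n in copies.items():
        if n != 2:
            by_copies.setdefault(n, []).append(chrom)
    if not by_copies:
        return EUPLOID_TOKEN

    clauses: list[tuple[float, str]] = []
    for n, chroms in by_copies.items():
        has_x = "X" in chroms
        autosomes = sorted(int(c) for c in chroms if c != "X")
        body = _collapse_runs(autosomes)
        if has_x:
            body = f"X, {body}" if body else "X"
        rank = 0.0 if has_x else float(autosomes[0])
        clauses.append((rank, f"cht({body})x{n}"))
    clauses.sort(key=lambda t: t[0])
    return "sseq " + ", ".join(text for _, text in clauses)


class KaryotypeParseError(ValueError):
    """Raised for strings outside the karyotype grammar; carries position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        at = f" (at position {position})" if position is not None else ""
        super().__init__(message + at)


_CLAUSE_RE = re.compile(r"cht\(([^)]*)\)\s*x\s*(\d+)")


def parse_karyotype(text: str, chromosomes: Sequence[str] = _KARYOTYPE_ORDER) -> dict[str, int]:
    """Parse a karyotype string back to per-chromosome designated copies.

    Whitespace-tolerant exact inverse of :func:`write_karyotype`;
    chromosomes not mentioned in any clause default to 2 copies.
    Malformed clauses, duplicated chromosomes, and copy values outside
    0..4 raise :class:`KaryotypeParseError`.
    """
    s = text.strip()
    copies: dict[str, int] = {c: 2 for c in chromosomes}
    if s == EUPLOID_TOKEN:
        return copies
    if not s.startswith("sseq"):
        raise KaryotypeParseError("karyotype must start with 'sseq'", 0)
    body = s[len("sseq"):].strip()
    if body == "euploid":
        return copies
    if not body:
        raise KaryotypeParseError("empty clause list", len("sseq"))

    pos = 0
    seen: set[str] = set()
    found_any = False
    remaining = body
    while remaining.strip():
        m = _CLAUSE_RE.match(remaining.strip())
        if m is None:
            raise KaryotypeParseError(
                f"malformed clause near {remaining.strip()[:25]!r}", pos
            )
        found_any = True
        chrom_list, n_str = m.group(1), m.group(2)
        n = int(n_str)
        if not (0 <= n <= TOTAL_CHROMATIDS):
            raise KaryotypeParseError(f"copy value {n} outside 0..4", pos)
        for item in chrom_list.split(","):
            item = item.strip()
            if not item:
                raise KaryotypeParseError("empty chromosome entry", pos)
            if item.upper() == "X":
                members = ["X"]
            elif "-" in item:
                lo_s, _, hi_s = item.partition("-")
                try:
                    lo, hi = int(lo_s.strip()), int(hi_s.strip())
                except ValueError:
                    raise KaryotypeParseError(f"bad range {item!r}", pos) from None
                if lo >= hi:
                    raise KaryotypeParseError(f"bad range {item!r}", pos)
                members = [str(k) for k in range(lo, hi + 1)]
            else:
                try:
                    int(item)
                except ValueError:
                    raise KaryotypeParseError(f"bad chromosome {item!r}", pos) from None
                members = [item]
            for chrom in members:
                if chrom not in copies:
                    raise KaryotypeParseError(f"unknown chromosome {chrom!r}", pos)
                if chrom in seen:
                    raise KaryotypeParseError(
                        f"chromosome {chrom!r} appears in more than one clause", pos
                    )
                seen.add(chrom)
                copies[chrom] = n
        consumed = len(remaining) - len(remaining.strip()) + m.end()
        remaining = remaining[consumed:]
        pos += consumed
        rest = remaining.lstrip()
        if rest.startswith(","):
            remaining = rest[1:]
        elif rest:
            raise KaryotypeParseError("expected ',' between clauses", pos)
        else:
            remaining = rest
    if not found_any:
        raise KaryotypeParseError("no clauses found", 0)
    return copies


def sex_concordance_blastomeres(
    sex_counts: Sequence[tuple[int, int]],
) -> dict[str, object]:
    """Check that all blastomeres of one embryo share identical (X, Y) counts.

    Returns the concordance flag, the consensus sex when concordant
    ((2,0) female, (1,1) male), and a warning for trivial single-member
    groups.
    """
    if not sex_counts:
        raise ValueError("empty blastomere group")
    warning = None
    if len(sex_counts) < 2:
        warning = "group has fewer than 2 blastomeres; concordance is trivial"
    concordant = len(set(sex_counts)) == 1
    sex = None
    if concordant:
        x, y = sex_counts[0]
        sex = {(2, 0): "female", (1, 1): "male"}.get((x, y), "atypical")
    return {
        "concordant": concordant,
        "sex": sex,
        "counts": list(sex_counts),
        "warning": warning,
    }


def sex_concordance_egg_pb(
    egg_sex: tuple[int, int], pb_sex: tuple[int, int]
) -> dict[str, object]:
    """Egg/PB sex check: both cells of a normal pair carry X=2, Y=0 chromatids."""
    expected = (2, 0)
    ok = egg_sex == expected and pb_sex == expected
    return {"concordant": ok, "egg": egg_sex, "pb": pb_sex, "expected": expected}
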