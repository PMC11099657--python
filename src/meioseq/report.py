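"""Cohort-level orchestration: calling, classification, and aggregation.

Ties the copy-number caller, the reciprocal designation, and the
morphokinetic statistics together into one report.  Every cohort
aggregate (incidence, type counts, severity counts) is recomputable
from the per-pair rows, and exclusion steps are logged with explicit
in/out counts so the n-accounting always sums.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cn import BinnedCounts, build_panel, call_profile, qc_sample, read_counts_tsv
from .genome import GenomeBinning, make_binning
from .morphokinetics import compare_groups, derive_variables, maturation_rates
from .reciprocal import ReciprocalCallSet, classify_sample, designate_pair
from .simulate import (
    MorphokineticRecord,
    SimulationConfig,
    StudyData,
    morphokinetics_to_frame,
    simulate_study,
)

__all__ = [
    "CohortReport",
    "PairResult",
    "call_pairs",
    "summarize_error_spectrum",
    "build_report",
    "run_pipeline",
]


@dataclass
class PairResult:
    pair_id: str
    treatment: str
    status: str  # analyzed | qc-failed
    qc_reason: str | None = None
    callset: ReciprocalCallSet | None = None


@dataclass
class CohortReport:
    """Per-pair rows plus cohort aggregates and processing log."""

    rows: pd.DataFrame
    aggregates: dict
    log: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "rows": self.rows.to_dict(orient="records"),
            "aggregates": self.aggregates,
            "log": self.log,
        }
        return json.dumps(payload, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def call_pairs(
    pairs: Sequence[tuple[BinnedCounts, BinnedCounts]],
    panel_norm: np.ndarray,
    binning: GenomeBinning,
    treatments: Mapping[str, str],
    *,
    rescale: bool = True,
    log: list[str] | None = None,
) -> list[PairResult]:
    """QC-gate and call every matched egg/PB pair against the panel.

    A pair is excluded (never silently dropped) when either sample fails
    the mapped-fraction QC.  Designation applies the conservation-
    constrained rescaling by default, which keeps pairs with
    near-whole-complement errors callable.
    """
    results: list[PairResult] = []
    log = log if log is not None else []
    for egg, pb in pairs:
        pair_id = egg.sample_id.removesuffix("_egg")
        treatment = treatments.get(pair_id, "unknown")
        failures = [
            (s.sample_id, qc_sample(s)) for s in (egg, pb)
        ]
        failed = [(sid, r) for sid, r in failures if not r.passed]
        if failed:
            reason = "; ".join(f"{sid}: {r.reason or r.status}" for sid, r in failed)
            log.append(f"pair {pair_id}: excluded at QC ({reason})")
            results.append(PairResult(pair_id, treatment, "qc-failed", reason))
            continue
        egg_profile = call_profile(egg, panel_norm, binning)
        pb_profile = call_profile(pb, panel_norm, binning)
        egg_cn = {c: v for c, v in egg_profile.observed_cn.items() if c != "Y"}
        pb_cn = {c: v for c, v in pb_profile.observed_cn.items() if c != "Y"}
        shared = set(egg_cn) & set(pb_cn)
        egg_cn = {c: egg_cn[c] for c in shared}
        pb_cn = {c: pb_cn[c] for c in shared}
        callset = designate_pair(egg_cn, pb_cn, pair_id=pair_id, rescale=rescale)
        results.append(PairResult(pair_id, treatment, "analyzed", None, callset))
    log.append(
        f"pairs in: {len(pairs)}; analyzed: "
        f"{sum(1 for r in results if r.status == 'analyzed')}; "
        f"qc-failed: {sum(1 for r in results if r.status == 'qc-failed')}"
    )
    return results


def summarize_error_spectrum(
    callsets: Sequence[ReciprocalCallSet],
) -> pd.DataFrame:
    """Chromosome x {NDJ, PSSC} event counts over all pairs.

    Egg-side perspective: each reciprocal event is counted once per
    pair, keyed by the chromosome it affects.
    """
    chroms: list[str] = []
    for cs in callsets:
        for call in cs.calls:
            if call.chrom not in chroms:
                chroms.append(call.chrom)
    table = pd.DataFrame(0, index=chroms, columns=["NDJ", "PSSC"])
    for cs in callsets:
        for call in cs.calls:
            if call.is_error:
                table.loc[call.chrom, call.label] += 1
    table.index.name = "chromosome"
    return table


def build_report(
    pair_results: Sequence[PairResult],
    morpho: pd.DataFrame | None = None,
    log: list[str] | None = None,
) -> CohortReport:
    """Assemble per-pair rows and cohort aggregates.

    Aggregates: per-group aneuploidy incidence over analyzable pairs,
    aneuploidy-type counts (partitioning the aneuploid set), severity
    counts, and — when morphokinetic records are supplied — group
    statistics of tGVBD, tPB1, and dMI by treatment and by ploidy
    class.
    """
    log = list(log or [])
    rows = []
    for res in pair_results:
        row = {
            "pair_id": res.pair_id,
            "treatment": res.treatment,
            "status": res.status,
            "qc_reason": res.qc_reason,
            "egg_karyotype": None,
            "pb_karyotype": None,
            "aneuploidy_type": None,
            "n_errors": None,
            "n_discordant": None,
            "severity": None,
        }
        if res.callset is not None:
            kt = classify_sample(res.callset)
            row.update(
                egg_karyotype=kt.egg_karyotype,
                pb_karyotype=kt.pb_karyotype,
                aneuploidy_type=kt.aneuploidy_type,
                n_errors=kt.n_errors,
                n_discordant=kt.n_discordant,
                severity=kt.severity,
            )
        rows.append(row)
    frame = pd.DataFrame(rows)

    analyzed = frame[frame["status"] == "analyzed"]
    incidence = {}
    for group, sub in analyzed.groupby("treatment", sort=False):
        n = len(sub)
        aneuploid = int((sub["n_errors"] > 0).sum())
        incidence[group] = {
            "analyzable": n,
            "aneuploid": aneuploid,
            "incidence_pct": 100.0 * aneuploid / n if n else float("nan"),
        }
    aneuploid_rows = analyzed[analyzed["n_errors"] > 0]
    type_counts = aneuploid_rows["aneuploidy_type"].value_counts().to_dict()
    severity_counts = analyzed["severity"].value_counts().to_dict()
    aggregates: dict = {
        "n_pairs": len(frame),
        "n_analyzed": len(analyzed),
        "n_qc_failed": int((frame["status"] == "qc-failed").sum()),
        "incidence_by_group": incidence,
        "type_counts": {str(k): int(v) for k, v in type_counts.items()},
        "severity_counts": {str(k): int(v) for k, v in severity_counts.items()},
    }

    if morpho is not None and len(morpho):
        morpho = derive_variables(morpho.copy())
        mii = morpho[(morpho["status"] == "MII") & morpho["exclusion_flag"].isna()]
        stats_block = {}
        for grouping in ("group", "severity"):
            if grouping not in mii.columns or mii[grouping].nunique() < 2:
                continue
            per_var = {}
            for variable in ("tGVBD_h", "tPB1_h", "dMI_h"):
                try:
                    res = compare_groups(mii, variable, grouping=grouping)
                except ValueError as exc:
                    log.append(f"{grouping}/{variable}: comparison skipped ({exc})")
                    continue
                per_var[variable] = {
                    "groups": res.groups,
                    "test_used": res.test_used,
                    "p_value": res.p_value,
                    "pairwise": {f"{a} vs {b}": p for (a, b), p in res.pairwise.items()},
                }
            stats_block[grouping] = per_var
        rates = maturation_rates(morpho, grouping="group")
        aggregates["morphokinetics"] = stats_block
        aggregates["maturation"] = {
            "proportions": rates["proportions"].to_dict(),
            "test_used": rates["test_used"],
            "p_value": rates["p_value"],
        }
    return CohortReport(rows=frame, aggregates=aggregates, log=log)


def run_pipeline(
    config: SimulationConfig,
    seed: int,
    outdir: str | Path | None = None,
    *,
    study: StudyData | None = None,
) -> CohortReport:
    """End-to-end run: simulate (or take a study), call, classify, report.

    Deterministic for a given (config, seed); artifacts (cohort CSV,
    report JSON, error-spectrum TSV, log) are written under ``outdir``
    when given.
    """
    if study is None:
        study = simulate_study(config, seed)
    log: list[str] = [f"seed: {seed}"]
    panel_norm = build_panel([study.panel], study.binning)
    treatments = {cfg.pair_id: cfg.treatment for cfg in study.configurations}
    pair_results = call_pairs(
        study.sample_pairs, panel_norm, study.binning, treatments, log=log
    )
    morpho = morphokinetics_to_frame(study.morphokinetics)
    # attach designated severity so class-conditional stats use the calls
    severity_map = {}
    for res in pair_results:
        if res.callset is not None:
            severity_map[res.pair_id] = classify_sample(res.callset).severity
    morpho["severity"] = morpho["sample_id"].map(severity_map)
    report = build_report(pair_results, morpho, log=log)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.rows.to_csv(outdir / "cohort.csv", index=False)
        (outdir / "report.json").write_text(report.to_json() + "\n")
        spectrum = summarize_error_spectrum(
            [r.callset for r in pair_results if r.callset is not None]
        )
        spectrum.to_csv(outdir / "error_spectrum.tsv", sep="\t")
        (outdir / "pipeline.log").write_text("\n".join(report.log) + "\n")
    return report


def load_pairs_from_dir(
    directory: str | Path, binning: GenomeBinning
) -> tuple[list[tuple[BinnedCounts, BinnedCounts]], dict[str, str], BinnedCounts]:
    """Read a study directory written by :func:`meioseq.simulate.write_study`."""
    directory = Path(directory)
    manifest = json.loads((directory / "pairs.json").read_text())
    counts_dir = directory / "counts"
    panel = read_counts_tsv(counts_dir / "normal_panel.tsv", binning)
    pairs = []
    treatments: dict[str, str] = {}
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    for entry in manifest:
        egg = read_counts_tsv(counts_dir / entry["egg"], binning)
        pb = read_counts_tsv(counts_dir / entry["pb"], binning)
        pairs.append((egg, pb))
        if entry["pair_id"] in truth:
            treatments[entry["pair_id"]] = truth[entry["pair_id"]]["treatment"]
    return pairs, treatments, panel
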