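"""Ground-truthed simulation of the egg/polar-body sequencing study.

The generator emulates a Nocodazole dose-response IVM experiment:

* per-chromosome meiosis-I segregation outcomes for matched egg/PB
  pairs, with dose-dependent error probabilities, an NDJ-vs-PSSC split,
  and rare catastrophic events in which nearly the whole complement
  segregates to one cell;
* overdispersed (negative-binomial) per-bin shallow-WGS read counts
  with bin biases shared across samples and the euploid male (40,XY)
  normal panel, occasional overrepresented bins (raw count > 1000), and
  occasional sub-90% mapped-fraction QC failures;
* ploidy-class-conditional maturation timings (tGVBD, tPB1, dMI).

Every chromatid configuration satisfies conservation: for each non-Y
chromosome the egg and PB chromatid counts sum to four.  Identical
(config, seed) inputs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cn import BinnedCounts, write_counts_tsv
from .genome import GenomeBinning, make_binning

__all__ = [
    "ChromatidConfiguration",
    "GroupParams",
    "MorphokineticClassParams",
    "MorphokineticRecord",
    "SimulationConfig",
    "StudyData",
    "make_bin_biases",
    "simulate_segregation",
    "simulate_read_counts",
    "simulate_normal_panel",
    "simulate_morphokinetics",
    "simulate_study",
    "severity_of",
    "write_study",
]

TOTAL_CHROMATIDS = 4


@dataclass(frozen=True)
class ChromatidConfiguration:
    """Ground-truth (egg, pb) chromatid counts per chromosome for one pair.

    Y is absent from oocyte-derived cells and is therefore not in the
    map; every listed chromosome satisfies ``egg + pb == 4``.
    """

    pair_id: str
    treatment: str
    counts: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for chrom, (egg, pb) in self.counts.items():
            if chrom == "Y":
                raise ValueError("Y must not appear in an oocyte configuration")
            if egg + pb != TOTAL_CHROMATIDS:
                raise ValueError(
                    f"pair {self.pair_id}, chromosome {chrom}: "
                    f"egg+pb = {egg + pb} violates chromatid conservation"
                )

    def egg_map(self) -> dict[str, int]:
        return {c: e for c, (e, _) in self.counts.items()}

    def pb_map(self) -> dict[str, int]:
        return {c: p for c, (_, p) in self.counts.items()}

    @property
    def n_errors(self) -> int:
        return sum(1 for pair in self.counts.values() if pair != (2, 2))


def severity_of(config: ChromatidConfiguration) -> str:
    """Ploidy class of a pair: euploid, 1-3 errors, or >=4 errors."""
    n = config.n_errors
    if n == 0:
        return "euploid"
    return "1-3" if n <= 3 else ">=4"


@dataclass(frozen=True)
class GroupParams:
    """Per-treatment-group cohort size and mis-segregation rates."""

    n_pairs: int
    p_err: float  # per-chromosome independent error probability
    p_cat: float = 0.0  # probability of a catastrophic whole-complement event
    n_gv: int = 0  # oocytes never resuming meiosis (no GVBD)
    n_gvbd_only: int = 0  # oocytes arresting after GVBD (no PB extrusion)


@dataclass(frozen=True)
class MorphokineticClassParams:
    """Timing distribution for one ploidy class.

    Means and SEMs are in hours; the per-oocyte SD is reconstructed as
    SEM * sqrt(n) from the group size the SEM was computed over.
    """

    tgvbd_mean: float
    tgvbd_sem: float
    tpb1_mean: float
    tpb1_sem: float
    n: int

    @property
    def tgvbd_sd(self) -> float:
        return self.tgvbd_sem * math.sqrt(self.n)

    @property
    def tpb1_sd(self) -> float:
        return self.tpb1_sem * math.sqrt(self.n)


def _default_groups() -> dict[str, GroupParams]:
    # Rates calibrated so the expected aneuploidy incidence per group
    # matches the study conditions: 0/11 control, ~7.7% at 25 nM
    # (1 - (1-p)^20), and ~83% at 50 nM where roughly a third of the
    # aneuploid pairs carry catastrophic whole-complement errors.
    return {
        "control": GroupParams(n_pairs=11, p_err=0.0, p_cat=0.0),
        "25 nM": GroupParams(n_pairs=13, p_err=0.0040, p_cat=0.0, n_gvbd_only=1),
        "50 nM": GroupParams(
            n_pairs=23, p_err=0.067, p_cat=0.304, n_gv=1, n_gvbd_only=6
        ),
    }


def _default_morphokinetics() -> dict[str, MorphokineticClassParams]:
    # Class-conditional defaults: group mean +/- SEM and n per ploidy class.
    return {
        "euploid": MorphokineticClassParams(0.92, 0.02, 9.19, 0.11, 27),
        "1-3": MorphokineticClassParams(1.00, 0.05, 11.23, 0.33, 9),
        ">=4": MorphokineticClassParams(0.95, 0.03, 13.80, 0.46, 11),
    }


@dataclass
class SimulationConfig:
    """All knobs of the study generator; defaults are the study conditions."""

    groups: dict[str, GroupParams] = field(default_factory=_default_groups)
    q_ndj: float = 0.935  # NDJ share among ordinary (non-catastrophic) errors
    p_egg_retains: float = 0.5  # direction of the extra material
    depth: int = 100_000  # total reads per sample
    nb_size: float | None = 200.0  # NB dispersion; None = deterministic counts
    bias_sigma: float = 0.1  # log-normal sigma of shared per-bin biases
    frac_overrepresented: float = 0.0  # bins forced to raw count > 1000
    p_qc_fail: float = 0.02  # per-sample sub-90% mapped-fraction failures
    window_size: int = 10_000_000
    morphokinetics: dict[str, MorphokineticClassParams] = field(
        default_factory=_default_morphokinetics
    )

    def __post_init__(self) -> None:
        for name, value in [
            ("q_ndj", self.q_ndj),
            ("p_egg_retains", self.p_egg_retains),
            ("frac_overrepresented", self.frac_overrepresented),
            ("p_qc_fail", self.p_qc_fail),
        ]:
            if not (0 <= value <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        for gname, grp in self.groups.items():
            if not (0 <= grp.p_err <= 1) or not (0 <= grp.p_cat <= 1):
                raise ValueError(f"group {gname}: probabilities must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.nb_size is not None and self.nb_size <= 0:
            raise ValueError("nb_size must be > 0 (or None for deterministic)")

    # -- structured key-value config file (YAML) --

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        groups = {k: GroupParams(**v) for k, v in data.pop("groups", {}).items()}
        morpho = {
            k: MorphokineticClassParams(**v)
            for k, v in data.pop("morphokinetics", {}).items()
        }
        cfg = cls(**data)
        if groups:
            cfg.groups = groups
        if morpho:
            cfg.morphokinetics = morpho
        return cfg


@dataclass
class MorphokineticRecord:
    """t0-anchored event times (hours) and derived variables for one oocyte."""

    sample_id: str
    treatment: str
    t0: float = 0.0
    tgvbd: float | None = None
    tpb1: float | None = None
    dmi: float | None = None
    maturation_status: str = "MII"  # GV | GVBD-only | MII
    severity: str | None = None  # ploidy class when sequenced
    exclusion_flag: str | None = None

    def __post_init__(self) -> None:
        if self.tpb1 is not None and self.tgvbd is not None:
            if not (self.tpb1 > self.tgvbd > self.t0):
                raise ValueError(
                    f"{self.sample_id}: event order must be tPB1 > tGVBD > t0"
                )
        if (self.maturation_status == "MII") != (self.tpb1 is not None):
            raise ValueError(
                f"{self.sample_id}: MII status iff tPB1 is present"
            )


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _oocyte_chromosomes(binning: GenomeBinning) -> list[str]:
    return [s.name for s in binning.chromosomes if s.name != "Y"]


def _ordinary_error(rng: np.random.Generator, q_ndj: float, p_egg: float) -> tuple[int, int]:
    """Draw one mis-segregation pattern: NDJ 4/0 or PSSC 3/1, either direction."""
    is_ndj = rng.random() < q_ndj
    egg_side = rng.random() < p_egg
    if is_ndj:
        return (4, 0) if egg_side else (0, 4)
    return (3, 1) if egg_side else (1, 3)


def _catastrophic(
    rng: np.random.Generator, chroms: Sequence[str], p_egg: float
) -> dict[str, tuple[int, int]]:
    """Whole-complement event: all chromosomes to one cell except a small
    independently resampled autosomal subset segregating the other way
    (as full bivalents or with a premature sister separation)."""
    egg_gets_all = rng.random() < p_egg
    autosomes = [c for c in chroms if c != "X"]
    k = int(rng.integers(1, 5))  # 1..4 exception chromosomes
    minority = set(rng.choice(autosomes, size=k, replace=False))
    counts: dict[str, tuple[int, int]] = {}
    for chrom in chroms:
        if chrom in minority:
            u = rng.random()
            if u < 0.4:
                minority_pattern = 4  # full bivalent opposite the bulk
            elif u < 0.9:
                minority_pattern = 3  # sister separation, 3 opposite the bulk
            else:
                minority_pattern = 1
            egg = TOTAL_CHROMATIDS - minority_pattern if egg_gets_all else minority_pattern
        else:
            egg = TOTAL_CHROMATIDS if egg_gets_all else 0
        counts[chrom] = (egg, TOTAL_CHROMATIDS - egg)
    return counts


def simulate_segregation(
    config: SimulationConfig, seed: int | np.random.Generator
) -> list[ChromatidConfiguration]:
    """Draw meiosis-I segregation outcomes for every pair in every group."""
    rng = _rng(seed)
    binning = make_binning(window_size=config.window_size)
    chroms = _oocyte_chromosomes(binning)
    out: list[ChromatidConfiguration] = []
    for group, params in config.groups.items():
        for i in range(params.n_pairs):
            pair_id = f"{group.replace(' ', '')}_{i + 1:02d}"
            if rng.random() < params.p_cat:
                counts = _catastrophic(rng, chroms, config.p_egg_retains)
            else:
                counts = {}
                for chrom in chroms:
                    if rng.random() < params.p_err:
                        counts[chrom] = _ordinary_error(
                            rng, config.q_ndj, config.p_egg_retains
                        )
                    else:
                        counts[chrom] = (2, 2)
            out.append(ChromatidConfiguration(pair_id, group, counts))
    return out


def make_bin_biases(
    binning: GenomeBinning, sigma: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Shared multiplicative per-bin biases, log-normal around 1."""
    rng = _rng(seed)
    if sigma == 0:
        return np.ones(binning.n_bins)
    return np.exp(rng.normal(0.0, sigma, size=binning.n_bins))


def _expected_counts(
    copy_map: Mapping[str, float],
    binning: GenomeBinning,
    biases: np.ndarray,
    depth: float,
) -> np.ndarray:
    """Expected reads per bin: bin width x bias x (chromatid count / 2).

    ``depth`` is the total for a diploid-content cell; a cell carrying
    more or less DNA yields proportionally more or fewer reads, so a
    near-empty egg does not concentrate a full library on its few
    remaining chromosomes.
    """
    weights = np.zeros(binning.n_bins)
    ref = 0.0
    for i, (chrom, start, end) in enumerate(binning.bins):
        copies = copy_map.get(chrom, 0.0)
        width = end - start
        weights[i] = width * biases[i] * copies / 2.0
        if chrom != "Y":
            ref += width * biases[i]  # diploid-equivalent content
    if weights.sum() <= 0:
        raise ValueError("copy map yields zero expected signal")
    return depth * weights / ref


def _draw_counts(
    expected: np.ndarray, nb_size: float | None, rng: np.random.Generator
) -> np.ndarray:
    if nb_size is None:
        return expected.copy()
    counts = np.zeros_like(expected)
    pos = expected > 0
    p = nb_size / (nb_size + expected[pos])
    counts[pos] = rng.negative_binomial(nb_size, p)
    return counts


def _one_sample(
    sample_id: str,
    role: str,
    copy_map: Mapping[str, float],
    binning: GenomeBinning,
    biases: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    qc_fail: bool,
) -> BinnedCounts:
    expected = _expected_counts(copy_map, binning, biases, config.depth)
    counts = _draw_counts(expected, config.nb_size, rng)
    n_over = int(round(config.frac_overrepresented * binning.n_bins))
    if n_over > 0:
        idx = rng.choice(binning.n_bins, size=n_over, replace=False)
        counts[idx] = rng.integers(1500, 4000, size=n_over)
    if qc_fail:
        mapped = float(rng.uniform(0.60, 0.89))
    else:
        mapped = float(rng.uniform(0.95, 0.995))
    return BinnedCounts(
        sample_id=sample_id, counts=counts, mapped_fraction=mapped, sample_role=role
    )


def simulate_read_counts(
    configurations: Sequence[ChromatidConfiguration],
    binning: GenomeBinning,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    biases: np.ndarray | None = None,
) -> list[tuple[BinnedCounts, BinnedCounts]]:
    """Binned read counts for each pair's egg and polar body.

    QC failures are designated per sample with probability
    ``config.p_qc_fail`` and show up only in the mapped-fraction
    metadata; their counts are otherwise ordinary.
    """
    rng = _rng(seed)
    if biases is None:
        biases = np.ones(binning.n_bins)
    chrom_names = set(binning.chromosome_names())
    out: list[tuple[BinnedCounts, BinnedCounts]] = []
    for cfg in configurations:
        unknown = set(cfg.counts) - chrom_names
        if unknown:
            raise ValueError(
                f"pair {cfg.pair_id}: chromosomes {sorted(unknown)} not in binning"
            )
        egg = _one_sample(
            f"{cfg.pair_id}_egg", "egg", cfg.egg_map(), binning, biases, config,
            rng, qc_fail=rng.random() < config.p_qc_fail,
        )
        pb = _one_sample(
            f"{cfg.pair_id}_pb", "polar_body", cfg.pb_map(), binning, biases, config,
            rng, qc_fail=rng.random() < config.p_qc_fail,
        )
        out.append((egg, pb))
    return out


PANEL_TRUTH: dict[str, float] = {}  # filled lazily per binning


def panel_copy_map(binning: GenomeBinning) -> dict[str, float]:
    """Reference copies of the euploid male panel: autosomes 2, X 1, Y 1.

    Expressed on the chromatid scale used throughout (2 chromatids per
    autosome copy-pair member), i.e. per-bin expected signal factor is
    copies/2."""
    out: dict[str, float] = {}
    for spec in binning.chromosomes:
        out[spec.name] = 1.0 if spec.is_sex else 2.0
    return out


def simulate_normal_panel(
    binning: GenomeBinning,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    biases: np.ndarray | None = None,
) -> tuple[BinnedCounts, dict[str, float]]:
    """Euploid male (40,XY) reference sample with the shared bin biases."""
    rng = _rng(seed)
    if biases is None:
        biases = np.ones(binning.n_bins)
    truth = panel_copy_map(binning)
    sample = _one_sample(
        "normal_panel", "panel", truth, binning, biases, config, rng, qc_fail=False
    )
    return sample, truth


def simulate_morphokinetics(
    configurations: Sequence[ChromatidConfiguration],
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> list[MorphokineticRecord]:
    """Class-conditional maturation timings for sequenced MII pairs plus
    immature (GV / GVBD-only) oocytes configured per group.

    tGVBD and tPB1 are drawn from the ploidy class's normal
    distributions and rejection-resampled until t0 < tGVBD < tPB1; dMI
    is then the exact difference.
    """
    rng = _rng(seed)
    records: list[MorphokineticRecord] = []
    for cfg in configurations:
        cls = severity_of(cfg)
        params = config.morphokinetics[cls]
        while True:
            tgvbd = rng.normal(params.tgvbd_mean, params.tgvbd_sd)
            tpb1 = rng.normal(params.tpb1_mean, params.tpb1_sd)
            if 0.0 < tgvbd < tpb1:
                break
        records.append(
            MorphokineticRecord(
                sample_id=cfg.pair_id,
                treatment=cfg.treatment,
                tgvbd=float(tgvbd),
                tpb1=float(tpb1),
                dmi=float(tpb1 - tgvbd),
                maturation_status="MII",
                severity=cls,
            )
        )
    # immature oocytes never reach PB extrusion; GVBD-only ones still
    # show a germinal-vesicle breakdown time
    gvbd_params = config.morphokinetics["euploid"]
    for group, params in config.groups.items():
        for i in range(params.n_gv):
            records.append(
                MorphokineticRecord(
                    sample_id=f"{group.replace(' ', '')}_gv_{i + 1:02d}",
                    treatment=group,
                    maturation_status="GV",
                )
            )
        for i in range(params.n_gvbd_only):
            while True:
                tgvbd = rng.normal(gvbd_params.tgvbd_mean, gvbd_params.tgvbd_sd)
                if tgvbd > 0:
                    break
            records.append(
                MorphokineticRecord(
                    sample_id=f"{group.replace(' ', '')}_gvbd_{i + 1:02d}",
                    treatment=group,
                    tgvbd=float(tgvbd),
                    maturation_status="GVBD-only",
                )
            )
    return records


@dataclass
class StudyData:
    """One complete simulated study, ready for the calling pipeline."""

    binning: GenomeBinning
    config: SimulationConfig
    biases: np.ndarray
    configurations: list[ChromatidConfiguration]
    panel: BinnedCounts
    panel_truth: dict[str, float]
    sample_pairs: list[tuple[BinnedCounts, BinnedCounts]]
    morphokinetics: list[MorphokineticRecord]


def simulate_study(config: SimulationConfig, seed: int) -> StudyData:
    """Generate segregation truth, panel, read counts, and timings.

    Independent child RNG streams are spawned from the seed so each
    component is reproducible and insensitive to the others' draw
    counts.
    """
    ss = np.random.SeedSequence(seed)
    s_bias, s_seg, s_panel, s_counts, s_morpho = [
        np.random.default_rng(child) for child in ss.spawn(5)
    ]
    binning = make_binning(window_size=config.window_size)
    biases = make_bin_biases(binning, config.bias_sigma, s_bias)
    configurations = simulate_segregation(config, s_seg)
    panel, panel_truth = simulate_normal_panel(binning, config, s_panel, biases)
    pairs = simulate_read_counts(configurations, binning, config, s_counts, biases)
    morpho = simulate_morphokinetics(configurations, config, s_morpho)
    return StudyData(
        binning=binning,
        config=config,
        biases=biases,
        configurations=configurations,
        panel=panel,
        panel_truth=panel_truth,
        sample_pairs=pairs,
        morphokinetics=morpho,
    )


def morphokinetics_to_frame(records: Sequence[MorphokineticRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "group": [r.treatment for r in records],
            "t0": [r.t0 for r in records],
            "tGVBD_h": [r.tgvbd for r in records],
            "tPB1_h": [r.tpb1 for r in records],
            "dMI_h": [r.dmi for r in records],
            "status": [r.maturation_status for r in records],
            "severity": [r.severity for r in records],
            "exclusion_flag": [r.exclusion_flag for r in records],
        }
    )


def write_study(study: StudyData, outdir: str | Path) -> None:
    """Serialize a study: counts as BED-like TSV + JSON sidecars, truth as
    JSON, morphokinetics as CSV, config as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_dir = outdir / "counts"
    counts_dir.mkdir(exist_ok=True)
    write_counts_tsv(study.panel, study.binning, counts_dir / "normal_panel.tsv")
    manifest = []
    for egg, pb in study.sample_pairs:
        write_counts_tsv(egg, study.binning, counts_dir / f"{egg.sample_id}.tsv")
        write_counts_tsv(pb, study.binning, counts_dir / f"{pb.sample_id}.tsv")
        pair_id = egg.sample_id.removesuffix("_egg")
        manifest.append(
            {"pair_id": pair_id, "egg": f"{egg.sample_id}.tsv", "pb": f"{pb.sample_id}.tsv"}
        )
    truth = {
        cfg.pair_id: {
            "treatment": cfg.treatment,
            "counts": {c: list(v) for c, v in cfg.counts.items()},
        }
        for cfg in study.configurations
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    (outdir / "pairs.json").write_text(json.dumps(manifest, indent=2) + "\n")
    morphokinetics_to_frame(study.morphokinetics).to_csv(
        outdir / "morphokinetics.csv", index=False
    )
    study.config.to_yaml(outdir / "config.yaml")
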