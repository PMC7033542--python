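"""Synthetic CNV cohorts with known per-locus class frequencies.

The generator emulates the structure an array-CNV population study
assumes: several breeds/groups of individuals, a genome of autosomes, and
a set of disjoint CNV loci at which each individual independently draws a
copy-number class from its group's frequency vector.  Neutral loci share
one frequency vector across groups (drawn from a Dirichlet prior
concentrated on the diploid class A2, matching the sparsity of real call
sets — on the order of 150 calls per individual genome-wide); planted loci
have divergent per-group vectors and are the ground truth for selection-
scan recovery tests.  Non-diploid draws are emitted as PennCNV-style
calls; literally abutting equal-copy-number draws of one individual
coalesce into a single call.

The truth table records every locus' generating frequency vectors and the
plug-in expected Fst, computed through the same equations as the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .io import ChromSizes, CnvCall, PopulationMap, chrom_sort_key
from .qc import QcThresholds, SampleQcRecord
from .scan import AlleleFrequencies, fst_segment
from .segmentation import CN_CLASSES

__all__ = [
    "PlantedLocus",
    "QcSimParams",
    "SimConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "expected_fst_of_truth",
    "write_cohort",
]

#: numeric copy number emitted for each class (Agt4 -> 5)
_CLASS_CN = (0, 1, 2, 3, 4, 5)
_A2 = 2


@dataclass(frozen=True)
class PlantedLocus:
    """A locus with per-group class-frequency vectors (class order A0..Agt4).

    With ``chrom``/``start``/``length`` unset the locus takes over a
    randomly chosen neutral locus, which keeps the simulated loci disjoint
    without a second placement pass.
    """

    freqs: dict[str, Sequence[float]]
    chrom: Optional[str] = None
    start: Optional[int] = None
    length: Optional[int] = None

    def __post_init__(self) -> None:
        for label, vec in self.freqs.items():
            v = np.asarray(vec, dtype=float)
            if v.shape != (len(CN_CLASSES),):
                raise ValueError(
                    f"planted locus: group {label} needs {len(CN_CLASSES)} frequencies"
                )
            if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"planted locus: invalid frequency vector for {label}")


@dataclass(frozen=True)
class QcSimParams:
    """Distributions for the per-sample QC metrics.

    Clean samples draw each metric from a normal (truncated at 0 for the
    non-negative metrics) well inside the thresholds; a ``contamination``
    fraction of samples gets one metric pushed beyond its threshold.
    """

    lrr_sd: tuple[float, float] = (0.15, 0.04)
    baf_drift: tuple[float, float] = (0.002, 0.0015)
    waviness: tuple[float, float] = (0.0, 0.03)
    contamination: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.contamination <= 1:
            raise ValueError("contamination must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study design of a simulated cohort.

    groups: (label, n_individuals) pairs; each label doubles as the breed
    code and the comparison-group label.  Loci are disjoint intervals,
    ``n_loci_per_chrom`` per chromosome, with lengths uniform in
    ``locus_length`` and >= 2 bp gaps.  ``neutral_alpha`` are Dirichlet
    concentration parameters over (A0..Agt4); the default puts ~93% of the
    expected mass on A2.
    """

    seed: int
    groups: tuple[tuple[str, int], ...] = (("high", 25), ("low", 25))
    chrom_sizes: Optional[ChromSizes] = None
    n_loci_per_chrom: int = 40
    locus_length: tuple[int, int] = (1_000, 20_000)
    neutral_alpha: tuple[float, ...] = (0.3, 0.6, 28.0, 0.7, 0.3, 0.1)
    planted: tuple[PlantedLocus, ...] = ()
    qc: QcSimParams = field(default_factory=QcSimParams)
    comparison: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if any(n < 2 for _, n in self.groups):
            raise ValueError("each group needs n >= 2")
        if len({label for label, _ in self.groups}) != len(self.groups):
            raise ValueError("duplicate group labels")
        if len(self.neutral_alpha) != len(CN_CLASSES):
            raise ValueError(f"neutral_alpha needs {len(CN_CLASSES)} entries")
        if any(a <= 0 for a in self.neutral_alpha):
            raise ValueError("Dirichlet concentrations must be positive")
        if self.chrom_sizes is None:
            object.__setattr__(
                self, "chrom_sizes",
                ChromSizes({f"chr{i}": 2_000_000 for i in range(1, 6)}),
            )

    @property
    def comparison_pair(self) -> tuple[str, str]:
        if self.comparison is not None:
            return self.comparison
        labels = [label for label, _ in self.groups]
        return labels[0], labels[1]


@dataclass(frozen=True)
class SimulatedCohort:
    calls: list[CnvCall]
    popmap: PopulationMap
    qc_records: list[SampleQcRecord]
    truth: pd.DataFrame
    drawn_classes: pd.DataFrame  # samples x locus ids, integer class codes


def _place_loci(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """Disjoint loci with >= 2 bp gaps, n_loci_per_chrom per chromosome."""
    loci: list[tuple[str, int, int]] = []
    lo, hi = config.locus_length
    for chrom in sorted(config.chrom_sizes, key=chrom_sort_key):
        size = config.chrom_sizes[chrom]
        slot = size // config.n_loci_per_chrom
        if slot < hi + 4:
            raise ValueError(
                f"{chrom}: too short for {config.n_loci_per_chrom} loci of up to {hi} bp"
            )
        for k in range(config.n_loci_per_chrom):
            length = int(rng.integers(lo, hi + 1))
            offset = int(rng.integers(2, slot - length - 1))
            start = k * slot + offset + 1
            loci.append((chrom, start, start + length - 1))
    return loci


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw a cohort: calls, population map, QC metrics and truth table.

    Reproducible: the same config (including seed) yields the identical
    cohort.  Individuals are named ``<GROUP><k>``.
    """
    rng = np.random.default_rng(config.seed)
    labels = [label for label, _ in config.groups]
    samples: list[str] = []
    sample_group: dict[str, str] = {}
    for label, n in config.groups:
        for k in range(1, n + 1):
            sid = f"{label}{k:03d}"
            samples.append(sid)
            sample_group[sid] = label

    loci = _place_loci(config, rng)

    # choose which loci are planted
    planted_at: dict[int, PlantedLocus] = {}
    explicit = [p for p in config.planted if p.start is not None]
    auto = [p for p in config.planted if p.start is None]
    for p in explicit:
        if p.chrom is None or p.length is None:
            raise ValueError("explicit planted locus needs chrom, start and length")
        iv = (p.chrom, p.start, p.start + p.length - 1)
        for j, (c, s, e) in enumerate(loci):
            if c == iv[0] and s <= iv[2] and iv[1] <= e:
                raise ValueError(f"planted locus {iv} overlaps simulated locus {loci[j]}")
        loci.append(iv)
        planted_at[len(loci) - 1] = p
    if auto:
        free = [j for j in range(len(loci)) if j not in planted_at]
        chosen = rng.choice(len(free), size=len(auto), replace=False)
        for p, jj in zip(auto, sorted(int(c) for c in chosen)):
            planted_at[free[jj]] = p

    loci_order = sorted(range(len(loci)),
                        key=lambda j: (chrom_sort_key(loci[j][0]), loci[j][1]))

    # per-locus, per-group frequency vectors
    group_freqs: dict[int, dict[str, np.ndarray]] = {}
    for j in loci_order:
        if j in planted_at:
            p = planted_at[j]
            missing = [l for l in labels if l not in p.freqs]
            if missing:
                raise ValueError(f"planted locus lacks frequencies for group(s) {missing}")
            group_freqs[j] = {l: np.asarray(p.freqs[l], dtype=float) for l in labels}
        else:
            vec = rng.dirichlet(config.neutral_alpha)
            group_freqs[j] = {l: vec for l in labels}  # neutral: x = y

    # draw classes: samples x loci (vectorised per group and locus)
    group_rows = {
        label: np.array([i for i, s in enumerate(samples) if sample_group[s] == label])
        for label in labels
    }
    codes = np.full((len(samples), len(loci)), _A2, dtype=np.int8)
    for col, j in enumerate(loci_order):
        for label in labels:
            rows_idx = group_rows[label]
            f = group_freqs[j][label]
            codes[rows_idx, col] = rng.choice(len(CN_CLASSES), p=f, size=len(rows_idx))

    # emit calls; abutting equal-cn draws coalesce
    locus_at = [loci[j] for j in loci_order]
    calls: list[CnvCall] = []
    for i, sid in enumerate(samples):
        run: Optional[list] = None  # [chrom, start, end, cn]
        for col, (chrom, start, end) in enumerate(locus_at):
            cn = _CLASS_CN[codes[i, col]]
            if cn == 2:
                continue
            if run and run[0] == chrom and run[2] + 1 == start and run[3] == cn:
                run[2] = end
                continue
            if run:
                calls.append(CnvCall(sid, run[0], run[1], run[2], run[3]))
            run = [chrom, start, end, cn]
        if run:
            calls.append(CnvCall(sid, run[0], run[1], run[2], run[3]))

    popmap = PopulationMap({s: (sample_group[s], sample_group[s]) for s in samples})

    # QC metrics
    thresholds = QcThresholds()
    qc_records: list[SampleQcRecord] = []
    for sid in samples:
        lrr = abs(rng.normal(*config.qc.lrr_sd))
        drift = abs(rng.normal(*config.qc.baf_drift))
        wav = rng.normal(*config.qc.waviness)
        if rng.random() < config.qc.contamination:
            which = rng.integers(3)
            if which == 0:
                lrr = thresholds.max_lrr_sd * float(rng.uniform(1.05, 1.8))
            elif which == 1:
                drift = thresholds.max_baf_drift * float(rng.uniform(1.05, 1.8))
            else:
                wav = thresholds.max_waviness * float(rng.uniform(1.05, 1.8))
        qc_records.append(SampleQcRecord(sid, lrr, drift, wav))

    # truth table with plug-in expected Fst for the comparison pair
    gx, gy = config.comparison_pair
    nx = dict(config.groups)[gx]
    ny = dict(config.groups)[gy]
    rows = []
    for col, j in enumerate(loci_order):
        chrom, start, end = loci[j]
        row: dict = {
            "locus_id": f"{chrom}:{start}-{end}",
            "chrom": chrom,
            "start": start,
            "end": end,
            "planted": j in planted_at,
            "n_x": nx,
            "n_y": ny,
        }
        fx, fy = group_freqs[j][gx], group_freqs[j][gy]
        for c, name in enumerate(CN_CLASSES):
            row[f"x_{name}"] = fx[c]
            row[f"y_{name}"] = fy[c]
        res = fst_segment(
            AlleleFrequencies({n: f for n, f in zip(CN_CLASSES, fx) if f > 0}, nx),
            AlleleFrequencies({n: f for n, f in zip(CN_CLASSES, fy) if f > 0}, ny),
        )
        row["expected_fst"] = res.fst if res.defined else np.nan
        rows.append(row)
    truth = pd.DataFrame(rows)

    drawn = pd.DataFrame(codes, index=samples,
                         columns=[f"{c}:{s}-{e}" for c, s, e in locus_at])
    return SimulatedCohort(calls, popmap, qc_records, truth, drawn)


def expected_fst_of_truth(truth: pd.DataFrame) -> pd.Series:
    """Per-locus plug-in Fst, recomputed from the stored generating vectors.

    Uses the identical formula path as the scan (fst_segment) with the
    group sizes implied by the truth table's frequency columns' cohort;
    sizes are taken from the n_x/n_y columns if present, else equal groups.
    """
    nx = int(truth["n_x"].iloc[0]) if "n_x" in truth else 1
    ny = int(truth["n_y"].iloc[0]) if "n_y" in truth else 1
    out = []
    for row in truth.itertuples(index=False):
        x = {n: getattr(row, f"x_{n}") for n in CN_CLASSES if getattr(row, f"x_{n}") > 0}
        y = {n: getattr(row, f"y_{n}") for n in CN_CLASSES if getattr(row, f"y_{n}") > 0}
        res = fst_segment(AlleleFrequencies(x, nx), AlleleFrequencies(y, ny))
        out.append(res.fst if res.defined else np.nan)
    return pd.Series(out, index=truth["locus_id"], name="expected_fst")


def write_cohort(cohort: SimulatedCohort, outdir: Path) -> dict[str, Path]:
    """Write rawcnv, population map, QC table and truth table to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": outdir / "calls.rawcnv",
        "popmap": outdir / "population_map.tsv",
        "qc": outdir / "qc_metrics.tsv",
        "truth": outdir / "truth.tsv",
    }
    cio.write_penncnv_calls(cohort.calls, paths["calls"])
    cio.write_population_map(cohort.popmap, paths["popmap"])
    cio.write_qc_table(
        pd.DataFrame(
            [
                {"sample_id": r.sample_id, "lrr_sd": r.lrr_sd,
                 "baf_drift": r.baf_drift, "waviness": r.waviness}
                for r in cohort.qc_records
            ]
        ),
        paths["qc"],
    )
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
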