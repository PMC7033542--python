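"""Post-calling sample quality control.

Array-based CNV calling produces per-sample dispersion metrics — the
standard deviation of the Log R Ratio (LRR SD), B allele frequency (BAF)
drift, and the waviness factor — whose elevation marks noisy intensity
data.  Samples are removed when any metric strictly exceeds its threshold;
the defaults (0.30 / 0.008 / 0.08) are the conventional PennCNV cutoffs.
Waviness may be reported negative and is compared by absolute value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = ["SampleQcRecord", "QcThresholds", "filter_samples", "records_from_table"]

_METRICS = ("lrr_sd", "baf_drift", "waviness")


@dataclass(frozen=True)
class SampleQcRecord:
    sample_id: str
    lrr_sd: float
    baf_drift: float
    waviness: float

    def __post_init__(self) -> None:
        for name in _METRICS:
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValueError(f"sample {self.sample_id}: missing metric {name}")
            if not math.isfinite(value):
                raise ValueError(f"sample {self.sample_id}: non-finite {name}")
        # waviness is signed in the wild; normalise to magnitude
        object.__setattr__(self, "waviness", abs(self.waviness))
        for name in ("lrr_sd", "baf_drift"):
            if getattr(self, name) < 0:
                raise ValueError(f"sample {self.sample_id}: negative {name}")


@dataclass(frozen=True)
class QcThresholds:
    max_lrr_sd: float = 0.30
    max_baf_drift: float = 0.008
    max_waviness: float = 0.08

    def __post_init__(self) -> None:
        for name in ("max_lrr_sd", "max_baf_drift", "max_waviness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def filter_samples(
    records: Iterable[SampleQcRecord],
    thresholds: Optional[QcThresholds] = None,
) -> tuple[set[str], dict[str, list[str]]]:
    """Partition samples into (kept ids, removed id -> failed metrics).

    A sample is removed iff any metric *strictly* exceeds its threshold;
    a metric exactly at the threshold passes.  The removal report lists
    every failing metric, not just the first.
    """
    thresholds = thresholds or QcThresholds()
    limits = {
        "lrr_sd": thresholds.max_lrr_sd,
        "baf_drift": thresholds.max_baf_drift,
        "waviness": thresholds.max_waviness,
    }
    kept: set[str] = set()
    removed: dict[str, list[str]] = {}
    seen: set[str] = set()
    for rec in records:
        if rec.sample_id in seen:
            raise ValueError(f"duplicate QC record for sample {rec.sample_id}")
        seen.add(rec.sample_id)
        failed = [m for m in _METRICS if getattr(rec, m) > limits[m]]
        if failed:
            removed[rec.sample_id] = failed
        else:
            kept.add(rec.sample_id)
    return kept, removed


def records_from_table(df: pd.DataFrame) -> list[SampleQcRecord]:
    """Convert a QC metrics table (see io.read_qc_table) into records."""
    return [
        SampleQcRecord(
            sample_id=row.sample_id,
            lrr_sd=float(row.lrr_sd),
            baf_drift=float(row.baf_drift),
            waviness=float(row.waviness),
        )
        for row in df.itertuples(index=False)
    ]
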