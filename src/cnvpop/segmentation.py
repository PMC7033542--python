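"""Breakpoint partitioning of CNVRs and the copy-number-class genotype matrix.

Each CNVR is cut at every member-call boundary: the breakpoint set is the
union of call starts and call ends + 1, and the atomic segments are the
inter-breakpoint intervals restricted to bases covered by at least one
call.  After partitioning, every call covers whole segments, so each
(sample, segment) cell carries a single categorical copy-number class:

    A0  A1  A2  A3  A4  Agt4     for copy numbers 0 1 2 3 4 >4

A2 (diploid) is the reference class; a sample with no call over a segment
is diploid there.  The matrix is complete by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cnvr import Cnvr
from .io import CnvCall, chrom_sort_key

__all__ = [
    "CN_CLASSES",
    "CnvSegment",
    "GenotypeMatrix",
    "class_of_cn",
    "cn_of_class",
    "partition_cnvr",
    "partition_all",
    "build_genotype_matrix",
    "encode_matrix",
]

#: Copy-number classes in copy-number order; the matrix stores their indices.
CN_CLASSES: tuple[str, ...] = ("A0", "A1", "A2", "A3", "A4", "Agt4")

_CLASS_CODE = {name: i for i, name in enumerate(CN_CLASSES)}
_DIPLOID_CODE = _CLASS_CODE["A2"]


def class_of_cn(cn: int) -> str:
    """Map an integer copy number to its categorical class (cn>=5 -> Agt4)."""
    if cn < 0:
        raise ValueError(f"negative copy number {cn}")
    return CN_CLASSES[cn] if cn <= 4 else "Agt4"


def cn_of_class(name: str) -> int:
    """Numeric value used by the copy-number encoding (Agt4 -> 5)."""
    return _CLASS_CODE[name]


@dataclass(frozen=True)
class CnvSegment:
    """An atomic interval from the breakpoint partition of a CNVR.

    The id is the positional key ``chrom:start-end`` so a serialized
    genotype matrix can be mapped back to coordinates without a side table.
    """

    id: str
    chrom: str
    start: int
    end: int
    parent_cnvr_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.id}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _segment_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def segment_from_id(seg_id: str, parent_cnvr_id: str = "") -> CnvSegment:
    """Rebuild a segment from its positional id (used when re-reading TSVs)."""
    chrom, span = seg_id.rsplit(":", 1)
    start, end = span.split("-")
    return CnvSegment(seg_id, chrom, int(start), int(end), parent_cnvr_id)


def partition_cnvr(
    cnvr: Cnvr, member_calls: Optional[Sequence[CnvCall]] = None
) -> list[CnvSegment]:
    """Cut one CNVR into atomic segments at all member-call boundaries.

    Breakpoints are ``{start_j} U {end_j + 1}`` over the member calls;
    consecutive breakpoints b_k < b_{k+1} delimit the candidate segment
    [b_k, b_{k+1} - 1], kept only if covered by >= 1 call.  Gaps between
    chained calls therefore yield no segment: uncovered bases are diploid
    for everyone and carry no information.
    """
    calls = list(member_calls) if member_calls is not None else list(cnvr.members)
    if not calls:
        raise ValueError(f"CNVR {cnvr.id}: empty member set")
    breakpoints = sorted({c.start for c in calls} | {c.end + 1 for c in calls})
    starts = np.array([c.start for c in calls])
    ends = np.array([c.end for c in calls])
    segments: list[CnvSegment] = []
    for b, b_next in zip(breakpoints[:-1], breakpoints[1:]):
        if np.any((starts <= b) & (ends >= b)):  # covered (atomic: test 1 bp)
            segments.append(
                CnvSegment(_segment_id(cnvr.chrom, b, b_next - 1),
                           cnvr.chrom, b, b_next - 1, cnvr.id)
            )
    return segments


def partition_all(cnvrs: Sequence[Cnvr]) -> list[CnvSegment]:
    """Partition every CNVR; result ordered by (chrom, start)."""
    segments: list[CnvSegment] = []
    for cnvr in cnvrs:
        segments.extend(partition_cnvr(cnvr))
    segments.sort(key=lambda s: (chrom_sort_key(s.chrom), s.start))
    return segments


class GenotypeMatrix:
    """samples x segments matrix of copy-number classes, stored as int8 codes."""

    def __init__(self, samples: Sequence[str], segments: Sequence[CnvSegment],
                 codes: np.ndarray):
        samples = list(samples)
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        if codes.shape != (len(samples), len(segments)):
            raise ValueError("code matrix shape does not match samples x segments")
        self.samples = samples
        self.segments = list(segments)
        self.codes = codes
        self._sample_index = {s: i for i, s in enumerate(samples)}
        self._segment_index = {seg.id: j for j, seg in enumerate(self.segments)}

    @property
    def segment_ids(self) -> list[str]:
        return [s.id for s in self.segments]

    def class_at(self, sample_id: str, segment_id: str) -> str:
        return CN_CLASSES[
            self.codes[self._sample_index[sample_id], self._segment_index[segment_id]]
        ]

    def rows_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._sample_index[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None
        return self.codes[idx, :]

    def segment_column(self, segment_id: str) -> int:
        return self._segment_index[segment_id]

    def to_frame(self) -> pd.DataFrame:
        """Class-label DataFrame (index: samples, columns: segment ids)."""
        labels = np.asarray(CN_CLASSES, dtype=object)[self.codes]
        return pd.DataFrame(labels, index=self.samples, columns=self.segment_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        bad = sorted(set(np.unique(df.to_numpy())) - set(CN_CLASSES))
        if bad:
            raise ValueError(f"unknown class label(s): {bad}")
        segments = [segment_from_id(c) for c in df.columns]
        codes = np.vectorize(_CLASS_CODE.__getitem__, otypes=[np.int8])(df.to_numpy())
        return cls(list(df.index.astype(str)), segments, codes)


def build_genotype_matrix(
    samples: Sequence[str],
    segments: Sequence[CnvSegment],
    calls: Iterable[CnvCall],
    conflict_policy: str = "error",
) -> GenotypeMatrix:
    """Genotype each sample at each segment from its CNV calls.

    A cell is the class of the (unique) call of that sample covering the
    segment, A2 where no call covers it.  Calls from samples outside
    ``samples`` are ignored.  Two same-sample calls hitting one segment is
    an error by default (the per-sample calls of an HMM caller cannot
    overlap); ``conflict_policy="most-extreme"`` instead keeps the class
    farthest from diploid, preferring the loss on a tie.

    Segments must come from breakpoint partitioning: a call overlapping a
    segment only partially is rejected.
    """
    if conflict_policy not in {"error", "most-extreme"}:
        raise ValueError(f"unknown conflict policy {conflict_policy!r}")
    sample_index = {s: i for i, s in enumerate(samples)}
    codes = np.full((len(samples), len(segments)), _DIPLOID_CODE, dtype=np.int8)

    by_chrom: dict[str, list[tuple[int, CnvSegment]]] = {}
    for j, seg in enumerate(segments):
        by_chrom.setdefault(seg.chrom, []).append((j, seg))
    chrom_arrays = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort(key=lambda p: p[1].start)
        chrom_arrays[chrom] = (
            np.array([p[1].start for p in pairs]),
            np.array([p[1].end for p in pairs]),
            np.array([p[0] for p in pairs]),
        )

    for call in calls:
        i = sample_index.get(call.sample_id)
        if i is None or call.chrom not in chrom_arrays:
            continue
        seg_starts, seg_ends, cols = chrom_arrays[call.chrom]
        lo = int(np.searchsorted(seg_ends, call.start, side="left"))
        hi = int(np.searchsorted(seg_starts, call.end, side="right"))
        code = _CLASS_CODE[class_of_cn(call.copy_number)]
        for k in range(lo, hi):
            if seg_starts[k] < call.start or seg_ends[k] > call.end:
                raise ValueError(
                    f"call {call.key} partially overlaps segment "
                    f"{_segment_id(call.chrom, int(seg_starts[k]), int(seg_ends[k]))}; "
                    "segments must come from breakpoint partitioning"
                )
            j = cols[k]
            prev = codes[i, j]
            if prev != _DIPLOID_CODE and prev != code:
                if conflict_policy == "error":
                    raise ValueError(
                        f"sample {call.sample_id} has two conflicting calls over "
                        f"segment {segments[j].id}"
                    )
                # most-extreme: larger |class - A2|, loss wins ties
                if (abs(code - _DIPLOID_CODE), _DIPLOID_CODE - code) <= (
                    abs(prev - _DIPLOID_CODE), _DIPLOID_CODE - prev
                ):
                    continue
            codes[i, j] = code
    return GenotypeMatrix(samples, segments, codes)


def encode_matrix(matrix: GenotypeMatrix, scheme: str = "onehot") -> pd.DataFrame:
    """Numeric encoding of the genotype matrix for distances and PCA.

    ``onehot`` emits one indicator column per (segment, class observed in
    the matrix at that segment), named ``<segment>:<class>``; it treats the
    classes as purely categorical, which suits distances between states
    that are not equidistant on a copy-number scale.  ``copy-number`` emits
    one column per segment with values 0..5 (Agt4 -> 5).
    """
    if scheme == "copy-number":
        return pd.DataFrame(
            matrix.codes.astype(float),
            index=matrix.samples,
            columns=matrix.segment_ids,
        )
    if scheme == "onehot":
        blocks: list[np.ndarray] = []
        names: list[str] = []
        for j, seg in enumerate(matrix.segments):
            col = matrix.codes[:, j]
            for code in np.unique(col):
                blocks.append((col == code).astype(float))
                names.append(f"{seg.id}:{CN_CLASSES[code]}")
        data = np.column_stack(blocks) if blocks else np.empty((len(matrix.samples), 0))
        return pd.DataFrame(data, index=matrix.samples, columns=names)
    raise ValueError(f"unknown encoding scheme {scheme!r}")
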