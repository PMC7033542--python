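"""Readers and writers for every external file the pipeline touches.

All genomic coordinates are 1-based inclusive internally (the PennCNV
convention); conversion to/from 0-based half-open happens only at BED
boundaries.  Interval length is ``end - start + 1``.

Supported formats:

* PennCNV ``rawcnv`` call lists (read/write),
* sample -> breed -> comparison-group population maps (TSV),
* per-sample quality-control metric tables (TSV),
* chromosome size tables (two-column TSV, UCSC ``chrom.sizes`` style),
* gene annotation as BED (0-based half-open) or 1-based TSV,
* CNVR tables (TSV or BED).
"""

from __future__ import annotations

import io as _stdio
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, TextIO, Union

import pandas as pd

Source = Union[str, Path, TextIO]

__all__ = [
    "CnvCall",
    "PopulationMap",
    "GeneModel",
    "ChromSizes",
    "ParseError",
    "chrom_sort_key",
    "is_autosome",
    "read_penncnv_calls",
    "write_penncnv_calls",
    "read_population_map",
    "write_population_map",
    "read_gene_annotation",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_qc_table",
    "write_qc_table",
    "write_cnvr_table",
    "read_cnvr_table",
]


class ParseError(ValueError):
    """Raised when an input file does not follow its declared dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CnvCall:
    """One per-individual CNV call: a deviation from the diploid state.

    Coordinates are 1-based inclusive.  ``copy_number`` is the integer copy
    number estimated by the caller; 2 (the diploid reference state) is by
    definition not a CNV and is rejected.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    num_snps: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"call {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.start < 1:
            raise ValueError(f"call start must be >= 1, got {self.start}")
        if self.copy_number < 0:
            raise ValueError(f"copy number must be >= 0, got {self.copy_number}")
        if self.copy_number == 2:
            raise ValueError(
                f"call {self.chrom}:{self.start}-{self.end} in {self.sample_id} "
                "has cn=2: the diploid state is not a CNV"
            )
        if self.num_snps is not None and self.num_snps < 1:
            raise ValueError(f"num_snps must be positive, got {self.num_snps}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> str:
        """Canonical, order-independent identifier for this call."""
        return f"{self.sample_id}|{self.chrom}:{self.start}-{self.end}|cn={self.copy_number}"


class PopulationMap:
    """Mapping sample_id -> (breed code, optional comparison-group label)."""

    def __init__(self, entries: Mapping[str, tuple[str, Optional[str]]]):
        self._entries = dict(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PopulationMap) and self._entries == other._entries

    @property
    def samples(self) -> list[str]:
        return list(self._entries)

    def breed_of(self, sample_id: str) -> str:
        return self._entries[sample_id][0]

    def group_of(self, sample_id: str) -> Optional[str]:
        return self._entries[sample_id][1]

    def samples_in_breed(self, breed: str) -> list[str]:
        return [s for s, (b, _) in self._entries.items() if b == breed]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, (_, g) in self._entries.items() if g == group]

    @property
    def breeds(self) -> list[str]:
        seen: dict[str, None] = {}
        for b, _ in self._entries.values():
            seen.setdefault(b)
        return list(seen)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, g in self._entries.values():
            if g is not None:
                seen.setdefault(g)
        return list(seen)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 1-based inclusive after import."""

    chrom: str
    start: int
    end: int
    symbol: str
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.symbol}: start > end")
        if self.start < 1:
            raise ValueError(f"gene {self.symbol}: start must be >= 1")
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.strand is not None and self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.symbol}: bad strand {self.strand!r}")


class ChromSizes(dict):
    """chrom -> length (bp).  A plain dict with validation helpers."""

    def __init__(self, sizes: Mapping[str, int]):
        super().__init__()
        for chrom, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length {length}")
            self[chrom] = int(length)

    def require(self, chroms: Iterable[str]) -> None:
        missing = sorted({c for c in chroms if c not in self})
        if missing:
            raise KeyError(f"no length for chromosome(s): {', '.join(missing)}")

    @property
    def total_bp(self) -> int:
        return sum(self.values())


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_CHR_PREFIX = re.compile(r"^(chr)?(.+)$", re.IGNORECASE)


def _chrom_body(chrom: str) -> str:
    m = _CHR_PREFIX.match(chrom)
    return m.group(2) if m else chrom


def is_autosome(chrom: str) -> bool:
    """True for purely numeric chromosome names (with or without 'chr')."""
    return _chrom_body(chrom).isdigit()


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Natural ordering: chr1 < chr2 < ... < chr29 < chrX (alphabetic tail)."""
    body = _chrom_body(chrom)
    if body.isdigit():
        return (0, int(body), "")
    return (1, 0, body)


def _open_source(source: Source):
    """Return (file-like, should_close).  Strings holding newlines are data."""
    if hasattr(source, "read"):
        return source, False
    if isinstance(source, str) and "\n" in source:
        return _stdio.StringIO(source), True
    return open(source, "r"), True


# ---------------------------------------------------------------------------
# PennCNV rawcnv
# ---------------------------------------------------------------------------

_RAWCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)"
    r"\s+numsnp=(?P<numsnp>[\d,]+)"
    r"\s+length=(?P<length>[\d,]+)"
    r"\s+state(?P<state>\d+),cn=(?P<cn>\d+)"
    r"\s+(?P<file>\S+)"
    r"(?:\s+startsnp=(?P<startsnp>\S+))?"
    r"(?:\s+endsnp=(?P<endsnp>\S+))?"
    r"(?:\s+\S+)*$"
)

# PennCNV hidden-state code for each copy number; states 3/4 are the two
# diploid states and never appear in calls.
_CN_TO_STATE = {0: 1, 1: 2, 3: 5, 4: 6}


def _sample_from_file_token(token: str, sample_id_pattern: Optional[str]) -> str:
    if sample_id_pattern is not None:
        m = re.search(sample_id_pattern, token)
        if not m:
            raise ParseError(
                f"sample id pattern {sample_id_pattern!r} does not match {token!r}"
            )
        return m.group(1) if m.groups() else m.group(0)
    base = os.path.basename(token)
    stem, _ext = os.path.splitext(base)
    return stem or base


def read_penncnv_calls(
    source: Source,
    autosomes_only: bool = True,
    sample_id_pattern: Optional[str] = None,
) -> list[CnvCall]:
    """Parse a PennCNV ``rawcnv`` file into :class:`CnvCall` records.

    Each non-empty line follows the dialect::

        chr1:100-200 numsnp=10 length=101 state2,cn=1 FILE startsnp=rs1 endsnp=rs2

    The sample id is the basename of the FILE token with its extension
    stripped, unless ``sample_id_pattern`` (a regex whose first group, or
    whole match, is the id) is given.  With ``autosomes_only`` (the default)
    non-numeric chromosomes are rejected; the array study design calls CNVs
    on the 29 bovine autosomes only.
    """
    fh, close = _open_source(source)
    calls: list[CnvCall] = []
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            m = _RAWCNV_RE.match(line)
            if not m:
                raise ParseError(f"line {lineno}: not a rawcnv record: {line!r}")
            cn = int(m.group("cn"))
            if cn == 2:
                raise ParseError(
                    f"line {lineno}: cn=2 (diploid) is not a valid CNV call"
                )
            chrom = m.group("chrom")
            if autosomes_only and not is_autosome(chrom):
                raise ParseError(
                    f"line {lineno}: non-autosomal chromosome {chrom!r} "
                    "(pass autosomes_only=False to accept)"
                )
            numsnp = int(m.group("numsnp").replace(",", ""))
            try:
                calls.append(
                    CnvCall(
                        sample_id=_sample_from_file_token(
                            m.group("file"), sample_id_pattern
                        ),
                        chrom=chrom,
                        start=int(m.group("start")),
                        end=int(m.group("end")),
                        copy_number=cn,
                        num_snps=numsnp if numsnp > 0 else None,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    finally:
        if close:
            fh.close()
    return calls


def write_penncnv_calls(calls: Iterable[CnvCall], dest: Union[str, Path, TextIO]) -> None:
    """Write calls in the rawcnv dialect (numsnp=0 encodes a missing count)."""
    fh, close = (dest, False) if hasattr(dest, "write") else (open(dest, "w"), True)
    try:
        for c in calls:
            state = _CN_TO_STATE.get(c.copy_number, 6)
            numsnp = c.num_snps if c.num_snps is not None else 0
            fh.write(
                f"{c.chrom}:{c.start}-{c.end} numsnp={numsnp} "
                f"length={c.length} state{state},cn={c.copy_number} {c.sample_id}\n"
            )
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------


def read_population_map(source: Source) -> PopulationMap:
    """Read a TSV with header ``sample_id  breed  group`` (group may be blank)."""
    fh, close = _open_source(source)
    try:
        df = pd.read_csv(fh, sep="\t", dtype=str, comment="#")
    finally:
        if close:
            fh.close()
    for col in ("sample_id", "breed"):
        if col not in df.columns:
            raise ParseError(f"population map missing required column {col!r}")
    dupes = df["sample_id"][df["sample_id"].duplicated()]
    if not dupes.empty:
        raise ParseError(f"duplicate sample id(s): {', '.join(sorted(set(dupes)))}")
    has_group = "group" in df.columns
    entries: dict[str, tuple[str, Optional[str]]] = {}
    for row in df.itertuples(index=False):
        group = getattr(row, "group", None) if has_group else None
        if isinstance(group, float) or group in ("", None) or pd.isna(group):
            group = None
        entries[row.sample_id] = (row.breed, group)
    return PopulationMap(entries)


def write_population_map(pmap: PopulationMap, dest: Union[str, Path]) -> None:
    rows = [
        {"sample_id": s, "breed": pmap.breed_of(s), "group": pmap.group_of(s) or ""}
        for s in pmap.samples
    ]
    pd.DataFrame(rows, columns=["sample_id", "breed", "group"]).to_csv(
        dest, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def read_gene_annotation(source: Source, dialect: str = "bed") -> list[GeneModel]:
    """Read gene intervals.

    ``dialect="bed"``: headerless BED, 0-based half-open, columns
    chrom/start/end/name[/score/strand].  ``dialect="tsv"``: TSV with header
    chrom/start/end/symbol[/strand], 1-based inclusive.  Both are normalised
    to the 1-based inclusive internal convention.
    """
    if dialect not in {"bed", "tsv"}:
        raise ValueError(f"unknown gene annotation dialect {dialect!r}")
    fh, close = _open_source(source)
    genes: list[GeneModel] = []
    try:
        if dialect == "tsv":
            df = pd.read_csv(fh, sep="\t", dtype={"chrom": str}, comment="#")
            for col in ("chrom", "start", "end", "symbol"):
                if col not in df.columns:
                    raise ParseError(f"gene TSV missing column {col!r}")
            for row in df.itertuples(index=False):
                strand = getattr(row, "strand", None)
                if strand is not None and pd.isna(strand):
                    strand = None
                try:
                    genes.append(
                        GeneModel(row.chrom, int(row.start), int(row.end),
                                  row.symbol, strand)
                    )
                except ValueError as exc:
                    raise ParseError(str(exc)) from exc
        else:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError(f"line {lineno}: BED needs >= 4 columns")
                chrom, start0, end, name = parts[:4]
                strand = parts[5] if len(parts) >= 6 else None
                if int(start0) < 0:
                    raise ParseError(f"line {lineno}: negative BED start")
                try:
                    genes.append(
                        GeneModel(chrom, int(start0) + 1, int(end), name, strand)
                    )
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: {exc}") from exc
    finally:
        if close:
            fh.close()
    return genes


# ---------------------------------------------------------------------------
# chromosome sizes / QC table
# ---------------------------------------------------------------------------


def read_chrom_sizes(source: Source) -> ChromSizes:
    """Two-column TSV chrom<TAB>length; a non-numeric first row is a header."""
    fh, close = _open_source(source)
    sizes: dict[str, int] = {}
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: expected chrom<TAB>length")
            if lineno == 1 and not parts[1].strip().isdigit():
                continue  # header row
            if not parts[1].strip().lstrip("-").isdigit():
                raise ParseError(f"line {lineno}: non-integer length {parts[1]!r}")
            sizes[parts[0]] = int(parts[1])
    finally:
        if close:
            fh.close()
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, dest: Union[str, Path]) -> None:
    with open(dest, "w") as fh:
        for chrom in sorted(sizes, key=chrom_sort_key):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_qc_table(source: Source) -> pd.DataFrame:
    """TSV with header sample_id/lrr_sd/baf_drift/waviness."""
    fh, close = _open_source(source)
    try:
        df = pd.read_csv(fh, sep="\t", dtype={"sample_id": str}, comment="#")
    finally:
        if close:
            fh.close()
    for col in ("sample_id", "lrr_sd", "baf_drift", "waviness"):
        if col not in df.columns:
            raise ParseError(f"QC table missing column {col!r}")
    return df


def write_qc_table(df: pd.DataFrame, dest: Union[str, Path]) -> None:
    df.to_csv(dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CNVR tables
# ---------------------------------------------------------------------------

_CNVR_COLUMNS = ["cnvr_id", "chrom", "start", "end", "length", "type", "n_samples"]


def write_cnvr_table(cnvrs: Sequence, dest: Union[str, Path], dialect: str = "tsv") -> None:
    """Write CNVRs as a 1-based TSV or a 0-based half-open BED.

    Output is deterministically ordered by (chrom, start).  The TSV length
    column uses the inclusive convention ``end - start + 1``.
    """
    if dialect not in {"tsv", "bed"}:
        raise ValueError(f"unknown CNVR table dialect {dialect!r}")
    ordered = sorted(cnvrs, key=lambda r: (chrom_sort_key(r.chrom), r.start))
    with open(dest, "w") as fh:
        if dialect == "tsv":
            fh.write("\t".join(_CNVR_COLUMNS) + "\n")
            for r in ordered:
                fh.write(
                    f"{r.id}\t{r.chrom}\t{r.start}\t{r.end}\t"
                    f"{r.end - r.start + 1}\t{r.type}\t{r.n_samples}\n"
                )
        else:
            for r in ordered:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.id}\t0\t.\n")


def read_cnvr_table(source: Source):
    """Read a TSV written by :func:`write_cnvr_table` back into Cnvr records.

    Member calls are not stored in the table, so the returned regions carry
    empty member lists; interval, type and carrier count round-trip exactly.
    """
    from .cnvr import Cnvr  # local import to avoid a cycle

    fh, close = _open_source(source)
    try:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str}, comment="#")
    finally:
        if close:
            fh.close()
    for col in _CNVR_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"CNVR table missing column {col!r}")
    return [
        Cnvr(
            id=row.cnvr_id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            type=row.type,
            members=(),
            n_samples=int(row.n_samples),
        )
        for row in df.itertuples(index=False)
    ]
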