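"""Shared genomic coordinate types and plain-text format I/O.

Everything in the package speaks 0-based half-open coordinates (BED
convention).  Formats that use other conventions (RepeatMasker ``.out``
is 1-based inclusive) are converted at the boundary, here and nowhere
else.

Supported formats: ENCODE tagAlign (6-column BED-like, one mapped tag
per line), BED3/BED6, the UCSC ``rmsk`` tab table and RepeatMasker
``.out`` repeat annotations, and a tab-delimited expression matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TagCollection",
    "TEAnnotation",
    "Transcript",
    "ExpressionMatrix",
    "ParseError",
    "ConfigurationError",
    "read_tagalign",
    "write_tagalign",
    "read_bed",
    "write_bed",
    "read_repeatmasker",
    "read_expression_table",
    "write_expression_table",
]


class ParseError(ValueError):
    """A line of an input file violates its format contract."""


class ConfigurationError(ValueError):
    """Caller supplied inconsistent options or metadata."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint position, ``floor((start + end) / 2)``.

        Used as the canonical single-base location of a tag or anchor;
        it is strand-symmetric.
        """
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TagCollection:
    """Mapped sequencing tags for one assay over a declared genome.

    Tag positions are stored as sorted per-chromosome midpoint arrays so
    that window counting is a pair of binary searches.  The Poisson
    background rate ``lambda0`` (tags per bp) is total tags divided by
    total genome length.
    """

    mark: str
    genome: Mapping[str, int]
    _mids: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    total_tags: int = 0

    @classmethod
    def from_intervals(
        cls, mark: str, tags: Iterable[GenomicInterval], genome: Mapping[str, int]
    ) -> "TagCollection":
        by_chrom: dict[str, list[int]] = {c: [] for c in genome}
        n = 0
        for t in tags:
            if t.chrom not in genome:
                raise ConfigurationError(f"tag on undeclared chromosome {t.chrom}")
            by_chrom[t.chrom].append(t.midpoint)
            n += 1
        mids = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}
        return cls(mark=mark, genome=dict(genome), _mids=mids, total_tags=n)

    @classmethod
    def from_midpoints(
        cls, mark: str, mids: Mapping[str, np.ndarray], genome: Mapping[str, int]
    ) -> "TagCollection":
        clean = {}
        n = 0
        for c in genome:
            a = np.sort(np.asarray(mids.get(c, ()), dtype=np.int64))
            if a.size and (a[0] < 0 or a[-1] >= genome[c]):
                raise ConfigurationError(
                    f"{mark}: tag midpoint outside chromosome {c} bounds"
                )
            clean[c] = a
            n += int(a.size)
        return cls(mark=mark, genome=dict(genome), _mids=clean, total_tags=n)

    @property
    def genome_length(self) -> int:
        return int(sum(self.genome.values()))

    @property
    def lambda0(self) -> float:
        """Genome-wide background tag rate in tags/bp (0 when empty)."""
        gl = self.genome_length
        return self.total_tags / gl if gl else 0.0

    def midpoints(self, chrom: str) -> np.ndarray:
        return self._mids.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, window: GenomicInterval) -> int:
        """Number of tag midpoints inside ``window`` (half-open)."""
        m = self.midpoints(window.chrom)
        return int(
            np.searchsorted(m, window.end, "left")
            - np.searchsorted(m, window.start, "left")
        )


@dataclass(frozen=True)
class TEAnnotation:
    """A RepeatMasker repeat interval with classification and age proxy.

    ``divergence`` is percent substitutions from the family consensus;
    higher means older.
    """

    interval: GenomicInterval
    repeat_name: str
    repeat_class: str
    repeat_family: str
    divergence: float

    def __post_init__(self) -> None:
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")


@dataclass(frozen=True)
class Transcript:
    """A stranded transcript model (BED-like span plus an id)."""

    interval: GenomicInterval
    id: str

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("transcript strand must be + or -")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass
class ExpressionMatrix:
    """Normalized expression values, units x samples, with group labels."""

    unit_ids: list[str]
    sample_ids: list[str]
    group: dict[str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.unit_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match id lists")
        missing = [s for s in self.sample_ids if s not in self.group]
        if missing:
            raise ConfigurationError(f"samples without group label: {missing}")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.group[s], None)
        return list(seen)

    def sample_columns(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.group[s] == group]
        if not idx:
            raise KeyError(f"no samples in group {group!r}")
        return self.values[:, idx]

    def group_means(self, group: str) -> np.ndarray:
        return self.sample_columns(group).mean(axis=1)

    def unit_index(self, unit_id: str) -> int:
        return self.unit_ids.index(unit_id)


# ---------------------------------------------------------------------------
# tagAlign / BED


def _parse_coords(fields: Sequence[str], path: str, lineno: int) -> tuple[str, int, int]:
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start < 0 or start >= end:
        raise ParseError(f"{path}:{lineno}: invalid span {start}-{end}")
    return chrom, start, end


def read_tagalign(
    path: str,
    mark: str,
    genome: Mapping[str, int],
    *,
    on_unknown_chrom: str = "strict",
) -> TagCollection:
    """Read an ENCODE tagAlign file into a :class:`TagCollection`.

    Each line is ``chrom  start  end  sequence  score  strand``.  Tags on
    chromosomes absent from ``genome`` are an error under ``strict`` (the
    default) or skipped with a logged count under ``lenient``.
    """
    if on_unknown_chrom not in ("strict", "lenient"):
        raise ConfigurationError(f"unknown chromosome policy {on_unknown_chrom!r}")
    mids: dict[str, list[int]] = {c: [] for c in genome}
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >=6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, start, end = _parse_coords(fields, path, lineno)
            if chrom not in genome:
                if on_unknown_chrom == "strict":
                    raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom}")
                skipped += 1
                continue
            mid = (start + end) // 2
            if not (0 <= mid < genome[chrom]):
                raise ParseError(
                    f"{path}:{lineno}: tag outside chromosome {chrom} bounds"
                )
            mids[chrom].append(mid)
    if skipped:
        logger.warning("%s: skipped %d tags on undeclared chromosomes", path, skipped)
    arr = {c: np.asarray(v, dtype=np.int64) for c, v in mids.items()}
    coll = TagCollection.from_midpoints(mark, arr, genome)
    if coll.total_tags == 0:
        logger.warning("%s: no tags; background rate lambda0 = 0", path)
    return coll


def write_tagalign(
    tags: Iterable[GenomicInterval], path: str, *, tag_length: int | None = None
) -> None:
    """Write tag intervals as tagAlign lines (sequence ``N``, score 1000)."""
    with open(path, "w") as fh:
        for t in tags:
            end = t.end if tag_length is None else t.start + tag_length
            strand = t.strand if t.strand in ("+", "-") else "+"
            fh.write(f"{t.chrom}\t{t.start}\t{end}\tN\t1000\t{strand}\n")


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3+ records; a 6th column, when present, sets the strand."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 fields")
            chrom, start, end = _parse_coords(fields, path, lineno)
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str,
    *,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals in input order as BED3 (or BED6 when names/scores given)."""
    intervals = list(intervals)
    bed6 = names is not None or scores is not None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if bed6:
                name = names[i] if names is not None else "."
                score = scores[i] if scores is not None else 0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# RepeatMasker

#: column indices in the UCSC rmsk tab table
_RMSK_COLS = {"milliDiv": 2, "genoName": 5, "genoStart": 6, "genoEnd": 7,
              "strand": 9, "repName": 10, "repClass": 11, "repFamily": 12}


def read_repeatmasker(path: str, dialect: str = "ucsc_rmsk") -> list[TEAnnotation]:
    """Read TE annotations from a UCSC ``rmsk`` table or RepeatMasker ``.out``.

    Output coordinates are uniformly 0-based half-open; the ``.out``
    dialect's 1-based inclusive ``begin`` is shifted down by one.
    Divergence comes from ``milliDiv/10`` (ucsc_rmsk) or the ``%div``
    column (rm_out).
    """
    if dialect == "ucsc_rmsk":
        return _read_rmsk_table(path)
    if dialect == "rm_out":
        return _read_rm_out(path)
    raise ConfigurationError(f"unknown RepeatMasker dialect {dialect!r}")


def _read_rmsk_table(path: str) -> list[TEAnnotation]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) <= _RMSK_COLS["repFamily"]:
                raise ParseError(f"{path}:{lineno}: too few rmsk columns")
            try:
                start = int(f[_RMSK_COLS["genoStart"]])
                end = int(f[_RMSK_COLS["genoEnd"]])
                millidiv = int(f[_RMSK_COLS["milliDiv"]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer rmsk field") from exc
            strand = f[_RMSK_COLS["strand"]]
            iv = GenomicInterval(
                f[_RMSK_COLS["genoName"]], start, end,
                strand if strand in ("+", "-") else ".",
            )
            out.append(
                TEAnnotation(
                    interval=iv,
                    repeat_name=f[_RMSK_COLS["repName"]],
                    repeat_class=f[_RMSK_COLS["repClass"]],
                    repeat_family=f[_RMSK_COLS["repFamily"]],
                    divergence=millidiv / 10.0,
                )
            )
    return out


def _read_rm_out(path: str) -> list[TEAnnotation]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            f = line.split()
            if not f:
                continue
            # .out files open with two header lines starting "SW" / "score"
            if f[0] in ("SW", "score"):
                continue
            if len(f) < 11:
                raise ParseError(f"{path}:{lineno}: too few .out columns")
            try:
                div = float(f[1])
                begin, end = int(f[5]), int(f[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad .out numeric field") from exc
            if begin < 1:
                raise ParseError(f"{path}:{lineno}: 1-based begin < 1")
            strand = "+" if f[8] == "+" else "-"
            cls_fam = f[10]
            if "/" in cls_fam:
                rep_class, rep_family = cls_fam.split("/", 1)
            else:
                rep_class = rep_family = cls_fam
            out.append(
                TEAnnotation(
                    interval=GenomicInterval(f[4], begin - 1, end, strand),
                    repeat_name=f[9],
                    repeat_class=rep_class,
                    repeat_family=rep_family,
                    divergence=div,
                )
            )
    return out


def write_rmsk_table(tes: Iterable[TEAnnotation], path: str) -> None:
    """Write TEs in UCSC rmsk tab-table column layout (13 columns used)."""
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            row = ["0", "0", str(int(round(te.divergence * 10))), "0", "0",
                   iv.chrom, str(iv.start), str(iv.end),
                   str(iv.strand if iv.strand in ("+", "-") else "+"),
                   iv.strand if iv.strand in ("+", "-") else "+",
                   te.repeat_name, te.repeat_class, te.repeat_family]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# expression table


def read_expression_table(path: str, group_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (header = sample ids).

    Every sample must appear in ``group_map``; duplicate unit ids and
    negative or non-numeric cells are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = [str(s) for s in df.columns]
    missing = [s for s in samples if s not in group_map]
    if missing:
        raise ConfigurationError(f"samples missing from group map: {missing}")
    units = [str(u) for u in df.index]
    dup = pd.Index(units)[pd.Index(units).duplicated()]
    if len(dup):
        raise ParseError(f"duplicated unit id(s): {sorted(set(dup))}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression cell") from exc
    if np.isnan(values).any():
        raise ParseError(f"{path}: non-numeric or missing expression cell")
    if (values < 0).any():
        raise ParseError(f"{path}: negative expression value")
    return ExpressionMatrix(
        unit_ids=units,
        sample_ids=samples,
        group={s: group_map[s] for s in samples},
        values=values,
    )


def write_expression_table(expr: ExpressionMatrix, path: str) -> None:
    df = pd.DataFrame(expr.values, index=expr.unit_ids, columns=expr.sample_ids)
    df.to_csv(path, sep="\t", index_label="unit")
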