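"""Genomic coordinate types, cytoband tables and interval mapping.

All coordinates are 0-based half-open ``[start, end)`` — the native
convention of cytoBand.txt and BED — and chromosome names are normalised
to the ``chr``-prefixed form.  Cytoband labels follow cytogenetic usage:
a band is labelled ``8p12`` (chromosome number + arm + sub-band) and a
contiguous run of bands renders as ``8p12-p11.11``, collapsing the
repeated chromosome number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomeAnnotationError",
    "Cytoband",
    "FeatureLocus",
    "CytobandRange",
    "normalize_chrom",
    "read_cytoband_table",
    "read_feature_loci",
    "locate_feature",
    "make_range",
    "bands_in_range",
    "parse_range_label",
]

FEATURE_TYPES = ("miRNA", "protein_coding", "lncRNA", "other")


class GenomeAnnotationError(ValueError):
    """Raised for malformed annotation files or unresolvable coordinates."""


def normalize_chrom(name: str) -> str:
    name = str(name).strip()
    if not name:
        raise GenomeAnnotationError("empty chromosome name")
    return name if name.startswith("chr") else "chr" + name


def _chrom_number(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


@dataclass(frozen=True)
class Cytoband:
    """One Giemsa band: ``name`` is the on-chromosome label (e.g. ``p12``)."""

    chrom: str
    start: int
    end: int
    name: str
    stain: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise GenomeAnnotationError(
                f"cytoband {self.chrom}:{self.name} has start >= end"
            )
        if not self.name or self.name[0] not in "pq":
            raise GenomeAnnotationError(
                f"band name {self.name!r} must begin with the arm (p/q)"
            )

    @property
    def arm(self) -> str:
        return self.name[0]

    @property
    def band_label(self) -> str:
        """Full cytogenetic label including chromosome number, e.g. ``8p12``."""
        return f"{_chrom_number(self.chrom)}{self.name}"


@dataclass(frozen=True)
class FeatureLocus:
    """A genomic feature (miRNA, gene ...) with 0-based half-open coordinates."""

    feature_id: str
    feature_type: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise GenomeAnnotationError(
                f"feature {self.feature_id} has start >= end"
            )


@dataclass(frozen=True)
class CytobandRange:
    """A contiguous run of bands on one chromosome (Table-2-style range)."""

    chrom: str
    first_band: str
    last_band: str
    start: int
    end: int

    @property
    def label(self) -> str:
        num = _chrom_number(self.chrom)
        if self.first_band == self.last_band:
            return f"{num}{self.first_band}"
        return f"{num}{self.first_band}-{self.last_band}"


def _iter_rows(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_cytoband_table(path) -> list[Cytoband]:
    """Read a cytoBand.txt-dialect table (chrom, start, end, band, stain).

    Rows are returned sorted by (chrom, start).  Malformed coordinates and
    overlapping bands on one chromosome raise :class:`GenomeAnnotationError`
    naming the offending line.
    """
    bands: list[Cytoband] = []
    for lineno, parts in _iter_rows(path):
        if len(parts) < 4:
            raise GenomeAnnotationError(
                f"{path}: line {lineno}: expected >=4 tab-separated columns"
            )
        chrom = normalize_chrom(parts[0])
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise GenomeAnnotationError(
                f"{path}: line {lineno}: non-integer coordinates"
            ) from exc
        if start >= end:
            raise GenomeAnnotationError(
                f"{path}: line {lineno}: start >= end"
            )
        stain = parts[4] if len(parts) > 4 else ""
        try:
            bands.append(Cytoband(chrom, start, end, parts[3], stain))
        except GenomeAnnotationError as exc:
            raise GenomeAnnotationError(f"{path}: line {lineno}: {exc}") from exc
    bands.sort(key=lambda b: (b.chrom, b.start))
    for prev, cur in zip(bands, bands[1:]):
        if cur.chrom == prev.chrom and cur.start < prev.end:
            raise GenomeAnnotationError(
                f"overlapping bands {prev.band_label} and {cur.band_label}"
            )
    return bands


def read_feature_loci(path, feature_type: str) -> list[FeatureLocus]:
    """Read BED3+ loci (name in column 4) as a position-sorted list."""
    loci: list[FeatureLocus] = []
    seen: set[str] = set()
    for lineno, parts in _iter_rows(path):
        if len(parts) < 4 or not parts[3].strip():
            raise GenomeAnnotationError(
                f"{path}: line {lineno}: BED name column (4) is required"
            )
        chrom = normalize_chrom(parts[0])
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise GenomeAnnotationError(
                f"{path}: line {lineno}: non-integer coordinates"
            ) from exc
        name = parts[3].strip()
        if name in seen:
            raise GenomeAnnotationError(
                f"{path}: line {lineno}: duplicate feature id {name!r}"
            )
        seen.add(name)
        strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
        if start >= end:
            raise GenomeAnnotationError(f"{path}: line {lineno}: start >= end")
        loci.append(FeatureLocus(name, feature_type, chrom, start, end, strand))
    loci.sort(key=lambda f: (f.chrom, f.start, f.end))
    return loci


def locate_feature(locus: FeatureLocus, cytobands: Sequence[Cytoband]) -> list[str]:
    """Band labels overlapping ``[locus.start, locus.end)`` (strand-blind).

    A feature straddling a band boundary returns every overlapped band.
    """
    on_chrom = [b for b in cytobands if b.chrom == locus.chrom]
    if not on_chrom:
        raise GenomeAnnotationError(
            f"chromosome {locus.chrom} absent from cytoband table"
        )
    return [
        b.band_label
        for b in sorted(on_chrom, key=lambda b: b.start)
        if b.start < locus.end and locus.start < b.end
    ]


_RANGE_RE = re.compile(r"^(?:chr)?([0-9XYM]+)([pq][\d.]*)$")


def parse_range_label(label: str) -> tuple[str, str, str]:
    """Parse ``"8p12-p11.11"`` (or ``"8p12"``) into (chrom, first, last)."""
    parts = label.strip().split("-")
    if len(parts) not in (1, 2):
        raise GenomeAnnotationError(f"cannot parse cytoband range {label!r}")
    m = _RANGE_RE.match(parts[0])
    if not m:
        raise GenomeAnnotationError(f"cannot parse cytoband range {label!r}")
    chrom, first = normalize_chrom(m.group(1)), m.group(2)
    if len(parts) == 1:
        return chrom, first, first
    last = parts[1]
    m2 = _RANGE_RE.match(last)
    if m2:  # repeated chromosome number, e.g. "8p12-8p12"
        if normalize_chrom(m2.group(1)) != chrom:
            raise GenomeAnnotationError(
                f"range {label!r} spans two chromosomes"
            )
        last = m2.group(2)
    if not last or last[0] not in "pq":
        raise GenomeAnnotationError(f"cannot parse cytoband range {label!r}")
    return chrom, first, last


def make_range(
    chrom: str,
    first_band: str,
    last_band: str,
    cytobands: Sequence[Cytoband],
) -> CytobandRange:
    """Build a :class:`CytobandRange` whose extent is the union of its bands."""
    chrom = normalize_chrom(chrom)
    by_name = {b.name: b for b in cytobands if b.chrom == chrom}
    for name in (first_band, last_band):
        if name not in by_name:
            raise GenomeAnnotationError(f"band {name!r} not found on {chrom}")
    first, last = by_name[first_band], by_name[last_band]
    if first.start > last.start:
        raise GenomeAnnotationError(
            f"band {first_band} lies after {last_band} on {chrom}"
        )
    return CytobandRange(chrom, first_band, last_band, first.start, last.end)


def range_from_label(label: str, cytobands: Sequence[Cytoband]) -> CytobandRange:
    chrom, first, last = parse_range_label(label)
    return make_range(chrom, first, last, cytobands)


def bands_in_range(
    rng: CytobandRange, cytobands: Sequence[Cytoband]
) -> list[str]:
    """Labels of the contiguous inclusive run of bands covered by ``rng``."""
    run = sorted(
        (
            b
            for b in cytobands
            if b.chrom == rng.chrom and b.start < rng.end and rng.start < b.end
        ),
        key=lambda b: b.start,
    )
    if not run:
        raise GenomeAnnotationError(
            f"no bands on {rng.chrom} overlap range {rng.label}"
        )
    return [b.band_label for b in run]
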