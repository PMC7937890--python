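"""Domain types and readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open.  GFF3 input/output converts
to and from the 1-based closed convention at the boundary.  Numeric columns
in TSV outputs are serialised at 4 decimal places so files diff cleanly
across platforms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

FEATURE_TYPES = ("coding_gene", "ncRNA", "repeat_element", "pseudogene")
PROTEINS = ("RsmA", "RsmE", "RsmI")

#: default mapping from GFF3 ``type`` column to internal feature types
DEFAULT_GFF_TYPE_MAP = {
    "gene": "coding_gene",
    "CDS": "coding_gene",
    "ncRNA": "ncRNA",
    "sRNA": "ncRNA",
    "repeat_region": "repeat_element",
    "mobile_genetic_element": "repeat_element",
    "pseudogene": "pseudogene",
}
_INTERNAL_TO_GFF = {
    "coding_gene": "gene",
    "ncRNA": "ncRNA",
    "repeat_element": "repeat_region",
    "pseudogene": "pseudogene",
}


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


@dataclass(frozen=True)
class Feature:
    """One annotated RNA-producing element (gene, ncRNA, repeat copy, pseudogene)."""

    locus_id: str
    type: str
    replicon: str
    start: int
    end: int
    strand: str
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.locus_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeAnnotation:
    """Replicon lengths plus the feature catalogue of a genome."""

    replicons: tuple[tuple[str, int], ...]
    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        lengths = dict(self.replicons)
        seen: set[str] = set()
        for f in self.features:
            if f.locus_id in seen:
                raise ValueError(f"duplicate locus identifier {f.locus_id!r}")
            seen.add(f.locus_id)
            if f.replicon not in lengths:
                raise ValueError(f"{f.locus_id}: unknown replicon {f.replicon!r}")
            if f.end > lengths[f.replicon]:
                raise ValueError(
                    f"{f.locus_id}: feature end {f.end} beyond replicon "
                    f"{f.replicon} length {lengths[f.replicon]}"
                )

    @property
    def replicon_lengths(self) -> dict[str, int]:
        return dict(self.replicons)

    def features_on(self, replicon: str) -> list[Feature]:
        return [f for f in self.features if f.replicon == replicon]

    def by_locus(self) -> dict[str, Feature]:
        return {f.locus_id: f for f in self.features}


@dataclass(frozen=True)
class TagLibrary:
    """Aligned tag 5' positions for one sequencing sample.

    ``tags`` holds (replicon, five_prime_position, strand) triples.  The
    library is unstranded downstream -- strand is kept only to orient the
    3' extension of each tag during coverage computation.
    """

    sample_id: str
    protein: str
    role: str
    bio_rep: int
    tech_rep: int
    replicons: tuple[tuple[str, int], ...]
    tags: tuple[tuple[str, int, str], ...]

    def __post_init__(self) -> None:
        if self.protein not in PROTEINS + ("none",):
            raise ValueError(f"unknown protein {self.protein!r}")
        if self.role not in ("pulldown", "total_control"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.bio_rep < 1 or self.tech_rep < 1:
            raise ValueError("replicate indices are 1-based and must be >= 1")
        if not self.tags:
            raise ValueError(f"{self.sample_id}: empty tag library")
        lengths = dict(self.replicons)
        for repl, pos, strand in self.tags:
            if repl not in lengths:
                raise ValueError(f"{self.sample_id}: tag on unknown replicon {repl!r}")
            if not (0 <= pos < lengths[repl]):
                raise ValueError(
                    f"{self.sample_id}: tag position {pos} outside replicon "
                    f"{repl} of length {lengths[repl]}"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"{self.sample_id}: bad strand {strand!r}")

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    def positions_on(self, replicon: str) -> np.ndarray:
        """Sorted 5' positions on one replicon (strand dropped)."""
        return np.sort(
            np.array([p for r, p, _ in self.tags if r == replicon], dtype=np.int64)
        )


@dataclass(frozen=True)
class Peak:
    """A reads-enriched region called against the total-RNA control.

    ``pv_score`` is -10*log10(p-value) of the summit bin under the local
    Poisson background; ``fold_enrichment`` is summit-bin treatment signal
    over the local expectation; ``fdr_percent`` is the empirical sample-swap
    FDR, absent (None) until :func:`rsmscope.peakcall.empirical_fdr` runs.
    """

    replicon: str
    start: int
    end: int
    summit: int
    tag_count: int
    pv_score: float
    fold_enrichment: float
    fdr_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside peak [{self.start}, {self.end})"
            )
        for name in ("pv_score", "fold_enrichment"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.fdr_percent is not None and not (0 <= self.fdr_percent <= 100):
            raise ValueError(f"fdr_percent out of [0, 100]: {self.fdr_percent}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# BED tag libraries
# ---------------------------------------------------------------------------

def load_tag_library(
    path: str | Path,
    *,
    sample_id: str,
    protein: str,
    role: str,
    bio_rep: int,
    tech_rep: int,
    replicons: dict[str, int] | Sequence[tuple[str, int]],
) -> TagLibrary:
    """Read aligned tags from a BED file (>= 3 columns, column 6 = strand).

    Each BED record contributes one tag at its 5' coordinate: ``start`` for
    plus-strand reads, ``end - 1`` for minus-strand reads.  Records without a
    strand column are taken as plus-strand.
    """
    lengths = dict(replicons)
    tags: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED record needs >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            if chrom not in lengths:
                raise FormatError(f"{path}:{lineno}: unknown replicon {chrom!r}")
            five_prime = start if strand == "+" else end - 1
            if not (0 <= five_prime < lengths[chrom]):
                raise FormatError(
                    f"{path}:{lineno}: tag at {five_prime} outside replicon "
                    f"{chrom} (length {lengths[chrom]})"
                )
            tags.append((chrom, five_prime, strand))
    return TagLibrary(
        sample_id=sample_id,
        protein=protein,
        role=role,
        bio_rep=bio_rep,
        tech_rep=tech_rep,
        replicons=tuple(sorted(lengths.items())),
        tags=tuple(tags),
    )


def write_tag_library(lib: TagLibrary, path: str | Path, read_length: int = 75) -> None:
    """Write a tag library as a 6-column BED file, one record per tag.

    The record interval is the read footprint implied by the 5' position and
    ``read_length``; ``load_tag_library`` recovers the identical 5' positions.
    """
    lengths = dict(lib.replicons)
    with open(path, "w") as fh:
        for i, (repl, pos, strand) in enumerate(lib.tags):
            if strand == "+":
                start = pos
                end = min(pos + read_length, lengths[repl])
            else:
                end = pos + 1
                start = max(0, end - read_length)
            fh.write(f"{repl}\t{start}\t{end}\t{lib.sample_id}.{i}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

def load_annotation(
    path: str | Path,
    type_map: Optional[dict[str, str]] = None,
) -> GenomeAnnotation:
    """Read a GFF3 annotation with ``##sequence-region`` pragmas.

    GFF3 1-based closed coordinates become 0-based half-open.  The GFF type
    column is translated through ``type_map`` (default
    :data:`DEFAULT_GFF_TYPE_MAP`); unmapped types raise.
    """
    type_map = dict(DEFAULT_GFF_TYPE_MAP if type_map is None else type_map)
    replicons: list[tuple[str, int]] = []
    features: list[Feature] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise FormatError(f"{path}:{lineno}: malformed sequence-region")
                replicons.append((parts[1], int(parts[3])))
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            seqid, _source, gff_type, start1, end1, _score, strand, _phase, attrs = cols
            if gff_type not in type_map:
                raise FormatError(f"{path}:{lineno}: unmapped GFF type {gff_type!r}")
            attributes = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            locus_id = attributes.get("ID")
            if locus_id is None:
                raise FormatError(f"{path}:{lineno}: feature without ID attribute")
            if locus_id in seen_ids:
                raise FormatError(f"{path}:{lineno}: duplicate locus ID {locus_id!r}")
            seen_ids.add(locus_id)
            features.append(
                Feature(
                    locus_id=locus_id,
                    type=type_map[gff_type],
                    replicon=seqid,
                    start=int(start1) - 1,
                    end=int(end1),
                    strand=strand,
                    name=attributes.get("Name"),
                )
            )
    if not replicons:
        raise FormatError(f"{path}: no ##sequence-region pragma found")
    try:
        return GenomeAnnotation(tuple(replicons), tuple(features))
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write a GFF3 file that :func:`load_annotation` reads back identically."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.replicons:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for f in annotation.features:
            attrs = f"ID={f.locus_id}"
            if f.name:
                attrs += f";Name={f.name}"
            fh.write(
                "\t".join(
                    [
                        f.replicon,
                        "rsmscope",
                        _INTERNAL_TO_GFF[f.type],
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Peak tables (TSV)
# ---------------------------------------------------------------------------

PEAK_COLUMNS = [
    "replicon",
    "start",
    "end",
    "length",
    "summit",
    "tag_count",
    "pv_score",
    "fold_enrichment",
    "fdr_percent",
]


def write_peak_table(peaks: Iterable[Peak], path: str | Path) -> None:
    rows = [
        {
            "replicon": p.replicon,
            "start": p.start,
            "end": p.end,
            "length": p.length,
            "summit": p.summit,
            "tag_count": p.tag_count,
            "pv_score": round(p.pv_score, 4),
            "fold_enrichment": round(p.fold_enrichment, 4),
            "fdr_percent": "" if p.fdr_percent is None else round(p.fdr_percent, 4),
        }
        for p in peaks
    ]
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_peak_table(path: str | Path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t", dtype={"replicon": str})
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing peak-table columns {missing}")
    peaks = []
    for row in df.itertuples(index=False):
        fdr = getattr(row, "fdr_percent")
        peaks.append(
            Peak(
                replicon=row.replicon,
                start=int(row.start),
                end=int(row.end),
                summit=int(row.summit),
                tag_count=int(row.tag_count),
                pv_score=float(row.pv_score),
                fold_enrichment=float(row.fold_enrichment),
                fdr_percent=None if pd.isna(fdr) else float(fdr),
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# bedGraph coverage tracks
# ---------------------------------------------------------------------------

def write_coverage_track(
    coverage: dict[str, np.ndarray] | np.ndarray,
    path: str | Path,
    replicon: str = "replicon_1",
) -> None:
    """Write per-position coverage as a run-length-merged bedGraph.

    Zero-coverage runs are omitted, so a flat-zero vector yields an empty
    track.  Accepts either one vector (with ``replicon``) or a dict keyed by
    replicon name.
    """
    tracks = coverage if isinstance(coverage, dict) else {replicon: coverage}
    with open(path, "w") as fh:
        for name in sorted(tracks):
            vec = np.asarray(tracks[name])
            if vec.size == 0:
                continue
            if np.any(vec < 0):
                raise ValueError(f"negative coverage value on {name}")
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vec.size]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v == 0:
                    continue
                out = int(v) if float(v).is_integer() else round(float(v), 4)
                fh.write(f"{name}\t{s}\t{e}\t{out}\n")


def read_coverage_track(
    path: str | Path, replicon_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Reconstruct per-position coverage vectors from a bedGraph file."""
    out = {name: np.zeros(length) for name, length in replicon_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            if chrom not in out:
                raise FormatError(f"{path}:{lineno}: unknown replicon {chrom!r}")
            out[chrom][int(start):int(end)] = float(value)
    return out
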