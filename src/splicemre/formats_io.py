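"""Readers and writers for the pipeline's external file formats.

All interval coordinates are **0-based half-open** inside the package and
**1-based inclusive** in every file the package reads or writes, except BED12
which keeps its native 0-based half-open convention.  Nucleotide sequences are
normalized on input: RNA ``U`` becomes ``T`` and everything is upper-cased;
``N`` is accepted as an ambiguity code but never matches in exact search.

Strand is ignored throughout: ESTs and MRE catalogs are assumed to be oriented
to the mRNA sense strand of their reference transcript, as is the case for
UniGene-style clusters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ReferenceSequence",
    "LibraryAnnotation",
    "ESTAlignment",
    "MRESite",
    "ProteinChangeRecord",
    "ESTDataset",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "read_est_bed12",
    "write_est_bed12",
    "read_library_table",
    "write_library_table",
    "read_est2lib",
    "write_est2lib",
    "read_mre_table",
    "write_mre_table",
    "read_protein_table",
    "write_protein_table",
    "write_results_tsv",
]

_NUCLEOTIDES = frozenset("ACGTN")
_VALIDATION_VALUES = frozenset({"true", "false", "random", "unknown"})
_HISTOLOGY_VALUES = frozenset({"normal", "cancer"})


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_sequence(seq: str, context: str = "") -> str:
    """Upper-case a nucleotide string and map RNA U to DNA T.

    Raises :class:`FormatError` (naming *context*) on characters outside
    ``ACGTUN``.
    """
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - _NUCLEOTIDES
    if bad:
        where = f" in {context}" if context else ""
        raise FormatError(
            f"non-nucleotide characters {sorted(bad)}{where}"
        )
    return s


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference transcript sequence each EST and MRE is placed on."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("reference sequence with empty id")
        if not self.sequence:
            raise FormatError(f"reference {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LibraryAnnotation:
    """Tissue and histology annotation of one EST (cDNA) library."""

    library_id: str
    tissue: str
    histology: str = "normal"

    def __post_init__(self) -> None:
        if not self.library_id:
            raise FormatError("library with empty id")
        if not self.tissue:
            raise FormatError(f"library {self.library_id!r} has empty tissue")
        if self.histology not in _HISTOLOGY_VALUES:
            raise FormatError(
                f"library {self.library_id!r}: histology must be one of "
                f"{sorted(_HISTOLOGY_VALUES)}, got {self.histology!r}"
            )


@dataclass(frozen=True)
class ESTAlignment:
    """One EST's spliced alignment on a reference, as ordered exon blocks.

    ``blocks`` are 0-based half-open intervals in reference coordinates,
    sorted ascending with strictly positive gaps between consecutive blocks
    (the gaps are the putative introns).
    """

    est_id: str
    reference_id: str
    library_id: str
    blocks: tuple[tuple[int, int], ...]

    def structure_ok(self) -> bool:
        """True iff blocks are non-empty, valid, sorted, gap-separated."""
        if not self.blocks:
            return False
        prev_end = None
        for start, end in self.blocks:
            if start < 0 or start >= end:
                return False
            if prev_end is not None and start <= prev_end:
                return False
            prev_end = end
        return True

    def validate(self, reference_length: int | None = None) -> "ESTAlignment":
        if not self.blocks:
            raise FormatError(f"EST {self.est_id!r} has no aligned blocks")
        if not self.structure_ok():
            raise FormatError(
                f"EST {self.est_id!r}: blocks must be sorted, non-overlapping "
                f"intervals with positive gaps, got {self.blocks}"
            )
        if reference_length is not None and self.blocks[-1][1] > reference_length:
            raise FormatError(
                f"EST {self.est_id!r} extends past the end of reference "
                f"{self.reference_id!r} ({self.blocks[-1][1]} > {reference_length})"
            )
        return self

    @property
    def footprint(self) -> tuple[int, int]:
        """Half-open span from first block start to last block end."""
        return self.blocks[0][0], self.blocks[-1][1]


@dataclass(frozen=True)
class MRESite:
    """A microRNA recognition element placed on a reference transcript.

    ``start``/``end`` are 0-based half-open.  ``repressive_ratio`` is the
    percent reduction of the target protein's output attributable to the
    microRNA at this site (0-100 scale).  ``supported_tissues_*`` carry
    optional annotations of tissues in which the site was previously found
    splicing-regulated (by histology stratum).
    """

    site_id: str
    reference_id: str
    mirna_id: str
    start: int
    end: int
    site_sequence: str | None = None
    repressive_ratio: float | None = None
    validation: str = "unknown"
    supported_tissues_cancer: tuple[str, ...] = ()
    supported_tissues_normal: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0 or self.end - self.start < 1:
            raise FormatError(
                f"MRE {self.site_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.site_sequence is not None and len(self.site_sequence) != self.length:
            raise FormatError(
                f"MRE {self.site_id!r}: sequence length "
                f"{len(self.site_sequence)} does not match interval length "
                f"{self.length}"
            )
        if self.repressive_ratio is not None and not (
            0 <= self.repressive_ratio <= 100
        ):
            raise FormatError(
                f"MRE {self.site_id!r}: repressive ratio "
                f"{self.repressive_ratio} outside [0, 100]"
            )
        if self.validation not in _VALIDATION_VALUES:
            raise FormatError(
                f"MRE {self.site_id!r}: validation must be one of "
                f"{sorted(_VALIDATION_VALUES)}, got {self.validation!r}"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ProteinChangeRecord:
    """A protein's measured expression change plus set-membership flags.

    ``log2_fold_change`` is the SILAC-style log2 expression ratio after
    microRNA transfection; the flags record whether the transcript carries a
    seed match, is a predicted target, and is alternatively spliced.
    """

    gene_symbol: str
    log2_fold_change: float
    has_seed: bool
    predicted_target: bool
    splicing_regulated: bool

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.log2_fold_change):
            raise FormatError(
                f"protein {self.gene_symbol!r}: non-finite log2 fold change"
            )


@dataclass
class ESTDataset:
    """The joined EST evidence bundle consumed by the enrichment stages."""

    alignments: list[ESTAlignment]
    libraries: list[LibraryAnnotation]
    references: dict[str, ReferenceSequence] | None = None
    _by_ref: dict[str, list[ESTAlignment]] | None = field(
        default=None, repr=False, compare=False
    )

    def alignments_for(self, reference_id: str) -> list[ESTAlignment]:
        if self._by_ref is None:
            grouped: dict[str, list[ESTAlignment]] = {}
            for aln in self.alignments:
                grouped.setdefault(aln.reference_id, []).append(aln)
            self._by_ref = grouped
        return self._by_ref.get(reference_id, [])

    @property
    def library_by_id(self) -> dict[str, LibraryAnnotation]:
        return {lib.library_id: lib for lib in self.libraries}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read reference transcripts from FASTA, normalizing to DNA upper-case."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: list[ReferenceSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), context=f"record {rec.id!r}")
        out.append(ReferenceSequence(id=rec.id, sequence=seq))
    return out


def write_fasta(references: Iterable[ReferenceSequence], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for ref in references:
            fh.write(f">{ref.id}\n")
            for i in range(0, ref.length, width):
                fh.write(ref.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED12 EST alignments
# ---------------------------------------------------------------------------


def read_est_bed12(
    path: str | Path, library_map: Mapping[str, str]
) -> list[ESTAlignment]:
    """Read spliced EST alignments from BED12 and join each to its library.

    The BED name field is the EST id; *library_map* maps est_id to
    library_id.  Blocks are reconstructed as 0-based half-open intervals in
    reference coordinates and validated (sorted, gap-separated, consistent
    with blockCount/chromEnd).
    """
    alignments: list[ESTAlignment] = []
    unmapped: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}"
                )
            chrom, chrom_start, chrom_end, name = fields[0], fields[1], fields[2], fields[3]
            try:
                start = int(chrom_start)
                end = int(chrom_end)
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != block_count or len(starts) != block_count:
                raise FormatError(
                    f"{path}:{lineno}: blockCount={block_count} inconsistent "
                    f"with {len(sizes)} sizes / {len(starts)} starts"
                )
            if starts[0] != 0:
                raise FormatError(
                    f"{path}:{lineno}: first blockStart must be 0, got {starts[0]}"
                )
            for i in range(1, block_count):
                if starts[i] <= starts[i - 1] + sizes[i - 1]:
                    raise FormatError(
                        f"{path}:{lineno}: blocks must be ascending with "
                        f"positive gaps (block {i})"
                    )
            if any(sz <= 0 for sz in sizes):
                raise FormatError(f"{path}:{lineno}: non-positive blockSize")
            if start + starts[-1] + sizes[-1] != end:
                raise FormatError(
                    f"{path}:{lineno}: last block does not end at chromEnd"
                )
            lib = library_map.get(name)
            if lib is None:
                unmapped.append(name)
                continue
            blocks = tuple(
                (start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)
            )
            alignments.append(
                ESTAlignment(
                    est_id=name, reference_id=chrom, library_id=lib, blocks=blocks
                ).validate()
            )
    if unmapped:
        raise FormatError(
            f"{path}: {len(unmapped)} EST ids missing from the library map: "
            f"{sorted(set(unmapped))[:20]}"
        )
    return alignments


def write_est_bed12(alignments: Iterable[ESTAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for aln in alignments:
            start, end = aln.footprint
            sizes = ",".join(str(e - s) for s, e in aln.blocks)
            rel = ",".join(str(s - start) for s, _ in aln.blocks)
            fh.write(
                "\t".join(
                    [
                        aln.reference_id,
                        str(start),
                        str(end),
                        aln.est_id,
                        "0",
                        "+",
                        str(start),
                        str(end),
                        "0",
                        str(len(aln.blocks)),
                        sizes,
                        rel,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    df = df.fillna("")  # rows with omitted trailing optional columns
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def read_library_table(path: str | Path) -> list[LibraryAnnotation]:
    """Read library annotations (library_id, tissue, histology)."""
    df = _read_tsv(path, ["library_id", "tissue", "histology"])
    if df["library_id"].duplicated().any():
        dups = sorted(df.loc[df["library_id"].duplicated(), "library_id"])
        raise FormatError(f"{path}: duplicate library ids {dups}")
    return [
        LibraryAnnotation(row.library_id, row.tissue, row.histology)
        for row in df.itertuples()
    ]


def write_library_table(libraries: Iterable[LibraryAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("library_id\ttissue\thistology\n")
        for lib in libraries:
            fh.write(f"{lib.library_id}\t{lib.tissue}\t{lib.histology}\n")


def read_est2lib(path: str | Path) -> dict[str, str]:
    """Read the est_id -> library_id mapping table."""
    df = _read_tsv(path, ["est_id", "library_id"])
    if df["est_id"].duplicated().any():
        dups = sorted(df.loc[df["est_id"].duplicated(), "est_id"])
        raise FormatError(f"{path}: duplicate EST ids {dups}")
    return dict(zip(df["est_id"], df["library_id"]))


def write_est2lib(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("est_id\tlibrary_id\n")
        for est_id, lib in mapping.items():
            fh.write(f"{est_id}\t{lib}\n")


def _split_tissues(cell: str) -> tuple[str, ...]:
    return tuple(t.strip() for t in cell.split(";") if t.strip())


def read_mre_table(path: str | Path) -> list[MRESite]:
    """Read an MRE catalog.

    Required columns: ``gene_id``, ``mirna_id``, ``start``, ``end`` (1-based
    inclusive).  Optional: ``site_id``, ``sequence``, ``repressive_ratio``
    (percent), ``validation`` (true/false/random/unknown),
    ``supported_cancer`` / ``supported_normal`` (semicolon-separated tissue
    lists).  Coordinates are converted to 0-based half-open on read.
    """
    df = _read_tsv(path, ["gene_id", "mirna_id", "start", "end"])
    sites: list[MRESite] = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            start1 = int(row["start"])
            end1 = int(row["end"])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        if start1 < 1:
            raise FormatError(f"{path}:{lineno}: start must be >= 1")
        if end1 < start1:
            raise FormatError(
                f"{path}:{lineno}: end ({end1}) before start ({start1})"
            )
        ratio: float | None = None
        if "repressive_ratio" in df.columns and row["repressive_ratio"] != "":
            try:
                ratio = float(row["repressive_ratio"])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric repressive_ratio"
                ) from exc
            if not 0 <= ratio <= 100:
                raise FormatError(
                    f"{path}:{lineno}: repressive_ratio {ratio} outside [0, 100]"
                )
        seq: str | None = None
        if "sequence" in df.columns and row["sequence"] != "":
            seq = normalize_sequence(row["sequence"], context=f"{path}:{lineno}")
        validation = "unknown"
        if "validation" in df.columns and row["validation"] != "":
            validation = row["validation"]
            if validation not in _VALIDATION_VALUES:
                raise FormatError(
                    f"{path}:{lineno}: validation must be one of "
                    f"{sorted(_VALIDATION_VALUES)}"
                )
        if "site_id" in df.columns and row["site_id"] != "":
            site_id = row["site_id"]
        else:
            site_id = f"{row['gene_id']}:{row['mirna_id']}:{start1}-{end1}"
        cancer = (
            _split_tissues(row["supported_cancer"])
            if "supported_cancer" in df.columns
            else ()
        )
        normal = (
            _split_tissues(row["supported_normal"])
            if "supported_normal" in df.columns
            else ()
        )
        try:
            sites.append(
                MRESite(
                    site_id=site_id,
                    reference_id=row["gene_id"],
                    mirna_id=row["mirna_id"],
                    start=start1 - 1,
                    end=end1,
                    site_sequence=seq,
                    repressive_ratio=ratio,
                    validation=validation,
                    supported_tissues_cancer=cancer,
                    supported_tissues_normal=normal,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return sites


def _float_str(x: float) -> str:
    # shortest representation that round-trips exactly
    s = repr(float(x))
    return s


def write_mre_table(sites: Iterable[MRESite], path: str | Path) -> None:
    cols = [
        "gene_id",
        "mirna_id",
        "start",
        "end",
        "site_id",
        "sequence",
        "repressive_ratio",
        "validation",
        "supported_cancer",
        "supported_normal",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in sites:
            fh.write(
                "\t".join(
                    [
                        s.reference_id,
                        s.mirna_id,
                        str(s.start + 1),
                        str(s.end),
                        s.site_id,
                        s.site_sequence or "",
                        "" if s.repressive_ratio is None else _float_str(s.repressive_ratio),
                        s.validation,
                        ";".join(s.supported_tissues_cancer),
                        ";".join(s.supported_tissues_normal),
                    ]
                )
                + "\n"
            )


def read_protein_table(path: str | Path) -> list[ProteinChangeRecord]:
    """Read the protein differential-expression table.

    Columns: gene_symbol, log2fc, has_seed, predicted_target,
    splicing_regulated (flags 0/1).  Duplicate symbols are rejected.
    """
    df = _read_tsv(
        path,
        ["gene_symbol", "log2fc", "has_seed", "predicted_target", "splicing_regulated"],
    )
    if df["gene_symbol"].duplicated().any():
        dups = sorted(df.loc[df["gene_symbol"].duplicated(), "gene_symbol"])
        raise FormatError(f"{path}: duplicate gene symbols {dups}")
    records: list[ProteinChangeRecord] = []
    for idx, row in df.iterrows():
        lineno = idx + 2
        try:
            lfc = float(row["log2fc"])
        except ValueError as exc:
            raise FormatError(
                f"{path}:{lineno}: non-numeric log2fc {row['log2fc']!r}"
            ) from exc
        flags = {}
        for col in ("has_seed", "predicted_target", "splicing_regulated"):
            if row[col] not in {"0", "1"}:
                raise FormatError(
                    f"{path}:{lineno}: flag {col} must be 0 or 1, got {row[col]!r}"
                )
            flags[col] = row[col] == "1"
        try:
            records.append(
                ProteinChangeRecord(
                    gene_symbol=row["gene_symbol"], log2_fold_change=lfc, **flags
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_protein_table(records: Iterable[ProteinChangeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_symbol\tlog2fc\thas_seed\tpredicted_target\tsplicing_regulated\n")
        for r in records:
            fh.write(
                f"{r.gene_symbol}\t{_float_str(r.log2_fold_change)}\t"
                f"{int(r.has_seed)}\t{int(r.predicted_target)}\t"
                f"{int(r.splicing_regulated)}\n"
            )


# ---------------------------------------------------------------------------
# generic result output
# ---------------------------------------------------------------------------


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, ".6g")  # >= 4 significant digits for P-values
    return str(value)


def write_results_tsv(records, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a homogeneous result table as TSV with a deterministic column order.

    *records* may be a pandas DataFrame, or a sequence of dataclasses /
    mappings.  Floats are rendered with six significant digits; booleans as
    0/1.  Callers are responsible for presenting coordinates 1-based.
    """
    if isinstance(records, pd.DataFrame):
        cols = list(records.columns) if columns is None else list(columns)
        rows = records[cols].to_dict("records")
    else:
        records = list(records)
        if columns is not None:
            cols = list(columns)
        elif records and dataclasses.is_dataclass(records[0]):
            cols = [f.name for f in dataclasses.fields(records[0])]
        elif records:
            cols = list(records[0].keys())
        else:
            raise FormatError(
                "cannot infer columns for an empty table; pass columns="
            )
        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records
        ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_format_cell(row.get(c)) for c in cols) + "\n")
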