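"""Readers and writers for the pipeline's on-disk artifacts.

Coordinate conventions
----------------------
* Segment TSV input/output is **1-based inclusive** (the convention of
  array-based CNV callers).
* Everything in memory, and all BED output, is **0-based half-open**.
* Gene annotation tables are read as 0-based half-open (refFlat-style
  ``txStart``/``txEnd``).

All tabular formats are plain tab-delimited text with a header line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class ParseError(ValueError):
    """A malformed row in an input file; message names the line number."""


class ValidationError(ValueError):
    """A well-formed row whose values violate a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

#: Copy-number states a caller may emit. 2 (normal diploid) is never a call.
CALLABLE_STATES = frozenset({0, 1, 3, 4})

SEGMENT_COLUMNS = (
    "sample_id",
    "chrom",
    "start",
    "end",
    "cn_state",
    "n_probes",
    "max_gap",
    "lod",
    "confidence",
)


@dataclass(frozen=True)
class SegmentRecord:
    """One CNV call for one sample.

    ``start``/``end`` are 0-based half-open. ``cn_state`` is the diploid
    copy number in {0, 1, 3, 4} (2 = normal is never emitted as a call).
    ``max_gap`` is the largest inter-probe distance within the segment in bp.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    cn_state: int
    n_probes: int
    max_gap: int
    lod: float
    confidence: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"segment end ({self.end}) must exceed start ({self.start})"
            )
        if self.cn_state not in CALLABLE_STATES:
            raise ValidationError(
                f"cn_state must be one of {sorted(CALLABLE_STATES)} "
                f"(2 = normal copy is never a call), got {self.cn_state}"
            )
        if self.n_probes < 1:
            raise ValidationError(f"n_probes must be >= 1, got {self.n_probes}")
        if self.confidence < 0:
            raise ValidationError(
                f"confidence must be non-negative, got {self.confidence}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    population: str
    role: str  # admixed | ancestral_indian | ancestral_african | other

    ROLES = ("admixed", "ancestral_indian", "ancestral_african", "other")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise ValidationError(
                f"unknown role {self.role!r}; expected one of {self.ROLES}"
            )


@dataclass
class SampleManifest:
    """Sample -> (population, role) mapping for the cohort."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValidationError(f"duplicate sample_ids in manifest: {dupes}")

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.population, None)
        return list(seen)

    def population_of(self, sample_id: str) -> str:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e.population
        raise KeyError(f"sample {sample_id!r} not in manifest")

    def samples_in(self, population: str) -> list[str]:
        return [e.sample_id for e in self.entries if e.population == population]

    def populations_with_role(self, role: str) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            if e.role == role:
                seen.setdefault(e.population, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GenomeTable:
    """Chromosome lengths plus an autosome flag per chromosome."""

    lengths: dict[str, int]
    autosomes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValidationError(f"chromosome {chrom} has length {length} <= 0")
        unknown = self.autosomes - set(self.lengths)
        if unknown:
            raise ValidationError(f"autosome flags for unknown chromosomes: {unknown}")
        if not self.autosomes:
            raise ValidationError("autosome set must be non-empty")

    def is_autosome(self, chrom: str) -> bool:
        return chrom in self.autosomes

    @property
    def autosomal_length(self) -> int:
        return sum(self.lengths[c] for c in self.autosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True)
class GeneModel:
    """One gene interval (its longest transcript), 0-based half-open."""

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start "
                f"({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneSetCollection:
    """Named gene sets, each with a category label (e.g. a GMT file)."""

    sets: dict[str, frozenset[str]]
    categories: dict[str, str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) < 1:
                raise ValidationError(f"gene set {name!r} is empty")
        missing = set(self.sets) ^ set(self.categories)
        if missing:
            raise ValidationError(f"sets without categories (or vice versa): {missing}")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Segment TSV
# ---------------------------------------------------------------------------

def _split_header(line: str, expected: Sequence[str], path: str | Path) -> list[int]:
    cols = line.rstrip("\n").split("\t")
    try:
        return [cols.index(name) for name in expected]
    except ValueError as exc:
        raise ParseError(
            f"{path}: header must name columns {list(expected)}, got {cols}"
        ) from exc


def read_segments(path: str | Path, genome: GenomeTable) -> list[SegmentRecord]:
    """Read a caller-style segment TSV.

    File coordinates are 1-based inclusive and converted to the internal
    0-based half-open convention on read. The ``confidence`` column is
    optional (default 0.0). Records are returned in file order.
    """
    path = Path(path)
    records: list[SegmentRecord] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file")
        cols = header.rstrip("\n").split("\t")
        required = SEGMENT_COLUMNS[:-1]
        has_conf = "confidence" in cols
        idx = _split_header(header, required, path)
        conf_idx = cols.index("confidence") if has_conf else None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                sample_id = parts[idx[0]]
                chrom = parts[idx[1]]
                start1 = int(parts[idx[2]])
                end1 = int(parts[idx[3]])
                cn_state = int(parts[idx[4]])
                n_probes = int(parts[idx[5]])
                max_gap = int(parts[idx[6]])
                lod = float(parts[idx[7]])
                confidence = float(parts[conf_idx]) if conf_idx is not None else 0.0
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            if chrom not in genome:
                raise ValidationError(
                    f"{path}: line {lineno}: unknown chromosome {chrom!r}"
                )
            if not 0 <= cn_state <= 4:
                raise ValidationError(
                    f"{path}: line {lineno}: cn_state {cn_state} outside 0-4"
                )
            # 1-based inclusive -> 0-based half-open: start-1, end unchanged.
            rec = SegmentRecord(
                sample_id=sample_id,
                chrom=chrom,
                start=start1 - 1,
                end=end1,
                cn_state=cn_state,
                n_probes=n_probes,
                max_gap=max_gap,
                lod=lod,
                confidence=confidence,
            )
            if rec.end > genome.lengths[chrom]:
                raise ValidationError(
                    f"{path}: line {lineno}: segment end {rec.end} exceeds "
                    f"{chrom} length {genome.lengths[chrom]}"
                )
            records.append(rec)
    return records


def write_segments(records: Iterable[SegmentRecord], path: str | Path) -> None:
    """Write segments as 1-based inclusive TSV (inverse of :func:`read_segments`)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.chrom}\t{r.start + 1}\t{r.end}\t{r.cn_state}\t"
                f"{r.n_probes}\t{r.max_gap}\t{r.lod!r}\t{r.confidence!r}\n"
            )


# ---------------------------------------------------------------------------
# Manifest / genome TSV
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> SampleManifest:
    path = Path(path)
    entries: list[ManifestEntry] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file")
        idx = _split_header(header, ("sample_id", "population", "role"), path)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                entries.append(
                    ManifestEntry(parts[idx[0]], parts[idx[1]], parts[idx[2]])
                )
            except IndexError as exc:
                raise ParseError(f"{path}: malformed row at line {lineno}") from exc
    return SampleManifest(entries)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tpopulation\trole\n")
        for e in manifest.entries:
            fh.write(f"{e.sample_id}\t{e.population}\t{e.role}\n")


def read_genome_table(path: str | Path) -> GenomeTable:
    path = Path(path)
    lengths: dict[str, int] = {}
    autosomes: set[str] = set()
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file")
        idx = _split_header(header, ("chrom", "length", "is_autosome"), path)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                chrom = parts[idx[0]]
                lengths[chrom] = int(parts[idx[1]])
                if parts[idx[2]].strip().lower() in ("1", "true", "yes"):
                    autosomes.add(chrom)
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: malformed row at line {lineno}") from exc
    return GenomeTable(lengths, autosomes)


def write_genome_table(genome: GenomeTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("chrom\tlength\tis_autosome\n")
        for chrom, length in genome.lengths.items():
            fh.write(f"{chrom}\t{length}\t{int(genome.is_autosome(chrom))}\n")


# ---------------------------------------------------------------------------
# Gene annotation (refFlat-like) and GMT gene sets
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-like transcript table, one interval per gene.

    When a gene has multiple transcripts, the longest (end - start) is kept;
    ties break to the smaller start, then lexicographic transcript_id.
    Coordinates in the file are 0-based half-open (refFlat ``txStart/txEnd``).
    """
    path = Path(path)
    transcripts: dict[str, list[GeneModel]] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty gene table")
        idx = _split_header(
            header,
            ("gene_id", "transcript_id", "chrom", "strand", "start", "end"),
            path,
        )
        n_rows = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                model = GeneModel(
                    gene_id=parts[idx[0]],
                    transcript_id=parts[idx[1]],
                    chrom=parts[idx[2]],
                    strand=parts[idx[3]],
                    start=int(parts[idx[4]]),
                    end=int(parts[idx[5]]),
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            transcripts.setdefault(model.gene_id, []).append(model)
            n_rows += 1
    if n_rows == 0:
        raise ParseError(f"{path}: gene table has a header but no rows")

    genes: list[GeneModel] = []
    for gene_id, models in transcripts.items():
        chroms = {m.chrom for m in models}
        if len(chroms) > 1:
            raise ValidationError(
                f"gene {gene_id} has transcripts on multiple chromosomes: "
                f"{sorted(chroms)}"
            )
        best = min(models, key=lambda m: (-m.length, m.start, m.transcript_id))
        genes.append(best)
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\ttranscript_id\tchrom\tstrand\tstart\tend\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.transcript_id}\t{g.chrom}\t{g.strand}\t"
                f"{g.start}\t{g.end}\n"
            )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, category/description, members...)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    categories: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT rows need name, category and "
                    f">=1 gene"
                )
            name, category, members = parts[0], parts[1], parts[2:]
            if name in sets:
                raise ValidationError(f"{path}: duplicate gene set name {name!r}")
            sets[name] = frozenset(m for m in members if m)
            categories[name] = category
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, categories)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in collection.sets:
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.categories[name]}\t{members}\n")


# ---------------------------------------------------------------------------
# CNVR BED
# ---------------------------------------------------------------------------

BED_HEADER = (
    "#chrom\tstart\tend\tname\tclass\tdel_freqs\tdup_freqs"
)


def write_cnvr_bed(cnvr_set, path: str | Path) -> None:
    """Write a CNVRSet as BED4+ (0-based half-open), sorted by (chrom, start).

    Extended columns: region class (del|dup|gain_loss) and per-population
    deletion/duplication frequencies as ``pop:freq`` lists. Writing an empty
    set is an error by contract (a silent empty file would be mistaken for a
    successful run with no regions).
    """
    if len(cnvr_set.cnvrs) == 0:
        raise ValidationError("refusing to write an empty CNVRSet")
    path = Path(path)

    def freq_col(row: Mapping[str, float]) -> str:
        return ",".join(
            f"{pop}:{float(row[pop])!r}" for pop in cnvr_set.populations
        )

    ordered = sorted(cnvr_set.cnvrs, key=lambda c: (c.chrom, c.start, c.end))
    with path.open("w") as fh:
        fh.write(BED_HEADER + "\n")
        for cnvr in ordered:
            dels = freq_col(cnvr_set.del_freq.loc[cnvr.id])
            dups = freq_col(cnvr_set.dup_freq.loc[cnvr.id])
            fh.write(
                f"{cnvr.chrom}\t{cnvr.start}\t{cnvr.end}\t{cnvr.id}\t"
                f"{cnvr.cnvr_class}\t{dels}\t{dups}\n"
            )


def read_cnvr_bed(path: str | Path) -> list[dict]:
    """Read back :func:`write_cnvr_bed` output as plain dict rows."""
    path = Path(path)
    rows: list[dict] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#chrom"):
            raise ParseError(f"{path}: missing CNVR BED header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ParseError(f"{path}: line {lineno}: expected 7 columns")
            def parse_freqs(cell: str) -> dict[str, float]:
                out: dict[str, float] = {}
                for item in cell.split(","):
                    pop, _, val = item.partition(":")
                    out[pop] = float(val)
                return out
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "name": parts[3],
                    "class": parts[4],
                    "del_freqs": parse_freqs(parts[5]),
                    "dup_freqs": parse_freqs(parts[6]),
                }
            )
    return rows
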