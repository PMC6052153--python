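"""Sequence ingest and bookkeeping: FASTA/GenBank reading, coordinate
region and gene extraction, haplotype collapsing, and multigene
concatenation building.

All coordinates are 1-based inclusive (GenBank convention). Ambiguity
codes are retained on ingest; their handling is delegated to the
divergence module (pairwise deletion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq, UndefinedSequenceError

from .align import Scoring, DEFAULT_SCORING, progressive_align

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN-")


class SequenceFormatError(ValueError):
    """Raised on malformed sequence input."""


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene on a mitogenome record (1-based inclusive)."""

    name: str
    start: int
    end: int
    strand: str  # "+" | "-"


@dataclass
class SequenceRecord:
    """A labelled nucleotide sequence, optionally with gene features."""

    id: str
    residues: str
    group: str | None = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise SequenceFormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise SequenceFormatError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        for f in self.features:
            if not (1 <= f.start <= f.end <= len(self.residues)):
                raise SequenceFormatError(
                    f"record {self.id!r}: feature {f.name} coordinates "
                    f"{f.start}-{f.end} outside 1-{len(self.residues)}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Haplotype:
    """One collapsed haplotype: representative residues plus members."""

    hap_id: str
    residues: str
    member_ids: list[str]

    @property
    def multiplicity(self) -> int:
        return len(self.member_ids)


@dataclass
class HaplotypeSet:
    """Unique sequences after collapsing; the sum of multiplicities
    equals the number of input sequences."""

    haplotypes: list[Haplotype]
    collapse_mode: str

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def total_members(self) -> int:
        return sum(h.multiplicity for h in self.haplotypes)


@dataclass
class Concatenation:
    """Per-sample concatenated aligned genes with recorded per-gene
    boundaries (half-open offsets into the concatenation)."""

    sequences: dict[str, str]
    gene_order: list[str]
    boundaries: list[tuple[str, int, int]]
    total_length: int


def _header_lines(path: str | Path) -> dict[int, int]:
    """Map record index -> 1-based line number of its FASTA header."""
    out: dict[int, int] = {}
    idx = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                out[idx] = lineno
                idx += 1
    return out


def _parse_group(description: str) -> str | None:
    for token in description.split():
        if token.startswith("group="):
            return token[len("group=") :]
    return None


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The header token before the first whitespace becomes the id; a
    ``group=<label>`` key in the description, if present, is parsed into
    ``group``. Raises :class:`SequenceFormatError` (naming record id and
    header line number) on empty files, duplicate ids or non-IUPAC
    characters.
    """
    lines = _header_lines(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        lineno = lines.get(idx, -1)
        if rec.id in seen:
            raise SequenceFormatError(
                f"duplicate id {rec.id!r} at line {lineno}"
            )
        seen.add(rec.id)
        try:
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=str(rec.seq),
                    group=_parse_group(rec.description),
                )
            )
        except SequenceFormatError as exc:
            raise SequenceFormatError(f"{exc} (line {lineno})") from exc
    if not records:
        raise SequenceFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA (60-column wrap; ``group=`` echoed in the
    description when present)."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.group is not None:
                header += f" group={rec.group}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


_GENE_FEATURE_TYPES = ("gene", "CDS", "rRNA")


def read_genbank_features(path: str | Path) -> list[SequenceRecord]:
    """Read GenBank flat-file records, capturing gene/CDS/rRNA features
    with 1-based inclusive coordinates and strand; sequences are
    upper-cased. A record without an ORIGIN sequence is an error."""
    records: list[SequenceRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise SequenceFormatError(f"{path}: malformed GenBank file: {exc}") from exc
    for rec in parsed:
        try:
            residues = str(rec.seq).upper()
        except UndefinedSequenceError as exc:
            raise SequenceFormatError(
                f"record {rec.id!r}: no ORIGIN sequence"
            ) from exc
        if not residues:
            raise SequenceFormatError(f"record {rec.id!r}: no ORIGIN sequence")
        feats: list[GeneFeature] = []
        seen_spans: set[tuple[str, int, int]] = set()
        for f in rec.features:
            if f.type not in _GENE_FEATURE_TYPES:
                continue
            quals = f.qualifiers
            name = (quals.get("gene") or quals.get("product") or ["?"])[0]
            start = int(f.location.start) + 1
            end = int(f.location.end)
            strand = "-" if f.location.strand == -1 else "+"
            key = (name, start, end)
            if key in seen_spans:
                continue  # gene + CDS pair annotating the same span
            seen_spans.add(key)
            feats.append(GeneFeature(name, start, end, strand))
        records.append(SequenceRecord(id=rec.id, residues=residues, features=feats))
    if not records:
        raise SequenceFormatError(f"{path}: no GenBank records found")
    return records


def extract_region(record: SequenceRecord, start: int, end: int) -> SequenceRecord:
    """Extract the 1-based inclusive region [start, end]; the returned
    id is suffixed with the coordinate range."""
    if not (1 <= start <= end <= len(record)):
        raise SequenceFormatError(
            f"region {start}-{end} invalid for record {record.id!r} "
            f"of length {len(record)}"
        )
    return SequenceRecord(
        id=f"{record.id}:{start}-{end}",
        residues=record.residues[start - 1 : end],
        group=record.group,
    )


def extract_gene(record: SequenceRecord, gene: str) -> SequenceRecord:
    """Extract a named annotated gene, reverse-complementing
    minus-strand features so the result reads 5'->3'."""
    for f in record.features:
        if f.name == gene:
            seq = record.residues[f.start - 1 : f.end]
            if f.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            return SequenceRecord(
                id=f"{record.id}|{gene}", residues=seq, group=record.group
            )
    raise SequenceFormatError(f"record {record.id!r}: no feature named {gene!r}")


def collapse_haplotypes(
    records: list[SequenceRecord], mode: str = "exact"
) -> HaplotypeSet:
    """Collapse sequences into unique haplotypes.

    ``exact`` merges only full-string-identical sequences, so identical
    sequences of different lengths remain distinct haplotypes (the
    behaviour of the commonly used collapser, which inflates counts for
    datasets deposited with unequal lengths). ``length-aware``
    additionally merges a sequence that is an exact substring of a
    longer one into the longer haplotype.
    """
    if not records:
        raise SequenceFormatError("no records to collapse")
    if mode not in ("exact", "length-aware"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    groups: dict[str, list[str]] = {}
    for rec in records:
        groups.setdefault(rec.residues, []).append(rec.id)
    reps = list(groups)
    if mode == "length-aware":
        reps.sort(key=lambda s: (-len(s), s))
        merged: list[str] = []
        absorb: dict[str, str] = {}
        for s in reps:
            host = next((r for r in merged if s in r), None)
            if host is None:
                merged.append(s)
                absorb[s] = s
            else:
                absorb[s] = host
        members: dict[str, list[str]] = {r: [] for r in merged}
        for s, ids in groups.items():
            members[absorb[s]].extend(ids)
        reps = merged
        groups = members
    haplotypes = [
        Haplotype(hap_id=f"Hap{i + 1}", residues=rep, member_ids=list(groups[rep]))
        for i, rep in enumerate(reps)
    ]
    return HaplotypeSet(haplotypes=haplotypes, collapse_mode=mode)


def write_haplotype_table(hapset: HaplotypeSet, path: str | Path) -> None:
    """Write a TSV of haplotype id, multiplicity and member ids
    (semicolon-separated)."""
    with open(path, "w") as fh:
        fh.write("haplotype\tmultiplicity\tmembers\n")
        for h in hapset.haplotypes:
            fh.write(f"{h.hap_id}\t{h.multiplicity}\t{';'.join(h.member_ids)}\n")


def build_concatenation(
    mitogenomes: list[SequenceRecord],
    gene_order: list[str],
    scoring: Scoring = DEFAULT_SCORING,
) -> Concatenation:
    """Build a multigene concatenation across annotated mitogenomes.

    Each gene is extracted (minus-strand genes reverse-complemented to
    5'->3'), copies of unequal length are aligned pairwise-progressively
    and columns containing gaps are trimmed so every sample contributes
    the same flush-trimmed gene length, then genes are joined in
    ``gene_order`` with per-gene boundaries recorded.
    """
    if not mitogenomes:
        raise SequenceFormatError("no mitogenomes supplied")
    parts: dict[str, list[str]] = {m.id: [] for m in mitogenomes}
    boundaries: list[tuple[str, int, int]] = []
    offset = 0
    for gene in gene_order:
        copies = []
        for m in mitogenomes:
            try:
                copies.append(extract_gene(m, gene).residues)
            except SequenceFormatError:
                raise SequenceFormatError(
                    f"sample {m.id!r} is missing gene {gene!r}"
                ) from None
        if len(set(map(len, copies))) > 1:
            rows = progressive_align(copies, scoring)
            keep = [
                i
                for i in range(len(rows[0]))
                if all(r[i] != "-" for r in rows)
            ]
            copies = ["".join(r[i] for i in keep) for r in rows]
        glen = len(copies[0])
        for m, seq in zip(mitogenomes, copies):
            parts[m.id].append(seq)
        boundaries.append((gene, offset, offset + glen))
        offset += glen
    return Concatenation(
        sequences={mid: "".join(chunks) for mid, chunks in parts.items()},
        gene_order=list(gene_order),
        boundaries=boundaries,
        total_length=offset,
    )
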