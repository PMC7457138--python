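"""Sequence and annotation I/O plus core sequence operations.

Containers for annotated genomes with 1-based inclusive, stranded
coordinates (the GFF3 convention), readers and writers for FASTA, GFF3 and
NCBI assembly feature tables, the bacterial genetic code (NCBI translation
table 11), and protein substitution matrices in the NCBI/EMBOSS text
layout.  Everything downstream (ORF scanning, alignment, simulation) builds
on these primitives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable as _BioCodonTable

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFeature",
    "Genome",
    "CodonTable",
    "SubstitutionMatrix",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_features",
    "write_gff3",
    "reverse_complement",
    "translate",
    "read_matrix",
    "write_matrix",
    "blosum62",
    "to_zero_based",
    "to_one_based",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_NT = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


# ---------------------------------------------------------------------------
# coordinate conventions
#
# All interfaces (files, reports, dataclasses) use 1-based inclusive
# coordinates.  Python slicing needs 0-based half-open; these two helpers are
# the only place the conversion happens.
# ---------------------------------------------------------------------------

def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive [start, end] -> 0-based half-open [start0, end0)."""
    return start - 1, end


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open [start0, end0) -> 1-based inclusive [start, end]."""
    return start0 + 1, end0


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on a genome contig.

    Coordinates are 1-based inclusive on the forward strand of the contig;
    ``strand`` gives the coding strand.  ``kind`` is one of ``CDS``,
    ``rRNA``, ``tRNA`` or ``other``.
    """

    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"feature {self.feature_id}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.feature_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def frame_ok(self) -> bool:
        """True when the span length is divisible by 3 (a clean CDS)."""
        return self.length % 3 == 0


@dataclass
class Genome:
    """A genome: contig sequences plus annotated features.

    Invariants enforced at construction: contig sequences uppercase over
    A/C/G/T/N, and every feature lies within its contig.  CDS features whose
    span is not divisible by 3 are kept (annotation glitches should not
    abort a genome-wide scan) but logged.
    """

    genome_id: str
    contigs: dict[str, str]
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            bad = set(seq) - _VALID_NT
            if bad:
                raise ValueError(
                    f"contig {cid}: invalid characters {sorted(bad)!r}"
                )
        for f in self.features:
            if f.contig_id not in self.contigs:
                raise ValueError(
                    f"feature {f.feature_id}: unknown contig {f.contig_id}"
                )
            clen = len(self.contigs[f.contig_id])
            if f.end > clen:
                raise ValueError(
                    f"feature {f.feature_id}: end {f.end} exceeds contig "
                    f"{f.contig_id} length {clen}"
                )
            if f.kind == "CDS" and not f.frame_ok:
                logger.warning(
                    "genome %s: CDS %s span length %d not divisible by 3",
                    self.genome_id, f.feature_id, f.length,
                )

    def feature_seq(self, feature: GeneFeature) -> str:
        """Coding-strand sequence of a feature (5'->3')."""
        s0, e0 = to_zero_based(feature.start, feature.end)
        seq = self.contigs[feature.contig_id][s0:e0]
        return reverse_complement(seq) if feature.strand == "-" else seq

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{id: sequence}``.

    Sequences are uppercased with U converted to T; record ids are the first
    whitespace-delimited token of the header.  A sequence line before any
    header is a parse error naming the line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
        else:
            logger.warning("%s: empty FASTA file", path)
            return {}
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate sequence id {rec.id}")
        out[rec.id] = str(rec.seq).upper().replace("U", "T")
    return out


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# feature annotations: GFF3 and NCBI assembly feature tables
# ---------------------------------------------------------------------------

_FT_KINDS = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}


def _norm_kind(raw: str) -> str:
    return _FT_KINDS.get(raw, "other")


def read_features(path: str | Path, dialect: str = "gff3") -> list[GeneFeature]:
    """Read gene features from GFF3 or an NCBI ``*_feature_table.txt``.

    Coordinates are kept 1-based inclusive.  Feature types outside
    CDS/rRNA/tRNA are retained with ``kind='other'``.  Records whose start
    exceeds their end are rejected with a warning rather than an error.
    """
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "ncbi_feature_table":
        return _read_feature_table(path)
    raise ValueError(f"unknown feature dialect: {dialect!r}")


def _gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def _read_gff3(path: str | Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    n_anon = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                logger.warning("%s:%d: start > end, record skipped", path, lineno)
                continue
            if strand not in {"+", "-"}:
                logger.warning("%s:%d: unstranded feature skipped", path, lineno)
                continue
            fid = _gff3_attr(attrs, "ID")
            if fid is None:
                n_anon += 1
                fid = f"feature{n_anon}"
            feats.append(
                GeneFeature(fid, contig, start_i, end_i, strand, _norm_kind(ftype))
            )
    return feats


def _read_feature_table(path: str | Path) -> list[GeneFeature]:
    """NCBI assembly ``*_feature_table.txt``: tab-separated with a header row
    (columns include feature, genomic_accession, start, end, strand,
    locus_tag)."""
    feats: list[GeneFeature] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").lstrip()
        cols = header.split("\t")
        try:
            idx = {k: cols.index(k) for k in
                   ("feature", "genomic_accession", "start", "end", "strand")}
        except ValueError as exc:
            raise ParseError(f"{path}: missing feature-table column ({exc})")
        locus_idx = cols.index("locus_tag") if "locus_tag" in cols else None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            start_i = int(parts[idx["start"]])
            end_i = int(parts[idx["end"]])
            if start_i > end_i:
                logger.warning("%s:%d: start > end, record skipped", path, lineno)
                continue
            strand = parts[idx["strand"]]
            if strand not in {"+", "-"}:
                logger.warning("%s:%d: unstranded feature skipped", path, lineno)
                continue
            fid = (parts[locus_idx] if locus_idx is not None and
                   locus_idx < len(parts) and parts[locus_idx] else
                   f"line{lineno}")
            feats.append(
                GeneFeature(fid, parts[idx["genomic_accession"]], start_i,
                            end_i, strand, _norm_kind(parts[idx["feature"]]))
            )
    return feats


def write_gff3(path: str | Path, features: Iterable[GeneFeature],
               source: str = "asorf", extra_attrs: Mapping[str, Mapping[str, str]] | None = None) -> None:
    """Write features as GFF3.  ``extra_attrs`` maps feature_id -> extra
    key=value attributes (e.g. the host gene of an embedded ORF)."""
    kinds = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "other": "region"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = {"ID": f.feature_id}
            if extra_attrs and f.feature_id in extra_attrs:
                attrs.update(extra_attrs[f.feature_id])
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write("\t".join([
                f.contig_id, source, kinds.get(f.kind, "region"),
                str(f.start), str(f.end), ".", f.strand, ".", attr_s,
            ]) + "\n")


# ---------------------------------------------------------------------------
# nucleotide operations
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    """Reverse complement over A/C/G/T/N; any other symbol is an error."""
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"cannot reverse-complement symbols {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CodonTable:
    """A genetic code: 64 codon -> amino acid entries with stops as '*'.

    Built from NCBI translation tables via :meth:`from_ncbi_id`; the default
    throughout the package is table 11 (bacterial/archaeal/plant plastid).
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("codon table must have exactly 64 codons")

    @classmethod
    def from_ncbi_id(cls, table_id: int = 11) -> "CodonTable":
        bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(bio.forward_table)
        for stop in bio.stop_codons:
            mapping[stop] = "*"
        return cls(table_id, mapping, frozenset(bio.start_codons))

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa != "*"))


TABLE11 = CodonTable.from_ncbi_id(11)


def translate(seq: str, table: CodonTable = TABLE11,
              strip_terminal_stop: bool = False) -> str:
    """Translate a nucleotide sequence whose length is divisible by 3.

    Codons containing N become 'X'; internal stops are rendered '*'; a
    terminal stop is removed iff ``strip_terminal_stop``.
    """
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    aas = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            aas.append("X")
        else:
            try:
                aas.append(table.codon_to_aa[codon])
            except KeyError:
                raise ValueError(f"invalid codon {codon!r} at position {i + 1}")
    if strip_terminal_stop and aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


# ---------------------------------------------------------------------------
# substitution matrices
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionMatrix:
    """A symmetric residue substitution matrix (e.g. BLOSUM62)."""

    name: str
    alphabet: tuple[str, ...]
    _scores: Mapping[tuple[str, str], float]

    def score(self, a: str, b: str) -> float:
        try:
            return self._scores[(a, b)]
        except KeyError:
            raise KeyError(f"no substitution score for residue pair {a!r}, {b!r}")

    def __contains__(self, residue: str) -> bool:
        return residue in self.alphabet

    def to_biopython(self) -> substitution_matrices.Array:
        cached = getattr(self, "_bio_array", None)
        if cached is None:
            arr = substitution_matrices.Array(alphabet="".join(self.alphabet), dims=2)
            for (a, b), s in self._scores.items():
                arr[a, b] = s
            object.__setattr__(self, "_bio_array", arr)
            cached = arr
        return cached


def read_matrix(path: str | Path) -> SubstitutionMatrix:
    """Read a substitution matrix in NCBI/EMBOSS text layout.

    Lines starting with '#' are comments; the first data row lists the
    column residues; each following row is a residue label plus one integer
    per column.  Asymmetric entries are an error.
    """
    path = Path(path)
    columns: list[str] | None = None
    scores: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if columns is None:
                columns = parts
                continue
            row = parts[0]
            vals = parts[1:]
            if len(vals) != len(columns):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(columns)} scores, "
                    f"got {len(vals)}"
                )
            for col, v in zip(columns, vals):
                scores[(row, col)] = float(v)
    if columns is None:
        raise ParseError(f"{path}: no matrix data found")
    for (a, b), s in scores.items():
        if (b, a) in scores and scores[(b, a)] != s:
            raise ParseError(
                f"{path}: asymmetric entries for {a}/{b}: {s} vs {scores[(b, a)]}"
            )
    return SubstitutionMatrix(path.stem, tuple(columns), scores)


def write_matrix(path: str | Path, matrix: SubstitutionMatrix,
                 comment: str | None = None) -> None:
    """Write a matrix in the same text layout ``read_matrix`` accepts."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("   " + "  ".join(matrix.alphabet) + "\n")
        for a in matrix.alphabet:
            row = [f"{int(matrix.score(a, b)):3d}" for b in matrix.alphabet]
            fh.write(a + " " + " ".join(row) + "\n")


def blosum62() -> SubstitutionMatrix:
    """The standard BLOSUM62 matrix (24-letter alphabet incl. B, Z, X, *)."""
    arr = substitution_matrices.load("BLOSUM62")
    alpha = tuple(arr.alphabet)
    scores = {(a, b): float(arr[a, b]) for a in alpha for b in alpha}
    return SubstitutionMatrix("BLOSUM62", alpha, scores)
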