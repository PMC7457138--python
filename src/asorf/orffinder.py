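"""Discovery of ORFs fully embedded in antisense to annotated genes.

Antiparallel overlapping ORF candidates are open reading frames on the
strand opposite an annotated CDS whose whole genomic span — start codon
through stop codon — lies inside the host gene's span.  The scan works on
the reverse complement of each host CDS in all three frames, then maps the
hits back to genomic coordinates and deduplicates ORFs shared between
overlapping host genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import (
    CodonTable,
    TABLE11,
    Genome,
    reverse_complement,
    to_zero_based,
    translate,
)

__all__ = ["OrfRecord", "find_orfs", "find_embedded_antisense_orfs",
           "DEFAULT_START_CODONS", "DEFAULT_MIN_CODONS"]

# Table 11 initiator codons commonly used in bacterial gene calling.  The
# full table-11 initiator set is wider (ATA, ATC ...) but ATG/GTG/TTG are
# the initiators with appreciable usage in enterobacteria.
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})

# Minimum ORF length in codons (start codon included, stop excluded).
DEFAULT_MIN_CODONS = 20


@dataclass(frozen=True)
class OrfRecord:
    """An embedded antisense ORF.

    ``start``/``end`` are 1-based inclusive genomic coordinates including
    the stop codon; ``strand`` is the ORF strand (opposite the host);
    ``frame_offset`` is the 5' offset of the ORF within the reverse
    complement of the host span, modulo 3; ``nt_seq`` is the ORF-strand
    nucleotide sequence 5'->3'; ``protein`` has the terminal stop stripped.
    """

    orf_id: str
    host_gene_ids: tuple[str, ...]
    contig_id: str
    start: int
    end: int
    strand: str
    frame_offset: int
    nt_seq: str
    protein: str

    @property
    def host_gene_id(self) -> str:
        """Primary (first) host gene id."""
        return self.host_gene_ids[0]

    @property
    def n_codons(self) -> int:
        return len(self.protein)


def find_orfs(seq: str, table: CodonTable = TABLE11,
              min_codons: int = DEFAULT_MIN_CODONS,
              start_codons: frozenset[str] = DEFAULT_START_CODONS,
              longest_only: bool = True) -> list[tuple[int, int, str]]:
    """Enumerate start->stop ORFs on the given strand of ``seq``.

    Returns ``(start, end, protein)`` tuples with 1-based inclusive
    coordinates on ``seq``; ``end`` includes the stop codon.  ``min_codons``
    counts the start codon but not the stop.  With ``longest_only`` (the
    default) only the longest of several in-frame starts sharing a stop is
    reported; otherwise all are.
    """
    if min_codons < 2:
        raise ValueError("min_codons must be >= 2 (start + at least one codon)")
    stops = table.stop_codons
    out: list[tuple[int, int, str]] = []
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []  # 0-based codon start offsets awaiting a stop
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in stops:
                for s in starts:
                    n_codons = (pos - s) // 3
                    if n_codons >= min_codons:
                        nt = seq[s : pos + 3]
                        out.append((s + 1, pos + 3, translate(nt, table, True)))
                    if longest_only:
                        break  # starts[] is ordered 5'->3'; first is longest
                starts = []
            elif codon in start_codons:
                starts.append(pos)
    out.sort()
    return out


def _orf_id(contig: str, start: int, end: int, strand: str) -> str:
    return f"{contig}:{start}-{end}({strand})"


def find_embedded_antisense_orfs(
    genome: Genome,
    table: CodonTable = TABLE11,
    min_codons: int = DEFAULT_MIN_CODONS,
    start_codons: frozenset[str] = DEFAULT_START_CODONS,
    longest_only: bool = True,
) -> list[OrfRecord]:
    """Find all ORFs fully embedded in antisense to annotated CDS features.

    For each host CDS the reverse complement of the host span is scanned in
    all three frames; because the scan is restricted to the host span, every
    hit is by construction fully embedded (start through stop codon).  ORFs
    contained in several overlapping hosts are reported once per distinct
    genomic span with all hosts listed.
    """
    hosts = genome.cds_features()
    found: dict[tuple[str, int, int, str], dict] = {}
    for host in hosts:
        s0, e0 = to_zero_based(host.start, host.end)
        span = genome.contigs[host.contig_id][s0:e0]
        # Scan the strand opposite the host.  For a + host that strand runs
        # right-to-left, so scan reverse_complement(span); for a - host the
        # antisense strand is the contig forward strand, i.e. span itself.
        if host.strand == "+":
            scan_seq = reverse_complement(span)
            orf_strand = "-"
        else:
            scan_seq = span
            orf_strand = "+"
        L = len(span)
        for s, e, protein in find_orfs(scan_seq, table, min_codons,
                                       start_codons, longest_only):
            if orf_strand == "-":
                # position i (1-based) in revcomp(span) = genomic host.end-i+1
                g_start = host.end - e + 1
                g_end = host.end - s + 1
            else:
                g_start = host.start + s - 1
                g_end = host.start + e - 1
            key = (host.contig_id, g_start, g_end, orf_strand)
            if key in found:
                found[key]["hosts"].append(host.feature_id)
            else:
                found[key] = {
                    "hosts": [host.feature_id],
                    "frame_offset": (s - 1) % 3,
                    "nt_seq": scan_seq[s - 1 : e],
                    "protein": protein,
                }
    records = []
    for (contig, g_start, g_end, strand), info in sorted(found.items()):
        records.append(OrfRecord(
            orf_id=_orf_id(contig, g_start, g_end, strand),
            host_gene_ids=tuple(info["hosts"]),
            contig_id=contig,
            start=g_start,
            end=g_end,
            strand=strand,
            frame_offset=info["frame_offset"],
            nt_seq=info["nt_seq"],
            protein=info["protein"],
        ))
    return records
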