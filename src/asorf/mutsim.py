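"""Codon-usage null model: mutation-accumulation identity/similarity curves.

Random coding sequences are drawn codon-by-codon from an empirical codon
usage distribution (stop codons excluded), then subjected to successive
rounds of random point substitutions.  After each round the mutant is
translated — in the sense frame, or in frame 0 of the reverse complement
for the antisense control — and globally aligned against its unmutated
ancestor.  Collating the (identity, similarity) observations by integer
percent decrease in identity yields the neutral identity→similarity
trajectory against which observed ortholog conservation is compared: any
systematic similarity above the curve indicates a bias toward fixing
biochemically similar replacements.

Defaults are the study conditions: 50 sequences of 333 codons, 70 rounds of
10 substitutions each, codon usage of E. coli K-12 coding sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pairalign import AlignConfig, identity_similarity
from .seqio import CodonTable, SubstitutionMatrix, TABLE11, blosum62, reverse_complement, translate

__all__ = [
    "CodonUsage",
    "SimulationConfig",
    "TrajectoryCurve",
    "ECOLI_K12_CODON_USAGE",
    "ecoli_k12_usage",
    "codon_usage_from_cds",
    "generate_sequences",
    "mutate_rounds",
    "trajectory",
    "run_null_model",
]

_BASES = ("A", "C", "G", "T")

# Codon usage of E. coli K-12 annotated coding sequences, per-mille
# frequencies rounded to one decimal (standard codon-usage-table values).
# Stop codons are listed for completeness but removed before sampling.
ECOLI_K12_CODON_USAGE: dict[str, float] = {
    "TTT": 22.2, "TTC": 16.6, "TTA": 13.9, "TTG": 13.7,
    "CTT": 11.0, "CTC": 11.0, "CTA": 3.9, "CTG": 52.6,
    "ATT": 30.3, "ATC": 25.1, "ATA": 4.4, "ATG": 27.9,
    "GTT": 18.3, "GTC": 15.3, "GTA": 10.9, "GTG": 26.4,
    "TCT": 8.5, "TCC": 8.6, "TCA": 7.2, "TCG": 8.9,
    "CCT": 7.0, "CCC": 5.5, "CCA": 8.4, "CCG": 23.2,
    "ACT": 9.0, "ACC": 23.4, "ACA": 7.1, "ACG": 14.4,
    "GCT": 15.3, "GCC": 25.5, "GCA": 20.1, "GCG": 33.6,
    "TAT": 16.2, "TAC": 12.2, "TAA": 2.0, "TAG": 0.2,
    "CAT": 12.9, "CAC": 9.7, "CAA": 15.3, "CAG": 28.8,
    "AAT": 17.7, "AAC": 21.7, "AAA": 33.6, "AAG": 10.3,
    "GAT": 32.1, "GAC": 19.1, "GAA": 39.4, "GAG": 17.8,
    "TGT": 5.2, "TGC": 6.4, "TGA": 0.9, "TGG": 15.2,
    "CGT": 20.9, "CGC": 22.0, "CGA": 3.6, "CGG": 5.4,
    "AGT": 8.8, "AGC": 16.1, "AGA": 2.1, "AGG": 1.2,
    "GGT": 24.7, "GGC": 29.6, "GGA": 8.0, "GGG": 11.1,
}


@dataclass(frozen=True)
class CodonUsage:
    """Relative frequencies of the sense codons used for sequence sampling.

    Stop codons are excluded from the distribution so that sampled coding
    sequences have no in-frame stops; frequencies sum to 1.
    """

    frequencies: Mapping[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"codon frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.frequencies.values()):
            raise ValueError("negative codon frequency")

    @classmethod
    def from_counts(cls, counts: Mapping[str, float], source: str = "",
                    table: CodonTable = TABLE11) -> "CodonUsage":
        stops = table.stop_codons
        kept = {c: n for c, n in counts.items() if c not in stops and n > 0}
        total = sum(kept.values())
        if total == 0:
            raise ValueError("no sense codons in input")
        return cls({c: n / total for c, n in sorted(kept.items())}, source)

    def codons(self) -> tuple[str, ...]:
        return tuple(self.frequencies)

    def probs(self) -> np.ndarray:
        return np.asarray(list(self.frequencies.values()), dtype=float)


def ecoli_k12_usage() -> CodonUsage:
    """Default usage: E. coli K-12 coding sequences (stops removed)."""
    return CodonUsage.from_counts(ECOLI_K12_CODON_USAGE,
                                  source="E. coli K-12 codon usage table")


@dataclass(frozen=True)
class SimulationConfig:
    """Null-model dimensions; defaults are the full study conditions."""

    n_sequences: int = 50
    n_codons: int = 333
    n_rounds: int = 70
    mutations_per_round: int = 10
    frame: str = "sense"
    seed: int = 0
    # msbar-style knobs the original tool leaves unstated: whether a
    # substituted base may equal the original, and whether duplicate hit
    # positions within a round are resampled.
    allow_same_base: bool = False
    resample_duplicate_positions: bool = False

    def __post_init__(self) -> None:
        for name in ("n_sequences", "n_codons", "n_rounds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mutations_per_round < 0:
            raise ValueError("mutations_per_round must be >= 0")
        if self.frame not in {"sense", "antisense"}:
            raise ValueError("frame must be 'sense' or 'antisense'")


@dataclass(frozen=True)
class TrajectoryCurve:
    """Binned identity→similarity relation.

    ``bins`` maps integer percent decrease in identity to
    ``(median_identity_pct, median_similarity_pct, n_observations)``; bin 0
    holds the unmutated reference comparisons at (100, 100).
    """

    bins: Mapping[int, tuple[float, float, int]]
    frame: str = "sense"

    def median_similarity_at(self, identity_pct: float) -> float:
        """Null similarity at the bin closest to the given identity."""
        if not self.bins:
            raise ValueError("empty trajectory curve")
        target = round(100.0 - identity_pct)
        key = min(self.bins, key=lambda b: (abs(b - target), b))
        return self.bins[key][1]

    def to_frame(self) -> pd.DataFrame:
        rows = [(b, i, s, n) for b, (i, s, n) in sorted(self.bins.items())]
        return pd.DataFrame(rows, columns=["identity_decrease_pct",
                                           "median_identity_pct",
                                           "median_similarity_pct", "n"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def codon_usage_from_cds(cds_list: Sequence[str], table: CodonTable = TABLE11,
                         source: str = "pooled CDS") -> CodonUsage:
    """Pool codon counts over coding sequences; drop stops; renormalize."""
    if not cds_list:
        raise ValueError("empty CDS list")
    counts: dict[str, int] = {}
    for cds in cds_list:
        if len(cds) % 3:
            raise ValueError("CDS length not divisible by 3")
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if "N" in codon:
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return CodonUsage.from_counts(counts, source=source, table=table)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-sequence random streams spawned from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(n)]


def generate_sequences(usage: CodonUsage, cfg: SimulationConfig) -> list[str]:
    """Sample ``n_sequences`` coding sequences of ``n_codons`` codons i.i.d.
    from the usage distribution (no in-frame sense stops by construction)."""
    codons = np.asarray(usage.codons())
    probs = usage.probs()
    seqs = []
    for rng in _child_rngs(cfg.seed, cfg.n_sequences):
        picks = rng.choice(codons, size=cfg.n_codons, p=probs)
        seqs.append("".join(picks))
    return seqs


def mutate_rounds(seq: str, cfg: SimulationConfig,
                  rng: np.random.Generator) -> list[str]:
    """Apply ``n_rounds`` rounds of ``mutations_per_round`` point
    substitutions; returns one sequence per round (the input is not
    included).  Each substitution hits a uniformly random position; by
    default the replacement base always differs from the current base and
    duplicate positions within a round are kept (they collide, as msbar-like
    repeated hits do)."""
    current = np.frombuffer(seq.encode(), dtype="S1").copy()
    n = len(current)
    bases = np.array([b.encode() for b in _BASES])
    out = []
    for _ in range(cfg.n_rounds):
        if cfg.resample_duplicate_positions:
            positions = rng.choice(n, size=cfg.mutations_per_round, replace=False)
        else:
            positions = rng.integers(0, n, size=cfg.mutations_per_round)
        for pos in positions:
            if cfg.allow_same_base:
                current[pos] = bases[rng.integers(0, 4)]
            else:
                choices = [b for b in bases if b != current[pos]]
                current[pos] = choices[rng.integers(0, 3)]
        out.append(current.tobytes().decode())
    return out


def _frame_protein(nt: str, frame: str, table: CodonTable) -> str:
    """Sense protein, or frame 0 of the direct reverse complement (no
    further frame shift) for the antisense control."""
    if frame == "antisense":
        nt = reverse_complement(nt)
    return translate(nt, table)


def trajectory(originals: Sequence[str], cfg: SimulationConfig,
               matrix: SubstitutionMatrix | None = None,
               align_cfg: AlignConfig = AlignConfig(),
               table: CodonTable = TABLE11,
               return_observations: bool = False):
    """Mutate each original through all rounds and collate the identity →
    similarity observations into a :class:`TrajectoryCurve`.

    Bin key = round(100 − identity_pct).  Internal stops arising from
    mutation (or inherent to the antisense frame) are translated as '*' and
    aligned as such via the matrix's '*' scores — alignment lengths stay
    comparable across rounds.
    """
    if matrix is None:
        matrix = blosum62()
    rngs = _child_rngs(cfg.seed + 1, len(originals))  # distinct from sampling
    obs: list[tuple[str, int, int, float, float]] = []
    binned: dict[int, tuple[list[float], list[float]]] = {}

    def record(round_no: int, idx: int, ident: float, simil: float) -> None:
        obs.append((cfg.frame, round_no, idx, ident, simil))
        key = round(100.0 - ident)
        binned.setdefault(key, ([], []))
        binned[key][0].append(ident)
        binned[key][1].append(simil)

    for idx, (orig, rng) in enumerate(zip(originals, rngs)):
        ref_protein = _frame_protein(orig, cfg.frame, table)
        record(0, idx, 100.0, 100.0)  # round-0 reference vs itself
        for round_no, mutant in enumerate(mutate_rounds(orig, cfg, rng), start=1):
            mut_protein = _frame_protein(mutant, cfg.frame, table)
            ident, simil = identity_similarity(ref_protein, mut_protein,
                                               matrix, align_cfg)
            record(round_no, idx, ident, simil)

    bins = {k: (float(np.median(ids)), float(np.median(sims)), len(ids))
            for k, (ids, sims) in sorted(binned.items())}
    curve = TrajectoryCurve(bins=bins, frame=cfg.frame)
    if return_observations:
        df = pd.DataFrame(obs, columns=["frame", "round", "seq_index",
                                        "identity_pct", "similarity_pct"])
        return curve, df
    return curve


def run_null_model(usage: CodonUsage | None = None,
                   cfg: SimulationConfig = SimulationConfig(),
                   matrix: SubstitutionMatrix | None = None,
                   align_cfg: AlignConfig = AlignConfig(),
                   frames: Iterable[str] = ("sense", "antisense"),
                   return_observations: bool = False):
    """Convenience driver: sample originals once, then compute the curve for
    each requested frame from the same mutated nucleotide sequences."""
    if usage is None:
        usage = ecoli_k12_usage()
    originals = generate_sequences(usage, cfg)
    out = {}
    for frame in frames:
        out[frame] = trajectory(originals, replace(cfg, frame=frame), matrix,
                                align_cfg, return_observations=return_observations)
    return out
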