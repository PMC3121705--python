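"""Core data model: annotated genomes and their features.

Internal coordinates are 0-based half-open throughout the package; conversion
to/from the GenBank 1-based inclusive convention happens only in the readers
and writers (:mod:`phagecharm.genome_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

DNA_ALPHABET = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(COMPLEMENT)[::-1]


def clean_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and validate its alphabet."""
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return seq


@dataclass
class Feature:
    """A stranded genome feature in internal 0-based half-open coordinates."""

    kind: str  # CDS | tRNA | promoter | terminator | other
    start: int
    end: int
    strand: str  # '+' or '-'
    locus_tag: str = ""
    qualifiers: dict = field(default_factory=dict)
    translation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"bad feature coordinates [{self.start}, {self.end}) for {self.locus_tag!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def extract(self, sequence: str) -> str:
        """Feature sequence in reading orientation (revcomp on the - strand)."""
        sub = sequence[self.start : self.end]
        return revcomp(sub) if self.strand == "-" else sub


@dataclass
class AnnotatedGenome:
    """A DNA sequence plus typed, stranded features with locus tags."""

    id: str
    sequence: str
    topology: str = "linear"  # linear | circular_permuted
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = clean_sequence(self.sequence)
        if len(self.sequence) < 1:
            raise ValueError("genome sequence must be nonempty")
        if self.topology not in ("linear", "circular_permuted"):
            raise ValueError(f"unknown topology {self.topology!r}")
        self.validate_features()

    def validate_features(self) -> None:
        L = len(self.sequence)
        seen: set[str] = set()
        for f in self.features:
            if f.end > L:
                raise ValueError(
                    f"feature {f.locus_tag!r} [{f.start}, {f.end}) outside sequence of length {L}"
                )
            if f.locus_tag:
                if f.locus_tag in seen:
                    raise ValueError(f"duplicate locus_tag {f.locus_tag!r}")
                seen.add(f.locus_tag)

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    @property
    def cds(self) -> list[Feature]:
        return self.features_of_kind("CDS")

    @property
    def trnas(self) -> list[Feature]:
        return self.features_of_kind("tRNA")


@dataclass
class GenomeStats:
    """Whole-genome summary statistics."""

    length_bp: int
    gc_percent: float
    coding_fraction: float
    start_codon_usage: dict[str, float]
    trna_count: int
    trna_gc_range: Optional[tuple[float, float]]
    terminal_repeat_kb: Optional[float] = None

    def as_dict(self) -> dict:
        d = {
            "length_bp": self.length_bp,
            "gc_percent": self.gc_percent,
            "coding_fraction": self.coding_fraction,
            "trna_count": self.trna_count,
        }
        if self.trna_gc_range is not None:
            d["trna_gc_min"], d["trna_gc_max"] = self.trna_gc_range
        if self.terminal_repeat_kb is not None:
            d["terminal_repeat_kb"] = self.terminal_repeat_kb
        for codon, pct in sorted(self.start_codon_usage.items()):
            d[f"start_{codon}_percent"] = pct
        return d
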