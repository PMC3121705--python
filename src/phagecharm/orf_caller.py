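"""ORF discovery and ribosome-binding-site (Shine-Dalgarno) scoring.

Gene calling follows the classic manual-annotation rule for phage genomes:
an ORF opens at an ATG/GTG/CTG/TTG start codon, runs for at least 30 further
codons to the first in-frame stop, and carries an upstream hexamer resembling
the Shine-Dalgarno consensus GGAGGT at canonical spacing. "Resembling" is
operationalized as the best ungapped match score within a configurable
upstream window; the default gate is >= 4 of 6 matches with the motif's 3'
end 4-16 bp upstream of the start codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .model import AnnotatedGenome, Feature, revcomp

DEFAULT_STARTS = ("ATG", "GTG", "CTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")  # standard code / translation table 11
SD_MOTIF = "GGAGGT"
DEFAULT_RBS_WINDOW = (4, 16)  # bp between motif 3' end and start codon
DEFAULT_RBS_MIN_SCORE = 4
MIN_EXTRA_CODONS = 30


@dataclass
class OrfCandidate:
    """A candidate gene: one allowed start for one stop-anchored reading frame.

    Coordinates are 0-based half-open on the forward strand; ``start`` is the
    first base of the start codon's interval and ``end`` the base after the
    stop codon, regardless of strand.
    """

    frame: int  # +1..+3 / -1..-3
    start: int
    end: int
    strand: str
    start_codon: str
    n_codons_after_start: int
    rbs_score: int = 0
    rbs_offset: Optional[int] = None
    rbs_truncated: bool = False

    def __post_init__(self) -> None:
        if self.start_codon not in DEFAULT_STARTS:
            raise ValueError(f"disallowed start codon {self.start_codon}")

    @property
    def stop_anchor(self) -> tuple[str, int]:
        """(strand, stop position) key identifying the gene locus."""
        return (self.strand, self.end if self.strand == "+" else self.start)


def rbs_score(upstream: str, rbs_motif: str = SD_MOTIF) -> tuple[int, int, bool]:
    """Score a Shine-Dalgarno-like element in an upstream window.

    ``upstream`` is the window immediately 5' of the start codon on the coding
    strand, oriented 5'->3', with its right edge a configured minimum distance
    from the start codon (the caller supplies the slice). Returns
    ``(score, offset, truncated)``: score is the maximum number of matching
    positions over all ungapped placements of the motif in the window; offset
    is the distance from the best placement's 3' end to the window's right
    edge plus the window's own offset handled by the caller. Ties break toward
    the smaller offset (placement closest to the start codon). When the window
    is shorter than the motif, truncated placements are scored and flagged.
    """
    w, m = len(upstream), len(rbs_motif)
    if w == 0:
        return 0, 0, True
    truncated = w < m
    best_score, best_offset = -1, 0
    # placements indexed by distance of the motif 3' end from the window's right edge
    for offset in range(0, max(w - m, 0) + 1) if not truncated else range(0, 1):
        if truncated:
            # motif right-aligned, clipped at the left window edge
            seg = upstream
            mot = rbs_motif[m - w:]
        else:
            end = w - offset
            seg = upstream[end - m : end]
            mot = rbs_motif
        score = sum(1 for a, b in zip(seg, mot) if a == b)
        if score > best_score:  # offsets iterate small->large, so ties keep the smaller
            best_score, best_offset = score, offset
    return best_score, best_offset, truncated


def _forward_orfs(seq: str, min_extra_codons: int,
                  allowed_starts: tuple[str, ...]) -> list[tuple[int, int, int, str, int]]:
    """Stop-anchored ORF enumeration on the forward strand of ``seq``.

    Yields (frame0, start, end, start_codon, n_codons_after_start) with end
    just past the stop codon. ORFs running off the sequence end are excluded.
    """
    L = len(seq)
    out = []
    for frame in range(3):
        starts_pending: list[int] = []
        pos = frame
        while pos + 3 <= L:
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                stop_end = pos + 3
                for s in starts_pending:
                    n_extra = (pos - s) // 3 - 1
                    if n_extra >= min_extra_codons:
                        out.append((frame, s, stop_end, seq[s : s + 3], n_extra))
                starts_pending = []
            elif codon in allowed_starts:
                starts_pending.append(pos)
            pos += 3
    return out


def find_orfs(sequence: str, min_extra_codons: int = MIN_EXTRA_CODONS,
              allowed_starts: Iterable[str] = DEFAULT_STARTS,
              rbs_motif: str = SD_MOTIF,
              rbs_window: tuple[int, int] = DEFAULT_RBS_WINDOW) -> list[OrfCandidate]:
    """Enumerate start-codon candidates in all six frames of ``sequence``.

    Every allowed start with at least ``min_extra_codons`` codons between it
    (exclusive) and its in-frame stop (exclusive) is emitted, each scored for
    an upstream RBS. Candidates are sorted by forward-strand start position.
    """
    sequence = sequence.upper()
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    allowed = tuple(allowed_starts)
    lo, hi = rbs_window
    candidates: list[OrfCandidate] = []

    def window_for(start_pos: int, seq: str) -> tuple[str, bool]:
        # slice [start - hi - len(motif), start - lo) on the coding strand
        a = start_pos - hi - len(rbs_motif)
        b = start_pos - lo
        return seq[max(a, 0) : max(b, 0)], a < 0

    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        L = len(seq)
        for frame0, s, e, codon, n_extra in _forward_orfs(seq, min_extra_codons, allowed):
            win, clipped = window_for(s, seq)
            score, off, trunc = rbs_score(win, rbs_motif)
            if strand == "+":
                start, end, frame = s, e, frame0 + 1
            else:
                start, end, frame = L - e, L - s, -(frame0 + 1)
            candidates.append(OrfCandidate(
                frame=frame, start=start, end=end, strand=strand,
                start_codon=codon, n_codons_after_start=n_extra,
                rbs_score=score, rbs_offset=lo + off,
                rbs_truncated=trunc or clipped,
            ))
    candidates.sort(key=lambda c: (c.start, c.end, c.strand))
    return candidates


def call_genes(candidates: list[OrfCandidate],
               rbs_min_score: int = DEFAULT_RBS_MIN_SCORE,
               all_starts: bool = False,
               locus_prefix: str = "orf") -> list[Feature]:
    """Filter candidates on RBS score and emit CDS features.

    Default behaviour keeps, within each stop-anchored frame, the qualifying
    start yielding the longest ORF (one gene per locus); ``all_starts=True``
    emits every qualifying candidate. Overlaps between different loci are
    allowed (phage genes overlap); no overlap resolution is attempted.
    """
    kept = [c for c in candidates if c.rbs_score >= rbs_min_score]
    if not all_starts:
        by_anchor: dict[tuple[str, int], OrfCandidate] = {}
        for c in kept:
            prev = by_anchor.get(c.stop_anchor)
            if prev is None or (c.end - c.start) > (prev.end - prev.start):
                by_anchor[c.stop_anchor] = c
        kept = sorted(by_anchor.values(), key=lambda c: (c.start, c.end))
    feats = []
    for i, c in enumerate(kept, start=1):
        feats.append(Feature(
            kind="CDS", start=c.start, end=c.end, strand=c.strand,
            locus_tag=f"{locus_prefix}{i:03d}",
            qualifiers={"rbs_score": c.rbs_score, "rbs_offset": c.rbs_offset,
                        "start_codon": c.start_codon, "frame": c.frame},
        ))
    return feats


def annotate_genome(genome: AnnotatedGenome, **kwargs) -> AnnotatedGenome:
    """Convenience: run find_orfs + call_genes and return an annotated copy."""
    rbs_min = kwargs.pop("rbs_min_score", DEFAULT_RBS_MIN_SCORE)
    cands = find_orfs(genome.sequence, **kwargs)
    feats = call_genes(cands, rbs_min_score=rbs_min)
    return AnnotatedGenome(genome.id, genome.sequence, genome.topology, feats)
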