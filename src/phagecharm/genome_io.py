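"""Genome reading/writing and whole-genome summary statistics.

GenBank and FASTA parsing is delegated to Biopython; this module converts
between the file formats' 1-based inclusive coordinates and the package's
0-based half-open internal convention, and computes the summary quantities a
phage genome report opens with (length, G+C, coding fraction, start-codon
usage, tRNA statistics, GC skew, terminal redundancy).
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, NamedTuple, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .model import AnnotatedGenome, Feature, GenomeStats, revcomp

_KIND_MAP = {"CDS": "CDS", "tRNA": "tRNA", "promoter": "promoter",
             "regulatory": "promoter", "terminator": "terminator"}


class GenomeParseError(ValueError):
    """Raised when an input file cannot be parsed into a genome."""


def _feature_from_seqfeature(sf: SeqFeature, idx: int) -> Feature:
    kind = _KIND_MAP.get(sf.type, "other")
    strand = "-" if sf.location.strand == -1 else "+"
    quals = {k: (v[0] if isinstance(v, list) and v else v)
             for k, v in sf.qualifiers.items()}
    locus = quals.get("locus_tag", quals.get("gene", f"{sf.type.lower()}_{idx:04d}"))
    translation = quals.pop("translation", None)
    return Feature(
        kind=kind,
        start=int(sf.location.start),  # Biopython already stores 0-based starts
        end=int(sf.location.end),
        strand=strand,
        locus_tag=str(locus),
        qualifiers=quals,
        translation=str(translation) if translation else None,
    )


def read_genbank(path, feature_kinds: Iterable[str] = ("CDS", "tRNA")) -> AnnotatedGenome:
    """Read a GenBank flat file into an :class:`AnnotatedGenome`.

    Only features whose GenBank type maps onto the internal kinds in
    ``feature_kinds`` are kept (default: CDS and tRNA). Translations are kept
    when present. Raises :class:`GenomeParseError` on missing/empty sequence
    and ``ValueError`` on features outside the sequence.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad files
        raise GenomeParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    try:
        seq = str(record.seq)
    except Exception as exc:  # undefined sequence (no ORIGIN block)
        raise GenomeParseError(f"GenBank record {record.id} has no ORIGIN sequence") from exc
    if not seq:
        raise GenomeParseError(f"GenBank record {record.id} has no ORIGIN sequence")
    wanted = set(feature_kinds)
    feats = []
    for i, sf in enumerate(record.features):
        kind = _KIND_MAP.get(sf.type)
        if kind in wanted:
            feats.append(_feature_from_seqfeature(sf, i))
    topology = record.annotations.get("topology", "linear")
    return AnnotatedGenome(
        id=record.id or record.name,
        sequence=seq,
        topology="circular_permuted" if topology == "circular" else "linear",
        features=feats,
    )


def read_fasta(path) -> AnnotatedGenome:
    """Read a single-record FASTA into a genome with no features.

    Lowercase input is uppercased. Multi-record input is rejected with an
    error naming the record count.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise GenomeParseError(f"no FASTA records found in {path}")
    if len(records) > 1:
        raise GenomeParseError(
            f"expected a single-record FASTA, found {len(records)} records in {path}"
        )
    rec = records[0]
    return AnnotatedGenome(id=rec.id, sequence=str(rec.seq))


def read_fasta_many(path) -> dict[str, str]:
    """Read a multi-record FASTA into an id -> sequence mapping (e.g. proteomes)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeParseError(f"no FASTA records found in {path}")
    return {rec.id: str(rec.seq).upper() for rec in records}


def write_genbank(genome: AnnotatedGenome, path) -> None:
    """Write the genome back out as a GenBank flat file (round-trip safe)."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description="")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = (
        "circular" if genome.topology == "circular_permuted" else "linear"
    )
    for f in genome.features:
        quals = dict(f.qualifiers)
        if f.locus_tag:
            quals["locus_tag"] = f.locus_tag
        if f.translation:
            quals["translation"] = f.translation
        sf = SeqFeature(
            FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1),
            type=f.kind if f.kind != "other" else "misc_feature",
            qualifiers=quals,
        )
        record.features.append(sf)
    SeqIO.write(record, str(path), "genbank")


def write_fasta(genome: AnnotatedGenome, path) -> None:
    SeqIO.write(SeqRecord(Seq(genome.sequence), id=genome.id, description=""),
                str(path), "fasta")


def write_gff3(genome: AnnotatedGenome, path, extra_features: Iterable[Feature] = ()) -> None:
    """Export all features as GFF3 (1-based inclusive at the file boundary)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for f in list(genome.features) + list(extra_features):
            score = f.qualifiers.get("score", ".")
            attrs = [f"ID={f.locus_tag}"] if f.locus_tag else []
            for k, v in f.qualifiers.items():
                if k != "score":
                    attrs.append(f"{k}={v}")
            fh.write(
                "\t".join([
                    genome.id, "phagecharm", f.kind, str(f.start + 1), str(f.end),
                    str(score), f.strand, ".", ";".join(attrs) or ".",
                ]) + "\n"
            )


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def gc_percent(seq: str, ndigits: Optional[int] = 1) -> float:
    """G+C percentage over unambiguous bases.

    N characters count toward sequence length but are excluded from both the
    numerator and the denominator of the G+C ratio.
    """
    counts = Counter(seq)
    denom = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if denom == 0:
        return 0.0
    pct = 100.0 * (counts["G"] + counts["C"]) / denom
    return round(pct, ndigits) if ndigits is not None else pct


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total, cur_start, cur_end = 0, *intervals[0]
    for s, e in intervals[1:]:
        if s > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    return total + (cur_end - cur_start)


def coding_fraction(genome: AnnotatedGenome, kinds: Iterable[str] = ("CDS",)) -> float:
    """Fraction of genome positions covered by at least one feature of `kinds`.

    Computed on the union of intervals, not the sum of lengths, so overlapping
    genes are not double-counted.
    """
    wanted = set(kinds)
    ivals = [(f.start, f.end) for f in genome.features if f.kind in wanted]
    return _union_length(ivals) / len(genome)


def start_codon_usage(genome: AnnotatedGenome, ndigits: int = 1) -> dict[str, float]:
    """Percentage usage of each start codon over all CDS features.

    The start codon is read from the genome sequence at the CDS 5' end
    (reverse-complemented on the - strand), not from any qualifier.
    """
    counts: Counter[str] = Counter()
    for f in genome.cds:
        codon = f.extract(genome.sequence)[:3]
        if len(codon) == 3:
            counts[codon] += 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {c: round(100.0 * n / total, ndigits) for c, n in counts.items()}


def genome_summary(genome: AnnotatedGenome,
                   terminal_repeat_kb: Optional[float] = None) -> GenomeStats:
    """Compute the whole-genome report statistics."""
    trnas = genome.trnas
    trna_gc = [gc_percent(f.extract(genome.sequence)) for f in trnas]
    return GenomeStats(
        length_bp=len(genome),
        gc_percent=gc_percent(genome.sequence),
        coding_fraction=coding_fraction(genome),
        start_codon_usage=start_codon_usage(genome),
        trna_count=len(trnas),
        trna_gc_range=(min(trna_gc), max(trna_gc)) if trna_gc else None,
        terminal_repeat_kb=terminal_repeat_kb,
    )


class GcSkewPoint(NamedTuple):
    position: int  # 0-based window start
    skew: float
    defined: bool  # False when the window contains no G or C


def gc_skew_profile(sequence: str, window: int, step: int) -> list[GcSkewPoint]:
    """Sliding-window GC skew, skew = (G - C) / (G + C) per window.

    Windows with G+C = 0 report skew 0.0 and ``defined=False`` so the profile
    keeps a fixed length. Positions are 0-based window starts.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if window > len(sequence):
        raise ValueError(f"window {window} exceeds sequence length {len(sequence)}")
    out = []
    for pos in range(0, len(sequence) - window + 1, step):
        win = sequence[pos : pos + window]
        g, c = win.count("G"), win.count("C")
        if g + c == 0:
            out.append(GcSkewPoint(pos, 0.0, False))
        else:
            out.append(GcSkewPoint(pos, (g - c) / (g + c), True))
    return out


def rotate_origin(genome: AnnotatedGenome, new_origin: int) -> AnnotatedGenome:
    """Re-open a circularly permuted genome at a new origin.

    ``new_origin`` follows the GenBank 1-based convention: the base at that
    position becomes position 1 of the rotated genome. Features spanning the
    cut would lose the start <= end invariant and raise an error; choose an
    intergenic origin (the convention for circularly permuted phage genomes,
    which are re-opened upstream of a chosen gene before annotation).
    """
    L = len(genome)
    if genome.topology != "circular_permuted":
        raise ValueError("rotate_origin requires a circular_permuted genome")
    if not (1 <= new_origin <= L):
        raise ValueError(f"new_origin must be in [1, {L}], got {new_origin}")
    k = new_origin - 1  # 0-based cut point
    seq = genome.sequence[k:] + genome.sequence[:k]
    feats = []
    for f in genome.features:
        ns = (f.start - k) % L
        # half-open end: an end exactly at the cut maps to L, not 0
        ne = (f.end - k) % L or L
        if ns >= ne:
            raise ValueError(
                f"feature {f.locus_tag!r} spans the new origin at {new_origin}"
            )
        feats.append(Feature(f.kind, ns, ne, f.strand, f.locus_tag,
                             dict(f.qualifiers), f.translation))
    return AnnotatedGenome(genome.id, seq, genome.topology, feats)


def estimate_terminal_redundancy(experimental_size_kb: float,
                                 assembled_size_kb: float) -> float:
    """Terminal-repeat length implied by a physical vs assembled size gap.

    A terminally redundant chromosome carries the repeat at both ends, so the
    repeat length is half the excess of the physical (e.g. PFGE) size over the
    unique assembled sequence: (experimental - assembled) / 2.
    """
    if assembled_size_kb < 0 or experimental_size_kb < 0:
        raise ValueError("sizes must be non-negative")
    if experimental_size_kb < assembled_size_kb:
        raise ValueError(
            "experimental size below assembled size: no terminal-redundancy model"
        )
    return (experimental_size_kb - assembled_size_kb) / 2.0
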