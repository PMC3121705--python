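"""Regulatory-element scanning: promoters, degenerate motifs, terminators.

Three scanners cover the elements a phage genome report describes:

* ``scan_fixed_motif`` — mismatch-tolerant search for an exact motif, e.g. the
  T4-type late-promoter box TATAAATA with one mismatch allowed.
* ``scan_bipartite`` — sigma70 housekeeping promoters as a -35 box (TTGACA)
  and a -10 box (TATAAT) separated by a 15-18 bp spacer, with a total
  mismatch budget.
* ``scan_degenerate`` — IUPAC patterns (e.g. a WebLogo-derived consensus such
  as TNTNNNANNNNNNNNNNCNNATNAATA); N columns match anything and cost nothing.

Rho-independent terminators are called as stem-loop structures adjacent to a
polyT run, gated on a nearest-neighbor free energy: only hairpins with
dG below a threshold (default -10 kcal/mol) followed within a few bases by a
T-run are reported, optionally restricted to intergenic positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .model import AnnotatedGenome, Feature, revcomp

# ---------------------------------------------------------------------------
# IUPAC handling
# ---------------------------------------------------------------------------

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGTN character in sequence: {exc}") from exc


@dataclass
class MotifHit:
    pattern_id: str
    position: int  # 0-based match start on the forward strand
    strand: str
    mismatches: int
    matched_seq: str


@dataclass
class PromoterHit:
    box35: int  # 0-based start of the -35 box on the forward strand
    spacer_len: int
    box10: int  # 0-based start of the -10 box on the forward strand
    strand: str
    total_mismatches: int
    matched_seq: str = ""
    downstream_gene: Optional[str] = None

    @property
    def start(self) -> int:
        return min(self.box35, self.box10)

    @property
    def end(self) -> int:
        # forward-strand end of the downstream box (boxes are 6-mers)
        return max(self.box35, self.box10) + 6


@dataclass
class DegeneratePattern:
    """An IUPAC consensus pattern with the per-column counts that built it."""

    iupac_string: str
    per_column_counts: list[dict[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.iupac_string) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.iupac_string)


def _mismatch_profile(seq_codes: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatch count of `pattern` at every forward placement in `seq_codes`.

    N/degenerate columns in the pattern are free; an N in the *sequence*
    matches nothing except a pattern N.
    """
    L, w = len(seq_codes), len(pattern)
    if w > L:
        return np.zeros(0, dtype=np.int32)
    n_place = L - w + 1
    mism = np.zeros(n_place, dtype=np.int32)
    for j, code in enumerate(pattern):
        allowed = IUPAC[code]
        if allowed == "ACGT":
            continue
        col = seq_codes[j : j + n_place]
        ok = np.zeros(n_place, dtype=bool)
        for b in allowed:
            ok |= col == _BASE_INDEX[b]
        mism += ~ok
    return mism


def scan_fixed_motif(sequence: str, motif: str, max_mismatch: int = 0,
                     pattern_id: Optional[str] = None) -> list[MotifHit]:
    """All placements of ``motif`` on both strands with <= max_mismatch.

    The motif must be a plain ACGT string (use :func:`scan_degenerate` for
    IUPAC patterns). Overlapping hits are all reported, sorted by position.
    A palindromic motif yields one hit per strand at the same locus; collapse
    with ``dedupe_palindromic`` if single reporting is wanted.
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be plain ACGT; use scan_degenerate for IUPAC")
    return scan_degenerate(sequence, motif, max_mismatch,
                           pattern_id=pattern_id or motif)


def scan_degenerate(sequence: str, pattern: Union[str, DegeneratePattern],
                    max_mismatch: int = 0,
                    pattern_id: Optional[str] = None) -> list[MotifHit]:
    """IUPAC-aware mismatch scan of both strands.

    Mismatches are counted only at columns that constrain the base (an N
    column matches anything at zero cost); a sequence base inside the
    pattern's IUPAC class costs nothing.
    """
    if isinstance(pattern, DegeneratePattern):
        pat = pattern.iupac_string
        pid = pattern_id or "consensus"
    else:
        pat = pattern.upper()
        pid = pattern_id or pat
    if set(pat) - set(IUPAC):
        raise ValueError(f"invalid IUPAC codes in pattern {pat!r}")
    sequence = sequence.upper()
    if len(pat) > len(sequence):
        raise ValueError("pattern longer than sequence")
    w, L = len(pat), len(sequence)
    hits: list[MotifHit] = []
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        codes = _encode(seq)
        mism = _mismatch_profile(codes, pat)
        for pos in np.flatnonzero(mism <= max_mismatch):
            pos = int(pos)
            fwd_pos = pos if strand == "+" else L - pos - w
            hits.append(MotifHit(pid, fwd_pos, strand, int(mism[pos]),
                                 seq[pos : pos + w]))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def dedupe_palindromic(hits: list[MotifHit]) -> list[MotifHit]:
    """Collapse +/- hits at identical (position, pattern) to the + strand hit."""
    seen: dict[tuple[str, int], MotifHit] = {}
    for h in hits:
        key = (h.pattern_id, h.position)
        if key not in seen or (seen[key].strand == "-" and h.strand == "+"):
            seen[key] = h
    return sorted(seen.values(), key=lambda h: (h.position, h.strand))


def scan_bipartite(sequence: str, box1: str = "TTGACA", box2: str = "TATAAT",
                   spacer_min: int = 15, spacer_max: int = 18,
                   max_mismatch_total: int = 0) -> list[PromoterHit]:
    """Two-box promoter scan: box1 (N_spacer) box2 with a shared mismatch budget.

    Per box1 anchor position and strand, only the placement with the fewest
    total mismatches is kept; ties break toward the shorter spacer.
    """
    if spacer_min > spacer_max:
        raise ValueError("spacer_min > spacer_max")
    sequence = sequence.upper()
    L, w1, w2 = len(sequence), len(box1), len(box2)
    out: list[PromoterHit] = []
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        codes = _encode(seq)
        m1 = _mismatch_profile(codes, box1.upper())
        m2 = _mismatch_profile(codes, box2.upper())
        for p1 in np.flatnonzero(m1 <= max_mismatch_total):
            p1 = int(p1)
            best: Optional[tuple[int, int]] = None  # (total_mism, spacer)
            for spacer in range(spacer_min, spacer_max + 1):
                p2 = p1 + w1 + spacer
                if p2 >= len(m2):
                    break
                total = int(m1[p1] + m2[p2])
                if total <= max_mismatch_total and (best is None or total < best[0]):
                    best = (total, spacer)
            if best is not None:
                total, spacer = best
                p2 = p1 + w1 + spacer
                if strand == "+":
                    b35, b10 = p1, p2
                else:
                    b35, b10 = L - p1 - w1, L - p2 - w2
                out.append(PromoterHit(
                    box35=b35, spacer_len=spacer, box10=b10, strand=strand,
                    total_mismatches=total,
                    matched_seq=seq[p1 : p2 + w2],
                ))
    out.sort(key=lambda h: (h.start, h.strand))
    return out


def build_consensus(aligned_sites: Sequence[str], threshold: float = 0.8,
                    pair_min_each: float = 0.25) -> DegeneratePattern:
    """Build an IUPAC consensus from equal-length aligned sites.

    Per column: emit the base if its frequency >= ``threshold``; emit the
    two-base IUPAC code if the top two bases jointly reach the threshold and
    each occurs at >= ``pair_min_each``; otherwise N. This regenerates the
    shape of sequence-logo-derived consensi: conserved anchors in a sea of N.
    """
    if len(aligned_sites) < 2:
        raise ValueError("need at least 2 sites")
    w = len(aligned_sites[0])
    if any(len(s) != w for s in aligned_sites):
        raise ValueError("aligned sites must have equal length")
    two_base = {frozenset(v): k for k, v in IUPAC.items() if len(v) == 2}
    n = len(aligned_sites)
    cols, letters = [], []
    for j in range(w):
        counts = {b: 0 for b in "ACGT"}
        for s in aligned_sites:
            b = s[j].upper()
            if b in counts:
                counts[b] += 1
        cols.append(counts)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        (b1, c1), (b2, c2) = ranked[0], ranked[1]
        if c1 / n >= threshold:
            letters.append(b1)
        elif (c1 + c2) / n >= threshold and c1 / n >= pair_min_each and c2 / n >= pair_min_each:
            letters.append(two_base[frozenset((b1, b2))])
        else:
            letters.append("N")
    return DegeneratePattern("".join(letters), cols)


# ---------------------------------------------------------------------------
# Hairpin thermodynamics (DNA nearest-neighbor model, 37 C, 1 M NaCl)
# ---------------------------------------------------------------------------

# Unified DNA nearest-neighbor stack free energies, dG37 in kcal/mol.
# Keyed by the top-strand dinucleotide read 5'->3' (bottom strand is its
# Watson-Crick complement); values for a pair and its reverse complement are
# identical by symmetry.
NN_STACK_DG37 = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}

# Hairpin loop initiation penalties, dG37 in kcal/mol, by loop length.
HAIRPIN_LOOP_DG37 = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.1, 8: 4.1, 9: 4.2, 10: 4.3,
    12: 4.5, 14: 4.6, 16: 4.7, 18: 4.8, 20: 4.9, 25: 5.2, 30: 5.6,
}

# A mismatched pair inside the stem contributes no stacks and this penalty.
STEM_MISMATCH_PENALTY = 1.0

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _loop_penalty(loop_len: int) -> float:
    if loop_len in HAIRPIN_LOOP_DG37:
        return HAIRPIN_LOOP_DG37[loop_len]
    keys = sorted(HAIRPIN_LOOP_DG37)
    if loop_len > keys[-1]:
        # logarithmic extrapolation beyond the table
        import math
        return HAIRPIN_LOOP_DG37[keys[-1]] + 1.75 * 0.616 * math.log(loop_len / keys[-1])
    lo = max(k for k in keys if k < loop_len)
    hi = min(k for k in keys if k > loop_len)
    frac = (loop_len - lo) / (hi - lo)
    return HAIRPIN_LOOP_DG37[lo] + frac * (HAIRPIN_LOOP_DG37[hi] - HAIRPIN_LOOP_DG37[lo])


def hairpin_delta_g(stem5: str, loop: str, stem3: str) -> float:
    """Additive nearest-neighbor free energy of a DNA hairpin, kcal/mol.

    ``stem5`` and ``stem3`` are the two stem arms 5'->3' (so stem3 should be
    the reverse complement of stem5 except at declared mismatch positions);
    ``loop`` is the unpaired loop, length >= 3. dG = sum of stack energies
    over consecutive Watson-Crick pairs + a loop-initiation penalty tabulated
    by loop length + a fixed penalty per internal mismatched pair. A zero
    length stem has no stabilizing stacks, so dG >= 0.
    """
    stem5, loop, stem3 = stem5.upper(), loop.upper(), stem3.upper()
    if len(stem5) != len(stem3):
        raise ValueError("stem arms must have equal length")
    if len(loop) < 3:
        raise ValueError("hairpin loop must be at least 3 nt")
    n = len(stem5)
    # pair i: stem5[i] vs stem3[n-1-i]
    paired = [(_WC.get(stem5[i]) == stem3[n - 1 - i]) for i in range(n)]
    dg = _loop_penalty(len(loop))
    dg += STEM_MISMATCH_PENALTY * sum(1 for p in paired if not p)
    for i in range(n - 1):
        if paired[i] and paired[i + 1]:
            dg += NN_STACK_DG37[stem5[i : i + 2]]
    return round(dg, 2)


@dataclass
class TerminatorCall:
    stem_len: int
    loop_len: int
    left_arm: tuple[int, int]   # 0-based half-open, forward strand
    right_arm: tuple[int, int]
    strand: str
    delta_g: float
    polyt_tail: tuple[int, int]
    intergenic: bool
    n_mismatches: int = 0
    hairpin_seq: str = ""

    @property
    def start(self) -> int:
        return min(self.left_arm[0], self.polyt_tail[0])

    @property
    def end(self) -> int:
        return max(self.right_arm[1], self.polyt_tail[1])


def _polyt_runs(seq: str, min_t: int) -> list[tuple[int, int]]:
    runs, i, L = [], 0, len(seq)
    while i < L:
        if seq[i] == "T":
            j = i
            while j < L and seq[j] == "T":
                j += 1
            if j - i >= min_t:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _cds_mask(genome: AnnotatedGenome) -> np.ndarray:
    mask = np.zeros(len(genome), dtype=bool)
    for f in genome.cds:
        mask[f.start : f.end] = True
    return mask


def find_terminators(genome: AnnotatedGenome, dg_max: float = -10.0,
                     min_t: int = 4, polyt_window: int = 8,
                     require_intergenic: bool = True,
                     stem_range: tuple[int, int] = (4, 20),
                     loop_range: tuple[int, int] = (3, 10),
                     max_stem_mismatch: int = 1) -> list[TerminatorCall]:
    """Call rho-independent terminators: hairpin + polyT tail + dG gate.

    The search is anchored on polyT runs (a run of >= ``min_t`` T's must begin
    within ``polyt_window`` bp downstream of the hairpin's 3' arm,
    strand-aware), mirroring how such terminators are found by inspecting
    secondary structure adjacent to polyT tracts. For each anchor the
    lowest-dG hairpin over stems of ``stem_range`` bp and loops of
    ``loop_range`` nt with at most ``max_stem_mismatch`` internal mismatches
    is evaluated and reported iff dG < ``dg_max`` and (optionally) the whole
    call avoids every CDS interval on either strand.
    """
    if require_intergenic and not genome.cds:
        raise ValueError("require_intergenic needs CDS features on the genome")
    L = len(genome)
    cds = _cds_mask(genome) if require_intergenic else np.zeros(L, dtype=bool)
    smin, smax = stem_range
    lmin, lmax = loop_range
    calls: list[TerminatorCall] = []
    for strand, seq in (("+", genome.sequence), ("-", revcomp(genome.sequence))):
        for run_start, run_end in _polyt_runs(seq, min_t):
            best: Optional[tuple[float, tuple]] = None
            # 3' arm must end within polyt_window bp upstream of the run start
            for arm_end in range(max(run_start - polyt_window, smin + lmin + smin),
                                 run_start + 1):
                for stem in range(smin, smax + 1):
                    for loop in range(lmin, lmax + 1):
                        right_s = arm_end - stem
                        left_e = right_s - loop
                        left_s = left_e - stem
                        if left_s < 0:
                            continue
                        s5 = seq[left_s:left_e]
                        s3 = seq[right_s:arm_end]
                        mism = sum(1 for i in range(stem)
                                   if _WC.get(s5[i]) != s3[stem - 1 - i])
                        if mism > max_stem_mismatch:
                            continue
                        # terminal pairs must close the stem
                        if _WC.get(s5[0]) != s3[-1] or _WC.get(s5[-1]) != s3[0]:
                            continue
                        dg = hairpin_delta_g(s5, seq[left_e:right_s], s3)
                        key = (dg, (left_s, left_e, right_s, arm_end, stem, loop, mism))
                        if best is None or dg < best[0]:
                            best = key
            if best is None or best[0] >= dg_max:
                continue
            dg, (left_s, left_e, right_s, arm_end, stem, loop, mism) = best
            if strand == "+":
                la, ra = (left_s, left_e), (right_s, arm_end)
                tail = (run_start, run_end)
            else:
                la = (L - arm_end, L - right_s)
                ra = (L - left_e, L - left_s)
                tail = (L - run_end, L - run_start)
            span_lo = min(la[0], tail[0])
            span_hi = max(ra[1], tail[1])
            intergenic = not cds[span_lo:span_hi].any()
            if require_intergenic and not intergenic:
                continue
            calls.append(TerminatorCall(
                stem_len=stem, loop_len=loop, left_arm=la, right_arm=ra,
                strand=strand, delta_g=dg, polyt_tail=tail,
                intergenic=intergenic, n_mismatches=mism,
                hairpin_seq=seq[left_s:arm_end],
            ))
    calls.sort(key=lambda c: (c.start, c.strand))
    return calls


def validate_terminator(genome: AnnotatedGenome, call: TerminatorCall,
                        dg_max: float = -10.0, min_t: int = 4,
                        polyt_window: int = 8) -> bool:
    """Independently re-check a terminator call against the reporting rules."""
    L = len(genome)
    seq = genome.sequence if call.strand == "+" else revcomp(genome.sequence)
    if call.strand == "+":
        ls, le = call.left_arm
        rs, re_ = call.right_arm
        ts, te = call.polyt_tail
    else:
        ls, le = L - call.right_arm[1], L - call.right_arm[0]
        rs, re_ = L - call.left_arm[1], L - call.left_arm[0]
        ts, te = L - call.polyt_tail[1], L - call.polyt_tail[0]
    dg = hairpin_delta_g(seq[ls:le], seq[le:rs], seq[rs:re_])
    if not (dg < dg_max and abs(dg - call.delta_g) < 1e-9):
        return False
    if te - ts < min_t or set(seq[ts:te]) != {"T"}:
        return False
    if not (0 <= ts - re_ <= polyt_window):
        return False
    if call.intergenic:
        mask = _cds_mask(genome)
        if mask[call.start:call.end].any():
            return False
    return True


# ---------------------------------------------------------------------------
# Hit -> gene assignment
# ---------------------------------------------------------------------------

def assign_upstream(hits: Iterable[Union[MotifHit, PromoterHit]],
                    genome: AnnotatedGenome,
                    max_distance: int = 150) -> list[tuple[object, Optional[str], bool]]:
    """Assign each hit the nearest downstream same-strand CDS start.

    Returns (hit, locus_tag or None, inside_cds) triples. Distance is measured
    from the hit's downstream edge to the CDS start (strand-aware); hits with
    no CDS start within ``max_distance`` are unassigned. A hit lying inside a
    same-strand CDS is still assigned to the next start but flagged.
    """
    plus_starts = sorted((f.start, f.locus_tag) for f in genome.cds if f.strand == "+")
    minus_starts = sorted((f.end, f.locus_tag) for f in genome.cds if f.strand == "-")
    cds_iv = [(f.start, f.end, f.strand) for f in genome.cds]
    out = []
    for h in hits:
        if isinstance(h, PromoterHit):
            lo, hi, strand = h.start, h.end, h.strand
        else:
            lo, hi, strand = h.position, h.position + len(h.matched_seq), h.strand
        inside = any(s <= lo and hi <= e and st == strand for s, e, st in cds_iv)
        assigned = None
        if strand == "+":
            for start, tag in plus_starts:
                if start >= hi:
                    if start - hi <= max_distance:
                        assigned = tag
                    break
        else:
            for end, tag in reversed(minus_starts):
                if end <= lo:
                    if lo - end <= max_distance:
                        assigned = tag
                    break
        out.append((h, assigned, inside))
    return out
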