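"""Protein physical properties, SDS-PAGE band matching, peptide coverage,
and a hydropathy-based holin screen.

Molecular weights use average residue masses (matching how predicted masses
are compared with gel bands and intact-mass measurements); monoisotopic
masses are available behind a flag. Isoelectric points are solved by
bisection on the Henderson-Hasselbalch net-charge function with the EMBOSS
pKa set. Transmembrane segments are called as runs of high sliding-window
mean Kyte-Doolittle hydropathy; a holin candidate is a short protein
(<= 130 aa by default) with 2-3 such segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

# Average and monoisotopic residue masses (Da); residue = amino acid - water.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
MONO_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_AVERAGE = 18.0153
WATER_MONO = 18.010565

# EMBOSS pKa values for the ionizable groups.
PKA = {"Nterm": 8.6, "Cterm": 3.6, "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
       "K": 10.8, "R": 12.5, "Y": 10.1}

# Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def protein_mw(sequence: str, monoisotopic: bool = False) -> float:
    """Molecular weight in Da: sum of residue masses plus one water."""
    sequence = sequence.upper().rstrip("*")
    if not sequence:
        raise ValueError("empty protein sequence")
    table = MONO_RESIDUE_MASS if monoisotopic else AVERAGE_RESIDUE_MASS
    total = WATER_MONO if monoisotopic else WATER_AVERAGE
    for i, aa in enumerate(sequence):
        if aa not in table:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
        total += table[aa]
    return total


def protein_kda(sequence: str, monoisotopic: bool = False) -> float:
    """Molecular weight in kDa, rounded to 1 decimal."""
    return round(protein_mw(sequence, monoisotopic) / 1000.0, 1)


def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (termini + D,E,C,Y,H,K,R)."""
    sequence = sequence.upper().rstrip("*")

    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def neg(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))

    charge = pos(PKA["Nterm"]) + neg(PKA["Cterm"])
    for aa in sequence:
        if aa in ("K", "R", "H"):
            charge += pos(PKA[aa])
        elif aa in ("D", "E", "C", "Y"):
            charge += neg(PKA[aa])
    return charge


def protein_pi(sequence: str, charge_tol: float = 0.01) -> float:
    """Isoelectric point: the pH of zero net charge, by bisection.

    The charge function is strictly decreasing in pH, so bisection on
    [0, 14] converges; iteration stops when the net charge at the midpoint is
    within ``charge_tol`` of zero (and the bracket is tighter than 1e-6 pH),
    so the returned pH satisfies the defining property to that tolerance.
    """
    sequence = sequence.upper().rstrip("*")
    if not sequence:
        raise ValueError("empty protein sequence")
    lo, hi = 0.0, 14.0
    mid = 7.0
    while hi - lo > 1e-6:
        mid = (lo + hi) / 2
        q = net_charge(sequence, mid)
        if abs(q) < charge_tol / 10:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return round(mid, 3)


# ---------------------------------------------------------------------------
# SDS-PAGE band matching
# ---------------------------------------------------------------------------

@dataclass
class BandAssignment:
    band_id: str
    observed_kda: float
    assigned_locus: Optional[str]
    predicted_kda: Optional[float]
    delta_kda: Optional[float]  # observed - predicted
    anomalous: bool


def match_bands(observed: list[tuple[str, float]], proteome: dict[str, str],
                tolerance_kda: float = 8.0) -> list[BandAssignment]:
    """Assign each gel band the proteome member of nearest predicted mass.

    Bands with no candidate within ``tolerance_kda`` stay unassigned and are
    flagged anomalous — the signature of gel-mobility anomalies where a large
    protein reforms a compact structure and runs far below its true mass.
    Multiple bands may hit the same protein; callers can flag duplicates.
    """
    if not proteome:
        raise ValueError("empty proteome")
    predicted = {locus: protein_mw(seq) / 1000.0 for locus, seq in proteome.items()}
    out = []
    for band_id, kda in observed:
        locus, pred = min(predicted.items(), key=lambda kv: abs(kda - kv[1]))
        if abs(kda - pred) <= tolerance_kda:
            out.append(BandAssignment(band_id, kda, locus, round(pred, 1),
                                      round(kda - pred, 1), False))
        else:
            out.append(BandAssignment(band_id, kda, None, None, None, True))
    return out


# ---------------------------------------------------------------------------
# Peptide coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageResult:
    locus_tag: str
    protein_len: int
    covered_residues: int
    percent: float
    unmatched_peptides: list[str]


def peptide_coverage(protein: str, peptides: list[str],
                     locus_tag: str = "") -> CoverageResult:
    """Fraction of residues covered by exact peptide placements.

    Every occurrence of every peptide contributes to a coverage union, so each
    residue counts once however many peptides span it. Peptides with no exact
    placement are reported unmatched.
    """
    protein = protein.upper().rstrip("*")
    covered = [False] * len(protein)
    unmatched = []
    for pep in peptides:
        pep = pep.upper()
        found = False
        start = protein.find(pep)
        while start != -1:
            found = True
            for i in range(start, start + len(pep)):
                covered[i] = True
            start = protein.find(pep, start + 1)
        if not found:
            unmatched.append(pep)
    n = sum(covered)
    pct = round(100.0 * n / len(protein), 1) if protein else 0.0
    return CoverageResult(locus_tag, len(protein), n, pct, unmatched)


# ---------------------------------------------------------------------------
# Transmembrane / holin screen
# ---------------------------------------------------------------------------

@dataclass
class TMCandidate:
    locus_tag: str
    length_aa: int
    tm_segments: list[tuple[int, int]]  # 0-based half-open residue spans
    holin_like: bool


def hydropathy_profile(sequence: str, window: int = 19) -> list[float]:
    """Sliding-window mean Kyte-Doolittle hydropathy (one value per window)."""
    vals = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in sequence.upper().rstrip("*")]
    if len(vals) < window:
        return []
    csum = [0.0]
    for v in vals:
        csum.append(csum[-1] + v)
    return [(csum[i + window] - csum[i]) / window for i in range(len(vals) - window + 1)]


def tm_segments(sequence: str, window: int = 19, cutoff: float = 1.6,
                merge_gap: int = 5) -> list[tuple[int, int]]:
    """Maximal runs of residues whose centered-window hydropathy >= cutoff.

    A residue is membrane-like when the mean hydropathy of the full ``window``
    centered on it reaches the cutoff (residues too close to either terminus
    for a full window are not marked). Runs separated by fewer than
    ``merge_gap`` residues are merged — one membrane pass often shows as a
    briefly interrupted peak.
    """
    prof = hydropathy_profile(sequence, window)
    half = window // 2
    spans: list[list[int]] = []
    for i, v in enumerate(prof):
        center = i + half
        if v >= cutoff:
            if spans and center == spans[-1][1]:
                spans[-1][1] = center + 1
            else:
                spans.append([center, center + 1])
    merged: list[list[int]] = []
    for s in spans:
        if merged and s[0] - merged[-1][1] < merge_gap:
            merged[-1][1] = s[1]
        else:
            merged.append(s)
    return [(a, b) for a, b in merged]


def find_tm_candidates(proteome: dict[str, str], max_len: int = 130,
                       window: int = 19, hydropathy_cutoff: float = 1.6,
                       min_segments: int = 2, max_segments: int = 3) -> list[TMCandidate]:
    """Screen a proteome for holin-like proteins.

    A holin candidate is short (<= max_len residues) with 2-3 predicted
    transmembrane segments; all proteins are reported with their segments so
    near-misses remain inspectable.
    """
    if not proteome:
        raise ValueError("empty proteome")
    out = []
    for locus, seq in proteome.items():
        seq = seq.upper().rstrip("*")
        segs = tm_segments(seq, window, hydropathy_cutoff)
        holin = len(seq) <= max_len and min_segments <= len(segs) <= max_segments
        out.append(TMCandidate(locus, len(seq), segs, holin))
    return out
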