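"""Phage/host codon-usage comparison and tRNA decoding checks.

"Frequency" of a codon means its relative frequency within its synonymous
family (all codons encoding the same amino acid under translation table 11) —
the only reading under which a rule like "frequency >= 30%" is meaningful for
2-6-codon families. A per-1000-codons measure is available via
``per_thousand`` for completeness.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE11 = unambiguous_dna_by_id[11]
ALL_CODONS = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
STOPS = set(_TABLE11.stop_codons)

#: codon -> amino acid (single letter), '*' for stops, translation table 11
CODON_TO_AA = {c: _TABLE11.forward_table.get(c, "*") for c in ALL_CODONS}

#: amino acid -> synonymous codon family
AA_FAMILIES: dict[str, list[str]] = {}
for _c, _aa in CODON_TO_AA.items():
    AA_FAMILIES.setdefault(_aa, []).append(_c)


@dataclass
class CodonTable:
    counts: dict[str, int]
    organism_id: str = ""

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        for c, n in self.counts.items():
            c = c.upper().replace("U", "T")
            if c not in full:
                raise ValueError(f"invalid codon {c!r}")
            if n < 0:
                raise ValueError("codon counts must be >= 0")
            full[c] += n
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def codon_counts(cds_sequences: list[str], organism_id: str = "") -> CodonTable:
    """Count every codon (start and stop included) over a CDS collection.

    Sequences whose length is not a multiple of 3 are skipped with a warning
    reporting how many were dropped.
    """
    counts: dict[str, int] = {}
    skipped = 0
    for seq in cds_sequences:
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            skipped += 1
            continue
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] = counts.get(codon, 0) + 1
    if skipped:
        warnings.warn(f"skipped {skipped} CDS with length not a multiple of 3")
    return CodonTable(counts, organism_id)


def synonymous_frequencies(table: CodonTable,
                           include_stops: bool = False) -> dict[str, Optional[float]]:
    """Relative frequency of each codon within its synonymous family.

    Families with zero total count map to None (unobserved, not zero). Stop
    codons are excluded from normalization unless ``include_stops``.
    """
    if table.total == 0:
        raise ValueError("empty codon table")
    freqs: dict[str, Optional[float]] = {}
    for aa, family in AA_FAMILIES.items():
        if aa == "*" and not include_stops:
            for c in family:
                freqs[c] = None
            continue
        fam_total = sum(table.counts[c] for c in family)
        for c in family:
            freqs[c] = table.counts[c] / fam_total if fam_total else None
    return freqs


def per_thousand(table: CodonTable) -> dict[str, float]:
    """Codon usage per 1000 codons (alternative frequency basis)."""
    if table.total == 0:
        raise ValueError("empty codon table")
    return {c: 1000.0 * n / table.total for c, n in table.counts.items()}


@dataclass
class OverrepresentationCall:
    codon: str
    amino_acid: str
    phage_freq: float
    host_freq: Optional[float]
    fold: float  # math.inf when host_freq == 0
    flagged: bool


def overrepresented_codons(phage: CodonTable, host: CodonTable,
                           freq_min: float = 0.30,
                           fold_min: float = 1.5) -> list[OverrepresentationCall]:
    """Flag codons overrepresented in the phage relative to the host.

    A codon is flagged when its phage within-family frequency is >= freq_min
    and at least fold_min times the host frequency. A host frequency of 0 with
    a qualifying phage frequency flags with fold = inf.
    """
    pf = synonymous_frequencies(phage)
    hf = synonymous_frequencies(host)
    calls = []
    for codon in ALL_CODONS:
        aa = CODON_TO_AA[codon]
        if aa == "*":
            continue
        p, h = pf[codon], hf[codon]
        if p is None:
            continue
        if h is None or h == 0.0:
            fold = math.inf if p > 0 else 0.0
        else:
            fold = p / h
        calls.append(OverrepresentationCall(
            codon=codon, amino_acid=aa, phage_freq=p, host_freq=h, fold=fold,
            flagged=(p >= freq_min and fold >= fold_min),
        ))
    return calls


def comparison_frame(phage: CodonTable, host: CodonTable,
                     freq_min: float = 0.30, fold_min: float = 1.5) -> pd.DataFrame:
    """64-row codon comparison table (counts, family frequencies, fold, flag)."""
    pf = synonymous_frequencies(phage)
    hf = synonymous_frequencies(host)
    flags = {c.codon: (c.fold, c.flagged)
             for c in overrepresented_codons(phage, host, freq_min, fold_min)}
    rows = []
    for codon in ALL_CODONS:
        fold, flagged = flags.get(codon, (float("nan"), False))
        rows.append({
            "codon": codon, "aa": CODON_TO_AA[codon],
            "phage_count": phage.counts[codon], "phage_freq": pf[codon],
            "host_count": host.counts[codon], "host_freq": hf[codon],
            "fold": fold, "flagged": flagged,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tRNA decoding
# ---------------------------------------------------------------------------

_WC_PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

#: wobble pairing at the codon third position: anticodon 5' base -> codon 3' bases
WOBBLE = {"G": "CT", "T": "AG", "A": "T", "C": "G"}


def trna_decodes(anticodon: str, codon: str) -> bool:
    """Can a tRNA with this anticodon (DNA alphabet, 5'->3') decode the codon?

    Codon positions 1 and 2 must pair Watson-Crick with anticodon positions 3
    and 2 respectively; the codon third position pairs with the anticodon 5'
    base either Watson-Crick or by the wobble rules (G:T/C, T:A/G, A:T, C:G).
    """
    anticodon = anticodon.upper().replace("U", "T")
    codon = codon.upper().replace("U", "T")
    if len(anticodon) != 3 or len(codon) != 3:
        raise ValueError("anticodon and codon must be triplets")
    if (codon[0], anticodon[2]) not in _WC_PAIR:
        return False
    if (codon[1], anticodon[1]) not in _WC_PAIR:
        return False
    return codon[2] in WOBBLE[anticodon[0]]


def trnas_enhance_translation(anticodons: list[str],
                              calls: list[OverrepresentationCall]) -> dict[str, list[str]]:
    """Which flagged (overrepresented) codons can the phage tRNAs decode?

    Returns anticodon -> list of flagged codons it decodes; all-empty lists
    mean the tRNA complement is unlikely to enhance translation of the biased
    codons.
    """
    flagged = [c.codon for c in calls if c.flagged]
    return {ac: [cod for cod in flagged if trna_decodes(ac, cod)]
            for ac in anticodons}
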