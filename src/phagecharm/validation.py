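"""Validation against a deposited, annotated phage genome record.

The toolkit's synthetic generator covers day-to-day testing; this module is
the optional validation surface against a real deposited record (the study
genome, accession FJ373894). It needs one small network download — or a
locally cached copy of the GenBank flat file — and recomputes the record's
headline statistics from the parsed sequence and annotation.
"""

from __future__ import annotations

import os
import urllib.request
from typing import Optional

from . import genome_io, proteomics
from .model import AnnotatedGenome

STUDY_ACCESSION = "FJ373894"

#: Published host-range reactions of the study phage on 24 Shigella strains
#: (the printed host-range table), usable as input to summarize_host_range.
STUDY_REACTIONS = {
    "S. boydii C865": "D+", "S. sonnei C866": "C", "S. flexneri C869": "C",
    "S. sonnei C870": "C", "S. flexneri 61-1186": "N",
    "S. flexneri 71-2747": "C", "S. flexneri 04-3435": "C",
    "S. flexneri 95-3239": "C", "S. flexneri 05-3605": "C",
    "S. flexneri 86-3239": "N", "S. boydii 74-1789": "D+",
    "S. boydii 74-4334": "D+", "S. boydii 79-1109": "C",
    "S. boydii 74-3594": "D", "S. boydii 84-1119": "N",
    "S. boydii 83-578": "D+", "S. boydii 99-4528": "D+",
    "S. dysenteriae 04-3380": "C", "S. dysenteriae 91-3501": "D+",
    "S. dysenteriae 53-4738": "N", "S. dysenteriae 52-2050": "C",
    "S. dysenteriae 69-2387": "D+", "S. dysenteriae 94-3065": "C",
    "S. dysenteriae 79-8006": "D+",
}
EFETCH_URL = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
              "?db=nucleotide&id={acc}&rettype=gbwithparts&retmode=text")

#: Conventional cache locations checked before downloading.
CACHE_CANDIDATES = (
    "scratch/{acc}.gb",
    "{acc}.gb",
    os.path.expanduser("~/.cache/phagecharm/{acc}.gb"),
)


def fetch_genbank(accession: str = STUDY_ACCESSION, dest: Optional[str] = None,
                  timeout: float = 30.0) -> str:
    """Download a GenBank flat file from NCBI efetch; returns the local path.

    Raises URLError/OSError when the network is unavailable.
    """
    dest = dest or f"{accession}.gb"
    url = EFETCH_URL.format(acc=accession)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    if not data.startswith(b"LOCUS"):
        raise ValueError(f"efetch for {accession} did not return a GenBank record")
    with open(dest, "wb") as fh:
        fh.write(data)
    return dest


def load_study_genome(timeout: float = 30.0) -> AnnotatedGenome:
    """Load the study genome from a cached copy, else download it."""
    for tmpl in CACHE_CANDIDATES:
        path = tmpl.format(acc=STUDY_ACCESSION)
        if os.path.exists(path):
            return genome_io.read_genbank(path)
    path = fetch_genbank(STUDY_ACCESSION,
                         dest=os.path.join(os.getcwd(), f"{STUDY_ACCESSION}.gb"),
                         timeout=timeout)
    return genome_io.read_genbank(path)


def deposited_genome_checks(genome: AnnotatedGenome) -> dict:
    """Recompute the deposited record's headline statistics.

    Returns length, GC percent, CDS count, ATG start fraction, tRNA count and
    GC range, and the predicted masses (kDa) of the gp206 and gp185
    translations, located by locus-tag suffix.
    """
    stats = genome_io.genome_summary(genome)
    out = {
        "length_bp": stats.length_bp,
        "gc_percent": stats.gc_percent,
        "cds_count": len(genome.cds),
        "atg_start_percent": stats.start_codon_usage.get("ATG", 0.0),
        "trna_count": stats.trna_count,
        "trna_gc_max": stats.trna_gc_range[1] if stats.trna_gc_range else None,
    }
    for suffix, key in (("206", "gp206_kda"), ("185", "gp185_kda")):
        matches = [f for f in genome.cds
                   if f.translation and f.locus_tag.endswith(suffix)]
        out[key] = proteomics.protein_kda(matches[0].translation) if matches else None
    return out
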