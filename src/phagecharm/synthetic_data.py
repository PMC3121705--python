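"""Synthetic genomes, microplates and proteome pairs with known ground truth.

Every other module is testable without downloads because this generator
plants the features those modules are supposed to recover — genes with
Shine-Dalgarno-like upstream hexamers, sigma70 and late-promoter motifs,
rho-independent terminators with designed free energies, codon-biased coding
sequences, homolog pairs at a target identity, and Bioscreen-style growth
curves with category-determined delays — and emits the exact coordinates and
labels of everything it planted.

A single integer seed drives one explicit ``numpy.random.Generator`` passed
through all sampling; identical spec + seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .codon_usage import AA_FAMILIES, ALL_CODONS, CODON_TO_AA
from .host_range import GrowthCurve
from .model import AnnotatedGenome, Feature, revcomp
from .orf_caller import DEFAULT_STARTS, SD_MOTIF, STOP_CODONS
from .regulatory import hairpin_delta_g

AA20 = sorted(set(CODON_TO_AA.values()) - {"*"})


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside generated data."""

    planted_cds: list[tuple] = field(default_factory=list)
    # (start, end, strand, start_codon, rbs_seq) — 0-based half-open, end past stop
    planted_promoters: list[tuple] = field(default_factory=list)
    # (position, strand, kind) — position = 0-based motif/-35 start
    planted_terminators: list[tuple] = field(default_factory=list)
    # (position, strand, delta_g_design) — position = 0-based hairpin start
    codon_bias: dict = field(default_factory=dict)
    plate_truth: dict = field(default_factory=dict)
    # strain -> (category, planted_delay_h)
    homolog_truth: list[tuple] = field(default_factory=list)
    # (locus_a, locus_b, target_identity)


@dataclass
class GenomeSpec:
    length: int = 20_000
    gc: float = 0.50
    n_genes: int = 10
    rbs_quality: int = 6  # matches of the planted hexamer to GGAGGT (0..6)
    n_promoters: int = 3
    promoter_kind: str = "sigma70"  # sigma70 | late
    n_terminators: int = 2
    codon_bias: Optional[dict[str, float]] = None  # codon -> within-family fraction
    gene_codons: tuple[int, int] = (60, 200)  # body codons after the start
    min_gap: int = 60


def _background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n else ""


def _codon_weights(gc: float, bias: Optional[dict[str, float]]) -> dict[str, np.ndarray]:
    """Per-family codon sampling weights, GC-matched unless biased."""
    pbase = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    weights = {}
    for aa, family in AA_FAMILIES.items():
        if aa == "*":
            continue
        w = np.array([np.prod([pbase[b] for b in c]) for c in family], dtype=float)
        if bias:
            forced = {c: f for c, f in bias.items() if c in family}
            if forced:
                rest = [c for c in family if c not in forced]
                left = 1.0 - sum(forced.values())
                base = w / w.sum()
                rest_total = sum(base[family.index(c)] for c in rest) or 1.0
                w = np.array([
                    forced.get(c, left * base[family.index(c)] / rest_total)
                    for c in family
                ])
        weights[aa] = w / w.sum()
    return weights


def _sample_cds_body(rng: np.random.Generator, n_codons: int,
                     weights: dict[str, np.ndarray]) -> str:
    aas = rng.choice(AA20, size=n_codons)
    out = []
    for aa in aas:
        fam = AA_FAMILIES[aa]
        out.append(fam[int(rng.choice(len(fam), p=weights[aa]))])
    return "".join(out)


def _mutate_hexamer(rng: np.random.Generator, motif: str, n_matches: int) -> str:
    """A hexamer agreeing with ``motif`` at exactly n_matches positions."""
    seq = list(motif)
    to_change = rng.choice(len(motif), size=len(motif) - n_matches, replace=False)
    for i in to_change:
        choices = [b for b in "ACGT" if b != motif[i]]
        seq[i] = choices[int(rng.integers(3))]
    return "".join(seq)


def _gene_block(rng: np.random.Generator, spec: GenomeSpec,
                weights: dict[str, np.ndarray]) -> tuple[str, dict]:
    """One planted gene: [RBS hexamer][spacer][start][body][stop]."""
    rbs = _mutate_hexamer(rng, SD_MOTIF, spec.rbs_quality)
    offset = int(rng.integers(4, 17))  # motif 3' end to start codon, bp
    spacer = _background(rng, offset, spec.gc)
    start_codon = DEFAULT_STARTS[int(rng.integers(len(DEFAULT_STARTS)))] \
        if spec.rbs_quality >= 4 else "ATG"
    n_codons = int(rng.integers(spec.gene_codons[0], spec.gene_codons[1] + 1))
    body = _sample_cds_body(rng, n_codons, weights)
    stop = STOP_CODONS[int(rng.integers(3))]
    block = rbs + spacer + start_codon + body + stop
    meta = {"rbs": rbs, "offset": offset, "start_codon": start_codon,
            "cds_rel_start": len(rbs) + offset, "cds_rel_end": len(block)}
    return block, meta


def _promoter_block(rng: np.random.Generator, kind: str, gc: float) -> tuple[str, int]:
    """Planted promoter element; returns (block, motif start within block)."""
    if kind == "sigma70":
        spacer = int(rng.integers(15, 19))
        return "TTGACA" + _background(rng, spacer, gc) + "TATAAT", 0
    if kind == "late":
        return "TATAAATA", 0
    raise ValueError(f"unknown promoter kind {kind!r}")


_STRONG_STEMS = ["GCCGCGGCCG", "CGGCGCCGGC", "GGCGCGCCGG"]


def _terminator_block(rng: np.random.Generator, gc: float) -> tuple[str, float, int]:
    """A strong designed terminator: GC stem-loop + T8 tail.

    Returns (block, designed delta_g, hairpin start within block).
    """
    stem5 = _STRONG_STEMS[int(rng.integers(len(_STRONG_STEMS)))]
    loop = "".join(rng.choice(list("ACT"), size=4))  # no G: avoids stem slippage
    stem3 = revcomp(stem5)
    dg = hairpin_delta_g(stem5, loop, stem3)
    block = stem5 + loop + stem3 + "T" * 8 + "A"  # A caps the T run
    return block, dg, 0


def generate_genome(spec: GenomeSpec, seed: int) -> tuple[AnnotatedGenome, SyntheticTruth]:
    """Generate a genome with planted genes and regulatory elements.

    Genes are laid out left to right with intergenic background gaps; planted
    promoters and terminators go into distinct gaps (never inside genes), so
    every recovery metric is unambiguous. Raises on an infeasible spec,
    naming the violated constraint.
    """
    rng = np.random.default_rng(seed)
    if not 0.0 < spec.gc < 1.0:
        raise ValueError("infeasible spec: gc must be in (0, 1)")
    if spec.gene_codons[0] < 31:
        raise ValueError("infeasible spec: genes need >= 31 body codons to satisfy "
                         "the 30-additional-codon rule")
    weights = _codon_weights(spec.gc, spec.codon_bias)

    genes, gene_strands = [], []
    for _ in range(spec.n_genes):
        block, meta = _gene_block(rng, spec, weights)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((block, meta))
        gene_strands.append(strand)

    n_gaps = spec.n_genes + 1
    elements: list[tuple[str, object]] = []  # (type, payload)
    for _ in range(spec.n_promoters):
        elements.append(("promoter", _promoter_block(rng, spec.promoter_kind, spec.gc)))
    for _ in range(spec.n_terminators):
        elements.append(("terminator", _terminator_block(rng, spec.gc)))
    elems_by_gap: dict[int, list[tuple[str, object]]] = {}
    for elem in elements:
        elems_by_gap.setdefault(int(rng.integers(n_gaps)), []).append(elem)

    # each gap must hold the background minimum plus its elements with margins
    margin = 12
    gap_min = [spec.min_gap +
               sum(len(e[1][0]) + margin for e in elems_by_gap.get(i, []))
               for i in range(n_gaps)]
    gene_total = sum(len(b) for b, _ in genes)
    gap_total = spec.length - gene_total
    if gap_total < sum(gap_min):
        raise ValueError(
            f"infeasible spec: length {spec.length} leaves {gap_total} bp for gaps "
            f"but {sum(gap_min)} bp are required for {n_gaps} gaps and "
            f"{len(elements)} intergenic elements")
    # split the spare gap length randomly across gaps
    spare = gap_total - sum(gap_min)
    if n_gaps > 1:
        cuts = np.sort(rng.integers(0, spare + 1, size=n_gaps - 1))
        shares = np.diff(np.concatenate([[0], cuts, [spare]]))
    else:
        shares = [spare]
    gap_lens = [m + int(s) for m, s in zip(gap_min, shares)]

    truth = SyntheticTruth(codon_bias=dict(spec.codon_bias or {}))
    parts: list[str] = []
    pos = 0
    features: list[Feature] = []

    for gap_idx in range(n_gaps):
        gap = _background(rng, gap_lens[gap_idx], spec.gc)
        at = 10  # left margin inside the gap
        for etype, payload in elems_by_gap.get(gap_idx, []):
            block = payload[0]
            # random jitter within this element's slot, keeping order and margins
            at += int(rng.integers(0, margin - 10 + 1))
            gap = gap[:at] + block + gap[at + len(block):]
            abs_pos = pos + at
            if etype == "promoter":
                truth.planted_promoters.append((abs_pos, "+", spec.promoter_kind))
            else:
                truth.planted_terminators.append((abs_pos, "+", payload[1]))
            at += len(block) + 10
        parts.append(gap)
        pos += len(gap)
        if gap_idx < spec.n_genes:
            block, meta = genes[gap_idx]
            strand = gene_strands[gap_idx]
            emitted = block if strand == "+" else revcomp(block)
            if strand == "+":
                cds_start = pos + meta["cds_rel_start"]
                cds_end = pos + meta["cds_rel_end"]
            else:
                cds_start = pos + len(block) - meta["cds_rel_end"]
                cds_end = pos + len(block) - meta["cds_rel_start"]
            truth.planted_cds.append(
                (cds_start, cds_end, strand, meta["start_codon"], meta["rbs"]))
            features.append(Feature("CDS", cds_start, cds_end, strand,
                                    locus_tag=f"synth{gap_idx + 1:03d}"))
            parts.append(emitted)
            pos += len(emitted)

    sequence = "".join(parts)
    assert len(sequence) == spec.length
    genome = AnnotatedGenome("synthetic", sequence, "linear", features)
    return genome, truth


# ---------------------------------------------------------------------------
# Growth-curve plates
# ---------------------------------------------------------------------------

def _logistic_od(times_h: np.ndarray, delay_h: float, baseline: float = 0.1,
                 capacity: float = 1.2, rate: float = 1.0,
                 midpoint_h: float = 6.0) -> np.ndarray:
    t0 = midpoint_h + delay_h
    return baseline + (capacity - baseline) / (1.0 + np.exp(-rate * (times_h - t0)))


def simulate_growth_curves(strains: list[str], categories: dict[str, str],
                           noise_sd: float = 0.0, seed: int = 0,
                           duration_h: float = 24.0, cadence_min: float = 20.0,
                           replicates: int = 3) -> tuple[list[GrowthCurve], SyntheticTruth]:
    """Bioscreen-style plate: logistic growth with category-determined delays.

    Control wells grow undisturbed; phage wells are delayed by 0 h (N),
    uniform 1-4 h (D), uniform 5-10 h (D+), or held at baseline (C). Each arm
    is run in ``replicates`` wells with additive Gaussian noise, read at
    ``cadence_min`` over ``duration_h``.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_h + 1e-9, cadence_min / 60.0)
    truth = SyntheticTruth()
    curves: list[GrowthCurve] = []
    for strain in strains:
        cat = categories[strain]
        if cat == "N":
            delay = 0.0
        elif cat == "D":
            delay = float(rng.uniform(1.0, 4.0))
        elif cat == "D+":
            delay = float(rng.uniform(5.0, 10.0))
        elif cat == "C":
            delay = float("inf")
        else:
            raise ValueError(f"unknown category {cat!r} for strain {strain!r}")
        truth.plate_truth[strain] = (cat, delay)
        for treatment, d in (("control", 0.0), ("phage", delay)):
            for rep in range(replicates):
                if np.isinf(d):
                    od = np.full_like(times, 0.1)
                else:
                    od = _logistic_od(times, d)
                if noise_sd > 0:
                    od = od + rng.normal(0.0, noise_sd, size=times.shape)
                curves.append(GrowthCurve(
                    times=times.tolist(), od=od.tolist(),
                    well_id=f"{strain}:{treatment}:{rep + 1}",
                    strain_id=strain, treatment=treatment,
                ))
    return curves, truth


# ---------------------------------------------------------------------------
# Proteome pairs
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, lo: int = 150, hi: int = 400) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "M" + "".join(rng.choice(AA20, size=n - 1))


def _mutate_protein(rng: np.random.Generator, seq: str, identity: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() > identity:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def generate_proteome_pair(n_each: int, n_homologs: int, target_identity: float,
                           seed: int = 0) -> tuple[dict[str, str], dict[str, str], SyntheticTruth]:
    """Two proteomes sharing ``n_homologs`` diverged pairs.

    Homologs are made by point-substituting a parent protein at rate
    1 - target_identity; the remaining proteins in each proteome are
    independent random sequences of comparable length and composition.
    """
    if n_homologs > n_each:
        raise ValueError("n_homologs cannot exceed n_each")
    rng = np.random.default_rng(seed)
    a, b = {}, {}
    truth = SyntheticTruth()
    for i in range(n_homologs):
        parent = _random_protein(rng)
        ta, tb = f"A{i + 1:03d}", f"B{i + 1:03d}"
        a[ta] = parent
        b[tb] = _mutate_protein(rng, parent, target_identity)
        truth.homolog_truth.append((ta, tb, target_identity))
    for i in range(n_homologs, n_each):
        a[f"A{i + 1:03d}"] = _random_protein(rng)
        b[f"B{i + 1:03d}"] = _random_protein(rng)
    return a, b, truth
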