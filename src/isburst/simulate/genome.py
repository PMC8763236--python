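"""Synthetic genomes with annotated genes and planted IS-element copies.

The generator emulates the census substrate of a cyanobacterial genome with a
heavy transposable-element load: protein-coding genes at a chosen density and
coding GC, AT-richer intergenic sequence, and one or more IS families planted
at specified copy number and divergence. One copy per family can be left fully
intact (a clean transposase ORF flanked by terminal inverted repeats); the
remaining copies receive single-base frameshift deletions and so carry
premature stop codons in the shifted frame, emulating pseudogenized copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._util import array_to_seq, random_seq, revcomp, seq_to_array
from ..io import Gene, GenomeAnnotation

_STOPS = {"TAA", "TAG", "TGA"}
_BASE_STR = "ACGT"


class CapacityError(ValueError):
    """A contig is too short to host the IS copies assigned to it."""


@dataclass
class ISFamilySpec:
    """Structure of one IS family to plant: a transposase gene between terminal
    inverted repeats, duplicating ``tsd_length`` bp of target on insertion."""

    family_id: str
    element_length: int = 1500
    copy_number: int = 1
    intact_copies: int = 1
    divergence: float = 0.0   # expected substitutions/site from family consensus
    itr_length: int = 14
    tsd_length: int = 8

    def __post_init__(self):
        if self.intact_copies > self.copy_number:
            raise ValueError("intact_copies must be <= copy_number")
        if self.itr_length < 0 or self.tsd_length < 0:
            raise ValueError("repeat lengths must be >= 0")
        if self.element_length <= 2 * self.itr_length:
            raise ValueError("element_length must exceed twice the ITR length")


@dataclass
class PlantedCopy:
    family_id: str
    copy_id: str
    contig: str
    start: int   # 0-based inclusive, element span
    end: int     # 0-based exclusive
    strand: str
    intact: bool
    gene_id: str


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    """n sense codons; stop draws have the third base resampled from the
    non-stop alternatives (keeps the realized GC close to the target)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    for _ in range(n):
        codon = "".join(_BASE_STR[i] for i in rng.choice(4, size=3, p=p))
        while codon in _STOPS:
            allowed = [b for b in _BASE_STR if codon[:2] + b not in _STOPS]
            w = np.array([p["ACGT".index(b)] for b in allowed])
            codon = codon[:2] + rng.choice(allowed, p=w / w.sum())
        out.append(codon)
    return "".join(out)


def _random_orf(rng: np.random.Generator, length: int, gc: float) -> str:
    """Clean ORF of exactly ``length`` bp (multiple of 3): ATG ... TAA."""
    assert length % 3 == 0 and length >= 9
    return "ATG" + _random_codons(rng, length // 3 - 2, gc) + "TAA"


def build_element_consensus(
    rng: np.random.Generator, spec: ISFamilySpec, gc: float = 0.45
) -> tuple[str, int, int]:
    """Family consensus element: ITR + 5' UTR + transposase ORF + 3' UTR +
    revcomp(ITR). Returns (sequence, orf_start, orf_end)."""
    itr = random_seq(rng, spec.itr_length, gc)
    interior = spec.element_length - 2 * spec.itr_length
    utr5 = min(6, max(0, interior - 9))
    orf_len = 3 * ((interior - utr5) // 3)
    while orf_len + utr5 > interior:
        orf_len -= 3
    utr3 = interior - utr5 - orf_len
    seq = (
        itr
        + random_seq(rng, utr5, gc)
        + _random_orf(rng, orf_len, gc)
        + random_seq(rng, utr3, gc)
        + revcomp(itr)
    )
    orf_start = spec.itr_length + utr5
    return seq, orf_start, orf_start + orf_len


def _mutate_copy(
    rng: np.random.Generator,
    consensus: str,
    divergence: float,
    orf: tuple[int, int],
    keep_orf_intact: bool,
) -> tuple[str, int, int]:
    """Apply i.i.d. per-site substitutions at the given expected rate; for
    intact copies, substitutions that would create a stop codon or destroy the
    start codon are redirected to a harmless base."""
    arr = seq_to_array(consensus).copy()
    n_sites = len(arr)
    hits = np.nonzero(rng.random(n_sites) < divergence)[0]
    orf_start, orf_end = orf
    for pos in hits:
        old = chr(arr[pos])
        choices = [b for b in _BASE_STR if b != old]
        new = rng.choice(choices)
        if keep_orf_intact and orf_start <= pos < orf_end:
            codon_i = (pos - orf_start) // 3
            n_codons = (orf_end - orf_start) // 3
            if codon_i == 0 or codon_i == n_codons - 1:
                continue  # never touch the start or terminal stop codon
            c0 = orf_start + 3 * codon_i
            codon = bytearray(arr[c0:c0 + 3])
            safe = []
            for b in choices:
                codon[pos - c0] = ord(b)
                if codon.decode() not in _STOPS:
                    safe.append(b)
            if not safe:
                continue
            new = rng.choice(safe)
        arr[pos] = ord(new)
    seq = array_to_seq(arr)
    return seq, orf_start, orf_end


def _frameshift(rng: np.random.Generator, seq: str, orf: tuple[int, int]) -> tuple[str, int, int]:
    """Delete one base inside the ORF interior (frameshift pseudogenization)."""
    orf_start, orf_end = orf
    pos = int(rng.integers(orf_start + 6, orf_end - 6))
    return seq[:pos] + seq[pos + 1:], orf_start, orf_end - 1


def generate_genome(
    n_contigs: int,
    contig_lengths: list[int],
    gc_coding: float = 0.475,
    gc_noncoding: float = 0.415,
    gene_density: float = 0.6,
    family_specs: list[ISFamilySpec] = (),
    seed: int = 0,
) -> tuple[GenomeAnnotation, list[PlantedCopy]]:
    """Build an annotated genome with planted IS copies and return the truth.

    Background contigs alternate intergenic sequence (``gc_noncoding``) with
    random-codon gene ORFs (``gc_coding``); IS elements are then inserted at
    random intergenic junctions, distributed round-robin across contigs.
    Deterministic under ``seed``.
    """
    if len(contig_lengths) != n_contigs:
        raise ValueError("contig_lengths must have n_contigs entries")
    if any(L <= 0 for L in contig_lengths):
        raise ValueError("contig lengths must be positive")
    for frac, name in ((gc_coding, "gc_coding"), (gc_noncoding, "gc_noncoding")):
        if not 0 < frac < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    rng = np.random.default_rng(seed)

    # family consensus elements
    consensus: dict[str, tuple[str, int, int]] = {}
    for spec in family_specs:
        consensus[spec.family_id] = build_element_consensus(rng, spec)

    # assign each planted copy to a contig (round-robin) and check capacity
    assignments: list[list[tuple[ISFamilySpec, int]]] = [[] for _ in range(n_contigs)]
    ci = 0
    for spec in family_specs:
        for copy_idx in range(spec.copy_number):
            assignments[ci % n_contigs].append((spec, copy_idx))
            ci += 1
    for i, assigned in enumerate(assignments):
        need = sum(spec.element_length for spec, _ in assigned)
        if need > contig_lengths[i]:
            raise CapacityError(
                f"contig {i} (length {contig_lengths[i]}) cannot host "
                f"{len(assigned)} IS copies totalling {need} bp"
            )

    contigs: dict[str, str] = {}
    genes: list[Gene] = []
    planted: list[PlantedCopy] = []
    gene_counter = 0

    for idx in range(n_contigs):
        name = f"contig_{idx}"
        target_len = contig_lengths[idx]
        # alternating intergenic / gene blocks: (seq, gene_or_None)
        blocks: list[tuple[str, bool]] = []
        mean_gene = 900
        mean_gap = max(30, int(mean_gene * (1 - gene_density) / max(gene_density, 1e-6)))
        pos = 0
        while pos < target_len:
            gap_len = min(1 + int(rng.exponential(mean_gap)), target_len - pos)
            blocks.append((random_seq(rng, gap_len, gc_noncoding), False))
            pos += gap_len
            if pos >= target_len:
                break
            glen = 3 * int(rng.integers(100, 500))
            glen = min(glen, 3 * ((target_len - pos) // 3))
            if glen < 99:
                blocks.append((random_seq(rng, target_len - pos, gc_noncoding), False))
                break
            blocks.append((_random_orf(rng, glen, gc_coding), True))
            pos += glen

        # insert IS copies at intergenic block boundaries
        copy_payloads = []
        for spec, copy_idx in assignments[idx]:
            cons, orf_s, orf_e = consensus[spec.family_id]
            intact = copy_idx < spec.intact_copies
            seq, orf_s, orf_e = _mutate_copy(rng, cons, spec.divergence, (orf_s, orf_e), intact)
            if not intact:
                seq, orf_s, orf_e = _frameshift(rng, seq, (orf_s, orf_e))
            strand = "+" if rng.random() < 0.5 else "-"
            copy_payloads.append((spec, copy_idx, seq, orf_s, orf_e, intact, strand))

        gap_positions = [i for i, (_, is_gene) in enumerate(blocks) if not is_gene]
        insert_at = sorted(
            rng.choice(gap_positions, size=len(copy_payloads), replace=len(gap_positions) < len(copy_payloads))
        ) if copy_payloads else []

        # build final sequence, tracking coordinates
        final_parts: list[str] = []
        offset = 0
        payload_iter = list(zip(insert_at, copy_payloads))
        pi = 0
        for bi, (bseq, is_gene) in enumerate(blocks):
            while pi < len(payload_iter) and payload_iter[pi][0] == bi:
                spec, copy_idx, eseq, orf_s, orf_e, intact, strand = payload_iter[pi][1]
                placed = eseq if strand == "+" else revcomp(eseq)
                start = offset
                end = offset + len(placed)
                gene_id = f"{spec.family_id}_tnp_{copy_idx}"
                if strand == "+":
                    g_start, g_end = start + orf_s, start + orf_e
                else:
                    g_start, g_end = end - orf_e, end - orf_s
                genes.append(
                    Gene(gene_id, name, g_start, g_end, strand,
                         product="transposase", family=spec.family_id, is_transposase=True)
                )
                planted.append(
                    PlantedCopy(spec.family_id, gene_id, name, start, end, strand, intact, gene_id)
                )
                final_parts.append(placed)
                offset = end
                pi += 1
            if is_gene:
                gene_counter += 1
                genes.append(
                    Gene(f"gene_{gene_counter:05d}", name, offset, offset + len(bseq), "+",
                         product="hypothetical protein")
                )
            final_parts.append(bseq)
            offset += len(bseq)
        # any payloads targeted at trailing blocks
        while pi < len(payload_iter):
            spec, copy_idx, eseq, orf_s, orf_e, intact, strand = payload_iter[pi][1]
            placed = eseq if strand == "+" else revcomp(eseq)
            start = offset
            end = offset + len(placed)
            gene_id = f"{spec.family_id}_tnp_{copy_idx}"
            if strand == "+":
                g_start, g_end = start + orf_s, start + orf_e
            else:
                g_start, g_end = end - orf_e, end - orf_s
            genes.append(Gene(gene_id, name, g_start, g_end, strand,
                              product="transposase", family=spec.family_id, is_transposase=True))
            planted.append(PlantedCopy(spec.family_id, gene_id, name, start, end, strand, intact, gene_id))
            final_parts.append(placed)
            offset = end
            pi += 1

        contigs[name] = "".join(final_parts)

    return GenomeAnnotation(contigs=contigs, genes=genes), planted
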