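"""Pairwise synonymous/nonsynonymous divergence by codon counting (NG86).

Sites are counted per codon position as the fraction of the three possible
single-base changes that preserve the encoded amino acid, averaged over the
two sequences, so that S + N = 3 x (number of compared codons) exactly
(changes creating a stop codon count as nonsynonymous sites). Observed
differences in codons differing at more than one position are averaged over
all orderings of single-base steps, excluding paths that pass through a stop
codon. Proportions are corrected for multiple hits with the Jukes-Cantor
transform d = -(3/4) ln(1 - 4p/3); p >= 3/4 leaves the rate undefined and
sets a saturation flag.

Low synonymous divergence (dS) among duplicated copies of a transposase gene
is the signature of a recent within-genome expansion, which is what this
estimator is used to date.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data import CodonTable

_STOP = "*"


def _codon_map(table_id: int = 11) -> dict[str, str]:
    tbl = CodonTable.unambiguous_dna_by_id[table_id]
    m = dict(tbl.forward_table)
    for stop in tbl.stop_codons:
        m[stop] = _STOP
    return m

_CODON_AA = _codon_map(11)
_BASES = "ACGT"


@dataclass
class DivergencePair:
    """NG86 site counts, difference counts and JC-corrected rates for one pair."""

    gene_a: str
    gene_b: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # NaN when saturated
    dN: float
    saturated_s: bool
    saturated_n: bool
    skipped_codons: int = 0  # gap- or stop-containing codon columns dropped


def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (sum over positions of syn fraction)."""
    aa = _CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _CODON_AA[alt] == aa and _CODON_AA[alt] != _STOP:
                syn += 1
        s += syn / 3.0
    return s


def _path_steps(ca: str, cb: str) -> tuple[float, float]:
    """Average (syn, nonsyn) single-base steps over stop-free mutational paths."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur = ca
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if _CODON_AA[nxt] == _STOP:
                blocked = True
                break
            steps.append(1.0 if _CODON_AA[nxt] == _CODON_AA[cur] else 0.0)
            cur = nxt
        if not blocked:
            results.append((sum(steps), len(steps) - sum(steps)))
    if not results:
        # every ordering passes through a stop: fall back to averaging over all
        # orderings with the stop exclusion lifted (degenerate but defined)
        for order in permutations(diff):
            cur = ca
            syn = 0.0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if _CODON_AA[nxt] == _CODON_AA[cur] and _CODON_AA[nxt] != _STOP:
                    syn += 1.0
                cur = nxt
            results.append((syn, len(diff) - syn))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance; NaN outside the correction domain (p >= 3/4)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _iter_codon_pairs(a: str, b: str):
    for i in range(0, len(a), 3):
        yield a[i:i + 3], b[i:i + 3]


def pairwise_dnds(cds_a: str, cds_b: str, *, name_a: str = "a", name_b: str = "b") -> DivergencePair:
    """NG86 dN/dS between two aligned coding sequences.

    Sequences may contain '-' gap characters from a codon alignment; gapped,
    ambiguous or stop-containing codon columns are dropped and counted in
    ``skipped_codons``. After gap columns are removed both sequences must have
    equal length divisible by 3.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("aligned CDS lengths differ; codon-align the pair first")
    if len(a) % 3 != 0:
        raise ValueError("aligned length not divisible by 3")

    S = N = Sd = Nd = 0.0
    n_codons = 0
    skipped = 0
    for ca, cb in _iter_codon_pairs(a, b):
        if "-" in ca or "-" in cb or any(x not in _BASES for x in ca + cb):
            skipped += 1
            continue
        if _CODON_AA[ca] == _STOP or _CODON_AA[cb] == _STOP:
            skipped += 1
            continue
        sa, sb = _syn_sites(ca), _syn_sites(cb)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        sd, nd = _path_steps(ca, cb)
        Sd += sd
        Nd += nd
        n_codons += 1

    if n_codons == 0:
        raise ValueError("no comparable codons after filtering")

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return DivergencePair(
        gene_a=name_a,
        gene_b=name_b,
        n_codons=n_codons,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=jukes_cantor(pS),
        dN=jukes_cantor(pN),
        saturated_s=pS >= 0.75,
        saturated_n=pN >= 0.75,
        skipped_codons=skipped,
    )


def codon_align(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Protein-guided codon alignment of two CDSs (pal2nal-style threading).

    Terminal stop codons are trimmed before translation. Raises on internal
    stops or lengths not divisible by 3 (frameshifted pseudogene copies cannot
    be codon-aligned and should be excluded upstream).
    """
    from Bio.Align import PairwiseAligner, substitution_matrices

    def prep(cds: str) -> str:
        cds = cds.upper().replace("-", "")
        if len(cds) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        if _CODON_AA.get(cds[-3:]) == _STOP:
            cds = cds[:-3]
        return cds

    a, b = prep(cds_a), prep(cds_b)
    prot_a = "".join(_CODON_AA[a[i:i + 3]] for i in range(0, len(a), 3))
    prot_b = "".join(_CODON_AA[b[i:i + 3]] for i in range(0, len(b), 3))
    if _STOP in prot_a or _STOP in prot_b:
        raise ValueError("internal stop codon; sequence is not a clean ORF")

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(prot_a, prot_b)[0]
    rows = str_alignment(aln)

    out_a, out_b = [], []
    ia = ib = 0
    for ra, rb in zip(*rows):
        if ra == "-":
            out_a.append("---")
        else:
            out_a.append(a[3 * ia:3 * ia + 3])
            ia += 1
        if rb == "-":
            out_b.append("---")
        else:
            out_b.append(b[3 * ib:3 * ib + 3])
            ib += 1
    return "".join(out_a), "".join(out_b)


def str_alignment(aln) -> tuple[str, str]:
    """Gapped row strings of a Bio.Align.Alignment."""
    return str(aln[0]), str(aln[1])
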