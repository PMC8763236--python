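"""Transposase census: assembly statistics, paralog clustering, IS family
annotation, pseudogene flagging, element-copy scanning and per-family
divergence summaries.

The clustering + pairwise-divergence procedure mirrors the common workflow for
dating within-genome gene duplications: cluster homologs at >=50% amino acid
identity (over the shorter sequence) and >=50% coverage (of the target), then
estimate dS/dN between cluster members. A family whose copies show near-zero
synonymous divergence has expanded recently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from ._util import gc_fraction, revcomp
from .dnds import DivergencePair, codon_align, pairwise_dnds
from .io import GenomeAnnotation

log = logging.getLogger(__name__)

_AA = set("ACDEFGHIKLMNPQRSTVWYX*")

# Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1
# (the standard gapped values); the E-value model is fixed so that the
# e <= 1e-9 annotation cutoff is well defined.
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass
class AssemblyStats:
    n_contigs: int
    total_length: int
    n50: int
    gc_overall: float
    gc_coding: float | None = None
    gc_noncoding: float | None = None


@dataclass
class ParalogCluster:
    cluster_id: str
    members: list[str]
    representative: str
    family: str = "unclassified"


def assembly_stats(contigs: dict[str, str], annotation: GenomeAnnotation | None = None) -> AssemblyStats:
    """Contig count, total length, N50 and GC content (overall and, when an
    annotation is supplied, split into coding vs noncoding positions)."""
    if not contigs or any(len(s) == 0 for s in contigs.values()):
        raise ValueError("assembly must contain at least one non-empty contig")
    lengths = sorted((len(s) for s in contigs.values()), reverse=True)
    total = sum(lengths)
    cum = 0
    n50 = lengths[-1]
    for L in lengths:
        cum += L
        if cum >= total / 2:
            n50 = L
            break

    all_seq = "".join(contigs.values())
    gc_all = gc_fraction(all_seq)

    gc_cod = gc_non = None
    if annotation is not None:
        coding_parts, noncoding_parts = [], []
        for name, seq in contigs.items():
            mask = annotation.coding_mask(name)
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            coding_parts.append(arr[mask])
            noncoding_parts.append(arr[~mask])
        cod = np.concatenate(coding_parts).tobytes().decode()
        non = np.concatenate(noncoding_parts).tobytes().decode()
        gc_cod = gc_fraction(cod) if cod else None
        gc_non = gc_fraction(non) if non else None

    return AssemblyStats(
        n_contigs=len(contigs),
        total_length=total,
        n50=n50,
        gc_overall=gc_all,
        gc_coding=gc_cod,
        gc_noncoding=gc_non,
    )


def _protein_aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _identity_coverage(a: str, b: str, aligner: PairwiseAligner) -> tuple[float, float, float]:
    """(identity over shorter seq, coverage of b as target, coverage of a)."""
    aln = aligner.align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    aligned_cols = sum(1 for x, y in zip(ra, rb) if x != "-" and y != "-")
    ident = matches / min(len(a), len(b))
    return ident, aligned_cols / len(b), aligned_cols / len(a)


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id wins as root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def cluster_paralogs(
    proteins: dict[str, str],
    min_identity: float = 0.50,
    min_coverage: float = 0.50,
) -> list[ParalogCluster]:
    """Single-linkage clusters over the pairwise homology relation.

    Two proteins are linked when global-alignment identity over the shorter
    sequence is >= ``min_identity`` and the aligned fraction of either partner
    (taken as target) is >= ``min_coverage``. Invalid residues reject the
    record with a log entry. Output is deterministic: clusters and members are
    sorted lexicographically; the representative is the longest member (ties
    by id).
    """
    valid = {}
    for gid, seq in proteins.items():
        if not seq or set(seq.upper()) - _AA:
            log.warning("rejecting %s: invalid amino-acid residues", gid)
            continue
        valid[gid] = seq.upper().rstrip("*")
    ids = sorted(valid)
    uf = _UnionFind(ids)
    aligner = _protein_aligner("global")
    for i, gi in enumerate(ids):
        for gj in ids[i + 1:]:
            ident, cov_j, cov_i = _identity_coverage(valid[gi], valid[gj], aligner)
            if ident >= min_identity and max(cov_i, cov_j) >= min_coverage:
                uf.union(gi, gj)

    groups: dict[str, list[str]] = {}
    for gid in ids:
        groups.setdefault(uf.find(gid), []).append(gid)
    clusters = []
    for k, (root, members) in enumerate(sorted(groups.items())):
        members = sorted(members)
        rep = max(members, key=lambda g: (len(valid[g]), g))
        clusters.append(ParalogCluster(cluster_id=f"cluster_{k:04d}", members=members, representative=rep))
    return clusters


def _evalue(score: float, m: int, n: int) -> float:
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def annotate_is_families(
    proteins: dict[str, str],
    reference_transposases: dict[str, tuple[str, str]] | dict[str, str],
    max_evalue: float = 1e-9,
    family_of: dict[str, str] | None = None,
) -> dict[str, str]:
    """Label each query protein with the IS family of its best reference hit.

    ``reference_transposases`` maps reference id -> sequence; family labels
    come from ``family_of`` (reference id -> family) or, if omitted, from the
    reference id itself up to the first underscore. Local similarity is scored
    with BLOSUM62 (gap 11/1) and converted to an E-value under fixed
    Karlin-Altschul parameters; queries with no hit at E <= ``max_evalue``
    are labeled "unclassified".
    """
    if not reference_transposases:
        log.warning("empty reference transposase set: all queries unclassified")
        return {gid: "unclassified" for gid in proteins}

    refs: dict[str, str] = {}
    fams: dict[str, str] = {}
    for rid, val in reference_transposases.items():
        if isinstance(val, tuple):
            seq, fam = val
        else:
            seq, fam = val, None
        refs[rid] = seq.upper().rstrip("*")
        fams[rid] = (
            fam
            if fam
            else (family_of or {}).get(rid, rid.split("_")[0])
        )

    aligner = _protein_aligner("local")
    labels = {}
    for gid in sorted(proteins):
        q = proteins[gid].upper().rstrip("*")
        best = ("unclassified", math.inf)
        for rid in sorted(refs):
            score = aligner.score(q, refs[rid])
            e = _evalue(score, len(q), len(refs[rid]))
            if e < best[1]:
                best = (fams[rid], e)
        labels[gid] = best[0] if best[1] <= max_evalue else "unclassified"
    return labels


_START_CODONS = {"ATG", "GTG", "TTG"}  # bacterial/archaeal code 11
_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class PseudogeneCall:
    intact: bool
    reasons: list[str] = field(default_factory=list)


def flag_pseudogenes(cds: str, genetic_code: int = 11) -> PseudogeneCall:
    """Intact iff length % 3 == 0, starts with a start codon, and has exactly
    one stop codon, at the terminus. Everything else is flagged with reasons
    (frameshift, premature stop, missing start/stop)."""
    seq = cds.upper().replace("-", "")
    reasons = []
    if len(seq) % 3 != 0:
        reasons.append("frameshift")
    if seq[:3] not in _START_CODONS:
        reasons.append("no_start_codon")
    codons = [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    internal_stops = [i for i, c in enumerate(codons[:-1]) if c in _STOP_CODONS]
    if internal_stops:
        reasons.append("premature_stop")
    if codons and codons[-1] not in _STOP_CODONS and len(seq) % 3 == 0:
        reasons.append("no_terminal_stop")
    return PseudogeneCall(intact=not reasons, reasons=reasons)


@dataclass
class ElementCopy:
    contig: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str
    identity: float


def _seed_candidates(target: str, query: str, k: int = 16, step: int = 8):
    """Approximate start positions of query matches in target via k-mer seeds."""
    index: dict[str, list[int]] = {}
    for i in range(len(target) - k + 1):
        index.setdefault(target[i:i + k], []).append(i)
    diag_hits: dict[int, int] = {}
    for j in range(0, len(query) - k + 1, step):
        for i in index.get(query[j:j + k], ()):
            diag = i - j
            diag_hits[diag] = diag_hits.get(diag, 0) + 1
    # merge nearby diagonals into candidate windows
    starts = sorted(diag_hits)
    merged = []
    for d in starts:
        if merged and d - merged[-1][-1] <= len(query) // 2:
            merged[-1].append(d)
        else:
            merged.append([d])
    return [int(np.median(g)) for g in merged]


def scan_element_copies(
    genome: dict[str, str] | GenomeAnnotation,
    element_seq: str,
    min_identity: float = 0.95,
    min_length_fraction: float = 0.90,
) -> list[ElementCopy]:
    """Locate near-identical copies of an IS element on both strands.

    Seed-and-extend: exact 16-mer seeds nominate candidate loci, each refined
    with an infix edit-distance alignment of the full element; hits must reach
    ``min_identity`` (1 - editdist/|element|) over at least
    ``min_length_fraction`` of the element length. Overlapping candidates are
    resolved by highest identity, then leftmost position.
    """
    if len(element_seq) < 50:
        raise ValueError("element query must be >= 50 bp")
    contigs = genome.contigs if isinstance(genome, GenomeAnnotation) else genome
    element_seq = element_seq.upper()
    max_dist = int(math.ceil(len(element_seq) * (1 - min_identity)))

    candidates: list[ElementCopy] = []
    for name in sorted(contigs):
        seq = contigs[name].upper()
        for strand, query in (("+", element_seq), ("-", revcomp(element_seq))):
            for approx in _seed_candidates(seq, query):
                lo = max(0, approx - max_dist - 10)
                hi = min(len(seq), approx + len(query) + max_dist + 10)
                res = edlib.align(query, seq[lo:hi], mode="HW", task="locations", k=max_dist)
                if res["editDistance"] < 0:
                    continue
                for s, e in res["locations"][:1]:
                    span = e - s + 1
                    if span < min_length_fraction * len(query):
                        continue
                    ident = 1.0 - res["editDistance"] / len(query)
                    if ident < min_identity:
                        continue
                    candidates.append(ElementCopy(name, lo + s, lo + e + 1, strand, ident))

    # resolve overlaps: highest identity wins, then leftmost
    candidates.sort(key=lambda c: (-c.identity, c.contig, c.start))
    chosen: list[ElementCopy] = []
    for c in candidates:
        if any(o.contig == c.contig and c.start < o.end and o.start < c.end for o in chosen):
            continue
        chosen.append(c)
    chosen.sort(key=lambda c: (c.contig, c.start))
    return chosen


def family_divergence_report(
    clusters: list[ParalogCluster],
    pairs: list[DivergencePair],
    pseudogene_calls: dict[str, PseudogeneCall] | None = None,
) -> pd.DataFrame:
    """Per-family summary: copy number, mean/min dS over unsaturated pairs,
    saturated-pair count and pseudogenized fraction; sorted by mean dS
    ascending so the most recent expansion comes first."""
    pair_index: dict[frozenset, DivergencePair] = {
        frozenset((p.gene_a, p.gene_b)): p for p in pairs
    }
    rows = []
    for cl in clusters:
        ds_vals, saturated = [], 0
        for i, a in enumerate(cl.members):
            for b in cl.members[i + 1:]:
                p = pair_index.get(frozenset((a, b)))
                if p is None:
                    continue
                if p.saturated_s:
                    saturated += 1
                else:
                    ds_vals.append(p.dS)
        pseudo = None
        if pseudogene_calls is not None:
            flags = [not pseudogene_calls[m].intact for m in cl.members if m in pseudogene_calls]
            pseudo = sum(flags) / len(flags) if flags else None
        rows.append(
            {
                "family": cl.family,
                "cluster_id": cl.cluster_id,
                "copy_number": len(cl.members),
                "mean_dS": float(np.mean(ds_vals)) if ds_vals else np.nan,
                "min_dS": float(np.min(ds_vals)) if ds_vals else np.nan,
                "n_pairs": len(ds_vals),
                "n_saturated_pairs": saturated,
                "fraction_pseudogenized": pseudo,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["mean_dS", "cluster_id"], na_position="last").reset_index(drop=True)


def cluster_divergence_pairs(
    clusters: list[ParalogCluster],
    cds: dict[str, str],
) -> list[DivergencePair]:
    """All within-cluster pairwise NG86 estimates over codon-alignable members.

    Members whose CDS cannot be codon-aligned (frameshifted pseudogenes) are
    skipped; pairs of equal-length in-frame CDSs are compared directly.
    """
    out = []
    for cl in clusters:
        members = [m for m in cl.members if m in cds]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                try:
                    if len(cds[a]) == len(cds[b]) and len(cds[a]) % 3 == 0:
                        aln_a, aln_b = cds[a], cds[b]
                    else:
                        aln_a, aln_b = codon_align(cds[a], cds[b])
                    out.append(pairwise_dnds(aln_a, aln_b, name_a=a, name_b=b))
                except ValueError as exc:
                    log.info("skipping pair (%s, %s): %s", a, b, exc)
    return out
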