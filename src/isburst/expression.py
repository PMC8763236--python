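"""Ambiguity-aware expression quantification for near-identical paralogs.

Clusters of paralogous genes (e.g. nine nearly identical transposase copies)
defeat ordinary unique-mapping counters: most reads match several members
equally well. The approach here keeps two books per cluster: a *total* count
of reads recruited to the cluster as a whole, and an *unambiguous* count per
member gene of reads that match exactly one member perfectly over their full
length. Strand is resolved against the library protocol so sense and
antisense transcription are tallied separately, and counts are normalized to
transcripts per million (TPM).

Recruitment is substitution-only, end-to-end matching (no indels): a read is
recruited if it matches some member with at most ``max_mismatches``
substitutions at some offset, on either strand. This makes the downstream
perfect-match disambiguation exact and testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import revcomp, seq_to_array
from .simulate.reads import SimRead

log = logging.getLogger(__name__)

PROTOCOLS = ("RF", "FR", "unstranded")


@dataclass
class ClusterExpression:
    cluster_id: str
    total_count_sense: int = 0
    total_count_antisense: int = 0
    per_gene_unambiguous: dict[str, tuple[int, int]] = field(default_factory=dict)
    effective_length: int = 0
    tpm_sense: float = 0.0
    tpm_antisense: float = 0.0


@dataclass
class ReadHit:
    cluster_id: str
    mismatches: int
    orientation: str        # '+': read matches member sense strand as given
    unambiguous_gene: str | None  # set when exactly one member matches perfectly


def _best_match(read_arr: np.ndarray, member_arr: np.ndarray) -> int:
    """Minimum substitution count of an end-to-end placement of the read
    within the member (np sliding comparison); large when the read is longer
    than the member."""
    L, M = len(read_arr), len(member_arr)
    if L > M:
        return L + 1
    windows = np.lib.stride_tricks.sliding_window_view(member_arr, L)
    return int((windows != read_arr).sum(axis=1).min())


def _perfect_members(read: str, members: dict[str, str]) -> list[tuple[str, str]]:
    """(gene, orientation) for members containing the read exactly."""
    rc = revcomp(read)
    out = []
    for gid in sorted(members):
        if read in members[gid]:
            out.append((gid, "+"))
        elif rc in members[gid]:
            out.append((gid, "-"))
    return out


def recruit_reads(
    reads: list[SimRead],
    clusters: dict[str, dict[str, str]],
    max_mismatches: int = 3,
) -> tuple[dict[str, list[tuple[SimRead, ReadHit]]], int]:
    """Assign each read to at most one cluster.

    ``clusters`` maps cluster id -> {gene id -> sequence}. A read is
    recruited to a cluster if it matches some member end-to-end with at most
    ``max_mismatches`` substitutions (either strand). A read matching several
    clusters goes to the one with the fewest mismatches; exact ties across
    clusters are dropped and counted (returned alongside).
    """
    if not reads or not clusters:
        raise ValueError("reads and clusters must be non-empty")
    member_seqs = {
        cid: {g: (s.upper(), revcomp(s.upper())) for g, s in members.items()}
        for cid, members in clusters.items()
    }
    member_arrays = {
        cid: {g: (seq_to_array(f), seq_to_array(r)) for g, (f, r) in pair.items()}
        for cid, pair in member_seqs.items()
    }
    # exact pigeonhole prefilter: with <= max_mismatches substitutions, at
    # least one of (max_mismatches + 1) disjoint read k-mers matches a member
    # k-mer exactly, so only clusters sharing an indexed k-mer need scanning
    k = 18
    kmer_index: dict[str, set[str]] = {}
    for cid, members in clusters.items():
        for s in members.values():
            su = s.upper()
            for strand_seq in (su, revcomp(su)):
                for i in range(len(strand_seq) - k + 1):
                    kmer_index.setdefault(strand_seq[i:i + k], set()).add(cid)

    def candidate_clusters(read_seq: str) -> list[str]:
        n_pieces = max_mismatches + 1
        if len(read_seq) < n_pieces * k:
            return sorted(clusters)  # too short for the pigeonhole bound
        cands: set[str] = set()
        for j in range(n_pieces):
            cands |= kmer_index.get(read_seq[j * k:(j + 1) * k], set())
        return sorted(cands)

    recruited: dict[str, list[tuple[SimRead, ReadHit]]] = {cid: [] for cid in clusters}
    dropped_ties = 0
    for read in reads:
        arr = None
        per_cluster: list[tuple[int, str, str]] = []  # (mismatches, cid, orientation)
        for cid in candidate_clusters(read.seq):
            best = max_mismatches + 1
            best_orient = "+"
            for gid, (fwd_s, rev_s) in member_seqs[cid].items():
                # perfect-substring fast path before the sliding scan
                if read.seq in fwd_s:
                    best, best_orient = 0, "+"
                    break
                if read.seq in rev_s:
                    best, best_orient = 0, "-"
                    break
                if arr is None:
                    arr = seq_to_array(read.seq)
                fwd, rev = member_arrays[cid][gid]
                mm = _best_match(arr, fwd)
                if mm < best:
                    best, best_orient = mm, "+"
                mm = _best_match(arr, rev)
                if mm < best:
                    best, best_orient = mm, "-"
            if best <= max_mismatches:
                per_cluster.append((best, cid, best_orient))
        if not per_cluster:
            continue
        per_cluster.sort()
        if len(per_cluster) > 1 and per_cluster[0][0] == per_cluster[1][0]:
            dropped_ties += 1
            continue
        mm, cid, orient = per_cluster[0]
        perfect = _perfect_members(read.seq, clusters[cid])
        gene = perfect[0][0] if len(perfect) == 1 else None
        recruited[cid].append((read, ReadHit(cid, mm, orient, gene)))
    if dropped_ties:
        log.info("dropped %d reads tied across clusters", dropped_ties)
    return recruited, dropped_ties


def classify_ambiguity(read: SimRead | str, members: dict[str, str]) -> str | None:
    """Gene id when the read is a perfect full-length substring of exactly one
    member (either strand); None when ambiguous."""
    seq = read if isinstance(read, str) else read.seq
    perfect = _perfect_members(seq, members)
    return perfect[0][0] if len(perfect) == 1 else None


def count_expression(
    recruited: dict[str, list[tuple[SimRead, ReadHit]]],
    clusters: dict[str, dict[str, str]],
    protocol: str = "RF",
) -> list[ClusterExpression]:
    """Tally cluster totals and per-gene unambiguous counts by strand.

    Under RF, a read aligning to the reverse complement of the gene derives
    from a sense transcript; FR is the opposite; unstranded pools everything
    as sense. Each read increments exactly one cluster total and, when
    unambiguously placed, one member-gene counter.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    out = []
    for cid in sorted(clusters):
        members = clusters[cid]
        expr = ClusterExpression(
            cluster_id=cid,
            per_gene_unambiguous={g: (0, 0) for g in sorted(members)},
            effective_length=max(len(s) for s in members.values()),
        )
        for read, hit in recruited.get(cid, []):
            if protocol == "unstranded":
                sense = True
            elif protocol == "RF":
                sense = hit.orientation == "-"
            else:  # FR
                sense = hit.orientation == "+"
            if sense:
                expr.total_count_sense += 1
            else:
                expr.total_count_antisense += 1
            if hit.unambiguous_gene is not None:
                s, a = expr.per_gene_unambiguous[hit.unambiguous_gene]
                expr.per_gene_unambiguous[hit.unambiguous_gene] = (
                    (s + 1, a) if sense else (s, a + 1)
                )
        out.append(expr)
    return out


def compute_tpm(counts: np.ndarray | list[float], lengths: np.ndarray | list[float]) -> np.ndarray:
    """TPM_i = 1e6 * (count_i / length_i[kb]) / sum_j rate_j; all-zero counts
    yield all-zero TPM."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    rates = counts / (lengths / 1000.0)
    total = rates.sum()
    if total == 0:
        return np.zeros_like(rates)
    return 1e6 * rates / total


def expression_table(
    cluster_expr: list[ClusterExpression],
    singleton_counts: dict[str, tuple[int, int]] | None = None,
    singleton_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Combined feature table (clusters + single-copy genes) with TPM per
    strand. TPM is normalized over all features jointly, per strand."""
    rows = []
    for e in cluster_expr:
        rows.append(
            {
                "feature": e.cluster_id,
                "kind": "cluster",
                "length": e.effective_length,
                "count_sense": e.total_count_sense,
                "count_antisense": e.total_count_antisense,
            }
        )
    for gid, (s, a) in (singleton_counts or {}).items():
        rows.append(
            {
                "feature": gid,
                "kind": "gene",
                "length": (singleton_lengths or {}).get(gid, 1000),
                "count_sense": s,
                "count_antisense": a,
            }
        )
    df = pd.DataFrame(rows)
    df["tpm_sense"] = compute_tpm(df["count_sense"], df["length"])
    df["tpm_antisense"] = compute_tpm(df["count_antisense"], df["length"])
    for e in cluster_expr:
        row = df["feature"] == e.cluster_id
        e.tpm_sense = float(df.loc[row, "tpm_sense"].iloc[0])
        e.tpm_antisense = float(df.loc[row, "tpm_antisense"].iloc[0])
    return df


def is_transcriptome_fraction(
    tables: list[pd.DataFrame] | pd.DataFrame,
    is_flags: dict[str, bool],
) -> dict:
    """Percent of sense reads derived from IS features, per replicate, with
    mean and SD across replicates. Returns None values when a replicate has
    zero sense counts."""
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    per_rep = []
    for df in tables:
        missing = set(df["feature"]) - set(is_flags)
        if missing:
            raise ValueError(f"features without IS flag: {sorted(missing)[:5]}")
        total = df["count_sense"].sum()
        if total == 0:
            per_rep.append(None)
            continue
        is_sum = df.loc[df["feature"].map(is_flags), "count_sense"].sum()
        per_rep.append(100.0 * is_sum / total)
    valid = [x for x in per_rep if x is not None]
    return {
        "per_replicate": per_rep,
        "mean": float(np.mean(valid)) if valid else None,
        "sd": float(np.std(valid, ddof=1)) if len(valid) > 1 else None,
    }
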