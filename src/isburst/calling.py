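"""Junction-based IS insertion calling in mixed-population short reads.

A new insertion creates two novel junctions: reference flank joined to the
element's 5' end (left junction) and element 3' end joined to reference
(right junction). A read supports a junction when it splits into a
reference-matching segment and an element-terminus-matching segment, each at
least ``m`` bases with at most one mismatch. Junction groups on the two sides
are paired; the offset of their coordinates gives the target-site duplication
(a - b + 1 = k, the duplicated window length), and the insertion frequency is
estimated as the mean over sides of J/(J+S), junction reads against
reference-spanning reads.

Candidate calls below the frequency cutoff, with insufficient support, or
with only one junction side are emitted with explanatory status flags rather
than dropped. Strand-representation (Fisher exact) and base-quality
(one-sided Kolmogorov-Smirnov) bias tests annotate calls; they reject only in
strict mode, mirroring a manual-inspection workflow.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._util import gc_fraction, revcomp, seq_to_array
from .io import GenomeAnnotation
from .simulate.reads import SimRead


@dataclass
class SupportRead:
    read_id: str
    strand: str           # strand of the read on the reference
    ref_overhang: int
    elem_overhang: int
    junction_qual: float  # mean phred over the element-side bases nearest the junction


@dataclass
class JunctionEvidence:
    side: str             # 'left' or 'right'
    contig: str
    coord: int            # 1-based flank base adjacent to the element
    family: str
    orientation: str      # element orientation on the reference
    reads: list[SupportRead] = field(default_factory=list)

    @property
    def terminus(self) -> str:
        if self.side == "left":
            return "start" if self.orientation == "+" else "end"
        return "end" if self.orientation == "+" else "start"


@dataclass
class InsertionCall:
    family: str
    contig: str
    site: int             # 1-based position of the first TSD base
    orientation: str
    tsd_seq: str
    k: int
    J_left: int
    J_right: int
    S_left: int
    S_right: int
    frequency: float
    p_strand: float | None = None
    p_qual: float | None = None
    status: list[str] = field(default_factory=list)
    left: JunctionEvidence | None = None
    right: JunctionEvidence | None = None

    @property
    def passed(self) -> bool:
        return bool(self.status) and self.status[0] == "PASS"


@dataclass
class _RefAlignment:
    read_id: str
    contig: str
    start: int  # 0-based
    end: int
    strand: str
    quals: np.ndarray


def _mismatch_positions(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.nonzero(a != b)[0]


def _extend_forward(read: np.ndarray, ref: np.ndarray, p: int, max_mm: int = 1) -> int:
    """Length of the longest prefix of ``read`` matching ref starting at p
    with <= max_mm mismatches (mismatch at the cut is excluded)."""
    n = min(len(read), len(ref) - p)
    if n <= 0:
        return 0
    mm = _mismatch_positions(read[:n], ref[p:p + n])
    if len(mm) <= max_mm:
        return n
    return int(mm[max_mm])


def _extend_backward(read: np.ndarray, ref: np.ndarray, pe: int, max_mm: int = 1) -> int:
    """Length of the longest suffix of ``read`` matching ref ending at pe
    (exclusive) with <= max_mm mismatches."""
    n = min(len(read), pe)
    if n <= 0:
        return 0
    mm = _mismatch_positions(read[-n:], ref[pe - n:pe])
    if len(mm) <= max_mm:
        return n
    return int(n - 1 - mm[len(mm) - 1 - max_mm])


def _segment_matches(seg: np.ndarray, target: np.ndarray, max_mm: int = 1) -> bool:
    return len(seg) == len(target) and int((seg != target).sum()) <= max_mm


class _ReferenceIndex:
    def __init__(self, contigs: dict[str, str], k: int):
        self.k = k
        self.arrays = {name: seq_to_array(seq) for name, seq in contigs.items()}
        self.kmers: dict[bytes, list[tuple[str, int]]] = {}
        for name, arr in self.arrays.items():
            b = arr.tobytes()
            for i in range(len(b) - k + 1):
                self.kmers.setdefault(b[i:i + k], []).append((name, i))

    def hits(self, kmer: bytes) -> list[tuple[str, int]]:
        return self.kmers.get(kmer, [])


def find_junctions(
    reads: list[SimRead],
    reference: dict[str, str] | GenomeAnnotation,
    element_library: dict[str, str],
    m: int = 12,
    max_mismatch_per_segment: int = 1,
) -> tuple[list[JunctionEvidence], list[_RefAlignment]]:
    """Scan reads for junction support; also returns full-reference
    alignments (used downstream for reference-spanning counts).

    Detection anchors an exact ``m``-mer at the reference-matching end of the
    read, extends with at most one mismatch, and requires the remaining
    segment (>= m bases) to match an element terminus with at most one
    mismatch. Evidence is grouped by (contig, coordinate, family,
    orientation, side).
    """
    contigs = reference.contigs if isinstance(reference, GenomeAnnotation) else reference
    for fam, seq in element_library.items():
        if len(seq) < m:
            raise ValueError(f"element {fam} shorter than the minimum overhang {m}")
    index = _ReferenceIndex(contigs, m)

    # oriented element sequences: prefix/suffix arrays per (family, orientation)
    oriented = {}
    for fam in sorted(element_library):
        for orient in "+-":
            seq = element_library[fam] if orient == "+" else revcomp(element_library[fam])
            oriented[(fam, orient)] = seq_to_array(seq)

    groups: dict[tuple, JunctionEvidence] = {}
    spanning: list[_RefAlignment] = []

    def quals_of(q: str) -> np.ndarray:
        return np.frombuffer(q.encode(), dtype=np.uint8).astype(float) - 33

    all_ambiguous: list[tuple] = []
    for read in reads:
        L = len(read.seq)
        if L < 2 * m:
            continue
        matched_full = False
        junction_hits = []
        ambiguous_hits: list[tuple] = []
        for strand in "+-":
            seq = read.seq if strand == "+" else revcomp(read.seq)
            qual = quals_of(read.qual)[::1 if strand == "+" else -1]
            arr = seq_to_array(seq)

            # full-reference placement, anchored at the read start
            for contig, p in index.hits(arr[:m].tobytes()):
                ref = index.arrays[contig]
                ext = _extend_forward(arr, ref, p, max_mm=2)
                if ext == L:
                    spanning.append(_RefAlignment(read.read_id, contig, p, p + L, strand, qual))
                    matched_full = True
                    break
            if matched_full:
                break

            # left junction: reference prefix + element-start suffix. The
            # maximal reference extension can overshoot past the true split
            # (its allowed mismatch may swallow element bases), so split
            # points are tried from the maximal extension downward; the first
            # (longest-reference) split whose remainder matches a terminus
            # wins, which makes the coordinate deterministic.
            for contig, p in index.hits(arr[:m].tobytes()):
                ref = index.arrays[contig]
                ext = _extend_forward(arr, ref, p, max_mismatch_per_segment)
                if ext >= L:
                    continue
                for j in range(min(ext, L - m), m - 1, -1):
                    rem = arr[j:]
                    matched = [
                        key for key, earr in oriented.items()
                        if len(earr) >= len(rem)
                        and _segment_matches(rem, earr[:len(rem)], max_mismatch_per_segment)
                    ]
                    if matched:
                        # overhangs within the terminal inverted repeat match
                        # both orientations; such reads support the junction
                        # but cannot orient the element (resolved afterwards)
                        fams = {fam for fam, _ in matched}
                        a = p + j  # 1-based last reference base before element
                        support = SupportRead(read.read_id, strand, j, L - j,
                                              float(qual[j:j + m].mean()))
                        if len(matched) == 1:
                            junction_hits.append(("left", contig, a, matched[0][0], matched[0][1], support))
                        elif len(fams) == 1:
                            ambiguous_hits.append(("left", contig, a, fams.pop(), support))
                        break

            # right junction: element-end prefix + reference suffix
            for contig, pe_start in index.hits(arr[-m:].tobytes()):
                ref = index.arrays[contig]
                pe = pe_start + m
                ext = _extend_backward(arr, ref, pe, max_mismatch_per_segment)
                if ext >= L:
                    continue
                for j in range(min(ext, L - m), m - 1, -1):
                    rem = arr[:L - j]
                    matched = [
                        key for key, earr in oriented.items()
                        if len(earr) >= len(rem)
                        and _segment_matches(rem, earr[-len(rem):], max_mismatch_per_segment)
                    ]
                    if matched:
                        fams = {fam for fam, _ in matched}
                        b = pe - j + 1  # 1-based first reference base after element
                        support = SupportRead(read.read_id, strand, j, L - j,
                                              float(qual[max(0, L - j - m):L - j].mean()))
                        if len(matched) == 1:
                            junction_hits.append(("right", contig, b, matched[0][0], matched[0][1], support))
                        elif len(fams) == 1:
                            ambiguous_hits.append(("right", contig, b, fams.pop(), support))
                        break
        if matched_full:
            continue
        for side, contig, coord, fam, orient, support in junction_hits:
            key = (side, contig, coord, fam, orient)
            if key not in groups:
                groups[key] = JunctionEvidence(side, contig, coord, fam, orient)
            groups[key].reads.append(support)
        all_ambiguous.extend(ambiguous_hits)

    # orientation-ambiguous junction reads attach to the unique oriented
    # group at their (side, contig, coordinate, family), when there is one
    for side, contig, coord, fam, support in all_ambiguous:
        hits = [
            g for (s, c, co, f, _), g in groups.items()
            if (s, c, co, f) == (side, contig, coord, fam)
        ]
        if len(hits) == 1:
            hits[0].reads.append(support)

    return sorted(groups.values(), key=lambda g: (g.contig, g.coord, g.side)), spanning


class SpanningIndex:
    """Reference-spanning read lookup: reads crossing a boundary with >= m
    bases on each side, with strands and junction-position base qualities."""

    def __init__(self, alignments: list[_RefAlignment], m: int = 12):
        self.m = m
        self.by_contig: dict[str, list[_RefAlignment]] = {}
        for a in alignments:
            self.by_contig.setdefault(a.contig, []).append(a)
        for lst in self.by_contig.values():
            lst.sort(key=lambda a: a.start)
        self._starts = {c: [a.start for a in lst] for c, lst in self.by_contig.items()}

    def spanning(self, contig: str, coord: int) -> list[_RefAlignment]:
        """Reads covering the boundary after 1-based position ``coord`` with
        >= m bases on each side."""
        lst = self.by_contig.get(contig, [])
        starts = self._starts.get(contig, [])
        # need start <= coord - m (0-based start) and end >= coord + m
        hi = bisect_right(starts, coord - self.m)
        return [a for a in lst[:hi] if a.end >= coord + self.m]


def strand_bias_test(junction_strands: list[str], reference_strands: list[str]) -> float:
    """Two-sided Fisher exact p for strand representation of junction vs
    reference reads; empty margins give p = 1."""
    table = [
        [junction_strands.count("+"), junction_strands.count("-")],
        [reference_strands.count("+"), reference_strands.count("-")],
    ]
    if min(sum(table[0]), sum(table[1])) == 0:
        return 1.0
    if min(table[0][0] + table[1][0], table[0][1] + table[1][1]) == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def quality_bias_test(junction_quals: list[float], reference_quals: list[float]) -> float | None:
    """One-sided two-sample KS p against the alternative that
    junction-supporting base qualities are stochastically lower; exact
    small-sample p when both n <= 25. Returns None (insufficient data) below
    3 observations per class."""
    if len(junction_quals) < 3 or len(reference_quals) < 3:
        return None
    method = "exact" if max(len(junction_quals), len(reference_quals)) <= 25 else "asymp"
    # alternative='greater': ECDF of the first sample sits above the second,
    # i.e. junction qualities are stochastically smaller
    res = stats.ks_2samp(junction_quals, reference_quals, alternative="greater", method=method)
    return float(res.pvalue)


def infer_tsd(
    left_coord: int, right_coord: int, reference_contig: str
) -> tuple[str, int, list[str]]:
    """TSD from paired junction coordinates. a = left-flank boundary,
    b = right-flank resumption (both 1-based): k = a - b + 1. k > 0 gives the
    duplicated window reference[b..a]; k = 0 a blunt insertion; k < 0 an
    implied target deletion (flagged, no TSD)."""
    a, b = left_coord, right_coord
    k = a - b + 1
    if k < 0:
        return "", k, ["TARGET_DELETION"]
    if k == 0:
        return "", 0, []
    return reference_contig[b - 1:a], k, []


def call_insertions(
    evidence: list[JunctionEvidence],
    spanning_index: SpanningIndex,
    reference: dict[str, str] | GenomeAnnotation,
    min_freq: float = 0.02,
    min_support: int = 2,
    max_tsd: int = 20,
    bias_alpha: float = 0.01,
    strict: bool = False,
) -> list[InsertionCall]:
    """Pair left/right junction groups into insertion calls with frequency,
    TSD, and bias-test annotations.

    Pairing: same contig, family and orientation with -max_tsd <= a - b + 1
    <= max_tsd, nearest coordinates first. One-sided candidates are emitted
    with an UNPAIRED status; low-frequency and low-support candidates carry
    LOW_FREQ / LOW_SUPPORT. With ``strict`` set, bias flags also demote a
    call from PASS.
    """
    contigs = reference.contigs if isinstance(reference, GenomeAnnotation) else reference
    lefts = [e for e in evidence if e.side == "left"]
    rights = [e for e in evidence if e.side == "right"]
    used_right: set[int] = set()
    calls: list[InsertionCall] = []

    def side_stats(ev: JunctionEvidence | None):
        if ev is None:
            return 0, 0, [], [], [], []
        span = spanning_index.spanning(ev.contig, ev.coord if ev.side == "left" else ev.coord - 1)
        J, S = len(ev.reads), len(span)
        j_strands = [r.strand for r in ev.reads]
        s_strands = [a.strand for a in span]
        j_quals = [r.junction_qual for r in ev.reads]
        boundary = ev.coord if ev.side == "left" else ev.coord - 1
        s_quals = [float(a.quals[boundary - a.start]) for a in span if 0 <= boundary - a.start < len(a.quals)]
        return J, S, j_strands, s_strands, j_quals, s_quals

    for le in sorted(lefts, key=lambda e: (e.contig, e.coord)):
        best = None
        for ri, re_ in enumerate(rights):
            if ri in used_right:
                continue
            if (re_.contig, re_.family, re_.orientation) != (le.contig, le.family, le.orientation):
                continue
            k = le.coord - re_.coord + 1
            if -max_tsd <= k <= max_tsd:
                if best is None or abs(k) < abs(le.coord - rights[best].coord + 1):
                    best = ri
        re_ = rights[best] if best is not None else None
        if best is not None:
            used_right.add(best)

        Jl, Sl, jsl, ssl, jql, sql = side_stats(le)
        Jr, Sr, jsr, ssr, jqr, sqr = side_stats(re_)
        status = []
        if re_ is None:
            status.append("UNPAIRED")
            site = le.coord + 1  # unknown k; site approximated past the flank
            tsd, k, tsd_flags = "", 0, []
        else:
            tsd, k, tsd_flags = infer_tsd(le.coord, re_.coord, contigs[le.contig])
            site = re_.coord
        status.extend(tsd_flags)

        sides = [(Jl, Sl)] + ([(Jr, Sr)] if re_ is not None else [])
        freqs = [J / (J + S) if (J + S) > 0 else 0.0 for J, S in sides]
        f = float(np.mean(freqs))
        if f < min_freq:
            status.append("LOW_FREQ")
        if Jl + Jr < min_support:
            status.append("LOW_SUPPORT")

        p_strand = strand_bias_test(jsl + jsr, ssl + ssr)
        p_qual = quality_bias_test(jql + jqr, sql + sqr)
        if p_strand is not None and p_strand < bias_alpha:
            status.append("STRAND_BIAS")
        if p_qual is not None and p_qual < bias_alpha:
            status.append("QUAL_BIAS")
        if p_qual is None:
            status.append("INSUFFICIENT_QUAL_DATA")

        blocking = [s for s in status if s in ("UNPAIRED", "LOW_FREQ", "LOW_SUPPORT")]
        if strict:
            blocking += [s for s in status if s in ("STRAND_BIAS", "QUAL_BIAS")]
        if not blocking:
            status = ["PASS"] + [s for s in status if s in ("STRAND_BIAS", "QUAL_BIAS", "TARGET_DELETION")]

        calls.append(
            InsertionCall(
                family=le.family,
                contig=le.contig,
                site=site,
                orientation=le.orientation,
                tsd_seq=tsd,
                k=k,
                J_left=Jl,
                J_right=Jr,
                S_left=Sl,
                S_right=Sr,
                frequency=f,
                p_strand=p_strand,
                p_qual=p_qual,
                status=status,
                left=le,
                right=re_,
            )
        )

    for ri, re_ in enumerate(rights):
        if ri in used_right:
            continue
        Jr, Sr, jsr, ssr, jqr, sqr = side_stats(re_)
        f = Jr / (Jr + Sr) if (Jr + Sr) > 0 else 0.0
        status = ["UNPAIRED"]
        if f < min_freq:
            status.append("LOW_FREQ")
        if Jr < min_support:
            status.append("LOW_SUPPORT")
        calls.append(
            InsertionCall(
                family=re_.family, contig=re_.contig, site=re_.coord,
                orientation=re_.orientation, tsd_seq="", k=0,
                J_left=0, J_right=Jr, S_left=0, S_right=Sr,
                frequency=f, p_strand=None, p_qual=None, status=status, right=re_,
            )
        )

    calls.sort(key=lambda c: (c.contig, c.site, c.family))
    return calls


def call_insertions_from_reads(
    reads: list[SimRead],
    reference: dict[str, str] | GenomeAnnotation,
    element_library: dict[str, str],
    m: int = 12,
    **kwargs,
) -> list[InsertionCall]:
    """Convenience end-to-end pipeline: junction scan, spanning index, calls."""
    evidence, alignments = find_junctions(reads, reference, element_library, m=m)
    return call_insertions(evidence, SpanningIndex(alignments, m=m), reference, **kwargs)


def find_inverted_repeats(
    element_seq: str, min_len: int = 5, max_mismatch: int = 0
) -> tuple[int, str, str]:
    """Longest terminal inverted repeat: the longest prefix whose reverse
    complement equals the element suffix with at most ``max_mismatch``
    mismatches; (0, '', '') when none of at least ``min_len``."""
    seq = element_seq.upper()
    if len(seq) < 2 * min_len:
        raise ValueError("element shorter than twice min_len")
    for L in range(len(seq) // 2, min_len - 1, -1):
        prefix = seq[:L]
        suffix = seq[-L:]
        mm = sum(1 for x, y in zip(revcomp(prefix), suffix) if x != y)
        if mm <= max_mismatch:
            return L, prefix, suffix
    return 0, "", ""


def target_site_gc(
    calls: list[InsertionCall],
    reference: dict[str, str] | GenomeAnnotation,
    annotation: GenomeAnnotation | None = None,
) -> dict:
    """Unweighted mean GC over call TSDs, with genome coding/noncoding GC
    background from the assembly statistics."""
    from .census import assembly_stats

    tsds = [c.tsd_seq for c in calls if c.tsd_seq]
    mean_gc = float(np.mean([gc_fraction(t) for t in tsds])) if tsds else None
    contigs = reference.contigs if isinstance(reference, GenomeAnnotation) else reference
    ann = annotation if annotation is not None else (
        reference if isinstance(reference, GenomeAnnotation) else None
    )
    stats_ = assembly_stats(contigs, ann)
    return {
        "mean_tsd_gc": mean_gc,
        "n_tsds": len(tsds),
        "gc_coding": stats_.gc_coding,
        "gc_noncoding": stats_.gc_noncoding,
        "gc_overall": stats_.gc_overall,
    }
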