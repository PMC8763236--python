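"""Paired-end short-read simulation from a weighted mixture of genomes.

Emulates whole-population sequencing of an evolving culture: each genotype's
genome contributes fragments in proportion to its frequency (times genome
length), base-call errors are i.i.d. substitutions, and quality strings
encode the per-base error rate (Sanger Phred+33). Truth records the source
genome and fragment coordinates for every pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._util import BASES, array_to_seq, revcomp, seq_to_array


@dataclass
class SimRead:
    read_id: str
    seq: str
    qual: str


def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, max(2, round(-10 * np.log10(error_rate))))
    return chr(q + 33)


def _add_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = seq_to_array(seq).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for pos in hits:
        alts = BASES[BASES != arr[pos]]
        arr[pos] = rng.choice(alts)
    return array_to_seq(arr)


def simulate_reads(
    genome_mixture: list[tuple[dict[str, str], float]],
    depth: float,
    read_length: int = 100,
    insert_size: int = 300,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[SimRead, SimRead]], pd.DataFrame]:
    """Simulate paired reads at the given mean coverage.

    ``genome_mixture``: list of (contig dict, weight); weights must sum to 1.
    Fragments are sampled with probability proportional to weight x genome
    length; the fragment start is uniform along the genome. Returns the read
    pairs and a truth table (read_id, genome_index, contig, fragment start/
    end in 0-based half-open coordinates, strand of read 1).
    """
    if insert_size < read_length:
        raise ValueError("insert_size must be >= read_length")
    if depth <= 0:
        raise ValueError("depth must be positive")
    weights = np.array([w for _, w in genome_mixture], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("mixture weights must sum to 1")

    rng = np.random.default_rng(seed)
    lengths = np.array([sum(len(s) for s in g.values()) for g, _ in genome_mixture], dtype=float)
    p_genome = weights * lengths
    p_genome /= p_genome.sum()
    mean_len = float(np.sum(weights * lengths))
    n_frags = int(round(depth * mean_len / (2 * read_length)))

    qchar = _phred_char(error_rate)
    pairs: list[tuple[SimRead, SimRead]] = []
    truth_rows = []
    genome_ids = rng.choice(len(genome_mixture), size=n_frags, p=p_genome)
    for i, gi in enumerate(genome_ids):
        contigs = genome_mixture[gi][0]
        names = sorted(contigs)
        clens = np.array([len(contigs[n]) for n in names], dtype=float)
        ci = rng.choice(len(names), p=clens / clens.sum()) if len(names) > 1 else 0
        seq = contigs[names[ci]]
        if len(seq) <= insert_size:
            start = 0
            frag = seq
        else:
            start = int(rng.integers(0, len(seq) - insert_size + 1))
            frag = seq[start:start + insert_size]
        flip = rng.random() < 0.5
        r1_seq = frag[:read_length]
        r2_seq = revcomp(frag[-read_length:])
        if flip:
            r1_seq, r2_seq = r2_seq, r1_seq
        rid = f"frag_{i:07d}"
        r1 = SimRead(rid + "/1", _add_errors(rng, r1_seq, error_rate), qchar * read_length)
        r2 = SimRead(rid + "/2", _add_errors(rng, r2_seq, error_rate), qchar * read_length)
        pairs.append((r1, r2))
        truth_rows.append(
            {
                "read_id": rid,
                "genome_index": int(gi),
                "contig": names[ci],
                "frag_start": start,
                "frag_end": start + len(frag),
                "r1_strand": "-" if flip else "+",
            }
        )
    return pairs, pd.DataFrame(truth_rows)


def flatten_pairs(pairs: list[tuple[SimRead, SimRead]]) -> list[SimRead]:
    return [r for pair in pairs for r in pair]
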