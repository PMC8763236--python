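"""Stranded single-end RNA-seq simulation over a gene set.

Reads are sampled per gene in proportion to expression weight x gene length;
a configurable fraction is emitted antisense (transcription of the opposite
strand, common over IS transposase genes). Under the default RF (dUTP)
protocol a sense-transcript read is the reverse complement of the gene
sequence; FR is the opposite; unstranded reads take a random orientation.
Truth records per-gene sense/antisense read counts and the per-read source.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._util import revcomp
from .reads import SimRead, _add_errors, _phred_char


def simulate_rnaseq(
    genes: dict[str, str],
    weights: dict[str, float],
    antisense_fraction: float = 0.0,
    strandedness: str = "RF",
    depth: int = 100_000,
    read_length: int = 75,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SimRead], pd.DataFrame, pd.DataFrame]:
    """Returns (reads, per-gene truth counts, per-read truth).

    ``genes`` maps gene id -> sense-strand sequence (each >= read_length bp);
    ``weights`` are relative transcript abundances (>= 0, not all zero).
    """
    if strandedness not in ("RF", "FR", "unstranded"):
        raise ValueError(f"unknown strandedness {strandedness!r}")
    if not 0 <= antisense_fraction <= 1:
        raise ValueError("antisense_fraction must be in [0, 1]")
    ids = sorted(genes)
    w = np.array([weights.get(g, 0.0) for g in ids], dtype=float)
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be >= 0 and not all zero")
    for g in ids:
        if len(genes[g]) < read_length:
            raise ValueError(f"gene {g} shorter than the read length")

    rng = np.random.default_rng(seed)
    p = w * np.array([len(genes[g]) for g in ids], dtype=float)
    p /= p.sum()
    qchar = _phred_char(error_rate)

    picks = rng.choice(len(ids), size=depth, p=p)
    antisense = rng.random(depth) < antisense_fraction
    reads: list[SimRead] = []
    rows = []
    for i in range(depth):
        gid = ids[picks[i]]
        seq = genes[gid]
        pos = int(rng.integers(0, len(seq) - read_length + 1))
        frag = seq[pos:pos + read_length]  # sense-strand fragment
        is_anti = bool(antisense[i])
        # orientation of the emitted read relative to the gene's sense strand
        if strandedness == "RF":
            forward = is_anti
        elif strandedness == "FR":
            forward = not is_anti
        else:
            forward = bool(rng.random() < 0.5)
        out = frag if forward else revcomp(frag)
        rid = f"rna_{i:07d}"
        reads.append(SimRead(rid, _add_errors(rng, out, error_rate), qchar * read_length))
        rows.append({"read_id": rid, "gene_id": gid, "start": pos, "antisense": is_anti})

    per_read = pd.DataFrame(rows)
    truth = (
        per_read.groupby("gene_id")["antisense"]
        .agg(sense=lambda s: int((~s).sum()), antisense="sum")
        .reindex(ids, fill_value=0)
        .reset_index()
    )
    truth["antisense"] = truth["antisense"].astype(int)
    return reads, truth, per_read
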