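"""Copy-and-paste transposition with AT-biased target choice and target-site
duplication.

An event copies the (intact) donor element and inserts it at a site sampled
with weight proportional to exp(beta * AT-fraction of the k-bp target
window); the window is duplicated as flanking direct repeats. The donor copy
is never excised. ``calibrate_target_bias`` solves for the beta that yields a
chosen expected TSD GC on a given genome, so a simulation can be pinned to an
observed insertion-site composition (e.g. a 27% GC mean on a ~41% GC
background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .._util import revcomp, seq_to_array
from ..io import GenomeAnnotation
from .genome import PlantedCopy


@dataclass
class TranspositionEvent:
    event_id: str
    family_id: str
    donor_copy: str
    contig: str
    site: int          # 0-based index of the first base of the target window
    orientation: str   # '+' or '-'
    tsd_seq: str
    element_seq: str   # inserted sequence, already oriented


def _window_gc(seq: str, k: int) -> np.ndarray:
    """GC fraction of every k-bp window (positions 0 .. len-k)."""
    arr = seq_to_array(seq)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(float)
    if k == 0:
        return np.zeros(len(seq) + 1)
    csum = np.concatenate([[0.0], np.cumsum(is_gc)])
    return (csum[k:] - csum[:-k]) / k


def _site_weights(contigs: dict[str, str], k: int, beta: float):
    names, gcs, weights = [], [], []
    for name in sorted(contigs):
        gc = _window_gc(contigs[name], max(k, 1))
        w = np.exp(beta * (1.0 - gc))
        names.append(name)
        gcs.append(gc)
        weights.append(w)
    return names, gcs, weights


def expected_tsd_gc(genome: dict[str, str] | GenomeAnnotation, k: int, beta: float) -> float:
    """Exact expectation of target-window GC under the exp(beta*AT) weighting."""
    contigs = genome.contigs if isinstance(genome, GenomeAnnotation) else genome
    _, gcs, weights = _site_weights(contigs, k, beta)
    gc = np.concatenate(gcs)
    w = np.concatenate(weights)
    return float(np.sum(gc * w) / np.sum(w))


def calibrate_target_bias(
    genome: dict[str, str] | GenomeAnnotation, k: int, target_gc: float
) -> float:
    """beta such that the expected target-window GC equals ``target_gc``."""
    f = lambda b: expected_tsd_gc(genome, k, b) - target_gc
    if f(0.0) <= 0:
        return 0.0
    return float(brentq(f, 0.0, 80.0, xtol=1e-6))


def simulate_transposition(
    genome: GenomeAnnotation,
    planted: list[PlantedCopy],
    family_id: str,
    n_events: int,
    beta: float = 0.0,
    seed: int = 0,
    tsd_length: int = 8,
) -> tuple[list[dict[str, str]], list[TranspositionEvent]]:
    """Simulate ``n_events`` independent copy-and-paste insertions.

    Each event is applied to the input genome on its own, returning one
    mutated contig set per event plus the truth records. Raises if the family
    has no intact donor copy (a purely pseudogenized family cannot
    self-mobilize).
    """
    donors = [p for p in planted if p.family_id == family_id and p.intact]
    if not donors:
        raise ValueError(f"family {family_id} has no intact donor copy")
    if not np.isfinite(beta):
        raise ValueError("target bias beta must be finite")
    rng = np.random.default_rng(seed)
    donor = donors[0]
    donor_seq = genome.contigs[donor.contig][donor.start:donor.end]
    if donor.strand == "-":
        donor_seq = revcomp(donor_seq)

    names, _, weights = _site_weights(genome.contigs, tsd_length, beta)
    # insertions into an existing copy of a repeated element cannot be placed
    # uniquely by flank sequence (and self-insertion is not modelled): target
    # windows overlapping planted element spans get zero weight
    margin = 150
    for p in planted:
        if p.contig in names:
            w = weights[names.index(p.contig)]
            lo = max(0, p.start - margin)
            hi = min(len(w), p.end + margin)
            w[lo:hi] = 0.0
    flat_w = np.concatenate(weights)
    flat_w /= flat_w.sum()
    bounds = np.cumsum([len(w) for w in weights])

    events: list[TranspositionEvent] = []
    mutated: list[dict[str, str]] = []
    picks = rng.choice(len(flat_w), size=n_events, p=flat_w)
    for i, flat_idx in enumerate(picks):
        ci = int(np.searchsorted(bounds, flat_idx, side="right"))
        site = int(flat_idx - (bounds[ci - 1] if ci > 0 else 0))
        contig = names[ci]
        orientation = "+" if rng.random() < 0.5 else "-"
        inserted = donor_seq if orientation == "+" else revcomp(donor_seq)
        ev = TranspositionEvent(
            event_id=f"{family_id}_ev{i:04d}",
            family_id=family_id,
            donor_copy=donor.copy_id,
            contig=contig,
            site=site,
            orientation=orientation,
            tsd_seq=genome.contigs[contig][site:site + tsd_length],
            element_seq=inserted,
        )
        events.append(ev)
        mutated.append(apply_events(genome.contigs, [ev], tsd_length))
    return mutated, events


def apply_events(
    contigs: dict[str, str], events: list[TranspositionEvent], tsd_length: int = 8
) -> dict[str, str]:
    """Apply insertion events (flank + TSD + element + TSD + flank) to a
    contig set; events are applied right-to-left so coordinates (given on the
    unmutated reference) stay valid."""
    out = dict(contigs)
    for ev in sorted(events, key=lambda e: (e.contig, -e.site)):
        seq = out[ev.contig]
        s, k = ev.site, len(ev.tsd_seq)
        out[ev.contig] = seq[:s + k] + ev.element_seq + seq[s:]
    return out
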