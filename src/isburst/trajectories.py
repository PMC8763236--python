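"""Allele-frequency trajectories across sequenced timepoints and populations.

Per-timepoint insertion calls are merged into an allele x timepoint frequency
matrix per population (a fish-plot table). Undetected timepoints are stored
as null, distinct from 0: population sequencing cannot tell absence from
presence below the detection cutoff. Classification, parallelism across
populations, clonal-interference summaries and Muller-plot export operate on
these tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AlleleKey:
    family: str
    contig: str
    site: int
    orientation: str

    def matches(self, other: "AlleleKey", tolerance: int) -> bool:
        return (
            self.family == other.family
            and self.contig == other.contig
            and self.orientation == other.orientation
            and abs(self.site - other.site) <= tolerance
        )

    def label(self) -> str:
        return f"{self.family}:{self.contig}:{self.site}:{self.orientation}"


@dataclass
class TrajectoryTable:
    population: str
    timepoints: list[float]                      # generations
    frequencies: pd.DataFrame                    # index: allele label, columns: timepoints
    keys: dict[str, AlleleKey] = field(default_factory=dict)
    statuses: dict[str, str] = field(default_factory=dict)


def build_trajectories(
    call_sets: dict[float, list],
    population: str = "pop",
    site_tolerance: int = 5,
) -> TrajectoryTable:
    """Merge per-timepoint call lists into one trajectory table.

    ``call_sets`` maps generation -> list of calls (InsertionCall or any
    object with family/contig/site/orientation/frequency). Calls merge across
    timepoints when family, contig and orientation match and sites are within
    ``site_tolerance``; the lowest coordinate becomes the canonical site.
    Conflicting orientations at one site stay distinct alleles. Undetected
    timepoints are null.
    """
    timepoints = sorted(call_sets)
    canonical: list[AlleleKey] = []
    entries: dict[tuple[int, float], float] = {}

    for t in timepoints:
        for call in call_sets[t]:
            key = AlleleKey(call.family, call.contig, int(call.site), call.orientation)
            match_idx = None
            for i, ck in enumerate(canonical):
                if ck.matches(key, site_tolerance):
                    match_idx = i
                    break
            if match_idx is None:
                canonical.append(key)
                match_idx = len(canonical) - 1
            elif key.site < canonical[match_idx].site:
                canonical[match_idx] = key  # lowest coordinate wins
            freq = getattr(call, "frequency", None)
            prev = entries.get((match_idx, t))
            entries[(match_idx, t)] = max(prev, freq) if prev is not None else freq

    labels = [k.label() for k in canonical]
    mat = pd.DataFrame(np.nan, index=labels, columns=timepoints)
    for (i, t), f in entries.items():
        mat.iloc[i, timepoints.index(t)] = f
    return TrajectoryTable(
        population=population,
        timepoints=timepoints,
        frequencies=mat,
        keys=dict(zip(labels, canonical)),
    )


def classify_alleles(
    table: TrajectoryTable,
    fixed_threshold: float = 0.95,
    detect_threshold: float = 0.02,
) -> dict[str, str]:
    """fixed: final frequency >= fixed_threshold; lost: detected at some
    timepoint but below the detection cutoff (or null) at the final one;
    segregating otherwise. Pure function of the frequency vectors."""
    if table.frequencies.empty:
        raise ValueError("empty trajectory table")
    statuses = {}
    for label, row in table.frequencies.iterrows():
        vals = row.to_numpy(dtype=float)
        final = vals[-1]
        ever_detected = np.nanmax(vals) >= detect_threshold if not np.all(np.isnan(vals)) else False
        if not np.isnan(final) and final >= fixed_threshold:
            statuses[label] = "fixed"
        elif ever_detected and (np.isnan(final) or final < detect_threshold):
            statuses[label] = "lost"
        else:
            statuses[label] = "segregating"
    table.statuses = statuses
    return statuses


def fixation_rate(
    statuses_per_population: list[dict[str, str]],
    generations_per_population: list[float],
) -> float:
    """Fixed insertion alleles per 1,000 total generations, summed over
    populations (e.g. 10 fixed over 8 x 400 = 3,200 generations -> 3.125)."""
    if not statuses_per_population:
        raise ValueError("need at least one population")
    total_gens = float(sum(generations_per_population))
    if total_gens <= 0:
        raise ValueError("total generations must be positive")
    n_fixed = sum(
        sum(1 for s in statuses.values() if s == "fixed")
        for statuses in statuses_per_population
    )
    return 1000.0 * n_fixed / total_gens


def parallelism(
    tables: list[TrajectoryTable],
    locus_map: dict[str, str] | None = None,
    site_tolerance: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population counts per allele and per locus.

    Alleles are matched across populations with the same tolerance rule used
    within a population. ``locus_map`` maps allele label -> locus (gene or
    window); without it each merged allele is its own locus. Returns
    (per-allele, per-locus) tables sorted by descending population count.
    """
    if len(tables) < 2:
        raise ValueError("parallelism needs >= 2 populations")
    merged: list[AlleleKey] = []
    presence: dict[int, set[str]] = {}
    for tb in tables:
        for label, key in tb.keys.items():
            detected = not tb.frequencies.loc[label].isna().all()
            if not detected:
                continue
            idx = None
            for i, mk in enumerate(merged):
                if mk.matches(key, site_tolerance):
                    idx = i
                    break
            if idx is None:
                merged.append(key)
                idx = len(merged) - 1
            presence.setdefault(idx, set()).add(tb.population)

    rows = [
        {"allele": merged[i].label(), "n_populations": len(pops),
         "populations": ",".join(sorted(pops))}
        for i, pops in presence.items()
    ]
    per_allele = pd.DataFrame(rows).sort_values(
        ["n_populations", "allele"], ascending=[False, True]
    ).reset_index(drop=True)

    locus_pops: dict[str, set[str]] = {}
    for i, pops in presence.items():
        label = merged[i].label()
        locus = (locus_map or {}).get(label, label)
        locus_pops.setdefault(locus, set()).update(pops)
    per_locus = pd.DataFrame(
        [{"locus": loc, "n_populations": len(p)} for loc, p in locus_pops.items()]
    ).sort_values(["n_populations", "locus"], ascending=[False, True]).reset_index(drop=True)
    return per_allele, per_locus


def detect_clonal_interference(
    table: TrajectoryTable,
    locus_map: dict[str, str] | None = None,
    detect_threshold: float = 0.02,
) -> pd.DataFrame:
    """Interference events: (locus, timepoint) pairs where >= 2 distinct
    derived alleles are simultaneously at or above the detection threshold.
    With no locus map the whole genome is one locus (genome-wide clonal
    interference among co-segregating beneficial alleles)."""
    events = []
    loci: dict[str, list[str]] = {}
    for label in table.frequencies.index:
        locus = (locus_map or {}).get(label, "genome")
        loci.setdefault(locus, []).append(label)
    for locus, labels in loci.items():
        sub = table.frequencies.loc[labels]
        for t in table.timepoints:
            col = sub[t]
            above = col[col >= detect_threshold]
            if len(above) >= 2:
                events.append(
                    {
                        "locus": locus,
                        "timepoint": t,
                        "n_alleles": len(above),
                        "alleles": ",".join(above.index),
                        "frequencies": ",".join(f"{v:.3f}" for v in above),
                    }
                )
    return pd.DataFrame(events, columns=["locus", "timepoint", "n_alleles", "alleles", "frequencies"])


def max_cooccurring_alleles(table: TrajectoryTable, detect_threshold: float = 0.02) -> int:
    """Maximum number of distinct derived alleles detected at one timepoint."""
    counts = (table.frequencies >= detect_threshold).sum(axis=0)
    return int(counts.max()) if len(counts) else 0


def muller_export(table: TrajectoryTable, nesting: str = "auto") -> pd.DataFrame:
    """Long-format Muller (fish-plot) table: timepoint, lineage, parent,
    frequency.

    Nesting heuristic: B nests inside A when B's frequency never exceeds A's
    at shared non-null timepoints and B first appears no earlier than A;
    unresolved lineages attach to the root. Sibling frequencies exceeding the
    parent at a timepoint are clipped with a warning column rather than
    silently altered.
    """
    freqs = table.frequencies.fillna(0.0)
    labels = list(freqs.index)

    def first_seen(lb):
        row = table.frequencies.loc[lb]
        nz = row[row.notna() & (row > 0)]
        return nz.index[0] if len(nz) else np.inf

    parents = {lb: "root" for lb in labels}
    if nesting == "auto":
        order = sorted(labels, key=first_seen)
        for i, lb in enumerate(order):
            candidates = []
            for anc in order[:i]:
                shared = table.frequencies.loc[[lb, anc]].dropna(axis=1, how="any")
                if shared.shape[1] == 0:
                    continue
                if (shared.loc[lb] <= shared.loc[anc] + 1e-12).all() and first_seen(lb) >= first_seen(anc):
                    candidates.append(anc)
            if candidates:
                # nest under the tightest containing lineage (latest-arising)
                parents[lb] = max(candidates, key=first_seen)

    rows = []
    for t in table.timepoints:
        for lb in labels:
            rows.append(
                {
                    "timepoint": t,
                    "lineage": lb,
                    "parent": parents[lb],
                    "frequency": float(freqs.loc[lb, t]),
                }
            )
    df = pd.DataFrame(rows)

    # clip sibling sums exceeding the parent frequency
    clipped = []
    for t in table.timepoints:
        sub = df[df.timepoint == t]
        for parent in sub.parent.unique():
            if parent == "root":
                cap = 1.0
            else:
                cap_rows = sub[sub.lineage == parent]
                cap = float(cap_rows.frequency.iloc[0]) if len(cap_rows) else 1.0
            kids = sub[sub.parent == parent]
            total = kids.frequency.sum()
            if total > cap + 1e-9:
                scale = cap / total if total > 0 else 0.0
                df.loc[kids.index, "frequency"] *= scale
                clipped.append((t, parent))
    df["clipped"] = False
    for t, parent in clipped:
        df.loc[(df.timepoint == t) & (df.parent == parent), "clipped"] = True
    if clipped:
        import warnings

        warnings.warn(f"clipped sibling frequencies at {len(clipped)} (timepoint, parent) pairs", stacklevel=2)
    return df


def append_external_alleles(
    table: TrajectoryTable, external: pd.DataFrame
) -> TrajectoryTable:
    """Append externally supplied variant trajectories (e.g. SNPs) from a
    table with columns (allele, timepoint, frequency)."""
    mat = table.frequencies.copy()
    for allele, grp in external.groupby("allele"):
        row = pd.Series(np.nan, index=mat.columns, name=allele)
        for _, r in grp.iterrows():
            if r["timepoint"] in mat.columns:
                row[r["timepoint"]] = r["frequency"]
        mat.loc[allele] = row
    return TrajectoryTable(
        population=table.population,
        timepoints=table.timepoints,
        frequencies=mat,
        keys=dict(table.keys),
    )


def plot_fish(table: TrajectoryTable, ax=None):
    """Simple stacked-area fish plot of allele trajectories (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    t = table.timepoints
    for label, row in table.frequencies.iterrows():
        ax.fill_between(t, 0, row.fillna(0.0).to_numpy(), alpha=0.4, label=label)
    ax.set_xlabel("generation")
    ax.set_ylabel("allele frequency")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=6, loc="upper left")
    return ax
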