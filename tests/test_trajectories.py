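"""Trajectory building, fixation/loss classification, fixation rates,
parallelism, clonal interference and Muller export."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isburst.simulate import EvolutionParams, Genotype, MutationModel, simulate_serial_transfer
from isburst.trajectories import (
    TrajectoryTable,
    append_external_alleles,
    build_trajectories,
    classify_alleles,
    detect_clonal_interference,
    fixation_rate,
    max_cooccurring_alleles,
    muller_export,
    parallelism,
)


@dataclass
class FakeCall:
    family: str
    contig: str
    site: int
    orientation: str
    frequency: float


def _call(site, freq, fam="ISAm1", contig="c0", orient="+"):
    return FakeCall(fam, contig, site, orient, freq)


def _table(rows: dict[str, list], timepoints, population="pop"):
    mat = pd.DataFrame(rows, index=timepoints).T
    return TrajectoryTable(population=population, timepoints=list(timepoints), frequencies=mat,
                           keys={}, statuses={})


class TestBuildTrajectories:
    def test_same_site_merges_across_timepoints(self):
        sets = {
            200: [_call(1000, 0.1)],
            300: [_call(1000, 0.4)],
            400: [_call(1000, 0.9)],
        }
        tb = build_trajectories(sets)
        assert tb.frequencies.shape == (1, 3)
        assert tb.frequencies.notna().sum().sum() == 3

    def test_nearby_sites_merge_within_tolerance(self):
        sets = {100: [_call(1000, 0.2)], 200: [_call(1003, 0.5)]}
        tb = build_trajectories(sets, site_tolerance=5)
        assert tb.frequencies.shape[0] == 1
        # canonical site is the lowest coordinate
        assert list(tb.keys.values())[0].site == 1000

    def test_distant_sites_stay_distinct(self):
        sets = {100: [_call(1000, 0.2)], 200: [_call(1010, 0.5)]}
        tb = build_trajectories(sets, site_tolerance=5)
        assert tb.frequencies.shape[0] == 2

    def test_conflicting_orientations_stay_distinct(self):
        sets = {100: [_call(1000, 0.2, orient="+"), _call(1000, 0.3, orient="-")]}
        tb = build_trajectories(sets)
        assert tb.frequencies.shape[0] == 2

    def test_undetected_is_null_not_zero(self):
        sets = {100: [_call(1000, 0.2)], 200: []}
        tb = build_trajectories(sets)
        assert np.isnan(tb.frequencies.iloc[0][200])

    def test_merge_idempotent(self):
        sets = {
            100: [_call(1000, 0.2), _call(5000, 0.1)],
            200: [_call(1002, 0.5), _call(5001, 0.3)],
        }
        tb = build_trajectories(sets)
        rebuilt_sets = {
            t: [
                FakeCall(k.family, k.contig, k.site, k.orientation, tb.frequencies.loc[lab, t])
                for lab, k in tb.keys.items()
                if not np.isnan(tb.frequencies.loc[lab, t])
            ]
            for t in tb.timepoints
        }
        tb2 = build_trajectories(rebuilt_sets)
        pd.testing.assert_frame_equal(tb.frequencies, tb2.frequencies)


class TestClassifyAlleles:
    def test_rising_to_fixation(self):
        tb = _table({"a": [0.0, 0.1, 0.6, 0.98]}, [100, 200, 300, 400])
        assert classify_alleles(tb)["a"] == "fixed"

    def test_detected_then_lost(self):
        tb = _table({"a": [np.nan, 0.3, 0.05, np.nan]}, [100, 200, 300, 400])
        assert classify_alleles(tb)["a"] == "lost"

    def test_segregating(self):
        tb = _table({"a": [0.1, 0.5, 0.4, 0.3]}, [100, 200, 300, 400])
        assert classify_alleles(tb)["a"] == "segregating"

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
            min_size=2, max_size=6,
        )
    )
    def test_pure_function_of_vector_and_thresholds(self, vec):
        """Status depends only on the frequency vector: detected-and-ended-
        low means lost; high final means fixed; otherwise segregating."""
        tps = list(range(len(vec)))
        tb = _table({"a": [np.nan if v is None else v for v in vec]}, tps)
        status = classify_alleles(tb, 0.95, 0.02)["a"]
        final = vec[-1]
        vals = [v for v in vec if v is not None]
        if final is not None and final >= 0.95:
            assert status == "fixed"
        elif vals and max(vals) >= 0.02 and (final is None or final < 0.02):
            assert status == "lost"
        else:
            assert status == "segregating"

    def test_wf_truth_agreement_outside_boundary_band(self):
        """Statuses agree with simulation truth for alleles whose final
        truth frequency is away from the threshold boundaries."""
        params = EvolutionParams(
            bottleneck_size=1000, n_cycles=40, transposition_rate=2e-5,
            mutation_model=MutationModel(s_exponential=0.05),
        )
        for rep in range(5):
            res = simulate_serial_transfer(None, params, seed=900 + rep)
            af = res.allele_frequencies
            if af.empty:
                continue
            cycles = [int(c) for c in range(0, params.n_cycles + 1, 8)]
            sets = {}
            for cyc in cycles:
                calls = []
                for i, allele in enumerate(af.columns):
                    f = af.loc[cyc, allele]
                    if f >= 0.02:
                        calls.append(_call(1000 + 100 * i, float(f)))
                sets[cyc] = calls
            tb = build_trajectories(sets, site_tolerance=5)
            if tb.frequencies.empty:
                continue  # no allele ever reached the detection cutoff
            statuses = classify_alleles(tb)
            for i, allele in enumerate(af.columns):
                final = af.loc[cycles[-1], allele]
                label = f"ISAm1:c0:{1000 + 100 * i}:+"
                if label not in statuses:
                    continue
                if final > 0.97:
                    assert statuses[label] == "fixed"
                elif 0.03 < final < 0.9:
                    assert statuses[label] == "segregating"


class TestFixationRate:
    def test_experiment_scale(self):
        """10 fixed insertions over eight populations x 400 generations."""
        statuses = [{"a": "fixed"} for _ in range(8)]
        statuses[0]["b"] = "fixed"
        statuses[1]["c"] = "fixed"
        statuses[2]["d"] = "segregating"
        rate = fixation_rate(statuses, [400] * 8)
        assert rate == pytest.approx(1000 * 10 / 3200)
        assert round(rate) == 3

    def test_long_term_scale(self):
        statuses = [{f"m{i}": "fixed" for i in range(355)}]
        assert fixation_rate(statuses, [658_500]) == pytest.approx(0.539, abs=0.001)

    def test_zero_fixed(self):
        assert fixation_rate([{"a": "lost"}], [400]) == 0.0

    def test_zero_generations_rejected(self):
        with pytest.raises(ValueError):
            fixation_rate([{}], [0])

    def test_linear_in_count_and_inverse_in_generations(self):
        s1 = [{f"m{i}": "fixed" for i in range(4)}]
        s2 = [{f"m{i}": "fixed" for i in range(8)}]
        assert fixation_rate(s2, [1000]) == pytest.approx(2 * fixation_rate(s1, [1000]))
        assert fixation_rate(s1, [2000]) == pytest.approx(fixation_rate(s1, [1000]) / 2)


class TestParallelism:
    def _tables(self):
        tbs = []
        for i in range(8):
            rows = {"shared": [0.1, 0.3]}
            if i == 0:
                rows["private"] = [0.05, 0.2]
            tb = build_trajectories(
                {
                    100: [_call(1000, rows["shared"][0])]
                    + ([_call(9000, 0.05)] if i == 0 else []),
                    200: [_call(1000, rows["shared"][1])]
                    + ([_call(9000, 0.2)] if i == 0 else []),
                },
                population=f"pop{i}",
            )
            tbs.append(tb)
        return tbs

    def test_allele_in_all_populations(self):
        per_allele, per_locus = parallelism(self._tables())
        assert per_allele.iloc[0]["n_populations"] == 8
        assert per_allele.set_index("allele").loc["ISAm1:c0:9000:+", "n_populations"] == 1

    def test_disjoint_sets_all_singletons(self):
        tb1 = build_trajectories({100: [_call(1000, 0.2)]}, population="p1")
        tb2 = build_trajectories({100: [_call(9000, 0.2)]}, population="p2")
        per_allele, _ = parallelism([tb1, tb2])
        assert (per_allele["n_populations"] == 1).all()

    def test_hotspot_tops_ranking(self):
        """A mutational hot spot (elevated per-site rate shared across
        populations) ranks first in per-allele parallelism in most runs."""
        sites = [f"site_{i}" for i in range(30)]
        probs = np.full(30, 0.3 / 29)
        probs[7] = 0.7  # hot spot
        model = MutationModel(s_exponential=0.08, site_ids=sites, site_probs=probs)
        top_hits = 0
        n_rep = 20
        for rep in range(n_rep):
            tables = []
            for pop in range(6):
                params = EvolutionParams(
                    bottleneck_size=800, n_cycles=25, transposition_rate=2e-4,
                    mutation_model=model,
                )
                res = simulate_serial_transfer(None, params, seed=3000 + 97 * rep + pop)
                af = res.allele_frequencies
                sets = {}
                for cyc in (10, 18, 25):
                    calls = []
                    for allele in af.columns:
                        f = af.loc[cyc, allele]
                        if f >= 0.02:
                            idx = sites.index(allele)
                            calls.append(_call(1000 + 1000 * idx, float(f)))
                    sets[cyc] = calls
                tables.append(
                    build_trajectories(sets, population=f"p{pop}")
                )
            detected = [tb for tb in tables if tb.frequencies.shape[0]]
            if len(detected) < 2:
                continue
            per_allele, _ = parallelism(detected)
            if len(per_allele) and per_allele.iloc[0]["allele"] == "ISAm1:c0:8000:+":
                top_hits += 1
        assert top_hits / n_rep >= 0.9


class TestClonalInterference:
    def test_two_alleles_one_event(self):
        tb = _table({"a": [0.3], "b": [0.4]}, [200])
        ev = detect_clonal_interference(tb)
        assert len(ev) == 1
        assert ev.iloc[0]["n_alleles"] == 2

    def test_single_allele_no_event(self):
        tb = _table({"a": [0.3, 0.6]}, [100, 200])
        assert detect_clonal_interference(tb).empty

    def test_wf_cooccurrence_detected(self):
        founder = [
            (Genotype("anc", frozenset()), 0.98),
            (Genotype("g1", frozenset({"A"}), 1.08, 1.0), 0.01),
            (Genotype("g2", frozenset({"B"}), 1.08, 1.0), 0.01),
        ]
        params = EvolutionParams(bottleneck_size=2000, n_cycles=25)
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            res = simulate_serial_transfer(founder, params, seed=700 + rep)
            af = res.allele_frequencies
            cyc = list(range(0, 26, 5))
            truth_co = ((af.loc[cyc, "A"] >= 0.02) & (af.loc[cyc, "B"] >= 0.02)).any()
            sets = {
                c: [
                    _call(1000, float(af.loc[c, "A"])) if af.loc[c, "A"] >= 0.02 else None,
                    _call(5000, float(af.loc[c, "B"])) if af.loc[c, "B"] >= 0.02 else None,
                ]
                for c in cyc
            }
            sets = {c: [x for x in v if x] for c, v in sets.items()}
            tb = build_trajectories(sets)
            events = detect_clonal_interference(tb)
            if truth_co:
                assert not events.empty
                hits += 1
        assert hits > 0

    def test_max_cooccurring(self):
        tb = _table({"a": [0.3, 0.1], "b": [0.4, 0.01], "c": [0.05, 0.5]}, [100, 200])
        assert max_cooccurring_alleles(tb) == 3


class TestMullerExport:
    def test_nested_lineage(self):
        tb = _table(
            {"A": [0.2, 0.6, 1.0, 1.0], "B": [np.nan, 0.1, 0.4, 0.9]},
            [100, 200, 300, 400],
        )
        out = muller_export(tb)
        parents = out.groupby("lineage")["parent"].first()
        assert parents["B"] == "A"
        assert parents["A"] == "root"

    def test_mutually_exclusive_both_root(self):
        tb = _table({"A": [0.4, 0.6], "B": [0.5, 0.3]}, [100, 200])
        out = muller_export(tb)
        parents = out.groupby("lineage")["parent"].first()
        assert parents["A"] == "root" and parents["B"] == "root"

    def test_known_genealogy_recovered(self):
        """Nested sweep: C inside B inside A, with clear frequency gaps."""
        tps = [0, 100, 200, 300, 400]
        tb = _table(
            {
                "A": [0.1, 0.5, 0.9, 1.0, 1.0],
                "B": [np.nan, 0.2, 0.5, 0.7, 0.8],
                "C": [np.nan, np.nan, 0.1, 0.3, 0.5],
            },
            tps,
        )
        out = muller_export(tb)
        parents = out.groupby("lineage")["parent"].first()
        assert parents["A"] == "root"
        assert parents["B"] == "A"
        assert parents["C"] == "B"


class TestExternalAlleles:
    def test_append_snp_trajectory(self):
        tb = _table({"A": [0.2, 0.4]}, [100, 200])
        ext = pd.DataFrame(
            {"allele": ["snp:dgc"] * 2, "timepoint": [100, 200], "frequency": [0.1, 0.6]}
        )
        tb2 = append_external_alleles(tb, ext)
        assert "snp:dgc" in tb2.frequencies.index
        assert tb2.frequencies.loc["snp:dgc", 200] == 0.6
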