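"""Bleach subtraction, cross-cycle track matching, artificial-phenotype QC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chipcyto import (
    ChipGeometry,
    CycleKinetics,
    PopulationProfile,
    load_chip,
    simulate_cycles,
)
from chipcyto.correct_qc import (
    QC_PARTIAL,
    QC_REATTACHED,
    QC_RETAINED,
    assemble_cell_table,
    bleach_subtract,
    detections_from_experiment,
    flag_artificial,
    match_tracks,
    qc_summary,
    read_cell_table,
    write_cell_table,
)
from chipcyto.errors import IntegrityError, PairingError, ParameterError
from chipcyto.pipeline import analyze_experiment
from chipcyto.simulate import NOISE_FREE, expression
from chipcyto.presets import STANDARD_PANEL, ms_like


class TestBleachSubtract:
    def test_equal_values_give_zero(self):
        c, neg = bleach_subtract(412.0, 412.0)
        assert c == 0.0 and not neg

    def test_simple_arithmetic(self):
        c, _ = bleach_subtract(500.0, 120.0)
        assert c == 380.0

    def test_negative_floored_and_flagged(self):
        c, neg = bleach_subtract(100.0, 130.0)
        assert c == 0.0 and neg
        d, _ = bleach_subtract(100.0, 130.0, floor=False)
        assert d == -30.0

    def test_mismatched_pairing_rejected(self):
        with pytest.raises(PairingError):
            bleach_subtract(np.ones(3), np.ones(4))
        with pytest.raises(PairingError):
            bleach_subtract(-1.0, 0.0)

    def test_negative_population_mean_corrected_is_zero(self):
        # the core autofluorescence-removal claim: for cells that do not
        # express the marker (E = 0), the corrected signal is unbiased at 0
        # whatever the per-cell autofluorescence and per-FOV offset are
        comp = (PopulationProfile("neg", 1.0, {"M": expression("negative")}),)
        exp = load_chip(10_000, comp, ChipGeometry(5, 5), seed=21)
        exact = simulate_cycles(exp, ("M",), CycleKinetics(**NOISE_FREE), seed=21)
        d_exact, _ = bleach_subtract(exact.mfi_stained, exact.mfi_postbleach, floor=False)
        assert np.allclose(d_exact, 0.0, atol=1e-9)

        noisy_kin = CycleKinetics(detach_probability=0.0)
        noisy = simulate_cycles(exp, ("M",), noisy_kin, seed=22)
        d, _ = bleach_subtract(noisy.mfi_stained, noisy.mfi_postbleach, floor=False)
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean()) < 3 * se

    def test_corrected_invariant_to_additive_offset(self):
        # identical seeds, offsets 0 vs 150: corrected MFIs agree
        comp = ms_like()
        kw = dict(NOISE_FREE)
        exp = load_chip(500, comp, ChipGeometry(3, 3), seed=5)
        flat = simulate_cycles(exp, ("CD3", "CD19"), CycleKinetics(**kw), seed=5)
        kw["illum_offset_range"] = (150.0, 150.0)
        offset = simulate_cycles(exp, ("CD3", "CD19"), CycleKinetics(**kw), seed=5)
        a, _ = bleach_subtract(flat.mfi_stained, flat.mfi_postbleach)
        b, _ = bleach_subtract(offset.mfi_stained, offset.mfi_postbleach)
        np.testing.assert_allclose(a, b, atol=1e-8)


def toy_detections(rows):
    """rows: (cycle, x, y) triples -> detections frame."""
    df = pd.DataFrame(rows, columns=["cycle", "x", "y"])
    df["area_um2"] = 60.0
    df["fov"] = 0
    df["mfi_stained"] = 100.0
    df["mfi_postbleach"] = 10.0
    df.insert(0, "det_id", np.arange(len(df)))
    return df


def brute_force_tracks(det, radius):
    """Minimal-total-distance linking between consecutive cycles by enumeration."""
    cycles = sorted(det["cycle"].unique())
    tracks = {i: [i] for i in det.index[det["cycle"] == cycles[0]]}
    open_end = {i: i for i in tracks}  # detection index -> track key
    for prev, cur in zip(cycles[:-1], cycles[1:]):
        ends = list(open_end)
        cur_idx = list(det.index[det["cycle"] == cur])
        best, best_cost = None, np.inf
        m = min(len(ends), len(cur_idx))
        for k in range(m, -1, -1):
            for esub in itertools.combinations(ends, k):
                for csub in itertools.permutations(cur_idx, k):
                    cost = 0.0
                    ok = True
                    for e, c in zip(esub, csub):
                        d = np.hypot(det.at[e, "x"] - det.at[c, "x"], det.at[e, "y"] - det.at[c, "y"])
                        if d > radius:
                            ok = False
                            break
                        cost += d
                    if ok and (best is None or len(esub) > len(best[0]) or (len(esub) == len(best[0]) and cost < best_cost)):
                        if best is None or len(esub) > len(best[0]):
                            best, best_cost = (esub, csub), cost
                        elif cost < best_cost:
                            best, best_cost = (esub, csub), cost
        new_open = {}
        matched = set()
        for e, c in zip(*best):
            t = open_end[e]
            tracks[t].append(c)
            new_open[c] = t
            matched.add(c)
        for e, t in open_end.items():
            if t not in new_open.values():
                new_open[e] = t  # track stays open at its last detection
        for c in cur_idx:
            if c not in matched:
                tracks[c] = [c]
                new_open[c] = c
        open_end = new_open
    return sorted(tuple(sorted(v)) for v in tracks.values())


class TestMatchTracks:
    def test_single_cycle_gives_singleton_tracks(self):
        det = toy_detections([(0, 0, 0), (0, 50, 0), (0, 0, 50)])
        out = match_tracks(det)
        assert out["track_id"].nunique() == 3

    def test_static_cells_form_full_tracks(self, ms_composition):
        exp = load_chip(300, ms_composition, ChipGeometry(3, 3), seed=6)
        exp = simulate_cycles(exp, ("CD3", "CD19", "CD38"), CycleKinetics(detach_probability=0.0), seed=6)
        tracked = match_tracks(detections_from_experiment(exp))
        lengths = tracked.groupby("track_id").size()
        assert (lengths == 3).all()
        assert tracked["track_id"].nunique() == 300

    def test_matches_brute_force_assignment_on_reattachment_toy(self):
        # 5 cells, 3 cycles; cell E detaches after cycle 0 and reappears
        # elsewhere in cycle 2 -> linking equals exhaustive minimal-distance
        rows = []
        static = [(0.0, 0.0), (50.0, 0.0), (0.0, 50.0), (50.0, 50.0)]
        for k in range(3):
            for x, y in static:
                rows.append((k, x + 0.3 * k, y))  # small drift within radius
        rows.append((0, 25.0, 25.0))  # cell E, cycle 0 only
        rows.append((2, 100.0, 100.0))  # its reappearance elsewhere
        det = toy_detections(rows)
        out = match_tracks(det, radius_um=5.0)
        greedy = sorted(
            tuple(sorted(g["det_id"])) for _, g in out.groupby("track_id")
        )
        assert greedy == brute_force_tracks(det.set_index("det_id", drop=False), 5.0)

    def test_invalid_radius(self):
        with pytest.raises(ParameterError):
            match_tracks(toy_detections([(0, 0, 0)]), radius_um=0.0)


class TestFlagArtificial:
    def make_tracked(self, spans, n_cycles):
        rows = []
        for tid, cycles in enumerate(spans):
            for k in cycles:
                rows.append((tid * 100 + k, k, float(tid), 0.0, 60.0, 0, 100.0, 10.0, tid))
        df = pd.DataFrame(
            rows,
            columns=["det_id", "cycle", "x", "y", "area_um2", "fov", "mfi_stained", "mfi_postbleach", "track_id"],
        )
        return df

    def test_status_rules(self):
        n = 10
        tracked = self.make_tracked([range(10), range(3), range(3, 10)], n)
        records = {r.cell_id: r for r in flag_artificial(tracked, n)}
        assert records[0].qc_status == QC_RETAINED
        assert records[1].qc_status == QC_PARTIAL  # would read zero for markers 4-10
        assert records[2].qc_status == QC_REATTACHED

    def test_retained_records_have_every_marker(self, small_experiment):
        table, records, _ = analyze_experiment(small_experiment)
        panel = small_experiment.panel
        for r in records:
            if r.qc_status == QC_RETAINED:
                assert set(r.corrected_mfi) == set(panel)
        assert not table[list(panel)].isna().any().any()

    def test_reattachment_recall_on_ground_truth(self, ms_composition):
        # cells that detached and re-adhered elsewhere must be flagged
        exp = load_chip(3000, ms_composition, ChipGeometry(6, 6), seed=31)
        kin = CycleKinetics(detach_probability=0.05, reattach_probability=0.5)
        exp = simulate_cycles(exp, STANDARD_PANEL, kin, seed=31)
        _, records, _ = analyze_experiment(exp)
        # ground truth: cells measured again at/after their reattachment
        candidates = np.flatnonzero(
            (exp.reattach_cycle > 0) & (exp.reattach_cycle < exp.n_cycles)
        )
        truly_reattached = {
            i for i in candidates if exp.present[i, exp.reattach_cycle[i] :].any()
        }
        flagged = {
            r.true_cell
            for r in records
            if r.qc_status == QC_REATTACHED and r.true_cell is not None
        }
        recall = len(truly_reattached & flagged) / len(truly_reattached)
        assert recall >= 0.95

    def test_exclusion_rate_monotone_in_detach_probability(self, ms_composition):
        rates = []
        for p in (0.0, 0.02, 0.05, 0.10):
            exp = load_chip(1500, ms_composition, ChipGeometry(5, 5), seed=41)
            exp = simulate_cycles(
                exp, STANDARD_PANEL, CycleKinetics(detach_probability=p), seed=41
            )
            _, _, summary = analyze_experiment(exp)
            rates.append(summary["exclusion_rate"])
        assert all(a <= b for a, b in zip(rates, rates[1:]))

    def test_n_cycles_validation(self):
        with pytest.raises(ParameterError):
            flag_artificial(self.make_tracked([range(1)], 1), 0)


class TestAssemble:
    def test_empty_table_keeps_header(self):
        table = assemble_cell_table([], ("CD3", "CD19"))
        assert list(table.columns) == ["cell_id", "x", "y", "size_um2", "CD3", "CD19"]
        assert len(table) == 0

    def test_only_retained_rows(self):
        n = 3
        maker = TestFlagArtificial()
        tracked = maker.make_tracked([range(n), range(n), range(n), range(1), range(1, n)], n)
        records = flag_artificial(tracked, n, panel=("a", "b", "c"))
        table = assemble_cell_table(records, ("a", "b", "c"))
        assert len(table) == 3

    def test_duplicate_ids_rejected(self):
        maker = TestFlagArtificial()
        tracked = maker.make_tracked([range(2)], 2)
        records = flag_artificial(tracked, 2, panel=("a", "b"))
        with pytest.raises(IntegrityError):
            assemble_cell_table(records + records, ("a", "b"))

    def test_csv_roundtrip_value_identical(self, tmp_path, small_experiment):
        table, _, _ = analyze_experiment(small_experiment)
        path = tmp_path / "cells.csv"
        write_cell_table(table, path)
        back = read_cell_table(path)
        pd.testing.assert_frame_equal(table.reset_index(drop=True), back, check_exact=True)

    def test_qc_summary_counts_consistent(self, small_experiment):
        _, records, summary = analyze_experiment(small_experiment)
        assert sum(summary["counts"].values()) == summary["n_tracks"] == len(records)
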