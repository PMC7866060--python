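"""Control subtraction, locus calling, shared tables and BED intersection."""

import numpy as np
import pandas as pd
import pytest

import sevscan as sv


def _calls(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "probe_id", "direction", "beta", "excess"]
    )


class TestSubtractControlProfile:
    def test_probe_level_set_difference(self):
        case = _calls([("s1", "p1", "hyper", 0.9, 0.1),
                       ("s1", "p2", "hyper", 0.9, 0.1),
                       ("s1", "p3", "hyper", 0.9, 0.1)])
        control = _calls([("c1", "p2", "hyper", 0.9, 0.1)])
        out = sv.subtract_control_profile(case, control)
        assert list(out["probe_id"]) == ["p1", "p3"]

    def test_empty_control_union_is_identity(self):
        case = _calls([("s1", "p1", "hyper", 0.9, 0.1)])
        out = sv.subtract_control_profile(case, case.iloc[:0])
        pd.testing.assert_frame_equal(out, case)

    def test_fully_overlapping_case_yields_no_loci(self, toy_manifest):
        case = _calls([("s1", "p01", "hyper", 0.9, 0.1),
                       ("s1", "p02", "hyper", 0.9, 0.1)])
        control = _calls([("c1", "p01", "hyper", 0.9, 0.1),
                          ("c2", "p02", "hypo", 0.1, 0.1)])
        out = sv.subtract_control_profile(case, control)
        assert out.empty
        assert sv.call_gene_loci(out, toy_manifest).empty

    def test_gene_level_mode_removes_whole_gene(self, toy_manifest):
        case = _calls([("s1", "p01", "hyper", 0.9, 0.1),
                       ("s1", "p04", "hyper", 0.9, 0.1),
                       ("s1", "p05", "hyper", 0.9, 0.1)])
        control = _calls([("c1", "p02", "hyper", 0.9, 0.1)])  # g1 deregulated in controls
        probe_out = sv.subtract_control_profile(case, control)
        gene_out = sv.subtract_control_profile(
            case, control, gene_level=True, manifest=toy_manifest
        )
        assert list(probe_out["probe_id"]) == ["p01", "p04", "p05"]
        assert list(gene_out["probe_id"]) == ["p05"]  # p01, p04 belong to g1


class TestCallGeneLoci:
    def test_singleton_loci_dropped(self, toy_manifest):
        retained = _calls([("s1", "p01", "hyper", 0.9, 0.1),
                           ("s1", "p02", "hyper", 0.9, 0.1),
                           ("s1", "p05", "hyper", 0.9, 0.1)])
        loci = sv.call_gene_loci(retained, toy_manifest)
        assert len(loci) == 1
        locus = loci.iloc[0]
        assert locus["gene"] == "g1" and locus["n_sevs"] == 2
        assert locus["probe_ids"] == ["p01", "p02"]

    def test_multi_gene_label_kept_verbatim(self, toy_manifest):
        retained = _calls([("s1", "p09", "hypo", 0.1, 0.1),
                           ("s1", "p10", "hypo", 0.1, 0.1)])
        loci = sv.call_gene_loci(retained, toy_manifest)
        assert list(loci["gene"]) == ["g3;g4"]
        assert list(loci["direction"]) == ["hypo"]

    def test_intergenic_probes_dropped(self, toy_manifest):
        retained = _calls([("s1", "p00", "hyper", 0.9, 0.1),
                           ("s1", "p08", "hyper", 0.9, 0.1),
                           ("s1", "p11", "hyper", 0.9, 0.1)])
        assert sv.call_gene_loci(retained, toy_manifest).empty

    def test_mixed_direction_locus_flagged(self, toy_manifest):
        retained = _calls([("s1", "p05", "hyper", 0.9, 0.1),
                           ("s1", "p06", "hypo", 0.1, 0.1)])
        loci = sv.call_gene_loci(retained, toy_manifest)
        assert list(loci["direction"]) == ["mixed"]

    def test_empty_input_empty_output(self, toy_manifest):
        assert sv.call_gene_loci(_calls([]), toy_manifest).empty

    def test_rerun_on_own_probes_is_noop(self, toy_manifest):
        retained = _calls([("s1", "p01", "hyper", 0.9, 0.1),
                           ("s1", "p02", "hyper", 0.9, 0.1)])
        loci = sv.call_gene_loci(retained, toy_manifest)
        again = sv.call_gene_loci(retained, toy_manifest)
        pd.testing.assert_frame_equal(loci, again)


class TestSharedGeneTable:
    def test_most_shared_gene_layout(self):
        # six samples share one gene, with per-sample retained-SEV counts
        loci = pd.DataFrame(
            {
                "sample_id": ["S02", "S08", "S12", "S23", "S41", "S45", "S30"],
                "gene": ["PPFIA4"] * 6 + ["NPY"],
                "n_sevs": [5, 5, 5, 4, 4, 4, 5],
                "direction": ["hyper"] * 7,
                "probe_ids": [[]] * 7,
            }
        )
        table = sv.shared_gene_table(loci, "hyper")
        assert list(table["gene"]) == ["PPFIA4", "NPY"]
        top = table.iloc[0]
        assert top["n_cases"] == 6
        assert top["cases"] == "S02 (5), S08 (5), S12 (5), S23 (4), S41 (4), S45 (4)"

    def test_single_locus_table(self):
        loci = pd.DataFrame(
            {"sample_id": ["s1"], "gene": ["g"], "n_sevs": [3],
             "direction": ["hypo"], "probe_ids": [["a", "b", "c"]]}
        )
        table = sv.shared_gene_table(loci, "hypo")
        assert len(table) == 1 and table.iloc[0]["n_cases"] == 1

    def test_direction_tables_partition_unidirectional_loci(self):
        loci = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "gene": ["a", "b", "c"],
                "n_sevs": [2, 2, 2],
                "direction": ["hyper", "hypo", "mixed"],
                "probe_ids": [[]] * 3,
            }
        )
        hyper = sv.shared_gene_table(loci, "hyper")
        hypo = sv.shared_gene_table(loci, "hypo")
        assert set(hyper["gene"]) == {"a"}
        assert set(hypo["gene"]) == {"b"}
        # mixed loci appear in neither directional table
        assert "c" not in set(hyper["gene"]) | set(hypo["gene"])

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError):
            sv.shared_gene_table(pd.DataFrame(), "sideways")


class TestIntersectRegionSets:
    def test_five_of_seven_probe_report(self, toy_manifest):
        # region spanning probes p03..p09 (positions 3500..9500, 1-based)
        regions = pd.DataFrame(
            {"chromosome": ["chr1"], "start": [3000], "end": [10000], "name": ["dmr1"]}
        )
        retained = _calls(
            [("s1", f"p{i:02d}", "hypo", 0.05, 0.1) for i in (3, 4, 5, 6, 7)]
        )
        report = sv.intersect_region_sets(retained, toy_manifest, regions)
        row = report.iloc[0]
        assert row["n_retained"] == 5 and row["n_hypo"] == 5
        assert row["n_universe_probes"] == 7

    def test_half_open_boundary_convention(self):
        man = pd.DataFrame(
            {"chromosome": "chr1", "position": [101, 200], "gene": ""},
            index=pd.Index(["a", "b"], name="probe_id"),
        )
        # 0-based coords of the probes are 100 and 199
        regions = pd.DataFrame(
            {"chromosome": ["chr1"], "start": [100], "end": [199], "name": ["r"]}
        )
        retained = _calls([("s1", "a", "hyper", 0.9, 0.1),
                           ("s1", "b", "hyper", 0.9, 0.1)])
        report = sv.intersect_region_sets(retained, man, regions)
        row = report.iloc[0]
        assert row["n_retained"] == 1  # probe at start included, at end excluded
        assert row["n_universe_probes"] == 1

    def test_empty_region_table(self, toy_manifest):
        report = sv.intersect_region_sets(
            _calls([("s1", "p01", "hyper", 0.9, 0.1)]),
            toy_manifest,
            pd.DataFrame(columns=["chromosome", "start", "end", "name"]),
        )
        assert report.empty

    def test_universe_restriction_changes_denominator(self, toy_manifest):
        regions = pd.DataFrame(
            {"chromosome": ["chr1"], "start": [0], "end": [100000], "name": ["all"]}
        )
        retained = _calls([("s1", "p01", "hyper", 0.9, 0.1)])
        full = sv.intersect_region_sets(retained, toy_manifest, regions)
        half = sv.intersect_region_sets(
            retained, toy_manifest, regions, universe=toy_manifest.index[:6]
        )
        assert full.iloc[0]["n_universe_probes"] == 12
        assert half.iloc[0]["n_universe_probes"] == 6


class TestPipelineNesting:
    def test_monotone_subsets_end_to_end(self, small_manifest, small_cohort):
        beta, sheet, det_p, beads = small_cohort
        beta, truth = sv.inject_epivariants(
            beta, small_manifest, sheet, n_isolated=2, n_regions=1,
            region_length=4, fence_margin=0.15, seed=21,
        )
        res = sv.run_sev_pipeline(
            beta, small_manifest, sheet, detection_p=det_p, bead_counts=beads,
            fit_burden=False,
        )
        universe = set(res.beta.index)
        sev_keys = set(zip(res.sevs["sample_id"], res.sevs["probe_id"]))
        retained_keys = set(zip(res.retained["sample_id"], res.retained["probe_id"]))
        assert set(res.sevs["probe_id"]) <= universe
        assert retained_keys <= sev_keys
        control_probes = set(
            res.retained.loc[
                ~res.retained["sample_id"].isin(sheet.index[sheet["group"] == "case"]),
                "probe_id",
            ]
        )
        assert not (set(res.case_retained["probe_id"]) & control_probes)
        for locus in res.loci.itertuples():
            assert locus.n_sevs >= 2
            for probe in locus.probe_ids:
                assert (locus.sample_id, probe) in retained_keys
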