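"""CPM activity calls, active/silent contrasts, methylation metaprofiles."""

import math

import numpy as np
import pandas as pd
import pytest

from ltrkit.activity_methylation import (
    ProfileParams,
    call_activity,
    compare_active_silent,
    cpm,
    element_profile_features,
    flank_te_density,
    gene_vs_ltr_profile,
    metaprofile,
    _feature_bins,
)
from ltrkit.core_io import CytosineCall, GenomicInterval, RepeatHit
from ltrkit.ltr_age import date_elements


class TestCpmAndActivity:
    def test_cpm_normalization(self):
        counts = pd.DataFrame({"s1": [100, 999_900]}, index=["a", "rest"])
        c = cpm(counts)
        assert c.loc["a", "s1"] == pytest.approx(100.0)
        assert c.sum(axis=0)["s1"] == pytest.approx(1e6)

    def test_cpm_exactly_one_is_silent(self):
        counts = pd.DataFrame({"s1": [1, 999_999]}, index=["a", "rest"])
        calls = {c.element_id: c for c in call_activity(cpm(counts))}
        assert calls["a"].mean_cpm == pytest.approx(1.0)
        assert not calls["a"].active  # strict > 1 rule

    def test_zero_library_error(self):
        with pytest.raises(ValueError, match="library"):
            cpm(pd.DataFrame({"s1": [0, 0]}, index=["a", "b"]))

    @pytest.mark.parametrize("values,active",
                             [((0.4, 0.8), False), ((3.0, 1.5), True)])
    def test_mean_cpm_rule(self, values, active):
        m = pd.DataFrame({"rep1": [values[0]], "rep2": [values[1]]},
                         index=["el"])
        (call,) = call_activity(m)
        assert call.active is active

    def test_sim_truth_recovered_exactly(self, small_sim):
        calls = call_activity(cpm(small_sim.counts))
        got = {c.element_id: c.active for c in calls
               if c.element_id.startswith("sim_intact")}
        expected = {f.feature_id: f.active for f in small_sim.truth.intact}
        assert got == expected


class TestCompareActiveSilent:
    def test_direction_recovery(self, small_sim, small_elements):
        ages = {a.element_id: a.T
                for a in date_elements(small_elements, small_sim.genome)}
        truth = {f.interval.start: f.active for f in small_sim.truth.intact}
        activity = {el.element_id: truth[el.element_interval.start]
                    for el in small_elements}
        table = compare_active_silent(small_elements, ages, activity)
        assert set(table.index) == {"length_bp", "age_MY"}
        assert (table["n_active"] + table["n_silent"]).iloc[0] == \
            len(small_elements)

    def test_small_group_error(self, small_elements):
        activity = {el.element_id: False for el in small_elements}
        with pytest.raises(ValueError, match=">= 2"):
            compare_active_silent(small_elements, {}, activity)

    def test_constructed_directions(self):
        from ltrkit.ltr_detect import IntactLTRRT

        def el(eid, start, length):
            return IntactLTRRT(
                eid, GenomicInterval("c", start, start + length),
                GenomicInterval("c", start, start + 100),
                GenomicInterval("c", start + length - 100, start + length),
                GenomicInterval("c", start + 100, start + length - 100),
                "ACGT", True, 0.95,
            )

        short = [el(f"a{i}", 10_000 * i, 2000 + 10 * i) for i in range(5)]
        long_ = [el(f"s{i}", 10_000 * (i + 10), 8000 + 10 * i)
                 for i in range(5)]
        activity = {e.element_id: e.element_id.startswith("a")
                    for e in short + long_}
        ages = {e.element_id: (0.2 if e.element_id.startswith("a") else 2.0)
                for e in short + long_}
        table = compare_active_silent(short + long_, ages, activity)
        assert table.loc["length_bp", "active_mean"] < \
            table.loc["length_bp", "silent_mean"]
        assert table.loc["age_MY", "active_mean"] < \
            table.loc["age_MY", "silent_mean"]


def brute_force_bins(calls, features, params):
    """Independent per-cytosine enumeration of every profile bin."""
    acc = {}
    for fid, interval, lineage, activity in features:
        for c in calls:
            if c.seq_id != interval.seq_id or c.coverage < params.min_coverage:
                continue
            hit = _feature_bins(interval, c.pos, params)
            if hit is None:
                continue
            key = (c.context, lineage, activity, *hit)
            m, t = acc.get(key, (0, 0))
            acc[key] = (m + c.meth_count, t + c.coverage)
    return acc


class TestMetaprofile:
    def test_single_site_oracle(self):
        iv = GenomicInterval("c", 1000, 3000)
        calls = [CytosineCall("c", 1500, "+", "CG", 3, 1)]
        prof = metaprofile(calls, [("el", iv, "SIRE", "silent")])
        row = prof[(prof.region == "body") & (prof.level.notna())]
        assert len(row) == 1
        assert row.iloc[0]["level"] == pytest.approx(0.75)
        assert row.iloc[0]["bin"] == 5  # position 1500 of a 2000-bp body

    def test_every_bin_matches_brute_force(self, small_sim):
        params = ProfileParams()
        feats = [(f.feature_id, f.interval, f.lineage,
                  "active" if f.active else "silent")
                 for f in small_sim.truth.intact]
        calls = small_sim.cx_calls
        prof = metaprofile(calls, feats, params)
        expected = brute_force_bins(calls, feats, params)
        region_names = {"upstream", "body", "downstream"}
        assert set(prof.region) == region_names
        for _, row in prof.iterrows():
            key = (row.context, row.lineage, row.activity, row.region, row.bin)
            m, t = expected.get(key, (0, 0))
            assert row.meth == m and row.total == t
            if t:
                assert row.level == pytest.approx(m / t)
            else:
                assert math.isnan(row.level)
        # conservation: nothing double-counted or dropped
        assert prof.total.sum() == sum(t for _, t in expected.values())

    def test_invariant_under_input_permutation(self, small_sim):
        feats = [(f.feature_id, f.interval, f.lineage,
                  "active" if f.active else "silent")
                 for f in small_sim.truth.intact]
        prof1 = metaprofile(small_sim.cx_calls, feats)
        rng = np.random.default_rng(0)
        calls = list(small_sim.cx_calls)
        rng.shuffle(calls)
        feats2 = list(reversed(feats))
        prof2 = metaprofile(calls, feats2)
        pd.testing.assert_frame_equal(prof1, prof2)

    def test_planted_gap_recovered(self, small_sim):
        feats = [(f.feature_id, f.interval, "pooled",
                  "active" if f.active else "silent")
                 for f in small_sim.truth.intact]
        prof = metaprofile(small_sim.cx_calls, feats)
        body = prof[prof.region == "body"]
        level = body.groupby(["context", "activity"]).apply(
            lambda g: g.meth.sum() / g.total.sum(), include_groups=False
        )
        meth = small_sim.config.methylation
        for i, ctx in enumerate(("CG", "CHG", "CHH")):
            assert level[(ctx, "silent")] == pytest.approx(meth.silent[i],
                                                           abs=0.03)
            assert level[(ctx, "active")] == pytest.approx(meth.active[i],
                                                           abs=0.03)

    def test_edge_feature_missing_bins(self):
        iv = GenomicInterval("c", 500, 2500)  # upstream flank truncated
        calls = [CytosineCall("c", 400, "+", "CG", 4, 0),
                 CytosineCall("c", 600, "+", "CG", 2, 2)]
        prof = metaprofile(calls, [("el", iv, "x", "all")])
        up = prof[prof.region == "upstream"]
        present = up[up.level.notna()]
        assert len(present) == 1  # only the bin holding pos 400
        assert present.iloc[0]["level"] == 1.0

    def test_low_coverage_cytosines_excluded(self):
        iv = GenomicInterval("c", 1000, 3000)
        calls = [CytosineCall("c", 1500, "+", "CG", 1, 1)]  # coverage 2 < 4
        prof = metaprofile(calls, [("el", iv, "x", "all")])
        assert prof.empty  # no covered cytosine -> no stratum observed


class TestGeneVsLtr:
    def test_ltr_bodies_more_methylated_than_genes(self, small_sim,
                                                   small_elements):
        gene_prof, ltr_prof = gene_vs_ltr_profile(
            small_sim.cx_calls, small_sim.genes, small_elements
        )
        g = gene_prof[(gene_prof.region == "body")
                      & (gene_prof.context == "CG")]
        l = ltr_prof[(ltr_prof.region == "body")
                     & (ltr_prof.context == "CG")]
        assert l.meth.sum() / l.total.sum() > 4 * (g.meth.sum() / g.total.sum())

    def test_empty_gene_set_error(self, small_sim, small_elements):
        with pytest.raises(ValueError, match="empty gene set"):
            gene_vs_ltr_profile(small_sim.cx_calls, [], small_elements)

    def test_shared_binning_with_metaprofile(self, small_sim, small_elements):
        _, ltr_prof = gene_vs_ltr_profile(
            small_sim.cx_calls, small_sim.genes, small_elements
        )
        direct = metaprofile(
            small_sim.cx_calls,
            [(el.element_id, el.element_interval, "LTR-RT", "all")
             for el in small_elements],
        )
        pd.testing.assert_frame_equal(ltr_prof, direct)


class TestFlankTeDensity:
    def _element(self, eid, start, end, lineage):
        from ltrkit.ltr_detect import IntactLTRRT

        el = IntactLTRRT(
            eid, GenomicInterval("c", start, end),
            GenomicInterval("c", start, start + 100),
            GenomicInterval("c", end - 100, end),
            GenomicInterval("c", start + 100, end - 100),
            "ACGT", True, 0.95,
        )
        el.lineage = lineage
        return el

    def test_full_and_empty_flanks(self):
        el = self._element("e1", 10_000, 15_000, "CRM")
        full = [RepeatHit(GenomicInterval("c", 0, 30_000), "x", 0, 100, 0.9)]
        dens = flank_te_density([el], full)
        assert dens.loc["CRM", "density"] == 1.0
        dens = flank_te_density([el], [])
        assert dens.loc["CRM", "density"] == 0.0

    def test_planted_cluster_enrichment(self):
        crm = self._element("e1", 10_000, 15_000, "CRM")
        other = self._element("e2", 50_000, 55_000, "Ale")
        hits = [RepeatHit(GenomicInterval("c", 8_000, 10_000), "x", 0, 100, 0.9),
                RepeatHit(GenomicInterval("c", 15_000, 16_500), "x", 0, 100, 0.9)]
        dens = flank_te_density([crm, other], hits)
        assert dens.loc["CRM", "density"] > dens.loc["Ale", "density"]
        assert dens.loc["CRM", "density"] == pytest.approx(3500 / 4000)
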