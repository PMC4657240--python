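"""Acetylation subclassing, oriented boundary metaprofiles, qPCR arithmetic."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import crmclass as cc
from crmclass.boundary import oriented_profile, qpcr_enrichment, subclassify_histone
from crmclass.features import BindingMatrix

from conftest import make_track


def histone_matrix(df):
    meta = pd.DataFrame({"genomic_mean": 0.0, "genomic_max": 1.0,
                         "half_window": 250, "is_histone": True},
                        index=pd.Index(df.columns, name="dataset"))
    return BindingMatrix(df, meta)


class TestSubclassifyHistone:
    def planted(self, rng, n=30):
        cols = ["H3K27ac", "H3K18ac", "H3K23ac", "H3K27me3", "H3K4me1"]
        hi = rng.normal([3, 3, 1, 0, 1], 0.2, size=(n, 5))
        lo = rng.normal([0, 0, 1.2, 0.5, 1], 0.2, size=(n, 5))
        X = np.vstack([hi, lo])
        order = rng.permutation(2 * n)
        truth = (order >= n).astype(int)  # 1 = low acetyl
        df = pd.DataFrame(X[order], columns=cols,
                          index=[f"p{i}" for i in range(2 * n)])
        return histone_matrix(df), truth

    def test_recovers_planted_acetylation_split(self, rng):
        bm, truth = self.planted(rng)
        labels, high = subclassify_histone(bm, k=2)
        assert adjusted_rand_score(truth, labels) == 1.0
        # the high-acetyl flag must land on the truth-high subclass
        high_members = truth[labels == high]
        assert (high_members == 0).all()

    def test_k_exceeding_observations_rejected(self, rng):
        bm, _ = self.planted(rng, n=1)
        with pytest.raises(ValueError):
            subclassify_histone(bm, k=5)

    def test_identical_rows_degenerate_single_cluster(self, caplog):
        df = pd.DataFrame(np.ones((8, 3)), columns=["H3K27ac", "H3K9ac", "H3K4me1"])
        labels, high = subclassify_histone(histone_matrix(df), k=2)
        assert set(labels.tolist()) == {1}
        assert high is None


class TestOrientedProfile:
    def sloped_track(self, left_level, right_level, n_regions=10):
        """Regions at fixed centres with a plateau on the right flank."""
        bs, flank = 10, 2000
        spacing = 10_000
        n_bins = (n_regions + 2) * spacing // bs
        v = np.zeros(n_bins)
        centres = []
        for i in range(n_regions):
            c = (i + 1) * spacing
            centres.append(c)
            v[(c - flank) // bs:c // bs] = left_level
            v[c // bs:(c + flank) // bs] = right_level
        g = cc.GenomeModel(("c",), {"c": n_bins * bs}, bs)
        track = make_track(g, {"c": v}, "scaled")
        regions = cc.RegionSet.from_records([("c", c - 50, c + 50) for c in centres])
        return track, regions

    def test_right_flank_total_dominates_for_every_region(self, rng):
        g = cc.GenomeModel(("c",), {"c": 100_000}, 10)
        track = make_track(g, {"c": rng.normal(size=10_000)}, "scaled")
        regions = cc.RegionSet.from_records(
            [("c", int(c) - 50, int(c) + 50) for c in rng.integers(5000, 95_000, 30)])
        prof = oriented_profile(regions, track, flank=2000, out_bin=100)
        assert (prof.right_sum >= prof.left_sum).all()

    def test_symmetric_signal_unaffected_by_orientation(self):
        track, regions = self.sloped_track(2.0, 2.0)
        a = oriented_profile(regions, track, flank=2000, out_bin=100, orient=True)
        b = oriented_profile(regions, track, flank=2000, out_bin=100, orient=False)
        assert np.allclose(a.mean, b.mean)
        assert not a.flipped.any()  # exact ties are never flipped

    def test_low_signal_flank_oriented_left(self):
        track, regions = self.sloped_track(0.0, 2.0)
        prof = oriented_profile(regions, track, flank=2000, out_bin=100)
        left, right = prof.flank_means()
        assert left < 0.25 * right

    def test_orientation_idempotent(self):
        # flipping a set whose stronger flank already sits right is a no-op
        track, regions = self.sloped_track(0.0, 2.0)
        once = oriented_profile(regions, track, flank=2000, out_bin=100)
        again = oriented_profile(regions, track, flank=2000, out_bin=100)
        assert np.array_equal(once.mean, again.mean)
        assert not once.flipped.any()  # plateau built on the right already

    def test_domain_distance_filter_reports_counts(self):
        track, regions = self.sloped_track(0.0, 2.0)
        far_domains = cc.RegionSet.from_records([("c", 0, 50)])
        with pytest.raises(ValueError, match="far_from_domain"):
            oriented_profile(regions, track, flank=2000, out_bin=100,
                             domains=far_domains, max_domain_distance=100)

    def test_bad_binning_rejected(self):
        track, regions = self.sloped_track(0.0, 2.0)
        with pytest.raises(ValueError):
            oriented_profile(regions, track, flank=2000, out_bin=3)


class TestQpcrEnrichment:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["site", "antibody", "condition",
                                           "replicate", "cq"])

    def flat_table(self, cq=20.0, reps=2):
        rows = []
        for site in ("s1", "cA", "cB"):
            for cond in ("treated", "control"):
                for r in range(1, reps + 1):
                    for ab in ("input", "target", "H3"):
                        rows.append((site, ab, cond, r, cq))
        return self.table(rows)

    def test_parity_everywhere_gives_unit_folds(self):
        finals, summary = qpcr_enrichment(self.flat_table(), ("cA", "cB"))
        assert np.allclose(finals["value"], 1.0)
        assert summary.set_index("site").loc["s1", "fold"] == pytest.approx(1.0)

    def test_one_cycle_drop_is_exactly_twofold(self):
        t = self.flat_table()
        sel = (t["site"] == "s1") & (t["antibody"] == "target")
        t.loc[sel, "cq"] -= 1.0  # one cycle below input at the test site
        finals, _ = qpcr_enrichment(t, ("cA", "cB"))
        s1 = finals[finals["site"] == "s1"]["value"]
        assert np.allclose(s1, 2.0)

    def test_invariant_to_per_replicate_machine_offset(self):
        t = cc.simulate_qpcr(seed=9)
        finals_a, _ = qpcr_enrichment(t, ("ctrlA", "ctrlB"))
        t2 = t.copy()
        t2.loc[t2["replicate"] == 2, "cq"] += 1.37  # whole-replicate offset
        finals_b, _ = qpcr_enrichment(t2, ("ctrlA", "ctrlB"))
        assert np.allclose(finals_a["value"], finals_b["value"])

    def test_missing_control_site_rejected(self):
        with pytest.raises(ValueError, match="control site"):
            qpcr_enrichment(self.flat_table(), ("cA", "nope"))

    def test_missing_input_rejected(self):
        t = self.flat_table()
        t = t[~((t["antibody"] == "input") & (t["site"] == "s1")
                & (t["replicate"] == 1) & (t["condition"] == "treated"))]
        with pytest.raises(ValueError, match="input"):
            qpcr_enrichment(t, ("cA", "cB"))

    def test_recovers_simulated_fold(self):
        t = cc.simulate_qpcr(true_fold=2.4, sigma=0.1, replicates=4, seed=21)
        _, summary = qpcr_enrichment(t, ("ctrlA", "ctrlB"))
        row = summary.set_index("site").loc["site1"]
        assert 2.0 <= row["fold"] <= 2.9
        assert row["p"] < 0.05
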