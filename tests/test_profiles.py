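"""RPM/GPM computation, presence and pathway summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sedimeta import profiles
from sedimeta.profiles import PathwayRule

from conftest import (
    make_annotations,
    make_coverage,
    make_gene_calls,
    make_site_totals,
    naive_rpm_gpm,
    random_profile_instance,
)


def _one_gene_instance(c=200.0, L=1000, R=2_000_000, G=500_000):
    gc = make_gene_calls([("g1", "c1", "S1", 1, L)])
    cov = make_coverage([("S1", "g1", c)])
    ann = make_annotations([("S1", "g1", "amoA")])
    tot = make_site_totals([("S1", R, G)])
    return gc, cov, ann, tot


class TestRpm:
    def test_hand_computed_single_gene(self):
        # 200 reads on a 1 kb gene at 2M total reads: (200/1.0)/2 = 100 RPM
        prof = profiles.compute_rpm(*_one_gene_instance())
        assert prof.loc[0, "rpm"] == pytest.approx(100.0)
        assert prof.loc[0, "n_genes"] == 1

    def test_additive_over_identical_genes(self):
        gc = make_gene_calls(
            [("g1", "c1", "S1", 1, 1000), ("g2", "c2", "S1", 1, 1000)]
        )
        cov = make_coverage([("S1", "g1", 200.0), ("S1", "g2", 200.0)])
        ann = make_annotations([("S1", "g1", "amoA"), ("S1", "g2", "amoA")])
        tot = make_site_totals([("S1", 2_000_000, 500_000)])
        prof = profiles.compute_rpm(gc, cov, ann, tot)
        assert prof.loc[0, "rpm"] == pytest.approx(200.0)

    def test_family_with_no_reads_is_zero_everywhere(self):
        gc, cov, ann, tot = _one_gene_instance(c=0.0)
        prof = profiles.compute_rpm(gc, cov, ann, tot)
        assert (prof["rpm"] == 0).all()

    def test_missing_gene_call_lists_gene_ids(self):
        gc, cov, ann, tot = _one_gene_instance()
        ann = pd.concat(
            [ann, make_annotations([("S1", "ghost", "amoA")])],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="ghost"):
            profiles.compute_rpm(gc, cov, ann, tot)

    def test_nonpositive_read_total_rejected(self):
        gc, cov, ann, tot = _one_gene_instance()
        tot["total_reads"] = 0
        with pytest.raises(ValueError, match="total_reads"):
            profiles.compute_rpm(gc, cov, ann, tot)


class TestGpm:
    def test_hand_computed(self):
        gc = make_gene_calls(
            [(f"g{i}", "c1", "S1", 1, 900) for i in range(3)]
        )
        ann = make_annotations([("S1", f"g{i}", "amoA") for i in range(3)])
        tot = make_site_totals([("S1", 1_000_000, 500_000)])
        prof = profiles.compute_gpm(ann, tot)
        assert prof.loc[0, "gpm"] == pytest.approx(6.0)

    def test_duplicate_annotation_rows_counted_once(self):
        ann = make_annotations([("S1", "g1", "amoA"), ("S1", "g1", "amoA")])
        tot = make_site_totals([("S1", 1_000_000, 500_000)])
        prof = profiles.compute_gpm(ann, tot)
        assert prof.loc[0, "n_genes"] == 1
        assert prof.loc[0, "gpm"] == pytest.approx(2.0)

    def test_absent_family_zero_at_site(self):
        ann = make_annotations([("S1", "g1", "amoA")])
        tot = make_site_totals([("S1", 1e6, 1e5), ("S2", 1e6, 1e5)])
        prof = profiles.compute_gpm(ann, tot)
        s2 = prof[prof["site_id"] == "S2"].iloc[0]
        assert s2["n_genes"] == 0 and s2["gpm"] == 0


class TestOracleEquivalence:
    def test_matches_naive_double_loop_on_random_instances(self, rng):
        for _ in range(30):
            gc, cov, ann, tot = random_profile_instance(rng)
            prof = profiles.compute_profile(gc, cov, ann, tot)
            oracle = naive_rpm_gpm(gc, cov, ann, tot)
            for r in prof.itertuples(index=False):
                n, rpm, gpm = oracle[(r.site_id, r.family_id)]
                assert r.n_genes == n
                assert r.rpm == pytest.approx(rpm, rel=1e-12, abs=1e-300)
                assert r.gpm == pytest.approx(gpm, rel=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(scale=st.floats(0.01, 1e3), seed=st.integers(0, 10**6))
def test_rpm_scale_invariance(scale, seed):
    """Jointly rescaling every count and the site depth leaves RPM fixed."""
    gc, cov, ann, tot = random_profile_instance(np.random.default_rng(seed))
    base = profiles.compute_rpm(gc, cov, ann, tot)
    cov2 = cov.assign(mapped_reads=cov["mapped_reads"] * scale)
    tot2 = tot.assign(total_reads=tot["total_reads"] * scale)
    scaled = profiles.compute_rpm(gc, cov2, ann, tot2)
    np.testing.assert_allclose(scaled["rpm"], base["rpm"], rtol=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10**6))
def test_rpm_additive_over_gene_partition(seed):
    """Splitting one family's genes into two halves: the halves' RPM values
    sum to the whole family's RPM at every site."""
    rng = np.random.default_rng(seed)
    gc, cov, ann, tot = random_profile_instance(rng)
    fam = sorted(ann["family_id"].unique())[0]
    ann_f = ann[ann["family_id"] == fam].reset_index(drop=True)
    whole = profiles.compute_rpm(gc, cov, ann_f, tot)
    half = rng.random(len(ann_f)) < 0.5
    ann_split = ann_f.assign(family_id=np.where(half, "partA", "partB"))
    parts = profiles.compute_rpm(gc, cov, ann_split, tot)
    for site in tot["site_id"]:
        w = whole.query("site_id == @site")["rpm"].sum()
        p = parts.query("site_id == @site")["rpm"].sum()
        assert p == pytest.approx(w, rel=1e-9, abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10**6))
def test_gpm_invariant_under_gene_relabeling(seed):
    rng = np.random.default_rng(seed)
    gc, cov, ann, tot = random_profile_instance(rng)
    base = profiles.compute_gpm(ann, tot)
    mapping = {
        g: f"renamed_{i}" for i, g in enumerate(sorted(ann["gene_id"].unique()))
    }
    ann2 = ann.assign(gene_id=ann["gene_id"].map(mapping))
    renamed = profiles.compute_gpm(ann2, tot)
    np.testing.assert_allclose(renamed["gpm"], base["gpm"])
    np.testing.assert_array_equal(renamed["n_genes"], base["n_genes"])


class TestPresence:
    def _profile(self, counts):
        rows = [
            ("S%d" % i, "amoA", "nitrogen", c, float(c), float(c))
            for i, c in enumerate(counts)
        ]
        return pd.DataFrame(rows, columns=profiles.PROFILE_COLUMNS)

    def test_sites_present_tally(self):
        pres = profiles.presence(self._profile([1] * 12 + [0]))
        assert pres["n_sites_present"].iloc[0] == 12
        assert pres["present"].sum() == 12

    def test_all_zero_family(self):
        pres = profiles.presence(self._profile([0, 0, 0]))
        assert pres["n_sites_present"].iloc[0] == 0

    def test_threshold_is_strict(self):
        pres = profiles.presence(self._profile([1, 2]), threshold=1)
        assert list(pres["present"]) == [False, True]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            profiles.presence(self._profile([1]), threshold=-1)


class TestPathways:
    def _presence(self, spec):
        """spec: {site: set of present families} over a fixed universe."""
        universe = ["amoA", "amoB", "amoC", "nxrA", "nxrB"]
        rows = []
        for site, fams in spec.items():
            for f in universe:
                rows.append((site, f, "nitrogen", int(f in fams), f in fams, 0))
        return pd.DataFrame(
            rows,
            columns=["site_id", "family_id", "category", "n_genes",
                     "present", "n_sites_present"],
        )

    NITRIF = PathwayRule(
        "nitrification", frozenset({"amoA", "amoB", "amoC", "nxrA", "nxrB"})
    )

    def test_complete_when_all_present(self):
        pres = self._presence(
            {"S1": {"amoA", "amoB", "amoC", "nxrA", "nxrB"}}
        )
        out = profiles.pathway_status(pres, [self.NITRIF])
        assert out["complete"].iloc[0]

    def test_amo_without_nxr_incomplete(self):
        pres = self._presence({"S1": {"amoA", "amoB", "amoC"}})
        out = profiles.pathway_status(pres, [self.NITRIF])
        assert not out["complete"].iloc[0]
        assert out["n_present"].iloc[0] == 3

    def test_empty_site_all_incomplete(self):
        pres = self._presence({"S1": set()})
        out = profiles.pathway_status(pres, [self.NITRIF])
        assert not out["complete"].any()

    def test_unknown_family_warns_and_blocks_completion(self):
        pres = self._presence(
            {"S1": {"amoA", "amoB", "amoC", "nxrA", "nxrB"}}
        )
        rule = PathwayRule("x", frozenset({"amoA", "notAFamily"}))
        with pytest.warns(UserWarning, match="notAFamily"):
            out = profiles.pathway_status(pres, [rule])
        assert not out["complete"].any()

    def test_empty_rule_set_rejected(self):
        with pytest.raises(ValueError):
            profiles.pathway_status(self._presence({"S1": set()}), [])

    def test_shipped_default_rules_load(self):
        rules = profiles.load_pathway_rules()
        ids = {r.pathway_id for r in rules}
        assert "nitrification" in ids
        nitrif = next(r for r in rules if r.pathway_id == "nitrification")
        assert nitrif.required_families == frozenset(
            {"amoA", "amoB", "amoC", "nxrA", "nxrB"}
        )
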