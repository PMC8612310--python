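"""Contig-origin rules: top-hit selection, boundary semantics, recovery."""

import numpy as np
import pandas as pd
import pytest

from sedimeta import contigs
from sedimeta.contigs import classify_contig, classify_contigs
from sedimeta.simulate import SimConfig, plant_detrital_contigs

from conftest import make_gene_calls, make_hits


class TestTopHit:
    def test_max_bit_score_wins(self):
        hits = make_hits(
            [
                ("g1", "B", 80.0, 1e-20, 80.0, "Bacteria", "X"),
                ("g1", "A", 85.0, 1e-30, 120.0, "Bacteria", "Y"),
            ]
        )
        top = contigs.top_hit_per_gene(hits)
        assert len(top) == 1 and top.iloc[0]["subject_id"] == "A"

    def test_exact_tie_broken_by_subject_id(self):
        hits = make_hits(
            [
                ("g1", "B", 80.0, 1e-20, 100.0, "Bacteria", "X"),
                ("g1", "A", 80.0, 1e-20, 100.0, "Bacteria", "Y"),
            ]
        )
        top = contigs.top_hit_per_gene(hits)
        assert top.iloc[0]["subject_id"] == "A"

    def test_bit_tie_broken_by_evalue(self):
        hits = make_hits(
            [
                ("g1", "B", 80.0, 1e-40, 100.0, "Bacteria", "X"),
                ("g1", "A", 80.0, 1e-20, 100.0, "Bacteria", "Y"),
            ]
        )
        top = contigs.top_hit_per_gene(hits)
        assert top.iloc[0]["subject_id"] == "B"

    def test_empty_hits_give_empty_map(self):
        assert contigs.top_hit_per_gene(make_hits([])).empty


def _call(length_bp, n_genes, n_hit, n_cyano, n_euk):
    return classify_contig(length_bp, n_genes, n_hit, n_cyano, n_euk)


class TestRuleBoundaries:
    def test_canonical_eukaryotic_contig(self):
        # 2500 bp, 1 gene (0.4 genes/kb), 3 of 4 top hits eukaryotic
        assert _call(2500, 1, 4, 0, 3) == "eukaryotic"

    @pytest.mark.parametrize(
        "length,expected",
        [(2000, "unclassified"), (2001, "eukaryotic"), (1500, "unclassified")],
    )
    def test_length_threshold_strict(self, length, expected):
        # density stays < 0.5 and all hits eukaryotic; only length varies
        assert _call(length, 0, 4, 0, 4) == expected

    def test_density_threshold_strict(self):
        # 10000 bp: 5 genes = 0.5 genes/kb fails, 4 genes = 0.4 passes
        assert _call(10_000, 5, 5, 0, 5) == "unclassified"
        assert _call(10_000, 4, 4, 0, 4) == "eukaryotic"

    def test_euk_fraction_strictly_more_than_half(self):
        assert _call(10_000, 4, 4, 0, 2) == "unclassified"  # exactly 0.5
        assert _call(10_000, 4, 4, 0, 3) == "eukaryotic"     # 0.75

    def test_cyano_fraction_at_least_half(self):
        assert _call(5_000, 10, 10, 5, 0) == "cyanobacterial"  # exactly 0.5
        assert _call(5_000, 10, 10, 4, 0) == "unclassified"    # 0.4

    def test_short_gene_poor_euk_majority_is_not_eukaryotic(self):
        # fails the >2 kb requirement; cyano fraction < 0.5 -> unclassified
        assert _call(1500, 1, 4, 0, 4) == "unclassified"

    def test_no_hit_bearing_genes_unclassified(self):
        assert _call(5_000, 3, 0, 0, 0) == "unclassified"

    def test_eukaryotic_rule_takes_precedence(self):
        # satisfies both rules (all hits eukaryotic can't also be cyano,
        # so mix: 3 euk + 2 cyano of 5 -> euk 0.6 > 0.5, cyano 0.4)
        assert _call(10_000, 4, 5, 2, 3) == "eukaryotic"

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            _call(0, 1, 1, 1, 0)


class TestFeaturesAndCalls:
    def _setup(self):
        gene_calls = make_gene_calls(
            [
                ("g1", "c1", "S1", 1, 900),
                ("g2", "c1", "S1", 1001, 1900),
                ("g3", "c2", "S1", 1, 900),
            ]
        )
        hits = make_hits(
            [
                ("g1", "s1", 80, 1e-30, 100, "Bacteria", "Cyanobacteria"),
                ("g2", "s2", 80, 1e-30, 100, "Bacteria", "Proteobacteria"),
            ]
        )
        lengths = pd.Series(
            {"c1": 2000, "c2": 1000, "c3": 4000}, name="length_bp"
        )
        lengths.index.name = "contig_id"
        return gene_calls, lengths, contigs.top_hit_per_gene(hits)

    def test_features_counts_and_fractions(self):
        gc, lengths, top = self._setup()
        feats = contigs.contig_features(gc, lengths, top).set_index(
            "contig_id"
        )
        assert feats.loc["c1", "n_genes"] == 2
        assert feats.loc["c1", "n_hit_genes"] == 2
        assert feats.loc["c1", "cyano_fraction"] == pytest.approx(0.5)
        assert feats.loc["c1", "coding_density"] == pytest.approx(1.0)
        assert feats.loc["c2", "n_hit_genes"] == 0  # g3 has no hit
        assert feats.loc["c3", "n_genes"] == 0      # gene-less contig kept

    def test_every_contig_gets_exactly_one_call(self):
        gc, lengths, top = self._setup()
        feats = contigs.contig_features(gc, lengths, top)
        calls = classify_contigs(feats)
        assert len(calls) == 3
        assert calls["call"].isin(
            ["cyanobacterial", "eukaryotic", "unclassified"]
        ).all()


class TestSitePercentages:
    def _calls(self, spec):
        rows = [
            (site, f"{site}_c{i}", call)
            for site, call_list in spec.items()
            for i, call in enumerate(call_list)
        ]
        return pd.DataFrame(rows, columns=["site_id", "contig_id", "call"])

    def test_hand_computed_percentages(self):
        calls = self._calls(
            {"S1": ["cyanobacterial"] * 2 + ["unclassified"] * 8}
        )
        pct = contigs.site_percentages(calls)
        assert pct.iloc[0]["pct_cyanobacterial"] == pytest.approx(20.0)
        assert pct.iloc[0]["pct_eukaryotic"] == 0.0

    def test_all_one_class(self):
        pct = contigs.site_percentages(self._calls({"S1": ["eukaryotic"] * 5}))
        assert pct.iloc[0]["pct_eukaryotic"] == pytest.approx(100.0)

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            contigs.site_percentages(
                pd.DataFrame(columns=["site_id", "contig_id", "call"])
            )

    def test_percentages_sum_at_most_100(self):
        calls = self._calls(
            {"S1": ["cyanobacterial", "eukaryotic", "unclassified"]}
        )
        pct = contigs.site_percentages(calls)
        total = pct["pct_cyanobacterial"] + pct["pct_eukaryotic"]
        assert (total <= 100.0 + 1e-9).all()


def _recover_planted(epsilon, seed, n_contigs=150):
    """Plant one site's contigs at a given mislabel rate; classify them."""
    cfg = SimConfig(epsilon=epsilon, contigs_per_site=n_contigs)
    rng = np.random.default_rng(seed)
    seqs, gene_calls, hits, truth = plant_detrital_contigs(cfg, rng, "S1")
    lengths = pd.Series({k: len(v) for k, v in seqs.items()})
    lengths.index.name = "contig_id"
    top = contigs.top_hit_per_gene(hits)
    feats = contigs.contig_features(gene_calls, lengths, top, site_id="S1")
    calls = classify_contigs(feats)
    merged = truth.merge(calls, on="contig_id")
    recalls = {}
    for cls in ["cyanobacterial", "eukaryotic"]:
        t = merged["true_class"] == cls
        p = merged["call"] == cls
        recalls[cls] = {
            "recall": (t & p).sum() / max(t.sum(), 1),
            "precision": (t & p).sum() / max(p.sum(), 1),
        }
    return recalls


class TestPlantedRecovery:
    def test_perfect_at_zero_noise(self):
        rec = _recover_planted(0.0, seed=5)
        for cls in rec:
            assert rec[cls]["recall"] == 1.0
            assert rec[cls]["precision"] == 1.0

    def test_recall_degrades_monotonically_with_noise(self):
        """Average eukaryotic+cyano recall falls as mislabeling grows."""
        means = []
        for eps in (0.0, 0.3, 0.6):
            recs = [
                _recover_planted(eps, seed=s)["cyanobacterial"]["recall"]
                for s in range(3)
            ]
            means.append(np.mean(recs))
        assert means[0] == 1.0
        assert means[0] > means[1] > means[2]
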