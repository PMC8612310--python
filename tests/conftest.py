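import numpy as np
import pandas as pd
import pytest

from sedimeta import io as smio
from sedimeta.simulate import FamilyConfig, SimConfig


def make_gene_calls(rows):
    """rows: (gene_id, contig_id, site_id, start, end)."""
    df = pd.DataFrame(
        rows, columns=["gene_id", "contig_id", "site_id", "start", "end"]
    )
    df["strand"] = "+"
    df["length_bp"] = df["end"] - df["start"] + 1
    return df[smio.GENE_CALL_COLUMNS]


def make_coverage(rows):
    return pd.DataFrame(rows, columns=smio.COVERAGE_COLUMNS)


def make_annotations(rows, category="nitrogen"):
    df = pd.DataFrame(rows, columns=["site_id", "gene_id", "family_id"])
    df["category"] = category
    return df[smio.ANNOTATION_COLUMNS]


def make_site_totals(rows):
    return pd.DataFrame(rows, columns=smio.SITE_TOTAL_COLUMNS)


def make_hits(rows):
    """rows: (query_gene_id, subject_id, pident, evalue, bits, domain, label)."""
    out = []
    for q, s, pid, ev, bit, dom, lab in rows:
        out.append((q, s, pid, 100, 5, 1, 1, 300, 1, 100, ev, bit, dom, lab))
    return pd.DataFrame(out, columns=smio.HIT_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_sim_config():
    """A scaled-down study: 3 sites, few families, small bins — fast enough
    for repeated end-to-end runs."""
    return SimConfig(
        n_sites=3,
        reads_per_site=1_000_000,
        genes_per_site=50_000,
        families=(
            FamilyConfig("amoA", "nitrogen", 1.0, 3, 8.0),
            FamilyConfig("nxrA", "nitrogen", 0.6, 2, 5.0),
            FamilyConfig("dsrA", "sulfur", 0.8, 3, 6.0),
            FamilyConfig("soxZ", "sulfur", 0.5, 2, 4.0),
        ),
        contigs_per_site=20,
        n_bins=4,
        bin_size_range=(2e5, 5e5),
        bin_contig_len=50_000,
    )


def naive_rpm_gpm(gene_calls, coverage, annotations, site_totals):
    """Independent oracle: literal per-gene double loop over the formulas."""
    cov = {
        (r.site_id, r.gene_id): r.mapped_reads
        for r in coverage.itertuples(index=False)
    }
    length = {
        (r.site_id, r.gene_id): r.length_bp
        for r in gene_calls.itertuples(index=False)
    }
    ann = annotations.drop_duplicates(["site_id", "gene_id", "family_id"])
    out = {}
    for site_row in site_totals.itertuples(index=False):
        s = site_row.site_id
        for f in sorted(annotations["family_id"].unique()):
            genes = sorted(
                set(
                    r.gene_id
                    for r in ann.itertuples(index=False)
                    if r.site_id == s and r.family_id == f
                )
            )
            rpk = 0.0
            for g in genes:
                rpk += cov.get((s, g), 0.0) / (length[(s, g)] / 1e3)
            rpm = rpk / (site_row.total_reads / 1e6)
            gpm = 1e6 * len(genes) / site_row.total_genes
            out[(s, f)] = (len(genes), rpm, gpm)
    return out


def random_profile_instance(rng, max_sites=3, max_genes=20):
    """A random small profiling instance for oracle/property checks."""
    n_sites = int(rng.integers(1, max_sites + 1))
    sites = [f"S{i}" for i in range(n_sites)]
    families = ["famA", "famB", "famC"][: int(rng.integers(1, 4))]
    gc_rows, cov_rows, ann_rows = [], [], []
    k = 0
    for s in sites:
        for f in families:
            for _ in range(int(rng.integers(0, max_genes // 2 + 1))):
                if k >= max_genes:
                    break
                g = f"g{k}"
                k += 1
                start = int(rng.integers(1, 1000))
                length = int(rng.integers(100, 3000))
                gc_rows.append((g, f"c{k}", s, start, start + length - 1))
                if rng.random() < 0.8:  # some genes lack coverage rows
                    cov_rows.append((s, g, float(rng.integers(0, 500))))
                ann_rows.append((s, g, f))
    if k == 0:  # always at least one annotated gene
        gc_rows.append(("g0", "c0", sites[0], 1, 900))
        cov_rows.append((sites[0], "g0", 10.0))
        ann_rows.append((sites[0], "g0", families[0]))
    totals = make_site_totals(
        [
            (s, int(rng.integers(10_000, 5_000_000)),
             int(rng.integers(1_000, 1_000_000)))
            for s in sites
        ]
    )
    return (
        make_gene_calls(gc_rows),
        make_coverage(cov_rows),
        make_annotations(ann_rows),
        totals,
    )
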