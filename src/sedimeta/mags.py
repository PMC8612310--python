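"""Per-MAG characterization statistics and the AAI / taxon-diversity test.

For each bin (MAG) this module summarizes: assembled length, GC content
(ambiguous bases excluded from both numerator and denominator), gene count,
coding density in genes/kb, completeness and redundancy, the
completion-corrected genome size estimate

    S_hat = total_length_bp * 100 / completeness_pct,

the mean percent identity of the bin's genes to their best database hits
("average amino acid identity", AAI), and the number of distinct taxonomic
labels among those best hits.

MAGs poorly represented in reference databases recruit best hits scattered
across many taxa, so AAI and taxon-hit diversity should be inversely
related.  :func:`aai_consistency` tests this with an ordinary least-squares
regression of taxon count on AAI (two-sided t-test on the slope), with a
Spearman rank correlation reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .contigs import top_hit_per_gene

BIN_STAT_COLUMNS = [
    "bin_id",
    "site_id",
    "n_contigs",
    "total_length_bp",
    "gc_pct",
    "n_genes",
    "coding_density",
    "completeness_pct",
    "redundancy_pct",
    "est_genome_size_bp",
    "mean_aai_pct",
    "n_taxa",
]

_GC = frozenset("GC")
_UNAMBIGUOUS = frozenset("ACGT")


def gc_percent(seq: str) -> float:
    """GC% over unambiguous bases only; NaN for a fully ambiguous sequence."""
    seq = seq.upper()
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    total = gc + at
    return float("nan") if total == 0 else 100.0 * gc / total


def bin_statistics(
    contig_seqs: dict[str, str],
    gene_calls: pd.DataFrame,
    membership: pd.DataFrame,
    hits: pd.DataFrame,
    exclude_na_taxa: bool = True,
) -> pd.DataFrame:
    """Compute :data:`BIN_STAT_COLUMNS` for every bin in ``membership``.

    Parameters
    ----------
    contig_seqs
        Sequences for (at least) every member contig.
    gene_calls
        Gene calls; genes are attributed to bins via their contig.
    membership
        Bin membership with completeness/redundancy.
    hits
        Alignment hits for the bins' genes; the best hit per gene
        contributes to the AAI mean and the taxon-label tally.
    exclude_na_taxa
        Drop hits whose taxon_label is "NA" from the distinct-taxon count.

    Raises
    ------
    ValueError
        If a member contig has no sequence, or a bin's completeness is <= 0
        (the corrected size would be undefined).
    """
    missing = sorted(set(membership["contig_id"]) - set(contig_seqs))
    if missing:
        raise ValueError(f"member contigs missing from FASTA: {missing}")
    bad_c = membership.loc[
        membership["completeness_pct"] <= 0, "bin_id"
    ].unique()
    if len(bad_c):
        raise ValueError(
            "completeness <= 0, corrected genome size undefined for bins: "
            f"{sorted(bad_c)}"
        )

    top = top_hit_per_gene(hits)
    gene_info = gene_calls.merge(
        top[["query_gene_id", "percent_identity", "taxon_label"]],
        left_on="gene_id", right_on="query_gene_id", how="left",
    )

    rows = []
    for bin_id, grp in membership.groupby("bin_id"):
        contigs = grp["contig_id"]
        gc_num = 0
        gc_den = 0
        total_len = 0
        for cid in contigs:
            seq = contig_seqs[cid].upper()
            total_len += len(seq)
            g = seq.count("G") + seq.count("C")
            a = seq.count("A") + seq.count("T")
            gc_num += g
            gc_den += g + a
        genes = gene_info[gene_info["contig_id"].isin(set(contigs))]
        n_genes = len(genes)
        with_hit = genes[genes["percent_identity"].notna()]
        labels = with_hit["taxon_label"]
        if exclude_na_taxa:
            labels = labels[labels != "NA"]
        completeness = float(grp["completeness_pct"].iloc[0])
        rows.append(
            (
                bin_id,
                grp["site_id"].iloc[0],
                len(contigs),
                total_len,
                float("nan") if gc_den == 0 else 100.0 * gc_num / gc_den,
                n_genes,
                1e3 * n_genes / total_len if total_len else float("nan"),
                completeness,
                float(grp["redundancy_pct"].iloc[0]),
                total_len * 100.0 / completeness,
                with_hit["percent_identity"].mean(),
                labels.nunique(),
            )
        )
    return pd.DataFrame(rows, columns=BIN_STAT_COLUMNS)


def filter_high_quality(
    stats: pd.DataFrame,
    min_completeness: float = 60.0,
    max_redundancy: float = 8.7,
) -> pd.DataFrame:
    """High-quality subset: completeness strictly above ``min_completeness``
    and redundancy strictly below ``max_redundancy``."""
    keep = (stats["completeness_pct"] > min_completeness) & (
        stats["redundancy_pct"] < max_redundancy
    )
    return stats[keep].reset_index(drop=True)


@dataclass(frozen=True)
class RegressionResult:
    """OLS of taxon-hit diversity on AAI, plus a Spearman cross-check."""

    slope: float
    intercept: float
    p_value: float
    n: int
    spearman_rho: float
    spearman_p: float
    method: str = "ols"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("ols", self.slope, self.intercept, self.p_value, self.n),
                ("spearman", self.spearman_rho, float("nan"),
                 self.spearman_p, self.n),
            ],
            columns=["method", "slope_or_rho", "intercept", "p_value", "n"],
        )


def aai_consistency(stats: pd.DataFrame) -> RegressionResult:
    """Regress taxon-hit diversity on mean AAI across bins.

    Returns the OLS slope, intercept and two-sided slope-t-test p-value,
    along with the Spearman rank correlation.  Requires >= 3 bins with
    defined AAI and positive AAI variance.
    """
    df = stats[["mean_aai_pct", "n_taxa"]].dropna()
    n = len(df)
    if n < 3:
        raise ValueError(f"need >= 3 bins with defined AAI, got {n}")
    x = df["mean_aai_pct"].to_numpy(float)
    y = df["n_taxa"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in AAI: slope test undefined")
    if np.ptp(y) == 0:
        # perfectly flat response: no effect, no evidence against the null
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), p_value=1.0, n=n,
            spearman_rho=0.0, spearman_p=1.0,
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    rho, sp_p = sps.spearmanr(x, y)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        n=n,
        spearman_rho=float(rho),
        spearman_p=float(sp_p),
    )


def density_size_regression(stats: pd.DataFrame) -> RegressionResult:
    """OLS of coding density on completion-corrected genome size (Mb) —
    the streamlining trend (smaller genomes, denser coding)."""
    df = stats[["est_genome_size_bp", "coding_density"]].dropna()
    if len(df) < 3:
        raise ValueError(f"need >= 3 bins, got {len(df)}")
    x = df["est_genome_size_bp"].to_numpy(float) / 1e6
    y = df["coding_density"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in genome size")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    rho, sp_p = sps.spearmanr(x, y)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        n=len(df),
        spearman_rho=float(rho),
        spearman_p=float(sp_p),
    )
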