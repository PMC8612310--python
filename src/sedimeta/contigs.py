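"""Rule-based classification of contig origin (cyanobacterial / eukaryotic).

Assembled sediment contigs can derive from sinking detrital material rather
than resident benthic prokaryotes.  Two screens flag such contigs from the
taxonomy of each gene's best database hit:

* **eukaryotic**: contig longer than 2 kb, coding density below
  0.5 genes/kb, and *more than half* of its genes' top hits to eukaryotic
  proteins — phytodetritus tends to assemble as long, gene-poor contigs;
* **cyanobacterial**: *at least half* of the top hits to cyanobacterial
  proteins.

The eukaryotic rule is evaluated first; the two classes are disjoint.  The
voting denominator is the number of genes that have at least one hit, and a
contig with no hit-bearing genes is unclassified.  Boundary semantics are
deliberate: the eukaryotic majority is strict (> 0.5) while the
cyanobacterial one is inclusive (>= 0.5); length > 2000 bp and density
< 0.5 genes/kb are strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CALL_COLUMNS = [
    "site_id",
    "contig_id",
    "call",
    "length_bp",
    "n_genes",
    "n_hit_genes",
    "coding_density",
    "cyano_fraction",
    "euk_fraction",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and taxonomy labels driving the contig-origin rules."""

    cyano_label: str = "Cyanobacteria"   # matched against taxon_label
    euk_domain: str = "Eukaryota"        # matched against taxon_domain
    euk_min_length_bp: int = 2000        # strict >
    euk_max_density: float = 0.5         # genes/kb, strict <
    euk_min_fraction: float = 0.5        # strict >
    cyano_min_fraction: float = 0.5      # inclusive >=


def top_hit_per_gene(hits: pd.DataFrame) -> pd.DataFrame:
    """Best hit per query gene: max bit score, then min e-value, then the
    lexicographically smallest subject_id (fully deterministic)."""
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(
        ["query_gene_id", "bit_score", "e_value", "subject_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.groupby("query_gene_id", as_index=False).head(1)


def contig_features(
    gene_calls: pd.DataFrame,
    lengths: pd.Series,
    top_hits: pd.DataFrame,
    config: ClassifierConfig = ClassifierConfig(),
    site_id: str | None = None,
) -> pd.DataFrame:
    """Per-contig evidence table for the classification rules.

    Parameters
    ----------
    gene_calls
        Gene calls for the contigs' site(s).
    lengths
        Per-contig length in bp, indexed by contig_id (every contig to be
        classified must appear here, gene-less contigs included).
    top_hits
        One row per gene, as produced by :func:`top_hit_per_gene`.
    """
    if (lengths <= 0).any():
        bad = sorted(lengths.index[lengths <= 0])
        raise ValueError(f"non-positive contig length: {bad}")
    genes = gene_calls.merge(
        top_hits[["query_gene_id", "taxon_domain", "taxon_label"]],
        left_on="gene_id", right_on="query_gene_id", how="left",
    )
    genes["has_hit"] = genes["query_gene_id"].notna()
    genes["is_cyano"] = genes["has_hit"] & (
        genes["taxon_label"] == config.cyano_label
    )
    genes["is_euk"] = genes["has_hit"] & (
        genes["taxon_domain"] == config.euk_domain
    )
    agg = genes.groupby("contig_id").agg(
        n_genes=("gene_id", "size"),
        n_hit_genes=("has_hit", "sum"),
        n_cyano=("is_cyano", "sum"),
        n_euk=("is_euk", "sum"),
    )
    feats = pd.DataFrame(index=lengths.index)
    feats["length_bp"] = lengths
    feats = feats.join(agg, how="left").fillna(0)
    for col in ["n_genes", "n_hit_genes", "n_cyano", "n_euk"]:
        feats[col] = feats[col].astype(int)
    feats["coding_density"] = 1e3 * feats["n_genes"] / feats["length_bp"]
    denom = feats["n_hit_genes"].where(feats["n_hit_genes"] > 0)
    feats["cyano_fraction"] = (feats["n_cyano"] / denom).fillna(0.0)
    feats["euk_fraction"] = (feats["n_euk"] / denom).fillna(0.0)
    if site_id is not None:
        feats["site_id"] = site_id
    else:
        site_of = gene_calls.drop_duplicates("contig_id").set_index(
            "contig_id"
        )["site_id"]
        feats["site_id"] = site_of.reindex(feats.index)
    return feats.reset_index().rename(columns={"index": "contig_id"})


def classify_contigs(
    features: pd.DataFrame, config: ClassifierConfig = ClassifierConfig()
) -> pd.DataFrame:
    """Apply the origin rules; returns one call per contig.

    Rule order: eukaryotic first, then cyanobacterial, else unclassified.
    Contigs with no hit-bearing genes are always unclassified (both hit
    fractions are 0).
    """
    if (features["length_bp"] <= 0).any():
        raise ValueError("non-positive contig length")
    f = features
    is_euk = (
        (f["length_bp"] > config.euk_min_length_bp)
        & (f["coding_density"] < config.euk_max_density)
        & (f["euk_fraction"] > config.euk_min_fraction)
    )
    is_cyano = ~is_euk & (f["cyano_fraction"] >= config.cyano_min_fraction) & (
        f["n_hit_genes"] > 0
    )
    call = np.where(is_euk, "eukaryotic",
                    np.where(is_cyano, "cyanobacterial", "unclassified"))
    out = f.copy()
    out["call"] = call
    cols = [c for c in CALL_COLUMNS if c in out.columns]
    return out[cols]


def classify_contig(length_bp: int, n_genes: int, n_hit_genes: int,
                    n_cyano: int, n_euk: int,
                    config: ClassifierConfig = ClassifierConfig()) -> str:
    """Classify a single contig from raw evidence counts."""
    if length_bp <= 0:
        raise ValueError("non-positive contig length")
    feats = pd.DataFrame(
        {
            "contig_id": ["c"],
            "length_bp": [length_bp],
            "n_genes": [n_genes],
            "n_hit_genes": [n_hit_genes],
            "coding_density": [1e3 * n_genes / length_bp],
            "cyano_fraction": [n_cyano / n_hit_genes if n_hit_genes else 0.0],
            "euk_fraction": [n_euk / n_hit_genes if n_hit_genes else 0.0],
        }
    )
    return classify_contigs(feats, config)["call"].iloc[0]


def site_percentages(calls: pd.DataFrame) -> pd.DataFrame:
    """Percent of contigs per site called cyanobacterial / eukaryotic."""
    if calls.empty:
        raise ValueError("no contig calls: cannot compute site percentages")
    rows = []
    for site, grp in calls.groupby("site_id", dropna=False):
        n = len(grp)
        rows.append(
            (
                site,
                n,
                100.0 * (grp["call"] == "cyanobacterial").sum() / n,
                100.0 * (grp["call"] == "eukaryotic").sum() / n,
            )
        )
    return pd.DataFrame(
        rows, columns=["site_id", "n_contigs", "pct_cyanobacterial",
                       "pct_eukaryotic"]
    )
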