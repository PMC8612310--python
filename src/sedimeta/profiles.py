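"""Site x gene-family abundance (RPM) and diversity (GPM) profiles.

Two normalized metrics are computed per (site, family) cell:

* **RPM** (reads per million) — per-gene mapped-read counts divided by gene
  length in kb, summed over the family's genes at the site, divided by the
  site's total read count in millions:

      rpm(f, s) = sum_{g in f,s} [ c_g / (L_g / 10^3) ] / (R_s / 10^6)

  The per-gene-then-sum order makes RPM additive over any partition of a
  family's genes and invariant to jointly rescaling counts and depth.

* **GPM** (genes per million) — the number of distinct predicted genes
  annotated to the family, per million genes predicted at the site:

      gpm(f, s) = 10^6 * n_{f,s} / G_s

Presence/absence and pathway-completeness summaries are derived from the
distinct-gene counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

PROFILE_COLUMNS = ["site_id", "family_id", "category", "n_genes", "rpm", "gpm"]


@dataclass(frozen=True)
class PathwayRule:
    """A pathway is complete at a site iff all required families are present."""

    pathway_id: str
    required_families: frozenset[str]

    def __post_init__(self):
        if not self.required_families:
            raise ValueError(f"pathway {self.pathway_id!r}: empty family set")


def _dedupe_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Distinct (site, gene, family) annotations; a gene counts once per family."""
    return annotations.drop_duplicates(["site_id", "gene_id", "family_id"])


def _family_universe(annotations: pd.DataFrame) -> pd.DataFrame:
    fam = annotations[["family_id", "category"]].drop_duplicates("family_id")
    return fam.sort_values("family_id").reset_index(drop=True)


def _full_grid(site_totals: pd.DataFrame, families: pd.DataFrame) -> pd.DataFrame:
    """All (site, family) cells, so absent families appear with zeros."""
    return site_totals[["site_id"]].merge(families, how="cross")


def compute_gpm(annotations: pd.DataFrame,
                site_totals: pd.DataFrame) -> pd.DataFrame:
    """Genes-per-million profile.

    Returns the full site x family grid with columns
    ``site_id, family_id, category, n_genes, gpm``.
    """
    if (site_totals["total_genes"] <= 0).any():
        bad = site_totals.loc[site_totals["total_genes"] <= 0, "site_id"]
        raise ValueError(f"non-positive total_genes for sites: {list(bad)}")
    ann = _dedupe_annotations(annotations)
    counts = (
        ann.groupby(["site_id", "family_id"], as_index=False)["gene_id"]
        .nunique()
        .rename(columns={"gene_id": "n_genes"})
    )
    grid = _full_grid(site_totals, _family_universe(annotations))
    out = grid.merge(counts, on=["site_id", "family_id"], how="left")
    out["n_genes"] = out["n_genes"].fillna(0).astype(int)
    out = out.merge(site_totals[["site_id", "total_genes"]], on="site_id")
    out["gpm"] = 1e6 * out["n_genes"] / out["total_genes"]
    return out.drop(columns="total_genes")


def compute_rpm(gene_calls: pd.DataFrame, coverage: pd.DataFrame,
                annotations: pd.DataFrame,
                site_totals: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million profile on the full site x family grid.

    Every annotated gene must have a gene call (its length is the
    normalizer); a missing coverage record is treated as zero mapped reads.
    """
    if (site_totals["total_reads"] <= 0).any():
        bad = site_totals.loc[site_totals["total_reads"] <= 0, "site_id"]
        raise ValueError(f"non-positive total_reads for sites: {list(bad)}")
    ann = _dedupe_annotations(annotations)
    merged = ann.merge(
        gene_calls[["site_id", "gene_id", "length_bp"]],
        on=["site_id", "gene_id"], how="left",
    )
    missing = merged["length_bp"].isna()
    if missing.any():
        ids = sorted(merged.loc[missing, "gene_id"].unique())
        raise ValueError(f"annotated genes with no gene call: {ids}")
    merged = merged.merge(coverage, on=["site_id", "gene_id"], how="left")
    merged["mapped_reads"] = merged["mapped_reads"].astype(float).fillna(0.0)
    merged["rpk"] = merged["mapped_reads"] / (merged["length_bp"] / 1e3)
    sums = (
        merged.groupby(["site_id", "family_id"], as_index=False)
        .agg(n_genes=("gene_id", "nunique"), rpk=("rpk", "sum"))
    )
    grid = _full_grid(site_totals, _family_universe(annotations))
    out = grid.merge(sums, on=["site_id", "family_id"], how="left")
    out["n_genes"] = out["n_genes"].fillna(0).astype(int)
    out["rpk"] = out["rpk"].fillna(0.0)
    out = out.merge(site_totals[["site_id", "total_reads"]], on="site_id")
    out["rpm"] = out["rpk"] / (out["total_reads"] / 1e6)
    return out.drop(columns=["rpk", "total_reads"])


def compute_profile(gene_calls: pd.DataFrame, coverage: pd.DataFrame,
                    annotations: pd.DataFrame,
                    site_totals: pd.DataFrame) -> pd.DataFrame:
    """Joint RPM + GPM profile with :data:`PROFILE_COLUMNS`."""
    rpm = compute_rpm(gene_calls, coverage, annotations, site_totals)
    gpm = compute_gpm(annotations, site_totals)
    out = rpm.merge(
        gpm[["site_id", "family_id", "gpm"]], on=["site_id", "family_id"]
    )
    return out[PROFILE_COLUMNS]


def presence(profile: pd.DataFrame, threshold: float = 0) -> pd.DataFrame:
    """Presence/absence per (site, family): present iff ``n_genes > threshold``.

    The threshold is in distinct-gene counts; the default 0 means any
    detected gene counts as presence.  Adds per-family ``n_sites_present``.
    """
    if threshold < 0:
        raise ValueError("presence threshold must be >= 0")
    out = profile[["site_id", "family_id", "category", "n_genes"]].copy()
    out["present"] = out["n_genes"] > threshold
    tallies = out.groupby("family_id")["present"].sum().astype(int)
    out["n_sites_present"] = out["family_id"].map(tallies)
    return out


def pathway_status(presence_df: pd.DataFrame,
                   rules: Sequence[PathwayRule]) -> pd.DataFrame:
    """Per-(site, pathway) completeness under conjunctive family rules.

    A family required by a rule but absent from the annotation universe
    triggers a warning and is treated as absent everywhere (so the pathway
    can never be complete).
    """
    if not rules:
        raise ValueError("empty pathway rule set")
    universe = set(presence_df["family_id"].unique())
    sites = sorted(presence_df["site_id"].unique())
    present = {
        (r.site_id, r.family_id)
        for r in presence_df.itertuples(index=False) if r.present
    }
    rows = []
    for rule in rules:
        unknown = rule.required_families - universe
        if unknown:
            warnings.warn(
                f"pathway {rule.pathway_id!r}: families not in annotation "
                f"universe, treated as absent: {sorted(unknown)}"
            )
        for site in sites:
            n_present = sum(
                (site, f) in present for f in rule.required_families
            )
            rows.append(
                (site, rule.pathway_id, len(rule.required_families),
                 n_present, n_present == len(rule.required_families))
            )
    return pd.DataFrame(
        rows,
        columns=["site_id", "pathway_id", "n_required", "n_present", "complete"],
    )


def load_pathway_rules(path: str | Path | None = None) -> list[PathwayRule]:
    """Load pathway rules from YAML (``{pathway_id: [family, ...]}``).

    With no path, the shipped default rule set is used: nitrification
    (amoABC + nxrAB), reverse-DSR sulfide oxidation (dsrAB + dsrEFH),
    sox-mediated thiosulfate oxidation (soxZXA), thiosulfate reduction
    (phsA) and anammox (hzoA + hzsA).
    """
    if path is None:
        text = (
            resources.files("sedimeta") / "data" / "pathway_rules.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    spec = yaml.safe_load(text)
    if not spec:
        raise ValueError("empty pathway rule set")
    return [
        PathwayRule(pid, frozenset(fams)) for pid, fams in sorted(spec.items())
    ]


def presence_report(presence_df: pd.DataFrame) -> list[str]:
    """Human-readable per-family detection lines, '<family>: k of N sites'."""
    n_sites = presence_df["site_id"].nunique()
    per_fam = (
        presence_df.drop_duplicates("family_id")
        .sort_values("family_id")[["family_id", "n_sites_present"]]
    )
    return [
        f"{r.family_id}: detected in {r.n_sites_present} of {n_sites} sites"
        for r in per_fam.itertuples(index=False)
    ]
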