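"""Orchestration: read an input bundle, run the stages, write result tables.

The on-disk bundle layout (produced by the simulator or assembled from real
per-site files) is::

    bundle/
      sites.tsv          site_id, total_reads, total_genes
      coverage.tsv       site_id, gene_id, mapped_reads
      annotations.tsv    site_id, gene_id, family_id, category
      hits.tsv           outfmt-6 + taxonomy columns
      bins.tsv           bin_id, contig_id, site_id, completeness, redundancy
      genes/<site>.gff   Prodigal-dialect CDS calls per site
      contigs/<site>.fasta

Outputs are canonical TSVs plus a JSON run manifest recording inputs and
every parameter value, so identical inputs reproduce identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as smio
from . import profiles, contigs, mags
from .contigs import ClassifierConfig

logger = logging.getLogger("sedimeta")


class StageError(RuntimeError):
    """An error in a named pipeline stage (and site, when applicable)."""


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, in one validated object."""

    bundle_dir: Path
    out_dir: Path
    rules_path: Path | None = None
    presence_threshold: float = 0.0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    min_completeness: float = 60.0
    max_redundancy: float = 8.7
    run_classifier: bool = True
    run_magstats: bool = True
    keep_going: bool = False

    def __post_init__(self):
        self.bundle_dir = Path(self.bundle_dir)
        self.out_dir = Path(self.out_dir)
        if not self.bundle_dir.is_dir():
            raise FileNotFoundError(f"bundle dir not found: {self.bundle_dir}")
        if self.rules_path is not None:
            self.rules_path = Path(self.rules_path)
            if not self.rules_path.is_file():
                raise FileNotFoundError(
                    f"pathway rules not found: {self.rules_path}"
                )
        if self.presence_threshold < 0:
            raise ValueError("presence_threshold must be >= 0")


def _require(path: Path, what: str, site: str | None = None) -> Path:
    if not path.exists():
        where = f" for site {site}" if site else ""
        raise StageError(f"missing {what}{where}: {path}")
    return path


def read_bundle_tables(config: RunConfig):
    b = config.bundle_dir
    site_totals = smio.read_site_totals(_require(b / "sites.tsv", "site table"))
    coverage = smio.read_coverage(_require(b / "coverage.tsv", "coverage table"))
    annotations = smio.read_annotations(
        _require(b / "annotations.tsv", "annotation table")
    )
    hits = smio.read_hits(_require(b / "hits.tsv", "hit table"))
    bins_path = b / "bins.tsv"
    bins = smio.read_bin_membership(bins_path) if bins_path.exists() else \
        pd.DataFrame(columns=smio.BIN_COLUMNS)
    return site_totals, coverage, annotations, hits, bins


def read_site_gene_calls(config: RunConfig, site: str) -> pd.DataFrame:
    path = _require(config.bundle_dir / "genes" / f"{site}.gff",
                    "gene calls", site)
    return smio.read_gene_calls(path, site)


def _input_fingerprints(bundle_dir: Path) -> dict[str, str]:
    """Content (sha256) of every bundle input file, keyed by relative path,
    so manifests are independent of where the bundle happens to live."""
    out = {}
    for p in sorted(bundle_dir.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(bundle_dir))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    return out


def _manifest(config: RunConfig, stage: str, outputs: list[str],
              errors: dict[str, str]) -> dict:
    cls = dataclasses.asdict(config.classifier)
    return {
        "tool": "sedimeta",
        "version": __version__,
        "stage": stage,
        "inputs": _input_fingerprints(config.bundle_dir),
        "parameters": {
            "presence_threshold": config.presence_threshold,
            "classifier": cls,
            "min_completeness": config.min_completeness,
            "max_redundancy": config.max_redundancy,
            "rules": hashlib.sha256(
                config.rules_path.read_bytes()
            ).hexdigest() if config.rules_path else "builtin",
        },
        "outputs": sorted(outputs),
        "site_errors": dict(sorted(errors.items())),
    }


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_profile(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Family profiling stage: profile, presence and pathway tables.

    With ``keep_going`` set, a site whose gene calls fail to load is dropped
    (recorded in the manifest) and the rest of the sites complete.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    site_totals, coverage, annotations, hits, _ = read_bundle_tables(config)

    gene_frames = []
    errors: dict[str, str] = {}
    for site in site_totals["site_id"]:
        try:
            gene_frames.append(read_site_gene_calls(config, site))
        except (smio.FormatError, StageError) as exc:
            if not config.keep_going:
                raise StageError(f"profile stage, site {site}: {exc}") from exc
            logger.warning("skipping site %s: %s", site, exc)
            errors[site] = str(exc)
    ok_sites = set(site_totals["site_id"]) - set(errors)
    gene_calls = pd.concat(gene_frames, ignore_index=True) if gene_frames \
        else pd.DataFrame(columns=smio.GENE_CALL_COLUMNS)
    site_totals = site_totals[site_totals["site_id"].isin(ok_sites)]
    annotations = annotations[annotations["site_id"].isin(ok_sites)]
    coverage = coverage[coverage["site_id"].isin(ok_sites)]

    try:
        profile = profiles.compute_profile(
            gene_calls, coverage, annotations, site_totals
        )
        pres = profiles.presence(profile, config.presence_threshold)
        rules = profiles.load_pathway_rules(config.rules_path)
        pathways = profiles.pathway_status(pres, rules)
    except ValueError as exc:
        raise StageError(f"profile stage: {exc}") from exc

    smio.write_long_table(profile, out / "profile.tsv")
    smio.write_long_table(pres, out / "presence.tsv")
    smio.write_long_table(pathways, out / "pathways.tsv")
    _write_manifest(
        _manifest(config, "profile",
                  ["profile.tsv", "presence.tsv", "pathways.tsv"], errors),
        out,
    )
    return {"profile": profile, "presence": pres, "pathways": pathways}


def run_classify(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Contig-origin classification stage."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    site_totals, _, _, hits, _ = read_bundle_tables(config)
    top = contigs.top_hit_per_gene(hits)
    call_frames = []
    errors: dict[str, str] = {}
    for site in site_totals["site_id"]:
        try:
            gene_calls = read_site_gene_calls(config, site)
            fasta = _require(
                config.bundle_dir / "contigs" / f"{site}.fasta",
                "contig FASTA", site,
            )
            lengths = smio.contig_lengths(fasta)
            feats = contigs.contig_features(
                gene_calls, lengths, top, config.classifier, site_id=site
            )
            call_frames.append(
                contigs.classify_contigs(feats, config.classifier)
            )
        except (smio.FormatError, StageError, ValueError) as exc:
            if not config.keep_going:
                raise StageError(
                    f"classify stage, site {site}: {exc}"
                ) from exc
            logger.warning("skipping site %s: %s", site, exc)
            errors[site] = str(exc)
    if not call_frames:
        raise StageError("classify stage: no sites classified")
    calls = pd.concat(call_frames, ignore_index=True)
    pct = contigs.site_percentages(calls)
    smio.write_long_table(calls, out / "contig_calls.tsv")
    smio.write_long_table(pct, out / "detrital_percent.tsv")
    _write_manifest(
        _manifest(config, "classify",
                  ["contig_calls.tsv", "detrital_percent.tsv"], errors),
        out,
    )
    return {"contig_calls": calls, "detrital_percent": pct}


def run_magstats(config: RunConfig) -> dict[str, pd.DataFrame]:
    """MAG statistics stage: per-bin stats, HQ subset and AAI regression."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    site_totals, _, _, hits, bins = read_bundle_tables(config)
    if bins.empty:
        raise StageError("magstats stage: empty bin membership")
    seqs: dict[str, str] = {}
    gene_frames = []
    for site in sorted(bins["site_id"].unique()):
        fasta = _require(
            config.bundle_dir / "contigs" / f"{site}.fasta",
            "contig FASTA", site,
        )
        seqs.update(smio.read_contigs(fasta))
        gene_frames.append(read_site_gene_calls(config, site))
    gene_calls = pd.concat(gene_frames, ignore_index=True)
    try:
        stats = mags.bin_statistics(seqs, gene_calls, bins, hits)
        hq = mags.filter_high_quality(
            stats, config.min_completeness, config.max_redundancy
        )
        reg = mags.aai_consistency(hq if len(hq) >= 3 else stats)
        dreg = mags.density_size_regression(hq if len(hq) >= 3 else stats)
    except ValueError as exc:
        raise StageError(f"magstats stage: {exc}") from exc
    smio.write_long_table(stats, out / "bin_stats.tsv")
    smio.write_long_table(hq, out / "bin_stats_hq.tsv")
    smio.write_long_table(reg.to_frame(), out / "aai_regression.tsv")
    smio.write_long_table(dreg.to_frame(), out / "density_size_regression.tsv")
    _write_manifest(
        _manifest(config, "magstats",
                  ["bin_stats.tsv", "bin_stats_hq.tsv", "aai_regression.tsv",
                   "density_size_regression.tsv"],
                  {}),
        out,
    )
    return {"bin_stats": stats, "bin_stats_hq": hq,
            "aai_regression": reg.to_frame(),
            "density_size_regression": dreg.to_frame()}


def run_all(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every enabled stage and write a combined summary report."""
    results = run_profile(config)
    if config.run_classifier:
        results.update(run_classify(config))
    if config.run_magstats:
        results.update(run_magstats(config))
    outputs = sorted(
        p.name for p in config.out_dir.iterdir() if p.suffix == ".tsv"
    )
    _write_manifest(_manifest(config, "all", outputs, {}), config.out_dir)
    report = summary_report(results)
    (config.out_dir / "report.txt").write_text(report)
    return results


def summary_report(results: dict[str, pd.DataFrame]) -> str:
    """Plain-text summary in 'k of N sites' style."""
    lines = ["# sedimeta run summary", ""]
    pres = results.get("presence")
    if pres is not None:
        n_sites = pres["site_id"].nunique()
        lines.append("## Family detection")
        lines.extend(profiles.presence_report(pres))
        lines.append("")
        pathways = results.get("pathways")
        if pathways is not None:
            lines.append("## Pathway completeness")
            for pid, grp in pathways.groupby("pathway_id"):
                k = int(grp["complete"].sum())
                lines.append(f"{pid}: complete in {k} of {n_sites} sites")
            lines.append("")
    pct = results.get("detrital_percent")
    if pct is not None:
        lines.append("## Detrital contigs")
        for r in pct.sort_values("site_id").itertuples(index=False):
            lines.append(
                f"{r.site_id}: {r.pct_cyanobacterial:.1f}% cyanobacterial, "
                f"{r.pct_eukaryotic:.1f}% eukaryotic of {r.n_contigs} contigs"
            )
        lines.append("")
    stats = results.get("bin_stats")
    if stats is not None:
        hq = results.get("bin_stats_hq")
        lines.append("## MAGs")
        lines.append(
            f"{len(hq)} of {len(stats)} bins pass the high-quality filter"
        )
        reg = results.get("aai_regression")
        if reg is not None:
            ols = reg[reg["method"] == "ols"].iloc[0]
            lines.append(
                "taxon-hit diversity vs AAI: slope "
                f"{ols['slope_or_rho']:.3f}, P = {ols['p_value']:.3e} "
                f"(n = {int(ols['n'])})"
            )
        lines.append("")
    return "\n".join(lines)
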