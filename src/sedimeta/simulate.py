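"""Seeded synthetic multi-site metagenome bundles with planted ground truth.

The generator emulates the input structure of a multi-site assembled
shotgun-metagenome study so that every pipeline stage can be exercised
against known answers:

* **Family abundance** — per site, each marker gene family is present with a
  configured probability; present families contribute a Poisson number of
  distinct gene calls, and each gene's mapped-read count is drawn from a
  negative binomial whose mean is ``lambda * (L_g/1e3) * (R_s/1e6)``, so the
  family's expected RPM is ``lambda`` per gene.  Dispersion ``alpha`` gives
  ``Var = mu + alpha * mu^2`` (``alpha = 0`` is Poisson).
* **Detrital contigs** — planted cyanobacterial, eukaryotic and background
  contigs constructed to provably satisfy (or fail) the origin-classification
  rules at mislabel rate ``epsilon = 0``; ``epsilon > 0`` randomly corrupts
  per-gene top-hit taxonomy.
* **MAGs** — bins with configured true genome size, completeness (emitted
  length = size x completeness/100), GC, per-bin AAI center, and a
  taxon-hit diversity generated linearly from AAI with Gaussian noise.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; a fixed seed reproduces the bundle
byte-for-byte.  Sequences are random nucleotides at the configured GC with
no codon structure (no downstream computation reads codons).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as smio


class ConfigError(ValueError):
    """A simulation-configuration field failed validation."""


@dataclass(frozen=True)
class FamilyConfig:
    """One marker gene family: how often it occurs and how abundant it is.

    ``abundance`` is the expected RPM contribution per gene; ``mean_genes``
    the expected number of distinct gene calls at a site where the family
    is present.
    """

    family_id: str
    category: str
    presence_prob: float
    mean_genes: float
    abundance: float

    def validate(self) -> None:
        if not self.family_id:
            raise ConfigError("FamilyConfig.family_id: must be nonempty")
        if not 0 <= self.presence_prob <= 1:
            raise ConfigError(
                f"FamilyConfig.presence_prob ({self.family_id}): "
                f"{self.presence_prob} not in [0, 1]"
            )
        if self.mean_genes < 0:
            raise ConfigError(
                f"FamilyConfig.mean_genes ({self.family_id}): must be >= 0"
            )
        if self.abundance < 0:
            raise ConfigError(
                f"FamilyConfig.abundance ({self.family_id}): must be >= 0"
            )


def default_families() -> list[FamilyConfig]:
    """Marker families spanning nitrogen and sulfur redox cycling plus a few
    accessory categories, with sporadic presence across sites: ammonia
    oxidation nearly ubiquitous, nitrite oxidation common, reductive
    nitrogen steps patchier, nitrous oxide reduction rare, and norB the
    single most abundant family where found."""
    f = FamilyConfig
    return [
        # nitrogen cycling
        f("amoA", "nitrogen", 0.92, 4, 8.0),
        f("amoB", "nitrogen", 0.92, 4, 7.0),
        f("amoC", "nitrogen", 0.92, 5, 9.0),
        f("hao", "nitrogen", 0.85, 3, 5.0),
        f("nxrA", "nitrogen", 0.70, 3, 6.0),
        f("nxrB", "nitrogen", 0.70, 3, 6.0),
        f("napA", "nitrogen", 0.46, 2, 3.0),
        f("napB", "nitrogen", 0.46, 2, 3.0),
        f("nirS", "nitrogen", 0.50, 2, 4.0),
        f("nirK", "nitrogen", 0.40, 2, 3.0),
        f("norB", "nitrogen", 0.38, 5, 12.0),
        f("nosD", "nitrogen", 0.08, 1, 2.0),
        f("nosZ", "nitrogen", 0.08, 1, 2.0),
        f("hzoA", "nitrogen", 0.30, 2, 3.0),
        f("hzsA", "nitrogen", 0.30, 2, 3.0),
        # sulfur cycling
        f("dsrA", "sulfur", 0.80, 4, 6.0),
        f("dsrB", "sulfur", 0.80, 4, 6.0),
        f("dsrE", "sulfur", 0.60, 2, 4.0),
        f("dsrF", "sulfur", 0.60, 2, 4.0),
        f("dsrH", "sulfur", 0.60, 2, 4.0),
        f("soxZ", "sulfur", 0.70, 3, 5.0),
        f("soxX", "sulfur", 0.70, 3, 5.0),
        f("soxA", "sulfur", 0.70, 3, 5.0),
        f("phsA", "sulfur", 0.40, 2, 3.0),
        f("sat", "sulfur", 0.80, 3, 5.0),
        f("aprA", "sulfur", 0.70, 3, 5.0),
        # accessory metabolic markers
        f("coxL", "carbon_fixation", 0.60, 3, 4.0),
        f("rbcL", "carbon_fixation", 0.75, 4, 6.0),
        f("hupL", "hydrogenase", 0.55, 3, 4.0),
        f("malK", "transporter", 0.90, 6, 8.0),
    ]


_BACTERIAL_LABELS = [
    "Proteobacteria", "Planctomycetes", "Chloroflexi", "Firmicutes",
    "Bacteroidetes", "Actinobacteria", "Acidobacteria", "Nitrospirae",
    "Verrucomicrobia", "Gemmatimonadetes",
]
_EUK_LABELS = ["Bacillariophyta", "Chlorophyta", "Haptophyta", "Metazoa"]
_CYANO_LABEL = "Cyanobacteria"


@dataclass(frozen=True)
class SimConfig:
    """Full study configuration; defaults mirror the shape of a 13-site
    survey with one deeply sequenced site yielding 16 usable MAGs."""

    seed: int = 0
    n_sites: int = 13
    reads_per_site: int = 20_000_000
    genes_per_site: int = 500_000
    families: tuple[FamilyConfig, ...] = field(
        default_factory=lambda: tuple(default_families())
    )
    dispersion: float = 0.1          # NB alpha; 0 = Poisson
    gene_len_mean: float = 900.0     # bp
    gene_len_sd: float = 200.0
    gene_len_min: int = 150
    site_gc_pct: float = 45.0
    # detrital contig model
    contigs_per_site: int = 120
    frac_cyano: float = 0.15
    frac_euk: float = 0.05
    epsilon: float = 0.0             # per-gene taxonomy mislabel rate
    euk_len_range: tuple[int, int] = (2600, 8000)
    cyano_len_range: tuple[int, int] = (2000, 12000)
    cyano_hit_fraction: float = 0.8     # >= 0.5 by construction
    background_cyano_fraction: float = 0.3  # < 0.5 by construction
    # MAG model (bins live on the first, deeply sequenced site)
    n_bins: int = 16
    bin_size_range: tuple[float, float] = (1.2e6, 4.6e6)
    bin_completeness_range: tuple[float, float] = (61.0, 99.0)
    bin_redundancy_range: tuple[float, float] = (0.0, 8.0)
    bin_gc_range: tuple[float, float] = (33.0, 56.0)
    bin_density_range: tuple[float, float] = (0.68, 1.12)  # genes/kb
    bin_aai_range: tuple[float, float] = (55.0, 90.0)
    bin_contig_len: int = 100_000
    taxa_intercept: float = 100.0
    taxa_slope: float = -1.0
    taxa_sigma: float = 1.0
    aai_gene_sd: float = 3.0

    def validate(self) -> None:
        pos = ["n_sites", "reads_per_site", "genes_per_site", "gene_len_mean",
               "gene_len_min", "contigs_per_site", "bin_contig_len"]
        for name in pos:
            if getattr(self, name) <= 0:
                raise ConfigError(f"SimConfig.{name}: must be positive")
        nonneg = ["dispersion", "gene_len_sd", "frac_cyano", "frac_euk",
                  "taxa_sigma", "aai_gene_sd"]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"SimConfig.{name}: must be >= 0")
        for name in ["epsilon", "cyano_hit_fraction",
                     "background_cyano_fraction"]:
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"SimConfig.{name}: must be in [0, 1]")
        if self.frac_cyano + self.frac_euk > 1:
            raise ConfigError(
                "SimConfig.frac_cyano: detrital fractions sum to > 1"
            )
        if self.cyano_hit_fraction < 0.5:
            raise ConfigError(
                "SimConfig.cyano_hit_fraction: must be >= 0.5 so planted "
                "cyanobacterial contigs satisfy the majority rule"
            )
        if self.background_cyano_fraction >= 0.5:
            raise ConfigError(
                "SimConfig.background_cyano_fraction: must be < 0.5 so "
                "background contigs stay unclassified"
            )
        if self.euk_len_range[0] <= 2000:
            raise ConfigError(
                "SimConfig.euk_len_range: eukaryotic target infeasible with "
                "length <= 2 kb"
            )
        for name in ["euk_len_range", "cyano_len_range", "bin_size_range",
                     "bin_completeness_range", "bin_redundancy_range",
                     "bin_gc_range", "bin_density_range", "bin_aai_range"]:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"SimConfig.{name}: lower bound > upper")
        lo, hi = self.bin_completeness_range
        if not (0 < lo and hi <= 100):
            raise ConfigError(
                "SimConfig.bin_completeness_range: must lie in (0, 100]"
            )
        if self.n_bins < 0:
            raise ConfigError("SimConfig.n_bins: must be >= 0")
        if not 0 <= self.site_gc_pct <= 100:
            raise ConfigError("SimConfig.site_gc_pct: must be in [0, 100]")
        for fam in self.families:
            fam.validate()
        ids = [f.family_id for f in self.families]
        if len(ids) != len(set(ids)):
            raise ConfigError("SimConfig.families: duplicate family_id")


@dataclass
class GroundTruth:
    """Planted parameters every emitted record traces back to."""

    families: pd.DataFrame   # site_id, family_id, lam, n_genes
    contigs: pd.DataFrame    # site_id, contig_id, true_class
    bins: pd.DataFrame       # bin_id, true_size_bp, completeness_pct, ...


@dataclass
class Bundle:
    """A complete in-memory input bundle plus its ground truth."""

    site_totals: pd.DataFrame
    gene_calls: pd.DataFrame
    coverage: pd.DataFrame
    annotations: pd.DataFrame
    hits: pd.DataFrame
    bins: pd.DataFrame
    contig_seqs: dict[str, dict[str, str]]   # site_id -> {contig_id: seq}
    truth: GroundTruth


# ---------------------------------------------------------------------------
# sequence + hit helpers
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_sequence(rng: np.random.Generator, length: int,
                    gc_pct: float) -> str:
    g = gc_pct / 200.0
    a = (100.0 - gc_pct) / 200.0
    idx = rng.choice(4, size=length, p=[a, g, g, a])
    return _BASES[idx].tobytes().decode("ascii")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray,
               alpha: float) -> np.ndarray:
    """Negative binomial with Var = mu + alpha*mu^2 (alpha=0 -> Poisson)."""
    mu = np.asarray(mu, dtype=float)
    if alpha == 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    out = np.zeros(mu.shape, dtype=np.int64)
    nz = mu > 0
    p = n / (n + mu[nz])
    out[nz] = rng.negative_binomial(n, p)
    return out


def _gene_lengths(rng: np.random.Generator, n: int,
                  config: SimConfig) -> np.ndarray:
    raw = rng.normal(config.gene_len_mean, config.gene_len_sd, size=n)
    return np.maximum(config.gene_len_min, np.round(raw)).astype(int)


def _hit_row(gene_id: str, subject: str, pident: float, aln: int,
             domain: str, label: str, rng: np.random.Generator) -> tuple:
    bit = round(max(30.0, aln * pident / 50.0 + rng.normal(0, 5)), 1)
    evalue = float(f"{10 ** -min(180.0, bit / 3.0):.2e}")
    return (gene_id, subject, round(pident, 1), aln,
            int(aln * (100 - pident) / 100), rng.integers(0, 3),
            1, aln * 3, 1, aln, evalue, bit, domain, label)


def site_ids(config: SimConfig) -> list[str]:
    return [f"WA.{i:03d}" for i in range(1, config.n_sites + 1)]


# ---------------------------------------------------------------------------
# family-abundance simulation
# ---------------------------------------------------------------------------

def simulate_sites(config: SimConfig, rng: np.random.Generator):
    """Per-site family gene calls, coverage, annotations and hits.

    Returns ``(gene_calls, coverage, annotations, hits, contig_seqs,
    family_truth)``.  Each family gene sits on its own small contig; its
    top hit is bacterial, so these contigs never trip the detrital rules.
    """
    config.validate()
    gc_rows, cov_rows, ann_rows, hit_rows, truth_rows = [], [], [], [], []
    contig_seqs: dict[str, dict[str, str]] = {}
    for s, site in enumerate(site_ids(config)):
        seqs: dict[str, str] = {}
        for fam in config.families:
            present = rng.random() < fam.presence_prob
            n = int(rng.poisson(fam.mean_genes)) if present else 0
            if present and n == 0:
                n = 1  # a present family has at least one gene call
            lam = fam.abundance if n else 0.0
            truth_rows.append((site, fam.family_id, lam, n))
            if n == 0:
                continue
            lens = _gene_lengths(rng, n, config)
            mu = lam * (lens / 1e3) * (config.reads_per_site / 1e6)
            counts = _nb_counts(rng, mu, config.dispersion)
            for j in range(n):
                cid = f"{site}_fam_{fam.family_id}_{j:03d}"
                gid = f"{cid}_g1"
                margin = int(rng.integers(50, 200))
                start = margin + 1
                end = start + int(lens[j]) - 1
                clen = end + margin
                seqs[cid] = random_sequence(rng, clen, config.site_gc_pct)
                gc_rows.append(
                    (gid, cid, site, start, end,
                     "+" if rng.random() < 0.5 else "-", int(lens[j]))
                )
                cov_rows.append((site, gid, float(counts[j])))
                ann_rows.append((site, gid, fam.family_id, fam.category))
                hit_rows.append(
                    _hit_row(
                        gid, f"ref_{fam.family_id}_{j:04d}",
                        float(np.clip(rng.normal(70, 10), 30, 99)),
                        int(lens[j]) // 3, "Bacteria",
                        _BACTERIAL_LABELS[
                            int(rng.integers(len(_BACTERIAL_LABELS)))
                        ],
                        rng,
                    )
                )
        contig_seqs[site] = seqs
    gene_calls = pd.DataFrame(gc_rows, columns=smio.GENE_CALL_COLUMNS)
    coverage = pd.DataFrame(cov_rows, columns=smio.COVERAGE_COLUMNS)
    annotations = pd.DataFrame(ann_rows, columns=smio.ANNOTATION_COLUMNS)
    hits = pd.DataFrame(hit_rows, columns=smio.HIT_COLUMNS)
    truth = pd.DataFrame(
        truth_rows, columns=["site_id", "family_id", "lam", "n_genes"]
    )
    return gene_calls, coverage, annotations, hits, contig_seqs, truth


# ---------------------------------------------------------------------------
# detrital contigs
# ---------------------------------------------------------------------------

def _plant_one(config: SimConfig, rng: np.random.Generator, site: str,
               cid: str, target: str):
    """One contig guaranteed to satisfy (target in {cyanobacterial,
    eukaryotic}) or fail (unclassified) the origin rules at epsilon = 0."""
    if target == "eukaryotic":
        length = int(rng.integers(*config.euk_len_range))
        n_genes = 1
        # density 1/length kb^-1 < 0.5 because length > 2000
        n_euk, n_cyano = 1, 0
    elif target == "cyanobacterial":
        length = int(rng.integers(*config.cyano_len_range))
        n_genes = max(1, int(round(length / 1000)))
        n_cyano = int(np.ceil(config.cyano_hit_fraction * n_genes))
        n_euk = 0
    elif target == "unclassified":
        length = int(rng.integers(*config.cyano_len_range))
        n_genes = max(1, int(round(length / 1000)))
        n_cyano = int(np.floor(config.background_cyano_fraction * n_genes))
        n_euk = 0
    else:
        raise ConfigError(f"unknown planted contig class: {target!r}")

    taxa = ["cyano"] * n_cyano + ["euk"] * n_euk + \
        ["bact"] * (n_genes - n_cyano - n_euk)
    rng.shuffle(taxa)

    gene_rows, hit_rows = [], []
    pos = 1
    span = length // n_genes
    for j, taxon in enumerate(taxa):
        glen = min(span - 50, int(_gene_lengths(rng, 1, config)[0]))
        glen = max(90, glen - glen % 3)
        start = pos + int(rng.integers(0, max(1, span - glen - 10)))
        end = start + glen - 1
        pos += span
        gid = f"{cid}_g{j + 1}"
        if rng.random() < config.epsilon:
            taxon = ["cyano", "euk", "bact"][int(rng.integers(3))]
        if taxon == "cyano":
            domain, label = "Bacteria", _CYANO_LABEL
        elif taxon == "euk":
            domain = "Eukaryota"
            label = _EUK_LABELS[int(rng.integers(len(_EUK_LABELS)))]
        else:
            domain = "Bacteria"
            label = _BACTERIAL_LABELS[
                int(rng.integers(len(_BACTERIAL_LABELS)))
            ]
        gene_rows.append(
            (gid, cid, site, start, end,
             "+" if rng.random() < 0.5 else "-", glen)
        )
        hit_rows.append(
            _hit_row(gid, f"ref_det_{cid}_{j}",
                     float(np.clip(rng.normal(75, 8), 30, 99)),
                     glen // 3, domain, label, rng)
        )
    seq = random_sequence(rng, length, config.site_gc_pct)
    return seq, gene_rows, hit_rows


def plant_detrital_contigs(config: SimConfig, rng: np.random.Generator,
                           site: str, counts: dict[str, int] | None = None):
    """Plant a site's detrital + background contigs.

    Returns ``(contig_seqs, gene_calls, hits, contig_truth)``.  Default
    class counts follow ``frac_cyano`` / ``frac_euk`` of
    ``contigs_per_site``; the remainder is unclassified background.
    """
    config.validate()
    if counts is None:
        n = config.contigs_per_site
        n_cy = int(round(config.frac_cyano * n))
        n_eu = int(round(config.frac_euk * n))
        counts = {
            "cyanobacterial": n_cy,
            "eukaryotic": n_eu,
            "unclassified": n - n_cy - n_eu,
        }
    known = {"cyanobacterial", "eukaryotic", "unclassified"}
    unknown = set(counts) - known
    if unknown:
        raise ConfigError(
            f"unknown planted contig class: {sorted(unknown)}"
        )
    seqs: dict[str, str] = {}
    gene_rows, hit_rows, truth_rows = [], [], []
    i = 0
    for target in ["cyanobacterial", "eukaryotic", "unclassified"]:
        for _ in range(counts.get(target, 0)):
            cid = f"{site}_det_{i:05d}"
            i += 1
            seq, g, h = _plant_one(config, rng, site, cid, target)
            seqs[cid] = seq
            gene_rows.extend(g)
            hit_rows.extend(h)
            truth_rows.append((site, cid, target))
    gene_calls = pd.DataFrame(gene_rows, columns=smio.GENE_CALL_COLUMNS)
    hits = pd.DataFrame(hit_rows, columns=smio.HIT_COLUMNS)
    truth = pd.DataFrame(
        truth_rows, columns=["site_id", "contig_id", "true_class"]
    )
    return seqs, gene_calls, hits, truth


# ---------------------------------------------------------------------------
# MAGs
# ---------------------------------------------------------------------------

def simulate_bins(config: SimConfig, rng: np.random.Generator, site: str):
    """Simulate bins with planted size/completeness/GC/AAI/taxon-diversity.

    Returns ``(membership, contig_seqs, gene_calls, hits, bin_truth)``.
    Emitted assembled length is ``true_size * completeness / 100``; taxon
    diversity is ``round(intercept + slope * AAI + N(0, sigma))`` realized
    exactly by cycling that many labels over the bin's gene hits.
    """
    config.validate()
    if config.n_bins and config.n_bins < 3:
        raise ConfigError("SimConfig.n_bins: need >= 3 bins (or 0 for none)")
    mem_rows, gene_rows, hit_rows, truth_rows = [], [], [], []
    seqs: dict[str, str] = {}
    aai_vals = np.linspace(*config.bin_aai_range, num=max(config.n_bins, 1))
    label_pool = [f"Taxon_{k:03d}" for k in range(512)]
    for b in range(config.n_bins):
        bin_id = f"MAG_{b + 1:02d}"
        size = float(rng.uniform(*config.bin_size_range))
        completeness = float(
            np.round(rng.uniform(*config.bin_completeness_range), 1)
        )
        redundancy = float(
            np.round(rng.uniform(*config.bin_redundancy_range), 1)
        )
        gc = float(np.round(rng.uniform(*config.bin_gc_range), 1))
        density = float(rng.uniform(*config.bin_density_range))
        aai = float(aai_vals[b])
        n_taxa = int(
            max(
                1,
                round(
                    config.taxa_intercept + config.taxa_slope * aai
                    + rng.normal(0, config.taxa_sigma)
                ),
            )
        )
        emitted = int(round(size * completeness / 100.0))
        # planted truth is the exact inverse of the emitted length, so the
        # downstream completion-corrected estimate recovers it exactly
        size = emitted * 100.0 / completeness
        truth_rows.append(
            (bin_id, site, size, completeness, redundancy, gc, density,
             aai, n_taxa, config.taxa_slope)
        )
        # split emitted length into contigs
        clens = []
        remaining = emitted
        while remaining > 0:
            c = min(config.bin_contig_len, remaining)
            clens.append(c)
            remaining -= c
        n_genes_total = max(1, int(round(density * emitted / 1e3)))
        # pre-assign taxon labels: first n_taxa distinct, then cycling
        chosen = [label_pool[k % len(label_pool)] for k in range(n_taxa)]
        g_idx = 0
        for ci, clen in enumerate(clens):
            cid = f"{site}_{bin_id}_c{ci:04d}"
            seqs[cid] = random_sequence(rng, clen, gc)
            mem_rows.append((bin_id, cid, site, completeness, redundancy))
            n_genes_c = int(round(n_genes_total * clen / emitted))
            if ci == len(clens) - 1:
                n_genes_c = n_genes_total - g_idx
            n_genes_c = max(0, min(n_genes_c, n_genes_total - g_idx))
            step = clen / max(1, n_genes_c) if n_genes_c else clen
            for j in range(n_genes_c):
                glen = int(min(step - 10, _gene_lengths(rng, 1, config)[0]))
                glen = max(90, glen - glen % 3)
                start = int(j * step) + 1
                end = min(start + glen - 1, clen)
                gid = f"{cid}_g{j + 1}"
                gene_rows.append(
                    (gid, cid, site, start, end,
                     "+" if rng.random() < 0.5 else "-", end - start + 1)
                )
                pident = float(
                    np.clip(rng.normal(aai, config.aai_gene_sd), 5, 100)
                )
                if g_idx < n_taxa:
                    label = chosen[g_idx]   # guarantee all labels occur
                else:
                    label = chosen[int(rng.integers(n_taxa))]
                hit_rows.append(
                    _hit_row(gid, f"ref_{bin_id}_{g_idx:05d}", pident,
                             (end - start + 1) // 3, "Bacteria", label, rng)
                )
                g_idx += 1
    membership = pd.DataFrame(mem_rows, columns=smio.BIN_COLUMNS)
    gene_calls = pd.DataFrame(gene_rows, columns=smio.GENE_CALL_COLUMNS)
    hits = pd.DataFrame(hit_rows, columns=smio.HIT_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=["bin_id", "site_id", "true_size_bp", "completeness_pct",
                 "redundancy_pct", "gc_pct", "density", "aai_center",
                 "n_taxa", "taxa_slope"],
    )
    return membership, seqs, gene_calls, hits, truth


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimConfig | None = None,
                    seed: int | None = None) -> Bundle:
    """Generate a complete input bundle under ``config`` (seeded).

    ``seed`` overrides ``config.seed``.  Bins are placed on the first site
    (the deeply sequenced one).
    """
    if config is None:
        config = SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_fam, rng_det, rng_bin = [
        np.random.default_rng(s) for s in ss.spawn(3)
    ]

    gene_calls, coverage, annotations, hits, fam_seqs, fam_truth = \
        simulate_sites(config, rng_fam)

    det_gene, det_hits, det_truth = [], [], []
    contig_seqs = {s: dict(v) for s, v in fam_seqs.items()}
    for site in site_ids(config):
        seqs, g, h, t = plant_detrital_contigs(config, rng_det, site)
        contig_seqs[site].update(seqs)
        det_gene.append(g)
        det_hits.append(h)
        det_truth.append(t)

    sites = site_ids(config)
    bin_site = sites[0]
    if config.n_bins:
        membership, bin_seqs, bin_genes, bin_hits, bin_truth = simulate_bins(
            config, rng_bin, bin_site
        )
        contig_seqs[bin_site].update(bin_seqs)
    else:
        membership = pd.DataFrame(columns=smio.BIN_COLUMNS)
        bin_genes = pd.DataFrame(columns=smio.GENE_CALL_COLUMNS)
        bin_hits = pd.DataFrame(columns=smio.HIT_COLUMNS)
        bin_truth = pd.DataFrame()

    all_genes = pd.concat(
        [gene_calls, *det_gene, bin_genes], ignore_index=True
    )
    all_hits = pd.concat([hits, *det_hits, bin_hits], ignore_index=True)

    n_emitted = all_genes.groupby("site_id").size()
    totals = pd.DataFrame(
        {
            "site_id": sites,
            "total_reads": config.reads_per_site,
            "total_genes": [
                max(config.genes_per_site, int(n_emitted.get(s, 0)))
                for s in sites
            ],
        }
    )
    # family contigs + detrital contigs carry no detrital truth conflict:
    fam_truth_contigs = pd.DataFrame(
        [
            (r.site_id, r.contig_id, "unclassified")
            for r in gene_calls.drop_duplicates("contig_id").itertuples()
        ],
        columns=["site_id", "contig_id", "true_class"],
    )
    contig_truth = pd.concat(
        [fam_truth_contigs, *det_truth], ignore_index=True
    )
    truth = GroundTruth(
        families=fam_truth, contigs=contig_truth, bins=bin_truth
    )
    return Bundle(
        site_totals=totals,
        gene_calls=all_genes,
        coverage=coverage,
        annotations=annotations,
        hits=all_hits,
        bins=membership,
        contig_seqs=contig_seqs,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# bundle (de)serialization
# ---------------------------------------------------------------------------

def write_bundle(bundle: Bundle, outdir: str | Path) -> None:
    """Write a bundle as the on-disk input layout consumed by the runner:

    ``sites.tsv``, ``coverage.tsv``, ``annotations.tsv``, ``hits.tsv``,
    ``bins.tsv``, ``genes/<site>.gff``, ``contigs/<site>.fasta`` and
    ``ground_truth/*.tsv``.
    """
    out = Path(outdir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    (out / "contigs").mkdir(exist_ok=True)
    (out / "ground_truth").mkdir(exist_ok=True)
    smio.write_long_table(bundle.site_totals, out / "sites.tsv")
    smio.write_long_table(bundle.coverage, out / "coverage.tsv")
    smio.write_long_table(bundle.annotations, out / "annotations.tsv")
    # outfmt-6 dialect: no header row, only a '#' comment
    hits = smio.canonicalize(bundle.hits)
    with open(out / "hits.tsv", "w") as fh:
        fh.write("#" + "\t".join(smio.HIT_COLUMNS) + "\n")
        hits.to_csv(fh, sep="\t", index=False, header=False,
                    lineterminator="\n")
    smio.write_long_table(bundle.bins, out / "bins.tsv")
    for site, grp in bundle.gene_calls.groupby("site_id"):
        smio.write_gene_calls_gff(grp, out / "genes" / f"{site}.gff")
    for site, seqs in sorted(bundle.contig_seqs.items()):
        smio.write_contigs(seqs, out / "contigs" / f"{site}.fasta")
    smio.write_long_table(
        bundle.truth.families, out / "ground_truth" / "families.tsv"
    )
    smio.write_long_table(
        bundle.truth.contigs, out / "ground_truth" / "contigs.tsv"
    )
    if len(bundle.truth.bins):
        smio.write_long_table(
            bundle.truth.bins, out / "ground_truth" / "bins.tsv"
        )


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from YAML; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fam_raw = raw.pop("families", None)
    known = {f.name for f in fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
    for key in ("euk_len_range", "cyano_len_range", "bin_size_range",
                "bin_completeness_range", "bin_redundancy_range",
                "bin_gc_range", "bin_density_range", "bin_aai_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    kwargs = dict(raw)
    if fam_raw is not None:
        kwargs["families"] = tuple(FamilyConfig(**f) for f in fam_raw)
    cfg = SimConfig(**kwargs)
    cfg.validate()
    return cfg
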