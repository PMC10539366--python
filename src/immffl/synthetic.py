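"""Synthetic tumor/normal cohort generator with planted ground truth.

Every input the pipeline consumes is generated here: negative-binomial
count matrices for mRNA and miRNA with planted differential features, a
weighted PPI table with a planted hub clique, typed regulatory edge tables
containing planted closed feed-forward loops, an immune-gene list, GMT gene
sets with one set enriched for the hubs, per-sample immune-infiltration
fractions tied to named genes through a Gaussian copula, and exponential
survival times with expression-dependent hazard.  Planted truth is written
alongside the data so every downstream recovery test reads truth only from
the truth file.

Counts follow a gamma-Poisson (negative binomial) model with log-normal
baseline means across features: variance = mu + dispersion * mu^2.  Planted
differential features have the tumor-group mean multiplied by
2^(+/- de_log2fc) with alternating sign, so both tails are populated.
Batch membership cycles over samples and batches >= 2 receive a log2-scale
location shift, exercising the batch-centering step.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .cohort import ExpressionCohort, NORMAL, TUMOR
from .enrich import GeneSetCollection
from .errors import ConfigurationError
from .ffl import MIRNA_MRNA, MIRNA_TF, TF_MRNA

BASELINE_LOG2_MEAN = 5.0
BASELINE_LOG2_SD = 1.5
BASELINE_MEDIAN_SURVIVAL_MONTHS = 40.0
MAX_INFILTRATION = 0.35
CELL_TYPES = ("Macrophage_M0", "Macrophage_M1", "Macrophage_M2", "NKT", "CD8_T")

# sub-stream tags so each generator draws from an independent, reproducible
# stream regardless of call order
_STREAM = {"counts": 1, "edges": 2, "survival": 3, "infiltration": 4}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; identical config + seed gives
    byte-identical outputs."""

    n_genes: int = 2000
    n_mirnas: int = 300
    n_tumor: int = 120
    n_normal: int = 12
    n_de_genes: int = 200
    n_de_mirnas: int = 30
    de_log2fc: float = 3.0
    dispersion: float = 0.2
    n_batches: int = 2
    batch_shift: float = 0.5
    n_tfs: int = 12
    hub_size: int = 4
    n_ppi_background: int = 200
    planted_ffls: list[tuple[str, str, str]] | None = None
    infiltration_targets: list[tuple[str, str, float]] | None = None
    survival_beta: float = -0.5
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_genes", "n_mirnas", "n_tumor", "n_normal", "n_batches", "n_tfs",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_de_genes > self.n_genes or self.n_de_genes < 0:
            raise ConfigurationError("need 0 <= n_de_genes <= n_genes")
        if self.n_de_mirnas > self.n_mirnas or self.n_de_mirnas < 0:
            raise ConfigurationError("need 0 <= n_de_mirnas <= n_mirnas")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if not 0 <= self.censor_rate <= 1:
            raise ConfigurationError("censor_rate must lie in [0, 1]")
        if self.hub_size > self.n_genes:
            raise ConfigurationError("hub set larger than gene universe")
        if self.planted_ffls is None:
            self.planted_ffls = self._default_ffls()
        self.planted_ffls = [tuple(t) for t in self.planted_ffls]
        if self.infiltration_targets is None:
            self.infiltration_targets = self._default_infiltration()
        self.infiltration_targets = [tuple(t) for t in self.infiltration_targets]
        self._validate_ids()

    # -- id universe -------------------------------------------------------

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def mirna_ids(self) -> list[str]:
        return [f"MIR{i + 1:04d}" for i in range(self.n_mirnas)]

    def tf_ids(self) -> list[str]:
        return [f"TF{i + 1:03d}" for i in range(self.n_tfs)]

    def de_gene_ids(self) -> list[str]:
        return self.gene_ids()[: self.n_de_genes]

    def de_mirna_ids(self) -> list[str]:
        return self.mirna_ids()[: self.n_de_mirnas]

    def up_gene_ids(self) -> list[str]:
        # alternating sign: even positions in the DE block are up
        return self.de_gene_ids()[0::2]

    def hub_genes(self) -> list[str]:
        """Planted hub clique: FFL mRNAs padded with planted-up genes."""
        hubs = list(dict.fromkeys(g for _, _, g in self.planted_ffls))
        for g in self.up_gene_ids():
            if len(hubs) >= self.hub_size:
                break
            if g not in hubs:
                hubs.append(g)
        if len(hubs) < 2:
            raise ConfigurationError("hub set needs >= 2 genes")
        return hubs

    def _default_ffls(self) -> list[tuple[str, str, str]]:
        if self.n_de_mirnas < 3 or self.n_de_genes < 3 or self.n_tfs < 2:
            return []
        m = self.mirna_ids()
        g = self.gene_ids()
        t = self.tf_ids()
        # both planted mRNAs are planted-up genes (even DE positions)
        return [(m[0], t[0], g[0]), (m[2], t[1], g[2])]

    def _default_infiltration(self) -> list[tuple[str, str, float]]:
        if not self.planted_ffls:
            return []
        g0 = self.planted_ffls[0][2]
        out = [(g0, "NKT", 0.35)]
        if len(self.planted_ffls) > 1:
            out.append((self.planted_ffls[1][2], "Macrophage_M2", 0.33))
        return out

    def _validate_ids(self) -> None:
        genes, mirnas, tfs = (
            set(self.gene_ids()), set(self.mirna_ids()), set(self.tf_ids()),
        )
        for m, t, g in self.planted_ffls:
            if m not in mirnas or t not in tfs or g not in genes:
                raise ConfigurationError(f"planted FFL ({m},{t},{g}) outside universe")
            if m not in set(self.de_mirna_ids()):
                raise ConfigurationError(f"planted FFL miRNA {m} is not planted DE")
            if g not in set(self.de_gene_ids()):
                raise ConfigurationError(f"planted FFL mRNA {g} is not planted DE")
        for g, ct, rho in self.infiltration_targets:
            if g not in genes:
                raise ConfigurationError(f"infiltration target gene {g} unknown")
            if abs(rho) > 1:
                raise ConfigurationError("infiltration rho must lie in [-1, 1]")
        cts = [ct for _, ct, _ in self.infiltration_targets]
        if len(cts) != len(set(cts)):
            raise ConfigurationError("one infiltration target per cell type")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_ffls"] = [list(t) for t in self.planted_ffls]
        d["infiltration_targets"] = [list(t) for t in self.infiltration_targets]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigurationError(f"unknown config key(s): {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], config.seed])


# ---------------------------------------------------------------------------
# counts


@dataclass
class CountsResult:
    mrna: ExpressionCohort
    mirna: ExpressionCohort
    truth_mrna: pd.DataFrame
    truth_mirna: pd.DataFrame


def _sample_annotations(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    sample_ids = [f"T{i + 1:04d}" for i in range(config.n_tumor)] + [
        f"N{i + 1:04d}" for i in range(config.n_normal)
    ]
    group = [TUMOR] * config.n_tumor + [NORMAL] * config.n_normal
    batch = [(i % config.n_batches) + 1 for i in range(len(sample_ids))]
    sex = rng.choice(["female", "male"], size=len(sample_ids))
    return pd.DataFrame(
        {"group": group, "batch": batch, "sex": sex},
        index=pd.Index(sample_ids, name="sample_id"),
    )


def _nb_matrix(
    rng: np.random.Generator,
    feature_ids: list[str],
    annotations: pd.DataFrame,
    n_de: int,
    de_log2fc: float,
    dispersion: float,
    batch_shift: float,
) -> tuple[np.ndarray, np.ndarray]:
    n_feat, n_samp = len(feature_ids), len(annotations)
    base = 2.0 ** rng.normal(BASELINE_LOG2_MEAN, BASELINE_LOG2_SD, size=n_feat)
    true_lfc = np.zeros(n_feat)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    true_lfc[:n_de] = signs * de_log2fc
    is_tumor = (annotations["group"] == TUMOR).to_numpy()
    batch = annotations["batch"].to_numpy()
    mu = np.tile(base[:, None], (1, n_samp))
    mu[:, is_tumor] *= 2.0 ** true_lfc[:, None]
    mu[:, batch >= 2] *= 2.0**batch_shift
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    counts = rng.poisson(lam)
    return counts, true_lfc


def generate_counts(config: SimulationConfig) -> CountsResult:
    """Negative-binomial mRNA and miRNA count cohorts with planted DE.

    Truth tables record the planted log2 fold change per feature; they are
    the only sanctioned source of ground truth for recovery tests.
    """
    rng = _rng(config, "counts")
    annotations = _sample_annotations(config, rng)
    gene_ids = config.gene_ids()
    mirna_ids = config.mirna_ids()
    g_counts, g_lfc = _nb_matrix(
        rng, gene_ids, annotations, config.n_de_genes, config.de_log2fc,
        config.dispersion, config.batch_shift,
    )
    m_counts, m_lfc = _nb_matrix(
        rng, mirna_ids, annotations, config.n_de_mirnas, config.de_log2fc,
        config.dispersion, config.batch_shift,
    )
    mrna = ExpressionCohort(
        pd.DataFrame(g_counts, index=gene_ids, columns=annotations.index),
        annotations.copy(),
    )
    mirna = ExpressionCohort(
        pd.DataFrame(m_counts, index=mirna_ids, columns=annotations.index),
        annotations.copy(),
    )
    truth_g = pd.DataFrame(
        {"feature_id": gene_ids, "true_log2fc": g_lfc, "is_de": g_lfc != 0}
    )
    truth_m = pd.DataFrame(
        {"feature_id": mirna_ids, "true_log2fc": m_lfc, "is_de": m_lfc != 0}
    )
    return CountsResult(mrna, mirna, truth_g, truth_m)


# ---------------------------------------------------------------------------
# edge tables, immune list, gene sets


@dataclass
class EdgeTables:
    regulatory: pd.DataFrame  # source, target, type, p
    ppi: pd.DataFrame  # a, b, score
    immune_genes: list[str]
    gene_sets: GeneSetCollection
    hub_genes: list[str]


def generate_edge_tables(config: SimulationConfig, de_truth: pd.DataFrame) -> EdgeTables:
    """PPI, regulatory, immune-list and gene-set inputs with planted structure.

    The PPI table carries a clique over the hub genes at confidence > 0.9
    plus uniform-[0.4, 0.95] background edges; the regulatory table carries
    each planted FFL's three edges plus decoy edges (including extra edges
    on the first planted triple's nodes so it is the top-degree motif);
    the immune list covers all hubs plus planted-DE and random genes; one
    gene set is enriched for the hubs.
    """
    rng = _rng(config, "edges")
    genes = config.gene_ids()
    hubs = config.hub_genes()
    if len(hubs) > len(genes):
        raise ConfigurationError("hub set larger than gene universe")
    de_genes = list(de_truth.loc[de_truth["is_de"], "feature_id"])

    # PPI: planted clique strictly above the 0.9 cutoff
    ppi_rows = []
    for i, a in enumerate(hubs):
        for b in hubs[i + 1 :]:
            ppi_rows.append({"a": a, "b": b, "score": round(rng.uniform(0.92, 0.995), 4)})
    seen = {(min(r["a"], r["b"]), max(r["a"], r["b"])) for r in ppi_rows}
    non_hub = [g for g in genes if g not in set(hubs)]
    n_clique = len(ppi_rows)
    while len(ppi_rows) - n_clique < config.n_ppi_background:
        a, b = rng.choice(non_hub, size=2, replace=False)
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        ppi_rows.append({"a": key[0], "b": key[1], "score": round(rng.uniform(0.4, 0.95), 4)})
    ppi = pd.DataFrame(ppi_rows)

    # regulatory edges: planted triples plus controlled decoys
    dems = config.de_mirna_ids()
    reg_rows: list[dict] = []

    def add(src, tgt, typ, p=np.nan):
        reg_rows.append({"source": src, "target": tgt, "type": typ, "p": p})

    used_tfs = [t for _, t, _ in config.planted_ffls]
    spare_tfs = [t for t in config.tf_ids() if t not in set(used_tfs)]
    spare_mirnas = [m for m in dems if m not in {m for m, _, _ in config.planted_ffls}]
    for i, (m, t, g) in enumerate(config.planted_ffls):
        add(t, g, TF_MRNA, p=1e-5)
        add(m, g, MIRNA_MRNA)
        add(m, t, MIRNA_TF)
        # degree boosts, largest for the first planted triple; miRNA decoys
        # targeting the TF are disjoint from those targeting the mRNA so no
        # unplanned loop closes
        n_boost = max(3 - 2 * i, 1)
        for t_extra in spare_tfs[:n_boost]:
            add(m, t_extra, MIRNA_TF)
        pool = spare_mirnas[i * 6 : i * 6 + 2 * n_boost]
        for m_extra in pool[:n_boost]:
            add(m_extra, t, MIRNA_TF)
        for m_extra in pool[n_boost:]:
            add(m_extra, g, MIRNA_MRNA)
    # decoy rows exercising the filters: non-significant TF evidence,
    # non-DEM miRNA sources, targets outside the hub set
    non_hub_de = [g for g in de_genes if g not in set(hubs)][:3]
    for g in non_hub_de:
        add(spare_tfs[0] if spare_tfs else used_tfs[0], g, TF_MRNA, p=1e-4)
    if hubs:
        add(used_tfs[0], hubs[0], TF_MRNA, p=0.5)  # fails the p <= 0.001 cut
        non_dem = [m for m in config.mirna_ids() if m not in set(dems)]
        if non_dem:
            add(non_dem[0], hubs[0], MIRNA_MRNA)
    regulatory = pd.DataFrame(reg_rows).drop_duplicates(["source", "target", "type"])

    # immune-related gene list: hubs + half of the DE block + random others
    immune = list(dict.fromkeys(hubs + de_genes[0::2]))
    extras = [g for g in non_hub if g not in set(immune)]
    idx = rng.choice(len(extras), size=min(100, len(extras)), replace=False)
    immune += [extras[i] for i in sorted(idx)]

    # gene sets: one set genuinely enriched for the hubs (hubs plus other
    # immune DE genes, so the DEIRG query overlaps it heavily) among random
    # background sets
    sets: dict[str, list[str]] = {}
    immune_de = [g for g in de_genes[0::2] if g not in set(hubs)][:8]
    filler = [g for g in non_hub if g not in set(immune_de)]
    idx = rng.choice(len(filler), size=6, replace=False)
    sets["HUB_COMPLEX"] = hubs + immune_de + [filler[i] for i in sorted(idx)]
    for k in range(10):
        idx = rng.choice(len(genes), size=20, replace=False)
        sets[f"RANDOM_SET_{k + 1:02d}"] = [genes[i] for i in sorted(idx)]
    collection = GeneSetCollection(sets, namespace="pathway")

    return EdgeTables(
        regulatory=regulatory.reset_index(drop=True),
        ppi=ppi,
        immune_genes=immune,
        gene_sets=collection,
        hub_genes=hubs,
    )


# ---------------------------------------------------------------------------
# survival


def generate_survival(
    config: SimulationConfig, cohort: ExpressionCohort, marker: str
) -> pd.DataFrame:
    """Exponential survival with hazard lambda0 * exp(beta * z_marker).

    z is the marker's standardized (log2) expression; censoring times are
    uniform on [0, c_max] with c_max calibrated so the expected censored
    fraction equals ``censor_rate`` (non-informative censoring).
    """
    if marker not in cohort.values.index:
        raise KeyError(f"survival marker '{marker}' not in cohort")
    rng = _rng(config, "survival")
    expr = cohort.values.loc[marker].to_numpy(dtype=float)
    if not cohort.is_log:
        expr = np.log2(expr + 1.0)
    sd = expr.std()
    z = (expr - expr.mean()) / sd if sd > 0 else np.zeros_like(expr)
    lam0 = math.log(2.0) / BASELINE_MEDIAN_SURVIVAL_MONTHS
    hazard = lam0 * np.exp(config.survival_beta * z)
    times = rng.exponential(1.0 / hazard)
    times = np.maximum(times, 1e-3)
    events = np.ones(len(times), dtype=int)
    if config.censor_rate > 0:
        def censored_frac(c_max: float) -> float:
            return float(np.mean(np.minimum(times / c_max, 1.0)))

        lo, hi = 1e-6, float(times.max()) * 1e3
        if config.censor_rate >= 1:
            c_max = lo
        else:
            c_max = optimize.brentq(
                lambda c: censored_frac(c) - config.censor_rate, lo, hi
            )
        censor_times = rng.uniform(0.0, c_max, size=len(times))
        events = (times <= censor_times).astype(int)
        times = np.minimum(times, censor_times)
        times = np.maximum(times, 1e-3)
    return pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "time_months": np.round(times, 4),
            "event": events,
        }
    )


# ---------------------------------------------------------------------------
# infiltration


def generate_infiltration(
    config: SimulationConfig, cohort: ExpressionCohort
) -> pd.DataFrame:
    """Sample x cell-type infiltration fractions plus tumor purity.

    Each targeted cell type's score is a Gaussian-copula transform of the
    named gene's expression ranks; the latent correlation is pre-warped
    (2 sin(pi rho / 6)) so the realized Spearman correlation matches the
    requested rho.  Purity is negatively coupled to total infiltration and
    all fractions lie in [0, 1].
    """
    for g, ct, rho in config.infiltration_targets:
        if g not in cohort.values.index:
            raise ConfigurationError(f"infiltration target gene {g} not in cohort")
    rng = _rng(config, "infiltration")
    n = len(cohort.sample_ids)
    cell_types = list(CELL_TYPES) + [
        ct for _, ct, _ in config.infiltration_targets if ct not in CELL_TYPES
    ]
    targets = {ct: (g, rho) for g, ct, rho in config.infiltration_targets}
    data: dict[str, np.ndarray] = {}
    for ct in cell_types:
        if ct in targets:
            g, rho = targets[ct]
            expr = cohort.values.loc[g].to_numpy(dtype=float)
            ranks = stats.rankdata(expr, method="average")
            z_gene = stats.norm.ppf((ranks - 0.5) / n)
            latent = 2.0 * math.sin(math.pi * rho / 6.0)
            z = latent * z_gene + math.sqrt(max(0.0, 1.0 - latent**2)) * rng.normal(
                size=n
            )
        else:
            z = rng.normal(size=n)
        data[ct] = np.clip(MAX_INFILTRATION * stats.norm.cdf(z), 0.0, 1.0)
    total = np.sum(list(data.values()), axis=0)
    purity = np.clip(1.0 - 0.8 * total + 0.05 * rng.normal(size=n), 0.0, 1.0)
    df = pd.DataFrame(data, index=pd.Index(cohort.sample_ids, name="sample_id"))
    df["purity"] = purity
    return df.round(6)


# ---------------------------------------------------------------------------
# dataset writer


def write_simulated_dataset(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input under ``out_dir`` and return the paths.

    Files: mrna_counts.tsv, mirna_counts.tsv, samples.tsv, immune_genes.txt,
    gene_sets.gmt, ppi_edges.tsv, regulatory_edges.tsv, survival.tsv,
    infiltration.tsv, truth.json.  Rerunning with the same config and seed
    reproduces every byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = generate_counts(config)
    edges = generate_edge_tables(config, counts.truth_mrna)
    marker = config.planted_ffls[0][2] if config.planted_ffls else config.gene_ids()[0]
    tumor_ids = counts.mrna.samples_in_group(TUMOR)
    tumor_mrna = counts.mrna.subset_samples(tumor_ids)
    surv = generate_survival(config, tumor_mrna, marker)
    infil = generate_infiltration(config, tumor_mrna)

    paths = {
        "mrna_counts": out / "mrna_counts.tsv",
        "mirna_counts": out / "mirna_counts.tsv",
        "samples": out / "samples.tsv",
        "immune_genes": out / "immune_genes.txt",
        "gene_sets": out / "gene_sets.gmt",
        "ppi_edges": out / "ppi_edges.tsv",
        "regulatory_edges": out / "regulatory_edges.tsv",
        "survival": out / "survival.tsv",
        "infiltration": out / "infiltration.tsv",
        "truth": out / "truth.json",
    }
    counts.mrna.write(paths["mrna_counts"], paths["samples"])
    counts.mirna.write(paths["mirna_counts"])
    with open(paths["immune_genes"], "w") as fh:
        fh.write("\n".join(edges.immune_genes) + "\n")
    edges.gene_sets.to_gmt(paths["gene_sets"])
    edges.ppi.to_csv(paths["ppi_edges"], sep="\t", index=False)
    edges.regulatory.to_csv(paths["regulatory_edges"], sep="\t", index=False)
    surv.to_csv(paths["survival"], sep="\t", index=False)
    infil.to_csv(paths["infiltration"], sep="\t", index_label="sample_id")
    truth = {
        "config": config.to_dict(),
        "de_genes": list(
            counts.truth_mrna.loc[counts.truth_mrna["is_de"], "feature_id"]
        ),
        "de_gene_signs": {
            r.feature_id: (1 if r.true_log2fc > 0 else -1)
            for r in counts.truth_mrna.itertuples()
            if r.is_de
        },
        "de_mirnas": list(
            counts.truth_mirna.loc[counts.truth_mirna["is_de"], "feature_id"]
        ),
        "hub_genes": edges.hub_genes,
        "planted_ffls": [list(t) for t in config.planted_ffls],
        "infiltration_targets": [list(t) for t in config.infiltration_targets],
        "survival_marker": marker,
        "survival_beta": config.survival_beta,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
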