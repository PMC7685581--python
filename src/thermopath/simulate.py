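"""Seeded generator of coupled geochemistry / community / annotation datasets.

The generator emulates the structure of a hot-spring "oil site" survey:
~10 water samples, a heterogeneous geochemical block (temperature, pH,
Eh, mineralization, major ions in g/l, trace elements in ug/l), an OTU
count table at amplicon read depths of ~12,000-29,000, and a taxon
annotation database / pathway catalog in which a fraction of taxa are
hydrocarbon degraders.

A single standard-normal latent gradient z couples everything (rank-1
coupling — the minimal structure under which both headline
associations, taxa~geochemistry and pathway-completeness~geochemistry,
emerge rather than being hard-coded):

* geochemistry:  g_ij = a_j * kappa * z_i + sigma_j * eps_ij, mapped to
  natural scales (linear for T/pH/Eh, log-normal for concentrations);
* community:     lambda_ik = mu_k + b_k * kappa * z_i + eta_ik, softmax
  per sample, multinomial read counts at a sampled depth;
* function:      "degrader" taxa have positive gradient response b_k and
  carry the KOs of the degradation pathways, so pathway completeness
  co-varies with z through which taxa are detected.

Everything is drawn from one numpy Generator: identical seeds give
byte-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    BELOW_DETECTION_LIMIT,
    MEASURED,
    MISSING,
    AnnotationDB,
    GeochemTable,
    Lineage,
    OtuTable,
    Pathway,
    PathwayCatalog,
    write_annotation_db,
    write_geochem_table,
    write_otu_table,
    write_pathway_catalog,
)

DEGRADATION_PATHWAY_NAMES = (
    "Naphthalene degradation",
    "Benzoate degradation",
    "Ethylbenzene degradation",
    "Xylene degradation",
    "Nitrotoluene degradation",
    "Dioxin degradation",
    "Styrene degradation",
)

#: (name, kind, base, gradient scale) for the default geochemical block.
#: kind 'linear' stays on its natural scale; 'log' is exponentiated
#: (log-normal concentrations). Bases chosen to sit in the ranges of
#: acid-sulfate/chloride thermal waters (T up to ~97 C, pH ~2-8,
#: Eh swings of hundreds of mV, TDS up to ~1.3 g/l, trace metals
#: and metalloids As/Sb/Hg/B at 1-1000 ug/l).
_GEOCHEM_VARS = (
    ("T (degC)", "linear", 55.0, 18.0),
    ("pH", "linear", 5.0, 1.4),
    ("Eh (mV)", "linear", 80.0, 160.0),
    ("TDS (g/l)", "log", 0.4, 0.9),
    ("Na (g/l)", "log", 0.15, 0.9),
    ("K (g/l)", "log", 0.02, 0.9),
    ("Ca (g/l)", "log", 0.03, 0.8),
    ("Mg (g/l)", "log", 0.01, 0.8),
    ("Cl (g/l)", "log", 0.2, 1.0),
    ("SO4 (g/l)", "log", 0.15, 0.8),
    ("HCO3 (g/l)", "log", 0.05, 0.8),
    ("B (ug/l)", "log", 400.0, 1.2),
    ("Li (ug/l)", "log", 150.0, 1.2),
    ("As (ug/l)", "log", 300.0, 1.4),
    ("Sb (ug/l)", "log", 40.0, 1.4),
    ("Hg (ug/l)", "log", 2.0, 1.4),
    ("Cu (ug/l)", "log", 8.0, 1.3),
    ("Ga (ug/l)", "log", 1.5, 1.3),
    ("Ge (ug/l)", "log", 3.0, 1.3),
    ("Fe (ug/l)", "log", 800.0, 1.4),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults mirror the study's scales.

    ``coupling`` is kappa in [0, 1]; 0 decouples the blocks entirely.
    ``seed`` is mandatory — there is no implicit randomness.
    """

    seed: int
    n_samples: int = 10
    n_taxa: int = 200
    n_geochem_vars: int = 20
    depth_range: tuple[int, int] = (12_000, 29_000)
    coupling: float = 0.9
    taxon_response_scale: float = 1.0
    taxon_noise_sd: float = 0.6
    geochem_noise_sd: float = 0.6
    base_log_abundance_sd: float = 2.5
    n_pathways: int = 10
    kos_per_pathway: int = 8
    degrader_fraction: float = 0.15
    degrader_ko_prob: float = 0.10
    background_ko_prob: float = 0.005
    housekeeping_ko_prob: float = 0.75
    missing_fraction: float = 0.02
    overdispersion: float | None = None  # Dirichlet concentration multiplier

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_taxa < 1 or self.n_geochem_vars < 1:
            raise ValidationError("all counts must be >= 1")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValidationError("coupling must lie in [0, 1]")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValidationError("invalid read-depth range")
        if self.n_pathways < 2 or self.kos_per_pathway < 1:
            raise ValidationError("need at least 2 pathways with >= 1 KO each")
        if not (0.0 <= self.degrader_fraction <= 1.0):
            raise ValidationError("degrader fraction must lie in [0, 1]")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValidationError("overdispersion concentration must be positive")


@dataclass
class Truth:
    """Generating parameters stored alongside the dataset."""

    z: np.ndarray
    geochem_loadings: np.ndarray
    geochem_noise_sds: np.ndarray
    taxon_responses: np.ndarray
    taxon_noise_sd: float
    coupling: float
    seed: int
    degrader_taxa: list[str]

    @property
    def rho(self) -> float:
        """Population axis-1 score correlation of the latent linear blocks.

        For the rank-1 model x = kappa*a*z + D_x*eps and
        lambda = kappa*b*z + sigma_y*eta the population PLS weights are
        a/||a|| and b/||b||, giving

            rho = k2*|a||b| / sqrt((k2*|a|^2 + sx2)(k2*|b|^2 + sy2))

        with sx2 = sum(a_j^2 sigma_j^2)/|a|^2 and sy2 = sigma_y^2.
        Exactly 0 when the coupling is 0.
        """
        a, b = self.geochem_loadings, self.taxon_responses
        k2 = self.coupling**2
        na2, nb2 = float(a @ a), float(b @ b)
        if k2 == 0 or na2 == 0 or nb2 == 0:
            return 0.0
        sx2 = float((a**2 * self.geochem_noise_sds**2).sum()) / na2
        sy2 = self.taxon_noise_sd**2
        num = k2 * np.sqrt(na2 * nb2)
        den = np.sqrt((k2 * na2 + sx2) * (k2 * nb2 + sy2))
        return float(num / den)


@dataclass
class SyntheticDataset:
    otu_table: OtuTable
    geochem: GeochemTable
    annotations: AnnotationDB
    catalog: PathwayCatalog
    truth: Truth
    config: SyntheticConfig


def _make_catalog(cfg: SyntheticConfig) -> tuple[PathwayCatalog, list[str], list[str]]:
    """Catalog with disjoint KO sets; returns (catalog, degradation KOs, extras)."""
    n_deg = min(len(DEGRADATION_PATHWAY_NAMES), max(1, cfg.n_pathways - 3))
    names = list(DEGRADATION_PATHWAY_NAMES[:n_deg])
    names += [f"Core metabolism {i + 1}" for i in range(cfg.n_pathways - n_deg)]
    pathways = []
    ko_counter = 1
    deg_kos: list[str] = []
    for i, name in enumerate(names):
        kos = [f"K{ko_counter + j:05d}" for j in range(cfg.kos_per_pathway)]
        ko_counter += cfg.kos_per_pathway
        if i < n_deg:
            deg_kos.extend(kos)
        pathways.append(Pathway(f"map{i + 1:05d}", name, frozenset(kos)))
    extras = [f"K{ko_counter + j:05d}" for j in range(40)]
    return PathwayCatalog(tuple(pathways)), deg_kos, extras


def generate_coupled_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset; all randomness from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, t = cfg.n_samples, cfg.n_taxa
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    otu_ids = [f"OTU{k + 1:04d}" for k in range(t)]

    z = rng.standard_normal(n)

    # --- geochemistry -----------------------------------------------------
    specs = [_GEOCHEM_VARS[j % len(_GEOCHEM_VARS)] for j in range(cfg.n_geochem_vars)]
    names = []
    for j, (name, *_rest) in enumerate(specs):
        names.append(name if j < len(_GEOCHEM_VARS) else f"{name} #{j}")
    signs = rng.choice([-1.0, 1.0], size=cfg.n_geochem_vars)
    a = signs * rng.uniform(0.5, 1.0, size=cfg.n_geochem_vars)
    sigma = cfg.geochem_noise_sd * rng.uniform(0.4, 1.3, size=cfg.n_geochem_vars)
    g = cfg.coupling * np.outer(z, a) + rng.standard_normal((n, cfg.n_geochem_vars)) * sigma

    values = np.empty_like(g)
    mask = np.full((n, cfg.n_geochem_vars), MEASURED, dtype=object)
    for j, (name, kind, base, scale) in enumerate(specs):
        if kind == "linear":
            values[:, j] = base + scale * g[:, j]
            if name == "pH":
                values[:, j] = np.clip(values[:, j], 0.5, 13.5)
            elif name.startswith("T"):
                values[:, j] = np.clip(values[:, j], 4.0, 97.0)
        else:
            values[:, j] = base * np.exp(scale * g[:, j])
            dl = base / 30.0  # crude per-variable detection limit
            censored = values[:, j] < dl
            values[censored, j] = dl / 2.0
            mask[censored, j] = BELOW_DETECTION_LIMIT
    if cfg.missing_fraction > 0:
        trace_cols = [j for j, (nm, kind, *_r) in enumerate(specs) if kind == "log"]
        for j in trace_cols:
            idx = np.where(rng.random(n) < cfg.missing_fraction)[0]
            idx = idx[: max(0, n - 3)]  # keep >= 3 measured cells per column
            values[idx, j] = np.nan
            mask[idx, j] = MISSING
    geochem = GeochemTable(
        values=pd.DataFrame(values, index=sample_ids, columns=names),
        mask=pd.DataFrame(mask, index=sample_ids, columns=names),
    )

    # --- community --------------------------------------------------------
    mu = rng.normal(0.0, cfg.base_log_abundance_sd, size=t)
    b = rng.normal(0.0, cfg.taxon_response_scale, size=t)
    n_deg_taxa = int(round(cfg.degrader_fraction * t))
    degrader_idx = rng.choice(t, size=n_deg_taxa, replace=False)
    # degraders respond positively to the gradient so that high-z samples
    # are enriched in degradation KOs
    b[degrader_idx] = np.abs(b[degrader_idx]) + 0.5 * cfg.taxon_response_scale

    lam = mu + cfg.coupling * np.outer(z, b)
    lam += rng.standard_normal((n, t)) * cfg.taxon_noise_sd
    lam -= lam.max(axis=1, keepdims=True)
    probs = np.exp(lam)
    probs /= probs.sum(axis=1, keepdims=True)

    depths = rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1, size=n)
    counts = np.empty((n, t), dtype=float)
    for i in range(n):
        p = probs[i]
        if cfg.overdispersion is not None:
            p = rng.dirichlet(p * cfg.overdispersion)
        counts[i] = rng.multinomial(depths[i], p)

    taxonomy = {}
    degrader_set = set(degrader_idx.tolist())
    for k, otu in enumerate(otu_ids):
        genus = f"degradens{k + 1:04d}" if k in degrader_set else f"thermus{k + 1:04d}"
        taxonomy[otu] = Lineage.parse(
            f"k__Bacteria; p__Synthetica; c__Simulata; o__Generatales; "
            f"f__Syntheticaceae; g__{genus}"
        )
    otu_table = OtuTable(
        data=pd.DataFrame(counts, index=sample_ids, columns=otu_ids),
        unit="counts",
        taxonomy=taxonomy,
    )

    # --- annotations ------------------------------------------------------
    catalog, deg_kos, extra_kos = _make_catalog(cfg)
    hk_kos = sorted(
        set().union(*(p.kos for p in catalog)) - set(deg_kos)
    )
    kos_by_taxon: dict[str, frozenset[str]] = {}
    for k, otu in enumerate(otu_ids):
        genus_label = taxonomy[otu].at_rank("genus")
        kos: set[str] = set()
        kos |= {ko for ko in hk_kos if rng.random() < cfg.housekeeping_ko_prob}
        kos |= {ko for ko in extra_kos if rng.random() < 0.3}
        p_deg = cfg.degrader_ko_prob if k in degrader_set else cfg.background_ko_prob
        kos |= {ko for ko in deg_kos if rng.random() < p_deg}
        if not kos:
            kos = {extra_kos[int(rng.integers(len(extra_kos)))]}
        kos_by_taxon[genus_label] = frozenset(kos)
    annotations = AnnotationDB(
        kos_by_taxon=kos_by_taxon, provenance=f"synthetic seed={cfg.seed}"
    )

    truth = Truth(
        z=z,
        geochem_loadings=a,
        geochem_noise_sds=sigma,
        taxon_responses=b,
        taxon_noise_sd=cfg.taxon_noise_sd,
        coupling=cfg.coupling,
        seed=cfg.seed,
        degrader_taxa=[otu_ids[k] for k in sorted(degrader_set)],
    )
    return SyntheticDataset(otu_table, geochem, annotations, catalog, truth, cfg)


def generate_null_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Same generative process with the coupling forced to zero."""
    return generate_coupled_dataset(replace(cfg, coupling=0.0))


def write_fixture(ds: SyntheticDataset, directory) -> list[str]:
    """Write all tables in the pipeline's flat formats plus truth + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    seed = ds.config.seed
    files = {
        "otu_table.tsv": lambda p: write_otu_table(ds.otu_table, p, seed=seed),
        "geochem.tsv": lambda p: write_geochem_table(ds.geochem, p, seed=seed),
        "annotations.tsv": lambda p: write_annotation_db(ds.annotations, p, seed=seed),
        "pathways.tsv": lambda p: write_pathway_catalog(ds.catalog, p, seed=seed),
    }
    for fname, writer in files.items():
        writer(directory / fname)
    truth_doc = {
        "seed": seed,
        "coupling": ds.truth.coupling,
        "rho": ds.truth.rho,
        "z": ds.truth.z.tolist(),
        "geochem_loadings": ds.truth.geochem_loadings.tolist(),
        "geochem_noise_sds": ds.truth.geochem_noise_sds.tolist(),
        "taxon_responses": ds.truth.taxon_responses.tolist(),
        "taxon_noise_sd": ds.truth.taxon_noise_sd,
        "degrader_taxa": ds.truth.degrader_taxa,
    }
    with open(directory / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
    names = [*files.keys(), "truth.json"]
    manifest = {"files": names, "seed": seed, "generator": "thermopath.simulate"}
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return names + ["manifest.json"]
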