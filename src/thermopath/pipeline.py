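"""End-to-end pipeline: diversity -> completeness -> two 2B-PLS analyses.

A run takes either file inputs (OTU table, geochemistry, annotation DB,
pathway catalog) or a simulation block, and produces a report bundle:
diversity TSV, completeness matrix + match report, the high-completeness
pathway list, and two 2B-PLS summaries (taxa~geochemistry and
pathway-completeness~geochemistry) with permutation p-values. Every
number in the human-readable outputs is also in ``summary.json``; all
randomness derives from the configured seed.

Default block preprocessing (all configurable):
geochemistry -> log10 on concentration variables then z-score (units
are wildly heterogeneous: degC, pH units, mV, g/l, ug/l); community ->
Hellinger then column-centering; completeness -> centering only (the
scale [0, 1] is already shared across pathways).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as _div
from .errors import ConfigurationError, ThermopathError
from .function import completeness_matrix, high_completeness_pathways
from .io import (
    MISSING,
    GeochemTable,
    OtuTable,
    read_annotation_db,
    read_geochem_table,
    read_otu_table,
    read_pathway_catalog,
    to_relative,
)
from .ordination import Block, BlockScaler, TwoBlockPLS, hellinger_transform
from .simulate import SyntheticConfig, generate_coupled_dataset

PIPELINE_VERSION = "0.1.0"


def concentration_variables(geo: GeochemTable) -> list[str]:
    """Variables whose names carry a concentration unit (g/l or ug/l)."""
    return [p for p in geo.parameters if "g/l" in p.lower()]


def geochem_block(geo: GeochemTable, max_missing_frac: float = 0.5) -> Block:
    """Raw geochemistry block; variables that are mostly missing are dropped.

    Below-detection-limit cells keep their policy-substituted numeric
    value; truly missing cells stay NaN for the downstream imputer.
    """
    keep = []
    for p in geo.parameters:
        frac_missing = (geo.mask[p] == MISSING).mean()
        if frac_missing <= max_missing_frac:
            keep.append(p)
    return Block(data=geo.values[keep].copy(), preprocessing="raw")


def community_block(table: OtuTable, transform: str = "hellinger") -> Block:
    """Community block: ``hellinger`` (default) or plain ``relative``."""
    if transform == "hellinger":
        return hellinger_transform(table)
    if transform == "relative":
        rel = to_relative(table) if table.unit == "counts" else table
        return Block(data=rel.data.copy(), preprocessing="raw")
    raise ConfigurationError(f"unknown community transform {transform!r}")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    seed: int
    outdir: str
    inputs: dict | None = None  # otu_table, geochem, annotations, pathways
    simulate: dict | None = None  # SyntheticConfig overrides
    n_perm: int = 999
    min_abundance: float = 0.0005
    completeness_threshold: float = 0.9
    community_transform: str = "hellinger"
    geochem_log10: bool = True
    geochem_scale: bool = True
    bdl_policy: str = "zero"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigurationError(
                "config must contain exactly one of 'inputs' or 'simulate'"
            )
        if self.inputs is not None:
            required = {"otu_table", "geochem", "annotations", "pathways"}
            missing = required - set(self.inputs)
            if missing:
                raise ConfigurationError(f"inputs block missing {sorted(missing)}")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        if "seed" not in doc or "outdir" not in doc:
            raise ConfigurationError(f"{path}: 'seed' and 'outdir' are required")
        return cls(**doc)

    def digest(self) -> str:
        # outdir is excluded: it does not affect the computation
        doc = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class ReportBundle:
    """In-memory results of a run; files live under ``outdir``."""

    diversity: pd.DataFrame
    completeness: pd.DataFrame
    high_completeness: pd.DataFrame
    pls_taxa: dict
    pls_completeness: dict
    summary: dict
    outdir: Path


def _pls_analysis(
    x_block: Block,
    y_block: Block,
    n_perm: int,
    seed: int,
    y_center_only: bool = False,
    geochem_log10: bool = True,
    geochem_scale: bool = True,
) -> tuple[dict, TwoBlockPLS, Block, Block]:
    log_vars = [v for v in x_block.variables if "g/l" in v.lower()] if geochem_log10 else []
    xs = BlockScaler(
        center=True, scale=geochem_scale, log10_vars=log_vars, impute="column_median"
    ).fit_transform(x_block)
    ys = BlockScaler(center=True, scale=False).fit_transform(y_block)
    n_axes = min(2, len(xs.variables), len(ys.variables))
    model = TwoBlockPLS(n_axes=n_axes).fit(xs, ys)
    p1 = model.permutation_test(axis=1, n_perm=n_perm, seed=seed)
    summary = {
        "n_samples": model.n_samples_,
        "n_axes": n_axes,
        "axis_correlations": [float(r) for r in model.score_correlations_],
        "singular_values": [float(d) for d in model.singular_values_],
        "p_value_axis1": float(p1),
        "n_permutations": n_perm,
        "seed": seed,
    }
    return summary, model, xs, ys


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all stages in order; deterministic given the config."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t_start = time.perf_counter()

    def log(stage: str, **kv) -> None:
        fields = " ".join(f"{k}={v}" for k, v in kv.items())
        log_lines.append(
            f"STAGE {stage} t={time.perf_counter() - t_start:.2f}s {fields}"
        )

    log("start", version=PIPELINE_VERSION, seed=config.seed, config=config.digest())
    try:
        if config.simulate is not None:
            sim_cfg = SyntheticConfig(seed=config.seed, **config.simulate)
            ds = generate_coupled_dataset(sim_cfg)
            otu, geo, db, catalog = ds.otu_table, ds.geochem, ds.annotations, ds.catalog
            log("simulate", n_samples=sim_cfg.n_samples, coupling=sim_cfg.coupling)
        else:
            otu = read_otu_table(config.inputs["otu_table"])
            geo = read_geochem_table(config.inputs["geochem"], bdl_policy=config.bdl_policy)
            db = read_annotation_db(config.inputs["annotations"])
            catalog = read_pathway_catalog(config.inputs["pathways"])
            log("load", samples=len(otu.sample_ids), otus=len(otu.otu_ids))
    except ThermopathError as exc:
        raise type(exc)(f"stage input: {exc}") from exc

    report = _div.diversity_report(otu)
    report.write(outdir / "diversity.tsv", seed=config.seed)
    log("diversity", samples=len(report.table))

    cm = completeness_matrix(otu, db, catalog, min_rel_abund=config.min_abundance)
    cm.write(outdir / "completeness.tsv", seed=config.seed)
    cm.write_match_report(outdir / "match_report.tsv")
    unmatched = sum(len(r.unmatched) for r in cm.match_reports.values())
    high = high_completeness_pathways(cm, threshold=config.completeness_threshold)
    high.to_csv(outdir / "high_completeness.tsv", sep="\t")
    log("completeness", pathways=cm.data.shape[1], unmatched_taxa=unmatched)

    geo_raw = geochem_block(geo)
    taxa_raw = community_block(otu, config.community_transform)
    pls_taxa, model_t, *_ = _pls_analysis(
        geo_raw, taxa_raw, config.n_perm, config.seed,
        geochem_log10=config.geochem_log10, geochem_scale=config.geochem_scale,
    )
    log("pls_taxa", r1=round(pls_taxa["axis_correlations"][0], 4),
        p=pls_taxa["p_value_axis1"])

    comp_raw = Block(data=cm.data.copy(), preprocessing="raw")
    pls_comp, model_c, *_ = _pls_analysis(
        geo_raw, comp_raw, config.n_perm, config.seed + 1,
        geochem_log10=config.geochem_log10, geochem_scale=config.geochem_scale,
    )
    log("pls_completeness", r1=round(pls_comp["axis_correlations"][0], 4),
        p=pls_comp["p_value_axis1"])

    for name, model in (("taxa", model_t), ("completeness", model_c)):
        scores = pd.DataFrame(
            {
                "geo_axis1": model.x_scores_[:, 0],
                f"{name}_axis1": model.y_scores_[:, 0],
            },
            index=pd.Index(otu.sample_ids, name="sample"),
        )
        scores.to_csv(outdir / f"pls_{name}_scores.tsv", sep="\t")

    if config.make_plots:
        _plot_axis1(outdir, model_t, model_c, otu.sample_ids)
        log("plots", file="pls_axis1.png")

    summary = {
        "pipeline_version": PIPELINE_VERSION,
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_samples": len(otu.sample_ids),
        "n_otus": len(otu.otu_ids),
        "diversity": {
            s: {
                "richness": int(report.table.loc[s, "richness"]),
                "shannon": round(float(report.table.loc[s, "shannon"]), 1),
                "inverse_simpson": round(float(report.table.loc[s, "inverse_simpson"]), 2),
            }
            for s in report.table.index
        },
        "n_high_completeness_pathways": int(len(high)),
        "high_completeness_pathways": {
            str(p): float(c) for p, c in high["completeness"].items()
        },
        "unmatched_taxa": int(unmatched),
        "pls_taxa_vs_geochem": pls_taxa,
        "pls_completeness_vs_geochem": pls_comp,
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log("done", files=7)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")

    return ReportBundle(
        diversity=report.table,
        completeness=cm.data,
        high_completeness=high,
        pls_taxa=pls_taxa,
        pls_completeness=pls_comp,
        summary=summary,
        outdir=outdir,
    )


def _plot_axis1(outdir: Path, model_t, model_c, sample_ids) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, model, label in (
        (axes[0], model_t, "Community axis 1"),
        (axes[1], model_c, "Completeness axis 1"),
    ):
        ax.scatter(model.x_scores_[:, 0], model.y_scores_[:, 0], c="firebrick", s=25)
        r = model.score_correlations_[0]
        ax.set_xlabel("Geo axis 1")
        ax.set_ylabel(label)
        ax.set_title(f"r = {r:.2f}")
    fig.tight_layout()
    fig.savefig(outdir / "pls_axis1.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Supplement-style reproduction sweep
# ---------------------------------------------------------------------------

MISSING_SUPPLEMENT_MESSAGE = (
    "Reproduction needs two user-supplied TSV files shaped like the study's\n"
    "supplementary tables: a geochemistry table (rows = samples, columns =\n"
    "parameters, tokens 'b.d.l.'/'n.d.' allowed) and a per-sample abundance\n"
    "table in the OTU TSV layout (rows = taxa, columns = samples, values in\n"
    "percent or fractions). Pass them as --geochem and --abundance. The\n"
    "package does not download them."
)

#: declared preprocessing grid: (community transform, geochem variant,
#: missingness policy)
SWEEP_GRID = [
    (ct, gv, mp)
    for ct in ("hellinger", "relative")
    for gv in ("log10_zscore", "zscore")
    for mp in ("column_median", "drop_variable")
]


def diversity_variants(table: OtuTable) -> pd.DataFrame:
    """Diversity under both truncation conventions, with the discrepancy.

    Truncated supplements hide entries below a display cutoff so columns
    sum to < 100%. The ``renormalized`` variant (the package default)
    rescales the shown entries to sum to 1; the ``truncated`` variant
    evaluates -sum p ln p / 1 over sum p^2 on the shown values as-is.
    """
    rows = []
    for s in table.sample_ids:
        p = table.data.loc[s].to_numpy(dtype=float)
        p = p[p > 0]
        h_ren = _div.shannon(p)
        d_ren = _div.inverse_simpson(p)
        h_trunc = float(-(p * np.log(p)).sum()) if p.size else float("nan")
        d_trunc = float(1.0 / (p**2).sum()) if p.size else float("nan")
        rows.append(
            {
                "shannon_renormalized": h_ren,
                "shannon_truncated": h_trunc,
                "shannon_discrepancy": h_ren - h_trunc,
                "inverse_simpson_renormalized": d_ren,
                "inverse_simpson_truncated": d_trunc,
                "inverse_simpson_discrepancy": d_ren - d_trunc,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(table.sample_ids, name="sample"))


def reproduce_supplementary(
    geochem_path,
    abundance_path,
    n_perm: int = 9_999,
    seed: int = 0,
    outdir=None,
    target_r1: float | None = None,
) -> pd.DataFrame:
    """Taxa~geochemistry 2B-PLS under a declared preprocessing grid.

    Reads supplement-shaped TSVs, converts percentage abundances to
    fractions if needed, runs every (community transform, geochem
    scaling, missingness policy) combination of :data:`SWEEP_GRID`, and
    reports axis-1 correlation and permutation p per variant. When
    ``target_r1`` is given, variants whose r1 rounds (2 d.p.) to it are
    flagged.
    """
    geochem_path, abundance_path = Path(geochem_path), Path(abundance_path)
    missing = [str(p) for p in (geochem_path, abundance_path) if not p.exists()]
    if missing:
        raise ConfigurationError(
            f"missing supplement file(s): {missing}\n{MISSING_SUPPLEMENT_MESSAGE}"
        )
    geo = read_geochem_table(geochem_path, bdl_policy="zero")
    otu = read_otu_table(abundance_path)
    if otu.unit == "relative":
        sums = otu.data.sum(axis=1)
        if sums.max() > 2:  # percentages, not fractions
            otu = OtuTable(data=otu.data / 100.0, unit="relative",
                           taxonomy=otu.taxonomy)
    geo = GeochemTable(
        values=geo.values.loc[otu.sample_ids],
        mask=geo.mask.loc[otu.sample_ids],
    )

    rows = []
    for i, (ct, gv, mp) in enumerate(SWEEP_GRID):
        raw = geochem_block(geo, max_missing_frac=0.0 if mp == "drop_variable" else 0.5)
        log_vars = concentration_variables(geo) if gv == "log10_zscore" else []
        xs = BlockScaler(
            center=True, scale=True, log10_vars=log_vars, impute="column_median"
        ).fit_transform(raw)
        ys = BlockScaler(center=True, scale=False).fit_transform(community_block(otu, ct))
        model = TwoBlockPLS(n_axes=1).fit(xs, ys)
        r1 = float(model.score_correlations_[0])
        p1 = model.permutation_test(axis=1, n_perm=n_perm, seed=seed + i)
        row = {
            "community_transform": ct,
            "geochem_variant": gv,
            "missing_policy": mp,
            "r1": r1,
            "p_value": p1,
        }
        if target_r1 is not None:
            row["matches_target"] = round(r1, 2) == round(target_r1, 2)
        rows.append(row)
    sweep = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sweep.to_csv(outdir / "reproduction_sweep.tsv", sep="\t", index=False)
        diversity_variants(otu).to_csv(outdir / "diversity_variants.tsv", sep="\t")
    return sweep
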