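"""Taxonomy-driven functional inference: KO repertoires and pathway completeness.

The statistic: for each sample, collect the taxa detected in its OTU
table, pool their (non-redundant) KEGG Orthology repertoires from an
annotation database, and score each catalog pathway by the fraction of
its required KO set present in the pooled repertoire,

    completeness(sample, pathway) = |KO_sample  intersect  KO_pathway| / |KO_pathway|.

This is a presence/absence statistic — abundance weights taxa only
through the detection threshold. Values are exact rationals with the
pathway KO-set size as denominator, and completeness can only grow as
taxa or KOs are added.

Matching is genus-first by default: 16S OTUs rarely resolve species, so
OTU lineages are collapsed to genus labels before the DB lookup, with
an optional species -> genus -> family fallback chain for databases
keyed at mixed ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SampleLookupError, ValidationError
from .io import (
    AnnotationDB,
    OtuTable,
    Pathway,
    PathwayCatalog,
    _provenance_header,
    to_relative,
)

_FALLBACK_CHAIN = ("species", "genus", "family")


def detected_taxa(
    table: OtuTable,
    sample_id: str,
    min_rel_abund: float = 0.0,
    rank: str = "genus",
) -> list[str]:
    """Taxon labels present in one sample at >= ``min_rel_abund``.

    OTUs are collapsed to their label at ``rank`` (deduplicated,
    insertion order kept); OTUs whose lineage lacks that rank fall back
    to their deepest assigned label, and untaxonomized OTUs to the OTU
    id itself.
    """
    if sample_id not in table.data.index:
        raise SampleLookupError(f"unknown sample id {sample_id!r}")
    if table.unit == "counts":
        table = to_relative(table)
    row = table.data.loc[sample_id]
    labels: list[str] = []
    for otu, abund in row.items():
        if abund < min_rel_abund or abund <= 0:
            continue
        label = otu
        if table.taxonomy and otu in table.taxonomy:
            lin = table.taxonomy[otu]
            label = lin.at_rank(rank) or lin.deepest() or otu
        if label not in labels:
            labels.append(label)
    return labels


@dataclass
class MatchReport:
    """Per-taxon outcome of the annotation-DB lookup for one sample."""

    matched: list[str] = field(default_factory=list)
    fallback: list[tuple[str, str]] = field(default_factory=list)  # (queried, used)
    unmatched: list[str] = field(default_factory=list)

    @property
    def n_queried(self) -> int:
        return len(self.matched) + len(self.fallback) + len(self.unmatched)


def _fallback_labels(label: str, taxonomy_lookup) -> list[str]:
    """Coarser-rank labels to retry, species -> genus -> family."""
    lineage = taxonomy_lookup(label) if taxonomy_lookup else None
    if lineage is None:
        return []
    out = []
    for rank in _FALLBACK_CHAIN:
        alt = lineage.at_rank(rank)
        if alt and alt != label:
            out.append(alt)
    return out


def sample_ko_set(
    taxa: list[str],
    db: AnnotationDB,
    rank_fallback: bool = True,
    taxonomy_lookup=None,
) -> tuple[frozenset[str], MatchReport]:
    """Union of KO sets over matched taxa (the non-redundant repertoire).

    With ``rank_fallback`` a label missing from the DB is retried at
    coarser ranks via ``taxonomy_lookup`` (label -> Lineage, optional).
    Unmatched taxa contribute nothing; the report records every outcome.
    """
    report = MatchReport()
    kos: set[str] = set()
    for taxon in taxa:
        hit = db.get(taxon)
        if hit is not None:
            kos |= hit
            report.matched.append(taxon)
            continue
        used = None
        if rank_fallback:
            for alt in _fallback_labels(taxon, taxonomy_lookup):
                hit = db.get(alt)
                if hit is not None:
                    kos |= hit
                    used = alt
                    break
        if used is not None:
            report.fallback.append((taxon, used))
        else:
            report.unmatched.append(taxon)
    return frozenset(kos), report


def pathway_completeness(kos: frozenset[str], pathway: Pathway) -> float:
    """Fraction of the pathway's KO set present in ``kos``."""
    if not pathway.kos:
        raise ValidationError(f"pathway {pathway.pathway_id!r} has an empty KO set")
    return len(kos & pathway.kos) / len(pathway.kos)


@dataclass
class CompletenessMatrix:
    """Samples x pathways completeness fractions plus per-sample KO counts."""

    data: pd.DataFrame
    ko_set_sizes: pd.Series
    match_reports: dict[str, MatchReport]

    def write(self, path, seed: int | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_provenance_header(seed) + "\n")
            fh.write("\t".join(["sample", *self.data.columns]) + "\n")
            for sample in self.data.index:
                cells = [str(sample)] + [repr(v) for v in self.data.loc[sample]]
                fh.write("\t".join(cells) + "\n")

    def write_match_report(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sample\ttaxon\tstatus\tmatched_as\n")
            for sample, rep in self.match_reports.items():
                for t in rep.matched:
                    fh.write(f"{sample}\t{t}\tmatched\t{t}\n")
                for t, used in rep.fallback:
                    fh.write(f"{sample}\t{t}\tfallback\t{used}\n")
                for t in rep.unmatched:
                    fh.write(f"{sample}\t{t}\tunmatched\t\n")


class KOCompleteness:
    """Transformer from OTU tables to pathway-completeness matrices.

    sklearn-style: parameters at construction, `fit` validates the
    annotation resources, `transform` maps any OTU table with taxonomy
    onto the catalog's pathways. Deterministic: output is independent
    of sample or OTU ordering of the input (up to label order).

    Parameters
    ----------
    db : AnnotationDB
        Taxon label -> KO set.
    catalog : PathwayCatalog
        Pathways with required KO sets.
    min_rel_abund : float
        Detection threshold for a taxon to contribute its repertoire
        (default 0: any nonzero abundance counts as detected).
    rank : str
        Rank at which OTU lineages are collapsed before lookup.
    rank_fallback : bool
        Retry unmatched labels at coarser ranks.
    """

    def __init__(
        self,
        db: AnnotationDB,
        catalog: PathwayCatalog,
        min_rel_abund: float = 0.0,
        rank: str = "genus",
        rank_fallback: bool = True,
    ):
        self.db = db
        self.catalog = catalog
        self.min_rel_abund = min_rel_abund
        self.rank = rank
        self.rank_fallback = rank_fallback

    def get_params(self, deep: bool = True) -> dict:
        return {
            "db": self.db,
            "catalog": self.catalog,
            "min_rel_abund": self.min_rel_abund,
            "rank": self.rank,
            "rank_fallback": self.rank_fallback,
        }

    def set_params(self, **params) -> "KOCompleteness":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: OtuTable | None = None, y=None) -> "KOCompleteness":
        if not (0.0 <= self.min_rel_abund < 1.0):
            raise ValidationError("min_rel_abund must lie in [0, 1)")
        if len(self.catalog) == 0:
            raise ValidationError("pathway catalog is empty")
        self.pathway_ids_ = list(self.catalog.pathway_ids)
        self.n_pathways_ = len(self.catalog)
        return self

    def transform(self, X: OtuTable) -> CompletenessMatrix:
        if not hasattr(self, "pathway_ids_"):
            self.fit()
        table = to_relative(X) if X.unit == "counts" else X
        lookup = (lambda lbl: None)
        if table.taxonomy:
            by_label = {}
            for lin in table.taxonomy.values():
                deep = lin.deepest()
                if deep is not None:
                    by_label.setdefault(deep, lin)
            lookup = by_label.get
        rows = []
        sizes = {}
        reports = {}
        for sample in table.sample_ids:
            taxa = detected_taxa(table, sample, self.min_rel_abund, self.rank)
            kos, report = sample_ko_set(taxa, self.db, self.rank_fallback, lookup)
            rows.append([pathway_completeness(kos, p) for p in self.catalog])
            sizes[sample] = len(kos)
            reports[sample] = report
        data = pd.DataFrame(
            rows,
            index=pd.Index(table.sample_ids, name="sample"),
            columns=self.pathway_ids_,
        )
        return CompletenessMatrix(
            data=data,
            ko_set_sizes=pd.Series(sizes, name="n_kos"),
            match_reports=reports,
        )

    def fit_transform(self, X: OtuTable, y=None) -> CompletenessMatrix:
        return self.fit(X).transform(X)


def completeness_matrix(
    table: OtuTable,
    db: AnnotationDB,
    catalog: PathwayCatalog,
    min_rel_abund: float = 0.0,
    rank: str = "genus",
    rank_fallback: bool = True,
) -> CompletenessMatrix:
    """Functional form of :class:`KOCompleteness`."""
    est = KOCompleteness(db, catalog, min_rel_abund, rank, rank_fallback)
    return est.fit_transform(table)


def high_completeness_pathways(
    matrix: CompletenessMatrix,
    threshold: float = 0.9,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Pathways whose aggregated completeness across samples >= threshold.

    Sorted by aggregated completeness descending, ties broken by
    pathway id; the boundary case (aggregate exactly equal to the
    threshold) is included.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError("threshold must lie in [0, 1]")
    if aggregate == "mean":
        agg = matrix.data.mean(axis=0)
    elif aggregate == "min":
        agg = matrix.data.min(axis=0)
    else:
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    hits = agg[agg >= threshold]
    out = pd.DataFrame({"completeness": hits})
    out.index.name = "pathway_id"
    # primary key: completeness descending; secondary: pathway id ascending
    order = np.lexsort((out.index.to_numpy(), -out["completeness"].to_numpy()))
    return out.iloc[order]
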