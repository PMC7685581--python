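"""Tabular I/O for the pipeline: OTU tables, geochemistry, KO annotations.

In-memory convention: **samples are rows** in every matrix this package
handles. On disk the OTU table follows the common amplicon layout
(one row per OTU, one column per sample, optional trailing ``taxonomy``
column); readers transpose into the samples-in-rows convention and
writers state the orientation in a comment header.

Geochemistry tables carry left-censoring semantics: the tokens
``b.d.l.`` (below detection limit) and ``n.d.`` (no data) are mapped to
numeric values under an explicit policy and tracked in a per-cell mask,
so downstream ordination never silently treats a censored concentration
as a measurement.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    FormatError,
    ValidationError,
)

__version__ = "0.1.0"

#: Greengenes-style rank prefixes, canonical order kingdom -> species.
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_KO_RE = re.compile(r"^K\d{5}$")

#: Cell-status codes for geochemistry tables.
MEASURED = "measured"
BELOW_DETECTION_LIMIT = "below_detection_limit"
MISSING = "missing"

_BDL_TOKENS = frozenset({"b.d.l.", "b.d.l", "bdl", "<dl"})
_ND_TOKENS = frozenset({"n.d.", "n.d", "nd", "na", ""})


def _provenance_header(seed: int | None = None) -> str:
    line = f"# thermopath v{__version__}; matrices samples-in-rows"
    if seed is not None:
        line += f"; seed={seed}"
    return line


# ---------------------------------------------------------------------------
# Lineage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lineage:
    """A ranked Greengenes-dialect taxonomy string.

    ``labels`` maps rank name ('kingdom'..'species') to the bare label
    (no prefix, lowercased); absent/empty ranks are omitted.
    ``similarity`` is the assignment similarity fraction when reported.
    """

    labels: tuple[tuple[str, str], ...]
    similarity: float | None = None

    @classmethod
    def parse(cls, text: str, similarity: float | None = None) -> "Lineage":
        labels = []
        last_rank = -1
        for part in str(text).split(";"):
            part = part.strip()
            if not part:
                continue
            prefix = part[:3].lower()
            if prefix not in RANK_PREFIXES:
                raise FormatError(f"unrecognized rank prefix in lineage field {part!r}")
            idx = RANK_PREFIXES.index(prefix)
            if idx <= last_rank:
                raise FormatError(f"ranks out of canonical order in lineage {text!r}")
            last_rank = idx
            label = part[3:].strip().lower()
            if label:
                labels.append((RANKS[idx], label))
        if similarity is not None and not (0.0 <= similarity <= 1.0):
            raise ValidationError(f"assignment similarity {similarity} outside [0, 1]")
        return cls(labels=tuple(labels), similarity=similarity)

    def at_rank(self, rank: str) -> str | None:
        """Prefixed, normalized label at ``rank`` (e.g. ``'g__rhodococcus'``), or None."""
        for r, label in self.labels:
            if r == rank:
                return RANK_PREFIXES[RANKS.index(r)] + label
        return None

    def deepest(self) -> str | None:
        if not self.labels:
            return None
        r, label = self.labels[-1]
        return RANK_PREFIXES[RANKS.index(r)] + label

    def __str__(self) -> str:  # round-trippable Greengenes form
        out = []
        have = dict(self.labels)
        for rank, prefix in zip(RANKS, RANK_PREFIXES):
            out.append(prefix + have.get(rank, ""))
        return "; ".join(out)


# ---------------------------------------------------------------------------
# OtuTable
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Samples x OTUs abundance matrix with optional taxonomy.

    ``data`` is a DataFrame indexed by sample id with one column per
    OTU. ``unit`` is ``'counts'`` (non-negative integers) or
    ``'relative'`` (row sums <= 1; truncated supplements may sum < 1).
    """

    data: pd.DataFrame
    unit: str
    taxonomy: dict[str, Lineage] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.unit not in ("counts", "relative"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate OTU id {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("OTU table contains missing values")
        if (values < 0).any():
            raise ValidationError("negative abundance in OTU table")
        if self.unit == "relative" and values.size:
            sums = values.sum(axis=1)
            if (sums > 1 + 1e-9).any():
                bad = self.data.index[int(np.argmax(sums > 1 + 1e-9))]
                raise ValidationError(
                    f"relative abundances of sample {bad!r} sum to more than 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def to_relative(table: OtuTable) -> OtuTable:
    """Convert a counts table to per-sample relative abundances.

    Each row is divided by its total so row sums are exactly 1 (within
    1e-12). All-zero samples have no defined composition and raise.
    """
    if table.unit != "counts":
        raise ValidationError("to_relative expects a counts table")
    sums = table.data.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise DegenerateInputError(
            f"sample {zero.index[0]!r} has zero total count; no relative composition"
        )
    return OtuTable(
        data=table.data.div(sums, axis=0),
        unit="relative",
        taxonomy=table.taxonomy,
    )


def filter_min_abundance(table: OtuTable, threshold: float) -> OtuTable:
    """Zero out per-sample entries strictly below ``threshold``.

    Mirrors supplementary-table truncation ("values below 0.05% not
    shown"): entries equal to the threshold survive, rows are NOT
    renormalized afterwards, and OTUs that become zero in every sample
    are dropped.
    """
    if not (0 <= threshold < 1):
        raise ValidationError(f"threshold {threshold} must lie in [0, 1)")
    if table.unit != "relative":
        raise ValidationError("filter_min_abundance expects a relative table")
    data = table.data.where(table.data >= threshold, other=0.0)
    keep = data.columns[(data > 0).any(axis=0)]
    data = data[keep]
    taxonomy = None
    if table.taxonomy is not None:
        taxonomy = {k: v for k, v in table.taxonomy.items() if k in set(keep)}
    return OtuTable(data=data, unit="relative", taxonomy=taxonomy)


def _infer_unit(values: np.ndarray) -> str:
    return "counts" if np.allclose(values, np.round(values), atol=0) else "relative"


def read_otu_table(path, dialect: str = "tsv") -> OtuTable:
    """Read an OTU table from TSV or BIOM-JSON (v1 dense/sparse).

    TSV layout: first column OTU id, one column per sample, optional
    last column ``taxonomy``; '#' lines are comments. Unit is inferred:
    an all-integer matrix is counts, anything else relative.
    """
    if dialect == "biom_json":
        return _read_biom_json(path)
    if dialect != "tsv":
        raise ConfigurationError(f"unknown OTU table dialect {dialect!r}")

    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                # '#OTU...' is the conventional header line, not a comment
                if not rows and line.lstrip().lower().startswith("#otu"):
                    rows.append(line.split("\t"))
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise FormatError(f"{path}: empty OTU table")
    header, body = rows[0], rows[1:]
    width = len(header)
    has_tax = header[-1].strip().lower() == "taxonomy"
    sample_cols = header[1 : width - 1] if has_tax else header[1:]
    if len(set(sample_cols)) != len(sample_cols):
        seen: set[str] = set()
        dup = next(s for s in sample_cols if s in seen or seen.add(s))
        raise FormatError(f"{path}: duplicate sample column {dup!r}")

    otu_ids: list[str] = []
    matrix: list[list[float]] = []
    taxonomy: dict[str, Lineage] = {}
    for i, row in enumerate(body, start=2):
        if len(row) != width:
            raise FormatError(f"{path}: line {i} has {len(row)} fields, expected {width}")
        otu = row[0].strip()
        if otu in otu_ids:
            raise FormatError(f"{path}: duplicate OTU id {otu!r}")
        otu_ids.append(otu)
        cells = row[1 : width - 1] if has_tax else row[1:]
        try:
            vals = [float(c) for c in cells]
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from None
        matrix.append(vals)
        if has_tax and row[-1].strip():
            taxonomy[otu] = Lineage.parse(row[-1])

    values = np.asarray(matrix, dtype=float).T  # -> samples x OTUs
    if (values < 0).any():
        raise ValidationError(f"{path}: negative abundance value")
    data = pd.DataFrame(values, index=list(sample_cols), columns=otu_ids)
    return OtuTable(data=data, unit=_infer_unit(values), taxonomy=taxonomy or None)


def write_otu_table(table: OtuTable, path, seed: int | None = None) -> None:
    """Write the TSV dialect (OTUs in rows, '#' provenance header)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed) + "; file layout OTUs-in-rows\n")
        cols = ["#OTU_ID", *table.sample_ids]
        if table.taxonomy is not None:
            cols.append("taxonomy")
        fh.write("\t".join(cols) + "\n")
        fmt = (lambda v: str(int(v))) if table.unit == "counts" else (
            lambda v: repr(float(v))
        )
        for otu in table.otu_ids:
            row = [otu] + [fmt(v) for v in table.data[otu].to_numpy()]
            if table.taxonomy is not None:
                lin = table.taxonomy.get(otu)
                row.append(str(lin) if lin is not None else "")
            fh.write("\t".join(row) + "\n")


def _read_biom_json(path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        n_obs, n_samp = doc["shape"]
        obs_ids = [r["id"] for r in doc["rows"]]
        samp_ids = [c["id"] for c in doc["columns"]]
        mtype = doc["matrix_type"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: not a BIOM v1 JSON table ({exc})") from None
    values = np.zeros((n_obs, n_samp), dtype=float)
    if mtype == "dense":
        values[:] = np.asarray(doc["data"], dtype=float)
    elif mtype == "sparse":
        for i, j, v in doc["data"]:
            values[int(i), int(j)] = float(v)
    else:
        raise FormatError(f"{path}: unsupported matrix_type {mtype!r}")
    taxonomy: dict[str, Lineage] = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy")
        if tax:
            text = "; ".join(tax) if isinstance(tax, list) else str(tax)
            taxonomy[r["id"]] = Lineage.parse(text)
    data = pd.DataFrame(values.T, index=samp_ids, columns=obs_ids)
    if (values < 0).any():
        raise ValidationError(f"{path}: negative abundance value")
    return OtuTable(data=data, unit=_infer_unit(values), taxonomy=taxonomy or None)


# ---------------------------------------------------------------------------
# Geochemistry
# ---------------------------------------------------------------------------

@dataclass
class GeochemTable:
    """Samples x physicochemical parameters with censoring mask.

    ``values`` and ``mask`` share shape and labels; mask cells are one
    of ``measured`` / ``below_detection_limit`` / ``missing``. Missing
    cells hold NaN. Parameter names may embed a unit, e.g. ``"Na (g/l)"``.
    """

    values: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape or list(self.values.columns) != list(
            self.mask.columns
        ):
            raise ValidationError("geochem values and mask shapes differ")
        for col in self.values.columns:
            if col.strip().lower().startswith("ph"):
                vals = self.values[col].dropna()
                if ((vals < 0) | (vals > 14)).any():
                    raise ValidationError(f"pH value outside [0, 14] in column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def parameters(self) -> list[str]:
        return list(self.values.columns)


def read_geochem_table(
    path,
    bdl_policy: str = "zero",
    dl_map: dict[str, float] | None = None,
    bdl_tokens: frozenset[str] = _BDL_TOKENS,
    nd_tokens: frozenset[str] = _ND_TOKENS,
) -> GeochemTable:
    """Read a geochemistry TSV (rows = samples, columns = parameters).

    ``b.d.l.`` cells become 0 (policy ``zero``), half the detection
    limit (policy ``half_dl``, requires ``dl_map``) or NaN (policy
    ``na``); the mask records ``below_detection_limit`` either way.
    ``n.d.`` cells are always NaN with mask ``missing``.
    """
    if bdl_policy not in ("zero", "half_dl", "na"):
        raise ConfigurationError(f"unknown b.d.l. policy {bdl_policy!r}")
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str, index_col=0)
    values = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns, dtype=float)
    mask = pd.DataFrame(MEASURED, index=values.index, columns=raw.columns)
    for col in raw.columns:
        for sample, cell in raw[col].items():
            token = ("" if cell is None or (isinstance(cell, float) and math.isnan(cell))
                     else str(cell).strip().lower())
            if token in nd_tokens:
                values.loc[sample, col] = np.nan
                mask.loc[sample, col] = MISSING
            elif token in bdl_tokens:
                mask.loc[sample, col] = BELOW_DETECTION_LIMIT
                if bdl_policy == "zero":
                    values.loc[sample, col] = 0.0
                elif bdl_policy == "na":
                    values.loc[sample, col] = np.nan
                else:
                    if dl_map is None or col not in dl_map:
                        raise ConfigurationError(
                            f"half_dl policy needs a detection limit for {col!r}"
                        )
                    values.loc[sample, col] = dl_map[col] / 2.0
            else:
                try:
                    values.loc[sample, col] = float(token)
                except ValueError:
                    raise FormatError(
                        f"{path}: unparsable cell {cell!r} at sample {sample!r}, "
                        f"parameter {col!r}"
                    ) from None
    return GeochemTable(values=values, mask=mask)


def write_geochem_table(table: GeochemTable, path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed) + "\n")
        fh.write("\t".join(["sample", *table.parameters]) + "\n")
        for sample in table.sample_ids:
            cells = [str(sample)]
            for col in table.parameters:
                status = table.mask.loc[sample, col]
                if status == MISSING:
                    cells.append("n.d.")
                elif status == BELOW_DETECTION_LIMIT:
                    cells.append("b.d.l.")
                else:
                    cells.append(repr(float(table.values.loc[sample, col])))
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Annotation DB and pathway catalog
# ---------------------------------------------------------------------------

def _normalize_taxon(label: str) -> str:
    return label.strip().lower()


def _parse_ko_list(text: str, where: str) -> frozenset[str]:
    kos = []
    for tok in text.split(","):
        tok = tok.strip()
        if not tok:
            continue
        if not _KO_RE.match(tok):
            raise FormatError(f"{where}: {tok!r} is not a KO identifier (K + 5 digits)")
        kos.append(tok)
    return frozenset(kos)


@dataclass
class AnnotationDB:
    """Map taxon label -> non-redundant KO set.

    Labels are matched exactly after lowercasing; rank prefixes
    (``g__`` etc.) are kept so a genus label never collides with a
    species label.
    """

    kos_by_taxon: dict[str, frozenset[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for taxon, kos in self.kos_by_taxon.items():
            if not kos:
                raise ValidationError(f"taxon {taxon!r} has an empty KO set")

    def get(self, label: str) -> frozenset[str] | None:
        return self.kos_by_taxon.get(_normalize_taxon(label))

    def __len__(self) -> int:
        return len(self.kos_by_taxon)


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    kos: frozenset[str]


@dataclass
class PathwayCatalog:
    """Ordered list of pathways, each a required KO set (study used 146)."""

    pathways: tuple[Pathway, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.pathways:
            if p.pathway_id in seen:
                raise ValidationError(f"duplicate pathway id {p.pathway_id!r}")
            seen.add(p.pathway_id)
            if not p.kos:
                raise ValidationError(f"pathway {p.pathway_id!r} has zero KOs")

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)


def read_annotation_db(path) -> AnnotationDB:
    """Read ``taxon<TAB>K00001,K00002,...`` lines; KO lists are deduplicated."""
    kos_by_taxon: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {i}: expected 2 tab-separated fields")
            taxon = _normalize_taxon(parts[0])
            if taxon in kos_by_taxon:
                raise FormatError(f"{path}: line {i}: duplicate taxon {parts[0]!r}")
            kos = _parse_ko_list(parts[1], f"{path}: line {i}")
            if not kos:
                raise ValidationError(f"{path}: line {i}: taxon with no KOs")
            kos_by_taxon[taxon] = kos
    return AnnotationDB(kos_by_taxon=kos_by_taxon, provenance=str(path))


def write_annotation_db(db: AnnotationDB, path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed) + "\n")
        for taxon in db.kos_by_taxon:
            fh.write(f"{taxon}\t{','.join(sorted(db.kos_by_taxon[taxon]))}\n")


def read_pathway_catalog(path) -> PathwayCatalog:
    """Read ``pathway_id<TAB>name<TAB>K00001,...`` lines."""
    pathways: list[Pathway] = []
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}: line {i}: expected 3 tab-separated fields")
            kos = _parse_ko_list(parts[2], f"{path}: line {i}")
            if not kos:
                raise ValidationError(f"{path}: line {i}: pathway with zero KOs")
            pathways.append(Pathway(parts[0].strip(), parts[1].strip(), kos))
    return PathwayCatalog(pathways=tuple(pathways))


def write_pathway_catalog(catalog: PathwayCatalog, path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed) + "\n")
        for p in catalog:
            fh.write(f"{p.pathway_id}\t{p.name}\t{','.join(sorted(p.kos))}\n")


# ---------------------------------------------------------------------------
# ICP-MS detection limit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionLimitInputs:
    """Inputs to the ICP-MS detection-limit calculation.

    sigma: SD of the blank (control water) signal, counts.
    std_conc: concentration of the calibration standard, ug/l.
    S: standard signal, counts.  B: blank signal, counts.
    """

    sigma: float
    std_conc: float
    S: float
    B: float


def detection_limit(inp: DetectionLimitInputs) -> float:
    """DL = 3*sigma*std_conc / (S - B), in the standard's concentration unit.

    The denominator is the instrument sensitivity (net counts per unit
    concentration); a standard signal at or below the blank means no
    sensitivity and is a domain error.
    """
    if inp.sigma < 0:
        raise ValidationError("blank-signal SD must be non-negative")
    if inp.std_conc <= 0:
        raise ValidationError("standard concentration must be positive")
    if inp.S <= inp.B:
        raise ValidationError(
            "standard signal must exceed blank signal (no valid sensitivity)"
        )
    return (3.0 * inp.sigma * inp.std_conc) / (inp.S - inp.B)
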