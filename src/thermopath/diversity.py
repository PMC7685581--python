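"""Alpha diversity of OTU tables: richness, Shannon entropy, inverse Simpson.

Shannon is reported in nats (natural log): printed index values of at
most ~4.1 for communities of up to ~206 OTUs are consistent with ln
(ln 206 ~ 5.3) and not with log2. Input vectors are renormalized before
computing either index so truncated abundance tables (row sums < 1,
as in supplements that hide entries below 0.05%) are handled; both
indices are therefore invariant to positive rescaling of the vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .io import OtuTable, _provenance_header


def _clean(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("abundance vector must be 1-D")
    if (p < 0).any():
        raise DegenerateInputError("negative abundance in vector")
    total = p.sum()
    if p.size == 0 or total <= 0:
        raise DegenerateInputError("empty or all-zero abundance vector")
    return p / total


def shannon(p) -> float:
    """Shannon entropy H = -sum p_i ln p_i over nonzero entries, in nats."""
    q = _clean(p)
    q = q[q > 0]
    return float(-(q * np.log(q)).sum())


def inverse_simpson(p) -> float:
    """Inverse Simpson D = 1 / sum p_i^2: effective number of equal OTUs."""
    q = _clean(p)
    return float(1.0 / (q**2).sum())


def richness(p, presence_threshold: float = 0.0) -> int:
    """Number of entries strictly above ``presence_threshold``."""
    if presence_threshold < 0:
        raise ValueError("presence threshold must be >= 0")
    p = np.asarray(p, dtype=float)
    return int((p > presence_threshold).sum())


@dataclass
class DiversityReport:
    """Per-sample richness / Shannon / inverse Simpson.

    ``table`` holds full-precision values; rounding happens only when
    writing (Shannon to 1 decimal, inverse Simpson to 2, matching the
    print precision of published diversity tables).
    """

    table: pd.DataFrame

    def rounded(self) -> pd.DataFrame:
        out = self.table.copy()
        out["shannon"] = out["shannon"].round(1)
        out["inverse_simpson"] = out["inverse_simpson"].round(2)
        return out

    def write(self, path, seed: int | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_provenance_header(seed) + "\n")
            fh.write("sample\trichness\tshannon\tinverse_simpson\n")
            for sample, row in self.rounded().iterrows():
                fh.write(
                    f"{sample}\t{int(row['richness'])}\t"
                    f"{row['shannon']:.1f}\t{row['inverse_simpson']:.2f}\n"
                )


def diversity_report(table: OtuTable) -> DiversityReport:
    """Compute all three indices for every sample of an OTU table.

    Counts tables are used as-is (the indices renormalize internally).
    Degenerate (all-zero) samples raise with the sample id.
    """
    if table.data.shape[0] == 0:
        raise DegenerateInputError("OTU table has no samples")
    records = []
    for sample in table.sample_ids:
        row = table.data.loc[sample].to_numpy(dtype=float)
        try:
            records.append(
                {
                    "richness": richness(row),
                    "shannon": shannon(row),
                    "inverse_simpson": inverse_simpson(row),
                }
            )
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"sample {sample!r}: {exc}") from None
    return DiversityReport(
        table=pd.DataFrame(records, index=pd.Index(table.sample_ids, name="sample"))
    )
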