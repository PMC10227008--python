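"""Readers and writers for the pipeline's external formats.

All genomic coordinates inside the package are 0-based half-open (BED
convention); conversions happen only at the I/O boundary.  Bismark coverage
files are treated as 1-based inclusive on input.

Doses are canonicalized through :data:`DOSE_LEVELS` so that 0.033 read from a
text file always maps to the same float key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical dose levels in mg/kg-day, keyed by their exact decimal strings
DOSE_LEVELS = {"0": 0.0, "0.033": 0.033, "0.2": 0.2, "2": 2.0}

GENERATIONS = ("F1", "F2", "F3")
SEXES = ("M", "F")

#: default RepeatMasker family -> class map for the murine repeat groups of
#: interest; unknown families fall back to "other"
DEFAULT_FAMILY_CLASS_MAP = {
    "IAPEz-int": "IAP",
    "IAPEy-int": "IAP",
    "IAPLTR1_Mm": "IAP",
    "IAPLTR2_Mm": "IAP",
    "L1Md_A": "LINE-1",
    "L1Md_T": "LINE-1",
    "L1Md_F": "LINE-1",
    "L1Md_Gf": "LINE-1",
    "L1_Mus1": "LINE-1",
    "L1_Mus2": "LINE-1",
    "L1_Mus3": "LINE-1",
    "B1_Mus1": "B1-B4",
    "B1_Mus2": "B1-B4",
    "B1_Mm": "B1-B4",
    "B2_Mm1a": "B1-B4",
    "B2_Mm1t": "B1-B4",
    "B2_Mm2": "B1-B4",
    "B3": "B1-B4",
    "B3A": "B1-B4",
    "B4": "B1-B4",
    "B4A": "B1-B4",
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def canonical_dose(value) -> float:
    """Map a dose given as string or number to its canonical float level."""
    s = str(value).strip()
    if s in DOSE_LEVELS:
        return DOSE_LEVELS[s]
    try:
        x = float(s)
    except ValueError as exc:
        raise FormatError(f"unparseable dose {value!r}") from exc
    for level in DOSE_LEVELS.values():
        if abs(x - level) < 1e-9:
            return level
    raise FormatError(f"dose {value!r} is not one of {sorted(DOSE_LEVELS)}")


@dataclass
class CountMatrix:
    """Gene-by-sample integer expression counts plus per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id;
        non-negative integers.
    metadata
        DataFrame indexed by sample id with columns ``generation``
        (F1/F2/F3), ``sex`` (M/F) and ``dose`` (mg/kg-day).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicated gene ids: {dups[:5]}")
        if self.counts.columns.duplicated().any():
            raise FormatError("duplicated sample ids in count matrix")
        if self.metadata.index.duplicated().any():
            raise FormatError("duplicated sample ids in metadata")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise FormatError(f"samples missing from metadata: {sorted(missing)[:5]}")
        extra = set(self.metadata.index) - set(self.counts.columns)
        if extra:
            raise FormatError(f"metadata samples absent from counts: {sorted(extra)[:5]}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.floor(vals)):
                bad = np.argwhere(~np.isfinite(vals) | (vals != np.floor(vals)))
                g, s = bad[0]
                raise FormatError(
                    f"non-integer count at gene {self.counts.index[g]!r}, "
                    f"sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)
            g, s = bad[0]
            raise FormatError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        for col in ("generation", "sex", "dose"):
            if col not in self.metadata.columns:
                raise FormatError(f"metadata missing column {col!r}")
        bad_gen = set(self.metadata["generation"]) - set(GENERATIONS)
        if bad_gen:
            raise FormatError(f"unknown generation levels: {sorted(bad_gen)}")
        bad_sex = set(self.metadata["sex"]) - set(SEXES)
        if bad_sex:
            raise FormatError(f"unknown sex levels: {sorted(bad_sex)}")
        self.metadata = self.metadata.copy()
        self.metadata["dose"] = [canonical_dose(d) for d in self.metadata["dose"]]
        # align metadata row order with count columns
        self.metadata = self.metadata.loc[list(self.counts.columns)]
        # canonical axis names so round trips through TSV compare equal
        self.counts = self.counts.rename_axis(index="gene_id", columns=None)
        self.metadata.index.name = "sample_id"

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(self.counts[sample_ids], self.metadata.loc[sample_ids])

    def select(self, generation=None, sex=None, dose=None) -> "CountMatrix":
        """Subset by metadata levels (each filter optional; scalars or lists)."""
        mask = pd.Series(True, index=self.metadata.index)
        for col, val in (("generation", generation), ("sex", sex), ("dose", dose)):
            if val is None:
                continue
            vals = [val] if np.isscalar(val) or isinstance(val, str) else list(val)
            if col == "dose":
                vals = [canonical_dose(v) for v in vals]
            mask &= self.metadata[col].isin(vals)
        return self.subset_samples(self.metadata.index[mask])


def _header_comment(seed=None) -> str:
    from . import __version__

    tail = f" seed={seed}" if seed is not None else ""
    return f"# pgcmasc v{__version__}{tail}\n"


def write_counts(cm: CountMatrix, counts_path, metadata_path, seed=None) -> None:
    """Write a CountMatrix as a counts TSV (genes x samples) and metadata TSV."""
    with open(counts_path, "w") as fh:
        fh.write(_header_comment(seed))
        cm.counts.rename_axis("gene_id").to_csv(fh, sep="\t")
    with open(metadata_path, "w") as fh:
        fh.write(_header_comment(seed))
        cm.metadata.rename_axis("sample_id").to_csv(fh, sep="\t")


def read_counts(counts_path, metadata_path) -> CountMatrix:
    """Read and validate a counts TSV plus its metadata TSV.

    Raises
    ------
    FormatError
        On duplicated ids, negative or non-integer entries, or a mismatch
        between count columns and metadata rows.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    # numeric coercion errors surface as object dtype
    for col in counts.columns:
        if counts[col].dtype == object:
            raise FormatError(f"non-numeric entries in sample column {col!r}")
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, comment="#")
    meta.index = meta.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountMatrix(counts, meta)


# ---------------------------------------------------------------------------
# Bismark coverage (CpG methylation calls)
# ---------------------------------------------------------------------------

def read_meth_coverage(path, pct_tol: float = 0.5) -> pd.DataFrame:
    """Read a Bismark coverage file into 0-based methylation-call records.

    Input columns (1-based inclusive coordinates):
    chrom, start, end, methylation %, count_methylated, count_unmethylated.

    Returns a DataFrame with columns ``chrom``, ``pos`` (0-based),
    ``meth``, ``unmeth``.  The percentage field is recomputed from the counts
    and must agree within ``pct_tol`` percentage points.  Records with zero
    total reads are dropped with a warning.
    """
    rows = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            chrom, start_s, _end_s, pct_s, meth_s, unmeth_s = parts
            try:
                start = int(start_s)
                pct = float(pct_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed numeric field") from exc
            if meth < 0 or unmeth < 0 or start < 1:
                raise FormatError(f"{path}:{lineno}: negative count or position")
            total = meth + unmeth
            if total == 0:
                dropped += 1
                continue
            recomputed = 100.0 * meth / total
            if abs(recomputed - pct) > pct_tol:
                raise FormatError(
                    f"{path}:{lineno}: methylation % {pct} inconsistent with "
                    f"counts {meth}/{unmeth} ({recomputed:.2f}%)"
                )
            rows.append((chrom, start - 1, meth, unmeth))
    if dropped:
        logger.warning("%s: dropped %d zero-coverage records", path, dropped)
    return pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])


def write_meth_coverage(calls: pd.DataFrame, path, seed=None) -> None:
    """Write 0-based call records back to Bismark coverage format (1-based)."""
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        for chrom, pos, meth, unmeth in calls[["chrom", "pos", "meth", "unmeth"]].itertuples(
            index=False
        ):
            total = meth + unmeth
            pct = 100.0 * meth / total
            fh.write(f"{chrom}\t{pos + 1}\t{pos + 1}\t{pct:g}\t{meth}\t{unmeth}\n")


# ---------------------------------------------------------------------------
# Repeat annotations (BED6-like)
# ---------------------------------------------------------------------------

def read_repeat_annotation(path, family_class_map=None) -> pd.DataFrame:
    """Read a BED6-like repeat annotation TSV.

    Columns: chrom, start, end (0-based half-open), family, class, strand.
    A missing or empty class field is filled from ``family_class_map``
    (default :data:`DEFAULT_FAMILY_CLASS_MAP`), falling back to ``"other"``.
    """
    if family_class_map is None:
        family_class_map = DEFAULT_FAMILY_CLASS_MAP
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 fields")
            chrom, start_s, end_s, family = parts[:4]
            rep_class = parts[4] if len(parts) > 4 and parts[4] not in (".", "") else None
            strand = parts[5] if len(parts) > 5 else "."
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed coordinates") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            if rep_class is None:
                rep_class = family_class_map.get(family, "other")
            rows.append((chrom, start, end, family, rep_class, strand))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "family", "rep_class", "strand"]
    )


def write_repeat_annotation(ann: pd.DataFrame, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        cols = ["chrom", "start", "end", "family", "rep_class", "strand"]
        for row in ann[cols].itertuples(index=False):
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_gene_set(path) -> set:
    """Read a gene-set file: one gene id per line, '#' comments allowed."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_gene_set(genes, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        for g in sorted(genes):
            fh.write(f"{g}\n")
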