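"""OTU count tables and per-sample species abundance distributions.

The universal input of every analysis in this package is a community matrix:
rows are OTUs (operational taxonomic units, a species-like unit), columns are
community samples, entries are non-negative integer read counts.  Tables are
exchanged as plain tab-separated text with one header row of sample ids and a
leading column of OTU ids, the dialect produced by most OTU-picking pipelines
(a leading ``#OTU ID`` header cell, the BIOM TSV export convention, is
tolerated).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("pyuntb")
if not logger.handlers:  # default: INFO to stderr, overridable by applications
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class FormatError(ValueError):
    """Raised when an input table violates the count-table contract."""


class EmptyResultError(ValueError):
    """Raised when a filter removes every sample."""


@dataclass
class CommunityMatrix:
    """OTU x sample table of non-negative integer counts with unique labels."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    dropped_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts).astype(np.int64)
            if not np.allclose(self.counts, as_int, rtol=0, atol=0):
                raise FormatError("counts must be integral")
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at OTU {self.otu_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        for name, labels in (("otu", self.otu_ids), ("sample", self.sample_ids)):
            if len(set(labels)) != len(labels):
                dup = sorted({x for x in labels if labels.count(x) > 1})
                raise FormatError(f"duplicate {name} ids: {dup}")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sizes(self) -> np.ndarray:
        """Column totals J (reads per sample)."""
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityMatrix):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SADSample:
    """One community's species abundance distribution.

    Zero-count species are dropped: every likelihood in this package
    conditions on the species actually observed in the sample.
    """

    abundances: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=np.int64)
        if self.abundances.ndim != 1 or len(self.abundances) == 0:
            raise ValueError("abundances must be a non-empty 1-d vector")
        if (self.abundances < 1).any():
            raise ValueError("abundances must be >= 1 (zero-count species dropped)")

    @property
    def J(self) -> int:
        """Total number of individuals (reads)."""
        return int(self.abundances.sum())

    @property
    def S(self) -> int:
        """Number of observed species."""
        return int(len(self.abundances))


def read_otu_table(path, orientation: str = "otus_as_rows") -> CommunityMatrix:
    """Read a tab-separated OTU table into canonical OTU x sample orientation.

    Parameters
    ----------
    path : str or pathlib.Path
        TSV file with one header row and one leading label column.
    orientation : {"otus_as_rows", "samples_as_rows"}
        Layout of the file; ``samples_as_rows`` tables are transposed.
    """
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                     comment=None, skip_blank_lines=True)
    if df.index.name and df.index.name.lstrip("#").strip().lower() in (
            "otu id", "otu_id", "otuid"):
        pass  # BIOM TSV export dialect; nothing else to do
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    non_numeric = numeric.isna().to_numpy()
    if non_numeric.any():
        i, j = np.argwhere(non_numeric)[0]
        raise FormatError(
            f"non-numeric cell at row {row_ids[i]!r}, column {col_ids[j]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    bad = ~np.isfinite(values) | (values != np.floor(values))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"non-integer cell at row {row_ids[i]!r}, column {col_ids[j]!r}"
        )
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative count at row {row_ids[i]!r}, column {col_ids[j]!r}"
        )
    counts = values.astype(np.int64)
    if orientation == "samples_as_rows":
        return CommunityMatrix(col_ids, row_ids, counts.T)
    return CommunityMatrix(row_ids, col_ids, counts)


def write_otu_table(cm: CommunityMatrix, path) -> None:
    """Write a community matrix in the same TSV dialect read_otu_table reads."""
    df = cm.to_dataframe()
    df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t")


def filter_min_reads(cm: CommunityMatrix, min_reads: int = 100) -> CommunityMatrix:
    """Drop samples with fewer than ``min_reads`` total reads.

    Shallow samples carry too few individuals for a species-abundance test;
    the default threshold of 100 reads is applied before any neutrality test.
    OTUs whose row total becomes zero are removed; dropped sample ids are
    recorded on the result and logged.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    totals = cm.sample_sizes()
    keep = totals >= min_reads
    dropped = [s for s, k in zip(cm.sample_ids, keep) if not k]
    if not keep.any():
        raise EmptyResultError(
            f"all {cm.n_samples} samples have < {min_reads} reads"
        )
    if dropped:
        logger.info("filter_min_reads: dropped %d sample(s): %s",
                    len(dropped), ", ".join(dropped))
    counts = cm.counts[:, keep]
    row_keep = counts.sum(axis=1) > 0
    return CommunityMatrix(
        [o for o, k in zip(cm.otu_ids, row_keep) if k],
        [s for s, k in zip(cm.sample_ids, keep) if k],
        counts[row_keep],
        dropped_samples=list(cm.dropped_samples) + dropped,
    )


def to_relative_abundance(cm: CommunityMatrix) -> np.ndarray:
    """Per-sample relative abundances; each column sums to 1."""
    totals = cm.sample_sizes()
    if (totals == 0).any():
        j = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(f"sample {cm.sample_ids[j]!r} has zero total reads")
    return cm.counts / totals[np.newaxis, :]


def extract_sad(cm: CommunityMatrix, sample_id: str) -> SADSample:
    """Extract one sample's SAD (zero-count species removed)."""
    try:
        j = cm.sample_ids.index(sample_id)
    except ValueError:
        raise KeyError(f"unknown sample id {sample_id!r}") from None
    col = cm.counts[:, j]
    return SADSample(col[col > 0], sample_id=sample_id)
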