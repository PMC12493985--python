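"""In-memory containers shared across the pipeline.

The canonical community container is :class:`OtuTable`, a thin wrapper around
a ``pandas.DataFrame`` holding non-negative integer counts with sites as rows
and OTUs as columns.  Gene catalogs and single-copy-marker coverage tables are
plain DataFrames wrapped with just enough validation to catch malformed input
early; no science lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGIONS = ("YRE", "ECS", "other")

GENE_LABELS = ("rrna16S", "ribosomal_protein", "transposase", "other")

#: Number of universal single-copy marker genes expected per sample.
N_UNIVERSAL_MARKERS = 35


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass(frozen=True)
class SiteRecord:
    """A sampling site with coordinates and a region label."""

    site_id: str
    region: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude {self.longitude} outside [-180, 180]")


class OtuTable:
    """Site x OTU count matrix.

    Parameters
    ----------
    counts
        DataFrame with site ids as the index and OTU ids as columns, holding
        non-negative integers.  Every site (row) must have a positive total.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate site ids: {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dupes}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("OTU table contains non-numeric entries")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("OTU table contains missing values")
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at site {counts.index[bad[0]]!r}, OTU {counts.columns[bad[1]]!r}"
            )
        if not np.allclose(values, np.round(values.astype(float))):
            raise ValidationError("OTU table contains non-integer counts")
        row_totals = values.sum(axis=1)
        if (row_totals <= 0).any():
            empty = counts.index[row_totals <= 0].tolist()
            raise ValidationError(f"sites with zero total counts: {empty}")
        self.counts = counts.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)

    # -- basic views -------------------------------------------------------

    @property
    def sites(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otus(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def site_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by each site's total (rows sum to 1)."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def drop_empty_otus(self) -> "OtuTable":
        """Return a copy without OTUs whose total count is zero."""
        keep = self.counts.sum(axis=0) > 0
        return OtuTable(self.counts.loc[:, keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"OtuTable({self.n_sites} sites x {self.n_otus} OTUs)"


@dataclass
class GeneCatalog:
    """Annotated gene records for one metagenome sample.

    ``genes`` holds one row per gene with columns ``gene_id``, ``label``
    (one of :data:`GENE_LABELS`), ``length`` (bp) and ``mean_coverage``
    (reads-per-base depth).  ``cds`` optionally maps gene ids to coding
    nucleotide sequences (length divisible by 3).
    """

    sample_id: str
    genes: pd.DataFrame
    cds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"gene_id", "label", "length", "mean_coverage"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValidationError(f"gene catalog missing columns: {sorted(missing)}")
        if self.genes["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene ids in catalog")
        bad_labels = set(self.genes["label"]) - set(GENE_LABELS)
        if bad_labels:
            raise ValidationError(f"unknown gene labels: {sorted(bad_labels)}")
        if (self.genes["length"] <= 0).any():
            raise ValidationError("gene lengths must be positive")
        if (self.genes["mean_coverage"] < 0).any():
            raise ValidationError("gene coverages must be non-negative")
        known = set(self.genes["gene_id"])
        for gene_id, seq in self.cds.items():
            if gene_id not in known:
                raise ValidationError(f"CDS for unknown gene {gene_id!r}")
            if len(seq) % 3 != 0:
                raise ValidationError(f"CDS length for {gene_id!r} not divisible by 3")

    def with_label(self, label: str) -> pd.DataFrame:
        return self.genes[self.genes["label"] == label]


@dataclass
class MarkerCoverage:
    """Per-sample mean coverage of universal single-copy marker genes."""

    sample_id: str
    coverage: pd.Series  # index: marker_id, values: mean coverage depth
    expected_markers: int = N_UNIVERSAL_MARKERS

    def __post_init__(self) -> None:
        if (self.coverage < 0).any():
            raise ValidationError("marker coverages must be non-negative")
        if self.coverage.index.has_duplicates:
            raise ValidationError("duplicate marker ids")

    @property
    def missing_markers(self) -> int:
        """Markers short of the declared universal set size."""
        return max(self.expected_markers - len(self.coverage), 0)
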