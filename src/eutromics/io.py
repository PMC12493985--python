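"""Reading and writing the tabular and sequence formats the pipeline touches.

Tables travel as TSV, trees as newick (via scikit-bio), coding sequences as
FASTA (via biopython), and run manifests / fitted parameters as JSON.  Output
tables carry a leading ``#`` comment line with the tool version and the RNG
seed so stochastic null-model results can be reproduced; readers skip ``#``
lines.  Missing chemistry values are empty cells and stay ``NaN`` downstream
("index not computable") -- zero is a valid concentration and is never used
as a fill value.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from . import __version__
from .containers import GeneCatalog, MarkerCoverage, OtuTable, ValidationError

ORIENTATIONS = ("sites_as_rows", "otus_as_rows")

WATER_COLUMNS = [
    "site_id", "chl_a_ug_l", "do_mg_l", "do_saturation_pct",
    "ammonia_umol_l", "nitrite_umol_l", "nitrate_umol_l",
    "phosphate_umol_l", "silicate_umol_l", "salinity", "temperature_c",
]

SEDIMENT_COLUMNS = ["site_id", "toc_pct", "tn_pct"]


def _version_comment(seed: int | None = None) -> str:
    tail = "" if seed is None else f" seed={seed}"
    return f"# eutromics v{__version__}{tail}\n"


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, orientation: str = "otus_as_rows") -> OtuTable:
    """Read a TSV count table; ``orientation`` names what the rows are.

    The canonical in-memory orientation is site x OTU; ``otus_as_rows`` input
    is transposed on read.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValidationError(
                f"non-numeric count at row {row!r}, column {col!r} in {path}"
            )
    if orientation == "otus_as_rows":
        df = df.T
    return OtuTable(df)


def write_otu_table(
    table: OtuTable,
    path: str | Path,
    orientation: str = "otus_as_rows",
    seed: int | None = None,
) -> None:
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {orientation!r}")
    df = table.counts if orientation == "sites_as_rows" else table.counts.T
    df.index.name = "otu_id" if orientation == "otus_as_rows" else "site_id"
    with open(path, "w") as fh:
        fh.write(_version_comment(seed))
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(path: str | Path) -> TreeNode:
    """Read a newick tree; every non-root branch must carry a length.

    Branch lengths are required because the nearest-taxon phylogenetic
    turnover statistics are defined on patristic distances.
    """
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(
                f"tree in {path} lacks branch lengths (node {node.name!r}); "
                "patristic distances require them"
            )
        if node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def check_tree_tips(tree: TreeNode, table: OtuTable) -> dict[str, set[str]]:
    """Report OTU/tip set mismatches instead of silently dropping taxa.

    Returns a dict with ``missing_from_tree`` (OTUs without a tip) and
    ``extra_tips`` (tips without an OTU).
    """
    tips = {t.name for t in tree.tips()}
    otus = set(table.otus)
    return {
        "missing_from_tree": otus - tips,
        "extra_tips": tips - otus,
    }


# ---------------------------------------------------------------------------
# Chemistry tables
# ---------------------------------------------------------------------------

def read_water_chemistry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "site_id" not in df.columns:
        raise ValidationError(f"water chemistry table {path} lacks a site_id column")
    for col in df.columns:
        if col == "site_id":
            continue
        df[col] = pd.to_numeric(df[col], errors="raise")
        if col != "temperature_c" and (df[col].dropna() < 0).any():
            raise ValidationError(f"negative values in column {col!r} of {path}")
    return df


def read_sediment_chemistry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SEDIMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"sediment chemistry table {path} missing columns {sorted(missing)}")
    for col in ("toc_pct", "tn_pct"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        ok = df[col].dropna().between(0, 100)
        if not ok.all():
            raise ValidationError(f"column {col!r} outside [0, 100] % in {path}")
    return df


# ---------------------------------------------------------------------------
# Gene catalogs and marker coverage
# ---------------------------------------------------------------------------

def read_gene_catalog(
    tsv_path: str | Path,
    fasta_path: str | Path | None = None,
    sample_id: str | None = None,
) -> GeneCatalog:
    """Read a per-sample annotated gene catalog (TSV + optional CDS FASTA)."""
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    if sample_id is None:
        sample_id = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns else Path(tsv_path).stem
    cds: dict[str, str] = {}
    if fasta_path is not None:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            cds[rec.id] = str(rec.seq).upper()
    return GeneCatalog(sample_id=sample_id, genes=df, cds=cds)


def write_gene_catalog(
    catalog: GeneCatalog, tsv_path: str | Path, fasta_path: str | Path | None = None
) -> None:
    df = catalog.genes.copy()
    df.insert(0, "sample_id", catalog.sample_id)
    with open(tsv_path, "w") as fh:
        fh.write(_version_comment())
        df.to_csv(fh, sep="\t", index=False)
    if fasta_path is not None:
        records = [
            SeqRecord(Seq(seq), id=gene_id, description="")
            for gene_id, seq in catalog.cds.items()
        ]
        SeqIO.write(records, str(fasta_path), "fasta")


def read_marker_coverage(path: str | Path) -> list[MarkerCoverage]:
    """Read a marker-coverage TSV (columns sample_id, marker_id, mean_coverage)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "marker_id", "mean_coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"marker coverage table {path} missing columns {sorted(missing)}")
    out = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        series = pd.Series(
            grp["mean_coverage"].to_numpy(float), index=grp["marker_id"].astype(str)
        )
        out.append(MarkerCoverage(sample_id=str(sample_id), coverage=series))
    return out


def write_marker_coverage(markers: Iterable[MarkerCoverage], path: str | Path) -> None:
    frames = []
    for mc in markers:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": mc.sample_id,
                    "marker_id": mc.coverage.index,
                    "mean_coverage": mc.coverage.to_numpy(),
                }
            )
        )
    with open(path, "w") as fh:
        fh.write(_version_comment())
        pd.concat(frames, ignore_index=True).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result tables and manifests
# ---------------------------------------------------------------------------

def write_result_table(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a result table with the version/seed comment header."""
    with open(path, "w") as fh:
        fh.write(_version_comment(seed))
        df.to_csv(fh, sep="\t", index=False)


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_manifest(path: str | Path, *, seed: int | None, inputs: dict, thresholds: dict) -> None:
    """Record everything needed to reproduce a run: inputs, seed, thresholds."""
    manifest = {
        "tool": "eutromics",
        "version": __version__,
        "seed": seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "thresholds": thresholds,
        "library_versions": _library_versions(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
        fh.write("\n")


def _library_versions() -> dict[str, str]:
    import scipy
    import skbio

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-bio": skbio.__version__,
    }


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
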