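"""Reading, validation and preprocessing of methylation array data.

Beta-values are per-probe methylation fractions M/(M + U + offset) computed
from methylated (M) and unmethylated (U) bead intensities; probes with
beta = 0 are treated as bad quality and marked missing.  Probe locations are
classified against a CpG-island interval set into island (I), shore (S,
within ``shore_width`` bp of an island, 2000 by default) and outside (O),
and each gene's first two probes (by genomic coordinate) form a probe pair.
Pair classes (I,S) are swapped into (S,I); mixed pairs involving O are
excluded from pair modeling (they are rare on the 27k design).

File dialects: the beta matrix is a TSV with probe_id in the first column
and one column per sample; annotations are a TSV with columns probe_id,
gene_id, chromosome, position (0-based); islands are standard 3-column BED
(0-based half-open).  Lines starting with '#' are ignored everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import ProbePair

DEFAULT_SHORE_WIDTH = 2000
#: Illumina BeadStudio convention adds 100 to the denominator for stability;
#: set offset=0 for the plain ratio M/(M+U).
DEFAULT_BETA_OFFSET = 100.0


@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    gene_id: str
    chromosome: str
    position: int
    location_class: str


def compute_beta(M, U, offset: float = DEFAULT_BETA_OFFSET):
    """Beta-value M / (M + U + offset) from bead intensities.

    Vectorized; raises if any denominator is zero (requires offset=0 and
    M=U=0) or any intensity is negative.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any(M < 0) or np.any(U < 0) or offset < 0:
        raise ValueError("intensities and offset must be non-negative")
    denom = M + U + offset
    if np.any(denom == 0):
        raise ValueError("zero denominator: M + U + offset must be positive")
    out = M / denom
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# CpG-island location classes


def merge_intervals(intervals) -> np.ndarray:
    """Merge overlapping/adjacent half-open intervals; returns sorted (n,2)."""
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if len(arr) == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="mergesort")]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def _island_distance(position: int, islands: np.ndarray) -> int:
    """Bases strictly between a position and the nearest island; -1 = inside.

    Islands are merged, sorted, 0-based half-open; positions 0-based.  A
    position immediately adjacent to an island (e.g. at its exclusive end)
    has distance 0 but is not inside.
    """
    starts, ends = islands[:, 0], islands[:, 1]
    i = int(np.searchsorted(starts, position, side="right")) - 1
    best = np.iinfo(np.int64).max
    if i >= 0:
        if position < ends[i]:
            return -1
        best = min(best, position - ends[i])
    if i + 1 < len(starts):
        best = min(best, starts[i + 1] - position - 1)
    return int(best)


def classify_location(
    position: int, islands: np.ndarray, shore_width: int = DEFAULT_SHORE_WIDTH
) -> str:
    """I if inside an island, S if within shore_width bp (inclusive), else O."""
    if position < 0:
        raise ValueError("position must be >= 0")
    if len(islands) == 0:
        return "O"
    d = _island_distance(int(position), islands)
    if d < 0:
        return "I"
    return "S" if d <= shore_width else "O"


def annotate_locations(
    annotations: pd.DataFrame,
    islands_by_chrom: dict[str, np.ndarray],
    shore_width: int = DEFAULT_SHORE_WIDTH,
) -> pd.DataFrame:
    """Add a location_class column (I/S/O) to a probe annotation table."""
    out = annotations.copy()
    classes = []
    unknown: set[str] = set()
    for chrom, pos in zip(out["chromosome"], out["position"]):
        iv = islands_by_chrom.get(str(chrom))
        if iv is None:
            unknown.add(str(chrom))
            classes.append("O")
        else:
            classes.append(classify_location(int(pos), iv, shore_width))
    if unknown:
        warnings.warn(
            f"chromosomes {sorted(unknown)} absent from island set; "
            "their probes classified as O"
        )
    out["location_class"] = classes
    return out


# ---------------------------------------------------------------------------
# File readers/writers


def load_beta_matrix(path) -> pd.DataFrame:
    """Read a probes x samples beta-value TSV.

    Empty fields and 'NA' are missing; beta = 0 entries are converted to
    missing at load (bad-quality probes).  Retained values must lie in
    (0, 1].
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
    df = df.astype(float)
    df = df.mask(df == 0.0)
    vals = df.to_numpy()
    bad = (vals < 0) | (vals > 1)
    if np.any(bad[~np.isnan(vals)]):
        raise ValueError("beta matrix contains values outside [0, 1]")
    if df.index.duplicated().any():
        raise ValueError("duplicate probe IDs in beta matrix")
    return df


def load_annotations(path) -> pd.DataFrame:
    """Read a probe annotation TSV (probe_id, gene_id, chromosome, position)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chromosome": str})
    required = {"probe_id", "gene_id", "chromosome", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns {sorted(missing)}")
    df = df.drop_duplicates(subset="probe_id")
    if (df["position"] < 0).any():
        raise ValueError("annotation positions must be >= 0")
    return df


def load_islands_bed(path) -> dict[str, np.ndarray]:
    """Read CpG islands from 3+ column BED; merges overlaps per chromosome."""
    bed = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str},
    )
    if (bed["end"] <= bed["start"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return {
        str(chrom): merge_intervals(grp[["start", "end"]].to_numpy())
        for chrom, grp in bed.groupby("chrom")
    }


def load_intensities(path, offset: float = DEFAULT_BETA_OFFSET) -> pd.DataFrame:
    """Read a (probe_id, sample, M, U) TSV and return a beta matrix."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"probe_id", "sample", "M", "U"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"intensity table lacks columns {sorted(missing)}")
    df = df.assign(beta=compute_beta(df["M"], df["U"], offset))
    mat = df.pivot(index="probe_id", columns="sample", values="beta")
    mat.columns.name = None
    return mat.mask(mat == 0.0)


# ---------------------------------------------------------------------------
# Pair assembly


def sample_probe_table(
    annotations: pd.DataFrame, betas: pd.DataFrame, sample_id: str
) -> pd.DataFrame:
    """Long per-sample probe table joining annotation and beta-values.

    Columns: probe_id, gene_id, location_class, position, beta (NaN when the
    probe is missing/filtered for this sample).
    """
    if "location_class" not in annotations.columns:
        raise ValueError("annotations lack location_class; run annotate_locations")
    if sample_id not in betas.columns:
        raise KeyError(f"sample {sample_id!r} not in beta matrix")
    tbl = annotations[["probe_id", "gene_id", "location_class", "position"]].copy()
    tbl["beta"] = betas[sample_id].reindex(tbl["probe_id"]).to_numpy()
    return tbl


def build_pairs(
    annotations: pd.DataFrame, betas: pd.DataFrame, sample_id: str
) -> tuple[list[ProbePair], list[str]]:
    """Assemble one sample's modeled probe pairs.

    Per gene, probes are ordered by genomic coordinate and the first two
    form the pair; (I,S) is swapped into (S,I); classes mixing O with I/S
    are excluded; pairs with a missing member are dropped.  Genes with a
    single usable probe are returned as the unpaired probe-ID list (they
    still contribute to marginal mixture fitting).
    """
    from .estimation import pairs_from_probe_table

    tbl = sample_probe_table(annotations, betas, sample_id)
    pairs = pairs_from_probe_table(tbl)
    usable = tbl.dropna(subset=["beta"])
    counts = usable.groupby("gene_id")["probe_id"].count()
    single_genes = set(counts[counts == 1].index)
    unpaired = [
        str(r.probe_id)
        for r in usable.itertuples()
        if r.gene_id in single_genes
    ]
    return pairs, unpaired
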