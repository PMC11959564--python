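"""Reading Visium-style inputs and spot/gene-level quality control.

Four bespoke filters are implemented:

* a minimum-detected-genes filter (spots with fewer than 100 detected genes
  are removed);
* a brightness filter removing too-light-to-be-tissue spots (luminance more
  than ``k`` SD above the per-section mean — lighter = larger values);
* a contiguity filter keeping only spots in hex-adjacency connected
  components of at least 200 spots, which drops small detached debris;
* a probe-specificity filter flagging genes whose probe-captured pseudobulk
  expression deviates from an OLS fit against polyA-captured pseudobulk by
  more than 3 residual SD.

The documented application order for the spot filters is brightness ->
min-genes -> contiguity: contiguity must run last because the earlier
filters change the retained set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.sparse.csgraph import connected_components

from .datatypes import CountMatrix, SpotGrid
from .hexgrid import adjacency_matrix

logger = logging.getLogger(__name__)

POSITION_COLUMNS = (
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "x_um",
    "y_um",
    "brightness",
)


@dataclass
class FilterResult:
    """Outcome of a single QC filter."""

    name: str
    n_in: int
    removed: list
    params: dict

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    @property
    def n_retained(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class QCReport:
    """Accumulated filter outcomes; removed + retained always reconcile."""

    filters: list[FilterResult] = field(default_factory=list)

    def add(self, result: FilterResult) -> None:
        self.filters.append(result)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "filter": f.name,
                "n_in": f.n_in,
                "n_removed": f.n_removed,
                "n_retained": f.n_retained,
                "params": repr(f.params),
            }
            for f in self.filters
        ]
        return pd.DataFrame(rows)

    def removed_frame(self) -> pd.DataFrame:
        rows = [
            {"filter": f.name, "removed_id": rid}
            for f in self.filters
            for rid in f.removed
        ]
        return pd.DataFrame(rows, columns=["filter", "removed_id"])


def read_visium(path: str | Path, section_id: str | None = None) -> tuple[CountMatrix, SpotGrid]:
    """Read a Space-Ranger-style directory written by the simulator.

    Expects ``matrix.mtx``, ``features.tsv``, ``barcodes.tsv`` and
    ``positions.csv``; unknown extra position columns are ignored.  The
    returned grid and counts share one spot order (the matrix barcode
    order).
    """
    p = Path(path)
    files = {name: p / name for name in
             ("matrix.mtx", "features.tsv", "barcodes.tsv", "positions.csv")}
    for name, f in files.items():
        if not f.exists():
            raise FileNotFoundError(f"missing {name} in {p}")
    mat = sp.csr_matrix(scipy.io.mmread(str(files["matrix.mtx"])))
    feats = pd.read_csv(files["features.tsv"], sep="\t", header=None)
    barcodes = pd.read_csv(files["barcodes.tsv"], sep="\t", header=None)[0].astype(str)
    genes = feats[0].astype(str)
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} features "
            f"x {len(barcodes)} barcodes"
        )
    if barcodes.duplicated().any():
        dup = list(barcodes[barcodes.duplicated()][:5])
        raise ValueError(f"duplicate barcodes: {dup}")
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("matrix contains negative entries")

    pos = pd.read_csv(files["positions.csv"])
    missing_cols = [c for c in POSITION_COLUMNS if c not in pos.columns]
    if missing_cols:
        raise ValueError(f"positions.csv missing columns: {missing_cols}")
    pos = pos[list(POSITION_COLUMNS)].copy()
    pos["barcode"] = pos["barcode"].astype(str)
    unknown = sorted(set(pos["barcode"]) - set(barcodes))
    if unknown:
        raise ValueError(f"positions barcode absent from matrix: {unknown[:5]}")
    missing_pos = sorted(set(barcodes) - set(pos["barcode"]))
    if missing_pos:
        raise ValueError(f"matrix barcode absent from positions: {missing_pos[:5]}")
    pos = pos.set_index("barcode").loc[barcodes].reset_index()

    sid = section_id if section_id is not None else p.name
    grid = SpotGrid(
        pd.DataFrame(
            {
                "spot_id": pos["barcode"],
                "section_id": sid,
                "array_row": pos["array_row"].astype(int),
                "array_col": pos["array_col"].astype(int),
                "x_um": pos["x_um"].astype(float),
                "y_um": pos["y_um"].astype(float),
                "in_tissue": pos["in_tissue"].astype(bool),
                "brightness": pos["brightness"].astype(float),
            }
        )
    )
    counts = CountMatrix(genes.to_numpy(object), barcodes.to_numpy(object), mat)
    return counts, grid


def filter_low_gene_spots(
    counts: CountMatrix, min_genes: int = 100
) -> tuple[np.ndarray, FilterResult]:
    """Retain spots with at least ``min_genes`` detected (count > 0) genes."""
    detected = counts.genes_detected_per_spot()
    mask = detected >= min_genes
    removed = [s for s, keep in zip(counts.spots, mask) if not keep]
    return mask, FilterResult("min_genes", len(mask), removed, {"min_genes": min_genes})


def filter_brightness(grid: SpotGrid, k_sd: float = 1.0) -> tuple[np.ndarray, FilterResult]:
    """Remove spots lighter than mean + k_sd * SD of their section.

    Brightness statistics are computed per section (staining intensity
    varies by slide); removal is one-sided on the light side only since
    darker spots are tissue.  Sections with fewer than two spots are skipped
    with a warning.
    """
    t = grid.table
    mask = np.ones(len(grid), dtype=bool)
    for sec in grid.sections:
        in_sec = (t["section_id"] == sec).to_numpy()
        b = t.loc[in_sec, "brightness"].to_numpy(dtype=float)
        if len(b) < 2:
            logger.warning("brightness filter skipped for section %s (<2 spots)", sec)
            continue
        thr = b.mean() + k_sd * b.std(ddof=1)
        mask[in_sec] = b <= thr
    removed = [s for s, keep in zip(grid.spot_ids, mask) if not keep]
    return mask, FilterResult("brightness", len(mask), removed, {"k_sd": k_sd})


def filter_contiguity(
    grid: SpotGrid, mask: np.ndarray, min_component: int = 200
) -> tuple[np.ndarray, FilterResult]:
    """Keep retained spots in hex-connected components of >= ``min_component``.

    Components are computed over the 6-neighbor hexagonal adjacency among
    currently retained spots; component size includes the spot itself.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(grid),):
        raise ValueError("mask not aligned to grid")
    out = mask.copy()
    idx = np.flatnonzero(mask)
    if len(idx):
        sub = grid.table.iloc[idx]
        adj = adjacency_matrix(sub)
        n_comp, labels = connected_components(adj, directed=False)
        sizes = np.bincount(labels, minlength=n_comp)
        out[idx] = sizes[labels] >= min_component
    removed = [s for s, was, keep in zip(grid.spot_ids, mask, out) if was and not keep]
    return out, FilterResult(
        "contiguity", int(mask.sum()), removed, {"min_component": min_component}
    )


def flag_unspecific_probes(
    pairs: pd.DataFrame, k_sd: float = 3.0
) -> tuple[list[str], FilterResult]:
    """Flag genes whose probe capture deviates from the polyA trend.

    Fits OLS of ``probe_value`` on ``polya_value`` over all genes and flags
    genes with absolute residual greater than ``k_sd`` residual-SD
    (two-sided).
    """
    required = {"gene", "probe_value", "polya_value"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 genes to fit the probe filter, got {len(pairs)}")
    x = pairs["polya_value"].to_numpy(dtype=float)
    y = pairs["probe_value"].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite expression values in pair table")
    if np.ptp(x) == 0:
        raise ValueError("polyA values have zero variance; cannot fit regression")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    resid = np.asarray(fit.resid)
    sd = resid.std(ddof=1)
    flagged_mask = np.abs(resid) > k_sd * sd if sd > 0 else np.zeros(len(resid), bool)
    flagged = [g for g, f in zip(pairs["gene"], flagged_mask) if f]
    return flagged, FilterResult("unspecific_probes", len(pairs), flagged, {"k_sd": k_sd})


def make_pseudobulk_pairs(
    probe: dict[str, CountMatrix], polya: dict[str, CountMatrix]
) -> pd.DataFrame:
    """Mean-normalized pseudobulk pair table for the probe-specificity filter.

    Per assay and sample, counts are summed over spots and scaled to counts
    per million; the per-gene mean over samples is then log1p-transformed.
    Only genes present in both assays are returned.
    """

    def assay_profile(samples: dict[str, CountMatrix]) -> pd.Series:
        profiles = []
        for name, cm in samples.items():
            total = cm.counts.sum()
            if total == 0:
                raise ValueError(f"sample {name!r} has zero total counts")
            cpm = np.asarray(cm.counts.sum(axis=1)).ravel() * 1e6 / total
            profiles.append(pd.Series(cpm, index=cm.genes))
        return np.log1p(pd.concat(profiles, axis=1).fillna(0.0).mean(axis=1))

    probe_prof = assay_profile(probe)
    polya_prof = assay_profile(polya)
    shared = probe_prof.index.intersection(polya_prof.index)
    return pd.DataFrame(
        {
            "gene": shared,
            "probe_value": probe_prof.loc[shared].to_numpy(),
            "polya_value": polya_prof.loc[shared].to_numpy(),
        }
    )


def run_spot_qc(
    grid: SpotGrid,
    counts: CountMatrix,
    min_genes: int = 100,
    k_sd_brightness: float = 1.0,
    min_component: int = 200,
) -> tuple[np.ndarray, QCReport]:
    """Apply the spot filters in order brightness -> min-genes -> contiguity."""
    if list(counts.spots) != list(grid.spot_ids):
        raise ValueError("counts and grid spot order differ")
    report = QCReport()
    bright_mask, res = filter_brightness(grid, k_sd_brightness)
    report.add(res)
    gene_mask, res = filter_low_gene_spots(counts, min_genes)
    report.add(res)
    combined = bright_mask & gene_mask
    final, res = filter_contiguity(grid, combined, min_component)
    report.add(res)
    return final, report
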