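"""Visium-like synthetic sections with known spatial structure.

The generator produces hexagonal spot lattices, spatially coherent
signature-high foci, and negative-binomial counts whose log-mean varies
linearly with distance (in spot-lengths) to the nearest focus.  Every
downstream stage of the pipeline — QC, signature scoring, spot
classification, distance modeling — can therefore be checked against known
ground truth without any external data.

The negative binomial is parameterized by mean ``mu`` and dispersion
``theta`` with ``var = mu + mu**2 / theta`` (theta -> inf is the Poisson
limit).  Optional ambient "bleed" redistributes a fraction of each spot's
expected counts uniformly over its lattice neighbors before sampling,
conserving the expected total per gene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import CountMatrix, SpotGrid
from .hexgrid import adjacency_matrix, nearest_anchor_distance

TRUTH_GENE_COLUMNS = (
    "gene",
    "baseline_log_mean",
    "beta_true",
    "dispersion",
    "is_signature_gene",
    "signature_bump",
)


@dataclass
class SyntheticTruth:
    """Ground-truth simulation parameters.

    ``genes`` has one row per gene with columns
    :data:`TRUTH_GENE_COLUMNS` plus an optional ``beta_delta_nr`` column
    (added to ``beta_true`` for sections whose group is the non-responder
    label).  ``sections`` has one row per section with ``section_id``,
    ``sample_effect`` (log-scale library offset) and optionally ``group``.
    """

    genes: pd.DataFrame
    sections: pd.DataFrame
    seed: int
    bleed_fraction: float = 0.0
    d_cap: float = 10.0
    nonresponder_label: str = "NR"

    def __post_init__(self) -> None:
        missing = [c for c in TRUTH_GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"truth gene table missing columns: {missing}")
        if (self.genes["dispersion"] <= 0).any():
            raise ValueError("dispersion must be positive")
        if not (0 <= self.bleed_fraction < 1):
            raise ValueError("bleed_fraction must be in [0, 1)")
        if "section_id" not in self.sections.columns:
            raise ValueError("truth section table needs a section_id column")
        self.genes = self.genes.reset_index(drop=True)
        self.sections = self.sections.reset_index(drop=True)

    @property
    def signature_genes(self) -> tuple[str, ...]:
        m = self.genes["is_signature_gene"].astype(bool)
        return tuple(self.genes.loc[m, "gene"])

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(out / "truth_genes.csv", index=False)
        self.sections.to_csv(out / "truth_sections.csv", index=False)
        meta = {
            "seed": int(self.seed),
            "bleed_fraction": float(self.bleed_fraction),
            "d_cap": float(self.d_cap),
            "nonresponder_label": self.nonresponder_label,
        }
        (out / "truth_meta.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, in_dir: str | Path) -> "SyntheticTruth":
        p = Path(in_dir)
        meta = json.loads((p / "truth_meta.json").read_text())
        return cls(
            genes=pd.read_csv(p / "truth_genes.csv"),
            sections=pd.read_csv(p / "truth_sections.csv"),
            **meta,
        )


def make_hex_grid(
    n_rows: int, n_cols: int, spacing_um: float, section_id: str
) -> SpotGrid:
    """Hexagonal spot lattice with exact nearest-neighbor spacing.

    ``array_col`` runs over even integers on even rows and odd integers on
    odd rows (equal-parity convention); physical coordinates are derived so
    every lattice neighbor sits exactly ``spacing_um`` away.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {n_rows}x{n_cols}")
    if spacing_um <= 0:
        raise ValueError(f"spacing_um must be positive, got {spacing_um}")
    rows = np.repeat(np.arange(n_rows), n_cols)
    cols = 2 * np.tile(np.arange(n_cols), n_rows) + rows % 2
    x = cols * (spacing_um / 2.0)
    y = rows * (spacing_um * np.sqrt(3.0) / 2.0)
    table = pd.DataFrame(
        {
            "spot_id": [f"{section_id}_{r}_{c}" for r, c in zip(rows, cols)],
            "section_id": section_id,
            "array_row": rows.astype(int),
            "array_col": cols.astype(int),
            "x_um": x,
            "y_um": y,
            "in_tissue": True,
            "brightness": 0.5,
        }
    )
    return SpotGrid(table)


def simulate_brightness(
    grid: SpotGrid,
    seed: int,
    mu_tissue: float = 0.45,
    sigma: float = 0.05,
    mu_light: float = 0.85,
    light_fraction: float = 0.02,
) -> SpotGrid:
    """Assign a per-spot luminance proxy.

    Tissue spots draw from Normal(mu_tissue, sigma); a ``light_fraction``
    subset emulates too-light-to-be-tissue debris at ``mu_light`` so the
    brightness QC filter has something to remove.  Higher values = lighter.
    """
    rng = np.random.default_rng(seed)
    n = len(grid)
    b = rng.normal(mu_tissue, sigma, size=n)
    n_light = int(round(light_fraction * n))
    if n_light:
        idx = rng.choice(n, size=n_light, replace=False)
        b[idx] = rng.normal(mu_light, sigma, size=n_light)
    table = grid.table.copy()
    table["brightness"] = b
    return SpotGrid(table)


def place_foci(grid: SpotGrid, n_foci: int, radius: float, seed: int) -> np.ndarray:
    """Boolean mask of spots within ``radius`` spot-lengths of a focus center.

    Centers are sampled uniformly without replacement from the grid's spots;
    distances are Euclidean in physical coordinates, in units of each
    section's nearest-neighbor spacing.  Deterministic given ``seed``.
    """
    if n_foci < 0 or radius < 0:
        raise ValueError("n_foci and radius must be nonnegative")
    if n_foci > len(grid):
        raise ValueError(f"n_foci={n_foci} exceeds spot count {len(grid)}")
    mask = np.zeros(len(grid), dtype=bool)
    if n_foci == 0:
        return mask
    rng = np.random.default_rng(seed)
    centers = rng.choice(len(grid), size=n_foci, replace=False)
    t = grid.table
    pos = grid.positions()
    for sec in grid.sections:
        in_sec = (t["section_id"] == sec).to_numpy()
        sec_centers = [c for c in centers if in_sec[c]]
        if not sec_centers:
            continue
        spacing = grid.spacing(sec)
        if np.isnan(spacing):  # singleton section: a center covers itself
            spacing = 1.0
        d = nearest_anchor_distance(pos[in_sec], pos[sec_centers]) / spacing
        mask[in_sec] |= d <= radius + 1e-9
    return mask


def distance_to_foci(
    grid: SpotGrid, focus_mask: np.ndarray, d_cap: float = 10.0
) -> np.ndarray:
    """Per-spot distance (spot-lengths) to the nearest focus spot, capped.

    Sections with no focus spots get ``d_cap`` everywhere (flat profile).
    """
    focus_mask = np.asarray(focus_mask, dtype=bool)
    if focus_mask.shape != (len(grid),):
        raise ValueError("focus mask not aligned to grid")
    t = grid.table
    pos = grid.positions()
    d = np.full(len(grid), float(d_cap))
    for sec in grid.sections:
        in_sec = (t["section_id"] == sec).to_numpy()
        anchors = pos[in_sec & focus_mask]
        if len(anchors) == 0:
            continue
        spacing = grid.spacing(sec)
        if np.isnan(spacing):
            spacing = 1.0
        dist = nearest_anchor_distance(pos[in_sec], anchors) / spacing
        d[in_sec] = np.minimum(dist, d_cap)
    return d


def _bleed_operator(grid: SpotGrid, bleed_fraction: float) -> sp.csr_matrix:
    """Column-stochastic redistribution operator for ambient bleed.

    Each spot keeps ``1 - b`` of its expected counts and spreads ``b``
    uniformly over its lattice neighbors; isolated spots keep everything so
    expected totals per gene are conserved exactly.
    """
    adj = adjacency_matrix(grid.table)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    keep = np.where(deg > 0, 1.0 - bleed_fraction, 1.0)
    inv_deg = np.divide(bleed_fraction, deg, out=np.zeros_like(deg), where=deg > 0)
    spread = sp.diags(inv_deg) @ adj  # row t -> neighbors of t
    return (sp.diags(keep) + spread.T).tocsr()


def simulate_counts(
    grid: SpotGrid,
    truth: SyntheticTruth,
    focus_mask: np.ndarray,
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """Sample NB counts with distance-dependent log-means.

    For each gene g and spot s::

        log mu = baseline_g + beta_g * d(s) + sample_effect(section(s))
                 [+ signature_bump_g if g is a signature gene and s in a focus]

    where ``d(s)`` is the distance in spot-lengths to the nearest focus spot,
    capped at ``truth.d_cap``, and ``beta_g`` includes the non-responder
    offset ``beta_delta_nr`` for sections of that group.  Deterministic given
    ``truth.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    focus_mask = np.asarray(focus_mask, dtype=bool)
    if focus_mask.shape != (len(grid),):
        raise ValueError("focus mask not aligned to grid")
    genes = truth.genes
    if genes["gene"].duplicated().any():
        raise ValueError("duplicate genes in truth table")
    if genes[["baseline_log_mean", "beta_true", "dispersion"]].isna().any().any():
        raise ValueError("missing gene parameters in truth table")

    sec_tab = truth.sections.set_index("section_id")
    spot_secs = grid.table["section_id"]
    unknown = sorted(set(spot_secs) - set(sec_tab.index))
    if unknown:
        raise ValueError(f"truth has no parameters for sections: {unknown}")
    sample_effect = sec_tab.loc[spot_secs, "sample_effect"].to_numpy(dtype=float)
    if "group" in sec_tab.columns:
        is_nr = (
            sec_tab.loc[spot_secs, "group"].to_numpy() == truth.nonresponder_label
        )
    else:
        is_nr = np.zeros(len(grid), dtype=bool)

    d = distance_to_foci(grid, focus_mask, truth.d_cap)
    baseline = genes["baseline_log_mean"].to_numpy(dtype=float)
    beta = genes["beta_true"].to_numpy(dtype=float)
    if "beta_delta_nr" in genes.columns:
        delta = genes["beta_delta_nr"].to_numpy(dtype=float)
    else:
        delta = np.zeros(len(genes))
    beta_per_spot = beta[:, None] + delta[:, None] * is_nr[None, :]

    log_mu = baseline[:, None] + beta_per_spot * d[None, :] + sample_effect[None, :]
    sig = genes["is_signature_gene"].to_numpy(dtype=bool)
    bump = genes["signature_bump"].to_numpy(dtype=float)
    log_mu[sig, :] += bump[sig, None] * focus_mask[None, :]
    mu = np.exp(log_mu)

    if truth.bleed_fraction > 0:
        mu = mu @ _bleed_operator(grid, truth.bleed_fraction).T.toarray()

    theta = genes["dispersion"].to_numpy(dtype=float)[:, None]
    p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p)
    return CountMatrix(
        genes["gene"].to_numpy(dtype=object),
        grid.spot_ids,
        sp.csr_matrix(counts),
    )


def expected_means(
    grid: SpotGrid, truth: SyntheticTruth, focus_mask: np.ndarray
) -> np.ndarray:
    """Expected count matrix (genes x spots) under the generative model.

    Same mean construction as :func:`simulate_counts`, without sampling;
    used for moment and bleed-conservation checks.
    """
    focus_mask = np.asarray(focus_mask, dtype=bool)
    sec_tab = truth.sections.set_index("section_id")
    spot_secs = grid.table["section_id"]
    sample_effect = sec_tab.loc[spot_secs, "sample_effect"].to_numpy(dtype=float)
    d = distance_to_foci(grid, focus_mask, truth.d_cap)
    genes = truth.genes
    baseline = genes["baseline_log_mean"].to_numpy(dtype=float)
    beta = genes["beta_true"].to_numpy(dtype=float)
    log_mu = baseline[:, None] + beta[:, None] * d[None, :] + sample_effect[None, :]
    sig = genes["is_signature_gene"].to_numpy(dtype=bool)
    bump = genes["signature_bump"].to_numpy(dtype=float)
    log_mu[sig, :] += bump[sig, None] * focus_mask[None, :]
    mu = np.exp(log_mu)
    if truth.bleed_fraction > 0:
        mu = mu @ _bleed_operator(grid, truth.bleed_fraction).T.toarray()
    return mu


def write_visium_like(grid: SpotGrid, counts: CountMatrix, out_dir: str | Path) -> Path:
    """Write one section as a Space-Ranger-style directory.

    Files: ``matrix.mtx`` (genes x spots, integer Matrix Market),
    ``features.tsv``, ``barcodes.tsv`` and ``positions.csv`` with columns
    (barcode, in_tissue, array_row, array_col, x_um, y_um, brightness).
    A read-back round trip reproduces counts and coordinates exactly.
    """
    if len(grid.sections) != 1:
        raise ValueError("write_visium_like writes one section per directory")
    if list(counts.spots) != list(grid.spot_ids):
        raise ValueError("counts and grid spot order differ")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = counts.counts.astype(np.int64).tocoo()
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat, field="integer")
    feats = pd.DataFrame(
        {"id": counts.genes, "name": counts.genes, "type": "Gene Expression"}
    )
    feats.to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.spots).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    pos = grid.table[
        ["spot_id", "in_tissue", "array_row", "array_col", "x_um", "y_um", "brightness"]
    ].rename(columns={"spot_id": "barcode"})
    pos.to_csv(out / "positions.csv", index=False)
    return out
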