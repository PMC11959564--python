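"""Distance-to-feature modeling of per-gene expression.

For each signature-LOW spot the Euclidean distance to the nearest
signature-HIGH spot of the same section is computed in spot-length units
(section nearest-neighbor spacing).  Modeling is restricted to tumor spots
within ``d_max`` (default 10) spot-lengths of a HIGH anchor; stroma and
pathology non-cancer spots are excluded.  Each gene's log1p
depth-normalized expression is then regressed on distance with sample
indicators and a diffusion-adjusted signature score as covariates.  A gene
is called significant when its Bonferroni-adjusted p-value is below alpha
AND its coefficient is more than 3 SD from the mean of all tested
coefficients (two-sided).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, SpotGrid
from .hexgrid import nearest_anchor_distance
from .signatures import HIGH, LOW, SignatureScores, SpotClassification

logger = logging.getLogger(__name__)

MODEL_COLUMNS = ("gene", "group", "beta_d", "se", "p", "p_bonf", "significant", "n_spots")


def nearest_high_distance(grid: SpotGrid, cls: SpotClassification) -> pd.DataFrame:
    """Distance from each LOW spot to its nearest HIGH spot, per section.

    Distances are exact Euclidean in physical coordinates divided by the
    section's nearest-neighbor spacing (so a lattice-adjacent HIGH spot is
    at d = 1).  Sections without any HIGH spot yield infinite distances and
    a logged warning; such spots are dropped downstream.
    """
    t = grid.table
    rows = []
    for sec in grid.sections:
        sub = t[t["section_id"] == sec]
        labs = cls.labels.loc[sub["spot_id"]]
        low_ids = sub.loc[(labs == LOW).to_numpy(), "spot_id"].to_numpy()
        if len(low_ids) == 0:
            continue
        high_pos = sub.loc[(labs == HIGH).to_numpy(), ["x_um", "y_um"]].to_numpy(float)
        low_pos = sub.set_index("spot_id").loc[low_ids, ["x_um", "y_um"]].to_numpy(float)
        if len(high_pos) == 0:
            logger.warning("section %s has no HIGH spots; distances are infinite", sec)
            d = np.full(len(low_ids), np.inf)
        else:
            spacing = grid.spacing(sec)
            d = nearest_anchor_distance(low_pos, high_pos) / spacing
        rows.append(pd.DataFrame({"spot_id": low_ids, "section_id": sec, "d": d}))
    if not rows:
        return pd.DataFrame(columns=["spot_id", "section_id", "d"])
    return pd.concat(rows, ignore_index=True)


def restrict_modeling_set(
    dist: pd.DataFrame,
    annotations: pd.DataFrame,
    d_max: float = 10.0,
    tumor_compartments: tuple[str, ...] = ("tumor",),
    known_compartments: tuple[str, ...] = ("tumor", "stroma"),
    cancer_classes: tuple[str, ...] = ("cancer",),
    known_classes: tuple[str, ...] = ("cancer", "non-cancer"),
) -> pd.Index:
    """LOW tumor spots within ``d_max`` spot-lengths of a HIGH anchor.

    ``annotations`` must carry ``spot_id``, ``compartment`` and
    ``pathology_class`` for every spot in ``dist``; unknown labels raise an
    error listing them.
    """
    ann = annotations.set_index("spot_id")
    missing = [s for s in dist["spot_id"] if s not in ann.index]
    if missing:
        raise ValueError(f"annotations missing for spots: {missing[:5]}")
    bad_comp = sorted(set(ann["compartment"]) - set(known_compartments))
    bad_cls = sorted(set(ann["pathology_class"]) - set(known_classes))
    if bad_comp or bad_cls:
        raise ValueError(
            f"unknown annotation labels: compartments {bad_comp}, classes {bad_cls}"
        )
    sub = ann.loc[dist["spot_id"]]
    keep = (
        np.isfinite(dist["d"].to_numpy(float))
        & (dist["d"].to_numpy(float) <= d_max)
        & sub["compartment"].isin(tumor_compartments).to_numpy()
        & sub["pathology_class"].isin(cancer_classes).to_numpy()
    )
    return pd.Index(dist.loc[keep, "spot_id"].to_numpy(), name="spot_id")


def adjust_signature_scores(
    scores: SignatureScores | pd.Series, dist: pd.DataFrame
) -> pd.Series:
    """Detrend signature scores against distance, per section.

    Signature transcripts diffuse out of signature-high regions and inflate
    nearby scores; the adjusted covariate is the residual of a per-section
    least-squares fit of score on distance, making it mean-zero and
    orthogonal to distance within each section.  Sections with fewer than 3
    spots pass raw scores through with a warning.
    """
    s = scores.scores if isinstance(scores, SignatureScores) else scores
    out = pd.Series(index=pd.Index(dist["spot_id"].to_numpy(), name="spot_id"),
                    dtype=float)
    for sec, sub in dist.groupby("section_id", sort=False):
        ids = sub["spot_id"].to_numpy()
        y = s.loc[ids].to_numpy(float)
        d = sub["d"].to_numpy(float)
        if len(ids) < 3:
            logger.warning(
                "section %s has < 3 modeling spots; raw scores passed through", sec
            )
            out.loc[ids] = y
            continue
        x = np.column_stack([np.ones_like(d), d])
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        out.loc[ids] = y - x @ coef
    return out


def _design_matrix(
    d: np.ndarray, sample_ids: np.ndarray, adj_scores: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """[intercept, d, sample indicators, adjusted score] with degenerate
    covariates dropped (logged, never silent)."""
    cols = [np.ones_like(d), d]
    names = ["intercept", "d"]
    levels = sorted(set(sample_ids))
    for level in levels[1:]:  # reference = lexicographically first sample
        cols.append((sample_ids == level).astype(float))
        names.append(f"sample[{level}]")
    cols.append(adj_scores)
    names.append("adj_score")
    x = np.column_stack(cols)
    keep = [0, 1]
    for j in range(2, x.shape[1]):
        if np.ptp(x[:, j]) == 0:
            logger.info("dropping constant covariate %s from the design", names[j])
        else:
            keep.append(j)
    x = x[:, keep]
    names = [names[j] for j in keep]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient after dropping "
                         "constant covariates")
    return x, names


def fit_distance_models(
    counts: CountMatrix,
    modeling_spots,
    dist: pd.DataFrame,
    sample_ids: pd.Series,
    adj_scores: pd.Series,
    group: str,
    signature_genes: tuple[str, ...] = (),
    min_detect_frac: float = 0.05,
    scale: float = 1e4,
) -> pd.DataFrame:
    """Per-gene OLS of log1p depth-normalized expression on distance.

    The response for gene g in spot s is ``log1p(count * scale / total_s)``
    with ``total_s`` the spot's library size over all genes.  Genes must be
    detected in at least ``min_detect_frac`` of the modeling spots;
    signature genes are never modeled.  All genes share one design matrix,
    so the fit is a single least-squares solve; coefficient standard
    errors, two-sided t p-values and Bonferroni adjustment (m = genes
    tested in this group) are reported per gene.
    """
    spots = list(modeling_spots)
    if not spots:
        raise ValueError("modeling set is empty")
    dtab = dist.set_index("spot_id")
    d = dtab.loc[spots, "d"].to_numpy(float)
    if not np.isfinite(d).all():
        raise ValueError("modeling set contains spots with infinite distance")
    samples = sample_ids.loc[spots].to_numpy()
    adj = adj_scores.loc[spots].to_numpy(float)

    totals_all = pd.Series(counts.spot_totals(), index=counts.spots)
    totals = totals_all.loc[spots].to_numpy(float)
    if (totals <= 0).any():
        raise ValueError("modeling set contains spots with zero total counts")

    sub = counts.subset_spots(spots)
    dense = sub.dense().astype(float)  # genes x n
    detect_frac = (dense > 0).mean(axis=1)
    sig = np.isin(sub.genes, list(signature_genes))
    tested = (detect_frac >= min_detect_frac) & ~sig
    if not tested.any():
        raise ValueError("no genes pass the detection threshold")

    y = np.log1p(dense[tested, :] * scale / totals[None, :]).T  # n x G
    x, names = _design_matrix(d, samples, adj)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"too few modeling spots ({n}) for {p} covariates")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)  # p x G
    resid = y - x @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    j = names.index("d")
    beta_d = beta[j, :]
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta_d / se, np.inf * np.sign(beta_d))
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    m = int(tested.sum())
    p_bonf = np.minimum(1.0, pval * m)
    return pd.DataFrame(
        {
            "gene": sub.genes[tested],
            "group": group,
            "beta_d": beta_d,
            "se": se,
            "p": pval,
            "p_bonf": p_bonf,
            "significant": False,
            "n_spots": n,
        }
    )


def call_significant(
    models: pd.DataFrame, alpha: float = 0.05, k_sd: float = 3.0
) -> pd.DataFrame:
    """Flag genes with p_bonf < alpha AND |beta - mean(beta)| > k_sd * SD.

    The coefficient mean and SD are taken over all tested genes of the
    group; the outlier rule is two-sided so both proximal (negative) and
    distal (positive) trends can be flagged.
    """
    if len(models) < 10:
        raise ValueError(f"need >= 10 genes to apply the coefficient rule, "
                         f"got {len(models)}")
    out = models.copy()
    b = out["beta_d"].to_numpy(float)
    sd = b.std(ddof=1)
    outlier = np.abs(b - b.mean()) > k_sd * sd if sd > 0 else np.zeros(len(b), bool)
    out["significant"] = (out["p_bonf"].to_numpy(float) < alpha) & outlier
    return out
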