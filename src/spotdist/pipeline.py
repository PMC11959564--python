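"""Study-level simulation and pipeline orchestration.

:class:`StudyDesign` fixes the synthetic study conditions — lattice size and
spacing, gene panel (signature genes, planted distance effects, null genes),
negative-binomial dispersion, focus geometry, sample effects — and
:func:`simulate_study` materializes a multi-section study from them.
:func:`run_group_model` chains scoring, classification, distance
computation, modeling-set restriction, score adjustment and per-gene model
fitting for the sections of one response group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io_qc, spatial_model
from .datatypes import CountMatrix, SpotGrid
from .signatures import SignatureScores, classify_spots, rank_signature_score
from .synthetic import (
    SyntheticTruth,
    make_hex_grid,
    place_foci,
    simulate_brightness,
    simulate_counts,
)


@dataclass
class StudyDesign:
    """Synthetic study conditions.

    Defaults describe the packaged recovery scene: 4 single-section tumors
    on 33x33 lattices (~1,089 spots each) at 100 µm spacing; 300 modeled
    genes of which 30 carry beta = +0.08, 30 carry -0.08 per spot-length
    and 240 are null; NB dispersion 0.5.  The anchoring feature is a
    coherent 16-gene signature (lower overdispersion, theta = 5) with a
    +2.5 log-mean bump inside 3 foci of radius 2.5 spot-lengths per
    section, so signature-high calls form spatially coherent regions as a
    real transcriptional program does.
    """

    n_rows: int = 33
    n_cols: int = 33
    spacing_um: float = 100.0
    tumors: tuple[tuple[str, str], ...] = (
        ("t1", "R"), ("t2", "R"), ("t3", "NR"), ("t4", "NR"),
    )
    sections_per_tumor: int = 1

    n_genes: int = 300
    n_signature: int = 16
    n_pos: int = 30
    n_neg: int = 30
    beta_effect: float = 0.08
    beta_delta_nr: float = 0.0
    n_delta: int = 0
    baseline_effect_log_mean: float = float(np.log(20.0))
    baseline_null_log_mean: float = float(np.log(5.0))
    baseline_null_log_sd: float = 0.5
    dispersion: float = 0.5
    signature_baseline_log_mean: float = float(np.log(5.0))
    signature_bump: float = 2.5
    signature_dispersion: float = 5.0

    n_foci: int = 3
    focus_radius: float = 2.5
    sample_effect_sd: float = 0.3
    bleed_fraction: float = 0.0
    d_cap: float = 10.0

    stroma_margin: int = 1
    brightness_mu_tissue: float = 0.45
    brightness_sigma: float = 0.05
    brightness_mu_light: float = 0.85
    brightness_light_fraction: float = 0.02


@dataclass
class PipelineParams:
    """Analysis parameters, with the study's documented defaults."""

    min_genes: int = 100
    k_sd_brightness: float = 1.0
    min_component: int = 200
    r_max: int = 1500
    high_k_sd: float = 1.5
    d_max: float = 10.0
    alpha: float = 0.05
    k_sd_coef: float = 3.0
    k_sd_delta: float = 2.0
    min_detect_frac: float = 0.05


@dataclass
class StudyData:
    """A materialized synthetic study."""

    grid: SpotGrid
    counts: CountMatrix
    annotations: pd.DataFrame
    truth: SyntheticTruth
    focus_mask: np.ndarray


def build_truth(design: StudyDesign, seed: int) -> SyntheticTruth:
    """Gene and section ground-truth tables for a study design."""
    rng = np.random.default_rng(seed)
    n_model = design.n_genes
    if design.n_pos + design.n_neg + design.n_delta > n_model:
        raise ValueError("more effect genes than modeled genes")
    genes = []
    for i in range(design.n_signature):
        genes.append(
            dict(gene=f"sig{i:03d}", baseline_log_mean=design.signature_baseline_log_mean,
                 beta_true=0.0, dispersion=design.signature_dispersion,
                 is_signature_gene=True, signature_bump=design.signature_bump,
                 beta_delta_nr=0.0)
        )
    k = 0
    for i in range(n_model):
        if i < design.n_pos:
            beta, base, role = design.beta_effect, design.baseline_effect_log_mean, "pos"
        elif i < design.n_pos + design.n_neg:
            beta, base, role = -design.beta_effect, design.baseline_effect_log_mean, "neg"
        else:
            beta = 0.0
            base = rng.normal(design.baseline_null_log_mean, design.baseline_null_log_sd)
            role = "null"
        delta = 0.0
        if role == "null" and k < design.n_delta:
            delta, k = design.beta_delta_nr, k + 1
            base = design.baseline_effect_log_mean
        genes.append(
            dict(gene=f"g{i:04d}", baseline_log_mean=base, beta_true=beta,
                 dispersion=design.dispersion, is_signature_gene=False,
                 signature_bump=0.0, beta_delta_nr=delta)
        )
    sections = []
    for tumor, group in design.tumors:
        for s in range(design.sections_per_tumor):
            sections.append(
                dict(section_id=f"{tumor}_s{s}", tumor_id=tumor, group=group,
                     sample_effect=float(rng.normal(0.0, design.sample_effect_sd)))
            )
    return SyntheticTruth(
        genes=pd.DataFrame(genes),
        sections=pd.DataFrame(sections),
        seed=seed,
        bleed_fraction=design.bleed_fraction,
        d_cap=design.d_cap,
    )


def simulate_study(design: StudyDesign, seed: int) -> StudyData:
    """Simulate all sections of a study; deterministic given ``seed``."""
    root = np.random.SeedSequence(seed)
    truth_seed, *sec_seeds = [
        int(s.generate_state(1)[0] % 2**31)
        for s in root.spawn(1 + len(design.tumors) * design.sections_per_tumor)
    ]
    truth = build_truth(design, truth_seed)
    grids, counts_list, masks, ann_rows = [], [], [], []
    for (sec_row, sseed) in zip(truth.sections.itertuples(), sec_seeds):
        child = np.random.SeedSequence(sseed)
        g_seed, f_seed, c_seed = [
            int(s.generate_state(1)[0] % 2**31) for s in child.spawn(3)
        ]
        grid = make_hex_grid(design.n_rows, design.n_cols, design.spacing_um,
                             sec_row.section_id)
        grid = simulate_brightness(
            grid, g_seed,
            mu_tissue=design.brightness_mu_tissue,
            sigma=design.brightness_sigma,
            mu_light=design.brightness_mu_light,
            light_fraction=design.brightness_light_fraction,
        )
        mask = place_foci(grid, design.n_foci, design.focus_radius, f_seed)
        cm = simulate_counts(grid, truth, mask, rng=np.random.default_rng(c_seed))
        t = grid.table
        margin = design.stroma_margin
        border = (
            (t["array_row"] < margin)
            | (t["array_row"] >= design.n_rows - margin)
            | (t["array_col"] // 2 < margin)
            | (t["array_col"] // 2 >= design.n_cols - margin)
        ).to_numpy()
        ann_rows.append(
            pd.DataFrame(
                {
                    "spot_id": t["spot_id"],
                    "section_id": sec_row.section_id,
                    "sample_id": sec_row.section_id,
                    "tumor_id": sec_row.tumor_id,
                    "group": sec_row.group,
                    "compartment": np.where(border, "stroma", "tumor"),
                    "pathology_class": np.where(border, "non-cancer", "cancer"),
                    "cluster": np.where(mask, "focus",
                                        np.where(border, "stroma", "tumor_core")),
                }
            )
        )
        grids.append(t)
        counts_list.append(cm)
        masks.append(mask)
    grid = SpotGrid(pd.concat(grids, ignore_index=True))
    counts = CountMatrix(
        counts_list[0].genes,
        np.concatenate([c.spots for c in counts_list]),
        sp.hstack([c.counts for c in counts_list]).tocsr(),
    )
    return StudyData(
        grid=grid,
        counts=counts,
        annotations=pd.concat(ann_rows, ignore_index=True),
        truth=truth,
        focus_mask=np.concatenate(masks),
    )


def apply_qc(data: StudyData, params: PipelineParams) -> tuple[StudyData, io_qc.QCReport]:
    """Run the spot QC filters and subset the study to retained spots."""
    mask, report = io_qc.run_spot_qc(
        data.grid, data.counts,
        min_genes=params.min_genes,
        k_sd_brightness=params.k_sd_brightness,
        min_component=params.min_component,
    )
    kept = data.grid.table.loc[mask].reset_index(drop=True)
    sub = StudyData(
        grid=SpotGrid(kept),
        counts=data.counts.subset_spots(kept["spot_id"]),
        annotations=data.annotations[
            data.annotations["spot_id"].isin(kept["spot_id"])
        ].reset_index(drop=True),
        truth=data.truth,
        focus_mask=data.focus_mask[np.asarray(mask, bool)],
    )
    return sub, report


def run_group_model(
    data: StudyData,
    group: str,
    params: PipelineParams,
    gene_set: tuple[str, ...] | None = None,
    scores: SignatureScores | None = None,
) -> dict:
    """Score, classify, compute distances and fit per-gene models for one group.

    ``data`` should already be QC-filtered.  Thresholds and distances are
    per section; only sections of ``group`` enter the fit.
    """
    gene_set = tuple(gene_set) if gene_set is not None else data.truth.signature_genes
    sec_groups = data.truth.sections.set_index("section_id")["group"]
    group_secs = [s for s in data.grid.sections if sec_groups.get(s) == group]
    if not group_secs:
        raise ValueError(f"no sections in group {group!r}")
    sub_tab = data.grid.table[data.grid.table["section_id"].isin(group_secs)]
    grid = SpotGrid(sub_tab.reset_index(drop=True))
    counts = data.counts.subset_spots(grid.spot_ids)

    if scores is None:
        scores = rank_signature_score(counts, gene_set, r_max=params.r_max)
    cls = classify_spots(scores, grid, k_sd=params.high_k_sd)
    dist = spatial_model.nearest_high_distance(grid, cls)
    modeling = spatial_model.restrict_modeling_set(
        dist, data.annotations, d_max=params.d_max
    )
    dist_m = dist[dist["spot_id"].isin(modeling)].reset_index(drop=True)
    adj = spatial_model.adjust_signature_scores(scores, dist_m)
    sample_ids = data.annotations.set_index("spot_id")["sample_id"]
    models = spatial_model.fit_distance_models(
        counts, list(modeling), dist_m, sample_ids, adj, group,
        signature_genes=gene_set, min_detect_frac=params.min_detect_frac,
    )
    models = spatial_model.call_significant(
        models, alpha=params.alpha, k_sd=params.k_sd_coef
    )
    return {
        "scores": scores,
        "classification": cls,
        "distances": dist,
        "modeling_spots": modeling,
        "adjusted_scores": adj,
        "models": models,
    }
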