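"""Shared fixtures: small grids and a reusable QC'd synthetic study."""

import numpy as np
import pandas as pd
import pytest

from spotdist import PipelineParams, StudyDesign, apply_qc, simulate_study
from spotdist.synthetic import make_hex_grid


@pytest.fixture
def grid10():
    return make_hex_grid(10, 10, 100.0, "s1")


@pytest.fixture(scope="session")
def small_study():
    """Two-group study on small sections, QC'd; reused by read-only tests."""
    design = StudyDesign(
        n_rows=22, n_cols=22,
        tumors=(("t1", "R"), ("t2", "R"), ("t3", "NR"), ("t4", "NR")),
    )
    data = simulate_study(design, seed=42)
    qc, report = apply_qc(data, PipelineParams())
    return {"design": design, "raw": data, "qc": qc, "report": report}


def brute_force_nearest(low_pos, high_pos, spacing):
    """All-pairs minimum-distance oracle (O(n*m)), in spot-length units."""
    low_pos = np.asarray(low_pos, float)
    high_pos = np.asarray(high_pos, float)
    out = np.empty(len(low_pos))
    for i, p in enumerate(low_pos):
        out[i] = np.sqrt(((high_pos - p) ** 2).sum(axis=1)).min()
    return out / spacing


def brute_force_score(counts_dense, gene_idx, n_genes_total, r_max):
    """Independent rank-score oracle: counting-based ranks, no rankdata.

    For each spot, the decreasing-expression rank of gene g is
    (# genes strictly greater) + (# tied genes + 1) / 2; ranks are capped at
    r_max + 1 and plugged into the Mann-Whitney score formula.
    """
    n_sig = len(gene_idx)
    n_spots = counts_dense.shape[1]
    scores = np.empty(n_spots)
    for s in range(n_spots):
        col = counts_dense[:, s]
        total = 0.0
        for g in gene_idx:
            v = col[g]
            rank = (col > v).sum() + ((col == v).sum() + 1) / 2.0
            total += min(rank, r_max + 1)
        u = total - n_sig * (n_sig + 1) / 2.0
        scores[s] = max(0.0, 1.0 - u / (n_sig * r_max))
    return scores


def bfs_components(table, mask):
    """Flood-fill connected components over hex adjacency; returns labels."""
    from spotdist.hexgrid import NEIGHBOR_OFFSETS

    idx = {
        (s, int(r), int(c)): i
        for i, (s, r, c) in enumerate(
            zip(table["section_id"], table["array_row"], table["array_col"])
        )
        if mask[i]
    }
    labels = {}
    comp = 0
    for key in idx:
        if key in labels:
            continue
        stack = [key]
        labels[key] = comp
        while stack:
            s, r, c = stack.pop()
            for dr, dc in NEIGHBOR_OFFSETS:
                nb = (s, r + dr, c + dc)
                if nb in idx and nb not in labels:
                    labels[nb] = comp
                    stack.append(nb)
        comp += 1
    out = np.full(len(table), -1)
    for key, lab in labels.items():
        out[idx[key]] = lab
    return out
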