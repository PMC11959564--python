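"""Rank-based gene-signature scoring and signature-high/low spot calling.

Scores follow the UCell-style Mann–Whitney U statistic: within each spot all
genes are ranked by decreasing expression (ties get average ranks), ranks
are capped at ``r_max + 1``, and the signature score is::

    U' = sum of capped ranks of signature genes - n_sig * (n_sig + 1) / 2
    score = max(0, 1 - U' / (n_sig * r_max))

Scores live in [0, 1] and depend only on within-spot ranks, so any per-spot
monotone transform of expression (e.g. depth normalization) leaves them
unchanged.  Signature genes absent from the matrix stay in the set and are
treated as undetected (rank ``r_max + 1``).

Spot classification uses per-section thresholds: a spot is signature-HIGH
if its score is >= median + 1.5 SD of the section's score distribution, LOW
if <= the median, and EXCLUDED in between.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import CountMatrix, SpotGrid

#: Cholesterol-pathway core genes packaged as an example signature
#: (transcriptional regulation, biosynthesis and transport of cholesterol
#: in mouse tumor cells).
CHOLESTEROL_CORE = (
    "Hmgcs1",
    "Nsdhl",
    "Ch25h",
    "Insig1",
    "Fdps",
    "Sqle",
    "Fdft1",
    "Cyp51",
    "Osbp",
)

HIGH, LOW, EXCLUDED = "HIGH", "LOW", "EXCLUDED"


@dataclass
class SignatureScores:
    """Per-spot scores in [0, 1] for one gene signature."""

    name: str
    gene_set: tuple[str, ...]
    r_max: int
    scores: pd.Series  # indexed by spot_id


@dataclass
class SpotClassification:
    """HIGH/LOW/EXCLUDED labels with the per-section thresholds used."""

    labels: pd.Series  # indexed by spot_id
    thresholds: pd.DataFrame  # section_id, median, sd, high_cutoff

    def spots(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


def read_gene_set(path: str | Path) -> tuple[str, ...]:
    """Plain-text gene set, one gene per line; blank lines and '#' comments skipped."""
    lines = Path(path).read_text().splitlines()
    genes = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    if not genes:
        raise ValueError(f"gene set file {path} is empty")
    return tuple(genes)


def read_gene_set_table(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Named-set table with columns (set_name, gene) -> {name: genes}."""
    table = pd.read_csv(path)
    missing = {"set_name", "gene"} - set(table.columns)
    if missing:
        raise ValueError(f"gene set table missing columns: {sorted(missing)}")
    return {
        name: tuple(sub["gene"]) for name, sub in table.groupby("set_name", sort=False)
    }


def rank_signature_score(
    counts: CountMatrix,
    gene_set,
    r_max: int = 1500,
    name: str = "signature",
) -> SignatureScores:
    """Score a gene set per spot by the capped-rank Mann–Whitney statistic."""
    gene_set = tuple(gene_set)
    if len(gene_set) == 0:
        raise ValueError("gene set is empty")
    n_sig = len(gene_set)
    if r_max < n_sig:
        raise ValueError(f"r_max={r_max} must be >= signature size {n_sig}")

    x = counts.dense().astype(float)
    # Decreasing-expression ranks per spot, average ranks on ties.
    ranks = rankdata(-x, axis=0, method="average")
    capped = np.minimum(ranks, r_max + 1)

    gene_index = pd.Index(counts.genes)
    locs = gene_index.get_indexer(gene_set)
    present = locs >= 0
    rank_sum = capped[locs[present], :].sum(axis=0) if present.any() else 0.0
    rank_sum = rank_sum + (~present).sum() * (r_max + 1)  # absent genes: worst rank

    u = rank_sum - n_sig * (n_sig + 1) / 2.0
    score = np.maximum(0.0, 1.0 - u / (n_sig * r_max))
    return SignatureScores(
        name=name,
        gene_set=gene_set,
        r_max=r_max,
        scores=pd.Series(score, index=pd.Index(counts.spots, name="spot_id")),
    )


def classify_spots(
    scores: SignatureScores | pd.Series,
    grid: SpotGrid,
    k_sd: float = 1.5,
) -> SpotClassification:
    """Call HIGH/LOW/EXCLUDED per spot using per-section score thresholds.

    HIGH: score >= median + k_sd * SD; LOW: score <= median; the band in
    between is EXCLUDED.  When a section's SD is zero the two rules overlap;
    the HIGH rule takes precedence, so every spot is HIGH.  Thresholds use
    the score distribution of that section's scored spots only.
    """
    s = scores.scores if isinstance(scores, SignatureScores) else scores
    t = grid.table
    missing = [sid for sid in t["spot_id"] if sid not in s.index]
    if missing:
        raise ValueError(f"scores missing for spots: {missing[:5]}")
    labels = pd.Series(index=pd.Index(t["spot_id"].to_numpy(), name="spot_id"),
                       dtype=object)
    rows = []
    for sec in grid.sections:
        ids = t.loc[t["section_id"] == sec, "spot_id"].to_numpy()
        if len(ids) < 2:
            raise ValueError(f"section {sec!r} has < 2 spots; cannot set thresholds")
        vals = s.loc[ids].to_numpy(dtype=float)
        med = float(np.median(vals))
        sd = float(np.std(vals, ddof=1))
        cutoff = med + k_sd * sd
        lab = np.where(vals >= cutoff, HIGH, np.where(vals <= med, LOW, EXCLUDED))
        labels.loc[ids] = lab
        rows.append({"section_id": sec, "median": med, "sd": sd, "high_cutoff": cutoff})
    return SpotClassification(labels=labels, thresholds=pd.DataFrame(rows))
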