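"""Homoeolog triad expression bias and hexaploid-vs-ancestor divergence.

Triad bias follows the seven-centroid scheme on the simplex of A/B/D
expression fractions (balanced, three dominant, three suppressed).
Divergence between a hexaploid gene and its ancestor counterpart is the
Pearson correlation of their stage profiles, clustered into
dysfunction/middle/conserved by deterministic 1-D k-means (or fixed
thresholds).  TE-in-promoter enrichment contrasts gene sets by presence of a
transposable element in a strand-aware upstream window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Genome, overlaps_any
from .stats import TestResult, fisher_exact, pearson_test
from .matrix import StageMatrix

TRIAD_CENTROIDS = {
    "balanced": np.array([1, 1, 1]) / 3.0,
    "A-dominant": np.array([1.0, 0.0, 0.0]),
    "B-dominant": np.array([0.0, 1.0, 0.0]),
    "D-dominant": np.array([0.0, 0.0, 1.0]),
    "A-suppressed": np.array([0.0, 0.5, 0.5]),
    "B-suppressed": np.array([0.5, 0.0, 0.5]),
    "D-suppressed": np.array([0.5, 0.5, 0.0]),
}


@dataclass
class TriadRecord:
    triad_id: str
    genes: tuple[str, str, str]
    stage: str                      # stage label or "pooled"
    fractions: tuple | None
    category: str | None
    expressed: bool


@dataclass
class DivergenceRecord:
    gene_id: str
    ancestor_id: str
    r: float
    cluster: str | None             # None when r is undefined


def classify_fractions(fractions) -> str:
    """Nearest-centroid triad category; exact ties resolve to balanced."""
    f = np.asarray(fractions, dtype=float)
    dists = {cat: float(np.linalg.norm(f - c))
             for cat, c in TRIAD_CENTROIDS.items()}
    dmin = min(dists.values())
    winners = [cat for cat, d in dists.items() if d <= dmin + 1e-12]
    return "balanced" if "balanced" in winners else min(winners)


def classify_triads(expr: StageMatrix, triad_map: pd.DataFrame,
                    stage: str = "pooled",
                    min_mean_tpm: float = 0.5) -> list[TriadRecord]:
    """Per-triad A/B/D expression fractions and nearest-centroid category.

    A triad is expressed when the mean expression over its three members
    (pooled over stages, or at the requested stage) reaches min_mean_tpm;
    unexpressed triads carry no category.
    """
    means = expr.stage_means()
    if stage != "pooled" and stage not in expr.stages:
        raise ValueError(f"unknown stage {stage!r}")
    out = []
    for row in triad_map.itertuples(index=False):
        genes = (row.A, row.B, row.D)
        if any(g not in means.index for g in genes):
            continue  # incomplete triad: skipped
        if stage == "pooled":
            vals = means.loc[list(genes)].mean(axis=1).values
        else:
            vals = means.loc[list(genes), stage].values
        mean_tpm = float(vals.mean())
        if mean_tpm < min_mean_tpm or vals.sum() == 0:
            out.append(TriadRecord(row.triad_id, genes, stage, None, None,
                                   False))
            continue
        frac = vals / vals.sum()
        out.append(TriadRecord(row.triad_id, genes, stage,
                               tuple(float(x) for x in frac),
                               classify_fractions(frac), True))
    return out


def _kmeans_1d(values: np.ndarray, k: int = 3,
               max_iter: int = 200) -> np.ndarray:
    """Deterministic 1-D Lloyd k-means: centers start at min/median/max."""
    centers = np.array([np.min(values), np.median(values), np.max(values)])
    labels = np.zeros(values.size, dtype=int)
    for _ in range(max_iter):
        d = np.abs(values[:, None] - centers[None, :])
        new_labels = d.argmin(axis=1)
        if (new_labels == labels).all() and _ > 0:
            break
        labels = new_labels
        for j in range(k):
            sel = labels == j
            if sel.any():
                centers[j] = values[sel].mean()
    return labels


def divergence_classify(hex_expr: StageMatrix, ancestor_expr: StageMatrix,
                        pair_map: dict[str, str] | None = None,
                        method: str = "kmeans3",
                        thresholds: tuple[float, float] = (0.3, 0.7)
                        ) -> list[DivergenceRecord]:
    """Pearson r per gene/ancestor pair, clustered into
    dysfunction < middle < conserved.

    ``pair_map`` maps hexaploid gene id -> ancestor row id (identity by
    default).  ``method`` is ``kmeans3`` (1-D k-means, deterministic
    min/median/max seeding, labels ordered by cluster mean) or ``threshold``
    (r < t1 -> dysfunction, r > t2 -> conserved, else middle).  Pairs with
    undefined correlation are flagged with cluster None and excluded from
    clustering.
    """
    hex_means = hex_expr.stage_means()
    anc_means = ancestor_expr.stage_means()
    if len(hex_expr.stages) < 3:
        raise ValueError("need >= 3 stages")
    if pair_map is None:
        pair_map = {g: g for g in hex_means.index if g in anc_means.index}
    records, rs = [], []
    for gid, anc_id in sorted(pair_map.items()):
        res = pearson_test(hex_means.loc[gid].values,
                           anc_means.loc[anc_id].values)
        if res.undefined:
            records.append(DivergenceRecord(gid, anc_id, float("nan"), None))
        else:
            records.append(DivergenceRecord(gid, anc_id, res.statistic, ""))
            rs.append(res.statistic)
    defined = [rec for rec in records if rec.cluster == ""]
    rvals = np.array(rs)
    if defined:
        if method == "kmeans3":
            labels = _kmeans_1d(rvals, 3)
            occupied = [j for j in range(3) if (labels == j).any()]
            occupied.sort(key=lambda j: rvals[labels == j].mean())
            # fewer than three distinct clusters: keep the extremes first
            names = {1: ["conserved"],
                     2: ["dysfunction", "conserved"],
                     3: ["dysfunction", "middle", "conserved"]}[len(occupied)]
            name_of = {j: names[i] for i, j in enumerate(occupied)}
            for rec, lab in zip(defined, labels):
                rec.cluster = name_of[int(lab)]
        elif method == "threshold":
            t1, t2 = thresholds
            for rec in defined:
                rec.cluster = ("dysfunction" if rec.r < t1 else
                               "conserved" if rec.r > t2 else "middle")
        else:
            raise ValueError(f"unknown method {method!r}")
    return records


def te_promoter_enrichment(gene_set_a, gene_set_b, genome: Genome,
                           window: tuple[int, int] = (1500, 3000)
                           ) -> tuple[TestResult, dict]:
    """Fisher test (greater) of TE presence in the strand-aware upstream
    window [TSS - hi, TSS - lo) for set A vs set B."""
    lo, hi = window
    if lo >= hi:
        raise ValueError("degenerate window: lo >= hi")
    genes = {g.gene_id: g for g in genome.genes}

    def window_iv(gid):
        g = genes[gid]
        if g.strand == "+":
            s, e = g.tss - hi, g.tss - lo
        else:
            s, e = g.tss + lo, g.tss + hi
        s = max(0, s)
        e = min(genome.chrom_sizes[g.chrom], e)
        return GenomicInterval(g.chrom, s, e) if s < e else None

    def has_te_count(gene_set):
        wins = [window_iv(g) for g in gene_set if g in genes]
        wins = [w for w in wins if w is not None]
        n = len(wins)
        k = int(overlaps_any(wins, genome.tes).sum()) if wins else 0
        return k, n

    ka, na = has_te_count(gene_set_a)
    kb, nb = has_te_count(gene_set_b)
    res = fisher_exact(ka, na - ka, kb, nb - kb, alternative="greater")
    freq = {"A": ka / na if na else float("nan"),
            "B": kb / nb if nb else float("nan"),
            "A_with_te": ka, "A_total": na,
            "B_with_te": kb, "B_total": nb}
    return res, freq


def triad_balance_timecourse(expr: StageMatrix, triad_map: pd.DataFrame,
                             min_mean_tpm: float = 0.5) -> pd.DataFrame:
    """Stage x category table of triad counts (plus not-expressed), with
    per-stage fractions over expressed triads summing to 1."""
    cats = list(TRIAD_CENTROIDS) + ["not-expressed"]
    counts = pd.DataFrame(0, index=expr.stages, columns=cats)
    for stage in expr.stages:
        for rec in classify_triads(expr, triad_map, stage, min_mean_tpm):
            counts.loc[stage, rec.category or "not-expressed"] += 1
    expressed = counts[list(TRIAD_CENTROIDS)].sum(axis=1)
    fractions = counts[list(TRIAD_CENTROIDS)].div(
        expressed.replace(0, np.nan), axis=0)
    fractions.columns = [f"frac_{c}" for c in fractions.columns]
    return pd.concat([counts, fractions], axis=1)
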