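"""TF->target regulatory-network inference.

Candidate edges come from motif hits falling inside gene-assigned accessible
regions; motifs are first screened for enrichment in the ACR set of interest
(Fisher, greater), and candidate TF-target pairs are retained only when
their stage-mean expression profiles co-vary significantly (Pearson
p < alpha, positive r by default).  TF families collapse into modules and a
TF-TF subnetwork can be extracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acr import AnnotatedPeak
from .intervals import GenomicInterval, overlap_pairs
from .matrix import StageMatrix
from .stats import fisher_exact, pearson_test

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    tf_gene_id: str
    interval: GenomicInterval
    score: float = 0.0


@dataclass
class RegEdge:
    tf_gene_id: str
    target_gene_id: str
    acr_id: str | None
    motif_id: str
    r: float
    p_value: float

    def __post_init__(self):
        if self.tf_gene_id == self.target_gene_id:
            raise ValueError("self-edge")


def hits_from_frame(df: pd.DataFrame) -> list[MotifHit]:
    """MotifHits from a table with motif_id, tf_gene_id, chrom, start, end."""
    return [
        MotifHit(row.motif_id, row.tf_gene_id,
                 GenomicInterval(row.chrom, int(row.start), int(row.end)),
                 float(getattr(row, "score", 0.0)))
        for row in df.itertuples(index=False)
    ]


def motif_enrichment(cluster_acrs: list[AnnotatedPeak],
                     background_acrs: list[AnnotatedPeak],
                     hits: list[MotifHit],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-motif Fisher test (greater) of hit-bearing ACRs, cluster vs
    background; motifs with p < alpha are flagged enriched."""
    if not cluster_acrs:
        raise ValueError("empty cluster")
    cl_iv = [p.interval for p in cluster_acrs]
    bg_iv = [p.interval for p in background_acrs]
    motifs = sorted({h.motif_id for h in hits})
    rows = []
    for motif in motifs:
        m_iv = [h.interval for h in hits if h.motif_id == motif]
        cl_hit = len({i for i, _ in overlap_pairs(cl_iv, m_iv)})
        bg_hit = len({i for i, _ in overlap_pairs(bg_iv, m_iv)})
        if cl_hit == 0 and bg_hit == 0:
            log.info("motif %s has zero hits in cluster and background; "
                     "skipped", motif)
            continue
        res = fisher_exact(cl_hit, len(cl_iv) - cl_hit,
                           bg_hit, len(bg_iv) - bg_hit,
                           alternative="greater")
        rows.append({"motif_id": motif, "cluster_hits": cl_hit,
                     "background_hits": bg_hit, "odds_ratio": res.effect,
                     "p_value": res.p_value,
                     "enriched": res.p_value < alpha})
    return pd.DataFrame(rows)


def link_tf_targets(enriched_motifs, hits: list[MotifHit],
                    annotated_peaks: list[AnnotatedPeak],
                    expr: StageMatrix, alpha: float = 0.05,
                    positive_only: bool = True) -> list[RegEdge]:
    """Join motif hits to gene-assigned ACRs and keep co-expressed pairs.

    A candidate exists for every hit of an enriched motif inside an ACR with
    an assigned gene; the pair is retained iff the Pearson test between TF
    and target stage-mean profiles gives p < alpha (and r > 0 when
    positive_only).  One edge per (tf, target), smallest p wins.
    """
    enriched = set(enriched_motifs)
    means = expr.stage_means()
    gene_set = set(means.index)
    assigned = [(p.interval, p.assigned_gene, p.interval.name)
                for p in annotated_peaks if p.assigned_gene is not None]
    acr_iv = [a[0] for a in assigned]
    hit_iv = [h.interval for h in hits]
    pair_map = overlap_pairs(acr_iv, hit_iv)

    best: dict[tuple[str, str], RegEdge] = {}
    for acr_i, hit_i in pair_map:
        hit = hits[hit_i]
        if hit.motif_id not in enriched:
            continue
        _, target, acr_id = assigned[acr_i]
        tf = hit.tf_gene_id
        if tf == target:
            continue
        if tf not in gene_set:
            log.info("TF %s absent from expression matrix; candidate dropped",
                     tf)
            continue
        if target not in gene_set:
            continue
        res = pearson_test(means.loc[tf].values, means.loc[target].values)
        if res.undefined:
            continue
        if res.p_value >= alpha:
            continue
        if positive_only and res.statistic <= 0:
            continue
        key = (tf, target)
        if key not in best or res.p_value < best[key].p_value:
            best[key] = RegEdge(tf, target, acr_id, hit.motif_id,
                                float(res.statistic), float(res.p_value))
    return [best[k] for k in sorted(best)]


def collapse_tf_modules(edges: list[RegEdge],
                        family_map: dict[str, str]) -> pd.DataFrame:
    """Module-level edges: one row per (family-or-singleton TF, target) with
    the member-edge count as weight."""
    rows: dict[tuple[str, str], int] = {}
    for e in edges:
        module = family_map.get(e.tf_gene_id, e.tf_gene_id)
        key = (module, e.target_gene_id)
        rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [(m, t, w) for (m, t), w in sorted(rows.items())],
        columns=["module", "target_gene_id", "weight"])


def tf_tf_subnetwork(edges: list[RegEdge], tf_set,
                     activation_stage: dict[str, str] | None = None
                     ) -> list[RegEdge]:
    """Edges whose target is itself a TF; optionally attach per-node
    first-activation stages (returned as edge attributes via a frame)."""
    tfs = set(tf_set)
    sub = [e for e in edges if e.target_gene_id in tfs]
    if activation_stage is not None:
        for e in sub:
            e.tf_activation = activation_stage.get(e.tf_gene_id)
            e.target_activation = activation_stage.get(e.target_gene_id)
    return sub


def edges_to_frame(edges: list[RegEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.tf_gene_id, e.target_gene_id, e.acr_id, e.motif_id, e.r,
          e.p_value) for e in edges],
        columns=["tf", "target", "acr", "motif", "r", "p"])


def first_activation_stages(expr: StageMatrix,
                            z_threshold: float = 1.0) -> dict[str, str]:
    """First stage where each gene's z-scored stage-mean profile reaches the
    threshold (expression-timing attribute for network nodes)."""
    z = expr.zscored_stage_means()
    out = {}
    for gid, row in z.iterrows():
        above = np.nonzero(row.values >= z_threshold)[0]
        out[gid] = expr.stages[int(above[0])] if above.size else None
    return out
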