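"""ACR taxonomy and stage dynamics.

Classifies accessible chromatin regions into promoter (pACR), gene-body
(gACR) and distal (dACR) classes, tracks gain/loss between adjacent stages,
separates transient from constant distal ACRs around a burst stage, computes
observed/expected enrichment against shuffled backgrounds, filters ncRNA
transcripts by coding-gene overlap, and compares collinear binned signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import (
    GenomicInterval, Genome, assign_peak_to_gene, overlaps_any,
    shuffle_intervals,
)
from .stats import fisher_exact

# gene-linked assignment categories folded into the three-way ACR taxonomy;
# downstream-assigned peaks count as distal so the taxonomy stays a partition
_GENIC = {"exon", "intron", "5UTR", "3UTR"}


@dataclass
class AnnotatedPeak:
    interval: GenomicInterval
    category: str                  # pACR | gACR | dACR
    assigned_gene: str | None
    stage: str | None = None

    def __post_init__(self):
        if (self.category == "dACR") != (self.assigned_gene is None):
            raise ValueError("dACR iff no assigned gene")


@dataclass
class EnrichmentResult:
    observed: int
    expected_mean: float
    obs_exp_ratio: float           # inf / nan flags for degenerate cases
    p_value: float
    n_shuffles: int
    seed: int


def classify_acrs(peaks, genome: Genome, stage: str | None = None,
                  up_bp: int = 3000, down_bp: int = 2500
                  ) -> list[AnnotatedPeak]:
    """Label every peak exactly once as pACR, gACR or dACR.

    pACR: assigned category is promoter; gACR: exon/intron/UTR; everything
    else (including downstream-window assignments) is distal.
    """
    out = []
    for p in peaks:
        gene, cat = assign_peak_to_gene(p, genome, up_bp, down_bp)
        if cat == "promoter":
            out.append(AnnotatedPeak(p, "pACR", gene, stage))
        elif cat in _GENIC:
            out.append(AnnotatedPeak(p, "gACR", gene, stage))
        else:
            out.append(AnnotatedPeak(p, "dACR", None, stage))
    return out


def stage_gain_loss(peaksets: dict[str, list[GenomicInterval]],
                    stage_order: list[str],
                    min_overlap_bp: int = 1) -> list[dict]:
    """Gain/loss between adjacent stages by >=1 bp overlap.

    A peak of stage s+1 with no overlap to any stage-s peak is gained;
    a stage-s peak with no overlap into s+1 is lost.
    """
    if len(stage_order) < 2:
        raise ValueError("need >= 2 stages")
    for s in stage_order:
        if s not in peaksets:
            raise ValueError(f"unknown stage label {s!r}")
    out = []
    for s_prev, s_next in zip(stage_order, stage_order[1:]):
        prev, nxt = peaksets[s_prev], peaksets[s_next]
        gained_mask = ~overlaps_any(nxt, prev, min_overlap_bp)
        lost_mask = ~overlaps_any(prev, nxt, min_overlap_bp)
        gained = [p for p, m in zip(nxt, gained_mask) if m]
        lost = [p for p, m in zip(prev, lost_mask) if m]
        out.append({"from": s_prev, "to": s_next,
                    "gained": len(gained), "lost": len(lost),
                    "gained_peaks": gained, "lost_peaks": lost})
    return out


def transient_dacrs(dacrs_prev, dacrs_burst, dacrs_next,
                    min_overlap_bp: int = 1):
    """Partition burst-stage distal ACRs into transient vs constant.

    Transient: present at the burst stage and overlapping nothing at either
    flanking stage; constant: overlapping the previous or the next stage.
    """
    in_prev = overlaps_any(dacrs_burst, dacrs_prev, min_overlap_bp)
    in_next = overlaps_any(dacrs_burst, dacrs_next, min_overlap_bp)
    transient, constant = [], []
    for p, a, b in zip(dacrs_burst, in_prev, in_next):
        (constant if (a or b) else transient).append(p)
    return transient, constant


def obs_exp_enrichment(query, features, background_domain,
                       n_shuffles: int = 100, seed: int = 0,
                       min_overlap_bp: int = 1) -> EnrichmentResult:
    """Observed/expected feature overlap of a query set vs shuffled placement.

    observed: query intervals with >= min_overlap_bp feature overlap.
    expected: mean of the same count over n_shuffles uniform placements of
    query-length intervals into the background domain.  The p-value pools all
    shuffles into one 2x2 Fisher table (overlap vs non-overlap, observed vs
    background), alternative=greater.
    """
    if not background_domain:
        raise ValueError("empty background domain")
    observed = int(overlaps_any(query, features, min_overlap_bp).sum())
    shuffles = shuffle_intervals(query, background_domain, seed, n_shuffles)
    bg_counts = np.array([
        int(overlaps_any(s, features, min_overlap_bp).sum())
        for s in shuffles])
    expected = float(bg_counts.mean())
    if expected > 0:
        ratio = observed / expected
    else:
        ratio = float("inf") if observed > 0 else float("nan")
    n = len(query)
    bg_hits = int(bg_counts.sum())
    res = fisher_exact(observed, n - observed,
                       bg_hits, n * n_shuffles - bg_hits,
                       alternative="greater")
    return EnrichmentResult(observed=observed, expected_mean=expected,
                            obs_exp_ratio=ratio, p_value=res.p_value,
                            n_shuffles=n_shuffles, seed=seed)


def ncrna_filter(transcripts, genome: Genome,
                 min_overlap_bp: int = 1) -> list[GenomicInterval]:
    """Keep transcripts with zero overlap to any coding gene span."""
    coding_spans = [g.span_interval for g in genome.genes
                    if g.biotype == "coding"]
    keep = ~overlaps_any(transcripts, coding_spans, min_overlap_bp)
    return [t for t, k in zip(transcripts, keep) if k]


def collinear_signal_compare(signal_a, signal_b, pseudocount: float = 1.0,
                             threshold: float = 1.0):
    """Per-bin Up/Dn/Nc status of signal_b relative to signal_a.

    log2fc = log2((b + pc) / (a + pc)); Up when >= threshold, Dn when
    <= -threshold, else Nc.
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("bin vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative signal")
    log2fc = np.log2((b + pseudocount) / (a + pseudocount))
    status = np.where(log2fc >= threshold, "Up",
                      np.where(log2fc <= -threshold, "Dn", "Nc"))
    return status.tolist(), log2fc
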