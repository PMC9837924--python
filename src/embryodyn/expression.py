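"""Expression normalization, differential thresholds, gene-set overlap
tests, binned fold-change correlation, ATAC-RNA synchronization and
per-stage mark contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import StageMatrix
from .stats import TestResult, bh_fdr, fisher_exact, pearson_test, \
    two_sample_log_test


@dataclass
class DiffResult:
    gene_id: str
    log2fc: float
    p_value: float
    fdr: float
    status: str  # Up | Dn | Nc


def tpm_normalize(counts: StageMatrix, gene_lengths_bp: dict | pd.Series
                  ) -> StageMatrix:
    """Transcripts-per-million: per column, count/length_kb rescaled to 1e6."""
    lengths = pd.Series(gene_lengths_bp, dtype=float).reindex(counts.gene_ids)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {missing!r}")
    if (lengths <= 0).any():
        raise ValueError("zero-length gene")
    rate = counts.df.div(lengths / 1000.0, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return StageMatrix(tpm, counts.stages, units="TPM")


def call_degs(matrix: StageMatrix, stage_a: str, stage_b: str,
              lfc_threshold: float = 1.0, fdr_threshold: float = 0.05
              ) -> list[DiffResult]:
    """Per-gene Welch test on log2(x+1) between two stages; BH FDR; status
    Up/Dn at |log2FC| >= 1 and FDR <= 0.05."""
    a = matrix.stage_values(stage_a)
    b = matrix.stage_values(stage_b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per stage")
    lfc, pvals = [], []
    for gid in matrix.gene_ids:
        res = two_sample_log_test(a.loc[gid].values, b.loc[gid].values)
        lfc.append(res.effect)
        pvals.append(res.p_value)
    qvals = bh_fdr(pvals)
    out = []
    for gid, fc, p, q in zip(matrix.gene_ids, lfc, pvals, qvals):
        if fc >= lfc_threshold and q <= fdr_threshold:
            status = "Up"
        elif fc <= -lfc_threshold and q <= fdr_threshold:
            status = "Dn"
        else:
            status = "Nc"
        out.append(DiffResult(gid, float(fc), float(p), float(q), status))
    return out


def set_overlap_test(set_a, set_b, universe) -> tuple[TestResult, float]:
    """Fisher (greater) on the 2x2 membership table plus fold enrichment
    over independence."""
    u = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= u or not b <= u:
        raise ValueError("sets must lie within the universe")
    n_ab = len(a & b)
    res = fisher_exact(n_ab, len(a - b), len(b - a), len(u - (a | b)),
                       alternative="greater")
    expected = len(a) * len(b) / len(u) if u else float("nan")
    fold = n_ab / expected if expected > 0 else float("nan")
    return res, fold


def binned_fc_correlation(primary: pd.Series, secondary: pd.Series,
                          n_bins: int = 50):
    """Rank genes by the primary metric, split into n_bins near-equal
    contiguous bins (earlier bins take the remainder), and Pearson-test the
    per-bin means of both metrics."""
    genes = primary.index
    if not genes.equals(secondary.index):
        secondary = secondary.reindex(genes)
        if secondary.isna().any():
            raise ValueError("gene universes differ")
    n = len(genes)
    if n_bins > n:
        raise ValueError("n_bins exceeds number of genes")
    order = primary.sort_values(kind="stable").index
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    bins_p, bins_s = [], []
    pos = 0
    for size in sizes:
        sel = order[pos:pos + size]
        bins_p.append(primary.loc[sel].mean())
        bins_s.append(secondary.loc[sel].mean())
        pos += size
    res = pearson_test(bins_p, bins_s)
    return pd.DataFrame({"bin_primary_mean": bins_p,
                         "bin_secondary_mean": bins_s}), res


def synchronization_detect(rna: StageMatrix, pacr_signal: StageMatrix,
                           baseline_stage: str | None = None,
                           r_min: float = 0.8, z_threshold: float = 1.0,
                           max_lag: int = 1) -> pd.DataFrame:
    """Genes whose RNA and promoter-accessibility activations coincide.

    A gene is synchronized iff both modalities cross z >= z_threshold after
    the baseline stage, the activation-stage lag is <= max_lag, and the
    Pearson r of the z-profiles is >= r_min.  Constant profiles are excluded.
    """
    stages = [s for s in rna.stages if s in pacr_signal.stages]
    if len(stages) < 3:
        raise ValueError("need >= 3 shared stages")
    base_idx = stages.index(baseline_stage) if baseline_stage else 0
    z_rna = rna.zscored_stage_means()[stages]
    z_atac = pacr_signal.zscored_stage_means()[stages]
    shared = z_rna.index.intersection(z_atac.index)

    def activation(zrow) -> int | None:
        for i in range(base_idx + 1, len(stages)):
            if zrow.iloc[i] >= z_threshold:
                return i
        return None

    rows = []
    for gid in shared:
        zr, za = z_rna.loc[gid], z_atac.loc[gid]
        ar, aa = activation(zr), activation(za)
        r = pearson_test(zr.values, za.values)
        sync = (ar is not None and aa is not None
                and abs(ar - aa) <= max_lag
                and not r.undefined and r.statistic >= r_min)
        rows.append({"gene_id": gid, "synchronized": bool(sync),
                     "rna_activation": stages[ar] if ar is not None else None,
                     "atac_activation": stages[aa] if aa is not None else None,
                     "r": r.statistic if not r.undefined else np.nan})
    return pd.DataFrame(rows).set_index("gene_id")


def mark_contribution(expr: StageMatrix,
                      mark_signals: dict[str, StageMatrix]) -> pd.DataFrame:
    """Squared Pearson r across genes between promoter mark signal and
    log2(TPM+1), per mark and stage.

    The r^2 operationalization treats positive and repressive marks
    symmetrically; the definition is recorded in the output attrs.
    """
    expr_means = np.log2(expr.stage_means() + 1.0)
    if expr_means.shape[0] < 3:
        raise ValueError("need >= 3 genes")
    out = {}
    for mark, sig in mark_signals.items():
        sig_means = sig.stage_means()
        shared = expr_means.index.intersection(sig_means.index)
        row = {}
        for stage in expr.stages:
            res = pearson_test(expr_means.loc[shared, stage].values,
                               sig_means.loc[shared, stage].values)
            row[stage] = np.nan if res.undefined else res.statistic ** 2
        out[mark] = row
    df = pd.DataFrame(out).T[list(expr.stages)]
    df.attrs["definition"] = "squared Pearson r across genes, per stage"
    return df
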