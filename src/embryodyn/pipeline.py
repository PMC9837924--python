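"""End-to-end orchestration: simulate -> annotate -> analyze, with seeds,
config hashing and a machine-readable run report.

A single global seed fans out to per-module streams by stable hashing of
module names, so adding a stage never perturbs another stage's randomness.
Every output file carries a header comment with the tool version and the
run-config hash; rerunning with the same seed reproduces every file
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acr import (classify_acrs, ncrna_filter, obs_exp_enrichment,
                  stage_gain_loss, transient_dacrs)
from .expression import (call_degs, mark_contribution, synchronization_detect,
                         tpm_normalize)
from .grn import (collapse_tf_modules, edges_to_frame,
                  first_activation_stages, hits_from_frame, link_tf_targets,
                  motif_enrichment, tf_tf_subnetwork)
from .intervals import GenomicInterval, merge_intervals, subtract_intervals
from .polyploidy import (classify_triads, divergence_classify,
                         triad_balance_timecourse)
from .pseudotime import angular_order, compute_dtu, order_heatmap_matrix
from .simulate import SimConfig, simulate_all, write_dataset


def module_seed(global_seed: int, module: str) -> int:
    """Stable per-module seed below 2^31 derived from the global seed."""
    h = hashlib.blake2b(f"{global_seed}:{module}".encode(),
                        digest_size=4).digest()
    return int.from_bytes(h, "big") % (2 ** 31)


def config_hash(config: SimConfig) -> str:
    text = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _write_frame(df: pd.DataFrame, path: Path, header: str,
                 index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def merged_acrs(atac_by_stage: dict[str, list[GenomicInterval]]
                ) -> list[GenomicInterval]:
    """Union ACR set across stages with stable sequential ids."""
    merged = merge_intervals(
        [iv for ivs in atac_by_stage.values() for iv in ivs])
    return [GenomicInterval(iv.chrom, iv.start, iv.end, ".", f"ACR{i:05d}")
            for i, iv in enumerate(merged)]


def background_marked_intergenic(peaks: dict, genome,
                                 flank_bp: int = 3000
                                 ) -> list[GenomicInterval]:
    """Intergenic intervals carrying any epigenetic modification: the merge
    of all mark peaks intersected with the gene-distal domain."""
    marks = [iv for mark in ("H3K27ac", "H3K27me3", "H3K9me2")
             for ivs in peaks[mark].values() for iv in ivs]
    distal = genome.intergenic_domain(flank_bp=flank_bp)
    covered = merge_intervals(marks)
    # intersection = covered minus (covered minus distal)
    return subtract_intervals(covered, subtract_intervals(covered, distal))


def run_all(seed: int, outdir: str | Path,
            sim_config: SimConfig | None = None,
            n_shuffles: int = 50) -> dict:
    """Full synthetic run: simulate, annotate, analyze; returns the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = sim_config or SimConfig(seed=seed)
    cfg.seed = seed
    tag = f"embryodyn v{__version__} config={config_hash(cfg)}"
    report = {"version": __version__, "seed": seed,
              "config_hash": config_hash(cfg),
              "parameters": asdict(cfg), "outputs": {}}

    def done(key, path, rows):
        report["outputs"][key] = {
            "path": str(Path(path).relative_to(outdir)), "rows": int(rows)}

    current: list[Path] = []
    try:
        # 1. simulate ---------------------------------------------------
        ds = simulate_all(cfg)
        sim_paths = write_dataset(ds, outdir / "simulated", header=tag)
        for key, p in sim_paths.items():
            if p.is_file():
                with open(p) as fh:
                    done(f"sim/{key}", p, sum(1 for _ in fh))
        genome, truth = ds.genome, ds.truth
        stages = list(cfg.stages)
        burst = cfg.burst_stage_index

        # 2. expression normalization -----------------------------------
        lengths = {g.gene_id: g.span[1] - g.span[0] for g in genome.genes}
        tpm = tpm_normalize(ds.expression.counts, lengths)
        p = outdir / "tpm.tsv"
        current = [p]
        tpm.to_tsv(p, header=tag)
        done("tpm", p, len(tpm.gene_ids))

        # 3. ACR annotation --------------------------------------------
        atac = ds.peaks.peaks["ATAC"]
        union = merged_acrs(atac)
        annotated = classify_acrs(union, genome)
        ann_df = pd.DataFrame(
            [(a.interval.name, a.interval.chrom, a.interval.start,
              a.interval.end, a.category, a.assigned_gene or "")
             for a in annotated],
            columns=["peak_id", "chrom", "start", "end", "category", "gene"])
        p = outdir / "acr_annotation.tsv"
        current = [p]
        _write_frame(ann_df, p, tag)
        done("acr_annotation", p, len(ann_df))

        per_stage_ann = {s: classify_acrs(atac[s], genome, stage=s)
                         for s in stages}

        # 4. stage dynamics ---------------------------------------------
        rows = []
        for cat in ("pACR", "dACR"):
            sets = {s: [a.interval for a in per_stage_ann[s]
                        if a.category == cat] for s in stages}
            for rec in stage_gain_loss(sets, stages):
                rows.append((cat, rec["from"], rec["to"], rec["gained"],
                             rec["lost"]))
        gl_df = pd.DataFrame(rows, columns=["category", "from", "to",
                                            "gained", "lost"])
        p = outdir / "gain_loss.tsv"
        current = [p]
        _write_frame(gl_df, p, tag)
        done("gain_loss", p, len(gl_df))

        # 5. transient vs constant distal ACRs ---------------------------
        dacr = {s: [a.interval for a in per_stage_ann[s]
                    if a.category == "dACR"] for s in stages}
        transient, constant = transient_dacrs(
            dacr[stages[burst - 1]], dacr[stages[burst]],
            dacr[stages[burst + 1]])
        tr_df = pd.DataFrame(
            [(iv.name, iv.chrom, iv.start, iv.end, "transient")
             for iv in transient]
            + [(iv.name, iv.chrom, iv.start, iv.end, "constant")
               for iv in constant],
            columns=["peak_id", "chrom", "start", "end", "status"])
        p = outdir / "transient_dacrs.tsv"
        current = [p]
        _write_frame(tr_df, p, tag)
        done("transient_dacrs", p, len(tr_df))

        # 6. TE enrichment against the marked intergenic background ------
        domain = background_marked_intergenic(ds.peaks.peaks, genome)
        enr_rows = []
        for label, query in (("transient", transient), ("constant", constant)):
            res = obs_exp_enrichment(
                query, genome.tes, domain, n_shuffles=n_shuffles,
                seed=module_seed(seed, f"enrich:{label}"))
            enr_rows.append((label, res.observed, res.expected_mean,
                             res.obs_exp_ratio, res.p_value, res.n_shuffles,
                             res.seed))
        enr_df = pd.DataFrame(enr_rows, columns=[
            "query", "observed", "expected_mean", "obs_exp_ratio", "p_value",
            "n_shuffles", "seed"])
        p = outdir / "te_enrichment.tsv"
        current = [p]
        _write_frame(enr_df, p, tag)
        done("te_enrichment", p, len(enr_df))

        # 7. ncRNA filter -------------------------------------------------
        nc_rows = []
        for s in stages:
            kept = ncrna_filter(ds.peaks.ncrna[s], genome)
            nc_rows.append((s, len(ds.peaks.ncrna[s]), len(kept)))
        nc_df = pd.DataFrame(nc_rows,
                             columns=["stage", "transcripts", "ncrna"])
        p = outdir / "ncrna_counts.tsv"
        current = [p]
        _write_frame(nc_df, p, tag)
        done("ncrna_counts", p, len(nc_df))

        # 8. adjacent-stage differential expression ----------------------
        deg_rows = []
        for s_prev, s_next in zip(stages, stages[1:]):
            for d in call_degs(tpm, s_prev, s_next):
                if d.status != "Nc":
                    deg_rows.append((s_prev, s_next, d.gene_id, d.log2fc,
                                     d.p_value, d.fdr, d.status))
        deg_df = pd.DataFrame(deg_rows, columns=[
            "from", "to", "gene", "log2fc", "p", "fdr", "status"])
        p = outdir / "degs.tsv"
        current = [p]
        _write_frame(deg_df, p, tag)
        done("degs", p, len(deg_df))

        # 9. pseudotime ----------------------------------------------------
        traj = compute_dtu(tpm)
        traj_df = pd.DataFrame(
            {"stage": stages, "dtu": traj.dtu,
             **{f"pc{i+1}": traj.pcs[:, i]
                for i in range(traj.pcs.shape[1])}})
        p = outdir / "trajectory.tsv"
        current = [p]
        _write_frame(traj_df, p, tag)
        done("trajectory", p, len(traj_df))

        orders = angular_order(tpm, traj)
        ord_df = pd.DataFrame(
            [(o.gene_id, o.angle, o.rank) for o in orders],
            columns=["gene", "angle", "rank"]).sort_values("rank")
        p = outdir / "gene_order.tsv"
        current = [p]
        _write_frame(ord_df, p, tag)
        done("gene_order", p, len(ord_df))

        heat = order_heatmap_matrix(orders)
        p = outdir / "order_heatmap.tsv"
        current = [p]
        _write_frame(heat, p, tag, index=True)
        done("order_heatmap", p, len(heat))

        # 10. GRN ----------------------------------------------------------
        hits = hits_from_frame(ds.peaks.motif_hits)
        rank_of = {o.gene_id: o.rank for o in orders}
        pacrs = [a for a in annotated if a.category == "pACR"]
        n_ranked = max(rank_of.values()) + 1 if rank_of else 1
        enriched: list[str] = []
        mot_frames = []
        for q in range(4):
            lo, hi = q * n_ranked / 4, (q + 1) * n_ranked / 4
            cluster = [a for a in pacrs
                       if a.assigned_gene in rank_of
                       and lo <= rank_of[a.assigned_gene] < hi]
            backgrd = [a for a in pacrs if a not in cluster]
            if not cluster:
                continue
            mdf = motif_enrichment(cluster, backgrd, hits)
            if len(mdf):
                mdf.insert(0, "cluster", q)
                mot_frames.append(mdf)
                enriched.extend(mdf.loc[mdf.enriched, "motif_id"])
        mot_df = (pd.concat(mot_frames, ignore_index=True)
                  if mot_frames else pd.DataFrame())
        p = outdir / "motif_enrichment.tsv"
        current = [p]
        _write_frame(mot_df, p, tag)
        done("motif_enrichment", p, len(mot_df))

        edges = link_tf_targets(sorted(set(enriched)), hits, annotated, tpm)
        edge_df = edges_to_frame(edges)
        p = outdir / "edges.tsv"
        current = [p]
        _write_frame(edge_df, p, tag)
        done("edges", p, len(edge_df))

        mod_df = collapse_tf_modules(edges, truth.tf_families)
        p = outdir / "module_edges.tsv"
        current = [p]
        _write_frame(mod_df, p, tag)
        done("module_edges", p, len(mod_df))

        activation = first_activation_stages(tpm)
        tf_edges = tf_tf_subnetwork(edges, set(truth.tf_families), activation)
        tft_df = edges_to_frame(tf_edges)
        tft_df["tf_activation"] = [e.tf_activation for e in tf_edges]
        tft_df["target_activation"] = [e.target_activation for e in tf_edges]
        p = outdir / "tf_tf_edges.tsv"
        current = [p]
        _write_frame(tft_df, p, tag)
        done("tf_tf_edges", p, len(tft_df))

        # 11. triads --------------------------------------------------------
        triad_map = ds.triad_map
        recs = classify_triads(tpm, triad_map)
        tri_df = pd.DataFrame(
            [(r.triad_id, r.stage, r.expressed,
              *(r.fractions or (np.nan,) * 3), r.category or "")
             for r in recs],
            columns=["triad_id", "stage", "expressed", "fA", "fB", "fD",
                     "category"])
        p = outdir / "triads.tsv"
        current = [p]
        _write_frame(tri_df, p, tag)
        done("triads", p, len(tri_df))

        tc = triad_balance_timecourse(tpm, triad_map)
        p = outdir / "triad_timecourse.tsv"
        current = [p]
        _write_frame(tc.reset_index(names="stage"), p, tag)
        done("triad_timecourse", p, len(tc))

        # 12. divergence ----------------------------------------------------
        div = divergence_classify(tpm, ds.expression.ancestor)
        div_df = pd.DataFrame(
            [(r.gene_id, r.ancestor_id, r.r, r.cluster or "undefined")
             for r in div],
            columns=["gene", "ancestor", "r", "cluster"])
        p = outdir / "divergence.tsv"
        current = [p]
        _write_frame(div_df, p, tag)
        done("divergence", p, len(div_df))

        # 13. ATAC-RNA synchronization --------------------------------------
        sync = synchronization_detect(tpm, ds.peaks.atac_signal)
        p = outdir / "synchronization.tsv"
        current = [p]
        _write_frame(sync.reset_index(), p, tag)
        done("synchronization", p, len(sync))

        # 14. mark contribution ---------------------------------------------
        contrib = mark_contribution(tpm, {
            "ATAC": ds.peaks.atac_signal,
            "H3K27ac": ds.peaks.k27ac_signal,
            "H3K27me3": ds.peaks.k27me3_signal,
        })
        p = outdir / "mark_contribution.tsv"
        current = [p]
        _write_frame(contrib.reset_index(names="mark"), p, tag)
        done("mark_contribution", p, len(contrib))

    except Exception:
        for p in current:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
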