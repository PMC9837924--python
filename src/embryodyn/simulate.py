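"""Deterministic miniature tri-subgenome embryogenesis dataset with planted
ground truth.

The generator emulates the structure of a time-course epigenome/transcriptome
study of a hexaploid embryo: eight ordered developmental stages with
replicated RNA counts and chromatin signal, homoeolog triads across the A/B/D
subgenomes with planted expression-bias categories, stage-ordered activation
waves, a planted TF->target network realised as motif hits inside
target-linked accessible regions, a transient burst of TE-overlapping distal
peaks at the middle (5th) stage with ncRNA emission, and ancestor expression
profiles with planted conserved/middle/dysfunction divergence.

Gene trajectories are stage-specific pulses: a fast logistic rise at the
gene's activation phase followed by a slower logistic decay.  Activation
order is therefore well defined, and the z-scored profiles of a phase-tiled
population trace the near-circular arrangement that angular ordering
exploits.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval, GeneModel, Genome,
    assign_peak_to_gene, merge_intervals, subtract_intervals,
    write_bed, write_gff3, write_chrom_sizes,
)
from .matrix import StageMatrix

log = logging.getLogger(__name__)

DEFAULT_STAGES = ("DPA0", "DPA2", "DPA4", "DPA6", "DPA8",
                  "DPA12", "DPA16", "DPA22")
TRIAD_CATEGORIES = ("balanced",
                    "A-dominant", "B-dominant", "D-dominant",
                    "A-suppressed", "B-suppressed", "D-suppressed")
DIVERGENCE_CLASSES = ("conserved", "middle", "dysfunction")
SUBGENOMES = ("A", "B", "D")

# target Pearson r planted for each divergence class
DIVERGENCE_RHO = {"conserved": 0.95, "middle": 0.5, "dysfunction": 0.0}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic dataset."""

    seed: int = 0
    chrom_length_bp: int = 2_000_000          # per subgenome
    n_triads: int = 500
    n_singletons: int = 100
    te_fraction: float = 0.4                  # of intergenic bp
    stages: tuple = DEFAULT_STAGES
    n_rna_replicates: int = 3
    n_atac_replicates: int = 2
    nb_dispersion: float = 0.1
    n_tf_families: int = 4
    tfs_per_family: int = 5
    targets_per_tf: int = 5
    transient_dacr_count: int = 200
    constant_dacr_count: int = 300
    background_dacr_count: int = 40           # per non-burst-window stage
    # TE-overlap rates mirror the ~75% (transient) vs ~40% (constant) contrast
    transient_te_overlap: float = 0.75
    constant_te_overlap: float = 0.40
    triad_category_fractions: dict = field(default_factory=lambda: {
        "balanced": 0.40,
        "A-dominant": 0.05, "B-dominant": 0.05, "D-dominant": 0.05,
        "A-suppressed": 0.15, "B-suppressed": 0.15, "D-suppressed": 0.15,
    })
    triad_fraction_noise_sd: float = 0.05
    divergence_fractions: dict = field(default_factory=lambda: {
        "conserved": 0.62, "middle": 0.30, "dysfunction": 0.08,
    })
    activation_phase_spread: float = 1.0
    staggered_phases: bool = False            # uniform phase tiling instead
                                              # of four discrete waves
    constitutive_median: float = 30.0         # median baseline expression;
                                              # 0 disables the baseline
    signal_noise_sd: float = 0.05             # relative, chromatin signal
    decoy_motif_hits: int = 40
    expressed_fraction_of_max: float = 0.25   # peak-presence threshold

    def validate(self) -> None:
        if len(self.stages) < 3:
            raise ValueError("need >= 3 stages")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("duplicate stage labels")
        for name, frac in (("triad_category_fractions",
                            self.triad_category_fractions),
                           ("divergence_fractions", self.divergence_fractions)):
            if abs(sum(frac.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for attr in ("n_triads", "n_singletons", "n_tf_families",
                     "tfs_per_family", "targets_per_tf",
                     "transient_dacr_count", "chrom_length_bp",
                     "n_rna_replicates", "n_atac_replicates"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if not 0 <= self.te_fraction < 1:
            raise ValueError("te_fraction must lie in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def burst_stage_index(self) -> int:
        return 4 if self.n_stages > 4 else self.n_stages // 2

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2 ** 31), stream])


@dataclass
class SimTruth:
    """Planted ground truth used as the acceptance oracle downstream."""

    phase_dtu: dict = field(default_factory=dict)       # gene -> [0, 10]
    edges: list = field(default_factory=list)           # [tf, target] pairs
    tf_families: dict = field(default_factory=dict)     # tf gene -> family
    peak_labels: dict = field(default_factory=dict)     # peak -> {...}
    transient_peaks: list = field(default_factory=list)
    constant_peaks: list = field(default_factory=list)
    triad_category: dict = field(default_factory=dict)  # triad -> label
    triad_fractions: dict = field(default_factory=dict) # triad -> [fA,fB,fD]
    divergence_label: dict = field(default_factory=dict)
    divergence_rho: dict = field(default_factory=dict)
    ncrna_provenance: dict = field(default_factory=dict) # ncrna -> peak name

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _pulse(s: np.ndarray, phase: float, w_rise: float, w_fall: float,
           decay: float) -> np.ndarray:
    """Stage-specific activation pulse: logistic rise, slower logistic decay."""
    rise = 1.0 / (1.0 + np.exp(-(s - phase) / w_rise))
    fall = 1.0 / (1.0 + np.exp(-(s - phase - decay) / w_fall))
    return np.clip(rise - fall, 0.0, None)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[Genome, SimTruth]:
    """Tile triad + singleton genes along three collinear subgenome
    chromosomes, place TEs in intergenic space, and pre-assign per-gene
    divergence labels (dysfunction genes preferentially receive a TE insert
    1.5-3 kb upstream of the TSS)."""
    config.validate()
    rng = config.rng(1)
    truth = SimTruth()

    n_per = [config.n_singletons // 3] * 3
    for i in range(config.n_singletons - sum(n_per)):
        n_per[i] += 1

    # per-slot draws shared across subgenomes (collinearity)
    n_slots = config.n_triads
    slot_strand = rng.choice(["+", "-"], size=n_slots)
    gene_len = rng.integers(900, 1301, size=(n_slots + max(n_per), 3))

    div_labels = list(config.divergence_fractions)
    div_p = np.array([config.divergence_fractions[k] for k in div_labels])

    genes: list[GeneModel] = []
    tes: list[GenomicInterval] = []
    chrom_sizes = {}

    for sg_i, sg in enumerate(SUBGENOMES):
        chrom = f"chr1{sg}"
        chrom_sizes[chrom] = config.chrom_length_bp
        entries = []  # (gene_id, triad_id, strand, length)
        for t in range(config.n_triads):
            entries.append((f"G{t:04d}{sg}", f"T{t:04d}", slot_strand[t],
                            int(gene_len[t, sg_i])))
        for k in range(n_per[sg_i]):
            entries.append((f"S{sg}{k:03d}", None,
                            "+" if (k % 2 == 0) else "-",
                            int(gene_len[config.n_triads + k, sg_i])))
        # interleave singletons deterministically among triad slots
        order = rng.permutation(len(entries))
        entries = [entries[i] for i in order]

        labels = rng.choice(div_labels, size=len(entries), p=div_p)
        # a planted upstream TE needs room, so TE planting implies a wide
        # 5' gap; the wide gap sits before a + gene and after a - gene
        wants_te = np.array([
            rng.random() < (0.7 if lab == "dysfunction" else 0.1)
            for lab in labels])
        wants_big = wants_te | (rng.random(len(entries)) < 0.08)
        pos = 1000
        planted_tes = []
        for idx, ((gid, triad, strand, length), label) in enumerate(
                zip(entries, labels)):
            truth.divergence_label[gid] = str(label)
            big = (strand == "+" and wants_big[idx]) or (
                idx > 0 and entries[idx - 1][2] == "-"
                and wants_big[idx - 1])
            gap = int(rng.integers(6500, 11501)) if big \
                else int(rng.integers(200, 601))
            pos += gap
            start, end = pos, pos + length
            if end + 1000 > config.chrom_length_bp:
                need = end + 1000
                raise ValueError(
                    f"genome too small for requested gene count: {chrom} needs "
                    f">= {need} bp")
            tss, tes_coord = (start, end) if strand == "+" else (end, start)
            if wants_te[idx]:
                if strand == "+":
                    te_s, te_e = tss - 2600, tss - 1800
                    te_s = max(te_s, pos - gap + 50)
                else:
                    # the wide gap follows this gene; keep only if it stays
                    # intergenic once every gene is placed
                    te_s, te_e = tss + 1800, tss + 2600
                    te_e = min(te_e, config.chrom_length_bp - 50)
                if te_e - te_s >= 200 and te_s >= 0:
                    planted_tes.append(GenomicInterval(chrom, te_s, te_e,
                                                       name="TEp"))
            a = start + int(0.40 * length)
            b = start + int(0.55 * length)
            feats = [
                ("exon", GenomicInterval(chrom, start, a, strand)),
                ("intron", GenomicInterval(chrom, a, b, strand)),
                ("exon", GenomicInterval(chrom, b, end, strand)),
            ]
            if strand == "+":
                feats.append(("5UTR", GenomicInterval(chrom, start,
                                                      start + 120, strand)))
                feats.append(("3UTR", GenomicInterval(chrom, end - 120, end,
                                                      strand)))
            else:
                feats.append(("5UTR", GenomicInterval(chrom, end - 120, end,
                                                      strand)))
                feats.append(("3UTR", GenomicInterval(chrom, start,
                                                      start + 120, strand)))
            genes.append(GeneModel(
                gene_id=gid, chrom=chrom, strand=strand, tss=tss,
                tes=tes_coord, feature_intervals=feats, biotype="coding",
                subgenome=sg, triad_id=triad))
            pos = end

        # keep planted TEs that ended up intergenic
        spans = [(g.span[0], g.span[1]) for g in genes if g.chrom == chrom]
        spans.sort()
        for te in planted_tes:
            inside_gene = any(s < te.end and te.start < e for s, e in spans)
            if not inside_gene and te.start >= 0 \
                    and te.end <= config.chrom_length_bp:
                tes.append(GenomicInterval(te.chrom, te.start, te.end,
                                           name="TE_promoter"))

    genome = Genome(chrom_sizes=chrom_sizes, genes=genes, tes=[])

    # general TE fill: per intergenic gap, chunked placement hitting the
    # configured fraction of intergenic bp
    te_id = 0
    for gap in genome.intergenic_domain():
        target = int(round(config.te_fraction * len(gap)))
        already = sum(max(0, min(gap.end, t.end) - max(gap.start, t.start))
                      for t in tes if t.chrom == gap.chrom)
        target -= already
        if target < 150:
            continue
        n_chunks = max(1, math.ceil(target / 1200))
        lens = [target // n_chunks] * n_chunks
        lens[0] += target - sum(lens)
        slack = len(gap) - target
        cuts = np.sort(rng.integers(0, slack + 1, size=n_chunks))
        offset = gap.start
        consumed = 0
        for cut, L in zip(cuts, lens):
            s = offset + int(cut) + consumed
            tes.append(GenomicInterval(gap.chrom, s, s + L,
                                       name=f"TE{te_id:05d}"))
            te_id += 1
            consumed += L
    tes.sort(key=GenomicInterval.sort_key)
    genome.tes = merge_intervals(tes)

    return genome, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSim:
    counts: StageMatrix                 # gene x (stage, rep), counts
    ancestor: StageMatrix               # gene x stage, one "anc" column each
    mean_trajectory: pd.DataFrame       # noiseless gene x stage means (counts)
    mean_tpm: pd.DataFrame              # noiseless means, TPM-normalized
    tf_genes: list
    target_genes: list


def _promoter_self_assigns(gene: GeneModel, genome: Genome) -> bool:
    peak = _promoter_peak_interval(gene, genome)
    if peak is None:
        return False
    gid, cat = assign_peak_to_gene(peak, genome)
    return gid == gene.gene_id


def _promoter_peak_interval(gene: GeneModel, genome: Genome,
                            stage: str | None = None,
                            score: float | None = None
                            ) -> GenomicInterval | None:
    if gene.strand == "+":
        s, e = gene.tss - 600, gene.tss - 100
    else:
        s, e = gene.tss + 100, gene.tss + 600
    if s < 0 or e > genome.chrom_sizes[gene.chrom]:
        return None
    name = f"pACR_{gene.gene_id}" + (f"_{stage}" if stage else "")
    return GenomicInterval(gene.chrom, s, e, ".", name, score)


def simulate_expression(config: SimConfig, genome: Genome,
                        truth: SimTruth) -> ExpressionSim:
    """Pulse trajectories over activation waves, NB replicate counts, planted
    TF cascades and targets (one-stage lag), triad bias scaling, and ancestor
    profiles with planted Pearson divergence."""
    rng = config.rng(2)
    n_stages = config.n_stages
    s_grid = np.arange(n_stages, dtype=float)
    genes = {g.gene_id: g for g in genome.genes}

    # --- activation waves ------------------------------------------------
    spread = config.activation_phase_spread
    wave_centers = np.linspace(0.5, (n_stages - 2.5), 4)
    triad_ids = sorted({g.triad_id for g in genome.genes if g.triad_id})
    singletons = sorted(g.gene_id for g in genome.genes if g.triad_id is None)

    phase: dict[str, float] = {}
    shape: dict[str, tuple] = {}

    def draw_shape():
        return (0.7, float(rng.uniform(1.8, 2.2)), float(rng.uniform(3.2, 3.8)))

    lo_phase, hi_phase = 0.0, float(n_stages - 1)

    def draw_phase(i, n_total):
        if config.staggered_phases:
            span = (hi_phase - lo_phase) * spread
            return lo_phase + span * (i + 0.5) / n_total
        c = wave_centers[i % 4]
        return float(np.clip(c + rng.normal(0, 0.7) * spread,
                             lo_phase, hi_phase))

    n_units = len(triad_ids) + len(singletons)
    for i, tid in enumerate(triad_ids):
        p = draw_phase(i, n_units)
        sh = draw_shape()
        for sg in SUBGENOMES:
            gid = f"G{tid[1:]}{sg}"
            phase[gid], shape[gid] = p, sh
    for j, gid in enumerate(singletons):
        phase[gid] = draw_phase(len(triad_ids) + j, n_units)
        shape[gid] = draw_shape()

    # --- triad bias categories -------------------------------------------
    cat_labels = list(config.triad_category_fractions)
    cat_p = np.array([config.triad_category_fractions[k] for k in cat_labels])
    centroids = {
        "balanced": np.array([1, 1, 1]) / 3.0,
        "A-dominant": np.array([1.0, 0, 0]),
        "B-dominant": np.array([0, 1.0, 0]),
        "D-dominant": np.array([0, 0, 1.0]),
        "A-suppressed": np.array([0, 0.5, 0.5]),
        "B-suppressed": np.array([0.5, 0, 0.5]),
        "D-suppressed": np.array([0.5, 0.5, 0]),
    }
    for tid in triad_ids:
        cat = str(rng.choice(cat_labels, p=cat_p))
        frac = centroids[cat] + rng.normal(0, config.triad_fraction_noise_sd, 3)
        frac = np.clip(frac, 0.0, None)
        frac = frac / frac.sum()
        truth.triad_category[tid] = cat
        truth.triad_fractions[tid] = [float(x) for x in frac]

    # --- TF selection and planted network --------------------------------
    n_tfs = config.n_tf_families * config.tfs_per_family
    tf_candidates = [gid for gid in singletons
                     if _promoter_self_assigns(genes[gid], genome)]
    if len(tf_candidates) < n_tfs:
        # small genomes: draft one representative per triad as extra TFs
        for tid in triad_ids:
            for sg_i, sg in enumerate(SUBGENOMES):
                gid = f"G{tid[1:]}{sg}"
                if truth.triad_fractions[tid][sg_i] >= 0.3 \
                        and _promoter_self_assigns(genes[gid], genome):
                    tf_candidates.append(gid)
                    break
            if len(tf_candidates) >= n_tfs:
                break
    if len(tf_candidates) < n_tfs:
        log.warning("only %d eligible TF genes (requested %d)",
                    len(tf_candidates), n_tfs)
        n_tfs = len(tf_candidates)
    tf_genes = list(rng.choice(tf_candidates, size=n_tfs, replace=False))
    family_names = [f"FAM{i}" for i in range(config.n_tf_families)]
    family_bases = np.linspace(1.5, 3.0, config.n_tf_families)

    edges: list[tuple[str, str]] = []
    for fi, fam in enumerate(family_names):
        members = tf_genes[fi * config.tfs_per_family:
                           (fi + 1) * config.tfs_per_family]
        sh = draw_shape()
        for k, tf in enumerate(members):
            truth.tf_families[tf] = fam
            # cascade chains are capped at three tiers so late-tier pulses
            # stay inside the observed stage window
            phase[tf] = float(family_bases[fi] + (k % 3))
            shape[tf] = sh
            if 0 < k < 3:
                edges.append((members[k - 1], tf))  # cascade TF->TF, lag 1

    # targets: triad members with adequate planted fraction whose promoter
    # peak assigns back to them; one target member per triad
    tf_set = set(tf_genes)
    target_pool = []
    for tid in triad_ids:
        frac = truth.triad_fractions[tid]
        for sg_i, sg in enumerate(SUBGENOMES):
            gid = f"G{tid[1:]}{sg}"
            if gid in tf_set:
                break  # triad already drafted as a TF
            if frac[sg_i] >= 0.15 and _promoter_self_assigns(genes[gid], genome):
                target_pool.append(gid)
                break  # at most one member per triad
    n_targets = n_tfs * config.targets_per_tf
    if len(target_pool) < n_targets:
        log.warning("only %d eligible target genes (requested %d)",
                    len(target_pool), n_targets)
        n_targets = len(target_pool)
    per_tf = n_targets // n_tfs if n_tfs else 0
    targets = list(rng.choice(target_pool, size=per_tf * n_tfs,
                              replace=False))
    for i, tf in enumerate(tf_genes):
        for tg in targets[i * per_tf:(i + 1) * per_tf]:
            edges.append((tf, tg))
            # target (and its whole triad) inherits the TF trajectory, lag 1
            p = phase[tf] + 1.0
            sh = shape[tf]
            tid = genes[tg].triad_id
            for sg in SUBGENOMES:
                gid = f"G{tid[1:]}{sg}"
                phase[gid], shape[gid] = p, sh
    truth.edges = [[a, b] for a, b in edges]

    # --- mean trajectories ----------------------------------------------
    # constitutive baseline + stage-specific pulse; the baseline keeps total
    # transcriptional output (and hence TPM column factors) stable across
    # stages, as in real transcriptomes
    amp: dict[str, float] = {}
    basal: dict[str, float] = {}
    network_tids = {genes[tg].triad_id for tg in targets}
    network_tids |= {genes[tf].triad_id for tf in tf_genes
                     if genes[tf].triad_id}
    tf_singletons = set(tf_genes)
    for tid in triad_ids:
        a = float(rng.lognormal(np.log(300), 0.5))
        # regulators and their targets are stage-specific: pulse-dominated,
        # with little constitutive expression
        b = 0.0 if tid in network_tids or not config.constitutive_median \
            else float(rng.lognormal(np.log(config.constitutive_median), 1.0))
        frac = truth.triad_fractions[tid]
        for sg_i, sg in enumerate(SUBGENOMES):
            gid = f"G{tid[1:]}{sg}"
            amp[gid] = a * 3.0 * frac[sg_i]
            basal[gid] = b * 3.0 * frac[sg_i]
    for gid in singletons:
        amp[gid] = float(rng.lognormal(np.log(300), 0.5))
        basal[gid] = 0.0 if gid in tf_singletons \
            or not config.constitutive_median \
            else float(rng.lognormal(np.log(config.constitutive_median), 1.0))

    gene_order = sorted(phase)
    basal_arr = np.array([basal[g] for g in gene_order])
    mu = np.zeros((len(gene_order), n_stages))
    for i, gid in enumerate(gene_order):
        wr, wf, d = shape[gid]
        mu[i] = 0.5 + basal_arr[i] + amp[gid] * _pulse(s_grid, phase[gid],
                                                       wr, wf, d)
    # Flatten total transcriptional output across stages by letting the
    # constitutive baseline absorb the activation-wave imbalance.  Pulse
    # shapes (the planted signal) are untouched, so per-million
    # normalization returns exactly the planted profiles; triad fractions
    # are preserved because each gene's baseline scales proportionally.
    lengths_kb = np.array([
        (genes[gid].span[1] - genes[gid].span[0]) / 1000.0
        for gid in gene_order])
    rate_sums = (mu / lengths_kb[:, None]).sum(axis=0)
    deficit = rate_sums.max() * 1.02 - rate_sums
    basal_rate_total = (basal_arr / lengths_kb).sum()
    if basal_rate_total > 0:
        mu = mu + np.outer(basal_arr, deficit / basal_rate_total)
    mean_df = pd.DataFrame(mu, index=gene_order, columns=list(config.stages))

    for gid in gene_order:
        truth.phase_dtu[gid] = float(phase[gid] / (n_stages - 1) * 10.0)

    # --- replicate counts -------------------------------------------------
    cols = {}
    for si, stage in enumerate(config.stages):
        for r in range(config.n_rna_replicates):
            m = mu[:, si]
            if config.nb_dispersion > 0:
                lam = rng.gamma(1.0 / config.nb_dispersion,
                                config.nb_dispersion * np.maximum(m, 1e-9))
                vals = rng.poisson(lam).astype(float)
            else:
                vals = m.copy()
            cols[f"{stage}.r{r + 1}"] = vals
    counts = StageMatrix(pd.DataFrame(cols, index=gene_order),
                         list(config.stages), units="counts")

    # --- ancestor profiles with planted Pearson r ------------------------
    # the planted correlation lives in TPM space (the scale on which
    # divergence is measured); after stage balancing this is an exact
    # per-gene rescaling of the noiseless means
    rate = mu / lengths_kb[:, None]
    mu_tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6
    anc_cols = {f"{stage}.anc": np.zeros(len(gene_order))
                for stage in config.stages}
    anc = np.zeros((len(gene_order), n_stages))
    for i, gid in enumerate(gene_order):
        label = truth.divergence_label.get(gid, "conserved")
        rho = float(np.clip(
            DIVERGENCE_RHO[label] + rng.normal(0, 0.03), -0.2, 0.995))
        truth.divergence_rho[gid] = rho
        prof = mu_tpm[i]
        z = prof - prof.mean()
        nz = np.linalg.norm(z)
        if nz < 1e-9:
            # constant hexaploid profile: divergence is undefined downstream
            anc[i] = prof
            continue
        z = z / nz
        e = rng.normal(size=n_stages)
        e -= e.mean()
        e -= (e @ z) * z
        e /= np.linalg.norm(e)
        anc_z = rho * z + math.sqrt(max(0.0, 1 - rho ** 2)) * e
        anc[i] = np.clip(prof.mean() + nz * anc_z, 0.0, None)
    for si, stage in enumerate(config.stages):
        anc_cols[f"{stage}.anc"] = anc[:, si]
    ancestor = StageMatrix(pd.DataFrame(anc_cols, index=gene_order),
                           list(config.stages), units="TPM")

    return ExpressionSim(counts=counts, ancestor=ancestor,
                         mean_trajectory=mean_df,
                         mean_tpm=pd.DataFrame(mu_tpm, index=gene_order,
                                               columns=list(config.stages)),
                         tf_genes=tf_genes, target_genes=targets)


# ---------------------------------------------------------------------------
# Peaks, motif hits, ncRNA
# ---------------------------------------------------------------------------

@dataclass
class PeakSim:
    peaks: dict                     # mark -> stage -> list[GenomicInterval]
    atac_signal: StageMatrix        # promoter accessibility, gene x stage/rep
    k27ac_signal: StageMatrix
    k27me3_signal: StageMatrix
    motif_hits: pd.DataFrame        # motif_id, tf_gene_id, chrom, start, end
    ncrna: dict                     # stage -> list[GenomicInterval]


def _place_nonoverlapping(rng, domain: list[GenomicInterval], length: int,
                          occupied: list[tuple], max_tries: int = 200
                          ) -> GenomicInterval | None:
    """Uniform placement in the domain, rejecting overlaps with `occupied`."""
    segs = [s for s in domain if len(s) >= length]
    if not segs:
        return None
    weights = np.array([len(s) - length + 1 for s in segs], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        seg = segs[int(rng.choice(len(segs), p=weights))]
        start = int(rng.integers(seg.start, seg.end - length + 1))
        iv = (seg.chrom, start, start + length)
        if all(not (c == iv[0] and s < iv[2] and iv[1] < e)
               for c, s, e in occupied):
            occupied.append(iv)
            return GenomicInterval(*iv)
    return None


def simulate_peaks(config: SimConfig, genome: Genome, truth: SimTruth,
                   expr: ExpressionSim) -> PeakSim:
    """Per-stage peak sets for ATAC and three histone marks, motif hits
    realising every planted edge, and ncRNA transcripts from the transient
    distal burst."""
    rng = config.rng(3)
    stages = list(config.stages)
    n_stages = len(stages)
    burst = config.burst_stage_index
    genes = {g.gene_id: g for g in genome.genes}
    mu = expr.mean_trajectory
    gmax = mu.max(axis=1)
    thr = config.expressed_fraction_of_max
    expressed = mu.ge(gmax * thr, axis=0) & (gmax > 10.0).values[:, None]

    peaks: dict[str, dict[str, list]] = {
        m: {s: [] for s in stages} for m in
        ("ATAC", "H3K27ac", "H3K27me3", "H3K9me2")}

    # --- promoter / genic peaks ------------------------------------------
    gacr_genes = set(rng.choice(mu.index, size=len(mu.index) // 3,
                                replace=False))
    for gid in mu.index:
        g = genes[gid]
        for si, stage in enumerate(stages):
            if not expressed.loc[gid, stage]:
                continue
            score = float(mu.loc[gid, stage])
            p = _promoter_peak_interval(g, genome, stage, score)
            if p is not None:
                peaks["ATAC"][stage].append(p)
                truth.peak_labels[p.name] = {"category": "pACR",
                                             "gene": gid, "stage": stage}
            if gid in gacr_genes:
                lo, hi = g.span
                mid = lo + (hi - lo) // 5
                q = GenomicInterval(g.chrom, mid, mid + 200, ".",
                                    f"gACR_{gid}_{stage}", score)
                peaks["ATAC"][stage].append(q)
                truth.peak_labels[q.name] = {"category": "gACR",
                                             "gene": gid, "stage": stage}
        # histone marks at promoters: K27ac tracks expression, K27me3 mirrors
        for si, stage in enumerate(stages):
            if g.strand == "+":
                s, e = max(0, g.tss - 800), g.tss + 200
            else:
                s, e = g.tss - 200, min(genome.chrom_sizes[g.chrom],
                                        g.tss + 800)
            if s >= e:
                continue
            if expressed.loc[gid, stage]:
                peaks["H3K27ac"][stage].append(
                    GenomicInterval(g.chrom, s, e, ".",
                                    f"K27ac_{gid}_{stage}"))
            else:
                peaks["H3K27me3"][stage].append(
                    GenomicInterval(g.chrom, s, e, ".",
                                    f"K27me3_{gid}_{stage}"))

    # --- distal space ----------------------------------------------------
    distal_domain = genome.intergenic_domain(flank_bp=3000)
    distal_domain = [d for d in distal_domain if len(d) >= 400]
    te_distal = []
    for te in genome.tes:
        for d in distal_domain:
            if te.chrom == d.chrom and te.start >= d.start and te.end <= d.end:
                te_distal.append(te)
                break
    nonte_distal = subtract_intervals(distal_domain, genome.tes)
    nonte_distal = [d for d in nonte_distal if len(d) >= 400]

    occupied: list[tuple] = []

    def place_dacrs(count, te_rate, prefix):
        placed = []
        n_te = int(round(count * te_rate))
        for i in range(count):
            on_te = i < n_te
            domain = te_distal if on_te else nonte_distal
            iv = _place_nonoverlapping(rng, domain, 300, occupied)
            if iv is None:  # fall back to the other stratum
                iv = _place_nonoverlapping(
                    rng, nonte_distal if on_te else te_distal, 300, occupied)
            if iv is None:
                raise ValueError("distal space exhausted while placing dACRs")
            placed.append(GenomicInterval(iv.chrom, iv.start, iv.end, ".",
                                          f"{prefix}{len(placed):04d}"))
        return placed

    transient = place_dacrs(config.transient_dacr_count,
                            config.transient_te_overlap, "tACR")
    constant = place_dacrs(config.constant_dacr_count,
                           config.constant_te_overlap, "cACR")
    truth.transient_peaks = [p.name for p in transient]
    truth.constant_peaks = [p.name for p in constant]
    for p in transient:
        truth.peak_labels[p.name] = {"category": "dACR", "transient": True,
                                     "stage": stages[burst]}
        peaks["ATAC"][stages[burst]].append(p)
    window = [max(0, burst - 1), burst, min(n_stages - 1, burst + 1)]
    for p in constant:
        truth.peak_labels[p.name] = {"category": "dACR", "transient": False}
        for si in window:
            peaks["ATAC"][stages[si]].append(p)
    for si, stage in enumerate(stages):
        if si in window:
            continue
        for j in range(config.background_dacr_count):
            iv = _place_nonoverlapping(rng, distal_domain, 300, occupied)
            if iv is None:
                break
            peaks["ATAC"][stage].append(
                GenomicInterval(iv.chrom, iv.start, iv.end, ".",
                                f"bACR_{stage}_{j:03d}"))

    # --- distal histone marks (background domain substrate) ---------------
    for te in te_distal:
        if rng.random() < 0.35:
            for stage in stages:
                peaks["H3K9me2"][stage].append(
                    GenomicInterval(te.chrom, te.start, te.end, ".",
                                    f"K9_{te.chrom}_{te.start}"))
    for i in range(150 * len(genome.chrom_sizes)):
        iv = _place_nonoverlapping(rng, nonte_distal, 500, occupied)
        if iv is None:
            break
        mark = "H3K27ac" if i % 2 == 0 else "H3K27me3"
        for stage in stages:
            peaks[mark][stage].append(
                GenomicInterval(iv.chrom, iv.start, iv.end, ".",
                                f"d{mark}_{i:04d}"))

    # --- promoter signal matrices ----------------------------------------
    s_grid = np.arange(n_stages, dtype=float)
    gene_order = list(mu.index)
    idx = {gid: i for i, gid in enumerate(gene_order)}
    # promoter accessibility leads expression by half a stage and scales
    # with the gene's expression amplitude
    gene_amp = (mu.max(axis=1) - mu.min(axis=1)).values
    atac_mean = np.zeros((len(gene_order), n_stages))
    for gid in gene_order:
        i = idx[gid]
        p = truth.phase_dtu[gid] / 10.0 * (n_stages - 1)
        atac_mean[i] = 1.0 + 0.3 * gene_amp[i] * _pulse(s_grid, p - 0.5,
                                                        0.7, 2.0, 3.5)
    k27ac_mean = mu.values.copy()
    k27me3_mean = (gmax.values[:, None] * 1.05 - mu.values) + 1.0

    def as_signal(mean, n_reps, tag):
        cols = {}
        for si, stage in enumerate(stages):
            for r in range(n_reps):
                noise = rng.normal(0, config.signal_noise_sd,
                                   size=mean.shape[0])
                cols[f"{stage}.{tag}{r + 1}"] = np.clip(
                    mean[:, si] * (1.0 + noise), 0.0, None)
        return StageMatrix(pd.DataFrame(cols, index=gene_order), stages,
                           units="signal")

    atac_signal = as_signal(atac_mean, config.n_atac_replicates, "a")
    k27ac_signal = as_signal(k27ac_mean, config.n_atac_replicates, "k")
    k27me3_signal = as_signal(k27me3_mean, config.n_atac_replicates, "m")

    # --- motif hits -------------------------------------------------------
    rows = []
    for tf, tg in truth.edges:
        g = genes[tg]
        if g.strand == "+":
            s = g.tss - 400
        else:
            s = g.tss + 392
        rows.append((f"M_{tf}", tf, g.chrom, s, s + 8, 10.0))
    expr_genes = [gid for gid in gene_order if gid not in expr.tf_genes]
    for _ in range(config.decoy_motif_hits):
        tf = expr.tf_genes[int(rng.integers(0, len(expr.tf_genes)))]
        tg = expr_genes[int(rng.integers(0, len(expr_genes)))]
        g = genes[tg]
        if not _promoter_self_assigns(g, genome):
            continue
        s = g.tss - 380 if g.strand == "+" else g.tss + 372
        rows.append((f"M_{tf}", tf, g.chrom, s, s + 8, 5.0))
    motif_hits = pd.DataFrame(
        rows, columns=["motif_id", "tf_gene_id", "chrom", "start", "end",
                       "score"]).sort_values(
        ["motif_id", "chrom", "start"]).reset_index(drop=True)

    # --- ncRNA transcripts ------------------------------------------------
    ncrna: dict[str, list] = {s: [] for s in stages}
    for p in transient:
        t = GenomicInterval(p.chrom, max(0, p.start - 100),
                            min(genome.chrom_sizes[p.chrom], p.end + 100),
                            ".", f"nc_{p.name}")
        ncrna[stages[burst]].append(t)
        truth.ncrna_provenance[t.name] = p.name
    for p in constant:
        if rng.random() < 0.3:
            t = GenomicInterval(p.chrom, max(0, p.start - 100), p.end + 100,
                                ".", f"nc_{p.name}")
            for si in window:
                ncrna[stages[si]].append(t)
            truth.ncrna_provenance[t.name] = p.name
    # decoy transcripts overlapping coding genes (removed by the filter)
    coding = [g for g in genome.genes if g.biotype == "coding"]
    for stage in stages:
        picks = rng.choice(len(coding), size=60, replace=False)
        for k, gi in enumerate(picks):
            g = coding[int(gi)]
            lo, hi = g.span
            ncrna[stage].append(
                GenomicInterval(g.chrom, lo + 50, lo + 450, ".",
                                f"tx_{stage}_{k:03d}"))

    return PeakSim(peaks=peaks, atac_signal=atac_signal,
                   k27ac_signal=k27ac_signal, k27me3_signal=k27me3_signal,
                   motif_hits=motif_hits, ncrna=ncrna)


# ---------------------------------------------------------------------------
# Bundled dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: Genome
    truth: SimTruth
    expression: ExpressionSim
    peaks: PeakSim

    @property
    def triad_map(self) -> pd.DataFrame:
        rows = [(tid, f"G{tid[1:]}A", f"G{tid[1:]}B", f"G{tid[1:]}D")
                for tid in sorted(self.truth.triad_category)]
        return pd.DataFrame(rows, columns=["triad_id", "A", "B", "D"])


def simulate_all(config: SimConfig | None = None) -> SimulatedDataset:
    config = config or SimConfig()
    genome, truth = simulate_genome(config)
    expr = simulate_expression(config, genome, truth)
    pk = simulate_peaks(config, genome, truth, expr)
    return SimulatedDataset(config=config, genome=genome, truth=truth,
                            expression=expr, peaks=pk)


def write_dataset(ds: SimulatedDataset, outdir: str | Path,
                  header: str | None = None) -> dict[str, Path]:
    """Write every simulator product as plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def reg(key, name):
        paths[key] = outdir / name
        return paths[key]

    write_gff3(ds.genome.genes, reg("genes", "genes.gff3"), header)
    write_bed(ds.genome.tes, reg("tes", "tes.bed"), header)
    write_chrom_sizes(ds.genome.chrom_sizes, reg("chrom_sizes", "chrom.sizes"))
    ds.expression.counts.to_tsv(reg("counts", "counts.tsv"), header)
    ds.expression.ancestor.to_tsv(reg("ancestor", "ancestor.tsv"), header)
    ds.peaks.atac_signal.to_tsv(reg("atac_signal", "atac_signal.tsv"), header)
    ds.peaks.k27ac_signal.to_tsv(reg("k27ac_signal", "h3k27ac_signal.tsv"),
                                 header)
    ds.peaks.k27me3_signal.to_tsv(reg("k27me3_signal", "h3k27me3_signal.tsv"),
                                  header)
    pdir = outdir / "peaks"
    pdir.mkdir(exist_ok=True)
    for mark, by_stage in ds.peaks.peaks.items():
        for stage, ivs in by_stage.items():
            write_bed(ivs, pdir / f"{mark}_{stage}.bed", header)
    paths["peaks_dir"] = pdir
    ndir = outdir / "transcripts"
    ndir.mkdir(exist_ok=True)
    for stage, ivs in ds.peaks.ncrna.items():
        write_bed(ivs, ndir / f"transcripts_{stage}.bed", header)
    paths["transcripts_dir"] = ndir
    with open(reg("motif_hits", "motif_hits.tsv"), "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        ds.peaks.motif_hits.to_csv(fh, sep="\t", index=False)
    with open(reg("triad_map", "triad_map.tsv"), "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        ds.triad_map.to_csv(fh, sep="\t", index=False)
    with open(reg("tf_families", "tf_families.tsv"), "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("tf_gene_id\tfamily\n")
        for tf in sorted(ds.truth.tf_families):
            fh.write(f"{tf}\t{ds.truth.tf_families[tf]}\n")
    ds.truth.to_json(reg("truth", "truth.json"))
    return paths
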