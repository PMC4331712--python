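"""Synthetic input generation with planted, recoverable structure.

Every pipeline input (miRNA annotation, two-platform expression, raw reads,
curated interaction tables, gene fold changes) can be generated from a single
seeded :class:`SyntheticConfig`.  The accompanying :class:`SyntheticTruth`
records what was planted — directions, fold changes, cluster membership,
per-miRNA target sets — so recovery tests can assert exact equality.

Cross-platform correlation model
--------------------------------
Each miRNA has a shared true log2 fold change ``t`` (planted for DE miRNAs,
``N(0, background_logfc_sd^2)`` otherwise).  Each platform observes
``t + e_p`` with independent ``e_p ~ N(0, sigma_e^2)``.  The Pearson
correlation between platform log2 fold changes is then

    rho = var(t) / (var(t) + sigma_e^2)

so the platform noise that realises a target ``rho`` is
``sigma_e = background_logfc_sd * sqrt(1/rho - 1)``.

Recovery guarantees are by construction: planted fold changes sit well
outside the calling thresholds, background ("none") molecules are drawn from
bounded distributions that cannot cross them, and planted DE-target gene
sets are disjoint across miRNAs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, FixtureIntegrityError, SizingError
from .interaction_db import BedPeak, InteractionRecord, MirnaLocus, PromoterConfig, promoter_window

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_CHROMOSOMES = [f"chr{i}" for i in range(1, 20)] + ["chrX"]

_FIXTURE_CHECKSUMS = {
    "demir_table.tsv": "181f8259dbb9a92a60a5040ecbc622c0dc68fe349f3537c7af09feedef414a83",
    "mti_stats_table.tsv": "ad4d1a88fcb94af679455befa15fb1042e33af52a0def8f555152cf21a994fe8",
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic data generator (all stages share one seed)."""

    n_mirnas: int = 500
    n_genes: int = 2000
    n_up_mirnas: int = 48
    n_down_mirnas: int = 17
    # (chromosome, start bp, end bp, n cluster members); members are up miRNAs
    cluster_spec: tuple[str, int, int, int] = ("chr12", 109_500_000, 109_750_000, 41)
    planted_fc_range: tuple[float, float] = (4.0, 60.0)
    cross_platform_rho: float = 0.7
    noise_sd_log2: float = 0.1
    background_logfc_sd: float = 1.0
    seq_depth: int = 1_000_000
    seq_dispersion: float | None = None  # gamma-Poisson overdispersion if set
    # ((miRNA index, planted DE-target degree), ...); index into the overall
    # miRNA ordering, where 0..n_up-1 are up and n_up..n_up+n_down-1 are down
    hub_spec: tuple[tuple[int, int], ...] = ()
    # (reference target-set size, n co-targeting miRNAs) or None
    cotarget_spec: tuple[int, int] | None = None
    baseline_de_targets: int = 3
    background_curated_range: tuple[int, int] = (5, 30)
    n_extra_de_genes: int = 100
    n_tfs: int = 4
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    error_rate: float = 0.0
    ct_baseline: float = 30.0
    include_u6: bool = True
    control_id: str = "U6"
    # plant a highly abundant miRNA that vanishes in KO (the knocked-out
    # miRNA itself); its WT abundance balances the planted up/down mass so
    # library-proportion fold changes of the others are not shifted by
    # composition.  Without it, proportion normalization shifts every
    # measured log FC by -log2(sum p_wt * 2^fc).
    include_knockout_absorber: bool = True
    knockout_name: str = "miR-ko"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_genes, self.n_up_mirnas, self.n_down_mirnas) < 0:
            raise ConfigError("all counts must be >= 0")
        if self.n_up_mirnas + self.n_down_mirnas > self.n_mirnas:
            raise ConfigError("n_up + n_down exceeds n_mirnas")
        if not -1.0 <= self.cross_platform_rho <= 1.0:
            raise ConfigError("cross_platform_rho must lie in [-1, 1]")
        chrom, start, end, n_members = self.cluster_spec
        if start > end:
            raise ConfigError("cluster interval start > end")
        if n_members > self.n_up_mirnas:
            raise ConfigError("cluster members must be up-regulated miRNAs")
        lo, hi = self.planted_fc_range
        if not (0 < lo <= hi):
            raise ConfigError("planted_fc_range must be positive and ordered")
        if self.noise_sd_log2 < 0:
            raise ConfigError("noise_sd_log2 must be >= 0")
        for idx, degree in self.hub_spec:
            if degree > self.n_genes:
                raise SizingError(f"hub degree {degree} exceeds n_genes")
            if not 0 <= idx < self.n_up_mirnas + self.n_down_mirnas:
                raise ConfigError(f"hub index {idx} is not a planted DE miRNA")
        if self.cotarget_spec is not None:
            n_ref, n_cot = self.cotarget_spec
            if n_cot > self.n_up_mirnas + self.n_down_mirnas:
                raise SizingError("more co-targeting miRNAs than DE miRNAs")
            if n_ref < n_cot:
                raise SizingError("reference set smaller than co-targeting group")

    @property
    def mirna_names(self) -> list[str]:
        return [f"miR-s{i + 1:04d}" for i in range(self.n_mirnas)]

    @property
    def gene_names(self) -> list[str]:
        return [f"GENE{i + 1:05d}" for i in range(self.n_genes)]


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic instance, for recovery tests."""

    config: SyntheticConfig
    direction: dict[str, str]                 # miRNA -> up/down/none
    log2fc_seq: dict[str, float]
    log2fc_array: dict[str, float]
    baseline_log2_abundance: dict[str, float]
    cluster_members: list[str]
    gene_direction: dict[str, str]
    gene_log2fc: dict[str, float]
    curated_targets: dict[str, set[str]]      # miRNA -> all curated target genes
    de_targets: dict[str, set[str]]           # miRNA -> planted DE-target subset
    reference_targets: set[str]               # miR-122 analog target set
    cotarget_mirnas: list[str]
    hub_degrees: dict[str, int]
    cluster_tf: str = ""
    absorber_name: str | None = None
    absorber_log2_abundance: float = 0.0

    def to_manifest(self) -> dict:
        return {
            "config": asdict(self.config),
            "direction": self.direction,
            "log2fc_seq": self.log2fc_seq,
            "log2fc_array": self.log2fc_array,
            "cluster_members": self.cluster_members,
            "gene_direction": self.gene_direction,
            "curated_targets": {k: sorted(v) for k, v in self.curated_targets.items()},
            "de_targets": {k: sorted(v) for k, v in self.de_targets.items()},
            "reference_targets": sorted(self.reference_targets),
            "cotarget_mirnas": self.cotarget_mirnas,
            "hub_degrees": self.hub_degrees,
            "cluster_tf": self.cluster_tf,
        }

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_manifest(), indent=1, sort_keys=True))


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    # independent stream per stage so regenerating one output never perturbs another
    return np.random.default_rng([cfg.seed, stage])


def generate_mirna_annotation(cfg: SyntheticConfig) -> list[MirnaLocus]:
    """Place miRNA loci: cluster members inside the cluster interval on its
    chromosome, all other miRNAs on other chromosomes.  Deterministic."""
    rng = _rng(cfg, 0)
    chrom, cstart, cend, n_members = cfg.cluster_spec
    names = cfg.mirna_names
    loci: list[MirnaLocus] = []
    if n_members > 0:
        slot = (cend - cstart + 1) // n_members
        if slot < 120:
            raise SizingError(
                f"cluster interval of {cend - cstart + 1} bp cannot hold "
                f"{n_members} loci"
            )
    other_chroms = [c for c in _CHROMOSOMES if c != chrom]
    for i, name in enumerate(names):
        length = int(rng.integers(60, 100))
        if i < n_members:  # cluster members are the first up miRNAs
            slot_start = cstart + i * slot
            jitter = int(rng.integers(0, max(1, slot - length - 1)))
            start = slot_start + jitter
            loci.append(MirnaLocus(name, chrom, start, start + length, "+"))
        else:
            c = other_chroms[int(rng.integers(len(other_chroms)))]
            start = int(rng.integers(1_000_000, 150_000_000))
            strand = "+" if rng.random() < 0.5 else "-"
            loci.append(MirnaLocus(name, c, start, start + length, strand))
    return loci


def generate_truth(cfg: SyntheticConfig,
                   loci: Sequence[MirnaLocus] | None = None) -> SyntheticTruth:
    """Draw the full planted ground truth for one synthetic instance."""
    rng = _rng(cfg, 1)
    names = cfg.mirna_names
    genes = cfg.gene_names
    n_up, n_down = cfg.n_up_mirnas, cfg.n_down_mirnas
    _, _, _, n_members = cfg.cluster_spec

    direction = {}
    for i, name in enumerate(names):
        direction[name] = "up" if i < n_up else ("down" if i < n_up + n_down else "none")

    # shared true log2 FC, then independent per-platform deviations (see module
    # docstring for the closed form linking sigma_e to cross_platform_rho)
    lo, hi = cfg.planted_fc_range
    rho = cfg.cross_platform_rho
    if rho <= 0:
        raise ConfigError("generation requires cross_platform_rho in (0, 1]")
    sigma_e = cfg.background_logfc_sd * np.sqrt(1.0 / rho - 1.0)
    t = np.empty(len(names))
    for i, name in enumerate(names):
        if direction[name] == "up":
            t[i] = np.log2(rng.uniform(lo, hi))
        elif direction[name] == "down":
            t[i] = -np.log2(rng.uniform(lo, hi))
        else:
            t[i] = rng.normal(0.0, cfg.background_logfc_sd)
    f_seq = t + rng.normal(0.0, sigma_e, len(names))
    f_array = t + rng.normal(0.0, sigma_e, len(names))
    # planted DE miRNAs keep their direction on both platforms: clip the
    # platform deviation so it cannot drag a planted FC across 1
    for i, name in enumerate(names):
        if direction[name] == "up":
            f_seq[i] = max(f_seq[i], 1.0)
            f_array[i] = max(f_array[i], 1.0)
        elif direction[name] == "down":
            f_seq[i] = min(f_seq[i], -1.0)
            f_array[i] = min(f_array[i], -1.0)

    # planted DE miRNAs get central baselines: a molecule at the same extreme
    # quantile in both samples has its fold change erased by quantile
    # normalization, so planted signal must not sit at the WT abundance edge
    baseline = {
        n: float(rng.uniform(7.5, 10.5)) if direction[n] != "none"
        else float(rng.uniform(6.0, 12.0))
        for n in names
    }

    absorber_name = None
    absorber_log2_ab = 0.0
    if cfg.include_knockout_absorber and names:
        ab = np.array([2.0 ** baseline[n] for n in names])
        excess = float(np.sum(ab * (2.0 ** f_seq - 1.0)))
        if excess > 0:
            absorber_name = cfg.knockout_name
            absorber_log2_ab = float(np.log2(excess))

    # --- gene pools ----------------------------------------------------------
    gene_direction = {g: "none" for g in genes}
    gene_log2fc = {}
    pool = list(genes)  # consumed from the front for planted structure

    de_mirnas = [n for n in names if direction[n] != "none"]
    hub_degrees = {names[i]: d for i, d in cfg.hub_spec}
    de_targets: dict[str, set[str]] = {n: set() for n in names}
    curated: dict[str, set[str]] = {n: set() for n in names}

    need = sum(hub_degrees.get(m, cfg.baseline_de_targets) for m in de_mirnas)
    n_ref = cfg.cotarget_spec[0] if cfg.cotarget_spec else 0
    if need + n_ref + cfg.n_extra_de_genes > len(genes):
        raise SizingError("n_genes too small for the planted structure")

    for m in de_mirnas:
        k = hub_degrees.get(m, cfg.baseline_de_targets)
        picked, pool = pool[:k], pool[k:]
        de_targets[m] = set(picked)
        curated[m] |= set(picked)
        opposite = "down" if direction[m] == "up" else "up"
        for g in picked:
            gene_direction[g] = opposite

    # reference (miR-122 analog) target set: direction-none genes reserved so
    # only the planted co-targeting group can share them
    reference, pool = set(pool[:n_ref]), pool[n_ref:]

    cotarget_mirnas: list[str] = []
    if cfg.cotarget_spec:
        n_ref, n_cot = cfg.cotarget_spec
        downs = [n for n in names if direction[n] == "down"]
        ups = [n for n in names if direction[n] == "up"]
        cotarget_mirnas = (downs + ups)[:n_cot]
        ref_sorted = sorted(reference)
        for j, g in enumerate(ref_sorted):  # round-robin: each shares >= 1, union = all
            curated[cotarget_mirnas[j % n_cot]].add(g)

    # extra DEGs not targeted by anything (DEG-table realism)
    extra, pool = pool[: cfg.n_extra_de_genes], pool[cfg.n_extra_de_genes:]
    for g in extra:
        gene_direction[g] = "up" if rng.random() < 0.6 else "down"

    # background curated targets: drawn from never-DE genes outside the
    # reference set, so they can never become DE targets or shared targets
    bg_pool = np.array(pool)
    lo_c, hi_c = cfg.background_curated_range
    for m in names:
        k = int(rng.integers(lo_c, hi_c + 1))
        if len(bg_pool) and k > 0:
            curated[m] |= set(rng.choice(bg_pool, size=min(k, len(bg_pool)), replace=False))

    glo, ghi = 2.0, 8.0  # planted DEG fold-change range
    for g in genes:
        d = gene_direction[g]
        if d == "up":
            gene_log2fc[g] = float(np.log2(rng.uniform(glo, ghi)))
        elif d == "down":
            gene_log2fc[g] = float(-np.log2(rng.uniform(glo, ghi)))
        else:
            # bounded: |log2 FC| < log2(1.5) so background genes never call DE
            gene_log2fc[g] = float(rng.uniform(-0.5, 0.5))

    cluster_members = names[:n_members]
    return SyntheticTruth(
        config=cfg,
        direction=direction,
        log2fc_seq={n: float(f_seq[i]) for i, n in enumerate(names)},
        log2fc_array={n: float(f_array[i]) for i, n in enumerate(names)},
        baseline_log2_abundance=baseline,
        cluster_members=cluster_members,
        gene_direction=gene_direction,
        gene_log2fc=gene_log2fc,
        curated_targets=curated,
        de_targets=de_targets,
        reference_targets=reference,
        cotarget_mirnas=cotarget_mirnas,
        hub_degrees=hub_degrees,
        cluster_tf="TF001" if n_members else "",
        absorber_name=absorber_name,
        absorber_log2_abundance=absorber_log2_ab,
    )


def generate_expression(cfg: SyntheticConfig,
                        truth: SyntheticTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit the OpenArray-style Ct table and the small RNA-Seq count table.

    Ct model: ``Ct = ct_baseline - log2(abundance) + N(0, noise_sd_log2)``,
    two technical replicate wells per (miRNA, sample), plus a control (U6)
    row with equal abundance in both samples.  Counts are multinomial draws
    at ``seq_depth`` from the per-sample abundance proportions; with
    ``noise_sd_log2 == 0`` expected counts are used instead (deterministic
    mode, exact fold-change recovery).
    """
    rng = _rng(cfg, 2)
    names = list(cfg.mirna_names)
    fc_seq = [2.0 ** truth.log2fc_seq[n] for n in names]
    fc_array = [2.0 ** truth.log2fc_array[n] for n in names]
    ab = [2.0 ** truth.baseline_log2_abundance[n] for n in names]
    if truth.absorber_name is not None:
        names = names + [truth.absorber_name]
        ab = ab + [2.0 ** truth.absorber_log2_abundance]
        fc_seq = fc_seq + [2.0 ** -20]  # knocked out: effectively absent in KO
        fc_array = fc_array + [2.0 ** -20]
    ab_wt = np.array(ab)
    ab_ko_array = ab_wt * np.array(fc_array)
    ab_ko_seq = ab_wt * np.array(fc_seq)

    rows = []
    # control far more abundant than any miRNA (as qPCR U6 is): it must hold
    # the extreme rank in BOTH samples, otherwise quantile normalization
    # assigns it different reference values per sample and every ddCt fold
    # change inherits the artifact
    u6_ab = 4.0 * max(float(ab_wt.max(initial=0.0)),
                      float(ab_ko_array.max(initial=0.0)), 2.0 ** 18)

    def ct_rows(name: str, sample: str, abundance: float) -> None:
        for rep in (1, 2):
            noise = rng.normal(0.0, cfg.noise_sd_log2) if cfg.noise_sd_log2 > 0 else 0.0
            rows.append({
                "mirna": name, "well": f"{name}_{sample}_w{rep}", "sample": sample,
                "Ct": cfg.ct_baseline - np.log2(abundance) + noise,
            })

    for i, name in enumerate(names):
        ct_rows(name, "WT", ab_wt[i])
        ct_rows(name, "KO", ab_ko_array[i])
    if cfg.include_u6:
        ct_rows(cfg.control_id, "WT", u6_ab)
        ct_rows(cfg.control_id, "KO", u6_ab)
    ct_table = pd.DataFrame(rows, columns=["mirna", "well", "sample", "Ct"])

    count_rows = []
    for sample, ab in (("WT", ab_wt), ("KO", ab_ko_seq)):
        if ab.sum() <= 0:
            counts = np.zeros(len(names), dtype=int)
        else:
            p = ab / ab.sum()
            if cfg.noise_sd_log2 == 0:
                counts = np.round(p * cfg.seq_depth).astype(int)
            elif cfg.seq_dispersion:
                lam = p * cfg.seq_depth
                shape = 1.0 / cfg.seq_dispersion
                lam = rng.gamma(shape, lam / shape)
                counts = rng.poisson(lam)
            else:
                counts = rng.multinomial(cfg.seq_depth, p)
        for name, c in zip(names, counts):
            count_rows.append({"mirna": name, "sample": sample, "count": int(c)})
    count_table = pd.DataFrame(count_rows, columns=["mirna", "sample", "count"])
    return ct_table, count_table


def generate_gene_fold_changes(cfg: SyntheticConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Microarray-style gene fold-change table (gene, fc) from planted truth."""
    return pd.DataFrame(
        {"gene": list(cfg.gene_names),
         "fc": [2.0 ** truth.gene_log2fc[g] for g in cfg.gene_names]}
    )


def generate_mature_sequences(cfg: SyntheticConfig) -> dict[str, str]:
    """Random mature sequences (20-23 nt) pairwise separated by Hamming
    distance, so error-free reads can never cross-assign."""
    rng = _rng(cfg, 3)
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    existing: list[str] = []
    for name in cfg.mirna_names:
        for _ in range(200):
            length = int(rng.integers(20, 24))
            seq = "".join(rng.choice(bases, size=length))
            if all(_min_sub_hamming(seq, other) > 4 and _min_sub_hamming(other, seq) > 4
                   for other in existing):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise SizingError("could not draw a sufficiently distinct mature sequence")
        seqs[name] = seq
        existing.append(seq)
    return seqs


def _min_sub_hamming(short: str, long: str) -> int:
    """Minimum Hamming distance of ``short`` against any equal-length window
    of ``long``; large when ``short`` does not fit."""
    if len(short) > len(long):
        return len(short)
    best = len(short)
    for off in range(len(long) - len(short) + 1):
        d = sum(a != b for a, b in zip(short, long[off:off + len(short)]))
        best = min(best, d)
    return best


def generate_reads(counts: Mapping[str, int], mature: Mapping[str, str],
                   cfg: SyntheticConfig) -> list[tuple[str, str, str]]:
    """Simulate adapter-bearing reads: for each miRNA, ``count`` copies of
    mature sequence + 3' adapter, padded with A / truncated to read_length.

    Returns (read id, sequence, Phred+33 quality) tuples.  ``error_rate``
    introduces uniform substitutions.
    """
    rng = _rng(cfg, 4)
    bases = "ACGT"
    reads = []
    for name in sorted(counts):
        seq = mature[name]
        if len(seq) < 16:
            raise ConfigError(f"mature sequence of {name} shorter than 16 nt")
        template = (seq + cfg.adapter + "A" * cfg.read_length)[: cfg.read_length]
        for i in range(int(counts[name])):
            read = template
            if cfg.error_rate > 0:
                chars = list(read)
                for j in range(len(chars)):
                    if rng.random() < cfg.error_rate:
                        chars[j] = bases[(bases.index(chars[j]) + int(rng.integers(1, 4))) % 4]
                read = "".join(chars)
            reads.append((f"{name}:{i}", read, "I" * len(read)))
    return reads


def generate_interactions(
    cfg: SyntheticConfig, truth: SyntheticTruth,
    loci: Sequence[MirnaLocus] | None = None,
) -> tuple[pd.DataFrame, list[BedPeak], pd.DataFrame]:
    """Curated TF-miRNA TSV rows, per-TF ChIP peaks, and the curated MTI TSV.

    The "cluster TF" receives one peak inside the promoter window of every
    cluster member; remaining TFs get curated (TransmiR-style) edges to
    random miRNAs.  MTI rows realise ``truth.curated_targets`` exactly.
    """
    rng = _rng(cfg, 5)
    loci = list(loci) if loci is not None else generate_mirna_annotation(cfg)
    by_name = {l.name: l for l in loci}

    tfs = [f"TF{i + 1:03d}" for i in range(max(cfg.n_tfs, 1 if truth.cluster_members else 0))]
    tf_rows = []
    for tf in tfs[1:]:
        k = int(rng.integers(3, 10))
        for m in rng.choice(cfg.mirna_names, size=min(k, cfg.n_mirnas), replace=False):
            tf_rows.append({"tf": tf, "mirna": m, "source": "transmir"})
    tf_table = pd.DataFrame(tf_rows, columns=["tf", "mirna", "source"])

    peaks = []
    if truth.cluster_members:
        for m in truth.cluster_members:
            chrom, lo, hi = promoter_window(by_name[m], PromoterConfig())
            centre = by_name[m].five_prime
            peaks.append(BedPeak(tf=truth.cluster_tf, chrom=chrom,
                                 start=max(lo, centre - 150), end=centre + 150,
                                 score=float(rng.integers(100, 1000))))

    mti_rows = []
    sources = ["mirtarbase", "tarbase", "starbase"]
    for m in cfg.mirna_names:
        for g in sorted(truth.curated_targets[m]):
            mti_rows.append({
                "mirna": m, "gene": g,
                "source": sources[int(rng.integers(3))],
                "evidence": "curated",
            })
    mti_table = pd.DataFrame(mti_rows, columns=["mirna", "gene", "source", "evidence"])
    return tf_table, peaks, mti_table


# --------------------------------------------------------------------------
# text writers (all outputs are plain text; byte-identical under a fixed seed)
# --------------------------------------------------------------------------

def write_gff3(loci: Sequence[MirnaLocus], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for l in loci:
        lines.append(
            "\t".join([l.chrom, "miremap", "miRNA", str(l.start), str(l.end),
                       ".", l.strand, ".", f"ID={l.name};Name={l.name}"])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(peaks: Sequence[BedPeak], path: str | Path) -> None:
    lines = []
    for p in peaks:  # internal 1-based closed -> BED 0-based half-open
        score = "." if p.score is None else str(int(p.score))
        lines.append("\t".join([p.chrom, str(p.start - 1), str(p.end), p.tf, score, "+"]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f">{name}\n{seq}\n" for name, seq in sorted(seqs.items()))
    )


def write_fastq(reads: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"@{rid}\n{seq}\n+\n{qual}\n" for rid, seq, qual in reads)
    )


def write_interaction_inputs(cfg: SyntheticConfig, truth: SyntheticTruth,
                             loci: Sequence[MirnaLocus], outdir: str | Path) -> dict[str, Path]:
    """Write every interaction-side input file; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tf_table, peaks, mti_table = generate_interactions(cfg, truth, loci)
    paths = {
        "tf_mirna": outdir / "tf_mirna.tsv",
        "peaks": outdir / "peaks.bed",
        "mti": outdir / "mti.tsv",
        "annotation": outdir / "mirna_loci.gff3",
    }
    tf_table.to_csv(paths["tf_mirna"], sep="\t", index=False)
    write_bed(peaks, paths["peaks"])
    mti_table.to_csv(paths["mti"], sep="\t", index=False)
    write_gff3(loci, paths["annotation"])
    return paths


# --------------------------------------------------------------------------
# packaged published reference tables
# --------------------------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("miremap").joinpath("data", name)


def load_paper_fixtures(verify: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the two packaged result tables.

    First table: 65 rows (mirna, direction, locus, seq_fc, array_fc) with the
    printed strings preserved and parsed numeric/locus columns added.
    Second table: 65 rows (mirna, direction, n_curated, n_de_targets).

    ``verify`` checks the recorded SHA-256 of each file and raises
    :class:`FixtureIntegrityError` on mismatch.
    """
    frames = []
    for fname in ("demir_table.tsv", "mti_stats_table.tsv"):
        raw = _fixture_path(fname).read_bytes()
        if verify:
            digest = hashlib.sha256(raw).hexdigest()
            if digest != _FIXTURE_CHECKSUMS[fname]:
                raise FixtureIntegrityError(
                    f"{fname}: checksum {digest} != recorded {_FIXTURE_CHECKSUMS[fname]}"
                )
        frames.append(pd.read_csv(pd.io.common.BytesIO(raw), sep="\t", dtype=str))
    table1, table2 = frames

    from .interaction_db import parse_locus_string  # local to avoid cycle at import

    table1 = table1.copy()
    table1["seq_fc_value"] = table1["seq_fc"].astype(float)
    table1["array_fc_value"] = table1["array_fc"].astype(float)  # "1.59E+01" -> 15.9
    parsed = [parse_locus_string(s, name=m) for s, m in zip(table1["locus"], table1["mirna"])]
    table1["chrom"] = [l.chrom for l in parsed]
    table1["locus_start"] = [l.start for l in parsed]
    table1["locus_end"] = [l.end for l in parsed]
    table1["strand"] = [l.strand for l in parsed]

    table2 = table2.copy()
    table2["n_curated"] = table2["n_curated"].astype(int)
    table2["n_de_targets"] = table2["n_de_targets"].astype(int)
    return table1, table2


def fixture_loci(table1: pd.DataFrame | None = None) -> dict[str, MirnaLocus]:
    """MirnaLocus per fixture miRNA, keyed by name."""
    if table1 is None:
        table1, _ = load_paper_fixtures()
    return {
        row.mirna: MirnaLocus(row.mirna, row.chrom, int(row.locus_start),
                              int(row.locus_end), row.strand)
        for row in table1.itertuples(index=False)
    }
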