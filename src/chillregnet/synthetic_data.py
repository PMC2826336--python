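"""Study-shaped synthetic data with planted ground truth.

The generator emulates the statistical structure of a chilling time-course
microarray study on rice seedlings: log2-ratio profiles over ten chilling
time points (0.5-96 h) and three H2O2 time points (1, 3, 6 h) with two
simulated biological replicates per cell; a three-phase induction mixture
(71/22/7% of non-TF genes); 18 co-expression groups with distinct consensus
profiles; 1,200-nt promoters carrying planted cis-element motifs per group;
and a QTL map with a configurable planted enrichment of upregulated TFs.
Every artifact is a deterministic function of the config seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from chillregnet.expression_calls import TimeCourseMatrix
from chillregnet.motif_discovery import PromoterSet, iupac_to_set, reverse_complement

__all__ = [
    "SimulationConfig",
    "PlantedMotif",
    "GroundTruth",
    "StudyBundle",
    "ConfigurationError",
    "generate_gene_universe",
    "simulate_timecourse",
    "simulate_promoters",
    "simulate_qtl_map",
    "generate_study",
    "write_bundle",
    "load_bundle",
]


class ConfigurationError(ValueError):
    pass


TF_FAMILIES = ("bZIP", "AP2/ERF", "MYB", "WRKY", "bHLH", "NAC")
# rough family weights mirroring the induced-TF family breakdown
_FAMILY_WEIGHTS = np.array([11, 31, 37, 17, 29, 23], dtype=float)

QTL_TRAITS = ("COLDTL", "SDLVIG", "OSADJCAP", "SALTSN", "CHLCN", "LFRL", "GERMSP")

# default one-planted-class-per-cluster cycle: (pattern, fine class, broad
# category, TF family of the catalog class)
PLANTED_CYCLE = (
    ("TGACGTCA", "as1/ocs/TGA-like", "as1/ocs/TGA-like", "bZIP"),
    ("TTAACTGG", "MYB2-box-like", "MYB2-box-like", "R2R3-MYB"),
    ("GCCGCCGC", "GCC-box-like", "GCC-box/JAre-like", "AP2/ERF"),
    ("ACCGACAT", "DRE/CRT-like", "DRE/CRT/rav1-like", "AP2/ERF"),
    ("TACGTGTC", "ABRE-like", "ABRE-like", "bZIP"),
    ("TAACAGAG", "GARE-like", "GARE/pyrimidine-box-like", "R1-MYB"),
    ("CCTTTTTT", "pyrimidine-box-like", "GARE/pyrimidine-box-like", "R1-MYB"),
    ("TTGACCTT", "W-box-like", "W-box-like", "WRKY"),
    ("TCAACAAC", "rav1-like", "DRE/CRT/rav1-like", "AP2/ERF"),
    ("CACATGTC", "MYC2-box-like", "MYC2-box-like", "bHLH"),
)

# H2O2-responsive member fractions per cluster, phase-1 first: two low
# clusters and ten in the 0.5-0.79 band, then the slower clusters
_DEFAULT_H2O2_FRACTIONS = (
    0.39, 0.16, 0.55, 0.60, 0.65, 0.70, 0.75, 0.79, 0.58, 0.62, 0.68, 0.72,
    0.12, 0.25, 0.35, 0.45, 0.49,
    0.20,
)


@dataclass(frozen=True)
class PlantedMotif:
    pattern: str
    cluster_index: int
    rate: float
    element_class: str = ""
    broad_category: str = ""
    tf_family: str = ""

    def __post_init__(self) -> None:
        for sym in self.pattern:
            iupac_to_set(sym)
        if not 0 <= self.rate <= 1:
            raise ConfigurationError("planted occurrence rate must lie in [0, 1]")


def default_planted_motifs(n_clusters: int, rate: float = 0.7) -> tuple:
    out = []
    for i in range(n_clusters):
        pattern, fine, broad, fam = PLANTED_CYCLE[i % len(PLANTED_CYCLE)]
        out.append(
            PlantedMotif(pattern, i, rate, fine, broad, fam)
        )
    return tuple(out)


@dataclass(frozen=True)
class SimulationConfig:
    """Study design constants for the synthetic bundle.

    The defaults are the study conditions: ten chilling hours
    (0.5..96), three H2O2 hours, two biological replicates, a 71/22/7 phase
    mixture, 18 clusters (12 phase-1, 5 phase-2, 1 phase-3), [-1000, +200)
    promoters and per-cluster planted cis-element classes at rate 0.7.
    """

    n_genes: int = 3600
    tf_fraction: float = 0.057
    up_fraction: float = 0.7233
    down_fraction: float = 0.14
    chilling_timepoints: tuple = (0.5, 2, 4, 6, 12, 18, 24, 36, 48, 96)
    h2o2_timepoints: tuple = (1, 3, 6)
    phase_mixture: tuple = (0.71, 0.22, 0.07)
    n_clusters: int = 18
    cluster_phase_counts: tuple = (12, 5, 1)
    per_cluster_h2o2_fraction: tuple = _DEFAULT_H2O2_FRACTIONS
    tf_h2o2_fraction: float = 0.42
    planted_motifs: tuple | None = None  # None -> default_planted_motifs
    planted_rate: float = 0.7
    promoter_length: int = 1200
    background_order: int = 0
    background_composition: tuple = (0.25, 0.25, 0.25, 0.25)
    noise_model: str = "gaussian"
    noise_sd: float = 0.2
    n_replicates: int = 2
    n_chromosomes: int = 12
    chromosome_length: int = 2_000_000
    qtl_per_trait: int = 2
    qtl_length: int = 150_000
    qtl_enrichment_factor: float = 3.0
    strand_mode: str = "both"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not 0 <= self.tf_fraction <= 1:
            raise ConfigurationError("tf_fraction must lie in [0, 1]")
        if abs(sum(self.phase_mixture) - 1.0) > 1e-9:
            raise ConfigurationError("phase_mixture must sum to 1")
        if any(p < 0 for p in self.phase_mixture):
            raise ConfigurationError("phase_mixture entries must be >= 0")
        for tps in (self.chilling_timepoints, self.h2o2_timepoints):
            if any(b <= a for a, b in zip(tps, tps[1:])):
                raise ConfigurationError("time points must be strictly increasing")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian",):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")
        if sum(self.cluster_phase_counts) != self.n_clusters:
            raise ConfigurationError("cluster_phase_counts must sum to n_clusters")
        if len(self.per_cluster_h2o2_fraction) != self.n_clusters:
            raise ConfigurationError("need one H2O2 fraction per cluster")
        if self.up_fraction + self.down_fraction > 1 + 1e-9:
            raise ConfigurationError("up_fraction + down_fraction must be <= 1")
        if self.n_replicates < 2:
            raise ConfigurationError("need >= 2 replicates for t-test p-values")
        for m in self.motifs():
            if not 0 <= m.rate <= 1:
                raise ConfigurationError("occurrence rates must lie in [0, 1]")
            if len(m.pattern) > self.promoter_length:
                raise ConfigurationError("planted pattern longer than promoter")

    def motifs(self) -> tuple:
        if self.planted_motifs is not None:
            return self.planted_motifs
        return default_planted_motifs(self.n_clusters, self.planted_rate)


@dataclass
class GroundTruth:
    gene_phase: dict  # up genes only
    gene_cluster: dict  # up NTF genes only
    cluster_elements: dict  # truth label -> broad category
    cluster_regulators: dict  # truth label -> annotation TF family
    up_genes: set
    down_genes: set
    h2o2_genes: set
    cluster_labels: tuple
    cluster_phases: dict

    def __post_init__(self) -> None:
        assert set(self.gene_cluster.values()) <= set(self.cluster_labels)


def _rngs(seed, n):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_gene_universe(config: SimulationConfig) -> pd.DataFrame:
    """Gene annotation table: ids, TF flag/family, coordinates, TSS.

    Genes are spread over ``n_chromosomes`` chromosomes with 2-kb bodies
    and strand-aware TSSs kept clear of contig ends so default promoter
    windows are untruncated.
    """
    if config.n_genes <= 0:
        raise ConfigurationError("n_genes must be positive")
    rng = _rngs(config.seed, 8)[0]
    n = config.n_genes
    gene_ids = [f"Osyn{i:05d}" for i in range(n)]
    is_tf = rng.random(n) < config.tf_fraction
    fams = np.array(TF_FAMILIES)[
        rng.choice(len(TF_FAMILIES), size=n, p=_FAMILY_WEIGHTS / _FAMILY_WEIGHTS.sum())
    ]
    fams = np.where(is_tf, fams, "")
    chrom_idx = np.sort(rng.integers(0, config.n_chromosomes, size=n))
    chroms = np.array([f"chr{i + 1:02d}" for i in range(config.n_chromosomes)])[chrom_idx]
    body = 2000
    margin = config.promoter_length + body + 100
    tss = rng.integers(margin, config.chromosome_length - margin, size=n)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    start = np.where(strand == "+", tss, tss - body)
    end = start + body
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_tf": is_tf,
            "tf_family": fams,
            "chrom": chroms,
            "strand": strand,
            "tss": tss,
            "start": start,
            "end": end,
        }
    )


def _phase_onset_indices(timepoints, boundaries=(6.0, 24.0)):
    """Allowed consensus-onset indices per phase (>= 2 consecutive points
    must remain after the onset)."""
    last_ok = len(timepoints) - 2
    b1, b2 = boundaries
    idx = {1: [], 2: [], 3: []}
    for i, t in enumerate(timepoints):
        if i > last_ok:
            break
        phase = 1 if t <= b1 else (2 if t <= b2 else 3)
        idx[phase].append(i)
    return idx


def _cluster_templates(config: SimulationConfig):
    """Deterministic distinct (onset, end, amplitude) per cluster."""
    tps = config.chilling_timepoints
    onset_idx = _phase_onset_indices(tps)
    last = len(tps) - 1
    templates = []
    counter = 0
    for phase, count in zip((1, 2, 3), config.cluster_phase_counts):
        starts = onset_idx[phase]
        if count and not starts:
            raise ConfigurationError(f"no feasible onset for phase-{phase} clusters")
        combos = []
        for s in starts:
            for e in range(s + 1, last + 1):
                combos.append((s, e))
        for j in range(count):
            s, e = combos[j % len(combos)]
            amp = 2.4 + 0.08 * (counter % 13)
            templates.append((phase, s, e, amp))
            counter += 1
    return templates


def _noisy_matrix(true_profiles, timepoints, gene_ids, noise_sd, n_reps, rng):
    """Replicate-simulated ratios and two-sided one-sample t-test p-values."""
    n, t = true_profiles.shape
    if noise_sd == 0:
        ratios = true_profiles.copy()
        pvals = np.where(true_profiles != 0, 0.0, 1.0)
    else:
        reps = true_profiles[..., None] + rng.normal(0, noise_sd, size=(n, t, n_reps))
        ratios = reps.mean(axis=2)
        sd = reps.std(axis=2, ddof=1)
        sd = np.where(sd == 0, 1e-12, sd)
        tstat = ratios / (sd / np.sqrt(n_reps))
        pvals = 2 * stats.t.sf(np.abs(tstat), df=n_reps - 1)
    return TimeCourseMatrix(
        tuple(timepoints),
        pd.DataFrame(ratios, index=gene_ids, columns=timepoints),
        pd.DataFrame(pvals, index=gene_ids, columns=timepoints),
    )


def simulate_timecourse(universe: pd.DataFrame, config: SimulationConfig):
    """Chilling and H2O2 matrices plus the planted ground truth.

    Up-truth non-TF genes inherit their cluster's template profile, so the
    noise-free matrices are recovered exactly by the induction-calling
    rules; up-truth TFs get individual profiles with onsets inside their
    assigned phase window, and every TF family is guaranteed one phase-1
    member so planted regulator classes always satisfy temporal precedence.
    """
    if universe.empty:
        raise ConfigurationError("empty gene universe")
    if config.noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng_assign, rng_tf, rng_noise_c, rng_noise_h, rng_h2o2 = _rngs(config.seed + 1, 5)
    tps = config.chilling_timepoints
    n_t = len(tps)
    genes = universe["gene_id"].to_numpy()
    is_tf = universe["is_tf"].to_numpy()
    n = len(genes)

    order = rng_assign.permutation(n)
    n_up = int(round(config.up_fraction * n))
    n_down = int(round(config.down_fraction * n))
    up_idx = order[:n_up]
    down_idx = order[n_up : n_up + n_down]

    true_c = np.zeros((n, n_t))
    gene_phase: dict = {}
    gene_cluster: dict = {}

    # --- clustered non-TF up genes
    ntf_up = np.array([i for i in up_idx if not is_tf[i]])
    templates = _cluster_templates(config)
    labels = tuple(f"G{i + 1:02d}" for i in range(config.n_clusters))
    # allocate genes to phases by the mixture, then to clusters within phase
    n_ntf = len(ntf_up)
    counts = np.floor(np.asarray(config.phase_mixture) * n_ntf).astype(int)
    while counts.sum() < n_ntf:
        counts[int(np.argmax(np.asarray(config.phase_mixture) - counts / max(n_ntf, 1)))] += 1
    pools = {}
    pos = 0
    shuffled = rng_assign.permutation(ntf_up)
    for phase, c in zip((1, 2, 3), counts):
        pools[phase] = shuffled[pos : pos + c]
        pos += c
    cluster_members: dict = {}
    cluster_phases: dict = {}
    for ci, (phase, s, e, amp) in enumerate(templates):
        cluster_phases[labels[ci]] = phase
    for phase in (1, 2, 3):
        cl_ids = [i for i, t in enumerate(templates) if t[0] == phase]
        pool = pools[phase]
        if not cl_ids:
            if len(pool):
                raise ConfigurationError(
                    f"phase-{phase} genes requested but no phase-{phase} cluster"
                )
            continue
        chunks = np.array_split(pool, len(cl_ids))
        for ci, chunk in zip(cl_ids, chunks):
            _phase, s, e, amp = templates[ci]
            label = labels[ci]
            cluster_members[label] = [genes[i] for i in chunk]
            for i in chunk:
                true_c[i, s : e + 1] = amp
                gene_phase[genes[i]] = phase
                gene_cluster[genes[i]] = label

    # --- TF up genes: individual profiles inside the phase window
    tf_up = np.array([i for i in up_idx if is_tf[i]])
    onset_idx = _phase_onset_indices(tps)
    tf_phases = rng_tf.choice([1, 2, 3], size=len(tf_up), p=config.phase_mixture)
    fams_up = universe["tf_family"].to_numpy()[tf_up]
    for fam in np.unique(fams_up):
        sel = np.nonzero(fams_up == fam)[0]
        if len(sel) and not (tf_phases[sel] == 1).any():
            tf_phases[sel[0]] = 1  # guarantee a phase-1 member per family
    for i, phase in zip(tf_up, tf_phases):
        starts = onset_idx[phase]
        if not starts:
            phase = 1
            starts = onset_idx[1]
        s = int(rng_tf.choice(starts))
        e = int(rng_tf.integers(s + 1, n_t))
        amp = float(rng_tf.uniform(2.4, 3.4))
        true_c[i, s : e + 1] = amp
        gene_phase[genes[i]] = int(phase)

    # --- down genes: one or two repressed time points, never above zero
    for i in down_idx:
        k = int(rng_assign.integers(1, 3))
        cols = rng_assign.choice(n_t, size=k, replace=False)
        true_c[i, cols] = -2.5

    # --- H2O2 truth and profiles
    h_tps = config.h2o2_timepoints
    true_h = np.zeros((n, len(h_tps)))
    h2o2_genes: set = set()
    for label, members in cluster_members.items():
        frac = config.per_cluster_h2o2_fraction[labels.index(label)]
        m = rng_h2o2.permutation(len(members))
        take = int(round(frac * len(members)))
        h2o2_genes.update(members[j] for j in m[:take])
    tf_resp = rng_h2o2.random(len(tf_up)) < config.tf_h2o2_fraction
    h2o2_genes.update(genes[i] for i, r in zip(tf_up, tf_resp) if r)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in h2o2_genes:
        i = gene_pos[g]
        k = int(rng_h2o2.integers(1, len(h_tps) + 1))
        cols = rng_h2o2.choice(len(h_tps), size=k, replace=False)
        true_h[i, cols] = 2.5

    chilling = _noisy_matrix(
        true_c, tps, list(genes), config.noise_sd, config.n_replicates, rng_noise_c
    )
    h2o2 = _noisy_matrix(
        true_h, h_tps, list(genes), config.noise_sd, config.n_replicates, rng_noise_h
    )
    planted = {m.cluster_index: m for m in config.motifs()}
    cluster_elements = {
        labels[ci]: m.broad_category for ci, m in planted.items() if ci < len(labels)
    }
    cluster_regulators = {
        labels[ci]: m.tf_family for ci, m in planted.items() if ci < len(labels)
    }
    truth = GroundTruth(
        gene_phase=gene_phase,
        gene_cluster=gene_cluster,
        cluster_elements=cluster_elements,
        cluster_regulators=cluster_regulators,
        up_genes={genes[i] for i in up_idx},
        down_genes={genes[i] for i in down_idx},
        h2o2_genes=h2o2_genes,
        cluster_labels=labels,
        cluster_phases=cluster_phases,
    )
    return chilling, h2o2, truth


def _sample_pattern(pattern, rng):
    return "".join(rng.choice(sorted(iupac_to_set(sym))) for sym in pattern)


def simulate_promoters(
    universe: pd.DataFrame, truth: GroundTruth, config: SimulationConfig
) -> PromoterSet:
    """Promoter windows with planted motif instances.

    Background is an order-``background_order`` chain over the configured
    base composition (order 0: i.i.d. draws).  For each planted
    (pattern, cluster, rate), every member promoter independently carries
    one concrete instance with probability ``rate``, at a uniform position
    and (in "both" strand mode) a random orientation.
    """
    rng = _rngs(config.seed + 2, 1)[0]
    L = config.promoter_length
    comp = np.asarray(config.background_composition, dtype=float)
    comp = comp / comp.sum()
    genes = universe["gene_id"].to_numpy()
    codes = rng.choice(4, size=(len(genes), L), p=comp)
    alphabet = np.array(list("ACGT"))
    seqs = {g: "".join(alphabet[row]) for g, row in zip(genes, codes)}

    members_by_cluster: dict = {}
    for g, lab in truth.gene_cluster.items():
        members_by_cluster.setdefault(lab, []).append(g)
    for motif in config.motifs():
        if len(motif.pattern) > L:
            raise ConfigurationError("planted pattern longer than promoter")
        label = truth.cluster_labels[motif.cluster_index]
        for g in members_by_cluster.get(label, []):
            if rng.random() >= motif.rate:
                continue
            inst = _sample_pattern(motif.pattern, rng)
            if config.strand_mode == "both" and rng.random() < 0.5:
                inst = reverse_complement(inst)
            pos = int(rng.integers(0, L - len(inst) + 1))
            s = seqs[g]
            seqs[g] = s[:pos] + inst + s[pos + len(inst):]
    return PromoterSet(seqs, window=(-1000, L - 1000))


def simulate_qtl_map(universe: pd.DataFrame, config: SimulationConfig, truth: GroundTruth | None = None):
    """QTL interval table plus (optionally) planted TF enrichment.

    Returns ``(qtl_table, universe)``; when a ground truth is supplied and
    the enrichment factor differs from 1, up-regulated TF genes are
    relocated into QTL intervals with probability ``min(1, factor * f)``
    where ``f`` is the genomic QTL fraction, planting the configured excess
    over the genome-wide association rate.  Factor 1 leaves all positions
    untouched (exact null).
    """
    rng = _rngs(config.seed + 3, 1)[0]
    rows = []
    chroms = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    for trait in QTL_TRAITS:
        for _ in range(config.qtl_per_trait):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            if config.qtl_length >= config.chromosome_length:
                raise ConfigurationError("QTL longer than its chromosome")
            start = int(rng.integers(0, config.chromosome_length - config.qtl_length))
            rows.append(
                {
                    "trait": trait,
                    "chrom": chrom,
                    "start": start,
                    "end": start + config.qtl_length,
                }
            )
    qtl = pd.DataFrame(rows)
    universe = universe.copy()
    factor = config.qtl_enrichment_factor
    if truth is not None and factor != 1.0:
        genome = config.n_chromosomes * config.chromosome_length
        f = float((qtl["end"] - qtl["start"]).sum()) / genome
        p_in = min(1.0, factor * f)
        tf_up = universe.index[
            universe["is_tf"].to_numpy()
            & universe["gene_id"].isin(truth.up_genes).to_numpy()
        ]
        body = 2000
        for i in tf_up:
            if rng.random() >= p_in:
                continue
            j = int(rng.integers(0, len(qtl)))
            q = qtl.iloc[j]
            lo = int(q["start"]) + body
            hi = int(q["end"]) - body
            tss = int(rng.integers(lo, hi))
            universe.loc[i, "chrom"] = q["chrom"]
            universe.loc[i, "tss"] = tss
            if universe.loc[i, "strand"] == "+":
                universe.loc[i, "start"] = tss
                universe.loc[i, "end"] = tss + body
            else:
                universe.loc[i, "start"] = tss - body
                universe.loc[i, "end"] = tss
    return qtl, universe


@dataclass
class StudyBundle:
    config: SimulationConfig
    universe: pd.DataFrame
    chilling: TimeCourseMatrix
    h2o2: TimeCourseMatrix
    promoters: PromoterSet
    qtl: pd.DataFrame
    truth: GroundTruth


def generate_study(config: SimulationConfig = SimulationConfig()) -> StudyBundle:
    """Single entry point: universe -> time courses -> promoters -> QTL."""
    universe = generate_gene_universe(config)
    chilling, h2o2, truth = simulate_timecourse(universe, config)
    promoters = simulate_promoters(universe, truth, config)
    qtl, universe = simulate_qtl_map(universe, config, truth)
    return StudyBundle(config, universe, chilling, h2o2, promoters, qtl, truth)


# ---------------------------------------------------------------------------
# bundle (de)serialization


def _truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "gene_phase": truth.gene_phase,
        "gene_cluster": truth.gene_cluster,
        "cluster_elements": truth.cluster_elements,
        "cluster_regulators": truth.cluster_regulators,
        "up_genes": sorted(truth.up_genes),
        "down_genes": sorted(truth.down_genes),
        "h2o2_genes": sorted(truth.h2o2_genes),
        "cluster_labels": list(truth.cluster_labels),
        "cluster_phases": truth.cluster_phases,
    }


def _truth_from_dict(d: dict) -> GroundTruth:
    return GroundTruth(
        gene_phase={k: int(v) for k, v in d["gene_phase"].items()},
        gene_cluster=dict(d["gene_cluster"]),
        cluster_elements=dict(d["cluster_elements"]),
        cluster_regulators=dict(d["cluster_regulators"]),
        up_genes=set(d["up_genes"]),
        down_genes=set(d["down_genes"]),
        h2o2_genes=set(d["h2o2_genes"]),
        cluster_labels=tuple(d["cluster_labels"]),
        cluster_phases={k: int(v) for k, v in d["cluster_phases"].items()},
    )


def write_bundle(bundle: StudyBundle, outdir) -> Path:
    """Write the bundle as plain-text artifacts with a checksum manifest."""
    import yaml

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigurationError(f"unwritable output path {outdir}: {exc}") from exc
    bundle.chilling.to_tsv(outdir / "chilling.tsv")
    bundle.h2o2.to_tsv(outdir / "h2o2.tsv")
    bundle.promoters.to_fasta(outdir / "promoters.fasta")
    u = bundle.universe
    bed = u[["chrom", "start", "end", "gene_id", "is_tf", "strand"]].copy()
    bed["score"] = 0
    bed[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
        outdir / "genes.bed", sep="\t", header=False, index=False
    )
    with open(outdir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for r in u.itertuples(index=False):
            attrs = f"ID={r.gene_id};is_tf={int(r.is_tf)};tf_family={r.tf_family or 'NA'}"
            fh.write(
                f"{r.chrom}\tchillregnet\tgene\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\t{attrs}\n"
            )
    u.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    bundle.qtl.to_csv(outdir / "qtl.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(_truth_to_dict(bundle.truth), fh, indent=1, sort_keys=True)
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(bundle.config).items()
        if k != "planted_motifs"
    }
    cfg["planted_motifs"] = [
        [m.pattern, m.cluster_index, m.rate, m.element_class, m.broad_category, m.tf_family]
        for m in bundle.config.motifs()
    ]
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    manifest = {}
    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir


def load_bundle(indir) -> StudyBundle:
    """Inverse of :func:`write_bundle` (config round-trips through YAML)."""
    import yaml

    indir = Path(indir)
    with open(indir / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    planted = tuple(PlantedMotif(*row) for row in cfg.pop("planted_motifs"))
    cfg = {
        k: (tuple(v) if isinstance(v, list) else v) for k, v in cfg.items()
    }
    config = SimulationConfig(planted_motifs=planted, **cfg)
    universe = pd.read_csv(indir / "genes.tsv", sep="\t", keep_default_na=False)
    universe["is_tf"] = universe["is_tf"].astype(bool)
    chilling = TimeCourseMatrix.from_tsv(indir / "chilling.tsv")
    h2o2 = TimeCourseMatrix.from_tsv(indir / "h2o2.tsv")
    promoters = PromoterSet.from_fasta(
        indir / "promoters.fasta",
        window=(-1000, config.promoter_length - 1000),
    )
    qtl = pd.read_csv(indir / "qtl.tsv", sep="\t")
    with open(indir / "truth.json") as fh:
        truth = _truth_from_dict(json.load(fh))
    return StudyBundle(config, universe, chilling, h2o2, promoters, qtl, truth)
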