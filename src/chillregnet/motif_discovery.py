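"""Promoter window extraction and ZOOPS-EM motif discovery.

Promoter windows are [-1000, +200) relative to the annotated TSS (strand
aware, clipped at contig ends).  Per co-expression cluster, over-represented
motifs of width 8-10 nt are found by an iterative seed-EM-mask procedure:

1. seed a PWM from the most frequent unexplored w-mer,
2. refine it by EM under a zero-or-one-site-per-sequence (ZOOPS) model with
   a fixed order-0 background,
3. call sites wherever the PWM log-odds score reaches ``site_threshold``
   (default 0.875) times the maximal achievable score,
4. mask the called sites and move to the next motif slot.

Motif strength is summarized by the total information content (TIC,
``sum_j (2 - H_j)`` bits over PWM columns against a uniform background) and
by a Bonferroni-scaled binomial enrichment e-value against a background
promoter set (``background_filter``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PromoterSet",
    "MotifModel",
    "DiscoveryConfig",
    "Site",
    "extract_promoters",
    "discover_motifs",
    "score_occurrence",
    "compute_tic",
    "background_filter",
    "scan_pwm",
    "reverse_complement",
    "iupac_to_set",
    "consensus_from_pwm",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_IUPAC = {frozenset(v): k for k, v in IUPAC.items()}


def iupac_to_set(symbol: str) -> frozenset:
    try:
        return frozenset(IUPAC[symbol.upper()])
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {symbol!r}") from exc


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N, masked) -> 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(b)] = i
    return arr


@dataclass
class PromoterSet:
    """Gene id -> uppercase promoter sequence plus window metadata."""

    sequences: dict
    window: tuple = (-1000, 200)
    coordinates: dict = field(default_factory=dict)  # gene -> (chrom, start, end, strand)
    truncated: set = field(default_factory=set)
    errors: dict = field(default_factory=dict)  # gene -> reason for skipping

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValueError(f"{gene}: non-DNA symbols {sorted(bad)}")
            self.sequences[gene] = seq.upper()

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, genes) -> "PromoterSet":
        genes = [g for g in genes if g in self.sequences]
        return PromoterSet(
            {g: self.sequences[g] for g in genes},
            window=self.window,
            coordinates={g: self.coordinates[g] for g in genes if g in self.coordinates},
            truncated={g for g in genes if g in self.truncated},
        )

    def to_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for gene, seq in self.sequences.items():
                fh.write(f">{gene}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path, window=(-1000, 200)) -> "PromoterSet":
        from Bio.SeqIO import parse as seqio_parse

        seqs = {rec.id: str(rec.seq).upper() for rec in seqio_parse(str(path), "fasta")}
        return cls(seqs, window=window)


def extract_promoters(genome_fasta, tss_table, window=(-1000, 200)) -> PromoterSet:
    """Cut strand-aware promoter windows out of a genome FASTA.

    ``tss_table`` needs columns gene_id, chrom, strand and tss (1-based, as
    in GFF3).  For + strand genes the window covers [TSS-1000, TSS+200) in
    0-based half-open coordinates; for - strand genes the reverse complement
    of the mirrored slice.  Windows are clipped at contig ends and flagged
    truncated; genes whose TSS falls off the contig are recorded in
    ``errors`` and skipped.
    """
    from pyfaidx import Fasta

    upstream, downstream = -window[0], window[1]
    fa = Fasta(str(genome_fasta), sequence_always_upper=True)
    sequences, coords, truncated, errors = {}, {}, set(), {}
    for row in tss_table.itertuples(index=False):
        gene, chrom, strand, tss1 = row.gene_id, str(row.chrom), row.strand, int(row.tss)
        if chrom not in fa:
            errors[gene] = f"unknown contig {chrom}"
            continue
        contig_len = len(fa[chrom])
        tss0 = tss1 - 1
        if not 0 <= tss0 < contig_len:
            errors[gene] = f"TSS {tss1} off contig {chrom} (len {contig_len})"
            continue
        if strand == "+":
            start, end = tss0 - upstream, tss0 + downstream
        else:
            start, end = tss0 - downstream + 1, tss0 + upstream + 1
        cstart, cend = max(start, 0), min(end, contig_len)
        seq = fa[chrom][cstart:cend].seq
        if strand != "+":
            seq = reverse_complement(seq)
        sequences[gene] = seq
        coords[gene] = (chrom, cstart, cend, strand)
        if cstart != start or cend != end:
            truncated.add(gene)
    return PromoterSet(sequences, window=window, coordinates=coords,
                       truncated=truncated, errors=errors)


@dataclass(frozen=True)
class DiscoveryConfig:
    n_motifs: int = 30
    widths: tuple = (8, 9, 10)
    site_threshold: float = 0.875
    max_iter: int = 50
    tol: float = 1e-5
    strand: str = "both"  # "forward" | "both"
    min_tic: float = 6.0
    pseudocount: float = 0.25
    seed_match_prob: float = 0.7
    max_seqs: int | None = None  # subsample cap for EM (occurrence scored on all)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.site_threshold <= 1:
            raise ValueError("site_threshold must lie in (0, 1]")
        if self.strand not in ("forward", "both"):
            raise ValueError("strand must be 'forward' or 'both'")
        if self.n_motifs < 1 or any(w < 2 for w in self.widths):
            raise ValueError("invalid n_motifs/widths")


@dataclass(frozen=True)
class Site:
    gene: str
    offset: int
    strand: str  # "+" | "-"


@dataclass
class MotifModel:
    pwm: np.ndarray  # (width, 4), columns sum to 1
    consensus: str
    occurrence_pct: float
    tic: float
    sites: list
    n_seqs: int
    e_value: float | None = None
    element_class: str | None = None
    broad_category: str | None = None
    tf_family: str | None = None
    secondary_class: str | None = None

    @property
    def width(self) -> int:
        return self.pwm.shape[0]


def compute_tic(pwm: np.ndarray) -> float:
    """Total information content in bits: sum_j (2 - H_j), uniform background."""
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("PWM must be (width, 4)")
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("PWM columns must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pwm > 0, pwm * np.log2(pwm), 0.0)
    entropy = -plogp.sum(axis=1)
    return float((2.0 - entropy).sum())


def _relative_info(pwm: np.ndarray, background: np.ndarray) -> float:
    """Kullback-Leibler information of the PWM against the observed base
    composition, in bits; unlike the uniform-background TIC this is ~0 for
    low-complexity motifs that merely mirror a skewed background.  The
    minimum over the two orientations is returned, so a motif whose
    reverse complement is background-like also scores low."""

    def kl(p):
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / background[None, :]), 0.0)
        return float(terms.sum())

    rc = pwm[::-1][:, [3, 2, 1, 0]]
    return min(kl(pwm), kl(rc))


def consensus_from_pwm(pwm: np.ndarray) -> str:
    """IUPAC consensus: per column the smallest base set reaching 80% mass
    (bases below 20% never enter unless the column needs them)."""
    letters = []
    for col in pwm:
        order = np.argsort(col)[::-1]
        chosen = [order[0]]
        mass = float(col[order[0]])
        for b in order[1:]:
            if mass >= 0.8 or col[b] < 0.2:
                break
            chosen.append(b)
            mass += float(col[b])
        bases = frozenset(_BASES[b] for b in chosen)
        letters.append(_SET_TO_IUPAC[bases])
    return "".join(letters)


# ---------------------------------------------------------------------------
# scanning machinery


class _WindowBatch:
    """Flattened valid windows over a panel: bases, owner sequence, offset,
    strand; rebuilt once per motif slot (windows are static during EM)."""

    __slots__ = ("bases", "seq_idx", "offsets", "strands", "n_seqs", "m_per_seq",
                 "starts", "seq_present", "_flat_idx")

    def __init__(self, bases, seq_idx, offsets, strands, n_seqs):
        self.n_seqs = n_seqs
        self.m_per_seq = np.bincount(seq_idx, minlength=n_seqs)
        order = np.argsort(seq_idx, kind="stable")
        self.bases = bases[order]
        self.seq_idx = seq_idx[order]
        self.offsets = offsets[order]
        self.strands = strands[order]
        present = np.nonzero(self.m_per_seq > 0)[0]
        self.seq_present = present
        self.starts = np.concatenate([[0], np.cumsum(self.m_per_seq[present])[:-1]])
        w = bases.shape[1]
        self._flat_idx = (
            self.bases.astype(np.int32) + 4 * np.arange(w, dtype=np.int32)[None, :]
        )

    def scores(self, log_odds):
        return log_odds.ravel()[self._flat_idx].sum(axis=1)


class _SequencePanel:
    """Integer-encoded view over a ragged promoter set with site masks."""

    def __init__(self, names, seqs):
        self.names = list(names)
        self.codes = [encode(s) for s in seqs]
        self.masks = [np.zeros(len(c), dtype=bool) for c in self.codes]
        comp = np.ones(4)  # add-one smoothing keeps log-odds finite on
        for c in self.codes:  # degenerate (single-letter) input
            comp += np.bincount(c[c < 4], minlength=4)
        self.background = comp / comp.sum()

    def windows(self, w, use_mask=True, both_strands=False) -> _WindowBatch:
        bases_parts, seq_parts, off_parts, strand_parts = [], [], [], []
        for i, (code, mask) in enumerate(zip(self.codes, self.masks)):
            n_off = len(code) - w + 1
            if n_off <= 0:
                continue
            win = np.lib.stride_tricks.sliding_window_view(code, w)
            ok = ~(win == 4).any(axis=1)
            if use_mask:
                mwin = np.lib.stride_tricks.sliding_window_view(mask, w)
                ok &= ~mwin.any(axis=1)
            offs = np.nonzero(ok)[0]
            if offs.size == 0:
                continue
            fwd = win[offs].astype(np.int8)
            bases_parts.append(fwd)
            seq_parts.append(np.full(offs.size, i, dtype=np.int32))
            off_parts.append(offs.astype(np.int32))
            strand_parts.append(np.zeros(offs.size, dtype=np.int8))
            if both_strands:
                bases_parts.append((3 - fwd[:, ::-1]).astype(np.int8))
                seq_parts.append(np.full(offs.size, i, dtype=np.int32))
                off_parts.append(offs.astype(np.int32))
                strand_parts.append(np.ones(offs.size, dtype=np.int8))
        if not bases_parts:
            return _WindowBatch(
                np.empty((0, w), dtype=np.int8),
                np.empty(0, dtype=np.int32),
                np.empty(0, dtype=np.int32),
                np.empty(0, dtype=np.int8),
                len(self.codes),
            )
        return _WindowBatch(
            np.concatenate(bases_parts),
            np.concatenate(seq_parts),
            np.concatenate(off_parts),
            np.concatenate(strand_parts),
            len(self.codes),
        )


def _log_odds(pwm, background):
    return np.log(pwm) - np.log(background)[None, :]


def _call_sites(panel, pwm, config, use_mask=False, batch=None):
    """Sites with log-odds >= site_threshold * maximal achievable score."""
    lo = _log_odds(pwm, panel.background)
    smax = lo.max(axis=1).sum()
    if smax <= 0:
        return []
    cutoff = config.site_threshold * smax
    if batch is None:
        batch = panel.windows(pwm.shape[0], use_mask, config.strand == "both")
    scores = batch.scores(lo)
    hits = np.nonzero(scores >= cutoff)[0]
    return [
        Site(
            panel.names[batch.seq_idx[i]],
            int(batch.offsets[i]),
            "+" if batch.strands[i] == 0 else "-",
        )
        for i in hits
    ]


def scan_pwm(pwm, promoters, config: DiscoveryConfig = DiscoveryConfig()) -> list:
    """Full scan of a PWM over a promoter set (no masking)."""
    names, seqs = _promoter_items(promoters)
    panel = _SequencePanel(names, seqs)
    return _call_sites(panel, np.asarray(pwm, dtype=float), config, use_mask=False)


def _promoter_items(promoters):
    if isinstance(promoters, PromoterSet):
        items = promoters.sequences.items()
    elif isinstance(promoters, dict):
        items = promoters.items()
    else:  # plain iterable of sequences
        items = [(f"seq{i}", s) for i, s in enumerate(promoters)]
    names = [k for k, _ in items]
    seqs = [v for _, v in items]
    return names, seqs


def _seed_counts(batch, w):
    """Frequency of every unmasked w-mer, rolling-hash encoded base-4."""
    if len(batch.bases) == 0:
        return np.zeros(4 ** w, dtype=np.int64)
    weights = (4 ** np.arange(w)[::-1]).astype(np.int64)
    codes = (batch.bases.astype(np.int64) * weights).sum(axis=1)
    return np.bincount(codes, minlength=4 ** w)


def _pwm_from_code(code_int, w, match_prob):
    digits = []
    for _ in range(w):
        digits.append(code_int % 4)
        code_int //= 4
    digits = digits[::-1]
    pwm = np.full((w, 4), (1 - match_prob) / 3)
    for j, b in enumerate(digits):
        pwm[j, b] = match_prob
    return pwm


def _em_zoops(panel, batch, pwm0, config):
    """ZOOPS EM over a flattened window batch.

    Returns (pwm, gamma, objective_trace); the incomplete log-likelihood
    (relative to the all-background model) is asserted non-decreasing up to
    round-off.
    """
    pwm = pwm0.copy()
    gamma = 0.5
    w = pwm.shape[0]
    trace = []
    present = batch.seq_present
    if present.size == 0:
        return pwm, gamma, trace
    m = batch.m_per_seq[present].astype(float)  # windows per active sequence
    # map every window to its compressed sequence slot
    slot_of_seq = np.full(batch.n_seqs, -1)
    slot_of_seq[present] = np.arange(present.size)
    win_slot = slot_of_seq[batch.seq_idx]
    for _it in range(config.max_iter):
        lo = _log_odds(pwm, panel.background)
        scores = batch.scores(lo)
        smax = np.maximum.reduceat(scores, batch.starts)
        ex = np.exp(np.clip(scores - smax[win_slot], -700, 50))
        sum_ex = np.bincount(win_slot, weights=ex, minlength=present.size)
        lik = (1 - gamma) * np.exp(np.clip(-smax, -700, 700)) + gamma * sum_ex / m
        # penalized objective: incomplete log-likelihood (relative to the
        # all-background model) plus the Dirichlet pseudocount prior, the
        # quantity the pseudocounted M-step maximizes
        obj = float((np.log(lik) + smax).sum())
        obj += float(config.pseudocount * np.log(pwm).sum())
        trace.append(obj)
        if len(trace) > 1:
            assert obj >= trace[-2] - 1e-6 * max(1.0, abs(trace[-2])), (
                "EM objective decreased"
            )
            if abs(obj - trace[-2]) < config.tol * max(1.0, abs(trace[-2])):
                break
        z = gamma * ex / (m * lik)[win_slot]
        counts = np.full((w, 4), config.pseudocount)
        for j in range(w):
            counts[j] += np.bincount(batch.bases[:, j], weights=z, minlength=4)
        pwm = counts / counts.sum(axis=1, keepdims=True)
        q_per_seq = np.bincount(win_slot, weights=z, minlength=present.size)
        gamma = float(np.clip(q_per_seq.mean(), 1e-3, 1 - 1e-3))
    return pwm, gamma, trace


def discover_motifs(promoters, config: DiscoveryConfig = DiscoveryConfig()) -> list:
    """Iterative seed-EM-mask motif discovery on one cluster's promoters.

    Deterministic for a fixed config seed.  Returns up to ``n_motifs``
    :class:`MotifModel` sorted in discovery order; motifs whose information
    content falls below ``min_tic`` are dropped (their sites are still
    masked so later slots explore new sequence).
    """
    names, seqs = _promoter_items(promoters)
    if len(seqs) < 5:
        raise ValueError("need >= 5 promoter sequences")
    max_w = max(config.widths)
    usable = [s for s in seqs if len(s.replace("N", "")) >= max_w]
    if not usable:
        raise ValueError("all promoter sequence is N or shorter than the motif width")
    if any(max_w > len(s) for s in seqs):
        raise ValueError("motif width exceeds a promoter length")
    rng = np.random.default_rng(config.seed)
    if config.max_seqs is not None and len(seqs) > config.max_seqs:
        pick = rng.choice(len(seqs), size=config.max_seqs, replace=False)
        pick.sort()
        em_names = [names[i] for i in pick]
        em_seqs = [seqs[i] for i in pick]
    else:
        em_names, em_seqs = names, seqs
    panel = _SequencePanel(em_names, em_seqs)
    full_panel = (
        panel if em_names is names else _SequencePanel(names, seqs)
    )
    both = config.strand == "both"
    used_seeds = {w: set() for w in config.widths}
    motifs = []
    for _slot in range(config.n_motifs):
        best = None
        for w in config.widths:
            batch = panel.windows(w, use_mask=True, both_strands=both)
            counts = _seed_counts(batch, w)
            for code in used_seeds[w]:
                counts[code] = 0
            seed_code = int(counts.argmax())
            if counts[seed_code] == 0:
                continue
            used_seeds[w].add(seed_code)
            pwm0 = _pwm_from_code(seed_code, w, config.seed_match_prob)
            pwm, _gamma, _trace = _em_zoops(panel, batch, pwm0, config)
            sites = _call_sites(panel, pwm, config, use_mask=True, batch=batch)
            covered = len({s.gene for s in sites})
            occ = 100.0 * covered / len(panel.names)
            tic = compute_tic(pwm)
            key = (occ, tic)
            if best is None or key > best[0]:
                best = (key, pwm, sites, occ, tic)
        if best is None:
            break
        _key, pwm, sites, occ, tic = best
        # mask called sites so the next slot explores different sequence
        name_to_idx = {n: i for i, n in enumerate(panel.names)}
        for s in sites:
            i = name_to_idx[s.gene]
            panel.masks[i][s.offset : s.offset + pwm.shape[0]] = True
        if (
            not sites
            or tic < config.min_tic
            or _relative_info(pwm, panel.background) < config.min_tic
        ):
            continue
        # report consensus on the strand carrying more sites
        n_rev = sum(1 for s in sites if s.strand == "-")
        if both and n_rev > len(sites) - n_rev:
            pwm = pwm[::-1][:, [3, 2, 1, 0]]
            sites = [
                Site(s.gene, s.offset, "+" if s.strand == "-" else "-") for s in sites
            ]
        if full_panel is not panel:
            full_sites = _call_sites(full_panel, pwm, config, use_mask=False)
            occ = 100.0 * len({s.gene for s in full_sites}) / len(names)
            sites = full_sites
        motifs.append(
            MotifModel(
                pwm=pwm,
                consensus=consensus_from_pwm(pwm),
                occurrence_pct=occ,
                tic=tic,
                sites=sites,
                n_seqs=len(names),
            )
        )
    return motifs


def score_occurrence(motif: MotifModel, promoters, config: DiscoveryConfig = DiscoveryConfig()) -> float:
    """Percent of promoters carrying >= 1 site at the calling threshold."""
    names, seqs = _promoter_items(promoters)
    if motif.width > min(len(s) for s in seqs):
        raise ValueError("motif wider than the shortest promoter")
    sites = scan_pwm(motif.pwm, promoters, config)
    return 100.0 * len({s.gene for s in sites}) / len(names)


def background_filter(
    motifs,
    foreground,
    background,
    alpha_e: float = 1e-3,
    config: DiscoveryConfig = DiscoveryConfig(),
    n_tests: int | None = None,
) -> list:
    """Bonferroni-scaled binomial enrichment of foreground site counts.

    For each motif the per-sequence site probability ``p0`` is estimated on
    the background promoters; the e-value is ``n_tests`` times the one-sided
    binomial tail P(X >= k) for the k foreground promoters carrying a site.
    Motifs with ``e_value > alpha_e`` are removed.
    """
    fg_names, _ = _promoter_items(foreground)
    bg_names, bg_seqs = _promoter_items(background)
    if not bg_names:
        raise ValueError("empty background promoter set")
    motifs = list(motifs)
    if n_tests is None:
        n_tests = max(len(motifs), 1)
    kept = []
    n_fg = len(fg_names)
    n_bg = len(bg_names)
    for motif in motifs:
        k_fg = len({s.gene for s in scan_pwm(motif.pwm, foreground, config)})
        k_bg = len({s.gene for s in scan_pwm(motif.pwm, background, config)})
        p0 = max(k_bg / n_bg, 0.5 / n_bg)
        e_value = float(n_tests * stats.binom.sf(k_fg - 1, n_fg, min(p0, 1.0)))
        motif = replace_evalue(motif, e_value)
        if e_value <= alpha_e and k_fg / n_fg > p0:
            kept.append(motif)
    return kept


def replace_evalue(motif: MotifModel, e_value: float) -> MotifModel:
    motif.e_value = e_value
    return motif


def write_meme(motifs, path, background=(0.25, 0.25, 0.25, 0.25)) -> None:
    """MEME minimal motif format writer."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            + " ".join(f"{b} {f:.4f}" for b, f in zip("ACGT", background))
            + "\n\n"
        )
        for m in motifs:
            n_sites = max(len({s.gene for s in m.sites}), 1)
            fh.write(f"MOTIF {m.consensus}\n")
            ev = m.e_value if m.e_value is not None else 1.0
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {n_sites} E= {ev:.3g}\n"
            )
            for row in m.pwm:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
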