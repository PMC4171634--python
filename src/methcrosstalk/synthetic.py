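"""Synthetic MBD-capture study generator with recorded ground truth.

Builds a toy genome (non-overlapping gene models, CpG islands, promoter
sequences with controlled CpG density classes), assigns each promoter a
chromatin-state category (H3K4me3 / H3K27me3 / H2AK119ub combinations with
a configurable bivalent fraction), and samples capture-seq tag libraries
for a control and one or more knockdown conditions in which hyper- or
hypomethylation is planted in configured strata at a known fold change.

The generative model for tags is Poisson per 200-bp window with rate
proportional to (true methylation x CpG-dinucleotide count of the window),
plus a uniform background floor (5% of total depth by default).  The CpG
weight ties capture efficiency to CpG density, mirroring the affinity of
the methyl-binding domain for CpG-dense methylated fragments; the Poisson
window model matches the island caller's background assumption so that
planted-truth recovery is well-posed.  Replicate beta-value matrices and
MeDIP-qPCR Ct pairs are derived from the same per-feature truth.

All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeAnnotation, TagLibrary, decode_sequence
from .enrichment import STATE_CATEGORIES

FEATURE_STRATA = ("promoter", "body", "three_prime_end", "cgi")

DEFAULT_STATE_PROBS = {
    "K4_only": 0.35, "bivalent": 0.25, "K27_only": 0.10,
    "ub_only": 0.10, "K27_and_ub": 0.10, "unmarked": 0.10,
}

# Methylation biology of the toy genome: CGIs hypomethylated, gene bodies
# and intergenic CpGs at the default methylated state, promoters in between.
DEFAULT_BASELINE_METH = {
    "cgi": 0.10, "promoter": 0.25, "body": 0.60,
    "three_prime_end": 0.50, "intergenic": 0.40,
}


@dataclass(frozen=True)
class KnockdownEffect:
    condition: str
    stratum: str  # a chromatin-state category or a feature class
    fold: float

    def __post_init__(self) -> None:
        if self.stratum not in STATE_CATEGORIES + FEATURE_STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.fold < 0:
            raise ValueError("fold change must be >= 0")


@dataclass
class SimConfig:
    n_chromosomes: int = 3
    chrom_length: int = 2_000_000
    n_genes: int = 300
    cgi_fraction_of_promoters: float = 0.6
    lcp_fraction_of_noncgi: float = 0.5
    state_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_PROBS))
    baseline_meth: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_METH))
    kd_effects: list[KnockdownEffect] = field(
        default_factory=lambda: [KnockdownEffect("siKD", "bivalent", 2.5)])
    depth: int = 500_000
    background_floor: float = 0.05
    window_size: int = 200
    beta_replicates: int = 4
    beta_noise_sd: float = 0.05
    ct_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.kd_effects = [
            e if isinstance(e, KnockdownEffect) else KnockdownEffect(*e)
            for e in self.kd_effects
        ]
        total = sum(self.state_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state_probs must sum to 1 (got {total})")
        for key, value in self.baseline_meth.items():
            if not 0 <= value <= 1:
                raise ValueError(f"baseline_meth[{key}] outside [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.chrom_length < 100_000:
            raise ValueError("chrom_length must be >= 100,000 bp")
        if not 0 <= self.cgi_fraction_of_promoters <= 1:
            raise ValueError("cgi_fraction_of_promoters outside [0, 1]")

    @property
    def conditions(self) -> list[str]:
        return ["control"] + list(dict.fromkeys(e.condition
                                                for e in self.kd_effects))


@dataclass
class GroundTruth:
    """Recorded truth of a simulated study.

    ``states``: gene -> chromatin-state category.
    ``features``: one row per feature (feature_id, gene, feature_class,
    chrom, start, end); promoter CGIs carry their host gene.
    ``meth``: feature_id x condition true methylation levels in [0, 1].
    ``planted``: differential features per condition with true fold change.
    ``intergenic_meth``: condition -> background methylation level.
    """

    states: pd.DataFrame
    features: pd.DataFrame
    meth: pd.DataFrame
    planted: pd.DataFrame
    intergenic_meth: dict[str, float]


# ---------------------------------------------------------------------------
# sequence helpers

def _random_seq(rng: np.random.Generator, length: int, probs) -> np.ndarray:
    return rng.choice(4, size=length, p=probs).astype(np.uint8)


def _deplete_cpg(codes: np.ndarray, rng: np.random.Generator, q: float) -> None:
    """Break a fraction q of CpG dinucleotides in place (G -> A)."""
    cg = np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))
    if cg.size:
        hit = cg[rng.random(cg.size) < q]
        codes[hit + 1] = 0


_BG_PROBS = (0.3, 0.2, 0.2, 0.3)      # AT-rich background, CpG broken at 0.9
_CGI_PROBS = (0.2, 0.3, 0.3, 0.2)     # GC 0.6, CpG o/e ~ 1 -> HCP
_ICP_PROBS = (0.25, 0.25, 0.25, 0.25)  # GC 0.5, CpG broken at 0.45 -> ICP
_BG_CPG_BREAK = 0.9
_ICP_CPG_BREAK = 0.45


# ---------------------------------------------------------------------------
# genome

def simulate_genome(config: SimConfig) -> GenomeAnnotation:
    """Toy genome: chromosomes, non-overlapping gene models, CGIs at a
    configured fraction of promoters plus intragenic/intergenic CGIs, and a
    genome sequence whose promoter CpG densities realize HCP/ICP/LCP classes.
    """
    rng = np.random.default_rng([config.seed, 0])
    chrom_lengths = {f"chr{i + 1}": config.chrom_length
                     for i in range(config.n_chromosomes)}
    chroms = list(chrom_lengths)

    # --- gene placement (round-robin across chromosomes)
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    min_gap = 4000
    gene_rows = []
    gi = 0
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        lengths = rng.integers(2000, 20001, size=k)
        required = int(lengths.sum()) + (k + 1) * min_gap
        if required > config.chrom_length:
            raise ValueError(
                f"cannot place {k} non-overlapping genes with {min_gap}-bp "
                f"margins on a {config.chrom_length}-bp chromosome "
                f"(needs {required} bp); reduce n_genes or lengthen chromosomes"
            )
        slack = config.chrom_length - required
        extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        pos = 0
        for j in range(k):
            pos += min_gap + int(extra[j])
            start = pos
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((f"gene{gi:04d}", chrom, strand, start, end))
            gi += 1
            pos = end
    genes = pd.DataFrame(gene_rows,
                         columns=["name", "chrom", "strand", "tx_start", "tx_end"])

    # --- CGI placement
    n_cgi_prom = int(round(config.cgi_fraction_of_promoters * len(genes)))
    order = rng.permutation(len(genes))
    cgi_prom_genes = set(genes["name"].to_numpy()[order[:n_cgi_prom]])
    non_cgi = genes["name"].to_numpy()[order[n_cgi_prom:]]
    n_lcp = int(round(config.lcp_fraction_of_noncgi * len(non_cgi)))
    lcp_genes = set(non_cgi[:n_lcp])
    icp_genes = set(non_cgi[n_lcp:])

    cgi_rows = []
    for _, g in genes.iterrows():
        tss = g["tx_start"] if g["strand"] == "+" else g["tx_end"]
        if g["name"] in cgi_prom_genes:
            s = max(0, tss - 500)
            cgi_rows.append((g["chrom"], s, min(tss + 500, config.chrom_length),
                             f"cgi_prom_{g['name']}"))
    # intragenic CGIs in ~15% of sufficiently long genes
    for _, g in genes.iterrows():
        if g["tx_end"] - g["tx_start"] >= 4000 and rng.random() < 0.15:
            mid = (g["tx_start"] + g["tx_end"]) // 2
            cgi_rows.append((g["chrom"], mid - 400, mid + 400,
                             f"cgi_body_{g['name']}"))
    # intergenic CGIs in large gaps
    quota = max(1, config.n_genes // 10)
    placed = 0
    for chrom in chroms:
        sub = genes[genes["chrom"] == chrom].sort_values("tx_start")
        prev = 0
        for _, g in sub.iterrows():
            gap_end = g["tx_start"] - 3000
            if gap_end - prev >= 10_000 and placed < quota:
                center = (prev + gap_end) // 2
                cgi_rows.append((chrom, center - 400, center + 400,
                                 f"cgi_inter_{placed:03d}"))
                placed += 1
            prev = g["tx_end"] + 3000
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "name"])
    cgis = cgis.sort_values(["chrom", "start"]).reset_index(drop=True)

    # --- sequence
    genome_seq: dict[str, np.ndarray] = {}
    for chrom in chroms:
        codes = _random_seq(rng, config.chrom_length, _BG_PROBS)
        _deplete_cpg(codes, rng, _BG_CPG_BREAK)
        genome_seq[chrom] = codes
    for _, row in cgis.iterrows():
        s, e = int(row["start"]), int(row["end"])
        seg = _random_seq(rng, e - s, _CGI_PROBS)
        genome_seq[row["chrom"]][s:e] = seg
    for _, g in genes.iterrows():
        if g["name"] not in icp_genes:
            continue
        tss = g["tx_start"] if g["strand"] == "+" else g["tx_end"]
        s, e = max(0, tss - 500), min(tss + 200, config.chrom_length)
        seg = _random_seq(rng, e - s, _ICP_PROBS)
        _deplete_cpg(seg, rng, _ICP_CPG_BREAK)
        genome_seq[g["chrom"]][s:e] = seg

    promoter_seqs = {}
    for _, g in genes.iterrows():
        tss = g["tx_start"] if g["strand"] == "+" else g["tx_end"]
        s, e = max(0, tss - 1000), min(tss + 1000, config.chrom_length)
        promoter_seqs[g["name"]] = decode_sequence(genome_seq[g["chrom"]][s:e])

    return GenomeAnnotation(chrom_lengths, genes, cgis, promoter_seqs,
                            genome_seq)


# ---------------------------------------------------------------------------
# chromatin states and methylation truth

def assign_chromatin_states(annotation: GenomeAnnotation, config: SimConfig
                            ) -> tuple[GroundTruth, dict[str, pd.DataFrame]]:
    """Sample one chromatin-state category per promoter and derive the
    consistent H3K4me3 / H3K27me3 / H2AK119ub peak sets plus the full
    methylation ground truth for every condition."""
    rng = np.random.default_rng([config.seed, 1])
    cats = list(config.state_probs)
    probs = np.array([config.state_probs[c] for c in cats])
    genes = annotation.genes
    drawn = rng.choice(len(cats), size=len(genes), p=probs)
    states = pd.DataFrame({"gene": genes["name"].to_numpy(),
                           "category": [cats[i] for i in drawn]})

    has = {
        "k4me3": {"K4_only", "bivalent"},
        "k27me3": {"bivalent", "K27_only", "K27_and_ub"},
        "h2aub": {"ub_only", "K27_and_ub"},
    }
    peak_rows: dict[str, list] = {"k4me3": [], "k27me3": [], "h2aub": []}
    for (_, g), cat in zip(genes.iterrows(), states["category"]):
        tss = g["tx_start"] if g["strand"] == "+" else g["tx_end"]
        s = max(0, tss - 800)
        e = min(tss + 800, annotation.chrom_lengths[g["chrom"]])
        for mark, members in has.items():
            if cat in members:
                peak_rows[mark].append((g["chrom"], s, e,
                                        f"{mark}_{g['name']}"))
    peaks = {
        mark: pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        .sort_values(["chrom", "start"]).reset_index(drop=True)
        for mark, rows in peak_rows.items()
    }

    truth = _build_truth(annotation, states, config)
    return truth, peaks


def _build_truth(annotation: GenomeAnnotation, states: pd.DataFrame,
                 config: SimConfig) -> GroundTruth:
    from .annotation import promoter_interval, three_prime_interval

    rows = []
    for _, g in annotation.genes.iterrows():
        clen = annotation.chrom_lengths[g["chrom"]]
        ps, pe = promoter_interval(g, chrom_length=clen)
        ts, te = three_prime_interval(g, chrom_length=clen)
        rows.append((f"prom_{g['name']}", g["name"], "promoter", g["chrom"], ps, pe))
        rows.append((f"body_{g['name']}", g["name"], "body", g["chrom"],
                     g["tx_start"], g["tx_end"]))
        rows.append((f"tes_{g['name']}", g["name"], "three_prime_end",
                     g["chrom"], ts, te))
    for _, c in annotation.cgis.iterrows():
        host = c["name"].split("cgi_prom_")[-1] if c["name"].startswith("cgi_prom_") else None
        rows.append((c["name"], host, "cgi", c["chrom"], c["start"], c["end"]))
    features = pd.DataFrame(rows, columns=["feature_id", "gene", "feature_class",
                                           "chrom", "start", "end"])

    base = config.baseline_meth
    control = features["feature_class"].map(
        {"promoter": base["promoter"], "body": base["body"],
         "three_prime_end": base["three_prime_end"], "cgi": base["cgi"]}
    ).to_numpy(dtype=float)
    meth = pd.DataFrame({"control": control}, index=features["feature_id"])
    intergenic = {"control": base["intergenic"]}

    cat = states.set_index("gene")["category"]
    planted_rows = []
    for condition in config.conditions[1:]:
        level = meth["control"].to_numpy().copy()
        intergenic[condition] = base["intergenic"]
        for eff in config.kd_effects:
            if eff.condition != condition:
                continue
            if eff.stratum in STATE_CATEGORIES:
                target_genes = set(cat.index[cat == eff.stratum])
                mask = (
                    ((features["feature_class"] == "promoter")
                     & features["gene"].isin(target_genes))
                    | ((features["feature_class"] == "cgi")
                       & features["gene"].isin(target_genes))
                ).to_numpy()
            else:
                mask = (features["feature_class"] == eff.stratum).to_numpy()
            level[mask] = np.clip(level[mask] * eff.fold, 0.0, 1.0)
            for fid, gene, fclass in features.loc[
                mask, ["feature_id", "gene", "feature_class"]
            ].itertuples(index=False):
                planted_rows.append((condition, fid, gene, fclass, eff.fold))
        meth[condition] = level
    planted = pd.DataFrame(planted_rows, columns=["condition", "feature_id",
                                                  "gene", "feature_class", "fold"])
    return GroundTruth(states, features, meth, planted, intergenic)


# ---------------------------------------------------------------------------
# tag libraries

_CLASS_PRECEDENCE = ("body", "three_prime_end", "promoter", "cgi")


def _window_cpg_weight(codes: np.ndarray, window: int) -> np.ndarray:
    is_cg = ((codes[:-1] == 1) & (codes[1:] == 2)).astype(np.int64)
    n_win = -(-len(codes) // window)
    starts = np.arange(n_win) * window
    padded = np.concatenate([is_cg, np.zeros(1, dtype=np.int64)])
    sums = np.add.reduceat(padded, starts)
    return sums.astype(float)


def window_methylation(annotation: GenomeAnnotation, truth: GroundTruth,
                       condition: str, window: int) -> dict[str, np.ndarray]:
    """Per-window true methylation for a condition, assembled from feature
    truth with precedence cgi > promoter > 3' end > body > intergenic."""
    if condition not in truth.meth.columns:
        raise ValueError(f"unknown condition {condition!r}; expected one of "
                         f"{list(truth.meth.columns)}")
    meth = truth.meth[condition]
    out = {}
    for chrom, length in annotation.chrom_lengths.items():
        n_win = -(-length // window)
        arr = np.full(n_win, truth.intergenic_meth[condition], dtype=float)
        sub = truth.features[truth.features["chrom"] == chrom]
        for fclass in _CLASS_PRECEDENCE:
            for fid, start, end in sub.loc[
                sub["feature_class"] == fclass,
                ["feature_id", "start", "end"],
            ].itertuples(index=False):
                # windows whose center lies inside the feature
                lo = int(np.ceil((start - window / 2) / window))
                hi = int(np.ceil((end - window / 2) / window))
                lo, hi = max(lo, 0), min(hi, n_win)
                if hi > lo:
                    arr[lo:hi] = meth.loc[fid]
        out[chrom] = arr
    return out


def simulate_mbd_library(annotation: GenomeAnnotation, truth: GroundTruth,
                         condition: str, config: SimConfig) -> TagLibrary:
    """Sample a capture-seq tag library for one condition.

    Per-window expected counts are proportional to methylation x CpG weight,
    scaled so the expected library size is ``depth`` (a fraction
    ``background_floor`` of which is uniform background); counts are Poisson,
    tag positions uniform within the window, strands uniform.
    """
    conditions = config.conditions
    if condition not in conditions:
        raise ValueError(f"unknown condition {condition!r}; expected one of "
                         f"{conditions}")
    rng = np.random.default_rng([config.seed, 2, conditions.index(condition)])
    w = config.window_size
    meth = window_methylation(annotation, truth, condition, w)

    signal = {}
    total_signal = 0.0
    n_windows_total = 0
    for chrom, codes in annotation.genome_seq.items():
        cpgw = _window_cpg_weight(codes, w)
        sig = meth[chrom] * cpgw
        signal[chrom] = sig
        total_signal += float(sig.sum())
        n_windows_total += sig.size

    floor = config.background_floor * config.depth / n_windows_total
    scale = ((1 - config.background_floor) * config.depth / total_signal
             if total_signal > 0 else 0.0)

    frames = []
    for chrom in sorted(annotation.chrom_lengths):
        rate = signal[chrom] * scale + floor
        counts = rng.poisson(rate)
        total = int(counts.sum())
        if total == 0:
            continue
        starts = np.repeat(np.arange(counts.size) * w, counts)
        offsets = rng.integers(0, w, size=total)
        pos = np.minimum(starts + offsets, annotation.chrom_lengths[chrom] - 1)
        strand = np.where(rng.random(total) < 0.5, "+", "-")
        frames.append(pd.DataFrame({"chrom": chrom, "pos": np.sort(pos),
                                    "strand": strand}))
    tags = (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["chrom", "pos", "strand"]))
    return TagLibrary(condition, tags)


# ---------------------------------------------------------------------------
# validation assays

def simulate_infinium(truth: GroundTruth, annotation: GenomeAnnotation,
                      config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Infinium-like beta matrix and probe map.

    Three probes per gene are placed in the -1700 bp promoter window
    upstream of the TSS; replicate betas are the true promoter methylation
    of the condition plus N(0, beta_noise_sd) noise, clipped to [0, 1].
    Returns (beta, probe_map): ``beta`` has a probe index and MultiIndex
    columns (condition, replicate).
    """
    if config.beta_replicates < 1:
        raise ValueError("beta_replicates must be >= 1")
    rng = np.random.default_rng([config.seed, 3])
    offsets = (-1500, -900, -300)
    probe_rows = []
    for _, g in annotation.genes.iterrows():
        if g["strand"] == "+":
            tss, sign = g["tx_start"], 1
        else:
            tss, sign = g["tx_end"], -1
        for k, off in enumerate(offsets):
            pos = tss + sign * off
            probe_rows.append((f"probe_{g['name']}_{k}", g["chrom"],
                               int(pos), g["name"]))
    probe_map = pd.DataFrame(probe_rows,
                             columns=["probe", "chrom", "pos", "gene"])
    prom_meth = truth.meth.loc[
        [f"prom_{g}" for g in probe_map["gene"]]
    ].reset_index(drop=True)
    data = {}
    for condition in config.conditions:
        base = prom_meth[condition].to_numpy()
        for rep in range(config.beta_replicates):
            noise = (rng.normal(0.0, config.beta_noise_sd, size=base.size)
                     if config.beta_noise_sd > 0 else 0.0)
            data[(condition, rep)] = np.clip(base + noise, 0.0, 1.0)
    beta = pd.DataFrame(data, index=probe_map["probe"])
    beta.columns = pd.MultiIndex.from_tuples(beta.columns,
                                             names=["condition", "replicate"])
    return beta, probe_map


def simulate_medip_ct(truth: GroundTruth, loci, config: SimConfig,
                      condition: str | None = None,
                      input_ct: float = 25.0) -> pd.DataFrame:
    """MeDIP-qPCR Ct pairs for promoter loci of the given condition.

    The planted enrichment of a locus is its true promoter methylation
    relative to the genome-average control methylation (the input);
    sample Ct = input Ct - log2(enrichment) + N(0, ct_noise_sd).
    """
    if condition is None:
        condition = config.conditions[-1]
    if condition not in truth.meth.columns:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng([config.seed, 4])
    reference = float(truth.meth["control"].mean())
    rows = []
    for gene in loci:
        fid = f"prom_{gene}"
        if fid not in truth.meth.index:
            raise ValueError(f"locus {gene!r} not in the annotation")
        enrichment = float(truth.meth.loc[fid, condition]) / reference
        noise = (rng.normal(0.0, config.ct_noise_sd)
                 if config.ct_noise_sd > 0 else 0.0)
        sample_ct = input_ct - np.log2(enrichment) + noise
        rows.append((gene, sample_ct, input_ct, enrichment))
    return pd.DataFrame(rows, columns=["locus", "sample_mean_ct",
                                       "input_mean_ct", "true_enrichment"])


# ---------------------------------------------------------------------------
# focused planted-truth benchmarks for the caller

def simulate_planted_domains(n_domains: int = 50, domain_length: int = 2000,
                             fold: float = 8.0, genome_length: int = 6_000_000,
                             n_chromosomes: int = 3,
                             background_tags: int = 13_000,
                             seed: int = 0) -> tuple[TagLibrary, pd.DataFrame]:
    """Uniform-background library with enriched domains planted at a known
    fold over background; returns (library, domain table).

    Default background depth gives roughly 0.5 expected background tags per
    200-bp window, a typical enrichment-sequencing coverage for a small
    genome.
    """
    rng = np.random.default_rng(seed)
    chrom_len = genome_length // n_chromosomes
    chrom_lengths = {f"chr{i + 1}": chrom_len for i in range(n_chromosomes)}
    per_chrom = [n_domains // n_chromosomes] * n_chromosomes
    for i in range(n_domains % n_chromosomes):
        per_chrom[i] += 1
    domains = []
    for chrom, k in zip(chrom_lengths, per_chrom):
        # evenly spaced, jittered, never closer than 10 kb
        spacing = chrom_len // (k + 1)
        for j in range(k):
            center = (j + 1) * spacing + int(rng.integers(-spacing // 4,
                                                          spacing // 4))
            start = max(0, center - domain_length // 2)
            domains.append((chrom, start, start + domain_length))
    domains = pd.DataFrame(domains, columns=["chrom", "start", "end"])

    bg_rate = background_tags / genome_length  # tags per bp
    frames = []
    for chrom, length in chrom_lengths.items():
        n_bg = rng.poisson(bg_rate * length)
        pos = rng.integers(0, length, size=n_bg)
        sub = domains[domains["chrom"] == chrom]
        extra = []
        for _, d in sub.iterrows():
            n_d = rng.poisson(bg_rate * (fold - 1) * (d["end"] - d["start"]))
            extra.append(rng.integers(d["start"], d["end"], size=n_d))
        pos = np.sort(np.concatenate([pos] + extra)) if extra else np.sort(pos)
        strand = np.where(rng.random(pos.size) < 0.5, "+", "-")
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                    "strand": strand}))
    lib = TagLibrary("planted_domains", pd.concat(frames, ignore_index=True))
    return lib, domains


def simulate_planted_differential(n_islands: int = 600, n_diff: int = 30,
                                  fold: float = 4.0, island_length: int = 2000,
                                  depth: int = 500_000,
                                  genome_length: int = 6_000_000,
                                  seed: int = 0):
    """Two libraries over a fixed island set, with ``n_diff`` islands
    enriched ``fold``-x in library A; returns (islands, lib_a, lib_b,
    differential island indices, chrom_lengths)."""
    rng = np.random.default_rng(seed)
    chrom_lengths = {"chr1": genome_length}
    spacing = genome_length // (n_islands + 1)
    if spacing <= island_length:
        raise ValueError("genome too small for the requested island count")
    starts = np.arange(1, n_islands + 1) * spacing
    islands = pd.DataFrame({"chrom": "chr1", "start": starts,
                            "end": starts + island_length})
    diff_idx = np.sort(rng.choice(n_islands, size=n_diff, replace=False))
    weights_b = np.ones(n_islands)
    weights_a = weights_b.copy()
    weights_a[diff_idx] = fold

    def sample(weights, label, child):
        r = np.random.default_rng([seed, child])
        lam = depth * weights / weights.sum()
        counts = r.poisson(lam)
        pos = np.concatenate([
            r.integers(s, s + island_length, size=c)
            for s, c in zip(starts, counts)
        ])
        pos = np.sort(pos)
        strand = np.where(r.random(pos.size) < 0.5, "+", "-")
        return TagLibrary(label, pd.DataFrame({"chrom": "chr1", "pos": pos,
                                               "strand": strand}))

    lib_a = sample(weights_a, "condition_a", 10)
    lib_b = sample(weights_b, "condition_b", 11)
    return islands, lib_a, lib_b, diff_idx, chrom_lengths
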