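"""Genomic feature annotation.

Maps intervals to genes and feature classes (promoter / body / 3' end /
intergenic), contexts CpG islands and their shores, and classifies promoters
by CpG density into HCP / ICP / LCP using sliding-window CpG
observed/expected and GC-content criteria.

Promoters default to TSS +/- 1 kb and gene 3' ends to TTS + 1 kb, both
strand-aware.  Multi-overlap intervals are resolved with the precedence
promoter > body > 3' end > intergenic; ties within a class are broken by
larger overlap, then by gene name, so classification is deterministic and
independent of gene-table order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PROMOTER_UP = 1000
PROMOTER_DOWN = 1000
THREE_PRIME_EXTENT = 1000
SHORE_FLANK = 2000

# HCP/ICP/LCP thresholds: CpG observed/expected and GC fraction over 500-bp
# windows stepped by 5 bp across the promoter core.
CPG_WINDOW = 500
CPG_STEP = 5
HCP_OE = 0.75
HCP_GC = 0.55
LCP_OE = 0.48

_CLASS_RANK = {"promoter": 0, "body": 1, "three_prime_end": 2}


def promoter_interval(gene, up: int = PROMOTER_UP, down: int = PROMOTER_DOWN,
                      chrom_length: int | None = None) -> tuple[int, int]:
    """Strand-aware promoter window around the TSS, clipped to the chromosome.

    ``gene`` is any mapping with strand/tx_start/tx_end.  Plus strand: TSS is
    tx_start and the window is [TSS - up, TSS + down); minus strand: TSS is
    tx_end and the window mirrors to [TSS - down, TSS + up).
    """
    if gene["strand"] == "+":
        tss = int(gene["tx_start"])
        start, end = tss - up, tss + down
    else:
        tss = int(gene["tx_end"])
        start, end = tss - down, tss + up
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, end


def three_prime_interval(gene, extent: int = THREE_PRIME_EXTENT,
                         chrom_length: int | None = None) -> tuple[int, int]:
    """Strand-aware window of ``extent`` bp immediately past the TTS."""
    if gene["strand"] == "+":
        start, end = int(gene["tx_end"]), int(gene["tx_end"]) + extent
    else:
        start, end = int(gene["tx_start"]) - extent, int(gene["tx_start"])
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, end


class GeneFeatureIndex:
    """Per-chromosome arrays of promoter/body/3'-end intervals for fast
    overlap classification."""

    def __init__(self, genes: pd.DataFrame, chrom_lengths: dict[str, int],
                 up: int = PROMOTER_UP, down: int = PROMOTER_DOWN,
                 three_prime_extent: int = THREE_PRIME_EXTENT):
        self.up, self.down = up, down
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, sub in genes.groupby("chrom"):
            clen = chrom_lengths.get(chrom)
            proms = np.array([
                promoter_interval(g, up, down, clen) for _, g in sub.iterrows()
            ]).reshape(-1, 2)
            tes = np.array([
                three_prime_interval(g, three_prime_extent, clen)
                for _, g in sub.iterrows()
            ]).reshape(-1, 2)
            self._by_chrom[chrom] = {
                "names": sub["name"].to_numpy(),
                "promoter": proms,
                "body": sub[["tx_start", "tx_end"]].to_numpy(),
                "three_prime_end": tes,
            }

    def classify(self, chrom: str, start: int, end: int) -> tuple[str, str | None]:
        """Feature class of [start, end) and the gene granting the winning
        overlap (class precedence first, then overlap size, then name)."""
        info = self._by_chrom.get(chrom)
        if info is None:
            return "intergenic", None
        best = None  # (rank, -overlap, name)
        for cls in ("promoter", "body", "three_prime_end"):
            iv = info[cls]
            ov = np.minimum(iv[:, 1], end) - np.maximum(iv[:, 0], start)
            hits = np.flatnonzero(ov > 0)
            if hits.size == 0:
                continue
            rank = _CLASS_RANK[cls]
            for i in hits:
                key = (rank, -int(ov[i]), str(info["names"][i]))
                if best is None or key < best[0]:
                    best = (key, cls, str(info["names"][i]))
            if best is not None and best[0][0] == rank:
                break  # lower-precedence classes cannot win
        if best is None:
            return "intergenic", None
        return best[1], best[2]


def classify_interval(interval, genes: pd.DataFrame, chrom_lengths: dict[str, int],
                      up: int = PROMOTER_UP, down: int = PROMOTER_DOWN
                      ) -> tuple[str, str | None]:
    """Classify a single (chrom, start, end) interval.  Convenience wrapper;
    build a :class:`GeneFeatureIndex` for repeated queries."""
    idx = GeneFeatureIndex(genes, chrom_lengths, up, down)
    chrom, start, end = interval
    return idx.classify(chrom, int(start), int(end))


def cgi_context(cgi_interval, genes: pd.DataFrame, chrom_lengths: dict[str, int],
                index: GeneFeatureIndex | None = None) -> str:
    """Context of a CGI: promoter, gene_body, three_prime, or intergenic."""
    chrom, start, end = cgi_interval
    idx = index or GeneFeatureIndex(genes, chrom_lengths)
    cls, _ = idx.classify(chrom, int(start), int(end))
    return {"promoter": "promoter", "body": "gene_body",
            "three_prime_end": "three_prime", "intergenic": "intergenic"}[cls]


def shore_intervals(cgi_interval, all_cgis: pd.DataFrame,
                    flank: int = SHORE_FLANK,
                    chrom_length: int | None = None) -> list[tuple[int, int]]:
    """CGI shores: up to ``flank`` bp on each side of a CGI, clipped to the
    chromosome, with any base falling inside another CGI removed."""
    if flank <= 0:
        raise ValueError("shore flank must be positive")
    chrom, start, end = cgi_interval
    segments = [(max(0, start - flank), start), (end, end + flank)]
    if chrom_length is not None:
        segments = [(s, min(e, chrom_length)) for s, e in segments]
    others = all_cgis[all_cgis["chrom"] == chrom]
    out: list[tuple[int, int]] = []
    for seg_start, seg_end in segments:
        pieces = [(seg_start, seg_end)]
        for _, row in others.iterrows():
            cs, ce = int(row["start"]), int(row["end"])
            nxt = []
            for ps, pe in pieces:
                if ce <= ps or cs >= pe:
                    nxt.append((ps, pe))
                    continue
                if ps < cs:
                    nxt.append((ps, cs))
                if ce < pe:
                    nxt.append((ce, pe))
            pieces = nxt
        out.extend((ps, pe) for ps, pe in pieces if pe > ps)
    return out


def cpg_observed_expected(seq: str) -> float:
    """CpG observed/expected ratio: (#CG x length) / (#C x #G).

    N bases are excluded from the length and never counted; a CG pair is
    counted only when both bases are called.  Returns 0 when #C x #G == 0.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    n_c = s.count("C")
    n_g = s.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cg = s.count("CG")
    length = len(s) - s.count("N")
    return (n_cg * length) / (n_c * n_g)


@dataclass
class PromoterCpGClass:
    cls: str  # HCP | ICP | LCP
    max_oe: float
    max_gc: float


def classify_promoter_cpg(seq: str, window: int = CPG_WINDOW, step: int = CPG_STEP,
                          hcp_oe: float = HCP_OE, hcp_gc: float = HCP_GC,
                          lcp_oe: float = LCP_OE) -> PromoterCpGClass:
    """HCP/ICP/LCP call from the promoter-core sequence.

    HCP: some window has CpG o/e >= hcp_oe AND GC fraction >= hcp_gc.
    LCP: no window reaches o/e >= lcp_oe.  Everything else is ICP.
    The scan uses ``window``-bp windows stepped by ``step`` bp and expects a
    sequence covering at least TSS -700..+200 (>= 900 bp recommended).
    """
    s = seq.upper()
    if len(s) < window:
        raise ValueError(
            f"promoter sequence of {len(s)} bp is shorter than the {window}-bp "
            f"scan window; supply at least the TSS -700..+200 core"
        )
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int32)
    is_g = (arr == ord("G")).astype(np.int32)
    is_n = (arr == ord("N")).astype(np.int32)
    is_cg = np.zeros_like(is_c)
    is_cg[:-1] = is_c[:-1] & is_g[1:]

    def window_sums(x):
        c = np.concatenate([[0], np.cumsum(x)])
        starts = np.arange(0, len(s) - window + 1, step)
        return c[starts + window] - c[starts]

    c_w = window_sums(is_c).astype(float)
    g_w = window_sums(is_g).astype(float)
    n_w = window_sums(is_n).astype(float)
    # CG pairs fully inside the window
    cg_cum = np.concatenate([[0], np.cumsum(is_cg)])
    starts = np.arange(0, len(s) - window + 1, step)
    cg_w = (cg_cum[np.minimum(starts + window - 1, len(s) - 1)] - cg_cum[starts]).astype(float)

    eff_len = window - n_w
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(c_w * g_w > 0, cg_w * eff_len / (c_w * g_w), 0.0)
        gc = np.where(eff_len > 0, (c_w + g_w) / eff_len, 0.0)

    max_oe = float(oe.max())
    max_gc = float(gc.max())
    if np.any((oe >= hcp_oe) & (gc >= hcp_gc)):
        cls = "HCP"
    elif max_oe < lcp_oe:
        cls = "LCP"
    else:
        cls = "ICP"
    return PromoterCpGClass(cls, max_oe, max_gc)


def classify_all_promoters(annotation, window: int = CPG_WINDOW,
                           step: int = CPG_STEP) -> pd.DataFrame:
    """HCP/ICP/LCP class for every gene from its stored promoter sequence."""
    rows = []
    for _, g in annotation.genes.iterrows():
        seq = annotation.promoter_seqs[g["name"]]
        res = classify_promoter_cpg(seq, window=window, step=step)
        rows.append((g["name"], res.cls, res.max_oe, res.max_gc))
    return pd.DataFrame(rows, columns=["gene", "cpg_class", "max_oe", "max_gc"])
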