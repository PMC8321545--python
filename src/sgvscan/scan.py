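"""Highly-differentiated-region (HDR) calling and gene-level annotation.

HDRs are maximal merges of sliding windows whose F_ST lies in the top
0.5% of a species pair's window distribution.  Regions gain a sweep flag
when a member window is simultaneously in the top 0.5% of both F_ST and
d_XY, a specificity label from the three pairwise HDR sets, and candidate
genes via a 10-kb flank overlap rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import GenotypeMatrix

DEFAULT_QUANTILE = 0.995
DEFAULT_FLANK = 10_000
MIN_WINDOWS_FOR_THRESHOLD = 200


@dataclass
class HDRegion:
    contig: str
    start: int
    end: int
    pair: tuple[str, str]
    threshold: float
    peak_fst: float
    peak_dxy: float = float("nan")
    sweep_flag: bool = False
    specificity: str = "unassigned"

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        return self.contig == contig and self.start < end and start < self.end


@dataclass
class GeneModel:
    """A gene interval with optional exon/UTR sub-intervals (0-based half-open)."""

    gene_id: str
    contig: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utrs: list[tuple[int, int]] = field(default_factory=list)

    def region_of(self, pos: int) -> str:
        """Classify a 0-based position: exon / UTR / intron / flank."""
        for s, e in self.utrs:
            if s <= pos < e:
                return "UTR"
        for s, e in self.exons:
            if s <= pos < e:
                return "exon"
        if self.start <= pos < self.end:
            return "intron" if self.exons else "exon"
        return "flank"


@dataclass
class CandidateGene:
    gene: GeneModel
    hdrs: list[HDRegion]
    max_dxy: float
    snps: pd.DataFrame | None = None


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Load gene models from BED (>=4 columns) or GFF3.

    BED rows become single-interval genes (no sub-structure).  GFF3 ``gene``
    features are associated with their ``exon`` and ``*UTR`` children via the
    Parent/ID attributes.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".gff", ".gff3"} or text.startswith("##gff"):
        return _read_gff3(text)
    genes = []
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        f = ln.split("\t")
        name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
        genes.append(GeneModel(name, f[0], int(f[1]), int(f[2])))
    return genes


def _read_gff3(text: str) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    children: list[tuple[str, str, int, int]] = []
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        f = ln.split("\t")
        if len(f) < 9:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
        )
        start, end = int(f[3]) - 1, int(f[4])  # GFF3 is 1-based inclusive
        ftype = f[2].lower()
        if ftype == "gene":
            gid = attrs.get("ID", f"{f[0]}:{f[3]}")
            genes[gid] = GeneModel(gid, f[0], start, end)
        elif ftype in {"exon", "five_prime_utr", "three_prime_utr", "utr"}:
            children.append((attrs.get("Parent", ""), ftype, start, end))
    for parent, ftype, start, end in children:
        g = genes.get(parent)
        if g is None:
            continue
        (g.exons if ftype == "exon" else g.utrs).append((start, end))
    return list(genes.values())


# ---------------------------------------------------------------------------
# HDR calling
# ---------------------------------------------------------------------------

def _top_quantile_threshold(values: np.ndarray, quantile: float) -> float:
    """Threshold of the empirical top ``1 - quantile`` tail.

    Defined as the k-th largest value with ``k = ceil((1 - quantile) * n)``,
    so exactly k windows exceed it when values are distinct and ties at the
    threshold are all included.  Deterministic by construction.
    """
    vals = values[~np.isnan(values)]
    if vals.size == 0:
        raise ValueError("all-missing statistic column")
    k = max(1, int(np.ceil((1.0 - quantile) * vals.size - 1e-9)))
    return float(np.sort(vals)[vals.size - k])


def _merge_windows(rows: pd.DataFrame) -> list[tuple[str, int, int, float, float]]:
    """Merge overlapping/book-ended windows into maximal regions."""
    merged = []
    for contig, grp in rows.groupby("contig", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for _, r in grp.iterrows():
            if cur is None or r["start"] > cur[2]:
                if cur is not None:
                    merged.append(cur)
                cur = [contig, int(r["start"]), int(r["end"]), r["_stat"], r.get("_dxy", np.nan)]
            else:
                cur[2] = max(cur[2], int(r["end"]))
                cur[3] = max(cur[3], r["_stat"])
                d = r.get("_dxy", np.nan)
                if not np.isnan(d) and (np.isnan(cur[4]) or d > cur[4]):
                    cur[4] = d
        if cur is not None:
            merged.append(cur)
    return [tuple(m) for m in merged]


def call_hdrs(
    stats: pd.DataFrame,
    pair: tuple[str, str],
    quantile: float = DEFAULT_QUANTILE,
    full_windows_only: bool = True,
) -> list[HDRegion]:
    """Call HDRs for one species pair from a WindowStatTable.

    Windows at or above the top-``1 - quantile`` empirical F_ST threshold are
    merged (overlapping or book-ended) into maximal regions.
    """
    col = _pair_col(stats, "fst", pair)
    dxy_col = _pair_col(stats, "dxy", pair, required=False)
    tbl = stats
    if full_windows_only and "full" in stats.columns:
        tbl = stats[stats["full"]]
    vals = tbl[col].to_numpy(dtype=float)
    n_valid = int(np.sum(~np.isnan(vals)))
    if n_valid < MIN_WINDOWS_FOR_THRESHOLD:
        warnings.warn(
            f"only {n_valid} valid windows for pair {pair}; "
            "quantile threshold may be unstable",
            stacklevel=2,
        )
    thr = _top_quantile_threshold(vals, quantile)
    hit = tbl[tbl[col] >= thr].copy()
    hit["_stat"] = hit[col]
    if dxy_col is not None:
        hit["_dxy"] = hit[dxy_col]
    regions = [
        HDRegion(contig, start, end, pair, thr, peak, peak_dxy=dxy)
        for contig, start, end, peak, dxy in _merge_windows(hit)
    ]
    return regions


def _pair_col(stats: pd.DataFrame, stat: str, pair: tuple[str, str], required: bool = True) -> str | None:
    a, b = pair
    for col in (f"{stat}_{a}_{b}", f"{stat}_{b}_{a}"):
        if col in stats.columns:
            return col
    if required:
        raise KeyError(f"no {stat} column for pair {pair}")
    return None


def sweep_flag(
    stats: pd.DataFrame,
    hdrs: Sequence[HDRegion],
    pair: tuple[str, str],
    dxy_quantile: float = DEFAULT_QUANTILE,
    full_windows_only: bool = True,
) -> list[HDRegion]:
    """Flag HDRs containing a window in the top tail of both F_ST and d_XY."""
    fst_col = _pair_col(stats, "fst", pair)
    dxy_col = _pair_col(stats, "dxy", pair)
    tbl = stats
    if full_windows_only and "full" in stats.columns:
        tbl = stats[stats["full"]]
    fst_thr = _top_quantile_threshold(tbl[fst_col].to_numpy(dtype=float), dxy_quantile)
    dxy_thr = _top_quantile_threshold(tbl[dxy_col].to_numpy(dtype=float), dxy_quantile)
    joint = tbl[(tbl[fst_col] >= fst_thr) & (tbl[dxy_col] >= dxy_thr)]
    for hdr in hdrs:
        hdr.sweep_flag = any(
            hdr.overlaps(r["contig"], int(r["start"]), int(r["end"]))
            for _, r in joint.iterrows()
        )
    return list(hdrs)


def assign_specificity(hdrs_by_pair: Mapping[tuple[str, str], Sequence[HDRegion]]) -> None:
    """Label every HDR as pair-only, species-specific, or multi-pair.

    An HDR of pair (A, B) overlapping (any bp) an HDR of the pair (A, C) but
    none of (B, C) is specific to the shared species A; overlap with both
    other pairs gives multi-pair; no overlap gives pair-only.
    """
    pairs = list(hdrs_by_pair)
    if len(pairs) != 3:
        raise ValueError("specificity assignment needs the three pairwise HDR sets")
    for pair in pairs:
        others = [p for p in pairs if p != pair]
        for hdr in hdrs_by_pair[pair]:
            hits = [
                any(hdr.overlaps(o.contig, o.start, o.end) for o in hdrs_by_pair[p])
                for p in others
            ]
            if all(hits):
                hdr.specificity = "multi-pair"
            elif not any(hits):
                hdr.specificity = "pair-only"
            else:
                shared_pair = others[hits.index(True)]
                shared = set(pair) & set(shared_pair)
                hdr.specificity = f"{next(iter(shared))}-specific"


# ---------------------------------------------------------------------------
# gene mapping and SNP annotation
# ---------------------------------------------------------------------------

def map_genes_to_hdrs(
    hdrs: Sequence[HDRegion],
    genes: Sequence[GeneModel],
    stats: pd.DataFrame | None = None,
    pair: tuple[str, str] | None = None,
    flank: int = DEFAULT_FLANK,
    known_contigs: Iterable[str] | None = None,
) -> list[CandidateGene]:
    """Genes whose ``flank``-expanded interval overlaps an HDR.

    ``max_dxy`` is the peak window d_XY over windows overlapping the gene
    (requires ``stats`` and ``pair``; NaN otherwise).
    """
    if known_contigs is not None:
        known = set(known_contigs)
    else:
        known = {h.contig for h in hdrs}
        if stats is not None:
            known |= set(stats["contig"].unique())
    dxy_col = _pair_col(stats, "dxy", pair) if stats is not None and pair else None
    out = []
    for gene in genes:
        if known and gene.contig not in known:
            warnings.warn(f"gene {gene.gene_id} on unknown contig {gene.contig}; skipped",
                          stacklevel=2)
            continue
        owning = [
            h for h in hdrs
            if h.overlaps(gene.contig, gene.start - flank, gene.end + flank)
        ]
        if not owning:
            continue
        max_dxy = float("nan")
        if dxy_col is not None:
            sub = stats[
                (stats["contig"] == gene.contig)
                & (stats["start"] < gene.end)
                & (stats["end"] > gene.start)
            ]
            vals = sub[dxy_col].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size:
                max_dxy = float(vals.max())
        out.append(CandidateGene(gene, owning, max_dxy))
    return out


def annotate_differentiated_snps(
    gm: GenotypeMatrix,
    candidates: Sequence[CandidateGene],
    pair: tuple[str, str],
    diff_freq: float = 0.5,
    large_delta: float = 0.6,
    flank: int = DEFAULT_FLANK,
) -> list[CandidateGene]:
    """Annotate SNPs within each candidate gene +/- ``flank``.

    A SNP is *differentiated* when either species' alt-allele frequency is
    >= ``diff_freq`` and it gets a *large-difference* flag when
    ``|p_A - p_B| >= large_delta``.  Each SNP is labelled by genic region
    (exon / intron / UTR / flank).
    """
    A, B = pair
    colsA = gm.columns_for_species(A)
    colsB = gm.columns_for_species(B)
    pA = gm.alt_freq(colsA)
    pB = gm.alt_freq(colsB)
    for cand in candidates:
        g = cand.gene
        in_range = (
            (gm.contig == g.contig)
            & (gm.pos >= g.start - flank)
            & (gm.pos < g.end + flank)
        )
        idx = np.flatnonzero(in_range)
        rows = []
        for i in idx:
            region = g.region_of(int(gm.pos[i]))
            fa, fb = float(pA[i]), float(pB[i])
            delta = abs(fa - fb) if not (np.isnan(fa) or np.isnan(fb)) else np.nan
            rows.append(
                {
                    "pos": int(gm.pos[i]),
                    "region": region,
                    f"freq_{A}": fa,
                    f"freq_{B}": fb,
                    "delta": delta,
                    "differentiated": bool(max(fa, fb) >= diff_freq)
                    if not (np.isnan(fa) or np.isnan(fb)) else False,
                    "large_difference": bool(delta >= large_delta)
                    if not np.isnan(delta) else False,
                }
            )
        cand.snps = pd.DataFrame(
            rows,
            columns=["pos", "region", f"freq_{A}", f"freq_{B}", "delta",
                     "differentiated", "large_difference"],
        )
    return list(candidates)


def coding_differentiated_summary(candidates: Sequence[CandidateGene]) -> pd.DataFrame:
    """Per-gene: does the coding region carry any differentiated SNP?"""
    rows = []
    for cand in candidates:
        snps = cand.snps
        has_coding = False
        if snps is not None and len(snps):
            has_coding = bool(
                ((snps["region"] == "exon") & snps["differentiated"]).any()
            )
        rows.append(
            {
                "gene": cand.gene.gene_id,
                "coding_differentiated": has_coding,
                "max_dxy": cand.max_dxy,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "coding_differentiated", "max_dxy"])


def hdrs_to_frame(hdrs: Iterable[HDRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": h.contig,
                "start": h.start,
                "end": h.end,
                "pair": f"{h.pair[0]}-{h.pair[1]}",
                "threshold": h.threshold,
                "peak_fst": h.peak_fst,
                "peak_dxy": h.peak_dxy,
                "sweep_flag": h.sweep_flag,
                "specificity": h.specificity,
            }
            for h in hdrs
        ],
        columns=["contig", "start", "end", "pair", "threshold", "peak_fst",
                 "peak_dxy", "sweep_flag", "specificity"],
    )
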