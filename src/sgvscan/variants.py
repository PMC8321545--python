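"""VCF ingestion, site filtering, LD pruning and per-individual inbreeding.

The central data structure is :class:`GenotypeMatrix`, a sites x individuals
table of diploid alt-allele dosages with per-site metadata and an
individual -> species map.  Filtering follows the usual chain applied to a
merged multi-sample VCF: biallelic only, no indels, no missing genotypes,
and a Hardy-Weinberg exact-test cutoff.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

MISSING = -1  # sentinel dosage for an uncalled genotype


class SampleMapError(ValueError):
    """A VCF sample is absent from the species map."""


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for many sites and individuals.

    Attributes
    ----------
    contig, pos, ref, alt :
        Per-site metadata.  ``pos`` is 0-based internally (VCF input is
        converted on read).
    dosage :
        ``(n_sites, n_individuals)`` int8 array of alt-allele dosages
        (0, 1, 2) with :data:`MISSING` for uncalled genotypes.
    haplotypes :
        ``(n_sites, 2 * n_individuals)`` int8 array of phased alleles, or
        ``None`` when phase is unavailable.  Column ``2i`` and ``2i+1`` are
        the two haplotypes of individual ``i``.
    is_indel, is_multiallelic :
        Per-site boolean flags (such records are retained but flagged).
    samples :
        Individual names, column order of ``dosage``.
    species_map :
        individual name -> species name; every individual must be mapped.
    """

    contig: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    samples: list[str]
    species_map: dict[str, str]
    haplotypes: np.ndarray | None = None
    is_indel: np.ndarray | None = None
    is_multiallelic: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.n_sites
        if self.is_indel is None:
            self.is_indel = np.zeros(n, dtype=bool)
        if self.is_multiallelic is None:
            self.is_multiallelic = np.zeros(n, dtype=bool)
        unmapped = [s for s in self.samples if s not in self.species_map]
        if unmapped:
            raise SampleMapError(
                f"samples missing from species map: {', '.join(unmapped)}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def is_phased(self) -> bool:
        return self.haplotypes is not None

    def species_of(self) -> np.ndarray:
        """Species label per dosage column."""
        return np.array([self.species_map[s] for s in self.samples])

    def columns_for_species(self, species: str) -> np.ndarray:
        """Dosage column indices of the individuals of ``species``."""
        idx = np.flatnonzero(self.species_of() == species)
        if idx.size == 0:
            raise KeyError(f"no individuals mapped to species {species!r}")
        return idx

    def haplotype_columns_for_species(self, species: str) -> np.ndarray:
        cols = self.columns_for_species(species)
        return np.sort(np.concatenate([2 * cols, 2 * cols + 1]))

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the sites selected by ``index`` (keeps column order)."""
        return GenotypeMatrix(
            contig=self.contig[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosage=self.dosage[index],
            samples=list(self.samples),
            species_map=dict(self.species_map),
            haplotypes=None if self.haplotypes is None else self.haplotypes[index],
            is_indel=self.is_indel[index],
            is_multiallelic=self.is_multiallelic[index],
        )

    def allele_counts(self, columns: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(alt allele count, called allele count) per site over ``columns``."""
        d = self.dosage if columns is None else self.dosage[:, columns]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=1)
        return alt.astype(np.int64), 2 * called.sum(axis=1).astype(np.int64)

    def alt_freq(self, columns: np.ndarray | None = None) -> np.ndarray:
        alt, m = self.allele_counts(columns)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(m > 0, alt / np.maximum(m, 1), np.nan)


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>species`` TSV."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
        out[parts[0]] = parts[1]
    return out


def read_vcf(path: str | Path, species_map: Mapping[str, str]) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and indel records are retained but flagged; ``./.`` becomes
    the missing sentinel.  Phase is kept when every genotype is phased.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in species_map]
    if missing:
        raise SampleMapError(
            f"samples missing from species map: {', '.join(missing)}"
        )

    contigs, positions, refs, alts = [], [], [], []
    dosages, hap_rows, indel, multi = [], [], [], []
    all_phased = True
    for rec in vcf:
        contigs.append(rec.CHROM)
        positions.append(rec.POS - 1)  # to 0-based
        refs.append(rec.REF)
        alt_alleles = rec.ALT
        alts.append(alt_alleles[0] if alt_alleles else ".")
        multi.append(len(alt_alleles) > 1)
        indel.append(
            len(rec.REF) != 1 or any(len(a) != 1 for a in alt_alleles)
        )
        row = np.empty(len(samples), dtype=np.int8)
        hrow = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(rec.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                row[i] = MISSING
                hrow[2 * i] = hrow[2 * i + 1] = MISSING
            else:
                # non-ref dosage; multiallelic records are flagged anyway
                row[i] = int(a > 0) + int(b > 0)
                hrow[2 * i] = a
                hrow[2 * i + 1] = b
            if not g[2]:
                all_phased = False
        dosages.append(row)
        hap_rows.append(hrow)

    n = len(positions)
    return GenotypeMatrix(
        contig=np.array(contigs),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs),
        alt=np.array(alts),
        dosage=np.array(dosages, dtype=np.int8) if n else np.empty((0, len(samples)), np.int8),
        samples=samples,
        species_map=dict(species_map),
        haplotypes=(np.array(hap_rows, dtype=np.int8) if (all_phased and n) else None),
        is_indel=np.array(indel, dtype=bool),
        is_multiallelic=np.array(multi, dtype=bool),
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path, contig_lengths: Mapping[str, int] | None = None,
              ancestral_is_ref: bool = False) -> None:
    """Write a GenotypeMatrix back out as VCF v4.2 (phased GT when available)."""
    lines = ["##fileformat=VCFv4.2", "##source=sgvscan"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in dict.fromkeys(gm.contig.tolist()):
            lines.append(f"##contig=<ID={name}>")
    if ancestral_is_ref:
        lines.append('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples))
    sep = "|" if gm.is_phased else "/"
    for i in range(gm.n_sites):
        info = f"AA={gm.ref[i]}" if ancestral_is_ref else "."
        if gm.is_phased:
            h = gm.haplotypes[i]
            gts = [
                "./." if h[2 * j] == MISSING else f"{h[2 * j]}{sep}{h[2 * j + 1]}"
                for j in range(gm.n_individuals)
            ]
        else:
            code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            gts = [code[int(d)] for d in gm.dosage[i]]
        lines.append(
            f"{gm.contig[i]}\t{int(gm.pos[i]) + 1}\t.\t{gm.ref[i]}\t{gm.alt[i]}\t.\t.\t{info}\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional (Levene) Hardy-Weinberg test.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities that are <= the probability of the
    observed heterozygote count.  Monomorphic sites return 1 by convention.
    Symmetric in the two homozygote counts.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_ref, n_alt)
    if n_minor == 0:
        return 1.0

    # log P(het = h | allele counts) up to a shared constant:
    #   P(h) ∝ 2^h * n! / (hom_ref! het! hom_alt!)  with fixed allele counts
    def log_weight(h: int) -> float:
        hom_min = (n_minor - h) // 2
        hom_maj = (max(n_ref, n_alt) - h) // 2
        return (
            h * math.log(2.0)
            - math.lgamma(hom_min + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_maj + 1)
        )

    hets = range(n_minor % 2, n_minor + 1, 2)
    logw = {h: log_weight(h) for h in hets}
    mx = max(logw.values())
    weights = {h: math.exp(w - mx) for h, w in logw.items()}
    total = sum(weights.values())
    obs = weights[n_het]
    # tolerance keeps the observed outcome included despite rounding
    p = sum(w for w in weights.values() if w <= obs * (1 + 1e-12)) / total
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Thresholds for the merged-VCF site-filter chain.

    ``maf_min`` is only applied when ``apply_maf`` is set (structure analyses
    prune on MAF; the genome scans do not).
    """

    require_biallelic: bool = True
    drop_indels: bool = True
    max_missing_fraction: float = 0.0
    hwe_alpha: float | None = 0.001
    hwe_pooled: bool = True
    maf_min: float = 0.05
    apply_maf: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.hwe_alpha is not None and not 0.0 <= self.hwe_alpha <= 1.0:
            raise ValueError("hwe_alpha must be in [0, 1]")
        if not 0.0 <= self.maf_min <= 1.0:
            raise ValueError("maf_min must be in [0, 1]")


def _hwe_pvalues(gm: GenotypeMatrix, columns: np.ndarray | None = None) -> np.ndarray:
    d = gm.dosage if columns is None else gm.dosage[:, columns]
    p = np.ones(gm.n_sites)
    for i in range(gm.n_sites):
        row = d[i]
        row = row[row != MISSING]
        p[i] = hwe_exact_test(
            int(np.sum(row == 0)), int(np.sum(row == 1)), int(np.sum(row == 2))
        )
    return p


def filter_sites(gm: GenotypeMatrix, cfg: FilterConfig | None = None) -> tuple[GenotypeMatrix, "pd.DataFrame"]:
    """Apply the site-filter chain; returns (filtered matrix, filter log).

    The log has one row per input site with the first rule that removed it
    (or ``pass``).  Rules run in order: biallelic, indel, missing, HWE, MAF.
    The HWE test pools all individuals by default (``cfg.hwe_pooled``);
    per-species mode removes a site if any species deviates.
    """
    import pandas as pd

    if cfg is None:
        cfg = FilterConfig()
    n = gm.n_sites
    reason = np.array(["pass"] * n, dtype=object)
    alive = np.ones(n, dtype=bool)

    def knock(mask: np.ndarray, tag: str) -> None:
        hit = alive & mask
        reason[hit] = tag
        alive[hit] = False

    if cfg.require_biallelic:
        knock(gm.is_multiallelic, "multiallelic")
    if cfg.drop_indels:
        knock(gm.is_indel, "indel")
    missing_frac = np.mean(gm.dosage == MISSING, axis=1)
    knock(missing_frac > cfg.max_missing_fraction, "missing")
    if cfg.hwe_alpha is not None:
        sub = gm.take_sites(np.flatnonzero(alive))
        if cfg.hwe_pooled:
            pvals = _hwe_pvalues(sub)
            bad = pvals < cfg.hwe_alpha
        else:
            bad = np.zeros(sub.n_sites, dtype=bool)
            for sp in sorted(set(sub.species_map.values())):
                cols = sub.columns_for_species(sp)
                bad |= _hwe_pvalues(sub, cols) < cfg.hwe_alpha
        full_bad = np.zeros(n, dtype=bool)
        full_bad[np.flatnonzero(alive)] = bad
        knock(full_bad, "hwe")
    if cfg.apply_maf:
        alt, m = gm.allele_counts()
        with np.errstate(invalid="ignore"):
            freq = np.where(m > 0, alt / np.maximum(m, 1), 0.0)
        maf = np.minimum(freq, 1 - freq)
        knock(maf < cfg.maf_min, "maf")

    log = pd.DataFrame(
        {
            "contig": gm.contig,
            "pos": gm.pos + 1,  # 1-based, as in the source VCF
            "filter": reason,
        }
    )
    return gm.take_sites(np.flatnonzero(alive)), log


# ---------------------------------------------------------------------------
# LD pruning (plink --indep-pairwise style)
# ---------------------------------------------------------------------------

def _dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (missing-pair dropped)."""
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok].astype(float), y[ok].astype(float)
    if len(x) < 2:
        return 0.0
    vx, vy = x.var(), y.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    c = np.cov(x, y, bias=True)[0, 1]
    return float(c * c / (vx * vy))


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.1,
) -> np.ndarray:
    """Greedy pairwise LD pruning; returns indices of kept sites.

    Windows of ``window_snps`` sites advance by ``step_snps``.  Within a
    window, while any kept pair has composite-LD r^2 > ``r2_max``, the member
    with the lower minor-allele frequency is removed (tie: the later site).
    Deterministic for fixed input.
    """
    n = gm.n_sites
    keep = np.ones(n, dtype=bool)
    alt, m = gm.allele_counts()
    with np.errstate(invalid="ignore"):
        freq = np.where(m > 0, alt / np.maximum(m, 1), 0.0)
    maf = np.minimum(freq, 1 - freq)
    any_missing = bool(np.any(gm.dosage == MISSING))

    def first_offending_pair(live: np.ndarray):
        if not any_missing:
            d = gm.dosage[live].astype(float)
            sd = d.std(axis=1)
            ok = sd > 0
            z = np.zeros_like(d)
            z[ok] = (d[ok] - d[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
            r2 = (z @ z.T / d.shape[1]) ** 2
            mask = np.triu(r2 > r2_max, k=1)
            hits = np.argwhere(mask)
            if len(hits):
                a, b = hits[0]
                return live[a], live[b]
            return None
        for ai in range(len(live)):
            for bi in range(ai + 1, len(live)):
                if _dosage_r2(gm.dosage[live[ai]], gm.dosage[live[bi]]) > r2_max:
                    return live[ai], live[bi]
        return None

    start = 0
    while True:
        idx = np.arange(start, min(start + window_snps, n))
        while True:
            live = idx[keep[idx]]
            pair = first_offending_pair(live) if len(live) > 1 else None
            if pair is None:
                break
            a, b = pair
            # drop lower-MAF member; tie -> later position
            drop = a if maf[a] < maf[b] else b
            if maf[a] == maf[b]:
                drop = b
            keep[drop] = False
        if start + window_snps >= n:
            break
        start += step_snps
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# Inbreeding coefficient
# ---------------------------------------------------------------------------

def inbreeding_coefficient(gm: GenotypeMatrix) -> "pd.Series":
    """Method-of-moments F per individual: (O_hom - E_hom) / (L - E_hom).

    E_hom at a site is ``1 - 2 p (1-p) m/(m-1)`` with p the pooled alt
    frequency and m the pooled called-allele count; the sum runs over the
    sites at which the individual is genotyped.  Individuals with a
    degenerate denominator are reported as NaN.
    """
    import pandas as pd

    if gm.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    alt, m = gm.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(m > 0, alt / np.maximum(m, 1), np.nan)
        e_hom = 1.0 - 2.0 * p * (1 - p) * m / np.maximum(m - 1, 1)
    usable = m >= 2

    out = {}
    for j, name in enumerate(gm.samples):
        called = (gm.dosage[:, j] != MISSING) & usable
        L = int(called.sum())
        if L == 0:
            out[name] = np.nan
            continue
        o_hom = int(np.sum((gm.dosage[called, j] == 0) | (gm.dosage[called, j] == 2)))
        e = float(np.sum(e_hom[called]))
        denom = L - e
        out[name] = (o_hom - e) / denom if abs(denom) > 1e-12 else np.nan
    return pd.Series(out, name="F")
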