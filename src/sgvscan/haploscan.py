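"""EHH / iHH / iHS selective-sweep scan on phased haplotypes.

Extended haplotype homozygosity around a core SNP is computed separately
for the ancestral- and derived-allele carrier classes, integrated over
physical distance (trapezoid) until EHH decays below a cutoff, and the log
ratio ln(iHH_A / iHH_D) is standardized within derived-allele-frequency
bins.  Sign convention: positive scores mean unusually long haplotypes
around the *ancestral* allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .variants import GenotypeMatrix

EHH_CUTOFF = 0.05
MAX_GAP = 20_000
MAF_FLOOR = 0.05
DEFAULT_BINS = 50
DEFAULT_CRIT = 0.01


class UnphasedError(ValueError):
    """Raised when a phased-haplotype operation receives unphased input."""


@dataclass
class PhasedHaplotypes:
    """Binary haplotype x site matrix with positions and ancestral calls.

    ``haps`` is ``(n_haplotypes, n_sites)`` with alleles coded 0/1;
    ``ancestral`` gives the ancestral allele (0 or 1) per site, so the
    derived allele is ``1 - ancestral``.
    """

    haps: np.ndarray
    positions: np.ndarray
    ancestral: np.ndarray

    def __post_init__(self) -> None:
        if self.haps.ndim != 2 or self.haps.shape[1] != len(self.positions):
            raise ValueError("haps must be (n_haplotypes, n_sites)")
        if not np.all(np.diff(self.positions) >= 0):
            raise ValueError("positions must be sorted")

    @property
    def n_haplotypes(self) -> int:
        return self.haps.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haps.shape[1]

    @classmethod
    def from_genotype_matrix(
        cls, gm: GenotypeMatrix, species: str, contig: str,
        ancestral: np.ndarray | None = None,
    ) -> "PhasedHaplotypes":
        """Extract one species' haplotypes on one contig.

        Ancestral alleles default to REF (the simulator writes ancestral as
        REF); pass an explicit array to override.
        """
        if not gm.is_phased:
            raise UnphasedError(
                "iHS requires phased genotypes; phase the VCF first"
            )
        sites = np.flatnonzero(gm.contig == contig)
        cols = gm.haplotype_columns_for_species(species)
        haps = gm.haplotypes[np.ix_(sites, cols)].T.astype(np.int8)
        anc = (
            np.zeros(len(sites), dtype=np.int8)
            if ancestral is None
            else np.asarray(ancestral, dtype=np.int8)[sites]
        )
        return cls(haps=haps, positions=gm.pos[sites].astype(np.int64), ancestral=anc)


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------

def _homozygosity(groups: np.ndarray) -> float:
    """Sum_h C(n_h, 2) / C(n, 2) over distinct extended haplotypes."""
    n = len(groups)
    if n < 2:
        return 0.0
    _, counts = np.unique(groups, return_counts=True)
    num = float(np.sum(counts * (counts - 1)))
    return num / (n * (n - 1))


def _ehh_one_side(
    haps: np.ndarray,
    positions: np.ndarray,
    carrier_rows: np.ndarray,
    core_idx: int,
    direction: int,
    cutoff: float,
    max_gap: int,
) -> tuple[list[int], list[float], bool]:
    """Walk outward from the core.

    Returns ``(site indices, EHH values, censored)`` where ``censored``
    flags a walk stopped by the region boundary or a large gap while EHH
    was still above the cutoff (the integral is then incomplete).
    """
    idx = [core_idx]
    ehh = [1.0]
    n = len(carrier_rows)
    total_pairs = n * (n - 1)  # ordered-pair count, cancels in the ratio
    groups = [np.asarray(carrier_rows)]  # only groups of size >= 2 are kept
    ident = total_pairs
    j = core_idx
    prev_pos = positions[core_idx]
    n_sites = haps.shape[1]
    censored = True
    while True:
        j += direction
        if j < 0 or j >= n_sites:
            break
        if abs(int(positions[j]) - int(prev_pos)) > max_gap:
            break  # assembly-gap guard: truncate this side
        col = haps[:, j]
        new_groups = []
        for g in groups:
            a = col[g]
            ones = int(a.sum())
            if ones == 0 or ones == len(g):
                new_groups.append(g)  # column constant within group: no split
                continue
            zeros = len(g) - ones
            ident -= len(g) * (len(g) - 1) - ones * (ones - 1) - zeros * (zeros - 1)
            if ones >= 2:
                new_groups.append(g[a == 1])
            if zeros >= 2:
                new_groups.append(g[a == 0])
        groups = new_groups
        h = ident / total_pairs
        idx.append(j)
        ehh.append(h)
        prev_pos = positions[j]
        if h < cutoff:
            censored = False
            break
    return idx, ehh, censored


def _integrate(positions: np.ndarray, idx: list[int], ehh: list[float], cutoff: float) -> float:
    """Trapezoid integral of EHH over bp, clipped at the decay cutoff."""
    if len(idx) < 2:
        return 0.0
    x = positions[idx].astype(float)
    y = np.asarray(ehh, dtype=float)
    area = 0.0
    for k in range(len(x) - 1):
        y0, y1 = y[k], y[k + 1]
        dx = abs(x[k + 1] - x[k])
        if y1 >= cutoff:
            area += 0.5 * (y0 + y1) * dx
        else:
            # interpolate the crossing point, integrate only above the cutoff
            if y0 > cutoff:
                frac = (y0 - cutoff) / (y0 - y1)
                area += 0.5 * (y0 + cutoff) * dx * frac
            break
    return area


def compute_ehh_ihh(
    haps: PhasedHaplotypes,
    core_site: int,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP,
) -> tuple[pd.DataFrame, float, float, bool]:
    """EHH profile and integrated haplotype homozygosity at one core SNP.

    Returns ``(profile, iHH_A, iHH_D, censored)`` where the profile holds
    EHH per visited site for both allele classes; A carries the ancestral
    allele at the core, D the derived.  ``censored`` is True when any walk
    hit the region boundary (or a >``max_gap`` gap) before EHH decayed
    below the cutoff, leaving an incomplete integral.
    """
    anc_allele = int(haps.ancestral[core_site])
    carriers = {
        "A": np.flatnonzero(haps.haps[:, core_site] == anc_allele),
        "D": np.flatnonzero(haps.haps[:, core_site] == 1 - anc_allele),
    }
    for label, rows in carriers.items():
        if len(rows) < 2:
            raise ValueError(
                f"allele class {label} has {len(rows)} haplotypes at core "
                f"{core_site}; need >= 2"
            )
    records = []
    ihh = {}
    any_censored = False
    for label, rows in carriers.items():
        total = 0.0
        for direction in (-1, 1):
            idx, ehh, censored = _ehh_one_side(
                haps.haps, haps.positions, rows, core_site, direction, cutoff, max_gap
            )
            any_censored |= censored
            total += _integrate(haps.positions, idx, ehh, cutoff)
            for i, e in zip(idx, ehh):
                records.append(
                    {"allele": label, "direction": direction,
                     "pos": int(haps.positions[i]), "ehh": e}
                )
        ihh[label] = total
    profile = pd.DataFrame(records, columns=["allele", "direction", "pos", "ehh"])
    return profile, ihh["A"], ihh["D"], any_censored


def _ihh_at_core(
    haps: PhasedHaplotypes, core_site: int, cutoff: float, max_gap: int
) -> tuple[float, float, bool]:
    """(iHH_A, iHH_D, censored) without building the EHH profile table."""
    anc_allele = int(haps.ancestral[core_site])
    ihh = []
    any_censored = False
    for allele in (anc_allele, 1 - anc_allele):
        rows = np.flatnonzero(haps.haps[:, core_site] == allele)
        if len(rows) < 2:
            raise ValueError("allele class of size < 2")
        total = 0.0
        for direction in (-1, 1):
            idx, ehh, censored = _ehh_one_side(
                haps.haps, haps.positions, rows, core_site, direction, cutoff, max_gap
            )
            any_censored |= censored
            if any_censored:
                break
            total += _integrate(haps.positions, idx, ehh, cutoff)
        if any_censored:
            break
        ihh.append(total)
    if any_censored:
        return 0.0, 0.0, True
    return ihh[0], ihh[1], False


# ---------------------------------------------------------------------------
# iHS standardization and scanning
# ---------------------------------------------------------------------------

def ihs_scores(
    raw: pd.DataFrame,
    n_bins: int = DEFAULT_BINS,
    crit_percent: float = DEFAULT_CRIT,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Standardize raw iHS within derived-allele-frequency bins.

    ``raw`` needs columns ``daf`` and ``ihs_raw``.  Bins partition (0, 1)
    evenly; each score is centered and scaled by its bin's mean and
    (population) SD.  Bins with < 2 scores, or zero SD, give missing values.
    The extreme flag marks the top ``crit_percent`` of |standardized| scores
    two-sided (ties at the threshold included).

    ``reference`` optionally supplies the table from which bin means/SDs are
    estimated (e.g. a genome-wide background when ``raw`` covers a candidate
    region that would otherwise dominate its own frequency bins).
    """
    out = raw.copy()
    ref = raw if reference is None else reference
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    def bin_of(df):
        return np.clip(np.digitize(df["daf"], edges) - 1, 0, n_bins - 1)

    bin_idx = bin_of(out)
    ref_bins = bin_of(ref)
    ref_vals = ref["ihs_raw"].to_numpy()
    std = np.full(len(out), np.nan)
    for b in np.unique(bin_idx):
        rv = ref_vals[ref_bins == b]
        rv = rv[~np.isnan(rv)]
        if len(rv) < 2:
            continue
        mu, sd = rv.mean(), rv.std()  # ddof=0 by construction
        if sd == 0.0:
            warnings.warn(f"iHS bin {b}: all scores identical; standardized values missing",
                          stacklevel=2)
            continue
        rows = np.flatnonzero(bin_idx == b)
        vals = out["ihs_raw"].to_numpy()[rows]
        ok = ~np.isnan(vals)
        std[rows[ok]] = (vals[ok] - mu) / sd
    out["ihs_std"] = std
    out["extreme"] = flag_extremes(std, crit_percent)
    return out


def flag_extremes(std_scores: np.ndarray, crit_percent: float = DEFAULT_CRIT) -> np.ndarray:
    """Two-sided extreme flag: |score| in the top ``crit_percent`` mass.

    Threshold is the k-th largest |score| with ``k = ceil(crit * n_valid)``;
    all scores tied at the threshold are flagged.
    """
    a = np.abs(np.asarray(std_scores, dtype=float))
    valid = ~np.isnan(a)
    n = int(valid.sum())
    flags = np.zeros(len(a), dtype=bool)
    if n == 0:
        return flags
    k = max(1, int(np.ceil(crit_percent * n)))
    thr = np.sort(a[valid])[::-1][k - 1]
    flags[valid] = a[valid] >= thr
    return flags


def scan_species(
    haps: PhasedHaplotypes,
    contig: str = "",
    maf_floor: float = MAF_FLOOR,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP,
    n_bins: int = DEFAULT_BINS,
    crit_percent: float = DEFAULT_CRIT,
    standardize: bool = True,
) -> pd.DataFrame:
    """iHS table for one species on one contig.

    Cores with minor-allele frequency below ``maf_floor``, or with an allele
    class of size < 2, are skipped.  ``ihs_raw = ln(iHH_A / iHH_D)``.
    """
    n = haps.n_haplotypes
    rows = []
    for s in range(haps.n_sites):
        alt = int(haps.haps[:, s].sum())
        freq = alt / n
        maf = min(freq, 1 - freq)
        if maf < maf_floor or maf == 0.0:
            continue
        anc = int(haps.ancestral[s])
        daf = 1 - freq if anc == 1 else freq
        try:
            ihh_a, ihh_d, censored = _ihh_at_core(haps, s, cutoff, max_gap)
        except ValueError:
            continue
        if censored or ihh_a <= 0.0 or ihh_d <= 0.0:
            continue  # incomplete integral at a boundary/gap: core skipped
        rows.append(
            {
                "contig": contig,
                "pos": int(haps.positions[s]),
                "daf": daf,
                "ihh_a": ihh_a,
                "ihh_d": ihh_d,
                "ihs_raw": float(np.log(ihh_a / ihh_d)),
            }
        )
    tbl = pd.DataFrame(
        rows, columns=["contig", "pos", "daf", "ihh_a", "ihh_d", "ihs_raw"]
    )
    if standardize and len(tbl):
        tbl = ihs_scores(tbl, n_bins=n_bins, crit_percent=crit_percent)
    return tbl
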