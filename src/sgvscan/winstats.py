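"""Sliding-window differentiation statistics and PCA.

Windows default to 10 kb with a 2-kb step.  Per-window statistics:

* pi       -- within-species nucleotide diversity, sum of per-site
              ``2 c_ref c_alt / (m (m-1))`` divided by window length
* fst      -- Weir & Cockerham (1984) weighted estimator, the ratio of the
              summed among-population variance component ``a`` to the summed
              total ``a + b + c`` over the window's usable sites
* dxy      -- absolute divergence, sum of ``pA (1-pB) + pB (1-pA)`` divided
              by window length

pi and dxy divide by full window length: invariant sites contribute zero,
so a per-site statistic over a fixed window is obtained without an
accessibility mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import MISSING, GenotypeMatrix

DEFAULT_WINDOW = 10_000
DEFAULT_STEP = 2_000


@dataclass(frozen=True)
class Window:
    contig: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(
    contig_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[Window]:
    """Sliding windows covering each contig; the tail may be truncated.

    Starts run 0, step, 2*step, ... while < contig length, each window being
    ``[start, min(start + window, contig_length))``.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    out: list[Window] = []
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {contig!r} has non-positive length")
        start = 0
        while start < length:
            out.append(Window(contig, start, min(start + window, length)))
            start += step
    return out


# ---------------------------------------------------------------------------
# per-site building blocks (vectorized across sites)
# ---------------------------------------------------------------------------

def _species_counts(gm: GenotypeMatrix, species: str) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele count, called allele count) per site within a species."""
    return gm.allele_counts(gm.columns_for_species(species))


def site_pi(alt: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Per-site heterozygosity 2 c_ref c_alt / (m (m-1)); NaN when m < 2."""
    m = m.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = 2.0 * alt * (m - alt) / (m * (m - 1.0))
    return np.where(m >= 2, val, np.nan)


def site_dxy(pA: np.ndarray, pB: np.ndarray) -> np.ndarray:
    """Per-site absolute divergence pA(1-pB) + pB(1-pA)."""
    return pA * (1.0 - pB) + pB * (1.0 - pA)


def wc_components(
    nA: np.ndarray, pA: np.ndarray, hA: np.ndarray,
    nB: np.ndarray, pB: np.ndarray, hB: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) variance components a, b, c for two samples.

    Arguments are per-site sample sizes (individuals), alt-allele frequencies
    and heterozygote frequencies.  Sites where either sample has < 2
    individuals yield NaN components.
    """
    nA = nA.astype(float)
    nB = nB.astype(float)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (nA + nB) / r
        nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1.0)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    bad = (nA < 2) | (nB < 2)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def _wc_site_inputs(gm: GenotypeMatrix, species: str):
    cols = gm.columns_for_species(species)
    d = gm.dosage[:, cols]
    called = d != MISSING
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, d, 0).sum(axis=1)
    het = np.where(called, d == 1, False).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n, p, h


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------

def _window_index(gm: GenotypeMatrix, windows: Sequence[Window]) -> list[np.ndarray]:
    """Site indices per window (sites are 0-based positions)."""
    out = []
    by_contig: dict[str, np.ndarray] = {}
    for c in dict.fromkeys(gm.contig.tolist()):
        by_contig[c] = np.flatnonzero(gm.contig == c)
    for w in windows:
        idx = by_contig.get(w.contig)
        if idx is None:
            out.append(np.empty(0, dtype=np.int64))
            continue
        pos = gm.pos[idx]
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="left")
        out.append(idx[lo:hi])
    return out


def window_pi(gm: GenotypeMatrix, windows: Sequence[Window], species: str) -> np.ndarray:
    """Window nucleotide diversity per species (NaN for empty species data)."""
    alt, m = _species_counts(gm, species)
    sp = site_pi(alt, m)
    out = np.empty(len(windows))
    for k, idx in enumerate(_window_index(gm, windows)):
        vals = sp[idx]
        vals = vals[~np.isnan(vals)]
        out[k] = vals.sum() / windows[k].length
    return out


def window_dxy(
    gm: GenotypeMatrix, windows: Sequence[Window], speciesA: str, speciesB: str
) -> np.ndarray:
    altA, mA = _species_counts(gm, speciesA)
    altB, mB = _species_counts(gm, speciesB)
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = np.where(mA > 0, altA / np.maximum(mA, 1), np.nan)
        pB = np.where(mB > 0, altB / np.maximum(mB, 1), np.nan)
    sd = site_dxy(pA, pB)
    out = np.empty(len(windows))
    for k, idx in enumerate(_window_index(gm, windows)):
        vals = sd[idx]
        vals = vals[~np.isnan(vals)]
        out[k] = vals.sum() / windows[k].length
    return out


def window_weighted_fst(
    gm: GenotypeMatrix,
    windows: Sequence[Window],
    speciesA: str,
    speciesB: str,
    return_genomewide: bool = False,
):
    """Weir-Cockerham weighted F_ST per window (ratio of sums, not mean of
    ratios).  Windows with no usable site are NaN.  With
    ``return_genomewide`` also returns the all-sites ratio-of-sums value.
    """
    nA, pA, hA = _wc_site_inputs(gm, speciesA)
    nB, pB, hB = _wc_site_inputs(gm, speciesB)
    a, b, c = wc_components(nA, pA, hA, nB, pB, hB)
    tot = a + b + c
    usable = ~np.isnan(tot) & (tot != 0.0)

    out = np.empty(len(windows))
    for k, idx in enumerate(_window_index(gm, windows)):
        use = idx[usable[idx]]
        if use.size == 0:
            out[k] = np.nan
        else:
            out[k] = a[use].sum() / tot[use].sum()
    if return_genomewide:
        gw = a[usable].sum() / tot[usable].sum() if usable.any() else np.nan
        return out, float(gw)
    return out


def compute_window_stats(
    gm: GenotypeMatrix,
    contig_lengths: Mapping[str, int],
    species: Sequence[str],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_window_fraction: float = 0.5,
) -> pd.DataFrame:
    """WindowStatTable: pi per species, F_ST and d_XY per species pair.

    ``full`` marks windows with >= ``min_window_fraction`` of nominal length;
    quantile scans downstream should restrict to these.
    """
    windows = make_windows(contig_lengths, window, step)
    counts = [len(idx) for idx in _window_index(gm, windows)]
    tbl = pd.DataFrame(
        {
            "contig": [w.contig for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_variants": counts,
            "full": [w.length >= min_window_fraction * window for w in windows],
        }
    )
    for sp in species:
        tbl[f"pi_{sp}"] = window_pi(gm, windows, sp)
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            A, B = species[i], species[j]
            tbl[f"fst_{A}_{B}"] = window_weighted_fst(gm, windows, A, B)
            tbl[f"dxy_{A}_{B}"] = window_dxy(gm, windows, A, B)
    return tbl


def genomewide_weighted_fst(gm: GenotypeMatrix, speciesA: str, speciesB: str) -> float:
    """All-sites ratio-of-sums Weir-Cockerham F_ST."""
    nA, pA, hA = _wc_site_inputs(gm, speciesA)
    nB, pB, hB = _wc_site_inputs(gm, speciesB)
    a, b, c = wc_components(nA, pA, hA, nB, pB, hB)
    tot = a + b + c
    usable = ~np.isnan(tot) & (tot != 0.0)
    if not usable.any():
        return float("nan")
    return float(a[usable].sum() / tot[usable].sum())


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_genotypes(gm: GenotypeMatrix, n_components: int | None = None):
    """PCA of the dosage matrix, smartpca-style normalization.

    Columns (sites) are centered by ``2 p`` and scaled by
    ``sqrt(2 p (1-p))``; monomorphic sites are dropped.  Returns
    ``(coords, explained)`` where ``coords`` is a DataFrame of individual
    coordinates and ``explained`` the eigenvalue fractions.  Axes are
    deterministic up to sign.
    """
    if gm.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    d = gm.dosage.astype(float).T  # individuals x sites
    d[gm.dosage.T == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    d = d[:, poly]
    p = p[poly]
    n_ind = d.shape[0]
    if d.shape[1] == 0:
        coords = np.zeros((n_ind, n_ind - 1))
        eigvals = np.zeros(n_ind - 1)
    else:
        z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        z[np.isnan(z)] = 0.0
        cov = z @ z.T / z.shape[1]
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.clip(eigvals[order], 0.0, None)
        eigvecs = eigvecs[:, order]
        coords = eigvecs * np.sqrt(eigvals)
        coords = coords[:, : n_ind - 1]
        eigvals = eigvals[: n_ind - 1]
        # sign convention: largest-|loading| entry positive
        for k in range(coords.shape[1]):
            col = coords[:, k]
            if col[np.argmax(np.abs(col))] < 0:
                coords[:, k] = -col
    if n_components is not None:
        coords = coords[:, :n_components]
        eigvals = eigvals[:n_components]
    total = eigvals.sum()
    explained = eigvals / total if total > 0 else eigvals
    df = pd.DataFrame(
        coords,
        index=gm.samples,
        columns=[f"PC{k + 1}" for k in range(coords.shape[1])],
    )
    df.insert(0, "species", [gm.species_map[s] for s in gm.samples])
    return df, explained
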