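"""Classify divergent alleles as standing variation vs new mutation.

For each candidate gene a per-taxon alignment is built (consensus of major
alleles over the gene's interval), a neighbor-joining tree on Jukes-Cantor
distances is estimated with column-bootstrap supports, and the focal
radiation taxa are tested for monophyly.  Non-monophyly backed by bootstrap
support >= 60 is diagnosed as standing genetic variation (SGV), with an
origin-depth label from the deepest non-focal taxon nested inside the
radiation clade; supported monophyly is diagnosed as a new mutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .variants import MISSING, GenotypeMatrix

DEFAULT_SUPPORT = 60.0
DEFAULT_BOOT = 100

# species-tree depth order of the non-focal tiers: Tanganyika deepest, then
# the riverine tier, then Malawi
TIER_DEPTH = {"LT": 3, "HB": 2, "LM": 1}
DEPTH_LABEL = {3: "before_LT", 2: "before_HB", 1: "before_LM"}


class AlignmentError(ValueError):
    pass


@dataclass
class GeneAlignment:
    """Per-taxon sequences over a gene, stored as variant columns.

    ``matrix`` is taxa x variant-columns with alleles 0/1; ``n_invariant``
    counts the constant columns so Jukes-Cantor distances are computed per
    alignment site.  Columns with gaps or missing data have already been
    removed.
    """

    taxa: list[str]
    matrix: np.ndarray
    positions: np.ndarray
    n_invariant: int
    dropped_columns: int = 0

    @property
    def length(self) -> int:
        return self.matrix.shape[1] + self.n_invariant

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def p_distances(self) -> np.ndarray:
        n = self.n_taxa
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                diff = int(np.sum(self.matrix[i] != self.matrix[j]))
                D[i, j] = D[j, i] = diff / self.length
        return D

    def to_fasta(self, path: str | Path, alphabet: tuple[str, str] = ("A", "C")) -> None:
        lines = []
        for t, row in zip(self.taxa, self.matrix):
            seq = np.full(self.length, alphabet[0], dtype="<U1")
            seq[np.arange(row.size)[row == 1]] = alphabet[1]
            lines.append(f">{t}")
            lines.append("".join(seq))
        Path(path).write_text("\n".join(lines) + "\n")


def build_gene_alignment(
    gm: GenotypeMatrix,
    contig: str,
    start: int,
    end: int,
    taxa: Mapping[str, Sequence[str]] | None = None,
    per_haplotype: bool = False,
    min_taxa: int = 4,
) -> GeneAlignment:
    """Consensus alignment of the gene interval ``[start, end)``.

    ``taxa`` maps taxon name -> individual names; defaults to one taxon per
    species in the matrix's species map.  The consensus takes the major
    allele per site (ties -> reference).  Columns where any taxon has no
    called genotype are removed, mirroring a no-deletion site filter.  With
    ``per_haplotype`` each haplotype of each listed individual becomes its
    own taxon (suffix ``/0``, ``/1``).
    """
    if taxa is None:
        taxa = {}
        for sample, sp in gm.species_map.items():
            if sample in gm.samples:
                taxa.setdefault(sp, []).append(sample)
    sites = np.flatnonzero((gm.contig == contig) & (gm.pos >= start) & (gm.pos < end))
    col_index = {s: i for i, s in enumerate(gm.samples)}

    rows, names = [], []
    for taxon, members in taxa.items():
        cols = np.array([col_index[m] for m in members])
        if per_haplotype:
            if not gm.is_phased:
                raise AlignmentError("per-haplotype mode requires phased input")
            for m in members:
                j = col_index[m]
                for k in (0, 1):
                    h = gm.haplotypes[sites, 2 * j + k].astype(np.int16)
                    rows.append(np.where(h == MISSING, -1, h))
                    names.append(f"{m}/{k}")
        else:
            d = gm.dosage[np.ix_(sites, cols)]
            called = d != MISSING
            m_alleles = 2 * called.sum(axis=1)
            alt = np.where(called, d, 0).sum(axis=1)
            cons = np.where(2 * alt > m_alleles, 1, 0).astype(np.int16)
            cons[m_alleles == 0] = -1
            rows.append(cons)
            names.append(taxon)

    M = np.vstack(rows) if rows else np.empty((0, len(sites)), dtype=np.int16)
    ok_cols = ~(M < 0).any(axis=0)
    dropped = int(np.sum(~ok_cols))
    M = M[:, ok_cols]
    positions = gm.pos[sites][ok_cols]
    # columns constant across retained taxa carry no signal beyond length;
    # dropped (missing/deleted) columns shorten the alignment for all taxa
    variable = M.min(axis=0) != M.max(axis=0)
    n_invariant = (end - start) - dropped - int(variable.sum())
    aln = GeneAlignment(
        taxa=names,
        matrix=M[:, variable].astype(np.int8),
        positions=positions[variable],
        n_invariant=n_invariant,
        dropped_columns=dropped,
    )
    if aln.n_taxa < min_taxa:
        raise AlignmentError(
            f"{aln.n_taxa} taxa after filtering (< {min_taxa}); gene skipped"
        )
    return aln


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

def jukes_cantor(p: float) -> float:
    """JC69 distance; falls back to the raw p-distance when undefined."""
    if p >= 0.75:
        return p
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def nj_tree(D: np.ndarray, labels: Sequence[str]):
    """Neighbor joining; returns a nested-tuple unrooted tree.

    Leaves are ``(label,)``; internal nodes are tuples of child subtrees.
    The final node joins the last three (or two) clusters.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes: list = [(lab,) for lab in labels]
    D = D.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        new = (nodes[ai], nodes[aj])
        # distances from the new node to the rest
        d_new = 0.5 * (sub[i, :] + sub[j, :] - sub[i, j])
        nodes.append(new)
        k = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for idx, a in enumerate(active):
            D[k, a] = D[a, k] = d_new[idx]
        active = [a for a in active if a not in (ai, aj)] + [k]
    root = tuple(nodes[a] for a in active)
    return root


def _clades(tree, all_taxa: frozenset) -> set[frozenset]:
    """Leaf sets of every internal edge (excluding trivial splits)."""
    out: set[frozenset] = set()

    def leaves(node) -> frozenset:
        if len(node) == 1 and isinstance(node[0], str):
            return frozenset([node[0]])
        acc = frozenset()
        for child in node:
            sub = leaves(child)
            acc |= sub
            if 1 < len(sub) < len(all_taxa) - 1:
                out.add(sub)
        return acc

    leaves(tree)
    return out


def _bipartition_keys(tree, all_taxa: frozenset, ref: str) -> set[frozenset]:
    """Canonical bipartitions: the side not containing ``ref``."""
    keys = set()
    for clade in _clades(tree, all_taxa):
        keys.add(clade if ref not in clade else all_taxa - clade)
    return keys


@dataclass
class SupportedTree:
    tree: tuple
    taxa: frozenset
    outgroup: str
    supports: dict[frozenset, float]  # clade (side without outgroup) -> % support

    def clades(self) -> set[frozenset]:
        return _bipartition_keys(self.tree, self.taxa, self.outgroup)

    def support_of(self, clade: frozenset) -> float:
        return self.supports.get(clade, 0.0)

    def newick(self) -> str:
        def fmt(node, parent_taxa):
            if len(node) == 1 and isinstance(node[0], str):
                return node[0]
            sub = ",".join(fmt(c, parent_taxa) for c in node)
            leafset = _leafset(node)
            key = leafset if self.outgroup not in leafset else self.taxa - leafset
            sup = self.supports.get(key)
            label = f"{sup:.0f}" if sup is not None else ""
            return f"({sub}){label}"

        return fmt(self.tree, self.taxa) + ";"


def _leafset(node) -> frozenset:
    if len(node) == 1 and isinstance(node[0], str):
        return frozenset([node[0]])
    return frozenset().union(*(_leafset(c) for c in node))


def nj_tree_with_bootstrap(
    aln: GeneAlignment,
    outgroup: str,
    n_boot: int = DEFAULT_BOOT,
    seed: int | None = None,
) -> SupportedTree:
    """NJ tree on JC distances with column-resampled bootstrap supports.

    Bootstrap replicates resample alignment columns (including the invariant
    ones) with replacement; supports are the percentage of replicate trees
    containing each internal bipartition.
    """
    if outgroup not in aln.taxa:
        raise ValueError(f"outgroup {outgroup!r} not in alignment")
    if aln.n_taxa < 4:
        raise AlignmentError("need >= 4 taxa for a supported tree")
    rng = np.random.default_rng(seed)
    all_taxa = frozenset(aln.taxa)
    n = aln.n_taxa
    L = aln.length
    nvar = aln.matrix.shape[1]

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    diff = np.array(
        [(aln.matrix[i] != aln.matrix[j]) for i, j in pairs], dtype=np.float64
    )

    def tree_from_weights(w_var: np.ndarray, total: float):
        D = np.zeros((n, n))
        ham = diff @ w_var if nvar else np.zeros(len(pairs))
        for (i, j), hd in zip(pairs, ham):
            D[i, j] = D[j, i] = jukes_cantor(hd / total)
        return nj_tree(D, aln.taxa)

    main = tree_from_weights(np.ones(nvar), float(L))
    counts: dict[frozenset, int] = {}
    probs = np.full(nvar + 1, 1.0 / L)
    probs[-1] = aln.n_invariant / L
    for _ in range(n_boot):
        draw = rng.multinomial(L, probs)
        boot = tree_from_weights(draw[:nvar].astype(float), float(L))
        for key in _bipartition_keys(boot, all_taxa, outgroup):
            counts[key] = counts.get(key, 0) + 1
    supports = {k: 100.0 * v / n_boot for k, v in counts.items()}
    # keep every main-tree clade in the table, even at zero support
    for key in _bipartition_keys(main, all_taxa, outgroup):
        supports.setdefault(key, 0.0)
    return SupportedTree(main, all_taxa, outgroup, supports)


# ---------------------------------------------------------------------------
# origin classification
# ---------------------------------------------------------------------------

@dataclass
class OriginCall:
    gene: str
    newick: str
    monophyletic: bool
    support: float
    origin: str  # SGV | new_mutation | unresolved
    depth_label: str  # before_LT | before_HB | before_LM | n/a
    max_dxy: float = float("nan")


def classify_origin(
    tree: SupportedTree,
    lineage_map: Mapping[str, str],
    support_min: float = DEFAULT_SUPPORT,
    gene: str = "",
    max_dxy: float = float("nan"),
) -> OriginCall:
    """Monophyly-based SGV vs new-mutation call for one gene tree.

    ``lineage_map`` assigns each taxon a tier: ``focal`` for the radiation
    species, ``LT`` / ``HB`` / ``LM`` for the outgroup tiers, ``outgroup``
    for the rooting taxon.  Supported monophyly of the focal set means a
    new mutation; a supported intrusion of a non-focal taxon into the
    smallest clade containing the focal taxa means SGV, with depth set by
    the deepest intruding tier.
    """
    focal = frozenset(t for t, tier in lineage_map.items() if tier == "focal")
    focal &= tree.taxa
    if tree.outgroup not in tree.taxa:
        raise ValueError("outgroup absent from tree")
    if not focal:
        raise ValueError("no focal taxa present")
    nonroot = tree.taxa - {tree.outgroup}
    clades = tree.clades() | {nonroot}
    # root split (everything but the outgroup) is certain by construction
    supports = dict(tree.supports)
    supports.setdefault(nonroot, 100.0)

    mono = focal in clades or focal == nonroot
    if mono:
        sup = supports.get(focal, 100.0 if focal == nonroot else 0.0)
        if sup >= support_min:
            return OriginCall(gene, tree.newick(), True, sup, "new_mutation", "n/a", max_dxy)
        return OriginCall(gene, tree.newick(), True, sup, "unresolved", "n/a", max_dxy)

    containing = [c for c in clades if focal <= c]
    smallest = min(containing, key=len) if containing else nonroot
    intruders = smallest - focal
    depth_rank = max(
        (TIER_DEPTH.get(lineage_map.get(t, ""), 0) for t in intruders), default=0
    )
    depth = DEPTH_LABEL.get(depth_rank, "n/a")

    # support consulted: smallest clade joining >=1 intruder with part (not
    # all) of the focal taxa
    mixing = [
        c for c in clades
        if (c & intruders) and (c & focal) and not focal <= c
    ]
    if mixing:
        key = min(mixing, key=len)
        sup = supports.get(key, 0.0)
    else:
        sup = supports.get(smallest, 0.0)
    if sup >= support_min:
        return OriginCall(gene, tree.newick(), False, sup, "SGV", depth, max_dxy)
    return OriginCall(gene, tree.newick(), False, sup, "unresolved", "n/a", max_dxy)


def origin_calls_to_frame(calls: Iterable[OriginCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "origin": c.origin,
                "depth": c.depth_label,
                "monophyletic": c.monophyletic,
                "support": c.support,
                "max_dxy": c.max_dxy,
                "tree": c.newick,
            }
            for c in calls
        ],
        columns=["gene", "origin", "depth", "monophyletic", "support", "max_dxy", "tree"],
    )


# ---------------------------------------------------------------------------
# max-dxy comparison between origin classes
# ---------------------------------------------------------------------------

def compare_dxy_by_origin(calls: Sequence[OriginCall]) -> dict:
    """Two-tailed Mann-Whitney on max d_XY: SGV vs new-mutation genes.

    Exact enumeration when both groups have n <= 8 and no ties; otherwise
    the tie-corrected normal approximation.  Returns medians per class and
    the p-value (None when a class is empty).
    """
    sgv = [c.max_dxy for c in calls if c.origin == "SGV" and not math.isnan(c.max_dxy)]
    new = [c.max_dxy for c in calls if c.origin == "new_mutation" and not math.isnan(c.max_dxy)]
    out = {
        "n_sgv": len(sgv),
        "n_new_mutation": len(new),
        "median_sgv": float(np.median(sgv)) if sgv else None,
        "median_new_mutation": float(np.median(new)) if new else None,
        "p_value": None,
        "U": None,
    }
    if not sgv or not new:
        return out
    pooled = sgv + new
    if len(set(pooled)) == 1:
        out["p_value"] = 1.0
        out["U"] = len(sgv) * len(new) / 2.0
        return out
    has_ties = len(set(pooled)) < len(pooled)
    method = "exact" if (len(sgv) <= 8 and len(new) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(sgv, new, alternative="two-sided", method=method)
    out["p_value"] = float(res.pvalue)
    out["U"] = float(res.statistic)
    return out
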