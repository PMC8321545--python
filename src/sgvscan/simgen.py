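"""Forward-time Wright-Fisher simulator of a radiating species complex.

Each region is simulated independently: founder haplotypes are drawn from a
coalescent (msprime) at neutral equilibrium, then a diploid Wright-Fisher
process with Poisson crossovers and infinite-sites mutations on continuous
coordinates runs forward through an ordered schedule of lineage splits.
Selection acts on a single tracked site per region:

* ``neutral``        -- no selection.
* ``de_novo_sweep``  -- a new beneficial mutation is injected into one
  target lineage after the final split and driven by genic selection;
  losses trigger bounded internal retries from the onset snapshot.
* ``sgv_sweep``      -- an ancient balanced polymorphism: the two
  selected-site haplotype classes are founded from coalescent populations
  that diverged ``class_divergence`` generations before the simulation
  start (long before any split), maintained by overdominance in every
  lineage until that lineage stops splitting, then driven to alternative
  fixation (derived allele in the target lineages, ancestral elsewhere).

Coordinates are continuous during simulation and discretized to integer bp
on output, resolving collisions by +1 shifts.  True gamete phase is kept.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import GenotypeMatrix


class ConfigError(ValueError):
    pass


class SimulationError(RuntimeError):
    """A conditioned scenario failed within the retry budget."""


@dataclass
class DemographyConfig:
    """Lineage sizes and the ordered split schedule.

    ``split_events`` is a list of ``(generation, parent, child)`` with
    strictly increasing generations; the parent persists, the child is
    founded from the parent's gamete pool at that generation.
    ``deep_outgroups`` maps lineage names present from generation 0 to
    their coalescent divergence time (generations before start) from the
    root lineage's ancestor.
    """

    ancestral_size: int
    lineage_sizes: dict[str, int]
    samples_per_lineage: dict[str, int]
    split_events: list[tuple[int, str, str]] = field(default_factory=list)
    deep_outgroups: dict[str, int] = field(default_factory=dict)
    root_lineage: str = "anc"
    end_generation: int = 0
    burn_in: int = 0
    generation_time_years: float = 2.0

    def __post_init__(self) -> None:
        gens = [g for g, _, _ in self.split_events]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ConfigError("split generations must be strictly increasing")
        alive = {self.root_lineage, *self.deep_outgroups}
        for g, parent, child in self.split_events:
            if parent not in alive:
                raise ConfigError(f"split at generation {g}: unknown parent {parent!r}")
            if child in alive:
                raise ConfigError(f"split at generation {g}: lineage {child!r} already exists")
            if g > self.end_generation:
                raise ConfigError("split after end_generation")
            alive.add(child)
        for lin, n in self.samples_per_lineage.items():
            if lin not in alive:
                raise ConfigError(f"sampled lineage {lin!r} never exists")
            if lin not in self.lineage_sizes:
                raise ConfigError(f"no size for lineage {lin!r}")
            if n > self.lineage_sizes[lin]:
                raise ConfigError(f"samples exceed size for lineage {lin!r}")
        for lin in alive:
            if lin not in self.lineage_sizes:
                raise ConfigError(f"no size for lineage {lin!r}")

    def founding_generation(self, lineage: str) -> int:
        for g, _, child in self.split_events:
            if child == lineage:
                return g
        return 0

    def resolution_generation(self, lineage: str) -> int:
        """Generation after which a lineage has no further child splits."""
        last = self.founding_generation(lineage)
        for g, parent, _ in self.split_events:
            if parent == lineage:
                last = max(last, g)
        return last

    def lineages(self) -> list[str]:
        out = [self.root_lineage, *self.deep_outgroups]
        out += [child for _, _, child in self.split_events]
        return out


@dataclass
class MutationConfig:
    mu: float  # mutations / bp / generation
    recomb_rate: float  # crossovers / bp / generation
    region_length: int

    def __post_init__(self) -> None:
        if self.mu < 0 or self.recomb_rate < 0:
            raise ConfigError("rates must be >= 0")
        if self.region_length <= 0:
            raise ConfigError("region_length must be > 0")


@dataclass
class SelectionScenario:
    mode: str  # neutral | de_novo_sweep | sgv_sweep
    selected_position: float = 0.0
    s: float = 0.5
    h: float = 0.5
    balancing_h: float = 0.15  # heterozygote advantage during the balanced phase
    target_lineages: tuple[str, ...] = ()
    allele1_lineages: tuple[str, ...] = ()  # extra lineages driven to the derived class
    onset_generation: int | None = None  # de novo injection; default: after final split
    class_divergence: int = 3000  # generations, sgv class coalescence before start
    min_final_freq: float = 0.0  # de novo conditioning: retry below this target freq
    max_final_freq: float = 1.0  # de novo conditioning: retry above (partial sweeps)
    force_forward: bool = False  # neutral regions default to the coalescent shortcut
    region_length: int | None = None  # per-region override of MutationConfig
    recomb_rate: float | None = None  # per-region override of MutationConfig
    sample_lineages: tuple[str, ...] | None = None  # emit only these lineages
    max_retries: int = 30

    def __post_init__(self) -> None:
        if self.mode not in {"neutral", "de_novo_sweep", "sgv_sweep"}:
            raise ConfigError(f"unknown scenario mode {self.mode!r}")


@dataclass
class RegionResult:
    name: str
    gm: GenotypeMatrix
    scenario: SelectionScenario
    selected_position: int | None  # discretized bp, None for neutral
    origin_depth: str  # pre_radiation | post_split | none
    lineage_freqs: dict[str, float]  # derived-allele frequency at sampling
    region_length: int = 0
    retries: int = 0


# ---------------------------------------------------------------------------
# core engine: haplotype = (sorted float position array, selected-site allele)
# ---------------------------------------------------------------------------

_EMPTY = np.empty(0, dtype=np.float64)


def _gamete(rng, ind, which, n_cross, n_mut, L, sel_pos):
    h0 = ind[which]
    h1 = ind[1 - which]
    if n_cross == 0:
        arr, sel = h0
    else:
        bp = np.sort(rng.uniform(0.0, L, n_cross))
        arr0, sel0 = h0
        arr1, sel1 = h1
        par0 = np.searchsorted(bp, arr0) % 2
        par1 = np.searchsorted(bp, arr1) % 2
        arr = np.sort(np.concatenate([arr0[par0 == 0], arr1[par1 == 1]]))
        sel = sel0 if np.searchsorted(bp, sel_pos) % 2 == 0 else sel1
    if n_mut:
        arr = np.sort(np.concatenate([arr, rng.uniform(0.0, L, n_mut)]))
    return (arr, sel)


def _next_generation(rng, pop, size, wvec, mut: MutationConfig, sel_pos):
    """One Wright-Fisher generation: selection, mating, recombination, mutation."""
    n = len(pop)
    if wvec is None:
        probs = None
    else:
        w = np.array([wvec[a[1] + b[1]] for a, b in pop])
        probs = w / w.sum()
    pidx = rng.choice(n, size=2 * size, p=probs)
    L = float(mut.region_length)
    rl = mut.recomb_rate * L
    ml = mut.mu * L
    n_cross = rng.poisson(rl, 2 * size) if rl > 0 else np.zeros(2 * size, dtype=np.int64)
    n_mut = rng.poisson(ml, 2 * size) if ml > 0 else np.zeros(2 * size, dtype=np.int64)
    which = rng.integers(0, 2, 2 * size)
    out = []
    for i in range(size):
        a, b = 2 * i, 2 * i + 1
        g1 = _gamete(rng, pop[pidx[a]], which[a], n_cross[a], n_mut[a], L, sel_pos)
        g2 = _gamete(rng, pop[pidx[b]], which[b], n_cross[b], n_mut[b], L, sel_pos)
        out.append((g1, g2))
    return out


def derived_freq(pop) -> float:
    n = 2 * len(pop)
    return sum(a[1] + b[1] for a, b in pop) / n if n else 0.0


def _fitness_vector(regime: str, scn: SelectionScenario):
    """3-vector of fitnesses indexed by derived-allele dosage, or None."""
    if regime == "neutral":
        return None
    if regime == "balanced":
        return np.array([1.0, 1.0 + scn.balancing_h, 1.0])
    if regime == "favor1":
        return np.array([1.0, 1.0 + scn.h * scn.s, 1.0 + scn.s])
    if regime == "favor0":
        return np.array([1.0 + scn.s, 1.0 + scn.h * scn.s, 1.0])
    raise AssertionError(regime)


# ---------------------------------------------------------------------------
# coalescent-equilibrium founders
# ---------------------------------------------------------------------------

def _coalescent_founders(
    demography: DemographyConfig,
    mut: MutationConfig,
    rng: np.random.Generator,
    sgv: SelectionScenario | None,
):
    """Found every generation-0 lineage from an msprime equilibrium sample.

    Returns ``{lineage: [(hap, hap), ...]}``; for an sgv scenario the root
    lineage is a 50/50 mix of two classes whose coalescence predates the
    simulation by ``class_divergence`` generations, and class-1 haplotypes
    carry the derived allele at the selected site.
    """
    import msprime

    N = demography.ancestral_size
    dem = msprime.Demography()
    dem.add_population(name="ANC", initial_size=N)
    root_pops: list[str]
    if sgv is not None:
        dem.add_population(name="CLA", initial_size=N)
        dem.add_population(name="CLB", initial_size=N)
        # mass migrations rather than population splits: the shared ancestor
        # stays active, so lineages coalesce in it at the intended rate
        dem.add_mass_migration(time=sgv.class_divergence, source="CLA",
                               dest="ANC", proportion=1)
        dem.add_mass_migration(time=sgv.class_divergence, source="CLB",
                               dest="ANC", proportion=1)
        root_pops = ["CLA", "CLB"]
    else:
        root_pops = ["ANC"]
    for lin, t in demography.deep_outgroups.items():
        if sgv is not None and t <= sgv.class_divergence:
            raise ConfigError(
                "deep outgroup isolation must predate the sgv class divergence"
            )
        dem.add_population(name=f"OUT_{lin}", initial_size=demography.lineage_sizes[lin])
        dem.add_mass_migration(time=t, source=f"OUT_{lin}", dest="ANC", proportion=1)
    dem.sort_events()

    root_size = demography.lineage_sizes[demography.root_lineage]
    samples = []
    if sgv is not None:
        half = root_size // 2
        samples.append(msprime.SampleSet(half, population="CLA", ploidy=2))
        samples.append(msprime.SampleSet(root_size - half, population="CLB", ploidy=2))
    else:
        samples.append(msprime.SampleSet(root_size, population="ANC", ploidy=2))
    for lin in demography.deep_outgroups:
        samples.append(
            msprime.SampleSet(
                demography.lineage_sizes[lin], population=f"OUT_{lin}", ploidy=2
            )
        )

    seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=mut.region_length,
        recombination_rate=mut.recomb_rate,
        discrete_genome=False,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=mut.mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=seed + 1,
    )
    positions = ts.tables.sites.position
    G = ts.genotype_matrix()  # sites x haplotypes
    hap_positions = [positions[G[:, h] > 0] for h in range(G.shape[1])]

    pops: dict[str, list] = {}
    cursor = 0

    def take(n_dip: int, sel_alleles: Sequence[int]):
        nonlocal cursor
        inds = []
        for k in range(n_dip):
            a = (np.ascontiguousarray(hap_positions[cursor]), sel_alleles[k])
            b = (np.ascontiguousarray(hap_positions[cursor + 1]), sel_alleles[k])
            inds.append((a, b))
            cursor += 2
        return inds

    if sgv is not None:
        half = root_size // 2
        root = take(half, [0] * half) + take(root_size - half, [1] * (root_size - half))
    else:
        root = take(root_size, [0] * root_size)
    pops[demography.root_lineage] = root
    for lin in demography.deep_outgroups:
        n = demography.lineage_sizes[lin]
        pops[lin] = take(n, [0] * n)
    return pops


def _coalescent_sample(
    demography: DemographyConfig,
    mut: MutationConfig,
    rng: np.random.Generator,
    lineages: Sequence[str] | None = None,
):
    """Neutral shortcut: sample the demography's coalescent directly.

    Equivalent in distribution to the forward engine for neutral regions
    (both are Wright-Fisher), but orders of magnitude cheaper; the forward
    path remains available via ``SelectionScenario(force_forward=True)``.
    """
    import msprime

    end = demography.end_generation
    dem = msprime.Demography()
    for lin in demography.lineages():
        dem.add_population(name=lin, initial_size=demography.lineage_sizes[lin])
    # mass migrations keep the (sampled) parent populations active throughout
    for g, parent, child in demography.split_events:
        dem.add_mass_migration(time=end - g, source=child, dest=parent, proportion=1)
    for lin, t in demography.deep_outgroups.items():
        dem.add_mass_migration(
            time=end + t, source=lin, dest=demography.root_lineage, proportion=1
        )
    # before generation 0 the root lineage has the ancestral size
    dem.add_population_parameters_change(
        time=end, population=demography.root_lineage,
        initial_size=demography.ancestral_size,
    )
    dem.sort_events()

    order = [
        lin for lin in demography.lineages()
        if demography.samples_per_lineage.get(lin, 0) > 0
        and (lineages is None or lin in lineages)
    ]
    samples = [
        msprime.SampleSet(demography.samples_per_lineage[lin], population=lin, ploidy=2)
        for lin in order
    ]
    seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=mut.region_length,
        recombination_rate=mut.recomb_rate,
        discrete_genome=False,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=mut.mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=seed + 1,
    )
    positions = ts.tables.sites.position
    G = ts.genotype_matrix()
    sampled: dict[str, list] = {}
    cursor = 0
    for lin in order:
        inds = []
        for _ in range(demography.samples_per_lineage[lin]):
            a = (positions[G[:, cursor] > 0], 0)
            b = (positions[G[:, cursor + 1] > 0], 0)
            inds.append((a, b))
            cursor += 2
        sampled[lin] = inds
    return sampled


# ---------------------------------------------------------------------------
# scenario orchestration
# ---------------------------------------------------------------------------

def _regime(lineage: str, gen: int, demography: DemographyConfig, scn: SelectionScenario,
            injected: bool) -> str:
    if scn.mode == "neutral":
        return "neutral"
    if scn.mode == "de_novo_sweep":
        if not injected:
            return "neutral"
        return "favor1" if lineage in scn.target_lineages else "neutral"
    # sgv_sweep
    if lineage in demography.deep_outgroups:
        return "neutral"
    if gen <= demography.resolution_generation(lineage):
        return "balanced"
    favored = set(scn.target_lineages) | set(scn.allele1_lineages)
    return "favor1" if lineage in favored else "favor0"


def _run_phase(pops, start_gen, end_gen, demography, mut, scn, rng, injected):
    """Advance every lineage from after ``start_gen`` through ``end_gen``.

    Returns ``(pops, ok)``; ``ok`` goes False as soon as a conditioned
    scenario's allele is lost (de novo) or the balanced polymorphism fixes
    or is lost before resolution (sgv).
    """
    splits = {g: (parent, child) for g, parent, child in demography.split_events}
    onset = scn.onset_generation
    if scn.mode == "de_novo_sweep" and onset is None:
        onset = (demography.split_events[-1][0] + 1) if demography.split_events else 1
    for gen in range(start_gen + 1, end_gen + 1):
        new_pops = {}
        for lin, pop in pops.items():
            regime = "neutral" if gen <= 0 else _regime(lin, gen, demography, scn, injected)
            wvec = _fitness_vector(regime, scn)
            new_pops[lin] = _next_generation(
                rng, pop, demography.lineage_sizes[lin], wvec, mut, sel_pos=float(scn.selected_position)
            )
        if gen in splits:
            parent, child = splits[gen]
            wvec = _fitness_vector(_regime(parent, gen, demography, scn, injected), scn)
            new_pops[child] = _next_generation(
                rng, pops[parent], demography.lineage_sizes[child], wvec, mut,
                sel_pos=float(scn.selected_position),
            )
        pops = new_pops
        if scn.mode == "de_novo_sweep" and gen == onset:
            for t in scn.target_lineages:
                if t not in pops:
                    raise ConfigError(
                        f"target lineage {t!r} does not exist at onset generation {onset}"
                    )
            lin = scn.target_lineages[0]
            pop = pops[lin]
            i = int(rng.integers(len(pop)))
            a, b = pop[i]
            pop[i] = ((a[0], 1), b)
            injected = True
        if scn.mode == "de_novo_sweep" and injected and gen > onset:
            if all(derived_freq(pops[t]) == 0.0 for t in scn.target_lineages):
                return pops, False  # lost; retry
        if scn.mode == "sgv_sweep":
            alive_focal = [
                l for l in pops
                if l not in demography.deep_outgroups
                and gen <= demography.resolution_generation(l)
            ]
            if alive_focal:
                f = np.mean([derived_freq(pops[l]) for l in alive_focal])
                if f == 0.0 or f == 1.0:
                    return pops, False  # balanced polymorphism lost; retry
    return pops, True


def _run_region(
    demography: DemographyConfig,
    mut: MutationConfig,
    scn: SelectionScenario,
    rng: np.random.Generator,
):
    """One attempt at a region; returns (pops, ok) where ok reports the
    scenario's conditioning (sweep established / classes resolved)."""
    pops = _coalescent_founders(
        demography, mut, rng, scn if scn.mode == "sgv_sweep" else None
    )
    injected = scn.mode != "de_novo_sweep"
    start = -demography.burn_in
    pops, alive = _run_phase(
        pops, start, demography.end_generation, demography, mut, scn, rng, injected
    )
    if not alive:
        return pops, False
    return pops, _final_conditioning_ok(demography, scn, pops)


def _final_conditioning_ok(demography, scn, pops) -> bool:
    if scn.mode == "de_novo_sweep":
        floor = max(scn.min_final_freq, np.nextafter(0.0, 1.0))
        return all(
            floor <= derived_freq(pops[t]) <= scn.max_final_freq
            for t in scn.target_lineages
        )
    if scn.mode == "sgv_sweep":
        favored = set(scn.target_lineages) | set(scn.allele1_lineages)
        ok = True
        for lin in pops:
            if lin in demography.deep_outgroups:
                continue
            f = derived_freq(pops[lin])
            ok &= f >= 0.5 if lin in favored else f <= 0.5
        return ok
    return True


def _run_de_novo_with_snapshot(
    demography: DemographyConfig,
    mut: MutationConfig,
    scn: SelectionScenario,
    rng: np.random.Generator,
):
    """De novo sweeps retry from a pre-onset snapshot instead of replaying
    the (expensive) neutral history; returns (pops, retries)."""
    onset = scn.onset_generation
    if onset is None:
        onset = (demography.split_events[-1][0] + 1) if demography.split_events else 1
    pops = _coalescent_founders(demography, mut, rng, None)
    pops, _ = _run_phase(
        pops, -demography.burn_in, onset - 1, demography, mut, scn, rng, injected=False
    )
    snapshot = {lin: list(pop) for lin, pop in pops.items()}
    retries = 0
    while True:
        attempt = {lin: list(pop) for lin, pop in snapshot.items()}
        attempt, alive = _run_phase(
            attempt, onset - 1, demography.end_generation, demography, mut, scn,
            rng, injected=False,
        )
        if alive and _final_conditioning_ok(demography, scn, attempt):
            return attempt, retries
        retries += 1
        if retries > scn.max_retries:
            raise SimulationError(
                f"de_novo_sweep failed conditioning after {scn.max_retries} retries"
            )


def _sample_population(demography: DemographyConfig, pops, rng,
                       lineages: Sequence[str] | None = None):
    """Draw the per-lineage diploid samples (without replacement)."""
    sampled = {}
    for lin in demography.lineages():
        k = demography.samples_per_lineage.get(lin, 0)
        if k == 0 or lin not in pops:
            continue
        if lineages is not None and lin not in lineages:
            continue
        idx = rng.choice(len(pops[lin]), size=k, replace=False)
        sampled[lin] = [pops[lin][i] for i in idx]
    return sampled


def _discretize(positions: np.ndarray, L: int) -> np.ndarray:
    """Continuous -> strictly increasing integer bp (collisions shift +1)."""
    out = np.empty(len(positions), dtype=np.int64)
    prev = -1
    for i, x in enumerate(positions):
        v = max(int(np.floor(x)), prev + 1)
        out[i] = v
        prev = v
    return out


def _build_matrix(
    sampled: Mapping[str, list],
    mut: MutationConfig,
    scn: SelectionScenario,
    region: str,
) -> tuple[GenotypeMatrix, int | None]:
    """Assemble the phased GenotypeMatrix for one region's samples."""
    hap_arrays = []
    sel_alleles = []
    names = []
    species_map = {}
    for lin, inds in sampled.items():
        for i, (a, b) in enumerate(inds):
            name = f"{lin}_{i}"
            names.append(name)
            species_map[name] = lin
            hap_arrays.extend([a[0], b[0]])
            sel_alleles.extend([a[1], b[1]])
    n_hap = len(hap_arrays)
    union = np.unique(np.concatenate(hap_arrays)) if hap_arrays else _EMPTY

    sel_continuous = float(scn.selected_position)
    include_sel = scn.mode != "neutral" and 0 < sum(sel_alleles) < n_hap
    all_pos = np.append(union, sel_continuous) if include_sel else union
    order = np.argsort(all_pos, kind="stable")
    all_pos = all_pos[order]

    H = np.zeros((len(all_pos), n_hap), dtype=np.int8)
    col_of = {x: i for i, x in enumerate(all_pos)}
    for h, arr in enumerate(hap_arrays):
        idx = np.searchsorted(all_pos, arr)
        # positions may repeat in all_pos if the selected site collides; match exact
        H[idx, h] = 1
    if include_sel:
        sel_row = int(np.searchsorted(all_pos, sel_continuous))
        while all_pos[sel_row] != sel_continuous:
            sel_row += 1
        H[sel_row, :] = 0
        H[sel_row, :] = np.array(sel_alleles, dtype=np.int8)

    # drop monomorphic columns (fixed derived across all samples, or lost)
    counts = H.sum(axis=1)
    poly = (counts > 0) & (counts < n_hap)
    if include_sel:
        poly[sel_row] = True
    H = H[poly]
    all_pos = all_pos[poly]
    int_pos = _discretize(all_pos, mut.region_length)
    sel_bp = None
    if include_sel:
        sel_bp = int(int_pos[int(np.flatnonzero(all_pos == sel_continuous)[0])])
    elif scn.mode != "neutral":
        sel_bp = int(np.floor(sel_continuous))

    n_ind = n_hap // 2
    dosage = H[:, 0::2] + H[:, 1::2]
    gm = GenotypeMatrix(
        contig=np.array([region] * len(int_pos)),
        pos=int_pos,
        ref=np.array(["A"] * len(int_pos)),
        alt=np.array(["C"] * len(int_pos)),
        dosage=dosage.astype(np.int8),
        samples=names,
        species_map=species_map,
        haplotypes=H,
    )
    return gm, sel_bp


def simulate_radiation(
    demography: DemographyConfig,
    mutation: MutationConfig,
    scenarios: Sequence[SelectionScenario],
    seed: int,
) -> tuple[list[RegionResult], pd.DataFrame]:
    """Simulate one region per scenario; returns (regions, truth table).

    Deterministic for a fixed seed.  Conditioned scenarios retry internally
    from scratch up to ``scenario.max_retries`` times and raise
    :class:`SimulationError` on exhaustion.
    """
    root = np.random.default_rng(seed)
    regions: list[RegionResult] = []
    truth_rows = []
    for r, scn in enumerate(scenarios):
        name = f"region_{r:03d}"
        overrides = {}
        if scn.region_length is not None:
            overrides["region_length"] = scn.region_length
        if scn.recomb_rate is not None:
            overrides["recomb_rate"] = scn.recomb_rate
        mut = dataclasses.replace(mutation, **overrides) if overrides else mutation
        region_rng = np.random.default_rng(root.integers(2**63 - 1))
        retries = 0
        if scn.mode == "neutral" and not scn.force_forward:
            attempt_rng = np.random.default_rng(region_rng.integers(2**63 - 1))
            sampled = _coalescent_sample(
                demography, mut, attempt_rng, scn.sample_lineages
            )
        elif scn.mode == "de_novo_sweep":
            attempt_rng = np.random.default_rng(region_rng.integers(2**63 - 1))
            try:
                pops, retries = _run_de_novo_with_snapshot(
                    demography, mut, scn, attempt_rng
                )
            except SimulationError as e:
                raise SimulationError(f"{name}: {e}") from e
            sampled = _sample_population(
                demography, pops, attempt_rng, scn.sample_lineages
            )
        else:
            while True:
                attempt_rng = np.random.default_rng(region_rng.integers(2**63 - 1))
                pops, ok = _run_region(demography, mut, scn, attempt_rng)
                if ok or scn.mode == "neutral":
                    break
                retries += 1
                if retries > scn.max_retries:
                    raise SimulationError(
                        f"{name}: scenario {scn.mode} failed conditioning after "
                        f"{scn.max_retries} retries"
                    )
            sampled = _sample_population(
                demography, pops, attempt_rng, scn.sample_lineages
            )
        gm, sel_bp = _build_matrix(sampled, mut, scn, name)
        depth = {
            "neutral": "none",
            "de_novo_sweep": "post_split",
            "sgv_sweep": "pre_radiation",
        }[scn.mode]
        freqs = {lin: derived_freq(inds) for lin, inds in sampled.items()}
        regions.append(
            RegionResult(name, gm, scn, sel_bp, depth, freqs,
                         mut.region_length, retries)
        )
        row = {
            "region": name,
            "mode": scn.mode,
            "selected_position": -1 if sel_bp is None else sel_bp,
            "origin_depth": depth,
            "class_divergence": scn.class_divergence if scn.mode == "sgv_sweep" else 0,
        }
        for lin in demography.lineages():
            if lin in freqs:
                row[f"freq_{lin}"] = round(freqs[lin], 6)
        truth_rows.append(row)
    return regions, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------

def species_tree_newick(demography: DemographyConfig) -> str:
    """Newick topology implied by the split schedule and deep outgroups."""
    label = {lin: lin for lin in demography.lineages()}
    for g, parent, child in reversed(demography.split_events):
        label[parent] = f"({label[parent]},{label[child]})"
    tree = label[demography.root_lineage]
    for lin, _t in sorted(
        demography.deep_outgroups.items(), key=lambda kv: kv[1]
    ):
        tree = f"({tree},{label[lin]})"
    return tree + ";"


def write_outputs(
    regions: Sequence[RegionResult],
    truth: pd.DataFrame,
    demography: DemographyConfig,
    mutation: MutationConfig,
    out_dir: str | Path,
    gene_halfwidth: int = 1_250,
) -> dict[str, Path]:
    """Write VCF + BED gene models + species map + newick tree + truth TSV.

    One VCF holds all regions (one contig each).  Every region gets one gene
    model centred on the selected site (or the region midpoint for neutral
    regions), clipped to the region.  Regions simulated for a lineage subset
    are written with reference genotypes for the absent individuals.
    """
    from .variants import write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    merged = _concat_regions(regions)
    contig_lengths = {r.name: r.region_length for r in regions}
    paths = {
        "vcf": out / "simulated.vcf",
        "genes": out / "genes.bed",
        "species_map": out / "species_map.tsv",
        "tree": out / "species_tree.nwk",
        "truth": out / "truth.tsv",
    }
    write_vcf(merged, paths["vcf"], contig_lengths, ancestral_is_ref=True)

    bed_lines = []
    for r in regions:
        L = r.region_length
        center = r.selected_position if r.selected_position is not None else L // 2
        start = max(0, center - gene_halfwidth)
        end = min(L, center + gene_halfwidth)
        bed_lines.append(f"{r.name}\t{start}\t{end}\tgene_{r.name}\t0\t+")
    paths["genes"].write_text("\n".join(bed_lines) + "\n")

    sm = merged.species_map
    paths["species_map"].write_text(
        "\n".join(f"{s}\t{sm[s]}" for s in merged.samples) + "\n"
    )
    paths["tree"].write_text(species_tree_newick(demography) + "\n")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def _concat_regions(regions: Sequence[RegionResult]) -> GenotypeMatrix:
    """Stack regions on the union sample set (absent samples -> ancestral)."""
    samples: list[str] = []
    species_map: dict[str, str] = {}
    for r in regions:
        for s in r.gm.samples:
            if s not in species_map:
                samples.append(s)
                species_map[s] = r.gm.species_map[s]
    n = len(samples)
    col = {s: i for i, s in enumerate(samples)}
    dosages, haps = [], []
    for r in regions:
        d = np.zeros((r.gm.n_sites, n), dtype=np.int8)
        h = np.zeros((r.gm.n_sites, 2 * n), dtype=np.int8)
        for j, s in enumerate(r.gm.samples):
            k = col[s]
            d[:, k] = r.gm.dosage[:, j]
            h[:, 2 * k] = r.gm.haplotypes[:, 2 * j]
            h[:, 2 * k + 1] = r.gm.haplotypes[:, 2 * j + 1]
        dosages.append(d)
        haps.append(h)
    return GenotypeMatrix(
        contig=np.concatenate([r.gm.contig for r in regions]),
        pos=np.concatenate([r.gm.pos for r in regions]),
        ref=np.concatenate([r.gm.ref for r in regions]),
        alt=np.concatenate([r.gm.alt for r in regions]),
        dosage=np.concatenate(dosages),
        samples=samples,
        species_map=species_map,
        haplotypes=np.concatenate(haps),
    )
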