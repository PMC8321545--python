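import hashlib

import numpy as np
import pytest

from sgvscan import simgen
from sgvscan.simgen import (
    ConfigError,
    DemographyConfig,
    MutationConfig,
    SelectionScenario,
    _next_generation,
    derived_freq,
    simulate_radiation,
    species_tree_newick,
    write_outputs,
)
from sgvscan.variants import read_species_map, read_vcf


def tiny_demography(n=20, samples=3, end=40):
    return DemographyConfig(
        ancestral_size=n,
        lineage_sizes={"A": n, "B": n},
        samples_per_lineage={"A": samples, "B": samples},
        split_events=[(10, "A", "B")],
        root_lineage="A",
        end_generation=end,
    )


def tiny_mutation(L=5_000):
    return MutationConfig(mu=2.5e-5, recomb_rate=1e-7, region_length=L)


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------

def test_split_generations_must_increase():
    with pytest.raises(ConfigError, match="increasing"):
        DemographyConfig(
            ancestral_size=10,
            lineage_sizes={"A": 10, "B": 10, "C": 10},
            samples_per_lineage={"A": 2},
            split_events=[(5, "A", "B"), (5, "A", "C")],
            root_lineage="A",
            end_generation=20,
        )


def test_unknown_parent_rejected():
    with pytest.raises(ConfigError, match="unknown parent"):
        DemographyConfig(
            ancestral_size=10,
            lineage_sizes={"A": 10, "B": 10},
            samples_per_lineage={"A": 2},
            split_events=[(5, "Z", "B")],
            root_lineage="A",
            end_generation=20,
        )


def test_unsampled_lineage_reference_rejected():
    with pytest.raises(ConfigError, match="never exists"):
        DemographyConfig(
            ancestral_size=10,
            lineage_sizes={"A": 10},
            samples_per_lineage={"A": 2, "GHOST": 2},
            root_lineage="A",
            end_generation=20,
        )


def test_samples_cannot_exceed_size():
    with pytest.raises(ConfigError, match="exceed"):
        DemographyConfig(
            ancestral_size=10,
            lineage_sizes={"A": 4},
            samples_per_lineage={"A": 5},
            root_lineage="A",
            end_generation=10,
        )


def test_bad_rates_rejected():
    with pytest.raises(ConfigError):
        MutationConfig(mu=-1e-8, recomb_rate=0, region_length=100)
    with pytest.raises(ConfigError):
        MutationConfig(mu=1e-8, recomb_rate=0, region_length=0)


def test_unknown_mode_rejected():
    with pytest.raises(ConfigError, match="mode"):
        SelectionScenario(mode="banana")


# ---------------------------------------------------------------------------
# determinism and output bookkeeping
# ---------------------------------------------------------------------------

def _small_run(seed, tmp_path, sub):
    dem = tiny_demography()
    mut = tiny_mutation()
    scens = [
        SelectionScenario(mode="neutral"),
        SelectionScenario(
            mode="de_novo_sweep", selected_position=2_500, s=0.8,
            target_lineages=("B",), onset_generation=11, max_retries=50,
        ),
        SelectionScenario(mode="neutral", force_forward=True),
    ]
    regions, truth = simulate_radiation(dem, mut, scens, seed=seed)
    paths = write_outputs(regions, truth, dem, mut, tmp_path / sub)
    return regions, truth, paths


def test_same_seed_byte_identical_vcf(tmp_path):
    _, _, p1 = _small_run(3, tmp_path, "a")
    _, _, p2 = _small_run(3, tmp_path, "b")
    h = lambda p: hashlib.sha256(p.read_bytes()).hexdigest()
    assert h(p1["vcf"]) == h(p2["vcf"])
    assert h(p1["truth"]) == h(p2["truth"])


def test_output_bookkeeping(tmp_path):
    regions, truth, paths = _small_run(4, tmp_path, "c")
    vcf_lines = [
        l for l in paths["vcf"].read_text().splitlines() if not l.startswith("#")
    ]
    header = [
        l for l in paths["vcf"].read_text().splitlines() if l.startswith("#CHROM")
    ][0]
    assert len(header.split("\t")) == 9 + 6  # 6 sampled individuals
    assert {l.split("\t")[0] for l in vcf_lines} == {
        "region_000", "region_001", "region_002"
    }
    assert len(truth) == 3
    assert paths["truth"].read_text().count("\n") == 4  # header + 3 rows
    assert paths["genes"].read_text().count("\n") == 3
    newick = paths["tree"].read_text().strip()
    assert newick == species_tree_newick(tiny_demography())
    assert newick.endswith(";") and "A" in newick and "B" in newick


def test_vcf_roundtrip_reproduces_matrix(tmp_path):
    regions, truth, paths = _small_run(5, tmp_path, "d")
    smap = read_species_map(paths["species_map"])
    gm = read_vcf(paths["vcf"], smap)
    merged = simgen._concat_regions(regions)
    np.testing.assert_array_equal(gm.dosage, merged.dosage)
    np.testing.assert_array_equal(gm.haplotypes, merged.haplotypes)
    np.testing.assert_array_equal(gm.pos, merged.pos)
    assert gm.samples == merged.samples


def test_sweep_conditioning_reached(tmp_path):
    regions, truth, _ = _small_run(6, tmp_path, "e")
    row = truth[truth["mode"] == "de_novo_sweep"].iloc[0]
    assert row["freq_B"] > 0
    assert row["origin_depth"] == "post_split"


# ---------------------------------------------------------------------------
# Wright-Fisher engine invariants
# ---------------------------------------------------------------------------

def _marker_population(rng, N, p0):
    n_derived = int(round(2 * N * p0))
    alleles = np.zeros(2 * N, dtype=int)
    alleles[:n_derived] = 1
    rng.shuffle(alleles)
    empty = np.empty(0)
    return [
        ((empty, int(alleles[2 * i])), (empty, int(alleles[2 * i + 1])))
        for i in range(N)
    ]


def test_neutral_heterozygosity_decay():
    # E[2 p_t (1 - p_t)] = H_0 (1 - 1/2N)^t with no mutation or selection
    rng = np.random.default_rng(42)
    N, t, reps = 20, 12, 600
    mut = MutationConfig(mu=0.0, recomb_rate=0.0, region_length=100)
    hets = []
    for _ in range(reps):
        pop = _marker_population(rng, N, 0.5)
        for _ in range(t):
            pop = _next_generation(rng, pop, N, None, mut, sel_pos=0.0)
        p = derived_freq(pop)
        hets.append(2 * p * (1 - p))
    expected = 0.5 * (1 - 1 / (2 * N)) ** t
    se = np.std(hets, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(hets) - expected) < 4 * se


def test_neutral_fixation_probability_equals_p0():
    rng = np.random.default_rng(43)
    N, p0, reps = 10, 0.2, 600
    mut = MutationConfig(mu=0.0, recomb_rate=0.0, region_length=100)
    fixed = 0
    segregating = 0
    for _ in range(reps):
        pop = _marker_population(rng, N, p0)
        for _ in range(600):  # far beyond the ~4N absorption scale
            pop = _next_generation(rng, pop, N, None, mut, sel_pos=0.0)
            p = derived_freq(pop)
            if p in (0.0, 1.0):
                break
        if p == 1.0:
            fixed += 1
        elif 0.0 < p < 1.0:
            segregating += 1
    assert segregating == 0
    se = np.sqrt(p0 * (1 - p0) / reps)
    assert abs(fixed / reps - p0) < 4 * se


def test_neutral_pi_matches_theta():
    # E[pi] = 4 N mu per site at equilibrium, averaged over replicate regions
    from sgvscan.winstats import Window, window_pi

    N, L = 500, 5_000
    theta = 0.005
    dem = DemographyConfig(
        ancestral_size=N, lineage_sizes={"A": N}, samples_per_lineage={"A": 10},
        root_lineage="A", end_generation=5,
    )
    mut = MutationConfig(mu=theta / (4 * N), recomb_rate=1e-8, region_length=L)
    scens = [SelectionScenario(mode="neutral") for _ in range(50)]
    regions, _ = simulate_radiation(dem, mut, scens, seed=7)
    pis = []
    for r in regions:
        w = [Window(r.name, 0, L)]
        pis.append(window_pi(r.gm, w, "A")[0])
    assert np.mean(pis) == pytest.approx(theta, rel=0.2)


def test_de_novo_establishment_oracle():
    # conditioned on establishment, a strongly selected allele is at high
    # frequency at sampling in nearly all replicates
    N, L = 100, 2_000
    dem = DemographyConfig(
        ancestral_size=N, lineage_sizes={"A": N}, samples_per_lineage={"A": 10},
        root_lineage="A", end_generation=400,
    )
    mut = MutationConfig(mu=1e-6, recomb_rate=1e-8, region_length=L)
    scens = [
        SelectionScenario(
            mode="de_novo_sweep", selected_position=L / 2, s=0.1, h=0.5,
            target_lineages=("A",), onset_generation=1, max_retries=200,
        )
        for _ in range(20)
    ]
    regions, truth = simulate_radiation(dem, mut, scens, seed=8)
    high = (truth["freq_A"] >= 0.9).sum()
    assert high >= 0.9 * len(truth)


def test_sgv_classes_predate_splits():
    dem = tiny_demography(n=30, samples=4, end=60)
    mut = tiny_mutation(L=4_000)
    scn = SelectionScenario(
        mode="sgv_sweep", selected_position=2_000, s=1.0, balancing_h=0.3,
        target_lineages=("B",), class_divergence=500, max_retries=60,
    )
    regions, truth = simulate_radiation(dem, mut, [scn], seed=9)
    r = regions[0]
    row = truth.iloc[0]
    # bookkeeping: the balanced classes coalesce before the first split
    assert row["class_divergence"] > dem.split_events[0][0]
    assert row["origin_depth"] == "pre_radiation"
    # genetic signature: near the selected site, divergence between the two
    # selected-site classes exceeds diversity within them
    sel = row["selected_position"]
    sel_row = np.flatnonzero(r.gm.pos == sel)[0]
    near = (r.gm.pos > sel - 500) & (r.gm.pos < sel + 500)
    H = r.gm.haplotypes[near]
    classes = r.gm.haplotypes[sel_row]
    h1 = H[:, classes == 1]
    h0 = H[:, classes == 0]
    between = np.mean(h1.mean(axis=1)[:, None] != (h0.mean(axis=1)[:, None] > 0.5))
    d_between = np.abs(h1.mean(axis=1) - h0.mean(axis=1)).mean()
    d_within = (h1.std(axis=1).mean() + h0.std(axis=1).mean())
    assert d_between > d_within


def test_coalescent_and_forward_paths_agree_on_dxy():
    # same demography, both engines: mean divergence must agree
    from sgvscan.winstats import Window, window_dxy

    dem = tiny_demography(n=30, samples=5, end=70)
    mut = tiny_mutation(L=10_000)

    def mean_dxy(force_forward, seed):
        scens = [
            SelectionScenario(mode="neutral", force_forward=force_forward)
            for _ in range(12)
        ]
        regions, _ = simulate_radiation(dem, mut, scens, seed=seed)
        vals = []
        for r in regions:
            w = [Window(r.name, 0, mut.region_length)]
            vals.append(window_dxy(r.gm, w, "A", "B")[0])
        return np.mean(vals)

    fwd = mean_dxy(True, 11)
    coal = mean_dxy(False, 12)
    assert fwd == pytest.approx(coal, rel=0.35)
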