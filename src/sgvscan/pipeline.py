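"""End-to-end orchestration: simulate -> filter -> winstats -> scan -> ihs -> origin.

All intermediates are plain TSV/VCF text files under the run directory and
every realized threshold is logged in ``report.json``, so any stage can be
re-run and inspected from its persisted inputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import haploscan, scan, sgv, simgen, winstats
from .variants import (
    FilterConfig,
    GenotypeMatrix,
    filter_sites,
    inbreeding_coefficient,
    ld_prune,
    read_species_map,
    read_vcf,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# demo radiation preset: 3 focal species + tiered outgroups
# ---------------------------------------------------------------------------

FOCAL_SPECIES = ("HChi", "HSau", "LRuf")
OUTGROUP_TIERS = {"NBri": "LT", "HBur": "HB", "ACal": "LM", "MZeb": "LM"}
ROOT_OUTGROUP = "ONil"


def lineage_tier_map() -> dict[str, str]:
    tiers = {sp: "focal" for sp in FOCAL_SPECIES}
    tiers.update(OUTGROUP_TIERS)
    tiers[ROOT_OUTGROUP] = "outgroup"
    return tiers


def demo_demography(
    n_focal: int = 50,
    n_outgroup: int = 25,
    samples_focal: int = 6,
    samples_outgroup: int = 2,
) -> simgen.DemographyConfig:
    """Radiation demography: deep root outgroup, tiered outgroup splits, a
    long focal stem and two recent focal splits (the root lineage itself is
    the third focal species)."""
    sizes = {sp: n_focal for sp in FOCAL_SPECIES}
    sizes.update({sp: n_outgroup for sp in (*OUTGROUP_TIERS, ROOT_OUTGROUP)})
    samples = {sp: samples_focal for sp in FOCAL_SPECIES}
    samples.update({sp: samples_outgroup for sp in (*OUTGROUP_TIERS, ROOT_OUTGROUP)})
    return simgen.DemographyConfig(
        ancestral_size=n_focal,
        lineage_sizes=sizes,
        samples_per_lineage=samples,
        split_events=[
            (10, "LRuf", "NBri"),
            (18, "LRuf", "HBur"),
            (25, "LRuf", "ACal"),
            (32, "ACal", "MZeb"),
            (200, "LRuf", "HChi"),
            (210, "LRuf", "HSau"),
        ],
        deep_outgroups={ROOT_OUTGROUP: 1500},
        root_lineage="LRuf",
        end_generation=225,
    )


def demo_mutation(region_length: int = 6_000, n_focal: int = 50,
                  theta_per_site: float = 0.01,
                  recomb_rate: float = 2e-6) -> simgen.MutationConfig:
    return simgen.MutationConfig(
        mu=theta_per_site / (4.0 * n_focal),
        recomb_rate=recomb_rate,
        region_length=region_length,
    )


SWEEP_ONSET = {"HChi": 201, "HSau": 211, "LRuf": 211}


def demo_scenarios(
    n_neutral: int = 20,
    n_de_novo: int = 5,
    n_sgv: int = 5,
    region_length: int = 6_000,
    neutral_region_length: int = 200_000,
    neutral_all_lineages: bool = False,
    s: float = 1.5,
    recomb_rate: float = 1e-5,
    sgv_recomb_rate: float = 2.5e-7,
) -> list[simgen.SelectionScenario]:
    """Demo scenario list: sweeps first, then neutral filler regions.

    Sweep targets cycle over the three focal species.  The neutral fillers
    provide the window mass that stabilizes the top-0.5% HDR thresholds;
    they are sampled for the focal species only (the outgroup columns are
    emitted as reference) unless ``neutral_all_lineages``.  SGV regions sit
    in a low-recombination regime so the ancient haplotype classes stay
    intact over the gene, as for real long divergent haplotypes.
    """
    mid = region_length / 2
    out: list[simgen.SelectionScenario] = []
    for k in range(n_de_novo):
        target = FOCAL_SPECIES[k % 3]
        out.append(
            simgen.SelectionScenario(
                mode="de_novo_sweep",
                selected_position=mid,
                s=s,
                h=0.5,
                target_lineages=(target,),
                onset_generation=SWEEP_ONSET[target],
                min_final_freq=0.85,
                region_length=region_length,
                recomb_rate=recomb_rate,
            )
        )
    for k in range(n_sgv):
        target = FOCAL_SPECIES[k % 3]
        out.append(
            simgen.SelectionScenario(
                mode="sgv_sweep",
                selected_position=mid,
                s=s,
                h=0.5,
                balancing_h=0.15,
                target_lineages=(target,),
                allele1_lineages=("NBri",),
                class_divergence=800,
                region_length=region_length,
                recomb_rate=sgv_recomb_rate,
            )
        )
    for _ in range(n_neutral):
        out.append(
            simgen.SelectionScenario(
                mode="neutral",
                region_length=neutral_region_length,
                recomb_rate=recomb_rate,
                sample_lineages=None if neutral_all_lineages else FOCAL_SPECIES,
            )
        )
    return out


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable defaults to the scan's canonical value (10-kb/2-kb
    windows, top 0.5%, HWE 0.001, MAF 0.05, LD 50/5/0.1, iHS crit 1%,
    100 bootstraps, support 60, 10-kb gene flanks)."""

    seed: int = 1
    out_dir: str = "sgvscan_run"
    # simulation scale
    n_neutral: int = 20
    n_de_novo: int = 5
    n_sgv: int = 5
    region_length: int = 6_000
    neutral_region_length: int = 200_000
    neutral_all_lineages: bool = False
    n_focal: int = 50
    # filtering
    hwe_alpha: float = 0.001
    apply_hwe: bool = False  # the origin analyses run on non-HWE-filtered data
    maf_min: float = 0.05
    ld_window: int = 50
    ld_step: int = 5
    ld_r2: float = 0.1
    # windows / HDRs
    window: int = 10_000
    step: int = 2_000
    hdr_quantile: float = 0.995
    gene_flank: int = 10_000
    # iHS
    run_ihs: bool = True
    ihs_crit: float = 0.01
    ihs_max_contigs: int = 10  # scan the leading (sweep) contigs only
    # origin
    origin_genes: str = "candidates"  # or "all": classify every gene model
    n_bootstrap: int = 100
    support_min: float = 60.0
    focal_species: tuple[str, ...] = FOCAL_SPECIES
    outgroup: str = ROOT_OUTGROUP

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclass_fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**data)
        if "focal_species" in data:
            cfg.focal_species = tuple(data["focal_species"])
        return cfg


def dataclass_fields(cls):
    import dataclasses

    return dataclasses.fields(cls)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage into ``cfg.out_dir``; returns the run report dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}

    # --- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        demography = demo_demography(n_focal=cfg.n_focal)
        mutation = demo_mutation(cfg.region_length, n_focal=cfg.n_focal)
        scenarios = demo_scenarios(
            cfg.n_neutral, cfg.n_de_novo, cfg.n_sgv, cfg.region_length,
            cfg.neutral_region_length, cfg.neutral_all_lineages,
        )
        regions, truth = simgen.simulate_radiation(
            demography, mutation, scenarios, seed=cfg.seed
        )
        sim_paths = simgen.write_outputs(
            regions, truth, demography, mutation, out / "sim"
        )
        report["stages"][stage] = {
            "n_regions": len(regions),
            "n_sites": int(sum(r.gm.n_sites for r in regions)),
        }
    except Exception as e:  # noqa: BLE001
        _persist_and_raise(report, out, stage, e)

    # --- filter -------------------------------------------------------------
    stage = "filter"
    try:
        species_map = read_species_map(sim_paths["species_map"])
        gm = read_vcf(sim_paths["vcf"], species_map)
        fcfg = FilterConfig(
            hwe_alpha=cfg.hwe_alpha if cfg.apply_hwe else None,
        )
        gm_f, flog = filter_sites(gm, fcfg)
        flog.to_csv(out / "filter_log.tsv", sep="\t", index=False)
        fvals = inbreeding_coefficient(gm_f)
        fvals.to_csv(out / "inbreeding.tsv", sep="\t", header=["F"])
        report["stages"][stage] = {
            "sites_in": gm.n_sites,
            "sites_out": gm_f.n_sites,
            "removed": flog[flog["filter"] != "pass"]["filter"].value_counts().to_dict(),
        }
    except Exception as e:  # noqa: BLE001
        _persist_and_raise(report, out, stage, e)

    # --- winstats -----------------------------------------------------------
    stage = "winstats"
    try:
        contig_lengths = {r.name: r.region_length for r in regions}
        stats = winstats.compute_window_stats(
            gm_f, contig_lengths, list(cfg.focal_species), cfg.window, cfg.step
        )
        stats.to_csv(out / "window_stats.tsv", sep="\t", index=False)
        gw = {}
        for i, A in enumerate(cfg.focal_species):
            for B in cfg.focal_species[i + 1:]:
                gw[f"{A}-{B}"] = winstats.genomewide_weighted_fst(gm_f, A, B)
        # PCA on the focal individuals, MAF + LD pruned
        focal_cols = np.concatenate(
            [gm_f.columns_for_species(sp) for sp in cfg.focal_species]
        )
        gm_focal = GenotypeMatrix(
            contig=gm_f.contig, pos=gm_f.pos, ref=gm_f.ref, alt=gm_f.alt,
            dosage=gm_f.dosage[:, focal_cols],
            samples=[gm_f.samples[i] for i in focal_cols],
            species_map=gm_f.species_map,
        )
        maf_cfg = FilterConfig(hwe_alpha=None, apply_maf=True, maf_min=cfg.maf_min)
        gm_maf, _ = filter_sites(gm_focal, maf_cfg)
        kept = ld_prune(gm_maf, cfg.ld_window, cfg.ld_step, cfg.ld_r2)
        coords, explained = winstats.pca_genotypes(gm_maf.take_sites(kept))
        coords.to_csv(out / "pca.tsv", sep="\t")
        report["stages"][stage] = {
            "n_windows": len(stats),
            "genomewide_fst": gw,
            "pca_sites": int(len(kept)),
            "pc1_explained": float(explained[0]) if len(explained) else None,
        }
    except Exception as e:  # noqa: BLE001
        _persist_and_raise(report, out, stage, e)

    # --- scan ---------------------------------------------------------------
    stage = "scan"
    try:
        genes = scan.read_gene_models(sim_paths["genes"])
        pairs = [
            (cfg.focal_species[i], cfg.focal_species[j])
            for i in range(len(cfg.focal_species))
            for j in range(i + 1, len(cfg.focal_species))
        ]
        hdrs_by_pair = {}
        candidates_by_pair = {}
        thresholds = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for pair in pairs:
                hdrs = scan.call_hdrs(stats, pair, cfg.hdr_quantile)
                scan.sweep_flag(stats, hdrs, pair, cfg.hdr_quantile)
                hdrs_by_pair[pair] = hdrs
                thresholds[f"{pair[0]}-{pair[1]}"] = (
                    hdrs[0].threshold if hdrs else None
                )
            scan.assign_specificity(hdrs_by_pair)
            for pair in pairs:
                cands = scan.map_genes_to_hdrs(
                    hdrs_by_pair[pair], genes, stats, pair, cfg.gene_flank
                )
                scan.annotate_differentiated_snps(gm_f, cands, pair, flank=cfg.gene_flank)
                candidates_by_pair[pair] = cands
        all_hdrs = [h for hs in hdrs_by_pair.values() for h in hs]
        scan.hdrs_to_frame(all_hdrs).to_csv(out / "hdrs.tsv", sep="\t", index=False)
        cand_rows = []
        for pair, cands in candidates_by_pair.items():
            for c in cands:
                cand_rows.append(
                    {
                        "gene": c.gene.gene_id,
                        "pair": f"{pair[0]}-{pair[1]}",
                        "contig": c.gene.contig,
                        "start": c.gene.start,
                        "end": c.gene.end,
                        "max_dxy": c.max_dxy,
                        "n_snps": 0 if c.snps is None else len(c.snps),
                    }
                )
        pd.DataFrame(
            cand_rows,
            columns=["gene", "pair", "contig", "start", "end", "max_dxy", "n_snps"],
        ).to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
        report["stages"][stage] = {
            "hdr_thresholds": thresholds,
            "n_hdrs": {f"{p[0]}-{p[1]}": len(h) for p, h in hdrs_by_pair.items()},
            "n_candidate_genes": len({r["gene"] for r in cand_rows}),
        }
    except Exception as e:  # noqa: BLE001
        _persist_and_raise(report, out, stage, e)

    # --- ihs ----------------------------------------------------------------
    stage = "ihs"
    if cfg.run_ihs:
        try:
            contigs = [r.name for r in regions[: cfg.ihs_max_contigs]]
            tables = []
            for sp in cfg.focal_species:
                for contig in contigs:
                    haps = haploscan.PhasedHaplotypes.from_genotype_matrix(
                        gm_f, sp, contig
                    )
                    tbl = haploscan.scan_species(
                        haps, contig, crit_percent=cfg.ihs_crit, standardize=False
                    )
                    tbl.insert(0, "species", sp)
                    tables.append(tbl)
            ihs_all = pd.concat(tables, ignore_index=True)
            parts = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for sp in cfg.focal_species:
                    sub = ihs_all[ihs_all["species"] == sp].copy()
                    if len(sub):
                        sub = haploscan.ihs_scores(sub, crit_percent=cfg.ihs_crit)
                    parts.append(sub)
            ihs_all = pd.concat(parts, ignore_index=True)
            ihs_all.to_csv(out / "ihs.tsv", sep="\t", index=False)
            report["stages"][stage] = {
                "n_cores": int(len(ihs_all)),
                "n_extreme": int(ihs_all.get("extreme", pd.Series(dtype=bool)).sum()),
            }
        except Exception as e:  # noqa: BLE001
            _persist_and_raise(report, out, stage, e)

    # --- origin -------------------------------------------------------------
    stage = "origin"
    try:
        tiers = lineage_tier_map()
        # classify the distinct candidate genes, using their best max_dxy
        best: dict[str, dict] = {}
        for pair, cands in candidates_by_pair.items():
            for c in cands:
                rec = best.setdefault(
                    c.gene.gene_id,
                    {"gene": c.gene, "max_dxy": c.max_dxy},
                )
                if not np.isnan(c.max_dxy) and (
                    np.isnan(rec["max_dxy"]) or c.max_dxy > rec["max_dxy"]
                ):
                    rec["max_dxy"] = c.max_dxy
        if cfg.origin_genes == "all":
            dxy_cols = [c for c in stats.columns if c.startswith("dxy_")]
            for g in genes:
                sub = stats[
                    (stats["contig"] == g.contig)
                    & (stats["start"] < g.end)
                    & (stats["end"] > g.start)
                ]
                vals = sub[dxy_cols].to_numpy(dtype=float).ravel()
                vals = vals[~np.isnan(vals)]
                best[g.gene_id] = {
                    "gene": g,
                    "max_dxy": float(vals.max()) if vals.size else float("nan"),
                }
        calls = []
        rng = np.random.default_rng(cfg.seed + 1)
        for gene_id in sorted(best):
            rec = best[gene_id]
            g = rec["gene"]
            try:
                aln = sgv.build_gene_alignment(gm_f, g.contig, g.start, g.end)
            except sgv.AlignmentError:
                continue
            tree = sgv.nj_tree_with_bootstrap(
                aln, cfg.outgroup, cfg.n_bootstrap,
                seed=int(rng.integers(2**31 - 1)),
            )
            calls.append(
                sgv.classify_origin(
                    tree, tiers, cfg.support_min, gene=gene_id,
                    max_dxy=rec["max_dxy"],
                )
            )
        sgv.origin_calls_to_frame(calls).to_csv(
            out / "origin_calls.tsv", sep="\t", index=False
        )
        mw = sgv.compare_dxy_by_origin(calls)
        tallies = {}
        for c in calls:
            tallies[c.origin] = tallies.get(c.origin, 0) + 1
        report["stages"][stage] = {"origin_tallies": tallies, "mann_whitney": mw}
    except Exception as e:  # noqa: BLE001
        _persist_and_raise(report, out, stage, e)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _persist_and_raise(report: dict, out: Path, stage: str, exc: Exception):
    report["failed_stage"] = stage
    report["error"] = str(exc)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    raise StageError(stage, str(exc)) from exc
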