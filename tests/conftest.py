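import numpy as np
import pytest

from sgvscan.variants import GenotypeMatrix


def make_gm(
    dosage,
    species,
    pos=None,
    contig="chr1",
    haplotypes=None,
    ref=None,
    alt=None,
):
    """Small GenotypeMatrix from a (sites x individuals) dosage list."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_ind = dosage.shape
    samples = [f"s{i}" for i in range(n_ind)]
    return GenotypeMatrix(
        contig=np.array([contig] * n_sites),
        pos=np.arange(n_sites, dtype=np.int64) if pos is None else np.asarray(pos),
        ref=np.array(["A"] * n_sites) if ref is None else np.asarray(ref),
        alt=np.array(["C"] * n_sites) if alt is None else np.asarray(alt),
        dosage=dosage,
        samples=samples,
        species_map={s: sp for s, sp in zip(samples, species)},
        haplotypes=None if haplotypes is None else np.asarray(haplotypes, dtype=np.int8),
    )


def gm_from_haplotypes(haps, species, pos=None, contig="chr1"):
    """GenotypeMatrix from a (sites x haplotypes) 0/1 matrix; consecutive
    haplotype pairs form individuals."""
    haps = np.asarray(haps, dtype=np.int8)
    dosage = haps[:, 0::2] + haps[:, 1::2]
    return make_gm(dosage, species, pos=pos, contig=contig, haplotypes=haps)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full demo pipeline run shared by the slower integration tests."""
    from sgvscan.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("demo_run")
    cfg = PipelineConfig(
        seed=11,
        out_dir=str(out),
        run_ihs=False,
        n_focal=100,
    )
    report = run_pipeline(cfg)
    return {"out": out, "cfg": cfg, "report": report}
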