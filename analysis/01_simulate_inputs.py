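#!/usr/bin/env python
"""Generate every synthetic input consumed by the downstream analyses.

Writes, under results/inputs/:
  * droplet_panel.csv       — four-population ddPCR panel (40 samples each)
  * <genome>.depth.tsv/.bed — per-base depth + paralog loci for three genomes
  * family_null.fa          — gene family, no gene conversion
  * family_conversion.fa    — gene family under frequent gene conversion
  * amplicon_ref.fa, clone_low.fa, clone_high.fa — CRISPR amplicon data
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dupfam.io_formats import Region, RegionSet, SequenceRecord, write_bed, write_depth_tsv, write_droplet_csv, write_fasta
from dupfam.simulate import (
    AmpliconSimConfig,
    DepthSimConfig,
    DropletSimConfig,
    FamilySimConfig,
    simulate_amplicon_reads,
    simulate_depth_track,
    simulate_droplets,
    simulate_gene_family,
)

SEED = 42
OUT = Path("results/inputs")
OUT.mkdir(parents=True, exist_ok=True)

# -- ddPCR panel: population means/SDs mirror a human copy-number survey
populations = {"CHS": (7.24, 1.24), "FIN": (7.61, 0.98), "LWK": (7.62, 0.71), "YRI": (7.62, 0.85)}
rng = np.random.default_rng(SEED)
frames = []
for pop, (mu, sd) in populations.items():
    for k in range(40):
        cfg = DropletSimConfig(
            true_cn=max(1.0, float(rng.normal(mu, sd))),
            n_droplets=20_000,
            population=pop,
            seed=int(rng.integers(0, 2**31)),
        )
        df = simulate_droplets(cfg)
        df["sample_id"] = f"{pop}_{k:03d}"
        frames.append(df)
panel = pd.concat(frames, ignore_index=True)
write_droplet_csv(panel, OUT / "droplet_panel.csv")
print(f"droplet panel: {panel.sample_id.nunique()} samples -> {OUT/'droplet_panel.csv'}")

# -- depth tracks: one-copy-per-locus genome vs progressively expanded ones
regions = RegionSet([Region("chrSim", 10_000, 20_000, "A"), Region("chrSim", 25_000, 35_000, "C")])
genomes = {
    "macaque_like": {"A": 2, "C": 2},
    "great_ape_like": {"A": 6, "C": 4},
    "human_like": {"A": 14, "C": 6},
}
for i, (genome, mults) in enumerate(genomes.items()):
    cfg = DepthSimConfig(
        genome_length=60_000, coverage=30, paralog_regions=regions,
        multiplicities=mults, seed=SEED + 100 + i,
    )
    track, _ = simulate_depth_track(cfg)
    write_depth_tsv([track], OUT / f"{genome}.depth.tsv")
    write_bed(regions, OUT / f"{genome}.bed")
    print(f"depth track: {genome} (haploid multiplicities {mults})")

# -- gene families with and without interlocus gene conversion
for name, rate in (("family_null", 0.0), ("family_conversion", 10.0)):
    aln = simulate_gene_family(FamilySimConfig(gene_conversion_rate=rate, seed=SEED + 7))
    write_fasta(aln.records, OUT / f"{name}.fa")
    print(f"gene family: {name} ({len(aln)} sequences, {aln.n_sites} sites)")

# -- CRISPR amplicons: a lightly and a heavily frameshifted clone
ref = SequenceRecord("amplicon", "".join(np.array(list("ACGT"))[np.random.default_rng(SEED + 9).integers(0, 4, 240)]))
write_fasta([ref], OUT / "amplicon_ref.fa")
clones = {
    "clone_low": dict(indel_spectrum=[(-3, 0.15), (-1, 0.10)], unedited_fraction=0.75),
    "clone_high": dict(indel_spectrum=[(-1, 0.45), (1, 0.25), (-2, 0.15)], unedited_fraction=0.15),
}
for i, (clone, kwargs) in enumerate(clones.items()):
    cfg = AmpliconSimConfig(reference=ref, cut_site=120, n_reads=400, seed=SEED + 20 + i, **kwargs)
    write_fasta(simulate_amplicon_reads(cfg), OUT / f"{clone}.fa")
    print(f"amplicons: {clone} (400 reads)")
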