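#!/usr/bin/env python
"""Call indels at the Cas9 cut site for both simulated single-cell clones
and classify them as low or high frameshift clones.

Also scans the amplicon reference for candidate 19-nt spacer + NGG sites.
"""

from pathlib import Path

import pandas as pd

from dupfam.crispr import AmpliconConfig, find_spacer_sites, summarize_clone
from dupfam.io_formats import read_fasta

OUT = Path("results/crispr")
OUT.mkdir(parents=True, exist_ok=True)

(reference,) = read_fasta("results/inputs/amplicon_ref.fa")
cfg = AmpliconConfig(reference=reference, cut_site=120, window=20, frameshift_threshold=0.5)

sites = find_spacer_sites(reference)
pd.DataFrame(sites).to_csv(OUT / "spacer_sites.tsv", sep="\t", index=False)
print(f"{len(sites)} candidate spacer+NGG sites in the {len(reference)} bp amplicon")

rows = []
for clone in ("clone_low", "clone_high"):
    reads = read_fasta(f"results/inputs/{clone}.fa")
    summary = summarize_clone(reads, cfg, clone_id=clone)
    rows.append(summary.__dict__)
    print(
        f"{clone}: {summary.n_frameshift}/{summary.n_reads} frameshift "
        f"({summary.frameshift_fraction:.1%}), {summary.n_in_frame} in-frame, "
        f"{summary.n_unedited} unedited -> class {summary.clone_class}"
    )

pd.DataFrame(rows).to_csv(OUT / "clone_summaries.tsv", sep="\t", index=False)
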