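"""Descriptive view of the interactome: lncRNA selection, cumulative
coverage, and the nearest-gene baseline.

The nearest-gene classifier is the zero-parameter baseline every model must
beat: assign each bound tile to the cis lncRNA whose gene is closest.  On
the cohort (one lncRNA per chromosome) it is trivially perfect, so a second
two-lncRNA single-chromosome map is built to show a non-trivial case.
"""

from pathlib import Path

import numpy as np

from lncloc.experiments import cohort_config
from lncloc.interactome import (InteractionMap, LncRNA, cumulative_coverage,
                                nearest_gene_classifier, select_lncrnas)
from lncloc.synthetic import (LncSpec, SyntheticConfig, generate_context_tracks,
                              generate_genome, generate_interactions)

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = cohort_config(seed=1)
    genome = generate_genome(cfg)
    tracks = generate_context_tracks(cfg, genome)
    imap = generate_interactions(cfg, genome, tracks)

    sel = select_lncrnas(imap, min_tiles=100)
    sel.to_csv(OUT / "lncrna_selection.tsv", sep="\t", index=False)
    cumulative_coverage(imap).to_csv(OUT / "cumulative_coverage.tsv",
                                     sep="\t", index=False)
    print("selection:\n", sel.to_string(index=False))

    # two lncRNAs sharing a chromosome: the nearest-gene task is non-trivial
    two = SyntheticConfig(
        n_chroms=1, chrom_length=4_000_000,
        lncrnas=(LncSpec("lnc_left", "chr1", 999_000, 1_001_000,
                         mechanism="noise", n_target_positives=150),
                 LncSpec("lnc_right", "chr1", 2_999_000, 3_001_000,
                         mechanism="noise", n_target_positives=150)),
        decay_scale=700_000.0, seed=2)
    g2 = generate_genome(two)
    t2 = generate_context_tracks(two, g2)
    m2 = generate_interactions(two, g2, t2)
    rep = nearest_gene_classifier(m2, g2.tiling)
    rep.to_csv(OUT / "nearest_gene_baseline.tsv", sep="\t")
    print("\nnearest-gene baseline (two cis lncRNAs):\n", rep.round(3).to_string())


if __name__ == "__main__":
    main()
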