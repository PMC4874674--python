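"""Site-model tests of positive selection on the panel haplotypes.

Runs the full selection stage per species and pooled: unit-stacked codon
alignment, NJ tree with M0 branch lengths, M1a/M2a (and optionally M7/M8)
fits with branch lengths fixed, likelihood-ratio tests, and BEB site
classification mapped back to zinc-finger helix positions.
"""

import argparse

from zfselect.pipeline import PipelineConfig, run_pipeline
from zfselect.seq_io import read_fasta
from zfselect.site_selection import lrt_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fasta", default="results/panel.fasta")
    ap.add_argument("--models", default="M1a,M2a")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/selection")
    args = ap.parse_args()

    config = PipelineConfig(
        records=read_fasta(args.fasta),
        models=tuple(args.models.split(",")),
        out_dir=args.out,
        seed=args.seed,
        n_starts=2,
    )
    result = run_pipeline(config)
    print(lrt_table(result.lrt_results).to_string(index=False))
    for group, positions in sorted(result.beb_flagged.items()):
        if positions:
            print(f"{group}: positively selected helix positions {positions}")
    print(f"\nreports under {args.out}")


if __name__ == "__main__":
    main()
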