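#!/usr/bin/env python
"""Mutation-accumulation null model: how identity and similarity decay
together under random point mutation, with no selection.

50 coding sequences of 333 codons are sampled from E. coli K-12 codon
usage and pushed through 70 rounds of 10 random substitutions each; after
every round each mutant is aligned against its unmutated ancestor,
translated either in the sense frame or in frame 0 of the direct reverse
complement (the antisense control).  Median identity/similarity per integer
percent of identity decrease are written to results/null_model/.
"""

import argparse
from pathlib import Path

from asorf.mutsim import SimulationConfig, ecoli_k12_usage, run_null_model


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/null_model"))
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    out = run_null_model(ecoli_k12_usage(), cfg, return_observations=True)

    args.outdir.mkdir(parents=True, exist_ok=True)
    for frame, (curve, obs) in out.items():
        curve.write_tsv(args.outdir / f"curve_{frame}.tsv")
        obs.to_csv(args.outdir / f"observations_{frame}.tsv", sep="\t",
                   index=False)
        df = curve.to_frame()
        deep = df[df.median_identity_pct <= 80]
        gap = (deep.median_similarity_pct - deep.median_identity_pct).median()
        print(f"{frame}: {len(df)} bins, identity "
              f"{df.median_identity_pct.min():.1f}..100.0; at <=80% identity "
              f"similarity exceeds identity by a median of {gap:.1f} points")
    print(f"wrote curves and per-round observations to {args.outdir}/")


if __name__ == "__main__":
    main()
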