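#!/usr/bin/env python
"""Generate the default synthetic study and serialize it with its truth.

500 kb genome, 60 stem-loop loci (20 per conservation class, seven
overlapping pairs), 200 accessions in five genetic groups at 20x
coverage, a 48-sample MLPA panel and an expression matrix with
planted dosage correlations. Everything downstream reads this
directory.
"""

from pathlib import Path

from mircnv import synthetic

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    study = synthetic.simulate_study(seed=SEED)
    study.write(OUT)
    n_pairs = sum(len(r.member_mir_ids) > 1 for r in study.regions)
    print(f"genome: {sum(len(s) for s in study.genome.values()):,} bp, "
          f"{len(study.repeats)} planted repeat blocks")
    print(f"catalogue: {len(study.mirs)} loci -> {len(study.regions)} "
          f"genotyping regions ({n_pairs} overlapping pairs)")
    print(f"population: {study.cn_truth.shape[1]} accessions, "
          f"{study.groups.nunique()} genetic groups")
    print(f"masked loci (planted genotyping failures): {study.masked_mirs}")
    print(f"wrote study to {OUT}")


if __name__ == "__main__":
    main()
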