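#!/usr/bin/env python
"""Generate the study inputs: a 10-genus weaning-infant community, a food
composition table (12 complementary foods + breastmilk), and the genus
abundance profile, all with analytically known ground truth.

Writes toy-json reconstructions, abundances.tsv, foods.csv and
ground_truth.json under results/inputs/.
"""

import argparse
from collections import Counter

import weanflux as wf


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--out", default="results/inputs")
    args = parser.parse_args()

    bundle = wf.gen_scenario(n_taxa=10, n_foods=12, seed=args.seed)
    paths = bundle.write(args.out)

    profile = bundle.profile
    kept = wf.filter_abundances(profile, 0.01)
    print(f"community: {len(profile.entries)} genera generated, "
          f"{len(kept.entries)} at >=1% abundance "
          f"({kept.total:.1%} of the community)")
    groups = Counter(f.group_label for f in bundle.foods.values())
    print(f"foods: {dict(groups)}")
    directions = Counter(bundle.ground_truth.expected_direction.values())
    print(f"ground-truth directions over {len(bundle.pairs) + len(bundle.food_ids)} "
          f"combinations x 2 panels: {dict(directions)}")
    for name, path in paths.items():
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
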