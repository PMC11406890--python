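#!/usr/bin/env python
"""Summarize the screen: direction counts per panel, and the combinations
with the strongest influence on total SCFA and total BCFA fluxes.

Reads results/screen/screen_full.json and writes results/summary.tsv.
"""

import argparse
from pathlib import Path

import weanflux as wf


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--screen", default="results/screen/screen_full.json")
    parser.add_argument("--out", default="results/summary.tsv")
    parser.add_argument("--top", type=int, default=5)
    args = parser.parse_args()

    results = wf.load_report(args.screen)
    combos = [r for r in results if r.combination_id != "breastmilk"]
    summary = wf.summarize_directions(results)

    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        fh.write("panel\tdirection\tcount\n")
        for panel, counts in summary.items():
            for direction, count in counts.items():
                fh.write(f"{panel}\t{direction}\t{count}\n")
    print(f"wrote {args.out}")

    for panel, label in (("total_scfa", "total SCFA"), ("total_bcfa", "total BCFA")):
        ranked = sorted(
            (r for r in combos if r.rel_variation.get(panel) is not None),
            key=lambda r: r.rel_variation[panel],
        )
        print(f"\n{label}: strongest decreases vs breastmilk")
        for r in ranked[: args.top]:
            print(f"  {r.combination_id:32s} {r.rel_variation[panel]:+7.1f}%")
        print(f"{label}: strongest increases vs breastmilk")
        for r in ranked[-args.top:][::-1]:
            print(f"  {r.combination_id:32s} {r.rel_variation[panel]:+7.1f}%")


if __name__ == "__main__":
    main()
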