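#!/usr/bin/env python
"""Generate the synthetic field campaign analysed by the later scripts.

Draws 250 shoals from the study-flavoured assembly model (four herbivore
species, two per biogeographic origin, across 7 locations) and 294 focal
foraging observations with Tweedie bite rates, and writes both tables under
data/synthetic/.
"""

import argparse
from pathlib import Path

import shoalmix as sm


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("data/synthetic"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    assembly = sm.default_assembly_params()
    shoals = sm.generate_shoal_observations(assembly, 250, seed=args.seed)
    sm.write_shoal_table(shoals, args.out_dir / "shoals.csv", assembly.catalog)

    design = sm.make_study_design(seed=args.seed + 1)
    foraging = sm.generate_foraging_observations(
        sm.default_foraging_params(), design, seed=args.seed + 2
    )
    sm.write_foraging_table(foraging, args.out_dir / "foraging.csv")

    sizes = [r.shoal_size for r in shoals]
    print(f"wrote {len(shoals)} shoals (sizes {min(sizes)}-{max(sizes)}) and")
    print(f"{len(foraging)} foraging records to {args.out_dir}/")
    print("species:", ", ".join(assembly.catalog.species))


if __name__ == "__main__":
    main()
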