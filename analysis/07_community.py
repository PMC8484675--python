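#!/usr/bin/env python
"""Community structure: Bray–Curtis, 2-D NMDS, PERMANOVA by reef and depth.

Computes the dissimilarity matrix on copy numbers, embeds it in two
dimensions, and tests reef-vs-surrounding and middle-vs-bottom groupings
with free-permutation PERMANOVA.
"""

import argparse
from pathlib import Path

import pandas as pd

from qmiseq import bray_curtis, nmds, permanova
from qmiseq.io import read_config, read_metadata

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=ROOT / "results")
    ap.add_argument("--bundle-dir", type=Path, default=ROOT / "results" / "bundle")
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--n-perm", type=int, default=999)
    args = ap.parse_args()

    ml = pd.read_csv(args.results_dir / "copies_per_ml_water.csv",
                     index_col="sample_id")
    metas = {m.sample_id: m for m in read_metadata(args.bundle_dir / "metadata.csv")}
    cfg = read_config(args.bundle_dir / "config.yaml")
    reef_ids = {s.station_id for s in cfg.stations if s.is_reef}

    dm = bray_curtis(ml)
    ordination = nmds(dm, k=2, n_starts=50, seed=args.seed)
    print(f"NMDS stress = {ordination.stress:.3f} "
          f"({ordination.n_starts} starts, seed {args.seed})")
    coords = pd.DataFrame(ordination.coordinates, index=ml.index,
                          columns=["NMDS1", "NMDS2"])
    coords["station_id"] = [metas[s].station_id for s in ml.index]
    coords["depth_layer"] = [metas[s].depth_layer for s in ml.index]
    coords.to_csv(args.results_dir / "nmds_coordinates.tsv", sep="\t")

    rows = []
    for name, groups in (
        ("ARs_vs_surrounding",
         ["AR" if metas[s].station_id in reef_ids else "surrounding"
          for s in ml.index]),
        ("middle_vs_bottom", [metas[s].depth_layer for s in ml.index]),
    ):
        res = permanova(dm, groups, n_perm=args.n_perm, seed=args.seed)
        rows.append({"comparison": name, "pseudo_F": res.pseudo_f,
                     "p_value": res.p_value, "n_perm": res.n_permutations})
        print(f"PERMANOVA {name}: F = {res.pseudo_f:.3f}, p = {res.p_value:.3f}")
    pd.DataFrame(rows).to_csv(args.results_dir / "permanova.tsv",
                              sep="\t", index=False)


if __name__ == "__main__":
    main()
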