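#!/usr/bin/env python
"""Process station echograms: mask, threshold at −70 dB, 10-minute means.

Writes one row per station with the mean linear volume backscattering
coefficient over the ten minutes following that station's sampling time.
"""

import argparse
from pathlib import Path

import pandas as pd

from qmiseq import apply_masks, threshold_echogram, window_mean_sv
from qmiseq.io import read_echogram, read_metadata

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle-dir", type=Path, default=ROOT / "results" / "bundle")
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results")
    ap.add_argument("--threshold-db", type=float, default=-70.0)
    args = ap.parse_args()

    metas = read_metadata(args.bundle_dir / "metadata.csv")
    t_sample = {}
    for m in metas:
        if not m.is_control and m.sampling_time:
            t_sample.setdefault(m.station_id, float(m.sampling_time))

    rows = []
    for path in sorted(args.bundle_dir.glob("echogram_*.csv")):
        st_id = path.stem.removeprefix("echogram_")
        eg = read_echogram(path, st_id)
        eg = threshold_echogram(apply_masks(eg), args.threshold_db)
        s = window_mean_sv(eg, t_sample[st_id], duration_s=600.0)
        rows.append({"station_id": st_id, "mean_sv_linear": s.mean_sv_linear,
                     "n_cells_used": s.n_cells_used, "flagged": s.flagged})
        print(f"{st_id:>5s}: mean S_V = {s.mean_sv_linear:.3e} "
              f"({s.n_cells_used} cells)")

    args.out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out_dir / "echo_summaries.tsv",
                              sep="\t", index=False)


if __name__ == "__main__":
    main()
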