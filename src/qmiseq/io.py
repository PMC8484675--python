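"""Plain-text I/O for the survey tables.

All tables are UTF-8 CSV/TSV with a header row.  Schemas:

* reads.csv         — wide table, ``sample_id`` index column, one column per
                      OTU/standard; ``standards.csv`` lists the standard ids
                      with their copies/µl.
* metadata.csv      — one row per sample (station, distance, layer,
                      replicate, volumes, sampling time, control flag).
* assignments.tsv   — otu_id, semicolon-joined hit species, identity %, bp,
                      taxon group.
* catch.csv         — classification, rank, biomass_kg.
* echogram_<id>.csv — long form: time_s, depth_m, sv_db, valid,
                      bottom_depth_m.
* config.yaml       — the generator configuration.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .acoustics import Echogram
from .catch import CatchRecord
from .filtering import AssignmentRecord
from .quantify import ReadTable, SampleMeta, StandardSpec
from .synthio import Station, SurveyBundle, SurveyConfig


def write_read_table(table: ReadTable, reads_path: Path, standards_path: Path,
                     spec: StandardSpec) -> None:
    table.counts.to_csv(reads_path)
    pd.DataFrame(spec.entries, columns=["standard_id", "copies_per_ul"]).to_csv(
        standards_path, index=False
    )


def read_read_table(reads_path: Path, standards_path: Path
                    ) -> tuple[ReadTable, StandardSpec]:
    counts = pd.read_csv(reads_path, index_col="sample_id")
    std = pd.read_csv(standards_path)
    spec = StandardSpec(
        tuple(zip(std["standard_id"], std["copies_per_ul"].astype(float)))
    )
    return ReadTable(counts, spec.ids), spec


def write_metadata(metas: Sequence[SampleMeta], path: Path) -> None:
    pd.DataFrame([dataclasses.asdict(m) for m in metas]).to_csv(path, index=False)


def read_metadata(path: Path) -> list[SampleMeta]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        SampleMeta(
            sample_id=str(r.sample_id), station_id=str(r.station_id),
            distance_m=float(r.distance_m), depth_layer=str(r.depth_layer),
            replicate=int(r.replicate),
            filtered_volume_ml=float(r.filtered_volume_ml),
            elution_volume_ul=float(r.elution_volume_ul),
            sampling_time=str(r.sampling_time),
            is_control=bool(r.is_control) if str(r.is_control) not in ("", "False")
            else False,
        )
        for r in df.itertuples()
    ]


def write_assignments(records: Sequence[AssignmentRecord], path: Path) -> None:
    pd.DataFrame(
        {
            "otu_id": [r.otu_id for r in records],
            "hit_species": [";".join(r.hit_species) for r in records],
            "identity_pct": [r.identity_pct for r in records],
            "aln_length": [r.aln_length for r in records],
            "taxon_group": [r.taxon_group for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_assignments(path: Path) -> list[AssignmentRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        AssignmentRecord(
            otu_id=str(r.otu_id),
            hit_species=tuple(str(r.hit_species).split(";")),
            identity_pct=float(r.identity_pct),
            aln_length=int(r.aln_length),
            taxon_group=str(r.taxon_group),
        )
        for r in df.itertuples()
    ]


def write_catch(records: Sequence[CatchRecord], path: Path) -> None:
    pd.DataFrame(
        {
            "classification": [r.name for r in records],
            "rank": [r.rank for r in records],
            "biomass_kg": [r.biomass_kg for r in records],
        }
    ).to_csv(path, index=False)


def read_catch(path: Path) -> list[CatchRecord]:
    df = pd.read_csv(path)
    return [
        CatchRecord(str(r.classification), str(r.rank), float(r.biomass_kg))
        for r in df.itertuples()
    ]


def write_echogram(eg: Echogram, path: Path) -> None:
    t_idx, d_idx = np.meshgrid(
        np.arange(len(eg.times)), np.arange(len(eg.depths)), indexing="ij"
    )
    bottom = (
        eg.bottom_depth[t_idx.ravel()]
        if eg.bottom_depth is not None
        else np.full(t_idx.size, np.nan)
    )
    pd.DataFrame(
        {
            "time_s": eg.times[t_idx.ravel()],
            "depth_m": eg.depths[d_idx.ravel()],
            "sv_db": eg.sv_db.ravel(),
            "valid": eg.valid.ravel(),
            "bottom_depth_m": bottom,
        }
    ).to_csv(path, index=False)


def read_echogram(path: Path, station_id: str = "") -> Echogram:
    df = pd.read_csv(path)
    times = np.unique(df["time_s"].to_numpy())
    depths = np.unique(df["depth_m"].to_numpy())
    shape = (len(times), len(depths))
    pivot = df.sort_values(["time_s", "depth_m"])
    sv = pivot["sv_db"].to_numpy().reshape(shape)
    valid = pivot["valid"].to_numpy().astype(bool).reshape(shape)
    bottom = pivot.groupby("time_s")["bottom_depth_m"].first().to_numpy()
    if np.isnan(bottom).all():
        bottom = None
    return Echogram(times, depths, sv, valid, bottom, station_id)


def write_config(config: SurveyConfig, path: Path) -> None:
    d = dataclasses.asdict(config)
    d["stations"] = [dataclasses.asdict(s) for s in config.stations]
    d["standards"] = [list(e) for e in config.standards.entries]
    d["depth_pref_probs"] = list(config.depth_pref_probs)
    path.write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")


def read_config(path: Path) -> SurveyConfig:
    d = yaml.safe_load(path.read_text(encoding="utf-8"))
    d["stations"] = tuple(Station(**s) for s in d["stations"])
    d["standards"] = StandardSpec(tuple((sid, float(c)) for sid, c in d["standards"]))
    d["depth_pref_probs"] = tuple(d["depth_pref_probs"])
    return SurveyConfig(**d)


def write_bundle(bundle: SurveyBundle, out_dir: Path) -> None:
    """Write every table of a survey bundle under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_read_table(bundle.read_table, out_dir / "reads.csv",
                     out_dir / "standards.csv", bundle.standards)
    write_metadata(bundle.metadata, out_dir / "metadata.csv")
    write_assignments(bundle.assignments, out_dir / "assignments.tsv")
    write_catch(bundle.catch, out_dir / "catch.csv")
    for st_id, eg in bundle.echograms.items():
        write_echogram(eg, out_dir / f"echogram_{st_id}.csv")
    bundle.truth.to_csv(out_dir / "truth_copies_per_ml.csv")
    bundle.slopes.rename_axis("sample_id").to_csv(out_dir / "true_slopes.csv")
    write_config(bundle.config, out_dir / "config.yaml")
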