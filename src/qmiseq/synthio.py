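"""Synthetic survey generator.

Emulates a reef-centred eDNA + acoustics survey: eight stations along a
transect through a focal artificial reef (plus a second reef found mid
survey), two depth layers × two replicate filtrations per station, a
five-point internal-standard ladder spiked into every library, and a field
negative control that carries standards but no fish DNA (33 libraries in
all).  The forward model is:

* true concentration (copies/ml water) of species *i* in sample *s*:
  μ_si = baseline_i × exp(−decay × reefassoc_i × log(d_s + 0.1)) ×
  depth-preference multiplier × lognormal noise;
* extract concentration (copies/µl) = μ_si × filtered_ml / elution_µl;
* reads r_si ~ Poisson(slope_s × copies/µl), with the sample slope drawn
  log-normally (every library amplifies differently — that is the reason
  the spike-in calibration exists); standards get r_sk ~ Poisson(slope_s ×
  c_k) for the ladder concentrations c_k.  A multinomial option instead
  conditions on a target total per sample, stressing compositionality;
* per-station echograms whose mean dB level tracks 10·log10 of the summed
  fish concentration at the station, plus Gaussian dB noise;
* a set-net catch record drawn from the same species pool with biomass
  proportional to summed density times lognormal error, including records
  logged above species rank and one congeneric pair the marker cannot
  separate.

Everything is driven by one integer seed; two runs with the same config are
bitwise identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .acoustics import Echogram
from .catch import CatchRecord
from .filtering import AssignmentRecord
from .quantify import (
    DEFAULT_STANDARD_LADDER,
    ReadTable,
    SampleMeta,
    StandardSpec,
)


@dataclass(frozen=True)
class Station:
    station_id: str
    signed_distance_m: float  # signed along-transect offset from the focal reef
    is_reef: bool = False

    @property
    def distance_m(self) -> float:
        return abs(self.signed_distance_m)


#: Transect layout: focal reef at 0 m, second reef at 220 m, and paired
#: stations 150/500/750 m to either side.
DEFAULT_STATIONS: tuple[Station, ...] = (
    Station("AR1", 0.0, is_reef=True),
    Station("AR2", 220.0, is_reef=True),
    Station("E150", 150.0),
    Station("E500", 500.0),
    Station("E750", 750.0),
    Station("W150", -150.0),
    Station("W500", -500.0),
    Station("W750", -750.0),
)


@dataclass(frozen=True)
class SurveyConfig:
    """Knobs of the forward model; defaults emulate the transect design."""

    stations: tuple[Station, ...] = DEFAULT_STATIONS
    n_replicates: int = 2
    n_species: int = 20
    baseline_log_mean: float = math.log(2.5)  # copies/ml, lognormal across species
    baseline_log_sd: float = 1.0
    reef_assoc_max: float = 1.5  # per-species coefficient ~ U(0, max) for reef taxa
    reef_assoc_fraction: float = 0.7  # fraction of species that are reef-associated
    decay: float = 0.3  # per unit log(distance + 0.1)
    depth_pref_probs: tuple[float, float, float] = (0.2, 0.5, 0.3)  # middle/bottom/none
    depth_pref_strength: float = 0.6  # log-scale shift toward the preferred layer
    noise_log_sd: float = 0.5  # lognormal sample-level noise on true concentration
    slope_log_mean: float = math.log(200.0)  # reads per (copy/µl)
    slope_log_sd: float = 0.5
    target_reads: int = 65_000  # per-sample total, used by the multinomial model
    read_noise: str = "poisson"  # "poisson" | "multinomial"
    echo_gain_db: float = -75.0
    echo_noise_db_sd: float = 3.0
    filtered_volume_ml: float = 2000.0
    elution_volume_ul: float = 100.0
    standards: StandardSpec = field(default_factory=StandardSpec)
    include_negative_control: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        zero = [s for s in self.stations if s.signed_distance_m == 0.0]
        if len(zero) != 1:
            raise ValueError("exactly one station must sit at 0 m (the focal reef)")
        if self.n_replicates < 1 or self.n_species < 1:
            raise ValueError("replicates and species pool must be positive")
        if self.slope_log_sd < 0 or self.noise_log_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.target_reads <= 0:
            raise ValueError("target_reads must be positive")
        if self.read_noise not in ("poisson", "multinomial"):
            raise ValueError(f"unknown read-noise model {self.read_noise!r}")
        if not math.isclose(sum(self.depth_pref_probs), 1.0):
            raise ValueError("depth preference probabilities must sum to 1")


@dataclass
class SurveyBundle:
    read_table: ReadTable
    standards: StandardSpec
    assignments: list[AssignmentRecord]
    metadata: list[SampleMeta]
    catch: list[CatchRecord]
    echograms: dict[str, Echogram]
    truth: pd.DataFrame  # samples × species, true copies/ml water
    slopes: pd.Series  # true per-sample amplification slopes
    species_info: pd.DataFrame  # per-species generator parameters
    config: SurveyConfig


def _species_pool(config: SurveyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-species parameters and names.

    Species 0 and 1 share a genus (the marker-indistinguishable pair); all
    other species get their own genus, so their OTUs resolve to species rank.
    """
    n = config.n_species
    names, genera = [], []
    for i in range(n):
        if i == 0:
            genus, epithet = "Geminus", "primus"
        elif i == 1:
            genus, epithet = "Geminus", "secundus"
        else:
            genus, epithet = f"Genus{i:02d}", f"species{i:02d}"
        names.append(f"{genus} {epithet}")
        genera.append(genus)
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)
    reef_assoc = np.where(
        rng.random(n) < config.reef_assoc_fraction,
        rng.uniform(0.0, config.reef_assoc_max, n),
        0.0,
    )
    pref = rng.choice(["middle", "bottom", "none"], size=n, p=config.depth_pref_probs)
    habitat = np.where(pref == "middle", "pelagic", "demersal")
    return pd.DataFrame(
        {
            "species": names,
            "genus": genera,
            "baseline_copies_ml": baseline,
            "reef_assoc": reef_assoc,
            "depth_pref": pref,
            "habitat": habitat,
        }
    ).set_index("species")


def _depth_multiplier(pref: str, layer: str, strength: float) -> float:
    if pref == "none":
        return 1.0
    return math.exp(strength if pref == layer else -strength)


def expected_concentration(
    species: pd.DataFrame, station: Station, layer: str, config: SurveyConfig
) -> np.ndarray:
    """Noise-free true copies/ml for every species at a station × layer."""
    logd = math.log(station.distance_m + 0.1)
    mult = np.array(
        [_depth_multiplier(p, layer, config.depth_pref_strength)
         for p in species["depth_pref"]]
    )
    return (
        species["baseline_copies_ml"].to_numpy()
        * np.exp(-config.decay * species["reef_assoc"].to_numpy() * logd)
        * mult
    )


def generate_survey(config: SurveyConfig | None = None) -> SurveyBundle:
    """Generate a complete synthetic survey bundle (deterministic per seed)."""
    config = config or SurveyConfig()
    rng = np.random.default_rng(config.seed)
    species = _species_pool(config, rng)
    n_sp = len(species)
    vol_factor = config.filtered_volume_ml / config.elution_volume_ul

    sample_rows = []
    metas: list[SampleMeta] = []
    truth_rows: dict[str, np.ndarray] = {}
    slopes: dict[str, float] = {}
    station_density: dict[str, float] = {}
    sampling_time = {}
    t0 = 0.0
    for st in config.stations:
        sampling_time[st.station_id] = t0
        t0 += 1800.0  # stations visited half an hour apart
        dens = 0.0
        for layer in ("middle", "bottom"):
            for rep in range(1, config.n_replicates + 1):
                sid = f"{st.station_id}_{layer}_r{rep}"
                mu = expected_concentration(species, st, layer, config)
                if config.noise_log_sd > 0:
                    mu = mu * rng.lognormal(0.0, config.noise_log_sd, n_sp)
                slope = float(
                    rng.lognormal(config.slope_log_mean, config.slope_log_sd)
                )
                truth_rows[sid] = mu
                slopes[sid] = slope
                dens += float(mu.sum())
                metas.append(
                    SampleMeta(
                        sample_id=sid,
                        station_id=st.station_id,
                        distance_m=st.distance_m,
                        depth_layer=layer,
                        replicate=rep,
                        filtered_volume_ml=config.filtered_volume_ml,
                        elution_volume_ul=config.elution_volume_ul,
                        sampling_time=str(sampling_time[st.station_id]),
                    )
                )
                sample_rows.append(sid)
        station_density[st.station_id] = dens / (2 * config.n_replicates)

    if config.include_negative_control:
        sid = "FNC"
        truth_rows[sid] = np.zeros(n_sp)
        slopes[sid] = float(rng.lognormal(config.slope_log_mean, config.slope_log_sd))
        metas.append(
            SampleMeta(
                sample_id=sid, station_id="FNC", distance_m=0.0,
                depth_layer="bottom", replicate=1,
                filtered_volume_ml=config.filtered_volume_ml,
                elution_volume_ul=config.elution_volume_ul,
                sampling_time="", is_control=True,
            )
        )
        sample_rows.append(sid)

    truth = pd.DataFrame(truth_rows, index=species.index).T
    truth.index.name = "sample_id"

    # species → OTUs: the congeneric pair collapses onto one OTU
    otu_of_species = {}
    otu_ids = []
    for i, sp in enumerate(species.index):
        if i == 1:
            otu_of_species[sp] = "OTU_0001"
            continue
        otu = f"OTU_{i + 1:04d}" if i > 1 else "OTU_0001"
        otu_of_species[sp] = otu
        otu_ids.append(otu)

    std_ids = list(config.standards.ids)
    std_copies = config.standards.copies
    counts = pd.DataFrame(0, index=sample_rows, columns=otu_ids + std_ids, dtype=int)
    for sid in sample_rows:
        slope = slopes[sid]
        lam_species = truth.loc[sid].to_numpy() * vol_factor * slope
        lam_otu = np.zeros(len(otu_ids))
        for sp, lam in zip(species.index, lam_species):
            lam_otu[otu_ids.index(otu_of_species[sp])] += lam
        lam_std = slope * std_copies
        if config.read_noise == "poisson":
            counts.loc[sid, otu_ids] = rng.poisson(lam_otu)
            counts.loc[sid, std_ids] = rng.poisson(lam_std)
        else:
            lam_all = np.concatenate([lam_otu, lam_std])
            total = lam_all.sum()
            if total > 0:
                counts.loc[sid] = rng.multinomial(
                    config.target_reads, lam_all / total
                )
            else:  # only standards can receive reads
                draw = rng.multinomial(config.target_reads, lam_std / lam_std.sum())
                counts.loc[sid, std_ids] = draw
    counts.index.name = "sample_id"
    read_table = ReadTable(counts, tuple(std_ids))

    assignments = []
    for i, sp in enumerate(species.index):
        if i == 1:
            continue  # folded into OTU_0001
        otu = otu_of_species[sp]
        hits = (species.index[0], species.index[1]) if i == 0 else (sp,)
        assignments.append(
            AssignmentRecord(
                otu_id=otu,
                hit_species=hits,
                identity_pct=float(np.round(rng.uniform(98.6, 100.0), 1)),
                aln_length=172,
                taxon_group="bony_fish",
            )
        )

    catch = generate_catch_record(
        truth, config, n_classifications=min(41, n_sp + 3), rng=rng
    )

    echograms = {
        st.station_id: _station_echogram(
            st, station_density[st.station_id],
            sampling_time[st.station_id], config, rng,
        )
        for st in config.stations
    }

    return SurveyBundle(
        read_table=read_table,
        standards=config.standards,
        assignments=assignments,
        metadata=metas,
        catch=catch,
        echograms=echograms,
        truth=truth,
        slopes=pd.Series(slopes, name="slope"),
        species_info=species,
        config=config,
    )


def _station_echogram(
    station: Station,
    mean_density: float,
    t_start: float,
    config: SurveyConfig,
    rng: np.random.Generator,
) -> Echogram:
    """12 minutes of pings whose dB level tracks the station's fish density."""
    times = t_start + np.arange(0.0, 720.0, 5.0)
    depths = np.arange(2.0, 81.0, 2.0)
    base_db = config.echo_gain_db + 10.0 * math.log10(max(mean_density, 1e-12))
    sv_db = base_db + rng.normal(0.0, config.echo_noise_db_sd,
                                 (len(times), len(depths)))
    valid = np.ones_like(sv_db, dtype=bool)
    bottom = np.full(len(times), 80.0)
    return Echogram(times, depths, sv_db, valid, bottom, station.station_id)


def generate_catch_record(
    truth: pd.DataFrame,
    config: SurveyConfig,
    n_classifications: int = 41,
    n_above_species: int = 3,
    n_indistinguishable_pairs: int = 1,
    biomass_scale_kg: float = 1000.0,
    biomass_log_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[CatchRecord]:
    """Set-net catch record drawn from the simulated species pool.

    Species-rank records have biomass proportional to the species' summed
    true density times lognormal error; ``n_above_species`` records are
    logged at genus/family rank, and the congeneric pair (one pair per
    ``n_indistinguishable_pairs``) is always included, since the marker
    cannot separate it.  Requesting more classifications than the pool can
    furnish raises.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    species = list(truth.columns)
    if not species:
        return []
    density = truth.sum(axis=0)

    n_species_records = n_classifications - n_above_species
    if n_species_records > len(species):
        raise ValueError(
            f"cannot draw {n_species_records} species records from a pool of "
            f"{len(species)}"
        )
    pair = species[: 2 * n_indistinguishable_pairs]
    others = [s for s in species if s not in pair]
    extra = list(
        rng.choice(others, size=n_species_records - len(pair), replace=False)
    )
    chosen = pair + extra

    records = []
    for sp in chosen:
        biomass = float(
            biomass_scale_kg * density[sp] * rng.lognormal(0.0, biomass_log_sd)
        )
        records.append(CatchRecord(sp, "species", round(biomass, 1)))
    for j in range(n_above_species):
        rank = "genus" if j == 0 else "family"
        name = f"CatchGenus{j}" if rank == "genus" else f"Catchfamilidae{j}"
        records.append(
            CatchRecord(name, rank, round(float(rng.lognormal(3.0, 1.0)), 1))
        )
    return records
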