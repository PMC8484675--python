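"""Detection-rate accounting against a set-net catch record.

The reference survey is a stationary coastal set net whose monthly catch is
recorded as (classification, rank, biomass).  The metabarcoding detection
rate is the fraction of net-caught *species* that the eDNA survey also
detected, after removing records the comparison cannot score fairly:
records logged above species rank, and species belonging to pairs the
marker cannot distinguish.  An optional biomass floor restricts the
denominator to species caught in non-trivial amounts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .filtering import TaxonLabel


@dataclass(frozen=True)
class CatchRecord:
    name: str
    rank: str  # "species" | "genus" | "family"
    biomass_kg: float

    def __post_init__(self) -> None:
        if self.rank not in ("species", "genus", "family"):
            raise ValueError(f"unknown rank {self.rank!r}")
        if not math.isfinite(self.biomass_kg) or self.biomass_kg < 0:
            raise ValueError("biomass must be finite and non-negative")


@dataclass
class DetectionReport:
    n_catch_total: int
    n_excluded_rank: int
    n_excluded_ambiguous: int
    n_excluded_biomass: int
    denominator: int
    n_detected: int
    rate: float  # proportion in [0, 1]; NaN when the denominator is empty
    rate_defined: bool
    detected_flags: dict[str, bool] = field(default_factory=dict)


def _normalise_detected(
    detected_taxa: Iterable[TaxonLabel | str],
) -> tuple[set[str], set[str]]:
    """Split the detected set into exact species names and spp.-covered genera."""
    species: set[str] = set()
    genera: set[str] = set()
    for t in detected_taxa:
        if isinstance(t, TaxonLabel):
            name, rank = t.name, t.rank
        else:
            name, rank = t, ("genus_spp" if t.endswith(" spp.") else "species")
        if rank == "genus_spp":
            genera.add(name.removesuffix(" spp."))
        elif rank == "species":
            species.add(name)
        # higher-rank labels cannot vouch for any particular species
    return species, genera


def detection_rate(
    catch: Sequence[CatchRecord],
    detected_taxa: Iterable[TaxonLabel | str],
    ambiguous_pairs: Sequence[Iterable[str]] = (),
    min_biomass_kg: float = 0.0,
) -> DetectionReport:
    """Score metabarcoding detections against the catch record.

    Exclusions, in order: catch records above species rank; species that
    belong to a marker-indistinguishable set in ``ambiguous_pairs``; then
    species below ``min_biomass_kg``.  A species counts as detected when its
    exact name is in the detected set, or a "Genus spp." label covering its
    genus is.  The biomass floor changes only denominator membership, never
    the per-species detected flag.
    """
    species_set, genus_set = _normalise_detected(detected_taxa)
    ambiguous = set().union(*[set(p) for p in ambiguous_pairs]) if ambiguous_pairs else set()

    n_total = len(catch)
    n_rank = sum(1 for r in catch if r.rank != "species")
    species_records = [r for r in catch if r.rank == "species"]
    n_ambig = sum(1 for r in species_records if r.name in ambiguous)
    eligible = [r for r in species_records if r.name not in ambiguous]
    n_biomass = sum(1 for r in eligible if r.biomass_kg < min_biomass_kg)
    scored = [r for r in eligible if r.biomass_kg >= min_biomass_kg]

    flags = {
        r.name: (r.name in species_set or r.name.split()[0] in genus_set)
        for r in eligible
    }
    n_detected = sum(1 for r in scored if flags[r.name])
    denominator = len(scored)
    if denominator == 0:
        return DetectionReport(
            n_total, n_rank, n_ambig, n_biomass, 0, 0,
            float("nan"), False, flags,
        )
    return DetectionReport(
        n_total, n_rank, n_ambig, n_biomass, denominator, n_detected,
        n_detected / denominator, True, flags,
    )
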