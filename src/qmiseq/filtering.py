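"""Post-assignment OTU filtering and taxonomy collapsing.

Reads have already been denoised upstream and matched against a reference
database; what arrives here is one summary record per OTU (best-hit species
list, % identity, alignment length, coarse taxon group).  This module applies
the standard screens for a fish 12S amplicon survey — drop non-fish hits,
weak or short alignments, per-sample low-frequency noise, and known
contaminant taxa — and collapses multi-species hits to the finest rank the
marker can support, using a regional species checklist to rescue genera with
a single local representative.

The mandated order of operations is: BLAST-style filters → taxonomy
collapsing → per-sample noise filter → contaminant removal
(:func:`filter_pipeline` enforces it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .quantify import ReadTable

logger = logging.getLogger(__name__)

TAXON_GROUPS = ("bony_fish", "shark", "ray", "other")

#: Taxa that cannot plausibly occur in the study area and are common food
#: items — treated as lab/kitchen contamination and removed outright.
DEFAULT_CONTAMINANT_BLOCKLIST = frozenset(
    {"Oncorhynchus nerka", "Gadus chalcogrammus", "Trachurus trachurus"}
)

MIN_IDENTITY_PCT = 98.5
MAX_DROPPED_ALN_LENGTH = 150  # alignments ≤ this are dropped (amplicon ≈ 172 bp)
NOISE_FRACTION = 0.0005  # per-sample relative-abundance noise floor (0.05%)


@dataclass(frozen=True)
class AssignmentRecord:
    """Per-OTU summary of the database search."""

    otu_id: str
    hit_species: tuple[str, ...]
    identity_pct: float
    aln_length: int
    taxon_group: str = "bony_fish"

    def __post_init__(self) -> None:
        if not self.hit_species:
            raise ValueError("hit list must be non-empty")
        if not 0 <= self.identity_pct <= 100:
            raise ValueError("identity must be in [0, 100]")
        if self.aln_length <= 0:
            raise ValueError("alignment length must be positive")
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(f"unknown taxon group {self.taxon_group!r}")


@dataclass(frozen=True)
class TaxonLabel:
    """Final label for an OTU at the finest defensible rank."""

    otu_id: str
    name: str
    rank: str  # "species" | "genus_spp" | "higher"

    def __post_init__(self) -> None:
        if self.rank not in ("species", "genus_spp", "higher"):
            raise ValueError(f"unknown rank {self.rank!r}")
        if self.rank == "genus_spp" and not self.name.endswith(" spp."):
            raise ValueError("genus-level labels must end in ' spp.'")


class RegionalChecklist:
    """Genus → set of species known from the study region.

    Used to re-assign a multi-species hit back to species rank when only one
    member of the genus occurs locally.
    """

    def __init__(self, species: Iterable[str]):
        self._by_genus: dict[str, set[str]] = {}
        for sp in species:
            genus = sp.split()[0]
            self._by_genus.setdefault(genus, set()).add(sp)

    def species_in_genus(self, genus: str) -> frozenset[str]:
        return frozenset(self._by_genus.get(genus, set()))

    def __contains__(self, species: str) -> bool:
        return species in self._by_genus.get(species.split()[0], set())


def apply_blast_filters(
    records: Sequence[AssignmentRecord],
    min_identity_pct: float = MIN_IDENTITY_PCT,
    max_dropped_aln_length: int = MAX_DROPPED_ALN_LENGTH,
) -> tuple[list[AssignmentRecord], list[tuple[AssignmentRecord, str]]]:
    """Partition records into kept and (dropped, reason) lists.

    Drop rules: non-fish taxon group; identity strictly below the floor
    (an exact 98.5% hit is kept); alignment length ≤ the cutoff.
    """
    kept: list[AssignmentRecord] = []
    dropped: list[tuple[AssignmentRecord, str]] = []
    for rec in records:
        if rec.taxon_group == "other":
            dropped.append((rec, "non_fish"))
        elif rec.identity_pct < min_identity_pct:
            dropped.append((rec, "low_identity"))
        elif rec.aln_length <= max_dropped_aln_length:
            dropped.append((rec, "short_alignment"))
        else:
            kept.append(rec)
    return kept, dropped


def _genus(name: str) -> str:
    return name.split()[0]


def collapse_assignments(
    record: AssignmentRecord,
    checklist: RegionalChecklist,
    genus_to_family: Mapping[str, str] | None = None,
) -> TaxonLabel:
    """Collapse a hit list to the finest rank the marker supports.

    * one hit → species rank (warn if absent from the regional checklist);
    * several hits, one genus → "Genus spp.", unless the checklist holds
      exactly one regional species of that genus, which is then assigned
      at species rank;
    * several genera → higher rank (the shared family when a genus→family
      map is supplied and resolves to one family, otherwise a composite
      label naming the genera).
    """
    hits = record.hit_species
    if len(set(hits)) == 1:
        sp = hits[0]
        if sp not in checklist:
            logger.warning(
                "OTU %s assigned to %s, which is not on the regional checklist",
                record.otu_id, sp,
            )
        return TaxonLabel(record.otu_id, sp, "species")

    genera = {_genus(h) for h in hits}
    if len(genera) == 1:
        genus = next(iter(genera))
        regional = checklist.species_in_genus(genus)
        if len(regional) == 1:
            return TaxonLabel(record.otu_id, next(iter(regional)), "species")
        return TaxonLabel(record.otu_id, f"{genus} spp.", "genus_spp")

    if genus_to_family is not None:
        families = {genus_to_family[g] for g in genera if g in genus_to_family}
        if len(families) == 1 and all(g in genus_to_family for g in genera):
            return TaxonLabel(record.otu_id, next(iter(families)), "higher")
    return TaxonLabel(record.otu_id, "/".join(sorted(genera)), "higher")


def noise_filter(
    read_table: ReadTable,
    noise_fraction: float = NOISE_FRACTION,
    include_standards_in_total: bool = False,
    iterative: bool = False,
) -> ReadTable:
    """Zero out per-sample low-frequency fish OTUs (strictly below 0.05%).

    The denominator is the sample's total fish reads (standards are carrier,
    not biological signal; set ``include_standards_in_total`` to count them).
    The comparison is strict: an OTU at exactly the threshold is kept.
    Standards are never modified.  The single-pass form is idempotent;
    ``iterative=True`` re-thresholds until a fixed point.
    """
    counts = read_table.counts.copy()
    fish_ids = read_table.fish_ids
    while True:
        fish = counts[fish_ids]
        totals = fish.sum(axis=1)
        if include_standards_in_total:
            totals = totals + counts[list(read_table.standard_ids)].sum(axis=1)
        threshold = noise_fraction * totals
        below = fish.lt(threshold, axis=0) & (fish > 0)
        if not below.to_numpy().any():
            break
        counts.loc[:, fish_ids] = fish.where(~below, 0)
        if not iterative:
            break
    return ReadTable(counts, tuple(read_table.standard_ids))


def remove_contaminants(
    read_table: ReadTable,
    blocklist: frozenset[str] | set[str] = DEFAULT_CONTAMINANT_BLOCKLIST,
    labels: Mapping[str, TaxonLabel] | None = None,
) -> ReadTable:
    """Drop OTU columns whose assigned taxon is on the contaminant blocklist.

    Matching is by assigned label when ``labels`` is given, otherwise by the
    OTU column name itself.  Absent taxa are a no-op.
    """
    def name_of(otu: str) -> str:
        if labels is not None and otu in labels:
            return labels[otu].name
        return otu

    drop = [otu for otu in read_table.fish_ids if name_of(otu) in blocklist]
    if not drop:
        return read_table.copy()
    counts = read_table.counts.drop(columns=drop)
    return ReadTable(counts, tuple(read_table.standard_ids))


def classify_habitat(
    label: TaxonLabel,
    habitat_map: Mapping[str, str],
    default: str = "demersal",
) -> str:
    """Demersal/pelagic lookup (a stand-in for a life-history database).

    Unknown taxa fall back to ``default`` with a warning so aggregate
    demersal + pelagic totals always partition the total.
    """
    habitat = habitat_map.get(label.name)
    if habitat is None:
        logger.warning("no habitat entry for %s; defaulting to %s", label.name, default)
        return default
    if habitat not in ("demersal", "pelagic"):
        raise ValueError(f"unknown habitat {habitat!r} for {label.name}")
    return habitat


def filter_pipeline(
    read_table: ReadTable,
    records: Sequence[AssignmentRecord],
    checklist: RegionalChecklist,
    blocklist: frozenset[str] | set[str] = DEFAULT_CONTAMINANT_BLOCKLIST,
    genus_to_family: Mapping[str, str] | None = None,
) -> tuple[ReadTable, dict[str, TaxonLabel], pd.DataFrame]:
    """Run the full screen in the mandated order and emit an audit table.

    Order: assignment filters → taxonomy collapsing → per-sample noise
    filter → contaminant removal.  OTUs dropped by the assignment filters
    are removed as columns; noise-filtered cells are zeroed in place.
    Returns the filtered table, the OTU → label map for surviving OTUs, and
    a per-OTU audit DataFrame (status, reason, label, rank).
    """
    kept, dropped = apply_blast_filters(records)
    labels = {r.otu_id: collapse_assignments(r, checklist, genus_to_family) for r in kept}

    audit_rows = []
    for rec, reason in dropped:
        audit_rows.append(
            {"otu_id": rec.otu_id, "status": "dropped", "reason": reason,
             "label": None, "rank": None}
        )

    keep_cols = [o for o in read_table.fish_ids if o in labels]
    counts = read_table.counts[keep_cols + list(read_table.standard_ids)]
    table = noise_filter(ReadTable(counts, tuple(read_table.standard_ids)))
    table = remove_contaminants(table, blocklist, labels)

    contaminated = {
        o for o in keep_cols if labels[o].name in blocklist
    }
    for otu in keep_cols:
        if otu in contaminated:
            audit_rows.append(
                {"otu_id": otu, "status": "dropped", "reason": "contaminant",
                 "label": labels[otu].name, "rank": labels[otu].rank}
            )
        else:
            audit_rows.append(
                {"otu_id": otu, "status": "kept", "reason": None,
                 "label": labels[otu].name, "rank": labels[otu].rank}
            )
    final_labels = {o: labels[o] for o in table.fish_ids}
    audit = pd.DataFrame(audit_rows).set_index("otu_id")
    return table, final_labels, audit
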