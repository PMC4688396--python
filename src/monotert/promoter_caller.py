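"""Promoter hotspot mutation calling from DNA allele depths.

Each line's promoter status is determined from its allele counts at the
catalog of recurrent promoter hotspot substitutions (C228T, C228A, C250T,
C242T/C243T and the rare upstream hotspot). A site with insufficient depth
renders the line UNDETERMINED for promoter analyses — mirroring a cohort in
which only lines with sufficient coverage at all previously defined hotspots
enter the promoter-status comparison. Hotspot mutations are expected to be
mutually exclusive; lines violating this are kept as MUTANT with a
``multi_hit_flag`` and a logged warning rather than dropped, since
exclusivity is an empirical observation, not a filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from .io_model import (
    HotspotCatalog,
    DEFAULT_HOTSPOT_CATALOG,
    PromoterSiteObservation,
    ValidationError,
)

logger = logging.getLogger("monotert")

WILD_TYPE = "WILD_TYPE"
MUTANT = "MUTANT"
INSUFFICIENT = "INSUFFICIENT"
UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class PromoterCallThresholds:
    """Evidence thresholds for a hotspot mutation call.

    ``min_depth`` defines "sufficient coverage" at a hotspot (default 8,
    mirroring the RNA coverage rule for internal consistency); a MUTANT call
    needs ≥``min_alt_reads`` alternate reads at ≥``min_alt_fraction`` of the
    site's depth (defaults echo the anchor-SNP read minimum).
    """

    min_depth: int = 8
    min_alt_reads: int = 3
    min_alt_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValidationError(f"min_depth must be >= 1, got {self.min_depth}")


@dataclass(frozen=True)
class PromoterStatus:
    line_id: str
    status: str
    mutation_label: str = ""
    multi_hit_flag: bool = False

    def __post_init__(self) -> None:
        if (self.status == MUTANT) != bool(self.mutation_label):
            raise ValidationError(
                f"{self.line_id}: mutation_label must be non-empty iff status is MUTANT"
            )


def call_site(
    obs: PromoterSiteObservation,
    t: PromoterCallThresholds,
    catalog: HotspotCatalog = DEFAULT_HOTSPOT_CATALOG,
) -> str:
    """Call one hotspot site: WILD_TYPE, MUTANT, or INSUFFICIENT (low depth)."""
    entry = catalog.get(obs.locus.pos, obs.locus.alt_base)
    if entry is None:
        raise ValidationError(
            f"site {obs.locus.chrom}:{obs.locus.pos} "
            f"{obs.locus.ref_base}>{obs.locus.alt_base} not in hotspot catalog"
        )
    if obs.dna.total < t.min_depth:
        return INSUFFICIENT
    if obs.dna.alt_count >= t.min_alt_reads and obs.dna.alt_fraction >= t.min_alt_fraction:
        return MUTANT
    return WILD_TYPE


def call_line(
    line_id: str,
    site_calls: Mapping[str, str],
    catalog: HotspotCatalog = DEFAULT_HOTSPOT_CATALOG,
) -> PromoterStatus:
    """Combine per-site calls (keyed by hotspot label) into a line status.

    Requires one call per catalog entry. Any INSUFFICIENT site →
    UNDETERMINED; exactly one MUTANT → MUTANT with that label; several
    MUTANT sites → MUTANT with ``multi_hit_flag`` (warning logged; the
    first catalog label is reported); none → WILD_TYPE.
    """
    missing = [lb for lb in catalog.labels if lb not in site_calls]
    if missing:
        raise ValidationError(f"{line_id}: missing site call(s) for hotspot(s) {missing}")
    calls = {lb: site_calls[lb] for lb in catalog.labels}
    for lb, c in calls.items():
        if c not in (WILD_TYPE, MUTANT, INSUFFICIENT):
            raise ValidationError(f"{line_id}: invalid site call {c!r} at {lb}")
    if any(c == INSUFFICIENT for c in calls.values()):
        return PromoterStatus(line_id, UNDETERMINED)
    mutant_labels = [lb for lb, c in calls.items() if c == MUTANT]
    if not mutant_labels:
        return PromoterStatus(line_id, WILD_TYPE)
    if len(mutant_labels) > 1:
        logger.warning(
            "%s: hotspot mutual exclusivity violated (%s); keeping MUTANT with multi_hit_flag",
            line_id, ",".join(mutant_labels),
        )
        return PromoterStatus(line_id, MUTANT, mutant_labels[0], multi_hit_flag=True)
    return PromoterStatus(line_id, MUTANT, mutant_labels[0])


def call_line_from_observations(
    line_id: str,
    observations,
    t: PromoterCallThresholds,
    catalog: HotspotCatalog = DEFAULT_HOTSPOT_CATALOG,
) -> PromoterStatus:
    """Call a line directly from its promoter-site observations.

    Catalog entries without an observation count as INSUFFICIENT (no
    coverage); duplicate observations of the same entry raise.
    """
    site_calls: dict[str, str] = {}
    for obs in observations:
        entry = catalog.get(obs.locus.pos, obs.locus.alt_base)
        if entry is None:
            raise ValidationError(
                f"{line_id}: observation at {obs.locus.chrom}:{obs.locus.pos} "
                f"{obs.locus.ref_base}>{obs.locus.alt_base} not in hotspot catalog"
            )
        if entry.label in site_calls:
            raise ValidationError(f"{line_id}: duplicate observation for hotspot {entry.label}")
        site_calls[entry.label] = call_site(obs, t, catalog)
    for lb in catalog.labels:
        site_calls.setdefault(lb, INSUFFICIENT)
    return call_line(line_id, site_calls, catalog)
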