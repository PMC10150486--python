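"""Strain-sharing baselines: popANI and private marker-allele tracking.

Both estimators operate on allele-count panels rather than read pileups, so
they are re-specifications of the original tools' logic at the count level:

* popANI — for each species, sites covered at >= ``min_depth`` in both
  samples are compared; a site is a population substitution when the two
  samples' detected-allele sets are disjoint.  Per-contig popANI is
  ``1 - substitutions / compared sites``; the species value is the unweighted
  mean over contigs.  Two samples whose popANI reaches 99.999% are read as
  carrying the same strain, and the fraction of a sink's species above that
  threshold is the popANI-based sharing estimate.

* marker alleles — an allele is considered in a sample when site depth
  >= 30 and the allele carries >= 10% of reads; it is a private marker when
  absent (< 3 reads by default) from every background sample.  A dyad shares
  a strain for a species when shared markers make up at least 5% of the
  dyad's marker alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .panel import AlleleCountPanel

logger = logging.getLogger(__name__)

__all__ = [
    "PopAniResult",
    "MarkerAlleleReport",
    "MarkerSharingSummary",
    "compute_popani",
    "shared_species_fraction",
    "find_marker_alleles",
    "marker_sharing_calls",
]

POPANI_STRAIN_THRESHOLD = 0.99999


@dataclass
class PopAniResult:
    species_id: str
    per_contig_popani: dict[str, float]
    species_popani: float  # unweighted mean over contigs
    n_compared_sites: int


@dataclass
class MarkerAlleleReport:
    """Per-species tallies of private marker alleles for one focal/partner pair."""

    species_id: str
    infant_only: int
    mother_only: int
    shared: int

    @property
    def total_markers(self) -> int:
        return self.infant_only + self.mother_only + self.shared

    @property
    def total_sharing(self) -> float | None:
        d = self.total_markers
        return self.shared / d if d > 0 else None

    @property
    def infant_proportion_shared(self) -> float | None:
        d = self.infant_only + self.shared
        return self.shared / d if d > 0 else None


@dataclass
class MarkerSharingSummary:
    per_species_shared: dict[str, bool | None]  # None = no-call (no markers)
    fraction_species_shared: float | None
    pooled_total_sharing: float | None
    pooled_infant_proportion_shared: float | None


# -------------------------------------------------------------------- popANI
def compute_popani(
    panel: AlleleCountPanel,
    sample_a: str,
    sample_b: str,
    min_depth: int = 5,
    min_allele_freq: float = 0.05,
) -> list[PopAniResult]:
    """Population ANI between two samples, per species.

    An allele is detected in a sample when it has >= 1 read and a within-
    sample frequency >= ``min_allele_freq``.  Species without any site covered
    at ``min_depth`` in both samples are omitted from the result.
    """
    ref_a, alt_a = panel.counts_for(sample_a)
    ref_b, alt_b = panel.counts_for(sample_b)
    depth_a = ref_a + alt_a
    depth_b = ref_b + alt_b
    compared = (depth_a >= min_depth) & (depth_b >= min_depth)

    def present(count, depth):
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(depth > 0, count / np.maximum(depth, 1), 0.0)
        return (count >= 1) & (freq >= min_allele_freq)

    share = (present(ref_a, depth_a) & present(ref_b, depth_b)) | (
        present(alt_a, depth_a) & present(alt_b, depth_b)
    )
    substitution = compared & ~share

    results: list[PopAniResult] = []
    keys = panel.keys
    for species, sp_idx in keys.groupby("species_id", sort=True).indices.items():
        sp_compared = compared[sp_idx]
        if not sp_compared.any():
            logger.info(
                "popANI undefined for %s: no site covered >= %dx in both %s and %s",
                species, min_depth, sample_a, sample_b,
            )
            continue
        per_contig: dict[str, float] = {}
        contigs = keys["contig_id"].to_numpy()[sp_idx]
        for contig in np.unique(contigs):
            c_idx = sp_idx[contigs == contig]
            n_cmp = int(compared[c_idx].sum())
            if n_cmp == 0:
                continue
            n_sub = int(substitution[c_idx].sum())
            per_contig[str(contig)] = 1.0 - n_sub / n_cmp
        results.append(
            PopAniResult(
                species_id=str(species),
                per_contig_popani=per_contig,
                species_popani=float(np.mean(list(per_contig.values()))),
                n_compared_sites=int(sp_compared.sum()),
            )
        )
    return results


def shared_species_fraction(
    results: list[PopAniResult], threshold: float = POPANI_STRAIN_THRESHOLD
) -> float:
    """Fraction of species (with a defined popANI) at or above the strain threshold."""
    if not results:
        raise ValueError("no species with a defined popANI result")
    n_shared = sum(r.species_popani >= threshold for r in results)
    return n_shared / len(results)


# ------------------------------------------------------------- marker alleles
def find_marker_alleles(
    panel: AlleleCountPanel,
    focal_sample: str,
    partner_sample: str,
    background_samples: list[str],
    min_depth: int = 30,
    min_freq: float = 0.10,
    absence_max_reads: int = 3,
    scaled_absence: bool = False,
) -> list[MarkerAlleleReport]:
    """Tally private marker alleles per species for a focal/partner pair.

    An allele is *considered* in a sample when the site depth is at least
    ``min_depth`` and the allele is supported by at least ``min_freq`` of the
    reads.  It is *absent* from a sample when it has fewer than
    ``absence_max_reads`` reads (or, with ``scaled_absence``, fewer than
    ``min_freq`` of that sample's site depth).  A considered focal allele
    absent from the partner and from every background sample is a focal-only
    marker; one considered in both focal and partner and absent from all
    background is a shared marker.
    """
    if not background_samples:
        raise ValueError("background_samples must be non-empty")

    def counts(sample):
        ref, alt = panel.counts_for(sample)
        return ref.astype(np.int64), alt.astype(np.int64)

    def considered(ref, alt):
        depth = ref + alt
        ok = depth >= min_depth
        return (
            ok & (ref >= min_freq * depth),
            ok & (alt >= min_freq * depth),
        )

    def absent(ref, alt):
        if scaled_absence:
            depth = ref + alt
            return ref < min_freq * depth, alt < min_freq * depth
        return ref < absence_max_reads, alt < absence_max_reads

    f_ref, f_alt = counts(focal_sample)
    p_ref, p_alt = counts(partner_sample)
    cons_f = considered(f_ref, f_alt)
    cons_p = considered(p_ref, p_alt)
    abs_p = absent(p_ref, p_alt)
    abs_f = absent(f_ref, f_alt)

    bg_absent_ref = np.ones(panel.n_sites, dtype=bool)
    bg_absent_alt = np.ones(panel.n_sites, dtype=bool)
    for sample in background_samples:
        b_ref, b_alt = counts(sample)
        a_ref, a_alt = absent(b_ref, b_alt)
        bg_absent_ref &= a_ref
        bg_absent_alt &= a_alt
    bg_absent = (bg_absent_ref, bg_absent_alt)

    focal_only = np.zeros(panel.n_sites, dtype=np.int64)
    partner_only = np.zeros(panel.n_sites, dtype=np.int64)
    shared = np.zeros(panel.n_sites, dtype=np.int64)
    for a in (0, 1):  # reference allele, alternative allele
        focal_only += (cons_f[a] & abs_p[a] & bg_absent[a]).astype(np.int64)
        partner_only += (cons_p[a] & abs_f[a] & bg_absent[a]).astype(np.int64)
        shared += (cons_f[a] & cons_p[a] & bg_absent[a]).astype(np.int64)

    reports: list[MarkerAlleleReport] = []
    for species, sp_idx in panel.keys.groupby("species_id", sort=True).indices.items():
        reports.append(
            MarkerAlleleReport(
                species_id=str(species),
                infant_only=int(focal_only[sp_idx].sum()),
                mother_only=int(partner_only[sp_idx].sum()),
                shared=int(shared[sp_idx].sum()),
            )
        )
    return reports


def marker_sharing_calls(
    reports: list[MarkerAlleleReport], share_threshold: float = 0.05
) -> MarkerSharingSummary:
    """Per-species strain-sharing calls plus pooled sharing statistics.

    A species shares a strain when its total sharing (shared / all markers)
    is at least ``share_threshold``; species without any marker allele are
    no-calls and excluded from the shared-species fraction.  Pooled
    proportions sum numerators and denominators across species.
    """
    per_species: dict[str, bool | None] = {}
    n_called = n_shared = 0
    tot_shared = tot_markers = tot_infant = 0
    for r in reports:
        ts = r.total_sharing
        per_species[r.species_id] = None if ts is None else ts >= share_threshold
        if ts is not None:
            n_called += 1
            n_shared += ts >= share_threshold
        tot_shared += r.shared
        tot_markers += r.total_markers
        tot_infant += r.infant_only + r.shared
    return MarkerSharingSummary(
        per_species_shared=per_species,
        fraction_species_shared=n_shared / n_called if n_called else None,
        pooled_total_sharing=tot_shared / tot_markers if tot_markers else None,
        pooled_infant_proportion_shared=tot_shared / tot_infant if tot_infant else None,
    )
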