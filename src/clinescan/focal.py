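"""Focal-allele selection for multi-allelic loci.

Every locus is reduced to a single frequency-vs-latitude series by choosing
the allele with the strongest north-south differentiation: sites are split
into northern (> 42 degrees N), central, and southern (< 34 degrees N)
regions, and for each allele the locus is binarised (allele vs rest) and
Weir-Cockerham theta computed over the northern + southern sites only.  The
allele maximising this binarised theta is the focal allele.
"""

from __future__ import annotations

import numpy as np

from .datasets import ClineDataset, PopulationSite
from .stats import wc_fst

NORTH_LATITUDE = 42.0
SOUTH_LATITUDE = 34.0


def assign_regions(
    sites: list[PopulationSite],
    north: float = NORTH_LATITUDE,
    south: float = SOUTH_LATITUDE,
) -> np.ndarray:
    """Label each site 'north' (lat > north), 'south' (lat < south) or 'central'."""
    lat = np.array([s.latitude for s in sites])
    out = np.full(len(sites), "central", dtype=object)
    out[lat > north] = "north"
    out[lat < south] = "south"
    return out


class FocalAlleleError(ValueError):
    """No north/south sites available; designate regions manually."""


def select_focal_allele(
    ds: ClineDataset,
    locus_id: str,
    north: float = NORTH_LATITUDE,
    south: float = SOUTH_LATITUDE,
) -> str:
    """Return the allele id maximising binarised north-vs-south theta.

    Biallelic loci tie exactly (the two alleles are complementary) and the
    first allele in locus order is returned.  Alleles whose binarised theta
    is undefined (e.g. fixed everywhere) are never selected.
    """
    loc = ds.locus(locus_id)
    regions = assign_regions(ds.sites, north, south)
    mask = (regions != "central") & ds.assayed_mask(locus_id)
    if not np.any((regions == "north") & ds.assayed_mask(locus_id)) or not np.any(
        (regions == "south") & ds.assayed_mask(locus_id)
    ):
        raise FocalAlleleError(
            f"locus {locus_id!r}: no assayed northern or southern sites; "
            "designate regions manually via the north/south thresholds"
        )
    c = ds.counts[locus_id][mask]
    best_id, best_theta = None, -np.inf
    for j, aid in enumerate(loc.allele_ids):
        bi = np.stack([c[:, j], c.sum(axis=1) - c[:, j]], axis=1)
        theta = wc_fst(bi)
        if np.isnan(theta):
            continue
        if theta > best_theta + 1e-12:
            best_id, best_theta = aid, theta
    if best_id is None:
        # every allele monomorphic across north+south; fall back to first allele
        best_id = loc.allele_ids[0]
    return best_id


def focal_series(ds: ClineDataset, locus_id: str, allele_id: str):
    """(latitudes, focal-allele counts, sample sizes) over assayed sites."""
    loc = ds.locus(locus_id)
    j = loc.allele_ids.index(allele_id)
    mask = ds.assayed_mask(locus_id)
    lat = ds.latitudes[mask]
    x = ds.counts[locus_id][mask, j].astype(float)
    n = ds.sample_sizes(locus_id)[mask].astype(float)
    return lat, x, n
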