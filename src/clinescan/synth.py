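"""Synthetic transect generators with known ground truth.

These emulate the kind of compiled multi-locus dataset the pipeline targets:
10-80 populations along a latitudinal transect (default 30-45 degrees N,
sampled more densely around 40 degrees N where the cline sits), a chosen
fraction of loci carrying logistic or stepped clines of varying midpoint and
frequency difference, the remainder flat, with binomial sampling noise at a
stated number of allele copies per site.  Every generated locus's parameters
are recorded in a truth table so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datasets import ClineDataset, Locus, PopulationSite


@dataclass
class GeneratorSpec:
    """Ground-truth parameters of a synthetic transect dataset."""

    n_sites: int = 30
    lat_range: tuple[float, float] = (30.0, 45.0)
    n_loci: int = 100
    fraction_clinal: float = 0.5
    midpoint_range: tuple[float, float] = (38.0, 42.0)
    delta_p_range: tuple[float, float] = (0.4, 0.9)
    cline_shape: str = "logistic"  # or "stepped"
    cline_width: float = 3.0  # degrees between the plateaus
    n_per_site: int = 40  # allele copies
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.fraction_clinal <= 1:
            raise ValueError("fraction_clinal must lie in [0, 1]")
        if not 0 < self.delta_p_range[0] <= self.delta_p_range[1] <= 1:
            raise ValueError("delta_p must lie in (0, 1]")
        if self.cline_shape not in ("logistic", "stepped"):
            raise ValueError("cline_shape must be 'logistic' or 'stepped'")


def transect_latitudes(spec: GeneratorSpec) -> np.ndarray:
    """Site latitudes: half spread over the full range, half packed near 40N."""
    lo, hi = spec.lat_range
    n_broad = spec.n_sites // 2
    n_dense = spec.n_sites - n_broad
    broad = np.linspace(lo, hi, n_broad)
    c = min(max(40.0, lo + 1), hi - 1)
    dense = np.linspace(max(lo, c - 3), min(hi, c + 3), n_dense)
    return np.sort(np.concatenate([broad, dense]))


def _cline_profile(lat, shape, midpoint, delta_p, width, direction, base):
    p_low = base
    p_high = base + delta_p
    if direction < 0:
        p_low, p_high = p_high, p_low
    if shape == "logistic":
        # steepness chosen so the central 80% of the transition spans `width`
        s = 2 * np.log(9) / width
        return p_low + (p_high - p_low) * expit(s * (lat - midpoint))
    a, b = midpoint - width / 2, midpoint + width / 2
    return np.interp(lat, [a, b], [p_low, p_high])


def generate_dataset(spec: GeneratorSpec) -> tuple[ClineDataset, pd.DataFrame]:
    """Synthetic ClineDataset plus its truth table.

    Clinal loci follow the chosen shape at a drawn midpoint and frequency
    difference (random direction); flat loci sit at a constant frequency
    drawn uniform(0.05, 0.95).  Observed counts are Binomial(n_per_site, p).
    """
    rng = np.random.default_rng(spec.seed)
    lats = transect_latitudes(spec)
    sites = [PopulationSite(f"s{i + 1}", float(lat)) for i, lat in enumerate(lats)]
    n_clinal = int(round(spec.fraction_clinal * spec.n_loci))
    loci, counts, truth = [], {}, []
    for j in range(spec.n_loci):
        lid = f"L{j + 1}"
        clinal = j < n_clinal
        if clinal:
            midpoint = rng.uniform(*spec.midpoint_range)
            delta_p = rng.uniform(*spec.delta_p_range)
            direction = rng.choice([-1, 1])
            base = rng.uniform(0.02, 1 - delta_p - 0.02)
            p = _cline_profile(
                lats, spec.cline_shape, midpoint, delta_p, spec.cline_width, direction, base
            )
        else:
            midpoint = np.nan
            delta_p = 0.0
            direction = 0
            base = rng.uniform(0.05, 0.95)
            p = np.full(len(lats), base)
        x = rng.binomial(spec.n_per_site, p)
        counts[lid] = np.stack([x, spec.n_per_site - x], axis=1)
        loci.append(Locus(lid, "SNP", ("1", "2")))
        truth.append(
            {
                "locus": lid,
                "is_clinal": clinal,
                "shape": spec.cline_shape if clinal else "flat",
                "midpoint": midpoint,
                "delta_p": delta_p,
                "direction": direction,
                "base_freq": base,
                "slope_true": (direction * delta_p / spec.cline_width) if clinal else 0.0,
            }
        )
    ds = ClineDataset(sites, loci, counts, provenance=f"synthetic {spec}")
    return ds, pd.DataFrame(truth)


def generate_multiallelic_locus(
    lats: np.ndarray,
    k: int = 3,
    delta_p: float = 0.6,
    midpoint: float = 40.0,
    width: float = 3.0,
    n: int = 40,
    seed: int | None = None,
    profiles: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Counts for one k-allele locus with a single clinal (focal) allele.

    Allele 0 runs a stepped cline of size ``delta_p``; the other k-1
    alleles share the complement in fixed proportions (flat-complementary),
    so exactly one geographic pattern is present.  Alternatively pass
    ``profiles`` as a (n_sites, k) matrix of frequencies (rows must sum
    to 1).  Returns (counts of shape (n_sites, k), focal allele index).
    """
    if k < 2:
        raise ValueError("need k >= 2 alleles")
    rng = np.random.default_rng(seed)
    lats = np.asarray(lats, float)
    if profiles is None:
        base = 0.5 - delta_p / 2
        p_focal = np.interp(
            lats, [midpoint - width / 2, midpoint + width / 2], [base, base + delta_p]
        )
        rest = rng.dirichlet(np.ones(k - 1))
        profiles = np.column_stack([p_focal] + [(1 - p_focal) * w for w in rest])
    else:
        profiles = np.asarray(profiles, float)
        if profiles.shape != (len(lats), k):
            raise ValueError("profiles must be (n_sites, k)")
        if not np.allclose(profiles.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("profiles rows must sum to 1")
    counts = np.stack([rng.multinomial(n, row) for row in profiles])
    return counts, 0
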