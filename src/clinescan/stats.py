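"""Core population-genetic estimators.

Expected heterozygosity, the Weir & Cockerham (1984) multi-allelic FST
estimator (theta) on allele-count data, pairwise-FST distance matrices, and a
seeded one-sided Mantel permutation test of isolation by distance.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix

from .datasets import ClineDataset


def expected_heterozygosity(freqs) -> float:
    """Gene diversity 1 - sum(p_a^2) of an allele-frequency vector."""
    p = np.asarray(freqs, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError(f"frequencies sum to {p.sum():.4f}, not 1")
    return float(1.0 - np.sum(p**2))


def wc_fst(counts) -> float:
    """Weir-Cockerham theta from per-site allele counts of one locus.

    ``counts`` is an ``(n_sites, k)`` array of allele counts; sites with no
    sampled copies are ignored.  The estimator is the allele-count (random
    union of gametes) variance-component form: per allele,

        MSP = sum_i n_i (p_i - pbar)^2 / (r - 1)          (among sites)
        MSG = sum_i n_i p_i (1 - p_i) / (sum_i n_i - r)   (within sites)
        n_c = (N - sum n_i^2 / N) / (r - 1)

    and theta = sum_a (MSP - MSG) / sum_a (MSP + (n_c - 1) MSG).  May be
    slightly negative; equals 1 for sites fixed for disjoint alleles.
    Returns NaN when every site is monomorphic for the same allele.
    """
    c = np.asarray(counts, dtype=float)
    n_i = c.sum(axis=1)
    c = c[n_i > 0]
    n_i = n_i[n_i > 0]
    r = len(c)
    if r < 2:
        raise ValueError("need >= 2 assayed sites")
    N = n_i.sum()
    if N - r <= 0:
        raise ValueError("need more than one sampled copy overall")
    p = c / n_i[:, None]
    pbar = c.sum(axis=0) / N
    n_c = (N - (n_i**2).sum() / N) / (r - 1)
    msp = (n_i[:, None] * (p - pbar) ** 2).sum(axis=0) / (r - 1)
    msg = (n_i[:, None] * p * (1 - p)).sum(axis=0) / (N - r)
    num = (msp - msg).sum()
    den = (msp + (n_c - 1) * msg).sum()
    if den <= 0:
        return float("nan")
    return float(num / den)


def pairwise_fst_matrix(ds: ClineDataset, locus_id: str) -> DistanceMatrix:
    """Pairwise-site Weir-Cockerham FST matrix for one locus.

    Negative estimates are clamped to 0 for use as a distance; unassayed
    sites are excluded.  Raises if fewer than 3 sites are assayed (the Mantel
    test downstream is undefined).
    """
    mask = ds.assayed_mask(locus_id)
    if mask.sum() < 3:
        raise ValueError(f"locus {locus_id!r}: < 3 assayed sites")
    idx = np.flatnonzero(mask)
    ids = [ds.sites[i].id for i in idx]
    c = ds.counts[locus_id][idx]
    m = len(idx)
    d = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            theta = wc_fst(c[[a, b]])
            if np.isnan(theta):
                theta = 0.0
            d[a, b] = d[b, a] = max(theta, 0.0)
    return DistanceMatrix(d, ids)


def latitude_distance_matrix(ds: ClineDataset, site_ids: list[str] | None = None) -> DistanceMatrix:
    """Geographic distance as absolute latitude difference in degrees."""
    sites = ds.sites if site_ids is None else [ds.sites[ds._site_index[s]] for s in site_ids]
    lat = np.array([s.latitude for s in sites])
    d = np.abs(lat[:, None] - lat[None, :])
    return DistanceMatrix(d, [s.id for s in sites])


def great_circle_distance_matrix(ds: ClineDataset) -> DistanceMatrix:
    """Great-circle distances in km (requires longitudes on every site)."""
    lat = np.radians(ds.latitudes)
    lon = np.array([s.longitude for s in ds.sites], dtype=float)
    if np.any(np.isnan(lon)):
        raise ValueError("great-circle distance needs longitudes for all sites")
    lon = np.radians(lon)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(d, ds.site_ids)


def mantel_test(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-sided (positive association) Mantel permutation test.

    r is the Pearson correlation of the lower triangles of A and B; the
    p-value is ``(1 + #{r_perm >= r_obs}) / (n_perm + 1)`` under joint
    row/column permutations of B.  A constant matrix yields ``(nan, 1.0)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if list(A.ids) != list(B.ids):
        B = B.filter(A.ids)
    a = np.asarray(A.data)
    b = np.asarray(B.data)
    m = a.shape[0]
    tril = np.tril_indices(m, k=-1)
    x = a[tril]
    y = b[tril]
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), 1.0
    xc = (x - x.mean()) / x.std()

    def corr(bmat):
        v = bmat[tril]
        return float(np.mean(xc * (v - v.mean()) / v.std()))

    r_obs = corr(b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        if corr(b[np.ix_(perm, perm)]) >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return r_obs, p
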