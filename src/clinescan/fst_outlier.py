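"""fdist-style FST-outlier analysis with a coalescent island-model null.

The null distribution of (heterozygosity, FST) pairs comes from coalescent
simulation of a finite island model: 100 demes, 11 of them sampled with 40
gene copies each, infinite-alleles mutation, with the migration rate
calibrated so that mean Weir-Cockerham FST across replicate loci hits a
target (0.33 by default, the system-wide differentiation of the empirical
transect).  A conditional quantile envelope of FST given heterozygosity is
built from the null pairs; empirical loci whose FST exceeds the upper
envelope at their heterozygosity are flagged as candidate targets of
diversifying selection.

The coalescent core is a direct structured-coalescent simulation of the
finite island model.  Demes are exchangeable, so the state is just each
lineage's deme label: lineages migrate to a uniformly chosen other deme at
the total rate m, and pairs sharing a deme coalesce at rate 1/Ne per pair.
Infinite-alleles mutation is dropped on the resulting genealogy branch by
branch (only the leafward-most mutation on a branch is visible, so a
Bernoulli(1 - exp(-mu * branch length)) per branch realises the allelic
partition exactly).  This event-driven implementation is validated against
an independent coalescent simulator and the island-model closed form in the
test suite.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datasets import ClineDataset
from .stats import expected_heterozygosity, wc_fst


@dataclass
class IslandNullConfig:
    """Configuration of the island-model null simulation."""

    n_demes_total: int = 100
    n_demes_sampled: int = 11
    sample_individuals_per_deme: int = 20  # diploids; 40 gene copies
    n_replicates: int = 50_000
    target_fst: float = 0.33
    ne_per_deme: float = 1000.0
    theta_range: tuple[float, float] = (0.05, 8.0)  # pooled 4*N_total*mu, log-uniform
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.target_fst < 1:
            raise ValueError("target_fst must lie in (0, 1)")
        if self.n_demes_sampled > self.n_demes_total:
            raise ValueError("cannot sample more demes than exist")
        if self.n_replicates < 1000:
            raise ValueError("need >= 1000 replicates for envelope construction")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def island_fst_closed_form(four_n_m: float, n_demes: int) -> float:
    """Equilibrium island-model expectation FST = 1/(1 + 4Nm (d/(d-1))^2)."""
    return 1.0 / (1.0 + four_n_m * (n_demes / (n_demes - 1)) ** 2)


def simulate_island_genealogy(
    n_demes: int,
    ne_per_deme: float,
    m_total: float,
    copies_per_deme: int,
    n_demes_sampled: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One structured-coalescent genealogy under the finite island model.

    Samples are ``copies_per_deme`` haploid gene copies in each of the first
    ``n_demes_sampled`` demes.  Each lineage emigrates at total rate
    ``m_total`` per generation to a uniformly chosen other deme; each pair
    of lineages sharing a deme coalesces at rate 1/``ne_per_deme``.

    Returns ``(parent, times)`` arrays over nodes; nodes 0..L-1 are the
    samples (deme of sample i is ``i // copies_per_deme``), internal nodes
    are appended in coalescence-time order, the root has parent -1.
    """
    n_samples = n_demes_sampled * copies_per_deme
    demes = list(np.repeat(np.arange(n_demes_sampled), copies_per_deme))
    nodes = list(range(n_samples))
    parent = [-1] * n_samples
    times = [0.0] * n_samples
    occ: dict[int, int] = {}
    for d in demes:
        occ[d] = occ.get(d, 0) + 1
    pairs = sum(v * (v - 1) // 2 for v in occ.values())
    t = 0.0
    uniform = rng.random
    while len(nodes) > 1:
        n_lin = len(nodes)
        r_coal = pairs / ne_per_deme
        r_mig = n_lin * m_total
        total_rate = r_coal + r_mig
        t += rng.exponential(1.0 / total_rate)
        if uniform() * total_rate < r_mig:
            i = int(uniform() * n_lin)
            d_old = demes[i]
            pairs -= occ[d_old] - 1
            occ[d_old] -= 1
            d_new = int(uniform() * (n_demes - 1))
            if d_new >= d_old:
                d_new += 1
            pairs += occ.get(d_new, 0)
            occ[d_new] = occ.get(d_new, 0) + 1
            demes[i] = d_new
        else:
            x = uniform() * pairs
            acc = 0.0
            d_sel = next(iter(occ))
            for d, cnt in occ.items():
                acc += cnt * (cnt - 1) / 2.0
                if x < acc:
                    d_sel = d
                    break
            members = [i for i, d in enumerate(demes) if d == d_sel]
            ia, ib = rng.choice(len(members), size=2, replace=False)
            a, b = sorted((members[int(ia)], members[int(ib)]))
            new_node = len(parent)
            parent.append(-1)
            times.append(t)
            parent[nodes[a]] = new_node
            parent[nodes[b]] = new_node
            nodes[a] = new_node
            del nodes[b], demes[b]
            occ[d_sel] -= 1
            pairs -= occ[d_sel]
            if occ[d_sel] == 0:
                del occ[d_sel]
    return np.asarray(parent), np.asarray(times)


def infinite_alleles_partition(
    parent: np.ndarray, times: np.ndarray, mu: float, n_samples: int, rng
) -> np.ndarray:
    """Leaf allele labels after infinite-alleles mutation at rate ``mu``.

    Each branch mutates with probability 1 - exp(-mu * length); a mutated
    branch gives its whole subtree a fresh allele (overridden by more
    recent mutations below it).  Labels are arbitrary contiguous ints.
    """
    n_nodes = len(parent)
    lengths = np.zeros(n_nodes)
    has_parent = parent >= 0
    lengths[has_parent] = times[parent[has_parent]] - times[has_parent]
    mutated = rng.random(n_nodes) < -np.expm1(-mu * lengths)
    allele = np.zeros(n_nodes, dtype=np.int64)
    next_allele = 0
    # parents are always created after children, so descending index order
    # visits every parent before its children
    for v in range(n_nodes - 1, -1, -1):
        if parent[v] == -1:
            allele[v] = 0
        elif mutated[v]:
            next_allele += 1
            allele[v] = next_allele
        else:
            allele[v] = allele[parent[v]]
    return allele[:n_samples]


def simulate_island_pairs(
    cfg: IslandNullConfig, m_total: float, n_replicates: int, seed: int
) -> pd.DataFrame:
    """Simulate (He, FST) pairs under the island-model null.

    One non-recombining locus per replicate; infinite-alleles mutation at a
    per-locus rate drawn log-uniformly from ``theta_range`` (pooled-sample
    scale theta = 4 N_total mu) so the null spans the heterozygosity axis.
    Monomorphic samples are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    copies = 2 * cfg.sample_individuals_per_deme
    n_total = cfg.n_demes_total * cfg.ne_per_deme
    lo, hi = cfg.theta_range
    n_samples = cfg.n_demes_sampled * copies
    out_he, out_fst = [], []
    n_rejected = 0
    while len(out_he) < n_replicates:
        parent, times = simulate_island_genealogy(
            cfg.n_demes_total, cfg.ne_per_deme, m_total, copies, cfg.n_demes_sampled, rng
        )
        theta = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        mu = theta / (4.0 * n_total)
        alleles = infinite_alleles_partition(parent, times, mu, n_samples, rng)
        uniq, inv = np.unique(alleles, return_inverse=True)
        if len(uniq) < 2:
            n_rejected += 1
            continue
        counts = np.zeros((cfg.n_demes_sampled, len(uniq)), dtype=np.int64)
        for d in range(cfg.n_demes_sampled):
            counts[d] = np.bincount(
                inv[d * copies : (d + 1) * copies], minlength=len(uniq)
            )
        pooled = counts.sum(axis=0)
        he = expected_heterozygosity(pooled / pooled.sum())
        fst = wc_fst(counts)
        if np.isnan(fst):
            n_rejected += 1
            continue
        out_he.append(he)
        out_fst.append(fst)
    df = pd.DataFrame({"he": out_he, "fst": out_fst})
    df.attrs["n_rejected"] = n_rejected
    return df


def calibrate_migration(
    cfg: IslandNullConfig,
    pilot_replicates: int = 2000,
    tol: float = 0.01,
    max_iter: int = 50,
) -> float:
    """Bisect the island-model migration rate to hit the target mean FST.

    Starts from the closed-form inversion of the infinite-island expectation
    and bisects on log(m) until the mean simulated Weir-Cockerham FST over
    ``pilot_replicates`` loci is within ``tol`` of ``cfg.target_fst``.
    Common random numbers (a fixed pilot seed) keep the objective monotone.
    Deterministic given ``cfg.seed``.
    """
    d = cfg.n_demes_total
    four_n_m0 = (1.0 / cfg.target_fst - 1.0) / (d / (d - 1)) ** 2
    m0 = four_n_m0 / (4.0 * cfg.ne_per_deme)
    seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % (2**31))

    def mean_fst(m):
        pairs = simulate_island_pairs(cfg, m, pilot_replicates, seed)
        return float(pairs["fst"].mean())

    # mean FST decreases with m; bracket the target
    lo_m, hi_m = m0 / 10.0, m0 * 10.0
    f_lo, f_hi = mean_fst(lo_m), mean_fst(hi_m)
    it = 2
    while not (f_hi - tol <= cfg.target_fst <= f_lo + tol):
        if cfg.target_fst > f_lo:
            lo_m /= 10.0
            f_lo = mean_fst(lo_m)
        elif cfg.target_fst < f_hi:
            hi_m *= 10.0
            f_hi = mean_fst(hi_m)
        it += 1
        if it >= max_iter:
            raise RuntimeError("calibration failed to bracket the target FST")
    while it < max_iter:
        mid = float(np.sqrt(lo_m * hi_m))
        f_mid = mean_fst(mid)
        if abs(f_mid - cfg.target_fst) <= tol:
            return mid
        if f_mid > cfg.target_fst:
            lo_m = mid
        else:
            hi_m = mid
        it += 1
    raise RuntimeError(f"calibration did not converge within {max_iter} iterations")


def simulate_island_locus(cfg: IslandNullConfig, m_total: float, seed: int | None = None):
    """One (He, FST) draw under the calibrated island-model null."""
    df = simulate_island_pairs(cfg, m_total, 1, seed if seed is not None else 0)
    return float(df["he"].iloc[0]), float(df["fst"].iloc[0])


# ---------------------------------------------------------------------------
# conditional quantile envelope
# ---------------------------------------------------------------------------


@dataclass
class NullEnvelope:
    """Conditional FST-given-He quantile curves from the null pairs."""

    bin_edges: np.ndarray
    curves: pd.DataFrame  # per bin: he_mid, q_lo95, q_hi95, q_lo99, q_hi99, median, n
    pairs: pd.DataFrame = field(repr=False)

    def bin_of(self, he: float) -> int:
        """Bin index for a heterozygosity; clamps to the nearest bin outside."""
        idx = int(np.searchsorted(self.bin_edges, he, side="right")) - 1
        return int(np.clip(idx, 0, len(self.curves) - 1))


def build_null_envelope(
    pairs: pd.DataFrame,
    n_bins: int = 25,
    levels: tuple[float, float] = (0.95, 0.99),
    smooth_window: int = 3,
) -> NullEnvelope:
    """Binned conditional quantile envelope, smoothed by a running median.

    He is cut into ``n_bins`` equal-count bins (empty/singleton bins merge
    with their neighbours via quantile-based edges); within each bin the
    two-sided quantiles at each level and the median FST are computed, then
    each curve is smoothed with a centred ``smooth_window``-bin running
    median.
    """
    if len(pairs) < 1000:
        raise ValueError("need >= 1000 null pairs")
    he = pairs["he"].to_numpy()
    fst = pairs["fst"].to_numpy()
    edges = np.unique(np.quantile(he, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 3:
        raise ValueError("heterozygosity values too degenerate to bin")
    edges[0], edges[-1] = -np.inf, np.inf
    idx = np.clip(np.searchsorted(edges, he, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.sum() == 0:
            continue
        f = fst[sel]
        row = {"he_mid": float(np.median(he[sel])), "n": int(sel.sum()),
               "median": float(np.median(f))}
        for lev in levels:
            a = (1 - lev) / 2
            row[f"q_lo{int(lev * 100)}"] = float(np.quantile(f, a))
            row[f"q_hi{int(lev * 100)}"] = float(np.quantile(f, 1 - a))
        rows.append(row)
    curves = pd.DataFrame(rows)
    if smooth_window > 1:
        half = smooth_window // 2
        for col in curves.columns:
            if col in ("n",):
                continue
            v = curves[col].to_numpy()
            sm = np.array(
                [np.median(v[max(0, i - half) : i + half + 1]) for i in range(len(v))]
            )
            curves[col] = sm
    # enforce quantile monotonicity within each bin after smoothing
    for lev in levels:
        lo, hi = f"q_lo{int(lev * 100)}", f"q_hi{int(lev * 100)}"
        curves[lo] = np.minimum(curves[lo], curves["median"])
        curves[hi] = np.maximum(curves[hi], curves["median"])
    kept_edges = np.asarray(edges)
    return NullEnvelope(kept_edges, curves, pairs.reset_index(drop=True))


def classify_fst_outliers(
    ds: ClineDataset, envelope: NullEnvelope, levels: tuple[float, float] = (0.95, 0.99)
) -> pd.DataFrame:
    """Per-locus He, FST, envelope flags and empirical upper-tail p-values.

    ``outlier_high`` / ``outlier_low`` refer to the first (95 %) level;
    columns for the 99 % level are included alongside.  The empirical p is
    the fraction of null pairs in the locus's He bin with FST >= observed.
    """
    he_null = envelope.pairs["he"].to_numpy()
    fst_null = envelope.pairs["fst"].to_numpy()
    null_bins = np.clip(
        np.searchsorted(envelope.bin_edges, he_null, side="right") - 1,
        0,
        len(envelope.curves) - 1,
    )
    rows = []
    for lid in ds.locus_ids:
        counts = ds.counts[lid]
        pooled = counts.sum(axis=0)
        if (pooled > 0).sum() < 2:
            continue  # monomorphic: FST undefined
        he = expected_heterozygosity(pooled / pooled.sum())
        fst = wc_fst(counts)
        if np.isnan(fst):
            continue
        b = envelope.bin_of(he)
        sel = null_bins == b
        emp_p = float((fst_null[sel] >= fst).mean()) if sel.any() else np.nan
        row = {"locus": lid, "he": he, "fst": fst, "bin": b, "empirical_p": emp_p}
        for lev in levels:
            tag = int(lev * 100)
            row[f"outlier_high_{tag}"] = bool(
                fst > envelope.curves[f"q_hi{tag}"].iloc[b]
            )
            row[f"outlier_low_{tag}"] = bool(fst < envelope.curves[f"q_lo{tag}"].iloc[b])
        row["outlier_high"] = row[f"outlier_high_{int(levels[0] * 100)}"]
        row["outlier_low"] = row[f"outlier_low_{int(levels[0] * 100)}"]
        rows.append(row)
    return pd.DataFrame(rows)


class FstOutlierClassifier(BaseEstimator):
    """Island-model FST-outlier test as a fit/predict estimator.

    fit() calibrates the migration rate to the target mean FST, simulates
    the null (He, FST) cloud and builds the conditional quantile envelope;
    predict() classifies the loci of a ClineDataset against it.
    """

    def __init__(
        self,
        n_demes_total: int = 100,
        n_demes_sampled: int = 11,
        sample_individuals_per_deme: int = 20,
        n_replicates: int = 50_000,
        target_fst: float = 0.33,
        ne_per_deme: float = 1000.0,
        theta_range: tuple = (0.05, 8.0),
        n_bins: int = 25,
        pilot_replicates: int = 2000,
        seed: int | None = None,
    ):
        self.n_demes_total = n_demes_total
        self.n_demes_sampled = n_demes_sampled
        self.sample_individuals_per_deme = sample_individuals_per_deme
        self.n_replicates = n_replicates
        self.target_fst = target_fst
        self.ne_per_deme = ne_per_deme
        self.theta_range = theta_range
        self.n_bins = n_bins
        self.pilot_replicates = pilot_replicates
        self.seed = seed

    def _config(self) -> IslandNullConfig:
        return IslandNullConfig(
            n_demes_total=self.n_demes_total,
            n_demes_sampled=self.n_demes_sampled,
            sample_individuals_per_deme=self.sample_individuals_per_deme,
            n_replicates=self.n_replicates,
            target_fst=self.target_fst,
            ne_per_deme=self.ne_per_deme,
            theta_range=tuple(self.theta_range),
            seed=self.seed,
        )

    def fit(self, X=None, y=None, null_pairs: pd.DataFrame | None = None):
        cfg = self._config()
        self.config_ = cfg
        if null_pairs is None:
            self.migration_rate_ = calibrate_migration(
                cfg, pilot_replicates=self.pilot_replicates
            )
            seed = int(np.random.SeedSequence(cfg.seed).spawn(2)[1].generate_state(1)[0] % (2**31))
            null_pairs = simulate_island_pairs(
                cfg, self.migration_rate_, cfg.n_replicates, seed
            )
        self.null_pairs_ = null_pairs
        self.envelope_ = build_null_envelope(null_pairs, n_bins=self.n_bins)
        self.mean_null_fst_ = float(null_pairs["fst"].mean())
        return self

    def predict(self, ds: ClineDataset) -> pd.DataFrame:
        return classify_fst_outliers(ds, self.envelope_)

    # -- null-pair caching -------------------------------------------------

    def save_null(self, path) -> None:
        df = self.null_pairs_.copy()
        df.attrs = {}
        df.to_csv(path, index=False)
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump({"config_hash": self.config_.config_hash()}, fh)

    def load_null(self, path) -> "FstOutlierClassifier":
        cfg = self._config()
        with open(str(path) + ".meta.json") as fh:
            meta = json.load(fh)
        if meta["config_hash"] != cfg.config_hash():
            raise ValueError("cached null pairs were built under a different config")
        return self.fit(null_pairs=pd.read_csv(path))
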