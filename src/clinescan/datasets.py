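"""Data model and I/O for multi-locus, multi-population allele data.

The universal container is :class:`ClineDataset`: a set of population sites
(with latitudes) crossed with loci, holding per-(site, locus) allele *counts*.
Counts, not frequencies, are canonical; a count vector summing to zero encodes
"not assayed".  Frequencies given without counts are converted to counts using
an assumed per-site sample size (default 40 allele copies, i.e. 20 diploids)
with largest-remainder rounding so the converted counts sum exactly to n.

Readers/writers cover a long-format CSV table and the GenePop genotype format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

MARKER_CLASSES = ("mtDNA", "allozyme", "microsatellite", "SNP", "simulated")

#: Assumed allele copies per site when only frequencies are published.
DEFAULT_ASSUMED_N = 40


class ClineDataError(ValueError):
    """Raised on malformed or inconsistent allele data."""


@dataclass(frozen=True)
class PopulationSite:
    """A sampled population with a latitude (decimal degrees N)."""

    id: str
    latitude: float
    longitude: float | None = None

    def __post_init__(self):
        if not math.isfinite(self.latitude):
            raise ClineDataError(f"site {self.id!r}: latitude must be finite")


@dataclass(frozen=True)
class Locus:
    """A genetic locus with an ordered list of allele ids (k >= 2)."""

    id: str
    marker_class: str = "SNP"
    allele_ids: tuple[str, ...] = ("1", "2")

    def __post_init__(self):
        if self.marker_class not in MARKER_CLASSES:
            raise ClineDataError(
                f"locus {self.id!r}: marker_class {self.marker_class!r} not one of {MARKER_CLASSES}"
            )
        if len(self.allele_ids) < 2:
            raise ClineDataError(f"locus {self.id!r}: need >= 2 alleles")
        if len(set(self.allele_ids)) != len(self.allele_ids):
            raise ClineDataError(f"locus {self.id!r}: duplicate allele ids")


class ClineDataset:
    """Populations x loci allele counts along a one-dimensional transect.

    Parameters
    ----------
    sites
        Ordered population sites; ids must be unique.
    loci
        Ordered loci; ids must be unique.
    counts
        Mapping ``locus_id -> (n_sites, k) int array`` of allele counts in
        site order.  A row summing to 0 means the locus was not assayed there.
    provenance
        Free-text description of where the data came from.
    """

    def __init__(
        self,
        sites: list[PopulationSite],
        loci: list[Locus],
        counts: dict[str, np.ndarray],
        provenance: str = "",
    ):
        ids = [s.id for s in sites]
        if len(set(ids)) != len(ids):
            raise ClineDataError("duplicate site ids")
        lids = [l.id for l in loci]
        if len(set(lids)) != len(lids):
            raise ClineDataError("duplicate locus ids")
        if set(counts) != set(lids):
            raise ClineDataError("counts keys must match locus ids exactly")
        self.sites = list(sites)
        self.loci = list(loci)
        self.provenance = provenance
        self._site_index = {s.id: i for i, s in enumerate(sites)}
        self._locus_index = {l.id: i for i, l in enumerate(loci)}
        self.counts: dict[str, np.ndarray] = {}
        for loc in loci:
            c = np.asarray(counts[loc.id])
            if c.shape != (len(sites), len(loc.allele_ids)):
                raise ClineDataError(
                    f"locus {loc.id!r}: counts shape {c.shape} != "
                    f"({len(sites)}, {len(loc.allele_ids)})"
                )
            if np.any(c < 0) or not np.allclose(c, np.round(c)):
                raise ClineDataError(f"locus {loc.id!r}: counts must be non-negative integers")
            self.counts[loc.id] = c.astype(np.int64)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def site_ids(self) -> list[str]:
        return [s.id for s in self.sites]

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    @property
    def latitudes(self) -> np.ndarray:
        return np.array([s.latitude for s in self.sites], dtype=float)

    def locus(self, locus_id: str) -> Locus:
        return self.loci[self._locus_index[locus_id]]

    def sample_sizes(self, locus_id: str) -> np.ndarray:
        """Allele copies sampled per site (0 = not assayed)."""
        return self.counts[locus_id].sum(axis=1)

    def frequencies(self, locus_id: str) -> np.ndarray:
        """Per-site allele frequencies; rows of NaN where not assayed."""
        c = self.counts[locus_id].astype(float)
        n = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, c / np.where(n > 0, n, 1), np.nan)
        return f

    def assayed_mask(self, locus_id: str) -> np.ndarray:
        return self.sample_sizes(locus_id) > 0

    # -- subsetting --------------------------------------------------------

    def subset_sites(self, site_ids: list[str]) -> "ClineDataset":
        idx = [self._site_index[s] for s in site_ids]
        sites = [self.sites[i] for i in idx]
        counts = {lid: self.counts[lid][idx] for lid in self.locus_ids}
        return ClineDataset(sites, self.loci, counts, self.provenance)

    def subset_loci(self, locus_ids: list[str]) -> "ClineDataset":
        loci = [self.locus(lid) for lid in locus_ids]
        counts = {lid: self.counts[lid] for lid in locus_ids}
        return ClineDataset(self.sites, loci, counts, self.provenance)

    # -- long-format table -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: site, latitude, locus, marker_class, allele, count."""
        rows = []
        for loc in self.loci:
            c = self.counts[loc.id]
            for i, site in enumerate(self.sites):
                for a, aid in enumerate(loc.allele_ids):
                    rows.append(
                        (site.id, site.latitude, loc.id, loc.marker_class, aid, int(c[i, a]))
                    )
        return pd.DataFrame(
            rows, columns=["site", "latitude", "locus", "marker_class", "allele", "count"]
        )

    def __repr__(self):
        return f"ClineDataset({self.n_sites} sites x {self.n_loci} loci)"


# ---------------------------------------------------------------------------
# Frequency-table I/O
# ---------------------------------------------------------------------------


def _counts_from_frequencies(freqs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder rounding of n*freqs so counts sum exactly to n."""
    raw = freqs * n
    base = np.floor(raw).astype(np.int64)
    short = int(n - base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def read_frequency_table(path, assumed_n: int = DEFAULT_ASSUMED_N) -> ClineDataset:
    """Read a long-format CSV of allele counts (or frequencies) into a dataset.

    Required columns: ``site``, ``latitude``, ``locus``, ``allele``, plus
    either ``count`` or ``frequency`` (with an optional ``sample_size``
    column; otherwise *assumed_n* allele copies per assayed site).  An
    optional ``marker_class`` column sets the locus type.
    """
    df = pd.read_csv(path)
    required = {"site", "latitude", "locus", "allele"}
    missing = required - set(df.columns)
    if missing:
        raise ClineDataError(f"missing columns: {sorted(missing)}")
    has_count = "count" in df.columns
    has_freq = "frequency" in df.columns
    if not has_count and not has_freq:
        raise ClineDataError("need a 'count' or 'frequency' column")
    if has_freq and not has_count:
        bad = df[(df["frequency"] < 0) | (df["frequency"] > 1)]
        if len(bad):
            raise ClineDataError(
                f"frequency outside [0,1] at row(s) {list(bad.index[:5])}"
            )
    for col in ("count",) if has_count else ():
        if df[col].isna().any():
            raise ClineDataError("NaN in count column")

    sites: list[PopulationSite] = []
    seen = {}
    for _, row in df.drop_duplicates("site").iterrows():
        try:
            lat = float(row["latitude"])
        except (TypeError, ValueError) as e:
            raise ClineDataError(f"bad latitude for site {row['site']!r}") from e
        seen[str(row["site"])] = lat
        sites.append(PopulationSite(str(row["site"]), lat))
    # latitude must be consistent within a site
    chk = df.groupby("site")["latitude"].nunique()
    if (chk > 1).any():
        raise ClineDataError(f"conflicting latitudes for site(s) {list(chk[chk > 1].index)}")

    site_index = {s.id: i for i, s in enumerate(sites)}
    loci: list[Locus] = []
    counts: dict[str, np.ndarray] = {}
    for lid, sub in df.groupby("locus", sort=False):
        alleles = tuple(dict.fromkeys(str(a) for a in sub["allele"]))
        mclass = "SNP"
        if "marker_class" in sub.columns:
            mclass = str(sub["marker_class"].iloc[0])
        loc = Locus(str(lid), mclass, alleles)
        c = np.zeros((len(sites), len(alleles)), dtype=np.int64)
        aidx = {a: j for j, a in enumerate(alleles)}
        if has_count:
            for _, row in sub.iterrows():
                c[site_index[str(row["site"])], aidx[str(row["allele"])]] += int(row["count"])
        else:
            for sid, ssub in sub.groupby("site", sort=False):
                f = np.zeros(len(alleles))
                for _, row in ssub.iterrows():
                    f[aidx[str(row["allele"])]] = float(row["frequency"])
                tot = f.sum()
                if tot == 0:
                    continue  # not assayed
                if not np.isclose(tot, 1.0, atol=1e-6):
                    raise ClineDataError(
                        f"locus {lid!r} site {sid!r}: frequencies sum to {tot:.4f}, not 1"
                    )
                n = int(ssub["sample_size"].iloc[0]) if "sample_size" in ssub.columns and not pd.isna(ssub["sample_size"].iloc[0]) else assumed_n
                c[site_index[str(sid)]] = _counts_from_frequencies(f / tot, n)
        counts[str(lid)] = c
        loci.append(loc)
    return ClineDataset(sites, loci, counts, provenance=f"read from {path}")


def write_frequency_table(ds: ClineDataset, path) -> None:
    """Write the dataset as a long-format CSV (counts; assayed rows only)."""
    df = ds.to_frame()
    assayed = df.groupby(["site", "locus"])["count"].transform("sum") > 0
    df[assayed].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotype tables and GenePop
# ---------------------------------------------------------------------------


class GenotypeTable:
    """Unordered diploid genotypes per (site, locus, individual).

    Genotypes are stored as integer allele indices (1-based into the locus's
    ``allele_ids``; 0 = missing) in arrays of shape ``(n_individuals, 2)``.
    """

    def __init__(
        self,
        sites: list[str],
        loci: list[Locus],
        genotypes: dict[str, dict[str, np.ndarray]],
    ):
        self.sites = list(sites)
        self.loci = list(loci)
        self.genotypes = genotypes
        for sid in sites:
            for loc in loci:
                g = np.asarray(genotypes[sid][loc.id])
                if g.ndim != 2 or g.shape[1] != 2:
                    raise ClineDataError(f"genotypes for ({sid}, {loc.id}) must be (n, 2)")
                if g.max(initial=0) > len(loc.allele_ids):
                    raise ClineDataError(
                        f"allele code out of range for locus {loc.id!r}"
                    )
                genotypes[sid][loc.id] = g.astype(np.int64)

    def n_individuals(self, site_id: str) -> int:
        return len(next(iter(self.genotypes[site_id].values())))

    def allele_counts(self, site_id: str, locus_id: str) -> np.ndarray:
        """Observed allele counts (missing alleles excluded)."""
        k = len(next(l for l in self.loci if l.id == locus_id).allele_ids)
        g = self.genotypes[site_id][locus_id].ravel()
        g = g[g > 0]
        return np.bincount(g - 1, minlength=k)

    def to_dataset(
        self, latitudes: dict[str, float], marker_class: str | None = None
    ) -> ClineDataset:
        """Collapse genotypes to allele counts in a :class:`ClineDataset`."""
        sites = [PopulationSite(s, latitudes[s]) for s in self.sites]
        loci = self.loci
        if marker_class is not None:
            loci = [Locus(l.id, marker_class, l.allele_ids) for l in loci]
        counts = {
            l.id: np.stack([self.allele_counts(s, l.id) for s in self.sites])
            for l in loci
        }
        return ClineDataset(sites, loci, counts)

    def __eq__(self, other):
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        if self.sites != other.sites:
            return False
        if [l.id for l in self.loci] != [l.id for l in other.loci]:
            return False
        return all(
            np.array_equal(self.genotypes[s][l.id], other.genotypes[s][l.id])
            for s in self.sites
            for l in self.loci
        )


class GenePopError(ValueError):
    """Raised on malformed GenePop input."""


def write_genepop(table: GenotypeTable, path, title: str = "clinescan export") -> None:
    """Write a GenotypeTable in GenePop format (3-digit allele codes)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(title.strip() + "\n")
        for loc in table.loci:
            fh.write(loc.id + "\n")
        for sid in table.sites:
            fh.write("POP\n")
            n = table.n_individuals(sid)
            for i in range(n):
                codes = []
                for loc in table.loci:
                    a, b = table.genotypes[sid][loc.id][i]
                    codes.append(f"{a:03d}{b:03d}")
                fh.write(f"{sid}_{i + 1} ,  " + " ".join(codes) + "\n")


def read_genepop(path) -> GenotypeTable:
    """Read a GenePop file (2- or 3-digit allele codes) into a GenotypeTable."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 3:
        raise GenePopError("file too short for GenePop format")
    # locus names: one per line (or comma-separated on one line) until first POP
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        locus_names.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenePopError("no POP keyword found")
    if not locus_names:
        raise GenePopError("no locus names before first POP")

    pops: list[list[tuple[str, list[tuple[int, int]]]]] = []
    current: list | None = None
    for ln in lines[i:]:
        if ln.strip().upper() == "POP":
            current = []
            pops.append(current)
            continue
        if current is None:
            raise GenePopError("genotype line before first POP")
        if "," not in ln:
            raise GenePopError(f"genotype line lacks comma separator: {ln[:40]!r}")
        name, rest = ln.split(",", 1)
        codes = rest.split()
        if len(codes) != len(locus_names):
            raise GenePopError(
                f"individual {name.strip()!r}: {len(codes)} genotypes for "
                f"{len(locus_names)} loci (truncated POP block?)"
            )
        genos = []
        for c in codes:
            if len(c) == 4:
                w = 2
            elif len(c) == 6:
                w = 3
            else:
                raise GenePopError(f"unknown allele-code width in {c!r}")
            genos.append((int(c[:w]), int(c[w:])))
        current.append((name.strip(), genos))
    if any(len(p) == 0 for p in pops):
        raise GenePopError("empty POP block")

    max_code = [0] * len(locus_names)
    for pop in pops:
        for _, genos in pop:
            for j, (a, b) in enumerate(genos):
                max_code[j] = max(max_code[j], a, b)
    loci = [
        Locus(nm, "SNP", tuple(str(a) for a in range(1, max(2, mc) + 1)))
        for nm, mc in zip(locus_names, max_code)
    ]
    sites = [f"pop{p + 1}" for p in range(len(pops))]
    genotypes: dict[str, dict[str, np.ndarray]] = {}
    for sid, pop in zip(sites, pops):
        per_locus = {loc.id: np.zeros((len(pop), 2), dtype=np.int64) for loc in loci}
        for ind, (_, genos) in enumerate(pop):
            for loc, (a, b) in zip(loci, genos):
                per_locus[loc.id][ind] = (a, b)
        genotypes[sid] = per_locus
    return GenotypeTable(sites, loci, genotypes)


# ---------------------------------------------------------------------------
# HWE genotype synthesis and locus filtering
# ---------------------------------------------------------------------------


def synthesize_genotypes(
    ds: ClineDataset, n_individuals: int = 20, seed: int | None = None
) -> GenotypeTable:
    """Draw diploid genotypes from per-site allele frequencies under HWE.

    Each of *n_individuals* genotypes is two alleles drawn independently from
    the site's frequency vector.  Unassayed (site, locus) cells are emitted as
    missing genotypes (code 0).  Default 20 individuals per site.
    """
    if n_individuals < 1:
        raise ClineDataError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    genotypes: dict[str, dict[str, np.ndarray]] = {}
    for i, site in enumerate(ds.sites):
        per_locus = {}
        for loc in ds.loci:
            c = ds.counts[loc.id][i]
            n = c.sum()
            if n == 0:
                g = np.zeros((n_individuals, 2), dtype=np.int64)
            else:
                p = c / n
                g = rng.choice(len(p), size=(n_individuals, 2), p=p) + 1
            per_locus[loc.id] = g
        genotypes[site.id] = per_locus
    return GenotypeTable(ds.site_ids, ds.loci, genotypes)


def filter_loci(
    ds: ClineDataset, require_variant: bool = True, require_all_sites: bool = False
) -> tuple[ClineDataset, list[str]]:
    """Drop invariant loci and/or loci not assayed at every site.

    Returns the filtered dataset and the list of dropped locus ids.
    """
    keep, dropped = [], []
    for loc in ds.loci:
        c = ds.counts[loc.id]
        assayed = c.sum(axis=1) > 0
        ok = True
        if require_all_sites and not assayed.all():
            ok = False
        if ok and require_variant:
            pooled = c.sum(axis=0)
            if (pooled > 0).sum() < 2:
                ok = False
        (keep if ok else dropped).append(loc.id)
    return ds.subset_loci(keep), dropped
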