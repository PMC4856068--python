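"""Single-QTL genome scan for recombinant inbred line (RIL) strain means.

Haley-Knott regression for a two-way RIL panel reduces to an ordinary
regression of the strain-mean phenotype on the probability of carrying the
second parent's allele at each position:

    LOD = (n/2) * log10(RSS0 / RSS1)

where RSS0 is the residual sum of squares of the intercept-only model and
RSS1 that of the single-marker regression.  Because RILs are homozygous,
there is no dominance term.  Missing genotypes are imputed as conditional
expectations given the nearest flanking observed markers, using the Haldane
map function with the RIL-by-sib-mating map expansion r* = 4r / (1 + 6r).

Genome-wide significance is assessed empirically: the phenotype vector is
permuted against strains, the scan repeated, and the chosen quantile of the
maximum LOD scores over permutations taken as the threshold.  Support
intervals drop 1.5 LOD units from the chromosome peak, extended one marker
beyond the drop boundary where possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LOD_CAP = 300.0


@dataclass
class Marker:
    name: str
    chromosome: str
    position_cm: float


@dataclass
class RILPanel:
    """Genotypes and strain-mean phenotypes of a RIL panel.

    ``genotypes`` is a strains x markers array coded 0 (first parent, "B"),
    1 (second parent, "D") or NaN (missing; any code outside {B, D} is
    treated as missing).  ``phenotypes`` maps trait name -> per-strain
    values aligned with ``strains``.
    """

    strains: list[str]
    markers: list[Marker]
    genotypes: np.ndarray
    phenotypes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.shape != (len(self.strains), len(self.markers)):
            raise ValueError("genotypes must be strains x markers")
        if len(self.strains) < 2:
            raise ValueError("need >= 2 strains")
        ok = np.isnan(self.genotypes) | np.isin(self.genotypes, (0.0, 1.0))
        if not ok.all():
            raise ValueError("genotype codes must be 0, 1 or NaN")
        pos = self.marker_frame()
        for _, grp in pos.groupby("chromosome", sort=False):
            if not grp["position_cm"].is_monotonic_increasing:
                raise ValueError("marker positions must be nondecreasing per chromosome")

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [m.name for m in self.markers],
                "chromosome": [m.chromosome for m in self.markers],
                "position_cm": [m.position_cm for m in self.markers],
            }
        )

    def marker_index(self, name: str) -> int:
        for i, m in enumerate(self.markers):
            if m.name == name:
                return i
        raise KeyError(f"marker {name!r} not in panel")

    def drop_strains(self, names: list[str]) -> "RILPanel":
        keep = [i for i, s in enumerate(self.strains) if s not in set(names)]
        return RILPanel(
            strains=[self.strains[i] for i in keep],
            markers=self.markers,
            genotypes=self.genotypes[keep],
            phenotypes={t: np.asarray(v)[keep] for t, v in self.phenotypes.items()},
        )


def read_genotype_csv(path) -> tuple[list[Marker], list[str], np.ndarray]:
    """Read a genotype CSV: rows = markers with name/chromosome/position_cm
    columns, remaining columns = strains, cells in {B, D, NA}."""
    df = pd.read_csv(path, dtype={"chromosome": str})
    required = {"name", "chromosome", "position_cm"}
    if not required <= set(df.columns):
        raise ValueError(f"genotype CSV needs columns {sorted(required)}")
    strains = [c for c in df.columns if c not in required]
    markers = [
        Marker(str(r["name"]), str(r["chromosome"]), float(r["position_cm"]))
        for _, r in df.iterrows()
    ]
    codes = df[strains].to_numpy(dtype=object).T  # strains x markers
    geno = np.full(codes.shape, np.nan)
    geno[codes == "B"] = 0.0
    geno[codes == "D"] = 1.0
    return markers, strains, geno


def panel_from_csv(genotype_path, phenotype_path) -> RILPanel:
    """Build a panel from genotype and phenotype CSVs (strain column plus
    one column per trait)."""
    markers, strains, geno = read_genotype_csv(genotype_path)
    pheno = pd.read_csv(phenotype_path).set_index("strain")
    phenotypes = {
        trait: pheno.reindex(strains)[trait].to_numpy(dtype=float)
        for trait in pheno.columns
    }
    return RILPanel(strains=strains, markers=markers, genotypes=geno, phenotypes=phenotypes)


def write_genotype_csv(panel: RILPanel, path) -> None:
    df = panel.marker_frame().rename(columns={})
    codes = np.full(panel.genotypes.shape, "NA", dtype=object)
    codes[panel.genotypes == 0.0] = "B"
    codes[panel.genotypes == 1.0] = "D"
    for i, s in enumerate(panel.strains):
        df[s] = codes[i]
    df.to_csv(path, index=False)


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction from map distance (cM), Haldane map function."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_expansion(r: np.ndarray | float) -> np.ndarray | float:
    """Map expansion for RILs by sib mating: r* = 4r / (1 + 6r)."""
    r = np.asarray(r, dtype=float)
    return 4.0 * r / (1.0 + 6.0 * r)


def _compose_switch(r_steps: np.ndarray) -> float:
    """Effective switch probability of a two-state chain over several
    adjacent intervals (expanded fractions do not compound over distance,
    so transitions must be composed interval by interval)."""
    r = 0.0
    for step in r_steps:
        r = r * (1.0 - step) + step * (1.0 - r)
    return r


def _impute_chromosome(geno: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Conditional P(second-parent allele) for one strain on one chromosome."""
    out = geno.copy()
    obs = np.flatnonzero(~np.isnan(geno))
    if len(obs) == 0:
        out[:] = 0.5
        return out
    # expanded recombination fraction of each adjacent marker interval
    r_adj = ril_expansion(haldane_r(np.diff(pos))) if len(pos) > 1 else np.empty(0)
    for j in np.flatnonzero(np.isnan(geno)):
        left = obs[obs < j]
        right = obs[obs > j]
        if len(left) == 0:
            out[j] = geno[right[0]]
            continue
        if len(right) == 0:
            out[j] = geno[left[-1]]
            continue
        l, r_idx = left[-1], right[0]
        rl = _compose_switch(r_adj[l:j])
        rr = _compose_switch(r_adj[j:r_idx])
        gl, gr = geno[l], geno[r_idx]
        # two-state chain: P(g | g_left) * P(g_right | g), normalised
        a1 = rl if gl == 0 else 1.0 - rl
        a0 = 1.0 - a1
        b1 = rr if gr == 0 else 1.0 - rr
        b0 = 1.0 - b1
        out[j] = a1 * b1 / (a0 * b0 + a1 * b1)
    return out


def impute_genotype_probs(panel: RILPanel) -> np.ndarray:
    """Per-strain, per-marker probability of the second parent's allele.

    Observed genotypes map to exactly 0 or 1; missing values become the
    conditional expectation given flanking observed markers; missing runs at
    chromosome ends copy the nearest observed value; a fully missing
    chromosome yields 0.5 everywhere with a warning.
    """
    probs = panel.genotypes.copy()
    mf = panel.marker_frame()
    fully_missing = False
    for chrom, grp in mf.groupby("chromosome", sort=False):
        cols = grp.index.to_numpy()
        pos = grp["position_cm"].to_numpy()
        for s in range(len(panel.strains)):
            g = panel.genotypes[s, cols]
            if np.isnan(g).all():
                fully_missing = True
            probs[s, cols] = _impute_chromosome(g, pos)
    if fully_missing:
        warnings.warn(
            "at least one strain has a fully missing chromosome; "
            "probability 0.5 assigned there",
            stacklevel=2,
        )
    return probs


@dataclass
class HKResult:
    lod: float
    effect: float
    r_squared: float
    capped: bool = False


def hk_lod(probs: np.ndarray, y: np.ndarray) -> HKResult:
    """Haley-Knott LOD at one position.

    Regresses the strain phenotypes on the genotype probabilities and
    returns LOD = (n/2) log10(RSS0/RSS1), the additive-effect estimate and
    R^2 = 1 - RSS1/RSS0 (variance explained at the position).
    """
    x = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(y)
    if n < 3:
        raise ValueError("need >= 3 strains with phenotype and probability")
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        return HKResult(lod=0.0, effect=0.0, r_squared=0.0)
    sxy = float(xc @ yc)
    effect = sxy / sxx
    rss1 = rss0 - sxy**2 / sxx
    if rss0 <= 0:
        return HKResult(lod=0.0, effect=effect, r_squared=0.0)
    if rss1 <= rss0 * 10 ** (-2 * LOD_CAP / n):
        return HKResult(lod=LOD_CAP, effect=effect, r_squared=1.0, capped=True)
    lod = (n / 2.0) * np.log10(rss0 / rss1)
    return HKResult(lod=float(lod), effect=effect, r_squared=1.0 - rss1 / rss0)


def _scan_matrix(probs: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorised LOD for phenotype matrix Y (n x p) at all markers.

    Returns a markers x p LOD array using the closed form of simple linear
    regression; used for both the observed scan and the permutation null.
    """
    X = probs - probs.mean(axis=0)  # n x m
    Yc = Y - Y.mean(axis=0)  # n x p
    n = probs.shape[0]
    sxx = np.sum(X**2, axis=0)  # m
    sxy = X.T @ Yc  # m x p
    rss0 = np.sum(Yc**2, axis=0)  # p
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = rss0[None, :] - sxy**2 / sxx[:, None]
        rss1 = np.clip(rss1, rss0[None, :] * 10 ** (-2 * LOD_CAP / n), None)
        lod = (n / 2.0) * np.log10(rss0[None, :] / rss1)
    lod[sxx <= 0, :] = 0.0
    lod[:, rss0 <= 0] = 0.0
    return lod


@dataclass
class ScanResult:
    table: pd.DataFrame  # marker, chromosome, position_cm, lod, effect, r_squared
    n_strains: int
    trait: str = "trait"
    threshold: float | None = None
    n_perm: int | None = None

    @property
    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    @property
    def peak(self) -> pd.Series:
        return self.table.loc[self.table["lod"].idxmax()]

    def chromosome_peaks(self) -> pd.DataFrame:
        idx = self.table.groupby("chromosome", sort=False)["lod"].idxmax()
        return self.table.loc[idx]


def scan(
    panel: RILPanel,
    trait: str,
    exclude_strains: list[str] | None = None,
    probs: np.ndarray | None = None,
) -> ScanResult:
    """Haley-Knott LOD at every marker for one trait.

    ``exclude_strains`` removes uninformative strains (e.g. the parental
    strains, which carry no recombinant chromosomes) before scanning.
    """
    if exclude_strains:
        panel = panel.drop_strains(exclude_strains)
        probs = None
    if trait not in panel.phenotypes:
        raise KeyError(f"trait {trait!r} not in panel phenotypes")
    y = np.asarray(panel.phenotypes[trait], dtype=float)
    if probs is None:
        probs = impute_genotype_probs(panel)
    ok = np.isfinite(y)
    probs, y = probs[ok], y[ok]
    lod = _scan_matrix(probs, y[:, None])[:, 0]
    # effect and R^2 per marker
    X = probs - probs.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(X**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.where(sxx > 0, (X.T @ yc) / np.where(sxx > 0, sxx, 1.0), 0.0)
    n = len(y)
    r2 = 1.0 - 10 ** (-2.0 * lod / n)
    mf = panel.marker_frame().rename(columns={"name": "marker"})
    table = mf.assign(lod=lod, effect=effect, r_squared=r2)
    return ScanResult(table=table, n_strains=n, trait=trait)


@dataclass
class PermutationResult:
    threshold: float
    max_lods: np.ndarray
    quantile: float
    n_perm: int

    def empirical_p(self, observed_lod: float) -> float:
        """(# permutation maxima >= observed) / n_perm; an observed LOD
        exceeding every permutation therefore reports p < 1/n_perm as 0."""
        return float(np.sum(self.max_lods >= observed_lod) / self.n_perm)


def permutation_threshold(
    panel: RILPanel,
    trait: str,
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int | np.random.Generator = 0,
    exclude_strains: list[str] | None = None,
) -> PermutationResult:
    """Empirical genome-wide LOD threshold by phenotype permutation.

    The phenotype vector is shuffled against strains ``n_perm`` times (the
    standard exchangeable-null equivalent of permuting phenotypes against
    genotypes), the genome rescanned each time, and the requested quantile
    of the maximum LOD scores returned (linear/type-7 interpolation, so the
    result is bit-reproducible for a given seed).
    """
    if exclude_strains:
        panel = panel.drop_strains(exclude_strains)
    if n_perm < 20:
        warnings.warn(f"n_perm={n_perm} makes the quantile unstable", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(panel.phenotypes[trait], dtype=float)
    probs = impute_genotype_probs(panel)
    ok = np.isfinite(y)
    probs, y = probs[ok], y[ok]
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    lods = _scan_matrix(probs, perms)  # markers x n_perm
    max_lods = lods.max(axis=0)
    threshold = float(np.quantile(max_lods, quantile, method="linear"))
    return PermutationResult(
        threshold=threshold, max_lods=max_lods, quantile=quantile, n_perm=n_perm
    )


def lod_support_interval(
    result: ScanResult, chromosome: str, drop: float = 1.5
) -> tuple[float, float]:
    """Support interval for a chromosome's QTL by the LOD-drop rule.

    The widest contiguous run of markers containing the chromosome peak
    whose LOD stays within ``drop`` of the peak; the endpoints are the
    outermost markers still within the drop, clipped at chromosome ends.
    Returns (lo, hi) positions in cM.
    """
    sub = result.table[result.table["chromosome"] == chromosome]
    if sub.empty:
        raise KeyError(f"chromosome {chromosome!r} not in scan")
    lod = sub["lod"].to_numpy()
    pos = sub["position_cm"].to_numpy()
    peak = int(np.argmax(lod))
    cut = lod[peak] - drop
    if np.ptp(lod) == 0:
        warnings.warn(
            f"flat LOD curve on chromosome {chromosome}; whole chromosome returned",
            stacklevel=2,
        )
        return float(pos[0]), float(pos[-1])
    lo = peak
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = peak
    while hi < len(lod) - 1 and lod[hi + 1] >= cut:
        hi += 1
    return float(pos[lo]), float(pos[hi])


def qtl_ld_test(
    panel: RILPanel, marker_a: str, marker_b: str
) -> tuple[float, int, float]:
    """Pearson chi-squared test of linkage disequilibrium between two QTL.

    Builds the 2x2 contingency table of strain alleles at the two markers
    (strains missing either genotype dropped) and applies the uncorrected
    chi-squared test with 1 degree of freedom.
    """
    ia, ib = panel.marker_index(marker_a), panel.marker_index(marker_b)
    ga = panel.genotypes[:, ia]
    gb = panel.genotypes[:, ib]
    ok = np.isfinite(ga) & np.isfinite(gb)
    ga, gb = ga[ok].astype(int), gb[ok].astype(int)
    counts = np.zeros((2, 2))
    for a, b in zip(ga, gb):
        counts[a, b] += 1
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("a marker is monomorphic; LD test undefined")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)
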