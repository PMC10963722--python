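"""Patterson D-statistic (ABBA/BABA) with weighted block jackknife.

Frequency form, AdmixTools sign convention:

    D = Σ_s (p_w − p_x)(p_y − p_z) / Σ_s (p_w + p_x − 2 p_w p_x)(p_y + p_z − 2 p_y p_z)

where p are derived-allele frequencies in the four populations W, X, Y, Z and
the numerator/denominator terms are the per-site BABA−ABBA and BABA+ABBA
expectations.  D(W, X, Y, Z) > 0 means W shares excess derived alleles with Y
relative to X.  The z-score comes from a leave-one-block-out weighted
jackknife over contiguous genomic blocks (Busing et al. 1999), the standard
treatment of linkage for this statistic.

Two screens built on D:

* African-admixture screen — D(X, French-like, African, outgroup) is
  significantly positive when X carries African admixture; such populations
  are excluded because African gene flow mimics Basal Eurasian ancestry in
  the sharing coordinates.
* EEC-source assignment — D(ASI-proxy, EastAsian, X, outgroup) is
  significantly negative when X's East Eurasian ancestry is East-Asian-like,
  positive when Andamanese-like, and near zero when both contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedValueError
from .genotypes import MISSING, PolarizedGenotypes

DEFAULT_BLOCK_SIZE = 5_000_000  # bp; ≈ the conventional 5 cM
DEFAULT_Z_THRESHOLD = 3.0


@dataclass
class DResult:
    D: float
    Z: float
    n_blocks: int
    n_abba: float
    n_baba: float
    n_sites: int

    def __post_init__(self):
        if not -1 - 1e-9 <= self.D <= 1 + 1e-9:
            raise ValueError(f"|D| > 1: {self.D}")


def _pop_frequencies(geno: PolarizedGenotypes, pop: str) -> np.ndarray:
    cols = geno.population_indices(pop)
    calls = geno.calls[:, cols]
    valid = calls != MISSING
    ploidy = geno.samples["ploidy"].to_numpy()[cols][None, :]
    n_alleles = (valid * ploidy).sum(axis=1)
    n_derived = np.where(valid, calls, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(n_alleles > 0, n_derived / np.maximum(n_alleles, 1), np.nan)


def d_statistic(
    geno: PolarizedGenotypes,
    w: str,
    x: str,
    y: str,
    z: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> DResult:
    """D(W, X, Y, Z) over sites with ≥1 non-missing call in all four
    populations; Z from the weighted block jackknife over ``block_size`` bp
    physical blocks."""
    freqs = np.column_stack([_pop_frequencies(geno, p) for p in (w, x, y, z)])
    ok = ~np.isnan(freqs).any(axis=1)
    if not ok.any():
        raise UndefinedValueError(f"D({w},{x},{y},{z}): no site with calls in all four")
    pw, px, py, pz = freqs[ok].T
    num = (pw - px) * (py - pz)  # BABA − ABBA
    den = (pw + px - 2 * pw * px) * (py + pz - 2 * py * pz)  # BABA + ABBA
    if den.sum() == 0:
        raise UndefinedValueError(f"D({w},{x},{y},{z}): no ABBA/BABA information")
    D = num.sum() / den.sum()
    baba = (den.sum() + num.sum()) / 2
    abba = (den.sum() - num.sum()) / 2

    chrom = geno.sites["chrom"].to_numpy()[ok]
    pos = geno.sites["pos"].to_numpy()[ok]
    block_key = np.array([f"{c}:{p // block_size}" for c, p in zip(chrom, pos)])
    blocks = [block_key == b for b in dict.fromkeys(block_key)]
    informative = [m for m in blocks if den[m].sum() > 0]
    n_blocks = len(informative)
    if n_blocks < 2:
        raise UndefinedValueError(
            f"D({w},{x},{y},{z}): {n_blocks} informative block(s); Z undefined"
        )
    Z = _weighted_jackknife_z(D, num, den, informative)
    return DResult(
        D=float(D),
        Z=float(Z),
        n_blocks=n_blocks,
        n_abba=float(abba),
        n_baba=float(baba),
        n_sites=int(ok.sum()),
    )


def _weighted_jackknife_z(D, num, den, blocks) -> float:
    """Busing-style delete-one weighted jackknife; block weight = its share of
    the denominator (the statistic's information content)."""
    tot_num, tot_den = num.sum(), den.sum()
    m = np.array([den[b].sum() for b in blocks])
    loo = np.array([(tot_num - num[b].sum()) / (tot_den - db) for b, db in zip(blocks, m)])
    n = len(blocks)
    M = m.sum()
    h = M / m
    pseudo = h * D - (h - 1) * loo
    theta_j = n * D - ((1 - m / M) * loo).sum()
    var = ((pseudo - theta_j) ** 2 / (h - 1)).sum() / n
    if var <= 0:
        return 0.0 if D == 0 else np.inf * np.sign(D)
    return D / np.sqrt(var)


@dataclass
class ScreenDecision:
    population: str
    keep: bool
    results: dict[str, DResult]


def screen_african_admixture(
    geno: PolarizedGenotypes,
    population: str,
    refs: tuple[str, list[str], str],
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> ScreenDecision:
    """Exclude ``population`` when D(X, French-like, African, outgroup) is
    significantly positive (Z ≥ threshold) for ANY of the African references.

    ``refs`` = (French-like population, list of African populations, outgroup).
    """
    french, africans, outgroup = refs
    results = {
        a: d_statistic(geno, population, french, a, outgroup, block_size)
        for a in africans
    }
    keep = all(r.Z < z_threshold for r in results.values())
    return ScreenDecision(population=population, keep=keep, results=results)


def assign_eec_source(
    geno: PolarizedGenotypes,
    population: str,
    quartet: tuple[str, str, str],
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> tuple[str, DResult]:
    """Which East-Eurasian source contributed to ``population``?

    Computes D(ASI-proxy, EastAsian, population, outgroup) with
    ``quartet = (ASI-proxy, EastAsian, outgroup)``.  Returns
    ``("EastAsian", result)`` when significantly negative, ``("Andamanese",
    result)`` when significantly positive and ``("average", result)``
    otherwise.
    """
    asi, east_asian, outgroup = quartet
    res = d_statistic(geno, asi, east_asian, population, outgroup, block_size)
    if res.Z <= -z_threshold:
        return "EastAsian", res
    if res.Z >= z_threshold:
        return "Andamanese", res
    return "average", res
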