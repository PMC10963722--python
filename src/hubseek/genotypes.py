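"""Genotype substrate: polarized biallelic sites × samples with derived-allele dosages.

The container stores, for every biallelic SNP, the dosage of one focal allele
per sample (0/1/2 for diploids, 0/1 for pseudo-haploids, -1 for missing).
Before :func:`polarize` the focal allele is simply the variant (alt) allele of
the source file; after polarization it is the derived allele, ancestral state
dosage 0.  All sharing statistics in the package operate on this substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StructuralError

MISSING = -1  # sentinel in the calls matrix

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")
SAMPLE_COLUMNS = ("id", "population", "ploidy")


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic site, polarized: ``ancestral_allele`` ≠ ``derived_allele``."""

    chromosome: str
    position: int
    ancestral_allele: str
    derived_allele: str

    def __post_init__(self):
        if self.ancestral_allele == self.derived_allele:
            raise ValueError(
                f"site {self.chromosome}:{self.position}: ancestral and derived "
                f"alleles are both {self.ancestral_allele!r}"
            )
        if self.position < 1:
            raise ValueError(f"position must be 1-based, got {self.position}")


@dataclass
class PolarizedGenotypes:
    """Sites × samples derived-allele dosage matrix with site/sample metadata.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom, pos, ref, alt``.  After polarization
        ``ref`` holds the ancestral and ``alt`` the derived allele.
    samples
        DataFrame with columns ``id, population, ploidy`` (ploidy 2 = diploid,
        1 = pseudo-haploid).
    calls
        ``int8`` array of shape (n_sites, n_samples); values are focal-allele
        dosages bounded by each sample's ploidy, or ``MISSING``.
    polarized
        True once dosages are counted against a known ancestral allele.
    provenance
        Append-only log of transformations and their site-attrition counts.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray
    polarized: bool = False
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if list(self.sites.columns[:4]) != list(SITE_COLUMNS):
            raise StructuralError(
                f"site table must have columns {SITE_COLUMNS}, got {tuple(self.sites.columns)}"
            )
        if list(self.samples.columns[:3]) != list(SAMPLE_COLUMNS):
            raise StructuralError(
                f"sample table must have columns {SAMPLE_COLUMNS}, got {tuple(self.samples.columns)}"
            )
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise StructuralError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites × {len(self.samples)} samples"
            )
        if (self.sites["ref"].values == self.sites["alt"].values).any():
            raise StructuralError("monomorphic site: ref == alt")
        # positions strictly increasing within each chromosome
        pos = self.sites["pos"].to_numpy()
        same_chrom = self.sites["chrom"].to_numpy()[1:] == self.sites["chrom"].to_numpy()[:-1]
        if (same_chrom & (np.diff(pos) <= 0)).any():
            raise StructuralError("positions not strictly increasing within a chromosome")
        ploidy = self.samples["ploidy"].to_numpy()
        if not np.isin(ploidy, (1, 2)).all():
            raise StructuralError("ploidy must be 1 (pseudo-haploid) or 2 (diploid)")
        bad = (self.calls != MISSING) & ((self.calls < 0) | (self.calls > ploidy[None, :]))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise StructuralError(
                f"dosage {self.calls[i, j]} at site {i}, sample "
                f"{self.samples['id'].iloc[j]!r} exceeds ploidy {ploidy[j]}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero(self.samples["id"].to_numpy() == sample_id)
        if idx.size == 0:
            raise ConfigurationError(f"unknown sample id {sample_id!r}")
        return int(idx[0])

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(self.samples["population"].to_numpy() == population)
        if idx.size == 0:
            raise ConfigurationError(f"unknown population {population!r}")
        return idx

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def take_sites(self, keep: np.ndarray, note: str | None = None) -> "PolarizedGenotypes":
        """New object restricted to the given site rows (bool mask or indices)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        out = replace(
            self,
            sites=self.sites.iloc[keep],
            calls=self.calls[keep],
            provenance=list(self.provenance),
        )
        if note:
            out.provenance.append(
                {"step": note, "sites_in": self.n_sites, "sites_out": out.n_sites}
            )
        return out


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def polarize(geno: PolarizedGenotypes, ancestral: dict) -> PolarizedGenotypes:
    """Recode dosages so 0 = homozygous ancestral.

    ``ancestral`` maps ``(chrom, pos)`` to the ancestral allele.  Sites with no
    ancestral assignment, or whose ancestral allele matches neither observed
    allele, are removed (counts recorded in provenance).  Sites where the
    ancestral equals the current alt allele have their dosages flipped.
    Idempotent: applying twice with the same map is a no-op on the survivors.
    """
    ref = geno.sites["ref"].to_numpy()
    alt = geno.sites["alt"].to_numpy()
    keys = list(zip(geno.sites["chrom"], geno.sites["pos"]))
    anc = np.array([ancestral.get(k, "") for k in keys], dtype=object)

    has_anc = anc != ""
    matches_ref = has_anc & (anc == ref)
    matches_alt = has_anc & (anc == alt)
    keep = matches_ref | matches_alt

    calls = geno.calls[keep].copy()
    flip = matches_alt[keep]
    ploidy = geno.samples["ploidy"].to_numpy()[None, :]
    block = calls[flip]
    miss = block == MISSING
    block = (ploidy - block).astype(np.int8)
    block[miss] = MISSING
    calls[flip] = block

    sites = geno.sites.loc[keep].copy()
    new_ref = np.where(flip, alt[keep], ref[keep])
    new_alt = np.where(flip, ref[keep], alt[keep])
    sites["ref"] = new_ref
    sites["alt"] = new_alt

    out = PolarizedGenotypes(
        sites=sites,
        samples=geno.samples,
        calls=calls,
        polarized=True,
        provenance=list(geno.provenance),
    )
    out.provenance.append(
        {
            "step": "polarize",
            "sites_in": geno.n_sites,
            "sites_out": out.n_sites,
            "no_ancestral_call": int((~has_anc).sum()),
            "ancestral_mismatch": int((has_anc & ~keep).sum()),
            "flipped": int(flip.sum()),
        }
    )
    return out


def mask_archaic_shared(
    geno: PolarizedGenotypes, archaic_samples: list[str]
) -> PolarizedGenotypes:
    """Drop sites at which any archaic genome carries ≥1 derived allele.

    A missing archaic call does not trigger removal (absence of evidence must
    not delete data).  Archaic sample columns are dropped from the output.
    """
    cols = np.array([geno.sample_index(s) for s in archaic_samples])
    derived = geno.calls[:, cols] >= 1
    drop = derived.any(axis=1)

    keep_cols = np.setdiff1d(np.arange(geno.n_samples), cols)
    out = PolarizedGenotypes(
        sites=geno.sites.loc[~drop],
        samples=geno.samples.iloc[keep_cols],
        calls=geno.calls[np.ix_(~drop, keep_cols)],
        polarized=geno.polarized,
        provenance=list(geno.provenance),
    )
    out.provenance.append(
        {
            "step": "mask_archaic_shared",
            "sites_in": geno.n_sites,
            "sites_out": out.n_sites,
            "archaic_derived_sites_removed": int(drop.sum()),
        }
    )
    return out


def filter_missingness(
    geno: PolarizedGenotypes, max_missing: float = 0.25
) -> PolarizedGenotypes:
    """Drop sites whose fraction of missing calls exceeds ``max_missing``."""
    if not 0 <= max_missing <= 1:
        raise ValueError(f"max_missing must be in [0, 1], got {max_missing}")
    frac = (geno.calls == MISSING).mean(axis=1)
    return geno.take_sites(frac <= max_missing, note="filter_missingness")


def pseudo_haploidize(
    geno: PolarizedGenotypes, seed: int, samples: list[str] | None = None
) -> PolarizedGenotypes:
    """Replace diploid calls by a single randomly sampled allele per site.

    The standard ancient-DNA representation: heterozygotes become 0 or 1 with
    equal probability, homozygotes keep their allele, ploidy drops to 1.  The
    expected sampled-allele state is linear in the underlying allele
    frequency, which makes the sharing statistic exactly linear under
    admixture — the property the deconfounding algebra inverts.  Deterministic
    given ``seed``; ``samples`` restricts the operation (default: all diploid
    samples).
    """
    rng = np.random.default_rng(seed)
    ids = geno.samples["id"].to_numpy()
    if samples is None:
        cols = np.flatnonzero(geno.samples["ploidy"].to_numpy() == 2)
    else:
        cols = np.array([geno.sample_index(s) for s in samples])
    calls = geno.calls.copy()
    block = calls[:, cols]
    draw = rng.integers(0, 2, size=block.shape).astype(np.int8)
    block = np.where(block == 1, draw, np.where(block == 2, 1, block)).astype(np.int8)
    calls[:, cols] = block
    new_samples = geno.samples.copy()
    new_samples.loc[new_samples.index[cols], "ploidy"] = 1
    out = PolarizedGenotypes(
        sites=geno.sites,
        samples=new_samples,
        calls=calls,
        polarized=geno.polarized,
        provenance=list(geno.provenance),
    )
    out.provenance.append(
        {"step": "pseudo_haploidize", "seed": seed, "n_samples": len(cols)}
    )
    return out


def swap_polarization(
    geno: PolarizedGenotypes, fraction: float, seed: int
) -> PolarizedGenotypes:
    """Invert ancestral/derived labels at ⌊fraction·n⌋ uniformly random sites.

    Deterministic given ``seed``; an involution (same seed applied twice
    restores the input).  Used to probe robustness of downstream rankings to
    mis-polarization.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    n_swap = int(fraction * geno.n_sites)
    chosen = rng.choice(geno.n_sites, size=n_swap, replace=False)
    flip = np.zeros(geno.n_sites, dtype=bool)
    flip[chosen] = True

    calls = geno.calls.copy()
    ploidy = geno.samples["ploidy"].to_numpy()[None, :]
    block = calls[flip]
    miss = block == MISSING
    block = (ploidy - block).astype(np.int8)
    block[miss] = MISSING
    calls[flip] = block

    sites = geno.sites.copy()
    ref = sites["ref"].to_numpy().copy()
    alt = sites["alt"].to_numpy().copy()
    ref[flip], alt[flip] = alt[flip].copy(), ref[flip].copy()
    sites["ref"] = ref
    sites["alt"] = alt

    out = PolarizedGenotypes(
        sites=sites,
        samples=geno.samples,
        calls=calls,
        polarized=geno.polarized,
        provenance=list(geno.provenance),
    )
    out.provenance.append(
        {"step": "swap_polarization", "fraction": fraction, "seed": seed, "swapped": n_swap}
    )
    return out
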