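"""Derived-allele-sharing (DAS) coordinates against reference ancient genomes.

The DAS of a target with a reference sample is the proportion of the
reference's derived alleles that the target also carries: over sites where the
reference carries ≥1 derived allele and the target is non-missing, the
fraction at which the target carries ≥1 derived allele.  The "carries ≥1
derived" predicate treats diploid and pseudo-haploid samples identically, so
the statistic is free of ploidy bias.  A population's coordinate is the
unweighted mean of its members' individual values.

Coordinates are conventionally named after the references: K (Kostenki14-like,
the West Eurasian Core proxy), T (Tianyuan-like, the East Eurasian Core
proxy) and U (Ust'Ishim-like, near-trifurcating with both and therefore a
Basal-ancestry dial).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import UndefinedValueError
from .genotypes import MISSING, PolarizedGenotypes


def _sharing_matrix(
    geno: PolarizedGenotypes, reference: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (shared count, valid count) against one reference sample."""
    r = geno.sample_index(reference)
    ref_derived = geno.calls[:, r] >= 1
    calls = geno.calls[ref_derived]
    valid = calls != MISSING
    shared = valid & (calls >= 1)
    return shared.sum(axis=0), valid.sum(axis=0)


def derived_allele_sharing(
    geno: PolarizedGenotypes, target: str, reference: str
) -> tuple[float, int]:
    """DAS of ``target`` (a sample id or a population label) with ``reference``.

    Returns ``(fraction, n_sites)``; for a population the fraction is the mean
    of its members' values and ``n_sites`` the smallest member count.
    Raises :class:`UndefinedValueError` when a member has zero qualifying sites.
    """
    shared, valid = _sharing_matrix(geno, reference)
    ids = geno.samples["id"].to_numpy()
    if (ids == target).any():
        cols = np.flatnonzero(ids == target)[:1]
    else:
        cols = geno.population_indices(target)
    if (valid[cols] == 0).any():
        bad = geno.samples["id"].iloc[cols[valid[cols] == 0][0]]
        raise UndefinedValueError(
            f"DAS({bad!r}, {reference!r}) undefined: zero qualifying sites"
        )
    fractions = shared[cols] / valid[cols]
    return float(fractions.mean()), int(valid[cols].min())


def individual_das_table(
    geno: PolarizedGenotypes, refs: dict[str, str]
) -> pd.DataFrame:
    """Per-individual DAS with each named reference.

    ``refs`` maps coordinate name (e.g. ``"K"``) to the reference sample id.
    Individuals with zero qualifying sites for a reference get NaN.
    """
    out = geno.samples[["id", "population"]].copy()
    for name, ref in refs.items():
        shared, valid = _sharing_matrix(geno, ref)
        with np.errstate(invalid="ignore"):
            out[name] = np.where(valid > 0, shared / np.maximum(valid, 1), np.nan)
        out[f"n_sites_{name}"] = valid
    return out


def compute_coordinates(
    geno: PolarizedGenotypes,
    refs: dict[str, str],
    populations: list[str] | None = None,
    per_chromosome_mean: bool = False,
) -> pd.DataFrame:
    """Tidy per-population DAS coordinate table.

    One row per population with columns ``K, T, U, …`` (whatever ``refs``
    names) and matching ``n_sites_*`` counts (summed over members).  With
    ``per_chromosome_mean`` each individual's coordinate is first computed per
    chromosome and then averaged across chromosomes — the convention used for
    simulated genome chunks — ignoring chromosomes with no qualifying site.
    """
    populations = populations or geno.populations()
    if per_chromosome_mean:
        chroms = geno.sites["chrom"].to_numpy()
        per_chrom = []
        for c in dict.fromkeys(chroms):
            sub = geno.take_sites(chroms == c)
            per_chrom.append(individual_das_table(sub, refs))
        indiv = per_chrom[0][["id", "population"]].copy()
        for name in refs:
            stack = np.array([t[name].to_numpy() for t in per_chrom])
            with np.errstate(invalid="ignore"):
                indiv[name] = np.nanmean(stack, axis=0)
            indiv[f"n_sites_{name}"] = np.array(
                [t[f"n_sites_{name}"].to_numpy() for t in per_chrom]
            ).sum(axis=0)
    else:
        indiv = individual_das_table(geno, refs)

    rows = []
    for pop in populations:
        members = indiv[indiv["population"] == pop]
        row = {"population": pop}
        for name in refs:
            vals = members[name].to_numpy()
            if np.isnan(vals).any():
                raise UndefinedValueError(
                    f"DAS({pop!r}, {refs[name]!r}) undefined for some members: "
                    "zero qualifying sites"
                )
            row[name] = float(vals.mean())
            row[f"n_sites_{name}"] = int(members[f"n_sites_{name}"].sum())
        rows.append(row)
    return pd.DataFrame(rows)
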