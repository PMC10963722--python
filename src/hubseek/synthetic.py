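"""Synthetic fixtures: chimeric genomes and self-contained test cohorts.

A chimera is assembled by whole-chromosome donation: every chromosome of the
genome is copied verbatim from one donor individual, drawn from one of three
source populations.  Because a sharing coordinate is a per-site average, the
chimera's expected coordinate is the SNP-count-weighted mean of its donors'
coordinates — the linearity on which the whole deconfounding algebra rests —
and comparing the empirical and analytic values measures how well that holds
at a given SNP count.

The module also writes small on-disk fixtures (EIGENSTRAT triplets, location
tables, ASCII rasters) with accompanying truth files, so every other module
can be tested without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .das import individual_das_table
from .errors import ConfigurationError, UndefinedValueError
from .focal import Raster, overland_distance, write_ascii_grid
from .genotypes import MISSING, PolarizedGenotypes
from .io import write_eigenstrat


@dataclass
class ChimeraPlan:
    """Assignment of every chromosome to one (source population, donor id)."""

    sources: tuple[str, str, str]
    assignment: dict[str, tuple[str, str]]  # chrom -> (source pop, donor sample id)
    true_weights: dict[str, float] = field(default_factory=dict)  # per source, SNP share

    def donors(self) -> list[str]:
        return list(dict.fromkeys(d for _, d in self.assignment.values()))


def round_robin_plan(
    geno: PolarizedGenotypes,
    sources: tuple[str, str, str],
    target_weights: tuple[float, float, float],
    individuals_per_source: int = 4,
    seed: int = 0,
) -> ChimeraPlan:
    """Assign chromosomes to sources so realized SNP shares approach the
    target weights, cycling through each source's donor individuals.

    Chromosomes are walked in descending SNP count and each is given to the
    source whose realized share lags its target the most (largest-remainder
    style), then to that source's next donor in rotation.
    """
    rng = np.random.default_rng(seed)
    counts = geno.sites.groupby("chrom", sort=False)["pos"].count()
    total = counts.sum()
    donor_pool = {}
    for s in sources:
        ids = geno.samples.loc[geno.samples["population"] == s, "id"].tolist()
        if len(ids) < individuals_per_source:
            raise ConfigurationError(
                f"source {s!r} has {len(ids)} individuals, need {individuals_per_source}"
            )
        donor_pool[s] = list(rng.permutation(ids[:individuals_per_source]))
    got = dict.fromkeys(sources, 0.0)
    rotation = dict.fromkeys(sources, 0)
    assignment = {}
    for chrom in counts.sort_values(ascending=False).index:
        deficit = {s: t - got[s] / total for s, t in zip(sources, target_weights)}
        pick = max(sources, key=lambda s: deficit[s])
        donor = donor_pool[pick][rotation[pick] % individuals_per_source]
        rotation[pick] += 1
        assignment[chrom] = (pick, donor)
        got[pick] += counts[chrom]
    return ChimeraPlan(
        sources=sources,
        assignment=assignment,
        true_weights={s: got[s] / total for s in sources},
    )


def build_chimera(
    geno: PolarizedGenotypes, plan: ChimeraPlan
) -> tuple[np.ndarray, dict[str, float]]:
    """Chimeric call column plus realized per-source SNP-share weights."""
    chroms = geno.sites["chrom"].to_numpy()
    present = set(chroms)
    missing = [c for c in plan.assignment if c not in present]
    if missing:
        raise ConfigurationError(f"planned chromosomes absent from data: {missing}")
    unplanned = present - set(plan.assignment)
    if unplanned:
        raise ConfigurationError(f"chromosomes without a plan entry: {sorted(unplanned)}")
    calls = np.full(geno.n_sites, MISSING, dtype=np.int8)
    counts = dict.fromkeys(plan.sources, 0)
    for chrom, (source, donor) in plan.assignment.items():
        rows = chroms == chrom
        calls[rows] = geno.calls[rows, geno.sample_index(donor)]
        counts[source] += int(rows.sum())
    total = sum(counts.values())
    weights = {s: c / total for s, c in counts.items()}
    plan.true_weights = weights
    return calls, weights


def add_chimeras(
    geno: PolarizedGenotypes, plans: dict[str, ChimeraPlan]
) -> PolarizedGenotypes:
    """Append one sample column per chimera (population label = chimera name)."""
    cols, rows = [], []
    for name, plan in plans.items():
        calls, _ = build_chimera(geno, plan)
        cols.append(calls)
        rows.append((name, name, 2))
    return PolarizedGenotypes(
        sites=geno.sites,
        samples=pd.concat(
            [geno.samples, pd.DataFrame(rows, columns=["id", "population", "ploidy"])],
            ignore_index=True,
        ),
        calls=np.column_stack([geno.calls] + cols),
        polarized=geno.polarized,
        provenance=list(geno.provenance),
    )


def analytic_coordinate(
    geno: PolarizedGenotypes, plan: ChimeraPlan, reference: str
) -> float:
    """SNP-count-weighted mean of the donor individuals' genome-wide DAS."""
    chroms = geno.sites["chrom"].to_numpy()
    das = individual_das_table(geno, {"c": reference}).set_index("id")["c"]
    weights: dict[str, float] = {}
    for chrom, (_, donor) in plan.assignment.items():
        weights[donor] = weights.get(donor, 0) + int((chroms == chrom).sum())
    total = sum(weights.values())
    value = sum(w / total * das[d] for d, w in weights.items())
    if np.isnan(value):
        raise UndefinedValueError("a donor has an undefined DAS with the reference")
    return float(value)


def verify_linearity(
    geno_with_chimeras: PolarizedGenotypes,
    plans: dict[str, ChimeraPlan],
    refs: dict[str, str],
) -> pd.DataFrame:
    """Empirical vs analytic coordinates for each chimera and reference.

    Returns a tidy frame (chimera, coordinate, empirical, analytic, ratio);
    ``.attrs['max_abs_dev']`` holds max |ratio − 1|."""
    das = individual_das_table(geno_with_chimeras, refs).set_index("id")
    rows = []
    for name, plan in plans.items():
        for coord, ref in refs.items():
            emp = float(das.loc[name, coord])
            ana = analytic_coordinate(geno_with_chimeras, plan, ref)
            if ana == 0:
                raise UndefinedValueError(
                    f"analytic {coord} of {name!r} is zero; ratio undefined"
                )
            rows.append(
                {"chimera": name, "coordinate": coord, "empirical": emp,
                 "analytic": ana, "ratio": emp / ana}
            )
    out = pd.DataFrame(rows)
    out.attrs["max_abs_dev"] = float((out["ratio"] - 1).abs().max())
    return out


def simulate_chimera_sources(
    n_chromosomes: int = 22,
    chromosome_length: float = 125e6,
    piece_length: float = 5e6,
    seed: int = 1,
    individuals_per_source: int = 4,
):
    """Simulate three well-diverged sources (African-, WEC- and EEC-like,
    mirroring the Gumuz/Sunghir/Han trio of the real chimera check) plus the
    Kostenki14- and Tianyuan-like references.

    22 chromosomes of 125 Mb — the mean human autosome length — stand in for
    the real autosomes.  Total genome LENGTH, not SNP count, controls the
    chimera linearity regime: the deviation of a chimera's coordinate from
    the weighted-donor mean has variance Σ w_c² σ_c² with the per-chromosome
    spread σ_c² inversely proportional to the number of independent gene
    trees, so the product depends only on the simulated total.  Each
    chromosome is therefore assembled from independently simulated
    ``piece_length`` segments (free recombination at the joins, slightly
    conservative), which keeps coalescent cost linear in genome size.

    Returns (geno, sources) where sources = ("WEC", "EEC", "AFR").
    """
    from .simulate import build_demography, simulate_cohort

    model = build_demography(
        compositions=[],
        sample_sizes={
            "AFR": individuals_per_source, "WEC": individuals_per_source,
            "EEC": individuals_per_source, "BEA": 0, "WEC2": 0,
        },
    )
    pieces_per_chrom = max(1, int(round(chromosome_length / piece_length)))
    geno = simulate_cohort(
        model, n_chunks=n_chromosomes * pieces_per_chrom,
        chunk_length=piece_length, seed=seed,
    )
    # regroup pieces into chromosomes with offset, strictly increasing positions
    piece_idx = geno.sites["chrom"].str.removeprefix("chunk").astype(int)
    chrom_idx = piece_idx // pieces_per_chrom
    offset = (piece_idx % pieces_per_chrom) * int(piece_length)
    sites = geno.sites.copy()
    sites["chrom"] = [f"chr{i + 1:02d}" for i in chrom_idx]
    sites["pos"] = geno.sites["pos"] + offset
    geno = PolarizedGenotypes(
        sites=sites, samples=geno.samples, calls=geno.calls,
        polarized=True, provenance=list(geno.provenance),
    )
    return geno, ("WEC", "EEC", "AFR")


def chimera_linearity_experiment(
    n_chromosomes: int = 22,
    chromosome_length: float = 125e6,
    seed: int = 1,
    target_weight_sets: list[tuple[float, float, float]] | None = None,
) -> pd.DataFrame:
    """End-to-end linearity check on simulated three-source chimeras.

    Builds one chimera per target-weight triple (WEC, EEC, AFR shares) and
    compares empirical K and T against the SNP-count-weighted analytic
    prediction.  Returns the :func:`verify_linearity` table."""
    targets = target_weight_sets or [
        (0.5, 0.3, 0.2), (0.34, 0.33, 0.33), (0.7, 0.2, 0.1),
        (0.2, 0.6, 0.2), (0.45, 0.1, 0.45), (0.1, 0.3, 0.6),
    ]
    geno, sources = simulate_chimera_sources(
        n_chromosomes=n_chromosomes, chromosome_length=chromosome_length, seed=seed
    )
    plans = {
        f"chimera{i}": round_robin_plan(geno, sources, t, seed=seed + i)
        for i, t in enumerate(targets)
    }
    merged = add_chimeras(geno, plans)
    return verify_linearity(merged, plans, {"K": "KOS_0", "T": "TIA_0"})


# ---------------------------------------------------------------------------
# on-disk fixtures
# ---------------------------------------------------------------------------

def generate_fixture(kind: str, out_dir: str | Path, seed: int = 0, **params) -> dict:
    """Write a deterministic fixture set under ``out_dir`` and return a truth
    dict (also saved as ``truth.json``).

    Kinds: ``toy_matrix`` (tiny EIGENSTRAT triplet with enumerated DAS truth),
    ``gradient_cohort`` (landmask + locations with a planted focal source) and
    ``dstat_quartet`` (EIGENSTRAT quartet with a directly computed D truth).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maker = {
        "toy_matrix": _toy_matrix_fixture,
        "gradient_cohort": _gradient_cohort_fixture,
        "dstat_quartet": _dstat_quartet_fixture,
    }.get(kind)
    if maker is None:
        raise ValueError(f"unknown fixture kind {kind!r}")
    truth = maker(out, seed, **params)
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return truth


def _toy_matrix_fixture(out: Path, seed: int, n_sites: int = 12, n_samples: int = 4):
    rng = np.random.default_rng(seed)
    calls = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.1] = MISSING
    calls[:, 0] = np.where(calls[:, 0] == MISSING, 0, calls[:, 0])  # reference: complete
    sites = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, n_sites + 1) * 100, "ref": "A", "alt": "G"}
    )
    samples = pd.DataFrame(
        {"id": [f"s{i}" for i in range(n_samples)],
         "population": ["ref"] + ["pop"] * (n_samples - 1), "ploidy": 2}
    )
    geno = PolarizedGenotypes(sites=sites, samples=samples, calls=calls, polarized=True)
    write_eigenstrat(geno, out / "toy")
    # truth by explicit per-site enumeration, independent of the vectorized path
    truth = {"das_vs_s0": {}}
    for j in range(1, n_samples):
        shared = valid = 0
        for i in range(n_sites):
            if calls[i, 0] >= 1 and calls[i, j] != MISSING:
                valid += 1
                if calls[i, j] >= 1:
                    shared += 1
        truth["das_vs_s0"][f"s{j}"] = {"shared": shared, "valid": valid}
    return truth


def _gradient_cohort_fixture(
    out: Path, seed: int, shape: tuple[int, int] = (15, 20),
    n_locations: int = 12, decay_per_km: float = 1e-4,
):
    rng = np.random.default_rng(seed)
    nrows, ncols = shape
    mask = Raster(
        values=np.ones((nrows, ncols)), xllcorner=20.0, yllcorner=25.0, cellsize=1.0
    )
    source = (int(rng.integers(2, nrows - 2)), int(rng.integers(2, ncols - 2)))
    cells = [
        (int(r), int(c))
        for r, c in zip(rng.integers(0, nrows, n_locations), rng.integers(0, ncols, n_locations))
    ]
    cells[0] = source  # guarantee a sample at the source itself
    dists = overland_distance(mask, source, cells)
    rows = []
    for k, ((r, c), d) in enumerate(zip(cells, dists)):
        lon, lat = mask.cell_center(r, c)
        rows.append({"population": f"pop{k}", "lon": lon, "lat": lat,
                     "value": float(np.exp(-decay_per_km * d))})
    pd.DataFrame(rows).to_csv(out / "locations.tsv", sep="\t", index=False)
    write_ascii_grid(mask, out / "landmask.asc")
    return {"source_cell": list(source), "decay_per_km": decay_per_km}


def _dstat_quartet_fixture(out: Path, seed: int, n_sites: int = 400, n_per_pop: int = 4):
    rng = np.random.default_rng(seed)
    pops = ["W", "X", "Y", "Z"]
    freqs = rng.random((n_sites, 4)) * np.array([0.8, 0.8, 0.8, 0.2])
    calls = np.concatenate(
        [rng.binomial(2, freqs[:, [j]], size=(n_sites, n_per_pop)) for j in range(4)],
        axis=1,
    ).astype(np.int8)
    sites = pd.DataFrame(
        {"chrom": np.repeat(["1", "2"], n_sites // 2),
         "pos": np.tile(np.arange(1, n_sites // 2 + 1) * 1000, 2),
         "ref": "A", "alt": "G"}
    )
    samples = pd.DataFrame(
        {"id": [f"{p}{i}" for p in pops for i in range(n_per_pop)],
         "population": np.repeat(pops, n_per_pop), "ploidy": 2}
    )
    geno = PolarizedGenotypes(sites=sites, samples=samples, calls=calls, polarized=True)
    write_eigenstrat(geno, out / "quartet")
    # direct-formula truth from realized sample frequencies
    p = np.stack([calls[:, i * n_per_pop:(i + 1) * n_per_pop].mean(axis=1) / 2
                  for i in range(4)], axis=1)
    pw, px, py, pz = p.T
    num = ((pw - px) * (py - pz)).sum()
    den = ((pw + px - 2 * pw * px) * (py + pz - 2 * py * pz)).sum()
    return {"D": float(num / den)}
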