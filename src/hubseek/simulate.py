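"""Coalescent validation of the hub-ranking pipeline.

The demographic scenario mirrors the history the sharing coordinates are
designed for: an Out-of-Africa bottleneck at 60 kya, Basal Eurasians
splitting soon after (57.5 kya) and staying isolated, and the East/West
Eurasian Core (EEC/WEC) divergence at 46 kya when the EEC expansion leaves
the hub.  Three ancient reference individuals — Kostenki14-like (38 kya, WEC
lineage), Tianyuan-like (40 kya, EEC lineage) and Ust'Ishim-like (45 kya,
near-trifurcating with both) — branch off 34 generations (~1000 years)
before their deaths.  Two West Eurasian populations are simulated: WEC, and
WEC2 which stays on the hub stem ``wec2_offset_ky`` thousand years longer
and therefore shares that much less drift with the Kostenki14 lineage.

Admixed populations are formed from {WEC or WEC2} × EEC × Basal sources on a
composition grid; the experiment asks how often the deconfounding algebra
ranks the WEC2-sourced population (truly closer to the hub) below the
WEC-sourced one on K_B, for every pair of compositions.

Effective sizes follow the classic three-population Out-of-Africa fit:
ancestral 7310, African 14474 (from 148 kya), out-of-Africa bottleneck 1861,
post-divergence sizes 1032 (WEC-like) / 554 (EEC-like) with exponential
growth 0.38%/0.48% per generation over the most recent 23 ky.  Mutation
1.25e-8 and recombination 1e-8 per bp per generation, generation time 29.4 y
(so 34 generations ≈ 1000 years).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd
from scipy import stats

from .correction import ReferenceBaselines, correct_population
from .das import compute_coordinates
from .errors import HubseekError, UndefinedValueError
from .genotypes import PolarizedGenotypes, pseudo_haploidize

REF_POPS = ("KOS", "TIA", "UST")
MODERN_EURASIAN_PANEL = ("WEC", "WEC2", "EEC")  # ascertainment panel


@dataclass(frozen=True)
class SimulationParams:
    generation_time: float = 29.4  # years; 34 generations ≈ 1000 years
    mutation_rate: float = 1.25e-8
    recombination_rate: float = 1e-8
    t_ooa_ky: float = 60.0
    t_basal_ky: float = 57.5
    t_split_ky: float = 46.0  # EEC/WEC divergence (EEC leaves the hub)
    kostenki_age_ky: float = 38.0
    tianyuan_age_ky: float = 40.0
    ustishim_age_ky: float = 45.0
    ref_branch_generations: int = 34
    admix_time_ky: float = 1.5
    afr_expansion_ky: float = 148.0
    growth_onset_ky: float = 23.0
    n_ancestral: float = 7310
    n_afr: float = 14474
    n_bottleneck: float = 1861
    n_eec0: float = 554
    n_wec0: float = 1032
    growth_eec: float = 0.0048
    growth_wec: float = 0.0038
    n_admixed: float = 10000  # modern human-scale size for the admixed cohorts
    # present-day sizes the kamm_style growth targets (classic OoA fit values)
    n_eec_present: float = 45852
    n_wec_present: float = 33189

    def gens(self, kya: float) -> float:
        return kya * 1000.0 / self.generation_time

    @property
    def ref_branch_ky(self) -> float:
        return self.ref_branch_generations * self.generation_time / 1000.0


def default_composition_grid() -> list[tuple[float, float, float]]:
    """(WEC, EEC, Basal) fractions: WEC ∈ {0.25 … 1.0} × Basal ∈ {0 … 0.3},
    EEC the remainder; combinations with a negative remainder are dropped."""
    grid = []
    for w in (0.25, 0.5, 0.75, 1.0):
        for b in (0.0, 0.1, 0.2, 0.3):
            e = round(1.0 - w - b, 10)
            if e >= 0:
                grid.append((w, e, b))
    return grid


def composition_label(comp: tuple[float, float, float]) -> str:
    """Percent-based label, e.g. (0.5, 0.3, 0.2) → ``W50_E30_B20``."""
    w, e, b = comp
    return f"W{round(w * 100)}_E{round(e * 100)}_B{round(b * 100)}"


@dataclass
class HubDemography:
    """A built scenario: msprime demography plus sampling/metadata."""

    demography: msprime.Demography
    sample_sets: list
    samples: pd.DataFrame  # id, population, role
    compositions: list[tuple[float, float, float]]
    scenario: str
    wec2_offset_ky: float
    params: SimulationParams
    events: list = field(default_factory=list)


def build_demography(
    scenario: str = "gravel_style",
    wec2_offset_ky: float = 3.0,
    compositions: list[tuple[float, float, float]] | None = None,
    params: SimulationParams | None = None,
    sample_sizes: dict[str, int] | None = None,
    n_admixed_diploids: int = 4,
) -> HubDemography:
    """Assemble the validation demography.

    ``sample_sizes`` overrides the modern sampling (defaults: 4 diploids each
    of BEA, EEC, WEC, WEC2; AFR present in the model but unsampled).
    """
    p = params or SimulationParams()
    compositions = default_composition_grid() if compositions is None else compositions
    if scenario not in ("gravel_style", "kamm_style"):
        raise ValueError(f"unknown scenario {scenario!r}")

    kos_branch = p.kostenki_age_ky + p.ref_branch_ky
    tia_branch = p.tianyuan_age_ky + p.ref_branch_ky
    ust_branch = p.ustishim_age_ky + p.ref_branch_ky
    wec2_branch = kos_branch + wec2_offset_ky
    if not (p.t_ooa_ky > p.t_basal_ky > p.t_split_ky):
        raise HubseekError("event times must be ordered OoA > Basal split > EEC/WEC split")
    if ust_branch > p.t_split_ky:
        raise HubseekError("Ust'Ishim-like branch point precedes the EEC/WEC split")
    if wec2_branch >= ust_branch:
        raise HubseekError(
            f"wec2_offset_ky={wec2_offset_ky} pushes the WEC2 divergence past the "
            "Ust'Ishim-like branch point"
        )
    if tia_branch >= p.t_split_ky:
        raise HubseekError("Tianyuan-like branch point precedes the EEC/WEC split")

    dem = msprime.Demography()
    g = p.gens
    if scenario == "gravel_style":
        n_eec_now = p.n_eec0 * np.exp(p.growth_eec * g(p.growth_onset_ky))
        n_wec_now = p.n_wec0 * np.exp(p.growth_wec * g(p.growth_onset_ky))
        r_eec, r_wec = p.growth_eec, p.growth_wec
    else:  # kamm_style: founding bottleneck at the divergence, growth throughout
        n_eec_now, n_wec_now = p.n_eec_present, p.n_wec_present
        r_eec = np.log(n_eec_now / p.n_bottleneck) / g(p.t_split_ky)
        r_wec = np.log(n_wec_now / p.n_bottleneck) / g(p.t_split_ky)

    dem.add_population(name="AFR", initial_size=p.n_afr, initially_active=True)
    dem.add_population(name="OOA", initial_size=p.n_bottleneck)
    dem.add_population(name="BEA", initial_size=p.n_bottleneck, initially_active=True)
    dem.add_population(name="EEC", initial_size=n_eec_now, growth_rate=r_eec,
                       initially_active=True)
    dem.add_population(name="WEC", initial_size=n_wec_now, growth_rate=r_wec,
                       initially_active=True)
    dem.add_population(name="WEC2", initial_size=n_wec_now, growth_rate=r_wec,
                       initially_active=True)
    for name in REF_POPS:
        dem.add_population(name=name, initial_size=p.n_bottleneck)

    admixed = []
    for src in ("WEC", "WEC2"):
        for comp in compositions:
            name = f"ADM_{src}_{composition_label(comp)}"
            admixed.append((name, src, comp))
            dem.add_population(name=name, initial_size=p.n_admixed)
            w, e, b = comp
            ancestral = [a for a, f in zip((src, "EEC", "BEA"), (w, e, b)) if f > 0]
            fracs = [f for f in (w, e, b) if f > 0]
            if len(ancestral) == 1:
                dem.add_population_split(time=g(p.admix_time_ky), derived=[name],
                                         ancestral=ancestral[0])
            else:
                dem.add_admixture(time=g(p.admix_time_ky), derived=name,
                                  ancestral=ancestral, proportions=fracs)

    if scenario == "gravel_style":
        for pop, n0 in (("EEC", p.n_eec0), ("WEC", p.n_wec0), ("WEC2", p.n_wec0)):
            dem.add_population_parameters_change(
                time=g(p.growth_onset_ky), population=pop, initial_size=n0, growth_rate=0
            )
    dem.add_population_split(time=g(kos_branch), derived=["KOS"], ancestral="WEC")
    dem.add_population_split(time=g(tia_branch), derived=["TIA"], ancestral="EEC")
    dem.add_population_split(time=g(wec2_branch), derived=["WEC2"], ancestral="WEC")
    dem.add_population_split(time=g(ust_branch), derived=["UST"], ancestral="WEC")
    dem.add_population_split(time=g(p.t_split_ky), derived=["EEC", "WEC"], ancestral="OOA")
    dem.add_population_split(time=g(p.t_basal_ky), derived=["BEA"], ancestral="OOA")
    dem.add_population_split(time=g(p.t_ooa_ky), derived=["OOA"], ancestral="AFR")
    dem.add_population_parameters_change(
        time=g(p.afr_expansion_ky), population="AFR", initial_size=p.n_ancestral
    )
    dem.sort_events()

    sizes = {"BEA": 4, "EEC": 4, "WEC": 4, "WEC2": 4, "AFR": 0}
    if sample_sizes:
        sizes.update(sample_sizes)
    sample_sets, rows = [], []
    ages = {"KOS": p.kostenki_age_ky, "TIA": p.tianyuan_age_ky, "UST": p.ustishim_age_ky}
    for pop, n in sizes.items():
        if n > 0:
            sample_sets.append(msprime.SampleSet(n, population=pop, time=0))
            rows += [(f"{pop}_{i}", pop, "modern") for i in range(n)]
    for name, comp_src in [(a[0], a[1]) for a in admixed]:
        sample_sets.append(msprime.SampleSet(n_admixed_diploids, population=name, time=0))
        rows += [(f"{name}_{i}", name, "admixed") for i in range(n_admixed_diploids)]
    for pop in REF_POPS:
        sample_sets.append(msprime.SampleSet(1, population=pop, time=g(ages[pop])))
        rows.append((f"{pop}_0", pop, "ancient_reference"))

    samples = pd.DataFrame(rows, columns=["id", "population", "role"])
    events = [
        ("admixture", p.admix_time_ky), ("KOS branch", kos_branch),
        ("TIA branch", tia_branch), ("WEC2 split", wec2_branch),
        ("UST branch", ust_branch), ("EEC/WEC split", p.t_split_ky),
        ("BEA split", p.t_basal_ky), ("OoA", p.t_ooa_ky),
    ]
    return HubDemography(
        demography=dem, sample_sets=sample_sets, samples=samples,
        compositions=compositions, scenario=scenario,
        wec2_offset_ky=wec2_offset_ky, params=p, events=events,
    )


# ---------------------------------------------------------------------------
# simulation → PolarizedGenotypes
# ---------------------------------------------------------------------------

def simulate_cohort(
    model: HubDemography,
    n_chunks: int = 10,
    chunk_length: float = 5e6,
    seed: int = 1,
    pseudo_haploid: bool = True,
) -> PolarizedGenotypes:
    """Simulate ``n_chunks`` independent genome chunks and stack them as
    chromosomes of one polarized genotype matrix (truth polarization: the
    simulated ancestral state is dosage 0).  Deterministic given ``seed``;
    a chunk with zero segregating sites is resimulated with a warning.

    By default every sample is pseudo-haploidized (one sampled allele per
    site), the representation of the capture data the method targets; it also
    keeps the sharing statistic linear under admixture, the regime in which
    the deconfounding algebra is exact."""
    rng = np.random.default_rng(seed)
    site_frames, call_blocks = [], []
    n_dip = len(model.samples)
    for c in range(n_chunks):
        for attempt in range(10):
            s_anc = int(rng.integers(1, 2**31 - 1))
            s_mut = int(rng.integers(1, 2**31 - 1))
            ts = msprime.sim_ancestry(
                samples=model.sample_sets,
                demography=model.demography,
                sequence_length=chunk_length,
                recombination_rate=model.params.recombination_rate,
                random_seed=s_anc,
            )
            mts = msprime.sim_mutations(
                ts, rate=model.params.mutation_rate,
                model=msprime.BinaryMutationModel(), random_seed=s_mut,
            )
            if mts.num_sites > 0:
                break
            warnings.warn(f"chunk {c}: zero segregating sites; resimulating")
        else:
            raise HubseekError(f"chunk {c}: no segregating sites after 10 attempts")
        H = mts.genotype_matrix()  # sites × haplotypes, 0 = ancestral
        dosage = (H[:, 0::2] + H[:, 1::2]).astype(np.int8)
        positions = np.array([int(s.position) + 1 for s in mts.sites()])
        site_frames.append(
            pd.DataFrame(
                {"chrom": f"chunk{c:02d}", "pos": positions, "ref": "A", "alt": "G"}
            )
        )
        call_blocks.append(dosage)
    sites = pd.concat(site_frames, ignore_index=True)
    calls = np.vstack(call_blocks)
    samples = pd.DataFrame(
        {"id": model.samples["id"], "population": model.samples["population"], "ploidy": 2}
    )
    geno = PolarizedGenotypes(sites=sites, samples=samples, calls=calls, polarized=True)
    if pseudo_haploid:
        # the ancient references stay diploid (high-coverage genomes in the
        # real resource); only target cohorts are represented pseudo-haploid
        targets = model.samples.loc[
            model.samples["role"] != "ancient_reference", "id"
        ].tolist()
        geno = pseudo_haploidize(geno, seed=int(rng.integers(1, 2**31 - 1)),
                                 samples=targets)
    return geno


# ---------------------------------------------------------------------------
# ranking experiment
# ---------------------------------------------------------------------------

def simulated_baselines(coords: pd.DataFrame) -> ReferenceBaselines:
    """Baselines taken from the simulation's own unadmixed populations.

    All baseline constants come from populations sampled at the same time as
    the admixed cohorts (the present): U_mean from the unadmixed WEC and EEC
    populations (the roles Kostenki14 and Tianyuan play in the real data),
    the sampled Basal population as its own proxy, T_WEC from the WEC source
    and the single simulated EEC population as the EEC source.  Using
    contemporaneous baselines matters: sharing fractions decay with a
    target's private drift, so an ancient sample's U or T is systematically
    inflated relative to a modern population's, and mixing sampling ages in
    the baseline constants would break the mixture algebra the correction
    inverts.  (The K, T, U coordinates themselves are still measured against
    the three ancient reference genomes.)"""
    t = coords.set_index("population")
    return ReferenceBaselines(
        U_K=float(t.loc["WEC", "U"]),
        U_T=float(t.loc["EEC", "U"]),
        basal_proxy=(
            float(t.loc["BEA", "K"]), float(t.loc["BEA", "T"]), float(t.loc["BEA", "U"])
        ),
        T_WEC=float(t.loc["WEC", "T"]),
        eec_sources={"EastAsian": (float(t.loc["EEC", "K"]), float(t.loc["EEC", "T"]))},
        wec_baseline_members=("WEC",),
    )


def ascertain_maf(
    geno: PolarizedGenotypes,
    panel: tuple[str, ...] = MODERN_EURASIAN_PANEL,
    maf: float = 0.05,
) -> PolarizedGenotypes:
    """Keep only sites with minor-allele frequency > ``maf`` in the pooled
    modern Eurasian panel, emulating SNP-chip ascertainment."""
    cols = np.concatenate([geno.population_indices(p) for p in panel])
    calls = geno.calls[:, cols]
    valid = calls >= 0
    ploidy = geno.samples["ploidy"].to_numpy()[cols][None, :]
    n_alleles = (valid * ploidy).sum(axis=1)
    n_derived = np.where(valid, calls, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.where(n_alleles > 0, n_derived / np.maximum(n_alleles, 1), 0.0)
    keep = np.minimum(p, 1 - p) > maf
    return geno.take_sites(keep, note="ascertain_maf")


def _admixed_kb(geno: PolarizedGenotypes, model: HubDemography) -> dict[str, float]:
    """K_B per admixed population (NaN when undefined), per-chunk-averaged DAS."""
    refs = {"K": "KOS_0", "T": "TIA_0", "U": "UST_0"}
    pops = ["BEA", "EEC", "WEC"] + [
        p for p in geno.populations() if p.startswith("ADM_")
    ]
    coords = compute_coordinates(geno, refs, populations=pops, per_chromosome_mean=True)
    baselines = simulated_baselines(coords)
    out = {}
    for _, r in coords.iterrows():
        if not r["population"].startswith("ADM_"):
            continue
        try:
            d = correct_population(
                r["population"], float(r["K"]), float(r["T"]), float(r["U"]),
                baselines, eec_source_choice="EastAsian",
            )
            out[r["population"]] = d.K_B if d.K_B_defined else float("nan")
        except UndefinedValueError:
            out[r["population"]] = float("nan")
    return out


def _score_matrix(
    kb: dict[str, float], compositions: list[tuple[float, float, float]]
) -> np.ndarray:
    """Binary correct-ranking matrix: rows = WEC-sourced compositions, columns
    = WEC2-sourced; 1 when the WEC2-sourced K_B is the smaller (WEC2 stayed in
    the hub longer, so its source is truly closer).  NaN when either K_B is
    undefined."""
    labels = [composition_label(c) for c in compositions]
    a = np.array([kb[f"ADM_WEC_{l}"] for l in labels])
    b = np.array([kb[f"ADM_WEC2_{l}"] for l in labels])
    m = (b[None, :] < a[:, None]).astype(float)
    m[np.isnan(a)[:, None] | np.isnan(b)[None, :]] = np.nan
    return m


def _score_replicate(geno, model, comps) -> np.ndarray:
    """One replicate's binary matrix; all-NaN when the sampled baselines are
    degenerate (possible at very small simulated genome sizes)."""
    from .errors import DegenerateBaselineError

    try:
        return _score_matrix(_admixed_kb(geno, model), comps)
    except DegenerateBaselineError:
        return np.full((len(comps), len(comps)), np.nan)


@dataclass
class RankingResult:
    accuracy: pd.DataFrame  # rows: WEC-sourced comp, cols: WEC2-sourced comp
    accuracy_ascertained: pd.DataFrame | None
    n_replicates: int
    n_undefined_cells: int
    wec2_offset_ky: float
    scenario: str
    compositions: list[tuple[float, float, float]]

    def min_accuracy(self, min_wec: float = 0.5, ascertained: bool = False) -> float:
        """Minimum cell accuracy among pairs where BOTH compared populations
        have a WEC fraction ≥ ``min_wec``."""
        m = (self.accuracy_ascertained if ascertained else self.accuracy).to_numpy()
        sel = np.array([c[0] >= min_wec for c in self.compositions])
        return float(np.nanmin(m[np.ix_(sel, sel)]))


def run_ranking_experiment(
    wec2_offset_ky: float = 3.0,
    scenario: str = "gravel_style",
    compositions: list[tuple[float, float, float]] | None = None,
    n_reps: int = 100,
    n_chunks: int = 10,
    chunk_length: float = 5e6,
    seed: int = 1,
    with_ascertainment: bool = False,
    maf: float = 0.05,
    params: SimulationParams | None = None,
    n_admixed_diploids: int = 4,
) -> RankingResult:
    """Replicate the simulation, decompose every admixed population and score
    the K_B ranking; average the binary matrices over replicates.  With
    ``with_ascertainment`` each replicate is additionally scored on the
    MAF-filtered site set (same simulations, hence paired matrices)."""
    model = build_demography(
        scenario=scenario, wec2_offset_ky=wec2_offset_ky,
        compositions=compositions, params=params,
        n_admixed_diploids=n_admixed_diploids,
    )
    comps = model.compositions
    labels = [composition_label(c) for c in comps]
    rng = np.random.default_rng(seed)
    stack, stack_asc = [], []
    n_undef = 0
    for _ in range(n_reps):
        rep_seed = int(rng.integers(1, 2**31 - 1))
        geno = simulate_cohort(model, n_chunks=n_chunks, chunk_length=chunk_length,
                               seed=rep_seed)
        m = _score_replicate(geno, model, comps)
        n_undef += int(np.isnan(m).sum())
        stack.append(m)
        if with_ascertainment:
            stack_asc.append(
                _score_replicate(ascertain_maf(geno, maf=maf), model, comps)
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        acc = pd.DataFrame(np.nanmean(stack, axis=0), index=labels, columns=labels)
        acc_asc = (
            pd.DataFrame(np.nanmean(stack_asc, axis=0), index=labels, columns=labels)
            if with_ascertainment else None
        )
    return RankingResult(
        accuracy=acc, accuracy_ascertained=acc_asc, n_replicates=n_reps,
        n_undefined_cells=n_undef, wec2_offset_ky=wec2_offset_ky,
        scenario=scenario, compositions=comps,
    )


# ---------------------------------------------------------------------------
# ascertainment comparison statistics
# ---------------------------------------------------------------------------

@dataclass
class AscertainmentComparison:
    mantel_r: float
    mantel_p: float
    wilcoxon_p: float
    max_abs_dev: float
    n_permutations: int


def mantel_test(
    a: np.ndarray, b: np.ndarray, permutations: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Matrix correlation with joint row/column permutation.

    Both matrices are square and indexed by the same cell labels; the null
    permutes the labels of ``b`` (rows and columns together).  One-sided p:
    fraction of permutations with r at least as large as observed, with the
    identity permutation included (so min p = 1/(permutations+1))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError(f"need two square matrices of equal shape, got {a.shape}, {b.shape}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedValueError("a matrix is constant; Mantel r undefined")
    def corr(x, y):
        return float(np.corrcoef(x.ravel(), y.ravel())[0, 1])
    r_obs = corr(a, b)
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    hits = 1  # identity permutation
    for _ in range(permutations):
        perm = rng.permutation(n)
        if corr(a, b[np.ix_(perm, perm)]) >= r_obs:
            hits += 1
    return r_obs, hits / (permutations + 1)


def ascertainment_comparison(
    matrix_full: pd.DataFrame | np.ndarray,
    matrix_ascertained: pd.DataFrame | np.ndarray,
    permutations: int = 999,
    seed: int = 0,
) -> AscertainmentComparison:
    """Compare paired accuracy matrices computed with and without the MAF
    ascertainment restriction: Mantel r/p, paired Wilcoxon on flattened
    cells, and the maximum absolute cell-wise deviation."""
    a = np.asarray(matrix_full, dtype=float)
    b = np.asarray(matrix_ascertained, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"matrix shapes differ: {a.shape} vs {b.shape}")
    r, p = mantel_test(a, b, permutations=permutations, seed=seed)
    diffs = (a - b).ravel()
    diffs = diffs[~np.isnan(diffs)]
    if np.allclose(diffs, 0):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(stats.wilcoxon(diffs).pvalue)
    return AscertainmentComparison(
        mantel_r=r, mantel_p=p, wilcoxon_p=wilcoxon_p,
        max_abs_dev=float(np.nanmax(np.abs(a - b))), n_permutations=permutations,
    )
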