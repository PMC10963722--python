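"""Deconfounding algebra: recover each population's unadmixed West Eurasian
source coordinate (K_B) from its observed sharing coordinates.

The observed (K, T, U) of a population X is modelled as a nested weighted mean
of three ancestries — Basal Eurasian (fraction pBEA), East Eurasian Core
(EEC) and West Eurasian Core (WEC) — because the sharing coordinate of an
admixed population is the mixture-weighted mean of its sources' coordinates.
Each step inverts one mixture:

1. pBEA_X  = (U_X − U_mean) / (U_BEA − U_mean)                 (Basal fraction)
2. K_BR    = (K_X − K_BEA·pBEA_X) / (1 − pBEA_X), same for T   (strip Basal)
3. pEEC_BR = (T_BR − T_WEC) / (T_EEC − T_WEC)                  (EEC fraction)
4. K_B     = (K_BR − K_EEC·pEEC_BR) / (1 − pEEC_BR)            (strip EEC)
5. pEEC_X  = pEEC_BR·(1 − pBEA_X);  pWEC_X = (1 − pEEC_BR)·(1 − pBEA_X)

U serves as the Basal dial because Ust'Ishim near-trifurcates with the
Kostenki14 and Tianyuan lineages, so all non-Basal Eurasians share a common
expected U (U_mean).  Clamping follows the procedure order: a negative pBEA is
set to 0 before step 2; pEEC_BR is clamped to [0, 1] before step 4, and when
it clamps to 1 the population is fully EEC and K_B is undefined.  The smaller
K_B, the less drift X's WEC source shared with the Kostenki14 lineage, i.e.
the closer that source remained to the population hub.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateBaselineError, UndefinedValueError

DEFAULT_WEC_BASELINE = ("Sunghir", "Vestonice16", "Muierii2", "Krems")
DEFAULT_MIN_WEC = 0.75


@dataclass
class ReferenceBaselines:
    """Coordinates of the fixed reference points entering the algebra.

    ``basal_proxy`` is (K, T, U) of the Basal-Eurasian stand-in (Gumuz in the
    real data — an East African population without back-flow from Eurasia, a
    conservative proxy since no Basal Eurasian genome has been sampled).
    ``eec_sources`` maps source label → (K_EEC, T_EEC).
    """

    U_K: float  # U of Kostenki14
    U_T: float  # U of Tianyuan
    basal_proxy: tuple[float, float, float]  # (K_BEA, T_BEA, U_BEA)
    T_WEC: float
    eec_sources: dict[str, tuple[float, float]]
    wec_baseline_members: tuple[str, ...] = DEFAULT_WEC_BASELINE

    def __post_init__(self):
        for v in (self.U_K, self.U_T, self.T_WEC, *self.basal_proxy):
            if not 0 <= v <= 1:
                raise ValueError(f"baseline fraction {v} outside [0, 1]")
        if self.U_BEA >= self.U_mean:
            raise DegenerateBaselineError(
                f"Basal proxy U ({self.U_BEA:.4f}) must lie below U_mean "
                f"({self.U_mean:.4f}); the proxy is not basal enough"
            )

    @property
    def U_mean(self) -> float:
        return (self.U_K + self.U_T) / 2

    @property
    def K_BEA(self) -> float:
        return self.basal_proxy[0]

    @property
    def T_BEA(self) -> float:
        return self.basal_proxy[1]

    @property
    def U_BEA(self) -> float:
        return self.basal_proxy[2]

    def eec_coordinates(self, choice: str) -> tuple[float, float]:
        """(K_EEC, T_EEC) for a source label, or the element-wise mean of all
        configured sources for ``"average"``."""
        if choice == "average":
            arr = np.array(list(self.eec_sources.values()), dtype=float)
            return tuple(arr.mean(axis=0))
        if choice not in self.eec_sources:
            raise ConfigurationError(
                f"unknown EEC source {choice!r}; configured: "
                f"{sorted(self.eec_sources)} or 'average'"
            )
        return self.eec_sources[choice]


@dataclass
class AncestryDecomposition:
    population: str
    pBEA_X: float
    K_BR: float
    T_BR: float
    pEEC_BR: float
    K_B: float  # NaN when undefined
    pEEC_X: float
    pWEC_X: float
    eec_source: str = "average"
    clamp_flags: set = field(default_factory=set)

    @property
    def K_B_defined(self) -> bool:
        return "K_B_undefined" not in self.clamp_flags


# ---------------------------------------------------------------------------
# elementary inversions
# ---------------------------------------------------------------------------

def basal_fraction(U_X: float, baselines: ReferenceBaselines) -> tuple[float, bool]:
    """Eq. for pBEA; negative results clamp to 0.  Returns (pBEA, clamped)."""
    denom = baselines.U_BEA - baselines.U_mean
    if denom == 0:
        raise DegenerateBaselineError("U_BEA equals U_mean")
    raw = (U_X - baselines.U_mean) / denom
    if raw < 0:
        return 0.0, True
    return raw, False


def deconfound_basal(
    K_X: float, T_X: float, pBEA: float, baselines: ReferenceBaselines
) -> tuple[float, float]:
    """Strip the Basal component: coordinates X would have without it."""
    if pBEA >= 1:
        raise UndefinedValueError(f"pBEA = {pBEA}: population is fully Basal")
    K_BR = (K_X - baselines.K_BEA * pBEA) / (1 - pBEA)
    T_BR = (T_X - baselines.T_BEA * pBEA) / (1 - pBEA)
    return K_BR, T_BR


def eec_fraction(T_BR: float, T_WEC: float, T_EEC: float) -> tuple[float, set]:
    """EEC fraction of the Basal-stripped point; clamps to [0, 1] with flags."""
    if T_EEC == T_WEC:
        raise DegenerateBaselineError("T_EEC equals T_WEC")
    raw = (T_BR - T_WEC) / (T_EEC - T_WEC)
    flags = set()
    if raw < 0:
        return 0.0, {"pEEC_clamped_low"}
    if raw > 1:
        return 1.0, {"pEEC_clamped_high"}
    return raw, flags


def wec_source_coordinate(K_BR: float, K_EEC: float, pEEC_BR: float) -> float:
    """K of the unadmixed WEC source; undefined (raises) when pEEC_BR = 1."""
    if pEEC_BR >= 1:
        raise UndefinedValueError("pEEC_BR = 1: population is fully EEC, K_B undefined")
    return (K_BR - K_EEC * pEEC_BR) / (1 - pEEC_BR)


def total_ancestry(pEEC_BR: float, pBEA: float) -> tuple[float, float]:
    """Total (pEEC_X, pWEC_X); conserves pBEA + pEEC_X + pWEC_X = 1 exactly."""
    pEEC_X = pEEC_BR * (1 - pBEA)
    pWEC_X = (1 - pEEC_BR) * (1 - pBEA)
    return pEEC_X, pWEC_X


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def build_baselines(
    coords: pd.DataFrame,
    *,
    kostenki: str = "Kostenki14",
    tianyuan: str = "Tianyuan",
    basal_proxy: str = "Gumuz",
    wec_members: tuple[str, ...] = DEFAULT_WEC_BASELINE,
    eec_sources: dict[str, str] | None = None,
) -> ReferenceBaselines:
    """Assemble baselines from a coordinate table (columns population, K, T, U).

    ``eec_sources`` maps source label → population name in the table
    (default EastAsian → Han, Andamanese → Onge).
    """
    eec_sources = eec_sources or {"EastAsian": "Han", "Andamanese": "Onge"}
    table = coords.set_index("population")

    def row(name: str) -> pd.Series:
        if name not in table.index:
            raise ConfigurationError(f"baseline population {name!r} not in coordinates")
        return table.loc[name]

    missing = [m for m in wec_members if m not in table.index]
    if missing:
        raise ConfigurationError(f"WEC baseline members missing: {missing}")
    proxy = row(basal_proxy)
    return ReferenceBaselines(
        U_K=float(row(kostenki)["U"]),
        U_T=float(row(tianyuan)["U"]),
        basal_proxy=(float(proxy["K"]), float(proxy["T"]), float(proxy["U"])),
        T_WEC=float(np.mean([row(m)["T"] for m in wec_members])),
        eec_sources={
            label: (float(row(p)["K"]), float(row(p)["T"]))
            for label, p in eec_sources.items()
        },
        wec_baseline_members=wec_members,
    )


def correct_population(
    population: str,
    K_X: float,
    T_X: float,
    U_X: float,
    baselines: ReferenceBaselines,
    eec_source_choice: str = "average",
) -> AncestryDecomposition:
    """Run the full deconfounding chain on one population's coordinates."""
    flags: set = set()
    pBEA, clamped = basal_fraction(U_X, baselines)
    if clamped:
        flags.add("pBEA_clamped")
    K_BR, T_BR = deconfound_basal(K_X, T_X, pBEA, baselines)
    K_EEC, T_EEC = baselines.eec_coordinates(eec_source_choice)
    pEEC_BR, eec_flags = eec_fraction(T_BR, baselines.T_WEC, T_EEC)
    flags |= eec_flags
    if pEEC_BR >= 1:
        flags.add("K_B_undefined")
        K_B = float("nan")
    else:
        K_B = wec_source_coordinate(K_BR, K_EEC, pEEC_BR)
    pEEC_X, pWEC_X = total_ancestry(pEEC_BR, pBEA)
    return AncestryDecomposition(
        population=population,
        pBEA_X=pBEA,
        K_BR=K_BR,
        T_BR=T_BR,
        pEEC_BR=pEEC_BR,
        K_B=K_B,
        pEEC_X=pEEC_X,
        pWEC_X=pWEC_X,
        eec_source=eec_source_choice,
        clamp_flags=flags,
    )


def decompose_table(
    coords: pd.DataFrame,
    baselines: ReferenceBaselines,
    eec_source_choices: dict[str, str] | None = None,
) -> list[AncestryDecomposition]:
    """Decompose every row of a coordinate table.

    ``eec_source_choices`` maps population → source label (from
    :func:`hubseek.dstat.assign_eec_source`); default "average"."""
    choices = eec_source_choices or {}
    return [
        correct_population(
            r["population"],
            float(r["K"]),
            float(r["T"]),
            float(r["U"]),
            baselines,
            choices.get(r["population"], "average"),
        )
        for _, r in coords.iterrows()
    ]


def rank_by_hub_proximity(
    decompositions: list[AncestryDecomposition],
    min_wec: float = DEFAULT_MIN_WEC,
) -> pd.DataFrame:
    """Populations with pWEC_X ≥ ``min_wec``, ascending by K_B.

    The 75% default is the strictest WEC-fraction threshold validated by the
    ranking simulations.  Populations with undefined K_B are excluded (their
    count is attached as ``.attrs['n_undefined']``); ties sort stably by
    population label.
    """
    eligible = [d for d in decompositions if d.K_B_defined and d.pWEC_X >= min_wec]
    n_undef = sum(not d.K_B_defined for d in decompositions)
    rows = [
        {
            "population": d.population,
            "K_B": d.K_B,
            "pBEA_X": d.pBEA_X,
            "pEEC_X": d.pEEC_X,
            "pWEC_X": d.pWEC_X,
            "clamp_flags": ",".join(sorted(d.clamp_flags)),
        }
        for d in sorted(eligible, key=lambda d: (d.K_B, d.population))
    ]
    out = pd.DataFrame(
        rows, columns=["population", "K_B", "pBEA_X", "pEEC_X", "pWEC_X", "clamp_flags"]
    )
    out.attrs["n_undefined"] = n_undef
    return out
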