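"""Cohort statistics: aggregation, day differences, Pearson screening,
bootstrap stability and subgroup comparisons.

The analysis operates on per-patient averages (each patient x timepoint
sample is the mean over its ~150 measured cells). Changes are defined
as later-day minus baseline per patient; pairs of change variables are
screened with two-sided Pearson tests. Effect stability is probed with
a with-replacement bootstrap: the sample p-value is the fraction of
resample means falling outside a +/-0.3 SD corridor around the original
mean, Benjamini-Hochberg adjusted across the tested family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import TIMEPOINTS
from .morpho import CellMeasurement


# ----------------------------------------------------------- aggregates

@dataclass
class SampleAggregate:
    patient_id: int | str
    timepoint: str
    cell_type: str
    n_cells: int
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)


def aggregate_sample(
    cells: list[CellMeasurement],
    patient_id: int | str = 0,
    timepoint: str = "PreOP",
) -> SampleAggregate:
    """Mean and sample SD (ddof=1) of V, n_cell, DM and FF over kept cells."""
    if not cells:
        raise ValueError("cannot aggregate an empty sample")
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    arrays = {
        "V_um3": np.array([c.volume_um3 for c in cells]),
        "n_cell": np.array([c.n_cell for c in cells]),
        "DM_pg": np.array([c.dry_mass_pg for c in cells]),
        "FF": np.array([c.ff for c in cells]),
    }
    means = {k: float(v.mean()) for k, v in arrays.items()}
    sds = {k: (float(v.std(ddof=1)) if v.size > 1 else float("nan"))
           for k, v in arrays.items()}
    return SampleAggregate(
        patient_id=patient_id, timepoint=timepoint,
        cell_type=cells[0].label, n_cells=len(cells),
        means=means, sds=sds,
    )


# ------------------------------------------------------ day differences

def day_difference(
    table: pd.DataFrame,
    later: str,
    baseline: str,
    column: str,
    cell_type: str | None = None,
) -> tuple[pd.Series, int]:
    """Per-patient difference ``column(later) - column(baseline)``.

    Patients missing either timepoint are dropped; returns the Series
    (indexed by patient_id) and the dropped-patient count.
    """
    for tp in (later, baseline):
        if tp not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {tp!r}")
    df = table
    if cell_type is not None:
        df = df[df["cell_type"] == cell_type]
    elif "cell_type" in df.columns:
        # marker/clinical columns repeat across cell-type rows
        df = df.drop_duplicates(subset=["patient_id", "timepoint"])
    a = df[df["timepoint"] == later].set_index("patient_id")[column]
    b = df[df["timepoint"] == baseline].set_index("patient_id")[column]
    common = a.index.intersection(b.index)
    dropped = len(a.index.union(b.index)) - len(common)
    return (a.loc[common] - b.loc[common]).rename(f"{column}_{later}-{baseline}"), dropped


# ------------------------------------------------------------- Pearson

def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationResult:
    var_a: str
    var_b: str
    r: float
    p: float
    n: int

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def pearson_matrix(
    deltas: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> list[CorrelationResult]:
    """Two-sided Pearson correlations over pairs of change columns.

    Pairwise-complete deletion per pair; p-values from the t
    distribution with n-2 df. Constant columns (r undefined) are
    skipped. Results are sorted by descending |r|, the convention of the
    screening table.
    """
    cols = list(deltas.columns)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    out: list[CorrelationResult] = []
    for a, b in pairs:
        sub = deltas[[a, b]].dropna()
        if len(sub) < 3:
            continue
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue  # r undefined on a constant column
        res = sps.pearsonr(x, y)
        out.append(CorrelationResult(a, b, float(res.statistic),
                                     float(res.pvalue), len(sub)))
    out.sort(key=lambda c: -abs(c.r))
    return out


def correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter_1": c.var_a,
        "parameter_2": c.var_b,
        "pearson_r": round(c.r, 3),
        "p_value": c.p,
        "n": c.n,
        "stars": c.stars,
    } for c in results])


# ------------------------------------------------------------ bootstrap

def expected_missing_fraction(n: int) -> float:
    """Expected fraction of distinct entities absent from one
    full-size with-replacement resample: (1 - 1/n)^n (36.7% at n = 150).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return float((1.0 - 1.0 / n) ** n)


@dataclass
class BootstrapResult:
    original_mean: float
    original_sd: float
    n: int
    n_boot: int
    corridor_sd: float
    sample_p: float
    bh_adjusted_p: float | None = None


def bootstrap_stability(
    values: np.ndarray,
    n_boot: int = 10_000,
    corridor_sd: float = 0.3,
    seed: int | np.random.Generator | None = None,
) -> BootstrapResult:
    """Stability of a sample mean under with-replacement resampling.

    sample_p is the fraction of ``n_boot`` resample means outside
    [mean - corridor_sd*SD, mean + corridor_sd*SD] of the original data;
    small values mean the estimate is stable within the corridor.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values (SD undefined otherwise)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = values[idx].mean(axis=1)
    half = corridor_sd * sd
    outside = np.abs(boot_means - mean) > half
    return BootstrapResult(
        original_mean=mean, original_sd=sd, n=n, n_boot=n_boot,
        corridor_sd=corridor_sd, sample_p=float(outside.mean()),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bootstrap_stability_family(
    samples: dict[str, np.ndarray],
    n_boot: int = 10_000,
    corridor_sd: float = 0.3,
    seed: int | None = None,
) -> dict[str, BootstrapResult]:
    """Bootstrap each sample and BH-adjust the sample p-values jointly."""
    rng = np.random.default_rng(seed)
    results = {k: bootstrap_stability(v, n_boot, corridor_sd, rng)
               for k, v in samples.items()}
    adjusted = bh_adjust([r.sample_p for r in results.values()])
    for r, adj in zip(results.values(), adjusted):
        r.bh_adjusted_p = float(adj)
    return results


# ------------------------------------------------------------ subgroups

@dataclass
class SubgroupComparison:
    grouping: str
    quantity: str
    n_in: int
    n_out: int
    mean_in: float
    mean_out: float
    sd_in: float
    sd_out: float
    difference: float
    p: float
    test: str

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def subgroup_compare(
    values: pd.Series,
    group: pd.Series,
    grouping: str = "group",
    quantity: str = "value",
    test: str = "welch",
) -> SubgroupComparison:
    """Compare a per-patient quantity between a subgroup and the rest.

    ``values`` and ``group`` (boolean) are aligned on patient index.
    Default test is Welch's two-sample t; ``test="mannwhitney"`` swaps in
    the rank-based alternative.
    """
    df = pd.DataFrame({"v": values, "g": group}).dropna()
    a = df.loc[df["g"].astype(bool), "v"].to_numpy(float)
    b = df.loc[~df["g"].astype(bool), "v"].to_numpy(float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if test == "welch":
        p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    elif test == "mannwhitney":
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return SubgroupComparison(
        grouping=grouping, quantity=quantity,
        n_in=a.size, n_out=b.size,
        mean_in=float(a.mean()), mean_out=float(b.mean()),
        sd_in=float(a.std(ddof=1)) if a.size > 1 else float("nan"),
        sd_out=float(b.std(ddof=1)) if b.size > 1 else float("nan"),
        difference=float(a.mean() - b.mean()), p=p, test=test,
    )


def group_overlap_counts(table: pd.DataFrame) -> dict[str, int]:
    """Venn-style counts of the three clinical subgroups (per patient)."""
    pat = table.drop_duplicates("patient_id").set_index("patient_id")
    comp = pat["complicated_course"].astype(bool)
    epi = pat["epinephrine"].astype(bool)
    crp = pat["crp_high"].astype(bool)
    return {
        "complicated": int(comp.sum()),
        "epinephrine": int(epi.sum()),
        "crp_high": int(crp.sum()),
        "complicated_and_epinephrine": int((comp & epi).sum()),
        "complicated_and_crp_high": int((comp & crp).sum()),
        "epinephrine_and_crp_high": int((epi & crp).sum()),
        "all_three": int((comp & epi & crp).sum()),
    }
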