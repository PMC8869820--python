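"""Synthetic perioperative cohort with injectable correlation structure.

Emulates a cardiac-surgery cohort measured at four timepoints (PreOP,
d1, d3, d6): per-patient DHM aggregates (volume, integral refractive
index, form factor, dry mass) for lymphocytes and monocytes, flow
cytometry marker levels, CRP, epinephrine dose, and the three clinical
subgroups (complicated course, epinephrine treatment, CRP > 14 mg/dL).

Generative model
----------------
Correlations between biophysical and marker changes are defined on the
d1 - PreOP difference scale: a latent standard multivariate normal with
the configured correlation matrix drives all difference variables
(a Gaussian copula with normal margins). Day levels are back-formed so
that every configured per-day mean/SD is reproduced exactly in
expectation: given a difference D with variance s_D^2 and target day
SDs (s_0, s_1), the baseline is drawn with cov(X0, D) =
(s_1^2 - s_0^2 - s_D^2)/2, which makes var(X0 + D) = s_1^2.

Subgroup effects enter as fixed, mean-centred offsets on the lymphocyte
volume difference (suppressed change under complicated course or
epinephrine, amplified change under high CRP); the latent correlation
for that variable is rescaled so the *total* realised correlation still
equals the configured value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantoms import CellPhantom, make_phantom_population

TIMEPOINTS = ("PreOP", "d1", "d3", "d6")
CELL_TYPES = ("lymphocyte", "monocyte")

#: Difference-scale variable names used in the correlation matrix.
DELTA_DHM_VARS = (
    "dV_lymphocyte", "dV_monocyte",
    "dn_lymphocyte", "dn_monocyte",
    "dFF_lymphocyte", "dFF_monocyte",
)
MARKERS = (
    "CD19_abs", "CD19_rel", "CD86", "mHLA_DR", "mCD206",
    "necrosis_late_apoptosis", "CD3", "CD4", "platelets",
)
DELTA_MARKER_VARS = tuple("d" + m for m in MARKERS) + ("dEpinephrine_dose",)
DELTA_VARS = DELTA_DHM_VARS + DELTA_MARKER_VARS


@dataclass(frozen=True)
class DayStats:
    """Per-timepoint cohort mean and between-patient SD (PreOP, d1, d3, d6)."""

    mean: tuple[float, float, float, float]
    sd: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.mean) != 4 or len(self.sd) != 4:
            raise ValueError("DayStats needs exactly 4 timepoints")
        if any(s < 0 for s in self.sd):
            raise ValueError("SDs must be non-negative")


def _default_volume() -> dict:
    # lymphocyte volumes rise at d1 and relax toward baseline by d6;
    # monocyte volumes rise and stay elevated
    return {
        "lymphocyte": DayStats((208.0, 218.0, 210.0, 210.0), (9.0, 11.0, 9.0, 9.0)),
        "monocyte": DayStats((390.0, 413.0, 414.0, 400.0), (25.0, 20.0, 27.0, 23.0)),
    }


def _default_n_cell() -> dict:
    return {
        "lymphocyte": DayStats((1.3495, 1.34945, 1.3495, 1.3495),
                               (1e-4, 1e-4, 1e-4, 1e-4)),
        "monocyte": DayStats((1.3497, 1.3485, 1.3490, 1.3494),
                             (1e-4, 1e-4, 1e-4, 1e-4)),
    }


def _default_form_factor() -> dict:
    return {
        "lymphocyte": DayStats((0.975, 0.974, 0.975, 0.975),
                               (0.005, 0.005, 0.005, 0.005)),
        "monocyte": DayStats((0.975, 0.955, 0.960, 0.970),
                             (0.006, 0.006, 0.006, 0.006)),
    }


def _default_markers() -> dict:
    # synthetic marker scales: plausible clinical magnitudes, constant SD/day
    return {
        "CD19_abs": DayStats((180.0, 150.0, 160.0, 175.0), (60.0,) * 4),
        "CD19_rel": DayStats((8.0, 7.0, 7.5, 8.0), (3.0,) * 4),
        "CD86": DayStats((100.0, 115.0, 110.0, 105.0), (30.0,) * 4),
        "mHLA_DR": DayStats((25.0, 18.0, 20.0, 23.0), (8.0,) * 4),
        "mCD206": DayStats((10.0, 13.0, 12.0, 11.0), (4.0,) * 4),
        "necrosis_late_apoptosis": DayStats((5.0, 8.0, 7.0, 6.0), (3.0,) * 4),
        "CD3": DayStats((60.0, 55.0, 57.0, 60.0), (10.0,) * 4),
        "CD4": DayStats((35.0, 32.0, 34.0, 35.0), (8.0,) * 4),
        "platelets": DayStats((220.0, 180.0, 200.0, 230.0), (60.0,) * 4),
    }


def _default_delta_corr() -> dict:
    """Default injected correlations on the d1-PreOP difference scale."""
    return {
        ("dV_lymphocyte", "dCD19_abs"): -0.514,
        ("dV_lymphocyte", "dEpinephrine_dose"): -0.484,
        ("dV_monocyte", "dnecrosis_late_apoptosis"): 0.479,
        ("dn_lymphocyte", "dCD86"): 0.464,
        ("dFF_monocyte", "dmHLA_DR"): 0.464,
        ("dn_monocyte", "dnecrosis_late_apoptosis"): -0.44,
        ("dV_monocyte", "dn_monocyte"): -0.431,
        ("dn_monocyte", "dmCD206"): 0.405,
        ("dFF_monocyte", "dn_monocyte"): 0.401,
    }


@dataclass
class SubgroupSpec:
    """Clinical subgroup sizes for a 25-patient cohort, scaled with n.

    Defaults reproduce the study's Venn structure: 9 complicated course,
    8 epinephrine, 7 high CRP; 6 complicated AND epinephrine, 2
    complicated AND high CRP, no epinephrine/high-CRP overlap.
    """

    n_complicated: int = 9
    n_epinephrine: int = 8
    n_crp_high: int = 7
    overlap_comp_epi: int = 6
    overlap_comp_crp: int = 2
    overlap_epi_crp: int = 0
    reference_n: int = 25
    #: additive shift of the lymphocyte d1-PreOP volume difference (µm^3)
    #: for complicated-course / epinephrine patients; None means "cancel
    #: the population-mean change", i.e. those patients show ~no change
    suppressed_shift_um3: float | None = None
    #: amplification for high-CRP patients
    crp_shift_um3: float = 5.0

    def validate(self) -> None:
        if self.overlap_epi_crp != 0:
            # supported, but the complicated-only remainder must stay valid
            pass
        comp_only = self.n_complicated - self.overlap_comp_epi - self.overlap_comp_crp
        if comp_only < 0:
            raise ValueError("subgroup overlaps exceed group size")
        total = (self.n_complicated
                 + (self.n_epinephrine - self.overlap_comp_epi - self.overlap_epi_crp)
                 + (self.n_crp_high - self.overlap_comp_crp - self.overlap_epi_crp))
        if total > self.reference_n:
            raise ValueError("subgroups exceed cohort size")


@dataclass
class CohortSpec:
    """Full configuration of the synthetic cohort."""

    n_patients: int = 25
    cells_per_sample: int = 150
    n_medium: float = 1.337
    alpha_um3_per_pg: float = 0.2
    volume: dict = field(default_factory=_default_volume)
    n_cell: dict = field(default_factory=_default_n_cell)
    form_factor: dict = field(default_factory=_default_form_factor)
    markers: dict = field(default_factory=_default_markers)
    delta_corr: dict = field(default_factory=_default_delta_corr)
    #: difference-scale SD per variable; None -> sqrt((s0^2 + s1^2)/2)
    delta_sd: dict = field(default_factory=dict)
    #: correlation between a patient's PreOP level and later-day levels
    patient_persistence: float = 0.7
    #: within-sample radius coefficient of variation and the d1 spread
    #: multiplier emulating the enlarged d1 scatter
    radius_cv: float = 0.05
    d1_spread_multiplier: float = 1.5
    subgroups: SubgroupSpec = field(default_factory=SubgroupSpec)
    dropout: dict = field(default_factory=dict)  # timepoint -> n missing patients

    # ---------------------------------------------------------------- helpers

    def day_stats(self, var: str) -> DayStats:
        """DayStats for a difference-variable name ('dV_lymphocyte', 'dCD19_abs', ...)."""
        if var.startswith("dV_"):
            return self.volume[var[3:]]
        if var.startswith("dn_"):
            return self.n_cell[var[3:]]
        if var.startswith("dFF_"):
            return self.form_factor[var[4:]]
        if var == "dEpinephrine_dose":
            return DayStats((0.0, 0.0, 0.0, 0.0), (1.0, 1.0, 1.0, 1.0))
        return self.markers[var[1:]]

    def delta_sd_of(self, var: str) -> float:
        if var in self.delta_sd:
            return float(self.delta_sd[var])
        ds = self.day_stats(var)
        return float(np.sqrt((ds.sd[0] ** 2 + ds.sd[1] ** 2) / 2.0))


# ----------------------------------------------------------- correlation

def build_correlation_matrix(spec: CohortSpec,
                             vars_: tuple[str, ...] = DELTA_VARS
                             ) -> np.ndarray:
    C = np.eye(len(vars_))
    idx = {v: i for i, v in enumerate(vars_)}
    for (a, b), r in spec.delta_corr.items():
        if a not in idx or b not in idx:
            raise KeyError(f"unknown correlation variable pair ({a}, {b})")
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    return C


def nearest_psd(C: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix."""
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    if w.min() >= eps:
        return C
    w = np.clip(w, eps, None)
    C = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


# ------------------------------------------------------------- subgroups

def assign_subgroups(n_patients: int, sub: SubgroupSpec) -> pd.DataFrame:
    """Deterministic patient-level subgroup flags scaled from the reference.

    Counts scale proportionally with the cohort size (rounded), keeping
    the overlap structure; at the reference size (25) the study's Venn
    counts are reproduced exactly.
    """
    sub.validate()
    scale = n_patients / sub.reference_n

    def sc(k: int) -> int:
        return int(round(k * scale))

    n_ce = sc(sub.overlap_comp_epi)
    n_cc = sc(sub.overlap_comp_crp)
    n_ec = sc(sub.overlap_epi_crp)
    n_comp = sc(sub.n_complicated)
    n_epi = sc(sub.n_epinephrine)
    n_crp = sc(sub.n_crp_high)
    comp = np.zeros(n_patients, dtype=bool)
    epi = np.zeros(n_patients, dtype=bool)
    crp = np.zeros(n_patients, dtype=bool)
    # block layout: [comp∩epi][comp∩crp][comp only][epi only][epi∩crp][crp only]
    i = 0
    comp[i:i + n_ce] = True
    epi[i:i + n_ce] = True
    i += n_ce
    comp[i:i + n_cc] = True
    crp[i:i + n_cc] = True
    i += n_cc
    comp[i:i + n_comp - n_ce - n_cc] = True
    i += n_comp - n_ce - n_cc
    epi[i:i + n_epi - n_ce - n_ec] = True
    i += n_epi - n_ce - n_ec
    epi[i:i + n_ec] = True
    crp[i:i + n_ec] = True
    i += n_ec
    crp[i:i + n_crp - n_cc - n_ec] = True
    i += n_crp - n_cc - n_ec
    if i > n_patients:
        raise ValueError("subgroups exceed cohort size")
    return pd.DataFrame({
        "patient_id": np.arange(n_patients),
        "complicated_course": comp,
        "epinephrine": epi,
        "crp_high": crp,
    })


def _delta_vl_offsets(flags: pd.DataFrame, spec: CohortSpec) -> np.ndarray:
    """Mean-centred subgroup offsets on the lymphocyte volume difference."""
    sub = spec.subgroups
    mu_delta = (spec.volume["lymphocyte"].mean[1]
                - spec.volume["lymphocyte"].mean[0])
    suppressed = (sub.suppressed_shift_um3
                  if sub.suppressed_shift_um3 is not None else -mu_delta)
    o = np.zeros(len(flags))
    suppress_mask = ((flags["complicated_course"] | flags["epinephrine"])
                     & ~flags["crp_high"]).to_numpy()
    o[suppress_mask] = suppressed
    o[flags["crp_high"].to_numpy()] = sub.crp_shift_um3
    return o - o.mean()


# -------------------------------------------------------------- simulate

def simulate_cohort(
    spec: CohortSpec | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the cohort table: one row per patient x timepoint x cell type.

    Columns: patient_id, timepoint, cell_type, n_cells, the DHM
    aggregates (V/n_cell/DM/FF mean and within-sample SD), the marker
    panel, CRP, epinephrine dose, and the subgroup flags. Deterministic
    under a fixed seed.
    """
    spec = spec or CohortSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_patients
    if n < 1:
        raise ValueError("n_patients must be >= 1")

    flags = assign_subgroups(n, spec.subgroups)
    offsets = _delta_vl_offsets(flags, spec)
    var_o = float(np.var(offsets))

    # latent correlated standard normals on the difference scale
    C = build_correlation_matrix(spec)
    sd_vl = spec.delta_sd_of("dV_lymphocyte")
    s_resid_sq = sd_vl**2 - var_o
    if s_resid_sq <= 0:
        raise ValueError(
            "subgroup offsets on dV_lymphocyte exceed its configured "
            "difference SD; reduce the shifts or enlarge delta_sd"
        )
    s_resid = float(np.sqrt(s_resid_sq))
    # rescale latent correlations of dV_lymphocyte so the realised total
    # correlation (offsets included) matches the configured value
    i_vl = DELTA_VARS.index("dV_lymphocyte")
    boost = sd_vl / s_resid
    C_adj = C.copy()
    C_adj[i_vl, :] *= boost
    C_adj[:, i_vl] *= boost
    np.fill_diagonal(C_adj, 1.0)
    if np.abs(C_adj[i_vl]).max() > 1.0 + 1e-12:
        raise ValueError("subgroup offsets leave too little residual "
                         "variance to realise the configured dV_lymphocyte "
                         "correlations")
    C_adj = nearest_psd(C_adj)
    L = np.linalg.cholesky(C_adj + 1e-12 * np.eye(len(DELTA_VARS)))
    z = rng.standard_normal((n, len(DELTA_VARS))) @ L.T

    # difference values and day levels per variable
    levels: dict[str, np.ndarray] = {}  # var -> (n, 4) array
    for j, var in enumerate(DELTA_VARS):
        ds = spec.day_stats(var)
        mu0, mu1 = ds.mean[0], ds.mean[1]
        s0, s1 = ds.sd[0], ds.sd[1]
        sd_d = spec.delta_sd_of(var)
        if var == "dV_lymphocyte":
            delta_centered = offsets + s_resid * z[:, j]
        else:
            delta_centered = sd_d * z[:, j]
        delta = (mu1 - mu0) + delta_centered
        # baseline correlated with the difference so var(X0 + delta) = s1^2
        c0 = (s1**2 - s0**2 - sd_d**2) / 2.0
        b_sq = s0**2 - (c0**2 / sd_d**2 if sd_d > 0 else 0.0)
        if b_sq < 0:
            raise ValueError(
                f"day SDs of {var} are incompatible with its difference SD "
                "(need |s1 - s0| <= delta_sd <= s0 + s1)"
            )
        a = c0 / sd_d**2 if sd_d > 0 else 0.0
        x0 = mu0 + a * delta_centered + np.sqrt(b_sq) * rng.standard_normal(n)
        x1 = x0 + delta
        out = np.empty((n, 4))
        out[:, 0] = x0
        out[:, 1] = x1
        # later days: persistence toward the patient's baseline deviation
        rho = spec.patient_persistence
        for t in (2, 3):
            st = ds.sd[t]
            scale = (st / s0) if s0 > 0 else 0.0
            noise = np.sqrt(max(1.0 - rho**2, 0.0)) * st
            out[:, t] = (ds.mean[t] + rho * scale * (x0 - mu0)
                         + noise * rng.standard_normal(n))
        levels[var] = out

    # CRP trajectory: the d1 level defines the dichotomy exactly
    crp = np.empty((n, 4))
    crp_high = flags["crp_high"].to_numpy()
    crp[:, 0] = np.clip(rng.normal(1.0, 0.5, n), 0.1, None)
    d1_high = np.clip(rng.normal(19.0, 3.0, n), 14.5, None)
    d1_low = np.clip(rng.normal(8.0, 3.0, n), 0.5, 13.5)
    crp[:, 1] = np.where(crp_high, d1_high, d1_low)
    crp[:, 2] = np.clip(0.6 * crp[:, 1] + rng.normal(0, 1.0, n), 0.1, None)
    crp[:, 3] = np.clip(0.3 * crp[:, 1] + rng.normal(0, 1.0, n), 0.1, None)

    # epinephrine dose: zero unless treated; treated doses follow the
    # latent difference variable so injected dose correlations survive
    # within the treated stratum
    epi_flag = flags["epinephrine"].to_numpy()
    latent_epi = levels["dEpinephrine_dose"][:, 1] - levels["dEpinephrine_dose"][:, 0]
    dose = np.where(epi_flag, np.clip(0.05 + 0.02 * latent_epi, 0.005, None), 0.0)

    dropped: set[tuple[int, str]] = set()
    for tp, n_missing in spec.dropout.items():
        if tp not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {tp!r}")
        # the last patients leave the study (discharged/deceased)
        for pid in range(n - int(n_missing), n):
            dropped.add((pid, tp))

    rows = []
    for pid in range(n):
        for t, tp in enumerate(TIMEPOINTS):
            if (pid, tp) in dropped:
                continue
            for ct in CELL_TYPES:
                v = float(levels[f"dV_{ct}"][pid, t])
                nc = float(levels[f"dn_{ct}"][pid, t])
                ff = float(np.clip(levels[f"dFF_{ct}"][pid, t], 0.0, 1.0))
                dm = v / spec.alpha_um3_per_pg * (nc - spec.n_medium)
                mult = spec.d1_spread_multiplier if tp == "d1" else 1.0
                v_sd = 3.0 * spec.radius_cv * mult * v  # CV_V ~ 3*CV_R
                row = {
                    "patient_id": pid,
                    "timepoint": tp,
                    "cell_type": ct,
                    "n_cells": spec.cells_per_sample,
                    "V_mean_um3": v,
                    "V_sd_um3": v_sd,
                    "n_cell_mean": nc,
                    "n_cell_sd": 5e-4 * mult,
                    "DM_mean_pg": dm,
                    "FF_mean": ff,
                    "FF_sd": 0.01,
                    "CRP_mg_dl": float(crp[pid, t]),
                    "epinephrine_dose": float(dose[pid]) if tp != "PreOP" else 0.0,
                    "complicated_course": bool(flags.loc[pid, "complicated_course"]),
                    "epinephrine": bool(flags.loc[pid, "epinephrine"]),
                    "crp_high": bool(flags.loc[pid, "crp_high"]),
                }
                for m in MARKERS:
                    row[m] = float(levels["d" + m][pid, t])
                rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------- phantoms

def phantoms_for_sample(
    v_mean_um3: float,
    n_cell_mean: float,
    n_cells: int,
    spec: CohortSpec,
    timepoint: str = "PreOP",
    label: str = "lymphocyte",
    rng: int | np.random.Generator | None = None,
) -> list[CellPhantom]:
    """Per-cell phantoms whose sample means match a drawn aggregate.

    Radii are drawn with the configured within-sample CV (inflated at
    d1) and then rescaled so the sample-mean volume and refractive index
    equal the aggregate exactly, making end-to-end imaging runs
    comparable to the aggregate path.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mult = spec.d1_spread_multiplier if timepoint == "d1" else 1.0
    r_mean = (3.0 * v_mean_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    phantoms = make_phantom_population(
        n_cells,
        radius_mean_um=r_mean,
        radius_sd_um=spec.radius_cv * mult * r_mean,
        n_cell_mean=n_cell_mean,
        n_cell_sd=5e-4 * mult,
        n_medium=spec.n_medium,
        label=label,
        seed=rng,
    )
    vols = np.array([p.volume_um3 for p in phantoms])
    r_scale = (v_mean_um3 / vols.mean()) ** (1.0 / 3.0)
    n_shift = n_cell_mean - float(np.mean([p.n_cell for p in phantoms]))
    for p in phantoms:
        p.radius_um *= r_scale
        p.n_cell += n_shift
    return phantoms
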