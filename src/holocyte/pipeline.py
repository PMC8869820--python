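"""End-to-end orchestration: simulate -> image -> fit -> aggregate -> stats.

Two execution modes:

``aggregates``
    The cohort simulator emits patient-level aggregates directly and the
    statistics run on those; fast enough for interactive use and tests.
``images``
    Per sample, per-cell phantoms are rendered to off-axis holograms,
    reconstructed and fitted; the measured (not the drawn) aggregates
    feed the statistics. Opt-in because it renders
    n_patients x 4 x 2 x cells_per_sample frames.

Every stage checkpoints a CSV into the run directory; identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import holo, morpho
from .cohort import (CELL_TYPES, MARKERS, TIMEPOINTS, CohortSpec,
                     phantoms_for_sample, simulate_cohort)
from .imaging import center_phantom, render_phase_image, synthesize_hologram
from .morpho import FitSettings, QCRules, fit_sphere_model, qc_filter, segment_cells
from .optics import OpticalConfig
from .stats import (correlation_table, day_difference, group_overlap_counts,
                    pearson_matrix, subgroup_compare)

log = logging.getLogger("holocyte.pipeline")

#: change-variable -> (cohort column, cell type or None for markers)
DELTA_COLUMNS = {
    "dV_lymphocyte": ("V_mean_um3", "lymphocyte"),
    "dV_monocyte": ("V_mean_um3", "monocyte"),
    "dn_lymphocyte": ("n_cell_mean", "lymphocyte"),
    "dn_monocyte": ("n_cell_mean", "monocyte"),
    "dFF_lymphocyte": ("FF_mean", "lymphocyte"),
    "dFF_monocyte": ("FF_mean", "monocyte"),
    "dDM_lymphocyte": ("DM_mean_pg", "lymphocyte"),
    "dDM_monocyte": ("DM_mean_pg", "monocyte"),
    **{"d" + m: (m, None) for m in MARKERS},
    "dEpinephrine_dose": ("epinephrine_dose", None),
}


@dataclass
class RunConfig:
    out_dir: Path = Path("run")
    mode: str = "aggregates"  # or "images"
    seed: int = 0
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    fit: FitSettings = field(default_factory=FitSettings)
    qc: QCRules = field(default_factory=QCRules)
    contrast: tuple[str, str] = ("d1", "PreOP")

    def __post_init__(self) -> None:
        if self.mode not in ("aggregates", "images"):
            raise ValueError("mode must be 'aggregates' or 'images'")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        kwargs: dict = {}
        if "optics" in data:
            kwargs["optics"] = OpticalConfig.from_dict(data["optics"])
        if "cohort" in data:
            kwargs["cohort"] = CohortSpec(**data["cohort"])
        for key in ("out_dir", "mode", "seed"):
            if key in data:
                kwargs[key] = data[key]
        kwargs.update(overrides)
        return cls(**kwargs)


def measure_sample_images(
    v_mean_um3: float,
    n_cell_mean: float,
    n_cells: int,
    config: OpticalConfig,
    cohort_spec: CohortSpec,
    timepoint: str,
    label: str,
    rng: np.random.Generator,
    fit_settings: FitSettings | None = None,
    qc_rules: QCRules | None = None,
) -> tuple[list[morpho.CellMeasurement], list]:
    """Render, record, reconstruct and fit one sample's worth of cells.

    One cell per frame, mirroring single-cell acquisition. Returns the
    QC-kept measurements and the excluded list.
    """
    phantoms = phantoms_for_sample(
        v_mean_um3, n_cell_mean, n_cells, cohort_spec,
        timepoint=timepoint, label=label, rng=rng,
    )
    measurements = []
    for ph in phantoms:
        center_phantom(ph, config)
        phase = render_phase_image(ph, config)
        hologram = synthesize_hologram(phase, config, rng=rng)
        recon = holo.reconstruct_hologram(hologram)
        masks = segment_cells(recon)
        if not masks:
            continue
        m = fit_sphere_model(recon, masks[0], config, fit_settings, label=label)
        measurements.append(m)
    return qc_filter(measurements, qc_rules)


def _cohort_with_imaging(cfg: RunConfig, cohort: pd.DataFrame,
                         rng: np.random.Generator,
                         cells_dir: Path) -> pd.DataFrame:
    cells_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    n_rendered = n_kept = n_excluded = 0
    for _, row in cohort.iterrows():
        kept, excluded = measure_sample_images(
            row["V_mean_um3"], row["n_cell_mean"], int(row["n_cells"]),
            cfg.optics, cfg.cohort, row["timepoint"], row["cell_type"],
            rng, cfg.fit, cfg.qc,
        )
        n_rendered += len(kept) + len(excluded)
        n_kept += len(kept)
        n_excluded += len(excluded)
        recs = morpho.measurements_to_records(
            kept + [m for m, _ in excluded])
        pd.DataFrame(recs).to_csv(
            cells_dir / f"p{int(row['patient_id']):03d}_{row['timepoint']}"
                        f"_{row['cell_type']}.csv", index=False)
        new = dict(row)
        if kept:
            new["n_cells"] = len(kept)
            new["V_mean_um3"] = float(np.mean([m.volume_um3 for m in kept]))
            new["V_sd_um3"] = float(np.std([m.volume_um3 for m in kept], ddof=1)) if len(kept) > 1 else np.nan
            new["n_cell_mean"] = float(np.mean([m.n_cell for m in kept]))
            new["DM_mean_pg"] = float(np.mean([m.dry_mass_pg for m in kept]))
            new["FF_mean"] = float(np.mean([m.ff for m in kept]))
        rows.append(new)
    log.info("imaging: %d cells rendered, %d kept, %d excluded",
             n_rendered, n_kept, n_excluded)
    return pd.DataFrame(rows)


def compute_delta_table(cohort: pd.DataFrame, later: str = "d1",
                        baseline: str = "PreOP") -> tuple[pd.DataFrame, dict]:
    """Per-patient change table over all DHM and marker variables."""
    deltas = {}
    dropped = {}
    for var, (col, ct) in DELTA_COLUMNS.items():
        series, n_drop = day_difference(cohort, later, baseline, col, ct)
        deltas[var] = series
        dropped[var] = n_drop
    return pd.DataFrame(deltas), dropped


def summarize_fig5(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean +/- SD per timepoint, cell type and DHM parameter,
    with paired-contrast p-values of each later day against PreOP."""
    from scipy import stats as sps
    params = {"V_mean_um3": "V", "n_cell_mean": "n_cell",
              "DM_mean_pg": "DM", "FF_mean": "FF"}
    rows = []
    for ct in CELL_TYPES:
        sub = cohort[cohort["cell_type"] == ct]
        if sub.empty:
            continue
        present = [tp for tp in TIMEPOINTS if (sub["timepoint"] == tp).any()]
        for tp in present:
            day = sub[sub["timepoint"] == tp]
            for col, name in params.items():
                row = {
                    "cell_type": ct, "timepoint": tp, "parameter": name,
                    "mean": float(day[col].mean()),
                    "sd": float(day[col].std(ddof=1)) if len(day) > 1 else np.nan,
                    "n_patients": int(day["patient_id"].nunique()),
                    "p_vs_PreOP": np.nan,
                }
                if tp != "PreOP" and "PreOP" in present:
                    a = day.set_index("patient_id")[col]
                    b = sub[sub["timepoint"] == "PreOP"].set_index("patient_id")[col]
                    common = a.index.intersection(b.index)
                    if len(common) >= 2:
                        row["p_vs_PreOP"] = float(
                            sps.ttest_rel(a.loc[common], b.loc[common]).pvalue)
                rows.append(row)
    return pd.DataFrame(rows)


def subgroup_report(cohort: pd.DataFrame, later: str = "d1",
                    baseline: str = "PreOP") -> pd.DataFrame:
    """Subgroup contrasts of the lymphocyte volume change plus overlap counts."""
    dvl, _ = day_difference(cohort, later, baseline, "V_mean_um3", "lymphocyte")
    pat = cohort.drop_duplicates("patient_id").set_index("patient_id")
    rows = []
    for grouping in ("complicated_course", "epinephrine", "crp_high"):
        group = pat[grouping].astype(bool)
        if group.all() or not group.any():
            continue  # degenerate grouping (e.g. subgroup disabled)
        cmp_ = subgroup_compare(dvl, group, grouping=grouping,
                                quantity=f"dV_lymphocyte_{later}-{baseline}")
        rows.append({
            "grouping": grouping, "quantity": cmp_.quantity,
            "n_in": cmp_.n_in, "n_out": cmp_.n_out,
            "mean_in": cmp_.mean_in, "mean_out": cmp_.mean_out,
            "difference": cmp_.difference, "p": cmp_.p, "stars": cmp_.stars,
        })
    report = pd.DataFrame(rows)
    for key, val in group_overlap_counts(cohort).items():
        report[f"venn_{key}"] = val
    return report


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages, checkpointing CSVs into the run directory.

    Emits cohort.csv, table1.csv (change correlations), fig5_summary.csv
    (per-day means), fig6_groups.csv (subgroup contrasts + Venn counts)
    and run.log; in images mode additionally cells/*.csv per sample.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        rng = np.random.default_rng(config.seed)
        log.info("stage simulate: %d patients, mode=%s, seed=%d",
                 config.cohort.n_patients, config.mode, config.seed)
        cohort = simulate_cohort(config.cohort, seed=rng)
        if config.mode == "images":
            log.info("stage imaging: %d samples x %d cells",
                     len(cohort), config.cohort.cells_per_sample)
            cohort = _cohort_with_imaging(config, cohort, rng, out / "cells")
        cohort.to_csv(out / "cohort.csv", index=False)

        later, baseline = config.contrast
        deltas, dropped = compute_delta_table(cohort, later, baseline)
        log.info("stage deltas: %d patients, dropped per variable: %s",
                 len(deltas), {k: v for k, v in dropped.items() if v})
        results = pearson_matrix(deltas)
        correlation_table(results).to_csv(out / "table1.csv", index=False)

        summarize_fig5(cohort).to_csv(out / "fig5_summary.csv", index=False)
        subgroup_report(cohort, later, baseline).to_csv(
            out / "fig6_groups.csv", index=False)
        log.info("run complete")
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
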