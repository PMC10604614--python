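"""End-to-end seeded pipeline: simulate → quantify → eplets → exposure → analyze.

Produces a report bundle (group-comparison tables, three ROC analyses, QC
summaries and figures) from a single YAML-expressible configuration. All
artifacts are stamped with the master seed and a configuration hash; rerun
with the same configuration is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .eplets import cohort_loads
from .exposure import summarize_exposure
from .quant import QuantConfig, estimate_dd_fraction
from .simulate import CohortDataset, SimulationConfig, simulate_cohort
from .stats import (
    DEFAULT_TABLE1_VARIABLES,
    DEFAULT_TABLE2_VARIABLES,
    RocResult,
    build_group_comparison,
    roc_auc_ci,
)

log = logging.getLogger("ddcfdna")


@dataclass
class RunConfig:
    out_dir: str = "ddcfdna_run"
    seed: int = 0
    n_patients: int = 42
    cutoff: float = 1.0
    mode: str = "bias_corrected"
    ci_method: str = "delong"
    continuity_correction: bool = False
    write_inputs: bool = True
    make_plots: bool = True
    simulation: SimulationConfig | None = None
    quant: QuantConfig | None = None

    def resolved_simulation(self) -> SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return SimulationConfig(n_patients=self.n_patients, seed=self.seed)

    def config_hash(self) -> str:
        # only fields that influence the computed results enter the hash
        skip = ("out_dir", "make_plots", "write_inputs")
        payload = {
            k: v for k, v in dataclasses.asdict(self).items() if k not in skip
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        quant = raw.pop("quant", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if quant is not None:
            cfg.quant = QuantConfig(**quant)
        return cfg


def quantify_cohort(
    cohort: CohortDataset, mode: str = "bias_corrected", config: QuantConfig | None = None
) -> pd.DataFrame:
    """Donor-fraction estimates and QC for every sampled patient."""
    rows = []
    for p in cohort.patients:
        if p.sample is None:
            raise ValueError(f"patient {p.patient_id} has no cfDNA sample")
        res = estimate_dd_fraction(p.sample, mode=mode, config=config)
        rows.append(
            {
                "patient_id": p.patient_id,
                "dd_fraction_percent": res.dd_fraction_percent,
                "n_informative": res.n_informative,
                "background_error": res.background_error,
                "qc_pass": res.qc.passed,
                "qc_total_reads": res.qc.total_reads,
                "qc_depth_cv": res.qc.depth_uniformity,
                "qc_n_outliers": res.qc.n_outlier_loci,
                "qc_contamination": res.qc.contamination_flag,
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(rows)


def assemble_analysis_frame(
    cohort: CohortDataset,
    estimates: pd.DataFrame,
    use_recomputed_loads: bool = True,
) -> pd.DataFrame:
    """Join outcomes, covariates, exposure metrics, loads and estimates."""
    truth = cohort.truth_frame()
    exposures = []
    for p in cohort.patients:
        m = summarize_exposure(p.tacrolimus, p.mpa_trough)
        row = {"patient_id": p.patient_id, **dataclasses.asdict(m)}
        row.pop("mpa_trough")  # already in the truth frame
        exposures.append(row)
    df = truth.merge(pd.DataFrame(exposures), on="patient_id", validate="1:1")
    df = df.merge(estimates, on="patient_id", validate="1:1")

    if use_recomputed_loads and cohort.eplet_table is not None:
        loads = cohort_loads(cohort)
        load_df = pd.DataFrame(
            [{"patient_id": pid, **ml.as_dict()} for pid, ml in loads.items()]
        )
    else:
        cols = [
            "true_antigen_mm_total", "true_classI_eplet_load", "true_classII_eplet_load",
            "true_drb1_eplet_load", "true_dqb1_eplet_load", "true_dqa1_eplet_load",
        ]
        load_df = truth[["patient_id"] + cols].rename(
            columns=lambda c: c.removeprefix("true_")
        )
    df = df.merge(load_df, on="patient_id", validate="1:1")
    for col in ("abmr", "acute_rejection", "troubled_graft", "first_year_rejection"):
        df[col] = df[col].astype(int)
    return df


def analyze_cohort(df: pd.DataFrame, cutoff: float = 1.0, ci_method: str = "delong"):
    """Group-comparison tables and the three ROC analyses."""
    table1 = build_group_comparison(df, DEFAULT_TABLE1_VARIABLES, cutoff=cutoff)
    table2 = build_group_comparison(df, DEFAULT_TABLE2_VARIABLES, cutoff=cutoff)
    rocs: dict[str, RocResult] = {}
    for outcome in ("abmr", "acute_rejection", "troubled_graft"):
        y = df[outcome].to_numpy(dtype=int)
        if 0 < y.sum() < y.size:
            rocs[outcome] = roc_auc_ci(
                df["dd_fraction_percent"], y, ci_method=ci_method
            )
    return table1, table2, rocs


def validate_inputs(directory: str | Path) -> list[str]:
    """Schema and cross-file identifier checks on a written input bundle.

    Returns a list of human-readable diagnostics; empty means consistent.
    """
    d = Path(directory)
    diags: list[str] = []
    frames: dict[str, pd.DataFrame] = {}
    expect = {
        "panel.csv": ["locus_id", "chrom", "ref", "alt", "alt_freq"],
        "outcomes.csv": dio.OUTCOME_COLUMNS,
        "tacrolimus.csv": dio.SERIES_COLUMNS,
        "typings.csv": dio.TYPING_COLUMNS,
        "eplet_table.csv": ["allele", "eplet", "class"],
    }
    for name, cols in expect.items():
        path = d / name
        if not path.exists():
            diags.append(f"{name}: file missing")
            continue
        df = pd.read_csv(path)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            diags.append(f"{name}: missing columns {missing}")
            continue
        frames[name] = df
    if "outcomes.csv" in frames:
        ids = set(frames["outcomes.csv"]["patient_id"].astype(str))
        for name in ("tacrolimus.csv", "typings.csv"):
            if name in frames:
                other = set(frames[name]["patient_id"].astype(str))
                for orphan in sorted(other - ids):
                    diags.append(f"{name}: patient {orphan} absent from outcomes.csv")
                for lonely in sorted(ids - other):
                    diags.append(f"outcomes.csv: patient {lonely} has no rows in {name}")
        pileups = sorted((d / "pileups").glob("*.tsv")) if (d / "pileups").is_dir() else []
        pileup_ids = {p.stem for p in pileups}
        for orphan in sorted(pileup_ids - ids):
            diags.append(f"pileups: sample {orphan} absent from outcomes.csv")
        for lonely in sorted(ids - pileup_ids):
            diags.append(f"outcomes.csv: patient {lonely} has no pileup TSV")
    return diags


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic study and write the report bundle.

    Stages: simulate the cohort; write the input files; quantify every
    sample; recompute eplet loads from the typings; derive exposure
    metrics; build the comparison tables and ROC analyses; render figures.
    Every artifact header carries the master seed and config hash.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}
    log.info("run %s: simulating cohort", stamp["config_hash"])

    try:
        cohort = simulate_cohort(config.resolved_simulation())
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    if config.write_inputs:
        try:
            dio.write_panel_csv(cohort.panel, out / "panel.csv")
            dio.write_outcomes_csv(cohort, out / "outcomes.csv")
            dio.write_series_csv(cohort, out / "tacrolimus.csv")
            if cohort.eplet_table is not None:
                dio.write_typings_csv(cohort, out / "typings.csv")
                dio.write_eplet_table_csv(cohort.eplet_table, out / "eplet_table.csv")
            pdir = out / "pileups"
            pdir.mkdir(exist_ok=True)
            for p in cohort.patients:
                if p.sample is not None:
                    dio.write_pileup_tsv(p.sample, pdir / f"{p.patient_id}.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage 'write_inputs' failed: {exc}") from exc

    log.info("quantifying %d samples", len(cohort))
    try:
        estimates = quantify_cohort(cohort, mode=config.mode, config=config.quant)
        df = assemble_analysis_frame(cohort, estimates)
    except Exception as exc:
        raise RuntimeError(f"stage 'quantify' failed: {exc}") from exc

    try:
        table1, table2, rocs = analyze_cohort(df, config.cutoff, config.ci_method)
    except Exception as exc:
        raise RuntimeError(f"stage 'analyze' failed: {exc}") from exc

    n_hi, n_lo = table1.attrs["n_elevated"], table1.attrs["n_low"]
    header = (
        f"# seed={stamp['seed']} config={stamp['config_hash']}\n"
        f"# groups: dd-cfDNA >= {config.cutoff}% (n = {n_hi}) vs "
        f"dd-cfDNA < {config.cutoff}% (n = {n_lo})\n"
    )
    for name, tab in (("table1_clinical.tsv", table1), ("table2_hla.tsv", table2)):
        with open(out / name, "w") as fh:
            fh.write(header)
            tab.to_csv(fh, sep="\t", index=False)
    df.to_csv(out / "per_patient.csv", index=False)

    roc_payload = {
        k: {
            "auc": r.auc, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p_value": r.p_value, "n_pos": r.n_pos, "n_neg": r.n_neg,
        }
        for k, r in rocs.items()
    }
    summary = {
        **stamp,
        "n_patients": len(cohort),
        "n_elevated": n_hi,
        "n_low": n_lo,
        "median_dd_percent": float(np.median(df["dd_fraction_percent"])),
        "qc_pass_rate": float(df["qc_pass"].mean()),
        "roc": roc_payload,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    if config.make_plots:
        try:
            _render_figures(df, rocs, out, config.cutoff)
        except Exception as exc:
            raise RuntimeError(f"stage 'figures' failed: {exc}") from exc

    log.info("report written to %s", out)
    return {"cohort": cohort, "frame": df, "table1": table1, "table2": table2,
            "rocs": rocs, "summary": summary}


def _render_figures(df: pd.DataFrame, rocs, out: Path, cutoff: float) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if rocs:
        fig, axes = plt.subplots(1, len(rocs), figsize=(4 * len(rocs), 4))
        axes = np.atleast_1d(axes)
        for ax, (name, r) in zip(axes, rocs.items()):
            xs, ys = zip(*r.curve_points)
            ax.plot(xs, ys, drawstyle="steps-post")
            ax.plot([0, 1], [0, 1], ls=":", c="grey")
            ax.set_title(f"{name}\nAUC {100 * r.auc:.1f}% [{100 * r.ci_low:.1f}-{100 * r.ci_high:.1f}]")
            ax.set_xlabel("1 - specificity")
            ax.set_ylabel("sensitivity")
        fig.tight_layout()
        fig.savefig(out / "roc_curves.png", dpi=120)
        plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(9, 4), sharey=True)
    for ax, outcome in zip(axes, ("abmr", "acute_rejection", "troubled_graft")):
        groups = [
            df.loc[df[outcome] == 1, "dd_fraction_percent"],
            df.loc[df[outcome] == 0, "dd_fraction_percent"],
        ]
        ax.boxplot(groups, tick_labels=["yes", "no"])
        ax.axhline(cutoff, ls=":", c="grey")
        ax.set_title(outcome)
    axes[0].set_ylabel("dd-cfDNA (%)")
    fig.tight_layout()
    fig.savefig(out / "group_boxplots.png", dpi=120)
    plt.close(fig)
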