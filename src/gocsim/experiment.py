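"""Study orchestration: replicated runs of many schemes with shared bases.

Within a replicate every scheme consumes the same haplotype pool, SNP panels,
QTL effects and initial random-selection generation; randomness downstream of
selection is scheme-specific.  Summaries aggregate across replicates into the
two standard layouts: rates of inbreeding and generation-20 deviations per
panel, and genetic gain with inbreeding at the neutral panel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scheme import (
    BaseConfig,
    SchemeResult,
    initialize_replicate,
    run_scheme,
    table1_schemes,
)

__all__ = [
    "ExperimentPlan",
    "ExperimentResult",
    "run_experiment",
    "paired_comparison",
    "summarize_records",
]


@dataclass(frozen=True)
class ExperimentPlan:
    schemes: tuple = field(default_factory=lambda: tuple(table1_schemes()))
    replicates: int = 100
    base: BaseConfig = field(default_factory=BaseConfig)
    n_generations: int = 20
    master_seed: int = 1
    out_dir: str | None = None

    @staticmethod
    def desk(master_seed: int = 1, **kwargs) -> "ExperimentPlan":
        """Desk-scale preset: 10 replicates, identical model constants."""
        kwargs.setdefault("replicates", 10)
        return ExperimentPlan(master_seed=master_seed, **kwargs)


@dataclass
class ExperimentResult:
    plan: ExperimentPlan
    records: pd.DataFrame            # per scheme x replicate x panel metrics
    rate_table: pd.DataFrame         # dF_hom / dF_drift / F_hom - F_drift per panel
    gain_table: pd.DataFrame         # gain, SE, F_hom(N), F_drift(N)
    results: dict                    # label -> list of SchemeResult per replicate
    failures: list = field(default_factory=list)


def _fit_rate(f_series: np.ndarray):
    """Rate regression on the pre-saturation portion (F < 1; drift-based F is
    unbounded and can saturate the log transform under extreme management)."""
    from .metrics import delta_f_regression

    t = np.arange(1, f_series.shape[0] + 1, dtype=float)
    ok = f_series < 1.0
    if ok.sum() < 3:
        return None
    return delta_f_regression(f_series[ok], t[ok])


def _scheme_record(result: SchemeResult, replicate: int) -> list[dict]:
    rows = []
    last_gen = int(result.panel_metrics["generation"].max())
    for panel in sorted(result.panel_metrics["panel"].unique()):
        est_hom = _fit_rate(result.f_series(panel, "F_hom"))
        est_drift = _fit_rate(result.f_series(panel, "F_drift"))
        fh = result.f_series(panel, "F_hom")[-1]
        fd = result.f_series(panel, "F_drift")[-1]
        rows.append(
            {
                "scheme": result.config.label,
                "replicate": replicate,
                "panel": panel,
                "dF_hom": est_hom.neg_slope if est_hom else np.nan,
                "dF_drift": est_drift.neg_slope if est_drift else np.nan,
                "dF_hom_exp": est_hom.delta_f if est_hom else np.nan,
                "dF_drift_exp": est_drift.delta_f if est_drift else np.nan,
                "F_hom_final": fh,
                "F_drift_final": fd,
                "hom_minus_drift": fh - fd,
                "r2_log1mFdrift": est_drift.r_squared if est_drift else np.nan,
                "final_generation": last_gen,
                "gain": result.gain(),
            }
        )
    return rows


def run_experiment(plan: ExperimentPlan, progress: bool = False) -> ExperimentResult:
    """Run every scheme on every replicate and aggregate.

    Deterministic given the master seed.  A replicate aborted by a solver
    failure in one scheme is logged and excluded for that scheme only.
    """
    rows: list[dict] = []
    results: dict[str, list[SchemeResult]] = {c.label: [] for c in plan.schemes}
    failures: list[dict] = []
    out = Path(plan.out_dir) if plan.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    for r in range(plan.replicates):
        shared = initialize_replicate(
            plan.base, np.random.SeedSequence([plan.master_seed, r])
        )
        for si, cfg in enumerate(plan.schemes):
            if cfg.n_generations != plan.n_generations:
                cfg = dataclasses.replace(cfg, n_generations=plan.n_generations)
            seed = np.random.SeedSequence([plan.master_seed, r, 1000 + si])
            try:
                res = run_scheme(shared, cfg, seed)
            except Exception as err:  # partial-failure tolerance
                failures.append({"scheme": cfg.label, "replicate": r, "error": str(err)})
                continue
            results[cfg.label].append(res)
            rows.extend(_scheme_record(res, r))
            if out:
                stem = cfg.label.replace("(", "_").replace(")", "").replace(",", "-")
                res.panel_metrics.assign(replicate=r).to_csv(
                    out / f"{stem}_rep{r}_panels.csv", index=False
                )
                res.generation_metrics.assign(replicate=r).to_csv(
                    out / f"{stem}_rep{r}_generations.csv", index=False
                )
            if progress:
                print(f"replicate {r} scheme {cfg.label} done", flush=True)
    records = pd.DataFrame(rows)
    rate_table, gain_table = summarize_records(records)
    if out:
        records.to_csv(out / "records.csv", index=False)
        rate_table.to_csv(out / "rate_table.csv", index=False)
        gain_table.to_csv(out / "gain_table.csv", index=False)
        manifest = {
            "master_seed": plan.master_seed,
            "replicates": plan.replicates,
            "schemes": [c.label for c in plan.schemes],
            "n_failures": len(failures),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ExperimentResult(
        plan=plan,
        records=records,
        rate_table=rate_table,
        gain_table=gain_table,
        results=results,
        failures=failures,
    )


def _sem(x: pd.Series) -> float:
    n = x.shape[0]
    return float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan


def summarize_records(records: pd.DataFrame):
    """Across-replicate means and standard errors in the two table layouts."""
    g = records.groupby(["scheme", "panel"])
    rate = g.agg(
        dF_hom=("dF_hom", "mean"),
        dF_hom_se=("dF_hom", _sem),
        dF_drift=("dF_drift", "mean"),
        dF_drift_se=("dF_drift", _sem),
        hom_minus_drift=("hom_minus_drift", "mean"),
        hom_minus_drift_se=("hom_minus_drift", _sem),
        replicates=("replicate", "count"),
    ).reset_index()
    n_panel = records[records["panel"] == "N"]
    gain = n_panel.groupby("scheme").agg(
        gain=("gain", "mean"),
        gain_se=("gain", _sem),
        F_hom=("F_hom_final", "mean"),
        F_drift=("F_drift_final", "mean"),
        replicates=("replicate", "count"),
    ).reset_index()
    return rate, gain


def paired_comparison(
    reference: list[SchemeResult],
    comparison: list[SchemeResult],
    panel: str = "N",
):
    """Per-replicate wins of the reference scheme at matched inbreeding.

    For each replicate the comparison scheme's gain-versus-inbreeding curve
    (inbreeding = the average of F_hom and F_drift on ``panel``) is linearly
    interpolated at the reference scheme's final-generation inbreeding; a win
    is a strictly greater reference gain.  Returns (wins, n_replicates).
    """
    if len(reference) != len(comparison):
        raise ValueError("need matched replicate lists")
    wins = 0
    for ref, cmp_ in zip(reference, comparison):
        x_ref = 0.5 * (ref.f_series(panel, "F_hom") + ref.f_series(panel, "F_drift"))
        g_ref = ref.generation_metrics.sort_values("generation")["mean_tbv_candidates"].to_numpy()
        x_cmp = 0.5 * (cmp_.f_series(panel, "F_hom") + cmp_.f_series(panel, "F_drift"))
        g_cmp = cmp_.generation_metrics.sort_values("generation")["mean_tbv_candidates"].to_numpy()
        order = np.argsort(x_cmp)
        g_interp = np.interp(x_ref[-1], x_cmp[order], g_cmp[order])
        if g_ref[-1] > g_interp:
            wins += 1
    return wins, len(reference)
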