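"""End-to-end analysis pipeline over a measurement table.

Reproduces the full analysis sequence on any cohort in the package's CSV
format: per-image threshold classification under the six rule sets,
congruence tables against the visual (BT-RADS) reference, ROC/AUC
comparison of the three percent-change measures with paired DeLong tests,
the threshold sensitivity/specificity sweep, inter-reader weighted kappa,
and trajectory-model classification versus the visual reference.

All randomness derives from one root seed; rerunning with the same seed and
inputs yields byte-identical structured output apart from a single isolated
timestamp metadata field.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .concordance import (
    delong_paired_test,
    optimal_threshold_range,
    stratified_bootstrap_auc_ci,
    weighted_kappa,
)
from .criteria import (
    CRITERIA_NAMES,
    ResponseLabel,
    build_criteria,
    classify_series,
    congruence_table,
    map_btrads_to_category,
)
from .growth import TumorGrowthModel, CohortGrowthModel
from .measurements import Measure, ParticipantSeries, percent_change

log = logging.getLogger("plggvol")


@dataclass
class RunConfig:
    """Settings for one pipeline run.

    The growth-stage sizes default to reduced values suited to a full-report
    run on one CPU; the library-level defaults on
    :meth:`~plggvol.growth.TumorGrowthModel.fit_bootstrap` retain the study
    settings (200 bootstrap replicates, 32 walkers x 2000 steps).
    """

    criteria: tuple[str, ...] = CRITERIA_NAMES
    measures: tuple[str, ...] = ("area2d", "solid_volume", "whole_volume")
    n_boot_roc: int = 2000
    pd_grid: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0)
    pr_grid: tuple[float, ...] = tuple(float(x) for x in range(-15, -70, -5))
    target_sensitivity: float = 0.80
    kappa_scheme: str = "linear"
    growth_enabled: bool = True
    growth_measure: str = "solid_volume"
    growth_noise_cv: float = 0.10
    growth_n_boot: int = 20
    growth_n_walkers: int = 16
    growth_n_steps: int = 600
    shared_lambda: bool = True
    cohort_fit_n_steps: int = 800
    min_prior_images: int = 3
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.criteria) - set(CRITERIA_NAMES)
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")
        for m in self.measures + (self.growth_measure,):
            Measure(m)
        if self.n_boot_roc < 1 or self.growth_n_boot < 1:
            raise ValueError("bootstrap counts must be >= 1")
        if self.kappa_scheme not in ("linear", "quadratic"):
            raise ValueError("kappa_scheme must be linear or quadratic")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def consensus_btrads(tp) -> Optional[str]:
    """Consensus visual score for one image: the first reader's score, which
    stands in for the adjudicated read (a third-reader tie-break is not
    representable with two recorded reads)."""
    if not tp.btrads_reads:
        return None
    return tp.btrads_reads[0]


def _assessment_rows(series_list: Sequence[ParticipantSeries]) -> pd.DataFrame:
    """Percent changes and visual labels for every image carrying a BT-RADS read."""
    rows = []
    for s in series_list:
        base = {m: s.baseline.value(m) for m in Measure}
        for tp in s.followups:
            score = consensus_btrads(tp)
            if score is None:
                continue
            row = {
                "participant_id": s.participant_id,
                "t_days": tp.t_days,
                "btrads": score,
                "btrads_category": map_btrads_to_category(score).value,
                "new_lesion": tp.new_lesion,
            }
            for m in Measure:
                v = tp.value(m)
                row[f"pct_{m.value}"] = (
                    percent_change(v, base[m])
                    if v is not None and base[m] and base[m] > 0
                    else math.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


def classification_frame(
    series_list: Sequence[ParticipantSeries], criteria_names: Sequence[str]
) -> pd.DataFrame:
    """Per-follow-up labels for each requested rule set, long format."""
    rows = []
    for name in criteria_names:
        spec = build_criteria(name)
        for s in series_list:
            base = s.baseline.value(spec.measure)
            for (t, label), tp in zip(classify_series(s, spec), s.followups):
                v = tp.value(spec.measure)
                pct = (
                    percent_change(v, base)
                    if v is not None and base and base > 0
                    else math.nan
                )
                rows.append({
                    "participant_id": s.participant_id,
                    "t_days": t,
                    "criteria": name,
                    "measure": spec.measure.value,
                    "pct_change": pct,
                    "label": label.value if label is not None else "",
                })
    return pd.DataFrame(rows)


def _grouped(label: ResponseLabel) -> str:
    """Fold minor response into PR for comparison against the visual labels."""
    return "PR" if label in (ResponseLabel.PR, ResponseLabel.MinR) else label.value


def run_pipeline(
    config: RunConfig,
    series_list: Sequence[ParticipantSeries],
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Execute classify → concordance → growth-model stages.

    Returns the report bundle as a dict; when ``out_dir`` is given the
    bundle is also written as JSON/CSV files.  Stage failures are isolated:
    a failing stage is logged and flagged in the report rather than aborting
    the run.
    """
    config.validate()
    report: dict = {
        "meta": {
            "package_version": __version__,
            "root_seed": config.seed,
            "config_hash": config.config_hash(),
            "timestamp": None,  # filled only on disk write, kept out of hashing
        },
        "stages": {},
    }
    log.info("pipeline start: seed=%s config=%s", config.seed,
             config.config_hash())

    # --- stage 1: threshold classification --------------------------------
    cls_df = classification_frame(series_list, config.criteria)
    report["stages"]["classification"] = {"n_rows": int(len(cls_df))}

    assess = _assessment_rows(series_list)
    if assess.empty:
        report["stages"]["concordance"] = {"skipped": "no BT-RADS reads"}
        conc_ok = False
    else:
        conc_ok = True

    congruence: dict = {}
    roc_report: dict = {}
    thresholds_df = pd.DataFrame()
    kappa_report: dict = {}

    if conc_ok:
        # --- congruence of rule-set labels vs visual reference ------------
        ref = [ResponseLabel(c) for c in assess["btrads_category"]]
        for name in config.criteria:
            spec = build_criteria(name)
            labels = []
            keep = []
            for i, (_, row) in enumerate(assess.iterrows()):
                pct = row[f"pct_{spec.measure.value}"]
                if math.isnan(pct) and not row["new_lesion"]:
                    continue
                from .criteria import classify_change

                lab = classify_change(
                    0.0 if math.isnan(pct) else pct, spec,
                    new_lesion=bool(row["new_lesion"]),
                )
                labels.append(ResponseLabel(_grouped(lab)))
                keep.append(i)
            tab = congruence_table(labels, [ref[i] for i in keep])
            congruence[name] = {
                "table": tab["table"].to_dict(),
                "sensitivity": tab["sensitivity"],
                "specificity": tab["specificity"],
                "observed_agreement": tab["observed_agreement"],
            }

        # --- ROC / AUC / DeLong -------------------------------------------
        rng = np.random.default_rng(config.seed)
        for positive in ("PD", "PR"):
            orient = 1 if positive == "PD" else -1
            y = (assess["btrads_category"] == positive).astype(int).to_numpy()
            entry: dict = {"auc": {}, "delong": {}}
            scores_by_measure = {}
            for m in config.measures:
                s = orient * assess[f"pct_{m}"].to_numpy()
                ok = ~np.isnan(s)
                if y[ok].sum() == 0 or y[ok].sum() == ok.sum():
                    entry["auc"][m] = None
                    continue
                scores_by_measure[m] = (s, ok)
                res = stratified_bootstrap_auc_ci(
                    s[ok], y[ok], n_boot=config.n_boot_roc,
                    seed=int(rng.integers(2**31 - 1)),
                )
                entry["auc"][m] = {
                    "auc": res.auc, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "n": int(ok.sum()),
                    "n_boot": res.n_boot,
                }
            ms = list(scores_by_measure)
            for i in range(len(ms)):
                for j in range(i + 1, len(ms)):
                    (sa, oka), (sb, okb) = (scores_by_measure[ms[i]],
                                            scores_by_measure[ms[j]])
                    ok = oka & okb
                    d, z, p = delong_paired_test(sa[ok], sb[ok], y[ok])
                    entry["delong"][f"{ms[i]}_vs_{ms[j]}"] = {
                        "auc_diff": d, "z": z, "p": p,
                    }
            roc_report[positive] = entry

        # --- threshold sweep on solid volume ------------------------------
        rows = []
        for positive, grid, orient in (
            ("PD", config.pd_grid, 1),
            ("PR", config.pr_grid, -1),
        ):
            y = (assess["btrads_category"] == positive).astype(int).to_numpy()
            s = assess["pct_solid_volume"].to_numpy()
            ok = ~np.isnan(s)
            if y[ok].sum() in (0, ok.sum()):
                continue
            perfs = optimal_threshold_range(
                orient * s[ok], y[ok], [orient * g for g in grid],
                target_sens=config.target_sensitivity,
                n_boot=config.n_boot_roc,
                seed=int(rng.integers(2**31 - 1)),
            )
            for g, perf in zip(grid, perfs):
                rows.append({
                    "positive": positive,
                    "threshold_pct": g,
                    "sensitivity": perf.sensitivity.value,
                    "sens_ci_low": perf.sensitivity.ci_low,
                    "sens_ci_high": perf.sensitivity.ci_high,
                    "specificity": perf.specificity.value,
                    "spec_ci_low": perf.specificity.ci_low,
                    "spec_ci_high": perf.specificity.ci_high,
                    "selected": perf.selected,
                })
        thresholds_df = pd.DataFrame(rows)

        # --- inter-reader agreement ---------------------------------------
        reads = [
            tp.btrads_reads
            for s in series_list
            for tp in s.followups
            if len(tp.btrads_reads) == 2
        ]
        if len(reads) >= 2:
            r1, r2 = zip(*reads)
            kr = weighted_kappa(r1, r2, scheme=config.kappa_scheme)
            kappa_report = {
                "kappa_weighted": kr.kappa_weighted,
                "kappa_unweighted": kr.kappa_unweighted,
                "observed_agreement": kr.observed_agreement,
                "weight_scheme": kr.weight_scheme,
                "n_images": len(reads),
            }
        report["stages"]["concordance"] = {
            "congruence": congruence,
            "roc": roc_report,
            "kappa": kappa_report,
        }

    # --- stage 3: growth-model classification -----------------------------
    growth_report: dict = {}
    if config.growth_enabled and conc_ok:
        try:
            growth_report = _growth_stage(config, series_list, assess)
        except Exception as e:  # noqa: BLE001 - stage isolation by contract
            log.exception("growth stage failed")
            growth_report = {"failed": str(e)}
    report["stages"]["growth"] = growth_report

    if out_dir is not None:
        _write_bundle(report, cls_df, thresholds_df, Path(out_dir))
    return {
        "report": report,
        "classification": cls_df,
        "thresholds": thresholds_df,
        "assessments": assess,
    }


def _growth_stage(config: RunConfig, series_list, assess: pd.DataFrame) -> dict:
    measure = Measure(config.growth_measure)
    rng = np.random.default_rng(config.seed + 1)

    # evaluation images with enough history for a trajectory fit
    eligible: list[tuple[ParticipantSeries, float, str]] = []
    skipped = []
    for _, row in assess.iterrows():
        s = next(x for x in series_list if x.participant_id == row["participant_id"])
        t_eval = row["t_days"]
        n_prior = sum(
            1 for tp in s.timepoints
            if tp.t_days < t_eval and tp.value(measure) is not None
        )
        if n_prior >= config.min_prior_images:
            eligible.append((s, t_eval, row["btrads_category"]))
        else:
            skipped.append((row["participant_id"], float(t_eval), n_prior))
    for pid, t, n in skipped:
        log.info("growth stage: skipping %s @ %.0f d (%d prior images < %d)",
                 pid, t, n, config.min_prior_images)
    if not eligible:
        return {"skipped": "no eligible evaluation images",
                "n_skipped": len(skipped)}

    fix_lam = None
    shared: dict = {}
    if config.shared_lambda:
        participants = {s.participant_id: s for s, _, _ in eligible}
        cohort = CohortGrowthModel(
            list(participants.values()), measure=measure,
            noise_cv=config.growth_noise_cv,
        )
        cres = cohort.fit(n_steps=config.cohort_fit_n_steps,
                          seed=int(rng.integers(2**31 - 1)))
        fix_lam = cres.lam_median
        shared = {"lambda_median": fix_lam,
                  "acceptance_fraction": cres.acceptance_fraction}

    fits = {}
    rows = []
    for s, t_eval, ref in eligible:
        key = s.participant_id
        if key not in fits:
            model = TumorGrowthModel(
                s, measure=measure, noise_cv=config.growth_noise_cv,
                fix_lam=fix_lam,
            )
            fits[key] = model.fit_bootstrap(
                n_boot=config.growth_n_boot,
                n_walkers=config.growth_n_walkers,
                n_steps=config.growth_n_steps,
                seed=int(rng.integers(2**31 - 1)),
            )
        cls = fits[key].classify(t_eval)
        rows.append({
            "participant_id": key,
            "t_days": t_eval,
            "model_label": cls.label,
            "btrads_category": ref,
            "t_vmin_q75": cls.t_vmin_q75,
        })
    df = pd.DataFrame(rows)
    cats = [ResponseLabel(c) for c in df["btrads_category"]]
    mod = [ResponseLabel(c) for c in df["model_label"]]
    tab = congruence_table(mod, cats)
    perf = {}
    for positive in ("PD", "PR"):
        tp_ = int(((df["model_label"] == positive)
                   & (df["btrads_category"] == positive)).sum())
        fp = int(((df["model_label"] == positive)
                  & (df["btrads_category"] != positive)).sum())
        fn = int(((df["model_label"] != positive)
                  & (df["btrads_category"] == positive)).sum())
        tn = len(df) - tp_ - fp - fn
        perf[positive] = {
            "sensitivity": tp_ / (tp_ + fn) if tp_ + fn else math.nan,
            "ppv": tp_ / (tp_ + fp) if tp_ + fp else math.nan,
            "npv": tn / (tn + fn) if tn + fn else math.nan,
        }
    return {
        "shared_lambda": shared,
        "n_images": int(len(df)),
        "n_skipped": len(skipped),
        "contingency": tab["table"].to_dict(),
        "observed_agreement": tab["observed_agreement"],
        "performance": perf,
        "per_image": df.to_dict(orient="records"),
    }


def _write_bundle(report: dict, cls_df: pd.DataFrame,
                  thresholds_df: pd.DataFrame, out_dir: Path) -> None:
    import datetime

    out_dir.mkdir(parents=True, exist_ok=True)
    report = dict(report)
    report["meta"] = dict(report["meta"])
    report["meta"]["timestamp"] = datetime.datetime.now().isoformat()
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float)
    )
    cls_df.to_csv(out_dir / "classification.csv", index=False,
                  float_format="%.17g")
    if not thresholds_df.empty:
        thresholds_df.to_csv(out_dir / "thresholds.csv", index=False,
                             float_format="%.17g")
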