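"""End-to-end orchestration: raw streams -> feature table -> cohort report.

``analyze_patient`` turns one patient's SpO2 and actigraphy streams into
long-format feature rows (one row per patient, period, feature) plus an
exclusion log.  ``cohort_report`` is a pure function of the assembled
feature table: re-running it on the written table reproduces the report bit
for bit.  ``run_pipeline`` wires file input and output around the two.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cleaning import BIN_MISSING, CleanSeries, clean_segment_audit, quality_fractions
from .config import PipelineConfig
from .features import (
    OCCASIONAL_DESATURATOR,
    FeatureError,
    classify_desaturator,
    period_features,
    sleep_metrics,
    two_night_vs_week_category,
    weekly_summary,
)
from .io_formats import (
    ActigraphySeries,
    FormatError,
    Spo2Series,
    read_actigraphy_csv,
    read_spo2_csv,
    write_feature_table,
)
from .segmentation import (
    ACTIVITY_NAMES,
    LIPA,
    MVPA,
    REST,
    Exclusion,
    Segment,
    apply_retention_rules,
    clock_windows,
    detect_bed_intervals,
    sample_activity_labels,
    split_day_night,
)

UNITS = {
    "mean_spo2": "percent",
    "spo2_sd": "points",
    "ct90": "percent",
    "range_spo2": "points",
    "n_valid_bins": "count",
    "n_raw_samples": "count",
    "fraction_error": "fraction",
    "fraction_cleaned": "fraction",
    "fraction_valid": "fraction",
    "tnst": "minutes",
    "waso": "minutes",
    "seff": "percent",
    "time_in_bed": "minutes",
}


def bin_activity_labels(cs: CleanSeries, act: ActigraphySeries, cfg) -> np.ndarray:
    """Activity label per 20-s bin, looked up at the bin midpoint second."""
    mid_secs = cs.bin_times.astype("int64") + cs.bin_seconds // 2
    probe = Spo2Series(
        mid_secs.astype("datetime64[s]"),
        np.zeros(len(mid_secs), dtype=np.int16),
    )
    return sample_activity_labels(probe, act, cfg)


def _rows(patient: str, date: str, kind: str, values: dict[str, float | None]) -> list[dict]:
    return [
        {
            "patient": patient,
            "period_date": date,
            "period_kind": kind,
            "feature": feat,
            "value": val,
            "units": UNITS[feat],
        }
        for feat, val in values.items()
        if val is not None
    ]


def analyze_patient(
    patient_id: str,
    spo2: Spo2Series,
    act: ActigraphySeries,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[dict], list[Exclusion]]:
    """Segment, clean and featurise one patient-week.

    Returns long-format feature rows plus the exclusion log.  Night periods
    carry SpO2 features, quality fractions and sleep metrics; day periods
    additionally carry rest/LIPA/MVPA-scoped quality fractions, day-in-rest
    features with the within-day range, and (for eligible days) afternoon
    and evening rest means.
    """
    if len(spo2) == 0:
        raise FormatError(f"{patient_id}: empty SpO2 series")
    if len(act) == 0:
        raise FormatError(f"{patient_id}: empty actigraphy series")
    fcfg, scfg, ccfg = config.features, config.segmentation, config.cleaning
    beds = detect_bed_intervals(act, scfg)
    segments = split_day_night(spo2, beds)
    retained, exclusions = apply_retention_rules(segments, scfg)

    rows: list[dict] = []
    for seg in retained:
        cs, qf, audited = clean_segment_audit(seg.spo2, seg.start, seg.end, ccfg)
        if not cs.nonmissing.any():
            exclusions.append(Exclusion(seg.date, seg.kind, "no valid bins after cleaning", 0))
            continue
        pf = period_features(cs, fcfg.spo2_threshold)
        base = {
            "mean_spo2": pf.mean_spo2,
            "spo2_sd": pf.spo2_sd,
            "ct90": pf.ct90,
            "n_valid_bins": float(pf.n_valid_bins),
            "n_raw_samples": float(qf.n_samples),
            **qf.as_dict(),
        }
        if seg.kind == "night":
            sm = sleep_metrics(act, seg.bed)
            base.update(
                tnst=sm.tnst, waso=sm.waso, seff=sm.seff, time_in_bed=sm.time_in_bed
            )
            rows += _rows(patient_id, seg.date, "night", base)
            continue

        rows += _rows(patient_id, seg.date, "day", base)
        sample_labels = sample_activity_labels(audited, act, fcfg)
        bin_labels = bin_activity_labels(cs, act, fcfg)
        for code in (REST, LIPA, MVPA):
            mask = sample_labels == code
            if not mask.any():
                continue
            qf_scope = quality_fractions(audited.status, mask)
            rows += _rows(
                patient_id, seg.date, f"day_{ACTIVITY_NAMES[code]}",
                {"n_raw_samples": float(qf_scope.n_samples), **qf_scope.as_dict()},
            )
        rest_bins = (bin_labels == REST) & cs.nonmissing
        if rest_bins.any():
            pf_rest = period_features(
                cs, fcfg.spo2_threshold, bin_mask=bin_labels == REST, with_range=True
            )
            rows += _rows(
                patient_id, seg.date, "day_rest",
                {
                    "mean_spo2": pf_rest.mean_spo2,
                    "spo2_sd": pf_rest.spo2_sd,
                    "ct90": pf_rest.ct90,
                    "range_spo2": pf_rest.range_spo2,
                    "n_valid_bins": float(pf_rest.n_valid_bins),
                },
            )
        windows = clock_windows(seg, scfg)
        if windows.afternoon_eligible and windows.evening_eligible:
            bin_secs = cs.bin_times.astype("int64")
            rest_valid = (bin_labels == REST) & cs.nonmissing
            means = {}
            for name, (a, b) in (
                ("afternoon", windows.afternoon), ("evening", windows.evening)
            ):
                in_window = (
                    (bin_secs >= a.astype("int64")) & (bin_secs < b.astype("int64")) & rest_valid
                )
                if in_window.any():
                    means[name] = float(cs.values[in_window].mean())
            if len(means) == 2:  # both windows contributed rest bins
                for name, value in means.items():
                    rows += _rows(patient_id, seg.date, name, {"mean_spo2": value})
    return rows, exclusions


def feature_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    return df.sort_values(["patient", "period_date", "period_kind", "feature"]).reset_index(
        drop=True
    )


def _pivot(table: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Wide per-period frame for one period kind."""
    sub = table[table["period_kind"] == kind]
    if sub.empty:
        return pd.DataFrame()
    return sub.pivot_table(
        index=["patient", "period_date"], columns="feature", values="value", aggfunc="first"
    ).reset_index()


def patient_weekly(table: pd.DataFrame) -> dict[str, dict]:
    """Per-patient weekly summaries (averages, ranges, category) from the table."""
    out: dict[str, dict] = {}
    kinds = {
        "night": ["mean_spo2", "spo2_sd", "ct90", "tnst", "waso", "seff"],
        "day": ["mean_spo2", "spo2_sd", "ct90"],
        "day_rest": ["mean_spo2", "spo2_sd", "ct90", "range_spo2"],
    }
    for patient in sorted(table["patient"].unique()):
        ptab = table[table["patient"] == patient]
        summary: dict = {"patient": patient}
        for kind, feats in kinds.items():
            wide = _pivot(ptab, kind)
            if wide.empty:
                continue
            present = [f for f in feats if f in wide.columns]
            summary[kind] = weekly_summary({f: wide[f].tolist() for f in present})
        nights = _pivot(ptab, "night")
        if not nights.empty and "ct90" in nights.columns:
            ct90 = nights.sort_values("period_date")["ct90"].dropna().tolist()
            if len(ct90) >= 2:
                summary["n_nights"] = len(ct90)
                summary["desaturator_category"] = classify_desaturator(ct90)
                summary["two_night_discordant"] = two_night_vs_week_category(ct90)
        out[patient] = summary
    return out


def _weighted_quality(table: pd.DataFrame, kinds: list[str]) -> dict[str, float] | None:
    sub = table[table["period_kind"].isin(kinds)]
    wide = sub.pivot_table(
        index=["patient", "period_date", "period_kind"],
        columns="feature", values="value", aggfunc="first",
    )
    needed = {"n_raw_samples", "fraction_error", "fraction_cleaned", "fraction_valid"}
    if wide.empty or not needed.issubset(wide.columns):
        return None
    n = wide["n_raw_samples"]
    total = float(n.sum())
    if total == 0:
        return None
    out = {"n_samples": total}
    for frac in ("fraction_error", "fraction_cleaned", "fraction_valid"):
        out[f"{frac.replace('fraction', 'pct')}"] = 100.0 * float((wide[frac] * n).sum()) / total
    return out


def _mean_sd(values: list[float]) -> dict[str, float] | None:
    arr = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
    if len(arr) == 0:
        return None
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "n": int(len(arr)),
    }


def cohort_report(table: pd.DataFrame) -> dict:
    """Cohort-level summary computed entirely from the feature table.

    Per-scope means (SD) of the patients' weekly averages and ranges, the
    night versus day-in-rest paired t test, SD-versus-mean correlations,
    desaturator category counts, sample-weighted quality fractions by scope
    and activity class, and the afternoon-evening contrast.  Nothing is
    hard-coded; single-patient input yields a report with the tests marked
    not applicable.
    """
    from .stats import StatsError, paired_t_test, pearson_correlation

    weekly = patient_weekly(table)
    report: dict = {"n_patients": len(weekly)}

    scopes: dict = {}
    for kind in ("night", "day", "day_rest"):
        feats: dict = {}
        names = ["mean_spo2", "spo2_sd", "ct90"] + (
            ["range_spo2"] if kind == "day_rest" else []
        ) + (["tnst", "waso", "seff"] if kind == "night" else [])
        for feat in names:
            averages = [w.get(kind, {}).get(feat, {}).get("average") for w in weekly.values()]
            ranges = [w.get(kind, {}).get(feat, {}).get("range") for w in weekly.values()]
            entry = {}
            avg = _mean_sd([a for a in averages if a is not None])
            rng = _mean_sd([r for r in ranges if r is not None])
            if avg:
                entry["weekly_average"] = avg
            if rng:
                entry["weekly_range"] = rng
            if entry:
                feats[feat] = entry
        if feats:
            scopes[kind] = feats
    report["weekly_features"] = scopes

    # night vs day-in-rest paired test on weekly averages of mean SpO2
    pairs = [
        (
            w["night"]["mean_spo2"]["average"],
            w["day_rest"]["mean_spo2"]["average"],
        )
        for w in weekly.values()
        if "mean_spo2" in w.get("night", {}) and "mean_spo2" in w.get("day_rest", {})
    ]
    if len(pairs) >= 2:
        try:
            res = paired_t_test([p[0] for p in pairs], [p[1] for p in pairs])
            report["night_vs_day_rest"] = asdict(res)
        except StatsError as exc:
            report["night_vs_day_rest"] = {"not_applicable": str(exc)}
    else:
        report["night_vs_day_rest"] = {"not_applicable": "fewer than two complete pairs"}

    # SD-versus-mean correlation per scope
    correlations: dict = {}
    for kind in ("night", "day", "day_rest"):
        xy = [
            (w[kind]["mean_spo2"]["average"], w[kind]["spo2_sd"]["average"])
            for w in weekly.values()
            if "mean_spo2" in w.get(kind, {}) and "spo2_sd" in w.get(kind, {})
        ]
        if len(xy) >= 3:
            try:
                res = pearson_correlation([p[0] for p in xy], [p[1] for p in xy])
                correlations[kind] = asdict(res)
            except StatsError as exc:
                correlations[kind] = {"not_applicable": str(exc)}
        else:
            correlations[kind] = {"not_applicable": "fewer than three patients"}
    report["sd_vs_mean_correlation"] = correlations

    # desaturator categories
    cats = [w["desaturator_category"] for w in weekly.values() if "desaturator_category" in w]
    counts = {c: cats.count(c) for c in sorted(set(cats))}
    occasional = [
        w for w in weekly.values()
        if w.get("desaturator_category") == OCCASIONAL_DESATURATOR
    ]
    discordant = sum(1 for w in occasional if w.get("two_night_discordant"))
    report["desaturation"] = {
        "category_counts": counts,
        "n_classified": len(cats),
        "pct_switching_category": 100.0 * len(occasional) / len(cats) if cats else None,
        "n_occasional_two_night_discordant": discordant,
        "pct_occasional_two_night_discordant": (
            100.0 * discordant / len(occasional) if occasional else None
        ),
    }

    # quality accounting by scope and activity class
    quality = {}
    for name, kinds in (
        ("overall", ["night", "day"]),
        ("night", ["night"]),
        ("day", ["day"]),
        ("day_rest", ["day_rest"]),
        ("day_lipa", ["day_lipa"]),
        ("day_mvpa", ["day_mvpa"]),
        ("day_rest_lipa", ["day_rest", "day_lipa"]),
    ):
        q = _weighted_quality(table, kinds)
        if q is not None:
            quality[name] = q
    report["data_quality"] = quality

    # afternoon vs evening rest means, paired per day
    aft = _pivot(table, "afternoon")
    eve = _pivot(table, "evening")
    if not aft.empty and not eve.empty:
        merged = aft.merge(eve, on=["patient", "period_date"], suffixes=("_aft", "_eve"))
        diffs = (merged["mean_spo2_aft"] - merged["mean_spo2_eve"]).tolist()
        stats = _mean_sd(diffs)
        if stats:
            stats["n_days"] = stats.pop("n")
            stats["n_patients"] = int(merged["patient"].nunique())
            report["afternoon_evening_difference"] = stats
    report.setdefault("afternoon_evening_difference", {"not_applicable": "no eligible days"})

    report["notes"] = [
        "p values are two-sided; no multiple-testing correction is applied",
    ]
    return report


def _pair_inputs(spo2_paths: list[Path], act_paths: list[Path]) -> list[tuple[str, Path, Path]]:
    if len(spo2_paths) != len(act_paths):
        raise FormatError(
            f"unequal stream counts: {len(spo2_paths)} SpO2 vs {len(act_paths)} actigraphy"
        )
    spo2_paths = sorted(spo2_paths)
    act_paths = sorted(act_paths)
    parents_s = [p.parent.name for p in spo2_paths]
    parents_a = [p.parent.name for p in act_paths]
    if len(set(parents_s)) == len(spo2_paths) and parents_s == parents_a:
        ids = parents_s  # per-patient directories
    else:
        ids = [p.stem for p in spo2_paths]
    return list(zip(ids, spo2_paths, act_paths))


def run_pipeline(
    spo2_paths: list[str | Path],
    act_paths: list[str | Path],
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Read the paired raw streams, analyse every patient and write artifacts.

    Writes ``features.csv`` (long feature table), ``exclusions.csv``,
    ``weekly.json``, ``report.json``, ``report.txt`` and the effective
    ``config.yaml`` into ``out_dir``.  Deterministic for fixed inputs and
    configuration.  Returns the cohort report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs = _pair_inputs(
        [Path(p) for p in spo2_paths], [Path(p) for p in act_paths]
    )
    if not pairs:
        raise FormatError("no input files")
    all_rows: list[dict] = []
    all_exclusions: list[dict] = []
    for patient_id, spo2_path, act_path in pairs:
        spo2 = read_spo2_csv(spo2_path)
        act = read_actigraphy_csv(act_path)
        rows, exclusions = analyze_patient(patient_id, spo2, act, config)
        all_rows += rows
        all_exclusions += [
            {"patient": patient_id, **asdict(e)} for e in exclusions
        ]
    table = feature_frame(all_rows)
    write_feature_table(table, out / "features.csv")
    pd.DataFrame(
        all_exclusions, columns=["patient", "period_date", "period_kind", "rule", "measured"]
    ).to_csv(out / "exclusions.csv", index=False, lineterminator="\n")
    weekly = patient_weekly(table)
    report = cohort_report(table)
    with open(out / "weekly.json", "w") as fh:
        json.dump(weekly, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    (out / "report.txt").write_text(render_report(report))
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering of the cohort report."""
    lines = [
        "Weekly continuous SpO2 monitoring report",
        "=" * 40,
        f"patients: {report['n_patients']}",
        "",
        "Weekly averages, mean (SD) across patients:",
    ]
    for kind, feats in report.get("weekly_features", {}).items():
        for feat, entry in feats.items():
            avg = entry.get("weekly_average")
            rng = entry.get("weekly_range")
            parts = []
            if avg:
                parts.append(f"weekly avg {avg['mean']:.2f} (SD {avg['sd']:.2f}, n={avg['n']})")
            if rng:
                parts.append(f"weekly range {rng['mean']:.2f} (SD {rng['sd']:.2f})")
            lines.append(f"  {kind:9s} {feat:11s} " + "; ".join(parts))
    t = report.get("night_vs_day_rest", {})
    if "t" in t:
        lines += [
            "",
            (
                f"night vs day-in-rest mean SpO2: diff {t['mean_difference']:.3f}, "
                f"t={t['t']:.3f}, df={t['df']}, p={t['p']:.2e}"
            ),
        ]
    lines += ["", "Data quality (percent of raw samples):"]
    for scope, q in report.get("data_quality", {}).items():
        lines.append(
            f"  {scope:14s} valid {q['pct_valid']:6.2f}  error {q['pct_error']:5.2f}  "
            f"cleaned {q['pct_cleaned']:5.2f}  (n={int(q['n_samples'])})"
        )
    d = report.get("desaturation", {})
    if d:
        lines += ["", "Nocturnal desaturation categories:"]
        for cat, n in d.get("category_counts", {}).items():
            lines.append(f"  {cat}: {n}")
        if d.get("pct_switching_category") is not None:
            lines.append(
                f"  switching category over the week: {d['pct_switching_category']:.0f}%"
            )
        if d.get("pct_occasional_two_night_discordant") is not None:
            lines.append(
                "  occasional desaturators concordant on the first two nights: "
                f"{d['pct_occasional_two_night_discordant']:.0f}%"
            )
    ae = report.get("afternoon_evening_difference", {})
    if "mean" in ae:
        lines.append(
            f"\nafternoon - evening rest SpO2: {ae['mean']:.2f} (SD {ae['sd']:.2f}) "
            f"over {ae['n_days']} days from {ae['n_patients']} patients"
        )
    for note in report.get("notes", []):
        lines.append(f"\nnote: {note}")
    return "\n".join(lines) + "\n"
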