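"""End-to-end microstate pipeline.

Step order mirrors the standard clinical workflow: average reference ->
2-20 Hz zero-phase band-pass -> trim to equal length -> individual AAHC at
GFP peaks -> group grand means -> grand grand mean -> sort against norms ->
cascade sort down the hierarchy -> backfit -> parameter and syntax
quantification with an M +/- 3 SD outlier screen -> group statistics
(mixed ANOVAs, Welch tests, Bonferroni-corrected transition tests,
randomization TANOVA).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .backfitting import Segmentation, assignment_quality, backfit
from .clustering import TemplateSet, fit_individual_microstates, grand_mean, sort_templates
from .montage import ifcn25
from .parameters import (
    TruncationPolicy,
    aggregate_overall,
    compute_parameters,
    exclude_outliers,
    transition_table,
)
from .preprocessing import (
    average_reference,
    bandpass,
    compute_gfp,
    detect_gfp_peaks,
    trim_to_length,
)
from .recording import EEGRecording
from .stats import StatTestResult, compare_transitions, mixed_anova, tanova
from .synthetic import make_canonical_templates

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

ANOVA_PARAMETERS = ("duration_ms", "occurrence_per_s", "coverage_pct")
OVERALL_PARAMETERS = ("duration_ms", "mean_gfp_uv", "gev_class")


@dataclass
class PipelineConfig:
    """Validated settings for one full analysis run."""

    band_hz: tuple[float, float] = (2.0, 20.0)
    trim_s: float = 129.996
    k: int = 4
    truncation_policy: str = TruncationPolicy.DURATION_ONLY
    n_permutations: int = 5000
    permutation_seed: int = 0
    subgroup: str = "all"  # all | migraine | no-migraine
    norms: TemplateSet | None = None
    outlier_sd: float = 3.0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ValueError("invalid band limits")
        if self.trim_s <= 0:
            raise ValueError("trim_s must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.subgroup not in ("all", "migraine", "no-migraine"):
            raise ValueError(f"unknown subgroup filter {self.subgroup!r}")
        if self.truncation_policy not in (TruncationPolicy.DURATION_ONLY, TruncationPolicy.STRICT):
            raise ValueError(f"unknown truncation policy {self.truncation_policy!r}")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")


@dataclass
class PipelineResult:
    """Everything a run produces, stage by stage."""

    config: PipelineConfig
    norms: TemplateSet
    grand_grand_mean: TemplateSet
    group_means: dict[str, TemplateSet]
    individual_sets: dict[str, TemplateSet]
    segmentations: dict[str, Segmentation]
    parameter_table: pd.DataFrame  # long: subject x class rows
    transition_tables: dict[str, np.ndarray]  # subject -> KxK percentages
    transition_counts: dict[str, np.ndarray]
    excluded: dict[str, list[str]]  # parameter -> excluded subject ids
    anovas: dict[str, list[StatTestResult]]
    overall_tests: dict[str, StatTestResult]
    transition_tests: list[StatTestResult]
    tanova_overall: object
    tanova_per_class: dict[str, object]
    groups: tuple[str, str]


def _validate_first_subject(rec: EEGRecording, config: PipelineConfig) -> None:
    """Fail fast: check stage preconditions on the first subject."""
    if rec.n_channels < 2:
        raise ValueError(f"subject {rec.subject_id}: need at least 2 channels")
    lo, hi = config.band_hz
    if not hi < rec.fs_hz / 2:
        raise ValueError(
            f"subject {rec.subject_id}: band edge {hi} Hz >= Nyquist {rec.fs_hz / 2} Hz"
        )
    if rec.n_epoch_samples < config.trim_s * rec.fs_hz:
        raise ValueError(
            f"subject {rec.subject_id}: {rec.n_epoch_samples / rec.fs_hz:.3f} s of "
            f"epoched data < trim length {config.trim_s} s"
        )


def run_pipeline(recs: list[EEGRecording], config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on a cohort of raw recordings.

    ``recs`` must carry group membership (exactly two group values) and,
    for subgroup runs, the migraine flag.  All randomness (TANOVA) is
    governed by ``config.permutation_seed``.
    """
    config = config or PipelineConfig()

    if config.subgroup == "migraine":
        recs = [r for r in recs if r.migraine]
    elif config.subgroup == "no-migraine":
        recs = [r for r in recs if not r.migraine]
    if not recs:
        raise ValueError("no recordings after subgroup filtering")
    groups = tuple(dict.fromkeys(r.group for r in recs))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")

    _validate_first_subject(recs[0], config)

    # --- preprocessing (steps: average reference, band-pass, trim) ---
    lo, hi = config.band_hz
    pre = [bandpass(average_reference(r), lo, hi) for r in recs]
    pre = trim_to_length(pre, config.trim_s)
    gfps = {}
    for r in pre:
        g = compute_gfp(r)
        gfps[r.subject_id] = detect_gfp_peaks(g, r.epochs)
    pre_by_id = {r.subject_id: r for r in pre}

    # --- individual AAHC ---
    indiv = {r.subject_id: fit_individual_microstates(r, gfps[r.subject_id], config.k) for r in pre}

    # --- hierarchy: group means -> grand grand mean -> sort against norms ---
    norms = config.norms or make_canonical_templates(recs[0].montage, config.k)
    group_means = {
        g: grand_mean([indiv[r.subject_id] for r in pre if r.group == g], level="grand_mean")
        for g in groups
    }
    ggm = grand_mean(list(group_means.values()), level="grand_grand_mean")
    ggm = sort_templates(ggm, norms)
    ggm.level = "grand_grand_mean"
    # cascade: grand grand mean -> group means -> individuals
    group_means = {g: sort_templates(gm, ggm) for g, gm in group_means.items()}
    for g in groups:
        group_means[g].level = "grand_mean"
    sorted_indiv = {}
    for r in pre:
        s = sort_templates(indiv[r.subject_id], group_means[r.group])
        s.level = "individual"
        sorted_indiv[r.subject_id] = s

    # --- backfit and quantify ---
    segmentations, param_rows, trans_pct, trans_counts = {}, [], {}, {}
    for r in pre:
        sid = r.subject_id
        seg = backfit(r, gfps[sid], sorted_indiv[sid])
        segmentations[sid] = seg
        per_class_gev, total_gev = assignment_quality(seg, r, gfps[sid], sorted_indiv[sid])
        dfp = compute_parameters(seg, gfps[sid], config.truncation_policy, gev_class=per_class_gev)
        dfp.insert(0, "subject_id", sid)
        dfp.insert(1, "group", r.group)
        dfp.insert(2, "migraine", r.migraine)
        dfp["total_gev"] = total_gev
        param_rows.append(dfp)
        tt = transition_table(seg, config.truncation_policy)
        trans_pct[sid] = tt.percentages
        trans_counts[sid] = tt.counts
    table = pd.concat(param_rows, ignore_index=True)

    # --- outlier screen (single pass, per parameter) ---
    excluded: dict[str, list[str]] = {}
    screened: dict[str, pd.DataFrame] = {}
    for param in set(ANOVA_PARAMETERS) | set(OVERALL_PARAMETERS):
        screened[param], excluded[param] = exclude_outliers(table, param, config.outlier_sd)

    # --- statistics ---
    anovas = {
        param: mixed_anova(screened[param], dv=param) for param in ANOVA_PARAMETERS
    }
    from .stats import welch_t

    overall_tests: dict[str, StatTestResult] = {}
    for param in OVERALL_PARAMETERS:
        sub = screened[param]
        a = sub.loc[sub["group"] == groups[0], param].to_numpy()
        b = sub.loc[sub["group"] == groups[1], param].to_numpy()
        overall_tests[param] = welch_t(b, a, name=f"overall:{param}")

    order = [r.subject_id for r in pre]
    ids_a = [sid for sid in order if pre_by_id[sid].group == groups[0]]
    ids_b = [sid for sid in order if pre_by_id[sid].group == groups[1]]
    transition_tests = compare_transitions(
        [trans_pct[s] for s in ids_a], [trans_pct[s] for s in ids_b]
    )

    mean_maps = {sid: sorted_indiv[sid].maps.mean(axis=0) for sid in order}
    # a mean of sign-aligned unit maps can degenerate; guard handled in tanova
    tan_overall = tanova(
        np.array([mean_maps[s] for s in ids_a]),
        np.array([mean_maps[s] for s in ids_b]),
        n_permutations=config.n_permutations,
        seed=config.permutation_seed,
        subject_ids=ids_a + ids_b,
    )
    tan_class = {}
    for j, lab in enumerate(norms.labels):
        tan_class[lab] = tanova(
            np.array([sorted_indiv[s].maps[j] for s in ids_a]),
            np.array([sorted_indiv[s].maps[j] for s in ids_b]),
            n_permutations=config.n_permutations,
            seed=config.permutation_seed + 1 + j,
            subject_ids=ids_a + ids_b,
        )

    result = PipelineResult(
        config=config,
        norms=norms,
        grand_grand_mean=ggm,
        group_means=group_means,
        individual_sets=sorted_indiv,
        segmentations=segmentations,
        parameter_table=table,
        transition_tables=trans_pct,
        transition_counts=trans_counts,
        excluded=excluded,
        anovas=anovas,
        overall_tests=overall_tests,
        transition_tests=transition_tests,
        tanova_overall=tan_overall,
        tanova_per_class=tan_class,
        groups=groups,
    )
    if config.out_dir is not None:
        _write_artifacts(result, Path(config.out_dir))
    return result


def _write_artifacts(res: PipelineResult, out: Path) -> None:
    """Write every intermediate artifact so any stage can be re-run alone."""
    out.mkdir(parents=True, exist_ok=True)
    (out / "templates").mkdir(exist_ok=True)
    msio.write_templates(out / "templates" / "norms.tsv", res.norms)
    msio.write_templates(out / "templates" / "grand_grand_mean.tsv", res.grand_grand_mean)
    for g, gm in res.group_means.items():
        msio.write_templates(out / "templates" / f"grand_mean_{g}.tsv", gm)
    (out / "segmentations").mkdir(exist_ok=True)
    for sid, seg in res.segmentations.items():
        msio.write_templates(out / "templates" / f"individual_{sid}.tsv", res.individual_sets[sid])
        msio.write_segmentation(
            out / "segmentations" / f"{sid}.tsv", seg, sid, res.norms.labels
        )
    res.parameter_table.to_csv(out / "parameters.tsv", sep="\t", index=False)
    trans_rows = []
    for sid, pct in res.transition_tables.items():
        for i, li in enumerate(res.norms.labels):
            for j, lj in enumerate(res.norms.labels):
                if i != j:
                    trans_rows.append(
                        {"subject_id": sid, "from": li, "to": lj,
                         "count": int(res.transition_counts[sid][i, j]),
                         "percentage": pct[i, j]}
                    )
    pd.DataFrame(trans_rows).to_csv(out / "transitions.tsv", sep="\t", index=False)
    _write_stats_report(res, out)
    log = {
        "permutation_seed": res.config.permutation_seed,
        "subgroup": res.config.subgroup,
        "band_hz": list(res.config.band_hz),
        "trim_s": res.config.trim_s,
        "k": res.config.k,
        "n_permutations": res.config.n_permutations,
        "groups": list(res.groups),
        "excluded": res.excluded,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))


def _stat_rows(res: PipelineResult):
    for param, tests in res.anovas.items():
        for t in tests:
            yield ("mixed_anova", t)
    for t in res.overall_tests.values():
        yield ("welch", t)
    for t in res.transition_tests:
        yield ("welch", t)


def _write_stats_report(res: PipelineResult, out: Path) -> None:
    rows = []
    for kind, t in _stat_rows(res):
        df = t.df if isinstance(t.df, tuple) else (t.df,)
        rows.append(
            {
                "test": kind,
                "name": t.name,
                "statistic": t.statistic,
                "df": ",".join(f"{d:.4g}" for d in df),
                "p": t.p,
                "p_corrected": t.p_corrected,
                "effect_size": t.effect_size,
                "effect_size_kind": t.effect_size_kind,
            }
        )
    rows.append(
        {
            "test": "tanova",
            "name": "tanova:overall",
            "statistic": res.tanova_overall.observed_effect,
            "df": "",
            "p": res.tanova_overall.p,
            "p_corrected": None,
            "effect_size": None,
            "effect_size_kind": None,
        }
    )
    for lab, t in res.tanova_per_class.items():
        rows.append(
            {
                "test": "tanova",
                "name": f"tanova:class_{lab}",
                "statistic": t.observed_effect,
                "df": "",
                "p": t.p,
                "p_corrected": None,
                "effect_size": None,
                "effect_size_kind": None,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "stats.tsv", sep="\t", index=False)

    lines = [f"Microstate group statistics ({res.groups[0]} vs {res.groups[1]})", ""]
    for param, ids in sorted(res.excluded.items()):
        if ids:
            lines.append(f"outliers excluded for {param}: {', '.join(ids)}")
    for _, t in _stat_rows(res):
        dfs = t.df if isinstance(t.df, tuple) else (t.df,)
        dftxt = ", ".join(f"{d:.2f}" for d in dfs)
        extra = f", corrected p = {t.p_corrected:.4g}" if t.p_corrected is not None else ""
        es = f", {t.effect_size_kind} = {t.effect_size:.3f}" if t.effect_size is not None else ""
        lines.append(f"{t.name}: stat({dftxt}) = {t.statistic:.3f}, p = {t.p:.4g}{extra}{es}")
    lines.append(
        f"tanova:overall: effect = {res.tanova_overall.observed_effect:.5f}, "
        f"p = {res.tanova_overall.p:.4g}"
    )
    for lab, t in res.tanova_per_class.items():
        lines.append(f"tanova:class_{lab}: effect = {t.observed_effect:.5f}, p = {t.p:.4g}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")


def overall_table(res: PipelineResult, parameter: str) -> pd.DataFrame:
    """Per-subject overall (class-mean) values for one parameter."""
    return aggregate_overall(res.parameter_table, parameter)
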