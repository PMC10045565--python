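"""Survey ingestion, validation and pipeline orchestration.

``read_survey`` loads a respondent-level delimited table, renames columns
through an optional mapping (so deposited data with different headers can
be ingested), and validates every item against its declared scale,
reporting offending rows and columns together.  ``run_pipeline`` executes
the full analysis battery -- scoring, correlation tables, curvature tests
with balanced resampling, slope contrasts, vaccine/sex/unimodality group
tests and the strong-rejector intersection randomization -- writing each
table as comma-separated text plus a JSON manifest that records the seed,
versions and per-analysis N needed to reproduce any output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._exceptions import DegenerateDataError, ParameterError, ValidationError
from .association import build_correlation_table
from .curvature import balanced_resample_test, fit_linear_quadratic, \
    split_correlations
from .group_tests import anova_tukey, dip_test, mann_whitney, \
    sex_ratio_heterogeneity
from .intersection import intersection_null_test, strong_negative_sets
from .scoring import cronbach_alpha, score_respondents
from .slope_contrast import compare_slopes
from .synthetic import SyntheticConfig, generate_respondents, \
    write_respondents, write_truth

__all__ = ["read_survey", "PipelineConfig", "run_pipeline"]

log = logging.getLogger("osdsurvey")

_ALL_ANALYSES = ("association", "curvature", "slope_contrast",
                 "group_tests", "intersection")

_ORDINAL_RULES = {
    **{c: (-2, 2) for c in ("trust_raw", "hype_raw", "gm_raw")},
    **{f"subj_q{i}": (0, 3) for i in (1, 2)},
    **{f"subj_q{i}": (0, 4) for i in (3, 4, 5, 6)},
    "religiosity": (0, 2), "education": (0, 2), "age": (0, 120),
    **{f"pol_q{i}": (-2, 2) for i in range(1, 11)},
}
_REQUIRED = (["trust_raw", "hype_raw", "gm_raw"]
             + [f"subj_q{i}" for i in range(1, 7)]
             + [f"know_q{i}" for i in range(1, 13)])
_MISSING_OK = {f"pol_q{i}" for i in range(1, 11)}
_VACCINE_LEVELS = {"taken", "will_take", "will_not", "prefer_not_say"}


def read_survey(path, column_mapping: dict | None = None) -> pd.DataFrame:
    """Read and validate a respondent table from delimited text.

    ``column_mapping`` maps file headers to the canonical column names
    (``trust_raw``, ``subj_q1``...).  Every out-of-scale value is collected
    and reported with its row number and column in a single
    :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    table = pd.read_csv(path)
    if column_mapping:
        table = table.rename(columns=column_mapping)
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")

    errors = []
    for col, (lo, hi) in _ORDINAL_RULES.items():
        if col not in table.columns:
            continue
        v = pd.to_numeric(table[col], errors="coerce")
        bad = (v < lo) | (v > hi)
        if col not in _MISSING_OK:
            bad |= v.isna() & table[col].notna()
            bad |= table[col].isna()
        for row in table.index[bad]:
            errors.append((int(row), col,
                           f"value {table.at[row, col]!r} outside "
                           f"{lo}..{hi}"))
        table[col] = v
    for i in range(1, 13):
        col = f"know_q{i}"
        raw = table[col]
        mapped = raw.map({True: True, False: False, "True": True,
                          "False": False, 1: True, 0: False,
                          "TRUE": True, "FALSE": False,
                          "true": True, "false": False})
        for row in table.index[mapped.isna()]:
            errors.append((int(row), col,
                           f"not a true/false answer: {raw[row]!r}"))
        table[col] = mapped
    if "vaccine_status" in table.columns:
        bad = ~table["vaccine_status"].isin(_VACCINE_LEVELS)
        for row in table.index[bad]:
            errors.append((int(row), "vaccine_status",
                           f"unknown level {table.at[row, 'vaccine_status']!r}"))
    if errors:
        head = "; ".join(f"row {r}, {c}: {m}" for r, c, m in errors[:5])
        raise ValidationError(
            f"{len(errors)} invalid values (first: {head})", errors=errors)
    return table


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; exactly one input source."""

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    column_mapping: dict | None = None
    analyses: tuple = _ALL_ANALYSES
    alpha: float = 0.05
    resample_replicates: int = 10_000
    intersection_replicates: int = 100_000
    dip_bootstrap_reps: int = 10_000
    seed: int = 0
    output_dir: str = "osdsurvey_out"

    def __post_init__(self):
        if (self.input_path is None) == (self.synthetic is None):
            raise ParameterError(
                "provide exactly one of input_path or synthetic")
        unknown = set(self.analyses) - set(_ALL_ANALYSES)
        if unknown:
            raise ParameterError(f"unknown analyses: {sorted(unknown)}")
        for name in ("resample_replicates", "intersection_replicates",
                     "dip_bootstrap_reps"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")


def _corr_variables(scored, extra):
    base = ["education", "age", "religiosity", "political"]
    return [v for v in base if v in scored.columns] + extra


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured analyses; returns the report bundle.

    The bundle maps analysis names to in-memory results; every table is
    also written under ``config.output_dir`` together with
    ``manifest.json``.  Any stage failure is re-raised annotated with the
    stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    bundle: dict = {"n": {}, "timings": {}}

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                bundle["timings"][name] = round(dt, 4)
                if exc is not None:
                    log.error("stage %s: failed (%s)", name, exc)
                    raise PipelineStageError(name, exc) from exc
                log.info("stage %s: done in %.2fs", name, dt)
        return _Stage()

    with stage("input"):
        if config.synthetic is not None:
            records, truth = generate_respondents(config.synthetic)
            write_respondents(records, out / "respondents.csv")
            write_truth(truth, out / "truth.json")
        else:
            records = read_survey(config.input_path, config.column_mapping)
    bundle["n"]["respondents"] = len(records)

    with stage("scoring"):
        scored = score_respondents(records)
        scored.to_csv(out / "scored.csv", index=False)
        subj_items = records[[f"subj_q{i}" for i in range(1, 7)]]
        alpha_subj, dropped = cronbach_alpha(subj_items.to_numpy(float))
        bundle["scoring"] = {"cronbach_alpha_subjective": alpha_subj,
                             "alpha_if_dropped": dropped.tolist()}
    bundle["scored"] = scored

    if "association" in config.analyses:
        with stage("association"):
            tables = {}
            for q in ("trust", "hype"):
                tables[f"strength_{q}"] = build_correlation_table(
                    scored.assign(**{f"abs_{q}": scored[q].abs()}),
                    _corr_variables(scored, ["subjective", f"abs_{q}"]),
                    alpha=config.alpha)
            for q in ("trust", "hype", "gm"):
                tables[f"osd_{q}"] = build_correlation_table(
                    scored, _corr_variables(scored, ["osd", q]),
                    alpha=config.alpha)
            tables["osd_covariates"] = build_correlation_table(
                scored, _corr_variables(scored, ["osd"]), alpha=config.alpha)
            for name, tab in tables.items():
                tab.matrix.to_csv(out / f"table_{name}.csv")
                tab.formatted().to_csv(out / f"table_{name}_flagged.csv")
                bundle["n"][f"table_{name}"] = tab.n
            bundle["association"] = tables

    if "curvature" in config.analyses:
        with stage("curvature"):
            res = {}
            for q in ("trust", "hype", "gm"):
                fit = fit_linear_quadratic(scored[q], scored["subjective"])
                bal = balanced_resample_test(
                    scored[q], scored["subjective"],
                    replicates=config.resample_replicates,
                    alpha=config.alpha, seed=rng)
                split = split_correlations(scored[q], scored["subjective"])
                res[q] = {"fit": fit, "balanced": bal, "split": split}
            fit_ks = fit_linear_quadratic(scored["knowledge"],
                                          scored["subjective"])
            res["subjective_vs_knowledge"] = {"fit": fit_ks}
            rows = []
            for q, r in res.items():
                row = {"question": q,
                       "adj_r2_linear": r["fit"].adj_r2_linear,
                       "adj_r2_quadratic": r["fit"].adj_r2_quadratic,
                       "improvement_p": r["fit"].improvement_p,
                       "quadratic_coefficient":
                           r["fit"].quadratic_coefficient}
                if "balanced" in r:
                    row["balanced_fraction_significant"] = (
                        r["balanced"].fraction_significant)
                    row["balanced_class_size"] = r["balanced"].class_size
                    row.update({k: v for k, v in r["split"].items()})
                rows.append(row)
            pd.DataFrame(rows).to_csv(out / "curvature.csv", index=False)
            bundle["curvature"] = res

    if "slope_contrast" in config.analyses:
        with stage("slope_contrast"):
            rows = []
            res = {}
            for q in ("trust", "hype", "gm"):
                pair = compare_slopes(scored[q], scored["subjective"],
                                      scored["knowledge"])
                res[q] = pair
                rows.append({"question": q, **dataclasses.asdict(pair)})
            pd.DataFrame(rows).to_csv(out / "slope_contrast.csv",
                                      index=False)
            bundle["slope_contrast"] = res

    if "group_tests" in config.analyses and "vaccine_status" in scored:
        with stage("group_tests"):
            res = {"vaccine": {}}
            groups = scored["vaccine_status"].to_numpy()
            for response in ("subjective", "knowledge", "osd"):
                comp = anova_tukey(groups, scored[response])
                res["vaccine"][response] = comp
                comp.pairwise.to_csv(
                    out / f"vaccine_tukey_{response}.csv", index=False)
            if "age" in scored:
                acceptors = scored["age"][np.isin(
                    groups, ["taken", "will_take"])]
                decliners = scored["age"][groups == "will_not"]
                res["vaccine"]["age_mannwhitney"] = mann_whitney(
                    acceptors, decliners)
            if "sex" in scored:
                res["sex_ratio"] = {
                    q: sex_ratio_heterogeneity(scored[q], scored["sex"])
                    for q in ("trust", "hype", "gm")}
            res["dip"] = {}
            for q in ("trust", "hype", "gm"):
                rejectors = scored.loc[scored[q] == -2, "knowledge"]
                if rejectors.size >= 4:
                    res["dip"][q] = dip_test(
                        rejectors, bootstrap_reps=config.dip_bootstrap_reps,
                        seed=rng)
            pd.DataFrame(
                [{"question": q, "dip": d, "p": p}
                 for q, (d, p) in res["dip"].items()]
            ).to_csv(out / "dip_tests.csv", index=False)
            bundle["group_tests"] = res

    if "intersection" in config.analyses:
        with stage("intersection"):
            sets = strong_negative_sets(scored)
            pool = len(scored)
            rows = []
            res = {"sets": sets, "tests": {}}
            pairs = [("hype", "gm"), ("hype", "trust"), ("trust", "gm")]
            for q1, q2 in pairs:
                obs = sets["pairwise"].get(
                    (q1, q2), sets["pairwise"].get((q2, q1)))
                sizes = (sets["sizes"][q1], sets["sizes"][q2])
                if min(sizes) == 0:
                    continue
                t = intersection_null_test(
                    pool, sizes, obs,
                    replicates=config.intersection_replicates, seed=rng)
                res["tests"][f"{q1}_v_{q2}"] = t
                rows.append({"comparison": f"{q1} v {q2}", "n1": sizes[0],
                             "n2": sizes[1], "n3": None, "intersect": obs,
                             "null_mean": t.null_mean, "null_sd": t.null_sd,
                             "z": t.z, "p": t.p_label})
            sizes3 = tuple(sets["sizes"][q] for q in ("gm", "trust", "hype"))
            if min(sizes3) > 0 and "three_way" in sets:
                t3 = intersection_null_test(
                    pool, sizes3, sets["three_way"],
                    replicates=config.intersection_replicates, seed=rng)
                res["tests"]["three_way"] = t3
                rows.append({"comparison": "three way", "n1": sizes3[0],
                             "n2": sizes3[1], "n3": sizes3[2],
                             "intersect": sets["three_way"],
                             "null_mean": t3.null_mean,
                             "null_sd": t3.null_sd, "z": t3.z,
                             "p": t3.p_label})
            pd.DataFrame(rows).to_csv(out / "intersections.csv",
                                      index=False)
            bundle["intersection"] = res

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": {k: (dataclasses.asdict(v)
                       if dataclasses.is_dataclass(v) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "n": bundle["n"],
        "timings": bundle["timings"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    bundle["manifest"] = manifest
    return bundle


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and root cause."""

    def __init__(self, stage_name, cause):
        super().__init__(f"stage {stage_name!r} failed: {cause}")
        self.stage_name = stage_name
        self.cause = cause
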