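"""Orchestration and the statistical stage.

Runs the full analysis over a study (synthetic or from files): per-tree
crown structure from the hemispherical photographs, diurnal crown light
interception and leaf STAR for the December average day, annual
interception, circular summaries of the leaf angles, the linear
mixed-model stage with AIC-based fixed-effects selection, and the annual
interception ~ CI_CV regression with an influential-point re-fit.

The mixed models follow a two-phase protocol: the random-effects
structure (random tree intercept vs none) is assessed under restricted
maximum likelihood with the saturated fixed structure, then candidate
fixed structures — every subset of {incident PAR, hour of day, tree
height} plus the null model — are compared by maximum-likelihood AIC.
Two models are treated as distinguishable only when their AIC differ by
more than a threshold (default 10); among indistinguishable models the
most parsimonious is selected.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import crown_light, leaf_star
from .circstats import sector_summary
from .config import GUAVA_SITE, GUAVA_SKY, SiteConfig, SkyConfig, load_config
from .hemiphoto import CrownStructure, HemiImage, SkyGrid, binarize, crown_structure
from .synth import StudyDataset


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# mixed models with AIC selection
# ---------------------------------------------------------------------------

CANDIDATE_TERMS = ("par", "hour", "height")


@dataclass(frozen=True)
class ModelSummary:
    """One fitted candidate: estimates, variances and its ML AIC."""

    label: str
    terms: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    var_tree: float
    var_resid: float
    aic: float
    n_params: int
    converged: bool
    singular: bool
    random_intercept: bool


@dataclass(frozen=True)
class ModelSelection:
    """Ranked candidates and the ΔAIC-rule selection."""

    summaries: list[ModelSummary]
    delta_aic_threshold: float
    reml_var_tree: float
    random_intercept: bool

    @property
    def table(self) -> pd.DataFrame:
        best = min((s.aic for s in self.summaries if math.isfinite(s.aic)),
                   default=math.nan)
        return pd.DataFrame([{
            "model": s.label, "aic": s.aic, "delta_aic": s.aic - best,
            "n_params": s.n_params, "converged": s.converged,
            "singular": s.singular,
        } for s in self.summaries]).sort_values(
            ["aic", "n_params"]).reset_index(drop=True)

    @property
    def selected(self) -> ModelSummary:
        """Most parsimonious model within the ΔAIC threshold of the best."""
        finite = [s for s in self.summaries if math.isfinite(s.aic)]
        if not finite:
            raise ValueError("no candidate model attained a finite AIC")
        best = min(s.aic for s in finite)
        eligible = [s for s in finite
                    if s.aic - best <= self.delta_aic_threshold]
        return min(eligible, key=lambda s: (s.n_params, s.aic))

    def by_label(self, label: str) -> ModelSummary:
        for s in self.summaries:
            if s.label == label:
                return s
        raise KeyError(label)


def _fit_one(df: pd.DataFrame, response: str, terms: tuple[str, ...],
             random_intercept: bool) -> ModelSummary:
    rhs = " + ".join(terms) if terms else "1"
    formula = f"{response} ~ {rhs}"
    label = "null" if not terms else "+".join(terms)
    if random_intercept:
        model = smf.mixedlm(formula, df, groups=df["tree_id"])
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in (["lbfgs", "powell"], ["bfgs"], ["nm"]):
                try:
                    cand = model.fit(reml=False, method=method)
                except Exception:
                    continue
                if np.isfinite(cand.llf):
                    res = cand
                    break
        if res is None:
            return _fit_one(df, response, terms, random_intercept=False)
        converged = bool(res.converged)
        var_tree = float(np.squeeze(res.cov_re.values))
        var_resid = float(res.scale)
        k = len(res.fe_params) + 2          # + tree variance + residual
        aic = -2.0 * res.llf + 2.0 * k
        singular = var_tree < 1e-8 * max(var_resid, 1e-12)
        if not np.isfinite(aic):            # degenerate likelihood
            aic, converged, singular = math.inf, False, True
        return ModelSummary(label=label, terms=terms,
                            params=res.fe_params, bse=res.bse_fe,
                            var_tree=var_tree, var_resid=var_resid,
                            aic=float(aic), n_params=k, converged=converged,
                            singular=singular, random_intercept=True)
    res = smf.ols(formula, df).fit()
    k = len(res.params) + 1                 # + residual variance
    return ModelSummary(label=label, terms=terms, params=res.params,
                        bse=res.bse, var_tree=0.0,
                        var_resid=float(res.scale), aic=float(res.aic),
                        n_params=k, converged=True, singular=False,
                        random_intercept=False)


def fit_diurnal_models(df: pd.DataFrame, response: str,
                       terms: tuple[str, ...] = CANDIDATE_TERMS,
                       delta_aic: float = 10.0) -> ModelSelection:
    """Two-phase LMM selection for a diurnal response.

    ``df`` is a long table with columns ``tree_id``, the candidate
    predictors and the response.  With fewer than two trees the random
    term is degenerate and every candidate falls back to a fixed-effects
    (OLS) fit.
    """
    for col in ("tree_id", response):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    terms = tuple(t for t in terms
                  if t in df.columns and df[t].nunique() > 1)
    n_trees = df["tree_id"].nunique()
    df = df.dropna(subset=[response] + list(terms)).copy()
    if n_trees < 2:
        random_intercept = False
        reml_var = 0.0
    else:
        # phase 1: random structure under REML with the saturated fixed part
        rhs = " + ".join(terms) if terms else "1"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reml = smf.mixedlm(f"{response} ~ {rhs}", df,
                                   groups=df["tree_id"]).fit(
                    reml=True, method=["lbfgs", "powell"])
            reml_var = float(np.squeeze(reml.cov_re.values))
            if not np.isfinite(reml_var):
                reml_var = 0.0
        except Exception:
            reml_var = 0.0
        random_intercept = reml_var > 1e-8
    candidates: list[tuple[str, ...]] = [()]
    for r in range(1, len(terms) + 1):
        candidates.extend(combinations(terms, r))
    summaries = [_fit_one(df, response, c, random_intercept)
                 for c in candidates]
    return ModelSelection(summaries=summaries, delta_aic_threshold=delta_aic,
                          reml_var_tree=reml_var,
                          random_intercept=random_intercept)


# ---------------------------------------------------------------------------
# annual regression with influence re-fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionFit:
    n: int
    slope: float
    slope_se: float
    slope_p: float
    r2: float
    params: pd.Series


@dataclass(frozen=True)
class AnnualRegression:
    """OLS of annual interception on CI_CV (height as covariate)."""

    full: RegressionFit
    influence_refit: RegressionFit | None
    excluded_tree: str | None


def _ols_fit(df: pd.DataFrame, use_height: bool) -> RegressionFit:
    rhs = "ci_cv + height" if use_height else "ci_cv"
    res = smf.ols(f"annual_pct ~ {rhs}", df).fit()
    return RegressionFit(n=int(res.nobs), slope=float(res.params["ci_cv"]),
                         slope_se=float(res.bse["ci_cv"]),
                         slope_p=float(res.pvalues["ci_cv"]),
                         r2=float(res.rsquared), params=res.params)


def annual_regression(df: pd.DataFrame, gap_fraction_threshold: float = 0.3
                      ) -> AnnualRegression:
    """Regress per-tree annual interception (%) on CI_CV.

    ``df`` needs columns ``tree_id, annual_pct, ci_cv`` and optionally
    ``height``.  When the largest gap in the sorted CI_CV values exceeds
    ``gap_fraction_threshold`` of the predictor range, the maximum-CI_CV
    tree is treated as a potentially influential point and the fit is
    repeated without it; both fits are always reported.
    """
    if len(df) < 4:
        raise ValueError("need at least 4 trees for the annual regression")
    if df["ci_cv"].nunique() < 2:
        raise ValueError("constant predictor: regression undefined")
    use_height = "height" in df.columns and df["height"].nunique() > 1
    full = _ols_fit(df, use_height)
    vals = np.sort(df["ci_cv"].values)
    rng_ = vals[-1] - vals[0]
    gaps = np.diff(vals)
    refit = None
    excluded = None
    if rng_ > 0 and gaps.size and gaps.max() > gap_fraction_threshold * rng_ \
            and np.argmax(gaps) == gaps.size - 1 and len(df) >= 5:
        drop_idx = df["ci_cv"].idxmax()
        excluded = str(df.loc[drop_idx, "tree_id"])
        refit = _ols_fit(df.drop(index=drop_idx), use_height)
    return AnnualRegression(full=full, influence_refit=refit,
                            excluded_tree=excluded)


# ---------------------------------------------------------------------------
# whole-study orchestration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """File-based configuration for :func:`run_all`."""

    image_paths: list[tuple[str, str | None]] = field(default_factory=list)
    tree_ids: list[str] = field(default_factory=list)
    leaves_path: str | None = None
    site_path: str | None = None
    heights_path: str | None = None
    threshold: int = 131
    element_width: float = 2.0
    year: int = 2012
    step_days: int = 4
    delta_aic: float = 10.0
    outdir: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


@dataclass
class StudyResult:
    """Everything the analysis produces for one study."""

    crowns: dict[str, CrownStructure]
    heights: dict[str, float]
    diurnal_crown: pd.DataFrame        # hour x tree PARi, December average
    diurnal_star: pd.DataFrame         # hour x tree mean STAR
    incident: pd.DataFrame             # hour, mean December PARs
    annual: pd.DataFrame               # tree_id, annual_pct, ci_cv, height
    circular_course: pd.DataFrame
    circular_tilt: pd.DataFrame
    homogeneity_course: object
    homogeneity_tilt: object
    models_star: ModelSelection | None
    models_pari: ModelSelection | None
    regression: AnnualRegression | None

    def mean_curves(self) -> pd.DataFrame:
        """Across-tree mean diurnal PARi and STAR with the hours column."""
        hours = self.diurnal_crown["hour"]
        pari = self.diurnal_crown.drop(columns="hour").mean(axis=1)
        star = self.diurnal_star.drop(columns="hour").mean(axis=1)
        return pd.DataFrame({"hour": hours, "pari": pari, "star": star})


def _december_days(year: int, step_days: int) -> list[int]:
    days = crown_light.sampled_days(year, step_days)
    return [int(d) for d in days
            if crown_light._month_of_day(int(d), year) == 12]


def run_study(dataset: StudyDataset, threshold: int = 131,
              element_width: float = 2.0, year: int = 2012,
              step_days: int = 4, delta_aic: float = 10.0,
              compute_clumping: bool = True,
              outdir: str | Path | None = None) -> StudyResult:
    """Execute the full analysis on an in-memory study bundle."""
    site, sky = dataset.site, dataset.sky
    crowns: dict[str, CrownStructure] = {}
    heights: dict[str, float] = {}
    try:
        for tree in dataset.trees:
            mask = binarize(tree.image, threshold)
            if compute_clumping:
                crowns[tree.tree_id] = crown_structure(mask, element_width=element_width)
            else:
                from .hemiphoto import segment_gap_fraction
                seg = segment_gap_fraction(mask).assign(clumping=np.nan)
                crowns[tree.tree_id] = CrownStructure(
                    segments=seg, grid=SkyGrid(), element_width=element_width)
            heights[tree.tree_id] = tree.height
    except Exception as exc:                      # pragma: no cover
        raise PipelineError("hemiphoto", str(exc)) from exc

    dec_days = _december_days(year, step_days)
    try:
        pari_cols, incident_rows = {}, None
        for tid, crown in crowns.items():
            acc = np.zeros(len(crown_light.HOURS))
            cnt = np.zeros(len(crown_light.HOURS))
            pars_acc = np.zeros(len(crown_light.HOURS))
            weights = None
            for d in dec_days:
                cur = crown_light.diurnal_course(crown, site, sky, d)
                ok = cur["pari"].notna().values
                acc[ok] += cur["pari"].values[ok]
                pars_acc[ok] += cur["pars"].values[ok]
                cnt[ok] += 1
            with np.errstate(invalid="ignore"):
                pari_cols[tid] = np.where(cnt > 0, acc / np.maximum(cnt, 1),
                                          np.nan)
            incident_rows = np.where(cnt > 0, pars_acc / np.maximum(cnt, 1),
                                     np.nan)
        diurnal_crown = pd.DataFrame({"hour": list(crown_light.HOURS),
                                      **pari_cols})
        incident = pd.DataFrame({"hour": list(crown_light.HOURS),
                                 "pars": incident_rows})
        annual = pd.DataFrame([{
            "tree_id": tid,
            "annual_pct": crown_light.annual_interception(
                crowns[tid], site, sky, year, step_days),
            "ci_cv": crowns[tid].ci_cv,
            "height": heights[tid],
        } for tid in crowns])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("crown_light", str(exc)) from exc

    if dataset.leaves is None or len(dataset.leaves) == 0:
        raise PipelineError("leaf_star", "no leaf records available")
    try:
        star_acc = None
        for d in dec_days:
            cur = leaf_star.diurnal_star(dataset.leaves, site, d, by="tree")
            star_acc = cur if star_acc is None else star_acc.add(
                cur, fill_value=0.0)
        diurnal_star = star_acc.copy()
        cols = [c for c in diurnal_star.columns if c != "hour"]
        diurnal_star[cols] = diurnal_star[cols] / len(dec_days)
        diurnal_star["hour"] = star_acc["hour"] / len(dec_days)
    except Exception as exc:
        raise PipelineError("leaf_star", str(exc)) from exc

    try:
        circ_course, homog_course = sector_summary(dataset.leaves, "course")
        circ_tilt, homog_tilt = sector_summary(dataset.leaves, "tilt")
    except Exception as exc:
        raise PipelineError("circstats", str(exc)) from exc

    try:
        long = _long_table(diurnal_crown, diurnal_star, incident, heights)
        models_star = fit_diurnal_models(long, "star", delta_aic=delta_aic)
        models_pari = fit_diurnal_models(long, "pari", delta_aic=delta_aic)
        regression = annual_regression(annual) if len(annual) >= 4 \
            and annual["ci_cv"].nunique() > 1 else None
    except Exception as exc:
        raise PipelineError("models", str(exc)) from exc

    result = StudyResult(crowns=crowns, heights=heights,
                         diurnal_crown=diurnal_crown,
                         diurnal_star=diurnal_star, incident=incident,
                         annual=annual, circular_course=circ_course,
                         circular_tilt=circ_tilt,
                         homogeneity_course=homog_course,
                         homogeneity_tilt=homog_tilt,
                         models_star=models_star, models_pari=models_pari,
                         regression=regression)
    if outdir is not None:
        _write_result(result, Path(outdir))
    return result


def _long_table(diurnal_crown: pd.DataFrame, diurnal_star: pd.DataFrame,
                incident: pd.DataFrame, heights: dict[str, float]
                ) -> pd.DataFrame:
    rows = []
    for tid in [c for c in diurnal_crown.columns if c != "hour"]:
        for i, h in enumerate(diurnal_crown["hour"]):
            rows.append({
                "tree_id": tid, "hour": float(h),
                "par": float(incident["pars"].iloc[i]),
                "pari": float(diurnal_crown[tid].iloc[i]),
                "star": float(diurnal_star[tid].iloc[i])
                if tid in diurnal_star.columns else np.nan,
                "height": heights.get(tid, np.nan),
            })
    return pd.DataFrame(rows)


def _write_result(result: StudyResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    seg = pd.concat([c.segments.assign(tree_id=tid)
                     for tid, c in result.crowns.items()])
    seg.to_csv(outdir / "crown_segments.csv", index=False)
    result.diurnal_crown.to_csv(outdir / "diurnal_crown.csv", index=False)
    result.diurnal_star.to_csv(outdir / "diurnal_star.csv", index=False)
    result.annual.to_csv(outdir / "annual.csv", index=False)
    result.circular_course.to_csv(outdir / "circular_course.csv", index=False)
    result.circular_tilt.to_csv(outdir / "circular_tilt.csv", index=False)
    models = {}
    for name, sel in (("star", result.models_star),
                      ("pari", result.models_pari)):
        if sel is not None:
            models[name] = {
                "selected": sel.selected.label,
                "random_intercept": sel.random_intercept,
                "table": sel.table.to_dict(orient="records"),
            }
    if result.regression is not None:
        models["annual_regression"] = {
            "slope": result.regression.full.slope,
            "r2": result.regression.full.r2,
            "p": result.regression.full.slope_p,
            "excluded_tree": result.regression.excluded_tree,
            "refit_r2": result.regression.influence_refit.r2
            if result.regression.influence_refit else None,
        }
    with open(outdir / "models.json", "w") as fh:
        json.dump(models, fh, indent=2, default=float)
        fh.write("\n")


def run_all(config: AnalysisConfig) -> StudyResult:
    """File-based entry point: load inputs per the config and run the study."""
    from .synth import StudyDesign, TreeData

    if config.leaves_path is None or not Path(config.leaves_path).exists():
        raise PipelineError("leaf_star",
                            f"leaf CSV not found: {config.leaves_path}")
    if config.site_path is not None:
        site, sky = load_config(config.site_path)
    else:
        site, sky = GUAVA_SITE, GUAVA_SKY
    leaves = leaf_star.read_leaves(config.leaves_path)
    heights = {}
    if config.heights_path and Path(config.heights_path).exists():
        hdf = pd.read_csv(config.heights_path)
        heights = dict(zip(hdf["tree_id"], hdf["height_m"]))
    trees = []
    for i, (img_path, meta_path) in enumerate(config.image_paths):
        if not Path(img_path).exists():
            raise PipelineError("hemiphoto", f"image not found: {img_path}")
        tid = config.tree_ids[i] if i < len(config.tree_ids) else f"T{i+1:02d}"
        image = HemiImage.from_file(img_path, meta_path)
        trees.append(TreeData(tree_id=tid, image=image, truth=None,
                              segment_truth=None,
                              height=heights.get(tid, np.nan)))
    dataset = StudyDataset(design=StudyDesign(n_trees=max(len(trees), 1)),
                           site=site, sky=sky, trees=trees, leaves=leaves,
                           leaf_truth=pd.DataFrame())
    return run_study(dataset, threshold=config.threshold,
                     element_width=config.element_width, year=config.year,
                     step_days=config.step_days, delta_aic=config.delta_aic,
                     outdir=config.outdir)
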