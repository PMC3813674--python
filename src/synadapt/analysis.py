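"""Reading-time analysis chain: exclusion, length correction, regression.

The chain mirrors standard practice for self-paced-reading data: (1) drop
implausibly fast or slow word RTs; (2) residualize the remaining raw RTs on
word length with a mixed model carrying a by-subject intercept and length
slope, yielding length-corrected RTs; (3) average residuals within sentence
regions; (4) regress the disambiguating-region residuals on the factorial
design -- sentence type x ambiguity x item order plus a log-stimulus-order
practice term -- with mean-centered predictors, so the three-way interaction
estimates how the garden-path contrast changes with syntactic exposure.

Coding conventions (documented because coefficient signs depend on them):
in the full factorial, sentence type is RC = +1/2 and ambiguity is coded
ambiguous = -1/2, so the type-by-ambiguity interaction (the RC garden-path
cost) is negative and adaptation surfaces as a *positive* three-way
interaction.  Simple-effect and two-group models instead code ambiguous =
+1/2, so their ambiguity coefficient is the garden-path effect itself and
its interactions read directly as changes in that effect.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

SIGNIFICANCE_T = 1.96  # |t| >= 1.96 <=> p <= .05, no df correction


class PipelineError(ValueError):
    """Raised for invalid pipeline configuration or degenerate inputs."""


# ---------------------------------------------------------------------------
# exclusion and length correction
# ---------------------------------------------------------------------------


def exclude_rts(
    records: pd.DataFrame, low: float = 100.0, high: float = 2000.0
) -> tuple[pd.DataFrame, float]:
    """Drop words with raw RTs strictly below ``low`` or above ``high`` ms.

    Boundary values are kept.  Returns the retained records and the fraction
    of words lost.
    """
    if low >= high:
        raise PipelineError(f"exclusion bounds inverted: low={low} >= high={high}")
    if len(records) == 0:
        raise PipelineError("no records to filter")
    keep = (records["rt_raw"] >= low) & (records["rt_raw"] <= high)
    kept = records[keep].reset_index(drop=True)
    loss = 1.0 - len(kept) / len(records)
    return kept, loss


@dataclass(frozen=True)
class LengthCorrectionModel:
    """Fitted word-length regression used to residualize raw RTs."""

    intercept: float
    length_slope: float
    subject_effects: pd.DataFrame  # subject_id, intercept_dev, slope_dev
    method: str  # "mixed" or "per_subject_ols"


def _mixed_length_fit(records: pd.DataFrame) -> LengthCorrectionModel:
    exog = sm.add_constant(records["word_length"].to_numpy())
    model = sm.MixedLM(
        records["rt_raw"].to_numpy(),
        exog,
        groups=records["subject_id"].to_numpy(),
        exog_re=exog,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True, method="lbfgs", maxiter=200)
    if not np.all(np.isfinite(result.fe_params)):
        raise RuntimeError("mixed length regression produced non-finite estimates")
    re = result.random_effects
    eff = pd.DataFrame(
        {
            "subject_id": list(re),
            "intercept_dev": [float(v.iloc[0]) for v in re.values()],
            "slope_dev": [float(v.iloc[1]) for v in re.values()],
        }
    )
    return LengthCorrectionModel(
        intercept=float(result.fe_params[0]),
        length_slope=float(result.fe_params[1]),
        subject_effects=eff,
        method="mixed",
    )


def _per_subject_ols_fit(records: pd.DataFrame) -> LengthCorrectionModel:
    rows = []
    for sid, grp in records.groupby("subject_id"):
        x = grp["word_length"].to_numpy(dtype=float)
        y = grp["rt_raw"].to_numpy(dtype=float)
        if np.ptp(x) == 0 or len(grp) < 3:
            b0, b1 = float(y.mean()), 0.0
        else:
            b1, b0 = np.polyfit(x, y, 1)
        rows.append({"subject_id": sid, "intercept_dev": b0, "slope_dev": b1})
    eff = pd.DataFrame(rows)
    return LengthCorrectionModel(
        intercept=0.0,
        length_slope=0.0,
        subject_effects=eff,
        method="per_subject_ols",
    )


def length_correct(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, LengthCorrectionModel]:
    """Attach length-corrected residual RTs (``rt_resid``) to every word.

    Fits raw RT on word length over *all* remaining words (criticals and
    fillers) with a by-subject random intercept and length slope, by REML;
    residuals are conditional on the subject effects.  If the mixed fit
    fails, falls back to per-subject ordinary least squares with a logged
    warning.
    """
    if len(records) == 0:
        raise PipelineError("no records to length-correct")
    try:
        model = _mixed_length_fit(records)
    except Exception as exc:  # noqa: BLE001 - any optimizer failure triggers backoff
        logger.warning("mixed length regression failed (%s); using per-subject OLS", exc)
        model = _per_subject_ols_fit(records)
    out = records.merge(model.subject_effects, on="subject_id", how="left")
    fitted = (
        model.intercept
        + out["intercept_dev"]
        + (model.length_slope + out["slope_dev"]) * out["word_length"]
    )
    out["rt_resid"] = out["rt_raw"] - fitted
    return out.drop(columns=["intercept_dev", "slope_dev"]), model


# ---------------------------------------------------------------------------
# region aggregation
# ---------------------------------------------------------------------------

_REGION_KEYS = [
    "subject_id",
    "list_id",
    "group",
    "block",
    "stimulus_order",
    "item_order",
    "kind",
    "structure",
    "ambiguity",
    "region",
]


def aggregate_regions(records: pd.DataFrame) -> pd.DataFrame:
    """Mean residual (and raw) RT per subject x trial x region."""
    if "rt_resid" not in records.columns:
        raise PipelineError("records lack rt_resid; run length_correct first")
    grouped = (
        records.groupby(_REGION_KEYS, dropna=False, observed=True)
        .agg(
            rt_resid=("rt_resid", "mean"),
            rt_raw=("rt_raw", "mean"),
            n_words=("rt_raw", "size"),
        )
        .reset_index()
    )
    return grouped


# ---------------------------------------------------------------------------
# regression machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelFitResult:
    """Fixed-effect estimates from one analysis regression."""

    predictors: pd.DataFrame  # predictor, beta, se, t_value
    converged: bool
    n_obs: int
    random_structure: str
    sig_threshold: float = SIGNIFICANCE_T
    continuous_variant: "ModelFitResult | None" = None

    def coef(self, name: str) -> float:
        return float(self.predictors.set_index("predictor").loc[name, "beta"])

    def tvalue(self, name: str) -> float:
        return float(self.predictors.set_index("predictor").loc[name, "t_value"])

    def significant(self, name: str) -> bool:
        return abs(self.tvalue(name)) >= self.sig_threshold

    def to_frame(self, region: str | None = None) -> pd.DataFrame:
        out = self.predictors.copy()
        out["significant"] = out["t_value"].abs() >= self.sig_threshold
        if region is not None:
            out.insert(0, "region", region)
        return out


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        aliased = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise PipelineError(f"design matrix is rank deficient; aliased: {aliased}")


def _fit_with_backoff(
    y: np.ndarray,
    X: pd.DataFrame,
    groups: np.ndarray,
    re_ladder: list[list[str]],
) -> tuple[pd.DataFrame, bool, str]:
    """Fit a mixed model, backing off the random structure on failure.

    ``re_ladder`` lists successively simpler random-effect column sets
    (columns of ``X``; the empty list means plain OLS).  Interaction slopes
    are never included, and slope sets are dropped before the intercept, per
    the documented backoff order.
    """
    names = list(X.columns)
    Xmat = X.to_numpy(dtype=float)
    _check_rank(Xmat, names)
    # Degenerate input: if the fixed effects already fit perfectly (noise-free
    # data), variance components are unidentified and OLS is the exact answer.
    ols0 = sm.OLS(y, Xmat).fit()
    scale = max(1.0, float(np.max(np.abs(y))))
    if float(np.max(np.abs(ols0.resid))) <= 1e-9 * scale:
        logger.info("response is an exact function of the predictors; using OLS")
        with np.errstate(divide="ignore", invalid="ignore"):
            bse = np.asarray(ols0.bse, dtype=float)
            t = np.where(bse > 0, ols0.params / bse, np.inf * np.sign(ols0.params))
        frame = pd.DataFrame(
            {"predictor": names, "beta": ols0.params, "se": bse, "t_value": t}
        )
        return frame, True, "none (OLS, saturated)"
    for re_cols in re_ladder:
        if not re_cols:
            break
        exog_re = np.column_stack(
            [np.ones(len(X))] + [X[c].to_numpy(dtype=float) for c in re_cols if c != "intercept"]
        )
        try:
            model = sm.MixedLM(y, Xmat, groups=groups, exog_re=exog_re)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = model.fit(reml=True, method="lbfgs", maxiter=200)
            bse = np.asarray(result.bse_fe, dtype=float)
            if not (np.all(np.isfinite(result.fe_params)) and np.all(np.isfinite(bse)) and np.all(bse > 0)):
                raise RuntimeError("non-finite fixed-effect estimates")
        except Exception as exc:  # noqa: BLE001
            logger.info("random structure %s failed (%s); backing off", re_cols, exc)
            continue
        frame = pd.DataFrame(
            {
                "predictor": names,
                "beta": np.asarray(result.fe_params, dtype=float),
                "se": bse,
                "t_value": np.asarray(result.fe_params, dtype=float) / bse,
            }
        )
        label = "subject: intercept" + (
            " + " + " + ".join(c for c in re_cols if c != "intercept")
            if len(re_cols) > 1
            else ""
        )
        return frame, bool(result.converged), label
    # OLS fallback (also the exact route for noise-free data)
    logger.info("all random structures failed; falling back to OLS")
    ols = sm.OLS(y, Xmat).fit()
    bse = np.asarray(ols.bse, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(bse > 0, ols.params / bse, np.inf * np.sign(ols.params))
    frame = pd.DataFrame(
        {"predictor": names, "beta": ols.params, "se": bse, "t_value": t}
    )
    return frame, True, "none (OLS)"


def _centered(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def _code_factor(values: pd.Series, positive: str, negative: str, name: str) -> np.ndarray:
    vals = values.to_numpy()
    known = np.isin(vals, [positive, negative])
    if not known.all():
        raise PipelineError(f"unexpected level(s) in {name}: {set(vals[~known])}")
    return _centered(np.where(vals == positive, 0.5, -0.5))


def _subset_region(table: pd.DataFrame, region: str) -> pd.DataFrame:
    sub = table[(table["kind"] == "critical") & (table["region"] == region)]
    if len(sub) == 0:
        raise PipelineError(f"no critical rows for region {region!r}")
    return sub.reset_index(drop=True)


# ---------------------------------------------------------------------------
# factorial and simple-effect analyses
# ---------------------------------------------------------------------------


def fit_adaptation_model(
    region_table: pd.DataFrame,
    region: str = "disambiguating_region",
    response: str = "rt_resid",
) -> ModelFitResult:
    """Full factorial adaptation model at one sentence region.

    Sentence type (RC = +1/2) x ambiguity (ambiguous = -1/2) x item order,
    all main effects and interactions, plus log stimulus order; every
    predictor mean-centered.  The three-way interaction is the adaptation
    estimate: positive when the RC garden-path cost shrinks with exposure.
    Random effects: by-subject intercept with slopes for the within-subject
    factors, backed off (slopes for order, then factors) until the fit
    converges.
    """
    sub = _subset_region(region_table, region)
    stype = _code_factor(sub["structure"], "RC", "MV", "structure")
    ambig = _code_factor(sub["ambiguity"], "unambiguous", "ambiguous", "ambiguity")
    order = _centered(sub["item_order"].to_numpy(dtype=float))
    logstim = _centered(np.log(sub["stimulus_order"].to_numpy(dtype=float)))
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(sub)),
            "log_stimulus_order": logstim,
            "ambiguity": ambig,
            "sentence_type": stype,
            "item_order": order,
            "sentence_type:ambiguity": _centered(stype * ambig),
            "sentence_type:item_order": _centered(stype * order),
            "ambiguity:item_order": _centered(ambig * order),
            "sentence_type:ambiguity:item_order": _centered(stype * ambig * order),
        }
    )
    ladder = [
        ["intercept", "sentence_type", "ambiguity", "item_order"],
        ["intercept", "sentence_type", "ambiguity"],
        ["intercept"],
        [],
    ]
    frame, converged, label = _fit_with_backoff(
        sub[response].to_numpy(dtype=float),
        X,
        sub["subject_id"].to_numpy(),
        ladder,
    )
    return ModelFitResult(frame, converged, len(sub), label)


def simple_effects(
    region_table: pd.DataFrame,
    structure: str,
    region: str = "disambiguating_region",
    response: str = "rt_resid",
) -> ModelFitResult:
    """Ambiguity x item order within one sentence type.

    Ambiguity is coded ambiguous = +1/2 here, so the ``ambiguity``
    coefficient is the garden-path effect and ``ambiguity:item_order`` its
    change per critical item (negative when the effect shrinks).
    """
    sub = _subset_region(region_table, region)
    sub = sub[sub["structure"] == structure].reset_index(drop=True)
    if len(sub) == 0:
        raise PipelineError(f"no rows for structure {structure!r}")
    ambig = _code_factor(sub["ambiguity"], "ambiguous", "unambiguous", "ambiguity")
    order = _centered(sub["item_order"].to_numpy(dtype=float))
    logstim = _centered(np.log(sub["stimulus_order"].to_numpy(dtype=float)))
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(sub)),
            "log_stimulus_order": logstim,
            "ambiguity": ambig,
            "item_order": order,
            "ambiguity:item_order": _centered(ambig * order),
        }
    )
    ladder = [
        ["intercept", "ambiguity", "item_order"],
        ["intercept", "ambiguity"],
        ["intercept"],
        [],
    ]
    frame, converged, label = _fit_with_backoff(
        sub[response].to_numpy(dtype=float), X, sub["subject_id"].to_numpy(), ladder
    )
    return ModelFitResult(frame, converged, len(sub), label)


def exp2_analyses(
    region_table: pd.DataFrame,
    question: str,
    region: str = "disambiguating_region",
    response: str = "rt_resid",
) -> ModelFitResult:
    """The three block analyses of the two-group design.

    Q1: Block-3 MV trials; ambiguity (ambiguous = +1/2) x group (RC-First =
    +1/2).  A positive interaction means the MV garden path is larger after
    RC exposure.
    Q2: RC-First Blocks 1-2; ambiguity x block (Block 2 = +1/2).  The
    continuous re-analysis (ambiguity x number of RCs seen, plus log
    stimulus order) is attached as ``continuous_variant`` with a
    Bonferroni-adjusted significance threshold for the two-test family.
    Q3: Block-2 RC trials from both groups; ambiguity x group.  A negative
    interaction means the RC garden path is smaller after RC exposure.
    """
    if question not in ("Q1", "Q2", "Q3"):
        raise PipelineError(f"unknown question {question!r}")
    sub = _subset_region(region_table, region)
    if question == "Q1":
        sub = sub[(sub["block"] == 3) & (sub["structure"] == "MV")].reset_index(drop=True)
        if len(sub) == 0:
            raise PipelineError("Q1 subset (Block-3 MV trials) is empty")
        ambig = _code_factor(sub["ambiguity"], "ambiguous", "unambiguous", "ambiguity")
        grp = _code_factor(sub["group"], "RC_First", "Filler_First", "group")
        X = pd.DataFrame(
            {
                "intercept": np.ones(len(sub)),
                "ambiguity": ambig,
                "group": grp,
                "ambiguity:group": _centered(ambig * grp),
            }
        )
        ladder = [["intercept", "ambiguity"], ["intercept"], []]
        frame, conv, label = _fit_with_backoff(
            sub[response].to_numpy(dtype=float), X, sub["subject_id"].to_numpy(), ladder
        )
        return ModelFitResult(frame, conv, len(sub), label)

    if question == "Q3":
        sub = sub[(sub["block"] == 2) & (sub["structure"] == "RC")].reset_index(drop=True)
        if len(sub) == 0:
            raise PipelineError("Q3 subset (Block-2 RC trials) is empty")
        ambig = _code_factor(sub["ambiguity"], "ambiguous", "unambiguous", "ambiguity")
        grp = _code_factor(sub["group"], "RC_First", "Filler_First", "group")
        X = pd.DataFrame(
            {
                "intercept": np.ones(len(sub)),
                "ambiguity": ambig,
                "group": grp,
                "ambiguity:group": _centered(ambig * grp),
            }
        )
        ladder = [["intercept", "ambiguity"], ["intercept"], []]
        frame, conv, label = _fit_with_backoff(
            sub[response].to_numpy(dtype=float), X, sub["subject_id"].to_numpy(), ladder
        )
        return ModelFitResult(frame, conv, len(sub), label)

    # Q2: categorical block analysis + continuous re-analysis
    sub = sub[
        (sub["group"] == "RC_First")
        & (sub["block"].isin([1, 2]))
        & (sub["structure"] == "RC")
    ].reset_index(drop=True)
    if len(sub) == 0:
        raise PipelineError("Q2 subset (RC-First Blocks 1-2) is empty")
    ambig = _code_factor(sub["ambiguity"], "ambiguous", "unambiguous", "ambiguity")
    block = _centered(np.where(sub["block"].to_numpy() == 2, 0.5, -0.5))
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(sub)),
            "ambiguity": ambig,
            "block": block,
            "ambiguity:block": _centered(ambig * block),
        }
    )
    ladder = [["intercept", "ambiguity"], ["intercept"], []]
    frame, conv, label = _fit_with_backoff(
        sub[response].to_numpy(dtype=float), X, sub["subject_id"].to_numpy(), ladder
    )

    # continuous variant: how many RCs seen so far as the exposure index
    order = _centered(sub["item_order"].to_numpy(dtype=float))
    logstim = _centered(np.log(sub["stimulus_order"].to_numpy(dtype=float)))
    Xc = pd.DataFrame(
        {
            "intercept": np.ones(len(sub)),
            "log_stimulus_order": logstim,
            "ambiguity": ambig,
            "item_order": order,
            "ambiguity:item_order": _centered(ambig * order),
        }
    )
    frame_c, conv_c, label_c = _fit_with_backoff(
        sub[response].to_numpy(dtype=float), Xc, sub["subject_id"].to_numpy(), ladder
    )
    from scipy.stats import norm

    bonf_t = float(norm.ppf(1 - 0.05 / (2 * 2)))  # two-test family, two-sided
    continuous = ModelFitResult(frame_c, conv_c, len(sub), label_c, sig_threshold=bonf_t)
    return ModelFitResult(frame, conv, len(sub), label, continuous_variant=continuous)


# ---------------------------------------------------------------------------
# whole-pipeline drivers
# ---------------------------------------------------------------------------

REGIONS = ("preamble", "ambiguous_region", "disambiguating_region", "final_word")


def run_pipeline(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Exclusion -> length correction -> region aggregation.

    Returns the region table and the exclusion loss fraction.  Counts
    reconcile at every boundary: kept words equal the words entering the
    length correction, and every kept word contributes to exactly one
    region-table row.
    """
    kept, loss = exclude_rts(records)
    corrected, _ = length_correct(kept)
    assert len(corrected) == len(kept), "length correction dropped rows"
    table = aggregate_regions(corrected)
    assert int(table["n_words"].sum()) == len(kept), "aggregation lost words"
    return table, loss


def analyze_exp1(records: pd.DataFrame) -> dict[str, ModelFitResult]:
    """Factorial adaptation model at each of the four sentence regions."""
    table, loss = run_pipeline(records)
    logger.info("exclusion loss fraction: %.4f", loss)
    return {region: fit_adaptation_model(table, region=region) for region in REGIONS}


def analyze_exp2(records: pd.DataFrame) -> dict[str, dict[str, ModelFitResult]]:
    """Q1-Q3 analyses at each of the four sentence regions."""
    table, loss = run_pipeline(records)
    logger.info("exclusion loss fraction: %.4f", loss)
    return {
        q: {region: exp2_analyses(table, q, region=region) for region in REGIONS}
        for q in ("Q1", "Q2", "Q3")
    }


def recovery_study(
    n_replicates: int,
    seed: int = 0,
    n_subjects: int = 72,
    adaptation: bool = True,
    region_effects: bool = True,
    alpha0: float = 1.0,
    include_simple: bool = True,
) -> pd.DataFrame:
    """Repeated generate-and-analyze runs of the interleaved design.

    Each replicate builds a fresh design and dataset from a derived seed,
    runs the full pipeline, and records the focal coefficients: the
    three-way adaptation interaction and the RC/MV simple-effect slopes.
    With ``adaptation=False`` the belief prior is made effectively
    immovable; with ``region_effects=False`` no garden-path costs are
    generated at all (the null generator for type-I calibration).
    """
    from .belief import PriorConfig
    from .generate import build_design_exp1, generate_dataset

    if n_replicates < 2:
        raise PipelineError(f"n_replicates must be >= 2, got {n_replicates}")
    prior = PriorConfig(alpha0=alpha0 if adaptation else 1e9)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n_replicates)]
    rows = []
    for rep, rep_seed in enumerate(seeds):
        design = build_design_exp1(n_subjects=n_subjects, seed=rep_seed)
        records = generate_dataset(
            design, prior=prior, seed=rep_seed, region_effects=region_effects
        )
        table, loss = run_pipeline(records)
        full = fit_adaptation_model(table)
        row = {
            "replicate": rep,
            "seed": rep_seed,
            "loss_fraction": loss,
            "three_way_beta": full.coef("sentence_type:ambiguity:item_order"),
            "three_way_t": full.tvalue("sentence_type:ambiguity:item_order"),
        }
        if include_simple:
            rc = simple_effects(table, "RC")
            mv = simple_effects(table, "MV")
            row.update(
                rc_slope_beta=rc.coef("ambiguity:item_order"),
                rc_slope_t=rc.tvalue("ambiguity:item_order"),
                mv_slope_beta=mv.coef("ambiguity:item_order"),
                mv_slope_t=mv.tvalue("ambiguity:item_order"),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_summary(study: pd.DataFrame) -> dict[str, float]:
    """Sign-recovery and rejection rates for a recovery study."""
    out = {
        "n_replicates": int(len(study)),
        "three_way_positive_rate": float((study["three_way_beta"] > 0).mean()),
        "three_way_rejection_rate": float(
            (study["three_way_t"].abs() >= SIGNIFICANCE_T).mean()
        ),
        "mean_loss_fraction": float(study["loss_fraction"].mean()),
    }
    if "rc_slope_beta" in study.columns:
        out.update(
            rc_slope_negative_rate=float((study["rc_slope_beta"] < 0).mean()),
            mean_rc_slope=float(study["rc_slope_beta"].mean()),
            mean_mv_slope=float(study["mv_slope_beta"].mean()),
        )
    return out


def export_results(fits: dict[str, ModelFitResult], path) -> None:
    """Write region-keyed fit results as the results CSV dialect."""
    frames = [fit.to_frame(region=key) for key, fit in fits.items()]
    out = pd.concat(frames, ignore_index=True)
    out[["region", "predictor", "beta", "t_value", "significant"]].to_csv(
        path, index=False
    )
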