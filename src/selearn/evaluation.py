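"""Model evaluation: LOO comparison, evidence classes, correlations, generative checks.

The generative-performance protocol simulates full cohorts from a population
configuration, computes each subject's percent-positive choices per persona,
runs the study's linear-mixed-effects test (BFNE x referent x persona with a
random intercept per participant) on every simulated dataset, and reports the
mean coefficient and the fraction of datasets in which each contrast is
significant. The reference levels are the self referent and the dislike
persona, so the BFNE main effect is the BFNE slope in self blocks and the
"self/other" contrast is the shift for the other referent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PopulationConfig, generate_cohort
from .errors import ComparisonError
from .inference import HierFit, MleFit
from .task import SessionData, percent_positive

# ---------------------------------------------------------------------------
# PSIS-LOO model comparison

@dataclass
class LooResult:
    """Expected log predictive density (PSIS-LOO) of one model."""

    label: str
    elpd: float
    se: float
    p_loo: float
    elpd_diff: float  # vs best model (best has 0)
    diff_se: float
    pointwise: np.ndarray
    pareto_k_frac: float  # fraction of observations with k > 0.7


def loo_compare(
    fits: list[HierFit],
    labels: list[str] | None = None,
    unit: str = "trial",
) -> list[LooResult]:
    """Rank hierarchical fits of the same data by PSIS-LOO.

    Pointwise predictive densities are per trial by default (``unit='subject'``
    sums each subject's trials into one unit). Pairwise difference standard
    errors use the paired pointwise contributions against the best model.
    """
    import arviz as az

    if labels is None:
        labels = [f"model_{i}" for i in range(len(fits))]
    fp = {f.data_fingerprint for f in fits}
    if len(fp) != 1:
        raise ComparisonError("fits were computed on different data")
    results = []
    for label, fit in zip(labels, fits):
        idata = fit.to_inference_data(unit=unit)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loo = az.loo(idata, pointwise=True)
        k = np.asarray(loo.pareto_k)
        results.append(
            LooResult(
                label=label,
                elpd=float(loo.elpd_loo),
                se=float(loo.se),
                p_loo=float(loo.p_loo),
                elpd_diff=0.0,
                diff_se=0.0,
                pointwise=np.asarray(loo.loo_i),
                pareto_k_frac=float(np.mean(k > 0.7)),
            )
        )
    best = max(results, key=lambda r: r.elpd)
    for r in results:
        if r is best:
            continue
        d = best.pointwise - r.pointwise
        r.elpd_diff = float(d.sum())
        r.diff_se = float(np.sqrt(len(d) * d.var()))
    results.sort(key=lambda r: -r.elpd)
    for r in results:
        if r.pareto_k_frac > 0.1:
            warnings.warn(
                f"{r.label}: {100 * r.pareto_k_frac:.0f}% of observations have "
                "Pareto k > 0.7; LOO may be unreliable",
                RuntimeWarning,
            )
    return results


# ---------------------------------------------------------------------------
# Individual-level evidence classification

@dataclass(frozen=True)
class EvidenceClass:
    """Per-subject likelihood-difference evidence class (model A vs model B)."""

    participant_id: str
    delta_loglik: float  # logL_A - logL_B
    label: str  # strong_A | mild_A | none | mild_B | strong_B


def _classify(delta: float) -> str:
    if abs(delta) < 3.0:
        return "none"
    side = "A" if delta > 0 else "B"
    return ("mild_" if abs(delta) < 6.0 else "strong_") + side


def classify_evidence(mle_a: MleFit, mle_b: MleFit) -> list[EvidenceClass]:
    """Classify each subject by the ML log-likelihood difference (A minus B).

    Boundaries at |delta| = 3 (mild) and 6 (strong), the conventional
    individual-evidence thresholds.
    """
    if mle_a.participant_ids != mle_b.participant_ids:
        raise ComparisonError("fits cover different participants")
    out = []
    for pid, la, lb in zip(
        mle_a.participant_ids, mle_a.total_loglik, mle_b.total_loglik
    ):
        d = float(la - lb)
        out.append(EvidenceClass(participant_id=pid, delta_loglik=d, label=_classify(d)))
    return out


# ---------------------------------------------------------------------------
# Parameter correlations

def correlate_parameters(
    param_table: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Spearman rank correlation for each requested column pair."""
    rows = []
    for a, b in pairs:
        xa = param_table[a].to_numpy(dtype=float)
        xb = param_table[b].to_numpy(dtype=float)
        if np.all(xa == xa[0]) or np.all(xb == xb[0]):
            raise ComparisonError(f"correlation of constant column in pair ({a}, {b})")
        rho, p = stats.spearmanr(xa, xb)
        rows.append({"x": a, "y": b, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Generative-performance protocol

#: model-term -> readable contrast label (self and dislike are reference levels)
_CONTRASTS = {
    "bfne": "bfne",
    "is_other": "selfother",
    "rule_like": "persona_like",
    "rule_neutral": "persona_neutral",
    "bfne:is_other": "bfne_x_selfother",
    "bfne:rule_like": "bfne_x_persona_like",
    "bfne:rule_neutral": "bfne_x_persona_neutral",
    "is_other:rule_like": "selfother_x_persona_like",
    "is_other:rule_neutral": "selfother_x_persona_neutral",
    "bfne:is_other:rule_like": "bfne_x_selfother_x_persona_like",
    "bfne:is_other:rule_neutral": "bfne_x_selfother_x_persona_neutral",
}


@dataclass
class GenerativeCheckReport:
    """LME contrasts across simulated datasets and the fraction significant."""

    per_dataset: pd.DataFrame  # dataset, contrast, coef, pvalue
    aggregate: pd.DataFrame  # contrast, mean_coef, lower95, upper95, pct_significant
    n_datasets: int
    n_excluded: int


def percent_positive_table(sessions: list[SessionData]) -> pd.DataFrame:
    """Per subject x persona percent-positive summary used by the LME."""
    rows = []
    for s in sessions:
        for block in s.blocks:
            persona = s.personas[block[0].persona_index]
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "bfne": s.bfne,
                    "is_other": 1.0 if persona.referent == "other" else 0.0,
                    "rule": persona.rule,
                    "pct_positive": percent_positive(block),
                }
            )
    return pd.DataFrame(rows)


def lme_contrasts(table: pd.DataFrame) -> pd.DataFrame:
    """Fit the mixed model and return one row per contrast with p-values.

    Random intercept per participant; fixed effects BFNE (raw scale) crossed
    with referent (self reference) and persona rule (dislike reference).
    """
    import statsmodels.formula.api as smf

    df = table.copy()
    df["rule_like"] = (df["rule"] == "like").astype(float)
    df["rule_neutral"] = (df["rule"] == "neutral").astype(float)
    formula = "pct_positive ~ bfne * is_other * (rule_like + rule_neutral)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["participant_id"])
        try:
            fit = model.fit(reml=True, method="bfgs")
        except np.linalg.LinAlgError:
            fit = model.fit(reml=True, method="powell")
    rows = []
    for term, label in _CONTRASTS.items():
        coef = float(fit.params[term])
        p = float(fit.pvalues[term])
        if not (np.isfinite(coef) and np.isfinite(p)):
            raise ComparisonError(f"singular mixed-model fit: term {term} undefined")
        rows.append({"contrast": label, "coef": coef, "pvalue": p})
    return pd.DataFrame(rows)


def generative_check(
    population: PopulationConfig,
    n_datasets: int = 10,
    n_subjects: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> GenerativeCheckReport:
    """Simulate datasets from a population and score the study's LME contrasts.

    Each dataset is an independent cohort of ``n_subjects``; datasets whose LME
    fit fails or does not converge are excluded (with a warning). Defaults are
    scaled down from the ideal-experiment protocol (100 datasets of 1000
    subjects), which remains available via the arguments.
    """
    cfg = population.with_updates(n_subjects=n_subjects)
    ss = np.random.SeedSequence(seed)
    frames = []
    n_excluded = 0
    for d, child in enumerate(ss.spawn(n_datasets)):
        cohort = generate_cohort(cfg, np.random.default_rng(child))
        table = percent_positive_table(cohort.sessions)
        try:
            res = lme_contrasts(table)
        except Exception as e:  # singular / non-converged fits
            warnings.warn(f"dataset {d} excluded from aggregation: {e}", RuntimeWarning)
            n_excluded += 1
            continue
        res.insert(0, "dataset", d)
        frames.append(res)
    if not frames:
        raise ComparisonError("every simulated dataset failed the LME fit")
    per_dataset = pd.concat(frames, ignore_index=True)
    agg = (
        per_dataset.groupby("contrast", sort=False)
        .apply(
            lambda g: pd.Series(
                {
                    "mean_coef": g["coef"].mean(),
                    "lower95": g["coef"].quantile(0.025),
                    "upper95": g["coef"].quantile(0.975),
                    "pct_significant": 100.0 * (g["pvalue"] < alpha).mean(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return GenerativeCheckReport(
        per_dataset=per_dataset,
        aggregate=agg,
        n_datasets=n_datasets,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Learning curves

def learning_curves(
    sessions: list[SessionData], bfne_split: bool = True
) -> pd.DataFrame:
    """Mean cumulative positive-choice trajectories by persona (and BFNE split).

    Returns one row per (referent, rule, group, trial_index) with the mean and
    SEM of the cumulative count of positive choices up to that trial.
    """
    if not sessions:
        raise ValueError("need at least one session")
    if bfne_split and len(sessions) > 1:
        med = float(np.median([s.bfne for s in sessions]))
        group_of = lambda s: "high_bfne" if s.bfne > med else "low_bfne"
    else:
        group_of = lambda s: "all"
    acc: dict[tuple, list[np.ndarray]] = {}
    for s in sessions:
        for block in s.blocks:
            persona = s.personas[block[0].persona_index]
            cum = np.cumsum([t.choice == "positive" for t in block])
            acc.setdefault((persona.referent, persona.rule, group_of(s)), []).append(cum)
    rows = []
    for (ref, rule, grp), curves in sorted(acc.items()):
        mat = np.vstack(curves)
        mean = mat.mean(axis=0)
        sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
        for t in range(mat.shape[1]):
            rows.append(
                {
                    "referent": ref,
                    "rule": rule,
                    "group": grp,
                    "trial_index": t,
                    "mean_cumulative_positive": float(mean[t]),
                    "sem": float(sem[t]),
                }
            )
    return pd.DataFrame(rows)


def plot_learning_curves(curves: pd.DataFrame, path=None):
    """Plot cumulative positive-choice curves (one panel per referent)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    referents = sorted(curves["referent"].unique())
    fig, axes = plt.subplots(1, len(referents), figsize=(5 * len(referents), 4),
                             squeeze=False)
    palette = {"like": "tab:green", "neutral": "tab:gray", "dislike": "tab:red"}
    for ax, ref in zip(axes[0], referents):
        sub = curves[curves["referent"] == ref]
        for (rule, grp), g in sub.groupby(["rule", "group"]):
            style = "-" if grp in ("all", "low_bfne") else "--"
            ax.plot(
                g["trial_index"], g["mean_cumulative_positive"],
                style, color=palette.get(rule, "k"), label=f"{rule} ({grp})",
            )
            ax.fill_between(
                g["trial_index"],
                g["mean_cumulative_positive"] - g["sem"],
                g["mean_cumulative_positive"] + g["sem"],
                color=palette.get(rule, "k"), alpha=0.15,
            )
        ax.set_title(f"referent: {ref}")
        ax.set_xlabel("trial")
        ax.set_ylabel("cumulative positive choices")
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
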